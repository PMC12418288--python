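"""Between-host distance matrices: phylogenetic (PD), trait-based Gower (TD),
geographic (GD) and environmental (ED), each normalized to [0, 1].

The four matrices share one container, :class:`DistanceMatrix`, which keeps
the host ordering, the distance kind and whether the matrix has been
normalized.  Normalization divides every entry by the maximum off-diagonal
entry so that distances range from zero to unity.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import grids, trees

KINDS = ("PD", "TD", "GD", "ED")


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative host x host distance matrix."""

    labels: list[str]
    values: np.ndarray = field(repr=False)
    kind: str = "PD"
    normalized: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if (v < 0).any():
            raise ValueError("distances must be nonnegative")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-10):
            raise ValueError("diagonal must be zero")
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        idx = pd.Index(self.labels, name="host_id")
        return pd.DataFrame(self.values, index=idx, columns=idx)

    def lookup(self, a: str, b: str) -> float:
        ia, ib = self.labels.index(a), self.labels.index(b)
        return float(self.values[ia, ib])


def normalize01(dm: DistanceMatrix) -> DistanceMatrix:
    """Rescale so the largest off-diagonal entry is 1.

    Order of entries is preserved (monotone scaling).  An all-zero matrix is
    returned unchanged with a warning.
    """
    v = dm.values
    off = v[~np.eye(len(dm.labels), dtype=bool)]
    m = off.max() if off.size else 0.0
    if m == 0.0:
        warnings.warn("all distances are zero; normalization skipped")
        return DistanceMatrix(dm.labels, v.copy(), dm.kind, normalized=True)
    return DistanceMatrix(dm.labels, v / m, dm.kind, normalized=True)


def phylogenetic_distance(tree, normalize: bool = True) -> DistanceMatrix:
    """PD: cophenetic distances from a (previously ultrametrized, binary) tree."""
    coph = trees.cophenetic_matrix(tree)
    dm = DistanceMatrix(list(coph.index), coph.to_numpy(), kind="PD")
    return normalize01(dm) if normalize else dm


# ---------------------------------------------------------------------------
# Trait (Gower) distance

@dataclass(frozen=True)
class Trait:
    name: str
    scale: str  # continuous | binary | categorical
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.scale not in ("continuous", "binary", "categorical"):
            raise ValueError(f"unknown trait scale {self.scale!r}")
        if self.weight <= 0:
            raise ValueError("trait weights must be positive")


def default_trait_spec(traits: pd.DataFrame) -> list[Trait]:
    """Infer a TraitSpec from column dtypes: object/categorical columns are
    categorical, {0,1}-valued numeric columns binary, the rest continuous."""
    spec = []
    for col in traits.columns:
        s = traits[col]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            scale = "categorical"
        elif s.dropna().isin([0, 1]).all():
            scale = "binary"
        else:
            scale = "continuous"
        spec.append(Trait(col, scale))
    return spec


def normalize_continuous_traits(traits: pd.DataFrame, spec: list[Trait]) -> pd.DataFrame:
    """Min-max scale every continuous trait to [0, 1] (constant columns left as 0)."""
    out = traits.copy()
    for t in spec:
        if t.scale != "continuous":
            continue
        col = pd.to_numeric(out[t.name])
        rng = col.max() - col.min()
        out[t.name] = (col - col.min()) / rng if rng > 0 else 0.0 * col
    return out


def gower_matrix(traits: pd.DataFrame, spec: list[Trait] | None = None,
                 normalize: bool = False) -> DistanceMatrix:
    """Gower mixed-type dissimilarity between hosts (rows of ``traits``).

    d(i,j) = sum_k w_k * delta_ijk * d_ijk / sum_k w_k * delta_ijk, with
    d_ijk = |x_ik - x_jk| / range_k for continuous traits and a mismatch
    indicator for binary/categorical ones; delta_ijk = 0 when either value
    is missing (pairwise trait exclusion).  Constant continuous traits
    (range 0) are dropped with a warning.  Gower distances already lie in
    [0, 1]; pass ``normalize=True`` to additionally rescale the max to 1.
    """
    if len(traits) < 2:
        raise ValueError("need at least 2 hosts")
    if spec is None:
        spec = default_trait_spec(traits)
    missing_cols = [t.name for t in spec if t.name not in traits.columns]
    if missing_cols:
        raise ValueError(f"traits table lacks declared columns: {missing_cols}")

    n = len(traits)
    labels = [str(h) for h in traits.index]
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    for t in spec:
        col = traits[t.name]
        valid = col.notna().to_numpy()
        both = np.outer(valid, valid)
        if t.scale == "continuous":
            x = pd.to_numeric(col).to_numpy(float)
            rng = np.nanmax(x) - np.nanmin(x)
            if not np.isfinite(rng) or rng == 0:
                warnings.warn(f"constant continuous trait {t.name!r} dropped")
                continue
            with np.errstate(invalid="ignore"):
                d = np.abs(x[:, None] - x[None, :]) / rng
            d = np.where(both, d, 0.0)
        else:
            codes = pd.factorize(col, use_na_sentinel=True)[0]
            d = (codes[:, None] != codes[None, :]).astype(float)
            d = np.where(both, d, 0.0)
        num += t.weight * np.where(both, d, 0.0)
        den += t.weight * both
    np.fill_diagonal(den, 1.0)  # diagonal distance is 0 regardless
    np.fill_diagonal(num, 0.0)
    bad = np.argwhere((den == 0) & ~np.eye(n, dtype=bool))
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"hosts {labels[i]!r} and {labels[j]!r} share no comparable trait"
        )
    d = num / den
    d = (d + d.T) / 2
    dm = DistanceMatrix(labels, d, kind="TD")
    return normalize01(dm) if normalize else dm


# ---------------------------------------------------------------------------
# Environmental distance

def environmental_profile(env_layers: pd.DataFrame, grid: grids.GridSpec,
                          centroid_lon: float, centroid_lat: float,
                          buffer_km: float = 100.0) -> pd.Series:
    """Mean of each environmental variable over grid cells whose centers lie
    within ``buffer_km`` (haversine) of the centroid.

    ``env_layers`` is a cell x variable frame in row-major cell order.  The
    cell nearest the centroid is always included; if no cell center falls
    inside the buffer the nearest cell is used with a warning.
    """
    if len(env_layers) != grid.n_cells:
        raise ValueError("environmental layers do not match the grid")
    centers = grid.cell_centers()
    d = grids.haversine(centroid_lon, centroid_lat, centers[:, 0], centers[:, 1])
    sel = d <= buffer_km
    sel[np.argmin(d)] = True  # the centroid's own (nearest) cell
    if sel.sum() == 1 and d.min() > buffer_km:
        warnings.warn("no cell center within buffer; using nearest cell")
    return env_layers.iloc[sel].mean(axis=0)


def environmental_profiles(env_layers: pd.DataFrame, grid: grids.GridSpec,
                           centroids: pd.DataFrame,
                           buffer_km: float = 100.0) -> pd.DataFrame:
    """Per-host environmental profiles at each host's range centroid."""
    rows = {
        host: environmental_profile(env_layers, grid,
                                    row["centroid_lon"], row["centroid_lat"],
                                    buffer_km)
        for host, row in centroids.iterrows()
    }
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("host_id")


def env_pca_distance(profiles: pd.DataFrame, n_components: int | None = None,
                     min_variance: float = 0.75, normalize: bool = True,
                     ) -> tuple[DistanceMatrix, dict]:
    """ED: Euclidean distance between hosts in retained principal-component
    space of their environmental profiles.

    Variables are centered and scaled to unit variance, so the PCA is an
    eigendecomposition of the correlation matrix.  ``n_components`` retains
    a fixed count; otherwise the smallest count whose cumulative explained
    variance reaches ``min_variance`` is used.  Zero-variance variables are
    dropped with a warning.  Returns the distance matrix and a report with
    per-component variance fractions.
    """
    if len(profiles) < 3:
        raise ValueError("need at least 3 hosts for a PCA-based distance")
    x = profiles.to_numpy(float)
    sd = x.std(axis=0, ddof=1)
    keep = sd > 0
    dropped = list(profiles.columns[~keep])
    if dropped:
        warnings.warn(f"zero-variance environmental variables dropped: {dropped}")
    x = x[:, keep]
    sd = sd[keep]
    p = x.shape[1]
    labels = [str(h) for h in profiles.index]
    if p == 0:  # identical profiles: no informative variable, all distances 0
        warnings.warn("all environmental variables are constant; distances are 0")
        dm = DistanceMatrix(labels, np.zeros((len(labels), len(labels))), kind="ED",
                            normalized=normalize)
        return dm, {"n_components": 0, "variance_fractions": [],
                    "cumulative_variance": 0.0, "dropped_variables": dropped}
    if n_components is not None and n_components > p:
        raise ValueError(f"n_components={n_components} exceeds {p} variables")
    z = (x - x.mean(axis=0)) / sd
    corr = (z.T @ z) / (len(z) - 1)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    frac = evals / evals.sum()
    if n_components is None:
        n_components = int(np.searchsorted(np.cumsum(frac), min_variance) + 1)
        n_components = min(n_components, p)
    scores = z @ evecs[:, :n_components]
    diff = scores[:, None, :] - scores[None, :, :]
    d = np.sqrt((diff**2).sum(axis=-1))
    np.fill_diagonal(d, 0.0)
    dm = DistanceMatrix(labels, (d + d.T) / 2, kind="ED")
    report = {
        "n_components": int(n_components),
        "variance_fractions": frac.tolist(),
        "cumulative_variance": float(np.cumsum(frac)[n_components - 1]),
        "dropped_variables": dropped,
    }
    if normalize:
        dm = normalize01(dm)
    return dm, report


def geographic_distance(centroids: pd.DataFrame, normalize: bool = True) -> DistanceMatrix:
    """GD: pairwise haversine distances between range centroids."""
    h = grids.haversine_matrix(centroids)
    dm = DistanceMatrix([str(i) for i in h.index], h.to_numpy(), kind="GD")
    return normalize01(dm) if normalize else dm
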