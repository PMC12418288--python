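"""Probability of parasite sharing between hosts as a function of between-host
distance.

For every parasite recorded on at least ``min_hosts`` hosts, each carrier is
treated as a potential source: carrier-carrier pairs are positive cases and
a random balanced sample of non-carriers provides the negatives.  A logistic
regression of the case response on the (normalized) between-host distance D
yields per-parasite intercepts and slopes; a species bootstrap (random sets
of parasites, refitted with fresh negative samples) yields the pooled mean
intercept a and slope b of the sharing curve

    P(D) = 1 / (1 + exp(-(a + b * D))),

together with PNS, the proportion of parasites with a negative slope.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

from .distances import DistanceMatrix


@dataclass
class SharingCases:
    """Pooled source->target cases for one parasite."""

    parasite_id: str
    distance: np.ndarray
    response: np.ndarray

    def __len__(self) -> int:
        return len(self.response)


@dataclass
class LogisticFit:
    intercept: float
    slope: float
    converged: bool
    n_cases: int
    n_iterations: int = 0


@dataclass
class SharingFit:
    """Result of the pooled sharing analysis for one distance type."""

    per_parasite: pd.DataFrame = field(repr=False)  # parasite_id, n_hosts, a_p, b_p, converged
    pooled_intercept: float = np.nan
    pooled_slope: float = np.nan
    bootstrap_intercepts: np.ndarray = field(default=None, repr=False)
    bootstrap_slopes: np.ndarray = field(default=None, repr=False)
    pns: float = np.nan
    n_iter: int = 0
    distance_kind: str = ""


def eligible_parasites(incidence: pd.DataFrame, min_hosts: int = 6) -> list[str]:
    """Parasites recorded on at least ``min_hosts`` host species, in the
    incidence matrix's row order."""
    counts = incidence.sum(axis=1)
    out = [str(p) for p, c in counts.items() if c >= min_hosts]
    if not out:
        warnings.warn(f"no parasite is recorded on >= {min_hosts} hosts")
    return out


def build_sharing_cases(parasite: str, incidence: pd.DataFrame,
                        dmatrix: DistanceMatrix, rng: np.random.Generator,
                        ) -> SharingCases:
    """Construct the case list for one parasite.

    Every carrier host s acts as a source: one response-1 case per other
    carrier t (D = dmatrix[s, t]) and one response-0 case per member of a
    uniform without-replacement sample of non-carriers, of size
    min(#carriers - 1, #non-carriers) per source (balanced negatives).
    """
    hosts = [str(h) for h in incidence.columns]
    if hosts != list(dmatrix.labels):
        raise ValueError("incidence hosts do not match distance-matrix labels")
    row = incidence.loc[parasite].to_numpy()
    # order by host label so results are equivariant under a simultaneous
    # permutation of hosts in the incidence and distance matrices
    label_order = np.argsort(np.asarray(hosts))
    carriers = label_order[row[label_order] == 1]
    non_carriers = label_order[row[label_order] == 0]
    if len(non_carriers) == 0:
        raise ValueError(f"parasite {parasite!r} infests every host; no negatives available")
    d = dmatrix.values
    n_neg = min(len(carriers) - 1, len(non_carriers))
    dist_parts, resp_parts = [], []
    for s in carriers:
        others = carriers[carriers != s]
        dist_parts.append(d[s, others])
        resp_parts.append(np.ones(len(others)))
        neg = rng.choice(non_carriers, size=n_neg, replace=False)
        dist_parts.append(d[s, neg])
        resp_parts.append(np.zeros(n_neg))
    return SharingCases(parasite, np.concatenate(dist_parts), np.concatenate(resp_parts))


def fit_sharing_logistic(cases: SharingCases, max_iter: int = 100,
                         tol: float = 1e-10, coef_bound: float = 50.0) -> LogisticFit:
    """Maximum-likelihood logistic regression of the case response on D via
    iteratively reweighted least squares.

    Convergence requires the log-likelihood change to drop below ``tol``.
    Complete or quasi-complete separation (diverging coefficients) and
    degenerate designs (constant D) are flagged as non-converged.
    """
    d = np.asarray(cases.distance, float)
    y = np.asarray(cases.response, float)
    if y.min() == y.max():
        raise ValueError("cases must include both response classes")
    if np.ptp(d) == 0.0:
        return LogisticFit(np.nan, np.nan, converged=False, n_cases=len(y))
    x = np.column_stack([np.ones_like(d), d])
    beta = np.zeros(2)
    ll_old = -np.inf
    for it in range(1, max_iter + 1):
        eta = x @ beta
        p = special.expit(eta)
        ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
        w = p * (1.0 - p)
        if not np.isfinite(ll) or w.max() < 1e-12:
            return LogisticFit(np.nan, np.nan, converged=False, n_cases=len(y), n_iterations=it)
        xtw = x.T * w
        try:
            beta = beta + np.linalg.solve(xtw @ x, x.T @ (y - p))
        except np.linalg.LinAlgError:
            return LogisticFit(np.nan, np.nan, converged=False, n_cases=len(y), n_iterations=it)
        if np.abs(beta).max() > coef_bound:  # separation guard
            return LogisticFit(np.nan, np.nan, converged=False, n_cases=len(y), n_iterations=it)
        if abs(ll - ll_old) < tol:
            return LogisticFit(float(beta[0]), float(beta[1]), converged=True,
                               n_cases=len(y), n_iterations=it)
        ll_old = ll
    return LogisticFit(np.nan, np.nan, converged=False, n_cases=len(y), n_iterations=max_iter)


def fit_parasites(parasites: list[str], incidence: pd.DataFrame,
                   dmatrix: DistanceMatrix, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    host_counts = incidence.sum(axis=1)
    for p in parasites:
        fit = fit_sharing_logistic(build_sharing_cases(p, incidence, dmatrix, rng))
        rows.append({"parasite_id": p, "n_hosts": int(host_counts[p]),
                     "a_p": fit.intercept, "b_p": fit.slope,
                     "converged": fit.converged})
    return pd.DataFrame(rows)


def pns(per_parasite_fits: pd.DataFrame) -> float:
    """Proportion of converged per-parasite fits with a negative slope
    (a slope of exactly 0 counts as non-negative)."""
    conv = per_parasite_fits[per_parasite_fits["converged"]]
    if len(conv) == 0:
        raise ValueError("no converged per-parasite fits; PNS undefined")
    return float((conv["b_p"] < 0).mean())


def pooled_coefficients(incidence: pd.DataFrame, dmatrix: DistanceMatrix,
                        n_iter: int = 1000, seed: int = 0, min_hosts: int = 6,
                        bootstrap: str = "with_replacement",
                        max_dropped_frac: float = 0.10) -> SharingFit:
    """Species-bootstrap pooled sharing coefficients.

    Per-parasite logistic fits are computed once (these give PNS); then
    ``n_iter`` bootstrap iterations each draw a random set of eligible
    parasites (with replacement, at the full pool size, by default), refit
    every drawn parasite with fresh negative samples, and record the
    iteration's mean intercept and slope.  The pooled coefficients are the
    means of those iteration means — the central tendency of each
    coefficient distribution.
    """
    if not dmatrix.normalized:
        raise ValueError("distance matrix must be normalized to [0, 1]")
    pool = eligible_parasites(incidence, min_hosts)
    if not pool:
        raise ValueError("no eligible parasites")
    rng = np.random.default_rng(seed)
    per_parasite = fit_parasites(pool, incidence, dmatrix, rng)
    prop_neg = pns(per_parasite)

    boot_a = np.full(n_iter, np.nan)
    boot_b = np.full(n_iter, np.nan)
    dropped = 0
    for it in range(n_iter):
        if bootstrap == "with_replacement":
            chosen = [pool[i] for i in rng.integers(0, len(pool), size=len(pool))]
        elif bootstrap == "without_replacement":
            size = max(1, len(pool) // 2)
            chosen = [pool[i] for i in rng.choice(len(pool), size=size, replace=False)]
        else:
            raise ValueError(f"unknown bootstrap rule {bootstrap!r}")
        fits = fit_parasites(chosen, incidence, dmatrix, rng)
        conv = fits[fits["converged"]]
        if len(conv) == 0:
            dropped += 1
            continue
        boot_a[it] = conv["a_p"].mean()
        boot_b[it] = conv["b_p"].mean()
    if dropped:
        warnings.warn(f"{dropped} of {n_iter} bootstrap iterations had no converged fit")
        if dropped > max_dropped_frac * n_iter:
            raise RuntimeError(
                f"{dropped}/{n_iter} bootstrap iterations dropped; data too unstable"
            )
    return SharingFit(
        per_parasite=per_parasite,
        pooled_intercept=float(np.nanmean(boot_a)),
        pooled_slope=float(np.nanmean(boot_b)),
        bootstrap_intercepts=boot_a,
        bootstrap_slopes=boot_b,
        pns=prop_neg,
        n_iter=n_iter,
        distance_kind=dmatrix.kind,
    )


def sharing_probability(a: float, b: float, d_grid: np.ndarray) -> np.ndarray:
    """Sharing-probability curve P(D) = 1 / (1 + exp(-(a + b*D))).

    With b < 0 the curve decreases in D: sharing is less likely between more
    distant hosts.
    """
    d_grid = np.asarray(d_grid, float)
    if d_grid.size and (d_grid.min() < 0 or d_grid.max() > 1):
        raise ValueError("D grid must lie in [0, 1]")
    return special.expit(a + b * d_grid)
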