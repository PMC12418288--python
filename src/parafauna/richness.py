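"""Host-level determinants of parasite species richness.

Species richness per host (the column sums of a parasite x host incidence
matrix) is modelled with a negative-binomial (NB2) GLM with a log link on
four predictors: ln body mass (ln_BM), ln geographic range size (ln_GR),
ln diversity field (ln_DF) and habitat breadth (HB).  All 16 predictor
subsets are fitted and ranked by AIC.  Before modelling, a Blomberg
phylogenetic-signal test on richness decides whether a phylogenetically
corrected model would be needed (the pipeline warns, it does not correct).
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, special

from . import trees

PREDICTORS = ("ln_BM", "ln_GR", "ln_DF", "HB")


def build_richness_dataset(incidence: pd.DataFrame, traits: pd.DataFrame,
                           range_summary: pd.DataFrame,
                           body_mass_col: str = "body_mass_g",
                           habitat_breadth_col: str = "habitat_breadth",
                           exclude_hosts: tuple[str, ...] = ()) -> pd.DataFrame:
    """Assemble the per-host richness table from pipeline artifacts.

    Richness is the number of parasite species recorded per host (column
    sums of the incidence matrix).  Body mass, range size and diversity
    field are ln-transformed; hosts with a zero diversity field get
    ln(DF + 1) with a warning.  ``exclude_hosts`` removes ubiquitous,
    cosmopolitan hosts that would otherwise dominate the ranges.
    """
    hosts = [h for h in incidence.columns if h not in set(exclude_hosts)]
    richness = incidence[hosts].sum(axis=0)
    df_raw = range_summary.loc[hosts, "diversity_field"]
    if (df_raw == 0).any():
        warnings.warn(
            f"{int((df_raw == 0).sum())} hosts have an empty diversity field; "
            "using ln(DF + 1) for them"
        )
        ln_df = np.where(df_raw > 0, np.log(df_raw.where(df_raw > 0, 1.0)), np.log1p(df_raw))
    else:
        ln_df = np.log(df_raw)
    out = pd.DataFrame(
        {
            "richness": richness.astype(int),
            "ln_BM": np.log(traits.loc[hosts, body_mass_col].astype(float)),
            "ln_GR": np.log(range_summary.loc[hosts, "range_size_km2"]),
            "ln_DF": ln_df,
            "HB": traits.loc[hosts, habitat_breadth_col].astype(float),
        },
        index=pd.Index(hosts, name="host_id"),
    )
    if not np.isfinite(out.to_numpy()).all():
        raise ValueError("non-finite predictor or response values")
    return out


# ---------------------------------------------------------------------------
# NB2 GLM with glm.nb-style alternating estimation


@dataclass
class NBModelFit:
    """A fitted NB2 log-link GLM."""

    predictors: tuple[str, ...]
    coefficients: pd.Series
    theta: float
    log_likelihood: float
    aic: float
    deviance: float
    null_deviance: float | None = None
    explained_deviance_percent: float | None = None
    nagelkerke_r2: float | None = None
    bse: pd.Series | None = field(default=None, repr=False)
    converged: bool = True
    n_obs: int = 0
    # response and fitted means, kept so explained deviance can be computed
    # on a common dispersion scale
    y: np.ndarray | None = field(default=None, repr=False)
    mu: np.ndarray | None = field(default=None, repr=False)

    @property
    def k_params(self) -> int:
        """Number of estimated parameters including theta."""
        return len(self.coefficients) + 1


def _nb2_loglik(y: np.ndarray, mu: np.ndarray, theta: float) -> float:
    return float(
        np.sum(
            special.gammaln(y + theta)
            - special.gammaln(theta)
            - special.gammaln(y + 1)
            + theta * np.log(theta / (theta + mu))
            + y * np.log(mu / (theta + mu))
        )
    )


def _update_theta(y: np.ndarray, mu: np.ndarray, theta0: float) -> float:
    """Univariate ML update of the NB dispersion for fixed means."""
    def nll(log_theta: float) -> float:
        return -_nb2_loglik(y, mu, np.exp(log_theta))

    res = optimize.minimize_scalar(nll, bracket=(np.log(theta0) - 1, np.log(theta0) + 1),
                                   method="brent", options={"xtol": 1e-10})
    return float(np.exp(np.clip(res.x, -15, 15)))


def nb_glm_fit(y, X: pd.DataFrame, max_iter: int = 200, tol: float = 1e-8) -> NBModelFit:
    """Fit an NB2 GLM with a log link by alternating IRLS for the coefficients
    (at fixed dispersion) with univariate ML updates of theta, until the
    log-likelihood changes by less than ``tol``.

    ``X`` must contain an intercept column named ``const`` (added if absent).
    """
    y = np.asarray(y, dtype=float)
    if (y < 0).any() or not np.allclose(y, np.round(y)):
        raise ValueError("richness must be nonnegative integers")
    X = sm.add_constant(pd.DataFrame(X), has_constant="add")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")

    # moment start for theta from a Poisson fit
    pois = sm.GLM(y, X, family=sm.families.Poisson()).fit()
    mu = np.asarray(pois.mu)
    resid = ((y - mu) ** 2 - mu) / mu**2
    theta = 1.0 / max(np.mean(resid), 1e-3)
    theta = float(np.clip(theta, 1e-3, 1e6))

    ll_old = -np.inf
    res = None
    converged = False
    for _ in range(max_iter):
        fam = sm.families.NegativeBinomial(alpha=1.0 / theta)
        res = sm.GLM(y, X, family=fam).fit(start_params=None if res is None else res.params)
        mu = np.asarray(res.mu)
        theta = _update_theta(y, mu, theta)
        ll = _nb2_loglik(y, mu, theta)
        if abs(ll - ll_old) < tol:
            converged = True
            break
        ll_old = ll
    if not converged:
        raise RuntimeError("NB GLM did not converge in %d iterations" % max_iter)

    coefs = pd.Series(np.asarray(res.params), index=X.columns)
    k = len(coefs) + 1  # theta counts as one estimated parameter
    dev = _nb_deviance(y, mu, theta)
    preds = tuple(c for c in X.columns if c != "const")
    return NBModelFit(
        predictors=preds,
        coefficients=coefs,
        theta=theta,
        log_likelihood=ll,
        aic=-2 * ll + 2 * k,
        deviance=dev,
        bse=pd.Series(np.asarray(res.bse), index=X.columns),
        n_obs=len(y),
        y=y,
        mu=mu,
    )


def _nb_deviance(y: np.ndarray, mu: np.ndarray, theta: float) -> float:
    """NB2 residual deviance: twice the log-likelihood gap to the saturated model."""
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    return float(2 * np.sum(term - (y + theta) * np.log((y + theta) / (mu + theta))))


def fit_summaries(model: NBModelFit, null_model: NBModelFit, n: int | None = None,
                  ) -> tuple[float, float]:
    """Explained deviance (percent) and Nagelkerke pseudo-R^2 of ``model``
    against the intercept-only ``null_model`` fitted to the same data.

    ED = 100 * (1 - D_model / D_null);
    R2_CS = 1 - exp((2/n) * (ll_null - ll_model));
    R2_N  = R2_CS / (1 - exp((2/n) * ll_null)).

    NB deviances are only comparable at a common dispersion, so the null
    deviance is evaluated at the model's fitted theta (the glm.nb
    convention) using the null model's fitted means.
    """
    if n is None:
        n = model.n_obs
    if n <= 0:
        raise ValueError("n must be positive")
    if model.y is not None and null_model.mu is not None:
        null_dev = _nb_deviance(model.y, null_model.mu, model.theta)
    else:
        null_dev = null_model.deviance
    ed = 100.0 * (1.0 - model.deviance / null_dev)
    r2_cs = 1.0 - np.exp((2.0 / n) * (null_model.log_likelihood - model.log_likelihood))
    r2_n = r2_cs / (1.0 - np.exp((2.0 / n) * null_model.log_likelihood))
    return float(ed), float(r2_n)


def all_subsets_select(dataset: pd.DataFrame, predictors=PREDICTORS,
                       use_aicc: bool = False) -> tuple[pd.DataFrame, NBModelFit]:
    """Fit all 2^4 = 16 predictor subsets (including intercept-only), rank by
    AIC (ties: fewer parameters), and return the ranking and the best fit.

    The best fit comes back with explained deviance and Nagelkerke R^2
    filled in relative to the intercept-only model.
    """
    y = dataset["richness"]
    n = len(dataset)
    fits: dict[tuple[str, ...], NBModelFit] = {}
    rows = []
    for r in range(len(predictors) + 1):
        for subset in itertools.combinations(predictors, r):
            X = dataset[list(subset)] if subset else pd.DataFrame(index=dataset.index)
            try:
                fit = nb_glm_fit(y, X)
            except Exception as exc:  # noqa: BLE001 - flagged, not fatal
                warnings.warn(f"subset {subset} failed to fit: {exc}")
                continue
            crit = fit.aic
            if use_aicc:
                k = fit.k_params
                crit = fit.aic + 2 * k * (k + 1) / max(n - k - 1, 1)
            fits[subset] = fit
            rows.append(
                {
                    "predictors": "+".join(subset) if subset else "(intercept)",
                    "n_predictors": len(subset),
                    "logLik": fit.log_likelihood,
                    "theta": fit.theta,
                    "AIC": crit,
                }
            )
    table = pd.DataFrame(rows).sort_values(["AIC", "n_predictors"], kind="mergesort")
    table["dAIC"] = table["AIC"] - table["AIC"].min()
    table = table.reset_index(drop=True)
    best_key = tuple(p for p in predictors
                     if p in table.iloc[0]["predictors"].split("+"))
    best = fits[best_key]
    null = fits[()]
    ed, r2 = fit_summaries(best, null, n)
    best.null_deviance = null.deviance
    best.explained_deviance_percent = ed
    best.nagelkerke_r2 = r2
    return table, best


# ---------------------------------------------------------------------------
# Blomberg's K / K* phylogenetic-signal test


@dataclass
class SignalTestResult:
    statistic: float
    variant: str
    n_permutations: int
    p_value: float


def _blomberg_stat(y: np.ndarray, v_inv: np.ndarray, ones_vinv: np.ndarray,
                   denom_expected: float, variant: str) -> float:
    n = len(y)
    if variant == "K":
        a_hat = float(ones_vinv @ y) / float(ones_vinv.sum())
    else:  # K*: arithmetic tip mean as the central value
        a_hat = float(np.mean(y))
    r = y - a_hat
    mse0 = float(r @ r)
    mse = float(r @ v_inv @ r)
    return (mse0 / mse) / denom_expected


def blomberg_k(tree, values: pd.Series, variant: str = "K*", n_perm: int = 999,
               seed: int = 0) -> SignalTestResult:
    """Blomberg's K (or K*) phylogenetic-signal statistic with a permutation
    test.

    K compares the observed ratio of the ordinary to the phylogenetically
    weighted mean squared error of tip values about a central value (GLS
    ancestral estimate for variant "K", arithmetic tip mean for "K*") with
    its Brownian-motion expectation (tr V - n / sum(V^-1)) / (n - 1).
    K ~ 1 under Brownian evolution, ~ 0 with no signal.  The p-value counts
    tip-label permutations whose K meets or exceeds the observed one.
    """
    if variant not in ("K", "K*"):
        raise ValueError("variant must be 'K' or 'K*'")
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    vcv = trees.phylo_vcv(tree)
    labels = list(vcv.index)
    if set(labels) != set(values.index):
        raise ValueError("tip labels do not match value labels")
    y = values.reindex(labels).to_numpy(float)
    v = vcv.to_numpy()
    n = len(y)
    try:
        v_inv = np.linalg.inv(v)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("singular phylogenetic covariance matrix") from exc
    ones_vinv = v_inv.sum(axis=0)
    denom_expected = (np.trace(v) - n / ones_vinv.sum()) / (n - 1)
    k_obs = _blomberg_stat(y, v_inv, ones_vinv, denom_expected, variant)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        yp = rng.permutation(y)
        if _blomberg_stat(yp, v_inv, ones_vinv, denom_expected, variant) >= k_obs:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return SignalTestResult(statistic=float(k_obs), variant=variant,
                            n_permutations=n_perm, p_value=float(p))
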