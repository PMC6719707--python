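"""TMF estimation from food-web data.

The trophic magnification factor is the antilog of the slope of
log-transformed, basis-normalized contaminant concentration regressed
on trophic level:

    log10(C) = a + b·TL,   TMF = 10^b      (or e^b for ln-transformed data)

TMF > 1 indicates biomagnification, TMF < 1 trophic dilution.  Besides
ordinary least squares this module offers a linear mixed model (random
species intercepts, for unbalanced designs), nondetect handling by
substitution, dropping, or a left-censored maximum-likelihood fit of
the same line, nonparametric bootstrap intervals, and the
endotherm-exclusion recalculation used when food webs include birds or
mammals.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.tools.numdiff import approx_hess

from .datamodel import Basis, FoodWebDataset
from .normalization import convert_sample
from .trophic import TrophicAssignment, assign_trophic_levels


class LogBase(str, enum.Enum):
    log10 = "log10"
    ln = "ln"


class CensoringPolicy(str, enum.Enum):
    substitute_half_lod = "substitute_half_lod"
    substitute_lod_sqrt2 = "substitute_lod_sqrt2"
    drop = "drop"
    censored_mle = "censored_mle"


class FitMethod(str, enum.Enum):
    ols = "ols"
    mixed = "mixed"
    censored_mle = "censored_mle"
    substitution = "substitution"


class InsufficientDesignError(ValueError):
    """Too few distinct trophic levels (or groups) to fit the model."""


class CensoringError(ValueError):
    """Censoring pattern makes the requested fit impossible."""


class FitError(RuntimeError):
    """The model fit failed to converge or produced no usable inference."""


def _base_value(log_base: LogBase) -> float:
    return 10.0 if LogBase(log_base) == LogBase.log10 else math.e


def tmf_from_slope(b: float, log_base: LogBase = LogBase.log10) -> float:
    """TMF = 10^b (or e^b), the antilog of the regression slope."""
    return _base_value(log_base) ** b


def tmf_from_d15n_slope(
    b: float, enrichment_factor: float = 3.4, log_base: LogBase = LogBase.log10
) -> float:
    """TMF from a δ15N-based slope: base^(b · Δ15N).

    When log concentration was regressed on δ15N (‰) instead of TL, the
    slope is per ‰ and must be multiplied by the enrichment factor (‰
    per TL step) before taking the antilog.
    """
    if enrichment_factor <= 0:
        raise ValueError("enrichment factor must be positive")
    return tmf_from_slope(b * enrichment_factor, log_base)


def geometric_mean_tmf(tmfs: Sequence[float]) -> float:
    """Geometric mean of TMF values, exp(mean(ln TMF))."""
    if len(tmfs) == 0:
        raise ValueError("need at least one TMF")
    arr = np.asarray(tmfs, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("TMFs must be positive")
    return float(np.exp(np.mean(np.log(arr))))


def tl_balance_index(tls: Iterable[float]) -> float:
    """Largest share of samples falling in any unit-width TL bin.

    Bins start at the floor of the lowest TL; 1.0 means every sample
    sits in one bin, 1/k is the best possible value over k occupied
    bins.  Values around 0.5 reproduce the pathological case where one
    top-predator bin holds half of all samples.
    """
    arr = np.asarray(list(tls), dtype=float)
    if arr.size == 0:
        raise ValueError("no trophic levels supplied")
    bins = np.floor(arr - math.floor(arr.min())).astype(int)
    counts = np.bincount(bins)
    return float(counts.max() / arr.size)


@dataclass
class TMFResult:
    """A fitted TMF with its regression provenance."""

    slope_b: float
    intercept_a: float
    log_base: LogBase
    slope_se: float
    slope_ci: tuple[float, float]
    p_value: float
    n_obs: int
    n_species: int
    tmf: float
    tmf_ci: tuple[float, float]
    basis: Basis
    method: FitMethod
    excluded_endotherms: bool = False
    diagnostics: dict = field(default_factory=dict)
    bootstrap_slope_ci: Optional[tuple[float, float]] = None
    bootstrap_tmf_ci: Optional[tuple[float, float]] = None

    def to_dict(self) -> dict:
        d = {
            "slope_b": self.slope_b,
            "intercept_a": self.intercept_a,
            "log_base": self.log_base.value,
            "slope_se": self.slope_se,
            "slope_ci": list(self.slope_ci),
            "p_value": self.p_value,
            "n_obs": self.n_obs,
            "n_species": self.n_species,
            "tmf": self.tmf,
            "tmf_ci": list(self.tmf_ci),
            "basis": self.basis.value,
            "method": self.method.value,
            "excluded_endotherms": self.excluded_endotherms,
            "diagnostics": self.diagnostics,
        }
        if self.bootstrap_slope_ci is not None:
            d["bootstrap_slope_ci"] = list(self.bootstrap_slope_ci)
            d["bootstrap_tmf_ci"] = list(self.bootstrap_tmf_ci)
        return d


def apply_censoring_policy(
    values: Sequence[float],
    detected: Sequence[bool],
    detection_limits: Sequence[Optional[float]],
    policy: CensoringPolicy = CensoringPolicy.substitute_half_lod,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Turn (value, detected, LOD) triples into analysis-ready values.

    Returns ``(values, include, censored)`` arrays: substitution
    policies replace nondetects with LOD/2 or LOD/√2; ``drop`` excludes
    them; ``censored_mle`` keeps the LOD as the value and flags the
    observation left-censored for a censored-likelihood fit.

    Raises :class:`CensoringError` for all-censored data, or when
    ``censored_mle`` is requested with more than 90% censoring (the
    slope is not identifiable from thresholds alone).
    """
    policy = CensoringPolicy(policy)
    det = np.asarray(detected, dtype=bool)
    vals = np.array(
        [v if d else lod for v, d, lod in zip(values, det, detection_limits)],
        dtype=float,
    )
    censored = ~det
    n = det.size
    if n == 0:
        raise CensoringError("no observations")
    frac = censored.mean()
    if frac == 1.0:
        raise CensoringError("all observations are below the detection limit")
    include = np.ones(n, dtype=bool)
    if policy == CensoringPolicy.substitute_half_lod:
        vals[censored] = vals[censored] / 2.0
    elif policy == CensoringPolicy.substitute_lod_sqrt2:
        vals[censored] = vals[censored] / math.sqrt(2.0)
    elif policy == CensoringPolicy.drop:
        include = det.copy()
    elif policy == CensoringPolicy.censored_mle:
        if frac > 0.9:
            raise CensoringError(
                f"{frac:.0%} of observations censored: a censored-likelihood "
                "slope is not identifiable; refuse to fit"
            )
    return vals, include, censored


def _prepare_frame(
    dataset: FoodWebDataset,
    assignments: Optional[Iterable[TrophicAssignment]],
    basis: Basis,
    exclude_endotherms: bool,
    fillet_factor: Optional[float],
) -> pd.DataFrame:
    if assignments is None:
        assignments = assign_trophic_levels(dataset)
    tl_by_id = {a.sample_id: a.tl for a in assignments}
    rows = []
    for s in dataset.samples:
        if s.sample_id not in tl_by_id:
            continue
        if exclude_endotherms and s.endotherm:
            continue
        conv = convert_sample(s, basis, fillet_factor=fillet_factor)
        rows.append(
            {
                "sample_id": s.sample_id,
                "species": s.species,
                "tl": tl_by_id[s.sample_id],
                "value": conv.value,
                "detected": s.detected,
                "detection_limit": None if s.detected else conv.value,
                "pool_size": s.pool_size,
            }
        )
    return pd.DataFrame(rows)


def _slope_ci_t(slope: float, se: float, df: int, alpha: float = 0.05):
    half = scipy.stats.t.ppf(1.0 - alpha / 2.0, df) * se
    return (slope - half, slope + half)


def _result_from_slope(
    slope: float,
    intercept: float,
    se: float,
    ci: tuple[float, float],
    p: float,
    n_obs: int,
    n_species: int,
    log_base: LogBase,
    basis: Basis,
    method: FitMethod,
    excluded_endotherms: bool,
    diagnostics: dict,
) -> TMFResult:
    return TMFResult(
        slope_b=float(slope),
        intercept_a=float(intercept),
        log_base=log_base,
        slope_se=float(se),
        slope_ci=(float(ci[0]), float(ci[1])),
        p_value=float(p),
        n_obs=int(n_obs),
        n_species=int(n_species),
        tmf=tmf_from_slope(float(slope), log_base),
        tmf_ci=(
            tmf_from_slope(float(ci[0]), log_base),
            tmf_from_slope(float(ci[1]), log_base),
        ),
        basis=basis,
        method=method,
        excluded_endotherms=excluded_endotherms,
        diagnostics=diagnostics,
    )


def _check_design(tls: np.ndarray) -> None:
    if np.unique(tls).size < 3:
        raise InsufficientDesignError(
            f"need >=3 distinct trophic levels, found {np.unique(tls).size}"
        )


def _bootstrap_slope_ci(
    logy: np.ndarray,
    tl: np.ndarray,
    weights: Optional[np.ndarray],
    reps: int,
    seed: int,
    alpha: float = 0.05,
) -> tuple[float, float]:
    rng = np.random.default_rng(seed)
    n = logy.size
    slopes = np.empty(reps)
    for r in range(reps):
        idx = rng.integers(0, n, size=n)
        x, y = tl[idx], logy[idx]
        w = weights[idx] if weights is not None else None
        if np.unique(x).size < 2:
            slopes[r] = np.nan
            continue
        if w is None:
            xm, ym = x.mean(), y.mean()
            slopes[r] = np.sum((x - xm) * (y - ym)) / np.sum((x - xm) ** 2)
        else:
            wm = w.sum()
            xm, ym = np.sum(w * x) / wm, np.sum(w * y) / wm
            slopes[r] = np.sum(w * (x - xm) * (y - ym)) / np.sum(w * (x - xm) ** 2)
    slopes = slopes[~np.isnan(slopes)]
    lo, hi = np.percentile(slopes, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def fit_tmf_ols(
    dataset: FoodWebDataset,
    assignments: Optional[Iterable[TrophicAssignment]] = None,
    basis: Basis = Basis.lipid_weight,
    log_base: LogBase = LogBase.log10,
    exclude_endotherms: bool = False,
    censoring: CensoringPolicy = CensoringPolicy.substitute_half_lod,
    species_means: bool = False,
    pool_weighted: bool = False,
    bootstrap_reps: int = 0,
    seed: Optional[int] = None,
    fillet_factor: Optional[float] = None,
) -> TMFResult:
    """Ordinary least squares TMF fit (individual samples by default).

    Concentrations are converted to ``basis``, nondetects handled by
    ``censoring`` (``censored_mle`` switches to the left-censored
    likelihood fit of the same line), and the 95% CI comes from the t
    distribution with n−2 df.  ``species_means`` collapses to one point
    per species before fitting; ``pool_weighted`` weights rows by
    ``pool_size``.  Set ``bootstrap_reps`` > 0 (with a seed) to attach
    a nonparametric observation-level percentile bootstrap CI.
    """
    log_base = LogBase(log_base)
    censoring = CensoringPolicy(censoring)
    frame = _prepare_frame(dataset, assignments, basis, exclude_endotherms, fillet_factor)
    if frame.empty:
        raise InsufficientDesignError("no usable samples")

    vals, include, censored = apply_censoring_policy(
        frame["value"].to_numpy(),
        frame["detected"].to_numpy(),
        [None if d else v for v, d in zip(frame["value"], frame["detected"])],
        censoring,
    )
    frame = frame.assign(avalue=vals, censored=censored)[include].reset_index(drop=True)
    censored_fraction = float(censored.mean())

    logf = np.log10 if log_base == LogBase.log10 else np.log

    if censoring == CensoringPolicy.censored_mle and frame["censored"].any():
        return _fit_censored_mle(
            frame, log_base, logf, basis, exclude_endotherms, censored_fraction
        )

    if species_means:
        grouped = frame.assign(logy=logf(frame["avalue"])).groupby("species")
        tl = grouped["tl"].mean().to_numpy()
        logy = grouped["logy"].mean().to_numpy()
        weights = None
        n_species = tl.size
    else:
        tl = frame["tl"].to_numpy(dtype=float)
        logy = logf(frame["avalue"].to_numpy(dtype=float))
        weights = (
            frame["pool_size"].to_numpy(dtype=float) if pool_weighted else None
        )
        n_species = frame["species"].nunique()

    _check_design(tl)
    exog = sm.add_constant(tl)
    model = sm.WLS(logy, exog, weights=weights) if weights is not None else sm.OLS(logy, exog)
    fit = model.fit()
    slope, intercept = fit.params[1], fit.params[0]
    se = fit.bse[1]
    ci = _slope_ci_t(slope, se, fit.df_resid)
    p = fit.pvalues[1]

    hat = fit.get_influence().hat_matrix_diag if logy.size > 2 else np.zeros(1)
    diagnostics = {
        "resid_sd": float(np.sqrt(fit.mse_resid)) if fit.df_resid > 0 else 0.0,
        "balance_index": tl_balance_index(tl),
        "leverage_max": float(np.max(hat)),
        "censored_fraction": censored_fraction,
        "censoring_policy": censoring.value,
        "species_means": species_means,
    }
    method = (
        FitMethod.substitution
        if censored_fraction > 0
        and censoring
        in (CensoringPolicy.substitute_half_lod, CensoringPolicy.substitute_lod_sqrt2)
        else FitMethod.ols
    )
    result = _result_from_slope(
        slope, intercept, se, ci, p, logy.size, n_species, log_base, basis,
        method, exclude_endotherms, diagnostics,
    )
    if bootstrap_reps > 0:
        if seed is None:
            raise ValueError("bootstrap requires a seed")
        blo, bhi = _bootstrap_slope_ci(logy, tl, weights, bootstrap_reps, seed)
        result.bootstrap_slope_ci = (blo, bhi)
        result.bootstrap_tmf_ci = (
            tmf_from_slope(blo, log_base),
            tmf_from_slope(bhi, log_base),
        )
    return result


def _fit_censored_mle(
    frame: pd.DataFrame,
    log_base: LogBase,
    logf,
    basis: Basis,
    exclude_endotherms: bool,
    censored_fraction: float,
) -> TMFResult:
    """Left-censored Gaussian MLE of log(C) = a + b·TL.

    Nondetects contribute Φ((log LOD − a − b·TL)/σ) to the likelihood.
    Standard errors come from the inverse observed information at the
    optimum; the CI and p-value use the normal approximation.
    """
    tl = frame["tl"].to_numpy(dtype=float)
    _check_design(tl)
    y = logf(frame["avalue"].to_numpy(dtype=float))  # log LOD where censored
    cens = frame["censored"].to_numpy(dtype=bool)

    # start from substitution OLS
    y0 = y.copy()
    y0[cens] = y0[cens] - (math.log10(2.0) if log_base == LogBase.log10 else math.log(2.0))
    X = sm.add_constant(tl)
    start = sm.OLS(y0, X).fit()
    theta0 = np.array(
        [start.params[0], start.params[1], math.log(max(np.sqrt(start.mse_resid), 1e-3))]
    )

    def nll(theta: np.ndarray) -> float:
        a, b, log_s = theta
        s = math.exp(log_s)
        mu = a + b * tl
        z = (y - mu) / s
        ll_obs = scipy.stats.norm.logpdf(z[~cens]) - log_s
        ll_cens = scipy.stats.norm.logcdf(z[cens])
        return -(ll_obs.sum() + ll_cens.sum())

    opt = scipy.optimize.minimize(nll, theta0, method="BFGS")
    if not np.all(np.isfinite(opt.x)):
        raise FitError(f"censored MLE did not converge: {opt.message}")
    a_hat, b_hat, log_s_hat = opt.x
    hess = approx_hess(opt.x, nll)
    try:
        cov = np.linalg.inv(hess)
        se = float(np.sqrt(cov[1, 1]))
    except np.linalg.LinAlgError:
        raise FitError("censored MLE information matrix is singular")
    z975 = scipy.stats.norm.ppf(0.975)
    ci = (b_hat - z975 * se, b_hat + z975 * se)
    p = 2.0 * scipy.stats.norm.sf(abs(b_hat) / se) if se > 0 else 0.0
    diagnostics = {
        "resid_sd": float(math.exp(log_s_hat)),
        "balance_index": tl_balance_index(tl),
        "censored_fraction": censored_fraction,
        "censoring_policy": CensoringPolicy.censored_mle.value,
        "nll": float(opt.fun),
    }
    return _result_from_slope(
        b_hat, a_hat, se, ci, p, tl.size, frame["species"].nunique(),
        log_base, basis, FitMethod.censored_mle, exclude_endotherms, diagnostics,
    )


def fit_tmf_mixed(
    dataset: FoodWebDataset,
    assignments: Optional[Iterable[TrophicAssignment]] = None,
    basis: Basis = Basis.lipid_weight,
    log_base: LogBase = LogBase.log10,
    exclude_endotherms: bool = False,
    censoring: CensoringPolicy = CensoringPolicy.substitute_half_lod,
    fillet_factor: Optional[float] = None,
) -> TMFResult:
    """Linear mixed model: fixed TL slope, random intercept per species.

    The recommended recalculation for unbalanced designs, where one
    heavily sampled species would otherwise dominate the OLS slope.
    Requires ≥4 species groups spanning ≥2 distinct TLs.  Nondetects
    are handled by substitution (``censored_mle`` is not available in
    the mixed model).
    """
    log_base = LogBase(log_base)
    censoring = CensoringPolicy(censoring)
    if censoring == CensoringPolicy.censored_mle:
        raise CensoringError(
            "censored_mle is not supported in the mixed model; "
            "use a substitution policy"
        )
    frame = _prepare_frame(dataset, assignments, basis, exclude_endotherms, fillet_factor)
    if frame.empty:
        raise InsufficientDesignError("no usable samples")
    vals, include, censored = apply_censoring_policy(
        frame["value"].to_numpy(),
        frame["detected"].to_numpy(),
        [None if d else v for v, d in zip(frame["value"], frame["detected"])],
        censoring,
    )
    frame = frame.assign(avalue=vals)[include].reset_index(drop=True)

    n_groups = frame["species"].nunique()
    if n_groups < 4:
        raise InsufficientDesignError(
            f"mixed model needs >=4 species groups, found {n_groups}"
        )
    if frame.groupby("species")["tl"].mean().nunique() < 2:
        raise InsufficientDesignError("species groups span <2 distinct TLs")

    logf = np.log10 if log_base == LogBase.log10 else np.log
    logy = logf(frame["avalue"].to_numpy(dtype=float))
    tl = frame["tl"].to_numpy(dtype=float)
    exog = sm.add_constant(tl)
    model = MixedLM(logy, exog, groups=frame["species"].to_numpy())
    try:
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            fit = model.fit(reml=True)
    except Exception as exc:  # pragma: no cover - optimizer failure path
        raise FitError(f"mixed model failed to converge: {exc}") from exc
    slope, intercept = fit.fe_params[1], fit.fe_params[0]
    se = fit.bse_fe[1]
    if not np.isfinite(se):
        raise FitError("mixed model produced no usable slope standard error")
    df = logy.size - 2
    ci = _slope_ci_t(slope, se, df)
    p = 2.0 * scipy.stats.t.sf(abs(slope) / se, df)
    diagnostics = {
        "resid_sd": float(np.sqrt(fit.scale)),
        "species_intercept_var": float(np.asarray(fit.cov_re)[0, 0]),
        "balance_index": tl_balance_index(tl),
        "censored_fraction": float(censored.mean()),
        "censoring_policy": censoring.value,
        "converged": bool(fit.converged),
    }
    return _result_from_slope(
        slope, intercept, se, ci, p, logy.size, n_groups, log_base, basis,
        FitMethod.mixed, exclude_endotherms, diagnostics,
    )
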