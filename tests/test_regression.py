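"""TMF regression: slope→TMF algebra, OLS/mixed/censored fits, invariances."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from tmfkit import (
    Basis,
    BiotaSample,
    CensoringPolicy,
    FitMethod,
    FoodWebDataset,
    LogBase,
    apply_censoring_policy,
    fit_tmf_mixed,
    fit_tmf_ols,
    generate_synthetic_foodweb,
    geometric_mean_tmf,
    tl_balance_index,
    tmf_from_d15n_slope,
    tmf_from_slope,
)
from tmfkit.regression import CensoringError, InsufficientDesignError


@pytest.mark.parametrize(
    "slope,expected,decimals",
    [
        (-0.52, 0.30, 2),  # total-PAH regression, birds included
        (-0.61, 0.24, 2),  # birds excluded (printed value; see tolerance note)
        (0.3, 2.0, 1),
        (0.5, 3.2, 1),
        (0.0, 1.0, 12),
    ],
)
def test_slope_to_tmf_reference_values(slope, expected, decimals):
    # agreement within one unit in the last printed decimal: the printed
    # slopes are themselves rounded, so half-unit agreement cannot be
    # demanded of their antilogs (10^-0.61 = 0.2455)
    assert abs(tmf_from_slope(slope) - expected) <= 10.0 ** (-decimals)


def test_ln_base_uses_e():
    assert tmf_from_slope(1.0, LogBase.ln) == pytest.approx(math.e)


@given(b=st.floats(-1, 1), ef=st.floats(3.0, 5.0))
def test_d15n_slope_equivalence(b, ef):
    """TMF from a per-‰ slope equals TMF from the per-TL slope b·EF."""
    assert tmf_from_d15n_slope(b, ef) == tmf_from_slope(b * ef)


@pytest.mark.parametrize(
    "tmfs,expected",
    [([2.0, 8.0], 4.0), ([3.7], 3.7), ([0.30, 0.24], math.sqrt(0.30 * 0.24))],
)
def test_geometric_mean(tmfs, expected):
    assert geometric_mean_tmf(tmfs) == pytest.approx(expected, rel=1e-12)


@pytest.mark.parametrize("bad", [[], [2.0, -1.0], [0.0]])
def test_geometric_mean_domain(bad):
    with pytest.raises(ValueError):
        geometric_mean_tmf(bad)


def test_noiseless_fit_recovers_slope_exactly(noiseless_dataset):
    fit = fit_tmf_ols(noiseless_dataset)
    assert fit.slope_b == pytest.approx(np.log10(2.0), abs=1e-12)
    assert fit.p_value < 1e-30
    assert fit.method == FitMethod.ols


def test_tmf_field_is_antilog_of_slope_bit_identically(lake_dataset):
    fit = fit_tmf_ols(lake_dataset)
    assert fit.tmf == tmf_from_slope(fit.slope_b, fit.log_base)
    assert fit.tmf_ci == (
        tmf_from_slope(fit.slope_ci[0]), tmf_from_slope(fit.slope_ci[1])
    )
    assert fit.tmf > 0


def test_concentration_scaling_moves_intercept_not_slope(lake_dataset):
    scaled = lake_dataset.model_copy(deep=True)
    for s in scaled.samples:
        if s.concentration is not None:
            s.concentration *= 137.0
    f0 = fit_tmf_ols(lake_dataset)
    f1 = fit_tmf_ols(scaled)
    assert f1.slope_b == pytest.approx(f0.slope_b, abs=1e-12)
    assert f1.intercept_a == pytest.approx(f0.intercept_a + np.log10(137.0), abs=1e-9)


def test_basis_effect_direction():
    """Lipid rising with TL inflates wet-weight TMFs above lipid-based ones."""
    rising = generate_synthetic_foodweb(seed=11)  # default lipid gradient
    fw = fit_tmf_ols(rising, basis=Basis.wet_weight)
    fl = fit_tmf_ols(rising, basis=Basis.lipid_weight)
    assert fw.tmf > fl.tmf
    flat = generate_synthetic_foodweb(lipid_by_tl=0.05, seed=11)
    fw2 = fit_tmf_ols(flat, basis=Basis.wet_weight)
    fl2 = fit_tmf_ols(flat, basis=Basis.lipid_weight)
    assert fw2.slope_b == pytest.approx(fl2.slope_b, abs=1e-12)


def test_endotherm_exclusion_flag_and_agreement():
    ds = generate_synthetic_foodweb(n_endotherm_species=2, seed=21)
    incl = fit_tmf_ols(ds)
    excl = fit_tmf_ols(ds, exclude_endotherms=True)
    assert excl.excluded_endotherms and excl.n_obs < incl.n_obs
    # endotherms generated on the same law: slopes agree within 2 SE
    assert abs(incl.slope_b - excl.slope_b) < 2 * max(incl.slope_se, excl.slope_se)


def test_insufficient_design_two_levels():
    ds = generate_synthetic_foodweb(n_species=2, samples_per_species=5, seed=0)
    with pytest.raises(InsufficientDesignError):
        fit_tmf_ols(ds)


def test_species_means_mode(lake_dataset):
    fit = fit_tmf_ols(lake_dataset, species_means=True)
    assert fit.n_obs == len(lake_dataset.species)
    assert fit.diagnostics["species_means"] is True


# ---- censoring -----------------------------------------------------------


def test_substitution_values():
    vals, include, cens = apply_censoring_policy(
        [None, 5.0], [False, True], [1.0, None], CensoringPolicy.substitute_half_lod
    )
    assert vals[0] == 0.5 and vals[1] == 5.0 and cens[0] and include.all()
    vals, _, _ = apply_censoring_policy(
        [None, 5.0], [False, True], [1.0, None], CensoringPolicy.substitute_lod_sqrt2
    )
    assert vals[0] == pytest.approx(1 / math.sqrt(2))
    _, include, _ = apply_censoring_policy(
        [None, 5.0], [False, True], [1.0, None], CensoringPolicy.drop
    )
    assert list(include) == [False, True]


def test_all_censored_refused():
    with pytest.raises(CensoringError, match="all observations"):
        apply_censoring_policy([None], [False], [1.0], CensoringPolicy.drop)


def test_censored_mle_refuses_over_90_percent():
    vals = [None] * 19 + [5.0]
    det = [False] * 19 + [True]
    lods = [1.0] * 19 + [None]
    with pytest.raises(CensoringError, match="not identifiable"):
        apply_censoring_policy(vals, det, lods, CensoringPolicy.censored_mle)


def test_uncensored_data_identical_across_policies(lake_dataset):
    fits = [
        fit_tmf_ols(lake_dataset, censoring=p)
        for p in [
            CensoringPolicy.substitute_half_lod,
            CensoringPolicy.substitute_lod_sqrt2,
            CensoringPolicy.drop,
            CensoringPolicy.censored_mle,
        ]
    ]
    assert all(f.slope_b == fits[0].slope_b for f in fits)
    assert all(f.method == FitMethod.ols for f in fits)


def test_censored_mle_less_biased_than_substitution():
    """With 30% left-censoring the censored likelihood recovers the slope
    with smaller absolute bias than LOD/2 substitution (200 replicates)."""
    true = np.log10(2.0)
    mle, sub = [], []
    for seed in range(200):
        ds = generate_synthetic_foodweb(censor_fraction=0.3, seed=seed)
        mle.append(fit_tmf_ols(ds, censoring=CensoringPolicy.censored_mle).slope_b)
        sub.append(fit_tmf_ols(ds, censoring=CensoringPolicy.substitute_half_lod).slope_b)
    assert abs(np.mean(mle) - true) < abs(np.mean(sub) - true)


def test_censored_fit_method_labels():
    ds = generate_synthetic_foodweb(censor_fraction=0.3, seed=4)
    assert fit_tmf_ols(ds).method == FitMethod.substitution
    assert (
        fit_tmf_ols(ds, censoring=CensoringPolicy.censored_mle).method
        == FitMethod.censored_mle
    )


# ---- mixed model ---------------------------------------------------------


def test_mixed_equals_ols_without_species_variance(lake_dataset):
    mixed = fit_tmf_mixed(lake_dataset)
    ols = fit_tmf_ols(lake_dataset)
    assert mixed.slope_b == pytest.approx(ols.slope_b, abs=1e-6)
    assert mixed.method == FitMethod.mixed


def test_mixed_requires_four_groups():
    ds = generate_synthetic_foodweb(n_species=3, samples_per_species=10, seed=0)
    with pytest.raises(InsufficientDesignError, match="4 species"):
        fit_tmf_mixed(ds)


def test_mixed_beats_ols_on_unbalanced_designs():
    """Top-predator-dominated sampling with species-level scatter: the
    random-intercept model has lower slope RMSE than OLS (200 replicates)."""
    true = np.log10(2.0)
    counts = [3] * 9 + [27]  # one species is half the samples
    err_m, err_o = [], []
    for seed in range(200):
        ds = generate_synthetic_foodweb(
            n_species=10, samples_per_species=counts, species_sd=0.25,
            resid_sd=0.15, seed=seed,
        )
        err_m.append(fit_tmf_mixed(ds).slope_b - true)
        err_o.append(fit_tmf_ols(ds).slope_b - true)
    rmse = lambda e: float(np.sqrt(np.mean(np.square(e))))
    assert rmse(err_m) <= rmse(err_o)


# ---- bootstrap & diagnostics --------------------------------------------


def test_bootstrap_requires_seed(lake_dataset):
    with pytest.raises(ValueError, match="seed"):
        fit_tmf_ols(lake_dataset, bootstrap_reps=100)


def test_bootstrap_ci_brackets_point_estimate(lake_dataset):
    fit = fit_tmf_ols(lake_dataset, bootstrap_reps=500, seed=1)
    lo, hi = fit.bootstrap_tmf_ci
    assert lo < fit.tmf < hi


@pytest.mark.parametrize(
    "tls,expected",
    [
        ([2.1, 2.5, 3.1, 3.5, 4.1, 4.5], 1 / 3),
        ([4.0, 4.1, 4.2], 1.0),
        ([2.0, 2.5, 4.0, 4.1, 4.2, 4.3], 4 / 6),
    ],
)
def test_balance_index_bins(tls, expected):
    assert tl_balance_index(tls) == pytest.approx(expected)
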