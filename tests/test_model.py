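"""Hierarchical model: log-joint oracle, HDI, sampler correctness, effects."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from polystream import (
    MeasurementCell, ModelConfig, ResponseCounts, cell_effects, contrast,
    edge_corrected_bias, edge_corrected_dprime, fit_model, gamma_prior_stats,
    hdi, log_joint, prepare_data, initial_state,
)


def _cell(subject, attention, counts, timbre=None):
    rc = ResponseCounts(*counts)
    return MeasurementCell(subject, attention, timbre, rc,
                           edge_corrected_dprime(rc), edge_corrected_bias(rc))


TOY_CELLS = [
    _cell("s1", "bassoon", (10, 6, 2, 14)),
    _cell("s1", "cello", (15, 1, 0, 16)),
    _cell("s2", "bassoon", (8, 8, 5, 11)),
]
TOY_CONFIG = ModelConfig(experiment="exp1", n_samples=10, burn_in=0, n_chains=1)


# ---------------------------------------------------------------------------
# brute-force log-joint oracle (term-by-term, naive loops, scipy densities)

def oracle_log_joint(state, data, config):
    total = 0.0
    groups = ("att", "subj") if data.experiment == "exp1" else (
        "att", "timb", "ati", "subj")
    for sub in ("d", "b"):
        sig_res = state[f"{sub}_sigma_res"]
        sig_beta = state[f"{sub}_sigma_beta"]
        if np.any(sig_res <= 0) or np.any(sig_res >= config.sigma_dprime_upper) \
                or np.any(sig_beta <= 0):
            return -np.inf
    for m in range(data.n_cells):
        d, b = state["d_latent"][m], state["b_latent"][m]
        total += sps.binom.logpmf(data.H[m], data.n_tri[m],
                                  sps.norm.cdf(0.5 * d - b))
        total += sps.binom.logpmf(data.FA[m], data.n_ntri[m],
                                  sps.norm.cdf(-0.5 * d - b))
    for sub in ("d", "b"):
        for m in range(data.n_cells):
            mu = state[f"{sub}_beta0"] \
                + state[f"{sub}_beta_att"][data.att_idx[m]] \
                + state[f"{sub}_beta_subj"][data.subj_idx[m]]
            if data.experiment == "exp2":
                mu += state[f"{sub}_beta_timb"][data.timb_idx[m]]
                mu += state[f"{sub}_beta_ati"][data.ati_idx[m]]
            total += sps.norm.logpdf(state[f"{sub}_latent"][m], mu,
                                     state[f"{sub}_sigma_res"][data.att_idx[m]])
        for s in state[f"{sub}_sigma_res"]:
            total += sps.uniform.logpdf(s, 0, config.sigma_dprime_upper)
        total += sps.norm.logpdf(state[f"{sub}_beta0"], 0,
                                 math.sqrt(config.prior_intercept_variance))
        for g, group in enumerate(groups):
            sg = state[f"{sub}_sigma_beta"][g]
            for beta in np.atleast_1d(state[f"{sub}_beta_{group}"]):
                total += sps.norm.logpdf(beta, 0, sg)
            total += sps.gamma.logpdf(sg, a=config.gamma_shape,
                                      scale=1 / config.gamma_rate)
    return total


def _random_state(data, rng):
    state = initial_state(data)
    for key, value in state.items():
        if key.endswith("sigma_res"):
            state[key] = rng.uniform(0.2, 3.8, np.shape(value))
        elif key.endswith("sigma_beta"):
            state[key] = rng.gamma(2.0, 1.0, np.shape(value)) + 0.1
        elif isinstance(value, float):
            state[key] = float(rng.normal(0, 1.5))
        else:
            state[key] = rng.normal(0, 1.5, np.shape(value))
    return state


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_log_joint_matches_brute_force_oracle(seed):
    data = prepare_data(TOY_CELLS, "exp1")
    rng = np.random.default_rng(seed)
    state = _random_state(data, rng)
    assert log_joint(state, data, TOY_CONFIG) == pytest.approx(
        oracle_log_joint(state, data, TOY_CONFIG), abs=1e-10)


def test_log_joint_oracle_exp2():
    cells = [
        _cell("s1", "bassoon", (9, 1, 2, 4), "maximum"),
        _cell("s1", "cello", (5, 5, 1, 5), "minimum"),
        _cell("s2", "aggregate", (7, 3, 0, 6), "intermediate"),
    ]
    config = ModelConfig(experiment="exp2", n_samples=10, burn_in=0, n_chains=1)
    data = prepare_data(cells, "exp2")
    state = _random_state(data, np.random.default_rng(7))
    assert log_joint(state, data, config) == pytest.approx(
        oracle_log_joint(state, data, config), abs=1e-10)


def test_log_joint_outside_uniform_support():
    data = prepare_data(TOY_CELLS, "exp1")
    state = initial_state(data)
    state["d_sigma_res"] = np.array([4.5, 1.0, 1.0])
    assert log_joint(state, data, TOY_CONFIG) == -np.inf


def test_log_joint_likelihood_ratio_for_one_extra_hit():
    data = prepare_data(TOY_CELLS, "exp1")
    state = _random_state(data, np.random.default_rng(11))
    base = log_joint(state, data, TOY_CONFIG)
    shifted = [_cell("s1", "bassoon", (11, 5, 2, 14)),
               TOY_CELLS[1], TOY_CELLS[2]]
    data2 = prepare_data(shifted, "exp1")
    # latent priors unchanged (the edge-corrected inits differ but the state
    # carries its own latents), so the change is a pure binomial pmf ratio
    after = log_joint(state, data2, TOY_CONFIG)
    p = sps.norm.cdf(0.5 * state["d_latent"][0] - state["b_latent"][0])
    expected = (sps.binom.logpmf(11, 16, p) - sps.binom.logpmf(10, 16, p))
    assert after - base == pytest.approx(expected, abs=1e-10)


def test_exp1_model_is_restriction_of_exp2():
    """With the timbre blocks zeroed, the exp2 density equals the exp1
    density plus the analytic prior mass of the extra blocks."""
    cells1 = TOY_CELLS
    cells2 = [_cell(c.subject_id, c.attention,
                    (c.counts.n_hit, c.counts.n_miss, c.counts.n_fa,
                     c.counts.n_cr), "maximum") for c in cells1]
    data1 = prepare_data(cells1, "exp1")
    config2 = ModelConfig(experiment="exp2", n_samples=10, burn_in=0, n_chains=1)
    data2 = prepare_data(cells2, "exp2")
    rng = np.random.default_rng(13)
    state1 = _random_state(data1, rng)
    state2 = dict(state1)
    extra = 0.0
    for sub in ("d", "b"):
        # exp2 groups: att, timb, ati, subj; reuse att/subj sigmas, add new ones
        s_att, s_subj = state1[f"{sub}_sigma_beta"]
        s_timb, s_ati = 1.3, 0.8
        state2[f"{sub}_sigma_beta"] = np.array([s_att, s_timb, s_ati, s_subj])
        n_timb = len(data2.timb_levels)
        state2[f"{sub}_beta_timb"] = np.zeros(n_timb)
        state2[f"{sub}_beta_ati"] = np.zeros(3 * n_timb)
        for s, n in ((s_timb, n_timb), (s_ati, 3 * n_timb)):
            extra += n * sps.norm.logpdf(0.0, 0, s)
            extra += sps.gamma.logpdf(s, a=config2.gamma_shape,
                                      scale=1 / config2.gamma_rate)
    lhs = log_joint(state2, data2, config2)
    rhs = log_joint(state1, data1, TOY_CONFIG) + extra
    assert lhs == pytest.approx(rhs, abs=1e-10)


# ---------------------------------------------------------------------------
# HDI and the gamma prior

def test_hdi_of_standard_normal():
    draws = np.random.default_rng(0).standard_normal(10_000_000)
    iv = hdi(draws, 0.95)
    assert iv.low == pytest.approx(-1.96, abs=0.01)
    assert iv.high == pytest.approx(1.96, abs=0.01)


def test_hdi_of_uniform_has_mass_width():
    draws = np.random.default_rng(1).uniform(0, 1, 1_000_000)
    assert hdi(draws, 0.95).width == pytest.approx(0.95, abs=0.01)


def test_hdi_symmetric_about_mode_for_symmetric_draws():
    draws = np.random.default_rng(2).standard_t(df=5, size=1_000_000)
    iv = hdi(draws, 0.9)
    assert iv.low == pytest.approx(-iv.high, abs=0.02)


def test_hdi_input_validation():
    with pytest.raises(ValueError):
        hdi(np.arange(50), 0.95)
    with pytest.raises(ValueError):
        hdi(np.arange(1000), 1.5)


def test_gamma_prior_statistics():
    mode, sd = gamma_prior_stats(1.64, 0.32)
    assert mode == pytest.approx(2.0, abs=1e-12)
    assert sd == pytest.approx(4.0, abs=0.01)
    mode, sd = gamma_prior_stats(2.0, 1.0)
    assert (mode, sd) == (1.0, pytest.approx(math.sqrt(2)))
    with pytest.raises(ValueError):
        gamma_prior_stats(0.9, 0.32)


# ---------------------------------------------------------------------------
# sampler output contracts

@pytest.fixture(scope="module")
def small_fit():
    cells = [
        _cell("s1", "bassoon", (12, 4, 3, 13)),
        _cell("s1", "cello", (14, 2, 1, 15)),
        _cell("s2", "bassoon", (9, 7, 6, 10)),
        _cell("s2", "cello", (11, 5, 2, 14)),
        _cell("s3", "bassoon", (13, 3, 2, 14)),
        _cell("s3", "cello", (10, 6, 4, 12)),
    ]
    config = ModelConfig(experiment="exp1", n_samples=400, burn_in=300,
                         n_chains=2, seed=21)
    return fit_model(cells, config)


def test_retained_draw_counts_match_config(small_fit):
    for name, arr in small_fit.draws.items():
        assert arr.shape[:2] == (2, 400), name
    assert set(small_fit.rhat) == set(small_fit.draws)


def test_fit_reproducible_under_seed(small_fit):
    cells = [
        _cell("s1", "bassoon", (12, 4, 3, 13)),
        _cell("s1", "cello", (14, 2, 1, 15)),
        _cell("s2", "bassoon", (9, 7, 6, 10)),
        _cell("s2", "cello", (11, 5, 2, 14)),
        _cell("s3", "bassoon", (13, 3, 2, 14)),
        _cell("s3", "cello", (10, 6, 4, 12)),
    ]
    config = ModelConfig(experiment="exp1", n_samples=400, burn_in=300,
                         n_chains=2, seed=21)
    again = fit_model(cells, config)
    for name in small_fit.draws:
        assert np.array_equal(small_fit.draws[name], again.draws[name])


def test_recentered_effects_sum_to_zero(small_fit):
    eff = cell_effects(small_fit)
    assert np.allclose(eff.attention.sum(axis=1), 0.0, atol=1e-10)
    # reconstruction identity: grand + effect = marginal mean
    assert np.allclose(eff.grand_mean[:, None] + eff.attention,
                       eff.cell_means, atol=1e-10)


def test_contrast_matches_direct_subtraction(small_fit):
    eff = cell_effects(small_fit)
    res = contrast(small_fit, "attention", "bassoon", "cello")
    i, j = eff.att_levels.index("bassoon"), eff.att_levels.index("cello")
    direct = eff.cell_means[:, i] - eff.cell_means[:, j]
    assert np.max(np.abs(res.draws - direct)) < 1e-12


def test_self_contrast_centers_on_zero(small_fit):
    res = contrast(small_fit, "attention", "bassoon", "bassoon")
    assert np.all(res.draws == 0.0)
    assert not res.excludes_zero


def test_exp1_fit_carries_no_timbre_terms(small_fit):
    assert "d_beta_timb" not in small_fit.draws
    eff = cell_effects(small_fit)
    assert eff.timbre is None and eff.interaction is None
    with pytest.raises(ValueError):
        contrast(small_fit, "timbre", "maximum", "minimum")


def test_insufficient_subjects_rejected():
    with pytest.raises(ValueError):
        fit_model([_cell("s1", "bassoon", (4, 4, 4, 4))], TOY_CONFIG)


# ---------------------------------------------------------------------------
# simulation-based calibration (reduced model)

def _sbc_replicate(seed, config):
    """Draw truth from the priors, simulate data, fit, return rank statistics."""
    rng = np.random.default_rng(seed)
    n_subj, atts = 2, ("bassoon", "cello")
    truth = {}
    for sub in ("d", "b"):
        sig_beta = rng.gamma(config.gamma_shape, 1 / config.gamma_rate, 2)
        truth[f"{sub}_beta0"] = rng.normal(0, math.sqrt(config.prior_intercept_variance))
        truth[f"{sub}_beta_att"] = rng.normal(0, sig_beta[0], len(atts))
        truth[f"{sub}_beta_subj"] = rng.normal(0, sig_beta[1], n_subj)
        truth[f"{sub}_sigma_res"] = rng.uniform(0, config.sigma_dprime_upper, len(atts))
    cells = []
    latents = []
    for s in range(n_subj):
        for a, att in enumerate(atts):
            d = rng.normal(truth["d_beta0"] + truth["d_beta_att"][a]
                           + truth["d_beta_subj"][s], truth["d_sigma_res"][a])
            b = rng.normal(truth["b_beta0"] + truth["b_beta_att"][a]
                           + truth["b_beta_subj"][s], truth["b_sigma_res"][a])
            latents.append(d)
            n = 20
            h = rng.binomial(n, sps.norm.cdf(0.5 * d - b))
            fa = rng.binomial(n, sps.norm.cdf(-0.5 * d - b))
            cells.append(_cell(f"s{s}", att, (h, n - h, fa, n - fa)))
    post = fit_model(cells, config)
    rank_beta0 = np.mean(post.stacked("d_beta0") < truth["d_beta0"])
    rank_latent = np.mean(post.stacked("d_latent")[:, 0] < latents[0])
    return rank_beta0, rank_latent


def test_sampler_calibration_on_reduced_model():
    """Prior-predictive rank statistics of the true parameter are uniform if
    the sampler targets the correct posterior (chi-square GoF at 0.01)."""
    config = ModelConfig(experiment="exp1", n_samples=1000, burn_in=500,
                         n_chains=1, seed=0, prior_intercept_variance=4.0)
    ranks = np.array([_sbc_replicate(1000 + k, config) for k in range(20)])
    for column in ranks.T:
        observed = np.histogram(column, bins=np.linspace(0, 1, 5))[0]
        chi2 = np.sum((observed - 5.0) ** 2 / 5.0)
        assert chi2 < sps.chi2.ppf(0.99, df=3)
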