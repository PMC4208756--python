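"""Hierarchical rater model: convergence diagnostic, sampler correctness
(prior reproduction, parameter recovery), derived-quantity identities and
group comparisons."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from phexam import (
    EstimationError,
    ExamDataset,
    RaterModelPosterior,
    RaterModelSpec,
    SimulationConfig,
    average_examiner_summary,
    build_contingency,
    fit_rater_model,
    gelman_rubin,
    generate_cohort,
    posterior_summary,
    prob_group_lr_greater,
)
from phexam.rater_model import _run_chains, _slice_update, _SuffStats
from phexam.simulate import single_sign_truth

QUICK = RaterModelSpec(chains=3, burn_in=400, keep=800, seed=5)


# --- Gelman-Rubin ----------------------------------------------------------

def test_identical_chains_give_sub_unity_rhat():
    chain = np.sin(np.arange(100.0))
    n = chain.size
    assert gelman_rubin([chain, chain]) == pytest.approx(math.sqrt((n - 1) / n))


def test_rhat_matches_hand_computation():
    x = np.array([[1.0, 2.0, 3.0], [2.0, 4.0, 6.0]])
    w = (1.0 + 4.0) / 2  # within-chain variances 1 and 4
    b = 3 * ((2 - 3) ** 2 + (4 - 3) ** 2) / 1  # n * var of chain means
    expected = math.sqrt((2 / 3 * w + b / 3) / w)
    assert gelman_rubin(x) == pytest.approx(expected, abs=1e-12)


def test_rhat_flags_gross_non_convergence():
    rng = np.random.default_rng(0)
    chains = np.stack([rng.normal(0, 1, 500), rng.normal(10, 1, 500)])
    assert gelman_rubin(chains) > 1.5


def test_rhat_near_one_under_the_null():
    rng = np.random.default_rng(1)
    chains = rng.normal(size=(3, 10_000))
    assert gelman_rubin(chains) < 1.05


def test_rhat_input_validation():
    with pytest.raises(EstimationError):
        gelman_rubin(np.ones((1, 100)))
    with pytest.raises(EstimationError):
        gelman_rubin(np.ones((2, 1)))


# --- slice sampler ---------------------------------------------------------

def test_slice_sampler_targets_a_standard_normal():
    logf = lambda x: -0.5 * x * x
    rng = np.random.default_rng(0)
    x, fx = 0.0, 0.0
    draws = np.empty(20_000)
    for i in range(draws.size):
        x, fx = _slice_update(logf, x, fx, width=1.0, rng=rng)
        draws[i] = x
    assert np.mean(draws) == pytest.approx(0.0, abs=0.03)
    assert np.std(draws) == pytest.approx(1.0, abs=0.03)


def test_empty_likelihood_reproduces_the_priors():
    """With no data in the likelihood the sampler must return the priors:
    sigma_u ~ Uniform(0,1), betas ~ Normal(0, 10)."""
    stats = _SuffStats(
        k=np.zeros((2, 2)),
        n=np.zeros((2, 2)),
        group_idx=np.zeros(2, dtype=np.int64),
        groups=("all",),
        examiner_ids=("E1", "E2"),
    )
    spec = RaterModelSpec(chains=3, burn_in=500, keep=2500, seed=9)
    draws, names = _run_chains(stats, spec)
    sigma = draws[:, :, names.index("sigma_u")].ravel()
    beta0 = draws[:, :, names.index("beta0")].ravel()
    assert np.mean(sigma) == pytest.approx(0.5, abs=0.03)
    assert np.std(sigma) == pytest.approx(1 / math.sqrt(12), abs=0.03)
    assert sigma.min() > 0 and sigma.max() < 1
    assert np.mean(beta0) == pytest.approx(0.0, abs=1.0)
    assert np.std(beta0) == pytest.approx(10.0, abs=1.5)


# --- model fits ------------------------------------------------------------

@pytest.fixture(scope="module")
def recovery_fit():
    """Fit to a sigma_u = 0 cohort with known Sn = 0.37, Sp = 0.87."""
    config = SimulationConfig(
        n_subjects=500, n_ph=250, sigma_u=0.0, seed=21,
        truth=single_sign_truth(0.37, 0.87),
    )
    ds, _ = generate_cohort(config)
    post = fit_rater_model(ds, "loud_p2", "inspiration", QUICK)
    return ds, post


def test_parameter_recovery_at_known_truth(recovery_fit):
    _, post = recovery_fit
    assert post.converged
    est = average_examiner_summary(post)
    assert est.sensitivity.point == pytest.approx(0.37, abs=0.05)
    assert est.specificity.point == pytest.approx(0.87, abs=0.05)
    # closed-form LR+ from the generator truth: 0.37 / 0.13
    assert est.lr_pos.point == pytest.approx(0.37 / 0.13, abs=0.6)


def test_posterior_matches_descriptive_rates_when_unclustered(recovery_fit):
    """With sigma_u = 0 and plenty of data the model-based Sn/Sp land on the
    pooled 2x2 proportions."""
    ds, post = recovery_fit
    table = build_contingency(ds, "loud_p2", "inspiration")
    est = average_examiner_summary(post)
    assert est.sensitivity.point == pytest.approx(
        table.tp / table.n_diseased, abs=0.03
    )
    assert est.specificity.point == pytest.approx(table.tn / table.n_healthy, abs=0.03)


def test_derived_draws_satisfy_lr_identities(recovery_fit):
    _, post = recovery_fit
    sn, sp = post.sn_draws(), post.sp_draws()
    assert np.all((0 < sn) & (sn < 1) & (0 < sp) & (sp < 1))
    np.testing.assert_array_equal(post.lr_pos_draws(), sn / (1 - sp))
    np.testing.assert_array_equal(post.lr_neg_draws(), (1 - sn) / sp)
    assert post.n_draws == QUICK.chains * QUICK.keep


def test_posterior_summary_layout(recovery_fit):
    _, post = recovery_fit
    frame = posterior_summary(post)
    assert {"parameter", "median", "q2.5", "q97.5", "rhat"} <= set(frame.columns)
    assert {"beta0", "beta1", "sigma_u", "sn", "lr_pos"} <= set(frame["parameter"])
    assert (frame["q2.5"] <= frame["median"]).all()
    assert (frame["median"] <= frame["q97.5"]).all()


def test_seed_reproducibility(paper_dataset):
    spec = RaterModelSpec(chains=2, burn_in=100, keep=200, seed=17)
    a = fit_rater_model(paper_dataset, "loud_p2", "rest", spec)
    b = fit_rater_model(paper_dataset, "loud_p2", "rest", spec)
    for name in a.draws:
        np.testing.assert_array_equal(a.draws[name], b.draws[name])


def test_doubling_the_data_narrows_the_posterior():
    """Information monotonicity: replicating every assessment must shrink
    the credible interval. Uses a small cohort with little examiner
    heterogeneity so binomial noise (which duplication halves) dominates
    the posterior width."""
    config = SimulationConfig(
        n_subjects=60, n_ph=30, sigma_u=0.1, seed=3, truth=single_sign_truth(0.4, 0.85)
    )
    ds, _ = generate_cohort(config)
    from phexam.rater_model import _sufficient_stats

    stats = _sufficient_stats(ds, "loud_p2", "inspiration", "pooled")
    doubled = _SuffStats(
        k=2 * stats.k, n=2 * stats.n, group_idx=stats.group_idx,
        groups=stats.groups, examiner_ids=stats.examiner_ids,
    )
    spec = RaterModelSpec(chains=3, burn_in=400, keep=1500, seed=5)
    d1, names = _run_chains(stats, spec)
    d2, _ = _run_chains(doubled, spec)
    i0, i1 = names.index("beta0"), names.index("beta1")
    sn1 = expit(d1[:, :, i0] + d1[:, :, i1]).ravel()
    sn2 = expit(d2[:, :, i0] + d2[:, :, i1]).ravel()
    width = lambda x: np.quantile(x, 0.975) - np.quantile(x, 0.025)
    assert width(sn2) < width(sn1)


def test_no_signal_data_centre_lr_on_one():
    findings = pd.DataFrame(
        [
            {
                "subject_id": f"P{i}", "examiner_id": e,
                "examiner_group": "specialist" if e in ("E1", "E2") else "generalist",
                "sign": "s4", "phase": "rest", "present": 0,
            }
            for i in range(10)
            for e in ("E1", "E2", "E3")
        ]
    )
    rhc = pd.DataFrame(
        {"subject_id": [f"P{i}" for i in range(10)], "mpap": [40.0] * 5 + [15.0] * 5}
    )
    ds = ExamDataset(findings=findings, rhc=rhc)
    post = fit_rater_model(
        ds, "s4", "rest", RaterModelSpec(chains=3, burn_in=400, keep=800, seed=2)
    )
    b1 = np.concatenate([c for c in post.draws["beta1"]])
    # with no positive findings the disease effect stays prior-dominated:
    # centred well within one prior SD of zero, and the LR+ CrI spans 1
    assert abs(np.median(b1)) < 5.0
    lr = post.lr_pos_draws()
    assert np.quantile(lr, 0.025) < 1.0 < np.quantile(lr, 0.975)


def test_single_disease_class_is_an_error():
    findings = pd.DataFrame(
        [
            {
                "subject_id": f"P{i}", "examiner_id": e, "examiner_group": "specialist",
                "sign": "s4", "phase": "rest", "present": i % 2,
            }
            for i in range(6)
            for e in ("E1", "E2")
        ]
    )
    rhc = pd.DataFrame({"subject_id": [f"P{i}" for i in range(6)], "mpap": [40.0] * 6})
    ds = ExamDataset(findings=findings, rhc=rhc)
    with pytest.raises(EstimationError, match="disease class"):
        fit_rater_model(ds, "s4", "rest", QUICK)


# --- group comparison ------------------------------------------------------

def _grouped_posterior(b0_s, b1_s, b0_g, b1_g):
    zeros = np.zeros_like(np.atleast_2d(b0_s))
    return RaterModelPosterior(
        draws={
            "beta0[specialist]": np.atleast_2d(b0_s),
            "beta1[specialist]": np.atleast_2d(b1_s),
            "beta0[generalist]": np.atleast_2d(b0_g),
            "beta1[generalist]": np.atleast_2d(b1_g),
            "sigma_u": zeros,
        },
        grouping="by_group",
        groups=("specialist", "generalist"),
        examiner_ids=("E1", "E2"),
        sign="loud_p2",
        phase="rest",
        spec=RaterModelSpec(grouping="by_group", chains=2, burn_in=1, keep=1),
    )


def test_identical_groups_never_strictly_exceed():
    b0 = np.linspace(-1, 0, 100)
    b1 = np.linspace(0.5, 1.5, 100)
    post = _grouped_posterior(b0, b1, b0.copy(), b1.copy())
    assert prob_group_lr_greater(post, "lr_pos") == 0.0


def test_hand_built_draws_count_strict_exceedances():
    b0 = np.full(1000, -1.0)
    b1_g = np.full(1000, 0.5)
    b1_s = np.full(1000, 1.0)
    b1_s[:40] = 0.1  # specialist LR+ smaller in exactly 40 of 1000 draws
    post = _grouped_posterior(b0, b1_s, b0.copy(), b1_g)
    assert prob_group_lr_greater(post, "lr_pos") == pytest.approx(0.96)


def test_group_comparison_requires_grouped_fit(recovery_fit):
    _, post = recovery_fit
    with pytest.raises(EstimationError):
        prob_group_lr_greater(post)
    with pytest.raises(EstimationError):
        post.sn_draws("specialist")
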