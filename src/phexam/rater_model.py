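"""Bayesian random-effects logistic model for clustered examiner findings.

Every subject in the study is assessed by several examiners, so the
per-assessment binary outcomes are clustered by rater. For one sign and
phase the model is

    y_ie | p_ie ~ Bernoulli(p_ie)
    logit p_ie  = beta0 + beta1 * D_i + u_e
    u_e         ~ Normal(0, sigma_u^2)      (one shared intercept per examiner)

with D_i the catheterization-confirmed disease status of subject i. Priors
are diffuse Normal(0, sd=10) on the regression parameters and Uniform(0, 1)
on sigma_u. Under ``grouping="by_group"`` the (beta0, beta1) pair is
group-specific (specialist vs generalist) while the examiner random effect
and its SD are shared.

For the "average examiner" (random effect at its central value u = 0) each
posterior draw maps to

    Sn = invlogit(beta0 + beta1)     Sp = 1 - invlogit(beta0)
    LR+ = Sn / (1 - Sp)              LR- = (1 - Sn) / Sp

so credible intervals for sensitivity, specificity and likelihood ratios
come directly from the transformed draws.

Sampling uses univariate slice sampling (stepping-out and shrinkage) within
a Gibbs scan over all parameters — a tuning-free, correct MCMC for this
low-dimensional posterior. The likelihood collapses to sufficient statistics
(positive-finding counts per examiner x disease class), so each density
evaluation is O(#examiners). Convergence is monitored with the Gelman-Rubin
potential scale reduction factor across parallel chains.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy.special import expit

from .data import GROUPS, PHASES, SIGNS, ExamDataset
from .errors import EmptySelectionError, EstimationError

__all__ = [
    "RaterModelSpec",
    "RaterModelPosterior",
    "fit_rater_model",
    "average_examiner_summary",
    "prob_group_lr_greater",
    "gelman_rubin",
    "posterior_summary",
    "accuracy_report",
]


class RaterModelSpec(BaseModel):
    """Priors and MCMC settings for the rater model.

    Defaults mirror the study's analysis: three parallel chains, 10,000
    burn-in and 10,000 retained iterations each. Shorter, still-convergent
    runs (e.g. ``burn_in=2000, keep=2000``) are fine for this posterior and
    are what the bundled pipeline uses by default.
    """

    grouping: Literal["pooled", "by_group"] = "pooled"
    prior_sd_beta: float = Field(default=10.0, gt=0)
    prior_sigma_range: tuple[float, float] = (0.0, 1.0)
    chains: int = Field(default=3, ge=2)
    burn_in: int = Field(default=10_000, gt=0)
    keep: int = Field(default=10_000, gt=0)
    seed: int = Field(default=0, ge=0)
    rhat_threshold: float = Field(default=1.1, gt=1.0)

    @model_validator(mode="after")
    def _check_sigma_range(self) -> "RaterModelSpec":
        lo, hi = self.prior_sigma_range
        if not 0 <= lo < hi:
            raise ValueError(f"prior_sigma_range must satisfy 0 <= lo < hi, got {(lo, hi)}")
        return self


@dataclass
class RaterModelPosterior:
    """Retained draws and convergence diagnostics from one model fit.

    ``draws`` maps parameter names ("beta0", "beta1[specialist]",
    "sigma_u", "u[E1]", ...) to arrays of shape (chains, keep). Derived
    per-draw quantities (Sn, Sp, LRs) are computed on demand from the
    transformation above, so the LR identities hold exactly by construction.
    """

    draws: dict[str, np.ndarray]
    grouping: str
    groups: tuple[str, ...]
    examiner_ids: tuple[str, ...]
    sign: str
    phase: str
    spec: RaterModelSpec
    rhat: dict[str, float] = field(default_factory=dict)
    converged: bool = True

    @property
    def n_draws(self) -> int:
        first = next(iter(self.draws.values()))
        return int(first.size)

    def _beta_names(self, group: str | None) -> tuple[str, str]:
        if self.grouping == "pooled":
            if group is not None:
                raise EstimationError(
                    "posterior was fitted pooled; no group-specific draws available"
                )
            return "beta0", "beta1"
        if group is None:
            raise EstimationError(
                "posterior was fitted by_group; pass group='specialist' or 'generalist'"
            )
        if group not in self.groups:
            raise EstimationError(f"unknown group {group!r}; fitted groups: {self.groups}")
        return f"beta0[{group}]", f"beta1[{group}]"

    def sn_draws(self, group: str | None = None) -> np.ndarray:
        b0, b1 = self._beta_names(group)
        return expit(self.draws[b0].ravel() + self.draws[b1].ravel())

    def sp_draws(self, group: str | None = None) -> np.ndarray:
        b0, _ = self._beta_names(group)
        return 1.0 - expit(self.draws[b0].ravel())

    def lr_pos_draws(self, group: str | None = None) -> np.ndarray:
        sn, sp = self.sn_draws(group), self.sp_draws(group)
        return sn / (1.0 - sp)

    def lr_neg_draws(self, group: str | None = None) -> np.ndarray:
        sn, sp = self.sn_draws(group), self.sp_draws(group)
        return (1.0 - sn) / sp


def gelman_rubin(chains) -> float:
    """Potential scale reduction factor for one scalar parameter.

    ``R̂ = sqrt(((n−1)/n · W + B/n) / W)`` with W the mean within-chain
    variance and B the between-chain variance (n times the variance of the
    chain means). Requires at least two chains of equal length >= 2.
    Two identical chains give ``sqrt((n−1)/n)`` (just below 1); grossly
    separated chains give values far above 1.
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise EstimationError("gelman_rubin needs >= 2 chains (a 2-d array: chains x draws)")
    m, n = x.shape
    if n < 2:
        raise EstimationError("each chain needs >= 2 draws")
    w = x.var(axis=1, ddof=1).mean()
    b = n * x.mean(axis=1).var(ddof=1)
    if w == 0.0:
        return 1.0 if b == 0.0 else math.inf
    return float(math.sqrt(((n - 1) / n * w + b / n) / w))


# ---------------------------------------------------------------------------
# sufficient statistics and posterior density


@dataclass(frozen=True)
class _SuffStats:
    """Positive-finding counts per examiner x disease class.

    ``k[e, d]`` positives out of ``n[e, d]`` assessments by examiner e of
    subjects with disease status d (0 = no PH, 1 = PH); ``group_idx[e]``
    indexes the examiner's stratum in ``groups``.
    """

    k: np.ndarray
    n: np.ndarray
    group_idx: np.ndarray
    groups: tuple[str, ...]
    examiner_ids: tuple[str, ...]


def _sufficient_stats(
    dataset: ExamDataset, sign: str, phase: str, grouping: str
) -> _SuffStats:
    if sign not in SIGNS or phase not in PHASES:
        raise EmptySelectionError(f"unknown sign/phase {(sign, phase)!r}")
    merged = dataset.merged_findings()
    sel = merged.loc[(merged["sign"] == sign) & (merged["phase"] == phase)]
    if sel.empty:
        raise EmptySelectionError(f"no assessments for sign={sign!r}, phase={phase!r}")
    roster = (
        sel[["examiner_id", "examiner_group"]].drop_duplicates().sort_values("examiner_id")
    )
    examiner_ids = tuple(str(e) for e in roster["examiner_id"])
    if len(examiner_ids) < 2:
        raise EstimationError("rater model needs assessments from >= 2 examiners")
    groups: tuple[str, ...] = GROUPS if grouping == "by_group" else ("all",)
    if grouping == "by_group":
        group_idx = roster["examiner_group"].map({g: i for i, g in enumerate(GROUPS)})
        group_idx = group_idx.to_numpy(dtype=np.int64)
        if len(set(group_idx.tolist())) < 2:
            raise EstimationError("by_group fit needs examiners from both strata")
    else:
        group_idx = np.zeros(len(examiner_ids), dtype=np.int64)
    e_index = {e: i for i, e in enumerate(examiner_ids)}
    k = np.zeros((len(examiner_ids), 2))
    n = np.zeros((len(examiner_ids), 2))
    eis = sel["examiner_id"].astype(str).map(e_index).to_numpy()
    dis = sel["ph_status"].to_numpy(dtype=np.int64)
    np.add.at(n, (eis, dis), 1.0)
    np.add.at(k, (eis, dis), sel["present"].to_numpy(dtype=float))
    if n[:, 0].sum() == 0 or n[:, 1].sum() == 0:
        raise EstimationError(
            "both disease classes must be present among the assessed subjects"
        )
    return _SuffStats(k=k, n=n, group_idx=group_idx, groups=groups,
                      examiner_ids=examiner_ids)


def _make_log_posterior(stats: _SuffStats, spec: RaterModelSpec) -> Callable:
    k, n, gidx = stats.k, stats.n, stats.group_idx
    n_groups = len(stats.groups)
    n_exam = len(stats.examiner_ids)
    sig_lo, sig_hi = spec.prior_sigma_range
    inv_two_var_beta = 0.5 / spec.prior_sd_beta**2
    d = np.array([0.0, 1.0])

    def log_post(theta: np.ndarray) -> float:
        b0 = theta[:n_groups]
        b1 = theta[n_groups : 2 * n_groups]
        sigma = theta[2 * n_groups]
        u = theta[2 * n_groups + 1 :]
        if not sig_lo < sigma < sig_hi:
            return -math.inf
        eta = (b0[gidx] + u)[:, None] + np.outer(b1[gidx], d)
        ll = float(np.sum(k * eta) - np.sum(n * np.logaddexp(0.0, eta)))
        lp = (
            -inv_two_var_beta * float(b0 @ b0 + b1 @ b1)
            - n_exam * math.log(sigma)
            - 0.5 * float(u @ u) / sigma**2
        )
        return ll + lp

    return log_post


# ---------------------------------------------------------------------------
# slice sampler


def _slice_update(
    logf: Callable[[float], float],
    x0: float,
    log_fx0: float,
    width: float,
    rng: np.random.Generator,
    max_steps: int = 32,
) -> tuple[float, float]:
    """One univariate slice-sampling update (Neal 2003: stepping-out with a
    random step budget, then shrinkage). Returns the new point and its
    log-density."""
    log_y = log_fx0 + math.log(rng.random())
    left = x0 - width * rng.random()
    right = left + width
    j = int(rng.integers(max_steps))
    kk = max_steps - 1 - j
    while j > 0 and logf(left) > log_y:
        left -= width
        j -= 1
    while kk > 0 and logf(right) > log_y:
        right += width
        kk -= 1
    while True:
        x1 = left + rng.random() * (right - left)
        log_fx1 = logf(x1)
        if log_fx1 >= log_y:
            return x1, log_fx1
        if x1 < x0:
            left = x1
        else:
            right = x1


def _run_chains(
    stats: _SuffStats, spec: RaterModelSpec
) -> tuple[np.ndarray, list[str]]:
    """Run the configured chains; returns draws (chains, keep, P) and the
    parameter names in column order."""
    n_groups = len(stats.groups)
    n_exam = len(stats.examiner_ids)
    if n_groups == 1:
        names = ["beta0", "beta1"]
    else:
        names = [f"beta0[{g}]" for g in stats.groups] + [
            f"beta1[{g}]" for g in stats.groups
        ]
    names.append("sigma_u")
    names += [f"u[{e}]" for e in stats.examiner_ids]
    n_par = len(names)
    sig_lo, sig_hi = spec.prior_sigma_range
    sig_width = min(0.25 * (sig_hi - sig_lo), 0.5)
    widths = np.concatenate(
        [np.full(2 * n_groups, 2.0), [sig_width], np.full(n_exam, 0.5)]
    )
    log_post = _make_log_posterior(stats, spec)

    draws = np.empty((spec.chains, spec.keep, n_par))
    seeds = np.random.SeedSequence(spec.seed).spawn(spec.chains)
    for c in range(spec.chains):
        rng = np.random.default_rng(seeds[c])
        theta = np.empty(n_par)
        theta[: 2 * n_groups] = rng.normal(0.0, 2.0, size=2 * n_groups)
        theta[2 * n_groups] = rng.uniform(
            sig_lo + 0.05 * (sig_hi - sig_lo), sig_hi - 0.05 * (sig_hi - sig_lo)
        )
        theta[2 * n_groups + 1 :] = rng.normal(0.0, 0.1, size=n_exam)
        log_fx = log_post(theta)
        for it in range(spec.burn_in + spec.keep):
            for i in range(n_par):
                def logf_i(v: float, _i: int = i) -> float:
                    theta[_i] = v
                    return log_post(theta)

                x0 = theta[i]
                x1, log_fx = _slice_update(logf_i, x0, log_fx, widths[i], rng)
                theta[i] = x1
            if it >= spec.burn_in:
                draws[c, it - spec.burn_in] = theta
    return draws, names


def fit_rater_model(
    dataset: ExamDataset, sign: str, phase: str, spec: RaterModelSpec | None = None
) -> RaterModelPosterior:
    """Fit the random-effects logistic model to one sign x phase.

    Missing assessments (an examiner who skipped a subject) are simply
    absent from the likelihood. Non-convergence (any monitored R̂ at or
    above ``spec.rhat_threshold``) is flagged on the returned posterior,
    never silently ignored.
    """
    spec = spec or RaterModelSpec()
    stats = _sufficient_stats(dataset, sign, phase, spec.grouping)
    draws, names = _run_chains(stats, spec)
    draw_map = {name: draws[:, :, i] for i, name in enumerate(names)}
    rhat = {name: gelman_rubin(draw_map[name]) for name in names}
    converged = all(r < spec.rhat_threshold for r in rhat.values())
    return RaterModelPosterior(
        draws=draw_map,
        grouping=spec.grouping,
        groups=stats.groups if spec.grouping == "by_group" else ("all",),
        examiner_ids=stats.examiner_ids,
        sign=sign,
        phase=phase,
        spec=spec,
        rhat=rhat,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# posterior summaries


def _central_interval(x: np.ndarray) -> tuple[float, float, float]:
    return (
        float(np.median(x)),
        float(np.quantile(x, 0.025)),
        float(np.quantile(x, 0.975)),
    )


def average_examiner_summary(post: RaterModelPosterior, group: str | None = None):
    """Posterior median and central 95% credible interval for Sn, Sp, LR+
    and LR− of the average examiner (random effect at 0).

    Returns an :class:`~phexam.contingency.AccuracyEstimate` whose intervals
    are credible intervals (``method`` says so).
    """
    from .contingency import AccuracyEstimate, IntervalEstimate

    if post.n_draws == 0:
        raise EstimationError("posterior contains no draws")
    parts = {}
    for name, arr in (
        ("sensitivity", post.sn_draws(group)),
        ("specificity", post.sp_draws(group)),
        ("lr_pos", post.lr_pos_draws(group)),
        ("lr_neg", post.lr_neg_draws(group)),
    ):
        med, lo, hi = _central_interval(arr)
        parts[name] = IntervalEstimate(med, lo, hi)
    return AccuracyEstimate(method="posterior median, 95% CrI", **parts)


def prob_group_lr_greater(
    post: RaterModelPosterior, quantity: Literal["lr_pos", "lr_neg"] = "lr_pos"
) -> float:
    """Posterior probability that the specialist likelihood ratio strictly
    exceeds the generalist one (fraction of draws with a strict ``>``; draws
    where the two are exactly tied count as zero)."""
    if post.grouping != "by_group":
        raise EstimationError("group comparison requires a by_group fit")
    fn = post.lr_pos_draws if quantity == "lr_pos" else post.lr_neg_draws
    spec_draws, gen_draws = fn("specialist"), fn("generalist")
    return float(np.mean(spec_draws > gen_draws))


def posterior_summary(post: RaterModelPosterior) -> pd.DataFrame:
    """One row per parameter and derived quantity: median, 2.5% and 97.5%
    quantiles, and R̂ where per-chain draws exist."""
    rows = []
    for name, arr in post.draws.items():
        med, lo, hi = _central_interval(arr.ravel())
        rows.append(
            {"parameter": name, "median": med, "q2.5": lo, "q97.5": hi,
             "rhat": post.rhat.get(name, np.nan)}
        )
    group_iter = [None] if post.grouping == "pooled" else list(post.groups)
    for group in group_iter:
        label = "" if group is None else f"[{group}]"
        for qname, fn in (
            ("sn", post.sn_draws), ("sp", post.sp_draws),
            ("lr_pos", post.lr_pos_draws), ("lr_neg", post.lr_neg_draws),
        ):
            med, lo, hi = _central_interval(fn(group))
            rows.append(
                {"parameter": f"{qname}{label}", "median": med, "q2.5": lo,
                 "q97.5": hi, "rhat": np.nan}
            )
    return pd.DataFrame(rows)


def accuracy_report(
    dataset: ExamDataset,
    signs: tuple[str, ...] | None = None,
    phases: tuple[str, ...] | None = None,
    spec: RaterModelSpec | None = None,
) -> pd.DataFrame:
    """Model-based test-characteristics table across signs and phases.

    For every sign x phase two models are fitted: pooled (the "all
    examiners" row) and by_group (specialist and generalist rows, plus the
    posterior probabilities that the specialist LRs are larger). Row layout
    mirrors the familiar summary table: sign, phase, examiner stratum, Sn%,
    Sp%, LR+ [CrI], LR− [CrI]. Seeds for the individual fits are derived
    deterministically from ``spec.seed``.
    """
    base = spec or RaterModelSpec()
    signs = signs or SIGNS
    phases = phases or PHASES
    rows = []
    fit_idx = 0
    for sign in signs:
        for phase in phases:
            try:
                _sufficient_stats(dataset, sign, phase, "pooled")
            except EmptySelectionError:
                continue
            for grouping in ("pooled", "by_group"):
                sub_seed = int(
                    np.random.SeedSequence([base.seed, fit_idx]).generate_state(1)[0]
                    % (2**31)
                )
                fit_idx += 1
                fit_spec = base.model_copy(
                    update={"grouping": grouping, "seed": sub_seed}
                )
                post = fit_rater_model(dataset, sign, phase, fit_spec)
                if grouping == "pooled":
                    targets = [("all", None)]
                    p_pos = p_neg = np.nan
                else:
                    targets = [(g, g) for g in post.groups]
                    p_pos = prob_group_lr_greater(post, "lr_pos")
                    p_neg = prob_group_lr_greater(post, "lr_neg")
                for label, group in targets:
                    est = average_examiner_summary(post, group)
                    rows.append(
                        {
                            "sign": sign,
                            "phase": phase,
                            "examiners": label,
                            **est.to_row(),
                            "p_specialist_lr_pos_greater": p_pos,
                            "p_specialist_lr_neg_greater": p_neg,
                            "rhat_max": max(post.rhat.values()),
                            "converged": post.converged,
                        }
                    )
    return pd.DataFrame(rows)
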