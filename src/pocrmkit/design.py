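"""Two-stage likelihood-based POCRM: working model, ordering selection,
combination recommendation, and sequential trial execution.

Stage 1 escalates along a pre-specified path in cohorts of one patient until
the first dose-limiting toxicity (DLT); stage 2 is model-based: after each
cohort the one-parameter power ("empiric") CRM working model

    p(theta; alpha_l) = alpha_l ** exp(theta)

is fitted under every candidate ordering (the skeleton value alpha_l attaches
to ordering position l), the ordering with the largest prior-weighted
likelihood is selected, and the next cohort is assigned to the combination
whose estimated DLT probability is closest to the target toxicity level.

Estimation is either ``"ml"`` (maximized Bernoulli likelihood; the default,
matching a likelihood-based two-stage design) or ``"bayes"`` (integrated
likelihood under a zero-mean normal prior on theta, Gauss-Hermite
quadrature, posterior-mean probability estimates).

The ML solve exploits that the log-likelihood is concave in u = exp(theta)
(its u-derivative is monotone decreasing), so a safeguarded bisection on the
sign of the score finds the unique maximizer; it is vectorized over
orderings and simulated trials, which is what makes 10^4-replicate operating
characteristics affordable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

from .poset import Combination, CombinationPoset, Ordering, is_linear_extension
from .scenarios import ToxicityScenario
from .selection import PriorWeights

_BISECT_ITERS = 25
_DEFAULT_BOUNDS = (-10.0, 10.0)
#: prior s.d. for theta in "bayes" mode (the conventional CRM choice)
DEFAULT_PRIOR_SD = 1.34


def crm_prob(theta: float, skeleton_value: float) -> float:
    """Power-model DLT probability ``alpha ** exp(theta)``.

    Equals the skeleton value at theta = 0 and decreases in theta.
    """
    if not 0.0 < skeleton_value < 1.0:
        raise ValueError("skeleton value must lie in (0, 1)")
    return float(skeleton_value ** math.exp(theta))


@dataclass(frozen=True)
class DesignConfig:
    """POCRM design parameters.

    ``skeleton`` is the increasing sequence of guess probabilities attached
    to ordering positions (not to combinations); ``priors`` defaults to
    equal weights over ``orderings``.
    """

    poset: CombinationPoset
    ttl: float
    skeleton: np.ndarray
    orderings: tuple[Ordering, ...]
    stage1_path: Ordering
    n_max: int
    priors: Optional[PriorWeights] = None
    stage2_cohort: int = 1
    estimation: str = "ml"
    theta_bounds: tuple[float, float] = _DEFAULT_BOUNDS
    prior_sd: float = DEFAULT_PRIOR_SD

    def __post_init__(self) -> None:
        skeleton = np.asarray(self.skeleton, dtype=float)
        object.__setattr__(self, "skeleton", skeleton)
        object.__setattr__(self, "orderings", tuple(self.orderings))
        L = len(self.poset)
        if skeleton.shape != (L,):
            raise ValueError("skeleton length must equal the number of combinations")
        if not ((skeleton > 0) & (skeleton < 1)).all():
            raise ValueError("skeleton values must lie in (0, 1)")
        if not (np.diff(skeleton) > 0).all():
            raise ValueError("skeleton must be strictly increasing")
        if not 0.0 < self.ttl < 1.0:
            raise ValueError("ttl must lie in (0, 1)")
        if not self.orderings:
            raise ValueError("at least one ordering is required")
        for o in self.orderings:
            if not is_linear_extension(o, self.poset):
                raise ValueError(f"ordering {o.labels()} is not a linear extension")
        if not is_linear_extension(self.stage1_path, self.poset):
            raise ValueError("stage1_path must be a linear extension")
        if self.priors is not None and len(self.priors) != len(self.orderings):
            raise ValueError("priors must be defined exactly on the orderings")
        if self.estimation not in ("ml", "bayes"):
            raise ValueError("estimation must be 'ml' or 'bayes'")
        if self.n_max < 1 or self.stage2_cohort < 1:
            raise ValueError("n_max and stage2_cohort must be positive")
        if not self.theta_bounds[0] < self.theta_bounds[1]:
            raise ValueError("theta_bounds must be an increasing interval")

    def prior_weights(self) -> PriorWeights:
        return self.priors if self.priors is not None else PriorWeights.equal(
            len(self.orderings)
        )

    def with_n_max(self, n_max: int) -> "DesignConfig":
        return replace(self, n_max=n_max)


@dataclass(frozen=True)
class TrialResult:
    """Outputs of one simulated trial."""

    recommended: Combination
    final_ordering: Optional[int]
    n_treated: int
    allocation: dict[Combination, int]
    dlt_count: int
    assignments: tuple[Combination, ...]
    outcomes: tuple[int, ...]
    stages: tuple[int, ...]
    selected_orderings: tuple[Optional[int], ...]


class TrialBatch:
    """Vectorized results of many independent simulated trials.

    Per-trial recommendation/ordering vectors plus full per-patient
    histories (assignment, outcome, stage, selected ordering), all indexed
    into ``poset.elements`` / the ordering list; -1 encodes "none".
    """

    def __init__(
        self,
        poset: CombinationPoset,
        recommended_idx: np.ndarray,
        final_ordering: np.ndarray,
        assign_hist: np.ndarray,
        outcome_hist: np.ndarray,
        stage_hist: np.ndarray,
        selected_hist: np.ndarray,
    ) -> None:
        self.poset = poset
        self.recommended_idx = recommended_idx
        self.final_ordering = final_ordering
        self.assign_hist = assign_hist
        self.outcome_hist = outcome_hist
        self.stage_hist = stage_hist
        self.selected_hist = selected_hist

    @property
    def n_sims(self) -> int:
        return len(self.recommended_idx)

    def recommended(self) -> list[Combination]:
        return [self.poset.elements[i] for i in self.recommended_idx]


# ---------------------------------------------------------------------------
# likelihood kernels
# ---------------------------------------------------------------------------


def _score_loglik(
    logalpha: np.ndarray,
    tox: np.ndarray,
    notox: np.ndarray,
    theta_bounds: tuple[float, float],
) -> tuple[np.ndarray, np.ndarray]:
    """MLE of theta and the maximized log-likelihood, per (sim, ordering).

    ``logalpha``: (M, L) log skeleton value of each combination under each
    ordering; ``tox``/``notox``: (S, L) per-combination outcome counts.
    Returns theta_hat (S, M) and loglik (S, M).  Combinations never treated
    contribute zero to both the score and the likelihood, so no masking is
    needed.  With homogeneous data the score never changes sign and the
    bisection collapses onto the relevant bound.
    """
    S = tox.shape[0]
    M = logalpha.shape[0]
    lo = np.full((S, M), theta_bounds[0])
    hi = np.full((S, M), theta_bounds[1])
    la = logalpha[None, :, :]
    # score g(theta) = sum_c la_c * tox_c  -  sum_c (la_c * notox_c) p_c/(1-p_c)
    # with p/(1-p) = 1/expm1(-lp); the first term is theta-free
    g_const = (la * tox[:, None, :]).sum(axis=2)
    lant = la * notox[:, None, :]
    with np.errstate(over="ignore"):  # expm1 -> inf simply zeroes the ratio
        for _ in range(_BISECT_ITERS):
            mid = 0.5 * (lo + hi)
            lp = np.exp(mid)[:, :, None] * la
            g = g_const - (lant / np.expm1(-lp)).sum(axis=2)
            # score nonnegative: maximum lies at or above mid.  Ties at 0
            # occur only where the likelihood is flat (underflow or no
            # data): moving up implements the clamp-to-upper-bound rule.
            gt = g >= 0
            lo = np.where(gt, mid, lo)
            hi = np.where(gt, hi, mid)
    theta = 0.5 * (lo + hi)
    return theta, _loglik_at(logalpha, tox, notox, theta)


def _loglik_at(
    logalpha: np.ndarray, tox: np.ndarray, notox: np.ndarray, theta: np.ndarray
) -> np.ndarray:
    """Bernoulli log-likelihood at per-(sim, ordering) theta values."""
    lp = np.minimum(np.exp(theta)[:, :, None] * logalpha[None, :, :], -1e-15)
    return (tox[:, None, :] * lp).sum(axis=2) + (
        notox[:, None, :] * np.log1p(-np.exp(lp))
    ).sum(axis=2)


def _hermite_nodes(prior_sd: float, n_nodes: int = 25) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Hermite nodes/log-weights for integrating against N(0, sd^2)."""
    x, w = np.polynomial.hermite.hermgauss(n_nodes)
    return math.sqrt(2.0) * prior_sd * x, np.log(w) - 0.5 * math.log(math.pi)


def _bayes_loglik_nodes(
    logalpha: np.ndarray, tox: np.ndarray, notox: np.ndarray, theta_nodes: np.ndarray
) -> np.ndarray:
    """Log-likelihood at fixed quadrature nodes: (S, M, K)."""
    out = np.empty((tox.shape[0], logalpha.shape[0], len(theta_nodes)))
    for k, th in enumerate(theta_nodes):
        lp = np.minimum(math.exp(th) * logalpha, -1e-15)  # (M, L)
        out[:, :, k] = tox @ lp.T + notox @ np.log1p(-np.exp(lp)).T
    return out


def _logsumexp(a: np.ndarray, axis: int) -> np.ndarray:
    m = a.max(axis=axis, keepdims=True)
    return (m + np.log(np.exp(a - m).sum(axis=axis, keepdims=True))).squeeze(axis)


# ---------------------------------------------------------------------------
# public single-fit operations
# ---------------------------------------------------------------------------


def _counts_from_positions(
    data: Iterable[tuple[int, int]], L: int
) -> tuple[np.ndarray, np.ndarray]:
    tox = np.zeros(L)
    notox = np.zeros(L)
    for pos, y in data:
        if not 1 <= pos <= L:
            raise ValueError(f"position {pos} out of range 1..{L}")
        if y:
            tox[pos - 1] += 1
        else:
            notox[pos - 1] += 1
    return tox, notox


def fit_crm(
    data: Iterable[tuple[int, int]],
    skeleton: Sequence[float],
    ordering: Optional[Ordering] = None,
    theta_bounds: tuple[float, float] = _DEFAULT_BOUNDS,
    estimation: str = "ml",
    prior_sd: float = DEFAULT_PRIOR_SD,
) -> tuple[float, np.ndarray]:
    """Fit the power-model CRM on (1-based position, outcome) pairs.

    Returns ``(theta_hat, estimates)`` with one estimate per ordering
    position; estimates are nondecreasing along the ordering because the
    skeleton is.  ``ordering`` is accepted so callers can map positions back
    to combinations; it does not enter the fit.  With ``"ml"`` and no data
    the likelihood is flat and a ``ValueError`` is raised; with homogeneous
    data theta clamps to the relevant bound.
    """
    skeleton = np.asarray(skeleton, dtype=float)
    logalpha = np.log(skeleton)[None, :]
    tox, notox = _counts_from_positions(data, len(skeleton))
    if estimation == "ml":
        if tox.sum() + notox.sum() == 0:
            raise ValueError("ML fit requires at least one observation")
        theta, _ = _score_loglik(logalpha, tox[None, :], notox[None, :], theta_bounds)
        th = float(theta[0, 0])
        return th, skeleton ** math.exp(th)
    if estimation != "bayes":
        raise ValueError("estimation must be 'ml' or 'bayes'")
    theta_nodes, logw = _hermite_nodes(prior_sd)
    ll = _bayes_loglik_nodes(logalpha, tox[None, :], notox[None, :], theta_nodes)[0, 0]
    post = np.exp(ll + logw - _logsumexp(ll + logw, axis=0))
    probs = skeleton[None, :] ** np.exp(theta_nodes)[:, None]  # (K, L)
    return float(post @ theta_nodes), post @ probs


def ordering_score(
    data: Iterable[tuple[Combination, int]],
    ordering: Ordering,
    prior: float,
    skeleton: Sequence[float],
    theta_bounds: tuple[float, float] = _DEFAULT_BOUNDS,
    estimation: str = "ml",
    prior_sd: float = DEFAULT_PRIOR_SD,
) -> float:
    """Prior-weighted likelihood of one ordering on (combination, outcome) data.

    ``"ml"``: prior times the maximized likelihood (plug-in); ``"bayes"``:
    prior times the likelihood integrated over the normal theta prior.
    Scores are comparable across orderings for fixed data.  For long trials
    prefer comparing log-scores: the product can underflow.
    """
    data = list(data)
    if not data:
        raise ValueError("ordering score requires at least one observation")
    pos_data = [(ordering.position(c), y) for c, y in data]
    skeleton = np.asarray(skeleton, dtype=float)
    tox, notox = _counts_from_positions(pos_data, len(skeleton))
    logalpha = np.log(skeleton)[None, :]
    if estimation == "ml":
        _, ll = _score_loglik(logalpha, tox[None, :], notox[None, :], theta_bounds)
        return prior * float(np.exp(ll[0, 0]))
    theta_nodes, logw = _hermite_nodes(prior_sd)
    ll = _bayes_loglik_nodes(logalpha, tox[None, :], notox[None, :], theta_nodes)[0, 0]
    return prior * float(np.exp(_logsumexp(ll + logw, axis=0)))


def select_ordering(scores: Sequence[float]) -> int:
    """Index of the maximal score; ties resolve to the lowest index."""
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("no scores to select from")
    return int(np.argmax(scores))


def recommend_combination(
    estimates: Sequence[tuple[Combination, float]],
    ttl: float,
    safety_state: bool = False,
) -> Combination:
    """Combination whose estimated DLT probability is closest to the TTL.

    ``estimates`` are (combination, estimate) pairs in increasing-toxicity
    position order of the selected ordering.  Ties resolve toward the less
    toxic entry (smaller estimate, then earlier position).  When
    ``safety_state`` is set — every patient so far had a DLT, so the clamped
    fit is not trustworthy — the least toxic combination is recommended.
    """
    estimates = list(estimates)
    if not estimates:
        raise ValueError("no estimates")
    if safety_state:
        return estimates[0][0]
    best = min(
        range(len(estimates)),
        key=lambda i: (abs(estimates[i][1] - ttl), estimates[i][1], i),
    )
    return estimates[best][0]


# ---------------------------------------------------------------------------
# sequential trial engine
# ---------------------------------------------------------------------------


class _Engine:
    """Per-config precomputation shared across simulated trials."""

    def __init__(self, scenario: ToxicityScenario, config: DesignConfig) -> None:
        if scenario.poset != config.poset:
            raise ValueError("scenario and design are on different posets")
        poset = config.poset
        L = len(poset)
        M = len(config.orderings)
        self.config = config
        self.prob = scenario.prob_array()
        self.logprior = np.log(config.prior_weights().weights)
        # logalpha_mat[m, c] = log skeleton value of combination c under ordering m
        self.logalpha_mat = np.empty((M, L))
        self.pos_mat = np.empty((M, L), dtype=np.int64)
        logskel = np.log(config.skeleton)
        for m, o in enumerate(config.orderings):
            for pos0, combo in enumerate(o.sequence):
                c = poset.index(combo)
                self.logalpha_mat[m, c] = logskel[pos0]
                self.pos_mat[m, c] = pos0
        self.path_idx = np.array(
            [poset.index(c) for c in config.stage1_path.sequence], dtype=np.int64
        )
        if config.estimation == "bayes":
            self.theta_nodes, self.logw = _hermite_nodes(config.prior_sd)

    def fit_select_recommend(
        self, tox: np.ndarray, n: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """Selected ordering index and recommended combination index per sim."""
        cfg = self.config
        notox = n - tox
        if cfg.estimation == "ml":
            theta, ll = _score_loglik(self.logalpha_mat, tox, notox, cfg.theta_bounds)
            msel = np.argmax(self.logprior[None, :] + ll, axis=1)
            rows = np.arange(len(msel))
            theta_sel = theta[rows, msel]
            p_all = np.exp(
                np.exp(theta_sel)[:, None] * self.logalpha_mat[msel]
            )
        else:
            ll = _bayes_loglik_nodes(self.logalpha_mat, tox, notox, self.theta_nodes)
            integrated = _logsumexp(ll + self.logw[None, None, :], axis=2)
            msel = np.argmax(self.logprior[None, :] + integrated, axis=1)
            rows = np.arange(len(msel))
            ll_sel = ll[rows, msel]  # (S, K)
            post = np.exp(ll_sel + self.logw - _logsumexp(ll_sel + self.logw, 1)[:, None])
            la_sel = self.logalpha_mat[msel]  # (S, L)
            p_nodes = np.exp(
                np.exp(self.theta_nodes)[None, :, None] * la_sel[:, None, :]
            )  # (S, K, L)
            p_all = np.einsum("sk,skl->sl", post, p_nodes)
        pos_sel = self.pos_mat[msel]  # (S, L)
        diff = np.abs(p_all - cfg.ttl)
        tie1 = diff == diff.min(axis=1, keepdims=True)
        est = np.where(tie1, p_all, np.inf)
        tie2 = est == est.min(axis=1, keepdims=True)
        rec = np.where(tie2, pos_sel, np.iinfo(np.int64).max).argmin(axis=1)
        all_dlt = notox.sum(axis=1) == 0
        if all_dlt.any():
            rec = np.where(all_dlt, pos_sel.argmin(axis=1), rec)
        return msel, rec


def run_trials(
    scenario: ToxicityScenario,
    config: DesignConfig,
    n_sims: int,
    rng_seed: int = 0,
) -> TrialBatch:
    """Simulate independent POCRM trials, vectorized across replicates.

    All trials share one seeded generator (one uniform draw per patient per
    trial), so results are reproducible given ``rng_seed`` and ``n_sims``.
    """
    eng = _Engine(scenario, config)
    poset = config.poset
    L = len(poset)
    N = config.n_max
    S = n_sims
    rng = np.random.default_rng(rng_seed)

    n_cnt = np.zeros((S, L))
    tox_cnt = np.zeros((S, L))
    in_stage1 = np.ones(S, dtype=bool)
    s1pos = np.zeros(S, dtype=np.int64)
    next_combo = np.full(S, eng.path_idx[0], dtype=np.int64)
    since_fit = np.zeros(S, dtype=np.int64)
    assign_hist = np.full((S, N), -1, dtype=np.int16)
    outcome_hist = np.zeros((S, N), dtype=np.int8)
    stage_hist = np.zeros((S, N), dtype=np.int8)
    selected_hist = np.full((S, N), -1, dtype=np.int32)
    rows = np.arange(S)
    last_path = len(eng.path_idx) - 1

    for t in range(N):
        assign = np.where(
            in_stage1, eng.path_idx[np.minimum(s1pos, last_path)], next_combo
        )
        out = rng.random(S) < eng.prob[assign]
        n_cnt[rows, assign] += 1.0
        tox_cnt[rows, assign] += out
        assign_hist[:, t] = assign
        outcome_hist[:, t] = out
        stage_hist[:, t] = np.where(in_stage1, 1, 2)
        s1pos[in_stage1 & ~out] += 1
        in_stage1 &= ~out
        active = ~in_stage1
        due = active & (since_fit == 0)
        if due.any():
            idx = np.flatnonzero(due)
            msel, rec = eng.fit_select_recommend(tox_cnt[idx], n_cnt[idx])
            next_combo[idx] = rec
            selected_hist[idx, t] = msel
        since_fit[active] = (since_fit[active] + 1) % config.stage2_cohort

    # final recommendation on the complete data
    recommended = eng.path_idx[np.minimum(s1pos, last_path)].copy()
    final_ordering = np.full(S, -1, dtype=np.int64)
    had_dlt = np.flatnonzero(~in_stage1)
    if had_dlt.size:
        msel, rec = eng.fit_select_recommend(tox_cnt[had_dlt], n_cnt[had_dlt])
        recommended[had_dlt] = rec
        final_ordering[had_dlt] = msel
    return TrialBatch(
        poset,
        recommended,
        final_ordering,
        assign_hist,
        outcome_hist,
        stage_hist,
        selected_hist,
    )


def run_trial(
    scenario: ToxicityScenario, config: DesignConfig, rng_seed: int = 0
) -> TrialResult:
    """Run a single trial; fully reproducible given the seed."""
    batch = run_trials(scenario, config, n_sims=1, rng_seed=rng_seed)
    poset = config.poset
    assignments = tuple(poset.elements[i] for i in batch.assign_hist[0])
    outcomes = tuple(int(y) for y in batch.outcome_hist[0])
    allocation: dict[Combination, int] = {c: 0 for c in poset.elements}
    for c in assignments:
        allocation[c] += 1
    fo = int(batch.final_ordering[0])
    return TrialResult(
        recommended=poset.elements[int(batch.recommended_idx[0])],
        final_ordering=None if fo < 0 else fo,
        n_treated=config.n_max,
        allocation=allocation,
        dlt_count=sum(outcomes),
        assignments=assignments,
        outcomes=outcomes,
        stages=tuple(int(s) for s in batch.stage_hist[0]),
        selected_orderings=tuple(
            None if m < 0 else int(m) for m in batch.selected_hist[0]
        ),
    )
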