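"""Theory of Visual Attention (TVA) encoding model and parameter fitting.

Briefly flashed letter arrays are modelled as an exponential race into a
capacity-limited visual short-term memory (VSTM).  Each display element i
receives an attentional weight w_i; its encoding rate is
``v_i = C * w_i / sum(w)`` where ``C`` (items/s) is the total processing
rate.  An element is encoded iff its exponential finishing time falls
within the effective exposure *and* fewer than K elements have already
filled VSTM.  The effective exposure is the nominal exposure minus the
perceptual threshold ``t0`` (ms); unmasked displays gain a constant iconic
prolongation ``mu`` (ms).

Whole report (all letters targets, equal weights) identifies ``t0``, ``C``,
``K`` and ``mu``.  Partial report (red targets among blue distractors,
left/right placement) additionally identifies the top-down selectivity
``alpha`` (distractor weight relative to targets; lower is better
selectivity) and the spatial laterality ``w_lat`` (attentional weight of
the left hemifield).

Fractional capacity K is interpreted as a two-point mixture over the
neighbouring integers: capacity is floor(K) with probability ceil(K) - K
and ceil(K) with probability K - floor(K).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from functools import lru_cache
from scipy import optimize

from .errors import DataIntegrityError, EstimationFailureError, UndefinedRatioError

# fixed-order Gauss-Legendre rule used for all race integrals
_QUAD_ORDER = 64
_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(_QUAD_ORDER)

#: fitting bounds (C in items/s, times in ms)
C_BOUNDS = (1e-3, 200.0)
MU_BOUNDS = (0.0, 500.0)
ALPHA_BOUNDS = (1e-3, 4.0)
W_LAT_BOUNDS = (1e-3, 1.0 - 1e-3)


# ---------------------------------------------------------------------------
# trial containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WholeReportTrial:
    """One whole-report display: all letters are to be reported."""

    exposure_ms: float
    masked: bool
    n_displayed: int
    n_correct_reported: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_correct_reported <= self.n_displayed):
            raise DataIntegrityError(
                f"reported {self.n_correct_reported} of {self.n_displayed} displayed"
            )


#: a layout is a sequence of (side, role) pairs
Element = tuple[str, str]  # ("left"|"right", "target"|"distractor")


@dataclass(frozen=True)
class PartialReportTrial:
    """One partial-report display: report targets, ignore distractors."""

    exposure_ms: float
    layout: tuple[Element, ...]
    reported_targets: int

    def __post_init__(self) -> None:
        n_targets = sum(1 for _, role in self.layout if role == "target")
        if not (0 <= self.reported_targets <= n_targets):
            raise DataIntegrityError(
                f"reported {self.reported_targets} of {n_targets} targets"
            )


@dataclass
class TVAParams:
    """Fitted attention parameters with fit diagnostics."""

    t0: float  # ms
    C: float  # items/s
    K: float  # items (may be fractional)
    mu: float  # ms, unmasked iconic prolongation
    alpha: float | None = None
    w_lat: float | None = None
    loglik: float = math.nan
    convergence: dict = field(default_factory=dict)


@dataclass(frozen=True)
class ChangeScores:
    """Pre/post change scores of the analysed whole-report parameters."""

    C_change: float
    C_rc: float
    K_change: float
    K_rc: float


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------


def effective_exposure(exposure_ms: float, t0: float, masked: bool, mu: float) -> float:
    """Usable processing time: exposure minus threshold, plus iconic
    persistence ``mu`` when the display is not masked."""
    tau = max(0.0, exposure_ms - t0)
    return tau if masked else tau + mu


@lru_cache(maxsize=64)
def _binom_coeffs(n: int) -> np.ndarray:
    return np.array([math.comb(n, j) for j in range(n + 1)], dtype=float)


def _binom_pmf(n: int, q: float) -> np.ndarray:
    j = np.arange(n + 1)
    return _binom_coeffs(n) * np.power(q, j) * np.power(1.0 - q, n - j)


def _capacity_mixture(K: float, n: int) -> list[tuple[int, float]]:
    """Two-point integer mixture representing fractional capacity K."""
    K = min(float(K), float(n))
    lo = math.floor(K)
    hi = math.ceil(K)
    if lo == hi:
        return [(lo, 1.0)]
    return [(lo, hi - K), (hi, K - lo)]


def whole_report_score_dist(n: int, C: float, K: float, tau_eff_ms: float) -> np.ndarray:
    """Probability vector of the whole-report score (0..n correct).

    With equal weights each of the n items finishes by ``tau_eff``
    independently with probability ``q = 1 - exp(-(C/n) * tau/1000)``; the
    score is the finisher count truncated at capacity:  P(score=j) =
    P(N=j) for j < k and P(N >= k) at j = k, mixed over the fractional-K
    integer pair.
    """
    if n < 1:
        raise DataIntegrityError("display size must be >= 1")
    q = 1.0 - math.exp(-(C / n) * max(tau_eff_ms, 0.0) / 1000.0)
    pmf = _binom_pmf(n, q)
    out = np.zeros(n + 1)
    for k, wk in _capacity_mixture(K, n):
        capped = np.zeros(n + 1)
        capped[:k] = pmf[:k]
        capped[k] = pmf[k:].sum()
        out += wk * capped
    return out


def _layout_rates(
    layout: Sequence[Element], C: float, alpha: float, w_lat: float
) -> np.ndarray:
    """Exponential race rates v_i (per second) for a partial-report layout."""
    weights = np.array(
        [
            (w_lat if side == "left" else 1.0 - w_lat)
            * (1.0 if role == "target" else alpha)
            for side, role in layout
        ]
    )
    total = weights.sum()
    if total <= 0:
        return np.zeros(len(weights))
    return C * weights / total


def _poisson_binomial_cdf_below(p: np.ndarray, k: int) -> np.ndarray:
    """P(sum of independent Bernoullis < k), vectorised over the last axis
    of per-trial probability columns ``p`` with shape (m, nodes)."""
    m, nodes = p.shape
    dist = np.zeros((m + 1, nodes))
    dist[0] = 1.0
    for i in range(m):
        pi = p[i]
        dist[1 : i + 2] = dist[1 : i + 2] * (1 - pi) + dist[: i + 1] * pi
        dist[0] = dist[0] * (1 - pi)
    return dist[:k].sum(axis=0)


def partial_report_probs(
    layout: Sequence[Element],
    params: TVAParams | Mapping,
    tau_eff_ms: float,
) -> np.ndarray:
    """Marginal report probability of each target element in ``layout``.

    A target t is reported iff it finishes by ``tau_eff`` with fewer than
    capacity-many other elements having finished first:

        P = integral_0^tau  v_t e^(-v_t s) * P(#others finished < k) ds

    evaluated by fixed-order Gauss-Legendre quadrature, mixed over the
    fractional-K pair.  Returns one probability per target, in layout order.
    """
    p = params if isinstance(params, Mapping) else params.__dict__
    C, K, alpha, w_lat = p["C"], p["K"], p["alpha"], p["w_lat"]
    if len(layout) > 6:
        raise DataIntegrityError("layouts of more than 6 elements are unsupported")
    v = _layout_rates(layout, C, alpha, w_lat) / 1000.0  # per ms
    tau = max(float(tau_eff_ms), 0.0)
    target_idx = [i for i, (_, role) in enumerate(layout) if role == "target"]
    if tau == 0.0 or not target_idx:
        return np.zeros(len(target_idx))
    # map GL nodes from [-1, 1] to [0, tau]
    s = 0.5 * tau * (_GL_NODES + 1.0)
    w_quad = 0.5 * tau * _GL_WEIGHTS
    probs = []
    for t in target_idx:
        others = np.array([i for i in range(len(layout)) if i != t], dtype=int)
        p_others = 1.0 - np.exp(-np.outer(v[others], s))  # (m-1, nodes)
        total = 0.0
        for k, wk in _capacity_mixture(K, len(layout)):
            if k == 0:
                continue
            if k > len(others):
                room = np.ones_like(s)
            else:
                room = _poisson_binomial_cdf_below(p_others, k)
            integrand = v[t] * np.exp(-v[t] * s) * room
            total += wk * float(np.dot(w_quad, integrand))
        probs.append(total)
    return np.asarray(probs)


def partial_report_count_dist(
    layout: Sequence[Element],
    params: TVAParams | Mapping,
    tau_eff_ms: float,
) -> np.ndarray:
    """Exact distribution of the number of reported targets (0..n_targets).

    Enumerates candidate encoded element sets S.  For |S| < capacity the
    set is encoded iff exactly the elements of S finish within ``tau``;
    for |S| = capacity the elements of S must be the first k finishers and
    the k-th finishing time must fall within ``tau`` (the integral over
    the maximum finishing time of S is evaluated by quadrature).
    """
    from itertools import combinations

    p = params if isinstance(params, Mapping) else params.__dict__
    C, K, alpha, w_lat = p["C"], p["K"], p["alpha"], p["w_lat"]
    m = len(layout)
    v = _layout_rates(layout, C, alpha, w_lat) / 1000.0
    tau = max(float(tau_eff_ms), 0.0)
    is_target = np.array([role == "target" for _, role in layout])
    n_targets = int(is_target.sum())
    out = np.zeros(n_targets + 1)
    if tau == 0.0:
        out[0] = 1.0
        return out
    s = 0.5 * tau * (_GL_NODES + 1.0)
    w_quad = 0.5 * tau * _GL_WEIGHTS
    p_fin = 1.0 - np.exp(-v[:, None] * s[None, :])  # (m, nodes)
    p_fin_tau = 1.0 - np.exp(-v * tau)

    for k, wk in _capacity_mixture(K, m):
        if k == 0:
            out[0] += wk
            continue
        for size in range(0, min(k, m) + 1):
            for S in combinations(range(m), size):
                S = list(S)
                rest = [i for i in range(m) if i not in S]
                n_t = int(is_target[S].sum()) if S else 0
                if size < k or size == m:
                    # all of S finish by tau, the rest do not
                    prob = float(np.prod(p_fin_tau[S])) * float(
                        np.prod(1.0 - p_fin_tau[rest])
                    )
                else:
                    # S are the first k finishers, k-th time <= tau:
                    # integrate density of max_{i in S} T_i against
                    # P(all others still unfinished at that time)
                    dens = np.zeros_like(s)
                    for i in S:
                        others_in_S = [j for j in S if j != i]
                        dens += (
                            v[i]
                            * np.exp(-v[i] * s)
                            * np.prod(p_fin[others_in_S], axis=0)
                        )
                    unfinished = np.prod(np.exp(-v[rest, None] * s[None, :]), axis=0)
                    prob = float(np.dot(w_quad, dens * unfinished))
                out[n_t] += wk * prob
    # guard against quadrature round-off
    out = np.clip(out, 0.0, None)
    return out / out.sum()


# ---------------------------------------------------------------------------
# likelihoods
# ---------------------------------------------------------------------------

_NEG_INF = -1e12  # finite surrogate for impossible observations


def _aggregate_whole(trials: Iterable[WholeReportTrial]):
    """Group trials by (exposure, masked, n) into observed-score count vectors."""
    groups: dict[tuple, np.ndarray] = {}
    for t in trials:
        key = (float(t.exposure_ms), bool(t.masked), int(t.n_displayed))
        if key not in groups:
            groups[key] = np.zeros(t.n_displayed + 1)
        groups[key][t.n_correct_reported] += 1
    return groups


def whole_report_loglik(
    params: TVAParams | Mapping, trials: Sequence[WholeReportTrial]
) -> float:
    """Log-likelihood (nats) of whole-report trials under the race model."""
    if not trials:
        raise DataIntegrityError("whole_report_loglik requires at least one trial")
    p = params if isinstance(params, Mapping) else params.__dict__
    return _whole_loglik_grouped(
        p["t0"], p["C"], p["K"], p["mu"], _aggregate_whole(trials)
    )


def _whole_loglik_grouped(t0, C, K, mu, groups) -> float:
    total = 0.0
    for (exposure, masked, n), counts in groups.items():
        tau = effective_exposure(exposure, t0, masked, mu)
        dist = whole_report_score_dist(n, C, K, tau)
        obs = counts > 0
        with np.errstate(divide="ignore"):
            logp = np.log(dist[obs])
        logp[~np.isfinite(logp)] = _NEG_INF
        total += float(np.dot(counts[obs], logp))
    return total


def partial_report_loglik(
    alpha: float,
    w_lat: float,
    whole_params: TVAParams,
    trials: Sequence[PartialReportTrial],
) -> float:
    """Log-likelihood of partial-report target counts, conditioning on the
    whole-report estimates of (t0, C, K); partial displays are always
    masked, so ``mu`` does not enter."""
    groups: dict[tuple, dict[int, int]] = {}
    for t in trials:
        key = (float(t.exposure_ms), t.layout)
        groups.setdefault(key, {})
        groups[key][t.reported_targets] = groups[key].get(t.reported_targets, 0) + 1
    p = dict(
        C=whole_params.C, K=whole_params.K, alpha=alpha, w_lat=w_lat
    )
    total = 0.0
    for (exposure, layout), counts in groups.items():
        tau = effective_exposure(exposure, whole_params.t0, True, whole_params.mu)
        dist = partial_report_count_dist(layout, p, tau)
        for score, cnt in counts.items():
            prob = dist[score]
            total += cnt * (math.log(prob) if prob > 0 else _NEG_INF)
    return total


# ---------------------------------------------------------------------------
# fitting (deterministic grid + Nelder-Mead refinement)
# ---------------------------------------------------------------------------


def _clip(x, lo, hi):
    return min(max(x, lo), hi)


def fit_whole_report(
    trials: Sequence[WholeReportTrial],
    *,
    grid_refine: bool = True,
) -> TVAParams:
    """Maximum-likelihood whole-report fit of (t0, C, K, mu).

    Deterministic: a coarse grid scan over the bounded parameter box is
    followed by Nelder-Mead refinement from the best grid point.  Fits at a
    parameter boundary are flagged as non-converged.
    """
    trials = list(trials)
    if not trials:
        raise EstimationFailureError("no whole-report trials")
    exposures = sorted({t.exposure_ms for t in trials})
    if len(exposures) < 3:
        raise EstimationFailureError(
            "whole-report fit needs >= 3 distinct exposures; "
            f"got {len(exposures)}"
        )
    if not any(t.masked for t in trials):
        raise EstimationFailureError("whole-report fit needs masked trials")
    n = max(t.n_displayed for t in trials)
    groups = _aggregate_whole(trials)

    # the threshold may exceed the smallest exposure (that condition then
    # yields all-zero reports); it is still identified by the intermediate
    # exposures, so the bound is a fixed 60 ms rather than min(exposures)
    t0_hi = min(60.0, max(exposures))
    t0_grid = np.linspace(0.0, t0_hi, 7)
    c_grid = np.geomspace(2.0, 150.0, 10)
    k_grid = np.linspace(0.5, n, 8)
    has_unmasked = any(not t.masked for t in trials)
    mu_grid = np.array([0.0, 50.0, 100.0, 200.0, 350.0]) if has_unmasked else np.array([0.0])

    best = (-math.inf, None)
    for t0 in t0_grid:
        for C in c_grid:
            for K in k_grid:
                for mu in mu_grid:
                    ll = _whole_loglik_grouped(t0, C, K, mu, groups)
                    if ll > best[0]:
                        best = (ll, (t0, C, K, mu))
    ll0, x0 = best

    def objective(x):
        t0 = _clip(x[0], 0.0, t0_hi)
        C = _clip(x[1], *C_BOUNDS)
        K = _clip(x[2], 1e-3, n)
        mu = _clip(x[3], *MU_BOUNDS)
        return -_whole_loglik_grouped(t0, C, K, mu, groups)

    res = optimize.minimize(
        objective,
        np.array(x0),
        method="Nelder-Mead",
        options={"xatol": 1e-3, "fatol": 1e-6, "maxiter": 2000},
    )
    if grid_refine and res.fun <= -ll0:
        t0 = _clip(res.x[0], 0.0, t0_hi)
        C = _clip(res.x[1], *C_BOUNDS)
        K = _clip(res.x[2], 1e-3, n)
        mu = _clip(res.x[3], *MU_BOUNDS)
        loglik = -float(res.fun)
    else:  # pragma: no cover - refinement can only improve the grid optimum
        t0, C, K, mu = x0
        loglik = ll0

    at_bound = C <= C_BOUNDS[0] * 1.01 or C >= C_BOUNDS[1] * 0.999 or K <= 2e-3
    convergence = {
        "converged": bool(res.success) and not at_bound,
        "at_boundary": bool(at_bound),
        "n_iter": int(res.nit),
        "grid_loglik": float(ll0),
        "message": str(res.message),
    }
    return TVAParams(t0=t0, C=C, K=K, mu=mu, loglik=loglik, convergence=convergence)


def fit_partial_report(
    trials: Sequence[PartialReportTrial], whole_params: TVAParams
) -> TVAParams:
    """Maximum-likelihood partial-report fit of (alpha, w_lat).

    The whole-report estimates (t0, C, K, mu) are held fixed; only the
    selectivity and laterality parameters are free.  Requires at least one
    distractor condition (else alpha is structurally non-identifiable) and
    targets on both sides (else w_lat is).
    """
    trials = list(trials)
    if not trials:
        raise EstimationFailureError("no partial-report trials")
    has_distractor = any(
        any(role == "distractor" for _, role in t.layout) for t in trials
    )
    target_sides = {
        side for t in trials for side, role in t.layout if role == "target"
    }
    if not has_distractor:
        raise EstimationFailureError(
            "alpha is non-identifiable: no distractor conditions present"
        )
    if len(target_sides) < 2:
        raise EstimationFailureError(
            "w_lat is non-identifiable: targets appear on one side only"
        )

    alpha_grid = np.geomspace(0.05, ALPHA_BOUNDS[1], 10)
    wlat_grid = np.linspace(0.1, 0.9, 9)
    best = (-math.inf, None)
    for a in alpha_grid:
        for w in wlat_grid:
            ll = partial_report_loglik(a, w, whole_params, trials)
            if ll > best[0]:
                best = (ll, (a, w))
    ll0, x0 = best

    def objective(x):
        a = _clip(x[0], *ALPHA_BOUNDS)
        w = _clip(x[1], *W_LAT_BOUNDS)
        return -partial_report_loglik(a, w, whole_params, trials)

    res = optimize.minimize(
        objective,
        np.array(x0),
        method="Nelder-Mead",
        options={"xatol": 1e-4, "fatol": 1e-7, "maxiter": 500},
    )
    a = _clip(res.x[0], *ALPHA_BOUNDS)
    w = _clip(res.x[1], *W_LAT_BOUNDS)
    loglik = -float(res.fun)
    convergence = {
        "converged": bool(res.success),
        "n_iter": int(res.nit),
        "grid_loglik": float(ll0),
        "message": str(res.message),
    }
    return TVAParams(
        t0=whole_params.t0,
        C=whole_params.C,
        K=whole_params.K,
        mu=whole_params.mu,
        alpha=a,
        w_lat=w,
        loglik=loglik,
        convergence=convergence,
    )


def change_scores(pre: TVAParams, post: TVAParams) -> ChangeScores:
    """Pre/post change scores: C_change, C_rc, K_change, K_rc."""
    if pre.C <= 0 or pre.K <= 0:
        raise UndefinedRatioError("pre-test C and K must be positive")
    return ChangeScores(
        C_change=post.C - pre.C,
        C_rc=post.C / pre.C,
        K_change=post.K - pre.K,
        K_rc=post.K / pre.K,
    )
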