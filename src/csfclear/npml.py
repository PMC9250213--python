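"""Nonparametric maximum-likelihood population estimation (adaptive grid).

The population distribution of the structural parameters is estimated as a
discrete distribution — support points with probability weights — that
maximizes the marginal likelihood

    L(w, theta_1..K) = prod_i  sum_j  w_j * p(y_i | theta_j)

For fixed support the inner problem is concave in ``w`` on the simplex and is
solved by a monotone multiplicative EM update.  The support itself is refined
by an adaptive grid: a seeded quasi-random initial grid over the parameter
bounds, then cycles of weight optimization, condensation (dropping
negligible-weight points) and local expansion of each surviving point by
+/- delta per dimension, with delta halved whenever a cycle fails to improve
the log-likelihood.

Bayesian posterior individual estimates re-weight the population support by
each subject's own likelihood; the posterior-mean parameter vector is the
basis for all individual predictions downstream.

All likelihood accumulation is done in the log domain with a per-subject
max-shift so that 8-11 observation profiles never underflow.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.stats import qmc

from csfclear.model import (
    STRUCTURE_PARAMS,
    TWO_COMPARTMENT,
    AssayErrorModel,
    DoseEvent,
    PKParameters,
    SubjectRecord,
    solve_profile,
)

__all__ = [
    "DEFAULT_BOUNDS",
    "FitConfig",
    "PopulationModel",
    "PosteriorEstimate",
    "SupportPoint",
    "condense",
    "expand",
    "fit",
    "information_criteria",
    "init_grid",
    "model_from_json",
    "model_to_json",
    "optimize_weights",
    "posterior_individual",
]

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)

#: Default parameter bounds for fitting. Absorption half-lives of ~0.5-35 h:
#: with the first venous sample at ~1 h and the last at 48 h, half-lives much
#: outside the sampling window are not identifiable, and open tails only feed
#: likelihood ridges that smear individual posteriors toward the bounds.
#: Lags up to 3 h, central volumes 20-300 L, elimination half-lives ~0.5-14 h.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "ka": (0.02, 1.4),
    "tlag": (0.0, 3.0),
    "v": (20.0, 300.0),
    "ke": (0.05, 1.5),
    "kcp": (0.0, 6.0),
    "kpc": (0.01, 3.0),
}


@dataclass(frozen=True)
class SupportPoint:
    params: PKParameters
    weight: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.weight <= 1.0 + 1e-12):
            raise ValueError(f"weight must be in [0, 1], got {self.weight}")


@dataclass(frozen=True)
class FitConfig:
    """Settings of the adaptive-grid fit.

    n_initial defaults to 50 * 2**d quasi-random points for d structural
    parameters; weight_floor defaults to 1e-8 * n_subjects; expansion starts
    at delta0 = 0.2 of each parameter range and is halved down to delta_min.
    """

    structure: str = TWO_COMPARTMENT
    bounds: dict[str, tuple[float, float]] | None = None
    n_initial: int | None = None
    seed: int = 0
    weight_floor: float | None = None
    delta0: float = 0.2
    delta_min: float = 1e-4
    tol: float = 0.01
    max_cycles: int = 100
    em_tol: float = 1e-10
    em_max_iter: int = 2000
    merge_tol: float = 1e-8
    subject_seeding: bool = True
    max_support: int | None = None

    def __post_init__(self) -> None:
        if self.structure not in STRUCTURE_PARAMS:
            raise ValueError(f"unknown structure {self.structure!r}")
        if self.delta_min >= self.delta0:
            raise ValueError("delta_min must be < delta0")
        for name, (lo, hi) in self.resolved_bounds().items():
            if not lo < hi:
                raise ValueError(f"bounds for {name} must satisfy low < high")

    def resolved_bounds(self) -> dict[str, tuple[float, float]]:
        names = STRUCTURE_PARAMS[self.structure]
        base = dict(DEFAULT_BOUNDS)
        if self.bounds:
            base.update(self.bounds)
        return {n: tuple(base[n]) for n in names}

    def resolved_n_initial(self) -> int:
        if self.n_initial is not None:
            return self.n_initial
        return 50 * 2 ** len(STRUCTURE_PARAMS[self.structure])


@dataclass(frozen=True)
class PopulationModel:
    """Discrete nonparametric population distribution."""

    support: tuple[SupportPoint, ...]
    loglik: float
    n_cycles: int
    n_subjects: int
    structure: str
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    seed: int = 0
    loglik_trace: tuple[float, ...] = ()
    converged: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "support", tuple(self.support))
        object.__setattr__(self, "loglik_trace", tuple(self.loglik_trace))
        total = sum(p.weight for p in self.support)
        if self.support and abs(total - 1.0) > 1e-10:
            raise ValueError(f"support weights sum to {total}, expected 1")
        if not math.isfinite(self.loglik):
            raise ValueError("loglik must be finite")

    @property
    def weights(self) -> np.ndarray:
        return np.array([p.weight for p in self.support])

    def points_array(self) -> np.ndarray:
        return np.array([p.params.as_array(self.structure) for p in self.support])

    def mean_params(self) -> PKParameters:
        """Population-mean parameter vector (weight-averaged coordinates)."""
        avg = self.weights @ self.points_array()
        return PKParameters.from_array(avg, self.structure)


@dataclass(frozen=True)
class PosteriorEstimate:
    """Per-subject Bayesian update of the population support."""

    subject_id: str
    posterior_weights: np.ndarray
    posterior_mean: PKParameters
    support: tuple[SupportPoint, ...]
    structure: str

    def __post_init__(self) -> None:
        w = np.asarray(self.posterior_weights, dtype=float)
        object.__setattr__(self, "posterior_weights", w)
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("posterior weights must sum to 1")


# ---------------------------------------------------------------------------
# grid initialization

def init_grid(
    bounds: dict[str, tuple[float, float]],
    n_initial_points: int,
    seed: int,
    structure: str = TWO_COMPARTMENT,
) -> list[PKParameters]:
    """Seeded low-discrepancy (Halton) grid of parameter vectors in bounds."""
    if n_initial_points <= 0:
        raise ValueError("n_initial_points must be positive")
    names = STRUCTURE_PARAMS[structure]
    lo = np.array([bounds[n][0] for n in names])
    hi = np.array([bounds[n][1] for n in names])
    sampler = qmc.Halton(d=len(names), seed=seed)
    unit = sampler.random(n_initial_points)
    pts = lo + unit * (hi - lo)
    return [PKParameters.from_array(row, structure) for row in pts]


# ---------------------------------------------------------------------------
# likelihood matrices (log domain)

class _StackedData:
    """All subjects' usable observations flattened for vectorized evaluation.

    Profiles are evaluated once per support point at the globally sorted
    observation times for a unit dose and rescaled per observation by the
    subject's dose amount (dose linearity of the system).
    """

    def __init__(self, subjects: Sequence[SubjectRecord]):
        times, conc, dose_amt, subj_idx = [], [], [], []
        for i, s in enumerate(subjects):
            t = s.obs_times
            if t.size == 0:
                raise ValueError(f"subject {s.id} has no usable observations")
            times.append(t)
            conc.append(s.obs_conc)
            dose_amt.append(np.full(t.size, s.dose.amount))
            subj_idx.append(np.full(t.size, i, dtype=int))
        self.subjects = list(subjects)
        self.times = np.concatenate(times)
        self.conc = np.concatenate(conc)
        self.dose_amt = np.concatenate(dose_amt)
        self.subj_idx = np.concatenate(subj_idx)
        self.order = np.argsort(self.times, kind="stable")
        self.sorted_times = self.times[self.order]
        self.inv = np.empty_like(self.order)
        self.inv[self.order] = np.arange(self.order.size)
        self.n_subjects = len(subjects)

    def loglik_column(
        self, params: PKParameters, error: AssayErrorModel, structure: str
    ) -> np.ndarray:
        unit = solve_profile(params, DoseEvent(1.0), self.sorted_times, structure)
        pred = unit[self.inv] * self.dose_amt
        sd = error.c0 + error.c1 * self.conc  # polynomial on the measurement
        resid = self.conc - pred
        per_obs = -np.log(sd) - _LOG_SQRT_2PI - 0.5 * (resid / sd) ** 2
        return np.bincount(self.subj_idx, weights=per_obs, minlength=self.n_subjects)


def _unit_central_matrix(
    points: np.ndarray, times: np.ndarray, structure: str
) -> np.ndarray:
    """Unit-dose central concentrations for all points at once: (K, T).

    Vectorized form of the closed-form solution in :mod:`csfclear.model`,
    with the same 1e-9 relative perturbations for confluent exponents.
    """
    ka = points[:, 0].copy()
    tlag = points[:, 1]
    v = points[:, 2]
    ke = points[:, 3]
    if structure == TWO_COMPARTMENT:
        kcp, kpc = points[:, 4], points[:, 5]
    else:
        kcp = np.zeros_like(ka)
        kpc = np.zeros_like(ka)
    s = ke + kcp + kpc
    disc = np.maximum(s * s - 4.0 * ke * kpc, 0.0)
    root = np.sqrt(disc)
    alpha = 0.5 * (s + root)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(alpha > 0, ke * kpc / np.where(alpha > 0, alpha, 1.0), 0.0)
    rep = (alpha > 0) & (np.abs(alpha - beta) < 1e-9 * alpha)
    if np.any(rep):
        ke2 = ke[rep] * (1.0 + 1e-7)
        s2 = ke2 + kcp[rep] + kpc[rep]
        root2 = np.sqrt(np.maximum(s2 * s2 - 4.0 * ke2 * kpc[rep], 0.0))
        alpha[rep] = 0.5 * (s2 + root2)
        beta[rep] = ke2 * kpc[rep] / alpha[rep]
    for _ in range(3):
        scale = np.maximum(np.maximum(ka, alpha), 1e-30)
        clash = (np.abs(ka - alpha) <= 1e-9 * scale) | (np.abs(ka - beta) <= 1e-9 * scale)
        if not np.any(clash):
            break
        ka[clash] *= 1.0 + 1e-9

    ts = times[None, :] - tlag[:, None]
    active = ts > 0.0
    tsc = np.where(active, ts, 0.0)
    ea = np.exp(-alpha[:, None] * tsc)
    eb = np.exp(-beta[:, None] * tsc)
    ek = np.exp(-ka[:, None] * tsc)
    c1 = (kpc - alpha) / ((ka - alpha) * (beta - alpha))
    c2 = (kpc - beta) / ((ka - beta) * (alpha - beta))
    c3 = (kpc - ka) / ((alpha - ka) * (beta - ka))
    ac = ka[:, None] * (c1[:, None] * ea + c2[:, None] * eb + c3[:, None] * ek)
    conc = np.where(active, ac, 0.0) / v[:, None]
    return np.maximum(conc, 0.0)


def _loglik_matrix(
    data: _StackedData,
    points: np.ndarray,
    error: AssayErrorModel,
    structure: str,
    block: int = 512,
) -> np.ndarray:
    """(n_subjects, n_points) log-likelihood matrix, evaluated in blocks."""
    k = len(points)
    if k == 0:
        return np.zeros((data.n_subjects, 0))
    boundaries = np.flatnonzero(np.r_[1, np.diff(data.subj_idx)])
    out = np.empty((data.n_subjects, k))
    sd = error.c0 + error.c1 * data.conc  # polynomial on the measurement
    for start in range(0, k, block):
        pts = points[start : start + block]
        unit = _unit_central_matrix(pts, data.sorted_times, structure)
        pred = unit[:, data.inv] * data.dose_amt[None, :]
        resid = data.conc[None, :] - pred
        per_obs = -np.log(sd)[None, :] - _LOG_SQRT_2PI - 0.5 * (resid / sd[None, :]) ** 2
        out[:, start : start + block] = np.add.reduceat(per_obs, boundaries, axis=1).T
    return out


# ---------------------------------------------------------------------------
# inner convex problem: weights on the simplex

def _em_weights(
    log_l: np.ndarray,
    w0: np.ndarray | None = None,
    tol: float = 1e-10,
    max_iter: int = 2000,
) -> tuple[np.ndarray, float]:
    """Monotone multiplicative EM for the NPML weights, in the log domain.

    Maximizes sum_i log sum_j w_j exp(log_l[i, j]) over the simplex.
    Returns (weights, objective).
    """
    n, _ = log_l.shape
    shift = np.max(log_l, axis=1, keepdims=True)
    if not np.all(np.isfinite(shift)):
        bad = int(np.argmax(~np.isfinite(shift.ravel())))
        raise ValueError(
            f"subject index {bad} is incompatible with every support point"
        )
    l_mat = np.exp(log_l - shift)  # row maxima are 1
    k = log_l.shape[1]
    w = np.full(k, 1.0 / k) if w0 is None else np.asarray(w0, dtype=float).copy()
    w = np.maximum(w, 0.0)
    w /= w.sum()
    mix = l_mat @ w
    obj = float(np.sum(np.log(mix)))
    for _ in range(max_iter):
        # w_j <- (1/N) sum_i w_j L_ij / (L w)_i
        w = w * (l_mat.T @ (1.0 / mix)) / n
        w = np.maximum(w, 0.0)
        w /= w.sum()
        mix = l_mat @ w
        new_obj = float(np.sum(np.log(mix)))
        if new_obj - obj < tol:
            obj = max(obj, new_obj)
            break
        obj = new_obj
    return w, obj + float(np.sum(shift))


def optimize_weights(
    likelihood_matrix: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 2000,
) -> np.ndarray:
    """Simplex weights maximizing sum_i log sum_j w_j L_ij.

    ``likelihood_matrix`` holds non-negative per-subject likelihoods (one row
    per subject, one column per support point); every row must contain a
    positive entry.
    """
    l_mat = np.asarray(likelihood_matrix, dtype=float)
    if l_mat.ndim != 2 or 0 in l_mat.shape:
        raise ValueError("likelihood matrix must be 2-D and non-empty")
    if np.any(l_mat < 0):
        raise ValueError("likelihoods must be non-negative")
    row_max = l_mat.max(axis=1)
    if np.any(row_max <= 0):
        bad = int(np.argmax(row_max <= 0))
        raise ValueError(
            f"subject index {bad} is incompatible with every support point"
        )
    with np.errstate(divide="ignore"):
        log_l = np.log(l_mat)
    w, _ = _em_weights(log_l, tol=tol, max_iter=max_iter)
    return w


# ---------------------------------------------------------------------------
# support maintenance

def _merge_close_points(
    points: np.ndarray,
    weights: np.ndarray | None,
    lo: np.ndarray,
    hi: np.ndarray,
    tol: float,
) -> tuple[np.ndarray, np.ndarray | None, np.ndarray]:
    """Merge points closer than ``tol`` in scaled coordinates, summing weights.

    Returns (points, weights, keep_index) where keep_index maps surviving
    rows back to rows of the input.
    """
    scaled = (points - lo) / (hi - lo)
    keys = np.round(scaled / tol).astype(np.int64)
    seen: dict[tuple, int] = {}
    keep, accum = [], []
    for i, key in enumerate(map(tuple, keys)):
        if key in seen:
            if weights is not None:
                accum[seen[key]] += weights[i]
        else:
            seen[key] = len(keep)
            keep.append(i)
            if weights is not None:
                accum.append(weights[i])
    keep_idx = np.array(keep, dtype=int)
    out_w = np.array(accum) if weights is not None else None
    return points[keep_idx], out_w, keep_idx


def _condense_arrays(
    points: np.ndarray,
    weights: np.ndarray,
    log_l: np.ndarray,
    eps: float,
    em_tol: float,
    em_max_iter: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    keep = weights >= eps
    if not np.any(keep):
        raise ValueError("condensation removed every support point")
    points, log_l = points[keep], log_l[:, keep]
    w0 = weights[keep] / weights[keep].sum()
    w, obj = _em_weights(log_l, w0=w0, tol=em_tol, max_iter=em_max_iter)
    return points, w, log_l, obj


def _subject_ml_points(
    data: _StackedData,
    points: np.ndarray,
    log_l: np.ndarray,
    error: AssayErrorModel,
    structure: str,
    lo: np.ndarray,
    hi: np.ndarray,
) -> np.ndarray:
    """Per-subject local maximum-likelihood parameter vectors.

    The optimal support of the nonparametric MLE lies where individual
    likelihoods peak, so each subject's best grid point is polished by a
    bounded local search and offered as a candidate support point.
    """
    from scipy.optimize import minimize

    span = hi - lo
    n_starts = 3
    out = []
    for i in range(data.n_subjects):
        starts = points[np.argsort(-log_l[i])[:n_starts]]

        def nll(x: np.ndarray, idx: int = i) -> float:
            p = lo + np.clip(x, 0.0, 1.0) * span
            col = _loglik_matrix(data, p[None, :], error, structure)[:, 0]
            return -float(col[idx])

        best_x, best_f = None, np.inf
        for start in starts:
            res = minimize(
                nll, (start - lo) / span, method="Nelder-Mead",
                options={"maxiter": 400, "xatol": 1e-4, "fatol": 1e-6},
            )
            if res.fun < best_f:
                best_x, best_f = res.x, res.fun
        out.append(lo + np.clip(best_x, 0.0, 1.0) * span)
    return np.array(out)


def _expansion_candidates(
    points: np.ndarray,
    delta: float,
    lo: np.ndarray,
    hi: np.ndarray,
    merge_tol: float,
) -> np.ndarray:
    """Candidate points at +/- delta*(hi-lo) per dimension, clipped to bounds
    and deduplicated against the current support."""
    span = hi - lo
    cands = []
    for row in points:
        for dim in range(points.shape[1]):
            for sign in (-1.0, 1.0):
                cand = row.copy()
                cand[dim] = np.clip(
                    cand[dim] + sign * delta * span[dim], lo[dim], hi[dim]
                )
                cands.append(cand)
    if not cands:
        return np.zeros((0, points.shape[1]))
    cand_arr = np.array(cands)
    merged = np.vstack([points, cand_arr])
    _, _, keep_idx = _merge_close_points(merged, None, lo, hi, merge_tol)
    new_idx = keep_idx[keep_idx >= len(points)]
    return merged[new_idx]


# ---------------------------------------------------------------------------
# public condense / expand on fitted models

def _model_from_arrays(
    points: np.ndarray,
    weights: np.ndarray,
    obj: float,
    template: PopulationModel,
    n_cycles: int | None = None,
) -> PopulationModel:
    weights = weights / weights.sum()
    support = tuple(
        SupportPoint(PKParameters.from_array(row, template.structure), float(w))
        for row, w in zip(points, weights)
    )
    return replace(
        template,
        support=support,
        loglik=float(obj),
        n_cycles=template.n_cycles if n_cycles is None else n_cycles,
    )


def condense(
    model: PopulationModel,
    eps: float,
    subjects: Sequence[SubjectRecord],
    error: AssayErrorModel,
) -> PopulationModel:
    """Drop support points with weight < eps, renormalize and re-optimize."""
    data = _StackedData(subjects)
    points = model.points_array()
    log_l = _loglik_matrix(data, points, error, model.structure)
    pts, w, _, obj = _condense_arrays(points, model.weights, log_l, eps, 1e-10, 2000)
    return _model_from_arrays(pts, w, obj, model)


def expand(
    model: PopulationModel,
    delta: float,
    subjects: Sequence[SubjectRecord],
    error: AssayErrorModel,
    bounds: dict[str, tuple[float, float]] | None = None,
) -> PopulationModel:
    """Spawn +/- delta candidates around each support point and re-optimize.

    The refit never returns a worse model: if the enlarged support does not
    improve the objective the input model is returned unchanged.
    """
    names = STRUCTURE_PARAMS[model.structure]
    resolved = bounds or model.bounds or DEFAULT_BOUNDS
    lo = np.array([resolved[n][0] for n in names])
    hi = np.array([resolved[n][1] for n in names])
    data = _StackedData(subjects)
    points = model.points_array()
    log_l = _loglik_matrix(data, points, error, model.structure)
    cand = _expansion_candidates(points, delta, lo, hi, 1e-8)
    if cand.size:
        log_l = np.hstack([log_l, _loglik_matrix(data, cand, error, model.structure)])
        points = np.vstack([points, cand])
        w0 = np.concatenate([model.weights * 0.5, np.full(len(cand), 0.5 / len(cand))])
    else:
        w0 = model.weights
    w, obj = _em_weights(log_l, w0=w0)
    if obj < model.loglik:  # keep the better of the two optima
        return model
    return _model_from_arrays(points, w, obj, model)


# ---------------------------------------------------------------------------
# the adaptive-grid fit

def fit(
    subjects: Sequence[SubjectRecord],
    error_model: AssayErrorModel,
    config: FitConfig,
) -> PopulationModel:
    """Nonparametric adaptive-grid population fit.

    Cycles of weight optimization -> condensation -> local expansion, with
    the expansion step delta halved whenever a cycle improves the
    log-likelihood by less than ``config.tol``; terminates when delta has
    shrunk below ``delta_min`` with no further improvement. The recorded
    log-likelihood trace is non-decreasing by construction (a cycle that
    fails to improve keeps the previous state).
    """
    if len(subjects) == 0:
        raise ValueError("at least one subject is required")
    # canonical order makes the fit exactly invariant to input permutation
    subjects = sorted(subjects, key=lambda s: s.id)
    structure = config.structure
    names = STRUCTURE_PARAMS[structure]
    bounds = config.resolved_bounds()
    lo = np.array([bounds[n][0] for n in names])
    hi = np.array([bounds[n][1] for n in names])
    eps = config.weight_floor
    if eps is None:
        eps = 1e-8 * len(subjects)

    data = _StackedData(subjects)
    grid = init_grid(bounds, config.resolved_n_initial(), config.seed, structure)
    points = np.array([p.as_array(structure) for p in grid])
    log_l = _loglik_matrix(data, points, error_model, structure)
    w, _ = _em_weights(log_l, tol=config.em_tol, max_iter=config.em_max_iter)
    if config.subject_seeding:
        # candidate support at each subject's own likelihood peak: the
        # optimal nonparametric support lives where subject likelihoods are
        # large, which a global quasi-random grid easily misses in 4-6 dims
        ml_pts = _subject_ml_points(data, points, log_l, error_model, structure, lo, hi)
        merged = np.vstack([points, ml_pts])
        _, _, keep_idx = _merge_close_points(merged, None, lo, hi, config.merge_tol)
        new_idx = keep_idx[keep_idx >= len(points)]
        if new_idx.size:
            cand = merged[new_idx]
            log_l = np.hstack([log_l, _loglik_matrix(data, cand, error_model, structure)])
            points = np.vstack([points, cand])
            w0 = np.concatenate([w * 0.5, np.full(len(cand), 0.5 / len(cand))])
            w, _ = _em_weights(log_l, w0=w0, tol=config.em_tol, max_iter=config.em_max_iter)
    points, w, log_l, obj = _condense_arrays(
        points, w, log_l, eps, config.em_tol, config.em_max_iter
    )
    trace = [obj]

    max_support = config.max_support
    if max_support is None:
        max_support = max(20 * len(subjects), 200)

    delta = config.delta0
    converged = False
    cycle = 0
    while cycle < config.max_cycles:
        cycle += 1
        cand = _expansion_candidates(points, delta, lo, hi, config.merge_tol)
        improved = 0.0
        if cand.size:
            log_l_new = _loglik_matrix(data, cand, error_model, structure)
            all_points = np.vstack([points, cand])
            all_log_l = np.hstack([log_l, log_l_new])
            w0 = np.concatenate([w * 0.5, np.full(len(cand), 0.5 / len(cand))])
            w2, _ = _em_weights(
                all_log_l, w0=w0, tol=config.em_tol, max_iter=config.em_max_iter
            )
            pts2, w2, log_l2, obj2 = _condense_arrays(
                all_points, w2, all_log_l, eps, config.em_tol, config.em_max_iter
            )
            if len(pts2) > max_support:
                # EM keeps near-duplicate ridge points above the weight
                # floor; bound the support by retaining the heaviest points
                # (the cycle-level accept test below preserves monotonicity)
                top = np.argsort(-w2)[:max_support]
                pts2, log_l2 = pts2[top], log_l2[:, top]
                w2, obj2 = _em_weights(
                    log_l2, w0=w2[top] / w2[top].sum(),
                    tol=config.em_tol, max_iter=config.em_max_iter,
                )
            if obj2 > obj:
                improved = obj2 - obj
                points, w, log_l, obj = pts2, w2, log_l2, obj2
        trace.append(obj)
        if improved < config.tol:
            delta *= 0.5
            if delta < config.delta_min:
                converged = True
                break

    support = tuple(
        SupportPoint(PKParameters.from_array(row, structure), float(wi))
        for row, wi in zip(points, w / w.sum())
    )
    return PopulationModel(
        support=support,
        loglik=float(obj),
        n_cycles=cycle,
        n_subjects=len(subjects),
        structure=structure,
        bounds=bounds,
        seed=config.seed,
        loglik_trace=tuple(trace),
        converged=converged,
    )


# ---------------------------------------------------------------------------
# posterior individual estimation and information criteria

def posterior_individual(
    subject: SubjectRecord,
    model: PopulationModel,
    error: AssayErrorModel,
) -> PosteriorEstimate:
    """Bayesian update of the population support for one subject.

    Posterior weight of point j is proportional to the prior weight times the
    subject's likelihood at that point (computed in the log domain).
    """
    data = _StackedData([subject])
    points = model.points_array()
    log_l = _loglik_matrix(data, points, error, model.structure)[0]
    with np.errstate(divide="ignore"):
        log_post = np.log(model.weights) + log_l
    shift = np.max(log_post)
    if not np.isfinite(shift):
        raise ValueError(f"subject {subject.id} has zero posterior mass")
    post = np.exp(log_post - shift)
    total = post.sum()
    if total <= 0 or not np.isfinite(total):
        raise ValueError(f"subject {subject.id} has zero posterior mass")
    post /= total
    mean = PKParameters.from_array(post @ points, model.structure)
    return PosteriorEstimate(
        subject_id=subject.id,
        posterior_weights=post,
        posterior_mean=mean,
        support=model.support,
        structure=model.structure,
    )


def information_criteria(
    model: PopulationModel, subjects: Sequence[SubjectRecord]
) -> dict[str, float]:
    """AIC/BIC with p = n_support * (d + 1) - 1 effective parameters.

    Each support point contributes d coordinates plus a weight, minus one for
    the simplex constraint. Only relative comparisons between candidate
    structures are meaningful.
    """
    d = len(STRUCTURE_PARAMS[model.structure])
    p = len(model.support) * (d + 1) - 1
    n_obs = sum(len(s.usable_observations()) for s in subjects)
    aic = -2.0 * model.loglik + 2.0 * p
    bic = -2.0 * model.loglik + p * math.log(n_obs)
    return {"AIC": aic, "BIC": bic}


# ---------------------------------------------------------------------------
# serialization (bit-exact round trip via repr-precision JSON floats)

def model_to_json(model: PopulationModel) -> str:
    names = STRUCTURE_PARAMS[model.structure]
    payload = {
        "structure": model.structure,
        "bounds": {k: list(v) for k, v in model.bounds.items()},
        "support": [
            {**{n: getattr(p.params, n) for n in names}, "weight": p.weight}
            for p in model.support
        ],
        "loglik": model.loglik,
        "n_cycles": model.n_cycles,
        "n_subjects": model.n_subjects,
        "seed": model.seed,
        "loglik_trace": list(model.loglik_trace),
        "converged": model.converged,
    }
    return json.dumps(payload, indent=1)


def model_from_json(text: str) -> PopulationModel:
    payload = json.loads(text)
    structure = payload["structure"]
    names = STRUCTURE_PARAMS[structure]
    support = tuple(
        SupportPoint(PKParameters(**{n: entry[n] for n in names}), entry["weight"])
        for entry in payload["support"]
    )
    return PopulationModel(
        support=support,
        loglik=payload["loglik"],
        n_cycles=payload["n_cycles"],
        n_subjects=payload["n_subjects"],
        structure=structure,
        bounds={k: tuple(v) for k, v in payload["bounds"].items()},
        seed=payload["seed"],
        loglik_trace=tuple(payload["loglik_trace"]),
        converged=payload["converged"],
    )
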