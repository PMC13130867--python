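"""Multiobjective Bayesian optimization with GP surrogates and EHVI.

One independent Gaussian-process surrogate (constant mean, isotropic RBF
kernel, hyperparameters by marginal likelihood) models each objective over
the unit-cube-normalized parameter space.  Candidates are drawn from a
scrambled Sobol pool and scored by Monte-Carlo expected hypervolume
improvement; an optional stability-ordering constraint biases acquisition
through the posterior probability that the polymorph lattice energies come
out in the right order.

Everything is seeded: rerunning with the same seed reproduces the exact
evaluation sequence.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import qmc

__all__ = [
    "GPModel",
    "OptState",
    "sobol_points",
    "gp_fit",
    "gp_predict",
    "pareto_front",
    "hypervolume",
    "hypervolume_improvement",
    "ehvi_select",
    "feasibility_weight",
    "optimize",
]

_JITTER = 1e-8


# ----------------------------------------------------------------- Sobol
def sobol_points(bounds: np.ndarray, n: int, seed: int = 0) -> np.ndarray:
    """n scrambled-Sobol points mapped into the (d, 2) bounds box."""
    bounds = np.asarray(bounds, dtype=float)
    if n < 1:
        raise ValueError("n must be >= 1")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # non-power-of-two draw is fine here
        sampler = qmc.Sobol(d=bounds.shape[0], scramble=True, seed=seed)
        u = sampler.random(n)
    return bounds[:, 0] + u * (bounds[:, 1] - bounds[:, 0])


# ------------------------------------------------------------------- GP
@dataclass
class GPModel:
    """Constant-mean isotropic-RBF GP posterior over the unit cube.

    Outputs are standardized internally; ``y_loc``/``y_scale`` map back to
    the original objective units.
    """

    train_x: np.ndarray
    length_scale: float
    signal_variance: float
    noise_variance: float
    mean_const: float
    y_loc: float
    y_scale: float
    _chol: np.ndarray = field(repr=False, default=None)
    _alpha: np.ndarray = field(repr=False, default=None)

    @property
    def degenerate(self) -> bool:
        return self.signal_variance == 0.0


def _corr(a: np.ndarray, b: np.ndarray, l: float) -> np.ndarray:
    return np.exp(-cdist(a, b, "sqeuclidean") / (2.0 * l * l))


def gp_fit(X: np.ndarray, y: np.ndarray) -> GPModel:
    """Fit μ, l and the variances by maximizing the log marginal likelihood.

    A multi-start grid over log-spaced length scales and noise ratios is
    scanned; μ and the signal variance have closed forms at fixed (l, η).
    An all-equal target degenerates gracefully to a constant (prior-like)
    model.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if n < 2:
        raise ValueError("need at least two observations")
    y_loc, y_scale = float(y.mean()), float(y.std())
    if y_scale < 1e-12:
        return GPModel(X, 1.0, 0.0, _JITTER, 0.0, y_loc, 1.0)
    ys = (y - y_loc) / y_scale
    best = None
    ones = np.ones(n)
    for l in np.geomspace(0.05, 3.0, 24):
        R0 = _corr(X, X, l)
        for eta in (1e-8, 1e-6, 1e-4, 1e-2):
            R = R0 + (eta + _JITTER) * np.eye(n)
            try:
                L = np.linalg.cholesky(R)
            except np.linalg.LinAlgError:
                continue
            rinv_y = np.linalg.solve(L.T, np.linalg.solve(L, ys))
            rinv_1 = np.linalg.solve(L.T, np.linalg.solve(L, ones))
            mu = float(ones @ rinv_y / (ones @ rinv_1))
            resid = ys - mu
            rinv_r = np.linalg.solve(L.T, np.linalg.solve(L, resid))
            sig2 = max(float(resid @ rinv_r) / n, 1e-12)
            logdet = 2.0 * np.log(np.diag(L)).sum()
            lml = -0.5 * (n * np.log(sig2) + logdet + n)
            if best is None or lml > best[0]:
                best = (lml, l, eta, mu, sig2, L, rinv_r)
    _, l, eta, mu, sig2, L, rinv_r = best
    model = GPModel(X, float(l), float(sig2), float(eta * sig2), mu, y_loc, y_scale)
    model._chol = L
    model._alpha = rinv_r  # R^{-1} (y_std - mu)
    return model


def gp_predict(model: GPModel, x: np.ndarray):
    """Posterior (mean, variance) in original objective units.

    Accepts a single point or an (m, d) array.  Far from all data the mean
    reverts to the constant prior mean and the variance to the signal
    variance.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if model.degenerate:
        m = np.full(len(x), model.y_loc)
        v = np.zeros(len(x))
        return (m[0], v[0]) if len(x) == 1 else (m, v)
    r = _corr(x, model.train_x, model.length_scale)
    mean_std = model.mean_const + r @ model._alpha
    v = np.linalg.solve(model._chol, r.T)
    var_std = model.signal_variance * np.maximum(1.0 - (v**2).sum(axis=0), 0.0)
    mean = model.y_loc + model.y_scale * mean_std
    var = (model.y_scale**2) * var_std
    return (float(mean[0]), float(var[0])) if len(x) == 1 else (mean, var)


# ------------------------------------------------------ Pareto/hypervolume
def pareto_front(points: np.ndarray, feasibility=None) -> np.ndarray:
    """Indices of feasible, mutually nondominated points (minimization).

    Infeasible points never enter the front while any feasible point
    exists; with no feasible point at all the front is computed over the
    full set.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if n == 0:
        return np.array([], dtype=int)
    feas = np.ones(n, dtype=bool) if feasibility is None else np.asarray(feasibility, dtype=bool)
    pool = np.where(feas)[0] if feas.any() else np.arange(n)
    sub = pts[pool]
    le = (sub[:, None, :] <= sub[None, :, :]).all(axis=2)
    lt = (sub[:, None, :] < sub[None, :, :]).any(axis=2)
    dominates = le & lt  # [i, j]: i dominates j
    return pool[~dominates.any(axis=0)]


def _hv_exact(pts: np.ndarray, ref: np.ndarray) -> float:
    """Exact dominated hypervolume by recursive slicing (any d, small fronts)."""
    if len(pts) == 0:
        return 0.0
    d = pts.shape[1]
    if d == 1:
        return float(ref[0] - pts[:, 0].min())
    order = np.argsort(pts[:, -1])
    pts = pts[order]
    zs = np.concatenate([pts[:, -1], [ref[-1]]])
    vol = 0.0
    for i in range(len(pts)):
        dz = zs[i + 1] - zs[i]
        if dz <= 0:
            continue
        slab = pts[: i + 1, :-1]
        keep = pareto_front(slab)
        vol += _hv_exact(slab[keep], ref[:-1]) * dz
    return vol


def hypervolume(front: np.ndarray, ref_point: np.ndarray,
                mc_samples: int = 100_000, seed: int = 0):
    """Lebesgue measure of the region dominated by the front up to ref_point.

    Exact (recursive sweep) for up to three objectives; seeded Monte Carlo
    above that, returning (volume, standard_error) instead of a float.
    """
    pts = np.atleast_2d(np.asarray(front, dtype=float))
    ref = np.asarray(ref_point, dtype=float)
    if len(pts) and np.any(pts >= ref):
        bad = np.where((pts >= ref).any(axis=1))[0]
        raise ValueError(f"front points {bad.tolist()} do not dominate the reference")
    if pts.shape[1] <= 3:
        return _hv_exact(pts, ref)
    lo = pts.min(axis=0)
    box = np.prod(ref - lo)
    rng = np.random.default_rng(seed)
    u = lo + rng.random((mc_samples, len(ref))) * (ref - lo)
    dom = np.zeros(mc_samples, dtype=bool)
    for p in pts:
        dom |= (u >= p).all(axis=1)
    frac = dom.mean()
    vol = box * frac
    stderr = box * np.sqrt(max(frac * (1 - frac), 0.0) / mc_samples)
    return vol, stderr


def hypervolume_improvement(point: np.ndarray, front: np.ndarray,
                            ref_point: np.ndarray) -> float:
    """Exact HVI of one candidate vector for up to three objectives."""
    point = np.asarray(point, dtype=float)
    front = np.atleast_2d(np.asarray(front, dtype=float)) if len(front) else np.zeros((0, len(point)))
    ref = np.asarray(ref_point, dtype=float)
    if np.any(point >= ref):
        return 0.0
    base = _hv_exact(front, ref) if len(front) else 0.0
    joint = np.vstack([front, point]) if len(front) else point[None, :]
    keep = pareto_front(joint)
    return _hv_exact(joint[keep], ref) - base


# ------------------------------------------------------------- acquisition
@dataclass
class OptState:
    """Evaluation history, surrogates and Pareto bookkeeping."""

    bounds: np.ndarray
    X: np.ndarray  # (n, d) raw parameter vectors
    F: np.ndarray  # (n, m) objective vectors
    feasible: np.ndarray  # (n,) bool
    energies: np.ndarray | None = None  # (n, 3) raw lattice energies, if any
    models: list = field(default_factory=list)
    energy_models: list = field(default_factory=list)
    ref_point: np.ndarray | None = None
    iteration: int = 0
    rng_seed: int = 0
    history: list = field(default_factory=list)

    @property
    def pareto(self) -> np.ndarray:
        return pareto_front(self.F, self.feasible)

    def front(self) -> np.ndarray:
        return self.F[self.pareto]

    def normalized_x(self) -> np.ndarray:
        lo, hi = self.bounds[:, 0], self.bounds[:, 1]
        width = np.where(hi > lo, hi - lo, 1.0)
        return (self.X - lo) / width

    def update_ref_point(self) -> np.ndarray:
        obs = self.F[self.feasible] if self.feasible.any() else self.F
        obs = obs[np.all(np.isfinite(obs), axis=1)]
        cand = np.maximum(obs.max(axis=0), 1e-9) * 1.1 if len(obs) else np.ones(self.F.shape[1])
        if self.ref_point is None:
            self.ref_point = cand
        else:
            self.ref_point = np.maximum(self.ref_point, cand)
        return self.ref_point

    def refit(self) -> None:
        Xn = self.normalized_x()
        self.models = [gp_fit(Xn, self.F[:, j]) for j in range(self.F.shape[1])]
        self.energy_models = []
        if self.energies is not None:
            ok = np.all(np.isfinite(self.energies), axis=1)
            if ok.sum() >= 2:
                self.energy_models = [
                    gp_fit(Xn[ok], self.energies[ok, j]) for j in range(3)
                ]

    # resumability: plain-text round trip of the sample set
    def to_json(self) -> str:
        return json.dumps({
            "bounds": self.bounds.tolist(),
            "X": self.X.tolist(),
            "F": self.F.tolist(),
            "feasible": self.feasible.tolist(),
            "energies": None if self.energies is None else self.energies.tolist(),
            "iteration": self.iteration,
            "rng_seed": self.rng_seed,
            "history": self.history,
        })

    @classmethod
    def from_json(cls, text: str) -> "OptState":
        d = json.loads(text)
        state = cls(
            bounds=np.array(d["bounds"]),
            X=np.array(d["X"]),
            F=np.array(d["F"]),
            feasible=np.array(d["feasible"], dtype=bool),
            energies=None if d["energies"] is None else np.array(d["energies"]),
            iteration=d["iteration"],
            rng_seed=d["rng_seed"],
            history=d["history"],
        )
        state.update_ref_point()
        state.refit()
        return state


def _order_probability(samples: np.ndarray) -> np.ndarray:
    """P(e_gamma <= e_alpha <= e_beta) per candidate from MC energy samples.

    ``samples``: (n_cand, n_mc, 3) with columns (alpha, beta, gamma).
    """
    ok = (samples[..., 2] <= samples[..., 0]) & (samples[..., 0] <= samples[..., 1])
    return ok.mean(axis=1)


def feasibility_weight(state: OptState, x: np.ndarray, mc_samples: int = 256,
                       seed: int = 0) -> float:
    """Posterior probability of the correct stability ordering at x."""
    if not state.energy_models:
        return 1.0
    lo, hi = state.bounds[:, 0], state.bounds[:, 1]
    xn = np.atleast_2d((np.asarray(x, dtype=float) - lo) / np.where(hi > lo, hi - lo, 1.0))
    rng = np.random.default_rng(seed)
    draws = np.empty((len(xn), mc_samples, 3))
    for j, model in enumerate(state.energy_models):
        m, v = gp_predict(model, xn)
        m, v = np.atleast_1d(m), np.atleast_1d(v)
        draws[:, :, j] = m[:, None] + np.sqrt(v)[:, None] * rng.standard_normal(
            (len(xn), mc_samples)
        )
    p = _order_probability(draws)
    return float(p[0]) if len(xn) == 1 else p


def ehvi_select(state: OptState, candidate_pool_size: int = 128,
                mc_samples: int = 16, seed: int = 0,
                volume_points: int = 2048, refine_top: int = 5) -> np.ndarray:
    """Next parameter vector by Monte-Carlo expected hypervolume improvement.

    A shared set of uniform volume points in [0, ref] turns hypervolume
    improvement into a dominated-point count, so thousands of posterior
    samples are scored with one boolean reduction.  The EHVI of each
    candidate is weighted by its stability-ordering probability; if every
    candidate scores zero the maximum-posterior-variance candidate is
    returned instead (exploration fallback).
    """
    rng = np.random.default_rng(seed)
    ref = state.update_ref_point()
    m_obj = state.F.shape[1]
    front = state.front()
    front = front[np.all(front < ref, axis=1)] if len(front) else front

    lo, hi = state.bounds[:, 0], state.bounds[:, 1]
    width = np.where(hi > lo, hi - lo, 1.0)
    pool = sobol_points(state.bounds, candidate_pool_size, seed=int(rng.integers(2**31)))
    # bias part of the pool toward the best evaluated points so the
    # acquisition can exploit once the surrogates localize the optimum
    good = np.where(state.feasible)[0]
    if len(good):
        best = good[np.argsort(state.F[good].max(axis=1))[:5]]
        anchors = np.repeat(state.X[best], 6, axis=0)
        jitter = rng.standard_normal(anchors.shape) * 0.05 * width
        pool = np.vstack([pool, np.clip(anchors + jitter, lo, hi)])

    # Shared volume points turn hypervolume improvement into a dominated-
    # point count.  The sampling box is localized around the incumbent
    # front (improvement far beyond its nadir is ignored for ranking), so
    # the Monte-Carlo resolution keeps pace as the front tightens.
    if len(front):
        ref_use = np.minimum(ref, 2.0 * front.max(axis=0) + 1e-12)
    else:
        ref_use = ref
    u = rng.random((volume_points, m_obj)) * ref_use
    if len(front):
        dom = np.zeros(len(u), dtype=bool)
        for p in front:
            dom |= (u >= p).all(axis=1)
        u = u[~dom]
    cell_vol = float(np.prod(ref_use)) / volume_points

    def score(cands: np.ndarray) -> np.ndarray:
        xn = (cands - lo) / width
        mean = np.empty((len(cands), m_obj))
        var = np.empty((len(cands), m_obj))
        for j, model in enumerate(state.models):
            mj, vj = gp_predict(model, xn)
            mean[:, j], var[:, j] = np.atleast_1d(mj), np.atleast_1d(vj)
        draws = mean[:, None, :] + np.sqrt(var)[:, None, :] * rng.standard_normal(
            (len(cands), mc_samples, m_obj)
        )
        if len(u):
            flat = draws.reshape(-1, m_obj)
            counts = np.zeros(len(flat))
            chunk = max(1, 2_000_000 // max(len(u), 1))
            for a in range(0, len(flat), chunk):
                blk = flat[a : a + chunk]
                counts[a : a + chunk] = (
                    (blk[:, None, :] <= u[None, :, :]).all(axis=2).sum(axis=1)
                )
            hvi = counts.reshape(len(cands), mc_samples) * cell_vol
        else:
            hvi = np.zeros((len(cands), mc_samples))
        ehvi = hvi.mean(axis=1)
        if state.energy_models:
            ehvi = ehvi * feasibility_weight(
                state, cands, mc_samples=256, seed=int(rng.integers(2**31))
            )
        return ehvi

    scores = score(pool)
    # local coordinate refinement of the most promising candidates
    if refine_top and scores.max() > 0:
        for jit in (0.04, 0.015):
            top = pool[np.argsort(scores)[-refine_top:]]
            jitter = rng.standard_normal((len(top) * 4, pool.shape[1])) * jit * width
            extra = np.clip(np.repeat(top, 4, axis=0) + jitter, lo, hi)
            extra_scores = score(extra)
            pool = np.vstack([pool, extra])
            scores = np.concatenate([scores, extra_scores])
    if scores.max() <= 0:
        # all-zero acquisition: fall back to maximum posterior variance
        xn = (pool - lo) / width
        total_var = np.zeros(len(pool))
        for model in state.models:
            _, vj = gp_predict(model, xn)
            total_var += np.atleast_1d(vj)
        return pool[int(np.argmax(total_var))]
    return pool[int(np.argmax(scores))]


# --------------------------------------------------------------- main loop
def optimize(eval_fn, bounds: np.ndarray, n_init: int = 15,
             max_iter: int = 100, seed: int = 0,
             candidate_pool_size: int = 128, mc_samples: int = 16,
             volume_points: int = 2048, callback=None) -> OptState:
    """Sobol initialization followed by the fit → acquire → evaluate loop.

    ``eval_fn`` maps a parameter vector to an object with ``values`` (the
    objective vector), ``feasible`` and optionally ``raw["energies"]``.
    The full audit trail (every x, f, feasibility, incumbent hypervolume)
    is retained in ``state.history``; the state is JSON-serializable and
    the loop can be resumed from it.
    """
    bounds = np.asarray(bounds, dtype=float)
    rng = np.random.default_rng(seed)
    X = sobol_points(bounds, n_init, seed=int(rng.integers(2**31)))
    evals = [eval_fn(x) for x in X]
    state = _state_from_evals(bounds, X, evals, seed)
    _log_iteration(state, rng)
    for it in range(max_iter):
        state.refit()
        x_next = ehvi_select(
            state,
            candidate_pool_size=candidate_pool_size,
            mc_samples=mc_samples,
            volume_points=volume_points,
            seed=int(rng.integers(2**31)),
        )
        result = eval_fn(x_next)
        _append_eval(state, x_next, result)
        state.iteration = it + 1
        _log_iteration(state, rng)
        if callback is not None:
            callback(state)
    if len(state.X) >= 2:
        state.refit()
    return state


def select_best(state: OptState) -> int:
    """Default report point: feasible minimizer of the worst-case objective."""
    feas = np.where(state.feasible)[0]
    pool = feas if len(feas) else np.arange(len(state.X))
    worst = state.F[pool].max(axis=1)
    return int(pool[np.argmin(worst)])


def _state_from_evals(bounds, X, evals, seed) -> OptState:
    F = np.array([np.asarray(e.values, dtype=float) for e in evals])
    feas = np.array([bool(e.feasible) for e in evals])
    energies = _energies_of(evals)
    state = OptState(
        bounds=bounds, X=np.asarray(X, dtype=float), F=F, feasible=feas,
        energies=energies, rng_seed=seed,
    )
    state.update_ref_point()
    return state


def _energies_of(evals):
    rows = []
    for e in evals:
        raw = getattr(e, "raw", None) or {}
        if "energies" not in raw:
            return None
        rows.append(raw["energies"])
    return np.array(rows, dtype=float)


def _append_eval(state: OptState, x, result) -> None:
    state.X = np.vstack([state.X, x])
    state.F = np.vstack([state.F, np.asarray(result.values, dtype=float)])
    state.feasible = np.append(state.feasible, bool(result.feasible))
    if state.energies is not None:
        raw = getattr(result, "raw", None) or {}
        row = raw.get("energies", [np.nan] * state.energies.shape[1])
        state.energies = np.vstack([state.energies, row])
    state.update_ref_point()


def _log_iteration(state: OptState, rng) -> None:
    front = state.front()
    ref = state.ref_point
    front = front[np.all(front < ref, axis=1)] if len(front) else front
    if len(front):
        hv = hypervolume(front, ref, mc_samples=20_000, seed=int(rng.integers(2**31)))
        hv_val = hv if np.isscalar(hv) else hv[0]
    else:
        hv_val = 0.0
    state.history.append({
        "iteration": state.iteration,
        "n_evals": len(state.X),
        "hypervolume": float(hv_val),
        "n_feasible": int(state.feasible.sum()),
        "best_worst_objective": float(
            state.F[state.feasible].max(axis=1).min()
        ) if state.feasible.any() else None,
    })
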