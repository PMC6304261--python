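"""Gradient-descent estimation of the eight model parameters.

Two estimation routes share one optimiser:

* the accelerometry route fits the model's upper-mass proper acceleration
  to a measured trunk-accelerometer stance segment (objective in g);
* the force route fits the model GRF to the measured, body-mass
  normalised GRF (objective in N/kg).

The optimiser is projected gradient descent in a dimensionless parameter
space (each parameter divided by a characteristic scale), with a
backtracking line search (halve the step until the objective decreases)
and a Barzilai-Borwein initial step.  Gradients are central finite
differences.  Multiple restarts are drawn uniformly inside the bounds
from a seed; the best endpoint wins and every endpoint is retained in the
result, because waveform fits of this model are known to admit multiple
near-equivalent parameter combinations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence, Tuple

import numpy as np

from . import _kernels
from .model import (
    PARAM_NAMES,
    ScaledParameters,
    SimulationConfig,
)
from .signals import TrialSeries, detect_stance, gravity_correct, normalise_bw

#: objective value standing in for a diverged simulation (per objective units)
DIVERGENCE_PENALTY = _kernels.PENALTY

#: parameter bounds spanning the physically plausible running regime
DEFAULT_BOUNDS: Mapping[str, Tuple[float, float]] = {
    "p1": (-0.10, 0.05),
    "p2": (-0.10, 0.05),
    "v1": (-4.0, 1.0),
    "v2": (-4.0, 1.0),
    "omega1_sq": (50.0, 2000.0),
    "omega2_sq": (500.0, 8000.0),
    "lam": (0.3, 10.0),
    "zeta": (0.0, 1.2),
}

#: characteristic magnitudes for dimensionless stepping
DEFAULT_SCALES: Mapping[str, float] = {
    "p1": 0.05,
    "p2": 0.05,
    "v1": 1.0,
    "v2": 1.0,
    "omega1_sq": 500.0,
    "omega2_sq": 2000.0,
    "lam": 1.0,
    "zeta": 0.3,
}


class FitFailedError(RuntimeError):
    """Every restart ended in a diverged or unevaluable objective."""

    def __init__(self, message: str, objectives: Sequence[float] = ()):
        super().__init__(message)
        self.objectives = list(objectives)


@dataclass(frozen=True)
class FitOptions:
    """Optimiser settings.

    ``fixed`` maps parameter names to values held constant during the
    fit (their gradient components are zero and every start uses the
    fixed value).  ``bounds`` and ``scales`` may override individual
    parameters; unspecified entries fall back to the defaults.
    """

    max_iters: int = 200
    tol: float = 1e-6
    n_restarts: int = 8
    seed: int = 0
    bounds: Mapping[str, Tuple[float, float]] = field(default_factory=dict)
    fixed: Mapping[str, float] = field(default_factory=dict)
    scales: Mapping[str, float] = field(default_factory=dict)
    grad_rel_step: float = 1e-5

    def __post_init__(self) -> None:
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        lo, hi = self.bounds_arrays()
        if np.any(lo >= hi):
            raise ValueError("each bound must satisfy low < high")
        for name, value in self.fixed.items():
            if name not in PARAM_NAMES:
                raise ValueError(f"unknown fixed parameter {name!r}")
            i = PARAM_NAMES.index(name)
            if not lo[i] <= value <= hi[i]:
                raise ValueError(f"fixed value {name}={value} outside bounds ({lo[i]}, {hi[i]})")

    def bounds_arrays(self) -> Tuple[np.ndarray, np.ndarray]:
        lo = np.array([dict(DEFAULT_BOUNDS, **self.bounds)[n][0] for n in PARAM_NAMES])
        hi = np.array([dict(DEFAULT_BOUNDS, **self.bounds)[n][1] for n in PARAM_NAMES])
        return lo, hi

    def scales_array(self) -> np.ndarray:
        merged = dict(DEFAULT_SCALES, **self.scales)
        return np.array([merged[n] for n in PARAM_NAMES], dtype=float)

    def fixed_arrays(self) -> Tuple[np.ndarray, np.ndarray]:
        mask = np.zeros(len(PARAM_NAMES), dtype=bool)
        values = np.zeros(len(PARAM_NAMES))
        for name, value in self.fixed.items():
            i = PARAM_NAMES.index(name)
            mask[i] = True
            values[i] = value
        return mask, values


@dataclass(frozen=True)
class FitResult:
    """Outcome of a multi-restart fit.

    ``restarts`` keeps every restart endpoint (parameters, objective) so
    that near-equivalent alternative solutions remain visible.
    """

    params: ScaledParameters
    objective: float
    n_iters: int
    converged: bool
    restart_index: int
    trace: np.ndarray
    restarts: Tuple[Tuple[ScaledParameters, float], ...]

    def to_dict(self) -> dict:
        return {
            "params": {n: getattr(self.params, n) for n in PARAM_NAMES},
            "mass_kg": self.params.M,
            "objective": self.objective,
            "n_iters": self.n_iters,
            "converged": self.converged,
            "restart_index": self.restart_index,
            "trace": [float(v) for v in self.trace],
            "restarts": [
                {"params": {n: getattr(p, n) for n in PARAM_NAMES}, "objective": o}
                for p, o in self.restarts
            ],
        }


# ---------------------------------------------------------------------------
# objectives


def objective_acc(sc: ScaledParameters, trunk_acc: TrialSeries, cfg: SimulationConfig) -> float:
    """RMSE (g) between the model upper-mass proper acceleration and a
    stance-windowed trunk-accelerometer series.

    The model is simulated over ``cfg`` and interpolated onto the
    accelerometer's own grid.  The target's ``t0`` is interpreted as time
    since touchdown (model time zero), which absorbs the sub-sample
    offset between the 100 Hz accelerometer grid and the platform-defined
    touchdown instant.  A diverged simulation yields the finite penalty
    :data:`DIVERGENCE_PENALTY` instead of raising, so line searches can
    back away from unphysical regions.
    """
    if trunk_acc.unit != "g":
        raise ValueError(f"accelerometer target must be in g, got {trunk_acc.unit!r}")
    t_target = trunk_acc.t0 + np.arange(trunk_acc.n) / trunk_acc.rate
    return float(
        _kernels.acc_objective(
            sc.to_array(), sc.M, cfg.g, cfg.dt, cfg.n_steps, t_target, trunk_acc.values
        )
    )


def objective_grf(sc: ScaledParameters, grf: TrialSeries, cfg: SimulationConfig) -> float:
    """RMSE (N/kg) between the model GRF and a stance-windowed, body-mass
    normalised GRF series, on the platform grid.  As for the
    accelerometer objective, ``t0`` is time since touchdown."""
    if grf.unit != "N/kg":
        raise ValueError(f"GRF target must be in N/kg, got {grf.unit!r}")
    t_target = grf.t0 + np.arange(grf.n) / grf.rate
    return float(
        _kernels.grf_objective(
            sc.to_array(), sc.M, cfg.g, cfg.dt, cfg.n_steps, t_target, grf.values
        )
    )


def _bind(f: Callable, target: TrialSeries, cfg: SimulationConfig, mass: float):
    """Return ``(obj, obj_batch)``: a fast array objective x8 -> float
    equivalent to ``f(ScaledParameters.from_array(x, mass), target, cfg)``
    and, for the built-in objectives, a row-wise batch version (used for
    finite-difference probes); ``obj_batch`` is ``None`` otherwise."""
    t_target = target.t0 + np.arange(target.n) / target.rate
    values = target.values
    if f is objective_acc:
        def obj(x: np.ndarray) -> float:
            return float(
                _kernels.acc_objective(x, mass, cfg.g, cfg.dt, cfg.n_steps, t_target, values)
            )

        def obj_batch(X: np.ndarray) -> np.ndarray:
            return _kernels.acc_objective_batch(
                X, mass, cfg.g, cfg.dt, cfg.n_steps, t_target, values
            )

        return obj, obj_batch
    if f is objective_grf:
        def obj(x: np.ndarray) -> float:
            return float(
                _kernels.grf_objective(x, mass, cfg.g, cfg.dt, cfg.n_steps, t_target, values)
            )

        def obj_batch(X: np.ndarray) -> np.ndarray:
            return _kernels.grf_objective_batch(
                X, mass, cfg.g, cfg.dt, cfg.n_steps, t_target, values
            )

        return obj, obj_batch

    def obj(x: np.ndarray) -> float:
        try:
            sc = ScaledParameters.from_array(x, mass)
        except ValueError:
            return DIVERGENCE_PENALTY
        return float(f(sc, target, cfg))

    return obj, None


# ---------------------------------------------------------------------------
# gradients


def numeric_gradient(
    f: Callable[[ScaledParameters], float],
    sc: ScaledParameters,
    rel_step: float = 1e-5,
    scales: Optional[Mapping[str, float]] = None,
    fixed: Sequence[str] = (),
) -> np.ndarray:
    """Central-difference gradient in the dimensionless parameter space.

    Each coordinate is probed with a physical step ``rel_step * scale``;
    the returned component is the derivative with respect to the
    dimensionless coordinate ``x / scale``.  ``scales`` defaults to 1 for
    every parameter.  Coordinates named in ``fixed`` get gradient 0.  A
    non-finite (or penalty) probe value falls back to a one-sided
    difference on the valid side.
    """
    if scales is None:
        s = np.ones(len(PARAM_NAMES))
    else:
        s = np.array([scales.get(n, 1.0) for n in PARAM_NAMES], dtype=float)
    x0 = sc.to_array()

    def eval_at(x: np.ndarray) -> float:
        try:
            return float(f(ScaledParameters.from_array(x, sc.M)))
        except ValueError:
            return np.nan

    return _gradient_arrays(
        lambda x: eval_at(x), x0, s, rel_step,
        np.array([n in fixed for n in PARAM_NAMES]),
    )


def _gradient_arrays(
    obj: Callable[[np.ndarray], float],
    x0: np.ndarray,
    scales: np.ndarray,
    rel_step: float,
    fixed_mask: np.ndarray,
    f0: Optional[float] = None,
) -> np.ndarray:
    g = np.zeros_like(x0)
    for i in range(x0.size):
        if fixed_mask[i]:
            continue
        h = rel_step * scales[i]
        xp = x0.copy()
        xp[i] += h
        xm = x0.copy()
        xm[i] -= h
        fp = obj(xp)
        fm = obj(xm)
        ok_p = np.isfinite(fp) and fp < DIVERGENCE_PENALTY
        ok_m = np.isfinite(fm) and fm < DIVERGENCE_PENALTY
        if ok_p and ok_m:
            g[i] = (fp - fm) / (2.0 * rel_step)
        else:
            if f0 is None:
                f0 = obj(x0)
            if ok_p:
                g[i] = (fp - f0) / rel_step
            elif ok_m:
                g[i] = (f0 - fm) / rel_step
            else:
                g[i] = 0.0
    return g


def _descent_gradient(
    obj: Callable,
    obj_batch: Optional[Callable],
    z: np.ndarray,
    scales: np.ndarray,
    rel_step: float,
    fixed_mask: np.ndarray,
    f0: float,
) -> np.ndarray:
    """Central-difference gradient and diagonal curvature with respect to
    the dimensionless coordinates ``z`` (physical parameters are
    ``z * scales``).  All probes go through one batched kernel call when
    available.  A penalty probe falls back to a one-sided difference (with
    undefined curvature, returned as NaN)."""
    free = np.nonzero(~fixed_mask)[0]
    g = np.zeros_like(z)
    h = np.full_like(z, np.nan)
    if free.size == 0:
        return g, h
    if obj_batch is not None:
        Z = np.repeat(z[None, :], 2 * free.size, axis=0)
        for j, i in enumerate(free):
            Z[2 * j, i] += rel_step
            Z[2 * j + 1, i] -= rel_step
        vals = obj_batch(Z * scales[None, :])
    else:
        vals = np.empty(2 * free.size)
        for j, i in enumerate(free):
            zp = z.copy()
            zp[i] += rel_step
            zm = z.copy()
            zm[i] -= rel_step
            vals[2 * j] = obj(zp * scales)
            vals[2 * j + 1] = obj(zm * scales)
    for j, i in enumerate(free):
        fp, fm = vals[2 * j], vals[2 * j + 1]
        ok_p = np.isfinite(fp) and fp < DIVERGENCE_PENALTY
        ok_m = np.isfinite(fm) and fm < DIVERGENCE_PENALTY
        if ok_p and ok_m:
            g[i] = (fp - fm) / (2.0 * rel_step)
            h[i] = (fp + fm - 2.0 * f0) / (rel_step * rel_step)
        elif ok_p:
            g[i] = (fp - f0) / rel_step
        elif ok_m:
            g[i] = (f0 - fm) / rel_step
    return g, h


# ---------------------------------------------------------------------------
# the optimiser


def fit(
    f: Callable,
    target: TrialSeries,
    opts: FitOptions,
    cfg: SimulationConfig,
    mass: float,
) -> FitResult:
    """Multi-restart projected gradient descent on an objective.

    ``f`` is one of :func:`objective_acc` / :func:`objective_grf` (or any
    callable with the same signature).  Starts are drawn uniformly inside
    the bounds from ``opts.seed``; each descent halves its step until the
    objective decreases and stops after 5 successive accepted steps whose
    relative decrease is below ``opts.tol``, or at ``opts.max_iters``.
    The best restart wins; ties go to the lowest restart index.
    """
    obj, obj_batch = _bind(f, target, cfg, mass)
    lo, hi = opts.bounds_arrays()
    scales = opts.scales_array()
    fixed_mask, fixed_values = opts.fixed_arrays()

    rng = np.random.default_rng(opts.seed)
    starts = rng.uniform(lo, hi, size=(opts.n_restarts, len(PARAM_NAMES)))
    starts[:, fixed_mask] = fixed_values[fixed_mask]

    zlo = lo / scales
    zhi = hi / scales
    endpoints = []
    for r in range(opts.n_restarts):
        z = starts[r] / scales
        f_cur = obj(z * scales)
        trace = [f_cur]
        z_prev = None
        g_prev = None
        t_last = 1.0
        small_count = 0
        converged = False
        n_iters = 0
        for it in range(opts.max_iters):
            g, _h = _descent_gradient(
                obj, obj_batch, z, scales, opts.grad_rel_step, fixed_mask, f_cur
            )
            gnorm = float(np.max(np.abs(g)))
            if gnorm == 0.0 or not np.isfinite(gnorm):
                converged = True
                break
            # Barzilai-Borwein initial step, else grow the last accepted one
            d = g
            t0 = None
            if z_prev is not None:
                sdiff = z - z_prev
                ydiff = g - g_prev
                sy = float(sdiff @ ydiff)
                if sy > 0:
                    t0 = float(sdiff @ sdiff) / sy
            if t0 is None or not np.isfinite(t0):
                t0 = min(2.0 * t_last, 1.0 / gnorm)
            t = float(np.clip(t0, 1e-10, 1e3))
            accepted = False

            def _probe(step):
                z_try = np.clip(z - step * d, zlo, zhi)
                z_try[fixed_mask] = fixed_values[fixed_mask] / scales[fixed_mask]
                return z_try, obj(z_try * scales)

            for _ in range(40):
                z_new, f_new = _probe(t)
                if f_new < f_cur:
                    accepted = True
                    break
                t *= 0.5
            if not accepted:
                converged = True
                break
            # expand: keep doubling while the objective keeps dropping
            for _ in range(8):
                z_big, f_big = _probe(2.0 * t)
                if f_big < f_new:
                    t *= 2.0
                    z_new, f_new = z_big, f_big
                else:
                    break
            rel_dec = (f_cur - f_new) / max(f_cur, 1e-30)
            z_prev, g_prev = z, g
            z, f_cur = z_new, f_new
            t_last = t
            trace.append(f_cur)
            n_iters = it + 1
            small_count = small_count + 1 if rel_dec < opts.tol else 0
            if small_count >= 5:
                converged = True
                break
        endpoints.append(
            {
                "x": z * scales,
                "objective": f_cur,
                "trace": np.array(trace),
                "converged": converged,
                "n_iters": n_iters,
            }
        )

    objectives = [e["objective"] for e in endpoints]
    best = int(np.argmin(objectives))
    if not np.isfinite(objectives[best]) or objectives[best] >= DIVERGENCE_PENALTY:
        raise FitFailedError(
            f"all {opts.n_restarts} restarts diverged or failed to evaluate",
            objectives=objectives,
        )
    restarts = tuple(
        (ScaledParameters.from_array(e["x"], mass), float(e["objective"]))
        for e in endpoints
        if np.isfinite(e["objective"]) and e["objective"] < DIVERGENCE_PENALTY
    )
    e = endpoints[best]
    return FitResult(
        params=ScaledParameters.from_array(e["x"], mass),
        objective=float(e["objective"]),
        n_iters=int(e["n_iters"]),
        converged=bool(e["converged"]),
        restart_index=best,
        trace=e["trace"],
        restarts=restarts,
    )


# ---------------------------------------------------------------------------
# orchestration


def _default_cfg(target: TrialSeries, cfg: Optional[SimulationConfig]) -> SimulationConfig:
    if cfg is not None:
        return cfg
    return SimulationConfig(duration=max(target.t0 + target.duration, 2.0 / 3000.0))


def fit_acc_param(
    trunk_acc: TrialSeries,
    mass: float,
    opts: Optional[FitOptions] = None,
    cfg: Optional[SimulationConfig] = None,
) -> FitResult:
    """Estimate the eight parameters from a stance-windowed trunk
    accelerometer series (the accelerometry route)."""
    if mass <= 0:
        raise ValueError(f"mass must be positive, got {mass}")
    opts = opts or FitOptions()
    target = gravity_correct(trunk_acc)
    cfg = _default_cfg(target, cfg)
    return fit(objective_acc, target, opts, cfg, mass)


def fit_grf_param(
    grf: TrialSeries,
    mass: float,
    opts: Optional[FitOptions] = None,
    cfg: Optional[SimulationConfig] = None,
) -> FitResult:
    """Estimate the eight parameters from measured GRF (the force route).

    A series in newtons is stance-windowed (20 N threshold) and body-mass
    normalised first; a series already in N/kg is taken as windowed.
    """
    if mass <= 0:
        raise ValueError(f"mass must be positive, got {mass}")
    opts = opts or FitOptions()
    if grf.unit == "N":
        from dataclasses import replace as _replace

        w = detect_stance(grf)
        grf = normalise_bw(grf.crop(w.i_touchdown, w.i_takeoff), mass)
        grf = _replace(grf, t0=0.0)  # model time zero is touchdown
    cfg = _default_cfg(grf, cfg)
    return fit(objective_grf, grf, opts, cfg, mass)
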