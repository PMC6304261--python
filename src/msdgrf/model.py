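"""Two-mass spring-damper model of the running stance phase.

The body is reduced to two point masses on a single vertical axis: a lower
mass ``m2`` (the support leg) resting on a linear spring ``k2`` in parallel
with a damper ``c`` against the ground, and an upper mass ``m1`` (the rest
of the body) connected to the lower mass through a second linear spring
``k1``.  The axis is up-positive, positions are displacements from the
unloaded spring lengths, and gravity ``g = -9.81 m s^-2`` acts on both
masses.

The physical parameters are used in a scaled form that removes the mass
unit:

    lam        = m1 / m2             (mass ratio)
    omega1_sq  = k1 / m1             (upper natural frequency squared, s^-2)
    omega2_sq  = k2 / m2             (lower natural frequency squared, s^-2)
    zeta       = c / (2 sqrt(k2 m2)) (damping ratio of the lower element)

together with the touchdown state (p1, p2, v1, v2).  The equations of
motion are

    a1 = -omega1_sq (p1 - p2) + g
    a2 = -omega2_sq p2 + omega1_sq lam (p1 - p2) - 2 zeta omega2 v2 + g

and the ground reaction force on the model is the force in the lower
spring-damper,

    GRF(t) = -(k2 p2 + c v2)
           = -(M omega2 / (1 + lam)) (omega2 p2 + 2 zeta v2),

positive upward: compression (p2 < 0) and downward lower-mass velocity
(v2 < 0) load the ground.  With this sign the Newton identity
``GRF = m1 (a1 - g) + m2 (a2 - g)`` holds exactly.  Note the damping
acceleration uses the first power of omega2 (2 zeta omega2 v2); this is
the only dimensionally consistent form and the one that makes the GRF
expression equal k2 p2 + c v2.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from ._kernels import rk4_path
from .signals import TrialSeries

#: gravitational acceleration on the up-positive axis, m s^-2
G_DEFAULT = -9.81

#: magnitude of 1 g used for unit conversion, m s^-2
G_PER_MS2 = 9.81

#: canonical ordering of the eight fitted parameters
PARAM_NAMES = ("p1", "p2", "v1", "v2", "omega1_sq", "omega2_sq", "lam", "zeta")


class SimulationDivergedError(RuntimeError):
    """Integration produced a non-finite or unbounded state.

    Attributes
    ----------
    t_last : float
        Last time at which the state was still valid.
    """

    def __init__(self, t_last: float):
        super().__init__(f"simulation diverged; last valid state at t = {t_last:.6f} s")
        self.t_last = t_last


@dataclass(frozen=True)
class NaturalParameters:
    """Physical masses, stiffnesses and damping.

    ``M`` must equal ``m1 + m2``; use :meth:`from_masses` to have it
    filled in.
    """

    m1: float  # upper mass, kg
    m2: float  # lower mass, kg
    k1: float  # upper spring constant, N/m
    k2: float  # lower spring constant, N/m
    c: float   # damping coefficient, N s/m
    M: float   # total mass, kg

    def __post_init__(self) -> None:
        if self.m1 <= 0 or self.m2 <= 0:
            raise ValueError(f"masses must be positive (m1={self.m1}, m2={self.m2})")
        if self.k1 < 0 or self.k2 <= 0:
            raise ValueError(f"stiffnesses must be k1 >= 0, k2 > 0 (k1={self.k1}, k2={self.k2})")
        if self.c < 0:
            raise ValueError(f"damping must be non-negative, got {self.c}")
        if abs(self.M - (self.m1 + self.m2)) > 1e-9 * max(self.M, 1.0):
            raise ValueError(f"M={self.M} does not equal m1+m2={self.m1 + self.m2}")

    @classmethod
    def from_masses(cls, m1: float, m2: float, k1: float, k2: float, c: float) -> "NaturalParameters":
        return cls(m1=m1, m2=m2, k1=k1, k2=k2, c=c, M=m1 + m2)


@dataclass(frozen=True)
class ScaledParameters:
    """The eight fitted quantities plus total mass.

    ``omega1_sq = 0`` is admitted (absent upper spring, upper mass in free
    fall), which is the standard decoupling limit used to validate the
    integrator.
    """

    p1: float          # initial upper-mass position, m
    p2: float          # initial lower-mass position, m
    v1: float          # initial upper-mass velocity, m/s
    v2: float          # initial lower-mass velocity, m/s
    omega1_sq: float   # k1/m1, s^-2
    omega2_sq: float   # k2/m2, s^-2
    lam: float         # m1/m2
    zeta: float        # c / (2 sqrt(k2 m2))
    M: float           # total mass, kg

    def __post_init__(self) -> None:
        if self.omega1_sq < 0 or self.omega2_sq <= 0:
            raise ValueError(
                f"natural frequencies must be omega1_sq >= 0, omega2_sq > 0 "
                f"(got {self.omega1_sq}, {self.omega2_sq})"
            )
        if self.lam <= 0:
            raise ValueError(f"mass ratio must be positive, got {self.lam}")
        if self.zeta < 0:
            raise ValueError(f"damping ratio must be non-negative, got {self.zeta}")
        if self.M <= 0:
            raise ValueError(f"total mass must be positive, got {self.M}")
        for name in ("p1", "p2", "v1", "v2"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"initial condition {name} must be finite")

    def to_array(self) -> np.ndarray:
        """The eight parameters in :data:`PARAM_NAMES` order."""
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, x: np.ndarray, M: float) -> "ScaledParameters":
        return cls(**dict(zip(PARAM_NAMES, (float(v) for v in x))), M=M)

    def replace(self, **kw) -> "ScaledParameters":
        return replace(self, **kw)


@dataclass(frozen=True)
class ModelState:
    """Instantaneous state of the two masses."""

    t: float
    p1: float
    p2: float
    v1: float
    v2: float

    def __post_init__(self) -> None:
        for name in ("t", "p1", "p2", "v1", "v2"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"state field {name} must be finite")


@dataclass(frozen=True)
class SimulationConfig:
    """Fixed-step integration settings.

    ``dt`` defaults to the force-platform sampling interval (1/3000 s) so
    the model grid and the measured GRF grid coincide.  ``g`` defaults to
    -9.81 m s^-2 on the up-positive axis; g = 0 is admitted for
    conservation checks.
    """

    dt: float = 1.0 / 3000.0
    duration: float = 0.3
    g: float = G_DEFAULT

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.duration < self.dt:
            raise ValueError(f"duration {self.duration} shorter than one step {self.dt}")
        if not np.isfinite(self.g) or self.g > 0:
            raise ValueError(f"g must be finite and non-positive, got {self.g}")

    @property
    def n_steps(self) -> int:
        return int(np.floor(self.duration / self.dt + 1e-12))


@dataclass(frozen=True)
class Trajectory:
    """Simulated states on the uniform grid ``t = 0, dt, ..., n_steps*dt``."""

    t: np.ndarray
    p1: np.ndarray
    p2: np.ndarray
    v1: np.ndarray
    v2: np.ndarray
    params: ScaledParameters
    config: SimulationConfig

    @property
    def n(self) -> int:
        return int(self.t.size)

    def state(self, i: int) -> ModelState:
        return ModelState(
            t=float(self.t[i]), p1=float(self.p1[i]), p2=float(self.p2[i]),
            v1=float(self.v1[i]), v2=float(self.v2[i]),
        )


def to_scaled(
    nat: NaturalParameters,
    p1: float = 0.0,
    p2: float = 0.0,
    v1: float = 0.0,
    v2: float = 0.0,
) -> ScaledParameters:
    """Convert physical parameters (plus a touchdown state) to scaled form."""
    return ScaledParameters(
        p1=p1, p2=p2, v1=v1, v2=v2,
        omega1_sq=nat.k1 / nat.m1,
        omega2_sq=nat.k2 / nat.m2,
        lam=nat.m1 / nat.m2,
        zeta=nat.c / (2.0 * np.sqrt(nat.k2 * nat.m2)),
        M=nat.M,
    )


def to_natural(sc: ScaledParameters) -> NaturalParameters:
    """Recover physical masses, stiffnesses and damping from scaled form."""
    m2 = sc.M / (1.0 + sc.lam)
    m1 = sc.lam * m2
    k2 = sc.omega2_sq * m2
    k1 = sc.omega1_sq * m1
    c = 2.0 * sc.zeta * np.sqrt(k2 * m2)
    return NaturalParameters(m1=m1, m2=m2, k1=k1, k2=k2, c=c, M=sc.M)


def derivatives(s: ModelState, sc: ScaledParameters, g: float = G_DEFAULT):
    """Time derivatives (dp1, dp2, dv1, dv2) of the model state."""
    spring = sc.omega1_sq * (s.p1 - s.p2)
    a1 = -spring + g
    a2 = (
        -sc.omega2_sq * s.p2
        + sc.lam * spring
        - 2.0 * sc.zeta * np.sqrt(sc.omega2_sq) * s.v2
        + g
    )
    return (s.v1, s.v2, a1, a2)


def simulate(sc: ScaledParameters, cfg: SimulationConfig) -> Trajectory:
    """Integrate the equations of motion with classic fixed-step RK4.

    Raises :class:`SimulationDivergedError` (carrying the last valid time)
    if the state becomes non-finite or unbounded.
    """
    n_steps = cfg.n_steps
    P1, P2, V1, V2, n_valid = rk4_path(
        sc.p1, sc.p2, sc.v1, sc.v2,
        sc.omega1_sq, sc.omega2_sq, sc.lam, sc.zeta,
        cfg.g, cfg.dt, n_steps,
    )
    if n_valid < n_steps + 1:
        raise SimulationDivergedError(t_last=(n_valid - 1) * cfg.dt)
    t = np.arange(n_steps + 1) * cfg.dt
    return Trajectory(t=t, p1=P1, p2=P2, v1=V1, v2=V2, params=sc, config=cfg)


def grf(traj: Trajectory) -> TrialSeries:
    """Model ground reaction force in newtons on the model grid.

    ``GRF = -(k2 p2 + c v2)``, positive upward.
    """
    sc = traj.params
    nat = to_natural(sc)
    values = -(nat.k2 * traj.p2 + nat.c * traj.v2)
    return TrialSeries(t0=0.0, rate=1.0 / traj.config.dt, values=values, unit="N")


def upper_acc_in_g(traj: Trajectory) -> TrialSeries:
    """Upper-mass proper acceleration in g on the model grid.

    Returns ``(a1 - g) / 9.81``, the accelerometer-equivalent signal: 1 g
    when standing still, 0 g in free fall.  This is the model channel
    compared against gravity-corrected trunk accelerometry.
    """
    sc = traj.params
    values = -(sc.omega1_sq / G_PER_MS2) * (traj.p1 - traj.p2)
    return TrialSeries(t0=0.0, rate=1.0 / traj.config.dt, values=values, unit="g")


def takeoff_time(traj: Trajectory) -> Optional[float]:
    """Model take-off: first zero crossing of the model GRF after its
    maximum, located by linear interpolation; ``None`` if the GRF never
    returns to zero inside the simulated window."""
    f = grf(traj).values
    i_max = int(np.argmax(f))
    after = f[i_max:]
    below = np.nonzero(after <= 0.0)[0]
    if below.size == 0:
        return None
    j = int(below[0])
    if j == 0:
        return float(traj.t[i_max])
    i1 = i_max + j
    f0, f1 = f[i1 - 1], f[i1]
    frac = f0 / (f0 - f1) if f0 != f1 else 0.0
    return float(traj.t[i1 - 1] + frac * traj.config.dt)
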