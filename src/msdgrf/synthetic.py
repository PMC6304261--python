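"""Synthetic cohorts of paired GRF and trunk-accelerometer running trials.

Ground-truth parameters are drawn around the force-route parameter
medians and interquartile ranges reported for treadmill-free overground
running at 2-5 m s^-1, so each drawn model produces a realistic stance
GRF (impact and active peak, contact time from the model's own take-off).
The instrument model then emulates the study-grade hardware:

* force platform: 3,000 Hz sampling, additive white noise;
* trunk accelerometer: resultant proper acceleration in g, a damped
  15 Hz sinusoidal impact-shock artifact superimposed at touchdown
  (foot-strike shock transmitted up the spine, which the rigid two-mass
  model cannot produce), additive white noise, a 50 Hz second-order
  single-pass device low-pass, 100 Hz sampling and clipping at +/-13 g.

Because ground truth is known, every downstream stage (fitting, cohort
summaries, sensitivity experiments) is testable without any recorded data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Optional, Sequence

import numpy as np
from scipy import signal as _sig

from .model import (
    ScaledParameters,
    SimulationConfig,
    Trajectory,
    grf as model_grf,
    simulate,
    takeoff_time,
    upper_acc_in_g,
    SimulationDivergedError,
)
from .signals import TrialSeries, detect_stance


class GenerationError(RuntimeError):
    """A drawn ground truth produced no usable stance phase."""


# Force-route parameter anchors (median, q25, q75) per nominal speed,
# used as triangular-distribution sampling ranges for ground truth.
_TRUTH_ANCHORS = {
    2.0: {
        "p1": (0.00, -0.01, 0.00),
        "p2": (0.00, 0.00, 0.01),
        "v1": (-0.91, -1.12, -0.72),
        "v2": (-0.02, -0.40, 0.00),
        "omega1_sq": (528.0, 370.0, 721.0),
        "omega2_sq": (2421.0, 1516.0, 3420.0),
        "lam": (4.02, 2.14, 6.62),
        "zeta": (0.38, 0.29, 0.58),
    },
    3.0: {
        "p1": (0.00, -0.01, 0.00),
        "p2": (0.00, 0.00, 0.01),
        "v1": (-1.04, -1.26, -0.92),
        "v2": (-0.05, -0.28, 0.00),
        "omega1_sq": (577.0, 357.0, 935.0),
        "omega2_sq": (2966.0, 2265.0, 4593.0),
        "lam": (5.19, 2.82, 6.51),
        "zeta": (0.39, 0.28, 0.51),
    },
    4.0: {
        "p1": (0.00, -0.02, 0.00),
        "p2": (0.00, 0.00, 0.00),
        "v1": (-1.24, -1.34, -1.11),
        "v2": (-0.01, -0.24, 0.00),
        "omega1_sq": (621.0, 385.0, 959.0),
        "omega2_sq": (3574.0, 2305.0, 5094.0),
        "lam": (2.84, 1.86, 5.90),
        "zeta": (0.37, 0.28, 0.45),
    },
    5.0: {
        "p1": (-0.01, -0.02, -0.01),
        "p2": (0.00, 0.00, 0.00),
        "v1": (-1.13, -1.27, -0.98),
        "v2": (0.00, -0.10, 0.00),
        "omega1_sq": (687.0, 495.0, 1025.0),
        "omega2_sq": (4006.0, 3111.0, 6550.0),
        "lam": (2.74, 1.82, 3.40),
        "zeta": (0.31, 0.25, 0.40),
    },
}


@dataclass(frozen=True)
class DeviceModel:
    """Instrumentation emulation settings.

    The impact artifact amplitude scales linearly with approach speed
    between ``impact_amp_2ms`` (at 2 m s^-1) and ``impact_amp_5ms`` (at
    5 m s^-1); set both to 0 to disable the artifact.  ``device_lowpass``
    may be ``None`` for an ideal (unfiltered) accelerometer channel.
    """

    acc_rate: float = 100.0          # Hz
    acc_range: float = 13.0          # +/- g
    device_lowpass: Optional[float] = 50.0  # Hz, 2nd-order single-pass
    acc_noise_sd: float = 0.03       # g, before the device filter
    impact_amp_2ms: float = 3.0      # g
    impact_amp_5ms: float = 6.0      # g
    impact_freq: float = 15.0        # Hz
    impact_decay: float = 0.040      # s (exponential time constant)
    grf_rate: float = 3000.0         # Hz
    grf_noise_sd: float = 5.0        # N

    def __post_init__(self) -> None:
        if self.acc_rate <= 0 or self.grf_rate <= 0:
            raise ValueError("sample rates must be positive")
        if self.acc_range <= 0:
            raise ValueError("accelerometer range must be positive")
        if self.acc_noise_sd < 0 or self.grf_noise_sd < 0:
            raise ValueError("noise levels must be non-negative")

    def impact_amplitude(self, speed: float) -> float:
        """Artifact amplitude (g) at a given approach speed, m s^-1."""
        frac = np.clip((speed - 2.0) / 3.0, 0.0, 1.0)
        return float(self.impact_amp_2ms + frac * (self.impact_amp_5ms - self.impact_amp_2ms))

    def without_artifact(self) -> "DeviceModel":
        return replace(self, impact_amp_2ms=0.0, impact_amp_5ms=0.0)

    @classmethod
    def ideal(cls) -> "DeviceModel":
        """Noise-free, artifact-free, unfiltered instruments (pass-through)."""
        return cls(
            device_lowpass=None, acc_noise_sd=0.0,
            impact_amp_2ms=0.0, impact_amp_5ms=0.0, grf_noise_sd=0.0,
        )


@dataclass(frozen=True)
class CohortConfig:
    """Study-scale cohort layout: 20 subjects, 4 trials at each of
    2, 3, 4 and 5 m s^-1 (+/-5% realised speed), body mass 76 +/- 11 kg."""

    n_subjects: int = 20
    trials_per_speed: int = 4
    speeds: Sequence[float] = (2.0, 3.0, 4.0, 5.0)
    mass_mean: float = 76.0
    mass_sd: float = 11.0
    speed_jitter: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.trials_per_speed < 1:
            raise ValueError("counts must be >= 1")
        if any(s <= 0 for s in self.speeds):
            raise ValueError("speeds must be positive")
        if self.mass_sd < 0:
            raise ValueError("mass_sd must be non-negative")


@dataclass(frozen=True)
class SyntheticTrial:
    """A paired GRF + accelerometer trial with its generating truth."""

    grf: TrialSeries        # N, platform grid
    trunk_acc: TrialSeries  # g, accelerometer grid
    truth: ScaledParameters
    mass: float
    speed: float            # realised approach speed, m/s
    speed_nominal: float
    subject_id: int
    trial_id: str
    seed: int


def sample_truth(speed: float, mass: float, rng: np.random.Generator) -> ScaledParameters:
    """Draw a physically plausible ground-truth parameter set.

    Each parameter comes from a triangular distribution whose mode is the
    force-route median for the nearest nominal speed and whose support is
    the printed interquartile range; the lower-element stiffness and
    touchdown velocity magnitude therefore increase with speed while the
    lower mass starts near rest (p2 about 0, v2 about -0.02 m s^-1) with
    damping ratio about 0.36.
    """
    if not 1.5 <= speed <= 6.0:
        raise ValueError(f"speed {speed} m/s outside the supported 1.5-6 m/s range")
    nominal = min(_TRUTH_ANCHORS, key=lambda s: abs(s - speed))
    draws = {}
    for name, (mode, q25, q75) in _TRUTH_ANCHORS[nominal].items():
        lo, hi = min(q25, q75), max(q25, q75)
        if hi - lo < 1e-12:
            draws[name] = mode
        else:
            draws[name] = float(rng.triangular(lo, mode, hi))
    # keep v2 weakly negative so the damper loads (not unloads) the ground
    draws["v2"] = min(draws["v2"], 0.0)
    draws["zeta"] = max(draws["zeta"], 1e-3)
    return ScaledParameters(M=mass, **draws)


def _stance_trajectory(truth: ScaledParameters, dt: float, max_duration: float = 1.5) -> Trajectory:
    """Simulate the truth over its own stance: touchdown to the model GRF
    zero crossing after the force maximum."""
    probe = simulate(truth, SimulationConfig(dt=dt, duration=max_duration))
    t_off = takeoff_time(probe)
    if t_off is None or t_off < 20 * dt:
        raise GenerationError(
            f"no usable take-off within {max_duration} s (got {t_off})"
        )
    n_steps = max(int(np.ceil(t_off / dt - 1e-9)), 1)
    return simulate(truth, SimulationConfig(dt=dt, duration=n_steps * dt))


def generate_trial(
    truth: ScaledParameters,
    mass: float,
    device: DeviceModel,
    seed: int,
    speed: float = 4.0,
    subject_id: int = 0,
    trial_id: str = "trial",
) -> SyntheticTrial:
    """Render one trial through the instrument model.

    The truth is simulated over its own stance duration; the GRF channel
    adds platform noise on the 3,000 Hz grid, the accelerometer channel
    adds the impact-shock artifact and sensor noise, passes through the
    device low-pass, is sampled at 100 Hz and clipped to the sensor range.
    All randomness derives from ``seed``.
    """
    if abs(truth.M - mass) > 1e-9 * max(mass, 1.0):
        raise ValueError(f"truth.M={truth.M} does not match mass={mass}")
    rng = np.random.default_rng(seed)
    dt = 1.0 / device.grf_rate
    try:
        traj = _stance_trajectory(truth, dt)
    except SimulationDivergedError as exc:
        raise GenerationError(f"truth simulation diverged: {exc}") from exc

    grf_clean = model_grf(traj)
    grf_values = grf_clean.values.copy()
    if device.grf_noise_sd > 0:
        grf_values = grf_values + rng.normal(0.0, device.grf_noise_sd, grf_values.size)
    grf_series = TrialSeries(t0=0.0, rate=device.grf_rate, values=grf_values, unit="N")

    acc_clean = upper_acc_in_g(traj)
    t = traj.t
    amp = device.impact_amplitude(speed)
    acc_values = acc_clean.values.copy()
    if amp > 0:
        acc_values = acc_values + amp * np.exp(-t / device.impact_decay) * np.sin(
            2.0 * np.pi * device.impact_freq * t
        )
    if device.acc_noise_sd > 0:
        acc_values = acc_values + rng.normal(0.0, device.acc_noise_sd, acc_values.size)
    if device.device_lowpass is not None:
        sos = _sig.butter(
            2, device.device_lowpass / (device.grf_rate / 2.0), btype="low", output="sos"
        )
        acc_values = _sig.sosfilt(sos, acc_values)  # causal single pass, as a device would
    # sample at the accelerometer rate by linear interpolation, then clip
    n_acc = int(np.floor(t[-1] * device.acc_rate + 1e-9)) + 1
    t_acc = np.arange(n_acc) / device.acc_rate
    acc_sampled = np.interp(t_acc, t, acc_values)
    acc_sampled = np.clip(acc_sampled, -device.acc_range, device.acc_range)
    acc_series = TrialSeries(t0=0.0, rate=device.acc_rate, values=acc_sampled, unit="g")

    detect_stance(grf_series)  # raises NoContactError if the trial is unusable
    return SyntheticTrial(
        grf=grf_series,
        trunk_acc=acc_series,
        truth=truth,
        mass=mass,
        speed=speed,
        speed_nominal=speed,
        subject_id=subject_id,
        trial_id=trial_id,
        seed=seed,
    )


def generate_cohort(
    cfg: CohortConfig, device: Optional[DeviceModel] = None
) -> List[SyntheticTrial]:
    """Generate ``n_subjects * len(speeds) * trials_per_speed`` trials.

    Body mass is drawn once per subject; each trial's realised speed is
    jittered uniformly within +/-5% of nominal.  A truth draw that yields
    no usable stance is redrawn (bounded retries).  Deterministic under
    ``cfg.seed``.
    """
    device = device or DeviceModel()
    rng = np.random.default_rng(cfg.seed)
    masses = np.clip(
        rng.normal(cfg.mass_mean, cfg.mass_sd, cfg.n_subjects), 45.0, 120.0
    )
    trials: List[SyntheticTrial] = []
    for subject in range(cfg.n_subjects):
        mass = float(masses[subject])
        for nominal in cfg.speeds:
            for k in range(cfg.trials_per_speed):
                speed = float(
                    nominal * (1.0 + rng.uniform(-cfg.speed_jitter, cfg.speed_jitter))
                )
                trial_seed = int(rng.integers(0, 2**31 - 1))
                for attempt in range(20):
                    truth = sample_truth(nominal, mass, rng)
                    try:
                        trial = generate_trial(
                            truth, mass, device, seed=trial_seed,
                            speed=speed, subject_id=subject,
                            trial_id=f"s{subject:02d}_v{nominal:g}_t{k}",
                        )
                        break
                    except GenerationError:
                        continue
                else:
                    raise GenerationError(
                        f"could not draw a usable truth for subject {subject} "
                        f"at {nominal} m/s after 20 attempts"
                    )
                trial = replace(trial, speed_nominal=float(nominal))
                trials.append(trial)
    return trials
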