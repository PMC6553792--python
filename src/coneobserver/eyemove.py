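"""Fixational eye movements: drift, microsaccades, and cone-shift quantization.

Drift follows a delayed-feedback autoregressive random walk (the
Mergenthaler-Engbert form): at each step the 2-D displacement combines
Gaussian noise, an autoregressive persistence term, and a delayed negative
feedback with separate horizontal/vertical delays, producing persistent
dynamics at short lags and antipersistent dynamics at long lags. Positions
are smoothed with a 3rd-order Savitzky-Golay filter over a 41-ms window.
The model-internal position units are converted to arcmin with a fixed gain
calibrated once so that the within-trial retinal displacement of a 54-ms
trial is mostly 2-4 cone spacings or less at the reference mosaic
(cone pitch ~1.52 arcmin at 1,560 cones/deg^2).

Microsaccades are ballistic jumps of ~8 arcmin whose onsets follow a
gamma-distributed interval process (mean 450 ms, minimum 2 ms); most 54-ms
trials therefore contain none. Jump direction is either corrective (toward
the mosaic center) or random, and the displacement is spread over samples
at ~39 deg/s.

Continuous arcmin paths are quantized to integer cone shifts: sub-pitch
displacement accumulates until it crosses one cone pitch. A 216-ms warm-up
precedes each trial; it sets the trial's starting offset but is excluded
from the analysis window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

#: arcmin per model-internal drift position unit; fixed calibration (see docs)
DRIFT_GAIN_ARCMIN = 0.45

WARMUP_MS = 216.0


@dataclass(frozen=True)
class DriftParams:
    """Delayed-feedback drift model parameters (model-internal units)."""

    delay_x_s: float = 0.07
    delay_y_s: float = 0.04
    feedback_steepness: float = 1.1
    feedback_gain: float = 0.15
    control_mean: float = 0.0
    control_sd: float = 0.075
    control_gamma: float = 0.25
    noise_mean: float = 0.0
    noise_sd: float = 0.35
    savgol_order: int = 3
    savgol_window_ms: float = 41.0
    gain_arcmin: float = DRIFT_GAIN_ARCMIN

    def __post_init__(self):
        if self.control_sd < 0 or self.noise_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.delay_x_s <= 0 or self.delay_y_s <= 0:
            raise ValueError("feedback delays must be positive")


@dataclass(frozen=True)
class MicrosaccadeParams:
    """Microsaccade interval/amplitude/speed statistics."""

    interval_mean_ms: float = 450.0
    interval_min_ms: float = 2.0
    interval_shape: float = 2.0
    mean_amplitude_arcmin: float = 8.0
    amplitude_jitter_arcmin: float = 0.3
    direction_jitter_deg: float = 15.0
    mean_speed_deg_s: float = 39.0
    speed_sd_deg_s: float = 2.0
    corrective_probability: float = 0.5

    def __post_init__(self):
        if self.mean_amplitude_arcmin <= 0 or self.mean_speed_deg_s <= 0:
            raise ValueError("amplitude and speed must be positive")


@dataclass
class ConeShiftPath:
    """Integer cone-unit eye position per trial time sample."""

    shifts: np.ndarray  # (n_time, 2) int, (dx, dy) in cone units
    path_arcmin: np.ndarray  # (n_time, 2) source path (warm-up removed)
    cone_pitch_arcmin: float
    warmup_ms: float = WARMUP_MS

    @property
    def max_excursion_cones(self) -> int:
        return int(np.max(np.abs(self.shifts))) if len(self.shifts) else 0


def simulate_drift(
    duration_ms: float,
    dt_ms: float = 2.0,
    params: DriftParams | None = None,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Simulate a 2-D drift path; returns (n_steps, 2) positions in arcmin.

    Per axis: delta_{t+1} = gamma * delta_t + eta_t - lam * tanh(eps * x_{t-tau}),
    with eta white Gaussian noise plus a slow control input, per-axis
    feedback delays tau, steepness eps and gain lam; positions are smoothed
    with the Savitzky-Golay filter and scaled to arcmin.
    """
    params = params or DriftParams()
    if duration_ms <= 0:
        raise ValueError("duration must be positive")
    delays = np.array([params.delay_x_s, params.delay_y_s]) * 1000.0
    if dt_ms > delays.min():
        raise ValueError("time step exceeds the feedback delays")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    n = int(round(duration_ms / dt_ms)) + 1
    lag = np.maximum(1, np.round(delays / dt_ms).astype(int))
    pos = np.zeros((n, 2))
    delta = np.zeros(2)
    for t in range(1, n):
        noise = rng.normal(params.noise_mean, params.noise_sd, size=2)
        control = rng.normal(params.control_mean, params.control_sd, size=2)
        fb = np.zeros(2)
        for ax in range(2):
            t_del = t - 1 - lag[ax]
            if t_del >= 0:
                fb[ax] = params.feedback_gain * np.tanh(
                    params.feedback_steepness * pos[t_del, ax]
                )
        delta = params.control_gamma * delta + noise + control - fb
        pos[t] = pos[t - 1] + delta

    win = int(round(params.savgol_window_ms / dt_ms))
    win += win % 2 == 0  # odd window
    if params.savgol_order < win <= n:
        pos = savgol_filter(pos, win, params.savgol_order, axis=0)
    return pos * params.gain_arcmin


def sample_microsaccades(
    duration_ms: float,
    params: MicrosaccadeParams | None = None,
    current_offset_arcmin: tuple[float, float] = (0.0, 0.0),
    seed: int | np.random.Generator = 0,
) -> list[dict]:
    """Draw microsaccade events within a window of ``duration_ms``.

    Returns a list of events ``{"t_ms", "vector_arcmin", "duration_ms"}``.
    Onsets follow the gamma interval process; each event is an ~8-arcmin
    vector with endpoint jitter, directed toward the mosaic center
    (corrective mode) or uniformly at random, traversed at the sampled speed.
    """
    params = params or MicrosaccadeParams()
    if duration_ms <= 0:
        raise ValueError("duration must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    events = []
    offset = np.asarray(current_offset_arcmin, dtype=float)
    scale = params.interval_mean_ms / params.interval_shape
    t = 0.0
    while True:
        interval = max(rng.gamma(params.interval_shape, scale), params.interval_min_ms)
        t += interval
        if t >= duration_ms:
            break
        amplitude = max(
            0.1, params.mean_amplitude_arcmin + rng.normal(0.0, params.amplitude_jitter_arcmin)
        )
        corrective = rng.random() < params.corrective_probability
        if corrective and np.linalg.norm(offset) > 1e-9:
            base_angle = np.arctan2(-offset[1], -offset[0])
        else:
            base_angle = rng.uniform(0.0, 2.0 * np.pi)
        angle = base_angle + np.deg2rad(rng.normal(0.0, params.direction_jitter_deg))
        vec = amplitude * np.array([np.cos(angle), np.sin(angle)])
        speed_arcmin_ms = max(1.0, rng.normal(params.mean_speed_deg_s, params.speed_sd_deg_s)) * 60.0 / 1000.0
        events.append(
            {"t_ms": t, "vector_arcmin": vec, "duration_ms": amplitude / speed_arcmin_ms}
        )
        offset = offset + vec
    return events


def _add_events_to_path(path: np.ndarray, dt_ms: float, events: list[dict]) -> np.ndarray:
    """Superimpose microsaccade displacement ramps onto a drift path."""
    out = path.copy()
    n = len(path)
    for ev in events:
        i0 = int(ev["t_ms"] / dt_ms)
        n_span = max(1, int(np.ceil(ev["duration_ms"] / dt_ms)))
        # partial vector during the ballistic phase, full vector afterwards
        for i in range(i0 + 1, n):
            frac = min(1.0, (i - i0) / n_span)
            out[i] += ev["vector_arcmin"] * frac
    return out


def path_to_cone_shifts(
    path_arcmin: np.ndarray,
    cone_pitch_arcmin: float,
    warmup_ms: float = WARMUP_MS,
    dt_ms: float = 2.0,
) -> ConeShiftPath:
    """Quantize an arcmin path to integer cone shifts.

    Displacement accumulates across samples; an integer shift is emitted only
    when the accumulated displacement crosses one cone pitch. The warm-up
    segment determines the trial's starting offset and is then discarded.
    """
    if cone_pitch_arcmin <= 0:
        raise ValueError("cone pitch must be positive")
    path = np.atleast_2d(np.asarray(path_arcmin, dtype=float))
    n_warm = int(round(warmup_ms / dt_ms))
    quant = np.zeros_like(path, dtype=int)
    q = np.zeros(path.shape[1], dtype=int)
    for t in range(len(path)):
        # emit shifts only when accumulated displacement crosses one pitch
        for ax in range(path.shape[1]):
            acc = path[t, ax] - q[ax] * cone_pitch_arcmin
            if abs(acc) >= cone_pitch_arcmin * (1.0 - 1e-9):
                q[ax] += int(np.trunc(acc / cone_pitch_arcmin + np.sign(acc) * 1e-9))
        quant[t] = q
    trial_q = quant[n_warm:]
    trial_path = path[n_warm:]
    return ConeShiftPath(
        shifts=trial_q,
        path_arcmin=trial_path,
        cone_pitch_arcmin=float(cone_pitch_arcmin),
        warmup_ms=warmup_ms,
    )


def simulate_em_path(
    trial_duration_ms: float,
    cone_pitch_arcmin: float,
    dt_ms: float = 2.0,
    drift: DriftParams | None = None,
    microsaccades: MicrosaccadeParams | None = None,
    enabled: bool = True,
    seed: int | np.random.Generator = 0,
) -> ConeShiftPath:
    """Full fixational path (warm-up + trial) quantized to cone shifts.

    With ``enabled=False`` the path is identically zero, reproducing the
    no-eye-movement condition.
    """
    n_total = int(round((WARMUP_MS + trial_duration_ms) / dt_ms)) + 1
    n_trial = int(round(trial_duration_ms / dt_ms)) + 1
    if not enabled:
        zeros = np.zeros((n_trial, 2))
        return ConeShiftPath(
            shifts=zeros.astype(int),
            path_arcmin=zeros,
            cone_pitch_arcmin=float(cone_pitch_arcmin),
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    path = simulate_drift(WARMUP_MS + trial_duration_ms, dt_ms, drift, rng)
    events = sample_microsaccades(
        WARMUP_MS + trial_duration_ms, microsaccades, tuple(path[-1]), rng
    )
    path = _add_events_to_path(path, dt_ms, events)
    return path_to_cone_shifts(path, cone_pitch_arcmin, WARMUP_MS, dt_ms)


def path_to_csv(path: ConeShiftPath, file, dt_ms: float = 2.0) -> None:
    """Write a quantized path as CSV (t_ms, x_arcmin, y_arcmin, dx_cones, dy_cones)."""
    import csv

    writer = csv.writer(file)
    writer.writerow(["t_ms", "x_arcmin", "y_arcmin", "dx_cones", "dy_cones"])
    for i in range(len(path.shifts)):
        writer.writerow([
            i * dt_ms,
            f"{path.path_arcmin[i, 0]:.4f}",
            f"{path.path_arcmin[i, 1]:.4f}",
            int(path.shifts[i, 0]),
            int(path.shifts[i, 1]),
        ])
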