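"""Orbital-shaker stage: compare device outputs against each other and
against the centripetal-acceleration oracle.

An orbital shaker translates its tray in a horizontal circle of radius r at a
platform speed of ``rpm`` revolutions per minute without rotating it, so a
mounted accelerometer experiences a centripetal acceleration of constant
magnitude a = omega**2 * r (omega = 2*pi*rpm/60) that appears as quadrature
sinusoids on the two in-plane axes, while the vertical axis reads a constant
1 g.  This closed form is the ground truth ("oracle") that simulated and
recorded trials are checked against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .signal_core import Recording, vector_magnitude

#: g-conversion constant in m/s^2.  9.81 (not 9.80665) is used throughout
#: because it reproduces the printed centrifugal-acceleration table exactly.
G_MS2 = 9.81

#: Default platform speeds (rev/min) with their nominal frequency labels in Hz.
DEFAULT_RPMS = (40, 80, 140, 200, 240)
NOMINAL_HZ = {40: 0.7, 80: 1.3, 140: 2.3, 200: 3.3, 240: 4.0}


def centripetal_acceleration(rpm: float, radius_m: float, g_ms2: float = G_MS2) -> float:
    """Centripetal acceleration a = omega**2 * r, returned in g.

    Parameters
    ----------
    rpm : float
        Platform speed in revolutions per minute (>= 0).
    radius_m : float
        Orbit radius in metres (> 0).
    g_ms2 : float
        g-conversion constant, default 9.81 m/s^2.
    """
    if rpm < 0:
        raise ValueError(f"rpm must be >= 0, got {rpm}")
    if radius_m <= 0:
        raise ValueError(f"radius_m must be > 0, got {radius_m}")
    omega = 2.0 * math.pi * rpm / 60.0
    return omega**2 * radius_m / g_ms2


@dataclass
class ShakerTrial:
    """One 2-minute oscillation trial recorded by one or more devices."""

    rpm: float
    radius_m: float
    trial_index: int
    recordings: dict[str, Recording]
    analysis_window: tuple[float, float] = (60.0, 120.0)

    def __post_init__(self) -> None:
        durs = {round(r.duration_s, 6) for r in self.recordings.values()}
        fss = {r.fs for r in self.recordings.values()}
        if len(durs) > 1 or len(fss) > 1:
            raise ValueError("trial recordings must share fs and duration")
        lo, hi = self.analysis_window
        for r in self.recordings.values():
            if not (0 <= lo < hi <= r.duration_s + 1e-9):
                raise ValueError(
                    f"analysis window {self.analysis_window} outside recording "
                    f"of duration {r.duration_s}s"
                )


@dataclass
class ShakerComparison:
    """Inter-device comparison at one platform speed."""

    rpm: float
    oracle_g: float
    mean_vm: dict[str, float]
    mean_peak: dict[str, float]
    pct_difference: float  # 100 * (B - A) / A over trial mean VMs
    p_value: float
    n_trials: dict[str, int]
    device_a: str = ""
    device_b: str = ""


def trial_mean_vm(trial: ShakerTrial, device_id: str) -> float:
    """Mean triaxial vector magnitude over the trial's analysis window.

    The analysis window defaults to the second minute of a 2-minute trial,
    excluding spin-up.
    """
    if device_id not in trial.recordings:
        raise ValueError(
            f"device {device_id!r} absent from trial (has "
            f"{sorted(trial.recordings)})"
        )
    rec = trial.recordings[device_id].slice_seconds(*trial.analysis_window)
    return float(np.mean(vector_magnitude(rec)))


def mean_peak_acceleration(
    series: np.ndarray, rpm: float, fs: float
) -> tuple[float, int]:
    """Mean per-half-revolution peak |acceleration| of one in-plane axis.

    The analysis window is partitioned into half-revolution segments of
    duration 60/(2*rpm) seconds; within each segment the peak of the absolute
    signal is taken (one acceleration peak on either side of the 0-g baseline
    per revolution), and the mean over segments is returned together with the
    number of peaks found.
    """
    if rpm <= 0:
        raise ValueError(f"rpm must be > 0 for peak extraction, got {rpm}")
    series = np.asarray(series, dtype=float)
    seg_len = fs * 60.0 / (2.0 * rpm)  # samples per half-revolution
    n_seg = int(len(series) / seg_len)
    if n_seg < 4:
        raise ValueError(
            f"window holds only {n_seg} half-revolutions (< 4) at {rpm} rpm"
        )
    edges = np.round(np.arange(n_seg + 1) * seg_len).astype(int)
    peaks = np.array(
        [np.max(np.abs(series[edges[k]:edges[k + 1]])) for k in range(n_seg)]
    )
    return float(peaks.mean()), n_seg


def compare_devices(
    trials: list[ShakerTrial],
    device_a: str,
    device_b: str,
    n_perm: int = 10_000,
    seed: int = 0,
) -> ShakerComparison:
    """Compare two devices' trial-level mean VMs at one platform speed.

    The percent difference uses device_a (the reference device) as the
    denominator.  Significance is assessed with a two-sided permutation test
    on the difference of trial means, with the trial as the exchangeable
    unit: trial labels are shuffled ``n_perm`` times and the permutation
    p-value includes the observed statistic
    (p = (1 + #{|perm| >= |obs|}) / (n_perm + 1)).
    """
    if n_perm < 100:
        raise ValueError(f"n_perm must be >= 100, got {n_perm}")
    rpms = {t.rpm for t in trials}
    if len(rpms) != 1:
        raise ValueError(f"trials span multiple rpms: {sorted(rpms)}")
    rpm = rpms.pop()
    a = np.array([trial_mean_vm(t, device_a) for t in trials])
    b = np.array([trial_mean_vm(t, device_b) for t in trials])
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need >= 3 trials per device")
    obs = b.mean() - a.mean()
    pooled = np.concatenate([a, b])
    rng = np.random.default_rng(seed)
    n_a = len(a)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if abs(perm[n_a:].mean() - perm[:n_a].mean()) >= abs(obs) - 1e-15:
            count += 1
    p_value = (1 + count) / (n_perm + 1)

    radius = trials[0].radius_m
    oracle = centripetal_acceleration(rpm, radius)
    mean_peak: dict[str, float] = {}
    for dev in (device_a, device_b):
        vals = []
        for t in trials:
            rec = t.recordings[dev].slice_seconds(*t.analysis_window)
            vals.append(mean_peak_acceleration(rec.x, rpm, rec.fs)[0])
        mean_peak[dev] = float(np.mean(vals))
    return ShakerComparison(
        rpm=rpm,
        oracle_g=oracle,
        mean_vm={device_a: float(a.mean()), device_b: float(b.mean())},
        mean_peak=mean_peak,
        pct_difference=float(100.0 * obs / a.mean()),
        p_value=float(p_value),
        n_trials={device_a: len(a), device_b: len(b)},
        device_a=device_a,
        device_b=device_b,
    )
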