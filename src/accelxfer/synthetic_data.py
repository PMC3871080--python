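"""Synthetic shaker and wrist-activity signal generation with a parametric
device model.

No raw data were deposited by the inter-monitor comparison study this package
replays, so the study conditions are re-created synthetically with known
ground truth:

* **Shaker trials** — an orbital shaker translates (does not rotate) its tray
  in a circle, so the true signal is a pair of quadrature sinusoids of
  amplitude ``a = omega**2 * r`` on the in-plane axes and a constant 1 g on
  the gravity axis.  The closed form doubles as the oracle the simulated
  device output is verified against.

* **Activity bouts** — 2-minute wrist-worn bouts of eight activity
  conditions, modelled per class as jittered sinusoidal harmonics (rhythmic
  activities: walking, running, vacuuming) plus Poisson-timed impulsive
  bursts (intermittent activities: cleaning, throwing) over a white baseline,
  with multiplicative between-subject variability.

* **Device model** — a parametric transfer function (per-axis gain and
  offset, single-pole low-pass, additive white noise, uniform mid-tread
  quantization, clipping at the dynamic range) standing in for the
  proprietary sensor/signal-path differences between commercial monitors.

Two default device models are provided: an identity-like reference device
(``AG``) and a mismatched device (``GE``) whose gain/offset were chosen so
that its mean-VM elevation over the reference grows from roughly 4% to 6%
across the shaker speed range, mirroring the inter-monitor pattern reported
for real hardware.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import lfilter

from .shaker_analysis import centripetal_acceleration
from .signal_core import Bout, Recording

#: Relative per-axis coupling of wrist movement into the device frame:
#: movement is strongest along the forearm axis and weakest along gravity.
AXIS_WEIGHTS = (1.0, 0.6, 0.3)


def child_rng(seed: int, *tags) -> np.random.Generator:
    """Deterministic named child stream of a master seed.

    Child streams are keyed by hashing the string form of each tag, so the
    same (seed, tags) always yields the same generator and distinct tags
    yield independent streams.  No global random state is used anywhere.
    """
    entropy = [int(seed) & 0x7FFFFFFF]
    entropy += [zlib.crc32(str(t).encode()) for t in tags]
    return np.random.default_rng(np.random.SeedSequence(entropy))


# ---------------------------------------------------------------------------
# Device model
# ---------------------------------------------------------------------------

def _as_axis_triple(v) -> tuple[float, float, float]:
    a = np.broadcast_to(np.asarray(v, dtype=float), (3,))
    return (float(a[0]), float(a[1]), float(a[2]))


@dataclass(frozen=True)
class DeviceModel:
    """Parametric transfer function from true to recorded acceleration.

    Applied per axis, in order: gain -> offset -> first-order low-pass (if
    ``lowpass_hz`` set) -> additive white noise -> uniform mid-tread
    quantization over +/-``range_g`` (if ``adc_bits`` set) -> clipping to
    +/-``range_g``.

    ``gain`` and ``offset`` may be scalars or per-axis triples; ``noise_sd``
    is the white-noise sigma in g; ``range_g`` is the dynamic range (clip
    limit) in g.
    """

    device_id: str
    gain: float | tuple[float, float, float] = 1.0
    offset: float | tuple[float, float, float] = 0.0
    noise_sd: float = 0.0
    lowpass_hz: float | None = None
    adc_bits: int | None = None
    range_g: float = 6.0
    fs: float = 80.0

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.gain) <= 0):
            raise ValueError(f"gain must be > 0, got {self.gain}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.range_g <= 0:
            raise ValueError(f"range_g must be > 0, got {self.range_g}")
        if self.adc_bits is not None and not (8 <= self.adc_bits <= 16):
            raise ValueError(f"adc_bits must be in 8..16, got {self.adc_bits}")

    @property
    def gain3(self) -> tuple[float, float, float]:
        return _as_axis_triple(self.gain)

    @property
    def offset3(self) -> tuple[float, float, float]:
        return _as_axis_triple(self.offset)


#: Reference device: unit gain, no bias — its output is the true signal plus
#: sensor noise.
DEFAULT_DEVICE_A = DeviceModel(device_id="AG", gain=1.0, offset=0.0, noise_sd=0.01)

#: Mismatched device: 6% sensitivity excess and a -0.02 g per-axis zero-g
#: offset, giving a mean-VM elevation over the reference that rises from
#: ~4% at the lowest shaker speed to ~6% at the highest.
DEFAULT_DEVICE_B = DeviceModel(device_id="GE", gain=1.06, offset=-0.02, noise_sd=0.01)


def _lowpass_first_order(x: np.ndarray, cutoff_hz: float, fs: float) -> np.ndarray:
    # single-pole IIR; state initialised at x[0] to avoid a spin-up transient
    dt = 1.0 / fs
    rc = 1.0 / (2.0 * np.pi * cutoff_hz)
    alpha = dt / (rc + dt)
    b, a = [alpha], [1.0, alpha - 1.0]
    y, _ = lfilter(b, a, x, zi=[(1.0 - alpha) * x[0]])
    return y


def apply_device_model(
    true_recording: Recording, dev: DeviceModel, seed: int
) -> Recording:
    """Pass a true-acceleration recording through a device model.

    Deterministic given ``seed`` (noise is drawn from a named child stream
    per axis).  The identity model (unit gain, zero offset/noise, no filter
    or quantizer) returns the input samples exactly.
    """
    rng = child_rng(seed, "device-noise")
    out = {}
    for axis, g, o in zip("xyz", dev.gain3, dev.offset3):
        v = getattr(true_recording, axis) * g + o
        if dev.lowpass_hz is not None:
            v = _lowpass_first_order(v, dev.lowpass_hz, dev.fs)
        if dev.noise_sd > 0:
            v = v + rng.normal(0.0, dev.noise_sd, size=len(v))
        if dev.adc_bits is not None:
            step = 2.0 * dev.range_g / (2**dev.adc_bits)
            v = np.round(v / step) * step
        out[axis] = np.clip(v, -dev.range_g, dev.range_g)
    return replace(
        true_recording,
        device_id=dev.device_id,
        x=out["x"],
        y=out["y"],
        z=out["z"],
    )


# ---------------------------------------------------------------------------
# Shaker trials
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ShakerConfig:
    """Geometry and timing of one orbital-shaker trial.

    ``rpm`` is the platform speed in revolutions per minute (the shaker's
    nominal frequency in Hz is rpm/60); ``radius_m`` the orbit radius.  The
    two ``plane_axes`` carry the quadrature sinusoids and ``gravity_axis``
    the constant 1 g.
    """

    rpm: float
    radius_m: float = 0.0508
    duration_s: float = 120.0
    fs: float = 80.0
    plane_axes: tuple[str, str] = ("x", "y")
    gravity_axis: str = "z"
    phase0: float = 0.0

    def __post_init__(self) -> None:
        if self.rpm < 0:
            raise ValueError(f"rpm must be >= 0, got {self.rpm}")
        if self.radius_m <= 0:
            raise ValueError(f"radius_m must be > 0, got {self.radius_m}")
        if self.gravity_axis in self.plane_axes:
            raise ValueError("gravity_axis must differ from plane_axes")


def true_shaker_recording(cfg: ShakerConfig) -> Recording:
    """Noise-free true signal of an orbital-shaker trial.

    In-plane axes see ``A*cos(omega*t + phase0)`` and ``A*sin(...)`` with
    ``A = omega**2 * r`` in g; the gravity axis reads a constant 1 g.  The
    vector magnitude is therefore constant at sqrt(A**2 + 1).
    """
    n = int(round(cfg.duration_s * cfg.fs))
    t = np.arange(n) / cfg.fs
    amp = centripetal_acceleration(cfg.rpm, cfg.radius_m)
    omega = 2.0 * np.pi * cfg.rpm / 60.0
    axes = {
        cfg.plane_axes[0]: amp * np.cos(omega * t + cfg.phase0),
        cfg.plane_axes[1]: amp * np.sin(omega * t + cfg.phase0),
        cfg.gravity_axis: np.ones(n),
    }
    return Recording(
        device_id="true",
        fs=cfg.fs,
        x=axes["x"],
        y=axes["y"],
        z=axes["z"],
        annotations=[Bout(label=f"shaker_{cfg.rpm:g}rpm", start_s=0.0, end_s=n / cfg.fs)],
    )


def simulate_shaker_trial(cfg: ShakerConfig, dev: DeviceModel, seed: int) -> Recording:
    """Simulate one shaker trial as recorded by a device model.

    Warns (does not fail) if the configured motion amplitude exceeds the
    device's dynamic range after gain and offset, since clipping will occur.
    """
    amp = centripetal_acceleration(cfg.rpm, cfg.radius_m)
    if amp * max(dev.gain3) + max(abs(o) for o in dev.offset3) > dev.range_g:
        warnings.warn(
            f"shaker amplitude {amp:.2f} g exceeds device range "
            f"+/-{dev.range_g:g} g after gain/offset: output will clip",
            stacklevel=2,
        )
    return apply_device_model(true_shaker_recording(cfg), dev, seed)


# ---------------------------------------------------------------------------
# Activity bouts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ActivityModel:
    """Generative model of one wrist-worn activity condition.

    ``harmonics`` is a list of ``(frequency_hz, amplitude_g, amplitude_cv)``
    sinusoidal components with slowly varying amplitude (coefficient of
    variation ``amplitude_cv`` on a ~1 s timescale); ``burst_rate`` and
    ``burst_amp`` control Poisson-timed impulsive events (half-sine pulses in
    a random 3-D direction); ``baseline_sd`` is white movement noise and
    ``subject_cv`` the log-scale sigma of the per-subject multiplicative
    vigour factor.
    """

    label: str
    harmonics: tuple[tuple[float, float, float], ...] = ()
    burst_rate: float = 0.0
    burst_amp: float = 0.0
    baseline_sd: float = 0.01
    subject_cv: float = 0.2

    def __post_init__(self) -> None:
        for f, a, _cv in self.harmonics:
            if a < 0:
                raise ValueError(f"harmonic amplitude must be >= 0, got {a}")
        if self.burst_rate < 0 or self.burst_amp < 0 or self.baseline_sd < 0:
            raise ValueError("burst_rate, burst_amp and baseline_sd must be >= 0")


def default_activity_models() -> dict[str, ActivityModel]:
    """The eight default activity conditions of the synthetic protocol.

    Rhythmic locomotion carries a dominant harmonic near the step frequency
    (in the 0.6-2.5 Hz band for walking, above it for running); vacuuming is
    a low-amplitude fast repetitive movement; cleaning is intermittent
    (frequent moderate bursts over a weak ambulatory harmonic); throwing is
    sparse large bursts; computer work is near-still.
    """
    return {
        "computer": ActivityModel(
            "computer", harmonics=(), burst_rate=0.05, burst_amp=0.05,
            baseline_sd=0.01, subject_cv=0.3,
        ),
        "clean": ActivityModel(
            "clean", harmonics=((1.9, 0.10, 0.4),), burst_rate=1.2,
            burst_amp=0.45, baseline_sd=0.05, subject_cv=0.3,
        ),
        "vacuum": ActivityModel(
            "vacuum", harmonics=((3.9, 0.22, 0.15),), burst_rate=0.2,
            burst_amp=0.10, baseline_sd=0.03, subject_cv=0.2,
        ),
        "throw": ActivityModel(
            "throw", harmonics=(), burst_rate=0.4, burst_amp=1.3,
            baseline_sd=0.04, subject_cv=0.3,
        ),
        "walk_2.0": ActivityModel(
            "walk_2.0", harmonics=((1.9, 0.28, 0.15), (0.95, 0.08, 0.2)),
            baseline_sd=0.02, subject_cv=0.2,
        ),
        "walk_3.5": ActivityModel(
            "walk_3.5", harmonics=((2.4, 0.50, 0.15), (1.2, 0.10, 0.2)),
            baseline_sd=0.02, subject_cv=0.2,
        ),
        "run_5.5": ActivityModel(
            "run_5.5", harmonics=((2.7, 1.10, 0.15), (1.35, 0.15, 0.2)),
            baseline_sd=0.04, subject_cv=0.2,
        ),
        "run_7.5": ActivityModel(
            "run_7.5", harmonics=((3.0, 1.60, 0.15), (1.5, 0.20, 0.2)),
            baseline_sd=0.05, subject_cv=0.2,
        ),
    }


def _amplitude_envelope(
    rng: np.random.Generator, n: int, fs: float, cv: float
) -> np.ndarray:
    """Slow multiplicative amplitude jitter: per-second lognormal factors,
    linearly interpolated to the sample grid."""
    if cv <= 0:
        return np.ones(n)
    n_sec = max(2, int(np.ceil(n / fs)) + 1)
    knots = np.exp(rng.normal(0.0, cv, size=n_sec))
    tk = np.arange(n_sec) * fs
    return np.interp(np.arange(n), tk, knots)


def _burst_train(
    rng: np.random.Generator,
    n: int,
    fs: float,
    rate: float,
    amp: float,
) -> np.ndarray:
    """Poisson-timed half-sine pulses in random 3-D directions; (3, n)."""
    out = np.zeros((3, n))
    if rate <= 0 or amp <= 0:
        return out
    n_events = rng.poisson(rate * n / fs)
    width = max(4, int(round(0.2 * fs)))  # ~200 ms impact
    pulse = np.sin(np.pi * np.arange(width) / (width - 1))
    for _ in range(n_events):
        start = rng.integers(0, max(1, n - width))
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction) + 1e-12
        mag = amp * rng.uniform(0.5, 1.5)
        for ax in range(3):
            out[ax, start:start + width] += mag * direction[ax] * pulse
    return out


def true_activity_recording(
    model: ActivityModel,
    subject_id: str,
    duration_s: float,
    fs: float,
    seed: int,
) -> Recording:
    """True (pre-device) wrist acceleration for one subject x activity bout.

    Harmonics are distributed over the three axes with fixed relative
    weights and independent random phases; the gravity axis additionally
    carries +1 g.  Deterministic given ``seed``.
    """
    for f, _a, _cv in model.harmonics:
        if f >= fs / 2:
            raise ValueError(
                f"harmonic at {f} Hz aliases at fs={fs} Hz (Nyquist {fs/2} Hz)"
            )
    rng = child_rng(seed, "activity", model.label, subject_id)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    subj_factor = float(np.exp(rng.normal(0.0, model.subject_cv)))
    axes = np.zeros((3, n))
    for f, a, cv in model.harmonics:
        env = _amplitude_envelope(rng, n, fs, cv)
        for ax, w in enumerate(AXIS_WEIGHTS):
            phase = rng.uniform(0.0, 2.0 * np.pi)
            axes[ax] += w * a * subj_factor * env * np.sin(2 * np.pi * f * t + phase)
    axes += _burst_train(rng, n, fs, model.burst_rate, model.burst_amp * subj_factor)
    axes += rng.normal(0.0, model.baseline_sd, size=(3, n))
    axes[2] += 1.0  # gravity
    return Recording(
        device_id="true",
        fs=fs,
        x=axes[0],
        y=axes[1],
        z=axes[2],
        annotations=[
            Bout(label=model.label, start_s=0.0, end_s=n / fs, subject_id=subject_id)
        ],
    )


def simulate_activity_bout(
    model: ActivityModel,
    subject_id: str,
    dev: DeviceModel,
    duration_s: float = 120.0,
    seed: int = 0,
) -> Recording:
    """One annotated activity bout as recorded by a device model."""
    truth = true_activity_recording(model, subject_id, duration_s, dev.fs, seed)
    return apply_device_model(truth, dev, child_rng(seed, "bout-dev", dev.device_id).integers(2**31))


# ---------------------------------------------------------------------------
# Study assembly
# ---------------------------------------------------------------------------

@dataclass
class StudyConfig:
    """Sample sizes and models of the synthetic simultaneous-wear study."""

    subjects: tuple[str, ...] = tuple(f"S{i:02d}" for i in range(1, 9))
    activities: dict[str, ActivityModel] = field(default_factory=default_activity_models)
    device_a: DeviceModel = DEFAULT_DEVICE_A
    device_b: DeviceModel | None = DEFAULT_DEVICE_B
    duration_s: float = 120.0
    fs: float = 80.0
    master_seed: int = 0


def build_study(cfg: StudyConfig) -> dict[str, list[Recording]]:
    """Simulate the paired-device wear protocol.

    For each subject x activity, one true signal is generated and passed
    through BOTH device models (simultaneous wear: the devices disagree only
    through their transfer functions and independent sensor noise).  Returns
    ``{device_id: [bout Recording, ...]}`` with identical annotations across
    devices.
    """
    if len(cfg.subjects) < 2:
        raise ValueError("need >= 2 subjects")
    if len(set(cfg.subjects)) != len(cfg.subjects):
        raise ValueError(f"duplicate subject ids in {cfg.subjects}")
    devices = [cfg.device_a] + ([cfg.device_b] if cfg.device_b is not None else [])
    out: dict[str, list[Recording]] = {d.device_id: [] for d in devices}
    if len(out) != len(devices):
        raise ValueError("device models must have distinct device_ids")
    for subject in cfg.subjects:
        for label, model in sorted(cfg.activities.items()):
            truth_seed = int(
                child_rng(cfg.master_seed, "truth", subject, label).integers(2**31)
            )
            truth = true_activity_recording(
                model, subject, cfg.duration_s, cfg.fs, truth_seed
            )
            for dev in devices:
                # noise stream keyed by device *parameters*: two identical
                # models worn simultaneously record identical samples
                params_key = (dev.gain3, dev.offset3, dev.noise_sd,
                              dev.lowpass_hz, dev.adc_bits, dev.range_g)
                dev_seed = int(
                    child_rng(cfg.master_seed, "devnoise", subject, label, params_key)
                    .integers(2**31)
                )
                out[dev.device_id].append(apply_device_model(truth, dev, dev_seed))
    return out
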