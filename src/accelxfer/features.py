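"""Time-domain and frequency-domain feature extraction on signal windows.

The two feature sets mirror the inputs of the activity-recognition models
under comparison:

* **TD** — mean, standard deviation, the 10th/25th/50th/75th/90th
  percentiles of the signal distribution, and the lag-1 autocorrelation.
  All but the autocorrelation are expressed in g and therefore scale with
  any device gain applied to the signal.

* **FD** — mean acceleration, total spectral power, dominant frequency,
  power in the 0.6-2.5 Hz band, that band power divided by total power, and
  the cumulative-spectral-power 10th/90th percentile frequencies (f10/f90).
  The shape descriptors (dominant frequency, band ratio, f10, f90) are
  invariant under a uniform gain, which is the mechanism by which FD models
  transfer between miscalibrated devices while TD models do not.

The spectral estimator is a plain one-sided periodogram of the demeaned
window, normalized so that the spectral powers sum exactly to the biased
sample variance (Parseval).  With the default 20-s window at 80 Hz the
frequency resolution is 0.05 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .signal_core import Window

#: Frequency band (Hz) capturing locomotor rhythms.
DEFAULT_BAND = (0.6, 2.5)

TD_COLUMNS = ("mean", "sd", "p10", "p25", "p50", "p75", "p90", "lag1_autocorr")
FD_COLUMNS = (
    "mean_acc",
    "total_power",
    "dom_freq",
    "band_power",
    "band_ratio",
    "f10",
    "f90",
)


@dataclass(frozen=True)
class TDFeatures:
    mean: float
    sd: float
    p10: float
    p25: float
    p50: float
    p75: float
    p90: float
    lag1_autocorr: float

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in TD_COLUMNS}


@dataclass(frozen=True)
class FDFeatures:
    mean_acc: float
    total_power: float
    dom_freq: float
    band_power: float
    band_ratio: float
    f10: float
    f90: float

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in FD_COLUMNS}


def td_features(signal: np.ndarray) -> TDFeatures:
    """Time-domain feature vector of a window.

    Sample SD uses the n-1 denominator; percentiles use linear
    interpolation; lag-1 autocorrelation is
    ``sum((x_t - m)(x_{t+1} - m)) / sum((x_t - m)^2)`` and is defined as 0
    for a constant signal.
    """
    x = np.asarray(signal, dtype=float)
    if len(x) < 2:
        raise ValueError(f"need >= 2 samples, got {len(x)}")
    m = x.mean()
    d = x - m
    denom = float(d @ d)
    lag1 = float(d[:-1] @ d[1:]) / denom if denom > 0 else 0.0
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    return TDFeatures(
        mean=float(m),
        sd=float(x.std(ddof=1)),
        p10=float(p10),
        p25=float(p25),
        p50=float(p50),
        p75=float(p75),
        p90=float(p90),
        lag1_autocorr=lag1,
    )


def power_spectrum(signal: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided periodogram of the demeaned signal.

    Normalized so that ``power.sum()`` equals the biased sample variance of
    the window exactly (Parseval); frequency resolution is ``fs / n``.
    """
    x = np.asarray(signal, dtype=float)
    if len(x) < 16:
        raise ValueError(f"need >= 16 samples, got {len(x)}")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite samples")
    n = len(x)
    d = x - x.mean()
    spec = np.abs(np.fft.rfft(d)) ** 2 / n**2
    # one-sided: double every bin that has a negative-frequency twin
    spec[1:] *= 2.0
    if n % 2 == 0:
        spec[-1] /= 2.0  # Nyquist bin is its own twin
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    return freqs, spec


def fd_features(
    signal: np.ndarray,
    fs: float,
    band: tuple[float, float] = DEFAULT_BAND,
) -> FDFeatures:
    """Frequency-domain feature vector of a window.

    ``mean_acc`` is the mean of the raw (not demeaned) signal; spectral
    quantities come from :func:`power_spectrum`.  The dominant frequency is
    the argmax bin (ties broken toward the lower frequency); band edges are
    inclusive; f10/f90 are the smallest frequencies at which cumulative
    spectral power reaches 10%/90% of the total.  For a zero-power
    (constant) window the ratio and percentile frequencies are defined as 0.
    """
    lo, hi = band
    if not (0 < lo < hi < fs / 2):
        raise ValueError(f"band {band} must satisfy 0 < lo < hi < fs/2")
    x = np.asarray(signal, dtype=float)
    freqs, spec = power_spectrum(x, fs)
    total = float(spec.sum())
    dom = float(freqs[int(np.argmax(spec))])  # argmax takes the first (lowest) max
    in_band = (freqs >= lo) & (freqs <= hi)
    band_power = float(spec[in_band].sum())
    if total > 0:
        cum = np.cumsum(spec)
        f10 = float(freqs[int(np.searchsorted(cum, 0.10 * total))])
        f90 = float(freqs[int(np.searchsorted(cum, 0.90 * total))])
        ratio = band_power / total
    else:
        f10 = f90 = 0.0
        ratio = 0.0
    return FDFeatures(
        mean_acc=float(x.mean()),
        total_power=total,
        dom_freq=dom,
        band_power=band_power,
        band_ratio=float(ratio),
        f10=f10,
        f90=f90,
    )


def extract_table(
    windows: list[Window],
    feature_set: str,
    channel: str = "vm",
    band: tuple[float, float] = DEFAULT_BAND,
) -> pd.DataFrame:
    """Feature table with one row per window.

    ``feature_set`` is ``"TD"`` or ``"FD"``; ``channel`` selects which
    window channel features are computed on (default the vector magnitude).
    Rows are ordered deterministically by (subject, activity, device, window
    index).  The returned frame carries ``feature_set`` in ``df.attrs``.
    """
    if feature_set not in ("TD", "FD"):
        raise ValueError(f"feature_set must be 'TD' or 'FD', got {feature_set!r}")
    lengths = {len(w) for w in windows}
    if len(lengths) > 1:
        raise ValueError(f"mixed window lengths: {sorted(lengths)}")
    rows = []
    for w in sorted(windows, key=lambda w: (w.subject_id, w.label, w.device_id, w.index)):
        sig = getattr(w, channel)
        feats = (
            td_features(sig).as_dict()
            if feature_set == "TD"
            else fd_features(sig, w.fs, band).as_dict()
        )
        rows.append(
            {
                "subject_id": w.subject_id,
                "device_id": w.device_id,
                "activity": w.label,
                "window_index": w.index,
                **feats,
            }
        )
    cols = ["subject_id", "device_id", "activity", "window_index"] + list(
        TD_COLUMNS if feature_set == "TD" else FD_COLUMNS
    )
    df = pd.DataFrame(rows, columns=cols)
    df.attrs["feature_set"] = feature_set
    return df
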