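"""Core data types, CSV I/O, vector magnitude and windowing.

All acceleration is expressed in g (1 g = 9.81 m/s**2), time in seconds, and
windows are half-open intervals [start, end).  These conventions are shared by
every downstream stage (simulation, shaker comparison, feature extraction,
transfer evaluation).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Fine-grained activity vocabulary used for bout annotations.
FINE_LABELS = (
    "clean",
    "computer",
    "throw",
    "walk_2.0",
    "walk_3.5",
    "run_5.5",
    "run_7.5",
    "vacuum",
)

#: Coarse classification vocabulary: the two walking speeds collapse to
#: "walk" and the two running speeds to "run" at windowing time.
COARSE_LABELS = ("clean", "computer", "throw", "walk", "run", "vacuum")

_COARSE_MAP = {
    "walk_2.0": "walk",
    "walk_3.5": "walk",
    "run_5.5": "run",
    "run_7.5": "run",
}


def coarse_label(label: str) -> str:
    """Map a fine activity label (e.g. ``walk_2.0``) to its coarse class."""
    return _COARSE_MAP.get(label, label)


@dataclass(frozen=True)
class Bout:
    """An annotated activity interval within a recording.

    ``label`` is either a fine activity label from :data:`FINE_LABELS` or a
    shaker trial tag (e.g. ``shaker_240rpm``); ``start_s``/``end_s`` are
    seconds from the start of the recording, half-open.
    """

    label: str
    start_s: float
    end_s: float
    subject_id: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start_s < self.end_s):
            raise ValueError(
                f"bout {self.label!r}: need 0 <= start_s < end_s, "
                f"got [{self.start_s}, {self.end_s})"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class Recording:
    """A uniformly sampled triaxial acceleration series in g.

    Parameters
    ----------
    device_id : str
        Identifier of the (possibly simulated) monitor that produced the data.
    fs : float
        Sampling rate in Hz, > 0.
    x, y, z : ndarray
        Equal-length per-axis samples in g; must be finite.
    start_time : float
        Offset of the first sample in seconds (default 0).
    annotations : list of Bout
        Activity bouts, each fully contained in the recording.
    """

    device_id: str
    fs: float
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    start_time: float = 0.0
    annotations: list[Bout] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"fs must be > 0, got {self.fs}")
        n = len(self.x)
        if n < 1 or len(self.y) != n or len(self.z) != n:
            raise ValueError(
                "x, y, z must have identical length >= 1, got "
                f"({len(self.x)}, {len(self.y)}, {len(self.z)})"
            )
        for name, a in (("x", self.x), ("y", self.y), ("z", self.z)):
            if not np.all(np.isfinite(a)):
                raise ValueError(f"axis {name} contains non-finite samples")
        for b in self.annotations:
            if b.end_s > self.duration_s + 1e-9:
                raise ValueError(
                    f"bout {b.label!r} ends at {b.end_s}s, beyond recording "
                    f"duration {self.duration_s}s"
                )

    def __len__(self) -> int:
        return len(self.x)

    @property
    def duration_s(self) -> float:
        return len(self.x) / self.fs

    def slice_seconds(self, start_s: float, end_s: float) -> "Recording":
        """Return the sub-recording covering the half-open [start_s, end_s)."""
        i0 = int(round(start_s * self.fs))
        i1 = int(round(end_s * self.fs))
        if not (0 <= i0 < i1 <= len(self)):
            raise ValueError(f"slice [{start_s}, {end_s})s outside recording")
        return replace(
            self,
            x=self.x[i0:i1],
            y=self.y[i0:i1],
            z=self.z[i0:i1],
            start_time=self.start_time + start_s,
            annotations=[],
        )


@dataclass
class Window:
    """A fixed-duration segment of a recording used for feature extraction.

    Carries the per-axis samples plus the vector-magnitude channel, the
    subject, the coarse activity class, the device, and the window's index
    within its bout.  Windows within a bout never overlap.
    """

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    vm: np.ndarray
    subject_id: str
    label: str
    device_id: str
    index: int
    fs: float

    def __len__(self) -> int:
        return len(self.vm)


# ---------------------------------------------------------------------------
# CSV I/O
#
# On-disk signal format: header `x,y,z` or `t,x,y,z`, one sample per row,
# acceleration in g.  Annotation sidecar: `subject,label,start_s,end_s`.
# ---------------------------------------------------------------------------

def _annotation_path(path: str) -> str:
    root, _ = os.path.splitext(path)
    return root + ".annotations.csv"


def write_recording(recording: Recording, path: str) -> None:
    """Write a recording as a `x,y,z` CSV plus an annotation sidecar."""
    df = pd.DataFrame({"x": recording.x, "y": recording.y, "z": recording.z})
    df.to_csv(path, index=False, float_format="%.6f")
    if recording.annotations:
        ann = pd.DataFrame(
            [
                {
                    "subject": b.subject_id,
                    "label": b.label,
                    "start_s": b.start_s,
                    "end_s": b.end_s,
                }
                for b in recording.annotations
            ]
        )
        ann.to_csv(_annotation_path(path), index=False)


def read_recording(path: str, fs: float, device_id: str) -> Recording:
    """Read a signal CSV (header ``x,y,z`` or ``t,x,y,z``) into a Recording.

    An annotation sidecar ``<stem>.annotations.csv`` with columns
    ``subject,label,start_s,end_s`` is merged if present.  Malformed numeric
    fields raise with the offending 1-based file line number; a ``t`` column,
    if present, must be strictly increasing.
    """
    try:
        df = pd.read_csv(path, dtype=str, skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty file") from None
    if len(df) == 0:
        raise ValueError(f"{path}: no data rows")
    cols = [c.strip() for c in df.columns]
    if cols not in (["x", "y", "z"], ["t", "x", "y", "z"]):
        raise ValueError(
            f"{path}: expected header 'x,y,z' or 't,x,y,z', got {cols}"
        )
    df.columns = cols
    numeric = {}
    for c in cols:
        vals = pd.to_numeric(df[c], errors="coerce")
        bad = vals.index[vals.isna()]
        if len(bad):
            # +2: header line plus 1-based counting
            raise ValueError(
                f"{path}: malformed value {df[c].iloc[bad[0]]!r} in column "
                f"{c!r} at line {bad[0] + 2}"
            )
        numeric[c] = vals.to_numpy()
    start_time = 0.0
    if "t" in numeric:
        t = numeric["t"]
        if len(t) > 1 and np.any(np.diff(t) <= 0):
            k = int(np.argmax(np.diff(t) <= 0))
            raise ValueError(
                f"{path}: time column not strictly increasing at line {k + 3}"
            )
        start_time = float(t[0])
    annotations = []
    ann_path = _annotation_path(path)
    if os.path.exists(ann_path):
        ann = pd.read_csv(ann_path)
        for _, row in ann.iterrows():
            annotations.append(
                Bout(
                    label=str(row["label"]),
                    start_s=float(row["start_s"]),
                    end_s=float(row["end_s"]),
                    subject_id=str(row["subject"]),
                )
            )
    return Recording(
        device_id=device_id,
        fs=fs,
        x=numeric["x"],
        y=numeric["y"],
        z=numeric["z"],
        start_time=start_time,
        annotations=annotations,
    )


# ---------------------------------------------------------------------------
# Vector magnitude and windowing
# ---------------------------------------------------------------------------

def vector_magnitude(recording: Recording) -> np.ndarray:
    """Per-sample Euclidean norm sqrt(x**2 + y**2 + z**2), in g."""
    return np.sqrt(recording.x**2 + recording.y**2 + recording.z**2)


def make_windows(
    recording: Recording,
    window_s: float = 20.0,
    use_last_s: float = 60.0,
) -> list[Window]:
    """Cut non-overlapping feature windows from the tail of each bout.

    Per annotated bout, exactly ``floor(use_last_s / window_s)`` contiguous
    windows are taken from the final ``use_last_s`` seconds of the bout; a
    trailing remainder shorter than ``window_s`` is discarded.  Each window
    inherits the subject, the device, and the coarse activity class (walking
    and running speeds are merged at this point).

    Raises
    ------
    ValueError
        If a bout is shorter than ``use_last_s`` (named in the message).
    """
    if window_s <= 0 or use_last_s <= 0:
        raise ValueError("window_s and use_last_s must be > 0")
    vm = vector_magnitude(recording)
    windows: list[Window] = []
    for bout in recording.annotations:
        if bout.duration_s < use_last_s - 1e-9:
            raise ValueError(
                f"bout {bout.label!r} (subject {bout.subject_id!r}) lasts "
                f"{bout.duration_s:g}s, shorter than use_last_s={use_last_s:g}s"
            )
        n_win = int(use_last_s // window_s)
        tail_start = bout.end_s - use_last_s
        for k in range(n_win):
            w0 = tail_start + k * window_s
            i0 = int(round(w0 * recording.fs))
            i1 = i0 + int(round(window_s * recording.fs))
            windows.append(
                Window(
                    x=recording.x[i0:i1],
                    y=recording.y[i0:i1],
                    z=recording.z[i0:i1],
                    vm=vm[i0:i1],
                    subject_id=bout.subject_id,
                    label=coarse_label(bout.label),
                    device_id=recording.device_id,
                    index=k,
                    fs=recording.fs,
                )
            )
    return windows
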