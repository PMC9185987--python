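"""Segmental circumferential-strain summaries and the CURE dyssynchrony index.

Works on a 6-segment x n_frames matrix of Eulerian circumferential strain
(%) over one cardiac cycle, frame 0 = end diastole.  Strain is negative
during contraction, so a segment's "peak" is its most negative value.

Segments follow the mid-ventricular AHA circumferential order
anterior -> anteroseptal -> inferoseptal -> inferior -> inferolateral ->
anterolateral; input rows are reordered by label, not by position, so the
spatial Fourier transform in the CURE index sees a consistent circumference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

#: canonical circumferential order of the six mid-ventricular segments
SEGMENTS = (
    "anterior",
    "anteroseptal",
    "inferoseptal",
    "inferior",
    "inferolateral",
    "anterolateral",
)


class UndefinedCureError(ZeroDivisionError):
    """CURE is undefined: zero spatial power at every frame."""


@dataclass
class StrainTimeCourse:
    """Strain of the six mid-ventricular segments over one cardiac cycle."""

    segments: Sequence[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != 6:
            raise ValueError(
                f"expected a 6 x n_frames matrix, got shape {self.values.shape}")
        if self.values.shape[1] < 8:
            raise ValueError(
                f"need >= 8 frames, got {self.values.shape[1]}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("strain values must be finite")
        if sorted(self.segments) != sorted(SEGMENTS):
            raise ValueError(
                f"segment labels must be a permutation of {SEGMENTS}, "
                f"got {tuple(self.segments)}")
        order = [list(self.segments).index(s) for s in SEGMENTS]
        self.values = self.values[order]
        self.segments = list(SEGMENTS)

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


@dataclass
class StrainSummary:
    """Per-visit strain summary row."""

    segment_peaks: np.ndarray
    peak_composite: float
    global_strain: float
    systole_frame: int
    cure: float


def segment_peak_strain(tc: StrainTimeCourse) -> np.ndarray:
    """Most negative strain per segment over the cycle (canonical order)."""
    return tc.values.min(axis=1)


def composite_peak_strain(tc: StrainTimeCourse) -> float:
    """Mean of the six segmental peak strains (mean peak composite Ecc%)."""
    return float(segment_peak_strain(tc).mean())


def global_strain(tc: StrainTimeCourse) -> tuple[float, int]:
    """Across-segment mean strain at systole.

    Systole is the frame at which the mean over the six segments is most
    negative (earliest such frame on ties).  Returns ``(strain, frame)``.
    """
    mean_curve = tc.values.mean(axis=0)
    frame = int(np.argmin(mean_curve))
    return float(mean_curve[frame]), frame


def cure_index(tc: StrainTimeCourse, per_frame_mean: bool = False) -> float:
    """Circumferential uniformity ratio estimate (CURE), in [0, 1].

    At each frame the six segmental strains are Fourier-transformed around
    the circumference; ``S0`` is the squared magnitude of the zeroth spatial
    harmonic (uniform contraction) and ``S1`` the summed squared magnitude of
    the +/- first harmonics (a single dyssynchronous bulge).  CURE is the
    power ratio

        sum_t S0(t) / sum_t (S0(t) + S1(t)),

    1 for perfectly synchronous contraction and 0 for a pure zero-mean first
    harmonic.  With six samples, harmonics above the first alias; only
    orders 0 and 1 enter.

    ``per_frame_mean=True`` averages the per-frame ratio S0/(S0+S1) over the
    frames with nonzero power instead of taking the ratio of sums; both
    variants share the 0/1 anchors.
    """
    spectrum = np.fft.fft(tc.values, axis=0)
    s0 = np.abs(spectrum[0]) ** 2
    s1 = np.abs(spectrum[1]) ** 2 + np.abs(spectrum[5]) ** 2
    total = s0 + s1
    if not np.any(total > 0):
        raise UndefinedCureError(
            "all-zero strain field: S0 + S1 vanishes at every frame")
    if per_frame_mean:
        live = total > 0
        return float(np.mean(s0[live] / total[live]))
    return float(s0.sum() / total.sum())


def summarize_timecourse(tc: StrainTimeCourse) -> StrainSummary:
    """All strain summaries for one subject-visit."""
    peaks = segment_peak_strain(tc)
    gs, frame = global_strain(tc)
    return StrainSummary(
        segment_peaks=peaks,
        peak_composite=float(peaks.mean()),
        global_strain=gs,
        systole_frame=frame,
        cure=cure_index(tc),
    )
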