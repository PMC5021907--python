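"""Circumferential wall-stress slices: loading, peak finding, peak selection.

A stress slice is the wall stress sampled around the stent-graft perimeter at
one axial level, as (angle, stress) pairs.  Slices are ingested, never
computed — the fluid–structure simulation that produces them is upstream of
this package.  Peak identification replaces visual reading of solver colour
maps with an explicit, reproducible rule: circular moving-average smoothing
over a configurable angular window, then circular local maxima separated by
a configurable minimum angle, ranked by stress.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import circular_difference

__all__ = [
    "StressSlice",
    "StressPeak",
    "load_stress_slice",
    "stress_slice_from_arrays",
    "find_peaks",
    "peak_nearest",
    "write_peaks_csv",
]


@dataclass(frozen=True)
class StressSlice:
    """One axial level's circumferential stress profile.

    ``angles_deg`` strictly increasing in ``[0, 360)``; ``stress_mpa`` >= 0.
    """

    angles_deg: np.ndarray
    stress_mpa: np.ndarray
    level_id: str = ""

    def __post_init__(self) -> None:
        a = np.asarray(self.angles_deg, dtype=float)
        s = np.asarray(self.stress_mpa, dtype=float)
        if a.shape != s.shape or a.ndim != 1:
            raise ValueError("angles and stresses must be matching 1-D arrays")
        if len(a) < 8:
            raise ValueError(f"a stress slice needs >= 8 samples; got {len(a)}")
        if np.any(a < 0) or np.any(a >= 360):
            raise ValueError("angles must lie in [0, 360) after normalisation")
        if np.any(np.diff(a) <= 0):
            raise ValueError("angles must be strictly increasing (duplicates present)")
        if np.any(s < 0):
            bad = int(np.argmax(s < 0))
            raise ValueError(f"negative stress at sample {bad} (angle {a[bad]:.1f} deg)")
        object.__setattr__(self, "angles_deg", a)
        object.__setattr__(self, "stress_mpa", s)

    def __len__(self) -> int:
        return len(self.angles_deg)


@dataclass(frozen=True)
class StressPeak:
    angle_deg: float
    stress: float
    rank: int

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise ValueError("rank must be >= 1")


def stress_slice_from_arrays(
    angles_deg, stress_mpa, level_id: str = ""
) -> StressSlice:
    """Build a validated slice: angles reduced mod 360, samples sorted by angle."""
    a = np.asarray(angles_deg, dtype=float) % 360.0
    s = np.asarray(stress_mpa, dtype=float)
    order = np.argsort(a, kind="stable")
    a, s = a[order], s[order]
    if np.any(np.diff(a) == 0):
        i = int(np.argmax(np.diff(a) == 0))
        raise ValueError(f"duplicate angle {a[i]:.3f} deg after normalisation")
    return StressSlice(angles_deg=a, stress_mpa=s, level_id=level_id)


def load_stress_slice(path, level_id: str | None = None) -> StressSlice:
    """Load a 2-column CSV ``angle_deg,stress_mpa`` (one header line)."""
    df = pd.read_csv(path)
    required = {"angle_deg", "stress_mpa"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"stress CSV must have columns angle_deg,stress_mpa; got {list(df.columns)}"
        )
    neg = df.index[df["stress_mpa"] < 0]
    if len(neg):
        raise ValueError(f"negative stress in row {int(neg[0])} of {path}")
    return stress_slice_from_arrays(
        df["angle_deg"].to_numpy(),
        df["stress_mpa"].to_numpy(),
        level_id=level_id if level_id is not None else str(path),
    )


def _circular_smooth(slice_: StressSlice, window_deg: float) -> np.ndarray:
    """Moving average over +-window_deg/2, wrapping across the 0/360 seam."""
    if window_deg <= 0:
        return slice_.stress_mpa.copy()
    a = slice_.angles_deg
    s = slice_.stress_mpa
    half = window_deg / 2.0
    out = np.empty_like(s)
    for i in range(len(a)):
        d = np.abs(a - a[i])
        d = np.minimum(d, 360.0 - d)
        out[i] = s[d <= half].mean()
    return out


def _refine_peak(slice_: StressSlice, smoothed: np.ndarray, idx: int,
                 halfwidth_deg: float) -> float:
    """Sub-sample vertex of a local quadratic fit around sample ``idx``.

    Standard parabolic peak interpolation, done on signed angular offsets so
    it wraps cleanly across the 0/360 seam.  Unbiased for a symmetric bump;
    averages the noise over the whole fitting window instead of trusting a
    single argmax sample.
    """
    a = slice_.angles_deg
    d = (a - a[idx] + 180.0) % 360.0 - 180.0
    sel = np.abs(d) <= halfwidth_deg
    if sel.sum() < 3:
        return float(a[idx] % 360.0)
    coeffs = np.polyfit(d[sel], smoothed[sel], 2)
    if coeffs[0] >= 0:  # fit has no maximum; keep the sample angle
        return float(a[idx] % 360.0)
    vertex = float(np.clip(-coeffs[1] / (2.0 * coeffs[0]), -halfwidth_deg, halfwidth_deg))
    return float((a[idx] + vertex) % 360.0)


def find_peaks(
    slice_: StressSlice,
    smooth_window_deg: float = 10.0,
    min_separation_deg: float = 30.0,
    min_height_frac: float = 0.2,
) -> list[StressPeak]:
    """Detect circular local maxima of the smoothed profile.

    A sample is a candidate if it strictly exceeds at least one circular
    neighbour, is >= both, and rises at least ``min_height_frac`` of the
    smoothed profile's range above its minimum (suppressing noise ripple on
    the baseline); candidates are accepted greedily by descending stress,
    discarding any within ``min_separation_deg`` of an accepted peak, and
    each accepted peak's angle is refined by local parabolic interpolation
    of the smoothed profile.  Rank 1 is the global peak.  A constant profile
    has no strict maximum and yields an empty list.
    """
    if smooth_window_deg < 0:
        raise ValueError("smooth_window_deg must be >= 0")
    smoothed = _circular_smooth(slice_, smooth_window_deg)
    if np.ptp(smoothed) == 0:
        return []
    a = slice_.angles_deg
    left = np.roll(smoothed, 1)
    right = np.roll(smoothed, -1)
    cand = (smoothed >= left) & (smoothed >= right) & ((smoothed > left) | (smoothed > right))
    cand &= smoothed >= smoothed.min() + min_height_frac * np.ptp(smoothed)
    idx = np.nonzero(cand)[0]
    # order: descending stress, then lower angle for deterministic ties
    idx = idx[np.lexsort((a[idx], -smoothed[idx]))]
    accepted: list[int] = []
    for i in idx:
        if all(circular_difference(a[i], a[j]) >= min_separation_deg for j in accepted):
            accepted.append(int(i))
    # fit wider than the smoothing window so the vertex averages many
    # effectively independent samples, but never past the separation limit
    # (a neighbouring peak inside the window would bias the fit)
    halfwidth = max(min(3.0 * smooth_window_deg, min_separation_deg), 5.0)
    return [
        StressPeak(
            angle_deg=_refine_peak(slice_, smoothed, i, halfwidth),
            stress=float(slice_.stress_mpa[i]),
            rank=r + 1,
        )
        for r, i in enumerate(accepted)
    ]


def peak_nearest(peaks: list[StressPeak], reference_angle: float) -> StressPeak:
    """The peak closest (minimal circular difference) to ``reference_angle``.

    Mirrors the selection rule used when a slice shows several stress peaks
    but an endoleak has been verified at one position: the index is computed
    against the peak nearest that position.  Ties break to higher stress,
    then lower angle.
    """
    if not peaks:
        raise ValueError("peak_nearest requires a non-empty peak list")
    return min(
        peaks,
        key=lambda p: (
            circular_difference(p.angle_deg, reference_angle),
            -p.stress,
            p.angle_deg,
        ),
    )


def write_peaks_csv(peaks: list[StressPeak], path) -> None:
    pd.DataFrame(
        {
            "rank": [p.rank for p in peaks],
            "angle_deg": [p.angle_deg for p in peaks],
            "stress_mpa": [p.stress for p in peaks],
        }
    ).to_csv(path, index=False)
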