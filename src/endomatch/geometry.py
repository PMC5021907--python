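"""Angular positions about a centroid and the endoleak/wall-stress matching index.

All angles in this package follow a single convention: degrees in ``[0, 360)``,
measured from the +x image axis (rightward, increasing column), rotating
counterclockwise with the image row axis negated (rows increase downward, so a
point *above* a centroid — smaller row — lies at 90 deg).  The convention is
arbitrary but must be fixed package-wide: the matching index compares two
angles measured about the same centroid, and its denominator is a raw angle,
so the index is not invariant to the choice of reference axis.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from typing import Iterable

import pandas as pd

__all__ = [
    "AngularPosition",
    "MatchReport",
    "angle_to_centroid",
    "circular_difference",
    "matching_index",
    "round_half_away",
    "reports_to_frame",
    "write_reports_csv",
    "write_reports_json",
]


@dataclass(frozen=True)
class AngularPosition:
    """An angle in degrees in ``[0, 360)`` about a named reference centroid.

    Parameters
    ----------
    degrees : float
        Angle in ``[0, 360)``.
    reference : str
        Name of the centroid the angle is measured about, e.g. ``"SGC"`` for
        the whole stent-graft centroid or ``"branch"`` for a daughter-branch
        centroid.  The matching index refuses to compare angles measured
        about different references.
    """

    degrees: float
    reference: str = "SGC"

    def __post_init__(self) -> None:
        if not 0.0 <= self.degrees < 360.0:
            raise ValueError(
                f"AngularPosition.degrees must lie in [0, 360); got {self.degrees}"
            )


@dataclass(frozen=True)
class MatchReport:
    """One row of the position-concordance table for a single case.

    ``numerator_deg`` is the minimal circular difference actually used in the
    index, recorded so the angular disagreement is readable independently of
    the (reference-axis-dependent) percentage.
    """

    case_id: str
    angle_endoleak_deg: float
    angle_ws_deg: float
    matching_index_pct: float
    numerator_deg: float

    def __post_init__(self) -> None:
        if self.matching_index_pct < 0:
            raise ValueError("matching_index_pct must be >= 0")
        if not 0.0 <= self.numerator_deg <= 180.0:
            raise ValueError("numerator_deg must lie in [0, 180]")


def angle_to_centroid(
    point: tuple[float, float],
    centroid: tuple[float, float],
    reference: str = "SGC",
) -> AngularPosition:
    """Angle of the vector ``centroid -> point`` in image coordinates.

    ``point`` and ``centroid`` are ``(row, col)`` pairs.  A point one pixel to
    the right of the centroid is at 0 deg; one pixel above (smaller row) is at
    90 deg.

    Raises
    ------
    ValueError
        If ``point == centroid`` (the angle is undefined).
    """
    dr = point[0] - centroid[0]
    dc = point[1] - centroid[1]
    if dr == 0 and dc == 0:
        raise ValueError("angle undefined: point coincides with centroid")
    deg = math.degrees(math.atan2(-dr, dc)) % 360.0
    return AngularPosition(degrees=deg, reference=reference)


def circular_difference(a: float, b: float) -> float:
    """Minimal arc between two angles in degrees, in ``[0, 180]``.

    Inputs are reduced mod 360 first, so adding any multiple of 360 to either
    argument leaves the result unchanged.
    """
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


def matching_index(
    angle_endoleak: AngularPosition | float,
    angle_ws: AngularPosition | float,
) -> float:
    """Concordance index between an endoleak angle and a wall-stress-peak angle.

    Defined as ``100 * circular_difference(angle_endoleak, angle_ws) /
    angle_ws`` — the minimal wrap-around angular disagreement expressed as a
    percentage of the wall-stress-peak angle.  A value of 0 means the two
    positions coincide exactly; small values indicate close spatial agreement.

    Both angles must be measured about the same reference centroid.  The
    denominator is the raw wall-stress angle, so the index diverges as that
    angle approaches 0 deg; callers screening arbitrary scenes should also
    inspect the numerator (``circular_difference``), which is reference-free.

    Raises
    ------
    ValueError
        If ``angle_ws`` is 0 (undefined denominator) or the two angles carry
        different reference centroids.
    """
    if isinstance(angle_endoleak, AngularPosition) and isinstance(
        angle_ws, AngularPosition
    ):
        if angle_endoleak.reference != angle_ws.reference:
            raise ValueError(
                "matching_index requires both angles about the same centroid: "
                f"{angle_endoleak.reference!r} vs {angle_ws.reference!r}"
            )
    a = angle_endoleak.degrees if isinstance(angle_endoleak, AngularPosition) else float(angle_endoleak)
    w = angle_ws.degrees if isinstance(angle_ws, AngularPosition) else float(angle_ws)
    if w == 0:
        raise ValueError("matching_index undefined for a wall-stress angle of 0 deg")
    return 100.0 * circular_difference(a, w) / w


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round with ties going away from zero (reporting convention).

    Python's builtin ``round`` uses banker's rounding; printed tables in this
    field round halves away from zero.
    """
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


def build_report(
    case_id: str,
    angle_endoleak: AngularPosition | float,
    angle_ws: AngularPosition | float,
) -> MatchReport:
    """Assemble a :class:`MatchReport` from one angle pair."""
    a = angle_endoleak.degrees if isinstance(angle_endoleak, AngularPosition) else float(angle_endoleak)
    w = angle_ws.degrees if isinstance(angle_ws, AngularPosition) else float(angle_ws)
    return MatchReport(
        case_id=case_id,
        angle_endoleak_deg=a,
        angle_ws_deg=w,
        matching_index_pct=matching_index(angle_endoleak, angle_ws),
        numerator_deg=circular_difference(a, w),
    )


_REPORT_COLUMNS = [
    "case_id",
    "angle_endoleak_deg",
    "angle_ws_deg",
    "numerator_deg",
    "matching_index_pct",
]


def reports_to_frame(reports: Iterable[MatchReport]) -> pd.DataFrame:
    df = pd.DataFrame([asdict(r) for r in reports])
    return df[_REPORT_COLUMNS] if len(df) else pd.DataFrame(columns=_REPORT_COLUMNS)


def write_reports_csv(reports: Iterable[MatchReport], path) -> None:
    reports_to_frame(reports).to_csv(path, index=False)


def write_reports_json(reports: Iterable[MatchReport], path) -> None:
    with open(path, "w") as fh:
        json.dump([asdict(r) for r in reports], fh, indent=2)
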