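"""Visit-to-visit retinopathy screening by vessel-pixel count.

Segmenting two registered fundus images of the same eye taken at different
visits yields two vessel masks whose pixel counts can be compared.  Vessel
growth (swelling, neovascularization) is a sign of diabetic retinopathy;
vessel shrinkage is a sign of hypertensive retinopathy.  The rule here flags
a relative count change beyond a configurable threshold (default 5%) — a
screening placeholder, not a clinically validated cut-off.  Registration of
the two images is assumed to have happened upstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["VisitRecord", "ScreeningVerdict", "vessel_pixel_count", "compare_visits"]


@dataclass(frozen=True)
class VisitRecord:
    visit_id: str
    vessel_pixels: int
    total_pixels: int
    date: str | None = None  # ISO date

    def __post_init__(self) -> None:
        if not 0 <= self.vessel_pixels <= self.total_pixels:
            raise ValueError("vessel_pixels must lie in [0, total_pixels]")


@dataclass(frozen=True)
class ScreeningVerdict:
    status: str  # stable | diabetic-suspect | hypertensive-suspect
    relative_change: float


def vessel_pixel_count(mask: np.ndarray) -> tuple[int, int]:
    """(vessel pixels, total pixels) of a binary mask."""
    mask = np.asarray(mask)
    if not np.isin(np.unique(mask), (0, 1)).all():
        raise ValueError("mask is not binary {0,1}")
    return int(mask.sum()), int(mask.size)


def compare_visits(
    prev: VisitRecord, curr: VisitRecord, threshold: float = 0.05
) -> ScreeningVerdict:
    """Classify the relative vessel-count change between two visits.

    change = (curr - prev) / prev; above +threshold the verdict is
    diabetic-suspect (vessel growth), below -threshold hypertensive-suspect
    (vessel shrinkage), otherwise stable.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if prev.total_pixels != curr.total_pixels:
        raise ValueError("visits must be registered to the same pixel grid")
    if prev.vessel_pixels == 0:
        raise ValueError("previous visit has zero vessel pixels")
    change = (curr.vessel_pixels - prev.vessel_pixels) / prev.vessel_pixels
    if change > threshold:
        status = "diabetic-suspect"
    elif change < -threshold:
        status = "hypertensive-suspect"
    else:
        status = "stable"
    return ScreeningVerdict(status, change)
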