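"""Vascular morphometry scores for zebrafish trunk annotations.

These operations encode explicit manual-scoring rules on structured
annotations rather than on raw images:

* thoracic duct (TD) extent as a percentage of a 10-somite trunk span, with
  overlapping annotation spans merged first;
* TD defect classes binned on that percentage;
* parachordal lymphangioblast (PL) presence counted over 10 somite segments;
* arterial vs venous intersegmental vessel (aISV/vISV) identity proportions
  from DA/PCV connectivity labels;
* secondary-sprout connection time from protrusion-length tracks sampled
  every 20 min, using the strict 15-um protrusion criterion;
* filopodia density (protrusions strictly longer than 5 um, per 40 um of
  contour);
* cortical actin enrichment as the mean-intensity ratio of a cell's
  peripheral band to its interior.

All thresholds are strict ("longer than"), matching how the scores were
defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_erosion

N_SOMITES = 10

#: TD defect classes: absent, <20 % visible, intermediate, >=50 %.
TD_CLASSES = ("absent", "<20%", "20-50%", ">=50%")


@dataclass
class TrunkAnnotation:
    """Manual annotation of one embryo's 10-somite trunk segment."""

    trunk_span: tuple[float, float]  # (start, end) um
    td_spans: list[tuple[float, float]] = field(default_factory=list)
    pl_flags: list[bool] = field(default_factory=lambda: [False] * N_SOMITES)
    isv_labels: list[str] = field(default_factory=list)  # "DA" or "PCV"

    def __post_init__(self) -> None:
        lo, hi = self.trunk_span
        if hi <= lo:
            raise ValueError("trunk span must have positive length")
        if len(self.pl_flags) != N_SOMITES:
            raise ValueError(f"need exactly {N_SOMITES} PL flags")
        for s, e in self.td_spans:
            if s < lo or e > hi:
                raise ValueError(f"TD span ({s}, {e}) outside trunk {self.trunk_span}")


@dataclass
class ProtrusionTrack:
    """Protrusion length (um) per time frame, uniformly sampled."""

    lengths: np.ndarray
    frame_interval: float = 20.0  # min
    contact_frame: int | None = None

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=float)
        if (self.lengths < 0).any():
            raise ValueError("protrusion lengths must be >= 0")


def merge_spans(spans: list[tuple[float, float]]) -> list[tuple[float, float]]:
    """Merge overlapping or touching intervals; returns sorted disjoint spans."""
    if not spans:
        return []
    ordered = sorted((min(s, e), max(s, e)) for s, e in spans)
    merged = [list(ordered[0])]
    for s, e in ordered[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def td_extent(annotation: TrunkAnnotation) -> float:
    """Visible TD length as % of the trunk span, after merging spans."""
    lo, hi = annotation.trunk_span
    total = sum(e - s for s, e in merge_spans(annotation.td_spans))
    return 100.0 * total / (hi - lo)


def classify_td_defect(percent: float) -> str:
    """Bin a TD extent percentage into defect classes.

    0 -> "absent"; (0, 20) -> "<20%"; [20, 50) -> "20-50%"; [50, 100] -> ">=50%".
    """
    if not 0 <= percent <= 100:
        raise ValueError(f"TD percentage must be in [0, 100], got {percent}")
    if percent == 0:
        return TD_CLASSES[0]
    if percent < 20:
        return TD_CLASSES[1]
    if percent < 50:
        return TD_CLASSES[2]
    return TD_CLASSES[3]


def count_pl(annotation: TrunkAnnotation) -> tuple[int, float]:
    """(number of somite segments with a PL, proportion of the 10 segments)."""
    count = int(sum(bool(f) for f in annotation.pl_flags))
    return count, count / N_SOMITES


def isv_proportions(annotation: TrunkAnnotation) -> tuple[float, float]:
    """(percent aISV, percent vISV) from DA/PCV connectivity labels."""
    labels = annotation.isv_labels
    if not labels:
        raise ValueError("no ISV labels")
    bad = set(labels) - {"DA", "PCV"}
    if bad:
        raise ValueError(f"unknown ISV connectivity labels: {sorted(bad)}")
    n_v = sum(1 for lab in labels if lab == "PCV")
    pct_v = 100.0 * n_v / len(labels)
    return 100.0 - pct_v, pct_v


def sprout_connection_time(
    track: ProtrusionTrack,
    threshold: float = 15.0,
    frame_interval: float | None = None,
) -> float | str:
    """Minutes between the first protrusion > threshold and aISV contact.

    Returns ``"no sprout"`` if the protrusion never strictly exceeds the
    threshold, ``"no contact"`` if no contact frame is recorded.  Contact
    before the first threshold crossing is an annotation error.
    """
    interval = track.frame_interval if frame_interval is None else frame_interval
    above = np.nonzero(track.lengths > threshold)[0]
    if len(above) == 0:
        return "no sprout"
    first = int(above[0])
    if track.contact_frame is None:
        return "no contact"
    if track.contact_frame < first:
        raise ValueError(
            f"contact frame {track.contact_frame} precedes first threshold "
            f"crossing at frame {first}"
        )
    return (track.contact_frame - first) * interval


def filopodia_density(
    lengths: np.ndarray | list[float],
    contour_length: float,
    min_length: float = 5.0,
    window: float = 40.0,
) -> float:
    """Filopodia (strictly longer than ``min_length`` um) per ``window`` um."""
    if contour_length <= 0:
        raise ValueError("contour_length must be > 0")
    lengths = np.asarray(lengths, dtype=float)
    count = int((lengths > min_length).sum())
    return count * window / contour_length


def cortical_enrichment(
    image: np.ndarray,
    cell_mask: np.ndarray,
    cortex_width: int = 3,
) -> dict[str, float]:
    """Cortical F-actin enrichment of one cell.

    The cortex band is the mask minus its erosion by a disk of radius
    ``cortex_width``; the interior is the erosion.  Returns both orientations
    — ``cortex_over_middle`` (the reported enrichment; > 1 means cortical
    accumulation) and its reciprocal ``middle_over_cortex``.
    """
    image = np.asarray(image, dtype=float)
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if image.shape != cell_mask.shape:
        raise ValueError("image and cell_mask must share shape")
    yy, xx = np.mgrid[-cortex_width:cortex_width + 1, -cortex_width:cortex_width + 1]
    selem = xx**2 + yy**2 <= cortex_width**2
    interior = binary_erosion(cell_mask, structure=selem)
    if not interior.any():
        raise ValueError("erosion by cortex_width empties the cell interior")
    cortex = cell_mask & ~interior
    mid = float(image[interior].mean())
    if mid == 0:
        raise ValueError("interior mean intensity is zero; ratio undefined")
    ratio = float(image[cortex].mean()) / mid
    return {"cortex_over_middle": ratio, "middle_over_cortex": 1.0 / ratio}
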