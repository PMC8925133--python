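"""CTR geometry: ID, MRD and MLD line extraction from lung/heart masks.

The cardiothoracic ratio is the maximal horizontal cardiac diameter divided by
the maximal internal thoracic diameter (ID) on a PA chest film; CTR > 0.5
suggests cardiomegaly.  Conventions used here, chosen to match standard
radiological practice and to make the arithmetic exactly checkable:

* The ID line lies on a single row — the row where the cleaned lung-field
  union is widest (ties resolved to the uppermost row).  Its length is the
  inclusive pixel count ``right - left + 1``.
* The midline is the midpoint of the ID endpoints (may be half-integral).
* MRD and MLD are measured on the rows where the heart reaches its extreme
  columns, which may differ; each runs from the midline to the *outer edge*
  of the extreme pixel, i.e. ``MRD = midline - heart_min_col + 0.5`` and
  ``MLD = heart_max_col - midline + 0.5``.  Consequently
  ``MRD + MLD = heart_max_col - heart_min_col + 1`` — the heart's global
  horizontal extent — holds exactly whatever the midline position, and the
  CTR never depends on the MRD/MLD split.
* No sub-pixel refinement: quantisation error on the CTR is bounded by about
  2/ID and is accepted as such.

A heart lying entirely on one side of the midline produces a negative MRD or
MLD; the measurement is flagged pathological but the CTR, which depends only
on the global extent, is still reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ContractError, MeasurementFailure

__all__ = ["CTRMeasurement", "IoUReport", "clean_mask", "measure_ctr", "iou"]


@dataclass(frozen=True)
class CTRMeasurement:
    """The extracted ID/MRD/MLD lines and the resulting CTR, in pixels."""

    id_length: float
    id_row: int
    id_left_x: int
    id_right_x: int
    midline_x: float
    mrd_length: float
    mrd_row: int
    mld_length: float
    mld_row: int
    cardiac_width: float
    ctr: float
    pathological: bool = False

    def as_dict(self) -> dict:
        return {
            "id_length": self.id_length,
            "id_row": self.id_row,
            "id_left_x": self.id_left_x,
            "id_right_x": self.id_right_x,
            "midline_x": self.midline_x,
            "mrd_length": self.mrd_length,
            "mrd_row": self.mrd_row,
            "mld_length": self.mld_length,
            "mld_row": self.mld_row,
            "cardiac_width": self.cardiac_width,
            "ctr": self.ctr,
            "pathological": self.pathological,
        }


@dataclass(frozen=True)
class IoUReport:
    lung_iou: float
    heart_iou: float


def clean_mask(
    mask: np.ndarray,
    min_area_frac: float = 0.005,
    keep_components: int = 2,
) -> np.ndarray:
    """Fill holes and keep the ``keep_components`` largest components.

    Components smaller than ``min_area_frac`` of the frame are dropped even if
    ranked.  An empty result is legal — downstream grading reads it as a
    segmentation failure (*poor*), so no error is raised here.
    """
    m = np.asarray(mask) > 0
    if not m.any():
        return np.zeros_like(m)
    m = ndimage.binary_fill_holes(m)
    labels, n = ndimage.label(m)
    if n == 0:
        return np.zeros_like(m)
    areas = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    order = np.argsort(areas)[::-1][:keep_components]
    min_area = min_area_frac * m.size
    keep = [int(i) + 1 for i in order if areas[i] >= min_area]
    if not keep:
        return np.zeros_like(m)
    return np.isin(labels, keep)


def _row_extent(mask: np.ndarray) -> tuple[int, int, int]:
    """(row, left, right) of the single widest row; ties -> uppermost row."""
    any_row = mask.any(axis=1)
    rows = np.flatnonzero(any_row)
    cols = np.arange(mask.shape[1])
    left = np.where(mask[rows], cols, mask.shape[1]).min(axis=1)
    right = np.where(mask[rows], cols, -1).max(axis=1)
    widths = right - left + 1
    k = int(np.argmax(widths))  # argmax returns the first (uppermost) maximum
    return int(rows[k]), int(left[k]), int(right[k])


def measure_ctr(lung_mask: np.ndarray, heart_mask: np.ndarray) -> CTRMeasurement:
    """Measure ID, MRD, MLD and the CTR from a cleaned lung/heart mask pair.

    Raises :class:`MeasurementFailure` when either mask is empty; callers that
    grade results map this to the *poor* grade.
    """
    lung = np.asarray(lung_mask) > 0
    heart = np.asarray(heart_mask) > 0
    if lung.shape != heart.shape:
        raise ContractError(f"mask shapes differ: {lung.shape} vs {heart.shape}")
    if not lung.any():
        raise MeasurementFailure("empty lung mask")
    if not heart.any():
        raise MeasurementFailure("empty heart mask")

    id_row, id_left, id_right = _row_extent(lung)
    id_length = float(id_right - id_left + 1)
    midline_x = (id_left + id_right) / 2.0

    heart_cols = np.flatnonzero(heart.any(axis=0))
    h_min, h_max = int(heart_cols[0]), int(heart_cols[-1])
    mrd_row = int(np.flatnonzero(heart[:, h_min])[0])
    mld_row = int(np.flatnonzero(heart[:, h_max])[0])
    # Half-pixel terms measure to the outer edge of the extreme pixel so that
    # MRD + MLD telescopes to the inclusive extent h_max - h_min + 1 exactly.
    mrd = midline_x - h_min + 0.5
    mld = h_max - midline_x + 0.5
    cardiac_width = float(h_max - h_min + 1)

    return CTRMeasurement(
        id_length=id_length,
        id_row=id_row,
        id_left_x=id_left,
        id_right_x=id_right,
        midline_x=midline_x,
        mrd_length=float(mrd),
        mrd_row=mrd_row,
        mld_length=float(mld),
        mld_row=mld_row,
        cardiac_width=cardiac_width,
        ctr=cardiac_width / id_length,
        pathological=bool(mrd <= 0 or mld <= 0),
    )


def iou(predicted: np.ndarray, truth: np.ndarray) -> float:
    """Intersection over union of two binary rasters.

    Both empty -> 1 (perfect agreement on absence); exactly one empty -> 0.
    """
    p = np.asarray(predicted) > 0
    t = np.asarray(truth) > 0
    if p.shape != t.shape:
        raise ContractError(f"mask shapes differ: {p.shape} vs {t.shape}")
    union = np.count_nonzero(p | t)
    if union == 0:
        return 1.0
    return np.count_nonzero(p & t) / union
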