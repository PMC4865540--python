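"""Threshold-based metabolic tumour volume segmentation.

The primary method labels every voxel with SUV >= 2.5 (inclusive) that is not
covered by the physiological-uptake edit mask, joins voxels into lesions by
3-D 26-connectivity, and reports per-lesion and total quantities:

* MTV  — metabolic tumour volume, cm^3 (voxel count x voxel volume),
* SUVmean — voxel-weighted mean SUV over all labelled voxels,
* SUVmax  — maximum labelled SUV,
* TLG  — total lesion glycolysis = MTV x SUVmean (cm^3 · SUV).

An alternative per-lesion relative mode re-thresholds each lesion at a fixed
fraction (default 41 %) of that lesion's SUVmax after detection at the fixed
threshold; it is provided for method comparison and is not the primary mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist

from .volume import SuvVolume

__all__ = [
    "LesionStats",
    "SegmentationResult",
    "NoLesionsError",
    "segment_mtv",
    "segment_mtv_pct",
    "max_tumour_dimension",
]

#: 26-neighbourhood structuring element for 3-D connected components.
_STRUCTURE_26 = np.ones((3, 3, 3), dtype=bool)


class NoLesionsError(ValueError):
    """Raised when an operation requires at least one segmented lesion."""


@dataclass(frozen=True)
class LesionStats:
    """Per-lesion quantities (volume in cm^3, SUVs unitless)."""

    label: int
    voxel_count: int
    volume_cm3: float
    suv_mean: float
    suv_max: float

    @property
    def tlg(self) -> float:
        """Lesion glycolysis, volume x mean SUV."""
        return self.volume_cm3 * self.suv_mean


@dataclass
class SegmentationResult:
    """Labelled lesions plus totals over all labelled voxels.

    Invariants (held by construction): ``mtv_total`` is the sum of lesion
    volumes, ``tlg_total = mtv_total * suv_mean_total`` exactly, and
    ``suv_max_total`` is the maximum over lesions.  A result with no lesions
    has all totals equal to 0.
    """

    label_map: np.ndarray
    lesions: list[LesionStats]
    mtv_total: float
    suv_mean_total: float
    suv_max_total: float
    tlg_total: float
    threshold_used: float
    fraction: float | None = None
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    meta: dict = field(default_factory=dict)

    @property
    def n_lesions(self) -> int:
        return len(self.lesions)

    def to_dict(self) -> dict:
        """JSON-serialisable summary (label map excluded; store it as NIfTI)."""
        return {
            "threshold_used": self.threshold_used,
            "fraction": self.fraction,
            "spacing_mm": list(self.spacing),
            "mtv_total_cm3": self.mtv_total,
            "suv_mean_total": self.suv_mean_total,
            "suv_max_total": self.suv_max_total,
            "tlg_total": self.tlg_total,
            "lesions": [
                {
                    "label": l.label,
                    "voxel_count": l.voxel_count,
                    "volume_cm3": l.volume_cm3,
                    "suv_mean": l.suv_mean,
                    "suv_max": l.suv_max,
                }
                for l in self.lesions
            ],
        }


def _candidate_mask(vol: SuvVolume, threshold: float) -> np.ndarray:
    if vol.values.size == 0:
        raise ValueError("cannot segment an empty volume")
    mask = vol.values >= threshold
    if vol.edit_mask is not None:
        mask &= ~vol.edit_mask
    return mask


def _result_from_labels(
    vol: SuvVolume,
    label_map: np.ndarray,
    threshold: float,
    min_voxels: int,
    fraction: float | None = None,
) -> SegmentationResult:
    """Build a SegmentationResult from a labelled map, dropping small lesions
    and relabelling the survivors 1..k in ascending original-label order."""
    labels = np.unique(label_map)
    labels = labels[labels > 0]
    voxvol = vol.voxel_volume_cm3

    keep: list[int] = []
    counts: dict[int, int] = {}
    for lab in labels:
        n = int(np.count_nonzero(label_map == lab))
        if n >= min_voxels:
            keep.append(int(lab))
            counts[int(lab)] = n

    out_map = np.zeros_like(label_map, dtype=np.int32)
    lesions: list[LesionStats] = []
    for new_lab, lab in enumerate(keep, start=1):
        sel = label_map == lab
        out_map[sel] = new_lab
        vals = vol.values[sel]
        lesions.append(
            LesionStats(
                label=new_lab,
                voxel_count=counts[lab],
                volume_cm3=counts[lab] * voxvol,
                suv_mean=float(vals.mean()),
                suv_max=float(vals.max()),
            )
        )

    if lesions:
        all_vals = vol.values[out_map > 0]
        mtv_total = float(sum(l.volume_cm3 for l in lesions))
        suv_mean_total = float(all_vals.mean())
        suv_max_total = float(max(l.suv_max for l in lesions))
    else:
        mtv_total = suv_mean_total = suv_max_total = 0.0
    tlg_total = mtv_total * suv_mean_total

    return SegmentationResult(
        label_map=out_map,
        lesions=lesions,
        mtv_total=mtv_total,
        suv_mean_total=suv_mean_total,
        suv_max_total=suv_max_total,
        tlg_total=tlg_total,
        threshold_used=float(threshold),
        fraction=fraction,
        spacing=vol.spacing,
    )


def segment_mtv(
    vol: SuvVolume, threshold: float = 2.5, min_voxels: int = 1
) -> SegmentationResult:
    """Segment lesions at a fixed SUV threshold (inclusive).

    Voxels with ``SUV >= threshold`` outside the edit mask are joined by
    26-connectivity; components smaller than ``min_voxels`` are discarded.
    A volume where every candidate voxel is excluded yields a valid result
    with ``mtv_total == 0`` (not an error).

    Parameters
    ----------
    vol : SuvVolume
    threshold : float
        SUV cut; the clinical default is 2.5.  Must be positive.
    min_voxels : int
        Minimum component size retained; default 1 (no size filter).
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    mask = _candidate_mask(vol, threshold)
    label_map, _ = ndimage.label(mask, structure=_STRUCTURE_26)
    return _result_from_labels(vol, label_map, threshold, min_voxels)


def segment_mtv_pct(
    vol: SuvVolume,
    fraction: float = 0.41,
    detect_threshold: float = 2.5,
    min_voxels: int = 1,
) -> SegmentationResult:
    """Per-lesion relative threshold segmentation (fraction of lesion SUVmax).

    Lesions are first located at ``detect_threshold`` exactly as in
    :func:`segment_mtv`; each lesion is then re-thresholded at
    ``fraction * lesion SUVmax``, keeping only its voxels at or above that
    per-lesion cut.  Lesion identity (label) is preserved through the
    re-thresholding, so a lesion can only shrink — the retained volume is
    monotone non-increasing in ``fraction``.
    """
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must lie in (0, 1), got {fraction}")
    mask = _candidate_mask(vol, detect_threshold)
    label_map, n = ndimage.label(mask, structure=_STRUCTURE_26)
    refined = np.zeros_like(label_map)
    for lab in range(1, n + 1):
        sel = label_map == lab
        lesion_max = vol.values[sel].max()
        refined[sel & (vol.values >= fraction * lesion_max)] = lab
    return _result_from_labels(vol, refined, detect_threshold, min_voxels, fraction=fraction)


def max_tumour_dimension(
    seg: SegmentationResult, spacing: tuple[float, float, float] | None = None
) -> float:
    """Maximum tumour dimension (MTD) in cm.

    The largest Euclidean distance between any two voxel centres belonging to
    the same lesion, maximised over lesions.  A single-voxel lesion has
    MTD 0.  Raises :class:`NoLesionsError` when the segmentation is empty.
    """
    if not seg.lesions:
        raise NoLesionsError("MTD is undefined for a segmentation with no lesions")
    sp = np.asarray(spacing if spacing is not None else seg.spacing, dtype=float)
    best = 0.0
    for lesion in seg.lesions:
        coords = np.argwhere(seg.label_map == lesion.label) * sp  # mm
        if len(coords) < 2:
            continue
        best = max(best, _diameter_mm(coords))
    return best / 10.0  # mm -> cm


def _diameter_mm(points: np.ndarray) -> float:
    """Largest pairwise distance; convex hull prunes large point sets."""
    if len(points) > 2000:
        try:
            points = points[ConvexHull(points).vertices]
        except QhullError:
            pass  # degenerate (coplanar/collinear) blobs: fall through to pdist
    return float(pdist(points).max())
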