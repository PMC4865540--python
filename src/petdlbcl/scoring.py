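"""Interim-PET response scoring.

Deauville five-point scale against mediastinal blood pool and liver
references, percentage-change metrics versus baseline, and the response
categories used to steer therapy:

* CMR (complete metabolic response): Deauville 1-3,
* PMR (partial metabolic response): Deauville 4-5 with improvement,
* NR/progression: Deauville 4-5 without improvement.

With T the residual-tumour SUVmax, M the mediastinal SUVmax and L the liver
SUVmax, the scale is: DS 1 no residual uptake; DS 2 T <= M; DS 3 M < T <= L;
DS 4 L < T < 3L; DS 5 T >= 3L.  Boundaries at a reference value resolve to
the lower score; the tripled-liver rule for DS 5 is inclusive.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .segmentation import SegmentationResult
from .volume import SuvVolume

__all__ = [
    "ReferenceRegions",
    "ResponseCategory",
    "ResponseAssessment",
    "assign_deauville",
    "percent_change",
    "classify_response",
    "assess_response",
]


@dataclass(frozen=True)
class ReferenceRegions:
    """Liver and mediastinal blood-pool reference uptake (SUV)."""

    liver_suv_max: float
    liver_suv_mean: float
    mediastinum_suv_max: float
    mediastinum_suv_mean: float

    def __post_init__(self) -> None:
        for name in (
            "liver_suv_max",
            "liver_suv_mean",
            "mediastinum_suv_max",
            "mediastinum_suv_mean",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def from_masks(
        cls,
        vol: SuvVolume,
        liver_mask: np.ndarray,
        mediastinum_mask: np.ndarray,
        tumour_labels: np.ndarray | None = None,
    ) -> "ReferenceRegions":
        """Measure references from boolean masks over ``vol``.

        The liver mask must not intersect segmented tumour (pass the label
        map as ``tumour_labels`` to enforce this).
        """
        liver = np.asarray(liver_mask, bool)
        medi = np.asarray(mediastinum_mask, bool)
        if liver.shape != vol.shape or medi.shape != vol.shape:
            raise ValueError("reference masks must match the volume shape")
        if not liver.any() or not medi.any():
            raise ValueError("reference masks must be non-empty")
        if tumour_labels is not None and bool((np.asarray(tumour_labels) > 0)[liver].any()):
            raise ValueError("liver reference mask overlaps segmented tumour")
        return cls(
            liver_suv_max=float(vol.values[liver].max()),
            liver_suv_mean=float(vol.values[liver].mean()),
            mediastinum_suv_max=float(vol.values[medi].max()),
            mediastinum_suv_mean=float(vol.values[medi].mean()),
        )


class ResponseCategory(str, enum.Enum):
    CMR = "CMR"
    PMR = "PMR"
    NR_PROGRESSION = "NR_progression"


@dataclass(frozen=True)
class ResponseAssessment:
    """Deauville score, percentage changes and the derived category."""

    deauville: int
    delta_suvmax: float
    delta_mtv: float
    delta_tlg: float
    category: ResponseCategory

    def to_dict(self) -> dict:
        return {
            "deauville": self.deauville,
            "delta_suvmax_pct": self.delta_suvmax,
            "delta_mtv_pct": self.delta_mtv,
            "delta_tlg_pct": self.delta_tlg,
            "category": self.category.value,
        }


def assign_deauville(interim: SegmentationResult, refs: ReferenceRegions) -> int:
    """Score an interim segmentation on the Deauville 1-5 scale."""
    if interim.mtv_total == 0:
        return 1
    if refs.liver_suv_max == 0:
        raise ValueError("residual uptake present but liver reference SUVmax is 0: un-scorable")
    t = interim.suv_max_total
    if t <= refs.mediastinum_suv_max:
        return 2
    if t <= refs.liver_suv_max:
        return 3
    if t < 3.0 * refs.liver_suv_max:
        return 4
    return 5


def percent_change(pre_value: float, post_value: float) -> float:
    """Percentage change ``100 * (post - pre) / pre``; reductions are negative."""
    if pre_value <= 0:
        raise ValueError(f"baseline value must be positive, got {pre_value}")
    # divide before scaling so complete resolution is exactly -100 %
    return 100.0 * ((post_value - pre_value) / pre_value)


def classify_response(ds: int, improved: bool) -> ResponseCategory:
    """Map a Deauville score and an improvement flag to a response category."""
    if ds not in (1, 2, 3, 4, 5):
        raise ValueError(f"Deauville score must be 1-5, got {ds}")
    if ds <= 3:
        return ResponseCategory.CMR
    return ResponseCategory.PMR if improved else ResponseCategory.NR_PROGRESSION


def assess_response(
    baseline: SegmentationResult,
    interim: SegmentationResult,
    refs: ReferenceRegions,
) -> ResponseAssessment:
    """Full interim assessment: Deauville score, deltas and category.

    "Improvement" (separating PMR from no response among Deauville 4-5) is
    operationalised as any reduction in SUVmax versus baseline
    (``delta_suvmax < 0``).
    """
    if baseline.mtv_total <= 0:
        raise ValueError("baseline segmentation has no assessable disease")
    ds = assign_deauville(interim, refs)
    d_suv = percent_change(baseline.suv_max_total, interim.suv_max_total)
    d_mtv = percent_change(baseline.mtv_total, interim.mtv_total)
    d_tlg = percent_change(baseline.tlg_total, interim.tlg_total)
    return ResponseAssessment(
        deauville=ds,
        delta_suvmax=d_suv,
        delta_mtv=d_mtv,
        delta_tlg=d_tlg,
        category=classify_response(ds, improved=d_suv < 0),
    )
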