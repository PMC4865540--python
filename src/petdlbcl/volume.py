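"""SUV image volumes.

The standardised uptake value (SUV, body-weight convention, unitless g/mL)
normalises a measured activity concentration by the injected dose per body
weight::

    SUV = C [kBq/mL] * weight [kg] / dose [MBq]

All volumes carry their voxel spacing in millimetres; derived volumes are
reported in cm^3 downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["SuvVolume", "compute_suv"]


@dataclass
class SuvVolume:
    """A 3-D SUV grid with voxel spacing and an optional exclusion mask.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Voxel SUVs; must be non-negative.
    spacing : tuple of 3 floats
        Voxel edge lengths in mm, all positive.
    edit_mask : ndarray of bool, optional
        ``True`` marks voxels excluded from segmentation as physiological
        uptake (e.g. myocardium, bladder).  Same shape as ``values``.
    meta : dict
        Free-form acquisition metadata (e.g. ``weight_kg``, ``dose_mbq``).
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    edit_mask: np.ndarray | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"values must be 3-D, got ndim={self.values.ndim}")
        if self.values.size and float(self.values.min()) < 0:
            raise ValueError("SUV values must be non-negative")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be 3 positive lengths in mm, got {self.spacing}")
        self.spacing = spacing
        if self.edit_mask is not None:
            self.edit_mask = np.asarray(self.edit_mask, dtype=bool)
            if self.edit_mask.shape != self.values.shape:
                raise ValueError(
                    f"edit_mask shape {self.edit_mask.shape} != values shape {self.values.shape}"
                )

    @property
    def voxel_volume_cm3(self) -> float:
        """Volume of one voxel in cm^3 (mm^3 / 1000)."""
        return float(np.prod(self.spacing)) / 1000.0

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape


def compute_suv(
    activity_kbq_ml: np.ndarray,
    dose_mbq: float,
    weight_kg: float,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    edit_mask: np.ndarray | None = None,
) -> SuvVolume:
    """Convert an activity-concentration grid to a body-weight SUV volume.

    Parameters
    ----------
    activity_kbq_ml : ndarray
        Decay-corrected activity concentration in kBq/mL.
    dose_mbq : float
        Injected dose in MBq; must be positive.
    weight_kg : float
        Patient body weight in kg; must be positive.

    Returns
    -------
    SuvVolume
        ``SUV = activity * weight / dose`` (the kBq→MBq and kg→g factors of
        1000 cancel on the g/mL convention).
    """
    if dose_mbq <= 0:
        raise ValueError(f"injected dose must be positive, got {dose_mbq} MBq")
    if weight_kg <= 0:
        raise ValueError(f"body weight must be positive, got {weight_kg} kg")
    activity = np.asarray(activity_kbq_ml, dtype=float)
    if activity.size and float(activity.min()) < 0:
        raise ValueError("activity concentration must be non-negative")
    suv = activity * (float(weight_kg) / float(dose_mbq))
    return SuvVolume(
        suv,
        spacing,
        edit_mask=edit_mask,
        meta={"weight_kg": float(weight_kg), "dose_mbq": float(dose_mbq)},
    )
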