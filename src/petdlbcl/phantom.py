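"""Synthetic PET phantoms with voxel-exact ground truth.

A phantom is a 3-D SUV field assembled from a uniform soft-tissue background
and a set of ellipsoidal (or box) regions — lesions, liver, mediastinal blood
pool and physiological-uptake structures — optionally smoothed with a
Gaussian point-spread blur and degraded with additive Gaussian noise
(truncated at zero, since SUV cannot be negative).

Ground truth is defined *before* blur and noise by a voxel-centre-in-region
test: a voxel belongs to an ellipsoid iff its centre satisfies
sum(((x - c) / r)^2) <= 1.  True per-lesion MTV is therefore exactly
voxel count x voxel volume, which makes the generator oracle-checkable.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy import ndimage

from .volume import SuvVolume

__all__ = ["Region", "PhantomSpec", "PhantomTruth", "generate_phantom", "demo_phantom_spec"]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class Region:
    """An ellipsoid or axis-aligned box region of uniform uptake.

    ``center`` and ``radii`` are in mm (box: half-edge lengths); ``suv`` is
    the nominal uptake; ``label`` names the region in error messages and the
    truth masks.
    """

    center: tuple[float, float, float]
    radii: tuple[float, float, float]
    suv: float
    label: str = ""
    shape: str = "ellipsoid"

    def __post_init__(self) -> None:
        if self.suv < 0:
            raise ValueError(f"region {self.label!r}: SUV must be non-negative")
        if any(r <= 0 for r in self.radii):
            raise ValueError(f"region {self.label!r}: radii must be positive")
        if self.shape not in ("ellipsoid", "box"):
            raise ValueError(f"region {self.label!r}: unknown shape {self.shape!r}")


@dataclass
class PhantomSpec:
    """Phantom layout and degradation parameters.

    Defaults emulate a small torso field of view at PET-typical 3 mm voxels:
    soft-tissue background SUV 1.0, liver ~2.2, mediastinal blood pool ~1.8,
    lesions well above the 2.5 segmentation threshold, 6 mm FWHM blur and
    SUV noise sd 0.05.
    """

    grid_shape: tuple[int, int, int] = (48, 48, 48)
    voxel_spacing: tuple[float, float, float] = (3.0, 3.0, 3.0)
    background_suv: float = 1.0
    lesions: list[Region] = field(default_factory=list)
    liver_region: Region | None = None
    mediastinum_region: Region | None = None
    physiological_regions: list[Region] = field(default_factory=list)
    noise_sd: float = 0.0
    blur_fwhm: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background_suv < 0:
            raise ValueError("background SUV must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.blur_fwhm < 0:
            raise ValueError("blur_fwhm must be non-negative")
        if any(n <= 0 for n in self.grid_shape) or any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("grid_shape and voxel_spacing must be positive")

    def all_regions(self) -> list[Region]:
        regions = list(self.lesions)
        if self.liver_region is not None:
            regions.append(self.liver_region)
        if self.mediastinum_region is not None:
            regions.append(self.mediastinum_region)
        regions.extend(self.physiological_regions)
        return regions

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


@dataclass
class PhantomTruth:
    """Ground truth for a generated phantom.

    ``lesion_mask`` labels lesion voxels 1..n in spec order (0 elsewhere);
    ``region_masks`` holds boolean masks for the named non-lesion regions;
    ``true_mtv_cm3``/``true_tlg`` are per-lesion values from the pre-blur
    membership masks and nominal SUVs.
    """

    lesion_mask: np.ndarray
    region_masks: dict[str, np.ndarray]
    true_mtv_cm3: list[float]
    true_tlg: list[float]

    @property
    def total_mtv_cm3(self) -> float:
        return float(sum(self.true_mtv_cm3))


def _membership(region: Region, centers: tuple[np.ndarray, np.ndarray, np.ndarray]) -> np.ndarray:
    cx, cy, cz = centers
    if region.shape == "box":
        return (
            (np.abs(cx - region.center[0]) <= region.radii[0])
            & (np.abs(cy - region.center[1]) <= region.radii[1])
            & (np.abs(cz - region.center[2]) <= region.radii[2])
        )
    q = (
        ((cx - region.center[0]) / region.radii[0]) ** 2
        + ((cy - region.center[1]) / region.radii[1]) ** 2
        + ((cz - region.center[2]) / region.radii[2]) ** 2
    )
    return q <= 1.0


def generate_phantom(spec: PhantomSpec) -> tuple[SuvVolume, PhantomTruth]:
    """Render a phantom volume and its ground truth.

    Deterministic for a fixed ``spec.seed``.  Raises if a region extends
    outside the grid or if any two regions overlap (the error names the
    offending pair).
    """
    shape = tuple(int(n) for n in spec.grid_shape)
    sp = np.asarray(spec.voxel_spacing, dtype=float)
    extent = np.asarray(shape) * sp
    axes = [(np.arange(n) + 0.5) * s for n, s in zip(shape, sp)]
    centers = np.meshgrid(*axes, indexing="ij")

    regions = spec.all_regions()
    for i, reg in enumerate(regions):
        name = reg.label or f"region[{i}]"
        c = np.asarray(reg.center)
        r = np.asarray(reg.radii)
        if np.any(c - r < 0) or np.any(c + r > extent):
            raise ValueError(
                f"region {name!r} extends outside the grid (extent {extent.tolist()} mm)"
            )

    masks = [_membership(reg, centers) for reg in regions]
    for i in range(len(regions)):
        for j in range(i + 1, len(regions)):
            if np.any(masks[i] & masks[j]):
                a = regions[i].label or f"region[{i}]"
                b = regions[j].label or f"region[{j}]"
                raise ValueError(f"regions {a!r} and {b!r} overlap")

    values = np.full(shape, float(spec.background_suv))
    for reg, mask in zip(regions, masks):
        values[mask] = reg.suv

    n_lesions = len(spec.lesions)
    lesion_mask = np.zeros(shape, dtype=np.int32)
    true_mtv: list[float] = []
    true_tlg: list[float] = []
    voxvol = float(np.prod(sp)) / 1000.0
    for k in range(n_lesions):
        lesion_mask[masks[k]] = k + 1
        mtv = float(masks[k].sum()) * voxvol
        true_mtv.append(mtv)
        true_tlg.append(mtv * spec.lesions[k].suv)

    region_masks: dict[str, np.ndarray] = {}
    for reg, mask in zip(regions[n_lesions:], masks[n_lesions:]):
        region_masks[reg.label or f"region[{len(region_masks)}]"] = mask

    if spec.blur_fwhm > 0:
        sigma_vox = spec.blur_fwhm * _FWHM_TO_SIGMA / sp
        values = ndimage.gaussian_filter(values, sigma=sigma_vox)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        values = values + rng.normal(0.0, spec.noise_sd, size=shape)
    np.clip(values, 0.0, None, out=values)

    vol = SuvVolume(values, tuple(sp), meta={"phantom_seed": spec.seed})
    truth = PhantomTruth(
        lesion_mask=lesion_mask,
        region_masks=region_masks,
        true_mtv_cm3=true_mtv,
        true_tlg=true_tlg,
    )
    return vol, truth


def demo_phantom_spec(
    seed: int = 0, interim: bool = False, noise_sd: float = 0.05, blur_fwhm: float = 6.0
) -> PhantomSpec:
    """A small two-lesion torso-like phantom used by the pipeline demo.

    The baseline layout has two avid lesions (SUV 12 and 8); the interim
    layout keeps one shrunken residual lesion at SUV 4.2 (Deauville 4
    territory against a liver reference near 2.2-2.5).
    """
    liver = Region(center=(100.0, 44.0, 44.0), radii=(30.0, 24.0, 24.0), suv=2.2, label="liver")
    medi = Region(center=(40.0, 72.0, 72.0), radii=(10.0, 10.0, 26.0), suv=1.8, label="mediastinum")
    bladder = Region(center=(110.0, 110.0, 110.0), radii=(12.0, 12.0, 12.0), suv=9.0, label="bladder")
    if interim:
        lesions = [
            Region(center=(44.0, 108.0, 40.0), radii=(6.0, 6.0, 6.0), suv=4.2, label="lesion_1")
        ]
    else:
        lesions = [
            Region(center=(44.0, 108.0, 40.0), radii=(16.0, 12.0, 12.0), suv=12.0, label="lesion_1"),
            Region(center=(104.0, 36.0, 104.0), radii=(10.0, 10.0, 14.0), suv=8.0, label="lesion_2"),
        ]
    return PhantomSpec(
        grid_shape=(48, 48, 48),
        voxel_spacing=(3.0, 3.0, 3.0),
        background_suv=1.0,
        lesions=lesions,
        liver_region=liver,
        mediastinum_region=medi,
        physiological_regions=[bladder],
        noise_sd=noise_sd,
        blur_fwhm=blur_fwhm,
        seed=seed,
    )
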