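"""Synthetic two-habitat tumor phantoms.

Each phantom is an ellipsoidal "tumor" on a constant background: a bright,
noisy shell (the marginal, texture-rich habitat) around a darker, smoother
core (the inner habitat).  Local entropy responds to the higher rim noise, so
the planted structure reproduces the marginal/inner dichotomy that habitat
partitioning is meant to recover: the rim has both higher mean intensity and
higher local entropy than the core.

Default geometry and spacing emulate a 3T T1CE acquisition with 0.359 mm
in-plane pixel spacing and 5 mm slices; the tumor is a ~8 mm-radius ellipsoid
spanning a handful of axial slices.  Second-observer segmentations are
simulated by a randomized in-plane morphological perturbation of the mask
boundary, mimicking manual re-contouring variability.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from habitomics.imaging_io import ImageVolume, RoiMask, write_mask, write_volume


@dataclass
class PhantomSpec:
    """Parameters of one synthetic tumor volume.

    rim_fraction is the shell thickness as a fraction of the tumor radius;
    intensities are arbitrary MR-like units.  rim_sd > core_sd plants the
    texture contrast that raises local entropy in the rim.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 12)
    voxel_spacing_mm: tuple[float, float, float] = (0.359, 0.359, 5.0)
    tumor_radius_mm: float = 8.0
    rim_fraction: float = 0.3
    core_mean: float = 100.0
    rim_mean: float = 200.0
    core_sd: float = 5.0
    rim_sd: float = 30.0
    background_mean: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.rim_fraction < 1.0):
            raise ValueError(f"rim_fraction must be in (0,1), got {self.rim_fraction}")
        if self.core_sd < 0 or self.rim_sd < 0:
            raise ValueError("noise standard deviations must be non-negative")
        radii_vox = [self.tumor_radius_mm / s for s in self.voxel_spacing_mm]
        for r, n in zip(radii_vox, self.grid_shape):
            if 2 * r >= n - 2:
                raise ValueError(
                    f"tumor (radius {self.tumor_radius_mm} mm) does not fit inside "
                    f"grid {self.grid_shape} at spacing {self.voxel_spacing_mm}"
                )


@dataclass
class PhantomCase:
    """One generated phantom: volume, mask, planted habitat labels (rim=1,
    core=2 on mask-positive voxels) and a simulated second-observer mask."""

    case_id: str
    volume: ImageVolume
    mask: RoiMask
    truth_labels: np.ndarray
    mask_observer2: RoiMask
    spec: PhantomSpec = None  # type: ignore[assignment]


@dataclass
class SyntheticCohort:
    """Labeled cohort of phantoms with a class-dependent rim-texture shift."""

    cases: list[PhantomCase]
    outcome: np.ndarray
    effect_size: float

    def __post_init__(self) -> None:
        self.outcome = np.asarray(self.outcome, dtype=int)
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if len(set(self.outcome.tolist())) < 2:
            raise ValueError("both outcome classes must be non-empty")


def _ellipsoid_distance(spec: PhantomSpec) -> np.ndarray:
    """Normalized radial coordinate (1.0 on the tumor surface)."""
    center = [(n - 1) / 2.0 for n in spec.grid_shape]
    radii_vox = [spec.tumor_radius_mm / s for s in spec.voxel_spacing_mm]
    grids = np.ogrid[tuple(slice(0, n) for n in spec.grid_shape)]
    d2 = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii_vox))
    return np.sqrt(d2)


def generate_case(spec: PhantomSpec, case_id: str = "case") -> PhantomCase:
    """Generate one two-compartment phantom, deterministic given spec.seed."""
    rng = np.random.default_rng(spec.seed)
    dist = _ellipsoid_distance(spec)
    mask_arr = dist <= 1.0
    core = dist <= (1.0 - spec.rim_fraction)
    rim = mask_arr & ~core
    if not rim.any() or not core.any():
        raise ValueError("degenerate phantom: rim or core compartment is empty")

    data = np.full(spec.grid_shape, spec.background_mean, dtype=np.float64)
    data[rim] = spec.rim_mean + spec.rim_sd * rng.standard_normal(int(rim.sum()))
    data[core] = spec.core_mean + spec.core_sd * rng.standard_normal(int(core.sum()))

    truth = np.zeros(spec.grid_shape, dtype=np.uint8)
    truth[rim] = 1
    truth[core] = 2

    mask = RoiMask(data=mask_arr)
    obs2_seed = int(rng.integers(0, 2**31 - 1))
    mask_obs2 = perturb_mask(mask, magnitude_vox=1, seed=obs2_seed)

    volume = ImageVolume(data=data, spacing_mm=spec.voxel_spacing_mm)
    return PhantomCase(
        case_id=case_id,
        volume=volume,
        mask=mask,
        truth_labels=truth,
        mask_observer2=mask_obs2,
        spec=spec,
    )


def generate_cohort(
    n_cases: int,
    effect_size: float,
    base_spec: PhantomSpec | None = None,
    seed: int = 0,
) -> SyntheticCohort:
    """Balanced binary cohort with a rim-texture effect in class 1.

    Class-1 cases have rim_mean and rim_sd shifted by ``effect_size * core_sd``
    (the core noise scale serves as the reference SD).  Per-case biological
    variability is emulated by jittering tumor radius, rim thickness, means
    and noise levels around the base spec so that between-case feature
    variance dominates segmentation-perturbation variance, as in real
    cohorts.
    """
    if n_cases < 4:
        raise ValueError("need at least 4 cases to form two non-empty classes")
    if base_spec is None:
        base_spec = PhantomSpec()
    rng = np.random.default_rng(seed)

    outcome = np.zeros(n_cases, dtype=int)
    outcome[: n_cases // 2] = 1
    rng.shuffle(outcome)

    shift = effect_size * base_spec.core_sd
    cases = []
    for i in range(n_cases):
        jitter = rng.uniform
        spec_i = replace(
            base_spec,
            tumor_radius_mm=base_spec.tumor_radius_mm * jitter(0.85, 1.15),
            rim_fraction=float(np.clip(base_spec.rim_fraction * jitter(0.8, 1.2), 0.05, 0.95)),
            core_mean=base_spec.core_mean * jitter(0.9, 1.1),
            rim_mean=(base_spec.rim_mean + shift * outcome[i]) * jitter(0.95, 1.05),
            core_sd=base_spec.core_sd * jitter(0.8, 1.2),
            rim_sd=(base_spec.rim_sd + shift * outcome[i]) * jitter(0.9, 1.1),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        cases.append(generate_case(spec_i, case_id=f"case_{i:03d}"))

    return SyntheticCohort(cases=cases, outcome=outcome, effect_size=effect_size)


def perturb_mask(mask: RoiMask, magnitude_vox: int, seed: int = 0) -> RoiMask:
    """Randomized in-plane morphological boundary perturbation.

    A smoothed random field decides, voxel-wise, between the mask dilated and
    eroded by up to ``magnitude_vox`` (2-D, per axial slice, respecting the
    anisotropic slice spacing).  magnitude 0 returns the mask unchanged;
    identical seeds give identical outputs.
    """
    if mask.n_voxels == 0:
        raise ValueError("cannot perturb an empty mask")
    if magnitude_vox == 0:
        return RoiMask(data=mask.data.copy())

    rng = np.random.default_rng(seed)
    field_ = ndimage.gaussian_filter(
        rng.standard_normal(mask.shape[:2] + (mask.shape[2],)), sigma=(3, 3, 0)
    )
    structure = ndimage.generate_binary_structure(2, 1)
    out = np.zeros_like(mask.data, dtype=bool)
    for z in range(mask.shape[2]):
        sl = mask.data[:, :, z].astype(bool)
        if not sl.any():
            continue
        dil = ndimage.binary_dilation(sl, structure, iterations=magnitude_vox)
        ero = ndimage.binary_erosion(sl, structure, iterations=magnitude_vox)
        out[:, :, z] = np.where(field_[:, :, z] > 0, dil, ero)
    if not out.any():
        raise ValueError("perturbation emptied the mask; reduce magnitude_vox")
    return RoiMask(data=out)


def dice(a: RoiMask, b: RoiMask) -> float:
    """Dice overlap of two binary masks."""
    inter = int((a.data & b.data).sum())
    denom = a.n_voxels + b.n_voxels
    return 2.0 * inter / denom if denom else 0.0


def write_cohort(cohort: SyntheticCohort, out_dir) -> None:
    """Write NIfTI volume/mask pairs and a CSV manifest to ``out_dir``."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for case, y in zip(cohort.cases, cohort.outcome):
        vol_path = out / f"{case.case_id}_volume.nii.gz"
        mask_path = out / f"{case.case_id}_mask.nii.gz"
        mask2_path = out / f"{case.case_id}_mask_obs2.nii.gz"
        write_volume(case.volume, vol_path)
        write_mask(case.mask, mask_path, case.volume.spacing_mm, case.volume.affine)
        write_mask(case.mask_observer2, mask2_path, case.volume.spacing_mm, case.volume.affine)
        rows.append(
            {
                "case_id": case.case_id,
                "outcome": int(y),
                "volume": vol_path.name,
                "mask": mask_path.name,
                "mask_observer2": mask2_path.name,
            }
        )
    with open(out / "manifest.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
        writer.writeheader()
        writer.writerows(rows)
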