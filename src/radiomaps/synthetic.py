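"""Synthetic two-class prostate phantom cohort.

Generates everything the downstream stages consume, with the statistical
structure the analysis assumes, so the whole pipeline is testable without
patient data:

* a cohort table of 52 patients by default — 33 without cancer (25 PZ /
  8 TZ), 8 with clinically insignificant cancer (4/4) and 11 with
  clinically significant cancer (8/3) — with PSA and prostate volume drawn
  from log-normal distributions whose group medians (PSA 6 / 7.45 / 9.7
  ng/mL; volume 62 / 47 / 46 mL) and spreads follow the cohort the package
  is calibrated to; PSA density is PSA / volume;
* per patient a T2w-like phantom: a smoothed correlated Gaussian noise
  background with an ellipsoidal lesion whose voxel intensities carry a
  class-dependent median shift (csPCa darker) and extra local contrast
  (csPCa noisier), positioned in a posterior band for PZ lesions and
  centrally for TZ lesions;
* two lesion masks: rater 1 draws the exact ellipsoid, rater 2 a
  morphologically perturbed copy (random 1-voxel boundary additions and
  removals), giving Dice > 0.5 by construction.

Setting ``lesion_effect`` to zero makes lesion and background voxel
distributions identical in expectation — the null phantom used for
type-I-error checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .image import ImageVolume, SegmentationMask

__all__ = [
    "LesionEffect",
    "CohortConfig",
    "PatientRecord",
    "PhantomCase",
    "psad",
    "generate_records",
    "generate_phantom",
    "generate_cohort",
    "cohort_dataframe",
]

GROUPS = ("noPCa", "ciPCa", "csPCa")
ZONES = ("PZ", "TZ")


def psad(psa: float, volume: float) -> float:
    """PSA density in (ng/mL)/cm^3: serum PSA divided by prostate volume."""
    if volume <= 0:
        raise ValueError("prostate volume must be positive")
    return psa / volume


@dataclass(frozen=True)
class LesionEffect:
    """Class contrast of the simulated lesion, in background-SD units.

    ``median_shift`` lowers the lesion's median intensity (fully for csPCa,
    attenuated for non-csPCa), reproducing the darker appearance of
    significant tumors on T2w; ``contrast`` adds local intensity noise
    inside the lesion (again stronger for csPCa). Zero on both -> the
    lesion is statistically indistinguishable from background.
    """

    median_shift: float = 1.2
    contrast: float = 0.8
    noncs_attenuation: float = 0.35

    def shift_for(self, significant: bool) -> float:
        return self.median_shift * (1.0 if significant else self.noncs_attenuation)

    def contrast_for(self, significant: bool) -> float:
        return self.contrast * (1.0 if significant else self.noncs_attenuation)


# Group medians and log-scale sigmas follow the reference cohort's
# medians/IQRs (log-normal: sigma ~= log(IQR ratio) / 1.349).
_PSA_MEDIANS = {"noPCa": 6.0, "ciPCa": 7.45, "csPCa": 9.7}
_PSA_SIGMAS = {"noPCa": 0.32, "ciPCa": 0.26, "csPCa": 0.69}
_VOL_MEDIANS = {"noPCa": 62.0, "ciPCa": 47.0, "csPCa": 46.0}
_VOL_SIGMAS = {"noPCa": 0.36, "ciPCa": 0.28, "csPCa": 0.18}


@dataclass(frozen=True)
class CohortConfig:
    """Cohort composition, covariate distributions and phantom geometry."""

    n_noPCa_PZ: int = 25
    n_noPCa_TZ: int = 8
    n_ciPCa_PZ: int = 4
    n_ciPCa_TZ: int = 4
    n_csPCa_PZ: int = 8
    n_csPCa_TZ: int = 3
    psa_median_by_group: dict = field(default_factory=lambda: dict(_PSA_MEDIANS))
    psa_sigma_by_group: dict = field(default_factory=lambda: dict(_PSA_SIGMAS))
    volume_median_by_group: dict = field(default_factory=lambda: dict(_VOL_MEDIANS))
    volume_sigma_by_group: dict = field(default_factory=lambda: dict(_VOL_SIGMAS))
    lesion_effect: LesionEffect = LesionEffect()
    image_shape: tuple[int, int, int] = (96, 96, 16)
    spacing: tuple[float, float, float] = (0.5, 0.5, 3.0)  # mm, T2w-like
    background_mean: float = 300.0
    background_sd: float = 60.0
    lesion_radii_mm: tuple[float, float] = (4.0, 12.0)  # in-plane range
    rater2_flip_rate: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        counts = [
            self.n_noPCa_PZ, self.n_noPCa_TZ, self.n_ciPCa_PZ,
            self.n_ciPCa_TZ, self.n_csPCa_PZ, self.n_csPCa_TZ,
        ]
        if any(c < 0 for c in counts):
            raise ValueError("group counts must be >= 0")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")
        for d in (self.psa_median_by_group, self.volume_median_by_group):
            if any(v <= 0 for v in d.values()):
                raise ValueError("median parameters must be positive")

    def count_for(self, group: str, zone: str) -> int:
        return getattr(self, f"n_{group}_{zone}")

    @property
    def n_total(self) -> int:
        return sum(self.count_for(g, z) for g in GROUPS for z in ZONES)


@dataclass
class PatientRecord:
    id: str
    zone: str  # PZ or TZ
    psa: float  # ng/mL
    prostate_volume: float  # mL
    outcome: str  # noPCa / ciPCa / csPCa

    def __post_init__(self) -> None:
        if self.zone not in ZONES:
            raise ValueError(f"unknown zone {self.zone!r}")
        if self.outcome not in GROUPS:
            raise ValueError(f"unknown outcome {self.outcome!r}")

    @property
    def psad(self) -> float:
        return psad(self.psa, self.prostate_volume)

    @property
    def label(self) -> str:
        """Binary endpoint: csPCa vs non-csPCa (noPCa and ciPCa collapsed)."""
        return "csPCa" if self.outcome == "csPCa" else "non-csPCa"

    @property
    def is_cs(self) -> bool:
        return self.outcome == "csPCa"


@dataclass
class PhantomCase:
    volume: ImageVolume
    mask_rater1: SegmentationMask
    mask_rater2: SegmentationMask
    lesion_center_mm: tuple[float, float, float]
    lesion_radii_mm: tuple[float, float, float]


def generate_records(config: CohortConfig, rng: np.random.Generator) -> list[PatientRecord]:
    records = []
    i = 0
    for group in GROUPS:
        mu_psa = np.log(config.psa_median_by_group[group])
        mu_vol = np.log(config.volume_median_by_group[group])
        s_psa = config.psa_sigma_by_group[group]
        s_vol = config.volume_sigma_by_group[group]
        for zone in ZONES:
            for _ in range(config.count_for(group, zone)):
                i += 1
                records.append(
                    PatientRecord(
                        id=f"P{i:03d}",
                        zone=zone,
                        psa=float(rng.lognormal(mu_psa, s_psa)),
                        prostate_volume=float(rng.lognormal(mu_vol, s_vol)),
                        outcome=group,
                    )
                )
    return records


def _smoothed_field(shape, rng: np.random.Generator, mean, sd) -> np.ndarray:
    """Correlated Gaussian background: white noise smoothed with a 1-voxel
    kernel, rescaled to the requested mean/SD."""
    raw = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=1.0)
    raw = (raw - raw.mean()) / raw.std()
    return mean + sd * raw


def _ellipsoid_mask(shape, spacing, center_mm, radii_mm) -> np.ndarray:
    coords = [
        ((np.arange(n) + 0.5) * sp - c) / r
        for n, sp, c, r in zip(shape, spacing, center_mm, radii_mm)
    ]
    xx, yy, zz = np.meshgrid(*coords, indexing="ij")
    return xx**2 + yy**2 + zz**2 <= 1.0


def _perturb_mask(mask: np.ndarray, rng: np.random.Generator, flip_rate: float) -> np.ndarray:
    """Second-rater mask: randomly drop inner-boundary voxels and add
    outer-boundary voxels (1-voxel erosion/dilation patches)."""
    structure = ndimage.generate_binary_structure(3, 1)
    inner = mask & ~ndimage.binary_erosion(mask, structure)
    outer = ndimage.binary_dilation(mask, structure) & ~mask
    out = mask.copy()
    out[inner] &= rng.random(int(inner.sum())) >= flip_rate
    add = rng.random(int(outer.sum())) < flip_rate
    out[outer] = add
    if not out.any():  # tiny lesions: keep at least the original core
        out = mask.copy()
    return out


def generate_phantom(
    record: PatientRecord, config: CohortConfig, seed: int | np.random.Generator
) -> PhantomCase:
    """One phantom volume plus dual-rater lesion masks for ``record``."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    shape = tuple(config.image_shape)
    spacing = tuple(config.spacing)
    extent = np.array(shape) * np.array(spacing)

    volume_data = _smoothed_field(shape, rng, config.background_mean, config.background_sd)

    # Lesion geometry: radii in mm, clipped to fit the phantom interior.
    r_lo, r_hi = config.lesion_radii_mm
    r_hi_eff = min(r_hi, float(extent[:2].min()) / 4.0)
    if r_hi_eff < r_lo:
        raise ValueError("lesion radii exceed the volume extent")
    rx, ry = rng.uniform(r_lo, r_hi_eff, size=2)
    rz = min(rng.uniform(3.0, 6.0), extent[2] / 3.0)

    # Zone determines the in-plane lesion position: PZ posterior, TZ central.
    cx = extent[0] / 2.0
    cy = extent[1] * (0.68 if record.zone == "PZ" else 0.5)
    cz = extent[2] / 2.0
    jitter = rng.uniform(-1.5, 1.5, size=3)
    center = np.array([cx, cy, cz]) + jitter
    center = np.clip(center, [rx, ry, rz], extent - [rx, ry, rz])

    lesion = _ellipsoid_mask(shape, spacing, center, (rx, ry, rz))
    if not lesion.any():
        raise ValueError("degenerate lesion: radii smaller than one voxel")

    eff = config.lesion_effect
    shift = eff.shift_for(record.is_cs) * config.background_sd
    extra_sd = eff.contrast_for(record.is_cs) * config.background_sd
    n_lesion = int(lesion.sum())
    volume_data[lesion] += -shift + extra_sd * rng.standard_normal(n_lesion)

    mask1 = lesion
    mask2 = _perturb_mask(lesion, rng, config.rater2_flip_rate)

    volume = ImageVolume(volume_data, spacing)
    return PhantomCase(
        volume=volume,
        mask_rater1=SegmentationMask(mask1, spacing),
        mask_rater2=SegmentationMask(mask2, spacing),
        lesion_center_mm=tuple(float(c) for c in center),
        lesion_radii_mm=(float(rx), float(ry), float(rz)),
    )


def generate_cohort(
    config: CohortConfig = CohortConfig(),
    with_phantoms: bool = True,
) -> list[tuple[PatientRecord, PhantomCase | None]]:
    """Deterministic cohort: records plus (optionally) one phantom each."""
    root = np.random.SeedSequence(config.seed)
    rec_rng = np.random.default_rng(root.spawn(1)[0])
    records = generate_records(config, rec_rng)
    out = []
    case_seeds = root.spawn(len(records) + 1)[1:]
    for record, ss in zip(records, case_seeds):
        case = (
            generate_phantom(record, config, np.random.default_rng(ss))
            if with_phantoms
            else None
        )
        out.append((record, case))
    return out


def cohort_dataframe(records: list[PatientRecord]) -> pd.DataFrame:
    """Cohort table with columns id,zone,psa_ng_ml,volume_ml,psad,outcome,label."""
    return pd.DataFrame(
        {
            "id": [r.id for r in records],
            "zone": [r.zone for r in records],
            "psa_ng_ml": [r.psa for r in records],
            "volume_ml": [r.prostate_volume for r in records],
            "psad": [r.psad for r in records],
            "outcome": [r.outcome for r in records],
            "label": [r.label for r in records],
        }
    )
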