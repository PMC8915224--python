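"""Synthetic cat CT phantoms with known tissue ground truth.

Each phantom is an ellipsoidal soft-tissue body with an embedded rod
skeleton, fat and lean voxels interleaved at a requested fraction, and
optional excludable contents (non-aerated lung, GI/bladder contents, a
metal implant) plus an external table slab.  HU values are tissue means
plus Gaussian noise, rounded half-away-from-zero to integers, with all
non-body background fixed at the air sentinel -1024 HU.

Cohort generation additionally emits matched necropsy records in which
the falciform fat pad weight (FFPW) scales linearly with true body fat
volume plus noise, and femur length (FL) scales with body size — the
statistical structure the downstream adiposity analysis assumes.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace

import numpy as np
import pandas as pd

from ._util import round_half_away, round_half_away_array
from .ct import (
    AIR_HU,
    LABEL_CONTENTS,
    LABEL_EXTERNAL,
    LABEL_LUNG,
    LABEL_NONSKELETAL,
    CTVolume,
    ExclusionMasks,
)

# Visual fat-category bands on the true fat fraction of soft tissue.
# Arbitrary but fixed, loosely guided by the %BF cutoffs 27.1/37.4.
FC_BANDS = ((0.15, "underweight"), (0.27, "normal"), (0.40, "overweight"))


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic cat volume.

    target_fat_fraction is the fraction of soft-tissue voxels assigned
    fat HU; hit exactly at voxel resolution by construction.
    """

    cat_id: str = "phantom"
    target_fat_fraction: float = 0.30
    body_extent: tuple[int, int, int] = (64, 64, 64)
    voxel_spacing: tuple[float, float, float] = (0.05, 0.05, 0.06)  # cm
    fat_hu_mean: float = -100.0
    lean_hu_mean: float = 60.0
    bone_hu_mean: float = 700.0
    lung_hu_mean: float = -400.0
    contents_hu_mean: float = 20.0
    implant_hu_mean: float = 3000.0
    hu_sd: float = 10.0
    include_lung: bool = True
    include_gi_contents: bool = True
    include_implant: bool = False
    include_table: bool = True
    ffpw_slope: float = 5.0  # g per cm^3 of true BFV
    ffpw_noise_sd: float = 4.5  # g
    fl_base: float = 11.4  # cm at the reference 64-voxel extent
    seed: int = 0
    allow_degenerate: bool = False

    def validate(self) -> None:
        if not 0.0 <= self.target_fat_fraction <= 1.0:
            raise ValueError("target_fat_fraction must lie in [0, 1]")
        if any(e < 8 for e in self.body_extent):
            raise ValueError("body_extent axes must be >= 8 voxels")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel_spacing must be positive")
        if not (-250 <= self.fat_hu_mean < self.lean_hu_mean <= 250):
            raise ValueError(
                "fat and lean HU means must lie in [-250, 250] with fat < lean"
            )
        if self.bone_hu_mean < 350 + 3 * self.hu_sd:
            raise ValueError("bone_hu_mean must be >= 350 + 3*hu_sd")
        separable = self.lean_hu_mean - self.fat_hu_mean >= 6 * self.hu_sd
        if not separable and not self.allow_degenerate:
            raise ValueError(
                "fat/lean peak separation below 6*hu_sd; set "
                "allow_degenerate=True to generate anyway"
            )

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PhantomSpec":
        d = json.loads(text)
        for key in ("body_extent", "voxel_spacing"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass(frozen=True)
class PhantomTruth:
    """Exact compartment counts and derived ground-truth metrics."""

    cat_id: str
    true_fat_voxels: int
    true_lean_voxels: int
    true_bone_voxels: int
    vv: float  # cm^3
    generated_ffpw: float = float("nan")  # g, filled by generate_cohort
    generated_fl: float = float("nan")  # cm

    @property
    def true_bfv(self) -> float:
        return self.true_fat_voxels * self.vv

    @property
    def true_tbbv(self) -> float:
        return self.true_bone_voxels * self.vv

    @property
    def true_nbfv(self) -> float:
        return self.true_fat_voxels / self.true_bone_voxels

    @property
    def true_soft_fat_fraction(self) -> float:
        return self.true_fat_voxels / (self.true_fat_voxels + self.true_lean_voxels)


def _ellipsoid(shape, center, semi) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi))
    return acc <= 1.0


def generate_phantom(
    spec: PhantomSpec,
) -> tuple[CTVolume, ExclusionMasks, PhantomTruth]:
    """Build one phantom volume with exclusion masks and exact truth.

    Deterministic in (spec, spec.seed): identical inputs give bitwise
    identical outputs.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    shape = tuple(int(e) for e in spec.body_extent)
    nx, ny, nz = shape
    center = tuple((s - 1) / 2.0 for s in shape)

    body = _ellipsoid(shape, center, tuple(0.42 * s for s in shape))

    # Skeleton proxy: an axial spine rod plus two transverse limb rods.
    xg, yg, zg = np.ogrid[0:nx, 0:ny, 0:nz]
    r_spine = max(2, nx // 16)
    spine = ((xg - center[0]) ** 2 + (yg - center[1]) ** 2) <= r_spine**2
    spine = spine & (np.abs(zg - center[2]) <= 0.38 * nz)
    r_limb = max(1, nx // 24)
    limb_lo = ((yg - center[1]) ** 2 + (zg - 0.25 * nz) ** 2) <= r_limb**2
    limb_hi = ((yg - center[1]) ** 2 + (zg - 0.75 * nz) ** 2) <= r_limb**2
    limbs = (limb_lo | limb_hi) & (np.abs(xg - center[0]) <= 0.3 * nx)
    bone = (spine | limbs) & body

    occupied = bone.copy()
    lung = np.zeros(shape, dtype=bool)
    if spec.include_lung:
        lung = _ellipsoid(
            shape,
            (center[0], center[1] + 0.18 * ny, 0.28 * nz),
            (0.12 * nx, 0.12 * ny, 0.12 * nz),
        ) & body & ~occupied
        occupied |= lung
    contents = np.zeros(shape, dtype=bool)
    if spec.include_gi_contents:
        contents = _ellipsoid(
            shape,
            (center[0], center[1] - 0.15 * ny, 0.70 * nz),
            (0.10 * nx, 0.10 * ny, 0.10 * nz),
        ) & body & ~occupied
        occupied |= contents
    implant = np.zeros(shape, dtype=bool)
    if spec.include_implant:
        implant[
            int(0.70 * nx) : int(0.70 * nx) + 3,
            int(0.30 * ny) : int(0.30 * ny) + 3,
            int(0.30 * nz) : int(0.30 * nz) + 3,
        ] = True
        implant &= body & ~occupied
        occupied |= implant

    soft = body & ~occupied
    soft_idx = np.flatnonzero(soft.ravel())
    n_soft = soft_idx.size
    n_fat = int(round(spec.target_fat_fraction * n_soft))
    # Fixed permutation regardless of n_fat: raising the target fraction
    # only grows the fat set, so truth nBFV is monotone in the target.
    order = rng.permutation(n_soft)
    fat_flat = soft_idx[order[:n_fat]]
    fat = np.zeros(shape, dtype=bool).ravel()
    fat[fat_flat] = True
    fat = fat.reshape(shape)
    lean = soft & ~fat

    table = np.zeros(shape, dtype=bool)
    if spec.include_table:
        table[:, :2, :] = True
        table &= ~body

    hu = np.full(shape, float(AIR_HU))
    hu[fat] = spec.fat_hu_mean
    hu[lean] = spec.lean_hu_mean
    hu[bone] = spec.bone_hu_mean
    hu[lung] = spec.lung_hu_mean
    hu[contents] = spec.contents_hu_mean
    hu[implant] = spec.implant_hu_mean
    hu[table] = 0.0
    noisy = body | table
    hu[noisy] += rng.normal(0.0, spec.hu_sd, size=int(noisy.sum()))
    hu = round_half_away_array(hu).astype(np.int32)
    hu = np.maximum(hu, AIR_HU)

    labels = np.zeros(shape, dtype=np.int16)
    labels[table] = LABEL_EXTERNAL
    labels[lung] = LABEL_LUNG
    labels[contents] = LABEL_CONTENTS
    labels[implant] = LABEL_NONSKELETAL

    w, l, t = spec.voxel_spacing
    truth = PhantomTruth(
        cat_id=spec.cat_id,
        true_fat_voxels=int(fat.sum()),
        true_lean_voxels=int(lean.sum()),
        true_bone_voxels=int(bone.sum()),
        vv=w * l * t,
    )
    volume = CTVolume(hu=hu, spacing=spec.voxel_spacing, cat_id=spec.cat_id)
    return volume, ExclusionMasks(labels=labels), truth


def assign_visual_fc(fat_fraction: float) -> str:
    """Visual fat category from the true soft-tissue fat fraction."""
    for upper, label in FC_BANDS:
        if fat_fraction < upper:
            return label
    return "obese"


def generate_cohort(
    n_cats: int,
    fat_fraction_range: tuple[float, float] = (0.10, 0.60),
    seed: int = 0,
    base_spec: PhantomSpec | None = None,
) -> tuple[list[tuple[CTVolume, ExclusionMasks, PhantomTruth]], pd.DataFrame]:
    """Generate a cohort of phantoms plus matched necropsy records.

    Fat fractions are spread evenly over ``fat_fraction_range`` and body
    size varies by +/-10% around the base extent.  FFPW is generated as
    ffpw_slope * true_BFV + Gaussian noise, floored at 0 g and rounded
    to whole grams (matching scale resolution; a 0 g reading is kept and
    flagged below_scale).  FL follows fl_base scaled by relative body
    size, rounded to 2 decimals.
    """
    if n_cats < 4:
        raise ValueError("n_cats must be >= 4 to populate all fat categories")
    lo, hi = fat_fraction_range
    if not (0.05 <= lo <= hi <= 0.70):
        raise ValueError("fat_fraction_range must lie within [0.05, 0.70]")
    base = base_spec if base_spec is not None else PhantomSpec()

    fractions = np.linspace(lo, hi, n_cats)
    child_seeds = np.random.SeedSequence(seed).generate_state(n_cats) % (2**31)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 1)))

    triples = []
    rows = []
    for i in range(n_cats):
        size_scale = rng.uniform(0.9, 1.1)
        extent = tuple(max(8, int(round(e * size_scale))) for e in base.body_extent)
        spec = replace(
            base,
            cat_id=f"cat{i:03d}",
            target_fat_fraction=float(fractions[i]),
            body_extent=extent,
            seed=int(child_seeds[i]),
        )
        volume, masks, truth = generate_phantom(spec)

        ffpw_raw = base.ffpw_slope * truth.true_bfv + rng.normal(0, base.ffpw_noise_sd)
        ffpw = max(0.0, round_half_away(ffpw_raw, 0))
        rel_size = np.mean(extent) / np.mean(base.body_extent)
        fl = round_half_away(base.fl_base * rel_size + rng.normal(0, 0.05), 2)
        truth = replace(truth, generated_ffpw=ffpw, generated_fl=fl)
        triples.append((volume, masks, truth))

        body_voxels = (
            truth.true_fat_voxels + truth.true_lean_voxels + truth.true_bone_voxels
        )
        muscle = rng.choice(
            ["atrophic", "normal", "hypertrophic"], p=[0.20, 0.78, 0.02]
        )
        rows.append(
            {
                "cat_id": spec.cat_id,
                "body_weight": round(body_voxels * truth.vv * 1.05, 1),
                "ffpw": ffpw,
                "fl": fl,
                "visual_fc": assign_visual_fc(truth.true_soft_fat_fraction),
                "muscle_grade": str(muscle),
                "fl_source": "postmortem",
                "below_scale": bool(ffpw == 0.0),
            }
        )
    return triples, pd.DataFrame(rows)
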