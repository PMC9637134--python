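"""Synthetic cohorts for exercising the connectome-survival pipeline.

Real gray-matter covariance studies start from segmented, spatially
normalized T1-weighted gray-matter probability maps that cannot be shared.
This module produces a stand-in cohort with the same downstream contract:
atlas-labeled gray-matter volumes carrying a *planted* inter-regional
covariance structure, a clinical table using standard neuro-oncology
coding, and survival times drawn from a known Weibull proportional-hazards
model with independent right censoring.

The planted structure is a latent-factor model. Each subject s has
``latent_dim`` standard-normal factor scores f_s. Region r responds with a
regional intensity offset (L f_s)_r, where L is the loading matrix, and
with a within-cube texture: a fixed zero-mean 27-component template (one
per factor) whose amplitude grows with the regional signal. The offset
moves regional *mean* gray matter (detectable by volumetry); the texture
makes cube-to-cube Pearson correlations between co-loaded regions rise
with the subject's factor scores, so network density — and hence local
efficiency — carries the same latent signal that drives the hazard.
Setting ``texture_amp=0`` recovers a pure offset-plus-noise volume.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "CohortSpec",
    "SyntheticCohort",
    "GrayMatterVolume",
    "default_loading_matrix",
    "generate_atlas",
    "generate_subject_volume",
    "generate_survival",
    "generate_clinical_table",
    "generate_cohort",
    "write_cohort",
]

#: columns of the full clinical design, in fixed order
CLINICAL_COLUMNS = (
    "tumor_location",
    "laterality",
    "multifocal",
    "grade",
    "histology",
    "resection",
    "age_years",
    "sex",
)

#: the presurgically known subset (tumor grade, histology and extent of
#: resection are only established at surgery)
PRESURGICAL_COLUMNS = (
    "tumor_location",
    "laterality",
    "multifocal",
    "age_years",
    "sex",
)


@dataclass(frozen=True)
class GrayMatterVolume:
    """A segmented gray-matter probability map with voxel geometry."""

    values: np.ndarray  # 3D, nonnegative
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    mask: np.ndarray | None = None  # 3D boolean; None = all in-mask

    def __post_init__(self) -> None:
        if self.values.ndim != 3:
            raise ValueError("values must be a 3D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")
        if self.mask is not None and self.mask.shape != self.values.shape:
            raise ValueError("mask shape must equal values shape")

    @property
    def effective_mask(self) -> np.ndarray:
        if self.mask is None:
            return np.ones(self.values.shape, dtype=bool)
        return self.mask


def default_loading_matrix(
    n_regions: int, latent_dim: int, weight: float = 0.2, seed: int = 0
) -> np.ndarray:
    """One dominant factor per region, assigned round-robin, random sign.

    The magnitude ``weight`` is on the gray-matter probability scale, so a
    one-SD factor excursion moves a region's mean density by ±weight.
    """
    rng = np.random.default_rng(seed)
    L = np.zeros((n_regions, latent_dim))
    signs = rng.choice([-1.0, 1.0], size=n_regions)
    for r in range(n_regions):
        L[r, r % latent_dim] = signs[r] * weight
    return L


@dataclass
class CohortSpec:
    """Study conditions for a synthetic cohort.

    Defaults emulate a mid-size single-center neuro-oncology cohort at
    desk scale: a 90-region parcellation on a small lattice, five latent
    factors driving both gray-matter covariance and hazard, Weibull
    baseline with median ≈133 months, and 30% independent censoring.
    """

    n_subjects: int = 305
    volume_shape: tuple[int, int, int] = (36, 42, 36)
    n_regions: int = 90
    latent_dim: int = 5
    loading_matrix: np.ndarray | None = None  # n_regions × latent_dim
    voxel_noise_sd: float = 0.08
    base_mean: float = 0.6
    texture_amp: float = 0.07
    texture_gain: float = 2.0
    beta_true: np.ndarray | None = None  # log-hazard ratios per factor
    baseline_shape: float = 1.2
    baseline_scale: float = 180.0
    target_censoring: float = 0.30
    margin: int = 3  # background border around the labeled core
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 1:
            raise ValueError("n_regions must be >= 1")
        if not (0.0 <= self.target_censoring < 1.0):
            raise ValueError("target_censoring must lie in [0, 1)")
        if self.baseline_shape <= 0 or self.baseline_scale <= 0:
            raise ValueError("Weibull baseline parameters must be positive")
        if self.voxel_noise_sd < 0:
            raise ValueError("voxel_noise_sd must be nonnegative")
        if self.loading_matrix is None:
            self.loading_matrix = default_loading_matrix(
                self.n_regions, self.latent_dim, seed=self.seed
            )
        self.loading_matrix = np.asarray(self.loading_matrix, dtype=float)
        if self.loading_matrix.shape != (self.n_regions, self.latent_dim):
            raise ValueError("loading_matrix must be n_regions × latent_dim")
        if self.beta_true is None:
            signs = np.resize([1.0, -1.0], self.latent_dim)
            self.beta_true = 0.8 * signs
        self.beta_true = np.asarray(self.beta_true, dtype=float)
        if self.beta_true.shape != (self.latent_dim,):
            raise ValueError("beta_true must have length latent_dim")


@dataclass
class SyntheticCohort:
    volumes: list[GrayMatterVolume]
    atlas: np.ndarray
    latent_factors: np.ndarray  # n_subjects × latent_dim
    survival: pd.DataFrame  # columns time_months, event
    clinical: pd.DataFrame
    spec: CohortSpec


def _factor_triple(n_regions: int, core_shape: tuple[int, int, int]) -> tuple[int, int, int]:
    """Split n_regions into a × b × c block grid fitting the core shape."""
    best = None
    for a in range(1, n_regions + 1):
        if n_regions % a:
            continue
        for b in range(1, n_regions // a + 1):
            if (n_regions // a) % b:
                continue
            c = n_regions // (a * b)
            sizes = (core_shape[0] // a, core_shape[1] // b, core_shape[2] // c)
            if min(sizes) < 3:
                continue
            # prefer near-cubic blocks
            score = np.std(sizes)
            if best is None or score < best[0]:
                best = (score, (a, b, c))
    if best is None:
        raise ValueError(
            f"volume core {core_shape} too small to hold {n_regions} regions "
            "with at least one full 3x3x3 cube each"
        )
    return best[1]


def generate_atlas(
    volume_shape: tuple[int, int, int],
    n_regions: int,
    seed: int = 0,
    margin: int = 3,
) -> np.ndarray:
    """A contiguous block parcellation: labels 1..n_regions, 0 = background.

    Regions are rectangular blocks in a lattice; anatomical topology is
    irrelevant to the downstream computations (only the node→region map
    matters). The labeled core is surrounded by a ``margin`` of background
    so boundary cubes exercise the in-mask inclusion rule. Deterministic:
    the layout depends only on shape and n_regions (seed kept for
    interface symmetry with the stochastic generators).
    """
    shape = tuple(int(s) for s in volume_shape)
    core = tuple(s - 2 * margin for s in shape)
    if min(core) < 3:
        raise ValueError(f"volume_shape {shape} too small for margin {margin}")
    a, b, c = _factor_triple(n_regions, core)
    atlas = np.zeros(shape, dtype=np.int32)
    xs = np.linspace(0, core[0], a + 1, dtype=int)
    ys = np.linspace(0, core[1], b + 1, dtype=int)
    zs = np.linspace(0, core[2], c + 1, dtype=int)
    label = 1
    for i in range(a):
        for j in range(b):
            for k in range(c):
                atlas[
                    margin + xs[i] : margin + xs[i + 1],
                    margin + ys[j] : margin + ys[j + 1],
                    margin + zs[k] : margin + zs[k + 1],
                ] = label
                label += 1
    present = np.unique(atlas)
    expected = np.arange(0, n_regions + 1)
    if not np.array_equal(present, expected if margin > 0 else expected[1:]):
        raise RuntimeError("atlas construction failed to place every label")
    return atlas


def _texture_templates(latent_dim: int, voxels_per_cube: int, seed: int) -> np.ndarray:
    """Fixed zero-mean, unit-SD within-cube templates, one per factor."""
    rng = np.random.default_rng(seed)
    T = rng.standard_normal((latent_dim, voxels_per_cube))
    T -= T.mean(axis=1, keepdims=True)
    T /= T.std(axis=1, keepdims=True)
    return T


def _region_factor(loading_matrix: np.ndarray) -> np.ndarray:
    """Dominant factor index per region (largest |loading|)."""
    return np.argmax(np.abs(loading_matrix), axis=1)


def generate_subject_volume(
    atlas: np.ndarray,
    factor_scores: np.ndarray,
    loading_matrix: np.ndarray,
    voxel_noise_sd: float,
    seed: int,
    *,
    base_mean: float = 0.6,
    texture_amp: float = 0.07,
    texture_gain: float = 2.0,
    cube_edge: int = 3,
    texture_seed: int = 0,
) -> GrayMatterVolume:
    """One subject's gray-matter map from the latent-factor model.

    Voxel value = base_mean + regional offset + texture + iid noise,
    clipped to [0, 1]. The regional offset is (loading_matrix ·
    factor_scores)[region]. The texture term tiles the volume with the
    region's dominant-factor template at amplitude
    ``texture_amp * max(0.1, 1 + texture_gain * offset)`` so cube-level
    correlation structure tracks the planted signal; it vanishes when
    ``texture_amp=0``. Background voxels are 0 and out of mask.
    """
    factor_scores = np.asarray(factor_scores, dtype=float)
    loading_matrix = np.asarray(loading_matrix, dtype=float)
    if loading_matrix.ndim != 2 or factor_scores.shape != (loading_matrix.shape[1],):
        raise ValueError(
            "factor_scores length must equal loading_matrix column count"
        )
    rng = np.random.default_rng(seed)
    offsets = loading_matrix @ factor_scores  # per region
    n_regions = loading_matrix.shape[0]

    values = np.zeros(atlas.shape, dtype=float)
    mask = atlas > 0
    region_of = atlas  # labels 1..n_regions
    values[mask] = base_mean + offsets[region_of[mask] - 1]

    if texture_amp > 0:
        vpc = cube_edge**3
        T = _texture_templates(loading_matrix.shape[1], vpc, texture_seed)
        dom = _region_factor(loading_matrix)
        amp = texture_amp * np.maximum(0.1, 1.0 + texture_gain * offsets)
        # paint the template tile-aligned with the cube grid
        tex = np.zeros(atlas.shape, dtype=float)
        sx, sy, sz = atlas.shape
        ex, ey, ez = (sx // cube_edge) * cube_edge, (sy // cube_edge) * cube_edge, (sz // cube_edge) * cube_edge
        for f in range(loading_matrix.shape[1]):
            tile = T[f].reshape(cube_edge, cube_edge, cube_edge)
            full = np.tile(
                tile, (ex // cube_edge, ey // cube_edge, ez // cube_edge)
            )
            sel = np.zeros(atlas.shape, dtype=bool)
            sel[:ex, :ey, :ez] = True
            in_f = mask & sel & np.isin(atlas, np.flatnonzero(dom == f) + 1)
            tex[in_f] = full[in_f[:ex, :ey, :ez]]
        values[mask] += (amp[region_of[mask] - 1]) * tex[mask]

    if voxel_noise_sd > 0:
        noise = rng.normal(0.0, voxel_noise_sd, size=atlas.shape)
        values[mask] += noise[mask]
    np.clip(values, 0.0, 1.0, out=values)
    return GrayMatterVolume(values=values, mask=mask)


def _censoring_rate(event_times: np.ndarray, target: float) -> float:
    """Exponential censoring rate hitting the target fraction, by bisection.

    P(censored) = E[1 - exp(-rate * T)] over the realized event times.
    """
    if target <= 0:
        return 0.0

    def frac(rate: float) -> float:
        return float(np.mean(-np.expm1(-rate * event_times)))

    lo, hi = 1e-12, 1.0
    while frac(hi) < target:
        hi *= 10.0
        if hi > 1e9:
            break
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if frac(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_survival(
    latent_factors: np.ndarray,
    beta_true: np.ndarray,
    baseline_shape: float,
    baseline_scale: float,
    target_censoring: float,
    seed: int,
) -> pd.DataFrame:
    """Weibull proportional-hazards times with independent right censoring.

    The hazard is h0(t)·exp(f·β) with Weibull baseline; event time
    T = scale · (−ln U · e^{−f·β})^{1/shape}. Censoring is exponential
    with rate calibrated by bisection so the realized censored fraction
    matches ``target_censoring``. Returns columns ``time_months`` (> 0)
    and ``event`` (1 = death observed).
    """
    if baseline_shape <= 0 or baseline_scale <= 0:
        raise ValueError("baseline parameters must be positive")
    if not (0.0 <= target_censoring < 1.0):
        raise ValueError("target_censoring must lie in [0, 1)")
    latent_factors = np.atleast_2d(np.asarray(latent_factors, dtype=float))
    beta_true = np.asarray(beta_true, dtype=float)
    rng = np.random.default_rng(seed)
    eta = latent_factors @ beta_true
    u = rng.uniform(size=eta.shape[0])
    t_event = baseline_scale * (-np.log(u) * np.exp(-eta)) ** (1.0 / baseline_shape)
    t_event = np.maximum(t_event, 1e-9)
    if target_censoring == 0:
        time, event = t_event, np.ones(eta.shape[0], dtype=bool)
    else:
        rate = _censoring_rate(t_event, target_censoring)
        t_cens = rng.exponential(1.0 / rate, size=eta.shape[0])
        event = t_event <= t_cens
        time = np.minimum(t_event, t_cens)
    return pd.DataFrame({"time_months": time, "event": event.astype(int)})


def generate_clinical_table(n_subjects: int, seed: int) -> pd.DataFrame:
    """Clinical covariates with standard neuro-oncology coding.

    Codes: tumor_location 1=occipital, 2=parietal, 3=temporal, 4=frontal;
    laterality 1=left, 0=right; multifocal 1=yes; grade ∈ {2,3,4};
    histology 1=astrocytoma, 2=oligodendroglioma, 3=oligoastrocytoma;
    resection 1=gross total, 2=subtotal, 3=biopsy; age in years; sex
    1=male, 0=female. Drawn independently of the latent factors, so in a
    synthetic cohort the clinical design is uninformative by construction.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "tumor_location": rng.integers(1, 5, n_subjects),
            "laterality": rng.integers(0, 2, n_subjects),
            "multifocal": (rng.uniform(size=n_subjects) < 0.15).astype(int),
            "grade": rng.choice([2, 3, 4], n_subjects),
            "histology": rng.choice([1, 2, 3], n_subjects),
            "resection": rng.choice([1, 2, 3], n_subjects),
            "age_years": np.clip(rng.normal(44.0, 15.0, n_subjects), 18.0, 82.0),
            "sex": rng.integers(0, 2, n_subjects),
        }
    )
    df.index.name = "subject_id"
    return df


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Full synthetic cohort: atlas, volumes, factors, survival, clinical."""
    rng = np.random.default_rng(spec.seed)
    atlas = generate_atlas(
        spec.volume_shape, spec.n_regions, seed=spec.seed, margin=spec.margin
    )
    factors = rng.standard_normal((spec.n_subjects, spec.latent_dim))
    child_seeds = rng.integers(0, 2**31 - 1, size=spec.n_subjects + 2)
    volumes = [
        generate_subject_volume(
            atlas,
            factors[i],
            spec.loading_matrix,
            spec.voxel_noise_sd,
            seed=int(child_seeds[i]),
            base_mean=spec.base_mean,
            texture_amp=spec.texture_amp,
            texture_gain=spec.texture_gain,
            texture_seed=spec.seed,
        )
        for i in range(spec.n_subjects)
    ]
    survival = generate_survival(
        factors,
        spec.beta_true,
        spec.baseline_shape,
        spec.baseline_scale,
        spec.target_censoring,
        seed=int(child_seeds[-2]),
    )
    survival.index.name = "subject_id"
    clinical = generate_clinical_table(spec.n_subjects, seed=int(child_seeds[-1]))
    return SyntheticCohort(
        volumes=volumes,
        atlas=atlas,
        latent_factors=factors,
        survival=survival,
        clinical=clinical,
        spec=spec,
    )


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> Path:
    """Write NIfTI volumes + atlas, CSV tables, and a manifest CSV.

    Returns the manifest path. The manifest links subject_id to the
    per-subject volume file; atlas, clinical and survival paths are shared.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4)
    nib.save(nib.Nifti1Image(cohort.atlas.astype(np.int32), affine), out / "atlas.nii")
    rows = []
    for i, vol in enumerate(cohort.volumes):
        p = out / f"subject_{i:04d}_gm.nii"
        nib.save(nib.Nifti1Image(vol.values.astype(np.float32), affine), p)
        rows.append({"subject_id": i, "volume_path": p.name})
    cohort.clinical.to_csv(out / "clinical.csv")
    cohort.survival.to_csv(out / "survival.csv")
    manifest = pd.DataFrame(rows)
    manifest_path = out / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    return manifest_path
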