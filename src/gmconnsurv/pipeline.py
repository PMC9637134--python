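"""End-to-end orchestration across model designs.

A run extracts per-subject connectome features and regional gray-matter
volumes, assembles the requested design matrices (clinical, clinical+,
connectome, post-hoc combinations, regional volumes, optional external
feature tables such as precomputed radiomics), cross-validates a ridge
Cox model per design with shared fold partitions, scores each fold by
integrated time-dependent AUC, and compares designs pairwise.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time as _time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .connectome import (
    connectome_feature_names,
    regional_gray_matter_volumes,
    subject_connectome_features,
)
from .evaluation import (
    compare_model_aucs,
    cross_validated_iauc,
    kaplan_meier,
)
from .survival import cross_validate_design, fold_coefficient_table
from .synthetic import (
    CLINICAL_COLUMNS,
    PRESURGICAL_COLUMNS,
    CohortSpec,
    GrayMatterVolume,
    SyntheticCohort,
    generate_cohort,
)

logger = logging.getLogger("gmconnsurv")

KNOWN_DESIGNS = (
    "clinical",
    "clinical_plus",
    "connectome",
    "radiomic",
    "connectome_clinical",
    "connectome_clinical_plus",
    "gm_volumes",
)

CLINICAL_RANGES = {
    "tumor_location": (1, 4),
    "laterality": (0, 1),
    "multifocal": (0, 1),
    "grade": (2, 4),
    "histology": (1, 3),
    "resection": (1, 3),
    "sex": (0, 1),
}


@dataclass
class RunConfig:
    """Everything needed to reproduce a run."""

    mode: str = "synthetic"  # or "real"
    output_dir: str = "gmconnsurv_out"
    designs: tuple[str, ...] = ("clinical", "clinical_plus", "connectome", "gm_volumes")
    # connectome parameters
    cube_edge: int = 3
    min_mask_fraction: float = 0.5
    fdr_alpha: float = 0.05
    n_permutations: int = 20
    reconnect_policy: str = "relax"
    maximize_over_rotations: bool = False
    # model parameters
    lam: float = 1.0
    k_folds: int = 10
    seed: int = 0
    # real-mode inputs
    manifest: str | None = None
    atlas_path: str | None = None
    clinical_path: str | None = None
    survival_path: str | None = None
    # synthetic-mode cohort conditions
    cohort: dict = field(default_factory=dict)
    # design_id -> CSV path of precomputed features (e.g. radiomics)
    external_tables: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if not (0.0 < self.fdr_alpha < 1.0):
            raise ValueError("fdr_alpha must lie in (0, 1)")
        unknown = set(self.designs) - set(KNOWN_DESIGNS)
        if unknown:
            raise ValueError(f"unknown designs: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "designs" in raw:
            raw["designs"] = tuple(raw["designs"])
        return cls(**raw)

    def content_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunResult:
    feature_tables: dict[str, pd.DataFrame]
    fold_auc: pd.DataFrame  # models × folds
    comparisons: pd.DataFrame
    km_median_months: float | None
    coefficient_tables: dict[str, pd.DataFrame]
    provenance: dict


def validate_clinical(clinical: pd.DataFrame) -> None:
    missing = [c for c in CLINICAL_COLUMNS if c not in clinical.columns]
    if missing:
        raise ValueError(f"clinical table missing columns: {missing}")
    for col, (lo, hi) in CLINICAL_RANGES.items():
        bad = ~clinical[col].between(lo, hi)
        if bad.any():
            raise ValueError(
                f"clinical column {col!r} outside [{lo}, {hi}] for subjects "
                f"{clinical.index[bad].tolist()}"
            )
    if (clinical["age_years"] <= 0).any():
        raise ValueError("age_years must be positive")


def build_design_matrix(
    design_id: str,
    clinical: pd.DataFrame | None = None,
    connectome_features: pd.DataFrame | None = None,
    regional_volumes: pd.DataFrame | None = None,
    external_tables: dict[str, pd.DataFrame] | None = None,
) -> pd.DataFrame:
    """Assemble the named feature design with a fixed column order.

    clinical → 5 presurgical covariates; clinical_plus → all 8;
    connectome → n_regions + 3; connectome_clinical(+) → concatenations;
    gm_volumes → n_regions regional volumes; any other design must be
    supplied as an external table.
    """
    external_tables = external_tables or {}

    def need(obj, what):
        if obj is None:
            raise ValueError(f"design {design_id!r} requires {what}")
        return obj

    if design_id == "clinical":
        return need(clinical, "a clinical table")[list(PRESURGICAL_COLUMNS)].copy()
    if design_id == "clinical_plus":
        return need(clinical, "a clinical table")[list(CLINICAL_COLUMNS)].copy()
    if design_id == "connectome":
        return need(connectome_features, "connectome features").copy()
    if design_id == "gm_volumes":
        return need(regional_volumes, "regional gray-matter volumes").copy()
    if design_id == "connectome_clinical":
        conn = need(connectome_features, "connectome features")
        clin = need(clinical, "a clinical table")[list(PRESURGICAL_COLUMNS)]
        return pd.concat([conn, clin], axis=1)
    if design_id == "connectome_clinical_plus":
        conn = need(connectome_features, "connectome features")
        clin = need(clinical, "a clinical table")[list(CLINICAL_COLUMNS)]
        return pd.concat([conn, clin], axis=1)
    if design_id in external_tables:
        return external_tables[design_id].copy()
    raise ValueError(
        f"design {design_id!r} needs an external feature table and none was given"
    )


def extract_cohort_features(
    volumes: Sequence[GrayMatterVolume],
    atlas: np.ndarray,
    config: RunConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Connectome feature table and regional-volume table for a cohort."""
    n_regions = int(atlas.max())
    rng = np.random.default_rng(config.seed + 7919)
    subj_seeds = rng.integers(0, 2**31 - 1, size=len(volumes))
    conn_rows, vol_rows = [], []
    t0 = _time.perf_counter()
    for i, vol in enumerate(volumes):
        fv = subject_connectome_features(
            vol,
            atlas,
            cube_edge=config.cube_edge,
            min_mask_fraction=config.min_mask_fraction,
            fdr_alpha=config.fdr_alpha,
            n_permutations=config.n_permutations,
            reconnect_policy=config.reconnect_policy,
            seed=int(subj_seeds[i]),
            maximize_over_rotations=config.maximize_over_rotations,
        )
        conn_rows.append(fv.to_array())
        vol_rows.append(regional_gray_matter_volumes(vol, atlas))
        if (i + 1) % 50 == 0:
            logger.info(
                "features: %d/%d subjects (%.1fs)",
                i + 1,
                len(volumes),
                _time.perf_counter() - t0,
            )
    conn = pd.DataFrame(conn_rows, columns=connectome_feature_names(n_regions))
    vols = pd.DataFrame(
        vol_rows, columns=[f"gmvol_r{r:03d}" for r in range(1, n_regions + 1)]
    )
    conn.index.name = vols.index.name = "subject_id"
    return conn, vols


def load_inputs(
    manifest: str | Path,
    atlas_path: str | Path,
    clinical_path: str | Path,
    survival_path: str | Path,
) -> tuple[list[GrayMatterVolume], np.ndarray, pd.DataFrame, pd.DataFrame]:
    """Load and align a real (or serialized synthetic) cohort by subject id."""
    man = pd.read_csv(manifest)
    if "subject_id" not in man.columns or "volume_path" not in man.columns:
        raise ValueError("manifest must have subject_id and volume_path columns")
    clinical = pd.read_csv(clinical_path, index_col="subject_id")
    surv = pd.read_csv(survival_path, index_col="subject_id")
    ids = man["subject_id"].tolist()
    for name, table in (("clinical", clinical), ("survival", surv)):
        missing = sorted(set(ids) - set(table.index))
        if missing:
            raise ValueError(f"{name} table missing subjects: {missing}")
    validate_clinical(clinical.loc[ids])
    if (surv.loc[ids, "time_months"] <= 0).any():
        raise ValueError("survival times must be positive")
    atlas_img = nib.load(str(atlas_path))
    atlas = np.asarray(atlas_img.dataobj).astype(np.int32)
    base = Path(manifest).parent
    volumes = []
    for p in man["volume_path"]:
        path = Path(p)
        if not path.is_absolute():
            path = base / path
        img = nib.load(str(path))
        vals = np.asarray(img.dataobj, dtype=float)
        zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
        volumes.append(
            GrayMatterVolume(values=vals, voxel_size_mm=zooms, mask=atlas > 0)
        )
    return volumes, atlas, clinical.loc[ids], surv.loc[ids]


def run_analysis(
    config: RunConfig,
    cohort: SyntheticCohort | None = None,
    write: bool = True,
) -> RunResult:
    """Execute the full pipeline for every requested design.

    All randomness derives from ``config.seed``. Fold partitions are
    shared across designs so per-fold AUCs are paired for comparison.
    """
    if config.mode == "synthetic":
        if cohort is None:
            spec = CohortSpec(**{"seed": config.seed, **config.cohort})
            cohort = generate_cohort(spec)
        volumes, atlas = cohort.volumes, cohort.atlas
        clinical, surv = cohort.clinical, cohort.survival
    elif config.mode == "real":
        for name in ("manifest", "atlas_path", "clinical_path", "survival_path"):
            if getattr(config, name) is None:
                raise ValueError(f"real mode requires config.{name}")
        volumes, atlas, clinical, surv = load_inputs(
            config.manifest, config.atlas_path, config.clinical_path, config.survival_path
        )
    else:
        raise ValueError(f"unknown mode {config.mode!r}")

    time_m = surv["time_months"].to_numpy(float)
    event = surv["event"].to_numpy(int).astype(bool)

    needs_volumes = bool(
        {"connectome", "connectome_clinical", "connectome_clinical_plus", "gm_volumes"}
        & set(config.designs)
    )
    conn_feats = reg_vols = None
    if needs_volumes:
        logger.info("extracting connectome features for %d subjects", len(volumes))
        conn_feats, reg_vols = extract_cohort_features(volumes, atlas, config)

    external = {
        k: pd.read_csv(v, index_col="subject_id")
        for k, v in config.external_tables.items()
    }

    feature_tables: dict[str, pd.DataFrame] = {}
    fold_auc_rows = {}
    coef_tables = {}
    for design in config.designs:
        X_df = build_design_matrix(
            design,
            clinical=clinical.reset_index(drop=True),
            connectome_features=conn_feats,
            regional_volumes=reg_vols,
            external_tables=external,
        )
        if X_df.isna().any().any():
            raise ValueError(f"design {design!r} contains missing values")
        feature_tables[design] = X_df
        results = cross_validate_design(
            X_df.to_numpy(float),
            time_m,
            event,
            k=config.k_folds,
            lam=config.lam,
            seed=config.seed,
            names=list(X_df.columns),
        )
        fold_auc_rows[design] = cross_validated_iauc(results, time_m, event)
        coef_tables[design] = fold_coefficient_table(results, list(X_df.columns))
        logger.info(
            "design %-24s p=%3d  iAUC %.3f ± %.3f",
            design,
            X_df.shape[1],
            fold_auc_rows[design].mean(),
            fold_auc_rows[design].std(ddof=1),
        )

    fold_auc = pd.DataFrame(
        fold_auc_rows, index=[f"fold_{i}" for i in range(config.k_folds)]
    ).T
    fold_auc.index.name = "model"
    comparisons = (
        compare_model_aucs(fold_auc) if len(config.designs) > 1 else pd.DataFrame()
    )
    km = kaplan_meier(time_m, event)
    provenance = {
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "version": __version__,
        "n_subjects": int(time_m.size),
        "designs": list(config.designs),
    }
    result = RunResult(
        feature_tables=feature_tables,
        fold_auc=fold_auc,
        comparisons=comparisons,
        km_median_months=km.median_months,
        coefficient_tables=coef_tables,
        provenance=provenance,
    )
    if write:
        write_run_result(result, surv, config)
    return result


def write_run_result(
    result: RunResult, surv: pd.DataFrame, config: RunConfig
) -> Path:
    """Write all output CSVs plus a JSON provenance file; returns out dir."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    fold_long = (
        result.fold_auc.reset_index()
        .melt(id_vars="model", var_name="fold", value_name="auc")
        .sort_values(["model", "fold"], kind="stable")
    )
    fold_long.to_csv(out / "fold_aucs.csv", index=False)
    if not result.comparisons.empty:
        result.comparisons.to_csv(out / "comparisons.csv", index=False)
    km = kaplan_meier(surv["time_months"], surv["event"])
    pd.DataFrame(
        {"time_months": km.times, "survival_prob": km.survival_prob}
    ).to_csv(out / "km_curve.csv", index=False)
    for design, table in result.feature_tables.items():
        table.to_csv(out / f"features_{design}.csv", index=True)
    for design, table in result.coefficient_tables.items():
        table.to_csv(out / f"coefficients_{design}.csv", index=False)
    with open(out / "provenance.json", "w") as fh:
        json.dump(result.provenance, fh, indent=2, sort_keys=True)
    return out
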