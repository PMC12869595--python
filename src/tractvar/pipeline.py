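"""Run configuration and stage orchestration.

A :class:`RunConfig` carries the statistical levels (FDR q, Bonferroni
alpha, outlier k, overlap thresholds), the synthetic-cohort settings, the
seed and the directories. ``run_pipeline`` executes
simulate -> spatial -> stats -> behavior, writing tidy CSVs whose first
line records the config hash and seed so every output is traceable to the
exact configuration that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior as beh_mod
from . import io as tio
from . import simulate as sim
from . import spatial as sp
from . import stats as st
from .registry import DEFAULT_EPOCHS, FEATURE_NAMES, load_pathway_registry

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "simulate_fixture", "spatial_stage",
           "stats_stage", "behavior_stage"]

# Bundles the fixture emits masks/fields for by default; mask generation for
# all 64 bundles is reserved for the full overlap analysis.
DEFAULT_MASK_PATHWAYS = ("AF_left", "AF_right", "CST_left", "CST_right", "CC_2")


@dataclass
class RunConfig:
    fixture_dir: str = "fixture"
    out_dir: str = "results"
    registry_path: str | None = None
    q: float = 0.05
    alpha: float = 0.05
    outlier_k: float = 4.0
    overlap_thresholds: tuple[float, ...] = (10.0, 50.0, 90.0)
    overlap_epoch: str = "young_adulthood"
    n_per_epoch: int = 10
    mask_pathways: tuple[str, ...] = DEFAULT_MASK_PATHWAYS
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.q < 1):
            raise ValueError(f"q must lie in (0, 1), got {self.q}")
        if not (0 < self.alpha < 1):
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.outlier_k <= 0:
            raise ValueError("outlier_k must be positive")
        for t in self.overlap_thresholds:
            if not (0 < t <= 100):
                raise ValueError(f"overlap threshold {t} outside (0, 100]")
        if self.n_per_epoch < 2:
            raise ValueError("n_per_epoch must be >= 2")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())
        doc["overlap_thresholds"] = tuple(doc.get("overlap_thresholds", (10, 50, 90)))
        doc["mask_pathways"] = tuple(doc.get("mask_pathways", DEFAULT_MASK_PATHWAYS))
        cfg = cls(**doc)
        cfg.validate()
        return cfg

    def hash(self) -> str:
        canonical = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:12]

    def provenance(self) -> str:
        return f"config_hash={self.hash()} seed={self.seed}"

    def synthetic(self) -> sim.SyntheticConfig:
        return sim.SyntheticConfig(n_per_epoch=self.n_per_epoch, seed=self.seed)


def simulate_fixture(config: RunConfig) -> Path:
    """Emit a complete fixture directory: tables, ground truth, masks, fields."""
    config.validate()
    scfg = config.synthetic()
    registry = load_pathway_registry(config.registry_path)
    fixture = Path(config.fixture_dir)
    fixture.mkdir(parents=True, exist_ok=True)

    subjects = sim.make_cohort(scfg)
    table, truth = sim.make_feature_table(subjects, registry, scfg)
    behavior, btruth = sim.make_behavior_table(subjects, table, scfg)
    truth.behavior_coefficients = btruth.behavior_coefficients

    subj_df = pd.DataFrame(
        [dataclasses.asdict(s) for s in subjects],
        columns=["subject_id", "age", "sex", "cohort", "epoch"],
    )
    prov = config.provenance()
    tio.write_table(subj_df, fixture / "subjects.csv", prov)
    tio.write_table(
        table[["subject_id", "pathway", "feature", "value"]],
        fixture / "features.csv", prov,
    )
    tio.write_table(behavior, fixture / "behavior.csv", prov)
    truth.to_json(fixture / "ground_truth.json")

    by_name = {r.name: r for r in registry}
    mask_dir = fixture / "masks"
    field_dir = fixture / "fields"
    mask_dir.mkdir(exist_ok=True)
    field_dir.mkdir(exist_ok=True)
    for name in config.mask_pathways:
        if name not in by_name:
            raise ValueError(f"mask pathway {name!r} not in registry")
        pdir = mask_dir / name
        pdir.mkdir(exist_ok=True)
        masks = sim.make_tract_masks(subjects, by_name[name], scfg)
        for sid, mask in masks.items():
            tio.write_volume(mask, pdir / f"{sid}.nii.gz")
    fields = sim.make_displacement_fields(subjects, scfg)
    for sid, fld in fields.items():
        tio.write_volume(fld, field_dir / f"{sid}.nii.gz")
    logger.info("fixture written to %s", fixture)
    return fixture


def spatial_stage(config: RunConfig) -> Path:
    """Displacement and overlap summaries from a fixture directory."""
    config.validate()
    fixture = Path(config.fixture_dir)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    subjects = tio.read_table(fixture / "subjects.csv")
    prov = config.provenance()

    mags = {}
    for path in sorted((fixture / "fields").glob("*.nii*")):
        sid = path.name.split(".")[0]
        mags[sid] = sp.displacement_magnitude(tio.read_volume(path))

    disp_rows, overlap_rows = [], []
    for pdir in sorted((fixture / "masks").iterdir()):
        masks = {
            p.name.split(".")[0]: tio.read_volume(p, kind="mask")
            for p in sorted(pdir.glob("*.nii*"))
        }
        if len(masks) < 2:
            continue
        stack = list(masks.values())
        pmap = sp.probabilistic_map(stack)
        mean_vol = float(np.mean([sp.mask_volume(m) for m in stack]))
        for thr in config.overlap_thresholds:
            overlap_rows.append(
                {
                    "pathway": pdir.name,
                    "threshold": thr,
                    "overlap_index": sp.overlap_index(pmap, thr, mean_vol),
                    "mean_volume_mm3": mean_vol,
                    "n_subjects": len(masks),
                }
            )
        for sid, mask in masks.items():
            if sid in mags:
                disp_rows.append(
                    {
                        "pathway": pdir.name,
                        "subject_id": sid,
                        "mean_displacement_mm": sp.bundle_mean_displacement(
                            mags[sid], mask
                        ),
                    }
                )
    tio.write_table(pd.DataFrame(overlap_rows), out / "overlap_indices.csv", prov)
    disp_df = pd.DataFrame(disp_rows)
    if not disp_df.empty:
        disp_df = disp_df.merge(
            subjects[["subject_id", "epoch", "cohort"]], on="subject_id"
        )
    tio.write_table(disp_df, out / "bundle_displacement.csv", prov)
    return out


def stats_stage(config: RunConfig) -> Path:
    """Asymmetry, lifespan and population-variability scans for every feature."""
    config.validate()
    registry = load_pathway_registry(config.registry_path)
    table, _, _ = tio.read_tables(config.fixture_dir)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov = config.provenance()
    features = [f for f in FEATURE_NAMES if f in set(table["feature"])]

    asym = pd.concat(
        [st.asymmetry_scan(table, f, registry=registry, q=config.q) for f in features],
        ignore_index=True,
    )
    life = pd.concat(
        [st.lifespan_scan(table, f, q=config.q) for f in features], ignore_index=True
    )
    var_asym = pd.concat(
        [
            st.variance_asymmetry_scan(
                table, f, config.overlap_epoch, registry=registry, q=config.q
            )
            for f in features
        ],
        ignore_index=True,
    )
    sd_prof = pd.concat(
        [
            st.population_sd_profile(table, f, config.overlap_epoch, registry=registry)
            for f in features
        ],
        ignore_index=True,
    )
    tio.write_table(asym, out / "asymmetry_tests.csv", prov)
    tio.write_table(life, out / "lifespan_tests.csv", prov)
    tio.write_table(var_asym, out / "variance_asymmetry_tests.csv", prov)
    tio.write_table(sd_prof, out / "population_sd.csv", prov)
    return out


def behavior_stage(config: RunConfig) -> Path:
    """The structure-function regression grid."""
    config.validate()
    registry = load_pathway_registry(config.registry_path)
    table, _, behavior = tio.read_tables(config.fixture_dir)
    if behavior is None:
        raise FileNotFoundError("behavior.csv missing from fixture directory")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scan = beh_mod.BehaviorScan(
        alpha=config.alpha, outlier_k=config.outlier_k, registry=registry
    )
    scan.fit(table, behavior)
    prov = config.provenance()
    tio.write_table(scan.results_, out / "behavior_regressions.csv", prov)
    for b in scan.behaviors:
        grid = scan.grid(b).reset_index()
        tio.write_table(grid, out / f"behavior_grid_{b}.csv", prov)
    return out


_STAGES = (
    ("simulate", simulate_fixture),
    ("spatial", spatial_stage),
    ("stats", stats_stage),
    ("behavior", behavior_stage),
)


def run_pipeline(config: RunConfig, simulate: bool = True) -> Path:
    """Execute all stages; a stage failure aborts naming the stage."""
    config.validate()
    for name, fn in _STAGES:
        if name == "simulate" and not simulate:
            continue
        try:
            fn(config)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    return Path(config.out_dir)
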