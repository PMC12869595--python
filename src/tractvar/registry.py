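"""Canonical definitions of pathways, lifespan epochs, features, and subjects.

The default registry describes 64 white-matter bundles (TractSeg
nomenclature) in six anatomical categories -- association, commissural,
thalamic, striatal, projection, cerebellar -- with left/right homologue
links and an anterior->posterior plotting rank. Lifespan ages are binned
into eight epochs, each drawn from a single acquisition cohort (Infant,
Development, YoungAdult, Aging), because cross-protocol comparisons are
confounded by scanner differences.
"""

from __future__ import annotations

import csv
import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import yaml

__all__ = [
    "PathwayRecord",
    "EpochRecord",
    "FeatureDef",
    "SubjectRecord",
    "RegistryError",
    "CATEGORIES",
    "DEFAULT_EPOCHS",
    "DEFAULT_FEATURES",
    "load_pathway_registry",
    "save_pathway_registry",
    "assign_epoch",
    "bilateral_pairs",
]

CATEGORIES = (
    "association",
    "commissural",
    "thalamic",
    "striatal",
    "projection",
    "cerebellar",
)

HEMISPHERES = ("left", "right", "midline")


class RegistryError(ValueError):
    """A registry file or record violates a structural invariant."""


@dataclass(frozen=True)
class PathwayRecord:
    """One white-matter bundle: identity, class, laterality, plot order."""

    name: str
    category: str
    hemisphere: str
    ap_rank: int
    homologue: str | None = None


@dataclass(frozen=True)
class EpochRecord:
    """A lifespan age bin [age_lo, age_hi) tied to one acquisition cohort."""

    name: str
    age_lo: float
    age_hi: float  # inf for the open-ended last epoch
    cohort: str


@dataclass(frozen=True)
class FeatureDef:
    name: str
    scale_kind: str  # microstructural | macrostructural
    units: str


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    age: float
    sex: str  # F | M
    cohort: str
    epoch: str


# Eight epochs, contiguous half-open intervals from birth; the last is
# open-ended. Cohort mapping is many-to-one (protocol per age range).
DEFAULT_EPOCHS: tuple[EpochRecord, ...] = (
    EpochRecord("early_infancy", 0.0, 2.0, "Infant"),
    EpochRecord("late_infancy", 2.0, 5.0, "Infant"),
    EpochRecord("childhood", 5.0, 12.0, "Development"),
    EpochRecord("adolescence", 12.0, 21.0, "Development"),
    EpochRecord("young_adulthood", 21.0, 35.0, "YoungAdult"),
    EpochRecord("middle_adulthood", 35.0, 55.0, "Aging"),
    EpochRecord("older_adulthood", 55.0, 75.0, "Aging"),
    EpochRecord("late_life", 75.0, float("inf"), "Aging"),
)

# The nine structural features: four DTI scalars, three NODDI scalars,
# and two volume measures (absolute and normalised to total brain volume).
DEFAULT_FEATURES: tuple[FeatureDef, ...] = (
    FeatureDef("FA", "microstructural", "dimensionless"),
    FeatureDef("MD", "microstructural", "mm^2/s"),
    FeatureDef("AD", "microstructural", "mm^2/s"),
    FeatureDef("RD", "microstructural", "mm^2/s"),
    FeatureDef("ICVF", "microstructural", "dimensionless"),
    FeatureDef("ISOVF", "microstructural", "dimensionless"),
    FeatureDef("OD", "microstructural", "dimensionless"),
    FeatureDef("volume", "macrostructural", "mm^3"),
    FeatureDef("volume_norm", "macrostructural", "dimensionless"),
)

MICRO_FEATURES = tuple(f.name for f in DEFAULT_FEATURES if f.scale_kind == "microstructural")
MACRO_FEATURES = tuple(f.name for f in DEFAULT_FEATURES if f.scale_kind == "macrostructural")
FEATURE_NAMES = tuple(f.name for f in DEFAULT_FEATURES)


def _validate(records: Sequence[PathwayRecord]) -> list[PathwayRecord]:
    names = [r.name for r in records]
    seen: set[str] = set()
    for n in names:
        if n in seen:
            raise RegistryError(f"duplicate pathway name: {n!r}")
        seen.add(n)
    by_name = {r.name: r for r in records}
    for r in records:
        if r.category not in CATEGORIES:
            raise RegistryError(f"{r.name}: unknown category {r.category!r}")
        if r.hemisphere not in HEMISPHERES:
            raise RegistryError(f"{r.name}: unknown hemisphere {r.hemisphere!r}")
        if r.hemisphere == "midline":
            if r.homologue is not None:
                raise RegistryError(f"{r.name}: midline pathway must not have a homologue")
            continue
        if r.homologue is None:
            raise RegistryError(f"{r.name}: lateralised pathway missing homologue")
        partner = by_name.get(r.homologue)
        if partner is None:
            raise RegistryError(f"{r.name}: homologue {r.homologue!r} not in registry")
        expected = "right" if r.hemisphere == "left" else "left"
        if partner.hemisphere != expected:
            raise RegistryError(
                f"{r.name}: homologue {partner.name} is {partner.hemisphere}, expected {expected}"
            )
        if partner.homologue != r.name:
            raise RegistryError(f"{r.name}: homologue link is not reciprocal")
    return list(records)


def _records_from_dicts(rows: Iterable[dict]) -> list[PathwayRecord]:
    out = []
    for row in rows:
        homol = row.get("homologue")
        if homol in ("", "None", None):
            homol = None
        out.append(
            PathwayRecord(
                name=str(row["name"]),
                category=str(row["category"]),
                hemisphere=str(row["hemisphere"]),
                ap_rank=int(row["ap_rank"]),
                homologue=homol,
            )
        )
    return out


def load_pathway_registry(config: str | Path | None = None) -> list[PathwayRecord]:
    """Load and validate a pathway registry.

    Without ``config`` the default 64-bundle registry shipped with the
    package is returned. ``config`` may be a YAML file (top-level key
    ``pathways``) or a CSV file with columns name, category, hemisphere,
    ap_rank, homologue.
    """
    if config is None:
        text = (
            importlib.resources.files("tractvar").joinpath("data/pathways.yaml").read_text()
        )
        rows = yaml.safe_load(text)["pathways"]
        return _validate(_records_from_dicts(rows))
    path = Path(config)
    if path.suffix.lower() in (".yaml", ".yml"):
        doc = yaml.safe_load(path.read_text())
        rows = doc["pathways"] if isinstance(doc, dict) else doc
    elif path.suffix.lower() == ".csv":
        with open(path, newline="") as fh:
            rows = list(csv.DictReader(fh))
    else:
        raise RegistryError(f"unsupported registry format: {path.suffix!r}")
    return _validate(_records_from_dicts(rows))


def save_pathway_registry(records: Sequence[PathwayRecord], path: str | Path) -> None:
    """Write a registry to YAML or CSV; inverse of :func:`load_pathway_registry`."""
    path = Path(path)
    rows = [
        {
            "name": r.name,
            "category": r.category,
            "hemisphere": r.hemisphere,
            "ap_rank": r.ap_rank,
            "homologue": r.homologue,
        }
        for r in records
    ]
    if path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump({"pathways": rows}, sort_keys=False))
    elif path.suffix.lower() == ".csv":
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(
                fh, fieldnames=["name", "category", "hemisphere", "ap_rank", "homologue"]
            )
            writer.writeheader()
            writer.writerows(rows)
    else:
        raise RegistryError(f"unsupported registry format: {path.suffix!r}")


def assign_epoch(age: float, epochs: Sequence[EpochRecord] = DEFAULT_EPOCHS) -> EpochRecord:
    """Return the unique epoch with age_lo <= age < age_hi.

    Ages are in years; negative ages are rejected. The final epoch is
    open-ended, so every non-negative age maps to exactly one epoch.
    """
    if not age >= 0:
        raise ValueError(f"age must be >= 0 years, got {age}")
    for ep in epochs:
        if ep.age_lo <= age < ep.age_hi:
            return ep
    raise ValueError(f"no epoch covers age {age}")  # unreachable with default epochs


def bilateral_pairs(records: Sequence[PathwayRecord]) -> list[tuple[PathwayRecord, PathwayRecord]]:
    """(left, right) homologue pairs, ordered by category then ap_rank."""
    by_name = {r.name: r for r in records}
    cat_order = {c: i for i, c in enumerate(CATEGORIES)}
    lefts = [r for r in records if r.hemisphere == "left"]
    lefts.sort(key=lambda r: (cat_order.get(r.category, 99), r.ap_rank, r.name))
    return [(r, by_name[r.homologue]) for r in lefts]


def base_name(pathway: str) -> str:
    """Strip a _left/_right suffix, giving the bilateral bundle name."""
    for suffix in ("_left", "_right"):
        if pathway.endswith(suffix):
            return pathway[: -len(suffix)]
    return pathway
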