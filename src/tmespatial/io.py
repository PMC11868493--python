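"""Cell-table and region I/O, marker-rule phenotyping, and IT/PT assignment.

The pipeline's atom is a segmented cell: an (x, y) centroid in micrometres
plus per-marker positivity flags and staining intensities. Tables travel as
plain CSV (comma-separated, UTF-8, header row, ``.`` decimal) with columns

    cell_id, sample_id, x_um, y_um, flag_<MARKER> (0/1), int_<MARKER>,
    [region_label], [phenotype]

Tissue regions travel as GeoJSON FeatureCollections whose features carry a
``region_label`` property in {IT, PT} (intratumoral tumor-nest area vs the
peritumoral stromal complement), with coordinates in micrometres.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

from .errors import ConfigError, InputError, SchemaError

REQUIRED_COLUMNS = ("cell_id", "sample_id", "x_um", "y_um")

#: Markers the pipeline knows about by default (others are allowed).
KNOWN_MARKERS = ("PanCK", "G9", "CD8", "CD4", "Tim3", "GzB", "RIPK1", "Beclin", "DAPI")

UNASSIGNED = "unassigned"


def flag_col(marker: str) -> str:
    return f"flag_{marker}"


def intensity_col(marker: str) -> str:
    return f"int_{marker}"


# ---------------------------------------------------------------------------
# cell tables
# ---------------------------------------------------------------------------

def read_cells(path) -> pd.DataFrame:
    """Read a cell table from CSV, validating schema and coordinate types.

    Unknown columns are preserved untouched. Raises :class:`SchemaError` when
    a required column is missing and :class:`InputError` (naming the first
    offending ``cell_id``) when a coordinate fails to parse as a number.
    """
    table = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"cell table is missing required column(s): {', '.join(missing)}")
    for coord in ("x_um", "y_um"):
        parsed = pd.to_numeric(table[coord], errors="coerce")
        bad = parsed.isna() & table[coord].notna()
        if bad.any():
            cid = table.loc[bad, "cell_id"].iloc[0]
            raise InputError(f"non-numeric {coord} for cell_id={cid}")
        if parsed.isna().any():
            cid = table.loc[parsed.isna(), "cell_id"].iloc[0]
            raise InputError(f"missing {coord} for cell_id={cid}")
        table[coord] = parsed.astype(float)
    for col in table.columns:
        if col.startswith("flag_"):
            table[col] = table[col].astype(int)
    if table.groupby("sample_id")["cell_id"].apply(lambda s: s.duplicated().any()).any():
        raise InputError("cell_id values must be unique within each sample")
    return table


def write_cells(table: pd.DataFrame, path) -> None:
    """Write a cell table to CSV (round-trips through :func:`read_cells`)."""
    table.to_csv(path, index=False)


def derive_flags(table: pd.DataFrame, thresholds: dict[str, float]) -> pd.DataFrame:
    """Derive 0/1 marker flags from intensities via per-marker thresholds.

    Opt-in only — flags are never derived silently. A marker's flag is 1 when
    ``int_<marker> >= threshold``. Returns a copy.
    """
    out = table.copy()
    for marker, thr in thresholds.items():
        col = intensity_col(marker)
        if col not in out.columns:
            raise SchemaError(f"cannot derive flag for {marker!r}: missing column {col!r}")
        out[flag_col(marker)] = (out[col] >= thr).astype(int)
    return out


# ---------------------------------------------------------------------------
# phenotyping
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhenotypeRule:
    """A marker-combination rule: all positives true and all negatives false.

    When several rules match one cell, the rule with the highest priority
    wins; priorities must be unique within a rule set.
    """

    name: str
    positive_markers: frozenset[str]
    negative_markers: frozenset[str] = field(default_factory=frozenset)
    priority: int = 0

    def __post_init__(self):
        object.__setattr__(self, "positive_markers", frozenset(self.positive_markers))
        object.__setattr__(self, "negative_markers", frozenset(self.negative_markers))
        if self.positive_markers & self.negative_markers:
            raise ConfigError(
                f"rule {self.name!r}: positive and negative marker sets overlap"
            )


#: Standard phenotype vocabulary: G9+/G9- tumor cells and the T-cell subsets.
DEFAULT_RULES = (
    PhenotypeRule("PanCK+G9+", {"PanCK", "G9"}, frozenset(), 100),
    PhenotypeRule("PanCK+G9-", {"PanCK"}, {"G9"}, 90),
    PhenotypeRule("CD8+Tim3+", {"CD8", "Tim3"}, {"PanCK"}, 70),
    PhenotypeRule("CD8+Tim3-", {"CD8"}, {"Tim3", "PanCK"}, 60),
    PhenotypeRule("CD4+", {"CD4"}, {"PanCK", "CD8"}, 50),
)

#: Alternative rule set for cytolytic-granule analyses (GzB+ CTLs vs tumor).
GZB_RULES = (
    PhenotypeRule("PanCK+G9+", {"PanCK", "G9"}, frozenset(), 100),
    PhenotypeRule("PanCK+G9-", {"PanCK"}, {"G9"}, 90),
    PhenotypeRule("CD8+GzB+", {"CD8", "GzB"}, {"PanCK"}, 80),
    PhenotypeRule("CD8+GzB-", {"CD8"}, {"GzB", "PanCK"}, 70),
)


def assign_phenotypes(table: pd.DataFrame, rules=DEFAULT_RULES) -> pd.DataFrame:
    """Label each cell with the highest-priority matching rule.

    Cells matching no rule receive ``"unassigned"``. The result is
    independent of row order and idempotent. Returns a copy.
    """
    rules = tuple(rules)
    names = [r.name for r in rules]
    if len(set(names)) != len(names):
        raise ConfigError("phenotype rule names must be unique")
    priorities = [r.priority for r in rules]
    if len(set(priorities)) != len(priorities):
        raise ConfigError("phenotype rule priorities must be unique")

    out = table.copy()
    labels = np.full(len(out), UNASSIGNED, dtype=object)
    # ascending priority, later (higher) rules overwrite earlier matches
    for rule in sorted(rules, key=lambda r: r.priority):
        mask = np.ones(len(out), dtype=bool)
        for marker in rule.positive_markers:
            col = flag_col(marker)
            if col not in out.columns:
                raise SchemaError(f"rule {rule.name!r} needs missing column {col!r}")
            mask &= out[col].to_numpy().astype(bool)
        for marker in rule.negative_markers:
            col = flag_col(marker)
            if col not in out.columns:
                raise SchemaError(f"rule {rule.name!r} needs missing column {col!r}")
            mask &= ~out[col].to_numpy().astype(bool)
        labels[mask] = rule.name
    out["phenotype"] = labels
    return out


# ---------------------------------------------------------------------------
# regions
# ---------------------------------------------------------------------------

@dataclass
class RegionGeometry:
    """Labeled IT/PT polygons for one sample, with areas in mm².

    IT is the tumor-nest area (pan-cytokeratin-positive epithelium); PT is
    its stromal complement within the imaged window.
    """

    sample_id: str
    polygons: dict[str, BaseGeometry]

    def __post_init__(self):
        for label, geom in self.polygons.items():
            if not geom.is_valid:
                raise InputError(f"region {label!r} polygon is not simple/valid")

    @property
    def areas_mm2(self) -> dict[str, float]:
        # coordinates are µm, so area is µm²; 1 mm² = 1e6 µm²
        return {label: geom.area / 1e6 for label, geom in self.polygons.items()}

    def to_geojson(self, path) -> None:
        features = []
        for label, geom in self.polygons.items():
            features.append(
                {
                    "type": "Feature",
                    "properties": {"region_label": label, "sample_id": self.sample_id},
                    "geometry": mapping(geom),
                }
            )
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({"type": "FeatureCollection", "features": features}, fh)

    @classmethod
    def from_geojson(cls, path) -> "RegionGeometry":
        with open(path, encoding="utf-8") as fh:
            collection = json.load(fh)
        polygons: dict[str, BaseGeometry] = {}
        sample_id = None
        for feat in collection.get("features", []):
            label = feat["properties"]["region_label"]
            sample_id = feat["properties"].get("sample_id", sample_id)
            geom = shape(feat["geometry"])
            polygons[label] = polygons[label].union(geom) if label in polygons else geom
        if sample_id is None:
            raise InputError(f"no features with a sample_id found in {path}")
        return cls(sample_id=str(sample_id), polygons=polygons)


def assign_regions(table: pd.DataFrame, geometry: RegionGeometry) -> pd.DataFrame:
    """Assign each cell an IT/PT label by point-in-polygon membership.

    Boundary points go to IT (deterministic tie rule, tumor-nest-centric);
    cells outside every polygon are labeled ``"unassigned"``. Returns a copy.
    """
    sample_ids = set(table["sample_id"].unique())
    if sample_ids and sample_ids != {geometry.sample_id}:
        raise InputError(
            f"sample_id mismatch: cells {sorted(sample_ids)} vs geometry "
            f"{geometry.sample_id!r}"
        )
    out = table.copy()
    pts = shapely.points(out["x_um"].to_numpy(), out["y_um"].to_numpy())
    labels = np.full(len(out), UNASSIGNED, dtype=object)
    # PT first, then IT overwrites, so shared IT/PT boundaries resolve to IT
    for label in ("PT", "IT"):
        if label in geometry.polygons:
            covered = shapely.covers(geometry.polygons[label], pts)
            labels[covered] = label
    out["region_label"] = labels
    n_out = int((labels == UNASSIGNED).sum())
    if n_out:
        warnings.warn(f"{n_out} cell(s) fall outside all region polygons", stacklevel=2)
    return out


def read_survival(path) -> pd.DataFrame:
    """Read a right-censored survival table (patient_id, time_months, event)."""
    table = pd.read_csv(path)
    missing = [c for c in ("patient_id", "time_months", "event") if c not in table.columns]
    if missing:
        raise SchemaError(f"survival table is missing column(s): {', '.join(missing)}")
    table["time_months"] = pd.to_numeric(table["time_months"])
    table["event"] = table["event"].astype(int)
    if (table["time_months"] < 0).any():
        raise InputError("negative time_months in survival table")
    return table
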