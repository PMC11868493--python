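"""Spatial statistics on segmented-cell tables.

Implements the quantities used to characterize tumor–immune cell geography
in multiplex IHC sections: phenotype densities per mm² in IT/PT regions,
reference-cell-to-nearest-neighbor distance sets (nucleus-to-nucleus,
Euclidean on centroids), cumulative proximity curves over 0–300 µm, the
"effective percentage" of reference cells whose nearest target lies within
an effective-contact radius (default 15 µm), nearest-other-phenotype
interaction matrices (the chord-diagram data structure), and across-sample
density–density correlations.

Conventions
-----------
* All radius/distance comparisons are inclusive (``<=``), so "within 15 µm"
  includes cells at exactly 15 µm and P(0) counts coincident centroids.
* Reference cells with no eligible neighbor stay in denominators: a
  "proportion of reference cells" is always over all reference cells.
* Distances are computed within a single sample; pooling across samples
  happens at the statistic level, never at the coordinate level.
* Equidistant neighbor ties resolve to the smallest ``cell_id``.

A k-d tree accelerates the searches; correctness is defined by (and tested
against) an O(n²) brute-force scan.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

from .errors import InputError
from .io import UNASSIGNED, RegionGeometry

DEFAULT_EFFECTIVE_RADIUS_UM = 15.0


# ---------------------------------------------------------------------------
# densities
# ---------------------------------------------------------------------------

def phenotype_density(
    cells: pd.DataFrame, geometry: RegionGeometry, phenotype: str, region: str
) -> float:
    """Cells of ``phenotype`` with ``region_label == region`` per mm² of region."""
    areas = geometry.areas_mm2
    if region not in areas:
        raise InputError(f"region {region!r} not present in geometry")
    area = areas[region]
    if area <= 0:
        raise InputError(f"region {region!r} has zero area")
    count = int(((cells["phenotype"] == phenotype) & (cells["region_label"] == region)).sum())
    return count / area


def density_table(cells: pd.DataFrame, geometry: RegionGeometry, phenotypes=None) -> pd.DataFrame:
    """Tidy per-phenotype, per-region density report for one sample."""
    if phenotypes is None:
        phenotypes = sorted(p for p in cells["phenotype"].unique() if p != UNASSIGNED)
    rows = []
    for phenotype in phenotypes:
        for region in geometry.polygons:
            if geometry.areas_mm2[region] <= 0:
                continue
            rows.append(
                {
                    "sample_id": geometry.sample_id,
                    "phenotype": phenotype,
                    "region": region,
                    "density_per_mm2": phenotype_density(cells, geometry, phenotype, region),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# nearest-neighbor distances
# ---------------------------------------------------------------------------

def _single_sample(cells: pd.DataFrame) -> str:
    ids = cells["sample_id"].unique()
    if len(ids) > 1:
        raise InputError(
            "spatial statistics operate on one sample at a time; "
            f"got sample_ids {sorted(map(str, ids))}"
        )
    return str(ids[0]) if len(ids) else ""


def _check_phenotype(cells: pd.DataFrame, phenotype: str) -> None:
    if phenotype not in set(cells["phenotype"].unique()):
        raise InputError(f"unknown phenotype {phenotype!r}: not present in cell table")


def _scope_filter(cells: pd.DataFrame, scope: str) -> pd.DataFrame:
    if scope in (None, "sample", "all"):
        return cells
    if scope in ("IT", "PT"):
        if "region_label" not in cells.columns:
            raise InputError(f"scope {scope!r} requires region labels; run assign_regions first")
        return cells[cells["region_label"] == scope]
    raise InputError(f"scope must be 'sample', 'IT' or 'PT', got {scope!r}")


@dataclass
class NNDistanceSet:
    """Per-reference-cell nearest-neighbor distances for one phenotype pair."""

    sample_id: str
    ref_phenotype: str
    neighbor_phenotype: str
    ref_cell_ids: np.ndarray  # reference cells that do have a neighbor
    neighbor_cell_ids: np.ndarray
    distances_um: np.ndarray
    n_ref_total: int

    @property
    def n_ref_with_neighbor(self) -> int:
        return len(self.distances_um)

    def median_um(self) -> float:
        """Median nucleus-to-nucleus distance (NaN when no pairs exist)."""
        return float(np.median(self.distances_um)) if len(self.distances_um) else float("nan")


def nn_distances(
    cells: pd.DataFrame,
    ref_phenotype: str,
    neighbor_phenotype: str,
    scope: str = "sample",
) -> NNDistanceSet:
    """For each reference cell, the Euclidean distance to its nearest
    neighbor cell of ``neighbor_phenotype`` within the same sample and scope.

    Reference cells with no neighbor (none of that phenotype in scope) are
    recorded only in ``n_ref_total``.
    """
    sample_id = _single_sample(cells)
    _check_phenotype(cells, ref_phenotype)
    _check_phenotype(cells, neighbor_phenotype)
    scoped = _scope_filter(cells, scope)
    ref = scoped[scoped["phenotype"] == ref_phenotype]
    nbr = scoped[scoped["phenotype"] == neighbor_phenotype]
    n_ref_total = len(ref)
    if n_ref_total == 0 or len(nbr) == 0:
        return NNDistanceSet(
            sample_id, ref_phenotype, neighbor_phenotype,
            np.empty(0, dtype=int), np.empty(0, dtype=int), np.empty(0), n_ref_total,
        )
    nbr_xy = nbr[["x_um", "y_um"]].to_numpy()
    nbr_ids = nbr["cell_id"].to_numpy()
    tree = cKDTree(nbr_xy)
    d, j = tree.query(ref[["x_um", "y_um"]].to_numpy(), k=1)
    nearest_ids = _tie_break_smallest_id(tree, ref[["x_um", "y_um"]].to_numpy(), d, j, nbr_ids)
    return NNDistanceSet(
        sample_id,
        ref_phenotype,
        neighbor_phenotype,
        ref["cell_id"].to_numpy(),
        nearest_ids,
        d.astype(float),
        n_ref_total,
    )


def _tie_break_smallest_id(tree, query_xy, d, j, ids) -> np.ndarray:
    """Resolve equidistant nearest neighbors to the smallest cell_id."""
    nearest = ids[j].copy()
    k = min(8, tree.n)
    if k > 1:
        dk, jk = tree.query(query_xy, k=k)
        for i in range(len(query_xy)):
            tied = jk[i][np.isclose(dk[i], d[i], rtol=0.0, atol=0.0)]
            if len(tied) > 1:
                nearest[i] = ids[tied].min()
    return nearest


# ---------------------------------------------------------------------------
# proximity curves
# ---------------------------------------------------------------------------

@dataclass
class ProximityCurve:
    """Cumulative proportion of reference cells with nearest neighbor <= d."""

    sample_id: str
    ref_phenotype: str
    neighbor_phenotype: str
    grid_um: np.ndarray
    proportion: np.ndarray
    n_ref_total: int

    def at(self, d_um: float) -> float:
        """Curve value at the largest grid point <= d_um."""
        idx = np.searchsorted(self.grid_um, d_um, side="right") - 1
        if idx < 0:
            raise InputError(f"distance {d_um} below curve grid start")
        return float(self.proportion[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_id,
                "ref_phenotype": self.ref_phenotype,
                "neighbor_phenotype": self.neighbor_phenotype,
                "distance_um": self.grid_um,
                "proportion": self.proportion,
            }
        )


def proximity_curve(
    nnset: NNDistanceSet, grid_step_um: float = 5.0, max_d_um: float = 300.0
) -> ProximityCurve:
    """Cumulative 0–300 µm profile of an :class:`NNDistanceSet`.

    The denominator is ``n_ref_total``: neighbor-less reference cells never
    enter the numerator but always count in the denominator.
    """
    if grid_step_um <= 0:
        raise InputError("grid_step_um must be > 0")
    if nnset.n_ref_total == 0:
        raise InputError("proximity curve undefined for an empty reference set")
    grid = np.arange(0.0, max_d_um + grid_step_um / 2, grid_step_um)
    d = np.sort(nnset.distances_um)
    counts = np.searchsorted(d, grid, side="right")  # inclusive <= d
    return ProximityCurve(
        nnset.sample_id,
        nnset.ref_phenotype,
        nnset.neighbor_phenotype,
        grid,
        counts / nnset.n_ref_total,
        nnset.n_ref_total,
    )


# ---------------------------------------------------------------------------
# effective percentage
# ---------------------------------------------------------------------------

@dataclass
class EffectiveStat:
    """Effective-contact statistics at radius r for reference sub-phenotypes.

    ``effective_fraction_pct`` maps each reference sub-phenotype to the
    percentage of its cells whose nearest target lies within r.
    ``composition_pct`` splits the pooled effective cells across the
    sub-phenotypes (100% total); it is None when no cell is effective.
    """

    sample_id: str
    target_phenotype: str
    radius_um: float
    n_ref: dict[str, int]
    n_effective: dict[str, int]
    effective_fraction_pct: dict[str, float]
    composition_pct: dict[str, float] | None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sub in self.n_ref:
            rows.append(
                {
                    "sample_id": self.sample_id,
                    "ref_phenotype": sub,
                    "target_phenotype": self.target_phenotype,
                    "radius_um": self.radius_um,
                    "n_ref": self.n_ref[sub],
                    "n_effective": self.n_effective[sub],
                    "effective_fraction_pct": self.effective_fraction_pct[sub],
                    "composition_pct": (
                        self.composition_pct[sub] if self.composition_pct else float("nan")
                    ),
                }
            )
        return pd.DataFrame(rows)


def effective_stat(
    cells: pd.DataFrame,
    ref_subphenotypes,
    target_phenotype: str,
    radius_um: float = DEFAULT_EFFECTIVE_RADIUS_UM,
    scope: str = "sample",
) -> EffectiveStat:
    """"Effective percentage": reference cells whose nearest target cell lies
    within ``radius_um`` (inclusive), per sub-phenotype and as a composition.
    """
    if radius_um < 0:
        raise InputError("radius_um must be >= 0")
    subs = list(ref_subphenotypes)
    if len(set(subs)) != len(subs):
        raise InputError("ref sub-phenotypes must be disjoint (unique names)")
    sample_id = _single_sample(cells)
    n_ref: dict[str, int] = {}
    n_eff: dict[str, int] = {}
    for sub in subs:
        nnset = nn_distances(cells, sub, target_phenotype, scope=scope)
        n_ref[sub] = nnset.n_ref_total
        n_eff[sub] = int((nnset.distances_um <= radius_um).sum())
    fractions = {
        sub: (100.0 * n_eff[sub] / n_ref[sub]) if n_ref[sub] else 0.0 for sub in subs
    }
    total_eff = sum(n_eff.values())
    composition = (
        {sub: 100.0 * n_eff[sub] / total_eff for sub in subs} if total_eff else None
    )
    return EffectiveStat(
        sample_id, target_phenotype, radius_um, n_ref, n_eff, fractions, composition
    )


# ---------------------------------------------------------------------------
# interaction matrix
# ---------------------------------------------------------------------------

@dataclass
class InteractionMatrix:
    """Counts of nearest-other-phenotype pairings (chord-diagram structure).

    ``matrix[p, q]`` is the number of cells of phenotype p whose nearest cell
    of *any other* phenotype has phenotype q; the diagonal is zero by
    construction. Row totals are the per-phenotype arc sizes.
    """

    sample_id: str
    phenotypes: list[str]
    matrix: np.ndarray

    @property
    def totals(self) -> dict[str, int]:
        return dict(zip(self.phenotypes, self.matrix.sum(axis=1).astype(int)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.phenotypes, columns=self.phenotypes)


def nn_interactions(cells: pd.DataFrame, phenotypes=None) -> InteractionMatrix:
    """For every cell, find its nearest cell *excluding its own phenotype*
    and tally the pairings into a phenotype-by-phenotype count matrix.
    """
    sample_id = _single_sample(cells)
    if phenotypes is None:
        phenotypes = sorted(p for p in cells["phenotype"].unique() if p != UNASSIGNED)
    phenotypes = list(phenotypes)
    sub = cells[cells["phenotype"].isin(phenotypes)]
    idx = {p: i for i, p in enumerate(phenotypes)}
    matrix = np.zeros((len(phenotypes), len(phenotypes)), dtype=int)
    present = [p for p in phenotypes if (sub["phenotype"] == p).any()]
    if len(present) < 2:
        warnings.warn(
            "fewer than two phenotypes present; interaction matrix is all zeros",
            stacklevel=2,
        )
        return InteractionMatrix(sample_id, phenotypes, matrix)
    labels = sub["phenotype"].to_numpy()
    xy = sub[["x_um", "y_um"]].to_numpy()
    ids = sub["cell_id"].to_numpy()
    for p in present:
        is_p = labels == p
        others = ~is_p
        tree = cKDTree(xy[others])
        d, j = tree.query(xy[is_p], k=1)
        other_labels = labels[others]
        other_ids = ids[others]
        nearest_ids = _tie_break_smallest_id(tree, xy[is_p], d, j, other_ids)
        # map tie-broken ids back to labels
        id_to_label = dict(zip(other_ids, other_labels))
        for nid in nearest_ids:
            matrix[idx[p], idx[id_to_label[nid]]] += 1
    return InteractionMatrix(sample_id, phenotypes, matrix)


# ---------------------------------------------------------------------------
# density correlations
# ---------------------------------------------------------------------------

@dataclass
class CorrelationResult:
    phenotype_a: str
    phenotype_b: str
    method: str
    n: int
    r: float
    p: float
    undefined: bool = False


def density_correlation(
    densities: pd.DataFrame, phenotype_pair: tuple[str, str], method: str = "pearson"
) -> CorrelationResult:
    """Across-sample correlation of two phenotype densities with two-tailed p.

    ``densities`` has one row per sample and one column per phenotype. A
    zero-variance vector yields an undefined-correlation flag, not a number.
    """
    if method not in ("pearson", "spearman"):
        raise InputError(f"method must be 'pearson' or 'spearman', got {method!r}")
    a, b = phenotype_pair
    for col in (a, b):
        if col not in densities.columns:
            raise InputError(f"phenotype column {col!r} not in density table")
    x = densities[a].to_numpy(dtype=float)
    y = densities[b].to_numpy(dtype=float)
    if len(x) < 3:
        raise InputError("density correlation requires >= 3 samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(a, b, method, len(x), float("nan"), float("nan"), True)
    if method == "pearson":
        res = stats.pearsonr(x, y)
    else:
        res = stats.spearmanr(x, y)
    return CorrelationResult(a, b, method, len(x), float(res.statistic), float(res.pvalue))
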