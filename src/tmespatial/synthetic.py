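"""Synthetic tissues, cohorts, killing assays, and expression panels.

Every downstream statistic in this package is testable without access to
clinical imaging data because these generators emit data with the exact
statistical structure the analyses assume:

* **Tissue** — tumor cells are a homogeneous Poisson process restricted to a
  union of circular tumor nests (the IT region); each tumor cell is G9+ with
  a configurable probability; immune cells are placed either uniformly in
  the window or "attracted" to a G9+ tumor cell (isotropic Gaussian
  displacement), with a tunable attracted fraction ρ and spread σ.
* **Cohort** — exponential survival times whose hazard is log-linear in a
  per-patient G9 level and intratumoral CD8 density, with administrative
  censoring.
* **Killing assay** — killed targets are a binomial thinning
  ``Binomial(T, k_max·(1 − exp(−(E/T)^γ)))``, which makes the expected
  per-capita killing efficacy strictly decreasing in the E:T ratio for
  γ ≤ 1.
* **Expression panels** — two patient groups drawn from zero-mean Gaussians
  with group-specific correlation matrices.

Reproducibility: each generator derives its own independent random stream
from the master seed via a fixed documented offset (tissue=0, cohort=1,
killing=2, expression=3), so adding draws to one generator never perturbs
another's output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point, box
from shapely.ops import unary_union

from .errors import ConfigError, InputError
from .io import RegionGeometry, flag_col, intensity_col

_STREAM_OFFSETS = {"tissue": 0, "cohort": 1, "killing": 2, "expression": 3}

#: Cancer-relevant gene panel used by the expression generator.
PANEL_GENES = ("LGALS9", "RIPK1", "RIPK3", "MLKL", "BECN1", "MAP1LC3B", "MTOR", "GZMB")


def stream(seed: int, name: str) -> np.random.Generator:
    """Independent random stream for one generator, derived from the master seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAM_OFFSETS[name],)))


# ---------------------------------------------------------------------------
# tissue
# ---------------------------------------------------------------------------

def _default_immune_counts() -> dict[str, int]:
    # Tim3- CTLs dominate the CD8 infiltrate in this tumor type
    return {"CD8+Tim3-": 300, "CD8+Tim3+": 80, "CD4+": 200}


def _default_intensity_params() -> dict[str, tuple[float, float]]:
    # log-median ≈ ln(0.05) AU with ~0.5 log-sd, typical of normalized mIHC
    return {m: (np.log(0.05), 0.5) for m in ("PanCK", "G9", "CD8", "CD4", "Tim3", "GzB", "DAPI")}


@dataclass
class TissueConfig:
    """Configuration for one synthetic multiplex-stained tissue sample."""

    window_width_um: float = 1500.0
    window_height_um: float = 1500.0
    nest_centers: tuple[tuple[float, float], ...] = ((400.0, 400.0), (1050.0, 700.0), (500.0, 1100.0))
    nest_radius_um: float = 250.0
    tumor_intensity_per_mm2: float = 2000.0
    p_g9_positive: float = 0.5
    immune_counts: dict[str, int] = field(default_factory=_default_immune_counts)
    attraction_fraction: float = 0.6
    attraction_sigma_um: float = 20.0
    p_gzb_positive: float = 0.5  # GzB+ fraction among CD8 cells
    intensity_lognorm_params: dict[str, tuple[float, float]] = field(
        default_factory=_default_intensity_params
    )
    sample_id: str = "S1"
    seed: int = 0

    def __post_init__(self):
        if self.window_width_um <= 0 or self.window_height_um <= 0:
            raise ConfigError("window dimensions must be > 0")
        if self.nest_radius_um <= 0:
            raise ConfigError("nest_radius_um must be > 0")
        if self.attraction_sigma_um <= 0:
            raise ConfigError("attraction_sigma_um must be > 0")
        if self.tumor_intensity_per_mm2 < 0:
            raise ConfigError("tumor_intensity_per_mm2 must be >= 0")
        for p, name in (
            (self.p_g9_positive, "p_g9_positive"),
            (self.attraction_fraction, "attraction_fraction"),
            (self.p_gzb_positive, "p_gzb_positive"),
        ):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        if any(n < 0 for n in self.immune_counts.values()):
            raise ConfigError("immune counts must be >= 0")


_PHENOTYPE_FLAGS = {
    "CD8+Tim3-": {"CD8": 1, "Tim3": 0},
    "CD8+Tim3+": {"CD8": 1, "Tim3": 1},
    "CD4+": {"CD4": 1},
}

_ALL_MARKERS = ("PanCK", "G9", "CD8", "CD4", "Tim3", "GzB", "DAPI")


def region_geometry(config: TissueConfig) -> RegionGeometry:
    """IT = union of nest disks (64-gon approximation), PT = window minus IT."""
    window = box(0.0, 0.0, config.window_width_um, config.window_height_um)
    # quad_segs=16 -> 64 segments per circle: exact polygon areas for densities
    disks = [Point(c).buffer(config.nest_radius_um, quad_segs=16) for c in config.nest_centers]
    it = unary_union(disks).intersection(window)
    pt = window.difference(it)
    return RegionGeometry(sample_id=config.sample_id, polygons={"IT": it, "PT": pt})


def _uniform_in_polygon(rng: np.random.Generator, geom, n: int) -> np.ndarray:
    """Uniform points inside a polygon by rejection from its bounding box."""
    if n == 0:
        return np.empty((0, 2))
    minx, miny, maxx, maxy = geom.bounds
    pts: list[np.ndarray] = []
    need = n
    while need > 0:
        m = max(4 * need, 64)
        x = rng.uniform(minx, maxx, m)
        y = rng.uniform(miny, maxy, m)
        keep = shapely.contains_xy(geom, x, y)
        accepted = np.column_stack([x[keep], y[keep]])[:need]
        pts.append(accepted)
        need -= len(accepted)
    return np.concatenate(pts)


def gen_tissue(config: TissueConfig) -> tuple[pd.DataFrame, RegionGeometry]:
    """Generate one synthetic tissue: a cell table plus IT/PT geometry.

    Returns ``(cells, regions)`` where ``cells`` has the standard cell-CSV
    columns and ``regions`` holds the IT/PT polygons with areas in mm².
    Fully reproducible from ``config.seed``.
    """
    rng = stream(config.seed, "tissue")
    geometry = region_geometry(config)
    it = geometry.polygons["IT"]
    window = box(0.0, 0.0, config.window_width_um, config.window_height_um)

    # --- tumor cells: homogeneous Poisson restricted to the IT region
    area_mm2 = it.area / 1e6
    n_tumor = rng.poisson(config.tumor_intensity_per_mm2 * area_mm2) if area_mm2 > 0 else 0
    tumor_xy = _uniform_in_polygon(rng, it, n_tumor)
    g9_flags = rng.random(n_tumor) < config.p_g9_positive
    g9_xy = tumor_xy[g9_flags]

    rows_xy = [tumor_xy]
    phenotype_of_rows = ["tumor"] * n_tumor

    # --- immune cells: attracted fraction anchors at a G9+ tumor cell
    immune_blocks: list[tuple[str, np.ndarray]] = []
    for phenotype, count in config.immune_counts.items():
        n_attr = int(round(config.attraction_fraction * count))
        if n_attr > 0 and len(g9_xy) == 0:
            warnings.warn(
                "attraction requested but no G9+ tumor cells exist; "
                "placing all immune cells uniformly",
                stacklevel=2,
            )
            n_attr = 0
        xy = np.empty((count, 2))
        if n_attr:
            anchors = g9_xy[rng.integers(0, len(g9_xy), n_attr)]
            placed = anchors + rng.normal(0.0, config.attraction_sigma_um, (n_attr, 2))
            # re-draw displacements that leave the window (max 100), then clip:
            # avoids the density pile-up that plain clipping causes at edges
            for _ in range(100):
                outside = ~shapely.contains_xy(window, placed[:, 0], placed[:, 1])
                # boundary counts as inside for our purposes
                outside &= ~(
                    (placed[:, 0] >= 0)
                    & (placed[:, 0] <= config.window_width_um)
                    & (placed[:, 1] >= 0)
                    & (placed[:, 1] <= config.window_height_um)
                )
                if not outside.any():
                    break
                k = int(outside.sum())
                placed[outside] = anchors[outside] + rng.normal(
                    0.0, config.attraction_sigma_um, (k, 2)
                )
            placed[:, 0] = np.clip(placed[:, 0], 0.0, config.window_width_um)
            placed[:, 1] = np.clip(placed[:, 1], 0.0, config.window_height_um)
            xy[:n_attr] = placed
        n_unif = count - n_attr
        if n_unif:
            xy[n_attr:, 0] = rng.uniform(0.0, config.window_width_um, n_unif)
            xy[n_attr:, 1] = rng.uniform(0.0, config.window_height_um, n_unif)
        immune_blocks.append((phenotype, xy))
        rows_xy.append(xy)
        phenotype_of_rows.extend([phenotype] * count)

    all_xy = np.concatenate(rows_xy) if rows_xy else np.empty((0, 2))
    n = len(all_xy)
    table = pd.DataFrame(
        {
            "cell_id": np.arange(n, dtype=int),
            "sample_id": config.sample_id,
            "x_um": all_xy[:, 0],
            "y_um": all_xy[:, 1],
        }
    )

    flags = {m: np.zeros(n, dtype=int) for m in _ALL_MARKERS}
    flags["DAPI"][:] = 1
    flags["PanCK"][:n_tumor] = 1
    flags["G9"][:n_tumor] = g9_flags.astype(int)
    offset = n_tumor
    for phenotype, xy in immune_blocks:
        count = len(xy)
        for marker, value in _PHENOTYPE_FLAGS[phenotype].items():
            flags[marker][offset : offset + count] = value
        if phenotype.startswith("CD8"):
            flags["GzB"][offset : offset + count] = (
                rng.random(count) < config.p_gzb_positive
            ).astype(int)
        offset += count
    for m in _ALL_MARKERS:
        table[flag_col(m)] = flags[m]

    # intensities: lognormal, positives bright, negatives ~4.5x dimmer
    for m in _ALL_MARKERS:
        mu, sd = config.intensity_lognorm_params.get(m, (np.log(0.05), 0.5))
        values = rng.lognormal(mu, sd, n)
        dim = rng.lognormal(mu - 1.5, sd, n)
        table[intensity_col(m)] = np.where(flags[m] == 1, values, dim)

    return table, geometry


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

@dataclass
class CohortConfig:
    """Exponential proportional-hazards cohort with administrative censoring."""

    n_patients: int = 92
    baseline_hazard_per_month: float = 0.005
    beta_g9: float = 0.7
    beta_cd8: float = -0.7
    admin_censor_months: float = 120.0
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 2:
            raise ConfigError("n_patients must be >= 2")
        if self.baseline_hazard_per_month <= 0:
            raise ConfigError("baseline_hazard_per_month must be > 0")
        if self.admin_censor_months < 0:
            raise ConfigError("admin_censor_months must be >= 0")


def gen_cohort(config: CohortConfig, covariates) -> pd.DataFrame:
    """Generate a right-censored survival table from per-patient covariates.

    ``covariates`` is an (n_patients, 2) array-like of (g9_level,
    cd8_density). Event times are exponential with hazard
    ``h0 * exp(beta_g9*g9 + beta_cd8*cd8)``; observed time is the minimum of
    the event time and the administrative censoring horizon.
    """
    cov = np.asarray(covariates, dtype=float)
    if cov.shape != (config.n_patients, 2):
        raise InputError(
            f"covariates must have shape ({config.n_patients}, 2), got {cov.shape}"
        )
    if not np.isfinite(cov).all():
        raise InputError("covariates must be finite")
    rng = stream(config.seed, "cohort")
    hazard = config.baseline_hazard_per_month * np.exp(
        config.beta_g9 * cov[:, 0] + config.beta_cd8 * cov[:, 1]
    )
    event_time = rng.exponential(1.0 / hazard)
    time = np.minimum(event_time, config.admin_censor_months)
    event = (event_time <= config.admin_censor_months).astype(int)
    return pd.DataFrame(
        {
            "patient_id": [f"P{i:04d}" for i in range(config.n_patients)],
            "time_months": time,
            "event": event,
            "g9_level": cov[:, 0],
            "cd8_density": cov[:, 1],
        }
    )


# ---------------------------------------------------------------------------
# killing assay
# ---------------------------------------------------------------------------

@dataclass
class KillingConfig:
    """Binomial-thinning killing assay across an effector-count sweep."""

    target_count: int = 200
    effector_grid: tuple[int, ...] = (100, 200, 1000)  # E:T of 0.5, 1, 5
    k_max: float = 0.8
    gamma: float = 0.7
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.target_count <= 0:
            raise ConfigError("target_count must be > 0")
        if any(e <= 0 for e in self.effector_grid):
            raise ConfigError("effector counts must be > 0")
        if not 0.0 < self.k_max <= 1.0:
            raise ConfigError("k_max must be in (0, 1]")
        if not 0.0 < self.gamma <= 1.0:
            raise ConfigError("gamma must be in (0, 1]")
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")


def expected_kill_probability(et_ratio, k_max: float, gamma: float):
    """Per-target death probability ``k_max · (1 − exp(−(E/T)^γ))``."""
    et = np.asarray(et_ratio, dtype=float)
    return k_max * (1.0 - np.exp(-(et**gamma)))


def gen_killing(config: KillingConfig) -> pd.DataFrame:
    """Generate killed-target counts for each effector count and replicate."""
    rng = stream(config.seed, "killing")
    rows = []
    for rep in range(config.n_replicates):
        for e in config.effector_grid:
            p = float(expected_kill_probability(e / config.target_count, config.k_max, config.gamma))
            killed = int(rng.binomial(config.target_count, p))
            rows.append(
                {
                    "replicate": rep,
                    "effector_count": e,
                    "target_count": config.target_count,
                    "killed_count": killed,
                    "et_ratio": e / config.target_count,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# expression panels
# ---------------------------------------------------------------------------

def _default_corr(planted: dict[tuple[str, str], float]) -> np.ndarray:
    mat = np.eye(len(PANEL_GENES))
    idx = {g: i for i, g in enumerate(PANEL_GENES)}
    for (a, b), r in planted.items():
        mat[idx[a], idx[b]] = mat[idx[b], idx[a]] = r
    return mat


def default_corr_high() -> np.ndarray:
    """Correlation structure of the cytolytically active (GzB-high) group:
    necroptosis genes anti-correlated with galectin-9, autophagy genes
    anti-correlated with each other, plus two conserved positive pairs."""
    return _default_corr(
        {
            ("LGALS9", "RIPK1"): -0.65,
            ("BECN1", "MAP1LC3B"): -0.65,
            ("MAP1LC3B", "RIPK1"): 0.4,
            ("BECN1", "MTOR"): 0.4,
            ("MTOR", "RIPK3"): 0.6,
        }
    )


def default_corr_low() -> np.ndarray:
    """GzB-low group: only the two conserved positive pairs remain."""
    return _default_corr({("MAP1LC3B", "RIPK1"): 0.5, ("BECN1", "MTOR"): 0.5})


@dataclass
class PanelConfig:
    """Two-group patient-by-gene expression panel with planted correlations."""

    genes: tuple[str, ...] = PANEL_GENES
    n_high: int = 5
    n_low: int = 6
    corr_high: np.ndarray = field(default_factory=default_corr_high)
    corr_low: np.ndarray = field(default_factory=default_corr_low)
    seed: int = 0

    def __post_init__(self):
        g = len(self.genes)
        for name, mat in (("corr_high", self.corr_high), ("corr_low", self.corr_low)):
            mat = np.asarray(mat, dtype=float)
            setattr(self, name, mat)
            if mat.shape != (g, g):
                raise ConfigError(f"{name} must be {g}x{g}")
            if not np.allclose(mat, mat.T):
                raise ConfigError(f"{name} must be symmetric")
            if not np.allclose(np.diag(mat), 1.0):
                raise ConfigError(f"{name} must have unit diagonal")
            if np.abs(mat).max() > 1.0 + 1e-12:
                raise ConfigError(f"{name} entries must be in [-1, 1]")
            if np.linalg.eigvalsh(mat).min() < -1e-10:
                raise ConfigError(f"{name} must be positive semi-definite")
        if self.n_high < 0 or self.n_low < 0:
            raise ConfigError("group sizes must be >= 0")


def _draw_group(rng: np.random.Generator, corr: np.ndarray, genes, n: int, label: str,
                start: int) -> pd.DataFrame:
    # eigen-decomposition factor handles semi-definite matrices too
    w, v = np.linalg.eigh(corr)
    factor = v * np.sqrt(np.clip(w, 0.0, None))
    z = rng.standard_normal((n, len(genes))) @ factor.T
    out = pd.DataFrame(z, columns=list(genes))
    out.insert(0, "patient_id", [f"E{start + i:04d}" for i in range(n)])
    out.insert(1, "group", label)
    return out


def gen_expression(config: PanelConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (high-group, low-group) patient-by-gene tables."""
    rng = stream(config.seed, "expression")
    high = _draw_group(rng, config.corr_high, config.genes, config.n_high, "GzB-high", 0)
    low = _draw_group(rng, config.corr_low, config.genes, config.n_low, "GzB-low", config.n_high)
    return high, low
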