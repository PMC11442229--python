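"""Synthetic four-way-cross data with known ground truth.

Generates the data structures the real study consumes — a composite linkage
map, four-way outbred genotype classes (AC/AD/BC/BD), multi-year spatially
structured phenotypes, and categorical berry-shape scores — from explicit
generative parameters, so downstream estimation can be checked against
truth.

Meiosis is modeled per parental gamete as a Markov chain along each linkage
group with Haldane recombination fractions (no crossover interference):
``r = (1 - exp(-2 d / 100)) / 2`` for adjacent markers ``d`` cM apart. The
maternal gamete carries allele A or B, the paternal gamete C or D; the
progeny genotype class is the pair.

The phenotype generator mirrors the across-year mixed model used for BLUP
estimation: a grand mean, fixed year effects, QTL contrast effects, an iid
polygenic genotype effect, genotype-by-year deviations, row and column
effects, a smooth two-dimensional spatial surface, and per-upright residual
noise. Every realized component is returned in a sidecar truth table whose
columns sum exactly to the emitted observation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GENOTYPE_CLASSES = ("AC", "AD", "BC", "BD")

MAP_COLUMNS = ["marker_id", "linkage_group", "position"]


def haldane_r(d_cm: np.ndarray | float) -> np.ndarray | float:
    """Recombination fraction for a map distance in cM (Haldane, no interference)."""
    return (1.0 - np.exp(-2.0 * np.asarray(d_cm, dtype=float) / 100.0)) / 2.0


def validate_map(lmap: pd.DataFrame) -> pd.DataFrame:
    """Check linkage-map invariants; returns the map sorted by (LG, position)."""
    missing = set(MAP_COLUMNS) - set(lmap.columns)
    if missing:
        raise ValueError(f"linkage map missing columns: {sorted(missing)}")
    if lmap["marker_id"].duplicated().any():
        raise ValueError("marker_ids must be unique")
    if (lmap["position"] < 0).any():
        raise ValueError("map positions must be non-negative")
    out = lmap.sort_values(["linkage_group", "position"], kind="stable").reset_index(drop=True)
    sizes = out.groupby("linkage_group").size()
    if (sizes < 2).any():
        raise ValueError("every linkage group needs at least 2 markers")
    return out


@dataclass(frozen=True)
class QtlEffect:
    """Ground-truth QTL: parental contrast effects at a map position."""

    linkage_group: int
    position: float
    maternal: float = 0.0
    paternal: float = 0.0
    interaction: float = 0.0


@dataclass
class TraitArchitecture:
    """Generative parameters for one trait (all variances in trait-units²)."""

    qtl: list[QtlEffect] = field(default_factory=list)
    polygenic_variance: float = 0.0
    gxy_variance: float = 0.0
    residual_variance: float = 1.0
    spatial_amplitude: float = 0.0
    row_variance: float = 0.0
    col_variance: float = 0.0
    mu: float = 0.0

    def __post_init__(self) -> None:
        for name in ("polygenic_variance", "gxy_variance", "residual_variance",
                     "row_variance", "col_variance"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def simulate_map(n_lg: int, markers_per_lg: int, length_cm: float,
                 seed: int, spacing: str = "uniform") -> pd.DataFrame:
    """Simulate a linkage map of ``n_lg`` groups with ``markers_per_lg`` markers each.

    ``spacing='uniform'`` places markers evenly on [0, length_cm];
    ``spacing='random'`` draws sorted uniform positions (endpoints pinned so
    each group spans its full length).
    """
    if n_lg < 1 or markers_per_lg < 2:
        raise ValueError("need n_lg >= 1 and markers_per_lg >= 2")
    if length_cm <= 0:
        raise ValueError("length_cm must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for lg in range(1, n_lg + 1):
        if spacing == "uniform":
            pos = np.linspace(0.0, length_cm, markers_per_lg)
        elif spacing == "random":
            pos = np.sort(rng.uniform(0.0, length_cm, markers_per_lg))
            pos[0], pos[-1] = 0.0, length_cm
        else:
            raise ValueError(f"unknown spacing {spacing!r}")
        for k, p in enumerate(pos, start=1):
            rows.append((f"LG{lg}_M{k:03d}", lg, float(p)))
    return pd.DataFrame(rows, columns=MAP_COLUMNS)


def _simulate_gamete(rng: np.random.Generator, n_progeny: int,
                     r: np.ndarray) -> np.ndarray:
    """Markov chain of gamete states (0/1) along one LG; r = adjacent recomb fracs."""
    n_mark = len(r) + 1
    states = np.empty((n_progeny, n_mark), dtype=np.int8)
    states[:, 0] = rng.integers(0, 2, size=n_progeny)
    if n_mark > 1:
        switches = rng.random((n_progeny, n_mark - 1)) < r[None, :]
        flips = (np.cumsum(switches, axis=1) % 2).astype(np.int8)
        states[:, 1:] = states[:, [0]] ^ flips
    return states


def simulate_cross(lmap: pd.DataFrame, n_progeny: int, seed: int) -> pd.DataFrame:
    """Simulate four-way cross genotype classes for every progeny × marker.

    Returns a wide DataFrame (index = progeny_id, columns = marker_id,
    values in {"AC","AD","BC","BD"}). Maternal (A/B) and paternal (C/D)
    gametes segregate independently.
    """
    if n_progeny < 1:
        raise ValueError("n_progeny must be >= 1")
    lmap = validate_map(lmap)
    rng = np.random.default_rng(seed)
    blocks = []
    for _, grp in lmap.groupby("linkage_group", sort=True):
        d = np.diff(grp["position"].to_numpy())
        r = haldane_r(d)
        mat = _simulate_gamete(rng, n_progeny, r)   # 0=A, 1=B
        pat = _simulate_gamete(rng, n_progeny, r)   # 0=C, 1=D
        classes = np.array([["AC", "AD"], ["BC", "BD"]])[mat, pat]
        blocks.append(pd.DataFrame(classes, columns=grp["marker_id"].to_numpy()))
    geno = pd.concat(blocks, axis=1)
    geno.index = pd.Index([f"G{i + 1:04d}" for i in range(n_progeny)], name="progeny_id")
    return geno


def make_layout(progeny_ids, n_cols: int = 20) -> pd.DataFrame:
    """Assign progeny to a rectangular field grid row-major (rows/cols 1-based)."""
    ids = list(progeny_ids)
    if n_cols < 1:
        raise ValueError("n_cols must be >= 1")
    rows = [(pid, i // n_cols + 1, i % n_cols + 1) for i, pid in enumerate(ids)]
    return pd.DataFrame(rows, columns=["progeny_id", "row", "col"])


def _spatial_surface(row: np.ndarray, col: np.ndarray, amplitude: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Smooth 2-D field trend: low-order polynomial plus a sinusoid.

    Deliberately contains both a straight-line component and curvature that
    row/column blocking cannot absorb, so spatial-model selection has
    something to find.
    """
    if amplitude == 0:
        return np.zeros_like(row, dtype=float)
    r = (row - row.mean()) / max(row.std(), 1.0)
    c = (col - col.mean()) / max(col.std(), 1.0)
    coef = rng.normal(0.0, 1.0, size=5)
    phase = rng.uniform(0, 2 * np.pi, size=2)
    surf = (coef[0] * r + coef[1] * c + coef[2] * r * c
            + coef[3] * np.sin(2 * np.pi * r / 3.0 + phase[0])
            + coef[4] * np.sin(2 * np.pi * c / 3.0 + phase[1]))
    return amplitude * surf / max(surf.std(), 1e-12)


def _qtl_genetic_values(geno: pd.DataFrame, lmap: pd.DataFrame,
                        arch: TraitArchitecture) -> np.ndarray:
    """Sum of QTL contrast effects per progeny, at each QTL's nearest marker."""
    total = np.zeros(len(geno))
    for q in arch.qtl:
        grp = lmap[lmap["linkage_group"] == q.linkage_group]
        if grp.empty:
            raise ValueError(f"QTL on unknown linkage group {q.linkage_group}")
        idx = (grp["position"] - q.position).abs().idxmin()
        calls = geno[lmap.loc[idx, "marker_id"]].to_numpy()
        mat = np.where(np.char.startswith(calls.astype(str), "A"), 0.5, -0.5)
        pat = np.where(np.char.endswith(calls.astype(str), "C"), 0.5, -0.5)
        total += q.maternal * mat + q.paternal * pat + q.interaction * (2 * mat * pat)
    return total


def simulate_traits(geno: pd.DataFrame, lmap: pd.DataFrame, arch: TraitArchitecture,
                    layout: pd.DataFrame, years: list, uprights_per_genotype: int,
                    seed: int, trait: str = "trait",
                    year_effects: dict | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate per-upright phenotypes plus a component-level truth table.

    Returns ``(phenotypes, truth)``. ``phenotypes`` is long format with columns
    genotype, year, row, col, upright, trait, value; ``truth`` holds one row
    per observation with every additive component (mu, year, qtl, polygenic,
    gxy, row_effect, col_effect, spatial, residual) that sums exactly to value.
    """
    if len(years) == 0:
        raise ValueError("years must be non-empty")
    if uprights_per_genotype < 1:
        raise ValueError("uprights_per_genotype must be >= 1")
    lmap = validate_map(lmap)
    layout = layout.set_index("progeny_id") if "progeny_id" in layout.columns else layout
    missing = set(geno.index) - set(layout.index)
    if missing:
        raise ValueError(f"{len(missing)} progeny missing from field layout")

    rng = np.random.default_rng(seed)
    ids = geno.index.to_numpy()
    n = len(ids)
    rowpos = layout.loc[ids, "row"].to_numpy(dtype=float)
    colpos = layout.loc[ids, "col"].to_numpy(dtype=float)

    if year_effects is None:
        year_effects = {y: float(e) for y, e in
                        zip(years, rng.normal(0.0, 1.0, size=len(years)))}
    qtl_val = _qtl_genetic_values(geno, lmap, arch)
    poly = rng.normal(0.0, np.sqrt(arch.polygenic_variance), size=n)
    row_levels = np.unique(rowpos)
    col_levels = np.unique(colpos)
    row_eff = dict(zip(row_levels, rng.normal(0.0, np.sqrt(arch.row_variance), len(row_levels))))
    col_eff = dict(zip(col_levels, rng.normal(0.0, np.sqrt(arch.col_variance), len(col_levels))))
    spatial = _spatial_surface(rowpos, colpos, arch.spatial_amplitude, rng)

    recs = []
    for year in years:
        gxy = rng.normal(0.0, np.sqrt(arch.gxy_variance), size=n)
        for i, gid in enumerate(ids):
            eps = rng.normal(0.0, np.sqrt(arch.residual_variance),
                             size=uprights_per_genotype)
            for u in range(uprights_per_genotype):
                recs.append((gid, year, int(rowpos[i]), int(colpos[i]), u + 1,
                             arch.mu, year_effects[year], qtl_val[i], poly[i],
                             gxy[i], row_eff[rowpos[i]], col_eff[colpos[i]],
                             spatial[i], eps[u]))
    truth = pd.DataFrame(recs, columns=[
        "genotype", "year", "row", "col", "upright",
        "mu", "year_effect", "qtl", "polygenic", "gxy",
        "row_effect", "col_effect", "spatial", "residual"])
    comp_cols = ["mu", "year_effect", "qtl", "polygenic", "gxy",
                 "row_effect", "col_effect", "spatial", "residual"]
    pheno = truth[["genotype", "year", "row", "col", "upright"]].copy()
    pheno["trait"] = trait
    pheno["value"] = truth[comp_cols].sum(axis=1)
    return pheno, truth


def simulate_shape_scores(n_genotypes: int, uprights_per_genotype: int,
                          class_bias: np.ndarray, seed: int,
                          years: list | None = None,
                          class_names: tuple = (1, 2, 3, 4, 5)) -> pd.DataFrame:
    """Draw categorical berry-shape classes per (genotype, year, upright).

    ``class_bias`` is either one probability vector over the five shape
    classes, or an (n_genotypes, 5) matrix of per-genotype distributions.
    """
    bias = np.asarray(class_bias, dtype=float)
    if bias.ndim == 1:
        bias = np.tile(bias, (n_genotypes, 1))
    if bias.shape != (n_genotypes, 5):
        raise ValueError("class_bias must be length-5 or (n_genotypes, 5)")
    if (bias < 0).any():
        raise ValueError("class distribution has negative mass")
    if not np.allclose(bias.sum(axis=1), 1.0):
        raise ValueError("class distributions must sum to 1")
    if years is None:
        years = [1]
    rng = np.random.default_rng(seed)
    names = np.asarray(class_names)
    recs = []
    for i in range(n_genotypes):
        gid = f"G{i + 1:04d}"
        for year in years:
            draws = rng.choice(5, size=uprights_per_genotype, p=bias[i])
            for u, k in enumerate(draws, start=1):
                recs.append((gid, year, u, names[k]))
    return pd.DataFrame(recs, columns=["genotype", "year", "upright", "shape_class"])
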