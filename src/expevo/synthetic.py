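"""Synthetic-data generators for every input the pipeline consumes.

The generators emulate the statistical structure the downstream analyses
assume:

* log2 expression evolving by Brownian motion along a 9-taxon mammal
  phylogeny, with optional species-specific shifts on a designated gene
  fraction and Gaussian measurement noise at the tips;
* gene coordinates on a small set of chromosomes, so "spatially close"
  neighborhoods exist;
* group-structured longitudinal lipid panels with configurable per-group
  means and SDs (group sizes mirror the in-vivo cohorts: 10 WT vs 6
  homozygous knockouts, 8 heterozygotes; 3 per group on the atherogenic
  diet);
* exponential-decay lipoprotein clearance series on the seven standard
  sampling times, and linear post-lipase-inhibitor secretion series on the
  1-4 h window.

Every generator is bit-deterministic under its ``seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GeneAnnotation, PANEL_COLUMNS, SERIES_COLUMNS
from .errors import ValidationError

#: Balanced 9-mammal tree with unit-scale nucleotide-divergence branch
#: lengths, used as the default phylogeny for all simulations.
DEFAULT_TREE_NEWICK = (
    "(((human:0.10,macaque:0.10):0.20,((mouse:0.15,rat:0.15):0.25,rabbit:0.30):0.10):0.10,"
    "((pig:0.20,cow:0.20):0.10,(dog:0.25,horse:0.25):0.05):0.15);"
)

#: Blood-sampling times for the lipoprotein clearance assay:
#: 0 min, 5 min, 1 h, 4 h, 12 h, 24 h and 48 h, in hours.
DEFAULT_CLEARANCE_TIMES_H = (0.0, 5.0 / 60.0, 1.0, 4.0, 12.0, 24.0, 48.0)

#: Sampling times after lipase-inhibitor (Poloxamer-407) injection, hours.
DEFAULT_SECRETION_TIMES_H = (1.0, 2.0, 3.0, 4.0)


def default_tree() -> dendropy.Tree:
    """Return a fresh copy of the default 9-taxon tree."""
    return dendropy.Tree.get(data=DEFAULT_TREE_NEWICK, schema="newick")


@dataclass(frozen=True)
class ShiftSpec:
    """Species-specific expression shift injected on a terminal lineage.

    ``shift_effect`` is added (in log2-expression units) to the focal
    species' tip value for ``round(shifted_gene_fraction * n_genes)``
    randomly chosen genes.
    """

    focal_species: str
    shifted_gene_fraction: float
    shift_effect: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.shifted_gene_fraction <= 1.0:
            raise ValidationError(
                f"shifted_gene_fraction must be in [0,1], got {self.shifted_gene_fraction}"
            )


def _leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def simulate_expression(
    tree: dendropy.Tree,
    n_genes: int,
    sigma2_range: tuple[float, float] = (0.2, 1.0),
    shifts: ShiftSpec | None = None,
    noise_sd: float = 0.1,
    seed: int = 0,
    root_mean: float = 5.0,
    root_sd: float = 2.0,
    tissue: str | None = None,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Simulate log2 expression by Brownian motion along ``tree``.

    Each gene draws a rate sigma^2 uniformly from ``sigma2_range`` and a
    root value from Normal(root_mean, root_sd); values then diffuse along
    the tree (variance sigma^2 * branch length per edge).  If ``shifts`` is
    given, ``shift_effect`` is added to the focal species for the selected
    gene fraction, before independent Gaussian measurement noise
    (``noise_sd``) is applied at every tip.

    Returns the log2-scale :class:`ExpressionMatrix` and a truth table
    (``gene_id``, ``shifted``, ``effect``).
    """
    leaves = _leaf_labels(tree)
    if len(leaves) < 3:
        raise ValidationError("tree must have at least 3 leaves")
    if n_genes < 1:
        raise ValidationError("n_genes must be >= 1")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be non-negative")
    lo, hi = sigma2_range
    if lo < 0 or hi < lo:
        raise ValidationError(f"invalid sigma2_range {sigma2_range}")
    if shifts is not None and shifts.focal_species not in leaves:
        raise ValidationError(f"focal species {shifts.focal_species!r} is not a leaf of the tree")

    rng = np.random.default_rng(seed)
    gene_ids = [f"g{i:05d}" for i in range(1, n_genes + 1)]
    sigma2 = rng.uniform(lo, hi, n_genes)

    node_values: dict[int, np.ndarray] = {}
    tip_values: dict[str, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            vals = root_mean + root_sd * rng.standard_normal(n_genes)
        else:
            bl = node.edge.length or 0.0
            if bl < 0:
                raise ValidationError("negative branch length in input tree")
            step_sd = np.sqrt(sigma2 * bl)
            vals = node_values[id(node.parent_node)] + step_sd * rng.standard_normal(n_genes)
        node_values[id(node)] = vals
        if node.is_leaf():
            tip_values[node.taxon.label] = vals.copy()

    shifted = np.zeros(n_genes, dtype=bool)
    if shifts is not None:
        n_shift = round(shifts.shifted_gene_fraction * n_genes)
        idx = rng.choice(n_genes, size=n_shift, replace=False)
        shifted[idx] = True
        tip_values[shifts.focal_species] = (
            tip_values[shifts.focal_species] + shifted * shifts.shift_effect
        )

    for sp in leaves:
        if noise_sd > 0:
            tip_values[sp] = tip_values[sp] + noise_sd * rng.standard_normal(n_genes)

    values = pd.DataFrame({sp: tip_values[sp] for sp in leaves}, index=gene_ids)
    values.index.name = "gene_id"
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "shifted": shifted,
            "effect": np.where(shifted, shifts.shift_effect if shifts else 0.0, 0.0),
        }
    )
    return ExpressionMatrix(values, scale="log2", tissue=tissue), truth


DEFAULT_CHROMOSOME_LENGTHS = {"chr1": 50_000_000, "chr2": 40_000_000, "chr12": 60_000_000}


def simulate_gene_coordinates(
    n_genes: int,
    chromosome_lengths: dict[str, int] | None = None,
    gene_span: int = 20_000,
    seed: int = 0,
    gene_ids: list[str] | None = None,
) -> GeneAnnotation:
    """Place genes uniformly at random on a set of chromosomes.

    Chromosomes are chosen with probability proportional to length; each
    gene occupies a fixed ``gene_span`` interval (0-based, half-open)
    whose start is uniform on [0, length - span].
    """
    if chromosome_lengths is None:
        chromosome_lengths = dict(DEFAULT_CHROMOSOME_LENGTHS)
    if n_genes < 1:
        raise ValidationError("n_genes must be >= 1")
    if any(length <= 0 for length in chromosome_lengths.values()):
        raise ValidationError("chromosome lengths must be positive")
    if any(length < gene_span for length in chromosome_lengths.values()):
        raise ValidationError(
            f"gene span {gene_span} does not fit on every chromosome"
        )
    if gene_ids is None:
        gene_ids = [f"g{i:05d}" for i in range(1, n_genes + 1)]
    elif len(gene_ids) != n_genes:
        raise ValidationError("gene_ids length must equal n_genes")

    rng = np.random.default_rng(seed)
    chroms = list(chromosome_lengths)
    lengths = np.array([chromosome_lengths[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    chosen = rng.choice(len(chroms), size=n_genes, p=probs)
    starts = np.array(
        [rng.integers(0, chromosome_lengths[chroms[c]] - gene_span + 1) for c in chosen]
    )
    table = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "chrom": [chroms[c] for c in chosen],
            "start": starts,
            "end": starts + gene_span,
        }
    )
    return GeneAnnotation(table)


def simulate_lipid_panel(design: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Draw one value per animal x analyte x age from the panel design.

    ``design`` has one row per (genotype, diet, age_months, analyte) cell
    with columns ``mean``, ``sd``, ``n_animals`` and ``unit``.  Animals are
    longitudinal: the same animal id recurs across ages and analytes within
    a (genotype, diet) cohort.
    """
    required = {"genotype", "diet", "age_months", "analyte", "mean", "sd", "n_animals", "unit"}
    if design is None or len(design) == 0:
        raise ValidationError("empty panel design")
    missing = required - set(design.columns)
    if missing:
        raise ValidationError(f"panel design missing columns {sorted(missing)}")
    if (design["sd"] < 0).any():
        raise ValidationError("design sd must be >= 0")
    if (design["n_animals"] < 1).any():
        raise ValidationError("design n_animals must be >= 1")

    rng = np.random.default_rng(seed)
    rows = []
    for _, cell in design.sort_values(
        ["genotype", "diet", "age_months", "analyte"], kind="mergesort"
    ).iterrows():
        n = int(cell["n_animals"])
        values = cell["mean"] + cell["sd"] * rng.standard_normal(n)
        for i, v in enumerate(values, start=1):
            rows.append(
                {
                    "animal_id": f"{cell['genotype']}-{cell['diet']}-{i:02d}",
                    "genotype": cell["genotype"],
                    "diet": cell["diet"],
                    "age_months": int(cell["age_months"]),
                    "analyte": cell["analyte"],
                    "value": float(v),
                    "unit": cell["unit"],
                }
            )
    return pd.DataFrame(rows, columns=list(PANEL_COLUMNS))


# Per-analyte WT means (mmol/L except ApoB in g/L) and the printed percent
# reductions at 10 months used to anchor the knockout / heterozygote means.
_STANDARD_PANEL_ANCHORS = {
    # analyte: (WT mean, homozygote % lower, heterozygote % lower, unit)
    "non-HDL-C": (2.0, 42.51, 23.64, "mmol/L"),
    "LDL-C": (1.5, 46.93, 36.27, "mmol/L"),
    "TC": (3.4, 31.19, 18.58, "mmol/L"),
    "VLDL-C": (0.5, 34.06, 21.98, "mmol/L"),
    "TG": (0.6, 32.43, 23.39, "mmol/L"),
    "ApoB": (0.45, 17.72, 14.64, "g/L"),
    "HDL-C": (1.1, 0.0, 0.0, "mmol/L"),
}


def default_standard_panel_design(cv: float = 0.15) -> pd.DataFrame:
    """Standard-diet longitudinal panel design.

    Cohorts mirror the in-vivo study: 10 WT vs 6 ASGR1-/- (ages 6, 10, 17,
    24 months) and 8 ASGR1+/- (ages 4, 6, 10, 17 months).  Genotypes differ
    only from 10 months on, by the anchored percent reductions; before that
    all groups share the WT mean (the age-dependent phenotype).  ``cv`` sets
    each group's SD as a fraction of its mean; ``cv=0`` gives an exact,
    deterministic panel.
    """
    rows = []
    for analyte, (wt_mean, ko_pct, het_pct, unit) in _STANDARD_PANEL_ANCHORS.items():
        for age in (6, 10, 17, 24):
            for genotype, n, pct in (("WT", 10, 0.0), ("ASGR1-/-", 6, ko_pct)):
                mean = wt_mean * (1 - pct / 100.0) if age >= 10 else wt_mean
                rows.append(
                    dict(genotype=genotype, diet="standard", age_months=age, analyte=analyte,
                         mean=mean, sd=cv * mean, n_animals=n, unit=unit)
                )
        for age in (4, 6, 10, 17):
            mean = wt_mean * (1 - het_pct / 100.0) if age >= 10 else wt_mean
            rows.append(
                dict(genotype="ASGR1+/-", diet="standard", age_months=age, analyte=analyte,
                     mean=mean, sd=cv * mean, n_animals=8, unit=unit)
            )
    return pd.DataFrame(rows)


def default_hfhc_panel_design(cv: float = 0.15) -> pd.DataFrame:
    """Atherogenic-diet panel design (n = 3 per group, 6 to 12 months).

    Non-HDL-C starts at 1.2 mmol/L in both groups and ends at 9.9 mmol/L in
    WT (8.25-fold) versus 3.3246 mmol/L in heterozygotes (2.77-fold).
    """
    folds = {"WT": 8.25, "ASGR1+/-": 2.77}
    baseline = 1.2
    rows = []
    for genotype, fold in folds.items():
        for age, mean in ((6, baseline), (12, baseline * fold)):
            rows.append(
                dict(genotype=genotype, diet="HFHC", age_months=age, analyte="non-HDL-C",
                     mean=mean, sd=cv * mean, n_animals=3, unit="mmol/L")
            )
    return pd.DataFrame(rows)


def simulate_clearance_series(
    C0: float,
    k: float,
    baseline: float = 0.0,
    noise_sd: float = 0.0,
    times: tuple[float, ...] = DEFAULT_CLEARANCE_TIMES_H,
    seed: int = 0,
    group: str = "WT",
    unit: str = "g/L",
) -> pd.DataFrame:
    """Exponential-decay concentration series: baseline + C0*exp(-k t) + noise."""
    if k <= 0:
        raise ValidationError("decay rate k must be positive")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be non-negative")
    t = np.asarray(times, dtype=float)
    if t.size == 0:
        raise ValidationError("empty time grid")
    if (t < 0).any() or (np.diff(t) <= 0).any():
        raise ValidationError("times must be non-negative and strictly increasing")
    rng = np.random.default_rng(seed)
    values = baseline + C0 * np.exp(-k * t)
    if noise_sd > 0:
        values = values + noise_sd * rng.standard_normal(t.size)
    return pd.DataFrame(
        {"group": group, "time_h": t, "value": values, "unit": unit},
        columns=list(SERIES_COLUMNS),
    )


def simulate_secretion_series(
    slope: float,
    intercept: float = 0.0,
    noise_sd: float = 0.0,
    times: tuple[float, ...] = DEFAULT_SECRETION_TIMES_H,
    seed: int = 0,
    group: str = "WT",
    unit: str = "mmol/L",
) -> pd.DataFrame:
    """Linear accumulation series: intercept + slope*t + noise (mmol/L)."""
    if noise_sd < 0:
        raise ValidationError("noise_sd must be non-negative")
    t = np.asarray(times, dtype=float)
    if t.size == 0:
        raise ValidationError("empty time grid")
    if (np.diff(t) <= 0).any():
        raise ValidationError("times must be strictly increasing")
    rng = np.random.default_rng(seed)
    values = intercept + slope * t
    if noise_sd > 0:
        values = values + noise_sd * rng.standard_normal(t.size)
    return pd.DataFrame(
        {"group": group, "time_h": t, "value": values, "unit": unit},
        columns=list(SERIES_COLUMNS),
    )


def half_life_to_rate(t_half_hours: float) -> float:
    """Convert a half-life in hours to a first-order rate constant (1/h)."""
    if t_half_hours <= 0:
        raise ValidationError("half-life must be positive")
    return math.log(2.0) / t_half_hours
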