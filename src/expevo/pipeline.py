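"""End-to-end orchestration: simulate -> analyze -> report.

A :class:`RunConfig` fully determines a run.  One top-level seed is
deterministically expanded into per-stage seeds (``stage_seed =
(seed * 100003 + offset) mod 2^31`` with a fixed offset per stage), so each
stage is independently reproducible.  Every artifact is written under
``outdir`` and listed, with a SHA-256 checksum, in ``manifest.json``;
identical config + seed gives identical checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io_formats, kinetics, lipids, shifts, synthetic
from .errors import ExpevoError, ValidationError
from .exprtree import distance_matrix, neighbor_joining, tissue_divergence_report
from .io_formats import tree_to_newick

STAGES = ("simulate", "exprtree", "shifttest", "kinetics", "lipids")
_STAGE_OFFSETS = {name: i + 1 for i, name in enumerate(STAGES)}


def stage_seed(base_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the top-level seed."""
    return (base_seed * 100_003 + _STAGE_OFFSETS[stage]) % (2**31)


@dataclass
class RunConfig:
    """Everything a pipeline run depends on.

    ``tissues`` maps tissue label to the (low, high) range the per-gene BM
    rate sigma^2 is drawn from; the shift spec is applied to
    ``shift_tissue`` only.  Clearance half-lives are in hours per group.
    """

    seed: int
    outdir: str
    stages: tuple[str, ...] = STAGES
    # expression simulation
    n_genes: int = 400
    tissues: dict = field(default_factory=lambda: {"liver": (0.2, 0.6), "lung": (0.8, 1.6)})
    shift_tissue: str = "liver"
    focal_species: str = "pig"
    focal_gene: str = "g00001"
    shift_fraction: float = 0.10
    shift_effect: float = 2.0
    noise_sd: float = 0.1
    # shift test
    window_bp: int = 1_000_000
    n_iter: int = 10_000
    # panels and kinetics
    panel_cv: float = 0.15
    clearance_half_lives: dict = field(
        default_factory=lambda: {"WT": 39.14, "ASGR1+/-": 25.89}
    )
    clearance_c0: float = 0.8
    clearance_baseline: float = 0.2
    clearance_noise_sd: float = 0.016
    secretion_slopes: dict = field(default_factory=lambda: {"WT": 2.0, "ASGR1+/-": 1.2})
    secretion_intercept: float = 1.0
    secretion_noise_sd: float = 0.05

    def __post_init__(self) -> None:
        if not isinstance(self.seed, int):
            raise ValidationError("config must carry an integer seed for every stochastic stage")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValidationError(f"unknown stage(s) {sorted(unknown)}")
        if self.shift_tissue not in self.tissues:
            raise ValidationError(
                f"shift_tissue {self.shift_tissue!r} not among tissues {list(self.tissues)}"
            )

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        payload = json.loads(Path(path).read_text())
        if "seed" not in payload:
            raise ValidationError("config file missing required 'seed'")
        if "stages" in payload:
            payload["stages"] = tuple(payload["stages"])
        if "tissues" in payload:
            payload["tissues"] = {k: tuple(v) for k, v in payload["tissues"].items()}
        return cls(**payload)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in dependency order.

    Returns the manifest (also written to ``outdir/manifest.json``).  A
    failing stage halts the run with the stage named; artifacts written by
    earlier stages are retained.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, list[str]] = {}
    manifest = {
        "config": dataclasses.asdict(config),
        "stage_seeds": {s: stage_seed(config.seed, s) for s in config.stages},
        "artifacts": artifacts,
    }

    def record(stage: str, *paths: Path) -> None:
        artifacts.setdefault(stage, []).extend(str(p.name) for p in paths)

    for stage in (s for s in STAGES if s in config.stages):
        try:
            runner = _STAGE_RUNNERS[stage]
            runner(config, outdir, record)
        except Exception as exc:
            raise ExpevoError(f"stage {stage!r} failed: {exc}") from exc

    checksums = {}
    for stage, names in artifacts.items():
        for name in names:
            checksums[name] = _sha256(outdir / name)
    manifest["checksums"] = checksums
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


# ---------------------------------------------------------------------------
# stages

def _stage_simulate(config: RunConfig, outdir: Path, record) -> None:
    seed = stage_seed(config.seed, "simulate")
    tree = synthetic.default_tree()
    path = outdir / "species_tree.nwk"
    io_formats.write_newick(tree, path)
    record("simulate", path)

    for i, (tissue, sigma2_range) in enumerate(sorted(config.tissues.items())):
        shift = None
        if tissue == config.shift_tissue and config.shift_fraction > 0:
            shift = synthetic.ShiftSpec(config.focal_species, config.shift_fraction,
                                        config.shift_effect)
        matrix, truth = synthetic.simulate_expression(
            tree, config.n_genes, sigma2_range=tuple(sigma2_range), shifts=shift,
            noise_sd=config.noise_sd, seed=seed + 10 + i, tissue=tissue,
        )
        mpath = outdir / f"expression_{tissue}.tsv"
        tpath = outdir / f"shift_truth_{tissue}.tsv"
        io_formats.write_expression_tsv(matrix, mpath)
        truth.to_csv(tpath, sep="\t", index=False)
        record("simulate", mpath, tpath)

    annotation = synthetic.simulate_gene_coordinates(config.n_genes, seed=seed + 50)
    bpath = outdir / "genes.bed"
    io_formats.write_bed(annotation, bpath)
    record("simulate", bpath)

    std = synthetic.simulate_lipid_panel(
        synthetic.default_standard_panel_design(cv=config.panel_cv), seed=seed + 60
    )
    hfhc = synthetic.simulate_lipid_panel(
        synthetic.default_hfhc_panel_design(cv=config.panel_cv), seed=seed + 61
    )
    ppath, hpath = outdir / "panel_standard.csv", outdir / "panel_hfhc.csv"
    io_formats.write_panel_csv(std, ppath)
    io_formats.write_panel_csv(hfhc, hpath)
    record("simulate", ppath, hpath)

    clearance = pd.concat(
        [
            synthetic.simulate_clearance_series(
                C0=config.clearance_c0,
                k=synthetic.half_life_to_rate(t_half),
                baseline=config.clearance_baseline,
                noise_sd=config.clearance_noise_sd,
                seed=seed + 70 + i,
                group=group,
            )
            for i, (group, t_half) in enumerate(sorted(config.clearance_half_lives.items()))
        ],
        ignore_index=True,
    )
    secretion = pd.concat(
        [
            synthetic.simulate_secretion_series(
                slope=slope, intercept=config.secretion_intercept,
                noise_sd=config.secretion_noise_sd, seed=seed + 80 + i, group=group,
            )
            for i, (group, slope) in enumerate(sorted(config.secretion_slopes.items()))
        ],
        ignore_index=True,
    )
    cpath, spath = outdir / "clearance.csv", outdir / "secretion.csv"
    io_formats.write_series_csv(clearance, cpath)
    io_formats.write_series_csv(secretion, spath)
    record("simulate", cpath, spath)


def _stage_exprtree(config: RunConfig, outdir: Path, record) -> None:
    matrices = {
        tissue: io_formats.read_expression_tsv(
            outdir / f"expression_{tissue}.tsv", scale="log2", tissue=tissue
        )
        for tissue in sorted(config.tissues)
    }
    for tissue, matrix in matrices.items():
        result = neighbor_joining(distance_matrix(matrix), tissue=tissue)
        tpath = outdir / f"exprtree_{tissue}.nwk"
        tpath.write_text(tree_to_newick(result.tree))
        record("exprtree", tpath)
    report = tissue_divergence_report(matrices)
    rpath = outdir / "tissue_divergence.tsv"
    report.to_csv(rpath, sep="\t", index=False)
    record("exprtree", rpath)


def _stage_shifttest(config: RunConfig, outdir: Path, record) -> None:
    seed = stage_seed(config.seed, "shifttest")
    matrix = io_formats.read_expression_tsv(
        outdir / f"expression_{config.shift_tissue}.tsv", scale="log2",
        tissue=config.shift_tissue,
    )
    tree = io_formats.read_newick(outdir / "species_tree.nwk")
    annotation = io_formats.read_bed(outdir / "genes.bed")

    result = shifts.genomewide_delta_aic(matrix, tree, focal_species=config.focal_species)
    table = result.table.set_index("gene_id", drop=False)
    dpath = outdir / "delta_aic.tsv"
    result.table.to_csv(dpath, sep="\t", index=False)
    hpath = outdir / "delta_aic_hist.tsv"
    shifts.delta_aic_histogram(result.table["delta_aic"]).to_csv(hpath, sep="\t", index=False)
    record("shifttest", dpath, hpath)

    neighbors = shifts.spatial_neighbors(annotation, config.focal_gene,
                                         window_bp=config.window_bp)
    neighbors = [g for g in neighbors if g in table.index]
    focal_delta = float(table.loc[config.focal_gene, "delta_aic"])
    pool = table.loc[
        (table["gene_id"] != config.focal_gene) & (~table["gene_id"].isin(neighbors)),
        "delta_aic",
    ].to_numpy()
    null = shifts.resampled_median_null(pool, draw_size=max(1, len(neighbors)),
                                        n_iter=config.n_iter, seed=seed,
                                        focal_gene=config.focal_gene)
    npath = outdir / "null_medians.tsv"
    pd.DataFrame({"median_delta_aic": null.medians}).to_csv(npath, sep="\t", index=False)
    record("shifttest", npath)

    neighbor_deltas = table.loc[neighbors, "delta_aic"].to_numpy()
    report = shifts.shift_report(focal_delta, neighbor_deltas, null,
                                 genomewide_deltas=table["delta_aic"].to_numpy())
    payload = {
        "focal_gene": config.focal_gene,
        "focal_species": config.focal_species,
        "focal_delta_aic": report.focal_delta_aic,
        "n_neighbors": report.n_neighbors,
        "percentile_vs_null_medians": report.percentile_vs_null_medians,
        "percentile_vs_genomewide": report.percentile_vs_genomewide,
        "neighbor_vs_null_wilcoxon_p": (
            report.neighbor_vs_null_wilcoxon.p_value
            if report.neighbor_vs_null_wilcoxon else None
        ),
        "focal_vs_null_less_p": report.focal_vs_null_less_p,
        "n_degenerate_genes": len(result.degenerate_genes),
    }
    jpath = outdir / "shift_report.json"
    jpath.write_text(json.dumps(payload, indent=2) + "\n")
    record("shifttest", jpath)


def _stage_kinetics(config: RunConfig, outdir: Path, record) -> None:
    clearance = io_formats.read_series_csv(outdir / "clearance.csv")
    secretion = io_formats.read_series_csv(outdir / "secretion.csv")
    # baseline handling is a convention, not a measurement: report every mode
    clearance_fits: dict[str, dict] = {}
    for mode in ("zero", "subtract_t0", "free"):
        for group in sorted(clearance["group"].unique()):
            try:
                fit = kinetics.fit_clearance(clearance, baseline_mode=mode, group=group)
                entry = dataclasses.asdict(fit)
            except ValidationError as exc:
                # e.g. subtract_t0 on a post-injection-peak series
                entry = {"error": str(exc)}
            clearance_fits.setdefault(str(group), {})[mode] = entry
    payload = {
        "clearance": clearance_fits,
        "secretion": {
            group: dataclasses.asdict(fit)
            for group, fit in kinetics.secretion_rate_by_group(secretion).items()
        },
    }
    path = outdir / "kinetics.json"
    path.write_text(json.dumps(payload, indent=2) + "\n")
    record("kinetics", path)


def _stage_lipids(config: RunConfig, outdir: Path, record) -> None:
    std = io_formats.read_panel_csv(outdir / "panel_standard.csv")
    hfhc = io_formats.read_panel_csv(outdir / "panel_hfhc.csv")
    rows = []
    analytes = sorted(std["analyte"].unique())
    for analyte in analytes:
        for alt in ("ASGR1-/-", "ASGR1+/-"):
            cmp_ = lipids.group_percent_difference(std, analyte, age=10,
                                                   diet="standard", alt_group=alt)
            rows.append(
                {
                    "kind": "percent_difference", "analyte": analyte,
                    "group": alt, "age_months": 10, "diet": "standard",
                    "value": cmp_.percent_difference, "t": cmp_.t_statistic,
                    "p": cmp_.p_value, "n_ref": cmp_.n_ref, "n_alt": cmp_.n_alt,
                }
            )
    for group in ("WT", "ASGR1+/-"):
        fc = lipids.fold_change(hfhc, "non-HDL-C", group, ref_age=6, post_age=12)
        rows.append(
            {
                "kind": "fold_change", "analyte": "non-HDL-C", "group": group,
                "age_months": 12, "diet": "HFHC", "value": fc.fold,
                "t": float("nan"), "p": float("nan"), "n_ref": 3, "n_alt": 3,
            }
        )
    frame = pd.DataFrame(rows)
    tpath = outdir / "lipid_comparisons.tsv"
    frame.to_csv(tpath, sep="\t", index=False)
    jpath = outdir / "lipid_comparisons.json"
    jpath.write_text(frame.to_json(orient="records", indent=2) + "\n")
    record("lipids", tpath, jpath)


_STAGE_RUNNERS = {
    "simulate": _stage_simulate,
    "exprtree": _stage_exprtree,
    "shifttest": _stage_shifttest,
    "kinetics": _stage_kinetics,
    "lipids": _stage_lipids,
}
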