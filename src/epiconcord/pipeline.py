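"""End-to-end orchestration: simulate -> quantify -> test -> integrate.

Stages run in the order quantification, normalization/testing, gene sets,
promoter states, TF targets, integration, GWAS cross-referencing; each
writes flat TSV outputs into its own subdirectory of the run directory and
registers parameters and SHA-256 output hashes in ``manifest.json``.
Deterministic stages are bit-identical across reruns of the same config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as eio
from .differential import (benjamini_hochberg, drop_all_zero, fit_moderated_t,
                           log2_with_pseudocount, loess_normalize,
                           select_differential)
from .genesets import GeneSetCollection, page_scan, read_gmt
from .gwas import (bin_by_association_p, merge_snp_sets, nearest_tss_map,
                   proximal_background_contrast, snp_groups)
from .integrate import (cluster_gene_profiles, cluster_overlap_exact,
                        cross_celltype_sharing_odds, principal_components,
                        rna_chip_concordance)
from .quantify import (count_promoter_reads, extend_reads, filter_reads,
                       make_promoter_windows, snp_window_coverage)
from .simulate import SimulationConfig, simulate_study
from .states import (classify_by_posterior, consensus_state,
                     fit_three_component_mixture, state_change_association)
from .tftargets import build_target_sets, gc_adjust_scores, read_pwm_library, scan_library

logger = logging.getLogger(__name__)

STAGES = ("simulate", "quantify", "diffexp", "diffchip", "page", "states",
          "tftargets", "integrate", "gwas")


@dataclass
class PipelineConfig:
    """All thresholds and paths of one pipeline run."""

    outdir: str = "run"
    seed: int = 0
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    min_fold: float = 2.0
    max_p: float = 0.05
    cluster_p: float = 0.01
    k: int = 8
    top_n: int = 300
    snp_halfwidth: int = 500
    bin_edges: tuple[float, ...] = (1e-8, 1e-5, 1e-3, 1.0)
    n_perm: int = 2000
    min_mapq: int = 20
    extend_to: int = 200
    window_anchor: str = "centered"
    page_min_size: int = 10
    stages: tuple[str, ...] = STAGES

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not 0 < self.max_p <= 1 or not 0 < self.cluster_p <= 1:
            raise ValueError("p-value thresholds must lie in (0, 1]")
        if self.min_fold <= 0:
            raise ValueError("min_fold must be positive")
        if self.k < 2 or self.top_n < 1:
            raise ValueError("k and top_n must be positive")
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim", {})
        cfg = cls(**{k: v for k, v in raw.items() if k != "sim"},
                  sim=SimulationConfig(**sim_raw))
        return cfg

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class Manifest:
    """Stage registry: parameters and output hashes, JSON-serialized."""

    def __init__(self, run_dir: Path):
        self.path = Path(run_dir) / "manifest.json"
        self.data: dict = {"stages": {}}
        if self.path.exists():
            self.data = json.loads(self.path.read_text())

    def record(self, stage: str, params: dict, outputs: list[Path]) -> None:
        self.data["stages"][stage] = {
            "params": params,
            "outputs": {str(Path(p).name): _sha256(Path(p)) for p in outputs},
        }
        self.path.write_text(json.dumps(self.data, indent=2, sort_keys=True,
                                        default=str))

    def has(self, stage: str) -> bool:
        return stage in self.data["stages"]


def _require(run_dir: Path, relpath: str, needed_by: str, produced_by: str) -> Path:
    p = run_dir / relpath
    if not p.exists():
        raise FileNotFoundError(
            f"stage '{needed_by}' needs {relpath}; run stage '{produced_by}' first")
    return p


@dataclass
class PipelineResult:
    """Handles onto everything the stages computed (also on disk)."""

    config: PipelineConfig
    run_dir: Path
    sim: object = None
    chip_counts: pd.DataFrame | None = None
    snp_coverage: pd.DataFrame | None = None
    promoter_coverage: pd.DataFrame | None = None
    rna_norm: dict = field(default_factory=dict)
    rna_diff: dict = field(default_factory=dict)
    chip_norm: dict = field(default_factory=dict)
    chip_diff: dict = field(default_factory=dict)
    rna_de_lists: dict = field(default_factory=dict)
    chip_de_lists: dict = field(default_factory=dict)
    page_tables: dict = field(default_factory=dict)
    consensus_states: dict = field(default_factory=dict)
    state_assoc: dict = field(default_factory=dict)
    tf_scores: pd.DataFrame | None = None
    tf_targets: GeneSetCollection | None = None
    tf_enrichment: dict = field(default_factory=dict)
    pca: dict = field(default_factory=dict)
    sharing: tuple | None = None
    clusters_rna: object = None
    clusters_chip: object = None
    cluster_overlap: pd.DataFrame | None = None
    concordance: pd.DataFrame | None = None
    gwas_contrasts: pd.DataFrame | None = None
    snp_map: object = None


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every configured stage; returns in-memory handles plus files."""
    run_dir = Path(config.outdir)
    run_dir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(run_dir / "config.yaml")
    manifest = Manifest(run_dir)
    result = PipelineResult(config=config, run_dir=run_dir)

    runners = {
        "simulate": stage_simulate, "quantify": stage_quantify,
        "diffexp": stage_diffexp, "diffchip": stage_diffchip,
        "page": stage_page, "states": stage_states,
        "tftargets": stage_tftargets, "integrate": stage_integrate,
        "gwas": stage_gwas,
    }
    for stage in STAGES:
        if stage in config.stages:
            logger.info("pipeline: running stage %s", stage)
            runners[stage](config, run_dir, manifest, result)
    write_report(run_dir)
    return result


# ---------------------------------------------------------------------------
# stages


def stage_simulate(config, run_dir: Path, manifest: Manifest, result: PipelineResult):
    sim_dir = run_dir / "sim"
    sim = simulate_study(dataclasses.replace(config.sim, seed=config.seed),
                         outdir=sim_dir)
    result.sim = sim
    outputs = [p for p in sim.paths.values() if isinstance(p, Path)]
    outputs += list(sim.paths["reads"].values())
    manifest.record("simulate", dataclasses.asdict(sim.config), outputs)


def _load_sim_inputs(run_dir: Path, needed_by: str):
    sim_dir = run_dir / "sim"
    ann = eio.read_annotation(_require(run_dir, "sim/annotation.tsv", needed_by, "simulate"))
    samples = eio.read_sample_table(_require(run_dir, "sim/samples.tsv", needed_by, "simulate"))
    return sim_dir, ann, samples


def stage_quantify(config, run_dir, manifest, result):
    sim_dir, ann, samples = _load_sim_inputs(run_dir, "quantify")
    snps = eio.read_snp_table(_require(run_dir, "sim/snps.tsv", "quantify", "simulate"))
    windows = make_promoter_windows(ann, anchor=config.window_anchor)
    chip_samples = samples.loc[samples["assay"] == "chip", "sample_id"]
    reads = {}
    for sample in chip_samples:
        path = _require(run_dir, f"sim/reads/{sample}.bed", "quantify", "simulate")
        raw = eio.read_reads(path)
        reads[sample] = extend_reads(filter_reads(raw, min_mapq=config.min_mapq),
                                     target_length=config.extend_to)
    counts = count_promoter_reads(reads, windows)
    coverage = snp_window_coverage(reads, snps, halfwidth=config.snp_halfwidth)
    # identical mean-depth statistic at every gene TSS: the background the
    # SNP windows are contrasted against in the GWAS stage
    tss_windows = pd.DataFrame({"snp_id": ann["gene_id"], "chrom": ann["chrom"],
                                "pos": ann["tss"]})
    promoter_cov = snp_window_coverage(reads, tss_windows,
                                       halfwidth=config.snp_halfwidth)
    qdir = run_dir / "quantify"
    qdir.mkdir(exist_ok=True)
    eio.write_matrix(counts, qdir / "chip_counts.tsv")
    eio.write_matrix(coverage, qdir / "snp_coverage.tsv")
    eio.write_matrix(promoter_cov, qdir / "promoter_coverage.tsv")
    result.chip_counts, result.snp_coverage = counts, coverage
    result.promoter_coverage = promoter_cov
    manifest.record("quantify",
                    {"min_mapq": config.min_mapq, "extend_to": config.extend_to,
                     "window_anchor": config.window_anchor,
                     "snp_halfwidth": config.snp_halfwidth},
                    [qdir / "chip_counts.tsv", qdir / "snp_coverage.tsv",
                     qdir / "promoter_coverage.tsv"])


def _differential_per_celltype(counts, samples, assay, config, out_prefix, run_dir):
    """Normalize and test control-vs-SLE per cell type; returns dicts."""
    meta = samples.loc[samples["assay"] == assay]
    norm_d, diff_d, lists = {}, {}, {}
    outputs = []
    for ct, block in meta.groupby("cell_type", sort=True):
        ids = [s for s in block["sample_id"] if s in counts.columns]
        sub = drop_all_zero(counts[ids])
        norm = loess_normalize(log2_with_pseudocount(sub))
        groups = block.set_index("sample_id").loc[ids, "group"]
        diff, _ = fit_moderated_t(norm, groups)
        up, down = select_differential(diff, min_fold=config.min_fold,
                                       max_p=config.max_p)
        norm_d[ct], diff_d[ct], lists[ct] = norm, diff, {"up": set(up), "down": set(down)}
        eio.write_matrix(norm, run_dir / f"{out_prefix}_norm_{ct}.tsv")
        diff.to_csv(run_dir / f"{out_prefix}_diff_{ct}.tsv", sep="\t")
        outputs += [run_dir / f"{out_prefix}_norm_{ct}.tsv",
                    run_dir / f"{out_prefix}_diff_{ct}.tsv"]
    return norm_d, diff_d, lists, outputs


def stage_diffexp(config, run_dir, manifest, result):
    _, ann, samples = _load_sim_inputs(run_dir, "diffexp")
    counts = eio.read_matrix(_require(run_dir, "sim/rna_counts.tsv", "diffexp", "simulate"))
    ddir = run_dir / "differential"
    ddir.mkdir(exist_ok=True)
    norm, diff, lists, outputs = _differential_per_celltype(
        counts, samples, "rna", config, "rna", ddir)
    result.rna_norm, result.rna_diff, result.rna_de_lists = norm, diff, lists
    manifest.record("diffexp", {"min_fold": config.min_fold, "max_p": config.max_p},
                    outputs)


def stage_diffchip(config, run_dir, manifest, result):
    _, ann, samples = _load_sim_inputs(run_dir, "diffchip")
    counts = result.chip_counts
    if counts is None:
        counts = eio.read_matrix(_require(run_dir, "quantify/chip_counts.tsv",
                                          "diffchip", "quantify"))
    ddir = run_dir / "differential"
    ddir.mkdir(exist_ok=True)
    norm, diff, lists, outputs = _differential_per_celltype(
        counts, samples, "chip", config, "chip", ddir)
    result.chip_norm, result.chip_diff, result.chip_de_lists = norm, diff, lists
    manifest.record("diffchip", {"min_fold": config.min_fold, "max_p": config.max_p},
                    outputs)


def stage_page(config, run_dir, manifest, result):
    collection = read_gmt(_require(run_dir, "sim/gene_sets.gmt", "page", "simulate"))
    pdir = run_dir / "page"
    pdir.mkdir(exist_ok=True)
    outputs = []
    for assay, diffs in (("rna", result.rna_diff), ("chip", result.chip_diff)):
        for ct, diff in diffs.items():
            table = page_scan(diff["logFC"], collection,
                              min_size=config.page_min_size)
            result.page_tables[(assay, ct)] = table
            p = pdir / f"page_{assay}_{ct}.tsv"
            table.to_csv(p, sep="\t", index=False)
            outputs.append(p)
    manifest.record("page", {"min_size": config.page_min_size}, outputs)


def stage_states(config, run_dir, manifest, result):
    _, ann, samples = _load_sim_inputs(run_dir, "states")
    counts = result.chip_counts
    if counts is None:
        counts = eio.read_matrix(_require(run_dir, "quantify/chip_counts.tsv",
                                          "states", "quantify"))
    sdir = run_dir / "states"
    sdir.mkdir(exist_ok=True)
    meta = samples.loc[samples["assay"] == "chip"].set_index("sample_id")
    log2_counts = log2_with_pseudocount(counts)
    outputs = []
    for ct, block in meta.groupby("cell_type", sort=True):
        controls = [s for s in block.index
                    if block.loc[s, "group"] == "control" and s in counts.columns]
        per_sample = []
        for s in controls:
            fit = fit_three_component_mixture(log2_counts[s].to_numpy(),
                                              seed=config.seed)
            classes, _ = classify_by_posterior(fit, log2_counts[s].to_numpy())
            per_sample.append(classes)
        consensus = pd.Series(consensus_state(np.vstack(per_sample)),
                              index=counts.index, name="consensus")
        result.consensus_states[ct] = consensus
        assoc_frames = []
        diff = result.chip_diff.get(ct)
        if diff is not None:
            for direction in ("either", "up", "down"):
                assoc = state_change_association(consensus, diff,
                                                direction=direction,
                                                max_p=config.max_p)
                assoc_frames.append(assoc)
            assoc = pd.concat(assoc_frames, ignore_index=True)
            result.state_assoc[ct] = assoc
            p = sdir / f"state_association_{ct}.tsv"
            assoc.to_csv(p, sep="\t", index=False)
            outputs.append(p)
        p = sdir / f"consensus_{ct}.tsv"
        consensus.rename_axis("feature_id").reset_index().to_csv(p, sep="\t", index=False)
        outputs.append(p)
    manifest.record("states", {"max_p": config.max_p, "seed": config.seed}, outputs)


def stage_tftargets(config, run_dir, manifest, result):
    sequences = eio.read_fasta(_require(run_dir, "sim/promoters.fa", "tftargets", "simulate"))
    pwms = read_pwm_library(_require(run_dir, "sim/pwms.jaspar", "tftargets", "simulate"))
    gc_path = run_dir / "sim" / "truth_gc.tsv"
    gc = None
    if gc_path.exists():
        gc_frame = pd.read_csv(gc_path, sep="\t")
        gc = gc_frame.set_index("gene_id")["gc"]
    tdir = run_dir / "tftargets"
    tdir.mkdir(exist_ok=True)
    scores = scan_library(sequences, pwms)
    top_n = min(config.top_n, len(scores))
    targets = build_target_sets(scores, top_n=top_n)
    result.tf_scores, result.tf_targets = scores, targets
    outputs = [tdir / "best_match_scores.tsv"]
    scores.to_csv(outputs[0], sep="\t")
    from .genesets import write_gmt
    write_gmt(targets, tdir / "target_sets.gmt")
    outputs.append(tdir / "target_sets.gmt")
    for assay, diffs, use_gc in (("rna", result.rna_diff, False),
                                 ("chip", result.chip_diff, True)):
        for ct, diff in diffs.items():
            score_vec = diff["logFC"]
            if use_gc and gc is not None:
                score_vec = gc_adjust_scores(score_vec, gc)
            table = page_scan(score_vec, targets, min_size=config.page_min_size,
                              max_size=max(2000, top_n))
            result.tf_enrichment[(assay, ct)] = table
            p = tdir / f"tf_{assay}_{ct}.tsv"
            table.to_csv(p, sep="\t", index=False)
            outputs.append(p)
    manifest.record("tftargets", {"top_n": top_n, "gc_adjust": "chip"}, outputs)


def stage_integrate(config, run_dir, manifest, result):
    _, ann, samples = _load_sim_inputs(run_dir, "integrate")
    idir = run_dir / "integrate"
    idir.mkdir(exist_ok=True)
    outputs = []
    universe = set(ann["gene_id"])

    rna_all = pd.concat(result.rna_norm.values(), axis=1).dropna()
    coords, varfrac = principal_components(rna_all, n_components=min(5, rna_all.shape[1]))
    result.pca["rna"] = (coords, varfrac)
    p = idir / "pca_rna.tsv"
    coords.to_csv(p, sep="\t", index_label="sample_id")
    outputs.append(p)
    pd.DataFrame({"component": coords.columns,
                  "variance_fraction": varfrac}).to_csv(
        idir / "pca_rna_variance.tsv", sep="\t", index=False)
    outputs.append(idir / "pca_rna_variance.tsv")

    sharing, summary = cross_celltype_sharing_odds(result.rna_de_lists, universe)
    result.sharing = (sharing, summary)
    p = idir / "sharing_odds.tsv"
    sharing.to_csv(p, sep="\t", index=False)
    outputs.append(p)
    (idir / "sharing_summary.json").write_text(json.dumps(summary, indent=2))
    outputs.append(idir / "sharing_summary.json")

    # eight-cluster analysis on genes differential at cluster_p in >= 1 cell type
    selected = sorted({g for ct, diff in result.rna_diff.items()
                       for g in diff.index[diff["pvalue"] < config.cluster_p]})
    rna_samples = samples.loc[samples["assay"] == "rna"]
    clusters_rna = cluster_gene_profiles(rna_all, rna_samples, selected,
                                         k=config.k, seed=config.seed)
    result.clusters_rna = clusters_rna
    p = idir / "clusters_rna.tsv"
    clusters_rna.labels.rename_axis("gene_id").reset_index().to_csv(p, sep="\t", index=False)
    outputs.append(p)

    chip_all = pd.concat(result.chip_norm.values(), axis=1).dropna()
    chip_samples = samples.loc[samples["assay"] == "chip"]
    chip_selected = sorted({g for ct, diff in result.chip_diff.items()
                            for g in diff.index[diff["pvalue"] < config.cluster_p]})
    if len(chip_selected) >= config.k:
        clusters_chip = cluster_gene_profiles(chip_all, chip_samples, chip_selected,
                                              k=config.k, seed=config.seed)
        result.clusters_chip = clusters_chip
        p = idir / "clusters_chip.tsv"
        clusters_chip.labels.rename_axis("gene_id").reset_index().to_csv(
            p, sep="\t", index=False)
        outputs.append(p)
        overlap = cluster_overlap_exact(clusters_rna, clusters_chip)
        result.cluster_overlap = overlap
        p = idir / "cluster_overlap.tsv"
        overlap.to_csv(p, sep="\t", index=False)
        outputs.append(p)

    conc = rna_chip_concordance(result.rna_de_lists, result.chip_de_lists, universe)
    result.concordance = conc
    p = idir / "rna_chip_concordance.tsv"
    conc.to_csv(p, sep="\t", index=False)
    outputs.append(p)
    manifest.record("integrate", {"k": config.k, "cluster_p": config.cluster_p,
                                  "seed": config.seed}, outputs)


def stage_gwas(config, run_dir, manifest, result):
    _, ann, samples = _load_sim_inputs(run_dir, "gwas")
    snps = eio.read_snp_table(_require(run_dir, "sim/snps.tsv", "gwas", "simulate"))
    gdir = run_dir / "gwas"
    gdir.mkdir(exist_ok=True)
    merged = merge_snp_sets([snps])
    binned = bin_by_association_p(merged, edges=config.bin_edges)
    snp_map = nearest_tss_map(merged, ann)
    result.snp_map = snp_map
    outputs = [gdir / "snps_binned.tsv", gdir / "nearest_tss.tsv"]
    binned.to_csv(outputs[0], sep="\t", index=False)
    snp_map.table.to_csv(outputs[1], sep="\t", index=False)

    # expression modes: genes nearest any merged SNP vs all other genes;
    # coverage modes: SNP windows in the most-significant association bin
    # vs the remaining SNP windows
    focal_genes = set(snp_map.table["gene_id"])
    top_bin = binned["p_bin"].cat.categories[0]
    focal_snps = set(binned.loc[binned["p_bin"] == top_bin, "snp_id"])
    coverage = result.snp_coverage
    if coverage is None:
        coverage = eio.read_matrix(_require(run_dir, "quantify/snp_coverage.tsv",
                                            "gwas", "quantify"))
    cov_log = log2_with_pseudocount(coverage, pseudocount=0.5)
    cov_norm = loess_normalize(cov_log) if len(cov_log) >= 10 else cov_log
    meta = samples.set_index("sample_id")

    rows = []

    def _contrast(mode, ct, values, focal):
        try:
            res = proximal_background_contrast(values, focal, n_perm=config.n_perm,
                                               seed=config.seed)
        except ValueError as exc:
            logger.warning("gwas contrast %s/%s skipped: %s", mode, ct, exc)
            return
        rows.append((mode, ct, res))

    for ct in sorted(meta["cell_type"].unique()):
        rna_diff = result.rna_diff.get(ct)
        rna_norm = result.rna_norm.get(ct)
        if rna_norm is not None:
            controls = [s for s in rna_norm.columns if meta.loc[s, "group"] == "control"]
            _contrast("baseline_expression", ct, rna_norm[controls].mean(axis=1),
                      focal_genes)
        if rna_diff is not None:
            _contrast("differential_expression", ct, rna_diff["logFC"], focal_genes)
        chip_cols = [s for s in cov_norm.columns if meta.loc[s, "cell_type"] == ct]
        if chip_cols:
            ctrl = [s for s in chip_cols if meta.loc[s, "group"] == "control"]
            sle = [s for s in chip_cols if meta.loc[s, "group"] == "sle"]
            _contrast("baseline_coverage", ct, cov_norm[ctrl].mean(axis=1), focal_snps)
            change = cov_norm[sle].mean(axis=1) - cov_norm[ctrl].mean(axis=1)
            _contrast("differential_coverage", ct, change, focal_snps)

    contrast = pd.DataFrame(
        [(mode, ct, r["delta"], r["z"], r["p_perm"], r["welch_t"], r["welch_p"],
          r["m"], r["n"]) for mode, ct, r in rows],
        columns=["mode", "cell_type", "delta", "z", "p_perm", "welch_t", "welch_p",
                 "n_focal", "n_universe"])
    result.gwas_contrasts = contrast
    outputs.append(gdir / "contrasts.tsv")
    contrast.to_csv(outputs[-1], sep="\t", index=False)
    manifest.record("gwas", {"bin_edges": list(config.bin_edges),
                             "n_perm": config.n_perm, "seed": config.seed}, outputs)


# ---------------------------------------------------------------------------
# report


def write_report(run_dir: Path) -> Path:
    """Summaries per results theme as TSVs; missing stages marked, not
    silently zeroed. Idempotent."""
    run_dir = Path(run_dir)
    rdir = run_dir / "report"
    rdir.mkdir(exist_ok=True)
    status = []

    def _missing(section, why):
        status.append((section, "missing", why))

    # DE counts per cell type and assay
    ddir = run_dir / "differential"
    rows = []
    if ddir.exists():
        for p in sorted(ddir.glob("*_diff_*.tsv")):
            assay, _, ct = p.stem.split("_", 2)
            diff = pd.read_csv(p, sep="\t", index_col="feature_id")
            rows.append((assay, ct, int((diff["direction"] == "up").sum()),
                         int((diff["direction"] == "down").sum())))
    if rows:
        pd.DataFrame(rows, columns=["assay", "cell_type", "n_up", "n_down"]).to_csv(
            rdir / "de_counts.tsv", sep="\t", index=False)
        status.append(("de_counts", "ok", ""))
    else:
        _missing("de_counts", "differential stage outputs not found")

    for section, glob, outname in (
        ("gene_sets", "page/page_*.tsv", "top_gene_sets.tsv"),
        ("tf_targets", "tftargets/tf_*.tsv", "top_pwms.tsv"),
    ):
        parts = []
        for p in sorted(run_dir.glob(glob)):
            t = pd.read_csv(p, sep="\t")
            t.insert(0, "source", p.stem)
            parts.append(t.head(5))
        if parts:
            pd.concat(parts, ignore_index=True).to_csv(rdir / outname, sep="\t", index=False)
            status.append((section, "ok", ""))
        else:
            _missing(section, f"no files matching {glob}")

    sdir = run_dir / "states"
    parts = []
    for p in sorted(sdir.glob("state_association_*.tsv")) if sdir.exists() else []:
        t = pd.read_csv(p, sep="\t")
        t.insert(0, "cell_type", p.stem.rsplit("_", 1)[1])
        parts.append(t)
    if parts:
        pd.concat(parts, ignore_index=True).to_csv(rdir / "state_association.tsv",
                                                   sep="\t", index=False)
        status.append(("state_association", "ok", ""))
    else:
        _missing("state_association", "states stage outputs not found")

    gpath = run_dir / "gwas" / "contrasts.tsv"
    if gpath.exists():
        pd.read_csv(gpath, sep="\t").to_csv(rdir / "gwas_contrasts.tsv",
                                            sep="\t", index=False)
        status.append(("gwas_contrasts", "ok", ""))
    else:
        _missing("gwas_contrasts", "gwas stage outputs not found")

    pd.DataFrame(status, columns=["section", "status", "note"]).to_csv(
        rdir / "report_status.tsv", sep="\t", index=False)
    return rdir
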