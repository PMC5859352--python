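"""Synthetic multi-omics data with planted, recorded ground truth.

The generator emulates the statistical structure the downstream analysis
assumes for a two-group (control vs SLE) study of three immune cell types:

* negative-binomial RNA counts with planted shared and cell-specific
  differential genes (eight direction archetypes: shared up/down plus
  up/down specific to each cell type);
* promoter H3K4me3 ChIP reads whose per-promoter depth follows a trimodal
  (inactive / poised / active) log2 distribution, with SLE-related changes
  planted preferentially in the poised class;
* 1 kb promoter sequences with controlled GC content and planted PWM
  consensus occurrences;
* a Dirichlet-sampled PWM library;
* SNP tables with three overlapping source sets and variants planted near
  downregulated genes.

Every generator draws from a named substream of one master seed
(:func:`epiconcord._rng.substream`), so outputs are byte-reproducible and
stages are independent.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._rng import substream
from . import io as eio
from .tftargets import PositionWeightMatrix

logger = logging.getLogger(__name__)

STATES = ("inactive", "poised", "active")
GROUPS = ("control", "sle")
ARCHETYPES_SHARED = ("shared_up", "shared_down")


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults define the study conditions.

    ``trimodal_means`` are log2 reads per 1 kb promoter window per sample;
    the defaults (2, 5, 8) put the inactive/poised/active classes at about
    4 / 32 / 256 reads, spanning the dynamic range of promoter H3K4me3 at
    moderate sequencing depth with ~3 SD separation between classes.
    """

    seed: int = 0
    n_genes: int = 2000
    n_chromosomes: int = 4
    chrom_length: int = 1_500_000
    cell_types: tuple[str, ...] = ("Bcell", "Tcell", "Monocyte")
    n_per_group: int = 6
    nb_dispersion: float = 0.1
    trimodal_means: tuple[float, float, float] = (2.0, 5.0, 8.0)
    trimodal_sds: tuple[float, float, float] = (0.8, 0.8, 0.8)
    trimodal_weights: tuple[float, float, float] = (0.4, 0.3, 0.3)
    frac_shared_de: float = 0.11
    frac_cellspecific_de: float = 0.09
    effect_logfc: float = 2.0
    snp_count: int = 143
    snp_proximal_fraction: float = 0.5
    # ChIP-specific knobs
    frac_chip_change: float = 0.15
    poised_change_odds: float = 3.0
    chip_effect_logfc: float = 2.0
    chip_sample_sd: float = 0.3
    chip_read_length: int = 36
    chip_decoy_fraction: float = 0.05
    # promoter sequences / PWM library
    gc_low: float = 0.35
    gc_high: float = 0.60
    n_pwms: int = 30
    pwm_width_min: int = 8
    pwm_width_max: int = 14
    pwm_concentration: float = 0.5

    def __post_init__(self) -> None:
        self.cell_types = tuple(self.cell_types)
        self.trimodal_means = tuple(float(x) for x in self.trimodal_means)
        self.trimodal_sds = tuple(float(x) for x in self.trimodal_sds)
        self.trimodal_weights = tuple(float(x) for x in self.trimodal_weights)
        self.validate()

    def validate(self) -> None:
        if len(self.cell_types) != 3:
            raise ValueError("exactly 3 cell-type labels are required")
        if self.n_genes < 1 or self.n_chromosomes < 1 or self.chrom_length < 1:
            raise ValueError("n_genes, n_chromosomes and chrom_length must be positive")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if abs(sum(self.trimodal_weights) - 1.0) > 1e-9:
            raise ValueError("trimodal_weights must sum to 1 within 1e-9")
        if any(w < 0 for w in self.trimodal_weights):
            raise ValueError("trimodal_weights must be nonnegative")
        if any(s <= 0 for s in self.trimodal_sds):
            raise ValueError("trimodal_sds must be positive")
        for name in ("frac_shared_de", "frac_cellspecific_de", "snp_proximal_fraction",
                     "frac_chip_change", "chip_decoy_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.frac_shared_de + self.frac_cellspecific_de > 1.0:
            raise ValueError("frac_shared_de + frac_cellspecific_de must be <= 1")
        if self.effect_logfc < 0 or self.chip_effect_logfc < 0:
            raise ValueError("effect sizes must be nonnegative")
        if self.poised_change_odds <= 0:
            raise ValueError("poised_change_odds must be positive")
        if not 0.0 < self.gc_low <= self.gc_high < 1.0:
            raise ValueError("need 0 < gc_low <= gc_high < 1")
        if self.snp_count < 1:
            raise ValueError("snp_count must be >= 1")
        if not 2 <= self.pwm_width_min <= self.pwm_width_max:
            raise ValueError("need 2 <= pwm_width_min <= pwm_width_max")


@dataclass
class TruthTable:
    """Planted ground truth recorded by the generators.

    ``genes`` carries one row per gene: DE status per cell type
    ({up,down,none}), the direction archetype, baseline log2 expression,
    true promoter state, and ChIP change per cell type.
    ``pwm_targets`` maps PWM id -> planted target gene ids.
    ``snps`` carries the per-SNP proximal_effect flag and anchor gene.
    """

    genes: pd.DataFrame
    pwm_targets: dict[str, list[str]] = field(default_factory=dict)
    snps: pd.DataFrame | None = None

    def de_status(self, cell_type: str) -> pd.Series:
        return self.genes.set_index("gene_id")[f"de_{cell_type}"]

    def chip_status(self, cell_type: str) -> pd.Series:
        return self.genes.set_index("gene_id")[f"chip_{cell_type}"]


# ---------------------------------------------------------------------------
# annotation


MIN_TSS_SPACING = 2000


def generate_annotation(config: SimulationConfig) -> pd.DataFrame:
    """Place genes on chromosomes with TSSs at least 2 kb apart.

    Returns a DataFrame (gene_id, chrom, tss, strand); 0-based TSS, kept at
    least 500 bp from chromosome ends so promoter windows never clamp.
    """
    rng = substream(config.seed, "annotation")
    n_per_chrom = np.full(config.n_chromosomes, config.n_genes // config.n_chromosomes)
    n_per_chrom[: config.n_genes % config.n_chromosomes] += 1
    records = []
    gid = 0
    for ci, n_c in enumerate(n_per_chrom):
        if n_c == 0:
            continue
        required = 1000 + (n_c - 1) * MIN_TSS_SPACING + 1000
        if required > config.chrom_length:
            raise ValueError(
                f"chromosome chr{ci + 1} of length {config.chrom_length} bp cannot hold "
                f"{n_c} TSSs spaced >= {MIN_TSS_SPACING} bp; needs at least {required} bp"
            )
        slack = config.chrom_length - required
        extra = np.sort(rng.uniform(0.0, slack, size=n_c)).astype(np.int64)
        tss = 1000 + np.arange(n_c) * MIN_TSS_SPACING + extra
        strands = rng.choice(["+", "-"], size=n_c)
        for t, s in zip(tss, strands):
            records.append((f"G{gid:05d}", f"chr{ci + 1}", int(t), s))
            gid += 1
    ann = pd.DataFrame(records, columns=["gene_id", "chrom", "tss", "strand"])
    return ann


# ---------------------------------------------------------------------------
# PWM library


def generate_pwm_library(
    n_pwms: int,
    width_min: int,
    width_max: int,
    concentration: float,
    seed: int,
) -> list[PositionWeightMatrix]:
    """Sample column-stochastic PWMs from a Dirichlet(concentration) prior.

    Small concentrations give peaked (information-rich) columns, large ones
    near-uniform columns.
    """
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    if not 2 <= width_min <= width_max:
        raise ValueError("need 2 <= width_min <= width_max")
    rng = substream(seed, "pwm_library")
    pwms = []
    for i in range(n_pwms):
        width = int(rng.integers(width_min, width_max + 1))
        probs = rng.dirichlet(np.full(4, concentration), size=width).T  # 4 x W
        pwms.append(PositionWeightMatrix(id=f"PWM{i:04d}", probs=probs))
    return pwms


# ---------------------------------------------------------------------------
# promoter sequences

_BASES = np.array(list("ACGT"))


def generate_promoter_sequences(
    annotation: pd.DataFrame,
    gc_low: float,
    gc_high: float,
    plantings: Mapping[str, Sequence[str]] | None,
    pwms: Sequence[PositionWeightMatrix] | None,
    seed: int,
    length: int = 1000,
) -> tuple[dict[str, str], pd.Series]:
    """One promoter sequence per gene with recorded GC and planted motifs.

    Per-gene GC fraction is drawn uniformly in [gc_low, gc_high]; bases are
    i.i.d. with that GC. For each planting the PWM's consensus string is
    embedded once at a random offset (forward strand).
    Returns (sequences, gc_truth).
    """
    if not 0.0 < gc_low <= gc_high < 1.0:
        raise ValueError("need 0 < gc_low <= gc_high < 1")
    plantings = dict(plantings or {})
    pwm_by_id = {p.id: p for p in (pwms or [])}
    gene_ids = annotation["gene_id"].tolist()
    known = set(gene_ids)
    for pwm_id, genes in plantings.items():
        if pwm_id not in pwm_by_id:
            raise ValueError(f"planting references unknown PWM {pwm_id!r}")
        unknown = set(genes) - known
        if unknown:
            raise ValueError(f"planting for {pwm_id} references unknown genes: {sorted(unknown)[:5]}")
        if pwm_by_id[pwm_id].width > length:
            raise ValueError(f"PWM {pwm_id} wider ({pwm_by_id[pwm_id].width}) than sequence ({length})")

    rng = substream(seed, "promoter_sequences")
    gc = pd.Series(rng.uniform(gc_low, gc_high, size=len(gene_ids)), index=gene_ids, name="gc")
    sequences: dict[str, str] = {}
    for g in gene_ids:
        p_gc = gc[g]
        probs = np.array([(1 - p_gc) / 2, p_gc / 2, p_gc / 2, (1 - p_gc) / 2])
        seq = rng.choice(_BASES, size=length, p=probs)
        sequences[g] = "".join(seq)
    # embed consensus occurrences after background generation so every
    # planted gene carries at least one exact match
    for pwm_id, genes in plantings.items():
        consensus = pwm_by_id[pwm_id].consensus
        w = len(consensus)
        for g in genes:
            off = int(rng.integers(0, length - w + 1))
            s = sequences[g]
            sequences[g] = s[:off] + consensus + s[off + w:]
    return sequences, gc


# ---------------------------------------------------------------------------
# expression counts


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB with variance mu + dispersion*mu^2 (gamma-Poisson mixture)."""
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def generate_expression_counts(
    annotation: pd.DataFrame, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame, TruthTable]:
    """Negative-binomial counts for genes x (3 cell types x 2 groups x n).

    Plants shared-DE genes (same +-effect_logfc shift in all 3 cell types)
    and cell-specific DE genes (one cell type), recording the archetype.
    Returns (counts, sample_table, truth).
    """
    rng = substream(config.seed, "expression")
    genes = annotation["gene_id"].to_numpy()
    n = len(genes)
    baseline = rng.normal(5.0, 1.5, size=n)  # log2 mean counts

    archetype = np.array(["none"] * n, dtype=object)
    n_shared = int(round(config.frac_shared_de * n))
    n_spec = int(round(config.frac_cellspecific_de * n))
    if config.effect_logfc > 0 and (n_shared + n_spec) > 0:
        chosen = rng.permutation(n)[: n_shared + n_spec]
        shared, spec = chosen[:n_shared], chosen[n_shared:]
        half = n_shared // 2
        archetype[shared[:half]] = "shared_up"
        archetype[shared[half:]] = "shared_down"
        # cell-specific genes split evenly over (cell type x direction)
        specs = [f"{ct}_{d}" for ct in config.cell_types for d in ("up", "down")]
        for i, gi in enumerate(spec):
            archetype[gi] = specs[i % len(specs)]

    de = {ct: np.array(["none"] * n, dtype=object) for ct in config.cell_types}
    shift = {ct: np.zeros(n) for ct in config.cell_types}
    for i, arch in enumerate(archetype):
        if arch == "none":
            continue
        if arch.startswith("shared"):
            d = arch.split("_")[1]
            for ct in config.cell_types:
                de[ct][i] = d
                shift[ct][i] = config.effect_logfc if d == "up" else -config.effect_logfc
        else:
            ct, d = arch.rsplit("_", 1)
            de[ct][i] = d
            shift[ct][i] = config.effect_logfc if d == "up" else -config.effect_logfc

    columns, sample_rows, blocks = [], [], []
    for ct in config.cell_types:
        for grp in GROUPS:
            mean_log2 = baseline + (shift[ct] if grp == "sle" else 0.0)
            mu = np.power(2.0, mean_log2)
            for r in range(1, config.n_per_group + 1):
                sample = f"rna_{ct}_{grp}{r}"
                columns.append(sample)
                sample_rows.append((sample, ct, grp, "rna"))
                blocks.append(_nb_draw(rng, mu, config.nb_dispersion))
    counts = pd.DataFrame(np.column_stack(blocks), index=genes, columns=columns)
    counts.index.name = "feature_id"
    samples = pd.DataFrame(sample_rows, columns=["sample_id", "cell_type", "group", "assay"])

    truth_genes = pd.DataFrame({"gene_id": genes, "archetype": archetype,
                                "baseline_log2": baseline})
    for ct in config.cell_types:
        truth_genes[f"de_{ct}"] = de[ct]
    return counts, samples, TruthTable(genes=truth_genes)


# ---------------------------------------------------------------------------
# ChIP reads


def generate_chip_reads(
    annotation: pd.DataFrame, config: SimulationConfig, truth: TruthTable | None = None
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame, TruthTable]:
    """Per-sample stranded read intervals with trimodal promoter depth.

    Per promoter a true state is drawn from ``trimodal_weights`` and a
    promoter-level log2 depth from the matching normal component; each
    sample adds lognormal noise (SD ``chip_sample_sd``) and draws a Poisson
    read count around 2^depth. SLE-related changes (+-chip_effect_logfc)
    are planted with probability proportional to ``poised_change_odds`` in
    the poised class. Reads are ``chip_read_length`` bp, uniform within the
    1 kb promoter window; a ``chip_decoy_fraction`` of extra low-quality
    reads (low mapq, clipped CIGAR, some secondary/duplicate flags) is
    scattered uniformly to make the SAM-field filter consequential.

    Returns (reads_per_sample, sample_table, truth) where truth gains the
    promoter_state and chip_<cell type> columns.
    """
    config.validate()
    rng = substream(config.seed, "chip")
    genes = annotation["gene_id"].to_numpy()
    n = len(genes)
    rl = config.chip_read_length
    if rl <= 0 or rl > 1000:
        raise ValueError("chip_read_length must lie in (0, 1000]")

    states = rng.choice(3, size=n, p=np.asarray(config.trimodal_weights))
    means = np.asarray(config.trimodal_means)[states]
    sds = np.asarray(config.trimodal_sds)[states]
    base_depth = rng.normal(means, sds)

    # plant changes, enriched in the poised (intermediate) class
    odds = np.where(states == 1, config.poised_change_odds, 1.0)
    w = np.asarray(config.trimodal_weights)
    norm = w[0] + w[1] * config.poised_change_odds + w[2]
    p_change = np.minimum(config.frac_chip_change * odds / norm, 1.0)
    changed = rng.random(n) < p_change
    direction = np.where(rng.random(n) < 0.5, 1.0, -1.0)
    shared = rng.random(n) < 0.5
    spec_ct = rng.integers(0, len(config.cell_types), size=n)

    chip = {ct: np.array(["none"] * n, dtype=object) for ct in config.cell_types}
    delta = {ct: np.zeros(n) for ct in config.cell_types}
    if config.chip_effect_logfc > 0:
        for k, ct in enumerate(config.cell_types):
            affect = changed & (shared | (spec_ct == k))
            chip[ct][affect] = np.where(direction[affect] > 0, "up", "down")
            delta[ct][affect] = direction[affect] * config.chip_effect_logfc

    windows = np.column_stack([annotation["tss"].to_numpy() - 500,
                               annotation["tss"].to_numpy() + 500])
    chroms = annotation["chrom"].to_numpy()

    reads_per_sample: dict[str, pd.DataFrame] = {}
    sample_rows = []
    for ct in config.cell_types:
        for grp in GROUPS:
            for r in range(1, config.n_per_group + 1):
                sample = f"chip_{ct}_{grp}{r}"
                sample_rows.append((sample, ct, grp, "chip"))
                depth = base_depth + (delta[ct] if grp == "sle" else 0.0)
                depth = depth + rng.normal(0.0, config.chip_sample_sd, size=n)
                lam = np.power(2.0, depth)
                counts = rng.poisson(lam)
                total = int(counts.sum())
                prom_idx = np.repeat(np.arange(n), counts)
                starts = (windows[prom_idx, 0]
                          + rng.integers(0, 1000 - rl + 1, size=total)).astype(np.int64)
                strands = rng.choice(["+", "-"], size=total)
                n_decoy = int(round(config.chip_decoy_fraction * total))
                d_chrom = rng.choice(np.unique(chroms), size=n_decoy)
                d_start = rng.integers(0, config.chrom_length - rl, size=n_decoy)
                d_flag = rng.choice([256, 1024, 0], size=n_decoy, p=[0.4, 0.3, 0.3])
                frame = pd.DataFrame({
                    "chrom": np.concatenate([chroms[prom_idx], d_chrom]),
                    "start": np.concatenate([starts, d_start]),
                    "end": np.concatenate([starts + rl, d_start + rl]),
                    "name": [f"{sample}_r{i}" for i in range(total + n_decoy)],
                    "mapq": np.concatenate([np.full(total, 60, dtype=np.int32),
                                            rng.integers(0, 15, size=n_decoy).astype(np.int32)]),
                    "strand": np.concatenate([strands, rng.choice(["+", "-"], size=n_decoy)]),
                    "flag": np.concatenate([np.where(strands == "-", 16, 0),
                                            d_flag]).astype(np.int64),
                    "cigar": [f"{rl}M"] * total + [f"10S{rl - 10}M"] * n_decoy,
                })
                frame["cigar_clean"] = eio.cigar_is_clean(frame["cigar"].to_numpy())
                reads_per_sample[sample] = frame
    samples = pd.DataFrame(sample_rows, columns=["sample_id", "cell_type", "group", "assay"])

    if truth is None:
        truth = TruthTable(genes=pd.DataFrame({"gene_id": genes}))
    tg = truth.genes.set_index("gene_id")
    tg["promoter_state"] = pd.Series(np.array(STATES)[states], index=genes)
    for ct in config.cell_types:
        tg[f"chip_{ct}"] = pd.Series(chip[ct], index=genes)
    truth.genes = tg.reset_index()
    return reads_per_sample, samples, truth


# ---------------------------------------------------------------------------
# SNP tables

SNP_SET_NAMES = ("GWAS95", "LD46", "META25")
# relative sizes mimic the three published source sets (95 / 46 / 25 SNPs)
_SNP_SET_FRACTIONS = (95 / 143, 46 / 143, 25 / 143)


def generate_snp_table(
    annotation: pd.DataFrame, truth: TruthTable, config: SimulationConfig
) -> tuple[pd.DataFrame, TruthTable]:
    """SNPs with association p-values and three overlapping source sets.

    A fraction ``snp_proximal_fraction`` is placed within 10 kb of TSSs of
    planted shared-downregulated genes (preferring the higher-baseline half,
    so that baseline signal near variants exceeds background); the rest are
    uniform. Proximal SNPs draw association p below 1e-8; the remainder
    spread log-uniformly over (1e-8, 1].
    """
    rng = substream(config.seed, "snp")
    n = config.snp_count
    n_prox = int(round(config.snp_proximal_fraction * n))

    tg = truth.genes
    down_mask = tg.get("archetype", pd.Series("none", index=tg.index)) == "shared_down"
    if not down_mask.any():
        de_cols = [c for c in tg.columns if c.startswith("de_")]
        down_mask = (tg[de_cols] == "down").any(axis=1) if de_cols else down_mask
    if n_prox > 0 and not down_mask.any():
        raise ValueError("snp_proximal_fraction > 0 but no downregulated genes were planted")

    ann = annotation.set_index("gene_id")
    positions, chroms, prox_flags, anchors = [], [], [], []
    if n_prox > 0:
        down = tg.loc[down_mask].copy()
        if "baseline_log2" in down.columns and len(down) > 1:
            down = down.sort_values("baseline_log2", ascending=False)
            down = down.head(max(1, len(down) // 2))  # higher-expressed anchors
        anchor_genes = rng.choice(down["gene_id"].to_numpy(), size=n_prox)
        for g in anchor_genes:
            tss = int(ann.loc[g, "tss"])
            # well within the 10 kb proximity definition, and close enough
            # that the anchor is usually the nearest TSS despite neighbors
            pos = int(np.clip(tss + rng.integers(-2_000, 2_001),
                              0, config.chrom_length - 1))
            positions.append(pos)
            chroms.append(ann.loc[g, "chrom"])
            prox_flags.append(True)
            anchors.append(g)
    all_chroms = annotation["chrom"].unique()
    for _ in range(n - n_prox):
        chroms.append(rng.choice(all_chroms))
        positions.append(int(rng.integers(0, config.chrom_length)))
        prox_flags.append(False)
        anchors.append("")

    pvals = np.empty(n)
    prox = np.asarray(prox_flags)
    pvals[prox] = 10.0 ** rng.uniform(-12.0, -8.05, size=prox.sum())
    pvals[~prox] = 10.0 ** rng.uniform(-8.0, 0.0, size=(~prox).sum())

    # three overlapping source sets; every SNP gets at least one label
    labels = [set() for _ in range(n)]
    for name, frac in zip(SNP_SET_NAMES, _SNP_SET_FRACTIONS):
        size = max(1, int(round(frac * n)))
        for i in rng.choice(n, size=min(size, n), replace=False):
            labels[i].add(name)
    for lab in labels:
        if not lab:
            lab.add(SNP_SET_NAMES[0])

    snps = pd.DataFrame({
        "snp_id": [f"rs{i:05d}" for i in range(n)],
        "chrom": chroms,
        "pos": positions,
        "pvalue": pvals,
        "set_label": [",".join(sorted(l)) for l in labels],
    })
    truth.snps = pd.DataFrame({
        "snp_id": snps["snp_id"],
        "proximal_effect": prox,
        "anchor_gene": anchors,
    })
    return snps, truth


# ---------------------------------------------------------------------------
# gene sets derived from planted truth (exercise the GMT path end-to-end)


def truth_gene_sets(truth: TruthTable, seed: int, n_random: int = 8,
                    random_size: int = 100) -> dict[str, tuple[str, list[str]]]:
    """Planted shared-up/down sets plus random decoy sets, as GMT content."""
    rng = substream(seed, "gene_sets")
    tg = truth.genes
    sets: dict[str, tuple[str, list[str]]] = {}
    for arch, name in (("shared_up", "SHARED_UP_TRUTH"), ("shared_down", "SHARED_DOWN_TRUTH")):
        members = tg.loc[tg["archetype"] == arch, "gene_id"].tolist()
        if members:
            sets[name] = (f"planted {arch} genes", members)
    genes = tg["gene_id"].to_numpy()
    for i in range(n_random):
        members = rng.choice(genes, size=min(random_size, len(genes)), replace=False)
        sets[f"RANDOM_{i:02d}"] = ("random decoy set", sorted(members))
    return sets


# ---------------------------------------------------------------------------
# one-call simulation writing every output format


@dataclass
class SimulationOutput:
    """In-memory handles plus file paths for one simulated study."""

    config: SimulationConfig
    annotation: pd.DataFrame
    sequences: dict[str, str]
    gc: pd.Series
    pwms: list[PositionWeightMatrix]
    rna_counts: pd.DataFrame
    samples: pd.DataFrame
    chip_reads: dict[str, pd.DataFrame]
    snps: pd.DataFrame
    truth: TruthTable
    gene_sets: dict[str, tuple[str, list[str]]]
    paths: dict[str, object] = field(default_factory=dict)


def simulate_study(config: SimulationConfig, outdir=None,
                   plant_pwm_targets: bool = True) -> SimulationOutput:
    """Run every generator under one master seed; optionally write files.

    When ``plant_pwm_targets`` is set, the consensus of the most
    information-rich library PWM is embedded in the promoters of planted
    shared-up genes (plus random fill to 300 genes) and the second-richest
    in ChIP-up promoters, so the TF target-recovery path has signal to
    find. (Only a specific motif is recoverable: a low-information
    consensus is matched by background sequence by chance.)
    """
    annotation = generate_annotation(config)
    pwms = generate_pwm_library(config.n_pwms, config.pwm_width_min,
                                config.pwm_width_max, config.pwm_concentration,
                                config.seed)
    rna_counts, rna_samples, truth = generate_expression_counts(annotation, config)
    chip_reads, chip_samples, truth = generate_chip_reads(annotation, config, truth)
    snps, truth = generate_snp_table(annotation, truth, config)

    plantings: dict[str, list[str]] = {}
    if plant_pwm_targets and len(pwms) >= 2:
        rng = substream(config.seed, "plantings")
        tg = truth.genes
        all_genes = tg["gene_id"].to_numpy()

        def _total_ic(p: PositionWeightMatrix) -> float:
            q = np.clip(p.probs, 1e-12, 1.0)
            return float(np.sum(2.0 + (q * np.log2(q)).sum(axis=0)))

        by_ic = sorted(pwms, key=_total_ic, reverse=True)

        def _fill(core: list[str], target: int) -> list[str]:
            pool = np.setdiff1d(all_genes, np.asarray(core, dtype=object))
            extra = rng.choice(pool, size=max(0, min(target - len(core), len(pool))),
                               replace=False)
            return sorted(set(core) | set(extra))

        up = tg.loc[tg["archetype"] == "shared_up", "gene_id"].tolist()
        chip_up = tg.loc[(tg[[f"chip_{ct}" for ct in config.cell_types]] == "up").any(axis=1),
                         "gene_id"].tolist()
        target_size = min(300, len(all_genes))
        plantings[by_ic[0].id] = _fill(up, target_size)
        plantings[by_ic[1].id] = _fill(chip_up, target_size)
    truth.pwm_targets = {k: list(v) for k, v in plantings.items()}

    sequences, gc = generate_promoter_sequences(
        annotation, config.gc_low, config.gc_high, plantings, pwms, config.seed)
    gene_sets = truth_gene_sets(truth, config.seed)
    samples = pd.concat([rna_samples, chip_samples], ignore_index=True)

    out = SimulationOutput(config=config, annotation=annotation, sequences=sequences,
                           gc=gc, pwms=pwms, rna_counts=rna_counts, samples=samples,
                           chip_reads=chip_reads, snps=snps, truth=truth,
                           gene_sets=gene_sets)
    if outdir is not None:
        out.paths = write_simulation(out, Path(outdir))
    return out


def write_simulation(sim: SimulationOutput, outdir: Path) -> dict[str, object]:
    """Write every simulated artifact in its flat text format."""
    from .genesets import write_gmt
    from .tftargets import write_pwm_library

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reads_dir = outdir / "reads"
    reads_dir.mkdir(exist_ok=True)

    paths: dict[str, object] = {
        "annotation": outdir / "annotation.tsv",
        "promoters": outdir / "promoters.fa",
        "pwms": outdir / "pwms.jaspar",
        "rna_counts": outdir / "rna_counts.tsv",
        "samples": outdir / "samples.tsv",
        "snps": outdir / "snps.tsv",
        "gene_sets": outdir / "gene_sets.gmt",
        "truth_genes": outdir / "truth_genes.tsv",
        "truth_snps": outdir / "truth_snps.tsv",
        "truth_gc": outdir / "truth_gc.tsv",
        "truth_pwm_targets": outdir / "truth_pwm_targets.tsv",
    }
    eio.write_annotation(sim.annotation, paths["annotation"])
    eio.write_fasta(sim.sequences, paths["promoters"])
    write_pwm_library(sim.pwms, paths["pwms"])
    eio.write_matrix(sim.rna_counts, paths["rna_counts"])
    eio.write_sample_table(sim.samples, paths["samples"])
    eio.write_snp_table(sim.snps, paths["snps"])
    write_gmt({k: v for k, v in sim.gene_sets.items()}, paths["gene_sets"])
    sim.truth.genes.to_csv(paths["truth_genes"], sep="\t", index=False)
    sim.truth.snps.to_csv(paths["truth_snps"], sep="\t", index=False)
    sim.gc.rename_axis("gene_id").reset_index().to_csv(paths["truth_gc"], sep="\t", index=False)
    with open(paths["truth_pwm_targets"], "w") as fh:
        fh.write("pwm_id\tgene_id\n")
        for pwm_id, genes in sim.truth.pwm_targets.items():
            for g in genes:
                fh.write(f"{pwm_id}\t{g}\n")

    read_paths = {}
    for sample, frame in sim.chip_reads.items():
        p = reads_dir / f"{sample}.bed"
        eio.write_reads(frame, p)
        read_paths[sample] = p
    paths["reads"] = read_paths
    return paths
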