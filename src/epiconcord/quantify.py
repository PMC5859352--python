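"""Promoter-level and SNP-window quantification of aligned ChIP reads.

The pipeline mirrors standard promoter H3K4me3 processing: reads are
filtered on SAM fields (mapq, flag bits, CIGAR cleanliness), extended to
200 bp at their 3' end, and counted into 1 kb promoter windows (>=1 bp
overlap; a read spanning two windows counts in both). SNP windows get mean
per-base depth instead of counts.

Coordinates are 0-based half-open throughout. Counting uses a vectorized
searchsorted scheme over windows sorted by start, exact for any window set
whose lengths are bounded (the bound is taken from the data).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_MIN_MAPQ = 20
# unmapped, secondary, PCR/optical duplicate
DEFAULT_EXCLUDE_FLAGS = 0x4 | 0x100 | 0x400


def filter_reads(
    reads: pd.DataFrame,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    exclude_flags: int = DEFAULT_EXCLUDE_FLAGS,
    require_clean_cigar: bool = True,
) -> pd.DataFrame:
    """Keep reads with mapq >= min_mapq, none of the excluded flag bits set,
    and (optionally) an ungapped CIGAR. Input order is preserved."""
    keep = reads["mapq"].to_numpy() >= min_mapq
    keep &= (reads["flag"].to_numpy() & exclude_flags) == 0
    if require_clean_cigar:
        keep &= reads["cigar_clean"].to_numpy().astype(bool)
    return reads.loc[keep]


def extend_reads(reads: pd.DataFrame, target_length: int = 200) -> pd.DataFrame:
    """Extend each read to ``target_length`` bp at its 3' end.

    Plus-strand reads keep their start; minus-strand reads keep their end
    and grow upstream, clamped at position 0. Idempotent on its own output.
    """
    lengths = reads["end"].to_numpy() - reads["start"].to_numpy()
    too_long = lengths > target_length
    if too_long.any():
        offender = reads.loc[too_long].iloc[0]
        raise ValueError(
            f"target_length {target_length} is shorter than read "
            f"{offender['name']!r} ({offender['chrom']}:{offender['start']}-{offender['end']})"
        )
    out = reads.copy()
    plus = out["strand"].to_numpy() == "+"
    starts = out["start"].to_numpy().copy()
    ends = out["end"].to_numpy().copy()
    ends[plus] = starts[plus] + target_length
    starts[~plus] = np.maximum(ends[~plus] - target_length, 0)
    out["start"] = starts
    out["end"] = ends
    return out


def make_promoter_windows(
    annotation: pd.DataFrame, span: int = 1000, anchor: str = "centered"
) -> pd.DataFrame:
    """1 kb promoter windows around each TSS.

    ``centered`` (default): [TSS - span/2, TSS + span/2) regardless of
    strand, matching the symmetric SNP windows. ``upstream``: the span
    immediately 5' of the TSS on the annotated strand. Starts clamp at 0.
    """
    if span % 2 != 0:
        raise ValueError("span must be even")
    tss = annotation["tss"].to_numpy()
    if anchor == "centered":
        start = tss - span // 2
        end = tss + span // 2
    elif anchor == "upstream":
        plus = annotation["strand"].to_numpy() == "+"
        start = np.where(plus, tss - span, tss)
        end = np.where(plus, tss, tss + span)
    else:
        raise ValueError(f"unknown anchor {anchor!r}")
    windows = pd.DataFrame({
        "gene_id": annotation["gene_id"].to_numpy(),
        "chrom": annotation["chrom"].to_numpy(),
        "start": np.maximum(start, 0).astype(np.int64),
        "end": end.astype(np.int64),
        "strand": annotation["strand"].to_numpy(),
    })
    return windows


# ---------------------------------------------------------------------------
# overlap machinery


def _overlap_pairs(w_start, w_end, r_start, r_end):
    """Indices (read_idx, win_idx) of every read/window pair overlapping by
    >= 1 bp. Windows must be sorted by start; lengths may vary (bounded)."""
    w_start = np.asarray(w_start, dtype=np.int64)
    w_end = np.asarray(w_end, dtype=np.int64)
    r_start = np.asarray(r_start, dtype=np.int64)
    r_end = np.asarray(r_end, dtype=np.int64)
    if len(w_start) == 0 or len(r_start) == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    max_w = int((w_end - w_start).max())
    # candidate windows: w_start in (r_start - max_w, r_end)
    lo = np.searchsorted(w_start, r_start - max_w + 1, side="left")
    hi = np.searchsorted(w_start, r_end, side="left")
    counts = hi - lo
    total = int(counts.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    read_idx = np.repeat(np.arange(len(r_start)), counts)
    offsets = np.arange(total) - np.repeat(np.cumsum(counts) - counts, counts)
    win_idx = np.repeat(lo, counts) + offsets
    keep = w_end[win_idx] > r_start[read_idx]
    return read_idx[keep], win_idx[keep]


def count_promoter_reads(
    reads_per_sample: dict[str, pd.DataFrame], windows: pd.DataFrame
) -> pd.DataFrame:
    """Integer matrix of reads overlapping each promoter window (>= 1 bp).

    A read overlapping two windows counts in both; input read order is
    irrelevant. Reads are expected to be filtered and extended already.
    """
    windows = windows.reset_index(drop=True)
    order = {c: g.sort_values("start") for c, g in windows.groupby("chrom", sort=False)}
    result = pd.DataFrame(0, index=windows["gene_id"],
                          columns=list(reads_per_sample), dtype=np.int64)
    for sample, reads in reads_per_sample.items():
        col = np.zeros(len(windows), dtype=np.int64)
        win_groups = order
        skipped = 0
        for chrom, block in reads.groupby("chrom", sort=False):
            wb = win_groups.get(str(chrom))
            if wb is None:
                skipped += len(block)
                continue
            ri, wi = _overlap_pairs(wb["start"].to_numpy(), wb["end"].to_numpy(),
                                    block["start"].to_numpy(), block["end"].to_numpy())
            np.add.at(col, wb.index.to_numpy()[wi], 1)
        if skipped:
            logger.warning("count_promoter_reads[%s]: skipped %d reads on "
                           "chromosomes absent from the window set", sample, skipped)
        result[sample] = col
    result.index.name = "feature_id"
    return result


def snp_window_coverage(
    reads_per_sample: dict[str, pd.DataFrame],
    snps: pd.DataFrame,
    halfwidth: int = 500,
) -> pd.DataFrame:
    """Mean per-base read depth over [pos - halfwidth, pos + halfwidth).

    Entry (snp, sample) = sum over reads of overlap length / window width.
    SNPs on chromosomes without reads get zero rows (flagged in the log).
    """
    snps = snps.reset_index(drop=True)
    width = 2 * halfwidth
    win = pd.DataFrame({
        "gene_id": snps["snp_id"],
        "chrom": snps["chrom"],
        "start": np.maximum(snps["pos"].to_numpy() - halfwidth, 0),
        "end": snps["pos"].to_numpy() + halfwidth,
    })
    order = {c: g.sort_values("start") for c, g in win.groupby("chrom", sort=False)}
    result = pd.DataFrame(0.0, index=snps["snp_id"], columns=list(reads_per_sample))
    seen_chroms = set()
    for sample, reads in reads_per_sample.items():
        seen_chroms.update(reads["chrom"].unique())
        col = np.zeros(len(win))
        for chrom, block in reads.groupby("chrom", sort=False):
            wb = order.get(str(chrom))
            if wb is None:
                continue
            ws, we = wb["start"].to_numpy(), wb["end"].to_numpy()
            rs, re_ = block["start"].to_numpy(), block["end"].to_numpy()
            ri, wi = _overlap_pairs(ws, we, rs, re_)
            overlap = np.minimum(re_[ri], we[wi]) - np.maximum(rs[ri], ws[wi])
            np.add.at(col, wb.index.to_numpy()[wi], overlap / width)
        result[sample] = col
    unknown = set(snps["chrom"]) - seen_chroms
    if unknown:
        logger.warning("snp_window_coverage: SNPs on chromosomes %s have no reads; "
                       "rows left at zero", sorted(unknown))
    result.index.name = "feature_id"
    return result
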