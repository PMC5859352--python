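"""Parametric analysis of gene set enrichment (PAGE) and GMT I/O.

PAGE compares each set's mean score against the global score distribution:
with global mean mu and *population* standard deviation delta over all
scored genes, a set of size m with mean S_m gets

    Z = (S_m - mu) * sqrt(m) / delta,

two-sided normal p, and a signed enrichment score S_m - mu whose sign gives
the direction of the overall change. Scores are typically log2 fold changes
so a positive enrichment means the set moves up in disease.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .differential import benjamini_hochberg

logger = logging.getLogger(__name__)

DEFAULT_MIN_SIZE = 10
DEFAULT_MAX_SIZE = 2000


@dataclass
class GeneSetCollection:
    """Named gene sets with descriptions; members are deduplicated."""

    sets: dict[str, set[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: set id, description, then member ids, tab-separated.

    Duplicate members are deduplicated; a line with fewer than 3 fields or
    an empty member list raises with the offending line number.
    """
    collection = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 tab-separated fields")
            set_id, desc, *members = fields
            members = {m for m in members if m}
            if not members:
                raise ValueError(f"{path}:{lineno}: gene set {set_id!r} has no members")
            if set_id in collection.sets:
                raise ValueError(f"{path}:{lineno}: duplicate set id {set_id!r}")
            collection.sets[set_id] = members
            collection.descriptions[set_id] = desc
    return collection


def write_gmt(sets, path) -> None:
    """Write gene sets as GMT. Accepts a GeneSetCollection or a mapping
    set_id -> (description, members)."""
    with open(path, "w") as fh:
        if isinstance(sets, GeneSetCollection):
            items = ((sid, sets.descriptions.get(sid, ""), members)
                     for sid, members in sets)
        else:
            items = ((sid, desc, members) for sid, (desc, members) in sets.items())
        for sid, desc, members in items:
            fh.write("\t".join([sid, desc, *sorted(set(members))]) + "\n")


@dataclass
class EnrichmentResult:
    set_id: str
    m: int
    z: float
    enrichment_score: float
    pvalue: float
    fdr: float = np.nan


def page_statistic(scores: pd.Series, set_members, set_id: str = "set") -> EnrichmentResult:
    """PAGE Z statistic for one gene set against the global distribution.

    Membership is intersected with the scored genes first; raises on an
    empty intersection or a degenerate (zero-spread) score distribution.
    """
    values = scores.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("scores must be finite")
    mu = values.mean()
    delta = values.std(ddof=0)
    if delta == 0.0:
        raise ValueError("degenerate score distribution")
    members = set(set_members) & set(scores.index)
    m = len(members)
    if m == 0:
        raise ValueError(f"gene set {set_id!r} has no scored members")
    s_m = scores.loc[sorted(members)].to_numpy().mean()
    z = (s_m - mu) * np.sqrt(m) / delta
    p = float(min(2.0 * stats.norm.sf(abs(z)), 1.0))
    p = max(p, np.finfo(float).tiny)
    return EnrichmentResult(set_id=set_id, m=m, z=float(z),
                            enrichment_score=float(s_m - mu), pvalue=p)


def page_scan(
    scores: pd.Series,
    collection: GeneSetCollection,
    min_size: int = DEFAULT_MIN_SIZE,
    max_size: int = DEFAULT_MAX_SIZE,
) -> pd.DataFrame:
    """PAGE over a collection with BH FDR across all tested sets.

    Sets whose intersection with the scored genes falls outside
    [min_size, max_size] are skipped with a log entry. Rows sorted by p.
    """
    if len(collection) == 0:
        raise ValueError("empty gene set collection")
    rows = []
    scored = set(scores.index)
    for set_id, members in collection:
        m = len(set(members) & scored)
        if m < min_size or m > max_size:
            logger.info("page_scan: skipping %s (m=%d outside [%d, %d])",
                        set_id, m, min_size, max_size)
            continue
        res = page_statistic(scores, members, set_id=set_id)
        rows.append((res.set_id, res.m, res.z, res.enrichment_score, res.pvalue))
    table = pd.DataFrame(rows, columns=["set_id", "m", "z", "enrichment_score", "pvalue"])
    if len(table):
        table["fdr"] = benjamini_hochberg(table["pvalue"].to_numpy())
        table = table.sort_values("pvalue", kind="mergesort").reset_index(drop=True)
    else:
        table["fdr"] = []
    return table
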