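"""Per-gene boolean binding calls at TSS/PAS windows and overlap statistics.

A gene is "bound" by an evidence type (ChIP summit, PAR-CLIP crosslink,
motif density) when enough point features fall inside a strand-oriented
window around the anchor.  The default windows follow the genome-wide
analyses: [TSS - 10, TSS + 250) at the 5' end and PAS +/- 250 nt at the 3'
end.  Features are not deduplicated across genes: a summit between two
close units may support both.
"""

from __future__ import annotations

from itertools import product
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .core_model import GeneSet, PointFeatures, StrandedCoverage, oriented_window
from .metagene import enrichment_ratio

__all__ = [
    "call_in_window",
    "overlap_stats",
    "peak_summits",
    "length_group_test",
    "TSS_WINDOW",
    "PAS_WINDOW",
]

TSS_WINDOW = (10, 250)  # upstream, downstream of the TSS
PAS_WINDOW = (250, 250)  # symmetric around the PAS


def call_in_window(
    features: PointFeatures,
    genes: GeneSet,
    anchor: str = "PAS",
    upstream: int = 250,
    downstream: int = 250,
    min_count: int = 1,
    match_strand: bool = True,
) -> pd.Series:
    """True per gene iff >= min_count features lie in the oriented window
    [anchor - upstream, anchor + downstream), half-open at the downstream
    edge.  ``match_strand=False`` admits features on either strand (useful
    for strand-less ChIP summits)."""
    anchor = anchor.upper()
    calls = {}
    for g in genes:
        a = g.tss if anchor == "TSS" else g.pas
        lo, hi = oriented_window(a, g.strand, -upstream, downstream)
        df = features.on(g.chrom, g.strand if match_strand else None)
        n = int(((df["position"] >= lo) & (df["position"] < hi)).sum())
        calls[g.gene_id] = n >= min_count
    return pd.Series(calls, dtype=bool)


def overlap_stats(
    calls: pd.DataFrame, evidences: Optional[List[str]] = None
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Venn region counts over k call vectors plus conditional fractions.

    Returns (regions, conditionals): ``regions`` has one row per membership
    pattern with its gene count (all 2^k rows, summing to the cohort size);
    ``conditionals`` reports P(B|A) for every ordered evidence pair with
    its numerator and denominator.
    """
    if evidences is None:
        evidences = list(calls.columns)
    mat = calls[evidences].astype(bool)
    rows = []
    for pattern in product([False, True], repeat=len(evidences)):
        mask = np.ones(len(mat), dtype=bool)
        for ev, val in zip(evidences, pattern):
            mask &= mat[ev].to_numpy() == val
        rows.append(
            {**{ev: val for ev, val in zip(evidences, pattern)}, "count": int(mask.sum())}
        )
    regions = pd.DataFrame(rows)
    cond_rows = []
    for a in evidences:
        for b in evidences:
            if a == b:
                continue
            denom = int(mat[a].sum())
            numer = int((mat[a] & mat[b]).sum())
            cond_rows.append(
                {
                    "given": a,
                    "event": b,
                    "numerator": numer,
                    "denominator": denom,
                    "fraction": numer / denom if denom else np.nan,
                }
            )
    return regions, pd.DataFrame(cond_rows)


def peak_summits(
    ip: StrandedCoverage,
    control: StrandedCoverage,
    min_enrichment: float = 2.0,
    min_width: int = 50,
    eps: float = 1.0,
) -> PointFeatures:
    """Transparent threshold peak caller on the per-base IP/input ratio.

    Contiguous runs with ratio >= min_enrichment spanning >= min_width
    bases become peaks; the summit is the argmax of the ratio within the
    run (leftmost position on ties).  The input is floored at ``eps``
    reads per base before dividing.
    """
    ratio = enrichment_ratio(ip, control, eps=eps)
    records = []
    for chrom, strand in ratio.keys():
        vec = ratio.get(chrom, strand)
        above = vec >= min_enrichment
        if not above.any():
            continue
        edges = np.flatnonzero(np.diff(above.astype(int)))
        starts = list(edges[~above[edges]] + 1) if edges.size else []
        ends = list(edges[above[edges]] + 1) if edges.size else []
        if above[0]:
            starts = [0] + starts
        if above[-1]:
            ends = ends + [len(vec)]
        for s, e in zip(starts, ends):
            if e - s < min_width:
                continue
            summit = s + int(np.argmax(vec[s:e]))  # argmax: leftmost on ties
            records.append((chrom, strand, summit, float(vec[summit])))
    return PointFeatures.from_records(records, role="summit")


def length_group_test(
    genes: GeneSet, calls_a: pd.Series, calls_b: pd.Series
) -> Tuple[pd.DataFrame, float]:
    """Are genes called by evidence A but not B longer than the rest?

    Splits the cohort into (A and not B) versus the complement and compares
    gene-length distributions by a two-sided Wilcoxon-Mann-Whitney test.
    """
    lengths = pd.Series({g.gene_id: g.length for g in genes}, dtype=float)
    a = calls_a.reindex(lengths.index).fillna(False).astype(bool)
    b = calls_b.reindex(lengths.index).fillna(False).astype(bool)
    group = a & ~b
    x = lengths[group].to_numpy()
    y = lengths[~group].to_numpy()
    if x.size == 0 or y.size == 0:
        raise ValueError("one of the length groups is empty")
    summary = pd.DataFrame(
        [
            {"group": "a_not_b", "n": x.size, "median_length": float(np.median(x))},
            {"group": "rest", "n": y.size, "median_length": float(np.median(y))},
        ]
    ).set_index("group")
    p = float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)
    return summary, p
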