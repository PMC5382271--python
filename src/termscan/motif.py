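"""Fixed-motif (UGUA) scanning on the transcribed strand.

The binding motif is given in RNA alphabet and matched against genomic DNA
with T standing for U.  Minus-strand matches are located on the reverse
complement and reported back in genomic coordinates; a match position is
always the genomic coordinate of the motif's 5' base on its own strand,
which is what windowed proximity statistics operate on.  Overlapping
matches are all reported.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .core_model import GeneSet, PointFeatures, oriented_window
from .metagene import AnchoredMatrix

__all__ = [
    "DEFAULT_MOTIF",
    "motif_to_dna",
    "motif_hits",
    "site_motif_fraction",
    "motif_metagene",
    "high_motif_flag",
]

DEFAULT_MOTIF = "UGUA"


def motif_to_dna(motif: str) -> str:
    motif = motif.upper().replace("U", "T")
    if len(motif) < 2 or any(b not in "ACGT" for b in motif):
        raise ValueError(f"motif must be >=2 unambiguous ACGU letters, got {motif!r}")
    return motif


def _scan(seq: str, pattern: str) -> List[int]:
    """All (overlapping) start indices of pattern in seq."""
    hits = []
    i = seq.find(pattern)
    while i != -1:
        hits.append(i)
        i = seq.find(pattern, i + 1)
    return hits


def motif_hits(sequence: str, strand: str, motif: str = DEFAULT_MOTIF) -> List[int]:
    """Genomic coordinates of the 5' base of every motif match on a strand.

    On the plus strand this is the usual left-most match coordinate; on the
    minus strand the motif is searched on the reverse complement and the 5'
    base maps to the right-most genomic base of the match.
    """
    pattern = motif_to_dna(motif)
    seq = sequence.upper()
    if strand == "+":
        return _scan(seq, pattern)
    rc = str(Seq(seq).reverse_complement())
    n = len(seq)
    return sorted(n - 1 - i for i in _scan(rc, pattern))


def site_motif_fraction(
    sites: PointFeatures,
    sequences: Dict[str, str],
    flank: int = 25,
    motif: str = DEFAULT_MOTIF,
) -> float:
    """Fraction of sites with >= 1 motif start within +/-flank nt.

    Matches the motif-occurrence statistic computed around crosslink sites:
    a site counts as positive when at least one motif 5' base lies within
    ``flank`` nt of it on the site's strand.
    """
    if len(sites) == 0:
        raise ValueError("site_motif_fraction undefined for zero sites")
    n_pos = 0
    hit_cache: Dict[tuple, np.ndarray] = {}
    for chrom, strand in sites.frame[["chrom", "strand"]].drop_duplicates().itertuples(
        index=False
    ):
        key = (chrom, strand)
        hit_cache[key] = np.asarray(
            motif_hits(sequences[chrom], strand, motif), dtype=int
        )
    for row in sites.frame.itertuples(index=False):
        hits = hit_cache[(row.chrom, row.strand)]
        if hits.size and np.any(np.abs(hits - row.position) <= flank):
            n_pos += 1
    return n_pos / len(sites)


def motif_metagene(
    genes: GeneSet,
    sequences: Dict[str, str],
    anchor: str = "PAS",
    L: int = 250,
    R: int = 250,
    motif: str = DEFAULT_MOTIF,
) -> AnchoredMatrix:
    """Anchored 0/1 indicator matrix of motif 5' positions per gene.

    Rows feed metagene aggregation; abundance normalization (motif
    frequency per transcript level) is applied by the caller.
    """
    width = L + R
    values = np.ma.masked_all((len(genes), width))
    positions = np.arange(-L, R)
    for i, g in enumerate(genes):
        a = g.tss if anchor.upper() == "TSS" else g.pas
        lo, hi = oriented_window(a, g.strand, -L, R)
        size = genes.chrom_sizes[g.chrom]
        row = np.zeros(width)
        mask = np.zeros(width, dtype=bool)
        hits = motif_hits(sequences[g.chrom], g.strand, motif)
        for h in hits:
            if lo <= h < hi:
                rel = (h - a) if g.strand == "+" else (a - 1 - h)
                row[rel + L] = 1.0
        # mask off-chromosome columns
        for j, p in enumerate(positions):
            x = (a + p) if g.strand == "+" else (a - 1 - p)
            if not (0 <= x < size):
                mask[j] = True
        values[i] = np.ma.MaskedArray(row, mask=mask)
    return AnchoredMatrix(
        values=values, positions=positions, gene_ids=list(genes.gene_ids), anchor=anchor
    )


def high_motif_flag(
    genes: GeneSet,
    sequences: Dict[str, str],
    upstream: int = 250,
    downstream: int = 250,
    anchor: str = "PAS",
    motif: str = DEFAULT_MOTIF,
) -> pd.Series:
    """Per-gene flag: motif count in the anchor window strictly above the
    cohort mean count.  Ties with the mean are False."""
    counts = {}
    for g in genes:
        a = g.tss if anchor.upper() == "TSS" else g.pas
        lo, hi = oriented_window(a, g.strand, -upstream, downstream)
        hits = motif_hits(sequences[g.chrom], g.strand, motif)
        counts[g.gene_id] = sum(lo <= h < hi for h in hits)
    ser = pd.Series(counts, dtype=float)
    if ser.empty:
        return ser.astype(bool)
    return ser > ser.mean()
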