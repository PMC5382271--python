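"""Anchor-aligned (metagene) profiles of coverage or point signals.

Genes are aligned at the TSS or PAS boundary and oriented in the direction
of transcription; relative position ``p`` (half-open window ``[-L, R)``)
addresses the genomic base ``a + p`` on the plus strand and ``a - 1 - p``
on the minus strand, so ``p = 0`` is the first base downstream of the
anchor on either strand.  Positions falling off the chromosome are masked,
not zero-filled, so short chromosomes do not bias window edges.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Sequence, Union

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .core_model import GeneSet, PointFeatures, StrandedCoverage

__all__ = [
    "AnchoredMatrix",
    "MetageneProfile",
    "anchored_matrix",
    "abundance_normalize",
    "aggregate",
    "gaussian_smooth",
    "rescale_to",
    "align_start",
    "enrichment_ratio",
]


@dataclass
class AnchoredMatrix:
    """Genes x relative-positions signal matrix (masked where off-chromosome)."""

    values: np.ma.MaskedArray  # shape (n_genes, width)
    positions: np.ndarray  # transcription-directed offsets, [-L, R)
    gene_ids: List[str]
    anchor: str  # "TSS" or "PAS"

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]


@dataclass
class MetageneProfile:
    positions: np.ndarray
    values: np.ndarray
    n: np.ndarray  # genes contributing per position
    aggregator: str = "mean"


def _relative_indices(anchor_pos: int, strand: str, positions: np.ndarray) -> np.ndarray:
    if strand == "+":
        return anchor_pos + positions
    return anchor_pos - 1 - positions


def anchored_matrix(
    signal: Union[StrandedCoverage, PointFeatures],
    genes: GeneSet,
    anchor: str = "PAS",
    L: int = 250,
    R: int = 250,
) -> AnchoredMatrix:
    """Build the per-gene anchored matrix from coverage or point features.

    Point features are binned at single-base resolution (values summed per
    base); minus-strand rows are reversed so the axis runs with
    transcription.
    """
    anchor = anchor.upper()
    if anchor not in ("TSS", "PAS"):
        raise ValueError("anchor must be TSS or PAS")
    positions = np.arange(-L, R)
    width = positions.size
    values = np.ma.masked_all((len(genes), width))

    is_points = isinstance(signal, PointFeatures)
    for i, g in enumerate(genes):
        a = g.tss if anchor == "TSS" else g.pas
        size = genes.chrom_sizes[g.chrom]
        idx = _relative_indices(a, g.strand, positions)
        valid = (idx >= 0) & (idx < size)
        row = np.zeros(width)
        if is_points:
            feats = signal.on(g.chrom, g.strand)
            if len(feats):
                pos = feats["position"].to_numpy()
                val = feats["value"].to_numpy()
                rel = (pos - a) if g.strand == "+" else (a - 1 - pos)
                inside = (rel >= -L) & (rel < R)
                np.add.at(row, rel[inside] + L, val[inside])
        else:
            row[valid] = signal.get(g.chrom, g.strand)[idx[valid]]
        values[i] = np.ma.MaskedArray(row, mask=~valid)
    return AnchoredMatrix(
        values=values, positions=positions, gene_ids=list(genes.gene_ids), anchor=anchor
    )


def abundance_normalize(
    matrix: AnchoredMatrix, abundance: Dict[str, float]
) -> AnchoredMatrix:
    """Divide each gene's row by its transcript abundance; genes with zero
    (or missing) abundance are masked rather than producing infinities."""
    values = matrix.values.copy()
    for i, gid in enumerate(matrix.gene_ids):
        a = abundance.get(gid, 0.0)
        if a > 0:
            values[i] = values[i] / a
        else:
            values[i] = np.ma.masked
    return replace(matrix, values=values)


def aggregate(matrix: AnchoredMatrix, aggregator: str = "mean") -> MetageneProfile:
    """Per-position mean or median over unmasked rows."""
    if aggregator not in ("mean", "median"):
        raise ValueError("aggregator must be mean or median")
    n = (~np.ma.getmaskarray(matrix.values)).sum(axis=0)
    if aggregator == "mean":
        agg = np.ma.mean(matrix.values, axis=0)
    else:
        agg = np.ma.median(matrix.values, axis=0)
    vals = np.ma.filled(agg, np.nan)
    return MetageneProfile(
        positions=matrix.positions.copy(), values=np.asarray(vals, dtype=float),
        n=n, aggregator=aggregator,
    )


def gaussian_smooth(profile: MetageneProfile, sigma: float) -> MetageneProfile:
    """Convolve with a discrete Gaussian kernel (sum 1, reflect-padded).

    ``sigma`` is in nucleotides; sigma <= 0 returns the profile unchanged.
    Total signal is conserved for pulses supported away from the edges.
    """
    if sigma <= 0:
        return replace(profile, values=profile.values.copy())
    smoothed = gaussian_filter1d(profile.values, sigma=sigma, mode="reflect")
    return replace(profile, values=smoothed)


def rescale_to(profile: MetageneProfile, reference: MetageneProfile) -> MetageneProfile:
    """Scale so the profile's maximum matches the reference's maximum
    (used to overlay signals of different units on one axis)."""
    pmax = np.nanmax(profile.values)
    if not pmax > 0:
        raise ValueError("cannot rescale a non-positive profile")
    factor = np.nanmax(reference.values) / pmax
    return replace(profile, values=profile.values * factor)


def align_start(
    profiles: Sequence[MetageneProfile], k: int = 1
) -> List[MetageneProfile]:
    """Normalize each profile to its value at the leftmost position.

    If that value is zero the mean of the first ``k`` positions is used as
    a fallback; a zero fallback raises.
    """
    out = []
    for p in profiles:
        v0 = p.values[0]
        if v0 == 0:
            v0 = float(np.nanmean(p.values[:k]))
        if not np.isfinite(v0) or v0 == 0:
            raise ValueError("profile starts at zero; cannot align")
        out.append(replace(p, values=p.values / v0))
    return out


def enrichment_ratio(
    ip: StrandedCoverage, control: StrandedCoverage, eps: float = 1.0
) -> StrandedCoverage:
    """Per-base IP / input ratio with an input floor of ``eps`` reads to
    avoid division by zero in unsequenced regions."""
    out = StrandedCoverage(ip.chrom_sizes)
    for chrom, strand in ip.keys():
        denom = np.maximum(control.get(chrom, strand), eps)
        out.set(chrom, strand, ip.get(chrom, strand) / denom)
    return out
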