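"""Synthetic genomes, coverage, crosslink sites and titrations with known
ground truth.

The generator emulates the features of the real assays that the analysis
stages consume:

* stranded RNA-Seq with a flat gene-body plateau, tunable post-PAS
  read-through that decays exponentially (fraction ``theta`` of the body
  depth at the PAS, decay length ``lambda``), and a low Poisson
  antisense/intergenic background;
* ChIP IP/input pairs where the IP is enriched by a Gaussian bump centred
  ~160 nt downstream of the PAS;
* PAR-CLIP crosslink sites drawn proportionally to transcript abundance
  under a Gaussian envelope centred ~80 nt downstream of the PAS, boosted
  at UGUA motifs;
* genome sequence with UGUA planted downstream of PASs at a configurable
  per-position probability;
* single-site anisotropy titrations with ligand depletion.

Every generator is a pure function of its configuration and seed; all
per-base counts are Poisson draws around documented closed-form means.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import binding_affinity
from .core_model import GeneModel, GeneSet, PointFeatures, StrandedCoverage

__all__ = [
    "SimulationConfig",
    "simulate_annotation",
    "simulate_genome",
    "gene_expression",
    "simulate_rnaseq",
    "simulate_chip",
    "simulate_parclip",
    "simulate_titration",
    "simulate_crosslink_sites",
]

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults: 200 genes of 1.5 kb spaced 800 nt apart on alternating
    strands; mean gene-body depth 20 reads/nt with a lognormal spread;
    wild-type read-through fraction 0.05 against a mutant at 0.40; ChIP
    enrichment centred 160 nt and crosslinks 80 nt downstream of the PAS.
    """

    seed: int = 0
    n_genes: int = 200
    gene_length: int = 1500
    gene_spacing: int = 800
    chrom: str = "chrI"
    chrom_length: Optional[int] = None  # computed from the layout if None
    expression: float = 20.0  # mean gene-body depth, reads/nt
    expression_lognorm_sigma: float = 0.5
    readthrough: Dict[str, float] = field(
        default_factory=lambda: {"wt": 0.05, "mut": 0.40}
    )
    decay_length: float = 200.0  # nt, exponential read-through decay
    antisense_background: float = 0.1  # Poisson mean depth off-gene/off-strand
    chip_offset: int = 160
    chip_sd: float = 40.0
    chip_amplitude: float = 8.0
    chip_input_depth: float = 10.0
    parclip_offset: int = 80
    parclip_sd: float = 20.0
    parclip_rate: float = 0.5  # peak crosslinks/nt at unit relative abundance
    motif_boost: float = 50.0
    motif_plant_prob: float = 0.02  # per position within the plant window
    motif_plant_window: Tuple[int, int] = (0, 100)  # rel. to PAS, downstream
    motif_free_background: bool = False
    reference_gene_id: str = "adh1-like"
    reference_expression: float = 100.0

    def __post_init__(self) -> None:
        for strain, theta in self.readthrough.items():
            if not 0.0 <= theta <= 1.0:
                raise ValueError(f"theta for {strain} outside [0,1]")
        if self.decay_length <= 0:
            raise ValueError("decay_length must be positive")

    def rng(self, stream: str) -> np.random.Generator:
        """Independent deterministic stream per purpose (no global state)."""
        key = zlib.crc32(stream.encode())
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(key,)))


def _layout_length(config: SimulationConfig) -> int:
    margin = 600
    return (
        2 * margin
        + config.n_genes * config.gene_length
        + (config.n_genes - 1) * config.gene_spacing
    )


def simulate_annotation(config: SimulationConfig) -> GeneSet:
    """Deterministic gene layout: equal-length units in a row, alternating
    strands, separated by ``gene_spacing`` nt.  The first gene doubles as a
    highly expressed housekeeping reference."""
    needed = _layout_length(config)
    length = config.chrom_length or needed
    if length < needed:
        raise ValueError(
            f"chrom_length {length} cannot pack {config.n_genes} genes (need {needed})"
        )
    genes: List[GeneModel] = []
    cursor = 600
    for i in range(config.n_genes):
        gid = config.reference_gene_id if i == 0 else f"g{i:04d}"
        strand = "+" if i % 2 == 0 else "-"
        genes.append(
            GeneModel(gid, config.chrom, strand, cursor, cursor + config.gene_length)
        )
        cursor += config.gene_length + config.gene_spacing
    return GeneSet(genes, {config.chrom: length}).with_downstream_gaps()


def _scrub_motif(seq: np.ndarray, patterns: Sequence[str]) -> None:
    """Remove every occurrence of the given patterns in place by rewriting
    the second base; loops until none remain (rewrites may create new
    overlapping occurrences)."""
    text = "".join(seq)
    for _ in range(100):
        dirty = False
        for pat in patterns:
            i = text.find(pat)
            while i != -1:
                repl = "C" if text[i + 1] != "C" else "G"
                seq[i + 1] = repl
                dirty = True
                i = text.find(pat, i + 1)
        text = "".join(seq)
        if not any(pat in text for pat in patterns):
            return
        if not dirty:
            break
    raise RuntimeError("failed to scrub motif from background sequence")


def simulate_genome(
    config: SimulationConfig,
) -> Tuple[GeneSet, Dict[str, str], Dict[str, List[int]]]:
    """Genome sequence with UGUA planted downstream of each PAS.

    Background bases are i.i.d. uniform ACGT (optionally scrubbed of the
    motif on both strands).  Within ``motif_plant_window`` nt downstream of
    each gene's PAS, the motif is written on the transcribed strand at each
    position independently with probability ``motif_plant_prob``.  Returns
    (genes, sequences, planted 5'-base genomic positions per gene).
    """
    genes = simulate_annotation(config)
    rng = config.rng("genome")
    size = genes.chrom_sizes[config.chrom]
    seq = _BASES[rng.integers(0, 4, size=size)]
    if config.motif_free_background:
        _scrub_motif(seq, ["TGTA", "TACA"])
    planted: Dict[str, List[int]] = {}
    w_lo, w_hi = config.motif_plant_window
    for g in genes:
        planted[g.gene_id] = []
        for d in range(w_lo, w_hi):
            if rng.random() >= config.motif_plant_prob:
                continue
            if g.strand == "+":
                five = g.pas + d
                if five + 4 <= size:
                    seq[five : five + 4] = list("TGTA")
                    planted[g.gene_id].append(five)
            else:
                five = g.pas - 1 - d
                if five - 3 >= 0:
                    seq[five - 3 : five + 1] = list("TACA")
                    planted[g.gene_id].append(five)
    return genes, {config.chrom: "".join(seq)}, planted


def gene_expression(genes: GeneSet, config: SimulationConfig) -> Dict[str, float]:
    """Per-gene mean body depth e_g: lognormal around ``expression`` (mean
    preserved), shared by the RNA-Seq and PAR-CLIP generators; the
    housekeeping reference is pinned at ``reference_expression``."""
    rng = config.rng("expression")
    sigma = config.expression_lognorm_sigma
    out = {}
    for g in genes:
        if g.gene_id == config.reference_gene_id:
            out[g.gene_id] = config.reference_expression
        elif sigma > 0:
            out[g.gene_id] = config.expression * rng.lognormal(-0.5 * sigma**2, sigma)
        else:
            out[g.gene_id] = config.expression
    return out


def _post_pas_indices(g: GeneModel, d: np.ndarray) -> np.ndarray:
    return g.pas + d if g.strand == "+" else g.pas - 1 - d


def simulate_rnaseq(
    genes: GeneSet,
    config: SimulationConfig,
    strain: str,
    expression: Optional[Dict[str, float]] = None,
) -> StrandedCoverage:
    """Stranded RNA-Seq coverage for one strain.

    Expected depth is e_g across the gene body [TSS, PAS), then
    ``theta * e_g * exp(-d / lambda)`` at distance d past the PAS, plus a
    constant antisense/intergenic background on both strands; realized
    values are per-base Poisson draws.
    """
    if strain not in config.readthrough:
        raise KeyError(f"no read-through fraction configured for strain {strain!r}")
    theta = config.readthrough[strain]
    expr = expression or gene_expression(genes, config)
    rng = config.rng(f"rnaseq:{strain}")
    mu: Dict[Tuple[str, str], np.ndarray] = {}
    for chrom, size in genes.chrom_sizes.items():
        mu[(chrom, "+")] = np.full(size, config.antisense_background)
        mu[(chrom, "-")] = np.full(size, config.antisense_background)
    max_size = max(genes.chrom_sizes.values(), default=0)
    tail = int(min(np.ceil(8 * config.decay_length), max_size))
    for g in genes:
        e_g = expr[g.gene_id]
        body = mu[(g.chrom, g.strand)]
        body[g.start : g.end] += e_g
        if theta > 0:
            d = np.arange(tail)
            idx = _post_pas_indices(g, d)
            ok = (idx >= 0) & (idx < body.size)
            body[idx[ok]] += theta * e_g * np.exp(-d[ok] / config.decay_length)
    cov = StrandedCoverage(genes.chrom_sizes)
    for (chrom, strand), m in mu.items():
        cov.set(chrom, strand, rng.poisson(m).astype(float))
    return cov


def simulate_chip(
    genes: GeneSet, config: SimulationConfig
) -> Tuple[StrandedCoverage, StrandedCoverage, PointFeatures]:
    """ChIP IP and input tracks plus ground-truth summit positions.

    IP mean = input mean * (1 + A * Gaussian(centre = PAS + chip_offset,
    sd = chip_sd)); the enrichment is applied on both strands (the signal
    is DNA-based) and the true centres are returned as summit features on
    the gene's strand.
    """
    rng = config.rng("chip")
    factor: Dict[str, np.ndarray] = {
        chrom: np.ones(size) for chrom, size in genes.chrom_sizes.items()
    }
    summits = []
    for g in genes:
        centre = int(_post_pas_indices(g, np.array([config.chip_offset]))[0])
        size = genes.chrom_sizes[g.chrom]
        span = int(np.ceil(4 * config.chip_sd))
        lo, hi = max(centre - span, 0), min(centre + span + 1, size)
        x = np.arange(lo, hi)
        factor[g.chrom][lo:hi] += config.chip_amplitude * np.exp(
            -0.5 * ((x - centre) / config.chip_sd) ** 2
        )
        summits.append((g.chrom, g.strand, centre, config.chip_amplitude))
    ip = StrandedCoverage(genes.chrom_sizes)
    control = StrandedCoverage(genes.chrom_sizes)
    for chrom, size in genes.chrom_sizes.items():
        for strand in "+-":
            control.set(
                chrom, strand, rng.poisson(config.chip_input_depth, size).astype(float)
            )
            ip.set(
                chrom,
                strand,
                rng.poisson(config.chip_input_depth * factor[chrom]).astype(float),
            )
    return ip, control, PointFeatures.from_records(summits, role="summit")


def simulate_parclip(
    genes: GeneSet,
    sequences: Dict[str, str],
    config: SimulationConfig,
    expression: Optional[Dict[str, float]] = None,
) -> PointFeatures:
    """PAR-CLIP crosslink sites on the transcribed strand.

    The per-base crosslink rate is (relative transcript abundance) x
    (Gaussian envelope centred parclip_offset nt past the PAS) x
    (motif_boost within +/-2 nt of a UGUA 5' base, else 1); counts are
    Poisson and zero-count positions are dropped.
    """
    from .motif import motif_hits  # local import: motif depends on metagene

    expr = expression or gene_expression(genes, config)
    rng = config.rng("parclip")
    records = []
    half_span = 250
    for g in genes:
        rel_abund = expr[g.gene_id] / config.expression
        if rel_abund <= 0:
            continue
        hits = np.asarray(motif_hits(sequences[g.chrom], g.strand), dtype=int)
        d = np.arange(-half_span, half_span)
        idx = _post_pas_indices(g, d)
        size = genes.chrom_sizes[g.chrom]
        ok = (idx >= 0) & (idx < size)
        d, idx = d[ok], idx[ok]
        envelope = np.exp(-0.5 * ((d - config.parclip_offset) / config.parclip_sd) ** 2)
        rate = config.parclip_rate * rel_abund * envelope
        if hits.size and config.motif_boost != 1.0:
            near = np.min(np.abs(idx[:, None] - hits[None, :]), axis=1) <= 2
            rate = np.where(near, rate * config.motif_boost, rate)
        counts = rng.poisson(rate)
        for pos, c in zip(idx[counts > 0], counts[counts > 0]):
            records.append((g.chrom, g.strand, int(pos), float(c)))
    return PointFeatures.from_records(records, role="crosslink")


def simulate_titration(
    kd: float,
    probe_conc: float,
    protein_concs: Sequence[float],
    r_free: float = 0.05,
    r_bound: float = 0.20,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> binding_affinity.TitrationCurve:
    """Noisy anisotropy titration from the ligand-depletion model."""
    P = np.asarray(protein_concs, dtype=float)
    r = binding_affinity.predict_anisotropy(kd, probe_conc, P, r_free, r_bound)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        r = r + rng.normal(0.0, noise_sd, size=r.shape)
    return binding_affinity.TitrationCurve(P, r, probe_conc)


def simulate_crosslink_sites(
    n_sites: int = 1000,
    plant_prob: float = 0.3,
    flank: int = 25,
    seed: int = 0,
    chrom: str = "chrS",
) -> Tuple[PointFeatures, Dict[str, str]]:
    """Isolated crosslink sites where each site independently carries a
    nearby motif with probability ``plant_prob``.

    The background sequence is scrubbed of the motif on both strands so the
    expected motif-positive site fraction equals ``plant_prob`` exactly;
    sites alternate strands and are spaced so flanking windows do not
    overlap.
    """
    rng = np.random.default_rng(seed)
    spacing = 2 * flank + 12
    size = (n_sites + 1) * spacing
    seq = _BASES[rng.integers(0, 4, size=size)]
    _scrub_motif(seq, ["TGTA", "TACA"])
    records = []
    for i in range(n_sites):
        pos = (i + 1) * spacing
        strand = "+" if i % 2 == 0 else "-"
        if rng.random() < plant_prob:
            delta = int(rng.integers(-flank, flank + 1))
            five = pos + delta if strand == "+" else pos - delta
            if strand == "+":
                seq[five : five + 4] = list("TGTA")
            else:
                seq[five - 3 : five + 1] = list("TACA")
        records.append((chrom, strand, pos, 1.0))
    return (
        PointFeatures.from_records(records, role="crosslink"),
        {chrom: "".join(seq)},
    )
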