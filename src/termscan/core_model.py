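"""Genome data model, coordinate conventions and annotation/coverage I/O.

All coordinates are stored 0-based half-open; conversion from 1-based
formats (GFF3) happens only at the I/O boundary.  TSS and PAS are held as
*boundary* coordinates of the transcription unit: on the plus strand the
gene body is ``[tss, pas)``, on the minus strand it is ``[pas, tss)``.
A window of ``(start_offset, end_offset)`` nucleotides measured in the
direction of transcription around an anchor boundary ``a`` maps to the
genomic half-open interval ``[a + start, a + end)`` on the plus strand and
``[a - end, a - start)`` on the minus strand, so that e.g. the first 50
post-PAS bases are ``[pas, pas + 50)`` for a plus-strand gene and
``[pas - 50, pas)`` for a minus-strand gene.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Optional, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "GeneModel",
    "GeneSet",
    "StrandedCoverage",
    "PointFeatures",
    "AnnotationError",
    "CoverageError",
    "oriented_window",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_annotation",
    "write_annotation",
    "filter_genes",
    "read_coverage",
    "write_coverage",
]

BIOTYPES = ("coding", "ncRNA", "sn_snoRNA")


class AnnotationError(ValueError):
    """Raised for malformed or out-of-bounds annotation records."""


class CoverageError(ValueError):
    """Raised for invalid coverage tracks (overlaps, negative values)."""


@dataclass(frozen=True)
class GeneModel:
    """One transcription unit with strand-aware TSS/PAS boundaries."""

    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    start: int  # 0-based half-open interval [start, end)
    end: int
    biotype: str = "coding"
    downstream_gap: float = math.inf

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"{self.gene_id}: strand must be + or -")
        if not self.end > self.start:
            raise AnnotationError(f"{self.gene_id}: empty or inverted interval")
        if self.downstream_gap < 0:
            raise AnnotationError(f"{self.gene_id}: negative downstream_gap")

    @property
    def tss(self) -> int:
        """5' boundary of the unit (start on +, end on -)."""
        return self.start if self.strand == "+" else self.end

    @property
    def pas(self) -> int:
        """3' boundary of the unit (end on +, start on -)."""
        return self.end if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start


def oriented_window(
    anchor: int, strand: str, start_offset: int, end_offset: int
) -> Tuple[int, int]:
    """Genomic half-open interval for a transcription-direction window.

    Offsets are measured downstream-positive from the anchor boundary;
    ``start_offset < end_offset`` is required.
    """
    if end_offset <= start_offset:
        raise ValueError("end_offset must exceed start_offset")
    if strand == "+":
        return anchor + start_offset, anchor + end_offset
    return anchor - end_offset, anchor - start_offset


class GeneSet:
    """Ordered collection of genes plus chromosome sizes."""

    def __init__(self, genes: Iterable[GeneModel], chrom_sizes: Dict[str, int]):
        self.genes: List[GeneModel] = list(genes)
        self.chrom_sizes: Dict[str, int] = dict(chrom_sizes)
        seen = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise AnnotationError(f"duplicate gene_id {g.gene_id}")
            seen.add(g.gene_id)
            size = self.chrom_sizes.get(g.chrom)
            if size is None:
                raise AnnotationError(f"{g.gene_id}: unknown chromosome {g.chrom}")
            if g.start < 0 or g.end > size:
                raise AnnotationError(
                    f"{g.gene_id}: [{g.start},{g.end}) outside {g.chrom} (len {size})"
                )

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self.genes)

    def __getitem__(self, i: int) -> GeneModel:
        return self.genes[i]

    def by_id(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    @property
    def gene_ids(self) -> List[str]:
        return [g.gene_id for g in self.genes]

    def with_downstream_gaps(self) -> "GeneSet":
        """Recompute downstream_gap for every gene.

        The gap is the distance from a gene's PAS boundary to the nearest
        point of any other annotated unit lying downstream of it in the
        direction of transcription, on either strand (read-through invades
        either strand's unit); +inf if no such neighbour exists.  Ties take
        the minimum distance.
        """
        out = []
        for g in self.genes:
            gap = math.inf
            for h in self.genes:
                if h is g or h.chrom != g.chrom:
                    continue
                if g.strand == "+":
                    if h.end > g.pas:  # any part beyond the PAS
                        gap = min(gap, max(h.start - g.pas, 0))
                else:
                    if h.start < g.pas:
                        gap = min(gap, max(g.pas - h.end, 0))
            out.append(replace(g, downstream_gap=gap))
        return GeneSet(out, self.chrom_sizes)

    def mirrored(self) -> "GeneSet":
        """Reflect every gene through its chromosome (coordinate and strand
        mirror); used to assert strand symmetry of downstream statistics."""
        out = []
        for g in self.genes:
            size = self.chrom_sizes[g.chrom]
            out.append(
                replace(
                    g,
                    start=size - g.end,
                    end=size - g.start,
                    strand="-" if g.strand == "+" else "+",
                )
            )
        return GeneSet(out, self.chrom_sizes)


def filter_genes(genes: GeneSet, min_length: int = 500, min_gap: int = 250) -> GeneSet:
    """Cohort filter: drop genes shorter than ``min_length`` or closer than
    ``min_gap`` to their downstream neighbour.  Order preserved; idempotent."""
    kept = [
        g
        for g in genes
        if g.length >= min_length and g.downstream_gap >= min_gap
    ]
    return GeneSet(kept, genes.chrom_sizes)


class StrandedCoverage:
    """Per-chromosome, per-strand dense non-negative signal vectors."""

    def __init__(
        self,
        chrom_sizes: Dict[str, int],
        data: Optional[Dict[Tuple[str, str], np.ndarray]] = None,
    ):
        self.chrom_sizes = dict(chrom_sizes)
        self._data: Dict[Tuple[str, str], np.ndarray] = {}
        if data:
            for key, vec in data.items():
                self.set(key[0], key[1], vec)

    def set(self, chrom: str, strand: str, values: np.ndarray) -> None:
        vec = np.asarray(values, dtype=float)
        size = self.chrom_sizes.get(chrom)
        if size is None:
            raise CoverageError(f"unknown chromosome {chrom}")
        if vec.shape != (size,):
            raise CoverageError(
                f"{chrom}{strand}: vector length {vec.shape} != chromosome size {size}"
            )
        if np.any(vec < 0):
            raise CoverageError(f"{chrom}{strand}: negative coverage")
        self._data[(chrom, strand)] = vec

    def get(self, chrom: str, strand: str) -> np.ndarray:
        key = (chrom, strand)
        if key not in self._data:
            self._data[key] = np.zeros(self.chrom_sizes[chrom])
        return self._data[key]

    def keys(self) -> List[Tuple[str, str]]:
        return list(self._data.keys())

    def copy(self) -> "StrandedCoverage":
        return StrandedCoverage(
            self.chrom_sizes, {k: v.copy() for k, v in self._data.items()}
        )

    def scaled(self, factor: float) -> "StrandedCoverage":
        return StrandedCoverage(
            self.chrom_sizes, {k: v * factor for k, v in self._data.items()}
        )

    def mirrored(self) -> "StrandedCoverage":
        """Coordinate-reversed, strand-swapped copy (strand-symmetry checks)."""
        flip = {"+": "-", "-": "+"}
        return StrandedCoverage(
            self.chrom_sizes,
            {(c, flip[s]): v[::-1].copy() for (c, s), v in self._data.items()},
        )

    def window_sum(self, chrom: str, strand: str, lo: int, hi: int) -> Tuple[float, bool]:
        """Sum over genomic [lo, hi); off-chromosome parts are clipped and
        flagged via the returned boolean."""
        size = self.chrom_sizes[chrom]
        clo, chi = max(lo, 0), min(hi, size)
        clipped = (clo, chi) != (lo, hi)
        if chi <= clo:
            return 0.0, True
        return float(self.get(chrom, strand)[clo:chi].sum()), clipped


class PointFeatures:
    """Single-base features (PAR-CLIP crosslink sites or ChIP peak summits)."""

    COLUMNS = ["chrom", "strand", "position", "value"]

    def __init__(self, frame: pd.DataFrame, role: str = "crosslink"):
        if role not in ("crosslink", "summit"):
            raise ValueError(f"unknown role {role!r}")
        df = frame.reset_index(drop=True)[self.COLUMNS].copy()
        if (df["value"] < 0).any():
            raise ValueError("negative feature values")
        self.frame = df
        self.role = role

    @classmethod
    def from_records(cls, records, role: str = "crosslink") -> "PointFeatures":
        df = pd.DataFrame(list(records), columns=cls.COLUMNS)
        return cls(df, role=role)

    def __len__(self) -> int:
        return len(self.frame)

    def on(self, chrom: str, strand: Optional[str] = None) -> pd.DataFrame:
        df = self.frame[self.frame["chrom"] == chrom]
        if strand is not None:
            df = df[df["strand"] == strand]
        return df

    def mirrored(self, chrom_sizes: Dict[str, int]) -> "PointFeatures":
        df = self.frame.copy()
        sizes = df["chrom"].map(chrom_sizes)
        df["position"] = sizes - 1 - df["position"]
        df["strand"] = df["strand"].map({"+": "-", "-": "+"})
        return PointFeatures(df, role=self.role)

    def to_bed(self, path) -> None:
        df = self.frame
        bed = pd.DataFrame(
            {
                "chrom": df["chrom"],
                "start": df["position"].astype(int),
                "end": df["position"].astype(int) + 1,
                "name": [f"{self.role}_{i}" for i in range(len(df))],
                "score": df["value"],
                "strand": df["strand"],
            }
        )
        bed.to_csv(path, sep="\t", header=False, index=False)

    @classmethod
    def from_bed(cls, path, role: str = "crosslink") -> "PointFeatures":
        bed = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["chrom", "start", "end", "name", "score", "strand"],
            comment="#",
        )
        df = pd.DataFrame(
            {
                "chrom": bed["chrom"],
                "strand": bed["strand"],
                "position": bed["start"].astype(int),
                "value": bed["score"].astype(float),
            }
        )
        return cls(df, role=role)


# ---------------------------------------------------------------------------
# annotation I/O


def read_chrom_sizes(path) -> Dict[str, int]:
    sizes: Dict[str, int] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        name, size = line.split()[:2]
        sizes[name] = int(size)
    return sizes


def write_chrom_sizes(sizes: Dict[str, int], path) -> None:
    Path(path).write_text("".join(f"{c}\t{n}\n" for c, n in sizes.items()))


def _parse_bed(path) -> List[GeneModel]:
    genes = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split()
        if len(fields) < 6:
            raise AnnotationError(f"{path}:{lineno}: BED6 needs 6 fields")
        chrom, start, end, name, _score, strand = fields[:6]
        try:
            s, e = int(start), int(end)
        except ValueError as exc:
            raise AnnotationError(f"{path}:{lineno}: bad coordinates") from exc
        genes.append(GeneModel(name, chrom, strand, s, e))
    return genes


def _parse_gff3(path) -> List[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for feat in db.all_features(order_by="start"):
        if feat.featuretype not in ("gene", "ncRNA_gene", "transcript", "mRNA"):
            continue
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        biotype = feat.attributes.get("biotype", ["coding"])[0]
        if biotype not in BIOTYPES:
            biotype = "coding"
        # GFF3 is 1-based closed; gffutils keeps it that way
        genes.append(
            GeneModel(gene_id, feat.seqid, feat.strand, feat.start - 1, feat.end, biotype)
        )
    return genes


def read_annotation(path, chrom_sizes: Optional[Dict[str, int]] = None) -> GeneSet:
    """Load genes from BED6 or GFF3 into the internal 0-based half-open model.

    ``chrom_sizes`` may be a dict or a path to a two-column chrom.sizes file;
    if omitted, sizes are inferred as the maximal gene end per chromosome.
    Downstream gaps are computed against all other genes.
    """
    path = Path(path)
    if path.suffix.lower() in (".gff", ".gff3"):
        genes = _parse_gff3(path)
    else:
        genes = _parse_bed(path)
    if chrom_sizes is None:
        sizes: Dict[str, int] = {}
        for g in genes:
            sizes[g.chrom] = max(sizes.get(g.chrom, 0), g.end)
    elif isinstance(chrom_sizes, (str, Path)):
        sizes = read_chrom_sizes(chrom_sizes)
    else:
        sizes = dict(chrom_sizes)
    return GeneSet(genes, sizes).with_downstream_gaps()


def write_annotation(genes: GeneSet, path, fmt: str = "gff3") -> None:
    path = Path(path)
    if fmt == "bed":
        lines = [
            f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}"
            for g in genes
        ]
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
        return
    lines = ["##gff-version 3"]
    for g in genes:
        attrs = f"ID={g.gene_id};biotype={g.biotype}"
        lines.append(
            f"{g.chrom}\ttermscan\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}"
        )
    path.write_text("\n".join(lines) + "\n")


def read_fasta(path) -> Dict[str, str]:
    """Chromosome sequences as plain upper-case strings."""
    from pyfaidx import Fasta

    with Fasta(str(path)) as fa:
        return {name: str(fa[name][:]).upper() for name in fa.keys()}


def write_fasta(sequences: Dict[str, str], path, width: int = 70) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# coverage I/O (bedGraph, one file per strand)


def _read_bedgraph_into(cov: StrandedCoverage, path, strand: str) -> None:
    last_end: Dict[str, int] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split()
        if len(fields) < 4:
            raise CoverageError(f"{path}:{lineno}: bedGraph needs 4 fields")
        chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
        if value < 0:
            raise CoverageError(f"{path}:{lineno}: negative value")
        if start < last_end.get(chrom, 0):
            raise CoverageError(
                f"{path}:{lineno}: overlapping or unsorted intervals on {chrom}"
            )
        last_end[chrom] = end
        vec = cov.get(chrom, strand)
        if end > len(vec):
            raise CoverageError(f"{path}:{lineno}: interval beyond chromosome end")
        vec[start:end] = value


def read_coverage(plus_path, minus_path, chrom_sizes: Dict[str, int]) -> StrandedCoverage:
    """Read a pair of per-strand bedGraph files into dense vectors.

    Intervals must be 0-based half-open and non-overlapping within a file
    (sorted per chromosome); bases not covered by any interval are zero.
    """
    cov = StrandedCoverage(chrom_sizes)
    _read_bedgraph_into(cov, plus_path, "+")
    _read_bedgraph_into(cov, minus_path, "-")
    return cov


def _write_bedgraph(cov: StrandedCoverage, path, strand: str) -> None:
    lines = []
    for chrom in sorted(cov.chrom_sizes):
        if (chrom, strand) not in cov._data:
            continue
        vec = cov.get(chrom, strand)
        if len(vec) == 0:
            continue
        # run-length encode
        change = np.flatnonzero(np.diff(vec)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [len(vec)]))
        for s, e in zip(starts, ends):
            v = vec[s]
            if v != 0:
                lines.append(f"{chrom}\t{s}\t{e}\t{v:g}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_coverage(cov: StrandedCoverage, plus_path, minus_path) -> None:
    """Write run-length-encoded per-strand bedGraph; inverse of read_coverage."""
    _write_bedgraph(cov, plus_path, "+")
    _write_bedgraph(cov, minus_path, "-")
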