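"""Readers, writers and the domain types shared by the whole pipeline.

All coordinates are held internally as 0-based half-open intervals
(BED convention); GTF input/output converts at the boundary.  Strand is
one of ``+``, ``-`` or ``.`` (unknown; only legal on assembled transcripts
before the strand filter runs).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from gffutils.feature import feature_from_line
from intervaltree import IntervalTree

STRANDS = ("+", "-", ".")


class FormatError(ValueError):
    """A malformed input file (the message names the offending line)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval, 0-based start, exclusive end."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Shared base pairs with *other* (0 if different chromosome)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def distance_to(self, other: "GenomicInterval") -> int:
        """Gap in bp between the two intervals; 0 if they touch or overlap."""
        if self.chrom != other.chrom:
            raise ValueError("distance undefined across chromosomes")
        return max(0, max(self.start, other.start) - min(self.end, other.end))


@dataclass
class TranscriptModel:
    """One assembled transcript: exon chain plus per-sample expression."""

    transcript_id: str
    gene_id: str
    exons: list[GenomicInterval]
    fpkm: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript without exons")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValueError(
                f"{self.transcript_id}: exons span multiple chromosomes/strands"
            )
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError(f"{self.transcript_id}: overlapping exons")

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    @property
    def length(self) -> int:
        return sum(e.length for e in self.exons)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )


@dataclass
class GeneRecord:
    gene_id: str
    span: GenomicInterval
    biotype: str = "protein_coding"

    @property
    def strand(self) -> str:
        return self.span.strand


@dataclass(frozen=True)
class HomologyHit:
    """One query-subject pair, HSPs already merged (coverage = union)."""

    query_id: str
    subject_id: str
    pct_identity: float
    align_len: int
    evalue: float
    bitscore: float
    query_cov: float

    def __post_init__(self) -> None:
        if not (0 <= self.pct_identity <= 100):
            raise ValueError(f"pct_identity out of range: {self.pct_identity}")
        if not (0 <= self.query_cov <= 100 + 1e-9):
            raise ValueError(f"query_cov out of range: {self.query_cov}")
        if self.evalue < 0:
            raise ValueError(f"negative E-value: {self.evalue}")


class GenomeAnnotation:
    """Indexed reference annotation: genes, mRNAs, TEs.

    Interval queries are served from per-(chrom[, strand]) interval trees and
    must return exactly what a linear scan would.
    """

    def __init__(
        self,
        genes: Iterable[GeneRecord],
        mrnas: Iterable[TranscriptModel] = (),
        tes: Iterable[GenomicInterval] = (),
    ) -> None:
        self.genes: dict[str, GeneRecord] = {}
        for g in genes:
            if g.gene_id in self.genes:
                raise ValueError(f"duplicate gene id {g.gene_id}")
            self.genes[g.gene_id] = g
        self.mrnas: dict[str, TranscriptModel] = {}
        for m in mrnas:
            if m.transcript_id in self.mrnas:
                raise ValueError(f"duplicate mRNA id {m.transcript_id}")
            self.mrnas[m.transcript_id] = m
        self.tes: list[GenomicInterval] = list(tes)

        # gene spans, strand-agnostic tree keyed by chrom
        self._gene_tree: dict[str, IntervalTree] = {}
        for g in self.genes.values():
            self._gene_tree.setdefault(g.span.chrom, IntervalTree()).addi(
                g.span.start, g.span.end, g
            )
        # mRNA exons and spans keyed (chrom, strand)
        self._mrna_exon_tree: dict[tuple[str, str], IntervalTree] = {}
        self._mrna_span_tree: dict[tuple[str, str], IntervalTree] = {}
        for m in self.mrnas.values():
            key = (m.chrom, m.strand)
            et = self._mrna_exon_tree.setdefault(key, IntervalTree())
            for e in m.exons:
                et.addi(e.start, e.end, m)
            self._mrna_span_tree.setdefault(key, IntervalTree()).addi(
                m.span.start, m.span.end, m
            )
        self._te_tree: dict[str, IntervalTree] = {}
        for t in self.tes:
            self._te_tree.setdefault(t.chrom, IntervalTree()).addi(
                t.start, t.end, t
            )
        # positional ordering of protein-coding genes per chromosome
        self.flank_order: dict[str, list[GeneRecord]] = {}
        for g in sorted(
            (g for g in self.genes.values() if g.biotype == "protein_coding"),
            key=lambda g: (g.span.chrom, g.span.start, g.gene_id),
        ):
            self.flank_order.setdefault(g.span.chrom, []).append(g)

    # -- queries ------------------------------------------------------------

    def genes_overlapping(
        self, iv: GenomicInterval, strand: str | None = None
    ) -> list[GeneRecord]:
        tree = self._gene_tree.get(iv.chrom)
        if tree is None:
            return []
        hits = [h.data for h in tree.overlap(iv.start, iv.end)]
        if strand is not None:
            hits = [g for g in hits if g.strand == strand]
        return sorted(hits, key=lambda g: (g.span.start, g.gene_id))

    def mrnas_near_span(
        self, iv: GenomicInterval, strand: str, flank_bp: int = 0
    ) -> list[TranscriptModel]:
        """mRNAs on *strand* whose span overlaps iv extended by flank_bp."""
        tree = self._mrna_span_tree.get((iv.chrom, strand))
        if tree is None:
            return []
        lo = max(0, iv.start - flank_bp)
        hits = [h.data for h in tree.overlap(lo, iv.end + flank_bp)]
        return sorted(hits, key=lambda m: (m.span.start, m.transcript_id))

    def mrna_exon_overlap_bp(self, exons: Sequence[GenomicInterval], strand: str) -> int:
        """Exonic bp shared between *exons* and any same-strand mRNA exon."""
        if not exons:
            return 0
        tree = self._mrna_exon_tree.get((exons[0].chrom, strand))
        if tree is None:
            return 0
        total = 0
        for e in exons:
            for h in tree.overlap(e.start, e.end):
                total += min(e.end, h.end) - max(e.start, h.begin)
        return total

    def te_overlaps(self, iv: GenomicInterval) -> list[GenomicInterval]:
        tree = self._te_tree.get(iv.chrom)
        if tree is None:
            return []
        return [h.data for h in tree.overlap(iv.start, iv.end)]


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------


def _parse_gtf_lines(path: str | Path):
    """Yield (lineno, gffutils Feature) with interval sanity checks."""
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                feat = feature_from_line(line, dialect=None)
            except Exception as exc:  # gffutils raises assorted types
                raise FormatError(f"{path}: malformed GTF at line {lineno}: {exc}")
            if feat.start is None or feat.end is None or not feat.featuretype:
                raise FormatError(
                    f"{path}: malformed GTF at line {lineno}: "
                    "missing coordinates or feature type"
                )
            if feat.end < feat.start:
                raise FormatError(
                    f"{path}: line {lineno}: end ({feat.end}) < start ({feat.start})"
                )
            yield lineno, feat


def read_gtf(path: str | Path, kind: str = "transcripts"):
    """Read a GTF2.2 file.

    kind="transcripts" returns a list of :class:`TranscriptModel` built from
    exon features grouped by ``transcript_id``; kind="annotation" returns a
    :class:`GenomeAnnotation` of gene records and mRNA exon chains.
    GTF's 1-based closed coordinates are converted to 0-based half-open.
    """
    if kind not in ("transcripts", "annotation"):
        raise ValueError(f"unknown kind {kind!r}")
    exons: dict[str, list[GenomicInterval]] = {}
    tx_gene: dict[str, str] = {}
    gene_feats: dict[str, GeneRecord] = {}
    order: list[str] = []
    for lineno, feat in _parse_gtf_lines(path):
        iv = GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand or ".")
        if feat.featuretype == "gene":
            gid = feat.attributes.get("gene_id", [None])[0]
            if gid is None:
                raise FormatError(f"{path}: line {lineno}: gene without gene_id")
            biotype = (
                feat.attributes.get("gene_biotype", [])
                or feat.attributes.get("biotype", [])
                or ["protein_coding"]
            )[0]
            gene_feats[gid] = GeneRecord(gid, iv, biotype)
        elif feat.featuretype == "exon":
            tid = feat.attributes.get("transcript_id", [None])[0]
            gid = feat.attributes.get("gene_id", [tid])[0]
            if tid is None:
                raise FormatError(f"{path}: line {lineno}: exon without transcript_id")
            if tid not in exons:
                order.append(tid)
            exons.setdefault(tid, []).append(iv)
            tx_gene[tid] = gid
    transcripts = [
        TranscriptModel(tid, tx_gene[tid], exons[tid]) for tid in order
    ]
    if kind == "transcripts":
        return transcripts
    if not gene_feats:
        # derive gene spans from transcript extents when no gene lines exist
        for t in transcripts:
            g = gene_feats.get(t.gene_id)
            if g is None:
                gene_feats[t.gene_id] = GeneRecord(t.gene_id, t.span)
            else:
                s = g.span
                gene_feats[t.gene_id] = GeneRecord(
                    g.gene_id,
                    GenomicInterval(
                        s.chrom,
                        min(s.start, t.span.start),
                        max(s.end, t.span.end),
                        s.strand,
                    ),
                    g.biotype,
                )
    return GenomeAnnotation(gene_feats.values(), transcripts)


def write_gtf(
    transcripts: Iterable[TranscriptModel],
    path: str | Path,
    source: str = "lncflow",
    extra_attrs: Mapping[str, Mapping[str, str]] | None = None,
) -> None:
    """Write exon features, converting back to 1-based closed coordinates."""
    extra_attrs = extra_attrs or {}
    with open(path, "w") as fh:
        for t in transcripts:
            attrs = [f'gene_id "{t.gene_id}"', f'transcript_id "{t.transcript_id}"']
            for k, v in extra_attrs.get(t.transcript_id, {}).items():
                attrs.append(f'{k} "{v}"')
            attr_s = "; ".join(attrs) + ";"
            for e in t.exons:
                fh.write(
                    f"{e.chrom}\t{source}\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f"{e.strand}\t.\t{attr_s}\n"
                )


# ---------------------------------------------------------------------------
# BED (TEs)
# ---------------------------------------------------------------------------


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """BED3/BED6; 0-based half-open, strand column honored when present."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}: line {lineno}: fewer than 3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}")
            strand = parts[5] if len(parts) >= 6 and parts[5] in ("+", "-") else "."
            try:
                out.append(GenomicInterval(parts[0], start, end, strand))
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}")
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\tte{i}\t0\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# expression / trait / Ct tables
# ---------------------------------------------------------------------------


def read_expression(path: str | Path | io.StringIO) -> pd.DataFrame:
    """FPKM table: first column id, header of sample ids; ids × samples.

    Missing cells and negative values are errors — expression must be
    complete before any filter runs.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicated ids in expression table: {dups}")
    if df.isna().any().any():
        bad = df.index[df.isna().any(axis=1)].tolist()
        raise FormatError(f"missing FPKM cells for ids: {bad}")
    df = df.astype(float)
    if (df.to_numpy() < 0).any():
        bad = df.index[(df < 0).any(axis=1)].tolist()
        raise FormatError(f"negative FPKM for ids: {bad}")
    return df


def write_expression(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="id")


def read_trait_table(path: str | Path) -> pd.DataFrame:
    """Per-sample traits (index sample id), e.g. oil_content and daf."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise FormatError("duplicated sample ids in trait table")
    return df.astype(float)


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """qPCR Ct values: columns gene, condition, replicate, ct."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "condition", "replicate", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"Ct table missing columns: {sorted(missing)}")
    df["ct"] = df["ct"].astype(float)
    return df


# ---------------------------------------------------------------------------
# BLAST tabular (12-column) homology hits
# ---------------------------------------------------------------------------

BLAST_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def merge_query_spans(spans: Iterable[tuple[int, int]]) -> int:
    """Total bp in the union of 1-based closed query spans."""
    ivs = sorted((min(a, b), max(a, b)) for a, b in spans)
    total = 0
    cur_s = cur_e = None
    for s, e in ivs:
        if cur_e is None or s > cur_e + 1:
            if cur_e is not None:
                total += cur_e - cur_s + 1
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s + 1
    return total


def read_homology_hits(
    path: str | Path | io.StringIO, query_lengths: Mapping[str, int]
) -> list[HomologyHit]:
    """Parse 12-column BLAST tabular output into per-pair hits.

    HSPs of one (query, subject) pair are merged: ``query_cov`` is
    100 × (union of query-aligned spans) / query length, and identity,
    E-value, bitscore and aligned length come from the best-bitscore HSP.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=BLAST_COLUMNS,
                         comment="#")
    except pd.errors.EmptyDataError:
        return []
    if df.empty:
        return []
    hits: list[HomologyHit] = []
    for (q, s), grp in df.groupby(["qseqid", "sseqid"], sort=False):
        if q not in query_lengths:
            raise KeyError(f"query id {q!r} absent from query_lengths")
        qlen = query_lengths[q]
        union = merge_query_spans(zip(grp["qstart"], grp["qend"]))
        best = grp.loc[grp["bitscore"].idxmax()]
        hits.append(
            HomologyHit(
                query_id=str(q),
                subject_id=str(s),
                pct_identity=float(best["pident"]),
                align_len=int(best["length"]),
                evalue=float(best["evalue"]),
                bitscore=float(best["bitscore"]),
                query_cov=min(100.0, 100.0 * union / qlen),
            )
        )
    return hits


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
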