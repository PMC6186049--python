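"""Six-filter lncRNA identification cascade, classification and locus merging.

The cascade removes, in order: (1) strand-unknown transcripts, (2) single-exon
transcripts within 500 bp of a same-strand annotated mRNA, (3) transcripts with
same-strand exonic overlap with annotated mRNAs, (4) weakly expressed
(max FPKM < 0.5, or < 2 for single-exon models) or short (< 200 bp)
transcripts, (5) transcripts with positive coding-potential score, and
(6) transcripts with a known protein-domain hit.  Survivors are classified as
lincRNA (intergenic) or lncNAT (antisense overlap with a protein-coding gene)
and merged transitively into non-redundant loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .formats_io import GenomeAnnotation, GenomicInterval, TranscriptModel

FILTER_STAGES = (
    "strand",
    "proximity",
    "sense_overlap",
    "expr_length",
    "coding_potential",
    "pfam",
)

LINCRNA = "lincRNA"
LNCNAT = "lncNAT"


@dataclass
class FilterTrace:
    """Per-transcript record of the first rule that dropped it (or 'none')."""

    records: dict[str, tuple[str, str]] = field(default_factory=dict)

    def drop(self, transcript_id: str, stage: str, detail: str) -> None:
        if stage not in FILTER_STAGES:
            raise ValueError(f"unknown stage {stage!r}")
        if transcript_id in self.records:
            raise ValueError(f"{transcript_id} already traced")
        self.records[transcript_id] = (stage, detail)

    def keep(self, transcript_id: str) -> None:
        if transcript_id in self.records:
            raise ValueError(f"{transcript_id} already traced")
        self.records[transcript_id] = ("none", "survived all filters")

    def dropped_at(self, transcript_id: str) -> str:
        return self.records[transcript_id][0]

    def merge(self, other: "FilterTrace") -> None:
        for tid, rec in other.records.items():
            if tid in self.records:
                raise ValueError(f"{tid} traced twice")
            self.records[tid] = rec

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"transcript_id": t, "dropped_at": s, "detail": d}
                for t, (s, d) in self.records.items()
            ]
        )

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class LncLocus:
    """Non-redundant lncRNA locus: merged overlapping same-strand survivors."""

    locus_id: str
    class_label: str
    chrom: str
    strand: str
    span: GenomicInterval
    transcripts: list[str]
    subgenome: str = "unplaced"


# ---------------------------------------------------------------------------
# individual filters — each returns (kept, trace-of-dropped)
# ---------------------------------------------------------------------------


def filter_strand(
    transcripts: Sequence[TranscriptModel],
) -> tuple[list[TranscriptModel], FilterTrace]:
    """Filter 1: discard transcripts without strand information."""
    kept, trace = [], FilterTrace()
    for t in transcripts:
        if t.strand in ("+", "-"):
            kept.append(t)
        else:
            trace.drop(t.transcript_id, "strand", "no strand information")
    return kept, trace


def filter_single_exon_proximity(
    transcripts: Sequence[TranscriptModel],
    annotation: GenomeAnnotation,
    flank_bp: int = 500,
) -> tuple[list[TranscriptModel], FilterTrace]:
    """Filter 2: drop single-exon transcripts within *flank_bp* of (or
    overlapping) a same-strand annotated mRNA span."""
    kept, trace = [], FilterTrace()
    for t in transcripts:
        if t.exon_count == 1:
            near = annotation.mrnas_near_span(t.span, t.strand, flank_bp)
            if near:
                trace.drop(
                    t.transcript_id,
                    "proximity",
                    f"single-exon within {flank_bp} bp of same-strand mRNA "
                    f"{near[0].transcript_id}",
                )
                continue
        kept.append(t)
    return kept, trace


def filter_sense_overlap(
    transcripts: Sequence[TranscriptModel],
    annotation: GenomeAnnotation,
) -> tuple[list[TranscriptModel], FilterTrace]:
    """Filter 3: drop transcripts whose exons share >= 1 bp with exons of a
    same-strand annotated mRNA.  Antisense overlaps are retained — these are
    the lncNAT candidates."""
    kept, trace = [], FilterTrace()
    for t in transcripts:
        bp = annotation.mrna_exon_overlap_bp(t.exons, t.strand)
        if bp >= 1:
            trace.drop(
                t.transcript_id,
                "sense_overlap",
                f"{bp} exonic bp shared with same-strand annotated mRNA",
            )
        else:
            kept.append(t)
    return kept, trace


def filter_expr_length(
    transcripts: Sequence[TranscriptModel],
    fpkm: pd.DataFrame | Mapping[str, Mapping[str, float]],
    min_fpkm: float = 0.5,
    min_fpkm_single: float = 2.0,
    min_len: int = 200,
) -> tuple[list[TranscriptModel], FilterTrace]:
    """Filter 4: drop transcripts with max FPKM across samples below the
    threshold (higher bar for single-exon models) or shorter than *min_len*.

    The expression table is keyed by the assembler locus id (gene-level
    FPKM); a transcript missing from it is an error, never silently kept.
    """
    if not isinstance(fpkm, pd.DataFrame):
        fpkm = pd.DataFrame(fpkm).T
    kept, trace = [], FilterTrace()
    for t in transcripts:
        key = t.gene_id if t.gene_id in fpkm.index else t.transcript_id
        if key not in fpkm.index:
            raise KeyError(
                f"transcript {t.transcript_id} (locus {t.gene_id}) absent "
                "from expression table"
            )
        mx = float(fpkm.loc[key].max())
        threshold = min_fpkm_single if t.exon_count == 1 else min_fpkm
        if mx < threshold:
            trace.drop(
                t.transcript_id,
                "expr_length",
                f"max FPKM {mx:g} < {threshold:g}",
            )
        elif t.length < min_len:
            trace.drop(
                t.transcript_id,
                "expr_length",
                f"length {t.length} bp < {min_len} bp",
            )
        else:
            kept.append(t)
    return kept, trace


def filter_coding(
    transcripts: Sequence[TranscriptModel],
    coding_scores: Mapping[str, float],
    domain_hits: Iterable[str] = (),
) -> tuple[list[TranscriptModel], FilterTrace]:
    """Filters 5+6: drop transcripts with coding-potential score > 0 or with
    a known protein-domain hit."""
    domain_hits = set(domain_hits)
    kept, trace = [], FilterTrace()
    for t in transcripts:
        if t.transcript_id not in coding_scores:
            raise KeyError(f"no coding-potential score for {t.transcript_id}")
        score = coding_scores[t.transcript_id]
        if score > 0:
            trace.drop(
                t.transcript_id, "coding_potential", f"coding score {score:g} > 0"
            )
        elif t.transcript_id in domain_hits:
            trace.drop(t.transcript_id, "pfam", "known protein-domain hit")
        else:
            kept.append(t)
    return kept, trace


# ---------------------------------------------------------------------------
# coding-potential surrogate
# ---------------------------------------------------------------------------

_STOPS = ("TAA", "TAG", "TGA")
ORF_CODING_MIN_NT = 300


def longest_orf(sequence: str) -> int:
    """Length in nt (ATG through stop codon, inclusive) of the longest ORF in
    the three forward frames."""
    seq = sequence.upper().replace("U", "T")
    best = 0
    for frame in range(3):
        start = None
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if start is None:
                if codon == "ATG":
                    start = i
            elif codon in _STOPS:
                best = max(best, i + 3 - start)
                start = None
    return best


def surrogate_coding_score(sequence: str) -> float:
    """Deterministic ORF-based coding-potential score: +1 if the longest
    forward-frame ORF is >= 300 nt, else -1."""
    if not sequence:
        raise ValueError("empty sequence")
    return 1.0 if longest_orf(sequence) >= ORF_CODING_MIN_NT else -1.0


# ---------------------------------------------------------------------------
# classification and locus merging
# ---------------------------------------------------------------------------

_OPPOSITE = {"+": "-", "-": "+"}


def classify(transcript: TranscriptModel, annotation: GenomeAnnotation) -> str:
    """lncNAT iff the transcript's genomic span overlaps a protein-coding
    gene on the opposite strand; otherwise lincRNA.

    A survivor overlapping a same-strand protein-coding gene's exons cannot
    reach here (removed by the sense-overlap filter); the classification uses
    span-level overlap, so same-strand span overlap without exon overlap
    still classifies as lincRNA.
    """
    anti = annotation.genes_overlapping(
        transcript.span, strand=_OPPOSITE[transcript.strand]
    )
    anti = [g for g in anti if g.biotype == "protein_coding"]
    return LNCNAT if anti else LINCRNA


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def merge_loci(
    survivors: Sequence[TranscriptModel],
    classes: Mapping[str, str],
    subgenome_of=None,
    prefix: str = "LNC",
) -> list[LncLocus]:
    """Merge survivors sharing >= 1 bp span overlap on the same chromosome
    and strand, transitively, into non-redundant loci.

    Mixed-class merges are an error: a locus cannot be both lincRNA and
    lncNAT (classification is a span property shared by overlapping models).
    """
    from .properties import subgenome_of as default_subgenome

    subgenome_of = subgenome_of or default_subgenome
    by_key: dict[tuple[str, str], list[TranscriptModel]] = {}
    for t in survivors:
        by_key.setdefault((t.chrom, t.strand), []).append(t)

    loci: list[LncLocus] = []
    for (chrom, strand), txs in sorted(by_key.items()):
        txs = sorted(txs, key=lambda t: (t.span.start, t.transcript_id))
        # sweep over start-sorted spans: the union of a connected component is
        # one contiguous region [first start, running max end), so a span
        # starting before the running end overlaps the open component
        uf = _UnionFind(len(txs))
        running_end = txs[0].span.end
        rep = 0
        for i in range(1, len(txs)):
            if txs[i].span.start < running_end:
                uf.union(rep, i)
            else:
                rep = i
            running_end = max(running_end, txs[i].span.end)
        groups: dict[int, list[TranscriptModel]] = {}
        for i, t in enumerate(txs):
            groups.setdefault(uf.find(i), []).append(t)
        for root in sorted(groups, key=lambda r: groups[r][0].span.start):
            members = groups[root]
            labels = {classes[t.transcript_id] for t in members}
            if len(labels) > 1:
                ids = [t.transcript_id for t in members]
                raise ValueError(
                    f"mixed-class locus on {chrom}{strand} "
                    f"({min(t.span.start for t in members)}-"
                    f"{max(t.span.end for t in members)}): {sorted(labels)} "
                    f"members {ids}"
                )
            span = GenomicInterval(
                chrom,
                min(t.span.start for t in members),
                max(t.span.end for t in members),
                strand,
            )
            loci.append(
                LncLocus(
                    locus_id="",
                    class_label=labels.pop(),
                    chrom=chrom,
                    strand=strand,
                    span=span,
                    transcripts=sorted(t.transcript_id for t in members),
                    subgenome=subgenome_of(chrom),
                )
            )
    loci.sort(key=lambda l: (l.chrom, l.span.start, l.strand))
    width = max(4, len(str(len(loci))))
    return [
        replace(l, locus_id=f"{prefix}_{i + 1:0{width}d}")
        for i, l in enumerate(loci)
    ]


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------


@dataclass
class IdentifyParams:
    flank_bp: int = 500
    min_fpkm: float = 0.5
    min_fpkm_single: float = 2.0
    min_len: int = 200


def run_identification(
    transcripts: Sequence[TranscriptModel],
    annotation: GenomeAnnotation,
    fpkm: pd.DataFrame,
    coding_scores: Mapping[str, float],
    domain_hits: Iterable[str] = (),
    params: IdentifyParams | None = None,
) -> tuple[list[LncLocus], FilterTrace, dict[str, str]]:
    """Apply the six filters in order, classify survivors, merge loci.

    Returns (loci, trace, classes); the trace accounts for every input
    transcript exactly once.
    """
    params = params or IdentifyParams()
    trace = FilterTrace()

    kept, t1 = filter_strand(transcripts)
    trace.merge(t1)
    kept, t2 = filter_single_exon_proximity(kept, annotation, params.flank_bp)
    trace.merge(t2)
    kept, t3 = filter_sense_overlap(kept, annotation)
    trace.merge(t3)
    kept, t4 = filter_expr_length(
        kept, fpkm, params.min_fpkm, params.min_fpkm_single, params.min_len
    )
    trace.merge(t4)
    kept, t56 = filter_coding(kept, coding_scores, domain_hits)
    trace.merge(t56)

    classes = {t.transcript_id: classify(t, annotation) for t in kept}
    for t in kept:
        trace.keep(t.transcript_id)
    if len(trace) != len(transcripts):
        raise AssertionError("trace does not account for all inputs")
    loci = merge_loci(kept, classes)
    return loci, trace, classes
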