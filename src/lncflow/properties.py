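"""Descriptive features of lncRNA catalogues.

Exon counts, transcript length, A/U content, transposable-element overlap and
subgenome placement per class (lincRNA / lncNAT / mRNA), plus the small
reporting arithmetic (percentages to one printed decimal, subgenome fold
ratios) used on published catalogue counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .formats_io import GenomeAnnotation, GenomicInterval
from .identify import LncLocus

SUBGENOMES = ("A", "C", "unplaced")


@dataclass
class FeatureRecord:
    id: str
    feature_class: str  # lincRNA | lncNAT | mRNA
    exon_count: int
    length_bp: int
    au_fraction: float
    te_overlap: bool
    subgenome: str
    max_fpkm: float

    def __post_init__(self) -> None:
        if self.exon_count < 1:
            raise ValueError(f"{self.id}: exon_count must be >= 1")
        if not (0 <= self.au_fraction <= 1):
            raise ValueError(f"{self.id}: au_fraction out of [0,1]")


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round half away from zero, matching how percentages are printed."""
    factor = 10**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


def percentage(part: float, whole: float, decimals: int = 1) -> float:
    if whole == 0:
        raise ZeroDivisionError("percentage of an empty total")
    return round_half_up(100.0 * part / whole, decimals)


def fold_ratio(a: float, b: float, decimals: int = 1) -> float:
    if b == 0:
        raise ZeroDivisionError("fold ratio with zero denominator")
    return round_half_up(a / b, decimals)


def au_content(sequence: str) -> float:
    """Fraction of A/U(T) bases; N bases excluded from the denominator."""
    seq = sequence.upper()
    n_count = seq.count("N")
    denom = len(seq) - n_count
    if denom == 0:
        raise ValueError("sequence has no non-N bases")
    au = sum(seq.count(b) for b in ("A", "T", "U"))
    return au / denom


def subgenome_of(
    chrom: str, prefixes: Mapping[str, str] | None = None
) -> str:
    """Map a chromosome name to its subgenome (default: 'A*'→A, 'C*'→C)."""
    prefixes = prefixes or {"A": "A", "C": "C"}
    for pref, sub in prefixes.items():
        if chrom.startswith(pref) and len(chrom) > len(pref) and chrom[len(pref)].isdigit():
            return sub
    return "unplaced"


def te_overlap_flags(
    loci: Sequence[LncLocus] | Sequence[GenomicInterval] | Mapping[str, GenomicInterval],
    tes: Sequence[GenomicInterval] | GenomeAnnotation,
    min_overlap_bp: int = 10,
) -> dict[str, bool]:
    """True for loci whose genomic span shares >= *min_overlap_bp* with some
    single TE interval (strand-agnostic; introns included)."""
    if isinstance(loci, Mapping):
        spans = dict(loci)
    else:
        spans = {}
        for i, l in enumerate(loci):
            if isinstance(l, GenomicInterval):
                spans[f"iv{i}"] = l
            else:
                spans[l.locus_id] = l.span
    te_list = tes.tes if isinstance(tes, GenomeAnnotation) else list(tes)
    tree: dict[str, list[GenomicInterval]] = {}
    for t in te_list:
        tree.setdefault(t.chrom, []).append(t)
    out: dict[str, bool] = {}
    for name, span in spans.items():
        out[name] = any(
            span.overlap_bp(t) >= min_overlap_bp for t in tree.get(span.chrom, ())
        )
    return out


def expression_summary(
    fpkm: pd.DataFrame, ids: Iterable[str] | None = None
) -> pd.Series:
    """Per-id maximum FPKM across all samples (the expression value used in
    the boxplot summaries)."""
    if ids is None:
        return fpkm.max(axis=1)
    ids = list(ids)
    missing = [i for i in ids if i not in fpkm.index]
    if missing:
        raise KeyError(f"ids absent from expression table: {missing}")
    return fpkm.loc[ids].max(axis=1)


def class_report(features: Sequence[FeatureRecord]) -> pd.DataFrame:
    """Per-class summary: % single/two exon, mean length, mean A/U (with
    rank across classes), % TE overlap per subgenome.

    Percentages are printed to one decimal (half away from zero).  Empty
    classes are omitted with a warning.
    """
    import warnings

    by_class: dict[str, list[FeatureRecord]] = {}
    for f in features:
        by_class.setdefault(f.feature_class, []).append(f)
    for cls in ("lincRNA", "lncNAT", "mRNA"):
        if cls not in by_class:
            warnings.warn(f"class {cls!r} empty; omitted from report")

    rows = {}
    for cls, recs in by_class.items():
        n = len(recs)
        row = {
            "n": n,
            "single_exon_pct": percentage(
                sum(r.exon_count == 1 for r in recs), n
            ),
            "two_exon_pct": percentage(sum(r.exon_count == 2 for r in recs), n),
            "mean_length_bp": round_half_up(
                sum(r.length_bp for r in recs) / n, 1
            ),
            "mean_au": sum(r.au_fraction for r in recs) / n,
        }
        for sub in ("A", "C"):
            sub_recs = [r for r in recs if r.subgenome == sub]
            row[f"te_pct_{sub}"] = (
                percentage(sum(r.te_overlap for r in sub_recs), len(sub_recs))
                if sub_recs
                else float("nan")
            )
        rows[cls] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    # A/U ranking is an observed ordering, not an assertion
    df["au_rank"] = df["mean_au"].rank(ascending=False).astype(int)
    return df.sort_index()


def build_feature_records(
    transcripts,
    classes: Mapping[str, str],
    annotation: GenomeAnnotation,
    sequences: Mapping[str, str],
    fpkm: pd.DataFrame,
    min_te_overlap_bp: int = 10,
) -> list[FeatureRecord]:
    """Assemble per-transcript FeatureRecords.

    ``classes`` maps transcript id to lincRNA/lncNAT/mRNA; ``sequences``
    maps transcript id to nucleotide sequence (transcripts lacking a
    sequence are skipped with their A/U fraction unavailable).  Expression
    is looked up by the assembler locus id with per-transcript fallback.
    """
    maxfpkm = expression_summary(fpkm)
    spans = {t.transcript_id: t.span for t in transcripts}
    te_flags = te_overlap_flags(spans, annotation, min_te_overlap_bp)
    out: list[FeatureRecord] = []
    for t in transcripts:
        if t.transcript_id not in sequences:
            continue
        key = t.gene_id if t.gene_id in maxfpkm.index else t.transcript_id
        out.append(
            FeatureRecord(
                id=t.transcript_id,
                feature_class=classes[t.transcript_id],
                exon_count=t.exon_count,
                length_bp=t.length,
                au_fraction=au_content(sequences[t.transcript_id]),
                te_overlap=te_flags[t.transcript_id],
                subgenome=subgenome_of(t.chrom),
                max_fpkm=float(maxfpkm.get(key, 0.0)),
            )
        )
    return out
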