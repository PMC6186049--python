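"""Cross-genome conservation of lncRNAs: sequence and positional synteny.

Sequence conservation uses strict BLAST cutoffs (E-value < 1e-5, merged
query coverage > 40%, identity > 50%).  Independently of that call, the
broader homolog set (hits passing the E-value cutoff alone) is binned into
four coverage levels: [20,40) -> 1, [40,60) -> 2, [60,80) -> 3,
[80,100] -> 4; coverage below 20% gets no level.  The two sets answer
different questions and are never conflated.

Positional synteny compares the 10 protein-coding genes flanking a lncRNA
on each side with the flanks of its top-5 BLAST hit loci in the target
genome, through a protein-level ortholog map; the locus is syntenically
conserved when at least one side-matched flanking ortholog pair is shared.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .formats_io import GenomeAnnotation, GenomicInterval, HomologyHit

SEQ_EVALUE_MAX = 1e-5
SEQ_COV_MIN = 40.0
SEQ_IDENT_MIN = 50.0
LEVEL_EDGES = (20.0, 40.0, 60.0, 80.0, 100.0)


@dataclass
class SyntenyContext:
    """Ordered flanking protein-coding genes of one locus (nearest first)."""

    lnc_id: str
    upstream: list[str] = field(default_factory=list)
    downstream: list[str] = field(default_factory=list)


@dataclass
class ConservationRecord:
    lnc_id: str
    target_genome: str
    seq_conserved: bool = False
    best_coverage: float = float("nan")
    best_identity: float = float("nan")
    best_evalue: float = float("nan")
    level: int | None = None  # 1..4, None = below 20% / no homolog
    synteny_conserved: bool = False
    shared_flank_genes: list[tuple[str, str]] = field(default_factory=list)


def coverage_level(coverage: float) -> int | None:
    """Coverage bin: [20,40)->1, [40,60)->2, [60,80)->3, [80,100]->4."""
    if not (0 <= coverage <= 100):
        raise ValueError(f"coverage out of [0, 100]: {coverage}")
    if coverage < LEVEL_EDGES[0]:
        return None
    for lvl in (4, 3, 2, 1):
        if coverage >= LEVEL_EDGES[lvl - 1]:
            return lvl
    return None  # unreachable


def sequence_conservation(
    hits: Sequence[HomologyHit],
    query_lengths: Mapping[str, int],
    target_genome: str = "target",
    evalue_max: float = SEQ_EVALUE_MAX,
    cov_min: float = SEQ_COV_MIN,
    ident_min: float = SEQ_IDENT_MIN,
) -> dict[str, ConservationRecord]:
    """Per-query conservation records from merged BLAST hits.

    Conserved iff some subject passes all three strict cutoffs; best_* come
    from the highest-bitscore passing pair.  When no pair passes, best_*
    report the highest-bitscore pair within the E-value cutoff (the homolog
    set used for level binning), and the level comes from that coverage.
    Queries with no hit at all get an empty record (level None).
    """
    records = {
        q: ConservationRecord(lnc_id=q, target_genome=target_genome)
        for q in query_lengths
    }
    by_query: dict[str, list[HomologyHit]] = {}
    for h in hits:
        by_query.setdefault(h.query_id, []).append(h)
    for q, hs in by_query.items():
        if q not in records:
            raise KeyError(f"hit query {q!r} absent from query_lengths")
        rec = records[q]
        significant = [h for h in hs if h.evalue < evalue_max]
        if not significant:
            continue
        passing = [
            h
            for h in significant
            if h.query_cov > cov_min and h.pct_identity > ident_min
        ]
        pool = passing if passing else significant
        best = max(pool, key=lambda h: (h.bitscore, -h.evalue, h.subject_id))
        rec.seq_conserved = bool(passing)
        rec.best_coverage = max(h.query_cov for h in pool)
        rec.best_identity = best.pct_identity
        rec.best_evalue = best.evalue
        rec.level = coverage_level(rec.best_coverage)
    return records


def top_hits(
    hits: Sequence[HomologyHit], query_id: str, k: int = 5
) -> list[HomologyHit]:
    """Top *k* hits of one query, ranked by bitscore; ties broken by lower
    E-value then subject id."""
    mine = [h for h in hits if h.query_id == query_id]
    mine.sort(key=lambda h: (-h.bitscore, h.evalue, h.subject_id))
    return mine[:k]


def flanking_context(
    lnc_id: str,
    span: GenomicInterval,
    annotation: GenomeAnnotation,
    n: int = 10,
) -> SyntenyContext:
    """The nearest *n* protein-coding genes on each side of *span*, ordered
    by increasing midpoint distance; truncated at chromosome ends.

    Genes overlapping the locus (e.g. the antisense partner of a lncNAT)
    are assigned to a side by midpoint and rank nearest.
    """
    order = annotation.flank_order.get(span.chrom, [])
    order = [g for g in order if g.gene_id != lnc_id]
    mid = span.midpoint
    upstream = [g for g in order if g.span.midpoint <= mid]
    downstream = [g for g in order if g.span.midpoint > mid]
    upstream.sort(key=lambda g: (mid - g.span.midpoint, g.gene_id))
    downstream.sort(key=lambda g: (g.span.midpoint - mid, g.gene_id))
    return SyntenyContext(
        lnc_id=lnc_id,
        upstream=[g.gene_id for g in upstream[:n]],
        downstream=[g.gene_id for g in downstream[:n]],
    )


def build_ortholog_map(
    protein_hits: Sequence[HomologyHit],
    evalue_max: float = 1e-5,
    max_targets: int = 5,
    reciprocal: bool = False,
) -> dict[str, set[str]]:
    """Query-gene -> target-ortholog map from a protein homology table.

    Keeps up to *max_targets* best-bitscore subjects per query below the
    E-value cutoff (mirroring a BLASTp run with max_target_seqs < 6).  In
    reciprocal mode a pair is kept only when the query is also among the
    subject's best partners.
    """
    by_query: dict[str, list[HomologyHit]] = {}
    for h in protein_hits:
        if h.evalue < evalue_max:
            by_query.setdefault(h.query_id, []).append(h)
    out: dict[str, set[str]] = {}
    for q, hs in by_query.items():
        hs.sort(key=lambda h: (-h.bitscore, h.evalue, h.subject_id))
        out[q] = {h.subject_id for h in hs[:max_targets]}
    if reciprocal:
        by_subject: dict[str, list[HomologyHit]] = {}
        for h in protein_hits:
            if h.evalue < evalue_max:
                by_subject.setdefault(h.subject_id, []).append(h)
        back: dict[str, set[str]] = {}
        for s, hs in by_subject.items():
            hs.sort(key=lambda h: (-h.bitscore, h.evalue, h.query_id))
            back[s] = {h.query_id for h in hs[:max_targets]}
        out = {
            q: {s for s in subs if q in back.get(s, ())}
            for q, subs in out.items()
        }
        out = {q: subs for q, subs in out.items() if subs}
    return out


def synteny_conservation(
    context: SyntenyContext,
    hit_contexts: Sequence[SyntenyContext],
    ortholog_map: Mapping[str, Iterable[str]],
    side_matched: bool = True,
) -> tuple[bool, list[tuple[str, str]]]:
    """Synteny verdict for one lncRNA.

    *hit_contexts* are the flanking contexts of the lncRNA's top BLAST hit
    loci in the target genome.  Conserved iff, for at least one hit locus,
    at least one of the lncRNA's flanking genes has an ortholog among the
    hit locus's flanking genes on the matching side (upstream<->upstream or
    downstream<->downstream); ``side_matched=False`` relaxes the side rule
    for inverted blocks.  Returns the verdict and the witness gene pairs.
    """
    witnesses: list[tuple[str, str]] = []
    for hc in hit_contexts:
        if side_matched:
            side_pairs = [
                (context.upstream, hc.upstream),
                (context.downstream, hc.downstream),
            ]
        else:
            both = list(hc.upstream) + list(hc.downstream)
            side_pairs = [(context.upstream, both), (context.downstream, both)]
        for own_side, target_side in side_pairs:
            target_set = set(target_side)
            for g in own_side:
                shared = set(ortholog_map.get(g, ())) & target_set
                for s in sorted(shared):
                    witnesses.append((g, s))
    return bool(witnesses), sorted(set(witnesses))


def conservation_expression_profile(
    records: Mapping[str, ConservationRecord],
    max_fpkm: Mapping[str, float],
) -> tuple[dict[int, np.ndarray], float]:
    """Max-FPKM distribution per conservation level, plus the Spearman
    correlation between level (1-4) and expression.

    The correlation is reported, never asserted; all-tied inputs yield 0.
    """
    levels, expr = [], []
    by_level: dict[int, list[float]] = {}
    for lnc_id, rec in records.items():
        if rec.level is None or lnc_id not in max_fpkm:
            continue
        by_level.setdefault(rec.level, []).append(float(max_fpkm[lnc_id]))
        levels.append(rec.level)
        expr.append(float(max_fpkm[lnc_id]))
    profile = {lvl: np.asarray(v) for lvl, v in sorted(by_level.items())}
    if len(set(levels)) < 2 or len(set(expr)) < 2:
        rho = 0.0
    else:
        rho = float(stats.spearmanr(levels, expr).statistic)
        if not np.isfinite(rho):
            rho = 0.0
    return profile, rho
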