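"""Seeded generator of every input the pipeline consumes, with ground truth.

The generator emulates the downstream products of a seed-development
transcriptome study in an allotetraploid crop: a two-subgenome ("A"/"C")
reference annotation, assembled transcripts planting one known-fate case per
identification filter plus lincRNA/lncNAT survivors, transcript sequences
with controlled A/U content and ORF presence, TE intervals, a DEG expression
matrix with planted coexpression modules (one tied to a sigmoidal oil-content
trait over days after flowering), cross-genome homology tables realizing
chosen conservation coverages and synteny blocks, and replicate qPCR Ct
tables with planted ddCt effects.

Every output is a deterministic function of the seed; a manifest records the
intended fate/class/module/level of every record so each downstream stage is
testable end to end.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .formats_io import (
    GeneRecord,
    GenomeAnnotation,
    GenomicInterval,
    HomologyHit,
    TranscriptModel,
    write_bed,
    write_expression,
    write_fasta,
    write_gtf,
)

_STOP_CODONS = {"TAA", "TAG", "TGA"}


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class SimConfig:
    seed: int = 42
    # genome / identification
    n_chroms_per_subgenome: int = 2
    genes_per_chrom: int = 12
    gene_length: int = 2000
    gene_spacing: int = 15000
    planted_drops: dict = field(
        default_factory=lambda: {
            "strand": 3,
            "proximity": 3,
            "sense_overlap": 3,
            "expr_length_low": 2,
            "expr_length_low_single": 2,
            "expr_length_short": 2,
            "coding_potential": 3,
            "pfam": 2,
        }
    )
    n_lincrna: int = 10
    n_lincrna_isoform_pairs: int = 2
    n_lncnat: int = 6
    n_tes_per_chrom: int = 4
    lnc_au: float = 0.60
    mrna_au: float = 0.45
    # separation margins around the 500 bp / FPKM 0.5 cutoffs
    drop_flank_bp: int = 400
    keep_flank_bp: int = 600
    low_fpkm: float = 0.4
    low_fpkm_single: float = 1.5
    survivor_fpkm: float = 5.0
    # coexpression
    n_modules: int = 3
    genes_per_module: int = 40
    n_samples: int = 12
    within_module_r: float = 0.8
    trait_link_module: int = 0
    n_lnc_in_trait_module: int = 4
    n_lipid_in_trait_module: int = 2
    # conservation
    cons_per_level: int = 3
    synteny_true: int = 10
    synteny_false: int = 5
    # qPCR
    qpcr_ddct: dict = field(
        default_factory=lambda: {"lnc_up": -3.0, "lnc_down": 1.5, "lnc_flat": 0.0}
    )
    qpcr_replicates: int = 3
    qpcr_noise_sd: float = 0.1

    def validate(self) -> None:
        if self.genes_per_module < 2:
            raise ValueError("modules need >= 2 genes")
        if not (0 < self.within_module_r < 1):
            raise ValueError("within_module_r must be in (0, 1)")
        if any(v < 0 for v in self.planted_drops.values()):
            raise ValueError("planted drop counts must be >= 0")
        if self.keep_flank_bp <= 500 or self.drop_flank_bp >= 500:
            raise ValueError("flank margins must straddle the 500 bp rule")


# ---------------------------------------------------------------------------
# sequence helpers
# ---------------------------------------------------------------------------


def random_sequence(rng: np.random.Generator, length: int, au: float = 0.5) -> str:
    p = np.array([au / 2, (1 - au) / 2, (1 - au) / 2, au / 2])
    seq = "".join(rng.choice(list("ACGT"), size=length, p=p))
    return seq


def orf_free(seq: str) -> str:
    """Destroy every ATG so no forward-frame ORF can start."""
    out = list(seq)
    i = 0
    while i < len(out) - 2:
        if out[i] == "A" and out[i + 1] == "T" and out[i + 2] == "G":
            out[i + 2] = "C"
        i += 1
    return "".join(out)


def with_long_orf(rng: np.random.Generator, length: int, orf_nt: int = 303) -> str:
    """ORF-free background with one embedded ORF of *orf_nt* nt."""
    if length < orf_nt + 6:
        raise ValueError("sequence too short for the planted ORF")
    safe = [
        a + b + c
        for a in "ACGT"
        for b in "ACGT"
        for c in "ACGT"
        if a + b + c not in _STOP_CODONS and a + b + c != "ATG"
    ]
    n_codons = orf_nt // 3 - 2
    body = "".join(rng.choice(safe, size=n_codons))
    orf = "ATG" + body + "TAA"
    pad = length - len(orf)
    left = pad // 2
    prefix = orf_free(random_sequence(rng, left))
    suffix = orf_free(random_sequence(rng, pad - left))
    return prefix + orf + suffix


# ---------------------------------------------------------------------------
# genome + identification fixture
# ---------------------------------------------------------------------------


@dataclass
class IdentificationBundle:
    annotation: GenomeAnnotation
    transcripts: list[TranscriptModel]
    fpkm: pd.DataFrame
    sequences: dict[str, str]
    mrna_sequences: dict[str, str]
    coding_scores: dict[str, float]
    domain_hits: set[str]
    tes: list[GenomicInterval]
    fates: dict[str, str]  # transcript -> first-dropping stage or "none"
    classes: dict[str, str]  # survivors -> lincRNA | lncNAT
    locus_groups: dict[str, int]  # survivors -> planted locus group index


def _make_annotation(cfg: SimConfig, rng: np.random.Generator) -> GenomeAnnotation:
    chroms = [
        f"{sub}{i + 1:02d}"
        for sub in ("A", "C")
        for i in range(cfg.n_chroms_per_subgenome)
    ]
    genes, mrnas = [], []
    for chrom in chroms:
        for i in range(cfg.genes_per_chrom):
            start = 5000 + i * cfg.gene_spacing
            strand = "+" if i % 2 == 0 else "-"
            gid = f"Gene_{chrom}_{i:03d}"
            span = GenomicInterval(chrom, start, start + cfg.gene_length, strand)
            genes.append(GeneRecord(gid, span, "protein_coding"))
            third = cfg.gene_length // 3
            mrnas.append(
                TranscriptModel(
                    transcript_id=gid + ".1",
                    gene_id=gid,
                    exons=[
                        GenomicInterval(chrom, start, start + third, strand),
                        GenomicInterval(
                            chrom, start + 2 * third, start + cfg.gene_length, strand
                        ),
                    ],
                )
            )
    return GenomeAnnotation(genes, mrnas)


class _GapAllocator:
    """Deterministically hand out one intergenic gap per planted case."""

    def __init__(self, annotation: GenomeAnnotation, cfg: SimConfig) -> None:
        self.slots: list[tuple[str, int]] = []  # (chrom, gap mid-start)
        for chrom, order in sorted(annotation.flank_order.items()):
            for g1, g2 in zip(order, order[1:]):
                mid = (g1.span.end + g2.span.start) // 2
                self.slots.append((chrom, mid))
        self.i = 0

    def next(self) -> tuple[str, int]:
        if self.i >= len(self.slots):
            raise ValueError("not enough intergenic gaps for the planted cases")
        slot = self.slots[self.i]
        self.i += 1
        return slot


def simulate_identification(cfg: SimConfig, rng: np.random.Generator) -> IdentificationBundle:
    annotation = _make_annotation(cfg, rng)
    gaps = _GapAllocator(annotation, cfg)
    gene_cycle = sorted(annotation.genes.values(), key=lambda g: (g.span.chrom, g.span.start))

    transcripts: list[TranscriptModel] = []
    fates: dict[str, str] = {}
    classes: dict[str, str] = {}
    locus_groups: dict[str, int] = {}
    sequences: dict[str, str] = {}
    coding_scores: dict[str, float] = {}
    domain_hits: set[str] = set()
    fpkm_rows: dict[str, float] = {}
    xloc = iter(range(1, 10000))

    def add(tid: str, exons, fate: str, fpkm_val: float, seq: str | None = None,
            gene_id: str | None = None, coding: bool = False) -> TranscriptModel:
        gid = gene_id or f"XLOC_{next(xloc):05d}"
        t = TranscriptModel(tid, gid, exons)
        transcripts.append(t)
        fates[tid] = fate
        fpkm_rows.setdefault(gid, fpkm_val)
        if seq is None:
            seq = orf_free(random_sequence(rng, t.length, cfg.lnc_au))
        sequences[tid] = seq
        coding_scores[tid] = 1.0 if coding else -1.0
        return t

    d = cfg.planted_drops
    # filter 1: strand-unknown
    for i in range(d.get("strand", 0)):
        chrom, mid = gaps.next()
        add(f"T_strand_{i}", [GenomicInterval(chrom, mid, mid + 400, ".")],
            "strand", cfg.survivor_fpkm)
    # filter 2: single exon within drop_flank_bp of a same-strand mRNA
    for i in range(d.get("proximity", 0)):
        g = gene_cycle[i % len(gene_cycle)]
        start = g.span.end + cfg.drop_flank_bp
        add(f"T_prox_{i}",
            [GenomicInterval(g.span.chrom, start, start + 300, g.strand)],
            "proximity", cfg.survivor_fpkm)
    # filter 3: exonic same-strand overlap with an annotated mRNA
    for i in range(d.get("sense_overlap", 0)):
        g = gene_cycle[(i + 3) % len(gene_cycle)]
        c, s = g.span.chrom, g.span.start
        add(f"T_sense_{i}",
            [GenomicInterval(c, s + 100, s + 400, g.strand),
             GenomicInterval(c, g.span.end + 600, g.span.end + 900, g.strand)],
            "sense_overlap", cfg.survivor_fpkm)
    # filter 4: low FPKM (multi-exon)
    for i in range(d.get("expr_length_low", 0)):
        chrom, mid = gaps.next()
        add(f"T_lowfpkm_{i}",
            [GenomicInterval(chrom, mid, mid + 300, "+"),
             GenomicInterval(chrom, mid + 500, mid + 800, "+")],
            "expr_length", cfg.low_fpkm)
    # filter 4: low FPKM (single-exon, below the higher single-exon bar)
    for i in range(d.get("expr_length_low_single", 0)):
        chrom, mid = gaps.next()
        add(f"T_lowfpkm1x_{i}",
            [GenomicInterval(chrom, mid, mid + 400, "-")],
            "expr_length", cfg.low_fpkm_single)
    # filter 4: short
    for i in range(d.get("expr_length_short", 0)):
        chrom, mid = gaps.next()
        add(f"T_short_{i}",
            [GenomicInterval(chrom, mid, mid + 75, "+"),
             GenomicInterval(chrom, mid + 200, mid + 275, "+")],
            "expr_length", cfg.survivor_fpkm)
    # filter 5: positive coding potential (planted >= 300 nt ORF)
    for i in range(d.get("coding_potential", 0)):
        chrom, mid = gaps.next()
        exons = [GenomicInterval(chrom, mid, mid + 250, "+"),
                 GenomicInterval(chrom, mid + 400, mid + 650, "+")]
        t = TranscriptModel("tmp", "tmp", exons)
        add(f"T_coding_{i}", exons, "coding_potential", cfg.survivor_fpkm,
            seq=with_long_orf(rng, t.length), coding=True)
    # filter 6: known protein-domain hit
    for i in range(d.get("pfam", 0)):
        chrom, mid = gaps.next()
        tid = f"T_pfam_{i}"
        add(tid,
            [GenomicInterval(chrom, mid, mid + 250, "-"),
             GenomicInterval(chrom, mid + 400, mid + 650, "-")],
            "pfam", cfg.survivor_fpkm)
        domain_hits.add(tid)

    group = iter(range(10000))
    # lincRNA survivors (some single-exon at keep_flank distance, some mid-gap)
    for i in range(cfg.n_lincrna):
        gidx = next(group)
        if i % 3 == 0:
            g = gene_cycle[(2 * i + 1) % len(gene_cycle)]
            start = g.span.end + cfg.keep_flank_bp
            exons = [GenomicInterval(g.span.chrom, start, start + 600, g.strand)]
        else:
            chrom, mid = gaps.next()
            strand = "+" if i % 2 else "-"
            exons = [GenomicInterval(chrom, mid, mid + 350, strand),
                     GenomicInterval(chrom, mid + 500, mid + 850, strand)]
        tid = f"T_linc_{i}"
        add(tid, exons, "none", cfg.survivor_fpkm)
        classes[tid] = "lincRNA"
        locus_groups[tid] = gidx
    # isoform pairs sharing a locus
    for i in range(cfg.n_lincrna_isoform_pairs):
        chrom, mid = gaps.next()
        gidx = next(group)
        gid = f"XLOC_ISO_{i:03d}"
        for j, shift in enumerate((0, 200)):
            tid = f"T_iso_{i}_{j}"
            add(tid,
                [GenomicInterval(chrom, mid + shift, mid + shift + 300, "+"),
                 GenomicInterval(chrom, mid + 600, mid + 950, "+")],
                "none", cfg.survivor_fpkm, gene_id=gid)
            classes[tid] = "lincRNA"
            locus_groups[tid] = gidx
    # lncNAT survivors: two-exon models inside a gene span, opposite strand
    for i in range(cfg.n_lncnat):
        g = gene_cycle[(5 * i + 2) % len(gene_cycle)]
        anti = "-" if g.strand == "+" else "+"
        c, s = g.span.chrom, g.span.start
        tid = f"T_nat_{i}"
        add(tid,
            [GenomicInterval(c, s + 50, s + 350, anti),
             GenomicInterval(c, s + 700, s + 1000, anti)],
            "none", cfg.survivor_fpkm)
        classes[tid] = "lncNAT"
        locus_groups[tid] = next(group)

    # TEs: one overlapping each third survivor's span, the rest intergenic
    tes: list[GenomicInterval] = []
    survivors = [t for t in transcripts if fates[t.transcript_id] == "none"]
    for i, t in enumerate(survivors):
        if i % 3 == 0:
            tes.append(GenomicInterval(t.chrom, t.span.start + 20,
                                       t.span.start + 120, "."))
    for chrom in sorted({t.chrom for t in transcripts}):
        for i in range(cfg.n_tes_per_chrom):
            pos = 1000 + i * 3001
            tes.append(GenomicInterval(chrom, pos, pos + 500, "."))
    annotation.tes.extend(tes)

    samples = [f"s{i + 1}" for i in range(4)]
    fpkm = pd.DataFrame(
        {s: {gid: v * f for gid, v in sorted(fpkm_rows.items())}
         for s, f in zip(samples, (1.0, 0.7, 0.4, 0.2))}
    )
    mrna_sequences = {
        m.transcript_id: orf_free(random_sequence(rng, m.length, cfg.mrna_au))
        for m in annotation.mrnas.values()
    }
    for m in annotation.mrnas.values():
        fpkm.loc[m.gene_id] = [
            cfg.survivor_fpkm * 4 * f for f in (1.0, 0.7, 0.4, 0.2)
        ]
    return IdentificationBundle(
        annotation=annotation,
        transcripts=transcripts,
        fpkm=fpkm,
        sequences=sequences,
        mrna_sequences=mrna_sequences,
        coding_scores=coding_scores,
        domain_hits=domain_hits,
        tes=tes,
        fates=fates,
        classes=classes,
        locus_groups=locus_groups,
    )


# ---------------------------------------------------------------------------
# coexpression fixture
# ---------------------------------------------------------------------------


def oil_content_curve(daf: np.ndarray) -> np.ndarray:
    """Sigmoidal seed-oil accumulation over days after flowering: low until
    ~20 DAF, steep rise through 20-35 DAF, plateau after."""
    daf = np.asarray(daf, float)
    return 5.0 + 40.0 / (1.0 + np.exp(-(daf - 27.0) / 4.0))


@dataclass
class ExpressionBundle:
    expr: pd.DataFrame  # genes x samples, FPKM
    traits: pd.DataFrame  # samples x (oil_content, daf)
    modules: pd.Series  # planted module index per gene
    trait_module: int
    lnc_ids: list[str]
    lipid_ids: list[str]


def simulate_expression_modules(
    cfg: SimConfig, rng: np.random.Generator
) -> ExpressionBundle:
    n_rep = cfg.n_samples // 4
    daf = np.repeat([15, 25, 30, 40], n_rep)[: cfg.n_samples]
    if daf.size < cfg.n_samples:
        daf = np.concatenate([daf, np.full(cfg.n_samples - daf.size, 40)])
    samples = [f"s{i + 1:02d}" for i in range(cfg.n_samples)]
    oil = oil_content_curve(daf) + rng.normal(0, 0.5, cfg.n_samples)

    def _std(v: np.ndarray) -> np.ndarray:
        return (v - v.mean()) / v.std()

    # module seed profiles are mutually orthogonal so the planted partition
    # is well separated: modules differ by construction, not by luck
    seeds = []
    for m in range(cfg.n_modules):
        if m == cfg.trait_link_module:
            seeds.append(_std(oil))
        else:
            v = rng.normal(size=cfg.n_samples)
            for s in seeds:
                v = v - (v @ s) / (s @ s) * s
            seeds.append(_std(v))

    r = cfg.within_module_r
    names, rows, modules = [], [], []
    lnc_ids, lipid_ids = [], []
    for m in range(cfg.n_modules):
        for g in range(cfg.genes_per_module):
            name = f"m{m}_g{g:03d}"
            if m == cfg.trait_link_module and g < cfg.n_lnc_in_trait_module:
                name = f"lnc_{g + 1}"
                lnc_ids.append(name)
            elif (
                m == cfg.trait_link_module
                and g < cfg.n_lnc_in_trait_module + cfg.n_lipid_in_trait_module
            ):
                name = f"lipid_{g - cfg.n_lnc_in_trait_module + 1}"
                lipid_ids.append(name)
            z = np.sqrt(r) * seeds[m] + np.sqrt(1 - r) * rng.normal(
                size=cfg.n_samples
            )
            x = np.clip(4.0 + 1.5 * z, 0.0, None)  # log2 scale
            rows.append(2.0**x - 1.0)
            names.append(name)
            modules.append(m)
    expr = pd.DataFrame(rows, index=names, columns=samples)
    traits = pd.DataFrame(
        {"oil_content": oil, "daf": daf.astype(float)}, index=samples
    )
    return ExpressionBundle(
        expr=expr,
        traits=traits,
        modules=pd.Series(modules, index=names, name="module"),
        trait_module=cfg.trait_link_module,
        lnc_ids=lnc_ids,
        lipid_ids=lipid_ids,
    )


# ---------------------------------------------------------------------------
# conservation fixture
# ---------------------------------------------------------------------------


@dataclass
class ConservationBundle:
    query_lengths: dict[str, int]
    hit_rows: list[tuple]  # 12-column BLAST rows for the sequence search
    levels: dict[str, int | None]  # planted level per query
    conserved: dict[str, bool]
    max_fpkm: dict[str, float]
    # synteny part
    query_annotation: GenomeAnnotation
    target_annotation: GenomeAnnotation
    lnc_spans: dict[str, GenomicInterval]  # query lncRNA loci
    target_lnc_spans: dict[str, GenomicInterval]  # hit loci in target genome
    lnc_hit_rows: list[tuple]  # lncRNA -> target-locus BLAST rows
    protein_hit_rows: list[tuple]  # flank-gene ortholog BLAST rows
    synteny_truth: dict[str, bool]


def _blast_row(q, s, pident, length, qstart, qend, evalue, bitscore,
               sstart=1, send=None):
    send = send if send is not None else sstart + length - 1
    return (q, s, pident, length, 0, 0, qstart, qend, sstart, send, evalue, bitscore)


def simulate_conservation(
    cfg: SimConfig, rng: np.random.Generator
) -> ConservationBundle:
    qlen = 1000
    query_lengths: dict[str, int] = {}
    hit_rows: list[tuple] = []
    levels: dict[str, int | None] = {}
    conserved: dict[str, bool] = {}
    max_fpkm: dict[str, float] = {}

    # planted coverages sit mid-bin to keep clear of the boundaries
    for lvl, cov in zip((1, 2, 3, 4), (30, 50, 70, 90)):
        for i in range(cfg.cons_per_level):
            q = f"qlnc_L{lvl}_{i}"
            query_lengths[q] = qlen
            span_nt = qlen * cov // 100
            if i % 2 == 0:
                hit_rows.append(
                    _blast_row(q, f"sub_{q}", 82.0, span_nt, 1, span_nt, 1e-20, 400.0)
                )
            else:  # two overlapping HSPs whose union realizes the coverage
                a_end = span_nt * 2 // 3
                hit_rows.append(
                    _blast_row(q, f"sub_{q}", 82.0, a_end, 1, a_end, 1e-20, 400.0)
                )
                hit_rows.append(
                    _blast_row(q, f"sub_{q}", 78.0, span_nt - a_end + 50,
                               a_end - 49, span_nt, 1e-18, 300.0)
                )
            levels[q] = lvl
            conserved[q] = cov > 40
            max_fpkm[q] = lvl * 8.0 + float(rng.uniform(0, 2))
    # identity failure: significant homolog (level 2 bin) but not conserved
    q = "qlnc_lowident"
    query_lengths[q] = qlen
    hit_rows.append(_blast_row(q, "sub_li", 45.0, 550, 1, 550, 1e-20, 350.0))
    levels[q], conserved[q] = 2, False
    # E-value failure: no significant homolog at all
    q = "qlnc_weak"
    query_lengths[q] = qlen
    hit_rows.append(_blast_row(q, "sub_wk", 80.0, 700, 1, 700, 1e-3, 40.0))
    levels[q], conserved[q] = None, False
    # no hit
    query_lengths["qlnc_nohit"] = qlen
    levels["qlnc_nohit"], conserved["qlnc_nohit"] = None, False

    # ---- synteny ----
    n_lnc = cfg.synteny_true + cfg.synteny_false
    n_genes = max(4 * n_lnc + 10, 40)
    spacing, glen = 10000, 2000

    q_genes = []
    for k in range(n_genes):
        start = 5000 + k * spacing
        q_genes.append(
            GeneRecord(
                f"qg{k:03d}",
                GenomicInterval("Q1", start, start + glen, "+" if k % 2 else "-"),
            )
        )
    query_annotation = GenomeAnnotation(q_genes)

    t_genes = []
    for k in range(n_genes):
        start = 7000 + k * spacing  # global translation: synteny is shift-invariant
        t_genes.append(
            GeneRecord(
                f"tg{k:03d}",
                GenomicInterval("T1", start, start + glen, "+" if k % 3 else "-"),
            )
        )
    # a scrambled target chromosome with no orthologs at all
    for k in range(30):
        start = 5000 + k * spacing
        t_genes.append(
            GeneRecord(f"tx{k:03d}", GenomicInterval("T2", start, start + glen, "+"))
        )
    target_annotation = GenomeAnnotation(t_genes)

    protein_hit_rows = [
        _blast_row(f"qg{k:03d}", f"tg{k:03d}", 90.0, 500, 1, 500, 1e-30, 900.0)
        for k in range(n_genes)
    ]

    lnc_spans: dict[str, GenomicInterval] = {}
    target_lnc_spans: dict[str, GenomicInterval] = {}
    lnc_hit_rows: list[tuple] = []
    synteny_truth: dict[str, bool] = {}
    for i in range(n_lnc):
        name = f"slnc_{i}"
        j = 2 + 3 * i  # host gap: between qg{j} and qg{j+1}
        gap_mid = 5000 + j * spacing + glen + (spacing - glen) // 2
        lnc_spans[name] = GenomicInterval("Q1", gap_mid, gap_mid + 800, "+")
        query_lengths.setdefault(name, 800)
        tname = f"tlnc_{i}"
        if i < cfg.synteny_true:
            t_mid = 7000 + j * spacing + glen + (spacing - glen) // 2
            target_lnc_spans[tname] = GenomicInterval("T1", t_mid, t_mid + 800, "+")
            synteny_truth[name] = True
        else:
            t_mid = 5000 + (3 * (i - cfg.synteny_true) + 1) * spacing + glen + 2000
            target_lnc_spans[tname] = GenomicInterval("T2", t_mid, t_mid + 800, "+")
            synteny_truth[name] = False
        lnc_hit_rows.append(
            _blast_row(name, tname, 85.0, 600, 1, 600, 1e-15, 300.0)
        )

    return ConservationBundle(
        query_lengths=query_lengths,
        hit_rows=hit_rows,
        levels=levels,
        conserved=conserved,
        max_fpkm=max_fpkm,
        query_annotation=query_annotation,
        target_annotation=target_annotation,
        lnc_spans=lnc_spans,
        target_lnc_spans=target_lnc_spans,
        lnc_hit_rows=lnc_hit_rows,
        protein_hit_rows=protein_hit_rows,
        synteny_truth=synteny_truth,
    )


# ---------------------------------------------------------------------------
# qPCR fixture
# ---------------------------------------------------------------------------


def simulate_ct(
    cfg: SimConfig,
    rng: np.random.Generator,
    baseline: str = "10-20DAF",
    treatment: str = "30DAF",
    reference: str = "EF-1a",
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Replicate Ct table with planted ddCt shifts per gene."""
    rows = []
    for cond in (baseline, treatment):
        for rep in range(1, cfg.qpcr_replicates + 1):
            rows.append(
                {"gene": reference, "condition": cond, "replicate": rep,
                 "ct": 20.0 + rng.normal(0, cfg.qpcr_noise_sd)}
            )
    for gene, ddct in sorted(cfg.qpcr_ddct.items()):
        for cond, shift in ((baseline, 0.0), (treatment, ddct)):
            for rep in range(1, cfg.qpcr_replicates + 1):
                rows.append(
                    {"gene": gene, "condition": cond, "replicate": rep,
                     "ct": 26.0 + shift + rng.normal(0, cfg.qpcr_noise_sd)}
                )
    return pd.DataFrame(rows), dict(cfg.qpcr_ddct)


# ---------------------------------------------------------------------------
# file bundle
# ---------------------------------------------------------------------------


def generate(cfg: SimConfig, outdir: str | Path) -> dict:
    """Write the full file bundle plus a ground-truth manifest (JSON).

    Byte-identical output for identical seeds.
    """
    cfg.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    ident = simulate_identification(cfg, rng)
    write_gtf(
        sorted(ident.annotation.mrnas.values(), key=lambda m: m.transcript_id),
        out / "reference.gtf",
        source="sim",
    )
    # prepend gene lines so the annotation reader sees biotypes
    gene_lines = []
    for g in sorted(ident.annotation.genes.values(), key=lambda g: g.gene_id):
        s = g.span
        gene_lines.append(
            f'{s.chrom}\tsim\tgene\t{s.start + 1}\t{s.end}\t.\t{s.strand}\t.\t'
            f'gene_id "{g.gene_id}"; gene_biotype "{g.biotype}";\n'
        )
    body = (out / "reference.gtf").read_text()
    (out / "reference.gtf").write_text("".join(gene_lines) + body)

    write_gtf(ident.transcripts, out / "transcripts.gtf", source="sim")
    write_fasta(ident.sequences, out / "transcripts.fa")
    write_fasta(ident.mrna_sequences, out / "mrna.fa")
    write_bed(ident.tes, out / "te.bed")
    write_expression(ident.fpkm, out / "fpkm.tsv")
    pd.Series(ident.coding_scores, name="score").rename_axis("transcript_id") \
        .to_csv(out / "coding_scores.tsv", sep="\t")
    (out / "pfam_hits.txt").write_text(
        "".join(f"{t}\n" for t in sorted(ident.domain_hits))
    )

    expr = simulate_expression_modules(cfg, rng)
    write_expression(expr.expr, out / "coexpr_fpkm.tsv")
    expr.traits.to_csv(out / "traits.tsv", sep="\t", index_label="sample")
    (out / "degs.txt").write_text("".join(f"{g}\n" for g in expr.expr.index))

    cons = simulate_conservation(cfg, rng)
    _write_blast(cons.hit_rows, out / "cons_hits.tsv")
    _write_blast(cons.lnc_hit_rows, out / "synteny_lnc_hits.tsv")
    _write_blast(cons.protein_hit_rows, out / "synteny_protein_hits.tsv")
    pd.Series(cons.query_lengths, name="length").rename_axis("id") \
        .to_csv(out / "query_lengths.tsv", sep="\t")

    ct, ddct_truth = simulate_ct(cfg, rng)
    ct.to_csv(out / "ct.tsv", sep="\t", index=False)

    manifest = {
        "seed": cfg.seed,
        "identification": {
            "fates": ident.fates,
            "classes": ident.classes,
            "locus_groups": ident.locus_groups,
            "n_transcripts": len(ident.transcripts),
        },
        "coexpression": {
            "modules": expr.modules.to_dict(),
            "trait_module": expr.trait_module,
            "lnc_ids": expr.lnc_ids,
            "lipid_ids": expr.lipid_ids,
        },
        "conservation": {
            "levels": cons.levels,
            "conserved": cons.conserved,
            "synteny": cons.synteny_truth,
        },
        "qpcr": {"ddct": ddct_truth},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _write_blast(rows, path: Path) -> None:
    with open(path, "w") as fh:
        for r in rows:
            fh.write("\t".join(str(x) for x in r) + "\n")


def load_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
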