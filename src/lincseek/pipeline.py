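"""The seven-stage lincRNA identification filter cascade.

Starting from assembled multi-exon transcripts the cascade removes, in
fixed order: (1) single-exon and short (<200 nt mature) transcripts;
(2) transcripts whose genomic span shares any base with an annotated
protein-coding gene locus; (3) transcripts with positive coding
potential on either strand; (4) transcripts with a significant protein
similarity hit (E <= 1e-5); (5) transcripts with a significant protein
domain hit in any translation frame (E <= 1e-5); (6) transcripts hit by
a known small-RNA family; (7) transcripts more than 90% covered by
annotated mRNA UTR regions (assembly fragments).  Survivors are the
putative lincRNAs; grouping them on gene_id yields lincRNA loci.

Every stage emits an audit entry; the :class:`FilterReport` chain
invariant (input = removed + surviving, stage k+1 input = stage k
survivors) is validated on completion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Optional, Sequence

from intervaltree import IntervalTree

from .model import (
    GeneLocus,
    GenomeSequence,
    HitRecord,
    Interval,
    LincseekError,
    TranscriptModel,
    build_gene_loci,
)
from .io import extract_sequence
from .orf import scan_orfs

DEFAULT_SMALL_RNA_CLASSES = frozenset(
    {"snRNA", "snoRNA", "tRNA", "miRNA", "rRNA"}
)


@dataclass(frozen=True)
class StageEntry:
    """Audit record of one filter stage."""

    stage: str
    parameters: dict
    n_input: int
    n_removed: int
    n_surviving: int
    removed_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.n_input != self.n_removed + self.n_surviving:
            raise ValueError(
                f"stage {self.stage}: {self.n_input} != "
                f"{self.n_removed} + {self.n_surviving}"
            )


@dataclass
class FilterReport:
    """Ordered per-stage audit of a cascade run."""

    stages: list[StageEntry] = field(default_factory=list)

    def add(self, entry: StageEntry) -> None:
        if self.stages and entry.n_input != self.stages[-1].n_surviving:
            raise ValueError(
                f"stage {entry.stage}: input {entry.n_input} != previous "
                f"survivors {self.stages[-1].n_surviving}"
            )
        self.stages.append(entry)

    def to_records(self) -> list[dict]:
        return [
            {
                "stage": s.stage,
                "parameters": s.parameters,
                "n_input": s.n_input,
                "n_removed": s.n_removed,
                "n_surviving": s.n_surviving,
                "removed_ids": list(s.removed_ids),
            }
            for s in self.stages
        ]

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_records(), fh, indent=2)

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("stage\tn_input\tn_removed\tn_surviving\tparameters\n")
            for s in self.stages:
                fh.write(
                    f"{s.stage}\t{s.n_input}\t{s.n_removed}\t{s.n_surviving}\t"
                    f"{json.dumps(s.parameters, sort_keys=True)}\n"
                )


def _make_entry(stage: str, params: dict, ts: Sequence[TranscriptModel],
                keep: Callable[[TranscriptModel], bool]
                ) -> tuple[list[TranscriptModel], StageEntry]:
    survivors, removed = [], []
    for t in ts:
        (survivors if keep(t) else removed).append(t)
    entry = StageEntry(
        stage=stage,
        parameters=params,
        n_input=len(ts),
        n_removed=len(removed),
        n_surviving=len(survivors),
        removed_ids=tuple(t.transcript_id for t in removed),
    )
    return survivors, entry


# ---------------------------------------------------------------------------
# Stage (1): size / exon-count selection


def filter_size_exons(
    ts: Sequence[TranscriptModel],
    min_exons: int = 2,
    min_length: int = 200,
) -> tuple[list[TranscriptModel], StageEntry]:
    """Remove single-exon transcripts and transcripts shorter than 200 nt.

    "Shorter than" is strict: a 200-nt transcript survives.
    """
    return _make_entry(
        "size_exons",
        {"min_exons": min_exons, "min_mature_length": min_length},
        ts,
        lambda t: t.exon_count >= min_exons and t.mature_length >= min_length,
    )


# ---------------------------------------------------------------------------
# Stage (2): overlap with protein-coding gene loci


def _span_tree(intervals: Iterable[Interval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    return trees


def filter_coding_overlap(
    ts: Sequence[TranscriptModel],
    protein_gene_loci: Sequence[GeneLocus],
    exon_level: bool = False,
    protein_exons: Optional[Sequence[Interval]] = None,
) -> tuple[list[TranscriptModel], StageEntry]:
    """Remove transcripts whose genomic span shares >=1 base with a protein gene.

    Overlap is strand-agnostic and evaluated between the transcript's
    genomic span and each gene's locus extent.  With ``exon_level=True``
    the comparison is transcript exons vs annotated protein exons
    (``protein_exons`` required).
    """
    if exon_level:
        if protein_exons is None:
            raise LincseekError("exon_level overlap requires protein_exons")
        trees = _span_tree(protein_exons)

        def keep(t: TranscriptModel) -> bool:
            tree = trees.get(t.chrom)
            if tree is None:
                return True
            return not any(tree.overlap(e.start, e.end) for e in t.exons)

    else:
        trees = _span_tree(l.span for l in protein_gene_loci)

        def keep(t: TranscriptModel) -> bool:
            tree = trees.get(t.chrom)
            if tree is None:
                return True
            span = t.span
            return not tree.overlap(span.start, span.end)

    return _make_entry(
        "coding_gene_overlap",
        {"min_overlap_bp": 1, "exon_level": exon_level},
        ts,
        keep,
    )


# ---------------------------------------------------------------------------
# Stage (3): coding potential


@dataclass(frozen=True)
class CodingPotentialScore:
    """Per-strand coding score from ORF length and coverage.

    For each strand, with L the longest ORF in codons and C the ORF's nt
    length divided by the mature length:

        s = min(L, 300) / 300 + C - 1

    A full-length ORF scores about +1; an ORF-free sequence scores -1.
    A transcript is called coding when max(s+, s-) > 0 (strictly).
    """

    score_plus: float
    score_minus: float
    orf_codons_plus: int
    orf_codons_minus: int
    orf_coverage_plus: float
    orf_coverage_minus: float

    @property
    def max_score(self) -> float:
        return max(self.score_plus, self.score_minus)

    @property
    def is_coding(self) -> bool:
        return self.max_score > 0.0


def score_coding_potential(seq: str) -> CodingPotentialScore:
    """Score the coding potential of a mature sequence on both strands."""
    if len(seq) < 3:
        raise ValueError("sequence shorter than one codon")
    bad = set(seq.upper()) - set("ACGTN")
    if bad:
        raise ValueError(f"non-DNA symbols in sequence: {sorted(bad)}")
    seq = seq.upper()
    per_strand = {}
    for strand in "+-":
        spans = scan_orfs(seq, strands=strand)
        best = max(spans, key=lambda o: o.n_codons, default=None)
        L = best.n_codons if best else 0
        C = (3 * L) / len(seq)
        per_strand[strand] = (min(L, 300) / 300 + C - 1.0, L, C)
    (sp, lp, cp), (sm, lm, cm) = per_strand["+"], per_strand["-"]
    return CodingPotentialScore(
        score_plus=sp, score_minus=sm,
        orf_codons_plus=lp, orf_codons_minus=lm,
        orf_coverage_plus=cp, orf_coverage_minus=cm,
    )


def filter_coding_potential(
    ts: Sequence[TranscriptModel],
    genome: Optional[GenomeSequence] = None,
    score_table: Optional[Mapping[str, float]] = None,
) -> tuple[list[TranscriptModel], StageEntry]:
    """Remove transcripts with coding score > 0 on either strand (strict).

    Scores come from the built-in scorer applied to the mature sequence
    (``genome`` required), or from an external score table keyed by
    transcript id (e.g. CPC output), which takes precedence when given.
    """
    if ts and score_table is None and genome is None:
        raise LincseekError("need a genome or an external score table")

    def max_score(t: TranscriptModel) -> float:
        if score_table is not None:
            if t.transcript_id not in score_table:
                raise LincseekError(
                    f"external score table lacks transcript {t.transcript_id!r}"
                )
            return float(score_table[t.transcript_id])
        return score_coding_potential(extract_sequence(t, genome)).max_score

    return _make_entry(
        "coding_potential",
        {"threshold": 0.0,
         "mode": "external_table" if score_table is not None else "builtin"},
        ts,
        lambda t: max_score(t) <= 0.0,
    )


# ---------------------------------------------------------------------------
# Stages (4)-(6): hit-table filters


def _ids_hit(hits: Iterable[HitRecord], pred) -> set[str]:
    return {h.query_id for h in hits if pred(h)}


def filter_protein_similarity(
    ts: Sequence[TranscriptModel],
    hits: Sequence[HitRecord],
    e_max: float = 1e-5,
) -> tuple[list[TranscriptModel], StageEntry]:
    """Remove transcripts with a known-protein hit at E <= e_max (inclusive)."""
    flagged = _ids_hit(hits, lambda h: h.source_kind == "protein"
                       and h.e_value <= e_max)
    return _make_entry(
        "protein_similarity",
        {"e_max": e_max},
        ts,
        lambda t: t.transcript_id not in flagged,
    )


def filter_domain_hits(
    ts: Sequence[TranscriptModel],
    hits: Sequence[HitRecord],
    e_max: float = 1e-5,
) -> tuple[list[TranscriptModel], StageEntry]:
    """Remove transcripts with a protein-domain hit at E <= e_max in any frame."""
    flagged = _ids_hit(hits, lambda h: h.source_kind == "domain"
                       and h.e_value <= e_max)
    return _make_entry(
        "domain_hits",
        {"e_max": e_max},
        ts,
        lambda t: t.transcript_id not in flagged,
    )


def filter_rna_families(
    ts: Sequence[TranscriptModel],
    hits: Sequence[HitRecord],
    small_rna_classes: frozenset[str] = DEFAULT_SMALL_RNA_CLASSES,
) -> tuple[list[TranscriptModel], StageEntry]:
    """Remove transcripts assigned to a known small-RNA family class."""
    flagged = _ids_hit(
        hits,
        lambda h: h.source_kind == "rna_family"
        and h.family_class in small_rna_classes,
    )
    return _make_entry(
        "small_rna_families",
        {"classes": sorted(small_rna_classes)},
        ts,
        lambda t: t.transcript_id not in flagged,
    )


# ---------------------------------------------------------------------------
# Stage (7): UTR coverage


def _merge_intervals(ivs: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    if not ivs:
        return []
    ivs = sorted(ivs)
    merged = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [tuple(x) for x in merged]


def utr_coverage_fraction(
    t: TranscriptModel, utr_by_chrom: Mapping[str, list[tuple[int, int]]]
) -> float:
    """Fraction of mature (exonic) bases covered by the UTR interval union."""
    merged = utr_by_chrom.get(t.chrom, [])
    covered = 0
    for exon in t.exons:
        for s, e in merged:
            if e <= exon.start:
                continue
            if s >= exon.end:
                break
            covered += min(e, exon.end) - max(s, exon.start)
    return covered / t.mature_length


def filter_utr_overlap(
    ts: Sequence[TranscriptModel],
    utr_intervals: Sequence[Interval],
    max_fraction: float = 0.9,
) -> tuple[list[TranscriptModel], StageEntry]:
    """Discard transcripts with more than 90% of their length in UTR regions.

    Strictly "more than": a transcript exactly 90% covered survives.
    Coverage is computed on genomic coordinates against the union of
    annotated UTR intervals, over exonic bases only.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in utr_intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    merged = {c: _merge_intervals(v) for c, v in by_chrom.items()}
    return _make_entry(
        "utr_overlap",
        {"max_fraction": max_fraction},
        ts,
        lambda t: utr_coverage_fraction(t, merged) <= max_fraction,
    )


# ---------------------------------------------------------------------------
# Whole cascade


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds of the cascade; defaults are the published values."""

    min_exons: int = 2
    min_mature_length: int = 200
    protein_e_max: float = 1e-5
    domain_e_max: float = 1e-5
    small_rna_classes: frozenset[str] = DEFAULT_SMALL_RNA_CLASSES
    utr_max_fraction: float = 0.9
    exon_level_overlap: bool = False


@dataclass
class PipelineInputs:
    """Reference data consumed by the cascade."""

    protein_gene_loci: Sequence[GeneLocus]
    utr_intervals: Sequence[Interval]
    protein_hits: Sequence[HitRecord] = ()
    domain_hits: Sequence[HitRecord] = ()
    rfam_hits: Sequence[HitRecord] = ()
    cpc_scores: Optional[Mapping[str, float]] = None
    protein_exons: Optional[Sequence[Interval]] = None


@dataclass
class PipelineResult:
    lincrnas: list[TranscriptModel]
    loci: list[GeneLocus]
    report: FilterReport


def run_pipeline(
    ts: Sequence[TranscriptModel],
    genome: Optional[GenomeSequence],
    inputs: PipelineInputs,
    config: Optional[PipelineConfig] = None,
) -> PipelineResult:
    """Run stages (1)-(7) in order and group survivors into lincRNA loci."""
    cfg = config or PipelineConfig()
    report = FilterReport()

    cur, entry = filter_size_exons(ts, cfg.min_exons, cfg.min_mature_length)
    report.add(entry)
    cur, entry = filter_coding_overlap(
        cur, inputs.protein_gene_loci,
        exon_level=cfg.exon_level_overlap, protein_exons=inputs.protein_exons,
    )
    report.add(entry)
    cur, entry = filter_coding_potential(cur, genome, inputs.cpc_scores)
    report.add(entry)
    cur, entry = filter_protein_similarity(cur, inputs.protein_hits,
                                           cfg.protein_e_max)
    report.add(entry)
    cur, entry = filter_domain_hits(cur, inputs.domain_hits, cfg.domain_e_max)
    report.add(entry)
    cur, entry = filter_rna_families(cur, inputs.rfam_hits,
                                     cfg.small_rna_classes)
    report.add(entry)
    cur, entry = filter_utr_overlap(cur, inputs.utr_intervals,
                                    cfg.utr_max_fraction)
    report.add(entry)

    return PipelineResult(
        lincrnas=cur,
        loci=build_gene_loci(cur) if cur else [],
        report=report,
    )


# ---------------------------------------------------------------------------
# Protein-coding transcript classification (companion analysis)


def classify_protein_coding(
    ts: Sequence[TranscriptModel],
    reference_mrna_lengths: Mapping[str, int],
    alignments: Sequence[HitRecord],
    min_identity: float = 96.0,
    min_coverage: float = 0.9,
) -> set[str]:
    """Transcript ids classified protein-coding by similarity to reference mRNAs.

    A multi-exon transcript is coding when some nucleotide alignment to a
    reference mRNA has percent identity >= 96 and alignment length >= 90%
    of that mRNA's length (both inclusive).
    """
    multi = {t.transcript_id for t in ts if t.exon_count >= 2}
    coding: set[str] = set()
    for h in alignments:
        if h.query_id not in multi:
            continue
        if h.subject_id not in reference_mrna_lengths:
            raise LincseekError(
                f"reference mRNA {h.subject_id!r} missing from length map"
            )
        ref_len = reference_mrna_lengths[h.subject_id]
        if (h.percent_identity >= min_identity
                and h.alignment_length / ref_len >= min_coverage):
            coding.add(h.query_id)
    return coding
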