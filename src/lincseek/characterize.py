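"""Structural, repeat-content and neighborhood characterization of a
transcript set (typically the lincRNAs surviving the cascade)."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from intervaltree import IntervalTree

from .model import (
    GeneLocus,
    GenomeSequence,
    Interval,
    RepeatFeature,
    TranscriptModel,
    build_gene_loci,
)
from .io import splice_site_dinucleotides


@dataclass(frozen=True)
class StructureSummary:
    """Transcript-level structural statistics."""

    n_transcripts: int
    n_loci: int
    isoforms_per_locus: float
    mean_length: float          # mature nt
    min_length: int
    max_length: int
    mean_exons: float
    mean_exon_length: float     # pooled over all exons
    fraction_two_exon: float
    fraction_canonical_splice: Optional[float]
    per_chromosome: dict[str, int] = field(default_factory=dict)


def transcript_stats(
    ts: Sequence[TranscriptModel],
    genome: Optional[GenomeSequence] = None,
) -> StructureSummary:
    """Structural summary of a transcript set.

    The splice-site fraction needs the genome; without one it is None.
    """
    if not ts:
        raise ValueError("transcript set is empty")
    lengths = [t.mature_length for t in ts]
    exon_counts = [t.exon_count for t in ts]
    exon_lengths = [e.length for t in ts for e in t.exons]
    loci = build_gene_loci(ts)
    per_chrom: dict[str, int] = {}
    for t in ts:
        per_chrom[t.chrom] = per_chrom.get(t.chrom, 0) + 1
    frac_canonical = None
    if genome is not None:
        multi = [t for t in ts if t.exon_count >= 2]
        if multi:
            frac_canonical = splice_site_summary(multi, genome)
    return StructureSummary(
        n_transcripts=len(ts),
        n_loci=len(loci),
        isoforms_per_locus=len(ts) / len(loci),
        mean_length=float(np.mean(lengths)),
        min_length=int(min(lengths)),
        max_length=int(max(lengths)),
        mean_exons=float(np.mean(exon_counts)),
        mean_exon_length=float(np.mean(exon_lengths)),
        fraction_two_exon=sum(c == 2 for c in exon_counts) / len(ts),
        fraction_canonical_splice=frac_canonical,
        per_chromosome=per_chrom,
    )


def exon_length_histogram(
    ts: Sequence[TranscriptModel], bin_edges: Sequence[float]
) -> np.ndarray:
    """Exon counts per half-open bin [e_i, e_{i+1}).

    Every exon must fall inside the edge range; the total equals the
    pooled exon count.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be ascending with >= 2 entries")
    lengths = np.array([e.length for t in ts for e in t.exons], dtype=float)
    counts = np.zeros(edges.size - 1, dtype=int)
    if lengths.size == 0:
        return counts
    if lengths.min() < edges[0] or lengths.max() >= edges[-1]:
        raise ValueError("exon length outside histogram range")
    idx = np.searchsorted(edges, lengths, side="right") - 1
    for i in idx:
        counts[i] += 1
    return counts


@dataclass(frozen=True)
class RepeatSummary:
    """Repeat-element content over a transcript set.

    Coverage is computed on exonic (mature) coordinates against the
    union of repeat intervals; family percentages count each repeat
    feature that touches any exon, over the total touched-feature count.
    The content histogram has ten bins [0,10), [10,20) ... [90,100] in
    percent; repeat-free transcripts sit in the first bin.
    """

    n_transcripts: int
    n_with_repeat: int
    fraction_with_repeat: float
    fraction_ge_half_repeat: float
    mean_repeat_fragment_bp: float      # mean covered bp per repeat-bearing transcript
    mean_transcript_length_of_repeat_bearing: float
    mean_repeat_content_fraction: float  # ratio of the two means above
    family_percentages: dict[str, float]
    content_histogram: np.ndarray
    per_transcript_fraction: dict[str, float]


def _repeat_trees(repeats: Sequence[RepeatFeature]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for i, r in enumerate(repeats):
        trees.setdefault(r.interval.chrom, IntervalTree()).addi(
            r.interval.start, r.interval.end, i
        )
    return trees


def repeat_covered_bases(t: TranscriptModel,
                         trees: dict[str, IntervalTree]) -> int:
    """Exonic bases of *t* covered by the union of repeat intervals."""
    tree = trees.get(t.chrom)
    if tree is None:
        return 0
    covered = 0
    for exon in t.exons:
        pieces = sorted(
            (max(iv.begin, exon.start), min(iv.end, exon.end))
            for iv in tree.overlap(exon.start, exon.end)
        )
        last_end = exon.start
        for s, e in pieces:
            s = max(s, last_end)
            if e > s:
                covered += e - s
                last_end = e
    return covered


def repeat_content(
    ts: Sequence[TranscriptModel], repeats: Sequence[RepeatFeature]
) -> RepeatSummary:
    if not ts:
        raise ValueError("transcript set is empty")
    trees = _repeat_trees(repeats)
    fractions: dict[str, float] = {}
    covered_bp: dict[str, int] = {}
    touched_features: set[int] = set()
    for t in ts:
        cov = repeat_covered_bases(t, trees)
        covered_bp[t.transcript_id] = cov
        fractions[t.transcript_id] = cov / t.mature_length
        tree = trees.get(t.chrom)
        if tree is not None:
            for exon in t.exons:
                for iv in tree.overlap(exon.start, exon.end):
                    touched_features.add(iv.data)
    bearing = [tid for tid, c in covered_bp.items() if c > 0]
    lengths = {t.transcript_id: t.mature_length for t in ts}
    fam_counts: dict[str, int] = {}
    for i in touched_features:
        fam = repeats[i].repeat_family
        fam_counts[fam] = fam_counts.get(fam, 0) + 1
    total_feats = sum(fam_counts.values())
    fam_pct = {
        f: 100.0 * c / total_feats for f, c in sorted(fam_counts.items())
    } if total_feats else {}
    hist = np.zeros(10, dtype=int)
    for tid, frac in fractions.items():
        pct = 100.0 * frac
        idx = 9 if pct >= 90.0 else int(pct // 10)
        hist[idx] += 1
    mean_frag = float(np.mean([covered_bp[t] for t in bearing])) if bearing else 0.0
    mean_len = float(np.mean([lengths[t] for t in bearing])) if bearing else 0.0
    return RepeatSummary(
        n_transcripts=len(ts),
        n_with_repeat=len(bearing),
        fraction_with_repeat=len(bearing) / len(ts),
        fraction_ge_half_repeat=sum(
            f >= 0.5 for f in fractions.values()) / len(ts),
        mean_repeat_fragment_bp=mean_frag,
        mean_transcript_length_of_repeat_bearing=mean_len,
        mean_repeat_content_fraction=(mean_frag / mean_len) if mean_len else 0.0,
        family_percentages=fam_pct,
        content_histogram=hist,
        per_transcript_fraction=fractions,
    )


@dataclass(frozen=True)
class Neighbor:
    gene_id: str
    distance: int  # gap in bp between locus spans, > 0


@dataclass(frozen=True)
class NeighborAssignment:
    """Nearest non-overlapping protein-coding neighbors per lincRNA locus."""

    window: int
    upstream: dict[str, Neighbor]    # lincRNA gene_id -> left neighbor
    downstream: dict[str, Neighbor]  # lincRNA gene_id -> right neighbor
    neighbor_genes: tuple[str, ...]  # pooled, deduplicated
    n_with_neighbor: int
    fraction_with_neighbor: float


def neighbor_analysis(
    linc_loci: Sequence[GeneLocus],
    protein_loci: Sequence[GeneLocus],
    window: int = 10_000,
) -> NeighborAssignment:
    """Nearest upstream/downstream protein locus within the window, per
    lincRNA locus.

    Upstream/downstream are genomic left/right (strand-ignored, since
    assembled lincRNAs may be unstranded).  Overlapping protein loci are
    excluded, as are adjacent loci with zero gap; the window bound is
    strict (a gap of exactly *window* bp does not qualify).
    """
    by_chrom: dict[str, list[GeneLocus]] = {}
    for p in protein_loci:
        by_chrom.setdefault(p.span.chrom, []).append(p)
    for v in by_chrom.values():
        v.sort(key=lambda l: l.span.start)
    upstream: dict[str, Neighbor] = {}
    downstream: dict[str, Neighbor] = {}
    pooled: set[str] = set()
    n_with = 0
    for locus in linc_loci:
        span = locus.span
        best_left = best_right = None
        for p in by_chrom.get(span.chrom, []):
            if p.span.overlap_bp(span) > 0:
                continue
            if p.span.end <= span.start:
                gap = span.start - p.span.end
                if 0 < gap < window and (
                    best_left is None or gap < best_left.distance
                ):
                    best_left = Neighbor(p.gene_id, gap)
            elif p.span.start >= span.end:
                gap = p.span.start - span.end
                if 0 < gap < window and (
                    best_right is None or gap < best_right.distance
                ):
                    best_right = Neighbor(p.gene_id, gap)
        if best_left:
            upstream[locus.gene_id] = best_left
            pooled.add(best_left.gene_id)
        if best_right:
            downstream[locus.gene_id] = best_right
            pooled.add(best_right.gene_id)
        if best_left or best_right:
            n_with += 1
    return NeighborAssignment(
        window=window,
        upstream=upstream,
        downstream=downstream,
        neighbor_genes=tuple(sorted(pooled)),
        n_with_neighbor=n_with,
        fraction_with_neighbor=n_with / len(linc_loci) if linc_loci else 0.0,
    )


def splice_site_summary(
    ts: Sequence[TranscriptModel], genome: GenomeSequence
) -> float:
    """Fraction of introns with canonical (GT, AG) donor/acceptor pairs."""
    n_introns = 0
    n_canonical = 0
    for t in ts:
        if t.exon_count < 2:
            continue
        for donor, acceptor in splice_site_dinucleotides(t, genome):
            n_introns += 1
            if (donor, acceptor) == ("GT", "AG"):
                n_canonical += 1
    if n_introns == 0:
        raise ValueError("no introns in transcript set")
    return n_canonical / n_introns
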