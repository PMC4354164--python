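"""Cross-species conservation analysis.

A desk-scale seed-and-extend nucleotide homology searcher (exact 11-mer
seeds, ungapped X-drop extension, Karlin-Altschul E-values with fixed
parameters for +1/-2 scoring), intron-exon boundary conservation flags,
chain-based positional remapping in the liftOver style (minimum ratio of
bases that must remap, inclusive), and reciprocal locus-overlap
counting.  Agreement of E-values with NCBI BLASTN is a non-goal; the
contract is threshold behaviour at E <= 1e-5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .model import ChainMapping, GeneLocus, Interval, TranscriptModel

KARLIN_LAMBDA = 1.28
KARLIN_K = 0.46


@dataclass(frozen=True)
class HomologySegment:
    """An ungapped homologous segment between two mature transcript sequences.

    Coordinates are 1-based inclusive on each mature sequence.
    """

    query_id: str
    subject_id: str
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    percent_identity: float
    score: int
    e_value: float

    @property
    def length(self) -> int:
        return self.query_end - self.query_start + 1


def _extend(q: str, s: str, qi: int, si: int, word: int,
            match: int, mismatch: int, xdrop: int) -> tuple[int, int, int, int]:
    """Ungapped X-drop extension around an exact seed at (qi, si).

    Returns (qstart, qend_exclusive, score, matches) in 0-based query
    coordinates; the subject range follows the same diagonal.
    """
    score = word * match
    matches = word
    best_score, best_matches = score, matches
    # right
    i, j = qi + word, si + word
    cur, cur_m = score, matches
    best_right = 0
    r = 0
    while i < len(q) and j < len(s):
        cur += match if q[i] == s[j] else mismatch
        cur_m += 1 if q[i] == s[j] else 0
        r += 1
        if cur > best_score:
            best_score, best_matches, best_right = cur, cur_m, r
        if best_score - cur > xdrop:
            break
        i += 1
        j += 1
    # left
    i, j = qi - 1, si - 1
    cur, cur_m = best_score, best_matches
    best_left = 0
    l = 0
    while i >= 0 and j >= 0:
        cur += match if q[i] == s[j] else mismatch
        cur_m += 1 if q[i] == s[j] else 0
        l += 1
        if cur > best_score:
            best_score, best_matches, best_left = cur, cur_m, l
        if best_score - cur > xdrop:
            break
        i -= 1
        j -= 1
    qstart = qi - best_left
    qend = qi + word + best_right
    return qstart, qend, best_score, best_matches


def homology_search(
    queries: Mapping[str, str],
    subjects: Mapping[str, str],
    e_max: float = 1e-5,
    word_size: int = 11,
    match: int = 1,
    mismatch: int = -2,
    xdrop: int = 20,
) -> list[HomologySegment]:
    """Seed-and-extend homology search of query vs subject sequences.

    E = K * m * n * exp(-lambda * S) with m the query length and n the
    summed subject length; segments with E <= e_max are reported, best
    first per (query, subject) pair.  An external BLAST outfmt-6 table
    read through :func:`lincseek.io.read_hits_table` is an accepted
    drop-in wherever these segments are consumed.
    """
    if not queries or not subjects:
        return []
    index: dict[str, list[tuple[str, int]]] = {}
    total_n = 0
    for sid, sseq in subjects.items():
        sseq = sseq.upper()
        total_n += len(sseq)
        for i in range(len(sseq) - word_size + 1):
            index.setdefault(sseq[i:i + word_size], []).append((sid, i))
    out: list[HomologySegment] = []
    for qid, qseq in queries.items():
        qseq = qseq.upper()
        m = len(qseq)
        found: dict[str, list[tuple[int, int, int]]] = {}  # sid -> (diag,qs,qe)
        for qi in range(m - word_size + 1):
            seed = qseq[qi:qi + word_size]
            for sid, si in index.get(seed, ()):  # exact seeds only
                diag = qi - si
                if any(d == diag and qs <= qi < qe
                       for d, qs, qe in found.get(sid, ())):
                    continue
                sseq = subjects[sid].upper()
                qs, qe, score, matches = _extend(
                    qseq, sseq, qi, si, word_size, match, mismatch, xdrop
                )
                e_value = KARLIN_K * m * total_n * math.exp(
                    -KARLIN_LAMBDA * score
                )
                found.setdefault(sid, []).append((diag, qs, qe))
                if e_value <= e_max:
                    ss = qs - diag
                    out.append(
                        HomologySegment(
                            query_id=qid, subject_id=sid,
                            query_start=qs + 1, query_end=qe,
                            subject_start=ss + 1, subject_end=ss + (qe - qs),
                            percent_identity=100.0 * matches / (qe - qs),
                            score=score, e_value=e_value,
                        )
                    )
    # deduplicate identical segments found from different seeds
    seen = set()
    unique = []
    for seg in sorted(out, key=lambda g: (g.query_id, g.subject_id,
                                          g.e_value, g.query_start)):
        key = (seg.query_id, seg.subject_id, seg.query_start, seg.query_end,
               seg.subject_start)
        if key not in seen:
            seen.add(key)
            unique.append(seg)
    return unique


def boundary_conservation(
    seg: HomologySegment, t: TranscriptModel, tolerance: int = 0
) -> tuple[str, str]:
    """Flag each segment end as at an intron-exon boundary or internal.

    Junction positions live in mature coordinates: after exon i the
    junction sits between mature positions c and c+1 where c is the
    cumulative exon length.  An end within *tolerance* of either side of
    a junction is 'at_boundary'.
    """
    if not (1 <= seg.query_start <= seg.query_end <= t.mature_length):
        raise ValueError(
            f"segment [{seg.query_start},{seg.query_end}] outside transcript "
            f"of mature length {t.mature_length}"
        )
    junctions = []
    c = 0
    for e in t.exons[:-1]:
        c += e.length
        junctions.append(c)

    def flag(pos: int) -> str:
        for c in junctions:
            if min(abs(pos - c), abs(pos - (c + 1))) <= tolerance:
                return "at_boundary"
        return "internal"

    return flag(seg.query_start), flag(seg.query_end)


@dataclass(frozen=True)
class LiftResult:
    """Outcome of remapping one interval through a chain set."""

    source: Interval
    mapped: Optional[Interval]
    mapped_base_ratio: float
    success: bool
    reason: str = ""


def liftover_map(
    iv: Interval,
    chains: ChainMapping | Sequence[ChainMapping],
    min_ratio: float = 0.5,
) -> LiftResult:
    """Remap *iv* base-by-base through the chain(s).

    Success requires the fraction of source bases with an image to reach
    *min_ratio* (inclusive, matching liftOver's minimum-remap semantics)
    and all images to fall on one target chromosome and orientation; the
    mapped interval is the hull [min image, max image + 1).  A source
    chromosome absent from every chain yields a failure result, not an
    exception.
    """
    chain_list = [chains] if isinstance(chains, ChainMapping) else list(chains)
    # block-interval arithmetic; earlier chains win where chains overlap
    covered: list[tuple[int, int]] = []  # mapped source sub-intervals, disjoint
    hulls: dict[tuple[str, str], tuple[int, int]] = {}
    n_mapped = 0
    for chain in chain_list:
        if chain.source_chrom != iv.chrom:
            continue
        for src, tgt in chain.blocks:
            lo = max(src.start, iv.start)
            hi = min(src.end, iv.end)
            if lo >= hi:
                continue
            # subtract already-covered source ranges
            fresh = [(lo, hi)]
            for cs, ce in covered:
                nxt = []
                for s, e in fresh:
                    if ce <= s or cs >= e:
                        nxt.append((s, e))
                    else:
                        if s < cs:
                            nxt.append((s, cs))
                        if ce < e:
                            nxt.append((ce, e))
                fresh = nxt
            for s, e in fresh:
                covered.append((s, e))
                n_mapped += e - s
                if chain.orientation == "+":
                    t_lo = tgt.start + (s - src.start)
                    t_hi = tgt.start + (e - src.start)
                else:
                    t_lo = tgt.end - (e - src.start)
                    t_hi = tgt.end - (s - src.start)
                key = (chain.target_chrom, chain.orientation)
                if key in hulls:
                    a, b = hulls[key]
                    hulls[key] = (min(a, t_lo), max(b, t_hi))
                else:
                    hulls[key] = (t_lo, t_hi)
    ratio = n_mapped / iv.length
    if not hulls:
        return LiftResult(iv, None, 0.0, False, "no bases remap")
    if ratio < min_ratio:
        return LiftResult(iv, None, ratio, False,
                          f"mapped ratio {ratio:.3f} < {min_ratio}")
    if len(hulls) > 1:
        return LiftResult(iv, None, ratio, False,
                          "images split across chromosomes/orientations")
    (tchrom, _orient), (t_lo, t_hi) = next(iter(hulls.items()))
    mapped = Interval(tchrom, t_lo, t_hi, iv.strand)
    return LiftResult(iv, mapped, ratio, True)


def reciprocal_overlap_count(
    lifted: Mapping[str, LiftResult],
    target_loci: Sequence[GeneLocus],
    min_bp: int = 1,
) -> tuple[int, list[tuple[str, str, int]]]:
    """Count successfully lifted source loci overlapping a target locus.

    A source locus counts once if its mapped interval shares at least
    *min_bp* bases with any target locus; the pair list records every
    (source, target, overlap_bp) match.
    """
    pairs: list[tuple[str, str, int]] = []
    counted = 0
    for source_id in sorted(lifted):
        res = lifted[source_id]
        if not res.success or res.mapped is None:
            continue
        any_hit = False
        for locus in target_loci:
            ov = res.mapped.overlap_bp(locus.span)
            if ov >= min_bp:
                pairs.append((source_id, locus.gene_id, ov))
                any_hit = True
        if any_hit:
            counted += 1
    return counted, pairs
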