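"""Homology search, boundary conservation, liftover and overlap counting."""

import numpy as np
import pytest

from lincseek.conserve import (
    HomologySegment,
    boundary_conservation,
    homology_search,
    liftover_map,
    reciprocal_overlap_count,
)
from lincseek.model import ChainMapping, GeneLocus, Interval
from conftest import make_transcript


def random_dna(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


class TestHomologySearch:
    def test_self_match_covers_nearly_everything(self, rng):
        seq = random_dna(rng, 500)
        segs = homology_search({"q": seq}, {"s": seq})
        assert segs
        best = max(segs, key=lambda s: s.score)
        assert best.length >= 490
        assert best.percent_identity == 100.0
        assert best.e_value < 1e-50

    def test_no_shared_word_means_no_hits(self):
        assert homology_search({"q": "A" * 60}, {"s": "C" * 60}) == []

    def test_empty_query_set(self):
        assert homology_search({}, {"s": "ACGTACGTACGT"}) == []

    def test_role_swap_symmetry_on_exact_match(self, rng):
        seq = random_dna(rng, 300)
        fwd = homology_search({"q": seq}, {"s": seq})
        rev = homology_search({"s": seq}, {"q": seq})
        b_f = max(fwd, key=lambda s: s.score)
        b_r = max(rev, key=lambda s: s.score)
        assert (b_f.query_start, b_f.query_end) == (b_r.subject_start,
                                                    b_r.subject_end)
        assert b_f.score == b_r.score

    def test_evalue_monotone_in_score(self, rng):
        seq = random_dna(rng, 400)
        # second subject shares only a 60 nt window: lower score, higher E
        partial = random_dna(rng, 170) + seq[100:160] + random_dna(rng, 170)
        segs = homology_search({"q": seq}, {"full": seq, "part": partial},
                               e_max=1.0)
        by_subject = {}
        for s in segs:
            if (s.subject_id not in by_subject
                    or s.score > by_subject[s.subject_id].score):
                by_subject[s.subject_id] = s
        assert by_subject["full"].score > by_subject["part"].score
        assert by_subject["full"].e_value < by_subject["part"].e_value

    def test_planted_ortholog_pairs_all_recovered(self, dataset):
        from lincseek.io import extract_sequence

        orth = dataset.ortholog
        queries = {
            t.transcript_id: extract_sequence(t, dataset.genome)
            for t in dataset.transcripts_of("lincRNA")
        }
        subjects = {
            t.transcript_id: extract_sequence(t, orth.genome)
            for t in orth.transcripts
        }
        segs = homology_search(queries, subjects)
        hit_pairs = {(s.query_id, s.subject_id) for s in segs}
        assert all(pair in hit_pairs for pair in orth.pairs)


class TestBoundaryConservation:
    def seg(self, qs, qe):
        return HomologySegment("q", "s", qs, qe, qs, qe, 100.0, qe - qs + 1,
                               1e-9)

    def test_start_at_junction(self):
        t = make_transcript(exons=((0, 300), (400, 800)))  # junction at 300
        flags = boundary_conservation(self.seg(301, 700), t)
        assert flags == ("at_boundary", "internal")

    def test_fully_internal(self):
        t = make_transcript(exons=((0, 300), (400, 800)))
        assert boundary_conservation(self.seg(10, 250), t) == (
            "internal", "internal"
        )

    def test_tolerance_window(self):
        t = make_transcript(exons=((0, 300), (400, 800)))
        assert boundary_conservation(self.seg(303, 700), t)[0] == "internal"
        assert boundary_conservation(
            self.seg(303, 700), t, tolerance=5
        )[0] == "at_boundary"

    def test_segment_outside_transcript_errors(self):
        t = make_transcript(exons=((0, 100),))
        with pytest.raises(ValueError):
            boundary_conservation(self.seg(50, 200), t)


def identity_chain(chrom="chr1", size=10_000, gaps=()):
    """Identity chain over [0, size) with the given source gaps removed."""
    blocks = []
    pos = 0
    for lo, hi in sorted(gaps):
        if lo > pos:
            blocks.append((Interval(chrom, pos, lo), Interval(chrom, pos, lo)))
        pos = hi
    if pos < size:
        blocks.append((Interval(chrom, pos, size), Interval(chrom, pos, size)))
    return ChainMapping("c", chrom, chrom, "+", tuple(blocks),
                        source_size=size, target_size=size)


def brute_force_lift(iv, chains, min_ratio):
    """Per-base oracle: map every source base through ChainMapping.map_base."""
    images = {}
    for pos in range(iv.start, iv.end):
        for chain in chains:
            if chain.source_chrom != iv.chrom:
                continue
            img = chain.map_base(pos)
            if img is not None:
                key = (chain.target_chrom, chain.orientation)
                images.setdefault(key, {})[pos] = img
                break
    n_mapped = sum(len(v) for v in images.values())
    ratio = n_mapped / iv.length
    if not images or ratio < min_ratio or len(images) > 1:
        return None, ratio
    (tchrom, _), mapping = next(iter(images.items()))
    vals = list(mapping.values())
    return Interval(tchrom, min(vals), max(vals) + 1, iv.strand), ratio


class TestLiftover:
    def test_identity_chain_is_identity(self):
        res = liftover_map(Interval("chr1", 100, 200), identity_chain())
        assert res.success
        assert res.mapped == Interval("chr1", 100, 200)
        assert res.mapped_base_ratio == 1.0

    def test_half_deleted_succeeds_at_inclusive_bound(self):
        chain = identity_chain(gaps=[(0, 150)])
        res = liftover_map(Interval("chr1", 100, 200), chain, min_ratio=0.5)
        assert res.success and res.mapped_base_ratio == 0.5
        res = liftover_map(Interval("chr1", 99, 199), chain, min_ratio=0.5)
        assert not res.success  # 49/100 mapped

    def test_absent_chromosome_is_failure_not_exception(self):
        res = liftover_map(Interval("chrZ", 0, 100), identity_chain())
        assert not res.success and res.mapped is None
        assert res.mapped_base_ratio == 0.0

    def test_matches_per_base_oracle_on_random_chains(self, rng):
        """Block arithmetic equals the per-base mapper over random
        fragmented chains, both orientations."""
        for _ in range(500):
            size = 400
            orientation = "+" if rng.integers(0, 2) else "-"
            blocks = []
            pos = 0
            tpos = int(rng.integers(0, 50))
            while pos < size - 20:
                bl = int(rng.integers(5, 40))
                if rng.random() < 0.75:
                    if orientation == "+":
                        blocks.append(
                            (Interval("a", pos, pos + bl),
                             Interval("b", tpos, tpos + bl))
                        )
                        tpos += bl + int(rng.integers(0, 10))
                    else:
                        blocks.append(
                            (Interval("a", pos, pos + bl),
                             Interval("b", 1000 - tpos - bl, 1000 - tpos))
                        )
                        tpos += bl + int(rng.integers(0, 10))
                pos += bl + int(rng.integers(0, 15))
            if not blocks:
                continue
            chain = ChainMapping("c", "a", "b", orientation, tuple(blocks),
                                 source_size=size, target_size=1000)
            a = int(rng.integers(0, size - 2))
            iv = Interval("a", a, a + int(rng.integers(1, 60)))
            res = liftover_map(iv, chain, min_ratio=0.5)
            expect, ratio = brute_force_lift(iv, [chain], 0.5)
            assert res.mapped_base_ratio == pytest.approx(ratio)
            assert res.mapped == expect

    def test_round_trip_through_inverse(self, rng):
        chain = identity_chain(gaps=[(2000, 2500), (7000, 7100)])
        inv = chain.invert()
        for _ in range(50):
            a = int(rng.integers(0, 9_900))
            iv = Interval("chr1", a, a + int(rng.integers(1, 100)))
            fwd = liftover_map(iv, chain, min_ratio=1.0)
            if not fwd.success or fwd.mapped_base_ratio < 1.0:
                continue
            back = liftover_map(fwd.mapped, inv, min_ratio=1.0)
            assert back.success and back.mapped == iv


class TestReciprocalOverlap:
    def lift(self, iv):
        return liftover_map(iv, identity_chain())

    def test_single_base_overlap_counts(self):
        lifted = {"L1": self.lift(Interval("chr1", 100, 200))}
        targets = [GeneLocus("T1", ("T1",), Interval("chr1", 199, 300))]
        count, pairs = reciprocal_overlap_count(lifted, targets, min_bp=1)
        assert count == 1 and pairs == [("L1", "T1", 1)]

    def test_disjoint_not_counted(self):
        lifted = {"L1": self.lift(Interval("chr1", 100, 200))}
        targets = [GeneLocus("T1", ("T1",), Interval("chr1", 200, 300))]
        count, pairs = reciprocal_overlap_count(lifted, targets)
        assert count == 0 and pairs == []

    def test_source_counted_once_despite_multiple_targets(self):
        lifted = {"L1": self.lift(Interval("chr1", 100, 400))}
        targets = [
            GeneLocus("T1", ("T1",), Interval("chr1", 150, 200)),
            GeneLocus("T2", ("T2",), Interval("chr1", 300, 350)),
        ]
        count, pairs = reciprocal_overlap_count(lifted, targets)
        assert count == 1 and len(pairs) == 2

    def test_matches_exhaustive_pairwise_check(self, rng):
        lifted = {}
        targets = []
        for i in range(40):
            a = int(rng.integers(0, 5000))
            lifted[f"L{i}"] = self.lift(
                Interval("chr1", a, a + int(rng.integers(10, 400)))
            )
            b = int(rng.integers(0, 5000))
            targets.append(
                GeneLocus(f"T{i}", (f"T{i}",),
                          Interval("chr1", b, b + int(rng.integers(10, 400))))
            )
        count, _ = reciprocal_overlap_count(lifted, targets)
        brute = 0
        for res in lifted.values():
            src = set(range(res.mapped.start, res.mapped.end))
            if any(src & set(range(t.span.start, t.span.end))
                   for t in targets):
                brute += 1
        assert count == brute
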