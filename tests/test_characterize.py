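"""Structural statistics, repeat content and neighbor assignment."""

import numpy as np
import pytest

from lincseek.characterize import (
    exon_length_histogram,
    neighbor_analysis,
    repeat_content,
    splice_site_summary,
    transcript_stats,
    _repeat_trees,
    repeat_covered_bases,
)
from lincseek.model import (
    GeneLocus,
    GenomeSequence,
    Interval,
    RepeatFeature,
    TranscriptModel,
    build_gene_loci,
)
from conftest import make_transcript


def single_exon(tid, gid, start, length, chrom="chr1"):
    return TranscriptModel(
        tid, gid, (Interval(chrom, start, start + length),)
    )


class TestTranscriptStats:
    def test_mean_length(self):
        ts = [single_exon("a", "ga", 0, 100), single_exon("b", "gb", 500, 300)]
        s = transcript_stats(ts)
        assert s.mean_length == 200
        assert (s.min_length, s.max_length) == (100, 300)

    def test_one_transcript_per_locus(self):
        s = transcript_stats([single_exon("a", "ga", 0, 100)])
        assert s.isoforms_per_locus == 1.0

    def test_isoform_ratio_from_published_counts(self):
        """570 transcripts over 476 loci give 1.2 isoforms per locus."""
        ts = []
        pos = 0
        for g in range(476):
            n_iso = 2 if g < 570 - 476 else 1
            for i in range(n_iso):
                ts.append(single_exon(f"t{g}_{i}", f"g{g}", pos, 50))
                pos += 60
        s = transcript_stats(ts)
        assert s.n_transcripts == 570 and s.n_loci == 476
        assert round(s.isoforms_per_locus, 1) == 1.2

    def test_fraction_two_exon_and_mean_exons(self):
        ts = [
            make_transcript("a", "ga", exons=((0, 100), (200, 300))),
            make_transcript("b", "gb", exons=((400, 500), (600, 700),
                                              (800, 900))),
        ]
        s = transcript_stats(ts)
        assert s.fraction_two_exon == 0.5
        assert s.mean_exons == 2.5

    def test_empty_input_is_error(self):
        with pytest.raises(ValueError):
            transcript_stats([])


class TestExonHistogram:
    def test_half_open_bin_assignment(self):
        t = single_exon("a", "g", 0, 200)
        counts = exon_length_histogram([t], [0, 200, 400])
        assert counts.tolist() == [0, 1]

    def test_empty_set_gives_zeros(self):
        assert exon_length_histogram([], [0, 100, 200]).tolist() == [0, 0]

    def test_total_conserved_on_fixture(self, dataset):
        n_exons = sum(t.exon_count for t in dataset.transcripts)
        counts = exon_length_histogram(
            dataset.transcripts, np.arange(0, 10_001, 100)
        )
        assert counts.sum() == n_exons


class TestRepeatContent:
    def test_repeat_free_transcript_excluded_from_bearing(self):
        t = single_exon("a", "g", 0, 100)
        s = repeat_content([t], [])
        assert s.n_with_repeat == 0
        assert s.per_transcript_fraction["a"] == 0.0
        assert s.content_histogram.tolist()[0] == 1

    def test_fully_covered_transcript_has_fraction_one(self):
        t = single_exon("a", "g", 10, 100)
        rep = RepeatFeature(Interval("chr1", 0, 500), "SINE")
        s = repeat_content([t], [rep])
        assert s.per_transcript_fraction["a"] == 1.0
        assert s.content_histogram.tolist()[9] == 1

    def test_overlapping_repeats_unioned(self):
        t = single_exon("a", "g", 0, 200)
        reps = [
            RepeatFeature(Interval("chr1", 0, 100), "SINE"),
            RepeatFeature(Interval("chr1", 50, 150), "LINE"),
        ]
        s = repeat_content([t], reps)
        assert s.per_transcript_fraction["a"] == pytest.approx(0.75)
        # family percentages count features, not unioned bases
        assert s.family_percentages == {"LINE": 50.0, "SINE": 50.0}

    def test_histogram_sums_to_transcript_count(self, dataset):
        linc = dataset.transcripts_of("lincRNA")
        s = repeat_content(linc, dataset.repeats)
        assert s.content_histogram.sum() == len(linc)

    def test_union_coverage_matches_per_base_oracle(self, rng):
        """Interval-union coverage equals an exhaustive per-base count on
        randomized transcripts and repeat sets."""
        for _ in range(500):
            exons = []
            pos = int(rng.integers(0, 30))
            for _ in range(int(rng.integers(1, 4))):
                L = int(rng.integers(5, 50))
                exons.append((pos, pos + L))
                pos += L + int(rng.integers(1, 15))
            t = make_transcript(exons=tuple(exons))
            reps = []
            for _ in range(int(rng.integers(0, 8))):
                a = int(rng.integers(0, 250))
                reps.append(
                    RepeatFeature(
                        Interval("chr1", a, a + int(rng.integers(1, 40))),
                        "SINE",
                    )
                )
            got = repeat_covered_bases(t, _repeat_trees(reps))
            exonic = {p for s, e in exons for p in range(s, e)}
            rep_bases = {
                p
                for r in reps
                for p in range(r.interval.start, r.interval.end)
            }
            assert got == len(exonic & rep_bases)


def locus(gid, start, end, chrom="chr1"):
    return GeneLocus(gid, (gid,), Interval(chrom, start, end))


class TestNeighborAnalysis:
    def test_downstream_gap_arithmetic(self):
        nb = neighbor_analysis(
            [locus("L", 1000, 2000)], [locus("P", 2500, 4000)]
        )
        assert nb.downstream["L"].gene_id == "P"
        assert nb.downstream["L"].distance == 500
        assert "L" not in nb.upstream
        assert nb.n_with_neighbor == 1

    def test_overlapping_gene_excluded(self):
        nb = neighbor_analysis(
            [locus("L", 1000, 2000)], [locus("P", 1500, 4000)]
        )
        assert nb.n_with_neighbor == 0

    def test_window_bound_is_strict(self):
        nb = neighbor_analysis(
            [locus("L", 1000, 2000)], [locus("P", 12_000, 13_000)]
        )
        assert nb.n_with_neighbor == 0  # gap exactly 10,000
        nb = neighbor_analysis(
            [locus("L", 1000, 2000)], [locus("P", 11_999, 13_000)]
        )
        assert nb.downstream["L"].distance == 9_999

    def test_nearest_of_several_chosen_and_pooled_list_deduplicated(self):
        lincs = [locus("L1", 1000, 2000), locus("L2", 10_000, 11_000)]
        prots = [
            locus("P1", 3000, 4000),
            locus("P2", 5000, 6000),
            locus("P3", 12_000, 13_000),
        ]
        nb = neighbor_analysis(lincs, prots)
        assert nb.downstream["L1"].gene_id == "P1"
        assert nb.upstream["L2"].gene_id == "P2"
        assert set(nb.neighbor_genes) == {"P1", "P2", "P3"}

    def test_symmetric_under_coordinate_reflection(self, rng):
        """Reflecting all loci about the chromosome end swaps upstream and
        downstream but preserves every distance."""
        L = 100_000
        lincs, prots = [], []
        pos = 0
        for i in range(20):
            pos += int(rng.integers(100, 3000))
            width = int(rng.integers(100, 2000))
            (lincs if i % 2 else prots).append(
                locus(f"x{i}", pos, pos + width)
            )
            pos += width
        nb = neighbor_analysis(lincs, prots)

        def reflect(l):
            return GeneLocus(
                l.gene_id, l.transcript_ids,
                Interval(l.span.chrom, L - l.span.end, L - l.span.start),
            )

        nb_r = neighbor_analysis([reflect(l) for l in lincs],
                                 [reflect(p) for p in prots])
        assert {k: v.distance for k, v in nb.upstream.items()} == {
            k: v.distance for k, v in nb_r.downstream.items()
        }
        assert {k: v.distance for k, v in nb.downstream.items()} == {
            k: v.distance for k, v in nb_r.upstream.items()
        }


class TestSpliceSummary:
    def test_all_canonical_on_planted_lincrnas(self, dataset):
        assert splice_site_summary(
            dataset.transcripts_of("lincRNA"), dataset.genome
        ) == 1.0

    def test_noncanonical_intron_counted(self):
        # one GC-AG intron among one GT-AG
        g = GenomeSequence({"chr1": "AAA" + "GTCCAG" + "TTT" + "GCCCAG" + "AAA"})
        t1 = make_transcript("a", "ga", exons=((0, 3), (9, 12)))
        t2 = make_transcript("b", "gb", exons=((9, 12), (18, 21)))
        assert splice_site_summary([t1, t2], g) == 0.5

    def test_no_introns_is_error(self):
        g = GenomeSequence({"chr1": "ACGTACGT"})
        with pytest.raises(ValueError):
            splice_site_summary([single_exon("a", "g", 0, 4)], g)
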