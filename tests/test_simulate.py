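"""The synthetic generator: determinism and planted-class construction."""

import filecmp
import math
import os

import numpy as np
import pytest

from lincseek.io import extract_sequence, splice_site_dinucleotides
from lincseek.pipeline import score_coding_potential
from lincseek.simulate import (
    SyntheticConfig,
    generate_ct_table,
    generate_dataset,
    generate_genome,
    plant_repeats,
    sample_repeat_family,
    suppress_orfs,
    max_allowed_orf_codons,
    write_dataset,
)
from lincseek.assays import ddct_quantify
from test_orf import brute_force_longest_orf


class TestDeterminism:
    def test_identical_config_gives_identical_objects(self, dataset):
        other = generate_dataset(SyntheticConfig())
        assert other.genome.to_dict() == dataset.genome.to_dict()
        assert other.transcripts == dataset.transcripts
        assert other.repeats == dataset.repeats
        assert [c.blocks for c in other.ortholog.chains] == [
            c.blocks for c in dataset.ortholog.chains
        ]

    def test_written_files_are_byte_identical(self, tmp_path):
        cfg = SyntheticConfig(seed=7, n_lincrna=5, n_coding=5,
                              n_single_exon=2, n_short=2, n_utr_fragment=2,
                              n_small_rna=2, chrom_length=60_000)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_dataset(generate_dataset(cfg), d1)
        write_dataset(generate_dataset(cfg), d2)
        names = sorted(os.listdir(d1))
        assert names == sorted(os.listdir(d2))
        match, mismatch, errors = filecmp.cmpfiles(d1, d2, names, shallow=False)
        assert mismatch == [] and errors == []

    def test_different_seed_changes_genome(self):
        cfg_a = SyntheticConfig(seed=1, n_chromosomes=1, chrom_length=2000,
                                n_lincrna=0, n_coding=0, n_single_exon=0,
                                n_short=0, n_utr_fragment=0, n_small_rna=0)
        cfg_b = SyntheticConfig(seed=2, n_chromosomes=1, chrom_length=2000,
                                n_lincrna=0, n_coding=0, n_single_exon=0,
                                n_short=0, n_utr_fragment=0, n_small_rna=0)
        assert (generate_genome(cfg_a).sequence("chr1")
                != generate_genome(cfg_b).sequence("chr1"))


class TestGenome:
    def test_chromosome_count_and_length(self):
        cfg = SyntheticConfig(n_chromosomes=2, chrom_length=1000)
        g = generate_genome(cfg)
        assert g.chrom_names == ["chr1", "chr2"]
        assert all(g.length(c) == 1000 for c in g.chrom_names)

    def test_gc_fraction_near_half(self):
        cfg = SyntheticConfig(n_chromosomes=1, chrom_length=10_000)
        seq = generate_genome(cfg).sequence("chr1")
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 0.5) < 0.05
        assert "N" not in seq


class TestPlantedClasses:
    def test_lincrnas_have_canonical_splice_sites(self, dataset):
        for t in dataset.transcripts_of("lincRNA"):
            pairs = splice_site_dinucleotides(t, dataset.genome)
            assert pairs and all(p == ("GT", "AG") for p in pairs)

    def test_lincrna_orfs_capped_by_brute_force_scan(self, dataset):
        """Independent six-frame enumeration confirms the ORF caps that
        keep the coding score negative."""
        for t in dataset.transcripts_of("lincRNA"):
            seq = extract_sequence(t, dataset.genome)
            L = brute_force_longest_orf(seq)
            assert L < 100
            assert 3 * L / len(seq) < 0.5
            assert score_coding_potential(seq).max_score <= 0.0

    def test_coding_class_scores_coding(self, dataset):
        for t in dataset.transcripts_of("coding"):
            seq = extract_sequence(t, dataset.genome)
            assert score_coding_potential(seq).is_coding

    def test_short_class_below_200(self, dataset):
        for t in dataset.transcripts_of("short"):
            assert t.exon_count >= 2 and t.mature_length <= 199

    def test_single_exon_class(self, dataset):
        for t in dataset.transcripts_of("single_exon"):
            assert t.exon_count == 1

    def test_small_rna_class_sized_and_annotated(self, dataset):
        hits_by_query = {h.query_id for h in dataset.rfam_hits}
        for t in dataset.transcripts_of("small_rna"):
            assert 70 <= t.mature_length <= 150
            assert t.transcript_id in hits_by_query

    def test_utr_fragments_live_inside_utr(self, dataset):
        from lincseek.pipeline import _merge_intervals, utr_coverage_fraction

        merged = {}
        for iv in dataset.utr_intervals:
            merged.setdefault(iv.chrom, []).append((iv.start, iv.end))
        merged = {c: _merge_intervals(v) for c, v in merged.items()}
        for t in dataset.transcripts_of("utr_fragment"):
            assert utr_coverage_fraction(t, merged) > 0.9

    def test_every_transcript_labelled_once(self, dataset):
        assert set(dataset.truth.labels) == {
            t.transcript_id for t in dataset.transcripts
        }
        counts = {}
        for lab in dataset.truth.labels.values():
            counts[lab] = counts.get(lab, 0) + 1
        assert counts == {
            "lincRNA": 30, "coding": 30, "single_exon": 10,
            "short": 10, "utr_fragment": 10, "small_rna": 10,
        }


class TestOrfSuppression:
    def test_suppression_enforces_cap(self, rng):
        bases = "ACGT"
        for _ in range(20):
            seq = "".join(bases[i] for i in rng.integers(0, 4, size=600))
            cap = max_allowed_orf_codons(len(seq))
            out = suppress_orfs(seq, cap, rng)
            assert len(out) == len(seq)
            assert brute_force_longest_orf(out) <= cap

    def test_cap_keeps_score_negative(self):
        # the cap bounds both ORF length and coverage terms below zero
        for n in (300, 451, 1000, 1499):
            cap = max_allowed_orf_codons(n)
            assert cap < 100 and 3 * cap / n < 0.5


class TestRepeats:
    def test_zero_bearing_fraction_plants_nothing(self, dataset):
        cfg = SyntheticConfig(repeat_bearing_fraction=0.0)
        assert plant_repeats(cfg, dataset.genome, dataset.transcripts) == []

    def test_family_mix_recovered_within_multinomial_bound(self, rng):
        probs = {"SINE": 0.4, "LINE": 0.3, "LTR": 0.3}
        draws = [sample_repeat_family(rng, probs) for _ in range(300)]
        for fam, p in probs.items():
            assert abs(draws.count(fam) / 300 - p) < 0.07

    def test_repeats_fall_on_lincrna_exons(self, dataset):
        linc_exons = {
            (e.chrom, e.start, e.end)
            for t in dataset.transcripts_of("lincRNA")
            for e in t.exons
        }
        for r in dataset.repeats:
            assert any(
                c == r.interval.chrom and s <= r.interval.start
                and r.interval.end <= e
                for c, s, e in linc_exons
            )


class TestOrtholog:
    def test_identity_settings_remap_everything(self, dataset):
        cfg = SyntheticConfig(ortholog_substitution_rate=0.0,
                              ortholog_unmappable_fraction=0.0)
        ds = generate_dataset(cfg)
        assert ds.ortholog.genome.to_dict() == ds.genome.to_dict()
        from lincseek.conserve import liftover_map

        for t in ds.transcripts_of("lincRNA"):
            res = liftover_map(t.span, ds.ortholog.chains)
            assert res.success and res.mapped == t.span
            assert res.mapped_base_ratio == 1.0

    def test_substitution_rate_observed_directly(self, dataset):
        src = dataset.genome.sequence("chr1")
        tgt = dataset.ortholog.genome.sequence("chr1")
        diff = sum(a != b for a, b in zip(src, tgt)) / len(src)
        assert abs(diff - dataset.config.ortholog_substitution_rate) < 0.01

    def test_conserved_and_unmappable_sets_disjoint(self, dataset):
        orth = dataset.ortholog
        assert not orth.conserved_ids & orth.unmappable_ids
        assert len(orth.pairs) == len(orth.conserved_ids) == 18
        assert len(orth.unmappable_ids) == 6


class TestCtGeneration:
    def test_noise_free_fold_one_gives_zero_ddct(self):
        table = generate_ct_table(
            [("GM", "target", 1.0), ("DM", "target", 1.0)],
            n_replicates=3, noise_sd=0.0,
        )
        res = ddct_quantify(table, "target", "REF", "GM")
        assert res.fold("DM") == pytest.approx(1.0)

    def test_noise_free_fold_four_recovered_exactly(self):
        table = generate_ct_table(
            [("GM", "target", 1.0), ("DM", "target", 4.0)],
            n_replicates=6, noise_sd=0.0,
        )
        res = ddct_quantify(table, "target", "REF", "GM")
        assert res.fold("DM") == pytest.approx(4.0)
        assert res.per_condition.loc["DM", "n"] == 6

    def test_noisy_fold_recovered_within_band(self):
        table = generate_ct_table(
            [("GM", "target", 1.0), ("DM", "target", 4.0)],
            n_replicates=6, noise_sd=0.2, seed=42,
        )
        res = ddct_quantify(table, "target", "REF", "GM")
        assert 3.0 <= res.fold("DM") <= 5.3

    def test_nonpositive_fold_rejected(self):
        with pytest.raises(ValueError):
            generate_ct_table([("GM", "t", 0.0)])
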