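"""Seeded synthetic data with planted ground truth.

The generator emulates the study conditions the identification cascade
was designed for: a small random genome carrying planted multi-exon
lincRNAs (canonical GT-AG introns, no long ORFs), protein-coding genes
(one long ORF covering >=80% of the mature length, flanked by annotated
UTRs), and decoy classes removed by specific stages (single-exon
transcripts, short transcripts, UTR fragments, small-RNA-like
transcripts), plus repeat annotations, an "orthologous" second genome
with a chain mapping, and qPCR Ct tables with planted fold-changes.

Everything is drawn from one seeded NumPy generator: identical
configurations produce byte-identical outputs.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .model import (
    ChainMapping,
    GeneLocus,
    GenerationError,
    GenomeSequence,
    HitRecord,
    Interval,
    RepeatFeature,
    TranscriptModel,
    build_gene_loci,
    reverse_complement,
)
from . import io as lio
from .orf import scan_orfs
from .assays import CtRecord, CtTable

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_NONSTOP_CODONS = tuple(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
)

DEFAULT_FAMILY_PROBS = {
    "SINE": 0.35,
    "LINE": 0.23,
    "LTR": 0.155,
    "Simple_repeat": 0.10,
    "Low_complexity": 0.09,
    "DNA": 0.05,
    "Other": 0.025,
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Frozen study conditions for the synthetic dataset.

    The default is the versioned fixture: 2 chromosomes x 200 kb,
    30 lincRNAs, 30 coding genes and 10 of each decoy class, seed 1.
    """

    seed: int = 1
    n_chromosomes: int = 2
    chrom_length: int = 200_000

    n_lincrna: int = 30
    n_coding: int = 30
    n_single_exon: int = 10
    n_short: int = 10
    n_utr_fragment: int = 10
    n_small_rna: int = 10

    lincrna_exon_range: tuple[int, int] = (2, 4)
    lincrna_exon_length_range: tuple[int, int] = (120, 600)
    lincrna_min_mature: int = 300
    coding_exon_range: tuple[int, int] = (4, 6)
    coding_exon_length_range: tuple[int, int] = (120, 300)
    intron_length_range: tuple[int, int] = (40, 400)
    single_exon_length_range: tuple[int, int] = (300, 1500)
    short_exon_length_range: tuple[int, int] = (60, 99)
    small_rna_length_range: tuple[int, int] = (70, 150)
    utr_length: int = 500
    coding_orf_coverage: float = 0.85

    repeat_bearing_fraction: float = 0.65
    repeat_content_beta: tuple[float, float] = (1.0, 2.57)
    repeat_family_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FAMILY_PROBS)
    )

    ortholog_substitution_rate: float = 0.05
    ortholog_conserved_fraction: float = 0.6
    ortholog_unmappable_fraction: float = 0.2
    chain_block_length: int = 10_000

    ct_noise_sd: float = 0.2

    placement_margin: int = 50
    max_placement_attempts: int = 5000

    def __post_init__(self) -> None:
        for name in ("n_lincrna", "n_coding", "n_single_exon", "n_short",
                     "n_utr_fragment", "n_small_rna"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("repeat_bearing_fraction", "ortholog_conserved_fraction",
                     "ortholog_unmappable_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0.0 <= self.ortholog_substitution_rate <= 0.3:
            raise ValueError("ortholog_substitution_rate must be in [0, 0.3]")
        if (self.ortholog_conserved_fraction
                + self.ortholog_unmappable_fraction) > 1.0:
            raise ValueError("conserved + unmappable fractions exceed 1")
        total = sum(self.repeat_family_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"repeat family probabilities sum to {total}")


@dataclass
class TruthTable:
    """Planted class label per emitted transcript, plus locus placements."""

    labels: dict[str, str]
    placements: dict[str, Interval]

    def ids_of(self, label: str) -> set[str]:
        return {t for t, lab in self.labels.items() if lab == label}


@dataclass
class OrthologSet:
    """The second genome, its chain mapping, and the planted ortholog pairs."""

    genome: GenomeSequence
    chains: list[ChainMapping]
    transcripts: list[TranscriptModel]
    pairs: list[tuple[str, str]]          # (source id, ortholog id)
    conserved_ids: set[str]
    unmappable_ids: set[str]


@dataclass
class SyntheticDataset:
    """Everything the cascade and the downstream analyses consume."""

    config: SyntheticConfig
    genome: GenomeSequence
    transcripts: list[TranscriptModel]
    truth: TruthTable
    protein_annotation: list[TranscriptModel]
    protein_gene_loci: list[GeneLocus]
    utr_intervals: list[Interval]
    repeats: list[RepeatFeature]
    protein_hits: list[HitRecord]
    domain_hits: list[HitRecord]
    rfam_hits: list[HitRecord]
    reference_mrna_lengths: dict[str, int]
    mrna_alignments: list[HitRecord]
    ortholog: OrthologSet

    def transcripts_of(self, label: str) -> list[TranscriptModel]:
        wanted = self.truth.ids_of(label)
        return [t for t in self.transcripts if t.transcript_id in wanted]


# ---------------------------------------------------------------------------
# Primitive helpers


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode("ascii")


def _random_nonstop_codons(rng: np.random.Generator, n: int) -> str:
    idx = rng.integers(0, len(_NONSTOP_CODONS), size=n)
    return "".join(_NONSTOP_CODONS[i] for i in idx)


def max_allowed_orf_codons(mature_length: int) -> int:
    """Largest ORF (codons) keeping the built-in coding score negative.

    Requires both the <100-codon cap and ORF-nt coverage < 1/2 of the
    mature length (3L < mature/2).
    """
    by_coverage = (mature_length + 5) // 6 - 1
    return max(0, min(99, by_coverage))


def suppress_orfs(seq: str, max_codons: int, rng: np.random.Generator,
                  max_iter: int = 500) -> str:
    """Rewrite *seq* so no ORF on either strand exceeds *max_codons* codons.

    Scans all six frames; whenever an ATG-initiated run reaches
    ``max_codons + 1`` codons, the codon near the middle of the run is
    overwritten with an in-frame TAA (TTA on the forward strand for
    reverse-strand ORFs).  Neither replacement can create a new ATG on
    either strand, so the scan converges.
    """
    del rng  # deterministic overwrite position; kept for signature stability
    n = len(seq)
    for _ in range(max_iter):
        offender = None
        for orf in scan_orfs(seq):
            if orf.n_codons > max_codons:
                offender = orf
                break
        if offender is None:
            return seq
        j = max(1, max_codons // 2) if max_codons > 0 else 0
        if offender.strand == "+":
            p = offender.start + 3 * j
            seq = seq[:p] + "TAA" + seq[p + 3:]
        else:
            p_rc = offender.start + 3 * j
            p = n - p_rc - 3
            seq = seq[:p] + "TTA" + seq[p + 3:]
    raise GenerationError("ORF suppression did not converge")


def _mature_genomic_positions(t: TranscriptModel) -> list[int]:
    """Genomic coordinate of each mature base, in transcript (5'->3') order."""
    pos = [p for e in t.exons for p in range(e.start, e.end)]
    if t.strand == "-":
        pos.reverse()
    return pos


def _positions_to_intervals(chrom: str, positions: Iterable[int]) -> list[Interval]:
    ordered = sorted(positions)
    out: list[Interval] = []
    run_start = prev = None
    for p in ordered:
        if run_start is None:
            run_start = prev = p
        elif p == prev + 1:
            prev = p
        else:
            out.append(Interval(chrom, run_start, prev + 1))
            run_start = prev = p
    if run_start is not None:
        out.append(Interval(chrom, run_start, prev + 1))
    return out


class _Placer:
    """Rejection-sampling placement of non-overlapping loci with a margin."""

    def __init__(self, cfg: SyntheticConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.rng = rng
        self.occupied: dict[str, list[tuple[int, int]]] = {
            f"chr{i + 1}": [] for i in range(cfg.n_chromosomes)
        }

    def place(self, span_length: int) -> tuple[str, int]:
        m = self.cfg.placement_margin
        for _ in range(self.cfg.max_placement_attempts):
            chrom = f"chr{int(self.rng.integers(0, self.cfg.n_chromosomes)) + 1}"
            limit = self.cfg.chrom_length - span_length
            if limit <= 0:
                continue
            start = int(self.rng.integers(0, limit))
            if all(start + span_length + m <= s or e + m <= start
                   for s, e in self.occupied[chrom]):
                self.occupied[chrom].append((start, start + span_length))
                return chrom, start
        raise GenerationError(
            f"could not place a {span_length} bp locus after "
            f"{self.cfg.max_placement_attempts} attempts"
        )


def _build_exons(chrom: str, start: int, strand: str,
                 exon_lengths: Sequence[int],
                 intron_lengths: Sequence[int]) -> tuple[Interval, ...]:
    exons = []
    pos = start
    for i, L in enumerate(exon_lengths):
        exons.append(Interval(chrom, pos, pos + L, strand))
        pos += L
        if i < len(intron_lengths):
            pos += intron_lengths[i]
    return tuple(exons)


class _GenomeBuffer:
    """Mutable per-chromosome character buffers during generation."""

    def __init__(self, genome: GenomeSequence):
        self.bufs = {c: list(genome.sequence(c)) for c in genome.chrom_names}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        return "".join(self.bufs[chrom][start:end])

    def write(self, chrom: str, start: int, text: str) -> None:
        self.bufs[chrom][start:start + len(text)] = list(text)

    def write_positions(self, chrom: str, positions: Sequence[int],
                        text: str) -> None:
        buf = self.bufs[chrom]
        for p, base in zip(positions, text):
            buf[p] = base

    def mature_sequence(self, t: TranscriptModel) -> str:
        spliced = "".join(self.fetch(e.chrom, e.start, e.end) for e in t.exons)
        return reverse_complement(spliced) if t.strand == "-" else spliced

    def to_genome(self) -> GenomeSequence:
        return GenomeSequence({c: "".join(b) for c, b in self.bufs.items()})


def _imprint_mature(buf: _GenomeBuffer, t: TranscriptModel, mature: str) -> None:
    """Write a mature sequence into the genome buffer along the exons."""
    assert len(mature) == t.mature_length
    spliced = reverse_complement(mature) if t.strand == "-" else mature
    pos = 0
    for e in t.exons:
        buf.write(e.chrom, e.start, spliced[pos:pos + e.length])
        pos += e.length


def _canonical_introns(buf: _GenomeBuffer, t: TranscriptModel) -> None:
    """Overwrite intron boundary bases so every intron is GT..AG on the
    transcript strand (genomic CT..AC for minus-strand transcripts)."""
    for intron in t.introns:
        if t.strand == "-":
            buf.write(intron.chrom, intron.start, "CT")
            buf.write(intron.chrom, intron.end - 2, "AC")
        else:
            buf.write(intron.chrom, intron.start, "GT")
            buf.write(intron.chrom, intron.end - 2, "AG")


# ---------------------------------------------------------------------------
# Public generator operations


def generate_genome(cfg: SyntheticConfig,
                    rng: Optional[np.random.Generator] = None) -> GenomeSequence:
    """A uniform-random A/C/G/T genome per the configuration."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    return GenomeSequence(
        {
            f"chr{i + 1}": _random_dna(rng, cfg.chrom_length)
            for i in range(cfg.n_chromosomes)
        }
    )


def _sample_strand(rng: np.random.Generator) -> str:
    return "+" if rng.integers(0, 2) == 0 else "-"


def sample_repeat_family(rng: np.random.Generator,
                         probs: Mapping[str, float]) -> str:
    fams = list(probs)
    p = np.array([probs[f] for f in fams], dtype=float)
    return fams[int(rng.choice(len(fams), p=p / p.sum()))]


def plant_transcripts(
    cfg: SyntheticConfig,
    genome: GenomeSequence,
    rng: Optional[np.random.Generator] = None,
):
    """Plant all transcript classes into a copy of *genome*.

    Returns ``(edited_genome, transcripts, truth, protein_annotation,
    utr_intervals, aux)`` where *aux* carries the hit tables and the
    reference mRNA length/alignment data for the coding classifier.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    buf = _GenomeBuffer(genome)
    placer = _Placer(cfg, rng)

    transcripts: list[TranscriptModel] = []
    labels: dict[str, str] = {}
    placements: dict[str, Interval] = {}
    annotation: list[TranscriptModel] = []
    utr_intervals: list[Interval] = []
    protein_hits: list[HitRecord] = []
    domain_hits: list[HitRecord] = []
    rfam_hits: list[HitRecord] = []
    reference_mrna_lengths: dict[str, int] = {}
    mrna_alignments: list[HitRecord] = []

    def register(t: TranscriptModel, label: str) -> None:
        transcripts.append(t)
        labels[t.transcript_id] = label
        placements[t.gene_id] = t.span

    # --- lincRNA class: 2-4 exons, GT-AG introns, no long ORFs -------------
    for i in range(cfg.n_lincrna):
        while True:
            n_exons = int(rng.integers(cfg.lincrna_exon_range[0],
                                       cfg.lincrna_exon_range[1] + 1))
            exon_lens = [int(rng.integers(*cfg.lincrna_exon_length_range))
                         for _ in range(n_exons)]
            if sum(exon_lens) >= cfg.lincrna_min_mature:
                break
        intron_lens = [int(rng.integers(*cfg.intron_length_range))
                       for _ in range(n_exons - 1)]
        span = sum(exon_lens) + sum(intron_lens)
        chrom, start = placer.place(span)
        strand = _sample_strand(rng)
        t = TranscriptModel(
            transcript_id=f"LINC.{i + 1}",
            gene_id=f"LINCG.{i + 1}",
            exons=_build_exons(chrom, start, strand, exon_lens, intron_lens),
            biotype_label="lincRNA",
        )
        _canonical_introns(buf, t)
        mature = buf.mature_sequence(t)
        mature = suppress_orfs(mature, max_allowed_orf_codons(len(mature)), rng)
        _imprint_mature(buf, t, mature)
        register(t, "lincRNA")
        # a sub-threshold protein hit: present but not significant
        protein_hits.append(
            HitRecord(
                query_id=t.transcript_id, subject_id=f"SP_WEAK{i + 1}",
                percent_identity=float(rng.uniform(40, 70)),
                alignment_length=60, query_start=1, query_end=60,
                subject_start=1, subject_end=60,
                bit_score=float(rng.uniform(20, 35)),
                e_value=float(10 ** rng.uniform(-3, 0)),
                source_kind="protein",
            )
        )

    # --- coding class: one long ORF (>=80% of mature), annotated UTRs ------
    for i in range(cfg.n_coding):
        n_exons = int(rng.integers(cfg.coding_exon_range[0],
                                   cfg.coding_exon_range[1] + 1))
        exon_lens = [int(rng.integers(*cfg.coding_exon_length_range))
                     for _ in range(n_exons)]
        intron_lens = [int(rng.integers(*cfg.intron_length_range))
                       for _ in range(n_exons - 1)]
        span = sum(exon_lens) + sum(intron_lens)
        chrom, start = placer.place(span)
        strand = _sample_strand(rng)
        t = TranscriptModel(
            transcript_id=f"CODT.{i + 1}",
            gene_id=f"CODG.{i + 1}",
            exons=_build_exons(chrom, start, strand, exon_lens, intron_lens),
            biotype_label="coding",
        )
        _canonical_introns(buf, t)
        M = t.mature_length
        n_codons_total = int(M * cfg.coding_orf_coverage) // 3
        orf_nt = 3 * n_codons_total
        utr5 = (M - orf_nt) // 2
        utr3 = M - orf_nt - utr5
        mature = (
            _random_dna(rng, utr5)
            + "ATG"
            + _random_nonstop_codons(rng, n_codons_total - 2)
            + "TAA"
            + _random_dna(rng, utr3)
        )
        _imprint_mature(buf, t, mature)
        register(t, "coding")

        # annotation twin under its own gene id (the "known protein gene")
        ann = TranscriptModel(
            transcript_id=f"NM_{1000 + i}",
            gene_id=f"PCG.{i + 1}",
            exons=t.exons,
            biotype_label="protein_coding",
        )
        annotation.append(ann)
        positions = _mature_genomic_positions(t)
        for lo, hi in ((0, utr5), (utr5 + orf_nt, M)):
            if hi > lo:
                utr_intervals.extend(
                    _positions_to_intervals(chrom, positions[lo:hi])
                )
        reference_mrna_lengths[ann.transcript_id] = M
        # strong similarity evidence for the assembled twin
        aln_len = int(M * rng.uniform(0.92, 1.0))
        mrna_alignments.append(
            HitRecord(
                query_id=t.transcript_id, subject_id=ann.transcript_id,
                percent_identity=float(rng.uniform(97, 100)),
                alignment_length=aln_len, query_start=1, query_end=aln_len,
                subject_start=1, subject_end=aln_len,
                bit_score=float(aln_len * 1.8),
                e_value=float(10 ** rng.uniform(-60, -30)),
                source_kind="nucleotide",
            )
        )
        protein_hits.append(
            HitRecord(
                query_id=t.transcript_id, subject_id=f"SP_{2000 + i}",
                percent_identity=float(rng.uniform(90, 100)),
                alignment_length=n_codons_total,
                query_start=1, query_end=n_codons_total,
                subject_start=1, subject_end=n_codons_total,
                bit_score=float(rng.uniform(150, 400)),
                e_value=float(10 ** rng.uniform(-40, -10)),
                source_kind="protein",
            )
        )
        domain_hits.append(
            HitRecord(
                query_id=t.transcript_id, subject_id=f"PF{30000 + i}",
                percent_identity=100.0, alignment_length=80,
                query_start=1, query_end=80, subject_start=1, subject_end=80,
                bit_score=float(rng.uniform(80, 200)),
                e_value=float(10 ** rng.uniform(-30, -8)),
                source_kind="domain",
            )
        )

    # --- single-exon decoys ------------------------------------------------
    for i in range(cfg.n_single_exon):
        L = int(rng.integers(*cfg.single_exon_length_range))
        chrom, start = placer.place(L)
        t = TranscriptModel(
            transcript_id=f"SE.{i + 1}", gene_id=f"SEG.{i + 1}",
            exons=(Interval(chrom, start, start + L, _sample_strand(rng)),),
            biotype_label="single_exon",
        )
        register(t, "single_exon")

    # --- short (<200 nt) multi-exon decoys ---------------------------------
    for i in range(cfg.n_short):
        exon_lens = [int(rng.integers(*cfg.short_exon_length_range))
                     for _ in range(2)]
        intron_lens = [int(rng.integers(*cfg.intron_length_range))]
        chrom, start = placer.place(sum(exon_lens) + sum(intron_lens))
        t = TranscriptModel(
            transcript_id=f"SHORT.{i + 1}", gene_id=f"SHORTG.{i + 1}",
            exons=_build_exons(chrom, start, _sample_strand(rng),
                               exon_lens, intron_lens),
            biotype_label="short",
        )
        _canonical_introns(buf, t)
        register(t, "short")

    # --- UTR-fragment decoys ------------------------------------------------
    # Each fragment sits wholly inside the 3' UTR of a dedicated "donor"
    # locus.  The donor contributes UTR intervals (stage 7 input) but is
    # excluded from the protein gene set and emits no assembled
    # transcript, so stage (7) is the only stage that can catch the
    # fragment.
    for i in range(cfg.n_utr_fragment):
        U = cfg.utr_length
        host_span = U + 1000 + U
        chrom, host_start = placer.place(host_span)
        utr5 = Interval(chrom, host_start, host_start + U)
        utr3 = Interval(chrom, host_start + U + 1000, host_start + host_span)
        utr_intervals.extend([utr5, utr3])
        exon_lens = [int(rng.integers(100, 141)) for _ in range(2)]
        intron_len = int(rng.integers(60, 121))
        frag_span = sum(exon_lens) + intron_len
        offset = int(rng.integers(0, U - frag_span))
        t = TranscriptModel(
            transcript_id=f"UTRF.{i + 1}", gene_id=f"UTRFG.{i + 1}",
            exons=_build_exons(chrom, utr3.start + offset,
                               _sample_strand(rng), exon_lens, [intron_len]),
            biotype_label="utr_fragment",
        )
        _canonical_introns(buf, t)
        mature = buf.mature_sequence(t)
        mature = suppress_orfs(mature, max_allowed_orf_codons(len(mature)), rng)
        _imprint_mature(buf, t, mature)
        register(t, "utr_fragment")

    # --- small-RNA-like decoys ----------------------------------------------
    for i in range(cfg.n_small_rna):
        L = int(rng.integers(*cfg.small_rna_length_range))
        chrom, start = placer.place(L)
        t = TranscriptModel(
            transcript_id=f"SRNA.{i + 1}", gene_id=f"SRNAG.{i + 1}",
            exons=(Interval(chrom, start, start + L, _sample_strand(rng)),),
            biotype_label="small_rna",
        )
        register(t, "small_rna")
        fam = ("tRNA", "snoRNA", "miRNA", "snRNA")[int(rng.integers(0, 4))]
        rfam_hits.append(
            HitRecord(
                query_id=t.transcript_id, subject_id=f"RF{i + 1:05d}",
                percent_identity=100.0, alignment_length=L,
                query_start=1, query_end=L, subject_start=1, subject_end=L,
                bit_score=float(rng.uniform(40, 120)), e_value=1e-10,
                source_kind="rna_family", family_class=fam,
            )
        )

    truth = TruthTable(labels=labels, placements=placements)
    aux = {
        "protein_hits": protein_hits,
        "domain_hits": domain_hits,
        "rfam_hits": rfam_hits,
        "reference_mrna_lengths": reference_mrna_lengths,
        "mrna_alignments": mrna_alignments,
    }
    return buf.to_genome(), transcripts, truth, annotation, utr_intervals, aux


def plant_repeats(
    cfg: SyntheticConfig,
    genome: GenomeSequence,
    transcripts: Sequence[TranscriptModel],
    rng: Optional[np.random.Generator] = None,
) -> list[RepeatFeature]:
    """Plant repeat features over lincRNA exons.

    A configurable fraction of lincRNA-class transcripts receives one
    repeat whose exonic footprint is a Beta-distributed fraction of the
    mature length (contiguous in mature coordinates, so a repeat may be
    split across exons into several genomic pieces sharing one name).
    """
    del genome  # placement is purely coordinate-based
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    feats: list[RepeatFeature] = []
    counter = 0
    for t in transcripts:
        if t.biotype_label != "lincRNA":
            continue
        if rng.random() >= cfg.repeat_bearing_fraction:
            continue
        a, b = cfg.repeat_content_beta
        content = float(rng.beta(a, b))
        covered = max(20, int(round(content * t.mature_length)))
        covered = min(covered, t.mature_length)
        m0 = int(rng.integers(0, t.mature_length - covered + 1))
        positions = _mature_genomic_positions(t)[m0:m0 + covered]
        fam = sample_repeat_family(rng, cfg.repeat_family_probs)
        counter += 1
        name = f"REP_{counter}"
        for piece in _positions_to_intervals(t.chrom, positions):
            feats.append(RepeatFeature(interval=piece, repeat_family=fam,
                                       name=name))
    feats.sort(key=lambda f: (f.interval.chrom, f.interval.start))
    return feats


def generate_ortholog(
    cfg: SyntheticConfig,
    genome: GenomeSequence,
    transcripts: Sequence[TranscriptModel],
    rng: Optional[np.random.Generator] = None,
) -> OrthologSet:
    """A second genome, its chain, and ortholog copies of chosen lincRNAs.

    The target genome is a base-substituted copy (identity coordinates).
    The chain covers each chromosome except deleted regions spanning the
    "unmappable" lincRNA loci; kept regions are split into blocks at
    regular breakpoints.  Ortholog transcripts mirror the conserved
    lincRNAs' exon structure on the target genome.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    lincs = [t for t in transcripts if t.biotype_label == "lincRNA"]
    order = list(rng.permutation(len(lincs)))
    n_cons = int(round(cfg.ortholog_conserved_fraction * len(lincs)))
    n_del = int(round(cfg.ortholog_unmappable_fraction * len(lincs)))
    conserved = [lincs[i] for i in order[:n_cons]]
    unmappable = [lincs[i] for i in order[n_cons:n_cons + n_del]]

    # substituted copy
    target = {}
    for chrom in genome.chrom_names:
        arr = np.frombuffer(genome.sequence(chrom).encode("ascii"),
                            dtype=np.uint8).copy()
        hit = rng.random(arr.size) < cfg.ortholog_substitution_rate
        shifts = rng.integers(1, 4, size=int(hit.sum()))
        idx = {65: 0, 67: 1, 71: 2, 84: 3}
        codes = np.array([idx[b] for b in arr[hit]], dtype=np.int64)
        arr[hit] = _BASES[(codes + shifts) % 4]
        target[chrom] = arr.tobytes().decode("ascii")
    target_genome = GenomeSequence(target)

    # chain: whole chromosome minus deleted spans, split at breakpoints
    deleted: dict[str, list[tuple[int, int]]] = {c: [] for c in genome.chrom_names}
    for t in unmappable:
        span = t.span
        lo = max(0, span.start - 10)
        hi = min(genome.length(span.chrom), span.end + 10)
        deleted[span.chrom].append((lo, hi))
    chains: list[ChainMapping] = []
    for chrom in genome.chrom_names:
        L = genome.length(chrom)
        cuts = sorted(deleted[chrom])
        kept: list[tuple[int, int]] = []
        pos = 0
        for lo, hi in cuts:
            if lo > pos:
                kept.append((pos, lo))
            pos = max(pos, hi)
        if pos < L:
            kept.append((pos, L))
        blocks = []
        step = cfg.chain_block_length
        for s, e in kept:
            p = s
            while p < e:
                q = min(e, p + step)
                blocks.append((Interval(chrom, p, q), Interval(chrom, p, q)))
                p = q
        if blocks:
            chains.append(
                ChainMapping(
                    chain_id=f"chain_{chrom}", source_chrom=chrom,
                    target_chrom=chrom, orientation="+",
                    blocks=tuple(blocks), source_size=L, target_size=L,
                )
            )

    orth_ts = []
    pairs = []
    for t in conserved:
        orth = TranscriptModel(
            transcript_id=t.transcript_id + "_orth",
            gene_id=t.gene_id + "_orth",
            exons=t.exons,
            biotype_label="lincRNA_ortholog",
        )
        orth_ts.append(orth)
        pairs.append((t.transcript_id, orth.transcript_id))

    return OrthologSet(
        genome=target_genome,
        chains=chains,
        transcripts=orth_ts,
        pairs=pairs,
        conserved_ids={t.transcript_id for t in conserved},
        unmappable_ids={t.transcript_id for t in unmappable},
    )


def generate_ct_table(
    design: Sequence[tuple[str, str, float]],
    n_replicates: int = 6,
    noise_sd: float = 0.2,
    seed: int = 0,
    reference_gene: str = "REF",
    base_ct_target: float = 25.0,
    base_ct_reference: float = 20.0,
    fraction_labels: Optional[Mapping[str, str]] = None,
) -> CtTable:
    """A Ct table with planted fold-changes.

    *design* rows are ``(condition, gene, fold_change_vs_calibrator)``
    with fold > 0.  Target Cts are ``base - log2(fold) + eps`` and the
    reference gene is constant plus the same Gaussian noise, so the
    2^-ddCt estimate recovers the planted fold exactly at ``noise_sd=0``.
    """
    rng = np.random.default_rng(seed)
    records: list[CtRecord] = []
    fraction_labels = fraction_labels or {}
    conditions = []
    for cond, gene, fold in design:
        if fold <= 0:
            raise ValueError(f"fold-change must be > 0, got {fold}")
        if cond not in conditions:
            conditions.append(cond)
        for rep in range(1, n_replicates + 1):
            eps = float(rng.normal(0.0, noise_sd)) if noise_sd > 0 else 0.0
            records.append(
                CtRecord(
                    sample=cond, condition=cond, gene=gene,
                    replicate=rep,
                    ct=base_ct_target - math.log2(fold) + eps,
                    fraction=fraction_labels.get(cond),
                )
            )
    for cond in conditions:
        for rep in range(1, n_replicates + 1):
            eps = float(rng.normal(0.0, noise_sd)) if noise_sd > 0 else 0.0
            records.append(
                CtRecord(
                    sample=cond, condition=cond, gene=reference_gene,
                    replicate=rep, ct=base_ct_reference + eps,
                    fraction=fraction_labels.get(cond),
                )
            )
    return CtTable(records)


def generate_dataset(cfg: Optional[SyntheticConfig] = None) -> SyntheticDataset:
    """Generate the full synthetic study from one seeded stream."""
    cfg = cfg or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)
    genome = generate_genome(cfg, rng)
    genome, transcripts, truth, annotation, utrs, aux = plant_transcripts(
        cfg, genome, rng
    )
    repeats = plant_repeats(cfg, genome, transcripts, rng)
    ortholog = generate_ortholog(cfg, genome, transcripts, rng)
    return SyntheticDataset(
        config=cfg,
        genome=genome,
        transcripts=transcripts,
        truth=truth,
        protein_annotation=annotation,
        protein_gene_loci=build_gene_loci(annotation),
        utr_intervals=utrs,
        repeats=repeats,
        protein_hits=aux["protein_hits"],
        domain_hits=aux["domain_hits"],
        rfam_hits=aux["rfam_hits"],
        reference_mrna_lengths=aux["reference_mrna_lengths"],
        mrna_alignments=aux["mrna_alignments"],
        ortholog=ortholog,
    )


def write_dataset(ds: SyntheticDataset, outdir: str | os.PathLike) -> None:
    """Write the dataset as plain-text files (FASTA/GTF/TSV/chain/BED)."""
    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    lio.write_fasta(ds.genome.to_dict(), os.path.join(outdir, "genome.fa"))
    lio.write_gtf(ds.transcripts, os.path.join(outdir, "transcripts.gtf"))
    lio.write_gtf(ds.protein_annotation,
                  os.path.join(outdir, "protein_annotation.gtf"))
    lio.write_bed(ds.utr_intervals, os.path.join(outdir, "utr.bed"))
    lio.write_repeat_table(ds.repeats, os.path.join(outdir, "repeats.tsv"))
    lio.write_hits_table(ds.protein_hits,
                         os.path.join(outdir, "swissprot_hits.tsv"))
    lio.write_hits_table(ds.domain_hits, os.path.join(outdir, "pfam_hits.tsv"))
    lio.write_hits_table(ds.rfam_hits, os.path.join(outdir, "rfam_hits.tsv"))
    lio.write_fasta(ds.ortholog.genome.to_dict(),
                    os.path.join(outdir, "target_genome.fa"))
    lio.write_chain_file(ds.ortholog.chains,
                         os.path.join(outdir, "source_to_target.chain"))
    lio.write_gtf(ds.ortholog.transcripts,
                  os.path.join(outdir, "ortholog_lincrnas.gtf"))
    with open(os.path.join(outdir, "truth.tsv"), "w") as fh:
        fh.write("transcript_id\tclass\n")
        for tid in sorted(ds.truth.labels):
            fh.write(f"{tid}\t{ds.truth.labels[tid]}\n")
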