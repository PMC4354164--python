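"""Core domain types shared by every stage of the lincRNA workflow.

Coordinate convention: all in-memory intervals are 0-based, half-open
``[start, end)`` on the forward genomic strand.  GTF and other 1-based
formats are converted at the I/O boundary.  Transcript "length" always
means the mature (spliced) length, i.e. the sum of exon lengths, never
the genomic span.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence


class LincseekError(Exception):
    """Base class for errors raised by this package."""


class CoordinateError(LincseekError):
    """An interval or position falls outside its chromosome, or is malformed."""


class ParseError(LincseekError):
    """A file could not be parsed; the message names the offending line."""


class GenerationError(LincseekError):
    """The synthetic-data generator could not satisfy its constraints."""


STRANDS = ("+", "-", ".")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class Interval:
    """A genomic interval, 0-based half-open, with optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise CoordinateError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in STRANDS:
            raise CoordinateError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "Interval") -> int:
        """Number of shared bases with *other* (0 if different chromosome)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def overlaps(self, other: "Interval", min_bp: int = 1) -> bool:
        return self.overlap_bp(other) >= min_bp

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


class GenomeSequence:
    """A set of named chromosomes holding uppercase DNA over {A,C,G,T,N}."""

    _ALPHABET = frozenset("ACGTN")

    def __init__(self, sequences: Mapping[str, str]):
        if not sequences:
            raise ValueError("genome must contain at least one chromosome")
        self._seqs: dict[str, str] = {}
        for name, seq in sequences.items():
            seq = seq.upper()
            if not seq:
                raise ValueError(f"chromosome {name!r} is empty")
            bad = set(seq) - self._ALPHABET
            if bad:
                raise ValueError(
                    f"chromosome {name!r} contains non-DNA symbols: {sorted(bad)}"
                )
            self._seqs[name] = seq

    @property
    def chrom_names(self) -> list[str]:
        return list(self._seqs)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    def sequence(self, chrom: str) -> str:
        return self._seqs[chrom]

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Return the forward-strand bases of ``[start, end)``; bounds-checked."""
        if chrom not in self._seqs:
            raise CoordinateError(f"unknown chromosome {chrom!r}")
        seq = self._seqs[chrom]
        if not (0 <= start < end <= len(seq)):
            raise CoordinateError(
                f"[{start}, {end}) outside {chrom} (length {len(seq)})"
            )
        return seq[start:end]

    def with_edit(self, chrom: str, start: int, replacement: str) -> None:
        """Overwrite bases in place starting at *start* (generator use)."""
        seq = self._seqs[chrom]
        end = start + len(replacement)
        if not (0 <= start < end <= len(seq)):
            raise CoordinateError(f"edit [{start}, {end}) outside {chrom}")
        self._seqs[chrom] = seq[:start] + replacement.upper() + seq[end:]

    def copy(self) -> "GenomeSequence":
        return GenomeSequence(dict(self._seqs))

    def to_dict(self) -> dict[str, str]:
        return dict(self._seqs)


@dataclass(frozen=True)
class TranscriptModel:
    """A spliced transcript: ordered disjoint exons on one chromosome/strand.

    ``biotype_label`` is an optional ground-truth tag used by the synthetic
    generator; real assemblies leave it ``None``.
    """

    transcript_id: str
    gene_id: str
    exons: tuple[Interval, ...]
    biotype_label: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript needs >=1 exon")
        object.__setattr__(self, "exons", tuple(self.exons))
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) != 1:
            raise ValueError(
                f"{self.transcript_id}: exons span chromosomes {sorted(chroms)}"
            )
        if len(strands) != 1:
            raise ValueError(f"{self.transcript_id}: exons mix strands")
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start <= a.end:
                raise ValueError(
                    f"{self.transcript_id}: exons not sorted/disjoint "
                    f"({a.start}-{a.end} then {b.start}-{b.end})"
                )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    @property
    def mature_length(self) -> int:
        return sum(e.length for e in self.exons)

    @property
    def span(self) -> Interval:
        return Interval(self.chrom, self.exons[0].start, self.exons[-1].end,
                        self.strand)

    @property
    def introns(self) -> tuple[Interval, ...]:
        return tuple(
            Interval(self.chrom, a.end, b.start, self.strand)
            for a, b in zip(self.exons, self.exons[1:])
        )

    def with_label(self, label: str) -> "TranscriptModel":
        return replace(self, biotype_label=label)


@dataclass(frozen=True)
class GeneLocus:
    """A gene-level locus: the genomic span covering all member transcripts."""

    gene_id: str
    transcript_ids: tuple[str, ...]
    span: Interval

    def __post_init__(self) -> None:
        if not self.transcript_ids:
            raise ValueError(f"{self.gene_id}: locus needs >=1 transcript")


def build_gene_loci(transcripts: Iterable[TranscriptModel]) -> list[GeneLocus]:
    """Group transcripts into loci by assembler gene_id.

    The span is the union extent of all member exons.  Strand is taken
    from the members when unanimous, else '.'.
    """
    groups: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        groups.setdefault(t.gene_id, []).append(t)
    loci = []
    for gene_id, members in groups.items():
        chroms = {t.chrom for t in members}
        if len(chroms) != 1:
            raise ValueError(f"gene {gene_id}: members on several chromosomes")
        strands = {t.strand for t in members}
        strand = strands.pop() if len(strands) == 1 else "."
        start = min(t.span.start for t in members)
        end = max(t.span.end for t in members)
        loci.append(
            GeneLocus(
                gene_id=gene_id,
                transcript_ids=tuple(t.transcript_id for t in members),
                span=Interval(chroms.pop(), start, end, strand),
            )
        )
    loci.sort(key=lambda l: (l.span.chrom, l.span.start, l.gene_id))
    return loci


HIT_KINDS = ("nucleotide", "protein", "domain", "rna_family")


@dataclass(frozen=True)
class HitRecord:
    """A similarity/domain/family hit from a BLAST-, HMMER- or Rfam-style table.

    Coordinates are 1-based inclusive on the query/subject as in BLAST
    tabular output.
    """

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    bit_score: float
    e_value: float
    source_kind: str
    family_class: Optional[str] = None

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise ValueError(f"negative E-value {self.e_value}")
        if self.query_start > self.query_end:
            raise ValueError("query_start > query_end")
        if not (0.0 <= self.percent_identity <= 100.0):
            raise ValueError(f"percent identity {self.percent_identity} not in [0,100]")
        if self.source_kind not in HIT_KINDS:
            raise ValueError(f"unknown source_kind {self.source_kind!r}")


REPEAT_FAMILIES = (
    "SINE", "LINE", "LTR", "DNA", "Simple_repeat", "Low_complexity", "Other",
)


def normalize_repeat_family(raw: str) -> str:
    """Collapse a RepeatMasker class/family string into the closed family set.

    The text before '/' decides the family; anything unrecognized maps
    to 'Other'.
    """
    head = raw.split("/", 1)[0].strip()
    return head if head in REPEAT_FAMILIES[:-1] else "Other"


@dataclass(frozen=True)
class RepeatFeature:
    """A repetitive/transposable element annotation on the genome."""

    interval: Interval
    repeat_family: str
    name: str = ""

    def __post_init__(self) -> None:
        if self.repeat_family not in REPEAT_FAMILIES:
            raise ValueError(f"repeat family {self.repeat_family!r} not in closed set")


@dataclass(frozen=True)
class ChainMapping:
    """An ordered set of ungapped aligned blocks between two genomes.

    Each block pairs a source interval with a target interval of equal
    length.  Target intervals are stored in forward coordinates; when
    ``orientation`` is '-', base k of a source block maps to base
    ``target.end - 1 - k`` of its target block (the image runs backwards).
    Blocks are non-overlapping and strictly increasing on the source.
    """

    chain_id: str
    source_chrom: str
    target_chrom: str
    orientation: str
    blocks: tuple[tuple[Interval, Interval], ...]
    source_size: int = 0
    target_size: int = 0

    def __post_init__(self) -> None:
        if self.orientation not in ("+", "-"):
            raise ValueError(f"chain orientation {self.orientation!r}")
        if not self.blocks:
            raise ValueError("chain needs >=1 block")
        prev_end = -1
        for src, tgt in self.blocks:
            if src.length != tgt.length:
                raise ValueError(
                    f"chain {self.chain_id}: block lengths differ "
                    f"({src.length} vs {tgt.length})"
                )
            if src.chrom != self.source_chrom or tgt.chrom != self.target_chrom:
                raise ValueError(f"chain {self.chain_id}: block on wrong chromosome")
            if src.start <= prev_end:
                raise ValueError(
                    f"chain {self.chain_id}: blocks overlap or unsorted on source"
                )
            prev_end = src.end - 1

    def map_base(self, pos: int) -> Optional[int]:
        """Image of source base *pos* on the target, or None if unmapped."""
        for src, tgt in self.blocks:
            if src.contains(pos):
                off = pos - src.start
                if self.orientation == "+":
                    return tgt.start + off
                return tgt.end - 1 - off
        return None

    def invert(self) -> "ChainMapping":
        """The chain mapping target back to source."""
        blocks = [
            (tgt, src)
            for src, tgt in self.blocks
        ]
        blocks.sort(key=lambda b: b[0].start)
        return ChainMapping(
            chain_id=self.chain_id + "_inv",
            source_chrom=self.target_chrom,
            target_chrom=self.source_chrom,
            orientation=self.orientation,
            blocks=tuple(blocks),
            source_size=self.target_size,
            target_size=self.source_size,
        )
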