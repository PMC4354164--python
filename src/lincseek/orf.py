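"""Open-reading-frame scanning and six-frame translation.

An ORF here is an ATG-initiated codon run in a single frame, extending to
the first in-frame stop codon or, if none occurs, to the last complete
codon of the sequence (an "open" ORF).  ORF length is counted in codons
excluding the stop.  These primitives drive the built-in coding-potential
score and the synthetic generator's ORF suppression.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

from .model import reverse_complement

STOP_CODONS = frozenset(("TAA", "TAG", "TGA"))
START_CODON = "ATG"


@dataclass(frozen=True)
class OrfSpan:
    """An ORF in one frame of one strand of the *mature* sequence.

    ``start`` is the 0-based nt offset of the ATG on the scanned strand;
    ``n_codons`` excludes the stop codon; ``has_stop`` records whether the
    run ended at an in-frame stop.
    """

    strand: str          # '+' or '-': which strand of the input was scanned
    frame: int           # 0, 1 or 2: nt offset of the frame on that strand
    start: int
    n_codons: int
    has_stop: bool

    @property
    def nt_length(self) -> int:
        return 3 * self.n_codons


def orfs_in_frame(seq: str, offset: int) -> list[OrfSpan]:
    """All ATG-initiated ORFs in the single forward frame starting at *offset*."""
    out = []
    i = offset
    open_start = None
    n = len(seq)
    while i + 3 <= n:
        codon = seq[i:i + 3]
        if open_start is None:
            if codon == START_CODON:
                open_start = i
        elif codon in STOP_CODONS:
            out.append(OrfSpan("+", offset, open_start,
                               (i - open_start) // 3, True))
            open_start = None
        i += 3
    if open_start is not None:
        out.append(OrfSpan("+", offset, open_start,
                           (i - open_start) // 3, False))
    return out


def scan_orfs(seq: str, strands: str = "+-") -> list[OrfSpan]:
    """ORFs over the three frames of each requested strand of *seq*."""
    out: list[OrfSpan] = []
    for strand in strands:
        s = seq if strand == "+" else reverse_complement(seq)
        for offset in range(3):
            for orf in orfs_in_frame(s, offset):
                out.append(OrfSpan(strand, offset, orf.start,
                                   orf.n_codons, orf.has_stop))
    return out


def longest_orf(seq: str, strands: str = "+-") -> int:
    """Length in codons of the longest ORF over the requested strands (0 if none)."""
    spans = scan_orfs(seq, strands)
    return max((o.n_codons for o in spans), default=0)


def six_frame_translate(seq: str) -> list[str]:
    """Translate *seq* in all six frames (order +1, +2, +3, -1, -2, -3).

    Standard genetic code, stops as '*', trailing partial codons dropped.
    """
    if len(seq) < 3:
        raise ValueError("sequence shorter than one codon")
    peptides = []
    for strand_seq in (seq, reverse_complement(seq)):
        for offset in range(3):
            sub = strand_seq[offset:]
            sub = sub[: len(sub) - len(sub) % 3]
            peptides.append(str(Seq(sub).translate()))
    return peptides
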