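"""Readers and writers for the formats the workflow touches.

GTF (Ensembl dialect, exon features), FASTA, BLAST tabular outfmt-6,
HMMER-like domain tables, Rfam-like family hit tables, RepeatMasker
``.out`` (or a simplified 5-column TSV), a UCSC-chain subset restricted
to ungapped blocks, BED, and qPCR Ct CSV tables.  All coordinates are
converted to the package's 0-based half-open convention at this boundary.
"""

from __future__ import annotations

import os
from typing import Iterable, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from gffutils.feature import feature_from_line

from .model import (
    ChainMapping,
    GenomeSequence,
    HitRecord,
    Interval,
    ParseError,
    RepeatFeature,
    TranscriptModel,
    normalize_repeat_family,
    reverse_complement,
)

# ---------------------------------------------------------------------------
# FASTA


def read_genome_fasta(path: str | os.PathLike) -> GenomeSequence:
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    if not seqs:
        raise ParseError(f"{path}: no FASTA records")
    return GenomeSequence(seqs)


def write_fasta(sequences: dict[str, str], path: str | os.PathLike) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# GTF


def read_gtf(
    path: str | os.PathLike,
    genome: Optional[GenomeSequence] = None,
) -> list[TranscriptModel]:
    """Load exon features from a GTF into TranscriptModels.

    GTF coordinates (1-based inclusive) become 0-based half-open.  Exons
    are grouped on ``transcript_id``, sorted by start, and validated.
    When *genome* is given, exons on unknown chromosomes or outside
    chromosome bounds raise :class:`CoordinateError`-flavoured errors.
    """
    exons: dict[str, list[Interval]] = {}
    gene_of: dict[str, str] = {}
    label_of: dict[str, Optional[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                feat = feature_from_line(line)
            except Exception as exc:  # gffutils raises several flavours
                raise ParseError(f"{path}:{lineno}: cannot parse GTF line: {exc}")
            if feat.featuretype != "exon":
                continue
            attrs = feat.attributes
            if "transcript_id" not in attrs or "gene_id" not in attrs:
                raise ParseError(
                    f"{path}:{lineno}: exon lacks transcript_id/gene_id attributes"
                )
            tid = attrs["transcript_id"][0]
            gid = attrs["gene_id"][0]
            strand = feat.strand if feat.strand in ("+", "-") else "."
            try:
                iv = Interval(feat.seqid, feat.start - 1, feat.end, strand)
            except Exception as exc:
                raise ParseError(f"{path}:{lineno}: bad exon coordinates: {exc}")
            if genome is not None:
                if feat.seqid not in genome:
                    raise ParseError(
                        f"{path}:{lineno}: unknown chromosome {feat.seqid!r}"
                    )
                if iv.end > genome.length(feat.seqid):
                    raise ParseError(
                        f"{path}:{lineno}: exon beyond end of {feat.seqid}"
                    )
            exons.setdefault(tid, []).append(iv)
            gene_of.setdefault(tid, gid)
            if "biotype_label" in attrs:
                label_of.setdefault(tid, attrs["biotype_label"][0])
    transcripts = []
    for tid, ivs in exons.items():
        ivs.sort(key=lambda e: e.start)
        try:
            transcripts.append(
                TranscriptModel(
                    transcript_id=tid,
                    gene_id=gene_of[tid],
                    exons=tuple(ivs),
                    biotype_label=label_of.get(tid),
                )
            )
        except ValueError as exc:
            raise ParseError(f"{path}: transcript {tid}: {exc}")
    transcripts.sort(key=lambda t: (t.chrom, t.span.start, t.transcript_id))
    return transcripts


def write_gtf(transcripts: Iterable[TranscriptModel], path: str | os.PathLike,
              source: str = "lincseek") -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            for i, exon in enumerate(t.exons, start=1):
                attrs = (
                    f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                    f'exon_number "{i}";'
                )
                if t.biotype_label:
                    attrs += f' biotype_label "{t.biotype_label}";'
                fh.write(
                    "\t".join(
                        [
                            exon.chrom,
                            source,
                            "exon",
                            str(exon.start + 1),
                            str(exon.end),
                            ".",
                            t.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# Sequence extraction


def extract_sequence(t: TranscriptModel, genome: GenomeSequence) -> str:
    """Mature (spliced) sequence of *t*; reverse-complemented on '-' strand.

    An unstranded transcript ('.') is read as '+'.
    """
    spliced = "".join(genome.fetch(e.chrom, e.start, e.end) for e in t.exons)
    if t.strand == "-":
        return reverse_complement(spliced)
    return spliced


def splice_site_dinucleotides(
    t: TranscriptModel, genome: GenomeSequence
) -> list[tuple[str, str]]:
    """(donor, acceptor) 2-mers per intron, read on the transcript strand.

    For a canonical intron this is ('GT', 'AG').  Single-exon transcripts
    yield an empty list.  Introns shorter than 4 bases cannot supply two
    disjoint dinucleotides and raise.
    """
    pairs = []
    for intron in t.introns:
        if intron.length < 4:
            raise ValueError(
                f"{t.transcript_id}: intron [{intron.start},{intron.end}) too short"
            )
        seq = genome.fetch(intron.chrom, intron.start, intron.end)
        if t.strand == "-":
            seq = reverse_complement(seq)
        pairs.append((seq[:2], seq[-2:]))
    if t.strand == "-":
        pairs.reverse()
    return pairs


# ---------------------------------------------------------------------------
# Hit tables

#: outfmt-6 columns: qseqid sseqid pident length mismatch gapopen
#: qstart qend sstart send evalue bitscore
_OUTFMT6_NCOLS = 12
#: domain dialect: query_id subject_id bit_score e_value query_start query_end
_DOMAIN_NCOLS = 6
#: rna_family dialect: query_id family_id family_class bit_score e_value
#: query_start query_end
_RFAM_NCOLS = 7


def _parse_float(text: str, path, lineno: int, what: str) -> float:
    try:
        return float(text)
    except ValueError:
        raise ParseError(f"{path}:{lineno}: unparseable {what} {text!r}")


def read_hits_table(path: str | os.PathLike, source_kind: str) -> list[HitRecord]:
    """Parse a similarity/domain/family hit table into HitRecords.

    ``nucleotide``/``protein`` expect 12-column BLAST outfmt 6;
    ``domain`` a 6-column TSV (query, subject, bit score, E-value,
    query start/end); ``rna_family`` a 7-column TSV that adds the family
    class after the subject id.  Lines starting with '#' are ignored.
    """
    if source_kind not in ("nucleotide", "protein", "domain", "rna_family"):
        raise ValueError(f"unknown source_kind {source_kind!r}")
    hits: list[HitRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if source_kind in ("nucleotide", "protein"):
                if len(cols) != _OUTFMT6_NCOLS:
                    raise ParseError(
                        f"{path}:{lineno}: expected {_OUTFMT6_NCOLS} columns, "
                        f"got {len(cols)}"
                    )
                hits.append(
                    HitRecord(
                        query_id=cols[0],
                        subject_id=cols[1],
                        percent_identity=_parse_float(cols[2], path, lineno, "identity"),
                        alignment_length=int(cols[3]),
                        query_start=int(cols[6]),
                        query_end=int(cols[7]),
                        subject_start=int(cols[8]),
                        subject_end=int(cols[9]),
                        bit_score=_parse_float(cols[11], path, lineno, "bit score"),
                        e_value=_parse_float(cols[10], path, lineno, "E-value"),
                        source_kind=source_kind,
                    )
                )
            elif source_kind == "domain":
                if len(cols) != _DOMAIN_NCOLS:
                    raise ParseError(
                        f"{path}:{lineno}: expected {_DOMAIN_NCOLS} columns, "
                        f"got {len(cols)}"
                    )
                qs, qe = int(cols[4]), int(cols[5])
                hits.append(
                    HitRecord(
                        query_id=cols[0],
                        subject_id=cols[1],
                        percent_identity=100.0,
                        alignment_length=qe - qs + 1,
                        query_start=qs,
                        query_end=qe,
                        subject_start=1,
                        subject_end=qe - qs + 1,
                        bit_score=_parse_float(cols[2], path, lineno, "bit score"),
                        e_value=_parse_float(cols[3], path, lineno, "E-value"),
                        source_kind="domain",
                    )
                )
            else:
                if len(cols) != _RFAM_NCOLS:
                    raise ParseError(
                        f"{path}:{lineno}: expected {_RFAM_NCOLS} columns, "
                        f"got {len(cols)}"
                    )
                qs, qe = int(cols[5]), int(cols[6])
                hits.append(
                    HitRecord(
                        query_id=cols[0],
                        subject_id=cols[1],
                        percent_identity=100.0,
                        alignment_length=qe - qs + 1,
                        query_start=qs,
                        query_end=qe,
                        subject_start=1,
                        subject_end=qe - qs + 1,
                        bit_score=_parse_float(cols[3], path, lineno, "bit score"),
                        e_value=_parse_float(cols[4], path, lineno, "E-value"),
                        source_kind="rna_family",
                        family_class=cols[2],
                    )
                )
    return hits


def write_hits_table(hits: Sequence[HitRecord], path: str | os.PathLike) -> None:
    """Write hits in the dialect matching their source_kind (homogeneous list)."""
    with open(path, "w") as fh:
        for h in hits:
            if h.source_kind in ("nucleotide", "protein"):
                row = [
                    h.query_id, h.subject_id, f"{h.percent_identity:.2f}",
                    str(h.alignment_length), "0", "0",
                    str(h.query_start), str(h.query_end),
                    str(h.subject_start), str(h.subject_end),
                    f"{h.e_value:.3g}", f"{h.bit_score:.1f}",
                ]
            elif h.source_kind == "domain":
                row = [
                    h.query_id, h.subject_id, f"{h.bit_score:.1f}",
                    f"{h.e_value:.3g}", str(h.query_start), str(h.query_end),
                ]
            else:
                row = [
                    h.query_id, h.subject_id, h.family_class or "",
                    f"{h.bit_score:.1f}", f"{h.e_value:.3g}",
                    str(h.query_start), str(h.query_end),
                ]
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# Repeat tables


def read_repeat_table(path: str | os.PathLike) -> list[RepeatFeature]:
    """Read RepeatMasker ``.out``-style output or the simplified 5-column TSV.

    Simplified dialect (tab-separated): chrom, start (1-based), end,
    class/family, name.  RepeatMasker ``.out`` rows are whitespace-split
    with the query/start/end/family at their standard positions; the
    two or three header lines are skipped.  Family strings collapse on
    the text before '/' into the closed family set (unknown -> Other).
    """
    feats: list[RepeatFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            if "\t" in line:
                cols = stripped.split("\t")
                if len(cols) != 5:
                    raise ParseError(
                        f"{path}:{lineno}: expected 5 tab-separated columns"
                    )
                chrom, start1, end, fam, name = cols
            else:
                cols = stripped.split()
                # RepeatMasker header lines start with 'SW' / 'score' or are blank
                if cols[0] in ("SW", "score"):
                    continue
                if len(cols) < 11:
                    raise ParseError(
                        f"{path}:{lineno}: not a RepeatMasker .out data row"
                    )
                chrom, start1, end = cols[4], cols[5], cols[6]
                name, fam = cols[9], cols[10]
            start1, end = int(start1), int(end)
            if start1 > end:
                raise ParseError(f"{path}:{lineno}: start > end")
            feats.append(
                RepeatFeature(
                    interval=Interval(chrom, start1 - 1, end),
                    repeat_family=normalize_repeat_family(fam),
                    name=name,
                )
            )
    return feats


def write_repeat_table(feats: Sequence[RepeatFeature],
                       path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for f in feats:
            fh.write(
                "\t".join(
                    [
                        f.interval.chrom,
                        str(f.interval.start + 1),
                        str(f.interval.end),
                        f.repeat_family,
                        f.name or f.repeat_family,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# UCSC chain subset


def read_chain_file(path: str | os.PathLike) -> list[ChainMapping]:
    """Parse a UCSC chain file (ungapped-block subset).

    Header: ``chain score tName tSize tStrand tStart tEnd qName qSize
    qStrand qStart qEnd id``; here *t* is the source genome and *q* the
    target.  Alignment lines carry ``size [dt dq]``.  Negative-strand
    target coordinates are converted to forward coordinates with the
    chain's orientation flag preserved.
    """
    chains: list[ChainMapping] = []
    header = None
    sizes: list[tuple[int, int, int]] = []

    def flush(lineno: int) -> None:
        nonlocal header, sizes
        if header is None:
            return
        (_, s_name, s_size, s_strand, s_start, _s_end,
         t_name, t_size, t_strand, t_start, _t_end, chain_id) = header
        if s_strand != "+":
            raise ParseError(f"{path}:{lineno}: source strand must be '+'")
        blocks = []
        s_cur, t_cur = s_start, t_start
        for size, dt, dq in sizes:
            src = Interval(s_name, s_cur, s_cur + size)
            if t_strand == "+":
                tgt = Interval(t_name, t_cur, t_cur + size)
            else:
                # q coords are on the reversed strand; flip to forward
                tgt = Interval(t_name, t_size - (t_cur + size), t_size - t_cur)
            blocks.append((src, tgt))
            s_cur += size + dt
            t_cur += size + dq
        chains.append(
            ChainMapping(
                chain_id=str(chain_id),
                source_chrom=s_name,
                target_chrom=t_name,
                orientation=t_strand,
                blocks=tuple(blocks),
                source_size=s_size,
                target_size=t_size,
            )
        )
        header, sizes = None, []

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            cols = stripped.split()
            if cols[0] == "chain":
                flush(lineno)
                if len(cols) != 13:
                    raise ParseError(f"{path}:{lineno}: malformed chain header")
                header = (
                    int(cols[1]), cols[2], int(cols[3]), cols[4], int(cols[5]),
                    int(cols[6]), cols[7], int(cols[8]), cols[9], int(cols[10]),
                    int(cols[11]), cols[12],
                )
                sizes = []
            else:
                if header is None:
                    raise ParseError(f"{path}:{lineno}: data line before header")
                if len(cols) == 1:
                    sizes.append((int(cols[0]), 0, 0))
                elif len(cols) == 3:
                    sizes.append((int(cols[0]), int(cols[1]), int(cols[2])))
                else:
                    raise ParseError(f"{path}:{lineno}: malformed alignment line")
    flush(-1)
    return chains


def write_chain_file(chains: Sequence[ChainMapping],
                     path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for c in chains:
            s_start = c.blocks[0][0].start
            s_end = c.blocks[-1][0].end
            if c.orientation == "+":
                t_fwd_start = c.blocks[0][1].start
                t_fwd_end = c.blocks[-1][1].end
                t_start, t_end = t_fwd_start, t_fwd_end
            else:
                # forward-coordinate extent, expressed on the reversed strand
                t_fwd_start = c.blocks[-1][1].start
                t_fwd_end = c.blocks[0][1].end
                t_start = c.target_size - t_fwd_end
                t_end = c.target_size - t_fwd_start
            fh.write(
                f"chain 1000 {c.source_chrom} {c.source_size} + "
                f"{s_start} {s_end} {c.target_chrom} {c.target_size} "
                f"{c.orientation} {t_start} {t_end} {c.chain_id}\n"
            )
            for i, (src, tgt) in enumerate(c.blocks):
                if i + 1 < len(c.blocks):
                    nsrc, ntgt = c.blocks[i + 1]
                    dt = nsrc.start - src.end
                    if c.orientation == "+":
                        dq = ntgt.start - tgt.end
                    else:
                        dq = tgt.start - ntgt.end
                    fh.write(f"{src.length} {dt} {dq}\n")
                else:
                    fh.write(f"{src.length}\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# BED


def read_bed(path: str | os.PathLike) -> list[Interval]:
    """Read a BED3/BED6 file into Intervals (already 0-based half-open)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.rstrip("\n")
            if not stripped or stripped.startswith(("#", "track", "browser")):
                continue
            cols = stripped.split("\t")
            if len(cols) < 3:
                raise ParseError(f"{path}:{lineno}: BED needs >=3 columns")
            strand = cols[5] if len(cols) >= 6 else "."
            out.append(Interval(cols[0], int(cols[1]), int(cols[2]), strand))
    return out


def write_bed(intervals: Iterable[Interval], path: str | os.PathLike,
              names: Optional[Sequence[str]] = None) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names else f"region_{i + 1}"
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n"
            )
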