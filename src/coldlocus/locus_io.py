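"""Gene-model I/O and exon/intron interval arithmetic.

Internal convention is 0-based half-open genomic intervals; GFF3 and GenBank
coordinates (1-based inclusive) are converted on the way in and out.  A
:class:`GeneModel` stores its exons in transcript order (5'->3' along the
mRNA), so minus-strand genes hold exons in decreasing genomic coordinate.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq

from .errors import (
    AlphabetError,
    BoundsError,
    EmptyIntronError,
    GeneNotFoundError,
    MalformedAnnotationError,
)

log = logging.getLogger(__name__)

NUCLEOTIDES = set("ACGTN")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Strand-aware genomic interval, 0-based half-open."""

    scaffold_id: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GeneModel:
    """One gene on one scaffold: exons in transcript order plus CDS/UTR info.

    ``cds_span`` is a pair of transcript coordinates (0-based half-open on the
    spliced transcript) when CDS features are annotated.
    """

    gene_id: str
    exons: list[GenomicInterval]
    cds_span: tuple[int, int] | None = None
    utr5_len: int = 0
    utr3_len: int = 0

    def __post_init__(self) -> None:
        if not self.exons:
            raise MalformedAnnotationError(f"gene {self.gene_id}: no exons")
        strands = {e.strand for e in self.exons}
        scaffolds = {e.scaffold_id for e in self.exons}
        if len(strands) != 1 or len(scaffolds) != 1:
            raise MalformedAnnotationError(
                f"gene {self.gene_id}: exons on mixed strands/scaffolds"
            )
        genomic = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(genomic, genomic[1:]):
            if b.start < a.end:
                raise MalformedAnnotationError(
                    f"gene {self.gene_id}: overlapping exons {a} / {b}"
                )
            if b.start == a.end:
                raise MalformedAnnotationError(
                    f"gene {self.gene_id}: zero-length intron between {a} / {b}"
                )
        expected = genomic if self.strand == "+" else genomic[::-1]
        if list(self.exons) != expected:
            raise MalformedAnnotationError(
                f"gene {self.gene_id}: exons not in transcript order"
            )

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def scaffold_id(self) -> str:
        return self.exons[0].scaffold_id

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def exon_lengths(self) -> list[int]:
        return [e.length for e in self.exons]

    @property
    def transcript_length(self) -> int:
        return sum(self.exon_lengths)

    @property
    def span(self) -> GenomicInterval:
        """Genomic footprint: first exon start to last exon end.

        This is the "gene size" convention used in comparative tables (the
        component sums of published exon/intron lengths do not always agree
        with the published total; both are therefore exposed).
        """
        start = min(e.start for e in self.exons)
        end = max(e.end for e in self.exons)
        return GenomicInterval(self.scaffold_id, start, end, self.strand)

    @property
    def span_length(self) -> int:
        return self.span.length


@dataclass
class IntronSet:
    gene_id: str
    introns: list[GenomicInterval] = field(default_factory=list)

    @property
    def lengths(self) -> list[int]:
        return [i.length for i in self.introns]


def extract_introns(model: GeneModel) -> IntronSet:
    """Introns are the genomic gaps between genomically adjacent exons.

    Returned 5'->3' in transcript orientation.  Raises
    :class:`EmptyIntronError` for single-exon genes rather than silently
    returning an empty set.
    """
    if model.n_exons < 2:
        raise EmptyIntronError(f"gene {model.gene_id} has a single exon")
    genomic = sorted(model.exons, key=lambda e: e.start)
    introns = [
        GenomicInterval(model.scaffold_id, a.end, b.start, model.strand)
        for a, b in zip(genomic, genomic[1:])
    ]
    if model.strand == "-":
        introns = introns[::-1]
    return IntronSet(model.gene_id, introns)


def spliced_sequence(model: GeneModel, scaffold_seq: str) -> str:
    """Concatenate exon sequences; reverse-complement for minus-strand genes.

    Accepts A/C/G/T/N (case-insensitive); N propagates to the output.
    """
    seq = scaffold_seq.upper()
    bad = set(seq) - NUCLEOTIDES
    if bad:
        raise AlphabetError(f"non-ACGTN characters in scaffold: {sorted(bad)}")
    genomic = sorted(model.exons, key=lambda e: e.start)
    for e in genomic:
        if e.end > len(seq):
            raise BoundsError(
                f"exon [{e.start},{e.end}) beyond scaffold length {len(seq)}"
            )
    joined = "".join(seq[e.start : e.end] for e in genomic)
    if model.strand == "-":
        joined = str(Seq(joined).reverse_complement())
    return joined


# ---------------------------------------------------------------------------
# annotation parsing


def _as_text(source) -> str:
    if hasattr(source, "read"):
        return source.read()
    text = str(source)
    if "\n" not in text and Path(text).exists():
        return Path(text).read_text()
    return text


def _sniff_format(text: str) -> str:
    head = text.lstrip()[:200]
    if head.startswith("LOCUS"):
        return "genbank"
    return "gff3"


def read_gene_model(source, gene_id: str, fmt: str | None = None) -> GeneModel:
    """Read one gene's model from a GFF3 or GenBank flat-file annotation.

    ``source`` may be a path, a file-like object, or the annotation text
    itself.  The annotation must contain exactly one gene matching
    ``gene_id`` (by ID, Name or gene qualifier) with at least one exon.
    """
    text = _as_text(source)
    fmt = fmt or _sniff_format(text)
    if fmt == "gff3":
        return _read_gff3(text, gene_id)
    if fmt == "genbank":
        return _read_genbank(text, gene_id)
    raise ValueError(f"unknown annotation format {fmt!r}")


def _read_gff3(text: str, gene_id: str) -> GeneModel:
    db = gffutils.create_db(
        text,
        dbfn=":memory:",
        from_string=True,
        merge_strategy="create_unique",
        keep_order=True,
    )
    matches = []
    for feat in db.features_of_type("gene"):
        names = set(feat.attributes.get("ID", [])) | set(
            feat.attributes.get("Name", [])
        )
        if gene_id in names:
            matches.append(feat)
    if not matches:
        raise GeneNotFoundError(f"gene {gene_id!r} not found in GFF3")
    if len(matches) > 1:
        raise MalformedAnnotationError(f"gene {gene_id!r} matches {len(matches)} records")
    gene = matches[0]
    exon_feats = list(db.children(gene, featuretype="exon"))
    if not exon_feats:
        raise MalformedAnnotationError(f"gene {gene_id!r} has no exon features")
    strand = gene.strand if gene.strand in "+-" else "+"
    exons = sorted(
        (
            GenomicInterval(f.seqid, f.start - 1, f.end, strand)
            for f in exon_feats
        ),
        key=lambda e: e.start,
    )
    cds_feats = sorted(db.children(gene, featuretype="CDS"), key=lambda f: f.start)
    if strand == "-":
        exons = exons[::-1]
    cds_span, utr5, utr3 = _cds_to_transcript(
        exons, [(f.start - 1, f.end) for f in cds_feats], strand
    )
    return GeneModel(gene_id, exons, cds_span, utr5, utr3)


def _read_genbank(text: str, gene_id: str) -> GeneModel:
    record = SeqIO.read(io.StringIO(text), "genbank")
    gene_feats = [
        f
        for f in record.features
        if f.type in {"gene", "mRNA", "CDS"}
        and gene_id in f.qualifiers.get("gene", []) + f.qualifiers.get("locus_tag", [])
    ]
    if not gene_feats:
        raise GeneNotFoundError(f"gene {gene_id!r} not found in GenBank record")
    mrnas = [f for f in gene_feats if f.type == "mRNA"]
    src = mrnas[0] if mrnas else gene_feats[0]
    strand = "+" if (src.location.strand or 1) >= 0 else "-"
    exons = sorted(
        (
            GenomicInterval(record.id, int(p.start), int(p.end), strand)
            for p in src.location.parts
        ),
        key=lambda e: e.start,
    )
    if strand == "-":
        exons = exons[::-1]
    cds_feats = [f for f in gene_feats if f.type == "CDS"]
    cds_parts: list[tuple[int, int]] = []
    if cds_feats:
        cds_parts = sorted(
            (int(p.start), int(p.end)) for p in cds_feats[0].location.parts
        )
    cds_span, utr5, utr3 = _cds_to_transcript(exons, cds_parts, strand)
    return GeneModel(gene_id, exons, cds_span, utr5, utr3)


def _cds_to_transcript(
    exons: Sequence[GenomicInterval],
    cds_parts: Iterable[tuple[int, int]],
    strand: str,
) -> tuple[tuple[int, int] | None, int, int]:
    """Project genomic CDS parts onto spliced-transcript coordinates."""
    cds_parts = list(cds_parts)
    if not cds_parts:
        return None, 0, 0
    genomic = sorted(exons, key=lambda e: e.start)
    offsets: list[tuple[GenomicInterval, int]] = []
    pos = 0
    for e in genomic:
        offsets.append((e, pos))
        pos += e.length
    total = pos

    def to_tx(g: int) -> int:
        for e, off in offsets:
            if e.start <= g <= e.end:
                return off + (g - e.start)
        raise MalformedAnnotationError(f"CDS coordinate {g} outside exons")

    cds_start_g = min(s for s, _ in cds_parts)
    cds_end_g = max(e for _, e in cds_parts)
    lo, hi = to_tx(cds_start_g), to_tx(cds_end_g)
    if strand == "-":
        lo, hi = total - hi, total - lo
    return (lo, hi), lo, total - hi


def write_gene_model_gff3(model: GeneModel, handle=None) -> str:
    """Serialize a GeneModel to GFF3 (1-based inclusive); round-trips exactly."""
    lines = ["##gff-version 3"]
    span = model.span
    gid = model.gene_id
    lines.append(
        "\t".join(
            [
                model.scaffold_id,
                "coldlocus",
                "gene",
                str(span.start + 1),
                str(span.end),
                ".",
                model.strand,
                ".",
                f"ID={gid};Name={gid}",
            ]
        )
    )
    lines.append(
        "\t".join(
            [
                model.scaffold_id,
                "coldlocus",
                "mRNA",
                str(span.start + 1),
                str(span.end),
                ".",
                model.strand,
                ".",
                f"ID={gid}.t1;Parent={gid}",
            ]
        )
    )
    genomic = sorted(model.exons, key=lambda e: e.start)
    for i, e in enumerate(genomic, 1):
        lines.append(
            "\t".join(
                [
                    model.scaffold_id,
                    "coldlocus",
                    "exon",
                    str(e.start + 1),
                    str(e.end),
                    ".",
                    model.strand,
                    ".",
                    f"ID={gid}.e{i};Parent={gid}.t1",
                ]
            )
        )
    if model.cds_span is not None:
        for s, e in _transcript_to_genomic(model, *model.cds_span):
            lines.append(
                "\t".join(
                    [
                        model.scaffold_id,
                        "coldlocus",
                        "CDS",
                        str(s + 1),
                        str(e),
                        ".",
                        model.strand,
                        "0",
                        f"ID={gid}.cds;Parent={gid}.t1",
                    ]
                )
            )
    text = "\n".join(lines) + "\n"
    if handle is not None:
        handle.write(text)
    return text


def _transcript_to_genomic(model: GeneModel, lo: int, hi: int) -> list[tuple[int, int]]:
    """Map a transcript-coordinate span back to genomic (start, end) pieces."""
    pieces: list[tuple[int, int]] = []
    pos = 0
    for e in model.exons:  # transcript order
        e_lo, e_hi = pos, pos + e.length
        ov_lo, ov_hi = max(lo, e_lo), min(hi, e_hi)
        if ov_lo < ov_hi:
            if model.strand == "+":
                pieces.append((e.start + (ov_lo - e_lo), e.start + (ov_hi - e_lo)))
            else:
                pieces.append((e.end - (ov_hi - e_lo), e.end - (ov_lo - e_lo)))
        pos = e_hi
    return sorted(pieces)


def read_fasta(source) -> dict[str, str]:
    """Read a (multi-)FASTA into an id -> uppercase-sequence dict."""
    text = _as_text(source)
    records = SeqIO.parse(io.StringIO(text), "fasta")
    return {r.id: str(r.seq).upper() for r in records}


def write_fasta(seqs: dict[str, str], handle=None, width: int = 70) -> str:
    out = []
    for name, seq in seqs.items():
        out.append(f">{name}")
        out.extend(seq[i : i + width] for i in range(0, len(seq), width))
    text = "\n".join(out) + "\n"
    if handle is not None:
        handle.write(text)
    return text
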