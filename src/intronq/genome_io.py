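"""Genome and annotation I/O: FASTA reading, GFF3 exon parsing, gene models.

Internal coordinates are 0-based half-open throughout; GFF3 coordinates
(1-based inclusive) are converted at the parsing boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
from Bio import SeqIO

__all__ = [
    "GenomeSequence",
    "Interval",
    "GeneModel",
    "ExonFeature",
    "GenomeFormatError",
    "parse_fasta",
    "parse_gff3",
    "build_gene_models",
    "select_gene_model",
    "extract_interval_sequence",
    "reverse_complement",
    "interval_to_gff3_coords",
    "gff3_coords_to_interval",
]

_ALLOWED = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class GenomeFormatError(ValueError):
    """Raised for malformed FASTA/GFF3 input."""


def reverse_complement(seq: str) -> str:
    """Reverse complement of an upper-case DNA string over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeSequence:
    """A named DNA sequence restricted to the alphabet {A,C,G,T,N}."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise GenomeFormatError("genome id must be non-empty")
        bad = next(
            ((i, c) for i, c in enumerate(self.seq) if c not in _ALLOWED), None
        )
        if bad is not None:
            raise GenomeFormatError(
                f"sequence {self.id!r}: disallowed character {bad[1]!r} "
                f"at position {bad[0]}"
            )

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True, order=True)
class Interval:
    """0-based half-open interval with a strand."""

    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, other: "Interval") -> bool:
        return self.start <= other.start and other.end <= self.end

    def overlaps(self, other: "Interval") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass(frozen=True)
class GeneModel:
    """Ordered exon structure of one transcript; introns are derived.

    Invariants: exons sorted by start and pairwise disjoint; introns
    exactly tile the gaps between consecutive exons, so
    ``len(introns) == len(exons) - 1``.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[Interval, ...]
    introns: tuple[Interval, ...] = field(init=False)

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"gene {self.gene_id!r}: no exons")
        exons = tuple(sorted(self.exons, key=lambda iv: iv.start))
        for a, b in zip(exons, exons[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"gene {self.gene_id!r}: overlapping exons "
                    f"[{a.start},{a.end}) and [{b.start},{b.end})"
                )
        introns = tuple(
            Interval(a.end, b.start, self.strand)
            for a, b in zip(exons, exons[1:])
        )
        object.__setattr__(self, "exons", exons)
        object.__setattr__(self, "introns", introns)

    @property
    def span(self) -> Interval:
        return Interval(self.exons[0].start, self.exons[-1].end, self.strand)


@dataclass(frozen=True)
class ExonFeature:
    """One raw annotation feature grouped under a transcript/gene key."""

    group: str
    gene: str
    chrom: str
    interval: Interval


def parse_fasta(path: str | Path) -> list[GenomeSequence]:
    """Read a (multi-)FASTA file into :class:`GenomeSequence` records.

    Sequences are upper-cased. RNA (U) and IUPAC ambiguity codes other
    than N are rejected; duplicate record ids are an error.
    """
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise GenomeFormatError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        records.append(GenomeSequence(id=rec.id, seq=str(rec.seq).upper()))
    if not records:
        raise GenomeFormatError(f"no FASTA records found in {path}")
    return records


def gff3_coords_to_interval(start_1based: int, end_1based: int, strand: str) -> Interval:
    """Convert GFF3 1-based inclusive coordinates to the internal convention."""
    return Interval(start_1based - 1, end_1based, strand)


def interval_to_gff3_coords(iv: Interval) -> tuple[int, int]:
    """Inverse of :func:`gff3_coords_to_interval` (coordinates only)."""
    return iv.start + 1, iv.end


def parse_gff3(path: str | Path, feature_type: str = "exon") -> list[ExonFeature]:
    """Read features of one type from a GFF3 file.

    The grouping key is the ``Parent`` attribute if present, else
    ``gene_id``, else ``ID``; a secondary gene key is taken from
    ``gene_id``/``gene`` when present so models can be looked up by gene
    name as well as transcript id.
    """
    features: list[ExonFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                feat = gffutils.feature.feature_from_line(line)
            except Exception as exc:  # noqa: BLE001 - library raises bare exceptions
                raise GenomeFormatError(
                    f"{path}:{lineno}: unparseable GFF3 line ({exc})"
                ) from exc
            if feat.featuretype != feature_type:
                continue
            if feat.end < feat.start:
                raise GenomeFormatError(
                    f"{path}:{lineno}: end ({feat.end}) < start ({feat.start})"
                )
            attrs = feat.attributes
            group = None
            for key in ("Parent", "gene_id", "ID"):
                if attrs.get(key):
                    group = attrs[key][0]
                    break
            if group is None:
                raise GenomeFormatError(
                    f"{path}:{lineno}: {feature_type} feature lacks a "
                    "Parent/gene_id/ID grouping attribute"
                )
            gene = (attrs.get("gene_id") or attrs.get("gene") or [group])[0]
            strand = feat.strand if feat.strand in ("+", "-") else "+"
            features.append(
                ExonFeature(
                    group=group,
                    gene=gene,
                    chrom=feat.seqid,
                    interval=gff3_coords_to_interval(feat.start, feat.end, strand),
                )
            )
    return features


def build_gene_models(features: Iterable[ExonFeature]) -> list[GeneModel]:
    """Assemble one :class:`GeneModel` per grouping key.

    Errors on overlapping exons or mixed chromosomes/strands inside a
    group. Model order follows first appearance of each group.
    """
    grouped: dict[str, list[ExonFeature]] = {}
    for feat in features:
        grouped.setdefault(feat.group, []).append(feat)
    models = []
    for group, feats in grouped.items():
        chroms = {f.chrom for f in feats}
        if len(chroms) > 1:
            raise ValueError(
                f"group {group!r} spans multiple chromosomes: {sorted(chroms)}"
            )
        strands = {f.interval.strand for f in feats}
        if len(strands) > 1:
            raise ValueError(f"group {group!r} mixes strands")
        models.append(
            GeneModel(
                gene_id=group,
                chrom=feats[0].chrom,
                strand=feats[0].interval.strand,
                exons=tuple(f.interval for f in feats),
            )
        )
    return models


def select_gene_model(
    features: Sequence[ExonFeature], gene_id: str, transcript_id: str | None = None
) -> GeneModel:
    """Pick the gene model to design against.

    Matches ``gene_id`` against either the grouping key or the gene
    attribute. When several transcripts match, the one with the most
    exons wins (ties broken by first appearance) unless a specific
    ``transcript_id`` is requested.
    """
    if transcript_id is not None:
        chosen = [f for f in features if f.group == transcript_id]
        if not chosen:
            raise KeyError(f"transcript {transcript_id!r} not found")
        return build_gene_models(chosen)[0]
    matching = [f for f in features if f.group == gene_id or f.gene == gene_id]
    if not matching:
        available = sorted({f.gene for f in features} | {f.group for f in features})
        raise KeyError(
            f"gene {gene_id!r} not found; available ids: {', '.join(available)}"
        )
    models = build_gene_models(matching)
    return max(models, key=lambda m: len(m.exons))


def extract_interval_sequence(genome: GenomeSequence, interval: Interval) -> str:
    """Strand-aware subsequence: '-' returns the reverse complement."""
    if interval.end > len(genome):
        raise ValueError(
            f"interval [{interval.start},{interval.end}) exceeds genome "
            f"{genome.id!r} length {len(genome)}"
        )
    sub = genome.seq[interval.start : interval.end]
    return reverse_complement(sub) if interval.strand == "-" else sub
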