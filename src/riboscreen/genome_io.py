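"""Readers and writers for the standard formats the screen touches.

All internal coordinates are 0-based half-open; GFF3 (1-based inclusive)
and Infernal tblout (1-based inclusive, from > to on the minus strand) are
converted at the boundary and back on output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

from gffutils.feature import feature_from_line

log = logging.getLogger(__name__)

RELATIONS = ("SENSE_5P", "ANTISENSE_3P", "UNASSIGNED")

#: GFF3 attribute keys whose values are harvested into GeneFeature.labels.
LABEL_ATTRIBUTES = ("product", "Product", "Note", "note", "COG", "cog",
                    "EC", "ec_number", "eC_number", "function", "gene")


class ParseError(ValueError):
    """Malformed input line; message names the offending line number."""


@dataclass(frozen=True, slots=True)
class GeneFeature:
    """An annotated gene (or pseudogene) interval on one contig."""

    gene_id: str
    contig: str
    start: int        # 0-based inclusive
    end: int          # 0-based exclusive
    strand: str       # '+' or '-'
    kind: str = "gene"
    labels: frozenset[str] = field(default_factory=frozenset)
    genome_id: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"gene {self.gene_id}: need 0 <= start < end, "
                             f"got [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if self.kind not in ("gene", "pseudogene"):
            raise ValueError(f"gene {self.gene_id}: kind must be gene or pseudogene")

    @property
    def length_nt(self) -> int:
        return self.end - self.start


@dataclass(frozen=True, slots=True)
class RiboswitchHit:
    """One covariance-model match as emitted by cmsearch."""

    hit_id: str
    model_class: str
    contig: str
    start: int
    end: int
    strand: str
    bit_score: float
    e_value: float
    genome_id: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"hit {self.hit_id}: start must be < end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"hit {self.hit_id}: strand must be + or -")
        if not (self.bit_score == self.bit_score and abs(self.bit_score) != float("inf")):
            raise ValueError(f"hit {self.hit_id}: bit score must be finite")
        if self.e_value < 0:
            raise ValueError(f"hit {self.hit_id}: E-value must be >= 0")


@dataclass(frozen=True, slots=True)
class GenomeMetadata:
    genome_id: str
    species_key: str
    orf_count: int

    def __post_init__(self) -> None:
        if self.orf_count < 0:
            raise ValueError("orf_count must be >= 0")


def read_gene_annotations(stream: IO[str] | Iterable[str], genome_id: str,
                          promote_cds: bool = True) -> list[GeneFeature]:
    """Parse gene/pseudogene features out of a GFF3 stream.

    CDS features without a parent gene feature are promoted to genes when
    ``promote_cds`` is set (many bacterial GFF3 files annotate CDS only).
    Features lacking a strand are rejected with a warning, never kept.
    Returns features sorted by (contig, start).
    """
    genes: dict[str, GeneFeature] = {}
    orphan_cds: list[tuple[GeneFeature, str | None]] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            if line.startswith("##FASTA"):
                break
            continue
        try:
            feat = feature_from_line(line)
        except Exception as exc:  # gffutils raises bare exceptions on bad lines
            raise ParseError(f"malformed GFF3 at line {lineno}: {exc}") from exc
        ftype = feat.featuretype
        if ftype not in ("gene", "pseudogene", "CDS"):
            continue
        if feat.strand not in ("+", "-"):
            log.warning("line %d: feature without strand rejected (%s)",
                        lineno, feat.id or ftype)
            continue
        try:
            start, end = int(feat.start) - 1, int(feat.end)
        except (TypeError, ValueError) as exc:
            raise ParseError(f"malformed GFF3 coordinates at line {lineno}") from exc
        if start < 0 or start >= end:
            raise ParseError(f"bad GFF3 interval at line {lineno}: {feat.start}..{feat.end}")
        labels = frozenset(v for key in LABEL_ATTRIBUTES
                           for v in feat.attributes.get(key, []))
        gid = feat.id or feat.attributes.get("ID", [f"feat{lineno}"])[0]
        gf = GeneFeature(gene_id=gid, contig=feat.seqid, start=start, end=end,
                         strand=feat.strand,
                         kind="pseudogene" if ftype == "pseudogene" else "gene",
                         labels=labels, genome_id=genome_id)
        if ftype == "CDS":
            parent = feat.attributes.get("Parent", [None])[0]
            orphan_cds.append((gf, parent))
        else:
            genes[gid] = gf
    if promote_cds:
        for gf, parent in orphan_cds:
            if parent in genes:
                # fold CDS labels into the parent gene record
                merged = genes[parent].labels | gf.labels
                genes[parent] = replace(genes[parent], labels=merged)
            elif gf.gene_id not in genes:
                genes[gf.gene_id] = gf
    return sorted(genes.values(), key=lambda g: (g.contig, g.start, g.gene_id))


# column indices of the standard 18-column cmsearch --tblout layout
_TBL_TARGET, _TBL_QUERY, _TBL_FROM, _TBL_TO = 0, 2, 7, 8
_TBL_STRAND, _TBL_SCORE, _TBL_EVALUE = 9, 14, 15


def read_cm_hits(stream: IO[str] | Iterable[str], genome_id: str) -> list[RiboswitchHit]:
    """Parse Infernal tblout rows into RiboswitchHit records.

    Strand is taken from coordinate order (seq-from > seq-to means minus);
    when the strand column is present it must agree, otherwise the record
    is rejected with a warning. Comment lines ('#') are skipped.
    """
    hits: list[RiboswitchHit] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) <= _TBL_EVALUE:
            raise ParseError(f"tblout line {lineno}: expected >= {_TBL_EVALUE + 1} "
                             f"columns, got {len(parts)}")
        try:
            frm, to = int(parts[_TBL_FROM]), int(parts[_TBL_TO])
            score = float(parts[_TBL_SCORE])
            evalue = float(parts[_TBL_EVALUE])
        except ValueError as exc:
            raise ParseError(f"tblout line {lineno}: non-numeric coordinate, "
                             f"score or E-value") from exc
        if frm > to:
            start, end, strand = to - 1, frm, "-"
        else:
            start, end, strand = frm - 1, to, "+"
        col_strand = parts[_TBL_STRAND]
        if col_strand in ("+", "-") and col_strand != strand and frm != to:
            log.warning("tblout line %d: strand column %s contradicts coordinate "
                        "order %d..%d; record rejected", lineno, col_strand, frm, to)
            continue
        if frm == to and col_strand in ("+", "-"):
            strand = col_strand
        hits.append(RiboswitchHit(
            hit_id=f"{genome_id}|{len(hits) + 1:06d}",
            model_class=parts[_TBL_QUERY], contig=parts[_TBL_TARGET],
            start=start, end=end, strand=strand,
            bit_score=score, e_value=evalue, genome_id=genome_id))
    return hits


def select_representatives(metadata: Iterable[GenomeMetadata]) -> list[str]:
    """One genome per species: the one with the most ORFs, ties to the
    lexicographically smallest genome id. Returns sorted genome ids."""
    best: dict[str, GenomeMetadata] = {}
    for rec in metadata:
        cur = best.get(rec.species_key)
        if cur is None or (rec.orf_count, _neg_lex(rec.genome_id)) > \
                (cur.orf_count, _neg_lex(cur.genome_id)):
            best[rec.species_key] = rec
    return sorted(rec.genome_id for rec in best.values())


class _neg_lex(str):
    """Orders strings descending so that max() picks the lexicographic min."""

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)


def read_metadata(stream: IO[str] | Iterable[str]) -> list[GenomeMetadata]:
    """Read a genome metadata TSV (genome_id, species_key, orf_count)."""
    out = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#") or line.startswith("genome_id\t"):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ParseError(f"metadata line {lineno}: expected 3 columns")
        out.append(GenomeMetadata(parts[0], parts[1], int(parts[2])))
    return out


CALL_COLUMNS = ("locus_id", "genome_id", "family", "winning_class", "contig",
                "start", "end", "strand", "bit_score", "e_value", "n_suppressed",
                "relation", "target_gene_id", "distance_nt")


def write_calls(calls: Sequence, loci: Mapping[str, object],
                tsv_dest: str | Path, bed_dest: str | Path | None = None,
                header_meta: Mapping[str, str] | None = None) -> None:
    """Write orientation calls as a TSV table and (optionally) BED6.

    ``loci`` maps locus_id to the ResolvedRiboswitch carrying coordinates and
    score. The BED name field is family|relation and the score is the bit
    score clipped to [0, 1000], per the BED convention.
    """
    rows = sorted(calls, key=lambda c: c.locus_id)
    with open(tsv_dest, "w") as fh:
        for key, value in (header_meta or {}).items():
            fh.write(f"# {key}: {value}\n")
        fh.write("\t".join(CALL_COLUMNS) + "\n")
        for call in rows:
            loc = loci[call.locus_id]
            fh.write("\t".join(map(str, (
                call.locus_id, call.genome_id, call.family, loc.winning_class,
                loc.contig, loc.start, loc.end, loc.strand,
                repr(loc.bit_score), repr(loc.e_value), loc.n_suppressed,
                call.relation, call.target_gene_id or ".", call.distance_nt,
            ))) + "\n")
    if bed_dest is not None:
        with open(bed_dest, "w") as fh:
            for call in rows:
                loc = loci[call.locus_id]
                score = int(min(1000, max(0, round(loc.bit_score))))
                fh.write(f"{loc.contig}\t{loc.start}\t{loc.end}\t"
                         f"{call.family}|{call.relation}\t{score}\t{loc.strand}\n")


def read_calls(stream: IO[str] | Iterable[str]):
    """Re-read a calls TSV written by write_calls.

    Returns (calls, loci) with field values identical to what was written.
    """
    from .hit_resolution import ResolvedRiboswitch
    from .orientation import OrientationCall

    calls, loci = [], {}
    header_seen = False
    for raw in stream:
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        if not header_seen:
            if line.split("\t") != list(CALL_COLUMNS):
                raise ParseError("calls TSV: unexpected header")
            header_seen = True
            continue
        (locus_id, genome_id, family, winning_class, contig, start, end,
         strand, bit_score, e_value, n_suppressed, relation, target,
         distance) = line.split("\t")
        loci[locus_id] = ResolvedRiboswitch(
            locus_id=locus_id, family=family, winning_class=winning_class,
            contig=contig, start=int(start), end=int(end), strand=strand,
            bit_score=float(bit_score), e_value=float(e_value),
            genome_id=genome_id, n_suppressed=int(n_suppressed))
        calls.append(OrientationCall(
            locus_id=locus_id, family=family,
            target_gene_id=None if target == "." else target,
            relation=relation, distance_nt=int(distance), genome_id=genome_id))
    return calls, loci
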