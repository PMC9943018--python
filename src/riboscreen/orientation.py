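"""Strand-aware classification of riboswitch/gene geometry.

A riboswitch is scanned in its own transcription direction (rightward on
'+', leftward on '-'). The nearest gene whose body lies downstream of, or
overlaps, the riboswitch in that direction — within ``max_distance``
nucleotides — is its candidate target:

* same strand as the riboswitch: the riboswitch sits in the gene's 5'
  leader and is sense-acting (``SENSE_5P``);
* opposite strand: convergent transcription meets the gene's 3' end and
  the riboswitch is antisense-acting (``ANTISENSE_3P``).

The single geometric rule reproduces both canonical arrangements: the 5'
leader of a co-oriented gene, and the 3'-end antisense element typified by
the cobalamin riboswitch behind *pocR* in *Listeria monocytogenes*. A
riboswitch wholly contained inside a same-strand gene is internal, not a
leader, and stays ``UNASSIGNED``.
"""

from __future__ import annotations

import logging
from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from typing import Iterable, Sequence

from .genome_io import GeneFeature
from .hit_resolution import ResolvedRiboswitch

log = logging.getLogger(__name__)

DEFAULT_MAX_DISTANCE = 500


@dataclass(frozen=True, slots=True)
class OrientationCall:
    locus_id: str
    family: str
    target_gene_id: str | None
    relation: str            # SENSE_5P | ANTISENSE_3P | UNASSIGNED
    distance_nt: int
    genome_id: str = ""

    def __post_init__(self) -> None:
        if (self.relation == "UNASSIGNED") != (self.target_gene_id is None):
            raise ValueError("UNASSIGNED if and only if target_gene_id is None")
        if self.distance_nt < 0:
            raise ValueError("distance_nt must be >= 0")


@dataclass(frozen=True, slots=True)
class TandemGroup:
    """Two or more riboswitches sharing one target gene and relation."""

    target_gene_id: str
    relation: str
    member_locus_ids: tuple[str, ...]
    same_family: bool
    genome_id: str = ""

    def __post_init__(self) -> None:
        if len(self.member_locus_ids) < 2:
            raise ValueError("a tandem group needs at least two members")


class _ContigIndex:
    """Genes of one contig, sorted by start, with bisectable coordinates."""

    def __init__(self, genes: Sequence[GeneFeature]):
        self.genes = sorted(genes, key=lambda g: (g.start, g.end, g.gene_id))
        self.starts = [g.start for g in self.genes]
        # gene bodies are typically disjoint but GFF3 does not promise it,
        # so keep a running maximum of ends for the leftward scan
        self.max_end_upto = []
        m = -1
        for g in self.genes:
            m = max(m, g.end)
            self.max_end_upto.append(m)


def build_gene_index(genes: Iterable[GeneFeature]) -> dict[str, _ContigIndex]:
    by_contig: dict[str, list[GeneFeature]] = {}
    for g in genes:
        by_contig.setdefault(g.contig, []).append(g)
    return {c: _ContigIndex(gs) for c, gs in by_contig.items()}


def classify_orientation(locus: ResolvedRiboswitch,
                         genes: Iterable[GeneFeature] | dict[str, _ContigIndex],
                         max_distance: int = DEFAULT_MAX_DISTANCE) -> OrientationCall:
    """Classify one resolved riboswitch against the gene annotation."""
    if max_distance < 0:
        raise ValueError("max_distance must be >= 0")
    index = genes if isinstance(genes, dict) else build_gene_index(genes)
    contig = index.get(locus.contig)
    if contig is None:
        log.warning("locus %s: contig %s absent from annotation", locus.locus_id,
                    locus.contig)
        return _unassigned(locus)

    candidates = _scan_candidates(locus, contig, max_distance)
    if not candidates:
        return _unassigned(locus)
    # nearest first; on a shared boundary prefer the sense (co-oriented)
    # reading, then the lexicographically smaller gene id — deterministic
    # and conservative for antisense calls
    candidates.sort(key=lambda item: (item[0], item[1].strand != locus.strand,
                                      item[1].gene_id))
    distance, gene = candidates[0]
    if gene.strand == locus.strand and gene.start <= locus.start \
            and locus.end <= gene.end:
        return _unassigned(locus)  # internal to a same-strand gene
    relation = "SENSE_5P" if gene.strand == locus.strand else "ANTISENSE_3P"
    return OrientationCall(locus_id=locus.locus_id, family=locus.family,
                           target_gene_id=gene.gene_id, relation=relation,
                           distance_nt=distance, genome_id=locus.genome_id)


def _scan_candidates(locus: ResolvedRiboswitch, contig: _ContigIndex,
                     max_distance: int) -> list[tuple[int, GeneFeature]]:
    """Genes overlapping the locus or downstream of it in scan direction,
    with gap <= max_distance, as (clipped distance, gene) pairs."""
    out: list[tuple[int, GeneFeature]] = []
    if locus.strand == "+":
        # candidate iff gene.end > locus.start and gene.start - locus.end <= max_distance
        hi = bisect_right(contig.starts, locus.end + max_distance)
        lo = bisect_right(contig.max_end_upto, locus.start)
        for g in contig.genes[lo:hi]:
            if g.end > locus.start:
                out.append((max(0, g.start - locus.end), g))
    else:
        # candidate iff gene.start < locus.end and locus.start - gene.end <= max_distance
        hi = bisect_left(contig.starts, locus.end)
        lo = bisect_left(contig.max_end_upto, locus.start - max_distance)
        for g in contig.genes[lo:hi]:
            if g.end >= locus.start - max_distance:
                out.append((max(0, locus.start - g.end), g))
    return out


def _unassigned(locus: ResolvedRiboswitch) -> OrientationCall:
    return OrientationCall(locus_id=locus.locus_id, family=locus.family,
                           target_gene_id=None, relation="UNASSIGNED",
                           distance_nt=0, genome_id=locus.genome_id)


def classify_all(loci: Iterable[ResolvedRiboswitch],
                 genes: Iterable[GeneFeature],
                 max_distance: int = DEFAULT_MAX_DISTANCE) -> list[OrientationCall]:
    """One call per locus; loci and genes must come from one genome."""
    index = build_gene_index(genes)
    return [classify_orientation(loc, index, max_distance) for loc in loci]


def detect_tandem(calls: Iterable[OrientationCall]) -> list[TandemGroup]:
    """Group calls by (target gene, relation); groups of size >= 2 are
    tandem arrangements. ``same_family`` marks single-family groups."""
    grouped: dict[tuple[str, str, str], list[OrientationCall]] = {}
    for call in calls:
        if call.relation == "UNASSIGNED":
            continue
        grouped.setdefault((call.genome_id, call.target_gene_id, call.relation),
                           []).append(call)
    out = []
    for (genome_id, target, relation), members in sorted(grouped.items()):
        if len(members) < 2:
            continue
        out.append(TandemGroup(
            target_gene_id=target, relation=relation,
            member_locus_ids=tuple(sorted(c.locus_id for c in members)),
            same_family=len({c.family for c in members}) == 1,
            genome_id=genome_id))
    return out
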