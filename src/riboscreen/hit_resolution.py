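"""Collapse overlapping covariance-model hits and map Rfam classes to families.

Related covariance models (the six c-di-GMP models, the three cobalamin
models, ...) tend to recognize the same RNA sequence, so raw cmsearch output
carries stacks of overlapping hits at one locus. Hits sharing a contig and
strand are single-linkage clustered on interval overlap (one shared base is
enough) and each cluster is reduced to the member with the highest bit
score. Classes are then grouped into ligand-defined families for the
enrichment analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import IO, Iterable, Mapping

from .genome_io import RiboswitchHit

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FamilyMap:
    """Mapping from riboswitch class (covariance model) to family name."""

    mapping: Mapping[str, str]

    @property
    def families(self) -> frozenset[str]:
        return frozenset(self.mapping.values())

    @classmethod
    def from_stream(cls, stream: IO[str] | Iterable[str]) -> "FamilyMap":
        mapping: dict[str, str] = {}
        for lineno, raw in enumerate(stream, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0] or not parts[1]:
                raise ValueError(f"family map line {lineno}: expected "
                                 f"'class<TAB>family', got {line!r}")
            if parts[0] in mapping and mapping[parts[0]] != parts[1]:
                raise ValueError(f"family map line {lineno}: class {parts[0]} "
                                 f"mapped to two families")
            mapping[parts[0]] = parts[1]
        if not mapping:
            raise ValueError("family map is empty")
        return cls(mapping=mapping)

    @classmethod
    def load(cls, path: str | Path) -> "FamilyMap":
        with open(path) as fh:
            return cls.from_stream(fh)

    @classmethod
    def default(cls) -> "FamilyMap":
        """The shipped map: 50 Rfam riboswitch classes in 27 families."""
        ref = resources.files("riboscreen.data").joinpath("family_map.tsv")
        return cls.from_stream(ref.read_text().splitlines())


def map_family(model_class: str, fmap: FamilyMap, passthrough: bool = False) -> str:
    """Family of a riboswitch class; unknown classes error unless
    ``passthrough`` lets the class stand as its own family (with a warning)."""
    try:
        return fmap.mapping[model_class]
    except KeyError:
        if passthrough:
            log.warning("unknown riboswitch class %r kept as its own family",
                        model_class)
            return model_class
        raise KeyError(f"riboswitch class {model_class!r} not in family map; "
                       f"use passthrough=True to keep it as its own family")


@dataclass(frozen=True, slots=True)
class ResolvedRiboswitch:
    """One riboswitch locus: the best-scoring member of an overlap cluster."""

    locus_id: str
    family: str
    winning_class: str
    contig: str
    start: int
    end: int
    strand: str
    bit_score: float
    e_value: float
    genome_id: str = ""
    n_suppressed: int = 0

    # duck-type RiboswitchHit so resolution is idempotent on its own output
    @property
    def model_class(self) -> str:
        return self.winning_class


def resolve_overlaps(hits: Iterable[RiboswitchHit | ResolvedRiboswitch],
                     fmap: FamilyMap,
                     passthrough: bool = False) -> list[ResolvedRiboswitch]:
    """Single-linkage cluster same-contig same-strand overlapping hits and
    keep the highest-scoring member of each cluster.

    Ties break by lower E-value, then lexicographic class name. Hits on
    opposite strands never merge: orientation is the object of study.
    The sum of (1 + n_suppressed) over output loci equals the input count.
    """
    by_key: dict[tuple[str, str, str], list] = {}
    for h in hits:
        by_key.setdefault((h.genome_id, h.contig, h.strand), []).append(h)

    out: list[ResolvedRiboswitch] = []
    for (genome_id, contig, strand) in sorted(by_key):
        members = sorted(by_key[(genome_id, contig, strand)],
                         key=lambda h: (h.start, h.end, h.model_class))
        cluster: list = []
        cluster_end = -1
        for h in members + [None]:
            if h is not None and cluster and h.start < cluster_end:
                cluster.append(h)
                cluster_end = max(cluster_end, h.end)
                continue
            if cluster:
                out.append(_reduce(cluster, fmap, passthrough))
            if h is not None:
                cluster = [h]
                cluster_end = h.end
    return out


def _reduce(cluster: list, fmap: FamilyMap, passthrough: bool) -> ResolvedRiboswitch:
    winner = max(cluster, key=lambda h: (h.bit_score, -h.e_value,
                                         _neg_lex_key(h.model_class)))
    absorbed = sum(getattr(h, "n_suppressed", 0) for h in cluster) \
        + len(cluster) - 1
    return ResolvedRiboswitch(
        locus_id=f"{winner.genome_id}:{winner.contig}:{winner.start}-"
                 f"{winner.end}({winner.strand})",
        family=map_family(winner.model_class, fmap, passthrough),
        winning_class=winner.model_class, contig=winner.contig,
        start=winner.start, end=winner.end, strand=winner.strand,
        bit_score=winner.bit_score, e_value=winner.e_value,
        genome_id=winner.genome_id, n_suppressed=absorbed)


class _neg_lex_key(str):
    """Inverts lexicographic order so max() prefers the smaller class name."""

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)
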