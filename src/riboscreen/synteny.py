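"""Cross-genome context checks for suspect antisense targets.

Transposases, pseudogenes and small hypothetical ORFs called as antisense
targets often sit where a riboswitch was canonically leading a neighboring
gene before an insertion or a spurious ORF annotation appeared. For each
such call, the gene just beyond the suspect target in the riboswitch's
transcription direction — the gene the riboswitch would lead in 5'-sense
geometry were the suspect absent — is looked up in an ortholog table, and
each related genome votes: consistent if the ortholog there is the 5'-sense
target of a riboswitch of the same family. A call whose consistency
fraction reaches the threshold (default 0.5) is flagged for reassignment to
the neighboring gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import IO, Iterable, Mapping, Sequence

from .genome_io import GeneFeature
from .hit_resolution import ResolvedRiboswitch
from .orientation import OrientationCall

log = logging.getLogger(__name__)

DEFAULT_CONSISTENCY_THRESHOLD = 0.5

#: categories whose antisense calls are treated as suspect
SUSPECT_CATEGORIES = ("transposase", "pseudogene", "hypothetical",
                      "uncharacterized")


@dataclass(frozen=True)
class OrthologTable:
    """(genome_id, gene_id) -> ortholog group id; a gene has at most one."""

    mapping: Mapping[tuple[str, str], str]

    def group_of(self, genome_id: str, gene_id: str) -> str | None:
        return self.mapping.get((genome_id, gene_id))

    def members(self, group_id: str) -> list[tuple[str, str]]:
        return sorted(k for k, g in self.mapping.items() if g == group_id)

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self.mapping

    @classmethod
    def from_stream(cls, stream: IO[str] | Iterable[str]) -> "OrthologTable":
        mapping: dict[tuple[str, str], str] = {}
        for lineno, raw in enumerate(stream, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("genome_id\t"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"ortholog table line {lineno}: expected "
                                 f"genome_id, gene_id, group_id")
            key = (parts[0], parts[1])
            if key in mapping and mapping[key] != parts[2]:
                raise ValueError(f"ortholog table line {lineno}: gene "
                                 f"{key} in two groups")
            mapping[key] = parts[2]
        return cls(mapping=mapping)


@dataclass(frozen=True, slots=True)
class SyntenyReport:
    locus_id: str
    genome_id: str
    category: str
    target_gene_id: str
    upstream_gene_id: str | None
    ortholog_group: str | None
    n_compared: int
    n_consistent: int
    consistency: float
    reassigned: bool


def upstream_gene(locus: ResolvedRiboswitch, call: OrientationCall,
                  genes: Sequence[GeneFeature]) -> GeneFeature | None:
    """The next gene beyond the call's target in the riboswitch's
    transcription direction, or None at a contig edge.

    In canonical 5'-sense geometry this is the gene the riboswitch would
    lead if the suspect target were absent.
    """
    if call.target_gene_id is None:
        return None
    on_contig = sorted((g for g in genes if g.contig == locus.contig),
                       key=lambda g: (g.start, g.end, g.gene_id))
    idx = next((i for i, g in enumerate(on_contig)
                if g.gene_id == call.target_gene_id), None)
    if idx is None:
        return None
    step = 1 if locus.strand == "+" else -1
    nxt = idx + step
    if 0 <= nxt < len(on_contig):
        return on_contig[nxt]
    return None


def context_consistency(locus: ResolvedRiboswitch, call: OrientationCall,
                        category: str,
                        genes_by_genome: Mapping[str, Sequence[GeneFeature]],
                        calls_by_genome: Mapping[str, Sequence[OrientationCall]],
                        orthologs: OrthologTable,
                        threshold: float = DEFAULT_CONSISTENCY_THRESHOLD,
                        ) -> SyntenyReport:
    """Score one suspect call against the ortholog contexts of its
    would-be canonical target."""
    up = upstream_gene(locus, call, genes_by_genome.get(call.genome_id, ()))
    group = None if up is None else orthologs.group_of(call.genome_id, up.gene_id)
    n_compared = n_consistent = 0
    if group is not None:
        sense_targets = {
            gid: {(c.target_gene_id, c.family)
                  for c in calls_by_genome.get(gid, ())
                  if c.relation == "SENSE_5P"}
            for gid in calls_by_genome}
        for genome_id, gene_id in orthologs.members(group):
            if genome_id == call.genome_id:
                continue
            n_compared += 1
            if (gene_id, call.family) in sense_targets.get(genome_id, set()):
                n_consistent += 1
    consistency = n_consistent / n_compared if n_compared else 0.0
    return SyntenyReport(
        locus_id=call.locus_id, genome_id=call.genome_id, category=category,
        target_gene_id=call.target_gene_id,
        upstream_gene_id=None if up is None else up.gene_id,
        ortholog_group=group, n_compared=n_compared, n_consistent=n_consistent,
        consistency=consistency,
        reassigned=n_compared > 0 and consistency >= threshold)


def batch_context_report(calls: Iterable[OrientationCall],
                         categories: Mapping[tuple[str, str], str],
                         loci: Mapping[str, ResolvedRiboswitch],
                         genes_by_genome: Mapping[str, Sequence[GeneFeature]],
                         calls_by_genome: Mapping[str, Sequence[OrientationCall]],
                         orthologs: OrthologTable,
                         threshold: float = DEFAULT_CONSISTENCY_THRESHOLD,
                         ) -> tuple[list[SyntenyReport], dict[str, dict[str, float]]]:
    """One report per suspect antisense call, plus per-category summaries.

    ``categories`` maps (genome_id, gene_id) to the assigned category; only
    calls on SUSPECT_CATEGORIES genes are scored. The summary gives, per
    category, the fraction of calls flagged for reassignment and the mean
    consistency across cases.
    """
    reports: list[SyntenyReport] = []
    for call in sorted(calls, key=lambda c: c.locus_id):
        if call.relation != "ANTISENSE_3P":
            continue
        category = categories.get((call.genome_id, call.target_gene_id))
        if category not in SUSPECT_CATEGORIES:
            continue
        reports.append(context_consistency(
            loci[call.locus_id], call, category, genes_by_genome,
            calls_by_genome, orthologs, threshold))
    summary: dict[str, dict[str, float]] = {}
    for cat in SUSPECT_CATEGORIES:
        sub = [r for r in reports if r.category == cat]
        if not sub:
            continue
        summary[cat] = {
            "n_cases": float(len(sub)),
            "reassigned_fraction": sum(r.reassigned for r in sub) / len(sub),
            "mean_consistency": sum(r.consistency for r in sub) / len(sub),
        }
    return reports, summary


def write_synteny_tsv(reports: Iterable[SyntenyReport], dest,
                      header_meta: Mapping[str, str] | None = None) -> None:
    with open(dest, "w") as fh:
        for key, value in (header_meta or {}).items():
            fh.write(f"# {key}: {value}\n")
        fh.write("locus_id\tgenome_id\tcategory\ttarget_gene_id\t"
                 "upstream_gene_id\tortholog_group\tn_compared\t"
                 "n_consistent\tconsistency\treassigned\n")
        for r in reports:
            fh.write("\t".join(map(str, (
                r.locus_id, r.genome_id, r.category, r.target_gene_id,
                r.upstream_gene_id or ".", r.ortholog_group or ".",
                r.n_compared, r.n_consistent, f"{r.consistency:.4f}",
                int(r.reassigned)))) + "\n")
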