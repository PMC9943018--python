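"""End-to-end orchestration of the screen over a file bundle."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

from . import genome_io
from .enrichment import (build_contingency, category_frequencies,
                         consistent_case_count, family_enrichment,
                         write_category_tsv, write_enrichment_tsv)
from .gene_categories import CategoryRuleSet, categorize_all
from .hit_resolution import FamilyMap, resolve_overlaps
from .orientation import classify_all, detect_tandem
from .synteny import OrthologTable, batch_context_report, write_synteny_tsv

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    max_distance_nt: int = 500
    min_real_gene_nt: int = 300
    consistency_threshold: float = 0.5
    family_map_path: str | None = None
    rules_path: str | None = None
    bh_correction: bool = False
    passthrough_families: bool = False
    seed: int = 0
    out_dir: str = "results"

    def __post_init__(self) -> None:
        if self.max_distance_nt < 0:
            raise ValueError("max_distance_nt must be >= 0")
        if not 0.0 <= self.consistency_threshold <= 1.0:
            raise ValueError("consistency_threshold must be in [0, 1]")

    def config_hash(self) -> str:
        # analysis parameters only: where the results land must not change
        # what they contain
        params = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        blob = json.dumps(params, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class PipelineResult:
    out_dir: Path
    representatives: list[str]
    loci_by_genome: dict
    calls_by_genome: dict
    contingency: object
    enrichment: list
    assignments: list
    category_table: object
    consistent_cases: int
    tandem_by_genome: dict
    synteny_reports: list
    synteny_summary: dict


def discover_bundle(bundle_dir: str | Path) -> dict:
    """Locate the standard bundle layout: genomes/*.gff3, hits/*.tblout,
    metadata.tsv, orthologs.tsv (the last two optional)."""
    bundle_dir = Path(bundle_dir)
    gffs = {p.stem: p for p in sorted((bundle_dir / "genomes").glob("*.gff3"))}
    tbls = {p.stem: p for p in sorted((bundle_dir / "hits").glob("*.tblout"))}
    if not gffs:
        raise FileNotFoundError(f"no GFF3 files under {bundle_dir}/genomes")
    meta = bundle_dir / "metadata.tsv"
    orth = bundle_dir / "orthologs.tsv"
    return {"gff3": gffs, "tblout": tbls,
            "metadata": meta if meta.exists() else None,
            "orthologs": orth if orth.exists() else None}


def run_all(bundle_dir: str | Path, config: PipelineConfig | None = None,
            ) -> PipelineResult:
    """Run every stage in order and write the result bundle.

    Stage order: representative selection, hit resolution, orientation
    classification, contingency + enrichment, categorization + frequency
    table, tandem detection, synteny context report. Outputs are TSV/BED
    files headed by the config hash and seed; a rerun on identical inputs
    is byte-identical.
    """
    config = config or PipelineConfig()
    inputs = discover_bundle(bundle_dir)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = {"config": config.config_hash(), "seed": str(config.seed)}

    fmap = FamilyMap.load(config.family_map_path) if config.family_map_path \
        else FamilyMap.default()
    rules = CategoryRuleSet.from_yaml(config.rules_path) if config.rules_path \
        else CategoryRuleSet.default()

    if inputs["metadata"] is not None:
        with open(inputs["metadata"]) as fh:
            metadata = genome_io.read_metadata(fh)
        representatives = [g for g in genome_io.select_representatives(metadata)
                           if g in inputs["gff3"]]
    else:
        representatives = sorted(inputs["gff3"])
    log.info("stage select_representatives: %d genomes", len(representatives))

    genes_by_genome, loci_by_genome, calls_by_genome = {}, {}, {}
    tandem_by_genome = {}
    all_calls, all_loci = [], {}
    for genome in representatives:
        with open(inputs["gff3"][genome]) as fh:
            genes = genome_io.read_gene_annotations(fh, genome)
        hits = []
        if genome in inputs["tblout"]:
            with open(inputs["tblout"][genome]) as fh:
                hits = genome_io.read_cm_hits(fh, genome)
        loci = resolve_overlaps(hits, fmap,
                                passthrough=config.passthrough_families)
        calls = classify_all(loci, genes, config.max_distance_nt)
        genes_by_genome[genome] = genes
        loci_by_genome[genome] = loci
        calls_by_genome[genome] = calls
        tandem_by_genome[genome] = detect_tandem(calls)
        all_calls.extend(calls)
        all_loci.update({loc.locus_id: loc for loc in loci})
    log.info("stage classify: %d loci, %d genomes", len(all_loci),
             len(representatives))

    genome_io.write_calls(all_calls, all_loci, out_dir / "calls.tsv",
                          out_dir / "calls.bed", header_meta=meta)

    contingency = build_contingency(all_calls)
    with open(out_dir / "contingency.tsv", "w") as fh:
        for key, value in meta.items():
            fh.write(f"# {key}: {value}\n")
        fh.write("family\tsense\tantisense\n")
        for fam, (s, a) in contingency.rows.items():
            fh.write(f"{fam}\t{s}\t{a}\n")
    enrichment = family_enrichment(contingency, bh_correction=config.bh_correction)
    write_enrichment_tsv(enrichment, out_dir / "enrichment.tsv", header_meta=meta)

    gene_index = {(g.genome_id, g.gene_id): g
                  for genes in genes_by_genome.values() for g in genes}
    orthologs = OrthologTable(mapping={})
    if inputs["orthologs"] is not None:
        with open(inputs["orthologs"]) as fh:
            orthologs = OrthologTable.from_stream(fh)
    assignments = categorize_all(all_calls, gene_index,
                                 set(orthologs.mapping), rules)
    with open(out_dir / "categories.tsv", "w") as fh:
        for key, value in meta.items():
            fh.write(f"# {key}: {value}\n")
        fh.write("genome_id\tgene_id\tcategory\tmatched_rule\n")
        for a in assignments:
            fh.write(f"{a.genome_id}\t{a.gene_id}\t{a.category}\t{a.matched_rule}\n")
    table = category_frequencies(assignments)
    write_category_tsv(table, out_dir / "category_table.tsv", header_meta=meta)
    consistent = consistent_case_count(table)

    with open(out_dir / "tandem.tsv", "w") as fh:
        for key, value in meta.items():
            fh.write(f"# {key}: {value}\n")
        fh.write("genome_id\ttarget_gene_id\trelation\tn_members\t"
                 "same_family\tmember_locus_ids\n")
        for genome in representatives:
            for g in tandem_by_genome[genome]:
                fh.write("\t".join((g.genome_id, g.target_gene_id, g.relation,
                                    str(len(g.member_locus_ids)),
                                    str(int(g.same_family)),
                                    ",".join(g.member_locus_ids))) + "\n")

    categories_map = {(a.genome_id, a.gene_id): a.category for a in assignments}
    reports, summary = batch_context_report(
        all_calls, categories_map, all_loci, genes_by_genome, calls_by_genome,
        orthologs, threshold=config.consistency_threshold)
    write_synteny_tsv(reports, out_dir / "synteny.tsv", header_meta=meta)
    with open(out_dir / "summary.json", "w") as fh:
        json.dump({"n_genomes": len(representatives),
                   "n_loci": len(all_loci),
                   "n_calls": len(all_calls),
                   "consistent_cases": consistent,
                   "synteny_summary": summary}, fh, indent=2, sort_keys=True)
        fh.write("\n")

    return PipelineResult(
        out_dir=out_dir, representatives=representatives,
        loci_by_genome=loci_by_genome, calls_by_genome=calls_by_genome,
        contingency=contingency, enrichment=enrichment,
        assignments=assignments, category_table=table,
        consistent_cases=consistent, tandem_by_genome=tandem_by_genome,
        synteny_reports=reports, synteny_summary=summary)
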