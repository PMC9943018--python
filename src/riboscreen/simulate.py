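"""Synthetic-genome generator with planted ground truth.

Generates the exact file dialects the readers accept — GFF3 annotations,
Infernal tblout hit tables, a genome metadata TSV and an ortholog TSV —
with every riboswitch planted in known geometry, so every pipeline stage
can be scored against the truth without downloading anything.

The generator plants geometry directly, not nucleotide sequence: no
downstream stage reads sequence, covariance-model search being consumed
only through its tabular output. Genes are laid left to right per contig
with lognormal lengths and geometric-like intergenic gaps; each planted
riboswitch is placed in canonical 5'-sense or 3'-antisense geometry at a
gap of at most 400 nt from its designated gene, safely inside the 500 nt
assignment rule. Overlapping lower-scoring decoy hits emulate the stacks
of related covariance models matching one locus; tandem pairs share one
target; suspect-category targets (transposase, pseudogene, hypothetical)
get ortholog scaffolding in related genomes where the would-be canonical
neighbor is 5'-sense regulated with a configurable probability.

Default rates mirror the observed scale of the screen: an overall
antisense base rate near 1.2%, with the most enriched family near 5.6%
(the 152/2706 ratio).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .gene_categories import CATEGORIES
from .hit_resolution import FamilyMap

DEFAULT_FAMILY_PLAN: dict[str, tuple[int, float]] = {
    "c-di-GMP": (50, 0.056),
    "Cobalamin": (80, 0.017),
    "TPP": (60, 0.0085),
    "SAM": (40, 0.0070),
    "Glycine": (30, 0.0101),
    "T-box": (30, 0.0067),
    "ykoK / M-box": (10, 0.0316),
}

DEFAULT_CATEGORY_PLAN: dict[str, int] = {
    "interconversion": 2, "cofactor": 2, "transporter": 2, "signaling": 2,
    "tf": 2, "transposase": 2, "pseudogene": 2, "uncharacterized": 2,
    "hypothetical": 4, "other": 2,
}

CATEGORY_PRODUCTS: dict[str, str] = {
    "interconversion": "4-guanidinobutanamide amidohydrolase AmyE",
    "cofactor": "cobalamin-dependent methionine synthase MetH",
    "transporter": "ABC-type transport system permease component",
    "signaling": "two-component signal transduction histidine kinase",
    "tf": "XRE family transcriptional regulator",
    "transposase": "IS4 family transposase",
    "pseudogene": "degenerate gene fragment",
    "uncharacterized": "uncharacterized protein",
    "hypothetical": "hypothetical protein",
    "other": "ribosomal protein L7/L12",
}


@dataclass(frozen=True)
class SimulationConfig:
    n_genomes: int = 10
    contigs_per_genome: int = 2
    genes_per_contig: int = 100
    gene_length_log_mean: float = math.log(900.0)
    gene_length_log_sigma: float = 0.45
    min_gene_length_nt: int = 100
    mean_intergenic_gap_nt: int = 150
    min_intergenic_gap_nt: int = 25
    family_plan: Mapping[str, tuple[int, float]] = field(
        default_factory=lambda: dict(DEFAULT_FAMILY_PLAN))
    decoy_overlap_probability: float = 0.3
    n_tandem_pairs: int = 7
    tandem_family: str = "Glycine"
    category_plan: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_PLAN))
    synteny_consistency_rate: float = 0.72
    n_related_genomes: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genomes < 1 or self.contigs_per_genome < 1 \
                or self.genes_per_contig < 3:
            raise ValueError("need >= 1 genome, >= 1 contig, >= 3 genes/contig")
        for fam, (count, p) in self.family_plan.items():
            if count < 0 or not 0.0 <= p <= 1.0:
                raise ValueError(f"family plan for {fam!r}: count >= 0 and "
                                 f"probability in [0, 1] required")
        if not 0.0 <= self.decoy_overlap_probability <= 1.0:
            raise ValueError("decoy_overlap_probability must be in [0, 1]")
        if not 0.0 <= self.synteny_consistency_rate <= 1.0:
            raise ValueError("synteny_consistency_rate must be in [0, 1]")
        if any(c not in CATEGORIES for c in self.category_plan):
            raise ValueError("category plan names an unknown category")
        if self.n_tandem_pairs < 0:
            raise ValueError("n_tandem_pairs must be >= 0")
        if self.mean_intergenic_gap_nt <= self.min_intergenic_gap_nt:
            raise ValueError("mean intergenic gap must exceed the minimum")


@dataclass(frozen=True, slots=True)
class PlantedRiboswitch:
    rs_id: str
    genome_id: str
    contig: str
    start: int
    end: int
    strand: str
    model_class: str
    family: str
    relation: str
    target_gene_id: str
    tandem_group: str | None
    has_decoy: bool


@dataclass(frozen=True, slots=True)
class PlantedSyntenyCase:
    genome_id: str
    target_gene_id: str
    category: str
    upstream_gene_id: str
    group_id: str
    n_related: int
    n_consistent: int


@dataclass
class PlantedTruth:
    riboswitches: list[PlantedRiboswitch]
    gene_categories: dict[tuple[str, str], str]
    synteny_cases: list[PlantedSyntenyCase]
    seed: int


@dataclass(frozen=True)
class Bundle:
    root: Path
    genome_ids: tuple[str, ...]

    def gff3_path(self, genome_id: str) -> Path:
        return self.root / "genomes" / f"{genome_id}.gff3"

    def tblout_path(self, genome_id: str) -> Path:
        return self.root / "hits" / f"{genome_id}.tblout"

    @property
    def metadata_path(self) -> Path:
        return self.root / "metadata.tsv"

    @property
    def orthologs_path(self) -> Path:
        return self.root / "orthologs.tsv"


def sample_relations(family_plan: Mapping[str, tuple[int, float]],
                     rng: np.random.Generator) -> list[tuple[str, str]]:
    """Draw the planted orientation of every riboswitch in the plan.

    This is the sampler the generator itself uses; exposing it lets
    contingency-level studies run many replicates without genome layout.
    """
    out = []
    for family in sorted(family_plan):
        count, p_anti = family_plan[family]
        draws = rng.random(count) < p_anti
        out.extend((family, "ANTISENSE_3P" if d else "SENSE_5P") for d in draws)
    return out


# ---------------------------------------------------------------------------
# internal plan records

@dataclass
class _Plant:
    rs_id: str
    family: str
    model_class: str
    relation: str          # SENSE_5P / ANTISENSE_3P
    tandem_group: str | None = None
    n_members: int = 1     # 2 for a tandem pair


@dataclass
class _GenePlan:
    plant: _Plant | None = None
    category: str | None = None
    forced_strand: str | None = None
    forced_length: int | None = None
    product: str | None = None
    cog: str | None = None
    kind: str = "gene"
    ortholog_group: str | None = None


def _gene_id(contig: str, idx: int) -> str:
    return f"{contig}_g{idx:04d}"


class _SlotPool:
    """Free gene slots of one genome, allocated deterministically."""

    def __init__(self, genome_id: str, contigs: Sequence[str], n_genes: int,
                 rng: np.random.Generator):
        self.rng = rng
        self.free: dict[str, list[int]] = {c: list(range(n_genes)) for c in contigs}
        self.contigs = list(contigs)
        self.n_genes = n_genes
        self.genome_id = genome_id

    def take(self, interior: bool) -> tuple[str, int]:
        """Allocate a free gene slot.

        ``interior`` slots (antisense hosts) must have both neighbor slots
        free as well; the neighbors are reserved alongside so no later plant
        or ortholog partner lands next to a suspect target.
        """
        order = list(self.contigs)
        self.rng.shuffle(order)
        for contig in order:
            free = set(self.free[contig])
            if interior:
                candidates = [i for i in self.free[contig]
                              if 0 < i < self.n_genes - 1
                              and i - 1 in free and i + 1 in free]
            else:
                candidates = self.free[contig]
            if candidates:
                idx = int(self.rng.choice(candidates))
                self.free[contig].remove(idx)
                if interior:
                    self.free[contig].remove(idx - 1)
                    self.free[contig].remove(idx + 1)
                return contig, idx
        raise ValueError(f"genome {self.genome_id}: gene slots exhausted; "
                         f"raise genes_per_contig or contigs_per_genome")


def generate(config: SimulationConfig, out_dir: str | Path,
             ) -> tuple[Bundle, PlantedTruth]:
    """Write the file bundle and return it with the planted truth.

    Identical seed and config produce byte-identical output files: one
    seed sequence drives the planning stream and per-genome layout
    substreams spawned by counter.
    """
    out_dir = Path(out_dir)
    fmap = FamilyMap.default()
    classes_by_family: dict[str, list[str]] = {}
    for cls_name, fam in fmap.mapping.items():
        classes_by_family.setdefault(fam, []).append(cls_name)
    for fam in config.family_plan:
        if fam not in classes_by_family:
            raise ValueError(f"family plan names unknown family {fam!r}")
    if config.tandem_family not in classes_by_family:
        raise ValueError(f"unknown tandem family {config.tandem_family!r}")

    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_genomes + 1)
    plan_rng = np.random.default_rng(children[0])

    genomes = [f"g{i:03d}" for i in range(config.n_genomes)]
    contigs = {g: [f"{g}_c{j}" for j in range(config.contigs_per_genome)]
               for g in genomes}
    pools = {g: _SlotPool(g, contigs[g], config.genes_per_contig, plan_rng)
             for g in genomes}
    plans: dict[str, dict[tuple[str, int], _GenePlan]] = {g: {} for g in genomes}

    def plan_of(genome: str, contig: str, idx: int) -> _GenePlan:
        return plans[genome].setdefault((contig, idx), _GenePlan())

    # --- riboswitch plan: relations drawn per family, hosts round-robin ---
    rs_counter = 0
    antisense_cases: list[tuple[str, str, int, _Plant]] = []  # genome, contig, idx
    placements: list[tuple[str, str, int, _Plant]] = []

    def new_plant(family: str, relation: str, tandem_group: str | None = None,
                  n_members: int = 1, model_class: str | None = None) -> _Plant:
        nonlocal rs_counter
        rs_counter += 1
        if model_class is None:
            model_class = str(plan_rng.choice(sorted(classes_by_family[family])))
        return _Plant(rs_id=f"rs{rs_counter:05d}", family=family,
                      model_class=model_class, relation=relation,
                      tandem_group=tandem_group, n_members=n_members)

    for i, (family, relation) in enumerate(
            sample_relations(config.family_plan, plan_rng)):
        genome = genomes[i % len(genomes)]
        plant = new_plant(family, relation)
        contig, idx = pools[genome].take(interior=relation == "ANTISENSE_3P")
        gp = plan_of(genome, contig, idx)
        gp.plant = plant
        placements.append((genome, contig, idx, plant))
        if relation == "ANTISENSE_3P":
            antisense_cases.append((genome, contig, idx, plant))

    for t in range(config.n_tandem_pairs):
        genome = genomes[t % len(genomes)]
        plant = new_plant(config.tandem_family, "ANTISENSE_3P",
                          tandem_group=f"T{t:03d}", n_members=2)
        contig, idx = pools[genome].take(interior=True)
        gp = plan_of(genome, contig, idx)
        gp.plant = plant
        placements.append((genome, contig, idx, plant))
        antisense_cases.append((genome, contig, idx, plant))

    # --- categories for antisense-targeted genes, cycling the plan ---
    # slots interleave round-robin across categories so even a handful of
    # antisense cases spans the whole plan
    remaining = {c: config.category_plan.get(c, 0) for c in CATEGORIES}
    slots: list[str] = []
    while any(remaining.values()):
        for c in CATEGORIES:
            if remaining[c] > 0:
                slots.append(c)
                remaining[c] -= 1
    gene_categories: dict[tuple[str, str], str] = {}
    synteny_cases: list[PlantedSyntenyCase] = []
    group_counter = 0

    for case_no, (genome, contig, idx, plant) in enumerate(antisense_cases):
        category = slots[case_no % len(slots)] if slots else "other"
        gp = plans[genome][(contig, idx)]
        gp.category = category
        gp.product = CATEGORY_PRODUCTS[category]
        gene = _gene_id(contig, idx)
        gene_categories[(genome, gene)] = category
        # strand decided now so the neighbor and geometry are fixed
        gp.forced_strand = str(plan_rng.choice(["+", "-"]))
        if category == "pseudogene":
            gp.kind = "pseudogene"
        elif category == "transposase":
            gp.cog = "COG3039"
        elif category == "hypothetical":
            gp.forced_length = int(plan_rng.integers(config.min_gene_length_nt, 300))
        elif category in ("uncharacterized", "other"):
            gp.forced_length = int(plan_rng.integers(400, 1200))

        if category == "uncharacterized":
            # a bona fide ortholog elsewhere, no riboswitch attached
            group_counter += 1
            group = f"OG{group_counter:04d}"
            gp.ortholog_group = group
            partner_genome = genomes[(genomes.index(genome) + 1) % len(genomes)]
            if partner_genome != genome:
                pc, pi = pools[partner_genome].take(interior=False)
                pgp = plan_of(partner_genome, pc, pi)
                pgp.ortholog_group = group
                pgp.product = CATEGORY_PRODUCTS["uncharacterized"]
                pgp.forced_length = int(plan_rng.integers(400, 1200))

        if category in ("transposase", "pseudogene", "hypothetical"):
            # canonical-neighbor scaffold across related genomes
            rs_strand = "-" if gp.forced_strand == "+" else "+"
            nb_idx = idx - 1 if gp.forced_strand == "+" else idx + 1
            nbp = plan_of(genome, contig, nb_idx)
            nbp.forced_strand = rs_strand
            group_counter += 1
            group = f"OG{group_counter:04d}"
            nbp.ortholog_group = group
            gi = genomes.index(genome)
            related = [genomes[(gi + 1 + r) % len(genomes)]
                       for r in range(min(config.n_related_genomes,
                                          len(genomes) - 1))]
            n_consistent = 0
            for rgenome in related:
                rc, ri = pools[rgenome].take(interior=False)
                rgp = plan_of(rgenome, rc, ri)
                rgp.ortholog_group = group
                if plan_rng.random() < config.synteny_consistency_rate:
                    n_consistent += 1
                    rplant = new_plant(plant.family, "SENSE_5P",
                                       model_class=plant.model_class)
                    rgp.plant = rplant
                    placements.append((rgenome, rc, ri, rplant))
            synteny_cases.append(PlantedSyntenyCase(
                genome_id=genome, target_gene_id=gene, category=category,
                upstream_gene_id=_gene_id(contig, nb_idx), group_id=group,
                n_related=len(related), n_consistent=n_consistent))

    # decoy decisions, one uniform draw per planted riboswitch member
    decoy_flags: dict[str, bool] = {}
    for genome, contig, idx, plant in placements:
        for m in range(plant.n_members):
            decoy_flags[f"{plant.rs_id}.{m}"] = bool(
                plan_rng.random() < config.decoy_overlap_probability)

    # --- layout and file writing, one substream per genome ---
    (out_dir / "genomes").mkdir(parents=True, exist_ok=True)
    (out_dir / "hits").mkdir(parents=True, exist_ok=True)
    truth_rs: list[PlantedRiboswitch] = []
    orf_counts: dict[str, int] = {}
    ortholog_rows: list[tuple[str, str, str]] = []

    for gi, genome in enumerate(genomes):
        rng = np.random.default_rng(children[gi + 1])
        gff_lines = ["##gff-version 3"]
        tbl_rows: list[tuple] = []
        n_genes = 0
        for contig in contigs[genome]:
            contig_genes, contig_hits, contig_truth = _layout_contig(
                genome, contig, plans[genome], config, rng, decoy_flags,
                classes_by_family)
            n_genes += len(contig_genes)
            contig_len = max(end for _, _, end, *_ in contig_genes) + 200
            gff_lines.append(f"##sequence-region {contig} 1 {contig_len}")
            for gid, start, end, strand, kind, attrs in contig_genes:
                gff_lines.append("\t".join((
                    contig, "riboscreen-sim", kind, str(start + 1), str(end),
                    ".", strand, ".", attrs)))
            tbl_rows.extend(contig_hits)
            truth_rs.extend(contig_truth)
        orf_counts[genome] = n_genes
        Bundle(out_dir, ()).gff3_path(genome).write_text("\n".join(gff_lines) + "\n")
        _write_tblout(Bundle(out_dir, ()).tblout_path(genome), tbl_rows)
        for (contig, idx), gp in sorted(plans[genome].items()):
            if gp.ortholog_group:
                ortholog_rows.append((genome, _gene_id(contig, idx),
                                      gp.ortholog_group))

    with open(out_dir / "metadata.tsv", "w") as fh:
        fh.write("genome_id\tspecies_key\torf_count\n")
        for i, genome in enumerate(genomes):
            fh.write(f"{genome}\tsp{i:03d}\t{orf_counts[genome]}\n")
    with open(out_dir / "orthologs.tsv", "w") as fh:
        fh.write("genome_id\tgene_id\tgroup_id\n")
        for row in sorted(ortholog_rows):
            fh.write("\t".join(row) + "\n")

    truth = PlantedTruth(riboswitches=truth_rs, gene_categories=gene_categories,
                         synteny_cases=synteny_cases, seed=config.seed)
    _write_truth(out_dir, truth)
    return Bundle(out_dir, tuple(genomes)), truth


def _layout_contig(genome: str, contig: str,
                   plan: Mapping[tuple[str, int], _GenePlan],
                   config: SimulationConfig, rng: np.random.Generator,
                   decoy_flags: Mapping[str, bool],
                   classes_by_family: Mapping[str, Sequence[str]]):
    """Place genes and their planted riboswitches left to right."""
    genes, hits, truth = [], [], []
    cursor = int(rng.integers(50, 150))
    mean_extra = config.mean_intergenic_gap_nt - config.min_intergenic_gap_nt

    def sample_gap() -> int:
        return config.min_intergenic_gap_nt + int(rng.geometric(1.0 / mean_extra))

    def sample_len() -> int:
        raw = int(rng.lognormal(config.gene_length_log_mean,
                                config.gene_length_log_sigma))
        return max(config.min_gene_length_nt, raw)

    def emit_rs(plant: _Plant, member: int, start: int, end: int, strand: str,
                target: str) -> None:
        score = float(np.round(rng.uniform(35.0, 85.0), 1))
        log_e = float(rng.uniform(-12.0, -4.0))
        hits.append((contig, plant.model_class, start, end, strand, score,
                     10.0 ** log_e))
        key = f"{plant.rs_id}.{member}"
        has_decoy = decoy_flags.get(key, False)
        if has_decoy:
            alts = [c for c in classes_by_family[plant.family]
                    if c != plant.model_class]
            decoy_class = sorted(alts)[0] if alts else plant.model_class
            shift = int(rng.integers(-20, 21))
            d_score = float(np.round(score - rng.uniform(2.0, 10.0), 1))
            hits.append((contig, decoy_class, start + shift, end + shift,
                         strand, d_score, 10.0 ** (log_e + float(rng.uniform(0.5, 3.0)))))
        truth.append(PlantedRiboswitch(
            rs_id=key, genome_id=genome, contig=contig, start=start, end=end,
            strand=strand, model_class=plant.model_class, family=plant.family,
            relation=plant.relation, target_gene_id=target,
            tandem_group=plant.tandem_group, has_decoy=has_decoy))

    for idx in range(config.genes_per_contig):
        gp = plan.get((contig, idx)) or _GenePlan()
        gid = _gene_id(contig, idx)
        strand = gp.forced_strand or str(rng.choice(["+", "-"]))
        length = gp.forced_length or sample_len()
        plant = gp.plant
        # a plant sits left of its gene when it transcribes rightward into
        # it: sense leader of a '+' gene, or antisense element of a '-' gene
        left_side = plant is not None and (
            (plant.relation == "SENSE_5P") == (strand == "+"))
        rs_strand = "+" if left_side else "-"
        rs_lens = [int(rng.integers(80, 151)) for _ in range(
            plant.n_members if plant else 0)]
        if plant and plant.n_members > 1:
            d_near = int(rng.integers(1, 101))
            d_gaps = [int(rng.integers(25, 51)) for _ in rs_lens[1:]]
        elif plant:
            d_near, d_gaps = int(rng.integers(1, 401)), []

        gap = sample_gap()
        if plant and left_side:
            extent = d_near + sum(rs_lens) + sum(d_gaps)
            gene_start = cursor + gap + extent
            edge = gene_start - d_near
            for m, (rl, dg) in enumerate(zip(rs_lens, [0] + d_gaps)):
                edge -= dg if m else 0
                emit_rs(plant, m, edge - rl, edge, rs_strand, gid)
                edge -= rl
        else:
            gene_start = cursor + gap
        gene_end = gene_start + length
        attrs = f"ID={gid};product={gp.product or 'conserved protein'}"
        if gp.cog:
            attrs += f";COG={gp.cog}"
        genes.append((gid, gene_start, gene_end, strand, gp.kind, attrs))
        cursor = gene_end
        if plant and not left_side:
            edge = gene_end + d_near
            for m, (rl, dg) in enumerate(zip(rs_lens, [0] + d_gaps)):
                edge += dg if m else 0
                emit_rs(plant, m, edge, edge + rl, rs_strand, gid)
                edge += rl
            cursor = edge
    hits.sort(key=lambda h: (h[0], h[2], h[3], h[1]))
    return genes, hits, truth


def _write_tblout(path: Path, rows: Iterable[tuple]) -> None:
    lines = ["# generated by riboscreen-sim",
             "#target name  accession  query name  accession  mdl  mdl-from  "
             "mdl-to  seq-from  seq-to  strand  trunc  pass  gc  bias  score  "
             "E-value  inc  description"]
    for contig, model, start, end, strand, score, evalue in rows:
        if strand == "+":
            frm, to = start + 1, end
        else:
            frm, to = end, start + 1
        lines.append(" ".join(map(str, (
            contig, "-", model, "-", "cm", 1, 100, frm, to, strand, "no", 1,
            "0.50", "0.0", f"{score:.1f}", f"{evalue:.2e}", "!", "-"))))
    path.write_text("\n".join(lines) + "\n")


def _write_truth(out_dir: Path, truth: PlantedTruth) -> None:
    with open(out_dir / "truth_riboswitches.tsv", "w") as fh:
        fh.write("rs_id\tgenome_id\tcontig\tstart\tend\tstrand\tmodel_class\t"
                 "family\trelation\ttarget_gene_id\ttandem_group\thas_decoy\n")
        for r in truth.riboswitches:
            fh.write("\t".join(map(str, (
                r.rs_id, r.genome_id, r.contig, r.start, r.end, r.strand,
                r.model_class, r.family, r.relation, r.target_gene_id,
                r.tandem_group or ".", int(r.has_decoy)))) + "\n")
    with open(out_dir / "truth_genes.tsv", "w") as fh:
        fh.write("genome_id\tgene_id\tcategory\n")
        for (genome, gene), cat in sorted(truth.gene_categories.items()):
            fh.write(f"{genome}\t{gene}\t{cat}\n")
    with open(out_dir / "truth_synteny.tsv", "w") as fh:
        fh.write("genome_id\ttarget_gene_id\tcategory\tupstream_gene_id\t"
                 "group_id\tn_related\tn_consistent\n")
        for c in truth.synteny_cases:
            fh.write("\t".join(map(str, (
                c.genome_id, c.target_gene_id, c.category, c.upstream_gene_id,
                c.group_id, c.n_related, c.n_consistent))) + "\n")


def score_recovery(truth: PlantedTruth,
                   loci_by_genome: Mapping[str, Sequence],
                   calls_by_genome: Mapping[str, Sequence],
                   assignments: Sequence,
                   tandem_by_genome: Mapping[str, Sequence],
                   synteny_reports: Sequence = (),
                   consistency_threshold: float = 0.5) -> dict[str, float]:
    """Per-stage exact-match recovery fractions against the planted truth."""
    loci_index = {}
    for genome, loci in loci_by_genome.items():
        for loc in loci:
            loci_index[(genome, loc.contig, loc.strand, loc.start, loc.end)] = loc
    calls_index = {}
    for genome, calls in calls_by_genome.items():
        for call in calls:
            calls_index[call.locus_id] = call

    n = len(truth.riboswitches)
    if n == 0:
        raise ValueError("truth contains no planted riboswitches")
    res_ok = ori_ok = tgt_ok = 0
    locus_of_rs: dict[str, str] = {}
    for r in truth.riboswitches:
        loc = loci_index.get((r.genome_id, r.contig, r.strand, r.start, r.end))
        if loc is None or loc.winning_class != r.model_class:
            continue
        res_ok += 1
        locus_of_rs[r.rs_id] = loc.locus_id
        call = calls_index.get(loc.locus_id)
        if call is None:
            continue
        if call.relation == r.relation:
            ori_ok += 1
        if call.target_gene_id == r.target_gene_id:
            tgt_ok += 1

    planted_groups = {}
    for r in truth.riboswitches:
        if r.tandem_group is not None:
            planted_groups.setdefault((r.genome_id, r.target_gene_id), set()) \
                .add(locus_of_rs.get(r.rs_id))
    detected_groups = {
        (g.genome_id, g.target_gene_id): set(g.member_locus_ids)
        for genome, groups in tandem_by_genome.items() for g in groups
        if g.relation == "ANTISENSE_3P"}
    tandem_ok = sum(1 for key, members in planted_groups.items()
                    if detected_groups.get(key) == members)

    cat_index = {(a.genome_id, a.gene_id): a.category for a in assignments}
    cat_ok = sum(1 for key, cat in truth.gene_categories.items()
                 if cat_index.get(key) == cat)

    report = {
        "n_planted": float(n),
        "resolution": res_ok / n,
        "orientation_relation": ori_ok / n,
        "target_gene": tgt_ok / n,
        "category": cat_ok / len(truth.gene_categories)
        if truth.gene_categories else 1.0,
        "tandem_detected": float(len(detected_groups)),
        "tandem_planted": float(len(planted_groups)),
        "tandem": tandem_ok / len(planted_groups) if planted_groups else 1.0,
    }
    if synteny_reports:
        expected = {(c.genome_id, c.target_gene_id):
                    c.n_related > 0 and
                    c.n_consistent / c.n_related >= consistency_threshold
                    for c in truth.synteny_cases}
        seen = {}
        for rep in synteny_reports:
            seen[(rep.genome_id, rep.target_gene_id)] = rep.reassigned
        ok = sum(1 for key, exp in expected.items() if seen.get(key) == exp)
        report["reassignment"] = ok / len(expected) if expected else 1.0
    return report
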