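import hashlib
from pathlib import Path

import numpy as np
import pytest

from riboscreen import genome_io, pipeline
from riboscreen.simulate import (SimulationConfig, generate, sample_relations,
                                 score_recovery)


def _tree_hash(root: Path) -> str:
    h = hashlib.sha256()
    for p in sorted(Path(root).rglob("*")):
        if p.is_file():
            h.update(p.relative_to(root).as_posix().encode())
            h.update(p.read_bytes())
    return h.hexdigest()


SMALL = dict(n_genomes=4, contigs_per_genome=1, genes_per_contig=60,
             family_plan={"TPP": (20, 0.2), "Glycine": (10, 0.2)},
             n_tandem_pairs=2, n_related_genomes=3)


class TestGenerate:
    def test_same_seed_byte_identical(self, tmp_path):
        generate(SimulationConfig(seed=7, **SMALL), tmp_path / "a")
        generate(SimulationConfig(seed=7, **SMALL), tmp_path / "b")
        generate(SimulationConfig(seed=8, **SMALL), tmp_path / "c")
        assert _tree_hash(tmp_path / "a") == _tree_hash(tmp_path / "b")
        assert _tree_hash(tmp_path / "a") != _tree_hash(tmp_path / "c")

    def test_degenerate_probability_plants_only_sense(self, tmp_path):
        cfg = SimulationConfig(seed=3, n_genomes=2, contigs_per_genome=1,
                               genes_per_contig=80,
                               family_plan={"FMN": (40, 0.0)},
                               n_tandem_pairs=0)
        _, truth = generate(cfg, tmp_path / "s")
        relations = [r.relation for r in truth.riboswitches]
        assert len(relations) == 40
        assert set(relations) == {"SENSE_5P"}

    def test_outputs_reparse_without_warnings(self, tmp_path, caplog):
        bundle, truth = generate(SimulationConfig(seed=5, **SMALL),
                                 tmp_path / "s")
        with caplog.at_level("WARNING"):
            for genome in bundle.genome_ids:
                with open(bundle.gff3_path(genome)) as fh:
                    genes = genome_io.read_gene_annotations(fh, genome)
                with open(bundle.tblout_path(genome)) as fh:
                    hits = genome_io.read_cm_hits(fh, genome)
                assert genes and hits
        assert caplog.text == ""

    def test_planted_gaps_within_assignment_rule(self, default_bundle,
                                                 default_pipeline):
        # planted geometry must never be lost to the 500 nt threshold
        _, truth, result = default_pipeline
        assert all(r.relation != "UNASSIGNED" for r in truth.riboswitches)
        called = {c.locus_id: c for calls in result.calls_by_genome.values()
                  for c in calls}
        for call in called.values():
            assert call.distance_nt <= 400

    def test_antisense_draws_match_binomial_scale(self):
        # plan-level sampler: n=10,000 at p=0.012 stays within 3 sigma of 120
        rng = np.random.default_rng(123)
        rels = sample_relations({"TPP": (10_000, 0.012)}, rng)
        n_anti = sum(r == "ANTISENSE_3P" for _, r in rels)
        sigma = (10_000 * 0.012 * 0.988) ** 0.5
        assert abs(n_anti - 120) <= 3 * sigma

    def test_infeasible_layout_fails_before_writing(self, tmp_path):
        cfg = SimulationConfig(seed=1, n_genomes=1, contigs_per_genome=1,
                               genes_per_contig=5,
                               family_plan={"TPP": (40, 0.5)},
                               n_tandem_pairs=0)
        out = tmp_path / "never"
        with pytest.raises(ValueError, match="exhausted"):
            generate(cfg, out)
        assert not out.exists()

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(family_plan={"TPP": (10, 1.5)})
        with pytest.raises(ValueError):
            SimulationConfig(decoy_overlap_probability=-0.1)
        with pytest.raises(ValueError):
            SimulationConfig(category_plan={"nonsense": 1})


class TestRecovery:
    def test_empty_truth_is_an_error(self):
        from riboscreen.simulate import PlantedTruth
        with pytest.raises(ValueError):
            score_recovery(PlantedTruth([], {}, [], 0), {}, {}, [], {})

    def test_decoy_resolution_recovered(self, tmp_path):
        cfg = SimulationConfig(seed=11, decoy_overlap_probability=1.0, **{
            k: v for k, v in SMALL.items()})
        bundle, truth = generate(cfg, tmp_path / "s")
        assert all(r.has_decoy for r in truth.riboswitches)
        result = pipeline.run_all(bundle.root, pipeline.PipelineConfig(
            out_dir=str(tmp_path / "out")))
        rec = score_recovery(truth, result.loci_by_genome,
                             result.calls_by_genome, result.assignments,
                             result.tandem_by_genome, result.synteny_reports)
        assert rec["resolution"] == 1.0
        # every decoy was absorbed: one suppressed hit per planted locus
        n_absorbed = sum(l.n_suppressed for loci in
                         result.loci_by_genome.values() for l in loci)
        assert n_absorbed == len(truth.riboswitches)

    def test_planted_synteny_rate_recovered(self, tmp_path):
        # >= 200 hypothetical suspect cases planted at 72% per-genome
        # consistency; the recovered mean consistency estimates the rate
        cfg = SimulationConfig(
            seed=404, n_genomes=8, contigs_per_genome=2, genes_per_contig=120,
            family_plan={"Glycine": (208, 1.0)}, n_tandem_pairs=0,
            category_plan={"hypothetical": 208},
            synteny_consistency_rate=0.72, n_related_genomes=5)
        bundle, truth = generate(cfg, tmp_path / "s")
        assert len(truth.synteny_cases) >= 200
        result = pipeline.run_all(bundle.root, pipeline.PipelineConfig(
            out_dir=str(tmp_path / "out")))
        summary = result.synteny_summary["hypothetical"]
        n_votes = sum(c.n_related for c in truth.synteny_cases)
        sigma = (0.72 * 0.28 / n_votes) ** 0.5
        assert summary["mean_consistency"] == pytest.approx(0.72,
                                                            abs=4 * sigma)
        # and the per-case reassignment flags match the planted outcomes
        rec = score_recovery(truth, result.loci_by_genome,
                             result.calls_by_genome, result.assignments,
                             result.tandem_by_genome, result.synteny_reports)
        assert rec["reassignment"] == 1.0
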