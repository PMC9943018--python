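import pytest

from riboscreen.genome_io import GeneFeature
from riboscreen.hit_resolution import ResolvedRiboswitch
from riboscreen.orientation import OrientationCall
from riboscreen.synteny import (OrthologTable, batch_context_report,
                                context_consistency, upstream_gene)


def _gene(gid, start, end, strand, genome="g0", contig="c"):
    return GeneFeature(gid, contig, start, end, strand, genome_id=genome)


def _locus(start, end, strand, genome="g0", contig="c"):
    return ResolvedRiboswitch(f"{genome}:{contig}:{start}-{end}({strand})",
                              "T-box", "T-box", contig, start, end, strand,
                              50.0, 1e-8, genome)


def _call(locus, target, relation="ANTISENSE_3P", family="T-box"):
    return OrientationCall(locus.locus_id, family, target, relation, 50,
                           locus.genome_id)


class TestUpstreamGene:
    # layout: geneU(+) [1000,2000) .. riboswitch(+) [2300,2400) ..
    # transposase(-) [2450,3200) .. bona fide gene(-) beyond? No: for a '+'
    # riboswitch the canonical lead is the NEXT gene rightward past the target.
    def test_next_gene_beyond_target_in_scan_direction(self):
        genes = [_gene("geneU", 1000, 2000, "+"),
                 _gene("tnp", 2450, 3200, "-"),
                 _gene("bona", 3500, 4600, "+")]
        locus = _locus(2300, 2400, "+")
        up = upstream_gene(locus, _call(locus, "tnp"), genes)
        assert up.gene_id == "bona"

    def test_leftward_scan_steps_left(self):
        genes = [_gene("bona", 100, 900, "-"),
                 _gene("hypo", 1200, 1400, "+")]
        locus = _locus(1500, 1600, "-")
        up = upstream_gene(locus, _call(locus, "hypo"), genes)
        assert up.gene_id == "bona"

    def test_contig_edge_and_single_gene_give_none(self):
        genes = [_gene("only", 1000, 2000, "-")]
        locus = _locus(2300, 2400, "+")
        assert upstream_gene(locus, _call(locus, "only"), genes) is None

    def test_unassigned_call_gives_none(self):
        locus = _locus(0, 100, "+")
        call = OrientationCall(locus.locus_id, "T-box", None, "UNASSIGNED",
                               0, "g0")
        assert upstream_gene(locus, call, [_gene("g", 500, 900, "+")]) is None


def _scaffold(n_related=5, n_consistent=4):
    """Focal genome g0: riboswitch(+) -> transposase(-) -> bona(+); related
    genomes carry the ortholog of bona, 5'-sense regulated in the first
    n_consistent of them."""
    genes_by_genome = {"g0": [_gene("geneU", 100, 900, "+"),
                              _gene("tnp", 2450, 3200, "-"),
                              _gene("bona", 3500, 4600, "+")]}
    locus = _locus(2300, 2400, "+")
    call = _call(locus, "tnp")
    calls_by_genome = {"g0": [call]}
    mapping = {("g0", "bona"): "OG1"}
    for i in range(n_related):
        genome = f"g{i + 1}"
        ortho = _gene("orth", 1000, 2100, "+", genome=genome)
        genes_by_genome[genome] = [ortho]
        mapping[(genome, "orth")] = "OG1"
        if i < n_consistent:
            rlocus = _locus(400, 500, "+", genome=genome)
            calls_by_genome[genome] = [_call(rlocus, "orth", "SENSE_5P")]
        else:
            calls_by_genome[genome] = []
    return locus, call, genes_by_genome, calls_by_genome, OrthologTable(mapping)


class TestContextConsistency:
    def test_four_of_five_reassigns(self):
        locus, call, genes, calls, orth = _scaffold(5, 4)
        rep = context_consistency(locus, call, "transposase", genes, calls, orth)
        assert (rep.n_compared, rep.n_consistent) == (5, 4)
        assert rep.consistency == pytest.approx(0.8)
        assert rep.reassigned and rep.upstream_gene_id == "bona"

    def test_zero_consistent_not_reassigned(self):
        locus, call, genes, calls, orth = _scaffold(5, 0)
        rep = context_consistency(locus, call, "transposase", genes, calls, orth)
        assert rep.consistency == 0.0 and not rep.reassigned

    def test_no_ortholog_group_is_vacuous(self):
        locus, call, genes, calls, _ = _scaffold(5, 4)
        empty = OrthologTable(mapping={})
        rep = context_consistency(locus, call, "transposase", genes, calls, empty)
        assert (rep.n_compared, rep.consistency, rep.reassigned) == (0, 0.0, False)

    def test_wrong_family_is_inconsistent(self):
        locus, call, genes, calls, orth = _scaffold(5, 5)
        other = {g: [OrientationCall(c.locus_id, "Glycine", c.target_gene_id,
                                     c.relation, c.distance_nt, c.genome_id)
                     for c in cs] if g != "g0" else cs
                 for g, cs in calls.items()}
        rep = context_consistency(locus, call, "transposase", genes, other, orth)
        assert rep.n_consistent == 0

    def test_genome_without_ortholog_changes_nothing(self):
        locus, call, genes, calls, orth = _scaffold(5, 4)
        base = context_consistency(locus, call, "transposase", genes, calls, orth)
        genes["g99"] = [_gene("stray", 10, 500, "+", genome="g99")]
        calls["g99"] = []
        again = context_consistency(locus, call, "transposase", genes, calls, orth)
        assert (again.n_compared, again.consistency) \
            == (base.n_compared, base.consistency)

    def test_reassignment_monotone_in_threshold(self):
        locus, call, genes, calls, orth = _scaffold(5, 3)
        flags = [context_consistency(locus, call, "transposase", genes, calls,
                                     orth, threshold=t).reassigned
                 for t in (0.9, 0.6, 0.3, 0.1)]
        # once set while lowering the threshold, never unset
        assert flags == sorted(flags)


class TestBatchReport:
    def test_only_suspect_categories_scored(self):
        locus, call, genes, calls, orth = _scaffold(5, 4)
        categories = {("g0", "tnp"): "transposase"}
        reports, summary = batch_context_report(
            [call], categories, {call.locus_id: locus}, genes, calls, orth)
        assert len(reports) == 1
        assert summary["transposase"]["reassigned_fraction"] == 1.0
        assert summary["transposase"]["mean_consistency"] == pytest.approx(0.8)

        categories = {("g0", "tnp"): "tf"}  # consistent class: not suspect
        reports, summary = batch_context_report(
            [call], categories, {call.locus_id: locus}, genes, calls, orth)
        assert reports == [] and summary == {}


class TestOrthologTable:
    def test_round_trip_and_duplicate_rejection(self):
        table = OrthologTable.from_stream(
            ["genome_id\tgene_id\tgroup_id", "g0\ta\tOG1", "g1\tb\tOG1"])
        assert table.group_of("g0", "a") == "OG1"
        assert table.members("OG1") == [("g0", "a"), ("g1", "b")]
        with pytest.raises(ValueError, match="two groups"):
            OrthologTable.from_stream(["g0\ta\tOG1", "g0\ta\tOG2"])
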