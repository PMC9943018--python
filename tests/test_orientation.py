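import numpy as np
import pytest

from riboscreen.genome_io import GeneFeature
from riboscreen.hit_resolution import ResolvedRiboswitch
from riboscreen.orientation import (OrientationCall, classify_all,
                                    classify_orientation, detect_tandem)


def _gene(gid, start, end, strand, contig="c", genome="g"):
    return GeneFeature(gid, contig, start, end, strand, genome_id=genome)


def _locus(start, end, strand, lid="L", family="TPP", contig="c", genome="g"):
    return ResolvedRiboswitch(lid, family, "TPP", contig, start, end, strand,
                              40.0, 1e-6, genome)


class TestClassifyOrientation:
    def test_sense_leader_geometry(self):
        call = classify_orientation(_locus(400, 520, "+"),
                                    [_gene("gA", 1000, 2000, "+")])
        assert (call.relation, call.target_gene_id, call.distance_nt) \
            == ("SENSE_5P", "gA", 480)

    def test_antisense_three_prime_geometry(self):
        # convergent: riboswitch transcribes leftward into the gene's 3' end
        call = classify_orientation(_locus(2100, 2220, "-"),
                                    [_gene("gA", 1000, 2000, "+")])
        assert (call.relation, call.target_gene_id, call.distance_nt) \
            == ("ANTISENSE_3P", "gA", 100)

    def test_distance_threshold(self):
        call = classify_orientation(_locus(2700, 2820, "-"),
                                    [_gene("gA", 1000, 2000, "+")],
                                    max_distance=500)
        assert call.relation == "UNASSIGNED" and call.target_gene_id is None

    def test_contained_in_same_strand_gene_is_internal(self):
        call = classify_orientation(_locus(1200, 1300, "+"),
                                    [_gene("gA", 1000, 2000, "+")])
        assert call.relation == "UNASSIGNED"

    def test_contained_in_opposite_strand_gene_is_antisense_at_zero(self):
        call = classify_orientation(_locus(1200, 1300, "-"),
                                    [_gene("gA", 1000, 2000, "+")])
        assert (call.relation, call.distance_nt) == ("ANTISENSE_3P", 0)

    def test_scan_is_directional(self):
        # gene strictly behind a '+' riboswitch is never its target
        call = classify_orientation(_locus(3000, 3100, "+"),
                                    [_gene("gA", 1000, 2000, "+")])
        assert call.relation == "UNASSIGNED"

    def test_nearest_gene_wins(self):
        genes = [_gene("near", 700, 900, "-"), _gene("far", 1100, 1400, "+")]
        call = classify_orientation(_locus(400, 520, "+"), genes)
        assert (call.target_gene_id, call.relation) == ("near", "ANTISENSE_3P")

    def test_missing_contig_warns_and_unassigns(self, caplog):
        with caplog.at_level("WARNING"):
            call = classify_orientation(
                _locus(0, 100, "+", contig="nope"),
                [_gene("gA", 1000, 2000, "+", contig="c")])
        assert call.relation == "UNASSIGNED"
        assert "absent" in caplog.text

    def test_invalid_relation_combination_rejected(self):
        with pytest.raises(ValueError):
            OrientationCall("L", "TPP", None, "SENSE_5P", 0)


class TestClassifyAllProperties:
    def _random_layout(self, rng, n_genes=20, n_loci=6, span=30_000):
        genes, pos = [], 0
        for i in range(n_genes):
            pos += int(rng.integers(50, 400))
            length = int(rng.integers(100, 1500))
            genes.append(_gene(f"g{i}", pos, pos + length,
                               "+" if rng.random() < 0.5 else "-"))
            pos += length
        loci = []
        for j in range(n_loci):
            start = int(rng.integers(0, span))
            loci.append(_locus(start, start + int(rng.integers(60, 160)),
                               "+" if rng.random() < 0.5 else "-", lid=f"L{j}"))
        return genes, loci

    def test_partition_translation_and_mirror(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            genes, loci = self._random_layout(rng)
            calls = classify_all(loci, genes)
            assert len(calls) == len(loci)  # totality

            shift = int(rng.integers(1, 10_000))
            genes_t = [_gene(g.gene_id, g.start + shift, g.end + shift,
                             g.strand) for g in genes]
            loci_t = [ResolvedRiboswitch(l.locus_id, l.family, l.winning_class,
                                         l.contig, l.start + shift,
                                         l.end + shift, l.strand, l.bit_score,
                                         l.e_value, l.genome_id)
                      for l in loci]
            assert classify_all(loci_t, genes_t) == calls  # translation

            M = 1_000_000
            flip = {"+": "-", "-": "+"}
            genes_m = [_gene(g.gene_id, M - g.end, M - g.start,
                             flip[g.strand]) for g in genes]
            loci_m = [ResolvedRiboswitch(l.locus_id, l.family, l.winning_class,
                                         l.contig, M - l.end, M - l.start,
                                         flip[l.strand], l.bit_score,
                                         l.e_value, l.genome_id)
                      for l in loci]
            mirrored = classify_all(loci_m, genes_m)
            for orig, mirr in zip(calls, mirrored):
                assert orig.relation == mirr.relation
                assert orig.distance_nt == mirr.distance_nt

    def test_empty_locus_set(self):
        assert classify_all([], [_gene("g", 0, 100, "+")]) == []


class TestDetectTandem:
    def _call(self, lid, target, relation="ANTISENSE_3P", family="Glycine"):
        return OrientationCall(lid, family, target, relation, 10, "g")

    def test_same_family_pair(self):
        groups = detect_tandem([self._call("L1", "gX"), self._call("L2", "gX")])
        (grp,) = groups
        assert grp.member_locus_ids == ("L1", "L2")
        assert grp.same_family and grp.relation == "ANTISENSE_3P"

    def test_mixed_family_pair(self):
        groups = detect_tandem([self._call("L1", "gX"),
                                self._call("L2", "gX", family="TPP")])
        assert groups[0].same_family is False

    def test_singletons_and_unassigned_make_no_groups(self):
        calls = [self._call("L1", "gX"), self._call("L2", "gY"),
                 OrientationCall("L3", "TPP", None, "UNASSIGNED", 0, "g")]
        assert detect_tandem(calls) == []

    def test_relation_separates_groups(self):
        calls = [self._call("L1", "gX"), self._call("L2", "gX", "SENSE_5P"),
                 self._call("L3", "gX", "SENSE_5P")]
        (grp,) = detect_tandem(calls)
        assert grp.relation == "SENSE_5P"
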