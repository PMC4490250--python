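"""Contact-to-locus mapping and multilayer graph assembly."""

import random

import pytest

from locushub.eqtl import EqtlResult, PopulationStat
from locushub.graph import (
    ChromosomeNamingError,
    ContactPair,
    TypedEdge,
    augment_loci_with_genes,
    build_graph,
    eqtl_edges,
    map_contacts_to_loci,
)
from locushub.io import load_worked_example
from locushub.ld import Locus


def _locus(lid, chrom, start, end, gwas=False):
    return Locus(lid, chrom, start, end, gwas_flag=gwas)


def _contact(cid, chrom_a, sa, ea, chrom_b, sb, eb):
    return ContactPair(cid, chrom_a, sa, ea, chrom_b, sb, eb)


THREE_LOCI = [
    _locus("L1", "1", 100_000, 110_000),
    _locus("L2", "1", 500_000, 510_000),
    _locus("L3", "2", 100_000, 110_000),
]


class TestMapContacts:
    def test_two_anchors_in_two_loci_one_edge(self):
        contacts = [_contact("c1", "1", 101_000, 102_000, "1", 501_000, 502_000)]
        (edge,) = map_contacts_to_loci(contacts, THREE_LOCI, flank=0)
        assert (edge.locus_u, edge.locus_v, edge.layer) == ("L1", "L2", "spatial")
        assert edge.evidence == ["c1"]

    def test_both_anchors_same_locus_is_dropped(self):
        contacts = [_contact("c1", "1", 101_000, 102_000, "1", 103_000, 104_000)]
        assert map_contacts_to_loci(contacts, THREE_LOCI, flank=0) == []

    def test_toy_contact_list_hand_oracle(self):
        """5 contacts over 3 loci: 2 informative, 2 duplicates, 1 outside."""
        contacts = [
            _contact("c1", "1", 101_000, 102_000, "1", 501_000, 502_000),  # L1-L2
            _contact("c2", "1", 105_000, 106_000, "1", 505_000, 506_000),  # L1-L2 dup
            _contact("c3", "1", 101_000, 102_000, "2", 101_000, 102_000),  # L1-L3
            _contact("c4", "1", 900_000, 901_000, "2", 101_000, 102_000),  # anchor outside
            _contact("c5", "2", 900_000, 901_000, "1", 900_000, 901_000),  # both outside
        ]
        edges = map_contacts_to_loci(contacts, THREE_LOCI, flank=0)
        assert len(edges) == 2
        by_pair = {(e.locus_u, e.locus_v): e for e in edges}
        assert by_pair[("L1", "L2")].evidence == ["c1", "c2"]
        assert by_pair[("L1", "L3")].evidence == ["c3"]

    def test_flank_extends_the_overlap(self):
        contacts = [_contact("c1", "1", 95_000, 96_000, "1", 501_000, 502_000)]
        assert map_contacts_to_loci(contacts, THREE_LOCI, flank=0) == []
        (edge,) = map_contacts_to_loci(contacts, THREE_LOCI, flank=10_000)
        assert (edge.locus_u, edge.locus_v) == ("L1", "L2")

    def test_chromosome_convention_mismatch_raises_without_autonormalize(self):
        contacts = [_contact("c1", "chr1", 101_000, 102_000, "chr1", 501_000, 502_000)]
        with pytest.raises(ChromosomeNamingError):
            map_contacts_to_loci(contacts, THREE_LOCI, auto_normalize=False)
        (edge,) = map_contacts_to_loci(contacts, THREE_LOCI, flank=0, auto_normalize=True)
        assert (edge.locus_u, edge.locus_v) == ("L1", "L2")

    def test_matches_brute_force_overlap_oracle(self):
        rng = random.Random(5)
        for _ in range(30):
            loci = [
                _locus(f"L{i}", str(rng.randint(1, 2)), s := rng.randrange(0, 900_000, 1000) + 1, s + 20_000)
                for i in range(6)
            ]
            contacts = []
            for c in range(12):
                sa = rng.randrange(0, 900_000, 500) + 1
                sb = rng.randrange(0, 900_000, 500) + 1
                contacts.append(
                    _contact(f"c{c}", str(rng.randint(1, 2)), sa, sa + 2000, str(rng.randint(1, 2)), sb, sb + 2000)
                )
            flank = rng.choice([0, 5000])
            got = {
                (e.locus_u, e.locus_v): sorted(e.evidence)
                for e in map_contacts_to_loci(contacts, loci, flank=flank)
            }
            # oracle: all-pairs interval check
            expected: dict[tuple[str, str], list[str]] = {}
            for contact in contacts:
                hits_a = [
                    l.locus_id
                    for l in loci
                    if l.chrom == contact.chrom_a
                    and contact.start_a <= l.end + flank
                    and contact.end_a >= l.start - flank
                ]
                hits_b = [
                    l.locus_id
                    for l in loci
                    if l.chrom == contact.chrom_b
                    and contact.start_b <= l.end + flank
                    and contact.end_b >= l.start - flank
                ]
                for u, v in {tuple(sorted((a, b))) for a in hits_a for b in hits_b if a != b}:
                    expected.setdefault((u, v), []).append(contact.contact_id)
            expected = {k: sorted(v) for k, v in expected.items()}
            assert got == expected


def _result(snp, probe, verdict):
    return EqtlResult(
        snp_id=snp,
        probe_id=probe,
        per_population=[PopulationStat("pop1", 0.5, 0.01, True)],
        verdict=verdict,
        rule_fired="replication" if verdict == "significant" else "none",
    )


class TestEqtlEdges:
    snp_map = {"rs1": "MYRF"}
    probe_map = {"usp6_probe": "USP6", "myrf_probe": "MYRF"}

    def test_significant_trans_result_becomes_edge(self):
        (edge,) = eqtl_edges([_result("rs1", "usp6_probe", "significant")], self.snp_map, self.probe_map)
        assert {edge.locus_u, edge.locus_v} == {"MYRF", "USP6"}
        assert edge.layer == "eqtl" and edge.evidence == ["rs1:usp6_probe"]

    def test_not_significant_yields_no_edge(self):
        assert eqtl_edges([_result("rs1", "usp6_probe", "not_significant")], self.snp_map, self.probe_map) == []

    def test_same_locus_result_yields_no_edge(self):
        assert eqtl_edges([_result("rs1", "myrf_probe", "significant")], self.snp_map, self.probe_map) == []

    def test_unmapped_probe_skipped_with_log(self, caplog):
        with caplog.at_level("WARNING"):
            out = eqtl_edges([_result("rs1", "mystery", "significant")], self.snp_map, self.probe_map)
        assert out == []
        assert any("unmapped" in r.message for r in caplog.records)


class TestBuildGraph:
    def test_figure_fixture_has_ten_nodes_nine_edges(self):
        loci, edges = load_worked_example("tm6sf2_hub")
        spatial = [e for e in edges if e.layer == "spatial"]
        functional = [e for e in edges if e.layer == "functional"]
        g = build_graph(spatial, [], functional, loci)
        assert g.number_of_nodes() == 10
        assert g.number_of_edges() == 9
        assert sum(1 for _, d in g.nodes(data=True) if d["gwas_flag"]) == 3

    def test_isolated_gwas_loci_stay_as_nodes(self):
        loci = [_locus("A", "1", 1, 10, gwas=True), _locus("B", "2", 1, 10, gwas=True)]
        g = build_graph([], [], [], loci)
        assert set(g.nodes) == {"A", "B"} and g.number_of_edges() == 0

    def test_same_pair_in_two_layers_gives_parallel_edges(self):
        loci = [_locus("A", "1", 1, 10), _locus("B", "2", 1, 10)]
        spatial = [TypedEdge("A", "B", "spatial", ["c1"])]
        eqtl = [TypedEdge("A", "B", "eqtl", ["rs1:p1"])]
        g = build_graph(spatial, eqtl, [], loci)
        assert g.number_of_edges() == 2
        assert {d["layer"] for _, _, d in g.edges(data=True)} == {"spatial", "eqtl"}

    def test_unknown_locus_reference_is_an_error_listing_offenders(self):
        loci = [_locus("A", "1", 1, 10)]
        with pytest.raises(ValueError, match="GHOST"):
            build_graph([TypedEdge("A", "GHOST", "spatial", ["c1"])], [], [], loci)

    def test_construction_is_order_independent(self):
        loci, edges = load_worked_example("tm6sf2_hub")
        spatial = [e for e in edges if e.layer == "spatial"]
        functional = [e for e in edges if e.layer == "functional"]
        g1 = build_graph(spatial, [], functional, loci)
        rng = random.Random(0)
        for _ in range(5):
            s2, f2, l2 = spatial[:], functional[:], loci[:]
            rng.shuffle(s2), rng.shuffle(f2), rng.shuffle(l2)
            g2 = build_graph(s2, [], f2, l2)
            assert set(g1.nodes) == set(g2.nodes)
            e1 = sorted((min(u, v), max(u, v), d["layer"]) for u, v, d in g1.edges(data=True))
            e2 = sorted((min(u, v), max(u, v), d["layer"]) for u, v, d in g2.edges(data=True))
            assert e1 == e2


class TestAugmentLoci:
    def test_annotation_only_genes_become_non_gwas_loci(self):
        snp_loci = [_locus("L1", "1", 100_000, 110_000, gwas=True)]
        genes = [("GENEX", "2", 5_000, 9_000), ("INSIDE", "1", 100_000, 120_000)]
        out = augment_loci_with_genes(snp_loci, genes)
        ids = {l.locus_id for l in out}
        assert ids == {"L1", "GENEX"}  # INSIDE overlaps L1, not duplicated
        genex = next(l for l in out if l.locus_id == "GENEX")
        assert not genex.gwas_flag
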