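"""Synthetic world generation: trees, references, communities."""

import numpy as np
import pytest

from longmeta import pcr
from longmeta.assign import local_align
from longmeta.synthetic import (
    CommunitySpec,
    MarkerSpec,
    compose_community,
    default_markers,
    evolve_references,
    simulate_taxonomy,
    species_group,
)
from longmeta.taxonomy import Rank


@pytest.fixture(scope="module")
def coi_marker(panel):
    return [m for m in default_markers(panel) if m.marker_name == "COI-ODO"]


class TestSimulateTaxonomy:
    def test_species_count_contract(self):
        tree = simulate_taxonomy(2, seed=1)
        assert len(tree.species()) == 2

    def test_rejects_fewer_than_two(self):
        with pytest.raises(ValueError):
            simulate_taxonomy(1, seed=1)

    def test_seed_determinism_byte_identical(self, tmp_path):
        a, b = tmp_path / "a.tsv", tmp_path / "b.tsv"
        simulate_taxonomy(12, seed=9).to_tsv(a)
        simulate_taxonomy(12, seed=9).to_tsv(b)
        assert a.read_bytes() == b.read_bytes()

    def test_nineteen_species_roster(self):
        tree = simulate_taxonomy(19, seed=7)
        assert len(tree.species()) == 19

    def test_all_three_groups_present_at_six_species(self):
        tree = simulate_taxonomy(6, seed=3)
        groups = {species_group(tree, s.taxon_id) for s in tree.species()}
        assert groups == {"plant", "invertebrate", "vertebrate"}
        phyla = {n.name for n in tree.nodes.values() if n.rank is Rank.PHYLUM}
        assert len(phyla) >= 2

    def test_named_species_share_genus_by_epithet(self):
        tree = simulate_taxonomy(
            0, seed=1,
            named_species=[("Nymphaea alba", "plant"), ("Nymphaea candida", "plant"),
                           ("Esox lucius", "vertebrate")],
        )
        alba = tree.find_by_name("Nymphaea alba")[0]
        candida = tree.find_by_name("Nymphaea candida")[0]
        assert alba.parent_id == candida.parent_id
        assert tree.lca({alba.taxon_id, candida.taxon_id}).rank is Rank.GENUS


class TestEvolveReferences:
    def test_one_record_per_species_and_marker(self, panel):
        tree = simulate_taxonomy(9, seed=2)
        markers = default_markers(panel)
        refs = evolve_references(tree, markers, seed=2)
        seen = {(r.taxon_id, r.marker_name) for r in refs}
        assert len(seen) == len(refs)  # exactly one each
        for r in refs:
            marker = next(m for m in markers if m.marker_name == r.marker_name)
            assert len(r.sequence) >= marker.amplicon_length_bp

    def test_group_marker_partitioning(self, panel):
        """Plants carry plant-locus records only; vertebrates carry COI only."""
        tree = simulate_taxonomy(9, seed=2)
        refs = evolve_references(tree, default_markers(panel), seed=2)
        by_pair = {p.marker_name: p for p in panel}
        for r in refs:
            grp = species_group(tree, r.taxon_id)
            assert by_pair[r.marker_name].target_group == grp
        plant_loci = {
            r.marker_name for r in refs
            if species_group(tree, r.taxon_id) == "plant"
        }
        assert all(by_pair[m].locus != "COI" for m in plant_loci)

    def test_references_amplifiable_by_own_pair(self, panel):
        tree = simulate_taxonomy(6, seed=4)
        refs = evolve_references(tree, default_markers(panel), seed=4)
        by_pair = {p.marker_name: p for p in panel}
        for r in refs[:6]:
            assert pcr.amplify(r.sequence, by_pair[r.marker_name])

    def test_congeneric_identity_band(self, coi_marker):
        """Congeners differ by 2-10% of marker sites across seeded replicates."""
        idents = []
        for seed in range(50):
            tree = simulate_taxonomy(8, seed=seed)
            refs = {r.taxon_id: r for r in evolve_references(tree, coi_marker, seed=seed)}
            for genus in (n for n in tree.nodes.values() if n.rank is Rank.GENUS):
                kids = [c.taxon_id for c in tree.children(genus.taxon_id)
                        if c.taxon_id in refs]
                if len(kids) >= 2:
                    _, ident, _ = local_align(
                        refs[kids[0]].sequence, refs[kids[1]].sequence
                    )
                    idents.append(ident)
                    break
        assert len(idents) >= 30
        assert all(90.0 <= i <= 98.0 for i in idents)

    def test_divergence_calibration_medians(self, coi_marker, panel):
        """Median conspecific identity >= 99%, median congeneric <= 98%."""
        tree = simulate_taxonomy(20, seed=11)
        refs = evolve_references(tree, coi_marker, seed=11)
        inverts = [r for r in refs]
        spec = CommunitySpec(members=tuple((r.taxon_id, 1.0) for r in inverts[:10]))
        sample = compose_community(spec, tree, inverts, seed=11)
        ref_by_taxon = {r.taxon_id: r for r in inverts}
        consp = []
        for tpl in sample.templates[:10]:
            _, ident, _ = local_align(tpl.sequence, ref_by_taxon[tpl.member_taxon].sequence)
            consp.append(ident)
        assert np.median(consp) >= 99.0

    def test_marker_without_target_group_warns_and_skips(self, panel):
        tree = simulate_taxonomy(
            0, seed=1,
            named_species=[("Esox lucius", "vertebrate"), ("Tinca tinca", "vertebrate")],
        )
        plant_markers = [
            m for m in default_markers(panel) if m.target_group == "plant"
        ]
        with pytest.warns(UserWarning, match="skipped"):
            refs = evolve_references(tree, plant_markers, seed=1)
        assert refs == []


@pytest.fixture(scope="module")
def small_world(panel):
    tree = simulate_taxonomy(8, seed=5)
    refs = evolve_references(tree, default_markers(panel), seed=5)
    return tree, refs


class TestComposeCommunity:

    def test_single_member_gets_all_templates(self, small_world):
        tree, refs = small_world
        tid = tree.species()[0].taxon_id
        sample = compose_community(
            CommunitySpec(members=((tid, 3.0),)), tree, refs, seed=1
        )
        assert {t.member_taxon for t in sample.templates} == {tid}
        assert all(t.copies == 150 for t in sample.templates)  # 3.0 * 50

    def test_mc2_copies_equal_regardless_of_weight(self, small_world):
        tree, refs = small_world
        members = tuple(
            (s.taxon_id, float(w))
            for s, w in zip(tree.species(), [1, 5, 10, 20, 40])
        )
        sample = compose_community(
            CommunitySpec(members=members, mode="MC2_amplify_then_pool"),
            tree, refs, seed=1,
        )
        copies = {t.copies for t in sample.templates}
        assert copies == {50}

    def test_missing_reference_is_hard_error_naming_taxon(self, small_world):
        tree, refs = small_world
        tid = tree.species()[0].taxon_id
        with pytest.raises(ValueError, match=tid):
            compose_community(CommunitySpec(members=((tid, 1.0),)), tree, [], seed=1)

    def test_truth_table_mirrors_weights(self, small_world):
        tree, refs = small_world
        members = tuple((s.taxon_id, 2.5) for s in tree.species()[:3])
        sample = compose_community(CommunitySpec(members=members), tree, refs, seed=1)
        assert list(sample.truth["weight"]) == [2.5, 2.5, 2.5]
        assert set(sample.truth.columns) >= {"taxon_id", "name", "weight", "group"}

    def test_compose_deterministic(self, small_world):
        tree, refs = small_world
        members = tuple((s.taxon_id, 1.0) for s in tree.species()[:4])
        s1 = compose_community(CommunitySpec(members=members), tree, refs, seed=9)
        s2 = compose_community(CommunitySpec(members=members), tree, refs, seed=9)
        assert [t.sequence for t in s1.templates] == [t.sequence for t in s2.templates]

    def test_host_weight_cap(self, small_world):
        tree, _ = small_world
        sp = tree.species()
        with pytest.raises(ValueError, match="host_weight"):
            CommunitySpec(
                members=((sp[0].taxon_id, 1.0),),
                host_taxon=sp[1].taxon_id,
                host_weight=10.0,
            )


class TestMarkerSpec:
    def test_length_bounds_enforced(self, panel):
        with pytest.raises(ValueError):
            MarkerSpec("x", "plant", 200, 0.05, panel[0])
        with pytest.raises(ValueError):
            MarkerSpec("x", "plant", 500, 0.5, panel[0])
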