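"""Orthogroup vetting, rescue, homology evidence, and overlap statistics."""

import pytest
from hypothesis import given, settings, strategies as st

from immunome.io import GeneMap, HomologyHit, OrthogroupTable, load_gene_map, \
    parse_interproscan_tsv, parse_orthogroups
from immunome.ortho import (
    SubsetDef, attach_homology_evidence, orthology_rescue, overlap_stats,
    percent, vet_families,
)
from immunome.rules import FamilyRule, RuleClause, screen_proteome

SPECIES = ["Aplysia", "Cgigas", "Bglabrata", "Human", "Drosophila"]
MOLLUSKS = {"Aplysia", "Cgigas", "Bglabrata"}
GASTROPODS = {"Aplysia", "Bglabrata"}


def table_from_presence(presence_rows):
    """Build an OrthogroupTable from per-row present-species sets."""
    rows = {}
    for i, present in enumerate(presence_rows):
        rows[f"OG{i:07d}"] = {
            sp: ([f"{sp}_g{i}"] if sp in present else []) for sp in SPECIES
        }
    return OrthogroupTable(SPECIES, rows)


class TestOverlapStats:
    def test_hand_built_table_tallies(self):
        presence = [
            set(SPECIES),                       # all five
            MOLLUSKS | {"Human"},               # mollusks + human, no fly
            MOLLUSKS,                           # mollusk-only
            GASTROPODS,                         # gastropod-only
            {"Aplysia"},                        # focal-unique
            {"Drosophila"},                     # other single species
        ]
        table = table_from_presence(presence)
        named = {
            "mollusk_human_not_fly": SubsetDef(
                include=frozenset({"Human"}), exclude=frozenset({"Drosophila"}),
                include_any=(frozenset(MOLLUSKS),)),
            "mollusk_only": SubsetDef(include=frozenset(MOLLUSKS), exact=True),
            "gastropod_only": SubsetDef(include=frozenset(GASTROPODS), exact=True),
        }
        s = overlap_stats(table, "Aplysia", named)
        assert s.total_orthogroups == 6
        assert s.at_least_two_species == 4
        assert s.all_species == 1
        assert s.single_species == 2
        assert s.focal_unique == 1
        # "common to mollusks and humans but not fly" also counts the
        # all-species-minus-fly style rows; here rows 1 only
        assert s.named == {"mollusk_human_not_fly": 1, "mollusk_only": 1,
                           "gastropod_only": 1}

    def test_single_species_table(self):
        table = OrthogroupTable(["only"], {f"OG{i}": {"only": [f"g{i}"]}
                                           for i in range(4)})
        s = overlap_stats(table, "only")
        assert s.focal_unique == 4 and s.at_least_two_species == 0
        assert s.all_species == 4  # every orthogroup spans the single species

    def test_unknown_species_hard_error(self):
        table = table_from_presence([{"Aplysia"}])
        with pytest.raises(ValueError, match="unknown focal species"):
            overlap_stats(table, "Octopus")
        with pytest.raises(ValueError, match="unknown species"):
            overlap_stats(table, "Aplysia",
                          {"bad": SubsetDef(include=frozenset({"Octopus"}))})

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.sets(st.sampled_from(SPECIES), min_size=1), min_size=1,
                    max_size=30))
    def test_partition_property(self, presence):
        table = table_from_presence(presence)
        s = overlap_stats(table, "Aplysia")
        assert s.at_least_two_species + s.single_species == s.total_orthogroups
        assert s.focal_unique <= s.single_species
        assert s.all_species <= s.at_least_two_species

    def test_percent_helper(self):
        assert percent(26209, 26658) == 98.3
        assert percent(4606, 19353) == 23.8


class TestRescue:
    def test_rescue_without_domain_evidence(self):
        # TAB1-style case: the focal gene shares an orthogroup with a human
        # reference but carries only a generic domain the screen ignores
        table = OrthogroupTable(
            ["Aplysia", "Human"],
            {"OG1": {"Aplysia": ["XP_1", "XP_2"], "Human": ["hTAB1"]},
             "OG2": {"Aplysia": ["XP_3"], "Human": []}},
        )
        gm = GeneMap({"XP_1": "LOC_TAB1", "XP_2": "LOC_TAB1", "XP_3": "LOC_X"})
        refs = {"TAB1": {"Human": ["hTAB1"]}}
        rescued = orthology_rescue("TAB1", refs, table, set(), gene_map=gm,
                                   focal_species="Aplysia")
        assert rescued == {"LOC_TAB1"}

    def test_family_without_references_rescues_nothing(self):
        table = table_from_presence([set(SPECIES)])
        assert orthology_rescue("F", {}, table, set()) == set()

    def test_rescue_equals_brute_force_set_algebra(self, rng):
        n_og = 25
        rows = {}
        all_focal = []
        ref_ids = []
        for i in range(n_og):
            focal = [f"A_g{i}_{k}" for k in range(int(rng.integers(0, 3)))]
            human = [f"H_g{i}"] if rng.random() < 0.5 else []
            rows[f"OG{i}"] = {"Aplysia": focal, "Human": human}
            all_focal.extend(focal)
            if human and rng.random() < 0.4:
                ref_ids.append(human[0])
        table = OrthogroupTable(["Aplysia", "Human"], rows)
        refs = {"F": {"Human": ref_ids}}
        matched = {g for g in all_focal if rng.random() < 0.3}
        got = orthology_rescue("F", refs, table, matched,
                               focal_species="Aplysia")
        ref_ogs = {table.orthogroup_of(r) for r in ref_ids}
        expected = {
            g for og in ref_ogs if og
            for g in table.members(og, "Aplysia") if g not in matched
        }
        assert got == expected

    def test_rescue_disjoint_from_screen(self, bundle, catalog):
        hits, _ = parse_interproscan_tsv(bundle.ips_tsv)
        gene_map = load_gene_map(bundle.gene_map_tsv)
        table = parse_orthogroups(bundle.orthogroups_tsv)
        results = screen_proteome(hits, catalog)
        from immunome.rules import collapse_to_genes
        counts, _ = collapse_to_genes(results, gene_map)
        for family, c in counts.items():
            rescued = orthology_rescue(
                family, bundle.truth.reference_genes, table, c.gene_ids,
                gene_map=gene_map, focal_species="Aplysia")
            assert rescued.isdisjoint(c.gene_ids)


class TestVetting:
    def test_planted_families_all_orthology_supported(self, bundle, catalog):
        hits, _ = parse_interproscan_tsv(bundle.ips_tsv)
        gene_map = load_gene_map(bundle.gene_map_tsv)
        table = parse_orthogroups(bundle.orthogroups_tsv)
        results = screen_proteome(hits, catalog)
        entries, rejects = vet_families(
            results, gene_map, table, bundle.truth.reference_genes, catalog,
            focal_species="Aplysia")
        assert rejects == []
        got = {(e.gene_id, e.family) for e in entries}
        want = set(bundle.truth.gene_to_family.items())
        assert got == want
        assert all(e.evidence.shares_orthogroup_with_reference for e in entries)
        assert all(e.evidence.orthogroup_id ==
                   bundle.truth.gene_to_orthogroup[e.gene_id] for e in entries)

    def test_empty_reference_catalog_keeps_screen_with_false_flags(
            self, bundle, catalog):
        hits, _ = parse_interproscan_tsv(bundle.ips_tsv)
        gene_map = load_gene_map(bundle.gene_map_tsv)
        table = parse_orthogroups(bundle.orthogroups_tsv)
        results = screen_proteome(hits, catalog)
        entries, _ = vet_families(results, gene_map, table, {}, catalog,
                                  focal_species="Aplysia")
        assert {(e.gene_id, e.family) for e in entries} == \
            set(bundle.truth.gene_to_family.items())
        assert not any(e.evidence.shares_orthogroup_with_reference
                       for e in entries)

    def test_generic_domain_gene_retained_via_orthology(self):
        # IkB-style case: ankyrin-repeat-only candidate is indistinguishable
        # at the domain level; orthogroup sharing with the reference keeps it
        catalog = [FamilyRule("IkB", "tf", (
            RuleClause("relaxed", frozenset({"IPR002110"})),))]
        from immunome.io import DomainHit
        hits = [DomainHit("XP_1", "Pfam", "PF00023", start=10, stop=40,
                          interpro_acc="IPR002110")]
        gm = GeneMap({"XP_1": "LOC_IKB"})
        table = OrthogroupTable(
            ["Aplysia", "Human"],
            {"OG1": {"Aplysia": ["XP_1"], "Human": ["hNFKBIA"]}})
        refs = {"IkB": {"Human": ["hNFKBIA"]}}
        results = screen_proteome(hits, catalog)
        entries, rejects = vet_families(results, gm, table, refs, catalog,
                                        focal_species="Aplysia")
        assert len(entries) == 1
        assert entries[0].evidence.shares_orthogroup_with_reference
        # under the strict policy, orthology support still retains the gene
        entries2, rejects2 = vet_families(
            results, gm, table, refs, catalog, focal_species="Aplysia",
            require_orthology_for_relaxed=True)
        assert len(entries2) == 1 and rejects2 == []

    def test_relaxed_only_gene_rejected_under_strict_policy(self):
        catalog = [FamilyRule("F", "c", (
            RuleClause("relaxed", frozenset({"IPR000001"})),))]
        from immunome.io import DomainHit
        hits = [DomainHit("XP_1", "x", "s", start=1, stop=9,
                          interpro_acc="IPR000001")]
        gm = GeneMap({"XP_1": "LOC_1"})
        table = OrthogroupTable(["Aplysia"], {"OG1": {"Aplysia": ["XP_1"]}})
        results = screen_proteome(hits, catalog)
        entries, rejects = vet_families(
            results, gm, table, {}, catalog, focal_species="Aplysia",
            require_orthology_for_relaxed=True)
        assert entries == [] and len(rejects) == 1

    def test_vetting_independent_of_row_and_list_order(self, bundle, catalog):
        hits, _ = parse_interproscan_tsv(bundle.ips_tsv)
        gene_map = load_gene_map(bundle.gene_map_tsv)
        table = parse_orthogroups(bundle.orthogroups_tsv)
        shuffled_rows = dict(reversed(list(table.rows.items())))
        table2 = OrthogroupTable(table.species, {
            og: {sp: list(reversed(ids)) for sp, ids in cells.items()}
            for og, cells in shuffled_rows.items()
        })
        results = screen_proteome(hits, catalog)
        e1, _ = vet_families(results, gene_map, table,
                             bundle.truth.reference_genes, catalog,
                             focal_species="Aplysia")
        e2, _ = vet_families(results, gene_map, table2,
                             bundle.truth.reference_genes, catalog,
                             focal_species="Aplysia")
        assert e1 == e2


class TestHomologyEvidence:
    def _entries(self):
        from immunome.ortho import ImmunomeEntry, VettingEvidence
        ev = VettingEvidence("LOC_1", "VIgL", domain_clause="strict")
        return [ImmunomeEntry("LOC_1", "VIgL", "PRR/lectin", ev)]

    def test_frep_style_queries_enter_family(self):
        gm = GeneMap({"XP_F1": "LOC_FREP1", "XP_F2": "LOC_FREP2",
                      "XP_1": "LOC_1"})
        hits = [
            HomologyHit("XP_F1", "BgFREP2", 45.0, 300, 1e-40, 200.0),
            HomologyHit("XP_F2", "BgFREP3", 40.0, 280, 1e-30, 150.0),
        ]
        out = attach_homology_evidence(self._entries(), hits, "VIgL", gm)
        genes = {e.gene_id for e in out if e.evidence.homology_rescued}
        assert genes == {"LOC_FREP1", "LOC_FREP2"}

    def test_hit_above_threshold_ignored(self):
        gm = GeneMap({"XP_9": "LOC_9"})
        hits = [HomologyHit("XP_9", "s", 30.0, 100, 1e-3, 40.0)]
        out = attach_homology_evidence(self._entries(), hits, "VIgL", gm,
                                       max_evalue=1e-5)
        assert not any(e.gene_id == "LOC_9" for e in out)

    def test_flags_equal_brute_force_filtering(self, rng):
        gm = GeneMap({f"XP_{i}": f"LOC_{i}" for i in range(30)})
        hits = []
        for i in range(30):
            for j in range(int(rng.integers(1, 4))):
                hits.append(HomologyHit(
                    f"XP_{i}", f"s{j}", 50.0, 100,
                    float(10.0 ** -rng.integers(0, 12)), 50.0))
        out = attach_homology_evidence([], hits, "F", gm, max_evalue=1e-5)
        got = {e.gene_id for e in out}
        best = {}
        for h in hits:
            if h.query_id not in best or h.evalue < best[h.query_id]:
                best[h.query_id] = h.evalue
        expected = {f"LOC_{q.split('_')[1]}" for q, ev in best.items()
                    if ev <= 1e-5}
        assert got == expected
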