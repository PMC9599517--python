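"""AMG classification, partner colocation, T8SS extraction and typing."""

import itertools

import pytest

from phagepan.modules import (
    adjacency_implication,
    assign_family,
    classify_amgs,
    composition_table,
    compute_family_floors,
    extract_modules,
    filter_terminal,
    pairwise_count_ratio,
    partner_amg_pairs,
    region_fraction,
    station_frequencies,
)
from phagepan.records import Gene


def mk_genes(spec, genome="g"):
    """spec: list of (label, category, component[, strand]) tuples."""
    genes = []
    pos = 0
    for i, item in enumerate(spec):
        label, cat, comp = item[:3]
        strand = item[3] if len(item) > 3 else "+"
        genes.append(
            Gene(
                id=f"{genome}_g{i:03d}", genome_id=genome, start=pos, length=700,
                strand=strand, label=label, category=cat, component=comp,
            )
        )
        pos += 720
    return genes


HYP = ("hyp", "hypothetical", "none")
CORE = ("terminase", "core-viral", "none")


class TestClassifyAmgs:
    def test_cellular_function_is_amg_core_is_not(self):
        genes = mk_genes([
            ("thymidylate synthase", "AMG-hypermodification", "none"),
            CORE,
            HYP,
            ("purM", "AMG-nucleotide", "none"),
        ])
        amgs = classify_amgs(genes)
        assert [g.label for g in amgs] == ["thymidylate synthase", "purM"]

    def test_matches_planted_truth(self, small_sim):
        _, genomes, _ = small_sim
        for g in genomes[:5]:
            expected = {x.id for x in g.genes if x.category.startswith("AMG")}
            assert {x.id for x in classify_amgs(g.genes)} == expected


class TestAdjacencyImplication:
    def test_holds_when_always_flanked(self):
        genomes = {
            "g1": mk_genes([HYP, ("x", "AMG-other", "none"), ("y", "AMG-other", "none"), HYP]),
            "g2": mk_genes([("y", "AMG-other", "none"), ("x", "AMG-other", "none"), HYP]),
        }
        holds, cx = adjacency_implication(genomes, "x", "y", max_gap_genes=0)
        assert holds and cx == []

    def test_isolated_x_is_counterexample(self):
        genomes = {
            "ok": mk_genes([("x", "AMG-other", "none"), ("y", "AMG-other", "none")]),
            "bad": mk_genes([("x", "AMG-other", "none"), HYP, HYP, HYP,
                             ("y", "AMG-other", "none"), HYP, HYP, HYP]),
        }
        holds, cx = adjacency_implication(genomes, "x", "y", max_gap_genes=1)
        assert not holds and cx == ["bad"]

    def test_circular_adjacency_wraps_origin(self):
        genes = mk_genes([("x", "AMG-other", "none"), HYP, HYP,
                          ("y", "AMG-other", "none")])
        holds, _ = adjacency_implication({"g": genes}, "x", "y", max_gap_genes=0,
                                         circular=True)
        assert holds  # x at index 0, y at the last index: adjacent on a circle
        holds_linear, _ = adjacency_implication({"g": genes}, "x", "y",
                                                max_gap_genes=0, circular=False)
        assert not holds_linear

    def test_matches_exhaustive_scan_on_random_genomes(self, rng):
        labels = ["x", "y", "z", None]
        for trial in range(20):
            n = int(rng.integers(5, 15))
            spec = []
            for _ in range(n):
                lab = labels[int(rng.integers(0, len(labels)))]
                spec.append((lab, "AMG-other" if lab else "hypothetical", "none"))
            genomes = {"g": mk_genes(spec)}
            gap = int(rng.integers(0, 3))
            holds, cx = adjacency_implication(genomes, "x", "y", max_gap_genes=gap)
            # oracle: brute-force neighborhood scan over all x positions
            labs = [s[0] for s in spec]
            xs = [i for i, l in enumerate(labs) if l == "x"]
            ys = [i for i, l in enumerate(labs) if l == "y"]
            expect = True
            if xs:
                expect = any(
                    min((x - y) % n, (y - x) % n) <= gap + 1 for x in xs for y in ys
                ) if ys else False
            assert holds == expect, (labs, gap)


class TestPartnerPairs:
    def test_same_category_within_window_reported(self):
        genes = mk_genes([
            ("TS", "AMG-hypermodification", "none"),
            HYP,
            ("aG/PT-PPlase1", "AMG-hypermodification", "none"),
            HYP, HYP, HYP,
        ])
        pairs = partner_amg_pairs(genes, window_genes=5)
        assert pairs == [(genes[0].id, genes[2].id, 2)]

    def test_different_categories_not_reported(self):
        genes = mk_genes([
            ("TS", "AMG-hypermodification", "none"),
            ("purM", "AMG-nucleotide", "none"),
        ])
        assert partner_amg_pairs(genes) == []

    def test_matches_brute_force_filter(self, rng):
        cats = ["AMG-nucleotide", "AMG-other", "hypothetical", "core-viral"]
        for _ in range(10):
            n = int(rng.integers(6, 20))
            spec = [(f"l{i}", cats[int(rng.integers(0, len(cats)))], "none")
                    for i in range(n)]
            genes = mk_genes(spec)
            got = set((a, b) for a, b, _ in partner_amg_pairs(genes, window_genes=3))
            want = set()
            for i, j in itertools.combinations(range(n), 2):
                ci, cj = spec[i][1], spec[j][1]
                if ci == cj and ci.startswith("AMG"):
                    if min(j - i, n - (j - i)) <= 3:
                        want.add((genes[i].id, genes[j].id))
            assert got == want


T8SS = lambda comp, strand="+": (comp, "AMG-T8SS", comp, strand)


class TestExtractModules:
    def test_canonical_composition_forward(self):
        genes = mk_genes([HYP, T8SS("HK"), T8SS("CsgF"), T8SS("CsgG"),
                          T8SS("CsgA/B"), T8SS("FecR"), HYP])
        (inst,) = extract_modules(genes)
        assert inst.composition == "HK-CsgF-CsgG-CsgA/B-FecR"
        assert not inst.terminal
        assert inst.span == 5 * 720 - 20

    def test_reverse_strand_module_canonicalized(self):
        fwd = ["HK", "CsgF", "CsgG", "CsgA/B", "FecR"]
        genes = mk_genes([HYP] + [T8SS(c, "-") for c in reversed(fwd)] + [HYP])
        (inst,) = extract_modules(genes)
        assert inst.composition == "HK-CsgF-CsgG-CsgA/B-FecR"

    def test_no_components_no_modules(self):
        assert extract_modules(mk_genes([HYP, CORE, HYP])) == []

    def test_gap_tolerance_merges_and_splits(self):
        genes = mk_genes([T8SS("CsgF"), HYP, T8SS("CsgG"), HYP, HYP, T8SS("FecR")])
        insts = extract_modules(genes, max_gap_genes=1)
        assert [m.composition for m in insts] == ["CsgF-CsgG", "FecR"]
        insts0 = extract_modules(genes, max_gap_genes=0)
        assert [m.composition for m in insts0] == ["CsgF", "CsgG", "FecR"]

    def test_duplicate_components_preserved(self):
        genes = mk_genes([HYP, T8SS("HK"), T8SS("HK"), T8SS("CsgF"), T8SS("CsgG"),
                          T8SS("CsgA/B"), T8SS("FecR"), T8SS("CsgA/B"), HYP])
        (inst,) = extract_modules(genes)
        assert inst.composition == "HK-HK-CsgF-CsgG-CsgA/B-FecR-CsgA/B"

    def test_planted_modules_recovered_exactly(self, small_sim):
        _, genomes, truth = small_sim
        planted = {m.contig_id: m for m in truth.planted_modules}
        for g in genomes:
            insts = extract_modules(g.genes, contig_id=g.id)
            if g.id in planted:
                assert len(insts) == 1
                assert insts[0].components == planted[g.id].components
                assert (insts[0].start, insts[0].end) == (
                    planted[g.id].start, planted[g.id].end
                )
            else:
                assert insts == []


class TestFilterTerminal:
    def test_module_at_contig_start_removed(self):
        genes = mk_genes([T8SS("CsgF"), T8SS("CsgG"), HYP, HYP])
        insts = extract_modules(genes)
        assert insts[0].terminal
        assert filter_terminal(insts) == []

    def test_interior_module_retained(self):
        genes = mk_genes([HYP, T8SS("CsgF"), T8SS("CsgG"), HYP])
        insts = extract_modules(genes)
        assert filter_terminal(insts) == insts


class TestCompositionTable:
    def test_single_composition_is_100_percent(self):
        genes = mk_genes([HYP, T8SS("CsgF"), T8SS("CsgG"), HYP])
        table = composition_table(extract_modules(genes), by_family=False)
        assert table.loc[0, "percent"] == 100.0

    def test_count_ties_ranked_lexicographically(self):
        g1 = mk_genes([HYP, T8SS("CsgF"), T8SS("CsgG"), HYP], genome="c1")
        g2 = mk_genes([HYP, T8SS("CsgA/B"), HYP], genome="c2")
        table = composition_table(
            extract_modules(g1) + extract_modules(g2), by_family=False
        )
        assert list(table["composition"]) == ["CsgA/B", "CsgF-CsgG"]
        assert list(table["count"]) == [1, 1]

    def test_top_k_and_family_grouping(self):
        insts = []
        for i, fam in enumerate(["Podoviridae"] * 3 + ["Myoviridae"]):
            genes = mk_genes([HYP, T8SS("CsgF"), T8SS("CsgG"), HYP], genome=f"c{i}")
            (m,) = extract_modules(genes)
            m.family = fam
            insts.append(m)
        table = composition_table(insts, top_k=10, by_family=True)
        assert set(table["family"]) == {"Podoviridae", "Myoviridae"}
        assert (table["percent"] == 100.0).all()


class TestAssignFamily:
    def test_identical_to_reference_assigns_family(self, default_sim):
        _, genomes, truth = default_sim
        floors = compute_family_floors(truth.family_references)
        ref = truth.family_references[("CsgG", "Podoviridae")][0]
        assert assign_family(ref, truth.family_references, floors,
                             component="CsgG") == "Podoviridae"

    def test_below_floor_unassigned(self, default_sim, rng):
        _, genomes, truth = default_sim
        floors = compute_family_floors(truth.family_references)
        from phagepan.simulate import random_protein

        stranger = random_protein(
            len(truth.family_references[("CsgG", "Podoviridae")][0]), rng
        )
        assert assign_family(stranger, truth.family_references, floors,
                             component="CsgG") == "unassigned"

    def test_missing_floor_is_error(self, default_sim):
        _, _, truth = default_sim
        ref = truth.family_references[("CsgG", "Podoviridae")][0]
        with pytest.raises(KeyError):
            assign_family(ref, truth.family_references, floors={}, component="CsgG")

    def test_carrier_proteins_assign_to_their_family(self, default_sim):
        _, genomes, truth = default_sim
        floors = compute_family_floors(truth.family_references)
        carriers = {m.contig_id for m in truth.planted_modules}
        results = []
        for g in genomes:
            if g.id not in carriers:
                continue
            for x in g.genes:
                if x.component != "none":
                    results.append(
                        assign_family(x.protein, truth.family_references, floors,
                                      component=x.component)
                    )
        assert results
        # never assigned to the wrong family; floors may leave a few
        # borderline proteins unassigned, which is their purpose
        assert "Myoviridae" not in results
        assert results.count("Podoviridae") / len(results) > 0.9


class TestStationFrequencies:
    def test_arithmetic(self):
        profiles = station_frequencies(
            {"st1": {("CsgG", "Podoviridae"): 5}}, {"st1": 10000}
        )
        assert profiles[0].frequencies[("CsgG", "Podoviridae")] == pytest.approx(5e-4)

    def test_zero_hits_zero_frequency(self):
        profiles = station_frequencies({"st1": {}}, {"st1": 100})
        assert profiles[0].frequencies == {}

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            station_frequencies({"st1": {("CsgG", "Podoviridae"): 1}}, {"st1": 0})


class TestRegionFraction:
    def test_worked_example(self):
        genes = mk_genes([HYP, T8SS("CsgF"), HYP])
        (inst,) = extract_modules(genes)
        inst.end = inst.start + 4524
        assert region_fraction(58000, inst) == pytest.approx(7.8)

    def test_whole_genome_span(self):
        genes = mk_genes([T8SS("CsgF")])
        (inst,) = extract_modules(genes)
        inst.start, inst.end = 0, 1000
        assert region_fraction(1000, inst) == 100.0

    def test_planted_spans_match_truth(self, small_sim):
        _, genomes, truth = small_sim
        planted = {m.contig_id: m for m in truth.planted_modules}
        for g in genomes:
            if g.id not in planted:
                continue
            (inst,) = extract_modules(g.genes, contig_id=g.id)
            m = planted[g.id]
            assert region_fraction(len(g.seq), inst) == pytest.approx(
                100.0 * (m.end - m.start) / len(g.seq)
            )


class TestPairwiseCountRatio:
    def test_equal_counts(self):
        mean, sd = pairwise_count_ratio({"a": 4, "b": 4, "c": 4})
        assert mean == 1.0 and sd == 0.0

    def test_two_counts(self):
        mean, _ = pairwise_count_ratio({"a": 2, "b": 4})
        assert mean == 0.5

    def test_enumerated_three_counts(self):
        mean, sd = pairwise_count_ratio({"a": 3, "b": 4, "c": 5})
        assert mean == pytest.approx(0.71667, abs=1e-5)

    def test_zero_handling(self):
        mean, _ = pairwise_count_ratio({"a": 0, "b": 4})
        assert mean == 0.0
        with pytest.raises(ValueError):
            pairwise_count_ratio({"a": 0, "b": 0})
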