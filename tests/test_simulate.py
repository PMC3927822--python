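"""Ground-truth simulator: species trees, sequence evolution, events, emission."""

import filecmp
import json

import numpy as np
import pytest
from scipy import stats

from glxrs import genomes, phylo, simulate
from glxrs.simulate import SimEvent, SimulationConfig


class TestSpeciesTree:
    def test_deterministic_for_fixed_seed(self):
        cfg = SimulationConfig(seed=11)
        t1 = simulate.simulate_species_tree(cfg)
        t2 = simulate.simulate_species_tree(cfg)
        assert phylo.to_newick(t1) == phylo.to_newick(t2)

    def test_leaf_count_and_clade_labels(self):
        cfg = SimulationConfig(seed=2, n_clades=3, leaves_per_clade=4)
        tree = simulate.simulate_species_tree(cfg)
        leaves = [t.name for t in tree.tips()]
        assert len(leaves) == 12
        assert {simulate.clade_of(l) for l in leaves} == {"A", "B", "C"}

    def test_clades_are_monophyletic(self):
        from glxrs.concordance import is_monophyletic

        tree = simulate.simulate_species_tree(SimulationConfig(seed=5))
        leaves = [t.name for t in tree.tips()]
        for clade in "ABCD":
            members = {l for l in leaves if simulate.clade_of(l) == clade}
            assert is_monophyletic(tree, members)

    def test_total_length_decreases_with_birth_rate(self):
        def mean_total(rate):
            totals = []
            for seed in range(50):
                cfg = SimulationConfig(
                    seed=seed, birth_rate=rate, clade_separation=0.0
                )
                tree = simulate.simulate_species_tree(cfg)
                totals.append(
                    sum(n.length or 0 for n in tree.traverse(include_self=False))
                )
            return np.mean(totals)

        assert mean_total(0.5) > mean_total(4.0)

    def test_degenerate_sizes_rejected(self):
        with pytest.raises(ValueError):
            simulate.simulate_species_tree(SimulationConfig(n_clades=1))
        with pytest.raises(ValueError):
            simulate.simulate_species_tree(SimulationConfig(leaves_per_clade=1))


class TestEvolveSequences:
    def test_near_zero_rate_keeps_root_sequence(self):
        tree = phylo.parse_newick("(a:1,b:1,c:1);")
        rng = np.random.default_rng(0)
        root = simulate.random_protein(200, rng)
        out = simulate.evolve_sequences(tree, root, rate=1e-12, rng=rng)
        assert all(seq == root for seq in out.values())

    def test_p_distance_matches_closed_form(self):
        # two leaves at total path length t: E[p] = (19/20)(1 - exp(-20/19 t))
        t_total = 0.5
        tree = phylo.parse_newick(f"(a:{t_total / 2},b:{t_total / 2});")
        rng = np.random.default_rng(42)
        root = simulate.random_protein(10_000, rng)
        out = simulate.evolve_sequences(tree, root, rate=1.0, rng=rng)
        observed = np.mean(
            [x != y for x, y in zip(out["a"], out["b"])]
        )
        expected = (19 / 20) * (1 - np.exp(-(20 / 19) * t_total))
        lo = stats.binom.ppf(0.005, 10_000, expected) / 10_000
        hi = stats.binom.ppf(0.995, 10_000, expected) / 10_000
        assert lo <= observed <= hi

    def test_fixed_seed_reproducible(self):
        tree = phylo.parse_newick("((a:0.3,b:0.3):0.2,c:0.5);")
        root = simulate.random_protein(100, np.random.default_rng(1))
        out1 = simulate.evolve_sequences(tree, root, 1.0, np.random.default_rng(9))
        out2 = simulate.evolve_sequences(tree, root, 1.0, np.random.default_rng(9))
        assert out1 == out2

    def test_invalid_inputs_rejected(self):
        tree = phylo.parse_newick("(a:1,b:1);")
        with pytest.raises(ValueError):
            simulate.evolve_sequences(tree, "", 1.0, np.random.default_rng(0))
        with pytest.raises(ValueError):
            simulate.evolve_sequences(tree, "ACD", 0.0, np.random.default_rng(0))


class TestEvents:
    def test_no_events_all_native(self):
        ds = simulate.simulate(SimulationConfig(seed=3))
        verdicts = {ds.truth.expected_verdict(k) for k in ds.truth.records}
        assert verdicts == {"concordant_native"}

    def test_single_domain_hgt_yields_exactly_one_chimera(self):
        cfg = SimulationConfig(
            seed=3, events=(SimEvent("hgt_domain_C", "A_0", donor_clade="C"),)
        )
        ds = simulate.simulate(cfg)
        verdicts = [ds.truth.expected_verdict(k) for k in ds.truth.records]
        assert verdicts.count("chimera") == 1

    def test_duplication_adds_second_copy(self):
        cfg = SimulationConfig(seed=4, events=(SimEvent("duplication", "B_1"),))
        ds = simulate.simulate(cfg)
        assert "B_1.gltX2" in ds.n_seqs
        assert ds.truth.expected_verdict("B_1.gltX2") == "duplication"

    def test_losses_edit_inventory(self):
        cfg = SimulationConfig(
            seed=5, glnrs_clades=("A",),
            events=(
                SimEvent("loss_glnrs", "A_0"),
                SimEvent("loss_gatcab", "B_0"),
            ),
        )
        ds = simulate.simulate(cfg)
        genes_by_genome = {}
        for row in ds.inventory:
            genes_by_genome.setdefault(row.genome_id, set()).add(row.gene)
        assert "glnS" not in genes_by_genome["A_0"]
        assert "glnS" in genes_by_genome["A_1"]
        assert "gatA" not in genes_by_genome["B_0"]

    def test_missing_recipient_rejected(self):
        cfg = SimulationConfig(
            seed=1, events=(SimEvent("duplication", "Z_99"),)
        )
        with pytest.raises(ValueError, match="recipient"):
            simulate.simulate(cfg)

    def test_paper_like_truth_matches_scenario(self):
        ds = simulate.simulate(simulate.paper_like_scenario(7))
        expected = {
            "A_0.gltX2": "duplication",
            "B_0.gltX2": "chimera",
            "C_0.gltX1": "full_length_hgt",
        }
        for leaf, verdict in expected.items():
            assert ds.truth.expected_verdict(leaf) == verdict
        natives = [
            k for k in ds.truth.records
            if k not in expected
        ]
        assert all(
            ds.truth.expected_verdict(k) == "concordant_native" for k in natives
        )


class TestClassificationOfEmittedData:
    def test_zero_event_genomes_classify_single_copy_no_glnrs(self):
        ds = simulate.simulate(SimulationConfig(seed=8))
        invs = genomes.build_inventory(ds.inventory, phyla=("A", "B", "C", "D"))
        for inv in invs:
            assert genomes.classify_genome(inv).render() == "1|-|+"

    def test_paper_like_groups_match_config_intent(self):
        ds = simulate.simulate(simulate.paper_like_scenario(2))
        invs = {
            i.genome_id: i
            for i in genomes.build_inventory(
                ds.inventory, phyla=("A", "B", "C", "D")
            )
        }
        assert genomes.classify_genome(invs["A_0"]).render() == "2|+|+"
        assert genomes.classify_genome(invs["A_1"]).render() == "1|+|+"
        assert genomes.classify_genome(invs["B_0"]).render() == "2|-|+"
        assert genomes.classify_genome(invs["D_0"]).render() == "1|-|+"


class TestConfigFiles:
    def test_yaml_config_roundtrip(self, tmp_path):
        cfg_text = (
            "seed: 3\n"
            "n_clades: 4\n"
            "leaves_per_clade: 6\n"
            "glnrs_clades: [A]\n"
            "events:\n"
            "  - {type: duplication, recipient: A_0}\n"
            "  - {type: hgt_full, recipient: C_0, donor_clade: D}\n"
        )
        path = tmp_path / "sim.yaml"
        path.write_text(cfg_text)
        cfg = simulate.load_config(path)
        assert cfg.seed == 3
        assert cfg.glnrs_clades == ("A",)
        assert cfg.events[1] == SimEvent("hgt_full", "C_0", donor_clade="D")
        # the loaded config drives the simulator like a literal one
        ds = simulate.simulate(cfg)
        assert ds.truth.expected_verdict("C_0.gltX1") == "full_length_hgt"

    def test_json_config(self, tmp_path):
        path = tmp_path / "sim.json"
        path.write_text('{"seed": 2, "events": [{"type": "duplication", "recipient": "B_0"}]}')
        cfg = simulate.load_config(path)
        assert cfg.seed == 2 and cfg.events[0].type == "duplication"

    def test_unknown_event_type_rejected(self):
        with pytest.raises(ValueError, match="unknown event type"):
            simulate.config_from_dict(
                {"events": [{"type": "inversion", "recipient": "A_0"}]}
            )


class TestEmission:
    def test_byte_identical_across_runs(self, tmp_path):
        cfg = simulate.paper_like_scenario(6)
        p1 = simulate.emit_dataset(simulate.simulate(cfg), tmp_path / "run1")
        p2 = simulate.emit_dataset(simulate.simulate(cfg), tmp_path / "run2")
        assert set(p1) == set(p2)
        for key in p1:
            assert filecmp.cmp(p1[key], p2[key], shallow=False), key

    def test_inventory_row_count_is_total_gene_count(self, tmp_path):
        ds = simulate.simulate(SimulationConfig(seed=9, glnrs_clades=("A",)))
        paths = simulate.emit_dataset(ds, tmp_path / "d")
        rows = genomes.read_inventory(paths["inventory"])
        assert len(rows) == len(ds.inventory)

    def test_truth_json_covers_every_gene_copy(self, tmp_path):
        ds = simulate.simulate(simulate.paper_like_scenario(3))
        paths = simulate.emit_dataset(ds, tmp_path / "d")
        doc = json.loads(paths["truth"].read_text())
        assert set(doc["records"]) == set(ds.n_seqs)
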