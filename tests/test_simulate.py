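"""Synthetic-data generator: trees, networks, gene loss, hit tables."""

import numpy as np
import pytest

from trnreduce.network import NodeKind, RegType
from trnreduce.orthology import bidirectional_best_hits
from trnreduce.pic import leaf_labels
from trnreduce.simulate import (
    GenomeSizeModel,
    ReductionScenario,
    ReferenceSpec,
    emit_hit_tables,
    generate_scenario,
    simulate_brownian_trait,
    simulate_gene_loss,
    simulate_reference_network,
    simulate_tree,
)

SMALL_SPEC = ReferenceSpec(
    n_tf=20, n_sf=3, n_g=150, n_edges=320, n_nap=2
)


def root_to_leaf_depths(tree):
    out = {}
    for lf in tree.leaf_node_iter():
        d, node = 0.0, lf
        while node.parent_node is not None:
            d += node.edge.length
            node = node.parent_node
        out[lf.taxon.label] = d
    return out


class TestTree:
    def test_two_leaves_is_a_cherry(self):
        t = simulate_tree(2, seed=0)
        assert len(leaf_labels(t)) == 2
        assert len(t.seed_node.child_nodes()) == 2

    def test_seeded_determinism(self):
        a = simulate_tree(5, seed=7).as_string(schema="newick")
        b = simulate_tree(5, seed=7).as_string(schema="newick")
        c = simulate_tree(5, seed=8).as_string(schema="newick")
        assert a == b
        assert a != c

    def test_ultrametric(self):
        depths = root_to_leaf_depths(simulate_tree(64, seed=3))
        vals = np.array(list(depths.values()))
        assert np.allclose(vals, vals[0])

    def test_height_scaling(self):
        depths = root_to_leaf_depths(simulate_tree(16, seed=1, height=2.0))
        assert np.allclose(list(depths.values()), 2.0)

    def test_internal_node_count(self):
        t = simulate_tree(5, seed=2)
        internal = [n for n in t.preorder_node_iter() if not n.is_leaf()]
        assert len(internal) == 4


class TestReferenceNetwork:
    def test_exact_counts_small(self):
        net, _ = simulate_reference_network(SMALL_SPEC, seed=0)
        assert net.summary() == (20, 3, 150, 320)

    def test_full_scale_totals(self):
        net, ann = simulate_reference_network(ReferenceSpec(), seed=0)
        n_tf, n_sf, n_g, m = net.summary()
        assert (n_tf + n_sf + n_g, m) == (1784, 4058)
        assert len(ann) == 196

    def test_degenerate_minimal_spec(self):
        spec = ReferenceSpec(
            n_tf=2, n_sf=0, n_g=3, n_edges=5,
            type_proportions={"activator": 0.5, "repressor": 0.5,
                              "dual": 0.0, "unclassified": 0.0},
            n_nap=0,
        )
        net, _ = simulate_reference_network(spec, seed=1)
        assert net.summary() == (2, 0, 3, 5)

    def test_every_node_touched_by_an_edge(self):
        net, _ = simulate_reference_network(SMALL_SPEC, seed=5)
        touched = set()
        for e in net.edges:
            touched |= {e.regulator, e.target}
        assert touched == set(net.nodes)

    def test_hubs_are_preferentially_dual_and_nap_global_correlate(self):
        net, ann = simulate_reference_network(ReferenceSpec(), seed=2)
        degree = {tf: len(net.targets_of(tf)) for tf in ann}
        top20 = sorted(ann, key=lambda tf: -degree[tf])[:20]
        dual_share_top = np.mean(
            [ann[tf].reg_type is RegType.DUAL for tf in top20]
        )
        dual_share_all = np.mean(
            [a.reg_type is RegType.DUAL for a in ann.values()]
        )
        assert dual_share_top > dual_share_all
        naps = [tf for tf, a in ann.items() if a.is_nap]
        globals_ = {tf for tf, a in ann.items() if a.is_global}
        assert naps  # NAPs exist and are mostly global hubs
        assert np.mean([tf in globals_ for tf in naps]) > 0.5

    def test_type_proportions_respected(self):
        _, ann = simulate_reference_network(ReferenceSpec(), seed=0)
        counts = {t: 0 for t in RegType}
        for a in ann.values():
            counts[a.reg_type] += 1
        assert counts[RegType.ACTIVATOR] + counts[RegType.REPRESSOR] + \
            counts[RegType.DUAL] + counts[RegType.UNCLASSIFIED] == 196
        assert counts[RegType.UNCLASSIFIED] == pytest.approx(6, abs=1)
        assert counts[RegType.ACTIVATOR] > counts[RegType.DUAL]


@pytest.fixture(scope="module")
def small_ref():
    return simulate_reference_network(SMALL_SPEC, seed=0)


class TestGeneLoss:
    def test_zero_hazards_keep_everything(self, small_ref):
        net, ann = small_ref
        tree = simulate_tree(8, seed=0, height=1.0)
        hazards = dict.fromkeys(
            ["activator", "repressor", "dual", "unclassified", "sigma", "tg"], 0.0
        )
        presence, gene_ids, records = simulate_gene_loss(
            tree, net, ann, hazards, GenomeSizeModel(noise_sd=0.0), seed=1
        )
        for leaf, mask in presence.items():
            assert mask.all()
        sizes = [r.size_bp for r in records.values()]
        expected = 150_000 + 2516 * len(gene_ids)
        assert np.allclose(sizes, expected, rtol=1e-6)

    def test_extreme_activator_hazard_removes_only_activators(self, small_ref):
        net, ann = small_ref
        tree = simulate_tree(8, seed=0, height=1.0)
        hazards = {
            "activator": 1e6, "repressor": 0.0, "dual": 0.0,
            "unclassified": 0.0, "sigma": 0.0, "tg": 0.0,
        }
        presence, gene_ids, _ = simulate_gene_loss(
            tree, net, ann, hazards, seed=1
        )
        idx_act = [
            i for i, g in enumerate(gene_ids)
            if g in ann and ann[g].reg_type is RegType.ACTIVATOR
        ]
        idx_dual = [
            i for i, g in enumerate(gene_ids)
            if g in ann and ann[g].reg_type is RegType.DUAL
        ]
        for mask in presence.values():
            assert not mask[idx_act].any()
            assert mask[idx_dual].all()

    def test_mean_survival_matches_closed_form(self):
        """Mean per-type survival across leaves ~ exp(-lambda * depth)
        within 3 Monte-Carlo SDs (strict clock, common leaf depth)."""
        net, ann = simulate_reference_network(ReferenceSpec(), seed=0)
        tree = simulate_tree(64, seed=11, height=1.0)
        hazards = {
            "activator": 0.8, "repressor": 0.5, "dual": 0.1,
            "unclassified": 0.3, "sigma": 0.3, "tg": 0.3,
        }
        presence, gene_ids, _ = simulate_gene_loss(
            tree, net, ann, hazards, seed=12, rate_sd=0.0
        )
        by_type = {}
        for rt, lam in [(RegType.ACTIVATOR, 0.8), (RegType.REPRESSOR, 0.5),
                        (RegType.DUAL, 0.1)]:
            idx = [
                i for i, g in enumerate(gene_ids)
                if g in ann and ann[g].reg_type is rt
            ]
            fracs = [mask[idx].mean() for mask in presence.values()]
            mean_frac = float(np.mean(fracs))
            expected = np.exp(-lam * 1.0)
            # conservative MC sd: binomial across genes, ignoring tree correlation
            sd = np.sqrt(expected * (1 - expected) / len(idx))
            by_type[rt] = (mean_frac, expected, sd)
            assert abs(mean_frac - expected) < 6 * sd, by_type

    def test_loss_irreversible_along_tree(self, small_ref):
        net, ann = small_ref
        tree = simulate_tree(16, seed=4, height=1.5)
        hazards = dict.fromkeys(
            ["activator", "repressor", "dual", "unclassified", "sigma", "tg"], 0.5
        )
        presence, gene_ids, _ = simulate_gene_loss(tree, net, ann, hazards, seed=5)
        # sister leaves of a cherry: genes absent in both must include all
        # genes lost on the shared path; verified indirectly via phylogenetic
        # signal: closer leaves share more gene content
        leaves = sorted(presence)
        from itertools import combinations

        import dendropy

        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        dists, sims = [], []
        for a, b in combinations(leaves, 2):
            dists.append(pdm.distance(taxa[a], taxa[b]))
            sims.append(float((presence[a] & presence[b]).sum()))
        r = np.corrcoef(dists, sims)[0, 1]
        assert r < -0.3  # more distant pairs share fewer genes

    def test_categories_are_quartiles_of_gene_count(self, small_ref):
        net, ann = small_ref
        tree = simulate_tree(16, seed=6, height=1.0)
        hazards = dict.fromkeys(
            ["activator", "repressor", "dual", "unclassified", "sigma", "tg"], 0.4
        )
        presence, _, records = simulate_gene_loss(tree, net, ann, hazards, seed=7)
        counts = {leaf: int(mask.sum()) for leaf, mask in presence.items()}
        cats = {leaf: records[leaf].category for leaf in records}
        order = sorted(counts, key=lambda g: (counts[g], g))
        seen = [cats[g] for g in order]
        assert seen == sorted(
            seen,
            key=["tiny", "obligate", "host_restricted", "free_living"].index,
        )
        assert {c for c in cats.values()} == {
            "tiny", "obligate", "host_restricted", "free_living"
        }


class TestHitTables:
    def test_zero_decoys_round_trip_exactly(self):
        genes = [f"g{i:03d}" for i in range(50)]
        lengths = {g: 300 for g in genes}
        hb = emit_hit_tables(genes, "gen1", lengths, seed=0, decoy_fraction=0.0)
        omap = bidirectional_best_hits(hb.forward, hb.reverse, genome_id="gen1")
        assert {r for r, _ in omap.pairs} == set(genes)

    def test_decoys_do_not_change_the_map(self):
        genes = [f"g{i:03d}" for i in range(50)]
        lengths = {g: 300 for g in genes}
        clean = emit_hit_tables(genes, "gen1", lengths, seed=0, decoy_fraction=0.0)
        dirty = emit_hit_tables(genes, "gen1", lengths, seed=0, decoy_fraction=0.10)
        assert len(dirty.forward) > len(clean.forward)
        omap_clean = bidirectional_best_hits(clean.forward, clean.reverse)
        omap_dirty = bidirectional_best_hits(dirty.forward, dirty.reverse)
        assert {r for r, _ in omap_clean.pairs} == {r for r, _ in omap_dirty.pairs}

    def test_decoy_only_input_yields_empty_map(self):
        hb = emit_hit_tables([], "gen1", {}, seed=0, decoy_fraction=0.0)
        assert bidirectional_best_hits(hb.forward, hb.reverse).pairs == frozenset()


class TestBrownianTrait:
    def test_zero_rate_keeps_root_value(self):
        t = simulate_tree(8, seed=0)
        trait = simulate_brownian_trait(t, rate=0.0, root_value=7.0, seed=1)
        assert all(v == pytest.approx(7.0) for v in trait.values())

    def test_cherry_contrast_variance(self):
        import dendropy

        from trnreduce.pic import compute_contrasts, parse_newick

        t = parse_newick("(A:1,B:1);")
        contrasts = []
        for seed in range(600):
            trait = simulate_brownian_trait(t, rate=1.0, seed=seed)
            contrasts.append(trait["A"] - trait["B"])
        assert np.var(contrasts) == pytest.approx(2.0, rel=0.2)


class TestScenario:
    def test_seeded_byte_determinism(self, tmp_path):
        from trnreduce.simulate import write_scenario

        sc = ReductionScenario(
            n_genomes=8, reference_spec=SMALL_SPEC, seed=13
        )
        d1 = write_scenario(generate_scenario(sc), tmp_path / "a")
        d2 = write_scenario(generate_scenario(sc), tmp_path / "b")
        for f1 in sorted(d1.rglob("*")):
            if f1.is_file():
                f2 = d2 / f1.relative_to(d1)
                assert f1.read_bytes() == f2.read_bytes(), f1.name

    def test_scenario_shapes(self):
        sc = ReductionScenario(n_genomes=6, reference_spec=SMALL_SPEC, seed=2)
        b = generate_scenario(sc)
        assert len(b.presence) == 6
        assert len(b.genome_records) == 6
        assert len(b.hit_bundles) == 6
        assert b.reference.summary() == (20, 3, 150, 320)
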