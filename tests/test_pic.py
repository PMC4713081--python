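"""Independent contrasts: recursion, positivization, through-origin stats."""

import math

import dendropy
import numpy as np
import pytest

from trnreduce.pic import (
    DegenerateVarianceError,
    NewickError,
    compute_contrasts,
    contrast_diagnostics,
    correlation_through_origin,
    is_bifurcating,
    leaf_labels,
    parse_newick,
    positivize,
    prune_to_leaves,
    regression_through_origin,
    resolve_polytomies,
    write_newick,
)
from trnreduce.simulate import simulate_brownian_trait, simulate_tree


class TestNewick:
    def test_basic_parse(self):
        t = parse_newick("((A:1,B:1):1,C:2);")
        assert sorted(leaf_labels(t)) == ["A", "B", "C"]
        internal = [n for n in t.preorder_node_iter() if not n.is_leaf()]
        assert len(internal) == 2

    def test_single_leaf_accepted(self):
        t = parse_newick("(A:1);")
        assert leaf_labels(t) == ["A"]

    def test_unrooted_marker_rejected(self):
        with pytest.raises(NewickError):
            parse_newick("[&U] ((A:1,B:1):1,C:2);")

    def test_unbalanced_parens_rejected(self):
        with pytest.raises(NewickError):
            parse_newick("((A:1,B:1:1,C:2);")

    @pytest.mark.parametrize("seed", [0, 5])
    def test_random_tree_round_trip(self, seed):
        t = simulate_tree(20, seed=seed)
        text = write_newick(t)
        back = parse_newick(text)
        assert sorted(leaf_labels(back)) == sorted(leaf_labels(t))
        # branch lengths survive the round trip
        orig = {
            lf.taxon.label: lf.edge.length for lf in t.leaf_node_iter()
        }
        again = {
            lf.taxon.label: lf.edge.length for lf in back.leaf_node_iter()
        }
        for k in orig:
            assert again[k] == pytest.approx(orig[k], rel=1e-9)


class TestResolvePolytomies:
    def test_trifurcation_resolved(self):
        t = parse_newick("(A:1,B:1,C:1);")
        out = resolve_polytomies(t, seed=0)
        assert is_bifurcating(out)
        assert sorted(leaf_labels(out)) == ["A", "B", "C"]

    def test_already_bifurcating_unchanged(self):
        t = parse_newick("((A:1,B:1):1,C:2);")
        out = resolve_polytomies(t, seed=0)
        assert write_newick(out) == write_newick(t)

    def test_five_way_polytomy_adds_three_zero_nodes(self):
        t = parse_newick("(A:1,B:1,C:1,D:1,E:1);")
        out = resolve_polytomies(t, seed=1)
        internal = [n for n in out.preorder_node_iter() if not n.is_leaf()]
        assert len(internal) == 4  # root + 3 added
        added = [n for n in internal if n is not out.seed_node]
        assert all(n.edge.length == 0.0 for n in added)


class TestContrasts:
    def test_cherry_contrast(self):
        t = parse_newick("(A:1,B:1);")
        cs = compute_contrasts(t, {"A": 3.0, "B": 1.0})
        assert cs.n_contrasts == 1
        assert abs(cs.contrasts[0].standardized) == pytest.approx(2 / math.sqrt(2), abs=1e-5)

    def test_equal_traits_give_zero_contrasts(self):
        t = simulate_tree(10, seed=3)
        cs = compute_contrasts(t, {l: 5.0 for l in leaf_labels(t)})
        assert np.allclose(cs.standardized, 0.0)

    def test_three_taxon_hand_example(self):
        """Full Felsenstein recursion on ((A:1,B:1):1,C:2) with
        x = (1, 3, 6): contrasts, ancestral value, branch augmentation."""
        t = parse_newick("((A:1,B:1):1,C:2);")
        cs = compute_contrasts(t, {"A": 1.0, "B": 3.0, "C": 6.0})
        std = cs.standardized
        assert std == pytest.approx([-1.41421, -2.13809], abs=1e-5)
        # second contrast variance = augmented 1.5 + 2
        assert cs.contrasts[1].combined_variance == pytest.approx(3.5)
        # raw root contrast = ancestral AB value (2) - 6
        assert cs.contrasts[1].raw == pytest.approx(-4.0)

    def test_contrast_count_is_leaves_minus_one(self):
        for n in (2, 8, 33):
            t = simulate_tree(n, seed=n)
            trait = simulate_brownian_trait(t, seed=n)
            assert compute_contrasts(t, trait).n_contrasts == n - 1

    def test_missing_leaf_trait_rejected(self):
        t = parse_newick("(A:1,B:1);")
        with pytest.raises(KeyError):
            compute_contrasts(t, {"A": 1.0})

    def test_polytomy_rejected(self):
        t = parse_newick("(A:1,B:1,C:1);")
        with pytest.raises(ValueError, match="polytomies"):
            compute_contrasts(t, {"A": 1.0, "B": 2.0, "C": 3.0})

    def test_zero_variance_raises_without_epsilon(self):
        t = parse_newick("(A:0,B:0);")
        with pytest.raises(DegenerateVarianceError):
            compute_contrasts(t, {"A": 1.0, "B": 2.0}, zero_branch_epsilon=0.0)

    def test_zero_variance_perturbed_with_epsilon(self):
        t = parse_newick("(A:0,B:0);")
        cs = compute_contrasts(t, {"A": 1.0, "B": 2.0}, zero_branch_epsilon=1e-8)
        assert np.isfinite(cs.standardized).all()

    def test_agreement_with_dendropy_reference(self):
        """Cross-check standardized contrasts against dendropy's own PIC
        implementation on a simulated tree."""
        import dendropy
        from dendropy.model import continuous

        t = simulate_tree(16, seed=9)
        trait = simulate_brownian_trait(t, rate=2.0, seed=10)
        taxa = t.taxon_namespace
        cdm = dendropy.ContinuousCharacterMatrix.from_dict(
            {tx.label: [trait[tx.label]] for tx in taxa},
            taxon_namespace=taxa,
        )
        pic = continuous.PhylogeneticIndependentContrasts(tree=t, char_matrix=cdm)
        ctree = pic.contrasts_tree(0, state_values_as_node_labels=False)
        ref = sorted(
            abs(nd.pic[0]["pic_contrast_standardized"])
            for nd in ctree.postorder_internal_node_iter()
        )
        ours = sorted(abs(compute_contrasts(t, trait).standardized))
        assert ours == pytest.approx(ref, rel=1e-9)

    def test_brownian_contrast_variance_estimates_rate(self):
        """Defining PIC property: standardized contrasts of a Brownian
        trait are iid N(0, rate); their sample variance estimates it."""
        rate = 2.5
        variances = []
        for seed in range(12):
            t = simulate_tree(64, seed=100 + seed)
            trait = simulate_brownian_trait(t, rate=rate, seed=200 + seed)
            variances.append(float(np.var(compute_contrasts(t, trait).standardized, ddof=1)))
        assert np.mean(variances) == pytest.approx(rate, rel=0.2)

    def test_child_relabeling_flips_signs_only(self):
        t = simulate_tree(8, seed=4)
        trait = simulate_brownian_trait(t, seed=5)
        cs1 = compute_contrasts(t, trait).standardized
        swapped = t.clone(depth=1)
        for node in swapped.preorder_node_iter():
            kids = node.child_nodes()
            if len(kids) == 2:
                node.set_child_nodes(kids[::-1])
        cs2 = compute_contrasts(swapped, trait).standardized
        assert sorted(np.abs(cs1)) == pytest.approx(sorted(np.abs(cs2)))


class TestPositivize:
    def test_sign_rule(self):
        from trnreduce.pic import Contrast, ContrastSet

        cx = ContrastSet("x", (Contrast("n0", -1, -1, 1), Contrast("n1", 2, 2, 1)))
        cy = ContrastSet("y", (Contrast("n0", 3, 3, 1), Contrast("n1", 4, 4, 1)))
        px, py = positivize(cx, cy)
        assert list(px.standardized) == [1, 2]
        assert list(py.standardized) == [-3, 4]

    def test_identity_when_all_nonnegative(self):
        from trnreduce.pic import Contrast, ContrastSet

        cx = ContrastSet("x", (Contrast("n0", 1, 1, 1),))
        cy = ContrastSet("y", (Contrast("n0", 2, 2, 1),))
        assert positivize(cx, cy) == (cx, cy)

    def test_origin_correlation_invariant(self):
        from trnreduce.pic import Contrast, ContrastSet

        cx = ContrastSet("x", (Contrast("n0", -1, -1, 1), Contrast("n1", -1, -1, 1)))
        cy = ContrastSet("y", (Contrast("n0", -2, -2, 1), Contrast("n1", -2, -2, 1)))
        px, py = positivize(cx, cy)
        before = correlation_through_origin(cx, cy).r
        after = correlation_through_origin(px, py).r
        assert after == pytest.approx(before)
        assert (px.standardized >= 0).all()

    def test_mismatched_nodes_rejected(self):
        from trnreduce.pic import Contrast, ContrastSet

        cx = ContrastSet("x", (Contrast("n0", 1, 1, 1),))
        cy = ContrastSet("y", (Contrast("OTHER", 2, 2, 1),))
        with pytest.raises(ValueError):
            positivize(cx, cy)


class TestThroughOrigin:
    def test_proportional_gives_r_one(self):
        res = correlation_through_origin([1, 2], [2, 4])
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(0.0)

    def test_orthogonal_gives_r_zero(self):
        assert correlation_through_origin([1, 0], [0, 1]).r == pytest.approx(0.0)

    def test_direct_formula(self):
        res = correlation_through_origin([1, 2, 3], [1, 1, 1])
        assert res.r == pytest.approx(6 / math.sqrt(42), abs=1e-5)
        assert res.df == 2

    def test_exact_fit_slope(self):
        res = regression_through_origin([1, 2, 3], [3, 6, 9])
        assert res.slope == pytest.approx(3.0)
        assert res.p == pytest.approx(0.0)

    def test_orthogonal_slope_zero(self):
        assert regression_through_origin([1, 0], [0, 1]).slope == pytest.approx(0.0)

    def test_normal_equation_slope(self):
        res = regression_through_origin([1, 2, 3], [2, 3, 5])
        assert res.slope == pytest.approx(23 / 14, abs=1e-6)
        assert res.df == 2

    def test_zero_norm_rejected(self):
        with pytest.raises(ValueError):
            correlation_through_origin([0, 0], [1, 2])
        with pytest.raises(ValueError):
            regression_through_origin([0, 0], [1, 2])

    def test_star_tree_limit_matches_ordinary_correlation(self):
        """On a star phylogeny with equal terminal branches, contrasts
        are pairwise leaf differences; the through-origin |r| of the
        contrasts approximates the ordinary |r| of leaf values."""
        rng = np.random.default_rng(11)
        n = 200
        xs = rng.normal(size=n)
        ys = 0.8 * xs + 0.2 * rng.normal(size=n)
        newick = "(" + ",".join(f"L{i}:1" for i in range(n)) + ");"
        star = parse_newick(newick)
        tree = resolve_polytomies(star, seed=0)
        cx = compute_contrasts(tree, {f"L{i}": xs[i] for i in range(n)})
        cy = compute_contrasts(tree, {f"L{i}": ys[i] for i in range(n)})
        px, py = positivize(cx, cy)
        r_contrast = correlation_through_origin(px, py).r
        r_plain = float(np.corrcoef(xs, ys)[0, 1])
        assert abs(r_contrast) == pytest.approx(abs(r_plain), abs=0.1)


class TestUtilities:
    def test_prune_to_leaves(self):
        t = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        sub = prune_to_leaves(t, ["A", "C", "D"])
        assert sorted(leaf_labels(sub)) == ["A", "C", "D"]
        assert sorted(leaf_labels(t)) == ["A", "B", "C", "D"]  # original intact

    def test_diagnostics_report_shapiro(self):
        t = simulate_tree(32, seed=2)
        trait = simulate_brownian_trait(t, seed=3)
        d = contrast_diagnostics(compute_contrasts(t, trait))
        assert 0.0 <= d["shapiro_p"] <= 1.0
        assert d["n_contrasts"] == 31
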