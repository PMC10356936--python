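"""Module definitions: parsing, MCR evaluation, functional clustering."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from diazoscan.mcr import (
    ModuleParseError,
    Node,
    cluster_profiles,
    evaluate_mcr,
    linkage_to_newick,
    mcr_matrix,
    parse_module,
    serialize,
)


# ------------------------------------------------------------------ parsing

class TestParse:
    def test_single_leaf(self):
        assert parse_module("K00001").expression == Node("LEAF", ko="K00001")

    def test_space_is_and(self):
        node = parse_module("K00001 K00002").expression
        assert node == Node("AND", (Node("LEAF", ko="K00001"),
                                    Node("LEAF", ko="K00002")))

    def test_mixed_expression_ast(self):
        node = parse_module("(K00001,K00002) K00003+K00004 -K00005").expression
        expected = Node("AND", (
            Node("OR", (Node("LEAF", ko="K00001"), Node("LEAF", ko="K00002"))),
            Node("COMPLEX", (Node("LEAF", ko="K00003"), Node("LEAF", ko="K00004"))),
            Node("OPTIONAL", (Node("LEAF", ko="K00005"),)),
        ))
        assert node == expected

    def test_optional_subunit_in_complex(self):
        node = parse_module("K00001+K00002-K00003").expression
        assert node.kind == "COMPLEX"
        assert node.children[2].kind == "OPTIONAL"

    @pytest.mark.parametrize("bad", ["", "(K00001", "K00001)", "K00001,,K00002",
                                     "K00001,", "(K00001,)"])
    def test_malformed_rejected_with_position(self, bad):
        with pytest.raises(ModuleParseError):
            parse_module(bad)

    @pytest.mark.parametrize("definition", [
        "K00001", "K00001 K00002", "(K00001,K00002) K00003",
        "(K00001,K00002) K00003+K00004 -K00005",
        "K00001+K00002-K00003 (K00004,(K00005 K00006))",
    ])
    def test_serialize_round_trip(self, definition):
        tree = parse_module(definition).expression
        assert parse_module(serialize(tree)).expression == tree


# ----------------------------------------------------------------- evaluate

def _oracle(node, kos):
    """Independent recursion over the tree: explicit stack-free re-derivation."""
    if node.kind == "LEAF":
        return float(node.ko in kos)
    if node.kind == "OPTIONAL":
        return 0.0
    if node.kind == "OR":
        return max(_oracle(c, kos) for c in node.children)
    counted = [c for c in node.children if c.kind != "OPTIONAL"]
    if not counted:
        return 0.0
    return float(np.mean([_oracle(c, kos) for c in counted]))


def _random_expression(rng, depth=0):
    kos = [f"K{rng.integers(0, 20):05d}" for _ in range(rng.integers(1, 4))]
    if depth >= 2 or rng.random() < 0.35:
        return kos[0]
    kind = rng.integers(0, 3)
    parts = [_random_expression(rng, depth + 1) for _ in range(rng.integers(2, 4))]
    parts = [f"({p})" if (" " in p and kind != 0) or ("," in p) else p for p in parts]
    if kind == 0:
        expr = " ".join(parts)
    elif kind == 1:
        expr = ",".join(parts)
    else:
        expr = "+".join(p if ("(" not in p and " " not in p and "," not in p)
                        else f"({p})" for p in parts)
    if rng.random() < 0.25:
        expr += f" -K{rng.integers(0, 20):05d}"
    return expr


class TestEvaluate:
    def test_all_leaves_present_is_100(self):
        m = parse_module("(K00001,K00002) K00003+K00004")
        assert evaluate_mcr(m, {"K00001", "K00003", "K00004"}) == 100.0

    def test_and_mean_rule(self):
        assert evaluate_mcr(parse_module("K00001 K00002"), {"K00001"}) == 50.0

    def test_or_takes_best_branch(self):
        assert evaluate_mcr(parse_module("K00001,K00002"), {"K00002"}) == 100.0

    def test_optional_excluded_from_denominator(self):
        m = parse_module("K00001 -K00002")
        assert evaluate_mcr(m, {"K00001"}) == 100.0
        assert evaluate_mcr(m, {"K00002"}) == 0.0

    def test_empty_set_zero_full_set_hundred(self):
        for definition in ("K00001 K00002", "(K00001,K00002) K00003+K00004"):
            m = parse_module(definition)
            assert evaluate_mcr(m, set()) == 0.0
            assert evaluate_mcr(m, m.expression.leaves()) == 100.0

    def test_all_optional_module_scored_zero(self):
        assert evaluate_mcr(parse_module("-K00001 -K00002"), {"K00001"}) == 0.0

    def test_500_random_pairs_match_independent_oracle(self):
        rng = np.random.default_rng(77)
        for _ in range(500):
            module = parse_module(_random_expression(rng))
            kos = {f"K{k:05d}" for k in rng.choice(20, size=rng.integers(0, 15),
                                                   replace=False)}
            assert evaluate_mcr(module, kos) == pytest.approx(
                100.0 * _oracle(module.expression, kos))

    @given(st.sets(st.sampled_from([f"K{i:05d}" for i in range(8)])),
           st.sampled_from([f"K{i:05d}" for i in range(8)]))
    @settings(max_examples=100, deadline=None)
    def test_adding_a_ko_never_decreases_mcr(self, kos, extra):
        module = parse_module("(K00000,K00001) K00002+K00003 K00004 -K00005 "
                              "(K00006 K00007)")
        assert evaluate_mcr(module, kos | {extra}) >= evaluate_mcr(module, kos)


# --------------------------------------------------------------- clustering

def _naive_complete_linkage(X):
    """O(n^3) agglomerator: merge heights of complete-linkage clustering."""
    clusters = [[i] for i in range(len(X))]
    heights = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            d = max(np.linalg.norm(X[i] - X[j])
                    for i in clusters[a] for j in clusters[b])
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        heights.append(d)
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return sorted(heights)


class TestClustering:
    def test_identical_profiles_merge_at_zero(self):
        profiles = pd.DataFrame([[50.0, 10.0], [50.0, 10.0], [0.0, 90.0]],
                                index=["a", "b", "c"], columns=["M1", "M2"])
        Z, labels = cluster_profiles(profiles)
        assert Z[0, 2] == 0.0
        first = {labels[int(Z[0, 0])], labels[int(Z[0, 1])]}
        assert first == {"a", "b"}

    def test_all_zero_modules_excluded_then_error(self):
        profiles = pd.DataFrame([[0.0], [0.0]], index=["a", "b"], columns=["M1"])
        with pytest.raises(ValueError, match="no signal"):
            cluster_profiles(profiles)

    def test_zero_module_exclusion_changes_nothing_else(self):
        base = pd.DataFrame([[10.0, 5.0], [20.0, 0.0]],
                            index=["a", "b"], columns=["M1", "M2"])
        padded = base.assign(M3=0.0)
        Z1, _ = cluster_profiles(base)
        Z2, _ = cluster_profiles(padded)
        assert np.allclose(Z1, Z2)

    def test_linkage_heights_match_naive_agglomerator(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            X = rng.uniform(0, 100, size=(10, 6))
            profiles = pd.DataFrame(X, index=[f"g{i}" for i in range(10)])
            Z, _ = cluster_profiles(profiles)
            assert np.allclose(sorted(Z[:, 2]), _naive_complete_linkage(X))

    def test_permutation_invariance(self):
        rng = np.random.default_rng(6)
        X = rng.uniform(0, 100, size=(8, 4))
        profiles = pd.DataFrame(X, index=[f"g{i}" for i in range(8)])
        Z1, l1 = cluster_profiles(profiles)
        shuffled = profiles.sample(frac=1, random_state=3)
        Z2, l2 = cluster_profiles(shuffled)
        assert l1 == l2
        assert np.allclose(Z1, Z2)

    def test_newick_serialization_contains_all_genomes(self):
        profiles = pd.DataFrame([[10.0], [20.0], [80.0]],
                                index=["a", "b", "c"], columns=["M1"])
        Z, labels = cluster_profiles(profiles)
        nwk = linkage_to_newick(Z, labels)
        assert nwk.endswith(";")
        for g in "abc":
            assert g in nwk


class TestMatrix:
    def test_matrix_shape_and_values(self):
        modules = {"M1": parse_module("K00001 K00002", "M1"),
                   "M2": parse_module("K00003", "M2")}
        ko_sets = {"gA": {"K00001"}, "gB": {"K00003"}}
        m = mcr_matrix(modules, ko_sets)
        assert m.loc["gA", "M1"] == 50.0
        assert m.loc["gB", "M2"] == 100.0
        assert m.loc["gB", "M1"] == 0.0
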