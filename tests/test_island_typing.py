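"""Pearson similarity, UPGMA and the similarity-cutoff type assignment."""

import io

import numpy as np
import pytest

from fgi_typer import (
    SimilarityMatrix,
    UpgmaNode,
    assign_types,
    pearson_similarity,
    read_newick,
    to_newick,
    upgma,
    write_newick,
)
from fgi_typer.errors import ValidationError
from fgi_typer.orthology import PresenceAbsenceMatrix

from oracle_utils import brute_force_upgma, node_to_tuple, trees_equal


def _pam(profiles: dict[str, list[int]]) -> PresenceAbsenceMatrix:
    strains = sorted(profiles)
    cells = np.array([profiles[s] for s in strains], dtype=np.int8)
    fams = [f"F{i:03d}" for i in range(cells.shape[1])]
    return PresenceAbsenceMatrix(strains, fams, cells)


def _random_similarity(rng, n: int) -> SimilarityMatrix:
    d = rng.uniform(1.0, 100.0, size=(n, n))
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return SimilarityMatrix([f"L{i}" for i in range(n)], 100.0 - d)


class TestPearson:
    def test_identical_profiles(self):
        m = pearson_similarity(_pam({"a": [1, 0, 1, 1], "b": [1, 0, 1, 1]}))
        assert m.entries[0, 1] == pytest.approx(100.0)

    def test_complementary_profiles(self):
        m = pearson_similarity(_pam({"a": [1, 0, 1, 0], "b": [0, 1, 0, 1]}))
        assert m.entries[0, 1] == pytest.approx(-100.0)

    def test_orthogonal_profiles(self):
        # direct evaluation of Pearson's r gives exactly zero here
        m = pearson_similarity(_pam({"a": [1, 1, 0, 0], "b": [1, 0, 1, 0]}))
        assert m.entries[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_convention(self):
        m = pearson_similarity(_pam({"a": [1, 1, 1], "b": [1, 1, 1], "c": [1, 0, 1]}))
        assert m.entries[0, 1] == pytest.approx(100.0)  # identical flat profiles
        assert m.entries[0, 2] == pytest.approx(0.0)  # flat vs varying

    def test_single_strain_rejected(self):
        with pytest.raises(ValidationError):
            pearson_similarity(_pam({"a": [1, 0]}))

    def test_diagonal_and_symmetry(self):
        rng = np.random.default_rng(0)
        m = pearson_similarity(
            _pam({f"s{i}": rng.integers(0, 2, 12).tolist() for i in range(6)})
        )
        assert np.allclose(np.diag(m.entries), 100.0)
        assert np.allclose(m.entries, m.entries.T)


class TestUpgma:
    def test_two_leaves(self):
        sim = SimilarityMatrix(["A", "B"], np.array([[100.0, 90.0], [90.0, 100.0]]))
        tree = upgma(sim)
        assert tree.height == pytest.approx(5.0)
        assert to_newick(tree) == "(A:5,B:5);"

    def test_three_leaf_worked_example(self):
        # d(A,B)=2, d(A,C)=d(B,C)=8 -> ((A:1,B:1):3,C:4)
        entries = 100.0 - np.array([[0, 2, 8], [2, 0, 8], [8, 8, 0]], dtype=float)
        tree = upgma(SimilarityMatrix(["A", "B", "C"], entries))
        assert to_newick(tree) == "((A:1,B:1):3,C:4);"

    def test_matches_brute_force_recomputation(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            n = int(rng.integers(3, 8))
            sim = _random_similarity(rng, n)
            ours = node_to_tuple(upgma(sim))
            oracle = brute_force_upgma(sim.strains, (100.0 - sim.entries).tolist())
            assert trees_equal(ours, oracle, tol=1e-7)

    def test_ultrametric_input_reproduced_exactly(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            n = int(rng.integers(3, 6))
            base = _random_similarity(rng, n)
            tree = upgma(base)
            coph = tree.cophenetic_distances()
            names = sorted(base.strains)
            entries = np.zeros((n, n))
            for i, a in enumerate(names):
                for j, b in enumerate(names):
                    if i != j:
                        entries[i, j] = 100.0 - coph[(min(a, b), max(a, b))]
                    else:
                        entries[i, j] = 100.0
            tree2 = upgma(SimilarityMatrix(names, entries))
            coph2 = tree2.cophenetic_distances()
            for key, dist in coph.items():
                assert coph2[key] == pytest.approx(dist, abs=1e-9)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValidationError):
            SimilarityMatrix(["A", "B"], np.array([[100.0, 10.0], [20.0, 100.0]]))


class TestAssignTypes:
    def test_identical_profiles_single_type(self):
        m = pearson_similarity(_pam({f"s{i}": [1, 0, 1, 1] for i in range(4)}))
        result = assign_types(upgma(m), 50.0)
        assert result.n_types == 1
        assert set(result.type_of.values()) == {"I"}

    def test_two_blocks_give_two_types(self):
        profiles = {}
        for i in range(3):
            profiles[f"a{i}"] = [1, 1, 1, 0, 0, 0]
            profiles[f"b{i}"] = [0, 0, 0, 1, 1, 1]
        m = pearson_similarity(_pam(profiles))
        result = assign_types(upgma(m), 50.0)
        assert result.n_types == 2
        # labels by decreasing size, tie by lexicographically first strain
        assert result.type_of["a0"] == "I"
        assert result.type_of["b0"] == "II"
        # direct component search at the cutoff agrees
        names = m.strains
        same_type = {
            (x, y)
            for i, x in enumerate(names)
            for j, y in enumerate(names)
            if m.entries[i, j] >= 50.0
        }
        for x in names:
            for y in names:
                assert ((x, y) in same_type) == (result.type_of[x] == result.type_of[y])

    def test_monotone_in_cutoff(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            sim = _random_similarity(rng, 7)
            tree = upgma(sim)
            counts = [assign_types(tree, c).n_types for c in (-50, 0, 25, 50, 75, 99)]
            assert counts == sorted(counts)

    def test_partition_invariant_to_strain_order(self):
        rng = np.random.default_rng(31)
        profiles = {f"s{i}": rng.integers(0, 2, 10).tolist() for i in range(8)}
        res1 = assign_types(upgma(pearson_similarity(_pam(profiles))), 50.0)
        shuffled = dict(reversed(list(profiles.items())))
        res2 = assign_types(upgma(pearson_similarity(_pam(shuffled))), 50.0)

        def partition(res):
            groups = {}
            for s, t in res.type_of.items():
                groups.setdefault(t, set()).add(s)
            return {frozenset(g) for g in groups.values()}

        assert partition(res1) == partition(res2)


class TestNewick:
    def test_roundtrip_random_trees(self):
        rng = np.random.default_rng(41)
        for _ in range(25):
            n = int(rng.integers(2, 8))
            tree = upgma(_random_similarity(rng, n))
            text = to_newick(tree)
            back = read_newick(io.StringIO(text))
            assert trees_equal(node_to_tuple(tree), node_to_tuple(back), tol=1e-9)

    def test_quoted_labels_for_strain_names_with_spaces(self, tmp_path):
        sim = SimilarityMatrix(
            ["G. sp. one", "G. sp. two"], np.array([[100.0, 80.0], [80.0, 100.0]])
        )
        tree = upgma(sim)
        path = tmp_path / "t.nwk"
        write_newick(tree, path)
        assert "'G. sp. one'" in path.read_text()
        back = read_newick(path)
        assert sorted(back.leaves()) == ["G. sp. one", "G. sp. two"]
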