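import numpy as np
import pytest

from mtforestnet.chemspace import (
    DatasetGroup,
    Subset,
    average_similarity,
    common_chemical_percentage,
    pca_projection,
    pearson,
    tanimoto,
    task_correlation_summary,
)
from mtforestnet.exceptions import UndefinedCorrelationError, ValidationError


def bits(*on, length=16):
    v = np.zeros(length, dtype=np.uint8)
    v[list(on)] = 1
    return v


def group(name, *subsets):
    return DatasetGroup(
        name, [Subset(f"s{i}", ids, fps) for i, (ids, fps) in enumerate(subsets)]
    )


class TestTanimoto:
    def test_identity_disjoint_and_hand_example(self):
        assert tanimoto(bits(1, 2, 3), bits(1, 2, 3)) == 1.0
        assert tanimoto(bits(0, 1), bits(2, 3)) == 0.0
        # intersection {2,3} = 2 bits, union {1,2,3,4} = 4 bits
        assert tanimoto(bits(1, 2, 3), bits(2, 3, 4)) == 0.5

    def test_both_empty_defined_as_zero(self):
        assert tanimoto(bits(), bits()) == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            tanimoto(bits(1), bits(1, length=8))

    def test_symmetry(self, rng):
        for _ in range(50):
            a = (rng.random(32) < 0.3).astype(np.uint8)
            b = (rng.random(32) < 0.3).astype(np.uint8)
            assert tanimoto(a, b) == tanimoto(b, a)


class TestCommonChemicalPercentage:
    def test_identical_and_disjoint_and_hand_example(self):
        fp = np.ones((2, 4), np.uint8)
        a = group("A", (["c1", "c2"], fp))
        assert common_chemical_percentage(a, a) == 100.0
        b = group("B", (["d1", "d2"], fp))
        assert common_chemical_percentage(a, b) == 0.0
        # |common| = 1 (c2), |union| = 4
        c = group("C", (["c2", "c3", "c4"], np.ones((3, 4), np.uint8)))
        assert common_chemical_percentage(a, c) == 25.0

    def test_max_over_subset_pairs(self):
        fp1 = np.ones((1, 4), np.uint8)
        a = group("A", (["x"], fp1), (["c1"], fp1))
        b = group("B", (["y"], fp1), (["c1"], fp1))
        assert common_chemical_percentage(a, b) == 100.0

    def test_symmetric(self):
        fp = np.ones((2, 4), np.uint8)
        a = group("A", (["c1", "c2"], fp))
        b = group("B", (["c2", "c3"], fp))
        assert common_chemical_percentage(a, b) == common_chemical_percentage(b, a)


class TestAverageSimilarity:
    def test_self_single_chemical_is_100(self):
        g = group("A", (["c1"], bits(1, 5)[None, :]))
        assert average_similarity(g, g) == 100.0

    def test_disjoint_bitsets_are_0(self):
        a = group("A", (["c1"], bits(0, 1)[None, :]))
        b = group("B", (["d1"], bits(5, 6)[None, :]))
        assert average_similarity(a, b) == 0.0

    def test_four_term_hand_average(self):
        # cross-pairs: (a1,b1)=1/3, (a1,b2)=0, (a2,b1)=1/3, (a2,b2)=1/4
        a = group("A", (["a1", "a2"], np.vstack([bits(0, 1), bits(1, 2)])))
        b = group("B", (["b1", "b2"], np.vstack([bits(1, 3), bits(2, 4, 5)])))
        expected = 100 * (1 / 3 + 0 + 1 / 3 + 1 / 4) / 4
        assert average_similarity(a, b) == pytest.approx(expected)

    def test_order_invariance_and_symmetry(self, rng):
        fps = (rng.random((6, 16)) < 0.4).astype(np.uint8)
        a1 = group("A", (["a", "b", "c"], fps[:3]), (["d", "e"], fps[3:5]))
        a2 = group("A", (["d", "e"], fps[3:5]), (["c", "b", "a"], fps[:3][::-1]))
        b = group("B", (["z"], fps[5:6]))
        assert average_similarity(a1, b) == pytest.approx(average_similarity(a2, b))
        assert average_similarity(a1, b) == pytest.approx(average_similarity(b, a1))

    def test_missing_fingerprints_named(self):
        a = DatasetGroup("A", [Subset("s0", ["c1"], None)])
        b = group("B", (["d1"], bits(1)[None, :]))
        with pytest.raises(ValidationError, match="s0"):
            average_similarity(a, b)


class TestSubsetValidation:
    def test_empty_subset_rejected(self):
        with pytest.raises(ValidationError):
            Subset("s", [])

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValidationError):
            Subset("s", ["a", "a"])


class TestTaskCorrelationSummary:
    def test_identical_labels_very_high(self):
        labels = {"t1": {"a": 1, "b": 0, "c": 1}, "t2": {"a": 1, "b": 0, "c": 1}}
        s = task_correlation_summary(labels)
        assert s.counts["very_high"] == 1 and s.uncategorized_pairs == 0

    def test_no_shared_chemicals_uncategorized(self):
        labels = {"t1": {"a": 1, "b": 0, "c": 1}, "t2": {"x": 1, "y": 0, "z": 1}}
        s = task_correlation_summary(labels)
        assert s.uncategorized_pairs == 1 and sum(s.counts.values()) == 0

    def test_zero_variance_uncategorized(self):
        labels = {"t1": {"a": 1, "b": 1, "c": 1}, "t2": {"a": 1, "b": 0, "c": 1}}
        assert task_correlation_summary(labels).uncategorized_pairs == 1

    def test_five_shared_matches_textbook_pearson(self):
        x = [1, 1, 0, 0, 1]
        y = [1, 0, 0, 1, 1]
        labels = {
            "t1": dict(zip("abcde", x)),
            "t2": dict(zip("abcde", y)),
        }
        r = abs(np.corrcoef(x, y)[0, 1])
        s = task_correlation_summary(labels)
        # brute-force Pearson on the 5 pairs gives |r| ~ 0.167 -> low bin
        assert r < 0.3
        assert s.counts["low"] == 1

    def test_partition_invariant(self, rng):
        tasks = {}
        chems = [f"c{i}" for i in range(20)]
        for t in range(6):
            picked = rng.choice(chems, size=rng.integers(2, 15), replace=False)
            tasks[f"t{t}"] = {c: int(rng.integers(2)) for c in picked}
        s = task_correlation_summary(tasks)
        assert s.total_pairs == 15  # C(6,2)

    def test_min_shared_floor(self):
        with pytest.raises(ValidationError):
            task_correlation_summary({}, min_shared=2)


class TestPCAProjection:
    def test_rank_one_data_explained_by_first_component(self):
        base = bits(0, 3, 7)
        X = np.vstack([i * base for i in range(5)])
        coords, evr = pca_projection(X, 2)
        assert evr[0] == pytest.approx(1.0)
        assert evr[1] == pytest.approx(0.0, abs=1e-12)

    def test_variance_fractions_conserved(self, rng):
        X = (rng.random((8, 5)) < 0.5).astype(float)
        _, evr = pca_projection(X, 5)
        assert evr.sum() == pytest.approx(1.0)
        assert (np.diff(evr) <= 1e-12).all()

    def test_matches_dense_eigendecomposition(self, rng):
        X = (rng.random((10, 12)) < 0.4).astype(float)
        coords, evr = pca_projection(X, 3)
        Xc = X - X.mean(0)
        evals, evecs = np.linalg.eigh(Xc.T @ Xc / (len(X) - 1))
        order = np.argsort(evals)[::-1]
        ref = Xc @ evecs[:, order[:3]]
        # components are defined up to sign; compare pairwise distances
        d = lambda M: np.linalg.norm(M[:, None, :] - M[None, :, :], axis=-1)
        np.testing.assert_allclose(d(coords), d(ref), atol=1e-8)
        np.testing.assert_allclose(
            evr, evals[order[:3]] / evals.sum(), atol=1e-10
        )

    def test_too_few_rows(self):
        with pytest.raises(ValidationError):
            pca_projection(np.zeros((2, 4)), 2)


class TestPearson:
    def test_affine_and_antithetic(self):
        x = np.array([1.0, 2, 3, 4])
        assert pearson(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson(x, -x) == pytest.approx(-1.0)

    def test_hand_example(self):
        # sums: cov*n = 3.0, ss_x = ss_y = 5.0 -> r = 3/5
        assert pearson([1, 2, 3, 4], [2, 1, 4, 3]) == pytest.approx(0.6)

    def test_zero_variance_raises(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson([1, 1, 1], [1, 2, 3])
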