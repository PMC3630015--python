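"""Clustered-image-map contracts: agreement with a naive agglomerative
oracle, bijective permutations preserving every entry, monotone merge
heights, deterministic leaf ordering, and rendering."""

import numpy as np
import pytest

from paircorr import SimilarityMatrix, cluster_similarity, render_cim


def naive_ward(points):
    """O(n^3) agglomerative Ward (ward.D2): rescans all pair distances at
    every step using the Lance-Williams recurrence on squared Euclidean
    distances, heights square-rooted."""
    n = len(points)
    d2 = ((points[:, None, :] - points[None, :, :]) ** 2).sum(-1)
    dist = {frozenset((i, j)): d2[i, j] for i in range(n) for j in range(i + 1, n)}
    sizes = {i: 1 for i in range(n)}
    active = list(range(n))
    merges = []
    nxt = n
    while len(active) > 1:
        best = min(
            (dist[frozenset((a, b))], a, b)
            for i, a in enumerate(active)
            for b in active[i + 1:]
        )
        d_ab, a, b = best
        merges.append((a, b, np.sqrt(d_ab)))
        for k in active:
            if k in (a, b):
                continue
            na, nb, nk = sizes[a], sizes[b], sizes[k]
            dist[frozenset((nxt, k))] = (
                (na + nk) * dist[frozenset((a, k))]
                + (nb + nk) * dist[frozenset((b, k))]
                - nk * d_ab
            ) / (na + nb + nk)
        sizes[nxt] = sizes[a] + sizes[b]
        active = [x for x in active if x not in (a, b)] + [nxt]
        nxt += 1
    return merges


def matrix(vals):
    vals = np.asarray(vals, dtype=float)
    return SimilarityMatrix(
        vals,
        [f"x{i}" for i in range(vals.shape[0])],
        [f"y{i}" for i in range(vals.shape[1])],
        1,
        "t",
    )


class TestClusterSimilarity:
    @pytest.mark.parametrize("shape", [(4, 4), (6, 5), (8, 8)])
    def test_merge_trees_match_naive_oracle(self, rng, shape):
        vals = rng.uniform(-1, 1, size=shape)
        result = cluster_similarity(matrix(vals))
        for z, points in ((result.row_linkage, vals), (result.col_linkage, vals.T)):
            oracle = naive_ward(points)
            assert len(oracle) == len(z)
            for (a, b, h), row in zip(oracle, z):
                assert {a, b} == {int(row[0]), int(row[1])}
                assert h == pytest.approx(row[2], abs=1e-10)

    def test_permutations_preserve_entries(self, rng):
        vals = rng.uniform(-1, 1, size=(7, 5))
        result = cluster_similarity(matrix(vals))
        assert sorted(result.row_perm) == list(range(7))
        assert sorted(result.col_perm) == list(range(5))
        assert np.array_equal(
            result.matrix, vals[np.ix_(result.row_perm, result.col_perm)]
        )

    def test_block_sign_matrix_groups_contiguously(self):
        vals = np.zeros((6, 4))
        vals[:3, :2] = 0.9
        vals[3:, 2:] = 0.9
        order = [4, 0, 2, 5, 1, 3]  # shuffle rows
        result = cluster_similarity(matrix(vals[order]))
        labels = [0 if order[i] < 3 else 1 for i in result.row_perm]
        # each block occupies one contiguous run
        assert len([1 for a, b in zip(labels, labels[1:]) if a != b]) == 1

    def test_merge_heights_nondecreasing(self, sim30):
        from paircorr import fit_pls, similarity_from_fit

        m = similarity_from_fit(fit_pls(sim30, 3, "can"), sim30, 3)
        result = cluster_similarity(m)
        assert (np.diff(result.row_linkage[:, 2]) >= -1e-10).all()
        assert (np.diff(result.col_linkage[:, 2]) >= -1e-10).all()

    def test_relevant_blocks_form_contiguous_runs(self, sim30):
        from paircorr import fit_pls, similarity_from_fit

        m = similarity_from_fit(fit_pls(sim30, 3, "can"), sim30, 3)
        result = cluster_similarity(m)
        for letter, size in (("A", 10), ("B", 10), ("C", 3)):
            pos = [i for i, rid in enumerate(result.row_ids)
                   if rid.startswith(f"X{letter}")]
            assert max(pos) - min(pos) == size - 1

    def test_partition_equivariant_under_row_shuffle(self, rng):
        """Shuffling the rows changes neither the merge heights nor the
        partition of variable ids at any cut level."""
        from scipy.cluster.hierarchy import fcluster

        vals = rng.uniform(-1, 1, size=(6, 5))
        perm = rng.permutation(6)
        base = cluster_similarity(matrix(vals))
        shuffled = cluster_similarity(
            SimilarityMatrix(vals[perm], [f"x{i}" for i in perm],
                             [f"y{i}" for i in range(5)], 1, "t")
        )
        assert np.allclose(base.row_linkage[:, 2], shuffled.row_linkage[:, 2])
        base_ids = [f"x{i}" for i in range(6)]
        shuf_ids = [f"x{i}" for i in perm]
        for k in (2, 3, 4):
            parts = []
            for z, ids in ((base.row_linkage, base_ids), (shuffled.row_linkage, shuf_ids)):
                labels = fcluster(z, t=k, criterion="maxclust")
                groups = {}
                for vid, lab in zip(ids, labels):
                    groups.setdefault(lab, set()).add(vid)
                parts.append({frozenset(g) for g in groups.values()})
            assert parts[0] == parts[1]

    def test_unknown_metric_or_linkage_rejected(self, rng):
        m = matrix(rng.uniform(-1, 1, size=(3, 3)))
        with pytest.raises(ValueError):
            cluster_similarity(m, metric="mahalanobis")
        with pytest.raises(ValueError):
            cluster_similarity(m, method="median")

    def test_too_small_matrix_rejected(self):
        with pytest.raises(ValueError):
            cluster_similarity(matrix([[0.5, 0.5]]))


class TestRenderCim:
    def test_renders_two_by_two(self, tmp_path):
        result = cluster_similarity(matrix([[1.0, -1.0], [-1.0, 1.0]]))
        out = tmp_path / "cim.png"
        render_cim(result, out)
        assert out.stat().st_size > 0

    def test_constant_matrix_renders(self, tmp_path):
        result = cluster_similarity(matrix(np.zeros((3, 3))))
        render_cim(result, tmp_path / "flat.png")
        assert (tmp_path / "flat.png").exists()

    def test_deterministic_output_bytes(self, tmp_path, rng):
        vals = rng.uniform(-1, 1, size=(5, 4))
        result = cluster_similarity(matrix(vals))
        render_cim(result, tmp_path / "a.png")
        render_cim(result, tmp_path / "b.png")
        assert (tmp_path / "a.png").read_bytes() == (tmp_path / "b.png").read_bytes()
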