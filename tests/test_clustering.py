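import subprocess
import textwrap

import numpy as np
import pytest

import dendropatterns as dp
from dendropatterns.clustering import _classify_shape
from dendropatterns.segmentation import SegmentMatrix


def matrix_from(X, standardize=False):
    X = np.asarray(X, float)
    if standardize:
        X = (X - X.mean(0)) / X.std(0, ddof=1)
    return SegmentMatrix(
        tree_ids=tuple(f"t{i}" for i in range(X.shape[0])),
        values=X,
        col_means=np.zeros(X.shape[1]),
        col_sds=np.ones(X.shape[1]),
    )


def partition_from(matrix, labels):
    labels = np.asarray(labels)
    k = labels.max() + 1
    centers = np.vstack([matrix.values[labels == c].mean(axis=0) for c in range(k)])
    wss = sum(
        ((matrix.values[labels == c] - centers[c]) ** 2).sum() for c in range(k)
    )
    return dp.PatternPartition(
        k=int(k),
        tree_ids=matrix.tree_ids,
        assignments=labels,
        centers=centers,
        within_ss=float(wss),
    )


def ssi_oracle(centers, sizes):
    """Direct transliteration of the size-weighted simple structure index,
    computed with scalar loops, independent of the vectorized implementation."""
    centers = np.asarray(centers, float)
    sizes = np.asarray(sizes, float)
    k, p = centers.shape
    grand = centers.mean()
    total = 0.0
    devs, per_var = [], []
    for j in range(p):
        col = centers[:, j]
        hi = max(range(k), key=lambda c: (col[c], c))  # last max, as stable sort
        lo = min(range(k), key=lambda c: (col[c], c))  # first min
        span = col.max() - col.min()
        dev = abs(col.mean() - grand)
        devs.append(dev)
        per_var.append((span, dev, sizes[hi], sizes[lo]))
    max_size = max(max(s_hi for _, _, s_hi, _ in per_var), max(s_lo for *_, s_lo in per_var))
    norm = p * max_size * np.exp(-min(devs))
    for span, dev, s_hi, s_lo in per_var:
        total += span * np.exp(-dev) * np.sqrt(s_hi * s_lo)
    return total / norm


class TestBestKmeans:
    def two_blobs(self, sep=8.0, n=20, seed=0):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, size=(n, 4))
        b = rng.normal(sep, 1, size=(n, 4))
        return matrix_from(np.vstack([a, b])), np.r_[np.zeros(n), np.ones(n)]

    def test_k_equals_n_gives_zero_within_ss(self):
        rng = np.random.default_rng(1)
        m = matrix_from(rng.normal(size=(6, 3)))
        part = dp.best_kmeans(m, 6, n_restarts=20, seed=0)
        assert part.within_ss == pytest.approx(0, abs=1e-9)

    def test_recovers_two_blobs(self):
        m, truth = self.two_blobs()
        part = dp.best_kmeans(m, 2, n_restarts=20, seed=0)
        agree = (part.assignments == truth).mean()
        assert agree in (0.0, 1.0)  # label-switching aside, perfect recovery

    def test_seeded_determinism(self):
        m, _ = self.two_blobs()
        a = dp.best_kmeans(m, 3, n_restarts=30, seed=5)
        b = dp.best_kmeans(m, 3, n_restarts=30, seed=5)
        assert np.array_equal(a.assignments, b.assignments)
        assert a.within_ss == b.within_ss

    def test_k_beyond_n_rejected(self):
        m, _ = self.two_blobs(n=3)
        with pytest.raises(ValueError, match="outside"):
            dp.best_kmeans(m, 7, seed=0)

    def test_within_ss_non_increasing_in_restarts(self):
        rng = np.random.default_rng(3)
        m = matrix_from(rng.normal(size=(40, 6)))
        wss = [
            dp.best_kmeans(m, 5, n_restarts=r, seed=9).within_ss for r in (1, 5, 20, 50)
        ]
        assert all(a >= b - 1e-12 for a, b in zip(wss, wss[1:]))


class TestSsiScore:
    def test_matches_direct_formula_oracle(self):
        rng = np.random.default_rng(0)
        for trial in range(20):
            n = int(rng.integers(4, 11))
            p = int(rng.integers(2, 5))
            k = int(rng.integers(2, n))
            X = rng.normal(size=(n, p))
            labels = rng.permutation(np.r_[np.arange(k), rng.integers(0, k, n - k)])
            m = matrix_from(X)
            part = partition_from(m, labels)
            expected = ssi_oracle(part.centers, part.sizes)
            assert dp.ssi_score(m, part) == pytest.approx(expected, abs=1e-12)

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(12, 3))
        m = matrix_from(X)
        labels = np.array([0, 1, 2, 0, 1, 2, 0, 1, 2, 0, 1, 2])
        a = dp.ssi_score(m, partition_from(m, labels))
        b = dp.ssi_score(m, partition_from(m, (labels + 1) % 3))
        assert a == pytest.approx(b, abs=1e-12)

    def test_duplication_invariance(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(10, 3))
        labels = rng.integers(0, 3, 10)
        while len(set(labels)) < 3:
            labels = rng.integers(0, 3, 10)
        m1 = matrix_from(X)
        m2 = matrix_from(np.vstack([X, X]))
        a = dp.ssi_score(m1, partition_from(m1, labels))
        b = dp.ssi_score(m2, partition_from(m2, np.r_[labels, labels]))
        assert a == pytest.approx(b, abs=1e-12)

    def test_separated_blobs_score_higher(self):
        rng = np.random.default_rng(5)
        base = rng.normal(size=(20, 2))
        labels = np.r_[np.zeros(10, int), np.ones(10, int)]
        far = base + labels[:, None] * np.array([6.0, 6.0])
        near = base + labels[:, None] * np.array([1.0, 1.0])
        m_far, m_near = matrix_from(far), matrix_from(near)
        assert dp.ssi_score(m_far, partition_from(m_far, labels)) > dp.ssi_score(
            m_near, partition_from(m_near, labels)
        )

    def test_k1_undefined(self):
        m = matrix_from(np.random.default_rng(0).normal(size=(5, 2)))
        with pytest.raises(ValueError, match="k < 2"):
            dp.ssi_score(m, partition_from(m, np.zeros(5, int)))

    def test_matches_vegan_reference(self, tmp_path):
        """Cross-check against the community-ecology reference implementation."""
        rng = np.random.default_rng(11)
        X = rng.normal(size=(15, 4))
        labels = np.r_[np.zeros(5, int), np.ones(5, int), np.full(5, 2)]
        m = matrix_from(X)
        part = partition_from(m, labels)
        np.savetxt(tmp_path / "x.csv", X, delimiter=",")
        np.savetxt(tmp_path / "lab.csv", labels + 1, fmt="%d")
        rcode = textwrap.dedent(
            """
            x <- as.matrix(read.csv(file.path("{d}", "x.csv"), header=FALSE))
            lab <- scan(file.path("{d}", "lab.csv"), quiet=TRUE)
            k <- max(lab)
            centers <- t(sapply(1:k, function(i) colMeans(x[lab==i,,drop=FALSE])))
            wss <- sapply(1:k, function(i) sum(sweep(x[lab==i,,drop=FALSE],2,centers[i,])^2))
            km <- list(centers=centers, size=as.vector(table(lab)), withinss=wss)
            cat(sprintf("%.12f", vegan:::cIndexKM(km, x, index="ssi")))
            """
        ).format(d=tmp_path)
        out = subprocess.run(
            ["Rscript", "-e", rcode], capture_output=True, text=True, check=True
        )
        assert dp.ssi_score(m, part) == pytest.approx(float(out.stdout), abs=1e-9)


class TestSelectPatternCount:
    def test_single_value_range(self):
        rng = np.random.default_rng(0)
        m = matrix_from(rng.normal(size=(30, 4)))
        sel = dp.select_pattern_count(m, [4], n_restarts=10, seed=0)
        assert sel.k_best == 4

    def test_empty_range_rejected(self):
        m = matrix_from(np.random.default_rng(0).normal(size=(10, 3)))
        with pytest.raises(ValueError, match="empty"):
            dp.select_pattern_count(m, [], seed=0)

    def test_out_of_bounds_range_rejected(self):
        m = matrix_from(np.random.default_rng(0).normal(size=(10, 3)))
        with pytest.raises(ValueError, match="within"):
            dp.select_pattern_count(m, range(2, 11), seed=0)

    def test_null_blob_flagged_low_confidence(self):
        X = np.random.default_rng(0).normal(size=(120, 20))
        m = matrix_from(X, standardize=True)
        sel = dp.select_pattern_count(m, range(2, 13), n_restarts=50, seed=0)
        assert sel.low_confidence

    def test_structured_data_not_flagged(self, low_noise_matrix):
        _, m = low_noise_matrix
        sel = dp.select_pattern_count(m, range(2, 13), n_restarts=50, seed=0)
        assert not sel.low_confidence


class TestNamePatterns:
    def test_flat_low_center_is_linear(self):
        shape, flagged = _classify_shape(np.full(20, 0.4), dp.LabelThresholds())
        assert shape == "linear" and not flagged

    def test_monotone_rise_is_ascending(self):
        shape, _ = _classify_shape(np.linspace(0.2, 1.5, 20), dp.LabelThresholds())
        assert shape == "ascending"

    def test_interior_peak_with_narrow_start_is_sine(self):
        c = np.r_[np.full(7, 0.3), 1.6 * np.exp(-0.25 * np.arange(13)) + 0.3]
        shape, _ = _classify_shape(c, dp.LabelThresholds())
        assert shape == "sine"

    def test_early_peak_high_start_is_bell(self):
        c = np.r_[np.linspace(1.2, 1.8, 4), np.linspace(1.8, 0.6, 16)]
        shape, _ = _classify_shape(c, dp.LabelThresholds())
        assert shape == "bell"

    def test_templates_map_to_their_own_names(self, low_noise_dataset, low_noise_matrix):
        """Round-trip identity: archetype trees are labelled as their template."""
        _, _, truth = low_noise_dataset
        _, m = low_noise_matrix
        part = dp.name_patterns(dp.best_kmeans(m, 9, n_restarts=200, seed=3), m)
        pats = part.pattern_of()
        tdf = truth.set_index("tree_id")
        agree = np.mean([pats[t] == tdf.loc[t, "template"] for t in pats])
        assert agree >= 0.9

    def test_levels_rank_by_mean_width(self, low_noise_matrix):
        _, m = low_noise_matrix
        part = dp.name_patterns(dp.best_kmeans(m, 9, n_restarts=200, seed=3), m)
        centers_mm = m.destandardize_centers(part.centers)
        by_shape = {}
        for c, (shape, level) in part.labels.items():
            by_shape.setdefault(shape, []).append((level, centers_mm[c].mean()))
        order = {"low": 0, "moderate": 1, "high": 2}
        for shape, items in by_shape.items():
            if len(items) < 2:
                continue
            items.sort(key=lambda t: t[1])
            ranks = [order[level] for level, _ in items]
            assert ranks == sorted(ranks)
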