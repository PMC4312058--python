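"""AMOVA F_ST / R_ST, permutation tests, and classical MDS."""
import numpy as np
import pytest
from scipy import stats as sstats

from ylineage.distances import amova_phi, classical_mds, fst_haplogroup, rst
from ylineage.simulate import mutate_str, simulate_genealogy
from ylineage.types import STRHaplotype

LOCI = [f"L{i}" for i in range(15)]


def haps(rows):
    return [STRHaplotype(dict(zip(LOCI[: len(r)], r))) for r in rows]


def amova_oracle(sqd, sizes):
    """Independent brute-force AMOVA: explicit sums of squares from the
    textbook definitions, pure Python loops."""
    n = sum(sizes)
    ssd_total = 0.0
    for i in range(n):
        for j in range(n):
            ssd_total += sqd[i][j]
    ssd_total /= 2.0 * n
    ssd_within = 0.0
    start = 0
    for size in sizes:
        sub = 0.0
        for i in range(start, start + size):
            for j in range(start, start + size):
                sub += sqd[i][j]
        ssd_within += sub / (2.0 * size)
        start += size
    g = len(sizes)
    ms_among = (ssd_total - ssd_within) / (g - 1)
    sigma_w = ssd_within / (n - g)
    nbar = (n - sum(s * s for s in sizes) / n) / (g - 1)
    sigma_a = (ms_among - sigma_w) / nbar
    return sigma_a / (sigma_a + sigma_w)


class TestAmova:
    def test_matches_oracle_on_categorical_toy(self):
        # pop1: A,A,A,B; pop2: B,B,B,A
        labels = ["A", "A", "A", "B", "B", "B", "B", "A"]
        sqd = [[0.0 if a == b else 1.0 for b in labels] for a in labels]
        expected = amova_oracle(sqd, [4, 4])
        got = amova_phi(np.array(sqd), [4, 4])
        assert got == pytest.approx(expected, abs=1e-12)
        m = fst_haplogroup([labels[:4], labels[4:]], n_perm=0)
        assert m.values[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_rst_matches_oracle_on_str_toy(self, rng):
        rows = rng.integers(10, 14, size=(6, 4)).tolist()
        pops = [haps(rows[:2]), haps(rows[2:4]), haps(rows[4:])]
        X = np.array(rows, dtype=float)
        sqd = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2).tolist()
        m = rst(pops, LOCI[:4], n_perm=0)
        for (i, j), sizes in [((0, 1), [2, 2]), ((0, 2), [2, 2]), ((1, 2), [2, 2])]:
            idx = sum(([2 * i, 2 * i + 1], [2 * j, 2 * j + 1]), [])
            sub = [[sqd[a][b] for b in idx] for a in idx]
            assert m.values[i, j] == pytest.approx(amova_oracle(sub, sizes), abs=1e-12)

    def test_fixed_populations_give_one(self):
        m = fst_haplogroup([["A"] * 4, ["B"] * 4], n_perm=0)
        assert m.values[0, 1] == pytest.approx(1.0)

    def test_rst_fixed_one_step_apart(self):
        a = [13] * 15
        b = [13] * 14 + [14]
        m = rst([haps([a, a, a]), haps([b, b, b])], LOCI, n_perm=0)
        assert m.values[0, 1] == pytest.approx(1.0)

    def test_identical_populations_near_zero(self, rng):
        rows = rng.integers(10, 15, size=(8, 15)).tolist()
        m = rst([haps(rows), haps(rows)], LOCI, n_perm=0)
        assert m.values[0, 1] < 0.01

    def test_invariance_to_population_and_sample_order(self, rng):
        rows = rng.integers(10, 15, size=(9, 15)).tolist()
        pops = [haps(rows[:3]), haps(rows[3:6]), haps(rows[6:])]
        m1 = rst(pops, LOCI, n_perm=0, labels=["a", "b", "c"])
        m2 = rst([pops[2], pops[0], pops[1]], LOCI, n_perm=0, labels=["c", "a", "b"])
        assert m2.values[1, 2] == pytest.approx(m1.values[0, 1], abs=1e-12)
        shuffled = list(pops[0])
        rng.shuffle(shuffled)
        m3 = rst([shuffled, pops[1]], LOCI, n_perm=0)
        assert m3.values[0, 1] == pytest.approx(m1.values[0, 1], abs=1e-12)

    def test_small_population_rejected(self):
        with pytest.raises(ValueError, match="fewer than two"):
            fst_haplogroup([["A"], ["B", "B"]], n_perm=0)

    def test_permutation_pvalues_in_unit_interval(self, rng):
        rows = rng.integers(10, 15, size=(10, 15)).tolist()
        m = rst([haps(rows[:5]), haps(rows[5:])], LOCI, n_perm=99, seed=1)
        p = m.pvalues[0, 1]
        assert 0.0 < p <= 1.0
        assert m.n_permutations == 99

    def test_rst_increases_with_divergence_time(self):
        """Two populations drifting from a common founder under stepwise
        mutation: R_ST grows with divergence time (rank correlation > 0)."""
        rng = np.random.default_rng(7)
        founder = STRHaplotype({l: 13 for l in LOCI})
        rates = {l: 6.9e-4 for l in LOCI}
        times, values = [], []
        for t in (500.0, 8000.0, 32000.0, 128000.0):
            for _ in range(15):
                pops = []
                for _ in range(2):
                    # the population's own founder drifts for t years ...
                    split = simulate_genealogy(2, "star", t, 25.0, seed=rng)
                    pop_founder = mutate_str(split, rates, founder, seed=rng)[0]
                    # ... then a shallow star genealogy within the population
                    g = simulate_genealogy(12, "star", 500.0, 25.0, seed=rng)
                    pops.append(mutate_str(g, rates, pop_founder, seed=rng))
                m = rst(pops, LOCI, n_perm=0)
                times.append(t)
                values.append(m.values[0, 1])
        rho = sstats.spearmanr(times, values).statistic
        assert rho > 0.3


class TestClassicalMDS:
    def test_collinear_points_recovered(self):
        D = np.array([[0.0, 1, 2], [1, 0, 1], [2, 1, 0]])
        emb = classical_mds(D, k=2)
        X = emb.coordinates
        got = np.linalg.norm(X[:, None] - X[None, :], axis=2)
        assert np.allclose(got, D, atol=1e-9)

    def test_known_2d_configuration_recovered(self, rng):
        X = rng.normal(size=(7, 2))
        D = np.linalg.norm(X[:, None] - X[None, :], axis=2)
        emb = classical_mds(D, k=2)
        Y = emb.coordinates
        got = np.linalg.norm(Y[:, None] - Y[None, :], axis=2)
        assert np.allclose(got, D, atol=1e-9)
        assert np.allclose(Y.mean(axis=0), 0.0, atol=1e-9)
        assert np.all(np.diff(emb.eigenvalues) <= 1e-9)

    def test_zero_matrix_gives_zero_coordinates(self):
        emb = classical_mds(np.zeros((4, 4)), k=2)
        assert np.allclose(emb.coordinates, 0.0)

    def test_padding_warns_when_rank_deficient(self):
        D = np.array([[0.0, 1, 2], [1, 0, 1], [2, 1, 0]])  # rank-1 configuration
        with pytest.warns(UserWarning, match="padding"):
            emb = classical_mds(D, k=3)
        assert emb.coordinates.shape == (3, 3)
        assert np.allclose(emb.coordinates[:, 1:], 0.0, atol=1e-9)

    def test_negative_distances_clamped(self):
        D = np.array([[0.0, -0.01, 1.0], [-0.01, 0, 1], [1, 1, 0]])
        emb = classical_mds(D, k=2)
        assert np.isfinite(emb.coordinates).all()
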