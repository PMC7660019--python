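import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import admixkit as ak
from admixkit.fstats import JackknifeInput
from admixkit.genotype_io import GenotypeError

from conftest import make_freq


def random_freq(seed, pops=("A", "B", "C", "D", "E"), n_sites=300, n=20):
    rng = np.random.default_rng(seed)
    return make_freq(
        {q: np.rint(rng.uniform(0.05, 0.95, n_sites) * n) / n for q in pops}, n=n
    )


class TestPerSiteFormulas:
    def test_f2_hand_value(self):
        """a = b = 0.5 with n = 10: pure -2h/n correction, -0.055556."""
        val, usable = ak.f2_per_site(
            np.array([0.5]), np.array([10.0]), np.array([0.5]), np.array([10.0])
        )
        assert usable[0]
        assert val[0] == pytest.approx(-0.0555556, abs=1e-6)

    def test_f2_large_n_limit(self):
        p = np.array([0.3])
        n = np.array([1e6])
        val, _ = ak.f2_per_site(p, n, p, n)
        assert abs(val[0]) < 1e-5

    def test_f2_unusable_below_two_alleles(self):
        _, usable = ak.f2_per_site(
            np.array([0.5]), np.array([1.0]), np.array([0.5]), np.array([10.0])
        )
        assert not usable[0]

    def test_f3_hand_value(self):
        """(c-a)(c-b) - h_c/n_c = 0.06 - 0.027778 for the stated inputs."""
        blocks = ak.BlockSpec(np.array([0, 1]), np.array([1, 1]))
        # the jackknife needs >= 2 blocks, so state the site twice
        freq2 = make_freq({"C": [0.5, 0.5], "A": [0.2, 0.2], "B": [0.3, 0.3]}, n=10)
        r = ak.f3_stat(freq2, blocks, "C", "A", "B")
        assert r.estimate == pytest.approx(0.0322222, abs=1e-6)

    def test_f3_zero_when_target_equals_source(self):
        rng = np.random.default_rng(0)
        p = np.rint(rng.uniform(0.1, 0.9, 400) * 1000) / 1000
        freq = make_freq({"C": p, "A": p, "B": np.roll(p, 7)}, n=1000)
        blocks = ak.assign_blocks(freq.variants, 50)
        r = ak.f3_stat(freq, blocks, "C", "A", "B")
        # (c - a) = 0 leaves only the O(1/n) correction
        assert abs(r.estimate) < 5e-4


class TestF4:
    def test_duplicate_population_gives_zero(self):
        freq = random_freq(1)
        blocks = ak.assign_blocks(freq.variants, 50)
        r = ak.f4_stat(freq, blocks, "A", "B", "C", "C")
        assert r.estimate == 0.0

    def test_antisymmetry_exact(self):
        freq = random_freq(2)
        blocks = ak.assign_blocks(freq.variants, 50)
        r1 = ak.f4_stat(freq, blocks, "A", "B", "C", "D")
        r2 = ak.f4_stat(freq, blocks, "A", "B", "D", "C")
        assert r1.estimate == -r2.estimate
        assert r1.z == -r2.z

    def test_additivity_identity(self):
        """f4(A,B;C,D) = f4(A,B;C,E) + f4(A,B;E,D) on a shared site set."""
        freq = random_freq(3)
        blocks = ak.assign_blocks(freq.variants, 50)
        lhs = ak.f4_stat(freq, blocks, "A", "B", "C", "D").estimate
        rhs = (
            ak.f4_stat(freq, blocks, "A", "B", "C", "E").estimate
            + ak.f4_stat(freq, blocks, "A", "B", "E", "D").estimate
        )
        assert lhs == pytest.approx(rhs, abs=1e-12)


class TestDStat:
    def test_hand_computed_three_site_value(self):
        freq = make_freq(
            {
                "W": [0.1, 0.2, 0.3],
                "X": [0.5, 0.2, 0.1],
                "Y": [0.9, 0.4, 0.2],
                "Z": [0.1, 0.4, 0.6],
            },
            n=10,
        )
        blocks = ak.assign_blocks(freq.variants, 2)
        r = ak.d_stat(freq, blocks, "W", "X", "Y", "Z")
        assert r.estimate == pytest.approx(-0.4 / 0.754, abs=1e-6)
        assert r.estimate == pytest.approx(-0.530504, abs=1e-6)

    def test_identical_sisters_give_zero(self):
        freq = random_freq(4, pops=("W", "X", "Y"))
        freq2 = ak.FreqTable(
            ["W", "X", "Y", "Z"],
            freq.variants,
            np.vstack([freq.d, freq.d[2]]),
            np.vstack([freq.n, freq.n[2]]),
        )
        blocks = ak.assign_blocks(freq2.variants, 50)
        r = ak.d_stat(freq2, blocks, "W", "X", "Y", "Z")
        assert r.estimate == 0.0

    def test_swap_negates(self):
        freq = random_freq(5, pops=("W", "X", "Y", "Z"))
        blocks = ak.assign_blocks(freq.variants, 50)
        r1 = ak.d_stat(freq, blocks, "W", "X", "Y", "Z")
        r2 = ak.d_stat(freq, blocks, "W", "X", "Z", "Y")
        assert r1.estimate == -r2.estimate
        assert r1.z == pytest.approx(-r2.z, rel=1e-12)

    def test_point_estimate_matches_naive_oracle(self):
        """Blocking must not move the point estimate at all."""
        for seed in range(3):
            freq = random_freq(seed + 10)
            blocks = ak.assign_blocks(freq.variants, 37)
            r = ak.d_stat(freq, blocks, "A", "B", "C", "D")
            w, x, y, z = (freq.freq(q) for q in "ABCD")
            naive = np.sum((w - x) * (y - z)) / np.sum(
                (w + x - 2 * w * x) * (y + z - 2 * y * z)
            )
            assert r.estimate == pytest.approx(naive, abs=1e-12)

    def test_monomorphic_denominator_raises(self):
        freq = make_freq(
            {q: [0.0, 0.0] for q in "WXYZ"}, n=10
        )
        blocks = ak.BlockSpec(np.array([0, 1]), np.array([1, 1]))
        with pytest.raises(GenotypeError, match="monomorphic"):
            ak.d_stat(freq, blocks, "W", "X", "Y", "Z")


def test_f2_tracks_simulated_drift():
    """Mean per-site f2 between parent and child approximates
    c * E[p(1-p)] under Balding-Nichols drift."""
    c = 0.05
    graph = ak.AdmixtureGraph(
        {("root", "anc"): 0.0, ("anc", "P"): 0.0, ("anc", "Q"): c}
    )
    cfg = ak.SimulationConfig(
        graph,
        [ak.PopulationSpec("P", n_diploid=50), ak.PopulationSpec("Q", n_diploid=50)],
        n_sites=100_000,
        missing_rate=0.0,
        seed=19,
    )
    g, panel, truth = ak.simulate_dataset(cfg)
    freq = ak.population_counts(g, panel)
    blocks = ak.assign_blocks(g.variants, 100)
    r = ak.f2_stat(freq, blocks, "P", "Q")
    expected = c * np.mean(truth["P"] * (1 - truth["P"]))
    assert r.estimate == pytest.approx(expected, rel=0.05)


@given(st.integers(0, 10_000))
@settings(max_examples=20, deadline=None)
def test_allele_flip_invariance(seed):
    """Flipping p -> 1-p at any site subset leaves f2/f3/f4/D unchanged."""
    rng = np.random.default_rng(seed)
    n_sites, n = 120, 20
    base = {
        q: np.rint(rng.uniform(0.05, 0.95, n_sites) * n) / n for q in "ABCD"
    }
    flip = rng.random(n_sites) < 0.5
    flipped = {q: np.where(flip, 1.0 - p, p) for q, p in base.items()}
    f1 = make_freq(base, n=n)
    f2 = make_freq(flipped, n=n)
    blocks = ak.assign_blocks(f1.variants, 40)
    for fn, args in [
        (ak.f2_stat, ("A", "B")),
        (ak.f3_stat, ("C", "A", "B")),
        (ak.f4_stat, ("A", "B", "C", "D")),
        (ak.d_stat, ("A", "B", "C", "D")),
    ]:
        r1, r2 = fn(f1, blocks, *args), fn(f2, blocks, *args)
        assert r1.estimate == pytest.approx(r2.estimate, abs=1e-12)
        assert r1.se == pytest.approx(r2.se, abs=1e-12)


class TestBlockJackknife:
    def test_equal_weights_reduce_to_classic(self):
        rng = np.random.default_rng(8)
        g = 30
        num = rng.normal(0.1, 0.3, g)
        den = rng.uniform(5.0, 6.0, g)
        m = np.full(g, 100.0)
        est, jmean, se, z = ak.block_jackknife(JackknifeInput(num, den, m))
        theta_j = np.array(
            [(num.sum() - num[i]) / (den.sum() - den[i]) for i in range(g)]
        )
        classic = np.sqrt((g - 1) / g * np.sum((theta_j - theta_j.mean()) ** 2))
        assert se == pytest.approx(classic, abs=1e-12)
        assert est == pytest.approx(num.sum() / den.sum(), abs=1e-15)

    def test_unequal_weights_change_se(self):
        rng = np.random.default_rng(12)
        g = 20
        num, den = rng.normal(0.2, 0.1, g), rng.uniform(2, 3, g)
        m1 = np.full(g, 50.0)
        m2 = rng.integers(10, 200, g).astype(float)
        se1 = ak.block_jackknife(JackknifeInput(num, den, m1))[2]
        se2 = ak.block_jackknife(JackknifeInput(num, den, m2))[2]
        assert se1 != pytest.approx(se2, rel=1e-3)

    def test_degenerate_blocks_warn_with_infinite_z(self):
        num = np.array([1.0, 2.0, 3.0])
        den = np.array([2.0, 4.0, 6.0])  # every ratio identical
        m = np.array([10.0, 20.0, 30.0])
        with pytest.warns(RuntimeWarning, match="signed infinity"):
            est, _, se, z = ak.block_jackknife(JackknifeInput(num, den, m))
        assert se == 0.0 and np.isinf(z) and z > 0

    def test_single_block_rejected(self):
        jk = JackknifeInput(np.array([1.0]), np.array([2.0]), np.array([5.0]))
        with pytest.raises(GenotypeError, match="blocks"):
            ak.block_jackknife(jk)

    def test_zero_weight_blocks_dropped(self):
        num = np.array([1.0, 0.0, 2.0])
        den = np.array([2.0, 0.0, 5.0])
        m = np.array([10.0, 0.0, 30.0])
        est, _, se, _ = ak.block_jackknife(JackknifeInput(num, den, m))
        est2, _, se2, _ = ak.block_jackknife(
            JackknifeInput(num[[0, 2]], den[[0, 2]], m[[0, 2]])
        )
        assert est == est2 and se == se2
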