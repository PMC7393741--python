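"""Formation-model tests: closed forms vs exhaustive enumeration and
Monte-Carlo simulation."""

import itertools
import math

import numpy as np
import pytest

from hashdemux import (
    FormationParams,
    droplet_rates,
    expected_msm_venn,
    simulate_formation,
    singlet_rate,
)


def enumerate_droplet_rates(X, y):
    """Exact per-droplet occupancy probabilities by enumerating all X^Y
    equally likely assignments of labelled cells to droplets.

    Returns unconditional probabilities for droplet 0 (all droplets are
    exchangeable): non-empty, singlet, per-sample SSD, MSM, SSM, and the
    probability of each exact sample-subset occupancy.
    """
    M = len(y)
    Y = sum(y)
    sample_of_cell = [l for l in range(M) for _ in range(y[l])]
    total = X**Y
    stats = {"nonempty": 0, "singlet": 0, "msm": 0, "ssm": 0}
    ssd = [0] * M
    subset_counts: dict[frozenset, int] = {}
    for assign in itertools.product(range(X), repeat=Y):
        in0 = [sample_of_cell[c] for c in range(Y) if assign[c] == 0]
        if not in0:
            continue
        stats["nonempty"] += 1
        present = frozenset(in0)
        subset_counts[present] = subset_counts.get(present, 0) + 1
        if len(in0) == 1:
            stats["singlet"] += 1
        if len(present) >= 2:
            stats["msm"] += 1
        elif len(in0) >= 2:
            stats["ssm"] += 1
        if len(present) == 1:
            ssd[next(iter(present))] += 1
    return (
        {k: v / total for k, v in stats.items()},
        [v / total for v in ssd],
        {k: v / total for k, v in subset_counts.items()},
    )


def all_enumeration_configs():
    configs = []
    for X in range(1, 5):
        for M in range(1, 4):
            for split in itertools.product(range(1, 5), repeat=M):
                if sum(split) <= 4:
                    configs.append((X, split))
    return configs


class TestSingletRate:
    def test_one_cell_is_always_a_singlet(self):
        for X in (1, 2, 50, 1e6):
            assert singlet_rate(X, 1) == pytest.approx(1.0)

    def test_three_cells_three_droplets_vs_enumeration(self):
        stats, _, _ = enumerate_droplet_rates(3, (3,))
        assert singlet_rate(3, 3) == pytest.approx(
            stats["singlet"] / stats["nonempty"], abs=1e-12
        )

    def test_independent_of_sample_split(self):
        base = singlet_rate(100, 40)
        for y in [(40,), (20, 20), (10, 10, 10, 10), (1, 39)]:
            r = droplet_rates(FormationParams(X=100, r_cap=1.0, y=y))
            assert r.p_singlet == pytest.approx(base, abs=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            singlet_rate(0, 5)
        with pytest.raises(ValueError):
            singlet_rate(10, 0)


class TestEnumerationOracle:
    @pytest.mark.parametrize("X,split", all_enumeration_configs())
    def test_exact_agreement_small_configs(self, X, split):
        stats, ssd, _ = enumerate_droplet_rates(X, split)
        r = droplet_rates(FormationParams(X=X, r_cap=1.0, y=split))
        pne = stats["nonempty"]
        assert r.p_singlet == pytest.approx(stats["singlet"] / pne, abs=1e-12)
        assert r.p_msm == pytest.approx(stats["msm"] / pne, abs=1e-12)
        assert r.p_ssm == pytest.approx(stats["ssm"] / pne, abs=1e-12)
        for l, v in enumerate(ssd):
            assert r.p_ssd_by_sample[l] == pytest.approx(v / pne, abs=1e-12)

    @pytest.mark.parametrize("X,split", [(3, (1, 1, 1)), (2, (2, 1)), (4, (2, 2))])
    def test_venn_expectations_vs_enumeration(self, X, split):
        _, _, subsets = enumerate_droplet_rates(X, split)
        r_cap = 0.7
        venn = expected_msm_venn(FormationParams(X=X, r_cap=r_cap, y=split))
        for u, e in venn.items():
            # expected count of droplets whose occupied-sample set is exactly u
            assert e == pytest.approx(r_cap * X * subsets.get(u, 0.0), abs=1e-10)


class TestVennIdentities:
    def test_partition_of_nonempty(self):
        p = FormationParams(X=50, r_cap=0.6, y=(10, 20, 5))
        venn = expected_msm_venn(p)
        total = sum(venn.values())
        lq = math.log1p(-1 / 50)
        expected = 0.6 * 50 * -math.expm1(35 * lq)
        assert total == pytest.approx(expected, rel=1e-12)

    def test_two_sample_inclusion_exclusion(self):
        p = FormationParams(X=80, r_cap=1.0, y=(12, 30))
        venn = expected_msm_venn(p)
        r = droplet_rates(p)
        pne = -math.expm1(42 * math.log1p(-1 / 80))
        # non-empty droplets split into SSD_1, SSD_2 and the {1,2} class
        both = 80 * pne - venn[frozenset({0})] - venn[frozenset({1})]
        assert venn[frozenset({0, 1})] == pytest.approx(both, rel=1e-10)
        assert r.p_msm == pytest.approx(venn[frozenset({0, 1})] / (80 * pne), rel=1e-10)

    def test_monte_carlo_agreement(self):
        p = FormationParams(X=50, r_cap=0.6, y=(10, 20, 5))
        venn = expected_msm_venn(p, min_size=2)
        sim = simulate_formation(p, reps=20000, seed=5)
        for u, e in venn.items():
            if e < 1e-3:
                continue
            obs = sim.venn.get(u, 0) / sim.reps
            sd = math.sqrt(e / sim.reps)  # ~Poisson errors on the mean count
            assert abs(obs - e) < max(4 * sd, 0.02 * e + 1e-3)


class TestSimulator:
    def test_zero_capture_rate(self):
        sim = simulate_formation(FormationParams(X=20, r_cap=0.0, y=(10,)), reps=50, seed=0)
        assert sim.n_captured_nonempty == 0

    def test_single_droplet_holds_everything(self):
        sim = simulate_formation(FormationParams(X=1, r_cap=1.0, y=(3, 4)), reps=20, seed=0)
        assert sim.n_captured_nonempty == 20
        assert sim.n_msm == 20  # two samples in one droplet every time

    def test_rates_converge_to_closed_form(self):
        """Aggregate empirical rates (total tallies over all repetitions)
        are consistent estimators of the per-droplet conditional rates."""
        p = FormationParams(X=100, r_cap=1.0, y=(13, 13, 12, 12))
        r = droplet_rates(p)
        sim = simulate_formation(p, reps=30000, seed=7)
        for idx, (emp, analytic) in enumerate(
            ((sim.p_singlet, r.p_singlet), (sim.p_msm, r.p_msm), (sim.p_ssm, r.p_ssm))
        ):
            sem = np.nanstd(sim.per_rep[:, idx]) / math.sqrt(sim.reps)
            assert abs(emp - analytic) < 3.3 * sem + 1e-4, idx

    def test_identical_seed_and_chunking_reproduce(self):
        p = FormationParams(X=30, r_cap=0.8, y=(8, 9))
        a = simulate_formation(p, reps=500, seed=42, max_chunk_cells=100)
        b = simulate_formation(p, reps=500, seed=42, max_chunk_cells=100)
        assert (a.n_singlet, a.n_msm, a.n_ssm) == (b.n_singlet, b.n_msm, b.n_ssm)
        assert a.z == b.z

    def test_chunking_preserves_statistics(self):
        p = FormationParams(X=30, r_cap=0.8, y=(8, 9))
        a = simulate_formation(p, reps=4000, seed=42, max_chunk_cells=200)
        b = simulate_formation(p, reps=4000, seed=43, max_chunk_cells=10**6)
        assert a.n_captured_nonempty + a.n_singlet > 0
        assert abs(a.p_singlet - b.p_singlet) < 0.02
        assert abs(a.p_msm - b.p_msm) < 0.02


class TestRateIdentities:
    def test_ssm_routes_agree_on_random_draws(self, rng):
        """Complement route (1 - singlet - MSM) and the per-sample
        conditional-singlet route must agree to near machine precision."""
        for _ in range(1000):
            M = rng.integers(1, 6)
            X = rng.uniform(10, 2e5)
            y = rng.uniform(1, 5e4 / M, size=M)
            r = droplet_rates(FormationParams(X=X, r_cap=1.0, y=tuple(y)))
            complement = 1.0 - r.p_singlet - r.p_msm
            assert abs(r.p_ssm - complement) < 1e-12

    def test_rates_partition_unity(self, rng):
        for _ in range(200):
            M = rng.integers(1, 8)
            X = rng.uniform(5, 1e5)
            y = tuple(rng.uniform(1, 2e4 / M, size=M))
            r = droplet_rates(FormationParams(X=X, r_cap=0.5, y=y))
            assert r.p_singlet + r.p_msm + r.p_ssm == pytest.approx(1.0, abs=1e-12)
            assert r.p_ssd == pytest.approx(r.p_singlet + r.p_ssm, abs=1e-12)

    def test_more_samples_trade_ssm_for_msm(self):
        X, Y = 80000, 30000
        prev_msm, prev_ssm = -1.0, 2.0
        for M in range(1, 9):
            r = droplet_rates(FormationParams(X=X, r_cap=1.0, y=(Y / M,) * M))
            assert r.p_msm >= prev_msm - 1e-12
            assert r.p_ssm <= prev_ssm + 1e-12
            prev_msm, prev_ssm = r.p_msm, r.p_ssm

    def test_m1_has_no_msm(self):
        r = droplet_rates(FormationParams(X=500, r_cap=1.0, y=(200,)))
        assert r.p_msm == pytest.approx(0.0, abs=1e-12)
        assert r.p_ssm == pytest.approx(1.0 - singlet_rate(500, 200), abs=1e-12)
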