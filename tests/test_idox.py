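"""The dingo optimizer: update-rule arithmetic, invariants, and convergence."""

import numpy as np
import pytest
from scipy import stats

from wbancardio.idox import (
    IDOX,
    BETA_RANGES,
    IDOXConfig,
    OptimizationError,
    SearchSpace,
    adaptive_beta,
    decode_binary,
    decode_integer,
    group_attack,
    low_survival_update,
    persecution,
    scavenger,
    survival_rate,
)


def sphere(x):
    return float(np.sum(x * x))


def rastrigin(x):
    return float(10 * x.size + np.sum(x * x - 10 * np.cos(2 * np.pi * x)))


class TestUpdateRules:
    """Hand-evaluated oracles for each behavioural position update."""

    def test_group_attack_hand_case(self):
        # 1-D: agent at 2, attackers at {5, 9}, best at 1, beta1 = 0.5
        # mean offset = ((5-2)+(9-2))/2 = 5 -> 0.5*5 - 1 = 1.5
        out = group_attack(np.array([2.0]), np.array([[5.0], [9.0]]), np.array([1.0]), 0.5)
        assert out == pytest.approx([1.5])

    def test_group_attack_degenerate(self):
        agent = np.array([3.0, -1.0])
        best = np.array([0.5, 0.25])
        # all attackers equal to the agent: mean offset vanishes
        out = group_attack(agent, np.stack([agent, agent]), best, 1.7)
        assert out == pytest.approx(-best)
        assert group_attack(agent, np.array([[9.0, 9.0]]), best, 0.0) == pytest.approx(-best)

    def test_persecution_hand_case(self):
        # best + beta1*e^{beta2}*(peer - agent) = 4 + 0.5*e*(7-3) = 4 + 2e
        out = persecution(np.array([3.0]), np.array([4.0]), np.array([7.0]), 0.5, 1.0)
        assert out == pytest.approx([4.0 + 2.0 * np.e])

    def test_persecution_identities(self):
        agent, best, peer = np.array([1.0]), np.array([5.0]), np.array([2.0])
        assert persecution(agent, best, peer, 0.0, 0.7) == pytest.approx(best)
        # beta2 = 0 makes the exponential factor unity
        assert persecution(agent, best, peer, 1.5, 0.0) == pytest.approx(best + 1.5 * (peer - agent))

    def test_scavenger_hand_case(self):
        # 2-D, beta2=0.5, sigma=0: 0.5*(e^0.5*peer + ... sign -(-1)^0 = -1)
        peer = np.array([2.0, -4.0])
        agent = np.array([1.0, 1.0])
        out = scavenger(agent, peer, 0.5, 0)
        assert out == pytest.approx(0.5 * (np.exp(0.5) * peer - agent))

    def test_scavenger_sigma_flip(self):
        peer = agent = np.array([3.0])
        assert scavenger(agent, peer, 0.0, 1) == pytest.approx(agent)
        assert scavenger(agent, peer, 0.0, 0) == pytest.approx([0.0])

    def test_low_survival_hand_cases(self):
        best, p1 = np.array([1.0]), np.array([4.0])
        assert low_survival_update(best, p1, p1, 1) == pytest.approx(best + p1)
        assert low_survival_update(best, p1, p1, 0) == pytest.approx(best)
        # distinct peers: best + 0.5*(p1 - (-1)^sigma p2)
        p2 = np.array([10.0])
        assert low_survival_update(best, p1, p2, 0) == pytest.approx([1.0 - 3.0])


class TestSurvival:
    def test_orientation(self):
        sur = survival_rate(np.array([3.0, 1.0, 5.0]))
        assert sur[1] == 1.0  # best (minimum fitness)
        assert sur[2] == 0.0  # worst
        assert sur[0] == pytest.approx(0.5)  # midway -> linear interpolation

    def test_all_equal(self):
        assert np.all(survival_rate(np.full(4, 2.5)) == 1.0)

    def test_range_property(self, rng):
        for _ in range(50):
            sur = survival_rate(rng.normal(size=10))
            assert np.all((0 <= sur) & (sur <= 1))
            assert sur.max() == 1.0 and sur.min() == 0.0


class TestAdaptiveBeta:
    def test_degenerate_population_falls_back_to_classic(self, rng):
        draws = [adaptive_beta(np.ones(5), 1, rng) for _ in range(500)]
        assert min(draws) < -1 and max(draws) > 1  # spans the classic range

    def test_classic_mode_uniform(self, rng):
        draws = [adaptive_beta(rng.normal(size=8), 1, rng, mode="classic") for _ in range(10_000)]
        ks = stats.kstest(draws, stats.uniform(loc=-2, scale=4).cdf)
        assert ks.pvalue > 1e-4

    def test_improved_formula_hand_check(self):
        # fitnesses {0,1,2}: alpha = 0-2 = -2, X = (1-2)/(1-0) = -1
        # factor = alpha*c*X = 2c in [0,2]; always within the clipped beta1 range
        rng = np.random.default_rng(0)
        fit = np.array([0.0, 1.0, 2.0])
        draws = np.array([adaptive_beta(fit, 1, rng) for _ in range(2000)])
        assert np.all((0 <= draws) & (draws <= 2))
        # c ~ U(0,1) so the mean of 2c is ~1
        assert draws.mean() == pytest.approx(1.0, abs=0.05)

    def test_clipped_into_classic_range(self, rng):
        for idx in (1, 2):
            lo, hi = BETA_RANGES[idx]
            fit = np.array([0.0, 500.0, 1000.0])  # huge spread forces clipping
            draws = [adaptive_beta(fit, idx, rng) for _ in range(200)]
            assert all(lo <= d <= hi for d in draws)

    def test_empty_population(self, rng):
        with pytest.raises(OptimizationError):
            adaptive_beta(np.array([]), 1, rng)


class TestDecoding:
    def test_integer_round_and_clip(self):
        assert decode_integer(np.array([254.7]), 2, 255)[0] == 255
        assert decode_integer(np.array([-3.2]), 2, 255)[0] == 2
        assert decode_integer(np.array([16.4]), 2, 255)[0] == 16

    def test_binary_threshold_strict(self):
        # sigmoid(0) = 0.5 exactly: strict > keeps the bit off
        assert decode_binary(np.array([0.0, 1.0])).tolist() == [0, 1]

    def test_all_zero_repair(self):
        mask = decode_binary(np.array([-9.0, -5.0, -7.0]))
        assert mask.sum() == 1 and mask[1] == 1  # largest sigmoid forced on


class TestOptimize:
    def test_sphere_convergence_and_elitism(self):
        space = SearchSpace(5, -10, 10)
        cfg = IDOXConfig(population_size=20, max_iterations=50, seed=3)
        res = IDOX(space, cfg).optimize(sphere)
        hist = np.array(res.fitness_history)
        assert len(hist) == 50
        assert np.all(np.diff(hist) <= 0)  # elitism
        assert res.best_fitness < 0.1 * hist[0]

    @pytest.mark.parametrize("objective", [sphere, rastrigin])
    def test_beats_random_search_median(self, objective):
        """Equal-budget random search is the baseline oracle (dim <= 5)."""
        space = SearchSpace(3, -5.12, 5.12)
        idox_best, rand_best = [], []
        for seed in range(20):
            cfg = IDOXConfig(population_size=10, max_iterations=20, seed=seed)
            res = IDOX(space, cfg).optimize(objective)
            rng = np.random.default_rng(1000 + seed)
            lo, hi = space.bounds()
            samples = rng.uniform(lo, hi, size=(res.evaluations, space.dim))
            rand_best.append(min(objective(s) for s in samples))
            idox_best.append(res.best_fitness)
        assert np.median(idox_best) < np.median(rand_best)

    def test_bound_feasibility_tracked(self):
        space = SearchSpace(4, -1, 1)
        seen = []

        def spy(x):
            seen.append(x.copy())
            return sphere(x)

        IDOX(space, IDOXConfig(population_size=6, max_iterations=10, seed=5)).optimize(spy)
        arr = np.stack(seen)
        assert np.all(arr >= -1) and np.all(arr <= 1)

    def test_constant_objective_flat_history(self):
        space = SearchSpace(2, -1, 1)
        res = IDOX(space, IDOXConfig(population_size=5, max_iterations=8, seed=0)).optimize(
            lambda x: 1.0
        )
        assert res.fitness_history == [1.0] * 8

    def test_reference_budget_run(self):
        # population 100, 25 iterations, dim 30, bounds [-10, 10]
        space = SearchSpace(30, -10, 10)
        cfg = IDOXConfig(population_size=100, max_iterations=25, na_range=(2, 50), seed=1)
        res = IDOX(space, cfg).optimize(sphere)
        assert len(res.fitness_history) == 25

    def test_seeded_reproducibility(self):
        space = SearchSpace(3, -2, 2)
        cfg = IDOXConfig(population_size=8, max_iterations=12, seed=9)
        a = IDOX(space, cfg).optimize(sphere)
        b = IDOX(space, cfg).optimize(sphere)
        assert np.array_equal(a.best_position, b.best_position)
        assert a.fitness_history == b.fitness_history

    def test_zero_iterations_error(self):
        with pytest.raises(OptimizationError):
            IDOX(SearchSpace(2, -1, 1), IDOXConfig(max_iterations=0)).optimize(sphere)

    def test_nonfinite_objective_at_init(self):
        with pytest.raises(OptimizationError, match="non-finite"):
            IDOX(SearchSpace(2, -1, 1), IDOXConfig(seed=0)).optimize(lambda x: float("nan"))


class TestConfigValidation:
    def test_invalid_rates(self):
        with pytest.raises(ValueError):
            IDOXConfig(hunting_rate=1.5)

    def test_population_floor(self):
        with pytest.raises(ValueError):
            IDOXConfig(population_size=2)

    def test_space_validation(self):
        with pytest.raises(ValueError):
            SearchSpace(2, 1.0, 1.0)
        with pytest.raises(ValueError):
            SearchSpace(0, -1, 1)
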