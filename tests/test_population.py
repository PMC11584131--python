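import numpy as np
import pytest

from ssadrive import (
    AlleleState,
    GermlineParams,
    MatingCosts,
    SimulationConfig,
    expected_trajectory,
    initialize_population,
    mean_trajectory,
    next_generation,
    simulate,
)
from ssadrive.alleles import ALLELE_INDEX, G, R, S, U, V, W
from ssadrive.config import PRESETS
from ssadrive.population import (
    FEMALE_GENOTYPES,
    MALE_GENOTYPES,
    OffspringLaw,
    PopulationState,
)


def _neutral_config(**kw):
    defaults = dict(
        population_size=1000,
        generations=1,
        replicates=1,
        germline=GermlineParams(q=0.0, alpha_female=0.0, gamma=0.0),
        costs=MatingCosts.none(),
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestInitialize:
    def test_ten_percent_release(self):
        cfg = _neutral_config(population_size=1000, release_fraction=0.10)
        state = initialize_population(cfg)
        assert state.total == 1000
        assert state.n_females == state.n_males == 500
        assert state.count("female", (W, G)) == 50
        assert state.count("male", (G,)) == 50
        assert state.count("female", (W, W)) == 450
        assert state.count("male", (W,)) == 450

    def test_cage_seeding(self):
        cfg = _neutral_config(
            population_size=200, release_fraction=0.75, release_zygosity="homozygous"
        )
        state = initialize_population(cfg)
        assert state.count("female", (G, G)) == 75
        assert state.count("male", (G,)) == 75
        assert state.count("female", (W, W)) == 25
        assert state.count("male", (W,)) == 25

    def test_zero_release(self):
        cfg = _neutral_config(release_fraction=0.0)
        state = initialize_population(cfg)
        assert state.count("female", (W, W)) == 500
        assert state.count("male", (W,)) == 500
        assert state.allele_frequencies()[ALLELE_INDEX[W]] == 1.0

    def test_female_only_release(self):
        cfg = _neutral_config(population_size=100, release_fraction=0.1, release_sex="female")
        state = initialize_population(cfg)
        assert state.count("female", (W, G)) == 10
        assert state.count("male", (G,)) == 0


class TestNextGeneration:
    def test_wild_type_closure(self, rng):
        cfg = _neutral_config(release_fraction=0.0)
        state = initialize_population(cfg)
        out = next_generation(state, cfg, rng)
        assert out.count("female", (W, W)) == out.n_females
        assert out.count("male", (W,)) == out.n_males
        assert out.total == 1000

    def test_mendelian_neutrality_in_expectation(self):
        # q=0, alpha=0, no costs: drive frequency is a martingale.
        cfg = _neutral_config(population_size=500, release_fraction=0.2)
        state = initialize_population(cfg)
        f0 = state.allele_frequencies()
        drive0 = f0[ALLELE_INDEX[G]]
        law = OffspringLaw.from_config(cfg)
        rng = np.random.default_rng(0)
        n_rep = 10_000
        freqs = np.empty(n_rep)
        for k in range(n_rep):
            out = next_generation(state, cfg, rng, law=law)
            freqs[k] = out.allele_frequencies()[ALLELE_INDEX[G]]
        se = freqs.std(ddof=1) / np.sqrt(n_rep)
        assert freqs.mean() == pytest.approx(drive0, abs=4 * se + 1e-12)

    def test_het_female_cohort_transmission(self):
        # G/W mothers x W fathers: offspring drive-carrier fraction equals
        # the maternal-gamete drive mass (~0.87 at the calibrated q, p).
        cfg = _neutral_config(
            population_size=200_000,
            germline=GermlineParams(q=0.95, p=0.78, delta=0.4),
        )
        fc = np.zeros(len(FEMALE_GENOTYPES), dtype=np.int64)
        mc = np.zeros(len(MALE_GENOTYPES), dtype=np.int64)
        fc[FEMALE_GENOTYPES.index((W, G))] = 100
        mc[MALE_GENOTYPES.index((W,))] = 100
        state = PopulationState(fc, mc)
        out = next_generation(state, cfg, np.random.default_rng(3), n_offspring=200_000)
        carriers = 0
        for sex, genotypes, arr in (
            ("female", FEMALE_GENOTYPES, out.female_counts),
            ("male", MALE_GENOTYPES, out.male_counts),
        ):
            for g, c in zip(genotypes, arr):
                if any(a.is_drive for a in g):
                    carriers += int(c)
        assert carriers / out.total == pytest.approx(0.8705, abs=0.005)

    def test_extinct_state_is_terminal(self, rng):
        cfg = _neutral_config()
        state = PopulationState(
            np.zeros(len(FEMALE_GENOTYPES), dtype=np.int64),
            np.eye(1, len(MALE_GENOTYPES), dtype=np.int64)[0] * 5,
        )
        assert state.extinct
        out = next_generation(state, cfg, rng)
        assert out is state

    def test_yellow_males_rarely_father(self):
        # cost 0.97: yellow R males weight 0.03 against wild W males
        cfg = _neutral_config(costs=MatingCosts(cost_yellow_male=0.97, cost_yellow_female=0.0))
        law = OffspringLaw.from_config(cfg)
        state_m = np.zeros(len(MALE_GENOTYPES))
        state_m[MALE_GENOTYPES.index((W,))] = 50
        state_m[MALE_GENOTYPES.index((R,))] = 50
        state_f = np.zeros(len(FEMALE_GENOTYPES))
        state_f[FEMALE_GENOTYPES.index((W, W))] = 100
        _, pm = law.parent_distributions(state_f, state_m)
        assert pm[MALE_GENOTYPES.index((R,))] == pytest.approx(0.03 / 1.03)


class TestSimulate:
    def test_zero_generations(self):
        cfg = _neutral_config(generations=0, replicates=1, release_fraction=0.1)
        (traj,) = simulate(cfg)
        assert traj.allele_freq.shape[0] == 1
        init = initialize_population(cfg)
        np.testing.assert_allclose(traj.allele_freq[0], init.allele_frequencies())

    def test_reproducible_under_seed(self):
        cfg = PRESETS["fig6d"].replace(replicates=3, generations=5, seed=42)
        a = simulate(cfg)
        b = simulate(cfg)
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.allele_freq, tb.allele_freq)

    def test_frequencies_sum_to_one(self):
        cfg = PRESETS["fig6b"].replace(replicates=5, generations=10, seed=9)
        for traj in simulate(cfg):
            np.testing.assert_allclose(traj.allele_freq.sum(axis=1), 1.0, atol=1e-9)
            np.testing.assert_allclose(traj.phenotype_freq.sum(axis=1), 1.0, atol=1e-9)

    def test_stochastic_mean_matches_deterministic_oracle(self):
        # N=10^4: replicate mean within 3 Monte-Carlo s.e. of the exact
        # recursion, per generation, for the drive-class frequency.
        cfg = PRESETS["fig6d"].replace(
            population_size=10_000, replicates=100, generations=20, seed=11
        )
        trajs = simulate(cfg)
        det = expected_trajectory(cfg)
        drive = np.array([t.drive_freq for t in trajs])
        mean = drive.mean(axis=0)
        se = drive.std(axis=0, ddof=1) / np.sqrt(len(trajs))
        err = np.abs(mean - det.drive_freq)
        assert (err <= 3 * se + 1e-4).all()


class TestExpectedTrajectory:
    def test_neutral_constant(self):
        cfg = _neutral_config(generations=20, release_fraction=0.2)
        det = expected_trajectory(cfg)
        for t in range(21):
            np.testing.assert_allclose(det.allele_freq[t], det.allele_freq[0], atol=1e-12)

    def test_forced_excision_branch(self):
        # alpha=1, eps=1, gamma=0, q=0: all maternally transmitted G -> V
        cfg = _neutral_config(
            generations=1,
            release_fraction=0.2,
            release_sex="female",
            germline=GermlineParams(q=0.0, alpha_female=1.0, alpha_male=0.0, gamma=0.0, epsilon=1.0),
        )
        det = expected_trajectory(cfg)
        assert det.allele_freq[1, ALLELE_INDEX[G]] == pytest.approx(0.0, abs=1e-12)
        assert det.allele_freq[1, ALLELE_INDEX[V]] > 0

    def test_engines_agree_on_peak(self):
        cfg = PRESETS["fig6b"].replace(replicates=50, seed=5)
        stoch_peak = mean_trajectory(simulate(cfg)).drive_freq.max()
        det_peak = expected_trajectory(cfg).drive_freq.max()
        assert stoch_peak == pytest.approx(det_peak, abs=0.05)

    def test_drive_class_vanishes_with_excision(self):
        # alpha>0, gamma=0: (G+S) -> 0 over long horizons on every preset.
        # fig6e (alpha=0.05) decays the slowest and needs a longer window.
        for name, horizon in (("fig6b", 200), ("fig6c", 200), ("fig6d", 200), ("fig6e", 800)):
            cfg = PRESETS[name].replace(generations=horizon)
            det = expected_trajectory(cfg)
            assert det.drive_freq[-1] < 0.01, name
            peak_at = det.drive_freq.argmax()
            assert (np.diff(det.drive_freq[peak_at:]) <= 1e-12).all(), name

    def test_peak_monotone_decreasing_in_alpha(self):
        peaks = []
        for alpha in (0.05, 0.1, 0.3):
            cfg = PRESETS["fig6d"]
            cfg = cfg.replace(germline=cfg.germline.replace(alpha_female=alpha))
            peaks.append(expected_trajectory(cfg).drive_freq.max())
        assert peaks[0] >= peaks[1] >= peaks[2]

    def test_v_replaces_drive_with_isite_disruption(self):
        # fig6e with gamma=0.001: V takes over, S stays below 5%
        cfg = PRESETS["fig6e"].replace(generations=200)
        cfg = cfg.replace(germline=cfg.germline.replace(gamma=0.001))
        det = expected_trajectory(cfg)
        s_series = det.allele_series(S)
        v_series = det.allele_series(V)
        # S stays a small minority over the preset's 60-generation window
        assert (s_series[:61] < 0.05).all()
        assert s_series.max() < 0.10
        assert v_series[-1] > 0.5
        assert v_series[-1] > s_series[-1] + det.allele_series(G)[-1]
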