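import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ssadrive import (
    AlleleDistribution,
    AlleleState,
    GermlineParams,
    ZygoticParams,
    apply_zygotic_effects,
    gamete_distribution,
    resolve_drive_allele,
    resolve_susceptible_allele,
)
from ssadrive.alleles import ALLELE_ORDER, G, R, S, U, V, W
from ssadrive.germline import ParameterDomainError, zygotic_allele_law

from conftest import assert_distribution

probs = st.floats(0.0, 1.0, allow_nan=False)


class TestParams:
    def test_rejects_out_of_range(self):
        with pytest.raises(ParameterDomainError):
            GermlineParams(q=1.2)
        with pytest.raises(ParameterDomainError):
            GermlineParams(delta=-0.1)
        with pytest.raises(ParameterDomainError):
            ZygoticParams(z_maternal=2.0)

    def test_rejects_alpha_plus_gamma_above_one(self):
        with pytest.raises(ParameterDomainError):
            GermlineParams(alpha_female=0.7, gamma=0.5)
        # per-sex: male alpha may be small while female is large
        GermlineParams(alpha_female=0.9, alpha_male=0.0, gamma=0.1)

    def test_distribution_must_normalize(self):
        with pytest.raises(ValueError):
            AlleleDistribution(np.array([0.5, 0, 0, 0, 0, 0]))
        with pytest.raises(ValueError):
            AlleleDistribution(np.array([1.5, -0.5, 0, 0, 0, 0]))


class TestResolveSusceptible:
    def test_no_cutting(self):
        d = resolve_susceptible_allele(GermlineParams(q=0.0), drive_present=True)
        assert_distribution(d, {W: 1.0})

    def test_no_drive_present(self):
        d = resolve_susceptible_allele(GermlineParams(q=1.0, p=1.0), drive_present=False)
        assert_distribution(d, {W: 1.0})

    def test_complete_conversion(self):
        d = resolve_susceptible_allele(GermlineParams(q=1.0, p=1.0), drive_present=True)
        assert_distribution(d, {G: 1.0})

    def test_branch_products(self):
        # hand enumeration: W 0.1, G 0.9*0.8, U 0.9*0.2*0.4, R 0.9*0.2*0.6
        d = resolve_susceptible_allele(
            GermlineParams(q=0.9, p=0.8, delta=0.4), drive_present=True
        )
        assert_distribution(d, {W: 0.10, G: 0.72, U: 0.072, R: 0.108}, atol=1e-12)


class TestResolveDrive:
    def test_inert_second_nuclease(self):
        d = resolve_drive_allele(GermlineParams(alpha_female=0, gamma=0), "female")
        assert_distribution(d, {G: 1.0})

    def test_branch_products(self):
        d = resolve_drive_allele(
            GermlineParams(alpha_female=0.1, gamma=0.001, epsilon=1.0), "female"
        )
        assert_distribution(d, {V: 0.1, S: 0.001, G: 0.899})

    def test_full_excision_full_reversion(self):
        d = resolve_drive_allele(
            GermlineParams(alpha_female=1.0, gamma=0.0, epsilon=0.0), "female"
        )
        assert_distribution(d, {W: 1.0})

    def test_sex_specific_alpha(self):
        p = GermlineParams(alpha_female=0.3, alpha_male=0.02, epsilon=1.0)
        assert resolve_drive_allele(p, "female")[V] == pytest.approx(0.3)
        assert resolve_drive_allele(p, "male")[V] == pytest.approx(0.02)

    @given(eps=probs, alpha=st.floats(0.01, 1.0))
    def test_epsilon_extremes(self, eps, alpha):
        d = resolve_drive_allele(
            GermlineParams(alpha_female=alpha, epsilon=eps), "female"
        )
        if eps == 1.0:
            assert d[W] == 0.0
        if eps == 0.0:
            assert d[V] == 0.0


class TestGameteDistribution:
    def test_mendelian_segregation(self):
        d = gamete_distribution((G, W), "female", GermlineParams(q=0, alpha_female=0))
        assert_distribution(d, {G: 0.5, W: 0.5})

    def test_complete_homing(self):
        d = gamete_distribution(
            (G, W), "female", GermlineParams(q=1, p=1, alpha_female=0, gamma=0)
        )
        assert_distribution(d, {G: 1.0})

    def test_calibrated_transmission(self):
        d = gamete_distribution(
            (G, W),
            "female",
            GermlineParams(q=0.95, p=0.78, delta=0.4, alpha_female=0, gamma=0),
        )
        assert_distribution(d, {G: 0.8705, W: 0.025, U: 0.0418, R: 0.0627}, atol=1e-10)

    def test_male_w_never_cut(self):
        # hemizygous X has no homolog: no homing in males
        d = gamete_distribution((W,), "male", GermlineParams(q=1.0, p=1.0))
        assert_distribution(d, {W: 1.0})

    def test_male_drive_undergoes_ssa(self):
        d = gamete_distribution(
            (G,), "male", GermlineParams(alpha_male=0.05, epsilon=1.0)
        )
        assert_distribution(d, {G: 0.95, V: 0.05})

    def test_s_is_nuclease_source_but_ssa_immune(self):
        p = GermlineParams(q=1.0, p=1.0, alpha_female=0.5, epsilon=1.0)
        d = gamete_distribution((S, W), "female", p)
        # W fully converted by the S-driven nuclease; S itself untouched
        assert_distribution(d, {S: 0.5, G: 0.5})

    def test_wrong_arity_rejected(self):
        with pytest.raises(ValueError):
            gamete_distribution((W,), "female", GermlineParams())
        with pytest.raises(ValueError):
            gamete_distribution((W, W), "male", GermlineParams())

    @given(
        q=probs,
        p=probs,
        delta=probs,
        alpha=probs,
        eps=probs,
        gi=st.integers(0, 5),
        gj=st.integers(0, 5),
    )
    @settings(max_examples=200, deadline=None)
    def test_always_normalized(self, q, p, delta, alpha, eps, gi, gj):
        params = GermlineParams(
            q=q, p=p, delta=delta, alpha_female=alpha, epsilon=eps, gamma=0.0
        )
        geno = (ALLELE_ORDER[gi], ALLELE_ORDER[gj])
        d = gamete_distribution(geno, "female", params)
        assert d.probs.sum() == pytest.approx(1.0, abs=1e-12)
        assert (d.probs >= 0).all()

    @given(q=probs, delta=probs, gi=st.integers(0, 5), gj=st.integers(0, 5))
    @settings(max_examples=100, deadline=None)
    def test_q0_alpha0_is_mendelian(self, q, delta, gi, gj):
        # q=0 and alpha=0 must reduce to exact Mendelian segregation
        params = GermlineParams(q=0.0, delta=delta, alpha_female=0.0, gamma=0.0)
        geno = (ALLELE_ORDER[gi], ALLELE_ORDER[gj])
        d = gamete_distribution(geno, "female", params)
        expected = {}
        for a in geno:
            expected[a] = expected.get(a, 0.0) + 0.5
        assert_distribution(d, expected)


def _oracle_resolve(allele, params, sex, drive_present, rng):
    """Independent branch-by-branch sampling of the outcome tree."""
    if allele is W:
        if not drive_present or rng.random() >= params.q:
            return W
        if rng.random() < params.p:
            return G
        return U if rng.random() < params.delta else R
    if allele is G:
        u = rng.random()
        if u < params.alpha(sex):
            return V if rng.random() < params.epsilon else W
        if u < params.alpha(sex) + params.gamma:
            return S
        return G
    return allele


def test_monte_carlo_matches_analytic_law():
    """10^5 oracle-sampled gametes agree with the analytic law (4 sigma)."""
    params = GermlineParams(
        q=0.9, p=0.7, delta=0.4, alpha_female=0.15, gamma=0.01, epsilon=0.6
    )
    genotype = (G, W)
    n = 100_000
    rng = np.random.default_rng(7)
    counts = dict.fromkeys(ALLELE_ORDER, 0)
    for _ in range(n):
        parent = genotype[rng.integers(2)]
        counts[_oracle_resolve(parent, params, "female", True, rng)] += 1
    analytic = gamete_distribution(genotype, "female", params)
    for state in ALLELE_ORDER:
        p = analytic[state]
        sigma = np.sqrt(n * p * (1 - p))
        assert abs(counts[state] - n * p) <= 4 * sigma + 1, state


class TestZygoticEffects:
    def test_identity_when_off(self, rng):
        z = ZygoticParams(0.0, 0.0)
        geno = (W, W)
        out = apply_zygotic_effects(geno, (G, W), (W,), z, GermlineParams(), rng)
        assert out == geno

    def test_forced_branch(self, rng):
        z = ZygoticParams(z_maternal=1.0)
        params = GermlineParams(delta=0.0)
        out = apply_zygotic_effects((U, W), (G, W), (W,), z, params, rng)
        assert out == (U, R)  # paternal W forced to out-of-frame

    def test_per_allele_law(self):
        # z=0.86, delta=0.4 -> {W: 0.14, U: 0.344, R: 0.516}
        law = zygotic_allele_law(W, 0.86, 0.4)
        assert_distribution(law, {W: 0.14, U: 0.344, R: 0.516}, atol=1e-12)

    def test_non_w_untouched(self, rng):
        z = ZygoticParams(z_maternal=1.0, z_paternal=1.0)
        out = apply_zygotic_effects((V, U), (G, W), (W,), z, GermlineParams(), rng)
        assert out == (V, U)

    def test_no_maternal_cut_without_drive_mother(self, rng):
        z = ZygoticParams(z_maternal=1.0)
        out = apply_zygotic_effects((W, W), (W, W), (W,), z, GermlineParams(), rng)
        assert out == (W, W)

    def test_paternal_drive_cuts_maternal_w(self, rng):
        z = ZygoticParams(z_paternal=1.0)
        params = GermlineParams(delta=1.0)
        out = apply_zygotic_effects((W, G), (W, W), (G,), z, params, rng)
        assert out == (U, G)

    def test_sons_unaffected(self, rng):
        z = ZygoticParams(z_maternal=1.0, z_paternal=1.0)
        out = apply_zygotic_effects((W,), (G, W), (G,), z, GermlineParams(), rng)
        assert out == (W,)
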