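"""Discrete-generation X-linked population dynamics.

Two engines share one exact per-pair offspring law derived from the
germline model:

* :func:`simulate` — stochastic Wright–Fisher-style chains with a
  fixed census size, multinomial offspring resampling and weighted
  mate choice;
* :func:`expected_trajectory` — the infinite-population deterministic
  recursion on genotype frequencies, used as an oracle for the
  stochastic means.

Genotypes are tuples of :class:`~ssadrive.alleles.AlleleState`; female
genotypes carry two X alleles (stored in canonical sorted order once
parental origin no longer matters), male genotypes one.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np

from .alleles import ALLELE_INDEX, ALLELE_ORDER, AlleleState
from .germline import (
    GermlineParams,
    ZygoticParams,
    gamete_distribution,
    zygotic_allele_law,
)
from .phenotypes import YREMEDE, DriveVariant, score_phenotype

__all__ = [
    "MatingCosts",
    "SimulationConfig",
    "PopulationState",
    "Trajectory",
    "initialize_population",
    "next_generation",
    "simulate",
    "expected_trajectory",
    "mean_trajectory",
    "OffspringLaw",
]

#: Canonical female genotypes: unordered pairs of allele states.
FEMALE_GENOTYPES: tuple[tuple[AlleleState, AlleleState], ...] = tuple(
    itertools.combinations_with_replacement(ALLELE_ORDER, 2)
)
#: Canonical male genotypes: single X allele.
MALE_GENOTYPES: tuple[tuple[AlleleState], ...] = tuple((a,) for a in ALLELE_ORDER)

_FIDX = {g: i for i, g in enumerate(FEMALE_GENOTYPES)}
_MIDX = {g: i for i, g in enumerate(MALE_GENOTYPES)}

PHENOTYPE_CLASSES = ("wild", "drive", "yellow")


def canonical_female(pair: tuple[AlleleState, AlleleState]) -> tuple[AlleleState, AlleleState]:
    a, b = pair
    return (a, b) if ALLELE_INDEX[a] <= ALLELE_INDEX[b] else (b, a)


@dataclass(frozen=True)
class MatingCosts:
    """Fractional mating-success costs of the yellow body phenotype.

    A phenotypically yellow individual's mating weight is ``1 - cost``
    for its sex; wild-bodied individuals have weight 1.
    """

    cost_yellow_male: float = 0.97
    cost_yellow_female: float = 0.31

    def __post_init__(self) -> None:
        for name in ("cost_yellow_male", "cost_yellow_female"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} must lie in [0, 1]")

    @classmethod
    def none(cls) -> "MatingCosts":
        return cls(0.0, 0.0)


@dataclass(frozen=True)
class SimulationConfig:
    population_size: int = 1000
    generations: int = 60
    replicates: int = 100
    release_fraction: float = 0.10
    release_sex: str = "both"  # female | male | both
    release_zygosity: str = "heterozygous"  # heterozygous | homozygous | hemizygous
    seed: int = 0
    germline: GermlineParams = field(default_factory=GermlineParams)
    zygotic: ZygoticParams = field(default_factory=ZygoticParams)
    costs: MatingCosts = field(default_factory=MatingCosts.none)
    variant: DriveVariant = YREMEDE

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be at least 2")
        if not (0.0 <= self.release_fraction <= 1.0):
            raise ValueError("release_fraction must lie in [0, 1]")
        if self.release_sex not in ("female", "male", "both"):
            raise ValueError(f"unknown release_sex {self.release_sex!r}")
        if self.release_zygosity not in ("heterozygous", "homozygous", "hemizygous"):
            raise ValueError(f"unknown release_zygosity {self.release_zygosity!r}")
        if self.generations < 0 or self.replicates < 1:
            raise ValueError("generations must be >= 0 and replicates >= 1")

    def replace(self, **changes) -> "SimulationConfig":
        return replace(self, **changes)

    @property
    def effective_germline(self) -> GermlineParams:
        """Germline parameters with SSA forced off for non-excising variants."""
        if self.variant.ssa_enabled:
            return self.germline
        return self.germline.replace(alpha_female=0.0, alpha_male=0.0, gamma=0.0)


@dataclass
class PopulationState:
    """Genotype-by-sex counts for one discrete generation."""

    female_counts: np.ndarray  # length len(FEMALE_GENOTYPES)
    male_counts: np.ndarray  # length len(MALE_GENOTYPES)

    def __post_init__(self) -> None:
        self.female_counts = np.asarray(self.female_counts, dtype=np.int64)
        self.male_counts = np.asarray(self.male_counts, dtype=np.int64)
        if (self.female_counts < 0).any() or (self.male_counts < 0).any():
            raise ValueError("negative genotype count")

    @property
    def n_females(self) -> int:
        return int(self.female_counts.sum())

    @property
    def n_males(self) -> int:
        return int(self.male_counts.sum())

    @property
    def total(self) -> int:
        return self.n_females + self.n_males

    @property
    def extinct(self) -> bool:
        """True when either sex is absent (no further reproduction)."""
        return self.n_females == 0 or self.n_males == 0

    def count(self, sex: str, genotype: tuple[AlleleState, ...]) -> int:
        if sex == "female":
            return int(self.female_counts[_FIDX[canonical_female(genotype)]])
        return int(self.male_counts[_MIDX[tuple(genotype)]])

    def allele_frequencies(self) -> np.ndarray:
        """Frequency of each allele state among all X chromosomes."""
        counts = np.zeros(len(ALLELE_ORDER))
        for i, g in enumerate(FEMALE_GENOTYPES):
            c = self.female_counts[i]
            if c:
                counts[ALLELE_INDEX[g[0]]] += c
                counts[ALLELE_INDEX[g[1]]] += c
        for i, g in enumerate(MALE_GENOTYPES):
            counts[ALLELE_INDEX[g[0]]] += self.male_counts[i]
        total = counts.sum()
        return counts / total if total else counts

    def phenotype_frequencies(self, variant: DriveVariant = YREMEDE) -> np.ndarray:
        """Frequencies of (wild, drive, yellow) phenotype classes.

        ``drive`` is any fluorescent individual; the body-colour
        classes cover the non-fluorescent remainder.
        """
        counts = np.zeros(3)
        for sex, genotypes, arr in (
            ("female", FEMALE_GENOTYPES, self.female_counts),
            ("male", MALE_GENOTYPES, self.male_counts),
        ):
            for i, g in enumerate(genotypes):
                c = arr[i]
                if not c:
                    continue
                ph = score_phenotype(g, sex, variant)
                if ph.is_drive:
                    counts[1] += c
                elif ph.body == "wild":
                    counts[0] += c
                else:
                    counts[2] += c
        total = counts.sum()
        return counts / total if total else counts


@dataclass
class Trajectory:
    """Per-generation allele and phenotype frequencies of one run."""

    allele_freq: np.ndarray  # (generations + 1, 6)
    phenotype_freq: np.ndarray  # (generations + 1, 3)
    extinct_at: int | None = None

    @property
    def n_generations(self) -> int:
        return self.allele_freq.shape[0] - 1

    def allele_series(self, state: AlleleState) -> np.ndarray:
        return self.allele_freq[:, ALLELE_INDEX[state]]

    @property
    def drive_freq(self) -> np.ndarray:
        """Frequency of nuclease-bearing X alleles (G + S) per generation."""
        return self.allele_series(AlleleState.G) + self.allele_series(AlleleState.S)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def initialize_population(config: SimulationConfig) -> PopulationState:
    """Release-scenario initial population with balanced sexes."""
    n = config.population_size
    n_f = n // 2
    n_m = n - n_f
    n_carriers = min(_round_half_up(config.release_fraction * n), n)

    if config.release_sex == "both":
        carriers_f = min(_round_half_up(n_carriers / 2), n_f)
        carriers_m = min(n_carriers - carriers_f, n_m)
    elif config.release_sex == "female":
        carriers_f, carriers_m = min(n_carriers, n_f), 0
    else:
        carriers_f, carriers_m = 0, min(n_carriers, n_m)

    drive_female = (
        canonical_female((AlleleState.G, AlleleState.G))
        if config.release_zygosity == "homozygous"
        else canonical_female((AlleleState.W, AlleleState.G))
    )
    fc = np.zeros(len(FEMALE_GENOTYPES), dtype=np.int64)
    mc = np.zeros(len(MALE_GENOTYPES), dtype=np.int64)
    fc[_FIDX[drive_female]] = carriers_f
    fc[_FIDX[(AlleleState.W, AlleleState.W)]] += n_f - carriers_f
    mc[_MIDX[(AlleleState.G,)]] = carriers_m
    mc[_MIDX[(AlleleState.W,)]] += n_m - carriers_m
    return PopulationState(fc, mc)


class OffspringLaw:
    """Precomputed exact offspring-genotype law for every parent pair.

    For mother genotype ``i`` and father genotype ``j``, ``daughters[i, j]``
    is the probability vector over canonical female genotypes of one
    daughter, and ``sons[i, j]`` the vector over male genotypes of one
    son, after germline resolution of both gametes and zygotic effects.
    """

    def __init__(
        self,
        params: GermlineParams,
        zparams: ZygoticParams,
        costs: MatingCosts,
        variant: DriveVariant = YREMEDE,
    ):
        self.params = params
        self.zparams = zparams
        self.costs = costs
        self.variant = variant

        n_f, n_m, n_a = len(FEMALE_GENOTYPES), len(MALE_GENOTYPES), len(ALLELE_ORDER)
        egg = np.array(
            [gamete_distribution(g, "female", params).probs for g in FEMALE_GENOTYPES]
        )
        sperm = np.array(
            [gamete_distribution(g, "male", params).probs for g in MALE_GENOTYPES]
        )

        zyg_mat = np.array(  # paternal W under maternal deposition
            [zygotic_allele_law(a, zparams.z_maternal, params.delta).probs for a in ALLELE_ORDER]
        )
        zyg_pat = np.array(  # maternal W under paternal-drive zygotic expression
            [zygotic_allele_law(a, zparams.z_paternal, params.delta).probs for a in ALLELE_ORDER]
        )

        self.daughters = np.zeros((n_f, n_m, n_f))
        self.sons = np.zeros((n_f, n_m, n_m))
        drive_idx = [ALLELE_INDEX[AlleleState.G], ALLELE_INDEX[AlleleState.S]]

        for i, mg in enumerate(FEMALE_GENOTYPES):
            mother_drive = any(a.is_drive for a in mg)
            # Sons: maternal X only, no zygotic exposure (paternal Y).
            self.sons[i, :, :] = egg[i][None, :]
            for j in range(n_m):
                # Joint law over (maternal allele, paternal allele) before
                # zygotic resolution, conditioning on the *inherited*
                # paternal allele for zygotic expression.
                joint = np.outer(egg[i], sperm[j])
                out = np.zeros((n_a, n_a))
                for b in range(n_a):  # paternal inherited allele
                    col = joint[:, b]
                    mat = col.copy()
                    if b in drive_idx:  # zygotic expression cuts maternal W
                        mat = np.einsum("a,ab->b", col, zyg_pat)
                    pat = zyg_mat[b] if mother_drive else np.eye(n_a)[b]
                    out += np.outer(mat, pat)
                # Fold ordered pairs into canonical female genotypes.
                for a in range(n_a):
                    for b in range(n_a):
                        g = canonical_female((ALLELE_ORDER[a], ALLELE_ORDER[b]))
                        self.daughters[i, j, _FIDX[g]] += out[a, b]

        np.testing.assert_allclose(self.daughters.sum(axis=2), 1.0, atol=1e-9)
        np.testing.assert_allclose(self.sons.sum(axis=2), 1.0, atol=1e-9)

        self.female_weights = np.array(
            [
                1.0
                - (
                    costs.cost_yellow_female
                    if score_phenotype(g, "female", variant).body == "yellow"
                    else 0.0
                )
                for g in FEMALE_GENOTYPES
            ]
        )
        self.male_weights = np.array(
            [
                1.0
                - (
                    costs.cost_yellow_male
                    if score_phenotype(g, "male", variant).body == "yellow"
                    else 0.0
                )
                for g in MALE_GENOTYPES
            ]
        )

    @classmethod
    def from_config(cls, config: SimulationConfig) -> "OffspringLaw":
        return cls(config.effective_germline, config.zygotic, config.costs, config.variant)

    def parent_distributions(
        self, state_f: np.ndarray, state_m: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """Mate-choice laws: genotype frequencies weighted by mating weight."""
        wf = state_f * self.female_weights
        wm = state_m * self.male_weights
        sf, sm = wf.sum(), wm.sum()
        if sf <= 0 or sm <= 0:
            raise ValueError("no mating-capable parents of one sex")
        return wf / sf, wm / sm

    def offspring_laws(
        self, state_f: np.ndarray, state_m: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """Per-offspring genotype laws (daughter, son) given parent pools."""
        pf, pm = self.parent_distributions(state_f, state_m)
        pair = np.outer(pf, pm)
        daughter = np.einsum("ij,ijk->k", pair, self.daughters)
        son = np.einsum("ij,ijk->k", pair, self.sons)
        return daughter, son


def next_generation(
    state: PopulationState,
    config: SimulationConfig,
    rng: np.random.Generator,
    law: OffspringLaw | None = None,
    n_offspring: int | None = None,
) -> PopulationState:
    """One stochastic generation: weighted mating, gametes, multinomial census.

    Mothers are drawn proportionally to female mating weight and
    fathers to male mating weight; each of ``n_offspring`` (default:
    the configured census size) zygotes is female or male with equal
    probability.  An extinct input state is returned unchanged.
    """
    if state.extinct:
        return state
    if law is None:
        law = OffspringLaw.from_config(config)
    n = config.population_size if n_offspring is None else n_offspring
    daughter, son = law.offspring_laws(
        state.female_counts.astype(float), state.male_counts.astype(float)
    )
    combined = np.concatenate([0.5 * daughter, 0.5 * son])
    draw = rng.multinomial(n, combined / combined.sum())
    k = len(FEMALE_GENOTYPES)
    return PopulationState(draw[:k], draw[k:])


def _record(state: PopulationState, variant: DriveVariant) -> tuple[np.ndarray, np.ndarray]:
    return state.allele_frequencies(), state.phenotype_frequencies(variant)


def _run_chain(
    config: SimulationConfig, rng: np.random.Generator, law: OffspringLaw
) -> Trajectory:
    state = initialize_population(config)
    af = np.zeros((config.generations + 1, len(ALLELE_ORDER)))
    pf = np.zeros((config.generations + 1, len(PHENOTYPE_CLASSES)))
    af[0], pf[0] = _record(state, config.variant)
    extinct_at = None
    for t in range(1, config.generations + 1):
        if state.extinct:
            if extinct_at is None:
                extinct_at = t - 1
            af[t], pf[t] = af[t - 1], pf[t - 1]
            continue
        state = next_generation(state, config, rng, law=law)
        af[t], pf[t] = _record(state, config.variant)
    return Trajectory(af, pf, extinct_at)


def simulate(config: SimulationConfig) -> list[Trajectory]:
    """Run ``config.replicates`` independent seeded chains.

    Replicate ``k`` is driven by the ``k``-th child of
    ``SeedSequence(config.seed)``, so any single replicate is
    reproducible from ``(seed, k)`` alone.
    """
    law = OffspringLaw.from_config(config)
    children = np.random.SeedSequence(config.seed).spawn(config.replicates)
    return [
        _run_chain(config, np.random.default_rng(child), law) for child in children
    ]


def mean_trajectory(trajectories: list[Trajectory]) -> Trajectory:
    """Pointwise mean of replicate trajectories."""
    if not trajectories:
        raise ValueError("no trajectories")
    return Trajectory(
        np.mean([t.allele_freq for t in trajectories], axis=0),
        np.mean([t.phenotype_freq for t in trajectories], axis=0),
        None,
    )


def expected_trajectory(config: SimulationConfig) -> Trajectory:
    """Infinite-population deterministic recursion (expectation oracle).

    Iterates the exact genotype-frequency recursion induced by the same
    gamete laws, mating weights and zygotic effects as the stochastic
    engine, with no sampling and a fixed 1:1 sex ratio.
    """
    law = OffspringLaw.from_config(config)
    init = initialize_population(config)
    f = init.female_counts / max(init.n_females, 1)
    m = init.male_counts / max(init.n_males, 1)

    n_gen = config.generations
    af = np.zeros((n_gen + 1, len(ALLELE_ORDER)))
    pf = np.zeros((n_gen + 1, len(PHENOTYPE_CLASSES)))

    def freqs(fv: np.ndarray, mv: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        counts = np.zeros(len(ALLELE_ORDER))
        for i, g in enumerate(FEMALE_GENOTYPES):
            counts[ALLELE_INDEX[g[0]]] += fv[i]
            counts[ALLELE_INDEX[g[1]]] += fv[i]
        for i, g in enumerate(MALE_GENOTYPES):
            counts[ALLELE_INDEX[g[0]]] += mv[i]
        counts /= counts.sum()
        ph = np.zeros(3)
        for sex, genotypes, vec, w in (
            ("female", FEMALE_GENOTYPES, fv, 0.5),
            ("male", MALE_GENOTYPES, mv, 0.5),
        ):
            for i, g in enumerate(genotypes):
                p = score_phenotype(g, sex, config.variant)
                cls = 1 if p.is_drive else (0 if p.body == "wild" else 2)
                ph[cls] += w * vec[i]
        return counts, ph

    af[0], pf[0] = freqs(f, m)
    for t in range(1, n_gen + 1):
        f, m = law.offspring_laws(f, m)
        af[t], pf[t] = freqs(f, m)
    return Trajectory(af, pf, None)
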