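"""Cage-trial protocol emulation.

Each cage is founded by a seeded pool of adults.  Every generation the
seeded flies produce a brood, from which two disjoint random pools are
drawn: one pool is phenotype-scored and recorded, the other is seeded
into the next cage.  Only scored pools are observable, so elimination
times are measured on them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .population import (
    FEMALE_GENOTYPES,
    MALE_GENOTYPES,
    OffspringLaw,
    PopulationState,
    SimulationConfig,
    initialize_population,
    next_generation,
)
from .phenotypes import score_phenotype

__all__ = ["CageConfig", "CageTrialResult", "run_cage_trial", "run_cage_trials", "elimination_generation"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CageConfig:
    """Cage protocol on top of a base simulation configuration.

    ``base.population_size`` is the founding seed size;
    ``base.generations`` the number of scored cage generations.
    ``brood_size`` is the total offspring produced per generation
    before pooling and must normally exceed ``2 * pool_size``.
    """

    base: SimulationConfig = field(
        default_factory=lambda: SimulationConfig(
            population_size=200,
            generations=20,
            release_fraction=0.75,
            release_zygosity="homozygous",
        )
    )
    pool_size: int = 150
    brood_size: int = 600

    def __post_init__(self) -> None:
        if self.pool_size < 1 or self.brood_size < 2:
            raise ValueError("pool_size and brood_size must be positive")


@dataclass
class CageTrialResult:
    """Scored-pool record of one cage trial."""

    scored_states: list[PopulationState]  # one per scored generation, 1-based
    config: CageConfig

    def phenotype_counts(self) -> pd.DataFrame:
        """Tidy score sheet: generation, body, egfp, rfp, count."""
        rows = []
        variant = self.config.base.variant
        for gen, state in enumerate(self.scored_states, start=1):
            agg: dict[tuple[str, bool, bool], int] = {}
            for sex, genotypes, counts in (
                ("female", FEMALE_GENOTYPES, state.female_counts),
                ("male", MALE_GENOTYPES, state.male_counts),
            ):
                for g, c in zip(genotypes, counts):
                    if not c:
                        continue
                    ph = score_phenotype(g, sex, variant)
                    key = (ph.body, ph.egfp, ph.rfp)
                    agg[key] = agg.get(key, 0) + int(c)
            for (body, egfp, rfp), count in sorted(agg.items()):
                rows.append(
                    {"generation": gen, "body": body, "egfp": egfp, "rfp": rfp, "count": count}
                )
        return pd.DataFrame(rows, columns=["generation", "body", "egfp", "rfp", "count"])

    def _class_counts(self, predicate) -> list[int]:
        out = []
        variant = self.config.base.variant
        for state in self.scored_states:
            n = 0
            for sex, genotypes, counts in (
                ("female", FEMALE_GENOTYPES, state.female_counts),
                ("male", MALE_GENOTYPES, state.male_counts),
            ):
                for g, c in zip(genotypes, counts):
                    if c and predicate(score_phenotype(g, sex, variant)):
                        n += int(c)
            out.append(n)
        return out

    def drive_phenotype_counts(self) -> list[int]:
        """Per scored generation: number of fluorescent (drive) flies."""
        return self._class_counts(lambda ph: ph.is_drive)

    def non_wild_counts(self) -> list[int]:
        """Per scored generation: flies that are fluorescent or yellow.

        Zero here means the scored pool is 100% wild phenotype — the
        restoration event cage protocols report.
        """
        return self._class_counts(lambda ph: ph.is_drive or ph.body == "yellow")


def _split_pools(
    offspring: PopulationState, pool_size: int, rng: np.random.Generator
) -> tuple[PopulationState, PopulationState]:
    """Draw two disjoint uniform random pools from a brood."""
    total = offspring.total
    size = pool_size
    if total < 2 * pool_size:
        size = total // 2
        logger.warning(
            "brood of %d cannot fill two pools of %d; shrinking pools to %d",
            total,
            pool_size,
            size,
        )
    counts = np.concatenate([offspring.female_counts, offspring.male_counts])
    score = rng.multivariate_hypergeometric(counts, size)
    remaining = counts - score
    seed = rng.multivariate_hypergeometric(remaining, size)
    k = len(FEMALE_GENOTYPES)
    return (
        PopulationState(score[:k], score[k:]),
        PopulationState(seed[:k], seed[k:]),
    )


def run_cage_trial(config: CageConfig, rng: np.random.Generator) -> CageTrialResult:
    """Simulate one cage: seed, brood, score/seed split, repeat."""
    law = OffspringLaw.from_config(config.base)
    state = initialize_population(config.base)
    scored: list[PopulationState] = []
    for _ in range(config.base.generations):
        if state.extinct:
            scored.append(PopulationState(
                np.zeros(len(FEMALE_GENOTYPES), dtype=np.int64),
                np.zeros(len(MALE_GENOTYPES), dtype=np.int64),
            ))
            continue
        brood = next_generation(
            state, config.base, rng, law=law, n_offspring=config.brood_size
        )
        score_pool, seed_pool = _split_pools(brood, config.pool_size, rng)
        scored.append(score_pool)
        state = seed_pool
    return CageTrialResult(scored, config)


def run_cage_trials(config: CageConfig, replicates: int, seed: int) -> list[CageTrialResult]:
    """Independent replicate cages from one master seed."""
    children = np.random.SeedSequence(seed).spawn(replicates)
    return [run_cage_trial(config, np.random.default_rng(c)) for c in children]


def elimination_generation(series, index_offset: int = 0) -> int | None:
    """First scored generation at which a class count hits zero for good.

    ``series`` is the per-generation count of the class of interest, in
    scored-generation order.  Returns the (``index_offset``-based)
    generation index of the first zero that is followed only by zeros;
    ``None`` if the class is never eliminated.  Transient zeros with a
    later rebound are ignored.
    """
    counts = list(series)
    if not counts:
        raise ValueError("empty series")
    last_nonzero = -1
    for i, c in enumerate(counts):
        if c > 0:
            last_nonzero = i
    if last_nonzero == len(counts) - 1:
        return None
    return last_nonzero + 1 + index_offset
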