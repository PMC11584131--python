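"""Synthetic dataset generation.

Pair-mated cross broods, cage score sheets and courtship assay records
are drawn from the same exact category laws the analysis and
calibration modules assume, so every downstream stage can be tested
with known ground-truth parameters and no external data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alleles import ALLELE_ORDER
from .cross_model import CrossCategoryLaw, CrossDesign, seq_class_of
from .crosses import CrossOutcomeTable
from .germline import GermlineParams, ZygoticParams
from .phenotypes import DriveVariant, YREMEDE, score_phenotype

__all__ = [
    "BroodSizeLaw",
    "generate_cross_dataset",
    "CourtshipLaw",
    "generate_courtship_assays",
]


@dataclass(frozen=True)
class BroodSizeLaw:
    """Brood-size distribution: Poisson by default, or a fixed size.

    Poisson draws are truncated at one offspring so no cross is empty.
    """

    mean: float = 50.0
    fixed: bool = False

    def sample(self, rng: np.random.Generator) -> int:
        if self.fixed:
            return max(1, int(round(self.mean)))
        n = 0
        while n == 0:
            n = int(rng.poisson(self.mean))
        return n


def _phenotype_rows(sex: str, genotype_counts, variant: DriveVariant) -> dict:
    agg: dict[tuple, int] = {}
    for genotype, c in genotype_counts:
        if not c:
            continue
        ph = score_phenotype(genotype, sex, variant)
        key = (sex, ph.body, ph.egfp, ph.rfp)
        agg[key] = agg.get(key, 0) + int(c)
    return agg


def generate_cross_dataset(
    params: GermlineParams,
    zparams: ZygoticParams | None = None,
    variant: DriveVariant = YREMEDE,
    design: str = "maternal",
    n_crosses: int = 10,
    brood_size_law: BroodSizeLaw | None = None,
    seed: int = 0,
    full_span_genotyping: bool = False,
    unclassified_rate: float = 0.0,
) -> list[CrossOutcomeTable]:
    """Draw synthetic pair-mated cross outcome tables.

    Each offspring genotype is drawn from the exact cross-category law;
    the same individuals are then scored (phenotype rows) and sequenced
    (allele rows with parental-origin labels).  ``unclassified_rate``
    optionally reclassifies plain-sequence maternal/unassigned alleles
    as the indeterminate ``gGG`` class, which dynamics ignore.
    """
    if n_crosses < 1:
        raise ValueError("n_crosses must be at least 1")
    zparams = zparams or ZygoticParams()
    brood_size_law = brood_size_law or BroodSizeLaw()
    law = CrossCategoryLaw(params, zparams, design, variant, full_span_genotyping)
    rng = np.random.default_rng(seed)
    n_a = len(ALLELE_ORDER)

    pair_flat = law.daughter_pair.ravel()
    tables = []
    for k in range(n_crosses):
        n = brood_size_law.sample(rng)
        n_f = int(rng.binomial(n, 0.5))
        n_m = n - n_f
        pair_counts = rng.multinomial(n_f, pair_flat / pair_flat.sum()).reshape(n_a, n_a)
        son_counts = rng.multinomial(n_m, law.son_allele / law.son_allele.sum())

        pheno = _phenotype_rows(
            "male", [((a,), c) for a, c in zip(ALLELE_ORDER, son_counts)], variant
        )
        pheno.update(
            _phenotype_rows(
                "female",
                [
                    ((sa, sb), pair_counts[i, j])
                    for i, sa in enumerate(ALLELE_ORDER)
                    for j, sb in enumerate(ALLELE_ORDER)
                ],
                variant,
            )
        )

        alleles: dict[tuple, int] = {}

        def add_allele(sex: str, state, true_origin: str, c: int) -> None:
            if not c:
                return
            label = "maternal" if sex == "male" else law._assign_origin(state, true_origin)
            cls = seq_class_of(state, true_origin, law._wt_father)
            key = (sex, label, cls)
            alleles[key] = alleles.get(key, 0) + int(c)

        for a, state in enumerate(ALLELE_ORDER):
            add_allele("male", state, "maternal", son_counts[a])
        for i, sa in enumerate(ALLELE_ORDER):
            for j, sb in enumerate(ALLELE_ORDER):
                c = pair_counts[i, j]
                add_allele("female", sa, "maternal", c)
                add_allele("female", sb, "paternal", c)

        if unclassified_rate > 0:
            for key in list(alleles):
                sex, label, cls = key
                if cls == "TGG":
                    moved = int(rng.binomial(alleles[key], unclassified_rate))
                    if moved:
                        alleles[key] -= moved
                        gkey = (sex, label, "gGG")
                        alleles[gkey] = alleles.get(gkey, 0) + moved

        rows = [
            {
                "sex": sex,
                "body": body,
                "egfp": egfp,
                "rfp": rfp,
                "seq_class": "",
                "origin": "",
                "count": c,
            }
            for (sex, body, egfp, rfp), c in sorted(pheno.items())
        ] + [
            {
                "sex": sex,
                "body": "",
                "egfp": False,
                "rfp": False,
                "seq_class": cls,
                "origin": label,
                "count": c,
            }
            for (sex, label, cls), c in sorted(alleles.items())
            if c
        ]
        tables.append(CrossOutcomeTable(f"cross_{k + 1:03d}", pd.DataFrame(rows)))
    return tables


@dataclass(frozen=True)
class CourtshipLaw:
    """Per-pairing law of courtship assays.

    ``concentration`` parametrises a Beta law for the courtship index
    around ``mean_index``; ``None`` gives a degenerate (zero-variance)
    index.
    """

    mean_index: float = 0.5
    concentration: float | None = None
    copulation_prob: float = 1.0 / 30.0
    observation_time: float = 600.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.mean_index <= 1.0):
            raise ValueError("mean_index must lie in [0, 1]")
        if not (0.0 <= self.copulation_prob <= 1.0):
            raise ValueError("copulation_prob must lie in [0, 1]")
        if self.observation_time <= 0:
            raise ValueError("observation_time must be positive")


def generate_courtship_assays(index_law: CourtshipLaw, n: int, seed: int = 0) -> pd.DataFrame:
    """Synthetic single-pair courtship assay records.

    Returns a frame with columns ``courting_time``, ``observation_time``
    and ``copulated``; empty for ``n = 0``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n):
        if index_law.concentration is None:
            idx = index_law.mean_index
        else:
            a = index_law.mean_index * index_law.concentration
            b = (1.0 - index_law.mean_index) * index_law.concentration
            idx = float(rng.beta(max(a, 1e-9), max(b, 1e-9)))
        rows.append(
            {
                "courting_time": idx * index_law.observation_time,
                "observation_time": index_law.observation_time,
                "copulated": bool(rng.random() < index_law.copulation_prob),
            }
        )
    return pd.DataFrame(rows, columns=["courting_time", "observation_time", "copulated"])
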