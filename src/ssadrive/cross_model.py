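"""Exact observable-category laws for pair-mated crosses.

One shared probability model backs both the synthetic cross generator
and the calibration likelihood: for a given cross design it gives

* the joint law of a daughter's (maternal allele, paternal allele)
  pair after germline resolution and zygotic effects,
* the law of a son's single maternal allele,
* the induced laws over the observable categories — phenotype classes
  per sex, and (origin label, sequenced-allele class) pairs under the
  parental-origin assignment rules.

Designs: ``maternal`` is a drive-heterozygous female crossed to a
wild-type male; ``paternal`` a drive male crossed to a wild-type
female.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alleles import ALLELE_INDEX, ALLELE_ORDER, AlleleState
from .germline import (
    GermlineParams,
    ZygoticParams,
    gamete_distribution,
    zygotic_allele_law,
)
from .phenotypes import DriveVariant, YREMEDE, score_phenotype

__all__ = ["CrossDesign", "CrossCategoryLaw", "seq_class_of", "PHENO_CLASSES"]

PHENO_CLASSES = ("wild", "drive", "yellow")

_DESIGNS = {
    "maternal": ((AlleleState.G, AlleleState.W), (AlleleState.W,)),
    "paternal": ((AlleleState.W, AlleleState.W), (AlleleState.G,)),
}


def seq_class_of(state: AlleleState, origin: str, wild_type_father: bool = True) -> str:
    """Sequenced-allele class label of a model allele state.

    A plain-sequence ``W`` allele inherited from a wild-type father is
    its own class (``uncut_paternal``); every other ``W`` reads as
    ``TGG``.
    """
    if state.is_drive:
        return "drive"
    if state is AlleleState.V:
        return "TcG"
    if state is AlleleState.U:
        return "indel_in_frame"
    if state is AlleleState.R:
        return "indel_out_frame"
    return "uncut_paternal" if (origin == "paternal" and wild_type_father) else "TGG"


@dataclass(frozen=True)
class CrossDesign:
    """Which parent carries the drive, and the parental genotypes."""

    name: str  # "maternal" | "paternal"

    def __post_init__(self) -> None:
        if self.name not in _DESIGNS:
            raise ValueError(f"cross design must be one of {sorted(_DESIGNS)}")

    @property
    def mother(self) -> tuple[AlleleState, AlleleState]:
        return _DESIGNS[self.name][0]

    @property
    def father(self) -> tuple[AlleleState]:
        return _DESIGNS[self.name][1]


class CrossCategoryLaw:
    """All observable-category laws of one cross design."""

    def __init__(
        self,
        params: GermlineParams,
        zparams: ZygoticParams,
        design: CrossDesign | str,
        variant: DriveVariant = YREMEDE,
        full_span_genotyping: bool = False,
    ):
        if isinstance(design, str):
            design = CrossDesign(design)
        if not variant.ssa_enabled:
            params = params.replace(alpha_female=0.0, alpha_male=0.0, gamma=0.0)
        self.params = params
        self.zparams = zparams
        self.design = design
        self.variant = variant
        self.full_span = full_span_genotyping

        n = len(ALLELE_ORDER)
        egg = gamete_distribution(design.mother, "female", params).probs
        sperm = gamete_distribution(design.father, "male", params).probs

        # Sons carry the maternal X only; no zygotic exposure.
        self.son_allele = egg.copy()

        # Daughters: joint (maternal, paternal) law with zygotic effects,
        # conditioning zygotic expression on the inherited paternal allele.
        mother_drive = any(a.is_drive for a in design.mother)
        zyg_mat = np.array(
            [zygotic_allele_law(a, zparams.z_maternal, params.delta).probs for a in ALLELE_ORDER]
        )
        zyg_pat = np.array(
            [zygotic_allele_law(a, zparams.z_paternal, params.delta).probs for a in ALLELE_ORDER]
        )
        joint = np.zeros((n, n))
        for b, b_state in enumerate(ALLELE_ORDER):
            col = egg * sperm[b]
            mat = col @ zyg_pat if b_state.is_drive else col
            pat = zyg_mat[b] if mother_drive else np.eye(n)[b]
            joint += np.outer(mat, pat)
        self.daughter_pair = joint  # indexed [maternal allele, paternal allele]

        self._wt_father = design.father[0] is AlleleState.W
        self._build_phenotype_laws()
        self._build_allele_category_laws()

    # -- phenotype categories -------------------------------------------------

    def _build_phenotype_laws(self) -> None:
        son = np.zeros(len(PHENO_CLASSES))
        for a, state in enumerate(ALLELE_ORDER):
            son[self._pheno_class((state,), "male")] += self.son_allele[a]
        daughter = np.zeros(len(PHENO_CLASSES))
        for a, sa in enumerate(ALLELE_ORDER):
            for b, sb in enumerate(ALLELE_ORDER):
                w = self.daughter_pair[a, b]
                if w:
                    daughter[self._pheno_class((sa, sb), "female")] += w
        self.son_phenotype = son
        self.daughter_phenotype = daughter

    def _pheno_class(self, genotype, sex: str) -> int:
        ph = score_phenotype(genotype, sex, self.variant)
        if ph.is_drive:
            return PHENO_CLASSES.index("drive")
        return PHENO_CLASSES.index("wild" if ph.body == "wild" else "yellow")

    # -- sequenced-allele categories -----------------------------------------

    def _assign_origin(self, state: AlleleState, true_origin: str) -> str:
        """Origin label under the reporting rules.

        Male alleles are always maternal.  Female drive alleles are
        attributed to the drive-carrying parent; other female alleles
        are unassigned unless the cross was genotyped across the full
        construct span.
        """
        if self.full_span:
            return true_origin
        if state.is_drive:
            return self.design.name
        return "unassigned"

    def _build_allele_category_laws(self) -> None:
        son: dict[tuple[str, str], float] = {}
        for a, state in enumerate(ALLELE_ORDER):
            if self.son_allele[a]:
                key = ("maternal", seq_class_of(state, "maternal", self._wt_father))
                son[key] = son.get(key, 0.0) + self.son_allele[a]

        daughter: dict[tuple[str, str], float] = {}
        for a, sa in enumerate(ALLELE_ORDER):
            for b, sb in enumerate(ALLELE_ORDER):
                w = self.daughter_pair[a, b]
                if not w:
                    continue
                for state, origin in ((sa, "maternal"), (sb, "paternal")):
                    label = self._assign_origin(state, origin)
                    key = (label, seq_class_of(state, origin, self._wt_father))
                    daughter[key] = daughter.get(key, 0.0) + 0.5 * w
        self.son_allele_categories = son
        self.daughter_allele_categories = daughter
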