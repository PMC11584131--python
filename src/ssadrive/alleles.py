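"""Allele state space shared by every module.

The X-linked target locus is classified into six mutually exclusive
allele states:

===== ==========================================================
code  meaning
===== ==========================================================
``W`` susceptible wild type (cleavable, functional)
``G`` intact drive element (nuclease source, excisable)
``U`` in-frame NHEJ indel (functional, drive-resistant)
``R`` out-of-frame NHEJ indel (null, drive-resistant)
``V`` excision product retaining the engineered marker PAM
      (functional, drive-resistant)
``S`` drive with a disrupted internal cut site (nuclease source,
      excision-immune)
===== ==========================================================
"""

from __future__ import annotations

import enum


class AlleleState(enum.Enum):
    """Six-way classification of the X-linked target allele."""

    W = "W"
    G = "G"
    U = "U"
    R = "R"
    V = "V"
    S = "S"

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"AlleleState.{self.name}"

    @property
    def is_drive(self) -> bool:
        """True for nuclease-bearing alleles (``G`` and ``S``)."""
        return self in (AlleleState.G, AlleleState.S)

    @property
    def is_functional(self) -> bool:
        """True for alleles producing a functional (wild-body) product."""
        return self in (AlleleState.W, AlleleState.V, AlleleState.U)


#: Canonical ordering used by every array-valued representation.
ALLELE_ORDER: tuple[AlleleState, ...] = (
    AlleleState.W,
    AlleleState.G,
    AlleleState.U,
    AlleleState.R,
    AlleleState.V,
    AlleleState.S,
)

ALLELE_INDEX: dict[AlleleState, int] = {a: i for i, a in enumerate(ALLELE_ORDER)}

W, G, U, R, V, S = ALLELE_ORDER
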