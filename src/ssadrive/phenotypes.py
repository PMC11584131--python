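"""Genotype-to-phenotype scoring (body colour and fluorescent markers)."""

from __future__ import annotations

from dataclasses import dataclass

from .alleles import AlleleState

__all__ = ["Phenotype", "DriveVariant", "YMCR", "YREMEDE", "score_phenotype"]


@dataclass(frozen=True)
class Phenotype:
    """Scored phenotype: body colour plus fluorescence flags."""

    body: str  # "wild" or "yellow"
    egfp: bool
    rfp: bool

    @property
    def is_drive(self) -> bool:
        """Carries the visible drive cassette (any fluorescence)."""
        return self.egfp or self.rfp


@dataclass(frozen=True)
class DriveVariant:
    """A drive construct: its marker set and whether self-excision is wired in."""

    name: str
    markers: frozenset[str]
    ssa_enabled: bool

    def __post_init__(self) -> None:
        if self.name == "yMCR" and self.ssa_enabled:
            raise ValueError("the plain homing variant carries no excision machinery")


#: Plain homing drive: EGFP marker only, no self-excision machinery.
YMCR = DriveVariant(name="yMCR", markers=frozenset({"egfp"}), ssa_enabled=False)

#: Self-excising drive: EGFP + RFP markers, SSA enabled.
YREMEDE = DriveVariant(name="yReMEDE", markers=frozenset({"egfp", "rfp"}), ssa_enabled=True)

VARIANTS: dict[str, DriveVariant] = {v.name: v for v in (YMCR, YREMEDE)}


def score_phenotype(
    genotype: tuple[AlleleState, ...], sex: str, variant: DriveVariant = YREMEDE
) -> Phenotype:
    """Score body colour and fluorescence for one individual.

    Body is wild iff at least one allele is functional (``W``, ``V`` or
    ``U``): functional alleles are dominant.  Any drive allele
    (``G``/``S``) lights up the variant's fluorophores.
    """
    expected = 2 if sex == "female" else 1
    if len(genotype) != expected:
        raise ValueError(
            f"{sex} genotype must have {expected} allele(s), got {len(genotype)}"
        )
    body = "wild" if any(a.is_functional for a in genotype) else "yellow"
    fluorescent = any(a.is_drive for a in genotype)
    return Phenotype(
        body=body,
        egfp=fluorescent and "egfp" in variant.markers,
        rfp=fluorescent and "rfp" in variant.markers,
    )
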