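"""Per-allele germline repair-outcome model.

Every germline passage resolves each parental allele independently
through a flat probability tree:

* a susceptible ``W`` allele in a drive-bearing germline is cut with
  probability ``q``; a cut is repaired by homologous recombination
  (conversion to ``G``) with probability ``p``, otherwise by NHEJ,
  yielding an in-frame ``U`` allele with probability ``delta`` or an
  out-of-frame ``R`` allele with probability ``1 - delta``;
* a ``G`` allele is excised by single-strand annealing with a
  sex-specific probability ``alpha``, the excision product retaining
  the engineered marker (``V``) with probability ``epsilon`` or
  reverting to plain ``W`` with probability ``1 - epsilon``; with
  probability ``gamma`` the internal cut site is instead disrupted by
  NHEJ (``G`` -> ``S``);
* ``U``, ``R``, ``V`` and ``S`` alleles are inert and map to
  themselves.

Excision and homing within one passage are independent single-pass
draws: a ``W`` produced by excision is not re-exposed to cutting that
generation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .alleles import ALLELE_INDEX, ALLELE_ORDER, AlleleState

__all__ = [
    "GermlineParams",
    "ZygoticParams",
    "AlleleDistribution",
    "resolve_susceptible_allele",
    "resolve_drive_allele",
    "gamete_distribution",
    "zygotic_allele_law",
    "apply_zygotic_effects",
]


class ParameterDomainError(ValueError):
    """A probability parameter lies outside its admissible domain."""


def _check_unit(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ParameterDomainError(f"{name}={value!r} must lie in [0, 1]")


@dataclass(frozen=True)
class GermlineParams:
    """Probabilities of the germline repair-outcome tree.

    Parameters
    ----------
    q
        Probability that a drive-bearing germline cuts each susceptible
        ``W`` allele.
    p
        Probability a cut is repaired by homologous recombination
        (conversion to ``G``).
    delta
        Probability an NHEJ repair of a cut ``W`` yields an in-frame
        ``U`` allele (else out-of-frame ``R``).
    alpha_female, alpha_male
        Per-passage probability that a ``G`` allele is excised by SSA
        in the female / male germline.
    gamma
        Probability the internal cut site of ``G`` is disrupted by
        NHEJ (``G`` -> ``S``).
    epsilon
        Probability an SSA excision retains the engineered marker
        (product ``V``; else plain ``W``).
    """

    q: float = 0.95
    p: float = 0.78
    delta: float = 0.4
    alpha_female: float = 0.0
    alpha_male: float = 0.0
    gamma: float = 0.0
    epsilon: float = 1.0

    def __post_init__(self) -> None:
        for name in ("q", "p", "delta", "alpha_female", "alpha_male", "gamma", "epsilon"):
            _check_unit(name, getattr(self, name))
        for sex, alpha in (("female", self.alpha_female), ("male", self.alpha_male)):
            if alpha + self.gamma > 1.0 + 1e-12:
                raise ParameterDomainError(
                    f"alpha_{sex} + gamma = {alpha + self.gamma} exceeds 1"
                )

    def alpha(self, sex: str) -> float:
        if sex == "female":
            return self.alpha_female
        if sex == "male":
            return self.alpha_male
        raise ValueError(f"sex must be 'female' or 'male', got {sex!r}")

    def replace(self, **changes) -> "GermlineParams":
        return replace(self, **changes)


@dataclass(frozen=True)
class ZygoticParams:
    """Zygotic (post-fertilisation) cutting of inherited ``W`` alleles.

    ``z_maternal`` is the probability that nuclease deposited by a
    drive-carrying mother cuts a paternally inherited ``W`` allele in
    the zygote; ``z_paternal`` the probability that zygotic expression
    of a paternally inherited drive allele cuts the maternally
    inherited ``W``.  Zygotic cuts are resolved by NHEJ only, using the
    same in-frame split ``delta`` as the germline tree.
    """

    z_maternal: float = 0.0
    z_paternal: float = 0.0

    def __post_init__(self) -> None:
        _check_unit("z_maternal", self.z_maternal)
        _check_unit("z_paternal", self.z_paternal)


@dataclass(frozen=True)
class AlleleDistribution:
    """Discrete probability law over the six allele states."""

    probs: np.ndarray = field()

    TOL = 1e-12

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (len(ALLELE_ORDER),):
            raise ValueError(f"expected {len(ALLELE_ORDER)} probabilities, got {p.shape}")
        if (p < -self.TOL).any():
            raise ValueError(f"negative probability in {p}")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"probabilities sum to {p.sum()}, not 1")
        object.__setattr__(self, "probs", np.clip(p, 0.0, None))

    @classmethod
    def from_dict(cls, mapping: dict[AlleleState, float]) -> "AlleleDistribution":
        p = np.zeros(len(ALLELE_ORDER))
        for state, prob in mapping.items():
            p[ALLELE_INDEX[state]] = prob
        return cls(p)

    @classmethod
    def point(cls, state: AlleleState) -> "AlleleDistribution":
        return cls.from_dict({state: 1.0})

    def __getitem__(self, state: AlleleState) -> float:
        return float(self.probs[ALLELE_INDEX[state]])

    def as_dict(self, drop_zero: bool = True) -> dict[AlleleState, float]:
        out = {a: float(self.probs[i]) for i, a in enumerate(ALLELE_ORDER)}
        if drop_zero:
            out = {a: v for a, v in out.items() if v > 0.0}
        return out

    def sample(self, rng: np.random.Generator, size: int | None = None):
        idx = rng.choice(len(ALLELE_ORDER), size=size, p=self.probs / self.probs.sum())
        if size is None:
            return ALLELE_ORDER[int(idx)]
        return [ALLELE_ORDER[int(i)] for i in np.atleast_1d(idx)]


def resolve_susceptible_allele(
    params: GermlineParams, drive_present: bool
) -> AlleleDistribution:
    """Law of a germline ``W`` allele after one passage.

    With no nuclease source in the genotype the allele is untouched.
    Otherwise it is cut with probability ``q`` and repaired by HR
    (``G``) with probability ``p`` or by NHEJ (``U``/``R`` split by
    ``delta``).
    """
    if not drive_present:
        return AlleleDistribution.point(AlleleState.W)
    q, p, d = params.q, params.p, params.delta
    return AlleleDistribution.from_dict(
        {
            AlleleState.W: 1.0 - q,
            AlleleState.G: q * p,
            AlleleState.U: q * (1.0 - p) * d,
            AlleleState.R: q * (1.0 - p) * (1.0 - d),
        }
    )


def resolve_drive_allele(params: GermlineParams, sex: str) -> AlleleDistribution:
    """Law of a germline ``G`` allele after one passage.

    SSA excises with the sex-specific ``alpha`` (product ``V`` with
    probability ``epsilon``, else ``W``); NHEJ disrupts the internal
    cut site with probability ``gamma`` (``S``); otherwise the drive
    is retained intact.
    """
    a = params.alpha(sex)
    g, e = params.gamma, params.epsilon
    return AlleleDistribution.from_dict(
        {
            AlleleState.V: a * e,
            AlleleState.W: a * (1.0 - e),
            AlleleState.S: g,
            AlleleState.G: 1.0 - a - g,
        }
    )


def _resolve_allele(
    allele: AlleleState, params: GermlineParams, sex: str, drive_present: bool
) -> AlleleDistribution:
    if allele is AlleleState.W:
        return resolve_susceptible_allele(params, drive_present)
    if allele is AlleleState.G:
        return resolve_drive_allele(params, sex)
    # U, R, V are inert; S is a nuclease source but excision-immune.
    return AlleleDistribution.point(allele)


def gamete_distribution(
    genotype: tuple[AlleleState, ...], sex: str, params: GermlineParams
) -> AlleleDistribution:
    """X-gamete allele law for a parental genotype.

    Female genotypes carry two X alleles, male genotypes one.  Each
    parental allele is resolved independently through the outcome tree
    (homing requires a drive allele in the genotype); a female gamete
    then draws either resolved allele with weight 1/2, while a male
    X-bearing gamete carries the resolved single allele.  Y gametes are
    tracked implicitly as the other half of male output.

    Hemizygous males have no homologous target, so male ``W`` alleles
    are never converted; male drive alleles still undergo SSA with
    ``alpha_male``.
    """
    genotype = tuple(genotype)
    expected = 2 if sex == "female" else 1
    if sex not in ("female", "male"):
        raise ValueError(f"sex must be 'female' or 'male', got {sex!r}")
    if len(genotype) != expected:
        raise ValueError(
            f"{sex} genotype must have {expected} allele(s), got {len(genotype)}"
        )
    drive_present = sex == "female" and any(a.is_drive for a in genotype)
    resolved = [_resolve_allele(a, params, sex, drive_present) for a in genotype]
    probs = np.mean([r.probs for r in resolved], axis=0)
    return AlleleDistribution(probs)


def zygotic_allele_law(
    allele: AlleleState, z: float, delta: float
) -> AlleleDistribution:
    """Law of one inherited allele exposed to zygotic nuclease.

    Only ``W`` alleles are cleavable; a zygotic cut is repaired by NHEJ
    with the in-frame split ``delta`` (no HDR in the zygote).
    """
    if allele is not AlleleState.W or z == 0.0:
        return AlleleDistribution.point(allele)
    return AlleleDistribution.from_dict(
        {
            AlleleState.W: 1.0 - z,
            AlleleState.U: z * delta,
            AlleleState.R: z * (1.0 - delta),
        }
    )


def apply_zygotic_effects(
    offspring_genotype: tuple[AlleleState, ...],
    maternal_genotype: tuple[AlleleState, ...],
    paternal_genotype: tuple[AlleleState, ...],
    zparams: ZygoticParams,
    params: GermlineParams,
    rng: np.random.Generator,
) -> tuple[AlleleState, ...]:
    """Resolve zygotic cutting on one zygote's inherited alleles.

    Offspring genotypes are ordered (maternal allele, [paternal
    allele]); daughters carry both, sons only the maternal X.  A
    paternally inherited ``W`` is exposed to maternally deposited
    nuclease when the mother carries a drive allele; the maternally
    inherited ``W`` is exposed to zygotic expression when the
    paternally inherited allele is itself a drive.
    """
    alleles = list(offspring_genotype)
    mother_has_drive = any(a.is_drive for a in maternal_genotype)
    if len(alleles) == 2:
        maternal, paternal = alleles
        if paternal is AlleleState.W and mother_has_drive:
            law = zygotic_allele_law(paternal, zparams.z_maternal, params.delta)
            paternal = law.sample(rng)
        if maternal is AlleleState.W and alleles[1].is_drive:
            law = zygotic_allele_law(maternal, zparams.z_paternal, params.delta)
            maternal = law.sample(rng)
        return (maternal, paternal)
    # Sons inherit Y paternally: no zygotic drive expression and no
    # paternally inherited target for deposited nuclease.
    return tuple(alleles)
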