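"""Maximum-likelihood estimation of germline parameters from cross tables.

The likelihood is the product of multinomial laws over the observable
category groups of each cross — phenotype counts by sex, male sequenced
alleles, and female sequenced alleles with their origin labels — with
category probabilities induced by the germline outcome tree, zygotic
effects and phenotype scoring (:class:`~ssadrive.cross_model.CrossCategoryLaw`).
Female maternal/paternal alleles of one daughter are treated as
independent observations (a composite likelihood; exact for male
alleles and phenotype counts).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize

from .cross_model import PHENO_CLASSES, CrossCategoryLaw
from .crosses import CrossOutcomeTable
from .germline import GermlineParams, ZygoticParams
from .phenotypes import DriveVariant, YREMEDE

__all__ = ["cross_loglikelihood", "fit_params", "FitResult", "FREE_PARAM_NAMES"]

#: Parameters that may be freed in a fit.  ``qp`` frees the conversion
#: product q·p, holding the cut probability q at its configured value.
FREE_PARAM_NAMES = (
    "q",
    "p",
    "qp",
    "delta",
    "alpha_female",
    "alpha_male",
    "gamma",
    "epsilon",
    "z_maternal",
    "z_paternal",
)

_GERMLINE_FIELDS = {"q", "p", "delta", "alpha_female", "alpha_male", "gamma", "epsilon"}
_ZYGOTIC_FIELDS = {"z_maternal", "z_paternal"}


class NonIdentifiableError(ValueError):
    """The requested free-parameter set is not identifiable from the data."""


def _group_counts(table: CrossOutcomeTable):
    """Observed counts per likelihood group of one cross."""
    ph = table.phenotype_rows
    pheno = {}
    for _, row in ph.iterrows():
        fluor = bool(row["egfp"]) or bool(row["rfp"])
        cls = "drive" if fluor else ("wild" if row["body"] == "wild" else "yellow")
        key = (row["sex"], cls)
        pheno[key] = pheno.get(key, 0) + int(row["count"])

    male_alleles = {}
    female_alleles = {}
    for _, row in table.allele_rows.iterrows():
        cls = row["seq_class"]
        if cls == "gGG":  # indeterminate biogenesis: read as plain sequence
            cls = "TGG"
        if row["sex"] == "male":
            male_alleles[cls] = male_alleles.get(cls, 0) + int(row["count"])
        else:
            key = (row["origin"], cls)
            female_alleles[key] = female_alleles.get(key, 0) + int(row["count"])
    return pheno, male_alleles, female_alleles


def _infer_full_span(female_alleles: dict) -> bool:
    """A table with origin-labelled female non-drive alleles was genotyped
    across the full construct span."""
    return any(
        origin in ("maternal", "paternal") and cls != "drive"
        for (origin, cls) in female_alleles
    )


def cross_loglikelihood(
    params: GermlineParams,
    zparams: ZygoticParams,
    table: CrossOutcomeTable,
    cross_design: str,
    variant: DriveVariant = YREMEDE,
) -> float:
    """Multinomial log-likelihood of one cross's observed counts.

    Returns ``-inf`` (not an exception) when a category with positive
    observed count has probability zero under ``params``.  The
    multinomial coefficient is omitted: a table whose only occupied
    category has probability one scores exactly zero.
    """
    pheno, male_alleles, female_alleles = _group_counts(table)
    law = CrossCategoryLaw(
        params, zparams, cross_design, variant, _infer_full_span(female_alleles)
    )

    ll = 0.0

    def accumulate(counts: dict, probs: dict) -> float:
        out = 0.0
        for key, n in counts.items():
            if n == 0:
                continue
            p = probs.get(key, 0.0)
            if p <= 0.0:
                return -math.inf
            out += n * math.log(p)
        return out

    pheno_probs = {
        ("female", cls): 0.5 * law.daughter_phenotype[i]
        for i, cls in enumerate(PHENO_CLASSES)
    }
    pheno_probs.update(
        {("male", cls): 0.5 * law.son_phenotype[i] for i, cls in enumerate(PHENO_CLASSES)}
    )
    for counts, probs in (
        (pheno, pheno_probs),
        (male_alleles, {cls: p for (_, cls), p in law.son_allele_categories.items()}),
        (female_alleles, law.daughter_allele_categories),
    ):
        part = accumulate(counts, probs)
        if part == -math.inf:
            return -math.inf
        ll += part
    return ll


@dataclass
class FitResult:
    estimates: dict[str, float]
    loglik: float
    free_params: tuple[str, ...]
    converged: bool
    n_starts: int
    bootstrap: dict[str, tuple[float, float]] = field(default_factory=dict)
    bootstrap_samples: dict[str, np.ndarray] = field(default_factory=dict)

    def params(self, base: GermlineParams) -> GermlineParams:
        return _apply_free(base, ZygoticParams(), self.estimates, self.free_params)[0]


def _apply_free(
    base: GermlineParams,
    zbase: ZygoticParams,
    values: dict[str, float],
    free: tuple[str, ...],
) -> tuple[GermlineParams, ZygoticParams]:
    gkw, zkw = {}, {}
    for name in free:
        v = values[name]
        if name == "qp":
            if base.q <= 0:
                raise ValueError("qp requires a positive configured q")
            gkw["p"] = min(v / base.q, 1.0)
        elif name in _GERMLINE_FIELDS:
            gkw[name] = v
        elif name in _ZYGOTIC_FIELDS:
            zkw[name] = v
    return (
        replace(base, **gkw) if gkw else base,
        replace(zbase, **zkw) if zkw else zbase,
    )


def _check_identifiable(free: tuple[str, ...], tables: list[CrossOutcomeTable]) -> None:
    if "qp" in free and ({"q", "p"} & set(free)):
        raise NonIdentifiableError("'qp' cannot be freed together with 'q' or 'p'")
    has_alleles = any(not t.allele_rows.empty for t in tables)
    if {"q", "p"} <= set(free) and not has_alleles:
        raise NonIdentifiableError(
            "q and p are not jointly identifiable from phenotype counts alone: "
            "only their product enters the drive-phenotype probability. "
            "Free 'qp', or fix one of them, or supply sequenced-allele counts."
        )


def _total_loglik(params, zparams, tables, designs, variant) -> float:
    return sum(
        cross_loglikelihood(params, zparams, t, d, variant)
        for t, d in zip(tables, designs)
    )


def fit_params(
    tables: list[CrossOutcomeTable],
    free_params,
    base: GermlineParams | None = None,
    zbase: ZygoticParams | None = None,
    cross_design: str | list[str] = "maternal",
    variant: DriveVariant = YREMEDE,
    bounds: dict[str, tuple[float, float]] | None = None,
    n_starts: int = 10,
    n_bootstrap: int = 0,
    seed: int = 0,
    tol: float = 1e-8,
) -> FitResult:
    """Bounded multi-start ML fit of a subset of germline parameters.

    Parameters not freed are held at ``base`` / ``zbase``.  With
    ``n_bootstrap > 0``, parametric-bootstrap percentile intervals
    (95%) are computed by resampling category counts at the MLE and
    refitting from the MLE start.  Fully reproducible under ``seed``.
    """
    if not tables:
        raise ValueError("at least one cross table is required")
    free = tuple(free_params)
    for name in free:
        if name not in FREE_PARAM_NAMES:
            raise ValueError(f"unknown free parameter {name!r}")
    _check_identifiable(free, tables)

    base = base or GermlineParams()
    zbase = zbase or ZygoticParams()
    designs = (
        [cross_design] * len(tables) if isinstance(cross_design, str) else list(cross_design)
    )
    if len(designs) != len(tables):
        raise ValueError("one cross_design per table is required")

    bounds = bounds or {}
    default_hi = {name: (0.0, 1.0) for name in FREE_PARAM_NAMES}
    default_hi["qp"] = (0.0, base.q if base.q > 0 else 1.0)
    box = [bounds.get(name, default_hi[name]) for name in free]

    def negll(x: np.ndarray) -> float:
        values = dict(zip(free, x))
        try:
            p, z = _apply_free(base, zbase, values, free)
        except ValueError:
            return 1e12
        ll = _total_loglik(p, z, tables, designs, variant)
        return 1e12 if not np.isfinite(ll) else -ll

    rng = np.random.default_rng(seed)
    starts = [np.array([(lo + hi) / 2 for lo, hi in box])]
    starts += [
        np.array([rng.uniform(lo, hi) for lo, hi in box]) for _ in range(n_starts - 1)
    ]

    best = None
    for x0 in starts:
        res = optimize.minimize(
            negll, x0, method="L-BFGS-B", bounds=box, options={"ftol": tol, "gtol": 1e-10}
        )
        if best is None or res.fun < best.fun - 1e-9 or (
            abs(res.fun - best.fun) <= 1e-6 and tuple(res.x) < tuple(best.x)
        ):
            best = res

    estimates = dict(zip(free, (float(v) for v in best.x)))
    result = FitResult(
        estimates=estimates,
        loglik=-float(best.fun),
        free_params=free,
        converged=bool(best.success),
        n_starts=n_starts,
    )

    if n_bootstrap > 0:
        p_hat, z_hat = _apply_free(base, zbase, estimates, free)
        samples = {name: [] for name in free}
        for b in range(n_bootstrap):
            boot_tables = [
                _resample_table(t, p_hat, z_hat, d, variant, rng)
                for t, d in zip(tables, designs)
            ]

            def negll_b(x, boot_tables=boot_tables):
                values = dict(zip(free, x))
                try:
                    p, z = _apply_free(base, zbase, values, free)
                except ValueError:
                    return 1e12
                ll = _total_loglik(p, z, boot_tables, designs, variant)
                return 1e12 if not np.isfinite(ll) else -ll

            res = optimize.minimize(
                negll_b, best.x, method="L-BFGS-B", bounds=box, options={"ftol": tol}
            )
            for name, v in zip(free, res.x):
                samples[name].append(float(v))
        for name, vals in samples.items():
            arr = np.array(vals)
            result.bootstrap_samples[name] = arr
            result.bootstrap[name] = (
                float(np.percentile(arr, 2.5)),
                float(np.percentile(arr, 97.5)),
            )
    return result


def _resample_table(
    table: CrossOutcomeTable,
    params: GermlineParams,
    zparams: ZygoticParams,
    design: str,
    variant: DriveVariant,
    rng: np.random.Generator,
) -> CrossOutcomeTable:
    """Parametric-bootstrap replicate preserving the table's group totals."""
    import pandas as pd

    pheno, male_alleles, female_alleles = _group_counts(table)
    law = CrossCategoryLaw(params, zparams, design, variant, _infer_full_span(female_alleles))

    def draw(counts: dict, probs: dict) -> dict:
        keys = [k for k, p in probs.items() if p > 0]
        pvec = np.array([probs[k] for k in keys])
        n = sum(counts.values())
        if n == 0 or not keys:
            return {}
        sampled = rng.multinomial(n, pvec / pvec.sum())
        return dict(zip(keys, sampled))

    pheno_probs = {
        ("female", cls): 0.5 * law.daughter_phenotype[i] for i, cls in enumerate(PHENO_CLASSES)
    }
    pheno_probs.update(
        {("male", cls): 0.5 * law.son_phenotype[i] for i, cls in enumerate(PHENO_CLASSES)}
    )
    new_pheno = draw(pheno, pheno_probs)
    new_male = draw(male_alleles, {cls: p for (_, cls), p in law.son_allele_categories.items()})
    new_female = draw(female_alleles, law.daughter_allele_categories)

    rows = []
    for (sex, cls), c in new_pheno.items():
        if c:
            rows.append(
                {
                    "sex": sex,
                    "body": "wild" if cls != "yellow" else "yellow",
                    "egfp": cls == "drive",
                    "rfp": cls == "drive" and "rfp" in variant.markers,
                    "seq_class": "",
                    "origin": "",
                    "count": int(c),
                }
            )
    for cls, c in new_male.items():
        if c:
            rows.append(
                {"sex": "male", "body": "", "egfp": False, "rfp": False,
                 "seq_class": cls, "origin": "maternal", "count": int(c)}
            )
    for (origin, cls), c in new_female.items():
        if c:
            rows.append(
                {"sex": "female", "body": "", "egfp": False, "rfp": False,
                 "seq_class": cls, "origin": origin, "count": int(c)}
            )
    return CrossOutcomeTable(table.cross_id, pd.DataFrame(rows))
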