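"""Configuration loading, named presets and run manifests.

Config files are YAML mappings.  A top-level ``preset`` key expands to
a full parameter set which any other key then overrides; unknown keys
are rejected.  Probabilities are decimals in [0, 1].
"""

from __future__ import annotations

import dataclasses
import json
import pathlib
from typing import Any

import yaml

from .cage import CageConfig
from .germline import GermlineParams, ZygoticParams
from .phenotypes import VARIANTS, YMCR, YREMEDE
from .population import MatingCosts, SimulationConfig

__all__ = ["PRESETS", "CAGE_PRESETS", "preset_config", "load_config", "write_manifest"]


#: Calibrated cutting parameters: q=0.95, p=0.78 give a conversion
#: probability q*p = 0.741 per susceptible allele and hence ~87% drive
#: transmission from heterozygous females with excision off.
CALIBRATED_Q = 0.95
CALIBRATED_P = 0.78


def _remede(alpha_f, alpha_m, epsilon, gamma=0.0, resistant=True, costs=False):
    """Release-scenario preset: 10% drive carriers, N=1000, 100 replicates.

    With resistant-allele formation disabled, every cut repairs by HR;
    the cut probability is then reduced to the calibrated conversion
    product so heterozygous-female drive transmission stays at the
    empirical ~87% rate.
    """
    return SimulationConfig(
        population_size=1000,
        generations=60,
        replicates=100,
        release_fraction=0.10,
        release_sex="both",
        release_zygosity="heterozygous",
        germline=GermlineParams(
            q=CALIBRATED_Q if resistant else CALIBRATED_Q * CALIBRATED_P,
            p=CALIBRATED_P if resistant else 1.0,
            delta=0.4,
            alpha_female=alpha_f,
            alpha_male=alpha_m,
            gamma=gamma,
            epsilon=epsilon,
        ),
        costs=MatingCosts() if costs else MatingCosts.none(),
        variant=YREMEDE,
    )


#: Named release-scenario presets.  All are 10% releases without mating
#: costs; they differ in excision rate, marker retention and whether
#: NHEJ resistant alleles form at the empirically calibrated rate.
PRESETS: dict[str, SimulationConfig] = {
    # Plain homing drive with resistant-allele formation.
    "fig6a": SimulationConfig(
        population_size=1000,
        generations=60,
        replicates=100,
        release_fraction=0.10,
        germline=GermlineParams(q=0.95, p=0.78, delta=0.4),
        costs=MatingCosts.none(),
        variant=YMCR,
    ),
    # Self-excising drive, 10% SSA, full marker retention, resistant alleles on.
    "fig6b": _remede(0.1, 0.01, epsilon=1.0, resistant=True),
    # 30% SSA, quarter marker retention, no resistant alleles.
    "fig6c": _remede(0.3, 0.03, epsilon=0.25, resistant=False),
    # 10% SSA, full marker retention, no resistant alleles.
    "fig6d": _remede(0.1, 0.01, epsilon=1.0, resistant=False),
    # 5% SSA, quarter marker retention, no resistant alleles.
    "fig6e": _remede(0.05, 0.005, epsilon=0.25, resistant=False),
}


def _cage(variant, alpha_f=0.0, alpha_m=0.0, epsilon=1.0, gamma=0.0, q=CALIBRATED_Q, p=CALIBRATED_P):
    return CageConfig(
        base=SimulationConfig(
            population_size=200,
            generations=20,
            replicates=30,
            release_fraction=0.75,
            release_sex="both",
            release_zygosity="homozygous",
            germline=GermlineParams(
                q=q,
                p=p,
                delta=0.4,
                alpha_female=alpha_f,
                alpha_male=alpha_m,
                gamma=gamma,
                epsilon=epsilon,
            ),
            costs=MatingCosts(),  # empirical yellow costs on
            variant=variant,
        ),
        pool_size=150,
        brood_size=600,
    )


#: Cage-trial presets: 200 founders (75% drive homozygotes), 150/150
#: score/seed pools, empirical yellow mating costs.
#: The self-excising cage preset uses cutting parameters solved from
#: the empirical progeny-level F2 fractions of its own master-female
#: outcrosses (~54% drive transmission, ~11% yellow-bodied progeny,
#: remainder wild) with the excision rate held at alpha_female = 0.1.
#: With a heterozygous mother and wild-type father, every daughter is
#: wild-bodied, so yellow progeny are the sons carrying out-of-frame
#: alleles:
#:   0.45 + 0.5*q*p = 0.54  and  0.25*q*(1-p)*(1-delta) = 0.11.
CAGE_PRESETS: dict[str, CageConfig] = {
    "cage_ymcr": _cage(YMCR),
    "cage_yremede": _cage(
        YREMEDE, alpha_f=0.1, alpha_m=0.01, epsilon=0.2, gamma=0.001, q=0.9133, p=0.1971
    ),
}

_SIM_KEYS = {f.name for f in dataclasses.fields(SimulationConfig)}
_CAGE_KEYS = {"pool_size", "brood_size"}


def _build_simulation(data: dict[str, Any], base: SimulationConfig) -> SimulationConfig:
    changes: dict[str, Any] = {}
    for key, value in data.items():
        if key == "germline":
            changes["germline"] = dataclasses.replace(base.germline, **value)
        elif key == "zygotic":
            changes["zygotic"] = dataclasses.replace(base.zygotic, **value)
        elif key == "costs":
            changes["costs"] = dataclasses.replace(base.costs, **value)
        elif key == "variant":
            try:
                changes["variant"] = VARIANTS[value]
            except KeyError:
                raise ValueError(f"unknown variant {value!r}; known: {sorted(VARIANTS)}")
        elif key in _SIM_KEYS:
            changes[key] = value
        else:
            raise ValueError(f"unknown configuration key {key!r}")
    try:
        return base.replace(**changes) if changes else base
    except (ValueError, TypeError) as exc:
        raise ValueError(f"invalid configuration: {exc}") from exc


def preset_config(name: str) -> SimulationConfig | CageConfig:
    try:
        return PRESETS.get(name) or CAGE_PRESETS[name]
    except KeyError:
        known = sorted(PRESETS) + sorted(CAGE_PRESETS)
        raise ValueError(f"unknown preset {name!r}; known presets: {known}") from None


def load_config(path) -> SimulationConfig | CageConfig:
    """Load and validate a YAML config file.

    An empty file yields the all-defaults :class:`SimulationConfig`.
    Cage presets (or a ``cage`` section) yield a :class:`CageConfig`.
    """
    text = pathlib.Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError("config file must contain a YAML mapping")

    preset = data.pop("preset", None)
    cage_data = data.pop("cage", None)
    base: SimulationConfig | CageConfig
    base = preset_config(preset) if preset else SimulationConfig()

    if isinstance(base, CageConfig):
        cage_kw = {k: v for k, v in (cage_data or {}).items()}
        for key in list(data):
            if key in _CAGE_KEYS:
                cage_kw[key] = data.pop(key)
        bad = set(cage_kw) - _CAGE_KEYS
        if bad:
            raise ValueError(f"unknown cage configuration keys {sorted(bad)}")
        return CageConfig(
            base=_build_simulation(data, base.base),
            **{**{"pool_size": base.pool_size, "brood_size": base.brood_size}, **cage_kw},
        )
    if cage_data is not None or (_CAGE_KEYS & set(data)):
        cage_kw = dict(cage_data or {})
        for key in list(data):
            if key in _CAGE_KEYS:
                cage_kw[key] = data.pop(key)
        return CageConfig(base=_build_simulation(data, base), **cage_kw)
    return _build_simulation(data, base)


def _to_jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, frozenset):
        return sorted(obj)
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    return obj


def write_manifest(path, config, seed: int | None = None, extra: dict | None = None) -> None:
    """Write a JSON run manifest sufficient to reproduce the run."""
    from . import __version__

    manifest = {
        "package": "ssadrive",
        "version": __version__,
        "config": _to_jsonable(config),
        "seed": seed,
    }
    if extra:
        manifest.update(extra)
    pathlib.Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
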