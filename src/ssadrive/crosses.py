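"""Pair-mated cross outcome tabulation and mating-cost statistics.

The tabular interchange format is a tidy CSV with columns::

    cross_id, sex, body, egfp, rfp, seq_class, origin, count

Rows with an empty ``seq_class`` count scored individuals by phenotype;
rows with a ``seq_class`` count sequenced alleles, attributed to a
parental ``origin`` (``maternal``, ``paternal`` or ``unassigned``).
Male X alleles are always maternal; female non-drive alleles are
``unassigned`` unless the cross was genotyped across the full construct
span.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .alleles import AlleleState

__all__ = [
    "SEQ_CLASSES",
    "ORIGINS",
    "CrossOutcomeTable",
    "read_cross_tables",
    "write_cross_tables",
    "tabulate_crosses",
    "classify_sequenced_allele",
    "courtship_index",
    "estimate_mating_cost",
    "MatingCostEstimate",
    "compare_paired_indices",
    "exact_binomial_test",
]

SEQ_CLASSES = (
    "drive",
    "TcG",
    "TGG",
    "gGG",
    "indel_in_frame",
    "indel_out_frame",
    "uncut_paternal",
)
ORIGINS = ("maternal", "paternal", "unassigned")

_COLUMNS = ["cross_id", "sex", "body", "egfp", "rfp", "seq_class", "origin", "count"]

_TRUE_STRINGS = {"true", "1", "yes", "+"}


def _as_bool(value) -> bool:
    """Robust boolean parsing for CSV round trips."""
    if isinstance(value, str):
        return value.strip().lower() in _TRUE_STRINGS
    return bool(value) and not (isinstance(value, float) and np.isnan(value))

#: sequenced-allele class -> model allele state (gGG is deliberately
#: outside the model: tabulation reports it, dynamics ignore it).
_SEQ_TO_STATE = {
    "TcG": AlleleState.V,
    "TGG": AlleleState.W,
    "uncut_paternal": AlleleState.W,
    "indel_in_frame": AlleleState.U,
    "indel_out_frame": AlleleState.R,
}


def classify_sequenced_allele(record_class: str, i_site_disrupted: bool = False):
    """Map a sequenced-allele class label to a model allele state.

    Returns an :class:`AlleleState`, or the string ``"unclassified"``
    for classes of indeterminate biogenesis (``gGG``).
    """
    if record_class == "drive":
        return AlleleState.S if i_site_disrupted else AlleleState.G
    if record_class == "gGG":
        return "unclassified"
    try:
        return _SEQ_TO_STATE[record_class]
    except KeyError:
        raise ValueError(f"unknown sequenced-allele class {record_class!r}") from None


@dataclass
class CrossOutcomeTable:
    """Outcome counts of one pair-mated cross."""

    cross_id: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.copy()
        for col in _COLUMNS[1:]:
            if col not in df.columns:
                raise ValueError(f"cross table missing column {col!r}")
        for col in ("egfp", "rfp"):
            df[col] = df[col].map(_as_bool)
        df["seq_class"] = df["seq_class"].fillna("").astype(str)
        df["origin"] = df["origin"].fillna("").astype(str)
        bad = df.loc[~df["seq_class"].isin(("",) + SEQ_CLASSES), "seq_class"]
        if len(bad):
            raise ValueError(f"unknown seq_class values: {sorted(set(bad))}")
        bad = df.loc[~df["origin"].isin(("",) + ORIGINS), "origin"]
        if len(bad):
            raise ValueError(f"unknown origin values: {sorted(set(bad))}")
        if (df["count"] < 0).any() or not np.issubdtype(df["count"].dtype, np.integer):
            df["count"] = df["count"].astype(np.int64)
            if (df["count"] < 0).any():
                raise ValueError("counts must be nonnegative integers")
        if df["count"].sum() == 0:
            raise ValueError(f"cross {self.cross_id!r} is empty")
        self.data = df.reset_index(drop=True)

    @property
    def phenotype_rows(self) -> pd.DataFrame:
        return self.data[self.data["seq_class"] == ""]

    @property
    def allele_rows(self) -> pd.DataFrame:
        return self.data[self.data["seq_class"] != ""]

    def phenotype_fractions(self) -> dict[str, float]:
        """Fractions of scored individuals: drive / wild / yellow.

        ``drive`` is any fluorescent fly; body-colour classes cover the
        non-fluorescent remainder.
        """
        ph = self.phenotype_rows
        total = ph["count"].sum()
        if total == 0:
            raise ValueError(f"cross {self.cross_id!r} has no phenotype counts")
        fluor = ph["egfp"].astype(bool) | ph["rfp"].astype(bool)
        drive = ph.loc[fluor, "count"].sum()
        wild = ph.loc[~fluor & (ph["body"] == "wild"), "count"].sum()
        yellow = ph.loc[~fluor & (ph["body"] == "yellow"), "count"].sum()
        return {
            "drive": drive / total,
            "wild": wild / total,
            "yellow": yellow / total,
        }

    def allele_fractions(self) -> pd.DataFrame:
        """Sequenced allele-class fractions by parental origin."""
        al = self.allele_rows
        if al.empty:
            return pd.DataFrame(columns=["origin", "seq_class", "fraction"])
        grouped = al.groupby(["origin", "seq_class"], as_index=False)["count"].sum()
        totals = grouped.groupby("origin")["count"].transform("sum")
        grouped["fraction"] = grouped["count"] / totals
        return grouped[["origin", "seq_class", "fraction"]]


def read_cross_tables(path) -> list[CrossOutcomeTable]:
    """Read the tidy cross CSV into one table per cross."""
    df = pd.read_csv(path, dtype={"cross_id": str}, keep_default_na=False)
    df["count"] = df["count"].astype(np.int64)
    return [
        CrossOutcomeTable(cid, sub.drop(columns=["cross_id"]))
        for cid, sub in df.groupby("cross_id", sort=True)
    ]


def write_cross_tables(tables: list[CrossOutcomeTable], path) -> None:
    frames = []
    for t in tables:
        sub = t.data.copy()
        sub.insert(0, "cross_id", t.cross_id)
        frames.append(sub)
    pd.concat(frames, ignore_index=True)[_COLUMNS].to_csv(path, index=False)


def tabulate_crosses(tables: list[CrossOutcomeTable]) -> dict:
    """Per-cross fractions and across-cross means with standard errors."""
    if not tables:
        raise ValueError("at least one cross is required")
    per_cross = pd.DataFrame(
        [{"cross_id": t.cross_id, **t.phenotype_fractions()} for t in tables]
    ).set_index("cross_id")

    def mean_se(col: pd.Series) -> dict[str, float]:
        n = len(col)
        return {
            "mean": float(col.mean()),
            "se": float(col.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
        }

    summary = {
        f"{cls}_fraction": mean_se(per_cross[cls]) for cls in ("drive", "wild", "yellow")
    }

    allele_frames = [
        t.allele_fractions().assign(cross_id=t.cross_id)
        for t in tables
        if not t.allele_rows.empty
    ]
    allele_summary = pd.DataFrame(columns=["origin", "seq_class", "mean", "se", "n_crosses"])
    if allele_frames:
        allele = pd.concat(allele_frames, ignore_index=True)
        allele_summary = (
            allele.groupby(["origin", "seq_class"])["fraction"]
            .agg(mean="mean", se=lambda s: s.std(ddof=1) / np.sqrt(len(s)) if len(s) > 1 else 0.0, n_crosses="count")
            .reset_index()
        )
    return {
        "per_cross": per_cross,
        "summary": summary,
        "allele_classes": allele_summary,
    }


def courtship_index(courting_time: float, observation_time: float) -> float:
    """Fraction of the observation window spent in courtship activity."""
    if observation_time <= 0:
        raise ValueError("observation_time must be positive")
    if not (0 <= courting_time <= observation_time):
        raise ValueError("courting_time must lie in [0, observation_time]")
    return courting_time / observation_time


@dataclass(frozen=True)
class MatingCostEstimate:
    cost: float
    ci_low: float
    ci_high: float
    successes: int
    trials: int

    @property
    def rounded(self) -> float:
        """Cost reported to two decimal places."""
        return round(self.cost, 2)


def estimate_mating_cost(focal_successes: int, trials: int) -> MatingCostEstimate:
    """Mating cost from competitive assays: fraction of failed trials.

    The cost is ``(trials - successes) / trials`` with an exact
    (Clopper–Pearson) binomial confidence interval at 95%.
    """
    if trials <= 0:
        raise ValueError("trials must be positive")
    if not (0 <= focal_successes <= trials):
        raise ValueError("focal_successes must lie in [0, trials]")
    failures = trials - focal_successes
    lo, hi = proportion_confint(failures, trials, alpha=0.05, method="beta")
    return MatingCostEstimate(failures / trials, float(lo), float(hi), focal_successes, trials)


def compare_paired_indices(a, b):
    """Thin wrapper: Wilcoxon signed-rank test on paired index samples."""
    return stats.wilcoxon(a, b)


def exact_binomial_test(successes: int, trials: int, p: float = 0.5):
    """Thin wrapper: exact binomial test against a null proportion."""
    return stats.binomtest(successes, trials, p)
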