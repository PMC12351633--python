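"""Cross-subject montage transfer: evaluation tables, statistics, dose-response.

Montage protocols of four kinds are evaluated across a cohort: personalized
(optimized on and evaluated only on the own subject), group leave-one-out
(optimized on everyone else, evaluated on the held-out subject), template
(optimized on a designated template head excluded from the cohort), and
non-personalized individual (one cohort member's personalized montage applied
to everyone else). Comparisons follow the repeated-measures plan: pairwise
paired t-tests with Bonferroni adjustment, plus a Kruskal-Wallis omnibus test
with Dunn post-hoc comparisons.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .model import Montage, SubjectModel
from .objective import mean_en, nerni

__all__ = [
    "Protocol",
    "evaluate_transfer",
    "ComparisonReport",
    "compare_protocols",
    "dunn_test",
    "nerni_vs_mean_en_fit",
    "QuadraticFit",
]

PROTOCOL_KINDS = ("personalized", "group_loo", "template", "non_personalized_individual")


@dataclass
class Protocol:
    """A montage together with how it was derived.

    ``own_subject`` restricts evaluation to one subject (used for
    personalized and group-LOO protocols, which are only meaningful on the
    subject they were built for/around).
    """

    protocol_id: str
    kind: str
    montage: Montage
    own_subject: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in PROTOCOL_KINDS:
            raise ValueError(f"unknown protocol kind {self.kind!r}; expected {PROTOCOL_KINDS}")

    @property
    def condition(self) -> str:
        """Statistical condition label: per-subject kinds collapse to the kind."""
        return self.kind if self.own_subject is not None else self.protocol_id


def evaluate_transfer(
    protocols: Sequence[Protocol] | Mapping[str, Montage],
    cohort: Sequence[SubjectModel],
) -> pd.DataFrame:
    """Evaluate every protocol on every applicable subject.

    Returns a table with one row per (subject, protocol) pair: NERNI and the
    target-average En, plus the protocol kind and statistical condition.
    A plain mapping of id -> montage is treated as template-kind protocols.
    """
    if isinstance(protocols, Mapping):
        protocols = [Protocol(pid, "template", m) for pid, m in protocols.items()]
    rows = []
    for subject in cohort:
        for proto in protocols:
            if proto.own_subject is not None and proto.own_subject != subject.subject_id:
                continue
            try:
                rows.append(
                    {
                        "subject_id": subject.subject_id,
                        "protocol_id": proto.protocol_id,
                        "protocol_kind": proto.kind,
                        "condition": proto.condition,
                        "nerni": nerni(proto.montage, subject),
                        "mean_en": mean_en(proto.montage, subject),
                        "error": "",
                    }
                )
            except KeyError as exc:
                rows.append(
                    {
                        "subject_id": subject.subject_id,
                        "protocol_id": proto.protocol_id,
                        "protocol_kind": proto.kind,
                        "condition": proto.condition,
                        "nerni": np.nan,
                        "mean_en": np.nan,
                        "error": str(exc),
                    }
                )
    table = pd.DataFrame(rows)
    return table.sort_values(["subject_id", "protocol_id"], ignore_index=True)


@dataclass
class ComparisonReport:
    """Statistical comparison of protocol conditions."""

    paired_t: pd.DataFrame  # condition_a, condition_b, t, p_raw, p_bonferroni
    kruskal_h: float
    kruskal_p: float
    dunn_p: pd.DataFrame  # adjusted p-value matrix
    summary: pd.DataFrame  # per-condition mean and s.d.

    def to_dict(self) -> dict:
        return {
            "paired_t": self.paired_t.to_dict(orient="records"),
            "kruskal": {"H": self.kruskal_h, "p": self.kruskal_p},
            "dunn_p_adjusted": self.dunn_p.to_dict(),
            "summary": self.summary.to_dict(orient="index"),
        }


def dunn_test(groups: Mapping[str, np.ndarray]) -> pd.DataFrame:
    """Dunn post-hoc z test on rank sums with tie correction and Bonferroni
    adjustment; returns the adjusted p-value matrix."""
    names = list(groups)
    values = np.concatenate([np.asarray(groups[g], dtype=float) for g in names])
    sizes = np.array([len(groups[g]) for g in names])
    ranks = stats.rankdata(values)
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    mean_ranks = np.array(
        [ranks[bounds[i] : bounds[i + 1]].mean() for i in range(len(names))]
    )
    n = len(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n - 1))
    var_base = n * (n + 1) / 12.0 - tie_term
    m = len(names) * (len(names) - 1) // 2
    p = np.ones((len(names), len(names)))
    for i, j in itertools.combinations(range(len(names)), 2):
        se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se
        p_raw = 2.0 * stats.norm.sf(abs(z))
        p[i, j] = p[j, i] = min(1.0, p_raw * m)
    return pd.DataFrame(p, index=names, columns=names)


def compare_protocols(table: pd.DataFrame, value: str = "nerni") -> ComparisonReport:
    """Compare protocol conditions on a transfer table.

    Paired t-tests run on within-subject differences for every condition pair
    (requires a complete subject crossing, otherwise the missing cells are
    reported); p-values are Bonferroni-adjusted over the number of pairs.
    The Kruskal-Wallis test and Dunn post-hoc treat conditions as independent
    groups, as in the initial nonparametric analysis.
    """
    conditions = sorted(table["condition"].unique())
    if len(conditions) < 2:
        raise ValueError("need at least 2 conditions to compare")
    pivot = table.pivot_table(index="subject_id", columns="condition", values=value)
    if len(pivot) < 3:
        raise ValueError("need at least 3 subjects for paired comparisons")
    missing = pivot.isna()
    if missing.to_numpy().any():
        gaps = [
            f"({s}, {c})"
            for s in pivot.index
            for c in pivot.columns
            if missing.loc[s, c]
        ]
        raise ValueError(f"incomplete crossing for paired tests; missing cells: {gaps}")

    pairs = list(itertools.combinations(conditions, 2))
    records = []
    for a, b in pairs:
        t_stat, p_raw = stats.ttest_rel(pivot[a], pivot[b])
        records.append(
            {
                "condition_a": a,
                "condition_b": b,
                "t": float(t_stat),
                "p_raw": float(p_raw),
                "p_bonferroni": float(min(1.0, p_raw * len(pairs))),
            }
        )
    paired = pd.DataFrame(records)

    groups = {c: pivot[c].to_numpy() for c in conditions}
    h_stat, kw_p = stats.kruskal(*groups.values())
    dunn = dunn_test(groups)
    summary = pd.DataFrame(
        {
            "mean": {c: float(np.mean(v)) for c, v in groups.items()},
            "sd": {c: float(np.std(v, ddof=1)) for c, v in groups.items()},
        }
    )
    return ComparisonReport(
        paired_t=paired,
        kruskal_h=float(h_stat),
        kruskal_p=float(kw_p),
        dunn_p=dunn,
        summary=summary,
    )


@dataclass
class QuadraticFit:
    """Quadratic dose-response fit of NERNI on the target-average En."""

    intercept: float
    linear: float
    quadratic: float
    r_squared: float
    p_values: dict[str, float] = field(default_factory=dict)

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.intercept + self.linear * x + self.quadratic * x**2

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "linear": self.linear,
            "quadratic": self.quadratic,
            "r_squared": self.r_squared,
            "p_values": self.p_values,
        }


def nerni_vs_mean_en_fit(table: pd.DataFrame) -> QuadraticFit:
    """OLS of NERNI on (1, <En>, <En>^2) over all table rows.

    Very low and very high target-average fields both produce poor NERNI, so
    the pooled relationship is well described by a concave parabola.
    """
    x = table["mean_en"].to_numpy(dtype=float)
    y = table["nerni"].to_numpy(dtype=float)
    if len(np.unique(x)) < 3:
        raise ValueError("need at least 3 distinct mean_en values")
    X = sm.add_constant(np.column_stack([x, x**2]))
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError("rank-deficient quadratic design")
    fit = sm.OLS(y, X).fit()
    return QuadraticFit(
        intercept=float(fit.params[0]),
        linear=float(fit.params[1]),
        quadratic=float(fit.params[2]),
        r_squared=float(fit.rsquared),
        p_values={
            "intercept": float(fit.pvalues[0]),
            "linear": float(fit.pvalues[1]),
            "quadratic": float(fit.pvalues[2]),
        },
    )
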