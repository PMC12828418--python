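"""FRET-quenched protease cleavage kinetics: AUC metric and group tests.

Cleavage of a Dabcyl/EDANS peptide separates quencher from fluorophore, so
fluorescence rises with proteolysis. Traces are recorded on a plate reader
(typically every minute for 30 min, three replicates per peptide). The
comparison metric is the area under the baseline-corrected curve (baseline =
the T=0 reading). Two groups are compared by a two-tailed two-sample
Student's t test; more groups by one-way ANOVA with Tukey's HSD post hoc.
Significance stars follow p < 0.05 (*), p < 0.01 (**), p < 0.001 (***),
otherwise ns.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "KineticTrace",
    "AUCResult",
    "GroupComparison",
    "baseline_correct",
    "auc_trapezoid",
    "summarize_auc",
    "compare_groups",
    "significance_stars",
    "traces_from_long_table",
]


@dataclass(frozen=True)
class KineticTrace:
    """One replicate fluorescence time course for one FRET peptide."""

    peptide_label: str
    replicate_id: str
    time: np.ndarray  # minutes
    fluorescence: np.ndarray  # arbitrary units

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=float)
        fluo = np.asarray(self.fluorescence, dtype=float)
        if time.size == 0 or fluo.size == 0:
            raise ValueError("empty kinetic trace")
        if time.size != fluo.size:
            raise ValueError("time and fluorescence must have equal length")
        if time.size >= 2 and not np.all(np.diff(time) > 0):
            raise ValueError("time points must be strictly increasing")
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "fluorescence", fluo)


def baseline_correct(trace: KineticTrace) -> KineticTrace:
    """Subtract the T=0 reading so every corrected trace starts at zero."""
    return KineticTrace(
        peptide_label=trace.peptide_label,
        replicate_id=trace.replicate_id,
        time=trace.time,
        fluorescence=trace.fluorescence - trace.fluorescence[0],
    )


def auc_trapezoid(trace: KineticTrace) -> float:
    """Trapezoidal area under the curve in AU*min."""
    if trace.time.size < 2:
        raise ValueError("AUC needs at least two time points")
    return float(np.trapezoid(trace.fluorescence, trace.time))


@dataclass(frozen=True)
class AUCResult:
    """Replicate AUCs for one peptide, on baseline-corrected traces."""

    peptide_label: str
    aucs: tuple[float, ...]

    @property
    def mean(self) -> float:
        return float(np.mean(self.aucs))

    @property
    def sd(self) -> float:
        return float(np.std(self.aucs, ddof=1)) if len(self.aucs) > 1 else 0.0


def summarize_auc(traces: Iterable[KineticTrace]) -> list[AUCResult]:
    """Baseline-correct every trace and collect per-peptide AUCs."""
    by_label: dict[str, list[float]] = {}
    for trace in traces:
        by_label.setdefault(trace.peptide_label, []).append(
            auc_trapezoid(baseline_correct(trace))
        )
    return [AUCResult(label, tuple(vals)) for label, vals in by_label.items()]


def significance_stars(p: float) -> str:
    """Star annotation as a pure step function of the p-value.

    Boundary values belong to the less significant class (p = 0.05 -> ns).
    """
    if not 0 <= p <= 1 or np.isnan(p):
        raise ValueError(f"p-value out of range: {p}")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass(frozen=True)
class GroupComparison:
    """Pairwise comparison table plus the overall test used."""

    method: str  # "t-test" | "anova+tukey"
    table: pd.DataFrame  # group_a, group_b, p_value, significance
    anova_p: float | None = None


def compare_groups(
    results: Sequence[AUCResult] | Mapping[str, Sequence[float]],
    welch: bool = False,
) -> GroupComparison:
    """Compare per-peptide AUC distributions.

    Two groups: two-tailed two-sample Student's t test (classical
    equal-variance form; ``welch=True`` switches to Welch). More than two:
    one-way ANOVA followed by Tukey's HSD pairwise p-values.
    """
    if isinstance(results, Mapping):
        groups = {k: np.asarray(v, dtype=float) for k, v in results.items()}
    else:
        groups = {r.peptide_label: np.asarray(r.aucs, dtype=float) for r in results}
    if len(groups) < 2:
        raise ValueError("need at least two groups to compare")
    for label, vals in groups.items():
        if vals.size < 2:
            raise ValueError(f"group {label!r} has fewer than two replicates")
    if all(np.var(v) == 0 for v in groups.values()):
        raise ValueError(
            "all groups have zero within-group variance; comparison is degenerate"
        )

    labels = list(groups)
    if len(groups) == 2:
        a, b = (groups[k] for k in labels)
        stat = stats.ttest_ind(a, b, equal_var=not welch)
        p = float(stat.pvalue)
        table = pd.DataFrame(
            [
                {
                    "group_a": labels[0],
                    "group_b": labels[1],
                    "p_value": p,
                    "significance": significance_stars(p),
                }
            ]
        )
        return GroupComparison(method="welch-t-test" if welch else "t-test", table=table)

    anova_p = float(stats.f_oneway(*groups.values()).pvalue)
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    values = np.concatenate([groups[k] for k in labels])
    group_codes = np.concatenate([[k] * groups[k].size for k in labels])
    tukey = pairwise_tukeyhsd(values, group_codes)
    frame = pd.DataFrame(
        tukey.summary().data[1:], columns=tukey.summary().data[0]
    )
    table = pd.DataFrame(
        {
            "group_a": frame["group1"],
            "group_b": frame["group2"],
            "p_value": frame["p-adj"].astype(float),
            "significance": [significance_stars(p) for p in frame["p-adj"].astype(float)],
        }
    )
    return GroupComparison(method="anova+tukey", table=table, anova_p=anova_p)


def traces_from_long_table(table: pd.DataFrame) -> list[KineticTrace]:
    """Build traces from a long-format table (label, replicate, time_min, fluorescence)."""
    required = {"label", "replicate", "time_min", "fluorescence"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"kinetics table is missing column(s) {sorted(missing)}")
    traces = []
    for (label, rep), grp in table.groupby(["label", "replicate"], sort=True):
        grp = grp.sort_values("time_min")
        traces.append(
            KineticTrace(
                peptide_label=str(label),
                replicate_id=str(rep),
                time=grp["time_min"].to_numpy(dtype=float),
                fluorescence=grp["fluorescence"].to_numpy(dtype=float),
            )
        )
    return traces
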