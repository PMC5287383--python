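"""Differential analysis across the three cohorts (control strain, model
strain, treated model): Student's t and one-way ANOVA, plus the
presence/absence "modulation" classification that produces the headline
species counts.

Classification vocabulary
-------------------------
control-only            detectable in control, not in model
model-only              detectable in model, not in control
treatment-induced       not detectable in model, detectable in treated
treatment-suppressed    detectable in model, not detectable in treated
significantly-different-model-vs-control / significantly-changed-by-treatment
                        mean shifts supported either by recomputed tests
                        or by transcribed table markers
"modulated by treatment" is the union induced | suppressed |
significantly-changed-by-treatment.  Labels are not exclusive: a species
can be, e.g., both model-only and treatment-suppressed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigurationError, InsufficientData, UndefinedStatistic

__all__ = [
    "TestResult",
    "ModulationCall",
    "CATEGORIES",
    "students_t_from_summary",
    "students_t",
    "one_way_anova",
    "classify_modulation",
    "profile_comparison_counts",
]

CATEGORIES = (
    "control_only",
    "model_only",
    "treatment_induced",
    "treatment_suppressed",
    "significantly_changed_by_treatment",
    "significantly_different_model_vs_control",
    "unchanged",
)


@dataclass(frozen=True)
class TestResult:
    """Outcome of a t or F test; ``note`` marks degenerate no-test cases."""

    statistic: float
    df: float | tuple[float, float]
    p_two_tailed: float
    p_one_tailed: float | None = None
    note: str = "ok"

    @property
    def valid(self) -> bool:
        return self.note == "ok"


def students_t_from_summary(mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int) -> TestResult:
    """Pooled-variance Student's t from group summaries.

    t = (m1 - m2) / (sp * sqrt(1/n1 + 1/n2)) with the pooled variance
    sp^2 = ((n1-1) s1^2 + (n2-1) s2^2) / (n1 + n2 - 2), df = n1 + n2 - 2.
    The one-tailed p is for the observed direction (half the two-tailed p).
    """
    if n1 < 2 or n2 < 2:
        raise InsufficientData("Student's t needs n >= 2 per group")
    if sd1 < 0 or sd2 < 0:
        raise UndefinedStatistic("standard deviations must be >= 0")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    if sp2 == 0.0:
        if mean1 == mean2:
            return TestResult(statistic=0.0, df=df, p_two_tailed=1.0, p_one_tailed=0.5)
        raise UndefinedStatistic("zero pooled variance with unequal means")
    t = (mean1 - mean2) / math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p_two = 2.0 * sps.t.sf(abs(t), df)
    return TestResult(statistic=t, df=df, p_two_tailed=float(min(p_two, 1.0)), p_one_tailed=float(sps.t.sf(abs(t), df)))


def students_t(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Pooled Student's t from raw replicates; agrees exactly with
    :func:`students_t_from_summary` of their mean/SD/n."""
    a = np.asarray(x, dtype=float)
    b = np.asarray(y, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientData("Student's t needs n >= 2 per group")
    return students_t_from_summary(
        float(a.mean()), float(a.std(ddof=1)), int(a.size),
        float(b.mean()), float(b.std(ddof=1)), int(b.size),
    )


def one_way_anova(*groups: Sequence[float]) -> TestResult:
    """Classical one-way ANOVA (between/within decomposition).

    With two groups, F equals the square of the pooled t statistic.  When
    every observation is identical the F ratio is undefined and a no-test
    result is returned.
    """
    if len(groups) < 2:
        raise InsufficientData("ANOVA needs at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise InsufficientData("every group needs n >= 2")
    k = len(arrays)
    n_total = sum(a.size for a in arrays)
    grand = sum(a.sum() for a in arrays) / n_total
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_b, df_w = k - 1, n_total - k
    if ss_within == 0.0 and ss_between == 0.0:
        return TestResult(statistic=float("nan"), df=(df_b, df_w), p_two_tailed=float("nan"), note="all observations identical")
    if ss_within == 0.0:
        return TestResult(statistic=float("inf"), df=(df_b, df_w), p_two_tailed=0.0)
    f = (ss_between / df_b) / (ss_within / df_w)
    return TestResult(statistic=float(f), df=(df_b, df_w), p_two_tailed=float(sps.f.sf(f, df_b, df_w)))


@dataclass(frozen=True)
class ModulationCall:
    """Multi-label classification of one species across the three groups."""

    species: str
    categories: frozenset[str]
    significance_source: str  # "recomputed" | "markers"

    def __contains__(self, category: str) -> bool:
        return category in self.categories

    @property
    def modulated_by_treatment(self) -> bool:
        return bool(
            self.categories
            & {"treatment_induced", "treatment_suppressed", "significantly_changed_by_treatment"}
        )


def _detectable(row: Mapping, group: str) -> bool:
    return bool(row[f"{group}_detectable"])


def classify_modulation(
    summaries: pd.DataFrame,
    significance: str = "recomputed",
    alpha: float = 0.05,
    one_tailed: bool = False,
    markers: Mapping[str, Mapping[str, str]] | None = None,
    bh_correct: bool = False,
) -> list[ModulationCall]:
    """Classify every species of a group-summary frame.

    ``summaries`` is the frame produced by
    :func:`nglyco.quantify.group_summaries` (or transcribed from a printed
    table): per species the columns ``<group>_{mean,sd,n,detectable}`` for
    groups control/model/treated.

    ``significance`` selects how mean-shift categories are decided:
    ``"recomputed"`` runs pooled Student's t tests (control vs model and
    model vs treated) at ``alpha``; ``"markers"`` trusts the transcribed
    table markers passed via ``markers`` (per species a mapping with
    optional keys ``vs_control`` and ``vs_model``).  ``bh_correct``
    applies Benjamini-Hochberg across each recomputed test family
    (off by default).
    """
    for group in ("control", "model", "treated"):
        needed = {f"{group}_mean", f"{group}_sd", f"{group}_n", f"{group}_detectable"}
        if not needed <= set(summaries.columns):
            raise ConfigurationError(f"summaries missing columns for group {group!r}")
    if significance not in ("recomputed", "markers"):
        raise ConfigurationError("significance must be 'recomputed' or 'markers'")
    if significance == "markers" and markers is None:
        raise ConfigurationError("markers mode requires a markers mapping")

    p_cm: dict[str, float] = {}
    p_mt: dict[str, float] = {}
    if significance == "recomputed":
        for species, row in summaries.iterrows():
            if _detectable(row, "control") and _detectable(row, "model"):
                try:
                    res = students_t_from_summary(
                        row["control_mean"], row["control_sd"], int(row["control_n"]),
                        row["model_mean"], row["model_sd"], int(row["model_n"]),
                    )
                    p_cm[species] = res.p_one_tailed if one_tailed else res.p_two_tailed
                except UndefinedStatistic:
                    pass
            if _detectable(row, "model") and _detectable(row, "treated"):
                try:
                    res = students_t_from_summary(
                        row["model_mean"], row["model_sd"], int(row["model_n"]),
                        row["treated_mean"], row["treated_sd"], int(row["treated_n"]),
                    )
                    p_mt[species] = res.p_one_tailed if one_tailed else res.p_two_tailed
                except UndefinedStatistic:
                    pass
        if bh_correct:
            from statsmodels.stats.multitest import multipletests

            for family in (p_cm, p_mt):
                if family:
                    keys = list(family)
                    adj = multipletests([family[k] for k in keys], method="fdr_bh")[1]
                    family.update(dict(zip(keys, adj)))

    calls = []
    for species, row in summaries.iterrows():
        cats = set()
        det_c, det_m, det_t = (_detectable(row, g) for g in ("control", "model", "treated"))
        if det_c and not det_m:
            cats.add("control_only")
        if det_m and not det_c:
            cats.add("model_only")
        if det_t and not det_m:
            cats.add("treatment_induced")
        if det_m and not det_t:
            cats.add("treatment_suppressed")
        if significance == "markers":
            marks = markers.get(species, {})
            if marks.get("vs_control"):
                cats.add("significantly_different_model_vs_control")
            if marks.get("vs_model"):
                cats.add("significantly_changed_by_treatment")
        else:
            if p_cm.get(species, 1.0) < alpha:
                cats.add("significantly_different_model_vs_control")
            if p_mt.get(species, 1.0) < alpha:
                cats.add("significantly_changed_by_treatment")
        if not cats:
            cats.add("unchanged")
        calls.append(ModulationCall(species=str(species), categories=frozenset(cats), significance_source=significance))
    return calls


def profile_comparison_counts(calls: Iterable[ModulationCall]) -> dict[str, int]:
    """Per-category counts plus the 'modulated_by_treatment' union count."""
    counts = {c: 0 for c in CATEGORIES}
    counts["modulated_by_treatment"] = 0
    for call in calls:
        for cat in call.categories:
            counts[cat] += 1
        if call.modulated_by_treatment:
            counts["modulated_by_treatment"] += 1
    return counts
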