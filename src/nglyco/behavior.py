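"""Behavioral measures and glycan-behavior Pearson correlation screening.

The cognitive battery yields per-animal measures: novel-object
discrimination index (short/long retention, % of exploration time on the
novel object), step-down passive-avoidance latencies (2 h and 24 h, s),
final-day escape latency in the water maze (s), and the probe-trial
escape latency (s), time in the target quadrant (s) and platform
crossings (count).  Correlations against glycan corrected intensities
are computed across all animals pooled (both strains plus treated), with
two-tailed p from the t transform and a 95% Fisher-z confidence interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InsufficientData, SchemaError, UndefinedStatistic
from .quantify import AbundanceMatrix

__all__ = [
    "BEHAVIOR_MEASURES",
    "CorrelationResult",
    "discrimination_index",
    "pearson_correlation",
    "screen_glycan_behavior",
]

#: Per-animal behavioral measure columns (besides 'subject' and 'group').
BEHAVIOR_MEASURES = (
    "di_short",
    "di_long",
    "stepdown_latency_2h",
    "stepdown_latency_24h",
    "escape_latency_final",
    "probe_escape_latency",
    "target_quadrant_time",
    "platform_crossings",
)


def discrimination_index(t_novel: float, t_familiar: float) -> float:
    """Novel-object exploration as percent of total exploration time."""
    if t_novel < 0 or t_familiar < 0:
        raise UndefinedStatistic("exploration times must be >= 0")
    total = t_novel + t_familiar
    if total <= 0:
        raise UndefinedStatistic("zero total exploration time")
    return 100.0 * t_novel / total


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation with two-tailed p and 95% Fisher-z CI."""

    r: float
    n: int
    p: float
    ci_low: float
    ci_high: float

    @property
    def significant(self) -> bool:
        return self.p < 0.05


_Z95 = 1.959963984540054


def pearson_correlation(x, y) -> CorrelationResult:
    """Product-moment correlation of two vectors.

    Two-tailed p via t = r sqrt((n-2)/(1-r^2)) on n-2 df; the 95% CI is
    tanh(atanh r +- 1.96/sqrt(n-3)) (degenerate to [r, r] for n = 3).
    Constant vectors leave r undefined.
    """
    a = np.asarray(x, dtype=float)
    b = np.asarray(y, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise InsufficientData("x and y must be 1-d vectors of equal length")
    n = a.size
    if n < 3:
        raise InsufficientData(f"Pearson correlation needs n >= 3, got {n}")
    da = a - a.mean()
    db = b - b.mean()
    denom = math.sqrt(float(da @ da) * float(db @ db))
    if denom == 0.0:
        raise UndefinedStatistic("correlation undefined for a constant vector")
    r = float(da @ db) / denom
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * sps.t.sf(abs(t), n - 2))
    if n > 3:
        h = _Z95 / math.sqrt(n - 3)
        if abs(r) == 1.0:
            lo = hi = r
        else:
            z = math.atanh(r)
            lo, hi = math.tanh(z - h), math.tanh(z + h)
    else:
        lo = hi = r
    return CorrelationResult(r=r, n=n, p=min(p, 1.0), ci_low=lo, ci_high=hi)


def screen_glycan_behavior(
    matrix: AbundanceMatrix,
    behavior: pd.DataFrame,
    species: list[str] | None = None,
    measures: list[str] | None = None,
) -> pd.DataFrame:
    """Pearson screen of every (species, measure) pair across animals.

    ``behavior`` has one row per animal with a ``subject`` column matching
    the matrix sample ids.  Animals are pooled across groups.  Pairs where
    either vector is constant are skipped with a note; the output frame has
    columns species, measure, r, n, p, ci_low, ci_high, significant.
    """
    if "subject" not in behavior.columns:
        raise SchemaError("behavior table needs a 'subject' column")
    beh = behavior.set_index("subject")
    common = [s for s in matrix.samples if s in beh.index]
    if len(common) == 0:
        raise InsufficientData("no overlapping subjects between matrix and behavior table")
    if len(common) < 3:
        raise InsufficientData(f"need >= 3 overlapping subjects, got {len(common)}")
    species = species if species is not None else matrix.species
    measures = measures if measures is not None else [m for m in BEHAVIOR_MEASURES if m in beh.columns]
    rows = []
    for sp in species:
        x_full = matrix.data.loc[common, sp]
        for measure in measures:
            if measure not in beh.columns:
                raise SchemaError(f"behavior table missing measure column {measure!r}")
            y_full = beh.loc[common, measure]
            keep = x_full.notna() & y_full.notna()
            try:
                res = pearson_correlation(x_full[keep].to_numpy(), y_full[keep].to_numpy())
            except (InsufficientData, UndefinedStatistic):
                continue
            rows.append(
                {
                    "species": sp,
                    "measure": measure,
                    "r": res.r,
                    "n": res.n,
                    "p": res.p,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "significant": res.significant,
                }
            )
    return pd.DataFrame.from_records(
        rows, columns=["species", "measure", "r", "n", "p", "ci_low", "ci_high", "significant"]
    )
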