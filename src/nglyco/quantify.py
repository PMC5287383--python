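"""Internal-standard normalization, replicate aggregation and Dixon's Q
outlier screening.

Spectra are doped with a fixed amount of beta-cyclodextrin; glycan peak
intensities are scaled to the internal-standard intensity (times 100) to
give corrected intensities comparable across samples.  Corrected
intensities are aggregated per (species, group) with zeros standing in
for species absent from a replicate; a species is *detectable* in a group
iff any replicate is positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem import Peak
from .errors import GlycoError, InsufficientData, MissingInternalStandard
from .errors import ConfigurationError

__all__ = [
    "InternalStandardRef",
    "AbundanceMatrix",
    "GroupSummary",
    "DixonResult",
    "locate_internal_standard",
    "normalize_intensities",
    "aggregate_group",
    "group_summaries",
    "dixon_outlier_test",
    "screen_outliers",
    "GROUPS",
]

#: Canonical group labels: control strain, model strain, treated model.
GROUPS = ("control", "model", "treated")


@dataclass(frozen=True)
class InternalStandardRef:
    """Reference m/z of the internal standard per ionization mode.

    Defaults are the working beta-cyclodextrin references: [M+Na]+ m/z
    1157.25 in positive mode and [M-H]- m/z 1133.25 in negative mode,
    matched within ``window`` Da.
    """

    positive_mz: float = 1157.25
    negative_mz: float = 1133.25
    window: float = 0.5

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise ConfigurationError("internal-standard window must be positive")

    def mz_for(self, mode: str) -> float:
        if mode == "positive":
            return self.positive_mz
        if mode == "negative":
            return self.negative_mz
        raise ConfigurationError(f"mode must be 'positive' or 'negative', got {mode!r}")


def locate_internal_standard(peaks: list[Peak], mode: str, ref: InternalStandardRef | None = None) -> Peak:
    """Most intense peak inside the internal-standard window for ``mode``.

    Raises :class:`MissingInternalStandard` when no peak falls in the
    window; callers exclude the sample with a logged reason rather than
    silently zeroing it.
    """
    if not peaks:
        raise MissingInternalStandard("empty peak list")
    ref = ref or InternalStandardRef()
    target = ref.mz_for(mode)
    in_window = [p for p in peaks if p.mode == mode and abs(p.mz - target) <= ref.window]
    if not in_window:
        raise MissingInternalStandard(
            f"no {mode}-mode peak within {ref.window} Da of internal standard m/z {target}"
        )
    return max(in_window, key=lambda p: p.intensity)


def normalize_intensities(peaks: list[Peak], is_peak: Peak) -> list[Peak]:
    """Scale raw intensities to the internal standard: 100 * raw / IS.

    The internal standard itself maps to 100; zeros are preserved.
    """
    if is_peak.intensity <= 0:
        raise MissingInternalStandard("internal-standard intensity must be positive")
    scale = 100.0 / is_peak.intensity
    return [Peak(mz=p.mz, intensity=p.intensity * scale, mode=p.mode) for p in peaks]


@dataclass
class AbundanceMatrix:
    """Samples x glycan-species matrix of corrected intensities.

    ``data`` holds one row per sample and one column per species key
    (composition string + adduct label); absent species are 0.  ``groups``
    maps each sample id to its group label.
    """

    data: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        self.groups = pd.Series(self.groups)
        if not self.data.index.equals(self.groups.index):
            self.groups = self.groups.reindex(self.data.index)
        if self.groups.isna().any():
            missing = list(self.data.index[self.groups.isna()])
            raise GlycoError(f"samples without a group label: {missing}")
        bad = set(self.groups.unique()) - set(GROUPS)
        if bad:
            raise GlycoError(f"unknown group labels {sorted(bad)}; expected {GROUPS}")
        if self.data.columns.duplicated().any():
            raise GlycoError("species keys must be unique")
        if (self.data.to_numpy() < 0).any():
            raise GlycoError("corrected intensities must be >= 0")

    @property
    def species(self) -> list[str]:
        return list(self.data.columns)

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    def replicates(self, species: str, group: str) -> np.ndarray:
        if species not in self.data.columns:
            raise KeyError(f"unknown species {species!r}")
        if group not in GROUPS:
            raise KeyError(f"unknown group {group!r}")
        return self.data.loc[self.groups == group, species].to_numpy(dtype=float)


@dataclass(frozen=True)
class GroupSummary:
    """Per-(species, group) replicate summary: mean, sample SD (n-1),
    replicate count and detectability (any replicate > 0)."""

    mean: float
    sd: float
    n: int
    detectable: bool


def aggregate_group(matrix: AbundanceMatrix, species: str, group: str) -> GroupSummary:
    """Mean/SD over all group replicates, zeros included for absences."""
    values = matrix.replicates(species, group)
    if values.size == 0:
        raise KeyError(f"no samples in group {group!r}")
    detectable = bool((values > 0).any())
    if not detectable:
        return GroupSummary(mean=0.0, sd=0.0, n=int(values.size), detectable=False)
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    return GroupSummary(mean=float(values.mean()), sd=sd, n=int(values.size), detectable=True)


def group_summaries(matrix: AbundanceMatrix) -> pd.DataFrame:
    """Summary frame: one row per species, columns <group>_{mean,sd,n,detectable}."""
    rows = {}
    for species in matrix.species:
        row = {}
        for group in GROUPS:
            s = aggregate_group(matrix, species, group)
            row[f"{group}_mean"] = s.mean
            row[f"{group}_sd"] = s.sd
            row[f"{group}_n"] = s.n
            row[f"{group}_detectable"] = s.detectable
        rows[species] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "species"
    return out


# ---------------------------------------------------------------------------
# Dixon's Q-test

# Two-sided critical values of Dixon's r10 (Q) statistic, n = 3..10.
_DIXON_Q = {
    0.10: {3: 0.941, 4: 0.765, 5: 0.642, 6: 0.560, 7: 0.507, 8: 0.468, 9: 0.437, 10: 0.412},
    0.05: {3: 0.970, 4: 0.829, 5: 0.710, 6: 0.625, 7: 0.568, 8: 0.526, 9: 0.493, 10: 0.466},
    0.01: {3: 0.994, 4: 0.926, 5: 0.821, 6: 0.740, 7: 0.680, 8: 0.634, 9: 0.598, 10: 0.568},
}


@dataclass(frozen=True)
class DixonResult:
    """Outcome of a Dixon Q screen: index of the flagged suspect (or
    None), the Q statistic, the critical value used and a reason when no
    test was performed."""

    suspect: int | None
    q: float | None
    critical: float | None
    reason: str = "ok"

    @property
    def flagged(self) -> bool:
        return self.suspect is not None


def dixon_outlier_test(values, alpha: float = 0.05) -> DixonResult:
    """Dixon's Q-test for a single outlier in a small sample (3 <= n <= 10).

    Q = gap(suspect, nearest neighbour) / range, computed for the more
    extreme end; the suspect is flagged iff Q exceeds the two-sided
    critical value Q(n, alpha).  Zero range yields a no-test result.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise InsufficientData(f"Dixon's Q needs n >= 3, got {x.size}")
    if x.size > 10:
        raise InsufficientData(f"Dixon's Q table covers n <= 10, got {x.size}")
    if alpha not in _DIXON_Q:
        raise ConfigurationError(f"alpha must be one of {sorted(_DIXON_Q)}")
    rng = float(x.max() - x.min())
    if rng == 0.0:
        return DixonResult(suspect=None, q=None, critical=None, reason="zero range")
    order = np.argsort(x, kind="stable")
    xs = x[order]
    gap_low = xs[1] - xs[0]
    gap_high = xs[-1] - xs[-2]
    if gap_high >= gap_low:
        q = gap_high / rng
        suspect = int(order[-1])
    else:
        q = gap_low / rng
        suspect = int(order[0])
    crit = _DIXON_Q[alpha][int(x.size)]
    if q > crit:
        return DixonResult(suspect=suspect, q=float(q), critical=crit)
    return DixonResult(suspect=None, q=float(q), critical=crit)


def screen_outliers(matrix: AbundanceMatrix, alpha: float = 0.05, exclude: bool = False) -> tuple[pd.DataFrame, AbundanceMatrix]:
    """Dixon screen of every (species, group) replicate vector.

    Returns a report of flagged values and, when ``exclude`` is set, a
    copy of the matrix with flagged entries replaced by the group mean of
    the remaining replicates (default is report-only).
    """
    records = []
    data = matrix.data.copy()
    for species in matrix.species:
        for group in GROUPS:
            values = matrix.replicates(species, group)
            if values.size < 3 or values.size > 10:
                continue
            res = dixon_outlier_test(values, alpha=alpha)
            if res.flagged:
                sample_ids = matrix.data.index[matrix.groups == group]
                sample = sample_ids[res.suspect]
                records.append(
                    {
                        "species": species,
                        "group": group,
                        "sample": sample,
                        "value": values[res.suspect],
                        "q": res.q,
                        "critical": res.critical,
                    }
                )
                if exclude:
                    others = np.delete(values, res.suspect)
                    data.loc[sample, species] = float(others.mean())
    report = pd.DataFrame.from_records(records, columns=["species", "group", "sample", "value", "q", "critical"])
    return report, AbundanceMatrix(data=data, groups=matrix.groups)
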