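"""Packaged reference tables and the one-shot profile reproduction.

The two published N-glycan profile tables (43 cortex species, 56 serum
species) ship as verbatim TSV transcriptions: observed m/z, adduct label,
composition string, per-group mean/SD cells (blank = undetectable) and
the printed significance markers.  An "as-printed" policy applies — known
inconsistencies (duplicate species rows, masses that disagree with
monoisotopic theory, a narrative count that disagrees with the stated
rules) are never corrected; they are carried in a machine-readable flag
table and surfaced by the reconciliation report.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .chem import ion_mz, parse_adduct_label, parse_composition
from .errors import ConfigurationError, FixtureIntegrityError
from .groupstats import (
    classify_modulation,
    profile_comparison_counts,
    students_t_from_summary,
)

__all__ = [
    "FixtureTable",
    "load_fixture",
    "load_flags",
    "fixture_summaries",
    "fixture_markers",
    "mass_consistency_report",
    "marker_reproduction_report",
    "reproduce_tables",
]

_CHECKSUMS = {
    "cortex_table.tsv": "f15f31a3ac4c25502e352e526163f97ae905a3094f9e1e96f54de1113f6ed8b0",
    "serum_table.tsv": "f4a8208930a3c73b740525a789a3c54be19fdc9548b221a3f9370ebc072c855a",
    "table_flags.tsv": "7ad2be153f110d37425434e64b67f64d04ed01e4decd972f8b4104231c30bc34",
}

_EXPECTED_ROWS = {"cortex": 43, "serum": 56}

#: Narrative headline counts stated alongside each table, used only for
#: reconciliation reporting (never to force the computed counts).
NARRATIVE_COUNTS = {
    "cortex": {
        "control_only": 9,
        "model_only": 5,
        "treatment_induced": 15,
        "treatment_suppressed": 5,
        "modulated_by_treatment": 21,
    },
    "serum": {
        "control_only": 5,
        "model_only": 9,
        "treatment_induced": 1,
        "treatment_suppressed": 4,
        "modulated_by_treatment": 6,
    },
}


def _read_packaged(name: str) -> pd.DataFrame:
    ref = resources.files("nglyco.data") / name
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _CHECKSUMS[name]:
        raise FixtureIntegrityError(f"{name}: checksum mismatch ({digest})")
    from io import BytesIO

    return pd.read_csv(BytesIO(raw), sep="\t")


@dataclass(frozen=True)
class FixtureTable:
    """One transcribed profile table plus its tissue label."""

    tissue: str
    table: pd.DataFrame

    @property
    def n_rows(self) -> int:
        return len(self.table)

    def row_key(self, no: int) -> str:
        row = self.table.loc[self.table["no"] == no].iloc[0]
        return f"{row['no']}: {row['composition']} {row['adduct']}"


def load_fixture(which: str) -> FixtureTable:
    """Load the packaged transcription for ``cortex`` or ``serum``.

    Every composition and adduct string is parsed on load; undetectable
    cells are blank (NaN mean/SD).  A checksum failure raises
    :class:`FixtureIntegrityError`.
    """
    if which not in _EXPECTED_ROWS:
        raise ConfigurationError(f"fixture must be 'cortex' or 'serum', got {which!r}")
    df = _read_packaged(f"{which}_table.tsv")
    if len(df) != _EXPECTED_ROWS[which]:
        raise FixtureIntegrityError(f"{which} table has {len(df)} rows, expected {_EXPECTED_ROWS[which]}")
    for _, row in df.iterrows():
        parse_composition(row["composition"])
        parse_adduct_label(row["adduct"])
        for g in ("control", "model", "treated"):
            if pd.isna(row[f"{g}_mean"]) != pd.isna(row[f"{g}_sd"]):
                raise FixtureIntegrityError(f"{which} row {row['no']}: half-filled {g} cell")
    return FixtureTable(tissue=which, table=df)


def load_flags() -> pd.DataFrame:
    """Machine-readable list of known as-printed inconsistencies."""
    return _read_packaged("table_flags.tsv")


def fixture_summaries(fixture: FixtureTable, n: int = 3) -> pd.DataFrame:
    """Group-summary frame (as consumed by classify_modulation) from the
    printed mean/SD cells; undetectable cells become mean = SD = 0.

    Row numbers index the frame (species strings repeat in the printed
    tables), with the species key carried in a ``key`` column.
    """
    rows = {}
    for _, row in fixture.table.iterrows():
        entry = {"key": f"{row['composition']} {row['adduct']}"}
        for g in ("control", "model", "treated"):
            detectable = not pd.isna(row[f"{g}_mean"])
            entry[f"{g}_mean"] = float(row[f"{g}_mean"]) if detectable else 0.0
            entry[f"{g}_sd"] = float(row[f"{g}_sd"]) if detectable else 0.0
            entry[f"{g}_n"] = n
            entry[f"{g}_detectable"] = detectable
        rows[int(row["no"])] = entry
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "no"
    return out


def fixture_markers(fixture: FixtureTable) -> dict[int, dict[str, str]]:
    """Transcribed significance markers keyed by row number."""
    out: dict[int, dict[str, str]] = {}
    for _, row in fixture.table.iterrows():
        marks = {}
        if isinstance(row.get("sig_vs_control"), str):
            marks["vs_control"] = row["sig_vs_control"]
        if isinstance(row.get("sig_vs_model"), str):
            marks["vs_model"] = row["sig_vs_model"]
        if marks:
            out[int(row["no"])] = marks
    return out


def mass_consistency_report(fixture: FixtureTable, tol_da: float = 0.2) -> pd.DataFrame:
    """Printed observed m/z versus theoretical monoisotopic ion m/z.

    Rows whose absolute deviation exceeds ``tol_da`` are flagged
    inconsistent; the printed masses are data, not oracles for the mass
    model, so nothing is corrected.
    """
    records = []
    for _, row in fixture.table.iterrows():
        comp = parse_composition(row["composition"])
        adduct = parse_adduct_label(row["adduct"])
        theo = ion_mz(comp, adduct)
        dev = float(row["observed_mz"]) - theo
        records.append(
            {
                "no": int(row["no"]),
                "composition": row["composition"],
                "adduct": row["adduct"],
                "observed_mz": float(row["observed_mz"]),
                "theoretical_mz": theo,
                "deviation_da": dev,
                "consistent": abs(dev) <= tol_da,
            }
        )
    return pd.DataFrame.from_records(records)


def marker_reproduction_report(fixture: FixtureTable, alpha_map={"*": 0.05, "**": 0.01, "#": 0.05}) -> pd.DataFrame:
    """Recompute pooled t-tests behind every printed marker.

    For each marker the two-tailed and one-tailed p-values are reported
    together with whether each reproduces the printed threshold; markers
    reproducible only one-tailed are thereby listed without failing.
    """
    summaries = fixture_summaries(fixture)
    records = []
    for no, marks in fixture_markers(fixture).items():
        row = summaries.loc[no]
        for which, marker in marks.items():
            if which == "vs_control":
                a = ("control_mean", "control_sd", "control_n")
                b = ("model_mean", "model_sd", "model_n")
            else:
                a = ("model_mean", "model_sd", "model_n")
                b = ("treated_mean", "treated_sd", "treated_n")
            res = students_t_from_summary(
                row[a[0]], row[a[1]], int(row[a[2]]), row[b[0]], row[b[1]], int(row[b[2]])
            )
            threshold = alpha_map[marker]
            records.append(
                {
                    "no": no,
                    "comparison": which,
                    "marker": marker,
                    "threshold": threshold,
                    "t": res.statistic,
                    "p_two_tailed": res.p_two_tailed,
                    "p_one_tailed": res.p_one_tailed,
                    "reproduced_two_tailed": res.p_two_tailed < threshold,
                    "reproduced_one_tailed": res.p_one_tailed < threshold,
                }
            )
    return pd.DataFrame.from_records(
        records,
        columns=[
            "no",
            "comparison",
            "marker",
            "threshold",
            "t",
            "p_two_tailed",
            "p_one_tailed",
            "reproduced_two_tailed",
            "reproduced_one_tailed",
        ],
    )


def reproduce_tables() -> dict:
    """Fixture -> summaries -> marker-mode classification -> counts, for
    both tissues, with a reconciliation of computed against narrative
    numbers and the documented as-printed discrepancies."""
    report: dict = {"tissues": {}, "flags": load_flags().to_dict("records")}
    for tissue in ("cortex", "serum"):
        fixture = load_fixture(tissue)
        summaries = fixture_summaries(fixture)
        markers = fixture_markers(fixture)
        calls = classify_modulation(summaries, significance="markers", markers=markers)
        counts = profile_comparison_counts(calls)
        narrative = NARRATIVE_COUNTS[tissue]
        mass = mass_consistency_report(fixture)
        report["tissues"][tissue] = {
            "n_species": fixture.n_rows,
            "counts": counts,
            "narrative_counts": narrative,
            "count_discrepancies": {
                k: {"computed": counts[k], "narrative": v}
                for k, v in narrative.items()
                if counts[k] != v
            },
            "mass_inconsistent_rows": mass.loc[~mass["consistent"], "no"].tolist(),
            "marker_reproduction": marker_reproduction_report(fixture).to_dict("records"),
        }
    return report
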