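"""Delimited-text readers and writers.

All tabular I/O is TSV.  Writers prepend a comment header carrying the
tool version and a short hash of the writer's configuration, so primary
outputs are diff-able and reproducible; readers skip ``#`` comment lines.
Numeric round-trips are lossless to 6 significant digits.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import pandas as pd

from . import __version__
from .chem import Peak
from .errors import SchemaError
from .quantify import AbundanceMatrix
from .search import Assignment

__all__ = [
    "read_peaklist",
    "write_peaklist",
    "read_manifest",
    "read_behavior_table",
    "write_assignments",
    "write_matrix",
    "read_matrix",
    "write_table",
    "build_abundance_matrix",
]

# 10 significant digits: sub-0.001 ppm round-trip error on m/z values
_FLOAT_FMT = "%.10g"


def _config_hash(config: dict | None) -> str:
    payload = json.dumps(config or {}, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _header(config: dict | None) -> str:
    return f"# nglyco v{__version__} config={_config_hash(config)}\n"


def _write_frame(df: pd.DataFrame, path, config: dict | None, index: bool = False) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header(config))
        df.to_csv(fh, sep="\t", index=index, float_format=_FLOAT_FMT)


def _read_frame(path, required: set[str] | None = None) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path}: empty file, returning empty table")
        return pd.DataFrame(columns=sorted(required or []))
    except pd.errors.ParserError as exc:
        raise SchemaError(f"{path}: malformed delimited text: {exc}") from exc
    if required and not required <= set(df.columns):
        missing = sorted(required - set(df.columns))
        raise SchemaError(f"{path}: missing required columns {missing}")
    return df


def read_peaklist(path) -> list[Peak]:
    """Read a peak list (columns: mz, intensity, mode)."""
    df = _read_frame(path, required={"mz", "intensity", "mode"})
    peaks = []
    for i, row in df.iterrows():
        try:
            peaks.append(Peak(mz=float(row["mz"]), intensity=float(row["intensity"]), mode=str(row["mode"])))
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"{path}: bad peak on data line {i + 1}: {exc}") from exc
    return peaks


def write_peaklist(peaks: list[Peak], path, config: dict | None = None) -> None:
    df = pd.DataFrame([{"mz": p.mz, "intensity": p.intensity, "mode": p.mode} for p in peaks],
                      columns=["mz", "intensity", "mode"])
    _write_frame(df, path, config)


def read_manifest(path) -> pd.DataFrame:
    """Read the sample manifest (columns: sample, group)."""
    df = _read_frame(path, required={"sample", "group"})
    if df["sample"].duplicated().any():
        raise SchemaError(f"{path}: duplicate sample ids")
    return df


def read_behavior_table(path) -> pd.DataFrame:
    """Read the per-animal behavior table (columns: subject, group, measures...)."""
    return _read_frame(path, required={"subject"})


def write_assignments(assignments: list[Assignment], unassigned: list[Peak], path, config: dict | None = None) -> None:
    """Write the assignment table; unassigned peaks appear with blank
    composition fields so no peak is dropped silently."""
    rows = []
    for rank, a in enumerate(assignments, start=1):
        rows.append(
            {
                "mz": a.peak.mz,
                "intensity": a.peak.intensity,
                "mode": a.peak.mode,
                "adduct": a.adduct.label(),
                "composition": str(a.composition),
                "theoretical_mz": a.theoretical_mz,
                "ppm_error": a.ppm_error,
                "rank": rank,
            }
        )
    for p in unassigned:
        rows.append(
            {
                "mz": p.mz,
                "intensity": p.intensity,
                "mode": p.mode,
                "adduct": "",
                "composition": "",
                "theoretical_mz": "",
                "ppm_error": "",
                "rank": "",
            }
        )
    df = pd.DataFrame(rows, columns=["mz", "intensity", "mode", "adduct", "composition", "theoretical_mz", "ppm_error", "rank"])
    _write_frame(df, path, config)


def write_matrix(matrix: AbundanceMatrix, path, config: dict | None = None) -> None:
    """Write an abundance matrix: one row per sample, 'sample' and 'group'
    columns then one column per species key."""
    df = matrix.data.copy()
    df.insert(0, "group", matrix.groups)
    df.insert(0, "sample", df.index)
    _write_frame(df, path, config)


def read_matrix(path) -> AbundanceMatrix:
    df = _read_frame(path, required={"sample", "group"})
    df = df.set_index("sample")
    groups = df.pop("group")
    return AbundanceMatrix(data=df, groups=groups)


def write_table(df: pd.DataFrame, path, config: dict | None = None, index: bool = False) -> None:
    """Generic report writer (classification tables, correlation screens...)."""
    _write_frame(df, path, config, index=index)


def build_abundance_matrix(
    peaklists: dict[str, list[Peak]],
    manifest: pd.DataFrame,
    species_keys: dict[str, float],
    tol_ppm: float = 10.0,
) -> AbundanceMatrix:
    """Assemble corrected peak lists into a samples x species matrix.

    ``species_keys`` maps each species key to its theoretical ion m/z;
    within each sample the most intense peak inside the ppm window is
    taken as that species' corrected intensity, with 0 recorded for
    absences.  Peak lists must already be internal-standard corrected.
    """
    manifest = manifest.set_index("sample") if "sample" in manifest.columns else manifest
    data = {}
    for sample, peaks in peaklists.items():
        row = {}
        for key, theo in species_keys.items():
            tol = tol_ppm * 1e-6 * theo
            matches = [p for p in peaks if abs(p.mz - theo) <= tol]
            row[key] = max((p.intensity for p in matches), default=0.0)
        data[sample] = row
    frame = pd.DataFrame.from_dict(data, orient="index", columns=list(species_keys))
    frame.index.name = "sample"
    groups = manifest.loc[frame.index, "group"]
    return AbundanceMatrix(data=frame, groups=groups)
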