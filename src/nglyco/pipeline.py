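"""End-to-end composition of the pipeline stages.

These helpers wire the stages together the way the command-line
interface and the synthetic round-trip tests use them: per-sample
internal-standard normalization (per ionization mode), species discovery
via composition assignment, matrix assembly, group summaries and
modulation classification.
"""

from __future__ import annotations

import logging

import pandas as pd

from .chem import Peak, ion_mz, parse_adduct_label, parse_composition
from .errors import MissingInternalStandard
from .groupstats import ModulationCall, classify_modulation, profile_comparison_counts
from .io import build_abundance_matrix
from .quantify import (
    AbundanceMatrix,
    InternalStandardRef,
    group_summaries,
    locate_internal_standard,
    normalize_intensities,
    screen_outliers,
)
from .search import SearchParams, assign_peaklist
from .simulate import Cohort, SynthConfig, generate_cohort

logger = logging.getLogger("nglyco")

__all__ = [
    "normalize_sample",
    "species_mz_map",
    "quantify_cohort",
    "run_synthetic_pipeline",
]


def normalize_sample(peaks: list[Peak], is_ref: InternalStandardRef | None = None) -> list[Peak]:
    """Internal-standard correction of one sample's peak list, each
    ionization mode scaled to its own standard."""
    is_ref = is_ref or InternalStandardRef()
    corrected: list[Peak] = []
    for mode in ("positive", "negative"):
        mode_peaks = [p for p in peaks if p.mode == mode]
        if not mode_peaks:
            continue
        is_peak = locate_internal_standard(mode_peaks, mode, is_ref)
        corrected.extend(normalize_intensities(mode_peaks, is_peak))
    return corrected


def species_mz_map(keys) -> dict[str, float]:
    """Theoretical ion m/z per species key ('composition adduct-label')."""
    out = {}
    for key in keys:
        comp_str, adduct_str = key.rsplit(" ", 1)
        out[key] = ion_mz(parse_composition(comp_str), parse_adduct_label(adduct_str))
    return out


def quantify_cohort(
    peaklists: dict[str, list[Peak]],
    manifest: pd.DataFrame,
    species_keys: dict[str, float] | None = None,
    params: SearchParams | None = None,
    is_ref: InternalStandardRef | None = None,
    tol_ppm: float = 10.0,
    exclude_outliers: bool = False,
    outlier_alpha: float = 0.05,
) -> tuple[AbundanceMatrix, pd.DataFrame, list[str]]:
    """Normalize, identify and assemble a cohort into an abundance matrix.

    When ``species_keys`` is not given the species are discovered by
    running the composition assignment on every sample's corrected peaks
    (internal-standard peaks excluded) and taking the union of assigned
    keys.  Samples whose internal standard cannot be located are excluded
    with a logged reason and returned in the third element.

    Returns (matrix, outlier_report, excluded_samples).
    """
    is_ref = is_ref or InternalStandardRef()
    corrected: dict[str, list[Peak]] = {}
    excluded: list[str] = []
    for sample, peaks in peaklists.items():
        try:
            corrected[sample] = normalize_sample(peaks, is_ref)
        except MissingInternalStandard as exc:
            logger.warning("sample %s excluded: %s", sample, exc)
            excluded.append(sample)

    def _is_standard(p: Peak) -> bool:
        return abs(p.mz - is_ref.mz_for(p.mode)) <= is_ref.window

    if species_keys is None:
        params = params or SearchParams()
        species_keys = {}
        for sample, peaks in corrected.items():
            assigned, _ = assign_peaklist([p for p in peaks if not _is_standard(p)], params)
            for a in assigned:
                species_keys.setdefault(a.species_key, a.theoretical_mz)
        species_keys = dict(sorted(species_keys.items()))

    analyte_lists = {s: [p for p in peaks if not _is_standard(p)] for s, peaks in corrected.items()}
    kept_manifest = manifest[~manifest["sample"].isin(excluded)] if "sample" in manifest.columns else manifest
    matrix = build_abundance_matrix(analyte_lists, kept_manifest, species_keys, tol_ppm=tol_ppm)
    report, screened = screen_outliers(matrix, alpha=outlier_alpha, exclude=exclude_outliers)
    return (screened if exclude_outliers else matrix), report, excluded


def run_synthetic_pipeline(
    config: SynthConfig,
    significance: str = "markers",
    alpha: float = 0.05,
    discover_species: bool = False,
) -> tuple[Cohort, AbundanceMatrix, pd.DataFrame, list[ModulationCall], dict[str, int]]:
    """Generate a cohort and push it through the full analysis chain.

    ``significance="markers"`` classifies mean-shift categories from the
    generator-declared markers (the synthetic analogue of transcribed
    table markers); ``"recomputed"`` reruns the pooled t-tests instead.
    With ``discover_species`` the species keys are recovered by
    composition assignment rather than taken from the ground truth.
    """
    cohort = generate_cohort(config)
    keys = None if discover_species else species_mz_map(cohort.ground_truth.species["key"])
    matrix, _, _ = quantify_cohort(cohort.peaklists, cohort.manifest, species_keys=keys)
    summaries = group_summaries(matrix)
    markers = cohort.ground_truth.markers() if significance == "markers" else None
    calls = classify_modulation(summaries, significance=significance, alpha=alpha, markers=markers)
    counts = profile_comparison_counts(calls)
    return cohort, matrix, summaries, calls, counts
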