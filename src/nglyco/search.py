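"""Candidate glycan composition enumeration for observed MALDI peaks.

For an observed m/z the search enumerates every (composition, adduct)
pair on a bounded residue-count lattice whose theoretical ion m/z lies
within a relative (ppm) or absolute (Da) tolerance, then prunes
biologically implausible compositions with a deterministic rule set.
The lattice is exhaustively enumerated (no heuristics): at the default
bounds it has 66 000 points, which are pre-tabulated once per parameter
set and queried by binary search.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import numpy as np

from .chem import (
    NEGATIVE_ADDUCTS,
    POSITIVE_ADDUCTS,
    AdductSpec,
    DEFAULT_TABLE,
    GlycanComposition,
    MonosaccharideTable,
    Peak,
    format_composition,
    ion_mz,
    ppm_error,
)
from .errors import ConfigurationError

__all__ = [
    "SearchParams",
    "Assignment",
    "enumerate_candidates",
    "biological_filter",
    "assign_peaklist",
    "RULE_SETS",
]

DEFAULT_BOUNDS = {"Hex": 15, "HexNAc": 10, "Fuc": 4, "Neu5Ac": 4, "Neu5Gc": 4, "Sulfate": 2}


def _default_rules(comp: GlycanComposition, bounds: dict[str, int]) -> tuple[bool, str]:
    """Minimal biological plausibility rules for N-glycan compositions.

    Decorated residues (fucose, sialic acids, sulfate) require a HexNAc
    scaffold, and sialic acids cannot outnumber the available antennae
    (HexNAc + 1).  Counts must stay within the configured bounds.
    """
    counts = comp.counts()
    for residue, n in counts.items():
        if n > bounds[residue]:
            return False, f"{residue} count {n} exceeds bound {bounds[residue]}"
    if comp.neu5ac + comp.neu5gc > 0 and comp.hexnac < 1:
        return False, "sialic acid without HexNAc"
    if comp.fuc > 0 and comp.hexnac < 1:
        return False, "fucose without HexNAc"
    if comp.fuc > comp.hexnac + 1:
        return False, "more fucoses than attachment sites (HexNAc + 1)"
    if comp.neu5ac + comp.neu5gc > comp.hexnac + 1:
        return False, "more sialic acids than antennae (HexNAc + 1)"
    if comp.sulfate > 0 and comp.hexnac < 1:
        return False, "sulfate without HexNAc"
    return True, "ok"


def _no_rules(comp: GlycanComposition, bounds: dict[str, int]) -> tuple[bool, str]:
    return True, "ok"


RULE_SETS: dict[str, Callable[[GlycanComposition, dict[str, int]], tuple[bool, str]]] = {
    "default": _default_rules,
    "none": _no_rules,
}


def biological_filter(comp: GlycanComposition, rules: str = "default", bounds: dict[str, int] | None = None) -> tuple[bool, str]:
    """Evaluate the named plausibility rule set; returns (passes, reason)."""
    if rules not in RULE_SETS:
        raise ConfigurationError(f"unknown rule set {rules!r}; known: {sorted(RULE_SETS)}")
    return RULE_SETS[rules](comp, bounds or DEFAULT_BOUNDS)


@dataclass(frozen=True)
class SearchParams:
    """Parameters of the composition search.

    ``tol_ppm`` is the relative mass window; ``tol_da``, when set,
    overrides it with an absolute window (useful against rounded printed
    masses).  ``bounds`` caps each residue count; ``adducts_positive`` /
    ``adducts_negative`` are the candidate ion species per mode.
    """

    tol_ppm: float = 10.0
    tol_da: float | None = None
    bounds: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_BOUNDS))
    adducts_positive: tuple[AdductSpec, ...] = POSITIVE_ADDUCTS
    adducts_negative: tuple[AdductSpec, ...] = NEGATIVE_ADDUCTS
    rules: str = "default"
    table: MonosaccharideTable = DEFAULT_TABLE

    def __post_init__(self) -> None:
        if self.tol_ppm <= 0:
            raise ConfigurationError("tol_ppm must be positive")
        if self.tol_da is not None and self.tol_da <= 0:
            raise ConfigurationError("tol_da must be positive when given")
        if set(self.bounds) != set(DEFAULT_BOUNDS):
            raise ConfigurationError(f"bounds must cover exactly {sorted(DEFAULT_BOUNDS)}")
        if any(b < 0 for b in self.bounds.values()):
            raise ConfigurationError("bounds must be non-negative")
        if any(a.charge <= 0 for a in self.adducts_positive):
            raise ConfigurationError("positive-mode adducts must carry positive charge")
        if any(a.charge >= 0 for a in self.adducts_negative):
            raise ConfigurationError("negative-mode adducts must carry negative charge")
        if self.rules not in RULE_SETS:
            raise ConfigurationError(f"unknown rule set {self.rules!r}")

    @classmethod
    def instrument_primary(cls, **kwargs) -> "SearchParams":
        """Search restricted to the dominant ion species of NaCl-doped
        MALDI spectra: [M+Na]+ in positive and [M-H]- in negative mode.
        The default (full) adduct sets are needed to cover the rarer
        sodium-exchanged and potassiated table entries; this restriction
        is the right setting when assigning spectra known to be dominated
        by the primary species."""
        kwargs.setdefault("adducts_positive", (AdductSpec(na=1),))
        kwargs.setdefault("adducts_negative", (AdductSpec(h_removed=1),))
        return cls(**kwargs)

    def adducts_for(self, mode: str) -> tuple[AdductSpec, ...]:
        if mode == "positive":
            adducts = self.adducts_positive
        elif mode == "negative":
            adducts = self.adducts_negative
        else:
            raise ConfigurationError(f"mode must be 'positive' or 'negative', got {mode!r}")
        if not adducts:
            raise ConfigurationError(f"no candidate adducts configured for {mode} mode")
        return adducts


@dataclass(frozen=True)
class Assignment:
    """One candidate identification of a peak."""

    peak: Peak
    composition: GlycanComposition
    adduct: AdductSpec
    theoretical_mz: float
    ppm_error: float
    plausible: bool
    reason: str = "ok"

    @property
    def species_key(self) -> str:
        return f"{format_composition(self.composition)} {self.adduct.label()}"


# ---------------------------------------------------------------------------
# Lattice tabulation

_LATTICE_CACHE: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}


def _lattice(params: SearchParams) -> tuple[np.ndarray, np.ndarray]:
    """All residue-count vectors within bounds and their neutral masses,
    sorted by mass.  Cached per (bounds, mass table)."""
    key = (
        tuple(sorted(params.bounds.items())),
        tuple(sorted(params.table.residues.items())),
        params.table.water,
    )
    hit = _LATTICE_CACHE.get(key)
    if hit is not None:
        return hit
    from .chem import RESIDUE_ORDER

    ranges = [np.arange(params.bounds[r] + 1) for r in RESIDUE_ORDER]
    grids = np.meshgrid(*ranges, indexing="ij")
    counts = np.stack([g.ravel() for g in grids], axis=1)
    # require at least one non-sulfate residue
    keep = counts[:, :5].sum(axis=1) > 0
    counts = counts[keep]
    masses = counts @ np.array([params.table.residues[r] for r in RESIDUE_ORDER]) + params.table.water
    order = np.argsort(masses, kind="stable")
    result = (counts[order].astype(np.int64), masses[order])
    _LATTICE_CACHE[key] = result
    return result


def _tolerance_da(mz: float, params: SearchParams) -> float:
    return params.tol_da if params.tol_da is not None else params.tol_ppm * 1e-6 * mz


def enumerate_candidates(mz: float, mode: str, params: SearchParams | None = None) -> list[Assignment]:
    """All (composition, adduct) candidates for an observed m/z.

    Returns assignments ordered by |ppm error|, ties broken by fewer total
    residues then canonical composition string.  Each carries the verdict
    of the configured biological filter; nothing is pre-pruned, so the
    caller can audit implausible matches.
    """
    if mz <= 0:
        raise ConfigurationError(f"observed m/z must be positive, got {mz}")
    params = params or SearchParams()
    counts, masses = _lattice(params)
    table = params.table
    tol = _tolerance_da(mz, params)
    out: list[Assignment] = []
    for adduct in params.adducts_for(mode):
        z = abs(adduct.charge)
        shift = adduct.na * table.sodium + adduct.k * table.potassium
        shift += (adduct.h_added - adduct.h_removed) * table.proton
        # neutral mass window implied by the m/z window
        target = mz * z - shift
        lo = np.searchsorted(masses, target - tol * z, side="left")
        hi = np.searchsorted(masses, target + tol * z, side="right")
        for idx in range(lo, hi):
            comp = GlycanComposition(*(int(c) for c in counts[idx]))
            theo = (masses[idx] + shift) / z
            if abs(mz - theo) > tol:
                continue
            ok, reason = biological_filter(comp, params.rules, params.bounds)
            out.append(
                Assignment(
                    peak=Peak(mz=mz, intensity=0.0, mode=mode),
                    composition=comp,
                    adduct=adduct,
                    theoretical_mz=theo,
                    ppm_error=ppm_error(mz, theo),
                    plausible=ok,
                    reason=reason,
                )
            )
    # Exact isobars exist on this lattice (Hex + Neu5Ac and Fuc + Neu5Gc
    # share an elemental composition) and distinct charge states can
    # coincide to well below instrument accuracy, so the ppm key is
    # quantized to 0.01 ppm and quantized ties are broken by parsimony:
    # fewer residues, then fewer sulfates, Neu5Gc, Fuc, then canonically.
    # All candidates remain in the list; only the order encodes the
    # preference.
    out.sort(
        key=lambda a: (
            round(abs(a.ppm_error), 2),
            a.composition.total_residues,
            a.composition.sulfate,
            a.composition.neu5gc,
            a.composition.fuc,
            format_composition(a.composition),
            a.adduct.label(),
        )
    )
    return out


def assign_peaklist(
    peaks: Iterable[Peak],
    params: SearchParams | None = None,
) -> tuple[list[Assignment], list[Peak]]:
    """Best assignment per peak plus the peaks left unassigned.

    For each peak the candidates are ranked as in
    :func:`enumerate_candidates` and the first one passing the biological
    filter is retained; peaks with no surviving candidate are returned in
    the second list, never dropped silently.
    """
    params = params or SearchParams()
    assigned: list[Assignment] = []
    unassigned: list[Peak] = []
    for peak in peaks:
        winner = None
        for cand in enumerate_candidates(peak.mz, peak.mode, params):
            if cand.plausible:
                winner = replace(cand, peak=peak)
                break
        if winner is None:
            unassigned.append(peak)
        else:
            assigned.append(winner)
    return assigned, unassigned
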