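"""Domain types and the monoisotopic mass calculus for glycan compositions
and MALDI ion species.

A glycan *composition* is a count vector over the monosaccharide residue
classes Hex, HexNAc, Fuc (deoxyhexose), Neu5Ac, Neu5Gc plus a sulfate
class.  Residue masses follow the glycobiology convention: the residue is
the free monosaccharide minus one water, so a neutral glycan of n residues
weighs sum(residues) + one water.  Sulfate is modelled as SO3 attached
without further water loss.

Ion m/z arithmetic uses the proton mass for hydrogen transfers and the
cation masses of Na+ and K+; the electron mass is ignored (error < 0.6 ppm
at m/z 1000, well below the 10 ppm working tolerance).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from types import MappingProxyType
from typing import Iterator, Mapping

from .errors import AdductError, CompositionError, GlycoParseError

__all__ = [
    "RESIDUE_ORDER",
    "MonosaccharideTable",
    "DEFAULT_TABLE",
    "GlycanComposition",
    "AdductSpec",
    "Peak",
    "neutral_monoisotopic_mass",
    "ion_mz",
    "ppm_error",
    "parse_composition",
    "format_composition",
    "parse_adduct_label",
]

#: Canonical rendering order of the residue alphabet.
RESIDUE_ORDER = ("Hex", "HexNAc", "Fuc", "Neu5Ac", "Neu5Gc", "Sulfate")

# Aliases used in printed tables ("NeuAc" for N-acetylneuraminic acid, etc.)
_RESIDUE_ALIASES = {
    "Hex": "Hex",
    "HexNAc": "HexNAc",
    "Fuc": "Fuc",
    "dHex": "Fuc",
    "Neu5Ac": "Neu5Ac",
    "NeuAc": "Neu5Ac",
    "Neu5Gc": "Neu5Gc",
    "NeuGc": "Neu5Gc",
    "Sulfate": "Sulfate",
    "S": "Sulfate",
}


@dataclass(frozen=True)
class MonosaccharideTable:
    """Immutable table of monoisotopic residue masses (Da) plus the ion
    arithmetic constants.

    Residue masses are free monosaccharide minus water, derived from IUPAC
    atomic masses.  ``proton`` is the mass of H+ used for both hydrogen
    removal and protonation; ``sodium`` and ``potassium`` are cation (Na+,
    K+) masses.
    """

    residues: Mapping[str, float] = None  # type: ignore[assignment]
    water: float = 18.0105646837
    proton: float = 1.0072764666
    sodium: float = 22.9892207010
    potassium: float = 38.9631581001

    def __post_init__(self) -> None:
        if self.residues is None:
            # Element-derived residue masses (monosaccharide minus water).
            # Full precision is kept so that the exact elemental degeneracy
            # Hex + Neu5Ac = Fuc + Neu5Gc (both C17H27NO13) holds in the
            # table, not just approximately.
            object.__setattr__(
                self,
                "residues",
                MappingProxyType(
                    {
                        "Hex": 162.0528234187,       # C6H10O5
                        "HexNAc": 203.0793725197,    # C8H13NO5
                        "Fuc": 146.0579087991,       # C6H10O4 (deoxyhexose)
                        "Neu5Ac": 291.0954165068,    # C11H17NO8
                        "Neu5Gc": 307.0903311264,    # C11H17NO9
                        "Sulfate": 79.9568148588,    # SO3
                    }
                ),
            )
        else:
            object.__setattr__(self, "residues", MappingProxyType(dict(self.residues)))
        masses = self.residues
        if set(masses) != set(RESIDUE_ORDER):
            raise CompositionError(f"residue table must cover exactly {RESIDUE_ORDER}")
        if any(m <= 0 for m in masses.values()):
            raise CompositionError("all residue masses must be strictly positive")
        if not (masses["Hex"] < masses["HexNAc"] < masses["Neu5Ac"] < masses["Neu5Gc"]):
            raise CompositionError("residue mass ordering Hex < HexNAc < Neu5Ac < Neu5Gc violated")


DEFAULT_TABLE = MonosaccharideTable()


@dataclass(frozen=True, order=True)
class GlycanComposition:
    """Count vector over the residue alphabet.

    At least one non-sulfate residue count must be positive.  The canonical
    string form lists residues in the order Hex, HexNAc, Fuc, Neu5Ac,
    Neu5Gc, then ``S<count>`` for sulfate, omitting zero-count classes,
    e.g. ``(Hex)3(HexNAc)5(Fuc)1(Neu5Ac)1`` or ``(Hex)3(HexNAc)6S1``.
    """

    hex: int = 0
    hexnac: int = 0
    fuc: int = 0
    neu5ac: int = 0
    neu5gc: int = 0
    sulfate: int = 0

    _FIELDS = ("hex", "hexnac", "fuc", "neu5ac", "neu5gc", "sulfate")

    def __post_init__(self) -> None:
        for name in self._FIELDS:
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise CompositionError(f"residue count {name}={v!r} must be a non-negative integer")
        if self.total_residues - self.sulfate <= 0:
            raise CompositionError("composition needs at least one non-sulfate residue")

    @property
    def total_residues(self) -> int:
        return self.hex + self.hexnac + self.fuc + self.neu5ac + self.neu5gc + self.sulfate

    def counts(self) -> dict[str, int]:
        """Counts keyed by canonical residue-class name."""
        return dict(zip(RESIDUE_ORDER, (self.hex, self.hexnac, self.fuc, self.neu5ac, self.neu5gc, self.sulfate)))

    def __add__(self, other: "GlycanComposition") -> "GlycanComposition":
        return GlycanComposition(
            self.hex + other.hex,
            self.hexnac + other.hexnac,
            self.fuc + other.fuc,
            self.neu5ac + other.neu5ac,
            self.neu5gc + other.neu5gc,
            self.sulfate + other.sulfate,
        )

    def __str__(self) -> str:
        return format_composition(self)


@dataclass(frozen=True)
class AdductSpec:
    """Charge-carrier bookkeeping for a MALDI ion species.

    ``h_removed`` hydrogens are abstracted as H+ (s), ``h_added`` protons
    (r), ``na`` sodium (p) and ``k`` potassium (q) cations are attached;
    the net charge z = r + p + q - s must be nonzero with |z| in {1, 2}.
    Covers the label grammar seen in MALDI glycomics tables, e.g.
    ``[M+Na]+``, ``[M-2H]2-``, ``[M-3H+2Na]-``.
    """

    h_removed: int = 0
    h_added: int = 0
    na: int = 0
    k: int = 0

    def __post_init__(self) -> None:
        for name in ("h_removed", "h_added", "na", "k"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise AdductError(f"{name}={v!r} must be a non-negative integer")
        z = self.charge
        if z == 0:
            raise AdductError("adduct net charge must be nonzero")
        if abs(z) not in (1, 2):
            raise AdductError(f"|charge| must be 1 or 2, got {z}")

    @property
    def charge(self) -> int:
        return self.h_added + self.na + self.k - self.h_removed

    @property
    def polarity(self) -> str:
        return "positive" if self.charge > 0 else "negative"

    def label(self) -> str:
        parts = []
        if self.h_removed:
            parts.append(f"-{self.h_removed if self.h_removed > 1 else ''}H")
        if self.h_added:
            parts.append(f"+{self.h_added if self.h_added > 1 else ''}H")
        if self.na:
            parts.append(f"+{self.na if self.na > 1 else ''}Na")
        if self.k:
            parts.append(f"+{self.k if self.k > 1 else ''}K")
        z = self.charge
        mag = str(abs(z)) if abs(z) > 1 else ""
        sign = "+" if z > 0 else "-"
        return f"[M{''.join(parts)}]{mag}{sign}"

    def __str__(self) -> str:
        return self.label()


# Common adduct sets per ionization mode (sodiated spectra with NaCl dopant
# in positive mode; deprotonated / sodium-exchanged species in negative).
POSITIVE_ADDUCTS = (
    AdductSpec(h_added=1),
    AdductSpec(na=1),
    AdductSpec(k=1),
    AdductSpec(na=2),
)
NEGATIVE_ADDUCTS = (
    AdductSpec(h_removed=1),
    AdductSpec(h_removed=2),
    AdductSpec(h_removed=2, na=1),
    AdductSpec(h_removed=3, na=2),
    AdductSpec(h_removed=4, na=2),
)


@dataclass(frozen=True)
class Peak:
    """One centroided MALDI peak: m/z, intensity and ionization mode."""

    mz: float
    intensity: float
    mode: str

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise GlycoParseError(f"peak m/z must be positive, got {self.mz}")
        if self.intensity < 0:
            raise GlycoParseError(f"peak intensity must be >= 0, got {self.intensity}")
        if self.mode not in ("positive", "negative"):
            raise GlycoParseError(f"mode must be 'positive' or 'negative', got {self.mode!r}")


def neutral_monoisotopic_mass(comp: GlycanComposition, table: MonosaccharideTable = DEFAULT_TABLE) -> float:
    """Neutral monoisotopic mass in Da: sum of residue masses plus one water."""
    counts = comp.counts()
    return sum(counts[r] * table.residues[r] for r in RESIDUE_ORDER) + table.water


def ion_mz(
    comp: GlycanComposition,
    adduct: AdductSpec,
    table: MonosaccharideTable = DEFAULT_TABLE,
) -> float:
    """Theoretical m/z of the ion species ``adduct`` of ``comp``.

    m/z = (M + p*m(Na+) + q*m(K+) + r*m(H+) - s*m(H+)) / |z|.
    """
    m = neutral_monoisotopic_mass(comp, table)
    m += adduct.na * table.sodium + adduct.k * table.potassium
    m += (adduct.h_added - adduct.h_removed) * table.proton
    return m / abs(adduct.charge)


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass error in parts per million."""
    if theoretical <= 0:
        raise GlycoParseError(f"theoretical m/z must be positive, got {theoretical}")
    return 1e6 * (observed - theoretical) / theoretical


_COMP_TOKEN = re.compile(r"\(([A-Za-z0-9]+)\)(\d+)|([A-Za-z]+)(\d+)|\s+")


def _iter_composition_tokens(text: str) -> Iterator[tuple[str, int]]:
    pos = 0
    while pos < len(text):
        m = _COMP_TOKEN.match(text, pos)
        if m is None:
            raise GlycoParseError(f"malformed composition near {text[pos:pos + 12]!r}")
        pos = m.end()
        if m.group(1) is not None:
            yield m.group(1), int(m.group(2))
        elif m.group(3) is not None:
            # bare suffix form, e.g. the sulfate token "S1"
            yield m.group(3), int(m.group(4))


def parse_composition(text: str) -> GlycanComposition:
    """Parse a composition string like ``(Hex)3(HexNAc)5(Fuc)1(Neu5Ac)1``.

    Residues may appear in any order; ``S<n>`` denotes sulfate; the table
    aliases NeuAc/NeuGc are accepted.  Zero counts, duplicate residues and
    unknown tokens are rejected with an error naming the token.
    """
    if not isinstance(text, str) or not text.strip():
        raise GlycoParseError("empty composition string")
    counts: dict[str, int] = {}
    for token, n in _iter_composition_tokens(text.strip()):
        residue = _RESIDUE_ALIASES.get(token)
        if residue is None:
            raise GlycoParseError(f"unknown residue token {token!r}")
        if n <= 0:
            raise GlycoParseError(f"zero-count token ({token}){n} not allowed")
        if residue in counts:
            raise GlycoParseError(f"duplicate residue token {token!r}")
        counts[residue] = n
    if not counts:
        raise GlycoParseError(f"no residue tokens in {text!r}")
    return GlycanComposition(
        hex=counts.get("Hex", 0),
        hexnac=counts.get("HexNAc", 0),
        fuc=counts.get("Fuc", 0),
        neu5ac=counts.get("Neu5Ac", 0),
        neu5gc=counts.get("Neu5Gc", 0),
        sulfate=counts.get("Sulfate", 0),
    )


def format_composition(comp: GlycanComposition) -> str:
    """Canonical string form (fixed residue order, sulfate as S<n>)."""
    parts = []
    for residue, count in comp.counts().items():
        if count == 0:
            continue
        if residue == "Sulfate":
            parts.append(f"S{count}")
        else:
            parts.append(f"({residue}){count}")
    return "".join(parts)


_ADDUCT_RE = re.compile(r"^\[M((?:[+\-−]\d*(?:H|Na|K))*)\](\d*)([+\-−])$")
_ADDUCT_PART = re.compile(r"([+\-−])(\d*)(H|Na|K)")


def parse_adduct_label(text: str) -> AdductSpec:
    """Parse an adduct label such as ``[M-2H+Na]-`` into an :class:`AdductSpec`.

    The unicode minus is accepted alongside ASCII ``-``; the trailing charge
    magnitude and sign must be consistent with the charge carriers.
    """
    if not isinstance(text, str):
        raise GlycoParseError("adduct label must be a string")
    cleaned = text.strip().replace("^", "")
    m = _ADDUCT_RE.match(cleaned)
    if m is None:
        raise GlycoParseError(f"unrecognized adduct label {text!r}")
    body, mag, sign = m.groups()
    s = r = p = q = 0
    consumed = 0
    for part in _ADDUCT_PART.finditer(body):
        consumed += len(part.group(0))
        op, count_s, elem = part.groups()
        count = int(count_s) if count_s else 1
        if op in ("-", "−"):
            if elem != "H":
                raise GlycoParseError(f"cannot remove {elem} in {text!r}")
            s += count
        elif elem == "H":
            r += count
        elif elem == "Na":
            p += count
        else:
            q += count
    if consumed != len(body):
        raise GlycoParseError(f"unrecognized adduct label {text!r}")
    try:
        spec = AdductSpec(h_removed=s, h_added=r, na=p, k=q)
    except AdductError as exc:
        raise GlycoParseError(f"invalid adduct {text!r}: {exc}") from exc
    z = spec.charge
    stated = (int(mag) if mag else 1) * (1 if sign == "+" else -1)
    if stated != z:
        raise GlycoParseError(f"stated charge {stated:+d} inconsistent with carriers (net {z:+d}) in {text!r}")
    return spec
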