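"""Elemental mass arithmetic, ribonucleotide/modification registry and RNA
sequence mass computation for negative ion mode.

All masses are monoisotopic daltons.  The central analyte representation is
:class:`NASequence`: an ordered list of canonical residues plus per-position
modifications and explicit 5'/3' terminus chemistry.  Mass bookkeeping uses
the proton mass for charge states and the neutron mass for isotopologue
offsets; the two are deliberately distinct constants.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from math import isclose
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

__all__ = [
    "ChemicalFormula",
    "Ribonucleotide",
    "Modification",
    "TerminusChemistry",
    "NASequence",
    "ModificationRegistry",
    "PROTON_MASS",
    "NEUTRON_MASS",
    "C13_C12_DELTA",
    "WATER",
    "METAPHOSPHATE",
    "formula_mass",
    "sequence_mass",
    "sequence_formula",
    "mz_from_mass",
    "mass_from_mz",
    "adduct_mass_shift",
    "parse_sequence",
    "default_registry",
    "RIBONUCLEOTIDES",
]

# Monoisotopic atomic masses (CODATA / AME2020, most abundant isotope).
ELEMENT_MASSES: Dict[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
    "Se": 73.92247640,
    "Na": 22.98976928,
    "K": 38.96370649,
}

PROTON_MASS = 1.007276466879  # mass of H+; charge bookkeeping
NEUTRON_MASS = 1.008664916    # isotopologue precursor offsets
C13_C12_DELTA = 1.0033548378  # peak spacing inside an isotope envelope


class ChemistryError(ValueError):
    """Raised for unknown elements, bad formulas or invalid placements."""


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(-?\d*)")


@dataclass(frozen=True)
class ChemicalFormula:
    """An elemental composition; negative counts express difference formulas.

    Supports ``+``, ``-`` and integer ``*``.  Zero-count elements are dropped
    so that equality and hashing behave as expected.
    """

    element_counts: Tuple[Tuple[str, int], ...] = ()

    def __post_init__(self):
        counts: Dict[str, int] = {}
        for sym, n in self.element_counts:
            if sym not in ELEMENT_MASSES:
                raise ChemistryError(f"unknown element symbol: {sym!r}")
            counts[sym] = counts.get(sym, 0) + n
        cleaned = tuple(sorted((s, n) for s, n in counts.items() if n != 0))
        object.__setattr__(self, "element_counts", cleaned)

    @classmethod
    def parse(cls, text: str) -> "ChemicalFormula":
        """Parse e.g. ``"C9H13N3O5"`` or a difference such as ``"CH-1N-1O1"``."""
        text = text.strip()
        if not text:
            return cls()
        pos = 0
        counts: List[Tuple[str, int]] = []
        while pos < len(text):
            m = _FORMULA_TOKEN.match(text, pos)
            if not m or not m.group(1):
                raise ChemistryError(f"cannot parse formula {text!r} at offset {pos}")
            sym, num = m.group(1), m.group(2)
            counts.append((sym, int(num) if num not in ("", "-") else 1))
            pos = m.end()
        return cls(tuple(counts))

    def as_dict(self) -> Dict[str, int]:
        return dict(self.element_counts)

    def __add__(self, other: "ChemicalFormula") -> "ChemicalFormula":
        return ChemicalFormula(self.element_counts + other.element_counts)

    def __sub__(self, other: "ChemicalFormula") -> "ChemicalFormula":
        return ChemicalFormula(
            self.element_counts + tuple((s, -n) for s, n in other.element_counts)
        )

    def __mul__(self, k: int) -> "ChemicalFormula":
        return ChemicalFormula(tuple((s, n * k) for s, n in self.element_counts))

    __rmul__ = __mul__

    @property
    def mass(self) -> float:
        return sum(ELEMENT_MASSES[s] * n for s, n in self.element_counts)

    def __str__(self) -> str:
        # Hill-ish order: C, H, then alphabetical.
        d = self.as_dict()
        order = ["C", "H"] + sorted(k for k in d if k not in ("C", "H"))
        return "".join(f"{s}{d[s]}" for s in order if s in d) or "(empty)"


def formula_mass(formula: ChemicalFormula) -> float:
    """Monoisotopic mass of a formula in Da (linear in element counts)."""
    return formula.mass


WATER = ChemicalFormula.parse("H2O")
METAPHOSPHATE = ChemicalFormula.parse("HPO3")


@dataclass(frozen=True)
class Ribonucleotide:
    """A canonical ribonucleotide building block."""

    code: str
    nucleoside_formula: ChemicalFormula
    base_formula: ChemicalFormula  # neutral base BH
    origin_base: Optional[str] = None

    @property
    def residue_formula(self) -> ChemicalFormula:
        """Internal phosphodiester residue: nucleoside + HPO3 - H2O."""
        return self.nucleoside_formula + METAPHOSPHATE - WATER


RIBONUCLEOTIDES: Dict[str, Ribonucleotide] = {
    "A": Ribonucleotide("A", ChemicalFormula.parse("C10H13N5O4"),
                        ChemicalFormula.parse("C5H5N5"), "A"),
    "C": Ribonucleotide("C", ChemicalFormula.parse("C9H13N3O5"),
                        ChemicalFormula.parse("C4H5N3O"), "C"),
    "G": Ribonucleotide("G", ChemicalFormula.parse("C10H13N5O5"),
                        ChemicalFormula.parse("C5H5N5O"), "G"),
    "U": Ribonucleotide("U", ChemicalFormula.parse("C9H12N2O6"),
                        ChemicalFormula.parse("C4H4N2O2"), "U"),
}


@dataclass(frozen=True)
class Modification:
    """A mass-shift class applied to a residue.

    ``placement`` records whether the shift sits on the base, the sugar, or
    could be on either (search codes ending in ``?``).  Base-placed shifts are
    lost together with the nucleobase in a-B fragments; sugar-placed shifts
    are retained there.
    """

    search_code: str
    name: str
    mass_shift_formula: ChemicalFormula
    placement: str  # "base" | "sugar" | "either"
    target_bases: frozenset
    isobaric_set: Tuple[str, ...] = ()

    def __post_init__(self):
        if self.placement not in ("base", "sugar", "either"):
            raise ChemistryError(f"bad placement {self.placement!r}")
        if (self.placement == "either") != self.search_code.endswith("?"):
            raise ChemistryError(
                f"placement 'either' must pair with a '?' search code: "
                f"{self.search_code!r}"
            )
        m = self.mass_shift_formula.mass
        if not (-200.0 < m < 500.0):
            raise ChemistryError(f"implausible mass shift {m:.4f} for {self.search_code}")


class ModificationRegistry:
    """Lookup of :class:`Modification` by search code, loadable from TSV."""

    def __init__(self, mods: Iterable[Modification] = ()):
        self._mods: Dict[str, Modification] = {}
        for m in mods:
            self.add(m)

    def add(self, mod: Modification) -> None:
        self._mods[mod.search_code] = mod

    def __getitem__(self, code: str) -> Modification:
        try:
            return self._mods[code]
        except KeyError:
            raise ChemistryError(f"unknown modification code: {code!r}") from None

    def __contains__(self, code: str) -> bool:
        return code in self._mods

    def __iter__(self):
        return iter(self._mods.values())

    def __len__(self) -> int:
        return len(self._mods)

    def codes(self) -> List[str]:
        return list(self._mods)

    @classmethod
    def from_tsv(cls, path_or_file) -> "ModificationRegistry":
        """Load a registry from a tab-separated table.

        Columns: search_code, name, shift_formula, placement, target_bases
        (comma separated), isobaric_set (comma separated, may be empty).
        """
        if hasattr(path_or_file, "read"):
            lines = path_or_file.read().splitlines()
        else:
            with open(path_or_file, "rt", encoding="utf-8") as fh:
                lines = fh.read().splitlines()
        reg = cls()
        for lineno, line in enumerate(lines, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 5:
                raise ChemistryError(f"registry line {lineno}: expected >=5 columns")
            code, name, formula, placement, targets = parts[:5]
            isobaric = tuple(p for p in parts[5].split(",") if p) if len(parts) > 5 else ()
            reg.add(Modification(
                search_code=code,
                name=name,
                mass_shift_formula=ChemicalFormula.parse(formula),
                placement=placement,
                target_bases=frozenset(targets.split(",")),
                isobaric_set=isobaric,
            ))
        return reg


def default_registry() -> ModificationRegistry:
    """The registry shipped with the package (curated MODOMICS-derived subset)."""
    ref = resources.files("oligoms.data").joinpath("modifications.tsv")
    with ref.open("rt", encoding="utf-8") as fh:
        return ModificationRegistry.from_tsv(fh)


_FIVE_PRIME = ("hydroxyl", "phosphate")
_THREE_PRIME = ("hydroxyl", "phosphate", "cyclic_phosphate")


@dataclass(frozen=True)
class TerminusChemistry:
    five_prime: str = "hydroxyl"
    three_prime: str = "hydroxyl"

    def __post_init__(self):
        if self.five_prime not in _FIVE_PRIME:
            raise ChemistryError(f"bad 5' terminus {self.five_prime!r}")
        if self.three_prime not in _THREE_PRIME:
            raise ChemistryError(f"bad 3' terminus {self.three_prime!r}")


@dataclass(frozen=True)
class NASequence:
    """An RNA (oligo)nucleotide with modifications and terminus chemistry.

    ``modifications`` maps 1-based position to ``(Modification, placement)``
    where placement is resolved to ``"base"`` or ``"sugar"``.
    """

    residues: Tuple[str, ...]
    modifications: Tuple[Tuple[int, Modification, str], ...] = ()
    termini: TerminusChemistry = field(default_factory=TerminusChemistry)

    def __post_init__(self):
        if len(self.residues) < 1:
            raise ChemistryError("empty sequence")
        seen = set()
        for pos, mod, placement in self.modifications:
            if not (1 <= pos <= len(self.residues)):
                raise ChemistryError(f"modification position {pos} out of range")
            if pos in seen:
                raise ChemistryError(f"position {pos} carries more than one modification")
            seen.add(pos)
            if placement not in ("base", "sugar"):
                raise ChemistryError(f"unresolved placement {placement!r} at {pos}")
            res = self.residues[pos - 1]
            if res not in mod.target_bases:
                raise ChemistryError(
                    f"modification {mod.search_code} not applicable to {res} at {pos}"
                )
        for r in self.residues:
            if r not in RIBONUCLEOTIDES:
                raise ChemistryError(f"unknown residue code {r!r}")
        object.__setattr__(self, "modifications",
                           tuple(sorted(self.modifications)))

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def modification_map(self) -> Dict[int, Tuple[Modification, str]]:
        return {pos: (mod, pl) for pos, mod, pl in self.modifications}

    def n_modifications(self) -> int:
        return len(self.modifications)

    def to_string(self, show_placement: bool = False) -> str:
        """Render bracketed notation, e.g. ``UAAC[m5C]CAAUGp``.

        With ``show_placement`` an either-mod resolved to the sugar is
        rendered as ``[code|sugar]`` so that placement isomers have distinct
        strings.
        """
        mods = self.modification_map
        out = []
        for i, r in enumerate(self.residues, 1):
            if i in mods:
                mod, placement = mods[i]
                tag = mod.search_code
                if show_placement and mod.placement == "either":
                    tag = f"{tag}|{placement}"
                out.append(f"[{tag}]")
            else:
                out.append(r)
        prefix = "p" if self.termini.five_prime == "phosphate" else ""
        if self.termini.three_prime == "phosphate":
            suffix = "p"
        elif self.termini.three_prime == "cyclic_phosphate":
            suffix = ">p"
        else:
            suffix = ""
        return prefix + "".join(out) + suffix

    def __str__(self) -> str:
        return self.to_string()

    def subsequence(self, start: int, end: int,
                    termini: TerminusChemistry) -> "NASequence":
        """1-based inclusive slice with explicit new terminus chemistry."""
        if not (1 <= start <= end <= len(self)):
            raise ChemistryError(f"bad subsequence bounds {start}..{end}")
        mods = tuple((pos - start + 1, mod, pl)
                     for pos, mod, pl in self.modifications
                     if start <= pos <= end)
        return NASequence(self.residues[start - 1:end], mods, termini)


def sequence_formula(seq: NASequence) -> ChemicalFormula:
    """Neutral molecular formula of a sequence, termini and mods included."""
    n = len(seq)
    total = ChemicalFormula()
    for r in seq.residues:
        total = total + RIBONUCLEOTIDES[r].nucleoside_formula
    total = total + (n - 1) * (METAPHOSPHATE - WATER)
    if seq.termini.five_prime == "phosphate":
        total = total + METAPHOSPHATE
    if seq.termini.three_prime == "phosphate":
        total = total + METAPHOSPHATE
    elif seq.termini.three_prime == "cyclic_phosphate":
        total = total + METAPHOSPHATE - WATER
    for _, mod, _ in seq.modifications:
        total = total + mod.mass_shift_formula
    return total


def sequence_mass(seq: NASequence) -> float:
    """Neutral monoisotopic mass of a sequence in Da."""
    return sequence_formula(seq).mass


def mz_from_mass(neutral_mass: float, charge: int) -> float:
    """m/z of a deprotonated species at negative integer charge."""
    if charge >= 0:
        raise ChemistryError("negative-mode engine: charge must be <= -1")
    z = -charge
    return (neutral_mass - z * PROTON_MASS) / z


def mass_from_mz(mz: float, charge: int) -> float:
    """Neutral mass from observed m/z at a negative charge (inverse of above)."""
    if charge >= 0:
        raise ChemistryError("negative-mode engine: charge must be <= -1")
    z = -charge
    return mz * z + z * PROTON_MASS


def adduct_mass_shift(adduct_formula: ChemicalFormula, cation_charge: int) -> float:
    """Neutral mass shift of a salt adduct: cations replace backbone protons.

    ``adduct_formula`` holds the cation composition (e.g. Na1, Na1K1) and
    ``cation_charge`` the total positive charge carried by those cations.
    """
    counts = adduct_formula.as_dict()
    if not counts or any(n <= 0 for n in counts.values()):
        raise ChemistryError("adduct must contain a positive number of cations")
    unsupported = set(counts) - {"Na", "K"}
    if unsupported:
        raise ChemistryError(f"unsupported adduct cations: {sorted(unsupported)}")
    if cation_charge <= 0:
        raise ChemistryError("cation charge must be positive")
    return adduct_formula.mass - cation_charge * ELEMENT_MASSES["H"]


# -- sequence notation parsing ------------------------------------------------

_SEQ_TOKEN = re.compile(r"([ACGUT])|\[([^\]\[]+)\]")


def parse_sequence(text: str,
                   registry: Optional[ModificationRegistry] = None,
                   termini: Optional[TerminusChemistry] = None) -> NASequence:
    """Parse bracketed notation like ``"UAAC[m5C]CAAUGp"``.

    A bracketed registry code stands for one modified residue (its canonical
    origin is the modification's target base), so ``AUG[m5C]C`` carries m5C
    at position 4.  A trailing lowercase ``p`` marks a 3'-phosphate, trailing
    ``>p`` a 2',3'-cyclic phosphate, and a leading ``p`` a 5'-phosphate.  An
    explicit ``termini`` argument overrides the notation.  ``T`` is
    transliterated to ``U``.  Either-placement codes accept a
    ``|base``/``|sugar`` suffix inside the brackets; without one the base
    placement is assumed.
    """
    if registry is None:
        registry = default_registry()
    text = text.strip()
    five = "hydroxyl"
    three = "hydroxyl"
    if text.startswith("p"):
        five = "phosphate"
        text = text[1:]
    if text.endswith(">p"):
        three = "cyclic_phosphate"
        text = text[:-2]
    elif text.endswith("p"):
        three = "phosphate"
        text = text[:-1]
    if termini is not None:
        five, three = termini.five_prime, termini.three_prime

    residues: List[str] = []
    mods: List[Tuple[int, Modification, str]] = []
    pos = 0
    while pos < len(text):
        m = _SEQ_TOKEN.match(text, pos)
        if not m:
            raise ChemistryError(f"cannot parse sequence {text!r} at offset {pos}")
        if m.group(1):
            res = m.group(1)
            if res == "T":
                res = "U"
            residues.append(res)
        else:
            tag = m.group(2)
            placement = None
            if "|" in tag:
                tag, placement = tag.split("|", 1)
            mod = registry[tag]
            if len(mod.target_bases) != 1:
                raise ChemistryError(
                    f"cannot infer origin residue for [{tag}]: ambiguous targets")
            residues.append(next(iter(mod.target_bases)))
            if placement is None:
                placement = "base" if mod.placement in ("base", "either") else "sugar"
            mods.append((len(residues), mod, placement))
        pos = m.end()
    return NASequence(tuple(residues), tuple(mods),
                      TerminusChemistry(five, three))
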