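"""Theoretical fragment generation for the nine RNA backbone ion series.

Offset conventions (normative for this package; shared by common
oligonucleotide calculators):

* ``c_i``: the 5' subsequence of ``i`` residues carrying the parent 5'
  terminus and an intact 3'-phosphate; ``d = c + H2O``; ``b = c - HPO3``;
  ``a = b - H2O``; ``a-B_i = a_i`` minus the neutral nucleobase of residue
  ``i`` (including a base-placed modification shift, excluding sugar-placed).
* ``w_j``: the 3' subsequence of ``j`` residues carrying the parent 3'
  terminus and a 5'-phosphate; ``x = w - H2O``; ``y = w - HPO3``;
  ``z = y - H2O``.

These satisfy ``c_i + y_{n-i} = M + H2O`` and ``d_i + z_{n-i} = M + H2O``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

from .chem_core import (
    METAPHOSPHATE,
    RIBONUCLEOTIDES,
    WATER,
    ChemistryError,
    NASequence,
    mz_from_mass,
)

__all__ = [
    "ION_TYPES",
    "FIVE_PRIME_IONS",
    "THREE_PRIME_IONS",
    "TheoreticalFragment",
    "fragment_neutral_mass",
    "generate_theoretical_spectrum",
]

FIVE_PRIME_IONS = ("a-B", "a", "b", "c", "d")
THREE_PRIME_IONS = ("w", "x", "y", "z")
ION_TYPES = FIVE_PRIME_IONS + THREE_PRIME_IONS

_H2O = WATER.mass
_HPO3 = METAPHOSPHATE.mass

# neutral-mass offsets relative to the c (5' series) / w (3' series) anchors
_FIVE_OFFSETS = {"c": 0.0, "d": _H2O, "b": -_HPO3, "a": -_HPO3 - _H2O,
                 "a-B": -_HPO3 - _H2O}
_THREE_OFFSETS = {"w": 0.0, "x": -_H2O, "y": -_HPO3, "z": -_HPO3 - _H2O}


@dataclass(frozen=True)
class TheoreticalFragment:
    ion_type: str
    index: int          # cleavage position, 1..n-1, counted from the ion's end
    charge: int         # negative
    neutral_mass: float
    mz: float


def _anchor_masses(seq: NASequence) -> Tuple[List[float], List[float]]:
    """(c_i for i=1..n-1, w_j for j=1..n-1) plus per-position base masses."""
    n = len(seq)
    modmap = seq.modification_map
    nuc = [RIBONUCLEOTIDES[r].nucleoside_formula.mass for r in seq.residues]
    modshift = [0.0] * n
    for pos, (mod, _pl) in modmap.items():
        modshift[pos - 1] = mod.mass_shift_formula.mass

    link = _HPO3 - _H2O
    five_adj = _HPO3 if seq.termini.five_prime == "phosphate" else 0.0
    if seq.termini.three_prime == "phosphate":
        three_adj = _HPO3
    elif seq.termini.three_prime == "cyclic_phosphate":
        three_adj = _HPO3 - _H2O
    else:
        three_adj = 0.0

    c = []
    acc = five_adj
    for i in range(n - 1):
        acc += nuc[i] + modshift[i] + (link if i > 0 else 0.0)
        c.append(acc + _HPO3)
    w = []
    acc = three_adj
    for j in range(n - 1):
        idx = n - 1 - j
        acc += nuc[idx] + modshift[idx] + (link if j > 0 else 0.0)
        w.append(acc + _HPO3)
    return c, w


def _ab_base_loss(seq: NASequence, index: int) -> float:
    """Neutral base mass lost from the a ion at cleavage index (1-based)."""
    res = seq.residues[index - 1]
    loss = RIBONUCLEOTIDES[res].base_formula.mass
    entry = seq.modification_map.get(index)
    if entry is not None:
        mod, placement = entry
        if placement == "base":
            loss += mod.mass_shift_formula.mass
    return loss


def fragment_neutral_mass(seq: NASequence, ion_type: str, index: int) -> float:
    """Neutral monoisotopic mass of one backbone fragment."""
    n = len(seq)
    if not (1 <= index <= n - 1):
        raise ChemistryError(f"fragment index {index} out of range for n={n}")
    if ion_type in _FIVE_OFFSETS:
        c, _ = _anchor_masses(seq)
        mass = c[index - 1] + _FIVE_OFFSETS[ion_type]
        if ion_type == "a-B":
            mass -= _ab_base_loss(seq, index)
        return mass
    if ion_type in _THREE_OFFSETS:
        _, w = _anchor_masses(seq)
        return w[index - 1] + _THREE_OFFSETS[ion_type]
    raise ChemistryError(f"unknown ion type {ion_type!r}")


def generate_theoretical_spectrum(seq: NASequence,
                                  ion_types: Sequence[str] = ION_TYPES,
                                  charges: Iterable[int] = (-1,),
                                  ) -> List[TheoreticalFragment]:
    """One fragment per (ion type, cleavage index, charge), sorted by m/z."""
    if not ion_types:
        raise ChemistryError("empty ion type set")
    for t in ion_types:
        if t not in ION_TYPES:
            raise ChemistryError(f"unknown ion type {t!r}")
    charges = list(charges)
    if any(z >= 0 for z in charges):
        raise ChemistryError("fragment charges must be negative")
    n = len(seq)
    c, w = _anchor_masses(seq)
    frags: List[TheoreticalFragment] = []
    for i in range(1, n):
        for t in ion_types:
            if t in _FIVE_OFFSETS:
                mass = c[i - 1] + _FIVE_OFFSETS[t]
                if t == "a-B":
                    mass -= _ab_base_loss(seq, i)
            else:
                mass = w[i - 1] + _THREE_OFFSETS[t]
            if mass <= 0:
                continue
            for z in charges:
                frags.append(TheoreticalFragment(t, i, z, mass,
                                                 mz_from_mass(mass, z)))
    frags.sort(key=lambda f: f.mz)
    return frags
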