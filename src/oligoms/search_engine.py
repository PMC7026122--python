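"""Precursor-indexed candidate lookup with salt-adduct and isotopologue
correction, fragment peak matching and hyperscore ranking.

The experimental neutral mass of a spectrum at charge ``-z`` is
``M_exp = z*mz + z*m_proton``.  For every configured adduct ``a`` (plus "no
adduct") and isotopologue offset ``k``, ``M_test = M_exp - k*m_neutron -
shift(a)`` is compared against candidate masses within a ppm tolerance.
Matches are scored with a hyperscore variant: ``ln(1 + sum of matched
intensities) + ln(Nf!) + ln(Nr!)`` over matched 5'-series (a-B/a/b/c/d) and
3'-series (w/x/y/z) fragment counts.
"""

from __future__ import annotations

import math
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import yaml

from .chem_core import (
    NEUTRON_MASS,
    PROTON_MASS,
    ChemicalFormula,
    Modification,
    ModificationRegistry,
    adduct_mass_shift,
    default_registry,
)
from .fragmentation import (
    FIVE_PRIME_IONS,
    ION_TYPES,
    TheoreticalFragment,
    generate_theoretical_spectrum,
)
from .sequence_db import FastaRecord, ModifiedCandidate, build_candidates
from .spectrum_io import MS2Spectrum, deisotope, filter_peaks

__all__ = [
    "Adduct",
    "SearchConfig",
    "MassIndex",
    "OligoSpectrumMatch",
    "parse_adduct",
    "find_candidates",
    "match_peaks",
    "hyperscore",
    "search_run",
]


@dataclass(frozen=True)
class Adduct:
    """A salt adduct: cations replacing backbone protons."""

    name: str
    formula: ChemicalFormula
    charge: int  # total positive charge of the cations

    @property
    def mass_shift(self) -> float:
        return adduct_mass_shift(self.formula, self.charge)


def parse_adduct(name: str) -> Adduct:
    """Parse compact adduct names like ``"Na"``, ``"K2"`` or ``"NaK2"``.

    All supported cations are monovalent, so the total charge equals the
    cation count.
    """
    formula = ChemicalFormula.parse(name.strip().rstrip("+"))
    counts = formula.as_dict()
    charge = sum(counts.values())
    return Adduct(name, formula, charge)


@dataclass
class SearchConfig:
    """Search parameters; field names mirror the standard parameter table."""

    precursor_tol_ppm: float = 3.0
    fragment_tol_ppm: float = 3.0
    ion_types: Tuple[str, ...] = ION_TYPES
    adducts: Tuple[str, ...] = ()
    isotope_offsets: Tuple[int, int] = (0, 0)        # k_min, k_max
    variable_mods: Tuple[str, ...] = ()
    fixed_mods: Tuple[str, ...] = ()
    max_mods_per_oligo: int = 0
    digestion: str = "rnase_t1"                      # rnase_t1|unspecific|none
    missed_cleavages: int = 0
    min_length: int = 3
    max_length: int = 40
    top_hits_per_spectrum: int = 1
    precursor_charges: Tuple[int, ...] = (-2, -3, -4, -5, -6, -7)
    fragment_charge_cap: int = 4
    intensity_normalization: str = "raw"             # raw|base_peak
    intensity_filter_threshold: float = 0.0
    deisotope_spectra: bool = True
    cleave_modified_g: bool = True

    def __post_init__(self):
        if self.precursor_tol_ppm <= 0 or self.fragment_tol_ppm <= 0:
            raise ValueError("tolerances must be > 0")
        k_min, k_max = self.isotope_offsets
        if k_min > k_max:
            raise ValueError("isotope offset range inverted")
        if any(z >= 0 for z in self.precursor_charges):
            raise ValueError("precursor charges must be negative")

    @classmethod
    def from_yaml(cls, path) -> "SearchConfig":
        with open(path, "rt", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("ion_types", "adducts", "variable_mods", "fixed_mods",
                    "precursor_charges", "isotope_offsets"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)

    def adduct_objects(self) -> List[Adduct]:
        return [parse_adduct(a) for a in self.adducts]

    def resolve_mods(self, registry: ModificationRegistry
                     ) -> Tuple[List[Modification], List[Modification]]:
        return ([registry[c] for c in self.variable_mods],
                [registry[c] for c in self.fixed_mods])


class MassIndex:
    """Candidates sorted by neutral mass with exact ppm range queries."""

    def __init__(self, candidates: Sequence[ModifiedCandidate]):
        if not candidates:
            raise ValueError("empty candidate database")
        self.candidates = sorted(candidates, key=lambda c: c.neutral_mass)
        self.masses = np.array([c.neutral_mass for c in self.candidates])

    def __len__(self) -> int:
        return len(self.candidates)

    def query(self, mass: float, tol_ppm: float) -> List[ModifiedCandidate]:
        """All candidates with |mass - M_cand| <= tol_ppm * 1e-6 * M_cand."""
        rel = tol_ppm * 1e-6
        lo = np.searchsorted(self.masses, mass / (1.0 + rel), side="left")
        hi = np.searchsorted(self.masses, mass / (1.0 - rel), side="right")
        return [c for c in self.candidates[lo:hi]
                if abs(mass - c.neutral_mass) <= rel * c.neutral_mass]


@dataclass
class OligoSpectrumMatch:
    """One scored pairing of a spectrum and a candidate oligonucleotide."""

    spectrum_id: str
    candidate: ModifiedCandidate
    hyperscore: float
    matched_counts: Dict[str, int]
    adduct: Optional[str]
    isotope_offset: int
    precursor_error_ppm: float
    precursor_charge: int
    retention_time: float = 0.0
    rank: int = 1
    is_decoy: bool = False
    localization_ambiguous: bool = False
    q_value: Optional[float] = None

    @property
    def sequence_string(self) -> str:
        return self.candidate.sequence.to_string(show_placement=True)

    @property
    def n_matched(self) -> int:
        return sum(self.matched_counts.values())


def find_candidates(spectrum: MS2Spectrum, index: MassIndex,
                    config: SearchConfig,
                    charge: Optional[int] = None,
                    ) -> List[Tuple[ModifiedCandidate, Optional[Adduct], int, float]]:
    """(candidate, adduct, k, precursor_error_ppm) tuples for one spectrum."""
    z = charge if charge is not None else spectrum.precursor_charge
    if z >= 0:
        raise ValueError("precursor charge must be negative (or supplied)")
    zabs = -z
    m_exp = zabs * spectrum.precursor_mz + zabs * PROTON_MASS
    k_min, k_max = config.isotope_offsets
    adducts: List[Optional[Adduct]] = [None] + config.adduct_objects()
    out = []
    for adduct in adducts:
        shift = adduct.mass_shift if adduct is not None else 0.0
        for k in range(k_min, k_max + 1):
            m_test = m_exp - k * NEUTRON_MASS - shift
            for cand in index.query(m_test, config.precursor_tol_ppm):
                err = (m_test - cand.neutral_mass) / cand.neutral_mass * 1e6
                out.append((cand, adduct, k, err))
    return out


def match_peaks(spectrum: MS2Spectrum,
                fragments: Sequence[TheoreticalFragment],
                fragment_tol_ppm: float,
                ) -> List[Tuple[int, TheoreticalFragment]]:
    """Pair experimental peaks with theoretical fragments.

    Each peak pairs with at most one fragment: the nearest unmatched one
    within tolerance, ties resolved toward the lower-m/z fragment.  Each
    fragment is used at most once.
    """
    frag_mz = [f.mz for f in fragments]  # fragments arrive sorted by mz
    used = [False] * len(fragments)
    pairs: List[Tuple[int, TheoreticalFragment]] = []
    for pi, mz in enumerate(spectrum.mz):
        tol = mz * fragment_tol_ppm * 1e-6
        lo = bisect_left(frag_mz, mz - tol)
        hi = bisect_right(frag_mz, mz + tol)
        best = None
        best_dist = None
        for fi in range(lo, hi):
            if used[fi]:
                continue
            dist = abs(frag_mz[fi] - mz)
            if best is None or dist < best_dist - 1e-12:
                best, best_dist = fi, dist
        if best is not None:
            used[best] = True
            pairs.append((pi, fragments[best]))
    return pairs


def hyperscore(matched: Iterable[Tuple[float, str]]) -> float:
    """``ln(1 + sum intensities) + ln(Nf!) + ln(Nr!)``; 0.0 for no matches.

    ``matched`` yields (peak intensity, ion type) pairs.  Factorials are
    evaluated through the log-gamma function, so large counts are safe.
    """
    total = 0.0
    n_f = 0
    n_r = 0
    for inten, ion_type in matched:
        total += inten
        if ion_type in FIVE_PRIME_IONS:
            n_f += 1
        else:
            n_r += 1
    if n_f + n_r == 0:
        return 0.0
    return (math.log1p(total) + math.lgamma(n_f + 1) + math.lgamma(n_r + 1))


def _preprocess(spectrum: MS2Spectrum, config: SearchConfig) -> MS2Spectrum:
    spec = spectrum
    if config.intensity_filter_threshold > 0:
        spec = filter_peaks(spec, "relative_threshold",
                            config.intensity_filter_threshold)
    if config.deisotope_spectra:
        spec = deisotope(spec, config.fragment_tol_ppm,
                         max_charge=config.fragment_charge_cap)
    if config.intensity_normalization == "base_peak" and len(spec):
        base = spec.intensity.max()
        if base > 0:
            spec = type(spec)(native_id=spec.native_id, ms_level=spec.ms_level,
                              retention_time=spec.retention_time,
                              precursor_mz=spec.precursor_mz,
                              precursor_charge=spec.precursor_charge,
                              mz=spec.mz, intensity=spec.intensity / base,
                              peak_charges=spec.peak_charges,
                              polarity=spec.polarity)
    return spec


def _plain_key(cand: ModifiedCandidate) -> Tuple[str, Tuple[str, ...]]:
    """Residue string + termini + multiset of mod codes, placement ignored."""
    seq = cand.sequence
    mods = tuple(sorted(m.search_code for _, m, _ in seq.modifications))
    return ("".join(seq.residues) + "/" + seq.termini.five_prime + "/"
            + seq.termini.three_prime, mods)


def _score_spectrum(spectrum: MS2Spectrum, index: MassIndex,
                    config: SearchConfig,
                    theo_cache: Dict[Tuple[str, int], List[TheoreticalFragment]],
                    ) -> List[OligoSpectrumMatch]:
    charges = ([spectrum.precursor_charge] if spectrum.precursor_charge < 0
               else list(config.precursor_charges))
    spec = _preprocess(spectrum, config)
    scored: Dict[str, OligoSpectrumMatch] = {}
    for z in charges:
        max_frag_z = max(1, min(config.fragment_charge_cap, -z - 1))
        frag_charges = tuple(range(-1, -max_frag_z - 1, -1))
        for cand, adduct, k, err in find_candidates(spectrum, index, config, z):
            ckey = (cand.key, max_frag_z)
            theo = theo_cache.get(ckey)
            if theo is None:
                theo = generate_theoretical_spectrum(
                    cand.sequence, config.ion_types, frag_charges)
                theo_cache[ckey] = theo
            pairs = match_peaks(spec, theo, config.fragment_tol_ppm)
            score = hyperscore((spec.intensity[pi], frag.ion_type)
                               for pi, frag in pairs)
            if score <= 0.0:
                continue
            counts: Dict[str, int] = {}
            for _, frag in pairs:
                counts[frag.ion_type] = counts.get(frag.ion_type, 0) + 1
            osm = OligoSpectrumMatch(
                spectrum_id=spectrum.native_id,
                candidate=cand,
                hyperscore=score,
                matched_counts=counts,
                adduct=adduct.name if adduct is not None else None,
                isotope_offset=k,
                precursor_error_ppm=err,
                precursor_charge=z,
                retention_time=spectrum.retention_time,
                is_decoy=cand.is_decoy,
            )
            prev = scored.get(cand.key)
            if prev is None or _annotation_rank(osm) < _annotation_rank(prev):
                scored[cand.key] = osm
    osms = sorted(scored.values(),
                  key=lambda o: (-o.hyperscore,
                                 o.candidate.sequence.n_modifications(),
                                 o.sequence_string))
    if not osms:
        return []
    top = osms[0]
    tied = [o for o in osms
            if abs(o.hyperscore - top.hyperscore) < 1e-9
            and _plain_key(o.candidate) == _plain_key(top.candidate)
            and o.sequence_string != top.sequence_string]
    if tied:
        top.localization_ambiguous = True
    for rank, osm in enumerate(osms, 1):
        osm.rank = rank
    return osms[:config.top_hits_per_spectrum]


def _annotation_rank(osm: OligoSpectrumMatch) -> Tuple:
    """Prefer higher score; then simpler annotation and smaller mass error."""
    n_cations = 0
    if osm.adduct:
        n_cations = sum(parse_adduct(osm.adduct).formula.as_dict().values())
    return (-osm.hyperscore, n_cations, abs(osm.isotope_offset),
            abs(osm.precursor_error_ppm))


def search_run(spectra: Sequence[MS2Spectrum],
               database: Sequence[FastaRecord] | Sequence[ModifiedCandidate],
               config: SearchConfig,
               registry: Optional[ModificationRegistry] = None,
               log: Optional[dict] = None,
               ) -> List[OligoSpectrumMatch]:
    """Score all MS2 spectra against a sequence database.

    ``database`` is either a list of FASTA records (digested and
    modification-enumerated here according to ``config``) or a prebuilt
    candidate list.  Results are deterministic and independent across
    spectra.
    """
    if registry is None:
        registry = default_registry()
    if not database:
        raise ValueError("empty sequence database")
    if isinstance(database[0], FastaRecord):
        var_mods, fixed_mods = config.resolve_mods(registry)
        candidates = build_candidates(
            database, var_mods, fixed_mods, config.max_mods_per_oligo,
            digestion=config.digestion, registry=registry,
            missed_cleavages=config.missed_cleavages,
            min_length=config.min_length, max_length=config.max_length,
            cleave_modified_g=config.cleave_modified_g)
    else:
        candidates = list(database)
    if not candidates:
        raise ValueError("digestion/enumeration produced no candidates")
    index = MassIndex(candidates)
    theo_cache: Dict[Tuple[str, int], List[TheoreticalFragment]] = {}
    results: List[OligoSpectrumMatch] = []
    n_searched = n_matched = n_skipped = 0
    for spectrum in sorted((s for s in spectra if s.ms_level == 2),
                           key=lambda s: s.native_id):
        if spectrum.precursor_mz <= 0:
            n_skipped += 1
            continue
        n_searched += 1
        osms = _score_spectrum(spectrum, index, config, theo_cache)
        if osms:
            n_matched += 1
            results.extend(osms)
    if log is not None:
        log.update(spectra_searched=n_searched, spectra_matched=n_matched,
                   spectra_skipped=n_skipped, candidates=len(candidates))
    return results
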