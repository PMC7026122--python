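"""Synthetic-run generation: mzML-compatible MS2 (and MS1) spectra with
ground truth, so that search, FDR estimation and quantification can be
tested without any external data."""

from __future__ import annotations

import csv
import math
import random
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .chem_core import NEUTRON_MASS, mz_from_mass
from .fragmentation import ION_TYPES, generate_theoretical_spectrum
from .search_engine import Adduct, parse_adduct
from .sequence_db import ModifiedCandidate
from .spectrum_io import MS2Spectrum

__all__ = [
    "SimulationConfig",
    "GroundTruthRecord",
    "simulate_spectrum",
    "simulate_run",
    "make_calibration_benchmark",
    "simulate_ms1_map",
    "write_truth_tsv",
    "read_truth_tsv",
]


@dataclass
class SimulationConfig:
    """Knobs for synthetic MS2 runs; the seed is mandatory."""

    seed: int
    n_spectra: int = 100
    charges: Tuple[int, ...] = (-2, -3, -4)
    adduct_fractions: Mapping[str, float] = field(default_factory=dict)
    isotope_offset_probs: Mapping[int, float] = field(
        default_factory=lambda: {0: 1.0})
    fragment_dropout: float = 0.0
    noise_peaks: int = 0
    scan_range: Tuple[float, float] = (600.0, 3500.0)
    fragment_mz_range: Tuple[float, float] = (250.0, 3500.0)
    intensity_log_mu: float = 9.2      # fragment intensities ~ lognormal
    intensity_log_sigma: float = 0.5
    noise_intensity_scale: float = 50.0
    fragment_charge_cap: int = 4
    ion_types: Tuple[str, ...] = ION_TYPES

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        if not (0.0 <= self.fragment_dropout < 1.0):
            raise ValueError("fragment_dropout must be in [0, 1)")
        total_adduct = sum(self.adduct_fractions.values())
        if total_adduct > 1.0 + 1e-9:
            raise ValueError("adduct fractions sum to more than 1")
        for p in self.adduct_fractions.values():
            if not (0.0 <= p <= 1.0):
                raise ValueError("adduct fractions must be probabilities")


@dataclass(frozen=True)
class GroundTruthRecord:
    spectrum_id: str
    sequence: str          # with resolved mod placements
    charge: int
    adduct: str            # "" = none
    isotope_offset: int
    identifiable: bool = True


def _draw_categorical(rng: random.Random, probs: Mapping, default):
    r = rng.random()
    acc = 0.0
    for key, p in probs.items():
        acc += p
        if r < acc:
            return key
    return default


def simulate_spectrum(candidate: ModifiedCandidate, charge: int,
                      adduct: Optional[Adduct], k: int,
                      config: SimulationConfig, rng: random.Random,
                      native_id: str = "scan=1",
                      retention_time: float = 0.0) -> MS2Spectrum:
    """Build one MS2 spectrum from a candidate's theoretical fragments.

    Fragments are subject to independent dropout; uniform noise peaks are
    added across the fragment m/z range.  The precursor m/z reflects the
    adduct shift and the isotopologue offset ``k``.
    """
    max_frag_z = max(1, min(config.fragment_charge_cap, -charge - 1))
    frag_charges = tuple(range(-1, -max_frag_z - 1, -1))
    theo = generate_theoretical_spectrum(candidate.sequence, config.ion_types,
                                         frag_charges)
    mzs: List[float] = []
    intens: List[float] = []
    for frag in theo:
        if config.fragment_dropout > 0 and rng.random() < config.fragment_dropout:
            continue
        mzs.append(frag.mz)
        intens.append(math.exp(rng.gauss(config.intensity_log_mu,
                                         config.intensity_log_sigma)))
    if not mzs and theo:  # keep at least one fragment so the spectrum scores
        frag = theo[rng.randrange(len(theo))]
        mzs.append(frag.mz)
        intens.append(math.exp(rng.gauss(config.intensity_log_mu,
                                         config.intensity_log_sigma)))
    lo, hi = config.fragment_mz_range
    for _ in range(config.noise_peaks):
        mzs.append(rng.uniform(lo, hi))
        intens.append(rng.expovariate(1.0) * config.noise_intensity_scale)

    shift = adduct.mass_shift if adduct is not None else 0.0
    precursor_mass = candidate.neutral_mass + shift + k * NEUTRON_MASS
    return MS2Spectrum(
        native_id=native_id,
        ms_level=2,
        retention_time=retention_time,
        precursor_mz=mz_from_mass(precursor_mass, charge),
        precursor_charge=charge,
        mz=np.array(mzs),
        intensity=np.array(intens),
        polarity="negative",
    )


def _viable_charges(candidate: ModifiedCandidate, charges: Sequence[int],
                    scan_range: Tuple[float, float]) -> List[int]:
    lo, hi = scan_range
    ok = [z for z in charges
          if lo <= mz_from_mass(candidate.neutral_mass, z) <= hi]
    return ok or list(charges)


def simulate_run(candidates: Sequence[ModifiedCandidate],
                 config: SimulationConfig,
                 ) -> Tuple[List[MS2Spectrum], List[GroundTruthRecord]]:
    """Sample ``n_spectra`` spectra from the candidate pool with ground truth."""
    if not candidates:
        raise ValueError("no candidates to simulate from")
    rng = random.Random(config.seed)
    adducts = {name: parse_adduct(name) for name in config.adduct_fractions}
    spectra: List[MS2Spectrum] = []
    truth: List[GroundTruthRecord] = []
    for i in range(config.n_spectra):
        cand = candidates[rng.randrange(len(candidates))]
        charge = rng.choice(_viable_charges(cand, config.charges,
                                            config.scan_range))
        adduct_name = _draw_categorical(rng, config.adduct_fractions, "")
        adduct = adducts.get(adduct_name)
        k = _draw_categorical(rng, config.isotope_offset_probs, 0)
        native_id = f"scan={i + 1}"
        rt = 60.0 + 2.0 * i
        spectra.append(simulate_spectrum(cand, charge, adduct, k, config, rng,
                                         native_id=native_id,
                                         retention_time=rt))
        truth.append(GroundTruthRecord(native_id,
                                       cand.sequence.to_string(show_placement=True),
                                       charge, adduct_name or "", k))
    return spectra, truth


def make_calibration_benchmark(db_candidates: Sequence[ModifiedCandidate],
                               config: SimulationConfig,
                               foreign_fraction: float,
                               foreign_noise_peaks: int = 200,
                               ) -> Tuple[List[MS2Spectrum], List[GroundTruthRecord]]:
    """A run where a fraction of spectra is unidentifiable by construction.

    Unidentifiable spectra carry pure noise peak lists but precursor masses
    drawn from the searched candidate pool (targets and decoys alike), so
    they reach the scoring stage and exercise the FDR machinery.
    """
    if not (0.0 <= foreign_fraction <= 1.0):
        raise ValueError("foreign_fraction must be in [0, 1]")
    rng = random.Random(config.seed)
    targets_only = [c for c in db_candidates if not c.is_decoy]
    if not targets_only:
        raise ValueError("candidate pool contains no targets")
    adducts = {name: parse_adduct(name) for name in config.adduct_fractions}
    spectra: List[MS2Spectrum] = []
    truth: List[GroundTruthRecord] = []
    lo, hi = config.fragment_mz_range
    for i in range(config.n_spectra):
        native_id = f"scan={i + 1}"
        rt = 60.0 + 2.0 * i
        if rng.random() < foreign_fraction:
            # noise-only spectrum at a plausible precursor coordinate
            cand = db_candidates[rng.randrange(len(db_candidates))]
            charge = rng.choice(_viable_charges(cand, config.charges,
                                                config.scan_range))
            n_noise = foreign_noise_peaks
            mzs = [rng.uniform(lo, hi) for _ in range(n_noise)]
            intens = [rng.expovariate(1.0) * config.noise_intensity_scale
                      for _ in range(n_noise)]
            spectra.append(MS2Spectrum(
                native_id=native_id, ms_level=2, retention_time=rt,
                precursor_mz=mz_from_mass(cand.neutral_mass, charge),
                precursor_charge=charge,
                mz=np.array(mzs), intensity=np.array(intens),
                polarity="negative"))
            truth.append(GroundTruthRecord(native_id, "", charge, "", 0,
                                           identifiable=False))
        else:
            cand = targets_only[rng.randrange(len(targets_only))]
            charge = rng.choice(_viable_charges(cand, config.charges,
                                                config.scan_range))
            adduct_name = _draw_categorical(rng, config.adduct_fractions, "")
            k = _draw_categorical(rng, config.isotope_offset_probs, 0)
            spectra.append(simulate_spectrum(
                cand, charge, adducts.get(adduct_name), k, config, rng,
                native_id=native_id, retention_time=rt))
            truth.append(GroundTruthRecord(
                native_id, cand.sequence.to_string(show_placement=True),
                charge, adduct_name or "", k, identifiable=True))
    return spectra, truth


def simulate_ms1_map(profiles: Sequence[Tuple[float, float, float, float]],
                     rt_start: float = 0.0, rt_end: float = 600.0,
                     scan_interval: float = 2.0,
                     scan_range: Tuple[float, float] = (600.0, 3500.0),
                     ) -> List[MS2Spectrum]:
    """Rectangular elution profiles -> a list of MS1 scans.

    Each profile is ``(mz, rt_center, rt_width, total_intensity)``: the total
    intensity is spread uniformly over the scans falling inside
    ``rt_center +/- rt_width/2``.
    """
    rts = np.arange(rt_start, rt_end, scan_interval)
    in_window = [np.abs(rts - rt_center) <= rt_width / 2.0
                 for _, rt_center, rt_width, _ in profiles]
    n_scans = [max(1, int(mask.sum())) for mask in in_window]
    scans: List[MS2Spectrum] = []
    for si, rt in enumerate(rts):
        mzs: List[float] = []
        intens: List[float] = []
        for pi, (mz, rt_center, rt_width, total) in enumerate(profiles):
            if not (scan_range[0] <= mz <= scan_range[1]):
                continue
            if in_window[pi][si]:
                mzs.append(mz)
                intens.append(total / n_scans[pi])
        scans.append(MS2Spectrum(
            native_id=f"ms1_scan={si + 1}", ms_level=1, retention_time=float(rt),
            mz=np.array(mzs), intensity=np.array(intens), polarity="negative"))
    return scans


def write_truth_tsv(truth: Sequence[GroundTruthRecord], path) -> None:
    with open(path, "wt", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["spectrum_id", "sequence", "charge", "adduct",
                    "isotope_offset", "identifiable"])
        for rec in truth:
            w.writerow([rec.spectrum_id, rec.sequence, rec.charge, rec.adduct,
                        rec.isotope_offset, int(rec.identifiable)])


def read_truth_tsv(path) -> List[GroundTruthRecord]:
    out = []
    with open(path, "rt", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            out.append(GroundTruthRecord(
                row["spectrum_id"], row["sequence"], int(row["charge"]),
                row["adduct"], int(row["isotope_offset"]),
                bool(int(row["identifiable"]))))
    return out
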