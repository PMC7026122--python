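"""Export of label-free quantification targets from identifications and a
simplified targeted XIC quantifier with charge/adduct aggregation."""

from __future__ import annotations

import statistics
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .chem_core import (
    C13_C12_DELTA,
    ChemicalFormula,
    mz_from_mass,
    sequence_formula,
)
from .search_engine import OligoSpectrumMatch, parse_adduct
from .spectrum_io import MS2Spectrum

__all__ = [
    "QuantTarget",
    "FeatureIntensity",
    "export_quant_targets",
    "xic_quantify",
    "aggregate_intensities",
]


@dataclass(frozen=True)
class QuantTarget:
    """Target coordinates for one (oligo, charge, adduct) variant."""

    sequence: str
    sum_formula: str
    neutral_mass: float
    charge: int            # negative
    adduct: Optional[str]
    median_rt: float
    mz: float


@dataclass
class FeatureIntensity:
    target: QuantTarget
    intensity: float
    rt_window: Tuple[float, float]
    replicate: str = ""


def export_quant_targets(osms: Sequence[OligoSpectrumMatch]
                         ) -> List[QuantTarget]:
    """One target per distinct (oligo, charge, adduct) observed, with the
    median retention time over its supporting matches."""
    groups: Dict[Tuple[str, int, Optional[str]], List[OligoSpectrumMatch]] = \
        defaultdict(list)
    for osm in osms:
        groups[(osm.sequence_string, osm.precursor_charge, osm.adduct)].append(osm)
    targets = []
    for (seq_str, charge, adduct), members in sorted(
            groups.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2] or "")):
        formula = sequence_formula(members[0].candidate.sequence)
        neutral = formula.mass
        shift = parse_adduct(adduct).mass_shift if adduct else 0.0
        targets.append(QuantTarget(
            sequence=seq_str,
            sum_formula=str(formula),
            neutral_mass=neutral,
            charge=charge,
            adduct=adduct,
            median_rt=statistics.median(o.retention_time for o in members),
            mz=mz_from_mass(neutral + shift, charge),
        ))
    return targets


def xic_quantify(ms1_spectra: Sequence[MS2Spectrum],
                 targets: Sequence[QuantTarget],
                 mz_tol_ppm: float = 10.0,
                 rt_window_s: float = 60.0,
                 n_isotopologues: int = 3,
                 replicate: str = "") -> List[FeatureIntensity]:
    """Windowed XIC integration around each target coordinate.

    The intensity is the sum of MS1 peak intensities within the ppm tolerance
    of the monoisotopic target m/z and its first ``n_isotopologues - 1``
    isotopologue m/z values, over retention times within ``median_rt +/-
    rt_window_s``.  Zero when no signal is present.
    """
    ms1 = [s for s in ms1_spectra if s.ms_level == 1]
    rts = np.array([s.retention_time for s in ms1])
    order = np.argsort(rts)
    ms1 = [ms1[i] for i in order]
    rts = rts[order]
    features = []
    for target in targets:
        lo_rt = target.median_rt - rt_window_s
        hi_rt = target.median_rt + rt_window_s
        i0, i1 = np.searchsorted(rts, [lo_rt, hi_rt])
        zabs = -target.charge
        iso_mzs = [target.mz + j * C13_C12_DELTA / zabs
                   for j in range(n_isotopologues)]
        total = 0.0
        for spec in ms1[i0:i1]:
            for iso_mz in iso_mzs:
                tol = iso_mz * mz_tol_ppm * 1e-6
                a, b = np.searchsorted(spec.mz, [iso_mz - tol, iso_mz + tol])
                if b > a:
                    total += float(spec.intensity[a:b].sum())
        features.append(FeatureIntensity(target, total, (lo_rt, hi_rt),
                                         replicate))
    return features


def aggregate_intensities(features: Sequence[FeatureIntensity]
                          ) -> Dict[str, dict]:
    """Per-oligo summary across charge/adduct variants and replicates.

    Returns, per oligonucleotide sequence: the summed intensity per
    replicate over all variants, and the single (charge, adduct) variant
    with the lowest coefficient of variation across replicates, flagged
    ``best``.
    """
    per_oligo: Dict[str, Dict[Tuple[int, Optional[str]],
                              Dict[str, float]]] = defaultdict(
        lambda: defaultdict(lambda: defaultdict(float)))
    for f in features:
        per_oligo[f.target.sequence][(f.target.charge, f.target.adduct)][
            f.replicate] += f.intensity

    out: Dict[str, dict] = {}
    for seq, variants in per_oligo.items():
        summed: Dict[str, float] = defaultdict(float)
        for variant, reps in variants.items():
            for rep, val in reps.items():
                summed[rep] += val
        best_variant = None
        best_cv = None
        for variant, reps in sorted(variants.items(),
                                    key=lambda kv: (kv[0][0], kv[0][1] or "")):
            vals = list(reps.values())
            mean = statistics.fmean(vals)
            if mean <= 0:
                continue
            sd = statistics.pstdev(vals) if len(vals) > 1 else 0.0
            cv = sd / mean
            if best_cv is None or cv < best_cv:
                best_cv, best_variant = cv, variant
        out[seq] = {
            "summed_by_replicate": dict(summed),
            "total": sum(summed.values()),
            "best_variant": best_variant,
            "best_cv": best_cv,
            "variants": {v: dict(reps) for v, reps in variants.items()},
        }
    return out
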