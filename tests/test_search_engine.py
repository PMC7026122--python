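import math
import random

import numpy as np
import pytest

from oligoms.chem_core import (
    NEUTRON_MASS,
    PROTON_MASS,
    mz_from_mass,
    parse_sequence,
    sequence_mass,
)
from oligoms.fragmentation import TheoreticalFragment, generate_theoretical_spectrum
from oligoms.search_engine import (
    MassIndex,
    SearchConfig,
    find_candidates,
    hyperscore,
    match_peaks,
    parse_adduct,
    search_run,
)
from oligoms.sequence_db import (
    DigestProduct,
    FastaRecord,
    ModifiedCandidate,
    build_candidates,
)
from oligoms.simulate import SimulationConfig, simulate_run, simulate_spectrum
from oligoms.spectrum_io import MS2Spectrum

from .conftest import random_fasta_records


def make_candidate(text, is_decoy=False):
    seq = parse_sequence(text)
    product = DigestProduct("p", 1, len(seq), seq, 0)
    return ModifiedCandidate(product, seq, sequence_mass(seq), is_decoy,
                             (("p", 1, len(seq)),))


def spectrum_for_mass(m_exp, charge=-2, mz_peaks=(500.0,), intensities=None,
                      native_id="scan=1"):
    if intensities is None:
        intensities = [1.0] * len(mz_peaks)
    zabs = -charge
    return MS2Spectrum(native_id=native_id, ms_level=2,
                       precursor_mz=(m_exp - zabs * PROTON_MASS) / zabs,
                       precursor_charge=charge,
                       mz=np.asarray(mz_peaks, float),
                       intensity=np.asarray(intensities, float),
                       polarity="negative")


class TestMassIndex:
    def test_query_equals_brute_force(self, rng):
        cands = [make_candidate("".join(rng.choice("ACGU") for _ in range(6)))
                 for _ in range(80)]
        index = MassIndex(cands)
        for _ in range(50):
            mass = rng.uniform(1500, 2500)
            tol = rng.choice([3.0, 10.0, 100.0])
            got = set(id(c) for c in index.query(mass, tol))
            want = set(id(c) for c in cands
                       if abs(mass - c.neutral_mass) <= tol * 1e-6 * c.neutral_mass)
            assert got == want

    def test_empty_database_rejected(self):
        with pytest.raises(ValueError):
            MassIndex([])


class TestFindCandidates:
    def test_isotope_offset_match(self):
        cand = make_candidate("ACGU")
        cand = ModifiedCandidate(cand.product, cand.sequence, 3000.0,
                                 False, cand.locations)
        index = MassIndex([cand])
        cfg = SearchConfig(isotope_offsets=(0, 4))
        spec = spectrum_for_mass(3000.0 + NEUTRON_MASS)
        hits = find_candidates(spec, index, cfg)
        assert [(h[2]) for h in hits] == [1]

    def test_sodium_adduct_match(self):
        cand = make_candidate("ACGU")
        cand = ModifiedCandidate(cand.product, cand.sequence, 3000.0,
                                 False, cand.locations)
        index = MassIndex([cand])
        cfg = SearchConfig(adducts=("Na",), isotope_offsets=(0, 0))
        spec = spectrum_for_mass(3000.0 + 21.981944)
        hits = find_candidates(spec, index, cfg)
        assert len(hits) == 1
        _, adduct, k, err = hits[0]
        assert adduct.name == "Na" and k == 0
        assert abs(err) < 0.1

    def test_tolerance_bound(self):
        cand = make_candidate("ACGU")
        m = cand.neutral_mass
        index = MassIndex([cand])
        cfg = SearchConfig(precursor_tol_ppm=3.0, isotope_offsets=(0, 0))
        spec = spectrum_for_mass(m * (1 + 5e-6))
        assert find_candidates(spec, index, cfg) == []
        spec = spectrum_for_mass(m * (1 + 2e-6))
        assert len(find_candidates(spec, index, cfg)) == 1


class TestMatchPeaks:
    def frag(self, mz, ion_type="y"):
        return TheoreticalFragment(ion_type, 1, -1, mz + PROTON_MASS, mz)

    def test_within_tolerance(self):
        frags = [self.frag(500.000)]
        spec = spectrum_for_mass(3000, mz_peaks=[500.0005])
        pairs = match_peaks(spec, frags, 3.0)
        assert len(pairs) == 1

    def test_outside_tolerance(self):
        frags = [self.frag(500.000)]
        spec = spectrum_for_mass(3000, mz_peaks=[500.005])
        assert match_peaks(spec, frags, 3.0) == []

    def test_tie_breaks_to_lower_mz(self):
        frags = sorted([self.frag(500.0000), self.frag(500.0008)],
                       key=lambda f: f.mz)
        spec = spectrum_for_mass(3000, mz_peaks=[500.0004])
        pairs = match_peaks(spec, frags, 3.0)
        assert len(pairs) == 1
        assert pairs[0][1].mz == 500.0000

    def test_each_fragment_used_once(self):
        frags = [self.frag(500.0)]
        spec = spectrum_for_mass(3000, mz_peaks=[499.9995, 500.0005])
        pairs = match_peaks(spec, frags, 3.0)
        assert len(pairs) == 1


class TestHyperscore:
    def test_closed_form_example(self):
        matched = ([(1.0, t) for t in ("a", "b", "c", "d", "a-B")]
                   + [(1.0, t) for t in ("w", "x", "y", "z")] + [(1.0, "w")])
        expected = math.log(11) + 2 * math.log(math.factorial(5))
        assert hyperscore(matched) == pytest.approx(expected, abs=1e-4)
        assert expected == pytest.approx(11.9729, abs=1e-4)

    def test_empty_is_zero(self):
        assert hyperscore([]) == 0.0

    def test_order_invariant(self, rng):
        matched = [(rng.random(), rng.choice(["a", "y", "w", "c"]))
                   for _ in range(20)]
        shuffled = matched[:]
        rng.shuffle(shuffled)
        assert hyperscore(matched) == pytest.approx(hyperscore(shuffled))

    def test_removing_match_never_increases(self, rng):
        matched = [(rng.random(), rng.choice(["a", "b", "y", "w"]))
                   for _ in range(15)]
        full = hyperscore(matched)
        for i in range(len(matched)):
            reduced = matched[:i] + matched[i + 1:]
            assert hyperscore(reduced) <= full + 1e-12


class TestSearchRun:
    @pytest.fixture()
    def db_and_candidates(self):
        records = random_fasta_records(4, 200, seed=3)
        cfg = SearchConfig(variable_mods=("m5C",), max_mods_per_oligo=1,
                           missed_cleavages=1)
        return records, cfg

    def test_noise_free_self_consistency(self, db_and_candidates, registry):
        records, cfg = db_and_candidates
        var, fixed = cfg.resolve_mods(registry)
        cands = build_candidates(records, var, fixed, 1, registry=registry,
                                 missed_cleavages=1, min_length=3)
        sim = SimulationConfig(seed=9, n_spectra=25)
        spectra, truth = simulate_run(cands, sim)
        osms = search_run(spectra, records, cfg, registry=registry)
        tmap = {t.spectrum_id: t for t in truth}
        rank1 = [o for o in osms if o.rank == 1]
        assert len(rank1) == 25
        for o in rank1:
            assert o.sequence_string == tmap[o.spectrum_id].sequence
            assert o.hyperscore > 0
            assert o.isotope_offset == tmap[o.spectrum_id].isotope_offset
            assert (o.adduct or "") == tmap[o.spectrum_id].adduct
            assert abs(o.precursor_error_ppm) <= cfg.precursor_tol_ppm

    def test_determinism_under_spectrum_shuffle(self, db_and_candidates,
                                                registry, rng):
        records, cfg = db_and_candidates
        var, fixed = cfg.resolve_mods(registry)
        cands = build_candidates(records, var, fixed, 1, registry=registry,
                                 missed_cleavages=1, min_length=3)
        sim = SimulationConfig(seed=4, n_spectra=10)
        spectra, _ = simulate_run(cands, sim)
        osms1 = search_run(spectra, records, cfg, registry=registry)
        shuffled = spectra[:]
        rng.shuffle(shuffled)
        osms2 = search_run(shuffled, records, cfg, registry=registry)
        key = lambda o: (o.spectrum_id, o.rank, o.sequence_string,
                         round(o.hyperscore, 9))
        assert sorted(map(key, osms1)) == sorted(map(key, osms2))

    def test_localization_ambiguity_flag(self, registry):
        # candidate with an either-mod at an internal position; spectrum
        # contains every fragment except the discriminating a-B ion
        records = [FastaRecord("x", "", "AACAAGU")]
        cfg = SearchConfig(variable_mods=("mC?",), max_mods_per_oligo=1,
                           deisotope_spectra=False)
        var, fixed = cfg.resolve_mods(registry)
        cands = build_candidates(records, var, fixed, 1, registry=registry,
                                 min_length=3)
        target = next(c for c in cands
                      if c.key == "AA[mC?|base]AAGp")
        frags = generate_theoretical_spectrum(target.sequence,
                                              charges=(-1,))
        keep = [f for f in frags if not (f.ion_type == "a-B" and f.index == 3)]
        spec = MS2Spectrum(native_id="scan=1", ms_level=2,
                           precursor_mz=mz_from_mass(target.neutral_mass, -2),
                           precursor_charge=-2,
                           mz=np.array([f.mz for f in keep]),
                           intensity=np.ones(len(keep)),
                           polarity="negative")
        osms = search_run([spec], records, cfg, registry=registry)
        assert osms[0].rank == 1
        assert osms[0].localization_ambiguous

    def test_localization_unambiguous_with_ab_ion(self, registry):
        records = [FastaRecord("x", "", "AACAAGU")]
        cfg = SearchConfig(variable_mods=("mC?",), max_mods_per_oligo=1,
                           deisotope_spectra=False)
        var, fixed = cfg.resolve_mods(registry)
        cands = build_candidates(records, var, fixed, 1, registry=registry,
                                 min_length=3)
        target = next(c for c in cands if c.key == "AA[mC?|base]AAGp")
        frags = generate_theoretical_spectrum(target.sequence, charges=(-1,))
        spec = MS2Spectrum(native_id="scan=1", ms_level=2,
                           precursor_mz=mz_from_mass(target.neutral_mass, -2),
                           precursor_charge=-2,
                           mz=np.array([f.mz for f in frags]),
                           intensity=np.ones(len(frags)),
                           polarity="negative")
        osms = search_run([spec], records, cfg, registry=registry)
        assert osms[0].sequence_string == "AA[mC?|base]AAGp"
        assert not osms[0].localization_ambiguous

    def test_unknown_precursor_charge_iterated(self, registry):
        records = [FastaRecord("x", "", "AACAAUCG")]
        cfg = SearchConfig(deisotope_spectra=False,
                           precursor_charges=(-2, -3, -4))
        cands = build_candidates(records, [], [], 0, registry=registry,
                                 min_length=3)
        target = next(c for c in cands if c.key == "AACAAUCG")
        frags = generate_theoretical_spectrum(target.sequence, charges=(-1, -2))
        spec = MS2Spectrum(native_id="scan=1", ms_level=2,
                           precursor_mz=mz_from_mass(target.neutral_mass, -3),
                           precursor_charge=0,  # unknown
                           mz=np.array([f.mz for f in frags]),
                           intensity=np.ones(len(frags)),
                           polarity="negative")
        osms = search_run([spec], records, cfg, registry=registry)
        assert osms and osms[0].sequence_string == "AACAAUCG"
        assert osms[0].precursor_charge == -3

    def test_empty_database_rejected(self):
        with pytest.raises(ValueError):
            search_run([], [], SearchConfig())


class TestConfig:
    def test_yaml_round_trip(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text(
            "precursor_tol_ppm: 3\n"
            "fragment_tol_ppm: 3\n"
            "adducts: [Na, K]\n"
            "isotope_offsets: [-1, 3]\n"
            "variable_mods: [m5C]\n"
            "max_mods_per_oligo: 2\n"
            "digestion: rnase_t1\n"
            "missed_cleavages: 1\n")
        cfg = SearchConfig.from_yaml(p)
        assert cfg.adducts == ("Na", "K")
        assert cfg.isotope_offsets == (-1, 3)

    def test_unknown_key_rejected(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text("bogus_key: 1\n")
        with pytest.raises(ValueError, match="bogus_key"):
            SearchConfig.from_yaml(p)

    def test_invalid_tolerance(self):
        with pytest.raises(ValueError):
            SearchConfig(precursor_tol_ppm=0)

    def test_inverted_offsets(self):
        with pytest.raises(ValueError):
            SearchConfig(isotope_offsets=(3, -1))

    def test_adduct_parsing(self):
        assert parse_adduct("Na").charge == 1
        assert parse_adduct("NaK2").charge == 3
        assert parse_adduct("Na2K").mass_shift == pytest.approx(
            2 * 21.981944 + 37.955881, abs=1e-4)
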