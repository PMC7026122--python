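# oligoms

A database search engine for identifying (modified) RNA oligonucleotides
from negative-mode LC-MS/MS spectra, with:

- in-silico RNase T1 / unspecific digestion of FASTA sequence databases
  (inline modification codes supported, e.g. `UAAC[m5C]CAAUGp`),
- variable/fixed modification enumeration from a curated, user-extensible
  mass-shift registry (base vs. sugar placement tracked for a-B ions),
- precursor-indexed candidate lookup with salt-adduct (Na+/K+ combinations)
  and isotopologue-offset (multiples of a neutron mass, including −1)
  correction at ppm tolerances,
- theoretical spectra for the nine backbone ion series
  (a-B, a, b, c, d, w, x, y, z) and hyperscore-ranked
  oligonucleotide-spectrum matches,
- target/decoy q-value estimation, FDR filtering, single-hit removal,
  sequence coverage and modification-level reports,
- label-free quantification target export plus a simple windowed-XIC
  quantifier with charge/adduct aggregation,
- a synthetic-run simulator (mzML + ground truth) so everything is testable
  offline.

mzML 1.1 reading/writing (centroided spectra, 32/64-bit arrays, optional
zlib compression) is implemented with the standard library only.

## CLI

```sh
# add reverse or shuffled decoys to a database
oligoms decoys --in targets.fasta --out targets_decoys.fasta --method shuffle --seed 1

# simulate a run with ground truth
oligoms simulate --db targets.fasta --out run.mzML --truth truth.tsv \
    --n 200 --seed 1 --variable-mod m5C --max-mods 2

# search (config mirrors the standard parameter table; see below)
oligoms search --in run.mzML --db targets_decoys.fasta --config search.yaml \
    --out osms.tsv --fdr 0.01 --no-single-hits

# export label-free quantification target coordinates
oligoms quant-targets --in osms.tsv --out targets.tsv
```

Example `search.yaml`:

```yaml
precursor_tol_ppm: 3
fragment_tol_ppm: 3
adducts: [Na, K]
isotope_offsets: [-1, 3]
variable_mods: [m5C]
max_mods_per_oligo: 2
digestion: rnase_t1
missed_cleavages: 1
```

## Library sketch

```python
from oligoms import (SearchConfig, read_fasta, read_mzml, search_run,
                     compute_qvalues, filter_fdr)

records = read_fasta("targets_decoys.fasta")
spectra = read_mzml("run.mzML", ms_levels=(2,))
osms = search_run(spectra, records, SearchConfig(variable_mods=("m5C",),
                                                 max_mods_per_oligo=2,
                                                 missed_cleavages=1))
accepted = filter_fdr(compute_qvalues(osms), 0.01)
```

The modification registry ships at `src/oligoms/data/modifications.tsv`
(tab-separated: code, name, shift formula, placement, target bases, isobaric
set) and can be replaced via `ModificationRegistry.from_tsv`.

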