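# memtop

Native top-down mass spectrometry of membrane proteins as a reusable
analysis pipeline, exercised entirely on synthetic spectra from a bundled,
seeded simulator.

The package covers five stages:

| module | what it does |
| --- | --- |
| `memtop.masses_ions` | residue/peptide mass arithmetic, disulfide corrections, m/z conversion, and the disulfide-constrained theoretical b/y fragment ladder |
| `memtop.synthetic_data` | seeded generators of polytopic membrane-protein specs and of MS1/MS2 peak lists (detergent/lipid adduct ladders with a sigmoidal laser-power removal model; residue-pair + helix-stability + mobile-proton cleavage propensities) with ground truth for recovery tests |
| `memtop.ms1_deconv` | intact-mass inference from multi-charge peak series, adduct-ladder detection, and a "resolved fraction" spectrum-quality score |
| `memtop.fragment_match` | greedy global assignment of MS2 centroids to b/y fragments across charge states, repeat-fragment grouping, complementary-pair detection |
| `memtop.landscape` | charge-normalized fragment-intensity landscapes: per-site profiles, sequence coverage, sequence tags, residue-pair heat maps, transmembrane-topology enrichment (circular-shift permutation test), and IRMPD-vs-HCD comparison |

Conventions: intact (MS1) masses use the average scale and fragment (MS2)
masses the monoisotopic scale; a protein of length `L` has `L−1` cleavage
sites; only b/y ions are considered; fragment intensities are normalized by
charge (divide by z) before summation.

## Python API in one breath

```python
from memtop import synthetic_data as sd, fragment_match as fm, landscape as ls
from memtop.masses_ions import fragment_ladder

spec = sd.make_protein(7, helix_len=24, loop_len=14, n_disulfides=2, seed=1)
peaks, truth = sd.simulate_ms2(spec, precursor_z=17, activation="IRMPD",
                               config=sd.SimConfig(seed=1), seed=1)
matches = fm.match_fragments(peaks, fragment_ladder(spec), z_max=10, tol_ppm=10)
ls.normalize_by_charge(matches)
profile = ls.site_profile(matches, len(spec))
print(ls.coverage(matches, len(spec)),
      ls.sequence_tags(matches, spec.sequence, min_len=3))
```

## CLI

A `memtop` console script exposes the pipeline on files
(two-column TSV peak lists with a JSON metadata sidecar, FASTA sequences,
JSON topology annotations):

```sh
# synthesize a 7-TM protein and an IRMPD MS2 spectrum
memtop simulate --out-prefix out/sim --seed 1 --ms-level 2

# assign peaks to the theoretical b/y ladder
memtop assign --peaks out/sim.peaks.tsv --fasta out/sim.fasta \
              --topology out/sim.topology.json --zmax 16 --out out/matches.tsv

# landscape statistics (JSON report + site-profile and heat-map TSVs)
memtop landscape --matches out/matches.tsv --fasta out/sim.fasta \
                 --topology out/sim.topology.json --out-prefix out/land

# figures (bar plot with topology overlay, residue-pair heat map)
memtop report --matches out/matches.tsv --fasta out/sim.fasta \
              --topology out/sim.topology.json --out-prefix out/fig

# MS1 deconvolution of a simulated intact spectrum
memtop simulate --out-prefix out/ms1 --ms-level 1 --n-helices 11 \
                --loop-len 12 --disulfides 0 --oligomer 3 --power 20 --seed 2
memtop deconv --peaks out/ms1.peaks.tsv --mass-min 130000 --mass-max 137000 \
              --zmin 15 --zmax 30
```

## Notes

- Only text formats are read/written (TSV, FASTA, JSON); mzML export is not
  included because no mzML library is part of the supported environment.
- The MS1 deconvolution is a deliberately transparent grid search with
  refinement, not a Bayesian deconvolution; isotope structure and PTMs
  other than disulfides are out of scope.
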