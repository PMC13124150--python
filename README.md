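# specfret

Analysis toolkit for ratio-based spectral FRET quantification on
fluorescent-noncanonical-amino-acid-labeled membrane proteins, plus the
companion measurements that surround such experiments:

- **spectra** — parsing/validation of two-column optical traces (emission
  and absorption spectra, size-exclusion chromatograms), blank subtraction,
  normalization, and peak location.
- **ratio** — spectral FRET analysis: scale a donor-only control to the
  sample's donor band, extract the acceptor spectrum, form the
  per-wavelength ratio against the directly excited acceptor spectrum, and
  summarize it as `ratio_a`, `ratio_a0`, and their difference (proportional
  to FRET efficiency). Includes paired condition comparison
  (apo / Zn²⁺ / EDTA-reversal) with per-construct t-tests.
- **structure** — structure-based FRET prediction: simplified side-chain
  rotamer ensembles with clash filtering, donor–acceptor distance
  distributions, Förster efficiencies including the multi-acceptor k-sum
  rule for a dimer's two acceptor copies, all-donor vs intrasubunit
  aggregation, and through-origin regression of measured vs predicted.
- **tcspc** — TCSPC lifetime fitting by IRF reconvolution (weighted least
  squares with Poisson weights; Poisson-MLE optional).
- **flux** — liposome proton-flux trace normalization
  `(F(t) − F_min)/(F_max − F_min)` and quench extent/rate metrics.
- **synth** — seed-deterministic generators for all of the above with
  exact ground-truth records, used throughout the test suite.

## CLI

The `specfret` entry point exposes one subcommand per stage; all inputs and
outputs are plain delimited text, and each file output gets a JSON sidecar
log with a config hash.

```sh
specfret simulate --out-dir demo --n-replicates 4 --noise-sd 0.01 --seed 1
specfret fret-ratio demo/manifest.csv \
    --free-f280 free_f280.csv --free-f370 free_f370.csv --out ratios.csv
specfret zinc-compare ratios.csv --treated zinc --out zinc.csv
specfret predict model.pdb --sites 18,56,134 --mode all_donors --out pred.csv
specfret compare ratios.csv pred.csv
specfret spectra spectrum.csv --excitation-nm 370
specfret lifetime decay.csv --irf irf.csv --components 2
specfret flux trace.csv --events events.csv
```

Manifest format for `fret-ratio`: CSV with columns
`construct_id,condition,replicate,f280,f370,f280_notag` (spectrum paths
relative to the manifest).

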