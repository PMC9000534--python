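# airmark

Untargeted discovery of volatile-organic-compound (VOC) markers in
multi-group TD-GC-HRMS experiments.

## The problem

Breath and air analysis by thermal-desorption gas chromatography with
high-resolution mass spectrometry (TD-GC-HRMS) produces, after deconvolution,
one peak list per sample: a few hundred compounds, each with a retention time,
a chromatographic peak area, and an accurate-mass electron-ionization
fragment spectrum. Finding markers — compounds whose level differs between
sample groups (e.g. patients vs. controls, or spiked concentration levels) —
requires solving three problems that generic alignment tools handle poorly for
low-mass volatiles:

1. **Crowded low-mass spectra.** Small VOCs fragment into a handful of CHO(N,S)
   cations concentrated around m/z 40–45; many pairs are isobars separable
   only by accurate mass (C2H3O+ 43.018 vs. C3H7+ 43.054, C2H3N+ 41.026 vs.
   C3H5+ 41.038). Alignment must match ions at millidalton tolerance.
2. **Base-peak instability.** Near the detection limit the two or three most
   intense ions run close to parity and swap ranks between injections, so the
   base peak is an unreliable compound tag.
3. **Background contamination.** Sampling bags, sorbent tubes and the
   instrument contribute compounds that must be removed using blank samples
   before any group comparison.

`airmark` implements a two-stage workflow. **Stage I** merges the per-sample
peak lists of each group into one unified compound table: two records are the
same compound when their retention times differ by less than 0.12 min and
their spectra score above 0.5 on a base-peak-robust similarity measure. The
score is a weighted sum of three cosine terms — the full top-7 spectra, the
spectra with the first record's base peak removed, and the spectra with the
second record's base peak removed (weights 0.5/0.25/0.25, ions matched within
1.1 mDa) — which keeps rank-swapped replicates together. Compounds detected in
fewer than 30% of a group's samples are dropped. **Stage II** flags compounds
whose mean area is not more than 5× their blank-group counterpart, then
compares every ordered pair of groups with a two-sided pooled-variance t-test
on full-length area vectors (absent = 0). A compound is a marker candidate
when it is present in more than 60% of the focal group's samples, has the
larger mean, and p ≤ 0.05 (“significant”) or 0.05 < p < 0.1 (“possibly
significant”).

## Quick start

The package ships a deterministic simulator of a 13-sample spiked experiment
(one blank plus duplicate samples at 0.3/1/3/10/30/100 nL/L of a 27-compound
VOC mixture, grouped L/M/H), so you can run the whole workflow without any
instrument data:

```bash
$ airmark demo --seed 1 --out demo
comparison   significant  possible  disqualified
L_vs_M                 1         1           248
L_vs_H                 4         1           248
M_vs_L                25         3           244
M_vs_H                 3         0           244
H_vs_L                31         0           245
H_vs_M                28         2           245
```

The six directional marker lists land in `demo/results/markers_*.tsv`
(compound, consensus RT and spectrum, group means, fold change, p-value,
Benjamini–Hochberg-adjusted p-value, detection fractions, status, and the raw
per-sample areas). An excerpt from `markers_H_vs_L.tsv`:

```
name       rt_mean  mean_focal  mean_reference  fold    p_value   status
Phenol     30.704   365755.25   0.0             inf     3.35e-08  disqualified_blank
Limonene   27.604   1087892.45  15470.875       70.32   0.0203    significant
n-Pentane  2.491    787082.52   0.0             inf     0.0210    significant
Toluene    15.283   1874726.50  18977.375       98.79   0.0233    significant
```

Phenol is spiked into every sample *including the blank* by the simulator, so
the blank filter disqualifies it everywhere — exactly what should happen to a
ubiquitous background compound, however significant its raw p-value looks.

## Running on your own data

Inputs are MSP peak lists (the text export of a deconvolution tool such as
MS-DIAL: `NAME`, `RETENTIONTIME`/`RT`, `INTENSITY` (= peak area), `Num Peaks`
and the ion lines) plus a tab- or comma-separated manifest with columns
`file`, `sample_id`, `group`; one group must be the blank (default name
`blank`):

```
file     sample_id  group
B1.msp   B1         blank
L1.msp   L1         L
...
```

```bash
airmark run --manifest manifest.tsv --out results \
    --rt-tol 0.12 --score-min 0.5 --blank-ratio 5 --format both
```

All thresholds are flags (or a YAML config via `--config`), are logged at run
time, and are echoed into `results/run_summary.json` together with the
per-status counts of every comparison. `--welch` switches the pooled t-test to
Welch's. The same workflow is available as a library:

```python
from airmark import RunConfig, read_manifest, run_pipeline

manifest = read_manifest("manifest.tsv")
reports = run_pipeline(manifest, RunConfig(), "results")
print(reports["H_vs_L"].count("significant"))
```

## The synthetic fixture

`airmark simulate --seed 1 --out fixture` writes the 13 reference peak lists.
The generator emits post-deconvolution data with a realistic error model:
areas proportional to concentration with lognormal noise, retention-time and
m/z jitter, a ~280-compound background library shared across samples, and
relative-intensity noise that grows as concentration falls — so base-peak rank
swaps *emerge* at low concentration rather than being scripted. Deliberate
contaminant behaviour is built in (phenol in every sample including the blank;
pentane in the blank at about its 2 nL/L response; two compounds with a
0.5 nL/L detection limit; seven compounds with inflated group-specific area
variance that produce borderline p-values). Custom designs can be saved to
YAML and replayed with `airmark simulate --design my_design.yaml`.
Identical designs produce byte-identical files.

## Repository layout

```
src/airmark/
  spectra.py    exact masses, top-7 spectra, base-peak-robust similarity score
  msp_io.py     MSP parsing/writing, sample manifest
  grouping.py   stage I: per-group alignment and consensus spectra
  markers.py    stage II: blank filter, t-tests, marker reports
  synthfix.py   deterministic synthetic-experiment generator
  cli.py        run / demo / simulate commands, run provenance
scripts/acceptance.py   headline-number reproduction
docs/methods.md         methods note (statistics and calibration)
```
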