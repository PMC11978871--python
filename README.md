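# pkrscan

Simulation and analysis toolkit for the quantitative biophysics of PKR — the
dsRNA-activated protein kinase — scanning along double-stranded RNA, and its
restriction by the regulator PACT.

PKR activation requires two kinase molecules on the same duplex: each binds
with a ~15 bp footprint, diffuses one-dimensionally along the RNA, and
trans-autophosphorylates on collision (a lone PKR cannot autophosphorylate).
This makes activation depend on dsRNA length and concentration, and it makes
the kinase vulnerable to a co-occupying scanner: PACT restricts PKR's motion
and promotes its dissociation without sequestering the RNA. `pkrscan`
implements that picture end to end, for anyone who wants to analyze
single-molecule FRET scanning data, quantify multi-band gel shifts, explore
the stochastic activation model, or run the inverted-repeat/coverage
arithmetic used to identify endogenous dsRNA (IR-Alu) ligands.

## What is implemented

| module | contents |
| --- | --- |
| `pkrscan.fret_sim` | smFRET trace simulator: two-state binding kinetics, reflected Brownian scanning, Förster-geometry rendering with noise/leakage, and a hard-core PACT obstacle with contact-triggered eviction |
| `pkrscan.fret_analysis` | ratiometric FRET with corrections, On/abortive event segmentation (threshold 0.6, cutoff 2 s), donor–acceptor anticorrelation scores, per-event FRET autocorrelation `G(τ)` pooled across events, single-exponential sliding-time fits, residence-time statistics (Welch/paired t), high-FRET-gated histograms |
| `pkrscan.emsa` | multi-band gel-shift quantification — bound fraction `Σₙ I(n)·n / (Σₙ I(n)·8)` for a 112 bp duplex with eight sites — plus Hill-equation fitting `f(c) = cʰ/(K_dʰ + cʰ)` and a binomial-lane generator |
| `pkrscan.activation` | stochastic scanning-collision lattice model: binding/diffusion/dissociation with footprint exclusion, trans-only phosphorylation on collision, PACT eviction, heatmaps over length × concentration × PACT |
| `pkrscan.genomics` | inverted-repeat detection by exact affine-gap local alignment (match +2, mismatch −3, gap open 5, extend 2; ≤1.5 kb window, >80% identity), per-million coverage normalization, track subtraction, peak calling, AuC/log2FC enrichment, near-IR (<300 bp) annotation, A-to-G editing CPM, and a planted-repeat genome generator |
| `pkrscan.io` / `pkrscan.cli` | plain-text formats (TSV/CSV/BED/bedGraph/FASTA/JSON) and the `pkrscan` umbrella command with per-run manifests |

The two estimation procedures are statsmodels-style model objects:
`HillBindingModel(conc, frac).fit()` and `SlidingTimeModel(lags, G).fit()`
return results objects carrying estimates, standard errors and `summary()`.

## Worked example

Recover a dissociation constant from three replicate synthetic gel titrations
(0–4000 nM ladder, 2% multiplicative band noise, true K_d = 357.5 nM):

```python
from pkrscan import emsa

lanes = emsa.simulate_gel(true_kd=357.5, h=1.0, noise_sd=0.02, seed=1,
                          n_replicates=3)
res = emsa.HillBindingModel([l.protein_conc for l in lanes],
                            [emsa.bound_fraction(l) for l in lanes]).fit()
print(res.summary())
```

```
HillBindingModel fit: f(c) = c^h / (Kd^h + c^h)
  Kd            : 357.7 nM (SE 0.34)
  Hill coeff h  : 0.9986 (SE 0.00088)
  residual norm : 0.00472
  n points      : 36
```

The fitted K_d (357.7 nM) recovers the generating value within its standard
error, and the Hill coefficient is 1 because the synthetic lanes assume
independent sites.

Measure a sliding time from simulated scanning traces on a 112 bp duplex
(D = 1000 bp²/s, 33 ms frames, 15 bp footprint):

```python
from pkrscan import fret_sim as fs, fret_analysis as fa

cfg = fs.SimulationConfig(duplex_length=112, n_frames=60_000,
                          substeps_per_frame=5, diffusion_coeff=1000,
                          k_on=0.02, protein_conc=50, k_off=0.12, rng_seed=0)
truth = fs.simulate_trajectory(cfg)
trace = fs.render_intensities(truth, fs.SCANNING_GEOMETRY)
fret = fa.compute_fret(trace, fs.SCANNING_GEOMETRY)
events = fa.segment_events(fret, on_threshold=0.1, min_frames=5)
r = fa.fit_sliding_time(fa.autocorrelate_events(events, fret, max_lag=2.0))
print(f"{len(events)} binding events, {r.n_events} used for autocorrelation")
print(f"sliding time: {r.sliding_time:.3f} +/- {r.sliding_time_se:.3f} s")
```

```
211 binding events, 164 used for autocorrelation
sliding time: 0.630 +/- 0.004 s
```

Events shorter than 2 s are classified abortive and excluded from the
autocorrelation, which is why 164 of 211 events contribute. The fitted decay
time sits near the slowest relaxation mode of diffusion in a box,
τ₁ = (L−15)²/(π²D) ≈ 0.95 s, biased low by the FRET nonlinearity and
per-event mean subtraction (see `docs/methods.md`); it increases
monotonically with duplex length, the signature of genuine 1D scanning.

The same pipelines are scriptable from the shell:

```bash
pkrscan simulate-traces --config cfg.json --n-molecules 20 --seed 7 --out traces/
pkrscan analyze-traces --in traces/ --on-threshold 0.6 --abortive-s 2.0 --out analysis/
pkrscan fit-binding --in lanes.csv --sites 8 --out fit/
pkrscan simulate-activation --config kinetics.json --seed 1 --out heatmap/
pkrscan synth-genome --pairs 20 --divergence 0.1 --seed 7 --out genome/
pkrscan find-ir --genome genome/genome.fa --repeats genome/repeats.bed --out ir/
pkrscan quantify-peaks --fclip f.bedgraph --input i.bedgraph --totals totals.tsv --out peaks/
```

Every run writes a `manifest.json` (parameters, master seed, SHA-256 of each
output); rerunning with the same config and seed reproduces outputs
bit-exactly.

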