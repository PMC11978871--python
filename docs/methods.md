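# Methods

This note documents the models behind `pkrscan`, the parameter choices that
matter, what the synthetic-data generators do and do not emulate, and the
numerical decisions a user should know before trusting a number.

## smFRET trace simulator (`fret_sim`)

**Model.** One scanner on one surface-immobilized duplex. Binding from
solution is a Poisson process with pseudo-first-order rate `k_on ·
protein_conc` (defaults 0.01 /nM/s · 50 nM); unbinding is first-order at
`k_off`. While bound, the footprint's left edge performs reflected Brownian
motion on the continuous interval `[0, L − footprint]` (bp), integrated as a
Gaussian random walk with `substeps_per_frame` Euler substeps per 33 ms
frame (default 10; the length-scan scenarios use 5, keeping the RMS substep
a few bp). Dwell times are discretized as per-substep geometric draws — the
exact discretization of the two-state Markov chain — so the stationary bound
fraction is `k_on·c/(k_on·c + k_off)` up to O(rate·dt).

Frame-level truth: a frame is flagged bound when ≥50% of its substeps are
bound, and its position is the substep average (so rendered FRET is the
efficiency at the averaged position, not the time-averaged efficiency; at
the default substep counts the difference is below the rendering noise).
Camera-averaging also shrinks short-lag displacement statistics — the MSD of
window-averaged Brownian positions at lag one frame is (2/3)·2DΔt — so
free-diffusion oracles are checked with one substep per frame, where
sampling is instantaneous.

**FRET geometry.** `E(x) = 1/(1 + (r/R₀)⁶)` with `r = dye_offset +
x·helical_rise`. Defaults are the textbook Cy3/Cy5 values (R₀ = 5.4 nm,
0.28 nm/bp A-form rise, 1.5 nm offset). A rigid-rod mapping at 0.28 nm/bp
saturates E beyond ~25 bp, which cannot reproduce the observed behaviour of
scanning on ~100 bp duplexes, where FRET spans a broad range: in such
experiments the effective distance–position relation is strongly compressed
(flexible dye linkers, duplex bending, acceptor on the protein). The module
therefore ships `SCANNING_GEOMETRY` (effective rise 0.05 nm/bp, offset
2.0 nm, read noise 5 on a donor budget of 1000), under which every position
of a 112 bp duplex is FRET-resolved. All length-comparison analyses in the
tests and the acceptance script use it; all constants remain config-exposed.

**PACT obstacle.** One PACT molecule with its own binding, diffusion and
dissociation parameters shares the duplex under hard-core exclusion:
attempted moves across the other footprint are clamped at contact, and each
contact evicts the scanner with probability `eviction_prob_on_contact`.
Whether PACT acts as a static roadblock, a co-moving obstacle, or a
transient complex is not resolved by the data being emulated; the
obstacle-plus-eviction model is one consistent reading, and pinning PACT
(`pact_initial_position`, zero diffusion, zero off-rate) reproduces the
static-roadblock limit used in the restriction scenarios. The truth channel
counts footprint-overlap substeps (always zero) so exclusion is testable.

**Rendering.** Bound frames split the donor budget by E with optional
donor→acceptor leakage; unbound frames show full donor and background
acceptor; readout noise is i.i.d. Gaussian per channel, seeded. No
blinking, bleaching or gamma correction is modelled — synthetic traces are
cleaner than real ones, so passing tests validate the estimators, not
robustness to photophysics.

## Trace analysis (`fret_analysis`)

**FRET and segmentation.** `E = A'/(A'+D')` with background subtraction and
leakage correction; frames whose corrected total falls below 10% of the
donor budget are masked. On events are maximal runs of unmasked frames with
`E >` 0.6 (default; 0.1 under `SCANNING_GEOMETRY`, whose bound states reach
down to E ≈ 0.2 on 112 bp), at least `min_frames` long. Events shorter than
2 s are kept but labelled abortive and excluded from autocorrelation — the
convention for transient, non-scanning encounters.

**Autocorrelation.** The correlation integral over E within an event is
implemented as the standard mean-subtracted, variance-normalized sample
autocovariance with the biased 1/n estimator (lower variance at the short
lags that drive the fit), per-event mean subtraction (removes event-to-event
offsets before pooling), and pooling across events weighted by the number of
frame pairs contributing at each lag, so G(0) = 1 exactly. Events flat to
within rounding error are skipped; if none remain the function raises
rather than returning an undefined curve.

**Sliding-time fit.** `G(lag) = A·exp(−lag/τ) + C` by weighted least
squares (weights √n_pairs), with C fixed at 0 unless requested and the
default window running from lag 0 to the first lag with G < 0.05 — both
choices are free parameters of the underlying experimental convention, so
both are options. Non-convergence or τ ≤ 0 sets a failure flag; nothing is
silently substituted.

Two biases are documented rather than corrected: per-event mean subtraction
shrinks τ when event length is not ≫ τ, and the nonlinearity of E(x)
re-weights the diffusion spectrum. For reflected diffusion the fitted τ
tracks the slowest box mode τ₁ = (L−footprint)²/(π²D) within ~10% at 42–59
bp and reads ~35% low at 112 bp under the study conditions (10 s mean
events); the length *ordering* is unaffected, which is why comparative
claims are made on orderings, not absolute values. On exact AR(1) input
with a 5-frame correlation time the fit returns 0.149–0.151 s against the
true 0.165 s (≈−9%, the mean-subtraction bias at 400-frame events).

**Dwell statistics and histograms.** Residence times are event durations;
two-condition comparisons use Welch's t by default (pairing, when an
explicit pairing key exists, via the paired test). Gated histograms follow
the high-FRET-trace convention: a trace qualifies if any On-state frame
exceeds the gate (0.8), and all On frames of qualifying traces are binned —
per-frame counts, not per-event. Total counts equal the number of gated On
frames (a tested conservation law).

## Gel-shift quantification (`emsa`)

Bound fraction of a lane with bands I(0..8):
`Σₙ I(n)·n / (Σₙ I(n)·8)` — the intensity-weighted mean occupancy over the
eight binding sites of a 112 bp duplex, with band intensities proportional
to labelled RNA (no molar correction for complex size). The Hill fit treats
the site count and the Hill exponent separately: the eight sites enter
through the occupancy weighting, while h is a free shape parameter (fixable
by flag). A Hill coefficient equal to the site count would assert perfect
cooperativity among independent dsRNA-binding domains, which is not
physically credible; with h free, noiseless binomial lanes return exactly
(K_d, h) of the generator, and the half-saturation reading of K_d holds by
construction (`f(K_d) = 0.5`).

The generator produces lanes at the experimental 12-point ladder (0 and 3.9
→ 4000 nM in 2-fold steps) with Binomial(8, p(c)) band mass and
multiplicative Gaussian noise (default 2%, 3 replicates in recovery tests).
The binomial mean identity E[n]/8 = p ties generator to estimator exactly in
the noiseless limit.

## Scanning-collision activation model (`activation`)

**Scheme.** Fixed-time-step kinetic Monte Carlo (dt = 5 ms) over discrete
molecules and duplexes; exact event-driven simulation is unavailable because
continuous diffusion with hard-core exclusion has no finite reaction set.
The run refuses to start if any per-step event probability reaches 0.1.
Positions are continuous; per duplex, proposed moves are projected back to
an order-preserving, non-overlapping configuration (crossings become
contacts). Binding is pseudo-first-order per free molecule at `k_on ·
c_sites`, with `c_sites = c_dsRNA · ⌊L/15⌋`: association scales with
binding-*site* molarity, so at matched mass concentration the total binding
flux is length-independent while occupancy concentrates on fewer duplexes
for long dsRNA — the co-occupancy effect the mechanism requires. The landing
site is uniform over the gaps that fit a footprint; if none fits the attempt
fails (this, not an explicit penalty, is what suppresses short-duplex
activation). Free pools deplete as molecules bind, which produces the
dispersal inhibition at excess dsRNA.

**Reactions.** A *newly formed* contact (gap ≤ 1 bp) between two PKR
footprints phosphorylates both partners with probability 0.05 (trans only; a
lone PKR never activates; mutual phosphorylation is the default with a flag
for one-way). A new PKR–PACT contact evicts the PKR with probability 0.9.
Phosphorylated PKR keeps binding and scanning; there is no dephosphorylation,
so the phospho fraction is non-decreasing — activation is single-hit.

**Parameters.** Defaults (PKR: k_on 0.001 /nM/s, k_off 0.25 /s, D 10⁴
bp²/s; PACT: k_on 0.005, k_off 5 /s, D 10⁴; 2.5 nM per simulated molecule,
t_end 15 s) were chosen once as a regime demonstrator: under them the model
jointly shows (i) activation(112) > activation(62) > activation(42) at
matched mass, (ii) a biphasic dose response in dsRNA, (iii) exactly zero
activation for 21 bp duplexes and lone kinases, and (iv) >50% inhibition at
<10% stable PACT site occupancy (measured ~90% inhibition at ~6%
occupancy). They are not fitted to any kinase-assay gel, and absolute
activation values carry no meaning beyond these orderings and regimes. The
PKR and PACT random streams are independent children of the master seed, so
zeroing PACT parameters leaves the PKR trajectory bit-identical.

`mass_to_molarity` uses 660 g/mol/bp. Heatmaps report endpoint phospho
fraction with replicate SD plus co-occupancy diagnostics (PACT site
occupancy, mean PKR per occupied duplex, PKR–PACT co-occupancy fraction).

## Inverted repeats and coverage arithmetic (`genomics`)

**IR detection.** Candidate pairs are same-family, opposite-strand repeat
copies on one chromosome with gap ≤ 1.5 kb. One copy is aligned against the
reverse complement of the other by exact affine-gap local alignment
(Smith–Waterman) at blastn-style scores: match +2, mismatch −3, gap of
length k costs 5 + 2k (PairwiseAligner open −7, extend −2). The word-seeded
BLAST heuristic is deliberately replaced by the exact algorithm; at these
problem sizes exactness is free. "Over 80% identity of the whole sequences"
is ambiguous between identity over alignment columns and over repeat
length; the default is identity over alignment columns (gaps counted)
*and* alignment coverage ≥ 80% of the shorter copy, both thresholds
exposed.

**Planted-genome generator.** Constructs are separated by 2.5 kb of random
background so no cross-construct pair falls inside the window; decoys are
same-strand direct repeats (rejected by the strand rule) and inverted pairs
with 1.6–2.2 kb gaps (rejected by the window rule). Divergence plants an
*exactly counted* number of substitutions, `round(divergence · length)`,
rather than per-base Bernoulli mutation: with Bernoulli sampling the
identity of a 25%-diverged 300-mer has sd ≈ 2.5% and gapped alignment
inflates it by a few percent, putting individual pairs over the 80% gate
~3% of the time; with counted substitutions the measured distribution is
75.9 ± 0.8% (max 79.5% over 120 pairs), so the divergence gate is a sharp
property. Residual spread comes only from the aligner.

**Coverage.** Tracks are sorted, disjoint, 0-based half-open interval lists
(bedGraph dialect). Normalization multiplies values by 10⁶ / total
non-rRNA mapped reads; subtraction works on the union of breakpoints with
absent coverage as 0; the peak caller is threshold/merge/length
(value ≥ min, gaps ≤ merge_gap, length ≥ min) — a deliberately simple,
parameterized stand-in that is *not* parameter-compatible with dedicated
bedGraph peak callers. Peak AuC is Σ value·overlap_width; enrichment is
log2((AuC_fCLIP + φ)/(AuC_input + φ)) with a pseudo-AuC floor φ = 1 in
normalized units (distribution-based shrinkage is out of scope), filtered
by the tag-present ≥1 / tag-absent ≤0 criterion pair. Peaks overlapping a
pair member are "IR-Alu"; peaks within 300 bp of a member or lying between
the two members are "near IR-Alu". Editing rates are A→G mismatch counts
per million mapped reads, with counts strand-resolved upstream (A→G on
plus-strand features, T→C on minus).

## Reproducibility and problem sizes

Every stochastic entry point takes an explicit seed; CLI runs fan a single
master seed into per-molecule/per-module children via `SeedSequence` and
record parameters, seed and output SHA-256s in a manifest. The test suite
and the acceptance script use desk-scale problem sizes chosen for
statistical sufficiency: 10⁵-frame traces (≈200–600 events per condition),
5 seeds × 30 000 frames per obstacle arm (≥200 events each), 20-seed Hill
recovery, 3–5 seeds per activation condition with 40 kinase molecules, and
20 planted repeat pairs with 30 decoys. These sizes keep every Monte-Carlo
comparison at ≥3σ separation while the whole acceptance run stays under a
minute.

## Known limitations

- No photophysics beyond Gaussian noise and leakage; no hidden-Markov state
  modelling of FRET; drift/bleaching correction is out of scope.
- Sliding-time absolute values are biased low at long duplexes (documented
  above); comparisons should use orderings or matched conditions.
- The activation model is a regime demonstrator: its outputs are fractions
  of simulated molecules, not calibrated kinase activities, and the
  single-hit, no-dephosphorylation assumptions are untested simplifications.
- The obstacle model commits to hard-core exclusion + contact eviction among
  several microscopically distinct mechanisms consistent with the same
  phenotypes.
- IR detection reproduces scoring, window and identity rules but not BLAST's
  seeding heuristics, E-values, or multi-HSP behaviour; peak calling is not
  a substitute for a model-based caller on real data.
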