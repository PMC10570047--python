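# Methods

This note documents the generative model, the calibration of its
parameters, the detection algorithms, and the design decisions that were
genuinely open.  Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Kinetic model

Each molecule is one surface-immobilized transcription complex on a linear
template (coordinates are 1-based template positions; +1 is the
transcription start, upstream negative; t = 0 is NTP injection).  The
state machine, simulated exactly (event times drawn from their
distributions; deterministic motion between events):

1. **Activity.** A fraction `p_inactive` (default 0.03) never resumes;
   these complexes keep the stalled-state FRET and are removed downstream
   by the active filter.  Active complexes leave the stall site
   (transcript length 10 nt) at t = 0 and elongate at `k_elong`.
2. **Internal nucleation** (long templates).  While elongating, an R-loop
   may nucleate behind the polymerase at rate `k_nucleate_internal`.  From
   nucleation onward the elongation speed is multiplied by `f_hindrance`
   (a trailing hybrid impedes the polymerase); the hybrid's downstream
   border stays at the nucleation position while the upstream border
   migrates toward +1 at `v_ext`.
3. **End arrival.**  At the downstream end (the DSB mimic) a categorical
   branch is drawn per template: (p_rloop, p_runoff, p_retention).
   Branching is a categorical draw rather than competing rates because the
   assay reports fractions and mean dwell times, not rate constants; each
   branch's dwell is exponential with a configured mean.
   * **R-loop**: after an Exp(`k_rloop_init`) nucleation delay the hybrid
     nucleates at the end; the downstream border stays there and the
     upstream border extends at `v_ext` until it reaches +1 (absorbing).
   * **Runoff**: the transcript dissociates after Exp(`k_off_rna`).
   * **Retention**: the RNA stays bound, no R-loop, through `t_obs`
     (an absorbing state within the window; whether such complexes later
     convert is unknown, so no escape path is modelled).
4. **Antibody binding.**  S9.6 binding is a Poisson process gated by
   hybrid length: the first epitope opens at `L_epitope` (default 8 bp)
   and one further epitope per `epitope_spacing` (default 30 bp) of
   growth; every open, unoccupied epitope binds at rate `k_ab`.  The
   growing-hazard form is what makes late first bindings rare on fast
   templates; with a single epitope the wait is exactly Exp(`k_ab`).
5. **RNase H / re-initiation** are post-hoc operators on completed
   trajectories, mirroring buffer exchange: RNase H digests an existing
   hybrid after Exp(`k_rnaseh`), ending the RNA and antibody signals;
   initiation pressure attempts at rate `k_reinit` succeed (hybrid
   unwound, Cy3-RNA departs) only if no R-loop covers the promoter/+1
   region, else the attempt is logged as blocked.

Cohorts use per-molecule seeds from `SeedSequence([cohort_seed, index])`,
so identical inputs give byte-identical cohorts and the scheme is stable
across releases.

## Calibration of the presets (`calibration.py`)

The assay publishes summary statistics, not rate constants; every preset
rate is derived from them in closed form, once, and frozen:

| quantity | derivation | value |
|---|---|---|
| `k_elong` | 1093 bp traversed in the 5.3 s DT8 running time | 206.2 bp/s |
| `1/k_off_rna` | 15 s mean runoff time − 91 bp/`k_elong` | 14.56 s |
| `k_ab` | 6.6 s mean antibody wait | 0.1515 /s |
| `v_ext` (per template) | high-FRET lag L after antibody onset: L = (D−1−`L_epitope`)/v − 1/`k_ab`, with L = 25/31/105 s for DT3/DT2/DT1 | 2.91 / 2.45 / 0.82 bp/s |
| `1/k_rloop_init` | 74 s mean antibody onset − elongation − eligibility growth − binding wait | 57.25 s |
| `k_nucleate_internal` (DT8) | 11% of the 18% R-loop formers nucleate before the 5.3 s arrival | 3.77e-3 /s |
| `f_hindrance` (DT8) | E[t_run | internal] = 79 s with nucleation ~uniform over the run | 0.0343 |
| DT8 terminal p_rloop | internal + terminal formers total 18% | 0.1634 |

The three landmark timings are *not* jointly consistent with a single
constant extension speed (the mid-template lag implies a different v than
the endpoint lags); v_ext is calibrated from the +1-site lag, which makes
the simulated scheme-I lead ≈ 8.6 s rather than the printed 10 s and the
scheme-II lag ≈ 15 s rather than 9.1 s.  This inconsistency is in the
source statistics ("a few bp/s within an order of magnitude"), not a free
choice here.

Branch probabilities printed only graphically (DT2, DT4–DT7, the
runoff/retention splits, the overhang series) are configured once at
values consistent with the qualitative statements: retention rare (2–3%)
except on the stalling-prone DT5 (50%), runoff taking the remainder, and
overhang-series efficiencies decreasing monotonically with shorter
overhangs for both polarities.

## Photophysics

Dye separations are contour distances along the nucleic acid
(`bp_to_nm` = 0.34 nm/bp) passed through the Förster relation with
R0 = 6 nm, `gamma` = 1 and no crosstalk (the printed E values look
uncorrected, so the defaults reproduce them as-is).  Scheme-specific
effective separations are frozen by inverting the Förster relation at the
calibrated apparent-E levels: scheme III 0.69 (stalled) / 0.75 (border at
+1; the published criterion is only "E > 0.7", so the exact high level is
a declared choice), scheme II 0.21/0.64, scheme I 0.80/0.10 (levels not
printed; declared).  The RNA 5'-end's effective position sits at a
stall-proximal exit point, travels with the polymerase during elongation,
and returns to the promoter-proximal position when the border encloses it.

Channels per frame (state sampled at the frame midpoint; recording starts
`pre_time` = 10 s before injection so the stalled baseline exists):
donor = `I_total`(1−E)+bg, acceptor = `gamma·I_total`·E+bg (so the
noiseless green-excitation sum is constant while both dyes live), red
excitation = `I_red`×`pife_factor` while RNAP is within `pife_window`
(15 bp) of the Cy5 dye (instantaneous two-state PIFE), antibody channel =
n_bound×`I_ab`+bg.  Additive Gaussian noise (sd 30 counts at
I_total = 1000, i.e. SNR ≳ 8 on every step the classifier must detect)
models the camera for traces; movies instead use Poisson shot noise plus
Gaussian read noise on a 2-D Gaussian PSF per molecule.

`k_bleach` (default 3e-5 /s per fluorophore) is deliberately low —
bleaching is kept a minor perturbation, as under the assay's oxygen
scavenging and triplet quenching — and is drawn inside the renderer:
bleaching is photophysics, so ground-truth trajectories stay purely
kinetic.  Cy3 loss by bleaching is indistinguishable from dissociation at
the trace level and is read as runoff, matching the operational
definition; at the default rate this contaminates the runoff-time mean by
well under one second, and it slightly depletes high-FRET detections.
Antibody fluorophores are treated as non-bleaching (secondary antibody in
solution is replenished).

## Detection and classification

The step detector is a width-3 median filter (NaN-aware) plus a
hysteresis threshold: the onset is the first frame where the filtered
series crosses baseline ± `min_delta` and (a) stays beyond it for
`min_dwell_frames` = 3 consecutive frames and (b) holds beyond threshold
*on average* over a 2×dwell window — the confirmation step rejects the
correlated noise excursions that a width-3 median filter lets through.
The baseline is the median of the first `baseline_frames` (the
pre-injection segment for rendered traces), refined once with the full
pre-crossing segment.  Onset times are reported as the start time of the
first affected frame, which makes detections unbiased to within half a
frame for random event phases and at most half a frame early for
synchronized events (visible as the ~0.25 s low bias on the DT8 running
time at the 0.5 s default binning).  The detector was chosen over HMM
idealization for transparency and determinism and is validated in the
test suite against an exhaustive two-segment least-squares changepoint
oracle (≥95% of SNR-3 steps within ±2 frames for both).

Classification: the **active filter** requires a downward E step within
30 s of injection (applied automatically only to the labeling scheme that
defines it — donor on the RNA 5'-end; frames where E is undefined because
the total signal vanished count toward the dwell, so fast runoffs are not
lost).  Then **rloop** iff a sustained Alexa-488 up-step exists; else
**runoff** iff the donor+acceptor sum steps down to background; else
**retention**.  High-FRET entries are sustained intervals with E strictly
> 0.7; the entry reported for a molecule is the first one after its
antibody onset.  Antibody steps are counted by quantizing the filtered
Alexa channel to multiples of `I_ab`.  "Sustained" everywhere means ≥3
consecutive frames, guarding against single-frame nonspecific binding.
On the end-labeled schemes (I/II) the dyes sit on DNA, so transcript
dissociation is invisible and runoff-branch molecules are operationally
retention — the noiseless-equivalence tests encode exactly that mapping.

## Aggregation

Fractions carry Wilson 95% intervals (preferred over Wald at
single-molecule counts); timing-derived quantities use a seeded
molecule-level bootstrap (1000 resamples).  The high-FRET population
curve reports, at each grid time, the fraction of the *active cohort*
currently inside a sustained E > 0.7 interval (a survivor-normalized
column is emitted alongside; with runoff molecules leaving the surviving
pool, the survivor fraction is dominated by R-loop formers at late times
and does not measure population growth), with a Mann–Kendall trend
statistic.  Extension speed is the sign-flipped least-squares slope of
landmark position vs. time relative to antibody onset, with the pairwise
range and a bootstrap interval.  The blocking experiment simulates
R-loop-branch molecules to t_add = 180 s, keeps those whose border has
reached +1 with RNA still present (the challenged high-FRET population),
and compares Cy3 retention under re-initiation pressure, no pressure, and
RNase H.

## Timing-order caveat

The bubble-extension ordering — downstream FRET drop, then antibody
onset, then mid-template rise, then +1-site entry — is checked per
molecule by rendering the *same* trajectory under all three labeling
schemes.  The drop→antibody and mid→+1 orderings are mechanism-
deterministic and hold for every molecule in the noiseless limit.  The
antibody→mid ordering cannot hold for literally every molecule under
memoryless binding: the exponential first-binding wait exceeds the ~20 s
border transit to the mid-template site with probability
exp(−Λ) ≈ 1% (Λ the integrated multi-epitope hazard), so the full chain
runs at ~99% noiseless and ≥95% at default noise.

## Problem sizes and numerical choices

Acceptance-style experiments use 2000-molecule cohorts (pooled 10×200
sub-seeds) in `scripts/acceptance.py` (~0.5 min total on one CPU); the
pytest suite uses 200–800-molecule cohorts with binomial bands computed
at the size actually used (~2 min).  Frame interval defaults to 0.5 s
(0.2 s is supported), observation window 600 s.  Degenerate inputs
(empty cohorts, all-invalid traces, fields too small for the requested
molecule count, non-normalized branch probabilities) raise `ValueError`
at the boundary rather than propagating NaNs.

## Known limitations

* No sequence-level thermodynamics: overhang-length and G-richness
  effects enter only through configured branch probabilities, and no
  functional form is fitted to the overhang series.
* No supercoiling/topology model of extension; the border moves at a
  constant per-template speed.
* PIFE is binary and instantaneous; the transient PIFE that a passing
  polymerase causes on internal labels (scheme II) is not rendered.
* No donor leakage, direct acceptor excitation, gamma ≠ 1, drift, or
  aberration models; synthetic movies are drift-free (a correction hook
  exists but defaults off).
* Passing tests show the analysis recovers parameters from data generated
  by *this* model family; real traces add baseline drift, blinking and
  heterogeneous brightness that the generator does not emulate.
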