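# rlooptrace

Simulation and analysis of single-molecule fluorescence assays of
**cotranscriptional R-loop formation at DNA double-strand breaks (DSBs)**.

## The problem

When a transcribing RNA polymerase (RNAP) runs into a broken DNA end, the
nascent transcript can stay hybridized to the template strand, displacing
the nontemplate strand — an R-loop.  In the single-molecule TIRF assay this
package models, stalled *E. coli* RNAP elongation complexes carrying a
Cy3-labeled transcript sit on surface-immobilized, Cy5-labeled linear
templates whose downstream end mimics a DSB (blunt, or with a 3'/5'
overhang).  NTP injection (t = 0) restarts transcription and four detection
channels report what happens over a 10-minute window:

* **Cy3/Cy5 FRET** (green excitation) — position of the RNA 5'-end relative
  to a DNA-internal acceptor, `E = 1/(1 + (r/R0)^6)`;
* **Cy5 at direct red excitation** — protein-induced fluorescence
  enhancement (PIFE) times the arrival of RNAP at the labeled end
  (running time *t*_run);
* **Alexa-488** — an S9.6 antibody that binds RNA-DNA hybrids, giving a
  stepwise R-loop reporter.

Every active molecule ends the window as exactly one of three outcomes:
**R-loop** (antibody signal appears), **runoff** (Cy3 lost with no antibody
signal) or **retention** (Cy3 persists with no antibody signal).  Cohort
fractions, onset timings, the upstream extension speed of the R-loop border
(~3 bp/s from least squares on landmark positions vs. times), hindrance of
elongation by trailing internal R-loops, and blocking of next-round
initiation by fully extended R-loops are the figure-level quantities.

Because the underlying raw data are not deposited, the package is built as
a *parameter-recovery* instrument: a stochastic kinetic simulator
(`simulate`) plus photophysics renderer (`photophysics`, optional TIRF
movie rendering in `movie`) generate the multi-channel traces with known
ground truth, and the analysis half (`extraction`, `classify`, `aggregate`)
must recover the configured parameters through the same code paths real
data would take (tabular traces or TIFF stacks are ingested through the
same readers in `rlooptrace.io`).

## Worked example

```python
import rlooptrace as rl

kinetics = rl.preset_kinetics("DT1")        # calibrated template preset
optics   = rl.OpticsParams()
config   = rl.ClassifyConfig.from_optics(optics)

trajs  = rl.simulate_cohort("DT1", kinetics, 400, seed=7)
traces = rl.render_cohort(trajs, optics, seed=8)
calls  = rl.classify_cohort(traces, config)
s      = rl.summarize_cohort(calls, template="DT1")
```

prints (via the fields of `s`):

```
active complexes      : 386/400
R-loop efficiency     : 0.731  (95% CI 0.684-0.772)
runoff / retention    : 0.259 / 0.010
mean antibody onset   : 75.6 s
mean runoff time      : 17.7 s
mean high-FRET lag    : 105.2 s
extension speed       : 2.88 bp/s
```

386/400 molecules show the stepwise FRET decline that marks transcription
resumption (the ~97% active filter); 73% of those form R-loops on the
3'-overhang template DT1, with the S9.6 antibody first binding ~75 s after
NTP injection and transcripts running off in ~15 s when no R-loop forms.
The high-FRET lag is the time after antibody onset at which the R-loop's
upstream border reaches the transcription start (+1), read out as a
sustained E > 0.7; the extension speed comes from least squares on the
three landmark (position, time) pairs of the three labeling schemes.

The same stages run from the shell:

```sh
rlooptrace pipeline --template DT1 --n 400 --seed 7 --out out/
rlooptrace simulate --template DT1 --n 2000 --seed 7 --out traj.h5
rlooptrace render   --traj traj.h5 --seed 3 --out traces.h5 [--movie mov/]
rlooptrace classify --traces traces.h5 --out calls.tsv
rlooptrace summarize --calls calls.tsv --out report/
```

## File formats

* **Trajectories** (`*.h5`, `rlooptrace-trajectories-v1`): root attrs
  `template`/`params` (JSON), groups `/molecules/<i>` with a JSON `state`
  attr (landmark times) and an `ab_times` dataset; tidy event TSV export
  (`molecule_id, t, event_kind, payload`).
* **Traces** (`*.h5`, `rlooptrace-traces-v1`): `/t` (frame start times,
  negative before NTP injection), `/molecule_id`, and
  `/channels/{donor_em_green_ex, acceptor_em_green_ex, acceptor_em_red_ex,
  ab_em_blue_ex}` as (molecules x frames) arrays; also a wide per-molecule
  TSV.  Both round-trip through `rlooptrace.io`.
* **Movies**: one multi-frame float32 TIFF per channel plus a
  `spots.json` ground-truth sidecar.
* **Calls/summaries**: TSV (one row per molecule) and JSON.

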