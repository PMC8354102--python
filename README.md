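# polkin

Kinetic analysis of RNA polymerase II transcription from windowed
nascent-transcription data.

Acute loss of an elongation factor can change how often polymerases
initiate, how fast they move, how far they get before aborting
(processivity), how quickly they terminate after the polyadenylation site
(PAS), and how much RNA is made and degraded. `polkin` packages the
statistical machinery to separate these effects from standard genomics
read-outs — pulse-labeled nascent RNA (4sU-seq), DRB-release chases
(DRB-4sU-seq), polymerase occupancy (ChIP with spike-in normalization), and
metabolic-labeling tables (SLAM-seq) — together with a deterministic ODE
simulator and a ground-truthed synthetic cohort generator used to validate
every estimator. It is aimed at computational biologists analyzing
perturbation experiments on transcription elongation.

## Models at a glance

* **ODE simulator** (`polkin.simulate`): polymerase density o_i (unlabeled)
  and b_i (labeled) per 1-kb window under initiation interval p (min),
  elongation rate e (kb/min), and processivity defect d (fraction/kb):
  do_i/dt = 1/p − e(1+d)·o_1 at the TSS window and e·o_{i−1} − e(1+d)·o_i
  beyond, with a labeled-channel variant during 4sU exposure. Solved
  exactly (linear birth chain). Occupancy = o+b; 4sU profile = suffix sum
  of b. Steady state: o_i ∝ (1+d)^(−i).
* **LFC regression** (`polkin.lfc`): per-window log2 fold changes between
  arms follow the beta log-odds density dlfc(x; (a_i+p_a)·dds+1,
  (c_i+p_c)·dds+1) with a piecewise-linear trend l(i) = o + s·min(i,b);
  the slope converts to the processivity defect 100·(2^(−s)−1) %/kb.
* **Termination regression** (`polkin.termination`): post-PAS counts ~
  NB(o·e^(−r·i), disp) on a 250-nt grid with a Gaussian prior on o from the
  pre-PAS level; decline reported as 100·(1−e^(−4r)) %/kb.
* **Wavefront regression** (`polkin.wavefront`): DRB-chase counts ~ NB
  around a triangular ramp reaching background at the wavefront b (an
  exponential-linear shape when the arm has a processivity defect);
  elongation rate = b / chase time, with an expression-dependent
  quantile-regression prior on the background.
* **SLAM kinetics** (`polkin.slam`): da/dt = σ − δ·a in closed form;
  per-arm fits of synthesis σ and degradation δ from new/old RNA levels
  (count·NTR, count·(1−NTR)) across 0/1/2/4 h.
* **Scores** (`polkin.scores`): completion score (log2 last-15% / first-15%
  of the gene body), readthrough score (log2 post-/pre-PAS density), and an
  empirical-Bayes moderated t test with BH correction.

See `docs/methods.md` for assumptions, priors, and numerical choices.

## Worked example

Simulate a DRB chase on an 80-kb gene at 3 kb/min, then estimate the
elongation rate back from the window counts:

```python
import numpy as np
from polkin.simulate import SimParams, simulate_experiment
from polkin.wavefront import fit_wavefront
from polkin.windows import WindowVector

params = SimParams(p=2.0, e=3.0, d=0.0, L=80.0, w=1/256)  # fine grid
prof = simulate_experiment(params, "drb", label_min=20).binned(1.0)
counts = np.round(prof.foursu / prof.foursu.max() * 1000)
fit = fit_wavefront(WindowVector("sim", "body_1kb", 1000, counts), chase_min=20.0)
print(f"wavefront {fit.b:.1f} kb -> {fit.elongation_rate:.3f} kb/min")
```

```
wavefront 60.0 kb -> 3.001 kb/min
```

The fitted wavefront sits at e·t = 60 kb, so the recovered elongation rate
matches the simulation input. The same closure with e = 1.5 returns
1.501 kb/min. Comparing steady-state occupancy of a d = 2 %/kb gene
against an unperturbed one with the LFC regression:

```python
from polkin.lfc import fit_lfc
from polkin.simulate import steady_state

occ_un = steady_state(SimParams(p=2, e=3, d=0.0, L=80))
occ_pr = steady_state(SimParams(p=2, e=3, d=0.02, L=80))
scale = 10_000 / occ_un[0]
fit = fit_lfc(WindowVector("g", "body_1kb", 1000, np.round(occ_pr * scale)),
              WindowVector("g", "body_1kb", 1000, np.round(occ_un * scale)))
print(f"slope {fit.s:.4f} log2/kb -> defect {fit.defect_pct_per_kb:.3f} %/kb")
```

```
slope -0.0286 log2/kb -> defect 1.999 %/kb
```

i.e. the fitted slope −log2(1.02) converts back to the simulated 2 %/kb
loss of polymerases.

An end-to-end synthetic run (cohort → fits → scores → summary table):

```bash
polkin run --out demo_run          # or: polkin synth --seed 0 --n-genes 100 --out demo_run
```

writes `summary.tsv` joining per-gene ground truth with the fitted defect
(%/kb), post-PAS decline (%/kb), elongation rate (kb/min), and
synthesis-rate fold change, plus a `manifest.json` recording stage status.

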