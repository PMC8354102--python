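# Methods

`polkin` quantifies five kinetic properties of RNA polymerase II
transcription — initiation, elongation rate, processivity, termination, and
RNA synthesis/degradation — from windowed nascent-transcription read counts.
This note documents the models, the estimators, the numerical choices, and
what the synthetic-data tests do and do not demonstrate.

## The polymerase-chain ODE

A gene of length L kb is discretized into windows of width w kb (default
1 kb). Three parameters govern the dynamics:

* `p` — mean time between successful initiation events (min); the source
  term is 1/p polymerases per minute entering window 1.
* `e` — elongation rate (kb/min); the forward hop rate out of a window is
  e/w per minute.
* `d` — processivity defect: the fraction of polymerases aborting per kb.
  Stored internally as a fraction (0.02), rendered as %/kb (2) only at
  reporting boundaries. The abortion rate is d·e per minute.

Each window carries unlabeled (`o_i`) and 4sU-labeled (`b_i`) polymerase
densities. In `no4sU` mode new polymerases are unlabeled and both channels
advect independently; in `4sU` mode the source feeds `b`, and an unlabeled
polymerase is converted to the labeled channel on its next hop (its nascent
RNA acquires labeled nucleotides), so `o` only decays at rate (e/w + d·e).

**Integration.** The system is a linear birth chain with an affine source,
so no numerical ODE solver is needed: starting from an empty gene the
solution is

    o_i(t) = (1/p)/(a+mu) * (a/(a+mu))^(i-1) * P(i, (a+mu) t),

with a = e/w, mu = d·e and P the regularized lower incomplete gamma
function; propagation of an arbitrary initial state is a convolution with a
Poisson(a·t) kernel damped by e^(-mu t). In 4sU mode the total o+b obeys the
same chain (continuity across mode switches is exact) and o decays in place.
A dense matrix-exponential backend (`backend="expm"`) is retained purely as
an independent cross-check; the two agree to ~1e-15 relative error, far
inside the 1e-8 contract. At equilibrium (1000 min of no4sU mode, checked
against the closed form; a warning is raised if not converged)

    o_1 = (1/p) / (e(1+d)),   o_i = o_1 (1+d)^(-(i-1))     (w = 1).

**Read-outs.** Occupancy (ChIP-like) is o+b per window. The pulse/DRB "4sU
profile" is the suffix cumulative sum of b: a transcript whose polymerase
sits at window j covers all windows i ≤ j. Windows are indexed 1..L with
window 1 at the TSS.

**Discretization diffusion.** The compartment chain is an advection model
with numerical diffusion: after a DRB chase of t minutes the front, ideally
a step at e·t kb, is smeared with standard deviation sqrt(e·t·w) kb. At
w = 1 kb this is ~8 kb for a 20-min chase at 3 kb/min — large enough to bias
any front estimator fit to the w=1 profile by several windows. Closure tests
therefore simulate at fine discretization (w = 1/256 kb, smear < 0.5 kb) and
aggregate to 1-kb windows before fitting; `front_window` defaults to a
half-maximum criterion, which is where the physical front sits (an absolute
1e-6-of-maximum threshold lands in the diffusion tail instead and is not a
usable front locator on this model).

## Window systems and counting

Coordinates are 0-based half-open; window vectors are oriented 5'→3' in
transcription direction. Gene bodies are tiled with non-overlapping 1-kb
windows from the TSS (partial terminal windows dropped so every window has
identical exposure); termination grids tile PAS−5 kb .. PAS+25 kb in 250-nt
windows (20 upstream + 100 downstream). Windows overlapping an exon are
flagged missing; on the termination grid two further rules apply: a TU
shorter than 5 kb has all upstream windows flagged, and a same-strand
neighbor TU starting within 25 kb flags everything from its TSS on.
Spike-in size factors are per-sample totals divided by their median. ChIP
input subtraction may produce negative window values; these are retained in
the tables and 0-censored (then rounded half-to-even) only when an
integer-support likelihood is evaluated.

All regression models are evaluated at window *centers* (position i−0.5 in
window units): a window count approximates the profile at its midpoint, and
using the right edge instead biases front estimates by +0.5 windows
(verified on exact triangular profiles). Slopes and rates are unaffected by
this choice; intercepts refer to position 0 (the TSS or PAS).

## LFC regression (processivity)

For paired treated/control counts a_i, c_i the local log2 fold change
follows the beta log-odds density

    dlfc(x; α, β) = 2^(xα) ln2 / (B(α,β) (1+2^x)^(α+β)),

with α = (a_i+p_a)·dds+1, β = (c_i+p_c)·dds+1, library-proportion
pseudocounts p_a = s_a/(s_a+s_c), p_c = 1−p_a, and a downsampling factor
dds ∈ [1e-3, 1] that models overdispersion by flattening the implied LFC
density. The trend is piecewise linear, l(i) = o + s·min(i, b). The fit
maximizes the total log likelihood over (o, s, log b, log dds) by
multi-start L-BFGS-B (turning-point starts at L/4, L/2, 3L/4; ties broken
toward the smaller |s|), with confidence intervals from the central-
difference Hessian (step 1e-4·max(1,|θ|); non-positive-definite Hessian →
no CI). For genes that are linear to the end the turning point is
unidentified (b at the gene boundary flattens that likelihood direction);
the Hessian is then recomputed with b profiled out so the slope CI remains
available. A fit is "accurate" when the 95% CI of the per-kb defect is
narrower than 1 %/kb — the same gene-inclusion rule used for cohort
medians, which are additionally restricted to genes longer than 25 kb
(short noisy genes otherwise inflate the median; this mirrors how the
original analysis was restricted).

The slope converts to a processivity defect as 100·(2^(−s)−1) %/kb (the
geometric steady state gives s = −log2(1+d) exactly); the signed form
−100·(1−2^s) is also emitted.

## Termination regression

Post-PAS counts follow NB(mean o·e^(−r·i), size disp) on the 250-nt grid,
i in window units from the PAS. The level prior is Gaussian with the mean
and sd of the upstream windows (falling back to the first five downstream
windows when all upstream are missing; a degenerate sd is widened to
0.1·m+1), weighted by the number of usable windows n so prior and
likelihood carry equal weight. A noise cutoff flags everything after the
first run of four consecutive windows below 1% of the PAS level.
Optimization is multi-start L-BFGS-B over (log o, log r, log disp) with
r-starts {0.01, 0.05, 0.2}. The decline is reported per window, in nats/kb
(r/0.25), and as the survival form 100·(1−e^(−r/0.25)) %/kb, which is the
default printed unit (r = 0.0558/window ↦ 20.0 %/kb).

## DRB wavefront regression (elongation rate)

Window counts along the gene body after a DRB chase follow the same NB
likelihood with mean

    w(i) = (o + (bg·2^(−r·b) − o)/b · min(i,b)) · 2^(r·min(i,b)),

the triangular ramp from o at the TSS to the background bg at the wavefront
b for r = 0, multiplied by an exponential decay for r < 0 (r is fixed to
the gene's LFC slope in the treated arm, 0 in the control arm; genes
without an accurate LFC fit are dropped from treated-arm fits). The first
5 kb are masked (promoter-proximal peak). The background prior is Gaussian
on log bg with 5%/95% quantiles predicted by a quantile regression
(statsmodels `QuantReg`, pinball loss) of log background density — intronic
density in the last 5 kb of >150-kb genes — on log expression; the Gaussian
is recovered from the two quantiles via mean = midpoint and
sd = span/3.29 (the 5–95% span of a normal is 3.29 sd). Multi-start over
wavefronts implied by 1–4 kb/min. The elongation rate is b/chase_min with
no pause-offset correction; fits with b within half a window of either
bound are flagged `at_boundary` and excluded from cohort summaries.

## SLAM kinetics (synthesis and degradation)

Total RNA obeys da/dt = σ − δ·a, giving f_old,ctrl = (σ/δ)e^(−tδ),
f_old,aux = a0·e^(−tδ) (non-steady state after depletion), and
f_new = (σ/δ)(1−e^(−tδ)) in both arms. Counts are normalized by
median-of-ratios size factors; per-sample new/old levels are count·NTR and
count·(1−NTR). Fits minimize equally weighted residuals over (log σ,
log δ) (scipy bounded least squares, started from a log-linear decay
regression of the old-RNA levels); the treated arm fixes a0 to the mean
old-RNA level at t = 0. New-RNA points at 2 h and 4 h are excluded in both
arms (prolonged labeling depresses apparent new-RNA levels), so degradation
rates draw on all timepoints and synthesis rates effectively on the 1-h
new-RNA level plus the degradation rate; this joint fit with exclusions is
the default, and the exclusion list is configurable. Confidence intervals
use the quadratic approximation at the optimum (residual-scaled J^T J).
Single-timepoint data raise rather than returning defaults; δ at its bound
is flagged unconverged. Arm comparisons report σ_ctrl/σ_aux and its log2;
cohort averages of fold changes use the geometric mean (the arithmetic mean
of ratios is inflated by estimation noise in the denominator).

## Scores and the moderated test

Expressed genes: length > 5 kb and the sum of 150-bp bin read densities
over PAS±5 kb strictly greater than 4; for multi-TSS genes the longest unit
is used. The completion score is log2((distal+ε)/(proximal+ε)) over the
first/last 15% of length-normalized body bins; the readthrough score is the
log2 ratio of post-PAS (PAS+5..+15 kb) to pre-PAS (PAS−5..PAS for 4sU,
PAS−3..PAS for ChIP) read *densities* — densities rather than raw sums
because the two windows have different widths (ε = 1 normalized count on
sums, scaled by span for densities). Z-scores are computed on the anti-log
(2^score) scale with the sample (n−1) standard deviation. Differential
calls use an empirical-Bayes moderated t test: per-gene pooled variances
are shrunk toward a prior fitted by moment matching on log variances
(digamma/trigamma inversion); prior df 0 reduces to the ordinary two-sample
t test; p-values are BH-adjusted. This is a self-contained moderated test
in the limma style, not a reimplementation of limma, and it is not expected
to reproduce limma's exact p-values.

## TU annotation

TSS candidates (CAGE-like peaks plus transcript 5' ends) that leave more
than 50% of the gene's intronic signal upstream are removed (exactly 50%
is kept); among survivors the largest mean-coverage increment d_i−u_i wins,
ties to the 5'-most. PAS calls smooth the 3'-end read-start profile with a
Gaussian kernel (bandwidth read as sd = 20 nt), renormalized per source
point at the boundaries so total mass is conserved, and take the 3'-most
position p above 1% of the peak. An annotated PAS within 150 nt of p is
preferred; the window is symmetric because smoothing pushes the threshold
crossing ~3 sd past a sharp peak, which would otherwise defeat the match
against an annotation at the true cleavage site. Without a match the PAS is
p+100 nt. The searched span defaults to the annotated gene span + 10 kb.

## Synthetic cohort: what it emulates

`SynthConfig` defaults define the validation conditions: 300 genes,
log-uniform lengths 5–200 kb, initiation interval 2 min, control elongation
3 kb/min with the treated arm at 75%, control processivity defect 0 with
the treated arm at 1 %/kb, termination rates lognormal around 0.0558 per
250-nt window (≈20 %/kb survival) halved in the treated arm, NB window
dispersion uniform on [5, 10], triplicates, DRB chases at 10/20/30 min,
and SLAM timepoints 0/1/2/4 h with an 8-fold treated-arm synthesis
reduction. Per-gene/assay/arm/replicate random streams are derived from the
seed, so cohorts are bit-reproducible.

Gene-body 4sU window means are proportional to steady-state occupancy
(labeled nucleotides deposited in window i during a pulse scale with the
polymerase flux through it), which makes the 4sU and occupancy LFC slopes
identical — the behavior observed on real data. The simulator's suffix-sum
profile instead models whole-transcript capture; on a finite gene its LFC
against control is flatter than −log2(1+d), so it is used for the DRB
read-out (where the chase products are the labeled transcripts) but not for
gene-body 4sU counts. SLAM counts are per-TU totals: their NB size is the
per-window dispersion times the number of windows, since window-level
overdispersion averages out when summed over a gene; NTR noise is
Beta-distributed with concentration proportional to the read count (NTR is
estimated by classifying reads), floored at 20.

What passing these tests shows: the estimators invert the generative models
they assume, at realistic depths and dispersions, without systematic bias.
What they do not show: robustness to mappability artifacts, exon
contamination beyond masking, non-exponential termination, transcription
units with internal initiation, or mis-specified NTR posteriors — none of
which the generator emulates.

## Problem sizes

Closure tests run on a single 80-kb gene in well under a second. The
recovery suite uses one 300-gene cohort (the default size; large enough for
stable medians, small enough that the whole test suite completes in about a
minute). The pipeline's default demonstration cohort is 100 genes.

## Known limitations

* Pausing and pause-release kinetics are not modeled (no promoter-proximal
  peak in simulated profiles; real DRB data get the first 5 kb masked
  instead).
* The elongation rate is b/chase_min with no pause-escape offset; absolute
  rates inherit that convention.
* Stochastic single-polymerase behavior (traveling-wave broadening beyond
  compartment diffusion) is out of scope.
* Post-PAS transcript stability is not separated from termination: a
  slower apparent decline can reflect either.
* The moderated test is a stand-in with the same shrinkage structure as
  limma but simpler prior estimation.
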