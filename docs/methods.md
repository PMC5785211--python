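# Methods

## The biological problem

*Synechococcus elongatus* PCC 7942 schedules a large cohort of "dusk
genes" to peak before nightfall. Two OmpR-family response regulators
drive this program: RpaA~P, the output of the KaiABC clock, ramps from
dawn to dusk regardless of light fluctuations; RpaB~P responds to light
inversely and within minutes (falling roughly 3.1-fold after a
high-light step, rising roughly 1.9-fold after a shade step, and rising
roughly 1.7-fold over the sunset decline of a clear day). The package
implements the full analysis chain around this system: circadian
classification of expression time courses, clustering of dusk genes into
Early/Middle/Late waves, ChIP enrichment of RpaA/RpaB/RNA polymerase at
promoters, and phenomenological ODE models of the cluster dynamics —
plus a seeded synthetic-data generator that emulates every input.

## The cluster model

Each dusk cluster is coarse-grained to one effective gene X (0-1 scaled
mean expression) obeying an AND-gate promoter model

    dX/dt = B + beta * prod_i f_i(u_i(t)) - alpha * X

with activating Hill terms f(u) = (u/K)^H / (1 + (u/K)^H) and repressing
terms f(u) = 1 / (1 + (u/K)^H). Inputs u_i are *measured* series
(RpaA~P, RpaB~P, or another cluster's expression for the feedback
variants), normalized to [0, 1] jointly across the four light
conditions, interpolated piecewise-linearly between sample times, and
treated as exogenous — feedback sources are never co-simulated. Variants:
single-regulator (5 free parameters), joint RpaA+RpaB (7), joint plus
one feedback term (9).

Parameter bounds (the fitting box): H in [0, 7], beta and alpha in
[0, 80] per hour, B in [0, 10] per hour, K in [0, 1] (normalized
expression units). Degenerate Hill conventions keep the objective
continuous on the closed box: H = 0 gives f = 1/2 for both modes (the
(u/K)^0 = 1 limit with 0^0 = 1); K = 0 with u > 0 gives 1 (activation)
or 0 (repression); u = K = 0 gives 1/2. Both forms are evaluated as a
logistic of H*(ln u - ln K), which is numerically stable over the whole
box and makes activation + repression = 1 an exact identity.

### Numerical integration

Given exogenous inputs, the ODE is linear in X, so the default solver is
an exponential (phi-function) integrator: production is evaluated on a
fixed fine grid (default step 0.005 h), assumed piecewise-linear within
a step, and propagated exactly through the linear recurrence
X_{k+1} = e^(-alpha h) X_k + c_k (evaluated as an IIR filter). This is
unconditionally stable even at the decay-rate bound (alpha = 80/h, where
explicit adaptive steppers are stability-limited) and costs well under a
millisecond per trajectory, which is what makes multi-start fitting and
the repeated model-comparison harnesses cheap. An adaptive RK45 solve
(rtol 1e-6, atol 1e-9) is available as `method="rk45"` and serves as an
independent cross-check in the test suite, alongside a fixed-step Euler
oracle at dt = 1e-4 h.

### Fitting and model comparison

Fits minimize the concatenated residuals of the Clear Day and Shade
pulse conditions simultaneously (one shared parameter vector; each
condition is simulated from its own first observation). Fitting all four
conditions jointly is deliberately not a supported result. The optimizer
is trust-region-reflective bounded least squares started from a seeded
Latin hypercube inside the box (default 64 starts; the recovery and
ordering harnesses use 12-16, which suffices at their problem sizes);
the best converged start wins and the fit is bit-wise reproducible given
(seed, n_starts). The reported error is sqrt of the summed squared
deviations over all fitted conditions and times. Variants are compared
with the least-squares AIC, n*ln(RSS/n) + 2k, k being the number of free
parameters; with the reported Early-cluster errors (0.85, 1.01, 0.41,
0.21 for the two single-regulator fits, the joint fit and the best
feedback fit) this ranks the feedback variant first for any plausible
residual count. Residuals are unweighted across conditions and times.

The encoded reference parameter tables include one degenerate published
row (the RpaB-only Middle fit, whose decay rate is unresolved); it is
excluded because no finite parameter set reproduces it.

## Expression analysis

* **Normalization.** Counts are median-normalized per sample — each
  sample scaled so its median over genes nonzero in every sample equals
  the grand median (median of per-sample medians) — then divided by ORF
  length, giving normalized reads per nucleotide. Any fixed target
  median would do equally well: the choice shifts all values by one
  global constant and cancels from every downstream log-ratio.
* **Relative expression.** log2 of expression over the gene's mean in a
  reference condition, with a pseudocount of half the smallest nonzero
  value applied symmetrically.
* **Cosinor.** The classical single-component cosinor: linear least
  squares on {1, cos(2 pi t/24), sin(2 pi t/24)}, amplitude =
  sqrt(a^2 + b^2), acrophase in degrees = the fitted peak time mapped by
  360/24, with 0 degrees at subjective dawn. The period is fixed at
  24 h. The amplitude threshold (0.15) is applied to the log2-scale
  amplitude; whether the original analysis used log2 or linear amplitude
  is not determinable, and log2 is assumed.
* **Classification.** dawn = amplitude > 0.15, acrophase in [40, 189]
  degrees, and at least one normalized read per nucleotide in at least
  one sample; dusk = the same filters with acrophase in [190, 360) or
  [0, 39]. Boundaries are inclusive as printed; the one-degree gaps
  (39-40, 189-190) fall to non-circadian.
* **Clustering.** Sample blocks are z-scored per gene (sample sd,
  ddof 1; zero-variance genes are excluded and logged), then k-means
  with Pearson correlation distance d = 1 - r, k = 8 by default, with
  the member-mean centroid re-standardized to zero mean and unit norm,
  empty clusters re-seeded from the farthest point, and the best of the
  seeded restarts kept. The three largest clusters are named
  Early/Middle/Late by the first time their 0-1 scaled Low Light mean
  crosses 0.5 (linearly interpolated); ties for third place break toward
  earlier activation.
* **Unit scaling.** (x - min)/(max - min) with min/max pooled jointly
  over all four conditions, applied identically to cluster means and to
  regulator levels.

## ChIP analysis

Per-base IP and mock coverage is smoothed with a unit-mass truncated
Gaussian kernel (window 400 bp, sd 50 bp; circular wrap on the circular
chromosome). The peak caller is deliberately simple: IP is library-size
scaled to the mock total, the mock is floored at the 5th percentile of
its nonzero values (ratios against near-zero mock are unstable), and
peaks are maximal runs of IP/mock >= 3.5 at least 50 bp wide, with the
summit at the leftmost argmax of IP and runs that span the origin merged
by rotation. A peak is kept iff its interval overlaps a replicate-2 peak
by at least 1 bp (coordinates reported from replicate 1). This caller
implements exactly the printed criteria (Gaussian smoothing, 3.5-fold at
the summit, detection in both replicates); it is not a reimplementation
of Peak-seq, and no FDR is computed.

Gene targets follow three rules evaluated per strand: the start codon
(gene start on +, gene end on -) within 500 bp of the summit, inclusive;
the summit 5' of the start codon on the gene's strand; and the gene the
closest on its strand to the summit. Distances wrap on circular genomes;
a peak may target one gene per strand (divergent promoters). Coordinates
are 1-based inclusive in GFF3, 0-based half-open internally and in
bedGraph/BED output.

Per peak-gene pair and condition, the analysis pairs the log2 change of
summit enrichment with the log2 change of the linked gene's expression
between the same time points and reports the Pearson correlation per
condition (zero-variance columns yield NaN with a warning).

## The synthetic-data generator

The generator defines the study conditions; its defaults are fixed, not
tuning knobs.

* **Light.** Four 12-h profiles on a 3-minute grid: Low Light constant
  50 umol photons m-2 s-1; Clear Day 600*sin(pi t/12) (smooth, unimodal,
  peak 600 at hour 6 — a half-sine stand-in for measured irradiance);
  Shade pulse = Clear Day / 10 on [8, 9) h; High Light pulse = Clear Day
  values on [8, 9) h over a Low Light baseline.
* **Regulators.** RpaA~P is a logistic ramp 0.2 -> 1.0 (arbitrary raw
  units) centered at hour 6, identical in all conditions. RpaB~P is a
  baseline multiplied by the pulse responses (reaching 1/3.1 or 1.9
  log-linearly over 15 min, held through the pulse, relaxing back with a
  30-min exponential — the data show reversibility but no rate) and by a
  geometric 1.7-fold rise from hour 10 to 12 of the Clear Day. Raw
  scales are arbitrary because all downstream use is after joint 0-1
  scaling. Deterministic by default so the stated fold changes are exact.
* **Clusters.** Forward simulations from the encoded reference
  parameter sets, sampled at the default measurement times (2-h grid
  plus 15 and 60 min after the hour-8 pulse onset), 0-1 scaled jointly
  across conditions, plus i.i.d. Gaussian noise (default sd 0.05)
  clipped at zero. Feedback inputs are the source cluster's *sampled*
  scaled series, linearly interpolated — the same representation the
  fitter consumes, mirroring the use of measured Y. Because Middle and
  Late feed back on each other, generation is staged: Late is first
  simulated without feedback to provide a measured series, Early and
  Middle are generated against it, and Late is then regenerated from
  its feedback variant driven by the Middle series.
* **Counts.** Per gene, log2 reads-per-nucleotide follows a planted
  cosinor curve plus Gaussian noise; counts are Poisson around the
  per-nucleotide mean times ORF length times a per-sample scale factor
  (exercising median normalization). Planted classes default to 7%
  dawn / 13% dusk / 80% non-circadian — the rhythmic minority of a real
  transcriptome; a rhythmic majority would make the per-sample gene
  median itself oscillate and leak a common-mode rhythm into every
  normalized gene. Planted acrophases keep a margin from the 39/40 and
  189/190 class boundaries (dawn U(50, 180); dusk U(200, 350) or
  U(0, 30)) so the planted truth is unambiguous under count noise, and a
  small fraction of genes is planted below the one-read-per-nucleotide
  filter. The count series is labelled "ConstantLight" and sampled over
  a full cycle (0-22 h), matching how circadian phases are defined.
  Genes are laid head-to-tail with 100-bp gaps on a circular 2.7-Mb
  fixture chromosome.
* **ChIP tracks.** Mock = flat background plus Gaussian noise; IP =
  background times 1 + (fold - 1) * Gaussian bump around each planted
  summit, with replicates sharing summits and drawing independent
  noise. Overlapping planted bumps are rejected. Smoothing attenuates a
  bump of width w by w/sqrt(w^2 + 50^2); at the default widths
  (150-200 bp) a planted 4-fold bump stays above the 3.5 threshold and
  a 3.4-fold bump stays below it.

### What the synthetic data does not emulate

No sequencing-read simulation, alignment artifacts, rRNA depletion or
library-composition biases beyond per-sample scale factors; no
photophysiology behind the RpaB~P response; no stochastic transcription;
ChIP backgrounds are flat rather than structured. Passing the recovery
tests therefore demonstrates the correctness and self-consistency of the
analysis chain on data with the assumed structure, not performance on
raw sequencing data.

### Problem sizes

The test and acceptance harnesses run at desk scale: 300-gene count
matrices, 60-gene clustering fixtures, 200-kb ChIP fixtures, 16 fit
starts for recovery and 12 for the ten-repeat ordering harness. These
sizes keep full runs in the minutes range while leaving wide margins on
every threshold; all scale linearly if enlarged.

## Reproducibility

Every generator and fit is a pure function of its arguments and a seed;
k-means restarts, Latin-hypercube starts and noise draws all derive from
explicit seeds, and the pipeline manifest records the config hash, seeds
and output checksums (its deterministic section reproduces bit-wise on
re-run).

## Known limitations

* The original study's genome-wide tallies — 450 high-confidence
  circadian genes (169 dawn, 281 dusk), 114 RpaA / 218 RpaB / 451 RNAP
  peaks, and derived counts such as 159/281 genes two-fold induced after
  midday — are **not reproducible** from this package: they depend on
  the study's raw sequencing data, on constant-light phases inherited
  from an earlier dataset, and on an unpublished Peak-seq variant for
  peak calling. The package reproduces the *procedures* and validates
  them on planted-truth synthetic data instead.
* Refitting the published parameter tables against the study's own
  scaled cluster means requires the deposited source-data files and is
  not attempted offline.
* Cluster model parameters are generally non-identifiable (sloppy): the
  recovery criterion is trajectory agreement, not parameter agreement.
* The amplitude threshold's scale (log2 assumed) and the exact residual
  count behind any published AIC comparison are undetermined from the
  printed record; AIC conclusions are reported as rankings only.
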