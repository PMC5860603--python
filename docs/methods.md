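# Methods

`segmix` performs semi-automated genome annotation: it partitions a
genome into `K` labelled segments from one or more real-valued signal
tracks (ChIP-seq or DNase-seq style coverage), with no supervision. This
note describes the model, the training and evaluation procedures, the
synthetic genomes used for verification, and the numerical and design
choices a maintainer would want to know about.

## The model

Hidden state. Each genomic bin (at resolution `r` base pairs) carries a
hidden label `l ∈ {0..K−1}`. Labels follow a first-order Markov chain
with initial distribution `π` and transition matrix `A`; the diagonal of
`A` is the dwell probability, so segment lengths are geometric. Two
length constraints are layered on top:

* **Hard minimum `m` (bins).** Each label is expanded into `m` duration
  phases: a segment enters at phase 0, advances deterministically one
  phase per bin, and only the final phase may switch label. The chain is
  thus an HMM over `K·m` states. At chunk boundaries the constraint is
  relaxed — the chain starts in the final phase and may end mid-phase —
  so a segment truncated by a chunk edge is legal and chunked inference
  composes over the genome.
* **Soft expected length `L` (bins).** The dwell probability is
  initialized to `1 − 1/L`, and an optional prior with the same mean can
  be added to the transition M-step as pseudocounts
  (`TrainingConfig.transition_prior`, default 0).

Emissions. Given label `l`, track values are independent across tracks;
track `t` emits from a `C`-component Gaussian mixture with weights
`w[l,t,c]`, means `μ[l,t,c]`, and variances `σ²[t,c]` **tied across
labels** — there are `C` mean parameters per track–label pair but only
`C` variances per track. With `C = 1` this reduces to a single Gaussian
per track–label pair with one variance per track, which can additionally
be frozen (`freeze_variance`) to keep a fixed track variance throughout
training. Missing cells (bases with no coverage) are marginalized out:
they contribute nothing to the emission density, no imputation occurs.

All inference — forward–backward for the E-step and marginal
likelihood, Viterbi for decoding — runs in the natural-log domain. The
recursion step is computed as `log(exp(u − max u) @ A) + max u`, which
is algebraically log-sum-exp; no probability-domain scaling is used, so
underflow is impossible by construction. Viterbi ties break toward the
lowest state (hence lowest label) index, deterministically.

## Training

The genome is binned, cut into fixed-size chunks (`chunk_size` bins,
default 500; chunks never span chromosomes), and a held-out validation
set of whole chunks is drawn once — uniformly at random without
replacement until it first reaches `validation_fraction` of the genome's
bins (default 1.5%). Validation chunks are excluded from all training.
Whole chunks are used so training and validation likelihoods share the
same inference unit.

Two region regimes:

* **Fixed.** Each instance samples one region set (``training_fraction``
  of the genome) at round 0 and runs EM on it every round. Training
  likelihood is monotone non-decreasing; the instance may stop early
  when the relative change stays below `convergence_tol` (default 1e-5)
  for two consecutive rounds. The risk is overfitting the fixed region.
* **Minibatch.** Every round draws a fresh random region set of the same
  fraction (default 1%), so over many rounds training effectively
  samples the whole genome at the memory cost of one region. There is no
  convergence guarantee, so model selection is by validation: after
  every round the updated parameters are scored on the held-out set, and
  the final parameters are those of the (instance, round) pair with the
  highest validation log-likelihood over the whole run — not necessarily
  the last round.

Within a round, the region set is fitted with `em_iterations` full E–M
sweeps (default 5). This is still exact EM — each sweep increases the
region-set likelihood, so fixed-regime monotonicity is preserved — but
it converges in far fewer rounds when each round sees only a few percent
of the genome; with a single sweep per round, small-fraction training
needs roughly twice as many rounds to reach the same parameters. The
`em_round` function itself performs one sweep.

M-step (exact maximum likelihood by default): means are
responsibility-weighted averages per (label, track, component);
variances are pooled across labels per (track, component), with a floor
of 1e-4 times the global per-track data variance; weights come from
component responsibilities; transitions from expected free-transition
counts (deterministic phase advances excluded). Optional Dirichlet
pseudocounts on weights (`weight_pseudocount`) and the length prior
(`transition_prior`) are available but default to 0: with nonzero
priors the update is maximum a posteriori, which is monotone in the
penalized objective but not in the data likelihood, and exact-EM
monotonicity is a property we verify. Component death is handled
structurally instead: a label whose total responsibility falls to zero
is re-seeded by a deterministic, seeded perturbation around the live
labels' means (logged, never a crash).

Initialization per instance: component means at jittered random
quantiles of the per-track data, variances at the per-track data
variance, uniform weights, dwell `1 − 1/L`, uniform off-diagonal
transitions and initial distribution.

Likelihoods are reported per bin (nats/bin), dividing by the total bin
count of the scored regions (bins with all tracks missing contribute
0 nats but stay in the denominator). Per-bin units make rounds with
different region sizes and the validation set directly comparable; a
total-likelihood trace is the per-bin value times the region size.

Reproducibility: one master seed drives every random draw through named
child streams (`split`, `init[i]`, `batch[i][round]`, ...), so adding
instances or rounds never perturbs existing draws, and a fixed seed
yields bit-identical parameters, traces and BED output.

Interpretation choices where the procedure was open: the held-out
quantity is the data log-likelihood of the learned parameters on the
validation chunks; validation regions are random whole chunks rather
than a contiguous block; mixture weights are learned per (label, track)
pair; the winner is the global argmax over all instances and rounds.

## Annotation and evaluation

Decoding runs Viterbi per chunk with the winning parameters; per-bin
paths are concatenated in genome order and equal-label runs are merged
into maximal segments, including across chunk joins within a chromosome.
The merge is cosmetic — inference is chunked, so boundaries that
coincide with chunk joins are approximate. Output is BED4 with 0-based
half-open coordinates.

Distribution fit. For each label, the empirical distribution of the
track values assigned to it (all datapoints, bins weighted equally; an
optional seeded cap exists for speed) is compared with the label's
theoretical mixture CDF using the one-sample Kolmogorov–Smirnov
statistic `D = max_i max(i/n − F(x_(i)), F(x_(i)) − (i−1)/n)`; smaller
is better. Mean, median and best (minimum) `D` are reported across
labels, plus quantile–quantile points for plotting. `D` is computed on
the same values the model was trained on (no transform is applied).

TSS discrimination. Each label's segments are treated as predictions of
active transcription start sites. Inputs are two BED files of
single-base TSS positions — positives with independent activity support
(e.g. CAGE), negatives without — already reduced to one most-upstream
TSS per gene (a strand-aware helper over gene records is provided:
minimum start on `+`, maximum end on `−`). Per label, TP/FP/FN counts,
precision and recall are reported; the label with the best precision is
selected and its recall reported alongside. TSSs not covered by the
annotation are counted and reported, never dropped.

## Synthetic genomes

The generator draws a label path from the length-constrained chain,
emits per-bin values from the label's mixture, injects missing cells
completely at random, and writes the same text formats the tool reads
(bedGraph per track, chromosome sizes, truth BED, parameter JSON), so
parser round trips are part of the verified surface.

Ground-truth models place the `K·C` component means per track on a grid
with spacing `mean_separation` (default 3) times the largest component
standard deviation, randomly assigned to labels; within each label,
component means are sorted by component index, so component `c` is
consistently the label's `c`-th intensity tier. The sorting matters
because variances are tied across labels per (track, component): with
arbitrary mode-to-component assignment the tying pattern is
combinatorially ambiguous and the model is effectively unidentifiable —
estimation can settle into wrong-tying optima with biased means — while
the intensity-tier convention mirrors how mixture components are
actually used on signal data (background vs enrichment tiers).
Variances are drawn uniformly in [0.5, 1.5] squared signal units;
weights from a symmetric Dirichlet(5), so components are moderately but
not perfectly balanced.

Two presets target specific claims:

* **Bimodal** (`bimodal_params`): one track, each of `K = 3` labels a
  balanced two-component mixture, 2K well-separated modes in total. A
  single-Gaussian emission model cannot devote one label per mode at
  this `K`, so its per-label fit is measurably worse than a
  two-component fit. (With many labels and one track, a single-Gaussian
  model could tile the modes label-by-label and the contrast would
  vanish; the preset deliberately keeps `K` below the mode count.)
* **Block-heterogeneous** (`simulate_heterogeneous`): the genome is
  split into chromosomes that each use only a two-label subset of the
  repertoire. Any fixed region of a few chunks misses most of the label
  diversity while the validation set spans all blocks — the situation in
  which minibatch training outperforms a fixed region.

What the generator does not emulate: spatial autocorrelation of signal
within segments, heavy right tails and nonnegativity of real coverage,
mappability and copy-number artifacts, or structured missingness.
Passing tests on these genomes therefore demonstrate correctness of the
inference and training machinery under the model's own assumptions, not
performance on real chromatin data.

## Verification experiments and problem sizes

The `experiments` module re-runs the full pipeline under fixed study
conditions; `scripts/acceptance.py` executes them and writes the
measured numbers. Sizes are chosen to leave each effect far from its
decision threshold while completing in minutes on one core:

* Exact inference vs brute-force path enumeration: ≥200 random models,
  K ≤ 3, C ≤ 2, ≤8 bins, hard minimum up to 3.
* EM monotonicity: 20 random genomes (1000 bins each), 50 fixed-regime
  rounds, largest per-round decrease ≤ 1e-9 nats/bin.
* Parameter recovery: one 10⁵-bin chromosome at 10 bp, 2 tracks,
  3 labels, 2 components at 3σ separation, expected length 50 bins, 5%
  missing; minibatch fraction 0.05, validation 0.05, 30 rounds,
  2 instances. Measured: Hungarian-matched bin accuracy, worst component
  mean error in units of the true component SD, worst relative variance
  error.
* Minibatch vs fixed: 11 seeds on block-heterogeneous genomes
  (4×10⁴ bins), equal fractions, median winner validation likelihood.
* Mixture benefit: 11 seeds on bimodal single-track genomes
  (2×10⁴ bins), mean per-label KS D of C=1 vs C=2 fits.
* KS null calibration: 100 draws of n = 10⁴ from the model's own
  mixtures against the 1% critical value 1.63/√n.

## Numerical details and limitations

* Variance floor 1e-4 × per-track data variance, applied every M-step.
* Mixture quantiles by bracketed Brent root finding on the mixture CDF
  (tolerance 1e-12); QQ probabilities at `(i − 0.5)/n`.
* bedGraph/wiggle binning: a bin's value is the coverage-weighted mean
  of the bases covering it; a bin covered by exactly one interval takes
  that interval's value directly, so constant coverage round-trips
  bit-exactly. Overlapping input intervals are a hard error.
* Viterbi and argmax ties resolve to the lowest index; BED output is
  byte-stable for identical inputs.
* Winner selection bounds parameter precision. Each round's parameters
  carry the sampling noise of that round's region set (σ/√n_c per
  component), and the returned winner — the argmax of validation
  likelihood over all (instance, round) candidates — additionally
  inherits the validation set's own maximum-likelihood deviation from
  the generating values, amplified by selection over many candidates.
  At the recovery-experiment sizes (5% validation, ~60 candidates) the
  worst matched component-mean error lands around 0.05–0.2σ depending
  on seed even though full-data EM reaches ~0.03σ; tightening it would
  require a larger validation fraction or averaging over rounds, not a
  better optimizer.
* The phase expansion realizes "geometric plus hard and soft length
  constraints" in the standard way, but it is one concrete choice;
  other segment-duration mechanisms (duration tables, rulers) would
  differ in detail.
* Chunk-level Viterbi is exact per chunk but not genome-global;
  segments touching chunk joins can differ from a hypothetical
  whole-chromosome decode.
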