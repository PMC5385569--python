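# Methods

## Model

A chromosome is a sequence of L bins of 200 bp (roughly one nucleosome each),
with a binary observation vector x_i ∈ {0,1}^M per bin (M chromatin marks,
presence/absence). The hidden state of bin i is a pair π_i = {j, μ}: a
nucleosome-level state j ∈ {1..K_n} and a domain-level state μ ∈ {1..K_d}.

Assumptions:

1. *Markov property* for the joint state chain and *independence of
   observations* given the states, as in a standard HMM.
2. *Emissions depend only on the nucleosome-level state*, as a product of
   independent Bernoulli variables per mark:
   e_k(b) = Π_m E[k,m]^{b_m} (1−E[k,m])^{1−b_m}. (A multinomial over the 2^M
   patterns would be strictly more expressive; the product-Bernoulli is the
   convention of single-scale chromatin-state models and keeps the parameter
   count at K_n·M.)
3. *Nucleosome transitions are domain-dependent*: t^{(ν)}_{jk} is the
   probability of stepping j→k under the **destination** domain ν. The
   destination convention matters only at block boundaries, where source and
   destination may differ; it is applied consistently in sampling, inference
   and re-estimation, so the sampler and the recursions are exact adjoints.
4. *Block restriction*: the domain state is constant on blocks
   [b·D_S, (b+1)·D_S) and can change only on the step entering a block. In
   0-based indexing, the step into bin i permits a domain change iff
   i % D_S == 0 and i > 0. The composite transition is
   δ^{μν}·t^{(ν)}_{jk} off boundaries and T_{μν}·t^{(ν)}_{jk} at them.
   Consequently no domain segment can be shorter than D_S·bin_size (4 kb at
   the defaults) except a trailing partial block at a chromosome end, which
   is annotated, not dropped.

Initial probabilities are stored as a full joint matrix P0 (K_n × K_d); a
factorized form would be a special case and the Baum–Welch update estimates
the joint object anyway.

## Inference

Scaled forward recursion over the joint space with per-position normalizers
s_i (the rescaled forward rows sum to 1; Σ_i log s_i is the log-likelihood).
The backward variables are rescaled with the same factors, with
β̂_{L-1} = 1 and a division by s_{i+1} per step, so that
Σ_{j,μ} α̂_i β̂_i = 1 at every position and the product α̂·β̂ *is* the joint
posterior γ_i(j, μ). Pair marginals ξ_i follow the standard formula with the
composite transition; they are structurally zero across domains off
boundaries. All recursions cost O(L·K_d·K_n²) off boundaries and
O(L/D_S·K_d²·K_n²) at boundaries; the dense (K_n·K_d)² transition matrix is
never materialized (the brute-force test oracle does materialize everything,
by design). Inner loops are numba-compiled; results are independent of that
choice and are verified against a pure-Python enumeration oracle on small
instances.

A posterior domain marginal is necessarily constant within a block (the
domain state cannot change there); the test suite asserts this to 1e-9 on
random models as a structural regression check.

Decoding: Viterbi in log space (ties broken toward the lowest (j, μ) pair)
is the default because its output is structurally valid by construction.
A two-stage maximum-posterior decoder is provided as an alternative: argmax
of the block-constant domain marginal per block, then argmax of the joint
posterior conditional on that domain per bin.

Numerics: per-bin emission vectors are computed in log space; zero
probabilities are clamped to exp(−1e30) rather than −inf so that 0·log 0
terms vanish correctly. If the total probability mass at some position falls
to ≤1e-300 the forward pass raises a diagnosable error naming the position
instead of silently renormalizing.

## Training

Full-batch EM over all sequences (cell type × chromosome combinations),
which are independent given the shared parameter set; per-sequence expected
counts are summed before one global update per iteration. Updates:

- T: row-normalized expected pair counts summed over block-boundary steps;
- t^{(ν)}: row-normalized expected pair counts over **all** steps, credited
  to the destination domain ν with the source domain marginalized out;
- P0: first-bin posteriors averaged over sequences;
- E: expected (state, mark-on) counts over expected state occupancy, domain
  marginalized.

A pseudocount (default 1e-6) is added to every numerator (and matched in the
denominator) to prevent absorbing zeros; this perturbs exact EM monotonicity
by O(pseudocount), which the monotonicity assertions absorb with a 1e-8
relative slack.

**Convergence** is declared when the absolute improvement of the total
log-likelihood falls below `tol` (default 1e-4) or after `max_iter` (default
500) iterations. An absolute threshold is used rather than a relative one
because the total log-likelihood scales with the number of bins: on a
200,000-bin training set a relative 1e-4 criterion would stop EM while
per-iteration gains are still ~50 nats, far from a fixed point, whereas the
absolute criterion is scale-free in the quantity that matters (the remaining
likelihood gain). This matches the convention of common HMM libraries.

## Initialization (two-scale k-centre)

1. **Nucleosome level.** Distinct bin patterns are clustered by greedy
   farthest-point k-centre (the classical 2-approximation) under Hamming
   distance; the first centre is the most frequent pattern (lexicographic
   tie-break). Centre *candidates* are restricted to patterns covering at
   least 1/(4·K_n) of all bins (a quarter of a state's fair share); if fewer
   than K_n patterns qualify, the K_n most frequent are used. Without this
   restriction the farthest-point rule selects rare noise patterns — the
   farthest observed point from any centre is almost always a low-count
   corner of the hypercube — and the resulting centres do not represent any
   real state.
2. **Domain level.** Each block's nucleosome-state composition vector
   (length K_n) is clustered the same way under Euclidean distance, seeded
   at the block closest to the mean composition (lowest block index on
   ties).
3. All four parameter families are the pseudocount-smoothed empirical
   frequencies of the resulting hard assignment, with nucleosome steps
   credited to the destination block's domain. Emission rows are then shrunk
   toward 0.5 with weight 1/4 (E ← 0.75·Ê + 0.125). Hard assignment
   estimates a separating mark's emission rate from bins that were selected
   *by that mark*, which biases the estimate toward 0 or 1; near-deterministic
   emissions are nearly absorbing for EM and can strand it in a local optimum
   with deterministic emissions and inflated transition noise. The shrink
   weight is not critical — any moderate value restores the correct basin —
   and EM is free to sharpen the rates afterwards.

The procedure is fully deterministic; the `seed` argument exists for
interface stability and future stochastic variants.

## Binarization

Reads are reduced to 5′ positions, shifted `shift` bp toward the fragment
centre (default 100 bp, a typical half fragment length; 0 disables), and
counted in 200 bp bins; the trailing partial bin is kept. Each mark's
background is a single Poisson rate λ_m = mean count per bin over the
chromosome being binarized (no input-track subtraction). A bin is called
present iff its count c satisfies c ≥ 1 and P(X ≥ c | Poisson(λ_m)) ≤ p
with p = 1e-4 by default. The c ≥ 1 guard makes the zero-count edge explicit
(P(X ≥ 0) = 1, so it could never fire anyway). Whether λ should be computed
per chromosome or genome-wide is a user decision; the function binarizes
whatever counts it is given.

## Evaluation statistics

- **Fold enrichment** of a state against an interval annotation:
  (m/n)/(M/N) on bin counts (m = state bins overlapping the annotation,
  n = annotated bins, M = state bins, N = total bins), with a two-sided
  Fisher exact p-value on the 2×2 table. Undefined ratios (n = 0 or M = 0)
  are reported as undefined, never as silent NaN. No multiple-testing
  correction is applied by default; apply Benjamini–Hochberg downstream for
  multi-state tables if needed.
- **Boundary enrichment**: every junction between consecutive blocks is a
  potential domain transition; the fold change is the transition rate at
  junctions inside the supplied intervals (e.g. TAD boundaries from Hi-C)
  over the genome-wide rate, with a Fisher exact test.
- **TSS profiles**: state frequency per offset around all TSS, strand-aware
  (minus-strand genes flipped), min-max normalized to [0,1] per state; flat
  profiles are flagged, not divided by zero.
- **Expression by state**: per-gene z-scores across cell lines (population
  standard deviation; constant genes excluded and counted), a state mapped
  to a gene when any of its segments overlaps TSS ± 2 kb (inclusive at bp
  resolution), averaged per (state, cell line).
- **State-frequency vectors**: per-state bp-coverage fraction in 4 kb
  windows tiling each chromosome from 0 (identical to bin-count fractions
  when windows are bin-aligned).
- **Gini index** of a conditional distribution: the relative mean absolute
  difference Σ_{a,b}|p_a − p_b| / (2K²·p̄), which is 0 for uniform and
  (K−1)/K for a point mass. (The Gini *impurity* is a different quantity and
  is not used.)
- **Similarity score** between two segmentations X and Y on a shared window
  grid: for each state k of X, the best-match Pearson correlation
  max_j PCC(X_k, Y_j) is weighted by the Gini of the distribution of Y's
  dominant states over windows where X's dominant state is k, normalized by
  (K_Y−1)/K_Y so a perfect bijective mapping weighs 1; the mean over states
  is symmetrized over both directions. The two ingredients (best-match
  correlation of state-frequency vectors; conditional-Gini specificity of
  the state mapping) are the standard ones for comparing segmentations; the
  precise way they are combined here is this package's own construction. It
  is 1 for identical segmentations up to state relabelling,
  ≈0 for independent ones, and invariant to label permutation of either
  input. Constant (degenerate) frequency vectors contribute a correlation
  term of 0; negative best-match correlations are floored at 0.

## Synthetic data generator

`simulate` samples exactly from the generative model: initial pair from P0,
nucleosome steps from t under the current (destination) domain, domain
redrawn from T only at block entries, marks as independent Bernoulli draws.
`sample_counts` overlays Poisson read counts (rate λ_fg in chosen enriched
states, λ_bg elsewhere) to exercise the binarization end-to-end.
`make_fixture_model` builds well-separated truth models: emission rows are
0.5 ± separation following a repetition-coded binary expansion of the state
index (bits spread round-robin over marks, so rows are mutually distant in
Hamming terms), each domain owns a contiguous band of nucleosome states that
its transition matrix favours (which is what makes domains identifiable from
the nucleosome grammar), and the domain transition matrix is
diagonal-dominant (0.9 by default, matching slowly-switching chromatin
domains). All samplers derive their streams from one integer seed via
numpy's SeedSequence spawning and are bit-reproducible.

What the generator does *not* emulate: correlated noise between marks,
mappability artefacts, copy-number variation, unannotated (missing) regions,
chromosome-to-chromosome heterogeneity, and real mark co-occurrence
structure. Passing tests therefore demonstrate algorithmic correctness and
statistical consistency under the model's own assumptions, not performance
on real ChIP-seq, where model misspecification dominates.

## Study conditions used by the tests and the acceptance script

- Parameter recovery: K_n = 4, K_d = 2, M = 5, D_S = 10, separation 0.35
  (emission rates 0.15/0.85), L = 200,000 bins, seed 0; k-centre init;
  Baum–Welch to tol 1e-4. Emissions recover to ≤0.05 and domain transitions
  to ≤0.1 max-abs after Hungarian matching of states (matching on emission
  rows for nucleosome states, then on the permuted transition tensors for
  domains).
- Minimum domain size: 100 sequences of 2,000 bins at the default geometry
  (200 bp bins, D_S = 20), decoded by Viterbi: the smallest non-terminal
  domain segment is exactly 4,000 bp.
- Oracle equivalence: toy instances with (K_n·K_d)^L ≤ 10^6 against full
  path enumeration at 1e-10; K_d = 1 training against a textbook scaled
  flat-HMM Baum–Welch at 1e-9 per iteration (both run without pseudocount so
  the comparison is exact).
- Binarization: sensitivity/false-call rates measured on sparse planted
  peaks (1% of bins at λ_fg = 20 over λ_bg = 0.5), and call-by-call
  agreement with direct Poisson tail summation for λ ∈ {0.1, 1, 5},
  counts 0–50.

These problem sizes complete in seconds to a couple of minutes on one CPU
and were chosen to make the statistical assertions sharp (binomial standard
errors well inside the asserted tolerances) at interactive runtimes.

## Known limitations

- Exactly two levels; the recursions generalize (higher-level transitions at
  coarser block boundaries) but file formats and the CLI assume two.
- Full-batch EM only: training cost is O(iterations · L · K_d · K_n²), which
  is why training on one chromosome and annotating genome-wide is the
  intended workflow at K_n = K_d = 30.
- No model selection for the state counts; they are user judgement.
- The product-Bernoulli emission cannot represent mark co-occurrence beyond
  what states capture.
- Binarization implements no control-track normalization, duplicate
  filtering or mappability correction.
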