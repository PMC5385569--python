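# dihmm — multi-scale chromatin-state annotation with a two-level hidden Markov model

Chromatin-state segmentation tools such as ChromHMM classify the combinatorial
pattern of histone modifications and CTCF occupancy in 200 bp bins, one bin at
a time. That single length scale cannot distinguish an isolated enhancer from
an enhancer embedded in a broad super-enhancer domain, or a lone repressed bin
from a Polycomb-repressed region. `dihmm` implements a hierarchical
(two-level) hidden Markov model that annotates both scales simultaneously:

- a **nucleosome-level state** j for every 200 bp bin, driven by the
  combinatorial mark pattern, and
- a **domain-level state** μ for every block of D_S = 20 consecutive bins
  (4 kb), driven by the *transition grammar* of the nucleosome states inside
  the block.

It is aimed at epigenomics analysts working from binarized multi-mark
ChIP-seq tracks (the ChromHMM text format is read and written directly).

## Model

The hidden state at bin *i* is the pair π_i = {j, μ}. The model assumptions
are:

- **Emissions.** Each mark is an independent Bernoulli given the nucleosome
  state: e_k(**b**) = Π_m E[k,m]^{b_m} (1−E[k,m])^{1−b_m}, independent of the
  domain state.
- **Domain-dependent nucleosome transitions.** P(j→k) = t^{(ν)}_{jk},
  conditional on the destination domain ν.
- **Block-restricted domain transitions.** The domain state is frozen inside
  each block of D_S bins and may change only on the step entering a new
  block, with probability T_{μν}; off the boundary the composite transition
  is δ^{μν} t^{(ν)}_{jk}. With 200 bp bins and D_S = 20 the minimum possible
  domain segment is therefore 4 kb.

Parameters θ = (E, t, T, P0) are estimated by a hierarchical Baum–Welch
algorithm: scaled forward/backward recursions over the joint state space
(cost O(L·K_d·K_n²) off boundaries; the dense joint transition matrix is
never formed), expected sufficient statistics, and closed-form
re-estimation, iterated until the log-likelihood gain falls below an
absolute tolerance. Initialization is a two-scale greedy k-centre
clustering: bin mark-patterns under Hamming distance at 200 bp, block
state-composition vectors under Euclidean distance at block scale. Decoding
is by Viterbi (default) or two-stage maximum-posterior; consecutive
identical states are stitched into BED9 segments at both levels.

## Worked example

Simulate a 50,000-bin chromosome from a known 4-nucleosome-state /
2-domain-state model, refit it from scratch, and compare:

```python
from dihmm import DiHMM, simulate

truth = simulate.make_fixture_model(
    n_nuc=4, n_dom=2, n_marks=5, block_size=10, separation=0.35
)
bundle = simulate.simulate_bundle(truth, [50_000], seed=0)

est = DiHMM(bundle.tracks, n_nuc=4, n_dom=2, block_size=10)
res = est.fit(seed=0)
print(res.summary())

decoded = res.decode()[0]
print("domain-state agreement with truth path:",
      round((decoded.dom_states == bundle.paths[0].dom_states).mean(), 4))
```

prints

```
          Hierarchical chromatin-state HMM results
================================================================
Nucleosome-level states:       4    Sequences:          1
Domain-level states:           2    Total bins:     50000
Block size (bins):            10    Marks:              5
Free parameters:              53    Converged:       True
EM iterations:                39    Log-likelihood: -139871.3114
----------------------------------------------------------------
Emission probabilities P(mark on | nucleosome state):
state     mark1     mark2     mark3     mark4     mark5
  N1      0.8487    0.1464    0.8555    0.1488    0.8586
  N2      0.1503    0.8465    0.1492    0.8453    0.1479
  N3      0.1476    0.1479    0.1511    0.1499    0.1511
  N4      0.8532    0.8452    0.8497    0.8482    0.8513
----------------------------------------------------------------
Domain-level transition matrix:
  D1      0.8998    0.1002
  D2      0.1050    0.8950
================================================================
domain-state agreement with truth path: 0.9924
```

The truth model emits each mark at rate 0.15 or 0.85 depending on the state;
the fitted emission rows recover those rates to ~0.006 (up to state
relabelling), the fitted domain transition matrix recovers the 0.9-diagonal
truth, and the decoded domain track agrees with the generating path on 99.2%
of bins.

## Command line

```bash
dihmm simulate --n-nuc 4 --n-dom 2 --marks 5 --block 10 --length 200000 --seed 0 -o sim/
dihmm train    --binarized sim/ --n-nuc 4 --n-dom 2 --block 10 --seed 0 -o model.json --report report.json
dihmm annotate --model model.json --binarized sim/ --decoder viterbi -o anno/
dihmm evaluate enrich --segments anno/sim_chrS_nucleosome.bed --level nucleosome \
    --annotation peaks.bed -o enrichment.tsv
dihmm binarize --reads h3k4me3.bed --marks H3K4me3 --chrom-size 2000000 \
    --bin-size 200 --pval 1e-4 --shift 100 -o tracks/
```

All subcommands are deterministic given `--seed` and write a resolved
`.config.json` next to their primary output.

## Extension path

The recursions generalize to more than two levels (each extra level adds a
block-restricted transition matrix at a coarser scale and the emission stays
at the lowest level); this package implements, and its file formats assume,
exactly two.
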