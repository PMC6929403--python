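# Methods

## Model and assumptions

`cernet` infers ceRNA (competing endogenous RNA) crosstalks — triples
T = (lncRNA, miRNA, mRNA) in which the lncRNA and mRNA compete for the same
miRNA — from a paired tumor/normal expression matrix and a precomputed
miRNA target map. The method rests on the *competition rule*: when the
sponge lncRNA is highly expressed it sequesters the miRNA (miRNA low), so
the mRNA escapes repression (mRNA high); when the lncRNA is low the pattern
inverts. Two consequences are exploited at different scales:

* **Between conditions** (competition regulation mechanism): across the
  tumor/normal contrast the miRNA's fold-change sign must oppose that of
  both the lncRNA and the mRNA. Only the sign patterns
  (miRNA up, lncRNA down, mRNA down) and (miRNA down, lncRNA up, mRNA up)
  are admissible; the exhaustive 8-pattern truth table is tested.
* **Within tumor samples** (competition samples): after per-RNA median
  binarization, a sample supports the crosstalk when its pattern is
  (0, 1, 0) or (1, 0, 1) for (lnc, mir, mr). These two conditions are
  mutually exclusive per sample.

Within one miRNA's candidate network N′ = (lncR, mir, mR), support counts
over the n × m (lncRNA, mRNA) grid are normalized to a joint distribution
and each pair is scored by pointwise mutual information,
PMI(i, j) = log[P(i, j)/(P(i)P(j))]. PMI deliberately measures the
*pair-specific excess* of co-occurring competition samples over what the
two marginals predict — a promiscuous lncRNA that matches every mRNA's
competition samples earns no score. Scores ≤ 0 and undefined scores
(support 0) are discarded; the remaining scores are standardized within the
network, θ = (PMI − mean)/σ, converted to p = erfc(θ/√2), and crosstalks
with p < 0.05 (strict) are selected.

The method is distribution-agnostic past the binarization step: expression
values are assumed already normalized (FPKM-like), and no within-library
normalization, batch correction or multiple-testing adjustment is applied.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `min_expressed_fraction` | 0.5 | keep RNAs with > 0 values in ≥ ceil(f·|S|) samples |
| `pseudocount` | 1.0 | added to condition means before the log2 ratio |
| fold-change cutoffs | lncRNA 3.0, miRNA/mRNA 2.0 | ratio scale; an RNA passes when \|log2 FC\| ≥ log2(cutoff), inclusive |
| `p_max` | 0.05 | DE p-value gate (inclusive) |
| `binarize_scope` | `tumor` | take the binarization median over tumor samples only, or over all samples (`all`) |
| `log_base` | `e` | base of the PMI logarithm (`2` available) |
| `grouping` | `per_mirna` | significance statistics per candidate network, or pooled over all networks (`global`) |
| `alpha` | 0.05 | selection threshold, strict (p < alpha) |

Design choices where the procedure was genuinely open:

* **Fold change** is the log2 ratio of condition means with pseudocount 1;
  the printed cutoffs 2.0/3.0 are interpreted on the ratio scale. The sign
  convention (positive = up in tumor) is what the competition mechanism
  consumes.
* **The t-test** is the two-sided *paired* variant on log2(x+1), using the
  paired design. Zero-variance difference rows are resolved
  deterministically: all-zero differences → p = 1, constant nonzero
  differences → p = 0.
* **Median ties** binarize to 0 (strictly-greater-than-median → 1); the
  rule is deterministic and order-independent. Constant rows binarize to
  all 0 — they can never form competition samples, which is conservative.
* **Binarization scope**: competitive relationships are evaluated in tumor
  samples, so the default takes the median over tumor samples only; the
  all-samples variant is exposed as a flag.
* **Significance grouping**: scores are comparable within one miRNA's
  network, so per-network statistics are the default; `global` pools all
  positive scores instead. σ is the population standard deviation (ddof 0).
* **Degenerate groups**: σ below 1e-12 (relative) is treated as zero — all
  p-values become 1 with a warning; a group without positive scores is
  dropped with a warning. erfc(θ/√2) exceeds 1 for below-mean scores and is
  clamped to [0, 1]; only the small-p tail matters for selection.
* **Selection** is strict (p < 0.05); note that over t positive scores
  max θ ≤ (t − 1)/√t, so a network with ≤ 5 positive scores can never
  reach θ > 1.96 — tiny networks select nothing by construction, and a
  single-pair network always has PMI = 0 and is discarded outright.
* A crosstalk is exported as two graph edges (lnc–mir, mir–mr) in a
  multigraph star; the triple list survives intact in the TSV/JSON exports.

## Synthetic data

`cernet.simulate` generates a paired cohort with planted ceRNA triples so
the whole pipeline is testable without external data. Per planted triple:
normal-sample means sit at `baseline_mean` and tumor means are scaled by
the fold factors (lncRNA 4.0, mRNA 3.0, miRNA 1/3 — the negative
competition-regulation pattern). Within tumor samples a per-triple latent
competition state assigns each sample to a high or low regime (lncRNA and
mRNA high exactly when the miRNA is low), each RNA's regime is flipped
independently with probability `flip_prob`, and negative-binomial counts
(overdispersion `dispersion` = 8) are drawn from the regime mean.

Two constructions make the noise-free case exact rather than approximate:
the latent state is a *balanced* random assignment (exactly half of the
tumor samples high; marginally each sample is still Bernoulli(1/2)), and
regime draws are kept on opposite sides of the tumor mean (low draws capped
at ⌊mean⌋, high draws shifted above it, regime means preserved). Together
these guarantee that at `flip_prob` = 0 the equal-frequency median falls
between the regimes and every tumor sample reproduces the latent state —
hence satisfies competition Condition 1 or 2 for its triple. With i.i.d.
states or overlapping count distributions the guarantee would fail at a
handful of samples per cohort.

Decoy RNAs are sampled independently of every latent state; half of them
(`de_decoy_fraction`) are differentially expressed with the same fold
factors so that the DE gate, the sign filter and the PMI stage all face
non-trivial negatives. The target map contains every planted pair plus
random decoy edges (6 decoy lncRNAs and mRNAs per miRNA); planted RNAs are
not wired into other miRNAs' target lists, keeping ground-truth semantics
unambiguous.

What the generator does *not* emulate: library-size variation, shared
miRNAs between sponges, isoform structure, copy-number or methylation
confounding, and any sequence-level detail. Passing tests demonstrate the
pipeline's internal correctness and its behavior under the generator's
idealized competition structure, not performance on real cohorts.

### A structural limit on planted-triple recovery

The generator's planted triples are *not* recoverable by the PMI selection
step, and this is a property of the scoring model rather than a bug. Within
a network, supp(i, j) counts samples where lnc_i and mr_j both equal the
miRNA's complement. For a planted triple with independent per-RNA flips at
rate p, P(both match) = (1−p)³ + p³ while the product of marginals is
((1−p)² + p²)², so the planted pair's PMI tends to
ln[((1−p)³+p³)/((1−p)²+p²)²] ≈ 0.08 at p = 0.1 — and exactly 0 at p = 0,
where both match events become deterministic and the support grid is
rank-one. Decoy pairs contribute supp ~ Binomial(S, 1/4), whose sampling
noise at S = 51 tumor samples puts an sd of ≈ 0.24 on their PMI — three
times the planted signal — so the planted pair essentially never tops its
group at θ > 1.96. A planted triple alone in its network (a 1 × 1 grid)
always scores PMI = 0 and is discarded. High PMI requires pair-specific
co-occurrence structure *beyond* what the shared miRNA induces, which a
single sponge–target pair per miRNA cannot generate; the corresponding
recovery test documents this honestly and fails.

## Numerical notes

* Support counting is vectorized as (1−A)b(1−C)ᵀ + A(1−b)Cᵀ over 0/1
  matrices; tests compare it to a per-sample, per-pair Python loop to
  1e-12 on 1,000 random instances.
* Joint/marginal normalization holds to 1e-12; PMI ≤ min(−log p_lnc,
  −log p_mr) for all defined scores.
* All stage outputs are plain TSV/JSON with deterministic ordering
  (lexicographic crosstalks, sorted miRNA ids), so identical inputs
  reproduce byte-identical output trees.
* Problem sizes in the test-suite and acceptance runs (≤ 3×3 networks with
  ≤ 8 samples for oracle checks; 50-pair cohorts with 320 RNAs for
  end-to-end runs) keep every run well under a minute while exercising all
  code paths; the generator scales linearly if larger cohorts are wanted.

## Known limitations

* No multiple-testing correction at either the DE or the selection stage;
  thresholds are used exactly as stated above.
* The equal-frequency binarization is a deterministic strictly-greater-
  than-median rule, not a re-implementation of any particular toolkit's
  binning.
* The erfc conversion treats the within-group positive scores as roughly
  Gaussian; with few positive scores the p-values are conservative (see
  the max-θ bound above).
* Target maps are taken at face value; no sequence-based target prediction
  or seed-match validation is performed.
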