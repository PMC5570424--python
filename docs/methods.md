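# Methods

## The screen being modeled

`poolscreen` implements the computational arm of a pooled shRNA screen for
macrophage polarization phenotypes. A lentiviral library of 12,998 shRNAs
against 648 genes (~20 reagents per gene, each tagged with a unique 18-nt
barcode) is transduced into THP-1 monocytes at low multiplicity so each cell
carries one reagent. After differentiation and M1 (LPS/IFNγ, CD38+) or M2
(IL4/IL13, CD209+) polarization, phenotype-positive and -negative fractions
are FACS-sorted and the barcode abundance of every fraction is measured by
amplicon sequencing. An untreated arm ("viable Mo") sequenced against the
input identifies essential genes by reagent dropout.

A gene whose knockdown depletes cells from a phenotype-positive fraction is
inferred to be a **mediator** of that phenotype in its normal function; a
gene whose knockdown enriches cells there is a **suppressor**.

## Gene-level statistic (RSA)

For one comparison (e.g. M2+ vs input), every reagent gets a log2 fold
change of its depth-normalized counts. All N reagents are ranked — ascending
for mediator mode (most depleted first), descending for suppressor mode — so
both modes are depletion tests after orientation. For a gene with reagent
ranks r_1 < … < r_k the score is

  p = min over j of P(X ≥ j),  X ~ Hypergeometric(N, k successes, r_j draws),

the redundant-activity statistic: it is small only when several of the
gene's reagents cluster at the favorable extremity, which tolerates
individual off-target reagents. `best_j`/`best_rank` record the argmin
(smallest j on ties). Effect size is summarized by the 25th/75th percentiles
(linear interpolation) of the gene's reagent log2 fold changes, computed on
the log2 scale. No multiple-testing correction is applied: hits are called
by rank (top 10 per module, 1.5% of 648 genes), not by a p threshold.

### Numerical evaluation of the tail

Tails are evaluated in linear space as sums of
pmf(i) = C(k,i)·ff(r,i)·ff(N−r,k−i)/ff(N,k), with ff the falling factorial —
plain products of at most k double-precision factors. In the screening
domain (N ≤ ~10^6, k ≤ ~50) the smallest reachable tail is ~1e-70, far from
underflow, and the product form avoids the cancellation incurred by
differencing large log-gamma values; measured agreement with exact rational
arithmetic is ~1e-15 relative (tested to <1e-12 over an N ≤ 2000, k ≤ 25
grid). Impossible terms vanish automatically because a falling factorial
with more steps than its argument contains a zero factor. The per-gene scan
over all k cutoffs is vectorized (one small 2-D array per gene), so a full
648-gene module scores in tens of milliseconds.

### Determinism and tie-breaking

Reagent ranking uses a stable sort keyed on (oriented log2fc, reagent_id);
gene-score tables sort by (rsa_p, effect-size quartile — q1 ascending for
mediator, q3 descending for suppressor — gene symbol). Hit lists are
therefore always exactly N genes and byte-reproducible. Suppressor-mode
scores on a fold-change list equal mediator-mode scores on its negation.

## Normalization and pseudocount

Each sample column is scaled to 12 million reads (the screen's sequencing
target). The pseudocount is **one read on the normalized scale**, added to
every reagent in every sample before the ratio — exactly one raw read for a
sample sequenced to 12M reads. Expressing it on the common normalized scale
(rather than propagating each sample's raw depth) keeps all fold changes
finite for dropout reagents, never reorders observed counts within a
sample, and makes fold changes exactly invariant to each sample's raw
sequencing depth. Replicates are averaged as the arithmetic mean of
normalized counts before the ratio; per-replicate scoring with
meta-combination is deliberately out of scope.

## Analysis plan and hit classification

Five comparisons — M1+ vs input, M1+ vs M1−, M2+ vs input, M2+ vs M2−, and
M2+ vs M1+ — each run in both modes give ten polarization analysis modules;
viable-Mo vs input (mediator/depletion mode only) is the eleventh,
viability, module. Top-10 lists feed a per-gene contingency tally over
(phenotype ∈ {M1, M2}) × (role ∈ {mediator, suppressor}). The M2+ vs M1+
comparison is one signal with two readings: a mediator-mode hit there
counts as both an M2 mediator and an M1 suppressor (and the suppressor-mode
hit as M2 suppressor / M1 mediator), so each phenotype-role cell is bounded
by 3 comparisons. Confidence is binary — **high** for genes appearing in ≥2
distinct modules — and the dual-phenotype bookkeeping of the shared
comparison still counts as a single appearance, so a gene hit only there
remains low-confidence. Essential genes are the top-10 of the viability
module (the experiment defines no explicit cutoff; top-N is used for
symmetry with the polarization modules) and are removed from the
high-confidence validation shortlist, with removals logged.

## The synthetic screen

The generator is a forward model of the experiment, one multinomial
sequencing draw per sample over per-fraction cell abundances:

1. plasmid abundance a_r ∝ LogNormal(0, σ_pool), normalized to sum 1;
2. input cells c_r ~ Poisson(cells_per_reagent · N_reagents · a_r);
3. knockdown efficacy e_r ~ Beta(α, β) per reagent;
4. viability arm: survivors ~ Binomial(c_r, (1 − dropout)·(1 − s·e_r)) with
   s the planted essential strength (0 for nulls);
5. polarization arms: a cell sorts positive with probability p₀ for nulls,
   p₀·(1 − s·e_r) for mediators, p₀ + s·e_r·(1 − p₀) for suppressors;
   positives ~ Binomial, the remainder is the negative fraction;
6. each biological replicate multiplies expected abundance by
   LogNormal(0, σ_rep) noise;
7. reads ~ Multinomial(depth, fraction abundances).

Planted effects act through `strength × efficacy`: a weak-knockdown shRNA
yields a proportionally weak phenotype, producing the within-gene spread of
ranks that RSA exploits. Strength-0 effects are statistically
indistinguishable from unplanted genes (tested). Expected positive-fraction
occupancy is monotone in strength by construction (tested on the
expectations, pre-sampling).

### Parameters, defaults and calibration

| parameter | default | meaning / rationale |
|---|---|---|
| library | 648 genes, 12,998 reagents | the screen's library scale; 610×20 + 38×21 is the minimal-spread composition with mean ≈ 20/gene (only total and mean are known) |
| barcodes | random 18-mers, pairwise Hamming ≥ 3 | guarantees unique single-substitution correction during deconvolution |
| `pool_sigma` | 0.5 | log-normal abundance skew of a typical plasmid pool |
| `efficacy_beta` | (5, 2) | knockdown efficacies with mean ≈ 0.71, a realistic mix of strong and weak shRNAs |
| `p_M2` | 0.11 | baseline M2+ sort rate; the 11% positive-cell rate observed in unperturbed controls is the only measured positive-fraction rate available |
| `p_M1` | 0.30 | baseline M1+ sort rate; no measured value exists, chosen as a plausible free default |
| `dropout_rate` | 0.05 | baseline cell loss in the untreated arm |
| `cells_per_reagent` | 500 | pre-sort coverage per reagent |
| `depth` | 12,000,000 | reads per sample, the screen's sequencing target; `DESK_DEPTH` = 2,000,000 for desk-scale runs — gene-level scoring is depth-robust above ~150 reads/reagent |
| `rep_sigma` | 0.04 | per-replicate log-normal reagent noise, **calibrated** so replicate log10(count+1) R² ≥ 0.97 at default depth, the screen's reported replicate reproducibility (measured: min ≈ 0.976, mean ≈ 0.977 over 100 replicate pairs) |
| `n_replicates` | 2 | biological replicates for every sequenced fraction except M1−, which gets one, matching the screen design |

### What the simulator does and does not emulate

It reproduces pool skew, counting (Poisson/binomial/multinomial) noise,
replicate noise, dropout, and efficacy-scaled planted effects — the
features the scoring pipeline is sensitive to. It does **not** model PCR
amplification bias or jackpotting, multiple integrations (the screen used
MOI 0.3 precisely to exclude them), sorting impurity, double-positive
states (positive/negative gates are mutually exclusive per arm), or
cell-cycle/adherence dynamics. Passing recovery tests therefore shows the
statistical machinery recovers planted signals under realistic counting
noise; it does not certify performance against PCR artifacts or impure
sorts.

## Barcode deconvolution

Reads carry a 4-nt constant anchor, the 18-nt barcode at a fixed offset,
then filler (50 nt total; constant quality). The anchor check is an exact
match — a cheap structural filter whose failures are counted transparently.
Barcode matching is exact-first, then (optionally) unique Hamming-1
correction, enabled only after verifying no two whitelist barcodes are
within distance 2. Substitution-only correction is deliberate: barcodes sit
at a fixed offset on Illumina-type reads where substitutions dominate
indels. Ambiguous reads are discarded, never fractionally assigned, keeping
counts integer and unbiased for rank statistics. Read accounting
(anchor_fail / exact / corrected / ambiguous / unmatched) always sums to
total reads.

## Degenerate inputs and error handling

All-zero sample columns refuse normalization (named in the error); unknown
genes, missing fractions, duplicate (fraction, replicate) pairs, malformed
barcodes, duplicate reagent ids/barcodes, negative or fractional raw
counts, truncated FASTQ records (reported with record index) and top_n
exceeding the gene count are all validation errors. Reagents with zero
counts everywhere are retained — they carry the dropout signal. Normalized
counts are serialized with 15 significant digits so column sums round-trip
well within the 1e-9 relative tolerance.

## Problem sizes used by the test suite and acceptance script

Unit tests run on reduced libraries (tens of genes). Full-scale checks —
replicate calibration at 12M reads, planted-mediator rank-1 recovery and
the 15-gene panel recovery at 2M reads — use the complete 12,998-reagent
library over 20 seeds each; the package's vectorized scoring keeps a full
ten-module analysis under a second, so the whole suite completes in about a
minute.

## Known limitations

- Per-replicate RSA scoring with meta-analysis combination is not
  implemented (replicates are pooled by averaging).
- The fold-change reference is explicit per contrast (input or the paired
  sorted fraction); plasmid-anchored variants are configurable through
  `ContrastSpec` but not part of the default plan.
- The essential-gene rule (top-N depletion of viable-Mo vs input) is a
  documented stand-in; the experiment reports no explicit criterion.
- Exact RSA p-value ties across genes are broken by effect size and then
  gene symbol — reproducibility over statistical nicety; ties are
  vanishingly rare with real-valued fold changes.
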