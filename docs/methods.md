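# Methods

## The problem

Comparative-genomic screens for diet-driven molecular adaptation ask two
related questions about a set of orthologous protein-coding genes on a fixed
species tree in which some lineages (here: predatory carnivorous fish) are
designated *foreground* and the rest *background*:

1. **Selection on rates.** Is the ratio ω = dN/dS elevated on the foreground
   — either gene-wide (*rapidly evolving genes*, REGs) or at a subset of
   sites (*positively selected genes*, PSGs)?
2. **Convergence in sequence.** Are there alignment columns where every
   foreground species independently acquired one identical residue that no
   background species carries, at otherwise conserved positions?

`codonsel` implements both screens, the decision rules layered on top of
them, chi-square gene-set enrichment, and a simulator that generates data
with exactly the statistical structure the screens assume, so the whole
pipeline is testable end to end against planted ground truth.

## Codon substitution model

The engine is a Goldman–Yang (GY94) Markov process on the 61 sense codons of
the standard genetic code. For codons *i*, *j* differing at one nucleotide,

    q_ij ∝ π_j · κ^[transition] · ω^[nonsynonymous],

zero for multi-nucleotide changes, diagonal set so rows sum to zero. The
process is time-reversible (π_i q_ij = π_j q_ji), so likelihoods are
invariant to root placement and transition matrices are computed through the
symmetric eigendecomposition of diag(√π) Q diag(1/√π).

Equilibrium frequencies π default to **F3x4** (products of position-specific
nucleotide frequencies estimated from the alignment, renormalised over sense
codons, floored at 1e-8 so the generator stays irreducible on low-diversity
data); F61 (observed codon frequencies) and uniform are available.

Model configurations:

| name               | free parameters                  | role |
|--------------------|----------------------------------|------|
| `M0`               | κ, ω                             | one-ratio null |
| `branch`           | κ, ω_background, ω_foreground    | two-ratio alternative (REG test, df=1) |
| `branch-site`      | κ, p0, p1, ω0∈(0,1), ω2≥1        | Model A alternative (PSG test) |
| `branch-site-null` | κ, p0, p1, ω0                    | Model A with ω2 ≡ 1 (df=1 null) |

Model A mixes four site classes: (ω0, ω0), (1, 1), (ω0, ω2), (1, ω2) as
(background, foreground) pairs, with proportions p0, p1, (1−p0−p1)·p0/(p0+p1),
(1−p0−p1)·p1/(p0+p1).

### Rate scaling

Each single-ω generator is normalised to one expected substitution per codon
site at stationarity, so branch lengths read as substitutions/codon under
that branch's own process. For the site-class mixtures this per-class
normalisation would be wrong — a class with ω2 > 1 would merely shift its
substitution spectrum without evolving faster, which removes essentially all
power to detect episodic selection. The mixture models therefore share **one
common scale factor**, chosen so the class-proportion-weighted mean rate on
background branches equals 1: background branch lengths keep their
substitutions-per-codon reading while the positively selected classes
genuinely accelerate on the foreground. The simulator exposes the same
convention (`shared_time_scale=True`) for generating branch-site-like data.

### Likelihood and fitting

Felsenstein pruning over 61 states with per-node rescaling (log-space
accumulators) guards underflow; site patterns are compressed with counts;
the four Model A classes are pruned in one batched pass. Gaps, Ns and stop
codons in observed data are treated as missing (partial likelihood one over
all states), the cleandata=0 convention.

Fits maximise lnL by bounded L-BFGS-B on log-rates (κ ∈ [1e-3, 100],
ω ∈ [1e-6, 50]) with mixture proportions parameterised as (t, r) ↦
(p0, p1) = (t·r, t·(1−r)); by default one deterministic start plus seeded
random restarts, keeping the best optimum and reporting the optimizer's
convergence status honestly. Branch lengths are fixed at the input tree's
values (the species tree is taken as known). Likelihood-ratio tests use
2ΔlnL (clamped at 0) against the chi-square upper tail, df = 1 for both the
branch and the branch-site comparison — the plain chi-square, not the 50:50
boundary mixture, matching how the reproduced model-comparison table was
computed.

### Site posteriors

Per-site posteriors of the positive-selection classes (2a+2b) are computed
by naive empirical Bayes at the MLEs; output tables record the flavor
("NEB") so the downstream ≥ 0.95 filter is interpretable. Full BEB
integration over a parameter grid is not implemented.

## Selection calls

**PSG** (branch-site): the gene passes iff the LRT p < α (default 0.05) and
at least one codon position has posterior ≥ 0.95, with three false-positive
guards, each recorded as a machine-readable reason code:

- `consecutive_run` — three or more consecutive candidate positions
  (alignment gaps do not reset a run);
- `terminal_site` — a candidate at the first or last codon (window
  configurable, literal reading of "start or end of the coding sequence");
- `low_posterior` — no position reaches the 0.95 posterior cut.

**REG** (branch): the gene passes iff the M0-vs-two-ratio LRT p < α *and*
ω_foreground > ω_background. No multiple-testing correction is applied by
default (raw per-gene p < 0.05); Benjamini–Hochberg is available.

## Convergence screen

Inputs are per-gene protein alignments plus a group specification: IN_list
(foreground carnivores), ON_list (background herbivores), optional outgroup.
Stages, in order, with per-stage gene counts reported:

1. **Detection** — columns where every IN taxon carries one identical
   residue (columns with any IN gap/X skipped) that differs from the ON
   consensus. A strict mode requiring the residue to be absent from every
   ON taxon is available; the pipeline instead runs the relaxed consensus
   rule followed by stage 2, which composes to the same outcome while
   keeping the two rules separately testable.
2. **Background-shared filter** — any called site whose IN residue also
   occurs in an ON taxon at that position disqualifies the *whole gene*
   (partial convergence in the background), not just the site.
3. **Conservation (CCs) filter** — the site must be conserved across
   ON_list + outgroup before the change: the largest fraction of non-gap
   background residues agreeing at the column must reach a threshold
   (default 1.0). Two modes: residue **identity**, or **property** class,
   in which residues of one side-chain class (e.g. Lys and Arg, both basic)
   count as conserved — required to admit basic→neutral cases such as
   K/R→Q. The mode used is recorded in every output.
4. **Domain annotation** — flags whether the site's ungapped position in a
   reference taxon (default: first IN taxon) falls inside a 1-based closed
   domain interval; annotation never changes site counts. Out-of-bounds
   intervals are clamped with a warning.
5. **Property classification** — residues map to four side-chain classes
   (hydrophobic: GAVLIPFMW; polar-uncharged: STCYNQ; basic: KRH; acidic:
   DE). Change labels use the conventional phrasing: the polar class reads
   "hydrophilic" against a hydrophobicity change and "neutral" against a
   charge change, so S→G is hydrophilic→hydrophobic and {K,R}→Q is
   basic→neutral.

## Enrichment

Per category, genes are cross-classified in/out of the gene set × in/out of
the category and tested with the df=1 Pearson chi-square (no continuity
correction by default; Yates and BH adjustment behind flags). Expected cells
< 5 are flagged rather than suppressed. The universe defaults to all
annotated genes.

## Synthetic data

The generator evolves codon alignments on a fixed rooted tree: root codons
drawn from the configured frequencies (uniform over the 61 sense codons by
default — deliberately *not* the F3x4 family the fitting side estimates, so
inference is never handed its own frequency model), then branch-by-branch
transition sampling with branch-specific ω on tagged foreground branches.
One `SeedSequence` is split per branch in deterministic preorder, making
output bit-reproducible and subtree-order-independent. Stop codons cannot
occur. No indels, no among-site rate variation beyond the two-ω /
branch-site structure, no gene birth–death.

Convergent ground truth is planted in two steps: background columns are
first forced to their majority residue (stochastic simulation cannot
guarantee conservation), then all foreground tips receive a codon for the
target residue; the planting refuses non-conservative columns or targets
equal to the background residue.

What passing on these data does *not* show: robustness to alignment error,
indels, GC-biased gene conversion, codon-usage bias mismatches beyond
uniform-vs-F3x4, or among-site rate heterogeneity in the background — all
present in real ortholog sets.

## Study conditions used by the tests and the acceptance script

- Published model-comparison table: the eight lnL pairs are inputs; the df=1
  chi-square p-values are recomputed and agree to printed precision.
- Oracle equivalence: pruning vs explicit enumeration of all internal-node
  codon states on ≤4-taxon, ≤3-codon fixtures, within 1e-8 in log space.
- Parameter recovery: M0 on 4-taxon alignments of 2000 codons at
  ω ∈ {0.2, 1, 3} (observed max relative error ≈ 6%); branch-LRT power on
  ω_fg = 4 vs ω_bg = 0.2 at 500 codons, 10 replicates.
- Planted convergence: k ∈ {0, 1, 5} sites on a slow-clock 8-taxon gene of
  200 codons; exact precision/recall 1 required.
- Demo pipeline: 12 genes × 300 codons on an 8-taxon tree, 3 genes with five
  scattered interior sites under foreground selection (ω2 = 8, shared time
  scale), 2 conserved genes with one planted convergent site. Problem sizes
  were chosen so the whole suite runs comfortably on a single CPU.

## Known limitations

- Branch lengths are not re-optimised during fitting; a misspecified input
  tree biases ω estimates.
- Naive EB posteriors understate uncertainty relative to full BEB near the
  MLE boundary (small p2 mass).
- The CCs conservation rule is a declared approximation of
  convergence-at-conservative-sites methods: an identity-or-property-class
  fraction threshold, not the original statistic.
- The chi-square enrichment test is asymptotic; low-expected-count
  categories are flagged but still tested (use the flags).
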