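# Methods

This note documents the statistical procedures implemented in
`nichecomm`, the choices made where a convention had to be fixed, what
the synthetic-data generator does and does not emulate, and the known
limitations.

## Quality control

Cells are filtered by three rules applied in a fixed order.

1. **Doublet rule.** Let `T_c` be the total UMIs of cell *c*. Cells with
   `T_c > median(T) + k · MAD(T)` are putative doublets. The MAD is the
   *unscaled* median of absolute deviations from the median; the
   1.4826 normal-consistency factor is deliberately not applied (it is
   available via `QCParams.mad_scale` for callers who want the
   normal-consistent estimator). The rule is one-sided: only the upper
   tail is doublet-like; low-count cells are handled by the UMI floor.
   If the MAD is zero the rule degenerates to `T_c > median(T)`. The
   mask is computed on the full input population, before any removal.
   Default `k = 3`.
2. **UMI floor.** Cells with `T_c < min_umi` are removed. The boundary
   is inclusive — a cell with exactly `min_umi` total counts is
   retained — with `QCParams.umi_strict` switching to a strict
   inequality. Default `min_umi = 1000`.
3. **Mitochondrial ceiling.** Cells with more than `max_mito_pct`
   percent of their library on genes whose symbol starts with the
   mitochondrial prefix are removed. Prefix matching is
   case-insensitive by default (`mt-` / `MT-` both occur in practice),
   with a flag to force case sensitivity. Zero-library cells are defined
   to have 0% mitochondrial content. Defaults: 25%, prefix `mt-`.

Each removed cell is attributed to the first rule that removed it, so the
report counts always satisfy
`n_input = n_retained + n_doublet + n_low_umi + n_high_mito`.
No gene-level filtering is performed.

## Normalization and group means

Counts are library-size normalized and log-transformed:
`value(g, c) = ln(1 + count(g, c) / T_c · s)` with scale factor
`s = 10 000` — the standard single-cell LogNormalize convention. The
natural logarithm is the default because the downstream fold-change
computation back-transforms with `exp(·) − 1`; the conservation identity
`Σ_g (e^value − 1) = s` holds exactly for every cell with a nonzero
library and is enforced by tests at 10⁻⁸ relative tolerance. The log
base and scale factor are configurable.

Group means are arithmetic means of the log-normalized values over *all*
cells carrying a joint `(cell_type, time_point)` label — zeros included,
not "expressing cells only". This is a deliberate reading of "average
expression by one cell type": it makes the group mean a linear statistic
of the cells, which the permutation null then exchanges cleanly.

## Ligand–receptor screen

The interaction score of pair (L, R) from sender population A to
receiver population B at time point *t* is

    score = ( μ_L(A, t) + μ_R(B, t) ) / 2

with μ the group means above. By default each pair is scored in both
directions (ligand in A / receptor in B, and vice versa), since either
population can be the sender.

**Permutation null.** The joint `(cell_type, time_point)` label vector
is randomly permuted across all cells; group means and all pair scores
are recomputed under each of `n_perm` shuffles (default 1000). One
shuffle serves every pair simultaneously. Shuffling the *joint* label
moves cell type and time point together, preserving their co-occurrence
structure (the label multiset is invariant, so no shuffled group can be
empty); an `independent` mode that permutes the two columns separately
is provided for comparison, with empty shuffled groups contributing a
mean of 0.

**Empirical p.** `p = #(null ≥ observed) / n_perm`, ties counting
toward the upper set; p = 0 is attainable. No smoothing is applied by
default; a `(count+1)/(n_perm+1)` option exists for calibration studies.
No multiple-testing correction is applied to screen p-values by default.
With `n_perm` shuffles the smallest nonzero p is `1/n_perm`; at the
default 1000 shuffles the resolution is 0.001.

Under exchangeable labels the unsmoothed p at threshold α has rejection
probability ≈ `(⌊α·n_perm⌋ + 1)/(n_perm + 1)` (≈ 0.055 at α = 0.05,
n_perm = 200), which is why the calibration tests allow a ±0.02 band
around the nominal level.

**Outputs.** A flat table (ligand, receptor, sender, receiver,
time_point, score, p_value, n_perm) and a sender × receiver adjacency of
significant interactions (counts or summed scores) for chord-style
visualization; plotting itself is left to the user.

## Marker detection

Group-vs-rest differential expression uses the two-sided Wilcoxon
rank-sum test on log-normalized values, over the full gene universe.
Ranks use midranks for ties. When the number of rank assignments
`C(n, n_a) ≤ 10 000` the p-value is computed by exhaustive enumeration
(exact, valid under ties: p = 1 for identical samples); otherwise a
normal approximation with tie correction and a 0.5 continuity correction
is used. The two paths agree within 0.05 on small samples, verified by
test.

Bonferroni correction multiplies by the number of genes tested — the
whole universe, not the retained set — capped at 1. A gene is retained
as a marker iff `log2FC ≥ 0.25` **and** `p_adj < 0.001`.

The log2 fold change is computed on back-transformed means: for each
group, `m = mean_cells(e^value − 1)`, then
`log2((m_in + ε)/(m_out + ε))` with pseudocount `ε = 10⁻⁹`
(configurable). This follows the convention of widely used single-cell
marker-test implementations.

For downstream enrichment input a separate, looser selection is
provided: all genes with `p_adj < 0.05`, regardless of fold direction.

**Signature overlap.** Two gene sets within a declared universe are
tabulated exactly (sizes, intersection, union), with a one-sided
hypergeometric upper-tail p — the probability of drawing at least the
observed intersection when `|B|` genes are sampled from the universe
containing `|A|` successes. The choice of the hypergeometric test for
overlap significance is this package's own; it is validated against
Monte-Carlo resampling in the tests.

## Ortholog mapping

Reference pair lists are translated through a precomputed two-column
symbol map (e.g. a biomaRt export); no live service queries. A pair is
emitted only when both members map; unmapped pairs are dropped and
counted. One-to-many orthologs default to Cartesian-product expansion
with de-duplication (`policy="expand"`), the permissive choice that
keeps every candidate interaction testable; `policy="drop"` discards
ambiguous pairs instead. Gene symbols match case-sensitively throughout:
symbol case encodes species (`Apoe` vs `APOE`).

## Synthetic-data generator

The generator emulates the *structure* of a sorted two-population,
three-time-point plate experiment, not any particular tissue's
transcriptome:

- 3 plates × 384 wells = 1152 cells; cell type (microglia/NSPC, 1:1) and
  time point (uninjured/PT_D1/PT_D7, uniform) assigned independently per
  cell.
- Gene baseline means are log-normal (default: mean 2 UMIs per gene per
  cell, σ = 1 on the log scale, ~2000 genes → libraries around 4000
  UMIs, typical of plate-based UMI protocols). Counts are
  negative-binomial via a gamma–Poisson mixture with shared
  inverse-dispersion θ = 10.
- Per-cell capture efficiency is a uniform factor on [0.7, 1.3]. The
  bounded (sub-Gaussian) choice is deliberate: it keeps the singlet
  library-size distribution short-tailed, so the planted doublet truth
  is identifiable by the MAD rule (≤1% of singlets flagged, ≥80% of
  doublets caught, both covered by tests). Real data have heavier
  library-size tails, so MAD-rule false-positive rates on real data will
  exceed the simulated ones — a property of the data, not of the rule.
- The 13 protein-coding mouse mitochondrial genes form a reserved
  `mt-` block scaled to a 5% expected library share in healthy cells;
  dying cells (default 5%) have their mitochondrial share re-allocated
  to 40% at constant expected library size.
- Doublets (default 5%) add the counts of a second, independently drawn
  cell (own labels and capture factor) to a well.
- Planted ligand–receptor pairs multiply the ligand's mean in the
  (sender, time point) group and the receptor's mean in the (receiver,
  time point) group by `fold`; planted markers multiply one gene's mean
  in one cell type. Planted genes are assigned a fixed well-detected
  baseline (10 UMIs per cell in expectation) so that "a fold-`f`
  planted effect" is a well-defined, reproducible condition rather than
  contingent on a lottery over the log-normal baseline draw — mirroring
  the fact that annotated ligands and receptors are typically
  well-detected transcripts.

What the generator does **not** emulate: batch/plate effects,
gene–gene correlation beyond the planted effects, per-cell-type global
expression programs, zero-inflation beyond NB sampling, ambient RNA, or
read-level artifacts (barcode errors, UMI collapsing). Passing recovery
and calibration tests therefore demonstrates correctness of the
*statistics* under a clean generative model, not robustness to every
real-data pathology.

## Numerical and interface choices

- Empirical p-values and rank-sum enumeration use exact comparisons with
  a 10⁻⁹ slack only where floating-point rank sums are compared.
- All randomness flows through `numpy.random.default_rng(seed)`; the
  same seed reproduces matrices, null distributions and result tables
  bit for bit.
- The pipeline (`qc → normalize → screen → markers → report`) writes a
  manifest with a config hash (output path excluded, so relocated runs
  hash identically), the seed, per-stage status and a SHA-256 per output
  file. Any stage error aborts the run with a stage-named error and an
  incomplete-flagged manifest.
- Problem sizes in the test-suite and acceptance computations are chosen
  to make stochastic checks statistically decisive yet quick: 200-shuffle
  nulls over 600 pair-conditions for calibration, 20 independent datasets
  for planted-pair recovery, 200 random matrices for QC oracle
  equivalence.

## Known limitations

- The interaction score is a mean of means; it does not model
  subunit complexes, percent-expressing thresholds or trimean variants.
- Permutation p-values are reported uncorrected by default (a
  Benjamini–Hochberg pass over the result table is trivial for callers
  who want it); with shared shuffles, p-values across pairs are not
  independent.
- The UMI floor's inclusive boundary and the unscaled MAD are
  conventions; both are parameterized and both directions are tested.
- Wilcoxon exact enumeration is combinatorial; the 10 000-assignment
  cap keeps worst-case cost bounded, at the price of the asymptotic
  approximation (with tie/continuity corrections) for larger groups.
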