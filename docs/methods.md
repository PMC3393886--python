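# Methods

This note documents the models, algorithms, default calibrations and
numerical choices behind `cppherit`, and what the synthetic-data tests do
and do not establish about real data.

## Pedigree model and kinship

A pedigree is a validated DAG: every individual has both parents recorded
(at strictly smaller generation labels) or neither; ids are unique;
referenced parents exist; the parent graph is acyclic (checked with
Kahn's algorithm, so a record listing itself as its own sire is reported
as a cycle, not a missing parent). Founders of a fully inbred strain
carry a `founder_inbred` flag meaning F = 1 and self-kinship Φ = 1.

Kinship uses the standard recursion — Φ(i,i) = ½(1 + Φ(sire, dam));
Φ(i,j) = ½(Φ(sire_i, j) + Φ(dam_i, j)) for i ≠ j with i not an ancestor
of j; distinct founders unrelated — evaluated by the tabular method over
the ancestor closure of the requested ids in (generation, id) order, so
results are deterministic and parents always precede offspring. The
additive relationship matrix is A = 2Φ (diagonal 1 + F, entries up to 2
under inbreeding). Memory scales with the square of the ancestor-closure
size; the AIL simulator itself never materializes this matrix (see
below).

**Independent oracle.** `gene_drop_kinship` estimates Φ by transmitting
founder allele labels down the pedigree (two distinct labels per
non-inbred founder, one label used twice for inbred founders; each child
inherits one allele uniformly at random from each parent) and averaging
the four allele-identity indicators per pair. Its per-entry Monte-Carlo
standard error is bounded by 0.5/√reps, which the tests use as the
comparison tolerance (3 SEs at 10,000 replicates). The oracle shares no
code with the recursion.

## AIL breeding simulator

Generation 0 is two inbred founders (one per strain); generation 1 the
F1s of that single cross; every later generation is bred from pairs of
the previous one. The historical "systematic pairing to minimize
relatedness" is operationalized as *greedy minimum-kinship pairing*: the
available pair with the smallest kinship is chosen repeatedly, full-sib
matings are forbidden, and ties are broken by a seeded random jitter.
One structural exception is forced by the two-founder start: all F1s are
full sibs, so the F1 × F1 crosses that produce the F2 are necessarily
sib matings; the prohibition applies from the F2-parent generation
onward. Family counts and per-family offspring counts are drawn
uniformly from configured ranges (defaults: 45 generations, 50–70
families, 2–5 offspring — the scale of the emulated colony). Pairing
kinship is propagated generation-to-generation (parents of generation g
all lie in g−1), so the simulator is O(generation size²) in memory
rather than O(pedigree²).

A consequence of the two-founder design worth keeping in mind: every
individual from F2 onward has F ≈ 0.5 and any two cohort members share a
baseline kinship near 0.25. Heritability information therefore comes
from kinship *contrasts* (sib vs non-sib), not absolute kinship.

`sample_study_cohort` mirrors the emulated study: 2·n parents drawn from
the top generation (by default each from a different family), randomly
paired into n families, each with 4–11 offspring appended as a new
generation; parents and offspring are both phenotyped (default 10
families, ~90–110 animals).

## Synthetic phenotypes

`simulate_additive_phenotypes` draws y = μ + a + e with
a ~ N(0, σ²ₐ·A) via the eigendecomposition of A (eigenvalues clipped at
zero after a PSD check at relative tolerance 1e-8) and independent
e ~ N(0, σ²ₑ). This is exactly the model the ML estimator assumes, so
parameter-recovery tests are clean; the gene-drop oracle independently
validates A itself. Inbreeding-inflated diagonals are used as-is.

`simulate_nuclear_families` works on the standardized scale (total
variance 1): parent phenotypes A + E with Var(A) = h²; offspring
breeding value = midparent breeding value + Mendelian segregation
deviate of variance h²/2; offspring environment independent with
variance 1 − h². The expected offspring-on-midparent regression slope is
then h², which anchors both the estimator-recovery and the power tests.

### CPP session generator

Fifteen days, 1800-s sessions; time on the drug-paired side recorded on
the test days D1/D8/D15, distance on every session day; rest days D6–7
and D13–14 produce no records. Defaults (free calibration parameters are
marked †):

| parameter | default | rationale |
|---|---|---|
| initial bias range | 2–6 % of session | the apparatus's drug-paired side is slightly less preferred initially |
| conditioning gain mean | 175 s | center of the 100–250 s gain this protocol produces |
| conditioning gain SD † | 50 s | spreads animals across that range |
| preference noise SD † | 100 s | within-animal session noise; not identifiable from published summaries, declared here |
| baseline distance | 4000 ± 800 cm | typical open-field 30-min totals |
| MA multiplier | 2.0 | acute psychostimulant locomotor activation |
| sensitization / habituation | +5 % / −5 % per exposure | mild drift across training days |

The conditioning gain is a latent heritable *reward* trait (default
h² = 0.2) standardized and mapped through gain mean/SD, clipped at 0,
and applied **equally on D8 and D15** (preference is maximal after the
first training block). Distances are driven by a latent heritable
*activity* trait (default h² = 0.5). All times are clipped to
[0, 1800] s and distances to ≥ 0 (apparatus bounds). An all-saline
control schedule zeroes the gain, giving the null scenario. Given a
seed, output is bit-identical across runs.

What the generator does *not* emulate: dose–response pharmacology,
within-session time courses, sex-by-genotype interactions, non-additive
(dominance/epistatic/maternal) genetic variance, and genotype-specific
sensitization. Tests passing on this generator therefore certify the
*estimators* under the additive model, not the biology of any real
colony.

## Statistical tests

Paired/unpaired t and Pearson correlations are classical (two-sided by
default; p for r via the t transform). Degenerate inputs are explicit:
x = y gives t = 0, p = 1 with a degenerate flag; a constant trait yields
a missing correlation, never 0. The repeated-measures ANOVA is the
standard split-plot decomposition (subjects-within-groups error for the
between factor; subject × day error for within and interaction), giving
the uncorrected df pattern, e.g. F(2, 120) for 2 groups × 31 subjects ×
3 days; `pingouin` serves as the independent oracle in the tests. A
Greenhouse–Geisser option exists but is off by default since the
uncorrected df are the reporting convention here. Bonferroni thresholds
are exact α/k internally, with a two-significant-figure display helper
(0.017, 0.013, 0.0083).

## Heritability estimators

**Midparent regression.** OLS of offspring family means on midparent
means; h² is the slope, SE the OLS slope SE. Negative slopes are
reported raw (`slope_`) but the headline h² is clipped to [0, 1],
matching the 0.00 floor convention of heritability tables. The slope is
invariant to shifting or positively rescaling all phenotypes.

**Animal model by ML.** y ~ N(Xβ, σ²ₐ·A + σ²ₑ·I), X an intercept by
default. Writing σ²_t = σ²ₐ + σ²ₑ and h² = σ²ₐ/σ²_t, the covariance is
σ²_t·(h²·A + (1 − h²)I). After one eigendecomposition of A the
likelihood is diagonal; for fixed h², β is the GLS solution and σ²_t has
a closed form, leaving a one-dimensional profile likelihood over
h² ∈ [0, 1], maximized on a 101-point grid and refined by bounded Brent
iteration. This was chosen over 2-D quasi-Newton on
(logit h², log σ²_t) with multi-starts: it is deterministic, needs no
starting values, handles the boundaries h² ∈ {0, 1} natively, and
cannot converge to a local optimum the grid has already beaten (a grid
audit of local optimality is part of the test suite). Boundary solutions
are legal and flagged; A ∝ I (all eigenvalues equal) is reported as
degenerate/unidentifiable with h² = 0 rather than an arbitrary interior
value. REML is available (`reml=True`) but ML is the default, matching
the named method of the analyses this package re-implements.

*Known limitation (measured, not hypothetical):* on deep-AIL cohorts the
top eigen-direction of A — the near-constant baseline-relatedness
component — is absorbed by the fitted mean, and plain ML does not charge
the model for it, biasing σ̂²ₐ downward at low h² (at n ≈ 500 and
h² = 0.25, mean ĥ² ≈ 0.19; REML restores ≈ 0.24). Averaged over
h² ∈ {0, 0.25, 0.5, 0.75} the ML recovery error remains small (pooled
MAE ≈ 0.06 at n = 500), and on outbred related cohorts ML is accurate at
every h². Users estimating low heritabilities on deeply inbred
pedigrees should prefer `reml=True`.

**Jackknife SE.** Delete-d jackknife with random subsets:
SE² = ((n − d)/(d·m))·Σ(θ̂_k − θ̄)², defaults m = 50 subsets, d = 10.
Subsets are drawn without replacement within a draw, independently
across draws, seeded. A constant estimator returns exactly 0. At the
h² = 0 boundary every subset can return 0, giving SE = 0.00 — the
pipeline reproduces this behavior deliberately. Validated against the
analytic σ/√n for the sample mean.

## Power analysis

Each replicate simulates nuclear families, fits the midparent
regression, and tests the slope with the regression t-test on
n_families − 2 df. One-sided H0: slope ≤ 0 at α = 0.05 is the default —
the convention of the heritability-power literature, and the choice
under which the classical benchmark pair holds: at h² = 0.2 with two
offspring per family, ≈ 60 % power at 100 families and > 95 % at 400
(this package measures 60.7 % and 98.5 % at 30,000/8,000 replicates).
Sidedness is a flag. Degenerate replicates are re-drawn and counted.

## Problem sizes used in the test suite

Chosen so the full suite exercises every claim at meaningful scale:
kinship-vs-gene-drop equivalence on a ≤ 200-individual AIL at 10,000
gene-drop replicates; ML recovery on a 496-animal AIL parents+offspring
cohort (62 families × 6 offspring, 125 replicates per h² level) and on
outbred family cohorts; midparent recovery at 50,000 families; power
claims at 5,000 replicates; type-I-error calibration of every test at
5,000 null cohorts; study-scale instability at 500 replicate 10-family
cohorts. The 45-generation colony default is exercised at reduced
generation depth in tests since baseline relatedness (the quantity that
matters) saturates within the first few generations of a two-founder
AIL.

## Design choices where the design was open

* Phenotyped-subset choice is a parameter (`sample_study_cohort`), since
  which generations contribute phenotypes vs pedigree bookkeeping is a
  study-level decision.
* Bonferroni family sizes k are always passed explicitly by the caller;
  the package does not guess comparison families.
* Sexes are pooled throughout; sex is carried as a column for optional
  covariate use in the ML fit.
* The pipeline config is YAML; every run writes its resolved config and
  seed to `run_log.json`.
* Pedigree files accept "0" or "NA" for missing parents and write "0".
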