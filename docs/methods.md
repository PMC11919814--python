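# Methods

This note documents the models, statistics and design choices behind
lipidomix, in the order data flows through the package.

## Nomenclature grammar

The parser covers two levels of lipid shorthand over a registry of 20
common classes (glycerolipids TAG/DAG/MG; glycerophospholipids PC, PE,
PS, PI, PG, PA and their lyso forms; sphingolipids SM, Cer, HexCer;
sterol ester CE; free fatty acids FA):

- *sum composition* — `CLASS C:DB`, total acyl carbons and double bonds,
  chains unresolved (`TAG 48:0`);
- *molecular species* — one token per backbone chain (`PE 18:0_20:4`),
  where the chain count must equal the class's backbone capacity.

Accepted dialect variation: class synonyms (TG→TAG, DG→DAG, MAG→MG,
LysoPC→LPC, …), chain separators `/`, `_`, `-` and the typographic
en-dash, optional parentheses, ether prefixes `O-`/`P-` (plasmanyl /
plasmenyl, glycerophospholipids only), and sphingoid hydroxylation
prefixes `d`/`t` (2 / 3 hydroxyls, sphingolipids only).

The canonical serialization always joins chains with `_` in ascending
(carbons, double bonds, hydroxyls) order, so every dialect variant of a
species collapses to a single identifier and parse∘canonicalize∘parse is
the identity on structural fields. A `/`-separated input records
`sn_position_known=True` as provenance, but sn-order is deliberately not
part of the canonical identity: downstream analyses treat `PC 16:0/18:1`
and `PC 18:1_16:0` as the same species, which is what abundance tables
produced at mixed annotation depth require. Adducts, isotope labels,
oxidized lipids and glycan headgroups are outside the grammar and are
rejected with a reason code — a logged failure is recoverable, a silent
misparse is not.

## Preprocessing

Defaults (all recorded in `Experiment.processing_log`, all overridable):

| step | default | rationale |
|---|---|---|
| missing-value filter | drop species missing in > 50% of samples | species quantified in under half the cohort carry little testable signal |
| imputation | half of the per-species observed minimum | standard left-censoring surrogate for below-LOQ values |
| normalization | none (options: per-sample median, sum-to-constant) | acquisition pipelines differ; no default is universally right |
| transform | log2, pseudocount 1 only if zeros remain | fold changes become mean differences; tests assume approximate normality on this scale |

Preprocessing with all options disabled is the identity, so re-running a
processed matrix is safe.

## Differential testing

Default test: Welch's unequal-variance *t* on log2 values, two-sided;
Mann–Whitney (exact for ≤10 per group) as the distribution-free
alternative. Effect size is the log2 mean difference. Multiplicity:
Benjamini–Hochberg step-up within each family (all species; the levels
of one characteristic; the occupied cells of one dual grid). Defaults
α = 0.05 on FDR and fc-cut = 1 (two-fold) for up/down calls.

Degenerate case — both groups constant: Welch's denominator vanishes, so
the test falls back to the exact two-sided permutation p-value for
point-mass groups, 2/C(n₁+n₂, n₁) when the constants differ and 1
otherwise, with a signed sentinel statistic. This keeps p-values defined
and the label-swap antisymmetry exact.

Characteristic-level tests run on log2 of *summed* (not averaged) linear
abundances per level: summation preserves per-sample totals for
partition characteristics (class, category, total carbons, total double
bonds, ether type) and matches the class-total semantics the reaction
network uses. Chain-level characteristics are intentionally not a
partition — a PC 16:1_20:3 contributes to both the 16- and 20-carbon
levels — and are documented as such rather than forced into one.

The dual-characteristic grid reports, per (total carbons × total double
bonds) cell of one class, the mean species log2 fold change, the number
of member species, and a significance flag from testing the cell's
summed abundance (one value per sample, well-defined for multi-species
cells) with BH across occupied cells. The grid is an array of per-cell
effects and flags, not a single correlation coefficient: per-cell
significance marking requires per-cell tests.

## Enrichment

**ORA.** Universe = all species tested in the differential step
(conditioning on the tested universe avoids detection bias); query =
species called up (or down). Per set, the one-sided Fisher exact
p-value P[X ≥ k], X ~ Hypergeom(|U|, |S|, |Q|); odds ratio from the 2×2
table with a Haldane 0.5 correction when a margin is zero; BH across
sets. An empty query returns p = 1 for every set rather than an error.

**LSEA.** With species ranked by the signed test statistic (descending)
and a set of n_h members in a universe of N, the running sum steps up by
|s_i|^p / Σ_hits |s|^p at members and down by 1/(N − n_h) elsewhere;
ES is the extremum of largest magnitude, so ES ∈ [−1, 1] and with p = 0
it reduces to the signed Kolmogorov–Smirnov gap between hit and miss
CDFs. The null permutes *set membership* over the ranked universe (valid
at any sample size, unlike sample-label permutation at n = 10/group).
The p-value is one-sided within the observed sign:
p = (b + 1)/(n_same + 1), where b counts same-sign permuted scores with
|ES*| ≥ |ES| and n_same counts same-sign permutations. Normalizing by
the same-sign count keeps the nominal level: dividing by all
permutations would reject on both tails at the nominal rate each and
double the type-I error, which the calibration test would catch. NES =
ES / mean|same-sign permuted ES|. Defaults p = 1, 1000 permutations, set
size 3–500 — conventional for ranked set enrichment and configurable.
Permutation seeds spawn per set from one SeedSequence, so results are
reproducible and independent of set order.

## Reaction-network activity

The bundled graph curates well-established class conversions
(Kennedy-pathway DAG→PC/PE, PEMT PE→PC, base-exchange PS cycle,
PLD/PLA2 branches, the PA→DAG→TAG axis, and Cer↔SM/HexCer turnover).
It is a convenience default, not a claim of completeness; any edge list
over registered classes can replace it.

Edge score: with per-sample ratio r_s = log2(product-class total) −
log2(substrate-class total), z = (mean r_case − mean r_ctrl) / Welch SE,
p from the standard normal. The formulation is direction-aware (signed),
scale-free (global intensity cancels in the ratio), exactly antisymmetric
under group swap, and testable against planted effects. Zero-variance
ratios use a signed sentinel z (±1e6) instead of dividing by zero.
Call thresholds: |z| > 1.96 for single-edge active/repressed calls;
path highlighting at |mean z| > 1.5. Paths enumerate all simple paths of
at most 4 edges (class graphs are small; the bound keeps enumeration
trivially cheap and is configurable).

Note one deliberate semantic: class totals pool ester and ether species
(ether linkage is a within-class characteristic, not a class), so a
decrease confined to ether PCs lowers the PC total and hence the PE→PC
score — which is the intended class-level reading.

## Synthetic experiments

`generate_experiment` draws unique, parseable species per class with
chemically plausible sum compositions, then models
log2 abundance = baseline + shift·1[case] + N(0, σ), with per-species
baselines N(14, 2) — the magnitudes of typical normalized LC-MS
intensities — and within-group σ = 0.5 log2 units. Effects are additive
on the log2 scale, matching the differential model so that power and FDR
measurements are interpretable; missingness is completely at random.
What the generator does *not* emulate: intensity-dependent variance,
batch effects, censored (MNAR) missingness, correlated species, isotope
interference. Passing tests therefore demonstrate correctness of the
statistical machinery under its stated model, not robustness to every
artifact of real acquisitions.

The default study-shaped design — 185 species across 15 class keys,
10 + 10 samples, TAG +1 log2 (an extra +1 for ≤50 carbons and ≤2 double
bonds), ether PC −1, 2% missing — mirrors the canonical remodeling
pattern of a failing-heart lipidome and drives the end-to-end checks:
planted TAGs dominate the top-up table, TAG ranks first among
up-enriched sets and PC O- first among down-enriched, the short/saturated
TAG grid corner is flagged, and PE→PC scores negative.

## Problem sizes in the test and acceptance runs

Simulation-based checks use: 200 null datasets of 300 species at
10 vs 10 for p-value calibration (pooled 99% binomial band), 100
datasets with 30 planted 2σ shifts for recall/FDR, 500 LSEA replicates
at 500 permutations for permutation calibration, 1000 random
configurations for ORA exactness, 200 simulations for network sign
recovery, and 20 random fixtures for the antisymmetry sweep. These sizes
give tight Monte-Carlo bands while keeping the whole suite inside a few
minutes on one CPU.

## Known limitations

- Two groups only; no paired designs, covariates, or moderated variance.
- The grammar excludes oxidized/glycosylated species, adducts and
  isotope labels by design; such names fail loudly.
- Reaction scoring is class-level; species-resolved flux is out of scope,
  and edge scores are association statistics, not kinetic fluxes.
- t-SNE/UMAP outputs are seeded but carry no geometry guarantees; only
  PCA has interpretable variance decomposition.
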