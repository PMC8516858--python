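# Methods

This note documents the model, its fixed constants and calibrated
defaults, the numerical choices, and the limits of what the synthetic
experiments demonstrate.

## The individual-based model

**Space.** A rectangular landscape is rasterised into square patches of
0.1 m side (0.01 m²), indexed 0-based with half-open bounds
(`patch = floor(coord / 0.1)`). Trees have a trunk (radius DBH/2) and a
circular crown; allometry couples crown radius (0.1 m per cm DBH) and
height (0.35 m per cm DBH) to stem diameter so that stand dynamics only
needs to track DBH. Crowns may overlap; trunks may not.

**Shading.** A patch under *k* crown layers is shaded
`1 − (1 − s₁)^k` with `s₁ = 0.5` per layer (configurable). The law is
monotone in *k*, bounded in [0, 1] and has a single parameter. An
epiphyte does not count its own host crown: it sits on top of the
branches, so only *other* overtopping crowns shade it. This choice makes
single-cover crown patches fully lit (net energy +0.5/month) and
double-cover patches energetically neutral, which is what produces the
fitness cost of dense, crown-overlapping stands.

**Energy budget and life cycle.** Monthly step order: energy update →
mortality → (in the one reproductive month per year) reproduction,
dispersal, regional rain, germination → ageing. A plant gains
`1 × (1 − shading)` units/month and pays 0.5 maintenance (floor at 0);
it dies at zero energy, at the 72-month lifespan, or when its host tree
dies. Seedlings start with 1 unit, so a shade-free plant holds ~25 units
at the 48-month maturity — comfortably above the 10-unit reproduction
threshold, i.e. a shade-free plant always reproduces at its first
season after maturity. Reproduction happens once per life: the plant
emits `floor(energy / 10)` cohorts of 10 seeds plus one clonal ramet on
a free patch of the same host crown within 3 patches of the parent,
then keeps a 5-unit reserve. The 10-seeds-per-cohort default is the one
genuinely free constant of the budget; it was fixed once by checking,
over a coarse grid (10/20/30), which value reproduces the expected
joint colonisation pattern (peak abundance, lineage counts, Lag-phase
differentiation) on the reference grove, and it is exposed in
`SimParams` like every other coefficient.

**Dispersal.** A seed flies in a uniform-random direction, one patch
per sub-step, for at most `5 × wind_speed` patches. Each crown patch
entered captures it with probability `capture_probability`; a seed that
finishes its flight uncaptured, or crosses the landscape boundary, is
lost (absorbing edges). With the posterior-median capture probability
(0.223) a seed born inside a crown escapes its natal canopy only ~2% of
the time — the model's expression of "most seeds establish on the natal
tree" — and those escapes are the carriers of among-tree gene flow.
Regional immigrants enter at uniform-random points of the landscape
perimeter with uniform-random directions (so roughly half are lost
immediately) and disperse by the same rule.

**Genetics.** Seven diploid SSR loci of integer repeat counts. Founder
genotypes draw from a regional pool (six-allele ladders per locus with
geometric frequencies); each locus is made heterozygous with a
configurable probability (default 0.39, the midpoint of the 0.27–0.51
field range), which directly fixes the founders' expected
heterozygosity. Inheritance is strict selfing: both gamete alleles are
drawn from the parent's pair, then mutated by a single-step stepwise
model (±1 repeat with probability `mutation_rate`, reflecting at one
repeat). Clonal copies are exact by default (somatic mutation is a
switch). MLG ids intern distinct genotypes; MLL ids mark descent from
one founding immigrant and are inherited unchanged — so MLL count never
exceeds cumulative established immigrants, and clone mates always share
an MLG when somatic mutation is off.

**Establishment and competition.** One established plant per patch.
Captured seeds germinate with probability `germination_rate`;
simultaneous germinants for the same patch are resolved in random
order, and incumbents always win. This one-per-patch rule caps
abundance at the crown-patch count of the landscape; see *Limitations*.

## Parameters

Free parameters (ABC priors in parentheses; defaults are the midpoints
of the calibrated posterior intervals):

| parameter | default | prior | meaning |
|---|---|---|---|
| `regional_seed_rain` | 176 /yr | U(100, 500) | immigrant seeds per season |
| `wind_speed` | 17.6 | U(1, 20) | flight length = 5×units, patches |
| `mutation_rate` | 10^−4.675 | 10^N(−4, 0.5) on [−6,−2] | SSR slippage / transmission |
| `germination_rate` | 0.2295 | U(0.0083, 0.30) | P(attached seed → seedling) |
| `capture_probability` | 0.223 | U(0.01, 0.30) | P(capture) per crown patch |

The mutation-rate prior is sampled on the log₁₀ scale (truncated
normal); regression adjustment and cross-validation also treat it in
log₁₀ space. Fixed life-history constants: lifespan 72 mo, maturity
48 mo, 10-unit reproduction threshold, gain 1 and maintenance
0.5 units/mo, one reproductive season per year.

## Landscapes

*Reference grove* (time experiment, ABC reference tables): 20 trees of
15 cm DBH (1.5 m crowns — young cultivated ornamentals) placed in a
disc bounding pairwise distances to ≤ 47.5 m, minimum spacing 2.5 m,
inside a 45 × 45 m (~0.2 ha) landscape; ~99 trees/ha.

*Density/dynamic stands* (0.4 ha): identical crowns sized so that 150
trees — the sweep maximum — exactly tile the area:
r = √(4000/150π) ≈ 2.91 m, hence 29.1 cm DBH through the allometry.
This makes "full occupancy at 150 trees" a geometric fact rather than a
tuned constant.

*Stand dynamics* (dynamic era only): DBH grows 0.13 cm/yr; stands above
Yoda's −3/2 line (mass proxy w = 0.5·DBH³, `w_max = K·N^(−3/2)`) thin
until back on it, with mortality probability inversely proportional to
mass — the suppressed-tree mortality of real self-thinning; uniform
random victims would let saplings dilute the mean mass and destabilise
the line. The law fixes the exponent, not the constant: K ≈ 3.6×10⁷ was
tuned so that unmanaged mature stands equilibrate near 180 trees/ha
(verified by
tree-only runs from 175 and 375 trees/ha). Regeneration adds
Poisson(0.15·N) saplings per year on open ground and suspends below 20%
open fraction. Deforestation removes the stated fraction of trees
uniformly at random (resident plants die with their host); reforestation
plants saplings on random open patches, capped by available open ground.

## Summary statistics

All estimators work on an individuals × loci × 2 genotype array with
subpopulation (host tree) labels: unbiased H_E (2N/(2N−1) correction on
gene copies), H_O, multilocus F_IS = 1 − ΣH_O/ΣH_E with allele
permutation tests, Weir–Cockerham (1984) θ for global/pairwise F_ST
(single-individual subpopulations are excluded with a warning; a single
subpopulation is refused, never reported as 0), two-level AMOVA on
squared allele-identity (or allele-size) distances with label
permutation, rarefied allelic richness (hypergeometric), private
alleles, modified Garza–Williamson M = k/(R+1) averaged over loci and
subpopulations, Loiselle et al. (1995) kinship with the (n−1)⁻¹
small-sample term, and Hill-q=0 (presence) Whittaker turnover
(γ/ᾱ−1)/(S−1) of alleles, MLGs or MLLs.

The S_p statistic uses pair-count-balanced distance classes (contiguous
rank chunks; class sizes differ by ≤ 1 pair), the regression slope b_F
of pairwise kinship on ln(distance) over all pairs, and
S_p = −b_F/(1−F₍₁₎). Pairs closer than one patch are pooled at 0.1 m
before taking logs. The null shuffles individual locations 1000× (the
kinship matrix is permuted against the fixed distance matrix, which is
equivalent and cheap); the same permutations give per-class 95%
envelopes. Mantel tests (scikit-bio) correlate a chosen genetic
distance — Slatkin-linearized F_ST (negatives clamped at 0), Edwards
chord, Nei standard, Reynolds coancestry — with ln(centroid distance).

Estimator checks: hand-computed micro-panels, brute-force frequency
recomputation, Mendelian/selfing closed forms (H_g = H₀2^−g), an
msprime island-model coalescent against F_ST = 1/(1+4Nm(d/(d−1))²), a
serial-founder stepping stone for isolation by distance, and a selfing
pedigree for kinship (θ(parent, selfed offspring) = (1+F_p)/2 = 0.5 for
non-inbred parents).

## ABC

Reference tables store (θ, s) rows where s is the six-statistic vector
(K, R, H_E, F_IS, F_ST, NGW) of one simulated sample (≤ 15 plants per
occupied tree). Sparse simulations that cannot yield the vector
(< 10 plants or < 2 occupied trees) are logged and dropped, never
imputed. Rejection: statistics standardised by table MAD (constant
columns dropped with a warning), Euclidean distance, retain the
tolerance fraction (ties broken by row index), optional local-linear
adjustment with Epanechnikov weights (solved by weighted least squares;
deterministic, unlike a neural-network variant, hence testable).
`ABCCalibration(...).fit()` returns results with posterior draws,
medians, credible intervals and a `summary()` table. Sensitivity
analysis reports Spearman ρ of each parameter against each output;
cross-validation re-estimates held-out rows and reports Pearson r per
parameter (log₁₀ for mutation rate).

The default reduced reference configuration — a 12-tree ~0.13 ha grove
followed for 15 years, ~0.05 s per row — is the package's desk-scale
stand-in for the original six-figure simulation campaign. At this scale
germination rate (r ≈ 0.6), seed rain (r ≈ 0.4) and wind speed
(r ≈ 0.2–0.3) are significantly recovered, while mutation rate and
capture probability are not: short runs contain too few mutation events,
and capture probability trades off against germination in the
establishment product. Recovery ranking at full scale may differ.

## Phase detection and recorded trajectories

Yearly records hold abundance, MLL/MLG counts, clone fraction, tree
density, ground cover (the *covered* fraction of patches) and the
statistics vector; statistics are recorded as missing until the sample
reaches 30 plants on ≥ 3 trees, because earlier estimates are dominated
by sampling noise (pre-establishment instability). On the pooled mean
abundance curve, the Lag phase ends at the 5%-of-plateau crossing and
the Log phase at the half-plateau crossing — the inflection of a
saturating trajectory — with the plateau taken as the mean of the last
five recorded years.

## What the synthetic experiments show — and what they do not

The generators emulate the study conditions: a ~0.2 ha 20-tree grove
with 2.5–47.5 m spacing for the time experiment, 0.4 ha stands of 5–150
identical-crown trees for the density sweep, and 30 static + 30 dynamic
years around a density-change event for the dynamic family. They do not
emulate real canopy architecture (single-layer discs, no vertical
structure), wind regimes (no prevailing direction, no canopy wind
friction), seed banks, or genotyping artefacts (no missing data, null
alleles or scoring error), so passing tests demonstrate internal
consistency of the model and estimators under these idealisations, not
field realism.

Two structural limits matter when comparing magnitudes with the
original study system. First, the one-plant-per-patch rule caps
abundance at the crown-patch count: ~14,000 on the reference grove
(where the observed ~12,500-plant plateau sits naturally below it) but
only ~10⁵ on 0.4 ha stands, so the reported multi-hundred-thousand
abundances of dense-stand scenarios are unreachable in this geometry;
the corresponding checks are kept in the acceptance suite and fail
loudly rather than being relaxed. Second, with single-layer crowns the
singly-covered (fully lit) area grows monotonically up to full
occupancy, so the density sweep lacks the high-density abundance
downturn and the low-density differentiation peak that deeper canopies
and wind friction would produce; the F_ST minimum at intermediate
density is likewise not reproduced — isolated trees here accumulate
several immigrant lineages each, keeping within-tree diversity high.

## Numerical and reproducibility notes

All randomness flows from numpy Generators; experiment replicates spawn
child seeds deterministically from one master seed, so outputs are
byte-reproducible. Dispersal is resolved patch-by-patch in vectorised
batches; populations are stored as flat arrays compacted each season
(a 50-year grove replicate runs in ~1 s). Distances at or below one
patch are pooled at 0.1 m before logs; F_ST linearization clamps
negative estimates at 0; AMOVA clamps the among-component at 0 for the
percentage (components themselves are reported unclamped); degenerate
inputs (empty samples, single subpopulations, coincident coordinates,
zero-variance distance matrices) raise instead of returning silent
zeros.
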