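# Methods

## The neutral community model

The model treats each local community (one sequenced sample) as a
population of `N` individuals undergoing random death and replacement.
With probability `m` a vacancy is filled by an immigrant drawn from a
source metacommunity with taxon relative abundances `p`; otherwise by
local reproduction. At stationarity the relative abundance of taxon *i*
in a local community is `Beta(Nm·p_i, Nm·(1−p_i))` distributed. The
quantity actually fitted is the occurrence frequency: the probability
that the taxon's abundance exceeds a detection limit `d`,

    f̂_i = 1 − I_d(Nm·p_i, Nm·(1−p_i)),

with `I_d` the regularized incomplete beta function. Key assumptions:
all taxa are demographically equivalent (no fitness differences), the
source is well characterized and static, and samples are independent
replicates of the same assembly process.

### Fitting

`m` is the only free parameter (`N` is measured as the rounded mean read
depth of the target samples). The sum of squared residuals between
observed and predicted occurrence frequencies is minimized by bounded
scalar search (Brent, `m ∈ (1e-8, 1]`, tolerance 1e-10). The surface is
unimodal in practice; no multi-start is needed. If the optimum pins at
`m = 1` while the objective is still decreasing, the fit is flagged
`saturated` — the data demand more migration than the model can express,
usually meaning source and target are effectively the same community.
Goodness of fit is `R² = 1 − SSE/SStot` on occurrence frequencies; it is
negative when the neutral curve explains less than the mean, which is a
legitimate and informative outcome. Uncertainty on `m` comes from a
seeded nonparametric bootstrap over OTUs (default 1000 resamples,
percentile 2.5/97.5).

### Conventions

- **Occurrence**: a taxon is present in a sample at count ≥ 1.
- **Detection limit**: `d = 1/N` by default (one read at the mean
  depth); any fixed value can be supplied instead.
- **Source abundance `p`**: the mean of per-sample relative abundances
  across source samples, not pooled counts — deep samples must not
  dominate the metacommunity estimate. Taxa with `p = 0` (seen only in
  the target) cannot be predicted and are reported separately, never
  silently dropped.
- **Partition**: each OTU is classified against the Wilson score
  interval at 95% around its predicted frequency with `n` = number of
  target samples; strictly above the upper bound → "above", strictly
  below the lower bound → "below", otherwise "neutral".
- **Chaining**: `stepping_stone` fits consecutive pairs of an ordered
  community list (environment → first compartment → second …);
  `common_source` fits every community against one fixed external
  source. These are the two designs of gut-compartment and life-stage
  studies respectively.

### Known limitation: the neutrality band at saturated predictions

The Wilson interval is an estimation interval for a proportion; used as
an acceptance band for an *observed* frequency its coverage degrades at
the boundaries. When `f̂ → 1` the upper bound approaches 1 like
`1 − O((1−f̂)²)`, so a common taxon observed in *every* sample (the most
likely outcome) sits marginally above the band and is flagged "above";
symmetrically, a rare taxon absent everywhere can be flagged "below".
With realistic lognormal metacommunities a noticeable share of taxa
occupies this saturated regime, so the neutral share reported on purely
neutral simulated data is ~70–80%, not the ~95% a naive coverage
argument suggests. A binomial-quantile prediction band
(`qbinom(0.025/0.975; n, f̂)/n`) has correct coverage but cannot flag
genuinely planted taxa whose predicted occupancy is within `1/n` of 1.
The package keeps the Wilson convention (it is what existing
implementations of this analysis use) and documents the caveat; treat
"above" calls whose predicted frequency exceeds `1 − 1/n` with caution.

## The synthetic generator

`simulate_neutral_samples` draws, per sample, a composition from
`Dirichlet(Nm·p)` and then counts from `Multinomial(N_j, composition)`.
The Dirichlet aggregation property makes each taxon's marginal exactly
the beta distribution above, so parameter recovery is a well-posed test,
not an approximation. Defaults define the package's standard study
conditions: `S = 300` taxa, 10 source samples, 50 target samples,
`N = 10,000` reads with per-sample totals jittered ±20% uniformly,
`Nm = 1000`, and a lognormal metacommunity with `σ = 2` natural-log
units (the spread typical of 16S OTU abundance distributions; the
generator also offers a geometric series). Source samples are drawn at
`Nm = 1e8` so their mean composition is an accurate stand-in for `p`,
mirroring the use of pooled environmental samples as the metacommunity
proxy.

Departures from neutrality are injected after the neutral draw:
"above" taxa are planted in every sample at a forced relative abundance
(an error is raised if forced abundances exceed 90% of a sample);
"below" taxa are confined to a `round(q·n)` subset of samples. Column
totals are preserved exactly by reallocating the remaining reads over
unselected taxa with largest-remainder rounding. Clade-restricted
communities (all reads moved onto one tight clade) create phylogenetic
clustering for testing NRI/NTI.

What the generator does **not** emulate: sequencing error and chimeras,
taxon-taxon interactions, temporal autocorrelation between samples, and
compositional biases of extraction/PCR. One mismatch with the fitted
model is intrinsic and worth understanding: the model detects a taxon by
the hard threshold `x > 1/N`, but multinomial counting detects it softly
with probability `1 − (1−x)^N`. Rare taxa are therefore seen slightly
more often, and mid-abundance taxa slightly less often, than the
threshold model predicts. The visible consequences, measured by the test
suite, are an upward bias of ~10–20% in single-study `Nm` estimates at
the `Nm = 1000, N = 10⁴` regime (median error across regimes stays
within 15%) and extra structured residuals that the neutrality band
attributes to selection. Passing tests on this generator therefore
validate the estimator's mechanics, not its behavior under real
sequencing noise.

## Phylogenetic dispersion

MPD is the mean cophenetic distance over all unordered pairs of taxa
present in a sample; MNTD the mean distance to the nearest present
neighbor. Both are presence-based (abundance weighting is deliberately
not used by the pipeline). The null redraws the same number of taxa
uniformly without replacement from the pool of taxa observed anywhere in
the analyzed table — the taxon-label shuffle appropriate for presence
data — with 999 iterations by default, all driven by one seeded
generator. `SES = (obs − null_mean)/null_sd`, and the reported indices
are `NRI = −SES(MPD)`, `NTI = −SES(MNTD)`: positive values mean
phylogenetic clustering (habitat filtering), negative overdispersion,
zero the neutral expectation. Because the sign convention is a perennial
source of confusion in the literature, every output row carries both the
signed `ses` and the negated `index`, explicitly labelled. Degenerate
cases are flagged rather than raised: samples with fewer than two taxa,
and samples containing the entire pool (the null is then constant; a
relative tolerance of 1e-10 on the null standard deviation absorbs
float summation-order noise).

## Beta diversity

Generalized UniFrac weights each branch by `L_b·(p_A+p_B)^α`; `α = 0.5`
(the variant with the most even power across abundance scales) is the
default, `α = 1` reproduces weighted-normalized UniFrac (verified
against scikit-bio in the tests). The root's stem branch is excluded;
branches with no descendants in either sample contribute nothing; branch
lengths cancel under global rescaling. Taxa missing from the tree are a
hard error — silent pruning would change denominators.

PERMANOVA partitions squared distances by the Gower identity
(`SS_total = Σ_{i<j} d²_{ij}/n`, within-group sums analogously) into a
pseudo-F with `(k−1, n−k)` degrees of freedom. P-values use seeded label
permutations with the +1 correction, so the smallest attainable p is
`1/(n_perm+1)`; an exact mode enumerates all distinct label assignments
for small designs. PCoA is classical scaling of the double-centered
`−d²/2` matrix; negative eigenvalues are reported untouched (no Cailliez
or Lingoes correction), and axis shares are taken over the positive
eigenvalue sum.

## Alpha diversity and rank statistics

Richness counts taxa at count ≥ 1 on depth-filtered but unrarefied
counts (the read-depth filter at 8,000 reads — strictly-below removal,
applied once, globally, before any splitting — is the only
normalization; this caveat travels with the output). Shannon uses the
natural log; evenness is Pielou's `J = H/ln(richness)`, undefined at
richness ≤ 1. Group tests are Kruskal–Wallis (tie-corrected, chi-square
p) and pairwise Wilcoxon rank-sum (exact for groups of ≤ 8 without ties,
normal approximation with tie correction otherwise), with
Benjamini–Hochberg adjustment applied within each family of pairwise
comparisons — one family per analysis panel, never pooled across panels.

## Pipeline determinism

Every stochastic stage receives `stage_seed = (global·1000003 +
crc32(tag)) mod (2³¹−1)` for a stable stage tag, so adding or reordering
stages never shifts another stage's randomness. Outputs contain no
timestamps; two runs with the same config and seed are byte-identical.
The packaged synthetic study used for pipeline-level checks is
deliberately small (80 taxa, 8 samples per group, 4,000 reads, reduced
bootstrap/permutation counts) — the full-size defaults above apply to
single-stage analyses, and the test suite exercises the full sizes where
the property being checked demands them (e.g. 999-iteration null
calibration over 200 samples, 200-replicate PERMANOVA type-I
calibration).

## Design choices on genuinely open points

- Fitting the occurrence curve rather than per-taxon abundances keeps
  the estimator robust to compositional noise and is the established
  convention for this model family.
- NMDS was considered and rejected for ordination output: PCoA is
  deterministic, which the reproducibility contract requires, and on
  UniFrac-type distances the two read nearly identically.
- When an environmental source pools several sample types (feed and
  water), all source samples are weighted equally per sample; there is
  no principled basis for volumetric weighting of filtrate vs pellet
  material.
- The depth filter runs before any design split, so a sample is either
  in the study or not — per-panel filtering would make panels
  incomparable.
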