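# Methods

`soilcue` re-implements, as a tested pipeline, an analysis chain that links
soil microbial metabolic efficiency to enzyme stoichiometry, community
diversity, co-occurrence network structure, and composite-variable driver
models. This note documents the models, the defaults and why they were
chosen, what the synthetic generator does and does not emulate, and the
numerical conventions.

## Metabolic efficiency from ¹⁸O-water incubations

Soil is incubated for 48 h at 20 °C in sealed vials after adding 100 µL of
¹⁸O-enriched water (20.0 atom %). Four quantities describe the microbial
carbon economy:

* **C_respiration** (µg CO₂-C g⁻¹ h⁻¹) from the headspace CO₂ increase over
  an ambient-air control, converted with the ideal gas law
  (default 101 325 Pa, 293.15 K; both configurable).
* **C_growth** from ¹⁸O incorporation into DNA: the atom-percent excess of
  DNA oxygen over the natural-abundance control, divided by the vial-water
  enrichment excess, gives the fraction of DNA oxygen that is new; dividing
  by the oxygen mass fraction of DNA (0.31) gives new DNA, and the
  per-sample MBC:DNA mass ratio converts DNA to biomass carbon. The vial
  water enrichment is a mass-weighted two-pool mixture of label water and
  native soil water at natural abundance (0.2005 atom %). All constants are
  exposed as parameters.
* **C_uptake = C_growth + C_respiration** and **CUE = C_growth / C_uptake**
  (steady-state mass balance; CUE ∈ [0, 1] whenever both fluxes are
  non-negative).
* **MBC** by chloroform-fumigation extraction, (EC_fum − EC_unfum)/k_EC with
  k_EC = 0.45, the standard extraction-efficiency factor.
  **qCO₂ = C_respiration/MBC** and turnover time **τ = MBC/C_growth**.

Replicate triples (labeled CO₂, labeled and natural atom %) are averaged
before the excess computation. Physically impossible negative differences
produced by measurement noise (ΔCO₂, atom-percent excess, fumigation flush)
are clamped to zero with a logged warning rather than dropping the site;
undefined ratios return NaN with a warning.

## Ecoenzymatic vector model

Seven activities (BG, BX, CBH, PPO for C; NAG, LAP for N; ACP for P), in
nmol h⁻¹ g⁻¹ soil. The vector model uses

    x = (BG+CBH)/(BG+CBH+ACP),  y = (BG+CBH)/(BG+CBH+LAP+NAG)
    Length = √(x²+y²),          Angle = degrees(atan2(x, y))

Note the argument order **atan2(x, y)** — x first. This is deliberate and
kept literally from the vector-model convention this pipeline follows, so
the angle rises with relative P-acquisition effort: angle > 45° classifies a
site as P-limited, < 45° as N-limited (boundary tolerance configurable,
default 0, strict). Length is a relative C-limitation score with no absolute
threshold. The composite **enzyme activity index** is the row mean of
column-wise z-scores (sample SD, ddof = 1; population SD by flag). It is
computed on raw activities by default, with a flag to use MBC-normalized
specific activities instead — the choice is genuinely open, so both are
provided. PPO enters the index but not x/y, consistent with the ratio
definitions.

## Alpha diversity and zone tests

Chao1 uses the classical estimator S_obs + F1²/(2·F2), with the
bias-corrected fallback S_obs + F1(F1−1)/2 when no doubletons exist; no
rarefaction is applied. Shannon is reported in nats (base configurable).
Faith's PD follows the **rooted** convention (the branch path to the root is
included, so a single-leaf sample has its root-to-leaf path length); it is
computed by scikit-bio. Zones are compared by classical one-way ANOVA
(Kruskal–Wallis by option) with pairwise two-sample t-tests starred at
p < 0.05/0.01/0.001.

## Co-occurrence networks

Edges connect ASV pairs with |Spearman r| > 0.8 and two-sided p < 0.05
(raw p by default; Benjamini–Hochberg by flag). Module detection uses
greedy (Clauset–Newman–Moore) modularity maximization because it is
deterministic — reproducibility was preferred over stochastic Louvain,
which is available nowhere in the default path. Modules are labeled
Mod#0, Mod#1, … by descending size. Node roles use the cartographic
within-module degree z-score Zi and participation coefficient
Pi = 1 − Σ_t (k_it/k_i)², with the classical thresholds Zi ≥ 2.5 and
Pi ≥ 0.62 (module hub / connector / network hub / peripheral). Degrees are
unweighted. A prevalence prefilter (default: present in ≥20 % of sites)
is applied before correlation; thresholds are configurable and logged.

## Driver analysis

* **Random forest %IncMSE**: a bagged ensemble of regression trees
  (mtry = ⌈p/3⌉) in which each tree's out-of-bag rows are predicted intact
  and with each predictor column permuted; importance is the mean percent
  increase in OOB MSE. Significance is Altmann-style: the response is
  permuted and the forest refit `n_perm` times, and p is the upper-tail
  rank of the observed importance in that null (defaults 500 trees / 999
  permutations; the recovery checks use 100/99 at n = 40 sites, which the
  null-calibration test shows is already well resolved at the 0.05 level).
* **PCA composites**: each variable group (soil properties, alpha
  diversity, enzymes, efficiency) is summarized by the first principal
  component of its correlation matrix; the score sign is oriented so its
  correlation with an anchor variable is ≥ 0. The efficiency composite is
  anchored at CUE, so higher composite = higher efficiency and qCO₂ loads
  negatively — stated explicitly because orientation is otherwise
  arbitrary.
* **Recursive path model** over the four composites with the hypothesized
  structure soil → {diversity, enzymes, efficiency},
  diversity → {enzymes, efficiency}, enzymes → efficiency (configurable;
  bacteria and fungi can be fit separately). Composites are z-scored, each
  endogenous variable is regressed on its structural parents by OLS — the
  maximum-likelihood estimator for recursive, fully observed models — and
  coefficients are therefore standardized path weights. Fit statistics come
  from the ML discrepancy between the implied covariance
  (I−B)⁻¹Ψ(I−B)⁻ᵀ and the sample covariance: χ² = (n−1)·F_ML,
  df = p(p+1)/2 − free parameters, RMSEA = √(max(χ²−df, 0)/(df(n−1))),
  reported as 0 for a saturated model. Collinear composites (|r| > 0.999)
  are rejected with a diagnostic.

## Synthetic study generator

The generator's central design choice is **inversion**: per-site CUE, MBC
and qCO₂ are planted first, then the raw vial measurements (headspace ppm,
fumigation extract C, DNA mass, atom percents) are back-solved from the
forward formulas under a fixed, physically plausible vial protocol (50 mL
headspace, 0.5 g dry soil, 0.15 g native water, DNA yield set by an
MBC:DNA mass ratio of 12). Multiplicative Gaussian measurement noise
(relative SD `noise_sd`, default 0.05) is applied per replicate. At
`noise_sd = 0` the forward pipeline reproduces the planted values to
floating-point precision — an exact recovery oracle.

Study conditions follow the targeted design: 20 sites split 2/8/10 over
upstream/midstream/downstream zones, zone-mean CUE (0.2, 0.35, 0.5) rising
downstream, qCO₂ (0.0020, 0.0012, 0.0008) falling, MBC (200, 350, 500)
rising. Within-zone variation comes from a standardized latent chain
soil → diversity → enzymes → efficiency with defaults (0.5, 0.45) and a
configurable enzymes → efficiency path (default −0.65), plus small direct
paths; residuals are scaled analytically so every latent has unit variance
and the βs are exact standardized coefficients. Enzyme activities are
log-normal around field-typical baselines with loading 0.4 on the latent
enzyme factor; site CUE adds `site_sd` (default 0.03) times the latent
efficiency factor.

ASV tables plant `n_planted_modules` correlation blocks: members of a block
mix a shared per-site factor with idiosyncratic noise at latent Pearson
correlation 2·sin(π·ρ_S/6), the Gaussian-copula inverse of the Spearman
map, so the realized rank correlation targets `within_module_rho`. Mean
abundances are log-uniform between 5 and 300 counts, so rare ASVs produce
the absences and singletons that make Chao1 informative. Counts are Poisson
draws from the latent abundances (deterministic rounding at
`noise_sd = 0`); sequencing depth is tilted by exp(0.3·diversity latent) so
observed alpha diversity carries the latent diversity signal. Taxonomy is
drawn from the dominant riparian soil phyla (Actinobacteriota,
Proteobacteria, Chloroflexi, Acidobacteriota, Desulfobacterota,
Nitrospirota, Myxococcota; Ascomycota, unclassified_k_Fungi, Basidiomycota,
Mortierellomycota, Calcarisporiellomycota, Rozellomycota). Rooted trees are
random joins with exponential branch lengths, one per kingdom.

**What the generator does not emulate**: compositionality and sequencing
artifacts (no fixed library size, no overdispersion beyond Poisson, no
chimera/contamination structure), phylogenetic signal in the correlation
blocks (tree topology is independent of module membership), spatial
autocorrelation among neighboring sites, and isotope fractionation or
substrate preference in the ¹⁸O chain. Passing recovery tests therefore
demonstrates correctness of the *computations* and sensitivity of the
*statistical chain* under the assumed structure — not robustness to the
messiness of real amplicon data.

## Problem sizes and numerical choices

Recovery checks run at sizes chosen to make the statistical claims sharp
while keeping the suite fast: gradient recovery at 30 sites × 100 seeds;
module recovery at 40 sites × 100 ASVs × 10 seeds; path recovery at
n = 500 × 50 seeds; RF detection at 40 sites, 100 trees, 99 permutations ×
20 seeds; null calibration at 1,000 pairs of n = 30. Determinism: every
stage derives a named substream from the master seed; greedy modularity and
the bagged forest are exact functions of their seeds. Ties in Spearman
correlations use midranks. Integer rounding of latent abundances can tie
neighboring sites, so count-level within-module correlations at ρ = 1 are
≥ 0.99 rather than exactly 1.

## Known limitations

* The ¹⁸O growth chain assumes all new DNA oxygen derives from vial water
  and a fixed DNA oxygen mass fraction; both are parameters, not estimates.
* The path model is a complete-case, observed-variable analysis: no latent
  measurement model, no bootstrap confidence intervals, no model search.
* Zi/Pi use unweighted degrees; weighted variants are out of scope.
* Inter-domain (bacteria + fungi combined) networks are not built; the two
  kingdoms are analyzed separately.
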