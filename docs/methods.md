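# Methods

`phytocompare` cross-calibrates two observations of the same eukaryotic
phytoplankton community: amplicon sequencing of the 18S rRNA gene
(metabarcoding, "MB") and inverted-microscope counts of settled cells
(Utermöhl method, "UM"). This note documents the statistical procedures,
the generative model behind the synthetic data, the defaults and why
they were chosen, and the limits of what the simulation-based tests can
show about real data.

## Harmonization

Both data sources are mapped onto a fixed eight-rank frame (supergroup,
division, subdivision, class, order, family, genus, species). PR2-style
nine-field lineage strings drop the leading domain; microscopy exports
keep whatever depth they report, with deeper ranks `unassigned`.
Reconciliation of nomenclature happens exclusively through exact-match
name maps (rank, from, to) supplied by the user; the maps must be
idempotent and no fuzzy matching is attempted — deliberate, so that the
harmonization applied is always auditable from the map file. Two
built-in rules reflect how monitoring data are reported: the centric
diatom classes Coscinodiscophyceae and Mediophyceae are lumped into one
class (microscopists cannot split unknown centric cells between them),
and microscopy records reported at the paraphyletic order "Centrales"
without a class are assigned to that lumped class. The analyzed
community is then restricted to a 14-class whitelist; catch-all
categories ("unicells", "flagellates") are dropped first. `unassigned`
never counts as a taxon in overlap statistics at any rank.

## Abundance currencies and normalizations

Raw reads r_{i,s} of taxon i in sample s are converted to:

* **relative abundance** r_{i,s} / Σ_j r_{j,s}, spike reads excluded
  from numerator and denominator;
* **spike-normalized abundance** (r_{i,s} / r_{spike,s}) · (M_s / V_s),
  in molecules of marker per liter, where M_s is the known number of
  spike-in molecules added before lysis, V_s the filtered volume and
  r_{spike,s} the pooled reads of all spike ASVs. Because the spike is
  added before extraction, a shared extraction efficiency cancels in
  the ratio. The output is *molecules*, never cells: converting would
  require the unknown per-cell gene copy number, and that conversion is
  left to the user on purpose;
* **DNA-weighted abundance**: relative abundance × DNA yield of the
  extraction (concentration in ng/µl by default, total ng by flag) —
  comparative units only.

Microscopy supplies cells/L, biovolume (µm³/L) and carbon (µgC/L).
Carbon per cell follows the allometric law C = a·V^b with the standard
two-group coefficients (non-diatom protists: log10 C = −0.665 +
0.939·log10 V; diatoms: log10 C = −0.541 + 0.811·log10 V), shipped as
editable configuration. When a microscopy input already provides
carbon, it is used verbatim; the conversion is applied only in the
simulator and when carbon is absent. Community proportions in any
currency divide each sample by its sum over whitelist classes only.

## Comparison statistics

* **Replicate CV**: sample SD / mean of a class's community proportion
  across replicates; classes with zero mean are excluded and flagged.
  MB-vs-UM CV comparison uses a per-class Mann-Whitney test at α=0.05
  without multiplicity correction (a correction column is available).
* **Mann-Whitney U**: U = #{x_i > y_j} + ½·#{ties}. Exact two-sided p
  by the count distribution of U (Gaussian-binomial recurrence) when
  the pooled sample is tie-free and n_x+n_y ≤ 12; otherwise a normal
  approximation with tie and continuity corrections. A degenerate
  zero-variance case returns p = 1.
* **Log-log regression**: OLS on log10-transformed pairs pooled over
  class×sample (or genus×sample) observations. Zeros are dropped by
  default and counted (`zero_policy="drop"`); a pseudocount option
  (half the smallest positive value) exists. Fits with n < 3 are
  flagged, not reported. Spearman's ρ uses midranks.
* **Rare taxa**: relative abundance below 1e-4 in *every* sample;
  a cumulative variant (sum over samples below threshold) is also
  returned, plus a never-observed flag.
* **Top genera**: per method, genera ranked by mean relative abundance
  across samples (ties broken lexicographically); the two top-15 lists
  are united with membership flags.
* **Normalization grid**: full factorial {reads, spike, dna, relative}
  × {cells, carbon, biovolume} × {class, genus} × {all samples, per
  basin}, each cell a log-log fit plus Spearman on the taxa and samples
  shared between the two datasets.

## Distance-based community analysis

Bray-Curtis dissimilarity d_jk = Σ|x_ij−x_ik| / Σ(x_ij+x_ik) is
computed on community-relative proportions by default (configurable).
An all-zero sample is at distance 1 from any non-zero sample (flagged)
and 0 from another all-zero sample. PCoA uses Gower double-centering
B = −½·J·D²·J and an eigendecomposition; coordinates are eigenvectors
scaled by √eigenvalue for positive eigenvalues, negative eigenvalues
are reported but their axes omitted, and no Cailliez/Lingoes correction
is applied by default. PERMANOVA partitions squared distances
(SS_total = (1/N)Σ_{j<k} d²; SS_within = Σ_g (1/n_g)Σ_{j<k∈g} d²) into
the pseudo-F = (SS_between/(a−1))/(SS_within/(N−a)); significance comes
from random label permutations with the add-one rule
p = (1+#{F_perm ≥ F_obs})/(1+n_perm), so p is never 0 and never below
1/(n_perm+1). If SS_within = 0 the statistic is +∞ and p is reported at
that floor. Pairwise PERMANOVA runs each unordered group pair on the
sub-matrix, uncorrected p by default with a Benjamini-Hochberg column
always emitted. PERMDISP computes each sample's distance to its group
centroid in PCoA space — squared distances subtract the negative-axis
contribution and are clamped at zero before the square root — and
permutes those fixed distances across group labels around a one-way
ANOVA F. Taxon arrows are covariance biplot arrows (covariance of taxon
abundance with axis-1/axis-2 scores, scaled to unit maximum); this is a
declared approximation, not a reimplementation of any particular
plotting package.

## The synthetic-data generator

The simulator emulates a brackish-to-marine monitoring program across
five basins with mean surface salinities 2.5, 5, 7, 21.5 and 28.5
(stations jittered ±0.5), because basin-scale salinity turnover is what
structures the real communities the package targets.

**Truth layer.** Each of the 14 whitelist classes contributes
`taxa_per_class` taxa (default 3). Cell volume is lognormal around a
class-specific median (40–8000 µm³, nano- to micro-plankton;
σ_ln = 1.2, so within-class spread is comparable to the between-class
spread). The 18S copy number is k = κ·v^γ rounded to ≥ 1, defaults
κ = 100, γ = 0.9 — order-of-magnitude realistic copy numbers with the
size scaling that decouples reads from cells; γ is a first-class knob,
never hard-coded downstream. Each taxon has a Gaussian salinity niche
(center uniform on 1–32, width ≈ 4 ± 1, floored at 1.5) and a lognormal
baseline abundance (median 2·10⁴ cells/L at the optimum, σ_ln = 1.5).
True cells/L = baseline × niche factor × unit-mean lognormal noise
(CV 0.3); true molecules/L = cells × copy number, exactly.

**Metabarcoding observation.** Cells on the filter are Poisson in
c·V_s — this capture layer is what makes filtered volume matter for
detection at all; sequencing depth alone cannot. Extraction efficiency
η_s (lognormal, σ = 0.3) multiplies community and spike alike (the
spike is added before lysis), so it cancels in the spike ratio; a
mis-specification switch decouples them for robustness studies.
Per-taxon PCR bias is lognormal (σ = 0.4). Reads are multinomial over
captured molecules × η × bias plus the spike dose M·η (default
M = 2·10⁸ molecules, calibrated so the spike draws ~2% of reads, the
usual target for internal standards). Library output saturates with
DNA input as depth·y/(y+y_half) with y_half = 10⁹ molecules — roughly
the yield of a 10–20 ml sample — so very small filtered volumes return
fewer reads. Taxonomy annotation drops to genus, order or nothing with
probability 0.1 per ASV (reference-database gaps); optionally each
taxon is split into 1–5 ASVs.

**Microscopy observation.** Counts are Poisson in the 25 ml chamber
with logistic size-dependent detectability (midpoint 8 µm equivalent
spherical diameter, floor 0.05): small cells are systematically missed.
With a size-dependent blur probability (up to 0.8 below ~10 µm) a
record's lineage is truncated to order or class — small cells are
counted but not identified. Biovolume and carbon derive from the true
cell volume via the carbon model.

**Replication and volume designs.** The replication study draws six
occasions (alternating marine/brackish), freezes one true community per
occasion, and replays only the observation layers five times per
method, so between-replicate variance is purely observational. The
filtered-volume scenario (`simulate_volume_scenario`) emulates a
dedicated technical validation on one water batch: a log-spaced
concentration ladder (50 – 1.5·10⁴ cells/L) bounded below so that every
taxon is comfortably captured and sequenced from 200 ml up (≥ ~5 cells
on the filter, ≥ ~5 expected reads) while a sizable share of taxa sits
below the ~100 cells/L capture threshold of a 10 ml filter; the
library-input half-saturation is lowered to 5·10⁷ molecules so depth is
input-limited only below ~100 ml, as when libraries are pooled
equimolar. These bounds are derived from that design requirement, not
from field realism: a field community's unbounded rare tail always
leaves a few taxa between any two detection thresholds.

**Spike-recovery evaluation** regresses log estimated against log true
molecules/L and reports the median relative error over taxon×sample
pairs inside the quantification range — true within-sample proportion
≥ 10⁻³, i.e. ≥ ~100 expected reads at depth 10⁵. Below that limit
detection, not quantification, is limiting, and an error median over
detection-limited pairs would measure sequencing depth rather than the
normalization.

## What the simulations do and do not show

Passing recovery and directional tests show that the *pipeline
arithmetic* is faithful to its own generative assumptions: shared
spike/community extraction, multinomial sequencing, Poisson counting,
power-law copy numbers. Real data violate several of these in ways the
simulator only caricatures: primer and PCR bias are sequence-specific
and not lognormal-independent across taxa; reference databases miss
taxa entirely rather than dropping ranks at random; preservation
changes cell volumes; copy numbers scatter around any size law. In
particular, the simulator's one-ASV-per-taxon default understates ASV
richness relative to real communities (an ASV-splitting option
exercises the richness statistics). Quantitative agreement with any
real campaign's printed statistics is therefore out of scope for the
test suite; the suite checks oracle equivalence of the statistics,
calibration of the permutation tests, and the qualitative contrasts
the method comparison is built to detect.

One directional expectation deserves a caveat: with the copy-number
exponent γ = 0 (size-independent copy numbers), relative reads are
exactly proportional to true relative cell abundance at class level, so
the cells currency is *systematically* the best-correlated microscopy
currency whenever class median volumes differ. The carbon-vs-cells
contrast therefore does not become a coin flip at γ = 0 in this model;
it reverses sign. The test encoding a symmetric expectation at γ = 0 is
kept and documents this divergence.

## Numerical conventions

Permutations are drawn with numpy's seeded Generator without forcing
inclusion of the identity; all p-values use the add-one rule. Exact
Mann-Whitney enumeration switches to the approximation beyond pooled
n = 12. Eigenvalues within 1e-12 of zero (relative) are treated as
zero in PCoA. Degenerate inputs (all-zero samples, constant taxa,
zero within-group spread, zero spike reads) are flagged or excluded
with logged warnings rather than propagated as NaN. All generators are
bit-reproducible given (config, seed); derived seeds stay below 2³¹.

## Problem sizes used by the shipped analyses

The acceptance script simulates a 45-sample campaign (5 basins × 3
stations × 3 samples, 42 taxa, depth 10⁵), a 40-sample × 56-taxon
recovery design, a 20-sample volume series and a 6-occasion × 5-replicate
reproducibility study; the test suite uses the same or smaller sizes,
with 100-dataset batches for the directional contrasts and 1000
simulations for permutation-test calibration. These sizes keep every
Monte-Carlo standard error well inside the asserted margins.
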