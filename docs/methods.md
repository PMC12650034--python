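# Methods

## Data model and units

The analytical unit is a *sampling row*: one site visited in one season of
one reservoir, carrying a count density per taxon or functional group (FG)
in individuals per litre. Chamber counts convert to densities via
`N = 10·V0/(3·V1) · N1`, where `N1` is the number of cells counted over the
30 grid rows of a 0.1 mL chamber, `V0` the volume (mL) the 1 L sample was
concentrated to, and `V1` the volume (mL) loaded into the chamber. Both
volumes are explicit parameters — concentrate volumes of 30 and 50 mL are
both in routine use, so no constant is baked in. Biomass follows the
wet-weight convention that 1 mm³ of algal biovolume ≈ 1 mg (the factor is
configurable).

Counts have a natural zero, so missing values are forbidden in abundance
tables (absence is an explicit 0). Sensor data do not, so environment tables
admit NaN, excluded pairwise downstream. Season labels canonicalise to the
hydrological wet (spring/summer) vs dry (autumn/winter) dichotomy while the
four-season label is retained.

## Dominance

`Y_i = (n_i/N)·f_i` with `n_i` the unit's summed density over all rows, `N`
the grand total and `f_i` the fraction of rows with strictly positive
density. Both thresholds are strict inequalities as conventionally printed:
dominant taxon at `Y > 0.02`, dominant FG at a share `> 5%` of the scope
total. The share metric defaults to biomass (the layer on which dominant
groups are usually derived) with abundance as the switch; occurrence uses
strict positivity with no detection limit by default (an `eps` parameter
exists).

## Niche breadth and overlap

Site-use proportions `p_ij` are each group's density at row j divided by its
scope total; zero-total groups are excluded with a logged notice rather than
silently dropped. Levins breadth `B_i = 1/Σ p_ij²` ranges from 1 (single
quadrat) to r (uniform). Two overlap variants exist because the literature
conflates them: the **proportional-similarity (Schoener) form**
`O_ik = 1 − ½Σ|p_ij − p_kj|` is the default, and the **Pianka
product-moment form** is a flag for sensitivity analysis. Both are 1 for
identical and 0 for disjoint profiles; they differ in between
(e.g. p=(0.6,0.4) vs (0.4,0.6): 0.80 vs 0.923). High-overlap pairs use the
strict cutoff `O > 0.7`.

## Overall association (variance ratio)

On the presence/absence matrix (present iff density > eps, default 0):
`σ²_T = Σ p_i(1−p_i)` is the richness variance expected under independent
occurrences, `S²_T` the observed population variance (1/N denominator) of
per-row richness `T_j`, `VR = S²_T/σ²_T` and `W = VR·N`. The `Σ p_i(1−p_i)`
form is the only one for which VR = 1 holds in expectation under
independence, which is what makes the test interpretable; this is the form
implemented. Significance gates W against `[χ²_{0.95}(N), χ²_{0.05}(N)]`
with **N** degrees of freedom by default, matching the usual statement of
the test; a df = N−1 switch exists because part of the literature uses it.
The verdict is five-level: sign from VR vs 1, significance from the gate;
VR exactly 1 reports "none". The statistic is defined for a single group
(VR = 1 identically) and undefined when σ²_T = 0, which raises.

## Pairwise association

For each unordered FG pair a 2×2 table (a both, b only-second, c
only-first, d neither; a+b+c+d = N). Reported per pair:

- `Φ = (ad−bc)/√((a+b)(a+c)(b+d)(c+d))` — NaN (undefined, not dropped) when
  a margin is zero;
- Yates-corrected `χ² = N(|ad−bc|−N/2)²/Π(margins)`, clamped to 0 when
  `|ad−bc| ≤ N/2`, p from χ²₁; the uncorrected variant (equal to `N·Φ²`) is
  a flag. The Yates correction is the convention for the small N of survey
  data;
- the three-branch association coefficient:
  `AC = (ad−bc)/((a+b)(b+d))` when `ad ≥ bc`;
  `(ad−bc)/((a+b)(a+c))` when `bc > ad, a ≤ d`;
  `(ad−bc)/((b+d)(c+d))` when `bc > ad, a > d`;
- Bonferroni-adjusted p (`min(1, p·m)` over the m pairs), raw p kept
  alongside.

Network export is rule-configurable (`all` / `significant` / `nonzero`)
because which statistic defines an "association edge" is a presentation
choice; the edge list records sign, |strength| and significance so any rule
can be re-applied.

## Correlation and Mantel

Densities are log10(x+1)-transformed before Pearson correlation: counts are
right-skewed and contain true zeros, and the +1 pseudo-count is the
zero-preserving choice (offset configurable). "Strong" (r > 0.7, a
magnitude statement) and "significant" (adjusted p < α, an inference
statement) are deliberately separate columns — conflating them is a common
reporting slip.

Bray–Curtis distances `d = Σ|x−y|/Σ(x+y)` come from scipy's `pdist`; a pair
of all-zero rows has no defined contrast and is set to d = 0 with the pair
recorded in metadata. Environmental distances are Euclidean on per-variable
z-scores (population sd), rescaled for pairwise-deleted NaNs. The Mantel
test correlates the upper-triangle vectors (Pearson default, Spearman
optional), permutes rows and columns of the second matrix jointly, and uses
the one-sided "greater" p with the +1 correction,
`p = (1 + #{r_perm ≥ r_obs})/(1 + n_perm)`. It is implemented in-package
(rather than delegated) so that permutations are driven by an explicit seed
and runs are bit-reproducible; scikit-bio's implementation serves as an
independent cross-check in the test suite.

## Synthetic communities

The generator emulates a seasonal reservoir survey. Default design: one
reservoir × 4 seasons × 10 sites = 40 rows with the eight dominant coda
(A, D, H1, L0, M, MP, P, S1); the full four-reservoir survey (160 rows) is
one config change. Counts are sampled from a **Gaussian copula over
zero-inflated negative-binomial marginals**: per row a latent
`z ~ N(0, R)`, `u = Φ(z)`; group g is absent when `u_g ≤ 1 − occupancy_g`
and otherwise takes the NB quantile of the rescaled uniform. This yields
clumped, zero-rich counts in which a positive latent correlation produces
both positive co-occurrence and positive abundance covariation — exactly
the data pathology that makes Pearson screening and 2×2 association
disagree on real plankton data. The latent R is ground truth for
sign-recovery tests; realized count correlations are attenuated, so tests
assert signs and calibrated error rates, never exact correlation transfer.

Marginal defaults (per-FG): mean densities 6×10⁴–5×10⁵ ind./L (the common
range of reservoir phytoplankton), NB size 0.6–1.0 (strongly clumped),
occupancy 0.7, and unit biovolumes of 10⁻⁷–1.5×10⁻⁶ mm³/ind converting the
abundance layer to biomass. `mu` is the *design-wide* mean: the conditional
NB mean is `mu/occupancy`, so empirical means match `mu` regardless of
occupancy. Non-PSD correlation inputs raise with the offending eigenvalue.

Environment variables are seasonal baselines (winter COND/TDS above summer,
as in dry-season-concentrated arid reservoirs) plus `loading × site factor`
plus Gaussian noise, with pH clamped inside (0, 14) and concentrations at 0.
Two couplings to the community are available:

- default: the site factor is the realized mean latent of the community —
  a weak, emergent coupling;
- `gradient_strength γ > 0`: an explicit gradient `f_j ~ N(0,1)` is
  injected into the latent field as
  `z = √(1−γ²)·z_R + γ·f_j·g`, with response `g` alternating ±1 so the
  gradient shifts *composition*, not just yield. At γ = 0.8 with doubled
  loadings the Mantel test detects the coupling in essentially every
  40-row replicate.

Seasonal forcing of abundance (multipliers on `mu`) exists but defaults to
**off**: both the community and the environment would otherwise carry the
season signature, so a zero-loading configuration would not be a true
Mantel null. Enabling it (e.g. wet 1.3–1.6, dry 0.4–0.7) is appropriate
when the analysis pools seasons anyway.

Scenarios: `stable_reservoir` (all latent correlations +0.6, occupancy
0.75 — the shared-niche regime), `disturbed_reservoir` (two antagonistic
4-group blocks, +0.3 within and −0.45 between, occupancy 0.55 — an
all-negative equicorrelation matrix is not PSD for 8 groups, so antagonistic
blocks are the faithful competitive structure; eigenvalues 0.1/0.7/3.7 ≥ 0),
and `independent` (R = I). Replicated checks confirm the designed regimes:
the stable scenario yields more positive than negative pairs in ~100% of
replicates, the disturbed one VR < 1 in ~100%, and the independent one a
non-significant verdict in ~93% (two-tailed nominal level 0.10).

**What passing tests do and do not show.** The copula reproduces
overdispersion, zero inflation, controllable co-occurrence and an
environmental gradient; it does not simulate taxonomic aggregation error,
temporal autocorrelation between seasons, spatial autocorrelation among
sites, detection error at low density, or mechanistic dynamics (succession,
grazing, hydrology). Calibration and recovery results therefore validate
the *statistics*, not any field inference.

## Numerical choices and problem sizes

- Normalisation of niche profiles is validated to 1e-9; identity/oracle
  comparisons use 1e-10–1e-12 absolute tolerance.
- NB quantile inputs are clipped to [1e-12, 1−1e-12] to avoid infinite
  quantiles at u = 1.
- Chi-square quantiles and p-values come from scipy; random streams are
  numpy `default_rng` seeded explicitly everywhere (pipeline sub-stages
  derive fixed offsets from the run seed).
- Replication sizes were chosen so each simulation answers its question
  with comfortable Monte-Carlo error on a single CPU in minutes: 2000
  replicates for the variance-ratio level, 500 × 199 permutations for the
  Mantel null, 200 per scenario for sign recovery.
- Degenerate inputs: all-zero tables raise for dominance; zero-total FGs
  are excluded (and itemized) from niche profiles; zero-margin 2×2 tables
  propagate NaN; σ²_T = 0 raises; all-zero site pairs get Bray–Curtis 0
  with a flag.

## Known limitations

- The pipeline treats sampling rows as exchangeable quadrats; repeated
  visits to the same physical site across seasons are not modelled as
  repeated measures.
- Bonferroni is conservative at 28 pairs; no FDR option is wired in.
- The Mantel permutation loop is pure Python — ample for surveys of tens of
  sites, not tuned for hundreds.
- Ordination (RDA/NMDS), PERMANOVA and random-forest importance ranking are
  intentionally out of scope; the outputs (CSV matrices, GraphML) are meant
  to feed such tools.
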