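# fgniche

Niche differentiation and interspecific-association statistics for
phytoplankton functional groups in reservoir surveys.

Seasonal phytoplankton monitoring in reservoirs is usually summarised at the
level of Reynolds/Padisák functional groups (coda such as A, D, H1, L0, M,
MP, P, S1): sets of taxa sharing morphology, physiology and habitat
preference. Given a site × functional-group abundance table (ind./L, with an
optional biomass layer in mg/L) and a site × environment table, `fgniche`
answers the standard questions of quantitative community ecology for this
setting, for limnologists and ecologists analysing survey data:

- **Which groups dominate?** The dominance index
  `Y_i = (n_i / N) · f_i` (relative abundance × occurrence frequency;
  dominant when `Y > 0.02`), and the share rule (dominant when a group's
  share of total abundance or biomass strictly exceeds 5%).
- **How are niches partitioned?** Levins niche breadth
  `B_i = 1 / Σ_j p_ij²` over the r sampling quadrats, and pairwise niche
  overlap `O_ik = 1 − ½ Σ_j |p_ij − p_kj|` (proportional similarity; the
  product-moment Pianka form `Σ p_ij p_kj / √(Σp_ij² Σp_kj²)` is available
  as a comparator), with high-overlap pairs at `O > 0.7`.
- **Do groups associate overall?** The variance-ratio test on
  presence/absence: `σ²_T = Σ_i p_i(1−p_i)`, `S²_T = (1/N) Σ_j (T_j − t̄)²`,
  `VR = S²_T / σ²_T`, `W = VR·N`; VR > 1 means overall positive association,
  VR < 1 negative, with significance when W falls outside
  `[χ²_{0.95}(N), χ²_{0.05}(N)]`.
- **Which pairs associate?** 2×2 contingency tables (a, b, c, d) per pair
  with the point correlation coefficient
  `Φ = (ad − bc)/√((a+b)(a+c)(b+d)(c+d))`, the Yates-corrected χ², the
  three-branch association coefficient AC, and network export (edge list +
  GraphML).
- **Do abundances covary, and does the environment structure the
  community?** log10(x+1) Pearson pair screening with Bonferroni
  correction, Bray–Curtis distances, and a seed-deterministic one-sided
  permutation Mantel test against z-scored environmental distances.

Because field survey data of this kind are rarely deposited, the package
ships a first-class synthetic generator (`fgniche.synthetic`): a Gaussian
copula over zero-inflated negative-binomial marginals that reproduces the
clumped, zero-rich structure of phytoplankton counts with a *known* latent
association matrix, so every statistic can be validated against ground
truth. Three named scenarios (`stable_reservoir`, `disturbed_reservoir`,
`independent`) encode positive-association, competitive and null regimes.

## Worked example

```sh
fgniche run --scenario stable_reservoir --seed 3 --out results/demo --scope pooled
cat results/demo/summary.txt
```

prints:

```
fgniche pipeline summary
scope mode: pooled
dominant units (Y > 0.02): A, D, H1, L0, M, MP, P, S1
[pooled]
  VR = 2.6443, W = 105.7729, verdict = significant-positive; pairs: 26 positive / 1 negative
  high-overlap pairs (O > 0.7): 1
  correlations: 28 positive, 0 negative, 0 strong (r > 0.7), 5 significant
Mantel (community vs environment): r = 0.0896, p = 0.0880
```

Read: in this generated stable-reservoir year (40 sampling rows, 8 groups)
all eight groups are dominant; richness varies 2.6× more across sites than
independent occurrences would allow (W = 105.8 ≫ χ²₀.₀₅(40) ≈ 55.8), an
overall positive association; 26 of 28 pairs co-occur positively and all 28
abundance correlations are positive. Re-running with the same seed
reproduces the bundle byte-for-byte (manifest timestamp aside).

The same stages are available as library calls (`fgniche.dominance_index`,
`fgniche.variance_ratio`, `fgniche.mantel`, ...) and as the numbered
narrative drivers under `analysis/` (simulate → dominance → niche →
association → correlation/Mantel → calibration), which write their tables
under `results/`.

## Layout

- `src/fgniche/` — the library: `core_data` (I/O, aggregation, unit
  conversions), `dominance`, `niche`, `association`, `correlation`,
  `synthetic`, `pipeline`, `cli`.
- `analysis/` — numbered drivers over the library.
- `tests/` — unit, property (hypothesis) and acceptance suites.
- `docs/methods.md` — models, assumptions, parameter choices, limitations.
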