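# Methods

## Model

For an autosomal recessive disease under Hardy–Weinberg equilibrium (random
mating, no inbreeding or population structure, no selection differential
among genotypes at birth), the birth prevalence equals `q²`, where `q` is the
total disease-allele frequency. The indirect estimation chain therefore runs

```
F_d = n / (N · h)          registry prevalence
q   = √F_d                 Hardy–Weinberg inversion
af_v = q · f_a(v)          per-variant population AF
```

with `n` the registered affected children under the age horizon `h`, `N` the
mean annual births over that horizon, and `f_a(v)` variant *v*'s proportion
among disease alleles observed in genotyped patients. Since the `f_a(v)` over
a full partition of patient alleles sum to 1, the per-variant indirect AFs
sum to `q` exactly (a property test enforces this).

Assumptions worth stating explicitly: the registry is a complete census of
affected children (no ascertainment correction is applied — incompleteness
biases `q`, and hence every `af_v`, downward; `simulate.thin_registry`
emulates it but no correction is implemented); patients genotyped for the
spectrum are exchangeable with registered patients; and all cohorts are
diploid, so the allele number is always `2n` individuals.

## Parameters

| parameter | units | default | rationale |
|---|---|---|---|
| `horizon_years` | years | 18 | registries record children "under 18"; a parameter because conventions differ |
| `ci_level` | probability | 0.95 | standard reporting level |
| CI method | — | Clopper–Pearson | exact interval; reproduces the published (0.0053, 0.0117) for 27/3342, which the Wald interval does not; Wilson available |
| Yates policy | — | `auto` | continuity correction on 2×2 tables only, the convention of mainstream statistics software (and the one the published 2×2 value 15.238 ≈ 15.26 corrected, vs 16.04 uncorrected, implies); `on`/`off` override |
| keep set | — | top 2 categories by allele count | per-variant counts outside F508del and CFTRdele2,3(21kb) are too small to test region by region, so everything else is pooled into `other` |
| AF output precision | decimals | 4 | the convention of the source tables; full precision retained internally |

## Numerical and formatting choices

- **Missing data.** `n.a.`, `NA` and empty cells parse to MISSING (`None`);
  MISSING is never coerced to 0. Aggregates (total burden) report how many
  entries were excluded; pairwise cohort tests on a MISSING entry raise.
- **Count reconstruction.** Published AF columns are 3–4-decimal roundings;
  where a test needs counts, they are reconstructed as
  `round(af · allele_number)` and every reconstruction is logged, so small
  discrepancies with published statistics stay traceable.
- **Internally rounded source rows.** In the shipped spectrum tables one
  row's counts sum to 652 alleles against 2n = 646, and the national
  aggregate row's label (n = 3292) disagrees with the registry total
  (n = 3298). The reader warns (rather than fails) when counts deviate from
  2n by more than one allele, and when a printed AF disagrees with
  count/total by more than 5×10⁻⁴. Consequently the 8-district χ² is 198.68
  from the printed counts but 197.49 from counts re-derived as
  `round(AF · 2n)` (`read_spectrum_table(..., counts_from="af")`); the
  published 197.55 evidently traces to the rounded AFs. Both routes are
  computed and checked.
- **Degenerate tables.** A zero column margin has no defined χ² statistic
  and raises `DegenerateTableError`; expected counts below 5 log a warning
  (Fisher's exact test is deliberately out of scope). `yates="on"` for a
  non-2×2 table raises, since the correction is defined for df = 1 only.
- **p-values** are computed in full and rendered as `< 2.2e-16` below that
  floor in reports. No multiple-testing correction is applied; reports list
  nominal p-values.
- The published Yugra-direction statistic (14.065, df = 2) is not
  reproducible from any grouping of the published counts, and the three-way
  total-burden comparison (100.19, df = 2) depends on unpublished unrounded
  counts; both tests are implemented generically (`chi_square_test`,
  `compare_total_burden`) without asserting those two values.

## Synthetic data

The generator draws what the estimation chain assumes and nothing more:
alleles are i.i.d. (disease with probability `q_true`, variant assigned by
`fa_true`), affected births are `Binomial(N·h, q_true²)`, and the patient
spectrum is `Multinomial(2·n_patients, fa_true)` summing exactly to
`2·n_patients`. Defaults are the national registry-scale conditions:
`q_true = 0.0105`, spectrum 0.5155 / 0.0611 / 0.4234
(F508del / CFTRdele2,3(21kb) / other), 140,000 births/year over 18 years,
300 patients genotyped, and a 100,000-individual population draw.

It deliberately omits population structure and inbreeding, genotyping error,
variant-specific survival or diagnosis-age differences, and registry
ascertainment bias (beyond optional thinning). Passing recovery tests
therefore show the *arithmetic chain* is unbiased under its own assumptions
at these problem sizes — not that real registry estimates are unbiased;
against real data the chain inherits whatever incompleteness the registry
has (the direction of that bias is downward).

Reproducibility: one master seed per experiment; replicate `i` uses the
independent stream `SeedSequence(seed, spawn_key=(i,))`, so results are
portable across machines and replicate subsets.

## Validation problem sizes

Monte-Carlo checks run at: 500 replicate registries for recovery (mean
indirect AF within 5% relative of `q_true · f_a`), 10,000 replicates of 10⁶
births for Hardy–Weinberg prevalence convergence (within 2% relative of
`q²`), a 10⁶-individual population draw for the direct-AF moment check
(within 3 binomial SE), brute-force oracle equivalence for the χ² statistic
on all small tables (total ≤ 50; tolerance 10⁻¹⁰) and for Clopper–Pearson
bounds at allele numbers ≤ 200 (tolerance 10⁻⁶, against root-finding on
binomial tail sums). These sizes make the full suite run in a few seconds
while leaving Monte-Carlo error well inside the asserted tolerances.

## Known limitations

- No ascertainment-bias correction (see above); indirect AFs are lower
  bounds in under-registered regions.
- The q inversion assumes a *fully penetrant recessive* disease; CFTR-RD
  phenotypes (e.g. CBAVD) with milder alleles violate this for those alleles.
- HGVS strings in the variant catalog are carried as labels, not validated
  against a transcript; no liftover or annotation lookup.
- Collapsing to `keep + other` discards information about rare-variant
  heterogeneity; the choice of `keep` is configurable but results depend
  on it.
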