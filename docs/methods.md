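# Methods

## Two-level least-squares model

**Level 1 (per period).** For each calendar period t the Gompertz law
`ln μ(x) = ln m₀ + α·x` is fitted by unweighted OLS to (age, ln Mx) points
inside an inclusive age window, default [40, 95]. Central death rates Mx
are used directly as the mortality intensity; no smoothing or
transformation is applied. Mortality residuals around the Gompertz line are
U-shaped rather than Gaussian, so the fits are point estimates only — no
standard errors or tests are attached, and R² is reported purely as a
geometric goodness-of-fit.

**Level 2 (across periods).** The SM correlation `ln m₀ = YA − A·α` is
fitted by unweighted OLS with ln m₀ as the response and α as the predictor
(this direction follows from the model statement; orthogonal regression
would estimate a different quantity). The rotation age A is minus the
slope, YA the intercept.

**Residual band.** The band lines are the SM regression line shifted by the
extreme residuals r_max and r_min on the log-intensity scale; the band
width is reported as L2/L1 = exp(r_max − r_min). This reading makes the
ratio independent of where on the α axis it is measured and reproduces the
published band widths for the bundled Swedish and French series (2.06,
2.44), which validated it before freezing.

**Diagnostics.** First differences α(t) − α(t−1) are computed on
full-precision slopes; a strictly negative difference is flagged NEG ("N"),
zero is NONNEG (only a decrease contradicts SM-type development), and the
first period of a series is UNDEFINED. Cross-population concordance matches
periods by canonical label equality only — no fuzzy alignment of differing
period grids.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| age window | [40, 95] | years, inclusive | adult range where the log-linear law holds; childhood and extreme old age deviate |
| age coordinate | class label x | years | lower bound of [x, x+1); a midpoint switch (x+0.5) exists for sensitivity — it shifts ln m₀ by α/2 and leaves α and all second-level slopes unchanged |
| rate column | Total | — | combined-sex series |
| positivity filter | drop cells ≤ 0 or missing | — | ln of 0 undefined; exclusions are logged, never imputed |

## Synthetic data generator

The generator emits exactly the structure the analysis assumes:
`ln μ(x,t) = YA + α_t·(x − A) + δ_t`, Gompertz schedules rotating about
(A, YA) with optional per-period intercept shocks δ_t. Noise models:
`none` (rates equal exp of the true log intensity), `poisson`
(deaths ~ Poisson(exposure·μ), rate = deaths/exposure, zero-death cells
become missing — mirroring both the ln-positivity filter and the behaviour
of sparse historical cells), and `lognormal` (ln rate + N(0, σ²)).
Determinism is per-period: each period draws from a generator keyed on
(seed, CRC32 of its label), so subsetting periods does not reshuffle the
remainder.

The default scenario — 26 five-year periods, ages 40–95, A = 100 years,
YA = −0.6, α rising linearly 0.06 → 0.11, exposure 10⁶ person-years per
cell — matches the range the long Swedish series actually traversed
(α 0.0625 → 0.1102). No published noise level exists for deviations around
the SM line, so the Poisson/lognormal mechanisms are explicit stand-ins:
a green recovery test establishes that the estimation chain is unbiased
and tight under register-style sampling noise, not that real data meet the
rotation model. Real mortality surfaces additionally contain cohort
effects, age heaping, wars concentrated at specific adult ages, and
non-rotational intercept drift (the French mid-20th-century pattern), none
of which the generator emulates beyond the single-period intercept shock.

## Numerical choices

- Both OLS levels go through a single lstsq path; tests check it against an
  independent normal-equations oracle at 1e−10 relative tolerance.
- Zero total sum of squares (all responses equal) defines R² = 1 (the flat
  line fits perfectly); a single distinct predictor value is an error, not
  a NaN.
- Parameter tables carry display-rounded columns (α to 4 decimals, ln m₀ to
  2, R² to 4 — the conventional layout) alongside full-precision repr
  columns; reading prefers the full-precision set, making write→read the
  identity. Flags and differences are always computed on unrounded values;
  when a published table's own rounded entries disagree with a recomputed
  flag at printed precision (a known case exists in the French series,
  1900–1904), the recomputation is reported as-is rather than forced to
  match.
- Period labels are canonicalized with an en-dash; hyphens and single years
  are accepted on input, and trailing footnote asterisks are stripped.
- Any non-numeric rate token becomes a missing cell with a logged warning,
  so minor HMD dialect drift does not abort a run; duplicate (age, period)
  cells are an error.
- The Mx-dialect writer uses scientific notation at 12 significant digits:
  fixed 8-decimal formatting truncates small adult rates enough to perturb
  refits at the 1e−6 level.

## Design choices made where the design was open

- Regression direction ln m₀ on α, not the reverse and not total least
  squares (see above).
- Integer age-class labels as the age coordinate by default; the published
  parameter magnitudes are reproduced under this choice.
- Ties in the first-difference sign (diff exactly 0) break toward
  consistency with the SM model (NONNEG).
- Refits from printed-precision parameter tables are expected to match
  published second-level statistics only within rounding-driven tolerances
  (±1 year on A, ±0.01 on R², ±0.06 on L2/L1), since whether the original
  second-level fits used rounded or full-precision inputs is unknowable
  from the printed table alone.

## Limitations

- The bundled parameter series cover Sweden and France only; the
  Netherlands long series (1850–2021, published A ≈ 106.5, R² 0.985,
  L2/L1 1.89) was not available at build time. `load_netherlands_params`
  raises, and the corresponding acceptance test stays red until a user
  supplies that series as a CSV via `read_params_table`.
- Raw HMD Mx files are registration-gated and not redistributed; the full
  level-1 reproduction from national rate surfaces is an integration
  exercise requiring the user's own HMD download. Desk-scale validation of
  level 1 rests on the synthetic generator and the OLS oracle.
- No Gompertz–Makeham background term, no Poisson maximum likelihood, no
  cohort (diagonal) analysis, no inference on either regression level.
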