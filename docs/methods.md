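# Methods

This note documents the models, conventions and numerical choices behind
`resilnet`, in the spirit of a statistical software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Structural network efficiency

A connectome is an $n \times n$ symmetric matrix $W$ of streamline counts
between gray-matter atlas regions ($n = 106$ for the Harvard–Oxford
cortical parcellation the pipeline defaults to). A streamline touching
$k \ge 2$ regions increments all $k(k-1)/2$ region pairs by one — once
per streamline, regardless of how often it enters a region. Connections
supported by fewer than 3 streamlines are removed (`apply_threshold`,
threshold configurable).

Global efficiency is computed with the weighted convention: the edge
between $i$ and $j$ has length $1/W_{ij}$, $d_{ij}$ is the shortest
summed length over paths (Dijkstra from every source via
`scipy.sparse.csgraph`), and

$$\mathrm{SNE} = \frac{1}{n(n-1)} \sum_{i \ne j} d_{ij}^{-1},$$

summing over *ordered* pairs with $d_{ij}^{-1} := 0$ for unreachable
pairs. Design choices worth making explicit:

- **Disconnected graphs.** SNE is computed on the full node set, never a
  largest-component restriction; unreachable pairs simply contribute 0.
  Hence SNE = 0 exactly when the thresholded graph has no edges.
- **Linearity.** Scaling all counts by $c > 0$ scales SNE by $c$. The
  synthetic connectome generator exploits this: it draws an
  Erdős–Rényi support, rescales counts by target/SNE(base), rounds to
  integers, and verifies the achieved SNE lands within 2% of the target
  (raising an explicit error otherwise).
- With count weights on a dense cortical parcellation this measure lives
  on the scale of hundreds, matching the cohort summary the generator
  defaults to (250.6 ± 16.8).
- Shortest-path ties need no tie-breaking: only the distance value
  enters the formula.

## The resilience model

For each longitudinal cognitive outcome COG (inverted ADAS-cog, CDR-SOB,
MMSE), time from baseline $T$ (months), candidate resilience factor
RES = SNE and the three baseline pathology measures PATH ∈ {AV45, TAU,
WMHV}:

```
COG ~ 1 + T + RES + Σ_p [ PATH_p + T*PATH_p + RES*PATH_p ]
        + age + gender + education + APOE4            (base terms)
        [+ T*RES] [+ T*RES*AV45] [+ T*RES*TAU] [+ T*RES*WMHV]
        + (1 | subject) + (1 | clinical status) + ε
```

The four bracketed resilience terms are toggled on/off, giving a
16-member model group per outcome. The three-way terms do **not** force
`T*RES` into the model: general resilience is a separately toggled
hypothesis, while each three-way term's two-way children `T*PATH` and
`RES*PATH` are always present in the base, so marginality over the base
lattice holds for every member and all 16 members are distinct.

**Standardization.** All continuous variables are z-scored on full
analysis-sample moments *before* interactions are formed — baseline
variables at the subject level (one row per subject, so visit counts do
not weight the moments), time and outcomes at the visit level. Binary
covariates stay 0/1. Interaction columns are products of standardized
components; coefficients are therefore standardized regression
coefficients. WMHV enters as $z(\log(\mathrm{WMHV}/\mathrm{TIV}))$
(natural log); ADAS-cog is negated before standardization so that higher
always means better performance. Subjects with fewer than two visits are
excluded and logged.

## Mixed-model estimation

The model has independent Gaussian random intercepts for subject and
clinical status plus i.i.d. residuals. Writing
$\gamma_f = \sigma^2_f/\sigma^2_e$, the likelihood is profiled over the
fixed effects and $\sigma^2_e$, leaving a 2-dimensional bounded problem
in the variance ratios, solved by Nelder–Mead on $\theta_f =
\sqrt{\gamma_f}$ with $\theta_f \in [0, 10^3]$ (default tolerances
`xatol=1e-6`, `fatol=1e-9`). All per-evaluation algebra is pushed into
the random-effect dimension via the Woodbury identity
$V_0^{-1} = I - Z A^{-1} Z'$ with $A = \mathrm{diag}(1/\gamma) + Z'Z$,
so one evaluation costs $O(q^3)$ with $q$ = number of random-effect
levels, independent of the observation count — this is what makes
parametric bootstrapping at scale practical (a warm-started refit of a
240-observation model takes ~5 ms). A ratio optimized to (or started
at) zero drops its factor exactly; with all ratios zero the fit *is*
ordinary least squares, a boundary identity the tests assert.

Estimation is by **ML for every fit entering likelihood-ratio testing**
(fixed-effect LRTs require ML); REML is available and is validated
against the closed-form balanced one-way ANOVA estimators and against
`statsmodels.MixedLM`. Starting values come from a method-of-moments
pass on OLS residual group means. If a full model's optimizer lands
marginally below its reduced model (possible with any local optimizer),
the LRT refits the full model warm-started at the reduced model's
variance ratios and takes the better optimum; the statistic is clipped
at zero.

**Conditional AIC.** Model ranking uses
$\mathrm{cAIC} = -2\,\ell_{\mathrm{cond}} + 2(\rho + 1)$, where
$\ell_{\mathrm{cond}}$ evaluates the residual Gaussian density at the
conditional (BLUP) fitted values and $\rho$ is the trace of the hat
matrix mapping observations to conditional fitted values at the
plugged-in variance estimates,
$\rho = p + \mathrm{tr}(A^{-1}Z'Z) - \mathrm{tr}(A^{-1}U B^{-1} (Z'V_0^{-1}X)')$
with $U = Z'X$, $B = X'V_0^{-1}X$. At zero variance ratios
$\rho = p$ and cAIC is the linear-model AIC with $p+1$ parameters. The
Greven–Kneib boundary correction to the effective degrees of freedom is
*not* implemented; only cAIC differences within a model group sharing
one random structure are consumed, where the omission cancels to first
order. This is a documented limitation, not an oversight.

**Selection and testing.** Within each group the lowest-cAIC model is
best (ties break toward fewer toggled resilience terms); all models with
ΔcAIC < 2 are retained; significance testing is restricted to the
resilience terms contained in *all* retained models, which guards
against testing terms whose evidence is selection noise. Each common
term is tested by LRT (full = best model, reduced = best minus the term,
df = 1) and by a parametric bootstrap: B datasets simulated from the
reduced fit's estimated fixed effects and variance components, both
models refit per replicate (warm-started at the generating ratios, with
replicate tolerances relaxed to `xatol=1e-3`/`fatol=1e-7`, which costs
< 1e-5 in log-likelihood), and
$p = (1 + \#\{LRT^* \ge LRT_{\mathrm{obs}}\})/(B + 1)$ — never exactly
zero. The default B = 1000 is a desk-scale choice; B is a flag
(`inference.B`) for users who want bootstrap resolution comparable to
large-scale runs. Non-converged replicates are dropped and counted,
with a warning above 10%.

**FDR.** The LRT p-values of all tested resilience terms are pooled
across the three outcomes into a single Benjamini–Hochberg family at
q = 0.05 (one family rather than per-outcome families: the three
outcomes form one hypothesis screen, and a single family is the more
conservative reading when all terms are reported together). Bootstrap
p-values are reported alongside.

**Diagnostics.** Marginal R² is the fixed-effect variance share
$\mathrm{var}(X\hat\beta) / (\mathrm{var}(X\hat\beta) + \hat\sigma^2_s +
\hat\sigma^2_c + \hat\sigma^2_e)$; VIFs are computed per non-constant
design column of the best model.

## Synthetic cohort generator

The generator is first-class, tested code: it defines the conditions
under which the inference machinery is validated.

- **Baseline marginals** default to a published at-risk cohort summary
  (n = 85; age 72.6 ± 6.5, education 16.1 ± 2.7, SNE 250.6 ± 16.8, AV45
  1.19 ± 0.22, CSF tau 83.5 ± 52.7, WMHV 0.53 ± 0.49; 40% female, 48%
  APOE4 carriers, 60% MCI). TIV is not part of that summary and defaults
  to a typical adult 1400 ± 130 cm³. Continuous variables are truncated
  normals (pathology kept positive); binary variables Bernoulli.
- **Visits** default to months 0, 12, 24, 36, 48, complete for every
  subject; an optional per-visit dropout probability (never touching the
  first two visits, so the ≥ 2-visit inclusion rule is satisfied by
  construction) emulates variable follow-up.
- **Outcomes** are generated directly on the standardized scale from the
  full resilience model: linear predictor (built by the *same* term
  algebra the inference side uses, including the log-WMHV/TIV transform
  inside the predictor) + subject intercept (SD 0.5) + status intercept
  (SD 0.2) + residual (SD 0.6). The stored `adas_cog` column is negated
  relative to the model scale, mirroring the real instrument; the
  analysis re-inverts it. `table2_preset(outcome)` installs the
  published standardized resilience-term magnitudes (e.g. CDR-SOB:
  T×SNE = 0.098, T×SNE×AV45 = 0.276, T×SNE×TAU = −0.069,
  T×SNE×WMHV = −0.058) on top of plausible base effects (decline with
  time, steeper under pathology).

Because the analysis z-scores the outcome with its own sample SD, the
generating coefficients are recovered on the analysis scale as
$\beta/\mathrm{sd}(y)$; the validation harnesses apply exactly this
rescaling rather than tuning the generator so that sd(y) = 1.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: the visible right-skew of tau and WMHV
(truncated normals are a stand-in, not a distributional claim);
correlations among pathology measures (independent by default; a
Gaussian-copula correlation hook exists); floor/ceiling effects and
integer scoring of real cognitive instruments; site/scanner effects;
informative dropout.

## Validation problem sizes

The statistical harnesses in `tests/test_acceptance.py` use: parameter
recovery — 100 replicates of 200 subjects × 5 visits (coverage of ±2 SE
intervals ≥ 90% per coefficient); cAIC selection — 50 seeds with a
single nonzero resilience term (β = 0.276), plus 50 null seeds whose
false-inclusion rate is reported, not failed (AIC-family selection is
expected to overfit under the null); bootstrap calibration — 200 null
replicates of 60 subjects × 4 visits at B = 199, empirical size required
in [0.03, 0.08] at nominal 5%. These sizes were chosen as the smallest
designs at which the asymptotic approximations under test are expected
to hold.

## Known limitations

- The clinical-status random factor has two levels; its variance is
  weakly identified and often estimated at the boundary (zero). This
  follows the stated model; `status_random=False` demotes it out of the
  random structure if desired.
- Random intercepts only; no random slopes for time.
- No robust (Huber-type) mixed-model re-estimation; no Kenward–Roger or
  other small-sample df corrections — LRT p-values are asymptotic, which
  is precisely why the parametric bootstrap is offered alongside.
- cAIC effective df omits the Greven–Kneib boundary correction (above).
- The generator's marginals match published means/SDs, not shapes.
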