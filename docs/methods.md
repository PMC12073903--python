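# Methods

## Statistical model and procedure

The pipeline treats each (organ, sex) stratum independently — no
cross-organ pooling — matching per-organ reporting. Two passes run over
a samples × compounds intensity table:

**Univariate pass.** Each treatment arm and the 4-month Young reference
arm is compared against the 12-month control arm with a two-sided
Mann-Whitney *U* test. *U* is computed from midranks, so ties count ½.
Exact p-values come from the classic rank recurrence when the pooled
sample is tie-free (full assignment enumeration otherwise, guarded by a
feasibility cap); the asymptotic mode uses the normal approximation with
tie-corrected variance and a 0.5 continuity correction. The two-sided
p-value is the doubled smaller tail, capped at 1 — the convention that
matches common implementations and keeps exact and asymptotic modes
mutually consistent. Missing intensities are excluded pairwise per
compound and never imputed; a compound whose post-exclusion group sizes
fall below two is skipped with a logged reason rather than silently
dropped.

**Trend pass.** The Jonckheere-Terpstra statistic
J = Σ_{i<j} U_{ij} is computed over treatment groups ordered by the
per-sex average lifespan-extension percentage. Only the ordering enters
the statistic; the percentages are labels. The female ordering contains
a tie (17aE2 and Cana both at 1%): by default the printed left-to-right
order is used as the ordinal sequence, because the test requires a total
preorder and the tie cannot influence J's expectation either way;
`merge_tied_levels` collapses tied groups into one ordinal level for
sensitivity analysis. The Young arm is a reference, not an intervention,
and is excluded from the trend order by default (`include_young` places
it first at its own level).

Exact JT null distributions (tie-free) are obtained by Harding's
decomposition: under exchangeability J is the sum of independent
Mann-Whitney statistics of each group against the union of the groups
preceding it, so the null mass function is the convolution of
Mann-Whitney null counts, computed in exact integer arithmetic. This is
arithmetically identical to enumerating every distinct assignment of
observations to groups, at polynomial instead of multinomial cost. With
ties present, exact mode falls back to literal enumeration while the
multinomial count is at most 10^6. The permutation mode shuffles pooled
values with a caller-supplied seed recorded in the result metadata.

The asymptotic mode uses E[J] = (N² − Σ n_k²)/4, the standard
tie-corrected variance, a 0.5 continuity correction, and — tie-free —
an Edgeworth correction using the exact fourth cumulant
κ₄(U(m,n)) = −mn(m+n+1)(m²+n²+mn+m+n)/120 summed over the Harding
decomposition. The JT null is symmetric, so the skewness term vanishes
and the kurtosis term is the leading correction; it reduces the
worst-case deviation from the exact p on 3–4 groups of 2–4 observations
from ≈0.027 to ≈0.007 while being numerically inert at study-sized
groups.

**Multiple testing.** Benjamini-Hochberg step-up q-values, computed per
family. The family is the set of compounds within one
(organ, sex, contrast) for the univariate pass and one (organ, sex) for
the trend pass — the narrowest reading consistent with per-organ
reporting. NaN p-values are excluded from the family and re-inserted as
NaN. Significance thresholds default to q < 0.1 for both passes.

**Class enrichment.** Per annotation subclass with at least
`min_class_size` (default 3) members, the one-sample Kolmogorov-Smirnov
statistic of the members' *raw* p-values against Uniform(0,1). Exact KS
p-values for n ≤ 50 use the Marsaglia-Tsang-Wang matrix method; larger
sets use the Kolmogorov limit with Stephens' effective-√n correction.
A class is reported at raw KS p < 0.05; no correction is applied across
classes by default (an option exists) because the class statistic is a
screening summary, not an inferential endpoint. The up/down counts
inside the directional fraction (n↑ − n↓)/n need a per-compound
significance rule that the set statistic itself does not supply; the
default is BH q < 0.1 (the only rule stated anywhere in the reported
analysis), with `sig_rule="raw:0.05"` as the alternative. Set membership
is the annotation subclass directly; no structure-similarity clustering
is performed.

## Lipid annotation

Shorthand grammar: `CLASS C:D[;modifier]*`, with the parenthesised
dialect (`TG(58:8)`) normalised on input and `O-`/`P-` prefixes marking
ether species. Any `O`-family suffix modifier (`;O`, `;O2`, `;OH`)
flags oxidation; oxidized TAG and FA species form derived `ox_TAG` /
`ox_FA` subclasses rather than separate parses. Unknown class codes
raise a distinct error — the parser never guesses. `TAG 0:0` parses
(the grammar is total on well-formed strings) but is rejected by the
binning precondition `total_carbons > 0`.

Chain-length bins: TAG — short < 48, long 48–57, very-long ≥ 58 total
carbons. The printed bands ("48–56" and "> 57") leave exactly 57
unassigned; the long band absorbs it so the three bins partition the
integers, and the crisper "> 57" inequality for very-long is preserved.
DAG and PC share boundaries short < 33, long 33–38, very-long ≥ 39,
the unique clean partition consistent with the printed "> 38", "> 32",
"< 32" inequalities. Unsaturation bins: TAG — 0–2 saturated, 3–5
intermediate, ≥ 6 PUFA-enriched; DAG/PC — 0–2, 3–4, ≥ 5. The
PUFA-enriched thresholds are the complements of the printed saturated
and intermediate bands (a PUFA acyl chain carries ≥ 3 double bonds; no
explicit numeric threshold for the enriched band is printed, so the
complement reading is this package's decision). All boundaries are
configurable per class.

Amino-acid categories are assigned by a total rule cascade: exact match
against the 20 proteinogenic names; dipeptide detection by two-residue
naming (residue-yl prefix + proteinogenic name); a packaged
non-proteinogenic list; proteinogenic root + modification marker
(acetyl, methyl, hydroxy, sulfoxide, ...) → derivative; everything else
falls back to non-proteinogenic with a log entry. Chemical taxonomy for
non-lipids comes from a packaged name → (superclass, subclass) lookup
covering the synthetic universe and extensible by the caller; no
network taxonomy service is used.

## Synthetic data generator

The generator emulates the study design: per sex, 25 (male) / 23
(female) controls, five treatment arms of 12 mice (valid range 11–14),
a Young arm of 12, six organs sampled from the same mice. Intensities
are log-normal:

    log10 I = baseline + subclass offset + β·pct + young shift + N(0, σ)

with σ = 0.5 log units by default — a deliberately generous spread for
metabolomics intensity data that makes the prescribed power conditions
(β = 0.02 per percent, n = 12) non-trivial. Trend effects are linear in
lifespan percent: the trend test consumes only monotonicity, and
linearity is the simplest monotone choice. The default trend
specification injects class-structured effects that reproduce the
study's qualitative findings (neutral lipids down in plasma/liver, up
in fat and kidney; male-biased PC and free-fatty-acid effects;
sphingolipids up in kidney; dipeptides down in muscle), with male
effects deliberately broader so the male > female significance
asymmetry is a testable generator property. When `young_mimic` is on,
the Young arm receives the same shift as the strongest intervention
(CR), emulating the observation that lifespan-extending treatments move
metabolomes toward a biologically younger state.

Missingness is completely at random (default 2%). The generator does
*not* emulate: limit-of-detection censoring, platform/batch effects,
compound-specific variance structure (σ is a free parameter, not an
estimate), inter-compound correlation, or raw spectra. Passing tests
therefore demonstrate correctness of the statistical machinery under a
clean log-normal world, not robustness to real-data artefacts such as
informative missingness or heteroscedasticity.

The ground-truth ledger lists every (compound, organ, sex) triple with
its injected β and direction, and is structurally invariant to the
seed. The default universe holds 582 compounds across 28 subclasses
(≈ 90 subclasses exist in the real annotation space; the synthetic
universe keeps one-third of that diversity at full class-size realism).

## Numerical choices and problem sizes

- Two-sided p-values are doubled smaller tails capped at 1, everywhere.
- Direction is the sign of median(treated) − median(control) (univariate)
  or of J − E[J] (trend); a zero median difference with non-central U
  falls back to the U-based rank-dominance sign.
- Degenerate inputs (constant pooled data) return p = 1, direction
  "none", rather than raising.
- Exact-mode feasibility guards: Mann-Whitney rank recurrence capped at
  m·n ≤ 40 000; enumeration (ties) capped at 2×10^6 assignments
  (Mann-Whitney) / 10^6 (JT).
- Deterministic outputs: stable sort orders, fixed column schemas,
  `%.6g` float formatting; re-running a configuration reproduces
  byte-identical files.
- Verification problem sizes: the exactness battery runs 500 random
  3–4-group designs of 2–4 observations against a brute-force
  enumeration oracle, with instance sampling restricted to null spaces
  of at most 20 000 assignments so the oracle itself stays exhaustive;
  calibration and power simulations use 20 seeds × 500 compounds in a
  single stratum at the design's group sizes.

## Known limitations

- The exact JT convolution assumes tie-free data; heavily tied data at
  sizes beyond the enumeration cap fall back to permutation/asymptotic.
- The Edgeworth term uses the tie-free fourth cumulant and is disabled
  when ties are present.
- Chain-length/unsaturation boundaries are configured only for TAG, DAG
  and PC; other classes raise an unsupported-class error by design.
- The amino-acid classifier is name-based; exotic nomenclature defaults
  to non-proteinogenic (logged) rather than erroring.
- Loaders for externally deposited per-compound result tables are
  written against the package's own TSV schemas; adapting a
  supplementary spreadsheet requires a column mapping.
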