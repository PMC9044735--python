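# Methods

## Linkage model

Two registries are linked on the exact key **K = (date of birth, pc4)**,
pc4 being the 4-digit Dutch postal-code prefix (neighbourhood of ~2,000
households on average). Matching is exact equality only — no phonetic or
string-distance matching and no probabilistic (Fellegi–Sunter) scoring —
because the workflow this package models used purely deterministic
linkage. The flow is:

1. restrict both registries to `sex = female`; male and unknown-sex
   records are removed and counted in separate audit buckets (the source
   procedure is silent on unknown sex; auditing rather than guessing keeps
   the cohort definition explicit);
2. exclude A-records whose key recurs within A (ambiguous identity);
3. look the key up in B: absent → unmatched; unique → included iff the
   B-record carries the qualifying diagnosis; non-unique → included iff
   exactly one candidate carries it, that candidate being the match.

Diagnosis predicates: registry A qualifies via any ICD-10 code with prefix
`C50` (subsites C50.0–C50.9 count — registries code topography with
subsites), registry B via the ICPC-1 code `X76` exactly. The code *years*
are deliberately unconstrained: requiring temporal agreement would
strengthen an already strong double-diagnosis requirement.

Non-unique B-groups in which zero candidates carry the diagnosis are not
included; they are audited separately from the ambiguous (≥ 2 carriers)
case but merged in the flow report, whose branch structure only
distinguishes resolved from unresolved.

A useful exact characterization (tested): deleting B-record *r* newly
includes A-record *a* iff *r* shares *a*'s key, *r* carries the diagnosis,
and the B-group held exactly two diagnosis carriers — the only pathway by
which removing data adds an inclusion.

## Pseudonymization

The pre-pseudonym is computed over K only, serialized canonically as
`"YYYY-MM-DD|PPPP"` (fixed delimiter, so distinct pairs cannot alias) and
keyed with HMAC-SHA256 under the sender secret; the TTP re-keys with its
own secret. Any keyed PRF would do; HMAC-SHA256 gives determinism,
collision resistance at registry scale and a standard-library
implementation. The 2-letter postal suffix is discarded *before*
pseudonymization because linkage is defined at pc4 granularity. Key
separation is enforced structurally: the TTP operation accepts pseudonym
strings only, and sender outputs carry no field from which K can be
rebuilt beyond (birth year, quarter, pc4). This simulates the data-flow
contracts, not production key management — there is no defence against a
malicious TTP and no key rotation.

## Flow accounting

The report validates the node identities (remaining = total − excluded;
matched = unique + non-unique; included = unique-with-dx + resolved; all
counts ≥ 0) and reports percentages with explicit numerator/denominator
labels, to one decimal; a zero denominator yields a flagged `None`, never
a propagated NaN. Both the total-cohort and stage-specific denominators
are available because published linkage flows quote percentages against
different bases at different nodes.

## Inclusion-bias assessment

Per characteristic, categories are cross-tabulated against inclusion
status and tested with the Pearson chi-square test of independence
(`scipy.stats.chi2_contingency`, no continuity correction,
df = (r−1)(c−1)) — the standard test for such registry tables. Missing
attribute values form an explicit `Unknown` category; zero-N categories
are flagged and dropped from the test. No multiple-testing adjustment is
applied across characteristics, mirroring how such tables are customarily
presented; treat the p-values descriptively.

The GP validation sampler ranks practices by linked-patient count and
draws practices with probability proportional to size from the top half of
the ranking ("relatively large" practices operationalized; the source
procedure gives no formal rule), adding whole practices until the target
(default 44 patients, a feasible audit size) is reached; if the top half
is exhausted first it extends to the remaining practices before declaring
a shortfall. Sheets carry only year/quarter of birth, registration date,
both diagnosis years and the last visit — never a date of birth or postal
code.

## Synthetic registries

`SimulationConfig` defaults define the emulated study conditions:

| parameter | default | meaning |
|---|---|---|
| `mean_households_per_neighbourhood` | 2000 | pc4 neighbourhood size |
| `women_per_household` | 1.0 | household → adult-woman conversion (Poisson) |
| `n_neighbourhoods` | 50 | → population ≈ 100,000 women |
| `coverage_fraction` | 0.10 | share of GP practices contributing to B |
| `practices_per_neighbourhood` | 2 | ≈ 1,000 women per practice |
| `gp_recording_sensitivity` | 0.80 | P(X76 recorded \| true case in B) |
| `move_probability` | 0.05 / yr | whole-neighbourhood residential moves |
| `observation_window` | 2000–2016 | diagnosis years; B snapshot at 2016 |
| `incidence_schedule` | 0.05–0.35 %/yr | hazard rising with age band |

Choices made where the design was open: registry B's address is captured
at the window-end snapshot, so diagnosis-to-snapshot lag × mobility drives
mover-induced linkage misses (women who moved after diagnosis carry
different pc4s in A and B and cannot match — and surface as potential
control contamination); each woman keeps the practice of her initial
neighbourhood (coverage is a practice property, so later moves do not
silently change B membership); stage/surgery/therapy attributes are drawn
independently of linkage success so inclusion-bias tests have a clean
null; incidence hazards are round values rising with age band, not a
calibrated national schedule. The generator does not model male patients,
GP false-positive X76 codes, opt-outs, duplicate registrations or
non-random practice participation — passing tests demonstrate internal
consistency of the pipeline under these mechanisms, not fidelity to any
real registry.

The **exact-flow fixture** is the complement of the stochastic generator:
given branch counts it deterministically constructs registries that drive
the engine to those counts exactly, validating the flow identities first
and refusing inconsistent requests naming the violated identity. Keys are
laid out by a bijective scrambling of an ~80-year × 9,000-pc4 grid
(odd multiplier modulo the grid size), so a ~215k-record national-scale
instance builds in seconds with no accidental collisions. Unresolvable
non-unique groups alternate between the two-carrier and zero-carrier
sub-cases. `EXAMPLE_FLOW_BRANCHES` holds a realistic national-scale
parameterization; note its final inclusion count is *derived* as
unique-with-dx + resolved — the fixture never takes a total as input.

## Analytics

Collision rate: per-record probability `1 − (1 − 1/C)^(N−1)` under
uniform occupancy; the non-uniform form averages `1 − (1 − q_j)^(N−1)`
over a cell-probability vector. Documented assumption: record keys are
exchangeable across cells.

Performance is pair-level: a reported pair is correct iff both records
belong to the same person; the sensitivity denominator counts persons
truly present in both registries *with equal keys* (a mover is not
linkable by this design, so she burdens neither sensitivity nor PPV but
appears in the contamination analytics instead).

Dilution: with control exposure prevalence p₀ and true odds ratio OR, the
case prevalence is p₁ = OR·p₀ / (1 − p₀ + OR·p₀); contaminating a
fraction f of controls with case-distributed exposure gives
p₀' = (1−f)p₀ + f·p₁ and the observed odds ratio
[p₁/(1−p₁)] / [p₀'/(1−p₀')], monotone in f and exactly 1 under the null.
The mixture is deliberately simple — contaminated controls inherit the
full case exposure distribution; no bias-corrected estimator is provided.

## Numerical and testing choices

All randomness flows through `numpy.random.default_rng` seeds; generation
is byte-reproducible per seed. Monte-Carlo checks compare estimates to
closed forms within 3 empirical standard errors. Simulation-based tests
use 50 replicates of the ~100,000-woman default population for parameter
recovery and smaller configured populations (3,000–40,000) where a test
targets a single mechanism; the brute-force linkage oracle guards itself
above 10⁶ record pairs. Parameter-recovery calibration conditions on
ground truth (fraction of the cancer cohort truly present in B; X76
recording among true cases in B) because at neighbourhood scale the naive
matched-fraction estimator includes chance key-occupancy (~N_B/C of the
unlinkable cohort) and the included/unique-matched ratio is correspondingly
deflated by false key-matches; the ground-truth-conditioned estimators are
exact binomial draws of the configured parameters, which is what a
calibration check should measure. The same chance-occupancy closed form is
exposed in `analytics` for users who want to correct linkage-derived
estimates.

## Known limitations

Exact-equality linkage cannot recover from any key error (typos, postal
reorganizations); the double-diagnosis requirement biases the linked
cohort against patients with poor GP recording; the chi-square tests are
descriptive, unadjusted for multiplicity; the dilution model ignores
matching and stratification used in real case-control designs; and the
synthetic generator's realism limits are listed above.
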