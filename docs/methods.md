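# Methods

This note records the models, conventions and numerical choices behind
`sumstatfix`, and what the synthetic test bed does and does not establish
about behaviour on real data.

## The data model

A summary-statistics file is reduced to nine per-variant fields: chromosome
token, 1-based base-pair position, rsID, effect allele (EA), other allele
(OA), effect-allele frequency (EAF), effect size β, its standard error s,
and the two-tailed p-value. Internally every value is kept as its raw
string token; numbers are parsed on demand. This is deliberate: the
package's central promise is minimal mutation — an entry that was valid on
input is byte-identical on output — and keeping tokens rather than parsed
floats makes that promise checkable. Missing entries are `None` in memory
and `.` on disk.

Row order and row count are invariant through every stage. Restoration
failure is expressed by leaving the entry flagged, never by dropping the
row; a downstream consumer can then decide what to do with the residue.
This contrasts with standardization-first tools, which typically delete
rows that fail QC — including rows whose only defect was repairable.

## Validation

Each field has a pure token predicate: chromosome ∈ {1…23, X, Y, M}
(case-insensitive, leading zeros ignored), BP a non-negative integer
literal, rsID `rs`+digits (dbSNP convention; a bare `r` prefix is rejected),
alleles `-` or non-empty over {A, C, G, T}, EAF/p finite reals in [0, 1]
(inclusive), β/s finite reals. Validators are free of cross-field coupling;
the whole-file report simply aggregates them, so validation is idempotent.
Chromosome `23` is accepted as written and treated as equivalent to `X`
only inside lookups and concordance scoring — output tokens are never
rewritten silently.

The correctness report also computes the fraction of genome-wide
significant rows (valid p < 5×10⁻⁸, the conventional threshold) carrying
any invalid field, since damage among top hits is what hurts downstream
polygenic-score work most. The fraction is flagged undefined when no row is
genome-wide significant.

## Restoration

**Routes.** With a reference-variant index available: (a) invalid Chr or BP
→ look up the rsID and overwrite *both* coordinates (a half-trusted pair is
worthless — this is the single sanctioned mutation of a valid field);
(b) invalid rsID → look up (Chr, BP), disambiguating multi-record sites by
matching the row's valid alleles, else taking the lowest rsID number (and
logging); (c) exactly one invalid allele → the partner of the known allele
with the highest annotated frequency, ties preferring the reference allele
then alphabetical order; (d) invalid EAF → the reference database's
frequency of the effect allele. Restored EAFs are a proxy: reference-panel
frequencies are population-weighted averages and will seldom equal the
study cohort's EAF on real data. Without an index, only the statistical
route runs.

**The statistical triple.** For a Wald test, z = |β|/s and p = 2(1 − Φ(z)).
Any one member is recovered from the other two: s ← |β|/z, β ← |s|·z,
p ← 2Φ̄(|β|/s), with z = Φ⁻¹(1 − p/2) evaluated as `norm.isf(p/2)` in double
precision. A restored β is always non-negative: a two-tailed p-value is
sign-free, so the sign is genuinely unrecoverable and the CLI warns when β
was restored. Degenerate inputs are flagged unrestorable rather than
propagated: p = 1 (z = 0) and p = 0 (z = ∞) for s; p = 0 for β; s = 0 for
p; and p < 1e-300 as an inverse-CDF overflow guard.

**The loop.** Each pass revalidates, plans, and applies the routes; the
first pass additionally performs liftover when the input and target builds
differ (an error is raised before any mutation if the chain file is
absent). The pipeline models the original streaming design in which the
file is sorted by one key per pass: when both lookup directions are needed,
the pass sorts by the key with fewer invalid entries and defers the other
direction to the next pass. Allele/EAF lookups prefer the pass's sort key
but fall back to the other key when a row's sort-key fields are invalid —
an in-memory implementation has no reason to leave a restorable row
waiting. The loop stops when a pass restores nothing or no route applies;
since routes only turn invalid entries valid, the total invalid count is
non-increasing and termination is bounded by (number of fields + 1) passes.
Lookups run in logarithmic time over two sorted orders (by chromosome+
position and by numeric rsID) built once from the VCF and materialized as
BGZF-compressed TSVs with a JSON sidecar.

**Liftover.** UCSC chain files are expanded into ungapped blocks; chain
coordinates are 0-based half-open while summary-statistics BP is 1-based,
and the conversion happens exactly once at the module boundary. When
multiple chains cover a position the highest score wins. Negative-strand
destination blocks are reflected onto the forward strand; allele strand
flipping is *not* attempted (out of scope, logged). Rows whose position
falls in an inter-block gap have Chr/BP cleared and flagged — keeping the
stale source-build coordinate would silently mix builds — which leaves them
eligible for rsID-based coordinate restoration in a later pass.

## Evaluation

Test files are made by blanking one column at a time, mirroring how
incomplete files arise in practice. Qualitative columns (chr, bp, rsid,
ea, oa) are scored by normalized concordance; quantitative columns by
1 − min(k·|x₀ − xᵣ|, 1) with fixed band factors k = 2 (EAF), 6 (β), 4 (s),
3 (p), which score rounding-level discrepancies near 1 and gross errors 0.
Entries the restoration left missing score 0; rows where the original
itself has no value are excluded from the denominator. rsID concordance is
reported but explicitly labelled non-comparable across dbSNP versions.

The noise threshold estimates by Monte Carlo the score of a random guess:
uniform on [0, 1] for EAF/p, empirical resampling of the observed column
for β/s, uniform over the observed token set for qualitative columns. For
the uniform case with k = 2 the analytic expectation is
E[1 − min(2|x₀ − xᵣ|, 1)] = 5/12 ≈ 0.4167 (verified by numeric
integration), which the estimator converges to in tests.

## The synthetic test bed

The generator emulates a single-cohort quantitative-trait GWAS at desk
scale: biallelic SNPs with unique positions on chromosomes {1, 2, X},
alternate-allele frequencies uniform on [0.05, 0.5], β ~ N(0, 0.05²), and
the standard large-sample approximation s = 1/√(2N·f(1−f)) at N = 10,000 —
so every (β, s, p) triple is consistent by construction and z-scores span
roughly [0, 12]. Effect sizes, sample size and MAF range were chosen once
as typical of a mid-size GWAS; what matters for the tests is internal
consistency, not the trait. The summary-statistics file deliberately uses
non-standard column names and `chr`-prefixed chromosomes to exercise the
config-driven reader. Corruption draws from an invalid-token palette
modelled on failure modes seen in shared files (`NA`, non-numeric BP,
structural-variant IDs like `esv…`, out-of-range frequencies).

The fixture world is *closed*: every summary-statistics variant exists in
the fixture VCF, sites are unique, and frequencies are single-source. This
makes lookup restoration exactly recoverable, which is what lets the test
suite assert 100% concordance and ~1e-15 relative errors. Real data is not
closed: rsIDs get merged and renamed between dbSNP versions, multiple
records share positions, reference frequencies differ from cohort EAFs,
and newer databases carry more alternate alleles (hurting exact
effect-allele matches). Passing the closed-world suite therefore
establishes the *mechanics* — zero loss, correct lookups, correct algebra,
termination — not field accuracy on arbitrary real cohorts.

Chain fixtures shift each chromosome by a constant offset and carve one
deliberate 1 kb unmappable gap per chromosome; the inverse chain shifts its
covered interval and gap by the forward offset so the two compose to the
identity on every forward-mappable position. Fixture positions are sampled
away from the gap (with margin), so gap behaviour is exercised only by
tests that place positions there on purpose.

All generators are deterministic functions of (spec, seed), using
independent numbered child streams of one seed so that adding a generator
never perturbs another's draws.

## Problem sizes and numerical tolerances

The default verification runs use 300-variant fixtures for unit/property
tests and a 1,000-variant fixture (seed 7) for the end-to-end masking runs,
10,000 random pairs for the triple oracle, and 100 random corruption
patterns for loop-termination fuzzing — sizes at which every property that
should hold exactly can be checked exhaustively in seconds. Tolerances:
triple back-calculation is asserted to 1e-6 relative error for z ∈ [1e-3, 8]
(observed ~1e-14); restored EAF to 1e-9 absolute (observed at float
round-off); the triple-consistency residual accepted on input is
|Δz| ≤ 1e-3·max(1, z). Floats written by the pipeline use the shortest
17-significant-digit form, which round-trips IEEE doubles exactly.

## Known limitations

- No reference-genome sanity checks (EA/OA vs. the reference base), no
  strand-flip detection or repair.
- Indels are kept verbatim; a `-` allele in summary statistics is not
  matched against VCF-style anchored indel alleles.
- Restored β is unsigned; downstream use should treat it as |β| unless the
  sign can be recovered from another source.
- EAF restoration inherits the reference panel's population mix.
- The dbSNP index is held in memory; at desk scale (≤ ~10⁶ records) this is
  the simple and fast choice, but a full dbSNP build would need the
  streaming binary search the on-disk format was designed to allow.
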