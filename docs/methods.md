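# Methods

## The construction

`jemkit` estimates occupation-level psychosocial exposures and the Karasek
Demand–Control job strain classification from individual ordinal survey
responses, in four stages.

**Alignment.** Each item carries an `adverse_high` orientation. Responses
on protectively-oriented items (e.g. frequency of deciding one's own work
pace, where *high* frequency means *more* control) are reflected,
`scale_min + scale_max − value`, so that after alignment a larger value
always means more adverse exposure. Reflection is an involution and maps
the scale onto itself, so medians and cut-offs stay on the admissible
scale. Orientations for the packaged items are documented assumptions
(source questionnaires do not publish per-item codings); they live in the
YAML config, where control items must state the orientation explicitly
while demand items default to `adverse_high: true`.

**Individual median split.** Per item, the cut-off is the median of all
aligned non-missing responses, pooled over every survey wave and both
genders — one national cut-off per item, the convention for a fixed
exposure reference. (A `per_wave` option computes wave-specific cut-offs
for sensitivity analyses; it defaults off.) A respondent is *exposed* on an
item iff the aligned value is **strictly greater** than the cut-off, so
respondents at the median are non-exposed; with cut-off 2 on a 1–5 scale,
exposed responses are exactly {3, 4, 5}. The median of an even count is the
midpoint of the two central order statistics, possibly a half-integer such
as 2.5; under the strict-greater rule this is equivalent to "above the
lower central value" on integer scales and keeps the rule total.

**Cell shares.** Exposure flags aggregate within (JEM group × gender)
cells: `share = 100 · exposed / (exposed + non-exposed)` over non-missing
flags, kept at full precision in memory and rounded (default 1 decimal)
only on export. The boundary semantics are exact: share 0 ⇔ no non-missing
respondent in the cell is exposed, share 100 ⇔ all are. Cells with fewer
than `n_min` non-missing respondents (default 10) are suppressed to
*missing*, never to zero — conflating "no data" with "0 % exposed" would
break those semantics. Gender stratification defaults on because the index
is designed to merge on occupation code *and* gender. Rows whose
occupation code the group map does not cover are excluded and enumerated in
the build log, never dropped silently.

**Occupation split and strain.** Detailed occupation codes inherit their
JEM group's shares verbatim (codes sharing a group are identical by
construction). Per item, the occupation-level cut-off is the *unweighted
median of shares across (group × gender) cells* — the level at which shares
are defined — and an occupation is exposed iff its share is strictly above
it. A `median_over="codes"` switch instead takes the median over expanded
per-code rows, which weights groups by how many codes they contain; cell
level is the default because code multiplicity is a property of the coding
system, not of the exposure distribution. `demand_index` counts exposed
demand items and `control_index` counts exposed control items, with control
coded as *adversity* (exposed = low control) so that "strictly greater than
the median" reads identically on both dimensions. Each count is split at
its median across occupation rows (complete rows only); (high demand, low
control) gives *high_strain*, (high, not) *active*, (not, low) *passive*,
(not, not) *low_strain*, and `job_strain = high_demand AND low_control`.
The binary flag is the primary index; the quadrants and the two raw counts
are retained in the export because different register analyses want
different forms. Any missing constituent flag makes the row's indices and
quadrant missing.

**Ties and degenerate inputs.** Strict inequalities everywhere, ties fall
to the benign side: a single cell (or all-equal shares) yields no exposed
occupation; an all-constant item yields no exposed respondent; an item with
zero non-missing responses, an empty flag table, or a group map covering no
observed code raise errors rather than returning empty estimates.

## Linkage

Occupation-code conversion between classification revisions uses an
explicit key of (source, target) 4-digit pairs. Sources with several
targets are genuinely ambiguous; the default policy is **strict** (error)
because unofficial keys can introduce inconsistencies that should never be
resolved silently. `first_match` resolves deterministically to the
lexicographically first target with a warning per source; `expand_rows`
emits one row per candidate with a provenance column. Codes absent from
the key pass through unchanged and are counted.

The register merge is a left join on exact (4-digit occupation code,
gender): the register row count is preserved under all circumstances,
unmatched rows keep missing exposures and a `jem_matched = False` flag, and
the merge report partitions every input row into matched / unmatched-code /
unmatched-gender-cell, so the totals always balance. Gender codings are
normalized to a two-level enum at load time; unmappable values are an
error, not a third stratum. Hierarchical fallback to 3-digit prefixes is a
deliberate non-goal — the index is defined at exact 4-digit level.
Occupation codes are fixed-width 4-character strings throughout (leading
zeros are significant).

## Synthetic data: what it emulates and what it does not

The generator emulates the structure of a five-wave national working
conditions survey: 333 occupation codes in 268 JEM groups by default,
waves 2006–2019, balanced genders, and 16 respondents per
(group × gender × wave) cell, giving ≈ 43 000 respondents — the scale of
the surveys such indices are built from. Responses are drawn *two-sided
around the intended cut-off*: with planted probability *p* the aligned
value is uniform over the values strictly above the cut-off, otherwise
uniform over the values at or below it. The exceedance probability per
cell is therefore exactly *p* by construction, which is what downstream
share-recovery tests need; only the dichotomized variable matters to the
pipeline, so the within-side distribution is free. Default cell
probabilities are drawn U(0.10, 0.45); keeping them below one half pins
the pooled median at the intended cut-off (2 on the default 1–5 scale).
Item nonresponse is injected completely at random (default 5 %), so
complete-case estimates are unbiased in tests.

Not emulated: sampling weights and population calibration, panel overlap
between waves, interview mode effects, within-cell correlation between
items, informative (non-MCAR) missingness, and reporting bias correlated
with health. Passing tests therefore demonstrate the *arithmetic* of the
construction — medians, strict splits, share aggregation, quadrant
classification, linkage accounting — not robustness to those real-data
features.

## Verification

Every stage is cross-checked against an independent brute-force
re-computation (pure-Python sorting and counting, no shared code with the
vectorized path): individual cut-offs, cell shares, occupation cut-offs and
flags, indices and quadrants agree exactly on 200 random fixtures of up to
50 cells. Share recovery on planted-truth cells of 500 respondents lands
within three binomial standard errors for ≥ 99 % of cells. Invariants
under test include permutation invariance of all aggregations, the pooling
identity (sub-table counts add, shares recombine as weighted means),
monotonicity of flags and indices in any single share, the quadrant
partition of complete rows, row conservation of the register merge, and
byte-identical regeneration of synthetic tables from the same seed.
Problem sizes in the default suite (tens of groups, hundreds to tens of
thousands of respondents) were chosen to exercise every code path while
keeping the whole suite fast; they are not statistical claims about larger
surveys.

## Known limitations

- Cut-off conventions (pooled vs. per-wave medians, minimum cell sizes)
  vary between published national matrices; both are options here, with
  the defaults documented above.
- The exact merging rule used by any particular deposited strain index
  (binary flag vs. quadrants vs. demand/control ratio) varies; all three
  representations are exported, with the binary flag designated primary.
- The occupation-level split depends on the composition of cells present
  in the matrix: adding or removing occupations moves the median-of-shares
  cut-offs and can reclassify other occupations. A fixed reference matrix
  should therefore be versioned (the group-map digest and build options are
  recorded in the matrix metadata).
- No survey weighting: shares are unweighted respondent proportions.
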