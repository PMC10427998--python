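# Methods

## The index

For one sampling station (one column of the count table), let `R_I` and
`R_III` be the read totals of the taxa assigned to ecological groups EGI
(sensitive/indifferent) and EGIII (tolerant/opportunistic).  With the group
percentages `%EGI = 100·R_I/(R_I+R_III)` and `%EGIII = 100·R_III/(R_I+R_III)`
the index is the weighted mean

```
microgAMBI = (w_I · %EGI + w_III · %EGIII) / 100
```

with default weights `w_I = 0` and `w_III = 6`, the AMBI-family convention
that keeps microbial scores on the same 0–6 scale as the macroinvertebrate
index they descend from.  Because the two percentages sum to 100, the index
is affine in `%EGIII` with slope `(w_III − w_I)/100`; it equals `w_I` when
every assigned read is sensitive and `w_III` when every assigned read is
tolerant.

Status classes are right-closed intervals over boundaries
`b = (1.2, 3.3, 4.3, 5.5)`: `[w_I, b1]` high, `(b1, b2]` good, `(b2, b3]`
moderate, `(b3, b4]` poor, `(b4, w_III]` bad.  Right closure means a value
sitting exactly on a boundary takes the *better* class; the source material
does not resolve tie cases, so the convention is fixed here, documented, and
covered by boundary tests.  Classification is total and monotone over
`[w_I, w_III]`; values outside that interval are an error, not a clamp.

### Denominator policy

Reads whose taxa are *not assigned* (in the list, unknown function) or *not
in the list* at all do not enter the index under the default
`assigned_only` policy: the fractions are renormalized over `R_I + R_III`,
following the relative-abundance-ratio formulation of the AMBI lineage.  An
`all_reads` policy (divide by the station total, letting unmatched reads
dilute both fractions) is retained as an option because the template's
exact spreadsheet formula is not printed in the running text; both
percentages are reported either way, so the choice is always visible in the
output.  When `R_I + R_III = 0` the index is *undefined*: the station is
typed `unclassifiable` with a reason flag rather than producing NaN
arithmetic.

### Companion statistics

Richness (cells with reads > 0) and Shannon–Wiener `H′ = −Σ p_i log₂ p_i`
(bits) are computed over **all** taxa with reads in the column, including
unmatched ones, because the template computes them on the pasted data before
any reference matching.  `H′` is undefined (an error, not 0) for an all-zero
column.  A coverage flag `LOW_REFERENCE_COVERAGE` is raised when the
combined not-assigned + not-in-list percentage exceeds
`unmatched_warn_threshold` (default 20 %) — surveys in that regime should
treat the status with caution and seek updated group assignments.

## Taxon matching

Reference entries and queries are compared on a normalized key: whitespace
and underscores collapse to single spaces, trailing `sp.`/`sp`/`spp.`
tokens are removed (genera are curated without them; classifier outputs
often append them), and comparison case-folds while display preserves the
original casing.  Normalization is idempotent.  Duplicate normalized names
in a reference are a warning when both rows agree on the group (first
record wins) and an error when they conflict, since the index would then be
ambiguous.  An optional genus fallback retries an unmatched binomial as its
first token; it is off by default because a genus-level assignment is a
weaker claim than a species-level one.  Accession and evidence columns
(NCBI, WoRMS, DOIs, literature, comments) are carried verbatim and never
resolved over the network.

## Configuration

| parameter | default | meaning |
|---|---|---|
| `weight_egi`, `weight_egiii` | 0, 6 | group coefficients (index endpoints) |
| `class_boundaries` | 1.2, 3.3, 4.3, 5.5 | status-class cut points, strictly increasing, inside `(w_I, w_III)` |
| `denominator_policy` | `assigned_only` | fraction denominator (see above) |
| `unmatched_warn_threshold` | 20 (%) | coverage-flag trigger |

All four are configurable from the CLI or a flat `key = value` file and are
embedded in every report header, so a report is interpretable without the
invocation that produced it.

## Synthetic data

The generator emulates a metabarcoding survey as the smallest model
consistent with read-count data: per station, a single multinomial draw of
`total_reads_per_station` reads (default 10,000, a typical post-filtering
16S library) over all taxa.  Expected shares give not-assigned and
not-in-list taxa fixed small fractions (defaults 2 % and 3 %, a well-covered
survey) and split the remaining assigned share between EGIII and EGI as
`π : 1−π`, where `π` is the station's tolerant-read fraction — the ground
truth.  Within each group, reads spread uniformly, or with
symmetric-Dirichlet weights (concentration `1/dispersion`) when
`dispersion > 0`; `dispersion = 0` reproduces the exact multinomial
expectation, so `π ∈ {0, 1}` yields the index endpoints exactly.  The
default miniature list has 40 + 40 + 5 curated taxa plus 5 unlisted ones —
large enough that no single taxon dominates, small enough to keep every test
fast.  Generation is bit-for-bit reproducible from `seed`.

Under this model `E[index] ≈ w_I + (w_III − w_I)·π` (exact up to the
`O(1/n)` bias of the ratio of multinomial counts, negligible at 10⁴ reads),
which is the oracle for the parameter-recovery checks: over 200 replicates
the mean index must fall within three standard errors of the expectation at
`π ∈ {0, 0.25, 0.5, 0.75, 1}`.

What passing these checks shows — and does not.  The generator exercises the
arithmetic, matching, and bookkeeping of the pipeline, including the
`sp.`-suffix normalization path (genus-level taxa appear in the table with a
trailing ` sp.`).  It does not mimic real 16S compositional structure: no
phylogenetic correlation between taxa, no calibrated zero inflation, no
compositional bias between stations.  Agreement on synthetic data therefore
validates the implementation, not the ecological performance of the index on
any particular survey.

## Numerical choices

* Percentages, fractions and H′ are carried at full double precision;
  rounding (2 decimals for the index) happens only in the report's display
  column.
* Boundary classification uses `bisect_left` on the boundary vector, which
  realizes the right-closed convention without epsilon juggling; the
  validity check on the index range uses a 1e-9 tolerance to absorb
  floating-point drift from upstream divisions.
* Count tables must contain integers; blank cells read as 0 (spreadsheet
  convention), fractional or negative cells are rejected with the offending
  taxon and station named.
* Duplicate taxon rows in a count table are merged by summation (classifier
  outputs commonly split one taxon across `sp.` variants); merging never
  changes the station totals, which is property-tested.

## Known limitations

* The reference list is taken as given; no automated group assignment from
  literature, and no live NCBI/WoRMS resolution (accessions are provenance).
* Table orientation is declared (`--transpose`), not auto-detected.
* No uncertainty on the status call (confidence intervals, bootstrap over
  reads) and no multi-index intercalibration.
* In transposed input, duplicate taxon *columns* are renamed by the
  underlying table reader rather than merged; the standard orientation
  handles duplicates properly.
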