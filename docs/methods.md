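# Methods

`tcrisk` screens candidate tumor-specific TCRs for cross-reactivity and
fratricide risk from three inputs: an amino-acid exchange-scan ELISpot
table, a protein sequence database, and a per-allele MHC class I binding
matrix. This note records the model, the parameters that matter, the
numerical conventions, and what the synthetic benchmarks do and do not
show.

## Recognition calling from exchange scans

An exchange scan replaces each epitope position in turn with alanine (or
serine/threonine where the original residue is already alanine) and reads
T-cell recognition of each variant as replicate ELISpot spot counts,
alongside the unsubstituted peptide and an unpulsed or irrelevant-peptide
background. Replicates are summarized by the arithmetic mean (the assay is
typically run in triplicate; any replicate count ≥ 1 is accepted). The
per-variant relative activity is

    r = max(0, mean(variant) − mean(background)) / (mean(original) − mean(background)),

clamped at zero because a variant cannot meaningfully respond below
background. The normalization makes `r` invariant under rescaling all
counts by a common factor, so plates with different overall spot densities
are comparable. If the original peptide does not respond above background
the assay carries no information and the analysis refuses to proceed rather
than emit an arbitrary motif.

Calling is a two-threshold trichotomy on `r`:

| call       | band               | motif consequence                         |
|------------|--------------------|-------------------------------------------|
| abolished  | r < `low` (0.25)   | position fixed to the original residue     |
| partial    | low ≤ r < `high` (0.75) | bracket class `[original, substituted]` |
| unaffected | r ≥ `high`         | wildcard `X`                               |

The underlying experimental literature states only the two extreme rules —
a substitution that kills recognition marks a crucial position, one without
effect marks a wildcard — yet published motifs also contain two-residue
bracket classes (`[LA]`, `[ST]`, `[VT]`). The partial band is therefore
this package's operational definition of how such classes arise: it is the
only deterministic rule on `r` that can produce all three motif position
types. The defaults 0.25/0.75 reproduce the three-level structure and sit
far from the synthetic effect sizes (below); both are configurable
(`--low`, `--high`). In `strict` mode partial positions degrade to
wildcards, giving the widest (most conservative for off-target search)
pattern without bracket classes.

Positions with no tested variant remain fixed to the original residue and
are flagged in the derivation metadata — an untested position is *not*
evidence of tolerance, and fixing it avoids silently widening the motif.
Multiple substitutions at one position must agree in category (partial
calls pool their substituted residues into one bracket class); category
disagreement raises an ambiguity error instead of guessing.

Titration curves are summarized by the lowest tested concentration whose
background-subtracted response is still at least a fraction `low` of the
top-concentration response; with the usual half-log dilution series this
reproduces the "recognition persists down to 0.01 μM" style of readout.
If no concentration qualifies the threshold is reported as absent.

## Motif dialect and proteome scanning

Patterns use a restricted PROSITE dialect: hyphen-separated `X` (any
residue), single residue letters, `[..]` inclusion and `{..}` exclusion
classes. Repetition counts (`x(2,4)`) and terminal anchors (`<`, `>`) are
not part of the dialect because exchange-scan motifs are fixed-length by
construction. Parsing is case-insensitive with a tolerated trailing period;
rendering emits the canonical uppercase hyphenated form and preserves the
written residue order inside brackets (derived motifs put the original
residue first, e.g. `[LA]`).

Scanning enumerates every window of pattern length in every database
record; overlapping matches are all reported, ordered by (record, offset),
with 0-based half-open coordinates internally and 1-based inclusive
coordinates in human-readable output. The *burden* is the number of
distinct matching peptide strings, not the number of occurrences — two
copies of the same nonamer present the same pMHC surface. Windows
containing non-standard residues (B, J, O, U, X, Z, `*`) cannot match under
the default `skip` policy (they are also excluded from the scanned-window
tally); `wildcard-fail` counts them as scanned but unmatchable, and
`error` aborts. Published motif-carrier counts from online scans are not
reproducible without the exact database release, so the database is always
an explicit input here.

For an i.i.d. background the per-window match probability is the product
of per-position class probabilities; for `X-L-X-X-X-X-F-X-[LA]` on a
uniform alphabet this is (1/20)·(1/20)·(2/20) = 2.5×10⁻⁴, which the
scanner reproduces empirically (see benchmarks).

## Additive binding scores

Binding strength to the restricting HLA allele uses the classic additive
PSSM convention: integer score per (position, residue), peptide score =
sum over positions, no cooperativity between positions. Pairs absent from
a sparse matrix contribute `default_score` (0), matching the sparse
presentation of published matrices; real-valued matrices are accepted
behind a flag but flagged as non-canonical. No affinity (nM) or
percentile-rank conversion is attempted — the raw additive score is the
published comparison unit, and the risk index normalizes it by the
matrix's maximum achievable score so that weights are comparable across
alleles. Published per-allele matrices are external data and are not
bundled; all tests use toy matrices with known structure.

## Risk comparison and ranking

Each TCR's profile holds the burden (pre-filter) and the score list of its
unique matching peptides (post `min_score` filter, when given) — two
deliberately distinct numbers, since a binding-score filter shrinks the
scored set but not the motif's promiscuity. Pairs of profiles are compared
by burden ratio (larger/smaller) and a two-sided two-sample test on the
score lists. The default is the rank-based Mann–Whitney test — motif-scan
score distributions are discrete, bounded and usually skewed, so a rank
test is the safer default — with the unpaired two-tailed Student t-test
selectable for parity with common practice. Profiles with fewer than two
scores skip the distribution test with an explicit `insufficient_n` flag
rather than reporting a meaningless p-value. No multiple-testing
correction is applied by default (screens typically compare one pair); a
Bonferroni option covers multi-TCR screens.

The composite ranking index is

    risk = w_b · log10(burden + 1) + w_s · median(score) / max_score,

defaults w_b = w_s = 1. The log compresses the orders-of-magnitude spread
of burdens (tens to thousands); the score term is a dimensionless fraction
of the best possible binder. The index is a screening heuristic of this
package — the experimental evidence links burden and binding strength to
fratricide *correlatively*, across few TCRs — so it is deliberately
uncalibrated: no "high-risk" threshold is defined, raw components are
always embedded in the report, and ties break by burden then name.
Degenerate profiles (no scores) drop the score term and rank on burden
alone, so an empty profile ranks last.

## Synthetic data: what it emulates

The generators are pure functions of their spec (seed included) built on a
single `numpy.random.default_rng` per call.

- **Proteomes**: background residues i.i.d. from a configurable frequency
  table; planted peptides overwrite background residues at non-overlapping,
  uniformly chosen locations recorded in a manifest. Overwriting (rather
  than splicing) keeps protein lengths, window counts and the analytic
  background match rate exact. Real proteomes have residue-frequency
  structure, repeats and homologous families that inflate motif clustering;
  passing the synthetic benchmarks therefore validates the *machinery*
  (exactness of matching, counting and recall), not the biological
  representativeness of any particular burden number.
- **Exchange-scan tables**: per-variant mean = background + effect ×
  (original − background), with effect 0.05 / 0.5 / 0.95 for abolished /
  partial / unaffected. These sit well clear of the 0.25/0.75 call
  thresholds, emulating a clean assay; replicate counts are drawn Poisson
  (default), negative-binomial (dispersion parameter `r`, for overdispersed
  plates), or exact (rounded means — the noise-free limit in which the full
  pipeline inverts to planted truth exactly). Defaults: original mean 100
  spots, background 5, triplicates, 0.01 μM pulse — the scale of a typical
  nonamer ELISpot screen. At these settings Poisson noise gives a replicate-
  mean coefficient of variation of about 0.06 on the unaffected band, and
  motif recovery exceeds 95% over 200 seeds; the negative-binomial model at
  its default dispersion (r = 10) is substantially noisier and is provided
  for robustness exploration, not for the recovery guarantee.
- **Toy PSSMs**: uniform random integer baseline (0–3) plus a bonus (+5
  default) on the favored peptide's own cells, making the favored peptide
  the maximum over same-composition permutations by construction.

## Numerical and interface conventions

- Replicate summaries use exact float means; relative activities are
  clamped to [0, ∞) and compared to thresholds with plain `<`/`≥` (the
  bands are half-open: `r = low` is partial, `r = high` is unaffected).
- Score-set ordering is descending score with lexicographic peptide
  tie-break, so outputs are reproducible across runs and platforms.
- Matrix addition is entrywise with `default_score`s adding, preserving
  additivity of peptide scores.
- Reports serialize to JSON losslessly (infinite burden ratios map to
  `null`) and embed tool version plus the full parameter set.
- CLI exit codes: 0 success, 3 validation error, 4 configuration error,
  5 I/O error; logs go to stderr, results to stdout.

## Benchmark problem sizes

The shipped benchmarks use: 1000 randomized (pattern, database) cases for
scanner/oracle agreement; a 100 × 10 008-residue uniform proteome (10⁶
windows) for the background-rate check against the binomial 99% interval;
200 seeded Poisson assays for motif recovery; 1000 randomized matrices for
scorer/oracle agreement; and 50 end-to-end runs of a two-TCR scenario with
a planted 100:1 unique-match asymmetry (about 110 motif carriers in a
40-protein database) for ranking discrimination, plus 200 draws of
N(24, 3²) n=200 vs N(18, 3²) n=30 score sets for the distribution test's
power. In the planted-recall benchmark, carrier peptides draw their free
positions from an alphabet without the motif's anchor residues (L, F, A)
so that no shifted or straddling window can create an unplanted
occurrence — the unique-peptide count is then an exact ground-truth
equality rather than a probabilistic one.

## Known limitations

- The partial-band bracket rule is an operational reconstruction; the
  exact experimental criterion that produced published bracket classes is
  not stated in the experimental record.
- Burdens depend entirely on the database given; no database is bundled.
- The additive PSSM ignores position coupling and is not an affinity
  predictor; modern neural predictors are out of scope by design.
- The risk index is ordinal, not calibrated to fratricide probability.
- Motif matching is exact; near-miss (mismatch-tolerant) cross-reactivity
  search is out of scope.
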