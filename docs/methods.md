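# Methods

This note records the model behind each pipeline stage, the parameters
that matter, the design choices made where more than one reasonable
convention exists, and what the synthetic fixtures do and do not
demonstrate.

## Geometry

All coordinates are normalized page fractions with a top-left origin, the
convention of layout-aware OCR engines. Overlap between a line and a
detected table region is defined as

    overlap(line, region) = area(line ∩ region) / area(line)

i.e. normalized by the **line's own** area. This puts the value in [0, 1]
("what fraction of this line sits inside the region") and makes the
excision threshold interpretable independently of region size. Lines with
zero-area boxes cannot be scored; they are kept and logged rather than
silently removed. Full containment is snapped to exactly 1.0 within 1e-9
to absorb float noise from box merging.

## Fuzzy keyword search

Every keyword filter tolerates OCR character errors through a per-keyword
Levenshtein allowance. The default allowance, when a configuration does
not pin one, is `ceil(0.15 × phrase length)` — error tolerance should grow
with phrase length, and per-keyword values are expected to be tuned to
each keyword's observed mis-translation rate. Search is case-insensitive.

Implementation: a pigeonhole filter (any substring within distance k of a
phrase split into k+1 pieces must contain one piece verbatim) locates
candidate windows with plain substring search; each window is verified by
the Sellers semi-global dynamic program with start-index tracking. When
the allowance reaches the phrase length the filter is unsound and the DP
runs over the whole haystack. Overlapping candidate matches are resolved
by lowest edit distance, then leftmost start, then shortest span: an exact
occurrence always beats the distance-1 alignments that flank it, and at
allowance 0 the procedure reduces exactly to non-overlapping leftmost
substring search. Correctness is cross-checked in the test suite against
`edlib` infix alignment, an independent implementation.

## Case selection

A patient is kept iff they have exactly one distinct report identifier,
the reported sample is a primary tumor, and a survival time exists in the
outcomes table. Exclusion reasons are assigned in the fixed order
no-report → multiple-reports → non-primary → no-survival; a patient
qualifying for several gets the first. The order affects only audit
bookkeeping, never the kept set, and the outcome is invariant to input row
order. "Primary tumor" matching is exact (case-insensitive, trimmed)
rather than substring, so variants like "Primary Tumor Metastasis" are not
silently accepted.

## Report screening

Placeholder ("Missing Pathology Report") and diagnosis-discrepancy banner
reports are detected by fuzzy-searching each page's concatenated line text
for the two banner phrases, default allowance 2 (the phrases are long, so
two character errors are tolerable without collision risk); the missing
banner takes precedence. Poor-scan reports have no computable textual
signature, so they are supplied as an explicit id list; a mean word
confidence below a configurable floor (default 50) raises an advisory
flag for triage and never removes anything by itself.

## Form detection

Multiple-choice form text is unlearnable because OCR cannot recover which
option was ticked. Detection is a two-stage funnel: a structural screen
(report candidate if tables/report > 3, selection elements/report > 10,
mean selection elements/page > 4, or max/page > 8 — deliberately arbitrary
defaults, expected to be tuned per dataset since checkbox densities vary
by scanning pipeline) and a disease-specific keyword screen counting
distinct fuzzy-matched phrases against a minimum (the bundled colon set
has 8 phrases, minimum 2; liver and cervix sets ship as extensible stubs
seeded with their two public phrases). The default combination mode is
`and` (both screens must fire), mirroring a funnel tuned for specificity;
`or` is available for recall. A triggered report's form pages are those
that are checkbox-dense (≥ 5 selection elements, configurable) or carry a
keyword hit; if all pages qualify the whole report is proposed for
removal. Every automatic proposal carries `needs_review=True`: the
intended workflow is human confirmation through a review roster, which
overrides decisions and clears the flag.

## QC-table removal

QC tables are located by their section headers: each configured header
keyword is fuzzy-matched against each line; a hit contributes the line's
box expanded by per-header offsets (encoding the header's consistent
position relative to the table body); the merge of all hit boxes is the
max bounding box. One matched header suffices — header vocabulary is
distinct enough from diagnostic prose that lone hits are reliable — and at
most one table per page is assumed; disjoint header clusters still merge
into one box and are caught by the large-box audit flag (area > 0.6 of the
page by default), which feeds a review roster and never removes anything
itself. Lines overlapping the box by ≥ 0.25 of their own area are excised;
the threshold is inclusive ("minimum threshold" read as ≥). Removal is
monotone in the threshold and idempotent: once the headers are gone, a
re-run detects nothing.

The header keyword list is deployment-specific configuration (real QC
inserts vary); the package's generator defines its own nine plausible
slide/sample-quality headers, and all tests are agnostic to the specific
phrases.

## Line cleaning and assembly

Lines consisting entirely of handwriting-annotated words are removed
(annotation-collection artifacts, badly OCR-translated); mixed lines are
kept, and word-less lines cannot satisfy "entirely handwritten" and pass
through. Words lacking a text-type annotation default to PRINTED so that
missing annotation can never delete text. Boilerplate removal uses an
ordered regex list with *search* (substring) semantics, case-insensitive
by default — the targeted clinic headers carry trailing noise and
unpredictable casing; the first matching pattern is recorded per removed
line. The package bundles ~25 example patterns (page footers, fax banners,
accession lines); production lists are user-supplied and typically much
longer.

Reports with ≤ 5 surviving lines are flagged, never removed: short
reports are frequently terse but clinically complete, so they are surfaced
for review. Assembly joins lines with `". "` and pages with `" "`, no
leading/trailing delimiter and no deduplication of a line's own trailing
period — bit-exact and documented rather than clever. Every stage logs
(items_in, items_removed, items_out) into an audit log whose conservation
identity is enforced at entry.

## Synthetic fixtures

The generator emulates the features the pipeline exists to handle:
diagnostic body lines drawn from per-cancer-type vocabularies via
pathology-style templates; a planted QC table (3×3 header grid plus two
value rows at consistent relative positions, headers corrupted with up to
`max_typo_edits` random edits at `typo_rate`, kept within each header's
allowance by default); handwriting-only lines; clinic-header lines
matching the bundled regexes; checkbox-dense form pages carrying form
keywords; and banner reports for the screening stage. Layout is a fixed
vertical grid with clearance rows around the table sized so that expanded
header boxes never reach body text — planted artifacts are unambiguous by
construction. Randomness is a single seeded stream with per-report
substreams keyed by (seed, report index), so any report is reproducible in
isolation and equal seeds give byte-identical serializations.

Default condition parameters: 1–3 pages per report, 4–10 body lines per
page, QC-table plant rate 0.5 per page, handwriting line rate 0.1, header
line rate 0.15, typo rate 0.3 with ≤ 1 edit. The exclusion-category
arithmetic fixtures plant their categories disjointly and with exact
counts, so selection/screening totals are deterministic identities rather
than statistical outcomes.

What passing tests show — and what they do not: the generator's artifacts
are geometrically clean and its class vocabularies disjoint, so perfect
detection concordance and AU-ROC 1.0 are the *correct* results on these
fixtures and validate the machinery, not the difficulty of real scanned
reports. Real OCR output has skewed insertions, merged lines, variable
typo processes and overlapping class vocabularies; thresholds and
allowances must be re-tuned there, and the review-roster workflow exists
precisely because automatic screens are not perfectly specific on real
data.

## Evaluation protocol

The corpus is split train/validation/test (default 0.8/0.1/0.1 — the
exact fractions are configurable) stratified by cancer type, with
largest-remainder rounding (per-class counts within one of exact
proportion) and a guarantee that every class appears in every split.
For each cancer type a binary one-vs-rest scorer is trained per seed;
evaluation applies an overflow-safe softmax to the scorer's two raw
class scores and computes AU-ROC (Mann–Whitney form, ties half-credit)
and AU-PRC (step-interpolation / average-precision convention — one of
several PR-curve conventions, fixed and documented here). Per class, the
seed with the highest validation AU-ROC is selected (ties to the lowest
seed) and its test metrics are the headline; cross-seed confidence
intervals are Student-t at 95%. Metric computation is delegated to
scikit-learn and cross-checked in the tests against an O(n²) pairwise
concordance oracle and a hand-rolled average-precision sum.

The bundled `TermFrequencyScorer` (count vectorizer + L2 logistic
regression, inputs truncated to 512 whitespace tokens to honor the
protocol's input cap) exists so the full protocol runs deterministically
on one CPU. Transformer fine-tuning sits behind the same `ScorerContract`
(fit/score with a `max_tokens` attribute); typical fine-tuning settings
for a clinical BERT-style scorer (batch size 16, 10 epochs, evaluation
every 32 steps) are carried as configuration guidance for such adapters,
not implemented logic.

## Reference tables

The package bundles two published summary tables of the released corpus
this pipeline models — the demographic breakdown and the per-cancer-type
patient counts — as plain TSVs under `pathcorpus/data/`. They are inputs
for sanity arithmetic (age-band totals, gender shares, prevalence
extremes) and prevalence-ordered reporting; nothing in the pipeline's
computation depends on them.

## Known limitations

- Bounding boxes are assumed axis-aligned; rotated insertions are not
  modeled (their handwriting annotation, not their geometry, is what the
  pipeline exploits).
- Table *structure* (cells, merged headers) is never reconstructed; the
  pipeline only localizes and removes table regions.
- The fuzzy matcher reports match spans under one optimal alignment;
  distance ties between different spans of the same occurrence are broken
  by fixed rules, not enumerated.
- Checkbox selection states are treated as unreliable and never
  interpreted.
- No spelling correction, punctuation normalization, or uncasing is
  applied; these are downstream choices that depend on the consuming
  model's tokenizer.
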