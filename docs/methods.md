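# Methods

## The analysis unit and the data model

The unit of analysis is the deduplicated safety report: one report
identifier (`primaryid`), a case identifier (`caseid`; a case may have
several report versions), a receipt calendar quarter, one or more drug
mentions (free-text name plus route, dosage and reporting role), and one or
more reaction preferred terms from a MedDRA-like controlled vocabulary. The
report universe is the denominator N of every 2×2 table, so everything that
changes membership — deduplication, drug selection, extraction windows —
happens before any cell is counted.

Drug names are normalized by trimming, uppercasing, stripping trademark
glyphs (®, ™ and their ASCII renderings) and mapping through a synonym
vocabulary of generic and brand names. Normalization is total (unmapped
names pass through cleaned) and idempotent. Reaction terms are matched
exactly, case-insensitively, after whitespace trimming — never by
substring, because preferred terms are controlled vocabulary and substring
matching would silently widen a filter (e.g. capture "aphthous stomatitis"
from a filter that deliberately contains only "stomatitis").

## Deduplication

The duplicate key is (primary ID, normalized drug name, route, dosage).
Because one report holds one primary ID but many drugs, the key is applied
at two levels, each logged separately:

1. within a report, drug mentions with identical keys collapse to one;
2. a report whose primary ID, full drug-key multiset and reaction set
   duplicate an already-seen report is dropped; first occurrence in file
   order wins, which makes the operation deterministic and idempotent.

Missing route/dosage are empty strings and compare equal to each other.
Separately, multiple versions of one case can be collapsed to the highest
primary ID per case ID (natural ordering on digit runs); this is the
default (`latest`) but can be disabled (`all`) since source databases vary
in whether superseded versions are still present.

## Term filters

Four built-in screening strategies for stomatitis-associated events, in
increasing breadth: the single term "stomatitis"; SAMT (stomatitis,
aphthous ulcer, mouth ulceration — the three most frequent
stomatitis-related preferred terms); CTT, the eleven preferred terms pooled
from the four drugs' phase III registration trials (the SAMT terms plus lip
ulceration, glossodynia, glossitis, cheilitis, oral pain, gingival pain,
oral discomfort, oropharyngeal pain); and OTT, per-drug registration-trial
term sets. OTT membership differs by drug label and no universal default
exists, so OTT ships as user configuration (empty, with a warning, when
unset) rather than as hard-coded content.

Two aggregation conventions are exposed because published count tables use
both, sometimes inconsistently. `sum_of_terms` adds the per-term report
counts, counting a report once per matching term; it is the convention
under which a count table's term rows sum to its filter total, and it is
the default. `unique_reports` counts distinct reports matching at least one
term and is never larger. The 2×2 cells always use unique-report counting
— a report is one row of the universe — so a + b + c + d = N by
construction, whichever convention the descriptive totals use. Output
tables carry both totals so the difference is visible rather than silent.

## Disproportionality statistics

For cells (a, b, c, d) with n = a+b+c+d and z = 1.96 throughout (all
intervals are 95%):

- ROR = ad/bc, CI `exp(ln ROR ± z·√(1/a + 1/b + 1/c + 1/d))`.
- PRR = [a/(a+b)]/[c/(c+d)], CI
  `exp(ln PRR ± z·√(1/a − 1/(a+b) + 1/c − 1/(c+d)))`.
- IC = log2((a+½)/(E+½)) with E = (a+b)(a+c)/n — the observed-vs-expected
  information component with +½ shrinkage, in the form standard for
  spontaneous-report databases; credibility bounds use the series
  approximation `IC − 3.3(a+½)^−1/2 − 2(a+½)^−3/2` and
  `IC + 2.4(a+½)^−1/2 − ½(a+½)^−3/2`. The shrinkage makes IC exactly 0
  when a = E and keeps it finite at a = 0. The formula variant is recorded
  in the run manifest because other IC parameterizations exist.
- Fisher's exact test (two-sided: total hypergeometric probability of
  tables with the observed margins no more probable than the observed
  one) and the Pearson χ² test on 1 df, with and without Yates' continuity
  correction (the 0.5 subtraction capped at |O − E|). These standard tests
  are delegated to scipy.stats; the test suite checks Fisher against an
  independent exact-integer enumeration (max deviation < 1e-15 over all
  tables with total ≤ 20 plus sampled tables with margins up to 30).

Significance: ROR/PRR flag when the CI excludes 1.0 (α = 0.05); IC flags
when its lower bound exceeds 0. Flags are pure functions of the bounds.

**Zero cells.** Ratio estimators are undefined with a zero cell. The
default `haldane` policy adds 0.5 to *every* cell, only when some cell is
zero — rare-event tables (e.g. a drug with 13 event reports) stay defined
while non-degenerate tables are untouched. `strict` raises, naming the
cell. Degenerate margins (a drug with zero reports, or a universe
containing only the drug) are flagged on the table rather than silently
producing numbers.

## Synthetic generator

The generator emulates the structure the pipeline consumes, not the
clinical content of real data. Per report: one drug drawn from a weighted
vocabulary (six oncology agents by default, uniform weights), rendered as
generic or brand name (brand with probability 0.3, matching how reports mix
naming); one background reaction from a noise list disjoint from the
stomatitis sets; with probability p1 (target drug) or p0 (others), one
event term drawn uniformly from the event list; a receipt quarter uniform
over the configured window; route/dosage strings from small pools. Events
are generated at report level (≥ 1 matching term) because the analysis
counts reports, not term occurrences; the planted reporting odds ratio is
therefore analytically `[p1(1−p0)]/[p0(1−p1)]`.

Duplicates are appended after the base draw from a separate random stream,
so deduplication restores the duplicate-free universe of the same seed
exactly. `exact` mode re-emits sampled reports under the same primary ID
(exercising duplicate removal); `new_version` mode issues a
higher-versioned primary ID under the same case ID (exercising
case-version collapse). The generator records every planted label, which
serves as the oracle for the recovery and dedup tests.

Defaults are p0 = 0.005 and p1 set for a planted odds ratio of 30 at
n = 50,000 reports — the scale of a strong mTOR-inhibitor-like signal with
a few-per-thousand background reporting rate — so end-to-end tests exercise
a realistic cell-count regime (a in the hundreds to low thousands) while a
full run stays around a second.

What the generator does **not** emulate: reporter demographics and
reporting-odds confounders, polypharmacy (one drug per report),
within-report term correlation, secular reporting trends, notoriety
effects, and free-text messiness beyond brand synonyms and trademark
glyphs. Passing tests therefore demonstrate correctness of counting,
deduplication and estimation under the stated sampling model — not
robustness to the biases of real spontaneous-report data.

## Numerical and design choices

- File dialect: the public dollar-delimited ASCII layout is canonical
  (header row; columns beyond the required subset ignored, since quarterly
  schemas drift); plain CSV behind a flag. Receipt quarters parse from the
  `fda_dt` date, falling back to a caller-supplied quarter label.
- Round trip: writing then reading a universe is exact for universes with
  unique primary IDs. When duplicate primary IDs exist the flat files
  cannot attribute drug/reaction rows to a specific duplicate, so rows
  attach to every report sharing the ID; deduplication collapses the
  resulting unions to the same retained set.
- Tie-breaks are always "first occurrence in file order"; reruns with the
  same configuration and seed are byte-identical.
- Validation sizes: interval calibration uses 2,000 simulated tables
  (two-binomial model, OR = 3); pipeline recovery uses 100 seeds per
  planted odds ratio at n = 50,000; the Fisher oracle sweep enumerates all
  10,626 tables with total ≤ 20 exhaustively plus 2,000 sampled
  larger-margin tables. These sizes give comfortable Monte-Carlo
  margins for the 93–97% coverage and ≥ 90% recovery checks.
- Published point estimates (e.g. an ROR of 30.72 for the strongest
  signal) depend on the full external database snapshot at a fixed date
  and are not recomputable from a desk; the package instead reproduces the
  published count aggregation exactly and validates the estimators by
  calibration and planted-truth recovery.

## Known limitations

- No probabilistic/fuzzy duplicate detection (demographic similarity); the
  key-based rule only.
- No MedDRA hierarchy traversal — term sets are explicit lists.
- No empirical-Bayes scores (EBGM/MGPS) and no multiplicity adjustment
  across term sets or drugs.
- The XML FAERS dialect and API access are out of scope; inputs are the
  quarterly flat files or the generator.
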