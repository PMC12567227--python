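# faerspv

Pharmacovigilance disproportionality analysis for FAERS-style spontaneous
adverse-event reports, built around the stomatitis signal for four
HR+/HER2− breast-cancer kinase inhibitors (alpelisib, capivasertib,
everolimus, palbociclib) but usable for any drug–event question of the same
shape.

Spontaneous-report databases such as the FDA Adverse Event Reporting System
(FAERS) cannot give incidence rates, but they can show whether an adverse
event is reported *disproportionately often* with one drug compared with all
others. `faerspv` implements that workflow end to end:

1. **Ingestion** of the public FAERS quarterly ASCII dialect
   (dollar-delimited DEMO/DRUG/REAC files; plain CSV also accepted), with
   drug-name normalization through a generic + brand-name synonym
   vocabulary (PIQRAY® → ALPELISIB, …).
2. **Deduplication** on the key (primary ID, normalized drug name, route,
   dosage): identical drug mentions collapse within a report, and duplicate
   reports are dropped (first occurrence wins), with a removal log.
3. **Term-set filtering** with exact (case-insensitive) matching on MedDRA
   preferred terms. Built-in stomatitis filters: `stomatitis` alone; SAMT
   (stomatitis, aphthous ulcer, mouth ulceration); CTT (the 11 terms pooled
   from the drugs' phase III trials); per-drug OTT sets via config. Per-drug
   extraction windows (e.g. everolimus 2009Q2–2025Q1) restrict by receipt
   quarter.
4. **Signal statistics** on the 2×2 table (a, b, c, d) = (drug∧event,
   drug∧¬event, other∧event, other∧¬event):
   - reporting odds ratio `ROR = ad/bc`, 95% CI
     `exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d))`;
   - proportional reporting ratio `PRR = [a/(a+b)]/[c/(c+d)]` with its
     analogous log-scale CI;
   - Bayesian information component `IC = log2((a+½)/(E+½))`,
     `E = (a+b)(a+c)/n`, with the standard credibility-interval
     approximation — the +½ shrinkage keeps sparse estimates near zero;
   - Fisher's exact test and the χ² test with and without Yates'
     continuity correction.
   A signal is flagged when the ROR/PRR 95% CI excludes 1.0, or the IC
   lower bound is above 0. Zero cells use the Haldane–Anscombe +0.5
   correction by default (`strict` raises instead).
5. **Synthetic data** with planted ground truth (association odds ratio,
   duplicate count, synonym usage), so the whole pipeline is testable
   without downloading anything.

## Worked example

Metrics for any 2×2 table, e.g. 694 stomatitis-filter reports among 8,038
for a drug of interest against a ~30-million-report background:

```bash
faerspv stats 694 7344 261234 29910000
```

```json
{
  "ror": 10.819657541899804,
  "ror_low": 10.008480314387244,
  "ror_high": 11.696579864947905,
  "prr": 9.971829433654163,
  "ic": 3.3051507360826924,
  "ic_low": 3.179820274284667,
  "fisher_p": 0.0,
  "chi2": 5636.118864966244,
  "significant_ror": true
}
```

(abridged): the drug's reports carry the event at ~10.8 times the odds of
the background, the IC lower bound 3.18 is far above 0, and all
significance flags are set.

A full synthetic round trip — generate quarterly files with 10% injected
duplicates, then analyze them:

```bash
faerspv generate --out data/ --n 50000 --seed 1 --duplicate-rate 0.1
faerspv analyze --config run.yaml --out results/
```

with `run.yaml`:

```yaml
input:
  demo: data/DEMO.txt
  drug: data/DRUG.txt
  reac: data/REAC.txt
drugs:
  - token: EVEROLIMUS
    synonyms: [EVEROLIMUS, AFINITOR, ZORTRESS]
term_sets: [stomatitis, SAMT, CTT]
```

`results/` then holds a per-term count matrix, a signal table (cells,
ROR/PRR/IC with bounds, p-values, flags), a percentage-of-reports table
under both counting modes, the dedup removal log, and a JSON manifest
echoing the configuration, seed and formula variants.

Counting modes: `sum_of_terms` totals count a report once per matching term
(so per-term columns sum to the total); `unique_reports` counts distinct
reports. The 2×2 cells always use unique-report counting so cells sum to N.

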