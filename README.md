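# aldress

Drug-causality assessment for **DRESS syndrome** (Drug Reaction with
Eosinophilia and Systemic Symptoms) — a severe, delayed T-cell-mediated
drug hypersensitivity reaction with rash, eosinophilia and visceral
involvement, typically appearing two to eight weeks after the culprit drug
is started. Identifying *which* drug caused the reaction is decisive for
acute management and for the patient's future therapeutic options, yet it
is hard precisely when it matters most: patients on several concurrent
drugs.

This package is aimed at pharmacovigilance teams and clinical
pharmacologists. It implements:

- **ALDRESS** — a DRESS-specific causality score gated on the RegiSCAR
  diagnostic score (> +2). Per drug it sums points over chronology
  (DRESS latency windows), dechallenge, rechallenge, drug notoriety,
  microbiological alternative causes, immunology (LTT / patch test) and a
  concomitant-suspect penalty; a drug is *related* when the net score is
  strictly greater than 7.
- **SEFV** — the Spanish Pharmacovigilance System algorithm
  (Karch–Lasagna family), seven factors with its own 1–7-day chronology
  windows; *related* when the net score is strictly greater than 6.
- **RegiSCAR** — the DRESS validation score with its
  excluded / possible / probable / definite bands.
- A **diagnostics** module: sensitivity, specificity, PPV, NPV, accuracy
  with exact Clopper–Pearson intervals, LR+ = Se/(1−Sp), Fisher's exact
  test.
- An **agreement** module: percent exact agreement and Cohen's κ
  (unweighted / linear / quadratic) with the Fleiss–Cohen–Everitt
  asymptotic SE, z, p, CI and Landis–Koch interpretation.
- A **synthetic cohort generator**: seeded 7-case / 30-control DRESS
  cohorts with realistic marginals and *planted* misclassifications, so the
  whole scoring-and-validation pipeline can be exercised end to end with a
  known answer.

All three scoring algorithms run on one declarative score-table engine;
the point allocations ship as editable YAML configs
(`src/aldress/tables/`). The ALDRESS allocation is this package's own
documented convention (see `docs/methods.md`), constrained by the
algorithm's published contract (positivity > 7; a textbook single-drug
case must score related).

## Worked example

Score a single-drug case: lamotrigine started 23 days before onset,
withdrawn with improvement, CMV PCR negative, LTT not done:

```python
import datetime as dt
from aldress import DrugExposure, PatientRecord, RegiscarInputs, \
    default_table, score_drug, regiscar_score
from aldress.records import *

patient = PatientRecord(
    patient_id="P017", age=38.0, sex=Sex.female,
    index_date=dt.date(2021, 6, 10), resolution_date=dt.date(2021, 7, 5),
    regiscar=RegiscarInputs(
        fever_ge_38_5=TernaryFlag.yes, lymphadenopathy=TernaryFlag.yes,
        eosinophilia_grade=EosinophiliaGrade.marked,
        rash_suggestive=TernaryFlag.yes, organs_involved=2,
        resolution_ge_15_days=TernaryFlag.yes),
    exposures=[DrugExposure(
        drug_name="lamotrigine", start_date=dt.date(2021, 5, 18),
        stop_date=dt.date(2021, 6, 11), notoriety=Notoriety.well_known,
        dechallenge=Dechallenge.improved_after_withdrawal)],
    microbiology=[MicrobiologyResult(pathogen=Pathogen.cmv,
        method=TestMethod.pcr, result=TestResult.negative)],
    group=Group.case)

r = regiscar_score(patient.regiscar)
print("RegiSCAR:", r.total_score, r.category)
a = score_drug(patient, patient.exposures[0], default_table("aldress"))
print(dict(a.per_item_points))
print("net =", a.net_score, "| category =", a.category, "| related =", a.related)
```

prints

```
RegiSCAR: 6 definite
{'chronology': 3, 'dechallenge': 2, 'rechallenge': 0, 'notoriety': 2,
 'alternative_infection': 1, 'immunology': 0, 'concomitant_suspect': 0}
net = 8 | category = probable | related = True
```

The RegiSCAR total of +6 is a definite DRESS and passes the > +2 gate.
Compatible chronology (+3), improvement on withdrawal (+2), a well-known
culprit (+2) and a negative infection screen (+1) give a net 8 > 7, so
lamotrigine is called related.

Validate the algorithm on a simulated cohort with one planted miss and two
planted false alarms:

```python
from aldress import CohortProfile, generate, patient_level_calls, \
    confusion, diagnostic_report

cohort = generate(CohortProfile(planted_error=(1, 2)), seed=42)
truth, pred = patient_level_calls(cohort.records, default_table("aldress"))
print(diagnostic_report(confusion(truth, pred)).to_tsv())
```

prints

```
Metric	Value	95% Confidence Interval
Sensitivity	0.8571	0.4213 to 0.9964
Specificity	0.9333	0.7793 to 0.9918
Positive Predictive Value	0.7500	0.3491 to 0.9681
Negative Predictive Value	0.9655	0.8224 to 0.9991
Accuracy	0.9189	0.7809 to 0.9830
Likelihood Ratio	12.86	
```

i.e. the planted 6/1/2/28 confusion structure is recovered exactly:
sensitivity 6/7, specificity 28/30, and LR+ = 0.857/0.067 ≈ 12.86.

The same workflow is available from the shell:

```sh
aldress simulate --seed 42 --planted-miss 1 --planted-fp 2 -o cohort.csv
aldress score --algorithm aldress -i cohort.csv -o scores.csv
aldress evaluate --algorithm aldress -i cohort.csv
```

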