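# mipssr

Risk stratification for myelodysplastic syndromes (MDS) that folds gene
mutations into the revised International Prognostic Scoring System
(IPSS-R).

MDS treatment intensity is chosen by risk group, and the standard IPSS-R
uses only cytogenetics, bone-marrow blasts and blood counts.  Roughly 90%
of MDS patients carry at least one somatic mutation, and the mutation
burden carries prognostic information the IPSS-R ignores.  This package
implements a combined score, **MIPSS-R**, built from two components:

1. **Mutation points** (0–3) from the number of distinct mutated genes on a
   targeted myeloid panel: no mutation or *SF3B1* alone → low (0); one
   mutated gene other than *SF3B1* → intermediate-1 (1); two to four →
   intermediate-2 (2); five or more → high (3).  *SF3B1* is the single
   favorable gene; its privilege applies only when it is the sole mutation.
2. **IPSS-R total** (0–10 in half points) from cytogenetic risk (0–4),
   blasts, hemoglobin, platelets and neutrophil count, with ISCN karyotype
   strings parsed and classified into the five cytogenetic risk groups.

The combined score is the Cox-weighted sum

```
MIPSS-R = 1.047 × mutation points + 0.641 × IPSS-R total
```

where the weights are the multivariate Cox log-hazard coefficients of the
two components, and patients are assigned to five risk groups by quintiles
of the score (reference ranges: very low 1.28–2.24, low 2.33–3.93,
intermediate 4.02–4.34, high 4.57–5.30, very high 5.62–8.59; cut points at
the gap midpoints).  The package also ships the development pipeline that
re-derives weights and bins on any cohort, the survival statistics used to
validate such scores (Kaplan–Meier, log-rank, Cox PH, LASSO-Cox with
cross-validated penalty selection, time-dependent ROC), and a
synthetic-cohort generator so the whole pipeline is testable without
patient data.  For audiences: hematology biostatisticians, registry
analysts and methodologists comparing MDS risk models.

## Worked example

```python
>>> from mipssr import *
>>> cyto = classify_cytogenetics(parse_iscn("46,XX,del(5)(q13q33)"))
>>> ipssr = ipssr_total(ClinicalComponents(hemoglobin=9.2, platelets=53,
...                                        anc=1.18, blasts=1, cyto=cyto))
>>> mut = mutation_stratum(normalize_genes("TET2;ASXL1"))
>>> mipssr_score(mut.points, ipssr.total)
MIPSSRResult(score=3.6965, score_display=3.7, category='low')
```

Running `python examples/validate_stratification.py` scores a simulated
1000-patient cohort and prints:

```
median OS by MIPSS-R group (months):
  high         12.4248
  intermediate 20.3931
  low          52.1681
  very_high    2.84022
  very_low     >59.0665
log-rank chi2=649.8, df=4, p=2.55e-139
24-month AUC: {'mipssr': 0.832, 'ipssr': 0.774, 'mutation': 0.64}
```

Median overall survival falls monotonically from very-low to very-high
risk (`>` means the curve never reached 50% within follow-up), the
log-rank test confirms the groups differ, and the combined score
discriminates 24-month mortality better than either component alone.
The other scripts in `examples/` show single-patient scoring, re-deriving
the model on a cohort, and the risk-migration cross-table.

A thin CLI wraps the same functions for shell pipelines:

```bash
mipssr simulate --out cohort.tsv --seed 42 --n 500
mipssr score    --cohort cohort.tsv --out scored.tsv
mipssr develop  --cohort cohort.tsv --out model.json
mipssr validate --cohort scored.tsv --group mipssr_category --horizon 24 --out report.json
mipssr migrate  --cohort scored.tsv --out migration.json
```

Cohort files are TSV with columns `id`, `hgb_gdl`, `plt_1e9l`, `anc_1e9l`,
`blasts_pct`, `karyotype` (ISCN) or `cyto_category`, `mutations`
(semicolon-delimited gene symbols), `os_months`, `event`.

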