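# Table formats

All tables are UTF-8, comma-delimited CSV with a header row.

## Inputs

`records.csv` — one row per bioactivity measurement:
`compound_id,target_id,document_id,year,has_standard_units,assay_confidence,organism,target_type`.
`year` is a calendar year; `has_standard_units` is 1/0 (also accepts
true/false); `assay_confidence` is an integer 0–9.

`targets.csv` — one row per target:
`target_id,accession,class_path,tdl`. `class_path` is the ":"-joined
protein-class description, coarse to fine; `tdl` is one of
Tclin/Tchem/Tbio/Tdark (anything else becomes `unknown`).

`go_terms.csv` — `target_id,go_term` (GO biological-process annotations,
long format).

`diseases.csv` — `target_id,disease,score` with score in [0, 1]; rows below
the configured score threshold are dropped at load.

`efficacy.csv` — `target_id,drug_id,disease_efficacy` (flag 1/0: the target
is believed to mediate the drug's efficacy).

External counts for the causality stage: a counts table
`disease,year,count` and an optional totals table `year,total` (required
for normalized mode).

These five tables are also the ingest surface for real extracts: export the
equivalent columns from a ChEMBL dump (records, protein classification,
GO annotations), a DisGeNET association file (diseases), and drug-mechanism
tables (efficacy), and point `mtt` at the directory.

## Outputs

`trends.csv` — `scope,annotation,measure,slope,intercept,p_value,n_years,significant,selected`;
slope in percentage points per year, intercept the fitted percent in the
first year.

`tdl.csv` — `year,family,n_targets,empty,Tclin,Tchem,Tbio,Tdark,unknown`;
per-year TDL shares of the family's published targets (sum to 1, or all 0
with `empty=True`).

`decomposition.csv` — `annotation,year,class,percent,displayed`; percent of
the year's total bioactivities; `displayed` applies the 30%-of-largest rule.

`causality.csv` — `disease,rare_flag,n_years,r_squared,gt1,gt2,lag,n_contiguous,gt1_bh,gt2_bh`;
gt1 = p for Dp→Dt, gt2 = p for Dt→Dp, `_bh` columns Benjamini–Hochberg
adjusted.

`shuffle.csv` — `disease,scheme,n_reps,rnd_r_squared` with scheme
`within_series` or `across_diseases`.

`manifest.json` (simulator) and `run_manifest.json` (pipeline) are JSON:
ground truth of a synthetic universe, and the run's config/seeds/stage row
counts respectively.
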