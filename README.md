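# lrckit

Familial longevity scoring from multigenerational pedigrees and cohort
life tables.

Given (a) cohort life tables keyed by sex × birth year × age with yearly
death hazards and (b) PED-like pedigree files, the package computes:

- **survival percentiles** per person within their own sex and birth
  cohort (piecewise-exponential within years, explicit tail policy for
  ages beyond the table), plus threshold ages for top-10/5/1% survival;
- **relationship coefficients** from the standard recursive kinship
  algorithm (parent/sibling 0.5, grandparent and aunt/uncle 0.25, ...);
- the **longevity relatives count score**: the relationship-weighted
  proportion of a focal person's ancestral blood relatives who reached
  the top-Z survival percentile of their cohort, with the family
  case (score ≥ 0.30) / control (score = 0) / nonclassified ([0.2, 0.3))
  classification and the nine score bins;
- **standardized mortality ratios** against the life tables, with exact
  chi-square confidence limits, a family-resampling percentile bootstrap,
  left-truncation conditioning via per-person entry ages, and per-group
  tables with missing-age accounting;
- a **shared gamma-frailty proportional-hazards model** (own Newton
  Cox fitter with Breslow baseline, delayed entry and offsets; EM for
  the frailty variance) for contrasting family cases vs controls and
  their spouses, adjusted for sibship size, birth year and sex;
- a **synthetic cohort simulator** that emulates the restricted
  historical genealogy: case/control founder ascertainment by rejection,
  two descendant generations with spouses, shared-gamma or
  parent-averaged ("transmission") frailty, right-censoring, per-role
  missing ages, the generating and population-marginal life tables, and
  a truth record;
- a **pipeline** that chains percentiles → scores → classification →
  per-bin SMRs → frailty contrast and writes TSV tables plus a
  reproducibility manifest.

## Command-line interface

```bash
# generate a synthetic cohort (pedigree.tsv, life_tables.tsv,
# generating_tables.tsv, truth.tsv)
lrckit simulate --families 200 --theta 0.3 --seed 1 --out-dir sim/

# per-person longevity scores, labels and bins
lrckit lrc --pedigree sim/pedigree.tsv --tables sim/life_tables.tsv --out scores.tsv

# SMRs (overall, per group, or bootstrap CIs)
lrckit smr --persons persons.tsv --tables sim/life_tables.tsv --out smr.tsv
lrckit smr --persons persons.tsv --tables sim/life_tables.tsv --group-col bin --out smr.tsv

# frailty-adjusted case/control survival contrast
lrckit contrast --persons records.tsv --scheme A --out contrast.tsv

# full pipeline from a YAML config (RunConfig fields)
lrckit pipeline --config run.yaml
```

A minimal `run.yaml`:

```yaml
pedigree_path: sim/pedigree.tsv
life_table_path: sim/life_tables.tsv
out_dir: run/
top_fraction: 0.10
case_cutoff: 0.30
contrast_scheme: A
seed: 1
```

## File formats

- **Life tables** (CSV/TSV by extension): header
  `sex,birth_year,age,hazard`; ages must run contiguously from 0 per
  (sex, birth_year). A `qx` column of yearly death probabilities can be
  converted on read (`h = -ln(1 - q)`).
- **Pedigrees** (PED-like): `family_id, person_id, father_id, mother_id,
  sex, birth_year, age_end, vital_status[, role_tag, partner_id]`;
  `0`/empty marks unknown parents; `age_end` is the age at death or last
  observation.

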