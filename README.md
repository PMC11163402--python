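# fcdecomp

Variance decomposition of whole-brain functional connectivity (FC) into
common, group, session and individual components, for longitudinal
task/rest fMRI designs such as antidepressant trials that scan patients
with major depression (MD) and controls repeatedly over treatment.

The question the method answers: of the reliable variation in whole-brain
connectivity across people and scanning sessions, how much is shared by
everyone, how much tracks group membership (diagnosis, treatment response,
sex), how much tracks the scanning session, and how much is stable,
person-specific "fingerprint" variation?

## Method

For each analysis unit (a subject-session after concatenating the
session's runs, or a single run in per-task mode) connectivity is the
Pearson correlation between parcel time courses, Fisher transformed,
`z = atanh(r)`.  The upper triangles of all units' FC matrices are
correlated with one another (and Fisher transformed again) to form an
`N x N` similarity matrix.  Each source of variance is the mean similarity
over a mask of matrix cells:

| effect | cells averaged |
|---|---|
| common | all off-diagonal cells |
| session | same session, different subject |
| sex / diagnosis / response | same group level, different subject |
| group x session, group x sex | same on both factors, different subject |
| individual | same subject, different session |
| individual x session / x task (per-task mode) | within-subject, same session / same task |

Each effect is corrected against a baseline (common against 0; mains
against common; interactions against the larger of their constituent
mains; individual against the largest group/session effect; the
within-subject interactions against individual), floored at zero, and
normalised so the corrected magnitudes sum to 100%.  Participant-wise
effect averages feed dependent-sample t tests with a within-subject
permutation null (sign flips of the paired differences, two-sided,
add-one-smoothed p) and Benjamini-Hochberg FDR across each suite of
comparisons.

The package also provides FIR task regression (lagged indicator
regressors, 10 lags at TR = 2 s, collinear columns dropped by pivoted QR),
voxel-to-parcel averaging with a small-parcel filter, per-region
localization of the decomposition, split-half reliability curves over data
amount, a summary-statistics two-way ANOVA (unweighted-means Type III from
per-cell mean/SEM/n), and a synthetic cohort generator whose additive
latent-component model admits a closed-form oracle for every effect's
expected similarity — so the whole pipeline is verifiable without access
to restricted patient data.

## Worked example

```python
import fcdecomp as f

sim = f.SimulationConfig(n_rois=142, seed=1)          # P = 10_011 edges
rc = f.RunConfig(out_dir="results/demo", simulation=sim,
                 sample="all", mode="pooled", n_perm=1000, seed=1)
res = f.run_pipeline(rc)
print(res.effects[["effect", "raw_mean_z", "normalized_pct"]])
```

prints (seed 1):

```
             effect  raw_mean_z  normalized_pct
             common      0.5464         31.4947
            session      0.5401          0.0000
                sex      0.5421          0.0000
          diagnosis      0.5435          0.0000
diagnosis_x_session      0.5446          0.0624
    diagnosis_x_sex      0.5467          0.1862
         individual      1.7310         68.2567
```

Read: the average Fisher-z similarity between any two units is ~0.55;
within-person similarity across sessions is far higher (~1.73).  After
baseline correction, common and individual connectivity account for
essentially all (99.8%) of the explained variation, while diagnosis, sex
and session effects contribute well under 1% each — the generating weights
put exactly this structure in, and the decomposition recovers it
(`results/demo/effects.tsv`, `comparisons.tsv` hold the full tables).

The numbered scripts under `analysis/` run the complete study sequence on
synthetic study conditions: cohort generation (01), pooled whole-brain
decomposition for the three samples (02), exploratory per-task
decomposition (03), per-region localization (04), split-half reliability
(05), and the demographic summary ANOVAs (06).  Each accepts `--seed` and
`--out` and writes TSV/JSON under `results/`.

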