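# srmeeg

Evoked alpha power, phase-lag-index (PLI) connectivity and
graph-theoretic brain-network topology for EEG studies of
self-referential processing — with a synthetic cohort generator so the
whole chain is testable end to end without any recordings.

The package targets researchers analysing event-related EEG from
self-referential memory (SRM) paradigms: two groups (e.g. patients vs
healthy controls), three encoding conditions (*self*, *other*,
*physical*), multi-channel epochs around stimulus onset, plus
recognition-memory behaviour. It provides the complete analysis as a
library (and a thin `srmeeg` command-line wrapper):

1. **Preprocessing** — zero-phase Butterworth band-pass,
   averaged-mastoid re-referencing, epoch segmentation, and a
   power-spectrum distortion metric |ΔP| = Σ_f |P_recon − P_raw| for
   validating artifact cleaning.
2. **Evoked power** — complex Morlet decomposition (f0/σ_f = 7,
   0.1–30 Hz in 0.5 Hz steps) of the across-trial average, so only
   phase-locked activity survives; band × window means (alpha 8–13 Hz,
   100–300 ms is the headline measure) and per-electrode group t-maps.
3. **Connectivity** — Hilbert instantaneous phase with 100 ms edge
   trimming and the across-trials phase-lag index

       PLI_ij(t) = | (1/N) Σ_n sign(Δφ_ij(t, n)) |,

   which is 1 for a perfectly consistent nonzero lag and exactly 0 for
   zero-lag (volume-conducted) mixtures; windowed 59 × 59 matrices and
   active-vs-baseline edge statistics.
4. **Network topology** — proportional sparsity thresholding
   (S = 0.1 … 0.5), global efficiency, characteristic path length and
   nodal efficiency with area-under-curve summaries.
5. **Statistics** — recognition and SRM-bias scores, mixed-design
   ANOVA (group × condition), pooled-variance t-tests, Pearson
   correlation, linear regression, Bonferroni correction.
6. **Synthesis** — cohorts of 1/f-noise EEG with planted evoked alpha
   bursts, planted lag-consistency coupling on a posterior edge set,
   binomial recognition behaviour, and an optional planted correlation
   between alpha power and SRM bias; every planted effect is recorded
   as ground truth and everything regenerates bit-identically from one
   seed.

See `docs/methods.md` for the models, conventions and the generator's
assumptions.

## Worked example

Generate a small two-group cohort with the default planted effects
(patient alpha amplitude reduced 30 % in the self condition, weaker
posterior phase coupling) and test for them:

```python
import numpy as np
from srmeeg import SimulationConfig, mixed_anova, ttest_ind
from srmeeg.measures import cohort_alpha_measures
from srmeeg.synth import cohort_behavior

config = SimulationConfig(n_per_group=12, n_channels=16, fs=250.0, seed=7)
df = cohort_alpha_measures(config)   # one row per subject x condition

power = df.pivot_table(index="subject", columns="condition",
                       values="alpha_power")
groups = df.drop_duplicates("subject").set_index("subject")["group"]
groups = groups.loc[power.index].to_numpy()

anova = mixed_anova(power[["self", "other", "physical"]].to_numpy(), groups)
print(f"group x condition interaction: "
      f"F{anova['interaction'].df} = {anova['interaction'].statistic:.2f}, "
      f"p = {anova['interaction'].p:.4f}")

selfc = df[df.condition == "self"]
t = ttest_ind(selfc[selfc.group == "control"]["mean_pli"],
              selfc[selfc.group == "patient"]["mean_pli"])
print(f"self-condition PLI, control vs patient: "
      f"t({t.df}) = {t.statistic:.2f}, p = {t.p:.4f}")

eg = selfc.groupby("group")["e_global_auc"].mean()
print(f"global-efficiency AUC: control {eg['control']:.4f}, "
      f"patient {eg['patient']:.4f}")

bias = {g: [] for g in ("control", "patient")}
for rec in cohort_behavior(config).values():
    bias[rec.group].append(rec.srm_bias)
print(f"SRM bias: control {np.mean(bias['control']):.3f}, "
      f"patient {np.mean(bias['patient']):.3f}")
```

Output:

```
group x condition interaction: F(2, 44) = 23.50, p = 0.0000
self-condition PLI, control vs patient: t(22) = 3.47, p = 0.0022
global-efficiency AUC: control 0.2291, patient 0.2304
SRM bias: control 0.102, patient -0.071
```

Reading the numbers: the evoked-power deficit planted only in the
patients' self condition produces a strong group × condition
interaction; the weaker patient phase coupling shows up as a
self-condition PLI group difference; under proportional thresholding
the patients' scattered networks come out slightly *more* globally
efficient (the planted topology contrast); and only the control group
shows a positive self-referential memory bias. At this reduced size
(12 per group, 16 channels) the cohort generates in a few seconds.

The same analysis runs from the shell over a YAML configuration:

```
srmeeg simulate --config cohort.yaml --out fixtures/   # .npz + ground truth
srmeeg run      --config cohort.yaml --out results/    # tables + stats.json
srmeeg report   --out results/                         # headline summary
```

`run` writes per-subject band/window power tables, PLI matrices,
network-metric tables, behaviour tables and a statistics report, each
tagged with the configuration hash and seed; rerunning the same
configuration reproduces the files bit-exactly.

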