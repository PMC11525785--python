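# salnet — condition-dependent EEG salience-network analysis

`salnet` is a tested, reusable pipeline for studying how the brain's
salience network (SN) — dorsal anterior cingulate cortex (dACC) plus left
and right insula — reconfigures between resting-state EEG and a passive
auditory oddball (mismatch-negativity) paradigm, and whether that
reconfiguration predicts antidepressant treatment response in major
depressive disorder (non-remitted `nrMDD` vs remitted `rMDD`, plus healthy
controls `HC`).

It is written for EEG/clinical-neurophysiology researchers who want the
whole chain in one place:

1. **Preprocessing** — 0.1–50 Hz zero-phase 6th-order Butterworth filtering,
   700 ms epoching (resting: non-overlapping windows; oddball: −100 to
   600 ms around each stimulus), detrending, pre-stimulus baseline
   correction, 75 µV absolute-amplitude epoch rejection, and seeded random
   subsampling to fixed epoch quotas (250/300/45 for RS/Std/Dev).
2. **Source localization** — depth-weighted L2 minimum-norm inverse
   `K = W Gᵀ (G W Gᵀ + λC)⁻¹` with `W_vv = ‖g_v‖^(−2γ)`, ROI extraction as
   the first principal component of the voxels within 5 mm of each SN seed.
3. **Connectivity** — the weighted phase-lag index per 0.7 s epoch, band
   (α 8–12, low-β 12–18, high-β 18–30, γ 30–50 Hz) and ROI pair:

       wPLI = |E[sin Δϕ(t)]| / E[|sin Δϕ(t)|]

   with Hilbert-transform instantaneous phases, the first and last 0.1 s of
   each epoch trimmed against filter edge effects; SN *global strength* is
   the sum of the three epoch-averaged edges.
4. **Statistics** — mixed-design repeated-measures ANOVA
   (condition within, group between) with Mauchly sphericity screening and
   Greenhouse–Geisser correction, gated edge-level testing, and percentile
   bootstrap (n = 5,000) post-hoc group contrasts.
5. **Classification** — leave-one-out cross-validation of nrMDD vs rMDD
   from condition-dependent connectivity features (FCdev, FCdiff =
   Dev − Std), resting band power over six scalp regions, and MMN amplitude
   (mean of the 0.1–30 Hz deviant-minus-standard frontocentral difference
   wave over 130–280 ms); per fold, the top k = 1..15 features by Fisher
   score `(μ₁−μ₂)²/(σ₁²+σ₂²)` are z-normalized with training-fold statistics
   only, then fed to LDA, linear SVM, KNN and Gaussian naive Bayes; metrics,
   pooled-score ROC curves and AUC are reported per configuration.
6. **Synthetic data** — because clinical recordings of this kind are not
   publicly available, the package ships a generator with known ground
   truth: three SN sources oscillate per band inside an analytic
   spherical-head forward model; the phase difference between the dACC hub
   and each insula is a planted mean lag plus von Mises jitter whose
   concentration κ depends on (group, condition, band). Expected wPLI is
   strictly increasing in κ, giving closed-loop parameter-recovery tests
   for the entire pipeline.

## Worked example

Simulate a study-sized cohort (14 nrMDD / 17 rMDD / 21 HC) at the
coupling-model level and test the planted high-beta group-by-condition
reversal:

```python
import numpy as np
from salnet import (SimulationConfig, simulate_network_cohort, rm_anova,
                    bootstrap_posthoc)

cfg = SimulationConfig(n_subjects_per_group={"nrMDD": 14, "rMDD": 17,
                                             "HC": 21})
rng = np.random.default_rng(0)
nets = simulate_network_cohort(cfg, rng)   # high-beta salience networks

print(nets.groupby(["group", "condition"])["strength"].mean()
          .unstack()[["RS", "Std", "Dev"]].round(3))

mdd = nets[nets["group"].isin(["nrMDD", "rMDD"])]
wide = mdd.pivot_table(index="subject", columns="condition",
                       values="wpli_dACC_rIns")[["RS", "Std", "Dev"]]
groups = mdd.drop_duplicates("subject").set_index("subject") \
            .loc[wide.index, "group"]
res = rm_anova(wide.to_numpy(), groups.to_numpy())
print(f"group x condition interaction: F = {res.f_interaction:.2f}, "
      f"p = {res.p_interaction_reported:.4g}")

dev = wide["Dev"]
boot = bootstrap_posthoc(dev[groups == "nrMDD"], dev[groups == "rMDD"],
                         n_resamples=5000, seed=0)
print(f"Dev-condition nrMDD - rMDD: {boot.observed:.3f} "
      f"(95% CI {boot.ci_low:.3f} to {boot.ci_high:.3f})")
```

Output:

```
condition     RS    Std    Dev
group
HC         0.807  1.286  2.182
nrMDD      2.253  1.361  0.822
rMDD       0.900  1.313  2.078
group x condition interaction: F = 1489.02, p = 9.359e-27
Dev-condition nrMDD - rMDD: -0.420 (95% CI -0.459 to -0.382)
```

The strength table shows the planted pattern: controls and remitted
patients ramp SN coupling up from rest through standard to deviant
stimulation, non-remitted patients do the opposite; the mixed ANOVA detects
the interaction and the bootstrap contrast shows deviant-condition
dACC–rIns hypoconnectivity in the non-remitted group.

The full sensor-level path (simulation → EDF-style recordings →
preprocessing → inverse solution → connectivity → features → statistics →
classification) runs end to end from the command line:

```bash
salnet --seed 1 --out out/ run-all --sim-config my_cohort.yaml
```

which writes `networks.csv`, `features.csv`, `stats.csv`,
`cv_metrics.csv`, `cv_folds.csv`, `roc.csv`, `cv_summary.json` and a
`manifest.json` recording the config hash and every seed. Individual
stages (`simulate`, `preprocess`, `localize`, `connectivity`, `features`,
`stats`, `classify`) exchange files on disk so a run can be resumed
anywhere.

## Limitations

The generator plants coupling through a dACC-hub model (the insula–insula
edge is implied by the two hub edges), uses an analytic single-shell
spherical head with radially oriented sources instead of a boundary-element
model on real anatomy, and replaces manual independent-component artifact
rejection with the amplitude criterion alone. See `docs/methods.md` for the
full model description and design rationale.
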