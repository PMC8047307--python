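# dvhtox

Dose–volume histogram (DVH) reduction and logistic NTCP modelling for
radiation-induced **temporal lobe injury (TLI)** in nasopharyngeal carcinoma
(NPC) treated with intensity-modulated radiotherapy.

## The problem

Temporal-lobe dose constraints drive NPC planning, but the temporal lobe is
hard to contour consistently — across patients its manually contoured volume
varies by ~30%, versus ~10% for the skull-bounded brain.  Because the hot
spot responsible for TLI sits in the temporal pole, a **half-brain** contour
(the whole brain split at the midline) contains the same hot spot while
being far more reproducible.  This package implements the dosimetric
analysis pipeline behind that idea:

1. **DVH reduction** — cumulative DVHs per structure (brain, left/right
   half-brain, left/right temporal lobe) are reduced to `D_max`, covering
   doses `D_V` (0.03–20 cc) and hot volumes `V_D` (40–80 Gy), optionally as
   EQD2 with `EQD2 = D·(d + α/β)/(2 + α/β)`, α/β = 3 Gy.
2. **Inter-structure statistics** — coefficients of variation of contoured
   volumes, paired *t*-tests and percent reductions of temporal-lobe vs
   half-brain `D_V`, Pearson correlation, chi-square association tests.
3. **ROC screening** — AUC of every `D_V`/`V_D` grid point against per-side
   injury labels, DeLong 95% intervals, and Youden-optimal cutoffs; the AUC
   profile rises to a peak and declines, identifying the most predictive
   covering volume/dose.
4. **NTCP model** — the logistic dose/volume response
   `P(X) = 1/(1 + exp(−b0 − b1·X))`, fitted by an in-repo IRLS maximum
   likelihood routine, then inverted for tolerance points
   `X_p = (logit(p) − b0)/b1` such as TD5/5 and TD50/5 with delta-method
   confidence intervals.
5. **Synthetic cohorts** — a calibrated generator emulating the reference
   220-patient cohort (nested five-structure DVHs, T-stage-dependent hot
   spots, injury labels drawn from the published logistic model), so the
   whole pipeline runs and is tested without clinical data.

`LogisticNTCP` follows the scikit-learn estimator contract
(`fit`/`predict_proba`/`get_params`), and `DVHMetricExtractor` is a sklearn
transformer, so both compose with sklearn pipelines and model selection.

## Worked example

```python
from pathlib import Path
from dvhtox import SynthConfig
from dvhtox.cli import PipelineConfig, run_simulate, run_full_analysis

out = Path("demo")
run_simulate(PipelineConfig(out_dir=out, synth=SynthConfig(n_patients=300, seed=1)))
outputs = run_full_analysis(
    PipelineConfig(out_dir=out, dvh_csv=out / "dvh.csv", meta_csv=out / "metadata.csv")
)
```

or equivalently from the shell: `dvhtox all --seed 1 --n-patients 300 --out demo`.

The bundle contains, among others, the volume-variability report

```
   structure  mean_volume_cc  sd_volume_cc  cv_percent
       brain         1299.96        130.46       10.04
half_brain_L          640.05         65.31       10.20
  temporal_L           67.72         17.86       26.38
```

— brain and half-brain contours vary by ~10% across patients while temporal
lobes vary by ~26%, which is the case for the half-brain surrogate — and the
fitted dose-response model for half-brain `D_1.2cc` (Wald table and inverted
tolerance points):

```
    term       B    SE   Wald  Sig  Exp(B)
 D_1.2cc   0.135 0.023 33.150  0.0   1.144
Constant -10.835 1.648 43.243  0.0   0.000

 metric  probability  value  ci_low  ci_high
D_1.2cc         0.05  58.61   54.32    62.90
D_1.2cc         0.50  80.48   76.67    84.29
```

The 300-patient synthetic fit recovers the generating coefficient
(B = 0.135 vs the true 0.138; odds ratio 1.144 per Gy) and its tolerance
points — a TD5/5 of ≈58.6 Gy and TD50/5 of ≈80.5 Gy for the dose covering
the hottest 1.2 cc of the half-brain.

## Layout

```
src/dvhtox/dvh.py        DVHCurve, interpolation, EQD2, metric extraction, CSV I/O
src/dvhtox/synth.py      calibrated synthetic cohort generator
src/dvhtox/stats.py      CV, paired t, reduction table, Pearson, chi-square
src/dvhtox/screening.py  AUC, DeLong CI, Youden cutoffs, AUC profiles
src/dvhtox/ntcp.py       LogisticNTCP (IRLS), Wald table, TD_p inversion, curves
src/dvhtox/cli.py        dvhtox simulate/reduce/screen/fit/all
docs/methods.md          model, calibration and design notes
```
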