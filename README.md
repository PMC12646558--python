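# emgrehab

Surface-EMG-based longitudinal assessment of hand motor recovery after
stroke, packaged as a tested, reusable analysis pipeline.

Clinical scales (FMA-UE, ARAT, BBT) score what a therapist observes; surface
EMG offers an objective complement. In a two-arm rehabilitation study design,
five forearm muscles (extensor digitorum communis, flexor digitorum
superficialis, supinator, pronator teres, dorsal interossei) are recorded at
1926 Hz while the patient performs seven cued hand movements (flexion,
extension, opening, closing, pinch, pronation, supination; 5 s rest / 5 s
contraction, three repetitions). Recovery is then tracked three ways:

1. **Movement classification** — per patient and assessment week (baseline,
   weeks 4, 6, 9), windows of cleaned EMG are classified into the seven
   movements with KNN, random forest, and RBF-SVM. As selective muscle
   activation returns, movement-specific activation patterns become more
   distinct and accuracy rises; week-pair accuracy changes and the mean/SD
   of the three classifiers summarize progression.
2. **EMG–clinical correlation** — Spearman rank correlation between
   per-patient EMG feature summaries and each clinical scale, per group and
   week, with weak/moderate/strong labels (|ρ| cutoffs 0.3 / 0.6).
3. **MCID-referenced outcomes** — the between-group difference of change
   scores (difference-in-differences), compared against the minimal
   clinically important difference of each instrument (FMA-UE 9, ARAT 6,
   BBT 6 points; strict inequality).

The signal path is: 50 Hz IIR notch (Q = 30) → 4th-order Butterworth
bandpass 20–450 Hz (both zero-phase) → cue-based contraction epoching with a
250 ms guard trim → 250 ms windows with 50 % overlap (481 samples, step 240
at 1926 Hz) → a 16-feature bank per window per channel: RMS, MAV, IEMG, SSC,
ZC, PTP, VAR, SD, WL, CARD, IQR, kurtosis, average energy, AAC, and mean /
median frequency from a Welch power spectrum.

No patient data ship with the package. A synthetic cohort generator
(`emgrehab.synth`) produces a two-arm study (26 patients per arm by default)
in which one latent *separability* variable λ(w) — the distinctness of each
patient's movement-specific activation patterns — drives classification
accuracy, EMG amplitude, and the clinical scores at once, so every
downstream stage can be tested for parameter recovery.

## Worked example

```python
import emgrehab as er
from emgrehab.study import run_study

protocol = er.AcquisitionProtocol(rest_s=1.0, contract_s=2.0)  # scaled down
config = er.CohortConfig(n_per_group=8, weeks=(0, 6, 9), seed=1)
result = run_study(config, protocol)
print(result["summary"].pivot(index="week", columns="group", values="mean_acc").round(1))
```

prints the mean classification accuracy (percent, averaged over the three
classifiers) per group and week:

```
group  control  experimental
week
0         26.6          21.8
6         53.1          60.1
9         52.2          59.8
```

Both simulated arms start near chance-plus (seven classes, so chance is
~14 %) and improve before saturating at their recovery ceilings, with the
experimental arm — generated with a faster recovery rate and a higher
ceiling — ahead of the control arm from week 6 onward. (Absolute accuracies on this shortened 2 s-contraction
protocol are lower than on the full 5 s protocol, which yields more windows
per repetition.) The same `result` carries `correlations` (feature ×
instrument × group × week Spearman table), `outcomes`
(difference-in-differences vs. MCID), and `progression` (week-pair cells
with paired-t and between-group ANOVA p-values).

A file-based variant of the same pipeline, with YAML configuration, staged
intermediates keyed by a config hash, and CSV/JSON artifacts, is available
as a CLI:

```sh
emgrehab all --config run.yaml --seed 1
```

with subcommands `simulate`, `preprocess`, `features`, `classify`,
`correlate`, `clinical`, `report` for the individual stages.

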