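"""In-memory end-to-end study analysis on a synthetic cohort.

Convenience layer over the stage functions for parameter-recovery work:
simulate a cohort, preprocess and featurize every recording, classify per
patient-week, and compute the correlation and clinical outcome tables —
without touching the filesystem. The file-based pipeline in
:mod:`emgrehab.pipeline` persists the same products stage by stage.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import pandas as pd

from .classify import (ClassifierSpec, CvSpec, classifier_mean_summary,
                       crossval_accuracy, progression_table)
from .clinical import (McidThresholds, StatsConfig, correlation_table,
                       outcome_summary, summarize_patient_features)
from .features import FeatureSpec, build_feature_table
from .preprocess import PreprocessConfig, extract_epochs, make_windows, preprocess
from .synth import (AcquisitionProtocol, CohortConfig, make_cohort,
                    simulate_clinical_scores, simulate_emg_session)


def cohort_feature_table(config: CohortConfig,
                         protocol: AcquisitionProtocol,
                         pre: PreprocessConfig = PreprocessConfig(),
                         spec: FeatureSpec = FeatureSpec()) -> pd.DataFrame:
    """Simulate, filter, window and featurize the whole cohort."""
    cohort = make_cohort(config, protocol)
    window_sets = []
    for patient in cohort.patients:
        for week in config.weeks:
            for movement in protocol.movements:
                rec = simulate_emg_session(patient, week, movement, protocol, config)
                clean = preprocess(rec, pre)
                for epoch in extract_epochs(clean, protocol, pre.guard_ms):
                    window_sets.append(make_windows(epoch, pre, rec.fs))
    return build_feature_table(window_sets, protocol.fs_hz, spec)


def cohort_clinical_table(config: CohortConfig) -> pd.DataFrame:
    cohort = make_cohort(config)
    rows = [simulate_clinical_scores(p, w, config)
            for p in cohort.patients for w in config.weeks]
    return pd.DataFrame(rows)


def run_study(
    config: CohortConfig,
    protocol: AcquisitionProtocol,
    classifiers: Sequence[str] = ("knn", "random_forest", "svm"),
    clf: ClassifierSpec = ClassifierSpec(),
    cv: CvSpec = CvSpec(folds=3),
    pre: PreprocessConfig = PreprocessConfig(),
    spec: FeatureSpec = FeatureSpec(),
    stats: StatsConfig = StatsConfig(),
    mcid: McidThresholds = McidThresholds(),
) -> dict:
    """Full analysis of one synthetic cohort; returns the report frames.

    Keys of the result: ``accuracy`` (per patient-week-classifier, long),
    ``summary`` (classifier-mean per group-week), ``progression`` (week-pair
    cells, when two or more weeks exist), ``correlations`` and ``outcomes``.
    """
    table = cohort_feature_table(config, protocol, pre, spec)
    clinical = cohort_clinical_table(config)

    rows = []
    for (pid, week), sub in table.groupby(["patient_id", "week"]):
        for kind in classifiers:
            rep = crossval_accuracy(sub, dataclasses.replace(clf, kind=kind), cv)
            rows.append({"patient_id": pid, "group": sub["group"].iloc[0],
                         "week": week, "classifier": kind,
                         "accuracy": rep.accuracy})
    acc = pd.DataFrame(rows)
    weeks = sorted(acc["week"].unique())
    summaries = {w: summarize_patient_features(table, w) for w in weeks}
    result = {
        "features": table,
        "clinical": clinical,
        "accuracy": acc,
        "summary": classifier_mean_summary(acc),
        "correlations": correlation_table(summaries, clinical, weeks, stats),
        "outcomes": outcome_summary(clinical, mcid, stats, groups=config.groups),
    }
    if len(weeks) >= 2:
        result["progression"] = progression_table(acc, weeks, list(config.groups))
    return result
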