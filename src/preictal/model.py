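"""Top-level modelling interface.

:class:`SeizurePredictor` is built from a labelled feature matrix (or
directly from a record plus seizure annotations) and ``fit()`` runs the
whole patient-specific protocol: chronological train/test split,
preictal-period grid search on the training seizures, classifier
training, Firing Power smoothing and alarm generation on the test
span.  The returned :class:`SeizurePredictionResults` carries the
fitted classifier, the selected preictal duration, the alarm timeline
and the SS / FPR/h / TiW report, and exposes the surrogate significance
test, the circadian forecasting comparison and the explanation
procedures.

Example
-------
>>> from preictal import SimulationConfig, generate_patient, SeizurePredictor
>>> rec, ann, truth = generate_patient(SimulationConfig(n_seizures=5,
...     record_days=1.0, fs=128.0, channel_names=("Cz", "O1"),
...     min_separation_h=1.5, seed=7))
>>> res = SeizurePredictor.from_record(rec, ann).fit(seed=7)
>>> print(res.summary())            # doctest: +SKIP
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from . import alarms as alarms_mod
from . import evaluation as eval_mod
from . import explain as explain_mod
from .features import (FeatureMatrix, LABEL_EXCLUDED, LABEL_INTERICTAL,
                       extract_features)
from .records import EEGRecord, SeizureAnnotation
from .training import (GridSearchResult, LogisticTrainer, PREICTAL_GRID_MIN,
                       SvmEnsembleTrainer, TrainTestSplit,
                       chronological_split, grid_search_preictal,
                       predict_windows)

__all__ = ["SeizurePredictor", "SeizurePredictionResults"]


class SeizurePredictor:
    """Patient-specific seizure-prediction model.

    Parameters
    ----------
    features : FeatureMatrix
        Window-level features of the full recording (unlabelled is
        fine; labelling happens per candidate preictal duration).
    onsets_s : array-like
        Seizure onset times, seconds from the start of the recording.
    classifier : {"logistic", "svm-ensemble"}
        Final classifier family.  ``trainer`` overrides this with a
        custom trainer object.
    preictal_grid_min : sequence of float
        Candidate preictal durations for the grid search (minutes);
        pass ``fixed_preictal_min`` to skip the search.
    """

    def __init__(
        self,
        features: FeatureMatrix,
        onsets_s: np.ndarray,
        classifier: str = "logistic",
        preictal_grid_min: Sequence[float] = PREICTAL_GRID_MIN,
        fixed_preictal_min: float | None = None,
        n_train_seizures: int = 3,
        sph_min: float = 10.0,
        threshold: float = alarms_mod.DEFAULT_THRESHOLD,
        ictal_s: float = 60.0,
        grid_metric: str = "auc",
        trainer=None,
    ):
        self.features = features
        self.onsets_s = np.sort(np.asarray(onsets_s, dtype=float))
        self.classifier = classifier
        self.preictal_grid_min = tuple(preictal_grid_min)
        self.fixed_preictal_min = fixed_preictal_min
        self.n_train_seizures = n_train_seizures
        self.sph_min = sph_min
        self.threshold = threshold
        self.ictal_s = ictal_s
        self.grid_metric = grid_metric
        if trainer is not None:
            self.trainer = trainer
        elif classifier == "logistic":
            self.trainer = LogisticTrainer()
        elif classifier == "svm-ensemble":
            self.trainer = SvmEnsembleTrainer()
        else:
            raise ValueError(f"unknown classifier {classifier!r}")

    @classmethod
    def from_record(cls, record: EEGRecord, annotations: SeizureAnnotation,
                    **kwargs) -> "SeizurePredictor":
        """Extract the default feature bank from a record and build the model."""
        extract_kw = {k: kwargs.pop(k) for k in
                      ("bands", "families", "include_total_power")
                      if k in kwargs}
        annotations.validate_within(record)
        features = extract_features(record, **extract_kw)
        return cls(features, annotations.onsets_s(record.start_time), **kwargs)

    def fit(self, seed: int = 0) -> "SeizurePredictionResults":
        """Run the full training protocol and evaluate on the test span."""
        ss = np.random.SeedSequence(seed)
        s_grid, s_final = (int(s.generate_state(1)[0] % (2 ** 31))
                           for s in ss.spawn(2))
        split = chronological_split(self.features, self.onsets_s,
                                    self.n_train_seizures, self.ictal_s)
        if self.fixed_preictal_min is not None:
            grid_result = GridSearchResult(
                best_min=float(self.fixed_preictal_min),
                scores={float(self.fixed_preictal_min): np.nan}, per_fold={},
            )
        else:
            grid_result = grid_search_preictal(
                split.train, split.train_onsets_s, self.preictal_grid_min,
                trainer=self.trainer, metric=self.grid_metric,
                sph_min=self.sph_min, threshold=self.threshold,
                ictal_s=self.ictal_s, seed=s_grid,
            )
        best = grid_result.best_min
        train = split.train.relabel(split.train_onsets_s, best * 60.0,
                                    self.ictal_s)
        fit_rows = train.labels != LABEL_EXCLUDED
        model = self.trainer.fit(
            train.values[fit_rows], train.labels[fit_rows],
            train.feature_names, seed=s_final, preictal_min=best,
        )

        test = split.test.relabel(split.test_onsets_s, best * 60.0,
                                  self.ictal_s)
        preds = predict_windows(model, test.values)
        tau = max(1, int(round(best * 60.0 / test.window_s)))
        fps = alarms_mod.firing_power(preds, tau, threshold=self.threshold)
        ictal_mask = test.labels == LABEL_EXCLUDED
        events, refractory = alarms_mod.generate_alarms(
            fps, refractory_windows=tau, ictal_mask=ictal_mask,
            window_s=test.window_s, window_start_s=test.window_start_s,
        )
        horizon = alarms_mod.HorizonSpec(sop_min=best, sph_min=self.sph_min)
        classified, predicted = alarms_mod.classify_alarms(
            events, split.test_onsets_s, horizon,
        )
        n_false = sum(e.kind == "false_positive" for e in classified)
        n_true = len(classified) - n_false
        interictal = test.labels == LABEL_INTERICTAL
        interictal_s = float(interictal.sum()) * test.window_s
        refr_inter_s = float((refractory & interictal).sum()) * test.window_s
        warnings_tl = eval_mod.warning_timeline_from_fp(fps.fp, self.threshold)
        report = eval_mod.EvaluationReport(
            ss=eval_mod.seizure_sensitivity(predicted),
            fpr_h=eval_mod.false_positive_rate(n_false, interictal_s,
                                               refr_inter_s),
            tiw_h=eval_mod.time_in_warning(warnings_tl, test.window_s),
            n_test_seizures=len(split.test_onsets_s),
            n_false_alarms=n_false,
            n_true_alarms=n_true,
            interictal_hours_counted=(interictal_s - refr_inter_s) / 3600.0,
        )
        return SeizurePredictionResults(
            model=model, split=split, grid_result=grid_result,
            preictal_min=best, horizon=horizon, firing_power=fps,
            alarms=classified, refractory=refractory,
            predicted_flags=predicted, report=report, parent=self, seed=seed,
        )


@dataclasses.dataclass
class SeizurePredictionResults:
    """Fitted patient model, its alarm timeline and its evaluation."""

    model: object
    split: TrainTestSplit
    grid_result: GridSearchResult
    preictal_min: float
    horizon: alarms_mod.HorizonSpec
    firing_power: alarms_mod.FiringPowerSeries
    alarms: list
    refractory: np.ndarray
    predicted_flags: np.ndarray
    report: eval_mod.EvaluationReport
    parent: SeizurePredictor
    seed: int

    # -- derived quantities -----------------------------------------------
    @property
    def params(self) -> pd.Series | None:
        """Regression coefficients per selected feature (linear models)."""
        if hasattr(self.model, "weights"):
            return pd.Series(self.model.weights,
                             index=self.model.feature_names, name="coef")
        return None

    @property
    def test(self) -> FeatureMatrix:
        return self.split.test.relabel(self.split.test_onsets_s,
                                       self.preictal_min * 60.0,
                                       self.parent.ictal_s)

    def seizure_data_spans(self) -> np.ndarray:
        """Contiguous test block (start, end) around each test seizure."""
        spans = []
        prev = float(self.split.test.window_start_s[0])
        for onset in self.split.test_onsets_s:
            spans.append((prev, onset + self.parent.ictal_s))
            prev = onset + self.parent.ictal_s
        return np.asarray(spans)

    # -- statistics ---------------------------------------------------------
    def surrogate_test(self, n_surrogates: int = 1000, alpha: float = 0.05,
                       seed: int | None = None) -> eval_mod.SurrogateResult:
        """Chance-level significance of the observed SS (alarms fixed)."""
        return eval_mod.surrogate_test(
            self.alarms, self.split.test_onsets_s, self.seizure_data_spans(),
            self.horizon, n_surrogates=n_surrogates, alpha=alpha,
            seed=self.seed + 1 if seed is None else seed,
        )

    def compare_with_circadian(self) -> pd.DataFrame:
        """Forecast-mode SS / TiW of this model vs the circadian baseline."""
        start = self.parent.features.start_time
        start_tod = (start.hour * 3600 + start.minute * 60 + start.second)
        train_tod = (start_tod + self.split.train_onsets_s) % 86400.0
        circ = eval_mod.CircadianModel(train_onset_tod_s=train_tod)
        test = self.split.test
        circ_warn = eval_mod.circadian_forecast(circ, test.window_start_s,
                                                record_start_tod_s=start_tod)
        eeg_warn = eval_mod.warning_timeline_from_fp(
            self.firing_power.fp, self.parent.threshold)
        return eval_mod.compare_forecasters(
            eeg_warn, circ_warn, test.window_start_s, test.window_s,
            self.split.test_onsets_s,
        )

    # -- explanations -------------------------------------------------------
    def counterfactuals(self, window_idx: int) -> list:
        """Per-feature minimal flips for one test window."""
        x_raw = self.split.test.values[window_idx]
        if hasattr(self.model, "weights"):
            z = self.model.transform(x_raw[None, :])[0]
            return explain_mod.counterfactual_per_feature(self.model, z)
        return [
            explain_mod.counterfactual_ensemble(self.model, x_raw, name)
            for name in self.model.feature_names
        ]

    def ablation_traces(self, groups=None, seed: int | None = None) -> dict:
        """Single-feature-group retraining, Firing Power traces on test."""
        train = self.split.train.relabel(
            self.split.train_onsets_s, self.preictal_min * 60.0,
            self.parent.ictal_s)
        return explain_mod.single_feature_retrain(
            train, self.split.test, groups=groups,
            tau=self.firing_power.tau, threshold=self.parent.threshold,
            seed=self.seed if seed is None else seed,
        )

    def timeplot_bundle(self, sleep: np.ndarray | None = None,
                        ) -> explain_mod.TimeplotBundle:
        test = self.test
        return explain_mod.TimeplotBundle(
            window_start_s=test.window_start_s, fp=self.firing_power.fp,
            alarms=self.alarms, labels=test.labels, sleep=sleep,
            refractory=self.refractory, threshold=self.parent.threshold,
        )

    # -- presentation -------------------------------------------------------
    def summary(self) -> str:
        """Plain-text summary table of the fitted model and its evaluation."""
        r = self.report
        kind = type(self.model).__name__
        lines = [
            "Seizure prediction results",
            "=" * 58,
            f"{'Classifier:':<28}{kind}",
            f"{'Train seizures:':<28}{len(self.split.train_onsets_s)}",
            f"{'Test seizures:':<28}{r.n_test_seizures}",
            f"{'Selected preictal (min):':<28}{self.preictal_min:.0f}",
            f"{'SPH / SOP (min):':<28}"
            f"{self.horizon.sph_min:.0f} / {self.horizon.sop_min:.0f}",
            f"{'Alarm threshold:':<28}{self.parent.threshold:.2f}",
            "-" * 58,
            f"{'Seizure sensitivity (SS):':<28}{r.ss:.3f}",
            f"{'FPR/h:':<28}{r.fpr_h:.3f}",
            f"{'Time in warning (h):':<28}{r.tiw_h:.2f}",
            f"{'True / false alarms:':<28}{r.n_true_alarms} / {r.n_false_alarms}",
            f"{'Interictal hours counted:':<28}{r.interictal_hours_counted:.2f}",
            "=" * 58,
        ]
        if self.grid_result.scores and not any(
                np.isnan(list(self.grid_result.scores.values()))):
            grid = ", ".join(f"{k:.0f}: {v:.3f}"
                             for k, v in sorted(self.grid_result.scores.items()))
            lines.insert(-1, f"{'Grid scores (min: score):':<28}{grid}")
        return "\n".join(lines)
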