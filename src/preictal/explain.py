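"""Model-decision explanations.

Four procedures, all aimed at a clinical reviewer rather than at the
optimizer:

* **Counterfactuals** — for a given window, the slightest change in
  each single feature that flips the model's decision ("had this band
  power been x lower, no alarm would have contributed").  Closed form
  for linear models, line search for the voting ensemble.  Deltas are
  reported in standardized units and in raw feature units (delta times
  the train-set standard deviation), since clinicians read raw band
  powers.
* **Single-feature ablation retraining** — the model is retrained
  several times on one feature group at a time (per-band powers, the
  signal's time variance, total band power) on identical splits and
  seeds, and the resulting Firing Power traces are compared.  If a
  suspect group (for instance gamma, prone to muscle artifacts) is the
  only discriminative one, that is evidence about what the model uses.
* **Firing-Power scatter data** — tidy (firing power, feature value,
  label) rows for scatter plots, with user-supplied moments of
  interest highlighted.
* **Time-plot export** — the annotated Firing Power timeline (alarms,
  threshold, preictal shading, sleep state) as CSV and optionally a
  rendered figure.
"""

from __future__ import annotations

import dataclasses
import pathlib
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import alarms as alarms_mod
from .features import FeatureMatrix, LABEL_EXCLUDED, LABEL_PREICTAL
from .training import LinearModel, LogisticTrainer, SvmEnsemble, predict_windows

__all__ = [
    "CounterfactualResult", "TimeplotBundle",
    "counterfactual_per_feature", "counterfactual_ensemble",
    "default_ablation_groups", "single_feature_retrain",
    "fp_feature_scatter", "export_timeplot",
]


@dataclasses.dataclass
class CounterfactualResult:
    """Minimal single-feature change that flips one window's prediction."""

    feature: str
    original_std: float
    delta_std: float | None
    delta_raw: float | None
    flipped_prediction: int | None
    feasible: bool

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def counterfactual_per_feature(
    model: LinearModel,
    x_std: np.ndarray,
    margin_eps: float = 1e-9,
) -> list[CounterfactualResult]:
    """Closed-form minimal flips for a linear model, one feature at a time.

    ``x_std`` is the standardized selected-feature vector of one window.
    For feature j with weight w_j != 0 the flip is ``delta_j =
    (target - margin) / w_j`` where ``target`` is a sign-preserving
    epsilon past the decision boundary (a zero margin classifies
    preictal by the tie rule, but an exact zero target is numerically
    fragile, so a relative ``margin_eps`` is crossed in both
    directions).  Features with zero weight cannot flip the decision
    (feasible = False).  Results are sorted by |delta| ascending,
    infeasible last.
    """
    x = np.asarray(x_std, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("window contains non-finite standardized values")
    if x.shape != (len(model.weights),):
        raise ValueError("x_std must match the model's selected features")
    m = float(model.margin_standardized(x[None, :])[0])
    current = int(m >= 0.0)
    eps = margin_eps * (1.0 + abs(m))
    target = -eps if current == 1 else eps
    sds = model.selected_sd
    out = []
    for j, (w, name) in enumerate(zip(model.weights, model.feature_names)):
        if w == 0.0:
            out.append(CounterfactualResult(
                feature=name, original_std=float(x[j]), delta_std=None,
                delta_raw=None, flipped_prediction=None, feasible=False,
            ))
            continue
        delta = (target - m) / w
        out.append(CounterfactualResult(
            feature=name, original_std=float(x[j]), delta_std=float(delta),
            delta_raw=float(delta * sds[j]), flipped_prediction=1 - current,
            feasible=True,
        ))
    out.sort(key=lambda r: (not r.feasible,
                            abs(r.delta_std) if r.feasible else np.inf))
    return out


def counterfactual_ensemble(
    model: SvmEnsemble,
    x_raw: np.ndarray,
    feature: str | int,
    search_bounds: tuple[float, float] = (-50.0, 50.0),
    n_grid: int = 2001,
    tol: float = 1e-6,
) -> CounterfactualResult:
    """Smallest single-feature change flipping the ensemble majority vote.

    The perturbation is applied in standardized units to one feature of
    one raw-feature window.  A signed grid scan over ``search_bounds``
    locates the flip interval closest to zero and bisection refines it
    to ``tol``.  ``feasible=False`` when no flip exists within bounds.
    """
    if not np.all(np.isfinite(search_bounds)):
        raise ValueError("search bounds must be finite")
    Z = model.standardizer.transform(np.asarray(x_raw, dtype=float)[None, :])
    names = model.feature_names
    j = names.index(feature) if isinstance(feature, str) else int(feature)
    sd_j = model.standardizer.sd_[model.standardizer.kept_][j]

    def vote(delta: float) -> int:
        Zp = Z.copy()
        Zp[0, j] += delta
        votes = sum(
            int(svc.decision_function(Zp[:, sel])[0] >= 0.0)
            for svc, sel in model.members
        )
        return int(votes * 2 > model.n_members)

    base = vote(0.0)
    deltas = np.linspace(search_bounds[0], search_bounds[1], n_grid)
    order = np.argsort(np.abs(deltas), kind="stable")
    flip_at = None
    prev_by_sign = {1.0: 0.0, -1.0: 0.0}
    for d in deltas[order]:
        if d == 0.0:
            continue
        s = np.sign(d)
        if vote(float(d)) != base:
            flip_at = (prev_by_sign[s], float(d))
            break
        prev_by_sign[s] = float(d)
    if flip_at is None:
        return CounterfactualResult(
            feature=names[j], original_std=float(Z[0, j]), delta_std=None,
            delta_raw=None, flipped_prediction=None, feasible=False,
        )
    lo, hi = flip_at  # vote(lo) == base, vote(hi) != base
    while abs(hi - lo) > tol:
        mid = 0.5 * (lo + hi)
        if vote(mid) != base:
            hi = mid
        else:
            lo = mid
    return CounterfactualResult(
        feature=names[j], original_std=float(Z[0, j]), delta_std=float(hi),
        delta_raw=float(hi * sd_j), flipped_prediction=1 - base, feasible=True,
    )


# ---------------------------------------------------------------------------
# single-feature ablation retraining
# ---------------------------------------------------------------------------

def default_ablation_groups(feature_names: Sequence[str],
                            ) -> dict[str, list[str]]:
    """Feature groups for ablation retraining, from available columns.

    Per-band relative powers (gamma sub-bands pooled), the signal's
    time variance and -- when extracted -- the total band power.  Empty
    groups are omitted.
    """
    def match(pred: Callable[[str], bool]) -> list[str]:
        return [n for n in feature_names if pred(n.split("/")[-1])]

    groups = {
        "delta": match(lambda f: f == "pow_delta"),
        "theta": match(lambda f: f == "pow_theta"),
        "band_8_13": match(lambda f: f == "pow_band_8_13"),
        "band_13_30": match(lambda f: f == "pow_band_13_30"),
        "gamma": match(lambda f: f.startswith("pow_gamma")),
        "variance": match(lambda f: f == "variance"),
        "total_power": match(lambda f: f == "total_power"),
    }
    return {k: v for k, v in groups.items() if v}


def single_feature_retrain(
    train: FeatureMatrix,
    test: FeatureMatrix,
    groups: Mapping[str, Sequence[str]] | None = None,
    trainer=None,
    tau: int | None = None,
    threshold: float = alarms_mod.DEFAULT_THRESHOLD,
    seed: int = 0,
    include_original: bool = True,
) -> dict[str, np.ndarray]:
    """Retrain on one feature group at a time; return aligned FP traces.

    ``train`` must be labelled; for every group the pipeline
    (standardize -> train -> predict -> Firing Power) is rerun with the
    same split and seed, restricted to the group's columns.  The trace
    of the full-feature model is included under ``"original"``.  Raises
    for a group with no matching features.
    """
    if train.labels is None:
        raise ValueError("training features must be labelled")
    if trainer is None:
        trainer = LogisticTrainer(n_keep=None)
    if groups is None:
        groups = default_ablation_groups(train.feature_names)
    if tau is None:
        tau = max(1, int(round(
            (trainer_preictal_min(trainer) or 40.0) * 60.0 / train.window_s)))
    keep = train.labels != LABEL_EXCLUDED
    fit_fm = train.subset_rows(keep)

    jobs = dict(groups)
    for name, cols in jobs.items():
        if len(cols) == 0:
            raise ValueError(f"ablation group {name!r} matches no features")
    if include_original:
        jobs = {"original": list(train.feature_names), **jobs}

    traces: dict[str, np.ndarray] = {}
    for name, cols in jobs.items():
        tr = fit_fm.select_features(list(cols))
        te = test.select_features(list(cols))
        model = trainer.fit(tr.values, tr.labels, tr.feature_names, seed=seed)
        preds = predict_windows(model, te.values)
        traces[name] = alarms_mod.firing_power(preds, tau,
                                               threshold=threshold).fp
    return traces


def trainer_preictal_min(trainer) -> float | None:
    return getattr(trainer, "preictal_min", None)


# ---------------------------------------------------------------------------
# scatter and time-plot exports
# ---------------------------------------------------------------------------

def fp_feature_scatter(
    fp: np.ndarray,
    feature_values: np.ndarray,
    labels: np.ndarray,
    window_start_s: np.ndarray | None = None,
    interest_idx: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Tidy rows (firing_power, feature, label) per window for scatter plots.

    ``interest_idx`` marks user-chosen moments of interest (typically
    false alarms and missed seizures) in a ``highlight`` column.
    """
    fp = np.asarray(fp, dtype=float)
    feat = np.asarray(feature_values, dtype=float)
    labels = np.asarray(labels)
    if not (len(fp) == len(feat) == len(labels)):
        raise ValueError("fp, feature and label series must be aligned")
    df = pd.DataFrame({"firing_power": fp, "feature": feat, "label": labels})
    if window_start_s is not None:
        df.insert(0, "window_start_s", np.asarray(window_start_s, dtype=float))
    df["highlight"] = False
    if interest_idx is not None:
        df.loc[list(interest_idx), "highlight"] = True
    return df


@dataclasses.dataclass
class TimeplotBundle:
    """Everything behind an annotated Firing Power time plot."""

    window_start_s: np.ndarray
    fp: np.ndarray
    alarms: list
    labels: np.ndarray | None = None      # -1/0/1 per window
    sleep: np.ndarray | None = None       # bool per window
    refractory: np.ndarray | None = None  # bool per window
    threshold: float = alarms_mod.DEFAULT_THRESHOLD

    def __post_init__(self) -> None:
        n = len(self.window_start_s)
        for attr in ("fp", "labels", "sleep", "refractory"):
            v = getattr(self, attr)
            if v is not None and len(v) != n:
                raise ValueError(f"{attr} not on the common window grid")


def export_timeplot(bundle: TimeplotBundle, path: str | pathlib.Path,
                    figure_path: str | pathlib.Path | None = None) -> pd.DataFrame:
    """Write the time-plot data as CSV (and optionally render a figure).

    Columns: window_start_s, fp, alarm_flag, refractory_flag (when
    available), label (when available), sleep (when available).
    """
    df = pd.DataFrame({
        "window_start_s": np.asarray(bundle.window_start_s, dtype=float),
        "fp": np.asarray(bundle.fp, dtype=float),
    })
    alarm_flag = np.zeros(len(df), dtype=bool)
    for a in bundle.alarms:
        idx = a.index if isinstance(a, alarms_mod.AlarmEvent) else int(a)
        alarm_flag[idx] = True
    df["alarm_flag"] = alarm_flag
    if bundle.refractory is not None:
        df["refractory_flag"] = np.asarray(bundle.refractory, dtype=bool)
    if bundle.labels is not None:
        df["label"] = np.asarray(bundle.labels)
    if bundle.sleep is not None:
        df["sleep"] = np.asarray(bundle.sleep, dtype=bool)
    # %.17e keeps enough digits for an exact float64 round trip
    df.to_csv(path, index=False, float_format="%.17e")
    if figure_path is not None:
        _render_timeplot(bundle, df, figure_path)
    return df


def _render_timeplot(bundle: TimeplotBundle, df: pd.DataFrame,
                     figure_path: str | pathlib.Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t_h = df["window_start_s"] / 3600.0
    fig, ax = plt.subplots(figsize=(10, 3.2))
    if bundle.labels is not None:
        lab = np.asarray(bundle.labels)
        ax.fill_between(t_h, 0, 1, where=lab == LABEL_PREICTAL,
                        color="tab:blue", alpha=0.15, label="preictal")
        ax.fill_between(t_h, 0, 1, where=lab == LABEL_EXCLUDED,
                        color="tab:red", alpha=0.15, label="ictal")
    if bundle.sleep is not None:
        ax.fill_between(t_h, 0, 1, where=np.asarray(bundle.sleep, bool),
                        color="gray", alpha=0.10, label="sleep")
    ax.plot(t_h, df["fp"], color="black", lw=0.8, label="Firing Power")
    ax.axhline(bundle.threshold, color="tab:orange", ls="--", lw=0.8,
               label=f"threshold {bundle.threshold:g}")
    at = t_h[df["alarm_flag"].to_numpy()]
    ax.plot(at, np.full(len(at), bundle.threshold), "v", color="tab:red",
            ms=6, label="alarm")
    ax.set_xlabel("time (h)")
    ax.set_ylabel("Firing Power")
    ax.set_ylim(0, 1.02)
    ax.legend(loc="upper left", fontsize=7, ncol=3)
    fig.tight_layout()
    fig.savefig(figure_path, dpi=150)
    plt.close(fig)
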