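"""Metrics and the three validation scenarios.

Scenario 1 asks the library to predict a force profile it was trained on
(different trials of the same kind); scenarios 2 and 3 build the library
from 2 and 3 known profile kinds respectively and ask it to predict an
arbitrary profile none of the sub-models represents.  Metrics (R^2 and
RMSE) are computed on the normalised signals, past the library warm-up,
and the test trial never contributes to any sub-model's training data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import fusion
from .ann import MLPConfig, ann_estimate, build_lag_features, mlp_init, mlp_train_lm
from .hw import HWConfig
from .library import TrainingCouple, build_library
from .signals import FilterSpec, SignalTrace, preprocess
from .synthetic import SyntheticDataset, Trial

__all__ = [
    "r_squared",
    "rmse",
    "ScenarioSpec",
    "default_scenario",
    "EvaluationReport",
    "run_scenario",
    "compare_methods",
]


def r_squared(y: np.ndarray | SignalTrace, yhat: np.ndarray | SignalTrace) -> float:
    """Coefficient of determination 1 - SSres/SStot (can be negative)."""
    y = y.samples if isinstance(y, SignalTrace) else np.asarray(y, dtype=float)
    yhat = yhat.samples if isinstance(yhat, SignalTrace) else np.asarray(yhat, dtype=float)
    if y.size != yhat.size:
        raise ValueError("length mismatch")
    if y.size < 2:
        raise ValueError("need at least two samples")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("R^2 undefined for a constant reference")
    return 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot


def rmse(y: np.ndarray | SignalTrace, yhat: np.ndarray | SignalTrace) -> float:
    """Root mean squared error."""
    y = y.samples if isinstance(y, SignalTrace) else np.asarray(y, dtype=float)
    yhat = yhat.samples if isinstance(yhat, SignalTrace) else np.asarray(yhat, dtype=float)
    if y.size != yhat.size:
        raise ValueError("length mismatch")
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


@dataclass(frozen=True)
class ScenarioSpec:
    """Which trials build the library and which trial is held out.

    ``library_trials`` maps profile kind -> trial indices used for
    training; ``target_kind``/``target_trial`` define the held-out test
    trial, which must not appear among the training trials of its kind.
    """

    id: int
    library_trials: dict[str, tuple[int, ...]]
    target_kind: str
    target_trial: int

    def __post_init__(self) -> None:
        used = self.library_trials.get(self.target_kind, ())
        if self.target_trial in used:
            raise ValueError("held-out test trial appears in the training set")


def default_scenario(scenario_id: int) -> ScenarioSpec:
    """The three standard validation scenarios.

    1: three step trials train three sub-models; a fourth step trial is
       the test target (same kind, distinct trials).
    2: one step and one circle trial train two sub-models; a freely
       varying (vol) trial is the target.
    3: one step, one circle and one saw trial train three sub-models;
       a vol trial is the target.
    """
    if scenario_id == 1:
        return ScenarioSpec(id=1, library_trials={"step": (0, 1, 2)},
                            target_kind="step", target_trial=3)
    if scenario_id == 2:
        return ScenarioSpec(id=2, library_trials={"step": (0,), "circle": (0,)},
                            target_kind="vol", target_trial=0)
    if scenario_id == 3:
        return ScenarioSpec(id=3,
                            library_trials={"step": (0,), "circle": (0,), "saw": (0,)},
                            target_kind="vol", target_trial=0)
    raise ValueError("scenario id must be 1, 2 or 3")


@dataclass
class EvaluationReport:
    """Per-method metrics for one scenario run."""

    scenario_id: int
    metrics: dict[str, dict]        # method -> {"r2": [...], "rmse": [...], ...}
    n_test_samples: int
    train_refs: list[str]
    test_ref: str
    seed: int

    def aggregates(self) -> pd.DataFrame:
        rows = []
        for method, m in self.metrics.items():
            for name in ("r2", "rmse"):
                vals = np.asarray(m[name], dtype=float)
                rows.append({"scenario": self.scenario_id, "method": method,
                             "metric": name, "mean": vals.mean(),
                             "min": vals.min(), "max": vals.max(),
                             "std": vals.std()})
        return pd.DataFrame(rows)

    def to_rows(self) -> list[dict]:
        rows = []
        for method, m in self.metrics.items():
            for j, (r2, e) in enumerate(zip(m["r2"], m["rmse"])):
                rows.append({"scenario": self.scenario_id, "method": method,
                             "channel": j + 1, "r2": r2, "rmse": e,
                             "seed": self.seed})
        return rows


def _trial(dataset: SyntheticDataset, kind: str, index: int, subject: int = 0) -> Trial:
    for t in dataset.select(profile_kind=kind, subject=subject):
        if t.index == index:
            return t
    raise ValueError(f"dataset lacks trial {index} of profile {kind!r} "
                     f"(subject {subject})")


def run_scenario(
    dataset: SyntheticDataset,
    spec: ScenarioSpec | int,
    methods: tuple[str, ...] = ("mm", "ann"),
    hw_config: HWConfig | None = None,
    ann_config: MLPConfig | None = None,
    filter_spec: FilterSpec | None = None,
    mode: str = "normalised",
    seed: int = 0,
    input_channels: tuple[str, str] = ("emg_ecr", "emg_fds"),
    train_channels: tuple[str, ...] = ("emg_ecr", "emg_fds", "emg_fcr"),
    ann_max_train: int = 4000,
    subject: int = 0,
    residue_smooth_s: float = 0.25,
    norm_scope: str = "per_trial",
) -> EvaluationReport:
    """Build the scenario's library, evaluate the requested methods held out.

    The multimodel path trains one sub-model per training trial on the
    ``train_channel`` envelope against the normalised measured force, then
    estimates on the test trial with the ``input_channels`` envelopes as
    the two multimodel inputs (both referenced to the measured force).
    The ANN path trains the Fig-7-style network on the concatenated
    training trials with the same preprocessing.  Normalisation ranges are
    fitted on the pooled training trials only and frozen for the test
    trial.  Fully deterministic under a fixed seed.
    """
    spec = default_scenario(spec) if isinstance(spec, int) else spec
    hw_config = hw_config or HWConfig()
    filter_spec = filter_spec or FilterSpec()
    fs = dataset.config.fs
    lag = max(1, int(round(0.05 * fs)))
    lags = (0, lag, 2 * lag)

    train_trials: list[Trial] = []
    for kind, idxs in spec.library_trials.items():
        for idx in idxs:
            train_trials.append(_trial(dataset, kind, idx, subject))
    test_trial = _trial(dataset, spec.target_kind, spec.target_trial, subject)
    assert all(t.ref != test_trial.ref for t in train_trials), \
        "held-out trial leaked into training"

    channel_labels = list(train_trials[0].emg.keys())

    # --- preprocess each trial; pool training data to fit normalisation ---
    def chain(trial: Trial) -> dict[str, SignalTrace]:
        from .signals import lowpass_envelope, rectify
        out = {}
        for label in channel_labels:
            out[label] = lowpass_envelope(rectify(trial.emg[label]), filter_spec)
        out["force"] = lowpass_envelope(rectify(trial.force), filter_spec)
        return out

    from .signals import NormalizationParams, minmax_apply, minmax_fit

    train_env = [chain(t) for t in train_trials]
    test_env = chain(test_trial)

    if norm_scope == "per_trial":
        # each measurement couple normalised to its own range, the same
        # convention its sub-model is identified under
        def normalise(env: dict[str, SignalTrace]) -> dict[str, SignalTrace]:
            return {label: minmax_apply(tr, minmax_fit(tr))
                    for label, tr in env.items()}
    elif norm_scope == "pooled":
        params: dict[str, NormalizationParams] = {}
        for label in channel_labels + ["force"]:
            pooled = np.concatenate([e[label].samples for e in train_env])
            params[label] = NormalizationParams(d_min=float(pooled.min()),
                                                d_max=float(pooled.max()),
                                                source_label=label)

        def normalise(env: dict[str, SignalTrace]) -> dict[str, SignalTrace]:
            return {label: minmax_apply(tr, params[label])
                    for label, tr in env.items()}
    else:
        raise ValueError("norm_scope must be 'per_trial' or 'pooled'")

    train_norm = [normalise(e) for e in train_env]
    test_norm = normalise(test_env)

    metrics: dict[str, dict] = {}
    n_test = len(test_trial.force)

    if "mm" in methods:
        couples = [TrainingCouple(u=e[train_channels[0]], y=e["force"],
                                  ref=t.ref, profile_kind=t.profile_kind)
                   for t, e in zip(train_trials, train_norm)]
        library = build_library(couples, hw_config=hw_config, fusion_mode=mode)
        emg_in = [test_norm[c] for c in input_channels]
        refs = [test_norm["force"]] * len(emg_in)
        window = max(1, int(round(residue_smooth_s * fs)))
        out = fusion.estimate(library, emg_in, refs, mode=mode,
                              smooth_window=window)
        ref_sl = test_norm["force"].samples[out.start:]
        r2 = [r_squared(ref_sl, f.samples) for f in out.F_m]
        err = [rmse(ref_sl, f.samples) for f in out.F_m]
        individual = np.array([[r_squared(ref_sl, out.F_ij[i, j])
                                for j in range(out.F_ij.shape[1])]
                               for i in range(out.F_ij.shape[0])])
        metrics["mm"] = {"r2": r2, "rmse": err, "r2_mean": float(np.mean(r2)),
                         "individual_r2": individual.tolist(),
                         "converged": [e.model.converged for e in library.entries]}
        n_test = ref_sl.size

    if "ann" in methods:
        n_in = len(channel_labels) * len(lags)
        cfg = ann_config or MLPConfig(n_inputs=n_in, seed=seed)
        X_parts, Y_parts = [], []
        for e in train_norm:
            X = build_lag_features([e[c] for c in channel_labels], lags=lags)
            f = e["force"].samples
            Y = np.zeros((X.shape[0], cfg.n_outputs))
            Y[:, 0] = f
            Y[:, 1] = f
            X_parts.append(X)
            Y_parts.append(Y)
        X_all = np.vstack(X_parts)
        Y_all = np.vstack(Y_parts)
        stride = max(1, X_all.shape[0] // ann_max_train)
        w0 = mlp_init(cfg)
        w, _hist = mlp_train_lm(w0, X_all[::stride], Y_all[::stride], cfg)
        preds = ann_estimate(w, [test_norm[c] for c in channel_labels],
                             n_force_outputs=2, lags=lags)
        ref = test_norm["force"].samples
        r2 = [r_squared(ref, p.samples) for p in preds]
        err = [rmse(ref, p.samples) for p in preds]
        metrics["ann"] = {"r2": r2, "rmse": err, "r2_mean": float(np.mean(r2))}

    return EvaluationReport(scenario_id=spec.id, metrics=metrics,
                            n_test_samples=int(n_test),
                            train_refs=[t.ref for t in train_trials],
                            test_ref=test_trial.ref, seed=seed)


def compare_methods(reports: list[EvaluationReport]) -> pd.DataFrame:
    """Long-form comparison table, multimodel columns before ANN.

    One row per (scenario, channel); columns mm_r2/ann_r2/mm_rmse/ann_rmse
    in the conventional order.  No hypothesis testing.
    """
    rows = []
    for rep in reports:
        for r in rep.to_rows():
            rows.append(r)
    long = pd.DataFrame(rows)
    if long.empty:
        return long
    wide = long.pivot_table(index=["scenario", "channel"], columns="method",
                            values=["r2", "rmse"])
    wide.columns = [f"{method}_{metric}" for metric, method in wide.columns]
    order = [c for c in ("mm_r2", "ann_r2", "mm_rmse", "ann_rmse") if c in wide.columns]
    return wide[order].reset_index()
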