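"""Library construction: how many sub-models, and which trials train them.

The number of sub-models N is tied to the number of distinct statistical
behaviours among the EMG envelope trials.  Where a human analyst would
eyeball box plots and densities, this module computes per-trial
distribution features (quartiles, IQR, variance, skewness, kurtosis),
standardises them, clusters with k-means over a candidate range of N and
picks the N with the best mean silhouette.  A manual override always wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .hw import HWConfig, identify_hw
from .fusion import ModelLibrary, SubModelEntry
from .signals import SignalTrace

__all__ = [
    "TrainingCouple",
    "LibraryPlan",
    "trial_statistics",
    "suggest_submodel_count",
    "build_library",
]

FEATURE_COLUMNS = ["q1", "median", "q3", "iqr", "variance", "skewness", "kurtosis"]


@dataclass
class TrainingCouple:
    """One (EMG envelope, force) measurement couple available for training."""

    u: SignalTrace
    y: SignalTrace
    ref: str = ""
    profile_kind: str = ""


@dataclass
class LibraryPlan:
    """Suggested sub-model count plus the clustering evidence behind it."""

    suggested_n: int
    assignments: np.ndarray
    silhouette: dict[int, float]
    representatives: list[int] = field(default_factory=list)


def trial_statistics(trials: list[SignalTrace], ids: list[str] | None = None,
                     kinds: list[str] | None = None) -> pd.DataFrame:
    """Distribution features of each trial's EMG envelope.

    One row per trial: quartiles, IQR, variance, skewness and excess
    kurtosis.  Deterministic and invariant to trial order at row level.
    """
    if not trials:
        raise ValueError("no trials given")
    rows = []
    for i, tr in enumerate(trials):
        if len(tr) == 0:
            raise ValueError("empty trial")
        x = tr.samples
        q1, med, q3 = np.percentile(x, [25, 50, 75])
        rows.append({
            "trial_id": ids[i] if ids else tr.label or str(i),
            "profile_kind": kinds[i] if kinds else "",
            "q1": q1, "median": med, "q3": q3, "iqr": q3 - q1,
            "variance": float(np.var(x)),
            "skewness": float(stats.skew(x)) if np.ptp(x) > 0 else 0.0,
            "kurtosis": float(stats.kurtosis(x)) if np.ptp(x) > 0 else 0.0,
        })
    return pd.DataFrame(rows)


def _standardise(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    keep = sd > 0
    return (X[:, keep] - mu[keep]) / sd[keep]


def suggest_submodel_count(
    features: pd.DataFrame,
    candidates: range | list[int] | None = None,
    seed: int = 0,
) -> LibraryPlan:
    """Choose N by silhouette-scored k-means over standardised features.

    With all trials statistically identical the silhouette is undefined and
    the fallback is N = 1 (a single sub-model suffices).
    """
    from sklearn.cluster import KMeans
    from sklearn.metrics import silhouette_score

    n = len(features)
    if n < 3:
        raise ValueError("need at least 3 trials to suggest a sub-model count")
    if candidates is None:
        candidates = range(2, min(6, n - 1) + 1)
    candidates = [c for c in candidates]
    if candidates and min(candidates) > n:
        raise ValueError(f"fewer trials ({n}) than smallest candidate N "
                         f"({min(candidates)})")
    candidates = [c for c in candidates if 2 <= c <= n - 1]

    X = features[FEATURE_COLUMNS].to_numpy(dtype=float)
    Xs = _standardise(X)
    if Xs.size == 0 or Xs.shape[1] == 0:
        return LibraryPlan(suggested_n=1, assignments=np.zeros(n, dtype=int),
                           silhouette={})

    scores: dict[int, float] = {}
    labels: dict[int, np.ndarray] = {}
    for k in candidates:
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        lab = km.fit_predict(Xs)
        if len(np.unique(lab)) < 2:
            continue
        scores[k] = float(silhouette_score(Xs, lab))
        labels[k] = lab
    if not scores:
        return LibraryPlan(suggested_n=1, assignments=np.zeros(n, dtype=int),
                           silhouette={})
    best = max(scores, key=lambda k: (scores[k], -k))
    lab = labels[best]
    reps = _representatives(Xs, lab)
    return LibraryPlan(suggested_n=best, assignments=lab, silhouette=scores,
                       representatives=reps)


def _representatives(Xs: np.ndarray, labels: np.ndarray) -> list[int]:
    """Index of the trial nearest each cluster centroid (one per cluster)."""
    reps = []
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        centroid = Xs[idx].mean(axis=0)
        reps.append(int(idx[np.argmin(np.linalg.norm(Xs[idx] - centroid, axis=1))]))
    return reps


def build_library(
    couples: list[TrainingCouple],
    hw_config: HWConfig | None = None,
    plan: LibraryPlan | None = None,
    n_override: int | None = None,
    fusion_mode: str = "normalised",
) -> ModelLibrary:
    """Identify one H-W sub-model per selected training couple.

    Without a plan, every couple trains a sub-model.  With a plan, the
    representative couple of each cluster (nearest the centroid) is used.
    ``n_override`` truncates/limits the selection.  Identification failures
    are re-raised naming the offending couple.
    """
    hw_config = hw_config or HWConfig()
    if plan is not None and plan.representatives:
        selected = [couples[i] for i in plan.representatives]
    else:
        selected = list(couples)
    if n_override is not None:
        selected = selected[:n_override]
    if not selected:
        raise ValueError("no training couples selected")

    entries = []
    for i, c in enumerate(selected, start=1):
        try:
            model = identify_hw(c.u, c.y, hw_config)
        except Exception as exc:  # noqa: BLE001 - annotate provenance
            raise RuntimeError(
                f"identification failed for couple {c.ref or i!r}: {exc}"
            ) from exc
        entries.append(SubModelEntry(id=i, model=model, training_ref=c.ref,
                                     profile_kind=c.profile_kind))
    return ModelLibrary(entries=entries, fusion_mode=fusion_mode)
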