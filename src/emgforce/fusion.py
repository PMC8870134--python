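"""Multimodel fusion: residues, validities and fused MIMO force outputs.

A single Hammerstein-Wiener model rarely covers the whole operating range
of the EMG-force relation.  The multimodel approach keeps a library of N
local sub-models and, at every time step, weights each one by its momentary
pertinence:

    err_ij(k)   = |F_ij(k) - F_j(k)|                (residue of sub-model i
                                                     on output channel j)
    err'_ij(k)  = err_ij(k) / sum_i err_ij(k)       (normalised residue)
    mu_ij(k)    = 1 - err'_ij(k)                    (validity, in [0, 1])

and the fused output is the validity-weighted combination of the
sub-model outputs.  Because the validities sum to N - 1, the default
``normalised`` mode rescales them to sum to one (a convex combination);
``unnormalised`` uses the raw validities, and ``switching`` hard-selects
the sub-model with the largest validity at each step.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .hw import HWModel, simulate_hw
from .signals import SignalTrace

__all__ = [
    "SubModelEntry",
    "ModelLibrary",
    "ValidityMatrix",
    "MultimodelOutput",
    "run_submodels",
    "compute_residues",
    "normalize_residues",
    "compute_validities",
    "fusion_weights",
    "fuse_outputs",
    "estimate",
]

FUSION_MODES = ("normalised", "unnormalised", "switching")


@dataclass
class SubModelEntry:
    """One library entry: a sub-model and the provenance of its training couple."""

    id: int
    model: HWModel
    training_ref: str = ""
    profile_kind: str = ""

    def to_dict(self) -> dict:
        return {"id": self.id, "model": self.model.to_dict(),
                "training_ref": self.training_ref, "profile_kind": self.profile_kind}

    @classmethod
    def from_dict(cls, d: dict) -> "SubModelEntry":
        return cls(id=d["id"], model=HWModel.from_dict(d["model"]),
                   training_ref=d.get("training_ref", ""),
                   profile_kind=d.get("profile_kind", ""))


@dataclass
class ModelLibrary:
    """The model base: N sub-models sharing signal conventions."""

    entries: list[SubModelEntry]
    fusion_mode: str = "normalised"

    def __post_init__(self) -> None:
        ids = [e.id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("sub-model ids must be unique within a library")

    @property
    def N(self) -> int:
        return len(self.entries)

    @property
    def warmup(self) -> int:
        return max(e.model.warmup for e in self.entries)

    def to_dict(self) -> dict:
        return {"fusion_mode": self.fusion_mode,
                "entries": [e.to_dict() for e in self.entries]}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelLibrary":
        return cls(entries=[SubModelEntry.from_dict(e) for e in d["entries"]],
                   fusion_mode=d.get("fusion_mode", "normalised"))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "ModelLibrary":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class ValidityMatrix:
    """Full audit trail of the decision unit: arrays of shape (N, J, K)."""

    err: np.ndarray
    err_norm: np.ndarray
    mu: np.ndarray
    w: np.ndarray


@dataclass
class MultimodelOutput:
    """Fused force estimates plus the audit trail.

    ``F_m`` holds one fused trace per output channel, starting at the
    library warm-up index (``start``); ``F_ij`` the per-sub-model outputs
    over the same range.
    """

    F_m: list[SignalTrace]
    validity: ValidityMatrix
    F_ij: np.ndarray
    start: int


def run_submodels(library: ModelLibrary, emg: list[SignalTrace]) -> np.ndarray:
    """Simulate every sub-model on every multimodel input channel.

    Returns an array of shape (N, J, K): F_ij is sub-model i driven by
    input channel j.
    """
    if not emg:
        raise ValueError("at least one EMG input channel required")
    K = len(emg[0])
    out = np.empty((library.N, len(emg), K))
    for i, entry in enumerate(library.entries):
        for j, ch in enumerate(emg):
            out[i, j] = np.asarray(simulate_hw(entry.model, ch).samples)
    return out


def compute_residues(F_ij: np.ndarray, references: list[np.ndarray] | np.ndarray,
                     smooth_window: int = 1) -> np.ndarray:
    """Absolute residues err[i, j, k] = |F_ij(k) - F_j(k)|.

    *references* holds the measured/desired force per output channel; it is
    mandatory — the decision unit cannot run reference-free.  An optional
    centred moving average (``smooth_window`` > 1) stabilises the weights
    under noisy references.
    """
    refs = np.asarray(references, dtype=float)
    if refs.ndim == 1:
        refs = refs[None, :]
    if refs.shape != F_ij.shape[1:]:
        raise ValueError("reference shape must match (J, K) of the sub-model outputs")
    err = np.abs(F_ij - refs[None, :, :])
    if smooth_window > 1:
        from scipy.ndimage import uniform_filter1d

        err = uniform_filter1d(err, size=smooth_window, axis=-1, mode="nearest")
    return err


def normalize_residues(err: np.ndarray, tie_eps: float = 1e-12) -> np.ndarray:
    """Normalise residues across sub-models: err'[i] = err[i] / sum_i err[i].

    Where the residues of all sub-models sum to at most ``tie_eps`` (several
    simultaneously perfect sub-models) the tie rule assigns uniform 1/N.
    """
    err = np.asarray(err, dtype=float)
    if err.shape[0] < 2:
        raise ValueError("residue normalisation requires N >= 2 sub-models")
    total = err.sum(axis=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(total > tie_eps, err / np.where(total > 0, total, 1.0),
                       1.0 / err.shape[0])
    return out


def compute_validities(err_norm: np.ndarray) -> np.ndarray:
    """Validities mu[i] = 1 - err'[i]; in [0, 1], summing to N - 1 across i."""
    return 1.0 - np.asarray(err_norm, dtype=float)


def fusion_weights(mu: np.ndarray, mode: str = "normalised") -> np.ndarray:
    """Turn validities into fusion weights.

    ``unnormalised`` uses mu directly (for N > 2 the fused output is then
    scaled by up to N - 1); ``normalised`` (default) divides by the sum so
    the combination is convex; ``switching`` puts all weight on the most
    valid sub-model (ties broken toward the lowest id).
    """
    mu = np.asarray(mu, dtype=float)
    if mode not in FUSION_MODES:
        raise ValueError(f"unknown fusion mode {mode!r}")
    if mode == "unnormalised":
        return mu.copy()
    if mode == "switching":
        w = np.zeros_like(mu)
        best = np.argmax(mu, axis=0)
        np.put_along_axis(w, best[None, ...], 1.0, axis=0)
        return w
    total = mu.sum(axis=0, keepdims=True)
    if np.any(total <= 0):
        raise ValueError("validities sum to zero; need N >= 2 sub-models")
    return mu / total


def fuse_outputs(F_ij: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Fused output per channel: F_m_j(k) = sum_i w[i,j,k] F_ij(k)."""
    if w.shape != F_ij.shape:
        raise ValueError("weights and sub-model outputs must share shape (N, J, K)")
    return np.einsum("ijk,ijk->jk", w, F_ij)


def estimate(
    library: ModelLibrary,
    emg: list[SignalTrace],
    references: list[SignalTrace] | list[np.ndarray],
    mode: str | None = None,
    tie_eps: float = 1e-12,
    smooth_window: int = 1,
) -> MultimodelOutput:
    """Run the full decision chain on preprocessed inputs.

    Chains run_submodels -> compute_residues -> normalize_residues ->
    compute_validities -> fusion_weights -> fuse_outputs per time step,
    dropping the library warm-up; returns the fused traces plus the full
    validity matrix for audit.
    """
    mode = mode or library.fusion_mode
    refs = [r.samples if isinstance(r, SignalTrace) else np.asarray(r, dtype=float)
            for r in references]
    if len(refs) != len(emg):
        raise ValueError("one reference trace per output channel required")
    F_full = run_submodels(library, emg)
    k0 = library.warmup
    F_ij = F_full[:, :, k0:]
    ref_arr = np.stack([r[k0:] for r in refs])

    err = compute_residues(F_ij, ref_arr, smooth_window=smooth_window)
    err_norm = normalize_residues(err, tie_eps=tie_eps)
    mu = compute_validities(err_norm)
    w = fusion_weights(mu, mode=mode)
    fused = fuse_outputs(F_ij, w)

    fs = emg[0].fs
    F_m = [SignalTrace(fused[j], fs=fs, label=f"F_m{j + 1}", kind="normalised")
           for j in range(fused.shape[0])]
    return MultimodelOutput(F_m=F_m,
                            validity=ValidityMatrix(err=err, err_norm=err_norm, mu=mu, w=w),
                            F_ij=F_ij, start=k0)
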