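"""Signal containers and the EMG/force preprocessing chain.

Raw surface EMG is a broadband interference signal (here band-limited to
20-500 Hz); its low-frequency amplitude envelope tracks contraction
intensity and is the feature that drives force estimation.  The chain
implemented here is the standard one for proportional myoelectric control:

    full-wave rectification
      -> low-pass Butterworth envelope (default order 6, 1 Hz cut-off)
      -> min-max normalisation to [0, 1]

Force traces run through the same rectify/smooth/normalise chain so that
model inputs and outputs live on a comparable dimensionless scale.
Filtering defaults to zero-phase (forward-backward) application, which is
appropriate for offline identification; a causal mode is available for
online use.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

__all__ = [
    "SignalTrace",
    "NormalizationParams",
    "FilterSpec",
    "rectify",
    "lowpass_envelope",
    "minmax_fit",
    "minmax_apply",
    "minmax_invert",
    "preprocess",
]

#: Allowed values of :attr:`SignalTrace.kind`.
KINDS = ("emg_raw", "emg_envelope", "force", "normalised")


@dataclass
class SignalTrace:
    """A uniformly sampled scalar time series.

    Parameters
    ----------
    samples
        Sample values.  Volts for raw EMG, newtons for force,
        dimensionless after normalisation.
    fs
        Sampling rate in Hz (must be positive).
    label
        Channel name, e.g. ``"emg_ecr"`` or ``"force"``.
    kind
        One of ``emg_raw``, ``emg_envelope``, ``force``, ``normalised``.
    """

    samples: np.ndarray
    fs: float
    label: str = ""
    kind: str = "emg_raw"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError(f"trace {self.label!r} contains non-finite samples")
        if not self.fs > 0:
            raise ValueError("sampling rate fs must be positive")
        if self.kind not in KINDS:
            raise ValueError(f"unknown trace kind {self.kind!r}")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Trace duration in seconds."""
        return self.samples.size / self.fs

    @property
    def time(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.samples.size) / self.fs

    def with_samples(self, samples: np.ndarray, kind: str | None = None) -> "SignalTrace":
        return replace(self, samples=np.asarray(samples, dtype=float),
                       kind=self.kind if kind is None else kind)


@dataclass(frozen=True)
class NormalizationParams:
    """Fitted min-max range d_min/d_max for one channel.

    Normalisation maps d_r -> (d_r - d_min) / (d_max - d_min); applying
    the parameters of the training data to validation data may produce
    values outside [0, 1], which are deliberately left unclipped so the
    mapping stays invertible.
    """

    d_min: float
    d_max: float
    source_label: str = ""

    def __post_init__(self) -> None:
        if not (np.isfinite(self.d_min) and np.isfinite(self.d_max)):
            raise ValueError("normalisation bounds must be finite")
        if not self.d_max > self.d_min:
            raise ValueError(
                f"degenerate range for {self.source_label!r}: "
                f"d_max ({self.d_max}) must exceed d_min ({self.d_min})"
            )

    @property
    def span(self) -> float:
        return self.d_max - self.d_min


@dataclass(frozen=True)
class FilterSpec:
    """Low-pass Butterworth envelope filter specification."""

    order: int = 6
    cutoff_hz: float = 1.0
    mode: str = "zero_phase"  # or "causal"

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("filter order must be a positive integer")
        if not self.cutoff_hz > 0:
            raise ValueError("cutoff_hz must be positive")
        if self.mode not in ("zero_phase", "causal"):
            raise ValueError(f"unknown filter mode {self.mode!r}")

    def sos(self, fs: float) -> np.ndarray:
        """Second-order-section coefficients for sampling rate *fs*."""
        if not self.cutoff_hz < fs / 2:
            raise ValueError(
                f"cutoff {self.cutoff_hz} Hz must lie below the Nyquist "
                f"frequency {fs / 2} Hz"
            )
        return sps.butter(self.order, self.cutoff_hz, btype="low", fs=fs, output="sos")


def rectify(trace: SignalTrace) -> SignalTrace:
    """Full-wave rectification: absolute value, sample by sample.

    Idempotent; preserves sampling rate, length and kind.
    """
    return trace.with_samples(np.abs(trace.samples))


def lowpass_envelope(trace: SignalTrace, spec: FilterSpec | None = None) -> SignalTrace:
    """Extract the amplitude envelope of a rectified trace by low-pass filtering.

    The default spec (Butterworth order 6, cut-off 1 Hz) keeps only the slow
    amplitude modulation of the rectified EMG.  Zero-phase mode filters
    forward and backward (no group delay, squared magnitude response);
    causal mode applies the filter once.

    Raises
    ------
    ValueError
        If the cut-off is at or above Nyquist, or the trace is shorter than
        the filter warm-up (padding) length.
    """
    spec = spec or FilterSpec()
    sos = spec.sos(trace.fs)
    if spec.mode == "zero_phase":
        padlen = 3 * (2 * sos.shape[0] + 1)
        if len(trace) <= padlen:
            raise ValueError(
                f"trace of length {len(trace)} is shorter than the filter "
                f"warm-up length {padlen + 1}"
            )
        y = sps.sosfiltfilt(sos, trace.samples)
    else:
        if len(trace) <= 3 * spec.order:
            raise ValueError("trace shorter than filter warm-up length")
        y = sps.sosfilt(sos, trace.samples)
    kind = "emg_envelope" if trace.kind in ("emg_raw", "emg_envelope") else trace.kind
    return trace.with_samples(y, kind=kind)


def minmax_fit(trace: SignalTrace) -> NormalizationParams:
    """Fit min-max normalisation parameters on a (training) trace."""
    if len(trace) < 2:
        raise ValueError("need at least two samples to fit a range")
    return NormalizationParams(
        d_min=float(np.min(trace.samples)),
        d_max=float(np.max(trace.samples)),
        source_label=trace.label,
    )


def minmax_apply(trace: SignalTrace, params: NormalizationParams) -> SignalTrace:
    """Map samples through d_n = (d_r - d_min) / (d_max - d_min).

    Values outside the fitted range map outside [0, 1] and are not clipped.
    """
    y = (trace.samples - params.d_min) / params.span
    return trace.with_samples(y, kind="normalised")


def minmax_invert(trace: SignalTrace, params: NormalizationParams) -> SignalTrace:
    """Exact inverse of :func:`minmax_apply`."""
    y = trace.samples * params.span + params.d_min
    kind = "force" if "force" in (params.source_label or "") else "emg_envelope"
    return trace.with_samples(y, kind=kind)


def preprocess(
    emg: list[SignalTrace],
    force: list[SignalTrace],
    spec: FilterSpec | None = None,
    params: list[NormalizationParams] | None = None,
) -> tuple[list[SignalTrace], list[SignalTrace], list[NormalizationParams]]:
    """Run the full chain rectify -> envelope -> min-max on each channel.

    Channels are processed independently and never mixed.  When *params* is
    given (one entry per channel, EMG channels first, then force channels)
    the stored training ranges are re-applied instead of fitting new ones —
    this is how validation trials are normalised without information leakage.

    Returns the processed EMG traces, processed force traces, and the
    normalisation parameters in channel order (EMG first, force after).
    """
    spec = spec or FilterSpec()
    traces = list(emg) + list(force)
    if not traces:
        raise ValueError("no traces to preprocess")
    fs0, n0 = traces[0].fs, len(traces[0])
    for t in traces:
        if t.fs != fs0 or len(t) != n0:
            raise ValueError("all traces must share sampling rate and length")
    if params is not None and len(params) != len(traces):
        raise ValueError("one NormalizationParams per channel required")

    out: list[SignalTrace] = []
    fitted: list[NormalizationParams] = []
    for i, t in enumerate(traces):
        env = lowpass_envelope(rectify(t), spec)
        p = params[i] if params is not None else minmax_fit(env)
        out.append(minmax_apply(env, p))
        fitted.append(p)
    n_emg = len(emg)
    return out[:n_emg], out[n_emg:], fitted
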