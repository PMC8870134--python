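"""Hammerstein-Wiener sub-models: structure, simulation and identification.

A Hammerstein-Wiener (H-W) model is the serial association

    u --(static nonlinearity f)--> v --(linear dynamic block)--> x
      --(static nonlinearity h)--> y

The linear block is a discrete transfer function B(q)/F(q) with input delay
nk.  With both nonlinearities frozen the intermediate regression is linear
in the (b, f) coefficients, so they are estimated by recursive least
squares (RLS); the nonlinearity node values are then refit by ordinary
least squares, and the two stages alternate.  This keeps RLS as the core
estimator while making the (jointly non-convex) H-W problem well posed.

The scale ambiguity between the blocks (any gain can be moved from the
input nonlinearity into the linear block) is resolved by constraining the
input nonlinearity to pass through (0, 0) with unit mean slope.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .signals import SignalTrace

__all__ = [
    "StaticNonlinearity",
    "LinearBlock",
    "HWModel",
    "HWConfig",
    "RLSState",
    "UnstableModelWarning",
    "simulate_hw",
    "build_regressor",
    "rls_init",
    "rls_update",
    "identify_hw",
    "prediction_error",
]


class UnstableModelWarning(UserWarning):
    """Raised when a linear block with poles on/outside the unit circle is simulated."""


# ---------------------------------------------------------------------------
# model structure
# ---------------------------------------------------------------------------

@dataclass
class StaticNonlinearity:
    """Memoryless nonlinearity: piecewise-linear, polynomial, or identity.

    Piecewise-linear maps are defined by strictly increasing ``breakpoints``
    and free node ``values``; evaluation interpolates linearly between nodes
    and extrapolates linearly beyond the end nodes.  Polynomial maps store
    ascending-power ``coefficients``.
    """

    family: str = "identity"
    breakpoints: np.ndarray | None = None
    values: np.ndarray | None = None
    coefficients: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.family == "piecewise_linear":
            self.breakpoints = np.asarray(self.breakpoints, dtype=float)
            self.values = np.asarray(self.values, dtype=float)
            if self.breakpoints.size < 2:
                raise ValueError("piecewise_linear needs at least two breakpoints")
            if np.any(np.diff(self.breakpoints) <= 0):
                raise ValueError("breakpoints must be strictly increasing")
            if self.values.shape != self.breakpoints.shape:
                raise ValueError("one node value per breakpoint required")
        elif self.family == "polynomial":
            self.coefficients = np.asarray(self.coefficients, dtype=float)
            if self.coefficients.size < 2:
                raise ValueError("polynomial degree must be >= 1")
        elif self.family != "identity":
            raise ValueError(f"unknown nonlinearity family {self.family!r}")

    @property
    def n_params(self) -> int:
        if self.family == "piecewise_linear":
            return int(self.values.size)
        if self.family == "polynomial":
            return int(self.coefficients.size)
        return 0

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.family == "identity":
            return x
        if self.family == "polynomial":
            return np.polyval(self.coefficients[::-1], x)
        bp, val = self.breakpoints, self.values
        y = np.interp(x, bp, val)
        # linear extrapolation outside the node range
        lo = x < bp[0]
        if np.any(lo):
            s = (val[1] - val[0]) / (bp[1] - bp[0])
            y = np.where(lo, val[0] + s * (x - bp[0]), y)
        hi = x > bp[-1]
        if np.any(hi):
            s = (val[-1] - val[-2]) / (bp[-1] - bp[-2])
            y = np.where(hi, val[-1] + s * (x - bp[-1]), y)
        return y

    def inverse(self, y: np.ndarray) -> np.ndarray:
        """Inverse map, available for identity and monotone piecewise-linear."""
        y = np.asarray(y, dtype=float)
        if self.family == "identity":
            return y
        if self.family != "piecewise_linear":
            raise ValueError("inverse only defined for identity / piecewise_linear")
        val, bp = self.values, self.breakpoints
        if np.any(np.diff(val) <= 0):
            raise ValueError("inverse requires strictly increasing node values")
        x = np.interp(y, val, bp)
        lo = y < val[0]
        if np.any(lo):
            s = (bp[1] - bp[0]) / (val[1] - val[0])
            x = np.where(lo, bp[0] + s * (y - val[0]), x)
        hi = y > val[-1]
        if np.any(hi):
            s = (bp[-1] - bp[-2]) / (val[-1] - val[-2])
            x = np.where(hi, bp[-1] + s * (y - val[-1]), x)
        return x

    def params(self) -> np.ndarray:
        if self.family == "piecewise_linear":
            return self.values.copy()
        if self.family == "polynomial":
            return self.coefficients.copy()
        return np.empty(0)

    def with_params(self, p: np.ndarray) -> "StaticNonlinearity":
        if self.family == "piecewise_linear":
            return replace(self, values=np.asarray(p, dtype=float))
        if self.family == "polynomial":
            return replace(self, coefficients=np.asarray(p, dtype=float))
        return self

    @staticmethod
    def identity() -> "StaticNonlinearity":
        return StaticNonlinearity(family="identity")


@dataclass
class LinearBlock:
    """Discrete linear dynamic block y = q^{-nk} B(q)/F(q) u.

    ``b`` holds the nb numerator coefficients, ``f`` the nf free denominator
    coefficients of the monic polynomial 1 + f1 q^-1 + ... + f_nf q^-nf,
    and ``nk`` the input delay in samples.
    """

    b: np.ndarray
    f: np.ndarray
    nk: int = 0

    def __post_init__(self) -> None:
        self.b = np.atleast_1d(np.asarray(self.b, dtype=float))
        self.f = np.atleast_1d(np.asarray(self.f, dtype=float)) if np.size(self.f) else np.empty(0)
        if self.b.size < 1:
            raise ValueError("nb must be >= 1")
        if self.nk < 0:
            raise ValueError("nk must be >= 0")

    @property
    def nb(self) -> int:
        return self.b.size

    @property
    def nf(self) -> int:
        return self.f.size

    def is_stable(self) -> bool:
        if self.nf == 0:
            return True
        poles = np.roots(np.concatenate(([1.0], self.f)))
        return bool(np.all(np.abs(poles) < 1.0))

    def simulate(self, v: np.ndarray) -> np.ndarray:
        """Zero-initial-condition simulation of the block."""
        from scipy.signal import lfilter

        num = np.concatenate((np.zeros(self.nk), self.b))
        den = np.concatenate(([1.0], self.f))
        return lfilter(num, den, np.asarray(v, dtype=float))


@dataclass
class HWModel:
    """A complete Hammerstein-Wiener model with its flat parameter vector view."""

    input_nl: StaticNonlinearity
    linear: LinearBlock
    output_nl: StaticNonlinearity
    converged: bool = True
    theta_trajectory: np.ndarray | None = None  # RLS estimates over time (n, nb+nf)

    @property
    def orders(self) -> dict:
        return {
            "nb": self.linear.nb,
            "nf": self.linear.nf,
            "nk": self.linear.nk,
            "n_input_nl": self.input_nl.n_params,
            "n_output_nl": self.output_nl.n_params,
        }

    @property
    def warmup(self) -> int:
        """Samples affected by zero initial conditions; excluded from error metrics."""
        return max(self.linear.nb + self.linear.nk, self.linear.nf)

    # -- flat parameter vector ---------------------------------------------
    @property
    def theta(self) -> np.ndarray:
        return np.concatenate(
            [self.input_nl.params(), self.linear.b, self.linear.f, self.output_nl.params()]
        )

    def with_theta(self, theta: np.ndarray) -> "HWModel":
        theta = np.asarray(theta, dtype=float)
        if theta.size != self.theta.size:
            raise ValueError("theta length does not match model orders")
        n_in = self.input_nl.n_params
        nb, nf = self.linear.nb, self.linear.nf
        i = 0
        input_nl = self.input_nl.with_params(theta[i:i + n_in]); i += n_in
        b = theta[i:i + nb]; i += nb
        f = theta[i:i + nf]; i += nf
        output_nl = self.output_nl.with_params(theta[i:])
        return replace(self, input_nl=input_nl,
                       linear=LinearBlock(b=b, f=f, nk=self.linear.nk),
                       output_nl=output_nl)

    # -- serialisation ------------------------------------------------------
    def to_dict(self) -> dict:
        def nl_dict(nl: StaticNonlinearity) -> dict:
            d: dict = {"family": nl.family}
            if nl.family == "piecewise_linear":
                d["breakpoints"] = nl.breakpoints.tolist()
                d["values"] = nl.values.tolist()
            elif nl.family == "polynomial":
                d["coefficients"] = nl.coefficients.tolist()
            return d

        traj = self.theta_trajectory
        return {
            "input_nl": nl_dict(self.input_nl),
            "linear": {"b": self.linear.b.tolist(), "f": self.linear.f.tolist(),
                       "nk": self.linear.nk},
            "output_nl": nl_dict(self.output_nl),
            "converged": bool(self.converged),
            "theta_trajectory": None if traj is None else traj.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HWModel":
        def nl(dd: dict) -> StaticNonlinearity:
            return StaticNonlinearity(
                family=dd["family"],
                breakpoints=dd.get("breakpoints"),
                values=dd.get("values"),
                coefficients=dd.get("coefficients"),
            )

        traj = d.get("theta_trajectory")
        return cls(
            input_nl=nl(d["input_nl"]),
            linear=LinearBlock(b=d["linear"]["b"], f=d["linear"]["f"], nk=d["linear"]["nk"]),
            output_nl=nl(d["output_nl"]),
            converged=d.get("converged", True),
            theta_trajectory=None if traj is None else np.asarray(traj, dtype=float),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "HWModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class HWConfig:
    """Identification settings.

    Defaults: nb=2, nf=2, nk=1 linear orders; piecewise-linear blocks with
    10 uniformly spaced breakpoints over the observed signal range; 10 outer
    alternating iterations with tolerance 1e-6; RLS prior P0 = p0_scale * I.
    """

    nb: int = 2
    nf: int = 2
    nk: int = 1
    input_family: str = "piecewise_linear"
    output_family: str = "piecewise_linear"
    n_breakpoints: int = 10
    poly_degree: int = 3
    outer_iters: int = 10
    tol: float = 1e-6
    p0_scale: float = 1e4
    conv_tol: float = 1e-2

    def to_dict(self) -> dict:
        return dict(self.__dict__)


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def simulate_hw(model: HWModel, u: SignalTrace | np.ndarray) -> SignalTrace | np.ndarray:
    """Noise-free simulation y(k) = h( linear( f(u(k)) ) ), zero initial state.

    Accepts a :class:`SignalTrace` (returned as a trace) or a plain array.
    Warns (does not raise) if the linear block is unstable; raises on NaN.
    """
    is_trace = isinstance(u, SignalTrace)
    x = u.samples if is_trace else np.asarray(u, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("simulation input contains non-finite samples")
    if not model.linear.is_stable():
        warnings.warn("linear block has poles on/outside the unit circle; "
                      "simulation may diverge", UnstableModelWarning)
    y = model.output_nl(model.linear.simulate(model.input_nl(x)))
    if not np.all(np.isfinite(y)):
        raise ValueError("simulation produced non-finite output (unstable model?)")
    if is_trace:
        return u.with_samples(y, kind=u.kind)
    return y


def prediction_error(model: HWModel, u: SignalTrace, y: SignalTrace) -> SignalTrace:
    """Simulation error eps(k) = y(k) - yhat(k) for k past the model warm-up."""
    yhat = simulate_hw(model, u)
    k0 = model.warmup
    eps = y.samples[k0:] - np.asarray(yhat.samples)[k0:]
    return SignalTrace(eps, fs=y.fs, label=f"eps_{y.label}", kind=y.kind)


# ---------------------------------------------------------------------------
# recursive least squares
# ---------------------------------------------------------------------------

@dataclass
class RLSState:
    """RLS estimator state: parameter estimate, adaptation matrix, innovation."""

    theta_hat: np.ndarray
    P: np.ndarray
    eps: float = 0.0
    k: int = 0


def rls_init(p: int, p0_scale: float = 1e4) -> RLSState:
    """Fresh RLS state: zero estimate, P = p0_scale * I (a diffuse prior)."""
    if p < 1:
        raise ValueError("parameter count must be >= 1")
    if not p0_scale > 0:
        raise ValueError("p0_scale must be positive")
    return RLSState(theta_hat=np.zeros(p), P=np.eye(p) * p0_scale)


def rls_update(state: RLSState, phi: np.ndarray, y: float) -> RLSState:
    """One RLS step (no forgetting).

    The innovation is eps(k) = y(k) - theta_hat(k-1)' phi(k); the adaptation
    matrix update is P(k) = P(k-1) - P phi phi' P / (1 + phi' P phi); the
    estimate update uses the gain form theta_hat(k) = theta_hat(k-1)
    + P(k) phi eps(k).  P is re-symmetrised each step to keep it positive
    definite under round-off.
    """
    phi = np.asarray(phi, dtype=float)
    if not (np.all(np.isfinite(phi)) and np.isfinite(y)):
        raise ValueError("non-finite regressor or output in RLS update")
    P = state.P
    Pphi = P @ phi
    denom = 1.0 + phi @ Pphi
    P_new = P - np.outer(Pphi, Pphi) / denom
    P_new = 0.5 * (P_new + P_new.T)
    eps = y - state.theta_hat @ phi
    theta = state.theta_hat + P_new @ phi * eps
    return RLSState(theta_hat=theta, P=P_new, eps=float(eps), k=state.k + 1)


def build_regressor(
    u_transformed: SignalTrace | np.ndarray,
    y: SignalTrace | np.ndarray,
    k: int,
    orders: tuple[int, int, int],
) -> np.ndarray:
    """Regression vector phi(k) of lagged transformed inputs and outputs.

    phi = [u_t(k-nk), ..., u_t(k-nk-nb+1), -y(k-1), ..., -y(k-nf)]
    for orders (nb, nf, nk); 0-based time indexing.
    """
    nb, nf, nk = orders
    ut = u_transformed.samples if isinstance(u_transformed, SignalTrace) else np.asarray(u_transformed)
    ys = y.samples if isinstance(y, SignalTrace) else np.asarray(y)
    k0 = max(nb - 1 + nk, nf)
    if k < k0:
        raise ValueError(f"k={k} is below the warm-up index {k0}")
    phi = np.empty(nb + nf)
    phi[:nb] = ut[k - nk - nb + 1: k - nk + 1][::-1]
    if nf:
        phi[nb:] = -ys[k - nf: k][::-1]
    return phi


def _rls_pass_numpy(v: np.ndarray, z: np.ndarray, nb: int, nf: int, nk: int,
                    p0_scale: float) -> tuple[np.ndarray, np.ndarray]:
    """Run RLS over a whole record; returns (theta_hat, trajectory).

    Same update equations as :func:`rls_update`, written as a tight loop.
    """
    p = nb + nf
    k0 = max(nb - 1 + nk, nf)
    n = v.size
    theta = np.zeros(p)
    P = np.eye(p) * p0_scale
    traj = np.empty((n - k0, p))
    phi = np.empty(p)
    for i, k in enumerate(range(k0, n)):
        phi[:nb] = v[k - nk - nb + 1: k - nk + 1][::-1]
        if nf:
            phi[nb:] = -z[k - nf: k][::-1]
        Pphi = P @ phi
        P -= np.outer(Pphi, Pphi) / (1.0 + phi @ Pphi)
        P = 0.5 * (P + P.T)
        eps = z[k] - theta @ phi
        theta = theta + (P @ phi) * eps
        traj[i] = theta
    return theta, traj


try:  # optional compiled kernel: identical arithmetic, much faster on long records
    from numba import njit as _njit

    @_njit(cache=True)
    def _rls_pass_jit(v, z, nb, nf, nk, p0_scale):  # pragma: no cover - numeric twin
        p = nb + nf
        k0 = max(nb - 1 + nk, nf)
        n = v.size
        theta = np.zeros(p)
        P = np.eye(p) * p0_scale
        traj = np.empty((n - k0, p))
        phi = np.empty(p)
        Pphi = np.empty(p)
        for i in range(n - k0):
            k = k0 + i
            for j in range(nb):
                phi[j] = v[k - nk - j]
            for m in range(nf):
                phi[nb + m] = -z[k - 1 - m]
            denom = 1.0
            for a in range(p):
                s = 0.0
                for c in range(p):
                    s += P[a, c] * phi[c]
                Pphi[a] = s
                denom += phi[a] * s
            for a in range(p):
                for c in range(p):
                    P[a, c] -= Pphi[a] * Pphi[c] / denom
            for a in range(p):
                for c in range(a + 1, p):
                    m2 = 0.5 * (P[a, c] + P[c, a])
                    P[a, c] = m2
                    P[c, a] = m2
            eps = z[k]
            for a in range(p):
                eps -= theta[a] * phi[a]
            for a in range(p):
                s = 0.0
                for c in range(p):
                    s += P[a, c] * phi[c]
                theta[a] += s * eps
            traj[i] = theta
        return theta, traj

    def _rls_pass(v, z, nb, nf, nk, p0_scale):
        return _rls_pass_jit(np.ascontiguousarray(v, dtype=np.float64),
                             np.ascontiguousarray(z, dtype=np.float64),
                             nb, nf, nk, float(p0_scale))
except ImportError:  # pragma: no cover
    _rls_pass = _rls_pass_numpy


# ---------------------------------------------------------------------------
# identification
# ---------------------------------------------------------------------------

def _init_nl(family: str, samples: np.ndarray, config: HWConfig) -> StaticNonlinearity:
    if family == "identity":
        return StaticNonlinearity.identity()
    if family == "polynomial":
        coeffs = np.zeros(config.poly_degree + 1)
        coeffs[1] = 1.0  # start at identity
        return StaticNonlinearity(family="polynomial", coefficients=coeffs)
    lo, hi = float(np.min(samples)), float(np.max(samples))
    if hi - lo <= 0:
        raise ValueError("cannot place breakpoints on a constant signal")
    bp = np.linspace(lo, hi, config.n_breakpoints)
    return StaticNonlinearity(family="piecewise_linear", breakpoints=bp, values=bp.copy())


def _pwl_basis(x: np.ndarray, bp: np.ndarray) -> np.ndarray:
    """Hat-function design matrix: column l is the weight of node l at each x."""
    xc = np.clip(x, bp[0], bp[-1])
    B = np.zeros((x.size, bp.size))
    idx = np.clip(np.searchsorted(bp, xc, side="right") - 1, 0, bp.size - 2)
    t = (xc - bp[idx]) / (bp[idx + 1] - bp[idx])
    rows = np.arange(x.size)
    B[rows, idx] = 1.0 - t
    B[rows, idx + 1] = t
    return B


def _normalise_input_nl(nl: StaticNonlinearity, b: np.ndarray) -> tuple[StaticNonlinearity, np.ndarray]:
    """Anchor the input nonlinearity at (0,0) with unit mean slope; move the
    scale into the numerator coefficients b."""
    if nl.family == "identity":
        return nl, b
    if nl.family == "piecewise_linear":
        bp, val = nl.breakpoints, nl.values
        s = (val[-1] - val[0]) / (bp[-1] - bp[0])
        if abs(s) < 1e-12:
            return nl, b
        offset = float(nl(np.array([0.0]))[0]) if bp[0] <= 0 <= bp[-1] else val[0]
        new = replace(nl, values=(val - offset) / s)
        return new, b * s
    # polynomial: zero constant term (passes through 0); mean slope over [0,1]
    # is the integral of the derivative, i.e. f(1) - f(0)
    c = nl.coefficients.copy()
    c[0] = 0.0
    s = float(np.polyval(c[::-1], 1.0) - np.polyval(c[::-1], 0.0))
    if abs(s) < 1e-12:
        return replace(nl, coefficients=c), b
    return replace(nl, coefficients=c / s), b * s


def _monotone_project(values: np.ndarray, bp: np.ndarray,
                      slope_floor: float = 0.05) -> np.ndarray:
    """Project node values onto the increasing cone (PAVA), then enforce a
    minimum slope of ``slope_floor`` times the mean slope so the map stays
    strictly increasing and its inverse well conditioned."""
    from sklearn.isotonic import IsotonicRegression

    iso = IsotonicRegression(increasing=True)
    v = iso.fit_transform(bp, values)
    span = v[-1] - v[0]
    if span <= 0:
        span = max(float(np.ptp(values)), 1.0)
    mean_slope = span / (bp[-1] - bp[0])
    min_inc = slope_floor * mean_slope * np.diff(bp)
    out = v.copy()
    for i in range(1, out.size):
        out[i] = max(out[i], out[i - 1] + min_inc[i - 1])
    return out


def _stabilise(f: np.ndarray, radius: float = 0.98) -> np.ndarray:
    """Shrink the poles of the monic denominator [1, f...] inside the unit
    circle if the RLS estimate came out unstable (noise can push it there)."""
    if f.size == 0:
        return f
    poles = np.roots(np.concatenate(([1.0], f)))
    max_mod = np.max(np.abs(poles))
    if max_mod < 1.0:
        return f
    poles = poles * (radius / max_mod)
    return np.real(np.poly(poles))[1:]


def identify_hw(u: SignalTrace, y: SignalTrace, config: HWConfig | None = None) -> HWModel:
    """Identify a Hammerstein-Wiener model from an input/output record.

    Alternating scheme: with the nonlinearity shapes frozen, the
    intermediate ARX regression z(k) = sum_j b_j v(k-nk-j) - sum_m f_m z(k-m)
    (v the transformed input, z the output mapped through the inverse output
    nonlinearity) is linear in (b, f) and estimated by RLS over the whole
    record; the input-nonlinearity node values are then refit by linear
    least squares, the input block renormalised to unit mean slope through
    (0, 0), and the output-nonlinearity nodes refit against the simulated
    intermediate signal (with a monotone projection so it stays invertible).
    Outer iterations stop when the flat parameter vector changes by less
    than ``tol`` (relative).

    The convergence flag reports whether the RLS estimate settled, i.e.
    changed by less than ``conv_tol`` (relative) over the last 10% of the
    record on the final pass.
    """
    config = config or HWConfig()
    us = np.asarray(u.samples, dtype=float)
    ys = np.asarray(y.samples, dtype=float)
    nb, nf, nk = config.nb, config.nf, config.nk
    p_lin = nb + nf
    if us.size != ys.size:
        raise ValueError("input and output records must have equal length")
    if np.ptp(us) <= 0:
        raise ValueError("constant (degenerate) input: nothing to identify")
    if us.size < 10 * p_lin:
        raise ValueError(f"need at least {10 * p_lin} samples for orders "
                         f"nb={nb}, nf={nf}")

    input_nl = _init_nl(config.input_family, us, config)
    output_nl = _init_nl(config.output_family, ys, config)
    if config.output_family == "piecewise_linear":
        output_nl = replace(output_nl, values=_monotone_project(output_nl.values,
                                                                output_nl.breakpoints))
    b = np.ones(nb) / nb
    f = np.zeros(nf)
    k0 = max(nb - 1 + nk, nf)
    theta_prev: np.ndarray | None = None
    traj = np.empty((0, p_lin))
    best: tuple[float, HWModel] | None = None

    for _ in range(config.outer_iters):
        # ---- stage A: RLS on the linear-in-parameters ARX stage ----------
        v = input_nl(us)
        z = output_nl.inverse(ys)
        if not (np.all(np.isfinite(v)) and np.all(np.isfinite(z))):
            break  # a refit went degenerate; keep the best iterate so far
        theta_lin, traj_new = _rls_pass(v, z, nb, nf, nk, config.p0_scale)
        if not np.all(np.isfinite(theta_lin)):
            break
        traj = traj_new
        b, f = theta_lin[:nb].copy(), _stabilise(theta_lin[nb:].copy())

        # ---- stage B: refit input nonlinearity nodes by least squares ---
        if input_nl.family in ("piecewise_linear", "polynomial"):
            if input_nl.family == "piecewise_linear":
                B = _pwl_basis(us, input_nl.breakpoints)
            else:
                B = np.vander(us, config.poly_degree + 1, increasing=True)
            # target: z(k) + sum_m f_m z(k-m); design: sum_j b_j B[k-nk-j]
            n = us.size
            t = z[k0:].copy()
            for m in range(1, nf + 1):
                t += f[m - 1] * z[k0 - m: n - m]
            M = np.zeros((n - k0, B.shape[1]))
            for j in range(nb):
                M += b[j] * B[k0 - nk - j: n - nk - j]
            c, *_ = np.linalg.lstsq(M, t, rcond=None)
            if np.all(np.isfinite(c)):  # keep previous nodes on a failed fit
                input_nl = input_nl.with_params(c)
                input_nl, b = _normalise_input_nl(input_nl, b)

        linear = LinearBlock(b=b, f=f, nk=nk)

        # ---- stage C: refit output nonlinearity against simulated x ------
        x = linear.simulate(input_nl(us))
        if not np.all(np.isfinite(x)):
            break
        if output_nl.family == "piecewise_linear":
            lo, hi = float(np.min(x[k0:])), float(np.max(x[k0:]))
            if hi - lo > 0:
                bp_out = np.linspace(lo, hi, config.n_breakpoints)
                Bx = _pwl_basis(x[k0:], bp_out)
                val, *_ = np.linalg.lstsq(Bx, ys[k0:], rcond=None)
                if np.all(np.isfinite(val)):
                    val = _monotone_project(val, bp_out)
                    output_nl = StaticNonlinearity(family="piecewise_linear",
                                                   breakpoints=bp_out, values=val)

        model = HWModel(input_nl=input_nl, linear=linear, output_nl=output_nl)
        # the alternation is not guaranteed monotone; keep the best iterate
        # by training simulation error
        sim = model.output_nl(x)
        if not np.all(np.isfinite(sim)):
            break
        sse = float(np.sum((ys[k0:] - sim[k0:]) ** 2))
        if best is None or sse < best[0]:
            best = (sse, model)
        theta = model.theta
        if theta_prev is not None and theta.size == theta_prev.size:
            if np.linalg.norm(theta - theta_prev) <= config.tol * (1.0 + np.linalg.norm(theta)):
                break
        theta_prev = theta

    # convergence: RLS estimate settled over the last 10% of the record
    if traj.shape[0] < 2:
        converged = False
    else:
        tail = max(2, traj.shape[0] // 10)
        tail_traj = traj[-tail:]
        spread = np.max(np.abs(tail_traj - tail_traj[-1]), axis=0)
        scale = np.abs(tail_traj[-1]) + 1e-12
        converged = bool(np.all(spread / scale < config.conv_tol) or
                         np.all(spread < config.conv_tol))

    result = best[1] if best is not None else HWModel(
        input_nl=input_nl, linear=LinearBlock(b=b, f=f, nk=nk), output_nl=output_nl)
    return replace(result, converged=converged,
                   theta_trajectory=traj[:: max(1, traj.shape[0] // 1000)].copy())
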