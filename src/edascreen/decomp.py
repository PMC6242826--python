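"""Convex tonic/phasic decomposition of electrodermal activity.

Skin conductance is modelled as the sum of three parts: a slowly varying
tonic level (skin conductance level, SCL), a phasic component equal to a
biexponential response kernel convolved with a sparse, nonnegative sudomotor
driver (skin conductance responses, SCRs), and residual noise.  The
decomposition is posed as a convex quadratic program

    minimize   1/2 ||y - h*q - B c - D d||^2  +  alpha * sum(q)
               + gamma/2 * ||c||^2
    subject to q >= 0

over the driver ``q``, cubic B-spline coefficients ``c`` of the tonic curve
and an unpenalised affine drift ``d`` (offset + slope).  The l1 term on the
nonnegative driver induces sparsity; the ridge term keeps the spline from
absorbing phasic activity.

The program is smooth on the feasible set, so it is solved with a
bound-constrained quasi-Newton method (L-BFGS-B) using analytic gradients
and FFT-based convolution operators; no external QP solver is required.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import interpolate, optimize, signal


class SolverError(RuntimeError):
    """Raised when the decomposition QP fails to reach the requested tolerance."""

    def __init__(self, message: str, objective: float, grad_norm: float):
        super().__init__(f"{message} (objective={objective:.6g}, |grad|={grad_norm:.3g})")
        self.objective = objective
        self.grad_norm = grad_norm


@dataclass(frozen=True)
class DecompositionConfig:
    """Parameters of the convex decomposition.

    alpha : float
        Weight of the l1 sparsity penalty on the sudomotor driver.
    gamma : float
        Weight of the ridge penalty on the tonic spline coefficients.
    tau1_s, tau2_s : float
        Time constants of the biexponential SCR kernel, seconds.  The
        smaller of the two acts as the rise constant, the larger as the
        decay constant.
    knot_spacing_s : float
        Spacing of the cubic B-spline knots of the tonic curve, seconds.
    kernel_support_s : float
        Truncation length of the discretised SCR kernel, seconds.
    solver_tolerance : float
        Projected-gradient sup-norm at which the solver is considered
        converged.
    max_iter : int
        Iteration cap of the quasi-Newton solver.
    """

    alpha: float = 0.008
    gamma: float = 0.01
    tau1_s: float = 0.7
    tau2_s: float = 2.0
    knot_spacing_s: float = 10.0
    kernel_support_s: float = 12.0
    solver_tolerance: float = 1e-7
    max_iter: int = 20000

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.gamma <= 0:
            raise ValueError("alpha and gamma must be > 0")
        if self.tau1_s == self.tau2_s:
            raise ValueError("tau1_s and tau2_s must differ")
        if self.knot_spacing_s <= 0:
            raise ValueError("knot_spacing_s must be > 0")


@dataclass
class DecompositionResult:
    """Decomposition of one conductance series.

    ``tonic + phasic + residual`` reproduces the input sample-for-sample;
    ``phasic`` is the kernel convolved with the nonnegative ``driver``.
    """

    tonic: np.ndarray
    phasic: np.ndarray
    driver: np.ndarray
    residual: np.ndarray
    objective_value: float
    rate_hz: float
    config: DecompositionConfig = field(repr=False, default=DecompositionConfig())

    @property
    def reconstruction(self) -> np.ndarray:
        return self.tonic + self.phasic + self.residual


def biexponential_kernel(
    tau1_s: float, tau2_s: float, rate_hz: float, support_s: float = 12.0
) -> np.ndarray:
    """Discretised biexponential SCR kernel, normalised to unit peak.

    h(t) = exp(-t/tau_decay) - exp(-t/tau_rise) on [0, support_s), with
    tau_rise = min(tau1, tau2) and tau_decay = max(tau1, tau2).  h(0) = 0,
    and the kernel is nonnegative and unimodal with its maximum at
    t* = tau_r*tau_d/(tau_d-tau_r) * ln(tau_d/tau_r).
    """
    if tau1_s == tau2_s:
        raise ValueError("kernel time constants must differ (tau1_s == tau2_s)")
    if tau1_s <= 0 or tau2_s <= 0:
        raise ValueError("kernel time constants must be > 0")
    tau_r, tau_d = sorted((tau1_s, tau2_s))
    t = np.arange(0.0, support_s, 1.0 / rate_hz)
    h = np.exp(-t / tau_d) - np.exp(-t / tau_r)
    peak = h.max()
    if peak <= 0:
        raise ValueError("kernel support too short to contain the peak")
    return h / peak


def kernel_peak_time(tau1_s: float, tau2_s: float) -> float:
    """Continuous-time location of the kernel maximum, seconds."""
    tau_r, tau_d = sorted((tau1_s, tau2_s))
    return tau_r * tau_d / (tau_d - tau_r) * np.log(tau_d / tau_r)


def tonic_basis(n_samples: int, rate_hz: float, knot_spacing_s: float):
    """Cubic B-spline design matrix (sparse CSR) and affine drift columns.

    Knots are clamped and evenly spaced by ``knot_spacing_s`` over the
    record; the affine block carries an intercept and a unit-slope term in
    normalised time so the spline penalty does not fight slow linear drift.
    """
    duration = n_samples / rate_hz
    if duration < 2 * knot_spacing_s:
        raise ValueError(
            f"signal of {duration:.1f}s is shorter than twice the knot spacing "
            f"({knot_spacing_s:.1f}s)"
        )
    t = np.arange(n_samples) / rate_hz
    base = np.linspace(0.0, duration, int(np.ceil(duration / knot_spacing_s)) + 1)
    knots = np.r_[[base[0]] * 3, base, [base[-1]] * 3]
    # design_matrix requires x strictly inside the base interval for the last point
    x = np.clip(t, base[0], base[-1] - 1e-12)
    B = interpolate.BSpline.design_matrix(x, knots, 3).tocsr()
    D = np.column_stack([np.ones(n_samples), t / duration])
    return B, D


def _convolve(q: np.ndarray, h: np.ndarray) -> np.ndarray:
    n = q.shape[0]
    if h.shape[0] >= 32:
        return signal.fftconvolve(q, h)[:n]
    return np.convolve(q, h)[:n]


def _correlate(r: np.ndarray, h: np.ndarray) -> np.ndarray:
    """Adjoint of the (truncated) convolution with h."""
    n = r.shape[0]
    m = h.shape[0]
    if m >= 32:
        full = signal.fftconvolve(r, h[::-1])
    else:
        full = np.convolve(r, h[::-1])
    return full[m - 1 : m - 1 + n]


def decompose(
    samples: np.ndarray,
    rate_hz: float,
    config: DecompositionConfig | None = None,
) -> DecompositionResult:
    """Split a cleaned conductance series into tonic, phasic and residual parts.

    Solves the convex program described in the module docstring and returns
    the decomposition at the input sampling rate.  Raises ``SolverError``
    when the quasi-Newton solver stops before reaching the projected-gradient
    tolerance, and ``ValueError`` on NaNs or signals shorter than twice the
    tonic knot spacing.
    """
    config = config or DecompositionConfig()
    y = np.asarray(samples, dtype=float)
    if y.ndim != 1:
        raise ValueError("samples must be a 1-D series")
    if np.isnan(y).any():
        raise ValueError("input contains NaNs; clean the recording first")

    n = y.shape[0]
    h = biexponential_kernel(config.tau1_s, config.tau2_s, rate_hz, config.kernel_support_s)
    B, D = tonic_basis(n, rate_hz, config.knot_spacing_s)
    nc = B.shape[1]
    alpha, gamma = config.alpha, config.gamma
    BT = B.T.tocsr()

    def objective(x: np.ndarray):
        q = x[:n]
        c = x[n : n + nc]
        d = x[n + nc :]
        phasic = _convolve(q, h)
        r = phasic + B @ c + D @ d - y
        f = 0.5 * float(r @ r) + alpha * float(q.sum()) + 0.5 * gamma * float(c @ c)
        gq = _correlate(r, h) + alpha
        gc = BT @ r + gamma * c
        gd = D.T @ r
        return f, np.concatenate([gq, gc, gd])

    # Warm start: ridge fit of the tonic basis alone (q = 0).
    A = np.column_stack([B.toarray(), D]) if n <= 4096 else None
    if A is not None:
        reg = np.zeros(nc + 2)
        reg[:nc] = gamma
        z = np.linalg.solve(A.T @ A + np.diag(reg), A.T @ y)
    else:
        Bd = B  # sparse normal equations for long records
        G = np.empty((nc + 2, nc + 2))
        G[:nc, :nc] = (BT @ Bd).toarray()
        BD = BT @ D
        G[:nc, nc:] = BD
        G[nc:, :nc] = BD.T
        G[nc:, nc:] = D.T @ D
        G[:nc, :nc] += gamma * np.eye(nc)
        rhs = np.concatenate([BT @ y, D.T @ y])
        z = np.linalg.solve(G, rhs)
    x0 = np.concatenate([np.zeros(n), z])

    bounds = [(0.0, None)] * n + [(None, None)] * (nc + 2)
    res = optimize.minimize(
        objective,
        x0,
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={
            "maxiter": config.max_iter,
            "maxfun": 2 * config.max_iter,
            "ftol": 1e-15,
            "gtol": config.solver_tolerance,
        },
    )
    f_final, g_final = objective(res.x)
    # projected gradient: at an active lower bound a positive gradient is fine
    gproj = g_final.copy()
    at_bound = np.zeros_like(res.x, dtype=bool)
    at_bound[:n] = res.x[:n] <= 0
    gproj[at_bound & (gproj > 0)] = 0.0
    pg_norm = float(np.abs(gproj).max())
    # L-BFGS-B may also stop on ftol; accept if the projected gradient is small
    # relative to the problem scale.
    scale = max(1.0, float(np.abs(y).max()))
    if not res.success and pg_norm > 1e-4 * scale:
        raise SolverError("decomposition solver did not converge", f_final, pg_norm)

    q = np.maximum(res.x[:n], 0.0)
    c = res.x[n : n + nc]
    d = res.x[n + nc :]
    phasic = _convolve(q, h)
    tonic = B @ c + D @ d
    residual = y - tonic - phasic
    return DecompositionResult(
        tonic=tonic,
        phasic=phasic,
        driver=q,
        residual=residual,
        objective_value=f_final,
        rate_hz=rate_hz,
        config=config,
    )


def decomposition_objective(
    y: np.ndarray,
    q: np.ndarray,
    c: np.ndarray,
    d: np.ndarray,
    rate_hz: float,
    config: DecompositionConfig,
) -> float:
    """Objective value of the decomposition QP at an arbitrary feasible point."""
    h = biexponential_kernel(config.tau1_s, config.tau2_s, rate_hz, config.kernel_support_s)
    B, D = tonic_basis(len(y), rate_hz, config.knot_spacing_s)
    r = _convolve(np.asarray(q, float), h) + B @ c + D @ d - y
    return (
        0.5 * float(r @ r)
        + config.alpha * float(np.sum(q))
        + 0.5 * config.gamma * float(np.dot(c, c))
    )


def detect_scr_peaks(
    phasic: np.ndarray,
    rate_hz: float,
    min_amp_uS: float = 0.05,
    min_separation_s: float = 1.0,
) -> list[tuple[float, float]]:
    """Detect skin conductance responses on the phasic component.

    A response is a local maximum whose rise from the preceding trough is at
    least ``min_amp_uS`` and that is separated from the previous maximum by
    at least ``min_separation_s``.  Returns ``(time_s, amplitude_uS)`` pairs
    in time order; an empty list is a valid result.
    """
    x = np.asarray(phasic, dtype=float)
    distance = max(1, int(round(min_separation_s * rate_hz)))
    peaks, _ = signal.find_peaks(x, distance=distance)
    events: list[tuple[float, float]] = []
    prev = 0
    for p in peaks:
        trough = float(x[prev : p + 1].min())
        amp = float(x[p]) - trough
        if amp >= min_amp_uS:
            events.append((p / rate_hz, amp))
        prev = p
    return events
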