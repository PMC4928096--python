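"""Inverse-Gaussian point-process model of heartbeat dynamics.

The probability density of the waiting time to the next R-wave event is
inverse Gaussian with shape ``xi0`` and a mean parametrized as a Nonlinear
Autoregressive model with Laguerre expansion (NARL) of the Volterra terms:

    mu_RR(t) = RR[N(t)] + g0 + sum_i g1(i) l_i(t)
               + sum_ij g2(i,j) l_i(t) l_j(t)  [+ cubic g3 terms]

where ``l_i(t)`` are Laguerre filter outputs of the first-differenced R-R
series (see :mod:`pphrv.laguerre`).  Modelling the derivative series improves
local stationarity within the sliding window; anchoring the reconstruction to
the last observed interval keeps ``mu_RR`` in seconds.

Parameters are tracked by maximizing an exponentially weighted local
log-likelihood over the trailing window ``W`` on a ``delta``-spaced grid with
Newton-Raphson warm starts, and the fit is validated with the time-rescaling
theorem (Kolmogorov-Smirnov plot and autocorrelation of the rescaled
intervals).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import log_ndtr, ndtr
from scipy.stats import invgauss, norm

from .laguerre import LaguerreBasis, beat_regressors, build_basis

log = logging.getLogger(__name__)

__all__ = [
    "NARLParameters",
    "FitConfig",
    "ParameterTrajectory",
    "GoodnessOfFit",
    "ig_pdf",
    "ig_logpdf",
    "ig_logsf",
    "hr_moments",
    "conditional_mean",
    "local_loglikelihood",
    "fit_trajectory",
    "time_rescale",
]

_LOG2PI = np.log(2.0 * np.pi)


# ---------------------------------------------------------------------------
# inverse-Gaussian primitives


def ig_logpdf(x, mu, shape):
    """Log density of the inverse-Gaussian law with mean ``mu``, shape ``shape``."""
    x = np.asarray(x, dtype=float)
    return (0.5 * (np.log(shape) - _LOG2PI - 3.0 * np.log(x))
            - shape * (x - mu) ** 2 / (2.0 * mu**2 * x))


def ig_pdf(x, mu, shape):
    """Inverse-Gaussian density f(x; mu, shape), units 1/seconds.

    All arguments must be positive.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("elapsed time must be positive")
    if not np.all(np.asarray(mu) > 0) or not np.all(np.asarray(shape) > 0):
        raise ValueError("mu and shape must be positive")
    return np.exp(ig_logpdf(x, mu, shape))


def ig_logsf(x, mu, shape):
    """Log survival function of the inverse Gaussian (vectorized, stable)."""
    return invgauss.logsf(np.asarray(x, dtype=float), np.asarray(mu) / shape,
                          scale=shape)


def _censor_logsf_and_grads(tau: float, mu: float, shape: float):
    """log S(tau) and its partials w.r.t. mu and shape.

    Uses the identity exp(2*shape/mu) * phi(z2) == phi(z1) to collapse the
    derivative of the IG cdf to two stable terms.
    """
    a = np.sqrt(shape / tau)
    z1 = a * (tau / mu - 1.0)
    z2 = -a * (tau / mu + 1.0)
    t2 = np.exp(2.0 * shape / mu + log_ndtr(z2))
    s = ndtr(-z1) - t2
    s = max(s, 1e-300)
    phi1 = np.exp(-0.5 * z1 * z1) / np.sqrt(2.0 * np.pi)
    dlogs_dmu = (2.0 * shape / mu**2) * t2 / s
    dlogs_dshape = (phi1 / np.sqrt(shape * tau) - (2.0 / mu) * t2) / s
    return np.log(s), dlogs_dmu, dlogs_dshape


def hr_moments(mu: np.ndarray, shape: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean and SD of the instantaneous heart rate (beats/min).

    Closed-form moments of 60/X for X inverse Gaussian:
    E[1/X] = 1/mu + 1/shape and Var[1/X] = 1/(mu*shape) + 2/shape^2.
    """
    mu = np.asarray(mu, dtype=float)
    shape = np.asarray(shape, dtype=float)
    mu_hr = 60.0 * (1.0 / mu + 1.0 / shape)
    sigma_hr = 60.0 * np.sqrt(1.0 / (mu * shape) + 2.0 / shape**2)
    return mu_hr, sigma_hr


# ---------------------------------------------------------------------------
# parameters and configuration


@dataclass(frozen=True)
class NARLParameters:
    """Time-varying parameter vector of the NARL conditional mean.

    ``shape`` is the IG shape xi0 (> 0); ``g0`` the zeroth-order coefficient
    in seconds; ``g1`` the linear Laguerre coefficients; ``g2`` (and the
    optional cubic ``g3``) symmetric coefficient arrays.
    """

    shape: float
    g0: float = 0.0
    g1: np.ndarray = field(default_factory=lambda: np.zeros(0))
    g2: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))
    g3: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.shape <= 0:
            raise ValueError("shape xi0 must be positive")
        g1 = np.atleast_1d(np.asarray(self.g1, dtype=float))
        g2 = np.asarray(self.g2, dtype=float)
        object.__setattr__(self, "g1", g1)
        object.__setattr__(self, "g2", g2)
        if g2.size and np.max(np.abs(g2 - g2.T)) > 1e-12:
            raise ValueError("g2 must be symmetric")
        if self.g3 is not None:
            g3 = np.asarray(self.g3, dtype=float)
            for perm in ((0, 2, 1), (1, 0, 2), (2, 1, 0)):
                if g3.size and np.max(np.abs(g3 - np.transpose(g3, perm))) > 1e-12:
                    raise ValueError("g3 must be symmetric under index permutation")
            object.__setattr__(self, "g3", g3)


@dataclass(frozen=True)
class FitConfig:
    """Settings for local maximum-likelihood tracking.

    ``window_w`` is the local observation window W in seconds (90 s default),
    ``step_delta`` the grid spacing (5 ms default, coarser grids are valid and
    used for speed), ``weight_decay`` the exponential weighting rate (1/s) of
    w(tau) = exp(-weight_decay*tau).  The default 0.02/s gives an e-folding of
    50 s, inside W.
    """

    window_w: float = 90.0
    step_delta: float = 0.005
    weight_decay: float = 0.02
    alpha: float = 0.2
    p1: int = 3
    p2: int = 2
    p3: int = 2
    truncation: int | None = None
    censoring: bool = True
    newton_max_iter: int = 20
    newton_tol: float = 1e-6
    max_halvings: int = 30

    def __post_init__(self) -> None:
        if self.window_w <= 0 or self.step_delta <= 0 or self.weight_decay < 0:
            raise ValueError("window_w, step_delta must be > 0; weight_decay >= 0")

    def make_basis(self) -> LaguerreBasis:
        p = max(self.p1, self.p2)
        return build_basis(self.alpha, p, self.truncation)


def _quad_index(p2: int) -> list[tuple[int, int]]:
    return [(a, b) for a in range(p2) for b in range(a, p2)]


def pack_params(params: NARLParameters, p1: int, p2: int) -> np.ndarray:
    """Pack (log xi0, g0, g1, upper-triangular g2) into a flat theta vector."""
    g1 = np.zeros(p1)
    g1[: params.g1.size] = params.g1[:p1]
    quad = []
    for a, b in _quad_index(p2):
        if params.g2.size:
            val = params.g2[a, b] * (2.0 if a != b else 1.0)
        else:
            val = 0.0
        quad.append(val)
    return np.concatenate([[np.log(params.shape), params.g0], g1, quad])


def unpack_params(theta: np.ndarray, p1: int, p2: int) -> NARLParameters:
    shape = float(np.exp(theta[0]))
    g0 = float(theta[1])
    g1 = np.array(theta[2: 2 + p1])
    g2 = np.zeros((p2, p2))
    for (a, b), val in zip(_quad_index(p2), theta[2 + p1:]):
        if a == b:
            g2[a, a] = val
        else:
            g2[a, b] = g2[b, a] = 0.5 * val
    return NARLParameters(shape=shape, g0=g0, g1=g1, g2=g2)


def conditional_mean(params: NARLParameters, coeffs, last_rr: float) -> float:
    """Instantaneous R-R mean mu_RR(t) from the NARL polynomial.

    ``coeffs`` may be a LaguerreCoefficients object or a plain array of
    filter outputs.  A non-positive result is returned as-is; callers decide
    how to treat the invalid prediction (the fitter rejects such steps).
    """
    if last_rr <= 0:
        raise ValueError("last_rr must be positive")
    l = np.asarray(getattr(coeffs, "values", coeffs), dtype=float)
    mu = last_rr + params.g0
    p1 = params.g1.size
    if p1:
        mu += float(params.g1 @ l[:p1])
    p2 = params.g2.shape[0]
    if p2:
        l2 = l[:p2]
        mu += float(l2 @ params.g2 @ l2)
    if params.g3 is not None and params.g3.size:
        p3 = params.g3.shape[0]
        l3 = l[:p3]
        mu += float(np.einsum("ijk,i,j,k->", params.g3, l3, l3, l3))
    return float(mu)


# ---------------------------------------------------------------------------
# likelihood workspace


class _Workspace:
    """Per-recording precomputation shared by all grid times."""

    def __init__(self, events, config: FitConfig, basis: LaguerreBasis | None = None):
        self.config = config
        self.basis = basis if basis is not None else config.make_basis()
        self.u = np.asarray(events.event_times, dtype=float)
        self.rr = np.diff(self.u)
        n = self.rr.size
        lag, burn = beat_regressors(self.rr, self.basis)
        self.lin = lag[:, : config.p1]
        qi = _quad_index(config.p2)
        self.quad = np.stack([lag[:, a] * lag[:, b] for a, b in qi], axis=1) \
            if qi else np.zeros((n + 1, 0))
        self.X = np.concatenate(
            [np.ones((n + 1, 1)), self.lin, self.quad], axis=1)
        self.c = np.concatenate([[np.nan], self.rr])  # c[k] = rr[k-1]
        self.burn_in = burn
        self.n_params = self.X.shape[1] + 1  # + log xi0

    def window_indices(self, t: float) -> tuple[np.ndarray, int]:
        """Observed-interval indices with end event in (t-W, t], and N(t)."""
        u = self.u
        n_le = int(np.searchsorted(u, t, side="right"))
        n_t = n_le - 1  # index of last event <= t
        first_end = int(np.searchsorted(u, t - self.config.window_w, side="right"))
        k_lo = max(self.burn_in, first_end - 1)
        k_hi = n_t  # intervals k with k+1 <= n_t
        return np.arange(k_lo, k_hi), n_t

    def loglik(self, theta: np.ndarray, t: float, with_derivs: bool = False):
        cfg = self.config
        idx, n_t = self.window_indices(t)
        if idx.size == 0:
            raise ValueError(f"no complete interval in the window ending at t={t}")
        if not -12.0 < theta[0] < 25.0:
            # xi0 outside (~6e-6, 7e10): infeasible step, keeps the local MLE
            # bounded when a small window is nearly interpolated
            return (-np.inf, None, None) if with_derivs else -np.inf
        xi0 = np.exp(theta[0])
        beta = theta[1:]
        Xw = self.X[idx]
        rrw = self.rr[idx]
        cw = self.c[idx]
        ends = self.u[idx + 1]
        w = np.exp(-cfg.weight_decay * (t - ends))
        mu = cw + Xw @ beta
        if np.any(mu <= 0):
            return (-np.inf, None, None) if with_derivs else -np.inf
        resid = rrw - mu
        quad_term = resid**2 / (2.0 * mu**2 * rrw)
        terms = 0.5 * (theta[0] - _LOG2PI - 3.0 * np.log(rrw)) - xi0 * quad_term
        ll = float(w @ terms)

        use_censor = cfg.censoring and n_t >= self.burn_in and n_t < len(self.X)
        tau = t - self.u[n_t] if n_t >= 0 else 0.0
        mu_c = None
        if use_censor and tau > 1e-12:
            mu_c = self.c[n_t] + self.X[n_t] @ beta if n_t >= 1 else -1.0
            if not np.isfinite(mu_c) or mu_c <= 0:
                return (-np.inf, None, None) if with_derivs else -np.inf
            logs, ds_dmu, ds_dshape = _censor_logsf_and_grads(tau, mu_c, xi0)
            ll += logs
        else:
            use_censor = False

        if not with_derivs:
            return ll

        npar = self.n_params
        grad = np.zeros(npar)
        hess = np.zeros((npar, npar))
        # d/d log xi0
        grad[0] = float(w @ (0.5 - xi0 * quad_term))
        hess[0, 0] = float(w @ (-xi0 * quad_term))
        # d/d beta
        gmu = xi0 * resid / mu**3          # dlogf/dmu
        grad[1:] = (w * gmu) @ Xw
        hmu = xi0 * (2.0 * mu - 3.0 * rrw) / mu**4   # d2logf/dmu2
        hess[1:, 1:] = (Xw * (w * hmu)[:, None]).T @ Xw
        hess[0, 1:] = hess[1:, 0] = (w * gmu) @ Xw   # cross term (linear in xi0)
        if use_censor:
            grad[0] += xi0 * ds_dshape
            grad[1:] += ds_dmu * self.X[n_t]
        return ll, grad, hess

    def maximize(self, theta0: np.ndarray, t: float) -> tuple[np.ndarray, float, bool]:
        """Damped Newton ascent of the local log-likelihood at time t."""
        cfg = self.config
        theta = theta0.copy()
        ll = self.loglik(theta, t)
        if not np.isfinite(ll):
            return theta0, -np.inf, False
        converged = False
        for _ in range(cfg.newton_max_iter):
            ll, grad, hess = self.loglik(theta, t, with_derivs=True)
            gnorm = np.max(np.abs(grad))
            if gnorm < 1e-9:
                converged = True
                break
            step = None
            try:
                np.linalg.cholesky(-hess)
                step = np.linalg.solve(-hess, grad)
            except np.linalg.LinAlgError:
                step = grad / max(gnorm, 1.0) * 0.1  # safeguarded ascent step
            accepted = False
            for _h in range(cfg.max_halvings):
                cand = theta + step
                ll_new = self.loglik(cand, t)
                if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                    accepted = True
                    break
                step = 0.5 * step
            if not accepted:
                break
            rel = np.max(np.abs(step) / np.maximum(np.abs(theta), 1e-3))
            theta = cand
            if rel < cfg.newton_tol or abs(ll_new - ll) < cfg.newton_tol * max(abs(ll), 1.0):
                ll = ll_new
                converged = True
                break
            ll = ll_new
        return theta, ll, converged


def local_loglikelihood(events, params: NARLParameters, t: float,
                        config: FitConfig = FitConfig(),
                        with_grad: bool = False):
    """Exponentially weighted local log-likelihood at time ``t``.

    Sums ``w(t-u_j) log f(RR_j)`` over complete intervals with end event in
    (t-W, t], plus (when ``config.censoring``) the right-censoring term
    ``log S(t - u_N)`` for the open interval.  With ``with_grad=True`` also
    returns the analytic gradient with respect to the packed parameter vector
    ``(log xi0, g0, g1, upper-tri g2)``.
    """
    ws = _Workspace(events, config)
    if t <= ws.u[0]:
        raise ValueError(f"t={t} precedes the first event")
    theta = pack_params(params, config.p1, config.p2)
    if with_grad:
        ll, grad, _ = ws.loglik(theta, t, with_derivs=True)
        return ll, grad
    return ws.loglik(theta, t)


# ---------------------------------------------------------------------------
# trajectory


@dataclass
class ParameterTrajectory:
    """NARL parameters and instantaneous IG moments on a regular time grid.

    ``sigma_rr = sqrt(mu_rr^3 / xi0)``; heart-rate moments follow the
    closed-form moments of the reciprocal of an inverse-Gaussian variate.
    Non-converged grid points carry the last converged estimate and are
    flagged.
    """

    grid_times: np.ndarray
    shape: np.ndarray
    g0: np.ndarray
    g1: np.ndarray
    g2: np.ndarray
    mu_rr: np.ndarray
    sigma_rr: np.ndarray
    mu_hr: np.ndarray
    sigma_hr: np.ndarray
    last_rr: np.ndarray
    loglik: np.ndarray
    converged: np.ndarray
    config: FitConfig
    basis: LaguerreBasis

    @property
    def step_delta(self) -> float:
        return float(self.config.step_delta)

    def index_at(self, t) -> np.ndarray:
        """Grid index of the step function value active at time t."""
        idx = np.searchsorted(self.grid_times, np.asarray(t), side="right") - 1
        return np.clip(idx, 0, len(self.grid_times) - 1)

    def params_at(self, t: float) -> NARLParameters:
        i = int(self.index_at(t))
        return NARLParameters(shape=float(self.shape[i]), g0=float(self.g0[i]),
                              g1=self.g1[i].copy(), g2=self.g2[i].copy())

    def to_frame(self) -> pd.DataFrame:
        d = {"time": self.grid_times, "xi0": self.shape, "g0": self.g0}
        for i in range(self.g1.shape[1]):
            d[f"g1_{i}"] = self.g1[:, i]
        p2 = self.g2.shape[1]
        for a in range(p2):
            for b in range(a, p2):
                d[f"g2_{a}{b}"] = self.g2[:, a, b]
        d.update(mu_rr=self.mu_rr, sigma_rr=self.sigma_rr, mu_hr=self.mu_hr,
                 sigma_hr=self.sigma_hr, loglik=self.loglik,
                 converged=self.converged.astype(int))
        return pd.DataFrame(d)

    @classmethod
    def constant(cls, mu: float, shape: float, t_start: float, t_end: float,
                 step: float = 1.0, config: FitConfig | None = None
                 ) -> "ParameterTrajectory":
        """A constant-(mu, xi0) trajectory, e.g. known truth for simulations."""
        cfg = config or FitConfig(step_delta=step)
        basis = cfg.make_basis()
        grid = np.arange(t_start, t_end + step, step)
        n = grid.size
        ones = np.ones(n)
        mu_hr, sigma_hr = hr_moments(mu, shape)
        return cls(grid_times=grid, shape=shape * ones, g0=np.zeros(n),
                   g1=np.zeros((n, cfg.p1)), g2=np.zeros((n, cfg.p2, cfg.p2)),
                   mu_rr=mu * ones, sigma_rr=np.sqrt(mu**3 / shape) * ones,
                   mu_hr=mu_hr * ones, sigma_hr=sigma_hr * ones,
                   last_rr=mu * ones, loglik=np.zeros(n),
                   converged=np.ones(n, dtype=bool), config=cfg, basis=basis)


def fit_trajectory(events, config: FitConfig = FitConfig()) -> ParameterTrajectory:
    """Track the NARL parameters by local maximum likelihood.

    Newton-Raphson with damped (log-likelihood non-decreasing) steps, warm
    started from the estimate at the previous grid time.  The shape parameter
    is optimized on the log scale to enforce positivity.
    """
    ws = _Workspace(events, config)
    u, rr = ws.u, ws.rr
    if rr.size <= ws.burn_in + 2:
        raise ValueError("recording too short for the configured burn-in")
    # estimates start once the Laguerre burn-in is satisfied and the window
    # holds enough beats to identify the parameters; the local window
    # (t-W, t] is simply truncated at the recording start before t=W
    k0 = min(ws.burn_in + max(3 * ws.n_params, 10), rr.size - 2)
    t0 = u[k0 + 1]
    if events.t_end < max(config.window_w, t0 + 2 * config.step_delta):
        raise ValueError(
            f"recording length {events.t_end:.1f}s too short: need at least "
            f"the local window W = {config.window_w:.0f}s plus burn-in")
    delta = config.step_delta
    grid = np.arange(np.ceil(t0 / delta) * delta, events.t_end, delta)
    n = grid.size

    # moment-matched initial shape
    mu0 = float(np.mean(rr[ws.burn_in:]))
    var0 = float(np.var(rr[ws.burn_in:])) or 1e-8
    theta = np.zeros(ws.n_params)
    theta[0] = np.log(mu0**3 / var0)

    p1, p2 = config.p1, config.p2
    out = {k: np.zeros(n) for k in
           ("shape", "g0", "mu_rr", "sigma_rr", "mu_hr", "sigma_hr",
            "last_rr", "loglik")}
    g1_arr = np.zeros((n, p1))
    g2_arr = np.zeros((n, p2, p2))
    conv = np.zeros(n, dtype=bool)

    theta_good = theta
    for i, t in enumerate(grid):
        theta_new, ll, ok = ws.maximize(theta_good, t)
        if ok:
            theta_good = theta_new
        conv[i] = ok
        th = theta_good
        params = unpack_params(th, p1, p2)
        _, n_t = ws.window_indices(t)
        mu_pred = np.nan
        if ws.burn_in <= n_t < len(ws.X):
            mu_pred = float(ws.c[n_t] + ws.X[n_t] @ th[1:])
        if not np.isfinite(mu_pred) or mu_pred <= 0:
            conv[i] = False
            mu_pred = np.nan
        xi0 = params.shape
        out["shape"][i] = xi0
        out["g0"][i] = params.g0
        g1_arr[i] = params.g1
        g2_arr[i] = params.g2
        out["mu_rr"][i] = mu_pred
        out["sigma_rr"][i] = np.sqrt(mu_pred**3 / xi0) if mu_pred > 0 else np.nan
        if mu_pred > 0:
            out["mu_hr"][i], out["sigma_hr"][i] = hr_moments(mu_pred, xi0)
        else:
            out["mu_hr"][i] = out["sigma_hr"][i] = np.nan
        out["last_rr"][i] = ws.c[n_t] if n_t >= 1 else np.nan
        out["loglik"][i] = ll

    fail_rate = 1.0 - conv.mean() if n else 0.0
    if fail_rate > 0.20:
        log.warning("fit_trajectory: %.0f%% of grid points failed to converge",
                    100 * fail_rate)
    return ParameterTrajectory(grid_times=grid, shape=out["shape"],
                               g0=out["g0"], g1=g1_arr, g2=g2_arr,
                               mu_rr=out["mu_rr"], sigma_rr=out["sigma_rr"],
                               mu_hr=out["mu_hr"], sigma_hr=out["sigma_hr"],
                               last_rr=out["last_rr"], loglik=out["loglik"],
                               converged=conv, config=config, basis=ws.basis)


# ---------------------------------------------------------------------------
# time-rescaling goodness-of-fit


@dataclass(frozen=True)
class GoodnessOfFit:
    """Time-rescaling diagnostics of a fitted (or supplied) trajectory."""

    rescaled: np.ndarray
    ks_distance: float
    ks_plot: tuple[np.ndarray, np.ndarray]
    ks_bound95: float
    acf: np.ndarray
    acf_bound95: float

    @property
    def acf_within_fraction(self) -> float:
        return float(np.mean(np.abs(self.acf) <= self.acf_bound95))


def time_rescale(events, traj: ParameterTrajectory, max_lag: int = 60
                 ) -> GoodnessOfFit:
    """Transform intervals through the model's integrated hazard.

    Each interval is mapped to z_j = integral of the conditional intensity,
    then through 1 - exp(-z) to (0, 1); exactly uniform when the model is
    correct.  The KS distance is measured against the uniform quantiles
    (k - 1/2)/n with 95% bound 1.36/sqrt(n); the autocorrelation of the
    Gaussian-inverse-transformed variates is reported at lags 1..max_lag with
    bounds +-1.96/sqrt(n).
    """
    u = np.asarray(events.event_times, dtype=float)
    grid = traj.grid_times
    t_lo = grid[0]
    ks_idx = np.flatnonzero((u[:-1] >= t_lo))  # intervals starting in coverage
    if ks_idx.size < 10:
        raise ValueError("need at least 10 intervals inside the trajectory")

    tau_a, tau_b, mu_seg, sh_seg, owner = [], [], [], [], []
    for m, k in enumerate(ks_idx):
        a, b = u[k], u[k + 1]
        inner = grid[(grid > a) & (grid < b)]
        pts = np.concatenate([[a], inner, [b]])
        gi = traj.index_at(pts[:-1])
        mu = traj.mu_rr[gi]
        sh = traj.shape[gi]
        good = np.isfinite(mu) & (mu > 0)
        mu = np.where(good, mu, np.nanmedian(traj.mu_rr))
        tau_a.append(pts[:-1] - a)
        tau_b.append(pts[1:] - a)
        mu_seg.append(mu)
        sh_seg.append(sh)
        owner.append(np.full(pts.size - 1, m))
    tau_a = np.concatenate(tau_a)
    tau_b = np.concatenate(tau_b)
    mu_seg = np.concatenate(mu_seg)
    sh_seg = np.concatenate(sh_seg)
    owner = np.concatenate(owner)

    mus = mu_seg / sh_seg
    logsf_a = np.where(tau_a > 0, invgauss.logsf(np.maximum(tau_a, 1e-300),
                                                 mus, scale=sh_seg), 0.0)
    logsf_b = invgauss.logsf(tau_b, mus, scale=sh_seg)
    dz = logsf_a - logsf_b
    z = np.bincount(owner, weights=dz, minlength=ks_idx.size)
    resc = 1.0 - np.exp(-z)
    eps = 1e-12
    resc = np.clip(resc, eps, 1.0 - eps)

    n = resc.size
    srt = np.sort(resc)
    bk = (np.arange(1, n + 1) - 0.5) / n
    ks = float(np.max(np.abs(srt - bk)))

    from statsmodels.tsa.stattools import acf as sm_acf
    gvals = norm.ppf(resc)
    nlags = min(max_lag, n - 2)
    ac = sm_acf(gvals, nlags=nlags, fft=True)[1:]
    return GoodnessOfFit(rescaled=resc, ks_distance=ks, ks_plot=(bk, srt),
                         ks_bound95=1.36 / np.sqrt(n), acf=ac,
                         acf_bound95=1.96 / np.sqrt(n))
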