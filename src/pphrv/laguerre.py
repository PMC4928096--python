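"""Discrete orthonormal Laguerre basis and Laguerre-filtered heartbeat history.

The conditional mean of the next R-R interval is parametrized as a polynomial
in the outputs of a bank of discrete Laguerre filters applied to the
first-differenced interval series.  The basis compresses long autoregressive
memory into a handful of coefficients: each function decays geometrically with
rate ``sqrt(alpha)`` so a small number of functions spans tens of beats.

The differenced-series convention is fixed here once for the whole package:
``dRR[j] = RR[j] - RR[j-1]`` and the filter output feeding the prediction of
interval ``j`` is

    l_i(j) = sum_n phi_i(n) * dRR[j - 1 - n]

so that the model reconstruction ``mu_RR = RR[last] + NARL(l)`` stays in
seconds and is self-consistent (see :mod:`pphrv.pp_model`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LaguerreBasis",
    "LaguerreCoefficients",
    "build_basis",
    "laguerre_matrix",
    "default_truncation",
    "filter_history",
    "beat_regressors",
]

#: orthonormality tolerance enforced by build_basis
_ORTHO_TOL = 1e-6


def laguerre_matrix(alpha: float, num_functions: int, truncation: int) -> np.ndarray:
    """Evaluate phi_i(n) for i < num_functions, n < truncation.

    Uses the standard two-term recursion for discrete Laguerre functions

        phi_0(n) = sqrt(1-alpha) * alpha^(n/2)
        phi_i(n) = sqrt(alpha)*phi_i(n-1) + sqrt(alpha)*phi_{i-1}(n)
                   - phi_{i-1}(n-1)

    which is numerically stable for the truncations used here.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in the open interval (0, 1), got {alpha}")
    sa = np.sqrt(alpha)
    n = np.arange(truncation)
    phi = np.zeros((num_functions, truncation))
    phi[0] = np.sqrt(1.0 - alpha) * sa**n
    for i in range(1, num_functions):
        phi[i, 0] = sa * phi[i - 1, 0]
        for k in range(1, truncation):
            phi[i, k] = sa * phi[i, k - 1] + sa * phi[i - 1, k] - phi[i - 1, k - 1]
    return phi


def default_truncation(alpha: float, num_functions: int, tail: float = 1e-8,
                       cap: int = 200) -> int:
    """Smallest history length with alpha^(n/2) < ``tail``, capped at ``cap``.

    Always at least ``num_functions`` so the basis can be orthonormal.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in the open interval (0, 1), got {alpha}")
    n = int(np.ceil(2.0 * np.log(tail) / np.log(alpha)))
    return max(num_functions, min(max(n, 1), cap))


@dataclass(frozen=True)
class LaguerreBasis:
    """Bank of discrete orthonormal Laguerre functions.

    Attributes
    ----------
    alpha : float
        Decay parameter in (0, 1); geometric decay rate is sqrt(alpha).
    num_functions : int
        Number of functions phi_0 .. phi_{P-1}.
    truncation : int
        History length in beats over which each phi_i is evaluated.
    basis_matrix : ndarray, shape (num_functions, truncation)
        phi_i(n) values.
    """

    alpha: float
    num_functions: int
    truncation: int
    basis_matrix: np.ndarray

    def __post_init__(self) -> None:
        self.basis_matrix.setflags(write=False)

    def gram(self) -> np.ndarray:
        """Inner-product matrix of the truncated functions."""
        return self.basis_matrix @ self.basis_matrix.T


@dataclass(frozen=True)
class LaguerreCoefficients:
    """Laguerre filter outputs l_i(t) evaluated just before time t."""

    values: np.ndarray
    eval_time: float
    source_beat_index: int


def build_basis(alpha: float, num_functions: int,
                truncation: int | None = None) -> LaguerreBasis:
    """Construct an orthonormal Laguerre basis.

    Parameters
    ----------
    alpha : float
        Decay parameter, 0 < alpha < 1.
    num_functions : int
        Number of basis functions.
    truncation : int, optional
        History length in beats; defaults to the smallest length whose
        geometric tail is below 1e-8 (capped at 200 lags).

    Raises
    ------
    ValueError
        If alpha is outside (0, 1), or the requested truncation is too small
        for the basis to be orthonormal to 1e-6.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in the open interval (0, 1), got {alpha}")
    if num_functions < 1:
        raise ValueError("num_functions must be positive")
    if truncation is None:
        truncation = default_truncation(alpha, num_functions)
    if truncation < num_functions:
        raise ValueError(
            f"truncation ({truncation}) must be at least num_functions "
            f"({num_functions})")
    phi = laguerre_matrix(alpha, num_functions, truncation)
    gram = phi @ phi.T
    err = np.max(np.abs(gram - np.eye(num_functions)))
    if err > _ORTHO_TOL:
        raise ValueError(
            f"basis not orthonormal to {_ORTHO_TOL:g} at truncation "
            f"{truncation} (max deviation {err:.2e}); increase truncation")
    return LaguerreBasis(alpha=alpha, num_functions=num_functions,
                         truncation=truncation, basis_matrix=phi)


def beat_regressors(rr_intervals: np.ndarray, basis: LaguerreBasis) -> tuple[np.ndarray, int]:
    """Laguerre outputs aligned with each beat's prediction.

    Parameters
    ----------
    rr_intervals : ndarray
        R-R intervals in seconds, interval k spanning events (k, k+1).
    basis : LaguerreBasis

    Returns
    -------
    lag_outputs : ndarray, shape (n_intervals + 1, num_functions)
        Row k holds l_i used to predict interval k (i.e. the filter state just
        before the event that opens interval k).  Row ``n_intervals`` is the
        state available for the open interval after the last event.  Rows
        before the burn-in index are zero and must not be used.
    burn_in : int
        First interval index with a fully supported history
        (``truncation + 1`` complete intervals observed).
    """
    rr = np.asarray(rr_intervals, dtype=float)
    n = rr.size
    L = basis.truncation
    out = np.zeros((n + 1, basis.num_functions))
    burn_in = L + 1
    if n < 2:
        return out, burn_in
    drr = np.diff(rr)  # drr[j-1] = RR[j] - RR[j-1], first defined for j = 1
    # l[k, i] = sum_m phi_i(m) drr[k-1-m] where drr index is 1-based over rr;
    # with d = drr (0-based, d[q] = RR[q+1]-RR[q]) this is
    # l[k, i] = sum_m phi_i(m) d[k-2-m], valid for k >= L+1.
    for i in range(basis.num_functions):
        conv = np.convolve(drr, basis.basis_matrix[i])
        # conv[p] = sum_m phi_i(m) d[p-m]; want p = k-2
        ks = np.arange(burn_in, n + 1)
        out[ks, i] = conv[ks - 2]
    return out, burn_in


def filter_history(events, basis: LaguerreBasis, t: float) -> LaguerreCoefficients:
    """Laguerre filter outputs at time ``t`` (piecewise constant between beats).

    Requires at least ``truncation + 1`` complete intervals before ``t``;
    no zero-padding is applied (early estimates would otherwise be biased).
    """
    u = np.asarray(events.event_times, dtype=float)
    rr = np.diff(u)
    n_before = int(np.searchsorted(u, t, side="left"))  # events strictly before t
    last_interval = n_before - 2  # 0-based index of last complete interval
    L = basis.truncation
    if last_interval < L:
        raise ValueError(
            f"insufficient history at t={t}: need at least truncation+1="
            f"{L + 1} complete intervals, have {max(last_interval + 1, 0)}")
    drr = np.diff(rr)
    # filter state after interval `last_interval`: sum_m phi(m) d[last-1-m]
    idx = last_interval - 1 - np.arange(L)
    window = drr[idx]
    values = basis.basis_matrix @ window
    return LaguerreCoefficients(values=values, eval_time=float(t),
                                source_beat_index=last_interval)
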