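"""Instantaneous spectra and bispectra from the NARL parametrization.

The autoregressive Laguerre coefficients are transformed to input-output
Volterra transfer functions: with ``k1(n) = sum_i g1(i) phi_i(n)`` and
``k2(n,m) = sum_ij g2(i,j) phi_i(n) phi_j(m)``,

    Gamma1(f)     = sum_n k1(n)   e^{-i 2 pi f (n+1)}
    Gamma2(f1,f2) = sum_nm k2(n,m) e^{-i 2 pi (f1 (n+1) + f2 (m+1))}
    H1(f)         = 1 / (1 - Gamma1(f))
    H2(f1,f2)     = H1(f1+f2) Gamma2(f1,f2) H1(f1) H1(f2)

(the n+1 lag shift reflects that the filters act on the history up to the
previous beat).  Kernels live on the beat axis; frequencies in Hz are mapped
through the instantaneous mean, ``nu = f * mu_RR(t)`` cycles/beat.

The linear power spectrum is pinned by a Parseval convention:
``S(f,t) = 2 mu_RR(t) sigma^2(t) |H1(f,t)|^2`` with ``sigma^2 = mu^3/xi0``
the IG interval variance, so that for the null (white) model the integral of
S over [0, Nyquist] equals sigma_RR^2 exactly.

The bispectrum of the quadratically nonlinear system driven by the white
Gaussian-like innovation is assembled from the three canonical pairings of
two first-order and one second-order transfer evaluation; its magnitude
integrals over LFxLF, LFxHF and HFxHF quantify nonlinear sympatho-vagal
interactions (LL, LH, HH).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .laguerre import LaguerreBasis
from .pp_model import NARLParameters, ParameterTrajectory

__all__ = [
    "BANDS",
    "KernelTransform",
    "SpectralSurface",
    "BispectralSurface",
    "narl_to_kernels",
    "instantaneous_spectrum",
    "instantaneous_bispectrum",
    "band_power",
]

#: canonical heart-rate bands, Hz
BANDS = {"VLF": (0.01, 0.05), "LF": (0.05, 0.15), "HF": (0.15, 0.5)}

_POLE_TOL = 1e-8


@dataclass(frozen=True)
class KernelTransform:
    """First- and second-order transfer functions of the NARL model.

    ``H1`` is precomputed on ``freq_grid``; arbitrary-frequency evaluation
    (needed by the bispectrum, including negative frequencies) goes through
    :meth:`h1_at` / :meth:`gamma2_at` / :meth:`h2_at`.
    """

    freq_grid: np.ndarray
    H1: np.ndarray
    k1: np.ndarray
    k2: np.ndarray
    mu_rr: float

    def _exps(self, f):
        """e^{-i 2 pi nu (n+1)} rows for Hz frequencies f."""
        nu = np.asarray(f, dtype=float) * self.mu_rr
        n = np.arange(1, self.k1.size + 1)
        return np.exp(-2j * np.pi * nu[..., None] * n)

    def gamma1_at(self, f):
        return self._exps(f) @ self.k1

    def h1_at(self, f):
        g1 = self.gamma1_at(f)
        d = 1.0 - g1
        bad = np.abs(d) < _POLE_TOL
        if np.any(bad):
            fb = np.asarray(f)[np.nonzero(bad)][0] if np.ndim(f) else f
            raise ValueError(
                f"near-nonstationary pole: |1 - Gamma1| < {_POLE_TOL:g} at "
                f"f = {float(fb):.4f} Hz")
        return 1.0 / d

    def gamma2_at(self, f1, f2):
        e1 = self._exps(f1)
        e2 = self._exps(f2)
        return np.einsum("...n,nm,...m->...", e1, self.k2, e2)

    def h2_at(self, f1, f2):
        f1 = np.asarray(f1, dtype=float)
        f2 = np.asarray(f2, dtype=float)
        return (self.h1_at(f1 + f2) * self.gamma2_at(f1, f2)
                * self.h1_at(f1) * self.h1_at(f2))


def _kernels_from_params(params: NARLParameters, basis: LaguerreBasis
                         ) -> tuple[np.ndarray, np.ndarray]:
    phi = basis.basis_matrix
    p1 = params.g1.size
    k1 = params.g1 @ phi[:p1] if p1 else np.zeros(basis.truncation)
    p2 = params.g2.shape[0]
    if p2:
        k2 = phi[:p2].T @ params.g2 @ phi[:p2]
    else:
        k2 = np.zeros((basis.truncation, basis.truncation))
    return k1, k2


def narl_to_kernels(params: NARLParameters, basis: LaguerreBasis,
                    freq_grid: np.ndarray, mu_rr: float) -> KernelTransform:
    """Transform NARL coefficients to Volterra transfer functions.

    Only kernel orders up to 2 are supported; the general recursion for
    higher orders is intentionally not implemented (cubic terms feed the
    complexity path, not the spectra).
    """
    if mu_rr <= 0:
        raise ValueError("mu_rr must be positive for the beat-to-Hz mapping")
    if params.g3 is not None and params.g3.size and np.any(params.g3 != 0):
        raise NotImplementedError(
            "kernel transform implemented up to order M = 2; cubic terms are "
            "handled by the complexity estimators")
    freq_grid = np.asarray(freq_grid, dtype=float)
    k1, k2 = _kernels_from_params(params, basis)
    kt = KernelTransform(freq_grid=freq_grid, H1=np.zeros(0), k1=k1, k2=k2,
                         mu_rr=float(mu_rr))
    h1 = kt.h1_at(freq_grid)
    return KernelTransform(freq_grid=freq_grid, H1=h1, k1=k1, k2=k2,
                           mu_rr=float(mu_rr))


def band_power(freqs: np.ndarray, power: np.ndarray, lo: float, hi: float
               ) -> float:
    """Trapezoidal integral of a sampled spectrum over [lo, hi].

    Band edges are included (interpolated if not on the grid); adjacent bands
    share their edge point, which is measure-zero for the integral.
    """
    freqs = np.asarray(freqs, dtype=float)
    inside = (freqs > lo) & (freqs < hi)
    fs = np.concatenate([[lo], freqs[inside], [hi]])
    ps = np.concatenate([[np.interp(lo, freqs, power)], power[inside],
                         [np.interp(hi, freqs, power)]])
    return float(np.trapezoid(ps, fs))


@dataclass(frozen=True)
class SpectralSurface:
    """Time-resolved linear power spectrum with band integrals."""

    grid_times: np.ndarray
    freqs: np.ndarray
    power: np.ndarray            # (n_times, n_freqs), s^2/Hz
    bands: pd.DataFrame          # time, VLF, LF, HF, lf_hf


def instantaneous_spectrum(traj: ParameterTrajectory, basis: LaguerreBasis,
                           freqs: np.ndarray, hf_floor: float = 1e-18
                           ) -> SpectralSurface:
    """Evaluate S(f,t) = 2 mu sigma^2 |H1|^2 on the trajectory grid.

    Grid points flagged non-converged yield missing values.  The LF/HF ratio
    is guarded by ``hf_floor`` against an empty high-frequency band.
    """
    freqs = np.asarray(freqs, dtype=float)
    if freqs.size == 0:
        raise ValueError("empty frequency grid")
    nt = traj.grid_times.size
    power = np.full((nt, freqs.size), np.nan)
    cols = {k: np.full(nt, np.nan) for k in ("VLF", "LF", "HF", "lf_hf")}
    n = np.arange(1, basis.truncation + 1)
    phi1 = basis.basis_matrix[: traj.g1.shape[1]]
    for i in range(nt):
        mu = traj.mu_rr[i]
        if not (traj.converged[i] and np.isfinite(mu) and mu > 0):
            continue
        k1 = traj.g1[i] @ phi1
        nu = freqs * mu
        gamma1 = np.exp(-2j * np.pi * np.outer(nu, n)) @ k1
        d = 1.0 - gamma1
        if np.any(np.abs(d) < _POLE_TOL):
            continue
        h1sq = 1.0 / np.abs(d) ** 2
        sigma2 = traj.sigma_rr[i] ** 2
        s = 2.0 * mu * sigma2 * h1sq
        power[i] = s
        for name in ("VLF", "LF", "HF"):
            cols[name][i] = band_power(freqs, s, *BANDS[name])
        cols["lf_hf"][i] = cols["LF"][i] / max(cols["HF"][i], hf_floor)
    bands = pd.DataFrame({"time": traj.grid_times, **cols})
    return SpectralSurface(grid_times=traj.grid_times, freqs=freqs,
                           power=power, bands=bands)


@dataclass(frozen=True)
class BispectralSurface:
    """Time-resolved bispectrum magnitude band integrals (LL, LH, HH)."""

    grid_times: np.ndarray
    freqs: np.ndarray
    band_integrals: pd.DataFrame   # time, LL, LH, HH
    magnitude: np.ndarray | None   # (n_times, F, F) when kept


def _bispectrum_surface(k1: np.ndarray, k2: np.ndarray, mu: float,
                        sigma2: float, freqs: np.ndarray) -> np.ndarray:
    """|Bis(f1,f2)| on freqs x freqs for one time point.

    Three canonical pairings of a quadratic system driven by white Gaussian
    input with flat spectrum sigma^2; the per-axis beat-to-Hz conversion
    contributes a factor mu^2.
    """
    n = np.arange(1, k1.size + 1)
    nu = freqs * mu
    E = np.exp(-2j * np.pi * np.outer(nu, n))       # (F, L)
    g1 = E @ k1
    d = 1.0 - g1
    if np.any(np.abs(d) < _POLE_TOL):
        raise ValueError("near-nonstationary pole inside the bispectral region")
    h1 = 1.0 / d                                     # H1(f)
    a1 = np.abs(h1) ** 2
    nus = nu[:, None] + nu[None, :]
    Es = np.exp(-2j * np.pi * nus[..., None] * n)    # (F, F, L)
    g1s = Es @ k1
    ds = 1.0 - g1s
    if np.any(np.abs(ds) < _POLE_TOL):
        raise ValueError("near-nonstationary pole inside the bispectral region")
    h1s = 1.0 / ds                                   # H1(f1+f2)
    a1s = np.abs(h1s) ** 2

    g2 = E @ k2 @ E.T                                # Gamma2(f1, f2)
    ck = np.conj(E) @ k2                             # rows: Gamma2(-f, .) partial
    g2b = np.einsum("jm,ijm->ij", ck, Es)            # Gamma2(-f2, f1+f2)
    g2c = np.einsum("im,ijm->ij", ck, Es)            # Gamma2(-f1, f1+f2)

    t1 = a1[:, None] * a1[None, :] * np.conj(h1s) * np.conj(g2)
    t2 = h1[:, None] * a1[None, :] * a1s * g2b
    t3 = h1[None, :] * a1[:, None] * a1s * g2c
    return np.abs(2.0 * sigma2**2 * (t1 + t2 + t3)) * mu**2


def _trapz2d(freqs: np.ndarray, surf: np.ndarray, band1: tuple, band2: tuple
             ) -> float:
    m1 = (freqs >= band1[0] - 1e-12) & (freqs <= band1[1] + 1e-12)
    m2 = (freqs >= band2[0] - 1e-12) & (freqs <= band2[1] + 1e-12)
    sub = surf[np.ix_(m1, m2)]
    return float(np.trapezoid(np.trapezoid(sub, freqs[m2], axis=1), freqs[m1]))


def instantaneous_bispectrum(traj: ParameterTrajectory, basis: LaguerreBasis,
                             df: float = 0.005, time_stride: int = 1,
                             keep_surfaces: bool = False,
                             f_max: float = 0.5) -> BispectralSurface:
    """Bispectrum magnitude integrals LL, LH, HH along the trajectory.

    The surface is evaluated on the LF-union-HF square [0.05, f_max]^2 (cost
    control; the band edges lie on the grid when ``df`` divides 0.05).
    ``time_stride`` decimates the evaluation times; integrals are
    step-expanded back to the full grid.
    """
    lf, hf = BANDS["LF"], BANDS["HF"]
    if f_max > hf[1] + 1e-12:
        raise ValueError(f"frequency region exceeds the kernel grid "
                         f"({f_max} > {hf[1]} Hz)")
    freqs = np.round(np.arange(lf[0], f_max + df / 2, df), 10)
    phi = basis.basis_matrix
    nt = traj.grid_times.size
    eval_idx = np.arange(0, nt, max(int(time_stride), 1))
    cols = {k: np.full(nt, np.nan) for k in ("LL", "LH", "HH")}
    surfaces = np.full((eval_idx.size, freqs.size, freqs.size), np.nan) \
        if keep_surfaces else None
    p1 = traj.g1.shape[1]
    p2 = traj.g2.shape[2]
    last = {k: np.nan for k in cols}
    for j, i in enumerate(eval_idx):
        mu = traj.mu_rr[i]
        ok = traj.converged[i] and np.isfinite(mu) and mu > 0
        if ok:
            k1 = traj.g1[i] @ phi[:p1]
            k2 = phi[:p2].T @ traj.g2[i] @ phi[:p2]
            sigma2 = traj.sigma_rr[i] ** 2
            try:
                surf = _bispectrum_surface(k1, k2, mu, sigma2, freqs)
            except ValueError:
                ok = False
        if ok:
            last = {"LL": _trapz2d(freqs, surf, lf, lf),
                    "LH": _trapz2d(freqs, surf, lf, hf),
                    "HH": _trapz2d(freqs, surf, hf, hf)}
            if keep_surfaces:
                surfaces[j] = surf
        for k in cols:
            cols[k][i] = last[k]
    # step-expand the strided values onto the full grid
    for k in cols:
        vals = cols[k]
        filled = pd.Series(vals).ffill().to_numpy()
        cols[k] = filled
    bands = pd.DataFrame({"time": traj.grid_times, **cols})
    return BispectralSurface(grid_times=traj.grid_times, freqs=freqs,
                             band_integrals=bands, magnitude=surfaces)
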