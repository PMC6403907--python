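"""Autocorrelation functions and relaxation-time spectra.

For a fluctuating observable ``X(t)`` (radial coordinate R or angle
Omega of one Si atom) the normalised autocorrelation function is

    A(t) = <dX(t') dX(t'+t)> / <dX^2>,    dX = X - <X>,

time-averaged over all overlapping origins with the biased (divide by
N) normalisation, so ``A(0) = 1`` exactly.  These functions are well
described by a single exponential; the relaxation time ``tau`` is
defined as the time at which ``A(t)`` first reaches ``1/e`` (located by
linear interpolation between the bracketing lags).  A least-squares
single-exponential fit is computed alongside as a QC quantity.  Series
whose ACF never reaches ``1/e`` within the maximum lag are censored:
they carry a lower bound equal to the max lag and are excluded from
means/dispersions but counted.

Layer spectra pool the per-atom ``tau`` values over all atoms of a
branching layer and over all replicas supplied (the study design uses
8 replicas).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import ConstantSignalError, EmptySpectrumError

E_INV = 1.0 / np.e


@dataclass
class AutocorrelationResult:
    lags: np.ndarray          # ps
    values: np.ndarray        # dimensionless, values[0] == 1
    kind: str = ""            # "radial" | "angular" | free-form
    atom_id: int | None = None


@dataclass
class TauEstimate:
    """1/e-crossing relaxation time with the exponential-fit QC value."""

    tau: float | None          # ps; None when censored
    censored: bool
    lower_bound: float         # = max lag when censored, else tau
    tau_expfit: float | None = None
    fit_rel_deviation: float | None = None


@dataclass
class RelaxationSpectrum:
    layer: int
    kind: str
    taus: np.ndarray           # resolved samples, ps
    mean_tau: float
    d_tau: float
    n_resolved: int
    n_censored: int
    hist_edges: np.ndarray
    hist_masses: np.ndarray


def autocorrelation(
    series: np.ndarray,
    spacing: float = 1.0,
    max_lag: int | None = None,
    kind: str = "",
    atom_id: int | None = None,
) -> AutocorrelationResult:
    """FFT-based normalised ACF up to ``max_lag`` frames.

    ``max_lag`` defaults to 10% of the series length.  A zero-variance
    series raises :class:`ConstantSignalError`.
    """
    x = np.asarray(series, dtype=np.float64)
    n = len(x)
    if max_lag is None:
        max_lag = max(1, n // 10)
    if n < 2 * max_lag:
        raise ValueError(f"series length {n} < 2 x max_lag {max_lag}")
    dx = x - x.mean()
    var = np.dot(dx, dx) / n
    if var <= 0 or not np.isfinite(var):
        raise ConstantSignalError("autocorrelation of a constant (zero-variance) series")
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(dx, nfft)
    acov = np.fft.irfft(spec * np.conj(spec), nfft)[: max_lag + 1] / n
    values = acov / acov[0]
    lags = spacing * np.arange(max_lag + 1)
    return AutocorrelationResult(lags=lags, values=values, kind=kind, atom_id=atom_id)


def autocorrelation_bruteforce(series: np.ndarray, max_lag: int) -> np.ndarray:
    """Direct double-loop estimator (oracle for the FFT path)."""
    x = np.asarray(series, dtype=np.float64)
    n = len(x)
    dx = x - x.mean()
    out = np.empty(max_lag + 1)
    for lag in range(max_lag + 1):
        s = 0.0
        for t0 in range(n - lag):
            s += dx[t0] * dx[t0 + lag]
        out[lag] = s / n
    return out / out[0]


def relaxation_time(acf: AutocorrelationResult, fit: bool = True) -> TauEstimate:
    """First 1/e crossing of the ACF; censored if never reached."""
    a = acf.values
    t = acf.lags
    below = np.flatnonzero(a < E_INV)
    if len(below) == 0:
        return TauEstimate(tau=None, censored=True, lower_bound=float(t[-1]))
    k = int(below[0])
    if k == 0:
        tau = float(t[0])
    else:
        frac = (a[k - 1] - E_INV) / (a[k - 1] - a[k])
        tau = float(t[k - 1] + frac * (t[k] - t[k - 1]))
    tau_fit = None
    rel_dev = None
    if fit:
        # fit exp(-t/tau) over the initial decay (down to A ~ 0.05)
        stop = np.flatnonzero(a < 0.05)
        stop = int(stop[0]) if len(stop) else len(a)
        stop = max(stop, min(3, len(a)))
        try:
            popt, _ = curve_fit(
                lambda tt, tau_: np.exp(-tt / tau_),
                t[:stop],
                a[:stop],
                p0=[max(tau, 1e-9)],
                maxfev=2000,
            )
            tau_fit = float(popt[0])
            rel_dev = abs(tau_fit - tau) / tau if tau > 0 else None
        except Exception:
            pass
    return TauEstimate(tau=tau, censored=False, lower_bound=tau,
                       tau_expfit=tau_fit, fit_rel_deviation=rel_dev)


def layer_spectrum(
    estimates: list[TauEstimate],
    layer: int,
    kind: str = "",
    n_bins: int = 30,
) -> RelaxationSpectrum:
    """Pool per-atom-per-replica tau samples of one layer.

    Censored samples are excluded from the mean/dispersion and counted;
    a layer with no resolved sample raises :class:`EmptySpectrumError`.
    The histogram uses ``n_bins`` log-spaced bins across the observed
    range.
    """
    taus = np.array([e.tau for e in estimates if not e.censored], dtype=np.float64)
    n_cens = sum(1 for e in estimates if e.censored)
    if len(taus) == 0:
        raise EmptySpectrumError(f"all {n_cens} tau samples of layer {layer} are censored")
    lo, hi = taus.min(), taus.max()
    if hi <= lo:
        lo, hi = lo * 0.9 if lo > 0 else 0.1, hi * 1.1 if hi > 0 else 1.0
    lo = max(lo, 1e-12)
    edges = np.geomspace(lo, hi, n_bins + 1)
    edges[0] = min(edges[0], taus.min())
    edges[-1] = max(edges[-1], taus.max())
    masses, _ = np.histogram(taus, bins=edges)
    return RelaxationSpectrum(
        layer=layer,
        kind=kind,
        taus=taus,
        mean_tau=float(taus.mean()),
        d_tau=float(taus.std()),
        n_resolved=int(len(taus)),
        n_censored=int(n_cens),
        hist_edges=edges,
        hist_masses=masses / masses.sum(),
    )


def relaxation_table(series_sets, spacing: float, max_lag: int | None = None) -> pd.DataFrame:
    """Per-layer relaxation summary over one or more replica series sets.

    ``series_sets`` is a list of :func:`~dendromd.mobility.mobility_series_set`
    outputs (one per replica).  Returns rows (layer, kind, mean_tau,
    D_tau, n_resolved, n_censored).
    """
    from collections import defaultdict

    by_layer: dict = defaultdict(lambda: {"R": [], "Omega": []})
    for sset in series_sets:
        for s in sset:
            for kind, sig in (("R", s.r), ("Omega", np.where(s.valid, s.omega, np.nan))):
                sig = sig[np.isfinite(sig)]
                if len(sig) < 20 or np.std(sig) == 0:
                    continue
                acf = autocorrelation(sig, spacing=spacing, max_lag=max_lag)
                by_layer[s.layer][kind].append(relaxation_time(acf, fit=False))
    rows = []
    for layer in sorted(by_layer):
        for kind in ("R", "Omega"):
            ests = by_layer[layer][kind]
            if not ests:
                continue
            try:
                spec = layer_spectrum(ests, layer, kind=kind)
                rows.append(
                    {
                        "layer": layer,
                        "kind": kind,
                        "mean_tau_ps": spec.mean_tau,
                        "D_tau_ps": spec.d_tau,
                        "n_resolved": spec.n_resolved,
                        "n_censored": spec.n_censored,
                    }
                )
            except EmptySpectrumError:
                rows.append(
                    {
                        "layer": layer,
                        "kind": kind,
                        "mean_tau_ps": float("nan"),
                        "D_tau_ps": float("nan"),
                        "n_resolved": 0,
                        "n_censored": len(ests),
                    }
                )
    return pd.DataFrame(rows)
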