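"""Kinetics fitting: single-component FCS diffusion fits and FRAP
normalization / mono-exponential recovery fits, with the R^2 exclusion rule."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .correlation import CorrelationCurve

__all__ = [
    "FcsFit",
    "FrapFit",
    "fcs_diffusion_model",
    "fit_fcs",
    "normalize_frap",
    "fit_frap",
    "dynamics_profile",
]


def fcs_diffusion_model(
    lag: np.ndarray, n: float, tau_d: float, s: float, g_inf: float
) -> np.ndarray:
    """Single-component 3D diffusion autocorrelation (fluctuation part).

    g(tau) = (1/N) / (1 + tau/tau_D) / sqrt(1 + tau/(s^2 tau_D)) + G_inf
    """
    x = lag / tau_d
    return (1.0 / n) / (1.0 + x) / np.sqrt(1.0 + x / s**2) + g_inf


@dataclass
class FcsFit:
    n: float
    tau_d: float
    s: float
    g_inf: float
    r_squared: float
    converged: bool
    s_fixed: bool = False


def fit_fcs(curve: CorrelationCurve, fix_s: float | None = None) -> FcsFit:
    """Least-squares fit of the single-component diffusion model to a curve.

    ``fix_s`` pins the structural parameter (recommended; it is poorly
    constrained and fixing it hardly moves tau_D).  Non-convergence or
    non-positive fitted N/tau_D returns a flagged fit with nan parameters.
    """
    lags = curve.lags
    g = curve.values
    failed = FcsFit(math.nan, math.nan, math.nan, math.nan, math.nan, False, fix_s is not None)
    if lags.size < 8:
        return failed

    # scale-free initial guesses: amplitude from the earliest lags, tau_D
    # from where the curve drops to half of it, offset from the tail
    g_inf0 = float(np.median(g[-max(3, lags.size // 10):]))
    amp0 = float(np.median(g[: max(3, lags.size // 20)])) - g_inf0
    if amp0 <= 0:
        return failed
    half = g_inf0 + amp0 / 2.0
    below = np.nonzero(g <= half)[0]
    tau0 = float(lags[below[0]]) if below.size else float(np.sqrt(lags[0] * lags[-1]))
    n0 = 1.0 / amp0
    s0 = fix_s if fix_s is not None else 5.0

    if fix_s is not None:

        def model(lag, n, tau_d, g_inf):
            return fcs_diffusion_model(lag, n, tau_d, fix_s, g_inf)

        p0 = [n0, tau0, g_inf0]
        bounds = ([1e-12, 1e-12, -np.inf], [np.inf, np.inf, np.inf])
    else:
        model = fcs_diffusion_model
        p0 = [n0, tau0, s0, g_inf0]
        bounds = ([1e-12, 1e-12, 1e-3, -np.inf], [np.inf, np.inf, 1e4, np.inf])

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(model, lags, g, p0=p0, bounds=bounds, maxfev=20000)
    except (RuntimeError, ValueError):
        return failed

    if fix_s is not None:
        n_fit, tau_fit, ginf_fit = popt
        s_fit = fix_s
    else:
        n_fit, tau_fit, s_fit, ginf_fit = popt
    if n_fit <= 0 or tau_fit <= 0:
        return failed
    resid = g - fcs_diffusion_model(lags, n_fit, tau_fit, s_fit, ginf_fit)
    ss_tot = float(np.sum((g - g.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else math.nan
    return FcsFit(float(n_fit), float(tau_fit), float(s_fit), float(ginf_fit), r2, True, fix_s is not None)


@dataclass
class FrapFit:
    """Mono-exponential recovery fit of a normalized FRAP curve.

    ``valid`` is False when R^2 <= 0.7 (exclusion rule) or the fit failed.
    """

    mobile_fraction: float
    rate: float  # 1/s
    tau_half: float  # s
    r_squared: float
    valid: bool


def normalize_frap(
    time: np.ndarray,
    intensity: np.ndarray,
    background: np.ndarray,
    n_prebleach: int = 10,
    n_prebleach_mean: int = 9,
) -> tuple[np.ndarray, np.ndarray]:
    """Background-subtract and normalize a FRAP trace.

    The bleach frame is the frame at index ``n_prebleach`` (acquisition
    continues immediately after bleaching).  The pre-bleach level is the
    mean of the ``n_prebleach_mean`` frames immediately before bleaching.
    Returns ``(t, I)`` with t re-zeroed at the bleach frame, the pre-bleach
    mean normalized to 1 and the bleach-frame value to 0; only the bleach
    frame onward is returned.
    """
    time = np.asarray(time, float)
    intensity = np.asarray(intensity, float)
    background = np.asarray(background, float)
    if not time.shape == intensity.shape == background.shape:
        raise ValueError("time, intensity and background must have equal shapes")
    if time.size <= n_prebleach + 1:
        raise ValueError("trace has no post-bleach frames")
    if n_prebleach < n_prebleach_mean:
        raise ValueError("need at least n_prebleach_mean frames before the bleach")

    i_un = intensity - background
    pre = float(np.mean(i_un[n_prebleach - n_prebleach_mean : n_prebleach]))
    bleach = float(i_un[n_prebleach])
    if pre <= bleach:
        raise ValueError("no dynamic range: pre-bleach level does not exceed bleach level")
    norm = (i_un[n_prebleach:] - bleach) / (pre - bleach)
    t = time[n_prebleach:] - time[n_prebleach]
    return t, norm


def fit_frap(time: np.ndarray, normalized: np.ndarray, r2_min: float = 0.7) -> FrapFit:
    """Fit I(t) = M (1 - exp(-rate t)) to a normalized post-bleach curve."""
    time = np.asarray(time, float)
    normalized = np.asarray(normalized, float)
    if time.size != normalized.size:
        raise ValueError("time and curve must have equal length")
    failed = FrapFit(math.nan, math.nan, math.nan, math.nan, False)
    if time.size < 5:
        return failed

    def model(t, m, rate):
        return m * (1.0 - np.exp(-rate * t))

    tail = normalized[-max(2, normalized.size // 10):]
    m0 = float(np.clip(np.mean(tail), 1e-3, 1.5))
    above = np.nonzero(normalized >= 0.5 * m0)[0]
    t_half0 = float(time[above[0]]) if above.size and time[above[0]] > 0 else float(time[-1]) / 4
    rate0 = math.log(2.0) / max(t_half0, 1e-9)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                model,
                time,
                normalized,
                p0=[m0, rate0],
                bounds=([0.0, 1e-12], [1.5, np.inf]),
                maxfev=20000,
            )
    except (RuntimeError, ValueError):
        return failed
    m_fit, rate_fit = float(popt[0]), float(popt[1])
    resid = normalized - model(time, m_fit, rate_fit)
    ss_tot = float(np.sum((normalized - normalized.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
    tau_half = -math.log(0.5) / rate_fit
    return FrapFit(m_fit, rate_fit, tau_half, r2, bool(r2 > r2_min))


def dynamics_profile(fits_by_protein: dict, min_fits: int = 3):
    """Per-protein median dynamics from FRAP (and optionally FCS) fits.

    ``fits_by_protein`` maps a protein name to a list of records, each a
    mapping with keys ``tau_half`` and ``mobile_fraction`` (optionally
    ``tau_d``) and an optional ``valid`` flag.  Proteins with fewer than
    ``min_fits`` valid records are dropped with a warning.  Returns a
    :class:`fccskit.stats_network.DynamicsProfile`.
    """
    from .stats_network import DynamicsProfile

    medians: dict[str, dict[str, float]] = {}
    for protein in sorted(fits_by_protein):
        records = [r for r in fits_by_protein[protein] if r.get("valid", True)]
        if len(records) < min_fits:
            warnings.warn(
                f"protein {protein!r} has {len(records)} valid fits (< {min_fits}); excluded",
                stacklevel=2,
            )
            continue

        def col(key):
            vals = np.array([r[key] for r in records if key in r], float)
            return vals[np.isfinite(vals)]

        row: dict[str, float] = {}
        for key in ("tau_half", "mobile_fraction", "tau_d"):
            vals = col(key)
            if vals.size:
                med = float(np.median(vals))
                row[key] = med
                row[key + "_mad"] = float(np.median(np.abs(vals - med)))
        medians[protein] = row
    return DynamicsProfile(medians)
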