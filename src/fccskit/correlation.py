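"""Auto/cross-correlation of photon-count traces and robust curve summaries.

Curves are stored in the *fluctuation* convention

    g(tau) = <dI_x(t) dI_y(t+tau)> / (<I_x><I_y>)

i.e. without the ``+1`` baseline, so that a flat uncorrelated signal gives
g = 0 and the particle number is ``N = 1/g(0)`` directly.

The multi-tau correlator computes g on a quasi-logarithmic lag grid: the
first stage holds ``bins_per_stage`` linearly spaced lags at the native bin
width; each subsequent stage rebins the trace pairwise (doubling the bin
width) and contributes the upper half of the lag range, doubling lag
coverage per stage at constant cost.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np

__all__ = [
    "IntensityTrace",
    "CorrelationCurve",
    "CurveSummary",
    "AMPLITUDE_WINDOW",
    "OFFSET_WINDOW",
    "multitau_correlate",
    "average_curves",
    "summarize_curve",
    "read_curve_csv",
    "write_curve_csv",
]

#: Lag window (s, closed interval) over which curve amplitudes are medianed.
AMPLITUDE_WINDOW = (25.6e-6, 81.92e-6)
#: Lag window (s, closed interval) over which the curve offset is medianed.
OFFSET_WINDOW = (157.3e-3, 838.9e-3)


@dataclass
class IntensityTrace:
    """A single-channel binned photon-count trace.

    Parameters
    ----------
    bin_width : float
        Width of one counting bin in seconds.
    counts : numpy.ndarray
        Photon counts (or analog intensity) per bin.
    channel : str
        Channel label, ``"G"`` or ``"R"``.
    dark_rate : float
        Detector dark count rate in counts/s (metadata, used by QC).
    """

    bin_width: float
    counts: np.ndarray
    channel: str = "G"
    dark_rate: float = 0.0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 1 or self.counts.size < 2:
            raise ValueError("trace must be a 1-D array with at least 2 bins")
        if self.bin_width <= 0:
            raise ValueError("bin width must be positive")
        if self.channel not in ("G", "R"):
            raise ValueError(f"channel must be 'G' or 'R', got {self.channel!r}")

    @property
    def duration(self) -> float:
        """Trace duration in seconds."""
        return self.bin_width * self.counts.size

    @property
    def count_rate(self) -> float:
        """Mean count rate in counts/s (total counts over duration)."""
        return float(self.counts.sum()) / self.duration


@dataclass
class CorrelationCurve:
    """A correlation curve g(tau) for one channel pair on a lag grid."""

    lags: np.ndarray
    values: np.ndarray
    channel_pair: str = "GG"  # GG | RR | RG
    n_traces: int = 1

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.lags.shape != self.values.shape:
            raise ValueError("lags and values must have matching shapes")
        if self.lags.size and np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be strictly increasing")
        if self.channel_pair not in ("GG", "RR", "RG"):
            raise ValueError(f"channel pair must be GG, RR or RG, got {self.channel_pair!r}")


@dataclass
class CurveSummary:
    """Robust summary of one curve: windowed medians, MAD, clamped amplitude."""

    amplitude: float  # median of g over the amplitude window
    offset: float  # median of g over the offset window
    mad: float  # median |g_i - amplitude| over amplitude-window points
    g0: float  # amplitude - offset; clamped at 0 for RG curves
    n_amplitude_points: int
    n_offset_points: int
    channel_pair: str = "GG"


def _direct_g(x: np.ndarray, y: np.ndarray, k: int, mx: float, my: float) -> float:
    # <x(t) y(t+k)> over the overlapping segment, normalized by global means.
    n = x.size - k
    num = float(np.dot(x[:n], y[k:])) / n
    return num / (mx * my) - 1.0


def _rebin(x: np.ndarray) -> np.ndarray:
    n = x.size - (x.size % 2)
    return x[0:n:2] + x[1:n:2]


def multitau_correlate(
    trace_x: IntensityTrace,
    trace_y: IntensityTrace | None = None,
    bins_per_stage: int = 16,
    max_lag: float | None = None,
) -> CorrelationCurve:
    """Multi-tau correlation of two traces (autocorrelation if ``trace_y`` is None).

    Cross-correlations are the symmetric average of the (x, y) and (y, x)
    estimates.  Lags within the first stage coincide exactly with a direct
    (brute-force) lag-by-lag estimator; later stages operate on pairwise
    rebinned copies of the traces.

    Raises
    ------
    ValueError
        On mismatched trace lengths/bin widths, odd ``bins_per_stage``, or a
        zero-mean channel (normalization undefined).
    """
    auto = trace_y is None or trace_y is trace_x
    ty = trace_x if auto else trace_y
    if trace_x.counts.size != ty.counts.size:
        raise ValueError("traces must have equal length")
    if trace_x.bin_width != ty.bin_width:
        raise ValueError("traces must have equal bin width")
    if bins_per_stage < 2 or bins_per_stage % 2:
        raise ValueError("bins_per_stage must be even and >= 2")

    x = trace_x.counts.astype(float)
    y = x if auto else ty.counts.astype(float)
    if x.mean() == 0.0 or y.mean() == 0.0:
        raise ValueError("zero-mean channel: correlation normalization undefined")

    pair = trace_x.channel * 2 if auto else "RG"
    m = bins_per_stage
    dt = trace_x.bin_width
    lags: list[float] = []
    vals: list[float] = []
    stage = 0
    while x.size > m:
        width = dt * (1 << stage)
        ks = range(1, m + 1) if stage == 0 else range(m // 2 + 1, m + 1)
        mx, my = x.mean(), y.mean()
        stop = False
        for k in ks:
            lag = k * width
            if max_lag is not None and lag > max_lag:
                stop = True
                break
            if k >= x.size:
                stop = True
                break
            g = _direct_g(x, y, k, mx, my)
            if not auto:
                g = 0.5 * (g + _direct_g(y, x, k, my, mx))
            lags.append(lag)
            vals.append(g)
        if stop:
            break
        x = _rebin(x)
        y = x if auto else _rebin(y)
        stage += 1

    return CorrelationCurve(np.array(lags), np.array(vals), channel_pair=pair, n_traces=1)


def average_curves(curves: list[CorrelationCurve]) -> CorrelationCurve:
    """Pointwise mean of curves sharing a lag grid and channel pair."""
    if not curves:
        raise ValueError("cannot average an empty list of curves")
    ref = curves[0]
    for c in curves[1:]:
        if c.channel_pair != ref.channel_pair:
            raise ValueError("cannot average curves with different channel pairs")
        if c.lags.shape != ref.lags.shape or not np.allclose(c.lags, ref.lags, rtol=1e-12, atol=0):
            raise ValueError("cannot average curves on different lag grids")
    values = np.mean([c.values for c in curves], axis=0)
    return CorrelationCurve(
        ref.lags.copy(),
        values,
        channel_pair=ref.channel_pair,
        n_traces=sum(c.n_traces for c in curves),
    )


def summarize_curve(
    curve: CorrelationCurve,
    amplitude_window: tuple[float, float] = AMPLITUDE_WINDOW,
    offset_window: tuple[float, float] = OFFSET_WINDOW,
    min_points: int = 5,
) -> CurveSummary:
    """Windowed median amplitude/offset and amplitude-window MAD of a curve.

    The amplitude is the median of g over the closed amplitude window, the
    offset the median over the closed offset window, and the MAD the median
    absolute deviation of amplitude-window points from the amplitude.  For
    RG curves the baseline-subtracted amplitude is clamped at zero (a
    slightly negative cross-amplitude means "no association detected").
    """
    lo, hi = amplitude_window
    in_amp = (curve.lags >= lo) & (curve.lags <= hi)
    lo, hi = offset_window
    in_off = (curve.lags >= lo) & (curve.lags <= hi)
    n_amp, n_off = int(in_amp.sum()), int(in_off.sum())
    if n_amp < min_points or n_off < min_points:
        raise ValueError(
            f"lag grid does not cover the summary windows with >= {min_points} points "
            f"(amplitude window: {n_amp}, offset window: {n_off})"
        )
    amp_points = curve.values[in_amp]
    amplitude = float(np.median(amp_points))
    offset = float(np.median(curve.values[in_off]))
    mad = float(np.median(np.abs(amp_points - amplitude)))
    g0 = amplitude - offset
    if curve.channel_pair == "RG":
        g0 = max(g0, 0.0)
    return CurveSummary(
        amplitude=amplitude,
        offset=offset,
        mad=mad,
        g0=g0,
        n_amplitude_points=n_amp,
        n_offset_points=n_off,
        channel_pair=curve.channel_pair,
    )


def write_curve_csv(curve: CorrelationCurve, path) -> None:
    """Write a curve as CSV with a channel-pair comment header."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# channel_pair={curve.channel_pair} n_traces={curve.n_traces}\n")
        fh.write("lag_s,g_value\n")
        for lag, g in zip(curve.lags, curve.values):
            fh.write(f"{float(lag)!r},{float(g)!r}\n")


def read_curve_csv(path) -> CorrelationCurve:
    """Read a curve written by :func:`write_curve_csv` (or any lag_s,g_value CSV)."""
    pair, n_traces = "GG", 1
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    lines = text.splitlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            for tok in line.lstrip("# ").split():
                key, _, val = tok.partition("=")
                if key == "channel_pair":
                    pair = val
                elif key == "n_traces":
                    n_traces = int(val)
            body_start = i + 1
        else:
            break
    import pandas as pd

    df = pd.read_csv(io.StringIO("\n".join(lines[body_start:])), float_precision="round_trip")
    for col in ("lag_s", "g_value"):
        if col not in df.columns:
            raise ValueError(f"curve CSV is missing required column {col!r}")
    return CorrelationCurve(
        df["lag_s"].to_numpy(float), df["g_value"].to_numpy(float), channel_pair=pair, n_traces=n_traces
    )
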