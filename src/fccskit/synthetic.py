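"""Synthetic inputs with known ground truth.

Contains a particle-based Brownian-dynamics photon-trace simulator (two
diffusing labeled species plus their complex moving through 3D-Gaussian
detection volumes, Poisson shot noise, dark-red fraction, green-to-red
bleedthrough), a closed-form single-component correlation curve, a FRAP
recovery-curve generator, heavy-tailed association-score cohorts, and the
13-protein / 11-edge association-network fixture.

The simulator is deliberately independent of the correlation and fitting
code paths so it can serve as a physics oracle for them.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import asdict, dataclass

import numpy as np

from ._rng import derive_rng
from .correlation import CorrelationCurve, IntensityTrace

__all__ = [
    "SimulationParams",
    "FrapSimParams",
    "FrapTrace",
    "NetworkFixture",
    "simulate_ffs_traces",
    "closed_form_fcs_curve",
    "simulate_frap_curve",
    "simulate_score_cohorts",
    "make_network_fixture",
    "write_trace_csv",
    "read_trace_csv_sidecar",
    "write_frap_csv",
    "write_network_tsv",
]


@dataclass
class SimulationParams:
    """Ground truth for a two-color fluorescence-fluctuation simulation.

    Concentrations are particles per fl (= per um^3), diffusion coefficients
    in cm^2/s, detection-volume radii in um, brightnesses in counts/s per
    fluorophore at beam center.  The box is a periodic cube of edge
    ``box_size`` um, which must be at least 8x the largest axial radius so
    that boundary images contribute negligibly.
    """

    conc_red: float = 0.0  # unbound red, particles/fl
    conc_green: float = 0.0  # unbound green, particles/fl
    conc_complex: float = 0.0  # red-green complex, particles/fl
    d_red: float = 1e-7  # cm^2/s
    d_green: float = 1e-7
    d_complex: float = 1e-7
    omega0_g: float = 0.25  # um
    z0_g: float = 0.375  # um
    omega0_r: float = 0.25  # um
    z0_r: float = 0.375  # um
    channel_offset: float = 0.0  # um, red-volume center shift along x
    brightness_g: float = 30000.0  # counts/s at beam center
    brightness_r: float = 30000.0
    dark_red_fraction: float = 0.0
    bleedthrough: float = 0.0  # green -> red fraction
    dark_rate: float = 0.0  # counts/s per channel
    bin_width: float = 2e-6  # s
    duration: float = 10.0  # s
    n_traces: int = 10
    box_size: float = 3.0  # um, cubic edge
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "d_red",
            "d_green",
            "d_complex",
            "omega0_g",
            "z0_g",
            "omega0_r",
            "z0_r",
            "brightness_g",
            "brightness_r",
            "bin_width",
            "duration",
            "box_size",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("conc_red", "conc_green", "conc_complex", "dark_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("dark_red_fraction", "bleedthrough"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_traces < 1:
            raise ValueError("n_traces must be >= 1")
        z_max = max(self.z0_g, self.z0_r)
        if self.box_size < 8 * z_max:
            raise ValueError(
                f"box edge {self.box_size} um < 8 * z0 = {8 * z_max} um: "
                "periodic-boundary artifacts would not be negligible"
            )
        tau_fast = min(self.omega0_g, self.omega0_r) ** 2 / (
            4 * max(self.d_red, self.d_green, self.d_complex) * 1e8
        )  # s (um^2 / (um^2/s))
        if self.bin_width > tau_fast / 10:
            warnings.warn(
                f"bin width {self.bin_width:g} s exceeds tau_D/10 = {tau_fast / 10:g} s "
                "of the fastest species: transit shapes will be under-sampled",
                stacklevel=2,
            )

    @property
    def box_volume_fl(self) -> float:
        return self.box_size**3  # 1 um^3 = 1 fl


def _gaussian_weight(traj: np.ndarray, omega0: float, z0: float, x_shift: float) -> np.ndarray:
    # traj has shape (particles, 3, bins); returns per-particle weights
    x = traj[:, 0] - x_shift if x_shift else traj[:, 0]
    y = traj[:, 1]
    z = traj[:, 2]
    # exp(-2 (x^2+y^2)/w0^2 - 2 z^2/z0^2), built in place to limit temporaries
    arg = x * x
    arg += y * y
    arg *= np.float32(-2.0 / omega0**2)
    zz = z * z
    zz *= np.float32(2.0 / z0**2)
    arg -= zz
    return np.exp(arg, out=arg)


def _simulate_one_trace(p: SimulationParams, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    n_bins = int(round(p.duration / p.bin_width))
    dt = p.bin_width
    box = p.box_size
    same_psf = (
        p.omega0_g == p.omega0_r and p.z0_g == p.z0_r and p.channel_offset == 0.0
    )

    # (count, D um^2/s, emits green, emits red)
    species = [
        (int(round(p.conc_green * p.box_volume_fl)), p.d_green * 1e8, True, False),
        (int(round(p.conc_red * p.box_volume_fl)), p.d_red * 1e8, False, True),
        (int(round(p.conc_complex * p.box_volume_fl)), p.d_complex * 1e8, True, True),
    ]

    sum_g = np.zeros(n_bins)  # sum of green detection weights per bin
    sum_r = np.zeros(n_bins)
    for count, d_um, in_green, in_red in species:
        if count == 0:
            continue
        pos = rng.uniform(-box / 2, box / 2, size=(count, 3, 1)).astype(np.float32)
        bright = (
            rng.random(count) >= p.dark_red_fraction if in_red else np.ones(count, bool)
        )
        step_sd = math.sqrt(2.0 * d_um * dt)
        chunk = max(1, int(6e6 / (3 * count)))
        start = 0
        while start < n_bins:
            stop = min(start + chunk, n_bins)
            # layout (particles, 3, bins): cumulative sum over the (contiguous)
            # time axis turns per-bin steps into positions
            steps = rng.standard_normal((count, 3, stop - start), dtype=np.float32)
            steps *= np.float32(step_sd)
            steps[:, :, 0] += pos[:, :, 0]
            traj = np.cumsum(steps, axis=2, out=steps)
            traj -= box * np.round(traj * np.float32(1.0 / box))  # periodic wrap
            pos = traj[:, :, -1:].copy()
            if in_green:
                wg = _gaussian_weight(traj, p.omega0_g, p.z0_g, 0.0)
                sum_g[start:stop] += wg.sum(axis=0)
            if in_red and bright.any():
                if in_green and same_psf and p.dark_red_fraction == 0.0:
                    sum_r[start:stop] += wg.sum(axis=0)
                else:
                    wr = _gaussian_weight(
                        traj[bright], p.omega0_r, p.z0_r, p.channel_offset
                    )
                    sum_r[start:stop] += wr.sum(axis=0)
            start = stop

    exp_g_signal = p.brightness_g * dt * sum_g
    exp_r_signal = p.brightness_r * dt * sum_r
    exp_g = exp_g_signal + p.dark_rate * dt
    exp_r = exp_r_signal + p.bleedthrough * exp_g_signal + p.dark_rate * dt
    counts_g = rng.poisson(exp_g).astype(float)
    counts_r = rng.poisson(exp_r).astype(float)
    return counts_g, counts_r


def simulate_ffs_traces(params: SimulationParams) -> list[tuple[IntensityTrace, IntensityTrace]]:
    """Simulate ``params.n_traces`` two-channel photon-count trace pairs.

    Particles take Gaussian Brownian steps (sd = sqrt(2 D dt) per axis) in a
    periodic box; the expected count per bin is the brightness-weighted sum
    of 3D-Gaussian detection weights plus dark counts (and green-to-red
    bleedthrough), realized as Poisson draws.  The same seed reproduces the
    output bit for bit.
    """
    out = []
    for i in range(params.n_traces):
        rng = derive_rng(params.seed, "ffs-trace", i)
        counts_g, counts_r = _simulate_one_trace(params, rng)
        out.append(
            (
                IntensityTrace(params.bin_width, counts_g, "G", dark_rate=params.dark_rate),
                IntensityTrace(params.bin_width, counts_r, "R", dark_rate=params.dark_rate),
            )
        )
    return out


def closed_form_fcs_curve(
    n: float, tau_d: float, s: float, g_inf: float, lags: np.ndarray
) -> CorrelationCurve:
    """Exact single-component diffusion autocorrelation on a lag grid.

    g(tau) = (1/N)/(1 + tau/tau_D)/sqrt(1 + tau/(s^2 tau_D)) + G_inf
    (fluctuation convention, i.e. without the +1 baseline).
    """
    if n <= 0 or tau_d <= 0 or s <= 0:
        raise ValueError("N, tau_D and s must be positive")
    lags = np.asarray(lags, float)
    x = lags / tau_d
    g = (1.0 / n) / (1.0 + x) / np.sqrt(1.0 + x / s**2) + g_inf
    return CorrelationCurve(lags, g, channel_pair="GG")


@dataclass
class FrapSimParams:
    """Ground truth for a simulated FRAP recovery measurement."""

    mobile_fraction: float = 0.8
    tau_half: float = 30.0  # s
    frame_interval: float = 3.0  # s
    n_prebleach: int = 10
    post_duration: float = 180.0  # s
    pre_level: float = 100.0  # a.u.
    background_level: float = 10.0  # a.u.
    noise_sd: float = 0.0  # a.u., additive Gaussian
    bleach_floor: float = 0.0  # residual fraction left by the bleach
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.mobile_fraction <= 1:
            raise ValueError("mobile fraction must be in [0, 1]")
        if self.tau_half <= 0 or self.frame_interval <= 0 or self.post_duration <= 0:
            raise ValueError("tau_half, frame interval and post duration must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")
        if not 0 <= self.bleach_floor < 1:
            raise ValueError("bleach floor must be in [0, 1)")
        if self.n_prebleach < 1:
            raise ValueError("need at least one pre-bleach frame")


@dataclass
class FrapTrace:
    time: np.ndarray  # s
    intensity: np.ndarray  # a.u., raw (background included)
    background: np.ndarray  # a.u.
    bleach_index: int  # index of the first post-bleach frame


def simulate_frap_curve(params: FrapSimParams) -> FrapTrace:
    """Simulate a raw FRAP trace plus its background trace.

    Pre-bleach frames sit at the pre-bleach level; from the bleach frame
    (t = 0) on, the raw intensity follows
    background + (pre - background) * [floor + (1 - floor) * M (1 - e^(-rate t))]
    with rate = -ln(0.5)/tau_half.  Gaussian noise of sd ``noise_sd`` is
    added to both traces.
    """
    p = params
    rng = derive_rng(p.seed, "frap")
    n_post = int(round(p.post_duration / p.frame_interval)) + 1
    n_total = p.n_prebleach + n_post
    time = np.arange(n_total) * p.frame_interval
    t_post = np.arange(n_post) * p.frame_interval
    rate = -math.log(0.5) / p.tau_half
    recovery = p.bleach_floor + (1 - p.bleach_floor) * p.mobile_fraction * (
        1.0 - np.exp(-rate * t_post)
    )
    intensity = np.empty(n_total)
    intensity[: p.n_prebleach] = p.pre_level
    intensity[p.n_prebleach :] = p.background_level + (p.pre_level - p.background_level) * recovery
    background = np.full(n_total, p.background_level)
    if p.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, p.noise_sd, n_total)
        background = background + rng.normal(0.0, p.noise_sd, n_total)
    return FrapTrace(time, intensity, background, bleach_index=p.n_prebleach)


def simulate_score_cohorts(
    n_pair: int, n_neg: int, shift: float, spread: float, seed: int = 0, df: float = 3.0
) -> tuple[np.ndarray, np.ndarray]:
    """Heavy-tailed (location-scale t) score cohorts with a known median shift.

    The negative-control cohort is centered at 0, the pair cohort at
    ``shift``; both have scale ``spread``.  Returns (pair, negative).
    """
    if n_pair < 5 or n_neg < 5:
        raise ValueError("cohorts need at least 5 scores each")
    if spread <= 0:
        raise ValueError("spread must be positive")
    rng = derive_rng(seed, "score-cohorts")
    pair = shift + spread * rng.standard_t(df, n_pair)
    neg = spread * rng.standard_t(df, n_neg)
    return pair, neg


@dataclass
class NetworkFixture:
    """Reference association network: 13 proteins, 11 replicated edges."""

    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("fixture nodes must be unique")
        for a, b in self.edges:
            if a == b:
                raise ValueError("self-loop in fixture edges")
            if a not in self.nodes or b not in self.nodes:
                raise ValueError(f"edge ({a}, {b}) references unknown node")


_FIXTURE_NODES = (
    "CAS",
    "CSK",
    "FAK",
    "ILK",
    "PINCH",
    "VASP",
    "paxillin",
    "talin",
    "tensin",
    "vinculin",
    "zyxin",
    "α-actinin",
    "α-parvin",
)

_FIXTURE_EDGES = (
    ("ILK", "PINCH"),
    ("ILK", "α-parvin"),
    ("PINCH", "α-parvin"),
    ("CAS", "FAK"),
    ("CAS", "paxillin"),
    ("FAK", "paxillin"),
    ("paxillin", "vinculin"),
    ("VASP", "zyxin"),
    ("VASP", "α-actinin"),
    ("VASP", "vinculin"),
    ("CAS", "zyxin"),
)


def make_network_fixture() -> NetworkFixture:
    """The 13-protein adhesion-component fixture with its 11 reference edges."""
    return NetworkFixture(nodes=_FIXTURE_NODES, edges=_FIXTURE_EDGES)


# ---------------------------------------------------------------------------
# plain-text writers/readers for the simulated artifacts


def write_trace_csv(path, green: IntensityTrace, red: IntensityTrace, params=None) -> None:
    """Write a two-channel trace as (time_s, counts_green, counts_red) CSV.

    When ``params`` is given, a ``<path>.json`` sidecar records it.
    """
    if green.counts.size != red.counts.size or green.bin_width != red.bin_width:
        raise ValueError("green and red traces must share length and bin width")
    t = np.arange(green.counts.size) * green.bin_width
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("time_s,counts_green,counts_red\n")
        for ti, cg, cr in zip(t, green.counts, red.counts):
            fh.write(f"{float(ti)!r},{cg:g},{cr:g}\n")
    if params is not None:
        with open(str(path) + ".json", "w", encoding="utf-8") as fh:
            json.dump(asdict(params), fh, indent=2)


def read_trace_csv_sidecar(path) -> SimulationParams:
    with open(str(path) + ".json", "r", encoding="utf-8") as fh:
        return SimulationParams(**json.load(fh))


def write_frap_csv(path, trace: FrapTrace) -> None:
    """Write a FRAP measurement as (time_s, intensity, background) CSV plus a
    JSON sidecar holding the bleach-frame index."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("time_s,intensity,background\n")
        for t, i, b in zip(trace.time, trace.intensity, trace.background):
            fh.write(f"{float(t)!r},{float(i)!r},{float(b)!r}\n")
    with open(str(path) + ".json", "w", encoding="utf-8") as fh:
        json.dump({"bleach_index": trace.bleach_index}, fh)


def write_network_tsv(path, fixture: NetworkFixture) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("protein_a\tprotein_b\n")
        for a, b in fixture.edges:
            fh.write(f"{a}\t{b}\n")
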