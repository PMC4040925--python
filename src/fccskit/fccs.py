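"""Per-measurement FCCS quantities: particle numbers, concentrations,
apparent association constant, association score, and QC filtering."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy.constants import N_A

from .calibration import CalibrationSet
from .correlation import CurveSummary

__all__ = [
    "QcThresholds",
    "QcVerdict",
    "KaResult",
    "FccsMeasurement",
    "particle_numbers",
    "apparent_ka",
    "association_score",
    "concentration_report",
    "qc_filter",
    "analyze_summaries",
]

#: nM per (particle/fl): 1 particle/fl = 1/(N_A * 1e-15) mol/L.
NM_PER_PARTICLE_PER_FL = 1e9 / (N_A * 1e-15)


def particle_numbers(g0_gg: float, g0_rr: float, g0_rg: float) -> tuple[float, float, float]:
    """(N_GG, N_RR, N_RG) from baseline-free curve amplitudes.

    N_GG = 1/G0_GG, N_RR = 1/G0_RR, N_RG = G0_RG * N_RR * N_GG.  The cross
    amplitude must already be clamped at zero.
    """
    if g0_gg <= 0 or g0_rr <= 0:
        raise ValueError("auto-correlation amplitudes must be positive (finite N)")
    if g0_rg < 0:
        raise ValueError("cross-correlation amplitude must be clamped at >= 0")
    n_gg = 1.0 / g0_gg
    n_rr = 1.0 / g0_rr
    n_rg = g0_rg * n_rr * n_gg
    return n_gg, n_rr, n_rg


@dataclass
class KaResult:
    """Concentrations and apparent association constant of one measurement."""

    conc_complex: float  # [RG], particles/fl
    conc_red_total: float  # [R_T], particles/fl
    conc_green_total: float  # [G_T], particles/fl
    conc_red_free: float  # [R], particles/fl
    conc_green_free: float  # [G], particles/fl
    ka_fl: float  # fl per particle; nan when invalid
    ka_per_molar: float  # M^-1; nan when invalid
    negative: bool  # free concentration came out non-positive

    @property
    def valid(self) -> bool:
        return not self.negative


def apparent_ka(n_gg: float, n_rr: float, n_rg: float, calib: CalibrationSet) -> KaResult:
    """Apparent Ka = [RG]/([R][G]) with volume and red-maturation corrections.

    [RG] = N_RG/(V_RG phi), [R_T] = N_RR/(V_R phi), [G_T] = N_GG/V_G; the
    free concentrations are totals minus complex.  A non-positive free
    concentration flags the measurement invalid (too noisy cross curve).
    """
    if n_gg <= 0 or n_rr <= 0 or n_rg < 0:
        raise ValueError("particle numbers must satisfy N_GG, N_RR > 0 and N_RG >= 0")
    conc_rg = n_rg / (calib.v_rg * calib.phi)
    conc_rt = n_rr / (calib.v_r * calib.phi)
    conc_gt = n_gg / calib.v_g
    conc_r = conc_rt - conc_rg
    conc_g = conc_gt - conc_rg
    if n_rg == 0.0:
        ka = 0.0
        negative = False
    elif conc_r <= 0 or conc_g <= 0:
        ka = math.nan
        negative = True
    else:
        ka = conc_rg / (conc_r * conc_g)
        negative = False
    ka_molar = ka * N_A * 1e-15 if math.isfinite(ka) else math.nan
    return KaResult(
        conc_complex=conc_rg,
        conc_red_total=conc_rt,
        conc_green_total=conc_gt,
        conc_red_free=conc_r,
        conc_green_free=conc_g,
        ka_fl=ka,
        ka_per_molar=ka_molar,
        negative=negative,
    )


def association_score(summary_rg: CurveSummary) -> float:
    """Noise-weighted cross-correlation score (amp - offset)/MAD.

    Uses the *unclamped* amplitude-offset difference, so scores may be
    negative.  A zero MAD makes the score undefined (nan); such measurements
    are excluded from cohorts.
    """
    if summary_rg.mad == 0:
        return math.nan
    return (summary_rg.amplitude - summary_rg.offset) / summary_rg.mad


def concentration_report(n_particles: float, volume_fl: float) -> tuple[float, float]:
    """(particles/fl, nM) for ``n_particles`` in ``volume_fl``."""
    if n_particles < 0 or volume_fl <= 0:
        raise ValueError("particle number must be >= 0 and volume positive")
    per_fl = n_particles / volume_fl
    return per_fl, per_fl * NM_PER_PARTICLE_PER_FL


@dataclass(frozen=True)
class QcThresholds:
    """Exclusion thresholds; all boundaries are inclusive as written.

    A measurement fails when counts-per-molecule <= ``cpm_min`` in either
    channel, an auto-curve offset >= ``offset_max`` or <= ``offset_min``,
    the dark-corrected green/red count-rate ratio >= ``bleedthrough_max``,
    or the apparent Ka is negative.
    """

    cpm_min: float = 215.0  # Hz
    offset_max: float = 0.0025
    offset_min: float = -0.002
    bleedthrough_max: float = 20.0
    check_cross_offset: bool = False  # offset bound applied to RG curve too


@dataclass
class QcVerdict:
    passed: bool
    flags: list[str] = field(default_factory=list)
    cpm_g: float = math.nan
    cpm_r: float = math.nan
    bleedthrough_ratio: float = math.nan


@dataclass
class FccsMeasurement:
    """One cell's FCCS result: summaries, rates, derived quantities, QC."""

    summary_gg: CurveSummary
    summary_rr: CurveSummary
    summary_rg: CurveSummary
    count_rate_g: float  # counts/s
    count_rate_r: float  # counts/s
    dark_rate: float = 0.0  # counts/s
    # derived
    n_gg: float = math.nan
    n_rr: float = math.nan
    n_rg: float = math.nan
    ka: KaResult | None = None
    score: float = math.nan
    qc: QcVerdict | None = None
    # metadata
    pair: str = ""
    cell_id: str = ""
    cell_line: str = ""
    location: str = "cytosol"  # cytosol | near | far
    treatment: str = "none"


def qc_filter(m: FccsMeasurement, thresholds: QcThresholds = QcThresholds()) -> QcVerdict:
    """Evaluate the four exclusion criteria on a measurement."""
    flags: list[str] = []
    sig_g = m.count_rate_g - m.dark_rate
    sig_r = m.count_rate_r - m.dark_rate

    cpm_g = sig_g * m.summary_gg.g0  # (C_G - C_D)/N_GG with N = 1/G0
    cpm_r = sig_r * m.summary_rr.g0
    if cpm_g <= thresholds.cpm_min or cpm_r <= thresholds.cpm_min:
        flags.append("cpm_fail")

    offsets = [m.summary_gg.offset, m.summary_rr.offset]
    if thresholds.check_cross_offset:
        offsets.append(m.summary_rg.offset)
    if any(o >= thresholds.offset_max or o <= thresholds.offset_min for o in offsets):
        flags.append("offset_fail")

    if sig_r <= 0:
        flags.append("bleedthrough_undefined")
        ratio = math.inf
    else:
        ratio = sig_g / sig_r
        if ratio >= thresholds.bleedthrough_max:
            flags.append("bleedthrough_fail")

    if m.ka is not None and m.ka.negative:
        flags.append("negative_ka")

    return QcVerdict(
        passed=not flags, flags=flags, cpm_g=cpm_g, cpm_r=cpm_r, bleedthrough_ratio=ratio
    )


def analyze_summaries(
    summary_gg: CurveSummary,
    summary_rr: CurveSummary,
    summary_rg: CurveSummary,
    count_rate_g: float,
    count_rate_r: float,
    calib: CalibrationSet,
    thresholds: QcThresholds = QcThresholds(),
    **metadata,
) -> FccsMeasurement:
    """Assemble a full measurement from curve summaries and count rates."""
    m = FccsMeasurement(
        summary_gg=summary_gg,
        summary_rr=summary_rr,
        summary_rg=summary_rg,
        count_rate_g=count_rate_g,
        count_rate_r=count_rate_r,
        dark_rate=calib.dark_rate,
        **metadata,
    )
    if summary_gg.g0 > 0 and summary_rr.g0 > 0:
        m.n_gg, m.n_rr, m.n_rg = particle_numbers(summary_gg.g0, summary_rr.g0, summary_rg.g0)
        m.ka = apparent_ka(m.n_gg, m.n_rr, m.n_rg, calib)
    m.score = association_score(summary_rg)
    m.qc = qc_filter(m, thresholds)
    if m.ka is None:
        m.qc.passed = False
        m.qc.flags.append("degenerate_auto_amplitude")
    return m
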