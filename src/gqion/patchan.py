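"""Single-channel electrophysiology analysis.

Planar-bilayer / patch-clamp current records of an ionophore show discrete
switching between a closed level (near 0 pA) and one or more open levels.
This module provides the standard toolkit for such records:

* all-points amplitude histograms,
* half-amplitude-threshold idealization into open/closed states with open
  probability and mean dwell times,
* ohmic conductance as the OLS slope of an I-V relation (pA/mV = nS),
* reversal potentials from tail-current I-V families by zero-crossing
  interpolation,
* bi-ionic Goldman-Hodgkin-Katz permeability ratios from reversal
  potentials.

Sign convention: the reported potential is that of the *cis* side relative
to the grounded *trans* side; positive current is cation flow cis→trans.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .errors import InsufficientDataError, NoReversalError

__all__ = [
    "CurrentTrace", "GatingStats", "IVCurve", "PhysConstants",
    "ConductanceFit", "ReversalResult",
    "all_points_histogram", "detect_gating", "conductance_iv",
    "reversal_potential", "ghk_biionic", "ghk_reversal",
]


# ---------------------------------------------------------------------------
# domain types and constants
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhysConstants:
    """Physical constants for Nernst/GHK arithmetic."""

    F: float = 96485.33212      # C/mol
    R: float = 8.314462618      # J/(mol K)
    T: float = 298.15           # K

    def __post_init__(self):
        if not self.T > 0:
            raise ValueError("temperature must be positive")

    @property
    def rt_over_f_mv(self) -> float:
        """RT/F in millivolts (25.693 mV at 298.15 K)."""
        return 1000.0 * self.R * self.T / self.F


@dataclass
class CurrentTrace:
    """Sampled single-channel current at a fixed holding potential."""

    current: np.ndarray          # pA
    fs_khz: float                # sampling rate, kHz
    v_hold: float                # mV, cis relative to grounded trans
    solutions: dict = field(default_factory=dict)  # e.g. {"cis": "1 M KCl"}

    def __post_init__(self):
        self.current = np.asarray(self.current, dtype=float)
        if not np.all(np.isfinite(self.current)):
            raise ValueError("current samples must be finite")
        if not self.fs_khz > 0:
            raise ValueError("sampling rate must be positive")

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(self.current.size) / self.fs_khz


@dataclass
class GatingStats:
    """Idealized two-state gating statistics of a current trace."""

    closed_level: float          # pA
    open_levels: list[float]     # pA
    p_open: float
    mean_dwell_open: float       # ms
    mean_dwell_closed: float     # ms
    n_events: int
    flags: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not 0.0 <= self.p_open <= 1.0:
            raise ValueError("p_open must lie in [0, 1]")


@dataclass
class IVCurve:
    """Potential-current pairs; erev/g filled in by analysis."""

    potentials: np.ndarray       # mV
    currents: np.ndarray         # pA
    erev: float = float("nan")   # mV
    g: float = float("nan")      # nS

    def __post_init__(self):
        self.potentials = np.asarray(self.potentials, dtype=float)
        self.currents = np.asarray(self.currents, dtype=float)
        if np.unique(self.potentials).size != self.potentials.size:
            raise ValueError("potentials must be distinct")
        if self.potentials.shape != self.currents.shape:
            raise ValueError("potentials and currents must match in length")


@dataclass
class ConductanceFit:
    """OLS line through an I-V relation."""

    g_ns: float                  # slope, nS (pA/mV)
    intercept_pa: float
    g_se: float = float("nan")
    intercept_se: float = float("nan")
    r_squared: float = float("nan")
    flags: list[str] = field(default_factory=list)


@dataclass
class ReversalResult:
    """Zero-current potential of an I-V family."""

    erev_mv: float
    extrapolated: bool = False


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def all_points_histogram(trace: CurrentTrace, bin_width: float = 0.2):
    """All-points amplitude histogram of a current trace.

    Returns (bin_centers pA, counts); counts sum to the sample count and the
    bin range covers the data.
    """
    if not bin_width > 0:
        raise ValueError("bin_width must be positive")
    i = trace.current
    lo = np.floor(i.min() / bin_width) * bin_width
    hi = np.ceil(i.max() / bin_width) * bin_width
    n_bins = max(int(round((hi - lo) / bin_width)), 1)
    edges = lo + bin_width * np.arange(n_bins + 1)
    # guard against float rounding leaving the max sample outside the range
    edges[-1] = max(edges[-1], i.max())
    counts, edges = np.histogram(i, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, counts


def _histogram_modes(trace: CurrentTrace, bin_width: float):
    """Prominent modes of the all-points histogram, as current levels."""
    centers, counts = all_points_histogram(trace, bin_width)
    if centers.size < 3:
        return [float(np.mean(trace.current))]
    smooth = counts.astype(float)
    if centers.size >= 7:
        smooth = np.maximum(sps.savgol_filter(smooth, 7, 2), 0.0)
    # zero-pad so modes at the histogram edges count as peaks
    padded = np.concatenate(([0.0], smooth, [0.0]))
    peaks, _ = sps.find_peaks(padded, prominence=0.05 * smooth.max())
    peaks = peaks - 1
    if peaks.size == 0:
        peaks = np.array([int(np.argmax(counts))])
    return [float(centers[p]) for p in peaks]


def detect_gating(trace: CurrentTrace, bin_width: float = 0.2,
                  min_dwell_samples: int = 2) -> GatingStats:
    """Two-state idealization by half-amplitude threshold.

    The closed level is the histogram mode nearest 0 pA; remaining modes are
    open levels.  Samples are assigned open when they lie beyond the
    half-amplitude threshold between the closed level and the nearest open
    level.  Dwell times come from run lengths; runs shorter than
    ``min_dwell_samples`` are excluded from the dwell statistics.  A
    unimodal histogram yields a ``no-gating`` result (p_open 0 or 1).
    """
    levels = _histogram_modes(trace, bin_width)
    closed = min(levels, key=abs)
    open_levels = sorted((l for l in levels if l != closed), key=abs,
                         reverse=True)
    flags: list[str] = []
    if not open_levels:
        # unimodal: channel pinned closed (level near 0) or pinned open
        always_open = abs(closed) > bin_width
        total_ms = trace.current.size / trace.fs_khz
        return GatingStats(
            closed_level=0.0 if always_open else closed,
            open_levels=[closed] if always_open else [],
            p_open=1.0 if always_open else 0.0,
            mean_dwell_open=total_ms if always_open else float("nan"),
            mean_dwell_closed=float("nan") if always_open else total_ms,
            n_events=0, flags=["no-gating"])

    nearest_open = min(open_levels, key=lambda l: abs(l - closed))
    threshold = 0.5 * (closed + nearest_open)
    if nearest_open > closed:
        is_open = trace.current > threshold
    else:
        is_open = trace.current < threshold

    p_open = float(np.mean(is_open))
    # run-length encode the state sequence
    change = np.flatnonzero(np.diff(is_open.astype(np.int8)) != 0)
    starts = np.concatenate(([0], change + 1))
    lengths = np.diff(np.concatenate((starts, [is_open.size])))
    states = is_open[starts]
    n_events = int(states.size - 1)
    if n_events < 10:
        flags.append("low-event-count")
    keep = lengths >= min_dwell_samples
    open_runs = lengths[keep & states]
    closed_runs = lengths[keep & ~states]
    ms = 1.0 / trace.fs_khz
    mean_open = float(open_runs.mean() * ms) if open_runs.size else float("nan")
    mean_closed = (float(closed_runs.mean() * ms)
                   if closed_runs.size else float("nan"))
    return GatingStats(closed_level=closed, open_levels=open_levels,
                       p_open=p_open, mean_dwell_open=mean_open,
                       mean_dwell_closed=mean_closed, n_events=n_events,
                       flags=flags)


def conductance_iv(curve: IVCurve) -> ConductanceFit:
    """Ohmic conductance as the OLS slope of the I-V relation, in nS.

    A fitted intercept larger than its standard error is flagged
    ``non-ohmic`` (the line should pass through the origin for a symmetric
    ohmic pore in symmetric solutions).
    """
    v, i = curve.potentials, curve.currents
    if v.size < 3:
        raise InsufficientDataError("conductance fit needs >=3 potentials")
    A = np.column_stack((v, np.ones_like(v)))
    coef, res, *_ = np.linalg.lstsq(A, i, rcond=None)
    slope, intercept = float(coef[0]), float(coef[1])
    pred = A @ coef
    sse = float(np.sum((i - pred) ** 2))
    tss = float(np.sum((i - i.mean()) ** 2))
    r2 = 1.0 - sse / tss if tss > 0 else 1.0
    dof = v.size - 2
    if dof > 0 and sse > 0:
        s2 = sse / dof
        cov = s2 * np.linalg.inv(A.T @ A)
        slope_se, int_se = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
    else:
        slope_se = int_se = 0.0
    flags = []
    scale = float(np.max(np.abs(i))) or 1.0
    if int_se > 0 and abs(intercept) > max(int_se, 1e-9 * scale):
        flags.append("non-ohmic")
    curve.g = slope
    return ConductanceFit(g_ns=slope, intercept_pa=intercept, g_se=slope_se,
                          intercept_se=int_se, r_squared=r2, flags=flags)


def reversal_potential(curve: IVCurve, extrapolation_factor: float = 1.5,
                       method: str = "bracket") -> ReversalResult:
    """Zero-current potential of an I-V family.

    ``method="bracket"`` (default): when the currents change sign inside the
    sampled range, the crossing is interpolated linearly between the
    bracketing points; otherwise the root of the OLS line is used, accepted
    (with ``extrapolated=True``) only if it lies within
    ``extrapolation_factor`` times the observed voltage range.

    ``method="line"``: the root of the OLS line through all points — the
    appropriate estimator for ohmic (globally linear) tail-current families,
    where it uses every measurement instead of the two nearest the crossing.
    The two methods coincide on exactly linear data.
    """
    if method not in ("bracket", "line"):
        raise ValueError("method must be 'bracket' or 'line'")
    order = np.argsort(curve.potentials)
    v, i = curve.potentials[order], curve.currents[order]
    sign_change = np.flatnonzero(np.signbit(i[:-1]) != np.signbit(i[1:]))
    exact_zero = np.flatnonzero(i == 0.0)
    if method == "bracket" and exact_zero.size:
        erev = float(v[exact_zero[0]])
        curve.erev = erev
        return ReversalResult(erev_mv=erev)
    if method == "bracket" and sign_change.size:
        k = sign_change[0]
        erev = float(v[k] - i[k] * (v[k + 1] - v[k]) / (i[k + 1] - i[k]))
        curve.erev = erev
        return ReversalResult(erev_mv=erev)
    if method == "line" and (sign_change.size or exact_zero.size):
        slope, intercept = np.polyfit(v, i, 1)
        erev = float(-intercept / slope)
        curve.erev = erev
        return ReversalResult(erev_mv=erev)
    # no bracket: extrapolate the OLS line
    slope, intercept = np.polyfit(v, i, 1)
    if slope == 0:
        raise NoReversalError("flat I-V: no zero crossing")
    root = float(-intercept / slope)
    vspan = float(v.max() - v.min())
    lo = v.min() - (extrapolation_factor - 1.0) * vspan
    hi = v.max() + (extrapolation_factor - 1.0) * vspan
    if not lo <= root <= hi:
        raise NoReversalError(
            f"extrapolated crossing {root:.1f} mV outside the credible range")
    curve.erev = root
    return ReversalResult(erev_mv=root, extrapolated=True)


def ghk_biionic(erev_mv: float, conc_cis: float, conc_trans: float,
                constants: PhysConstants = PhysConstants()) -> float:
    """Bi-ionic GHK permeability ratio P_cis/P_trans from a reversal potential.

    For monovalent cations X (cis) and Y (trans),

        E_rev = (RT/F) ln( P_cis [X]_cis / (P_trans [Y]_trans) )

    so P_cis/P_trans = ([Y]_trans/[X]_cis) exp(E_rev F/(RT)).  E_rev is the
    cis-side potential relative to the grounded trans side.
    """
    if conc_cis <= 0 or conc_trans <= 0:
        raise ValueError("concentrations must be positive")
    return (conc_trans / conc_cis) * float(
        np.exp(erev_mv / constants.rt_over_f_mv))


def ghk_reversal(p_ratio: float, conc_cis: float, conc_trans: float,
                 constants: PhysConstants = PhysConstants()) -> float:
    """Inverse of :func:`ghk_biionic`: reversal potential (mV) from a ratio."""
    if p_ratio <= 0 or conc_cis <= 0 or conc_trans <= 0:
        raise ValueError("ratio and concentrations must be positive")
    return constants.rt_over_f_mv * float(
        np.log(p_ratio * conc_cis / conc_trans))
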