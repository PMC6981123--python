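"""Ligand-quadruplex binding characterization panel.

Four standard biophysical readouts of a small molecule binding a DNA
G-quadruplex:

* FRET melting — two-state Boltzmann sigmoid fits of normalized melt
  fraction versus temperature; ligand stabilization is the midpoint shift
  ΔTm between bound and free fits.
* Fluorescence titration — turn-on intensity fit with the exact 1:1
  quadratic (ligand-depletion-aware) bound-fraction solution to extract Kd.
* Continuous variation (Job plot) — the signal of an m:1 complex at fixed
  total concentration peaks at ligand mole fraction m/(m+1); the peak is
  located by quadratic interpolation and converted to an integer
  stoichiometry.
* ITC — per-injection molar heats fit with the single-set-of-identical-sites
  (Wiseman) isotherm including cumulative injection-dilution bookkeeping,
  yielding site number, Kd and ΔH.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal as sps

from .errors import FitError, InsufficientDataError, InvalidDesignError

__all__ = [
    "MeltCurve", "MeltFit", "TitrationSeries", "JobSeries", "ITCThermogram",
    "BindingFit", "fit_melt", "delta_tm", "fit_titration",
    "job_stoichiometry", "fit_itc", "boltzmann_sigmoid",
    "bound_fraction_1to1", "wiseman_heats",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class MeltCurve:
    """Normalized thermal melting profile."""

    temps: np.ndarray       # °C, strictly increasing
    signal: np.ndarray      # normalized emission / melt fraction
    label: str = ""         # e.g. "3 equiv MG, K+"

    def __post_init__(self):
        self.temps = np.asarray(self.temps, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.temps.size < 6:
            raise InsufficientDataError("melt curve needs >=6 temperature points")
        if not np.all(np.diff(self.temps) > 0):
            raise ValueError("temperatures must be strictly increasing")
        if self.temps.shape != self.signal.shape:
            raise ValueError("temps and signal must match in length")


@dataclass
class MeltFit:
    """Boltzmann two-state melt fit."""

    tm: float               # °C
    width: float            # °C (sigmoid slope parameter)
    baselines: tuple[float, float]
    residual_sse: float
    tm_se: float = float("nan")
    flags: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.width > 0:
            raise ValueError("width must be positive")


@dataclass
class TitrationSeries:
    """Fluorimetric titration of a fixed probe with increasing titrant."""

    titrant_concs: np.ndarray  # μM
    signal: np.ndarray         # a.u.
    probe_conc: float          # μM

    def __post_init__(self):
        self.titrant_concs = np.asarray(self.titrant_concs, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if np.any(self.titrant_concs < 0):
            raise ValueError("titrant concentrations must be non-negative")
        if np.any(np.diff(self.titrant_concs) < 0):
            raise ValueError("titrant concentrations must be non-decreasing")
        if not self.probe_conc > 0:
            raise ValueError("probe_conc must be positive")


@dataclass
class JobSeries:
    """Continuous-variation series at constant total concentration."""

    mole_fractions: np.ndarray  # of the ligand, in [0, 1]
    signal: np.ndarray          # a.u., proportional to complex concentration
    total_conc: float           # μM

    def __post_init__(self):
        self.mole_fractions = np.asarray(self.mole_fractions, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if np.any((self.mole_fractions < 0) | (self.mole_fractions > 1)):
            raise ValueError("mole fractions must lie in [0, 1]")
        if np.any(np.diff(self.mole_fractions) <= 0):
            raise ValueError("mole fractions must be strictly increasing")


@dataclass
class ITCThermogram:
    """Integrated per-injection heats of a calorimetric titration."""

    heats: np.ndarray          # kcal/mol of injectant, one per injection
    molar_ratios: np.ndarray   # cumulative [titrant]/[cell species]
    cell_conc: float           # μM, initial
    syringe_conc: float        # μM
    v_inject: float            # μL per injection
    cell_vol: float            # μL

    def __post_init__(self):
        self.heats = np.asarray(self.heats, dtype=float)
        self.molar_ratios = np.asarray(self.molar_ratios, dtype=float)
        if not np.all(np.diff(self.molar_ratios) > 0):
            raise ValueError("molar ratios must be strictly increasing")
        if self.heats.shape != self.molar_ratios.shape:
            raise ValueError("heats and molar_ratios must match in length")


@dataclass
class BindingFit:
    """Common result record for binding analyses."""

    kd: float                    # μM (nan where not applicable)
    stoichiometry: float         # integer m for Job/ITC, 1.0 for 1:1 fits
    dh: float = float("nan")     # kcal/mol (ITC only)
    residual_sse: float = float("nan")
    kd_se: float = float("nan")
    stoichiometry_raw: float = float("nan")  # un-rounded evidence for m
    amplitude: float = float("nan")
    offset: float = float("nan")
    flags: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------

def boltzmann_sigmoid(temp, low, high, tm, width):
    """Two-state melt: low + (high - low) / (1 + exp((tm - T)/width))."""
    temp = np.asarray(temp, dtype=float)
    return low + (high - low) / (1.0 + np.exp((tm - temp) / width))


def bound_fraction_1to1(titrant, probe_conc, kd):
    """Exact 1:1 complex concentration / probe, with ligand depletion.

    Solves [PL] from the quadratic mass balance for total probe P and total
    titrant L:  [PL] = ((P+L+Kd) - sqrt((P+L+Kd)^2 - 4 P L)) / 2.
    """
    lt = np.asarray(titrant, dtype=float)
    p = probe_conc
    s = p + lt + kd
    complex_conc = 0.5 * (s - np.sqrt(np.maximum(s * s - 4.0 * p * lt, 0.0)))
    return complex_conc / p


def wiseman_heats(n_sites, kd, dh, cell_conc, syringe_conc,
                  n_inject, v_inject, cell_vol, offset=0.0):
    """Forward single-set-of-identical-sites ITC model.

    Uses the standard displacement bookkeeping: each injection of volume v
    dilutes the pre-injection cell contents by (1 - v/V0) and adds titrant
    at syringe concentration.  The heat of injection i is the enthalpy times
    the change in moles of bound titrant, normalized per mole injected:

        q_i = dH * V0 * (B_i - B_{i-1} (1 - v/V0)) / (c_syr * v) + offset

    with B the bound-titrant concentration from the 1:1 quadratic between
    total titrant and total site concentration n_sites * [cell species].

    Returns (heats kcal/mol, molar_ratios).
    """
    f = v_inject / cell_vol
    q_cell = cell_conc
    l_tot = 0.0
    bound_prev = 0.0
    heats = np.empty(n_inject)
    ratios = np.empty(n_inject)
    for i in range(n_inject):
        q_cell = q_cell * (1.0 - f)
        l_tot = l_tot * (1.0 - f) + syringe_conc * f
        sites = n_sites * q_cell
        s = sites + l_tot + kd
        bound = 0.5 * (s - np.sqrt(max(s * s - 4.0 * sites * l_tot, 0.0)))
        dq = dh * cell_vol * (bound - bound_prev * (1.0 - f))
        heats[i] = dq / (syringe_conc * v_inject) + offset
        ratios[i] = l_tot / q_cell
        bound_prev = bound
    return heats, ratios


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def _derivative_tm(temps, signal):
    """Midpoint estimate from the maximum of a smoothed first derivative."""
    n = temps.size
    win = min(11, n if n % 2 == 1 else n - 1)
    if win >= 5:
        smooth = sps.savgol_filter(signal, win, polyorder=3)
    else:
        smooth = signal
    deriv = np.gradient(smooth, temps)
    mag = np.abs(deriv)
    i = int(np.argmax(mag))
    if 0 < i < n - 1:  # three-point parabolic refinement (locally uniform grid)
        y0, y1, y2 = mag[i - 1], mag[i], mag[i + 1]
        denom = y0 - 2.0 * y1 + y2
        if denom < 0:
            h = 0.5 * (temps[i + 1] - temps[i - 1])
            return float(temps[i] + 0.5 * (y0 - y2) / denom * h)
    return float(temps[i])


def fit_melt(curve: MeltCurve) -> MeltFit:
    """Fit a four-parameter Boltzmann sigmoid to a melting profile.

    The fitted midpoint is cross-checked against the temperature of the
    maximum of a smoothed first derivative; disagreement beyond width/2
    raises a ``derivative-disagreement`` flag.  A melt that is not monotone
    beyond the noise level is flagged ``non-two-state``.
    """
    t, y = curve.temps, curve.signal
    span = float(np.ptp(y))
    noise = float(np.std(np.diff(y))) / np.sqrt(2.0)
    if span < 4.0 * max(noise, 1e-12) and noise > 0:
        raise InsufficientDataError(
            "signal range does not exceed 4x the noise estimate")

    flags: list[str] = []
    # monotonicity check on a lightly smoothed curve
    win = min(9, t.size if t.size % 2 == 1 else t.size - 1)
    smooth = sps.savgol_filter(y, win, 2) if win >= 5 else y
    backsteps = np.diff(smooth)
    tol = 3.0 * max(noise, 1e-12)
    if np.any(backsteps < -tol) and np.any(backsteps > tol):
        flags.append("non-two-state")

    low0, high0 = float(y.min()), float(y.max())
    tm0 = float(t[np.argmin(np.abs(y - 0.5 * (low0 + high0)))])
    width0 = max(np.ptp(t) / 20.0, 0.5)
    p0 = (low0, high0, tm0, width0)
    try:
        popt, pcov = optimize.curve_fit(
            boltzmann_sigmoid, t, y, p0=p0,
            bounds=([-np.inf, -np.inf, t.min() - 20, 1e-3],
                    [np.inf, np.inf, t.max() + 20, np.ptp(t)]),
            maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        raise FitError("Boltzmann melt fit did not converge",
                       initial_guess=p0, diagnostics=str(exc)) from exc
    low, high, tm, width = (float(v) for v in popt)
    resid = y - boltzmann_sigmoid(t, *popt)
    tm_deriv = _derivative_tm(t, y)
    if abs(tm_deriv - tm) > width / 2.0:
        flags.append("derivative-disagreement")
    tm_se = float(np.sqrt(pcov[2, 2])) if np.isfinite(pcov[2, 2]) else np.nan
    return MeltFit(tm=tm, width=width, baselines=(low, high),
                   residual_sse=float(resid @ resid), tm_se=tm_se, flags=flags)


def delta_tm(bound: MeltFit, free: MeltFit) -> float:
    """Ligand-induced melting-midpoint shift, °C (bound minus free)."""
    return bound.tm - free.tm


def fit_titration(series: TitrationSeries) -> BindingFit:
    """Fit Kd from a depletion-aware 1:1 binding titration.

    The signal is modelled as amplitude * bound_fraction(titrant; probe, Kd).
    If the largest titrant concentration does not reach ~Kd the fit is
    returned with a ``saturation-not-approached`` flag (wide confidence).
    """
    lt, y = series.titrant_concs, series.signal
    if lt.size < 5:
        raise InsufficientDataError("titration needs >=5 points")

    def model(l, amp, kd):
        return amp * bound_fraction_1to1(l, series.probe_conc, kd)

    # coarse log-spaced Kd scan with the amplitude profiled out analytically
    # (the model is linear in amp), to start the optimizer near the optimum
    lmax = float(lt.max())
    kd_grid = np.geomspace(lmax * 1e-3, lmax * 1e2, 60)
    best_kd, best_amp, best_sse = kd_grid[0], 1.0, np.inf
    for kd_try in kd_grid:
        f = bound_fraction_1to1(lt, series.probe_conc, kd_try)
        denom = float(f @ f)
        amp_try = float(f @ y) / denom if denom > 0 else 0.0
        sse = float(np.sum((y - amp_try * f) ** 2))
        if sse < best_sse:
            best_kd, best_amp, best_sse = float(kd_try), amp_try, sse
    p0 = (max(best_amp, 1e-9), best_kd)

    try:
        popt, pcov = optimize.curve_fit(
            model, lt, y, p0=p0,
            bounds=([1e-12, 1e-9], [np.inf, np.inf]), maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        raise FitError("titration fit did not converge",
                       initial_guess=p0, diagnostics=str(exc)) from exc
    amp, kd = float(popt[0]), float(popt[1])
    flags = []
    if float(lt.max()) < kd:
        flags.append("saturation-not-approached")
    resid = y - model(lt, *popt)
    kd_se = float(np.sqrt(pcov[1, 1])) if np.isfinite(pcov[1, 1]) else np.nan
    return BindingFit(kd=kd, stoichiometry=1.0, residual_sse=float(resid @ resid),
                      kd_se=kd_se, amplitude=amp, flags=flags)


def job_stoichiometry(series: JobSeries) -> BindingFit:
    """Stoichiometry m from the peak of a continuous-variation series.

    For an m:1 (ligand:receptor) complex the signal maximum sits at ligand
    mole fraction x* = m/(m+1).  The peak is located by quadratic
    interpolation through the top three points; both the interpolated x*
    (as ``stoichiometry_raw`` = x*/(1-x*)) and the rounded integer m are
    returned.
    """
    x, y = series.mole_fractions, series.signal
    if x.size < 7 or x.min() > 0.1 or x.max() < 0.9:
        raise InsufficientDataError(
            "continuous-variation series needs >=7 fractions covering [0.1, 0.9]")
    i = int(np.argmax(y))
    if i == 0 or i == x.size - 1:
        raise InvalidDesignError("signal maximum lies on the design boundary")
    x3, y3 = x[i - 1:i + 2], y[i - 1:i + 2]
    # vertex of the parabola through the top three points
    denom = (x3[0] - x3[1]) * (x3[0] - x3[2]) * (x3[1] - x3[2])
    a = (x3[2] * (y3[1] - y3[0]) + x3[1] * (y3[0] - y3[2])
         + x3[0] * (y3[2] - y3[1])) / denom
    b = (x3[2] ** 2 * (y3[0] - y3[1]) + x3[1] ** 2 * (y3[2] - y3[0])
         + x3[0] ** 2 * (y3[1] - y3[2])) / denom
    x_star = float(x3[1]) if a >= 0 else float(-b / (2.0 * a))
    m_raw = x_star / (1.0 - x_star)
    return BindingFit(kd=float("nan"), stoichiometry=float(round(m_raw)),
                      stoichiometry_raw=m_raw)


def fit_itc(thermogram: ITCThermogram) -> BindingFit:
    """Single-set-of-identical-sites fit of an ITC thermogram.

    Fits (m, Kd, ΔH) plus a constant per-injection dilution-heat offset to
    the per-injection molar heats.  A Wiseman c-value (m * cell_conc / Kd)
    above 1000 means the titration ran in the stoichiometric regime where
    Kd is unidentifiable; the fit is then flagged ``kd-unidentifiable``.
    """
    q = thermogram.heats
    n_inject = q.size
    if n_inject < 8:
        raise InsufficientDataError("ITC fit needs >=8 injections")
    if thermogram.molar_ratios[-1] <= 1.0:
        raise InsufficientDataError(
            "titration must pass the equivalence point (molar ratio > 1)")
    span = float(np.ptp(q))
    if span < 1e-12 or span < 1e-3 * np.max(np.abs(q) + 1e-30):
        raise FitError("thermogram is flat: no binding heat to fit",
                       initial_guess=None)

    # starts: m from the molar ratio at the steepest heat drop, dH from the
    # first (saturating-regime) heats, Kd from a mid c-value assumption
    drops = np.abs(np.diff(q))
    m0 = float(np.clip(thermogram.molar_ratios[int(np.argmax(drops))], 0.2, 10))
    dh0 = float(q[0] - q[-1])
    kd0 = max(thermogram.cell_conc * m0 / 50.0, 1e-4)
    off0 = float(q[-1])
    p0 = (m0, kd0, dh0, off0)

    def model(_x, m, kd, dh, off):
        h, _ = wiseman_heats(m, kd, dh, thermogram.cell_conc,
                             thermogram.syringe_conc, n_inject,
                             thermogram.v_inject, thermogram.cell_vol,
                             offset=off)
        return h

    try:
        popt, pcov = optimize.curve_fit(
            model, np.arange(n_inject), q, p0=p0,
            bounds=([1e-3, 1e-9, -np.inf, -np.inf],
                    [50.0, np.inf, np.inf, np.inf]),
            maxfev=40000)
    except (RuntimeError, ValueError) as exc:
        raise FitError("ITC fit did not converge",
                       initial_guess=p0, diagnostics=str(exc)) from exc
    m, kd, dh, off = (float(v) for v in popt)
    flags = []
    if m * thermogram.cell_conc / kd > 1000.0:
        flags.append("kd-unidentifiable")
    resid = q - model(None, *popt)
    kd_se = float(np.sqrt(pcov[1, 1])) if np.isfinite(pcov[1, 1]) else np.nan
    return BindingFit(kd=kd, stoichiometry=float(round(m)), dh=dh,
                      residual_sse=float(resid @ resid), kd_se=kd_se,
                      stoichiometry_raw=m, offset=off, flags=flags)
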