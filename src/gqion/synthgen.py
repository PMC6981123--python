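"""Seeded synthetic-data generators for every gqion input data type.

Each generator produces data with exactly the statistical structure its
downstream analysis assumes — single-exponential H+/M+ exchange flux traces
with base-pulse and lysis events, Hill dose-responses, Boltzmann melt
curves, depletion-aware binding titrations, continuous-variation (Job)
series from the full m:1 equilibrium, Wiseman ITC thermograms, two-state
Markov gated current traces, ohmic tail-current I-V families, and
electro-diffusive BD trajectories (via :mod:`gqion.permbd`) — so that every
fitter can be verified by parameter recovery without any external data.

Noise is additive Gaussian with sigma expressed as a fraction of the
signal's dynamic range.  All randomness flows from one integer seed through
a counter-based per-replicate scheme (``default_rng([seed, replicate])``),
so replicate k is reproducible independently of generation order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .bindfit import (ITCThermogram, JobSeries, MeltCurve, TitrationSeries,
                      boltzmann_sigmoid, bound_fraction_1to1, wiseman_heats)
from .errors import InsufficientDataError, NumericalError, ProtocolError
from .fluxkin import DoseResponse, FluxTrace, first_order_model, hill_model
from .patchan import CurrentTrace, IVCurve

__all__ = [
    "NoiseSpec", "FluxProtocol",
    "gen_flux_trace", "gen_dose_response", "gen_melt_curve", "gen_titration",
    "gen_job_series", "gen_itc", "gen_gating_trace", "gen_tail_iv",
    "solve_job_equilibrium",
]


# ---------------------------------------------------------------------------
# plumbing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NoiseSpec:
    """Additive-Gaussian noise, sigma as a fraction of the dynamic range."""

    sigma: float = 0.0
    seed: int = 0
    kind: str = "additive-gaussian"

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.kind != "additive-gaussian":
            raise ValueError(f"unsupported noise kind: {self.kind!r}")

    def rng(self, replicate: int = 0) -> np.random.Generator:
        """Counter-based stream: replicate k is order-independent."""
        return np.random.default_rng([self.seed, replicate])

    def apply(self, signal: np.ndarray, dynamic_range: float,
              replicate: int = 0) -> np.ndarray:
        if self.sigma == 0.0:
            return np.asarray(signal, dtype=float)
        noise = self.rng(replicate).normal(
            0.0, self.sigma * dynamic_range, size=np.shape(signal))
        return np.asarray(signal, dtype=float) + noise


@dataclass(frozen=True)
class FluxProtocol:
    """Event timing of the HPTS transport assay."""

    t_start: float = 0.0     # s
    t_base: float = 50.0     # s, NaOH pulse
    t_lysis: float = 350.0   # s, detergent lysis
    t_end: float = 400.0     # s
    sample_interval: float = 1.0  # s

    def __post_init__(self):
        if not (self.t_start < self.t_base < self.t_lysis <= self.t_end):
            raise ProtocolError(
                "event times must satisfy t_start < t_base < t_lysis <= t_end")
        if not self.sample_interval > 0:
            raise ProtocolError("sample_interval must be positive")

    def times(self) -> np.ndarray:
        return np.arange(self.t_start, self.t_end + 0.5 * self.sample_interval,
                         self.sample_interval)


# ---------------------------------------------------------------------------
# flux / dose-response generators
# ---------------------------------------------------------------------------

def gen_flux_trace(k_obs: float, plateau: float,
                   protocol: FluxProtocol = FluxProtocol(),
                   noise: NoiseSpec = NoiseSpec(),
                   transporter_conc: float | None = None,
                   baseline: float = 0.0, scale: float = 1.0,
                   replicate: int = 0,
                   ion_internal: str = "Na+",
                   ion_external: str = "K+") -> FluxTrace:
    """Single-exponential H+/M+ exchange flux trace with assay events.

    The noise-free signal is flat at 0 before the base pulse, follows
    plateau * (1 - exp(-k_obs (t - t_base))) between base pulse and lysis,
    and steps to 1 after detergent lysis.  ``baseline``/``scale`` produce a
    raw (un-normalized) trace ``baseline + scale * y(t)`` for exercising the
    normalization step.
    """
    if k_obs < 0:
        raise ValueError("k_obs must be non-negative")
    if not 0.0 <= plateau <= 1.0:
        raise ValueError("plateau must lie in [0, 1]")
    t = protocol.times()
    y = np.where(
        t < protocol.t_base, 0.0,
        np.where(t <= protocol.t_lysis,
                 first_order_model(t, k_obs, plateau, protocol.t_base), 1.0))
    y = noise.apply(y, dynamic_range=1.0, replicate=replicate)
    sig = baseline + scale * y
    return FluxTrace(times=t, signal=sig, t_base=protocol.t_base,
                     t_lysis=protocol.t_lysis, ion_internal=ion_internal,
                     ion_external=ion_external,
                     transporter_conc=transporter_conc,
                     normalized=(baseline == 0.0 and scale == 1.0))


def gen_dose_response(ec50: float, n_hill: float, concentrations,
                      noise: NoiseSpec = NoiseSpec(),
                      replicate: int = 0) -> DoseResponse:
    """Hill dose-response Y(c) = c^n / (EC50^n + c^n), clipped to [0, 1]."""
    if not ec50 > 0:
        raise ValueError("ec50 must be positive")
    c = np.asarray(concentrations, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentrations must be non-negative")
    y = hill_model(c, ec50, n_hill)
    y = np.clip(noise.apply(y, 1.0, replicate), 0.0, 1.0)
    return DoseResponse(concentrations=c, activity=y)


# ---------------------------------------------------------------------------
# binding-panel generators
# ---------------------------------------------------------------------------

def gen_melt_curve(tm: float, width: float, temps,
                   baselines: tuple[float, float] = (0.0, 1.0),
                   noise: NoiseSpec = NoiseSpec(),
                   label: str = "", replicate: int = 0) -> MeltCurve:
    """Boltzmann sigmoid melt curve between the two baselines."""
    if not width > 0:
        raise ValueError("width must be positive")
    t = np.asarray(temps, dtype=float)
    if t.size < 6:
        raise InsufficientDataError("melt curve needs >=6 temperature points")
    if not np.all(np.diff(t) > 0):
        raise ValueError("temperatures must be strictly increasing")
    low, high = baselines
    y = boltzmann_sigmoid(t, low, high, tm, width)
    y = noise.apply(y, abs(high - low), replicate)
    return MeltCurve(temps=t, signal=y, label=label)


def gen_titration(kd: float, probe_conc: float, titrant_concs,
                  amplitude: float = 1.0, noise: NoiseSpec = NoiseSpec(),
                  replicate: int = 0) -> TitrationSeries:
    """Fluorescence titration from the exact 1:1 quadratic binding solution.

    The signal is ``amplitude`` times the bound fraction of the probe,
    computed with ligand depletion (probe and titrant at comparable
    concentrations).
    """
    if not kd > 0 or not probe_conc > 0:
        raise ValueError("kd and probe_conc must be positive")
    lt = np.asarray(titrant_concs, dtype=float)
    y = amplitude * bound_fraction_1to1(lt, probe_conc, kd)
    y = noise.apply(y, float(np.ptp(y)) or abs(amplitude), replicate)
    return TitrationSeries(titrant_concs=lt, signal=y, probe_conc=probe_conc)


def solve_job_equilibrium(m: int, k_assoc: float, ligand_tot: float,
                          receptor_tot: float) -> float:
    """Complex concentration of the single-step m:1 equilibrium.

    Solves  mL + Q = L_m Q  with  [LmQ] = Ka [L]^m [Q]  under the mass
    balances  L_tot = [L] + m [LmQ],  Q_tot = [Q] + [LmQ],  by bracketed
    root finding in [0, min(L_tot/m, Q_tot)].
    """
    cmax = min(ligand_tot / m, receptor_tot)
    if cmax <= 0:
        return 0.0

    def residual(c):
        free_l = ligand_tot - m * c
        free_q = receptor_tot - c
        return k_assoc * free_l ** m * free_q - c

    lo, hi = 0.0, cmax
    if residual(hi) > 0:          # numerically saturated: all limiting species bound
        return cmax
    try:
        return float(optimize.brentq(residual, lo, hi, xtol=1e-15,
                                     rtol=8.9e-16, maxiter=200))
    except (RuntimeError, ValueError) as exc:
        raise NumericalError(
            f"m:1 equilibrium root solve failed (m={m}, Ka={k_assoc:.3g}, "
            f"L={ligand_tot:.3g}, Q={receptor_tot:.3g}): {exc}") from exc


def gen_job_series(m: int, k_assoc: float, total_conc: float, fractions,
                   noise: NoiseSpec = NoiseSpec(),
                   replicate: int = 0) -> JobSeries:
    """Continuous-variation series from the full m:1 equilibrium.

    Per ligand mole fraction x the ligand and receptor totals are
    x * total_conc and (1-x) * total_conc; the signal is proportional to the
    equilibrium complex concentration, which for strong binding peaks at
    x = m/(m+1).
    """
    if m < 1:
        raise ValueError("stoichiometry m must be >= 1")
    if not total_conc > 0:
        raise ValueError("total_conc must be positive")
    x = np.asarray(fractions, dtype=float)
    if np.any((x < 0) | (x > 1)):
        raise ValueError("mole fractions must lie in [0, 1]")
    sig = np.array([
        solve_job_equilibrium(m, k_assoc, xi * total_conc,
                              (1.0 - xi) * total_conc)
        for xi in x
    ])
    sig = noise.apply(sig, float(sig.max()) if sig.max() > 0 else 1.0,
                      replicate)
    return JobSeries(mole_fractions=x, signal=sig, total_conc=total_conc)


def gen_itc(n_sites: float, kd: float, dh: float, cell_conc: float,
            syringe_conc: float, n_inject: int = 20, v_inject: float = 10.0,
            cell_vol: float = 1400.0, dilution_offset: float = 0.0,
            noise: NoiseSpec = NoiseSpec(),
            replicate: int = 0) -> ITCThermogram:
    """Wiseman single-set-of-identical-sites thermogram.

    Heats are per mole of injectant (kcal/mol) with cumulative dilution
    bookkeeping; see :func:`gqion.bindfit.wiseman_heats`.
    """
    if min(kd, cell_conc, syringe_conc, v_inject, cell_vol) <= 0:
        raise ValueError("concentrations and volumes must be positive")
    heats, ratios = wiseman_heats(n_sites, kd, dh, cell_conc, syringe_conc,
                                  n_inject, v_inject, cell_vol,
                                  offset=dilution_offset)
    heats = noise.apply(heats, float(np.ptp(heats)) or abs(dh) or 1.0,
                        replicate)
    return ITCThermogram(heats=heats, molar_ratios=ratios,
                         cell_conc=cell_conc, syringe_conc=syringe_conc,
                         v_inject=v_inject, cell_vol=cell_vol)


# ---------------------------------------------------------------------------
# electrophysiology generators
# ---------------------------------------------------------------------------

def gen_gating_trace(g_open: float, v_hold: float, p_open: float,
                     mean_dwell: float, duration: float, fs: float,
                     noise: NoiseSpec = NoiseSpec(),
                     replicate: int = 0) -> CurrentTrace:
    """Two-state Markov gated current trace.

    Open dwell times are exponential with mean ``mean_dwell`` (ms); closed
    dwells have mean ``mean_dwell * (1 - p_open)/p_open`` so the stationary
    open probability equals ``p_open``.  The open level is g_open * v_hold
    (nS * mV = pA); the closed level is 0 pA.  Noise sigma is a fraction of
    the open-level amplitude.
    """
    if not 0.0 <= p_open <= 1.0:
        raise ValueError("p_open must lie in [0, 1]")
    if 0.0 < p_open < 1.0 and fs * mean_dwell < 5:
        raise ValueError("need fs * mean_dwell >= 5 samples per open dwell")
    n = int(round(duration * fs))
    rng = NoiseSpec(sigma=0.0, seed=noise.seed).rng(replicate)
    open_level = g_open * v_hold

    state = np.zeros(n, dtype=bool)
    if p_open >= 1.0:
        state[:] = True
    elif p_open > 0.0:
        tau_open = mean_dwell
        tau_closed = mean_dwell * (1.0 - p_open) / p_open
        t = 0.0
        is_open = rng.random() < p_open
        while t < duration:
            tau = tau_open if is_open else tau_closed
            dwell = rng.exponential(tau)
            i0 = int(t * fs)
            i1 = min(int((t + dwell) * fs), n)
            state[i0:i1] = is_open
            t += dwell
            is_open = not is_open
    current = np.where(state, open_level, 0.0)
    amp = abs(open_level) if open_level != 0 else 1.0
    if noise.sigma > 0:
        current = current + rng.normal(0.0, noise.sigma * amp, size=n)
    return CurrentTrace(current=current, fs_khz=fs, v_hold=v_hold)


def gen_tail_iv(erev: float, g: float, potentials,
                noise: NoiseSpec = NoiseSpec(),
                replicate: int = 0) -> IVCurve:
    """Ohmic tail-current family I(V) = g (V - erev), in pA.

    Noise sigma is a fraction of the current range across the family.
    """
    v = np.asarray(potentials, dtype=float)
    if v.size < 2 or not (v.min() < erev < v.max()):
        raise ValueError(
            "need at least 2 potentials straddling the reversal potential")
    i = g * (v - erev)
    i = noise.apply(i, float(np.ptp(i)) or 1.0, replicate)
    return IVCurve(potentials=v, currents=i)
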