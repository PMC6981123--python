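"""Vesicle flux kinetics: HPTS proton/cation-exchange trace analysis.

The HPTS assay reports the intravesicular pH of dye-loaded liposomes as a
fluorescence signal.  After an external base pulse imposes a one-unit pH
gradient, a membrane-inserted ionophore collapses the gradient by H+/M+
exchange; the normalized internal pH then rises as a single exponential

    y(t) = plateau * (1 - exp(-k_obs * (t - t_base))),   t_base <= t <= t_lysis

with pseudo-first-order rate constant ``k_obs``.  Detergent lysis at
``t_lysis`` destroys the gradient and defines the 100% level.  This module
normalizes raw traces to the lysis endpoint, fits ``k_obs``, assembles
rate-versus-concentration tables, computes fractional activity at a fixed
readout time, and performs Hill analysis (EC50 and Hill coefficient) of the
resulting dose-response.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, stats

from .errors import DegenerateTraceError, FitError, InsufficientDataError

__all__ = [
    "FluxTrace",
    "FirstOrderFit",
    "DoseResponse",
    "HillFit",
    "normalize_trace",
    "fit_first_order",
    "rate_curve",
    "fractional_activity",
    "fit_hill",
    "hill_model",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class FluxTrace:
    """A timestamped HPTS fluorescence trace with its event times.

    Parameters
    ----------
    times : array, s
    signal : array, a.u. or normalized internal-pH proxy in [0, 1]
    t_base : s
        Time of the base (NaOH) pulse that imposes the pH gradient.
    t_lysis : s
        Time of detergent lysis (defines the 100% response level).
    ion_internal, ion_external : str
        Cation labels for the intra-/extravesicular buffers.
    transporter_conc : float or None, μM
    normalized : bool
        Whether ``signal`` is already on the 0 (pre-base) to 1 (post-lysis)
        scale.
    """

    times: np.ndarray
    signal: np.ndarray
    t_base: float
    t_lysis: float
    ion_internal: str = "Na+"
    ion_external: str = "K+"
    transporter_conc: float | None = None
    normalized: bool = False

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.times.shape != self.signal.shape:
            raise ValueError("times and signal must have equal length")
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if not self.t_base < self.t_lysis:
            raise ValueError("t_base must precede t_lysis")

    def value_at(self, t: float) -> float:
        """Signal linearly interpolated at time ``t``."""
        return float(np.interp(t, self.times, self.signal))


@dataclass
class FirstOrderFit:
    """Result of a pseudo-first-order exponential fit."""

    k_obs: float                 # s^-1
    plateau: float               # normalized asymptote
    residual_sse: float
    fit_window: tuple[float, float]
    k_obs_se: float = float("nan")
    plateau_se: float = float("nan")
    flags: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.k_obs < 0:
            raise ValueError("k_obs must be non-negative")


@dataclass
class DoseResponse:
    """Fractional activity versus transporter concentration."""

    concentrations: np.ndarray   # μM
    activity: np.ndarray         # Y, dimensionless
    readout_time: float = 300.0  # s
    flags: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.activity = np.asarray(self.activity, dtype=float)
        if self.concentrations.shape != self.activity.shape:
            raise ValueError("concentrations and activity must match in length")


@dataclass
class HillFit:
    """Fitted Hill parameters for a dose-response curve."""

    ec50: float                  # μM
    n_hill: float
    residual_sse: float
    ec50_se: float = float("nan")
    n_hill_se: float = float("nan")
    flags: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.ec50 > 0:
            raise ValueError("ec50 must be positive")
        if not self.n_hill > 0:
            raise ValueError("n_hill must be positive")

    def predict(self, c):
        return hill_model(np.asarray(c, dtype=float), self.ec50, self.n_hill)


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------

def first_order_model(t, k_obs, plateau, t_base):
    """plateau * (1 - exp(-k_obs (t - t_base))) for t >= t_base."""
    t = np.asarray(t, dtype=float)
    return plateau * -np.expm1(-k_obs * np.clip(t - t_base, 0.0, None))


def hill_model(c, ec50, n):
    """Hill equation Y = c^n / (EC50^n + c^n); Y(0) = 0."""
    c = np.asarray(c, dtype=float)
    out = np.zeros_like(c)
    pos = c > 0
    r = (c[pos] / ec50) ** n
    out[pos] = r / (1.0 + r)
    return out


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def normalize_trace(raw: FluxTrace) -> FluxTrace:
    """Normalize a raw trace to the pre-base baseline and post-lysis plateau.

    The output signal is (I_t - I0) / (Iinf - I0), where I0 is the mean over
    samples strictly before the base pulse and Iinf the mean over samples
    strictly after lysis.  Noise may push values slightly outside [0, 1];
    they are not clipped.
    """
    pre = raw.times < raw.t_base
    post = raw.times > raw.t_lysis
    if pre.sum() < 3 or post.sum() < 3:
        raise InsufficientDataError(
            "need >=3 samples before the base pulse and >=3 after lysis "
            f"(got {int(pre.sum())} and {int(post.sum())})"
        )
    i0 = float(raw.signal[pre].mean())
    iinf = float(raw.signal[post].mean())
    if iinf <= i0:
        raise DegenerateTraceError(
            f"no net response: post-lysis mean {iinf:.4g} <= baseline {i0:.4g}"
        )
    return replace(raw, signal=(raw.signal - i0) / (iinf - i0), normalized=True)


def fit_first_order(trace: FluxTrace,
                    window: tuple[float, float] | None = None) -> FirstOrderFit:
    """Least-squares fit of the pseudo-first-order influx model.

    The model y(t) = plateau (1 - e^{-k (t - t_base)}) is fit over ``window``
    (default: the span between the base pulse and lysis).  The rate start
    value comes from a log-linear regression of 1 - y/plateau0, the usual
    robust initialization for exponential approaches.
    """
    if window is None:
        window = (trace.t_base, trace.t_lysis)
    lo, hi = window
    mask = (trace.times >= lo) & (trace.times <= hi)
    if mask.sum() < 4:
        raise InsufficientDataError("fit window contains fewer than 4 samples")
    t = trace.times[mask]
    y = trace.signal[mask]

    plateau0 = max(float(y[-1]), 1e-6)
    # log-linear start for k: ln(1 - y/plateau) = -k (t - t_base)
    frac = 1.0 - y / (plateau0 * 1.05)
    ok = frac > 1e-3
    if ok.sum() >= 2 and np.ptp(t[ok]) > 0:
        slope, _, _, _, _ = stats.linregress(t[ok] - trace.t_base,
                                             np.log(frac[ok]))
        k0 = max(-float(slope), 1e-6)
    else:
        k0 = 1.0 / max(np.ptp(t), 1.0)
    p0 = (k0, plateau0)

    def model(tt, k, plateau):
        return first_order_model(tt, k, plateau, trace.t_base)

    try:
        popt, pcov = optimize.curve_fit(
            model, t, y, p0=p0, bounds=([0.0, 1e-9], [np.inf, 2.0]),
            maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - rare
        raise FitError("first-order fit did not converge",
                       initial_guess=p0, diagnostics=str(exc)) from exc
    resid = y - model(t, *popt)
    se = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else [np.nan] * 2
    return FirstOrderFit(
        k_obs=float(popt[0]), plateau=float(popt[1]),
        residual_sse=float(resid @ resid), fit_window=(float(lo), float(hi)),
        k_obs_se=float(se[0]), plateau_se=float(se[1]),
    )


def rate_curve(traces: list[FluxTrace], window=None):
    """Fit every trace and tabulate k_obs against transporter concentration.

    Replicates (duplicate concentrations) are aggregated as mean +/- SD.
    Failed fits are reported in the ``failures`` attribute of the returned
    DataFrame, never silently dropped.

    Returns
    -------
    pandas.DataFrame with columns
        ``concentration_uM, k_obs, k_obs_sd, n_replicates, n_failed``,
    sorted by concentration.  ``df.attrs['failures']`` holds a list of
    (concentration, error message) pairs.
    """
    import pandas as pd

    rows: dict[float, list[float]] = {}
    failures: list[tuple[float, str]] = []
    for tr in traces:
        if tr.transporter_conc is None:
            raise ValueError("every trace needs a transporter_conc tag")
        c = float(tr.transporter_conc)
        try:
            fit = fit_first_order(tr, window=window)
            rows.setdefault(c, []).append(fit.k_obs)
        except (FitError, InsufficientDataError) as exc:
            rows.setdefault(c, [])
            failures.append((c, str(exc)))
    table = pd.DataFrame(
        [
            {
                "concentration_uM": c,
                "k_obs": float(np.mean(ks)) if ks else np.nan,
                "k_obs_sd": float(np.std(ks, ddof=1)) if len(ks) > 1 else 0.0
                if ks else np.nan,
                "n_replicates": len(ks),
                "n_failed": sum(1 for fc, _ in failures if fc == c),
            }
            for c, ks in rows.items()
        ]
    ).sort_values("concentration_uM", ignore_index=True)
    table.attrs["failures"] = failures
    return table


def fractional_activity(traces: list[FluxTrace],
                        t_read: float = 300.0) -> DoseResponse:
    """Fractional activity Y at a fixed readout time, per concentration.

    Y(c) = (y_c(t_read) - y_blank(t_read)) / (y_max(t_read) - y_blank(t_read))
    where the blank is the 0 μM trace and y_max the largest response at
    t_read.  Without a blank the raw readouts are returned with a
    ``no-blank`` flag.
    """
    flags: list[str] = []
    for tr in traces:
        if not (tr.t_base < t_read < tr.t_lysis):
            raise ValueError(
                f"t_read={t_read} must lie between the base pulse and lysis"
            )
    concs = np.array([float(tr.transporter_conc) for tr in traces])
    reads = np.array([tr.value_at(t_read) for tr in traces])
    order = np.argsort(concs)
    concs, reads = concs[order], reads[order]

    blank_idx = np.flatnonzero(concs == 0.0)
    if blank_idx.size == 0:
        flags.append("no-blank")
        activity = reads
    else:
        y0 = float(reads[blank_idx].mean())
        ymax = float(reads.max())
        if ymax <= y0:
            raise DegenerateTraceError("maximal response does not exceed blank")
        activity = (reads - y0) / (ymax - y0)
    return DoseResponse(concentrations=concs, activity=activity,
                        readout_time=t_read, flags=flags)


def fit_hill(dr: DoseResponse) -> HillFit:
    """Fit the Hill equation Y = c^n / (EC50^n + c^n) to a dose-response.

    EC50 is bounded to (0, 10 * max concentration] and n to (0, 10]; a Hill
    exponent is not identifiable beyond that on sparse dose designs.  Data
    never reaching half-maximal activity are fit anyway and flagged
    ``no-saturation`` (the behaviour seen for poorly transported ions).
    """
    c, y = dr.concentrations, dr.activity
    distinct = np.unique(c[c > 0])
    if distinct.size < 4:
        raise InsufficientDataError("need >=4 distinct non-zero concentrations")
    flags = list(dr.flags)
    if np.nanmax(y) < 0.5:
        flags.append("no-saturation")

    # start EC50 at the concentration whose response is nearest half-maximal
    ec50_0 = float(c[np.argmin(np.abs(y - 0.5))])
    if ec50_0 <= 0:
        ec50_0 = float(np.median(distinct))
    p0 = (ec50_0, 1.0)
    hi_ec50 = 10.0 * float(c.max())
    try:
        popt, pcov = optimize.curve_fit(
            hill_model, c, y, p0=p0,
            bounds=([1e-12, 1e-3], [hi_ec50, 10.0]), maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        raise FitError("Hill fit did not converge",
                       initial_guess=p0, diagnostics=str(exc)) from exc
    resid = y - hill_model(c, *popt)
    se = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else [np.nan] * 2
    return HillFit(ec50=float(popt[0]), n_hill=float(popt[1]),
                   residual_sse=float(resid @ resid),
                   ec50_se=float(se[0]), n_hill_se=float(se[1]), flags=flags)
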