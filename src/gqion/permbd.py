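"""Brownian-dynamics electro-diffusion model of transmembrane permeation.

A reduced, one-dimensional surrogate for applied-field permeation
simulations: each ion species moves along the membrane normal z in a
periodic box of length L_z under a species-specific potential of mean force
W(z) plus the uniform force from a transmembrane voltage, integrated with
the overdamped (Euler-Maruyama) Langevin step

    z <- z + (D/kT) F(z) dt + sqrt(2 D dt) xi,
    F(z) = -dW/dz + q V / L_z.

Ions are independent (no pairwise interactions); concentration enters
through the ion count N per species.  From trajectories the module computes
the total-intensity instantaneous current

    I(t + dt/2) = (1/(dt L_z)) sum_i q_i dz_i,

its per-species decomposition and cumulative transferred charge, block-
averaged mean currents, I-V scans with ohmic conductance, equilibrium
density profiles, and PMFs recovered by Boltzmann inversion of those
densities.

Internal units: nm, ns, elementary charge e, mV.  Energies are carried in
e*mV (kT = 25.693 e*mV at 298.15 K) and currents convert via
1 e/ns = 160.218 pA, so every constant stays order-1 and conversions exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ModelError, StepSizeError, TrajectoryError
from .patchan import IVCurve

__all__ = [
    "SpeciesSpec", "ChannelModel", "IonTrajectory", "PermeationResult",
    "IVScanResult", "run_bd", "total_intensity_current", "iv_scan",
    "density_profile", "pmf_boltzmann", "gaussian_barrier_pmf",
    "model_to_dict", "model_from_dict",
    "KT_EMV_298", "PA_PER_E_NS",
]

#: kT in e*mV at 298.15 K  (1000 * R * T / F)
KT_EMV_298 = 25.693
#: picoamperes per elementary charge per nanosecond
PA_PER_E_NS = 160.218


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class SpeciesSpec:
    """One ion species: charge, mobility, PMF and copy number."""

    label: str
    q: float                    # valence, elementary charges
    d: float                    # diffusion coefficient, nm^2/ns
    pmf: np.ndarray             # W(z) on a uniform grid over [0, L_z], e*mV
    n_ions: int

    def __post_init__(self):
        self.pmf = np.asarray(self.pmf, dtype=float)
        if self.d < 0:
            raise ModelError("diffusion coefficient must be non-negative")
        if self.pmf.size < 2:
            raise ModelError("PMF grid needs at least 2 nodes")
        if not np.isclose(self.pmf[0], self.pmf[-1]):
            raise ModelError(
                f"PMF for {self.label} is not periodic: W(0)={self.pmf[0]:.4g}"
                f" != W(L_z)={self.pmf[-1]:.4g}")
        if self.n_ions < 0:
            raise ModelError("ion count must be non-negative")


@dataclass
class ChannelModel:
    """Species set plus box geometry and temperature."""

    species: list[SpeciesSpec]
    l_z: float                  # nm
    temperature: float = 298.15  # K

    def __post_init__(self):
        if not self.l_z > 0:
            raise ModelError("box length must be positive")
        if not self.temperature > 0:
            raise ModelError("temperature must be positive")

    @property
    def kt_emv(self) -> float:
        """kT in e*mV at the model temperature."""
        return KT_EMV_298 * self.temperature / 298.15

    def z_grid(self, spec: SpeciesSpec) -> np.ndarray:
        return np.linspace(0.0, self.l_z, spec.pmf.size)


@dataclass
class IonTrajectory:
    """Per-frame z positions of all ions (wrapped and unwrapped)."""

    times: np.ndarray           # ns, frame times
    z_wrapped: np.ndarray       # (n_frames, n_ions), in [0, L_z)
    z_unwrapped: np.ndarray     # (n_frames, n_ions)
    species: np.ndarray         # (n_ions,) labels
    charges: np.ndarray         # (n_ions,) e
    v_applied: float            # mV
    l_z: float                  # nm
    dt: float                   # ns, integrator step

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if np.any(self.z_wrapped < 0) or np.any(self.z_wrapped >= self.l_z):
            raise TrajectoryError("wrapped coordinates outside [0, L_z)")
        winding = (self.z_unwrapped - self.z_wrapped) / self.l_z
        if not np.allclose(winding, np.round(winding), atol=1e-6):
            raise TrajectoryError(
                "unwrapped minus wrapped is not an integer number of box lengths")


@dataclass
class PermeationResult:
    """Currents and transferred charge derived from a trajectory."""

    t_mid: np.ndarray                    # ns, midpoints of frame intervals
    current_pa: np.ndarray               # instantaneous total current
    species_current_pa: dict             # label -> instantaneous current
    cumulative_charge_e: np.ndarray      # total transferred charge, e
    species_cumulative_e: dict           # label -> cumulative charge
    mean_pa: float                       # stationary-window block mean
    se_pa: float
    species_mean_pa: dict                # label -> (mean, se)
    equil_fraction: float
    n_blocks: int


@dataclass
class IVScanResult:
    """I-V scan over applied biases with ohmic summary."""

    iv: IVCurve
    se_pa: np.ndarray
    g_ns: float
    g_se: float = float("nan")
    r_squared: float = float("nan")
    linear: bool = True
    results: list[PermeationResult] = field(default_factory=list)


def gaussian_barrier_pmf(l_z: float, height: float, width: float,
                         center: float | None = None,
                         n_nodes: int = 101) -> np.ndarray:
    """Periodic Gaussian membrane barrier W(z), in e*mV.

    ``height`` is the barrier top relative to the bulk (edges), ``width``
    the Gaussian sigma in nm; the profile is pinned to equal values at both
    box ends so it is periodic.
    """
    if center is None:
        center = 0.5 * l_z
    z = np.linspace(0.0, l_z, n_nodes)
    w = height * np.exp(-0.5 * ((z - center) / width) ** 2)
    w -= 0.5 * (w[0] + w[-1])
    w[0] = w[-1] = min(w[0], w[-1])
    w -= w.min()
    return w


def model_to_dict(model: ChannelModel) -> dict:
    """JSON-ready dictionary form of a channel model."""
    return {
        "l_z_nm": model.l_z,
        "temperature_K": model.temperature,
        "species": [
            {"label": s.label, "q": s.q, "d_nm2_ns": s.d,
             "n_ions": s.n_ions, "pmf_emv": s.pmf.tolist()}
            for s in model.species
        ],
    }


def model_from_dict(d: dict) -> ChannelModel:
    species = [
        SpeciesSpec(label=s["label"], q=s["q"], d=s["d_nm2_ns"],
                    pmf=np.asarray(s["pmf_emv"], dtype=float),
                    n_ions=s["n_ions"])
        for s in d["species"]
    ]
    return ChannelModel(species=species, l_z=d["l_z_nm"],
                        temperature=d.get("temperature_K", 298.15))


# ---------------------------------------------------------------------------
# dynamics
# ---------------------------------------------------------------------------

def _grid_force(pmf: np.ndarray, l_z: float) -> np.ndarray:
    """-dW/dz at the grid nodes by centered differences (periodic ends)."""
    dz = l_z / (pmf.size - 1)
    f = np.empty_like(pmf)
    f[1:-1] = -(pmf[2:] - pmf[:-2]) / (2.0 * dz)
    # periodic: node 0 and node -1 are the same physical point
    f[0] = f[-1] = -(pmf[1] - pmf[-2]) / (2.0 * dz)
    return f


def run_bd(model: ChannelModel, v_applied: float, n_steps: int, dt: float,
           seed: int, save_every: int = 10) -> IonTrajectory:
    """Integrate overdamped Langevin dynamics for all ions in the model.

    Positions start uniform over the box (use an equilibration discard in
    downstream estimators).  The step-size precondition requires the maximum
    deterministic drift per step to stay below one grid spacing.
    """
    kt = model.kt_emv
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    labels, charges, z0 = [], [], []
    forces_nodes, diffusion, dz_grid = [], [], []
    for spec in model.species:
        n = spec.n_ions
        labels += [spec.label] * n
        charges += [spec.q] * n
        z0.append(rng.uniform(0.0, model.l_z, size=n))
        f_nodes = _grid_force(spec.pmf, model.l_z) + spec.q * v_applied / model.l_z
        forces_nodes.append(f_nodes)
        diffusion.append(spec.d)
        dz_grid.append(model.l_z / (spec.pmf.size - 1))
        max_drift = spec.d / kt * np.max(np.abs(f_nodes)) * dt
        if max_drift >= model.l_z / (spec.pmf.size - 1):
            raise StepSizeError(
                f"drift per step {max_drift:.3g} nm exceeds the PMF grid "
                f"spacing for species {spec.label}; reduce dt")

    n_ions = len(labels)
    if n_ions == 0:
        raise ModelError("model contains no ions")
    z = np.concatenate(z0)
    unwrapped = z.copy()
    spans = np.cumsum([0] + [s.n_ions for s in model.species])

    n_frames = n_steps // save_every + 1
    zw = np.empty((n_frames, n_ions))
    zu = np.empty((n_frames, n_ions))
    times = np.empty(n_frames)
    zw[0], zu[0], times[0] = z, unwrapped, 0.0

    frame = 1
    for step in range(1, n_steps + 1):
        xi = rng.standard_normal(n_ions)
        for k, spec in enumerate(model.species):
            sl = slice(spans[k], spans[k + 1])
            if spans[k + 1] == spans[k]:
                continue
            # linear interpolation of the node forces at the wrapped positions
            pos = z[sl] / dz_grid[k]
            i0 = np.floor(pos).astype(int)
            w = pos - i0
            i1 = np.minimum(i0 + 1, forces_nodes[k].size - 1)
            f = (1.0 - w) * forces_nodes[k][i0] + w * forces_nodes[k][i1]
            step_z = (diffusion[k] / kt) * f * dt \
                + np.sqrt(2.0 * diffusion[k] * dt) * xi[sl]
            unwrapped[sl] += step_z
            z[sl] = np.mod(z[sl] + step_z, model.l_z)
        # np.mod can round a tiny negative remainder up to exactly L
        np.subtract(z, model.l_z, out=z, where=z >= model.l_z)
        if step % save_every == 0:
            zw[frame], zu[frame] = z, unwrapped
            times[frame] = step * dt
            frame += 1

    return IonTrajectory(times=times[:frame], z_wrapped=zw[:frame],
                         z_unwrapped=zu[:frame],
                         species=np.array(labels), charges=np.array(charges),
                         v_applied=v_applied, l_z=model.l_z, dt=dt)


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

def _block_stats(x: np.ndarray, n_blocks: int) -> tuple[float, float]:
    """Mean and block-averaged standard error."""
    if x.size == 0:
        return float("nan"), float("nan")
    n_blocks = max(min(n_blocks, x.size), 1)
    blocks = np.array_split(x, n_blocks)
    means = np.array([b.mean() for b in blocks])
    se = (float(means.std(ddof=1) / np.sqrt(n_blocks))
          if n_blocks > 1 else float("nan"))
    return float(x.mean()), se


def total_intensity_current(traj: IonTrajectory, equil_fraction: float = 0.25,
                            n_blocks: int = 10) -> PermeationResult:
    """Total-intensity current estimate from charge-weighted displacements.

    I(t + dt/2) = (1/(dt L_z)) sum_i q_i dz_i, with dz from the unwrapped
    coordinates (identical to nearest-image-corrected wrapped differences).
    The stationary mean +/- SE discards the first ``equil_fraction`` of
    frames and block-averages the remainder (default 10 blocks).  Per-species
    currents sum to the total exactly, and the cumulative charge equals the
    discrete time integral of the current.
    """
    if traj.times.size < 2:
        raise TrajectoryError("need at least 2 frames")
    dts = np.diff(traj.times)
    if not np.allclose(dts, dts[0], rtol=1e-9, atol=1e-12):
        raise TrajectoryError("inconsistent frame-time gaps")
    dt = dts[0]
    t_mid = traj.times[:-1] + 0.5 * dt

    dz = np.diff(traj.z_unwrapped, axis=0)                # (n_int, n_ions)
    per_ion = traj.charges[None, :] * dz / (dt * traj.l_z)  # e/ns
    total = per_ion.sum(axis=1) * PA_PER_E_NS             # pA

    labels = [str(s) for s in dict.fromkeys(traj.species)]
    species_i, species_q, species_stats = {}, {}, {}
    for lab in labels:
        mask = traj.species == lab
        i_s = per_ion[:, mask].sum(axis=1) * PA_PER_E_NS
        species_i[lab] = i_s
        species_q[lab] = np.cumsum(i_s * dt) / PA_PER_E_NS

    q_cum = np.cumsum(total * dt) / PA_PER_E_NS           # e

    start = int(np.floor(equil_fraction * total.size))
    mean, se = _block_stats(total[start:], n_blocks)
    for lab in labels:
        species_stats[lab] = _block_stats(species_i[lab][start:], n_blocks)

    return PermeationResult(
        t_mid=t_mid, current_pa=total, species_current_pa=species_i,
        cumulative_charge_e=q_cum, species_cumulative_e=species_q,
        mean_pa=mean, se_pa=se, species_mean_pa=species_stats,
        equil_fraction=equil_fraction, n_blocks=n_blocks)


def iv_scan(model: ChannelModel, voltages, n_steps: int, dt: float,
            seed: int, save_every: int = 10,
            r2_threshold: float = 0.95) -> IVScanResult:
    """One BD trajectory per bias; mean currents and OLS conductance.

    Each bias gets an independent child seed derived from ``seed`` so scans
    are reproducible regardless of voltage order.
    """
    voltages = np.asarray(voltages, dtype=float)
    if not (np.any(voltages > 0) and np.any(voltages < 0)):
        raise ValueError("voltage list must include positive and negative biases")
    children = np.random.SeedSequence(seed).spawn(voltages.size)
    means, ses, results = [], [], []
    for v, child in zip(voltages, children):
        traj = run_bd(model, v, n_steps, dt,
                      seed=int(child.generate_state(1)[0] % (2 ** 31)),
                      save_every=save_every)
        res = total_intensity_current(traj)
        results.append(res)
        means.append(res.mean_pa)
        ses.append(res.se_pa)
    means = np.array(means)
    slope, intercept = np.polyfit(voltages, means, 1)
    pred = slope * voltages + intercept
    tss = float(np.sum((means - means.mean()) ** 2))
    sse = float(np.sum((means - pred) ** 2))
    r2 = 1.0 - sse / tss if tss > 0 else 1.0
    dof = voltages.size - 2
    g_se = float(np.sqrt(sse / dof / np.sum((voltages - voltages.mean()) ** 2))) \
        if dof > 0 else float("nan")
    iv = IVCurve(potentials=voltages, currents=means)
    iv.g = float(slope)
    return IVScanResult(iv=iv, se_pa=np.array(ses), g_ns=float(slope),
                        g_se=g_se, r_squared=r2, linear=bool(r2 >= r2_threshold),
                        results=results)


def density_profile(traj: IonTrajectory, n_bins: int = 50,
                    equil_fraction: float = 0.0):
    """Per-species number density rho(z) from wrapped coordinates.

    rho integrates to the per-species ion count: sum(rho) * bin_width = N.
    Returns (bin_centers, {label: rho}).
    """
    if n_bins < 10:
        raise ValueError("need at least 10 bins")
    edges = np.linspace(0.0, traj.l_z, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    width = edges[1] - edges[0]
    start = int(np.floor(equil_fraction * traj.times.size))
    profiles = {}
    for lab in dict.fromkeys(traj.species):
        lab = str(lab)
        mask = traj.species == lab
        zs = traj.z_wrapped[start:, mask].ravel()
        counts, _ = np.histogram(zs, bins=edges)
        n_frames = traj.times.size - start
        profiles[lab] = counts / (n_frames * width)
    return centers, profiles


def pmf_boltzmann(density: np.ndarray, model: ChannelModel,
                  bulk_fraction: float = 0.1):
    """Recover a PMF from an equilibrium density by Boltzmann inversion.

    W(z) = -kT ln(rho(z)/rho_ref), with rho_ref the mean density over the
    bulk region (the outer ``bulk_fraction`` of the box at each end, where
    the membrane PMF is flat).  Empty bins are masked (NaN).  The profile is
    anchored so its minimum over the bulk region is zero.

    Returns (w_est in e*mV, mask of well-sampled bins).
    """
    density = np.asarray(density, dtype=float)
    n = density.size
    centers = (np.arange(n) + 0.5) * model.l_z / n
    bulk = (centers < bulk_fraction * model.l_z) | \
           (centers > (1.0 - bulk_fraction) * model.l_z)
    good = density > 0
    if not np.any(good & bulk):
        raise ModelError("no occupied bins in the bulk reference region")
    rho_ref = float(density[bulk & good].mean())
    w = np.full(n, np.nan)
    w[good] = -model.kt_emv * np.log(density[good] / rho_ref)
    w -= np.nanmin(w[bulk & good])
    return w, good
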