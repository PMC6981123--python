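"""Plain-text exchange formats and result records.

Every tabular data type travels as CSV with a commented header block:
``# gqion-type: <TypeName>`` followed by ``# key: value`` metadata lines,
then named columns.  :func:`write_table` / :func:`read_table` round-trip
every domain type losslessly.  Fit results serialize as JSON
:class:`ResultRecord` objects carrying parameter estimates, standard
errors, flags, and provenance (input hash, config hash, package version,
seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import io as _io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bindfit import ITCThermogram, JobSeries, MeltCurve, TitrationSeries
from .errors import TableFormatError
from .fluxkin import DoseResponse, FluxTrace
from .patchan import CurrentTrace, IVCurve

__all__ = ["read_table", "write_table", "write_trajectory", "read_trajectory",
           "ResultRecord", "record_from_fit", "config_hash", "input_hash"]


def _meta_value(v):
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return "none"
    return v


def _parse_meta(raw: str):
    if raw == "none":
        return None
    for cast in (int, float):
        try:
            return cast(raw)
        except ValueError:
            pass
    return raw


# per-type (columns, metadata fields) layout ---------------------------------

def _flux_payload(obj: FluxTrace):
    df = pd.DataFrame({"time_s": obj.times, "signal": obj.signal})
    meta = {"t_base_s": obj.t_base, "t_lysis_s": obj.t_lysis,
            "ion_internal": obj.ion_internal, "ion_external": obj.ion_external,
            "transporter_conc_uM": obj.transporter_conc,
            "normalized": int(obj.normalized)}
    return df, meta


def _flux_load(df, meta):
    return FluxTrace(times=df["time_s"].to_numpy(),
                     signal=df["signal"].to_numpy(),
                     t_base=meta["t_base_s"], t_lysis=meta["t_lysis_s"],
                     ion_internal=str(meta.get("ion_internal", "")),
                     ion_external=str(meta.get("ion_external", "")),
                     transporter_conc=meta.get("transporter_conc_uM"),
                     normalized=bool(meta.get("normalized", 0)))


def _dose_payload(obj: DoseResponse):
    df = pd.DataFrame({"concentration_uM": obj.concentrations,
                       "activity": obj.activity})
    return df, {"readout_time_s": obj.readout_time,
                "flags": ";".join(obj.flags) or "none"}


def _dose_load(df, meta):
    flags = meta.get("flags")
    return DoseResponse(concentrations=df["concentration_uM"].to_numpy(),
                        activity=df["activity"].to_numpy(),
                        readout_time=meta.get("readout_time_s", 300.0),
                        flags=str(flags).split(";") if flags else [])


def _melt_payload(obj: MeltCurve):
    return (pd.DataFrame({"temperature_C": obj.temps, "signal": obj.signal}),
            {"label": obj.label or "none"})


def _melt_load(df, meta):
    return MeltCurve(temps=df["temperature_C"].to_numpy(),
                     signal=df["signal"].to_numpy(),
                     label=str(meta.get("label") or ""))


def _titration_payload(obj: TitrationSeries):
    return (pd.DataFrame({"titrant_uM": obj.titrant_concs,
                          "signal": obj.signal}),
            {"probe_conc_uM": obj.probe_conc})


def _titration_load(df, meta):
    return TitrationSeries(titrant_concs=df["titrant_uM"].to_numpy(),
                           signal=df["signal"].to_numpy(),
                           probe_conc=meta["probe_conc_uM"])


def _job_payload(obj: JobSeries):
    return (pd.DataFrame({"mole_fraction": obj.mole_fractions,
                          "signal": obj.signal}),
            {"total_conc_uM": obj.total_conc})


def _job_load(df, meta):
    return JobSeries(mole_fractions=df["mole_fraction"].to_numpy(),
                     signal=df["signal"].to_numpy(),
                     total_conc=meta["total_conc_uM"])


def _itc_payload(obj: ITCThermogram):
    return (pd.DataFrame({"molar_ratio": obj.molar_ratios,
                          "heat_kcal_per_mol": obj.heats}),
            {"cell_conc_uM": obj.cell_conc, "syringe_conc_uM": obj.syringe_conc,
             "v_inject_uL": obj.v_inject, "cell_vol_uL": obj.cell_vol})


def _itc_load(df, meta):
    return ITCThermogram(heats=df["heat_kcal_per_mol"].to_numpy(),
                         molar_ratios=df["molar_ratio"].to_numpy(),
                         cell_conc=meta["cell_conc_uM"],
                         syringe_conc=meta["syringe_conc_uM"],
                         v_inject=meta["v_inject_uL"],
                         cell_vol=meta["cell_vol_uL"])


def _current_payload(obj: CurrentTrace):
    return (pd.DataFrame({"time_ms": obj.times_ms, "current_pA": obj.current}),
            {"fs_kHz": obj.fs_khz, "v_hold_mV": obj.v_hold,
             **{f"solution_{k}": v for k, v in obj.solutions.items()}})


def _current_load(df, meta):
    solutions = {k[len("solution_"):]: v for k, v in meta.items()
                 if k.startswith("solution_")}
    return CurrentTrace(current=df["current_pA"].to_numpy(),
                        fs_khz=meta["fs_kHz"], v_hold=meta["v_hold_mV"],
                        solutions=solutions)


def _iv_payload(obj: IVCurve):
    return (pd.DataFrame({"potential_mV": obj.potentials,
                          "current_pA": obj.currents}),
            {"erev_mV": obj.erev, "g_nS": obj.g})


def _iv_load(df, meta):
    return IVCurve(potentials=df["potential_mV"].to_numpy(),
                   currents=df["current_pA"].to_numpy(),
                   erev=meta.get("erev_mV") if meta.get("erev_mV") is not None
                   else float("nan"),
                   g=meta.get("g_nS") if meta.get("g_nS") is not None
                   else float("nan"))


_REGISTRY = {
    "FluxTrace": (FluxTrace, _flux_payload, _flux_load),
    "DoseResponse": (DoseResponse, _dose_payload, _dose_load),
    "MeltCurve": (MeltCurve, _melt_payload, _melt_load),
    "TitrationSeries": (TitrationSeries, _titration_payload, _titration_load),
    "JobSeries": (JobSeries, _job_payload, _job_load),
    "ITCThermogram": (ITCThermogram, _itc_payload, _itc_load),
    "CurrentTrace": (CurrentTrace, _current_payload, _current_load),
    "IVCurve": (IVCurve, _iv_payload, _iv_load),
}


def write_table(obj, path) -> None:
    """Write any gqion data object as commented-header CSV."""
    for name, (cls, dump, _) in _REGISTRY.items():
        if isinstance(obj, cls):
            df, meta = dump(obj)
            lines = [f"# gqion-type: {name}"]
            lines += [f"# {k}: {_meta_value(v)}" for k, v in meta.items()]
            buf = _io.StringIO()
            df.to_csv(buf, index=False, lineterminator="\n")
            Path(path).write_text("\n".join(lines) + "\n" + buf.getvalue())
            return
    raise TableFormatError(f"no table layout for object of type {type(obj)!r}")


def read_table(path):
    """Read a gqion CSV back into its declared domain type.

    The ``# gqion-type`` tag in the header block selects the target type;
    the type's own invariants are validated on construction, producing an
    informative error when violated.
    """
    text = Path(path).read_text()
    meta: dict = {}
    type_tag = None
    body_lines = []
    for line in text.splitlines():
        if line.startswith("#"):
            stripped = line.lstrip("#").strip()
            if ":" not in stripped:
                raise TableFormatError(f"malformed header line: {line!r}")
            key, _, raw = stripped.partition(":")
            key, raw = key.strip(), raw.strip()
            if key == "gqion-type":
                type_tag = raw
            else:
                meta[key] = _parse_meta(raw)
        else:
            body_lines.append(line)
    if type_tag is None:
        raise TableFormatError(f"{path}: missing '# gqion-type' tag")
    if type_tag not in _REGISTRY:
        raise TableFormatError(f"{path}: unknown type tag {type_tag!r}")
    df = pd.read_csv(_io.StringIO("\n".join(body_lines)))
    _, _, load = _REGISTRY[type_tag]
    try:
        return load(df, meta)
    except (KeyError, ValueError) as exc:
        raise TableFormatError(f"{path}: invalid {type_tag}: {exc}") from exc


# ---------------------------------------------------------------------------
# trajectories (long-format columnar text, gzip tolerated via suffix)
# ---------------------------------------------------------------------------

def write_trajectory(traj, path, model=None) -> None:
    """Write an ion trajectory as long-format columnar text.

    Columns: frame, time_ns, ion_id, species, z_wrapped, z_unwrapped.
    Box and bias metadata travel in the ``#`` header; if ``model`` is given a
    JSON sidecar ``<path>.model.json`` stores the full channel model.
    A ``.gz`` suffix triggers transparent compression.
    """
    from .permbd import model_to_dict

    n_frames, n_ions = traj.z_wrapped.shape
    frames = np.repeat(np.arange(n_frames), n_ions)
    df = pd.DataFrame({
        "frame": frames,
        "time_ns": np.repeat(traj.times, n_ions),
        "ion_id": np.tile(np.arange(n_ions), n_frames),
        "species": np.tile(traj.species, n_frames),
        "z_wrapped": traj.z_wrapped.ravel(),
        "z_unwrapped": traj.z_unwrapped.ravel(),
    })
    charges = {}
    for lab, q in zip(traj.species, traj.charges):
        charges[str(lab)] = float(q)
    header = "\n".join([
        "# gqion-type: IonTrajectory",
        f"# v_applied_mV: {traj.v_applied}",
        f"# l_z_nm: {traj.l_z}",
        f"# dt_ns: {traj.dt}",
        f"# charges: {json.dumps(charges)}",
    ]) + "\n"
    path = Path(path)
    if path.suffix == ".gz":
        import gzip
        with gzip.open(path, "wt") as fh:
            fh.write(header)
            df.to_csv(fh, index=False, lineterminator="\n")
    else:
        with open(path, "w") as fh:
            fh.write(header)
            df.to_csv(fh, index=False, lineterminator="\n")
    if model is not None:
        Path(str(path) + ".model.json").write_text(
            json.dumps(model_to_dict(model), indent=1))


def read_trajectory(path):
    """Read a trajectory written by :func:`write_trajectory`."""
    from .permbd import IonTrajectory

    path = Path(path)
    opener = None
    if path.suffix == ".gz":
        import gzip
        opener = gzip.open
    meta = {}
    with (opener(path, "rt") if opener else open(path)) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if not line.startswith("#"):
                fh.seek(pos)
                break
            pos = fh.tell()
            key, _, raw = line.lstrip("#").strip().partition(":")
            meta[key.strip()] = raw.strip()
        df = pd.read_csv(fh)
    if meta.get("gqion-type") != "IonTrajectory":
        raise TableFormatError(f"{path}: not an IonTrajectory file")
    charges_by_species = json.loads(meta["charges"])
    n_ions = int(df["ion_id"].max()) + 1
    n_frames = int(df["frame"].max()) + 1
    df = df.sort_values(["frame", "ion_id"], kind="stable")
    species = df["species"].to_numpy()[:n_ions].astype(str)
    return IonTrajectory(
        times=df["time_ns"].to_numpy()[::n_ions].copy(),
        z_wrapped=df["z_wrapped"].to_numpy().reshape(n_frames, n_ions),
        z_unwrapped=df["z_unwrapped"].to_numpy().reshape(n_frames, n_ions),
        species=species,
        charges=np.array([charges_by_species[s] for s in species]),
        v_applied=float(meta["v_applied_mV"]),
        l_z=float(meta["l_z_nm"]),
        dt=float(meta["dt_ns"]),
    )


# ---------------------------------------------------------------------------
# result records
# ---------------------------------------------------------------------------

def _sha256(data: bytes) -> str:
    return hashlib.sha256(data).hexdigest()


def config_hash(config: dict) -> str:
    """Stable hash of the semantically meaningful config content."""
    return _sha256(json.dumps(config, sort_keys=True, default=str).encode())


def input_hash(path) -> str:
    return _sha256(Path(path).read_bytes())


@dataclass
class ResultRecord:
    """One analysis result with parameters, flags and provenance."""

    operation: str
    parameters: dict                      # name -> {"estimate": x, "se": s}
    flags: list[str] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def to_json(self) -> str:
        def default(o):
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            if isinstance(o, np.ndarray):
                return o.tolist()
            raise TypeError(f"not JSON-serializable: {type(o)}")
        return json.dumps(dataclasses.asdict(self), sort_keys=True,
                          default=default)

    @classmethod
    def from_json(cls, text: str) -> "ResultRecord":
        d = json.loads(text)
        return cls(operation=d["operation"], parameters=d["parameters"],
                   flags=d.get("flags", []), provenance=d.get("provenance", {}))


def record_from_fit(operation: str, fit, param_names: dict[str, str],
                    provenance: dict | None = None) -> ResultRecord:
    """Build a ResultRecord from any fit dataclass.

    ``param_names`` maps record parameter names to fit attribute names; a
    matching ``<attr>_se`` attribute, when present, supplies the SE.
    """
    params = {}
    for out_name, attr in param_names.items():
        est = getattr(fit, attr)
        se = getattr(fit, f"{attr}_se", float("nan"))
        params[out_name] = {"estimate": float(est),
                            "se": float(se) if se == se else None}
    sse = getattr(fit, "residual_sse", None)
    if sse is not None and sse == sse:
        params["sse"] = {"estimate": float(sse), "se": None}
    prov = {"package_version": __version__}
    prov.update(provenance or {})
    return ResultRecord(operation=operation, parameters=params,
                        flags=list(getattr(fit, "flags", [])), provenance=prov)
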