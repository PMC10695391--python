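"""File formats, packaged fixtures and run configuration.

All tabular formats are comma-separated UTF-8 text with a header row;
metadata (seed, config hash) is embedded as ``# key: value`` comment lines
that readers skip.  Times are stored in days from a per-file origin
(diagnosis for patient files, treatment start for protocol files);
volumes are cm^3 throughout.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .fitting import FITTED_NAMES, FitResult, PatientRecord
from .model import DEFAULT_CLEARANCE, ModelParams, SimulationConfig, Trajectory, simulate
from .protocols import DoseEvent, Protocol, build_c28


class ParseError(ValueError):
    """A data file is malformed; the message names the offending line."""


class CorruptedFixtureError(RuntimeError):
    """A packaged data file does not match its recorded checksum."""


# sha256 of the packaged data files, fixed when they were generated
_CHECKSUMS = {
    "lgg_fitted_parameters.csv":
        "28661080e86b9defdf6790fd11f62295ae02452229f60530dea878bd5427700a",
    "synthetic_baseline_volumes.csv":
        "bdb34ac212f82763a9f94c42bf5389c0bbccbcc6602f340ba55aba63e2bf6aa3",
}


def _read_packaged(name: str) -> str:
    text = resources.files("gliotmz.data").joinpath(name).read_text(encoding="utf-8")
    digest = hashlib.sha256(text.encode("utf-8")).hexdigest()
    if digest != _CHECKSUMS[name]:
        raise CorruptedFixtureError(f"checksum mismatch for packaged file {name}")
    return text


@dataclass(frozen=True)
class Fixture:
    """Packaged reference data.

    ``param_table``: per-patient fitted rate constants (day^-1) for seven
    LGG patients with acquired TMZ resistance, indexed by patient number.
    ``baseline_volumes``: synthetic stand-in list of pre-chemotherapy
    volumes (cm^3) used by the cohort generator's KDE.
    ``demo_record``: a synthetic longitudinal record (patient-3-like
    dynamics under a cyclic schedule with multiplicative measurement
    noise) for examples and smoke tests.
    """

    param_table: pd.DataFrame
    baseline_volumes: tuple
    demo_record: PatientRecord


def fixture_params(table: pd.DataFrame, patient: int) -> ModelParams:
    """ModelParams for one patient row of the packaged table."""
    row = table.loc[patient]
    return ModelParams(
        rho1=row["rho1"], rho2=row["rho2"], psi=row["psi"],
        alpha1=row["alpha1"], alpha2=row["alpha2"], tau=row["tau"],
        beta=0.1, lam=DEFAULT_CLEARANCE,
    )


def _make_demo_record(params: ModelParams) -> PatientRecord:
    """Synthetic demo patient: cyclic treatment, 18% multiplicative noise."""
    schedule = build_c28(16, e0=1.0, start=60.0)
    obs_times = np.arange(0.0, 2501.0, 250.0)
    cfg = SimulationConfig(output_step=250.0, horizon=2600.0)
    traj = simulate(params, 35.0, schedule, cfg)
    volumes = np.interp(obs_times, traj.times, traj.total_volume)
    rng = np.random.default_rng(20231120)
    noisy = volumes * np.exp(rng.normal(0.0, 0.18, volumes.size))
    return PatientRecord(
        patient_id="demo",
        obs_times=obs_times,
        obs_volumes=noisy,
        schedule=schedule,
        volume_uncertainty=0.18,
    )


_fixture_cache: Fixture | None = None


def load_fixture() -> Fixture:
    """Load (and checksum-verify) the packaged fixtures."""
    global _fixture_cache
    if _fixture_cache is None:
        from io import StringIO

        table = pd.read_csv(
            StringIO(_read_packaged("lgg_fitted_parameters.csv")), comment="#"
        ).set_index("patient")
        table = table[list(FITTED_NAMES)].astype(float)
        vols = pd.read_csv(
            StringIO(_read_packaged("synthetic_baseline_volumes.csv")), comment="#"
        )["volume_cm3"].astype(float)
        demo = _make_demo_record(fixture_params(table, 3))
        _fixture_cache = Fixture(
            param_table=table,
            baseline_volumes=tuple(vols),
            demo_record=demo,
        )
    return _fixture_cache


# ---------------------------------------------------------------------------
# readers


def _read_table(path, required: set[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: cannot parse: {exc}") from exc
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    for col in required:
        bad = df[pd.to_numeric(df[col], errors="coerce").isna() & (col != "patient_id")]
        if col != "patient_id" and len(bad):
            raise ParseError(
                f"{path}: non-numeric value in column {col!r} at line {bad.index[0] + 2}"
            )
    return df


def read_patients(path, schedule_path) -> list[PatientRecord]:
    """Read long-format patient volumes plus a companion schedule file.

    Patient file columns: patient_id, day, volume_cm3.  Schedule file
    columns: patient_id, day, e0.  Times are days from diagnosis.
    """
    df = _read_table(path, {"patient_id", "day", "volume_cm3"})
    sched = _read_table(schedule_path, {"patient_id", "day", "e0"})
    if (df["volume_cm3"].astype(float) <= 0).any():
        line = df.index[df["volume_cm3"].astype(float) <= 0][0] + 2
        raise ParseError(f"{path}: non-positive volume at line {line}")
    records = []
    for pid, grp in df.groupby("patient_id", sort=True):
        grp = grp.sort_values("day")
        if grp["day"].duplicated().any():
            day = grp.loc[grp["day"].duplicated(), "day"].iloc[0]
            raise ParseError(f"{path}: duplicate observation day {day} for {pid}")
        s = sched[sched["patient_id"] == pid].sort_values("day")
        protocol = Protocol(
            f"{pid}-schedule",
            tuple(
                DoseEvent(float(t), float(e))
                for t, e in zip(s["day"], s["e0"])
            ),
        )
        records.append(
            PatientRecord(
                patient_id=str(pid),
                obs_times=grp["day"].to_numpy(dtype=float),
                obs_volumes=grp["volume_cm3"].to_numpy(dtype=float),
                schedule=protocol,
            )
        )
    return records


def read_protocol(path, name: str | None = None) -> Protocol:
    df = _read_table(path, {"time_days", "e0"})
    doses = tuple(
        DoseEvent(float(t), float(e)) for t, e in zip(df["time_days"], df["e0"])
    )
    return Protocol(name or Path(path).stem, doses)


# ---------------------------------------------------------------------------
# writers


def _metadata_lines(metadata: dict | None) -> str:
    if not metadata:
        return ""
    return "".join(f"# {k}: {v}\n" for k, v in metadata.items())


def write_protocol(protocol: Protocol, path, metadata: dict | None = None) -> None:
    df = pd.DataFrame({"time_days": protocol.times, "e0": protocol.e0s})
    Path(path).write_text(_metadata_lines(metadata) + df.to_csv(index=False))


def write_trajectory(traj: Trajectory, path, metadata: dict | None = None) -> None:
    """Trajectory table plus an events sidecar (``<path>.events.csv``)."""
    path = Path(path)
    path.write_text(_metadata_lines(metadata) + traj.to_frame().to_csv(index=False))
    events = pd.DataFrame({"time_days": traj.dose_times, "e0": traj.dose_e0})
    path.with_suffix(path.suffix + ".events.csv").write_text(
        _metadata_lines(metadata) + events.to_csv(index=False)
    )


def write_patients(records, path, schedule_path, metadata: dict | None = None) -> None:
    rows, srows = [], []
    for r in records:
        for t, v in zip(r.obs_times, r.obs_volumes):
            rows.append({"patient_id": r.patient_id, "day": t, "volume_cm3": v})
        for d in r.schedule.doses:
            srows.append({"patient_id": r.patient_id, "day": d.time, "e0": d.e0})
    Path(path).write_text(
        _metadata_lines(metadata) + pd.DataFrame(rows).to_csv(index=False)
    )
    Path(schedule_path).write_text(
        _metadata_lines(metadata) + pd.DataFrame(srows).to_csv(index=False)
    )


def write_cohort(cohort, path, metadata: dict | None = None) -> None:
    rows = []
    for i, vp in enumerate(cohort):
        row = {"patient": i, "V0": vp.V0, "dose_budget": vp.dose_budget,
               "V_fatal": vp.V_fatal}
        for name in FITTED_NAMES:
            row[name] = getattr(vp.params, name)
        rows.append(row)
    Path(path).write_text(
        _metadata_lines(metadata) + pd.DataFrame(rows).to_csv(index=False)
    )


def read_cohort(path):
    from .cohort import VirtualPatient

    df = _read_table(
        path, {"patient", "V0", "dose_budget", "V_fatal", *FITTED_NAMES}
    )
    out = []
    for _, row in df.iterrows():
        params = ModelParams(
            **{n: float(row[n]) for n in FITTED_NAMES},
            beta=0.1, lam=DEFAULT_CLEARANCE,
        )
        out.append(
            VirtualPatient(
                params=params, V0=float(row["V0"]),
                dose_budget=int(row["dose_budget"]), V_fatal=float(row["V_fatal"]),
            )
        )
    return out


def write_km_curve(km, path, metadata: dict | None = None) -> None:
    df = pd.DataFrame(
        {"time_days": km.times, "survival": km.survival, "at_risk": km.at_risk}
    )
    Path(path).write_text(_metadata_lines(metadata) + df.to_csv(index=False))


def write_fit_result(result: FitResult, path, metadata: dict | None = None) -> None:
    lines = [_metadata_lines(metadata)]
    for name in FITTED_NAMES:
        lines.append(f"{name} = {getattr(result.params, name)!r}\n")
    lines.append(f"beta = {result.params.beta!r}\n")
    lines.append(f"lam = {result.params.lam!r}\n")
    lines.append(f"rmse_cm3 = {result.rmse!r}\n")
    lines.append(f"rho2_gt_rho1 = {result.rho2_gt_rho1}\n")
    for i, rmse, ok in result.restart_table:
        lines.append(f"restart_{i} = {rmse!r}, converged={ok}\n")
    Path(path).write_text("".join(lines))


def write_trial_summary(result, path, metadata: dict | None = None) -> None:
    lines = [_metadata_lines(metadata)]
    lines.append(f"arm_a = {result.label_a}\n")
    lines.append(f"arm_b = {result.label_b}\n")
    lines.append(f"n_a = {len(result.outcomes_a)}\n")
    lines.append(f"n_b = {len(result.outcomes_b)}\n")
    lines.append(f"median_a_days = {result.median_a!r}\n")
    lines.append(f"median_b_days = {result.median_b!r}\n")
    gain = "unavailable" if result.gain_months is None else repr(result.gain_months)
    lines.append(f"gain_months = {gain}\n")
    lines.append(f"logrank_statistic = {result.logrank_statistic!r}\n")
    lines.append(f"p_value = {result.p_value!r}\n")
    for arm, outs in (("a", result.outcomes_a), ("b", result.outcomes_b)):
        for o in outs:
            lines.append(f"outcome_{arm}_{o.patient_id} = {o.time!r}, event={o.event}\n")
    Path(path).write_text("".join(lines))


# ---------------------------------------------------------------------------
# run configuration


def config_hash(values: dict) -> str:
    """Stable short hash of a configuration mapping (for output headers)."""
    blob = json.dumps(values, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode("utf-8")).hexdigest()[:12]


def read_config(path) -> dict:
    """Parse a flat ``key = value`` configuration file.

    Known keys are the dotted field names of the run's sub-configurations
    (e.g. ``sim.rel_tol``, ``cohort.n_patients``, ``trial.n_per_arm``,
    ``fit.n_restarts``, ``adaptive.threshold_fraction``) plus ``seed`` and
    ``out_dir``.  Unknown keys are errors.
    """
    known_prefixes = ("sim.", "cohort.", "trial.", "fit.", "adaptive.")
    known_bare = {"seed", "out_dir", "verbosity"}
    values: dict = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ParseError(f"{path}: line {lineno}: expected 'key = value'")
        key, _, val = line.partition("=")
        key, val = key.strip(), val.strip()
        if key not in known_bare and not key.startswith(known_prefixes):
            raise ParseError(f"{path}: line {lineno}: unknown key {key!r}")
        try:
            values[key] = json.loads(val)
        except json.JSONDecodeError:
            values[key] = val
    return values
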