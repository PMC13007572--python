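"""File round-trips: spin systems and configs (YAML/JSON), curves and
profiles (CSV with '#'-prefixed header metadata)."""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .analysis import Profile
from .sequences import DecayCurve
from .spin import ExchangeModel, SpinSystem

__all__ = [
    "save_system", "load_system", "save_exchange", "load_exchange",
    "write_curve_csv", "read_curve_csv", "write_profile_csv",
    "read_profile_csv", "load_config", "run_experiment_config",
    "golem_spec_from_config", "residue_summary_table",
]

_SYSTEM_FIELDS = ("offset_H", "offset_N", "J_NH", "R1_H", "R2_H",
                  "R1_N", "R2_N", "sigma_HN", "gamma_ratio")


def save_system(system: SpinSystem, path) -> None:
    doc = {k: float(getattr(system, k)) for k in _SYSTEM_FIELDS}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_system(path) -> SpinSystem:
    doc = yaml.safe_load(Path(path).read_text())
    return SpinSystem(**{k: float(doc[k]) for k in _SYSTEM_FIELDS
                         if k in doc})


def save_exchange(exchange: ExchangeModel, path) -> None:
    doc = {
        "states": [{"offset_N": float(o_n), "offset_H": float(o_h),
                    "population": float(p)}
                   for o_n, o_h, p in exchange.states],
        "rate_matrix": np.asarray(exchange.rate_matrix).tolist(),
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_exchange(path) -> ExchangeModel:
    doc = yaml.safe_load(Path(path).read_text())
    states = [(float(s["offset_N"]), float(s["offset_H"]),
               float(s["population"])) for s in doc["states"]]
    return ExchangeModel(states=states,
                         rate_matrix=np.asarray(doc["rate_matrix"], float))


def _write_csv(path, header: dict, columns: dict) -> None:
    keys = list(columns)
    arrays = [np.asarray(columns[k]) for k in keys]
    with open(path, "w") as fh:
        for k, v in header.items():
            fh.write(f"# {k}: {v}\n")
        fh.write(",".join(keys) + "\n")
        for row in zip(*arrays):
            fh.write(",".join(f"{v:.12g}" for v in row) + "\n")


def _read_csv(path):
    header: dict[str, str] = {}
    rows: list[list[float]] = []
    names: list[str] | None = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if ":" in body:
                    k, v = body.split(":", 1)
                    header[k.strip()] = v.strip()
                continue
            if names is None:
                names = [c.strip() for c in line.split(",")]
                continue
            rows.append([float(c) for c in line.split(",")])
    if names is None or not rows:
        raise ValueError(f"no data rows in {path}")
    data = np.asarray(rows)
    return header, {n: data[:, i] for i, n in enumerate(names)}


def write_curve_csv(curve: DecayCurve, path, **meta) -> None:
    header = dict(meta)
    if curve.noise_sd is not None:
        header["noise_sd"] = repr(float(curve.noise_sd))
    _write_csv(path, header, {"delay_s": curve.delays,
                              "intensity": curve.intensities})


def read_curve_csv(path) -> DecayCurve:
    header, cols = _read_csv(path)
    noise = float(header["noise_sd"]) if "noise_sd" in header else None
    return DecayCurve(cols["delay_s"], cols["intensity"], noise_sd=noise)


def write_profile_csv(profile: Profile, path, **meta) -> None:
    cols = {"offset_hz": profile.offsets, "response": profile.response}
    if profile.residual_z is not None:
        cols["residual_z"] = profile.residual_z
    _write_csv(path, dict(meta), cols)


def read_profile_csv(path) -> Profile:
    _, cols = _read_csv(path)
    prof = Profile(cols["offset_hz"], cols["response"])
    if "residual_z" in cols:
        prof.residual_z = cols["residual_z"]
    return prof


def load_config(path) -> dict:
    """YAML or JSON experiment/config document."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def run_experiment_config(config: dict, system: SpinSystem,
                          shape=None):
    """Run an experiment described by a config document.

    Recognized keys: ``sequence`` (r1 | r1rho | noe), ``timing`` (fields
    of SequenceTiming), ``spin_lock`` ({amplitude, offset}),
    ``shape_file`` (two-column shape table, overrides ``shape``),
    ``transfer`` (haha | rsfpt).  Returns the experiment's result
    (DecayCurve or nOe ratio).
    """
    from .sequences import (SequenceTiming, SpinLockParams,
                            run_noe_experiment, run_r1_experiment,
                            run_r1rho_experiment)
    from .shapes import read_shape

    timing = SequenceTiming(**config.get("timing", {}))
    if config.get("shape_file"):
        shape = read_shape(config["shape_file"])
    transfer = config.get("transfer", "haha")
    sequence = config.get("sequence", "r1")
    if sequence == "r1":
        return run_r1_experiment(system, shape, timing, transfer=transfer)
    if sequence == "r1rho":
        sl = SpinLockParams(**config["spin_lock"])
        return run_r1rho_experiment(system, shape, timing, sl,
                                    transfer=transfer)
    if sequence == "noe":
        return run_noe_experiment(system, shape, timing,
                                  transfer=transfer)
    raise ValueError(f"unknown sequence {sequence!r}")


def golem_spec_from_config(config: dict):
    """Build a pulse-design specification from a YAML/JSON document."""
    from .shapes import GolemSpec
    return GolemSpec(**config)


def residue_summary_table(labels, r1_fits, r2_fits=None, noe=None):
    """Per-residue summary (label, R1, R2, nOe with 95% CIs) as a
    DataFrame ready for CSV export."""
    import pandas as pd

    rows = {"residue": list(labels),
            "R1": [f.rate for f in r1_fits],
            "R1_ci_lo": [f.ci95_rate[0] for f in r1_fits],
            "R1_ci_hi": [f.ci95_rate[1] for f in r1_fits]}
    if r2_fits is not None:
        rows["R2"] = [f.rate for f in r2_fits]
        rows["R2_ci_lo"] = [f.ci95_rate[0] for f in r2_fits]
        rows["R2_ci_hi"] = [f.ci95_rate[1] for f in r2_fits]
    if noe is not None:
        rows["noe"] = list(noe)
    return pd.DataFrame(rows)
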