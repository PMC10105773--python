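"""Plain-text I/O: two-column profile files, transect tables, run
configuration (YAML) and the machine-readable run report (JSON)."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .balance import FluxSet, Uncertain
from .geometry import LakeMorphometry, TemperatureProfile


def read_two_column(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a delimited (whitespace/comma) two-column text file."""
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns")
    return df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float)


def write_two_column(path, col_a, col_b, header: tuple[str, str]) -> None:
    pd.DataFrame({header[0]: col_a, header[1]: col_b}).to_csv(path, index=False)


def read_temperature_profile(path) -> TemperatureProfile:
    z, t = read_two_column(path)
    return TemperatureProfile(depth_m=z, temp_c=t)


def read_transect_table(path) -> pd.DataFrame:
    """Transect stations: columns r_m, C_CH4 (mmol m-3), optional d13C."""
    df = pd.read_csv(path, comment="#")
    required = {"r_m", "C_CH4"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: transect table needs columns {sorted(required)}")
    return df


def fluxset_from_config(block: dict) -> FluxSet:
    """Build a FluxSet from a config mapping mirroring the input-table columns.

    Uncertain quantities accept either a scalar or a [mean, sd] pair.
    """

    def unc(key, default=0.0):
        v = block.get(key, default)
        if isinstance(v, (list, tuple)):
            return Uncertain(float(v[0]), float(v[1]))
        return Uncertain(float(v))

    return FluxSet(
        f_s=unc("F_s"),
        f_a=unc("F_a"),
        f_z=unc("F_z"),
        r_dis=unc("R_dis"),
        c_hyp=float(block.get("C_hyp", 0.0)),
        k_z=float(block.get("K_z", 0.0)),
        kbar_ch4=float(block.get("k_CH4", 1.0)),
        k_h=float(block.get("K_H", 1000.0)),
        dz=float(block.get("dz", 1.0)),
    )


def morphometry_from_config(block: dict) -> LakeMorphometry:
    hyps = None
    if "hypsograph_file" in block:
        z, a = read_two_column(block["hypsograph_file"])
        hyps = (z, a)
    return LakeMorphometry(
        a_surface=float(block["A_a"]),
        a_sediment=float(block["A_s"]),
        a_sml_base=float(block["A_z"]),
        v_sml=float(block["V_SML"]),
        hypsograph=hyps,
        altitude_m=float(block.get("altitude_m", 0.0)),
    )


def load_config(path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    for key in ("lake",):
        if key not in cfg:
            raise ValueError(f"{path}: missing required config block {key!r}")
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_report(path, report: dict) -> None:
    Path(path).write_text(json.dumps(_jsonify(report), indent=2, allow_nan=True))
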