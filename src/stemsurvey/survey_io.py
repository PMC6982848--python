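"""Tree-code codec, file I/O and configuration.

Trees are identified by QR payload strings of the form ``TN0002|YN0001``
(tree ID, plot ID); the codec here works on the payload text — rendering or
scanning the QR image is the scanner hardware's job.  Measurement CSVs,
anchor-survey configs and stem-map outputs (CSV and GeoJSON in the local
plot frame) round-trip losslessly through pandas / stdlib json.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from .errors import CodeParseError, SchemaError
from .geometry import AngleCalibration, DeviceGeometry
from .localization import AnchorSurvey

__all__ = [
    "TreeCode", "parse_code", "format_code", "next_code",
    "read_angle_observations", "read_tag_observations",
    "write_stem_map", "read_stem_map",
    "load_device_config", "load_anchor_survey",
]

_CODE_RE = re.compile(r"^\s*TN(\d+)\s*\|\s*YN(\d+)\s*$")


@dataclass(frozen=True, order=True)
class TreeCode:
    """Tree identifier within a plot: tree number + plot number."""

    tree_num: int
    plot_num: int

    @property
    def tree_id(self) -> str:
        return f"TN{self.tree_num:04d}"

    @property
    def plot_id(self) -> str:
        return f"YN{self.plot_num:04d}"


def parse_code(payload: str) -> TreeCode:
    """Parse a QR payload ``TNxxxx|YNxxxx`` (spaces around '|' tolerated)."""
    m = _CODE_RE.match(payload)
    if not m:
        raise CodeParseError(f"payload {payload!r} does not match 'TN<digits>|YN<digits>'")
    return TreeCode(tree_num=int(m.group(1)), plot_num=int(m.group(2)))


def format_code(code: TreeCode) -> str:
    """Canonical payload string, zero-padded to 4 digits, no spaces."""
    return f"{code.tree_id}|{code.plot_id}"


def next_code(code: TreeCode) -> TreeCode:
    """Auto-generate the next sequential tree code within the same plot."""
    return TreeCode(tree_num=code.tree_num + 1, plot_num=code.plot_num)


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")


def read_angle_observations(path) -> pd.DataFrame:
    """Read caliper observations: tree_code, direction, alpha1_deg, alpha2_deg.

    Tree codes are validated and canonicalised; a duplicated
    (tree_code, direction) pair is a data error reported with row numbers.
    """
    df = pd.read_csv(path)
    _require_columns(df, ["tree_code", "direction", "alpha1_deg", "alpha2_deg"], path)
    df["tree_code"] = [format_code(parse_code(c)) for c in df["tree_code"]]
    dup = df.duplicated(subset=["tree_code", "direction"])
    if dup.any():
        rows = [i + 2 for i in df.index[dup]]  # 1-based incl. header
        raise SchemaError(f"{path}: duplicate (tree_code, direction) at rows {rows}")
    return df


def read_tag_observations(path) -> pd.DataFrame:
    """Read UWB observations: tree_code, obs_index, A_n..D_n, H_n (cm)."""
    df = pd.read_csv(path)
    _require_columns(df, ["tree_code", "obs_index", "A_n", "B_n", "C_n", "D_n", "H_n"], path)
    df["tree_code"] = [format_code(parse_code(c)) for c in df["tree_code"]]
    dup = df.duplicated(subset=["tree_code", "obs_index"])
    if dup.any():
        rows = [i + 2 for i in df.index[dup]]
        raise SchemaError(f"{path}: duplicate (tree_code, obs_index) at rows {rows}")
    return df


def write_stem_map(records: pd.DataFrame, path, fmt: str = "csv") -> None:
    """Write a stem map (tree_code, x_cm, y_cm, dbh_mm) as CSV or GeoJSON.

    GeoJSON coordinates are metres in the local plot frame (not geographic);
    a top-level ``crs_note`` property says so.
    """
    cols = ["tree_code", "x_cm", "y_cm", "dbh_mm"]
    _require_columns(records, cols, "<records>")
    path = Path(path)
    if fmt == "csv":
        records[cols].to_csv(path, index=False)
    elif fmt == "geojson":
        features = [
            {
                "type": "Feature",
                "geometry": {"type": "Point",
                             "coordinates": [round(r.x_cm / 100.0, 6), round(r.y_cm / 100.0, 6)]},
                "properties": {"tree_code": r.tree_code, "dbh_mm": r.dbh_mm},
            }
            for r in records[cols].itertuples()
        ]
        doc = {
            "type": "FeatureCollection",
            "crs_note": "local plot frame OXY, metres; origin at anchor A, x-axis toward anchor B",
            "features": features,
        }
        path.write_text(json.dumps(doc, indent=2))
    else:
        raise ValueError(f"unknown stem-map format {fmt!r}")


def read_stem_map(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["tree_code", "x_cm", "y_cm", "dbh_mm"], path)
    return df


def load_device_config(path) -> tuple[DeviceGeometry, AngleCalibration | None]:
    """Load device geometry (s_cm, w_cm, h_cm) and optional ADC calibration.

    YAML keys: s_cm, w_cm, h_cm and, if raw counts are used, U_n, V_z1,
    V_z2, V_r.
    """
    cfg = yaml.safe_load(Path(path).read_text())
    try:
        geom = DeviceGeometry(s=float(cfg["s_cm"]), w=float(cfg["w_cm"]), h=float(cfg["h_cm"]))
    except KeyError as e:
        raise SchemaError(f"{path}: missing device constant {e}") from e
    cal = None
    if all(k in cfg for k in ("U_n", "V_z1", "V_z2", "V_r")):
        cal = AngleCalibration(U_n=float(cfg["U_n"]), V_z1=float(cfg["V_z1"]),
                               V_z2=float(cfg["V_z2"]), V_r=float(cfg["V_r"]))
    return geom, cal


def load_anchor_survey(path) -> AnchorSurvey:
    """Load an anchor survey from YAML (H_A..H_D, Dis_AB..Dis_CD, cm)."""
    cfg = yaml.safe_load(Path(path).read_text())
    keys = ["H_A", "H_B", "H_C", "H_D",
            "Dis_AB", "Dis_AC", "Dis_AD", "Dis_BC", "Dis_BD", "Dis_CD"]
    missing = [k for k in keys if k not in cfg]
    if missing:
        raise SchemaError(f"{path}: missing survey keys {missing}")
    return AnchorSurvey(**{k: float(cfg[k]) for k in keys})


def write_anchor_survey(survey: AnchorSurvey, path) -> None:
    data = {k: float(getattr(survey, k)) for k in
            ("H_A", "H_B", "H_C", "H_D",
             "Dis_AB", "Dis_AC", "Dis_AD", "Dis_BC", "Dis_BD", "Dis_CD")}
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
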