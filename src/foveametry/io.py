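"""CSV/JSON readers and writers plus the packaged reference table.

CSV dialect everywhere: comma-separated, '.' decimal, UTF-8, LF endings,
mandatory header.

Profiles CSV   : subject_id, group, layer, eccentricity_um, thickness_um
A-scan CSV     : depth_um, reflectivity
Ground truth   : group, layer, eccentricity_um, true_retardation_um
Retardation    : group, layer, eccentricity_um, retardation_um, residual_um
Normal curve   : eccentricity_um, displacement_um
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .errors import FixtureIntegrityError, SchemaError
from .types import (
    Group,
    Layer,
    LayerProfile,
    NormalDisplacementCurve,
    ReflectivityProfile,
    RetardationEstimate,
)

__all__ = [
    "read_profiles",
    "write_profiles",
    "read_ascan",
    "write_ascan",
    "read_normal_curve",
    "write_retardation",
    "read_retardation",
    "Table1Fixture",
    "load_table1_fixture",
    "read_config",
]

PathLike = Union[str, Path]

_PROFILE_COLS = ["subject_id", "group", "layer", "eccentricity_um", "thickness_um"]

_FIXTURE_SHA256 = {
    "table1_cells.csv": "a7013fd26b27cb74f6c3cfb3ef78426453db454505e8afb2f674517fef17aa0a",
    "table1_fc.csv": "b5a890dd4382bbda1ad256489ee3d082c85a8cc4940cddb48e7ecd038379e0d9",
}


def _read_csv(path: PathLike, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"input file not found: {path}")
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty file") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    return df


def _require_numeric(df: pd.DataFrame, path: PathLike, cols: Sequence[str]) -> pd.DataFrame:
    for c in cols:
        num = pd.to_numeric(df[c], errors="coerce")
        if num.isna().any():
            # +2: header line plus 1-based indexing
            lines = [int(i) + 2 for i in df.index[num.isna()]]
            raise SchemaError(f"{path}: non-numeric value in column {c!r} at line(s) {lines}")
        df[c] = num
    return df


def read_profiles(path: PathLike) -> list[LayerProfile]:
    """Read layer-thickness profiles, validating and normalising row order.

    Rows are grouped by (subject_id, group, layer); rows out of eccentricity
    order are sorted with a warning; duplicated or non-increasing
    eccentricities after sorting raise a schema error with line context.
    """
    df = _read_csv(path, _PROFILE_COLS)
    if df.empty:
        raise SchemaError(f"{path}: no data rows")
    df = _require_numeric(df, path, ["eccentricity_um", "thickness_um"])
    out: list[LayerProfile] = []
    for (sid, grp, lay), sub in df.groupby(["subject_id", "group", "layer"], sort=True):
        e = sub["eccentricity_um"].to_numpy()
        if np.any(np.diff(e) < 0):
            warnings.warn(
                f"{path}: rows for ({sid}, {grp}, {lay}) were out of "
                "eccentricity order; sorting",
                stacklevel=2,
            )
            sub = sub.sort_values("eccentricity_um")
        try:
            out.append(
                LayerProfile(
                    layer=Layer(lay), group=Group(grp), subject_id=str(sid),
                    eccentricity_um=sub["eccentricity_um"].to_numpy(),
                    thickness_um=sub["thickness_um"].to_numpy(),
                )
            )
        except (SchemaError, ValueError) as exc:
            first_line = int(sub.index[0]) + 2
            raise SchemaError(
                f"{path}: invalid profile ({sid}, {grp}, {lay}) starting at "
                f"line {first_line}: {exc}"
            ) from exc
    return out


def write_profiles(path: PathLike, profiles: Sequence[LayerProfile]) -> None:
    rows = []
    for p in profiles:
        for e, t in zip(p.eccentricity_um, p.thickness_um):
            rows.append((p.subject_id, p.group.value, p.layer.value, e, t))
    pd.DataFrame(rows, columns=_PROFILE_COLS).to_csv(path, index=False, lineterminator="\n", float_format="%.17g")


def read_ascan(path: PathLike) -> ReflectivityProfile:
    df = _read_csv(path, ["depth_um", "reflectivity"])
    df = _require_numeric(df, path, ["depth_um", "reflectivity"])
    try:
        return ReflectivityProfile(
            depth_um=df["depth_um"].to_numpy(),
            reflectivity=df["reflectivity"].to_numpy(),
        )
    except SchemaError as exc:
        raise SchemaError(f"{path}: {exc}") from exc


def write_ascan(path: PathLike, profile: ReflectivityProfile) -> None:
    pd.DataFrame(
        {"depth_um": profile.depth_um, "reflectivity": profile.reflectivity}
    ).to_csv(path, index=False, lineterminator="\n", float_format="%.17g")


def read_normal_curve(path: PathLike) -> NormalDisplacementCurve:
    """Read a user-supplied normative displacement curve (e.g. digitised
    from published histology); provenance is recorded as the file name."""
    df = _read_csv(path, ["eccentricity_um", "displacement_um"])
    df = _require_numeric(df, path, ["eccentricity_um", "displacement_um"])
    return NormalDisplacementCurve(
        eccentricity_um=df["eccentricity_um"].to_numpy(),
        displacement_um=df["displacement_um"].to_numpy(),
        provenance=str(path),
    )


def write_retardation(path: PathLike, estimates: Sequence[RetardationEstimate]) -> None:
    rows = [
        (e.group.value, e.layer.value, e.eccentricity_um, e.retardation_um,
         e.residual_um, e.error or "")
        for e in estimates
    ]
    pd.DataFrame(
        rows,
        columns=["group", "layer", "eccentricity_um", "retardation_um",
                 "residual_um", "error"],
    ).to_csv(path, index=False, lineterminator="\n", float_format="%.17g")


def read_retardation(path: PathLike) -> pd.DataFrame:
    df = _read_csv(path, ["group", "layer", "eccentricity_um", "retardation_um"])
    return _require_numeric(df, path, ["eccentricity_um", "retardation_um"])


@dataclass(frozen=True)
class Table1Fixture:
    """Packaged per-cell reference table of the published analysis.

    ``cells``: 36 rows (3 groups x 3 layers x 4 eccentricities) with
    retardation (µm), PG/C thickness ratio, and the *printed* area and
    volume ratios (comparison targets, never computation inputs).
    ``fc``: foveal-centre block (RT, FD, IRLt, FDA group means).
    """

    cells: pd.DataFrame
    fc: pd.DataFrame

    def retardation_um(self, group: str, layer: str, eccentricity_um: float) -> float:
        return float(self._cell(group, layer, eccentricity_um)["retardation_um"])

    def thickness_ratio(self, group: str, layer: str, eccentricity_um: float) -> float:
        return float(self._cell(group, layer, eccentricity_um)["thickness_ratio"])

    def _cell(self, group: str, layer: str, eccentricity_um: float) -> pd.Series:
        m = self.cells[
            (self.cells.group == str(group))
            & (self.cells.layer == str(layer))
            & (self.cells.eccentricity_um == float(eccentricity_um))
        ]
        if len(m) != 1:
            raise SchemaError(
                f"no unique fixture cell ({group}, {layer}, {eccentricity_um})"
            )
        return m.iloc[0]


def load_table1_fixture() -> Table1Fixture:
    """Load the packaged reference cells, verifying their checksums."""
    pkg = resources.files("foveametry") / "data"
    frames = {}
    for name, want in _FIXTURE_SHA256.items():
        raw = (pkg / name).read_bytes()
        got = hashlib.sha256(raw).hexdigest()
        if got != want:
            raise FixtureIntegrityError(
                f"packaged fixture {name} corrupted (sha256 {got[:12]}... != "
                f"{want[:12]}...)"
            )
        from io import BytesIO

        frames[name] = pd.read_csv(BytesIO(raw))
    cells = frames["table1_cells.csv"]
    if len(cells) != 36:
        raise FixtureIntegrityError("fixture must hold exactly 36 cells")
    return Table1Fixture(cells=cells, fc=frames["table1_fc.csv"])


def read_config(path: PathLike) -> dict:
    """Read a YAML or JSON configuration file into a plain dict."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml

        cfg = yaml.safe_load(text)
    else:
        cfg = json.loads(text)
    if not isinstance(cfg, dict):
        raise SchemaError(f"{path}: configuration must be a mapping")
    return cfg
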