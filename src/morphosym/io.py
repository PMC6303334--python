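"""Readers and writers: TPS landmark files, long-format CSV, effect tables,
symmetry-scheme files.

The TPS dialect follows the digitising tools of the field: an ``LM=k``
header, k whitespace-separated coordinate lines, then optional ``ID=``,
``IMAGE=`` and ``SCALE=`` keys (SCALE multiplies the coordinates).  Index
metadata (individual, part, replicate) is carried in the ID string using a
documented pattern, ``<individual>_<part>_<replicate>`` by default.
Landmark indices are 1-based everywhere.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .anova import EFFECT_TABLE_COLUMNS, ShapeDataset
from .geometry import LandmarkConfiguration
from .symmetry import SymmetryScheme

__all__ = [
    "read_tps",
    "write_tps",
    "read_long_csv",
    "write_long_csv",
    "write_effect_table",
    "read_effect_table",
    "read_scheme",
    "write_scheme",
]


class TPSParseError(ValueError):
    def __init__(self, msg: str, line: int):
        super().__init__(f"line {line}: {msg}")
        self.line = line


def read_tps(path) -> list[tuple[LandmarkConfiguration, dict]]:
    """Parse a TPS file into ``(configuration, metadata)`` pairs.

    Metadata holds the raw ``ID``/``IMAGE``/``SCALE`` keys; SCALE is applied
    to the coordinates.  Malformed records raise with the offending line
    number.
    """
    out = []
    coords, meta, expect = None, {}, 0
    with open(path) as fh:
        lines = fh.readlines()

    def flush(lineno):
        nonlocal coords, meta, expect
        if coords is None:
            return
        if len(coords) != expect:
            raise TPSParseError(
                f"LM={expect} but record has {len(coords)} coordinate lines", lineno
            )
        arr = np.asarray(coords, float)
        scale = meta.get("SCALE")
        if scale is not None:
            arr = arr * float(scale)
        out.append((LandmarkConfiguration(arr), dict(meta)))
        coords, meta, expect = None, {}, 0

    for n, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        upper = line.upper()
        if upper.startswith("LM="):
            flush(n)
            try:
                expect = int(line.split("=", 1)[1])
            except ValueError:
                raise TPSParseError(f"bad LM header {line!r}", n) from None
            coords = []
        elif "=" in line and not _is_coordinate(line):
            key, val = line.split("=", 1)
            meta[key.strip().upper()] = val.strip()
        else:
            if coords is None:
                raise TPSParseError("coordinate line before any LM= header", n)
            parts = line.split()
            try:
                coords.append([float(p) for p in parts])
            except ValueError:
                raise TPSParseError(f"malformed coordinate line {line!r}", n) from None
            if len(parts) not in (2, 3):
                raise TPSParseError(f"expected 2 or 3 coordinates, got {len(parts)}", n)
    flush(len(lines) + 1)
    return out


def _is_coordinate(line: str) -> bool:
    head = line.split("=", 1)[0].strip()
    try:
        float(head)
        return True
    except ValueError:
        return False


def write_tps(path, configs, ids=None, decimals: int = 6) -> None:
    """Write configurations as a TPS file (``decimals`` digits, default 6)."""
    with open(path, "w") as fh:
        for n, cfg in enumerate(configs):
            coords = cfg.coords if isinstance(cfg, LandmarkConfiguration) else np.asarray(cfg)
            fh.write(f"LM={coords.shape[0]}\n")
            for row in coords:
                fh.write(" ".join(f"{v:.{decimals}f}" for v in row) + "\n")
            if ids is not None:
                fh.write(f"ID={ids[n]}\n")


def dataset_to_tps(path, dataset: ShapeDataset, decimals: int = 6) -> None:
    ids = [
        f"{i}_{j}_{r}"
        for i, j, r in zip(dataset.individual, dataset.part, dataset.replicate)
    ]
    write_tps(path, dataset.configs, ids=ids, decimals=decimals)


def read_long_csv(path, scheme: SymmetryScheme) -> ShapeDataset:
    """Read long-format landmark data: columns
    individual, part, replicate, landmark, x, y."""
    df = pd.read_csv(path)
    need = {"individual", "part", "replicate", "landmark", "x", "y"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"long CSV missing columns: {sorted(missing)}")
    configs, ind, part, rep = [], [], [], []
    for (i, j, r), grp in df.groupby(["individual", "part", "replicate"], sort=True):
        grp = grp.sort_values("landmark")
        configs.append(LandmarkConfiguration(grp[["x", "y"]].to_numpy()))
        ind.append(int(i))
        part.append(int(j))
        rep.append(int(r))
    return ShapeDataset(configs, ind, part, rep, scheme)


def write_long_csv(path, dataset: ShapeDataset) -> None:
    rows = []
    for cfg, i, j, r in zip(
        dataset.configs, dataset.individual, dataset.part, dataset.replicate
    ):
        for l, (x, y) in enumerate(cfg.coords, start=1):
            rows.append(
                {"individual": i, "part": j, "replicate": r, "landmark": l, "x": x, "y": y}
            )
    pd.DataFrame(rows).to_csv(path, index=False)


_DISPLAY_COLUMNS = {
    "effect": "Effect",
    "conv_df": "Conv. df",
    "shape_df": "Shape df",
    "SS": "SS",
    "MS": "MS",
    "F": "F",
    "P_param": "P (param)",
    "P_perm": "P (permut)",
    "pillai": "Pillai",
    "pillai_P_param": "Pillai P (param)",
    "pillai_P_perm": "Pillai P (permut)",
}


def write_effect_table(table: pd.DataFrame, path) -> None:
    """Serialise an effect table as CSV in the canonical column order,
    numbers at 6 significant digits; deterministic output."""
    out = table[EFFECT_TABLE_COLUMNS].rename(columns=_DISPLAY_COLUMNS).copy()
    for col in out.columns:
        if out[col].dtype.kind == "f":
            out[col] = out[col].map(lambda v: "" if pd.isna(v) else f"{v:.6g}")
    out.to_csv(path, index=False)


def read_effect_table(path) -> pd.DataFrame:
    inv = {v: k for k, v in _DISPLAY_COLUMNS.items()}
    df = pd.read_csv(path).rename(columns=inv)
    for c in df.columns:
        if c not in ("effect", "conv_df", "shape_df"):
            df[c] = pd.to_numeric(df[c], errors="coerce")
    return df[EFFECT_TABLE_COLUMNS]


def write_scheme(path, scheme: SymmetryScheme) -> None:
    """Plain-JSON symmetry-scheme file: mode, n_landmarks, pairing (1-based
    index pairs swapped by the reflection), unpaired (on-axis indices),
    n_parts."""
    doc = {
        "mode": scheme.mode,
        "n_landmarks": scheme.n_landmarks,
        "pairing": [list(p) for p in scheme.pairing],
        "unpaired": list(scheme.unpaired),
        "n_parts": scheme.n_parts,
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def read_scheme(path) -> SymmetryScheme:
    doc = json.loads(Path(path).read_text())
    return SymmetryScheme(
        mode=doc["mode"],
        n_landmarks=int(doc["n_landmarks"]),
        pairing=tuple(tuple(p) for p in doc.get("pairing", ())),
        unpaired=tuple(doc.get("unpaired", ())),
        n_parts=int(doc.get("n_parts", 1)),
    )
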