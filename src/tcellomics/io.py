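"""Standard-format readers and writers.

All tabular formats are plain TSV with ``NA`` as the missing-value sentinel
(empty cells are also accepted on read and written back as ``NA``).  Gene sets
use the GMT convention (name, description, members...), interactomes a
three-column edge list (nodeA, nodeB, direction in {AB, BA, both, none}).

Every reader validates its input and raises :class:`FormatError` carrying the
offending line number, so malformed files fail loudly instead of propagating
NaNs downstream.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

NA_SENTINEL = "NA"

VALID_DIRECTIONS = {"AB", "BA", "both", "none"}


class FormatError(ValueError):
    """A file failed validation; the message carries file and line context."""


# ---------------------------------------------------------------------------
# intensity matrices (samples x features)
# ---------------------------------------------------------------------------

def read_intensity_matrix(path: str | Path) -> pd.DataFrame:
    """Read a samples x features intensity TSV.

    First column holds sample IDs, header holds feature IDs.  Missing values
    are ``NA`` or empty.  Non-missing values must be positive numbers.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA_SENTINEL, ""],
                     keep_default_na=False)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate sample IDs {dup}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate feature IDs {dup}")
    for col in df.columns:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()
                          & df[col].notna()]
            line = df.index.get_loc(bad.index[0]) + 2 if len(bad) else "?"
            raise FormatError(
                f"{path}: non-numeric cell in column {col!r} (line {line})"
            ) from exc
    vals = df.to_numpy(float)
    if np.any(vals[~np.isnan(vals)] <= 0):
        raise FormatError(f"{path}: intensities must be positive")
    return df


def write_intensity_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", na_rep=NA_SENTINEL, index_label="sample")


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a generic TSV table (first column = index) allowing any values."""
    return pd.read_csv(Path(path), sep="\t", index_col=0,
                       na_values=[NA_SENTINEL, ""], keep_default_na=False)


# ---------------------------------------------------------------------------
# sample design
# ---------------------------------------------------------------------------

DESIGN_FACTORS = ("CELL", "TREATMENT", "TIME")


def read_design(path: str | Path) -> pd.DataFrame:
    """Read the sample design table: sample ID index, CELL/TREATMENT/TIME.

    A ``group`` column (CELL x TREATMENT) is derived if absent.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                     na_values=[NA_SENTINEL, ""], keep_default_na=False)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        first = df.index.get_loc(dup[0])
        line = (first.start if isinstance(first, slice) else
                np.flatnonzero(first)[0] if isinstance(first, np.ndarray) else first)
        raise FormatError(f"{path}: duplicate sample ID {dup[0]!r} (line {line + 2})")
    missing = [f for f in DESIGN_FACTORS if f not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing design columns {missing}")
    if "group" not in df.columns:
        df["group"] = df["CELL"] + "/" + df["TREATMENT"]
    # covariate columns (e.g. protein_content) come back numeric
    for col in df.columns:
        if col in DESIGN_FACTORS or col == "group":
            continue
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError):
            pass
    return df


def write_design(design: pd.DataFrame, path: str | Path) -> None:
    design.to_csv(path, sep="\t", na_rep=NA_SENTINEL, index_label="sample")


def check_design_matches(matrix: pd.DataFrame, design: pd.DataFrame) -> None:
    """Every sample in the matrix must have exactly one design row."""
    missing = [s for s in matrix.index if s not in design.index]
    if missing:
        raise FormatError(f"samples without design rows: {missing}")


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT file: name <TAB> description <TAB> member...

    Returns ``{name: [members...]}``; descriptions are dropped.
    """
    path = Path(path)
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: GMT rows need name, description "
                    f"and at least one member")
            name = parts[0]
            if name in sets:
                raise FormatError(f"{path}: line {lineno}: duplicate set {name!r}")
            members = [m for m in parts[2:] if m]
            sets[name] = members
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path,
              descriptions: dict[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# edge lists
# ---------------------------------------------------------------------------

def read_edge_list(path: str | Path) -> pd.DataFrame:
    """Read a nodeA/nodeB/direction edge-list TSV.

    The direction column is optional; absent means ``none``.  A header row
    beginning with ``nodeA`` is accepted and skipped.
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[0].lower() in {"nodea", "source", "node_a"}:
                continue
            if len(parts) < 2:
                raise FormatError(f"{path}: line {lineno}: need at least 2 columns")
            direction = parts[2] if len(parts) > 2 and parts[2] else "none"
            if direction not in VALID_DIRECTIONS:
                raise FormatError(
                    f"{path}: line {lineno}: bad direction {direction!r} "
                    f"(allowed: {sorted(VALID_DIRECTIONS)})")
            rows.append((parts[0], parts[1], direction))
    return pd.DataFrame(rows, columns=["nodeA", "nodeB", "direction"])


def write_edge_list(edges: pd.DataFrame, path: str | Path) -> None:
    edges.to_csv(path, sep="\t", index=False)


def read_id_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV mapping old IDs to normalized IDs."""
    path = Path(path)
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}: line {lineno}: need 2 columns")
            mapping[parts[0]] = parts[1]
    return mapping


# ---------------------------------------------------------------------------
# config
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config must be a YAML mapping")
    return cfg


def save_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def config_hash(cfg: dict) -> str:
    """Stable short hash of a config mapping, for output provenance headers."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_json_report(obj: dict, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (set, frozenset)):
        return sorted(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
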