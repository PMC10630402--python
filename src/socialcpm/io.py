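"""Tabular readers/writers, schema validation and run records.

All interchange formats are plain delimited text: edge matrices as CSV with
``n{i}_n{j}`` headers (1-based node ids, row-major upper-triangle order),
behavior/confound tables as CSV with a ``subject`` column, atlas metadata
as TSV, item responses as CSV with blank cells for missing.  Every
pipeline run writes a JSON record of its resolved parameters and seed, and
a manifest of output hashes, so numeric outputs are reproducible from the
record alone.
"""

from __future__ import annotations

import hashlib
import json
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .connectome import ATLAS_COLUMNS, EdgeIndexMap, validate_atlas

#: float formatting used for all numeric CSV output; 17 significant digits
#: round-trips IEEE doubles exactly.
FLOAT_FORMAT = "%.17g"

_EDGE_RE = re.compile(r"^n(\d+)_n(\d+)$")


class SchemaError(ValueError):
    """A table does not match its declared schema."""


def read_table(
    path: str | Path,
    schema: dict[str, str],
    *,
    sep: str = ",",
    allow_extra: bool = True,
) -> pd.DataFrame:
    """Read a delimited table and coerce columns to a schema.

    ``schema`` maps column name -> semantic type, one of ``"str"``,
    ``"int"``, ``"float"``.  Missing required columns and non-numeric
    cells in numeric columns raise :class:`SchemaError` naming the
    offender.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required columns {missing}")
    if not allow_extra:
        extra = [c for c in df.columns if c not in schema]
        if extra:
            raise SchemaError(f"{path.name}: unknown columns {extra}")
    for col, kind in schema.items():
        if kind == "str":
            df[col] = df[col].astype(str)
        elif kind in ("int", "float"):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                row = int(np.flatnonzero(bad)[0])
                raise SchemaError(
                    f"{path.name}: non-numeric value {df[col].iloc[row]!r} "
                    f"in column {col!r}, row {row}"
                )
            df[col] = coerced.astype(float if kind == "float" else "Int64")
        else:
            raise ValueError(f"unknown schema kind {kind!r} for column {col!r}")
    return df


def write_table(df: pd.DataFrame, path: str | Path, *, sep: str = ",", index: bool = False) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=sep, index=index, float_format=FLOAT_FORMAT)
    return path


# ---------------------------------------------------------------------------
# domain-specific formats


def write_edge_matrix(edges: np.ndarray, subjects: list[str], index_map: EdgeIndexMap, path) -> Path:
    df = pd.DataFrame(edges, columns=index_map.edge_labels())
    df.insert(0, "subject", subjects)
    return write_table(df, path)


def read_edge_matrix(path) -> tuple[np.ndarray, list[str], EdgeIndexMap]:
    """Read a subjects x edges CSV; infers and checks the edge-index map
    from the ``n{i}_n{j}`` headers."""
    df = pd.read_csv(path, float_precision="round_trip")
    if "subject" not in df.columns:
        raise SchemaError(f"{Path(path).name}: missing required columns ['subject']")
    subjects = df["subject"].astype(str).tolist()
    edge_cols = [c for c in df.columns if c != "subject"]
    pairs = []
    for c in edge_cols:
        m = _EDGE_RE.match(c)
        if not m:
            raise SchemaError(f"{Path(path).name}: malformed edge column {c!r}")
        pairs.append((int(m.group(1)), int(m.group(2))))
    n_nodes = max(max(p) for p in pairs)
    index_map = EdgeIndexMap(n_nodes)
    expected = index_map.edge_labels()
    if edge_cols != expected:
        raise SchemaError(
            f"{Path(path).name}: edge columns are not in row-major upper-triangle "
            f"order for {n_nodes} nodes"
        )
    return df[edge_cols].to_numpy(dtype=float), subjects, index_map


def write_atlas(atlas: pd.DataFrame, path) -> Path:
    validate_atlas(atlas)
    return write_table(atlas, path, sep="\t")


def read_atlas(path) -> pd.DataFrame:
    schema = {c: "str" for c in ATLAS_COLUMNS}
    schema.update(node_id="int", mni_x="float", mni_y="float", mni_z="float")
    atlas = read_table(path, schema, sep="\t")
    atlas["node_id"] = atlas["node_id"].astype(int)
    return validate_atlas(atlas)


def write_items(responses: pd.DataFrame, path) -> Path:
    """Item responses as CSV, blank cells for missing."""
    return write_table(responses.reset_index(), path)


def read_items(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    id_col = df.columns[0]
    return df.set_index(id_col)


# ---------------------------------------------------------------------------
# run records


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_run_record(out_dir: str | Path, stage: str, config: dict, seed: int) -> Path:
    """Machine-readable record of a stage's resolved parameters."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    record = {
        "stage": stage,
        "seed": seed,
        "config": config,
        "config_hash": config_hash({"stage": stage, "seed": seed, **config}),
    }
    path = out_dir / f"{stage}_record.json"
    path.write_text(json.dumps(record, indent=2, sort_keys=True, default=str))
    return path


def write_manifest(out_dir: str | Path, files: list[Path], config: dict, seed: int) -> Path:
    out_dir = Path(out_dir)
    manifest = {
        "seed": seed,
        "config_hash": config_hash(config),
        "files": {
            str(Path(f).relative_to(out_dir)): file_sha256(f) for f in sorted(files)
        },
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path
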