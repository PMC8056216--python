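"""File formats: TSV abundance matrices, clinical CSV, GMT gene sets,
YAML configs, and JSON sidecars.

Matrix dialect: tab-separated, header row of sample ids, first column
feature ids. Empty cells are missing (undetected); parsing is strict and
reports the offending line on error.
"""

from __future__ import annotations

import csv
import hashlib
import json
import math
from pathlib import Path
from typing import Dict, List, Optional, Union

import numpy as np
import pandas as pd
import yaml

from .differential import IndicatorDefinition
from .preprocess import NormalizedMatrix, OmicsMatrix
from .survival import CLINICAL_COLUMNS, ClinicalTable

PathLike = Union[str, Path]


class ParseError(ValueError):
    pass


def _parse_matrix_tsv(path: Path):
    """Strict TSV parse -> (feature_ids, sample_ids, values array)."""
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file") from None
        if len(header) < 2:
            raise ParseError(f"{path}: header needs feature column + samples")
        sample_ids = header[1:]
        if len(set(sample_ids)) != len(sample_ids):
            dup = next(s for s in sample_ids if sample_ids.count(s) > 1)
            raise ParseError(f"{path}: duplicate sample id {dup!r}")
        feature_ids: List[str] = []
        rows: List[List[float]] = []
        seen = set()
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(header)} fields, "
                    f"got {len(row)}"
                )
            fid = row[0]
            if fid in seen:
                raise ParseError(
                    f"{path}:{lineno}: duplicate feature id {fid!r}"
                )
            seen.add(fid)
            vals = []
            for col, cell in enumerate(row[1:], start=2):
                cell = cell.strip()
                if cell == "" or cell.upper() in ("NA", "NAN"):
                    vals.append(float("nan"))
                    continue
                try:
                    vals.append(float(cell))
                except ValueError:
                    raise ParseError(
                        f"{path}:{lineno}: non-numeric cell {cell!r} "
                        f"in column {col}"
                    ) from None
            feature_ids.append(fid)
            rows.append(vals)
    if not rows:
        raise ParseError(f"{path}: no data rows")
    return feature_ids, sample_ids, np.array(rows, dtype=float)


def read_matrix(path: PathLike, layer: str = "rna") -> OmicsMatrix:
    """Read the TSV matrix dialect into an :class:`OmicsMatrix`."""
    feature_ids, sample_ids, values = _parse_matrix_tsv(Path(path))
    return OmicsMatrix(
        feature_ids=feature_ids,
        sample_ids=sample_ids,
        values=values,
        layer=layer,
    )


def write_matrix(
    matrix: Union[OmicsMatrix, NormalizedMatrix],
    path: PathLike,
    feature_column: str = "feature_id",
) -> None:
    path = Path(path)
    vals = matrix.values
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow([feature_column, *matrix.sample_ids])
        for i, fid in enumerate(matrix.feature_ids):
            writer.writerow(
                [fid]
                + [
                    "" if math.isnan(v) else repr(float(v))
                    for v in vals[i]
                ]
            )


def read_normalized(path: PathLike) -> NormalizedMatrix:
    """Read a normalized matrix (provenance restored from a JSON sidecar
    next to the TSV when present)."""
    path = Path(path)
    feature_ids, sample_ids, values = _parse_matrix_tsv(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    provenance = {}
    if sidecar.exists():
        provenance = json.loads(sidecar.read_text())
    return NormalizedMatrix(
        feature_ids=feature_ids,
        sample_ids=sample_ids,
        values=values,
        provenance=provenance,
    )


def write_normalized(matrix: NormalizedMatrix, path: PathLike) -> None:
    write_matrix(matrix, path)
    sidecar = Path(path).with_suffix(Path(path).suffix + ".json")
    sidecar.write_text(json.dumps(matrix.provenance, indent=2, default=str))


def read_clinical(path: PathLike) -> ClinicalTable:
    df = pd.read_csv(path)
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing clinical columns {missing}")
    return ClinicalTable(df)


def write_clinical(table: ClinicalTable, path: PathLike) -> None:
    table.data.to_csv(path, index=False)


def read_gmt(path: PathLike) -> Dict[str, Dict[str, object]]:
    """Read a GMT file: name <tab> description <tab> member genes."""
    out: Dict[str, Dict[str, object]] = {}
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line needs name, description, "
                    "and at least one member"
                )
            name, desc, members = parts[0], parts[1], parts[2:]
            if name in out:
                raise ParseError(f"{path}:{lineno}: duplicate set {name!r}")
            out[name] = {
                "description": desc,
                "members": {m for m in members if m},
            }
    if not out:
        raise ParseError(f"{path}: no gene sets")
    return out


def read_indicator_definitions(path: PathLike) -> List[IndicatorDefinition]:
    """Indicator definitions from YAML: list of {name, numerator,
    denominator} entries."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, list):
        raise ParseError(f"{path}: expected a YAML list of indicators")
    defs = []
    for entry in raw:
        defs.append(
            IndicatorDefinition(
                name=str(entry["name"]),
                numerator=[str(x) for x in entry["numerator"]],
                denominator=[str(x) for x in entry["denominator"]],
            )
        )
    return defs


def read_labels(path: PathLike) -> Dict[str, int]:
    """Sample labels CSV with columns sample_id, label."""
    df = pd.read_csv(path)
    for col in ("sample_id", "label"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    return dict(zip(df["sample_id"].astype(str), df["label"].astype(int)))


def write_labels(labels: Dict[str, int], path: PathLike) -> None:
    pd.DataFrame(
        {"sample_id": list(labels), "label": list(labels.values())}
    ).to_csv(path, index=False)


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_json(obj: object, path: PathLike) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=str))


def file_checksum(path: PathLike) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def write_cohort(cohort, out_dir: PathLike) -> Dict[str, str]:
    """Write a synthetic cohort's layers (TSV), clinical table (CSV), and
    planted truth (JSON). Returns the file map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {}
    for name, matrix in cohort.layers.items():
        p = out / f"{name}.tsv"
        write_matrix(matrix, p)
        files[name] = str(p)
    p = out / "clinical.csv"
    write_clinical(cohort.clinical, p)
    files["clinical"] = str(p)
    p = out / "truth.json"
    write_json(cohort.truth, p)
    files["truth"] = str(p)
    return files
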