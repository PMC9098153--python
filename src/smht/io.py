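"""File I/O: response CSVs, corpora, reports with checksummed manifests.

CSV dialect throughout: comma-separated, UTF-8, mandatory header row, '.'
decimal.  Response files have columns ``item_1..item_p``, one respondent per
row, integer entries 1-5.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import LabeledCorpus, ResponseMatrix, ValidationError


class ParseError(ValidationError):
    """Raised on malformed input files, with cell coordinates where possible."""


def read_response_csv(path) -> ResponseMatrix:
    """Read and validate a Likert response CSV.

    Rejects non-integer or out-of-range cells citing 1-based (row, column)
    data coordinates; header-only or empty files are errors.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty file") from exc
    if df.shape[0] == 0:
        raise ParseError(f"{path}: no data rows below the header")
    values = np.empty(df.shape, dtype=np.int64)
    for j, col in enumerate(df.columns):
        numeric = pd.to_numeric(df[col], errors="coerce")
        for i, v in enumerate(numeric):
            if pd.isna(v) or float(v) != int(v) or not 1 <= int(v) <= 5:
                raise ParseError(
                    f"{path}: invalid cell {df.iloc[i, j]!r} at row {i + 1}, "
                    f"column {j + 1} (expected integer 1-5)"
                )
            values[i, j] = int(v)
    return ResponseMatrix(values, item_names=list(df.columns))


def write_response_csv(matrix: ResponseMatrix, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    matrix.to_frame().to_csv(path, index=False)
    return path


def write_corpus(corpus: LabeledCorpus, doc_path, label_path) -> tuple[Path, Path]:
    """One whitespace-joined document per line plus a parallel label file."""
    doc_path, label_path = Path(doc_path), Path(label_path)
    doc_path.parent.mkdir(parents=True, exist_ok=True)
    doc_path.write_text(
        "\n".join(" ".join(doc) for doc in corpus.documents) + "\n", encoding="utf-8"
    )
    label_path.write_text("\n".join(corpus.labels) + "\n", encoding="utf-8")
    return doc_path, label_path


def read_corpus(doc_path, label_path) -> LabeledCorpus:
    docs = [
        line.split()
        for line in Path(doc_path).read_text(encoding="utf-8").splitlines()
        if line.strip()
    ]
    labels = [
        line.strip()
        for line in Path(label_path).read_text(encoding="utf-8").splitlines()
        if line.strip()
    ]
    return LabeledCorpus(documents=docs, labels=labels)


def _jsonable(obj):
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_json(data: dict, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(
        json.dumps(_jsonable(data), indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return path


def sha256_file(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_report(bundle: dict, out_dir) -> dict:
    """Write the report JSON and a checksummed file manifest.

    Returns the manifest mapping relative file names to SHA-256 digests; two
    runs with the same config and seed produce byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report_path = write_json(bundle, out_dir / "report.json")
    files = sorted(
        p for p in out_dir.rglob("*") if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "files": {str(p.relative_to(out_dir)): sha256_file(p) for p in files},
        "report": report_path.name,
    }
    write_json(manifest, out_dir / "manifest.json")
    return manifest
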