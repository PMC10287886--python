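"""On-disk feature store: TSV manifest + dense array + JSON metadata.

A store is a directory:

    store/
      manifest.tsv   # id, class_label, source_path, row_index (UTF-8 TSV)
      features.npy   # float64 array of shape (n_records, dim)
      meta.json      # format version, shape, extractor spec, creation info

The sidecar-manifest layout keeps records greppable and diffable while the
matrix round-trips bit-exactly.  ``load_db(save_db(db))`` reproduces ids,
labels, order and feature values exactly.
"""

from __future__ import annotations

import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .core import FeatureDatabase

FORMAT_VERSION = 1

__all__ = ["save_db", "load_db", "FORMAT_VERSION"]


def save_db(
    db: FeatureDatabase,
    path: str | Path,
    extractor: dict | None = None,
    timestamp: bool = True,
) -> Path:
    """Write a database to a store directory (created if missing)."""
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    manifest = pd.DataFrame(
        {
            "id": db.ids,
            "class_label": db.labels,
            "source_path": [r.source_path or "" for r in db],
            "row_index": range(len(db)),
        }
    )
    manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
    np.save(out / "features.npy", db.matrix)
    meta = {
        "format_version": FORMAT_VERSION,
        "n_records": len(db),
        "dim": db.dim,
        "extractor": extractor,
    }
    if timestamp:
        meta["created"] = datetime.now(timezone.utc).isoformat()
    (out / "meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return out


def load_db(path: str | Path) -> FeatureDatabase:
    """Load a store directory back into a database, validating consistency."""
    root = Path(path)
    for name in ("manifest.tsv", "features.npy", "meta.json"):
        if not (root / name).exists():
            raise FileNotFoundError(f"store {root} is missing {name}")
    meta = json.loads((root / "meta.json").read_text())
    version = meta.get("format_version")
    if version != FORMAT_VERSION:
        raise ValueError(f"unknown store format version {version!r} (expected {FORMAT_VERSION})")
    manifest = pd.read_csv(root / "manifest.tsv", sep="\t", dtype=str, keep_default_na=False)
    matrix = np.load(root / "features.npy")
    if len(manifest) != matrix.shape[0]:
        raise ValueError(
            f"store corrupt: manifest has {len(manifest)} rows but matrix has "
            f"{matrix.shape[0]}"
        )
    if meta.get("n_records") != matrix.shape[0] or meta.get("dim") != matrix.shape[1]:
        raise ValueError(
            f"store corrupt: metadata says ({meta.get('n_records')}, {meta.get('dim')}) "
            f"but matrix is {matrix.shape}"
        )
    expected_rows = [str(i) for i in range(len(manifest))]
    if list(manifest["row_index"]) != expected_rows:
        raise ValueError("store corrupt: manifest row_index is not 0..n-1 in order")
    return FeatureDatabase.from_arrays(
        ids=list(manifest["id"]),
        labels=list(manifest["class_label"]),
        matrix=matrix,
        source_paths=[p or None for p in manifest["source_path"]],
    )


def load_extractor_meta(path: str | Path) -> dict | None:
    """The extractor spec recorded in a store's metadata, if any."""
    meta = json.loads((Path(path) / "meta.json").read_text())
    return meta.get("extractor")
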