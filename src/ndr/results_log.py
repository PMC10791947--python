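"""Managed storage for decoding results.

Each saved result is one portable archive directory of plain-text files
(metric tables as CSV plus a JSON parameter record), and a ``manifest.csv``
at the root of the results directory records every save: the result name,
a timestamp, the archive path, and the flattened parameter map (dotted
keys such as ``datasource.num_cv_splits``). The manifest supports lookup
by name or by parameter values, and can be rebuilt from the archives if
it is lost.

Every manifest parameter cell is JSON-encoded so values round-trip
exactly through CSV regardless of type.
"""

from __future__ import annotations

import json
import os
import re
import shutil
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .crossval import DecodingResults
from .errors import ResultsLogError
from .metrics import ConfusionMatrix, ConfusionMatrixSet, MainResults

__all__ = [
    "ManifestEntry",
    "log_save_results",
    "log_load_results_from_result_name",
    "log_load_results_from_params",
    "list_results",
    "rebuild_manifest",
    "results_equal",
]

MANIFEST = "manifest.csv"
_FIXED_COLS = ["result_name", "timestamp", "file_path"]


@dataclass
class ManifestEntry:
    result_name: str
    timestamp: str
    file_path: str
    params: dict
    duplicate_params: bool = False


def _slug(name: str) -> str:
    return re.sub(r"[^A-Za-z0-9_.-]+", "_", name).strip("_") or "result"


def _encode(value) -> str:
    if isinstance(value, np.generic):
        value = value.item()
    return json.dumps(value, sort_keys=True)


def _read_manifest(save_dir: Path) -> pd.DataFrame:
    path = save_dir / MANIFEST
    if not path.exists():
        return pd.DataFrame(columns=_FIXED_COLS)
    # keep_default_na=False: cells like "null" are JSON payloads, not NA
    return pd.read_csv(path, dtype=str, keep_default_na=False)


def _write_manifest(save_dir: Path, df: pd.DataFrame) -> None:
    # write-to-temp + atomic rename: a crash never leaves a partial row
    tmp = save_dir / (MANIFEST + ".tmp")
    df.to_csv(tmp, index=False)
    os.replace(tmp, save_dir / MANIFEST)


def _save_archive(results: DecodingResults, archive: Path) -> None:
    archive.mkdir(parents=True, exist_ok=True)
    meta = {
        "params": {k: (v.item() if isinstance(v, np.generic) else v)
                   for k, v in results.params.items()},
        "has_main_results": results.main_results is not None,
        "has_confusion": results.confusion_matrices is not None,
    }
    if results.main_results is not None:
        meta["num_classes"] = int(results.main_results.num_classes)
        mr = results.main_results
        mr.zero_one_accuracy.to_csv(archive / "main_accuracy.csv")
        mr.normalized_rank.to_csv(archive / "main_rank.csv")
        mr.decision_values.to_csv(archive / "main_dv.csv")
        mr.per_run.to_csv(archive / "main_per_run.csv", index=False)
    if results.confusion_matrices is not None:
        rows = []
        for t in results.confusion_matrices.train_times:
            cm = results.confusion_matrices.matrices[t]
            long = (cm.counts.rename_axis("actual").reset_index()
                    .melt(id_vars="actual", var_name="predicted",
                          value_name="count"))
            long.insert(0, "test_time", cm.test_time)
            long.insert(0, "train_time", cm.train_time)
            rows.append(long)
        pd.concat(rows, ignore_index=True).to_csv(
            archive / "confusion.csv", index=False)
    with open(archive / "result.json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)


def _load_archive(archive: Path) -> DecodingResults:
    with open(archive / "result.json") as fh:
        meta = json.load(fh)
    results = DecodingResults(params=meta["params"])
    if meta["has_main_results"]:
        def load_pivot(name):
            df = pd.read_csv(archive / name, index_col=0,
                             float_precision="round_trip")
            df.index = df.index.astype(int)
            df.columns = df.columns.astype(int)
            df.index.name = "train_time"
            df.columns.name = "test_time"
            return df

        results.main_results = MainResults(
            num_classes=meta["num_classes"],
            zero_one_accuracy=load_pivot("main_accuracy.csv"),
            normalized_rank=load_pivot("main_rank.csv"),
            decision_values=load_pivot("main_dv.csv"),
            per_run=pd.read_csv(archive / "main_per_run.csv",
                                float_precision="round_trip"))
    if meta["has_confusion"]:
        long = pd.read_csv(archive / "confusion.csv")
        matrices = {}
        for t, grp in long.groupby("train_time"):
            counts = grp.pivot(index="actual", columns="predicted",
                               values="count")
            counts.index.name = None
            counts.columns.name = None
            matrices[int(t)] = ConfusionMatrix(
                train_time=int(t), test_time=int(grp["test_time"].iloc[0]),
                counts=counts)
        results.confusion_matrices = ConfusionMatrixSet(matrices=matrices)
    return results


def log_save_results(results: DecodingResults, save_dir,
                     result_name: str = None) -> ManifestEntry:
    """Serialize results and append a row to the manifest.

    ``result_name`` must be unique within the manifest (auto-generated
    ``result_NNNN`` if omitted). Saving a parameter set identical to an
    existing entry is allowed but flagged via ``duplicate_params`` on the
    returned entry.
    """
    save_dir = Path(save_dir)
    save_dir.mkdir(parents=True, exist_ok=True)
    manifest = _read_manifest(save_dir)

    if result_name is None:
        result_name = f"result_{len(manifest) + 1:04d}"
    if (manifest["result_name"] == result_name).any():
        raise ResultsLogError(
            f"result name {result_name!r} already exists in the manifest; "
            f"names are unique keys")

    encoded = {k: _encode(v) for k, v in results.params.items()}
    param_cols = [c for c in manifest.columns if c not in _FIXED_COLS]
    duplicate = False
    for _, row in manifest.iterrows():
        existing = {c: row[c] for c in param_cols if row[c] != ""}
        if existing == encoded:
            duplicate = True
            break

    archive = save_dir / _slug(result_name)
    if archive.exists():
        raise ResultsLogError(f"archive path {archive} already exists")
    try:
        _save_archive(results, archive)
        timestamp = datetime.now(timezone.utc).isoformat(timespec="seconds")
        row = {"result_name": result_name, "timestamp": timestamp,
               "file_path": str(archive.relative_to(save_dir)), **encoded}
        manifest = pd.concat([manifest, pd.DataFrame([row])],
                             ignore_index=True).fillna("")
        _write_manifest(save_dir, manifest)
    except Exception:
        shutil.rmtree(archive, ignore_errors=True)
        raise
    return ManifestEntry(result_name=result_name, timestamp=timestamp,
                         file_path=str(archive), params=dict(results.params),
                         duplicate_params=duplicate)


def list_results(save_dir) -> pd.DataFrame:
    """The manifest as a dataframe (empty if nothing saved yet)."""
    return _read_manifest(Path(save_dir))


def log_load_results_from_result_name(result_name: str,
                                      save_dir) -> DecodingResults:
    """Exact-name lookup; suggests near-matches for unknown names."""
    save_dir = Path(save_dir)
    manifest = _read_manifest(save_dir)
    hit = manifest[manifest["result_name"] == result_name]
    if len(hit) == 0:
        import difflib
        names = manifest["result_name"].tolist()
        near = difflib.get_close_matches(result_name, names, n=3, cutoff=0.3)
        raise ResultsLogError(
            f"no result named {result_name!r}; "
            + (f"did you mean {near}?" if near else f"saved results: {names}"))
    return _load_archive(save_dir / hit.iloc[0]["file_path"])


def log_load_results_from_params(param_subset: dict, save_dir) -> DecodingResults:
    """Load the unique saved result matching all given key=value pairs."""
    save_dir = Path(save_dir)
    manifest = _read_manifest(save_dir)
    param_cols = [c for c in manifest.columns if c not in _FIXED_COLS]
    unknown = [k for k in param_subset if k not in param_cols]
    if unknown:
        raise ResultsLogError(
            f"unknown parameter key(s) {unknown}; manifest has: {param_cols}")
    mask = pd.Series(True, index=manifest.index)
    for key, value in param_subset.items():
        mask &= manifest[key] == _encode(value)
    hits = manifest[mask]
    if len(hits) == 0:
        raise ResultsLogError(f"no saved result matches {param_subset}")
    if len(hits) > 1:
        raise ResultsLogError(
            f"{len(hits)} results match {param_subset}: "
            f"{hits['result_name'].tolist()}; refine the query or load by name")
    return _load_archive(save_dir / hits.iloc[0]["file_path"])


def rebuild_manifest(save_dir) -> pd.DataFrame:
    """Reconstruct manifest.csv by scanning archive directories.

    Timestamps are not stored inside archives, so rebuilt rows carry the
    rebuild time; parameter columns are reconstructed exactly.
    """
    save_dir = Path(save_dir)
    rows = []
    for archive in sorted(p for p in save_dir.iterdir() if p.is_dir()):
        meta_path = archive / "result.json"
        if not meta_path.exists():
            continue
        with open(meta_path) as fh:
            meta = json.load(fh)
        row = {"result_name": archive.name,
               "timestamp": datetime.now(timezone.utc).isoformat(
                   timespec="seconds"),
               "file_path": archive.name}
        row.update({k: _encode(v) for k, v in meta["params"].items()})
        rows.append(row)
    manifest = pd.DataFrame(rows).fillna("") if rows else pd.DataFrame(
        columns=_FIXED_COLS)
    _write_manifest(save_dir, manifest)
    return manifest


def results_equal(a: DecodingResults, b: DecodingResults) -> bool:
    """Exact equality of parameter records and all metric tables."""
    if dict(a.params) != dict(b.params):
        return False
    if (a.main_results is None) != (b.main_results is None):
        return False
    if a.main_results is not None:
        ma, mb = a.main_results, b.main_results
        if ma.num_classes != mb.num_classes:
            return False
        for attr in ("zero_one_accuracy", "normalized_rank", "decision_values"):
            if not getattr(ma, attr).equals(getattr(mb, attr)):
                return False
        if not ma.per_run.equals(mb.per_run):
            return False
    if (a.confusion_matrices is None) != (b.confusion_matrices is None):
        return False
    if a.confusion_matrices is not None:
        ta = a.confusion_matrices.matrices
        tb = b.confusion_matrices.matrices
        if set(ta) != set(tb):
            return False
        for t in ta:
            if not ta[t].counts.equals(tb[t].counts):
                return False
    return True
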