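"""Table readers/writers and model (de)serialization."""

from __future__ import annotations

import glob
import hashlib
import json
import os

import joblib
import numpy as np
import pandas as pd

from .config import RunConfig
from .ensemble import EnsembleModel, FittedPipeline, Submodel
from .weighting import LabeledMatrix, WeightingError, WeightSet, ZTransform

__all__ = [
    "IOError_",
    "read_feature_table",
    "read_feature_meta",
    "read_rate_table",
    "write_rate_table",
    "write_weight_table",
    "save_pipeline",
    "load_pipeline",
    "file_sha256",
]

_LABEL_MAP = {"0": 0, "1": 1, "good": 0, "poor": 1}


class IOError_(ValueError):
    pass


def _read_table(path: str) -> pd.DataFrame:
    sep = "," if path.endswith(".csv") else "\t"
    return pd.read_csv(path, sep=sep, dtype=str)


def read_feature_table(path: str, label_column: str) -> LabeledMatrix:
    """Read a samples-by-features CSV/TSV with a binary outcome column.

    The first column holds sample ids.  Labels accept 0/1 or good/poor.
    Non-numeric feature cells and missing values are rejected with their
    coordinates; duplicate sample ids are an error.
    """
    raw = _read_table(path)
    if raw.shape[1] < 2:
        raise IOError_(f"{path}: expected sample id column plus features")
    raw = raw.set_index(raw.columns[0])
    if raw.index.has_duplicates:
        dupes = raw.index[raw.index.duplicated()].unique().tolist()
        raise IOError_(f"{path}: duplicate sample ids {dupes}")
    if label_column not in raw.columns:
        raise IOError_(f"{path}: no label column {label_column!r}")

    labels = []
    for sid, val in raw[label_column].items():
        key = str(val).strip().lower()
        if key not in _LABEL_MAP:
            raise IOError_(
                f"{path}: non-binary label {val!r} for sample {sid!r}")
        labels.append(_LABEL_MAP[key])
    y = pd.Series(labels, index=raw.index, name=label_column)

    feats = raw.drop(columns=[label_column])
    values = pd.DataFrame(index=feats.index)
    for col in feats.columns:
        converted = pd.to_numeric(feats[col], errors="coerce")
        bad = converted.isna()
        if bad.any():
            sid = feats.index[bad.argmax()]
            raise IOError_(
                f"{path}: non-numeric or missing value at sample {sid!r}, "
                f"feature {col!r}")
        values[col] = converted
    return LabeledMatrix(X=values, y=y)


def read_feature_meta(path: str) -> pd.DataFrame:
    meta = _read_table(path)
    for col in ("feature_id", "kind"):
        if col not in meta.columns:
            raise IOError_(f"{path}: meta table needs a {col!r} column")
    if "gene_id" not in meta.columns:
        meta["gene_id"] = None
    meta["gene_id"] = meta["gene_id"].where(meta["gene_id"].notna(), None)
    return meta


def read_rate_table(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t").set_index("gene_id")
    if "WE" not in df.columns:
        if "R" not in df.columns:
            raise IOError_(f"{path}: rate table needs R or WE")
        df["WE"] = 1.0 / df["R"]
    return df


def write_rate_table(path: str, genes) -> None:
    rows = [{"gene_id": g.gene_id, "L": g.L, "L_effective": g.L_effective,
             "R": g.R, "WE": g.WE} for g in genes]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_site_table(path: str, per_gene_rates: dict) -> None:
    # columns are 1-based in reports, 0-based internally
    rows = []
    for gene_id, rates in per_gene_rates.items():
        for sr in rates:
            rows.append({"gene_id": gene_id, "column": sr.column_index + 1,
                         "s": sr.s, "t": sr.t,
                         "r": "" if sr.r is None else sr.r,
                         "n_taxa_ungapped": sr.n_taxa_ungapped})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_weight_table(path: str, weights: WeightSet) -> None:
    weights.table.rename_axis("feature_id").to_csv(path, sep="\t")


def file_sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# model archive: JSON manifest + per-submodel forest files

_FORMAT_VERSION = 1


def save_pipeline(fitted: FittedPipeline, out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    manifest = {
        "format_version": _FORMAT_VERSION,
        "mode": fitted.mode,
        "config": fitted.model.config.to_dict(),
        "ztransform": {
            "means": fitted.ztransform.means.to_dict(),
            "sds": fitted.ztransform.sds.to_dict(),
            "feature_order": list(fitted.ztransform.means.index),
        },
        "submodels": [
            {"file": f"submodel_{i:04d}.joblib",
             "features": sm.features,
             "sample_ids": [str(s) for s in sm.sample_ids],
             "seed": sm.seed,
             "fallback_used": sm.fallback_used}
            for i, sm in enumerate(fitted.model.submodels)
        ],
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)
    fitted.weights.table.rename_axis("feature_id").to_csv(
        os.path.join(out_dir, "weights.tsv"), sep="\t")
    for i, sm in enumerate(fitted.model.submodels):
        joblib.dump(sm.forest, os.path.join(out_dir, f"submodel_{i:04d}.joblib"))


def load_pipeline(model_dir: str) -> FittedPipeline:
    with open(os.path.join(model_dir, "manifest.json")) as fh:
        manifest = json.load(fh)
    if manifest.get("format_version") != _FORMAT_VERSION:
        raise IOError_(f"unsupported model format: {manifest.get('format_version')}")
    order = manifest["ztransform"]["feature_order"]
    tf = ZTransform(
        means=pd.Series(manifest["ztransform"]["means"]).reindex(order),
        sds=pd.Series(manifest["ztransform"]["sds"]).reindex(order))
    weights = WeightSet(pd.read_csv(
        os.path.join(model_dir, "weights.tsv"), sep="\t").set_index("feature_id"))
    config = RunConfig.from_dict(manifest["config"])
    submodels = []
    for entry in manifest["submodels"]:
        forest = joblib.load(os.path.join(model_dir, entry["file"]))
        submodels.append(Submodel(sample_ids=entry["sample_ids"],
                                  features=entry["features"],
                                  forest=forest, seed=entry["seed"],
                                  fallback_used=entry["fallback_used"]))
    model = EnsembleModel(submodels=submodels, weights=weights, config=config)
    return FittedPipeline(ztransform=tf, weights=weights, model=model,
                          mode=manifest["mode"])


def find_alignments(directory: str) -> dict[str, str]:
    """Map gene_id -> FASTA path for every alignment file in ``directory``."""
    out = {}
    for path in sorted(glob.glob(os.path.join(directory, "*.fa*"))):
        gene_id = os.path.splitext(os.path.basename(path))[0]
        out[gene_id] = path
    if not out:
        raise IOError_(f"no FASTA alignments found under {directory}")
    return out
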