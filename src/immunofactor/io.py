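"""Reading, writing and aligning multi-view datasets and fitted-model bundles.

All on-disk formats are plain text: tab-separated tables (UTF-8, ``.``
decimal), MatrixMarket for cell counts and a JSON manifest for model
bundles.  A *view* is one modality block (a cell-type cluster's pseudobulk,
cytokines, plasma proteomics, neutrophil bulk expression, clinical
markers); samples may be absent from individual views and are tracked by a
per-view presence mask rather than zero-filled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MODEL_BUNDLE_VERSION = 1

#: canonical ordering of timepoint labels used across the package
TIMEPOINT_ORDER = ["TP0", "TP1", "TP2", "TP3", "TP4"]

GROUP_LABELS = {"sterile_ACS", "ACS_infection", "ACS_delayed", "CCS", "non_CCS", "control"}


class DataFormatError(ValueError):
    """Raised when an on-disk table violates the format contract."""


@dataclass
class ViewMatrix:
    """One modality block: samples x features with sentinel bookkeeping.

    ``values`` holds parsed reals with NaN for *missing* cells; entries that
    carried the out-of-range token are NaN in ``values`` but flagged True in
    ``oor`` so that missing, OOR and literal zero stay distinct until a
    preprocessing rule decides what to do with them.
    """

    view_name: str
    values: pd.DataFrame
    oor: pd.DataFrame | None = None
    mask: pd.Series | None = None  # per-sample presence, set by align_samples

    def __post_init__(self) -> None:
        cols = pd.Index(self.values.columns)
        if cols.has_duplicates:
            dups = sorted(cols[cols.duplicated()].unique())
            raise DataFormatError(
                f"view '{self.view_name}': duplicate feature ids {dups}"
            )
        idx = pd.Index(self.values.index)
        if idx.has_duplicates:
            dups = sorted(idx[idx.duplicated()].unique())
            raise DataFormatError(
                f"view '{self.view_name}': duplicate sample ids {dups}"
            )
        if self.oor is None:
            self.oor = pd.DataFrame(
                False, index=self.values.index, columns=self.values.columns
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    def qualified_feature_ids(self) -> list[str]:
        """Feature ids in the pooled ``view::feature`` convention."""
        return [f"{self.view_name}::{f}" for f in self.values.columns]


@dataclass
class MultiViewDataset:
    """Aligned collection of views sharing one sample universe."""

    views: dict[str, ViewMatrix]
    meta: pd.DataFrame

    @property
    def sample_ids(self) -> list[str]:
        return list(self.meta["sample_id"])

    def view(self, name: str) -> ViewMatrix:
        return self.views[name]


OOR_TOKEN = "OOR"


def read_view_table(path: str | Path, view_name: str) -> ViewMatrix:
    """Read a sample x feature TSV, preserving missing and OOR sentinels.

    The first column holds sample ids, the header row feature ids.  Empty
    cells become NaN (missing); the literal token ``OOR`` is kept as a
    distinct sentinel state, not coerced to 0 or to missing.
    """
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    dup_cols = pd.Index(header)
    if dup_cols.has_duplicates:
        dups = sorted(dup_cols[dup_cols.duplicated()].unique())
        raise DataFormatError(f"view '{view_name}': duplicate feature ids {dups}")
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    raw.index = raw.index.astype(str)
    raw.columns = header
    if raw.shape[1] == 0:
        raise DataFormatError(f"view '{view_name}': table at {path} has no feature columns")
    oor = raw == OOR_TOKEN
    values = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        cell = raw[col].where(~oor[col], other="")
        parsed = pd.to_numeric(cell.mask(cell == ""), errors="coerce")
        bad = parsed.isna() & (cell != "") & ~oor[col].to_numpy()
        if bad.any():
            row = raw.index[np.flatnonzero(bad)[0]]
            raise DataFormatError(
                f"view '{view_name}': unparseable value at row '{row}', column '{col}'"
            )
        values[col] = parsed
    return ViewMatrix(view_name=view_name, values=values, oor=oor)


def write_view_table(view: ViewMatrix, path: str | Path) -> None:
    """Write a ViewMatrix back to TSV, re-emitting OOR tokens and blanks."""
    out = view.values.astype(object).copy()
    for col in out.columns:
        formatted = view.values[col].map(lambda v: "" if pd.isna(v) else repr(float(v)))
        formatted = formatted.where(~view.oor[col], other=OOR_TOKEN)
        out[col] = formatted
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_sample_meta(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "patient_id": str})
    return validate_sample_meta(meta)


def validate_sample_meta(meta: pd.DataFrame) -> pd.DataFrame:
    required = {"sample_id", "patient_id", "timepoint", "group"}
    missing = required - set(meta.columns)
    if missing:
        raise DataFormatError(f"sample metadata lacks columns {sorted(missing)}")
    dup = meta.duplicated(subset=["patient_id", "timepoint"])
    if dup.any():
        pair = meta.loc[dup, ["patient_id", "timepoint"]].iloc[0].tolist()
        raise DataFormatError(f"duplicate (patient_id, timepoint): {pair}")
    bad_tp = set(meta["timepoint"]) - set(TIMEPOINT_ORDER)
    if bad_tp:
        raise DataFormatError(f"unknown timepoint labels {sorted(bad_tp)}")
    bad_group = set(meta["group"]) - GROUP_LABELS
    if bad_group:
        raise DataFormatError(f"unknown group labels {sorted(bad_group)}")
    if "delta_EF" not in meta.columns:
        meta = meta.assign(delta_EF=np.nan)
    return meta


def align_samples(views: list[ViewMatrix] | dict[str, ViewMatrix],
                  meta: pd.DataFrame) -> MultiViewDataset:
    """Align views onto one canonical sample universe.

    The universe is the union of samples over all views; every one of them
    must appear in ``meta``.  Samples are ordered canonically by
    (patient_id, timepoint) so factor matrices are comparable across runs.
    Per view, a boolean mask marks which universe samples the view measured.
    """
    if isinstance(views, dict):
        views = list(views.values())
    meta = validate_sample_meta(meta)
    union: set[str] = set()
    for v in views:
        if len(v.sample_ids) == 0:
            raise DataFormatError(f"view '{v.view_name}' is empty")
        union |= set(v.sample_ids)
    known = set(meta["sample_id"])
    orphans = union - known
    if orphans:
        raise DataFormatError(f"samples missing from metadata: {sorted(orphans)}")

    meta = meta[meta["sample_id"].isin(union)].copy()
    tp_rank = {t: i for i, t in enumerate(TIMEPOINT_ORDER)}
    meta["_tp"] = meta["timepoint"].map(tp_rank)
    meta = meta.sort_values(["patient_id", "_tp"], kind="mergesort").drop(columns="_tp")
    meta = meta.reset_index(drop=True)
    order = list(meta["sample_id"])

    aligned: dict[str, ViewMatrix] = {}
    for v in views:
        present = pd.Series([s in set(v.sample_ids) for s in order],
                            index=order, dtype=bool)
        values = v.values.reindex(order)
        oor = v.oor.reindex(order, fill_value=False).astype(bool)
        aligned[v.view_name] = ViewMatrix(
            view_name=v.view_name, values=values, oor=oor, mask=present
        )
    return MultiViewDataset(views=aligned, meta=meta)


def save_dataset(dataset: MultiViewDataset, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "views").mkdir(exist_ok=True)
    for name, v in dataset.views.items():
        present = v.mask if v.mask is not None else pd.Series(True, index=v.values.index)
        sub = ViewMatrix(name, v.values.loc[present[present].index],
                         v.oor.loc[present[present].index])
        write_view_table(sub, out / "views" / f"{name}.tsv")
    dataset.meta.to_csv(out / "meta.tsv", sep="\t", index=False)
    manifest = {"kind": "dataset", "views": sorted(dataset.views)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))


def load_dataset(in_dir: str | Path) -> MultiViewDataset:
    src = Path(in_dir)
    manifest = json.loads((src / "manifest.json").read_text())
    views = [read_view_table(src / "views" / f"{n}.tsv", n) for n in manifest["views"]]
    meta = read_sample_meta(src / "meta.tsv")
    return align_samples(views, meta)


# ---------------------------------------------------------------------------
# model bundles


def _write_matrix(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", float_format="%.17g")


def serialize_model(fit, out_dir: str | Path) -> None:
    """Persist a fitted factor model as a directory of TSVs + JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    factors = [f"F{k + 1}" for k in range(fit.K)]
    _write_matrix(pd.DataFrame(fit.Z, index=fit.sample_ids, columns=factors),
                  out / "Z.tsv")
    for name in fit.view_names:
        _write_matrix(
            pd.DataFrame(fit.W[name], index=fit.feature_ids[name], columns=factors),
            out / f"W_{name}.tsv",
        )
    _write_matrix(pd.DataFrame({"tau": [fit.tau[n] for n in fit.view_names]},
                               index=fit.view_names), out / "tau.tsv")
    _write_matrix(pd.DataFrame(
        np.vstack([fit.alpha[n] for n in fit.view_names]),
        index=fit.view_names, columns=factors), out / "alpha.tsv")
    if fit.variance_table is not None:
        _write_matrix(fit.variance_table, out / "variance.tsv")
    manifest = {
        "kind": "factor_model",
        "version": MODEL_BUNDLE_VERSION,
        "K": int(fit.K),
        "views": list(fit.view_names),
        "n_samples": len(fit.sample_ids),
        "n_iter": len(fit.trace),
        "has_variance_table": fit.variance_table is not None,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    pd.DataFrame({"objective": fit.trace}).to_csv(out / "trace.tsv", sep="\t",
                                                  index=False, float_format="%.17g")


def deserialize_model(in_dir: str | Path):
    from .gfa import FactorModelFit  # local import to avoid a cycle

    src = Path(in_dir)
    mpath = src / "manifest.json"
    if not mpath.exists():
        raise DataFormatError(f"no manifest.json in {src}")
    manifest = json.loads(mpath.read_text())
    if manifest.get("kind") != "factor_model":
        raise DataFormatError(f"{src} is not a factor-model bundle")
    if manifest.get("version") != MODEL_BUNDLE_VERSION:
        raise DataFormatError(
            f"model bundle version {manifest.get('version')} unsupported "
            f"(expected {MODEL_BUNDLE_VERSION})"
        )
    Zdf = pd.read_csv(src / "Z.tsv", sep="\t", index_col=0)
    views = manifest["views"]
    W, feature_ids = {}, {}
    for name in views:
        wpath = src / f"W_{name}.tsv"
        if not wpath.exists():
            raise DataFormatError(f"model bundle truncated: missing {wpath.name}")
        wdf = pd.read_csv(wpath, sep="\t", index_col=0)
        W[name] = wdf.to_numpy(float)
        feature_ids[name] = list(wdf.index)
    tau_df = pd.read_csv(src / "tau.tsv", sep="\t", index_col=0)
    alpha_df = pd.read_csv(src / "alpha.tsv", sep="\t", index_col=0)
    trace = pd.read_csv(src / "trace.tsv", sep="\t")["objective"].tolist()
    variance = None
    if manifest.get("has_variance_table"):
        variance = pd.read_csv(src / "variance.tsv", sep="\t", index_col=0)
    K = int(manifest["K"])
    if Zdf.shape[1] != K:
        raise DataFormatError("model bundle truncated: Z column count != K")
    return FactorModelFit(
        Z=Zdf.to_numpy(float),
        W=W,
        tau={n: float(tau_df.loc[n, "tau"]) for n in views},
        alpha={n: alpha_df.loc[n].to_numpy(float) for n in views},
        trace=trace,
        K=K,
        sample_ids=list(Zdf.index.astype(str)),
        view_names=list(views),
        feature_ids=feature_ids,
        variance_table=variance,
    )
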