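"""Delimited-text readers and writers.

Canonical interchange is CSV/TSV with dot decimals and header rows carrying
IDs.  The matrix file and the two design files are aligned both by position
and by ID; an ID mismatch is an error, never a silent reorder.  Fitted
models and analysis results are persisted as a directory of delimited text
files plus a JSON manifest (no binary pickles), so every artifact is
diffable and re-loadable.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .bada import BadaModel, ClassificationReport
from .datamodel import AnalysisConfig, DiscriminantTable
from .gsvd import GsvdResult
from .preprocess import Preprocessor, PreprocessParams

__all__ = [
    "load_table",
    "save_table",
    "load_config",
    "save_model",
    "load_model",
    "save_results",
]

_FLOAT_FMT = "%.17g"  # round-trips IEEE doubles exactly through text


def _sep(path: Path) -> str:
    return "\t" if Path(path).suffix.lower() in (".tsv", ".tab") else ","


def load_table(
    matrix_path,
    row_design_path,
    col_design_path,
    masses_path=None,
    weights_path=None,
) -> DiscriminantTable:
    """Load a table from delimited text.

    matrix: header row = column IDs, first column = row IDs, numeric cells.
    row design: columns (row_id, category[, block]).
    col design: columns (col_id, subtable).
    Optional masses/weights: columns (row_id, mass) / (col_id, weight).
    """
    matrix_path = Path(matrix_path)
    mat = pd.read_csv(matrix_path, sep=_sep(matrix_path), index_col=0,
                      float_precision="round_trip")
    try:
        data = mat.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"non-numeric cell in {matrix_path}: {exc}") from exc

    rows = pd.read_csv(Path(row_design_path), sep=_sep(Path(row_design_path)), dtype=str)
    cols = pd.read_csv(Path(col_design_path), sep=_sep(Path(col_design_path)), dtype=str)
    for need, df, which in (({"row_id", "category"}, rows, "row"),
                            ({"col_id", "subtable"}, cols, "column")):
        missing = need - set(df.columns)
        if missing:
            raise ValueError(f"{which} design is missing column(s) {sorted(missing)}")
    if len(rows) != data.shape[0]:
        raise ValueError(
            f"row design has {len(rows)} records for a {data.shape[0]}-row matrix"
        )
    if len(cols) != data.shape[1]:
        raise ValueError(
            f"column design has {len(cols)} records for a {data.shape[1]}-column matrix"
        )
    if not np.array_equal(rows["row_id"].to_numpy(), mat.index.astype(str).to_numpy()):
        raise ValueError("row IDs in design do not match matrix row IDs (order included)")
    if not np.array_equal(cols["col_id"].to_numpy(), mat.columns.astype(str).to_numpy()):
        raise ValueError("column IDs in design do not match matrix column IDs (order included)")

    blocks = rows["block"].to_numpy() if "block" in rows.columns else None
    masses = None
    if masses_path is not None:
        mdf = pd.read_csv(Path(masses_path), sep=_sep(Path(masses_path)))
        if not np.array_equal(mdf.iloc[:, 0].astype(str).to_numpy(),
                              rows["row_id"].to_numpy()):
            raise ValueError("mass file row IDs do not match the row design")
        masses = mdf.iloc[:, 1].to_numpy(dtype=float)
    weights = None
    if weights_path is not None:
        wdf = pd.read_csv(Path(weights_path), sep=_sep(Path(weights_path)))
        if not np.array_equal(wdf.iloc[:, 0].astype(str).to_numpy(),
                              cols["col_id"].to_numpy()):
            raise ValueError("weight file column IDs do not match the column design")
        weights = wdf.iloc[:, 1].to_numpy(dtype=float)

    return DiscriminantTable(
        data=data,
        row_categories=rows["category"].to_numpy(),
        col_subtables=cols["subtable"].to_numpy(),
        row_blocks=blocks,
        row_masses=masses,
        col_weights=weights,
        row_ids=rows["row_id"].to_numpy(),
        col_ids=cols["col_id"].to_numpy(),
    )


def save_table(table: DiscriminantTable, out_dir) -> dict:
    """Write matrix.csv / rows.csv / cols.csv in the load_table layout."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rid = table.row_ids if table.row_ids is not None else np.array(
        [f"r{i + 1}" for i in range(table.n_rows)])
    cid = table.col_ids if table.col_ids is not None else np.array(
        [f"c{j + 1}" for j in range(table.n_cols)])
    pd.DataFrame(table.data, index=pd.Index(rid, name="row_id"), columns=cid).to_csv(
        out / "matrix.csv", float_format=_FLOAT_FMT)
    rows = pd.DataFrame({"row_id": rid, "category": table.row_categories})
    if table.row_blocks is not None:
        rows["block"] = table.row_blocks
    rows.to_csv(out / "rows.csv", index=False)
    pd.DataFrame({"col_id": cid, "subtable": table.col_subtables}).to_csv(
        out / "cols.csv", index=False)
    return {"matrix": "matrix.csv", "rows": "rows.csv", "cols": "cols.csv"}


def load_config(path) -> AnalysisConfig:
    with open(path) as fh:
        return AnalysisConfig.from_dict(json.load(fh))


# ----------------------------------------------------------------- model I/O
def _write_matrix(path: Path, M: np.ndarray, index, columns) -> None:
    pd.DataFrame(M, index=index, columns=columns).to_csv(path, float_format=_FLOAT_FMT)


def save_model(model: BadaModel, out_dir) -> None:
    """Persist a fitted model as delimited text + JSON (re-loadable)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    L = model.gsvd.rank
    dims = [f"dim{l + 1}" for l in range(L)]
    cats = pd.Index(model.categories, name="category")
    cols = pd.Index([f"c{j + 1}" for j in range(model.R.shape[1])], name="col")

    _write_matrix(out / "barycenters.csv", model.R, cats, cols)
    _write_matrix(out / "factor_scores.csv", model.F, cats, dims)
    _write_matrix(out / "loadings.csv", model.G, cols, dims)
    _write_matrix(out / "q.csv", model.gsvd.Q, cols, dims)
    pd.DataFrame({"delta": model.gsvd.delta}).to_csv(
        out / "delta.csv", index=False, float_format=_FLOAT_FMT)
    pd.DataFrame({"center": model.center}).to_csv(
        out / "center.csv", index=False, float_format=_FLOAT_FMT)
    pd.DataFrame({"b": model.b}, index=cats).to_csv(
        out / "category_masses.csv", float_format=_FLOAT_FMT)
    if model.w.ndim == 1:
        pd.DataFrame({"w": model.w}).to_csv(
            out / "weights.csv", index=False, float_format=_FLOAT_FMT)
    else:
        _write_matrix(out / "weights_matrix.csv", model.w,
                      pd.RangeIndex(model.w.shape[0]), pd.RangeIndex(model.w.shape[1]))
    pd.DataFrame({"subtable": model.col_subtables}).to_csv(
        out / "col_subtables.csv", index=False)
    meta = {
        "variant": model.variant,
        "config": model.config.to_dict(),
        "categories": [str(c) for c in model.categories],
        "preprocess_params": (
            None if model.preprocessor is None else model.preprocessor.params.to_dict()
        ),
        "w_diagonal": model.w.ndim == 1,
    }
    with open(out / "model.json", "w") as fh:
        json.dump(meta, fh, indent=2)


def load_model(model_dir) -> BadaModel:
    """Rebuild a fitted model from a save_model directory (enough state to
    project and classify new observations)."""
    d = Path(model_dir)
    with open(d / "model.json") as fh:
        meta = json.load(fh)
    config = AnalysisConfig.from_dict(meta["config"])
    R = pd.read_csv(d / "barycenters.csv", index_col=0, float_precision="round_trip").to_numpy(dtype=float)
    F = pd.read_csv(d / "factor_scores.csv", index_col=0, float_precision="round_trip").to_numpy(dtype=float)
    G = pd.read_csv(d / "loadings.csv", index_col=0, float_precision="round_trip").to_numpy(dtype=float)
    Q = pd.read_csv(d / "q.csv", index_col=0, float_precision="round_trip").to_numpy(dtype=float)
    delta = pd.read_csv(d / "delta.csv", float_precision="round_trip")["delta"].to_numpy(dtype=float)
    center = pd.read_csv(d / "center.csv", float_precision="round_trip")["center"].to_numpy(dtype=float)
    b = pd.read_csv(d / "category_masses.csv", index_col=0, float_precision="round_trip")["b"].to_numpy(dtype=float)
    if meta["w_diagonal"]:
        w = pd.read_csv(d / "weights.csv", float_precision="round_trip")["w"].to_numpy(dtype=float)
    else:
        w = pd.read_csv(d / "weights_matrix.csv", index_col=0, float_precision="round_trip").to_numpy(dtype=float)
    col_subtables = pd.read_csv(d / "col_subtables.csv", float_precision="round_trip")["subtable"].to_numpy()
    categories = np.array(meta["categories"])

    pre = None
    if meta["preprocess_params"] is not None:
        pre = Preprocessor(
            meta["preprocess_params"]["applied_steps"],
            col_subtables=col_subtables,
            subtable_order=pd.unique(pd.Series(col_subtables)).astype(col_subtables.dtype),
        )
        pre.params = PreprocessParams.from_dict(meta["preprocess_params"])

    with np.errstate(divide="ignore", invalid="ignore"):
        P = np.where(delta > 0, F / delta, 0.0)
    return BadaModel(
        R=R, center=center, gsvd=GsvdResult(P=P, Q=Q, delta=delta),
        F=F, G=G, b=b, w=w, masses=np.array([]), categories=categories,
        col_subtables=col_subtables, variant=meta["variant"],
        preprocessor=pre, config=config,
    )


# --------------------------------------------------------------- result I/O
def _hash_config(config: AnalysisConfig) -> str:
    return hashlib.sha256(
        json.dumps(config.to_dict(), sort_keys=True).encode()
    ).hexdigest()[:16]


def save_results(
    model: BadaModel,
    report: ClassificationReport | None,
    out_dir,
    random_report: ClassificationReport | None = None,
    inertia=None,
    permutation=None,
    ellipse_sets=None,
) -> dict:
    """Write the fitted model and every computed summary, plus a JSON
    manifest recording the config, seed and output list.  Outputs not
    computed in this run are flagged absent in the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_model(model, out)
    outputs = ["model.json", "barycenters.csv", "factor_scores.csv", "loadings.csv"]

    if report is not None and report.confusion is not None:
        report.confusion.to_csv(out / "confusion_fixed.csv")
        outputs.append("confusion_fixed.csv")
    if random_report is not None and random_report.confusion is not None:
        random_report.confusion.to_csv(out / "confusion_random.csv")
        outputs.append("confusion_random.csv")
    if inertia is not None:
        pd.DataFrame([{
            "total": inertia.total, "within": inertia.within,
            "between": inertia.between, "r_squared": inertia.r_squared,
            "permutation_p": inertia.permutation_p,
            "n_permutations": inertia.n_permutations,
        }]).to_csv(out / "inertia.csv", index=False, float_format=_FLOAT_FMT)
        outputs.append("inertia.csv")
    if ellipse_sets:
        rows = []
        for es in ellipse_sets:
            for cat, e in es.ellipses.items():
                rows.append({
                    "category": cat, "kind": e.kind,
                    "dim_x": es.dims[0] + 1, "dim_y": es.dims[1] + 1,
                    "center_x": e.center[0], "center_y": e.center[1],
                    "cov_xx": e.shape[0, 0], "cov_xy": e.shape[0, 1],
                    "cov_yy": e.shape[1, 1], "radius2": e.radius2,
                    "level": es.corrected, "degenerate": e.degenerate,
                })
        pd.DataFrame(rows).to_csv(out / "ellipses.csv", index=False,
                                  float_format=_FLOAT_FMT)
        outputs.append("ellipses.csv")

    manifest = {
        "config": model.config.to_dict(),
        "config_hash": _hash_config(model.config),
        "seed": model.config.seed,
        "outputs": outputs,
        "absent": {
            "confusion_random": random_report is None,
            "inertia": inertia is None,
            "ellipses": not ellipse_sets,
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
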