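"""TSV / JSON readers and writers for similarity matrices, associations,
features, predictions and model checkpoints.

All tabular artifacts are plain TSV.  Similarity and feature matrices carry
a header row and an index column of node names; associations travel as a
two-column edge list (miRNA name, disease name).  Writers prepend comment
lines (``# key=value``) carrying the config hash and seed that produced the
artifact; readers skip ``#`` lines.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .graph import AssociationData, SimilarityMatrix

__all__ = [
    "write_similarity",
    "read_similarity",
    "write_edge_list",
    "read_edge_list",
    "write_matrix",
    "read_matrix",
    "write_predictions",
    "load_dataset",
    "write_dataset",
    "save_checkpoint",
    "load_checkpoint",
]

logger = logging.getLogger(__name__)


def _write_tsv(df: pd.DataFrame, path: Path, meta: Mapping | None, index: bool) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, sep="\t", index=index, float_format="%.17g")  # bit-exact round trip


def write_similarity(sim: SimilarityMatrix, path: Path, meta: Mapping | None = None) -> None:
    df = pd.DataFrame(sim.values, index=sim.names, columns=sim.names)
    _write_tsv(df, path, meta, index=True)


def read_similarity(path: Path) -> SimilarityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#", float_precision="round_trip")
    return SimilarityMatrix(values=df.to_numpy(dtype=float), names=[str(c) for c in df.columns])


def write_matrix(values: np.ndarray, path: Path, meta: Mapping | None = None) -> None:
    """Dense unlabeled matrix (e.g. the combined feature matrix A_F)."""
    _write_tsv(pd.DataFrame(np.asarray(values)), path, meta, index=False)


def read_matrix(path: Path) -> np.ndarray:
    return pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip").to_numpy(dtype=float)


def write_edge_list(assoc: AssociationData, path: Path, meta: Mapping | None = None) -> None:
    rows = [
        (assoc.mirna_names[i], assoc.disease_names[j]) for i, j in np.argwhere(assoc.matrix == 1)
    ]
    df = pd.DataFrame(rows, columns=["mirna", "disease"])
    _write_tsv(df, path, meta, index=False)


def read_edge_list(
    path: Path, mirna_names: Sequence[str], disease_names: Sequence[str]
) -> AssociationData:
    """Resolve an edge list against the similarity name orders.

    Duplicated pairs are deduplicated with a warning; unknown names raise.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    if list(df.columns[:2]) != ["mirna", "disease"]:
        df.columns = ["mirna", "disease", *df.columns[2:]]
    before = len(df)
    df = df.drop_duplicates(subset=["mirna", "disease"])
    if len(df) < before:
        logger.warning("dropped %d duplicated association rows", before - len(df))
    mi = {name: i for i, name in enumerate(mirna_names)}
    di = {name: j for j, name in enumerate(disease_names)}
    unknown_m = sorted(set(df["mirna"]) - set(mi))
    unknown_d = sorted(set(df["disease"]) - set(di))
    if unknown_m or unknown_d:
        raise ValueError(
            f"association names missing from similarity headers: "
            f"miRNAs {unknown_m}, diseases {unknown_d}"
        )
    a = np.zeros((len(mirna_names), len(disease_names)), dtype=np.int8)
    for r, d in zip(df["mirna"], df["disease"]):
        a[mi[r], di[d]] = 1
    return AssociationData(a, list(mirna_names), list(disease_names))


def write_predictions(
    rows: Sequence[tuple[str, str, float]], path: Path, meta: Mapping | None = None
) -> None:
    """Prediction TSV with columns (mirna, disease, score, rank); rank 1 = best."""
    df = pd.DataFrame(rows, columns=["mirna", "disease", "score"])
    df = df.sort_values("score", ascending=False, kind="stable").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    _write_tsv(df, path, meta, index=False)


def load_dataset(
    sm_path: Path, sd_path: Path, assoc_path: Path
) -> tuple[SimilarityMatrix, SimilarityMatrix, AssociationData]:
    """Load and cross-validate the three inputs of a run."""
    sm = read_similarity(sm_path)
    sd = read_similarity(sd_path)
    assoc = read_edge_list(assoc_path, sm.names, sd.names)
    return sm, sd, assoc


def write_dataset(dataset, out_dir: Path, meta: Mapping | None = None) -> dict[str, Path]:
    """Write a synthetic dataset in the exact formats the loaders consume."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "sm": out_dir / "mirna_similarity.tsv",
        "sd": out_dir / "disease_similarity.tsv",
        "assoc": out_dir / "associations.tsv",
        "truth": out_dir / "truth.json",
    }
    write_similarity(dataset.sm, paths["sm"], meta)
    write_similarity(dataset.sd, paths["sd"], meta)
    write_edge_list(dataset.assoc, paths["assoc"], meta)
    truth = dict(dataset.truth_dict())
    truth.update(meta or {})
    paths["truth"].write_text(json.dumps(truth, indent=2))
    return paths


def save_checkpoint(model, path: Path, meta: Mapping | None = None) -> None:
    """Single-archive checkpoint: parameter matrices + config + names."""
    from dataclasses import asdict

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cfg = asdict(model.config)
    arrays = {
        "w0": model.w0,
        "w_prime": model.w_prime,
        "scores": model.scores,
        "embedding": model.embedding,
    }
    for name in ("w_att", "att_vec", "w_hidden"):
        value = getattr(model, name)
        if value is not None:
            arrays[name] = value
    header = {
        "config": cfg,
        "mirna_names": model.mirna_names,
        "disease_names": model.disease_names,
        "meta": dict(meta or {}),
        "loss": {
            "cross_entropy": model.loss_report.cross_entropy,
            "reinforcement": model.loss_report.reinforcement,
            "total": model.loss_report.total,
        },
    }
    np.savez(path, __header__=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: Path):
    from .model import LossReport, ModelConfig, ModelState

    with np.load(path) as npz:
        header = json.loads(bytes(npz["__header__"]).decode())
        arrays = {k: npz[k] for k in npz.files if k != "__header__"}
    cfg = ModelConfig(**header["config"])
    report = LossReport(**header["loss"])
    return ModelState(
        config=cfg,
        w0=arrays["w0"],
        w_att=arrays.get("w_att"),
        att_vec=arrays.get("att_vec"),
        w_hidden=arrays.get("w_hidden"),
        w_prime=arrays["w_prime"],
        scores=arrays["scores"],
        embedding=arrays["embedding"],
        mirna_names=header["mirna_names"],
        disease_names=header["disease_names"],
        loss_report=report,
    )
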