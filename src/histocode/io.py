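"""Structured-text persistence of codebooks, models and reports.

Everything is JSON/YAML/CSV; floating-point values round-trip exactly
(Python's JSON writer emits shortest-repr doubles), so a reloaded model
reproduces margins bit-for-bit.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from histocode.codebook import CodebookL1, CodebookPairL2
from histocode.config import PipelineConfig
from histocode.pipeline import FeatureRanking, FoldModel, SvmModel

__all__ = ["save_fold_model", "load_fold_model", "save_predictions", "load_predictions"]


def _dump(path: Path, obj: dict) -> None:
    path.write_text(json.dumps(obj, indent=1))


def save_fold_model(model: FoldModel, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _dump(
        out / "codebook_l1.json",
        {
            "k1": model.codebook_l1.k1,
            "centroids": model.codebook_l1.centroids.tolist(),
            "mean": model.codebook_l1.mean.tolist(),
            "sd": model.codebook_l1.sd.tolist(),
        },
    )
    _dump(
        out / "codebook_l2.json",
        {
            "k2": model.codebook_l2.k2,
            "positive": model.codebook_l2.positive.tolist(),
            "negative": model.codebook_l2.negative.tolist(),
        },
    )
    _dump(
        out / "ranking.json",
        {"order": model.ranking.order.tolist(), "method_tag": model.ranking.method_tag},
    )
    _dump(
        out / "svm.json",
        {
            "selected": model.svm.selected.tolist(),
            "c": model.svm.c,
            "gamma": model.svm.gamma,
            "support_vectors": model.svm.support_vectors.tolist(),
            "dual_coef": model.svm.dual_coef.tolist(),
            "intercept": model.svm.intercept,
            "threshold": model.svm.threshold,
            "f_star": model.f_star,
        },
    )
    model.size_table.to_csv(out / "size_table.csv", index=False)
    model.config.to_yaml(out / "config.yaml")
    (out / "config_hash.txt").write_text(model.config.content_hash() + "\n")


def load_fold_model(in_dir: str | Path) -> FoldModel:
    src = Path(in_dir)
    cb1 = json.loads((src / "codebook_l1.json").read_text())
    cb2 = json.loads((src / "codebook_l2.json").read_text())
    rk = json.loads((src / "ranking.json").read_text())
    sv = json.loads((src / "svm.json").read_text())
    return FoldModel(
        codebook_l1=CodebookL1(
            centroids=np.array(cb1["centroids"]),
            mean=np.array(cb1["mean"]),
            sd=np.array(cb1["sd"]),
            k1=int(cb1["k1"]),
        ),
        codebook_l2=CodebookPairL2(
            positive=np.array(cb2["positive"]), negative=np.array(cb2["negative"]), k2=int(cb2["k2"])
        ),
        ranking=FeatureRanking(order=np.array(rk["order"], dtype=int), method_tag=rk["method_tag"]),
        f_star=int(sv["f_star"]),
        c=float(sv["c"]),
        gamma=float(sv["gamma"]),
        svm=SvmModel(
            selected=np.array(sv["selected"], dtype=int),
            c=float(sv["c"]),
            gamma=float(sv["gamma"]),
            support_vectors=np.array(sv["support_vectors"]),
            dual_coef=np.array(sv["dual_coef"]),
            intercept=float(sv["intercept"]),
            threshold=float(sv["threshold"]),
        ),
        size_table=pd.read_csv(src / "size_table.csv"),
        config=PipelineConfig.from_yaml(src / "config.yaml"),
    )


def save_predictions(predictions: pd.DataFrame, path: str | Path) -> None:
    predictions.to_csv(path, index=False)


def load_predictions(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
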