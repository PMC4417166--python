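"""Cross-context model transfer.

A per-bin model fitted in one context — a cell line, or protein-coding
promoters — is applied to the *same bin index* in another context, using the
target context's epigenetic levels as inputs.  Comparing same-context CV
accuracy with cross-context accuracy quantifies how context-specific the
epigenetics-to-binding relationship is.  Enhancer-anchored analyses reuse
the ordinary same-context machinery with enhancer midpoints as anchors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .forest import ForestConfig
from .modeling import BinEvaluation, FittedBinModel, fit_bin_model, pearson_cc, \
    coefficient_of_determination, predict_affinity
from .signal import BinFeatureMatrix

__all__ = ["TransferResult", "train_full", "cross_apply", "transfer_report"]


@dataclass
class TransferResult:
    bin_index: int
    pcc: float
    r2: float
    predictions: np.ndarray
    source_context: tuple[str, str, str]


def train_full(
    matrix: BinFeatureMatrix,
    kind: str,
    hyper: ForestConfig | None = None,
    seed: int = 0,
    context: tuple[str, str, str] = ("", "", ""),
) -> FittedBinModel:
    """Fit on every row of the source context (no held-out split).

    The target context is a disjoint anchor or cell-line set, so no leakage
    arises from training on the full source.  A split-trained source model
    (for strict comparability with CV numbers) is obtained by fitting
    ``fit_bin_model`` on a split the caller draws.
    """
    return fit_bin_model(
        matrix.X, matrix.y, kind, hyper,
        feature_names=matrix.feature_names,
        bin_index=matrix.bin_index, seed=seed, context=context,
    )


def cross_apply(model: FittedBinModel, target: BinFeatureMatrix) -> TransferResult:
    """Apply a fitted model to the same bin of another context."""
    if model.bin_index != target.bin_index:
        raise ValueError(
            f"bin-index mismatch: model is for bin {model.bin_index}, "
            f"target matrix is bin {target.bin_index} (transfer is strictly same-bin)"
        )
    if list(model.feature_names) != list(target.feature_names):
        raise ValueError("feature name/order mismatch between model and target matrix")
    pred = predict_affinity(model, target.X)
    pcc = pearson_cc(target.y, pred)
    r2 = coefficient_of_determination(target.y, pred, "squared_pcc")
    return TransferResult(target.bin_index, pcc, r2, pred, model.context)


def transfer_report(
    same_context: list[BinEvaluation],
    cross_context: list[TransferResult],
) -> pd.DataFrame:
    """Per-bin same-vs-cross accuracy table with a summary row.

    delta = same-context mean PCC minus cross-context PCC; the summary row
    (bin_index column = "mean") carries the column means, and its delta
    equals the mean of the per-bin deltas.
    """
    same_by_bin = {e.bin_index: e for e in same_context}
    cross_by_bin = {r.bin_index: r for r in cross_context}
    missing = sorted(set(same_by_bin) ^ set(cross_by_bin))
    if missing:
        raise ValueError(f"bin sets differ between same and cross results: {missing}")
    rows = []
    for b in sorted(same_by_bin):
        s, c = same_by_bin[b], cross_by_bin[b]
        rows.append({
            "bin_index": b,
            "pcc_same": s.mean_pcc,
            "pcc_cross": c.pcc,
            "r2_same": s.mean_r2,
            "r2_cross": c.r2,
            "delta": s.mean_pcc - c.pcc,
        })
    df = pd.DataFrame(rows)
    summary = df.drop(columns="bin_index").mean().to_dict()
    summary["bin_index"] = "mean"
    return pd.concat([df, pd.DataFrame([summary])], ignore_index=True)
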