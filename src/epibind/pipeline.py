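"""Stage orchestration: datasets on disk -> matrices -> evaluations -> tables.

The stages communicate only through text artifacts in a run directory
(BED/refFlat/TSV/YAML), so any stage can be rerun from the previous one's
outputs and two runs with the same config and seed produce byte-identical
tables.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from ._rng import child_rng
from .anchors import (
    Anchor,
    BinScheme,
    anchors_from_genes,
    filter_genes,
    read_chrom_sizes,
    read_gene_annotation,
)
from .forest import ForestConfig
from .modeling import (
    BinEvaluation,
    SplitSpec,
    bin_importance,
    feature_target_correlations,
    repeated_cv,
)
from .signal import (
    DEFAULT_FEATURES,
    BinFeatureMatrix,
    MethylationTable,
    build_bin_feature_matrices,
    read_bed_reads,
)
from .transfer import cross_apply, train_full, transfer_report

logger = logging.getLogger(__name__)

__all__ = [
    "load_manifest_tracks",
    "quantify_cell_line",
    "write_matrices",
    "read_matrices",
    "evaluate_bins",
    "evaluations_to_frame",
    "importance_to_frame",
    "run_transfer",
    "parse_bin_spec",
]


def parse_bin_spec(spec: str | Sequence[int] | None, scheme: BinScheme = BinScheme()) -> list[int] | None:
    """Bin subsets: a list of indices or a range string like "-5..5"
    (bin 0 does not exist and is never included)."""
    if spec is None:
        return None
    if isinstance(spec, str):
        lo, hi = spec.split("..")
        lo, hi = int(lo), int(hi)
        sel = [b for b in range(lo, hi + 1) if b != 0]
    else:
        sel = [int(b) for b in spec]
    n = scheme.n_per_side
    for b in sel:
        if b == 0 or not -n <= b <= n:
            raise ValueError(f"invalid bin index {b}")
    return sel


# ---------------------------------------------------------------------------
# data loading / quantification


def load_manifest_tracks(data_dir: str | Path, cell_line: str):
    """Read one cell line's tracks and methylome as named in manifest.yaml."""
    data_dir = Path(data_dir)
    manifest_path = data_dir / "manifest.yaml"
    if not manifest_path.exists():
        raise FileNotFoundError(f"missing prerequisite artifact: {manifest_path}")
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    if cell_line not in manifest["cell_lines"]:
        raise KeyError(f"cell line {cell_line!r} not in manifest ({list(manifest['cell_lines'])})")
    entry = manifest["cell_lines"][cell_line]
    feature_tracks, tf_tracks = [], []
    for t in entry["tracks"]:
        rs = read_bed_reads(
            data_dir / t["file"],
            experiment_id=t["experiment_id"],
            feature_name=t["feature"],
            cell_line=cell_line,
            replicate=t["replicate"],
            library_size=t["library_size"],
        )
        (tf_tracks if t.get("role") == "tf" else feature_tracks).append(rs)
    methylation = MethylationTable.from_file(data_dir / entry["methylation"])
    return manifest, feature_tracks, tf_tracks, methylation


def load_anchors(data_dir: str | Path, scheme: BinScheme = BinScheme()) -> list[Anchor]:
    data_dir = Path(data_dir)
    genes = read_gene_annotation(data_dir / "genes.refflat", dialect="refFlat", biotype_column=11)
    sizes = read_chrom_sizes(data_dir / "chrom.sizes")
    return anchors_from_genes(filter_genes(genes), chrom_sizes=sizes, scheme=scheme)


def quantify_cell_line(
    data_dir: str | Path,
    cell_line: str,
    scheme: BinScheme = BinScheme(),
    bins: Sequence[int] | None = None,
) -> list[BinFeatureMatrix]:
    """End-to-end quantification of one cell line from the on-disk dataset."""
    manifest, feature_tracks, tf_tracks, methylation = load_manifest_tracks(data_dir, cell_line)
    anchors = load_anchors(data_dir, scheme)
    matrices = build_bin_feature_matrices(
        anchors, feature_tracks, methylation, tf_tracks, scheme, DEFAULT_FEATURES
    )
    keep = set(bins if bins is not None else manifest.get("bins") or [m.bin_index for m in matrices])
    return [m for m in matrices if m.bin_index in keep]


def write_matrices(matrices: Sequence[BinFeatureMatrix], outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for m in matrices:
        m.to_frame().to_csv(outdir / f"bin_{m.bin_index:+d}.tsv", sep="\t", float_format="%.6g")


def read_matrices(indir: str | Path) -> list[BinFeatureMatrix]:
    indir = Path(indir)
    paths = sorted(indir.glob("bin_*.tsv"), key=lambda p: int(p.stem.split("_")[1]))
    if not paths:
        raise FileNotFoundError(f"missing prerequisite artifact: no bin matrices under {indir}")
    out = []
    for p in paths:
        df = pd.read_csv(p, sep="\t", index_col="anchor_id")
        y = df.pop("tf_affinity").to_numpy()
        out.append(BinFeatureMatrix(
            int(p.stem.split("_")[1]), list(df.index.astype(str)), list(df.columns),
            df.to_numpy(), y,
        ))
    return out


# ---------------------------------------------------------------------------
# evaluation tables


def evaluate_bins(
    matrices: Sequence[BinFeatureMatrix],
    kind: str,
    spec: SplitSpec,
    hyper: ForestConfig | None = None,
) -> list[BinEvaluation]:
    evals = []
    for m in matrices:
        evals.append(repeated_cv(m, kind, spec, hyper))
        logger.info("bin %+d: mean PCC %.3f over %d repeats",
                    m.bin_index, evals[-1].mean_pcc, len(evals[-1].per_repeat_pcc))
    return evals


def evaluations_to_frame(evals: Sequence[BinEvaluation]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "bin_index": e.bin_index,
            "n_anchors": e.n_anchors,
            "mean_pcc": e.mean_pcc,
            "mean_r2": e.mean_r2,
            "mean_r2_ss": e.mean_r2_ss,
            "sd_pcc": e.sd_pcc,
            "n_skipped": e.n_skipped,
        }
        for e in evals
    ])


def importance_to_frame(
    matrices: Sequence[BinFeatureMatrix],
    hyper: ForestConfig | None = None,
    master_seed: int = 0,
) -> pd.DataFrame:
    """Wide per-bin importance table: %IncMSE and within-bin rank per feature."""
    rows = []
    for m in matrices:
        seed = int(child_rng(master_seed, "importance", m.bin_index).integers(0, 2**31 - 1))
        tab = bin_importance(m, hyper, seed=seed)
        row: dict = {"bin_index": m.bin_index, "has_ties": tab.has_ties}
        for j, f in enumerate(tab.feature_names):
            row[f"{f}_pct_inc_mse"] = tab.pct_inc_mse[j]
            row[f"{f}_rank"] = tab.ranks[j]
        rows.append(row)
    return pd.DataFrame(rows)


def correlations_to_frame(matrices: Sequence[BinFeatureMatrix]) -> pd.DataFrame:
    rows = []
    for m in matrices:
        row = {"bin_index": m.bin_index}
        row.update(zip(m.feature_names, feature_target_correlations(m)))
        rows.append(row)
    return pd.DataFrame(rows)


def run_transfer(
    source_matrices: Sequence[BinFeatureMatrix],
    target_matrices: Sequence[BinFeatureMatrix],
    kind: str,
    spec: SplitSpec,
    hyper: ForestConfig | None = None,
    source_context: tuple[str, str, str] = ("source", "TF", "coding"),
) -> pd.DataFrame:
    """Same-bin transfer: CV in the target context vs source-trained models
    applied to the target, reported as per-bin deltas plus a summary mean."""
    by_bin = {m.bin_index: m for m in target_matrices}
    same = evaluate_bins(target_matrices, kind, spec, hyper)
    cross = []
    for m in source_matrices:
        if m.bin_index not in by_bin:
            raise ValueError(f"target context lacks bin {m.bin_index}")
        seed = int(child_rng(spec.master_seed, "transfer", m.bin_index).integers(0, 2**31 - 1))
        model = train_full(m, kind, hyper, seed=seed, context=source_context)
        cross.append(cross_apply(model, by_bin[m.bin_index]))
    return transfer_report(same, cross)
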