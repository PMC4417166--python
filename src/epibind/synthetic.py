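"""Synthetic epigenomes with a known feature-to-binding link.

Generates every input class the pipeline consumes — gene and enhancer
annotations, per-replicate ChIP-style read tracks for the histone panel,
a CpG methylome, and a TF read track — from a single master seed, with a
configurable, bin-dependent, cell-line-specific generative link between
latent epigenetic levels and latent TF binding affinity:

    latent feature level   L[a, f, b] = exp(mu[f, b] + eps[a, f, b])
    weighted signal        s[a, b]    = sum_f w[c, f, b] * zscore_a(L[a, f, b])
    latent affinity        y*[a, b]   = link(s[a, b]) + Normal(0, noise_sd)

Reads per bin are Poisson around L * read_depth (features) or a monotone
2^y*-shaped rate (TF), so the observed log2(RPM + 1) target is a noisy
monotone image of y* and truly read-free bins occur where y* is smallest.
Because latents are standardized before weighting, each feature's share of
signal variance is its squared weight, which makes the ground-truth
importance order well defined.

All randomness flows from the master seed through named child streams
(annotation / latents:cell:feature / weights:cell / tf:cell / methylome:cell),
so regenerating any part — or restricting to a bin subset — leaves the rest
byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from ._rng import child_rng
from .anchors import (
    Anchor,
    BinScheme,
    EnhancerRecord,
    GeneRecord,
    anchors_from_enhancers,
    anchors_from_genes,
    bin_indices,
    filter_genes,
    make_bin_windows,
)
from .signal import DEFAULT_FEATURES, METHYLATION_FEATURE, BinFeatureMatrix, MethylationTable, ReadSet

__all__ = [
    "SimConfig",
    "GroundTruth",
    "SyntheticDataset",
    "simulate_annotation",
    "simulate_feature_tracks",
    "simulate_tf_track",
    "simulate_methylome",
    "simulate_dataset",
    "latent_bin_matrices",
    "ground_truth_ranks",
    "write_dataset",
]

LINKS = ("linear", "multiplicative", "saturating")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic epigenome.

    The defaults describe the reference scenario used throughout the test
    suite: 1000 modelable genes on one synthetic chromosome, the canonical
    12-feature panel with four informative marks whose weights decay
    exponentially with distance from the anchor (signal s.d. 1.6 at the
    anchor, e-folding scale 30 bins), additive latent noise of s.d. 0.45 —
    an anchor-proximal latent PCC near 0.96 falling to about 0.68 at 4 kb,
    averaging roughly 0.85 across the 80 bins — and sequencing depth of
    about 60 reads per bin and replicate, at which the observed RPM and
    log2(RPM+1) values track their latent counterparts at r > 0.98.
    """

    # annotation
    n_genes: int = 1000              # total gene records, decoys included
    decoy_fraction: float = 0.0      # fraction of n_genes shorter than the length filter
    n_noncoding: int = 0
    n_enhancers: int = 0
    chrom: str = "chrS"
    chrom_length: int | None = None  # None -> sized to fit the layout
    gene_slot: int = 20_000          # per-gene layout pitch, keeps genes disjoint
    gene_length_range: tuple[int, int] = (4_000, 12_000)
    decoy_length_range: tuple[int, int] = (500, 3_999)
    enhancer_width_range: tuple[int, int] = (200, 1_000)

    # cell lines and the feature->affinity link
    n_cell_lines: int = 1
    share_weights: bool = True       # False -> each extra cell line draws its own direction
    feature_names: tuple[str, ...] = DEFAULT_FEATURES
    informative_features: tuple[str, ...] = ("H3K4me3", "H3K9ac", "H3K27ac", "H3K4me1")
    weight_pattern: tuple[float, ...] = (1.0, 0.8, 0.5, 0.3)
    signal_amplitude: float = 1.6    # signal s.d. at |bin| = 1
    decay_scale: float = 30.0        # bins; exponential decay of signal with |bin|
    link: str = "linear"
    noise_sd: float = 0.45
    latent_sd: float = 0.5           # s.d. of eps in log space
    mu_sd: float = 0.3               # spread of per-(feature, bin) baselines

    # sequencing emulation
    read_depth: float = 50.0         # expected reads per unit latent level, per bin
    tf_depth: float = 8.0            # scale of the 2^y*-shaped TF read rate
    n_replicates: int = 2
    read_length: int = 36
    cross_bin_reads: bool = False    # allow reads to straddle bin boundaries

    # methylome
    cpg_peak_density: float = 7.0    # extra expected CpGs per bin at the anchor
    cpg_base_density: float = 1.0    # expected CpGs per bin far from the anchor
    cpg_density_scale: float = 8.0   # bins; decay of CpG density with |bin|
    cpg_level_noise: float = 0.05    # per-CpG level jitter around the bin latent

    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.link not in LINKS:
            raise ValueError(f"unknown link {self.link!r}; choose from {LINKS}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for f in self.informative_features:
            if f not in self.feature_names:
                raise ValueError(f"informative feature {f!r} not in the feature panel")
        if len(self.weight_pattern) != len(self.informative_features):
            raise ValueError("weight_pattern must match informative_features")

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def scheme(self) -> BinScheme:
        return BinScheme()

    def resolved_chrom_length(self) -> int:
        n_slots = self.n_genes + self.n_noncoding + self.n_enhancers
        needed = 20_000 + n_slots * self.gene_slot + 20_000
        if self.chrom_length is None:
            return needed
        if self.chrom_length < needed:
            raise ValueError(
                f"infeasible packing: chrom_length {self.chrom_length} < required {needed}"
            )
        return self.chrom_length

    def signal_sd(self, bin_idx: np.ndarray | int) -> np.ndarray:
        """Total signal s.d. as a function of bin index (exponential decay)."""
        return self.signal_amplitude * np.exp(-np.abs(bin_idx) / self.decay_scale)

    def cpg_density(self, bin_idx: np.ndarray | int) -> np.ndarray:
        return self.cpg_base_density + self.cpg_peak_density * np.exp(
            -np.abs(bin_idx) / self.cpg_density_scale
        )


# ---------------------------------------------------------------------------
# ground truth


def ground_truth_ranks(weights: np.ndarray) -> tuple[np.ndarray, bool]:
    """Importance order implied by a weight vector over standardized latents.

    The contribution of feature f to Var(signal) is w_f^2, so ranks follow
    descending |w| with ties broken by feature order and flagged.  Invariant
    to global rescaling of the weights.
    """
    from .modeling import importance_ranks  # local import to avoid a cycle

    return importance_ranks(np.asarray(weights, dtype=float) ** 2)


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    feature_names: list[str]
    bins: list[int]
    weights: np.ndarray        # (n_cell_lines, n_bins, p)
    ideal: np.ndarray          # (n_cell_lines, n_anchors, p, n_bins) noiseless feature levels
    signal: np.ndarray         # (n_cell_lines, n_anchors, n_bins) link(s), before noise
    y_star: np.ndarray         # (n_cell_lines, n_anchors, n_bins)
    latent_pcc: np.ndarray     # (n_cell_lines, n_bins) corr(link(s), y*)
    anchor_ids: list[str]

    def importance_order(self, cell: int, bin_pos: int) -> tuple[np.ndarray, bool]:
        return ground_truth_ranks(self.weights[cell, bin_pos])

    def top_features(self, cell: int, bin_pos: int, k: int = 2) -> set[str]:
        ranks, _ = self.importance_order(cell, bin_pos)
        return {self.feature_names[j] for j in np.argsort(ranks)[:k]}


# ---------------------------------------------------------------------------
# annotation


def simulate_annotation(cfg: SimConfig, master_seed: int | None = None) -> tuple[list[GeneRecord], list[EnhancerRecord]]:
    """Lay out non-overlapping genes (plus short decoys) and distal enhancers.

    Genes occupy disjoint 20-kb slots with jittered starts; strands are
    drawn 50/50.  round(decoy_fraction * n_genes) records are shorter than
    the 4-kb filter, so the retained count is exact by construction.
    Enhancers sit in their own slots beyond the gene region, at least 10 kb
    from every TSS.
    """
    seed = cfg.master_seed if master_seed is None else master_seed
    rng = child_rng(seed, "annotation")
    cfg.resolved_chrom_length()  # raises on infeasible packing

    n_decoys = int(round(cfg.decoy_fraction * cfg.n_genes))
    decoy_slots = set(rng.choice(cfg.n_genes, size=n_decoys, replace=False).tolist())

    genes: list[GeneRecord] = []
    base = 20_000
    for i in range(cfg.n_genes + cfg.n_noncoding):
        slot_start = base + i * cfg.gene_slot
        is_noncoding = i >= cfg.n_genes
        is_decoy = (i in decoy_slots) and not is_noncoding
        lo, hi = cfg.decoy_length_range if is_decoy else cfg.gene_length_range
        length = int(rng.integers(lo, hi + 1))
        start = slot_start + int(rng.integers(0, 2_000))
        end = start + length
        strand = "+" if rng.random() < 0.5 else "-"
        tss, tts = (start, end) if strand == "+" else (end, start)
        if is_noncoding:
            gid, biotype = f"ng{i - cfg.n_genes:05d}", "noncoding"
        else:
            gid, biotype = f"g{i:05d}", "coding"
        genes.append(GeneRecord(gid, cfg.chrom, strand, tss, tts, biotype))

    enhancers: list[EnhancerRecord] = []
    enh_base = base + (cfg.n_genes + cfg.n_noncoding) * cfg.gene_slot + 10_000
    for j in range(cfg.n_enhancers):
        width = int(rng.integers(*cfg.enhancer_width_range))
        start = enh_base + j * cfg.gene_slot + int(rng.integers(0, 2_000))
        enhancers.append(EnhancerRecord(cfg.chrom, start, start + width, f"e{j:05d}"))
    return genes, enhancers


def _modelable_anchors(cfg: SimConfig, genes: Sequence[GeneRecord]) -> list[Anchor]:
    kept = filter_genes(genes, min_length=4000)
    sizes = {cfg.chrom: cfg.resolved_chrom_length()}
    return anchors_from_genes(kept, chrom_sizes=sizes, scheme=cfg.scheme())


# ---------------------------------------------------------------------------
# latent structure


def _full_bins(cfg: SimConfig) -> list[int]:
    return bin_indices(cfg.scheme())


def _bin_positions(cfg: SimConfig, bins: Sequence[int] | None) -> tuple[list[int], np.ndarray]:
    full = _full_bins(cfg)
    if bins is None:
        return full, np.arange(len(full))
    pos_of = {b: i for i, b in enumerate(full)}
    sel = [int(b) for b in bins]
    for b in sel:
        if b not in pos_of:
            raise ValueError(f"bin index {b} outside the scheme")
    return sel, np.asarray([pos_of[b] for b in sel])


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _simulate_ideal(cfg: SimConfig, n_anchors: int, cell: int, seed: int) -> np.ndarray:
    """Noiseless feature levels for every bin: (n_anchors, p, n_full_bins).

    Histone levels are log-normal around a per-(feature, bin) baseline; the
    methylation column is a logistic transform of its latent, so it lives in
    [0, 1] like a real methylation level.  Drawn over the full bin range so
    a later bin subset never changes the values of the bins it keeps.
    """
    nb = len(_full_bins(cfg))
    ideal = np.empty((n_anchors, cfg.n_features, nb))
    for fi, fname in enumerate(cfg.feature_names):
        # Baselines are a property of the (feature, bin) position and are
        # shared by all cell lines; only the anchor-level variation is
        # cell-line-specific.  Matched-weight cell lines are therefore
        # statistically exchangeable.
        mu = child_rng(seed, "mu", fname).normal(0.0, cfg.mu_sd, size=nb)
        eps = child_rng(seed, "latents", cell, fname).normal(
            0.0, cfg.latent_sd, size=(n_anchors, nb)
        )
        if fname == METHYLATION_FEATURE:
            ideal[:, fi, :] = _logistic(mu + 1.5 * eps)
        else:
            ideal[:, fi, :] = np.exp(mu + eps)
    return ideal


def _build_weights(cfg: SimConfig, seed: int) -> np.ndarray:
    """(n_cell_lines, n_full_bins, p) weights over standardized latents."""
    full = np.asarray(_full_bins(cfg))
    nb, p = full.size, cfg.n_features
    amp = cfg.signal_sd(full)  # (nb,)
    informative = [cfg.feature_names.index(f) for f in cfg.informative_features]

    W = np.zeros((cfg.n_cell_lines, nb, p))
    for c in range(cfg.n_cell_lines):
        if c == 0 or cfg.share_weights:
            direction = np.asarray(cfg.weight_pattern, dtype=float)
        else:
            rng = child_rng(seed, "weights", c)
            direction = rng.normal(size=len(informative))
        norm = np.linalg.norm(direction)
        direction = direction / norm if norm > 0 else np.zeros_like(direction)
        for k, fi in enumerate(informative):
            W[c, :, fi] = amp * direction[k]
    return W


def _apply_link(cfg: SimConfig, z: np.ndarray, w_bin: np.ndarray) -> np.ndarray:
    """link(s) for one bin: z is (n, p), w_bin is (p,)."""
    norm = float(np.linalg.norm(w_bin))
    if norm == 0:
        return np.zeros(z.shape[0])
    s = z @ w_bin
    if cfg.link == "linear":
        return s
    if cfg.link == "saturating":
        return norm * np.tanh(s / norm)
    # multiplicative: product of the two half-sums of the weighted features,
    # rescaled to the same amplitude; linearly invisible, tree-recoverable.
    active = np.flatnonzero(w_bin)
    half = active[: max(1, active.size // 2)]
    other = active[max(1, active.size // 2):]
    s1 = z[:, half] @ w_bin[half]
    s2 = z[:, other] @ w_bin[other] if other.size else np.ones(z.shape[0])
    g = s1 * s2
    sd = g.std()
    return norm * (g - g.mean()) / sd if sd > 0 else np.zeros_like(g)


def _zscore(a: np.ndarray, axis: int = 0) -> np.ndarray:
    sd = a.std(axis=axis, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    return (a - a.mean(axis=axis, keepdims=True)) / sd


def _simulate_truth(cfg: SimConfig, n_anchors: int, anchor_ids: list[str], seed: int) -> GroundTruth:
    full = _full_bins(cfg)
    nb, p, C = len(full), cfg.n_features, cfg.n_cell_lines
    W = _build_weights(cfg, seed)
    ideal = np.empty((C, n_anchors, p, nb))
    signal = np.empty((C, n_anchors, nb))
    y_star = np.empty((C, n_anchors, nb))
    latent_pcc = np.empty((C, nb))
    for c in range(C):
        ideal[c] = _simulate_ideal(cfg, n_anchors, c, seed)
        noise = child_rng(seed, "noise", c).normal(0.0, cfg.noise_sd, size=(n_anchors, nb))
        for bi in range(nb):
            z = _zscore(ideal[c, :, :, bi])
            g = _apply_link(cfg, z, W[c, bi])
            signal[c, :, bi] = g
            y_star[c, :, bi] = g + noise[:, bi]
            gs, ys = g.std(), y_star[c, :, bi].std()
            latent_pcc[c, bi] = (
                float(np.corrcoef(g, y_star[c, :, bi])[0, 1]) if gs > 0 and ys > 0 else 0.0
            )
    return GroundTruth(list(cfg.feature_names), list(full), W, ideal, signal, y_star,
                       latent_pcc, anchor_ids)


# ---------------------------------------------------------------------------
# read-level emulation


def _window_starts(cfg: SimConfig, anchors: Sequence[Anchor], bins: Sequence[int]) -> np.ndarray:
    """Genomic start of each (anchor, bin) window, strand-aware: (n, nb_sel)."""
    scheme = cfg.scheme()
    out = np.empty((len(anchors), len(bins)), dtype=np.int64)
    for ai, a in enumerate(anchors):
        by_idx = {w.bin_index: w.start for w in make_bin_windows(a.chrom, a.pos, a.strand, scheme)}
        out[ai] = [by_idx[b] for b in bins]
    return out


def _draw_reads(cfg: SimConfig, rng: np.random.Generator, counts: np.ndarray,
                win_starts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    scheme = cfg.scheme()
    flat = counts.ravel()
    anchors_rep = np.repeat(win_starts.ravel(), flat)
    if cfg.cross_bin_reads:
        off = rng.integers(1 - cfg.read_length, scheme.bin_size, size=anchors_rep.size)
    else:
        off = rng.integers(0, scheme.bin_size - cfg.read_length + 1, size=anchors_rep.size)
    starts = np.maximum(anchors_rep + off, 0)
    return starts, starts + cfg.read_length


def simulate_feature_tracks(
    cfg: SimConfig,
    anchors: Sequence[Anchor],
    truth: GroundTruth,
    cell: int = 0,
    bins: Sequence[int] | None = None,
    master_seed: int | None = None,
) -> list[ReadSet]:
    """Per-feature, per-replicate read sets for the histone panel.

    Bin read counts are Poisson with mean L * read_depth; reads are placed
    uniformly within their bin (default: fully inside).  library_size is the
    total number of reads drawn for the replicate.
    """
    seed = cfg.master_seed if master_seed is None else master_seed
    sel, sel_pos = _bin_positions(cfg, bins)
    win_starts = _window_starts(cfg, anchors, sel)
    tracks: list[ReadSet] = []
    for fi, fname in enumerate(cfg.feature_names):
        if fname == METHYLATION_FEATURE:
            continue
        lam = truth.ideal[cell, :, fi, :][:, sel_pos] * cfg.read_depth
        for rep in range(1, cfg.n_replicates + 1):
            rng = child_rng(seed, "tracks", cell, fname, rep)
            counts = rng.poisson(lam)
            starts, ends = _draw_reads(cfg, rng, counts, win_starts)
            tracks.append(ReadSet(
                {cfg.chrom: (starts, ends)},
                experiment_id=f"cell{cell}_{fname}_rep{rep}",
                feature_name=fname, cell_line=f"cell{cell}", replicate=rep,
            ))
    return tracks


def simulate_tf_track(
    cfg: SimConfig,
    anchors: Sequence[Anchor],
    truth: GroundTruth,
    cell: int = 0,
    bins: Sequence[int] | None = None,
    master_seed: int | None = None,
    tf_name: str = "TF",
) -> list[ReadSet]:
    """TF read track whose log2(RPM + 1) is a noisy monotone image of y*.

    The Poisson rate is tf_depth * (2^(y* - min y*) - 1): exactly zero at the
    smallest latent affinity, so read-free bins (the -1 pseudo-count path)
    occur precisely where y* is low.
    """
    seed = cfg.master_seed if master_seed is None else master_seed
    sel, sel_pos = _bin_positions(cfg, bins)
    win_starts = _window_starts(cfg, anchors, sel)
    ys = truth.y_star[cell][:, sel_pos]
    t = ys - ys.min()
    lam = cfg.tf_depth * (np.exp2(t) - 1.0)
    tracks = []
    for rep in range(1, cfg.n_replicates + 1):
        rng = child_rng(seed, "tf", cell, tf_name, rep)
        counts = rng.poisson(lam)
        starts, ends = _draw_reads(cfg, rng, counts, win_starts)
        tracks.append(ReadSet(
            {cfg.chrom: (starts, ends)},
            experiment_id=f"cell{cell}_{tf_name}_rep{rep}",
            feature_name=tf_name, cell_line=f"cell{cell}", replicate=rep,
        ))
    return tracks


def simulate_methylome(
    cfg: SimConfig,
    anchors: Sequence[Anchor],
    truth: GroundTruth,
    cell: int = 0,
    bins: Sequence[int] | None = None,
    master_seed: int | None = None,
) -> MethylationTable:
    """CpG table: Poisson site counts per bin around the density profile,
    levels jittered around the bin's latent methylation and clipped to [0, 1].
    Bins that draw zero CpGs exercise the missing-bin policy downstream."""
    seed = cfg.master_seed if master_seed is None else master_seed
    sel, sel_pos = _bin_positions(cfg, bins)
    win_starts = _window_starts(cfg, anchors, sel)
    fi = list(cfg.feature_names).index(METHYLATION_FEATURE)
    latent = truth.ideal[cell, :, fi, :][:, sel_pos]
    rng = child_rng(seed, "methylome", cell)
    density = cfg.cpg_density(np.asarray(sel))
    counts = rng.poisson(np.broadcast_to(density, latent.shape))
    flat = counts.ravel()
    pos_base = np.repeat(win_starts.ravel(), flat)
    offsets = rng.integers(0, cfg.scheme().bin_size, size=pos_base.size)
    levels = np.repeat(latent.ravel(), flat) + rng.normal(0, cfg.cpg_level_noise, size=pos_base.size)
    levels = np.clip(levels, 0.0, 1.0)
    positions = pos_base + offsets
    return MethylationTable(
        (cfg.chrom, int(p), float(l)) for p, l in zip(positions, levels)
    )


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class SyntheticDataset:
    cfg: SimConfig
    genes: list[GeneRecord]
    enhancers: list[EnhancerRecord]
    anchors: list[Anchor]
    truth: GroundTruth
    bins: list[int]
    feature_tracks: dict[int, list[ReadSet]] = field(default_factory=dict)  # cell -> tracks
    tf_tracks: dict[int, list[ReadSet]] = field(default_factory=dict)
    methylomes: dict[int, MethylationTable] = field(default_factory=dict)

    @property
    def enhancer_anchors(self) -> list[Anchor]:
        sizes = {self.cfg.chrom: self.cfg.resolved_chrom_length()}
        return anchors_from_enhancers(self.enhancers, chrom_sizes=sizes, scheme=self.cfg.scheme())


def simulate_dataset(
    cfg: SimConfig,
    master_seed: int | None = None,
    bins: Sequence[int] | None = None,
    cell_lines: Sequence[int] | None = None,
) -> SyntheticDataset:
    """Full read-level dataset: annotation, tracks, TF and methylome per cell."""
    seed = cfg.master_seed if master_seed is None else master_seed
    genes, enhancers = simulate_annotation(cfg, seed)
    anchors = _modelable_anchors(cfg, genes)
    truth = _simulate_truth(cfg, len(anchors), [a.anchor_id for a in anchors], seed)
    sel, _ = _bin_positions(cfg, bins)
    ds = SyntheticDataset(cfg, genes, enhancers, anchors, truth, sel)
    for c in cell_lines if cell_lines is not None else range(cfg.n_cell_lines):
        ds.feature_tracks[c] = simulate_feature_tracks(cfg, anchors, truth, c, sel, seed)
        ds.tf_tracks[c] = simulate_tf_track(cfg, anchors, truth, c, sel, seed)
        ds.methylomes[c] = simulate_methylome(cfg, anchors, truth, c, sel, seed)
    return ds


def latent_bin_matrices(
    cfg: SimConfig,
    master_seed: int | None = None,
    bins: Sequence[int] | None = None,
    cell: int = 0,
    n_anchors: int | None = None,
) -> tuple[dict[int, BinFeatureMatrix], GroundTruth]:
    """Design matrices straight from the latent layer (no read emulation).

    X holds the noiseless feature levels and y the latent affinity y*; this
    isolates the statistical behaviour of the models from sequencing noise
    and is the fast path for model-level experiments.
    """
    seed = cfg.master_seed if master_seed is None else master_seed
    if n_anchors is None:
        n_decoys = int(round(cfg.decoy_fraction * cfg.n_genes))
        n_anchors = cfg.n_genes - n_decoys + cfg.n_noncoding
    ids = [f"a{i:05d}" for i in range(n_anchors)]
    truth = _simulate_truth(cfg, n_anchors, ids, seed)
    sel, sel_pos = _bin_positions(cfg, bins)
    matrices = {}
    for b, bp in zip(sel, sel_pos):
        matrices[b] = BinFeatureMatrix(
            b, list(ids), list(cfg.feature_names),
            truth.ideal[cell, :, :, bp], truth.y_star[cell, :, bp],
        )
    return matrices, truth


# ---------------------------------------------------------------------------
# file emission


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> dict:
    """Emit the exact text formats the readers consume, plus a manifest and
    a ground-truth JSON; returns the manifest mapping."""
    import yaml

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = ds.cfg

    with open(outdir / "genes.refflat", "w") as fh:
        for g in ds.genes:
            tx_start, tx_end = min(g.tss, g.tts), max(g.tss, g.tts)
            fh.write(
                f"{g.gene_id}\t{g.gene_id}\t{g.chrom}\t{g.strand}\t{tx_start}\t{tx_end}"
                f"\t{tx_start}\t{tx_end}\t1\t{tx_start},\t{tx_end},\t{g.biotype}\n"
            )
    with open(outdir / "enhancers.bed", "w") as fh:
        for e in ds.enhancers:
            fh.write(f"{e.chrom}\t{e.start}\t{e.end}\t{e.enhancer_id}\n")
    with open(outdir / "chrom.sizes", "w") as fh:
        fh.write(f"{cfg.chrom}\t{cfg.resolved_chrom_length()}\n")

    manifest: dict = {"cell_lines": {}, "bins": ds.bins,
                      "annotation": "genes.refflat", "enhancers": "enhancers.bed",
                      "chrom_sizes": "chrom.sizes"}
    for c in ds.feature_tracks:
        cell_dir = outdir / f"cell{c}"
        cell_dir.mkdir(exist_ok=True)
        entries = []
        for track in ds.feature_tracks[c] + ds.tf_tracks[c]:
            fname = f"{track.experiment_id}.bed"
            with open(cell_dir / fname, "w") as fh:
                starts, ends = track._by_chrom.get(cfg.chrom, (np.empty(0, int), np.empty(0, int)))
                for s, e in zip(starts, ends):
                    fh.write(f"{cfg.chrom}\t{s}\t{e}\n")
            entries.append({
                "experiment_id": track.experiment_id,
                "feature": track.feature_name,
                "replicate": track.replicate,
                "file": f"cell{c}/{fname}",
                "library_size": track.library_size,
                "role": "tf" if track in ds.tf_tracks[c] else "feature",
            })
        meth_file = f"cell{c}/methylation.tsv"
        with open(outdir / meth_file, "w") as fh:
            table = ds.methylomes[c]
            pos, lvl = table._by_chrom.get(cfg.chrom, (np.empty(0, int), np.empty(0)))
            for p_, l_ in zip(pos, lvl):
                fh.write(f"{cfg.chrom}\t{p_}\t{l_:.6f}\n")
        manifest["cell_lines"][f"cell{c}"] = {"tracks": entries, "methylation": meth_file}

    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    truth_payload = {
        "feature_names": ds.truth.feature_names,
        "bins": ds.truth.bins,
        "weights": ds.truth.weights.tolist(),
        "latent_pcc": ds.truth.latent_pcc.tolist(),
    }
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(truth_payload, fh)
    return manifest
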