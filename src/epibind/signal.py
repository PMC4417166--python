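"""Per-bin signal quantification.

Turns aligned-read sets (or per-base coverage tracks) and CpG methylation
tables into the per-bin quantities the models consume:

* histone marks / variants — per-base read coverage averaged over the bin,
  scaled to reads per million (RPM) using the experiment-wide library size,
  then averaged across replicates; no log transform,
* DNA methylation — the mean level of the CpGs mapping into the bin,
* the TF target — log2(RPM + 1) of the TF ChIP coverage, with the sentinel
  pseudo-count -1 for bins where no TF read maps at all, keeping truly
  read-free bins distinct from low-but-nonzero signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .anchors import Anchor, BinScheme, BinWindow, make_bin_windows, bin_indices

__all__ = [
    "DEFAULT_FEATURES",
    "METHYLATION_FEATURE",
    "ReadSet",
    "CoverageTrack",
    "MethylationTable",
    "BinFeatureMatrix",
    "per_base_coverage",
    "bin_mean",
    "rpm",
    "combine_replicates",
    "tf_binding_affinity",
    "bin_methylation_level",
    "build_bin_feature_matrices",
    "read_bed_reads",
]

METHYLATION_FEATURE = "DNAmeth"

# Canonical 12-feature panel: 11 histone marks/variants plus DNA methylation.
DEFAULT_FEATURES = (
    "H2az",
    "H3K4me1",
    "H3K4me2",
    "H3K4me3",
    "H3K9ac",
    "H3K9me3",
    "H3K27ac",
    "H3K27me3",
    "H3K36me3",
    "H3K79me2",
    "H4K20me1",
    METHYLATION_FEATURE,
)

PSEUDO_COUNT = -1.0


# ---------------------------------------------------------------------------
# read containers


class ReadSet:
    """Aligned reads of one sequencing experiment replicate.

    Reads are stored per chromosome as parallel ``starts``/``ends`` arrays
    sorted by start, which makes window queries a pair of binary searches.
    ``library_size`` is the experiment-wide total of mapped reads (never
    recomputed from a query window); it defaults to the number of stored
    reads when the read set is genome-complete, as with simulated data.
    """

    def __init__(
        self,
        reads: Iterable[tuple[str, int, int]] | Mapping[str, tuple[np.ndarray, np.ndarray]],
        experiment_id: str = "",
        feature_name: str = "",
        cell_line: str = "",
        replicate: int = 1,
        library_size: int | None = None,
    ):
        self.experiment_id = experiment_id
        self.feature_name = feature_name
        self.cell_line = cell_line
        self.replicate = replicate
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        self._max_len: dict[str, int] = {}
        n_total = 0
        if isinstance(reads, Mapping):
            items = {c: (np.asarray(s, dtype=np.int64), np.asarray(e, dtype=np.int64))
                     for c, (s, e) in reads.items()}
        else:
            tmp: dict[str, list[tuple[int, int]]] = {}
            for chrom, start, end in reads:
                tmp.setdefault(chrom, []).append((int(start), int(end)))
            items = {}
            for chrom, ivals in tmp.items():
                arr = np.asarray(ivals, dtype=np.int64).reshape(-1, 2)
                items[chrom] = (arr[:, 0], arr[:, 1])
        for chrom, (starts, ends) in items.items():
            if starts.size == 0:
                continue
            if np.any(ends <= starts):
                raise ValueError(f"{experiment_id}: read with end <= start on {chrom}")
            order = np.argsort(starts, kind="stable")
            starts, ends = starts[order], ends[order]
            self._by_chrom[chrom] = (starts, ends)
            self._max_len[chrom] = int(np.max(ends - starts))
            n_total += starts.size
        self.n_reads = n_total
        self.library_size = int(library_size) if library_size is not None else n_total
        if self.library_size < 0:
            raise ValueError("library_size must be >= 0")

    def overlapping(self, chrom: str, start: int, end: int) -> tuple[np.ndarray, np.ndarray]:
        """Clipped candidate reads intersecting [start, end) on chrom."""
        if chrom not in self._by_chrom:
            empty = np.empty(0, dtype=np.int64)
            return empty, empty
        starts, ends = self._by_chrom[chrom]
        lo = np.searchsorted(starts, start - self._max_len[chrom], side="left")
        hi = np.searchsorted(starts, end, side="left")
        s, e = starts[lo:hi], ends[lo:hi]
        keep = e > start
        return s[keep], e[keep]

    def window_profile(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base coverage over [start, end): counts of reads covering each base."""
        width = end - start
        s, e = self.overlapping(chrom, start, end)
        diff = np.zeros(width + 1, dtype=np.int64)
        if s.size:
            np.add.at(diff, np.clip(s - start, 0, width), 1)
            np.add.at(diff, np.clip(e - start, 0, width), -1)
        return np.cumsum(diff[:-1])


class CoverageTrack:
    """Precomputed per-base coverage (bedGraph-style), with a manifest-supplied
    library size since it cannot be counted from the track itself."""

    def __init__(
        self,
        intervals: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
        library_size: int,
        experiment_id: str = "",
        feature_name: str = "",
        cell_line: str = "",
        replicate: int = 1,
    ):
        if library_size <= 0:
            raise ValueError("library_size must be positive for coverage tracks")
        self.experiment_id = experiment_id
        self.feature_name = feature_name
        self.cell_line = cell_line
        self.replicate = replicate
        self.library_size = int(library_size)
        self._by_chrom = {
            c: (np.asarray(s, dtype=np.int64), np.asarray(e, dtype=np.int64),
                np.asarray(v, dtype=float))
            for c, (s, e, v) in intervals.items()
        }

    @classmethod
    def from_bedgraph(cls, path: str | Path, library_size: int, **meta) -> "CoverageTrack":
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                chrom, start, end, value = line.split("\t")[:4]
                by_chrom.setdefault(chrom, []).append((int(start), int(end), float(value)))
        arrays = {}
        for chrom, rows in by_chrom.items():
            rows.sort()
            arr = np.asarray(rows)
            arrays[chrom] = (arr[:, 0].astype(np.int64), arr[:, 1].astype(np.int64), arr[:, 2])
        return cls(arrays, library_size=library_size, **meta)

    def window_profile(self, chrom: str, start: int, end: int) -> np.ndarray:
        width = end - start
        out = np.zeros(width, dtype=float)
        if chrom not in self._by_chrom:
            return out
        starts, ends, values = self._by_chrom[chrom]
        lo = np.searchsorted(ends, start, side="right")
        hi = np.searchsorted(starts, end, side="left")
        for s, e, v in zip(starts[lo:hi], ends[lo:hi], values[lo:hi]):
            a, b = max(s, start), min(e, end)
            if a < b:
                out[a - start : b - start] += v
        return out


class MethylationTable:
    """CpG methylation levels: per-chromosome sorted positions with levels in [0, 1].

    Duplicated positions (e.g. the two strands of one CpG, or assay overlap)
    are averaged at load time so positions are unique per chromosome.
    """

    def __init__(self, records: Iterable[tuple[str, int, float]]):
        tmp: dict[str, list[tuple[int, float]]] = {}
        for chrom, pos, level in records:
            if not 0.0 <= level <= 1.0:
                raise ValueError(f"methylation level {level} at {chrom}:{pos} outside [0, 1]")
            tmp.setdefault(chrom, []).append((int(pos), float(level)))
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        n = 0
        for chrom, rows in tmp.items():
            arr = np.asarray(sorted(rows), dtype=float)
            pos = arr[:, 0].astype(np.int64)
            lvl = arr[:, 1]
            uniq, inverse, counts = np.unique(pos, return_inverse=True, return_counts=True)
            if uniq.size < pos.size:
                sums = np.zeros(uniq.size)
                np.add.at(sums, inverse, lvl)
                lvl = sums / counts
                pos = uniq
            self._by_chrom[chrom] = (pos, lvl)
            n += pos.size
        self.n_sites = n

    @classmethod
    def from_file(cls, path: str | Path) -> "MethylationTable":
        """3-column text (chrom, 0-based position, level) or bedGraph dialect
        (chrom, start, end, level; the start is taken as the CpG position)."""
        records = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith(("#", "track")):
                    continue
                fields = line.split("\t")
                try:
                    if len(fields) >= 4:
                        records.append((fields[0], int(fields[1]), float(fields[3])))
                    elif len(fields) == 3:
                        records.append((fields[0], int(fields[1]), float(fields[2])))
                    else:
                        raise ValueError("expected 3 or 4 columns")
                except ValueError as exc:
                    raise ValueError(f"{path} line {lineno}: {exc}") from exc
        return cls(records)

    def levels_in(self, chrom: str, start: int, end: int) -> np.ndarray:
        if chrom not in self._by_chrom:
            return np.empty(0)
        pos, lvl = self._by_chrom[chrom]
        lo = np.searchsorted(pos, start, side="left")
        hi = np.searchsorted(pos, end, side="left")
        return lvl[lo:hi]


# ---------------------------------------------------------------------------
# elementary operations


def per_base_coverage(reads: ReadSet, window: BinWindow) -> np.ndarray:
    """Number of reads covering each base of the window."""
    return reads.window_profile(window.chrom, window.start, window.end)


def bin_mean(coverage: Sequence[float], bin_size: int = 100) -> float:
    """Arithmetic mean of the per-base coverages of one bin."""
    cov = np.asarray(coverage, dtype=float)
    if cov.shape != (bin_size,):
        raise ValueError(f"expected a length-{bin_size} coverage vector, got shape {cov.shape}")
    return float(cov.mean())


def rpm(value: float, library_size: int) -> float:
    """Reads-per-million scaling: value * 1e6 / library_size."""
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    return value * 1e6 / library_size


def combine_replicates(values: Sequence[float]) -> float:
    """Average the per-replicate (already RPM-scaled) values."""
    if len(values) == 0:
        raise ValueError("no replicate values to combine")
    return float(np.mean(values))


def tf_binding_affinity(bin_read_overlap: int, bin_rpm: float) -> float:
    """log2(RPM + 1) of TF coverage, or the -1 pseudo-count for read-free bins.

    The pseudo-count is strictly below log2(RPM + 1) >= 0 of every bin with
    at least one read, so read-free bins stay separable from low-coverage ones.
    """
    if bin_rpm < 0:
        raise ValueError("rpm must be >= 0")
    if bin_read_overlap < 0:
        raise ValueError("read overlap count must be >= 0")
    if bin_read_overlap == 0:
        return PSEUDO_COUNT
    return float(np.log2(bin_rpm + 1.0))


def bin_methylation_level(
    table: MethylationTable,
    window: BinWindow,
    policy: str = "zero_fill",
) -> tuple[float, bool]:
    """Mean level of CpGs falling in [start, end); CpG-free bins are missing.

    Under ``zero_fill`` a missing bin reports 0.0 (and is flagged); under
    ``mask_only`` it reports NaN for the caller to resolve.
    """
    if policy not in ("zero_fill", "mask_only"):
        raise ValueError(f"unknown policy {policy!r}")
    levels = table.levels_in(window.chrom, window.start, window.end)
    if levels.size == 0:
        return (0.0 if policy == "zero_fill" else float("nan")), True
    return float(levels.mean()), False


# ---------------------------------------------------------------------------
# matrix assembly


@dataclass
class BinFeatureMatrix:
    """Anchors x features design matrix for one bin, plus the TF target.

    ``missing_mask`` records entries resolved by the missingness policy
    (currently CpG-free methylation bins); X itself is always complete.
    """

    bin_index: int
    anchor_ids: list[str]
    feature_names: list[str]
    X: np.ndarray
    y: np.ndarray
    missing_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.missing_mask is None:
            self.missing_mask = np.zeros(self.X.shape, dtype=bool)
        n, p = self.X.shape
        if len(self.anchor_ids) != n or self.y.shape != (n,):
            raise ValueError("anchor_ids, X rows and y must agree")
        if len(self.feature_names) != p:
            raise ValueError("feature_names must match X columns")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("X contains undefined values")

    @property
    def n_anchors(self) -> int:
        return self.X.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, index=self.anchor_ids, columns=self.feature_names)
        df.index.name = "anchor_id"
        df["tf_affinity"] = self.y
        return df

    def subset(self, row_idx: np.ndarray) -> "BinFeatureMatrix":
        return BinFeatureMatrix(
            self.bin_index,
            [self.anchor_ids[i] for i in row_idx],
            list(self.feature_names),
            self.X[row_idx],
            self.y[row_idx],
            self.missing_mask[row_idx],
        )


def _group_tracks(tracks: Sequence[ReadSet | CoverageTrack]) -> dict[str, list]:
    groups: dict[str, list] = {}
    for t in tracks:
        groups.setdefault(t.feature_name, []).append(t)
    return groups


def build_bin_feature_matrices(
    anchors: Sequence[Anchor],
    feature_tracks: Sequence[ReadSet | CoverageTrack],
    methylation: MethylationTable | None,
    tf_tracks: Sequence[ReadSet | CoverageTrack],
    scheme: BinScheme = BinScheme(),
    feature_names: Sequence[str] = DEFAULT_FEATURES,
    methylation_policy: str = "zero_fill",
) -> list[BinFeatureMatrix]:
    """Assemble one complete design matrix per bin, in canonical bin order.

    Histone columns hold replicate-averaged RPM of mean bin coverage; the
    methylation column holds mean CpG level under the missingness policy;
    the target y applies log2(RPM + 1) with the -1 pseudo-count evaluated on
    the replicate-pooled TF coverage.  Deterministic given inputs, and
    invariant to replicate file order (replicates enter through a mean).
    """
    feature_names = list(feature_names)
    groups = _group_tracks(feature_tracks)
    for name in feature_names:
        if name == METHYLATION_FEATURE:
            if methylation is None:
                raise ValueError(f"feature {name!r} requested but no methylation table given")
            continue
        if name not in groups or not groups[name]:
            raise ValueError(f"feature {name!r} configured but absent from the supplied tracks")
    if not tf_tracks:
        raise ValueError("at least one TF track is required")

    idx_order = bin_indices(scheme)
    pos_of = {b: i for i, b in enumerate(idx_order)}
    n, p, nb = len(anchors), len(feature_names), scheme.n_bins
    B = scheme.bin_size

    X = np.zeros((nb, n, p))
    y = np.zeros((nb, n))
    missing = np.zeros((nb, n, p), dtype=bool)

    for ai, anchor in enumerate(anchors):
        windows = make_bin_windows(anchor.chrom, anchor.pos, anchor.strand, scheme)
        span_start = anchor.pos - scheme.half_span
        span_end = anchor.pos + scheme.half_span

        for fi, fname in enumerate(feature_names):
            if fname == METHYLATION_FEATURE:
                for w in windows:
                    val, is_missing = bin_methylation_level(methylation, w, methylation_policy)
                    bi = pos_of[w.bin_index]
                    X[bi, ai, fi] = 0.0 if (is_missing and np.isnan(val)) else val
                    missing[bi, ai, fi] = is_missing
                continue
            reps = groups[fname]
            acc = np.zeros(nb)
            for track in reps:
                profile = track.window_profile(anchor.chrom, span_start, span_end)
                for w in windows:
                    off = w.start - span_start
                    acc[pos_of[w.bin_index]] += rpm(
                        float(profile[off : off + B].mean()), track.library_size
                    )
            X[:, ai, fi] = acc / len(reps)

        # TF target: replicate-mean RPM, zero-read rule on pooled coverage.
        rpm_acc = np.zeros(nb)
        pooled = np.zeros(nb)
        for track in tf_tracks:
            profile = track.window_profile(anchor.chrom, span_start, span_end)
            for w in windows:
                off = w.start - span_start
                seg = profile[off : off + B]
                bi = pos_of[w.bin_index]
                rpm_acc[bi] += rpm(float(seg.mean()), track.library_size)
                pooled[bi] += float(seg.sum())
        mean_rpm = rpm_acc / len(tf_tracks)
        for bi in range(nb):
            y[bi, ai] = PSEUDO_COUNT if pooled[bi] == 0 else float(np.log2(mean_rpm[bi] + 1.0))

    anchor_ids = [a.anchor_id for a in anchors]
    return [
        BinFeatureMatrix(b, list(anchor_ids), list(feature_names),
                         X[pos_of[b]], y[pos_of[b]], missing[pos_of[b]])
        for b in idx_order
    ]


def read_bed_reads(
    path: str | Path,
    experiment_id: str = "",
    feature_name: str = "",
    cell_line: str = "",
    replicate: int = 1,
    library_size: int | None = None,
) -> ReadSet:
    """Load aligned reads from a BED3+ file into a :class:`ReadSet`."""
    reads = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path} line {lineno}: expected >= 3 BED columns")
            try:
                reads.append((fields[0], int(fields[1]), int(fields[2])))
            except ValueError as exc:
                raise ValueError(f"{path} line {lineno}: non-numeric coordinates") from exc
    return ReadSet(
        reads,
        experiment_id=experiment_id,
        feature_name=feature_name,
        cell_line=cell_line,
        replicate=replicate,
        library_size=library_size,
    )
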