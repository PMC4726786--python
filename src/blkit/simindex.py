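"""All-pairs Pearson similarity index with sparse significance spans.

For each window duration, every pair of window feature vectors (length n =
channel count) is compared by Pearson correlation. A pair is *significant* —
and enters the index — iff r > 0 and the two-tailed p-value from the Student
t transform, t = r * sqrt((n-2) / (1-r^2)) with n-2 degrees of freedom, is at
most alpha (0.05 by default, no multiple-testing correction). Negative
correlations are never stored.

Storage exploits temporal clustering: per query window, the significant
target windows are encoded as maximal runs of consecutive indices, each run a
(start index, p-value list) pair — two aligned lists. A fully adversarial
alternating pattern degrades to one run per significant singleton, so the
index grows linearly in the number of significant pairs in the worst case;
block-structured task activity compresses to one run per block.

Rows are stored for both directions of each unordered pair, buying O(1)
row lookup at query time for double the space. The self pair (r = 1, p = 0)
is stored and returned by default — the query window appears among its own
results — and can be dropped with ``include_self=False``.

A query is (start time, length); its timescale is the largest indexed
duration not exceeding the query length (a 600 ms query resolves to the
500 ms scale), clamping to the smallest duration for shorter queries, and its
row is the grid window containing the start time.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
from scipy import stats

from .features import FeatureMatrix, WindowGrid

__all__ = [
    "CorrelationStat",
    "Run",
    "SparseSpanIndex",
    "Query",
    "SearchResult",
    "pearson_r",
    "r_pvalue",
    "correlation_matrix",
    "build_index",
    "select_timescale",
    "query",
    "save_index",
    "load_index",
    "file_sha256",
]

DEFAULT_ALPHA = 0.05

#: returned by pearson_r when a vector is constant: no similarity defined.
NO_SIMILARITY = float("nan")


@dataclass(frozen=True)
class CorrelationStat:
    """A correlation with its two-tailed significance."""

    r: float
    p: float
    df: int


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson product-moment correlation, clipped to [-1, 1].

    Returns the NaN "no similarity" sentinel (treated as not significant
    everywhere downstream) when either vector is constant.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two equal-length 1-d vectors of length >= 3")
    xd = x - x.mean()
    yd = y - y.mean()
    denom = np.sqrt(np.sum(xd**2) * np.sum(yd**2))
    if denom == 0:
        return NO_SIMILARITY
    return float(np.clip(np.dot(xd, yd) / denom, -1.0, 1.0))


def r_pvalue(r: float, n: int) -> float:
    """Two-tailed p-value for a Pearson correlation from *n* paired samples.

    Uses the exact-under-normality t transform with n-2 degrees of freedom;
    r = +/-1 maps to p = 0, the NaN sentinel to p = 1.
    """
    if n < 3:
        raise ValueError("need n >= 3 samples")
    if np.isnan(r):
        return 1.0
    if abs(r) > 1:
        raise ValueError(f"|r| must be <= 1, got {r}")
    if abs(r) == 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def correlation_matrix(features: np.ndarray) -> np.ndarray:
    """All-pairs Pearson correlations between rows of a windows x channels matrix.

    Symmetric with unit diagonal; rows with zero variance (constant feature
    vectors) get the NaN sentinel in every entry including the diagonal.
    """
    f = np.asarray(features, dtype=np.float64)
    centered = f - f.mean(axis=1, keepdims=True)
    norms = np.sqrt(np.sum(centered**2, axis=1))
    ok = norms > 0
    safe = np.where(ok, norms, 1.0)
    unit = centered / safe[:, None]
    r = np.clip(unit @ unit.T, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    r[~ok, :] = NO_SIMILARITY
    r[:, ~ok] = NO_SIMILARITY
    return r


def pvalue_matrix(r: np.ndarray, n: int) -> np.ndarray:
    """Elementwise two-tailed p-values for a correlation matrix (n samples)."""
    if n < 3:
        raise ValueError("need n >= 3 samples")
    r = np.asarray(r, dtype=np.float64)
    p = np.ones_like(r)
    finite = np.isfinite(r)
    exact = finite & (np.abs(r) == 1.0)
    mid = finite & ~exact
    t = r[mid] * np.sqrt((n - 2) / (1.0 - r[mid] ** 2))
    p[mid] = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[exact] = 0.0
    return p


@dataclass(frozen=True)
class Run:
    """One maximal block of consecutive significant target windows."""

    start: int
    pvalues: np.ndarray  # one per consecutive window from `start`

    @property
    def length(self) -> int:
        return len(self.pvalues)


@dataclass
class SparseSpanIndex:
    """Per-duration, per-query-window runs of significant positive correlations."""

    alpha: float
    n_channels: int
    include_self: bool
    rows: dict[float, list[list[Run]]] = field(default_factory=dict)
    grids: dict[float, WindowGrid] = field(default_factory=dict)
    r_matrices: dict[float, np.ndarray] = field(default_factory=dict)
    source_sha256: str | None = None

    @property
    def durations(self) -> list[float]:
        return sorted(self.rows)

    def n_entries(self, duration: float) -> int:
        return sum(run.length for row in self.rows[duration] for run in row)

    def densify(self, duration: float) -> np.ndarray:
        """Reconstruct the dense boolean significant-pair mask for one duration."""
        w = len(self.rows[duration])
        mask = np.zeros((w, w), dtype=bool)
        for i, row in enumerate(self.rows[duration]):
            for run in row:
                mask[i, run.start : run.start + run.length] = True
        return mask


def encode_runs(mask_row: np.ndarray, p_row: np.ndarray) -> list[Run]:
    """Run-length encode one row of the significance mask with its p-values."""
    (idx,) = np.nonzero(mask_row)
    runs: list[Run] = []
    if len(idx) == 0:
        return runs
    breaks = np.nonzero(np.diff(idx) > 1)[0] + 1
    for chunk in np.split(idx, breaks):
        runs.append(Run(start=int(chunk[0]), pvalues=p_row[chunk].copy()))
    return runs


def build_index(
    features: dict[float, FeatureMatrix],
    alpha: float = DEFAULT_ALPHA,
    include_self: bool = True,
    dense_r_cap: int = 2048,
) -> SparseSpanIndex:
    """Build the sparse span index over every duration's feature matrix.

    A (query, target) pair is stored iff r > 0 and p <= alpha; both
    directions of each unordered pair are stored. Feature matrices with fewer
    than 2 windows or fewer than 3 channels are skipped with a warning (the
    p-value needs n >= 3). When a duration has at most ``dense_r_cap``
    windows, its raw correlation matrix is retained on the index for
    programmatic use.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    index = SparseSpanIndex(alpha=alpha, n_channels=0, include_self=include_self)
    for duration in sorted(features):
        fm = features[duration]
        if fm.n_windows < 2 or fm.n_channels < 3:
            warnings.warn(
                f"duration {duration} s: degenerate feature matrix "
                f"({fm.n_windows} windows x {fm.n_channels} channels); skipped"
            )
            continue
        index.n_channels = fm.n_channels
        r = correlation_matrix(fm.features)
        p = pvalue_matrix(r, fm.n_channels)
        sig = np.isfinite(r) & (r > 0) & (p <= alpha)
        if not include_self:
            np.fill_diagonal(sig, False)
        index.rows[duration] = [encode_runs(sig[i], p[i]) for i in range(fm.n_windows)]
        index.grids[duration] = fm.grid
        if fm.n_windows <= dense_r_cap:
            index.r_matrices[duration] = r
    if not index.rows:
        warnings.warn("no duration produced an indexable feature matrix; empty index")
    return index


@dataclass(frozen=True)
class Query:
    """A query interval on a file's common time axis."""

    start: float
    length: float
    file_id: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError("start must be >= 0")
        if self.length <= 0:
            raise ValueError("length must be > 0")


@dataclass
class SearchResult:
    """Hits for one query: half-open window intervals with their p-values."""

    duration: float
    query_window: int
    hits: list[tuple[float, float, float]]  # (start s, end s, p), sorted


def select_timescale(query_length: float, durations: list[float]) -> float:
    """The largest indexed duration not exceeding the query length.

    A 600 ms query resolves to the 500 ms timescale under the defaults.
    Queries shorter than every duration clamp to the smallest one.
    """
    if not durations:
        raise ValueError("durations must be non-empty")
    eligible = [d for d in durations if d <= query_length + 1e-9]
    return max(eligible) if eligible else min(durations)


def query(index: SparseSpanIndex, q: Query) -> SearchResult:
    """Look up a query interval: resolve its timescale, decode its row's runs."""
    duration = select_timescale(q.length, index.durations)
    grid = index.grids[duration]
    widx = grid.window_of(q.start)
    if widx >= grid.n_windows:
        warnings.warn(
            f"query start {q.start} s lies beyond the indexed recording "
            f"({grid.n_windows} windows of {duration} s); empty result"
        )
        return SearchResult(duration=duration, query_window=widx, hits=[])
    hits: list[tuple[float, float, float]] = []
    for run in index.rows[duration][widx]:
        for j, p in enumerate(run.pvalues):
            t0 = (run.start + j) * duration
            hits.append((t0, t0 + duration, float(p)))
    hits.sort()
    return SearchResult(duration=duration, query_window=widx, hits=hits)


# ---------------------------------------------------------------------------
# HDF5 sidecar persistence: per duration, the two aligned lists of the span
# encoding (run starts + concatenated p-values) with CSR-style row pointers.


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def save_index(index: SparseSpanIndex, path) -> None:
    with h5py.File(path, "w") as h5:
        h5.attrs["alpha"] = index.alpha
        h5.attrs["nChannels"] = index.n_channels
        h5.attrs["includeSelf"] = index.include_self
        if index.source_sha256:
            h5.attrs["sourceSha256"] = index.source_sha256
        for duration in index.durations:
            rows = index.rows[duration]
            grid = index.grids[duration]
            g = h5.create_group(f"duration={duration:g}")
            g.attrs["duration"] = duration
            g.attrs["samplesPerWindow"] = grid.samples_per_window
            g.create_dataset("windowStarts", data=grid.starts)
            row_ptr = np.zeros(len(rows) + 1, dtype=np.int64)
            starts: list[int] = []
            lengths: list[int] = []
            pvals: list[np.ndarray] = []
            for i, row in enumerate(rows):
                row_ptr[i + 1] = row_ptr[i] + len(row)
                for run in row:
                    starts.append(run.start)
                    lengths.append(run.length)
                    pvals.append(run.pvalues)
            g.create_dataset("rowPtr", data=row_ptr)
            g.create_dataset("runStarts", data=np.asarray(starts, dtype=np.int64))
            g.create_dataset("runLengths", data=np.asarray(lengths, dtype=np.int64))
            g.create_dataset(
                "pValues",
                data=np.concatenate(pvals) if pvals else np.zeros(0),
            )
            if duration in index.r_matrices:
                g.create_dataset("rMatrix", data=index.r_matrices[duration])


def load_index(path) -> SparseSpanIndex:
    with h5py.File(path, "r") as h5:
        index = SparseSpanIndex(
            alpha=float(h5.attrs["alpha"]),
            n_channels=int(h5.attrs["nChannels"]),
            include_self=bool(h5.attrs["includeSelf"]),
            source_sha256=h5.attrs.get("sourceSha256"),
        )
        for name in h5:
            g = h5[name]
            duration = float(g.attrs["duration"])
            grid = WindowGrid(
                duration=duration,
                starts=g["windowStarts"][()],
                samples_per_window=int(g.attrs["samplesPerWindow"]),
            )
            row_ptr = g["rowPtr"][()]
            run_starts = g["runStarts"][()]
            run_lengths = g["runLengths"][()]
            pvals = g["pValues"][()]
            offsets = np.concatenate([[0], np.cumsum(run_lengths)])
            rows: list[list[Run]] = []
            for i in range(len(row_ptr) - 1):
                row = []
                for k in range(row_ptr[i], row_ptr[i + 1]):
                    row.append(
                        Run(
                            start=int(run_starts[k]),
                            pvalues=pvals[offsets[k] : offsets[k + 1]],
                        )
                    )
                rows.append(row)
            index.rows[duration] = rows
            index.grids[duration] = grid
            if "rMatrix" in g:
                index.r_matrices[duration] = g["rMatrix"][()]
    return index
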