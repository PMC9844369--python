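"""Recurrence quantification of joint-angle dynamics.

Three flavours are used on each block of ten movements:

* **PCA-aRQA** — auto-recurrence of the first principal-component score
  series, time-delay embedded with parameters chosen by average mutual
  information (delay) and false nearest neighbours (dimension).
* **cRQA** — cross-recurrence of the knee- and hip-flexion series, each
  scaled to [0, 1] per block.
* **mdRQA** — recurrence of the raw 7-dimensional joint state per frame
  (no additional embedding; channels z-scored).

Five measures are read off the recurrence plot: recurrence rate,
determinism, Shannon entropy (bits) of the diagonal line-length
distribution, the longest diagonal line (LMAX), and laminarity.  Line
statistics exclude the Theiler band around the line of identity for the
auto/multidimensional plots.  The recurrence radius defaults to a fixed
fraction of the maximum phase-space distance so that recurrence rate
remains a comparable outcome across blocks and conditions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

__all__ = [
    "RQAParams",
    "RQAMeasures",
    "embed",
    "select_delay",
    "select_dim",
    "recurrence_matrix",
    "rqa_measures",
    "run_arqa",
    "run_crqa",
    "run_mdrqa",
    "max_phase_space_distance",
]


@dataclass(frozen=True)
class RQAParams:
    """Embedding and thresholding settings.

    ``delay``/``dim`` of None mean "select from the data" (AMI first
    minimum, FNN < 1 %).  ``radius`` is a fraction of the maximum
    phase-space distance unless an absolute ``eps`` is passed to the run
    functions.  ``theiler`` of None means the analysis-specific default
    (delay·dim for aRQA, 1 for mdRQA, no exclusion for cRQA).
    """

    delay: int | None = None
    dim: int | None = None
    radius: float = 0.10
    norm: str = "euclidean"
    lmin: int = 2
    theiler: int | None = None
    max_delay: int = 40
    max_dim: int = 12

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be > 0")
        if self.lmin < 2:
            raise ValueError("lmin must be >= 2")
        if self.delay is not None and self.delay < 0:
            raise ValueError("delay must be >= 0")
        if self.dim is not None and self.dim < 1:
            raise ValueError("dim must be >= 1")


@dataclass(frozen=True)
class RQAMeasures:
    rec_pct: float
    det_pct: float
    entropy: float   # bits, diagonal line lengths >= lmin
    lmax: int
    lam_pct: float


def embed(series: np.ndarray, dim: int, delay: int) -> np.ndarray:
    """Time-delay embedding: rows are (x_t, x_{t+d}, ..., x_{t+(m-1)d})."""
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("embed expects a 1-D series")
    if dim == 1 or delay == 0:
        return x[:, None].copy()
    n = x.shape[0] - (dim - 1) * delay
    if n < 2:
        raise ValueError("series too short for this embedding")
    return np.column_stack([x[i * delay : i * delay + n] for i in range(dim)])


def _ami(x: np.ndarray, lag: int, bins: int) -> float:
    a, b = x[:-lag], x[lag:]
    h, _, _ = np.histogram2d(a, b, bins=bins)
    p = h / h.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float((p[nz] * np.log2(p[nz] / (px @ py)[nz])).sum())


def select_delay(series: np.ndarray, max_lag: int = 40, bins: int = 16) -> int:
    """First local minimum of average mutual information over lags 1..max_lag."""
    x = np.asarray(series, dtype=float)
    if x.shape[0] < 100:
        raise ValueError("need at least 100 samples to select a delay")
    if np.ptp(x) == 0:
        raise ValueError("constant series has no information structure")
    max_lag = min(max_lag, x.shape[0] // 4)
    ami = np.array([_ami(x, k, bins) for k in range(1, max_lag + 1)])
    # independence baseline: AMI of a shuffled copy estimates the histogram
    # bias; a series already at that level at lag 1 carries no lag structure
    shuffled = np.random.default_rng(12345).permutation(x)
    baseline = _ami(shuffled, 1, bins)
    if ami[0] <= 1.5 * baseline:
        return 1
    if max_lag >= 2 and ami[0] <= ami[1]:
        return 1
    for k in range(1, max_lag - 1):
        if ami[k] < ami[k - 1] and ami[k] <= ami[k + 1]:
            return k + 1
    warnings.warn("AMI has no local minimum within max_lag; using max_lag")
    return max_lag


def select_dim(
    series: np.ndarray,
    delay: int,
    max_dim: int = 12,
    rtol: float = 10.0,
    atol: float = 2.0,
    threshold: float = 0.01,
) -> int:
    """Smallest embedding dimension with < ``threshold`` false nearest neighbours."""
    x = np.asarray(series, dtype=float)
    if x.shape[0] < 100:
        raise ValueError("need at least 100 samples to select a dimension")
    ra = x.std()
    if ra == 0:
        raise ValueError("constant series cannot be embedded")
    delay = max(delay, 1)
    for m in range(1, max_dim + 1):
        n = x.shape[0] - m * delay
        if n < 10:
            break
        emb = embed(x[: x.shape[0] - delay], m, delay)[:n]
        nxt = x[m * delay : m * delay + n]
        tree = cKDTree(emb)
        dist, idx = tree.query(emb, k=2)
        rd, j = dist[:, 1], idx[:, 1]
        extra = np.abs(nxt - nxt[j])
        # exact duplicates (rd = 0, e.g. noiseless periodic series) are true
        # neighbours when the next coordinate also agrees
        crit1 = extra / np.maximum(rd, 1e-12) > rtol
        crit2 = np.sqrt(rd**2 + extra**2) / ra > atol
        fnn = float(np.mean(crit1 | crit2))
        if fnn < threshold:
            return m
    warnings.warn("false-nearest-neighbour fraction never fell below threshold; using cap")
    return max_dim


def recurrence_matrix(
    x_emb: np.ndarray,
    y_emb: np.ndarray | None = None,
    radius: float = 0.1,
    norm: str = "euclidean",
) -> np.ndarray:
    """Binary recurrence/cross-recurrence matrix: distance <= radius."""
    x_emb = np.atleast_2d(np.asarray(x_emb, dtype=float))
    y_emb = x_emb if y_emb is None else np.atleast_2d(np.asarray(y_emb, dtype=float))
    if x_emb.shape[1] != y_emb.shape[1]:
        raise ValueError("embedded trajectories must share the phase-space dimension")
    d = cdist(x_emb, y_emb, metric=norm)
    return d <= radius


def _line_lengths(runs_of: np.ndarray) -> np.ndarray:
    """Run lengths of True values in a 1-D boolean array."""
    if runs_of.size == 0:
        return np.empty(0, dtype=int)
    padded = np.concatenate([[False], runs_of, [False]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return ends - starts


def diagonal_line_lengths(r: np.ndarray, theiler: int | None) -> np.ndarray:
    """Lengths of all diagonal runs, excluding diagonals inside the Theiler band."""
    n, m = r.shape
    out = []
    for d in range(-(n - 1), m):
        if theiler is not None and abs(d) <= theiler:
            continue
        out.append(_line_lengths(np.diagonal(r, offset=d)))
    return np.concatenate(out) if out else np.empty(0, dtype=int)


def vertical_line_lengths(r: np.ndarray, theiler: int | None) -> np.ndarray:
    """Lengths of vertical runs, with Theiler-band cells blanked out first."""
    rr = r
    if theiler is not None:
        n, m = r.shape
        i, j = np.ogrid[:n, :m]
        rr = r & (np.abs(i - j) > theiler)
    return np.concatenate([_line_lengths(rr[:, j]) for j in range(r.shape[1])]) \
        if r.shape[1] else np.empty(0, dtype=int)


def rqa_measures(r: np.ndarray, lmin: int = 2, theiler: int | None = None) -> RQAMeasures:
    """The five recurrence measures of a binary (cross-)recurrence matrix.

    ``theiler=None`` applies no exclusion (cross plots); an integer t
    excludes all cells with |i−j| <= t from every statistic (auto plots;
    t=0 removes just the line of identity).
    """
    r = np.asarray(r, dtype=bool)
    if r.size == 0:
        raise ValueError("empty recurrence matrix")
    n, m = r.shape
    if theiler is None:
        valid = np.ones((n, m), dtype=bool)
    else:
        i, j = np.ogrid[:n, :m]
        valid = np.abs(i - j) > theiler
    n_valid = int(valid.sum())
    n_rec = int((r & valid).sum())
    if n_valid == 0:
        raise ValueError("Theiler window excludes the whole matrix")
    rec = 100.0 * n_rec / n_valid

    diag = diagonal_line_lengths(r, theiler)
    vert = vertical_line_lengths(r, theiler)
    dl = diag[diag >= lmin]
    vl = vert[vert >= lmin]
    det = 100.0 * dl.sum() / n_rec if n_rec else 0.0
    lam = 100.0 * vl.sum() / n_rec if n_rec else 0.0
    lmax = int(dl.max()) if dl.size else 0
    if dl.size:
        _, counts = np.unique(dl, return_counts=True)
        p = counts / counts.sum()
        ent = float(-(p * np.log2(p)).sum())
    else:
        ent = 0.0
    return RQAMeasures(rec_pct=rec, det_pct=det, entropy=ent, lmax=lmax, lam_pct=lam)


def max_phase_space_distance(x_emb: np.ndarray, y_emb: np.ndarray | None = None,
                             norm: str = "euclidean") -> float:
    x_emb = np.atleast_2d(np.asarray(x_emb, dtype=float))
    y_emb = x_emb if y_emb is None else np.atleast_2d(np.asarray(y_emb, dtype=float))
    return float(cdist(x_emb, y_emb, metric=norm).max())


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("constant channel cannot be z-scored")
    return (x - x.mean(axis=0)) / sd


def run_arqa(scores: np.ndarray, params: RQAParams = RQAParams(),
             eps: float | None = None) -> tuple[RQAMeasures, RQAParams]:
    """Auto-RQA of a (first principal component) score series.

    Returns the measures and the fully resolved parameters (selected
    delay/dimension, Theiler window delay·dim).
    """
    x = _zscore(np.asarray(scores, dtype=float))
    delay = params.delay if params.delay is not None else select_delay(x, params.max_delay)
    dim = params.dim if params.dim is not None else select_dim(x, delay, params.max_dim)
    emb = embed(x, dim, delay)
    theiler = params.theiler if params.theiler is not None else delay * dim
    if eps is None:
        eps = params.radius * max_phase_space_distance(emb, norm=params.norm)
    r = recurrence_matrix(emb, None, eps, params.norm)
    resolved = replace(params, delay=delay, dim=dim, theiler=theiler)
    return rqa_measures(r, params.lmin, theiler), resolved


def _unit_interval(x: np.ndarray) -> np.ndarray:
    rng = np.ptp(x)
    if rng == 0:
        raise ValueError("constant series cannot be scaled to [0, 1]")
    return (x - x.min()) / rng


def run_crqa(knee: np.ndarray, hip: np.ndarray, params: RQAParams = RQAParams(),
             eps: float | None = None) -> tuple[RQAMeasures, RQAParams]:
    """Cross-RQA of knee vs hip flexion, each min–max scaled to [0, 1].

    Embedding parameters are selected on the knee series and applied to
    both.  Cross plots have no line of identity, so no Theiler band is
    applied (the ``theiler`` parameter can still force one).
    """
    k = _unit_interval(np.asarray(knee, dtype=float))
    h = _unit_interval(np.asarray(hip, dtype=float))
    if k.shape != h.shape:
        raise ValueError("knee and hip series must be the same length")
    delay = params.delay if params.delay is not None else select_delay(k, params.max_delay)
    dim = params.dim if params.dim is not None else select_dim(k, delay, params.max_dim)
    ke, he = embed(k, dim, delay), embed(h, dim, delay)
    if eps is None:
        eps = params.radius * max_phase_space_distance(ke, he, params.norm)
    r = recurrence_matrix(ke, he, eps, params.norm)
    resolved = replace(params, delay=delay, dim=dim)
    return rqa_measures(r, params.lmin, params.theiler), resolved


def run_mdrqa(angles: np.ndarray, params: RQAParams = RQAParams(),
              eps: float | None = None) -> tuple[RQAMeasures, RQAParams]:
    """Multidimensional RQA of the 7-channel joint state, no extra embedding.

    Channels are z-scored; the state vector is the raw per-frame
    configuration (embedding dimension multiplier 1, delay 0); the Theiler
    default excludes only the immediate neighbourhood of the identity line.
    """
    x = np.asarray(angles, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a frames x channels block")
    state = _zscore(x)
    theiler = params.theiler if params.theiler is not None else 1
    if eps is None:
        eps = params.radius * max_phase_space_distance(state, norm=params.norm)
    r = recurrence_matrix(state, None, eps, params.norm)
    resolved = replace(params, delay=0, dim=1, theiler=theiler)
    return rqa_measures(r, params.lmin, theiler), resolved
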