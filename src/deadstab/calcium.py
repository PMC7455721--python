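"""Cytosolic Ca2+ trace analysis for islet beta-cell functional connectivity.

Traces are smoothed with a centered rolling average, normalized per cell to
the basal-glucose minimum (F/F_min), and all cell pairs are scored by
Pearson correlation (the autocorrelation diagonal is excluded). Significance
of each pair uses a circular time-shift permutation null -- one trace of the
pair is rotated by a uniform random shift of at least ``min_shift`` samples,
which preserves each trace's autocorrelation while breaking the pairing --
with a +1-corrected two-sided empirical p-value and Benjamini-Hochberg
control across pairs. Epoch responses are summarized by trapezoidal AUC of
the mean normalized trace over a stimulus window against a group-specific
baseline.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .de import bh_fdr
from .io import ConfigError

logger = logging.getLogger("deadstab")

#: migration of the published color ramp for connectivity line maps
DEFAULT_EDGE_BINS = (
    (0.10, 0.26, "blue"),
    (0.26, 0.51, "green"),
    (0.51, 0.76, "yellow"),
    (0.76, 1.00, "red"),
)


@dataclass
class TraceSet:
    """Cell x time fluorescence with stimulus epochs.

    ``f`` is a DataFrame indexed by time in seconds (strictly increasing),
    one column per cell. ``epochs`` maps epoch name (e.g. ``3G``, ``17G``,
    ``KCl``) to a ``(start_s, end_s)`` window. Optional ``coords`` holds
    per-cell (x, y) positions for line maps.
    """

    f: pd.DataFrame
    epochs: dict[str, tuple[float, float]]
    coords: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        t = self.f.index.to_numpy(float)
        if len(t) > 1 and not (np.diff(t) > 0).all():
            raise ConfigError("time vector must be strictly increasing")
        if not np.isfinite(self.f.to_numpy(float)).all():
            raise ConfigError("non-finite fluorescence values")
        for name, (a, b) in self.epochs.items():
            if a >= b:
                raise ConfigError(f"epoch {name!r}: start must precede end")

    @property
    def time_s(self) -> np.ndarray:
        return self.f.index.to_numpy(float)

    @property
    def cells(self) -> pd.Index:
        return self.f.columns

    @property
    def n_cells(self) -> int:
        return self.f.shape[1]

    def epoch_mask(self, name: str) -> np.ndarray:
        if name not in self.epochs:
            raise ConfigError(f"epoch {name!r} not annotated (have {list(self.epochs)})")
        a, b = self.epochs[name]
        t = self.time_s
        return (t >= a) & (t < b)

    def slice_epoch(self, name: str) -> "TraceSet":
        mask = self.epoch_mask(name)
        return replace(self, f=self.f.loc[mask], epochs={name: self.epochs[name]})


@dataclass
class ConnectivityResult:
    r: pd.DataFrame
    p_perm: pd.DataFrame
    significant: pd.DataFrame
    pct_connected: pd.Series
    edges: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def mean_pct_connected(self) -> float:
        return float(self.pct_connected.mean())


@dataclass
class AUCResult:
    auc: float
    baseline: float
    epoch: str


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def smooth_traces(traces: TraceSet, window: int = 5) -> TraceSet:
    """Centered moving average; edges use a shrunken window. window=1 is identity."""
    if window < 1 or window > len(traces.f):
        raise ConfigError(f"window must be in [1, trace length], got {window}")
    if window % 2 == 0:
        raise ConfigError("smoothing window must be odd (center ambiguity)")
    if window == 1:
        return traces
    sm = traces.f.rolling(window, center=True, min_periods=1).mean()
    return replace(traces, f=sm)


def normalize_fmin(traces: TraceSet, basal_epoch: str = "3G") -> TraceSet:
    """Divide each cell by its minimum fluorescence within the basal epoch."""
    mask = traces.epoch_mask(basal_epoch)
    if not mask.any():
        raise ConfigError(f"basal epoch {basal_epoch!r} covers no timepoints")
    fmin = traces.f.loc[mask].min(axis=0)
    bad = fmin[fmin <= 0]
    if not bad.empty:
        raise ConfigError(f"non-positive basal F_min for cell(s) {bad.index.tolist()}")
    return replace(traces, f=traces.f / fmin)


# ---------------------------------------------------------------------------
# connectivity
# ---------------------------------------------------------------------------

def pearson_matrix(traces: TraceSet) -> pd.DataFrame:
    """All-pairs Pearson R; the diagonal is NaN and never enters summaries."""
    if traces.n_cells < 2 or len(traces.f) < 3:
        raise ConfigError("need >= 2 cells and >= 3 timepoints")
    x = traces.f.to_numpy(float).T
    sd = x.std(axis=1)
    dead = sd == 0
    if dead.any():
        logger.warning(
            "zero-variance cell(s) excluded from correlations: %s",
            traces.cells[dead].tolist(),
        )
    r = np.corrcoef(x)
    r[dead, :] = np.nan
    r[:, dead] = np.nan
    np.fill_diagonal(r, np.nan)
    return pd.DataFrame(r, index=traces.cells, columns=traces.cells)


def _circular_correlations(x: np.ndarray) -> np.ndarray:
    """Pearson r of every cell pair at every circular lag, via FFT.

    Returns an array ``cc[i, j, lag]`` for the standardized rows of ``x``;
    ``lag = 0`` is the observed correlation.
    """
    n_cells, T = x.shape
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    z = (x - mu) / np.where(sd == 0, np.nan, sd)
    F = np.fft.rfft(z, axis=1)
    cc = np.empty((n_cells, n_cells, T))
    for i in range(n_cells):
        cc[i] = np.fft.irfft(F[i][None, :] * np.conj(F), n=T, axis=1) / T
    return cc


def permutation_significance(
    traces: TraceSet,
    n_perm: int = 1000,
    alpha: float = 0.05,
    min_shift: int = 10,
    seed: int | None = None,
) -> ConnectivityResult:
    """Circular-shift permutation test of every cell pair's correlation.

    For each pair the null correlations are Pearson r after rotating one
    trace by a random shift drawn uniformly from ``[min_shift, T -
    min_shift]``; p = (1 + #{|r_null| >= |r_obs|}) / (n_perm + 1), two-sided,
    BH-corrected across pairs at ``alpha``. ``pct_connected`` per cell is
    100 x significant partners / (n_cells - 1).
    """
    if n_perm < 100:
        raise ConfigError("n_perm must be >= 100")
    T = len(traces.f)
    if T < 2 * min_shift + 1:
        raise ConfigError(f"trace length {T} too short for min_shift {min_shift}")
    rng = np.random.default_rng(seed)
    x = traces.f.to_numpy(float).T
    cc = _circular_correlations(x)
    cells = traces.cells
    n = traces.n_cells
    shifts = rng.integers(min_shift, T - min_shift + 1, size=n_perm)

    r = pd.DataFrame(cc[:, :, 0], index=cells, columns=cells)
    np.fill_diagonal(r.values, np.nan)
    pairs = list(itertools.combinations(range(n), 2))
    pmat = np.full((n, n), np.nan)
    pvals = []
    kept_pairs = []
    for i, j in pairs:
        obs = cc[i, j, 0]
        if not np.isfinite(obs):
            continue  # zero-variance cell: pair undefined
        null = cc[i, j, shifts]
        p = (1.0 + np.sum(np.abs(null) >= np.abs(obs))) / (n_perm + 1.0)
        pmat[i, j] = pmat[j, i] = p
        pvals.append(p)
        kept_pairs.append((i, j))
    if not kept_pairs:
        raise ConfigError("no well-defined cell pair")

    fdr = bh_fdr(np.array(pvals))
    sig = np.zeros((n, n), dtype=bool)
    for (i, j), q in zip(kept_pairs, fdr):
        sig[i, j] = sig[j, i] = q < alpha
    pct = pd.Series(100.0 * sig.sum(axis=1) / (n - 1), index=cells, name="pct_connected")
    return ConnectivityResult(
        r=r,
        p_perm=pd.DataFrame(pmat, index=cells, columns=cells),
        significant=pd.DataFrame(sig, index=cells, columns=cells),
        pct_connected=pct,
    )


def bin_edges(
    r: pd.DataFrame,
    significant: pd.DataFrame | None = None,
    bins=DEFAULT_EDGE_BINS,
) -> pd.DataFrame:
    """Assign each (significant) pair its color bin; pairs below the lowest
    bound are not drawn. Bins are half-open ``[lo, hi)`` except the last.
    """
    lows = [b[0] for b in bins]
    highs = [b[1] for b in bins]
    for (lo, hi) in zip(lows, highs):
        if lo >= hi:
            raise ConfigError("each bin needs lo < hi")
    for k in range(1, len(bins)):
        if lows[k] < highs[k - 1]:
            raise ConfigError("overlapping bins")
    rows = []
    cells = r.index
    for a, b in itertools.combinations(range(len(cells)), 2):
        val = r.iloc[a, b]
        if not np.isfinite(val):
            continue
        if significant is not None and not bool(significant.iloc[a, b]):
            continue
        color = None
        for k, (lo, hi, name) in enumerate(bins):
            last = k == len(bins) - 1
            if (lo <= val < hi) or (last and lo <= val <= hi):
                color = name
                break
        if color is None:
            continue
        rows.append({"cell_i": cells[a], "cell_j": cells[b], "R": val, "color_bin": color})
    return pd.DataFrame(rows, columns=["cell_i", "cell_j", "R", "color_bin"])


def epoch_auc(
    traces: TraceSet,
    epoch: str,
    baseline: float,
    clamp: bool = False,
) -> AUCResult:
    """Trapezoidal AUC of the islet-mean normalized trace minus ``baseline``.

    Negative excursions below baseline are kept unless ``clamp`` is set.
    The baseline is a group-specific scalar (e.g. 0.95 for control vs 1.03
    for knockout at high glucose in the source study's design).
    """
    if not np.isfinite(baseline):
        raise ConfigError("baseline must be finite")
    mask = traces.epoch_mask(epoch)
    if mask.sum() < 2:
        raise ConfigError(f"epoch {epoch!r} spans fewer than two timepoints")
    t = traces.time_s[mask]
    y = traces.f.loc[mask].mean(axis=1).to_numpy(float) - baseline
    if clamp:
        y = np.maximum(y, 0.0)
    return AUCResult(auc=float(np.trapezoid(y, t)), baseline=baseline, epoch=epoch)


# ---------------------------------------------------------------------------
# trace I/O (CSV + epochs sidecar)
# ---------------------------------------------------------------------------

def read_traces(path, epochs_path) -> TraceSet:
    f = pd.read_csv(path)
    if f.columns[0] != "t_s":
        raise ConfigError(f"{path}: first column must be 't_s'")
    f = f.set_index("t_s")
    ep = pd.read_csv(epochs_path)
    epochs = {row["name"]: (row["start_s"], row["end_s"]) for _, row in ep.iterrows()}
    return TraceSet(f=f, epochs=epochs)


def write_traces(traces: TraceSet, path, epochs_path) -> None:
    traces.f.rename_axis("t_s").to_csv(path)
    pd.DataFrame(
        [{"name": k, "start_s": a, "end_s": b} for k, (a, b) in traces.epochs.items()]
    ).to_csv(epochs_path, index=False)
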