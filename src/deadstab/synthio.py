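"""Seeded generators for every input the pipeline consumes, with ground truth.

The exon/intron generator encodes the generative logic behind the
exon-intron split: intronic reads report transcription, so intron means
scale with the transcription effect only, while exon means scale with
transcription times stability. Counts are Gamma-Poisson: a per-(gene,
sample) Gamma(1/phi, phi) multiplier (unit mean, variance phi) times the
cell mean, then Poisson sampling, giving marginal NB counts with
``var = mu + phi mu^2``. The multiplier is shared between the exonic and
intronic features of a gene within a sample, reflecting that both read
classes come from the same RNA-seq library; across samples and genes the
multipliers are independent.

Trace, decay and densitogram generators emulate the corresponding assays:
islet Ca2+ traces with planted correlated cell blocks and stimulus epochs,
first-order exponential decay courses with multiplicative lognormal noise,
and gel lane profiles as tail-length mixtures mapped through a marker
calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calcium import TraceSet
from .io import ConfigError, CountMatrix
from .polya import Calibration, DensitogramProfile, calibrate

DEFAULT_EPOCHS: dict[str, tuple[float, float]] = {
    "3G": (0.0, 180.0),
    "17G": (180.0, 600.0),
    "KCl": (600.0, 720.0),
}

#: additive stimulus response (fraction of basal) per epoch
DEFAULT_EPOCH_STEPS = {"3G": 0.0, "17G": 0.5, "KCl": 1.0}


@dataclass
class SimTruth:
    """Ground-truth generative parameters recorded next to simulated data."""

    gene_ids: list[str] = field(default_factory=list)
    tx_logfc: np.ndarray | None = None
    stab_logfc: np.ndarray | None = None
    dispersion: np.ndarray | None = None
    adjacency: np.ndarray | None = None
    half_life_hr: dict | None = None

    def __post_init__(self) -> None:
        for name in ("tx_logfc", "stab_logfc"):
            v = getattr(self, name)
            if v is not None and not np.isfinite(v).all():
                raise ConfigError(f"{name} must be finite")
        if self.dispersion is not None and (np.asarray(self.dispersion) < 0).any():
            raise ConfigError("dispersion must be >= 0")
        if self.adjacency is not None:
            a = np.asarray(self.adjacency)
            if not np.array_equal(a, a.T) or a.diagonal().any():
                raise ConfigError("adjacency must be symmetric with a false diagonal")
        if self.half_life_hr is not None and any(
            v <= 0 for v in self.half_life_hr.values()
        ):
            raise ConfigError("half lives must be positive")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "tx_logfc": self.tx_logfc,
                "stab_logfc": self.stab_logfc,
                "dispersion": self.dispersion,
            }
        )


# ---------------------------------------------------------------------------
# exon/intron counts
# ---------------------------------------------------------------------------

def simulate_exon_intron_counts(
    n_genes: int,
    n_reps: int,
    truth_config: dict | None = None,
    lib_sizes: np.ndarray | None = None,
    seed: int | None = None,
) -> tuple[CountMatrix, CountMatrix, SimTruth]:
    """Paired exon and intron count matrices for a control-vs-knockout design.

    ``truth_config`` keys (defaults in parentheses): ``mu_range`` control
    exon mean per sample (100, 1000); ``intron_fraction`` intron/exon
    coverage ratio (0.1); ``frac_stabilized`` / ``frac_transcription``
    fractions of genes given ``stab_logfc`` (1.5) / ``tx_logfc`` (1.5);
    ``frac_tx_down`` fraction of transcription-affected genes whose effect
    is flipped to -tx_logfc (0.0);
    ``phi`` NB dispersion, scalar or ``{"lognormal": (mean_log, sd_log)}``
    (0.1); ``shared_sample_effect`` share the Gamma multiplier between a
    gene's exon and intron counts within a sample (True).

    Intron expected counts scale with transcription only; exon expected
    counts with transcription x stability. Identical seeds give identical
    output.
    """
    if not (isinstance(n_genes, (int, np.integer)) and n_genes > 0):
        raise ConfigError(f"n_genes must be a positive integer, got {n_genes!r}")
    if not (isinstance(n_reps, (int, np.integer)) and n_reps > 0):
        raise ConfigError(f"n_reps must be a positive integer, got {n_reps!r}")
    cfg = {
        "mu_range": (100.0, 1000.0),
        "intron_fraction": 0.1,
        "frac_stabilized": 0.1,
        "frac_transcription": 0.1,
        "stab_logfc": 1.5,
        "tx_logfc": 1.5,
        "frac_tx_down": 0.0,
        "phi": 0.1,
        "shared_sample_effect": True,
    }
    cfg.update(truth_config or {})
    rng = np.random.default_rng(seed)

    gene_ids = [f"g{i:05d}" for i in range(n_genes)]
    mu_exon = rng.uniform(*cfg["mu_range"], size=n_genes)

    # transcription and stability effects are assigned independently (a gene
    # may carry both), so intron fold changes carry no information about
    # stability truth
    stab = np.zeros(n_genes)
    tx = np.zeros(n_genes)
    n_stab = int(round(cfg["frac_stabilized"] * n_genes))
    n_tx = int(round(cfg["frac_transcription"] * n_genes))
    stab[rng.permutation(n_genes)[:n_stab]] = cfg["stab_logfc"]
    tx_idx = rng.permutation(n_genes)[:n_tx]
    tx[tx_idx] = cfg["tx_logfc"]
    n_down = int(round(cfg["frac_tx_down"] * n_tx))
    tx[tx_idx[:n_down]] *= -1.0  # optionally split the transcription effect by sign

    phi_spec = cfg["phi"]
    if isinstance(phi_spec, dict) and "lognormal" in phi_spec:
        mlog, slog = phi_spec["lognormal"]
        phi = rng.lognormal(mlog, slog, size=n_genes)
    else:
        phi = np.full(n_genes, float(phi_spec))
    if (phi < 0).any():
        raise ConfigError("negative dispersion")

    n_samples = 2 * n_reps
    samples = [f"ctrl_{i + 1}" for i in range(n_reps)] + [
        f"ko_{i + 1}" for i in range(n_reps)
    ]
    groups = pd.Series(
        ["control"] * n_reps + ["knockout"] * n_reps, index=samples
    )
    ko = np.array([0] * n_reps + [1] * n_reps, dtype=float)

    mu_intron = cfg["intron_fraction"] * mu_exon
    # per-cell means: exon gets tx + stab in the KO, intron only tx
    mean_exon = mu_exon[:, None] * 2.0 ** (np.outer(tx + stab, ko))
    mean_intron = mu_intron[:, None] * 2.0 ** (np.outer(tx, ko))
    if lib_sizes is not None:
        lib_sizes = np.asarray(lib_sizes, float)
        if lib_sizes.shape != (n_samples,):
            raise ConfigError(f"lib_sizes must have length {n_samples}")
        rel = lib_sizes / lib_sizes.mean()
        mean_exon = mean_exon * rel[None, :]
        mean_intron = mean_intron * rel[None, :]

    pos = phi > 0
    g_mult = np.ones((n_genes, n_samples))
    if pos.any():
        shape = 1.0 / phi[pos]
        g_mult[pos] = rng.gamma(
            shape[:, None], 1.0 / shape[:, None], size=(pos.sum(), n_samples)
        )
    if cfg["shared_sample_effect"]:
        g_exon = g_intron = g_mult
    else:
        g_exon = g_mult
        g_intron = np.ones_like(g_mult)
        if pos.any():
            g_intron[pos] = rng.gamma(
                shape[:, None], 1.0 / shape[:, None], size=(pos.sum(), n_samples)
            )

    exon_counts = rng.poisson(mean_exon * g_exon)
    intron_counts = rng.poisson(mean_intron * g_intron)

    exon_cm = CountMatrix(
        pd.DataFrame(exon_counts, index=gene_ids, columns=samples), groups, "exon"
    )
    intron_cm = CountMatrix(
        pd.DataFrame(intron_counts, index=gene_ids, columns=samples), groups, "intron"
    )
    truth = SimTruth(
        gene_ids=gene_ids, tx_logfc=tx, stab_logfc=stab, dispersion=phi
    )
    return exon_cm, intron_cm, truth


# ---------------------------------------------------------------------------
# Ca2+ traces
# ---------------------------------------------------------------------------

def simulate_traces(
    n_cells: int,
    epochs: dict[str, tuple[float, float]] | None = None,
    planted_blocks: list[dict] | None = None,
    noise_sd: float = 0.1,
    dt_s: float = 1.0,
    ar_coef: float = 0.8,
    epoch_steps: dict[str, float] | None = None,
    seed: int | None = None,
) -> tuple[TraceSet, SimTruth]:
    """Islet Ca2+ traces with planted correlated sub-populations.

    Each planted block is ``{"cells": [indices], "rho": target within-block
    Pearson}``; block members share a latent unit-variance AR(1) signal with
    loading sqrt(rho), plus independent AR(1) noise with loading
    sqrt(1 - rho), so the expected within-block pairwise correlation is rho
    and cross-block pairs are independent. Deterministic additive steps
    raise epoch means under stimulation (17G, KCl). ``noise_sd`` scales the
    stochastic part in units of basal fluorescence fraction; per-cell gains
    are random so traces need F/F_min normalization like real recordings.
    """
    if n_cells < 1:
        raise ConfigError("n_cells must be positive")
    epochs = dict(DEFAULT_EPOCHS) if epochs is None else dict(epochs)
    if not epochs:
        raise ConfigError("need at least one epoch")
    spans = sorted(epochs.values())
    for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
        if a2 < b1:
            raise ConfigError("epochs must be non-overlapping and ordered")
    steps = {**DEFAULT_EPOCH_STEPS, **(epoch_steps or {})}
    rng = np.random.default_rng(seed)

    t_end = max(b for _, b in epochs.values())
    t0 = min(a for a, _ in epochs.values())
    time = np.arange(t0, t_end, dt_s)
    T = len(time)

    def ar1(size) -> np.ndarray:
        e = rng.standard_normal(size)
        out = np.empty(size)
        out[..., 0] = e[..., 0]
        c = np.sqrt(1.0 - ar_coef ** 2)
        for k in range(1, size[-1]):
            out[..., k] = ar_coef * out[..., k - 1] + c * e[..., k]
        return out

    block_of = np.full(n_cells, -1)
    rho_of = np.zeros(n_cells)
    blocks = planted_blocks or []
    for b_idx, blk in enumerate(blocks):
        rho = float(blk["rho"])
        if not 0.0 <= rho < 1.0:
            raise ConfigError(f"block rho must satisfy 0 <= rho < 1, got {rho}")
        for c in blk["cells"]:
            if block_of[c] != -1:
                raise ConfigError(f"cell {c} assigned to two blocks")
            block_of[c] = b_idx
            rho_of[c] = rho

    latent_blocks = ar1((max(len(blocks), 1), T))
    noise = ar1((n_cells, T))
    x = np.sqrt(1.0 - rho_of)[:, None] * noise
    for c in range(n_cells):
        if block_of[c] >= 0:
            x[c] += np.sqrt(rho_of[c]) * latent_blocks[block_of[c]]

    step_tr = np.zeros(T)
    for name, (a, b) in epochs.items():
        step_tr[(time >= a) & (time < b)] += steps.get(name, 0.0)

    gains = rng.uniform(50.0, 200.0, size=n_cells)
    f = gains[:, None] * (1.0 + step_tr[None, :] + noise_sd * x)
    f = np.maximum(f, 1e-3)

    cells = [f"cell_{i:03d}" for i in range(n_cells)]
    ts = TraceSet(
        f=pd.DataFrame(f.T, index=pd.Index(time, name="t_s"), columns=cells),
        epochs=epochs,
    )
    adjacency = (block_of[:, None] == block_of[None, :]) & (block_of[:, None] >= 0)
    np.fill_diagonal(adjacency, False)
    return ts, SimTruth(gene_ids=cells, adjacency=adjacency)


# ---------------------------------------------------------------------------
# Act-D decay courses
# ---------------------------------------------------------------------------

def simulate_decay(
    half_lives: dict[str, float] | float,
    timepoints=(0.0, 4.0, 8.0),
    n_reps: int = 3,
    cv: float = 0.05,
    seed: int | None = None,
    gene: str = "gene",
) -> pd.DataFrame:
    """Relative-abundance decay courses: 100 x 2**(-t / t_half) per genotype.

    Multiplicative lognormal noise with the stated coefficient of variation
    (unit mean, so ensemble averages stay on the decay curve). Returns a
    tidy frame with columns gene, genotype, replicate, time_hr, value.
    """
    if not isinstance(half_lives, dict):
        half_lives = {"control": float(half_lives)}
    if any(h <= 0 for h in half_lives.values()):
        raise ConfigError("half lives must be positive")
    timepoints = np.asarray(timepoints, float)
    if 0.0 not in timepoints:
        raise ConfigError("timepoints must include 0")
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(cv ** 2))
    rows = []
    for genotype, t_half in half_lives.items():
        expected = 100.0 * 2.0 ** (-timepoints / t_half)
        for rep in range(1, n_reps + 1):
            if cv > 0:
                noise = rng.lognormal(-sigma ** 2 / 2.0, sigma, size=len(timepoints))
            else:
                noise = np.ones(len(timepoints))
            for t, v in zip(timepoints, expected * noise):
                rows.append(
                    {
                        "gene": gene,
                        "genotype": genotype,
                        "replicate": f"{genotype}_{rep}",
                        "time_hr": t,
                        "value": v,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# densitograms
# ---------------------------------------------------------------------------

DEFAULT_MARKER = ((150.0, 10.0), (80.0, 25.0), (50.0, 40.0), (30.0, 55.0), (20.0, 70.0))


def simulate_densitogram(
    tail_mixture,
    marker=DEFAULT_MARKER,
    n_points: int = 1200,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> DensitogramProfile:
    """Gel lane profile of a poly(A) tail-length mixture.

    ``tail_mixture`` is a list of ``(length_nt, weight, spread_nt)``
    components; weights must sum to 1. Each component is a Gaussian band in
    tail-length space, mapped through the marker calibration with the
    Jacobian |d length / d position| so the profile's area equals the
    component weight; the total area is 1 before noise.
    """
    comps = [(float(l), float(w), float(s)) for l, w, s in tail_mixture]
    wsum = sum(w for _, w, _ in comps)
    if abs(wsum - 1.0) > 1e-8:
        raise ConfigError(f"mixture weights must sum to 1, got {wsum}")
    cal: Calibration = calibrate(marker)
    # pad beyond the anchor range so bands near the edge lengths keep their
    # full mass on the lane (the calibration extrapolates log-linearly)
    span = cal.positions[-1] - cal.positions[0]
    pos = np.linspace(
        cal.positions[0] - 0.6 * span, cal.positions[-1] + 0.6 * span, n_points
    )
    lengths, _ = cal.length_at(pos)
    jac = np.abs(np.gradient(lengths, pos))
    intensity = np.zeros_like(pos)
    for L, w, s in comps:
        if s <= 0:
            raise ConfigError("component spread must be positive")
        pdf = np.exp(-0.5 * ((lengths - L) / s) ** 2) / (s * np.sqrt(2 * np.pi))
        intensity += w * pdf * jac
    intensity /= np.trapezoid(intensity, pos)  # unit area before noise
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        intensity = np.maximum(
            intensity + noise_sd * rng.standard_normal(len(pos)), 0.0
        )
    return DensitogramProfile(pos, intensity, list(marker))
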