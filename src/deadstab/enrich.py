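"""Gene-set enrichment (weighted Kolmogorov-Smirnov running sum) and
transcriptome-proteome log-fold-change correlation.

The enrichment score walks the ranked gene list from top to bottom,
incrementing at set members in proportion to |metric|**weight (normalized by
the set total) and decrementing 1/(N - n_set) at non-members; the ES is the
maximum signed deviation of this running sum and the leading edge is the set
members encountered up to that extremum. Significance uses a
gene-permutation null (random same-size sets), the natural choice when only
one ranked list is available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .io import ConfigError, GeneSet

logger = logging.getLogger("deadstab")


@dataclass
class EnrichmentResult:
    es: float
    n_set_in_ranking: int
    leading_edge: list[str]
    running_sum: np.ndarray = field(repr=False, default=None)
    p_perm: float | None = None


@dataclass
class IntegrationResult:
    r: float
    p: float
    n_matched: int

    @property
    def r_squared(self) -> float:
        return self.r ** 2


def rank_genes(de_table: pd.DataFrame, metric_col: str = "logFC") -> pd.Series:
    """Ranking metric from a DE table: signed logFC, ties broken by p-value
    then lexicographic gene id (a deterministic total order)."""
    df = de_table.sort_values(
        by=[metric_col, "PValue", "gene_id"], ascending=[False, True, True]
    )
    return pd.Series(df[metric_col].to_numpy(), index=df["gene_id"].to_numpy())


def _hit_mask(genes: np.ndarray, gene_set: GeneSet | list) -> np.ndarray:
    members = set(gene_set.genes if isinstance(gene_set, GeneSet) else gene_set)
    return np.isin(genes, list(members))


def gsea_es(
    ranking: pd.Series,
    gene_set: GeneSet | list,
    weight: float = 1.0,
) -> EnrichmentResult:
    """Enrichment score of ``gene_set`` in ``ranking`` (genes -> metric,
    ordered best-first). ``weight`` = 0 gives the classic unweighted KS
    statistic; ``weight`` = 1 weights hits by |metric|.
    """
    genes = np.asarray(ranking.index)
    if len(genes) != len(set(genes)):
        raise ConfigError("ranking contains duplicate genes")
    metric = ranking.to_numpy(float)
    if not np.isfinite(metric).all():
        raise ConfigError("ranking metric must be finite")
    hits = _hit_mask(genes, gene_set)
    n_hit = int(hits.sum())
    if n_hit == 0:
        raise ConfigError("no gene of the set appears in the ranking")
    if n_hit == len(genes):
        raise ConfigError("gene set covers the whole ranking; ES undefined")

    w = np.abs(metric) ** weight
    hit_total = w[hits].sum()
    steps = np.where(hits, (w / hit_total if hit_total > 0 else 1.0 / n_hit), 0.0)
    if hit_total == 0:
        steps = np.where(hits, 1.0 / n_hit, 0.0)
    steps = steps - np.where(~hits, 1.0 / (len(genes) - n_hit), 0.0)
    running = np.cumsum(steps)
    imax = int(np.argmax(np.abs(running)))
    es = float(running[imax])
    if es >= 0:
        leading = genes[: imax + 1][hits[: imax + 1]]
    else:
        leading = genes[imax + 1:][hits[imax + 1:]]
    return EnrichmentResult(
        es=es,
        n_set_in_ranking=n_hit,
        leading_edge=list(leading),
        running_sum=running,
    )


def gsea_permutation_p(
    ranking: pd.Series,
    gene_set: GeneSet | list,
    n_perm: int = 1000,
    seed: int | None = None,
    weight: float = 1.0,
) -> float:
    """Gene-permutation p-value: null ES from random same-size gene sets;
    p = (1 + #{|ES_null| >= |ES|}) / (n_perm + 1)."""
    if n_perm < 100:
        raise ConfigError("n_perm must be >= 100")
    obs = gsea_es(ranking, gene_set, weight=weight)
    genes = np.asarray(ranking.index)
    n_hit = obs.n_set_in_ranking
    if n_hit >= len(genes):
        raise ConfigError("set size must be smaller than the ranking")
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        null_set = rng.choice(genes, size=n_hit, replace=False)
        es_null = gsea_es(ranking, list(null_set), weight=weight).es
        if abs(es_null) >= abs(obs.es):
            exceed += 1
    return (1.0 + exceed) / (n_perm + 1.0)


def correlate_omics(
    gene_logfc: pd.DataFrame,
    protein_logfc: pd.DataFrame,
    id_map: pd.DataFrame | None = None,
    gene_col: str = "gene_id",
    protein_col: str = "protein_id",
    value_col: str = "logFC",
) -> IntegrationResult:
    """Pearson correlation of matched transcript and protein log fold changes.

    ``id_map`` (gene_id, protein_id) translates namespaces; without it the
    two tables are matched directly on ``gene_id``. Unmatched ids are logged.
    """
    prot = protein_logfc.copy()
    if id_map is not None:
        prot = prot.merge(id_map, on=protein_col, how="inner")
    key = gene_col
    merged = gene_logfc.merge(prot, on=key, suffixes=("_gene", "_protein"), how="inner")
    gcol, pcol = f"{value_col}_gene", f"{value_col}_protein"
    if gcol not in merged:  # no suffix collision
        gcol, pcol = value_col, value_col
    n_un = len(gene_logfc) + len(prot) - 2 * len(merged)
    if n_un:
        logger.info("correlate_omics: %d unmatched id(s)", n_un)
    if len(merged) < 3:
        raise ConfigError(f"need >= 3 matched pairs, got {len(merged)}")
    r, p = pearsonr(merged[gcol], merged[pcol])
    return IntegrationResult(r=float(r), p=float(p), n_matched=len(merged))
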