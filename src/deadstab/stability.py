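"""Exon/intron split analysis of mRNA stability.

Exonic reads track steady-state mRNA abundance while intronic reads track
transcription (pre-mRNA), so the per-gene difference between exonic and
intronic log2 fold changes -- delta = exon_logFC - intron_logFC -- estimates
the change in mRNA half-life between genotypes.

Significance of a stability change is assessed by the interaction term of an
NB log-linear model with per-sample intercepts, feature-class and
feature-class x group effects. Because a gene's exonic and intronic reads
come from the same sequencing library, the per-sample intercepts absorb
library size and shared sample-level biological fluctuation; profiling them
out by conditioning on the per-sample exon + intron total reduces the
interaction test exactly to binomial logistic regression of the exon count
against genotype (the log odds is the within-sample exon/intron log ratio).
A Wald z-test on the group coefficient gives the per-gene interaction
p-value, corrected across genes by Benjamini-Hochberg.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .de import bh_fdr
from .io import ConfigError, CountMatrix

logger = logging.getLogger("deadstab")

LN2 = np.log(2.0)

CLASS_LABELS = (
    "stabilized_up",
    "stabilized_not_up",
    "destabilized",
    "transcription_driven",
    "unchanged",
)


@dataclass
class OverlapSummary:
    """Counts behind the stabilized / stabilized-and-upregulated overlap."""

    n_stabilized: int
    n_stabilized_and_up: int
    n_stabilized_not_up: int

    def __post_init__(self) -> None:
        if self.n_stabilized != self.n_stabilized_and_up + self.n_stabilized_not_up:
            raise ValueError("overlap counts are inconsistent")

    @property
    def fraction_up(self) -> float:
        if self.n_stabilized == 0:
            logger.warning("no stabilized genes; fraction_up defined as 0")
            return 0.0
        return self.n_stabilized_and_up / self.n_stabilized


def delta_exon_intron(exon_de: pd.DataFrame, intron_de: pd.DataFrame) -> pd.DataFrame:
    """Join exon and intron DE tables and compute delta = exon - intron logFC.

    Genes present in only one table (e.g. filtered out for lacking intron
    signal) are excluded and logged. Raises if the intersection is empty.
    """
    merged = exon_de.merge(
        intron_de, on="gene_id", suffixes=("_exon", "_intron"), how="inner"
    )
    if merged.empty:
        raise ConfigError("exon and intron DE tables share no gene ids")
    n_dropped = len(exon_de) + len(intron_de) - 2 * len(merged)
    if n_dropped:
        logger.info(
            "delta_exon_intron: %d gene(s) present in only one feature class excluded",
            n_dropped,
        )
    out = pd.DataFrame(
        {
            "gene_id": merged["gene_id"],
            "exon_logfc": merged["logFC_exon"],
            "intron_logfc": merged["logFC_intron"],
        }
    )
    out["delta"] = out["exon_logfc"] - out["intron_logfc"]
    return out


def test_interaction(
    exon: CountMatrix,
    intron: CountMatrix,
    ref_group: str = "control",
    ratio_dispersion: float = 0.0,
) -> pd.DataFrame:
    """Per-gene test of H0: exon logFC == intron logFC (no stability change).

    Conditions on per-sample exon + intron totals (see module docstring);
    returns ``gene_id, delta_mle, p_interaction, fdr`` where ``delta_mle`` is
    the conditional-model estimate of delta in log2 units.

    ``ratio_dispersion`` adds an extra-binomial variance component
    (per-sample, natural-log scale) to the Wald variance for libraries where
    exon and intron reads are not strictly paired; the default 0 assumes full
    pairing.
    """
    if list(exon.samples) != list(intron.samples):
        raise ConfigError("exon and intron matrices must share samples in order")
    common = exon.gene_ids.intersection(intron.gene_ids)
    if common.empty:
        raise ConfigError("no genes shared between exon and intron matrices")
    skipped = len(exon.gene_ids.symmetric_difference(intron.gene_ids))
    if skipped:
        logger.info("test_interaction: %d unmatched gene(s) excluded", skipped)

    e = exon.counts.loc[common].to_numpy(float)
    i = intron.counts.loc[common].to_numpy(float)
    is_ref = np.asarray(exon.groups == ref_group)
    if is_ref.sum() == 0 or (~is_ref).sum() == 0:
        raise ConfigError(f"both groups needed; reference is {ref_group!r}")

    def group_logit(e_g: np.ndarray, i_g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        # Haldane-corrected aggregated binomial: beta = ln(sum_e / sum_i)
        se, si = e_g.sum(axis=1) + 0.5, i_g.sum(axis=1) + 0.5
        beta = np.log(se / si)
        var = 1.0 / se + 1.0 / si
        return beta, var

    b1, v1 = group_logit(e[:, is_ref], i[:, is_ref])
    b2, v2 = group_logit(e[:, ~is_ref], i[:, ~is_ref])
    n1, n2 = int(is_ref.sum()), int((~is_ref).sum())
    extra = ratio_dispersion * (1.0 / n1 + 1.0 / n2)
    beta = b2 - b1
    var = v1 + v2 + extra
    z = beta / np.sqrt(var)
    p = 2.0 * norm.sf(np.abs(z))
    return pd.DataFrame(
        {
            "gene_id": common,
            "delta_mle": beta / LN2,
            "p_interaction": p,
            "fdr": bh_fdr(p),
        }
    ).reset_index(drop=True)


def classify_targets(
    records: pd.DataFrame,
    exon_de: pd.DataFrame,
    fdr_alpha: float = 0.05,
) -> tuple[pd.DataFrame, OverlapSummary]:
    """Attach class labels and summarize the stabilized/upregulated overlap.

    A gene is *stabilized* when delta > 0 with interaction FDR < alpha;
    *stabilized_up* additionally requires exonic upregulation at FDR < alpha.
    Genes with a significant negative delta are *destabilized*; genes DE at
    the exon level without a stability change are *transcription_driven*.
    """
    if not 0.0 < fdr_alpha < 1.0:
        raise ConfigError(f"fdr_alpha must be in (0, 1), got {fdr_alpha}")
    df = records.merge(
        exon_de[["gene_id", "logFC", "FDR"]].rename(
            columns={"logFC": "exon_de_logfc", "FDR": "exon_de_fdr"}
        ),
        on="gene_id",
        how="left",
    )
    sig_int = df["fdr"] < fdr_alpha
    exon_up = (df["exon_de_fdr"] < fdr_alpha) & (df["exon_de_logfc"] > 0)
    exon_de_sig = df["exon_de_fdr"] < fdr_alpha

    label = np.full(len(df), "unchanged", dtype=object)
    label[exon_de_sig.fillna(False)] = "transcription_driven"
    label[sig_int & (df["delta"] < 0)] = "destabilized"
    stabilized = sig_int & (df["delta"] > 0)
    label[stabilized & ~exon_up.fillna(False)] = "stabilized_not_up"
    label[stabilized & exon_up.fillna(False)] = "stabilized_up"
    df["class"] = label

    n_up = int((df["class"] == "stabilized_up").sum())
    n_not = int((df["class"] == "stabilized_not_up").sum())
    return df, OverlapSummary(n_up + n_not, n_up, n_not)


def overlap_with_reference(
    target_genes, reference_up_genes
) -> tuple[list[str], int]:
    """Case-normalized sorted intersection of two gene lists."""
    targets = {str(g).casefold(): str(g) for g in target_genes}
    ref = {str(g).casefold() for g in reference_up_genes}
    hits = sorted(targets[g] for g in targets.keys() & ref)
    return hits, len(hits)


def stability_pipeline(
    exon: CountMatrix,
    intron: CountMatrix,
    ref_group: str = "control",
    cpm_min: float = 1.0,
    min_samples: int = 3,
    fdr_alpha: float = 0.05,
) -> tuple[pd.DataFrame, OverlapSummary]:
    """Full stability stage: DE both feature classes, delta, interaction, classes.

    Genes lacking intron signal after filtering never receive a class (their
    delta is undefined); they are simply absent from the returned table.

    Because a sample's exonic and intronic reads come from the same library,
    both feature classes are normalized with SHARED per-sample effective
    library sizes (TMM on the stacked exon + intron matrix). Any residual
    composition bias in the normalization then enters exon and intron log
    fold changes identically and cancels in delta.
    """
    from .de import de_pipeline, filter_expressed, tmm_factors

    exon_f = filter_expressed(exon, cpm_min=cpm_min, min_samples=min_samples)
    intron_f = filter_expressed(intron, cpm_min=cpm_min, min_samples=min_samples)
    stacked = pd.concat(
        [
            exon_f.counts.rename(index=lambda g: f"{g}::exon"),
            intron_f.counts.rename(index=lambda g: f"{g}::intron"),
        ]
    )
    shared_factors = tmm_factors(stacked)
    shared_lib = stacked.sum(axis=0)
    exon_de = de_pipeline(
        exon, cpm_min=cpm_min, min_samples=min_samples, ref_group=ref_group,
        factors=shared_factors, lib_sizes=shared_lib,
    )
    intron_de = de_pipeline(
        intron, cpm_min=cpm_min, min_samples=min_samples, ref_group=ref_group,
        factors=shared_factors, lib_sizes=shared_lib,
    )
    records = delta_exon_intron(exon_de, intron_de)
    inter = test_interaction(exon_f, intron_f, ref_group=ref_group)
    records = records.merge(inter, on="gene_id", how="inner")
    return classify_targets(records, exon_de, fdr_alpha=fdr_alpha)
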