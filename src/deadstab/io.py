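"""Readers and writers for the tabular formats the pipeline consumes.

Count matrices travel as TSV (gene rows, sample columns, first column
``gene_id``); fluorescence traces as CSV (time column ``t_s``, one column per
cell) with an epochs sidecar CSV (``name,start_s,end_s``); gene sets as GMT.
All readers validate their input and raise :class:`FormatError` naming the
offending row/column, so malformed files fail loudly rather than propagating
NaNs into the statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("deadstab")

VALID_FEATURE_CLASSES = ("exon", "intron")


class FormatError(ValueError):
    """A file violated the format contract (bad cell, duplicate id, ...)."""


class ConfigError(ValueError):
    """Configuration inconsistent with the data (unmapped sample, bad threshold)."""


@dataclass
class CountMatrix:
    """Gene x sample integer read counts for one feature class.

    Parameters
    ----------
    counts
        DataFrame indexed by unique gene ids, one column per sample,
        non-negative integers.
    groups
        Series mapping sample id -> group label (e.g. ``control`` /
        ``knockout``), indexed identically to ``counts.columns``.
    feature_class
        ``"exon"`` or ``"intron"``.
    """

    counts: pd.DataFrame
    groups: pd.Series
    feature_class: str

    def __post_init__(self) -> None:
        if self.feature_class not in VALID_FEATURE_CLASSES:
            raise ConfigError(
                f"feature_class must be one of {VALID_FEATURE_CLASSES}, "
                f"got {self.feature_class!r}"
            )
        if self.counts.index.duplicated().any():
            dups = self.counts.index[self.counts.index.duplicated()].unique()
            raise FormatError(f"duplicated gene ids: {list(dups[:5])}")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise FormatError("counts must be numeric")
        if np.isnan(arr.astype(float)).any():
            raise FormatError("missing values are not allowed in count matrices")
        if (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise FormatError(
                f"negative count at gene {self.counts.index[g]!r}, "
                f"sample {self.counts.columns[s]!r}"
            )
        if not np.allclose(arr, np.round(arr)):
            g, s = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
            raise FormatError(
                f"non-integer count at gene {self.counts.index[g]!r}, "
                f"sample {self.counts.columns[s]!r}"
            )
        self.counts = self.counts.astype(np.int64)
        self.counts.index.name = "gene_id"
        self.groups = pd.Series(self.groups)
        missing = [s for s in self.counts.columns if s not in self.groups.index]
        if missing:
            raise ConfigError(f"samples without a group label: {missing}")
        self.groups = self.groups.loc[self.counts.columns]

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    @property
    def lib_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def subset_genes(self, genes: Sequence[str]) -> "CountMatrix":
        return CountMatrix(self.counts.loc[genes], self.groups, self.feature_class)


@dataclass
class GeneSet:
    name: str
    description: str
    genes: list[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise FormatError(f"gene set {self.name!r} is empty")
        seen: dict[str, None] = {}
        for g in self.genes:
            if g in seen:
                logger.warning("gene set %s: duplicate gene %s de-duplicated", self.name, g)
            seen[g] = None
        self.genes = list(seen)

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class RunConfig:
    """Thresholds and seeds shared across analysis stages."""

    cpm_min: float = 1.0
    min_samples: int = 3
    fdr_alpha: float = 0.05
    logfc_min: float = 0.0
    polya_threshold_nt: float = 50.0
    n_permutations: int = 1000
    seed: int | None = None
    paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 < self.fdr_alpha < 1.0:
            raise ConfigError(f"fdr_alpha must be in (0, 1), got {self.fdr_alpha}")
        if self.n_permutations < 100:
            raise ConfigError("n_permutations must be >= 100")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)


def read_counts(
    path: str | Path,
    feature_class: str,
    groups: Mapping[str, str] | pd.Series,
) -> CountMatrix:
    """Read a gene x sample count TSV and attach group labels.

    The header row names the samples; every sample must appear in ``groups``.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.columns[0] != "gene_id":
        raise FormatError(f"{path}: first column must be 'gene_id', got {df.columns[0]!r}")
    df = df.set_index("gene_id")
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce")
        if bad.isna().any():
            row = df.index[bad.isna()][0]
            raise FormatError(f"{path}: non-numeric count at gene {row!r}, sample {col!r}")
        df[col] = bad
    groups = pd.Series(dict(groups)) if not isinstance(groups, pd.Series) else groups
    unmapped = [s for s in df.columns if s not in groups.index]
    if unmapped:
        raise ConfigError(f"{path}: samples not in group map: {unmapped}")
    return CountMatrix(df, groups.loc[df.columns], feature_class)


def write_counts(cm: CountMatrix, path: str | Path) -> None:
    cm.counts.rename_axis("gene_id").to_csv(path, sep="\t")


def read_groups(path: str | Path) -> pd.Series:
    """Read a two-column ``sample<TAB>group`` TSV into a Series."""
    df = pd.read_csv(path, sep="\t", header=0)
    if df.shape[1] != 2:
        raise FormatError(f"{path}: expected two columns (sample, group)")
    return df.set_index(df.columns[0])[df.columns[1]]


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file: ``name<TAB>description<TAB>gene1<TAB>gene2...``."""
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has {len(fields)} fields, need >=3")
            sets.append(GeneSet(fields[0], fields[1], [g for g in fields[2:] if g]))
    if not sets:
        logger.warning("%s: empty GMT file", path)
    return sets


def write_gmt(sets: Sequence[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description, *s.genes]) + "\n")


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a generic analysis table (TSV for .tsv, CSV otherwise)."""
    sep = "\t" if str(path).endswith(".tsv") else ","
    return pd.read_csv(path, sep=sep)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    sep = "\t" if str(path).endswith(".tsv") else ","
    df.to_csv(path, sep=sep, index=False)
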