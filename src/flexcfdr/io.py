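"""Summary-statistic table I/O and table-level preprocessing.

Tables are tab-separated with a header. Column names are configurable via a
mapping from the standard names (snp_id, chrom, pos, p, maf, indep, plus any
covariate columns) to the names in the file.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .core import _align_sign

logger = logging.getLogger(__name__)

__all__ = [
    "SummaryTable",
    "read_summary_table",
    "align_covariate_sign",
    "maf_match_independent_subset",
    "bh_adjust",
]

_CORE_COLUMNS = ("snp_id", "chrom", "pos", "p")


@dataclass
class SummaryTable:
    """Per-SNP records: identifiers, p-values, covariates, optional MAF and
    independent-subset flag. ``df`` uses the standard column names."""

    df: pd.DataFrame
    covariates: list = field(default_factory=list)

    @property
    def m(self) -> int:
        return len(self.df)

    @property
    def has_maf(self) -> bool:
        return "maf" in self.df.columns

    @property
    def has_indep(self) -> bool:
        return "indep" in self.df.columns

    def validate(self) -> None:
        for col in _CORE_COLUMNS:
            if col not in self.df.columns:
                raise ValueError(f"missing required column {col!r}")
        p = self.df["p"].to_numpy(dtype=float)
        bad = np.nonzero(~np.isfinite(p) | (p <= 0) | (p > 1))[0]
        if bad.size:
            raise ValueError(
                f"p-values outside (0, 1] at rows {bad[:20].tolist()} "
                "(zero p-values imply infinite Z-scores)"
            )
        for c in self.covariates:
            q = pd.to_numeric(self.df[c], errors="coerce").to_numpy(dtype=float)
            bad = np.nonzero(~np.isfinite(q))[0]
            if bad.size:
                raise ValueError(
                    f"covariate {c!r} non-finite at rows {bad[:20].tolist()}"
                )
        if self.has_indep and not bool(self.df["indep"].any()):
            raise ValueError("independence flag column supplied but no SNP is flagged")

    def indep_mask(self) -> np.ndarray:
        if self.has_indep:
            return self.df["indep"].to_numpy(dtype=bool)
        return np.ones(self.m, dtype=bool)


def read_summary_table(path, columns: dict | None = None, covariates=None) -> SummaryTable:
    """Load a tab-separated summary-statistic table.

    ``columns`` maps standard names to the file's column names (identity by
    default); ``covariates`` lists the covariate columns (file names).
    """
    columns = dict(columns or {})
    covariates = list(covariates or [])
    df = pd.read_csv(path, sep="\t")
    rename = {}
    for std in (*_CORE_COLUMNS, "maf", "indep"):
        src = columns.get(std, std)
        if src in df.columns:
            rename[src] = std
        elif std in _CORE_COLUMNS:
            raise KeyError(f"column {src!r} (for {std!r}) not found in {path}")
    for c in covariates:
        if c not in df.columns:
            raise KeyError(f"covariate column {c!r} not found in {path}")
    df = df.rename(columns=rename)
    if "indep" in df.columns:
        df["indep"] = df["indep"].astype(bool)
    table = SummaryTable(df=df, covariates=covariates)
    table.validate()
    return table


def align_covariate_sign(table: SummaryTable, covariate: str):
    """Flip the covariate's sign if its Pearson correlation with p over the
    independent subset is strictly negative, returning (table, flipped)."""
    if covariate not in table.df.columns:
        raise KeyError(f"no covariate column {covariate!r}")
    if table.m < 3:
        raise ValueError("need at least 3 records for sign alignment")
    p = table.df["p"].to_numpy(dtype=float)
    q = table.df[covariate].to_numpy(dtype=float)
    q_new, flipped = _align_sign(p, q, table.indep_mask())
    if flipped:
        out = SummaryTable(df=table.df.copy(), covariates=list(table.covariates))
        out.df[covariate] = q_new
        logger.info("covariate %r sign reversed for positive monotonicity", covariate)
        return out, True
    return table, False


def maf_match_independent_subset(
    table: SummaryTable, n_bins: int = 50, seed: int = 0
) -> np.ndarray:
    """Down-sample the independent subset to match the full-table MAF
    distribution, binned into equal-probability MAF bins.

    Missing MAFs are imputed by sampling from the empirical distribution of
    the observed MAFs. Within each bin the subset is down-sampled without
    replacement so its bin proportions equal the full table's, at the
    largest total the scarcest bin allows. Returns a mask (subset of indep).
    """
    if not table.has_maf:
        raise ValueError("MAF column required for MAF matching")
    if not table.has_indep:
        raise ValueError("independence flags required for MAF matching")
    rng = np.random.default_rng(seed)
    maf = pd.to_numeric(table.df["maf"], errors="coerce").to_numpy(dtype=float)
    missing = ~np.isfinite(maf)
    if np.all(missing):
        raise ValueError("all MAF values missing")
    if np.any(missing):
        maf = maf.copy()
        maf[missing] = rng.choice(maf[~missing], size=int(missing.sum()), replace=True)
        logger.info("imputed %d missing MAF values from the empirical distribution",
                    int(missing.sum()))

    edges = np.unique(np.quantile(maf, np.linspace(0, 1, n_bins + 1)))
    if edges.size < 3:
        raise ValueError("MAF distribution too degenerate to bin")
    if edges.size < n_bins + 1:
        logger.info("merged empty MAF bins: %d bins used", edges.size - 1)
    bins = np.clip(np.searchsorted(edges, maf, side="right") - 1, 0, edges.size - 2)

    indep = table.indep_mask()
    full_counts = np.bincount(bins, minlength=edges.size - 1)
    sub_counts = np.bincount(bins[indep], minlength=edges.size - 1)
    props = full_counts / full_counts.sum()
    # largest subset total such that every bin can supply its share
    with np.errstate(divide="ignore"):
        totals = np.where(props > 0, sub_counts / np.where(props > 0, props, 1.0), np.inf)
    target_total = int(np.floor(totals.min()))
    targets = np.floor(props * target_total).astype(int)

    mask = np.zeros(table.m, dtype=bool)
    for b in range(edges.size - 1):
        members = np.nonzero(indep & (bins == b))[0]
        k = min(targets[b], members.size)
        if k > 0:
            mask[rng.choice(members, size=k, replace=False)] = True
    return mask


def bh_adjust(values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty input to BH adjustment")
    if np.any(~np.isfinite(values)) or np.any(values <= 0) or np.any(values > 1):
        raise ValueError("values must lie in (0, 1]")
    return multipletests(values, method="fdr_bh")[1]
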