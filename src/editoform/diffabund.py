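"""Label-free differential protein abundance between two genotypes.

Input is a protein-group x sample matrix of label-free (MaxLFQ-style)
intensities for two groups (default 3+3 biological replicates). The stage
reproduces the standard quantified-protein workflow:

1. filter to protein groups quantified (> 0) in at least ``min_present``
   of all samples *and* in every replicate of at least one group;
2. log2-transform; replace missing values with draws from a downshifted
   per-sample normal distribution (default: mean - 1.8 sd, width 0.3 sd),
   modelling that missing intensities were too low to quantify;
3. per-protein two-sided two-sample t-test with Benjamini-Hochberg
   adjustment, yielding a volcano table (log2 fold change, p, adjusted p,
   significance flag);

plus per-complex summed intensities and a subcellular-compartment
summary of cumulative protein quantity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .complexome import ModuleDefinition

logger = logging.getLogger(__name__)

__all__ = [
    "QuantMatrix",
    "filter_quantified",
    "impute_and_test",
    "complex_level_sums",
    "compartment_summary",
    "read_quant_tsv",
    "write_quant_tsv",
]


@dataclass
class QuantMatrix:
    """Protein-group x sample label-free intensities with genotype groups.

    ``values``: DataFrame, index protein-group ids, columns sample ids;
    0 or NaN means "not quantified". ``groups`` maps each sample id to
    exactly one of two group labels.
    """

    values: pd.DataFrame
    groups: Mapping[str, str]

    def __post_init__(self):
        missing = [s for s in self.values.columns if s not in self.groups]
        if missing:
            raise ValueError(f"samples without group assignment: {missing}")
        if len(self.group_names) != 2:
            raise ValueError(
                f"need exactly 2 groups, got {self.group_names}"
            )

    @property
    def group_names(self) -> list[str]:
        seen = []
        for s in self.values.columns:
            g = self.groups[s]
            if g not in seen:
                seen.append(g)
        return seen

    def samples_of(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == group]


def filter_quantified(
    matrix: QuantMatrix, min_present: int = 4, require_full_group: bool = True
) -> QuantMatrix:
    """Keep protein groups quantified in >= ``min_present`` samples overall
    and (optionally) in every replicate of at least one group.

    Idempotent and invariant to row/column permutation.
    """
    n_samples = matrix.values.shape[1]
    if min_present > n_samples:
        raise ValueError(
            f"min_present {min_present} exceeds sample count {n_samples}"
        )
    present = matrix.values.fillna(0) > 0
    keep = present.sum(axis=1) >= min_present
    if require_full_group:
        full_any = pd.Series(False, index=matrix.values.index)
        for g in matrix.group_names:
            cols = matrix.samples_of(g)
            full_any |= present[cols].all(axis=1)
        keep &= full_any
    return QuantMatrix(matrix.values.loc[keep].copy(), dict(matrix.groups))


def impute_and_test(
    matrix: QuantMatrix,
    seed: int,
    downshift: float = 1.8,
    width: float = 0.3,
    fc_threshold: float = 0.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Impute missing values and test per-protein differential abundance.

    Missing/zero entries are replaced per sample by draws from
    ``Normal(mean - downshift*sd, (width*sd)^2)`` of that sample's observed
    log2 intensities. A two-sided two-sample t-test compares the groups;
    p-values are Benjamini-Hochberg adjusted. ``log2fc`` is the mean log2
    intensity of the second group minus that of the first (reference)
    group. Reproducible given ``seed``; with no missing values the output
    is seed-independent.
    """
    rng = np.random.default_rng(seed)
    log2 = np.log2(matrix.values.where(matrix.values > 0))
    imputed = log2.copy()
    for sample in log2.columns:
        col = log2[sample]
        observed = col.dropna()
        if len(observed) < 2:
            raise ValueError(
                f"sample {sample!r} has {len(observed)} observed values; need >= 2"
            )
        mu, sd = observed.mean(), observed.std(ddof=1)
        n_missing = int(col.isna().sum())
        if n_missing:
            draws = rng.normal(mu - downshift * sd, width * sd, size=n_missing)
            imputed.loc[col.isna(), sample] = draws

    ref, other = matrix.group_names
    a = imputed[matrix.samples_of(ref)].to_numpy()
    b = imputed[matrix.samples_of(other)].to_numpy()
    log2fc = b.mean(axis=1) - a.mean(axis=1)
    tstat, pval = stats.ttest_ind(b, a, axis=1)
    _, qval, _, _ = multipletests(pval, method="fdr_bh")
    significant = (qval <= alpha) & (np.abs(log2fc) >= fc_threshold)
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "t": tstat,
            "pvalue": pval,
            "qvalue": qval,
            "significant": significant,
        },
        index=matrix.values.index,
    )


def complex_level_sums(
    matrix: QuantMatrix, complexes: Sequence[ModuleDefinition]
) -> pd.DataFrame:
    """Summed member intensities per complex, then group mean +- sd.

    Complexes with no matched members are omitted with a warning.
    """
    if not complexes:
        raise ValueError("no complex definitions given")
    rows = []
    for cx in complexes:
        present = [p for p in cx.member_proteins if p in matrix.values.index]
        if not present:
            logger.warning("complex %s: no members in matrix; omitted", cx.name)
            continue
        missing = set(cx.member_proteins) - set(present)
        if missing:
            logger.info("complex %s: members absent: %s", cx.name, sorted(missing))
        sums = matrix.values.loc[present].fillna(0).sum(axis=0)
        row: dict[str, float | str | int] = {"complex": cx.name, "n_members": len(present)}
        for g in matrix.group_names:
            vals = sums[matrix.samples_of(g)]
            row[f"{g}_mean"] = float(vals.mean())
            row[f"{g}_sd"] = float(vals.std(ddof=1))
        rows.append(row)
    return pd.DataFrame(rows)


def compartment_summary(
    matrix: QuantMatrix, assignment: Mapping[str, str]
) -> pd.DataFrame:
    """Percent of total intensity per subcellular compartment, per sample.

    Proteins without an assignment are bucketed as ``unassigned``.
    Percentages sum to 100 in every sample. A ``mean`` column averages
    over samples.
    """
    labels = pd.Series(
        [assignment.get(p, "unassigned") for p in matrix.values.index],
        index=matrix.values.index,
    )
    totals = matrix.values.fillna(0).groupby(labels).sum()
    pct = totals.div(totals.sum(axis=0), axis=1) * 100.0
    pct["mean"] = pct[matrix.values.columns].mean(axis=1)
    return pct.sort_values("mean", ascending=False)


# ---------------------------------------------------------------------------
# File interfaces


def read_quant_tsv(path: str | Path, groups: Mapping[str, str]) -> QuantMatrix:
    """Quant matrix TSV: first column protein_group, then sample columns."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return QuantMatrix(df, dict(groups))


def write_quant_tsv(matrix: QuantMatrix, path: str | Path) -> None:
    out = matrix.values.copy()
    out.index.name = "protein_group"
    out.to_csv(path, sep="\t")


def read_groups_tsv(path: str | Path) -> dict[str, str]:
    """Group map TSV: columns sample_id, group."""
    df = pd.read_csv(path, sep="\t")
    if not {"sample_id", "group"} <= set(df.columns):
        raise ValueError(f"{path}: need columns sample_id, group")
    return dict(zip(df["sample_id"].astype(str), df["group"].astype(str)))
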