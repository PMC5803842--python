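"""Relative qPCR quantification: 2^-ddCt fold changes with replicate error.

Implements the Livak method as used for leaf-vs-storage-root comparisons:
technical replicates are averaged per biological replicate (avoiding
pseudo-replication), dCt = Ct_target - Ct_reference per biological
replicate, ddCt subtracts the mean calibrator dCt, and the fold change is
2^-ddCt.  The reported fold is the mean of per-replicate folds with its
standard error; significance is a two-sided two-sample Student's t-test on
dCt (condition vs calibrator) — the scale on which normality is plausible —
with Welch's test available by flag.  Stars use strict thresholds
(p < 0.05 / 0.01 / 0.001), so p = 0.05 exactly is not significant.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from ptbscan.errors import FormatError, ParameterError

logger = logging.getLogger(__name__)

CT_COLUMNS = ["gene", "condition", "bio_rep", "tech_rep", "ct"]


@dataclass(frozen=True)
class FoldChangeResult:
    """Fold change of one gene in one condition relative to the calibrator."""

    gene: str
    condition: str
    fold: float
    se: float
    p: float | None
    stars: str
    n_bio: int


def read_ct_table(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Read a delimited Ct table with header gene,condition,bio_rep,tech_rep,ct."""
    path = Path(path)
    df = pd.read_csv(path, sep=sep, engine="python")
    missing = [c for c in CT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing Ct table columns {missing}")
    df = df[CT_COLUMNS].copy()
    df["ct"] = pd.to_numeric(df["ct"], errors="raise")
    validate_ct_table(df)
    return df


def validate_ct_table(table: pd.DataFrame) -> None:
    if (table["ct"] <= 0).any():
        bad = table.loc[table["ct"] <= 0]
        raise FormatError(f"non-positive Ct values for {sorted(bad['gene'].unique())}")


def _bio_rep_means(table: pd.DataFrame, gene: str) -> pd.DataFrame:
    """Collapse technical replicates by mean per (condition, bio_rep)."""
    sub = table[table["gene"] == gene]
    return sub.groupby(["condition", "bio_rep"], sort=False)["ct"].mean().reset_index()


def stars(p: float | None) -> str:
    """Significance stars at strict thresholds; absent p -> 'ns'."""
    if p is None or (isinstance(p, float) and math.isnan(p)):
        return "ns"
    if not 0 <= p <= 1:
        raise ParameterError(f"p-value {p} outside [0,1]")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def delta_delta_ct(
    table: pd.DataFrame,
    gene: str,
    reference_gene: str,
    calibrator_condition: str,
    welch: bool = False,
) -> list[FoldChangeResult]:
    """2^-ddCt fold changes of ``gene`` per condition, relative to the calibrator.

    Returns one :class:`FoldChangeResult` per condition present for the
    gene (calibrator included, with fold 1 by construction).  Requires the
    reference gene in every condition of the gene, and matched biological
    replicate labels between gene and reference.
    """
    validate_ct_table(table)
    for g in (gene, reference_gene):
        if g not in set(table["gene"]):
            raise ParameterError(f"gene {g!r} not present in the Ct table")
    gene_ct = _bio_rep_means(table, gene)
    ref_ct = _bio_rep_means(table, reference_gene)
    conditions = list(dict.fromkeys(gene_ct["condition"]))
    if calibrator_condition not in conditions:
        raise ParameterError(f"calibrator condition {calibrator_condition!r} not present for gene {gene!r}")

    dct: dict[str, np.ndarray] = {}
    for cond in conditions:
        g = gene_ct[gene_ct["condition"] == cond].set_index("bio_rep")["ct"]
        r = ref_ct[ref_ct["condition"] == cond].set_index("bio_rep")["ct"]
        common = g.index.intersection(r.index)
        if len(common) == 0:
            raise FormatError(
                f"reference gene {reference_gene!r} missing (no shared biological replicates) "
                f"in condition {cond!r}"
            )
        dct[cond] = (g.loc[common] - r.loc[common]).to_numpy(dtype=float)

    cal = dct[calibrator_condition]
    cal_mean = float(np.mean(cal))
    results = []
    for cond in conditions:
        ddct = dct[cond] - cal_mean
        folds = np.exp2(-ddct)
        n = len(folds)
        se = float(np.std(folds, ddof=1) / math.sqrt(n)) if n > 1 else float("nan")
        if cond == calibrator_condition:
            # fold 1 by construction: the calibrator is its own baseline
            results.append(FoldChangeResult(gene, cond, 1.0, se, None, "ns", n))
            continue
        fold = float(np.mean(folds))
        if n < 2 or len(cal) < 2:
            logger.warning("gene %s condition %s: <2 biological replicates; p-value not computed", gene, cond)
            p = None
        elif np.var(dct[cond]) == 0.0 and np.var(cal) == 0.0:
            # degenerate noise-free groups: equal means -> no evidence, else certain
            p = 1.0 if np.isclose(np.mean(dct[cond]), cal_mean) else 0.0
        else:
            tt = stats.ttest_ind(dct[cond], cal, equal_var=not welch)
            p = float(tt.pvalue)
        results.append(FoldChangeResult(gene, cond, fold, se, p, stars(p), n))
    return results


def fold_change_table(results: list[FoldChangeResult]) -> pd.DataFrame:
    """Serializable table: gene, condition, fold, se, p, stars, n_bio."""
    return pd.DataFrame(
        {
            "gene": [r.gene for r in results],
            "condition": [r.condition for r in results],
            "fold": [r.fold for r in results],
            "se": [r.se for r in results],
            "p": [r.p if r.p is not None else float("nan") for r in results],
            "stars": [r.stars for r in results],
            "n_bio": [r.n_bio for r in results],
        }
    )
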