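"""Two-mutant expression filter defining the regulated gene set.

The design mirrors the classic switch/cofactor genetics: target genes are
down-regulated in the TF-null mutant (``svb``) and, because without its
cofactor the TF acts as a dominant repressor, drop at least a further
two-fold in the cofactor mutant (``pri``). Per-gene differential statistics
use a Welch two-sample test on log2 intensities with Benjamini–Hochberg
adjustment; genes showing no variation in either contrast form the negative
control set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger("crmkit")

CONDITIONS = ("wt", "svb", "pri")


@dataclass
class ExpressionMatrix:
    """Genes x samples log2 intensities plus a sample -> condition map."""

    values: pd.DataFrame
    conditions: dict[str, str]

    def __post_init__(self) -> None:
        unknown = set(self.conditions.values()) - set(CONDITIONS)
        if unknown:
            raise ValueError(f"unknown conditions {sorted(unknown)}")
        missing = [c for c in CONDITIONS if list(self.conditions.values()).count(c) < 2]
        if missing:
            raise ValueError(f"need >= 2 replicates for each of {CONDITIONS}; short: {missing}")
        absent = set(self.conditions) - set(self.values.columns)
        if absent:
            raise ValueError(f"condition map names unknown samples {sorted(absent)}")

    def samples(self, condition: str) -> list[str]:
        return [s for s, c in self.conditions.items() if c == condition]

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)


@dataclass
class SelectionParams:
    """Constants of the target/control selection.

    ``fold`` is the required further fold-drop in the cofactor mutant
    relative to the TF mutant; ``top_n`` caps the regulated set;
    ``control_p_min``/``control_fdr_min`` define "irrelevant variation" for
    the negative control set of size ``control_n``.
    """

    fold: float = 2.0
    top_n: int = 150
    fdr_pri: float = 0.01
    control_p_min: float = 0.8
    control_fdr_min: float = 0.99
    control_n: int = 100
    seed: int = 0
    pri_reference: str = "svb"  # "svb": further drop vs TF mutant; "wt": plain 2-fold vs wt

    def __post_init__(self) -> None:
        if self.fold <= 1:
            raise ValueError("fold must exceed 1")
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")


def differential(matrix: ExpressionMatrix, cond_a: str, cond_b: str) -> pd.DataFrame:
    """Per-gene Welch test of cond_a vs cond_b with BH adjustment.

    Returns a DataFrame indexed by gene with columns ``log2fc``
    (mean(cond_a) − mean(cond_b)), ``p``, ``fdr`` and ``degenerate`` (True
    where both groups had zero variance and the equal-means rule set p to
    0 or 1).
    """
    a = matrix.values[matrix.samples(cond_a)].to_numpy(dtype=float)
    b = matrix.values[matrix.samples(cond_b)].to_numpy(dtype=float)
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    degenerate = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    p = np.where(degenerate, np.where(log2fc != 0, 0.0, 1.0), p)
    if degenerate.any():
        log.warning("differential %s vs %s: %d genes with zero variance in both groups",
                    cond_a, cond_b, int(degenerate.sum()))
    p = np.nan_to_num(p, nan=1.0)
    fdr = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {"log2fc": log2fc, "p": p, "fdr": fdr, "degenerate": degenerate},
        index=matrix.values.index,
    )


def differential_all(matrix: ExpressionMatrix) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(svb vs wt, pri vs wt) differential tables."""
    return differential(matrix, "svb", "wt"), differential(matrix, "pri", "wt")


def select_targets(diff_svb: pd.DataFrame, diff_pri: pd.DataFrame,
                   params: SelectionParams | None = None) -> list[str]:
    """The regulated gene set: down in svb, a further >= ``fold``-fold down
    in pri (FDR-gated), ranked by pri log-fold-change, truncated to top_n.
    """
    params = params or SelectionParams()
    if not diff_svb.index.equals(diff_pri.index):
        raise ValueError("differential tables cover different genes")
    margin = np.log2(params.fold)
    down_svb = diff_svb["log2fc"] < 0
    if params.pri_reference == "svb":
        further = diff_pri["log2fc"] <= diff_svb["log2fc"] - margin
    elif params.pri_reference == "wt":
        further = diff_pri["log2fc"] <= -margin
    else:
        raise ValueError("pri_reference must be 'svb' or 'wt'")
    gated = diff_pri["fdr"] <= params.fdr_pri
    keep = diff_pri[down_svb & further & gated]
    order = keep.assign(_gene=keep.index).sort_values(["log2fc", "_gene"]).index
    return list(order[: params.top_n])


def select_controls(diff_svb: pd.DataFrame, diff_pri: pd.DataFrame,
                    params: SelectionParams | None = None) -> list[str]:
    """Genes with irrelevant variation in both contrasts, uniformly sampled."""
    params = params or SelectionParams()
    p_min = np.minimum(diff_svb["p"], diff_pri["p"])
    fdr_min = np.minimum(diff_svb["fdr"], diff_pri["fdr"])
    eligible = sorted(diff_svb.index[(p_min > params.control_p_min)
                                     & (fdr_min > params.control_fdr_min)])
    if len(eligible) <= params.control_n:
        return eligible
    rng = np.random.default_rng(params.seed)
    idx = rng.choice(len(eligible), size=params.control_n, replace=False)
    return sorted(eligible[i] for i in idx)
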