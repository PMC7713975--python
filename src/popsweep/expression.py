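"""qPCR relative quantification (2^-ddCt) and DE-table thresholding.

Per replicate, dCt = Ct_target - Ct_reference; ddCt subtracts the mean dCt
of the calibrator condition (Livak convention), and the relative quantity
is RQ = 2^-ddCt.  Significance per condition is a Welch two-sample t test
of the replicate dCt values against the calibrator's — dCt is the
approximately normal scale, RQ is not.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def ddct(
    ct: pd.DataFrame,
    calibrator: str,
    target_gene: str = "target",
    reference_gene: str = "reference",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Relative expression per condition by the 2^-ddCt method.

    ``ct`` must have columns (condition, replicate, gene, Ct) with both the
    target and the reference gene measured in every (condition, replicate).
    Returns (summary, replicates): summary has per-condition n, mean dCt,
    ddCt (of the mean), mean RQ (mean of per-replicate RQs) and the Welch
    t-test p-value vs the calibrator (1.0 for the calibrator itself and
    for zero-variance ties); replicates holds the per-replicate dCt, ddCt
    and RQ values.
    """
    required = {"condition", "replicate", "gene", "Ct"}
    if not required.issubset(ct.columns):
        raise ValueError(f"Ct table must have columns {sorted(required)}")
    wide = ct.pivot_table(index=["condition", "replicate"], columns="gene",
                          values="Ct", aggfunc="first")
    for gene in (target_gene, reference_gene):
        if gene not in wide.columns:
            raise ValueError(f"gene {gene!r} absent from the Ct table")
    missing = wide[wide[[target_gene, reference_gene]].isna().any(axis=1)]
    if len(missing):
        cond, rep = missing.index[0]
        raise ValueError(
            f"missing target or reference Ct for condition {cond!r} replicate {rep}")
    rep = wide.reset_index()
    rep["dct"] = rep[target_gene] - rep[reference_gene]
    cal = rep[rep["condition"] == calibrator]
    if len(cal) < 2:
        raise ValueError(f"calibrator {calibrator!r} needs >= 2 replicates")
    cal_mean = cal["dct"].mean()
    rep["ddct"] = rep["dct"] - cal_mean
    rep["rq"] = 2.0 ** (-rep["ddct"])

    rows = []
    cal_dct = cal["dct"].to_numpy()
    for cond, grp in rep.groupby("condition", sort=False):
        dct = grp["dct"].to_numpy()
        if cond == calibrator:
            p = 1.0
        elif np.ptp(dct) == 0 and np.ptp(cal_dct) == 0 and dct[0] == cal_dct[0]:
            p = 1.0
        else:
            p = float(stats.ttest_ind(dct, cal_dct, equal_var=False).pvalue)
        rows.append({
            "condition": cond,
            "n": len(grp),
            "mean_dct": float(dct.mean()),
            "ddct": float(dct.mean() - cal_mean),
            "rq": float(grp["rq"].mean()),
            "pvalue": p,
        })
    summary = pd.DataFrame(rows)
    keep = ["condition", "replicate", "dct", "ddct", "rq"]
    return summary, rep[keep].copy()


def de_flag(
    de: pd.DataFrame, fdr_max: float = 0.05, min_abs_log2fc: float = 2.0
) -> tuple[set[str], pd.DataFrame]:
    """Differential-expression thresholding on a (gene, log2fc, fdr) table.

    A gene is flagged when fdr < fdr_max AND |log2fc| > min_abs_log2fc —
    both strict, so log2fc exactly at the bound is NOT flagged.  Returns
    (flagged gene set, volcano-ready table with a ``flagged`` column).
    """
    required = {"gene", "log2fc", "fdr"}
    if not required.issubset(de.columns):
        raise ValueError(f"DE table must have columns {sorted(required)}")
    if ((de["fdr"] < 0) | (de["fdr"] > 1)).any():
        raise ValueError("fdr values must lie in [0, 1]")
    out = de.copy()
    out["flagged"] = (out["fdr"] < fdr_max) & (out["log2fc"].abs() > min_abs_log2fc)
    return set(out.loc[out["flagged"], "gene"]), out
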