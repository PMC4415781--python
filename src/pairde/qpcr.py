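"""Relative quantification by the 2^-ddCt method and array concordance.

dCt is the target gene's Ct minus the reference gene's Ct in the same
sample; ddCt subtracts the paired control (normal) sample's dCt from the
tumor sample's dCt; fold change is 2^-ddCt, so log2(fold change) = -ddCt
exactly and a fold change above 1 means higher expression in tumor.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .io import CT_RANGE, QPCRTable


def _check_ct(value: float, name: str) -> None:
    if not (CT_RANGE[0] < value <= CT_RANGE[1]):
        raise ValueError(f"{name} must lie in (0, 45], got {value}")


def delta_ct(ct_target: float, ct_reference: float) -> float:
    """Ct of the target minus Ct of the reference gene (same well/sample)."""
    _check_ct(ct_target, "ct_target")
    _check_ct(ct_reference, "ct_reference")
    return ct_target - ct_reference


@dataclasses.dataclass(frozen=True)
class FoldChangeRecord:
    gene: str
    pair: str
    dct_sample: float   # tumor dCt, cycles
    dct_control: float  # paired normal dCt, cycles
    ddct: float
    fc: float

    def __post_init__(self) -> None:
        if self.fc <= 0:
            raise ValueError("fold change must be positive")


def ddct_fold_change(dct_sample: float, dct_control: float,
                     gene: str = "", pair: str = "") -> FoldChangeRecord:
    """ddCt = sample dCt - control dCt; fold change = 2^-ddCt."""
    ddct = dct_sample - dct_control
    return FoldChangeRecord(gene=gene, pair=pair, dct_sample=dct_sample,
                            dct_control=dct_control, ddct=ddct, fc=float(2.0 ** -ddct))


def fold_changes(table: QPCRTable) -> pd.DataFrame:
    """Per (gene, pair) fold changes from a qPCR Ct table.

    The tumor sample of each pair is the "sample", its normal partner the
    control.  Returns columns gene, pair, dct_sample, dct_control, ddct, fc.
    """
    rows = []
    df = table.rows
    for (gene, pair), grp in df.groupby(["gene", "pair"], sort=True):
        tum = grp[grp["condition"] == "tumor"]
        nrm = grp[grp["condition"] == "normal"]
        if len(tum) != 1 or len(nrm) != 1:
            raise ValueError(f"gene {gene!r} pair {pair!r} needs exactly one tumor "
                             f"and one normal measurement")
        dct_t = delta_ct(float(tum["ct_target"].iloc[0]), float(tum["ct_reference"].iloc[0]))
        dct_n = delta_ct(float(nrm["ct_target"].iloc[0]), float(nrm["ct_reference"].iloc[0]))
        rec = ddct_fold_change(dct_t, dct_n, gene=str(gene), pair=str(pair))
        rows.append(dataclasses.asdict(rec))
    return pd.DataFrame(rows)


def per_gene_fold_change(fc_table: pd.DataFrame) -> pd.Series:
    """Geometric-mean fold change per gene across pairs (mean of log2 fc)."""
    log2fc = np.log2(fc_table["fc"])
    return (2.0 ** log2fc.groupby(fc_table["gene"]).mean()).rename("fc")


def concordance(qpcr_fc: pd.Series, array_log2fc: pd.Series) -> dict:
    """Direction agreement and rank correlation between qPCR and array.

    *qpcr_fc*: fold change per gene (linear scale); *array_log2fc*: the
    array's log2 fold change per gene.  Agreement per gene means
    (fc > 1) == (log2fc > 0).  Returns per-gene table, agreement fraction,
    and the Spearman correlation between log2(fc) and array log2fc.
    """
    genes = sorted(set(qpcr_fc.index) & set(array_log2fc.index))
    if not genes:
        raise ValueError("no genes shared between qPCR and array tables")
    q = qpcr_fc.loc[genes].astype(float)
    a = array_log2fc.loc[genes].astype(float)
    agree = (q > 1.0) == (a > 0.0)
    if len(genes) >= 3 and q.nunique() > 1 and a.nunique() > 1:
        rho = float(stats.spearmanr(np.log2(q), a).statistic)
    else:
        rho = float("nan")
    per_gene = pd.DataFrame({
        "gene": genes,
        "qpcr_fc": q.to_numpy(),
        "qpcr_log2fc": np.log2(q.to_numpy()),
        "array_log2fc": a.to_numpy(),
        "agree": agree.to_numpy(),
    })
    return {
        "per_gene": per_gene,
        "agreement": float(agree.mean()),
        "n_genes": len(genes),
        "spearman_rho": rho,
    }
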