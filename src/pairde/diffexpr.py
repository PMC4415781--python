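"""Paired differential expression with empirical-Bayes moderated t-statistics.

The paired design (one tumor and one adjacent-normal sample per patient)
reduces to a one-sample problem on within-patient log2 differences.  Per
probe, the mean difference is the log2 fold change and the sample variance
feeds an empirical-Bayes shrinkage step: the per-probe variances are modeled
as draws from a scaled inverse-chi-square prior with hyperparameters
``(d0, s0_sq)`` fitted by method of moments on log variances, and the
moderated t uses the posterior variance

    s2_post = (d0 * s0_sq + df * s2) / (d0 + df)

referred to Student t with ``d0 + df`` degrees of freedom (standard normal
in the ``d0 = inf`` limit; the ``d0 = 0`` limit is the classical paired t).
P-values are Benjamini-Hochberg adjusted, and a gene is called
differentially expressed under the triple threshold: fold change > 2
(|log2FC| > 1), P < 0.01 and FDR < 0.01.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix


@dataclasses.dataclass(frozen=True)
class EBHyperparams:
    """Prior degrees of freedom and prior variance of the variance model.

    ``d0 = inf`` collapses every probe onto the common prior variance;
    ``d0 = 0`` disables shrinkage (classical paired t)."""

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if not (self.d0 >= 0):
            raise ValueError("d0 must be >= 0 (inf allowed)")
        if not (self.s0_sq > 0):
            raise ValueError("s0_sq must be positive")


def paired_differences(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Probe x pair matrix of (tumor - normal) log2 differences.

    Raises ``DesignError`` naming any pair without exactly one tumor and one
    normal sample.
    """
    pairs = matrix.complete_pairs()
    cols = {}
    for pid in sorted(pairs):
        t, nrm = pairs[pid]
        cols[pid] = matrix.values[t].to_numpy() - matrix.values[nrm].to_numpy()
    return pd.DataFrame(cols, index=matrix.probe_ids)


def fit_gene_models(diffs: pd.DataFrame) -> pd.DataFrame:
    """Per-probe mean difference, sample variance and residual df.

    ``log2fc`` is the row mean, ``s2`` the row sample variance (denominator
    ``n_pairs - 1``), ``df = n_pairs - 1``.  Zero-variance probes are
    retained; shrinkage handles them.
    """
    n = diffs.shape[1]
    if n < 2:
        raise ValueError("need >= 2 pairs to fit per-probe models")
    x = diffs.to_numpy(dtype=float)
    log2fc = x.mean(axis=1)
    s2 = x.var(axis=1, ddof=1)
    return pd.DataFrame({"log2fc": log2fc, "s2": s2, "df": float(n - 1)}, index=diffs.index)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on the monotone decreasing map)."""
    if y <= 0:
        return math.inf
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(special.polygamma(1, x))
        tetra = float(special.polygamma(2, x))
        delta = tri * (1.0 - tri / y) / tetra
        x += delta
        if abs(delta) < 1e-10 * x:
            break
    return x


def estimate_eb_hyperparams(s2: np.ndarray | pd.Series, df: float) -> EBHyperparams:
    """Method-of-moments fit of the scaled inverse-chi-square variance prior.

    Under the model ``s2_g ~ s0_sq * F(df, d0)`` the log variances satisfy

        E[log s2]   = log s0_sq + digamma(df/2) - log(df/2)
                      - digamma(d0/2) + log(d0/2)
        Var[log s2] = trigamma(df/2) + trigamma(d0/2)

    so ``d0`` comes from inverting the trigamma function on the excess
    variance of log s2 and ``s0_sq`` from the mean.  When the empirical
    variance of log s2 does not exceed ``trigamma(df/2)`` the prior is
    degenerate and ``d0 = inf`` is returned.
    """
    s2 = np.asarray(s2, dtype=float)
    pos = s2[s2 > 0]
    if pos.size < 10:
        raise ValueError("need >= 10 probes with positive s2 to estimate hyperparameters")
    z = np.log(pos)
    e_mean = float(z.mean())
    e_var = float(z.var(ddof=1))
    tri_df = float(special.polygamma(1, df / 2.0))
    excess = e_var - tri_df
    if np.allclose(pos, pos[0]):
        # all observed variances identical: degenerate prior at that value
        return EBHyperparams(d0=math.inf, s0_sq=float(pos[0]))
    offset = float(special.digamma(df / 2.0)) - math.log(df / 2.0)
    if excess <= 0:
        return EBHyperparams(d0=math.inf, s0_sq=float(math.exp(e_mean - offset)))
    half_d0 = _trigamma_inverse(excess)
    d0 = 2.0 * half_d0
    log_s0 = e_mean - offset + float(special.digamma(half_d0)) - math.log(half_d0)
    return EBHyperparams(d0=d0, s0_sq=float(math.exp(log_s0)))


def moderated_t(
    log2fc: np.ndarray | pd.Series,
    s2: np.ndarray | pd.Series,
    df: float,
    hyper: EBHyperparams,
    n_pairs: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Moderated t-statistics and two-sided P-values.

    The posterior variance shrinks ``s2`` toward ``s0_sq`` with weight
    ``d0``; the reference distribution gains the prior degrees of freedom
    (Student t with ``d0 + df`` df; standard normal when ``d0 = inf``).
    """
    log2fc = np.asarray(log2fc, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    if math.isinf(hyper.d0):
        s2_post = np.full_like(s2, hyper.s0_sq)
        df_total = np.inf
    else:
        s2_post = (hyper.d0 * hyper.s0_sq + df * s2) / (hyper.d0 + df)
        df_total = hyper.d0 + df
    t = log2fc / np.sqrt(s2_post / n_pairs)
    p = 2.0 * stats.t.sf(np.abs(t), df=df_total)
    return t, np.minimum(p, 1.0)


def bh_adjust(p: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_de(
    records: pd.DataFrame,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.01,
    fdr_threshold: float = 0.01,
) -> pd.DataFrame:
    """Assign up/down/ns status under the triple threshold.

    ``up``  iff log2fc >  log2(fc_threshold) and p < p_threshold and fdr < fdr_threshold;
    ``down`` symmetric with log2fc < -log2(fc_threshold); otherwise ``ns``.
    """
    if fc_threshold <= 0 or p_threshold <= 0 or fdr_threshold <= 0:
        raise ValueError("thresholds must be positive")
    lfc_cut = math.log2(fc_threshold)
    out = records.copy()
    sig = (out["p"] < p_threshold) & (out["fdr"] < fdr_threshold)
    status = np.where(sig & (out["log2fc"] > lfc_cut), "up",
                      np.where(sig & (out["log2fc"] < -lfc_cut), "down", "ns"))
    out["status"] = status
    return out


def de_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Up/down counts split by biotype (mRNA / lncRNA)."""
    rows = []
    for bt in ("mRNA", "lncRNA"):
        sub = records[records["biotype"] == bt] if "biotype" in records else records.iloc[0:0]
        rows.append({"biotype": bt,
                     "up": int((sub["status"] == "up").sum()),
                     "down": int((sub["status"] == "down").sum())})
    return pd.DataFrame(rows)


def run_de(
    matrix: ExpressionMatrix,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.01,
    fdr_threshold: float = 0.01,
    hyper: EBHyperparams | None = None,
) -> pd.DataFrame:
    """Full per-probe differential expression table.

    Chains paired differences -> per-probe models -> empirical-Bayes
    hyperparameters (unless *hyper* is supplied, e.g. ``d0 = 0`` for the
    classical paired t) -> moderated t and P -> BH FDR -> triple-threshold
    status.  Columns: probe_id, gene_symbol, biotype, log2fc, s2, df, t_mod,
    p, fdr, status.
    """
    diffs = paired_differences(matrix)
    fits = fit_gene_models(diffs)
    n_pairs = diffs.shape[1]
    df = float(fits["df"].iloc[0])
    if hyper is None:
        hyper = estimate_eb_hyperparams(fits["s2"].to_numpy(), df)
    t, p = moderated_t(fits["log2fc"], fits["s2"], df, hyper, n_pairs)
    fdr = bh_adjust(p)
    out = pd.DataFrame({
        "probe_id": fits.index,
        "gene_symbol": matrix.probes["gene_symbol"].to_numpy(),
        "biotype": matrix.probes["biotype"].to_numpy(),
        "log2fc": fits["log2fc"].to_numpy(),
        "s2": fits["s2"].to_numpy(),
        "df": fits["df"].to_numpy(),
        "t_mod": t,
        "p": p,
        "fdr": fdr,
    })
    out = classify_de(out, fc_threshold, p_threshold, fdr_threshold)
    out.attrs["hyperparams"] = hyper
    return out
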