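"""Quantile normalization and sample-level quality control.

Normalization forces every sample column onto the common reference
distribution of row-rank means, the standard treatment for one-color array
intensities.  QC operationalizes the 3D-PCA + clustering triage of paired
cohorts: a sample is flagged when its squared Mahalanobis distance in the
top-3 principal-component space exceeds a chi-square(3) tail cutoff, and a
patient pair is dropped iff at least one of its members is flagged.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .io import DesignError, ExpressionMatrix

logger = logging.getLogger(__name__)


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize sample columns against the row-rank mean reference.

    After the transform every column holds the identical multiset of values
    (the means of the column-sorted rows), placed in each column's original
    rank order.  Ties within a column receive the mean of the reference
    values at the tied ranks.  Exactly idempotent on tie-free input.
    """
    x = matrix.values.to_numpy(dtype=float)
    if x.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    if np.isnan(x).any():
        bad = matrix.probe_ids[np.isnan(x).any(axis=1)]
        raise ValueError(f"NaN values in probes: {list(bad[:5])}")
    n, m = x.shape
    order = np.argsort(x, axis=0, kind="stable")
    sorted_x = np.take_along_axis(x, order, axis=0)
    reference = sorted_x.mean(axis=1)
    # exact idempotence: a rank whose values already agree across samples
    # keeps that value (float mean of identical values can be off 1 ulp)
    same = (sorted_x == sorted_x[:, [0]]).all(axis=1)
    reference[same] = sorted_x[same, 0]

    out = np.empty_like(x)
    for j in range(m):
        col_sorted = x[order[:, j], j]
        assigned = reference.copy()
        # average the reference over runs of tied values
        boundaries = np.flatnonzero(np.r_[True, col_sorted[1:] != col_sorted[:-1]])
        if boundaries.size < n:
            sums = np.add.reduceat(reference, boundaries)
            sizes = np.diff(np.r_[boundaries, n])
            means = sums / sizes
            assigned = np.repeat(means, sizes)
        out[order[:, j], j] = assigned
    return matrix.with_values(pd.DataFrame(out, index=matrix.probe_ids, columns=matrix.sample_ids))


@dataclasses.dataclass
class QCReport:
    """Per-sample PCA/outlier diagnostics and per-pair keep/drop decisions."""

    samples: pd.DataFrame  # index sample: pc1..pc3, mahal_sq, outlier, with_partner
    pairs: pd.DataFrame    # index pair_id: keep
    alpha: float
    skipped: bool = False

    @property
    def kept_pairs(self) -> list[str]:
        return list(self.pairs.index[self.pairs["keep"]])

    def apply(self, matrix: ExpressionMatrix) -> ExpressionMatrix:
        """Return the matrix restricted to samples of kept pairs."""
        if self.skipped:
            return matrix
        keep_pairs = set(self.kept_pairs)
        keep = [s for s in matrix.sample_ids if matrix.design.loc[s, "pair_id"] in keep_pairs]
        return matrix.subset_samples(keep)


def qc_flag_samples(matrix: ExpressionMatrix, alpha: float = 0.001) -> QCReport:
    """Flag outlying samples in principal-component space.

    PCA runs on sample profiles (probes as variables).  A sample is flagged
    when its squared Mahalanobis distance over the first three components
    exceeds the upper-``alpha`` quantile of chi-square(3); ``alpha = 0``
    flags nothing.  Average-linkage hierarchical clustering on 1 - Pearson
    correlation distance is recorded for the report (whether each sample
    co-clusters with its pair partner at the two-cluster cut).  A pair is
    dropped iff at least one member is flagged.
    """
    if not 0.0 <= alpha < 1.0:
        raise ValueError("alpha must be in [0, 1)")
    pairs = matrix.complete_pairs()
    n_samples = len(matrix.sample_ids)
    if n_samples < 4:
        logger.warning("QC skipped: only %d samples (<4)", n_samples)
        samples = pd.DataFrame(index=matrix.sample_ids)
        pair_df = pd.DataFrame({"keep": True}, index=pd.Index(sorted(pairs), name="pair_id"))
        return QCReport(samples=samples, pairs=pair_df, alpha=alpha, skipped=True)

    x = matrix.values.to_numpy(dtype=float).T  # samples x probes
    centered = x - x.mean(axis=0, keepdims=True)
    k = min(3, n_samples - 1)
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    scores = u[:, :k] * s[:k]
    variances = (s[:k] ** 2) / (n_samples - 1)
    variances = np.where(variances > 0, variances, np.inf)
    mahal_sq = ((scores ** 2) / variances).sum(axis=1)
    if alpha == 0.0:
        outlier = np.zeros(n_samples, dtype=bool)
    else:
        cutoff = stats.chi2.ppf(1.0 - alpha, df=3)
        outlier = mahal_sq > cutoff

    corr = np.corrcoef(x)
    dist = 1.0 - corr[np.triu_indices(n_samples, k=1)]
    link = hierarchy.linkage(np.clip(dist, 0.0, None), method="average")
    labels = hierarchy.fcluster(link, t=2, criterion="maxclust")
    label_of = dict(zip(matrix.sample_ids, labels))
    partner = {}
    for pid, (t, nrm) in pairs.items():
        partner[t], partner[nrm] = nrm, t
    with_partner = [label_of[s] == label_of.get(partner.get(s, s), None) for s in matrix.sample_ids]

    pc_cols = {f"pc{i + 1}": scores[:, i] if i < k else np.zeros(n_samples) for i in range(3)}
    samples = pd.DataFrame(
        {**pc_cols, "mahal_sq": mahal_sq, "outlier": outlier, "with_partner": with_partner},
        index=matrix.sample_ids,
    )
    keep = {pid: not (samples.loc[t, "outlier"] or samples.loc[nrm, "outlier"])
            for pid, (t, nrm) in pairs.items()}
    pair_df = pd.DataFrame({"keep": [keep[p] for p in sorted(keep)]},
                           index=pd.Index(sorted(keep), name="pair_id"))
    return QCReport(samples=samples, pairs=pair_df, alpha=alpha)
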