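"""Downstream utility of calibrated methylation.

Three analyses that ask whether calibrated (predicted-target) methylation is
a better stand-in for the target tissue than the raw surrogate measurements:

* a per-probe association scan of methylation on a binary outcome (simple
  linear regression; with a binary regressor the coefficient is exactly the
  case/control mean difference);
* an effect-size bias comparison: treating target-tissue effects as the gold
  standard, the fraction of probes where the calibrated effect is strictly
  closer to the truth than the raw surrogate effect;
* hierarchical clustering of samples (Euclidean distance on probes with
  complete data, average linkage by default) with Newick export and a
  cophenetic-correlation helper for comparing trees.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, linkage, to_tree
from scipy.spatial.distance import pdist, squareform

from .core_io import BetaMatrix, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationResult",
    "BiasComparison",
    "SampleDendrogram",
    "associate_outcome",
    "effect_bias_comparison",
    "cluster_samples",
    "cophenetic_correlation",
]


@dataclass
class AssociationResult:
    """Per-probe regression of methylation on a binary outcome.

    ``table`` columns: effect (case minus control mean), se, n, n_case,
    n_control. Probes where a group is unrepresented or variance is zero get
    NaN effects.
    """

    table: pd.DataFrame

    @property
    def probe_ids(self) -> list:
        return list(self.table.index)

    @property
    def effects(self) -> pd.Series:
        return self.table["effect"]


def associate_outcome(beta: BetaMatrix, outcome) -> AssociationResult:
    """Per-probe simple linear regression of methylation on a 0/1 outcome."""
    y = np.asarray(outcome, dtype=float)
    if y.shape != (beta.n_samples,):
        raise ValidationError("outcome vector is not aligned with the beta matrix samples")
    uniq = np.unique(y[~np.isnan(y)])
    if not np.all(np.isin(uniq, [0.0, 1.0])):
        raise ValidationError(f"outcome must be binary 0/1; saw values {uniq[:5]}")
    case = y == 1.0
    ctrl = y == 0.0
    if case.sum() < 2 or ctrl.sum() < 2:
        raise ValidationError("need at least 2 samples in each outcome group")
    A = beta.values
    obs = ~np.isnan(A)
    n1 = (obs & case[:, None]).sum(axis=0).astype(float)
    n0 = (obs & ctrl[:, None]).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        m1 = np.nansum(np.where(case[:, None], A, np.nan), axis=0) / np.where(n1 > 0, n1, np.nan)
        m0 = np.nansum(np.where(ctrl[:, None], A, np.nan), axis=0) / np.where(n0 > 0, n0, np.nan)
        effect = m1 - m0
        ss1 = np.nansum(np.where(case[:, None], (A - m1[None, :]) ** 2, np.nan), axis=0)
        ss0 = np.nansum(np.where(ctrl[:, None], (A - m0[None, :]) ** 2, np.nan), axis=0)
        df = n1 + n0 - 2.0
        sigma2 = (ss1 + ss0) / np.where(df > 0, df, np.nan)
        se = np.sqrt(sigma2 * (1.0 / n1 + 1.0 / n0))
    bad = (n1 < 1) | (n0 < 1)
    effect = np.where(bad, np.nan, effect)
    table = pd.DataFrame(
        {
            "effect": effect,
            "se": se,
            "n": (n1 + n0).astype(int),
            "n_case": n1.astype(int),
            "n_control": n0.astype(int),
        },
        index=beta.probe_ids,
    )
    return AssociationResult(table=table)


@dataclass
class BiasComparison:
    """Which of two effect estimates is closer to the gold standard, per probe."""

    fraction_calibrated_better: float
    n_better: int
    n_ties: int
    n_worse: int
    n_compared: int
    table: pd.DataFrame


def effect_bias_comparison(
    truth: AssociationResult,
    raw: AssociationResult,
    calibrated: AssociationResult,
) -> BiasComparison:
    """Fraction of probes where |calibrated - truth| < |raw - truth| strictly.

    Ties (equal absolute bias) are counted separately; the fraction's
    denominator is every probe with all three effects defined.
    """
    ids = truth.probe_ids
    if raw.probe_ids != ids or calibrated.probe_ids != ids:
        raise ValidationError("effect tables do not share an identical probe set/order")
    et = truth.effects.to_numpy()
    er = raw.effects.to_numpy()
    ec = calibrated.effects.to_numpy()
    ok = ~np.isnan(et) & ~np.isnan(er) & ~np.isnan(ec)
    dropped = int((~ok).sum())
    if dropped:
        logger.info("effect_bias_comparison: dropped %d probes with undefined effects", dropped)
    bias_raw = np.abs(er - et)
    bias_cal = np.abs(ec - et)
    better = ok & (bias_cal < bias_raw)
    ties = ok & (bias_cal == bias_raw)
    worse = ok & (bias_cal > bias_raw)
    n_compared = int(ok.sum())
    if n_compared == 0:
        raise ValidationError("no probes with defined effects in all three analyses")
    table = pd.DataFrame(
        {
            "effect_truth": et,
            "effect_raw": er,
            "effect_calibrated": ec,
            "bias_raw": bias_raw,
            "bias_calibrated": bias_cal,
            "calibrated_better": better,
        },
        index=ids,
    )
    return BiasComparison(
        fraction_calibrated_better=float(better.sum() / n_compared),
        n_better=int(better.sum()),
        n_ties=int(ties.sum()),
        n_worse=int(worse.sum()),
        n_compared=n_compared,
        table=table,
    )


@dataclass
class SampleDendrogram:
    """Hierarchical clustering of samples as a scipy linkage matrix."""

    linkage_matrix: np.ndarray
    sample_ids: list
    distance: str
    linkage_method: str
    n_probes_used: int

    def to_newick(self) -> str:
        """Serialize as a Newick string with branch lengths (merge-height
        differences; leaves sit at height 0)."""
        root = to_tree(self.linkage_matrix)

        def render(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.sample_ids[node.id]}:{length:.10g}"
            left = render(node.left, node.dist)
            right = render(node.right, node.dist)
            return f"({left},{right}):{length:.10g}"

        left = render(root.left, root.dist)
        right = render(root.right, root.dist)
        return f"({left},{right});"

    def cophenetic_matrix(self) -> pd.DataFrame:
        d = squareform(cophenet(self.linkage_matrix))
        return pd.DataFrame(d, index=self.sample_ids, columns=self.sample_ids)


def cluster_samples(
    beta,
    distance: str = "euclidean",
    linkage_method: str = "average",
) -> SampleDendrogram:
    """Agglomerative clustering of samples.

    Probes with any missing value are excluded from the distance computation
    (logged). Samples are processed in lexicographic id order so the result
    does not depend on input row order; trees built from row-permuted copies
    of a matrix are therefore identical.
    """
    if distance != "euclidean":
        raise ValidationError(f"unsupported distance {distance!r}")
    if linkage_method not in ("average", "complete", "ward"):
        raise ValidationError(f"unsupported linkage {linkage_method!r}")
    df = beta.data if isinstance(beta, BetaMatrix) else pd.DataFrame(beta)
    if df.shape[0] < 2:
        raise ValidationError("clustering needs at least 2 samples")
    complete = df.columns[~df.isna().any(axis=0)]
    n_dropped = df.shape[1] - len(complete)
    if n_dropped:
        logger.info("cluster_samples: excluded %d probes with missing values", n_dropped)
    if len(complete) == 0:
        raise ValidationError("no probes with complete data across samples")
    order = sorted(df.index)
    mat = df.loc[order, complete].to_numpy(dtype=float)
    dists = pdist(mat, metric="euclidean")
    Z = linkage(dists, method=linkage_method)
    return SampleDendrogram(
        linkage_matrix=Z,
        sample_ids=list(order),
        distance=distance,
        linkage_method=linkage_method,
        n_probes_used=len(complete),
    )


def cophenetic_correlation(a: SampleDendrogram, b: SampleDendrogram) -> float:
    """Pearson correlation between the cophenetic distances of two trees
    built on the same samples."""
    if set(a.sample_ids) != set(b.sample_ids):
        raise ValidationError("dendrograms were built on different sample sets")
    da = a.cophenetic_matrix()
    db = b.cophenetic_matrix().loc[a.sample_ids, a.sample_ids]
    iu = np.triu_indices(len(a.sample_ids), k=1)
    va = da.to_numpy()[iu]
    vb = db.to_numpy()[iu]
    return float(np.corrcoef(va, vb)[0, 1])
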