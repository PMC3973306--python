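"""Normalization and filtering of methylation array data.

Implements the standard chain from raw Infinium intensities to analysis-ready
beta matrices:

* beta recomputation ``M / (M + U + offset)`` with the conventional offset of
  100 intensity units;
* quality masking by detection p-value and bead count, and removal of samples
  with too many missing probes (masking thresholds are strict inequalities:
  ``P > 0.05`` masks for 27k-style data, ``P > 0.01`` or ``beads < 3`` for
  450k-style data, samples with ``> 20%`` missing probes are dropped);
* quantile normalization across samples (exact rank/mean construction on
  complete data; rank interpolation onto a common grid when values are
  missing);
* a simplified category-wise Infinium II -> Infinium I alignment: within each
  functional category and each sample, type II betas are mapped by a monotone
  empirical-quantile transform onto the distribution of that category's
  type I betas;
* removal of SNP-overlapping probes (flags are taken from the annotation
  table; the variant lookup itself is treated as given);
* extreme-probe filtering: probes constitutively methylated (pooled minimum
  beta above a threshold) or unmethylated (pooled maximum below a threshold)
  across all supplied subjects and tissues are removed before correlation
  summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .core_io import BetaMatrix, IntensitySet, ProbeAnnotation, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "QualityThresholds",
    "ExtremeProbeFilter",
    "PROFILE_27K",
    "PROFILE_450K",
    "DEFAULT_EXTREME_FILTERS",
    "compute_beta",
    "mask_low_quality",
    "drop_failed_samples",
    "quantile_normalize",
    "align_typeII_to_typeI",
    "filter_snp_probes",
    "filter_extreme_probes",
    "normalize_27k",
    "normalize_450k",
]


@dataclass(frozen=True)
class QualityThresholds:
    """Masking thresholds for probe-level quality control.

    A cell is masked when ``detection_p > detection_p_max`` or
    ``bead_count < min_bead_count``; a sample is dropped when its missing
    fraction strictly exceeds ``max_missing_fraction_per_sample``.
    """

    detection_p_max: float = 0.01
    min_bead_count: int = 3
    max_missing_fraction_per_sample: float = 0.20
    snp_filter: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.detection_p_max < 1.0):
            raise ValidationError("detection_p_max must be in (0, 1)")
        if self.min_bead_count < 0:
            raise ValidationError("min_bead_count must be >= 0")
        if not (0.0 < self.max_missing_fraction_per_sample <= 1.0):
            raise ValidationError("max_missing_fraction_per_sample must be in (0, 1]")


#: 27k-style profile: detection P > 0.05 masks, no bead-count information.
PROFILE_27K = QualityThresholds(detection_p_max=0.05, min_bead_count=0, snp_filter=False)
#: 450k-style profile: detection P > 0.01 or beads < 3 masks; sample QC at 20%.
PROFILE_450K = QualityThresholds(detection_p_max=0.01, min_bead_count=3, snp_filter=True)


@dataclass(frozen=True)
class ExtremeProbeFilter:
    """Remove probes with pooled min beta > ``min_beta_threshold`` or pooled
    max beta < ``max_beta_threshold`` across all subjects and tissues."""

    min_beta_threshold: float = 0.9
    max_beta_threshold: float = 0.1

    def __post_init__(self) -> None:
        if not (0.0 <= self.max_beta_threshold < self.min_beta_threshold <= 1.0):
            raise ValidationError(
                "require 0 <= max_beta_threshold < min_beta_threshold <= 1"
            )

    @property
    def label(self) -> str:
        return f"min>{self.min_beta_threshold:g}|max<{self.max_beta_threshold:g}"


DEFAULT_EXTREME_FILTERS = (
    ExtremeProbeFilter(0.9, 0.1),
    ExtremeProbeFilter(0.8, 0.2),
)


def compute_beta(intensities: IntensitySet, offset: float = 100.0) -> BetaMatrix:
    """Beta = methylated / (methylated + unmethylated + offset), elementwise.

    With ``offset > 0`` the result is strictly below 1. The degenerate cell
    M = U = offset = 0 is defined as beta 0.
    """
    if offset < 0:
        raise ValidationError("offset must be nonnegative")
    m = intensities.methylated.to_numpy(dtype=float)
    u = intensities.unmethylated.to_numpy(dtype=float)
    denom = m + u + offset
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(denom > 0, m / np.where(denom > 0, denom, 1.0), 0.0)
    beta = np.where(np.isnan(m) | np.isnan(u), np.nan, beta)
    return BetaMatrix(
        pd.DataFrame(beta, index=intensities.sample_ids, columns=intensities.probe_ids)
    )


def mask_low_quality(
    beta: BetaMatrix, intensities: IntensitySet, thr: QualityThresholds
) -> BetaMatrix:
    """Set cells failing detection-p or bead-count criteria to missing."""
    if beta.sample_ids != intensities.sample_ids or beta.probe_ids != intensities.probe_ids:
        raise ValidationError("beta matrix and intensity set do not share sample/probe ids")
    mask = np.zeros(beta.values.shape, dtype=bool)
    if intensities.detection_p is not None:
        p = intensities.detection_p.to_numpy()
        mask |= p > thr.detection_p_max
    if intensities.bead_count is not None and thr.min_bead_count > 0:
        b = intensities.bead_count.to_numpy()
        mask |= b < thr.min_bead_count
    vals = beta.values.copy()
    vals[mask] = np.nan
    n_masked = int(mask.sum())
    if n_masked:
        logger.info("mask_low_quality: masked %d cells", n_masked)
    return BetaMatrix(pd.DataFrame(vals, index=beta.sample_ids, columns=beta.probe_ids))


def drop_failed_samples(beta: BetaMatrix, thr: QualityThresholds) -> BetaMatrix:
    """Drop samples whose missing fraction strictly exceeds the QC threshold."""
    frac = beta.missing_mask.mean(axis=1)
    keep = frac <= thr.max_missing_fraction_per_sample
    removed = [s for s, k in zip(beta.sample_ids, keep) if not k]
    if removed:
        logger.info("drop_failed_samples: removed %s", removed)
    if not keep.any():
        raise ValidationError("all samples exceed the missing-fraction threshold")
    return BetaMatrix(beta.data.loc[keep.to_numpy()].copy())


def quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize rows (samples) of a matrix of reals.

    On complete data every sample's sorted value vector becomes the
    across-sample mean of order statistics, so all sorted rows are identical
    and within-sample ranks are preserved. With missing values, each sample's
    sorted non-missing values are interpolated onto a common quantile grid of
    length equal to the maximum non-missing count to build the reference, and
    the reference is interpolated back onto each sample's own grid.
    """
    arr = values.to_numpy(dtype=float)
    n_samples = arr.shape[0]
    if n_samples < 2:
        raise ValidationError("quantile normalization needs at least 2 samples")
    finite = ~np.isnan(arr)
    counts = finite.sum(axis=1)
    if (counts < 2).any():
        bad = [values.index[i] for i in np.where(counts < 2)[0]]
        raise ValidationError(f"samples with <2 non-missing values: {bad[:5]}")
    grid_len = int(counts.max())
    grid = np.linspace(0.0, 1.0, grid_len)
    ref = np.zeros(grid_len)
    sorted_rows = []
    for i in range(n_samples):
        v = np.sort(arr[i, finite[i]])
        sorted_rows.append(v)
        if v.size == grid_len:
            ref += v
        else:
            ref += np.interp(grid, np.linspace(0.0, 1.0, v.size), v)
    ref /= n_samples
    out = np.full_like(arr, np.nan)
    for i in range(n_samples):
        idx = np.where(finite[i])[0]
        k = idx.size
        order = np.argsort(arr[i, idx], kind="stable")
        target = ref if k == grid_len else np.interp(np.linspace(0.0, 1.0, k), grid, ref)
        out[i, idx[order]] = target
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def align_typeII_to_typeI(beta: BetaMatrix, ann: ProbeAnnotation) -> BetaMatrix:
    """Map Infinium II betas onto the type I distribution, per category/sample.

    Within each functional category and each sample, a type II beta at
    empirical quantile q among that sample's type II values is replaced by the
    q-quantile of the sample's type I values. Type I betas are unchanged; the
    mapping is monotone; output stays in [0, 1].
    """
    table = ann.for_probes(beta.probe_ids)
    df = beta.data.copy()
    arr = df.to_numpy()
    col_pos = {p: j for j, p in enumerate(df.columns)}
    for category, sub in table.groupby("category", sort=True):
        t2 = [p for p in sub.index[sub["design_type"] == "II"]]
        if not t2:
            continue
        t1 = [p for p in sub.index[sub["design_type"] == "I"]]
        if not t1:
            raise ValidationError(
                f"category {category!r} has type II probes but no type I probes"
            )
        j1 = [col_pos[p] for p in t1]
        j2 = [col_pos[p] for p in t2]
        for i in range(arr.shape[0]):
            ref = arr[i, j1]
            ref = ref[~np.isnan(ref)]
            v = arr[i, j2]
            obs = ~np.isnan(v)
            if not obs.any():
                continue
            if ref.size == 0:
                raise ValidationError(
                    f"category {category!r}: sample {df.index[i]!r} has no "
                    "non-missing type I betas to build a reference"
                )
            k = int(obs.sum())
            if k == 1:
                q = np.array([0.5])
            else:
                q = (rankdata(v[obs], method="average") - 1.0) / (k - 1.0)
            mapped = np.quantile(ref, q)
            out_row = arr[i, j2]
            out_row[obs] = mapped
            arr[i, j2] = out_row
    return BetaMatrix(pd.DataFrame(arr, index=df.index, columns=df.columns))


def filter_snp_probes(beta: BetaMatrix, ann: ProbeAnnotation) -> BetaMatrix:
    """Remove probes whose annotation carries a SNP-overlap flag."""
    table = ann.for_probes(beta.probe_ids)
    keep = [p for p in beta.probe_ids if not table.loc[p, "snp_flag"]]
    n_removed = beta.n_probes - len(keep)
    if n_removed:
        logger.info("filter_snp_probes: removed %d SNP-flagged probes", n_removed)
    if not keep:
        logger.warning("filter_snp_probes: all probes were SNP-flagged")
    return BetaMatrix(beta.data[keep].copy())


def filter_extreme_probes(
    matrices: Sequence[BetaMatrix], f: ExtremeProbeFilter
) -> list:
    """Return probe ids retained after the extreme-probe filter.

    The per-probe minimum and maximum pool all supplied matrices (all
    subjects and tissues). A probe is removed when its pooled minimum exceeds
    ``min_beta_threshold`` or its pooled maximum falls below
    ``max_beta_threshold``. Probes with no non-missing values anywhere are
    retained with a warning (they cannot be classified).
    """
    if not matrices:
        raise ValidationError("no matrices supplied")
    probes = matrices[0].probe_ids
    stacked = []
    for m in matrices:
        if set(m.probe_ids) != set(probes):
            raise ValidationError("matrices do not share an identical probe set")
        stacked.append(m.data[probes].to_numpy())
    pool = np.vstack(stacked)
    if not np.isfinite(pool).any():
        raise ValidationError("pooled beta values are all missing")
    with np.errstate(all="ignore"):
        pooled_min = np.nanmin(pool, axis=0)
        pooled_max = np.nanmax(pool, axis=0)
    all_missing = np.isnan(pooled_min)
    if all_missing.any():
        logger.warning(
            "filter_extreme_probes: %d probes have no data and are retained",
            int(all_missing.sum()),
        )
    with np.errstate(invalid="ignore"):
        remove = (pooled_min > f.min_beta_threshold) | (pooled_max < f.max_beta_threshold)
    remove &= ~all_missing
    kept = [p for p, r in zip(probes, remove) if not r]
    logger.info(
        "filter_extreme_probes(%s): removed %d of %d probes",
        f.label,
        int(remove.sum()),
        len(probes),
    )
    return kept


# -- profile pipelines ----------------------------------------------------


def normalize_27k(
    intensities: IntensitySet,
    thr: QualityThresholds = PROFILE_27K,
    offset: float = 100.0,
) -> BetaMatrix:
    """27k-style chain: pooled M+U quantile normalization, beta recomputation,
    detection-p masking."""
    pooled = pd.concat(
        [
            intensities.methylated.add_suffix("::M"),
            intensities.unmethylated.add_suffix("::U"),
        ],
        axis=1,
    )
    normed = quantile_normalize(pooled)
    n_probes = intensities.methylated.shape[1]
    m = normed.iloc[:, :n_probes]
    u = normed.iloc[:, n_probes:]
    m.columns = intensities.probe_ids
    u.columns = intensities.probe_ids
    qn = IntensitySet(
        methylated=m.clip(lower=0.0),
        unmethylated=u.clip(lower=0.0),
        detection_p=intensities.detection_p,
        bead_count=None,
    )
    beta = compute_beta(qn, offset=offset)
    return mask_low_quality(beta, qn, thr)


def normalize_450k(
    intensities: IntensitySet,
    ann: ProbeAnnotation,
    thr: QualityThresholds = PROFILE_450K,
    offset: float = 100.0,
) -> BetaMatrix:
    """Simplified 450k chain: beta recomputation, quality masking, sample QC,
    SNP-probe removal, sample-wise quantile normalization of betas, and
    category-wise Infinium II -> I alignment.

    Background and color-bias correction are accepted as pre-applied to the
    supplied intensities.
    """
    beta = compute_beta(intensities, offset=offset)
    beta = mask_low_quality(beta, intensities, thr)
    beta = drop_failed_samples(beta, thr)
    if thr.snp_filter:
        beta = filter_snp_probes(beta, ann)
    normed = quantile_normalize(beta.data).clip(lower=0.0, upper=1.0)
    beta = BetaMatrix(normed)
    return align_typeII_to_typeI(beta, ann)
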