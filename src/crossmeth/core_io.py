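"""Core containers and delimited-text I/O for methylation array data.

The central object is the :class:`BetaMatrix`: a samples x probes matrix of
methylation beta values (fractions in [0, 1]) with missing values stored as
NaN. Matrices are exchanged as tab-separated UTF-8 text with a header row of
probe ids, a first column of sample ids and the token ``NA`` for missing
cells -- the dialect of common array-matrix exports. Probe and sample ids are
compared case-sensitively (Illumina ``cg#########`` ids are canonical).

Also defined here: :class:`IntensitySet` (raw methylated/unmethylated signals
with detection p-values and bead counts), :class:`ProbeAnnotation` (design
type, functional category, SNP flag) and :class:`SampleMetadata` (family
structure and binary outcome), plus :func:`align_matrices` which restricts a
surrogate/target pair to their shared samples and probes.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING_TOKEN = "NA"

__all__ = [
    "ParseError",
    "ValidationError",
    "AlignmentError",
    "BetaMatrix",
    "IntensitySet",
    "ProbeAnnotation",
    "SampleMetadata",
    "read_beta_matrix",
    "write_beta_matrix",
    "align_matrices",
    "read_probe_annotation",
    "read_sample_metadata",
    "write_sample_metadata",
]


class ParseError(ValueError):
    """A delimited input file could not be parsed."""


class ValidationError(ValueError):
    """A domain invariant was violated."""


class AlignmentError(ValueError):
    """Two matrices cannot be aligned on shared samples/probes."""


def _check_unique(ids: pd.Index, what: str) -> None:
    if ids.has_duplicates:
        dups = ids[ids.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what} ids: {dups[:5]}")


class BetaMatrix:
    """Samples x probes methylation fractions in [0, 1]; NaN marks missing.

    Parameters
    ----------
    data:
        DataFrame with sample ids as index and probe ids as columns. Values
        must be numeric; every non-missing value must lie in [0, 1].
    """

    def __init__(self, data: pd.DataFrame):
        if not isinstance(data, pd.DataFrame):
            raise TypeError("BetaMatrix expects a pandas DataFrame (samples x probes)")
        try:
            data = data.astype(float)
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"non-numeric beta values: {exc}") from exc
        _check_unique(data.index, "sample")
        _check_unique(data.columns, "probe")
        vals = data.to_numpy()
        with np.errstate(invalid="ignore"):
            bad = (vals < 0.0) | (vals > 1.0)
        if bad.any():
            cells = [
                (data.index[i], data.columns[j], vals[i, j])
                for i, j in np.argwhere(bad)[:5]
            ]
            raise ValidationError(
                f"beta values outside [0, 1] at (sample, probe, value): {cells}"
            )
        self._data = data

    # -- accessors ---------------------------------------------------------
    @property
    def data(self) -> pd.DataFrame:
        return self._data

    @property
    def values(self) -> np.ndarray:
        return self._data.to_numpy()

    @property
    def sample_ids(self) -> list:
        return list(self._data.index)

    @property
    def probe_ids(self) -> list:
        return list(self._data.columns)

    @property
    def n_samples(self) -> int:
        return self._data.shape[0]

    @property
    def n_probes(self) -> int:
        return self._data.shape[1]

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self._data.isna()

    # -- manipulation ------------------------------------------------------
    def select(self, samples: Sequence | None = None, probes: Sequence | None = None) -> "BetaMatrix":
        df = self._data
        if samples is not None:
            missing = [s for s in samples if s not in df.index]
            if missing:
                raise ValidationError(f"unknown sample ids: {missing[:5]}")
            df = df.loc[list(samples)]
        if probes is not None:
            missing = [p for p in probes if p not in df.columns]
            if missing:
                raise ValidationError(f"unknown probe ids: {missing[:5]}")
            df = df[list(probes)]
        return BetaMatrix(df.copy())

    def copy(self) -> "BetaMatrix":
        return BetaMatrix(self._data.copy())

    def equals(self, other: "BetaMatrix") -> bool:
        if self.sample_ids != other.sample_ids or self.probe_ids != other.probe_ids:
            return False
        a, b = self.values, other.values
        both_nan = np.isnan(a) & np.isnan(b)
        return bool(np.all(both_nan | (a == b)))

    def __repr__(self) -> str:  # pragma: no cover
        return f"BetaMatrix({self.n_samples} samples x {self.n_probes} probes)"


def read_beta_matrix(path, orientation: str = "samples-by-probes") -> BetaMatrix:
    """Read a TSV beta matrix.

    ``orientation`` states how the file is laid out; the returned matrix is
    always samples x probes. The orientation is an explicit flag rather than
    auto-detected: silent transposition is the most dangerous failure mode
    for n << m methylation matrices.
    """
    if orientation not in ("samples-by-probes", "probes-by-samples"):
        raise ValueError(f"unknown orientation {orientation!r}")
    try:
        raw = pd.read_csv(
            path,
            sep="\t",
            index_col=0,
            dtype=str,
            keep_default_na=False,
            na_values=[],
        )
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ParseError(f"{path}: malformed file: {exc}") from exc
    _check_unique(raw.index, "row")
    _check_unique(raw.columns, "column")
    missing = raw == MISSING_TOKEN
    masked = raw.where(~missing)
    try:
        # float() parsing is exact (round-trips repr), unlike the fast csv parser
        df = masked.astype(np.float64)
    except (TypeError, ValueError):
        numeric = masked.apply(pd.to_numeric, errors="coerce")
        bad = numeric.isna() & ~missing
        cells = [
            (raw.index[i], raw.columns[j], raw.iloc[i, j])
            for i, j in np.argwhere(bad.to_numpy())[:5]
        ]
        raise ParseError(f"{path}: non-numeric cells at (row, column, value): {cells}") from None
    if orientation == "probes-by-samples":
        df = df.T
    df.index.name = None
    df.columns.name = None
    return BetaMatrix(df)


def write_beta_matrix(m: BetaMatrix, path) -> None:
    """Write a beta matrix as TSV; ``read_beta_matrix`` round-trips exactly."""
    m.data.to_csv(
        Path(path),
        sep="\t",
        na_rep=MISSING_TOKEN,
        index_label="sample_id",
        quoting=csv.QUOTE_MINIMAL,
    )


def align_matrices(x: BetaMatrix, y: BetaMatrix) -> tuple[BetaMatrix, BetaMatrix]:
    """Restrict two matrices to shared samples and probes, in x's order.

    Returns the pair restricted to the intersection of sample ids and of
    probe ids; both outputs share identical ordering. Requires at least two
    shared samples and one shared probe. Idempotent.
    """
    y_samples = set(y.sample_ids)
    y_probes = set(y.probe_ids)
    samples = [s for s in x.sample_ids if s in y_samples]
    probes = [p for p in x.probe_ids if p in y_probes]
    if len(samples) < 2 or len(probes) < 1:
        raise AlignmentError(
            f"matrices share {len(samples)} samples and {len(probes)} probes; "
            "need at least 2 samples and 1 probe"
        )
    dropped_s = (x.n_samples - len(samples)) + (y.n_samples - len(samples))
    dropped_p = (x.n_probes - len(probes)) + (y.n_probes - len(probes))
    if dropped_s or dropped_p:
        logger.info(
            "align_matrices: dropped %d sample entries and %d probe entries outside the intersection",
            dropped_s,
            dropped_p,
        )
    return x.select(samples, probes), y.select(samples, probes)


@dataclass
class IntensitySet:
    """Raw per-sample x per-probe probe intensities.

    ``detection_p`` and ``bead_count`` are optional (bead counts are absent
    for 27k-style exports). All frames must share sample/probe ids.
    """

    methylated: pd.DataFrame
    unmethylated: pd.DataFrame
    detection_p: pd.DataFrame | None = None
    bead_count: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        ref = self.methylated
        _check_unique(ref.index, "sample")
        _check_unique(ref.columns, "probe")
        for name in ("methylated", "unmethylated", "detection_p", "bead_count"):
            df = getattr(self, name)
            if df is None:
                continue
            df = df.astype(float)
            setattr(self, name, df)
            if list(df.index) != list(ref.index) or list(df.columns) != list(ref.columns):
                raise ValidationError(f"{name} does not share sample/probe ids with methylated signal")
        for name in ("methylated", "unmethylated"):
            vals = getattr(self, name).to_numpy()
            if np.nanmin(vals, initial=0.0) < 0:
                raise ValidationError(f"negative {name} signal")
        if self.detection_p is not None:
            p = self.detection_p.to_numpy()
            with np.errstate(invalid="ignore"):
                if ((p < 0) | (p > 1)).any():
                    raise ValidationError("detection p-values outside [0, 1]")
        if self.bead_count is not None:
            b = self.bead_count.to_numpy()
            with np.errstate(invalid="ignore"):
                if (b < 0).any():
                    raise ValidationError("negative bead counts")

    @property
    def sample_ids(self) -> list:
        return list(self.methylated.index)

    @property
    def probe_ids(self) -> list:
        return list(self.methylated.columns)


class ProbeAnnotation:
    """Probe design type (Infinium I/II), functional category and SNP flag."""

    REQUIRED = ("design_type", "category")

    def __init__(self, table: pd.DataFrame):
        table = table.copy()
        _check_unique(table.index, "probe")
        for col in self.REQUIRED:
            if col not in table.columns:
                raise ValidationError(f"probe annotation missing column {col!r}")
        bad_design = ~table["design_type"].isin(["I", "II"])
        if bad_design.any():
            raise ValidationError(
                f"design_type must be 'I' or 'II'; offending probes: {table.index[bad_design][:5].tolist()}"
            )
        if table["category"].isna().any() or (table["category"].astype(str) == "").any():
            raise ValidationError("empty functional category")
        if "snp_flag" not in table.columns:
            table["snp_flag"] = False
        table["snp_flag"] = table["snp_flag"].map(_to_bool)
        self.table = table

    @property
    def probe_ids(self) -> list:
        return list(self.table.index)

    def for_probes(self, probe_ids: Iterable) -> pd.DataFrame:
        probe_ids = list(probe_ids)
        missing = [p for p in probe_ids if p not in self.table.index]
        if missing:
            raise ValidationError(f"probes without annotation: {missing[:5]}")
        return self.table.loc[probe_ids]


def _to_bool(v) -> bool:
    if isinstance(v, str):
        s = v.strip().lower()
        if s in ("true", "t", "1", "yes"):
            return True
        if s in ("false", "f", "0", "no", ""):
            return False
        raise ValidationError(f"cannot interpret snp_flag value {v!r}")
    return bool(v)


def read_probe_annotation(path) -> ProbeAnnotation:
    table = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    return ProbeAnnotation(table)


class SampleMetadata:
    """Per-sample family id, optional binary outcome and extra covariates."""

    def __init__(self, table: pd.DataFrame):
        table = table.copy()
        _check_unique(table.index, "sample")
        if "family_id" not in table.columns:
            raise ValidationError("sample metadata missing column 'family_id'")
        if "outcome" in table.columns:
            out = pd.to_numeric(table["outcome"], errors="coerce")
            ok = out.isna() | out.isin([0, 1])
            if not ok.all():
                raise ValidationError("outcome must be binary 0/1 (or missing)")
            table["outcome"] = out
        self.table = table

    @property
    def sample_ids(self) -> list:
        return list(self.table.index)

    def family_map(self) -> dict:
        return dict(self.table["family_id"])

    def outcome_vector(self, sample_ids: Sequence) -> np.ndarray:
        if "outcome" not in self.table.columns:
            raise ValidationError("sample metadata has no 'outcome' column")
        self.check_covers(sample_ids)
        return self.table.loc[list(sample_ids), "outcome"].to_numpy(dtype=float)

    def check_covers(self, sample_ids: Iterable) -> None:
        missing = [s for s in sample_ids if s not in self.table.index]
        if missing:
            raise ValidationError(f"samples without metadata: {missing[:5]}")


def read_sample_metadata(path) -> SampleMetadata:
    table = pd.read_csv(path, sep="\t", index_col=0)
    return SampleMetadata(table)


def write_sample_metadata(meta: SampleMetadata, path) -> None:
    meta.table.to_csv(Path(path), sep="\t", index_label="sample_id")
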