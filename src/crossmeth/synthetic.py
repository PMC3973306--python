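"""Synthetic paired-tissue methylation data with known generating truth.

The generator emulates the statistical structure that cross-tissue
calibration assumes, so every other module can be exercised and validated
without external array data:

* a U-shaped (bimodal) beta-value distribution: configurable fractions of
  probes are constitutively methylated (means near 1) or unmethylated (means
  near 0) in both tissues;
* high between-tissue correlation with a minority of probes carrying
  consistent per-probe cross-tissue offsets (mean shifts above 0.1) -- the
  signature that makes per-probe recalibration worthwhile;
* per-probe affine tissue relationships: target = intercept + slope *
  surrogate + Gaussian technical noise, truncated to [0, 1]; conserved
  probes have slope near 1 and intercept near 0, tissue-divergent probes
  draw slopes from a wide range (attenuation and amplification, e.g. from
  cell-mixture dilution);
* family clustering: samples belong to nuclear families and share a
  per-family random intercept, giving leave-one-family-out cross-validation
  something real to protect against;
* an optional binary outcome whose effect is added to the target tissue only,
  for downstream-utility analyses.

Every draw flows from a single seeded generator, so outputs are
reproducible; the full generating truth (per-probe class, intercept, slope,
outcome effect, family and outcome assignments) is returned alongside the
matrices for recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import BetaMatrix, IntensitySet, SampleMetadata, ValidationError

#: Betas are clipped just below 1: measured betas never reach 1 because of
#: the offset in the beta formula, and intensity reconstruction requires
#: beta < 1.
BETA_CEILING = 0.999

__all__ = ["SyntheticConfig", "SyntheticTruth", "generate_pair", "generate_intensity_set", "BETA_CEILING"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Generating parameters for a paired surrogate/target study.

    Defaults describe a blood-plus-tissue family study: 39 samples in ~20
    nuclear families; 20% constitutively methylated and 20% constitutively
    unmethylated probes; 20% of probes carrying a cross-tissue mean shift
    above ``offset_min``; technical noise SD 0.02 (duplicate-level
    reproducibility); ~30% binary-outcome cases.
    """

    n_samples: int = 39
    n_probes: int = 2000
    family_sizes: tuple | None = None  # None: families of 2 (last may be 1)
    fraction_constitutive_high: float = 0.20
    fraction_constitutive_low: float = 0.20
    fraction_offset_probes: float = 0.20
    offset_min: float = 0.10
    offset_sd_between_probes: float = 0.10
    conserved_slope_sd: float = 0.15
    conserved_intercept_sd: float = 0.02
    offset_slope_range: tuple = (0.2, 1.8)
    probe_sd_min: float = 0.01
    probe_sd_scale: float = 0.06
    probe_sd_max: float = 0.25
    constitutive_sd_max: float = 0.03
    family_effect_share: float = 0.3
    noise_sd: float = 0.02
    fraction_outcome_probes: float = 0.05
    outcome_effect_sd: float = 0.10
    outcome_in_surrogate: bool = False
    case_fraction: float = 0.30
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = (
            self.fraction_constitutive_high,
            self.fraction_constitutive_low,
            self.fraction_offset_probes,
            self.fraction_outcome_probes,
            self.case_fraction,
        )
        if any(not (0.0 <= f <= 1.0) for f in fracs):
            raise ValidationError("all fractions must lie in [0, 1]")
        if (
            self.fraction_constitutive_high
            + self.fraction_constitutive_low
            + self.fraction_offset_probes
        ) > 1.0:
            raise ValidationError("constitutive + offset probe fractions exceed 1")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.n_samples < 2 or self.n_probes < 1:
            raise ValidationError("need at least 2 samples and 1 probe")
        if not (0.0 <= self.family_effect_share < 1.0):
            raise ValidationError("family_effect_share must be in [0, 1)")

    def resolved_family_sizes(self) -> list:
        if self.family_sizes is not None:
            sizes = list(self.family_sizes)
            if sum(sizes) != self.n_samples:
                raise ValidationError("family_sizes must sum to n_samples")
            if any(s < 1 for s in sizes):
                raise ValidationError("family sizes must be positive")
            return sizes
        sizes = [2] * (self.n_samples // 2)
        if self.n_samples % 2:
            sizes.append(1)
        return sizes


@dataclass
class SyntheticTruth:
    """The generating parameters behind one synthetic pair.

    ``probes`` is indexed by probe id with columns: class (constitutive-high
    / constitutive-low / conserved / offset), surrogate_mean, surrogate_sd,
    slope, intercept, offset (target-mean shift) and outcome_effect.
    """

    probes: pd.DataFrame
    family_of: dict
    outcome_of: dict
    config: SyntheticConfig

    def to_frame(self) -> pd.DataFrame:
        return self.probes.copy()


def generate_pair(config: SyntheticConfig):
    """Draw a paired surrogate/target study.

    Returns ``(X, Y, meta, truth)``: surrogate and target
    :class:`~crossmeth.core_io.BetaMatrix` objects, sample metadata with
    family and outcome columns, and the :class:`SyntheticTruth`.
    """
    rng = np.random.default_rng(config.seed)
    n, m = config.n_samples, config.n_probes

    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    probe_ids = [f"cg{j:08d}" for j in range(m)]

    # probe classes
    n_high = int(round(config.fraction_constitutive_high * m))
    n_low = int(round(config.fraction_constitutive_low * m))
    n_off = int(round(config.fraction_offset_probes * m))
    labels = np.array(
        ["constitutive-high"] * n_high
        + ["constitutive-low"] * n_low
        + ["offset"] * n_off
        + ["conserved"] * (m - n_high - n_low - n_off)
    )
    rng.shuffle(labels)
    is_high = labels == "constitutive-high"
    is_low = labels == "constitutive-low"
    is_off = labels == "offset"
    is_mid = ~is_high & ~is_low

    # surrogate means: bimodal mixture with a broad middle component
    mu = np.empty(m)
    mu[is_high] = rng.beta(40.0, 2.0, is_high.sum())
    mu[is_low] = rng.beta(2.0, 40.0, is_low.sum())
    mu[is_mid] = 0.1 + 0.8 * rng.beta(2.0, 2.0, is_mid.sum())

    # between-individual SD per probe
    sd = np.empty(m)
    sd[~is_mid] = rng.uniform(0.005, config.constitutive_sd_max, (~is_mid).sum())
    sd[is_mid] = np.clip(
        config.probe_sd_min + rng.exponential(config.probe_sd_scale, is_mid.sum()),
        config.probe_sd_min,
        config.probe_sd_max,
    )

    # per-probe affine relationship: y = (mu + delta) + b * (x - mu) + noise
    slope = np.ones(m)
    delta = np.zeros(m)
    conserved = labels == "conserved"
    slope[conserved] = np.clip(
        rng.normal(1.0, config.conserved_slope_sd, conserved.sum()), 0.3, 1.7
    )
    delta[conserved] = rng.normal(0.0, config.conserved_intercept_sd, conserved.sum())
    lo_s, hi_s = config.offset_slope_range
    slope[is_off] = rng.uniform(lo_s, hi_s, is_off.sum())
    sign = rng.choice([-1.0, 1.0], is_off.sum())
    delta[is_off] = sign * (
        config.offset_min + np.abs(rng.normal(0.0, config.offset_sd_between_probes, is_off.sum()))
    )
    # keep the target mean inside the measurable range
    delta = np.clip(mu + delta, 0.02, 0.98) - mu

    # families and outcome
    sizes = config.resolved_family_sizes()
    family_ids = []
    for f, s in enumerate(sizes):
        family_ids.extend([f"F{f + 1:03d}"] * s)
    family_of = dict(zip(sample_ids, family_ids))
    n_cases = int(round(config.case_fraction * n))
    case_idx = rng.choice(n, size=n_cases, replace=False)
    outcome = np.zeros(n)
    outcome[case_idx] = 1.0
    outcome_of = dict(zip(sample_ids, outcome.astype(int)))

    # outcome effects in the target tissue only
    n_out_probes = int(round(config.fraction_outcome_probes * m))
    outcome_effect = np.zeros(m)
    mid_idx = np.where(is_mid)[0]
    if n_out_probes > 0 and mid_idx.size > 0:
        chosen = rng.choice(mid_idx, size=min(n_out_probes, mid_idx.size), replace=False)
        outcome_effect[chosen] = rng.normal(0.0, config.outcome_effect_sd, chosen.size)

    # surrogate values: probe mean + shared family effect + individual noise
    share = config.family_effect_share
    fam_index = np.repeat(np.arange(len(sizes)), sizes)
    fam_noise = rng.normal(0.0, 1.0, (len(sizes), m))
    ind_noise = rng.normal(0.0, 1.0, (n, m))
    x = (
        mu[None, :]
        + np.sqrt(share) * sd[None, :] * fam_noise[fam_index]
        + np.sqrt(1.0 - share) * sd[None, :] * ind_noise
    )
    # an outcome effect expressed in the surrogate propagates to the target
    # through the affine map (slope-scaled), emulating an exposure that marks
    # both tissues; otherwise the effect marks the target tissue only
    if config.outcome_in_surrogate:
        x = x + outcome[:, None] * outcome_effect[None, :]
    x = np.clip(x, 0.0, BETA_CEILING)

    # target values through the per-probe affine map
    y = (mu + delta)[None, :] + slope[None, :] * (x - mu[None, :])
    if config.noise_sd > 0:
        y = y + rng.normal(0.0, config.noise_sd, (n, m))
    if not config.outcome_in_surrogate:
        y = y + outcome[:, None] * outcome_effect[None, :]
    y = np.clip(y, 0.0, BETA_CEILING)

    X = BetaMatrix(pd.DataFrame(x, index=sample_ids, columns=probe_ids))
    Y = BetaMatrix(pd.DataFrame(y, index=sample_ids, columns=probe_ids))
    meta = SampleMetadata(
        pd.DataFrame(
            {"family_id": family_ids, "outcome": outcome.astype(int)}, index=sample_ids
        )
    )
    probes = pd.DataFrame(
        {
            "class": labels,
            "surrogate_mean": mu,
            "surrogate_sd": sd,
            "slope": slope,
            "intercept": (mu + delta) - slope * mu,
            "offset": delta,
            "outcome_effect": outcome_effect,
        },
        index=probe_ids,
    )
    truth = SyntheticTruth(probes=probes, family_of=family_of, outcome_of=outcome_of, config=config)
    return X, Y, meta, truth


def generate_intensity_set(
    beta: BetaMatrix,
    total_signal_scale: float = 2000.0,
    detection_fail_rate: float = 0.0,
    low_bead_rate: float = 0.0,
    offset: float = 100.0,
    seed: int = 0,
) -> IntensitySet:
    """Invert the beta formula to raw intensities exercising the preprocess
    chain.

    With total signal S (methylated + unmethylated + offset), methylated
    signal is ``beta * S`` and unmethylated is the remainder, so
    ``compute_beta`` reproduces the input betas to 1e-9. Cells selected as
    detection failures get detection p 0.5; low-bead cells get 2 beads;
    everything else gets detection p 0 and 30 beads.
    """
    if total_signal_scale <= offset:
        raise ValidationError("total_signal_scale must exceed the beta offset")
    b = beta.values
    if np.nanmax(b, initial=0.0) >= 1.0:
        raise ValidationError("cannot invert beta values >= 1 to finite intensities")
    S = float(total_signal_scale)
    M = b * S
    U = S - offset - M
    neg = U < 0
    if neg.any():
        M = np.where(neg, offset * b / (1.0 - b), M)
        U = np.where(neg, 0.0, U)
    rng = np.random.default_rng(seed)
    shape = b.shape
    p = np.zeros(shape)
    beads = np.full(shape, 30.0)
    if detection_fail_rate > 0:
        p = np.where(rng.random(shape) < detection_fail_rate, 0.5, 0.0)
    if low_bead_rate > 0:
        beads = np.where(rng.random(shape) < low_bead_rate, 2.0, 30.0)
    idx, cols = beta.sample_ids, beta.probe_ids
    return IntensitySet(
        methylated=pd.DataFrame(M, index=idx, columns=cols),
        unmethylated=pd.DataFrame(U, index=idx, columns=cols),
        detection_p=pd.DataFrame(p, index=idx, columns=cols),
        bead_count=pd.DataFrame(beads, index=idx, columns=cols),
    )


def write_manifest(config: SyntheticConfig, path) -> None:
    """Record the full generating configuration and seed as JSON."""
    d = asdict(config)
    d["family_sizes"] = list(d["family_sizes"]) if d["family_sizes"] else None
    d["offset_slope_range"] = list(d["offset_slope_range"])
    Path(path).write_text(json.dumps(d, indent=2))
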