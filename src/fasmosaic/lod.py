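"""Limit-of-detection modelling for mosaic variant screening.

A heterozygous somatic mutation carried by a cell fraction *c* of the
sequenced sample has expected VAF c/2.  Whether the caller can see it at
a given depth is governed by two deterministic floors — the minimum VAF
and the minimum supporting-read count — plus binomial sampling noise.
This module provides the deterministic floor (which reproduces the
assay's empirically observed detection limits as supporting-reads/depth
arithmetic) and an exact-binomial generalization of it: the probability
that a variant at a given true VAF yields enough supporting reads to
pass the thresholds.  The power model assumes balanced strands and
ignores the strand-bias filter; the simulator quantifies that effect
empirically instead.
"""

from __future__ import annotations

import math

import numpy as np
from pydantic import BaseModel, model_validator
from scipy import stats

from .caller import DEFAULT_FILTER_CONFIG, FilterConfig


class UndetectableVariantError(ValueError):
    """No finite depth reaches the target detection power."""


class LodConfig(BaseModel):
    """Parameters of the detection-power model.

    ``error_rate`` is the per-base miscall probability toward the variant
    allele (a one-parameter inflation of the alt-read probability; no
    per-base quality modelling).  ``target_power`` is the detection
    probability demanded by :func:`required_depth`.
    """

    filter: FilterConfig = DEFAULT_FILTER_CONFIG
    error_rate: float = 1e-3
    target_power: float = 0.95

    @model_validator(mode="after")
    def _check(self) -> "LodConfig":
        if not 0 <= self.error_rate < self.filter.min_vaf:
            raise ValueError("error_rate must lie in [0, min_vaf)")
        if not 0 < self.target_power < 1:
            raise ValueError("target_power must lie in (0, 1)")
        return self


DEFAULT_LOD_CONFIG = LodConfig()


def expected_vaf(f_dnt: float, f_sp: float = 0.0) -> float:
    """Expected VAF of a heterozygous mosaic mutation.

    ``f_dnt`` is the mutant double-negative T-cell fraction of the sample
    and ``f_sp`` the additional mutant single-positive-cell fraction; the
    heterozygous mutation dilutes to (f_dnt + f_sp) / 2.
    """
    if not (0 <= f_dnt <= 1 and 0 <= f_sp <= 1 and f_dnt + f_sp <= 1):
        raise ValueError("cell fractions must lie in [0, 1] and sum to <= 1")
    return (f_dnt + f_sp) / 2


def _min_alt_reads(depth: int, config: FilterConfig) -> int:
    """Smallest supporting-read count that passes both count floors."""
    return max(config.min_allele_cov, math.ceil(config.min_vaf * depth))


def min_detectable_vaf(depth: int, config: LodConfig = DEFAULT_LOD_CONFIG) -> float:
    """Deterministic detection floor at a given depth.

    max(min_vaf, min_allele_cov / depth), capped at 1.0 (nothing is
    detectable with fewer reads than the supporting-read minimum).
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    f = config.filter
    if depth < f.min_allele_cov:
        return 1.0
    return min(1.0, max(f.min_vaf, f.min_allele_cov / depth))


def detection_power(
    depth: int, true_vaf: float, config: LodConfig = DEFAULT_LOD_CONFIG
) -> float:
    """Probability the caller's count thresholds are met at this depth.

    Supporting reads X ~ Binomial(depth, p) with
    p = true_vaf + error_rate * (1 - true_vaf); the variant is detected
    when X >= max(min_allele_cov, ceil(min_vaf * depth)).  Exact tail
    probability, no normal approximation.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if not 0 <= true_vaf <= 1:
        raise ValueError("true_vaf must lie in [0, 1]")
    p = true_vaf + config.error_rate * (1 - true_vaf)
    k_min = _min_alt_reads(depth, config.filter)
    if k_min > depth:
        return 0.0
    return float(stats.binom.sf(k_min - 1, depth, p))


def required_depth(
    true_vaf: float, config: LodConfig = DEFAULT_LOD_CONFIG
) -> int:
    """Smallest depth whose detection power reaches ``target_power``.

    Raises :class:`UndetectableVariantError` when the alt-read
    probability sits at or below the VAF floor, in which case power does
    not converge to 1 with depth.
    """
    if not 0 < true_vaf <= 1:
        raise ValueError("true_vaf must lie in (0, 1]")
    f = config.filter
    p = true_vaf + config.error_rate * (1 - true_vaf)
    if p <= f.min_vaf:
        raise UndetectableVariantError(
            f"alt-read probability {p:.4g} is at or below the VAF floor "
            f"{f.min_vaf}; no depth reaches power {config.target_power}"
        )
    # Exponential search for an upper bound, then an exact vectorized
    # scan: power is not strictly monotone in depth (the ceil'd VAF
    # floor introduces small saw-teeth), so bisection alone is unsafe.
    hi = 16
    while detection_power(hi, true_vaf, config) < config.target_power:
        hi *= 2
        if hi > 10_000_000:
            raise UndetectableVariantError(
                "target power unreachable below 1e7 reads"
            )
    depths = np.arange(1, hi + 1)
    k_min = np.maximum(f.min_allele_cov, np.ceil(f.min_vaf * depths))
    power = stats.binom.sf(k_min - 1, depths, p)
    power = np.where(k_min > depths, 0.0, power)
    return int(depths[power >= config.target_power][0])
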