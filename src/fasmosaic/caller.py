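"""Somatic variant filter chain and germline/somatic classification.

The screening assay calls low-allele-fraction FAS variants from
whole-blood amplicon sequencing with deliberately permissive thresholds:
minimum VAF 0.01, minimum 3 supporting reads, no per-strand coverage
requirement, and removal of strand-biased artifacts only when the bias
score exceeds 0.85 AND its Fisher exact p-value falls below 0.05.
Passing calls are then classified by VAF band: near-50% calls are
germline heterozygous, near-100% germline homozygous, everything else a
somatic (mosaic) candidate.
"""

from __future__ import annotations

import math
from typing import Sequence

from pydantic import BaseModel, model_validator
from scipy import stats

from .pileup_io import GenomicRegion, StrandedAlleleCount, VariantCall, in_regions


class FilterConfig(BaseModel):
    """Thresholds of the customized somatic caller.

    Defaults reproduce the validated clinical configuration.  The
    germline bands are a simplified stand-in for a separate germline
    caller: a heterozygous band around 50% VAF and a homozygous floor.
    """

    min_vaf: float = 0.01
    min_allele_cov: int = 3
    sb_score_max: float = 0.85
    sb_pvalue_min: float = 0.05
    min_strand_cov: int = 0
    germline_het_band: tuple[float, float] = (0.35, 0.65)
    germline_hom_min: float = 0.90

    @model_validator(mode="after")
    def _check(self) -> "FilterConfig":
        if not 0 <= self.min_vaf <= 1:
            raise ValueError("min_vaf must lie in [0, 1]")
        if self.min_allele_cov < 0:
            raise ValueError("min_allele_cov must be >= 0")
        if not 0.5 <= self.sb_score_max <= 1:
            raise ValueError("sb_score_max must lie in [0.5, 1]")
        lo, hi = self.germline_het_band
        if not (self.min_vaf <= lo <= hi):
            raise ValueError("germline_het_band must be ordered and above min_vaf")
        if self.germline_hom_min < hi:
            raise ValueError("germline bands must not overlap")
        return self


DEFAULT_FILTER_CONFIG = FilterConfig()


def compute_vaf(counts: StrandedAlleleCount) -> float:
    """Variant allele frequency: supporting reads over total depth."""
    if counts.depth <= 0:
        raise ValueError("VAF undefined at zero depth")
    return counts.alt_count / counts.depth


def format_vaf_percent(vaf: float) -> float:
    """Percent VAF rounded half-up to one decimal, the report convention."""
    return math.floor(vaf * 1000 + 0.5) / 10


def _strand_split(counts: StrandedAlleleCount) -> tuple[int, int]:
    """Per-strand total depths; imputed as an even split (ties to forward)
    when the input does not carry them."""
    if counts.depth_fwd is not None and counts.depth_rev is not None:
        return counts.depth_fwd, counts.depth_rev
    # clamp so the imputed split stays consistent with the observed
    # per-strand alt counts (alt_fwd <= depth_fwd, alt_rev <= depth_rev)
    fwd = (counts.depth + 1) // 2
    fwd = min(max(fwd, counts.alt_fwd), counts.depth - counts.alt_rev)
    return fwd, counts.depth - fwd


def strand_bias_score(counts: StrandedAlleleCount) -> float:
    """Symmetric strand-bias score in [0.5, 1].

    With per-strand variant rates r_f = alt_fwd/depth_fwd and
    r_r = alt_rev/depth_rev, the score is max(r_f, r_r) / (r_f + r_r):
    0.5 for perfectly balanced rates, 1.0 when one strand carries no
    variant reads.  Invariant under swapping strands.
    """
    if counts.alt_count == 0:
        raise ValueError("strand-bias score undefined without variant reads")
    depth_fwd, depth_rev = _strand_split(counts)
    if depth_fwd == 0 and depth_rev == 0:
        raise ValueError("strand-bias score undefined at zero depth")
    rate_f = counts.alt_fwd / depth_fwd if depth_fwd else 0.0
    rate_r = counts.alt_rev / depth_rev if depth_rev else 0.0
    return max(rate_f, rate_r) / (rate_f + rate_r)


def strand_bias_pvalue(counts: StrandedAlleleCount) -> float:
    """Two-sided Fisher exact test on the 2x2 strand table.

    Rows are strands, columns variant vs reference reads:
    [[alt_fwd, depth_fwd - alt_fwd], [alt_rev, depth_rev - alt_rev]].
    """
    depth_fwd, depth_rev = _strand_split(counts)
    ref_fwd = depth_fwd - counts.alt_fwd
    ref_rev = depth_rev - counts.alt_rev
    if ref_fwd < 0 or ref_rev < 0:
        raise ValueError("per-strand alt count exceeds strand depth")
    table = [[counts.alt_fwd, ref_fwd], [counts.alt_rev, ref_rev]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def apply_filters(
    counts: StrandedAlleleCount,
    config: FilterConfig = DEFAULT_FILTER_CONFIG,
) -> tuple[bool, list[str]]:
    """Run the filter chain; returns (passed, names of failed filters).

    The strand-bias filter removes a call only when BOTH the score
    exceeds ``sb_score_max`` and the Fisher p-value falls below
    ``sb_pvalue_min``; with ``min_strand_cov`` 0 (the default) no
    per-strand coverage is required.
    """
    if counts.depth <= 0:
        raise ValueError("cannot filter a record with zero depth")
    failed: list[str] = []
    if compute_vaf(counts) < config.min_vaf:
        failed.append("min_vaf")
    if counts.alt_count < config.min_allele_cov:
        failed.append("min_allele_cov")
    if config.min_strand_cov > 0:
        depth_fwd, depth_rev = _strand_split(counts)
        if depth_fwd < config.min_strand_cov or depth_rev < config.min_strand_cov:
            failed.append("min_strand_cov")
    if counts.alt_count > 0:
        score = strand_bias_score(counts)
        # p-value only needed when the score condition already holds
        if score > config.sb_score_max and (
            strand_bias_pvalue(counts) < config.sb_pvalue_min
        ):
            failed.append("strand_bias")
    return (not failed), failed


def classify_call(vaf: float, config: FilterConfig = DEFAULT_FILTER_CONFIG) -> str:
    """VAF-band classification of a passing call."""
    if not 0 <= vaf <= 1:
        raise ValueError("vaf must lie in [0, 1]")
    lo, hi = config.germline_het_band
    if lo <= vaf <= hi:
        return "germline_het"
    if vaf >= config.germline_hom_min:
        return "germline_hom"
    return "somatic"


def call_sample(
    pileup: Sequence[StrandedAlleleCount],
    regions: Sequence[GenomicRegion] | None = None,
    config: FilterConfig = DEFAULT_FILTER_CONFIG,
    sample_id: str = "",
) -> list[VariantCall]:
    """Run the full chain over one sample's pileup.

    Region restriction, then per record: VAF, strand-bias score and
    p-value, filters, and classification of passing records.  Rejected
    records are retained with classification ``rejected`` and the failed
    filter names.  Output order is deterministic: position, then alt
    allele lexicographically.
    """
    calls: list[VariantCall] = []
    for counts in pileup:
        if not in_regions(counts.chrom, counts.pos, regions):
            continue
        passed, failed = apply_filters(counts, config)
        vaf = compute_vaf(counts)
        if counts.alt_count > 0:
            sb = strand_bias_score(counts)
            sbp = strand_bias_pvalue(counts)
        else:
            sb, sbp = 0.5, 1.0  # no variant reads: no bias evidence
        calls.append(
            VariantCall(
                counts=counts,
                vaf=vaf,
                strand_bias=sb,
                sb_pvalue=sbp,
                filters_passed=passed,
                classification=classify_call(vaf, config) if passed else "rejected",
                failed_filters=tuple(failed),
                sample_id=sample_id,
            )
        )
    calls.sort(key=lambda c: (c.counts.chrom, c.counts.pos, c.counts.alt))
    return calls
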