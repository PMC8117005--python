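"""Synthetic mosaic-pileup generator with known somatic/germline truth.

Emulates whole-blood amplicon sequencing of ALPS-sFAS patients and
non-ALPS controls at the level the caller consumes: stranded allele
counts per panel site.  A patient carries one heterozygous somatic FAS
variant present in its double-negative T cells (DNT, percentages drawn
from the study's observed 4-30.7% range) plus, optionally, an additional
10-20% single-positive-cell contribution; the mutant-cell fraction c
yields alt reads at rate c/2 plus sequencing error.  Background sites
carry error-only alt reads; sporadic germline heterozygous SNPs are
injected at a configurable per-sample rate; a configurable fraction of
somatic events are small deletions.  No read-level simulation (no
FASTQ, no flow-space or homopolymer error model).

Determinism: every draw flows from the master seed through
``numpy.random.SeedSequence`` with one child stream per sample, so an
identical configuration reproduces an identical cohort.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, model_validator

from .datasets import DEFAULT_REGIONS
from .pileup_io import (
    DELETION_TOKEN,
    GenomicRegion,
    SampleRecord,
    StrandedAlleleCount,
    VariantSite,
)

_BASES = "ACGT"
# Knuth multiplicative hash: a stable pseudo-reference so every sample
# agrees on the base at a position without bundling a genome.
_HASH = 2654435761


def reference_base(pos: int) -> str:
    return _BASES[((pos * _HASH) >> 7) & 3]


def _alt_base(pos: int) -> str:
    ref = reference_base(pos)
    return _BASES[(_BASES.index(ref) + 1 + (((pos * _HASH) >> 11) % 3)) % 4]


class SimulationConfig(BaseModel):
    """Generative parameters of the synthetic cohort.

    Defaults mirror the validation study: 8 patients with DNT drawn from
    the observed 4-30.7% range, 44 controls, per-site depths lognormal
    with median ~200 spanning the observed 101-399, near-balanced
    strands, and a quarter of somatic events being deletions (two of the
    eight causal variants in the study are deletions).
    """

    n_patients: int = 8
    n_controls: int = 44
    dnt_range: tuple[float, float] = (4.0, 30.7)  # percent
    sp_fraction_range: tuple[float, float] = (0.10, 0.20)
    sp_patient_proportion: float = 1.0
    dnt_carrier_fraction: float = 1.0
    lymphocyte_scale: float = 1.0  # < 1 models T-cell lymphopenia
    depth_median: float = 200.0
    depth_sigma: float = 0.35  # lognormal scale; 0 fixes depth at the median
    error_rate: float = 1e-3
    strand_balance: float = 0.5
    germline_snp_rate: float = 0.05
    indel_fraction: float = 0.25
    indel_length: int = 3
    n_sites: int = 120
    regions: tuple[GenomicRegion, ...] = DEFAULT_REGIONS
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        for name in ("sp_patient_proportion", "dnt_carrier_fraction",
                     "error_rate", "strand_balance", "germline_snp_rate",
                     "indel_fraction", "lymphocyte_scale"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not (0 <= self.dnt_range[0] <= self.dnt_range[1] <= 100):
            raise ValueError("dnt_range must lie in [0, 100]")
        if not (0 <= self.sp_fraction_range[0] <= self.sp_fraction_range[1] <= 1):
            raise ValueError("sp_fraction_range must lie in [0, 1]")
        if self.n_patients < 0 or self.n_controls < 0:
            raise ValueError("cohort sizes must be >= 0")
        if self.depth_median < 1 or self.depth_sigma < 0:
            raise ValueError("invalid depth model parameters")
        return self


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one injected variant."""

    sample_id: str
    site: VariantSite
    true_class: str  # somatic | germline_het
    true_cell_fraction: float
    true_vaf: float


@dataclass
class SampleSpec:
    """Per-sample inputs to :func:`simulate_sample`."""

    sample_id: str
    group: str  # patient | control
    dnt_percent: float | None = None  # drawn from dnt_range when absent


def panel_sites(config: SimulationConfig) -> np.ndarray:
    """Deterministic assayed positions: evenly spaced across the regions."""
    spans = np.array([r.end - r.start + 1 for r in config.regions], dtype=float)
    per_region = np.maximum(1, np.round(config.n_sites * spans / spans.sum()))
    sites = []
    for region, n in zip(config.regions, per_region.astype(int)):
        sites.append(np.unique(np.linspace(region.start, region.end, n).round().astype(int)))
    return np.concatenate(sites)


def _draw_depths(config: SimulationConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    if config.depth_sigma == 0:
        return np.full(n, int(round(config.depth_median)))
    d = rng.lognormal(np.log(config.depth_median), config.depth_sigma, size=n)
    return np.maximum(1, d.round().astype(int))


def _stranded_counts(
    depth: int, p: float, strand_balance: float, rng: np.random.Generator
) -> tuple[int, int, int]:
    """(depth_fwd, alt_fwd, alt_rev): the strand split is drawn first, then
    alt reads per strand, so alt ~ Binomial(depth, p) marginally and every
    count invariant holds by construction."""
    depth_fwd = int(rng.binomial(depth, strand_balance))
    alt_fwd = int(rng.binomial(depth_fwd, p))
    alt_rev = int(rng.binomial(depth - depth_fwd, p))
    return depth_fwd, alt_fwd, alt_rev


def mutant_cell_fraction(
    config: SimulationConfig, dnt_percent: float, rng: np.random.Generator
) -> float:
    """Draw the whole-blood mutant-cell fraction for one patient."""
    f_dnt = config.dnt_carrier_fraction * dnt_percent / 100.0
    f_sp = 0.0
    if rng.random() < config.sp_patient_proportion:
        f_sp = rng.uniform(*config.sp_fraction_range)
    return min(1.0, config.lymphocyte_scale * (f_dnt + f_sp))


def simulate_sample(
    config: SimulationConfig,
    spec: SampleSpec,
    rng: np.random.Generator,
) -> tuple[list[StrandedAlleleCount], list[TruthRecord]]:
    """Simulate one sample's stranded pileup and its truth records."""
    sites = panel_sites(config)
    depths = _draw_depths(config, len(sites), rng)

    # choose special sites first so background generation is uniform
    chrom = config.regions[0].chrom
    variant_idx: dict[int, tuple[str, str, str, float, float]] = {}

    if spec.group == "patient":
        dnt = spec.dnt_percent
        if dnt is None:
            dnt = rng.uniform(*config.dnt_range)
        c = mutant_cell_fraction(config, dnt, rng)
        i = int(rng.integers(len(sites)))
        pos = int(sites[i])
        if rng.random() < config.indel_fraction:
            ref = "".join(reference_base(pos + k) for k in range(config.indel_length))
            alt = DELETION_TOKEN
        else:
            ref, alt = reference_base(pos), _alt_base(pos)
        variant_idx[i] = ("somatic", ref, alt, c, c / 2)

    if rng.random() < config.germline_snp_rate:
        free = [i for i in range(len(sites)) if i not in variant_idx]
        if free:
            i = free[int(rng.integers(len(free)))]
            pos = int(sites[i])
            variant_idx[i] = ("germline_het", reference_base(pos), _alt_base(pos), 1.0, 0.5)

    pileup: list[StrandedAlleleCount] = []
    truth: list[TruthRecord] = []
    for i, (pos, depth) in enumerate(zip(sites, depths)):
        pos, depth = int(pos), int(depth)
        if i in variant_idx:
            cls, ref, alt, frac, true_vaf = variant_idx[i]
            p = true_vaf + config.error_rate * (1 - true_vaf)
            site = VariantSite(chrom, pos, ref, alt)
            truth.append(TruthRecord(spec.sample_id, site, cls, frac, true_vaf))
        else:
            ref, alt = reference_base(pos), _alt_base(pos)
            p = config.error_rate
        depth_fwd, alt_fwd, alt_rev = _stranded_counts(
            depth, p, config.strand_balance, rng
        )
        pileup.append(StrandedAlleleCount(
            chrom=chrom, pos=pos, ref=ref, alt=alt, depth=depth,
            alt_fwd=alt_fwd, alt_rev=alt_rev,
            depth_fwd=depth_fwd, depth_rev=depth - depth_fwd,
        ))
    return pileup, truth


def sample_seed(master_seed: int, index: int) -> np.random.SeedSequence:
    """Stable child seed stream for sample *index* of a cohort."""
    return np.random.SeedSequence(master_seed, spawn_key=(index,))


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[dict[str, list[StrandedAlleleCount]], list[TruthRecord], pd.DataFrame]:
    """Simulate the full cohort.

    Returns pileups keyed by sample id, the pooled truth records, and a
    manifest table (sample id, group, DNT%, child seed entropy, injected
    variants).  Patients are named P1..Pn, controls C1..Cn.
    """
    specs = [
        SampleSpec(sample_id=f"P{i + 1}", group="patient")
        for i in range(config.n_patients)
    ] + [
        SampleSpec(sample_id=f"C{i + 1}", group="control")
        for i in range(config.n_controls)
    ]
    pileups: dict[str, list[StrandedAlleleCount]] = {}
    truth: list[TruthRecord] = []
    rows = []
    for index, spec in enumerate(specs):
        rng = np.random.default_rng(sample_seed(config.seed, index))
        if spec.group == "patient" and spec.dnt_percent is None:
            spec.dnt_percent = float(rng.uniform(*config.dnt_range))
        pileup, sample_truth = simulate_sample(config, spec, rng)
        pileups[spec.sample_id] = pileup
        truth.extend(sample_truth)
        rows.append({
            "sample_id": spec.sample_id,
            "group": spec.group,
            "dnt_percent": spec.dnt_percent,
            "seed_index": index,
            "n_true_variants": len(sample_truth),
            "true_somatic_vaf": next(
                (t.true_vaf for t in sample_truth if t.true_class == "somatic"),
                None,
            ),
        })
    manifest = pd.DataFrame(
        rows,
        columns=["sample_id", "group", "dnt_percent", "seed_index",
                 "n_true_variants", "true_somatic_vaf"],
    )
    return pileups, truth, manifest


def samples_from_manifest(manifest: pd.DataFrame, truth: list[TruthRecord]) -> list[SampleRecord]:
    """Convert a simulated cohort's manifest + truth into SampleRecords
    scoreable by the evaluation module."""
    somatic = {
        t.sample_id: t.site for t in truth if t.true_class == "somatic"
    }
    records = []
    for row in manifest.itertuples():
        records.append(SampleRecord(
            sample_id=row.sample_id,
            group=row.group,
            dnt_percent=row.dnt_percent if pd.notna(row.dnt_percent) else None,
            known_variant=somatic.get(row.sample_id),
            known_undetectable=(
                row.group == "patient" and row.sample_id not in somatic
            ),
        ))
    return records
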