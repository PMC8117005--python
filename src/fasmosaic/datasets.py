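"""Bundled study fixtures: cohort metadata and the published call report.

The validation cohort comprises 8 ALPS-sFAS patients (P1-P8, somatic FAS
mutations confirmed by Sanger sequencing of isolated DNT cells) and 44
non-ALPS controls (C1-C44).  The published somatic-caller report lists 12
variant records with raw stranded read counts on GRCh37 chr10, all within
FAS exons 7-9 and their splice flanks.

The printed strand-bias scores come from a vendor-internal formula that
cannot be recomputed from the printed counts (per-strand total coverage is
not given); they are carried as metadata only.  The recurrent variant row
("RV", a germline heterozygous polymorphism seen in 46 of the 52 samples)
is not attributable to named samples and is excluded from per-sample
confusion accounting.
"""

from __future__ import annotations

from .pileup_io import (
    GenomicRegion,
    SampleRecord,
    StrandedAlleleCount,
    VariantSite,
)

#: Default target region: FAS exons 7-9 plus splice flanks on GRCh37 chr10.
#: Exact exon boundaries are not bundled; a single interval with margin
#: covers every validated call site (90771767-90774155) and keeps intronic
#: splice-site variants (e.g. c.651+2T>C) in scope.
DEFAULT_REGIONS: tuple[GenomicRegion, ...] = (
    GenomicRegion("chr10", 90770500, 90774500, "FAS_exons7-9_splice"),
)

#: DNT percentages per patient (flow cytometry; reference range 0-4%).
PATIENT_DNT_PERCENT: dict[str, float] = {
    "P1": 5.2, "P2": 30.7, "P3": 6.1, "P4": 5.5,
    "P5": 18.0, "P6": 12.0, "P7": 27.0, "P8": 4.0,
}

N_CONTROLS = 44

# Published call report, one tuple per row:
# (sample ids, chrom, pos, ref, var, printed VAF %, total coverage,
#  allele coverage, alt reads forward, alt reads reverse,
#  printed strand-bias score, germline-heterozygous flag)
_CALL_REPORT: tuple[tuple, ...] = (
    (("P1",),       "chr10", 90771840, "T", "C", 4.2,  239, 10,  4,  6, 0.5318, False),
    (("P2",),       "chr10", 90773878, "G", "-", 7.6,  394, 30, 10, 20, 0.5125, False),
    (("P3",),       "chr10", 90773947, "G", "A", 11.5, 399, 46, 25, 21, 0.5497, False),
    (("P4",),       "chr10", 90773876, "T", "A", 2.7,  367, 10,  5,  5, 0.6237, False),
    (("P5",),       "chr10", 90773125, "G", "A", 7.9,  101,  8,  4,  4, 0.5148, False),
    (("P6",),       "chr10", 90773100, "G", "T", 8.7,  195, 17,  7, 10, 0.6249, False),
    (("P7",),       "chr10", 90773099, "G", "T", 1.9,  212,  4,  2,  2, 0.5279, False),
    (("P1", "P4"),  "chr10", 90771774, "A", "G", 2.1,  141,  3,  1,  2, 0.6497, False),
    (("C5",),       "chr10", 90773123, "T", "C", 2.9,  104,  3,  1,  2, 0.5451, False),
    (("C18",),      "chr10", 90771767, "G", "A", 54.2, 172, 96, 40, 56, 0.5219, True),
    (("C32",),      "chr10", 90774155, "C", "T", 48.1, 395, 190, 92, 98, 0.5337, True),
    (("RV",),       "chr10", 90771829, "T", "C", 54.1, 206, 112, 61, 51, 0.5133, True),
)

#: Known causal somatic FAS variants per patient, as reported by the
#: validated caller.  P8's causal 3-bp deletion (c.812_814del) was seen at
#: only one supporting read — below any call threshold — and its genomic
#: coordinates are not published, so P8 carries no matchable site.
PATIENT_KNOWN_VARIANTS: dict[str, VariantSite] = {
    "P1": VariantSite("chr10", 90771840, "T", "C"),
    "P2": VariantSite("chr10", 90773878, "G", "-"),
    "P3": VariantSite("chr10", 90773947, "G", "A"),
    "P4": VariantSite("chr10", 90773876, "T", "A"),
    "P5": VariantSite("chr10", 90773125, "G", "A"),
    "P6": VariantSite("chr10", 90773100, "G", "T"),
    "P7": VariantSite("chr10", 90773099, "G", "T"),
}


def fixture_samples() -> list[SampleRecord]:
    """The 52-sample validation cohort (8 patients, 44 controls)."""
    samples = [
        SampleRecord(
            sample_id=pid,
            group="patient",
            dnt_percent=dnt,
            known_variant=PATIENT_KNOWN_VARIANTS.get(pid),
            known_undetectable=(pid not in PATIENT_KNOWN_VARIANTS),
        )
        for pid, dnt in PATIENT_DNT_PERCENT.items()
    ]
    samples += [
        SampleRecord(sample_id=f"C{i}", group="control")
        for i in range(1, N_CONTROLS + 1)
    ]
    return samples


def fixture_pileup() -> list[StrandedAlleleCount]:
    """The 12 published variant records as stranded allele counts."""
    return [
        StrandedAlleleCount(
            chrom=chrom, pos=pos, ref=ref, alt=alt,
            depth=cov, alt_fwd=fwd, alt_rev=rev,
        )
        for _, chrom, pos, ref, alt, _, cov, _, fwd, rev, _, _ in _CALL_REPORT
    ]


def fixture_report() -> list[dict]:
    """The published report rows as dictionaries (all printed columns)."""
    return [
        {
            "samples": list(samples), "chrom": chrom, "pos": pos,
            "ref": ref, "alt": alt, "printed_vaf_pct": vaf, "depth": cov,
            "allele_cov": ac, "alt_fwd": fwd, "alt_rev": rev,
            "printed_strand_bias": sb, "germline_flag": germ,
        }
        for samples, chrom, pos, ref, alt, vaf, cov, ac, fwd, rev, sb, germ
        in _CALL_REPORT
    ]


def load_fixtures() -> tuple[list[SampleRecord], list["object"]]:
    """Bundled cohort + call skeletons with classification unset.

    Returns the 52 sample records and 12 VariantCall objects carrying the
    published counts; classification is left as ``unset`` until the filter
    chain runs (filters_passed is provisionally True so the skeletons are
    valid containers).
    """
    from .caller import compute_vaf, strand_bias_pvalue, strand_bias_score
    from .pileup_io import VariantCall

    samples = fixture_samples()
    calls = []
    for row, counts in zip(fixture_report(), fixture_pileup()):
        calls.append(
            VariantCall(
                counts=counts,
                vaf=compute_vaf(counts),
                strand_bias=strand_bias_score(counts),
                sb_pvalue=strand_bias_pvalue(counts),
                filters_passed=True,
                classification="unset",
                sample_id=",".join(row["samples"]),
            )
        )
    return samples, calls
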