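"""Input/output for stranded pileup tables, BED target regions, and VCF.

The pipeline's native tabular format is a "pileup TSV": one row per
(site, candidate allele) with read evidence split by sequencing strand.
Coordinates are 1-based inclusive throughout the package; BED input
(0-based half-open) is converted on read.  Deletion alleles are encoded
with the alt token ``-`` and the deleted bases in the ref column;
conversion to anchored VCF representation happens only at write time.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pysam

DELETION_TOKEN = "-"
# Unknown upstream anchor base for deletion records (no reference genome
# is bundled); pysam and the VCF spec both accept N here.
_ANCHOR_BASE = "N"

_ALLELE_RE = re.compile(r"^([ACGTN]+|-)$")


class PileupFormatError(ValueError):
    """A pileup TSV row failed parsing or validation."""


@dataclass(frozen=True)
class GenomicRegion:
    """A 1-based inclusive genomic interval."""

    chrom: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start > self.end:
            raise ValueError(f"region start {self.start} > end {self.end}")

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


@dataclass(frozen=True)
class VariantSite:
    """A site plus ref/alt alleles, the identity key for matching calls."""

    chrom: str
    pos: int
    ref: str
    alt: str


@dataclass
class StrandedAlleleCount:
    """Per-site, per-allele read evidence split by strand.

    ``depth`` is the total coverage at the site; ``alt_fwd``/``alt_rev``
    the variant-supporting reads per strand.  Per-strand total depths are
    optional — real pileups carry them, tabulated reports often do not.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    depth: int
    alt_fwd: int
    alt_rev: int
    depth_fwd: int | None = None
    depth_rev: int | None = None

    def __post_init__(self) -> None:
        for name in ("depth", "alt_fwd", "alt_rev"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.alt_fwd + self.alt_rev > self.depth:
            raise ValueError(
                f"alt_fwd + alt_rev = {self.alt_fwd + self.alt_rev} exceeds "
                f"depth {self.depth} at {self.chrom}:{self.pos}"
            )
        if (self.depth_fwd is None) != (self.depth_rev is None):
            raise ValueError("depth_fwd and depth_rev must be given together")
        if self.depth_fwd is not None and self.depth_rev is not None:
            if self.depth_fwd < 0 or self.depth_rev < 0:
                raise ValueError("per-strand depths must be >= 0")
            if self.depth_fwd + self.depth_rev != self.depth:
                raise ValueError("depth_fwd + depth_rev must equal depth")
            if self.alt_fwd > self.depth_fwd or self.alt_rev > self.depth_rev:
                raise ValueError("per-strand alt count exceeds strand depth")

    @property
    def alt_count(self) -> int:
        return self.alt_fwd + self.alt_rev

    @property
    def site(self) -> VariantSite:
        return VariantSite(self.chrom, self.pos, self.ref, self.alt)


@dataclass
class VariantCall:
    """A candidate variant with VAF, strand-bias statistics and class."""

    counts: StrandedAlleleCount
    vaf: float
    strand_bias: float
    sb_pvalue: float
    filters_passed: bool
    classification: str  # somatic | germline_het | germline_hom | rejected
    failed_filters: tuple[str, ...] = ()
    sample_id: str = ""

    def __post_init__(self) -> None:
        if (self.classification == "rejected") != (not self.filters_passed):
            raise ValueError(
                "classification is 'rejected' iff filters_passed is False"
            )

    @property
    def site(self) -> VariantSite:
        return self.counts.site


@dataclass
class SampleRecord:
    """A study sample: patient or control, with DNT% and known variant."""

    sample_id: str
    group: str  # patient | control
    dnt_percent: float | None = None
    known_variant: VariantSite | None = None
    # The causal variant is known from orthogonal evidence but sits below
    # the caller's support threshold (a false negative by construction).
    known_undetectable: bool = False

    def __post_init__(self) -> None:
        if self.group not in ("patient", "control"):
            raise ValueError(f"group must be patient or control, got {self.group!r}")
        if self.dnt_percent is not None and not 0 <= self.dnt_percent <= 100:
            raise ValueError("dnt_percent must lie in [0, 100]")


def in_regions(chrom: str, pos: int, regions: Sequence[GenomicRegion] | None) -> bool:
    """True when (chrom, pos) falls in any region; True when regions is None."""
    if regions is None:
        return True
    return any(r.contains(chrom, pos) for r in regions)


_REQUIRED_COLS = ("chrom", "pos", "ref", "alt", "depth", "alt_fwd", "alt_rev")
_OPTIONAL_COLS = ("depth_fwd", "depth_rev")


def read_pileup_tsv(
    path: str | Path,
    regions: Sequence[GenomicRegion] | None = None,
) -> list[StrandedAlleleCount]:
    """Read a stranded pileup TSV, optionally restricting to target regions.

    The file must carry a header row with columns
    ``chrom pos ref alt depth alt_fwd alt_rev`` and optionally
    ``depth_fwd depth_rev``.  Row order is preserved; rows outside
    *regions* (when given) are dropped.
    """
    path = Path(path)
    records: list[StrandedAlleleCount] = []
    with path.open() as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise PileupFormatError(f"{path}: empty file, header row required")
        cols = header.split("\t")
        missing = [c for c in _REQUIRED_COLS if c not in cols]
        if missing:
            raise PileupFormatError(f"{path}: missing columns {missing}")
        idx = {c: cols.index(c) for c in cols}
        has_strand_depth = all(c in idx for c in _OPTIONAL_COLS)
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < len(cols):
                raise PileupFormatError(
                    f"{path}:{lineno}: expected {len(cols)} fields, got {len(fields)}"
                )
            try:
                rec = StrandedAlleleCount(
                    chrom=fields[idx["chrom"]],
                    pos=int(fields[idx["pos"]]),
                    ref=_validate_allele(fields[idx["ref"]]),
                    alt=_validate_allele(fields[idx["alt"]]),
                    depth=int(fields[idx["depth"]]),
                    alt_fwd=int(fields[idx["alt_fwd"]]),
                    alt_rev=int(fields[idx["alt_rev"]]),
                    depth_fwd=int(fields[idx["depth_fwd"]]) if has_strand_depth else None,
                    depth_rev=int(fields[idx["depth_rev"]]) if has_strand_depth else None,
                )
            except ValueError as exc:
                raise PileupFormatError(f"{path}:{lineno}: {exc}") from exc
            if in_regions(rec.chrom, rec.pos, regions):
                records.append(rec)
    return records


def _validate_allele(allele: str) -> str:
    allele = allele.upper().replace("–", DELETION_TOKEN)  # en dash -> '-'
    if not _ALLELE_RE.match(allele):
        raise ValueError(f"malformed allele {allele!r}")
    return allele


def write_pileup_tsv(records: Iterable[StrandedAlleleCount], path: str | Path) -> None:
    """Write records in the pileup TSV format (with per-strand depths when present)."""
    records = list(records)
    with_depths = any(r.depth_fwd is not None for r in records)
    cols = list(_REQUIRED_COLS) + (list(_OPTIONAL_COLS) if with_depths else [])
    with Path(path).open("w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in records:
            row = [r.chrom, str(r.pos), r.ref, r.alt, str(r.depth),
                   str(r.alt_fwd), str(r.alt_rev)]
            if with_depths:
                row += [str(r.depth_fwd if r.depth_fwd is not None else ""),
                        str(r.depth_rev if r.depth_rev is not None else "")]
            fh.write("\t".join(row) + "\n")


def read_bed(path: str | Path) -> list[GenomicRegion]:
    """Read a 3+ column BED (0-based half-open) into 1-based inclusive regions.

    Overlapping lines are kept as separate regions; no merging.
    """
    regions: list[GenomicRegion] = []
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED line needs >= 3 columns")
            chrom, start0, end0 = fields[0], int(fields[1]), int(fields[2])
            if start0 >= end0:
                raise ValueError(
                    f"{path}:{lineno}: BED start {start0} >= end {end0}"
                )
            label = fields[3] if len(fields) > 3 else ""
            regions.append(GenomicRegion(chrom, start0 + 1, end0, label))
    return regions


def write_bed(regions: Iterable[GenomicRegion], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.label}\n")


# --- VCF ----------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=chr10>
##INFO=<ID=VAF,Number=1,Type=Float,Description="Variant allele frequency (alt reads / depth)">
##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth at the site">
##INFO=<ID=SAF,Number=1,Type=Integer,Description="Variant reads on the forward strand">
##INFO=<ID=SAR,Number=1,Type=Integer,Description="Variant reads on the reverse strand">
##INFO=<ID=SBS,Number=1,Type=Float,Description="Strand-bias score (0.5 balanced, 1 one-sided)">
##INFO=<ID=SBP,Number=1,Type=Float,Description="Two-sided Fisher exact strand-bias p-value">
##INFO=<ID=CLS,Number=1,Type=String,Description="Classification: somatic, germline_het, germline_hom or rejected">
##INFO=<ID=SAMPLE,Number=1,Type=String,Description="Sample identifier">
##FILTER=<ID=min_vaf,Description="VAF below the minimum allele frequency">
##FILTER=<ID=min_allele_cov,Description="Fewer supporting reads than the minimum allele coverage">
##FILTER=<ID=min_strand_cov,Description="Per-strand coverage below the minimum">
##FILTER=<ID=strand_bias,Description="Strand-bias score above threshold with significant Fisher p">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def _vcf_alleles(counts: StrandedAlleleCount) -> tuple[int, str, str]:
    """Map internal allele encoding to (POS, REF, ALT) per VCF conventions.

    Deletions (alt token ``-``) are anchored on the preceding base, which
    is unknown without a reference genome and therefore written as N.
    """
    if counts.alt == DELETION_TOKEN:
        return counts.pos - 1, _ANCHOR_BASE + counts.ref, _ANCHOR_BASE
    return counts.pos, counts.ref, counts.alt


def write_vcf(calls: Sequence[VariantCall], path: str | Path) -> None:
    """Write calls as a minimal VCF 4.2 with VAF/strand evidence in INFO."""
    with Path(path).open("w") as fh:
        fh.write(_VCF_HEADER)
        for call in calls:
            c = call.counts
            pos, ref, alt = _vcf_alleles(c)
            filt = "PASS" if call.filters_passed else ";".join(call.failed_filters)
            info = (
                f"VAF={call.vaf:.6g};DP={c.depth};SAF={c.alt_fwd};SAR={c.alt_rev};"
                f"SBS={call.strand_bias:.4f};SBP={call.sb_pvalue:.6g};"
                f"CLS={call.classification}"
            )
            if call.sample_id:
                info += f";SAMPLE={call.sample_id}"
            fh.write(f"{c.chrom}\t{pos}\t.\t{ref}\t{alt}\t.\t{filt}\t{info}\n")


def read_vcf(path: str | Path) -> list[VariantCall]:
    """Read back a VCF written by :func:`write_vcf` (via pysam).

    Anchored deletion records are converted back to the internal
    ``-`` encoding so that a write/read round trip is the identity.
    """
    calls: list[VariantCall] = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            ref, alt = rec.ref, rec.alts[0]
            pos = rec.pos
            if len(ref) > len(alt) and ref.startswith(alt):
                # anchored deletion -> internal encoding
                pos = rec.pos + len(alt)
                ref, alt = ref[len(alt):], DELETION_TOKEN
            info = rec.info
            counts = StrandedAlleleCount(
                chrom=rec.chrom, pos=pos, ref=ref, alt=alt,
                depth=int(info["DP"]),
                alt_fwd=int(info["SAF"]), alt_rev=int(info["SAR"]),
            )
            filters = list(rec.filter.keys())
            passed = filters == ["PASS"] or not filters
            calls.append(VariantCall(
                counts=counts,
                vaf=counts.alt_count / counts.depth if counts.depth else float(info["VAF"]),
                strand_bias=float(info["SBS"]),
                sb_pvalue=float(info["SBP"]),
                filters_passed=passed,
                classification=str(info["CLS"]),
                failed_filters=() if passed else tuple(filters),
                sample_id=str(info.get("SAMPLE", "") or ""),
            ))
    return calls
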