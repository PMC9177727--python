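"""Reading, validation, and filtering of allelic count and clinical tables.

Input formats
-------------
Allelic counts arrive either as a TSV with the header
``sample_id  chrom  pos  assay  wt_reads  mut_reads  mutation_class``
or as a VCF 4.x file with per-sample ``AD`` (allele depth) fields, where
``AD[0]`` is the reference (wild-type) depth and ``AD[1]`` the first
alternate (mutant) depth.  Coordinates are 1-based throughout, as in VCF;
loci are matched on (chrom, pos, alt).

Sample filtering keeps tumors with a missense mutation and a total allelic
depth (both alleles summed) of at least 30 reads in *each* assay, DNA and
RNA, at the mutated locus.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal

import pysam

logger = logging.getLogger(__name__)

MIN_READS = 30

Assay = Literal["DNA", "RNA"]

#: machine-readable reason codes for sample exclusion
REASON_NOT_MISSENSE = "not_missense"
REASON_LOW_DEPTH_DNA = "low_depth_dna"
REASON_LOW_DEPTH_RNA = "low_depth_rna"
REASON_MISSING_DNA = "missing_dna_assay"
REASON_MISSING_RNA = "missing_rna_assay"


class IngestError(ValueError):
    """Malformed input row or file; message carries the row address."""


@dataclass(frozen=True)
class Locus:
    """1-based genomic coordinate with the alternate (mutant) allele."""

    chrom: str
    pos: int
    alt: str = ""

    def __str__(self) -> str:  # pragma: no cover - repr convenience
        return f"{self.chrom}:{self.pos}" + (f":{self.alt}" if self.alt else "")


@dataclass(frozen=True)
class AllelicCount:
    """Mutant/wild-type read counts at one locus in one sample, one assay.

    ``wt_reads`` is X and ``mut_reads`` is Y in the log-ratio definitions
    (beta = log2(Y_DNA/X_DNA), alpha = log2(Y_RNA/X_RNA)).
    """

    sample_id: str
    locus: Locus
    assay: Assay
    wt_reads: int
    mut_reads: int
    mutation_class: str = "missense"

    def __post_init__(self) -> None:
        if self.wt_reads < 0 or self.mut_reads < 0:
            raise IngestError(
                f"negative read count for sample {self.sample_id!r} at {self.locus}"
            )
        if self.assay not in ("DNA", "RNA"):
            raise IngestError(f"unknown assay label {self.assay!r}")

    @property
    def depth(self) -> int:
        return self.wt_reads + self.mut_reads


@dataclass(frozen=True)
class ClinicalRecord:
    """Clinicopathological covariates and survival endpoints for one tumor."""

    sample_id: str
    er_status: str = "missing"
    pr_status: str = "missing"
    her2_status: str = "missing"
    grade: int | None = None
    size: float | None = None
    stage: int | None = None
    pam50: str = "missing"
    intclust: str = "missing"
    age: float | None = None
    os_time: float | None = None
    os_event: int | None = None
    dss_time: float | None = None
    dss_event: int | None = None

    def __post_init__(self) -> None:
        for t, e, name in (
            (self.os_time, self.os_event, "os"),
            (self.dss_time, self.dss_event, "dss"),
        ):
            if t is not None and t < 0:
                raise IngestError(f"negative {name} time for {self.sample_id!r}")
            if e is not None and t is None:
                raise IngestError(
                    f"{name} event without a time for {self.sample_id!r}"
                )


@dataclass
class FilterReport:
    """Per-exclusion reason codes recorded while filtering a cohort."""

    retained: list[str] = field(default_factory=list)
    excluded: dict[str, str] = field(default_factory=dict)

    @property
    def n_input(self) -> int:
        return len(self.retained) + len(self.excluded)


_TSV_COLUMNS = [
    "sample_id",
    "chrom",
    "pos",
    "assay",
    "wt_reads",
    "mut_reads",
    "mutation_class",
]


def _parse_tsv_row(row: dict, lineno: int) -> AllelicCount:
    try:
        pos = int(row["pos"])
        wt = int(row["wt_reads"])
        mut = int(row["mut_reads"])
    except (KeyError, TypeError, ValueError) as exc:
        raise IngestError(f"line {lineno}: malformed field ({exc})") from exc
    if wt < 0 or mut < 0:
        raise IngestError(f"line {lineno}: negative read count")
    assay = row["assay"].strip().upper()
    if assay not in ("DNA", "RNA"):
        raise IngestError(f"line {lineno}: unknown assay label {row['assay']!r}")
    return AllelicCount(
        sample_id=row["sample_id"],
        locus=Locus(chrom=row["chrom"], pos=pos, alt=row.get("alt", "")),
        assay=assay,
        wt_reads=wt,
        mut_reads=mut,
        mutation_class=row.get("mutation_class", "missense").strip().lower(),
    )


def read_counts(path: str, format: str = "tsv") -> list[AllelicCount]:
    """Read allelic counts from ``path``.

    Parameters
    ----------
    path:
        File to read.
    format:
        ``"tsv"`` for the tab-separated table described in the module
        docstring, or ``"vcf_ad"`` for a VCF with per-sample AD fields.
        VCF records must carry ``ASSAY`` (DNA/RNA) and optionally
        ``MUTCLASS`` in INFO; sites without them default to DNA/missense.

    Raises
    ------
    IngestError
        On a missing required column, a negative count, or an unknown
        assay label, with the offending row identified in the message.
    """
    if format == "tsv":
        return _read_counts_tsv(path)
    if format == "vcf_ad":
        return _read_counts_vcf(path)
    raise IngestError(f"unknown format {format!r}")


def _read_counts_tsv(path: str) -> list[AllelicCount]:
    records: list[AllelicCount] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(_TSV_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise IngestError(f"missing required column(s): {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            records.append(_parse_tsv_row(row, lineno))
    return records


def _read_counts_vcf(path: str) -> list[AllelicCount]:
    records: list[AllelicCount] = []
    with pysam.VariantFile(path) as vcf:
        for rec in vcf:
            assay = str(rec.info.get("ASSAY", "DNA")).upper()
            mutclass = str(rec.info.get("MUTCLASS", "missense")).lower()
            alt = rec.alts[0] if rec.alts else ""
            for sample_name, call in rec.samples.items():
                ad = call.get("AD")
                if ad is None or ad[0] is None:
                    continue
                wt, mut = int(ad[0]), int(ad[1])
                records.append(
                    AllelicCount(
                        sample_id=sample_name,
                        locus=Locus(chrom=str(rec.chrom), pos=rec.pos, alt=alt),
                        assay=assay,  # type: ignore[arg-type]
                        wt_reads=wt,
                        mut_reads=mut,
                        mutation_class=mutclass,
                    )
                )
    return records


def write_counts(records: Iterable[AllelicCount], path: str) -> None:
    """Write counts as the canonical TSV; inverse of :func:`read_counts`."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_TSV_COLUMNS + ["alt"])
        for r in records:
            writer.writerow(
                [
                    r.sample_id,
                    r.locus.chrom,
                    r.locus.pos,
                    r.assay,
                    r.wt_reads,
                    r.mut_reads,
                    r.mutation_class,
                    r.locus.alt,
                ]
            )


def pair_counts(
    counts: Iterable[AllelicCount],
) -> dict[tuple[str, Locus], dict[str, AllelicCount]]:
    """Group counts by (sample, locus) into {'DNA': ..., 'RNA': ...} pairs.

    Duplicate (sample, locus, assay) entries keep the highest-depth record.
    """
    pairs: dict[tuple[str, Locus], dict[str, AllelicCount]] = {}
    for rec in counts:
        key = (rec.sample_id, rec.locus)
        slot = pairs.setdefault(key, {})
        prev = slot.get(rec.assay)
        if prev is None or rec.depth > prev.depth:
            slot[rec.assay] = rec
    return pairs


def filter_samples(
    counts: Iterable[AllelicCount],
    min_reads: int = MIN_READS,
    collapse: str = "all",
) -> tuple[list[tuple[AllelicCount, AllelicCount]], FilterReport]:
    """Apply the cohort quality filters to paired DNA/RNA counts.

    A (sample, locus) pair is retained iff the mutation is missense and the
    summed depth of both alleles is at least ``min_reads`` in the DNA assay
    *and* in the RNA assay.  With ``collapse="keep-max-depth"`` a sample
    carrying several qualifying missense mutations contributes only the
    locus with the highest combined depth; with ``"all"`` (default) each
    mutation locus yields its own profile downstream.

    Returns
    -------
    (pairs, report)
        ``pairs`` is a list of (dna_count, rna_count) tuples;  ``report``
        records every exclusion with a machine-readable reason code.
    """
    report = FilterReport()
    retained: list[tuple[AllelicCount, AllelicCount]] = []
    for (sample_id, locus), assays in pair_counts(counts).items():
        key = f"{sample_id}@{locus}"
        dna, rna = assays.get("DNA"), assays.get("RNA")
        if dna is None:
            report.excluded[key] = REASON_MISSING_DNA
        elif rna is None:
            report.excluded[key] = REASON_MISSING_RNA
        elif not (dna.mutation_class == "missense" and rna.mutation_class == "missense"):
            report.excluded[key] = REASON_NOT_MISSENSE
        elif dna.depth < min_reads:
            report.excluded[key] = REASON_LOW_DEPTH_DNA
        elif rna.depth < min_reads:
            report.excluded[key] = REASON_LOW_DEPTH_RNA
        else:
            retained.append((dna, rna))
            report.retained.append(key)
    if collapse == "keep-max-depth":
        best: dict[str, tuple[AllelicCount, AllelicCount]] = {}
        for dna, rna in retained:
            prev = best.get(dna.sample_id)
            if prev is None or dna.depth + rna.depth > prev[0].depth + prev[1].depth:
                best[dna.sample_id] = (dna, rna)
        retained = list(best.values())
        report.retained = [f"{d.sample_id}@{d.locus}" for d, _ in retained]
    for key, reason in report.excluded.items():
        logger.info("excluded %s: %s", key, reason)
    return retained, report


def read_clinical(path: str) -> list[ClinicalRecord]:
    """Read a clinical covariate CSV (columns matching ClinicalRecord fields)."""

    def _opt_float(v: str) -> float | None:
        return None if v in ("", "NA", "missing") else float(v)

    def _opt_int(v: str) -> int | None:
        return None if v in ("", "NA", "missing") else int(v)

    records = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            records.append(
                ClinicalRecord(
                    sample_id=row["sample_id"],
                    er_status=row.get("er_status", "missing") or "missing",
                    pr_status=row.get("pr_status", "missing") or "missing",
                    her2_status=row.get("her2_status", "missing") or "missing",
                    grade=_opt_int(row.get("grade", "")),
                    size=_opt_float(row.get("size", "")),
                    stage=_opt_int(row.get("stage", "")),
                    pam50=row.get("pam50", "missing") or "missing",
                    intclust=row.get("intclust", "missing") or "missing",
                    age=_opt_float(row.get("age", "")),
                    os_time=_opt_float(row.get("os_time", "")),
                    os_event=_opt_int(row.get("os_event", "")),
                    dss_time=_opt_float(row.get("dss_time", "")),
                    dss_event=_opt_int(row.get("dss_event", "")),
                )
            )
    return records
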