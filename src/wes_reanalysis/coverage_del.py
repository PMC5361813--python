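"""Homozygous/hemizygous intragenic deletion calling from exon coverage.

Windowed CNV callers typically require three or more contiguous deleted
exons; a homozygous single-exon deletion instead manifests as a coverage
"dropout": near-zero reads over one exon in one sample while the cohort
covers it reliably. Coverage is normalized per sample (length-corrected
read rate divided by the sample's median rate), making samples with
different library depths comparable, and dropouts are called against the
cohort median per exon.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .models import PedigreeMember

log = logging.getLogger(__name__)

COVERAGE_COLUMNS = ["sample", "gene", "exon_index", "exon_length_bp", "read_count"]


@dataclass
class DeletionParams:
    """Dropout thresholds (this caller's own design, exposed for tuning).

    ``dropout_ratio_max``: maximum proband/cohort-median normalized
    coverage ratio for a deleted exon. ``cohort_median_min``: minimum
    cohort median normalized coverage for the exon to serve as a reliable
    reference. ``min_exons``: minimum contiguous run length; 1 admits
    single-exon dropout alleles, 3 reproduces the windowed-caller
    behaviour this method exists to improve on.
    """

    dropout_ratio_max: float = 0.10
    cohort_median_min: float = 0.30
    min_exons: int = 1

    def __post_init__(self):
        if not self.dropout_ratio_max < self.cohort_median_min:
            raise ValueError("dropout_ratio_max must be < cohort_median_min")
        if self.min_exons < 1:
            raise ValueError("min_exons must be >= 1")


@dataclass(frozen=True)
class DeletionCall:
    sample: str
    gene: str
    exon_start: int
    exon_end: int
    zygosity: str  # homozygous | hemizygous
    mean_ratio: float


def normalize_exon_coverage(records: pd.DataFrame) -> pd.DataFrame:
    """Add a ``normalized_coverage`` column.

    normalized = (read_count / exon_length) / median over the sample's
    exons of (read_count / exon_length). Invariant to uniform scaling of
    a sample's read counts. Requires >= 2 samples; a sample whose exons
    are all zero has no usable baseline and raises.
    """
    missing = [c for c in COVERAGE_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"coverage table lacks columns: {missing}")
    if records["sample"].nunique() < 2:
        raise ValueError("normalization requires at least 2 samples in the cohort")
    df = records.copy()
    df["_rate"] = df["read_count"] / df["exon_length_bp"]
    med = df.groupby("sample")["_rate"].transform("median")
    zero = med <= 0
    if zero.any():
        bad = sorted(df.loc[zero, "sample"].unique())
        raise ValueError(f"sample(s) with zero median coverage: {bad}")
    df["normalized_coverage"] = df["_rate"] / med
    return df.drop(columns="_rate")


def call_dropout_deletions(
    normalized: pd.DataFrame,
    pedigree: Optional[Sequence[PedigreeMember]] = None,
    params: DeletionParams = DeletionParams(),
    x_genes: frozenset = frozenset(),
) -> list[DeletionCall]:
    """Call maximal contiguous exon dropout runs per sample and gene.

    An exon qualifies when the sample's normalized coverage is at most
    ``dropout_ratio_max`` times the cohort median while that median is at
    least ``cohort_median_min``. Runs of at least ``min_exons`` qualifying
    exons become calls; zygosity is hemizygous for chrX genes in males
    (``x_genes`` names them), homozygous otherwise.
    """
    if "normalized_coverage" not in normalized.columns:
        raise ValueError("run normalize_exon_coverage first")
    sex_of = {m.sample_id: m.sex for m in pedigree} if pedigree else {}

    medians = (
        normalized.groupby(["gene", "exon_index"])["normalized_coverage"]
        .median()
        .rename("cohort_median")
    )
    df = normalized.join(medians, on=["gene", "exon_index"])

    calls: list[DeletionCall] = []
    for (sample, gene), sub in df.groupby(["sample", "gene"], sort=True):
        sub = sub.sort_values("exon_index")
        run: list[tuple[int, float]] = []
        last_exon = None

        def flush():
            if len(run) >= params.min_exons:
                ratios = [r for _, r in run]
                zyg = (
                    "hemizygous"
                    if gene in x_genes and sex_of.get(sample) == "male"
                    else "homozygous"
                )
                calls.append(
                    DeletionCall(
                        sample, gene, run[0][0], run[-1][0], zyg,
                        sum(ratios) / len(ratios),
                    )
                )

        for row in sub.itertuples(index=False):
            exon = int(row.exon_index)
            reliable = row.cohort_median >= params.cohort_median_min
            ratio = (
                row.normalized_coverage / row.cohort_median if reliable else float("nan")
            )
            is_dropout = reliable and ratio <= params.dropout_ratio_max
            contiguous = last_exon is None or exon == last_exon + 1
            if is_dropout and contiguous and run:
                run.append((exon, ratio))
            elif is_dropout:
                flush()
                run = [(exon, ratio)]
            else:
                flush()
                run = []
            last_exon = exon
        flush()

    calls.sort(key=lambda c: (c.sample, c.gene, c.exon_start))
    return calls


def write_deletions(calls: Sequence[DeletionCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tgene\texon_start\texon_end\tzygosity\tmean_ratio\n")
        for c in calls:
            fh.write(
                f"{c.sample}\t{c.gene}\t{c.exon_start}\t{c.exon_end}\t"
                f"{c.zygosity}\t{c.mean_ratio:.6g}\n"
            )
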