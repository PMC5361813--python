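"""B-allele frequency, absence-of-heterozygosity, and UPD detection.

The B-allele frequency (BAF) of a sample at a variant site is the
fraction of reads supporting the alternate allele: ~0.5 at heterozygous
sites, ~0 or ~1 at homozygous sites. A run of markers with no
heterozygous BAF signals absence of heterozygosity (AOH). A single
chromosome almost entirely covered by AOH while the rest of the genome is
heterozygous is the signature of isodisomic uniparental disomy (UPD);
AOH spread over many chromosomes instead suggests consanguinity.
Heterodisomic UPD produces no AOH and is invisible to this method.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

from .models import SiteCall, chromosome_sort_key

log = logging.getLogger(__name__)

AUTOSOMES = frozenset(str(i) for i in range(1, 23))


@dataclass(frozen=True)
class BafPoint:
    chromosome: str
    position: int
    baf: float
    total_reads: int
    informative: bool


@dataclass
class AohParams:
    """Detection parameters; tunable, since the phenomenon fixes none of them.

    ``het_band`` is the BAF interval treated as heterozygous;
    ``upd_chromosome_fraction`` is the minimum fraction of a chromosome's
    informative markers inside AOH for a whole-chromosome (UPD-like) flag;
    ``max_background_aoh_fraction`` bounds AOH on all other autosomes (the
    single-region condition).
    """

    min_total_reads: int = 15
    het_band: tuple[float, float] = (0.15, 0.85)
    min_markers_per_segment: int = 50
    upd_chromosome_fraction: float = 0.80
    max_background_aoh_fraction: float = 0.10

    def __post_init__(self):
        lo, hi = self.het_band
        if not 0 <= lo < hi <= 1:
            raise ValueError("het_band must satisfy 0 <= lower < upper <= 1")


@dataclass(frozen=True)
class AohSegment:
    chromosome: str
    start: int
    end: int
    n_markers: int
    fraction_of_chromosome_span: float


@dataclass(frozen=True)
class UpdFlag:
    chromosome: str
    aoh_marker_fraction: float
    background_aoh_fraction: float


def compute_baf(
    calls: Sequence[SiteCall],
    sample: str,
    params: AohParams = AohParams(),
) -> list[BafPoint]:
    """One BAF point per variant site with depth data for the sample.

    Points with total depth >= ``min_total_reads`` are marked informative.
    Output is sorted by chromosome then position.
    """
    points = []
    for site in calls:
        g = site.genotype_of(sample)
        if g.is_missing or g.total_reads == 0:
            continue
        points.append(
            BafPoint(
                site.chromosome,
                site.position,
                g.alt_reads / g.total_reads,
                g.total_reads,
                g.total_reads >= params.min_total_reads,
            )
        )
    points.sort(key=lambda p: (chromosome_sort_key(p.chromosome), p.position))
    return points


def detect_aoh(
    baf_points: Sequence[BafPoint],
    params: AohParams = AohParams(),
) -> list[AohSegment]:
    """Maximal runs of consecutive informative markers outside the het band.

    Non-informative (low-depth) markers are skipped and neither extend nor
    break a run. Runs with at least ``min_markers_per_segment`` markers are
    reported; the segment spans the first to last marker of the run.
    """
    keys = [(chromosome_sort_key(p.chromosome), p.position) for p in baf_points]
    if keys != sorted(keys):
        raise ValueError("detect_aoh requires input sorted by chromosome, position")
    lo, hi = params.het_band

    by_chrom: dict[str, list[BafPoint]] = {}
    chrom_span: dict[str, tuple[int, int]] = {}
    for p in baf_points:
        if p.chromosome in chrom_span:
            a, b = chrom_span[p.chromosome]
            chrom_span[p.chromosome] = (min(a, p.position), max(b, p.position))
        else:
            chrom_span[p.chromosome] = (p.position, p.position)
        if p.informative:
            by_chrom.setdefault(p.chromosome, []).append(p)

    segments: list[AohSegment] = []
    for chrom in sorted(by_chrom, key=chromosome_sort_key):
        markers = by_chrom[chrom]
        span_a, span_b = chrom_span[chrom]
        span = max(span_b - span_a, 1)
        run: list[BafPoint] = []
        for p in markers + [None]:  # sentinel flushes the last run
            outside = p is not None and (p.baf < lo or p.baf > hi)
            if outside:
                run.append(p)
                continue
            if len(run) >= params.min_markers_per_segment:
                segments.append(
                    AohSegment(
                        chrom,
                        run[0].position,
                        run[-1].position,
                        len(run),
                        (run[-1].position - run[0].position) / span,
                    )
                )
            run = []
    return segments


def flag_upd(
    segments: Sequence[AohSegment],
    markers_per_chromosome: dict[str, int],
    params: AohParams = AohParams(),
) -> list[UpdFlag]:
    """Flag whole-chromosome AOH consistent with isodisomic UPD.

    An autosome is flagged iff its AOH segments cover at least
    ``upd_chromosome_fraction`` of its informative markers while AOH on
    all other autosomes stays below ``max_background_aoh_fraction`` (the
    single-region condition). Multiple qualifying chromosomes suggest
    consanguinity instead and nothing is flagged (logged). chrX is
    excluded: a male's single X mimics AOH.
    """
    aoh_markers: dict[str, int] = {}
    for seg in segments:
        if seg.chromosome in AUTOSOMES:
            aoh_markers[seg.chromosome] = aoh_markers.get(seg.chromosome, 0) + seg.n_markers

    autosome_totals = {
        c: n for c, n in markers_per_chromosome.items() if c in AUTOSOMES and n > 0
    }
    candidates = [
        c
        for c, total in autosome_totals.items()
        if aoh_markers.get(c, 0) / total >= params.upd_chromosome_fraction
    ]
    if len(candidates) > 1:
        log.warning(
            "whole-chromosome AOH on %d chromosomes (%s): consanguinity pattern, not UPD",
            len(candidates), ",".join(sorted(candidates, key=chromosome_sort_key)),
        )
        return []

    flags = []
    for c in candidates:
        other_total = sum(n for ch, n in autosome_totals.items() if ch != c)
        other_aoh = sum(n for ch, n in aoh_markers.items() if ch != c)
        background = other_aoh / other_total if other_total else 0.0
        if background <= params.max_background_aoh_fraction:
            flags.append(
                UpdFlag(c, aoh_markers.get(c, 0) / autosome_totals[c], background)
            )
    return flags


def markers_per_chromosome(baf_points: Sequence[BafPoint]) -> dict[str, int]:
    """Count informative markers per chromosome (input to flag_upd)."""
    counts: dict[str, int] = {}
    for p in baf_points:
        if p.informative:
            counts[p.chromosome] = counts.get(p.chromosome, 0) + 1
    return counts


def infer_upd_parent(
    calls: Sequence[SiteCall],
    chromosome: str,
    proband: str,
    father: str,
    mother: str,
    majority: float = 0.90,
) -> tuple[str, int]:
    """Infer the contributing parent of a flagged chromosome.

    Counts Mendelian-inconsistent sites where the proband is homozygous
    for an allele one parent lacks while the other parent carries it; the
    parent carrying the proband's allele at >= ``majority`` of such sites
    contributed both homologs. Returns (origin, supporting site count)
    with origin in {paternal, maternal, undetermined}.
    """
    paternal = maternal = 0
    for site in calls:
        if site.chromosome != chromosome:
            continue
        pg = site.genotype_of(proband)
        fg = site.genotype_of(father)
        mg = site.genotype_of(mother)
        if pg.genotype not in ("hom_alt", "hom_ref") or fg.is_missing or mg.is_missing:
            continue
        if pg.genotype == "hom_alt":
            father_carries = fg.has_alt
            mother_carries = mg.has_alt
        else:
            father_carries = fg.genotype in ("hom_ref", "het", "hemi_ref")
            mother_carries = mg.genotype in ("hom_ref", "het", "hemi_ref")
        if father_carries and not mother_carries:
            paternal += 1
        elif mother_carries and not father_carries:
            maternal += 1

    total = paternal + maternal
    if total == 0:
        return "undetermined", 0
    if paternal / total >= majority:
        return "paternal", paternal
    if maternal / total >= majority:
        return "maternal", maternal
    return "undetermined", total


def brute_force_aoh(
    baf_points: Sequence[BafPoint],
    params: AohParams = AohParams(),
) -> list[AohSegment]:
    """Independent maximal-run oracle built on regular-expression matching.

    Encodes each chromosome's informative markers as a 0/1 string (1 =
    BAF outside the het band) and extracts maximal ``1+`` runs with the
    regex engine — a mechanism entirely separate from the scanner it
    cross-checks. Intended for test inputs (<= 10^4 markers).
    """
    import re

    lo, hi = params.het_band
    by_chrom: dict[str, list[BafPoint]] = {}
    chrom_span: dict[str, tuple[int, int]] = {}
    for p in baf_points:
        if p.chromosome in chrom_span:
            a, b = chrom_span[p.chromosome]
            chrom_span[p.chromosome] = (min(a, p.position), max(b, p.position))
        else:
            chrom_span[p.chromosome] = (p.position, p.position)
        if p.informative:
            by_chrom.setdefault(p.chromosome, []).append(p)

    segments = []
    for chrom in sorted(by_chrom, key=chromosome_sort_key):
        pts = sorted(by_chrom[chrom], key=lambda p: p.position)
        span_a, span_b = chrom_span[chrom]
        span = max(span_b - span_a, 1)
        encoded = "".join("1" if (p.baf < lo or p.baf > hi) else "0" for p in pts)
        for m in re.finditer(r"1+", encoded):
            i, j = m.start(), m.end() - 1
            if j - i + 1 >= params.min_markers_per_segment:
                segments.append(
                    AohSegment(
                        chrom,
                        pts[i].position,
                        pts[j].position,
                        j - i + 1,
                        (pts[j].position - pts[i].position) / span,
                    )
                )
    return segments
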