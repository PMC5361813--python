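"""De novo variant detection: parental subtraction plus read-count criteria.

The detector first removes every proband variant whose alternate allele is
called in either parent (in-silico subtraction), then applies four allelic
depth criteria that separate genuine de novo mutations from library and
alignment artifacts:

1. proband alternate read count strictly greater than 5;
2. proband alternate/reference read ratio strictly greater than 30%;
3. reference read count strictly greater than 10 in both parents;
4. alternate/reference read ratio strictly less than 5% in both parents.

All inequalities are strict. The alt/ref ratio convention (not alt/total)
is deliberate; the mosaicism module uses alt/total for its own statistic.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

from .models import CandidateVariant, SiteCall

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DnmConfig:
    """Thresholds for the four de novo read-count criteria (all strict)."""

    proband_min_alt_reads: int = 5
    proband_min_alt_ref_ratio: float = 0.30
    parent_min_ref_reads: int = 10
    parent_max_alt_ref_ratio: float = 0.05

    def __post_init__(self):
        if self.proband_min_alt_reads < 0 or self.parent_min_ref_reads < 0:
            raise ValueError("read-count thresholds must be non-negative")
        if not 0 <= self.proband_min_alt_ref_ratio <= 1:
            raise ValueError("proband_min_alt_ref_ratio must be in [0, 1]")
        if not 0 <= self.parent_max_alt_ref_ratio <= 1:
            raise ValueError("parent_max_alt_ref_ratio must be in [0, 1]")


@dataclass
class DnmDecision:
    passed: bool
    failed_criteria: list[int] = field(default_factory=list)
    indeterminate_criteria: list[int] = field(default_factory=list)


def _ratio(alt: int, ref: int) -> float:
    """alt/ref with 0/0 -> 0 and k/0 -> +inf (k > 0)."""
    if ref == 0:
        return math.inf if alt > 0 else 0.0
    return alt / ref


def dnm_decision(
    proband_alt: int,
    proband_ref: int,
    father_alt: int,
    father_ref: int,
    mother_alt: int,
    mother_ref: int,
    config: DnmConfig = DnmConfig(),
) -> DnmDecision:
    """Evaluate the four read-count criteria on raw depths.

    A parent with zero reference reads fails criterion 3 and renders its
    criterion 4 ratio indeterminate (reported, never passed silently).
    """
    failed: list[int] = []
    indeterminate: list[int] = []

    if not proband_alt > config.proband_min_alt_reads:
        failed.append(1)
    if not _ratio(proband_alt, proband_ref) > config.proband_min_alt_ref_ratio:
        failed.append(2)
    if not (father_ref > config.parent_min_ref_reads and mother_ref > config.parent_min_ref_reads):
        failed.append(3)
    c4_ok = True
    for alt, ref in ((father_alt, father_ref), (mother_alt, mother_ref)):
        if ref == 0:
            indeterminate.append(4)
            c4_ok = False
        elif not alt / ref < config.parent_max_alt_ref_ratio:
            c4_ok = False
    if not c4_ok and 4 not in indeterminate:
        failed.append(4)
    return DnmDecision(passed=not failed and not indeterminate, failed_criteria=failed,
                       indeterminate_criteria=sorted(set(indeterminate)))


def apply_dnm_criteria(
    site: SiteCall,
    proband: str,
    father: str,
    mother: str,
    config: DnmConfig = DnmConfig(),
) -> DnmDecision:
    """Apply the four criteria to one site of a trio."""
    p = site.genotype_of(proband)
    f = site.genotype_of(father)
    m = site.genotype_of(mother)
    return dnm_decision(
        p.alt_reads, p.ref_reads, f.alt_reads, f.ref_reads, m.alt_reads, m.ref_reads, config
    )


def subtract_parental(
    calls: Sequence[SiteCall],
    proband: str,
    father: str,
    mother: str,
) -> list[SiteCall]:
    """In-silico parental subtraction.

    Returns proband variant sites (alternate allele called) at which
    neither parent has the alternate allele called. Sites where a parent's
    genotype is missing are excluded (subtraction needs evidence of
    absence) and counted in a log message.
    """
    retained: list[SiteCall] = []
    n_missing = 0
    for site in calls:
        pg = site.genotype_of(proband)
        fg = site.genotype_of(father)
        mg = site.genotype_of(mother)
        if not pg.has_alt:
            continue
        if fg.is_missing or mg.is_missing:
            n_missing += 1
            continue
        if not fg.has_alt and not mg.has_alt:
            retained.append(site)
    if n_missing:
        log.info("subtract_parental: %d proband variant sites skipped (parent genotype missing)", n_missing)
    return retained


def find_de_novo(
    calls: Sequence[SiteCall],
    proband: str,
    father: str,
    mother: str,
    config: DnmConfig = DnmConfig(),
    family_id: str = ".",
) -> list[CandidateVariant]:
    """Parental subtraction followed by the four read-count criteria.

    Candidates carry the proband allele fraction and per-parent alt/ref
    ratios as evidence.
    """
    candidates = []
    for site in subtract_parental(calls, proband, father, mother):
        decision = apply_dnm_criteria(site, proband, father, mother, config)
        if not decision.passed:
            continue
        p = site.genotype_of(proband)
        f = site.genotype_of(father)
        m = site.genotype_of(mother)
        candidates.append(
            CandidateVariant(
                site=site,
                sample_id=proband,
                family_id=family_id,
                inheritance_class="de_novo",
                workflow_step=4,
                evidence={
                    "proband_alt_fraction": p.alt_reads / p.total_reads if p.total_reads else 0.0,
                    "father_alt_ref_ratio": _ratio(f.alt_reads, f.ref_reads),
                    "mother_alt_ref_ratio": _ratio(m.alt_reads, m.ref_reads),
                },
            )
        )
    return candidates
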