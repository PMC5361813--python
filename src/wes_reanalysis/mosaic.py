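"""Parental mosaicism detection from variant-read fractions.

A constitutional heterozygote is expected to show ~50% variant reads; a
parent transmitting a variant to affected children while carrying it in
only a fraction of cells shows a markedly lower fraction. The module
quantifies per-sample variant allele fractions (alt/total, the statistic
this analysis uses, distinct from the alt/ref ratios of the de novo
criteria) and tests deviation from 0.5 with an exact two-sided binomial
test (minimum-likelihood definition: the sum of probabilities of all
outcomes no more probable than the observation).
"""
from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Optional, Sequence

from scipy import stats

from .models import PedigreeMember, SiteCall


@dataclass
class MosaicConfig:
    """Decision parameters for flagging a parent as potentially mosaic.

    ``alpha`` = 0.01 lies conservatively between fractions the analysis
    treats as clearly deviant and clearly balanced. ``min_parent_alt_reads``
    requires carrier evidence: a parent with (near) zero alternate reads
    deviates from 50% but is a non-carrier, not a mosaic.
    """

    alpha: float = 0.01
    min_total_reads: int = 20
    require_affected_carriers: int = 1
    min_parent_alt_reads: int = 3

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class MosaicEvidence:
    sample_id: str
    site: SiteCall
    alt_reads: int
    total_reads: int
    fraction: Fraction
    p_value: float
    flagged: bool
    reason: Optional[str] = None


def variant_allele_fraction(alt_reads: int, total_reads: int) -> Fraction:
    """Exact ratio of variant to total reads."""
    if total_reads <= 0:
        raise ValueError("total_reads must be > 0")
    if alt_reads > total_reads:
        raise ValueError("alt_reads cannot exceed total_reads")
    return Fraction(alt_reads, total_reads)


def binomial_deviation_test(alt_reads: int, total_reads: int) -> float:
    """Exact two-sided binomial p-value against success probability 0.5.

    Minimum-likelihood two-sided definition; at p=0.5 the null is
    symmetric, so p(k, n) = p(n-k, n) and the observation at the mode
    gives p = 1.
    """
    if total_reads <= 0:
        raise ValueError("total_reads must be > 0")
    return stats.binomtest(alt_reads, total_reads, p=0.5, alternative="two-sided").pvalue


def flag_parental_mosaic(
    site: SiteCall,
    pedigree: Sequence[PedigreeMember],
    config: MosaicConfig = MosaicConfig(),
) -> list[MosaicEvidence]:
    """Evaluate each parent of the family at one shared variant site.

    A parent is flagged iff: enough affected children carry the variant;
    the parent shows carrier-level alternate reads at adequate depth; the
    parent's fraction deviates from 50% (p < alpha); and every carrier
    child is consistent with constitutional heterozygosity (p >= alpha).
    Evidence rows record all fractions and p-values either way.
    """
    by_id = {m.sample_id: m for m in pedigree}
    parent_ids = sorted(
        {m.father_id for m in pedigree if m.father_id}
        | {m.mother_id for m in pedigree if m.mother_id}
    )
    carriers = [
        m
        for m in pedigree
        if m.affected == "affected"
        and m.sample_id in site.genotypes
        and site.genotype_of(m.sample_id).has_alt
        and m.sample_id not in parent_ids
    ]

    child_evidence: list[MosaicEvidence] = []
    children_consistent = True
    for child in carriers:
        g = site.genotype_of(child.sample_id)
        if g.total_reads == 0:
            continue
        p = binomial_deviation_test(g.alt_reads, g.total_reads)
        child_evidence.append(
            MosaicEvidence(
                child.sample_id, site, g.alt_reads, g.total_reads,
                variant_allele_fraction(g.alt_reads, g.total_reads), p, False,
            )
        )
        if p < config.alpha:
            children_consistent = False

    enough_carriers = len(carriers) >= config.require_affected_carriers

    out: list[MosaicEvidence] = []
    for pid in parent_ids:
        if pid not in site.genotypes or pid not in by_id:
            continue
        g = site.genotype_of(pid)
        if g.is_missing or g.total_reads == 0:
            continue
        fraction = variant_allele_fraction(g.alt_reads, g.total_reads)
        p = binomial_deviation_test(g.alt_reads, g.total_reads)
        flagged = False
        reason = None
        if g.total_reads < config.min_total_reads:
            reason = "insufficient_depth"
        elif g.alt_reads < config.min_parent_alt_reads:
            reason = "no_carrier_evidence"
        elif fraction > Fraction(1, 2):
            # mosaicism depletes the variant fraction below the
            # constitutional 50%; balanced or enriched parents (e.g.
            # homozygotes) are not mosaic however extreme their p-value
            reason = "not_depleted"
        elif not enough_carriers:
            reason = "too_few_affected_carriers"
        elif not children_consistent:
            reason = "carrier_child_also_deviates"
        elif p >= config.alpha:
            reason = "balanced"
        else:
            flagged = True
        out.append(MosaicEvidence(pid, site, g.alt_reads, g.total_reads, fraction, p, flagged, reason))
    return out + child_evidence
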