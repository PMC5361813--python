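"""Stepwise Mendelian inheritance-model workflow.

Four steps, always all executed (a first hit never stops the analysis, so
dual molecular diagnoses are not missed):

1. autosomal-recessive homozygous (plus X-linked hemizygous in males);
2. compound heterozygous with trans phase inferred from the parents;
3. heterozygous loss-of-function (putative truncating de novo);
4. de novo variants plus a parental-mosaicism screen.

Variants are prioritized by annotated population frequency (MAF < 0.5% or
absent, i.e. novel) and consequence class before any genotype logic runs.
Homozygous proband variants a parent does not carry are never dropped:
they are classed ``mendelian_inconsistent`` and routed to the UPD and
deletion modules for explanation.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from . import denovo as _denovo
from . import mosaic as _mosaic
from .models import (
    CandidateVariant,
    LOF_CLASSES,
    SiteCall,
    chromosome_sort_key,
)

log = logging.getLogger(__name__)


@dataclass
class WorkflowConfig:
    maf_max: float = 0.005
    lof_classes: frozenset = field(default_factory=lambda: LOF_CLASSES)
    missense_allowed_steps: frozenset = field(
        default_factory=lambda: frozenset({"ar_homozygous", "compound_het"})
    )
    proband_only_mode: bool = False

    def __post_init__(self):
        if not 0 < self.maf_max <= 1:
            raise ValueError("maf_max must be in (0, 1]")
        if not self.lof_classes:
            raise ValueError("lof_classes must be non-empty")
        self.lof_classes = frozenset(self.lof_classes)
        self.missense_allowed_steps = frozenset(self.missense_allowed_steps)

    def allowed_classes(self, step: str) -> frozenset:
        if step in self.missense_allowed_steps:
            return self.lof_classes | {"missense"}
        return self.lof_classes


@dataclass(frozen=True)
class TrioContext:
    """One analysed proband with resolved parents."""

    proband: str
    father: str
    mother: str
    proband_sex: str
    family_id: str


def trios_from_pedigree(pedigree) -> list[TrioContext]:
    """All affected members with both parents present in the pedigree."""
    return [
        TrioContext(m.sample_id, m.father_id, m.mother_id, m.sex, m.family_id)
        for m in pedigree
        if m.father_id and m.mother_id and m.affected == "affected"
    ]


# ---------------------------------------------------------------------------
# step 0: frequency prioritization
# ---------------------------------------------------------------------------

def filter_by_frequency(calls: Sequence[SiteCall], maf_max: float = 0.005) -> list[SiteCall]:
    """Retain calls with annotated MAF strictly below the cutoff, or no
    annotation at all (novel variants)."""
    return [c for c in calls if c.maf is None or c.maf < maf_max]


# ---------------------------------------------------------------------------
# step 1: AR-homozygous (and X-linked hemizygous)
# ---------------------------------------------------------------------------

def find_ar_homozygous(
    calls: Sequence[SiteCall],
    trio: TrioContext,
    config: WorkflowConfig = WorkflowConfig(),
) -> list[CandidateVariant]:
    """Proband-homozygous recessive candidates from frequency-filtered calls.

    Both parents heterozygous yields an ``ar_homozygous`` candidate; a
    parent lacking the alternate allele yields ``mendelian_inconsistent``
    (possible UPD or a deletion uncovering the variant). A homozygous
    unaffected parent disqualifies the site silently.
    """
    allowed = config.allowed_classes("ar_homozygous")
    out: list[CandidateVariant] = []
    n_skipped = 0
    for site in calls:
        if site.consequence not in allowed:
            continue
        pg = site.genotype_of(trio.proband)
        if pg.genotype != "hom_alt":
            continue
        fg = site.genotype_of(trio.father)
        mg = site.genotype_of(trio.mother)
        if fg.is_missing or mg.is_missing:
            n_skipped += 1
            continue
        if fg.genotype == "het" and mg.genotype == "het":
            out.append(
                CandidateVariant(
                    site, trio.proband, trio.family_id, "ar_homozygous", 1,
                    evidence={"father_gt": fg.genotype, "mother_gt": mg.genotype},
                )
            )
        elif not fg.has_alt or not mg.has_alt:
            missing_parent = "father" if not fg.has_alt else "mother"
            out.append(
                CandidateVariant(
                    site, trio.proband, trio.family_id, "mendelian_inconsistent", 1,
                    evidence={
                        "father_gt": fg.genotype,
                        "mother_gt": mg.genotype,
                        "parent_lacking_allele": missing_parent,
                    },
                )
            )
    if n_skipped:
        log.info("find_ar_homozygous: %d sites skipped (missing parental genotypes)", n_skipped)
    return out


def find_hemizygous(
    calls: Sequence[SiteCall],
    trio: TrioContext,
    config: WorkflowConfig = WorkflowConfig(),
    dnm_config: Optional[_denovo.DnmConfig] = None,
) -> list[CandidateVariant]:
    """X-linked recessive hemizygous candidates in a male proband.

    Mother het or homozygous yields ``xl_hemizygous``; maternal absence of
    the allele routes the site through the de novo read-count criteria. A
    female proband's chrX is handled by the autosomal-style steps; unknown
    proband sex skips chrX with a warning.
    """
    if trio.proband_sex == "unknown":
        log.warning("proband %s has unknown sex; chrX skipped", trio.proband)
        return []
    if trio.proband_sex == "female":
        return []
    dnm_config = dnm_config or _denovo.DnmConfig()
    allowed = config.allowed_classes("xl_hemizygous")
    out: list[CandidateVariant] = []
    for site in calls:
        if site.chromosome != "X" or site.consequence not in allowed:
            continue
        pg = site.genotype_of(trio.proband)
        if pg.genotype != "hemi_alt":
            continue
        mg = site.genotype_of(trio.mother)
        if mg.is_missing:
            continue
        if mg.has_alt:
            out.append(
                CandidateVariant(
                    site, trio.proband, trio.family_id, "xl_hemizygous", 1,
                    evidence={"mother_gt": mg.genotype},
                )
            )
        else:
            decision = _denovo.apply_dnm_criteria(
                site, trio.proband, trio.father, trio.mother, dnm_config
            )
            if decision.passed:
                out.append(
                    CandidateVariant(
                        site, trio.proband, trio.family_id, "de_novo", 4,
                        evidence={"chrX": True},
                    )
                )
    return out


# ---------------------------------------------------------------------------
# step 2: compound heterozygous
# ---------------------------------------------------------------------------

def _parental_origin(site: SiteCall, trio: TrioContext) -> str:
    fg = site.genotype_of(trio.father)
    mg = site.genotype_of(trio.mother)
    if fg.is_missing or mg.is_missing:
        return "unknown"
    if fg.has_alt and mg.has_alt:
        return "both"
    if fg.has_alt:
        return "paternal"
    if mg.has_alt:
        return "maternal"
    return "neither"


def find_compound_het(
    calls: Sequence[SiteCall],
    trio: Optional[TrioContext] = None,
    config: WorkflowConfig = WorkflowConfig(),
    proband: Optional[str] = None,
    family_id: str = ".",
) -> list[CandidateVariant]:
    """Compound-heterozygous pairs within a gene.

    In trio mode a pair is reported in trans when one variant is
    transmitted only by the father and the other only by the mother; pairs
    involving a variant carried by both parents are phase-undecidable and
    flagged ``phase_unknown``; same-parent pairs (cis) are excluded. In
    proband-only mode every het pair per gene is reported phase_unknown.
    One candidate is emitted per pair, carrying its partner site.
    """
    if trio is None and proband is None:
        raise ValueError("either a trio context or a proband id is required")
    pid = trio.proband if trio else proband
    fid = trio.family_id if trio else family_id
    allowed = config.allowed_classes("compound_het")

    by_gene: dict[str, list[SiteCall]] = {}
    for site in calls:
        if site.gene is None or site.consequence not in allowed:
            continue
        if site.genotype_of(pid).genotype == "het":
            by_gene.setdefault(site.gene, []).append(site)

    out: list[CandidateVariant] = []
    for gene in sorted(by_gene):
        sites = sorted(by_gene[gene], key=lambda s: s.sort_key)
        if len(sites) < 2:
            continue
        for i in range(len(sites)):
            for j in range(i + 1, len(sites)):
                v1, v2 = sites[i], sites[j]
                if trio is not None and not config.proband_only_mode:
                    o1, o2 = _parental_origin(v1, trio), _parental_origin(v2, trio)
                    pair = {o1, o2}
                    if pair == {"paternal", "maternal"}:
                        phase = "trans"
                    elif "both" in pair and pair <= {"both", "paternal", "maternal"}:
                        phase = "phase_unknown"
                    else:
                        continue  # cis, de novo-like, or unresolvable
                    evidence = {"phase": phase, "v1_origin": o1, "v2_origin": o2, "gene": gene}
                else:
                    evidence = {"phase": "phase_unknown", "gene": gene}
                out.append(
                    CandidateVariant(
                        v1, pid, fid, "compound_het", 2,
                        evidence=evidence, partner=v2,
                    )
                )
    return out


# ---------------------------------------------------------------------------
# step 3: heterozygous LOF
# ---------------------------------------------------------------------------

def find_het_lof(
    calls: Sequence[SiteCall],
    proband: str,
    config: WorkflowConfig = WorkflowConfig(),
    trio: Optional[TrioContext] = None,
    family_id: str = ".",
) -> list[CandidateVariant]:
    """Heterozygous loss-of-function candidates (LOF-only by design).

    This step targets potential truncating de novo mutations. With parents
    available, only het LOF variants absent from both parents qualify
    (inherited het LOF from an unaffected parent is not a truncating de
    novo); in proband-only mode every rare het LOF is reported.
    """
    fid = trio.family_id if trio else family_id
    out: list[CandidateVariant] = []
    for site in calls:
        if site.consequence not in config.lof_classes:
            continue
        if site.genotype_of(proband).genotype != "het":
            continue
        if trio is not None and not config.proband_only_mode:
            fg = site.genotype_of(trio.father)
            mg = site.genotype_of(trio.mother)
            if fg.is_missing or mg.is_missing or fg.has_alt or mg.has_alt:
                continue
        out.append(
            CandidateVariant(
                site, proband, fid, "het_lof", 3,
                evidence={"consequence": site.consequence},
            )
        )
    return out


# ---------------------------------------------------------------------------
# step 4 + orchestration
# ---------------------------------------------------------------------------

#: consequence classes admitted to de novo / mosaic prioritization
_DNM_TYPE_EXCLUDED = frozenset({"synonymous", "other"})


def run_stepwise(
    calls: Sequence[SiteCall],
    trio: TrioContext,
    config: WorkflowConfig = WorkflowConfig(),
    dnm_config: _denovo.DnmConfig = _denovo.DnmConfig(),
) -> list[CandidateVariant]:
    """Execute workflow steps 1-4 in order, concatenating all candidates.

    Later steps always run even after earlier hits (dual-diagnosis
    support). Output ordering is deterministic: (step, chromosome,
    position, class); duplicates by (site, class, sample) are removed.
    """
    filtered = filter_by_frequency(calls, config.maf_max)

    candidates: list[CandidateVariant] = []
    candidates += find_ar_homozygous(filtered, trio, config)
    candidates += find_hemizygous(filtered, trio, config, dnm_config)
    candidates += find_compound_het(filtered, trio, config)
    candidates += find_het_lof(filtered, trio.proband, config, trio=trio)

    # step 4: de novo candidates plus the parental-mosaicism screen on
    # subtracted sites that fail only the parental alt/ref criterion
    dn = _denovo.find_de_novo(
        filtered, trio.proband, trio.father, trio.mother, dnm_config, trio.family_id
    )
    candidates += [c for c in dn if c.site.consequence not in _DNM_TYPE_EXCLUDED]
    for site in _denovo.subtract_parental(filtered, trio.proband, trio.father, trio.mother):
        if site.consequence in _DNM_TYPE_EXCLUDED:
            continue
        decision = _denovo.apply_dnm_criteria(
            site, trio.proband, trio.father, trio.mother, dnm_config
        )
        if decision.failed_criteria == [4] and not decision.indeterminate_criteria:
            fg = site.genotype_of(trio.father)
            mg = site.genotype_of(trio.mother)
            evidence = {}
            for label, g in (("father", fg), ("mother", mg)):
                if g.total_reads:
                    evidence[f"{label}_alt_fraction"] = g.alt_reads / g.total_reads
                    evidence[f"{label}_binomial_p"] = _mosaic.binomial_deviation_test(
                        g.alt_reads, g.total_reads
                    )
            candidates.append(
                CandidateVariant(
                    site, trio.proband, trio.family_id, "mosaic_parent", 4,
                    evidence=evidence,
                )
            )

    seen: set = set()
    unique: list[CandidateVariant] = []
    for c in candidates:
        key = (c.site.chromosome, c.site.position, c.site.alt_allele,
               c.inheritance_class, c.sample_id,
               c.partner.position if c.partner else None)
        if key not in seen:
            seen.add(key)
            unique.append(c)
    unique.sort(
        key=lambda c: (
            c.workflow_step,
            chromosome_sort_key(c.site.chromosome),
            c.site.position,
            c.inheritance_class,
        )
    )
    return unique
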