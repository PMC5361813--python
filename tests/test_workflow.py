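"""Stepwise workflow: frequency/type filters, genotype-configuration rules,
trans phasing, and dual-diagnosis completeness."""
import random

import pytest

from wes_reanalysis import cohort_sim, workflow
from wes_reanalysis.workflow import TrioContext, WorkflowConfig
from util import gt, site

TRIO = TrioContext("P", "FA", "MO", "male", "F1")
FEM_TRIO = TrioContext("P", "FA", "MO", "female", "F1")


def trio_site(pos, p, fa, mo, chrom="1", gene="GENE1", cons="stop_gain", maf=None):
    return site(
        chrom=chrom, pos=pos, gene=gene, cons=cons, maf=maf,
        genotypes={"P": gt(*p), "FA": gt(*fa), "MO": gt(*mo)},
    )


# ---------------------------------------------------------------------------
# frequency filter
# ---------------------------------------------------------------------------

def test_frequency_filter_strict_boundary():
    kept = site(pos=1, maf=0.004, genotypes={})
    removed = site(pos=2, maf=0.005, genotypes={})
    novel = site(pos=3, maf=None, genotypes={})
    out = workflow.filter_by_frequency([kept, removed, novel], 0.005)
    assert out == [kept, novel]


def test_frequency_filter_monotone_in_maf_max():
    sites = [site(pos=i, maf=i / 1000, genotypes={}) for i in range(1, 20)]
    smaller = workflow.filter_by_frequency(sites, 0.004)
    larger = workflow.filter_by_frequency(sites, 0.012)
    assert set(s.position for s in smaller) <= set(s.position for s in larger)


# ---------------------------------------------------------------------------
# step 1: AR homozygous
# ---------------------------------------------------------------------------

def test_ar_homozygous_candidate():
    s = trio_site(10, ("hom_alt", 0, 30), ("het", 15, 14), ("het", 16, 13), maf=0.001)
    (c,) = workflow.find_ar_homozygous([s], TRIO)
    assert c.inheritance_class == "ar_homozygous" and c.workflow_step == 1


def test_ar_homozygous_single_carrier_parent_is_mendelian_inconsistent():
    s = trio_site(10, ("hom_alt", 0, 30), ("het", 15, 14), ("hom_ref", 30, 0))
    (c,) = workflow.find_ar_homozygous([s], TRIO)
    assert c.inheritance_class == "mendelian_inconsistent"
    assert c.evidence["parent_lacking_allele"] == "mother"


def test_ar_homozygous_excludes_synonymous():
    s = trio_site(10, ("hom_alt", 0, 30), ("het", 15, 14), ("het", 16, 13), cons="synonymous")
    assert workflow.find_ar_homozygous([s], TRIO) == []


def test_ar_homozygous_parent_homozygous_not_candidate():
    s = trio_site(10, ("hom_alt", 0, 30), ("hom_alt", 0, 28), ("het", 16, 13))
    assert workflow.find_ar_homozygous([s], TRIO) == []


# ---------------------------------------------------------------------------
# step 2: compound het
# ---------------------------------------------------------------------------

def _comphet_sites(fa2=("hom_ref", 30, 0), mo2=("het", 14, 15)):
    v1 = trio_site(10, ("het", 15, 14), ("het", 14, 15), ("hom_ref", 30, 0), cons="stop_gain")
    v2 = trio_site(20, ("het", 15, 14), fa2, mo2, cons="missense")
    return [v1, v2]


def test_compound_het_trans_pair_reported():
    (c,) = workflow.find_compound_het(_comphet_sites(), TRIO)
    assert c.inheritance_class == "compound_het"
    assert c.evidence["phase"] == "trans"
    assert c.partner.position == 20


def test_compound_het_cis_pair_excluded():
    sites = _comphet_sites(fa2=("het", 14, 15), mo2=("hom_ref", 30, 0))
    assert workflow.find_compound_het(sites, TRIO) == []


def test_compound_het_double_carrier_parent_phase_unknown():
    sites = _comphet_sites(fa2=("het", 14, 15), mo2=("het", 15, 14))
    (c,) = workflow.find_compound_het(sites, TRIO)
    assert c.evidence["phase"] == "phase_unknown"


def test_compound_het_proband_only_mode():
    cfg = WorkflowConfig(proband_only_mode=True)
    sites = [
        site(pos=10, cons="stop_gain", genotypes={"P": gt("het", 15, 14)}),
        site(pos=20, cons="frameshift_indel", genotypes={"P": gt("het", 12, 13)}),
    ]
    (c,) = workflow.find_compound_het(sites, config=cfg, proband="P")
    assert c.evidence["phase"] == "phase_unknown"


def test_compound_het_requires_same_gene():
    v1, v2 = _comphet_sites()
    v2.gene = "OTHER"
    assert workflow.find_compound_het([v1, v2], TRIO) == []


# ---------------------------------------------------------------------------
# step 3: het LOF
# ---------------------------------------------------------------------------

def test_het_lof_candidate_when_absent_from_parents():
    s = trio_site(10, ("het", 15, 14), ("hom_ref", 30, 0), ("hom_ref", 28, 0), cons="frameshift_indel")
    (c,) = workflow.find_het_lof([s], "P", trio=TRIO)
    assert c.inheritance_class == "het_lof" and c.workflow_step == 3


def test_het_lof_inherited_excluded_in_trio_mode():
    s = trio_site(10, ("het", 15, 14), ("het", 14, 13), ("hom_ref", 28, 0), cons="frameshift_indel")
    assert workflow.find_het_lof([s], "P", trio=TRIO) == []


def test_het_lof_proband_only_reports_all():
    cfg = WorkflowConfig(proband_only_mode=True)
    s = site(pos=10, cons="splice_site", genotypes={"P": gt("het", 15, 14)})
    (c,) = workflow.find_het_lof([s], "P", config=cfg)
    assert c.inheritance_class == "het_lof"


def test_het_lof_excludes_missense():
    s = trio_site(10, ("het", 15, 14), ("hom_ref", 30, 0), ("hom_ref", 28, 0), cons="missense")
    assert workflow.find_het_lof([s], "P", trio=TRIO) == []


# ---------------------------------------------------------------------------
# step 1 chrX: hemizygous
# ---------------------------------------------------------------------------

def test_hemizygous_candidate_with_carrier_mother():
    s = trio_site(10, ("hemi_alt", 0, 30), ("hemi_ref", 30, 0), ("het", 16, 13), chrom="X")
    (c,) = workflow.find_hemizygous([s], TRIO)
    assert c.inheritance_class == "xl_hemizygous"


def test_hemizygous_maternal_absence_routes_to_de_novo():
    s = trio_site(10, ("hemi_alt", 10, 30), ("hemi_ref", 30, 0), ("hom_ref", 28, 1), chrom="X")
    (c,) = workflow.find_hemizygous([s], TRIO)
    assert c.inheritance_class == "de_novo" and c.workflow_step == 4


def test_female_proband_chrx_not_hemizygous():
    s = trio_site(10, ("het", 15, 14), ("hemi_ref", 30, 0), ("het", 16, 13), chrom="X")
    assert workflow.find_hemizygous([s], FEM_TRIO) == []


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def test_dual_diagnosis_both_candidates_reported():
    """A trio carrying both a compound-het pair and a de novo variant
    reports both; no step stops at the first hit."""
    cfg = cohort_sim.SimConfig(
        n_families=1,
        family_structures=("trio",),
        n_background_sites=230,
        base_error_fraction=0.0,
        planted_events=[
            cohort_sim.EventSpec("compound_het", "F01"),
            cohort_sim.EventSpec("de_novo", "F01"),
        ],
        seed=5,
    )
    cohort = cohort_sim.simulate_cohort(cfg)
    trio = workflow.trios_from_pedigree(cohort.pedigree)[0]
    cands = workflow.run_stepwise(cohort.site_calls, trio)
    classes = {c.inheritance_class for c in cands}
    assert {"compound_het", "de_novo"} <= classes


def test_clean_background_yields_no_candidates():
    cfg = cohort_sim.SimConfig(
        n_families=1,
        family_structures=("trio",),
        n_background_sites=2000,
        base_error_fraction=0.0,
        seed=7,
    )
    cohort = cohort_sim.simulate_cohort(cfg)
    trio = workflow.trios_from_pedigree(cohort.pedigree)[0]
    assert workflow.run_stepwise(cohort.site_calls, trio) == []


def test_shuffled_input_gives_identical_output(small_cohort):
    trio = workflow.trios_from_pedigree(small_cohort.pedigree)[0]
    a = workflow.run_stepwise(small_cohort.site_calls, trio)
    shuffled = list(small_cohort.site_calls)
    random.Random(3).shuffle(shuffled)
    b = workflow.run_stepwise(shuffled, trio)
    key = lambda c: (c.site.chromosome, c.site.position, c.inheritance_class)
    assert [key(c) for c in a] == [key(c) for c in b]


def test_no_candidate_exceeds_maf_cutoff(small_cohort):
    for trio in workflow.trios_from_pedigree(small_cohort.pedigree):
        for c in workflow.run_stepwise(small_cohort.site_calls, trio):
            assert c.site.maf is None or c.site.maf < 0.005


def test_candidates_unique_by_site_and_class(small_cohort):
    for trio in workflow.trios_from_pedigree(small_cohort.pedigree):
        cands = workflow.run_stepwise(small_cohort.site_calls, trio)
        keys = [
            (c.site.chromosome, c.site.position, c.inheritance_class,
             c.partner.position if c.partner else None)
            for c in cands
        ]
        assert len(keys) == len(set(keys))
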