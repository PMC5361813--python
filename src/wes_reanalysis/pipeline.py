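"""End-to-end reanalysis: workflow -> mosaic -> AOH/UPD -> deletions -> joins.

Runs every analysis stage over a cohort (multi-sample calls + pedigree +
optional exon coverage) and gathers per-family findings into one result
object. All stages run for every family; a hit in one stage never
suppresses another (dual-diagnosis support).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from . import baf_aoh, coverage_del, denovo, mosaic, reporting, workflow
from .models import CandidateVariant, PedigreeMember, SiteCall


@dataclass
class UpdFinding:
    proband: str
    family_id: str
    chromosome: str
    aoh_marker_fraction: float
    origin: str
    n_supporting_sites: int


@dataclass
class PipelineResult:
    candidates: list[CandidateVariant]
    mosaic_evidence: list
    upd_findings: list[UpdFinding]
    deletions: list
    summary: pd.DataFrame = field(default_factory=pd.DataFrame)


def run_pipeline(
    site_calls: Sequence[SiteCall],
    pedigree: Sequence[PedigreeMember],
    exon_coverage: Optional[pd.DataFrame] = None,
    wf_config: workflow.WorkflowConfig = None,
    dnm_config: denovo.DnmConfig = None,
    mosaic_config: mosaic.MosaicConfig = None,
    aoh_params: baf_aoh.AohParams = None,
    del_params: coverage_del.DeletionParams = None,
    x_genes: frozenset = frozenset(),
) -> PipelineResult:
    wf_config = wf_config or workflow.WorkflowConfig()
    dnm_config = dnm_config or denovo.DnmConfig()
    mosaic_config = mosaic_config or mosaic.MosaicConfig()
    aoh_params = aoh_params or baf_aoh.AohParams()
    del_params = del_params or coverage_del.DeletionParams()

    members_by_family: dict[str, list[PedigreeMember]] = {}
    for m in pedigree:
        members_by_family.setdefault(m.family_id, []).append(m)

    candidates: list[CandidateVariant] = []
    mosaic_evidence = []
    upd_findings: list[UpdFinding] = []

    for trio in workflow.trios_from_pedigree(pedigree):
        fam_members = members_by_family[trio.family_id]
        cands = workflow.run_stepwise(site_calls, trio, wf_config, dnm_config)

        # formal mosaic evaluation of sites the workflow screen surfaced
        for c in cands:
            if c.inheritance_class == "mosaic_parent":
                mosaic_evidence.extend(
                    mosaic.flag_parental_mosaic(c.site, fam_members, mosaic_config)
                )

        # BAF -> AOH -> UPD for the proband
        baf = baf_aoh.compute_baf(site_calls, trio.proband, aoh_params)
        segments = baf_aoh.detect_aoh(baf, aoh_params)
        flags = baf_aoh.flag_upd(
            segments, baf_aoh.markers_per_chromosome(baf), aoh_params
        )
        for f in flags:
            origin, n_support = baf_aoh.infer_upd_parent(
                site_calls, f.chromosome, trio.proband, trio.father, trio.mother
            )
            upd_findings.append(
                UpdFinding(
                    trio.proband, trio.family_id, f.chromosome,
                    f.aoh_marker_fraction, origin, n_support,
                )
            )
            # Mendelian-inconsistent homozygotes on a UPD chromosome are
            # explained by reduction to homozygosity
            for c in cands:
                if (
                    c.inheritance_class == "mendelian_inconsistent"
                    and c.site.chromosome == f.chromosome
                ):
                    c.evidence["explained_by"] = f"upd_{origin}"

        candidates.extend(cands)

    deletions = []
    if exon_coverage is not None and not exon_coverage.empty:
        normalized = coverage_del.normalize_exon_coverage(exon_coverage)
        deletions = coverage_del.call_dropout_deletions(
            normalized, pedigree, del_params, x_genes
        )

    candidates = reporting.join_snv_deletion_trans(candidates, deletions)

    rows = []
    for fid in sorted(members_by_family):
        fam_cands = [c for c in candidates if c.family_id == fid]
        fam_samples = {m.sample_id for m in members_by_family[fid]}
        rows.append(
            {
                "family_id": fid,
                "n_candidates": len(fam_cands),
                "n_de_novo": sum(c.inheritance_class == "de_novo" for c in fam_cands),
                "n_ar_homozygous": sum(c.inheritance_class == "ar_homozygous" for c in fam_cands),
                "n_compound_het": sum(c.inheritance_class == "compound_het" for c in fam_cands),
                "n_het_lof": sum(c.inheritance_class == "het_lof" for c in fam_cands),
                "n_xl_hemizygous": sum(c.inheritance_class == "xl_hemizygous" for c in fam_cands),
                "n_mosaic_parent": sum(c.inheritance_class == "mosaic_parent" for c in fam_cands),
                "n_mendelian_inconsistent": sum(
                    c.inheritance_class == "mendelian_inconsistent" for c in fam_cands
                ),
                "n_upd_chromosomes": sum(u.family_id == fid for u in upd_findings),
                "n_deletions": sum(d.sample in fam_samples for d in deletions),
            }
        )
    summary = pd.DataFrame(rows)
    return PipelineResult(candidates, mosaic_evidence, upd_findings, deletions, summary)
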