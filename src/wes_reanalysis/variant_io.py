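"""Read/write the standard formats and normalize variant records.

VCF access goes through pysam; records are decomposed to one biallelic
:class:`~wes_reanalysis.models.SiteCall` per alternate allele. Adjacent SNVs
sharing a genotype configuration across all samples can be merged into a
single dinucleotide (MNV) call, recovering substitutions that upstream
callers emit as two separate variants.
"""
from __future__ import annotations

import io
import os
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import pysam

from .models import (
    CandidateVariant,
    GenotypeCall,
    PedigreeMember,
    SiteCall,
    chromosome_sort_key,
    normalize_chromosome,
)

PathLike = Union[str, os.PathLike]

_SEX_FROM_PED = {"1": "male", "2": "female"}
_SEX_TO_PED = {"male": "1", "female": "2", "unknown": "0"}
_AFF_FROM_PED = {"1": "unaffected", "2": "affected"}
_AFF_TO_PED = {"unaffected": "1", "affected": "2", "unknown": "0"}


@dataclass(frozen=True)
class AnnotationKeys:
    """INFO keys carrying the gene symbol, consequence class, and MAF."""

    gene: str = "GENE"
    consequence: str = "CSQ"
    maf: str = "MAF"


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------

def read_pedigree(ped_source: Union[PathLike, io.TextIOBase, Iterable[str]]) -> list[PedigreeMember]:
    """Parse a 6-column whitespace-delimited PED file.

    Columns: family, sample, father, mother, sex (1=male, 2=female,
    0=unknown), phenotype (1=unaffected, 2=affected, 0=unknown). A ``0``
    parent code maps to ``None``; any non-zero parent id must resolve to a
    member of the file.
    """
    if isinstance(ped_source, (str, os.PathLike)):
        with open(ped_source) as fh:
            lines = fh.readlines()
    else:
        lines = list(ped_source)

    members: list[PedigreeMember] = []
    seen: set[str] = set()
    for ln, raw in enumerate(lines, 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 6:
            raise ValueError(f"PED line {ln}: expected 6 columns, got {len(fields)}")
        fam, sid, fa, mo, sex, aff = fields[:6]
        if sid in seen:
            raise ValueError(f"duplicate sample_id in pedigree: {sid!r}")
        seen.add(sid)
        members.append(
            PedigreeMember(
                sample_id=sid,
                family_id=fam,
                father_id=None if fa == "0" else fa,
                mother_id=None if mo == "0" else mo,
                sex=_SEX_FROM_PED.get(sex, "unknown"),
                affected=_AFF_FROM_PED.get(aff, "unknown"),
            )
        )
    ids = {m.sample_id for m in members}
    for m in members:
        for pid in (m.father_id, m.mother_id):
            if pid is not None and pid not in ids:
                raise ValueError(
                    f"parent id {pid!r} of sample {m.sample_id!r} does not "
                    "resolve to a pedigree member"
                )
    return members


def write_ped(pedigree: Sequence[PedigreeMember], path: PathLike) -> None:
    with open(path, "w") as fh:
        for m in pedigree:
            fh.write(
                "\t".join(
                    [
                        m.family_id,
                        m.sample_id,
                        m.father_id or "0",
                        m.mother_id or "0",
                        _SEX_TO_PED[m.sex],
                        _AFF_TO_PED[m.affected],
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _classify_genotype(alleles: tuple, allele_index: int) -> str:
    """Map a GT tuple to a genotype class for one decomposed alternate.

    Other alternate alleles at the same record count as reference-like for
    the decomposed site. A haploid GT yields a hemizygous class.
    """
    if alleles is None or len(alleles) == 0 or any(a is None for a in alleles):
        return "missing"
    n_alt = sum(1 for a in alleles if a == allele_index)
    if len(alleles) == 1:
        return "hemi_alt" if n_alt == 1 else "hemi_ref"
    if n_alt == 0:
        return "hom_ref"
    if n_alt == 1:
        return "het"
    return "hom_alt"


def read_calls(
    vcf_source: PathLike,
    pedigree: Sequence[PedigreeMember],
    keys: AnnotationKeys = AnnotationKeys(),
) -> list[SiteCall]:
    """Read a multi-sample VCF into decomposed biallelic site calls.

    Requires per-sample GT and AD for every genotyped sample; multi-allelic
    records are decomposed into one SiteCall per alternate allele with
    per-allele depths taken from the AD field.
    """
    vf = pysam.VariantFile(os.fspath(vcf_source))
    vcf_samples = set(vf.header.samples)
    wanted = [m.sample_id for m in pedigree]
    missing = [s for s in wanted if s not in vcf_samples]
    if missing:
        raise ValueError(f"samples in pedigree but absent from VCF: {missing}")

    calls: list[SiteCall] = []
    for rec in vf:
        alts = rec.alts or ()
        info = rec.info
        gene = info.get(keys.gene)
        consequence = info.get(keys.consequence, "other")
        maf_raw = info.get(keys.maf)
        for ai, alt in enumerate(alts):
            if isinstance(maf_raw, tuple):
                maf = maf_raw[ai] if ai < len(maf_raw) else maf_raw[0]
            else:
                maf = maf_raw
            genotypes: dict[str, GenotypeCall] = {}
            for sid in wanted:
                s = rec.samples[sid]
                gt = s.get("GT")
                cls = _classify_genotype(gt, ai + 1)
                if cls == "missing":
                    genotypes[sid] = GenotypeCall("missing", 0, 0)
                    continue
                ad = s.get("AD")
                if ad is None or ad[0] is None:
                    raise ValueError(
                        f"missing AD for genotyped sample {sid!r} at "
                        f"{rec.chrom}:{rec.pos}"
                    )
                ref_reads = int(ad[0])
                alt_reads = int(ad[ai + 1]) if len(ad) > ai + 1 and ad[ai + 1] is not None else 0
                genotypes[sid] = GenotypeCall(cls, ref_reads, alt_reads)
            calls.append(
                SiteCall(
                    chromosome=normalize_chromosome(rec.chrom),
                    position=rec.pos,
                    ref_allele=rec.ref,
                    alt_allele=alt,
                    gene=gene,
                    consequence=consequence if consequence else "other",
                    maf=float(maf) if maf is not None else None,
                    genotypes=genotypes,
                )
            )
    return calls


def write_vcf(
    calls: Sequence[SiteCall],
    sample_ids: Sequence[str],
    path: PathLike,
    keys: AnnotationKeys = AnnotationKeys(),
) -> None:
    """Write biallelic site calls as an uncompressed VCF v4.2 with GT:AD.

    Output is deterministic: identical inputs produce identical bytes.
    Hemizygous genotypes are written haploid.
    """
    header = pysam.VariantHeader()
    header.add_line('##INFO=<ID=%s,Number=1,Type=String,Description="Gene symbol">' % keys.gene)
    header.add_line('##INFO=<ID=%s,Number=1,Type=String,Description="Consequence class">' % keys.consequence)
    header.add_line('##INFO=<ID=%s,Number=1,Type=Float,Description="Population minor allele frequency">' % keys.maf)
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">')
    chrom_max: dict[str, int] = {}
    for c in calls:
        chrom_max[c.chromosome] = max(chrom_max.get(c.chromosome, 0), c.position)
    for chrom in sorted(chrom_max, key=chromosome_sort_key):
        header.add_line(f"##contig=<ID={chrom},length={chrom_max[chrom] + 10_000}>")
    for sid in sample_ids:
        header.add_sample(sid)

    _GT = {
        "hom_ref": (0, 0),
        "het": (0, 1),
        "hom_alt": (1, 1),
        "hemi_ref": (0,),
        "hemi_alt": (1,),
        "missing": (None,),
    }
    with pysam.VariantFile(os.fspath(path), "w", header=header) as out:
        for c in sorted(calls, key=lambda s: s.sort_key):
            rec = out.new_record(
                contig=c.chromosome,
                start=c.position - 1,
                alleles=(c.ref_allele, c.alt_allele),
            )
            if c.gene is not None:
                rec.info[keys.gene] = c.gene
            rec.info[keys.consequence] = c.consequence
            if c.maf is not None:
                rec.info[keys.maf] = c.maf
            for sid in sample_ids:
                g = c.genotypes.get(sid, GenotypeCall("missing", 0, 0))
                rec.samples[sid]["GT"] = _GT[g.genotype]
                if not g.is_missing:
                    rec.samples[sid]["AD"] = (g.ref_reads, g.alt_reads)
            out.write(rec)


# ---------------------------------------------------------------------------
# MNV merging
# ---------------------------------------------------------------------------

def _is_snv(call: SiteCall) -> bool:
    return len(call.ref_allele) == 1 and len(call.alt_allele) == 1


def _genotype_classes(call: SiteCall) -> dict[str, str]:
    return {sid: g.genotype for sid, g in call.genotypes.items()}


def merge_adjacent_snvs(calls: Sequence[SiteCall]) -> list[SiteCall]:
    """Merge consecutive-position SNV pairs into dinucleotide variants.

    Two SNVs at adjacent positions with identical per-sample genotype
    classes are replaced by one call with concatenated alleles; per-sample
    depths are the elementwise minimum of the pair (conservative support).
    Input must be sorted by chromosome then position. Idempotent: a merged
    MNV is no longer an SNV and is never merged again.
    """
    keyed = [c.sort_key for c in calls]
    if keyed != sorted(keyed):
        raise ValueError("merge_adjacent_snvs requires input sorted by chromosome, position")

    merged: list[SiteCall] = []
    i = 0
    while i < len(calls):
        a = calls[i]
        if i + 1 < len(calls):
            b = calls[i + 1]
            if (
                _is_snv(a)
                and _is_snv(b)
                and a.chromosome == b.chromosome
                and b.position == a.position + 1
                and _genotype_classes(a) == _genotype_classes(b)
                and any(g.has_alt for g in a.genotypes.values())
            ):
                genotypes = {
                    sid: GenotypeCall(
                        ga.genotype,
                        min(ga.ref_reads, b.genotypes[sid].ref_reads),
                        min(ga.alt_reads, b.genotypes[sid].alt_reads),
                    )
                    for sid, ga in a.genotypes.items()
                }
                maf = None
                if a.maf is not None and b.maf is not None:
                    maf = min(a.maf, b.maf)
                merged.append(
                    SiteCall(
                        chromosome=a.chromosome,
                        position=a.position,
                        ref_allele=a.ref_allele + b.ref_allele,
                        alt_allele=a.alt_allele + b.alt_allele,
                        gene=a.gene,
                        consequence=a.consequence,
                        maf=maf,
                        genotypes=genotypes,
                    )
                )
                i += 2
                continue
        merged.append(a)
        i += 1
    return merged


# ---------------------------------------------------------------------------
# Candidate output
# ---------------------------------------------------------------------------

CANDIDATE_COLUMNS = [
    "family_id",
    "sample_id",
    "chromosome",
    "position",
    "ref_allele",
    "alt_allele",
    "gene",
    "consequence",
    "maf",
    "inheritance_class",
    "workflow_step",
    "partner_position",
    "evidence",
]


def _format_evidence(evidence: dict) -> str:
    parts = []
    for k in sorted(evidence):
        v = evidence[k]
        if isinstance(v, float):
            v = f"{v:.6g}"
        parts.append(f"{k}={v}")
    return ";".join(parts) if parts else "."


def write_candidates(candidates: Sequence[CandidateVariant], sink: Union[PathLike, io.TextIOBase]) -> None:
    """Write candidates as a TSV with a stable column order and sort."""
    rows = sorted(
        candidates,
        key=lambda c: (
            chromosome_sort_key(c.site.chromosome),
            c.site.position,
            c.sample_id,
            c.inheritance_class,
        ),
    )
    own = isinstance(sink, (str, os.PathLike))
    fh = open(sink, "w") if own else sink
    try:
        fh.write("\t".join(CANDIDATE_COLUMNS) + "\n")
        for c in rows:
            s = c.site
            fh.write(
                "\t".join(
                    [
                        c.family_id,
                        c.sample_id,
                        s.chromosome,
                        str(s.position),
                        s.ref_allele,
                        s.alt_allele,
                        s.gene or ".",
                        s.consequence,
                        "." if s.maf is None else f"{s.maf:.6g}",
                        c.inheritance_class,
                        str(c.workflow_step),
                        str(c.partner.position) if c.partner is not None else ".",
                        _format_evidence(c.evidence),
                    ]
                )
                + "\n"
            )
    finally:
        if own:
            fh.close()
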