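"""Small constructors shared by the test modules."""
from __future__ import annotations

from wes_reanalysis.models import GenotypeCall, PedigreeMember, SiteCall


def gt(genotype: str, ref: int, alt: int) -> GenotypeCall:
    return GenotypeCall(genotype, ref, alt)


def site(
    chrom: str = "1",
    pos: int = 1000,
    gene: str | None = "GENE1",
    cons: str = "missense",
    maf: float | None = None,
    ref: str = "A",
    alt: str = "G",
    genotypes: dict | None = None,
) -> SiteCall:
    return SiteCall(chrom, pos, ref, alt, gene, cons, maf, genotypes or {})


def trio_pedigree(fid: str = "T1", proband_sex: str = "male"):
    """(pedigree, proband, father, mother) for a single affected child."""
    p, fa, mo = f"{fid}_P", f"{fid}_FA", f"{fid}_MO"
    ped = [
        PedigreeMember(p, fid, fa, mo, proband_sex, "affected"),
        PedigreeMember(fa, fid, None, None, "male", "unaffected"),
        PedigreeMember(mo, fid, None, None, "female", "unaffected"),
    ]
    return ped, p, fa, mo
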