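"""Core data model shared across the reanalysis modules.

The pipeline operates on three containers: a pedigree (family structure,
sex, affected status), a list of biallelic site calls with per-sample
genotypes and allelic depths, and candidate variants annotated with an
inheritance class and supporting evidence.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

#: Genotype classes after decomposition to a single alternate allele.
GENOTYPE_CLASSES = frozenset(
    {"hom_ref", "het", "hom_alt", "hemi_ref", "hemi_alt", "missing"}
)

#: Functional consequence classes consumed as input annotations.
CONSEQUENCE_CLASSES = frozenset(
    {"stop_gain", "frameshift_indel", "splice_site", "missense", "synonymous", "other"}
)

#: Predicted loss-of-function classes.
LOF_CLASSES = frozenset({"stop_gain", "frameshift_indel", "splice_site"})

#: Inheritance classes a candidate variant may carry.
INHERITANCE_CLASSES = frozenset(
    {
        "de_novo",
        "ar_homozygous",
        "compound_het",
        "het_lof",
        "xl_hemizygous",
        "mosaic_parent",
        "mendelian_inconsistent",
    }
)


def normalize_chromosome(chrom: str) -> str:
    """Strip a leading ``chr`` prefix; chromosome names are bare (``1``..``22``, ``X``)."""
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


def chromosome_sort_key(chrom: str):
    """Sort key placing autosomes numerically before X, Y, MT, then others."""
    c = normalize_chromosome(chrom)
    if c.isdigit():
        return (0, int(c), "")
    special = {"X": 23, "Y": 24, "MT": 25, "M": 25}
    if c.upper() in special:
        return (0, special[c.upper()], "")
    return (1, 0, c)


@dataclass(frozen=True)
class GenotypeCall:
    """One sample's genotype and allelic depths at a biallelic site."""

    genotype: str
    ref_reads: int
    alt_reads: int

    def __post_init__(self):
        if self.genotype not in GENOTYPE_CLASSES:
            raise ValueError(f"unknown genotype class: {self.genotype!r}")
        if self.ref_reads < 0 or self.alt_reads < 0:
            raise ValueError("read counts must be non-negative")

    @property
    def total_reads(self) -> int:
        return self.ref_reads + self.alt_reads

    @property
    def has_alt(self) -> bool:
        """True when the alternate allele is called in the genotype."""
        return self.genotype in ("het", "hom_alt", "hemi_alt")

    @property
    def is_missing(self) -> bool:
        return self.genotype == "missing"


@dataclass
class PedigreeMember:
    sample_id: str
    family_id: str
    father_id: Optional[str]
    mother_id: Optional[str]
    sex: str  # male | female | unknown
    affected: str  # affected | unaffected | unknown

    def __post_init__(self):
        if self.sex not in ("male", "female", "unknown"):
            raise ValueError(f"invalid sex: {self.sex!r}")
        if self.affected not in ("affected", "unaffected", "unknown"):
            raise ValueError(f"invalid affected status: {self.affected!r}")


@dataclass
class SiteCall:
    """One biallelic variant site with per-sample genotype calls and annotations.

    Positions are 1-based (VCF convention). ``maf`` is the annotated population
    minor allele frequency; ``None`` means the annotation is absent and the
    variant is treated downstream as novel.
    """

    chromosome: str
    position: int
    ref_allele: str
    alt_allele: str
    gene: Optional[str]
    consequence: str
    maf: Optional[float]
    genotypes: dict[str, GenotypeCall]

    def __post_init__(self):
        if self.position < 1:
            raise ValueError("position must be >= 1")
        if not self.ref_allele or not self.alt_allele:
            raise ValueError("alleles must be non-empty")
        if self.consequence not in CONSEQUENCE_CLASSES:
            raise ValueError(f"unknown consequence class: {self.consequence!r}")
        self.chromosome = normalize_chromosome(self.chromosome)

    def genotype_of(self, sample_id: str) -> GenotypeCall:
        try:
            return self.genotypes[sample_id]
        except KeyError:
            raise KeyError(
                f"sample {sample_id!r} absent from call at "
                f"{self.chromosome}:{self.position}"
            ) from None

    @property
    def sort_key(self):
        return (chromosome_sort_key(self.chromosome), self.position,
                self.ref_allele, self.alt_allele)


@dataclass
class CandidateVariant:
    """A site call promoted to a candidate under one inheritance model."""

    site: SiteCall
    sample_id: str
    family_id: str
    inheritance_class: str
    workflow_step: int
    evidence: dict = field(default_factory=dict)
    partner: Optional[SiteCall] = None  # trans partner for compound hets

    def __post_init__(self):
        if self.inheritance_class not in INHERITANCE_CLASSES:
            raise ValueError(
                f"unknown inheritance class: {self.inheritance_class!r}"
            )
        if not 1 <= self.workflow_step <= 4:
            raise ValueError("workflow_step must be in 1..4")


@dataclass
class TruthRecord:
    """A planted synthetic event against which recovery is scored."""

    event_type: str
    family_id: str
    chromosome: Optional[str]
    positions: tuple
    gene: Optional[str]
    carriers: tuple
    params: dict = field(default_factory=dict)
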