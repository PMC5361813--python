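"""Synthetic trio/quartet cohort generator.

Emits a multi-sample VCF-equivalent call set, a pedigree, a per-exon
coverage table, and a truth table of planted events, with the statistical
structure the downstream stages assume:

* background sites follow Hardy-Weinberg parental genotypes with children
  drawing one allele from each parental haplotype (Mendelian-consistent);
* allelic depths are Poisson totals with a binomial alternate split at the
  genotype's allele fraction, perturbed by a substitution-error rate;
* planted events (de novo, compound het, AR-homozygous, X-linked
  hemizygous, mosaic parent, whole-chromosome isodisomic UPD, exon
  dropout) override the background at dedicated sites and are recorded in
  the truth table.

Identical configuration and seed reproduce byte-identical outputs.
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .models import (
    GenotypeCall,
    PedigreeMember,
    SiteCall,
    TruthRecord,
    normalize_chromosome,
)
from . import variant_io

AUTOSOMES = [str(i) for i in range(1, 23)]
CHROMOSOMES = AUTOSOMES + ["X"]

EVENT_TYPES = frozenset(
    {
        "de_novo",
        "compound_het",
        "ar_homozygous",
        "xl_hemizygous",
        "mosaic_parent",
        "upd",
        "exon_dropout",
    }
)

FAMILY_STRUCTURES = frozenset({"trio", "quartet", "multiplex3", "singleton"})

#: genotype codes used internally: 0 hom_ref, 1 het, 2 hom_alt, 3 hemi_ref, 4 hemi_alt
_CODE_TO_CLASS = ("hom_ref", "het", "hom_alt", "hemi_ref", "hemi_alt")
_CODE_TO_FRACTION = np.array([0.0, 0.5, 1.0, 0.0, 1.0])

#: chromosomes used for placing SNV events, cycling; UPD chromosome is excluded
_EVENT_CHROM_CYCLE = ["3", "5", "7", "9", "11", "13", "15", "17", "19", "21"]

_GRID_START = 1_000_000
_GRID_SPACING = 5_000
_GENE_BLOCK = 10  # consecutive grid sites per gene
_MIN_UPD_MARKERS = 200

_BACKGROUND_CONSEQUENCES = ["synonymous", "missense", "other", "splice_site", "stop_gain", "frameshift_indel"]
_BACKGROUND_CONSEQUENCE_P = [0.35, 0.40, 0.22, 0.01, 0.01, 0.01]


@dataclass
class MafDistribution:
    """Population allele-frequency model: point masses plus a uniform rare tail.

    Defaults place 60% of sites at common frequencies (0.5, 0.25, 0.10) so
    heterozygous markers are dense enough for AOH detection, with a 40%
    uniform tail over [0, 0.05] supplying rare variation.
    """

    point_masses: dict = field(default_factory=lambda: {0.5: 0.2, 0.25: 0.2, 0.10: 0.2})
    tail_weight: float = 0.4
    tail_max: float = 0.05

    def __post_init__(self):
        total = sum(self.point_masses.values()) + self.tail_weight
        if not np.isclose(total, 1.0):
            raise ValueError(f"MAF distribution weights sum to {total}, expected 1")
        if not 0 < self.tail_max <= 0.5:
            raise ValueError("tail_max must be in (0, 0.5]")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        values = list(self.point_masses) + [-1.0]
        weights = list(self.point_masses.values()) + [self.tail_weight]
        picks = rng.choice(len(values), size=n, p=np.asarray(weights) / np.sum(weights))
        out = np.array([values[i] for i in picks], dtype=float)
        tail = out < 0
        out[tail] = rng.uniform(0.0, self.tail_max, size=int(tail.sum()))
        return out


@dataclass
class EventSpec:
    """One planted event."""

    event_type: str
    target_family: str
    gene: Optional[str] = None
    consequence: Optional[str] = None
    mosaic_fraction: Optional[float] = None
    upd_parent: Optional[str] = None
    n_exons: int = 1

    def __post_init__(self):
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event type: {self.event_type!r}")
        if self.event_type == "mosaic_parent":
            if self.mosaic_fraction is None or not 0 < self.mosaic_fraction < 1:
                raise ValueError("mosaic_parent requires mosaic_fraction in (0, 1)")
        elif self.mosaic_fraction is not None:
            raise ValueError("mosaic_fraction only valid for mosaic_parent events")
        if self.event_type == "upd":
            if self.upd_parent not in ("father", "mother"):
                raise ValueError("upd events require upd_parent in {father, mother}")
        if self.n_exons < 1:
            raise ValueError("n_exons must be >= 1")


@dataclass
class SimConfig:
    """Study conditions for a synthetic cohort.

    ``family_structures`` is cycled if shorter than ``n_families``. The
    depth model is a Poisson total with a binomial alternate split; the
    substitution-error rate sends a fraction ``base_error_fraction`` of
    bases to one of the three other bases (e/3 to the specific alternate).
    """

    n_families: int = 10
    family_structures: Sequence[str] = ("trio",)
    n_background_sites: int = 20_000
    mean_depth: float = 40.0
    base_error_fraction: float = 0.005
    planted_events: Sequence[EventSpec] = ()
    maf_distribution: MafDistribution = field(default_factory=MafDistribution)
    upd_chromosome: Optional[str] = None
    n_coverage_genes: int = 30
    n_coverage_exons: int = 8
    seed: int = None  # type: ignore[assignment]

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_families < 1:
            raise ValueError("n_families must be >= 1")
        if self.n_background_sites < 0:
            raise ValueError("n_background_sites must be >= 0")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")
        if not 0 <= self.base_error_fraction <= 0.05:
            raise ValueError("base_error_fraction must be in [0, 0.05]")
        for s in self.family_structures:
            if s not in FAMILY_STRUCTURES:
                raise ValueError(f"unknown family structure: {s!r}")
        if self.upd_chromosome is not None:
            self.upd_chromosome = normalize_chromosome(str(self.upd_chromosome))
            if self.upd_chromosome not in CHROMOSOMES:
                raise ValueError(
                    f"upd_chromosome {self.upd_chromosome!r} absent from site grid"
                )

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "planted_events" in d:
            d["planted_events"] = [
                e if isinstance(e, EventSpec) else EventSpec(**e)
                for e in d["planted_events"]
            ]
        if "maf_distribution" in d and isinstance(d["maf_distribution"], dict):
            md = dict(d["maf_distribution"])
            if "point_masses" in md:
                md["point_masses"] = {float(k): float(v) for k, v in md["point_masses"].items()}
            d["maf_distribution"] = MafDistribution(**md)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class SyntheticCohort:
    config: SimConfig
    pedigree: list[PedigreeMember]
    site_calls: list[SiteCall]
    exon_coverage: pd.DataFrame
    truth: list[TruthRecord]

    @property
    def sample_ids(self) -> list[str]:
        return [m.sample_id for m in self.pedigree]

    def write(self, out_dir) -> dict:
        """Write cohort.vcf, cohort.ped, coverage.tsv, truth.tsv; return the paths."""
        os.makedirs(out_dir, exist_ok=True)
        paths = {
            "vcf": os.path.join(out_dir, "cohort.vcf"),
            "ped": os.path.join(out_dir, "cohort.ped"),
            "coverage": os.path.join(out_dir, "coverage.tsv"),
            "truth": os.path.join(out_dir, "truth.tsv"),
        }
        variant_io.write_vcf(self.site_calls, self.sample_ids, paths["vcf"])
        variant_io.write_ped(self.pedigree, paths["ped"])
        self.exon_coverage.to_csv(paths["coverage"], sep="\t", index=False)
        write_truth(self.truth, paths["truth"])
        return paths


def write_truth(truth: Sequence[TruthRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("event_type\tfamily_id\tchromosome\tpositions\tgene\tcarriers\tparams\n")
        for t in truth:
            params = ";".join(f"{k}={t.params[k]}" for k in sorted(t.params)) or "."
            fh.write(
                "\t".join(
                    [
                        t.event_type,
                        t.family_id,
                        t.chromosome or ".",
                        ",".join(str(p) for p in t.positions) or ".",
                        t.gene or ".",
                        ",".join(t.carriers) or ".",
                        params,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# read-depth model
# ---------------------------------------------------------------------------

def _alt_probability(allele_fraction, base_error_fraction):
    """P(read supports alt) under the substitution-error model.

    A true alt base is misread with probability e (lost to the reference or
    another base); a true ref base is misread to the specific alt base with
    probability e/3.
    """
    f = np.asarray(allele_fraction, dtype=float)
    e = base_error_fraction
    return f * (1.0 - e) + (1.0 - f) * (e / 3.0)


_GENOTYPE_FRACTION = {"hom_ref": 0.0, "het": 0.5, "hom_alt": 1.0, "hemi_alt": 1.0, "mosaic": None}


def sample_read_depths(
    genotype: str,
    allele_fraction: float,
    mean_depth: float,
    rng: np.random.Generator,
    base_error_fraction: float = 0.0,
) -> tuple[int, int]:
    """Draw (ref_reads, alt_reads) for one sample at one site.

    Total depth is Poisson(mean_depth); alternate reads are binomial at the
    genotype's allele fraction perturbed by the substitution-error rate.
    For ``mosaic`` the caller supplies the fraction explicitly.
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be > 0")
    if not 0.0 <= allele_fraction <= 1.0:
        raise ValueError("allele_fraction must be in [0, 1]")
    if genotype not in _GENOTYPE_FRACTION:
        raise ValueError(f"unknown genotype for depth sampling: {genotype!r}")
    f = _GENOTYPE_FRACTION[genotype]
    if f is None:
        f = allele_fraction
    total = int(rng.poisson(mean_depth))
    alt = int(rng.binomial(total, float(_alt_probability(f, base_error_fraction)))) if total else 0
    return total - alt, alt


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

_STRUCTURE_CHILDREN = {"trio": ["P"], "quartet": ["P", "S2"], "multiplex3": ["P", "S2", "S3"], "singleton": ["P"]}


def _family_members(family_id: str, structure: str, proband_sex: str) -> list[PedigreeMember]:
    has_parents = structure != "singleton"
    fa = f"{family_id}_FA" if has_parents else None
    mo = f"{family_id}_MO" if has_parents else None
    sib_sex = {"S2": "female", "S3": "male"}
    members = []
    for role in _STRUCTURE_CHILDREN[structure]:
        sid = f"{family_id}_{role}"
        sex = proband_sex if role == "P" else sib_sex[role]
        # quartet and multiplex siblings are affected, mirroring multi-affected
        # sibships; this makes shared-variant screens meaningful
        members.append(PedigreeMember(sid, family_id, fa, mo, sex, "affected"))
    if has_parents:
        members.append(PedigreeMember(fa, family_id, None, None, "male", "unaffected"))
        members.append(PedigreeMember(mo, family_id, None, None, "female", "unaffected"))
    return members


def _site_grid(config: SimConfig, rng: np.random.Generator):
    """Evenly spaced per-chromosome positions with gene blocks and annotations."""
    base = config.n_background_sites // len(CHROMOSOMES)
    rem = config.n_background_sites % len(CHROMOSOMES)
    counts = {}
    for i, chrom in enumerate(CHROMOSOMES):
        n = base + (1 if i < rem else 0)
        if config.upd_chromosome == chrom:
            n = max(n, _MIN_UPD_MARKERS)
        counts[chrom] = n

    chroms, positions, genes = [], [], []
    for chrom in CHROMOSOMES:
        for i in range(counts[chrom]):
            chroms.append(chrom)
            positions.append(_GRID_START + i * _GRID_SPACING)
            genes.append(f"G{chrom}_{i // _GENE_BLOCK:04d}")
    n = len(chroms)
    maf = config.maf_distribution.sample(rng, n)
    cons_idx = rng.choice(
        len(_BACKGROUND_CONSEQUENCES), size=n, p=_BACKGROUND_CONSEQUENCE_P
    )
    consequences = [_BACKGROUND_CONSEQUENCES[i] for i in cons_idx]
    return {
        "chrom": np.array(chroms, dtype=object),
        "pos": np.array(positions, dtype=np.int64),
        "gene": genes,
        "maf": maf,
        "consequence": consequences,
        "counts": counts,
    }


def _assign_event_sites(config: SimConfig, grid) -> dict:
    """Reserve grid sites for planted SNV events; returns per-event site indices."""
    chrom_offsets = {}
    off = 0
    for chrom in CHROMOSOMES:
        chrom_offsets[chrom] = off
        off += grid["counts"][chrom]

    cycle = [c for c in _EVENT_CHROM_CYCLE if c != config.upd_chromosome]
    next_block: dict[str, int] = {}
    assignments: dict[int, list[int]] = {}
    cycle_i = 0
    for ei, ev in enumerate(config.planted_events):
        if ev.event_type in ("exon_dropout", "upd"):
            continue
        chrom = "X" if ev.event_type == "xl_hemizygous" else cycle[cycle_i % len(cycle)]
        if ev.event_type != "xl_hemizygous":
            cycle_i += 1
        block = next_block.get(chrom, 0)
        next_block[chrom] = block + 1
        n_sites_needed = 2 if ev.event_type == "compound_het" else 1
        first = chrom_offsets[chrom] + block * _GENE_BLOCK
        if block * _GENE_BLOCK + n_sites_needed > grid["counts"][chrom]:
            raise ValueError(
                f"chromosome {chrom} has too few grid sites for planted events; "
                "increase n_background_sites"
            )
        assignments[ei] = list(range(first, first + n_sites_needed))
    return assignments


def simulate_cohort(config: SimConfig) -> SyntheticCohort:
    """Generate a synthetic cohort realizing every planted event.

    Background genotypes are Mendelian-consistent; planted de novo / UPD
    events deliberately violate transmission and are recorded in the truth
    table. Identical config and seed reproduce identical outputs.
    """
    rng = np.random.default_rng(config.seed)

    structures = [
        config.family_structures[i % len(config.family_structures)]
        for i in range(config.n_families)
    ]
    family_ids = [f"F{i + 1:02d}" for i in range(config.n_families)]
    known = set(family_ids)
    for ev in config.planted_events:
        if ev.target_family not in known:
            raise ValueError(f"unknown target_family: {ev.target_family!r}")

    events = list(config.planted_events)
    implicit_upd = None
    upd_events = [e for e in events if e.event_type == "upd"]
    if upd_events and config.upd_chromosome is None:
        raise ValueError("upd events require upd_chromosome to be set")
    if config.upd_chromosome is not None and not upd_events:
        implicit_upd = EventSpec("upd", family_ids[0], upd_parent="father")
        events.append(implicit_upd)
    if len(upd_events) > 1:
        raise ValueError("at most one upd event per cohort")

    xl_families = {e.target_family for e in events if e.event_type == "xl_hemizygous"}

    grid = _site_grid(config, rng)
    n_sites = len(grid["pos"])
    site_chrom = grid["chrom"]
    is_x = site_chrom == "X"

    event_sites = _assign_event_sites(_config_with_events(config, events), grid)

    # event-site annotation overrides; background allele frequency forced to 0
    p = grid["maf"].copy()
    maf_annot: list[Optional[float]] = list(grid["maf"])
    genes = list(grid["gene"])
    consequences = list(grid["consequence"])
    event_site_mask = np.zeros(n_sites, dtype=bool)
    for ei, sites in event_sites.items():
        ev = events[ei]
        defaults = {
            "de_novo": ["missense"],
            "ar_homozygous": ["stop_gain"],
            "xl_hemizygous": ["stop_gain"],
            "mosaic_parent": ["missense"],
            "compound_het": ["stop_gain", "missense"],
        }[ev.event_type]
        for j, s in enumerate(sites):
            event_site_mask[s] = True
            p[s] = 0.0
            maf_annot[s] = None
            consequences[s] = ev.consequence or defaults[min(j, len(defaults) - 1)]
            if ev.gene is not None:
                genes[s] = ev.gene
        if ev.event_type == "compound_het":
            # both sites must share a gene for trans-phasing
            genes[sites[1]] = genes[sites[0]]

    # UPD bookkeeping
    upd_ev = next((e for e in events if e.event_type == "upd"), None)
    upd_mask = site_chrom == config.upd_chromosome if upd_ev is not None else None
    upd_first_idx = int(np.nonzero(upd_mask)[0][0]) if upd_ev is not None else None

    pedigree: list[PedigreeMember] = []
    codes_by_sample: dict[str, np.ndarray] = {}
    fraction_overrides: list[tuple[int, str, float]] = []
    truth: list[TruthRecord] = []

    sexes = ["male", "female"]
    for fi, (fid, structure) in enumerate(zip(family_ids, structures)):
        proband_sex = "male" if fid in xl_families else sexes[fi % 2]
        members = _family_members(fid, structure, proband_sex)
        pedigree.extend(members)
        children = [m for m in members if m.father_id is not None]
        if structure == "singleton":
            children = [members[0]]

        # parental haplotypes (phantom parents for singletons keep the
        # proband's background genotypes population-realistic)
        fh = (rng.random((n_sites, 2)) < p[:, None]).astype(np.int8)
        mh = (rng.random((n_sites, 2)) < p[:, None]).astype(np.int8)

        fam_events = [
            (ei, events[ei]) for ei in event_sites if events[ei].target_family == fid
        ]
        is_upd_family = upd_ev is not None and upd_ev.target_family == fid
        if is_upd_family:
            # force >=1 informative Mendelian-inconsistent site vs the
            # excluded parent: UPD parent het on haplotype 0, other hom-ref
            s0 = upd_first_idx
            if upd_ev.upd_parent == "father":
                fh[s0] = (1, 0)
                mh[s0] = (0, 0)
            else:
                mh[s0] = (1, 0)
                fh[s0] = (0, 0)

        fam_codes: dict[str, np.ndarray] = {}
        if structure != "singleton":
            fa_id, mo_id = f"{fid}_FA", f"{fid}_MO"
            fa_codes = (fh[:, 0] + fh[:, 1]).astype(np.int8)
            fa_codes[is_x] = 3 + fh[is_x, 0]
            mo_codes = (mh[:, 0] + mh[:, 1]).astype(np.int8)
            fam_codes[fa_id] = fa_codes
            fam_codes[mo_id] = mo_codes

        for child in children:
            ci = rng.integers(0, 2, n_sites)
            cj = rng.integers(0, 2, n_sites)
            pat = fh[np.arange(n_sites), ci]
            mat = mh[np.arange(n_sites), cj]
            codes = (pat + mat).astype(np.int8)
            if child.sex == "male":
                codes[is_x] = 3 + mat[is_x]
            else:
                codes[is_x] = (fh[is_x, 0] + mat[is_x]).astype(np.int8)
            fam_codes[child.sample_id] = codes

        proband_id = f"{fid}_P"
        if is_upd_family:
            # isodisomy: proband carries two copies of the UPD parent's
            # haplotype 0 across the whole chromosome
            src = fh if upd_ev.upd_parent == "father" else mh
            fam_codes[proband_id][upd_mask] = (2 * src[upd_mask, 0]).astype(np.int8)
            upd_pos = grid["pos"][upd_mask]
            truth.append(
                TruthRecord(
                    "upd",
                    fid,
                    config.upd_chromosome,
                    (int(upd_pos[0]), int(upd_pos[-1])),
                    None,
                    (proband_id,),
                    {"upd_parent": upd_ev.upd_parent, "n_markers": int(upd_mask.sum())},
                )
            )

        for ei, ev in fam_events:
            sites = event_sites[ei]
            fa_id = f"{fid}_FA" if structure != "singleton" else None
            mo_id = f"{fid}_MO" if structure != "singleton" else None
            carriers: tuple
            if ev.event_type == "de_novo":
                s = sites[0]
                fam_codes[proband_id][s] = 1
                if fa_id:
                    fam_codes[fa_id][s] = 0
                    fam_codes[mo_id][s] = 0
                carriers = (proband_id,)
            elif ev.event_type == "ar_homozygous":
                s = sites[0]
                fam_codes[proband_id][s] = 2
                if fa_id:
                    fam_codes[fa_id][s] = 1
                    fam_codes[mo_id][s] = 1
                carriers = (proband_id,)
            elif ev.event_type == "compound_het":
                s1, s2 = sites
                fam_codes[proband_id][s1] = 1
                fam_codes[proband_id][s2] = 1
                if fa_id:
                    fam_codes[fa_id][s1] = 1
                    fam_codes[mo_id][s1] = 0
                    fam_codes[fa_id][s2] = 0
                    fam_codes[mo_id][s2] = 1
                carriers = (proband_id,)
            elif ev.event_type == "xl_hemizygous":
                s = sites[0]
                fam_codes[proband_id][s] = 4  # male proband, hemizygous alt
                if fa_id:
                    fam_codes[fa_id][s] = 3
                    fam_codes[mo_id][s] = 1
                carriers = (proband_id,)
            elif ev.event_type == "mosaic_parent":
                s = sites[0]
                kid_ids = [c.sample_id for c in children if c.affected == "affected"]
                for kid in kid_ids:
                    fam_codes[kid][s] = 1
                if fa_id:
                    fam_codes[fa_id][s] = 0
                    fam_codes[mo_id][s] = 0
                    fraction_overrides.append((s, fa_id, ev.mosaic_fraction))
                carriers = tuple(kid_ids)
            else:  # pragma: no cover - upd/exon_dropout handled elsewhere
                continue
            truth.append(
                TruthRecord(
                    ev.event_type,
                    fid,
                    str(site_chrom[sites[0]]),
                    tuple(int(grid["pos"][s]) for s in sites),
                    genes[sites[0]],
                    carriers,
                    {"mosaic_fraction": ev.mosaic_fraction}
                    if ev.event_type == "mosaic_parent"
                    else {},
                )
            )

        codes_by_sample.update(fam_codes)

    sample_ids = [m.sample_id for m in pedigree]
    code_matrix = np.stack([codes_by_sample[s] for s in sample_ids], axis=1)

    fractions = _CODE_TO_FRACTION[code_matrix]
    col_of = {s: j for j, s in enumerate(sample_ids)}
    for s, sid, frac in fraction_overrides:
        fractions[s, col_of[sid]] = frac

    totals = rng.poisson(config.mean_depth, size=code_matrix.shape)
    p_alt = _alt_probability(fractions, config.base_error_fraction)
    alts = rng.binomial(totals, p_alt)
    refs = totals - alts

    site_calls: list[SiteCall] = []
    for s in range(n_sites):
        genotypes = {
            sid: GenotypeCall(
                _CODE_TO_CLASS[code_matrix[s, j]], int(refs[s, j]), int(alts[s, j])
            )
            for j, sid in enumerate(sample_ids)
        }
        site_calls.append(
            SiteCall(
                chromosome=str(site_chrom[s]),
                position=int(grid["pos"][s]),
                ref_allele="A",
                alt_allele="G",
                gene=genes[s],
                consequence=consequences[s],
                maf=maf_annot[s],
                genotypes=genotypes,
            )
        )

    coverage, cov_truth = _simulate_coverage(config, events, pedigree, rng)
    truth.extend(cov_truth)

    return SyntheticCohort(config, pedigree, site_calls, coverage, truth)


def _config_with_events(config: SimConfig, events: list[EventSpec]) -> SimConfig:
    # shallow stand-in passing the realized event list to site assignment
    import copy

    c = copy.copy(config)
    c.planted_events = events
    return c


def _simulate_coverage(
    config: SimConfig,
    events: list[EventSpec],
    pedigree: list[PedigreeMember],
    rng: np.random.Generator,
):
    """Per-exon read counts for every sample, with planted dropout spans zeroed."""
    n_genes, n_exons = config.n_coverage_genes, config.n_coverage_exons
    gene_names = [f"CVG{g + 1:02d}" for g in range(n_genes)]

    dropout_events = [e for e in events if e.event_type == "exon_dropout"]
    slot = 9  # first slot (0-based) handed to dropout events: CVG10 onward
    spans: list[tuple[str, str, int, int]] = []  # (sample, gene, start, end)
    truth: list[TruthRecord] = []
    for ev in dropout_events:
        if ev.n_exons > n_exons - 2:
            raise ValueError("dropout span exceeds gene exon count")
        if slot >= n_genes:
            raise ValueError("too many dropout events for the coverage gene set")
        if ev.gene is not None:
            gene_names[slot] = ev.gene
        gname = gene_names[slot]
        slot += 1
        proband = f"{ev.target_family}_P"
        start = 3
        end = start + ev.n_exons - 1
        spans.append((proband, gname, start, end))
        truth.append(
            TruthRecord(
                "exon_dropout",
                ev.target_family,
                None,
                (),
                gname,
                (proband,),
                {"exon_start": start, "exon_end": end},
            )
        )

    sample_ids = [m.sample_id for m in pedigree]
    lengths = np.array(
        [[90 + 30 * ((7 * g + 3 * e) % 5) for e in range(n_exons)] for g in range(n_genes)]
    )
    factors = rng.uniform(0.7, 1.3, size=len(sample_ids))  # per-sample library depth
    lam = config.mean_depth * (lengths[None, :, :] / 150.0) * factors[:, None, None]
    counts = rng.poisson(lam)

    dropout_lookup = {(s, g): (a, b) for s, g, a, b in spans}
    rows = []
    for si, sid in enumerate(sample_ids):
        for g, gname in enumerate(gene_names):
            span = dropout_lookup.get((sid, gname))
            for e in range(n_exons):
                c = int(counts[si, g, e])
                if span and span[0] <= e + 1 <= span[1]:
                    c = 0
                rows.append((sid, gname, e + 1, int(lengths[g, e]), c))
    df = pd.DataFrame(
        rows, columns=["sample", "gene", "exon_index", "exon_length_bp", "read_count"]
    )
    return df, truth


# ---------------------------------------------------------------------------
# canned configurations and small helpers
# ---------------------------------------------------------------------------

def default_cohort_config(seed: int, n_families: int = 10, n_background_sites: int = 20_000) -> SimConfig:
    """Ten-trio cohort exercising every planted event class.

    Depth 40, substitution error 0.005, 20k background sites; one event of
    each type across the first seven families; paternal isodisomy of
    chromosome 2 in family F06; mosaic father at allele fraction 0.15 in F05.
    """
    events = [
        EventSpec("de_novo", "F01"),
        EventSpec("ar_homozygous", "F02"),
        EventSpec("compound_het", "F03"),
        EventSpec("xl_hemizygous", "F04"),
        EventSpec("mosaic_parent", "F05", mosaic_fraction=0.15),
        EventSpec("upd", "F06", upd_parent="father"),
        EventSpec("exon_dropout", "F07", n_exons=2),
    ]
    valid = {f"F{i + 1:02d}" for i in range(n_families)}
    events = [e for e in events if e.target_family in valid]
    has_upd = any(e.event_type == "upd" for e in events)
    return SimConfig(
        n_families=n_families,
        family_structures=("trio",),
        n_background_sites=n_background_sites,
        mean_depth=40.0,
        base_error_fraction=0.005,
        planted_events=events,
        upd_chromosome="2" if has_upd else None,
        seed=seed,
    )


def simulate_mosaic_trio_site(
    mosaic_fraction: float,
    mean_depth: float,
    rng: np.random.Generator,
    n_children: int = 1,
    base_error_fraction: float = 0.0,
) -> tuple[SiteCall, list[PedigreeMember]]:
    """One synthetic family site with a mosaic father and heterozygous children.

    The father's genotype is called hom_ref (the caller misses low-fraction
    mosaicism) while his allelic depths reflect the mosaic fraction.
    """
    fid = "FM"
    child_ids = [f"{fid}_P"] + [f"{fid}_S{i + 2}" for i in range(n_children - 1)]
    pedigree = [
        PedigreeMember(c, fid, f"{fid}_FA", f"{fid}_MO", "male", "affected")
        for c in child_ids
    ]
    pedigree.append(PedigreeMember(f"{fid}_FA", fid, None, None, "male", "unaffected"))
    pedigree.append(PedigreeMember(f"{fid}_MO", fid, None, None, "female", "unaffected"))

    genotypes = {}
    ref, alt = sample_read_depths("mosaic", mosaic_fraction, mean_depth, rng, base_error_fraction)
    genotypes[f"{fid}_FA"] = GenotypeCall("hom_ref", ref, alt)
    ref, alt = sample_read_depths("hom_ref", 0.0, mean_depth, rng, base_error_fraction)
    genotypes[f"{fid}_MO"] = GenotypeCall("hom_ref", ref, alt)
    for c in child_ids:
        ref, alt = sample_read_depths("het", 0.5, mean_depth, rng, base_error_fraction)
        genotypes[c] = GenotypeCall("het", ref, alt)
    site = SiteCall("1", 1_000_000, "A", "G", "PIK-like", "missense", None, genotypes)
    return site, pedigree
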