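"""Cohort-wide scan for rare homozygous stop-gain variants per gene.

Genes recurrently tolerating or recurrently hit by biallelic truncation
across a large exome collection are sorted by the number of distinct
carriers, accelerating discovery of genes acting through a
loss-of-function mechanism. Hemizygous chrX stop-gains in males count as
homozygous-equivalent (single-allele loss of function).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .models import SiteCall


@dataclass
class GeneStopGainTally:
    gene: str
    n_individuals: int
    sample_ids: tuple
    variants: tuple  # (chromosome, position) pairs
    n_variants: int = field(init=False)

    def __post_init__(self):
        if self.n_individuals != len(self.sample_ids):
            raise ValueError("n_individuals must equal |sample_ids|")
        self.n_variants = len(self.variants)


def tally_rare_homozygous_stopgain(
    calls: Sequence[SiteCall],
    maf_max: float = 0.005,
) -> list[GeneStopGainTally]:
    """Tally distinct carriers of rare homozygous stop-gains per gene.

    Counts stop-gain variants with annotated MAF strictly below
    ``maf_max`` (absent annotation counts as rare/novel) carried
    hom_alt or hemi_alt. An individual counts once per gene however many
    qualifying variants they carry. Sorted by carrier count descending,
    ties broken lexicographically by gene symbol.
    """
    carriers: dict[str, set] = {}
    variants: dict[str, set] = {}
    for site in calls:
        if site.gene is None or site.consequence != "stop_gain":
            continue
        if site.maf is not None and site.maf >= maf_max:
            continue
        for sid, g in site.genotypes.items():
            if g.genotype in ("hom_alt", "hemi_alt"):
                carriers.setdefault(site.gene, set()).add(sid)
                variants.setdefault(site.gene, set()).add((site.chromosome, site.position))

    tallies = [
        GeneStopGainTally(
            gene,
            len(carriers[gene]),
            tuple(sorted(carriers[gene])),
            tuple(sorted(variants[gene])),
        )
        for gene in carriers
    ]
    tallies.sort(key=lambda t: (-t.n_individuals, t.gene))
    return tallies


def write_tallies(tallies: Sequence[GeneStopGainTally], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tn_individuals\tn_variants\tsample_ids\tvariants\n")
        for t in tallies:
            fh.write(
                "\t".join(
                    [
                        t.gene,
                        str(t.n_individuals),
                        str(t.n_variants),
                        ",".join(t.sample_ids),
                        ",".join(f"{c}:{p}" for c, p in t.variants),
                    ]
                )
                + "\n"
            )
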