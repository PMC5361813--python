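"""Diagnostic-yield summaries, projection arithmetic, and SNV/CNV joins.

Family outcomes are classified into three solved categories — known
disease genes, novel genes (identified in more than one family), and
candidate genes (a single family to date) — plus unsolved. Yields are
reported per family structure (trio, quartet, multiplex, singleton) and
per phenotype group, and a two-stage projection combines a first-pass
clinical yield with a residual research yield on the unsolved remainder:

    combined = initial + (1 - initial) * residual
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .coverage_del import DeletionCall
from .models import CandidateVariant

CATEGORIES = ("known_gene", "novel_gene", "candidate_gene", "unsolved")
SOLVED_CATEGORIES = frozenset({"known_gene", "novel_gene", "candidate_gene"})

OUTCOME_COLUMNS = [
    "family_id",
    "structure",
    "phenotype_group",
    "category",
    "independently_resolved",
]


@dataclass
class YieldReport:
    n_families: int
    category_counts: dict
    structure_rates: dict  # structure -> (numerator, denominator)
    phenotype_rates: dict  # group -> (numerator, denominator)
    known_novel: tuple  # (numerator, denominator)
    overall_with_candidates: tuple
    candidate_only: tuple
    independently_resolved: tuple  # of known/novel-solved families

    def formatted(self, decimals: int = 1) -> dict:
        out = {}
        for name, (num, den) in {
            "known_novel": self.known_novel,
            "overall_with_candidates": self.overall_with_candidates,
            "candidate_only": self.candidate_only,
            "independently_resolved": self.independently_resolved,
            **{f"structure:{k}": v for k, v in self.structure_rates.items()},
            **{f"phenotype:{k}": v for k, v in self.phenotype_rates.items()},
        }.items():
            out[name] = format_rate(num, den, decimals) if den else "NA"
        return out


@dataclass
class YieldProjection:
    initial_rate: float
    residual_rate: float
    combined_rate: float = field(init=False)

    def __post_init__(self):
        for r in (self.initial_rate, self.residual_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must be in [0, 1]")
        self.combined_rate = self.initial_rate + (1.0 - self.initial_rate) * self.residual_rate


def round_half_away(x: float, decimals: int = 0) -> float:
    """Round to nearest with halves away from zero (not banker's)."""
    scale = 10 ** decimals
    return math.copysign(math.floor(abs(x) * scale + 0.5) / scale, x)


def format_rate(numerator: int, denominator: int, decimals: int = 1) -> str:
    """Render numerator/denominator as a percentage string."""
    if denominator <= 0:
        raise ValueError("denominator must be > 0")
    if decimals < 0:
        raise ValueError("decimals must be >= 0")
    pct = round_half_away(100.0 * numerator / denominator, decimals)
    return f"{pct:.{decimals}f}%"


def project_overall_yield(initial_rate: float, residual_rate: float) -> YieldProjection:
    """Combined diagnostic yield of sequential clinical + research analysis.

    The residual yield applies to the fraction the first pass left
    unsolved: combined = initial + (1 - initial) * residual, algebraically
    identical to 1 - (1 - initial)(1 - residual).
    """
    return YieldProjection(initial_rate, residual_rate)


def summarize_yield(outcomes: pd.DataFrame) -> YieldReport:
    """Tabulate diagnostic yield from a one-row-per-family outcome table.

    Expected columns: family_id, structure, phenotype_group, category
    (known_gene | novel_gene | candidate_gene | unsolved), and optionally
    independently_resolved (bool). A family counts as solved when its
    category is any of the three gene categories.
    """
    missing = [c for c in OUTCOME_COLUMNS[:4] if c not in outcomes.columns]
    if missing:
        raise ValueError(f"outcome table lacks columns: {missing}")
    bad = set(outcomes["category"]) - set(CATEGORIES)
    if bad:
        raise ValueError(f"unknown category label(s): {sorted(bad)}")
    if outcomes["family_id"].duplicated().any():
        raise ValueError("outcome table must have one row per family")

    n = len(outcomes)
    counts = {c: int((outcomes["category"] == c).sum()) for c in CATEGORIES}
    solved = outcomes["category"].isin(SOLVED_CATEGORIES)
    known_novel = outcomes["category"].isin(("known_gene", "novel_gene"))

    structure_rates = {
        s: (int(solved[outcomes["structure"] == s].sum()), int((outcomes["structure"] == s).sum()))
        for s in sorted(outcomes["structure"].unique())
    }
    phenotype_rates = {
        g: (
            int(solved[outcomes["phenotype_group"] == g].sum()),
            int((outcomes["phenotype_group"] == g).sum()),
        )
        for g in sorted(outcomes["phenotype_group"].unique())
    }

    if "independently_resolved" in outcomes.columns:
        indep = int((outcomes["independently_resolved"].astype(bool) & known_novel).sum())
    else:
        indep = 0
    return YieldReport(
        n_families=n,
        category_counts=counts,
        structure_rates=structure_rates,
        phenotype_rates=phenotype_rates,
        known_novel=(int(known_novel.sum()), n),
        overall_with_candidates=(int(solved.sum()), n),
        candidate_only=(counts["candidate_gene"], n),
        independently_resolved=(indep, int(known_novel.sum())),
    )


def join_snv_deletion_trans(
    candidates: Sequence[CandidateVariant],
    deletions: Sequence[DeletionCall],
) -> list[CandidateVariant]:
    """Annotate het SNV candidates with overlapping-gene deletion calls.

    A heterozygous candidate SNV in a gene where the same proband carries
    a dropout deletion may form a compound SNV+deletion genotype in trans;
    such candidates gain a ``possible_compound_SNV_del`` evidence entry
    with the deletion's exon span. Homozygous SNVs are untouched (not a
    trans configuration).
    """
    dels = {}
    for d in deletions:
        dels.setdefault((d.sample, d.gene), []).append(d)
    for c in candidates:
        g = c.site.genotypes.get(c.sample_id)
        if g is None or g.genotype != "het" or c.site.gene is None:
            continue
        for d in dels.get((c.sample_id, c.site.gene), []):
            c.evidence["possible_compound_SNV_del"] = f"exons_{d.exon_start}-{d.exon_end}"
    return list(candidates)


# ---------------------------------------------------------------------------
# bundled example cohort
# ---------------------------------------------------------------------------

def bundled_pilot_outcomes() -> pd.DataFrame:
    """Outcome table of a published 74-family unsolved-exome reanalysis cohort.

    63 trios, 4 quartets, 1 multiplex sibship, 6 singletons; 19 families
    solved in known genes, 8 in novel genes, 11 with candidate-gene
    findings, 36 unsolved; 12 of the 27 known/novel-solved families were
    independently re-solved by the clinical laboratory; phenotype groups
    split 59 DD/ID (32 solved), 14 other (6 solved) and one unclassified
    unsolved family. Used as the worked example for yield summaries.
    """
    def block(structure, n, categories):
        rows = []
        for i, cat in enumerate(categories):
            rows.append({"structure": structure, "category": cat})
        assert len(categories) == n
        return rows

    rows = []
    rows += block("trio", 63, ["known_gene"] * 14 + ["novel_gene"] * 5 + ["candidate_gene"] * 11 + ["unsolved"] * 33)
    rows += block("quartet", 4, ["known_gene"] * 2 + ["novel_gene"] + ["unsolved"])
    rows += block("multiplex", 1, ["known_gene"])
    rows += block("singleton", 6, ["known_gene"] * 2 + ["novel_gene"] * 2 + ["unsolved"] * 2)

    df = pd.DataFrame(rows)
    df["family_id"] = [f"FAM{i + 1:02d}" for i in range(len(df))]

    solved_mask = df["category"].isin(SOLVED_CATEGORIES)
    phen = []
    solved_seen = unsolved_seen = 0
    for is_solved in solved_mask:
        if is_solved:
            phen.append("DD_ID" if solved_seen < 32 else "other")
            solved_seen += 1
        else:
            if unsolved_seen < 27:
                phen.append("DD_ID")
            elif unsolved_seen < 35:
                phen.append("other")
            else:
                phen.append("unclassified")
            unsolved_seen += 1
    df["phenotype_group"] = phen

    kn = df["category"].isin(("known_gene", "novel_gene"))
    indep = []
    kn_seen = 0
    for flag in kn:
        indep.append(bool(flag and kn_seen < 12))
        if flag:
            kn_seen += 1
    df["independently_resolved"] = indep
    return df[OUTCOME_COLUMNS]
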