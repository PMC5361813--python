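"""Simulator contracts: determinism, truth completeness, Mendelian structure,
and the read-depth model."""
import numpy as np
import pytest

from wes_reanalysis import cohort_sim
from wes_reanalysis.cohort_sim import (
    EventSpec,
    MafDistribution,
    SimConfig,
    sample_read_depths,
    simulate_cohort,
)


def tiny_config(seed, events=(), **kw):
    defaults = dict(
        n_families=2,
        family_structures=("trio",),
        n_background_sites=230,
        mean_depth=40.0,
        base_error_fraction=0.0,
        planted_events=list(events),
        seed=seed,
    )
    defaults.update(kw)
    return SimConfig(**defaults)


# ---------------------------------------------------------------------------
# config validation
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "kw",
    [
        {"seed": None},
        {"mean_depth": 0},
        {"base_error_fraction": 0.2},
        {"n_families": 0},
        {"upd_chromosome": "25"},
        {"family_structures": ("duo",)},
    ],
)
def test_invalid_config_rejected(kw):
    base = dict(n_families=2, family_structures=("trio",), seed=1)
    base.update(kw)
    with pytest.raises(ValueError):
        SimConfig(**base)


def test_unknown_target_family_rejected():
    cfg = tiny_config(1, events=[EventSpec("de_novo", "F99")])
    with pytest.raises(ValueError, match="target_family"):
        simulate_cohort(cfg)


def test_event_spec_invariants():
    with pytest.raises(ValueError):
        EventSpec("mosaic_parent", "F01")  # fraction required
    with pytest.raises(ValueError):
        EventSpec("de_novo", "F01", mosaic_fraction=0.2)
    with pytest.raises(ValueError):
        EventSpec("upd", "F01")  # parent required


# ---------------------------------------------------------------------------
# determinism and truth completeness
# ---------------------------------------------------------------------------

def test_identical_seed_reproduces_identical_outputs(tmp_path):
    events = [EventSpec("de_novo", "F01"), EventSpec("de_novo", "F02")]
    a = simulate_cohort(tiny_config(11, events))
    b = simulate_cohort(tiny_config(11, events))
    pa = a.write(tmp_path / "a")
    pb = b.write(tmp_path / "b")
    for key in pa:
        with open(pa[key], "rb") as f1, open(pb[key], "rb") as f2:
            assert f1.read() == f2.read(), f"{key} output not byte-identical"


def test_two_trios_one_de_novo_each(small=None):
    events = [EventSpec("de_novo", "F01"), EventSpec("de_novo", "F02")]
    cohort = simulate_cohort(tiny_config(1, events))
    dn = [t for t in cohort.truth if t.event_type == "de_novo"]
    assert len(dn) == 2
    by_pos = {c.position: c for c in cohort.site_calls}
    for t in dn:
        site = next(
            c for c in cohort.site_calls
            if c.chromosome == t.chromosome and c.position == t.positions[0]
        )
        proband = t.carriers[0]
        fid = t.family_id
        assert site.genotype_of(proband).has_alt
        assert not site.genotype_of(f"{fid}_FA").has_alt
        assert not site.genotype_of(f"{fid}_MO").has_alt


def test_truth_completeness_explicit_and_implicit_upd():
    events = [EventSpec("de_novo", "F01"), EventSpec("upd", "F02", upd_parent="mother")]
    cohort = simulate_cohort(tiny_config(3, events, upd_chromosome="2"))
    assert len(cohort.truth) == len(events)
    # upd_chromosome alone plants one implicit UPD record
    cohort2 = simulate_cohort(tiny_config(3, [EventSpec("de_novo", "F01")], upd_chromosome="2"))
    assert len(cohort2.truth) == 2
    assert sum(t.event_type == "upd" for t in cohort2.truth) == 1


# ---------------------------------------------------------------------------
# Mendelian structure
# ---------------------------------------------------------------------------

def _compatible(child, father, mother, child_sex, on_x):
    """Brute-force transmission oracle over genotype classes."""
    alleles = {
        "hom_ref": (0, 0), "het": (0, 1), "hom_alt": (1, 1),
        "hemi_ref": (0,), "hemi_alt": (1,),
    }
    fa, mo = alleles[father], alleles[mother]
    if on_x and child_sex == "male":
        return alleles[child] in {(a,) for a in mo}
    if on_x:
        combos = {tuple(sorted((fa[0], b))) for b in mo}
    else:
        combos = {tuple(sorted((a, b))) for a in fa for b in mo}
    return tuple(sorted(alleles[child])) in combos


def test_background_sites_mendelian_consistent(small_cohort):
    truth_positions = {
        (t.chromosome, p) for t in small_cohort.truth for p in t.positions
    }
    upd = next(t for t in small_cohort.truth if t.event_type == "upd")
    sex = {m.sample_id: m.sex for m in small_cohort.pedigree}
    trios = [
        (m.sample_id, m.father_id, m.mother_id)
        for m in small_cohort.pedigree
        if m.father_id
    ]
    checked = violations = 0
    for site in small_cohort.site_calls:
        if (site.chromosome, site.position) in truth_positions:
            continue
        for child, fa, mo in trios:
            if child == upd.carriers[0] and site.chromosome == upd.chromosome:
                continue  # whole chromosome overridden by the planted UPD
            checked += 1
            if not _compatible(
                site.genotype_of(child).genotype,
                site.genotype_of(fa).genotype,
                site.genotype_of(mo).genotype,
                sex[child],
                site.chromosome == "X",
            ):
                violations += 1
    assert checked > 10_000
    assert violations == 0


def test_planted_de_novo_violates_transmission(small_cohort):
    t = next(t for t in small_cohort.truth if t.event_type == "de_novo")
    site = next(
        c for c in small_cohort.site_calls
        if c.chromosome == t.chromosome and c.position == t.positions[0]
    )
    fid = t.family_id
    assert not _compatible(
        site.genotype_of(f"{fid}_P").genotype,
        site.genotype_of(f"{fid}_FA").genotype,
        site.genotype_of(f"{fid}_MO").genotype,
        "male", False,
    )


def test_upd_chromosome_has_inconsistent_site_vs_excluded_parent(small_cohort):
    t = next(t for t in small_cohort.truth if t.event_type == "upd")
    fid, proband = t.family_id, t.carriers[0]
    excluded = f"{fid}_MO" if t.params["upd_parent"] == "father" else f"{fid}_FA"
    inconsistent = 0
    for site in small_cohort.site_calls:
        if site.chromosome != t.chromosome:
            continue
        pg = site.genotype_of(proband)
        eg = site.genotype_of(excluded)
        if pg.genotype == "hom_alt" and not eg.has_alt:
            inconsistent += 1
    assert inconsistent >= 1


def test_upd_proband_homozygous_across_chromosome(small_cohort):
    t = next(t for t in small_cohort.truth if t.event_type == "upd")
    proband = t.carriers[0]
    for site in small_cohort.site_calls:
        if site.chromosome == t.chromosome:
            assert site.genotype_of(proband).genotype in ("hom_ref", "hom_alt")
    assert t.params["n_markers"] >= 200


# ---------------------------------------------------------------------------
# read-depth model
# ---------------------------------------------------------------------------

def test_depths_trivial_cases():
    rng = np.random.default_rng(0)
    for _ in range(50):
        ref, alt = sample_read_depths("hom_ref", 0.0, 30, rng)
        assert alt == 0
        ref, alt = sample_read_depths("hom_alt", 1.0, 30, rng)
        assert ref == 0


def test_depths_het_mean_fraction():
    rng = np.random.default_rng(1)
    fractions = []
    for _ in range(10_000):
        ref, alt = sample_read_depths("het", 0.5, 40, rng)
        if ref + alt:
            fractions.append(alt / (ref + alt))
    assert abs(np.mean(fractions) - 0.5) < 0.01


def test_depths_rejects_bad_fraction():
    rng = np.random.default_rng(0)
    with pytest.raises(ValueError):
        sample_read_depths("mosaic", 1.5, 30, rng)


def test_mosaic_fraction_monte_carlo():
    """Father's alt-read fraction at the mosaic site averages to the
    planted fraction over 200 seeded replicates."""
    fractions = []
    for seed in range(200):
        cohort = simulate_cohort(
            tiny_config(
                seed,
                [EventSpec("mosaic_parent", "F01", mosaic_fraction=0.15)],
                n_families=1,
            )
        )
        t = cohort.truth[0]
        site = next(
            c for c in cohort.site_calls
            if c.chromosome == t.chromosome and c.position == t.positions[0]
        )
        g = site.genotype_of("F01_FA")
        if g.total_reads:
            fractions.append(g.alt_reads / g.total_reads)
    assert abs(np.mean(fractions) - 0.15) < 0.02


def test_maf_distribution_weights_validated():
    with pytest.raises(ValueError):
        MafDistribution(point_masses={0.5: 0.5}, tail_weight=0.2)


def test_coverage_table_shape_and_dropout(small_cohort):
    df = small_cohort.exon_coverage
    t = next(t for t in small_cohort.truth if t.event_type == "exon_dropout")
    proband = t.carriers[0]
    sub = df[(df["sample"] == proband) & (df["gene"] == t.gene)]
    span = sub[
        (sub["exon_index"] >= t.params["exon_start"])
        & (sub["exon_index"] <= t.params["exon_end"])
    ]
    assert (span["read_count"] == 0).all()
    others = sub[~sub["exon_index"].isin(span["exon_index"])]
    assert (others["read_count"] > 0).all()
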