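"""Format I/O: PED parsing, VCF round-trips, decomposition, MNV merging."""
import pytest

from wes_reanalysis import variant_io
from wes_reanalysis.models import GenotypeCall, SiteCall
from util import gt, site, trio_pedigree


# ---------------------------------------------------------------------------
# PED
# ---------------------------------------------------------------------------

def test_read_pedigree_trio():
    lines = [
        "T1 T1_P T1_FA T1_MO 1 2",
        "T1 T1_FA 0 0 1 1",
        "T1 T1_MO 0 0 2 1",
    ]
    members = variant_io.read_pedigree(lines)
    assert [m.sample_id for m in members] == ["T1_P", "T1_FA", "T1_MO"]
    p = members[0]
    assert p.father_id == "T1_FA" and p.mother_id == "T1_MO"
    assert p.sex == "male" and p.affected == "affected"


def test_read_pedigree_singleton_zero_parents():
    members = variant_io.read_pedigree(["S1 S1_P 0 0 2 2"])
    assert members[0].father_id is None and members[0].mother_id is None


def test_read_pedigree_duplicate_id_errors():
    with pytest.raises(ValueError, match="T1_P"):
        variant_io.read_pedigree(["T1 T1_P 0 0 1 2", "T1 T1_P 0 0 1 2"])


def test_read_pedigree_unresolvable_parent_errors():
    with pytest.raises(ValueError, match="GHOST"):
        variant_io.read_pedigree(["T1 T1_P GHOST 0 1 2"])


def test_ped_round_trip(tmp_path):
    ped, *_ = trio_pedigree()
    path = tmp_path / "t.ped"
    variant_io.write_ped(ped, path)
    back = variant_io.read_pedigree(path)
    assert [(m.sample_id, m.father_id, m.sex, m.affected) for m in back] == [
        (m.sample_id, m.father_id, m.sex, m.affected) for m in ped
    ]


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _write_raw_vcf(path, body, samples=("S1",)):
    header = (
        "##fileformat=VCFv4.2\n"
        '##INFO=<ID=GENE,Number=1,Type=String,Description="g">\n'
        '##INFO=<ID=CSQ,Number=1,Type=String,Description="c">\n'
        '##INFO=<ID=MAF,Number=1,Type=Float,Description="m">\n'
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="gt">\n'
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="ad">\n'
        "##contig=<ID=1,length=2000000>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples)
        + "\n"
    )
    path.write_text(header + body)


def _singleton_ped(sid="S1"):
    return variant_io.read_pedigree([f"F {sid} 0 0 1 2"])


def test_read_calls_het_with_depths(tmp_path):
    p = tmp_path / "a.vcf"
    _write_raw_vcf(p, "1\t100\t.\tA\tG\t.\t.\tGENE=X1;CSQ=missense;MAF=0.01\tGT:AD\t0/1:12,6\n")
    calls = variant_io.read_calls(p, _singleton_ped())
    (c,) = calls
    g = c.genotype_of("S1")
    assert (g.genotype, g.ref_reads, g.alt_reads) == ("het", 12, 6)
    assert c.gene == "X1" and c.consequence == "missense"
    assert abs(c.maf - 0.01) < 1e-6


def test_read_calls_decomposes_multiallelic(tmp_path):
    p = tmp_path / "m.vcf"
    _write_raw_vcf(p, "1\t100\t.\tC\tA,T\t.\t.\tCSQ=missense\tGT:AD\t1/2:3,7,9\n")
    calls = variant_io.read_calls(p, _singleton_ped())
    assert len(calls) == 2
    a, t = calls
    assert a.alt_allele == "A" and t.alt_allele == "T"
    # each decomposed allele is het for the sample; depths are per-allele
    assert a.genotype_of("S1").alt_reads == 7
    assert t.genotype_of("S1").alt_reads == 9
    assert a.genotype_of("S1").genotype == "het"
    # allele-depth conservation: per-allele alt totals within original AD sum
    assert a.genotype_of("S1").alt_reads + t.genotype_of("S1").alt_reads <= 3 + 7 + 9


def test_read_calls_missing_ad_errors(tmp_path):
    p = tmp_path / "bad.vcf"
    _write_raw_vcf(p, "1\t100\t.\tA\tG\t.\t.\tCSQ=missense\tGT\t0/1\n")
    with pytest.raises(ValueError, match="AD"):
        variant_io.read_calls(p, _singleton_ped())


def test_read_calls_sample_missing_from_vcf_errors(tmp_path):
    p = tmp_path / "s.vcf"
    _write_raw_vcf(p, "1\t100\t.\tA\tG\t.\t.\tCSQ=missense\tGT:AD\t0/1:5,5\n")
    ped = variant_io.read_pedigree(["F OTHER 0 0 1 2"])
    with pytest.raises(ValueError, match="OTHER"):
        variant_io.read_calls(p, ped)


def test_vcf_round_trip_preserves_genotypes_and_depths(tmp_path, small_cohort):
    path = tmp_path / "c.vcf"
    samples = small_cohort.sample_ids
    variant_io.write_vcf(small_cohort.site_calls, samples, path)
    ped = small_cohort.pedigree
    back = variant_io.read_calls(path, ped)
    orig = sorted(small_cohort.site_calls, key=lambda s: s.sort_key)
    assert len(back) == len(orig)
    for a, b in zip(orig, back):
        assert (a.chromosome, a.position, a.ref_allele, a.alt_allele) == (
            b.chromosome, b.position, b.ref_allele, b.alt_allele
        )
        for sid in samples:
            ga, gb = a.genotype_of(sid), b.genotype_of(sid)
            assert (ga.genotype, ga.ref_reads, ga.alt_reads) == (
                gb.genotype, gb.ref_reads, gb.alt_reads
            )


def test_chromosome_prefix_stripped():
    c = site(chrom="chr2", pos=5)
    assert c.chromosome == "2"


# ---------------------------------------------------------------------------
# MNV merging
# ---------------------------------------------------------------------------

def _pair(pos2=1445, s1_gt=("het", 10, 8), s2_gt=("het", 12, 6), fa_gt=None):
    g1 = {"P": gt(*s1_gt)}
    g2 = {"P": gt(*s2_gt)}
    if fa_gt is not None:
        g1["FA"] = gt("het", 9, 9)
        g2["FA"] = gt(*fa_gt)
    a = site(chrom="22", pos=1444, ref="C", alt="T", genotypes=g1)
    b = site(chrom="22", pos=pos2, ref="C", alt="T", genotypes=g2)
    return [a, b]


def test_adjacent_snvs_merge_to_dinucleotide():
    merged = variant_io.merge_adjacent_snvs(_pair())
    (m,) = merged
    assert (m.ref_allele, m.alt_allele, m.position) == ("CC", "TT", 1444)
    g = m.genotype_of("P")
    # conservative support: elementwise minimum of the pair
    assert (g.ref_reads, g.alt_reads) == (10, 6)


def test_non_adjacent_snvs_not_merged():
    out = variant_io.merge_adjacent_snvs(_pair(pos2=1446))
    assert len(out) == 2


def test_genotype_class_mismatch_blocks_merge():
    # second variant absent (hom_ref) in the father: classes differ
    out = variant_io.merge_adjacent_snvs(_pair(fa_gt=("hom_ref", 20, 0)))
    assert len(out) == 2


def test_merge_idempotent():
    once = variant_io.merge_adjacent_snvs(_pair())
    twice = variant_io.merge_adjacent_snvs(once)
    assert twice == once


def test_merge_requires_sorted_input():
    a, b = _pair()
    with pytest.raises(ValueError, match="sorted"):
        variant_io.merge_adjacent_snvs([b, a])


def test_merge_three_in_a_row_merges_leading_pair():
    a, b = _pair()
    c = site(chrom="22", pos=1446, ref="C", alt="T", genotypes={"P": gt("het", 9, 7)})
    out = variant_io.merge_adjacent_snvs([a, b, c])
    assert [x.ref_allele for x in out] == ["CC", "C"]


# ---------------------------------------------------------------------------
# candidate output
# ---------------------------------------------------------------------------

def test_write_candidates_deterministic(tmp_path):
    from wes_reanalysis.models import CandidateVariant

    s = site(genotypes={"P": gt("het", 10, 10)})
    cands = [
        CandidateVariant(s, "P", "F1", "het_lof", 3, evidence={"b": 2, "a": 1.5}),
        CandidateVariant(site(pos=500, genotypes={"P": gt("hom_alt", 0, 20)}),
                         "P", "F1", "ar_homozygous", 1),
    ]
    p1, p2 = tmp_path / "1.tsv", tmp_path / "2.tsv"
    variant_io.write_candidates(cands, p1)
    variant_io.write_candidates(list(reversed(cands)), p2)
    assert p1.read_bytes() == p2.read_bytes()
    lines = p1.read_text().splitlines()
    assert len(lines) == 3  # header + 2 rows
    assert lines[1].split("\t")[3] == "500"  # sorted by position


def test_write_candidates_empty_is_header_only(tmp_path):
    p = tmp_path / "e.tsv"
    variant_io.write_candidates([], p)
    assert p.read_text().splitlines() == ["\t".join(variant_io.CANDIDATE_COLUMNS)]
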