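"""Variant reading, classification, filtering and annotation."""

import math

import numpy as np
import pytest

import chloropop as cp
from chloropop.variant_io import MISSING

from conftest import make_matrix


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("ref,alts,vclass,subst", [
    ("A", ["G"], "SNP", "transition"),
    ("G", ["A"], "SNP", "transition"),
    ("C", ["T"], "SNP", "transition"),
    ("A", ["T"], "SNP", "transversion"),
    ("A", ["C"], "SNP", "transversion"),
    ("T", ["TA"], "InDel", "NA"),
    ("TC", ["T"], "InDel", "NA"),
    ("A", ["C", "G"], "SNP", "NA"),  # multiallelic SNP: subst undefined
])
def test_classify_variant(ref, alts, vclass, subst):
    assert cp.classify_variant(ref, alts) == (vclass, subst)


def test_classify_variant_symmetric_in_ref_alt():
    for ref, alt in [("A", "G"), ("A", "T"), ("C", "T"), ("G", "C")]:
        assert cp.classify_variant(ref, [alt])[1] == cp.classify_variant(alt, [ref])[1]


def test_classify_variant_rejects_non_nucleotides():
    with pytest.raises(ValueError):
        cp.classify_variant("N", ["A"])


# ---------------------------------------------------------------------------
# VCF reading: haploid collapse rules
# ---------------------------------------------------------------------------

def test_read_vcf_collapses_diploid_calls(tmp_path):
    vcf = tmp_path / "toy.vcf"
    vcf.write_text(
        "##fileformat=VCFv4.2\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tx\ty\n"
        "cp\t5\t.\tA\tG\t.\tPASS\t.\tGT\t1/1\t1/1\n"
        "cp\t9\t.\tC\tT\t.\tPASS\t.\tGT\t0/1\t0/0\n"
        "cp\t12\t.\tG\tA\t.\tPASS\t.\tGT\t1\t./.\n"
    )
    m = cp.read_vcf(vcf)
    assert m.samples == ["x", "y"]
    assert m.records[0].calls.tolist() == [1, 1]      # 1/1 -> haploid 1
    assert m.records[1].calls.tolist() == [MISSING, 0]  # 0/1 -> MISSING
    assert m.records[2].calls.tolist() == [1, MISSING]

    m2 = cp.read_vcf(vcf, het_policy="major")
    assert m2.records[1].calls.tolist() == [0, 0]


def test_read_vcf_zero_samples_errors(tmp_path):
    vcf = tmp_path / "empty.vcf"
    vcf.write_text(
        "##fileformat=VCFv4.2\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
    )
    with pytest.raises(Exception):
        cp.read_vcf(vcf)


def test_vcf_round_trip_preserves_everything(tmp_path):
    rng = np.random.default_rng(7)
    calls = rng.integers(-1, 2, size=(12, 6))
    m = make_matrix(calls)
    cp.write_vcf(m, tmp_path / "rt.vcf")
    back = cp.read_vcf(tmp_path / "rt.vcf")
    assert back.samples == m.samples
    assert back.positions.tolist() == m.positions.tolist()
    for a, b in zip(m.records, back.records):
        assert a.ref == b.ref and a.alts == b.alts
        assert a.calls.tolist() == b.calls.tolist()


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def test_filter_missing_and_maf_rules():
    # 10 samples; site 0: 3 missing -> removed at 20%
    calls = np.zeros((2, 10), dtype=int)
    calls[0, :3] = MISSING
    calls[0, 3:7] = 1
    calls[1, :5] = 1
    m = make_matrix(calls)
    res = cp.filter_variants(m)
    assert res.n_retained == 1 and res.n_removed == 1
    assert res.matrix.positions.tolist() == [m.records[1].pos]


def test_filter_maf_boundary_exact_threshold_retained():
    # maf exactly 0.01: 1 alt among 100 calls
    calls = np.zeros((1, 100), dtype=int)
    calls[0, 0] = 1
    m = make_matrix(calls)
    res = cp.filter_variants(m, max_missing=0.2, min_maf=0.01)
    assert res.n_retained == 1


def test_filter_five_site_toy():
    # missing rates 0, .1, .25, 0, .5 and mafs .3, .005, .3, .2, .3
    # hand application of both rules keeps sites 1 and 4 only
    n = 200
    calls = np.zeros((5, n), dtype=int)
    specs = [(0.0, 0.3), (0.1, 0.005), (0.25, 0.3), (0.0, 0.2), (0.5, 0.3)]
    for i, (miss, maf) in enumerate(specs):
        n_miss = round(miss * n)
        n_obs = n - n_miss
        n_alt = round(maf * n_obs)
        calls[i, :n_miss] = MISSING
        calls[i, n_miss:n_miss + n_alt] = 1
    m = make_matrix(calls)
    res = cp.filter_variants(m, max_missing=0.20, min_maf=0.01)
    assert res.n_retained == 2
    assert res.matrix.positions.tolist() == [m.records[0].pos, m.records[3].pos]


def test_filter_idempotent_and_conserves_counts():
    rng = np.random.default_rng(3)
    calls = rng.integers(-1, 2, size=(30, 15))
    m = make_matrix(calls)
    first = cp.filter_variants(m)
    assert first.n_retained + first.n_removed == m.n_sites
    second = cp.filter_variants(first.matrix)
    assert second.n_removed == 0
    assert second.matrix.positions.tolist() == first.matrix.positions.tolist()


def test_filter_empty_matrix_errors():
    m = make_matrix(np.zeros((1, 4), dtype=int))
    empty = m.subset_sites([])
    with pytest.raises(ValueError):
        cp.filter_variants(empty)


# ---------------------------------------------------------------------------
# Ts/Tv, regions, density
# ---------------------------------------------------------------------------

def test_tstv_ratio():
    m = make_matrix(np.tile([0, 1], (3, 2)),
                    refs=["A", "C", "A"], alts=[("G",), ("T",), ("T",)])
    assert cp.tstv_ratio(m) == pytest.approx(2.0)


def test_tstv_infinite_when_no_transversions():
    m = make_matrix(np.tile([0, 1], (2, 2)), refs=["A", "C"],
                    alts=[("G",), ("T",)])
    assert math.isinf(cp.tstv_ratio(m))


def test_tstv_errors_without_snps():
    m = make_matrix(np.tile([0, 1], (1, 2)), refs=["T"], alts=[("TA",)])
    with pytest.raises(ValueError):
        cp.tstv_ratio(m)


def test_annotate_regions_boundaries_and_fraction():
    m = make_matrix(np.tile([0, 1], (4, 2)), positions=[100, 150, 151, 400])
    ann = cp.annotate_regions(m, [(50, 150), (300, 500)])
    regions = [r.region for r in ann.records]
    assert regions == ["coding", "coding", "noncoding", "coding"]
    assert sum(r == "coding" for r in regions) / len(regions) == 0.75


def test_annotate_regions_bad_interval():
    m = make_matrix(np.tile([0, 1], (1, 2)))
    with pytest.raises(ValueError):
        cp.annotate_regions(m, [(100, 50)])


def test_annotate_regions_from_gff(tmp_path):
    gff = tmp_path / "genes.gff3"
    gff.write_text(
        "##gff-version 3\n"
        "cp\ttest\tgene\t50\t150\t.\t+\t.\tID=gene1\n"
    )
    m = make_matrix(np.tile([0, 1], (2, 2)), positions=[100, 200])
    ann = cp.annotate_regions(m, gff)
    assert [r.region for r in ann.records] == ["coding", "noncoding"]


def test_variant_density():
    # 7 sites, 5 polymorphic within the subset, 10-kb genome -> 0.5/kb
    calls = np.zeros((7, 4), dtype=int)
    calls[:5, 0] = 1           # polymorphic in first two samples
    calls[5, 2] = 1            # polymorphic only outside the subset
    m = make_matrix(calls, genome_length=10_000)
    assert cp.variant_density(m, ["s0", "s1"]) == pytest.approx(0.5)
    assert cp.variant_density(m, ["s1", "s2"]) == pytest.approx(0.1)  # only site 5 varies
    with pytest.raises(ValueError):
        cp.variant_density(m, [])


def test_variant_density_monomorphic_subset_is_zero():
    calls = np.zeros((3, 4), dtype=int)
    calls[:, 0] = 1
    m = make_matrix(calls, genome_length=100_000)
    assert cp.variant_density(m, ["s1", "s2"]) == 0.0
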