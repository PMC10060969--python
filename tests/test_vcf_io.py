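"""VCF/BED ingestion: genotype mapping, covariable means, interval semantics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from replicall.simulate import SimConfig, simulate, write_vcf
from replicall.types import GenotypeCategory, IntervalSet
from replicall.vcf_io import cap_dp, read_bed, read_replicates, read_truth

HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=1>
##INFO=<ID=QD,Number=1,Type=Float,Description="qd">
##INFO=<ID=MQ,Number=1,Type=Float,Description="mq">
##FORMAT=<ID=GT,Number=1,Type=String,Description="gt">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="dp">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="ad">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="gq">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3
"""


def write_tiny_vcf(path, records):
    with open(path, "w") as fh:
        fh.write(HEADER)
        for r in records:
            fh.write(r + "\n")


def test_gt_categories_and_ab_mean(tmp_path):
    # ABs 0.5, 0.4, 0.96 -> mean 0.62; phasing separator ignored
    vcf = tmp_path / "t.vcf"
    write_tiny_vcf(vcf, [
        "1\t100\t.\tA\tG\t.\tPASS\tQD=12.3;MQ=60\tGT:DP:AD:GQ\t"
        "0/1:20:10,10:99\t0|1:20:12,8:99\t1/1:25:1,24:99",
    ])
    t = read_replicates(str(vcf))
    assert list(t.calls[0]) == [GenotypeCategory.HET, GenotypeCategory.HET,
                                GenotypeCategory.HOMALT]
    assert t.df.ab_mean[0] == pytest.approx(0.62)
    assert t.df.dp_mean[0] == pytest.approx(65 / 3)
    assert t.df.qd[0] == pytest.approx(12.3)


def test_no_variant_row_excluded_and_nocall_is_homref(tmp_path):
    vcf = tmp_path / "t.vcf"
    write_tiny_vcf(vcf, [
        # (./., 0/0, 0/0): no variant call anywhere -> dropped
        "1\t100\t.\tA\tG\t.\tPASS\tQD=1;MQ=60\tGT:DP:AD:GQ\t"
        "./.:10:10,0:10\t0/0:10:10,0:99\t0/0:10:10,0:99",
        # (./., 0/1, 0/1): kept, no-call counted as called HOMREF
        "1\t200\t.\tA\tG\t.\tPASS\tQD=10;MQ=60\tGT:DP:AD:GQ\t"
        "./.:10:10,0:10\t0/1:10:5,5:99\t0/1:10:5,5:99",
    ])
    t = read_replicates(str(vcf))
    assert len(t) == 1
    assert t.df.pos[0] == 200
    assert list(t.calls[0]) == [GenotypeCategory.HOMREF, GenotypeCategory.HET,
                                GenotypeCategory.HET]


def test_zero_depth_ab_convention(tmp_path):
    # AB undefined at DP=0: 0 for HOMREF calls, excluded from mean otherwise
    vcf = tmp_path / "t.vcf"
    write_tiny_vcf(vcf, [
        "1\t100\t.\tA\tG\t.\tPASS\tQD=10;MQ=60\tGT:DP:AD:GQ\t"
        "0/0:0:0,0:3\t0/1:0:0,0:3\t0/1:10:4,6:99",
    ])
    t = read_replicates(str(vcf))
    # mean over defined values: HOMREF 0.0 and 0.6; undefined HET excluded
    assert t.df.ab_mean[0] == pytest.approx((0.0 + 0.6) / 2)


def test_missing_info_median_imputed(tmp_path):
    vcf = tmp_path / "t.vcf"
    write_tiny_vcf(vcf, [
        "1\t100\t.\tA\tG\t.\tPASS\tMQ=60\tGT:DP:AD:GQ\t"
        "0/1:10:5,5:99\t0/1:10:5,5:99\t0/1:10:5,5:99",
        "1\t200\t.\tA\tG\t.\tPASS\tQD=8;MQ=60\tGT:DP:AD:GQ\t"
        "0/1:10:5,5:99\t0/1:10:5,5:99\t0/1:10:5,5:99",
        "1\t300\t.\tA\tG\t.\tPASS\tQD=12;MQ=60\tGT:DP:AD:GQ\t"
        "0/1:10:5,5:99\t0/1:10:5,5:99\t0/1:10:5,5:99",
    ])
    t = read_replicates(str(vcf))
    assert t.df.qd[0] == pytest.approx(10.0)  # median of 8, 12


def test_record_order_invariance(tmp_path):
    recs = [
        f"1\t{pos}\t.\tA\tG\t.\tPASS\tQD=10;MQ=60\tGT:DP:AD:GQ\t"
        "0/1:10:5,5:99\t0/1:10:5,5:99\t0/1:10:5,5:99"
        for pos in (100, 200, 300)
    ]
    a, b = tmp_path / "a.vcf", tmp_path / "b.vcf"
    write_tiny_vcf(a, recs)
    write_tiny_vcf(b, recs[::-1])
    ta = read_replicates(str(a)).df.sort_values("pos").reset_index(drop=True)
    tb = read_replicates(str(b)).df.sort_values("pos").reset_index(drop=True)
    assert ta.equals(tb)


def test_synthetic_round_trip_is_identity(tmp_path):
    ds = simulate(SimConfig(n_sites=400, seed=31))
    paths = write_vcf(ds, str(tmp_path))
    table = read_replicates(paths["replicates_vcf"], paths["difficult_bed"])
    ref = ds.to_site_table()
    assert (table.calls == ref.calls).all()
    for col in ("dp_mean", "ab_mean", "gq_mean", "qd", "mq"):
        np.testing.assert_allclose(table.df[col], ref.df[col], atol=1e-9)
    assert (table.df.difficult.to_numpy()
            == ref.df.difficult.to_numpy()).all()


def test_per_replicate_vcfs_merge_on_site_union(tmp_path):
    """Separate single-sample VCFs merge with no-call (HOMREF) fill."""
    single = HEADER.replace("\tS1\tS2\tS3", "\tS1")
    paths = []
    sites = {  # path -> {pos: gt}
        "r1.vcf": {100: "0/1:10:5,5:99", 200: "1/1:12:0,12:95"},
        "r2.vcf": {100: "0/1:14:7,7:99"},
        "r3.vcf": {200: "1/1:20:1,19:90"},
    }
    for name, recs in sites.items():
        p = tmp_path / name
        with open(p, "w") as fh:
            fh.write(single)
            for pos, sample in sorted(recs.items()):
                fh.write(f"1\t{pos}\t.\tA\tG\t.\tPASS\tQD=10;MQ=60\t"
                         f"GT:DP:AD:GQ\t{sample}\n")
        paths.append(str(p))
    t = read_replicates(paths)
    t.validate()
    df = t.df.sort_values("pos").reset_index(drop=True)
    assert len(df) == 2
    assert list(df.loc[0, ["call_1", "call_2", "call_3"]]) == [1, 1, 0]
    assert list(df.loc[1, ["call_1", "call_2", "call_3"]]) == [2, 0, 2]
    # covariable means use only the replicates with values at the site
    assert df.loc[0, "dp_mean"] == pytest.approx(12.0)
    assert df.loc[1, "ab_mean"] == pytest.approx((1.0 + 19 / 20) / 2)


class TestReadTruth:
    def test_lookup_semantics(self, tmp_path):
        vcf = tmp_path / "truth.vcf"
        with open(vcf, "w") as fh:
            fh.write(HEADER.replace("\tS1\tS2\tS3", "\tTRUTH"))
            fh.write("1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0/1\n")
            fh.write("1\t150\t.\tA\tG\t.\tPASS\t.\tGT\t1/1\n")
        bed = tmp_path / "conf.bed"
        bed.write_text("1\t50\t200\n")
        ts = read_truth(str(vcf), str(bed))
        assert ts.lookup("1", 100) == GenotypeCategory.HET
        assert ts.lookup("1", 150) == GenotypeCategory.HOMALT
        # inside region, absent from benchmark -> HOMREF
        assert ts.lookup("1", 120) == GenotypeCategory.HOMREF
        # outside region -> not evaluable
        assert ts.lookup("1", 300) is None
        assert ts.lookup("2", 100) is None

    def test_empty_bed_is_an_error(self, tmp_path):
        vcf = tmp_path / "truth.vcf"
        with open(vcf, "w") as fh:
            fh.write(HEADER.replace("\tS1\tS2\tS3", "\tTRUTH"))
        bed = tmp_path / "conf.bed"
        bed.write_text("")
        with pytest.raises(ValueError, match="empty BED"):
            read_truth(str(vcf), str(bed))


class TestCapDp:
    def test_extreme_depth_capped(self, default_table):
        t = default_table.df.copy()
        t.loc[t.index[0], "dp_mean"] = 13_858.0
        from replicall.types import SiteTable
        capped = cap_dp(SiteTable(t), 150)
        assert capped.df.dp_mean.iloc[0] == 150
        assert capped.df.dp_mean.max() <= 150

    def test_below_cap_unchanged_and_infinite_cap_identity(self, default_table):
        capped = cap_dp(default_table, np.inf)
        np.testing.assert_array_equal(capped.df.dp_mean,
                                      default_table.df.dp_mean)
        assert cap_dp(default_table, 150).df.dp_mean.min() == \
            default_table.df.dp_mean.min() if \
            default_table.df.dp_mean.min() < 150 else True

    def test_invalid_cap(self, default_table):
        with pytest.raises(ValueError):
            cap_dp(default_table, 0)


@settings(max_examples=200, deadline=None)
@given(start=st.integers(0, 1000), length=st.integers(1, 100),
       offset=st.integers(-3, 3))
def test_bed_halfopen_vcf_onebased_boundary(start, length, offset):
    """pos p (1-based) is inside [s, e) iff s < p <= e."""
    end = start + length
    iv = IntervalSet({"1": np.array([[start, end]])})
    p = start + offset if offset <= 0 else end + offset - 1
    inside = bool(iv.contains("1", np.array([p]))[0])
    assert inside == (start < p <= end)


def test_bed_merge_overlaps(tmp_path):
    bed = tmp_path / "x.bed"
    bed.write_text("1\t10\t20\n1\t15\t30\n1\t40\t50\n")
    iv = read_bed(str(bed))
    starts, ends = iv.intervals("1")
    assert list(starts) == [10, 40]
    assert list(ends) == [30, 50]
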