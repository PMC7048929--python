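import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from situscan.variant_io import (
    GT_HET,
    GT_HOM_ALT,
    GT_HOM_REF,
    GT_MISSING,
    genotype_columns,
    normalize_variant,
    read_cohort,
    site_quality_filter,
    tranche_lower_bound,
)

META = "subject_id\tgroup\tsex\tehi\tforced_switch\tdaily_wet_cough\tchd\n"


def write_inputs(tmp_path, vcf_body, samples=("S1", "S2"), groups=None):
    groups = groups or ["si_nonpcd"] * len(samples)
    vcf = tmp_path / "t.vcf"
    header = (
        "##fileformat=VCFv4.2\n"
        '##INFO=<ID=QD,Number=1,Type=Float,Description="qd">\n'
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="gt">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n"
    )
    vcf.write_text(header + vcf_body)
    meta = tmp_path / "meta.tsv"
    meta.write_text(
        META + "".join(
            f"{s}\t{g}\tmale\t0.9\tFalse\tno\tFalse\n" for s, g in zip(samples, groups)
        )
    )
    return vcf, meta


def test_single_biallelic_snp_gives_one_record(tmp_path):
    vcf, meta = write_inputs(tmp_path, "1\t100\t.\tA\tG\t50\tPASS\tQD=20\tGT\t0/1\t1/1\n")
    variants, subjects = read_cohort(vcf, meta)
    assert len(variants) == 1
    assert variants.loc[0, "S1"] == GT_HET and variants.loc[0, "S2"] == GT_HOM_ALT
    assert list(subjects["subject_id"]) == ["S1", "S2"]


def test_multiallelic_site_is_decomposed_with_dosage_conserved(tmp_path):
    vcf, meta = write_inputs(
        tmp_path, "1\t100\t.\tC\tA,T\t50\tPASS\tQD=20\tGT\t1/2\t2/2\n"
    )
    variants, _ = read_cohort(vcf, meta)
    assert len(variants) == 2
    assert list(variants["alt"]) == ["A", "T"]
    assert list(variants["pos"]) == [100, 100]
    # genotype of the non-focal alt maps to hom_ref for the focal record
    assert variants.loc[0, "S1"] == GT_HET and variants.loc[0, "S2"] == GT_HOM_REF
    assert variants.loc[1, "S1"] == GT_HET and variants.loc[1, "S2"] == GT_HOM_ALT
    # total alt dosage across decomposed records equals the original 1/2, 2/2 calls
    assert int(variants[["S1", "S2"]].to_numpy().sum()) == 4


def test_missing_genotype_lowers_call_rate(tmp_path):
    vcf, meta = write_inputs(tmp_path, "1\t100\t.\tA\tG\t50\tPASS\tQD=20\tGT\t./.\t0/1\n")
    variants, _ = read_cohort(vcf, meta)
    assert variants.loc[0, "S1"] == GT_MISSING
    assert variants.loc[0, "call_rate"] == pytest.approx(0.5)


def test_unknown_sample_is_a_hard_error(tmp_path):
    vcf, meta = write_inputs(tmp_path, "1\t100\t.\tA\tG\t50\tPASS\tQD=20\tGT\t0/1\t0/0\n")
    meta.write_text(META + "S1\tsi_nonpcd\tmale\t0.9\tFalse\tno\tFalse\n")
    with pytest.raises(ValueError, match="S2"):
        read_cohort(vcf, meta)


@pytest.mark.parametrize(
    "label, expected",
    [
        ("PASS", None),
        (".", None),
        ("VQSRTrancheSNP99.90to100.00", 99.9),
        ("VQSRTrancheINDEL99.00to99.90", 99.0),
    ],
)
def test_tranche_label_parsing(label, expected):
    assert tranche_lower_bound(label) == expected


def qc_frame(**overrides):
    row = {
        "chrom": "1", "pos": 100, "ref": "A", "alt": "G",
        "vqsr_label": "PASS", "quality_depth": 20.0, "call_rate": 1.0, "S1": 1,
    }
    row.update(overrides)
    return pd.DataFrame([row])


@pytest.mark.parametrize(
    "overrides, kept",
    [
        ({"vqsr_label": "VQSRTrancheSNP99.90to100.00"}, False),
        ({"vqsr_label": "VQSRTrancheSNP99.00to99.90"}, True),
        ({"quality_depth": 9.0}, False),
        ({"quality_depth": 9.5}, True),
        ({"call_rate": 0.8}, False),
        ({"call_rate": 0.81}, True),
        ({"quality_depth": np.nan}, True),  # kept with a warning, never a crash
    ],
)
def test_site_quality_filter_boundaries(overrides, kept):
    out = site_quality_filter(qc_frame(**overrides))
    assert (len(out) == 1) is kept


def test_site_filter_is_pure_subset_preserving_order():
    df = pd.concat(
        [qc_frame(pos=p, quality_depth=qd) for p, qd in
         [(1, 20), (2, 5), (3, 30), (4, 9), (5, 10)]],
        ignore_index=True,
    )
    out = site_quality_filter(df)
    assert list(out["pos"]) == [1, 3, 5]
    pd.testing.assert_frame_equal(out, df.loc[out.index])


class TestNormalize:
    def test_shared_suffix_prefix_trim(self):
        assert normalize_variant(100, "CT", "CA") == (101, "T", "A")

    def test_minimal_snp_unchanged(self):
        assert normalize_variant(100, "A", "G") == (100, "A", "G")

    def test_indel_keeps_anchor_base(self):
        assert normalize_variant(100, "ATT", "AT") == (100, "AT", "A")

    def test_ref_equal_alt_rejected(self):
        with pytest.raises(ValueError):
            normalize_variant(100, "A", "A")

    def test_inconsistent_reference_context_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            normalize_variant(100, "A", "G", reference_context=(100, "TTTT"))

    def test_homopolymer_deletion_left_aligned(self):
        # context G AAAA T starting at pos 10; a one-base A deletion placed
        # right-shifted must land on the canonical left-most representation
        ctx = (10, "GAAAAT")
        got = normalize_variant(13, "AA", "A", reference_context=ctx)
        # oracle: enumerate every placement of a 1-bp deletion in the window
        # and find all (pos, ref, alt) whose edited haplotype matches
        def apply(pos, ref, alt):
            off = pos - ctx[0]
            return ctx[1][:off] + alt + ctx[1][off + len(ref):]
        target = apply(13, "AA", "A")
        candidates = [
            (p, ctx[1][p - 10 : p - 10 + 2], ctx[1][p - 10])
            for p in range(10, 15)
            if apply(p, ctx[1][p - 10 : p - 10 + 2], ctx[1][p - 10]) == target
        ]
        assert got == min(candidates)

    @given(
        pos=st.integers(50, 60),
        core_ref=st.text(alphabet="ACGT", min_size=1, max_size=4),
        core_alt=st.text(alphabet="ACGT", min_size=1, max_size=4),
        pad=st.text(alphabet="ACGT", max_size=3),
    )
    @settings(max_examples=200, deadline=None)
    def test_idempotent_without_context(self, pos, core_ref, core_alt, pad):
        ref, alt = core_ref + pad, core_alt + pad
        if ref == alt:
            return
        once = normalize_variant(pos, ref, alt)
        assert normalize_variant(*once) == once

    def test_idempotent_with_context(self):
        ctx = (10, "GTAAAAAC")
        once = normalize_variant(14, "AA", "A", reference_context=ctx)
        assert normalize_variant(*once, reference_context=ctx) == once


def test_genotype_columns_excludes_core(tmp_path):
    vcf, meta = write_inputs(tmp_path, "1\t100\t.\tA\tG\t50\tPASS\tQD=20\tGT\t0/1\t0/0\n")
    variants, _ = read_cohort(vcf, meta)
    assert genotype_columns(variants) == ["S1", "S2"]
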