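import pandas as pd
import pytest

from situscan.inheritance import (
    GeneAssignment,
    PhaseEvidence,
    assign_dominant,
    assign_recessive,
    control_exclude,
    mirror_exclude,
    phase_exclude,
)

from conftest import make_subjects

SUBJECTS = make_subjects(
    [
        ("P1", "si_nonpcd", "male", 0.9, False),
        ("P2", "si_nonpcd", "female", -0.8, False),
        ("C1", "control", "female", 0.9, False),
    ]
)


def mut_table(rows):
    """rows: (chrom, pos, gene, {subject: gt_code}) with 0/1/2 codes."""
    out = []
    for chrom, pos, gene, gts in rows:
        row = {
            "chrom": chrom, "pos": pos, "ref": "A", "alt": "G", "gene": gene,
            "clinvar": "", "P1": 0, "P2": 0, "C1": 0,
        }
        row.update(gts)
        out.append(row)
    return pd.DataFrame(out)


class TestRecessiveAssignment:
    def test_homozygous_variant_assigns_gene(self):
        table = mut_table([("7", 100, "PKD1L1", {"P1": 2})])
        (a,) = assign_recessive(table, SUBJECTS)
        assert (a.subject_id, a.gene, a.mechanism) == ("P1", "PKD1L1", "hom")

    def test_two_distinct_hets_form_compound_het(self):
        table = mut_table(
            [("5", 100, "DNAH5", {"P2": 1}), ("5", 200, "DNAH5", {"P2": 1})]
        )
        (a,) = assign_recessive(table, SUBJECTS)
        assert a.mechanism == "chet" and len(a.variants) == 2
        assert a.phase_status == "unknown"

    def test_single_autosomal_het_yields_nothing(self):
        table = mut_table([("5", 100, "DNAH5", {"P1": 1})])
        assert assign_recessive(table, SUBJECTS) == []

    def test_male_single_x_het_is_hemizygous(self):
        table = mut_table([("X", 100, "ZIC3", {"P1": 1})])
        (a,) = assign_recessive(table, SUBJECTS)
        assert (a.subject_id, a.mechanism) == ("P1", "hemizygous_x")

    def test_female_needs_two_x_mutations(self):
        one = mut_table([("X", 100, "ZIC3", {"P2": 1})])
        assert assign_recessive(one, SUBJECTS) == []
        two = mut_table(
            [("X", 100, "ZIC3", {"P2": 1}), ("X", 200, "ZIC3", {"P2": 1})]
        )
        (a,) = assign_recessive(two, SUBJECTS)
        assert (a.subject_id, a.mechanism) == ("P2", "chet")

    def test_unknown_sex_with_x_mutation_is_an_error(self):
        subjects = SUBJECTS.copy()
        subjects.loc[subjects["subject_id"] == "P1", "sex"] = "unknown"
        table = mut_table([("X", 100, "ZIC3", {"P1": 1})])
        with pytest.raises(ValueError, match="sex"):
            assign_recessive(table, subjects)

    def test_invariant_to_variant_order(self):
        rows = [
            ("5", 300, "DNAH5", {"P2": 1}),
            ("5", 100, "DNAH5", {"P2": 1}),
            ("7", 50, "PKD1L1", {"P1": 2}),
        ]
        fwd = assign_recessive(mut_table(rows), SUBJECTS)
        rev = assign_recessive(mut_table(rows[::-1]), SUBJECTS)
        assert fwd == rev


class TestDominantAssignment:
    def test_single_rare_het_assigns_gene(self):
        table = mut_table([("8", 100, "LRRC6", {"P1": 1})])
        (a,) = assign_dominant(table, SUBJECTS)
        assert (a.subject_id, a.gene, a.mechanism) == ("P1", "LRRC6", "dominant_het")

    def test_no_qualifying_variant_no_assignment(self):
        table = mut_table([("8", 100, "LRRC6", {})])
        assert assign_dominant(table, SUBJECTS) == []


def chet(sid="P2", gene="DNAH5", keys=("5:100:A:G", "5:200:A:G")):
    return GeneAssignment(sid, gene, "chet", tuple(keys), "unknown")


class TestPhaseExclusion:
    def test_definite_cis_pair_dropped(self):
        ev = [PhaseEvidence("P2", "5:100:A:G", "5:200:A:G", 3, 0)]
        retained, excluded = phase_exclude([chet()], ev)
        assert retained == []
        assert excluded[0].phase_status == "cis_excluded"

    def test_no_spanning_fragments_retained_as_unknown(self):
        ev = [PhaseEvidence("P2", "5:100:A:G", "5:200:A:G", 0, 0)]
        retained, excluded = phase_exclude([chet()], ev)
        assert excluded == [] and retained[0].phase_status == "unknown"

    def test_any_trans_read_rescues_the_pair(self):
        ev = [PhaseEvidence("P2", "5:100:A:G", "5:200:A:G", 5, 1)]
        retained, excluded = phase_exclude([chet()], ev)
        assert excluded == [] and len(retained) == 1

    def test_hom_assignment_passes_untouched(self):
        hom = GeneAssignment("P1", "PKD1L1", "hom", ("7:100:A:G",))
        ev = [PhaseEvidence("P1", "7:100:A:G", "5:200:A:G", 9, 0)]
        retained, excluded = phase_exclude([hom], ev)
        assert retained == [hom] and excluded == []

    def test_evidence_for_unknown_keys_is_ignored(self):
        ev = [PhaseEvidence("P2", "9:1:A:G", "9:2:A:G", 3, 0)]
        retained, excluded = phase_exclude([chet()], ev)
        assert len(retained) == 1 and excluded == []

    def test_min_cis_reads_threshold(self):
        ev = [PhaseEvidence("P2", "5:100:A:G", "5:200:A:G", 1, 0)]
        assert phase_exclude([chet()], ev, min_cis_reads=2)[1] == []
        assert len(phase_exclude([chet()], ev, min_cis_reads=1)[1]) == 1


class TestControlExclusion:
    def test_gene_in_control_removed_from_cases(self):
        case = [chet("P1", "G1"), chet("P1", "G2")]
        ctrl = [chet("C1", "G1")]
        kept, excluded = control_exclude(case, ctrl)
        assert [a.gene for a in kept] == ["G2"]
        assert excluded == ["G1"]

    def test_case_only_gene_retained_and_empty_controls_are_identity(self):
        case = [chet("P1", "G1")]
        kept, excluded = control_exclude(case, [])
        assert kept == case and excluded == []

    def test_mirror_exclusion_yields_disjoint_gene_lists(self):
        case = [chet("P1", "G1"), chet("P1", "G2")]
        ctrl = [chet("C1", "G1"), chet("C1", "G3")]
        kept_case, _ = control_exclude(case, ctrl)
        kept_ctrl, _ = mirror_exclude(ctrl, kept_case)
        assert {a.gene for a in kept_case} & {a.gene for a in kept_ctrl} == set()
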