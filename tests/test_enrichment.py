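import itertools
from math import comb

import numpy as np
import pytest

from situscan.enrichment import (
    EnrichmentResult,
    GeneSetSchema,
    adjust_pvalues,
    control_mirror_gsea,
    empirical_min_p_null,
    hypergeom_enrich,
    prune_hierarchy,
    read_gmt,
    restrict_query,
)


def schema_of(sets, background=None):
    members = set().union(*[frozenset(m) for _, m in sets.values()]) if sets else set()
    bg = frozenset(background) if background is not None else frozenset(members)
    return GeneSetSchema({k: (n, frozenset(m)) for k, (n, m) in sets.items()}, bg)


def genes(n, prefix="g"):
    return [f"{prefix}{i:03d}" for i in range(n)]


def enumeration_p(background, term, query_size, min_overlap):
    """Exact P(overlap >= min_overlap) by enumerating all draws of query_size."""
    hits = sum(
        1
        for draw in itertools.combinations(sorted(background), query_size)
        if len(set(draw) & set(term)) >= min_overlap
    )
    return hits / comb(len(background), query_size)


class TestHypergeomEnrich:
    def test_worked_example_5_of_4845(self):
        bg = genes(20)
        term = bg[:5]
        schema = schema_of({"s1": ("term", term)}, background=bg)
        (res,) = hypergeom_enrich(bg[:4], schema, min_set=1, max_set=500, min_intersect=2)
        # all C(20,4)=4845 draws; exactly 5 contain 4 of the 5 term members
        assert res.overlap == 4
        assert res.p_raw == pytest.approx(5 / 4845, rel=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_agrees_with_enumeration_on_random_small_schemas(self, seed):
        rng = np.random.default_rng(seed)
        bg = genes(int(rng.integers(12, 21)))
        term = list(rng.choice(bg, size=int(rng.integers(3, 8)), replace=False))
        q = list(rng.choice(bg, size=4, replace=False))
        schema = schema_of({"s1": ("t", term)}, background=bg)
        results = hypergeom_enrich(q, schema, min_set=1, max_set=500, min_intersect=1)
        if not results:
            return
        (res,) = results
        expect = enumeration_p(bg, term, len(q), res.overlap)
        assert res.p_raw == pytest.approx(expect, rel=1e-10)

    def test_size_and_intersect_bounds(self):
        bg = genes(40)
        schema = schema_of(
            {"small": ("s", bg[:14]), "ok": ("o", bg[:20]), "thin": ("t", bg[25:40])},
            background=bg,
        )
        res = hypergeom_enrich(bg[:3], schema, min_set=15, max_set=500, min_intersect=2)
        ids = {r.set_id for r in res}
        assert "small" not in ids       # term_size 14 < 15
        assert "ok" in ids              # overlap 3
        assert "thin" not in ids        # overlap 0 < 2

    def test_query_outside_background_is_an_error(self):
        schema = schema_of({"s1": ("t", genes(16))})
        with pytest.raises(ValueError, match="restrict_query"):
            hypergeom_enrich(["nope"], schema)

    def test_p_monotone_in_overlap(self):
        bg = genes(100)
        schema = schema_of({"s1": ("t", bg[:30])}, background=bg)
        ps = []
        for k in range(2, 11):
            q = bg[:k] + bg[50 : 50 + (10 - k)]  # query size 10, overlap k
            (r,) = hypergeom_enrich(q, schema, min_set=1, max_set=500, min_intersect=2)
            assert r.overlap == k
            ps.append(r.p_raw)
        assert all(b <= a for a, b in zip(ps, ps[1:]))


class TestRestrictQuery:
    def test_restricts_and_deduplicates(self):
        schema = schema_of({"s1": ("t", genes(16))})
        q = genes(16)[:5] + ["zzz", "zzz"] + genes(16)[:2]
        assert restrict_query(q, schema) == sorted(set(genes(16)[:5]))

    def test_identity_when_all_in_background(self):
        schema = schema_of({"s1": ("t", genes(16))})
        assert restrict_query(genes(16), schema) == genes(16)

    def test_empty(self):
        schema = schema_of({"s1": ("t", genes(16))})
        assert restrict_query([], schema) == []


def result(p, sid="s1", qsize=5):
    return EnrichmentResult(sid, sid, 20, qsize, 3, (), p)


class TestCorrections:
    def test_bonferroni_closed_form(self):
        res = [result(0.001, "a"), result(0.02, "b"), result(0.5, "c")]
        out = adjust_pvalues(res, "bonferroni")
        assert [r.p_adj for r in out] == pytest.approx([0.003, 0.06, 1.0])

    def test_single_set_bonferroni_is_identity(self):
        (out,) = adjust_pvalues([result(0.01)], "bonferroni")
        assert out.p_adj == pytest.approx(0.01)

    def test_bh_never_below_raw_and_bounded(self):
        res = [result(p, str(i)) for i, p in enumerate([0.001, 0.01, 0.04, 0.9])]
        out = adjust_pvalues(res, "bh")
        for r in out:
            assert r.p_raw <= r.p_adj <= 1.0

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown correction"):
            adjust_pvalues([result(0.1)], "gscs")

    def test_empirical_sets_matches_enumerated_family_null(self):
        # tiny schema: background 10, one eligible set of 4; the family-wise
        # null of the min p is enumerable over all C(10,3) queries
        bg = genes(10)
        term = bg[:4]
        schema = schema_of({"s1": ("t", term)}, background=bg)
        q = bg[:3]  # overlap 3
        (res,) = hypergeom_enrich(q, schema, min_set=1, max_set=10, min_intersect=2)
        # enumerate exactly: P(min-p <= p_obs) = P(overlap >= 3) since the
        # only p values as small as the observed one come from overlap >= 3
        p_min_le = sum(
            1
            for draw in itertools.combinations(bg, 3)
            if len(set(draw) & set(term)) >= 3
        ) / comb(10, 3)
        rng = np.random.default_rng(11)
        (out,) = adjust_pvalues(
            [res], "empirical_sets", schema=schema, n_perm=4000, rng=rng,
            min_set=1, max_set=10, min_intersect=2,
        )
        se = np.sqrt(p_min_le * (1 - p_min_le) / 4000)
        assert abs(out.p_adj - p_min_le) < 4 * se + 1e-3

    def test_empirical_requires_schema_and_rng(self):
        with pytest.raises(ValueError):
            adjust_pvalues([result(0.1)], "empirical_sets")


class TestControlMirror:
    def make_planted_schema(self):
        bg = genes(60)
        planted = bg[:15]
        other = bg[15:45]
        return schema_of({"cilia": ("c", planted), "other": ("o", other)}, background=bg), bg

    def test_planted_set_significant_and_lost_on_causal_removal(self):
        schema, bg = self.make_planted_schema()
        causal = bg[:8]  # eight planted genes inside the 15-member set
        noise = bg[45:50]
        out = control_mirror_gsea(
            {"pcd": causal + noise}, bg[52:58], schema,
            min_set=10, max_set=500, min_intersect=2,
        )
        res, n_raw, n_in = out["pcd"]
        sig = [r for r in res if r.p_adj is not None and r.p_adj < 0.01]
        assert any(r.set_id == "cilia" for r in sig)
        # removing the causal genes destroys the signal
        out2 = control_mirror_gsea(
            {"pcd": noise}, bg[52:58], schema, min_set=10, max_set=500, min_intersect=2
        )
        res2, *_ = out2["pcd"]
        assert not [r for r in res2 if r.p_adj is not None and r.p_adj < 0.01]

    def test_mirrored_control_list_excludes_case_genes(self):
        schema, bg = self.make_planted_schema()
        out = control_mirror_gsea(
            {"cases": bg[:10]}, bg[:12], schema, min_set=10, max_set=500, min_intersect=2
        )
        _, n_raw, n_in = out["controls"]
        assert n_raw == 2  # only the two non-case genes remain


class TestHierarchyPruning:
    def test_child_less_significant_than_parent_is_pruned(self):
        parent = EnrichmentResult("p", "p", 20, 5, 4, (), 1e-5)
        child = EnrichmentResult("c", "c", 18, 5, 3, (), 1e-3)
        unrelated = EnrichmentResult("u", "u", 30, 5, 3, (), 0.5)
        kept = prune_hierarchy([parent, child, unrelated], [("c", "p")])
        assert [r.set_id for r in kept] == ["p", "u"]


def test_gmt_round_trip(tmp_path):
    p = tmp_path / "s.gmt"
    p.write_text("s1\tdesc one\ta\tb\tc\ns2\tdesc two\tb\td\n")
    schema = read_gmt(p)
    assert schema.n_sets == 2
    assert schema.background == frozenset("abcd")


def test_gmt_malformed_line_rejected(tmp_path):
    bad = tmp_path / "bad.gmt"
    bad.write_text("x\ty\n")
    with pytest.raises(ValueError, match="GMT"):
        read_gmt(bad)
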