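"""Gene-set over-representation analysis of mutated gene lists.

Hypergeometric upper-tail test of each GO-style gene set against a query
list of mutated genes, with the study's set-size and intersection bounds
(min set 15, max set 500, min intersect 2) and a multiple-testing
correction applied separately per query list.  Supported corrections:
Bonferroni, Benjamini–Hochberg, and an empirical min-p set-resampling
correction that estimates the family-wise null by drawing random same-size
queries from the background (an explicit approximation of hierarchical
set-aware corrections; adjusted values from such proprietary methods are
not expected to be matched numerically).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

MIN_SET_SIZE = 15
MAX_SET_SIZE = 500
MIN_INTERSECT = 2
SIGNIFICANCE_CUTOFF = 0.01

CORRECTION_METHODS = ("bonferroni", "bh", "empirical_sets")


@dataclass(frozen=True)
class GeneSetSchema:
    """A gene-set collection; the background is the union of annotated genes."""

    sets: dict  # set_id -> (name, frozenset of member symbols)
    background: frozenset

    def __post_init__(self):
        for sid, (_, members) in self.sets.items():
            extra = members - self.background
            if extra:
                raise ValueError(f"set {sid} has members outside the background: {sorted(extra)[:5]}")

    @property
    def n_sets(self) -> int:
        return len(self.sets)

    @property
    def n_background(self) -> int:
        return len(self.background)


def read_gmt(path: str | Path) -> GeneSetSchema:
    """Read a GMT file (set_id <tab> description <tab> members...).

    The background is the union of all set members — the 'genes with
    functional annotations' convention.
    """
    sets = {}
    background: set[str] = set()
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{ln}: GMT line needs id, description and >=1 member")
        sid, name, members = parts[0], parts[1], frozenset(parts[2:])
        sets[sid] = (name, members)
        background |= members
    return GeneSetSchema(sets, frozenset(background))


def restrict_query(genes, schema: GeneSetSchema) -> list[str]:
    """Deduplicated query ∩ background, with both sizes logged.

    Many mutated genes fall outside the annotation schema, so the usable
    query is always smaller than the raw mutated-gene list.
    """
    uniq = sorted(set(genes))
    kept = [g for g in uniq if g in schema.background]
    log.info("query restricted to schema: %d genes, of which %d in the schema",
             len(uniq), len(kept))
    return kept


@dataclass(frozen=True)
class EnrichmentResult:
    set_id: str
    term_name: str
    term_size: int
    query_size: int
    overlap: int
    intersect_genes: tuple[str, ...]
    p_raw: float
    p_adj: float | None = None


def hypergeom_enrich(
    query: list[str],
    schema: GeneSetSchema,
    min_set: int = MIN_SET_SIZE,
    max_set: int = MAX_SET_SIZE,
    min_intersect: int = MIN_INTERSECT,
) -> list[EnrichmentResult]:
    """Hypergeometric upper-tail test per gene set.

    For each set with min_set <= term_size <= max_set and overlap >=
    min_intersect, p_raw = P(X >= overlap) with population |background|,
    successes term_size, draws |query|.  Every query gene must be in the
    background (run :func:`restrict_query` first).
    """
    qset = set(query)
    outside = qset - schema.background
    if outside:
        raise ValueError(
            f"query genes absent from background (restrict_query first): {sorted(outside)[:5]}"
        )
    M, N = schema.n_background, len(qset)
    out = []
    for sid in sorted(schema.sets):
        name, members = schema.sets[sid]
        n = len(members)
        if not (min_set <= n <= max_set):
            continue
        inter = sorted(qset & members)
        k = len(inter)
        if k < min_intersect:
            continue
        p_raw = float(hypergeom.sf(k - 1, M, n, N))
        out.append(EnrichmentResult(sid, name, n, N, k, tuple(inter), min(p_raw, 1.0)))
    return out


def _eligible_sets(schema, min_set, max_set):
    return [
        (sid, members)
        for sid, (_, members) in sorted(schema.sets.items())
        if min_set <= len(members) <= max_set
    ]


def empirical_min_p_null(
    schema: GeneSetSchema,
    query_size: int,
    n_perm: int,
    rng: np.random.Generator,
    min_set: int = MIN_SET_SIZE,
    max_set: int = MAX_SET_SIZE,
    min_intersect: int = MIN_INTERSECT,
) -> np.ndarray:
    """Null distribution of the minimum raw p over the tested sets.

    Each permutation draws a random query of the observed size from the
    background and records the smallest hypergeometric p among sets passing
    the size bounds (1.0 when no set reaches min_intersect).
    """
    bg = np.array(sorted(schema.background))
    eligible = _eligible_sets(schema, min_set, max_set)
    member_sets = [members for _, members in eligible]
    M = schema.n_background
    mins = np.ones(n_perm)
    for b in range(n_perm):
        draw = set(bg[rng.choice(M, size=query_size, replace=False)])
        best = 1.0
        for members in member_sets:
            k = len(draw & members)
            if k >= min_intersect:
                p = float(hypergeom.sf(k - 1, M, len(members), query_size))
                if p < best:
                    best = p
        mins[b] = best
    return mins


def adjust_pvalues(
    results: list[EnrichmentResult],
    method: str = "bonferroni",
    schema: GeneSetSchema | None = None,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
    min_set: int = MIN_SET_SIZE,
    max_set: int = MAX_SET_SIZE,
    min_intersect: int = MIN_INTERSECT,
) -> list[EnrichmentResult]:
    """Multiple-testing correction over the tested sets of one query list.

    ``bonferroni`` multiplies by the number of sets passing the size
    bounds; ``bh`` is Benjamini–Hochberg over the reported results;
    ``empirical_sets`` converts each raw p to the probability that a random
    same-size query attains a smaller family-wise minimum p.
    """
    if method not in CORRECTION_METHODS:
        raise ValueError(f"unknown correction method {method!r}")
    if not results:
        return []
    p_raw = np.array([r.p_raw for r in results])
    if method == "bonferroni":
        # family = all size-eligible sets, not only those reaching min_intersect
        if schema is not None:
            m = len(_eligible_sets(schema, min_set, max_set))
        else:
            m = len(results)
        p_adj = np.minimum(p_raw * max(m, 1), 1.0)
    elif method == "bh":
        p_adj = multipletests(p_raw, method="fdr_bh")[1]
    else:
        if schema is None:
            raise ValueError("empirical_sets correction requires the schema")
        if rng is None:
            raise ValueError("empirical_sets correction requires a seeded rng")
        null_min = empirical_min_p_null(
            schema, results[0].query_size, n_perm, rng, min_set, max_set, min_intersect
        )
        # plus-one Monte-Carlo estimator of P(min-p under null <= p_raw)
        p_adj = np.array([(1 + (null_min <= p).sum()) / (n_perm + 1) for p in p_raw])
        p_adj = np.maximum(p_adj, p_raw)
    from dataclasses import replace

    return [replace(r, p_adj=float(min(max(a, r.p_raw), 1.0)))
            for r, a in zip(results, p_adj)]


def enrich_gene_list(
    genes,
    schema: GeneSetSchema,
    method: str = "bonferroni",
    rng: np.random.Generator | None = None,
    n_perm: int = 1000,
    min_set: int = MIN_SET_SIZE,
    max_set: int = MAX_SET_SIZE,
    min_intersect: int = MIN_INTERSECT,
) -> tuple[list[EnrichmentResult], int, int]:
    """restrict → test → correct for one gene list.

    Returns (results, n_genes_raw, n_genes_in_schema).
    """
    uniq = sorted(set(genes))
    query = restrict_query(uniq, schema)
    results = hypergeom_enrich(query, schema, min_set, max_set, min_intersect)
    results = adjust_pvalues(
        results, method, schema=schema, n_perm=n_perm, rng=rng,
        min_set=min_set, max_set=max_set, min_intersect=min_intersect,
    )
    return results, len(uniq), len(query)


def control_mirror_gsea(
    case_gene_lists: dict,
    control_genes,
    schema: GeneSetSchema,
    method: str = "bonferroni",
    rng: np.random.Generator | None = None,
    n_perm: int = 1000,
    **bounds,
) -> dict:
    """Enrichment per subject-group list plus the mirror-excluded control list.

    Genes mutated in any case list are removed from the control list before
    testing it ('mirrored exclusion'); correction runs separately per list.
    Returns {list_name: (results, n_raw, n_in_schema)}.
    """
    all_case_genes = set().union(*[set(g) for g in case_gene_lists.values()]) \
        if case_gene_lists else set()
    out = {}
    for name, genes in case_gene_lists.items():
        out[name] = enrich_gene_list(genes, schema, method, rng=rng, n_perm=n_perm, **bounds)
    mirrored = sorted(set(control_genes) - all_case_genes)
    out["controls"] = enrich_gene_list(mirrored, schema, method, rng=rng, n_perm=n_perm, **bounds)
    return out


def read_ontology_edges(path: str | Path) -> list[tuple[str, str]]:
    """Read (child, parent) set-id edges from a two-column TSV."""
    df = pd.read_csv(path, sep="\t", header=None, names=["child", "parent"], dtype=str)
    return list(df.itertuples(index=False, name=None))


def prune_hierarchy(
    results: list[EnrichmentResult], edges: list[tuple[str, str]]
) -> list[EnrichmentResult]:
    """Redundancy pruning over parent–child related sets (off by default).

    Among directly related tested sets, only the most significant is kept
    (ties broken by set id) — a simple stand-in for moderate hierarchical
    filtering of nested ontology terms.
    """
    by_id = {r.set_id: r for r in results}
    neighbours: dict[str, set[str]] = {sid: set() for sid in by_id}
    for child, parent in edges:
        if child in by_id and parent in by_id:
            neighbours[child].add(parent)
            neighbours[parent].add(child)
    kept = []
    for r in results:
        beaten = any(
            (by_id[o].p_raw, by_id[o].set_id) < (r.p_raw, r.set_id)
            for o in neighbours[r.set_id]
        )
        if not beaten:
            kept.append(r)
    return kept


def results_frame(results_by_group: dict) -> pd.DataFrame:
    """Flat report table: one row per (group, tested set)."""
    rows = []
    for group, (results, n_raw, n_in) in results_by_group.items():
        for r in results:
            rows.append(
                {
                    "group": group,
                    "p_adj": r.p_adj,
                    "term_size": r.term_size,
                    "query_size": r.query_size,
                    "overlap_size": r.overlap,
                    "term_id": r.set_id,
                    "term_name": r.term_name,
                    "intersection": ", ".join(r.intersect_genes),
                    "p_raw": r.p_raw,
                    "genes_raw": n_raw,
                    "genes_in_schema": n_in,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "group", "p_adj", "term_size", "query_size", "overlap_size",
            "term_id", "term_name", "intersection", "p_raw",
            "genes_raw", "genes_in_schema",
        ],
    )
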