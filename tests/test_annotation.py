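"""State assignment, Fisher exact test, enrichment and nearest-gene mapping."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dogclock.annotation import (
    UNANNOTATED,
    assign_state,
    clock_gene_overlap,
    fisher_exact_2x2,
    nearest_gene,
    state_enrichment,
)
from dogclock.simulate import simulate_direction_state_labels


def _states(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "state"])


def _features(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def test_assign_state_containment():
    states = _states([("chr1", 0, 1000, "3"), ("chr1", 1000, 2000, "7")])
    feats = _features([("chr1", 100, 300, "a")])
    assert assign_state(feats, states)["a"] == "3"


def test_assign_state_maximal_overlap():
    states = _states([("chr1", 0, 500, "A"), ("chr1", 500, 1500, "B")])
    feats = _features([("chr1", 200, 700, "a")])   # 300 bp in A, 200 bp in B
    assert assign_state(feats, states)["a"] == "A"


def test_assign_state_midpoint_mode():
    states = _states([("chr1", 0, 500, "A"), ("chr1", 500, 1500, "B")])
    feats = _features([("chr1", 200, 900, "a")])   # midpoint 550 in B; overlap max in B too
    assert assign_state(feats, states, mode="midpoint")["a"] == "B"


def test_assign_state_unmapped_contig():
    states = _states([("chr1", 0, 1000, "1")])
    feats = _features([("chrX", 0, 100, "a")])
    assert assign_state(feats, states)["a"] == UNANNOTATED


def test_assign_state_rejects_overlapping_intervals():
    states = _states([("chr1", 0, 1000, "1"), ("chr1", 500, 1500, "2")])
    with pytest.raises(ValueError, match="overlap"):
        assign_state(_features([("chr1", 0, 10, "a")]), states)


def test_assign_state_matches_per_base_oracle():
    rng = np.random.default_rng(0)
    # random non-overlapping segmentation of [0, 5000)
    cuts = np.sort(rng.choice(np.arange(100, 5000, 100), size=12, replace=False))
    bounds = np.concatenate([[0], cuts, [5000]])
    labels = [str(rng.integers(1, 14)) for _ in range(len(bounds) - 1)]
    states = _states([("chr1", int(a), int(b), s) for a, b, s in zip(bounds[:-1], bounds[1:], labels)])
    base_label = np.empty(5000, dtype=object)
    for _, row in states.iterrows():
        base_label[row.start:row.end] = row.state
    feats = []
    for i in range(50):
        start = int(rng.integers(0, 4800))
        end = start + int(rng.integers(1, 200))
        feats.append(("chr1", start, min(end, 5000), f"f{i}"))
    assigned = assign_state(_features(feats), states)
    for chrom, start, end, name in feats:
        counts = pd.Series(base_label[start:end]).value_counts()
        best = counts.max()
        best_states = set(counts[counts == best].index)
        assert assigned[name] in best_states


@pytest.mark.parametrize(
    "table,expected_p",
    [
        ([[5, 5], [5, 5]], 1.0),
        # frozen from exact Fraction-arithmetic enumeration over all tables
        # with the observed margins (13 tables); scipy agrees
        ([[1, 9], [11, 3]], 0.0027594561852200836),
    ],
)
def test_fisher_known_p(table, expected_p):
    odds, p = fisher_exact_2x2(table)
    assert p == pytest.approx(expected_p, rel=1e-6)
    if table == [[5, 5], [5, 5]]:
        assert odds == pytest.approx(1.0)


def test_fisher_extreme_diagonal_table():
    # the observed table and its mirror are the only ones as extreme
    odds, p = fisher_exact_2x2([[0, 10], [10, 0]])
    from math import comb
    expected = 2 * comb(10, 0) * comb(10, 10) / comb(20, 10)
    assert p == pytest.approx(expected, rel=1e-10)


def test_fisher_zero_margin():
    odds, p = fisher_exact_2x2([[0, 0], [5, 7]])
    assert p == 1.0
    assert np.isnan(odds)


def test_fisher_continuity_correction_on_zero_cell():
    odds, _ = fisher_exact_2x2([[0, 10], [10, 10]])
    assert odds == pytest.approx((0.5 * 10.5) / (10.5 * 10.5))


def test_fisher_matches_scipy_on_random_tables():
    rng = np.random.default_rng(1)
    for _ in range(200):
        t = rng.integers(0, 25, size=(2, 2))
        _, p = fisher_exact_2x2(t)
        ref = stats.fisher_exact(t).pvalue
        assert p == pytest.approx(ref, rel=1e-7, abs=1e-12)


def test_fisher_rejects_negative_entries():
    with pytest.raises(ValueError):
        fisher_exact_2x2([[1, -2], [3, 4]])


def test_state_enrichment_recovers_planted_bias():
    directions, states = simulate_direction_state_labels(
        2000, biased_state="4", enrichment=5.0, seed=3
    )
    table = state_enrichment(directions, states).set_index("state")
    row = table.loc["4"]
    assert row["q"] < 0.05
    assert row["odds_ratio"] < 1  # enriched among decreasing -> OR below 1 for increasing


def test_state_enrichment_margin_consistency():
    directions, states = simulate_direction_state_labels(500, seed=4)
    table = state_enrichment(directions, states)
    totals = table[["a", "b", "c", "d"]].sum(axis=1)
    assert (totals == len(directions)).all()


def test_state_enrichment_refuses_single_direction():
    idx = pd.Index([f"p{i}" for i in range(10)])
    directions = pd.Series(["increasing"] * 10, index=idx)
    states = pd.Series(["1"] * 10, index=idx)
    with pytest.raises(ValueError, match="per direction"):
        state_enrichment(directions, states)


def _genes(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])


def test_nearest_gene_containment_distance_zero():
    genes = _genes([("chr1", 100, 2000, "geneA", 0, "+")])
    feats = _features([("chr1", 500, 600, "f")])
    out = nearest_gene(feats, genes)
    assert out.loc["f", "gene"] == "geneA"
    assert out.loc["f", "distance"] == 0


def test_nearest_gene_tie_breaks_to_smaller_start_then_name():
    genes = _genes(
        [("chr1", 0, 1000, "geneB", 0, "+"), ("chr1", 3000, 4000, "geneA", 0, "-")]
    )
    feats = _features([("chr1", 1995, 2010, "f")])  # 995 bp from overhang... adjust below
    # distances: to geneB = 1995-1000 = 995; to geneA = 3000-2010 = 990 -> geneA wins
    out = nearest_gene(feats, genes)
    assert out.loc["f", "gene"] == "geneA"
    # exact tie: place feature symmetric
    feats2 = _features([("chr1", 1990, 2010, "g")])  # 990 both sides
    out2 = nearest_gene(feats2, genes)
    assert out2.loc["g", "gene"] == "geneB"  # smaller start wins the tie
    # same start tie -> lexicographic name
    genes3 = _genes(
        [("chr1", 3000, 4000, "geneZ", 0, "+"), ("chr1", 3000, 4000, "geneC", 0, "-")]
    )
    out3 = nearest_gene(_features([("chr1", 0, 10, "h")]), genes3)
    assert out3.loc["h", "gene"] == "geneC"


def test_nearest_gene_empty_set_errors():
    with pytest.raises(ValueError, match="empty"):
        nearest_gene(_features([("chr1", 0, 10, "f")]), _genes([]))


def test_nearest_gene_matches_brute_force():
    rng = np.random.default_rng(2)
    genes = _genes(
        [
            ("chr1", int(s), int(s + rng.integers(500, 3000)), f"g{i:02d}", 0, "+")
            for i, s in enumerate(rng.integers(0, 50_000, size=20))
        ]
    )
    feats = _features(
        [
            ("chr1", int(s), int(s + rng.integers(50, 400)), f"f{i:02d}")
            for i, s in enumerate(rng.integers(0, 50_000, size=50))
        ]
    )
    out = nearest_gene(feats, genes)
    for _, f in feats.iterrows():
        dists = {}
        for _, g in genes.iterrows():
            gap = max(g.start - f.end, f.start - g.end, 0)
            dists[g["name"]] = gap
        best = min(dists.values())
        candidates = {n for n, d in dists.items() if d == best}
        assert out.loc[f["name"], "gene"] in candidates
        assert out.loc[f["name"], "distance"] == best


def test_clock_gene_overlap_set_algebra():
    gene_map = pd.Series(
        {f"f{i}": f"g{i % 5}" for i in range(10)}, name="gene"
    )
    selected = {
        "atac": {"f0", "f1", "f2"},        # genes g0 g1 g2
        "dnam": {"f1", "f2", "f3"},        # genes g1 g2 g3
        "combined": {"f2", "f4"},          # genes g2 g4
    }
    out = clock_gene_overlap(selected, gene_map)
    assert out["intersection"] == ["g2"]
    assert out["n_intersection"] == 1
    assert out["venn_counts"]["atac&dnam&combined"] == 1
    assert out["venn_counts"]["atac&dnam"] == 1      # g1 (excluding g2)
    assert out["venn_counts"]["atac"] == 1           # g0 only
    assert out["venn_counts"]["combined"] == 1       # g4 only


def test_clock_gene_overlap_identical_and_disjoint():
    gene_map = pd.Series({"a": "g1", "b": "g2", "c": "g3", "d": "g4"})
    same = {k: {"a", "b"} for k in ("x", "y", "z")}
    out = clock_gene_overlap(same, gene_map)
    assert sorted(out["intersection"]) == ["g1", "g2"]
    disjoint = {"x": {"a"}, "y": {"b"}, "z": {"c"}}
    assert clock_gene_overlap(disjoint, gene_map)["n_intersection"] == 0
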