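import itertools

import numpy as np
import pandas as pd
import pytest

from fruitstrat.errors import FormatError, FruitstratError
from fruitstrat.orthology import (
    CATEGORY_CM_MISSING,
    CATEGORY_CM_NONDEV,
    CATEGORY_NONCONSERVED,
    CATEGORY_SHARED,
    RBHGroup,
    build_rbh_groups,
    classify_conserved,
    coverage_filter,
    filter_spurious_members,
    mcl_cluster,
    og_origin_enrichment,
    split_shared_cm,
    upstream_identity,
)
from fruitstrat.phylostrat import age_enrichment


# ---------------------------------------------------------------------------
# coverage filter
# ---------------------------------------------------------------------------

def _hit(qlen, slen, alnlen, **kw):
    row = {"query": "q", "target": "t", "pident": 90.0, "alnlen": alnlen,
           "mismatch": 1, "gapopen": 0, "qstart": 1, "qend": alnlen,
           "sstart": 1, "send": alnlen, "evalue": 1e-30, "bitscore": 100.0,
           "nident": alnlen, "qlen": qlen, "slen": slen}
    row.update(kw)
    return row


def test_coverage_kept_fragment():
    # shorter covered 90%, longer 25% -> kept by the asymmetric rule
    hits = pd.DataFrame([_hit(qlen=400, slen=100, alnlen=90)])
    assert len(coverage_filter(hits)) == 1


def test_coverage_dropped_short():
    hits = pd.DataFrame([_hit(qlen=400, slen=100, alnlen=70)])  # shorter 0.7 < 0.8
    assert len(coverage_filter(hits)) == 0


def test_coverage_equal_lengths_full():
    hits = pd.DataFrame([_hit(qlen=100, slen=100, alnlen=100)])
    assert len(coverage_filter(hits)) == 1


def test_coverage_long_cutoff():
    hits = pd.DataFrame([_hit(qlen=1000, slen=100, alnlen=100)])  # longer 0.1 < 0.2
    assert len(coverage_filter(hits)) == 0


def test_coverage_zero_length_errors():
    hits = pd.DataFrame([_hit(qlen=0, slen=100, alnlen=10)])
    with pytest.raises(FormatError):
        coverage_filter(hits)


# ---------------------------------------------------------------------------
# Markov clustering
# ---------------------------------------------------------------------------

def _clique_edges(nodes, w=1.0):
    return [(a, b, w) for a, b in itertools.combinations(nodes, 2)]


def test_mcl_disjoint_triangles():
    t1, t2 = ["a1", "a2", "a3"], ["b1", "b2", "b3"]
    clusters = mcl_cluster(t1 + t2, _clique_edges(t1) + _clique_edges(t2))
    assert sorted(map(set, clusters), key=min) == [set(t1), set(t2)]


def test_mcl_single_edge():
    clusters = mcl_cluster(["a", "b"], [("a", "b", 1.0)])
    assert clusters == [frozenset({"a", "b"})]


def test_mcl_partition_covers_all(rng):
    nodes = [f"v{i}" for i in range(20)]
    edges = [
        (nodes[i], nodes[j], float(rng.uniform(0.1, 1)))
        for i in range(20) for j in range(i + 1, 20) if rng.random() < 0.2
    ]
    clusters = mcl_cluster(nodes, edges)
    everything = sorted(v for c in clusters for v in c)
    assert everything == sorted(nodes)  # exactly once each

    # each cluster lies inside a connected component of the input graph
    import networkx as nx
    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_weighted_edges_from(edges)
    comp_of = {}
    for comp in nx.connected_components(g):
        for v in comp:
            comp_of[v] = min(comp)
    for cluster in clusters:
        assert len({comp_of[v] for v in cluster}) == 1


def _reference_mcl(nodes, edges, inflation=2.0, iterations=200):
    """Independent plain-Python MCL used as an oracle (dict-of-dicts,
    no shared code with the implementation under test)."""
    adj = {u: {} for u in nodes}
    for a, b, w in edges:
        adj[a][b] = max(w, adj[a].get(b, 0.0))
        adj[b][a] = max(w, adj[b].get(a, 0.0))
    for u in nodes:
        incident = max(adj[u].values()) if adj[u] else 1.0
        adj[u][u] = incident
    # column-stochastic: columns indexed by source vertex
    cols = {u: dict(adj[u]) for u in nodes}

    def normalize(c):
        for u in c:
            total = sum(c[u].values())
            c[u] = {v: x / total for v, x in c[u].items()}
    normalize(cols)
    for _ in range(iterations):
        prev = cols
        # expansion: new[u][v] = sum_k cols[u][k] * cols[k][v]
        new = {}
        for u in nodes:
            acc = {}
            for k, w1 in cols[u].items():
                for v, w2 in cols[k].items():
                    acc[v] = acc.get(v, 0.0) + w1 * w2
            new[u] = acc
        for u in nodes:
            new[u] = {v: x ** inflation for v, x in new[u].items() if x > 1e-12}
        normalize(new)
        cols = new
        delta = max(
            abs(cols[u].get(v, 0) - prev[u].get(v, 0))
            for u in nodes for v in set(cols[u]) | set(prev[u])
        )
        if delta < 1e-10:
            break
    # clusters = connected components of the nonzero support
    support = {u: {v for v, x in cols[u].items() if x > 1e-8} for u in nodes}
    for u in nodes:
        for v in list(support[u]):
            support.setdefault(v, set()).add(u)
    seen, clusters = set(), []
    for u in sorted(nodes):
        if u in seen:
            continue
        stack, comp = [u], set()
        while stack:
            x = stack.pop()
            if x in comp:
                continue
            comp.add(x)
            stack.extend(support[x] - comp)
        seen |= comp
        clusters.append(frozenset(comp))
    return sorted(clusters, key=lambda c: sorted(c)[0])


def test_mcl_barbell_matches_reference():
    """DERIVED: 12-vertex barbell (two 6-cliques joined by one edge) at
    inflation 2.0 against the independent reference implementation."""
    left = [f"l{i}" for i in range(6)]
    right = [f"r{i}" for i in range(6)]
    edges = _clique_edges(left) + _clique_edges(right) + [("l0", "r0", 1.0)]
    ours = mcl_cluster(left + right, edges, inflation=2.0)
    ref = _reference_mcl(left + right, edges, inflation=2.0)
    assert ours == ref
    assert sorted(map(set, ours), key=min) == [set(left), set(right)]


def test_mcl_random_graphs_match_reference(rng):
    for _ in range(3):
        nodes = [f"v{i}" for i in range(10)]
        edges = [
            (nodes[i], nodes[j], float(rng.uniform(0.2, 1)))
            for i in range(10) for j in range(i + 1, 10) if rng.random() < 0.3
        ]
        assert mcl_cluster(nodes, edges) == _reference_mcl(nodes, edges)


def test_mcl_empty_graph_errors():
    with pytest.raises(FruitstratError):
        mcl_cluster([], [])


# ---------------------------------------------------------------------------
# reciprocal best hits
# ---------------------------------------------------------------------------

def _hits_df(rows):
    return pd.DataFrame(
        rows, columns=["query", "target", "bitscore", "evalue"]
    ).assign(pident=90.0, alnlen=100, mismatch=0, gapopen=0, qstart=1, qend=100,
             sstart=1, send=100, nident=90, qlen=100, slen=100)


def test_rbh_symmetric_pair():
    tables = {
        ("sp1", "sp2"): _hits_df([("a1", "b1", 300.0, 1e-50)]),
        ("sp2", "sp1"): _hits_df([("b1", "a1", 300.0, 1e-50)]),
    }
    groups = build_rbh_groups(tables, "sp1")
    assert len(groups) == 1
    assert groups[0].members == {"sp2": "b1"}


def test_rbh_reciprocity_violated():
    tables = {
        ("sp1", "sp2"): _hits_df([("a1", "b1", 300.0, 1e-50)]),
        ("sp2", "sp1"): _hits_df([("b1", "a2", 300.0, 1e-50)]),  # best is a2, not a1
    }
    assert build_rbh_groups(tables, "sp1") == []


def test_rbh_evalue_cutoff():
    tables = {
        ("sp1", "sp2"): _hits_df([("a1", "b1", 300.0, 1e-3)]),  # above 1e-5
        ("sp2", "sp1"): _hits_df([("b1", "a1", 300.0, 1e-3)]),
    }
    assert build_rbh_groups(tables, "sp1") == []


def test_rbh_missing_reverse_table_skipped(caplog):
    tables = {("sp1", "sp2"): _hits_df([("a1", "b1", 300.0, 1e-50)])}
    with caplog.at_level("WARNING"):
        groups = build_rbh_groups(tables, "sp1")
    assert groups == []
    assert "no reverse hit table" in caplog.text


def test_rbh_brute_force_oracle(rng):
    """DERIVED: random 3-species hit tables vs exhaustive pair search."""
    species = ["s1", "s2", "s3"]
    proteins = {sp: [f"{sp}_p{i}" for i in range(4)] for sp in species}
    tables = {}
    for qs, ts in itertools.permutations(species, 2):
        rows = []
        for q in proteins[qs]:
            for t in proteins[ts]:
                if rng.random() < 0.7:
                    rows.append((q, t, float(rng.integers(50, 500)), 1e-30))
        tables[(qs, ts)] = _hits_df(rows)

    def brute_best(qs, ts, q):
        df = tables[(qs, ts)]
        cand = df[df["query"] == q]
        if cand.empty:
            return None
        cand = cand.sort_values(["bitscore", "evalue", "target"],
                                ascending=[False, True, True], kind="mergesort")
        return cand.iloc[0]["target"]

    groups = {g.seed: g for g in build_rbh_groups(tables, "s1")}
    for q in proteins["s1"]:
        expected = {}
        for ts in ("s2", "s3"):
            t = brute_best("s1", ts, q)
            if t is not None and brute_best(ts, "s1", t) == q:
                expected[ts] = t
        got = groups[q].members if q in groups else {}
        assert got == expected, q


def test_rbh_row_order_invariance(rng):
    species = ["s1", "s2"]
    rows_fwd = [(f"s1_p{i}", f"s2_p{j}", float(rng.integers(50, 500)), 1e-40)
                for i in range(5) for j in range(5)]
    rows_rev = [(t, q, bs, ev) for q, t, bs, ev in rows_fwd]
    t1 = {("s1", "s2"): _hits_df(rows_fwd), ("s2", "s1"): _hits_df(rows_rev)}
    shuffled = {
        k: v.sample(frac=1.0, random_state=7).reset_index(drop=True)
        for k, v in t1.items()
    }
    g1 = [(g.seed, tuple(sorted(g.members.items()))) for g in build_rbh_groups(t1, "s1")]
    g2 = [(g.seed, tuple(sorted(g.members.items())))
          for g in build_rbh_groups(shuffled, "s1")]
    assert g1 == g2


# ---------------------------------------------------------------------------
# spurious-member filter
# ---------------------------------------------------------------------------

def _group(bitscores, overlaps):
    return RBHGroup(
        group_id="g", seed_species="s0", seed="q",
        members={f"sp{i}": f"p{i}" for i in range(len(bitscores))},
        bitscores={f"sp{i}": b for i, b in enumerate(bitscores)},
        hit_overlap={f"sp{i}": o for i, o in enumerate(overlaps)},
    )


def test_spurious_removed():
    # 100 < mean(350, 350)/3 ~ 116.7 and overlap 0.4 < 0.5 -> removed
    g = filter_spurious_members(_group([100, 350, 350], [0.4, 0.9, 0.9]))
    assert "sp0" not in g.members
    assert len(g.members) == 2


def test_spurious_retained_bitscore():
    g = filter_spurious_members(_group([200, 350, 350], [0.4, 0.9, 0.9]))
    assert len(g.members) == 3  # 200 >= 350/3


def test_spurious_retained_overlap():
    g = filter_spurious_members(_group([100, 350, 350], [0.6, 0.9, 0.9]))
    assert len(g.members) == 3  # conjunction fails


def test_spurious_two_member_group_unchanged():
    # seed + one member = 2 total members: mean of "others" undefined
    g = filter_spurious_members(_group([10], [0.0]))
    assert len(g.members) == 1


def test_spurious_fixed_point():
    # removing the weakest member drags the mean down and exposes the next
    g = filter_spurious_members(
        _group([30, 100, 900, 900], [0.1, 0.1, 0.9, 0.9])
    )
    assert set(g.members) == {"sp2", "sp3"}


# ---------------------------------------------------------------------------
# conserved orthogroups
# ---------------------------------------------------------------------------

def _presence(n_species=9):
    cols = [f"sp{i}" for i in range(1, n_species + 1)]
    return cols


def test_conserved_rule():
    cols = _presence()
    present = pd.DataFrame([[True] * 9], index=["og1"], columns=cols)
    dev = present.copy()
    dev.iloc[0] = [True] * 5 + [False] * 4
    out = classify_conserved(present, dev)
    assert bool(out.loc["og1", "conserved"])  # 5 >= 4 and 5/9 >= 0.5
    assert out.loc["og1", "dev_proportion"] == pytest.approx(5 / 9)


def test_not_conserved_proportion():
    cols = _presence()
    present = pd.DataFrame([[True] * 9], index=["og1"], columns=cols)
    dev = present.copy()
    dev.iloc[0] = [True] * 4 + [False] * 5
    out = classify_conserved(present, dev)
    assert not bool(out.loc["og1", "conserved"])  # 4/9 < 0.5


def test_conserved_present_denominator():
    cols = _presence()
    present = pd.DataFrame([[True] * 6 + [False] * 3], index=["og1"], columns=cols)
    dev = pd.DataFrame([[True] * 4 + [False] * 5], index=["og1"], columns=cols)
    by_present = classify_conserved(present, dev, prop_denominator="present")
    assert bool(by_present.loc["og1", "conserved"])  # 4/6 >= 0.5
    by_all = classify_conserved(present, dev, prop_denominator="all")
    assert not bool(by_all.loc["og1", "conserved"])  # 4/9 < 0.5


def test_zero_dev_nonconserved():
    cols = _presence()
    present = pd.DataFrame([[True] * 9], index=["og1"], columns=cols)
    dev = pd.DataFrame([[False] * 9], index=["og1"], columns=cols)
    assert not bool(classify_conserved(present, dev).loc["og1", "conserved"])


def test_conserved_monotone_in_dev_species(rng):
    cols = _presence()
    present = pd.DataFrame(
        rng.random((30, 9)) < 0.8, index=[f"og{i}" for i in range(30)], columns=cols
    )
    present.iloc[:, 0] = True  # keep every orthogroup present somewhere
    dev = present & (rng.random((30, 9)) < 0.5)
    base = classify_conserved(present, dev)
    # flip one absent-dev species to developmental (where present)
    dev2 = dev.copy()
    for og in dev2.index:
        candidates = [c for c in cols if present.loc[og, c] and not dev2.loc[og, c]]
        if candidates:
            dev2.loc[og, candidates[0]] = True
    more = classify_conserved(present, dev2)
    assert (base["conserved"] <= more["conserved"]).all()


def test_absent_everywhere_errors():
    cols = _presence()
    present = pd.DataFrame([[False] * 9], index=["og1"], columns=cols)
    dev = present.copy()
    with pytest.raises(FruitstratError, match="absent"):
        classify_conserved(present, dev)


# ---------------------------------------------------------------------------
# shared / CM-specific split
# ---------------------------------------------------------------------------

def _conserved_frame(flags):
    return pd.DataFrame(
        {"n_present": 9, "n_dev_species": 5, "dev_proportion": 0.6,
         "conserved": flags},
        index=[f"og{i}" for i in range(len(flags))],
    )


def test_split_categories():
    conserved = _conserved_frame([True, True, True, False])
    status = pd.Series(["dev", "absent", "nondev", "dev"], index=conserved.index)
    out = split_shared_cm(conserved, status)
    assert list(out["category"]) == [
        CATEGORY_SHARED, CATEGORY_CM_MISSING, CATEGORY_CM_NONDEV,
        CATEGORY_NONCONSERVED,
    ]


def test_split_partitions_conserved_set(rng):
    n = 50
    conserved = _conserved_frame(list(rng.random(n) < 0.6))
    status = pd.Series(rng.choice(["dev", "nondev", "absent"], n),
                       index=conserved.index)
    out = split_shared_cm(conserved, status)
    n_conserved = int(out["conserved"].sum())
    cats = out.loc[out["conserved"], "category"].value_counts()
    assert cats.sum() == n_conserved  # shared + cm_missing + cm_nondev additive
    assert (out.loc[~out["conserved"], "category"] == CATEGORY_NONCONSERVED).all()


def test_split_unknown_status_errors():
    conserved = _conserved_frame([True])
    with pytest.raises(FruitstratError):
        split_shared_cm(conserved, pd.Series(["weird"], index=conserved.index))


# ---------------------------------------------------------------------------
# orthogroup-origin enrichment
# ---------------------------------------------------------------------------

def test_origin_enrichment_matches_age_enrichment(rng):
    n = 200
    classes = _conserved_frame(list(rng.random(n) < 0.5))
    status = pd.Series(rng.choice(["dev", "nondev", "absent"], n),
                       index=classes.index)
    classes = split_shared_cm(classes, status)
    ages = pd.Series(rng.integers(1, 8, n), index=classes.index)
    mine = og_origin_enrichment(classes, ages, CATEGORY_SHARED)
    direct = age_enrichment(classes["category"] == CATEGORY_SHARED, ages)
    pd.testing.assert_frame_equal(mine, direct)


def test_origin_enrichment_planted_node(rng):
    n = 500
    ogs = [f"og{i}" for i in range(n)]
    ages = pd.Series(rng.integers(1, 10, n), index=ogs)
    # plant all CM-specific orthogroups at node 6
    flags = ages == 6
    category = pd.Series(CATEGORY_NONCONSERVED, index=ogs, dtype=object)
    category[flags] = CATEGORY_CM_MISSING
    classes = pd.DataFrame({"conserved": flags, "category": category})
    result = og_origin_enrichment(classes, ages, CATEGORY_CM_MISSING)
    row = result.set_index("age").loc[6]
    assert row["odds_ratio"] > 1
    assert row["fdr"] < 0.05


# ---------------------------------------------------------------------------
# upstream identity
# ---------------------------------------------------------------------------

def test_identity_identical():
    seq = "ACGT" * 300  # 1200 nt
    assert upstream_identity(seq, seq) == pytest.approx(100.0)


def test_identity_one_substitution():
    a = "ACGTACGTAC"
    b = "ACGTACGTAG"
    assert upstream_identity(a, b) == pytest.approx(90.0)


def test_identity_symmetric(rng):
    bases = np.array(list("ACGT"))
    a = "".join(rng.choice(bases, 60))
    b = "".join(rng.choice(bases, 55))
    assert upstream_identity(a, b) == pytest.approx(upstream_identity(b, a))


def test_identity_rejects_bad_chars():
    with pytest.raises(FormatError):
        upstream_identity("ACGTX", "ACGTA")


def test_identity_empty_errors():
    with pytest.raises(FruitstratError):
        upstream_identity("", "ACGT")
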