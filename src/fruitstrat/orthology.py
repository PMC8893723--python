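"""Orthology from all-vs-all protein hits: asymmetric coverage filtering,
Markov clustering of family graphs, reciprocal-best-hit orthogroups with a
spurious-member filter, conserved-orthogroup classification, and the
shared vs. CM-specific split against a simple-development outgroup.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import Align
from scipy.sparse import csgraph, csr_matrix

from .errors import FormatError, FruitstratError
from .phylostrat import age_enrichment

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# coverage filter
# ---------------------------------------------------------------------------

def coverage_filter(
    hits: pd.DataFrame, long_cov: float = 0.2, short_cov: float = 0.8
) -> pd.DataFrame:
    """Asymmetric alignment-coverage filter.

    A hit is retained iff the alignment covers >= ``long_cov`` of the
    longer protein and >= ``short_cov`` of the shorter one. This drops
    aspecific hits while keeping gene fragments.
    """
    if (hits["qlen"] <= 0).any() or (hits["slen"] <= 0).any():
        raise FormatError("zero-length protein in hit table")
    qlen = hits["qlen"].to_numpy(float)
    slen = hits["slen"].to_numpy(float)
    alnlen = hits["alnlen"].to_numpy(float)
    longer = np.maximum(qlen, slen)
    shorter = np.minimum(qlen, slen)
    keep = (alnlen / longer >= long_cov) & (alnlen / shorter >= short_cov)
    return hits[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Markov clustering
# ---------------------------------------------------------------------------

def mcl_cluster(
    vertices: Iterable[str],
    edges: Iterable[tuple[str, str, float]],
    inflation: float = 2.0,
    tol: float = 1e-8,
    max_iter: int = 200,
    prune: float = 1e-9,
) -> list[frozenset[str]]:
    """Markov clustering of a weighted undirected graph.

    Standard MCL: add stabilizing self-loops (weight = vertex max incident
    edge weight), column-normalize, then iterate expansion (matrix square)
    and inflation (elementwise power + renormalization) with pruning until
    the matrix changes by less than ``tol``. Clusters are the connected
    components of the converged matrix's nonzero structure. Deterministic:
    vertices are processed in sorted label order.
    """
    labels = sorted(set(vertices))
    if not labels:
        raise FruitstratError("empty graph")
    if inflation <= 1:
        raise FruitstratError("inflation must be > 1")
    index = {v: i for i, v in enumerate(labels)}
    n = len(labels)
    m = np.zeros((n, n))
    for u, v, w in edges:
        if w < 0:
            raise FruitstratError(f"negative edge weight on ({u}, {v})")
        i, j = index[u], index[v]
        m[i, j] = max(m[i, j], w)
        m[j, i] = max(m[j, i], w)
    # self-loops: max incident weight (1.0 for isolated vertices)
    diag = m.max(axis=0)
    diag[diag == 0] = 1.0
    np.fill_diagonal(m, diag)

    m = m / m.sum(axis=0)
    converged = False
    for _ in range(max_iter):
        prev = m
        m = m @ m
        m = np.power(m, inflation)
        m[m < prune] = 0.0
        colsum = m.sum(axis=0)
        colsum[colsum == 0] = 1.0
        m = m / colsum
        if np.abs(m - prev).max() < tol:
            converged = True
            break
    if not converged:
        log.warning("MCL did not converge in %d iterations; returning current partition", max_iter)

    support = csr_matrix((m + m.T) > prune)
    n_comp, assignment = csgraph.connected_components(support, directed=False)
    clusters: dict[int, set[str]] = {}
    for label, comp in zip(labels, assignment):
        clusters.setdefault(comp, set()).add(label)
    return sorted((frozenset(c) for c in clusters.values()), key=lambda c: sorted(c)[0])


def family_graph_from_hits(hits: pd.DataFrame) -> list[tuple[str, str, float]]:
    """Edges weighted by nident/qlen (the family-graph weight) from a hit table."""
    w = hits["nident"].to_numpy(float) / hits["qlen"].to_numpy(float)
    return [
        (q, t, float(wi))
        for q, t, wi in zip(hits["query"], hits["target"], w)
        if q != t
    ]


# ---------------------------------------------------------------------------
# reciprocal best hits
# ---------------------------------------------------------------------------

@dataclass
class RBHGroup:
    """One orthogroup seeded on a focal protein: <=1 member per species."""

    group_id: str
    seed_species: str
    seed: str
    members: dict[str, str] = field(default_factory=dict)        # species -> protein
    bitscores: dict[str, float] = field(default_factory=dict)    # species -> bitscore to seed
    hit_overlap: dict[str, float] = field(default_factory=dict)  # species -> shared-hit fraction

    @property
    def species(self) -> set[str]:
        return {self.seed_species, *self.members}

    def __len__(self) -> int:
        return 1 + len(self.members)


def _best_hits(table: pd.DataFrame, evalue_cutoff: float) -> dict[str, tuple[str, float]]:
    """query -> (best target, bitscore); ties broken by bitscore desc,
    e-value asc, then lexicographic target label."""
    df = table[table["evalue"] <= evalue_cutoff]
    best: dict[str, tuple[str, float, float]] = {}
    for row in df.itertuples(index=False):
        cur = best.get(row.query)
        cand = (row.target, float(row.bitscore), float(row.evalue))
        if cur is None:
            best[row.query] = cand
            continue
        # higher bitscore wins; then lower e-value; then smaller label
        key_new = (-cand[1], cand[2], cand[0])
        key_old = (-cur[1], cur[2], cur[0])
        if key_new < key_old:
            best[row.query] = cand
    return {q: (t, bs) for q, (t, bs, _) in best.items()}


def build_rbh_groups(
    hit_tables: Mapping[tuple[str, str], pd.DataFrame],
    seed_species: str,
    evalue_cutoff: float = 1e-5,
) -> list[RBHGroup]:
    """Assemble one-per-species orthogroups around each seed-species protein.

    ``hit_tables`` maps directed species pairs (query species, target
    species) to hit tables. A pair (p, q) is a reciprocal best hit iff q is
    p's best hit in q's species and vice versa. For each seed protein, the
    group collects its RBH partner in every other species (if any). Species
    pairs missing the reverse table are skipped with a warning.
    """
    others = sorted({b for (a, b) in hit_tables if a == seed_species})
    forward = {
        sp: _best_hits(hit_tables[(seed_species, sp)], evalue_cutoff) for sp in others
    }
    reverse = {}
    for sp in others:
        if (sp, seed_species) not in hit_tables:
            log.warning("no reverse hit table for (%s, %s); pair skipped", sp, seed_species)
            continue
        reverse[sp] = _best_hits(hit_tables[(sp, seed_species)], evalue_cutoff)

    # hit neighborhoods for the shared-hit overlap statistic
    neighborhoods: dict[str, set[str]] = {}
    for table in hit_tables.values():
        sub = table[table["evalue"] <= evalue_cutoff]
        for row in sub.itertuples(index=False):
            neighborhoods.setdefault(row.query, set()).add(row.target)

    seeds = sorted(
        {q for sp in others for q in forward[sp]}
    )
    groups = []
    for seed in seeds:
        group = RBHGroup(group_id=seed, seed_species=seed_species, seed=seed)
        for sp in others:
            if sp not in reverse:
                continue
            hit = forward[sp].get(seed)
            if hit is None:
                continue
            target, bitscore = hit
            back = reverse[sp].get(target)
            if back is None or back[0] != seed:
                continue
            group.members[sp] = target
            group.bitscores[sp] = bitscore
            mine = neighborhoods.get(target, set())
            seed_hits = neighborhoods.get(seed, set())
            group.hit_overlap[sp] = (
                len(mine & seed_hits) / len(mine) if mine else 0.0
            )
        if group.members:
            groups.append(group)
    return groups


def filter_spurious_members(group: RBHGroup, min_overlap: float = 0.5) -> RBHGroup:
    """Drop spurious members: bitscore at least 3x below the mean of the
    other members' bitscores AND sharing < ``min_overlap`` of its hits with
    the seed query's hits. Applied to a fixed point (means recomputed after
    each removal round) so the result is order-independent. Groups with
    fewer than three members are returned unchanged.
    """
    if len(group) < 3:
        return group
    members = dict(group.members)
    bitscores = dict(group.bitscores)
    overlap = dict(group.hit_overlap)
    while len(members) >= 2:
        to_remove = []
        for sp in sorted(members):
            others = [bitscores[o] for o in members if o != sp]
            mean_others = sum(others) / len(others)
            if bitscores[sp] < mean_others / 3.0 and overlap.get(sp, 0.0) < min_overlap:
                to_remove.append(sp)
        if not to_remove:
            break
        for sp in to_remove:
            members.pop(sp)
            bitscores.pop(sp)
            overlap.pop(sp, None)
    return RBHGroup(
        group_id=group.group_id,
        seed_species=group.seed_species,
        seed=group.seed,
        members=members,
        bitscores=bitscores,
        hit_overlap=overlap,
    )


# ---------------------------------------------------------------------------
# conserved orthogroups and the shared / CM-specific split
# ---------------------------------------------------------------------------

CATEGORY_SHARED = "shared"
CATEGORY_CM_MISSING = "cm_missing"
CATEGORY_CM_NONDEV = "cm_nondev"
CATEGORY_NONCONSERVED = "nonconserved"


def classify_conserved(
    present: pd.DataFrame,
    dev: pd.DataFrame,
    min_species: int = 4,
    min_prop: float = 0.5,
    prop_denominator: str = "present",
) -> pd.DataFrame:
    """Conserved developmental orthogroups.

    ``present`` and ``dev`` are aligned boolean orthogroup x species
    frames. An orthogroup is conserved iff it is developmentally expressed
    in >= ``min_species`` species and the developmental proportion is
    >= ``min_prop``; the proportion denominator is the number of species
    possessing the orthogroup (default) or all species
    (``prop_denominator='all'``).
    """
    if not present.index.equals(dev.index) or list(present.columns) != list(dev.columns):
        raise FruitstratError("present and dev tables must be aligned")
    if (~present.to_numpy() & dev.to_numpy()).any():
        raise FruitstratError("a species cannot be developmental where absent")
    n_present = present.sum(axis=1)
    if (n_present == 0).any():
        empty = present.index[n_present == 0][0]
        raise FruitstratError(f"orthogroup {empty!r} absent from every species")
    n_dev = dev.sum(axis=1)
    denom = n_present if prop_denominator == "present" else len(present.columns)
    prop = n_dev / denom
    conserved = (n_dev >= min_species) & (prop >= min_prop)
    out = pd.DataFrame(
        {
            "n_present": n_present,
            "n_dev_species": n_dev,
            "dev_proportion": prop,
            "conserved": conserved,
        }
    )
    out.index.name = "orthogroup"
    return out


def split_shared_cm(
    conserved: pd.DataFrame, outgroup_status: pd.Series
) -> pd.DataFrame:
    """Split conserved orthogroups by the outgroup ortholog's behaviour.

    ``outgroup_status`` maps orthogroup to {'dev', 'nondev', 'absent'}.
    A conserved orthogroup is shared when the outgroup ortholog is
    developmentally expressed, cm_missing when the ortholog is absent, and
    cm_nondev when present but not developmental. Non-conserved orthogroups
    get category 'nonconserved'.
    """
    status = outgroup_status.reindex(conserved.index)
    bad = set(status.dropna().unique()) - {"dev", "nondev", "absent"}
    if bad:
        raise FruitstratError(f"unknown outgroup status values: {sorted(bad)}")
    if status.isna().any():
        missing = status.index[status.isna()][0]
        raise FruitstratError(f"no outgroup status for orthogroup {missing!r}")
    category = pd.Series(CATEGORY_NONCONSERVED, index=conserved.index, dtype=object)
    mask = conserved["conserved"].astype(bool)
    category[mask & (status == "dev")] = CATEGORY_SHARED
    category[mask & (status == "absent")] = CATEGORY_CM_MISSING
    category[mask & (status == "nondev")] = CATEGORY_CM_NONDEV
    out = conserved.copy()
    out["category"] = category
    return out


def og_origin_enrichment(
    classes: pd.DataFrame, ages: pd.Series, category: str
) -> pd.DataFrame:
    """Fisher/BH enrichment of one orthogroup category across age bins.

    Thin wrapper over the gene-age enrichment machinery: the flag set is
    membership in ``category``; the background is all classified
    orthogroups with an age.
    """
    flags = (classes["category"] == category)
    return age_enrichment(flags, ages)


# ---------------------------------------------------------------------------
# upstream-region identity
# ---------------------------------------------------------------------------

def upstream_identity(
    seq_a: str,
    seq_b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
) -> float:
    """Percent identity of a global end-to-end alignment of two regions.

    Identity = matching columns / total alignment columns x 100, from the
    best-scoring global alignment (linear gap penalty).
    """
    for name, seq in (("seq_a", seq_a), ("seq_b", seq_b)):
        if not seq:
            raise FruitstratError(f"{name} is empty")
        bad = set(seq.upper()) - set("ACGTN")
        if bad:
            raise FormatError(f"{name} contains non-ACGTN characters: {sorted(bad)}")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    alignment = aligner.align(seq_a.upper(), seq_b.upper())[0]
    counts = alignment.counts()
    columns = counts.gaps + counts.identities + counts.mismatches
    return 100.0 * counts.identities / columns
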