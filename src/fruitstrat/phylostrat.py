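"""Relative gene ages on a rooted species tree, transcriptome age index,
and age-stratified enrichment statistics.

Gene age is the number (1 at the root, increasing toward the focal tip) of
the node where the MRCA of the species carrying the orthogroup attaches to
the root -> focal-tip path. The transcriptome age index (TAI) is the
expression-weighted mean gene age, TAI = sum(RA_i * e_i) / sum(e_i) with
e_i = log2(FPKM_i + 1) by default.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

from .core_io import Design, ExpressionMatrix
from .errors import FruitstratError

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# species tree
# ---------------------------------------------------------------------------

class SpeciesTree:
    """A rooted species tree with a focal tip and numbered root->focal path.

    Node numbers start at 1 at the root and strictly increase toward the
    focal tip (which carries the largest number K).
    """

    def __init__(self, tree: dendropy.Tree, focal: str):
        tree.is_rooted = True
        self.tree = tree
        self.focal = focal
        labels = [t.label for t in tree.taxon_namespace]
        if focal not in labels:
            raise FruitstratError(f"focal species {focal!r} not among tips {labels}")
        focal_leaf = next(
            leaf for leaf in tree.leaf_node_iter() if leaf.taxon.label == focal
        )
        path = []
        node = focal_leaf
        while node is not None:
            path.append(node)
            node = node.parent_node
        path.reverse()  # root first
        self._path = path
        self._path_number = {id(n): i + 1 for i, n in enumerate(path)}
        self._leaf_by_label = {
            leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()
        }
        # precompute ancestor chains for brute-force-free MRCA
        self._ancestors: dict[str, list] = {}
        for label, leaf in self._leaf_by_label.items():
            chain = []
            n = leaf
            while n is not None:
                chain.append(n)
                n = n.parent_node
            self._ancestors[label] = chain

    @classmethod
    def from_newick(cls, source: str | Path, focal: str) -> "SpeciesTree":
        src = str(source)
        if "(" in src:  # literal newick string
            tree = dendropy.Tree.get(data=src, schema="newick")
        else:
            tree = dendropy.Tree.get(path=src, schema="newick")
        return cls(tree, focal)

    @property
    def tips(self) -> list[str]:
        return sorted(self._leaf_by_label)

    @property
    def n_path_nodes(self) -> int:
        return len(self._path)

    def mrca(self, species: Iterable[str]):
        species = list(species)
        unknown = [s for s in species if s not in self._leaf_by_label]
        if unknown:
            raise FruitstratError(f"unknown species: {unknown}")
        chains = [self._ancestors[s] for s in species]
        common = set(id(n) for n in chains[0])
        for chain in chains[1:]:
            common &= {id(n) for n in chain}
        # deepest common ancestor = first element of any chain that is common
        for node in chains[0]:
            if id(node) in common:
                return node
        raise FruitstratError("no common ancestor (disconnected tree?)")

    def path_number(self, node) -> int:
        """Project a node to the deepest ancestor on the root->focal path."""
        n = node
        while n is not None:
            num = self._path_number.get(id(n))
            if num is not None:
                return num
            n = n.parent_node
        raise FruitstratError("node not connected to root")


def assign_gene_age(og_species: Iterable[str], tree: SpeciesTree) -> int:
    """Age (path node number) of an orthogroup from its species set.

    The focal species must be a member: an ortholog set without it carries
    no focal-gene age.
    """
    species = set(og_species)
    if tree.focal not in species:
        raise FruitstratError(
            f"orthogroup does not contain focal species {tree.focal!r}"
        )
    return tree.path_number(tree.mrca(species))


def assign_ages(
    og_table: pd.DataFrame, tree: SpeciesTree, og_to_gene: dict[str, str] | None = None
) -> pd.Series:
    """Vectorized :func:`assign_gene_age` over a presence table.

    ``og_table`` is a boolean orthogroup x species DataFrame. Orthogroups
    missing the focal species are skipped with a warning. Returns a Series
    of ages indexed by orthogroup (or mapped gene when ``og_to_gene`` given).
    """
    ages = {}
    skipped = 0
    for og, row in og_table.iterrows():
        species = set(og_table.columns[row.astype(bool)])
        if tree.focal not in species:
            skipped += 1
            continue
        key = og_to_gene[og] if og_to_gene else og
        ages[key] = assign_gene_age(species, tree)
    if skipped:
        log.warning("assign_ages: skipped %d orthogroups without the focal species", skipped)
    return pd.Series(ages, dtype=int, name="age")


# ---------------------------------------------------------------------------
# transcriptome age index
# ---------------------------------------------------------------------------

def _expression_weight(fpkm: np.ndarray, mode: str) -> np.ndarray:
    if mode == "log2p1":
        return np.log2(fpkm + 1.0)
    if mode == "log2drop":
        w = np.where(fpkm >= 1.0, np.log2(np.maximum(fpkm, 1.0)), 0.0)
        return w
    raise FruitstratError(f"unknown TAI log mode {mode!r}")


def compute_tai(
    expr: ExpressionMatrix,
    ages: pd.Series,
    log_mode: str = "log2p1",
    age_scale: str = "raw",
) -> pd.DataFrame:
    """Per-stage TAI profile.

    Tissue-level samples of the same stage and replicate are averaged into
    a stage-level expression vector first; the TAI is computed per
    replicate and replicate values are then averaged per stage. Returns a
    DataFrame with columns ``stage, tai, n_replicates`` plus one
    ``rep<k>`` column per replicate.
    """
    missing = [g for g in expr.genes if g not in ages.index]
    if missing:
        raise FruitstratError(
            f"{len(missing)} expressed genes lack an age (e.g. {missing[0]!r})"
        )
    ra = ages.reindex(expr.genes).to_numpy(float)
    if age_scale == "minmax":
        lo, hi = ra.min(), ra.max()
        ra = (ra - lo) / (hi - lo) if hi > lo else np.zeros_like(ra)
    elif age_scale != "raw":
        raise FruitstratError(f"unknown age_scale {age_scale!r}")

    design = expr.design
    records = []
    rep_cols: set[int] = set()
    for stage in design.stages:
        stage_samples = [s for s in design.samples if s.stage == stage]
        reps = sorted({s.replicate for s in stage_samples})
        rep_tais = {}
        for rep in reps:
            ids = [
                s.sample_id
                for s in stage_samples
                if s.replicate == rep and s.sample_id in expr.data.columns
            ]
            if not ids:
                continue
            fpkm = expr.data[ids].mean(axis=1).to_numpy(float)  # average tissues
            e = _expression_weight(fpkm, log_mode)
            total = e.sum()
            if total <= 0:
                log.warning("stage %s replicate %d: all weights zero; TAI undefined", stage, rep)
                rep_tais[rep] = math.nan
            else:
                rep_tais[rep] = float((ra * e).sum() / total)
        values = [v for v in rep_tais.values() if not math.isnan(v)]
        rec = {
            "stage": stage,
            "tai": float(np.mean(values)) if values else math.nan,
            "n_replicates": len(values),
        }
        for rep, v in rep_tais.items():
            rec[f"rep{rep}"] = v
            rep_cols.add(rep)
        records.append(rec)
    cols = ["stage", "tai", "n_replicates"] + [f"rep{r}" for r in sorted(rep_cols)]
    return pd.DataFrame(records).reindex(columns=cols)


# ---------------------------------------------------------------------------
# enrichment statistics
# ---------------------------------------------------------------------------

def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    # enforce monotonicity from the largest rank down
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(n)
    out[order] = adj
    return out


def age_enrichment(flags: pd.Series, ages: pd.Series) -> pd.DataFrame:
    """Per-age Fisher enrichment of a boolean gene set.

    For each age category a 2x2 table (flagged/unflagged x in-age/other) is
    tested two-sided; BH correction is applied across ages. Returns a
    DataFrame with columns ``age, n_flagged, n_total, odds_ratio, p, fdr,
    direction``.
    """
    common = flags.index.intersection(ages.index)
    flags = flags.loc[common].astype(bool)
    ages = ages.loc[common]
    categories = sorted(ages.unique())
    if len(categories) < 2:
        raise FruitstratError("need >= 2 distinct ages for enrichment")
    rows = []
    for age in categories:
        in_age = ages == age
        a = int((flags & in_age).sum())
        b = int((flags & ~in_age).sum())
        c = int((~flags & in_age).sum())
        d = int((~flags & ~in_age).sum())
        if a + c == 0:
            rows.append((age, a, a + c, math.nan, math.nan, "none"))
            continue
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        if math.isnan(odds) or odds == 1.0 or p >= 1.0:
            direction = "none"
        else:
            direction = "over" if odds > 1.0 else "under"
        rows.append((age, a, a + c, float(odds), float(p), direction))
    df = pd.DataFrame(
        rows, columns=["age", "n_flagged", "n_total", "odds_ratio", "p", "direction"]
    )
    valid = df["p"].notna()
    fdr = np.full(len(df), math.nan)
    if valid.any():
        fdr[valid.to_numpy()] = bh_adjust(df.loc[valid, "p"].to_numpy())
    df["fdr"] = fdr
    return df[["age", "n_flagged", "n_total", "odds_ratio", "p", "fdr", "direction"]]


# ---------------------------------------------------------------------------
# Mann-Kendall trend test
# ---------------------------------------------------------------------------

def _inversion_counts(n: int) -> np.ndarray:
    """counts[k] = number of permutations of n distinct items with k inversions."""
    counts = np.array([1], dtype=float)
    for m in range(2, n + 1):
        # convolve with a run of m ones (inserting the m-th item adds 0..m-1 inversions)
        kernel = np.ones(m)
        counts = np.convolve(counts, kernel)
    return counts


def mann_kendall_trend(values: Sequence[float]) -> tuple[float, float]:
    """Mann-Kendall trend test on an ordered sequence.

    Returns (tau, two-sided p). S = sum over i<j of sign(v_j - v_i); tau is
    the tie-corrected (tau-b) statistic. The p-value is exact (enumeration
    over all orderings) for n <= 10 without ties, else a tie-corrected
    normal approximation with continuity correction.
    """
    v = np.asarray(values, dtype=float)
    n = len(v)
    if n < 3:
        raise FruitstratError("Mann-Kendall test needs n >= 3")
    diffs = np.sign(v[None, :] - v[:, None])
    s = int(np.triu(diffs, k=1).sum())

    _, tie_counts = np.unique(v, return_counts=True)
    ties = tie_counts[tie_counts > 1]
    d0 = n * (n - 1) / 2
    t_corr = float((ties * (ties - 1) / 2).sum())
    denom = math.sqrt((d0 - t_corr) * d0)
    tau = s / denom if denom > 0 else 0.0

    if s == 0:
        return tau, 1.0

    if n <= 10 and len(ties) == 0:
        counts = _inversion_counts(n)
        total = counts.sum()
        # S = d0 - 2k  =>  S >= |s|  <=>  k <= (d0 - |s|)/2
        kmax = int((d0 - abs(s)) // 2)
        tail = counts[: kmax + 1].sum() / total
        return tau, min(1.0, 2.0 * float(tail))

    var = (n * (n - 1) * (2 * n + 5) - float((ties * (ties - 1) * (2 * ties + 5)).sum())) / 18.0
    if var <= 0:
        return tau, 1.0
    z = (s - np.sign(s)) / math.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return tau, min(1.0, float(p))
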