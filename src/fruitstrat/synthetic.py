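"""Seed-deterministic generators for every pipeline input, with planted
ground truth so downstream stages can be validated without external data.

Each generator returns (data, truth) where the truth table records the
planted signal per item. Expression noise is lognormal on the log2 scale;
allele counts are binomial given a Poisson total depth; reads are drawn
over SNP haplotypes with an independent per-base error; orthogroups are
born on the focal root-to-tip path with independent stochastic loss.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import Design
from .errors import FruitstratError
from .phylostrat import SpeciesTree

log = logging.getLogger(__name__)

BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def gen_expression(
    n_genes: int,
    design: Design,
    frac_dev: float = 0.2,
    fc_range: tuple[float, float] = (4.0, 16.0),
    noise_sd: float = 0.25,
    vm_max_frac: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stage-structured lognormal expression with planted fold changes.

    Non-developmental genes share one mean across all groups up to log2
    noise. Developmental genes have one non-VM group's mean multiplied by a
    fold change drawn uniformly from ``fc_range``. A further
    ``vm_max_frac`` of the non-developmental genes has its maximum planted
    in the VM group (to exercise the exclusion rule). Returns (expression
    DataFrame gene x sample, truth table).
    """
    if not (0 <= frac_dev <= 1):
        raise FruitstratError("frac_dev must be in [0, 1]")
    if fc_range[0] < 1 or fc_range[1] < fc_range[0]:
        raise FruitstratError("fc_range must satisfy 1 <= low <= high")
    if len(design) == 0:
        raise FruitstratError("empty design")
    rng = np.random.default_rng(seed)
    genes = [f"g{i:05d}" for i in range(n_genes)]

    groups = list(design.groups().keys())
    nonvm = [g for g in groups if not design.is_vm_group(g)]
    vm = [g for g in groups if design.is_vm_group(g)]
    if not nonvm:
        raise FruitstratError("design has no non-VM group")

    base_log2 = rng.uniform(2.0, 8.0, size=n_genes)
    n_dev = int(round(frac_dev * n_genes))
    dev_idx = rng.choice(n_genes, size=n_dev, replace=False)
    is_dev = np.zeros(n_genes, dtype=bool)
    is_dev[dev_idx] = True
    planted_fc = np.ones(n_genes)
    planted_fc[dev_idx] = rng.uniform(fc_range[0], fc_range[1], size=n_dev)
    dev_group_idx = rng.integers(0, len(nonvm), size=n_genes)

    non_dev_idx = np.flatnonzero(~is_dev)
    n_vm_max = int(round(vm_max_frac * len(non_dev_idx))) if vm else 0
    vm_max = np.zeros(n_genes, dtype=bool)
    if n_vm_max:
        vm_max[rng.choice(non_dev_idx, size=n_vm_max, replace=False)] = True

    # per-group log2 means
    group_log2 = {g: base_log2.copy() for g in groups}
    for i in dev_idx:
        g = nonvm[dev_group_idx[i]]
        group_log2[g][i] += np.log2(planted_fc[i])
    for g in vm:
        group_log2[g][vm_max] += 2.0  # planted VM maximum (4x)

    data = {}
    for sample in design.samples:
        mu = group_log2[sample.group]
        noise = rng.normal(0.0, noise_sd, size=n_genes) if noise_sd > 0 else 0.0
        data[sample.sample_id] = np.exp2(mu + noise)
    expr = pd.DataFrame(data, index=genes)
    expr.index.name = "gene"

    truth = pd.DataFrame(
        {
            "gene": genes,
            "is_developmental": is_dev,
            "planted_fc": planted_fc,
            "dev_stage": [nonvm[dev_group_idx[i]][0] if is_dev[i] else "" for i in range(n_genes)],
            "dev_tissue": [nonvm[dev_group_idx[i]][1] if is_dev[i] else "" for i in range(n_genes)],
            "vm_max": vm_max,
        }
    ).set_index("gene")
    return expr, truth


# ---------------------------------------------------------------------------
# allele counts
# ---------------------------------------------------------------------------

def gen_allele_counts(
    n_genes: int,
    design: Design,
    class_mix: dict[str, float] | None = None,
    depth_mean: float = 200.0,
    indecisive_frac: float = 0.1,
    boundary_margin: float = 0.04,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-nucleus allele counts at planted AS ratios.

    Per gene a class is drawn from ``class_mix`` (default 70% EE / 15% S2 /
    15% S4) and a true AS ratio from the class band: EE at 0.5, S2 within
    (0.69, 0.8], S4 within (0.8, 1] (each mirrored to the lower band with
    probability 0.5). Draws keep ``boundary_margin`` away from the 0.8
    decision boundary: a gene planted exactly on the boundary is
    misclassified half the time by construction, which would make recovery
    rates meaningless. Per gene/sample the total read count is
    Poisson(depth_mean), an ``indecisive_frac`` binomial share is withheld
    as indecisive, and decisive reads split binomially at the true ratio.
    """
    if depth_mean <= 0:
        raise FruitstratError("depth_mean must be > 0")
    class_mix = class_mix or {"EE": 0.7, "S2": 0.15, "S4": 0.15}
    if abs(sum(class_mix.values()) - 1.0) > 1e-9:
        raise FruitstratError("class_mix proportions must sum to 1")
    if not (0 <= indecisive_frac <= 1):
        raise FruitstratError("indecisive_frac must be in [0, 1]")
    rng = np.random.default_rng(seed)
    genes = [f"g{i:05d}" for i in range(n_genes)]
    labels = sorted(class_mix)
    probs = np.array([class_mix[c] for c in labels])
    classes = rng.choice(labels, size=n_genes, p=probs)

    m = boundary_margin
    true_as = np.full(n_genes, 0.5)
    for i, cls in enumerate(classes):
        if cls == "EE":
            continue
        if cls == "S2":
            hi = rng.uniform(0.69 + 1e-6, 0.80 - m)
        elif cls == "S4":
            hi = rng.uniform(0.80 + m, 0.98)
        else:
            raise FruitstratError(f"unknown class {cls!r} in class_mix")
        true_as[i] = hi if rng.random() < 0.5 else 1.0 - hi

    rows = []
    for sample in design.samples:
        total = rng.poisson(depth_mean, size=n_genes)
        indecisive = rng.binomial(total, indecisive_frac)
        decisive = total - indecisive
        count_a = rng.binomial(decisive, true_as)
        count_b = decisive - count_a
        fpkm = total / 10.0  # proportional stand-in; keeps genes above the FPKM mask
        for i, gene in enumerate(genes):
            rows.append(
                (gene, sample.sample_id, int(count_a[i]), int(count_b[i]),
                 int(indecisive[i]), float(fpkm[i]))
            )
    counts = pd.DataFrame(
        rows,
        columns=["gene", "sample", "count_a", "count_b", "count_indecisive", "fpkm_total"],
    )
    truth = pd.DataFrame(
        {"gene": genes, "true_class": classes, "true_as_ratio": true_as}
    ).set_index("gene")
    return counts, truth


# ---------------------------------------------------------------------------
# reads over SNP haplotypes
# ---------------------------------------------------------------------------

def gen_reads(
    variants: pd.DataFrame,
    read_len: int = 150,
    n_reads: int = 1000,
    error_rate: float = 0.01,
    parent_mix: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-read SNP observations from one of two parental haplotypes.

    Each read starts at a uniform position on a uniform contig, covers the
    SNPs within ``read_len`` bases, carries parent A's alleles with
    probability ``parent_mix`` (else parent B's), and each observed base is
    replaced by a uniformly chosen different base independently with
    probability ``error_rate``. Reads covering no SNP are emitted in the
    truth table flagged with ``n_sites = 0`` but contribute no observation
    rows. Returns (observation table ``read, contig, pos, base, phred``,
    truth table ``read, true_parent, n_sites``).
    """
    if read_len < 1:
        raise FruitstratError("read_len must be >= 1")
    if not (0 <= error_rate <= 0.1):
        raise FruitstratError("error_rate must be in [0, 0.1]")
    if len(variants) == 0:
        raise FruitstratError("variant table is empty")
    rng = np.random.default_rng(seed)
    contigs = sorted(variants["contig"].unique())
    by_contig = {
        c: variants[variants["contig"] == c].sort_values("pos").reset_index(drop=True)
        for c in contigs
    }
    span = {c: int(by_contig[c]["pos"].max()) + read_len for c in contigs}

    obs_rows = []
    truth_rows = []
    for r in range(n_reads):
        read_id = f"r{r:06d}"
        contig = contigs[rng.integers(0, len(contigs))]
        sites = by_contig[contig]
        start = int(rng.integers(1, span[contig]))
        window = sites[(sites["pos"] >= start) & (sites["pos"] < start + read_len)]
        from_a = rng.random() < parent_mix
        truth_rows.append((read_id, "A" if from_a else "B", len(window)))
        if len(window) == 0:
            log.debug("read %s covers no SNP site", read_id)
            continue
        for site in window.itertuples(index=False):
            base = site.allele_a if from_a else site.allele_b
            if error_rate > 0 and rng.random() < error_rate:
                base = str(rng.choice(BASES[BASES != base]))
            obs_rows.append((read_id, contig, int(site.pos), base, 40))
    obs = pd.DataFrame(obs_rows, columns=["read", "contig", "pos", "base", "phred"])
    truth = pd.DataFrame(truth_rows, columns=["read", "true_parent", "n_sites"]).set_index("read")
    return obs, truth


# ---------------------------------------------------------------------------
# orthogroups on a species tree
# ---------------------------------------------------------------------------

def gen_orthogroups(
    tree: SpeciesTree,
    n_groups: int = 500,
    loss_prob: float = 0.2,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Orthogroup presence/absence by gene birth on the focal path with loss.

    Each orthogroup is born on a uniformly chosen node of the root->focal
    path (births elsewhere never contain the focal species and would be
    discarded, so the path nodes are sampled directly); it is present in
    the tips descending from the birth node except for independent losses
    at ``loss_prob`` per non-focal tip. The planted age is the birth node's
    path number. Returns (boolean orthogroup x species presence table,
    truth table with ``true_age``).
    """
    if not (0 <= loss_prob < 1):
        raise FruitstratError("loss_prob must be in [0, 1)")
    if len(tree.tips) < 2:
        raise FruitstratError("tree must have >= 2 tips")
    rng = np.random.default_rng(seed)
    path_nodes = tree._path  # root -> focal, numbered 1..K
    tips_below = []
    for node in path_nodes:
        if node.is_leaf():
            tips_below.append([node.taxon.label])
        else:
            tips_below.append(sorted(leaf.taxon.label for leaf in node.leaf_iter()))

    species = tree.tips
    rows = np.zeros((n_groups, len(species)), dtype=bool)
    col = {s: j for j, s in enumerate(species)}
    ages = np.zeros(n_groups, dtype=int)
    for i in range(n_groups):
        k = int(rng.integers(0, len(path_nodes)))
        ages[i] = k + 1
        for tip in tips_below[k]:
            if tip == tree.focal:
                rows[i, col[tip]] = True
            elif rng.random() >= loss_prob:
                rows[i, col[tip]] = True
    ogs = [f"og{i:05d}" for i in range(n_groups)]
    table = pd.DataFrame(rows, index=ogs, columns=species)
    table.index.name = "orthogroup"
    truth = pd.DataFrame({"orthogroup": ogs, "true_age": ages}).set_index("orthogroup")
    return table, truth
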