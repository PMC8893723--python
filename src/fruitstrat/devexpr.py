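"""FPKM computation and classification of developmentally expressed genes.

A gene is developmentally expressed at fold-change threshold ``t`` when the
ratio of replicate-mean FPKM between some ordered pair of non-VM
(stage, tissue) groups reaches ``t``, its peak group mean exceeds the
detectability floor (FPKM > 4 by default), and the global expression
maximum does not fall in the vegetative mycelium.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import Design, ExpressionMatrix
from .errors import FormatError, FruitstratError

log = logging.getLogger(__name__)


def compute_fpkm(
    counts: pd.DataFrame,
    gene_lengths: pd.Series,
    library_sizes: pd.Series,
) -> pd.DataFrame:
    """FPKM = count * 1e9 / (gene_length * library_size).

    Parameters
    ----------
    counts
        Gene x sample integer fragment counts.
    gene_lengths
        Transcript length in nt per gene (index aligned with ``counts``).
    library_sizes
        Mapped fragments per sample (index aligned with ``counts`` columns).
    """
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()][0]
        raise FormatError(f"no length for gene {missing!r}")
    if (lengths <= 0).any():
        bad = lengths.index[lengths <= 0][0]
        raise FormatError(f"non-positive length for gene {bad!r}")
    libs = library_sizes.reindex(counts.columns)
    if libs.isna().any() or (libs <= 0).any():
        raise FormatError("library sizes must be present and strictly positive")
    scale = 1e9 / np.outer(lengths.to_numpy(float), libs.to_numpy(float))
    return pd.DataFrame(
        counts.to_numpy(float) * scale, index=counts.index, columns=counts.columns
    )


@dataclass
class DevCall:
    """Per-gene developmental-expression call at the 2x and 4x thresholds."""

    gene: str
    max_fc: float
    max_group: tuple[str, str]
    is_dev_fc2: bool
    is_dev_fc4: bool
    excluded_vm: bool


def classify_developmental(
    expr: ExpressionMatrix,
    fc_threshold: float = 4.0,
    min_fpkm: float = 4.0,
    zero_floor: float = 0.1,
) -> pd.DataFrame:
    """Classify developmentally expressed genes.

    Per gene: replicate means are computed per (stage, tissue) group;
    ``max_fc`` is the maximum ratio (larger/smaller, means floored at
    ``zero_floor``) over all pairs of non-VM groups. A gene is
    developmental at threshold ``t`` iff ``max_fc >= t``, the best non-VM
    group mean exceeds ``min_fpkm``, and the globally maximal group is not
    the VM. Returns a DataFrame indexed by gene with columns
    ``max_fc, max_stage, max_tissue, is_dev_fc2, is_dev_fc4, is_dev, excluded_vm``
    where ``is_dev`` applies ``fc_threshold``.
    """
    design = expr.design
    all_means = expr.group_means(include_vm=True)
    nonvm_groups = [g for g in all_means.columns if not design.is_vm_group(g)]
    if len(nonvm_groups) < 2:
        raise FruitstratError("need >= 2 non-VM groups to compute fold changes")
    for group, members in design.groups().items():
        have = [s.sample_id for s in members if s.sample_id in expr.data.columns]
        if len(have) < len(members):
            log.warning(
                "group %s: only %d/%d replicates present; mean over available ones",
                group, len(have), len(members),
            )

    nonvm = all_means[nonvm_groups].to_numpy(float)
    floored = np.maximum(nonvm, zero_floor)
    max_ratio = floored.max(axis=1) / floored.min(axis=1)
    peak_idx = nonvm.argmax(axis=1)
    peak_mean = nonvm.max(axis=1)

    global_max = all_means.to_numpy(float).max(axis=1)
    vm_cols = [g for g in all_means.columns if design.is_vm_group(g)]
    if vm_cols:
        vm_max = all_means[vm_cols].to_numpy(float).max(axis=1)
        excluded_vm = vm_max >= global_max  # VM attains the global maximum
    else:
        excluded_vm = np.zeros(len(all_means), dtype=bool)

    detectable = peak_mean > min_fpkm
    base_ok = detectable & ~excluded_vm

    out = pd.DataFrame(index=all_means.index)
    out.index.name = "gene"
    out["max_fc"] = max_ratio
    out["max_stage"] = [nonvm_groups[i][0] for i in peak_idx]
    out["max_tissue"] = [nonvm_groups[i][1] for i in peak_idx]
    out["is_dev_fc2"] = (max_ratio >= 2.0) & base_ok
    out["is_dev_fc4"] = (max_ratio >= 4.0) & base_ok
    out["is_dev"] = (max_ratio >= fc_threshold) & base_ok
    out["excluded_vm"] = excluded_vm
    return out
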