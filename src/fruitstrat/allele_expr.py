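"""Allele-specific expression: read assignment to parental nuclei, AS
ratios with masking, EE/S2/S4 classification, and chromosome/nuclear read
ratios.

Reads are assigned to the parental haplotype with the smaller Hamming
distance (Hd = number of mismatched SNPs); a read is indecisive when
(i) Hd > 1 from both genomes, (ii) Hd > 15 from any genome (too divergent),
or (iii) the distances tie. The AS ratio of a gene in a sample is the
fraction of decisive reads attributed to parent A; it is masked to 0.5 at
low expression (FPKM < 2), few decisive reads (< 16), or a dominant
indecisive fraction (> 80%).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import Design
from .errors import FruitstratError

log = logging.getLogger(__name__)

PARENT_A = "parentA"
PARENT_B = "parentB"
INDECISIVE = "indecisive"


# ---------------------------------------------------------------------------
# read assignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReadAssignment:
    read: str
    hd_a: int
    hd_b: int
    call: str     # parentA | parentB | indecisive
    reason: str   # none | both_gt1 | too_divergent | tie


def hd_call(
    hd_a: int, hd_b: int, max_hd: int = 15, divergent_rule: str = "any"
) -> tuple[str, str]:
    """Decision rule mapping a pair of Hamming distances to a parent call.

    ``divergent_rule='any'`` applies the Hd > ``max_hd`` cutoff to either
    genome (literal published rule); ``'closer'`` applies it only to the
    nearer genome.
    """
    if hd_a < 0 or hd_b < 0:
        raise FruitstratError("Hamming distances must be nonnegative")
    if hd_a == hd_b:
        return INDECISIVE, "tie"
    if hd_a > 1 and hd_b > 1:
        return INDECISIVE, "both_gt1"
    divergent = (
        max(hd_a, hd_b) > max_hd if divergent_rule == "any" else min(hd_a, hd_b) > max_hd
    )
    if divergent:
        return INDECISIVE, "too_divergent"
    return (PARENT_A, "none") if hd_a < hd_b else (PARENT_B, "none")


def assign_read(
    obs: pd.DataFrame,
    variants: pd.DataFrame,
    read_id: str = "",
    max_hd: int = 15,
    divergent_rule: str = "any",
) -> ReadAssignment:
    """Assign one read from its per-SNP base observations.

    ``obs`` must have columns ``contig, pos, base`` and be restricted to
    sites present in ``variants`` (bases already Phred-filtered upstream).
    A read covering zero informative sites is indecisive (tie at 0 = 0).
    """
    if len(obs) == 0:
        return ReadAssignment(read_id, 0, 0, INDECISIVE, "tie")
    merged = obs.merge(variants, on=["contig", "pos"], how="left")
    if merged["allele_a"].isna().any():
        bad = merged.loc[merged["allele_a"].isna(), ["contig", "pos"]].iloc[0]
        raise FruitstratError(
            f"observation at {bad['contig']}:{bad['pos']} is not a known SNP site"
        )
    hd_a = int((merged["base"] != merged["allele_a"]).sum())
    hd_b = int((merged["base"] != merged["allele_b"]).sum())
    call, reason = hd_call(hd_a, hd_b, max_hd=max_hd, divergent_rule=divergent_rule)
    return ReadAssignment(read_id, hd_a, hd_b, call, reason)


def assign_reads(
    obs_table: pd.DataFrame,
    variants: pd.DataFrame,
    max_hd: int = 15,
    divergent_rule: str = "any",
) -> pd.DataFrame:
    """Assign every read in a per-read SNP observation table.

    ``obs_table`` columns: ``read, contig, pos, base`` (one row per covered
    SNP). Returns a DataFrame with columns ``read, hd_a, hd_b, call,
    reason``, one row per read, ordered by read label.
    """
    merged = obs_table.merge(variants, on=["contig", "pos"], how="left")
    if merged["allele_a"].isna().any():
        bad = merged.loc[merged["allele_a"].isna(), ["contig", "pos"]].iloc[0]
        raise FruitstratError(
            f"observation at {bad['contig']}:{bad['pos']} is not a known SNP site"
        )
    merged["mm_a"] = (merged["base"] != merged["allele_a"]).astype(int)
    merged["mm_b"] = (merged["base"] != merged["allele_b"]).astype(int)
    agg = merged.groupby("read", sort=True)[["mm_a", "mm_b"]].sum()
    rows = []
    for read, (hd_a, hd_b) in agg.iterrows():
        call, reason = hd_call(int(hd_a), int(hd_b), max_hd=max_hd, divergent_rule=divergent_rule)
        rows.append((read, int(hd_a), int(hd_b), call, reason))
    return pd.DataFrame(rows, columns=["read", "hd_a", "hd_b", "call", "reason"])


def aggregate_allele_counts(
    assignments: pd.DataFrame, read_meta: pd.DataFrame
) -> pd.DataFrame:
    """Aggregate per-read calls into a gene x sample allele count table.

    ``read_meta`` maps ``read`` to ``gene`` and ``sample``. Returns columns
    ``gene, sample, count_a, count_b, count_indecisive``.
    """
    df = assignments.merge(read_meta[["read", "gene", "sample"]], on="read", how="inner")
    grouped = df.groupby(["gene", "sample"])["call"]
    out = grouped.value_counts().unstack(fill_value=0)
    for col, name in ((PARENT_A, "count_a"), (PARENT_B, "count_b"), (INDECISIVE, "count_indecisive")):
        out[name] = out[col] if col in out.columns else 0
    out = out[["count_a", "count_b", "count_indecisive"]].reset_index()
    out.columns.name = None
    return out


# ---------------------------------------------------------------------------
# AS ratios
# ---------------------------------------------------------------------------

MASK_NONE = "none"
MASK_LOW_FPKM = "low_fpkm"
MASK_FEW_DECISIVE = "few_decisive"
MASK_INDECISIVE = "indecisive_dominant"


def compute_as_ratio(
    counts: pd.DataFrame,
    min_fpkm: float = 2.0,
    min_decisive: int = 16,
    max_indecisive_frac: float = 0.8,
) -> pd.DataFrame:
    """Per gene/sample AS ratio with masking.

    ``counts`` columns: ``gene, sample, count_a, count_b, count_indecisive``
    and optionally ``fpkm_total`` (total gene FPKM; without it the
    low-expression mask is not applied). ``as_ratio = count_a / (count_a +
    count_b)``, masked to 0.5 with the mask reason recorded when the gene
    expression is too low, decisive reads are too few, or the indecisive
    fraction is too high (first matching reason reported, in that order).
    """
    df = counts.copy()
    for col in ("count_a", "count_b", "count_indecisive"):
        if (df[col] < 0).any():
            raise FruitstratError(f"negative values in {col}")
    decisive = df["count_a"] + df["count_b"]
    total = decisive + df["count_indecisive"]
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = df["count_a"] / decisive
        ind_frac = np.where(total > 0, df["count_indecisive"] / total, 1.0)

    reason = np.full(len(df), MASK_NONE, dtype=object)
    if "fpkm_total" in df.columns:
        low = df["fpkm_total"].to_numpy(float) < min_fpkm
        reason[low] = MASK_LOW_FPKM
    few = (decisive.to_numpy() < min_decisive) & (reason == MASK_NONE)
    reason[few] = MASK_FEW_DECISIVE
    dom = (ind_frac > max_indecisive_frac) & (reason == MASK_NONE)
    reason[dom] = MASK_INDECISIVE

    masked = reason != MASK_NONE
    ratio = ratio.to_numpy(float)
    ratio[masked] = 0.5
    if np.isnan(ratio).any():  # decisive == 0 but unmasked configuration
        stray = np.isnan(ratio)
        reason[stray] = MASK_FEW_DECISIVE
        masked |= stray
        ratio[stray] = 0.5

    out = df[["gene", "sample"]].copy()
    out["as_ratio"] = ratio
    out["masked"] = masked
    out["mask_reason"] = reason
    return out


# ---------------------------------------------------------------------------
# EE / S2 / S4 classification
# ---------------------------------------------------------------------------

def _biased_gm(values: np.ndarray, side: str, gm_mode: str) -> float:
    """Geometric mean of replicate AS values on the stated side of 0.5.

    For parent-B bias the default ('mirrored') mode takes the geometric
    mean of (1 - AS) so the same upper thresholds apply; 'direct' compares
    the plain geometric mean of AS against the mirrored (lower) threshold
    upstream.
    """
    if side == "A" or gm_mode == "direct":
        vals = values
    else:
        vals = 1.0 - values
    if (vals <= 0).any():
        return 0.0
    return float(np.exp(np.mean(np.log(vals))))


def classify_ase(
    as_table: pd.DataFrame,
    design: Design,
    s2_lo: float = 0.31,
    s2_hi: float = 0.68,
    s4_lo: float = 0.2,
    s4_hi: float = 0.8,
    gm_mode: str = "mirrored",
) -> pd.DataFrame:
    """Classify genes as EE / S2 / S4 from per-sample AS ratios.

    A gene is allele-biased in a (stage, tissue) group when every replicate
    of that group is unmasked and strictly on the same side of 0.5. The
    geometric mean of the replicate AS values (mirrored onto the upper
    scale for parent-B bias by default) must exceed ``s4_hi`` for S4 or
    ``s2_hi`` for S2; S4 takes precedence over S2, and any qualifying group
    suffices. Returns a DataFrame indexed by gene with columns
    ``ase_class, direction, trigger_stage, trigger_tissue``.
    """
    groups = design.groups(include_vm=True)
    sample_to_group = {s.sample_id: s.group for s in design.samples}
    pivot = as_table.pivot_table(
        index="gene", columns="sample", values="as_ratio", aggfunc="first"
    )
    masked = as_table.pivot_table(
        index="gene", columns="sample", values="masked", aggfunc="first"
    ).astype(bool)

    records = []
    for gene in pivot.index:
        best_class = "EE"
        direction = "none"
        trigger: tuple[str, str] | None = None
        for group, members in groups.items():
            ids = [s.sample_id for s in members if s.sample_id in pivot.columns]
            if not ids:
                continue
            vals = pivot.loc[gene, ids].to_numpy(float)
            msk = masked.loc[gene, ids].to_numpy()
            if np.isnan(vals).any() or msk.any():
                continue  # masked replicates count as unbiased
            if (vals > 0.5).all():
                side = "A"
            elif (vals < 0.5).all():
                side = "B"
            else:
                continue
            gm = _biased_gm(vals, side, gm_mode)
            if gm_mode == "direct" and side == "B":
                is_s4 = gm < s4_lo
                is_s2 = gm < s2_lo
            else:
                is_s4 = gm > s4_hi
                is_s2 = gm > s2_hi
            if is_s4:
                best_class, direction, trigger = "S4", side, group
                break  # S4 is maximal; no need to scan further groups
            if is_s2 and best_class != "S4":
                if best_class != "S2":
                    best_class, direction, trigger = "S2", side, group
        records.append(
            {
                "gene": gene,
                "ase_class": best_class,
                "direction": direction,
                "trigger_stage": trigger[0] if trigger else "",
                "trigger_tissue": trigger[1] if trigger else "",
            }
        )
    return pd.DataFrame(records).set_index("gene")


# ---------------------------------------------------------------------------
# chromosome / nuclear read ratios
# ---------------------------------------------------------------------------

def compute_crr_nrr(
    fpkm_a: pd.Series, fpkm_b: pd.Series, contigs: pd.Series
) -> tuple[pd.Series, float]:
    """Chromosome read ratios and the global nuclear read ratio.

    CRR(c) = sum of parent-A FPKM over genes on contig c divided by the
    parent-B sum; NRR is the same ratio over all genes. Zero denominators
    yield NaN.
    """
    if not fpkm_a.index.equals(fpkm_b.index):
        fpkm_b = fpkm_b.reindex(fpkm_a.index)
        if fpkm_b.isna().any():
            raise FruitstratError("fpkm_a and fpkm_b must be aligned on genes")
    contigs = contigs.reindex(fpkm_a.index)
    if contigs.isna().any():
        raise FruitstratError("every gene needs a contig for CRR")
    num = fpkm_a.groupby(contigs).sum()
    den = fpkm_b.groupby(contigs).sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        crr = num / den
    crr[den == 0] = math.nan
    total_b = float(fpkm_b.sum())
    nrr = float(fpkm_a.sum()) / total_b if total_b > 0 else math.nan
    crr.name = "crr"
    return crr, nrr
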