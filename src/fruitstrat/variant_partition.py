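"""First stage of the mismatch pipeline: partition observed read bases into
allele-specific markers, editing/technical candidates, and discarded
low-quality bases, then aggregate editing candidates with VRS/RS/RVF
filters and A-to-I compatibility scoring.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Mapping

import pandas as pd

from .core_io import VALID_BASES
from .errors import FormatError, FruitstratError

log = logging.getLogger(__name__)

CLASS_MATCH = "match"
CLASS_ALLELE = "allele_marker"
CLASS_BOTH_DIFF = "both_diff"
CLASS_DISCARDED = "discarded_quality"


@dataclass(frozen=True)
class SiteClass:
    site_class: str
    third_allele: bool = False
    marker_parent: str = ""  # "A" or "B" for allele_marker sites


def classify_site(
    base: str,
    allele_a: str,
    allele_b: str,
    phred: int,
    min_phred: int = 30,
) -> SiteClass:
    """Classify one observed base against the two parental alleles.

    Low-quality or N bases are discarded. A base differing identically from
    both (equal) parental alleles is an editing/technical candidate
    (``both_diff``). Where the parents differ, a base matching exactly one
    parent is an allele marker; matching neither is ``both_diff`` flagged
    ``third_allele``. Everything else (parents agree and the base agrees)
    is a plain match.
    """
    if phred < 0:
        raise FormatError("negative Phred score")
    base, allele_a, allele_b = base.upper(), allele_a.upper(), allele_b.upper()
    for name, b in (("allele_a", allele_a), ("allele_b", allele_b)):
        if b not in VALID_BASES:
            raise FormatError(f"{name} must be one of ACGT, got {b!r}")
    if base == "N" or phred < min_phred:
        return SiteClass(CLASS_DISCARDED)
    if base not in VALID_BASES:
        raise FormatError(f"observed base must be ACGTN, got {base!r}")
    if allele_a == allele_b:
        if base == allele_a:
            return SiteClass(CLASS_MATCH)
        return SiteClass(CLASS_BOTH_DIFF)
    # parents differ at this site
    if base == allele_a:
        return SiteClass(CLASS_ALLELE, marker_parent="A")
    if base == allele_b:
        return SiteClass(CLASS_ALLELE, marker_parent="B")
    return SiteClass(CLASS_BOTH_DIFF, third_allele=True)


def partition_observations(obs: pd.DataFrame, min_phred: int = 30) -> pd.DataFrame:
    """Classify a stream of site observations.

    ``obs`` columns: ``contig, pos, base, phred, allele_a, allele_b`` (one
    row per read-base). Returns the same table with added ``site_class``,
    ``third_allele`` and ``marker_parent`` columns. The classes form an
    exhaustive, mutually exclusive partition of the input rows.
    """
    out = obs.copy()
    classes, thirds, parents = [], [], []
    for row in obs.itertuples(index=False):
        sc = classify_site(row.base, row.allele_a, row.allele_b, int(row.phred), min_phred)
        classes.append(sc.site_class)
        thirds.append(sc.third_allele)
        parents.append(sc.marker_parent)
    out["site_class"] = classes
    out["third_allele"] = thirds
    out["marker_parent"] = parents
    return out


def summarize_editing(
    partitioned: pd.DataFrame,
    strand: Mapping[str, str] | Callable[[str, int], str] | None = None,
    min_vrs: int = 3,
    min_rs: int = 10,
    min_rvf: float = 0.1,
) -> tuple[pd.DataFrame, float]:
    """Aggregate editing/technical candidate sites and score A->G compatibility.

    ``partitioned`` is :func:`partition_observations` output covering the
    candidate sites (all high-quality observations at each site contribute
    to read support). Per site: VRS = reads carrying the modal variant
    base, RS = total high-quality reads, RVF = VRS/RS. Sites passing all
    three thresholds are retained and scored for A->G compatibility on the
    transcript strand (A->G on '+', T->C on '-'); ``strand`` maps contig to
    orientation (or is a callable of (contig, pos)); unknown strands leave
    the flag missing.

    Returns the retained-candidate table and the fraction of
    A-to-I-compatible sites among retained candidates with known strand
    (NaN when there are none).
    """
    usable = partitioned[partitioned["site_class"] != CLASS_DISCARDED]
    rows = []
    for (contig, pos), site_obs in usable.groupby(["contig", "pos"], sort=True):
        cand = site_obs[site_obs["site_class"] == CLASS_BOTH_DIFF]
        if len(cand) == 0:
            continue
        ref = site_obs["allele_a"].iloc[0]
        variant_counts = cand["base"].value_counts()
        variant_base = variant_counts.index[0]
        vrs = int(variant_counts.iloc[0])
        rs = int(len(site_obs))
        rvf = vrs / rs
        if vrs < min_vrs or rs < min_rs or rvf < min_rvf:
            continue
        if strand is None:
            orient = ""
        elif callable(strand):
            orient = strand(contig, int(pos)) or ""
        else:
            orient = strand.get(contig, "")
        if orient == "+":
            ag = ref == "A" and variant_base == "G"
        elif orient == "-":
            ag = ref == "T" and variant_base == "C"
        else:
            ag = None
        rows.append(
            {
                "contig": contig,
                "pos": int(pos),
                "ref": ref,
                "variant_base": variant_base,
                "vrs": vrs,
                "rs": rs,
                "rvf": rvf,
                "strand": orient,
                "is_ag_compatible": ag,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "contig", "pos", "ref", "variant_base", "vrs", "rs", "rvf",
            "strand", "is_ag_compatible",
        ],
    )
    known = table["is_ag_compatible"].dropna() if len(table) else pd.Series(dtype=object)
    frac = float(known.astype(bool).mean()) if len(known) else math.nan
    return table, frac
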