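"""Readers and writers for every tabular format the pipeline touches.

Formats
-------
* sample design: TSV with columns ``sample_id  stage  tissue  replicate  is_vm``
* expression matrix: TSV, first column gene IDs, header row of sample IDs
* variants: VCF 4.x subset (CHROM/POS/REF/ALT consumed, other columns
  ignored) or a 4-column TSV ``contig  pos  allele_a  allele_b``
* hit table: 12-column tabular alignment format extended with
  ``nident  qlen  slen`` (15 columns total)

All coordinates are 1-based inclusive, both at I/O boundaries and in the
in-memory tables; only point positions are used downstream, so no interval
arithmetic is ever performed on them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ReconciliationError

log = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")

HIT_COLUMNS = [
    "query", "target", "pident", "alnlen", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
    "nident", "qlen", "slen",
]


# ---------------------------------------------------------------------------
# sample design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleDesign:
    """One sequencing sample: its stage/tissue group, replicate and VM flag."""

    sample_id: str
    stage: str
    tissue: str = ""
    replicate: int = 1
    is_vm: bool = False

    @property
    def group(self) -> tuple[str, str]:
        """(stage, tissue) key identifying the replicate group."""
        return (self.stage, self.tissue)


class Design:
    """An ordered collection of :class:`SampleDesign` with lookup helpers."""

    def __init__(self, samples: Sequence[SampleDesign]):
        ids = [s.sample_id for s in samples]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise FormatError(f"duplicate sample_ids in design: {dupes}")
        if not samples:
            raise FormatError("design is empty")
        for s in samples:
            if s.replicate < 1:
                raise FormatError(f"sample {s.sample_id}: replicate must be >= 1")
        if all(s.is_vm for s in samples):
            raise FormatError("design must contain at least one non-VM group")
        self.samples: list[SampleDesign] = list(samples)
        self._by_id = {s.sample_id: s for s in samples}

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    def __getitem__(self, sample_id: str) -> SampleDesign:
        return self._by_id[sample_id]

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self._by_id

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def groups(self, include_vm: bool = True) -> dict[tuple[str, str], list[SampleDesign]]:
        """Samples keyed by (stage, tissue), in first-seen order."""
        out: dict[tuple[str, str], list[SampleDesign]] = {}
        for s in self.samples:
            if not include_vm and s.is_vm:
                continue
            out.setdefault(s.group, []).append(s)
        return out

    def is_vm_group(self, group: tuple[str, str]) -> bool:
        members = [s for s in self.samples if s.group == group]
        return bool(members) and any(s.is_vm for s in members)

    @property
    def stages(self) -> list[str]:
        seen: list[str] = []
        for s in self.samples:
            if s.stage not in seen:
                seen.append(s.stage)
        return seen

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in self.samples],
                "stage": [s.stage for s in self.samples],
                "tissue": [s.tissue for s in self.samples],
                "replicate": [s.replicate for s in self.samples],
                "is_vm": [s.is_vm for s in self.samples],
            }
        )


def read_design(path: str | Path) -> Design:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"sample_id", "stage", "replicate", "is_vm"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"design {path}: missing columns {sorted(missing)}")
    samples = []
    for _, row in df.iterrows():
        try:
            rep = int(row["replicate"])
        except ValueError as exc:
            raise FormatError(
                f"design {path}: non-integer replicate {row['replicate']!r}"
            ) from exc
        is_vm = str(row["is_vm"]).strip().lower() in ("1", "true", "yes")
        samples.append(
            SampleDesign(
                sample_id=row["sample_id"],
                stage=row["stage"],
                tissue=row.get("tissue", ""),
                replicate=rep,
                is_vm=is_vm,
            )
        )
    return Design(samples)


def write_design(design: Design, path: str | Path) -> None:
    design.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# expression matrix
# ---------------------------------------------------------------------------

class ExpressionMatrix:
    """Gene x sample FPKM matrix tied to a :class:`Design`.

    ``data`` is a pandas DataFrame with gene IDs as index and sample IDs as
    columns, column order matching the design order of the samples present.
    """

    def __init__(self, data: pd.DataFrame, design: Design):
        if data.index.has_duplicates:
            dupes = sorted(data.index[data.index.duplicated()].unique())
            raise FormatError(f"duplicate gene IDs: {dupes[:5]}")
        unknown = [c for c in data.columns if c not in design]
        if unknown:
            raise ReconciliationError(
                f"samples not in design: {sorted(unknown)}"
            )
        values = data.to_numpy(dtype=float)
        if np.isnan(values).any():
            raise FormatError("expression matrix contains missing values")
        if (values < 0).any():
            bad = data.columns[(values < 0).any(axis=0)][0]
            raise FormatError(f"negative expression value in sample {bad!r}")
        order = [sid for sid in design.sample_ids if sid in data.columns]
        self.data = data[order].astype(float)
        self.data.index.name = "gene"
        self.design = design

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    def group_means(self, include_vm: bool = True) -> pd.DataFrame:
        """Replicate-mean FPKM per (stage, tissue) group; columns are group keys."""
        cols = {}
        for group, members in self.design.groups(include_vm=include_vm).items():
            ids = [s.sample_id for s in members if s.sample_id in self.data.columns]
            if not ids:
                continue
            cols[group] = self.data[ids].mean(axis=1)
        return pd.DataFrame(cols)


def read_expression(path: str | Path, design_path: str | Path | Design) -> ExpressionMatrix:
    """Read a TSV expression matrix and validate it against a sample design."""
    design = design_path if isinstance(design_path, Design) else read_design(design_path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    try:
        return ExpressionMatrix(df, design)
    except (FormatError, ReconciliationError) as exc:
        raise type(exc)(f"{path}: {exc}") from exc


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    out = matrix.data.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t", float_format="%.10g")


# ---------------------------------------------------------------------------
# variants
# ---------------------------------------------------------------------------

def _looks_like_vcf(path: Path) -> bool:
    with open(path) as fh:
        for line in fh:
            if line.strip():
                return line.startswith("#")
    return False


def read_variants(path: str | Path) -> pd.DataFrame:
    """Read biallelic SNP sites distinguishing the two parental genomes.

    Accepts a VCF 4.x subset (only CHROM/POS/REF/ALT consumed) or a
    4-column TSV ``contig  pos  allele_a  allele_b``. Indels and
    multiallelic records are dropped with a logged count. Returns a
    DataFrame with columns ``contig, pos, allele_a, allele_b`` sorted by
    (contig, pos); positions are 1-based.
    """
    path = Path(path)
    rows: list[tuple[str, int, str, str]] = []
    dropped = 0
    is_vcf = _looks_like_vcf(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                continue
            fields = line.split("\t")
            if is_vcf:
                # VCF: CHROM POS ID REF ALT ...
                if len(fields) < 5:
                    raise FormatError(f"{path}:{lineno}: expected >=5 VCF columns")
                contig, pos_s, ref, alt = fields[0], fields[1], fields[3], fields[4]
            else:
                if len(fields) < 4:
                    raise FormatError(f"{path}:{lineno}: expected 4 TSV columns")
                contig, pos_s, ref, alt = fields[:4]
            try:
                pos = int(pos_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer position {pos_s!r}") from exc
            if pos < 1:
                raise FormatError(f"{path}:{lineno}: position must be >= 1")
            ref, alt = ref.upper(), alt.upper()
            if "," in alt or len(ref) != 1 or len(alt) != 1:
                dropped += 1
                continue
            if ref not in VALID_BASES or alt not in VALID_BASES:
                dropped += 1
                continue
            rows.append((contig, pos, ref, alt))
    if dropped:
        log.info("read_variants: dropped %d non-biallelic-SNP records from %s", dropped, path)
    if not rows:
        log.warning("read_variants: no usable variants in %s", path)
    df = pd.DataFrame(rows, columns=["contig", "pos", "allele_a", "allele_b"])
    df = df.sort_values(["contig", "pos"], kind="mergesort").reset_index(drop=True)
    dup = df.duplicated(subset=["contig", "pos"])
    if dup.any():
        first = df.loc[dup, ["contig", "pos"]].iloc[0]
        raise FormatError(
            f"{path}: duplicate variant position {first['contig']}:{first['pos']}"
        )
    return df


def write_variants(variants: pd.DataFrame, path: str | Path) -> None:
    variants[["contig", "pos", "allele_a", "allele_b"]].to_csv(
        path, sep="\t", index=False, header=False
    )


# ---------------------------------------------------------------------------
# hit tables
# ---------------------------------------------------------------------------

def read_hits(path: str | Path) -> pd.DataFrame:
    """Read a 15-column tabular alignment file (outfmt-6 + nident/qlen/slen).

    Adds derived ``qcov``/``scov`` fractions. Validates nident <= alnlen and
    positive lengths.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=HIT_COLUMNS)
    return validate_hits(df)


def validate_hits(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    for col in ("alnlen", "nident", "qlen", "slen"):
        df[col] = df[col].astype(int)
    if (df["qlen"] <= 0).any() or (df["slen"] <= 0).any():
        raise FormatError("hit table contains zero-length protein")
    if (df["nident"] > df["alnlen"]).any():
        raise FormatError("hit table: nident > alnlen")
    if (df["evalue"] < 0).any():
        raise FormatError("hit table: negative e-value")
    df["qcov"] = df["alnlen"] / df["qlen"]
    df["scov"] = df["alnlen"] / df["slen"]
    return df


def write_hits(df: pd.DataFrame, path: str | Path) -> None:
    df[HIT_COLUMNS].to_csv(path, sep="\t", index=False, header=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# generic small tables
# ---------------------------------------------------------------------------

def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def setup_logging(verbose: bool = False, quiet: bool = False) -> None:
    level = logging.WARNING if quiet else (logging.DEBUG if verbose else logging.INFO)
    logging.basicConfig(level=level, format="%(levelname)s %(name)s: %(message)s")
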