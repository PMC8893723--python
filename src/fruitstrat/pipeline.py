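"""End-to-end orchestration of the synthetic pipeline from one config.

Stages run in dependency order (simulate -> devexpr -> age -> tai ->
enrich -> ase); each stage records sha256 digests of its inputs and
outputs in a run manifest. A rerun skips a stage when its outputs exist
and its recorded input digests are unchanged. All outputs are written
deterministically, so two runs with the same seed produce byte-identical
files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from importlib.metadata import version as pkg_version
from pathlib import Path

import pandas as pd

from . import allele_expr, devexpr, phylostrat, synthetic
from .config import PipelineConfig
from .core_io import (
    Design,
    SampleDesign,
    read_design,
    read_expression,
    write_design,
    write_expression,
    ExpressionMatrix,
)
from .errors import FruitstratError

log = logging.getLogger(__name__)

MANIFEST_NAME = "manifest.json"

#: nine-tip caterpillar used for synthetic runs; sp9 is the focal species
DEFAULT_TREE = (
    "((((((((sp9:1,sp8:1):1,sp7:2):1,sp6:3):1,sp5:4):1,sp4:5):1,sp3:6):1,"
    "sp2:7):1,sp1:8):1;"
)
DEFAULT_FOCAL = "sp9"


def default_design(n_replicates: int = 3) -> Design:
    """VM + four fruiting-body stages, ``n_replicates`` each, no tissues."""
    samples = []
    for stage, is_vm in (("VM", True), ("P1", False), ("P3", False),
                         ("YFB", False), ("FB", False)):
        for rep in range(1, n_replicates + 1):
            samples.append(
                SampleDesign(
                    sample_id=f"{stage}_r{rep}", stage=stage, tissue="",
                    replicate=rep, is_vm=is_vm,
                )
            )
    return Design(samples)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _digests(base: Path, paths: list[Path]) -> dict[str, str]:
    return {str(p.relative_to(base)): _sha256(p) for p in sorted(paths)}


class _Stage:
    def __init__(self, name: str, inputs: list[Path], outputs: list[Path]):
        self.name = name
        self.inputs = inputs
        self.outputs = outputs

    def is_fresh(self, base: Path, previous: dict) -> bool:
        if not all(p.exists() for p in self.outputs):
            return False
        rec = previous.get("stages", {}).get(self.name)
        if rec is None:
            return False
        try:
            current = _digests(base, self.inputs)
        except FileNotFoundError:
            return False
        return rec.get("inputs") == current and rec.get("outputs") == _digests(
            base, self.outputs
        )


def run_pipeline(config: PipelineConfig, force: bool = False) -> dict:
    """Run all stages; returns the manifest dict (also written to disk)."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / MANIFEST_NAME
    previous = {}
    if manifest_path.exists() and not force:
        try:
            previous = json.loads(manifest_path.read_text())
        except json.JSONDecodeError:
            log.warning("unreadable manifest; rerunning all stages")

    cfg = config.to_dict()
    for key in ("input_dir", "output_dir"):
        cfg.pop(key)  # paths excluded so manifests compare across run dirs
    manifest: dict = {
        "tool": "fruitstrat",
        "version": _tool_version(),
        "seed": config.seed,
        "config": cfg,
        "stages": {},
    }

    paths = {
        "design": out / "design.tsv",
        "expression": out / "expression.tsv",
        "truth_expression": out / "truth_expression.tsv",
        "tree": out / "tree.nwk",
        "orthogroups": out / "orthogroups.tsv",
        "truth_orthogroups": out / "truth_orthogroups.tsv",
        "allele_counts": out / "allele_counts.tsv",
        "truth_allele": out / "truth_allele.tsv",
        "dev_calls": out / "dev_calls.tsv",
        "gene_age": out / "gene_age.tsv",
        "tai": out / "tai.tsv",
        "enrichment": out / "enrichment.tsv",
        "as_ratio": out / "as_ratio.tsv",
        "ase_calls": out / "ase_calls.tsv",
    }

    def record(stage: _Stage) -> None:
        manifest["stages"][stage.name] = {
            "inputs": _digests(out, stage.inputs),
            "outputs": _digests(out, stage.outputs),
        }

    def run_stage(stage: _Stage, fn) -> None:
        if not force and stage.is_fresh(out, previous):
            log.info("stage %s: up to date, skipped", stage.name)
            manifest["stages"][stage.name] = previous["stages"][stage.name]
            return
        log.info("stage %s: running", stage.name)
        try:
            fn()
        except Exception as exc:
            raise FruitstratError(f"stage {stage.name} failed: {exc}") from exc
        record(stage)

    # ------------------------------------------------------------------ simulate
    sim_outputs = [
        paths[k]
        for k in ("design", "expression", "truth_expression", "tree", "orthogroups",
                  "truth_orthogroups", "allele_counts", "truth_allele")
    ]
    simulate = _Stage("simulate", [], sim_outputs)

    def do_simulate() -> None:
        design = default_design()
        write_design(design, paths["design"])
        expr, truth_e = synthetic.gen_expression(
            config.n_genes, design, frac_dev=config.frac_dev,
            fc_range=(config.fc_low, config.fc_high), noise_sd=config.noise_sd,
            seed=config.seed,
        )
        matrix = ExpressionMatrix(expr, design)
        write_expression(matrix, paths["expression"])
        truth_e.reset_index().to_csv(paths["truth_expression"], sep="\t",
                                     index=False, float_format="%.10g")
        paths["tree"].write_text(DEFAULT_TREE + "\n")
        tree = phylostrat.SpeciesTree.from_newick(DEFAULT_TREE, DEFAULT_FOCAL)
        ogs, truth_o = synthetic.gen_orthogroups(
            tree, n_groups=config.n_genes, loss_prob=config.loss_prob,
            seed=config.seed + 1,
        )
        # one orthogroup per gene, aligned by rank
        genes = list(expr.index)
        ogs.index = genes
        ogs.index.name = "gene"
        truth_o.index = genes
        truth_o.index.name = "gene"
        ogs.reset_index().to_csv(paths["orthogroups"], sep="\t", index=False)
        truth_o.reset_index().to_csv(paths["truth_orthogroups"], sep="\t", index=False)
        counts, truth_a = synthetic.gen_allele_counts(
            config.n_genes, design, depth_mean=config.depth_mean,
            indecisive_frac=config.indecisive_frac, seed=config.seed + 2,
        )
        counts.to_csv(paths["allele_counts"], sep="\t", index=False, float_format="%.10g")
        truth_a.reset_index().to_csv(paths["truth_allele"], sep="\t", index=False,
                                     float_format="%.10g")

    run_stage(simulate, do_simulate)

    design = read_design(paths["design"])
    matrix = read_expression(paths["expression"], design)

    # ------------------------------------------------------------------ devexpr
    stage_dev = _Stage("devexpr", [paths["expression"], paths["design"]],
                       [paths["dev_calls"]])

    def do_devexpr() -> None:
        calls = devexpr.classify_developmental(
            matrix, fc_threshold=config.fc_threshold, min_fpkm=config.min_fpkm,
            zero_floor=config.zero_floor,
        )
        calls.reset_index().to_csv(paths["dev_calls"], sep="\t", index=False,
                                   float_format="%.10g")

    run_stage(stage_dev, do_devexpr)

    # ------------------------------------------------------------------ age
    stage_age = _Stage("age", [paths["orthogroups"], paths["tree"]],
                       [paths["gene_age"]])

    def do_age() -> None:
        tree = phylostrat.SpeciesTree.from_newick(paths["tree"], DEFAULT_FOCAL)
        ogs = pd.read_csv(paths["orthogroups"], sep="\t", index_col=0)
        ages = phylostrat.assign_ages(ogs.astype(bool), tree)
        ages.rename_axis("gene").reset_index().to_csv(paths["gene_age"], sep="\t",
                                                      index=False)

    run_stage(stage_age, do_age)

    ages = pd.read_csv(paths["gene_age"], sep="\t", index_col=0)["age"]

    # ------------------------------------------------------------------ tai
    stage_tai = _Stage("tai", [paths["expression"], paths["gene_age"], paths["design"]],
                       [paths["tai"]])

    def do_tai() -> None:
        profile = phylostrat.compute_tai(
            matrix, ages, log_mode=config.tai_log_mode, age_scale=config.age_scale
        )
        profile.to_csv(paths["tai"], sep="\t", index=False, float_format="%.10g")

    run_stage(stage_tai, do_tai)

    # ------------------------------------------------------------------ enrich
    stage_enrich = _Stage("enrich", [paths["dev_calls"], paths["gene_age"]],
                          [paths["enrichment"]])

    def do_enrich() -> None:
        calls = pd.read_csv(paths["dev_calls"], sep="\t", index_col=0)
        result = phylostrat.age_enrichment(calls["is_dev"].astype(bool), ages)
        result.to_csv(paths["enrichment"], sep="\t", index=False, float_format="%.10g")

    run_stage(stage_enrich, do_enrich)

    # ------------------------------------------------------------------ ase
    stage_ase = _Stage("ase", [paths["allele_counts"], paths["design"]],
                       [paths["as_ratio"], paths["ase_calls"]])

    def do_ase() -> None:
        counts = pd.read_csv(paths["allele_counts"], sep="\t")
        ratios = allele_expr.compute_as_ratio(
            counts, min_fpkm=config.ase_min_fpkm, min_decisive=config.min_decisive,
            max_indecisive_frac=config.max_indecisive_frac,
        )
        ratios.to_csv(paths["as_ratio"], sep="\t", index=False, float_format="%.10g")
        calls = allele_expr.classify_ase(
            ratios, design, s2_lo=config.s2_lo, s2_hi=config.s2_hi,
            s4_lo=config.s4_lo, s4_hi=config.s4_hi, gm_mode=config.gm_mode,
        )
        calls.reset_index().to_csv(paths["ase_calls"], sep="\t", index=False)

    run_stage(stage_ase, do_ase)

    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def _tool_version() -> str:
    try:
        return pkg_version("fruitstrat")
    except Exception:  # pragma: no cover - not installed
        return "unknown"
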