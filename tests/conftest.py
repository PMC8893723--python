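import numpy as np
import pandas as pd
import pytest

from fruitstrat.core_io import Design, ExpressionMatrix, SampleDesign
from fruitstrat.phylostrat import SpeciesTree
from fruitstrat.pipeline import DEFAULT_FOCAL, DEFAULT_TREE, default_design


@pytest.fixture
def design() -> Design:
    """VM + 4 stages, 3 replicates, no tissues."""
    return default_design()


@pytest.fixture
def tissue_design() -> Design:
    """A design with two tissues inside one stage."""
    samples = [SampleDesign("VM_r1", "VM", "", 1, True),
               SampleDesign("VM_r2", "VM", "", 2, True)]
    for stage in ("P1", "FB"):
        for tissue in ("", "gill") if stage == "FB" else ("",):
            for rep in (1, 2):
                sid = f"{stage}{('_' + tissue) if tissue else ''}_r{rep}"
                samples.append(SampleDesign(sid, stage, tissue, rep, False))
    return Design(samples)


@pytest.fixture
def species_tree() -> SpeciesTree:
    return SpeciesTree.from_newick(DEFAULT_TREE, DEFAULT_FOCAL)


@pytest.fixture
def small_tree() -> SpeciesTree:
    """7-tip caterpillar with focal tip 't7' (path nodes 1..7)."""
    nwk = "((((((t7:1,t6:1):1,t5:2):1,t4:3):1,t3:4):1,t2:5):1,t1:6):1;"
    return SpeciesTree.from_newick(nwk, "t7")


def make_matrix(group_means: dict[str, float], design: Design,
                genes: list[str] | None = None) -> ExpressionMatrix:
    """Expression matrix with identical replicates at the given stage means.

    ``group_means`` maps stage -> mean (single-gene) or stage -> list of
    per-gene means.
    """
    first = next(iter(group_means.values()))
    n_genes = len(first) if isinstance(first, (list, tuple)) else 1
    genes = genes or [f"g{i}" for i in range(n_genes)]
    data = {}
    for s in design.samples:
        v = group_means[s.stage]
        data[s.sample_id] = list(v) if isinstance(v, (list, tuple)) else [v]
    return ExpressionMatrix(pd.DataFrame(data, index=genes), design)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
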