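import warnings

import numpy as np
import pandas as pd
import pytest

from temporadt.data_model import ExperimentSet
from temporadt.pipeline import RunConfig, run_all

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def default_run():
    """One full default-condition pipeline run shared by integration tests."""
    return run_all(RunConfig(seed=1, out_dir=""))


@pytest.fixture()
def tiny_experiment():
    """Hand-built 4-gene experiment: 1 genotype, 2 timepoints, 3 replicates.

    geneA doubles under drought at T1, geneB is flat, geneC is barely
    expressed, geneD quadruples.
    """
    rng = np.random.default_rng(0)
    rows = {}
    samples = []
    base = {"geneA": 10.0, "geneB": 5.0, "geneC": 0.0005, "geneD": 8.0}
    fold = {
        ("geneA", "D", "T1"): 2.0,
        ("geneD", "D", "T1"): 4.0,
        ("geneD", "D", "T2"): 4.0,
    }
    for cond in ("W", "D"):
        for tp in ("T1", "T2"):
            for rep in (1, 2, 3):
                sid = f"G1_{cond}_{tp}_r{rep}"
                samples.append(
                    dict(sample_id=sid, genotype="G1", condition=cond,
                         timepoint=tp, replicate=rep)
                )
                col = {}
                for gene, b in base.items():
                    f = fold.get((gene, cond, tp), 1.0)
                    col[gene] = b * f * float(np.exp(rng.normal(0, 0.02)))
                rows[sid] = col
    expr = pd.DataFrame(rows)
    sheet = pd.DataFrame(samples).set_index("sample_id")
    return ExperimentSet(expression=expr, samples=sheet)
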