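import numpy as np
import pandas as pd
import pytest

from circscape import simulate as sim


@pytest.fixture(scope="session")
def world():
    """Default synthetic genome/annotation/truth (the study conditions)."""
    return sim.generate_annotation(sim.SimSpec(seed=7))


@pytest.fixture(scope="session")
def cohort_counts(world):
    return sim.simulate_cohort_counts(world.annotation, world.truth, sim.SimSpec(seed=7))


@pytest.fixture(scope="session")
def small_world():
    """Small cohort with reads-friendly size for SAM round trips."""
    spec = sim.SimSpec(
        seed=3, n_genes=20, n_samples_per_group={"A": 2, "B": 2}, suppressed_group="B"
    )
    return spec, sim.generate_annotation(spec)


def ratio_table_from_matrices(world, counts) -> pd.DataFrame:
    """bsj/linear summary rows straight from simulated count matrices."""
    lin_gene = pd.Series({n: n.split("|")[0] for n in counts.linear.index})
    lin_mean = counts.linear.groupby(lin_gene).mean()
    rows = []
    for rec in world.truth.circ_records:
        for s in counts.bsj.columns:
            rows.append(
                {
                    "circ_id": rec.circ_id,
                    "gene_id": rec.gene_id,
                    "sample": s,
                    "bsj": counts.bsj.loc[rec.circ_id, s],
                    "linear_all_mean": lin_mean.loc[rec.gene_id, s],
                    "linear_external_mean": np.nan,
                }
            )
    return pd.DataFrame(rows)
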