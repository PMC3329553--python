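import numpy as np
import pandas as pd
import pytest

import refstab as rs


@pytest.fixture
def hand_rq():
    """Three-gene toy matrix with a known geNorm solution.

    Genes A and B share the profile (0.25, 0.5, 1); C is flat, so its
    pairwise variation with either is 1.0 and M_C = 1.0, M_A = M_B = 0.5.
    """
    return pd.DataFrame(
        [[0.25, 0.5, 1.0], [0.25, 0.5, 1.0], [1.0, 1.0, 1.0]],
        index=["A", "B", "C"],
        columns=["s1", "s2", "s3"],
        dtype=float,
    )


@pytest.fixture
def long_cq_csv(tmp_path):
    path = tmp_path / "cq.csv"
    path.write_text(
        "sample,gene,plate,bio_rep,tech_rep,cq\n"
        "s1,g1,1,1,1,20.1\n"
        "s1,g1,1,1,2,20.3\n"
        "s1,g1,1,1,3,20.2\n"
    )
    return path


def analyse(config, target="TARGET"):
    """Simulate a config and run Cq -> RQ with the true efficiencies."""
    table, meta, truth = rs.simulate_cq(config)
    agg = rs.aggregate_technical(table)
    eff = {g.name: g.amp_factor for g in config.genes}
    rq = rs.to_relative_quantities(agg, eff)
    candidates = [g for g in rq.genes if g != target]
    return rq, rq.rq.loc[candidates], meta


@pytest.fixture(scope="session")
def study_run():
    """One deterministic study-like simulation analysed by all methods."""
    config = rs.study_like_config(seed=0)
    table, meta, _ = rs.simulate_cq(config)
    agg = rs.aggregate_technical(table)
    eff = {g.name: g.amp_factor for g in config.genes}
    rq = rs.to_relative_quantities(agg, eff)
    candidates = [g for g in rq.genes if g != "TARGET"]
    return {
        "config": config,
        "meta": meta,
        "rq": rq,
        "candidates": rq.rq.loc[candidates],
    }
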