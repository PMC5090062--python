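import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from mirhsr.quantify import CountMatrix
from mirhsr.simulate import SimParams, generate_annotation, simulate_counts


@pytest.fixture(scope="session")
def tiny_params() -> SimParams:
    return SimParams(
        seed=11,
        n_mirnas=12,
        n_clusters=2,
        cluster_size_range=(2, 2),
        depth=200_000,
        editing_sites=(("mir-2-5p", 5, "A>G", 0.3),),
    )


@pytest.fixture(scope="session")
def tiny_annotation(tiny_params):
    return generate_annotation(tiny_params)


@pytest.fixture(scope="session")
def tiny_counts(tiny_annotation, tiny_params):
    annotation, _ = tiny_annotation
    return simulate_counts(annotation, tiny_params)


def make_matrix(counts: dict, design_rows: list[tuple[str, float, int]]) -> CountMatrix:
    """Build a CountMatrix from {mirna: [counts per sample]} and design tuples."""
    samples = [f"{s}_t{t:g}_r{r}" for s, t, r in design_rows]
    df = pd.DataFrame(counts, index=samples).T
    design = pd.DataFrame(
        [{"strain": s, "timepoint_h": t, "replicate": r} for s, t, r in design_rows],
        index=pd.Index(samples, name="sample"),
    )
    lib = df.sum(axis=0).astype(float)
    return CountMatrix(df, design, lib)
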