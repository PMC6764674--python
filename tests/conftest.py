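import numpy as np
import pandas as pd
import pytest

from myocourse import ExpressionMatrix


def make_matrix(values, days=None, probes=None, flags=None, condition="tc"):
    """Small ExpressionMatrix builder for hand-written cases."""
    values = np.asarray(values, dtype=float)
    n_probes, n_samples = values.shape
    if probes is None:
        probes = [f"p{i}" for i in range(n_probes)]
    if days is None:
        days = list(range(n_samples))
    sample_ids = [f"s{i}" for i in range(n_samples)]
    vdf = pd.DataFrame(values, index=probes, columns=sample_ids)
    fdf = None
    if flags is not None:
        fdf = pd.DataFrame(np.asarray(flags, dtype=bool), index=probes,
                           columns=sample_ids)
    samples = pd.DataFrame(
        {"day": days, "condition": condition,
         "replicate": list(range(1, n_samples + 1))},
        index=sample_ids,
    )
    return ExpressionMatrix(values=vdf, flags=fdf, samples=samples)


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
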