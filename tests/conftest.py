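import numpy as np
import pandas as pd
import pytest

from lipidomix.profiling import Experiment


def make_experiment(
    values: dict[str, list[float]] | pd.DataFrame,
    n_case: int,
    n_control: int,
    log2_scale: bool = True,
) -> Experiment:
    """Build an Experiment directly from given per-lipid values.

    ``values`` maps lipid name -> per-sample values; the first ``n_case``
    columns are case samples.  ``log2_scale=True`` means the given values
    are on the log2 scale (abundance is derived as 2**x).
    """
    if isinstance(values, dict):
        frame = pd.DataFrame(values).T
    else:
        frame = values.copy()
    samples = [f"case_{i+1}" for i in range(n_case)] + [
        f"ctrl_{i+1}" for i in range(n_control)
    ]
    frame.columns = samples
    group_of = {s: ("case" if s.startswith("case") else "control") for s in samples}
    if log2_scale:
        log2 = frame.astype(float)
        abundance = np.power(2.0, log2)
    else:
        abundance = frame.astype(float)
        log2 = np.log2(abundance)
    return Experiment(abundance=abundance, log2=log2, group_of=group_of)


@pytest.fixture
def toy_experiment():
    """1 lipid, 3 vs 3, hand-pickable log2 values (case 4,5,6; control 1,2,3)."""
    return make_experiment({"TAG 48:0": [4, 5, 6, 1, 2, 3]}, n_case=3, n_control=3)


@pytest.fixture
def rng():
    return np.random.default_rng(20250922)
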