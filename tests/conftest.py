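import numpy as np
import pandas as pd
import pytest

from modscape import synthetic_data as sd


@pytest.fixture(scope="session")
def design():
    return sd.generate_design(sd.DesignSpec())


@pytest.fixture(scope="session")
def small_design():
    spec = sd.DesignSpec(ligands=("EGF", "OSM"), times=(0.0, 24.0, 48.0), replicates=3)
    return sd.generate_design(spec)


@pytest.fixture(scope="session")
def default_multiomic(design):
    return sd.generate_multiomic(design, sd.ModuleSpec(), seed=7)


def bh_bruteforce(p):
    """Independent step-up oracle: q_i = min_{j: p_j >= p_i over ranks} (m p_(j) / j)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    prev = np.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * m / rank)
        q[i] = min(val, 1.0)
        prev = val
    return q


@pytest.fixture(scope="session")
def bh_oracle():
    return bh_bruteforce
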