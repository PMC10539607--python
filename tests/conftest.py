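import numpy as np
import pandas as pd
import pytest

import coexnet as cx


def make_expr(values, genes=None, samples=None) -> pd.DataFrame:
    values = np.asarray(values, dtype=float)
    genes = genes or [f"G{i + 1}" for i in range(values.shape[0])]
    samples = samples or [f"S{j + 1}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=genes, columns=samples)


@pytest.fixture(scope="session")
def default_cohort():
    """One realization of the default planted-module cohort (5 x 60 + 1000 bg)."""
    expr, truth = cx.simulate_cohort(seed=11)
    return expr, truth


@pytest.fixture(scope="session")
def detected(default_cohort):
    """Modules, eigengenes and kME detected on the default cohort at power 6."""
    expr, truth = default_cohort
    adj = cx.build_adjacency(expr, 6)
    tom = cx.topological_overlap(adj)
    modules = cx.detect_modules(tom, min_module_size=30)
    eig = cx.compute_eigengenes(expr, modules)
    kme = cx.module_membership(expr, eig)
    return modules, eig, kme


def match_modules(detected_labels: pd.Series, truth_labels: pd.Series) -> dict:
    """Map each detected (non-grey) module to the planted module that dominates it."""
    mapping = {}
    for m in detected_labels.unique():
        if m == cx.GREY:
            continue
        genes = detected_labels.index[detected_labels == m]
        counts = truth_labels.loc[genes].value_counts()
        counts = counts[counts.index != 0]
        if len(counts):
            mapping[m] = int(counts.idxmax())
    return mapping
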