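import numpy as np
import pandas as pd
import pytest

from imd.io import ExpressionMatrix
from imd.simulate import BulkCohortConfig, simulate_bulk_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic cohort (60 patients x pre/on), generated once."""
    return simulate_bulk_cohort(seed=7)


@pytest.fixture(scope="session")
def small_cohort():
    """A small cohort for cheap end-to-end checks."""
    cfg = BulkCohortConfig(n_patients=10, timepoints=("pre", "on"))
    return simulate_bulk_cohort(cfg, seed=11)


@pytest.fixture()
def tiny_expr():
    rng = np.random.default_rng(0)
    vals = pd.DataFrame(
        rng.normal(5, 1, size=(30, 6)),
        index=[f"g{i}" for i in range(30)],
        columns=[f"s{i}" for i in range(6)],
    )
    return ExpressionMatrix(vals, scale="log2")


def brute_force_es(values: np.ndarray, names: np.ndarray, members: set,
                   weight_p: float = 1.0) -> float:
    """Literal running-sum GSEA oracle: walks the ranked list one gene at a
    time, tracking the extremes; ties in |deviation| resolve to the positive
    extreme (same convention as the implementation, stated explicitly)."""
    order = np.lexsort((names, -values))
    v = values[order]
    nm = np.asarray(names)[order]
    hit = np.isin(nm, list(members))
    n, k = len(v), int(hit.sum())
    nr = float(np.sum(np.abs(v[hit]) ** weight_p))
    if nr == 0:
        nr = float(k)
        weights = np.ones(n)
    else:
        weights = np.abs(v) ** weight_p
    run = 0.0
    pos_best, neg_best = 0.0, 0.0
    for i in range(n):
        run += weights[i] / nr if hit[i] else -1.0 / (n - k)
        pos_best = max(pos_best, run)
        neg_best = min(neg_best, run)
    return pos_best if pos_best >= -neg_best else neg_best


def assert_es_equal(module_es: float, oracle_es: float, tol: float = 1e-12):
    """ES agreement up to the positive-preference tie-break: when the walk's
    positive and negative extremes have exactly equal magnitude, floating
    point may resolve the tie differently between two correct computations."""
    if abs(module_es - oracle_es) <= tol:
        return
    assert abs(abs(module_es) - abs(oracle_es)) <= 1e-9, (
        f"ES magnitude mismatch: {module_es} vs {oracle_es}")
    assert abs(module_es + oracle_es) <= 1e-9, (
        f"ES sign mismatch outside a tie: {module_es} vs {oracle_es}")
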