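"""Shared fixtures: synthetic cohorts and fitted nested-CV runs.

Heavy fitted objects are session-scoped so several test modules can probe
the same run (AUC curve, stability, endophenotypes) without refitting.
"""

import pytest

import txclass as t
from txclass.ranking import RfConfig
from txclass.nested_cv import CvConfig


@pytest.fixture(scope="session")
def small_cohort():
    """Low-signal desk cohort for structural tests."""
    cfg = t.SimConfig(n_cases=80, n_controls=40, n_genes=500, n_sites=5,
                      n_informative=20, seed=101)
    return (*t.generate_cohort(cfg), cfg)


@pytest.fixture(scope="session")
def strong_cohort():
    """Separable cohort: 20 planted genes at |lfc| 2."""
    cfg = t.SimConfig(n_cases=100, n_controls=50, n_genes=400, n_sites=5,
                      n_informative=20, lfc_range=(2.0, 2.0), seed=202)
    return (*t.generate_cohort(cfg), cfg)


@pytest.fixture(scope="session")
def strong_run(strong_cohort):
    """Fitted nested-CV results on the separable cohort."""
    counts, meta, annot, truth, _ = strong_cohort
    expr, meta2, _ = t.run_preprocess(counts, meta, annot)
    model = t.NestedCVClassifier(
        expr, meta2,
        RfConfig(n_trees=60, n_repetitions=2),
        CvConfig(k_folds=5, n_repetitions=4, C_grid=[5, 20, 80]))
    res = model.fit(seed=11)
    return res, truth, expr, meta2, counts


@pytest.fixture(scope="session")
def null_cohort():
    """No planted signal, no batch/covariate structure."""
    cfg = t.SimConfig(n_cases=100, n_controls=50, n_genes=400, n_sites=5,
                      n_informative=0, seed=303)
    return (*t.generate_cohort(cfg), cfg)


def preprocess_and_fit(counts, meta, annot, *, rf, cv, seed):
    expr, meta2, _ = t.run_preprocess(counts, meta, annot)
    model = t.NestedCVClassifier(expr, meta2, rf, cv)
    return model.fit(seed=seed), expr, meta2
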