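"""Shared fixtures: the demonstration-scale strong-effect cohort run.

Built once per session (it costs a couple of minutes of CPU) and shared by
the end-to-end acceptance tests.
"""

import warnings

import pytest

from nldeeg.evaluation import (ClassifierSpec, SelectorSpec,
                               permutation_test, run_nested_loocv)
from nldeeg.features import CohortLabels
from nldeeg.pipeline import extract_cohort_features
from nldeeg.cohort import simulate_cohort
from nldeeg.presets import demo_effect, demo_strong_spec


@pytest.fixture(scope="session")
def strong_cohort_run():
    """Matched-size (14 vs 40) strong-effect cohort: feature table, labels,
    Pearson+SVM nested LOOCV run and its 200-permutation null."""
    spec = demo_strong_spec(seed=11)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        recordings, label_map = simulate_cohort(spec, demo_effect())
        table, excluded = extract_cohort_features(recordings)
    labels = CohortLabels(label_map)
    selector = SelectorSpec("pearson", 20)
    classifier = ClassifierSpec("svm_rbf")
    run = run_nested_loocv(table, labels, selector, classifier, seed=0)
    perm = permutation_test(table, labels, selector, classifier,
                            n_permutations=200, seed=1, cv_run=run)
    return {"spec": spec, "table": table, "labels": labels,
            "excluded": excluded, "run": run, "perm": perm,
            "selector": selector, "classifier": classifier}
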