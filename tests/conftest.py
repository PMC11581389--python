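"""Shared fixtures: small synthetic cohorts and cached pipeline stages.

Expensive stages (deep-feature extraction, stability selection) are
session-scoped so several tests can share one fitted pipeline.
"""

from __future__ import annotations

import pytest
from hypothesis import settings

import clinimage as ci

settings.register_profile("suite", deadline=None, max_examples=30, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def null_cohort() -> ci.ClinicalCohort:
    """Effect-0 cohort at the 5-year class prevalence, no missingness."""
    return ci.simulate_cohort(ci.SimulationConfig(n_per_class=(60, 180), seed=42))


@pytest.fixture(scope="session")
def separable_cohort() -> tuple[ci.ClinicalCohort, list[str]]:
    """Strongly separable cohort (5 informative features, 2-IQR shift)."""
    return ci.simulate_separable_cohort((72, 228), n_informative=5, delta=2.0, seed=3)


@pytest.fixture(scope="session")
def separable_split(separable_cohort):
    cohort, informative = separable_cohort
    split = ci.stratified_holdout(cohort, 0.8, seed=11)
    return cohort.subset(split.train_idx), cohort.subset(split.test_idx), informative


@pytest.fixture(scope="session")
def fitted_imager(separable_split) -> ci.TableToImageTransformer:
    train, _, _ = separable_split
    return ci.TableToImageTransformer().fit(train.values)


@pytest.fixture(scope="session")
def deep_features(separable_split, fitted_imager):
    """(train_features, test_features) pool2 matrices for the separable split."""
    train, test, _ = separable_split
    extractor = ci.Pool2FeatureExtractor(seed=0).fit()
    f_train = extractor.transform(fitted_imager.transform(train.values))
    f_test = extractor.transform(fitted_imager.transform(test.values))
    return f_train, f_test


@pytest.fixture(scope="session")
def small_classifier(separable_split) -> ci.RecurrenceClassifier:
    """Full pipeline fitted at desk scale (reduced stability scheme/forest)."""
    train, _, _ = separable_split
    clf = ci.RecurrenceClassifier(
        n_folds=5, n_rounds=1, rf_trees=150, random_state=7, extractor_seed=0
    )
    clf.fit(train.values, train.labels)
    return clf
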