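"""Shared fixtures: the shipped free-energy table and a desk-scale
synthetic study — 500 promoters with a TATA-like box planted at −31…−26
paired with shuffled negatives — reused by the classifier, explainer and
acceptance tests so the expensive pipeline runs once per session."""

from __future__ import annotations

import numpy as np
import pytest

from promdds import (
    PlantedElement,
    PromoterModelSpec,
    background_reference,
    build_labeled_dataset,
    default_table,
    encode_batch,
    explain_sample,
    generate_promoters,
    stratified_cv,
    train_classifier,
)

TATA_WINDOW = (-31, -26)  # TSS-relative span of the planted box


@pytest.fixture(scope="session")
def table():
    return default_table()


@pytest.fixture(scope="session")
def tata_spec():
    """TATA-only architecture, certain planting: the separable scenario."""
    return PromoterModelSpec(
        gc_fraction=0.5,
        elements=(PlantedElement("TTTAWA", -31, 1.0),),
        seed=11,
    )


@pytest.fixture(scope="session")
def planted_dataset(tata_spec):
    positives = generate_promoters(tata_spec, 500, seed=11)
    return build_labeled_dataset(positives, seed=12)


@pytest.fixture(scope="session")
def planted_xy(planted_dataset, table):
    mat = encode_batch(planted_dataset.records, table)
    y = np.array([r.label for r in planted_dataset.records], dtype=int)
    return mat, y


@pytest.fixture(scope="session")
def trained_model(planted_xy):
    mat, y = planted_xy
    return train_classifier(mat, y, kernel="rbf", seed=13)


@pytest.fixture(scope="session")
def cv_report(planted_xy):
    mat, y = planted_xy
    return stratified_cv(mat.values, y, k=10, seed=14)


@pytest.fixture(scope="session")
def explanations(planted_xy, trained_model):
    """Kernel-SHAP explanations of 100 non-repeated planted promoters."""
    mat, y = planted_xy
    from promdds.dds import FeatureMatrix

    pos = FeatureMatrix(
        values=mat.values[y == 1],
        position_labels=mat.position_labels,
        ids=tuple(np.array(mat.ids)[y == 1]),
    )
    background = background_reference(mat.values, size=100, seed=15)
    return explain_sample(trained_model, pos, background, n_explain=100, seed=16), pos
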