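import numpy as np
import pytest

from radstab.data_model import (
    ExtractionSet,
    ExtractionVariant,
    FeatureTable,
    LabelVector,
)
from radstab.synthetic import GeneratorConfig, generate_cohort


def make_table(values, lesion_ids=None, feature_names=None, classes=None):
    values = np.asarray(values, dtype=float)
    n, d = values.shape
    lesion_ids = lesion_ids or [f"L{i:03d}" for i in range(n)]
    feature_names = feature_names or [f"f{j}" for j in range(d)]
    classes = classes or {f: "texture" for f in feature_names}
    return FeatureTable(
        lesion_ids=lesion_ids,
        feature_names=feature_names,
        values=values,
        feature_class=classes,
    )


def make_extraction_set(variant_values, reference=ExtractionVariant("standard", 25.0),
                        **table_kwargs):
    """Build an ExtractionSet from a {variant: matrix} dict."""
    variants = {
        var: make_table(vals, **table_kwargs) for var, vals in variant_values.items()
    }
    return ExtractionSet(variants=variants, reference=reference)


@pytest.fixture(scope="session")
def small_cohort():
    """A 24-lesion cohort with one strongly informative feature."""
    cfg = GeneratorConfig(
        n_lesions=24,
        prevalence=0.5,
        n_geometric=2,
        n_texture=4,
        informative_features=((2, 2.5),),
        redundant_pairs=(),
        seed=7,
    )
    es, labels, truth = generate_cohort(cfg)
    return es, labels, truth


@pytest.fixture
def two_patient_set():
    """Hand-written 2-lesion, 3-variant set for longhand instability checks."""
    ref = ExtractionVariant("standard", 25.0)
    values = {
        ref: [[1.0, 10.0], [3.0, 20.0]],
        ExtractionVariant("reduced", 25.0): [[1.5, 12.0], [2.0, 16.0]],
        ExtractionVariant("increased", 25.0): [[0.5, 10.0], [3.5, 26.0]],
    }
    return make_extraction_set(values)
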