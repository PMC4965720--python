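"""Shared fixtures: tiny hand-built spaces for exact checks, and a small
synthetic corpus + trained grid for integration-level tests."""

import numpy as np
import pytest

import semforest as sf
from semforest.corpus import CANONICAL_DATA_TYPES, DataType


def make_episode(
    episode_id="e0",
    patient_id="p0",
    words=(("pain", "head"),),
    diagnoses=(("dgA", 0),),
    drugs=(("rxA", 0),),
    measurements=(("msA", 0),),
):
    """Small helper to build a CareEpisode from token/day tuples."""
    return sf.CareEpisode(
        patient_id=patient_id,
        episode_id=episode_id,
        sentences=[sf.Sentence(toks) for toks in words],
        diagnosis_events=[
            sf.Event(DataType.DIAGNOSIS, c, d) for c, d in diagnoses
        ],
        drug_events=[sf.Event(DataType.DRUG, c, d) for c, d in drugs],
        measurement_events=[
            sf.Event(DataType.MEASUREMENT, c, d) for c, d in measurements
        ],
    )


@pytest.fixture(scope="session")
def hand_ensemble():
    """dim-2 ensemble with hand-chosen vectors at windows 1 and 2.

    Vocabulary per type: word {pain, head}, diagnosis {dgA, dgB},
    drug {rxA, rxB}, measurement {msA}.
    """
    def vecs(mapping):
        return {k: np.array(v, dtype=float) for k, v in mapping.items()}

    spaces = {}
    for w in (1, 2):
        scale = float(w)
        spaces[(DataType.WORD, w)] = sf.SemanticSpace(
            DataType.WORD, w, 2,
            vecs({"pain": [1 * scale, 0], "head": [0, 1 * scale]}),
        )
        spaces[(DataType.DIAGNOSIS, w)] = sf.SemanticSpace(
            DataType.DIAGNOSIS, w, 2,
            vecs({"dgA": [2 * scale, 1], "dgB": [0, 3]}),
        )
        spaces[(DataType.DRUG, w)] = sf.SemanticSpace(
            DataType.DRUG, w, 2,
            vecs({"rxA": [1, 1], "rxB": [-1 * scale, 2]}),
        )
        spaces[(DataType.MEASUREMENT, w)] = sf.SemanticSpace(
            DataType.MEASUREMENT, w, 2, vecs({"msA": [0.5, -0.5]}),
        )
    return sf.SemanticSpaceEnsemble(
        spaces=spaces, data_types=CANONICAL_DATA_TYPES, windows=(1, 2), dim=2
    )


@pytest.fixture(scope="session")
def small_config():
    return sf.SynthConfig(n_patients=120, seed=11)


@pytest.fixture(scope="session")
def small_corpus(small_config):
    return sf.generate_corpus(small_config)


@pytest.fixture(scope="session")
def small_dataset(small_corpus, small_config):
    return sf.generate_ade_dataset(
        small_corpus, small_config.ade_code, 15, seed=3
    )


@pytest.fixture(scope="session")
def small_grid(small_corpus, small_config):
    """A quickly trained 4x2 space grid (dim 12) on the small corpus."""
    cfg = sf.SkipGramConfig(dim=12, epochs=8, seed=11)
    return sf.build_space_grid(
        small_corpus, [2, 3], cfg, exclude_code=small_config.ade_code
    )
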