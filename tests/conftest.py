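"""Shared fixtures.

The expensive fixture is ``desk_study``: one complete desk-profile regime-A
reproduction (trained model, held-out action episodes, balanced 0-30
embedding set) shared across the whole session by the analysis-level and
acceptance tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from numerosense import model, scenes

STUDY_SEED = 1


@dataclass
class DeskStudy:
    scene_config: scenes.SceneConfig
    net: model.PerceptionModel
    history: model.TrainingHistory
    test_episodes: list
    balanced: scenes.LabeledImageSet
    embeddings: np.ndarray


@pytest.fixture(scope="session")
def desk_scene_a() -> scenes.SceneConfig:
    return scenes.desk_config("A")


@pytest.fixture(scope="session")
def desk_study(desk_scene_a) -> DeskStudy:
    """Train the desk-profile regime-A model once for the whole session."""
    rng = np.random.default_rng(STUDY_SEED)
    net = model.build_model(model.ModelConfig(profile="desk"), rng)
    tcfg = model.desk_schedule()
    stream = scenes.sequence_stream(desk_scene_a, tcfg.actions_per_minibatch, rng)
    history = model.train(net, stream, tcfg, rng)
    episodes = [scenes.generate_training_sequence(desk_scene_a, 180, rng)
                for _ in range(20)]
    balanced = scenes.generate_balanced_test_set(desk_scene_a, range(31), 300, rng)
    z = net.embed(balanced.images)
    return DeskStudy(scene_config=desk_scene_a, net=net, history=history,
                     test_episodes=episodes, balanced=balanced, embeddings=z)


@pytest.fixture(scope="session")
def tiny_model() -> model.PerceptionModel:
    """Untrained desk model for contract/inference tests."""
    return model.build_model(model.ModelConfig(profile="desk"),
                             np.random.default_rng(123))
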