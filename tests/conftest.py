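import numpy as np
import pytest

from volvoloss.synthetic import (
    DEFAULT_DISTANCES,
    GenomeSynthConfig,
    make_toy_genomes,
    make_tree,
)

TARGET_DISTANCES = {s: d for s, d in DEFAULT_DISTANCES.items() if s != "Chlamydomonas"}


@pytest.fixture(scope="session")
def toy_clean():
    """Noise-free toy genomes with planted retain/decay/delete events."""
    return make_toy_genomes(GenomeSynthConfig(neutral_rate=0.0, seed=42))


@pytest.fixture(scope="session")
def toy_noisy():
    """Same planted design under 0.05 substitutions/site of neutral noise."""
    return make_toy_genomes(GenomeSynthConfig(neutral_rate=0.05, seed=42))


@pytest.fixture(scope="session")
def target_tree():
    """Ladder tree of the five multicellular target species."""
    return make_tree(TARGET_DISTANCES)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def classify_toy(toy, target_tree, **kwargs):
    """Run the loss classifier over every group of a toy-genome bundle."""
    from volvoloss.synteny import classify_losses

    return classify_losses(
        toy["config"].anchor_species,
        toy["annotations"],
        toy["ortholog_table"],
        sorted(set(toy["groups"].values())),
        species_tree=target_tree,
        **kwargs,
    )


def toy_accuracy(toy, result):
    """Fraction of planted events reproduced by the classifier's calls."""
    label = {"retain": "retained", "decay": "decayed", "delete": "deleted"}
    calls = result["calls_table"].set_index(["anchor_gene", "species"])["call"]
    truth = toy["truth"]
    hits = sum(
        calls.loc[(r.anchor_gene, r.species)] == label[r.event]
        for r in truth.itertuples()
    )
    return hits / len(truth)


@pytest.fixture(scope="session")
def toy_clean_calls(toy_clean, target_tree):
    return classify_toy(toy_clean, target_tree)
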