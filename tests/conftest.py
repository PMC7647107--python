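import itertools

import numpy as np
import pytest

from hwtbbn import (BbnModel, Cpt, NetworkSpec, default_codebook,
                    default_ground_truth, generate)


@pytest.fixture(scope="session")
def codebook():
    return default_codebook()


@pytest.fixture(scope="session")
def small_survey():
    """n=60 synthetic survey with the default study conditions."""
    truth = default_ground_truth()
    return generate(truth, 60, seed=7)


@pytest.fixture(scope="session")
def study_survey():
    """Study-sized (n=202) synthetic survey."""
    truth = default_ground_truth()
    return generate(truth, 202, seed=11)


def make_random_model(rng: np.random.Generator, n_nodes: int,
                      max_card: int = 4, edge_p: float = 0.4) -> BbnModel:
    """Random DAG over n_nodes with Dirichlet CPTs (edges respect order)."""
    names = [f"n{i}" for i in range(n_nodes)]
    cards = rng.integers(2, max_card + 1, size=n_nodes)
    nodes = {names[i]: tuple(f"s{j}" for j in range(cards[i]))
             for i in range(n_nodes)}
    edges = [(names[i], names[j]) for i, j in
             itertools.combinations(range(n_nodes), 2)
             if rng.random() < edge_p]
    spec = NetworkSpec(nodes=nodes, edges=edges)
    cpts = {}
    for i, name in enumerate(names):
        parents = spec.parents(name)
        shape = tuple(cards[names.index(p)] for p in parents)
        table = rng.dirichlet(np.ones(cards[i]), size=shape or None)
        cpts[name] = Cpt(node=name, parents=parents, values=np.asarray(table))
    model = BbnModel(spec=spec, cpts=cpts)
    model.validate()
    return model


@pytest.fixture
def random_model_factory():
    return make_random_model


def random_evidence(rng: np.random.Generator, model: BbnModel,
                    max_nodes: int = 3) -> dict:
    """Evidence on a random subset of nodes (possibly empty)."""
    names = list(model.spec.nodes)
    k = int(rng.integers(0, max_nodes + 1))
    chosen = rng.choice(names, size=min(k, len(names)), replace=False)
    return {n: model.spec.nodes[n][rng.integers(model.spec.card(n))]
            for n in chosen}
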