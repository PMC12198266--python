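import numpy as np
import pytest

from aaokit import synthetic


@pytest.fixture(scope="session")
def clean_bundle():
    """Small mutation-free family: one generation per session."""
    config = synthetic.SynthConfig(n_per_type=3, mutation_rate=0.0, seed=101)
    records, truths = synthetic.generate_family(config)
    return config, records, truths


@pytest.fixture(scope="session")
def clean_references(clean_bundle):
    config, _, _ = clean_bundle
    return synthetic.reference_records(config), synthetic.reference_anchors(config)


@pytest.fixture(scope="session")
def study_bundle():
    """Full-size study conditions: 45 per (kingdom, type) cell, mutation-free,
    plus 5 decoys per ablated feature and kingdom (60 decoys)."""
    config = synthetic.SynthConfig(n_per_type=45, mutation_rate=0.0, seed=7)
    records, truths = synthetic.generate_family(config)
    decoy_config = synthetic.SynthConfig(n_per_type=5, mutation_rate=0.0, seed=7)
    for feature in synthetic.FEATURES:
        recs, trus = synthetic.generate_decoys(decoy_config, feature)
        records.extend(recs)
        truths.extend(trus)
    return config, records, truths


def random_rooted_tree(rng: np.random.Generator, n_leaves: int) -> str:
    """Random binary tree in Newick form with strictly positive lengths."""
    nodes = [f"T{i}" for i in range(n_leaves)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        li, lj = rng.integers(1, 9, size=2) * 0.25
        merged = f"({nodes[i]}:{li},{nodes[j]}:{lj})"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return nodes[0] + ";"
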