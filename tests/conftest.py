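import itertools

import numpy as np
import pytest

from limbjoints import io
from limbjoints.synthetic import SyntheticConfig, generate_all


@pytest.fixture(scope="session")
def fossils():
    return io.load_fossils()


@pytest.fixture(scope="session")
def fossil_by_id(fossils):
    return {f.specimen_id: f for f in fossils}


@pytest.fixture(scope="session")
def summaries():
    return io.load_extant_summaries()


@pytest.fixture(scope="session")
def extant_samples(summaries):
    """One default synthetic draw of all five extant taxa."""
    return generate_all(summaries, SyntheticConfig(seed=12345, rho=0.8))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


# ---------------------------------------------------------------------------
# independent brute-force parsimony oracle (enumerates all labelings)

def brute_force_parsimony(tree, tip_states, root_prior=None):
    """Minimum changes and all optimal labelings by exhaustive enumeration.

    Independent of the Sankoff implementation: walks every assignment of
    high/low to the internal nodes and counts mismatched edges directly
    (plus the virtual stem edge when a root prior is given).
    """
    nodes = list(tree.postorder())
    internal = [n for n in nodes if not n.is_leaf]
    edges = [(p.id, c.id) for p in nodes for c in p.children]
    fixed = {n.id: tip_states[n.label] for n in nodes if n.is_leaf}

    best, optimal = float("inf"), []
    for combo in itertools.product(("high", "low"), repeat=len(internal)):
        states = dict(fixed)
        states.update({n.id: s for n, s in zip(internal, combo)})
        changes = sum(states[p] != states[c] for p, c in edges)
        if root_prior is not None and states[tree.root.id] != root_prior:
            changes += 1
        if changes < best:
            best, optimal = changes, [states]
        elif changes == best:
            optimal.append(states)
    return best, optimal


def random_tree_newick(rng, n_tips):
    """Random rooted tree over tips t0..t{n-1}, with occasional polytomies."""
    groups = [f"t{i}" for i in range(n_tips)]
    while len(groups) > 1:
        k = 3 if (len(groups) >= 3 and rng.random() < 0.2) else 2
        idx = rng.choice(len(groups), size=k, replace=False)
        merged = "(" + ",".join(groups[i] for i in sorted(idx)) + ")"
        groups = [g for i, g in enumerate(groups) if i not in idx]
        groups.append(merged)
    return groups[0] + ";"
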