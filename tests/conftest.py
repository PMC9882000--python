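import numpy as np
import pytest

import hetpath as hp
from hetpath.fixtures import FixtureSpec, MetaedgeSpec, MetanodeSpec


@pytest.fixture
def triangle():
    """One metanode Gene with an interacts triangle (T1)."""
    return hp.toy_T1()


@pytest.fixture
def compound_gene():
    """Compound-binds-Gene toy with edges c1-g1, c1-g2, c2-g2 (T2)."""
    return hp.toy_T2()


@pytest.fixture
def compound_disease():
    """Compound-treats-Disease toy with edges c1-d1, c1-d2, c2-d1 (T2')."""
    return hp.toy_T2prime()


@pytest.fixture
def pattern_metagraph():
    """A metagraph rich enough to spell out every repeat pattern by hand:
    metanodes A..F, with same-metanode metaedges on A and B."""
    mns = {a: hp.Metanode(f"Type{a}", a) for a in "ABEF"}
    mes = [
        hp.Metaedge(mns["A"], mns["A"], "kind_w", "w"),
        hp.Metaedge(mns["A"], mns["A"], "kind_v", "v"),
        hp.Metaedge(mns["A"], mns["B"], "kind_x", "x"),
        hp.Metaedge(mns["B"], mns["B"], "kind_y", "y"),
        hp.Metaedge(mns["B"], mns["E"], "kind_z", "z"),
        hp.Metaedge(mns["A"], mns["E"], "kind_t", "t"),
        hp.Metaedge(mns["E"], mns["F"], "kind_u", "u"),
    ]
    return hp.Metagraph(mns.values(), mes)


def small_bipartite_spec(seed: int, n_a: int = 10, n_b: int = 10, density: float = 0.3):
    return FixtureSpec(
        metanodes=(
            MetanodeSpec("TypeA", "A", n_a),
            MetanodeSpec("TypeB", "B", n_b),
        ),
        metaedges=(MetaedgeSpec("A", "B", "kind_x", "x", density=density),),
        seed=seed,
    )


@pytest.fixture
def random_store():
    def factory(seed: int, **kwargs) -> hp.HetnetStore:
        return hp.make_fixture(hp.fixtures.random_fixture_spec(seed, **kwargs))

    return factory
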