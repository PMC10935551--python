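import numpy as np
import pytest

from hgtrace.foodweb import FoodWebModel, FunctionalGroup


def make_group(name, cls="consumer", B=1.0, PB=1.0, QB=None, EE=0.5, **kw):
    if QB is None:
        QB = 0.0 if cls in ("producer", "detritus") else max(PB, 1.0) * 3
    return FunctionalGroup(
        name=name, group_class=cls, biomass=B, production_rate=PB,
        consumption_rate=QB, ecotrophic_efficiency=EE, **kw,
    )


def make_web(groups, diet, area=570_000.0, depth=95.0):
    return FoodWebModel(groups=tuple(groups), diet=np.asarray(diet, float),
                        area=area, depth=depth)


@pytest.fixture
def two_group_web():
    """Producer grazed by a single consumer; exactly balanced (EE 0.5)."""
    producer = make_group("kelp", "producer", B=100.0, PB=10.0, EE=0.5)
    grazer = make_group("urchin", "consumer", B=10.0, PB=5.0, QB=50.0, EE=0.0)
    diet = [[0.0, 0.0], [1.0, 0.0]]
    return make_web([producer, grazer], diet)


@pytest.fixture
def chain3_web():
    """Producer -> zooplankton -> fish chain (fish splits its diet 50/50)."""
    producer = make_group("phyto", "producer", B=50.0, PB=40.0, EE=0.2,
                          direct_uptake=True)
    zoo = make_group("zoo", "consumer", B=10.0, PB=10.0, QB=40.0, EE=0.5,
                     direct_uptake=True)
    fish = make_group("fish", "consumer", B=2.0, PB=2.0, QB=8.0, EE=0.0,
                      muscle_fraction=0.5, commercial=True)
    diet = [
        [0.0, 0.0, 0.0],
        [1.0, 0.0, 0.0],
        [0.5, 0.5, 0.0],
    ]
    return make_web([producer, zoo, fish], diet)
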