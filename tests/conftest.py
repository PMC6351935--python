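import pytest

from spar_access import CityConfig, SpeedMap, generate_city
from spar_access.e2sfca import accessibility_analysis, shortage_summary
from spar_access.pipeline import build_mode_networks


@pytest.fixture(scope="session")
def small_city():
    """A 6x6-block city: fast, with every layer present."""
    return generate_city(CityConfig(seed=11, blocks_per_side=6, clinic_count=4))


@pytest.fixture(scope="session")
def default_city():
    """The default 20x20-block city used for the headline comparisons."""
    return generate_city(CityConfig(seed=42))


@pytest.fixture(scope="session")
def default_city_access(default_city):
    """Accessibility records for all three modes on the default city."""
    nets = build_mode_networks(default_city, SpeedMap(),
                               ["drive", "walk", "multimodal"])
    pops = {p.id: p for p in default_city.das}
    out = {}
    for mode, net in nets.items():
        records, ratios = accessibility_analysis(net, default_city.clinics,
                                                 default_city.das)
        out[mode] = {
            "records": records,
            "ratios": ratios,
            "shortage": shortage_summary(records, pops),
        }
    return out
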