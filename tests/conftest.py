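import copy

import pytest

from lvad_cea.parameters import load_parameters, to_dict
from lvad_cea.synthetic import generate_cost_tables


@pytest.fixture(scope="session")
def params():
    return load_parameters()


@pytest.fixture(scope="session")
def cost_tables():
    return generate_cost_tables(42)


@pytest.fixture(scope="session")
def ss_costs(cost_tables):
    return cost_tables["SS"]


def strip_uncertainty(tree):
    """Remove every SE and variability range from a parameter config tree,
    leaving only base values (degenerate distributions)."""
    if isinstance(tree, dict):
        out = {}
        for key, value in tree.items():
            if key in ("se", "low", "high", "lows", "highs"):
                continue
            out[key] = strip_uncertainty(value)
        return out
    if isinstance(tree, list):
        return [strip_uncertainty(v) for v in tree]
    return copy.deepcopy(tree)


@pytest.fixture(scope="session")
def degenerate_params(params):
    return load_parameters(strip_uncertainty(to_dict(params)), merge_defaults=False)
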