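import pandas as pd
import pytest

from toxtriage.registry import Registry


@pytest.fixture
def small_registry():
    reg = Registry()
    reg.register("107-36-8", "Isethionic acid", "OCCS(=O)(=O)O")
    reg.register("98-95-3", "Nitrobenzene", "O=[N+]([O-])c1ccccc1")
    reg.register("7647-14-5", "Sodium chloride", "[Na+].[Cl-]")
    reg.register("9009-54-5", "Polyurethane")  # no structure
    return reg


@pytest.fixture
def labels_frame(small_registry):
    from toxtriage.integration import integrate_all

    return integrate_all(small_registry, []).labels


def make_labels(rows):
    """rows: (cas, endpoint, value) triples -> integrated label frame."""
    return pd.DataFrame(
        [{"cas": c, "endpoint": e, "value": v, "provenance": "integrated"}
         for c, e, v in rows],
        columns=["cas", "endpoint", "value", "provenance"],
    )
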