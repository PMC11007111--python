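import numpy as np
import pytest

import textode as tx
from textode.simulate import SimulationCondition

DECAY_TEXT = "A is degraded | kf=0.5\n@init A = 1\n"

BIND_TEXT = "A binds B --> AB\n@init A = 1\n@init B = 1\n"

CYCLE_TEXT = "S0 is phosphorylated --> pS0\n@init S0 = 1\n"

# synthesize -> state transition -> degrade, observed through normalized
# phospho/total immunoblot-style readouts.  Three conditions: two stimulus
# levels plus a phospho-loaded relaxation experiment that isolates the
# reverse (dephosphorylation) rate, making all four rate constants
# practically identifiable at 5% noise.
RECOVERY_TEXT = """A is synthesized
A is phosphorylated --> pA
pA is degraded
@obs A: A
@obs pA: pA
@obs total: A + pA
@init A = 1
"""

RECOVERY_TRUTH = {"kf_r1": 0.5, "kf_r2": 1.2, "kr_r2": 0.4, "kf_r3": 0.8}


@pytest.fixture
def decay_model():
    return tx.ReactionNetworkModel.from_text(DECAY_TEXT)


@pytest.fixture
def bind_model():
    return tx.ReactionNetworkModel.from_text(BIND_TEXT)


@pytest.fixture
def diamond_model():
    return tx.ReactionNetworkModel.from_text(tx.fixtures.make_diamond_model())


@pytest.fixture
def recovery_setup():
    """Model + true parameters + conditions for the recovery benchmark."""
    m = tx.ReactionNetworkModel.from_text(RECOVERY_TEXT)
    true = m.compiled.parameter_values()
    names = m.compiled.parameter_names
    for n, v in RECOVERY_TRUTH.items():
        true[names.index(n)] = v
    conds = [
        SimulationCondition("basal", {"A": 1.0}, 10.0, 50),
        SimulationCondition("stimulus", {"A": 3.0}, 10.0, 50),
        SimulationCondition("phospho_loaded", {"A": 0.0, "pA": 2.0}, 10.0, 50),
    ]
    return m, true, conds


def assert_in_span(vectors, target):
    """target must lie in the integer span of the vectors (least squares)."""
    A = np.array(vectors, dtype=float).T
    target = np.asarray(target, dtype=float)
    coef, *_ = np.linalg.lstsq(A, target, rcond=None)
    assert np.allclose(A @ coef, target, atol=1e-10)
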