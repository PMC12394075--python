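import numpy as np
import pytest

import smfretkit as sk


@pytest.fixture(scope="session")
def slow_two_state_model():
    """Two-state model in the idealization-friendly regime (kτ ≈ 0.1)."""
    return sk.KineticModel.two_state(1.0, 1.0, 0.38, 0.63, 0.05)


@pytest.fixture(scope="session")
def fast_two_state_model():
    """Two-state model switching far above the frame rate."""
    return sk.KineticModel.two_state(100.0, 100.0, 0.38, 0.63, 0.05)


@pytest.fixture(scope="session")
def slow_trace_set(slow_two_state_model):
    traces, truths = sk.simulate_trace_set(slow_two_state_model, 60, 600,
                                           0.1, seed=11)
    return traces, truths


@pytest.fixture(scope="session")
def toy_pair_frame():
    atoms = [("A", 248, "ALA", "CA", "C", (0.0, 0.0, 0.0)),
             ("B", 248, "ALA", "CA", "C", (38.2, 0.0, 0.0))]
    return sk.make_toy_frames(atoms)[0]


def ideal_helix(chain, n=14, start_res=95, transform=None, offset=(0, 0, 0)):
    """Cα trace of an ideal α-helix along +z (100°/residue, 1.5 Å rise)."""
    out = []
    for i in range(n):
        ang = np.radians(100.0 * i)
        xyz = np.array([2.3 * np.cos(ang), 2.3 * np.sin(ang), 1.5 * i])
        if transform is not None:
            xyz = np.asarray(transform) @ xyz
        out.append((chain, start_res + i, "ALA", "CA", "C",
                    tuple(xyz + np.asarray(offset, dtype=float))))
    return out
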