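import numpy as np
import pytest

import anharmvoa as av


@pytest.fixture()
def morse_system():
    return av.make_morse_system(3000.0, 50.0)


@pytest.fixture()
def small_random_system():
    """Mildly anharmonic, resonance-free 2-mode system with all five tensors."""
    spec = av.GeneratorSpec(n_modes=2, omega_range=(700, 2600), cubic_scale=30,
                            quartic_scale=4, min_fermi_detuning=400, seed=42)
    return av.make_random_system(spec)


@pytest.fixture()
def fermi_dyad_system():
    """Overtone-type Fermi dyad: 2 omega_1 ~ omega_2, planted f_112."""
    spec = av.GeneratorSpec(n_modes=2, omega_range=(800, 1500), cubic_scale=15,
                            quartic_scale=3, seed=0,
                            resonance_plan=[av.FermiPlan(0, 0, 1, detuning=10.0, f=40.0)])
    return av.make_random_system(spec)
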