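import pytest

from alpharep.binding.itc import ITCExperiment, OneSiteParams


@pytest.fixture
def a3_ba317_setup():
    """Direct titration of the weaker A3 binder: cell 30 µM, syringe 350 µM,
    K_d 141 nM, n 0.9."""
    return (
        OneSiteParams(kd=141e-9, n=0.9, delta_h=-10.0),
        ITCExperiment(cell_conc=30e-6, syringe_conc=350e-6),
    )


@pytest.fixture
def ncs_setup():
    """Micromolar-affinity titration: cell 20 µM, syringe 211 µM,
    K_d 1.4 µM, n 1.4."""
    return (
        OneSiteParams(kd=1.4e-6, n=1.4, delta_h=-10.0),
        ITCExperiment(cell_conc=20e-6, syringe_conc=211e-6),
    )
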