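import numpy as np
import pytest

from pkanalog import AnalogParameters


@pytest.fixture
def defaults() -> AnalogParameters:
    return AnalogParameters()


@pytest.fixture
def small() -> AnalogParameters:
    """Default dynamics on a small grid, for fast multi-run tests."""
    return AnalogParameters(grid_width=20, grid_height=20)


def random_params(rng: np.random.Generator, *, max_dim: int = 10,
                  probs_one: bool = False, evap: bool = False) -> AnalogParameters:
    """Draw a random valid parameterization for property-style tests."""
    def frac() -> float:
        return float(rng.uniform(0.0, 1.0))

    def prob() -> float:
        return 1.0 if probs_one else frac()

    def delay() -> int:
        return int(rng.integers(0, 5))

    dim = (1, 1) if probs_one else (int(rng.integers(1, max_dim + 1)),
                                    int(rng.integers(1, max_dim + 1)))
    return AnalogParameters(
        grid_width=dim[0], grid_height=dim[1],
        init_dose=float(rng.uniform(100.0, 20000.0)),
        d_to_g_delay=delay(), d_to_g_fract=frac(), d_to_g_prob=prob(),
        diff_g_ratio=frac(),
        g_to_c_delay=delay(), g_to_c_fract=frac(), g_to_c_prob=prob(),
        ga_to_p_delay=delay(), ga_to_p_fract=frac(), ga_to_p_prob=prob(),
        gb_to_p_delay=delay(), gb_to_p_fract=frac(), gb_to_p_prob=prob(),
        gc_to_p_delay=delay(), gc_to_p_fract=frac(), gc_to_p_prob=prob(),
        p_to_e_delay=delay(), p_to_e_fract=frac(), p_to_e_prob=prob(),
        disperse_rate=frac(),
        evap_rate=float(rng.uniform(0.0, 0.3)) if evap else 0.0,
        disperse_count=int(rng.integers(0, 4)),
    )
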