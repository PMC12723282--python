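import numpy as np
import pytest

import scratchkit as sk


@pytest.fixture(scope="session")
def plate6():
    return sk.load_preset("6well")


@pytest.fixture(scope="session")
def plate24():
    return sk.load_preset("24well")


@pytest.fixture(scope="session")
def plate96():
    return sk.load_preset("96well")


@pytest.fixture(scope="session")
def single_line_spec():
    """The validated single-scratch protocol: one centered line, 2 mm offset,
    6000 mm/min feeds, 2 cycles."""
    return sk.PatternSpec(mode="mesh", line_number=1, line_distance=0.0)


@pytest.fixture(scope="session")
def mesh18_spec():
    """The full-well mesh protocol: 18 lines spaced 1.6 mm."""
    return sk.PatternSpec(mode="mesh", line_number=18, line_distance=1.6)


@pytest.fixture(scope="session")
def single_line_program_24(plate24, single_line_spec):
    r = sk.safe_radius(plate24, single_line_spec.tip_offset)
    paths = sk.generate_paths(single_line_spec, r)
    return sk.emit_program(plate24, sk.all_wells(plate24), paths, single_line_spec)


@pytest.fixture(scope="session")
def mesh18_program_6(plate6, mesh18_spec):
    r = sk.safe_radius(plate6, mesh18_spec.tip_offset)
    paths = sk.generate_paths(mesh18_spec, r)
    return sk.emit_program(plate6, sk.all_wells(plate6), paths, mesh18_spec)


def random_pattern_spec(rng: np.random.Generator, r_safe: float) -> sk.PatternSpec:
    """Draw a random mesh/grid/circle spec valid for a given safe radius."""
    mode = rng.choice(["mesh", "grid", "circle"])
    if mode == "circle":
        return sk.PatternSpec(
            mode="circle",
            inner_radius=float(rng.uniform(0.1, 1.0)) * r_safe,
            radial_step=float(rng.uniform(0.05, 0.5)) * r_safe,
            tip_offset=float(rng.uniform(0.5, 3.0)),
        )
    n = int(rng.integers(1, 12))
    # keep the outermost offset (n-1)/2 * d strictly inside the safe circle
    d_max = (2.0 * r_safe * 0.95) / n if n > 1 else 0.0
    return sk.PatternSpec(
        mode=mode,
        line_number=n,
        line_distance=float(rng.uniform(0.05, 1.0)) * d_max if n > 1 else 0.0,
        rotation=int(rng.choice([0, 90])),
        tip_offset=float(rng.uniform(0.5, 3.0)),
    )
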