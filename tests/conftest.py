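import numpy as np
import pytest

from autopatch import (
    PhantomSpec,
    darkness_map,
    generate_cell_phantom_stack,
    generate_pipette_phantom,
    initialize_pipette_model,
    refine_pipette_model,
)


@pytest.fixture(scope="session")
def pipette_case():
    """One noiseless pipette phantom with its darkness map and ground truth."""
    stack, truth = generate_pipette_phantom(seed=1)
    dmap = darkness_map(stack)
    return {"stack": stack, "truth": truth, "dmap": dmap}


@pytest.fixture(scope="session")
def refined_pipette(pipette_case):
    """Full init + refine run on the session phantom (expensive, shared)."""
    init = initialize_pipette_model(pipette_case["stack"], dmap=pipette_case["dmap"])
    model, trace = refine_pipette_model(pipette_case["dmap"], init)
    return {"init": init, "model": model, "trace": trace, **pipette_case}


@pytest.fixture(scope="session")
def cell_stack():
    """Default-condition cell phantom: 8 somata in a 60-slice stack."""
    spec = PhantomSpec(n_cells=8, seed=3)
    stack, cells = generate_cell_phantom_stack(spec)
    return {"spec": spec, "stack": stack, "cells": cells}


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
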