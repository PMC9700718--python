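"""Shared fixtures: small genome layouts and simulated Pu-seq datasets."""

import numpy as np
import pytest

from puseq.tracks import GenomeLayout
from puseq.usage import compute_usage
from puseq.simulate import (LibraryModel, ReplicationModel, default_model,
                            simulate_counts)


@pytest.fixture(scope="session")
def small_layout():
    return GenomeLayout({"chr1": 100_000, "chr2": 50_000})


@pytest.fixture(scope="session")
def recovery_sim():
    """10-Mb, 20-origin fixture at 200 reads/bin: the parameter-recovery
    study conditions (idealised library: no residual, no background)."""
    layout = GenomeLayout({"chrSim": 10_000_000})
    model = default_model(layout, n_origins=20, seed=0)
    library = LibraryModel(depth=200.0, residual=0.0, background=0.0,
                           control_depth=200.0)
    sim = simulate_counts(model, library, seed=0)
    profile = compute_usage(sim["eps"], sim["alpha"], sim["control"])
    return {"layout": layout, "model": model, "library": library,
            "sim": sim, "profile": profile}


@pytest.fixture(scope="session")
def coupled_sim():
    """2-Mb two-origin dataset with the generator's default library
    (residual 0.1), for coupling and RFD sign-structure checks."""
    layout = GenomeLayout({"chrA": 2_000_000})
    model = ReplicationModel(layout,
                             {"chrA": [(500_000, 0.9), (1_500_000, 0.9)]})
    library = LibraryModel(depth=200.0)
    sim = simulate_counts(model, library, seed=7)
    profile = compute_usage(sim["eps"], sim["alpha"], sim["control"])
    return {"layout": layout, "model": model, "sim": sim, "profile": profile}
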