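import numpy as np
import pytest

from svmap.pipeline import call_svs
from svmap.sv_discovery import RepeatAnnotation
from svmap.synthetic_data import (
    SimulationConfig,
    apply_variants,
    simulate_ancestral_genome,
)

DEFAULT_SEED = 1


@pytest.fixture(scope="session")
def default_sim():
    """The default half-megabase genome pair with full truth."""
    cfg = SimulationConfig(seed=DEFAULT_SEED)
    rng = np.random.default_rng(cfg.seed)
    ancestral, repeats, library = simulate_ancestral_genome(cfg, rng)
    derived, truth, derived_repeats = apply_variants(
        ancestral, repeats, library, cfg, rng
    )
    return dict(
        cfg=cfg,
        ancestral=ancestral,
        repeats=repeats,
        library=library,
        derived=derived,
        truth=truth,
        derived_repeats=derived_repeats,
    )


@pytest.fixture(scope="session")
def default_catalog(default_sim):
    """End-to-end SV catalog for the default simulation."""
    s = default_sim
    return call_svs(
        [s["ancestral"]],
        [s["derived"]],
        repeats_ref=RepeatAnnotation(s["repeats"]),
        repeats_qry=RepeatAnnotation(s["derived_repeats"]),
    )


@pytest.fixture(scope="session")
def small_sim():
    """A ~120 kb pair for faster module-level end-to-end checks."""
    cfg = SimulationConfig(
        genome_length=120_000, n_ancestral_te=8, te_insertions=4,
        non_te_insertions=3, deletions=5, tandem_dups=3, dups_with_spacer=2,
        inversions=2, seed=7,
    )
    rng = np.random.default_rng(cfg.seed)
    ancestral, repeats, library = simulate_ancestral_genome(cfg, rng)
    derived, truth, derived_repeats = apply_variants(
        ancestral, repeats, library, cfg, rng
    )
    return dict(
        cfg=cfg, ancestral=ancestral, repeats=repeats, library=library,
        derived=derived, truth=truth, derived_repeats=derived_repeats,
    )
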