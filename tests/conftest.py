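import numpy as np
import pytest

from puresim import (
    GeneSpec,
    ModelMetadata,
    PSComposition,
    SimulationConfig,
    VesicleGeometry,
    build_ps_model,
    parse_model,
    run,
)

# source + immediate demo model: A is produced continuously; one C appears
# for every 30 A consumed, so A oscillates in [0, 29]
SOURCE_GATE_MODEL = """
init A 0
init C 0
src: 0.9, null > A
gate: -, 30 A > C
"""


@pytest.fixture(scope="session")
def source_gate_doc():
    return parse_model(SOURCE_GATE_MODEL)


@pytest.fixture(scope="session")
def ps_doc_222():
    """Default full network at standard composition, 1e-16 L."""
    return build_ps_model(GeneSpec(), PSComposition(combination_code="222"),
                          VesicleGeometry(volume=1e-16))


@pytest.fixture(scope="session")
def ps_meta_222(ps_doc_222):
    return ModelMetadata.from_document(ps_doc_222)


@pytest.fixture(scope="session")
def ps_traj_222(ps_doc_222):
    """One hour of the standard model (shared across tests for speed)."""
    return run(ps_doc_222, SimulationConfig(t_end=3600.0, sample_dt=10.0, seed=42))


def firing_balance_residuals(doc, traj):
    """Exact per-species residual of initial + net stoichiometry x firings
    (+ timed adds/removes) - final count.  Zero everywhere for a correct
    simulation."""
    final = traj.final_firings()
    residuals = {}
    for si, name in enumerate(traj.species):
        net = 0
        for r in doc.kinetic_reactions:
            fired = final[r.id]
            net += fired * sum(nu for s, nu in r.products if s == name)
            net -= fired * sum(nu for s, nu in r.reactants if s == name)
        for im in doc.immediate_reactions:
            fired = final[im.id]
            net += fired * sum(nu for s, nu in im.products if s == name)
            net -= fired * sum(nu for s, nu in im.trigger if s == name)
        for e in doc.timed_events:
            if e.time <= traj.times[-1] and e.species == name:
                net += e.amount if e.kind == "add" else -e.amount
        residuals[name] = int(doc.initial_counts[name]) + net - int(traj.counts[-1, si])
    return residuals
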