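"""Tests of the network builder: unit conversions, the per-site reaction
boxes against their canonical printed form, full-network assembly, the
combination grid, and the steric/bookkeeping invariants of simulated
networks."""

import math

import numpy as np
import pytest

from puresim import (
    BuilderOptions,
    GeneSpec,
    ModelMetadata,
    PSComposition,
    SimulationConfig,
    VesicleGeometry,
    build_grid,
    build_ps_model,
    build_transcription_box,
    build_translation_box,
    combination_to_scalings,
    concentration_to_count,
    count_to_concentration,
    diameter_to_volume,
    peptide_length_range,
    run,
    volume_to_diameter,
)

from conftest import firing_balance_residuals


# ---------------------------------------------------------------------------
# conversions
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "code,expected",
    [
        ("201", (1.0, 1 / 3, 2 / 3)),
        ("222", (1.0, 1.0, 1.0)),
        ("000", (1 / 3, 1 / 3, 1 / 3)),
    ],
)
def test_combination_to_scalings(code, expected):
    assert combination_to_scalings(code) == pytest.approx(expected)


@pytest.mark.parametrize("bad", ["3a0", "22", "2222", "abc", "", None])
def test_combination_code_validation(bad):
    with pytest.raises(ValueError):
        combination_to_scalings(bad)


def test_concentration_count_round_trip():
    assert concentration_to_count(15e-9, 1e-14) == 90
    assert concentration_to_count(0.0, 1e-14) == 0
    assert count_to_concentration(3100, 1e-14) == pytest.approx(0.5e-6, rel=0.05)
    with pytest.raises(ValueError):
        concentration_to_count(-1e-9, 1e-14)
    with pytest.raises(ValueError):
        count_to_concentration(10, 0.0)


def test_volume_diameter_conversions():
    assert volume_to_diameter(1e-14) * 1e6 == pytest.approx(2.67, abs=0.005)
    assert volume_to_diameter(1e-16) * 1e9 == pytest.approx(575.9, abs=1.0)
    # inverse identity: sphere of diameter 2 m
    assert volume_to_diameter(diameter_to_volume(2.0)) == pytest.approx(2.0)
    with pytest.raises(ValueError):
        volume_to_diameter(0.0)


def test_peptide_length_bookkeeping():
    # a ribosome carrying PEPT3 holds a nascent chain of 81..107 aa
    assert peptide_length_range(3) == (81, 107)
    assert peptide_length_range(1) == (27, 53)


# ---------------------------------------------------------------------------
# per-site boxes
# ---------------------------------------------------------------------------


def test_transcription_box_site4_matches_printed_block():
    """Interior site: GTP binding (1e6), incorporation (28), ATP pair, and
    the 20+20 gate consuming DNA5 and releasing DNA3."""
    kin, imm = build_transcription_box(4, GeneSpec())
    assert [r.c for r in kin] == [1e6, 28.0, 1e6, 28.0]
    assert kin[0].reactants == [("T7ELGT4", 1), ("GTP", 1)]
    assert kin[0].products == [("T7pregEL4", 1)]
    assert kin[1].products == [("T7ELAT4", 1), ("Pi", 1), ("gtr4", 1)]
    assert kin[2].reactants == [("T7ELAT4", 1), ("ATP", 1)]
    assert kin[3].products == [("T7ELGT4", 1), ("Pi", 1), ("atr4", 1)]
    (gate,) = imm
    assert gate.trigger == [("gtr4", 20), ("atr4", 20), ("T7ELGT4", 1), ("DNA5", 1)]
    assert gate.products == [("T7ELGT5", 1), ("RNA4", 1), ("DNA3", 1)]


def test_transcription_box_boundaries():
    _, (first,) = build_transcription_box(1, GeneSpec())
    assert ("DNA2", 1) in first.trigger
    assert all(not s.startswith("DNA") for s, _ in first.products)
    _, (last,) = build_transcription_box(9, GeneSpec())
    assert ("T7", 1) in last.products
    assert ("DNA8", 1) in last.products and ("DNA9", 1) in last.products


def test_translation_box_site3_matches_printed_block():
    kin, imm = build_translation_box(3, GeneSpec())
    assert [r.c for r in kin] == [1e8, 79.0, 207.0, 3.45, 100.0, 638.0, 15.0,
                                  20.0, 1.5e8, 140.0, 250.0, 20.0]
    assert kin[0].reactants == [("eR3", 1), ("EFaRGTP", 1)]
    assert kin[-1].products == [("eR3", 1), ("tRNA", 1), ("TRANSL3", 1)]
    (gate,) = imm
    assert gate.trigger == [("TRANSL3", 27), ("RNA4", 1), ("PEPT2", 1), ("eR3", 1)]
    assert gate.products == [("eR4", 1), ("PEPT3", 1), ("RNA2", 1)]


def test_translation_box_termination_site():
    _, (gate,) = build_translation_box(9, GeneSpec())
    assert ("PEPT8", 1) in gate.trigger
    assert gate.products == [("eRterm", 1)]


def test_site_index_out_of_range():
    with pytest.raises(ValueError):
        build_transcription_box(10, GeneSpec())
    with pytest.raises(ValueError):
        build_translation_box(0, GeneSpec())


def test_gene_discretization():
    assert GeneSpec(length_bp=720).n_sites == 9
    assert GeneSpec(length_bp=400).n_sites == 5
    # remainder absorbed into the final site's incorporation counts
    g = GeneSpec(length_bp=760)
    assert g.n_sites == 9
    assert g.incorporations_at(9) == 30
    assert g.incorporations_at(1) == 20
    with pytest.raises(ValueError):
        GeneSpec(length_bp=80)  # fewer than 2 sites


# ---------------------------------------------------------------------------
# full network assembly
# ---------------------------------------------------------------------------


def test_default_network_size_sanity(ps_doc_222):
    assert len(ps_doc_222.species) >= 150
    n_reactions = len(ps_doc_222.kinetic_reactions) + len(ps_doc_222.immediate_reactions)
    assert n_reactions >= 150
    # one transcription and one translation gate per site
    assert sum(1 for im in ps_doc_222.immediate_reactions
               if im.id.startswith("tx_gate")) == 9
    assert sum(1 for im in ps_doc_222.immediate_reactions
               if im.id.startswith("tl_gate")) == 9


def test_scaling_000_thirds_every_standard_count():
    third = build_ps_model(comp=PSComposition(combination_code="000"))
    comp = PSComposition()
    volume = 1e-16
    for table in comp.standard_concentrations.values():
        for name, conc in table.items():
            key = "DNA1" if name == "DNA" else name
            assert third.initial_counts[key] == concentration_to_count(conc / 3, volume)


def test_low_dna_discretization_and_min_one():
    comp = PSComposition()
    comp.standard_concentrations["dna"]["DNA"] = 15e-9
    doc = build_ps_model(comp=comp, geom=VesicleGeometry(volume=1e-16))
    assert doc.initial_counts["DNA1"] == 1  # 15 nM * N_A * 1e-16 = 0.90 -> 1
    comp.standard_concentrations["dna"]["DNA"] = 0.5e-9
    doc = build_ps_model(comp=comp, geom=VesicleGeometry(volume=1e-16))
    assert doc.initial_counts["DNA1"] == 0
    doc = build_ps_model(comp=comp, geom=VesicleGeometry(volume=1e-16),
                         opts=BuilderOptions(min_one_dna=True))
    assert doc.initial_counts["DNA1"] == 1


def test_second_order_constants_are_volume_converted():
    doc14 = build_ps_model(geom=VesicleGeometry(volume=1e-14))
    doc16 = build_ps_model(geom=VesicleGeometry(volume=1e-16))
    c14 = doc14.reaction("tx_gbind_1").c
    c16 = doc16.reaction("tx_gbind_1").c
    assert c16 / c14 == pytest.approx(100.0)
    # first-order constants do not depend on volume
    assert doc14.reaction("tx_gincorp_1").c == doc16.reaction("tx_gincorp_1").c == 28.0


def test_ribosome_inactivation_timed_event():
    doc = build_ps_model()
    (event,) = doc.timed_events
    assert event.kind == "rate" and event.reaction_id == "rib_inact"
    assert event.time == 10800.0 and event.value > 0
    assert doc.reaction("rib_inact").c == 0.0
    doc_off = build_ps_model(opts=BuilderOptions(ribosome_inactivation=False))
    assert doc_off.timed_events == []


def test_build_grid_enumerates_27_codes():
    grid = build_grid()
    assert len(grid) == 27
    codes = list(grid)
    assert codes == sorted(codes)
    assert all(len(c) == 3 and set(c) <= set("012") for c in codes)
    assert grid["222"] == build_ps_model()


# ---------------------------------------------------------------------------
# simulated invariants of generated networks
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def single_template_traj():
    """One DNA copy at 1e-16 L, 20 min: enough transcription traffic to
    probe the steric gates."""
    comp = PSComposition()
    comp.standard_concentrations["dna"]["DNA"] = 15e-9  # -> 1 copy
    doc = build_ps_model(comp=comp, geom=VesicleGeometry(volume=1e-16))
    traj = run(doc, SimulationConfig(t_end=1200.0, sample_dt=5.0, seed=11))
    return doc, traj


def test_polymerase_spacing_on_single_template(single_template_traj):
    """With one template, elongating polymerases never occupy adjacent
    sites, and their total never exceeds ceil(sites/2)."""
    doc, traj = single_template_traj
    meta = ModelMetadata.from_document(doc)
    import re

    per_site = np.zeros((len(traj.times), 9), dtype=int)
    for s in meta.active_polymerase_species:
        site = int(re.search(r"(\d+)$", s).group(1))
        per_site[:, site - 1] += traj.column(s)
    assert per_site.sum(axis=1).max() <= math.ceil(9 / 2)
    adjacent = per_site[:, :-1] * per_site[:, 1:]
    assert adjacent.max() == 0


def test_transcription_translation_coupling(single_template_traj):
    """Translation initiation never precedes the first RBS-bearing RNA
    site (dynamic transcription/translation coupling)."""
    doc, traj = single_template_traj
    fir = dict(zip(traj.reaction_ids, traj.firings.T))
    started = fir["tl_init"] > 0
    if started.any():
        first = int(np.argmax(started))
        assert fir["tx_gate_1"][first] > 0


def test_nucleotide_bookkeeping_exact(ps_traj_222, ps_doc_222):
    """Trackers consumed by the site gates account for exactly 20+20
    incorporations per completed site transition."""
    fir = ps_traj_222.final_firings()
    for i in range(1, 10):
        gtr_left = ps_traj_222.column(f"gtr{i}")[-1]
        atr_left = ps_traj_222.column(f"atr{i}")[-1]
        assert fir[f"tx_gincorp_{i}"] - 20 * fir[f"tx_gate_{i}"] == gtr_left
        assert fir[f"tx_aincorp_{i}"] - 20 * fir[f"tx_gate_{i}"] == atr_left


def test_gfp_only_after_full_length_traversal(ps_traj_222):
    """GFP appears only via termination after the last site's gate: counts
    can never exceed the cumulative final-gate firings."""
    fir = dict(zip(ps_traj_222.reaction_ids, ps_traj_222.firings.T))
    gfp = ps_traj_222.column("GFP")
    assert (gfp <= fir["tl_gate_9"]).all()
    assert gfp[-1] == fir["tl_term"][-1]
    assert gfp[-1] > 0


def test_firing_balance_on_full_network(ps_doc_222, ps_traj_222):
    assert set(firing_balance_residuals(ps_doc_222, ps_traj_222).values()) == {0}
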