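"""Data-entry flow: ensembles, simulations, packing, ghosts, snapshots."""

import copy

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import trajstore as ts
from trajstore.boxes import BoxDescriptor
from trajstore.deposition import (deposit_snapshot, mark_ghosts, is_ghost,
                                  open_or_create_ensemble, pack_coordinates,
                                  register_simulation, unmark_ghosts,
                                  unpack_coordinates)
from trajstore.errors import IntegrityError, NotFoundError, ValidationError
from trajstore.fixtures import make_toy_system
from trajstore.records import LineageRef

META = dict(sim_summary="test run", sim_software="test", snap_interval=100,
            box_shape=1, box_periodicity=7, ensemble_type=1, sampler_type=2,
            parallel_mode=0, united_atom_model=0, deposit_mode=2)
BOX = BoxDescriptor.cuboid((20.0, 20.0, 20.0))


# -- ensemble tier ---------------------------------------------------------

def test_fresh_ensemble_populates_atoms_tier(store, toy_system):
    atoms, residues = toy_system
    ens_id = open_or_create_ensemble(store, "TOY_A", atoms, residues)
    assert ens_id == 1
    n = store.fetchone("SELECT COUNT(*) FROM atoms WHERE ens_id=1")[0]
    nratoms = store.fetchone("SELECT nratoms FROM ensembles WHERE ens_id=1")[0]
    assert n == nratoms == len(atoms)


def test_identical_redeposit_is_idempotent(store, toy_system):
    atoms, residues = toy_system
    ens_id = open_or_create_ensemble(store, "TOY_A", atoms, residues)
    again = open_or_create_ensemble(store, "TOY_A", atoms, residues)
    assert again == ens_id
    assert store.fetchone("SELECT COUNT(*) FROM atoms")[0] == len(atoms)


def test_empty_system_is_overwritten_under_same_id(store, toy_system):
    atoms, residues = toy_system
    ens_id = open_or_create_ensemble(store, "TOY_A", atoms, residues)
    changed = copy.deepcopy(atoms)
    changed[0].atom_name = "NX"
    assert open_or_create_ensemble(store, "TOY_A", changed, residues) == ens_id
    stored = ts.fetch_atoms(store, ens_id)
    assert stored[0].atom_name == "NX"


def test_mismatch_with_deposited_snapshots_is_refused(store, toy_system):
    atoms, residues = toy_system
    ens_id = open_or_create_ensemble(store, "TOY_A", atoms, residues)
    pair = register_simulation(store, ens_id, META)[0]
    seqs = list(range(1, len(atoms) + 1))
    deposit_snapshot(store, pair,
                     pack_coordinates(seqs, np.zeros((len(atoms), 3))), BOX)
    changed = copy.deepcopy(atoms)
    changed[0].atom_name = "NX"
    with pytest.raises(IntegrityError):
        open_or_create_ensemble(store, "TOY_A", changed, residues)


def test_asymmetric_bonds_are_rejected(store, toy_system):
    atoms, residues = toy_system
    broken = copy.deepcopy(atoms)
    broken[0].bound_partners = [2, 0, 0, 0, 0]
    broken[1].bound_partners = [3, 0, 0, 0, 0]  # does not list atom 1 back
    with pytest.raises(ValidationError, match="symmetric"):
        open_or_create_ensemble(store, "TOY_B", broken, residues)


# -- simulation tier -------------------------------------------------------

def test_single_run_registration(store, toy_system):
    atoms, residues = toy_system
    ens_id = open_or_create_ensemble(store, "TOY_A", atoms, residues)
    pairs = register_simulation(store, ens_id, META, n_replicas=1)
    assert pairs == [(1, 0)]
    assert store.table_exists("snapshots_1_0")
    rec, _ = ts.fetch_metadata(store, 1, 0)
    assert rec.sim_parent == rec.sim_id  # standalone runs self-parent


def test_replica_registration_creates_one_table_per_member(store, toy_system):
    atoms, residues = toy_system
    ens_id = open_or_create_ensemble(store, "TOY_A", atoms, residues)
    meta = dict(META, parallel_mode=1)
    pairs = register_simulation(store, ens_id, meta, n_replicas=4)
    assert [rank for _, rank in pairs] == [0, 1, 2, 3]
    parent_id = pairs[0][0]
    for sim_id, rank in pairs:
        assert store.table_exists(f"snapshots_{sim_id}_{rank}")
        rec, _ = ts.fetch_metadata(store, sim_id, rank)
        assert rec.sim_parent == parent_id
        if rank > 0:
            assert rec.sim_parent != rec.sim_id


def test_metadata_labels_are_accepted_and_encoded(store, toy_system):
    atoms, residues = toy_system
    ens_id = open_or_create_ensemble(store, "TOY_A", atoms, residues)
    meta = dict(META, sampler_type="brownian", ensemble_type="grand canonical",
                box_shape="sphere", box_periodicity=0)
    (sim_id, rank), = register_simulation(store, ens_id, meta)
    rec, labels = ts.fetch_metadata(store, sim_id, rank)
    assert rec.sampler_type == 4 and rec.ensemble_type == 6
    assert rec.box_shape == 2
    assert labels["sampler_type"] == "Brownian dynamics"


def test_append_requires_fieldwise_identical_metadata(store, toy_system):
    atoms, residues = toy_system
    ens_id = open_or_create_ensemble(store, "TOY_A", atoms, residues)
    (sim_id, _), = register_simulation(store, ens_id, META)
    same = register_simulation(store, ens_id, META, sim_id=sim_id)
    assert same == [(sim_id, 0)]
    with pytest.raises(IntegrityError, match="snap_interval"):
        register_simulation(store, ens_id, dict(META, snap_interval=999),
                            sim_id=sim_id)


def test_invalid_codes_and_inadmissible_boxes_are_rejected(store, toy_system):
    atoms, residues = toy_system
    ens_id = open_or_create_ensemble(store, "TOY_A", atoms, residues)
    with pytest.raises(ValidationError):
        register_simulation(store, ens_id, dict(META, sampler_type=9))
    with pytest.raises(ValidationError):
        register_simulation(store, ens_id,
                            dict(META, box_shape=2, box_periodicity=7))


# -- coordinate packing ----------------------------------------------------

def test_pack_direct_construction():
    assert pack_coordinates([1, 2], [(0, 0, 0), (1.5, 0, 0)]) == \
        [(1, 0.0, 0.0, 0.0), (2, 1.5, 0.0, 0.0)]


def test_subset_packing_retains_original_atom_seq():
    packed = pack_coordinates([2, 5, 9], [(1, 1, 1)] * 3)
    assert [t[0] for t in packed] == [2, 5, 9]


def test_pack_rejects_bad_index_sequences():
    with pytest.raises(ValidationError):
        pack_coordinates([1, 1], [(0, 0, 0)] * 2)
    with pytest.raises(ValidationError):
        pack_coordinates([2, 1], [(0, 0, 0)] * 2)
    with pytest.raises(ValidationError):
        pack_coordinates([1], [(0, 0, 0)] * 2)


@settings(derandomize=True, max_examples=50)
@given(st.integers(0, 2**32 - 1))
def test_pack_unpack_round_trip_is_exact(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(1, 1000))
    coords = rng.uniform(-1e3, 1e3, size=(n, 3))
    seqs = sorted(rng.choice(np.arange(1, 2 * n + 1), size=n, replace=False))
    got_seqs, got = unpack_coordinates(pack_coordinates(seqs, coords))
    assert got_seqs == [int(s) for s in seqs]
    np.testing.assert_array_equal(got, coords)


def test_precision_reduction_rounds_coordinates():
    packed = pack_coordinates([1], [(1.23456789, 0, 0)], precision=3)
    assert packed[0][1] == 1.235


# -- ghost particles -------------------------------------------------------

def test_all_present_particles_are_unchanged():
    coords = np.random.default_rng(0).uniform(0, 20, size=(10, 3))
    out = mark_ghosts(coords, [True] * 10, BOX)
    np.testing.assert_array_equal(out, coords)


def test_ghost_flag_round_trips_exactly():
    rng = np.random.default_rng(1)
    coords = rng.uniform(0, 20, size=(10, 3))
    present = rng.uniform(size=10) > 0.4
    marked = mark_ghosts(coords, present, BOX)
    for i in range(10):
        assert is_ghost(marked[i], BOX) == (not present[i])
    restored, flags = unmark_ghosts(marked, BOX)
    np.testing.assert_array_equal(flags, present)
    # present coordinates are untouched; unshifting a ghost costs at most
    # one floating-point rounding at the shift magnitude
    np.testing.assert_array_equal(restored[present], coords[present])
    np.testing.assert_allclose(restored, coords, rtol=0, atol=1e-10)


def test_grand_canonical_stream_keeps_fixed_length(store):
    """Fluctuating composition is stored as a fixed superset with ghosts."""
    atoms, residues = make_toy_system(1, 4, seed=3)
    n = len(atoms)
    ens_id = open_or_create_ensemble(store, "TOY_GC", atoms, residues)
    meta = dict(META, ensemble_type=6)
    pair = register_simulation(store, ens_id, meta)[0]
    rng = np.random.default_rng(5)
    seqs = list(range(1, n + 1))
    for _ in range(5):
        present = rng.uniform(size=n) > 0.3   # fluctuating particle count
        coords = rng.uniform(0, 20, size=(n, 3))
        marked = mark_ghosts(coords, present, BOX)
        deposit_snapshot(store, pair, pack_coordinates(seqs, marked), BOX)
    for frame in ts.fetch_coordinates(store, pair):
        assert len(frame.coordinates) == n


# -- snapshot deposition ---------------------------------------------------

def _prepared(store, toy_system):
    atoms, residues = toy_system
    ens_id = open_or_create_ensemble(store, "TOY_A", atoms, residues)
    pair = register_simulation(store, ens_id, META)[0]
    seqs = list(range(1, len(atoms) + 1))
    return ens_id, pair, seqs, len(atoms)


def test_first_frame_gets_nil_sentinel(store, toy_system):
    _, pair, seqs, n = _prepared(store, toy_system)
    snap = deposit_snapshot(store, pair,
                            pack_coordinates(seqs, np.zeros((n, 3))), BOX)
    assert snap == 1
    row = store.fetchone(
        f"SELECT previous_id, previous_rank, previous_snap "
        f"FROM snapshots_{pair[0]}_{pair[1]} WHERE snap_id=1")
    assert tuple(row) == (0, 0, 0)


def test_default_parent_is_the_preceding_snapshot(store, toy_system):
    _, pair, seqs, n = _prepared(store, toy_system)
    deposit_snapshot(store, pair, pack_coordinates(seqs, np.zeros((n, 3))), BOX)
    deposit_snapshot(store, pair, pack_coordinates(seqs, np.ones((n, 3))), BOX)
    assert ts.parent_of(store, LineageRef(pair[0], pair[1], 2)) == \
        LineageRef(pair[0], pair[1], 1)


def test_sim_step_default_formula_and_override(store, toy_system):
    _, pair, seqs, n = _prepared(store, toy_system)
    deposit_snapshot(store, pair, pack_coordinates(seqs, np.zeros((n, 3))), BOX)
    deposit_snapshot(store, pair, pack_coordinates(seqs, np.zeros((n, 3))),
                     BOX, sim_step=77777)
    tbl = f"snapshots_{pair[0]}_{pair[1]}"
    steps = [r[0] for r in store.fetchall(
        f"SELECT sim_step FROM {tbl} ORDER BY snap_id")]
    assert steps == [META["snap_interval"] * 1, 77777]


def test_parent_to_nonexistent_snapshot_is_refused(store, toy_system):
    _, pair, seqs, n = _prepared(store, toy_system)
    with pytest.raises(IntegrityError):
        deposit_snapshot(store, pair,
                         pack_coordinates(seqs, np.zeros((n, 3))), BOX,
                         parent=LineageRef(pair[0], pair[1], 99))


def test_out_of_range_atom_index_is_refused(store, toy_system):
    _, pair, _, n = _prepared(store, toy_system)
    with pytest.raises(ValidationError):
        deposit_snapshot(store, pair, [(n + 1, 0.0, 0.0, 0.0)], BOX)
    with pytest.raises(NotFoundError):
        deposit_snapshot(store, (99, 0), [(1, 0.0, 0.0, 0.0)], BOX)


def test_deposit_then_retrieve_is_bit_identical(store, toy_system):
    _, pair, seqs, n = _prepared(store, toy_system)
    rng = np.random.default_rng(17)
    deposited = []
    for _ in range(8):
        coords = rng.uniform(-100, 100, size=(n, 3))
        deposit_snapshot(store, pair, pack_coordinates(seqs, coords), BOX)
        deposited.append(coords)
    frames = ts.fetch_coordinates(store, pair)
    assert len(frames) == 8
    for frame, coords in zip(frames, deposited):
        _, got = unpack_coordinates(frame.coordinates)
        np.testing.assert_array_equal(got, coords)  # full double precision
        assert frame.box == ts.encode_box(BOX)
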