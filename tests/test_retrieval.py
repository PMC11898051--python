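"""Retrieval queries against brute-force in-memory oracles."""

import numpy as np
import pytest

import trajstore as ts
from trajstore.errors import NotFoundError, ValidationError
from trajstore.fixtures import deposit_random_walk, deposit_replica_exchange
from trajstore.retrieval import SelectionSpec


def test_empty_database_lists_no_keys(store):
    assert ts.list_keys(store) == []


def test_listed_keys_resolve_back_to_their_ids(store):
    deposit_random_walk(store, "KEY_B", n_frames=2, seed=1)
    deposit_random_walk(store, "KEY_A", n_frames=2, seed=2)
    listed = ts.list_keys(store)
    assert [k for k, *_ in listed] == ["KEY_A", "KEY_B"]  # key-sorted
    for key, ens_id, nratoms, _ in listed:
        row = store.fetchone(
            "SELECT ens_key, nratoms FROM ensembles WHERE ens_id=?", (ens_id,))
        assert (row[0], row[1]) == (key, nratoms)


def test_tables_for_key_plain_and_replica_ordering(store):
    deposit_random_walk(store, "PLAIN", n_frames=2, seed=1)
    _, pairs, _ = deposit_replica_exchange(store, "REMD", n_replicas=4,
                                           n_frames=4, swap_every=2, seed=2)
    assert ts.tables_for_key(store, "PLAIN") == ["snapshots_1_0"]
    expected = [f"snapshots_{sid}_{rank}" for sid, rank in pairs]
    assert ts.tables_for_key(store, "REMD") == expected
    with pytest.raises(NotFoundError):
        ts.tables_for_key(store, "NOSUCH")


def test_table_ordering_is_stable_under_registration_order(store):
    # independent simulations with distinct parents sort by parent, not
    # by insertion order
    deposit_random_walk(store, "K1", n_frames=1, seed=1)
    atoms_meta = dict(sim_summary="second run", sim_software="t",
                      snap_interval=50, box_shape=1, box_periodicity=7,
                      ensemble_type=1, sampler_type=2, parallel_mode=0,
                      united_atom_model=0, deposit_mode=2)
    ens_id = store.fetchone(
        "SELECT ens_id FROM ensembles WHERE ens_key='K1'")[0]
    ts.register_simulation(store, ens_id, atoms_meta)
    tables = ts.tables_for_key(store, "K1")
    parents = [store.fetchone(
        "SELECT sim_parent FROM simulations WHERE sim_id=?",
        (ts.parse_snapshot_table_name(t)[0],))[0] for t in tables]
    assert parents == sorted(parents)


# -- summary search --------------------------------------------------------

@pytest.fixture
def summary_db(store):
    meta = dict(sim_summary="", sim_software="t", snap_interval=10,
                box_shape=1, box_periodicity=7, ensemble_type=1,
                sampler_type=2, parallel_mode=0, united_atom_model=0,
                deposit_mode=2)
    summaries = [
        "apo bromodomain in TIP3P water",
        "holo structure, 100% of frames kept",
        "Bromodomain with ligand",
        "unrelated peptide",
    ]
    for i, summary in enumerate(summaries):
        deposit_random_walk(store, f"S{i}", n_frames=1, seed=i,
                            meta=dict(meta, sim_summary=summary))
    return store, summaries


def _oracle(store, needle, fold=False):
    rows = store.fetchall(
        "SELECT ens_id, sim_id, sim_rank, sim_summary FROM simulations "
        "ORDER BY sim_id")
    if fold:
        return [(r[0], r[1], r[2]) for r in rows
                if needle.lower() in (r[3] or "").lower()]
    return [(r[0], r[1], r[2]) for r in rows if needle in (r[3] or "")]


def test_substring_search_matches_scan_oracle(summary_db):
    store, _ = summary_db
    for needle in ("bromodomain", "Bromodomain", "water", "zzz"):
        assert ts.search_summaries(store, needle) == _oracle(store, needle)


def test_case_insensitive_flag(summary_db):
    store, _ = summary_db
    got = ts.search_summaries(store, "BROMODOMAIN", case_insensitive=True)
    assert got == _oracle(store, "BROMODOMAIN", fold=True)
    assert len(got) == 2


def test_wildcards_in_needle_are_literal(summary_db):
    store, _ = summary_db
    assert ts.search_summaries(store, "100%") == _oracle(store, "100%")
    assert len(ts.search_summaries(store, "100%")) == 1
    assert ts.search_summaries(store, "100_") == []
    with pytest.raises(ValidationError):
        ts.search_summaries(store, "")


# -- metadata --------------------------------------------------------------

def test_fetch_metadata_decodes_all_codes(walk_db):
    store, _, (sim_id, rank) = walk_db
    rec, labels = ts.fetch_metadata(store, sim_id, rank)
    assert labels["ensemble_type"] == "canonical (NVT)"
    for field, label in labels.items():
        assert ts.encode(field, label) == getattr(rec, field)
    with pytest.raises(NotFoundError):
        ts.fetch_metadata(store, 999, 0)


# -- coordinate slicing ----------------------------------------------------

def test_stride_selection_enumerates_expected_ids(store):
    deposit_random_walk(store, "W", n_frames=100, n_chains=1, chain_length=1,
                        seed=4)
    frames = ts.fetch_coordinates(store, (1, 0),
                                  SelectionSpec(snap_range=(1, 100, 10)))
    assert [f.snap_id for f in frames] == list(range(1, 100, 10))


def test_full_selection_reconstructs_deposited_frames(walk_db):
    store, _, pair = walk_db
    tbl = f"snapshots_{pair[0]}_{pair[1]}"
    raw = {r[0]: store.unpack_json(r[1]) for r in store.fetchall(
        f"SELECT snap_id, trajectories FROM {tbl}")}
    for frame in ts.fetch_coordinates(store, pair):
        assert [list(t) for t in frame.coordinates] == raw[frame.snap_id]


def test_atom_name_filter_matches_substring_oracle(walk_db):
    store, ens_id, pair = walk_db
    ca_seqs = {a.atom_seq for a in ts.fetch_atoms(store, ens_id)
               if "CA" in a.atom_name}
    frames = ts.fetch_coordinates(
        store, pair, SelectionSpec(snap_ids=[4], atom_name_pattern="CA"))
    assert {t[0] for t in frames[0].coordinates} == ca_seqs
    # exact-name flag is stricter than the substring default
    exact = ts.fetch_coordinates(
        store, pair, SelectionSpec(snap_ids=[4], atom_name_pattern="C",
                                   exact_name=True))
    c_seqs = {a.atom_seq for a in ts.fetch_atoms(store, ens_id)
              if a.atom_name == "C"}
    assert {t[0] for t in exact[0].coordinates} == c_seqs


def test_molecule_filter_and_empty_selection(walk_db):
    store, ens_id, pair = walk_db
    mol1 = {a.atom_seq for a in ts.fetch_atoms(store, ens_id)
            if a.molecule_id == 1}
    frames = ts.fetch_coordinates(store, pair,
                                  SelectionSpec(snap_ids=[1], molecule_id=1))
    assert {t[0] for t in frames[0].coordinates} == mol1
    empty = ts.fetch_coordinates(
        store, pair, SelectionSpec(snap_ids=[1], atom_name_pattern="ZZ"))
    assert empty[0].coordinates == []  # empty rows, not an error


def test_explicit_out_of_range_snapshot_errors(walk_db):
    store, _, pair = walk_db
    with pytest.raises(NotFoundError):
        ts.fetch_coordinates(store, pair, SelectionSpec(snap_ids=[999]))


def test_per_snapshot_queries_equal_composite_query(walk_db):
    store, _, pair = walk_db
    composite = ts.fetch_coordinates(store, pair,
                                     SelectionSpec(snap_range=(1, 12, 3)))
    singles = [ts.fetch_coordinates(store, pair,
                                    SelectionSpec(snap_ids=[f.snap_id]))[0]
               for f in composite]
    assert [(f.snap_id, f.coordinates, f.box) for f in composite] == \
        [(f.snap_id, f.coordinates, f.box) for f in singles]
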