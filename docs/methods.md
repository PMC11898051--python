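# Methods

## Data model

The store keeps four tiers. The ensemble tier maps a human-readable key
(`[A-Za-z0-9_-]+`) to the numeric `ens_id` that links everything else, and
carries two deliberately redundant fields — `nratoms` and the residue
sequence — that exist purely so corruption is detectable. The simulation
tier holds one row per trajectory with 16 attributes; categorical ones use
frozen integer code books (box shape 1–4; periodicity 0–7 with partial
periodicity ordered z, y, x, yz, xz, xy; ensemble type 1/2/3/5/6; sampler
type 1–7; parallel mode 0–6; united-atom model 0–3; deposit mode 1/2).
Labels are matched case-insensitively with underscores/hyphens/spaces
interchangeable, because free-text recognition of spellings is a known
source of metadata rot. A registry allows appending new codes but never
redefining the frozen ones.

A parallel run of R trajectories gets R simulation rows: each replica has
its own `sim_id`, the first (rank 0) is the parent and self-references
`sim_parent`, the others store the parent's `sim_id` there. Coordinates
live in one table `snapshots_<sim_id>_<sim_rank>` per trajectory. Each
frame stores packed `(atom_seq, x, y, z)` 4-tuples (1-based, aligned with
the atoms tier, so subset systems keep their original indices), a
12-element box (box vectors 1–3 then origin), and the backward-connectivity
triple addressing its geometric parent, with `(0, 0, 0)` as the nil
sentinel — the same 0-as-absent convention the Z-matrix reference columns
use.

## Backend

The standard's native target is PostgreSQL (arrays, a composite
`atomxyz` element type, TIMESTAMP); `trajstore.schema.emit_schema`
produces that DDL verbatim and idempotently. The operational store bundled
here runs on SQLite so that a complete database is a single local file
with no server: column names and order are identical, and array/composite
values travel as JSON text, which round-trips IEEE doubles exactly (the
round-trip tests assert bit-identity). Coordinates are bound as numeric
JSON values, never formatted through locale-dependent string conversion.
Every deposition commits per row by default, so each row is validated and
visible as soon as the call returns; `batch_size > 1` trades that safety
for bulk-load speed.

## Conventions chosen here

Where the standard fixes semantics but not a concrete convention, this
package documents its own choice:

* **Curved containers.** The 12-vector for a sphere is
  `[radius, 0×8, center]`; for a cylinder
  `[radius, height, axis-index(1/2/3), 0×6, center]`. This is explicitly
  *not* interoperable with CAMPARI's (unpublished) curved-container
  vectors.
* **Ghost particles.** Grand-type ensembles store a fixed superset system;
  an absent particle is shifted by `2 × (largest box extent)` along every
  axis. Presence is recovered exactly (a present coordinate lies within
  one extent of the origin per axis; a ghost sits beyond 1.25 extents);
  unshifting costs at most one floating-point rounding at the shift
  magnitude. The convention assumes present coordinates lie inside the
  container, which deposition-side wrapping guarantees.
* **`sim_step` default.** `equilibration_steps + snap_interval × snap_id`,
  overridable per frame for irregular saving.
* **Default parent.** A deposited frame is parented to the preceding frame
  of its own table unless an explicit cross-table parent (swap, reseed) or
  the nil sentinel is given.
* **PDB output.** The atom serial is `atom_seq` (not the global
  `atom_id`); occupancy is always `1.00`; no altLoc or insertion codes
  exist by construction; `chain_seq` may hold two characters but PDB has
  one chain column, so the first character is emitted and truncation
  warns; the temperature-factor column is fillable from any real-valued
  atoms-tier column (e.g. `partial_charge`). Element symbols are derived
  by nearest standard atomic weight, with the atom name arbitrating only
  near-ties — so mass 40.08 named "CA" is calcium while 12.011 "CA" is
  carbon.
* **Selection semantics.** `snap_id` and `atom_seq` are 1-based
  everywhere; CLI ranges are inclusive. Atom-name filtering is substring
  matching by default (mirroring `LIKE '%CA%'` query practice), with an
  exact-name flag because the substring form also matches e.g. "CA2".
  Slices are resolved client-side into bounded explicit id lists to keep
  intermediate results small; snapshot access is by primary key, never a
  scan.

## Lineage traversal and demultiplexing

`parent_of` resolves one backward triple (raising on dangling references),
`trace_lineage` follows it to the origin with cycle detection (a cycle is
impossible for data written by the deposition path and therefore reported
as corruption), and `demultiplex` traces the lineage of every member
trajectory's terminal frame. For replica exchange the result is a
permutation at every time slice — R frames map to R distinct continuous
trajectories — which the tests verify against the generator's recorded
swap schedule. For adaptive-sampling reseeds, lineages may share a prefix;
shared frames are reported once, with branch points annotated, since
frames are not duplicated in storage. Non-initial frames carrying the nil
sentinel (e.g. reservoir/library insertions, whose parentage the standard
does not record) are listed as orphans in the demux report.

## Integrity validation

`validate_database` is read-only and checks twelve invariants: the two
redundant `nratoms` agreements, `atom_seq` contiguity, snapshot-table
existence per simulation row, coordinate index range and strict ordering,
box length 12, resolvable and acyclic backward triples, shape/periodicity
admissibility (spheres aperiodic, cylinders at most one periodic
dimension), code-book membership, and key format. No repair mode is
offered: curation is a human decision, and an automatic fixer would have
to guess which of two disagreeing redundant fields is right.

## Synthetic fixtures

The generator builds linear bead chains (three backbone-like atoms N/CA/C
per residue with real nitrogen/carbon masses, symmetric bonds, a
backward-only Z-matrix), Gaussian random-walk trajectories wrapped into
the periodic container (step σ 0.3 Å, 20–25 Å cubic boxes by default —
small enough for fast tests, large enough that wrapping and ghost
conventions are exercised), and replica-exchange swap schedules in which
disjoint neighbor pairs exchange with probability 0.5 at every swap step,
recording the exact parent replica of every frame. All randomness flows
through one explicitly seeded generator per call; nothing uses global
random state.

What the fixtures do not emulate: energies or any force-field physics,
realistic polymer geometry, solvent, or temperature ladders. Passing tests
therefore demonstrate the bookkeeping guarantees of the storage standard —
exact round trips, lineage recovery, corruption detection — not the
scientific validity of any simulation protocol.

## Problem sizes

The test suite and acceptance script run at desk scale by design: the
round-trip check uses a 90-atom, 100-frame trajectory; lineage recovery
uses 4 replicas × 200 frames with swaps every 10; corruption detection
injects one corruption per invariant and validates 100 clean seeded
stores. The schema itself imposes no such limits; table-per-trajectory
layout and key-based snapshot access are exactly what keeps larger stores
tractable.

## Known limitations

* Binary trajectory formats (DCD/XTC/NetCDF) are not wired into the CLI;
  multi-model PDB is the mandatory interchange path. The library API
  accepts coordinates from any reader.
* PDB templates read back through `pdbio.read_template` carry no bond
  topology or Z-matrix (no chemical perception is attempted; those fields
  hold the 0 sentinel).
* The SQLite store is single-writer; concurrent parallel appending of
  replica tables — which the consistency checks are designed to protect —
  is sequential here.
* Ensemble thermodynamic quantities (energies, temperatures, pressures)
  have no dedicated columns on purpose; they belong in `sim_summary` as
  structured free text, and no search engine beyond literal substring
  matching is provided.
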