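# trajstore

Relational, FAIR-oriented storage for molecular simulation trajectories.

Molecular dynamics and Monte Carlo simulations produce trajectories —
time-ordered snapshots of a molecular system saved at a reduced interval —
that are usually archived as binary coordinate files plus loosely coupled
metadata (a template PDB, notes in a paper). That coupling is fragile: the
swap history of a replica-exchange run, the role of each atom, the boundary
condition, or the meaning of ghost particles in a grand-canonical run can
all be lost independently of the coordinates, destroying the
interpretability of the data set.

`trajstore` implements a four-tier relational storage standard that keeps
metadata and raw data strictly linked:

* **ensemble tier** — one row per stored system: a unique human-readable
  key `ens_key`, the numeric linking key `ens_id`, a redundant atom count
  `nratoms` used for corruption detection, and the residue sequence;
* **simulation tier** — 16 metadata attributes per trajectory (sampler,
  thermodynamic ensemble, box shape/periodicity, parallelization scheme,
  saving interval, …), categorical ones as frozen integer code books;
* **atoms tier** — 22 columns per atom (identity, polymer role, masses and
  charges, covalent topology in `bound_partners`, an internal-coordinate
  Z-matrix), enough to regenerate an annotated PDB template from the
  database alone;
* **coordinate tier** — one table `snapshots_<sim_id>_<sim_rank>` per
  trajectory, each row one frame: packed `(atom_seq, x, y, z)` 4-tuples in
  full double precision, a 12-element box descriptor (three box vectors
  plus origin), and a backward-connectivity triple
  `(previous_id, previous_rank, previous_snap)` naming the frame's
  geometric parent — possibly in another replica's table.

The backward-connectivity map is what makes nontrivial trajectory
ensembles (replica exchange, adaptive sampling / PIGS reseeding)
interpretable: because the forward map is one-to-many but never
many-to-one, each frame stores exactly one parent, and tracing parents
demultiplexes condition-ordered replica data into geometrically continuous
trajectories.

The package provides the schema (including the PostgreSQL DDL of the
standard; the bundled self-contained store runs on SQLite), the deposition
and retrieval logic with its integrity checks, structure-template
generation, lineage traversal, a synthetic-fixture generator with ground
truth, a 12-invariant database validator, and a `trajstore` command line.

## Worked example

```python
import trajstore as ts
from trajstore.fixtures import deposit_replica_exchange

store = ts.connect()  # in-memory store
ens_id, pairs, schedule = deposit_replica_exchange(
    store, "TOY_REMD", n_replicas=3, n_frames=8, swap_every=2, seed=42)

print("snapshot tables:", ts.tables_for_key(store, "TOY_REMD"))
rec, labels = ts.fetch_metadata(store, *pairs[1])
print("replica 1 parallel_mode:", rec.parallel_mode, "=", labels["parallel_mode"])

result = ts.demultiplex(store, pairs[0][0])
terminal = min(result.trajectories, key=lambda r: r.sim_id)
lineage = result.trajectories[terminal]
print("continuous trajectory ending at", terminal)
print("walks through replicas:", [ref.sim_rank for ref in lineage])
print("integrity violations:", len(ts.validate_database(store)))
```

prints

```
snapshot tables: ['snapshots_1_0', 'snapshots_2_1', 'snapshots_3_2']
replica 1 parallel_mode: 1 = replica exchange
continuous trajectory ending at LineageRef(sim_id=1, sim_rank=0, snap_id=8)
walks through replicas: [2, 2, 1, 1, 0, 0, 0, 0]
integrity violations: 0
```

Three replicas were deposited with a seeded swap schedule; each replica
got its own simulation row and snapshot table (ranks 0–2 under parent
`sim_id` 1). Demultiplexing traced the backward-connectivity map from the
final frame of rank 0: the geometrically continuous conformation that ends
there started in replica 2, was swapped into replica 1 at frame 3 and into
replica 0 at frame 5 — exactly the generator's recorded swap history. The
validator found no violated invariant in the resulting database.

The same flows are available from a shell:

```
trajstore --db my.db init
trajstore --db my.db deposit --key SYS1 --template t.pdb --traj traj.pdb --meta meta.yaml
trajstore --db my.db ls
trajstore --db my.db search bromodomain
trajstore --db my.db extract --key SYS1 --snaps 1:100:10 --atoms CA --out ca.pdb
trajstore --db my.db demux --sim 1 --out-prefix demuxed
trajstore --db my.db validate
trajstore demo --seed 7 --out demo_dir
```

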