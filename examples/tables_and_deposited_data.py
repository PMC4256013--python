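"""Trial tables on disk, and decoding deposited MAT experiment files.

Simulated experiments serialize to a flat CSV trial table (one row per
trial) that round-trips exactly.  Deposited MAT 5.0 files with stimulus
matrices s1/s2 and a correctness matrix c decode into the same schema,
so every analysis runs unchanged on recorded data: drop the published
experiment files into data/ and this script analyses them too.
"""

from pathlib import Path

import intervalbias as ib

observer = ib.ObserverParams(
    ib.ModelTag.MEMORY_TRACE, weights=ib.default_weights(), sigma=0.04
)
spec = ib.ProtocolSpec(ib.Protocol.REFERENCE_LOWER)
cfg = ib.SimulationConfig(spec, observer, n_participants=5,
                          blocks_per_participant=2, master_seed=1)
blocks, manifest = ib.simulate_experiment(cfg)

out = Path("scratch") if Path("scratch").exists() else Path(".")
path = out / "example_trials.csv"
table = ib.blocks_to_table(blocks)
ib.write_table(table, path)
back = ib.read_table(path)
print(f"wrote {len(table)} trial rows to {path}; round-trip exact: "
      f"{back.equals(table)}")

for name in ("reference-lower-data.mat", "reference-data.mat"):
    mat = Path("data") / name
    if not mat.exists():
        print(f"{mat}: not present (place the published file here to decode it)")
        continue
    protocol = ib.ProtocolSpec(
        ib.Protocol.REFERENCE_LOWER if "lower" in name else ib.Protocol.REFERENCE
    )
    recorded = ib.table_to_blocks(ib.read_dataset_s1(mat, protocol), protocol)
    split = ib.percent_correct_by_reference(recorded)
    print(f"{mat}: {len(recorded)} blocks; Ref1 {split.pc_group1:.1f}% "
          f"vs Ref2 {split.pc_group2:.1f}%")
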