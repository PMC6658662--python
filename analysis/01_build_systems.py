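"""Generate the three synthetic conditions and archive them as GRO + NDX.

Writes the trajectories (large, regenerable) under scratch/systems/ and a
per-condition ground-truth/summary table under results/. Every downstream
script rebuilds the same systems deterministically from the specs, so this
step is an archive, not a dependency.
"""

import json

import pandas as pd

from _common import RESULTS, SCRATCH, ensure_dirs, spec_for, system_for, CONDITIONS
from hyperbar import synth
from hyperbar.trajio import write_gro, write_ndx

ensure_dirs()
outdir = SCRATCH / "systems"
outdir.mkdir(parents=True, exist_ok=True)

rows = []
for name in CONDITIONS:
    spec, top, traj = system_for(name)
    write_gro(traj, outdir / f"{name}.gro")
    write_ndx(synth.standard_groups(spec, top), outdir / f"{name}.ndx")
    gt = synth.ground_truth(spec)
    (outdir / f"{name}.truth.json").write_text(json.dumps(gt, indent=1))
    rows.append({
        "condition": name,
        "atoms": top.n_atoms,
        "frames": traj.n_frames,
        "f_gap": spec.f_gap,
        "tmd_dehydration": spec.tmd_dehydration,
        "target_order": spec.target_order,
        "expected_gap_gas": gt["expected_gap_gas"],
        "slab_volume_nm3": gt["slab_volume_nm3"],
    })

table = pd.DataFrame(rows)
table.to_csv(RESULTS / "systems.tsv", sep="\t", index=False)
print(table.to_string(index=False))
print(f"\ntrajectories archived under {outdir}")
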