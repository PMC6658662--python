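"""RMSD from the starting structure and gromos clustering per condition.

Finding: with the generator's small per-frame jitter every condition is
conformationally stable — a single cluster holds all frames of the
clustering window, i.e. the control-like regime of the cluster table.
"""

import numpy as np
import pandas as pd

from _common import RESULTS, SCRATCH, ensure_dirs, system_for, CONDITIONS
from hyperbar.structure import gromos_cluster, pairwise_rmsd_matrix, rmsd_series, summarize_clusters
from hyperbar.trajio import select, write_pdb

ensure_dirs()
rows = []
for name in CONDITIONS:
    spec, top, traj = system_for(name)
    protein = select(top, name="CA", group_name="protein_ca")
    series = rmsd_series(traj, protein)
    series.to_frame().to_csv(RESULTS / f"rmsd_{name}.tsv", sep="\t", index=False)

    half = np.arange(traj.n_frames // 2, traj.n_frames)
    mat = pairwise_rmsd_matrix(traj, protein, half)
    res = gromos_cluster(mat, cutoff=0.5)
    summary = summarize_clusters(res, traj.times[half])
    centroid = int(half[res.centroids[0]])
    (SCRATCH / "centroids").mkdir(parents=True, exist_ok=True)
    write_pdb(traj.frames[centroid], top, SCRATCH / "centroids" / f"{name}.pdb")
    rows.append({
        "condition": name,
        "total_frames": summary["total_frames"],
        "n_clusters": summary["n_clusters"],
        "p_biggest": summary["biggest_probability"],
        "first_ps": summary["biggest_first_ps"],
        "middle_ps": summary["biggest_middle_ps"],
        "last_ps": summary["biggest_last_ps"],
        "mean_rmsd_nm": round(float(series.values.mean()), 4),
    })

table = pd.DataFrame(rows)
table.to_csv(RESULTS / "cluster_summary.tsv", sep="\t", index=False)
print(table.to_string(index=False))
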