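"""Z-density profiles and per-residue water/gas RDF layouts.

Finding: under the helium analogue the gas density concentrates in the
inter-leaflet slab, the gas layout peaks at the TMD rows of every chain,
and the water layout normalised to control drops to ~0.5 at the TMD rows
(the generator's dehydration factor) while staying at ~1 in the bulk.
"""

import numpy as np
import pandas as pd

from _common import RESULTS, ensure_dirs, system_for, CONDITIONS
from hyperbar import synth
from hyperbar.spatial import density_profile, normalize_layout, rdf_layout, sampling_windows
from hyperbar.trajio import select

ensure_dirs()

layouts = {}
for name in CONDITIONS:
    spec, top, traj = system_for(name)
    for label, kwargs in (("gas", {"residue_name": "HE"}),
                          ("lipid", {"residue_name": "DOPC"}),
                          ("protein", {"name": "CA"})):
        grp = select(top, group_name=label, **kwargs)
        prof = density_profile(traj, grp, n_bins=120)
        prof.to_frame().to_csv(RESULTS / f"density_{label}_{name}.tsv",
                               sep="\t", index=False)

    t = traj.times
    t0, t1 = t[len(t) // 2], t[-1]
    span = t1 - t0
    wins = sampling_windows(t0, t1, 0.17 * span, 0.1 * span)
    water = select(top, name="OW", group_name="water")
    gas = select(top, residue_name="HE", group_name="gas")
    layouts[name] = {}
    for ch in "ABCD":
        layouts[name][ch] = rdf_layout(traj, ch, water, wins)
        layouts[name][ch].to_frame().to_csv(
            RESULTS / f"layout_water_{name}_{ch}.tsv", sep="\t", index=False)
        rdf_layout(traj, ch, gas, wins).to_frame().to_csv(
            RESULTS / f"layout_gas_{name}_{ch}.tsv", sep="\t", index=False)

spec_he = system_for("helium")[0]
gt = synth.ground_truth(spec_he)
tmd_rows = [o // 5 for o in gt["tmd_row_ordinals"]]
print("normalised water layout (condition / control), chain A:")
for name in ("hydrostatic", "helium"):
    summary = []
    for ch in "ABCD":
        ratio = normalize_layout(layouts[name][ch], layouts["control"][ch])
        ratio.to_frame().to_csv(RESULTS / f"layout_water_norm_{name}_{ch}.tsv",
                                sep="\t", index=False)
        summary.append(np.nanmean(ratio.mean[tmd_rows]))
    print(f"  {name}: mean TMD ratio over chains = {np.mean(summary):.3f} "
          f"(truth {1 - system_for(name)[0].tmd_dehydration})")
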