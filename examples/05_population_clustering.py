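"""Run a small multi-cell synthetic study and phenotype the synapses.

The pipeline renders each cell's movies, segments, extracts and fits every
synapse, assembles the profile table (11 properties per synapse), z-scores
and K-means-clusters it (K = 3, labels ordered by ascending cooperativity
m), projects it with PCA, and compares the pillar and modiolar halves.
"""

import json

import pandas as pd

import ihcsynapse as ihc

cfg = ihc.PipelineConfig(out_dir="/tmp/ihc_run", n_cells=8,
                         synapses_per_cell=2, seed=3)
out = ihc.run_pipeline(cfg)
manifest = json.loads((out / "manifest.json").read_text())
print(f"analyzed {manifest['n_synapses_analyzed']} synapses from "
      f"{manifest['n_cells']} cells; {manifest['n_synapses_qc_pass']} "
      f"passed QC (R^2 > 0.7 on all fits)")

table = pd.read_csv(out / "synapse_profiles.csv")
ok = table[table["qc_pass"]]
print("\ncluster means (1 = lowest cooperativity m):")
print(ok.groupby("cluster_label")[["m", "dr_rel_mV", "v10_rel_mV"]]
      .mean().round(2))

import numpy as np
slope = np.polyfit(ok["position_01"], ok["v_half_ca_mV"], 1)[0]
print(f"\npillar->modiolar V1/2 gradient: {slope:+.1f} mV per unit position")
print("(positive slope: pillar synapses activate at more negative "
      "potentials, as planted by the generator)")
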