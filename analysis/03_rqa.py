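#!/usr/bin/env python
"""Within-trial exploration: covariance PCA and the three recurrence analyses.

For every block: PCA of the 7 filtered joint-angle channels (pca.csv,
loadings + variance accounted for), then PCA-aRQA of the first-component
scores, cross-RQA of knee vs hip flexion, and multidimensional RQA of the
full joint state (rqa_measures.csv).  Embedding parameters and the
recurrence radius are selected per participant and shared across that
participant's blocks, as in the pipeline.
"""

import argparse
from pathlib import Path

import pandas as pd

from stepshape.coordination import loading_similarity
from stepshape.kinio import read_recording
from stepshape.pipeline import run_pipeline

ap = argparse.ArgumentParser()
ap.add_argument("--data", type=Path, default=Path("results/data"))
ap.add_argument("--out", type=Path, default=Path("results"))
args = ap.parse_args()

recordings = [
    read_recording(tsv, tsv.parent / (tsv.stem + ".meta.yaml"))
    for tsv in sorted(args.data.glob("*.tsv"))
]
res = run_pipeline(recordings, expected_cycles=10, with_fits=False)

args.out.mkdir(parents=True, exist_ok=True)
rqa = res.measures[res.measures["analysis"].isin(["arqa", "crqa", "mdrqa"])]
rqa.to_csv(args.out / "rqa_measures.csv", index=False)
pca = res.measures[res.measures["analysis"] == "pca"]
pca.to_csv(args.out / "pca.csv", index=False)

print(f"recurrence measures for {rqa[['participant','step_height','block']].drop_duplicates().shape[0]} blocks")
print("median determinism (%) per analysis:")
det = rqa[rqa.measure == "det"].groupby("analysis")["value"].median().round(1)
print(det.to_string())

# are the coordination modes similar across blocks? (first-eigenvector dot products)
from stepshape.coordination import pca_first_component
from stepshape.preprocess import lowpass_zero_lag

loadings = {}
for rec in recordings:
    filt = lowpass_zero_lag(rec.angles_deg, rec.fs_hz, 6.0)
    loadings[(rec.participant_id, rec.step_height_m, rec.block)] = \
        pca_first_component(filt).loadings
sims = []
for p in sorted({k[0] for k in loadings}):
    keys = sorted(k for k in loadings if k[0] == p)
    ref = loadings[keys[0]]
    sims += [loading_similarity(ref, loadings[k]) for k in keys[1:]]
print(f"mean loading similarity to each participant's first block: {sum(sims)/len(sims):.3f}")
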