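#!/usr/bin/env python
"""Trial-to-trial dynamics: discontinuities, segment labels, jumps.

For each participant x step-height condition, concatenates the 50 peak
configurations, detects mean discontinuities in the hip/knee execution
variables, labels the segments between them (maintenance / covariation /
change) and classifies each discontinuity as jump or no-jump.  Writes
events.csv and segments.csv and, when ground-truth events are available,
scores the detector against them.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from stepshape.trialdyn import (
    TrialSeries, classify_jumps, classify_segments, detect_discontinuities,
)

ap = argparse.ArgumentParser()
ap.add_argument("--peaks", type=Path, default=Path("results/peaks.csv"))
ap.add_argument("--truth", type=Path, default=Path("results/data/truth_events.json"))
ap.add_argument("--out", type=Path, default=Path("results"))
ap.add_argument("--seed", type=int, default=1)
args = ap.parse_args()

peaks = pd.read_csv(args.peaks).sort_values(["participant", "step_height_m", "block", "movement"])
event_rows, segment_rows = [], []
blocks_with_jump = set()
all_blocks = set(map(tuple, peaks[["participant", "step_height_m", "block"]].drop_duplicates().to_numpy()))

import numpy as np
rng = np.random.default_rng(args.seed)
for (p, h), grp in peaks.groupby(["participant", "step_height_m"]):
    ts = TrialSeries(exec_vars=grp[["hip_deg", "knee_deg"]].to_numpy(),
                     outcome=grp["heel_z_m"].to_numpy())
    idx = detect_discontinuities(ts, rng=rng)
    blocks = grp["block"].to_numpy()
    for sg in classify_segments(ts, idx):
        segment_rows.append(dict(participant=p, step_height_m=h, start=sg.start,
                                 end=sg.end, label=sg.label))
    for ev in classify_jumps(ts, idx):
        blk = int(blocks[ev.at - 1])
        if ev.is_jump:
            blocks_with_jump.add((p, h, blk))
        event_rows.append(dict(participant=p, step_height_m=h, block=blk,
                               movement=ev.at, is_jump=ev.is_jump,
                               shift_hip_deg=ev.mean_shift[0],
                               shift_knee_deg=ev.mean_shift[1]))

events = pd.DataFrame(event_rows)
segments = pd.DataFrame(segment_rows)
args.out.mkdir(parents=True, exist_ok=True)
events.to_csv(args.out / "events.csv", index=False)
segments.to_csv(args.out / "segments.csv", index=False)

label_counts = segments["label"].value_counts().to_dict()
block_rate = len(blocks_with_jump) / len(all_blocks)
print(f"{len(events)} discontinuities ({int(events['is_jump'].sum()) if len(events) else 0} jumps) "
      f"across {len(all_blocks)} blocks")
print(f"segment labels: {label_counts}")
print(f"chance of a jump per block: {100 * block_rate:.1f}%")

if args.truth.exists():
    truth = json.loads(args.truth.read_text())
    truth_blocks = {(t["participant"], t["step_height_m"], t["block"])
                    for t in truth if t["jump_trials"]}
    found = len(truth_blocks & blocks_with_jump)
    print(f"ground truth: jumps injected in {len(truth_blocks)} blocks; "
          f"detector flagged {found} of them "
          f"(recall {found / max(len(truth_blocks), 1):.2f})")
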