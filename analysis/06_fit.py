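#!/usr/bin/env python
"""Block-level mixed-effects models over every measure.

Assembles the per-block measures from the earlier stages into one wide
table (one row per participant x condition x block), fits the
random-intercept linear mixed model (step height, block, interaction) to
every measure and the binomial mixed model to the per-block jump
indicator, and writes fits.csv plus a JSON summary of significant effects.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from stepshape.inference import assemble_results, build_block_table

ap = argparse.ArgumentParser()
ap.add_argument("--results", type=Path, default=Path("results"))
args = ap.parse_args()

peaks = pd.read_csv(args.results / "peaks.csv")
perf = (
    peaks.groupby(["participant", "step_height_m", "block"])
    .agg(clearing_m=("clearing_m", "mean"), peak_height_m=("heel_z_m", "mean"),
         hip_peak_deg=("hip_deg", "mean"), knee_peak_deg=("knee_deg", "mean"))
    .reset_index()
    .melt(id_vars=["participant", "step_height_m", "block"],
          var_name="measure", value_name="value")
    .assign(analysis="perf")
    .rename(columns={"step_height_m": "step_height"})
)
parts = [perf]
for name in ("rqa_measures.csv", "dispersion.csv"):
    path = args.results / name
    if not path.exists():
        continue
    df = pd.read_csv(path)
    if name == "dispersion.csv":
        df = df.melt(id_vars=["participant", "step_height_m", "block"],
                     var_name="measure", value_name="value").assign(analysis="taskspace")
        df = df.rename(columns={"step_height_m": "step_height"})
    parts.append(df[["participant", "step_height", "block", "analysis", "measure", "value"]])

measures = pd.concat(parts, ignore_index=True)
table = build_block_table(measures)

events_path = args.results / "events.csv"
if events_path.exists():
    ev = pd.read_csv(events_path)
    jumps = ev[ev["is_jump"]].groupby(["participant", "step_height_m", "block"]).size()
    heights = sorted(measures["step_height"].unique())
    cond_of = {h: i + 1 for i, h in enumerate(heights)}
    table["jump"] = [
        int((r.participant, heights[int(r.condition) - 1], r.block) in jumps.index)
        for r in table.itertuples()
    ]

bundle = assemble_results(table, jump_column="jump" if "jump" in table else None)
coef = bundle["coefficients"]
coef.to_csv(args.results / "fits.csv", index=False)

sig = coef[(coef["term"] != "Intercept") & (coef["p"] < 0.05)]
summary = {
    "n_measures_fit": len(bundle["fits"]),
    "significant_effects": [
        dict(measure=r.measure, term=r.term, beta=round(r.beta, 4),
             t=round(r.t, 2), df=(None if pd.isna(r.df) else int(r.df)),
             p=round(r.p, 4))
        for r in sig.itertuples()
    ],
}
(args.results / "summary.json").write_text(json.dumps(summary, indent=2))
print(f"fit {summary['n_measures_fit']} block-level models "
      f"(residual df = {int(coef['df'].dropna().iloc[0])})")
print(f"{len(sig)} significant fixed effects at alpha 0.05:")
for s in summary["significant_effects"]:
    print(f"  {s['measure']}: {s['term']} beta={s['beta']} t={s['t']} p={s['p']}")
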