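"""End-to-end orchestration of the stepping-exploration analysis.

Runs every stage on a set of recordings (typically from the synthetic
generator): segmentation and per-movement performance measures, covariance
PCA, the three recurrence analyses, the task-space dispersion measures,
trial-to-trial discontinuity/jump detection, and the block-level mixed
models.  Produces the tidy tables the study reports: a long measures
table, per-event records, and a coefficient table per measure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import coordination, inference, preprocess, rqa, taskspace, trialdyn
from .kinio import Recording, RunConfig, write_measures_table
from .taskspace import LimbModel

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    measures: pd.DataFrame       # long (participant, step_height, block, analysis, measure, value)
    block_table: pd.DataFrame    # wide, one row per participant x condition x block
    qc: pd.DataFrame
    events: pd.DataFrame         # trial-to-trial discontinuities
    segments: pd.DataFrame       # segment labels
    jump_rates: dict
    fits: dict = field(default_factory=dict)
    coefficients: pd.DataFrame | None = None
    underestimation_m: float = float("nan")  # mean measured-minus-model peak-height gap


def _block_measure_rows(rec: Recording, summary: preprocess.BlockSummary) -> list[dict]:
    key = dict(participant=rec.participant_id, step_height=rec.step_height_m, block=rec.block)
    vals = {
        "clearing_m": summary.mean_clearing_m,
        "peak_height_m": summary.mean_peak_height_m,
        "hip_peak_deg": summary.mean_hip_deg,
        "knee_peak_deg": summary.mean_knee_deg,
        "ankle_peak_deg": summary.mean_ankle_deg,
        "rom_hip_deg": summary.rom_hip_deg,
        "rom_knee_deg": summary.rom_knee_deg,
        "rom_ankle_deg": summary.rom_ankle_deg,
        "block_time_s": summary.block_time_s,
    }
    return [dict(**key, analysis="perf", measure=m, value=v) for m, v in vals.items()]


def _rqa_rows(rec: Recording, analysis: str, meas: rqa.RQAMeasures) -> list[dict]:
    key = dict(participant=rec.participant_id, step_height=rec.step_height_m, block=rec.block)
    vals = {"rec": meas.rec_pct, "det": meas.det_pct, "ent": meas.entropy,
            "lmax": float(meas.lmax), "lam": meas.lam_pct}
    return [dict(**key, analysis=analysis, measure=m, value=v) for m, v in vals.items()]


def run_pipeline(
    recordings: list[Recording],
    expected_cycles: int | None = None,
    config: RunConfig | None = None,
    rqa_downsample: int = 2,
    with_rqa: bool = True,
    with_fits: bool = True,
) -> PipelineResult:
    """Run the full analysis over a list of recordings.

    ``rqa_downsample`` decimates the (already 6 Hz low-passed) angle series
    before the recurrence analyses; 2 keeps every second frame (60 Hz),
    which preserves the line structure while quartering the plot size.
    Embedding parameters and the recurrence radius are selected once per
    participant and analysis type (first block) and shared across that
    participant's blocks so recurrence rate stays a comparable outcome.
    """
    cfg = config or RunConfig()
    rows: list[dict] = []
    qc_rows: list[dict] = []
    event_rows: list[dict] = []
    segment_rows: list[dict] = []
    gaps: list[float] = []

    # ---- per-recording segmentation, performance, PCA, task space ----
    per_rec: dict[tuple, dict] = {}
    for rec in recordings:
        cycles, qc = preprocess.segment_cycles(
            rec, expected_cycles, cfg.peak_window_frames, cfg.filter_cutoff_hz
        )
        qc_rows.append(qc)
        samples, summary = preprocess.peak_samples(cycles, rec)
        rows.extend(_block_measure_rows(rec, summary))

        filt = preprocess.lowpass_zero_lag(
            rec.angles_deg, rec.fs_hz, cfg.filter_cutoff_hz, cfg.filter_order
        )
        pca = coordination.pca_first_component(filt)
        rows.append(dict(participant=rec.participant_id, step_height=rec.step_height_m,
                         block=rec.block, analysis="pca", measure="vaf", value=pca.vaf))

        limb = LimbModel(hip_z_m=float(np.median(rec.hip_z_m)),
                         thigh_l_m=rec.thigh_l_m, shank_l_m=rec.shank_l_m)
        pts = np.array([[s.hip_deg, s.knee_deg] for s in samples])
        disp = taskspace.dispersion_summary(
            pts, limb, cfg.ellipse_coverage, cfg.tnc_half_width_deg, cfg.tnc_step_deg
        )
        key = dict(participant=rec.participant_id, step_height=rec.step_height_m, block=rec.block)
        rows.extend(dict(**key, analysis="taskspace", measure=m, value=v) for m, v in [
            ("area_deg2", disp.area_deg2), ("var_eq", disp.var_eq),
            ("var_orth", disp.var_orth), ("t_cost", disp.t_cost)])

        model_heights = taskspace.heel_height_from_recorded(limb, pts[:, 0], pts[:, 1])
        measured = np.array([s.heel_z_m for s in samples])
        gaps.extend((measured - model_heights).tolist())

        per_rec[(rec.participant_id, rec.step_height_m, rec.block)] = dict(
            rec=rec, filt=filt, pca=pca, samples=samples
        )

    # ---- recurrence analyses, radius shared per participant x analysis ----
    if with_rqa:
        ds = max(int(rqa_downsample), 1)
        participants = sorted({k[0] for k in per_rec})
        base_params = rqa.RQAParams(radius=cfg.rqa_radius_frac, lmin=cfg.rqa_lmin,
                                    max_delay=cfg.rqa_max_delay, max_dim=cfg.rqa_max_dim)
        for p in participants:
            keys = sorted(k for k in per_rec if k[0] == p)
            prepared = {}
            for k in keys:
                d = per_rec[k]
                i_hip = 0
                i_knee = 3
                prepared[k] = dict(
                    scores=d["pca"].scores[::ds],
                    knee=d["filt"][::ds, i_knee],
                    hip=d["filt"][::ds, i_hip],
                    angles=d["filt"][::ds, :],
                )
            first = prepared[keys[0]]
            # embedding parameters from the participant's first block
            z0 = (first["scores"] - first["scores"].mean()) / first["scores"].std()
            delay = base_params.delay or rqa.select_delay(z0, base_params.max_delay)
            dim = base_params.dim or rqa.select_dim(z0, delay, base_params.max_dim)
            a_params = rqa.RQAParams(delay=delay, dim=dim, radius=cfg.rqa_radius_frac,
                                     lmin=cfg.rqa_lmin)

            def _eps(maker) -> float:
                return cfg.rqa_radius_frac * max(maker(prepared[k]) for k in keys)

            eps_a = _eps(lambda d: rqa.max_phase_space_distance(
                rqa.embed(_z(d["scores"]), dim, delay)))
            eps_c = _eps(lambda d: rqa.max_phase_space_distance(
                rqa.embed(_unit(d["knee"]), dim, delay),
                rqa.embed(_unit(d["hip"]), dim, delay)))
            eps_m = _eps(lambda d: rqa.max_phase_space_distance(_zcols(d["angles"])))

            for k in keys:
                d = prepared[k]
                rec = per_rec[k]["rec"]
                m_a, _ = rqa.run_arqa(d["scores"], a_params, eps=eps_a)
                m_c, _ = rqa.run_crqa(d["knee"], d["hip"], a_params, eps=eps_c)
                m_m, _ = rqa.run_mdrqa(d["angles"], base_params, eps=eps_m)
                rows.extend(_rqa_rows(rec, "arqa", m_a))
                rows.extend(_rqa_rows(rec, "crqa", m_c))
                rows.extend(_rqa_rows(rec, "mdrqa", m_m))

    # ---- trial-to-trial dynamics per participant x step height ----
    jump_flags: dict[tuple, int] = {k: 0 for k in per_rec}
    conditions = sorted({(k[0], k[1]) for k in per_rec})
    events_by_condition: list[list[trialdyn.JumpEvent]] = []
    rng = np.random.default_rng(cfg.seed)
    for p, h in conditions:
        keys = sorted(k for k in per_rec if k[0] == p and k[1] == h)
        samples = [s for k in keys for s in per_rec[k]["samples"]]
        block_of = np.concatenate([
            np.full(len(per_rec[k]["samples"]), k[2]) for k in keys
        ])
        ts = trialdyn.TrialSeries(
            exec_vars=np.array([[s.hip_deg, s.knee_deg] for s in samples]),
            outcome=np.array([s.heel_z_m for s in samples]),
        )
        idx = trialdyn.detect_discontinuities(
            ts, cfg.trialdyn_alpha, cfg.trialdyn_min_segment, cfg.trialdyn_permutations, rng
        )
        segs = trialdyn.classify_segments(ts, idx, cfg.trialdyn_alpha)
        events = trialdyn.classify_jumps(ts, idx, cfg.trialdyn_alpha)
        events_by_condition.append(events)
        for ev in events:
            blk = int(block_of[ev.at - 1])
            if ev.is_jump:
                jump_flags[(p, h, blk)] = 1
            event_rows.append(dict(participant=p, step_height=h, block=blk,
                                   movement=ev.at, is_jump=ev.is_jump,
                                   shift_hip_deg=ev.mean_shift[0],
                                   shift_knee_deg=ev.mean_shift[1]))
        for sg in segs:
            segment_rows.append(dict(participant=p, step_height=h, start=sg.start,
                                     end=sg.end, label=sg.label))
    rates = trialdyn.jump_rates(events_by_condition)
    rates["block_rate"] = float(np.mean(list(jump_flags.values())))

    measures = write_measures_table(rows)
    block_table = inference.build_block_table(measures)
    jump_df = pd.DataFrame(
        [dict(participant=k[0], step_height=k[1], block=k[2], jump=v)
         for k, v in jump_flags.items()]
    )
    heights = sorted(jump_df["step_height"].unique())
    jump_df["condition"] = jump_df["step_height"].map({h: i + 1 for i, h in enumerate(heights)})
    block_table = block_table.merge(
        jump_df[["participant", "condition", "block", "jump"]],
        on=["participant", "condition", "block"], how="left",
    )

    result = PipelineResult(
        measures=measures,
        block_table=block_table,
        qc=pd.DataFrame(qc_rows),
        events=pd.DataFrame(event_rows),
        segments=pd.DataFrame(segment_rows),
        jump_rates=rates,
        underestimation_m=float(np.mean(gaps)),
    )
    if with_fits:
        bundle = inference.assemble_results(block_table, jump_column="jump",
                                            alpha=cfg.stats_alpha)
        result.fits = bundle["fits"]
        result.coefficients = bundle["coefficients"]
    return result


def _z(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std()


def _unit(x: np.ndarray) -> np.ndarray:
    return (x - x.min()) / np.ptp(x)


def _zcols(x: np.ndarray) -> np.ndarray:
    return (x - x.mean(axis=0)) / x.std(axis=0)
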