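"""Synthetic stepping kinematics with known ground truth.

Emulates the Shaping stepping exercise: a participant repeatedly places the
foot of one leg on a stepper and returns it to the ground.  Each movement
cycle produces a foot-height trace with two peaks (a larger one stepping
up, a smaller one lifting off to return) separated by a shallower interval
with the foot on the stepper, and hip/knee flexion that co-vary
proportionally along a single coordination path.  Foot height is generated
*through* the planar two-segment forward model plus a fixed heel-marker
offset, so the geometry and the kinematics are mutually consistent and the
forward model underestimates measured peak height by exactly that offset.

Across movements the (hip, knee, ankle) configuration at peak foot height
follows a piecewise-constant mean — flat "maintenance" stretches broken by
occasional discrete mean shifts ("jumps") — plus isotropic trial-to-trial
scatter and per-frame observation noise.  Every injected event is recorded
in :class:`SynthTruth` so downstream detectors can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

from .kinio import Recording, write_recording
from .taskspace import LimbModel, heel_height_from_recorded

__all__ = ["SynthConfig", "SynthTruth", "generate_cycle_template", "generate_dataset", "write_dataset"]

# relative foot-height profile: phase fractions of one cycle
_Q_DWELL0 = 0.02   # foot on the ground before lift-off
_Q_RISE1 = 0.23    # rise to the step-up peak
_Q_FALL1 = 0.10    # lower onto the stepper
_Q_STEP = 0.15     # foot on the stepper
_Q_RISE2 = 0.09    # lift off the stepper (second, smaller peak)
_Q_FALL2 = 0.39    # controlled lowering back to the ground
_Q_DWELL1 = 0.02
_STEP_LEVEL_FRAC = 0.55   # stepper-contact level as a fraction of peak lift
_SECOND_PEAK_FRAC = 0.80  # second peak as a fraction of peak lift


class SynthConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SynthConfig:
    """Study-design and signal parameters of the generator.

    Defaults reproduce the study conditions: 4 participants, two
    RCP-titrated step heights practiced in 5 blocks of 10 movements each
    (100 movements per participant), 120 Hz capture, and a 50 % per-block
    chance of a trial-to-trial jump in the peak configuration.
    """

    n_participants: int = 4
    step_heights_m: tuple[float, ...] = (0.20, 0.32)
    blocks_per_height: int = 5
    movements_per_block: int = 10
    fs_hz: float = 120.0
    cycle_duration_mean_s: float = 2.4
    cycle_duration_sd_s: float = 0.2
    thigh_l_m: float = 0.40
    shank_l_m: float = 0.42
    hip_z_m: float = 0.90
    toe_offset_m: float = 0.105     # heel-marker offset the planar model cannot see
    clearing_by_height_m: tuple[float, ...] = (0.079, -0.017)
    coupling_gain: float = 2.5      # knee flexion per unit hip flexion
    ankle_gain: float = 0.6         # ankle dorsiflexion per unit hip flexion
    angle_noise_sd_deg: float = 0.5
    peak_config_sd_deg: float = 2.0
    participant_clearing_sd_m: float = 0.01  # between-participant offset of mean clearing
    jump_prob: float = 0.5
    jump_size_deg: float = 6.0
    drift_deg_per_trial: float = 0.0  # optional continuous drift, off by default
    pre_baseline_s: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1 or self.blocks_per_height < 1:
            raise SynthConfigError("counts must be >= 1")
        if self.movements_per_block < 2:
            raise SynthConfigError("movements_per_block must be >= 2")
        for name in ("fs_hz", "thigh_l_m", "shank_l_m", "hip_z_m", "cycle_duration_mean_s"):
            if getattr(self, name) <= 0:
                raise SynthConfigError(f"{name} must be > 0")
        if any(h <= 0 for h in self.step_heights_m):
            raise SynthConfigError("step heights must be > 0")
        if len(self.clearing_by_height_m) != len(self.step_heights_m):
            raise SynthConfigError("clearing_by_height_m must match step_heights_m")
        if not 0 <= self.jump_prob <= 1:
            raise SynthConfigError("jump_prob must be in [0, 1]")
        if self.cycle_duration_sd_s < 0 or self.angle_noise_sd_deg < 0 or self.peak_config_sd_deg < 0:
            raise SynthConfigError("noise SDs must be >= 0")
        if self.coupling_gain <= 0:
            raise SynthConfigError("coupling_gain must be > 0")
        heel_standing = self.hip_z_m - self.thigh_l_m - self.shank_l_m
        for h, c in zip(self.step_heights_m, self.clearing_by_height_m):
            if h + c - self.toe_offset_m - heel_standing <= 0.01:
                raise SynthConfigError(
                    "step height + clearing must exceed the marker offset plus the "
                    "standing heel height (the limb must contribute lift)"
                )

    @property
    def limb(self) -> LimbModel:
        return LimbModel(hip_z_m=self.hip_z_m, thigh_l_m=self.thigh_l_m, shank_l_m=self.shank_l_m)

    @property
    def heel_standing_m(self) -> float:
        return self.hip_z_m - self.thigh_l_m - self.shank_l_m

    @property
    def foot_baseline_m(self) -> float:
        """Measured foot height with the foot flat on the ground."""
        return self.heel_standing_m


@dataclass
class SynthTruth:
    """Ground truth for one generated block (recording)."""

    cycle_starts: np.ndarray        # first raw frame of each movement
    cycle_ends: np.ndarray          # one-past-last raw frame of each movement
    peak_frames: np.ndarray         # raw frame of peak foot height per movement
    true_peak_configs: np.ndarray   # movements x 3: (hip, knee, ankle) deg, noise-free
    jump_trials: list[int]          # 1-based movement index at which a new mean starts
    generating_params: SynthConfig


def _half_cos(n: int, lo: float, hi: float) -> np.ndarray:
    """Smooth monotone transition lo -> hi over n samples (half raised cosine)."""
    if n <= 0:
        return np.empty(0)
    ph = np.linspace(0.0, np.pi, n, endpoint=False)
    return lo + (hi - lo) * 0.5 * (1.0 - np.cos(ph))


def _relative_profile(n_frames: int) -> np.ndarray:
    """Foot lift profile over one cycle, scaled so the first peak is 1."""
    qs = np.array([_Q_DWELL0, _Q_RISE1, _Q_FALL1, _Q_STEP, _Q_RISE2, _Q_FALL2, _Q_DWELL1])
    edges = np.rint(np.cumsum(np.concatenate([[0.0], qs])) * n_frames).astype(int)
    edges[-1] = n_frames
    seg = [
        np.zeros(edges[1] - edges[0]),
        _half_cos(edges[2] - edges[1], 0.0, 1.0),
        _half_cos(edges[3] - edges[2], 1.0, _STEP_LEVEL_FRAC),
        np.full(edges[4] - edges[3], _STEP_LEVEL_FRAC),
        _half_cos(edges[5] - edges[4], _STEP_LEVEL_FRAC, _SECOND_PEAK_FRAC),
        _half_cos(edges[6] - edges[5], _SECOND_PEAK_FRAC, 0.0),
        np.zeros(edges[7] - edges[6]),
    ]
    # transitions are half-open [lo, hi): each fall segment starts exactly at
    # its peak value, so both local maxima are unique single frames
    return np.concatenate(seg)


def _solve_hip_peak(cfg: SynthConfig, target_lift_m: float) -> float:
    """Hip flexion (deg) whose coupled configuration lifts the heel by target_lift_m."""
    limb = cfg.limb
    hip_max = min(90.0, 180.0 / (1.0 + cfg.coupling_gain)) - 1e-6

    def f(hip):
        return (heel_height_from_recorded(limb, hip, cfg.coupling_gain * hip)
                - cfg.heel_standing_m - target_lift_m)

    if f(hip_max) < 0:
        raise SynthConfigError("target lift unreachable with this geometry/coupling")
    return brentq(f, 1e-9, hip_max, xtol=1e-10)


def generate_cycle_template(
    cycle_duration_s: float,
    fs_hz: float,
    peak_config_deg: tuple[float, float, float],
    cfg: SynthConfig | None = None,
) -> tuple[np.ndarray, np.ndarray, int]:
    """One noise-free movement cycle for a given peak configuration.

    Returns ``(angles_deg, foot_z_m, peak_index)`` where angles is
    frames x 7 in recording channel order.  Joint angles follow a
    proportional path from standing to ``peak_config_deg``, obtained by
    inverting the measured-height map along that path.  Measured foot
    height is the forward model evaluated on the hip/knee channels plus
    the marker offset scaled by the path parameter — zero at standing,
    exactly ``toe_offset_m`` at the movement peak — emulating a planar
    model whose error grows with limb flexion.
    """
    angles, foot, s, pk = _cycle_core(cycle_duration_s, fs_hz, peak_config_deg,
                                      cfg or SynthConfig())
    return angles, foot, pk


def _cycle_core(
    cycle_duration_s: float,
    fs_hz: float,
    peak_config_deg: tuple[float, float, float],
    cfg: SynthConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    if cycle_duration_s < 0.5:
        raise SynthConfigError("cycle_duration_s must be >= 0.5 s")
    if fs_hz < 20:
        raise SynthConfigError("fs_hz must be >= 20 Hz")
    n = int(round(cycle_duration_s * fs_hz))
    if n < 40:
        raise SynthConfigError("cycle too short to contain two foot-height peaks")

    hip_pk, knee_pk, ankle_pk = (float(v) for v in peak_config_deg)
    if not (0 < hip_pk <= 90) or not (0 <= hip_pk + knee_pk <= 180):
        raise SynthConfigError("peak configuration outside the monotone-lift envelope")
    limb = cfg.limb
    lift = (heel_height_from_recorded(limb, hip_pk, knee_pk) + cfg.toe_offset_m
            - cfg.heel_standing_m)
    if lift <= 0:
        raise SynthConfigError("peak configuration does not lift the foot")

    prof = _relative_profile(n)
    target_foot = cfg.heel_standing_m + lift * prof

    # invert measured foot height along the proportional path s -> s * (hip, knee)
    s_grid = np.linspace(0.0, 1.0, 2001)
    foot_grid = (heel_height_from_recorded(limb, s_grid * hip_pk, s_grid * knee_pk)
                 + cfg.toe_offset_m * s_grid)
    s = np.interp(target_foot, foot_grid, s_grid)

    angles = np.empty((n, 7))
    angles[:, 0] = s * hip_pk             # hip_flex
    angles[:, 1] = s * 0.15 * hip_pk      # hip_abd
    angles[:, 2] = s * 0.10 * hip_pk      # hip_rot
    angles[:, 3] = s * knee_pk            # knee_flex
    angles[:, 4] = s * ankle_pk           # ankle_dorsi
    angles[:, 5] = s * 0.20 * ankle_pk    # ankle_inv
    angles[:, 6] = s * 0.10 * ankle_pk    # ankle_rot
    foot_z = heel_height_from_recorded(limb, angles[:, 0], angles[:, 3]) + cfg.toe_offset_m * s
    return angles, foot_z, s, int(np.argmax(prof))


def _base_config(cfg: SynthConfig, height_idx: int, clearing_offset_m: float = 0.0) -> np.ndarray:
    """Mean (hip, knee, ankle) peak configuration for one step-height condition.

    Solved so the *measured* peak foot height (forward model + full marker
    offset) equals step height + clearing target.
    """
    lift_fwd = (cfg.step_heights_m[height_idx] + cfg.clearing_by_height_m[height_idx]
                + clearing_offset_m - cfg.toe_offset_m - cfg.heel_standing_m)
    lift_fwd = max(lift_fwd, 0.01)
    hip = _solve_hip_peak(cfg, lift_fwd)
    return np.array([hip, cfg.coupling_gain * hip, cfg.ankle_gain * hip])


def generate_dataset(cfg: SynthConfig) -> tuple[list[Recording], list[SynthTruth]]:
    """Full synthetic study: one Recording (+ truth) per participant x height x block.

    The peak-configuration mean is piecewise constant across the movement
    sequence of each participant x height condition; with probability
    ``jump_prob`` a block receives one mean shift of ``jump_size_deg`` in a
    random direction of the (hip, knee) plane, at a movement index drawn
    away from the block edges.  Identical configs (including seed) give
    bit-identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    recordings: list[Recording] = []
    truths: list[SynthTruth] = []
    pre_n = int(round(cfg.pre_baseline_s * cfg.fs_hz))
    m = cfg.movements_per_block

    for p in range(cfg.n_participants):
        part_clearing = rng.normal(0.0, cfg.participant_clearing_sd_m)
        for hi in range(len(cfg.step_heights_m)):
            mean_cfg = _base_config(cfg, hi, part_clearing)
            trial_counter = 0
            for b in range(cfg.blocks_per_height):
                jump_trials: list[int] = []
                jump_here = rng.random() < cfg.jump_prob
                lo = min(4, m)  # keep >= 3 movements on each side when possible
                hi_pos = max(m - 2, lo)
                jump_at = int(rng.integers(lo, hi_pos + 1)) if jump_here else -1
                configs = np.empty((m, 3))
                durations = np.empty(m)
                for i in range(m):
                    if jump_here and (i + 1) == jump_at:
                        theta = rng.uniform(0.0, 2.0 * np.pi)
                        mean_cfg = mean_cfg + cfg.jump_size_deg * np.array(
                            [np.cos(theta), np.sin(theta), 0.0]
                        )
                        jump_trials.append(i + 1)
                    drift = cfg.drift_deg_per_trial * trial_counter
                    configs[i] = mean_cfg + drift + rng.normal(0.0, cfg.peak_config_sd_deg, 3)
                    configs[i, 0] = np.clip(configs[i, 0], 2.0, 85.0 / (1 + cfg.coupling_gain) * 2)
                    durations[i] = np.clip(
                        rng.normal(cfg.cycle_duration_mean_s, cfg.cycle_duration_sd_s),
                        cfg.cycle_duration_mean_s - 3 * cfg.cycle_duration_sd_s,
                        cfg.cycle_duration_mean_s + 3 * cfg.cycle_duration_sd_s,
                    )
                    trial_counter += 1

                angle_parts = [np.zeros((pre_n, 7))]
                s_parts = [np.zeros(pre_n)]
                starts = np.empty(m, dtype=int)
                ends = np.empty(m, dtype=int)
                peaks = np.empty(m, dtype=int)
                cursor = pre_n
                for i in range(m):
                    a, _, s, pk = _cycle_core(durations[i], cfg.fs_hz, tuple(configs[i]), cfg)
                    starts[i] = cursor
                    peaks[i] = cursor + pk
                    cursor += a.shape[0]
                    ends[i] = cursor
                    angle_parts.append(a)
                    s_parts.append(s)
                angles = np.vstack(angle_parts)
                s_all = np.concatenate(s_parts)
                if cfg.angle_noise_sd_deg > 0:
                    angles = angles + rng.normal(0.0, cfg.angle_noise_sd_deg, angles.shape)
                foot_z = heel_height_from_recorded(cfg.limb, angles[:, 0], angles[:, 3]) \
                    + cfg.toe_offset_m * s_all
                rec = Recording(
                    participant_id=f"P{p + 1}",
                    step_height_m=cfg.step_heights_m[hi],
                    block=b + 1,
                    fs_hz=cfg.fs_hz,
                    angles_deg=angles,
                    foot_z_m=foot_z,
                    hip_z_m=np.full(angles.shape[0], cfg.hip_z_m),
                    thigh_l_m=cfg.thigh_l_m,
                    shank_l_m=cfg.shank_l_m,
                )
                recordings.append(rec)
                truths.append(
                    SynthTruth(
                        cycle_starts=starts,
                        cycle_ends=ends,
                        peak_frames=peaks,
                        true_peak_configs=configs,
                        jump_trials=jump_trials,
                        generating_params=cfg,
                    )
                )
    return recordings, truths


def write_dataset(recordings: list[Recording], out_dir: str | Path) -> list[Path]:
    """Write every recording to the TSV + YAML schema under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for rec in recordings:
        stem = f"{rec.participant_id}_h{rec.step_height_m:.3f}_b{rec.block}"
        tsv = out / f"{stem}.tsv"
        write_recording(rec, tsv, out / f"{stem}.meta.yaml")
        paths.append(tsv)
    return paths
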