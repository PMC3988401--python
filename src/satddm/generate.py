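"""Synthetic motion-discrimination experiments with the study's design.

The generator emulates a six-session perceptual-learning experiment with a
block-level speed/accuracy manipulation: 6 participants x 6 sessions x 12
blocks x 56 trials (672 trials per session), 6 accuracy and 6 speed blocks
per session with the first block always an accuracy block, 50/50 leftward/
rightward stimuli per block, and per-subject trained direction pairs
(30/210 or 150/330) switched to the untrained pair in session 6.

Choices and RTs are drawn from the drift-diffusion process with per-cell
parameters that follow plausible learning trajectories: boundary separation
declines and drift rate rises over sessions 1-5; speed/accuracy condition
effects are present on a in all sessions and concentrated in early sessions
for v and Ter; session 6 (untrained directions) keeps session-5 boundary but
drops the drift rate. The default magnitudes are generator choices on the
s = 1 scale, not estimates from any dataset.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import ddm
from ._kernels import simulate_cell

__all__ = [
    "ExperimentDesign",
    "GeneratorConfig",
    "GroundTruth",
    "default_design",
    "default_config",
    "sample_ground_truth",
    "generate_experiment",
]

CONDITIONS = ("accuracy", "speed")


@dataclass(frozen=True)
class ExperimentDesign:
    """Design constants of the experiment."""

    n_subjects: int = 6
    n_sessions: int = 6
    blocks_per_session: int = 12
    trials_per_block: int = 56
    accuracy_blocks_per_session: int = 6
    speed_blocks_per_session: int = 6
    response_window_ms: float = 2400.0
    #: trained direction pairs alternated across subjects; each pair is
    #: (rightward deg, leftward deg). Session 6 uses the other pair.
    direction_pairs: tuple = ((30, 210), (150, 330))

    def __post_init__(self):
        if (self.accuracy_blocks_per_session + self.speed_blocks_per_session
                != self.blocks_per_session):
            raise ValueError("accuracy + speed blocks must fill the session")

    @property
    def trials_per_session(self):
        return self.blocks_per_session * self.trials_per_block


def default_design() -> ExperimentDesign:
    return ExperimentDesign()


@dataclass(frozen=True)
class GeneratorConfig:
    """Generating group-level means, trends and spreads (s = 1 scale).

    Trajectories over sessions 1-5 are linear; session 6 models the transfer
    session (boundary carried over from session 5, lower drift). Condition
    effects are additive, split evenly around the session mean: the effect on
    a is constant across sessions, the effects on v and Ter decay linearly to
    zero over `cond_decay_sessions` sessions (largest at the start of
    training).
    """

    a_start: float = 1.8
    a_end: float = 1.2
    a_cond_effect: float = 0.3
    v_start: float = 1.5
    v_end: float = 3.6
    v_session6: float = 2.2
    v_cond_effect0: float = 0.6
    ter_base: float = 0.38
    ter_cond_effect0: float = 0.06
    cond_decay_sessions: float = 3.0
    z_mean: float = 0.5
    sv: float = 1.0
    sz: float = 0.05
    st: float = 0.10
    sd_a: float = 0.15
    sd_v: float = 0.30
    sd_ter: float = 0.03
    sd_z: float = 0.02

    def cell_mean(self, param, session, cond, n_train_sessions=5):
        """Generating group mean of a cell (before subject-level noise)."""
        frac = (min(session, n_train_sessions) - 1) / (n_train_sessions - 1)
        decay = max(0.0, 1.0 - (session - 1) / self.cond_decay_sessions)
        sign = +0.5 if cond == "accuracy" else -0.5
        if param == "a":
            base = self.a_start + frac * (self.a_end - self.a_start)
            return base + sign * self.a_cond_effect
        if param == "v":
            if session > n_train_sessions:
                base = self.v_session6
            else:
                base = self.v_start + frac * (self.v_end - self.v_start)
            return base + sign * self.v_cond_effect0 * decay
        if param == "ter":
            return self.ter_base + sign * self.ter_cond_effect0 * decay
        if param == "z":
            return self.z_mean
        raise KeyError(param)

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def default_config() -> GeneratorConfig:
    return GeneratorConfig()


@dataclass
class GroundTruth:
    """True per-cell parameters plus the generating configuration."""

    params: dict                      # (subject, session, condition) -> DDMParams
    config: GeneratorConfig
    design: ExperimentDesign
    seed: int

    def frame(self) -> pd.DataFrame:
        rows = []
        for (i, s, c), p in self.params.items():
            rows.append({"subject": i, "session": s, "condition": c,
                         "a": p.a, "v": p.v, "z": p.z, "ter": p.ter,
                         "sv": p.sv, "sz": p.sz, "st": p.st})
        return pd.DataFrame(rows)

    def save(self, path):
        self.frame().to_csv(path, index=False)


def sample_ground_truth(design: ExperimentDesign = None,
                        config: GeneratorConfig = None,
                        seed: int = 0) -> GroundTruth:
    """Draw per-subject, per-cell true parameters around the group means.

    Subject deviations are independent normal per cell (matching the fitted
    hierarchy), truncated to the parameter domains. Zero SDs reproduce the
    group trajectory exactly.
    """
    design = design or default_design()
    config = config or default_config()
    if not (0 < config.z_mean - config.sz / 2
            and config.z_mean + config.sz / 2 < 1):
        raise ValueError(
            "generating configuration is invalid: z_mean +- sz/2 must stay "
            "strictly inside (0, 1)")
    for s in range(1, design.n_sessions + 1):
        for c in CONDITIONS:
            if config.cell_mean("ter", s, c) < config.st / 2:
                raise ValueError(
                    f"generating configuration is invalid: mean Ter in "
                    f"session {s} ({c}) is below st/2")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    params = {}
    for i in range(1, design.n_subjects + 1):
        for s in range(1, design.n_sessions + 1):
            # z is shared between conditions within a session
            z = config.z_mean + config.sd_z * rng.standard_normal()
            z = float(np.clip(z, 0.5 * config.sz + 1e-3,
                              1 - 0.5 * config.sz - 1e-3))
            for c in CONDITIONS:
                a = config.cell_mean("a", s, c) \
                    + config.sd_a * rng.standard_normal()
                v = config.cell_mean("v", s, c) \
                    + config.sd_v * rng.standard_normal()
                ter = config.cell_mean("ter", s, c) \
                    + config.sd_ter * rng.standard_normal()
                a = float(max(a, 0.2))
                ter = float(max(ter, 0.5 * config.st + 1e-3))
                try:
                    params[(i, s, c)] = ddm.DDMParams(
                        a=a, v=float(v), z=z, ter=ter,
                        sv=config.sv, sz=config.sz, st=config.st)
                except ddm.ParameterDomainError as err:
                    raise ValueError(
                        f"generating configuration implies an invalid cell "
                        f"(subject {i}, session {s}, {c}): {err}") from err
    return GroundTruth(params=params, config=config, design=design, seed=seed)


def _block_schedule(design, rng):
    """Condition labels of a session's blocks: first is accuracy, the rest a
    random interleaving of the remaining accuracy and speed blocks."""
    rest = (["accuracy"] * (design.accuracy_blocks_per_session - 1)
            + ["speed"] * design.speed_blocks_per_session)
    rng.shuffle(rest)
    return ["accuracy"] + rest


def generate_experiment(design: ExperimentDesign = None,
                        truth: GroundTruth = None,
                        seed: int = 0,
                        dt: float = ddm.DEFAULT_DT) -> pd.DataFrame:
    """Simulate the full trial table for all subjects and sessions.

    Responses are stimulus-coded: the upper boundary is the rightward
    response, and leftward-motion trials negate the drift sign. Trials whose
    simulated response falls outside the response window are emitted with a
    missing response and NaN RT (removable by
    :func:`satddm.behavior.filter_trials`).
    """
    design = design or default_design()
    if truth is None:
        truth = sample_ground_truth(design, seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 202]))
    max_t = design.response_window_ms / 1000.0
    rows = []
    for i in range(1, design.n_subjects + 1):
        trained = design.direction_pairs[(i - 1) % len(design.direction_pairs)]
        untrained = design.direction_pairs[i % len(design.direction_pairs)]
        for s in range(1, design.n_sessions + 1):
            pair = untrained if s == design.n_sessions else trained
            right_deg = pair[0] if pair[0] in (30, 330) else pair[1]
            left_deg = pair[1] if pair[0] in (30, 330) else pair[0]
            schedule = _block_schedule(design, rng)
            # per condition, simulate separate rightward and leftward trial
            # pools; a leftward stimulus negates the drift (stimulus coding:
            # the upper boundary is always the rightward response)
            n_left_blk = design.trials_per_block // 2
            n_right_blk = design.trials_per_block - n_left_blk
            sim = {}
            for c in CONDITIONS:
                n_blocks_c = schedule.count(c)
                p = truth.params[(i, s, c)]
                rt_r, up_r, out_r = simulate_cell(
                    n_blocks_c * n_right_blk, p.a, p.v, p.z, p.ter,
                    p.sv, p.sz, p.st, dt, max_t, int(rng.integers(2 ** 31)))
                rt_l, up_l, out_l = simulate_cell(
                    n_blocks_c * n_left_blk, p.a, -p.v, p.z, p.ter,
                    p.sv, p.sz, p.st, dt, max_t, int(rng.integers(2 ** 31)))
                sim[c] = {"right": [rt_r, up_r, out_r, 0],
                          "left": [rt_l, up_l, out_l, 0]}
            for b, cond in enumerate(schedule, start=1):
                block_rows = []
                for side, n_side in (("right", n_right_blk),
                                     ("left", n_left_blk)):
                    rt_p, up_p, out_p, used = sim[cond][side]
                    for t_idx in range(used, used + n_side):
                        if out_p[t_idx]:
                            resp, rt_ms, correct = None, np.nan, False
                        else:
                            resp = "right" if up_p[t_idx] else "left"
                            rt_ms = rt_p[t_idx] * 1000.0
                            correct = (resp == "right") == (side == "right")
                        block_rows.append({
                            "subject": i, "session": s, "block": b,
                            "condition": cond,
                            "direction_deg": (right_deg if side == "right"
                                              else left_deg),
                            "response": resp, "correct": bool(correct),
                            "rt_ms": rt_ms,
                        })
                    sim[cond][side][3] = used + n_side
                order = rng.permutation(len(block_rows))
                rows.extend(block_rows[j] for j in order)
    return pd.DataFrame(rows)
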