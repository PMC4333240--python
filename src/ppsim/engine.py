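"""The per-step simulation loop, seeded replicates, and per-run summaries.

A run advances t = 0 -> 72 h (E14.5 -> E17.5) in fixed steps (default 1 min):

1. inject newly arrived LTin and LTi cells at uniformly random positions,
   following the configured cumulative entry schedules;
2. move every migrating cell one step (unbiased walk for LTin,
   chemokine-biased walk for LTi);
3. collect cell-LTo overlap events and arrest tests against the LTo states
   at the start of the step, then apply all LTo updates at once.

The synchronous LTo update makes the step outcome independent of cell
ordering, which lets the engine update all cells with array operations; a
run is a pure function of (configuration, seed).  At the end of the window
arrested cells are clustered into patches and summarised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .agents import LTI, LTIN
from ._kernels import run_chunk
from .config import SimConfig
from .environment import Environment, create_environment
from .migration import InputSchedule, cells_to_inject, cumulative_input, e155_count
from .patches import detect_patches


def derive_seed(base_seed: int, index: int) -> int:
    """Collision-free replicate seed from (base seed, replicate index)."""
    ss = np.random.SeedSequence([int(base_seed), int(index)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


@dataclass
class RunResult:
    """Per-run summary: the two analysed responses plus audit fields."""

    patch_count: int
    median_patch_area: float  # um^2; 0.0 when no patches formed
    total_cells_in: int
    seed: int
    n_arrested: int = 0
    n_lto_differentiated: int = 0


@dataclass
class ConditionResult:
    """The distribution of run summaries for one parameter condition."""

    label: str
    runs: list[RunResult] = field(default_factory=list)

    @property
    def patch_counts(self) -> np.ndarray:
        return np.array([r.patch_count for r in self.runs], dtype=float)

    @property
    def median_areas(self) -> np.ndarray:
        return np.array([r.median_patch_area for r in self.runs], dtype=float)

    def response(self, name: str) -> np.ndarray:
        if name == "patch_count":
            return self.patch_counts
        if name == "median_patch_area":
            return self.median_areas
        raise KeyError(f"unknown response {name!r}")


RESPONSES = ("patch_count", "median_patch_area")


@dataclass
class SimState:
    """Mutable state of one run (exposed for summarisation and inspection)."""

    config: SimConfig
    env: Environment
    pos: np.ndarray  # (capacity, 2)
    kind: np.ndarray  # (capacity,) int8
    arrested: np.ndarray  # (capacity,) bool
    entry_time: np.ndarray  # (capacity,) hours
    n_cells: int = 0
    seed: int = 0


def build_schedules(config: SimConfig) -> tuple[InputSchedule, InputSchedule]:
    """LTin and LTi entry schedules implied by a configuration.

    The LTin count at E15.5 comes from the configured surface-area fraction
    (times any fold multiplier); the LTi schedule is configured
    independently (and ignores the fold), so perturbing the LTin assumption
    leaves inducer input untouched.
    """
    inp = config.input
    area = config.gut_area_um2
    r = config.cells.motile_radius_um
    n_ltin = e155_count(inp.fraction_pct / 100.0, area, r) * inp.fold
    n_lti = e155_count(inp.lti_fraction_pct / 100.0, area, r)
    ltin = InputSchedule(
        form=inp.form, n_e155=n_ltin, k=inp.k_per_hour, t_end=inp.t_end_hours
    )
    lti = InputSchedule(
        form=inp.lti_form, n_e155=n_lti, k=inp.k_per_hour, t_end=inp.t_end_hours
    )
    return ltin, lti


def _total_input(s: InputSchedule) -> int:
    return int(np.floor(cumulative_input(s.t_end, s) + 1e-9))


CHUNK_STEPS = 360  # steps advanced per compiled-kernel call


def _injection_plan(
    config: SimConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-step injection counts for both cell kinds, plus step end times.

    The plan depends only on the configuration (the schedules are
    deterministic), which is what allows random draws to be generated in
    blocks ahead of the compiled chunk loop.
    """
    sched_ltin, sched_lti = build_schedules(config)
    n_steps = config.n_steps
    dt_h = config.dt_minutes / 60.0
    ltin_counts = np.zeros(n_steps, dtype=np.int64)
    lti_counts = np.zeros(n_steps, dtype=np.int64)
    t_hours = np.zeros(n_steps)
    carry = [0.0, 0.0]
    t = 0.0
    for s in range(n_steps):
        t_next = t + dt_h
        c, carry[0] = cells_to_inject(
            t, min(t_next, sched_ltin.t_end), sched_ltin, carry[0]
        )
        ltin_counts[s] = c
        c, carry[1] = cells_to_inject(
            t, min(t_next, sched_lti.t_end), sched_lti, carry[1]
        )
        lti_counts[s] = c
        t_hours[s] = t_next
        t = t_next
    return ltin_counts, lti_counts, t_hours


def _kernel_params(config: SimConfig, env: Environment) -> tuple:
    return (
        env.width,
        env.height,
        config.cells.speed_um_per_min * config.dt_minutes,
        config.cells.motile_radius_um + env.lto_radius,
        config.adhesion.r_adh_um,
        env.r_chem,
        env.chemokine_threshold,
        env.fd_step,
        config.adhesion.l0,
        config.adhesion.dl,
    )


def run_simulation(config: SimConfig, seed: int) -> RunResult:
    """Simulate one 72-hour developmental window and summarise it."""
    state = _init_state(config, seed)
    rng = state._rng  # type: ignore[attr-defined]
    env = state.env
    ltin_counts, lti_counts, t_hours = _injection_plan(config)
    params = _kernel_params(config, env)
    n = 0
    for lo in range(0, config.n_steps, CHUNK_STEPS):
        hi = min(lo + CHUNK_STEPS, config.n_steps)
        lc = ltin_counts[lo:hi]
        ic = lti_counts[lo:hi]
        total_inj = int(lc.sum() + ic.sum())
        inj_pos = rng.random((total_inj, 2))
        n_max = n + total_inj
        theta_u = rng.random((hi - lo, n_max))
        arrest_u = rng.random((hi - lo, n_max))
        n = run_chunk(
            state.pos,
            state.kind,
            state.arrested,
            state.entry_time,
            n,
            lc,
            ic,
            inj_pos,
            t_hours[lo:hi],
            theta_u,
            arrest_u,
            env.lto_xy,
            env.lto_differentiated,
            env.lto_expression,
            env.lto_lti_contacts,
            *params,
        )
        state.n_cells = n
    return summarise_run(state)


def _init_state(config: SimConfig, seed: int) -> SimState:
    config.validate()
    rng = np.random.default_rng(seed)
    env = create_environment(config, rng)
    sched_ltin, sched_lti = build_schedules(config)
    capacity = _total_input(sched_ltin) + _total_input(sched_lti)
    state = SimState(
        config=config,
        env=env,
        pos=np.zeros((capacity, 2)),
        kind=np.zeros(capacity, dtype=np.int8),
        arrested=np.zeros(capacity, dtype=bool),
        entry_time=np.zeros(capacity),
        n_cells=0,
        seed=int(seed),
    )
    state._rng = rng  # type: ignore[attr-defined]
    env.motile_cells = state  # the environment's motile collection
    return state


def _inject(
    state: SimState, kind: int, n_new: int, t_h: float, rng: np.random.Generator
) -> None:
    lo, hi = state.n_cells, state.n_cells + n_new
    state.pos[lo:hi] = rng.random((n_new, 2)) * (
        state.env.width,
        state.env.height,
    )
    state.kind[lo:hi] = kind
    state.entry_time[lo:hi] = t_h
    state.n_cells = hi


def _step(state: SimState, rng: np.random.Generator) -> None:
    """Advance every motile cell by one time step (synchronous LTo update).

    Per-step random draws come from the run's Generator in a fixed order
    (directions, then arrest tests, each for the migrating cells in storage
    order); the compiled kernel consumes them deterministically.
    """
    n = state.n_cells
    if n == 0:
        return
    env = state.env
    theta_u = rng.random((1, n))
    arrest_u = rng.random((1, n))
    no_inject = np.zeros(1, dtype=np.int64)
    run_chunk(
        state.pos,
        state.kind,
        state.arrested,
        state.entry_time,
        n,
        no_inject,
        no_inject,
        np.empty((0, 2)),
        np.zeros(1),
        theta_u,
        arrest_u,
        env.lto_xy,
        env.lto_differentiated,
        env.lto_expression,
        env.lto_lti_contacts,
        *_kernel_params(state.config, env),
    )


def summarise_run(state: SimState) -> RunResult:
    """Cluster arrested cells into patches and reduce to count and median area.

    With ``patches.basis = "lto"`` the clustering runs over differentiated
    LTo centres instead of arrested motile cells (an alternative reading of
    what a measured patch is); the shipped default is cell clusters.
    """
    cfg = state.config
    n = state.n_cells
    if cfg.patches.basis == "lto":
        pts = state.env.lto_xy[state.env.lto_differentiated]
        radius = state.env.lto_radius
    else:
        pts = state.pos[:n][state.arrested[:n]]
        radius = cfg.cells.motile_radius_um
    found = detect_patches(
        pts,
        cfg.patches.linking_distance_um,
        cfg.patches.min_size,
        width=state.env.width,
        cell_radius=radius,
    )
    areas = np.array([p.area for p in found], dtype=float)
    median_area = float(np.median(areas)) if len(areas) else 0.0
    return RunResult(
        patch_count=len(found),
        median_patch_area=median_area,
        total_cells_in=n,
        seed=state.seed,
        n_arrested=int(state.arrested[:n].sum()),
        n_lto_differentiated=int(state.env.lto_differentiated.sum()),
    )


def run_replicates(config: SimConfig, n: int, base_seed: int, label: str = "") -> ConditionResult:
    """Run ``n`` independent replicates with seeds derived from ``base_seed``.

    Replicate i runs with ``derive_seed(base_seed, i)``; the mapping is
    deterministic and collision-free, and each run records its seed so any
    replicate can be reproduced in isolation.
    """
    if n < 1:
        raise ValueError("replicate count must be >= 1")
    result = ConditionResult(label=label or f"base_seed={base_seed}")
    for i in range(n):
        result.runs.append(run_simulation(config, derive_seed(base_seed, i)))
    return result
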