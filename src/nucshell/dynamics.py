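"""Langevin dynamics and the staged relaxation/production protocol.

Integration uses the BAOAB splitting of Langevin dynamics (velocity half-kick,
half-drift, Ornstein-Uhlenbeck velocity refresh, half-drift, half-kick) at
timestep dt = 0.005 tau with unit mass, unit friction and kT = 1 by default.
The staged protocol mirrors a nucleus-assembly run: a short shell-relaxation
phase with all chromatin-shell attractions off (the freshly built shell
contracts by ~30% onto its bond rest lengths), a polymer-relaxation phase with
attractions on, and a long production phase.  Inverted-organization runs keep
chromatin-shell attractions off throughout and run production twice as long.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels
from .forcefield import ForceFieldPreset, shell_bond
from .types import (
    BOND_BACKBONE,
    BOND_CROSSLINK,
    BOND_SHELL,
    BeadType,
    InitialConfiguration,
    SystemState,
    Trajectory,
)

FULL_SHELL_RELAX_STEPS = 30_000
FULL_POLYMER_RELAX_STEPS = 100_000
FULL_PRODUCTION_CONV = 5_000_000
FULL_PRODUCTION_INV = 10_000_000
REDUCED_STEP_FACTOR = 1.0 / 50.0
REDUCED_SHELL_RELAX_STEPS = 5_000
# The freshly built shell starts with every bond stretched ~43% over rest;
# the relaxation phase runs overdamped (friction x this factor) so the shell
# contracts quasi-statically onto its rest geometry instead of collapsing
# inertially into long-lived wrinkles.
SHELL_RELAX_FRICTION_FACTOR = 10.0


class IntegrationError(RuntimeError):
    pass


class IntegrityError(RuntimeError):
    pass


@dataclass
class IntegratorConfig:
    """Langevin integrator settings (reduced units)."""

    dt: float = 0.005
    temperature: float = 1.0
    friction: float = 1.0
    seed: int = 0
    neighbor_skin: float = 0.5
    remove_drift: bool = True

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.friction <= 0:
            raise ValueError("friction must be positive")
        if self.neighbor_skin <= 0:
            raise ValueError("neighbor_skin must be positive")


@dataclass
class ProtocolSchedule:
    """Step counts of the staged protocol, scalable for desk-size runs."""

    shell_relax_steps: int = FULL_SHELL_RELAX_STEPS
    polymer_relax_steps: int = FULL_POLYMER_RELAX_STEPS
    production_steps: int = FULL_PRODUCTION_CONV
    snapshot_interval: int = 25_000
    scale_factor: float = 1.0

    def __post_init__(self) -> None:
        if min(self.shell_relax_steps, self.polymer_relax_steps,
               self.production_steps) < 0:
            raise ValueError("step counts must be non-negative")

    def scaled(self) -> "ProtocolSchedule":
        f = self.scale_factor
        return ProtocolSchedule(
            shell_relax_steps=int(round(self.shell_relax_steps * f)),
            polymer_relax_steps=int(round(self.polymer_relax_steps * f)),
            production_steps=int(round(self.production_steps * f)),
            snapshot_interval=max(1, int(round(self.snapshot_interval * f))),
            scale_factor=1.0,
        )

    @classmethod
    def reduced(cls, inverted: bool = False,
                factor: float = REDUCED_STEP_FACTOR) -> "ProtocolSchedule":
        """Desk-scale schedule: production scaled down, relaxation kept converged.

        Production (a sampling problem) scales with ``factor``; the shell
        relaxation phase is a fixed physical-time transient (its duration is
        set by friction and bond stiffness, not by system size) and is kept at
        a length where the contraction has converged.
        """
        prod = FULL_PRODUCTION_INV if inverted else FULL_PRODUCTION_CONV
        sched = cls(
            shell_relax_steps=FULL_SHELL_RELAX_STEPS,
            polymer_relax_steps=FULL_POLYMER_RELAX_STEPS,
            production_steps=prod,
            snapshot_interval=25_000,
            scale_factor=factor,
        ).scaled()
        sched.shell_relax_steps = REDUCED_SHELL_RELAX_STEPS
        return sched


# ---------------------------------------------------------------------------
# state assembly

def make_state(
    config: InitialConfiguration,
    preset: ForceFieldPreset,
    cfg: IntegratorConfig | None = None,
) -> SystemState:
    """Assemble a SystemState (chain beads first, then shell beads).

    Velocities are Maxwell-Boltzmann at the integrator temperature, seeded.
    """
    cfg = cfg or IntegratorConfig()
    chain_types = config.chain_types()
    shell = config.shell
    n_chain = len(config.chain_positions)
    positions = np.concatenate([
        np.asarray(config.chain_positions, dtype=np.float64).reshape(n_chain, 3),
        shell.positions,
    ])
    types = np.concatenate([
        chain_types, np.full(shell.n_beads, BeadType.S, dtype=np.int8)
    ])
    chain_id = np.concatenate([
        config.chain_ids(), np.full(shell.n_beads, -1, dtype=np.int64)
    ])

    bi, bj, kind, r0, k, dmax = [], [], [], [], [], []
    # chain backbones
    offset = 0
    bb = preset.backbone
    for plan in config.plans:
        for i in range(plan.n_beads - 1):
            bi.append(offset + i)
            bj.append(offset + i + 1)
            kind.append(BOND_BACKBONE)
            r0.append(bb.rest_length)
            k.append(bb.stiffness)
            dmax.append(bb.max_extension)
        offset += plan.n_beads
    # crosslinks
    if config.crosslinks.enabled:
        cl = preset.crosslink
        for i, j in config.crosslinks.pairs:
            bi.append(int(i))
            bj.append(int(j))
            kind.append(BOND_CROSSLINK)
            r0.append(cl.rest_length)
            k.append(cl.stiffness)
            dmax.append(cl.max_extension)
    # shell bonds (per-bond rest lengths)
    for (i, j), rl in zip(shell.bonds, shell.rest_length):
        spec = shell_bond(float(rl), preset.shell_stiffness, preset.shell_ext_factor)
        bi.append(n_chain + int(i))
        bj.append(n_chain + int(j))
        kind.append(BOND_SHELL)
        r0.append(spec.rest_length)
        k.append(spec.stiffness)
        dmax.append(spec.max_extension)

    rng = np.random.default_rng(cfg.seed)
    vel = rng.normal(scale=np.sqrt(cfg.temperature), size=positions.shape)
    return SystemState(
        positions=positions,
        velocities=vel,
        types=types,
        chain_id=chain_id,
        bond_i=np.array(bi, dtype=np.int64),
        bond_j=np.array(bj, dtype=np.int64),
        bond_kind=np.array(kind, dtype=np.int8),
        bond_r0=np.array(r0, dtype=np.float64),
        bond_k=np.array(k, dtype=np.float64),
        bond_dmax=np.array(dmax, dtype=np.float64),
    )


# ---------------------------------------------------------------------------
# simulation driver

class Simulation:
    """Holds a state, a force field and the neighbor-list bookkeeping."""

    MAX_PAIRS_PER_BEAD = 90

    def __init__(self, state: SystemState, preset: ForceFieldPreset,
                 cfg: IntegratorConfig | None = None,
                 shell_attraction_off: bool = False):
        self.state = state
        self.preset = preset
        self.cfg = cfg or IntegratorConfig()
        self.rng = np.random.default_rng(self.cfg.seed)
        self.set_shell_attraction(off=shell_attraction_off)
        n = state.n_beads
        self._pairs = np.empty((self.MAX_PAIRS_PER_BEAD * n, 2), dtype=np.int64)
        self._n_pairs = 0
        self._forces = np.empty((n, 3))
        self._ref_pos = None
        self._pe = 0.0
        # BAOAB OU coefficients
        g = self.cfg.friction
        self._ou_c1 = np.exp(-g * self.cfg.dt)
        self._ou_c2 = np.sqrt((1.0 - self._ou_c1 ** 2) * self.cfg.temperature)
        self._compute_forces(rebuild=True)

    # -- force-field plumbing ------------------------------------------------
    def set_shell_attraction(self, off: bool) -> None:
        table = self.preset.table
        if off:
            table = table.with_shell_attraction_off()
        self._A, self._C, self._rc2, self._sig2 = table.kernel_tables()
        skin = self.cfg.neighbor_skin
        self._rlist2 = np.ascontiguousarray((np.sqrt(self._rc2) + skin) ** 2)
        self._cell_size = float(np.sqrt(self._rlist2).max())
        self._ref_pos = None  # force rebuild under the new cutoffs

    # -- internals -----------------------------------------------------------
    def _rebuild_needed(self) -> bool:
        if self._ref_pos is None:
            return True
        lim = (0.5 * self.cfg.neighbor_skin) ** 2
        return _kernels.max_displacement_sq(self.state.positions, self._ref_pos) > lim

    def _compute_forces(self, rebuild: bool | None = None) -> None:
        st = self.state
        if rebuild or (rebuild is None and self._rebuild_needed()):
            n = _kernels.build_neighbor_pairs_cells(
                st.positions, st.types, self._rlist2, self._cell_size, self._pairs
            )
            if n < 0:
                raise IntegrationError("neighbor list overflow; system too dense")
            self._n_pairs = n
            self._ref_pos = st.positions.copy()
        pe, bad = _kernels.compute_forces(
            st.positions, st.types, self._pairs, self._n_pairs,
            self._A, self._C, self._rc2, self._sig2,
            st.bond_i, st.bond_j, st.bond_r0, st.bond_k, st.bond_dmax,
            self._forces,
        )
        if bad >= 0:
            if np.isnan(pe):
                raise IntegrationError(
                    f"coincident bead pair at step {st.step} (singular geometry)"
                )
            raise IntegrationError(
                f"bond {bad} (beads {st.bond_i[bad]}-{st.bond_j[bad]}) overstretched "
                f"at step {st.step}"
            )
        self._pe = pe

    def step(self, n_steps: int = 1) -> None:
        """Advance n_steps of BAOAB Langevin dynamics."""
        st = self.state
        dt = self.cfg.dt
        half = 0.5 * dt
        for _ in range(n_steps):
            st.velocities += half * self._forces
            st.positions += half * st.velocities
            noise = self.rng.standard_normal(st.positions.shape)
            st.velocities *= self._ou_c1
            st.velocities += self._ou_c2 * noise
            st.positions += half * st.velocities
            if self.cfg.remove_drift:
                st.velocities -= st.velocities.mean(axis=0)
            self._compute_forces()
            st.velocities += half * self._forces
            st.step += 1

    # -- diagnostics ---------------------------------------------------------
    def potential_energy(self) -> float:
        return float(self._pe)

    def kinetic_energy(self) -> float:
        return float(0.5 * np.sum(self.state.velocities ** 2))

    def check_containment(self, margin: float = 3.0) -> None:
        st = self.state
        chain = st.positions[st.chain_mask]
        if len(chain) == 0:
            return
        shell_pos = st.positions[st.shell_mask]
        com = shell_pos.mean(axis=0)
        r_shell = np.linalg.norm(shell_pos - com, axis=1)
        r_chain = np.linalg.norm(chain - com, axis=1)
        worst = int(np.argmax(r_chain))
        if r_chain[worst] > r_shell.max() + margin:
            raise IntegrityError(
                f"chain bead escaped the shell at step {st.step} "
                f"(radius {r_chain[worst]:.2f} vs shell max {r_shell.max():.2f})"
            )


def _snapshot(sim: Simulation, frames, steps, phases, radii, diags, label) -> None:
    st = sim.state
    frames.append(st.positions.astype(np.float32).copy())
    steps.append(st.step)
    phases.append(label)
    r = st.mean_shell_radius() if st.shell_mask.any() else np.nan
    radii.append(r)
    med = {}
    for code in "EFCT":
        mask = st.types == BeadType[code]
        if mask.any():
            shell_pos = st.positions[st.shell_mask]
            com = shell_pos.mean(axis=0) if len(shell_pos) else np.zeros(3)
            med[f"median_r_{code}"] = float(
                np.median(np.linalg.norm(st.positions[mask] - com, axis=1))
            )
    diags.append({
        "step": st.step,
        "phase": label,
        "potential_energy": sim.potential_energy(),
        "kinetic_energy": sim.kinetic_energy(),
        "mean_shell_radius": r,
        **med,
    })


def run_phase(
    state: SystemState,
    preset: ForceFieldPreset,
    cfg: IntegratorConfig,
    n_steps: int,
    label: str = "production",
    snapshot_interval: int = 1000,
    shell_attraction_off: bool = False,
    sim: Simulation | None = None,
    check_containment: bool = True,
) -> Trajectory:
    """Advance one protocol phase in place; returns the phase trajectory.

    The first frame is the entry state; frames follow every
    ``snapshot_interval`` steps.  Deterministic for a fixed integrator seed.
    """
    if n_steps < 0:
        raise ValueError("n_steps must be non-negative")
    if sim is None:
        sim = Simulation(state, preset, cfg, shell_attraction_off=shell_attraction_off)
    else:
        sim.set_shell_attraction(off=shell_attraction_off)
        sim._compute_forces(rebuild=True)
    frames, steps, phases, radii, diags = [], [], [], [], []
    _snapshot(sim, frames, steps, phases, radii, diags, label)
    done = 0
    while done < n_steps:
        chunk = min(snapshot_interval, n_steps - done)
        try:
            sim.step(chunk)
        except IntegrationError as exc:
            raise IntegrationError(f"[{label}] {exc}") from exc
        done += chunk
        if check_containment:
            sim.check_containment()
        _snapshot(sim, frames, steps, phases, radii, diags, label)
    return Trajectory(
        frames=np.array(frames),
        steps=np.array(steps),
        phases=phases,
        types=state.types.copy(),
        chain_id=state.chain_id.copy(),
        mean_shell_radius=np.array(radii),
        diagnostics=pd.DataFrame(diags),
    )


def langevin_step(state: SystemState, preset: ForceFieldPreset,
                  cfg: IntegratorConfig) -> SystemState:
    """Single Langevin update (convenience wrapper; heavy use should hold a Simulation)."""
    sim = Simulation(state, preset, cfg)
    sim.step(1)
    return state


def run_protocol(
    config: InitialConfiguration,
    preset: ForceFieldPreset,
    schedule: ProtocolSchedule,
    cfg: IntegratorConfig | None = None,
) -> Trajectory:
    """Shell relaxation (chromatin-shell attraction off) -> polymer relaxation -> production."""
    cfg = cfg or IntegratorConfig()
    sched = schedule.scaled() if schedule.scale_factor != 1.0 else schedule
    state = make_state(config, preset, cfg)
    from dataclasses import replace as _replace

    relax_cfg = _replace(cfg, friction=cfg.friction * SHELL_RELAX_FRICTION_FACTOR)
    relax_sim = Simulation(state, preset, relax_cfg, shell_attraction_off=True)
    parts = []
    parts.append(run_phase(
        state, preset, relax_cfg, sched.shell_relax_steps, "shell_relax",
        snapshot_interval=max(1, min(sched.snapshot_interval, 500)),
        shell_attraction_off=True, sim=relax_sim,
    ))
    sim = Simulation(state, preset, cfg)
    parts.append(run_phase(
        state, preset, cfg, sched.polymer_relax_steps, "polymer_relax",
        snapshot_interval=sched.snapshot_interval, sim=sim,
    ))
    parts.append(run_phase(
        state, preset, cfg, sched.production_steps, "production",
        snapshot_interval=sched.snapshot_interval, sim=sim,
    ))
    return Trajectory.concatenate(parts)
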