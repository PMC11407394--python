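"""Scenario grid, reduced-scale presets and analytic shell fixtures.

The scenario runner replays the model's standard condition grid — volume-fraction,
heterochromatin-shell affinity, heterochromatin self-affinity and
heterochromatin-content sweeps, with conventional and inverted organization —
at a reduced desk scale that preserves the dimensionless control parameters
(affinities in kT, volume fraction, heterochromatin fraction).  The analytic
shell fixtures place beads on a sphere with imposed Fourier modes so the whole
analysis stage is testable without running any dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .builder import (
    add_crosslinks,
    build_chromosome_plan,
    build_shell_mesh,
    default_shell_count,
    place_compact_chains,
)
from .dynamics import IntegratorConfig, ProtocolSchedule, run_protocol
from .forcefield import ForceFieldPreset, make_preset
from .observables import (
    SliceSpec,
    chain_compaction,
    fluctuation_spectrum,
    median_radius_by_type,
    radial_density_profile,
)
from .types import BeadType, InitialConfiguration, SystemState, Trajectory

# ---------------------------------------------------------------------------
# reduced scale
#
# The reduced system keeps the full-scale composition ratios (1/6 of the
# chain is the constitutive block, two telomere beads, alternating E/F
# compartment blocks) in a shell of R0 = 14 sigma.  Chain length is chosen so
# that n_block = 8 fills the relaxed shell (radius 0.7*R0) to ~23% bead volume
# fraction, matching the condition labels phi = 14/19/23% for n_block = 4/6/8.

REDUCED_R0 = 14.0
REDUCED_N_CONSTITUTIVE = 35
REDUCED_N_COMPARTMENT = 175
REDUCED_BLOCK_LENGTH = 8.0  # beads; scaled with chain length from the 40-bead default

NBLOCK_PHI = {4: 14.0, 6: 19.0, 8: 23.0}


def reduced_chain_plan(f_het: float = 0.5, seed: int = 0,
                       block_length_mean: float = REDUCED_BLOCK_LENGTH):
    return build_chromosome_plan(
        REDUCED_N_CONSTITUTIVE, REDUCED_N_COMPARTMENT, f_het,
        block_length_mean, seed,
    )


def build_reduced_configuration(
    n_block: int = 8,
    f_het: float = 0.5,
    seed: int = 0,
    R0: float = REDUCED_R0,
    crosslinks: bool = False,
    crosslink_cutoff: float = 1.3,
) -> InitialConfiguration:
    """Reduced-scale initial configuration: chains + shell (+ crosslinks)."""
    rng = np.random.SeedSequence(seed)
    chain_seeds = rng.generate_state(n_block + 2)
    plans = [
        reduced_chain_plan(f_het, int(s) % (2 ** 31)) for s in chain_seeds[:n_block]
    ]
    shell = build_shell_mesh(
        n_shell=default_shell_count(R0), R0=R0,
        seed=int(chain_seeds[-1]) % (2 ** 31),
    )
    config = place_compact_chains(plans, shell, seed=int(chain_seeds[-2]) % (2 ** 31))
    config.phi_nominal = NBLOCK_PHI.get(n_block)
    if crosslinks:
        config = add_crosslinks(config, crosslink_cutoff, seed=seed)
    return config


# ---------------------------------------------------------------------------
# scenario grid

@dataclass
class ScenarioConfig:
    """One grid point of the condition sweeps."""

    scenario_id: str
    n_block: int = 8
    preset: str = "conventional"
    u_HS: float | None = None
    u_HH: float | None = None
    f_het: float = 0.5
    crosslinks: bool = False
    u_CC_on: bool = True
    het_shell_scope: str = "both"
    stiff_shell: bool = False
    seeds: list[int] = field(default_factory=lambda: [1, 2, 3])
    scale: str = "reduced"
    steps_factor: float = 1.0

    def phi_nominal(self) -> float | None:
        return NBLOCK_PHI.get(self.n_block)

    def make_preset(self) -> ForceFieldPreset:
        return make_preset(
            name="stiff_shell" if self.stiff_shell else self.preset,
            u_HS=self.u_HS,
            u_HH=self.u_HH,
            het_shell_scope=self.het_shell_scope,
            u_CC=None if self.u_CC_on else 0.0,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        return cls(**d)


def scenarios_to_yaml(configs: list[ScenarioConfig]) -> str:
    return yaml.safe_dump_all([c.to_dict() for c in configs], sort_keys=False)


def scenarios_from_yaml(doc: str) -> list[ScenarioConfig]:
    return [ScenarioConfig.from_dict(d) for d in yaml.safe_load_all(doc) if d]


def condition_grid(seeds: list[int] | None = None) -> list[ScenarioConfig]:
    """The full standard condition grid, one ScenarioConfig per condition.

    Volume-fraction grid: 3 phi analogs x {crosslinks on/off} x {C-C attraction
    on/off} x {conventional, inverted}.  Affinity grid: u_HS in {0.375, 0.75,
    1.5, 3} kT x heterochromatin-shell scope {both, C-only, F-only} at the
    phi = 19% analog.  Self-affinity grid: u_HH in {0, 0.65, 1.30, default}
    x u_HS in {0.375, 0.75, 1.5, 3}.  Content sweep: f in {10, 30, 45, 55,
    75}% x 3 phi analogs (conventional) plus the inverted f sweep at phi = 19%
    and the f = 75% / self-affinity-off condition at phi = 14%.  Plus the
    stiff-shell variant.
    """
    seeds = seeds or [1, 2, 3]
    grid: list[ScenarioConfig] = []

    def add(sid: str, **kw):
        grid.append(ScenarioConfig(scenario_id=sid, seeds=list(seeds), **kw))

    # volume fraction x internal-structure variants, conventional + inverted
    for n_block in (4, 6, 8):
        for preset in ("conventional", "inverted"):
            for xl in (False, True):
                for ucc in (True, False):
                    add(
                        f"phi{NBLOCK_PHI[n_block]:.0f}_{preset}"
                        f"_xl{'+' if xl else '-'}_ucc{'+' if ucc else '-'}",
                        n_block=n_block, preset=preset,
                        crosslinks=xl, u_CC_on=ucc,
                    )
    # heterochromatin-shell affinity x scope at phi = 19%
    for u_hs in (0.375, 0.75, 1.5, 3.0):
        for scope in ("both", "c_only", "f_only"):
            add(f"uHS{u_hs}_{scope}", n_block=6, u_HS=u_hs, het_shell_scope=scope)
    # self-affinity x shell affinity at phi = 19% (None = default u_FF)
    for u_hh in (0.0, 0.65, 1.30, None):
        for u_hs in (0.375, 0.75, 1.5, 3.0):
            tag = "default" if u_hh is None else f"{u_hh}"
            add(f"uHH{tag}_uHS{u_hs}", n_block=6, u_HH=u_hh, u_HS=u_hs)
    # facultative heterochromatin content
    for f in (0.10, 0.30, 0.45, 0.55, 0.75):
        for n_block in (4, 6, 8):
            add(f"f{f:.2f}_phi{NBLOCK_PHI[n_block]:.0f}",
                n_block=n_block, f_het=f)
        add(f"f{f:.2f}_inverted", n_block=6, preset="inverted", f_het=f)
    # f = 75% without facultative self-affinity, lowest volume fraction
    add("f0.75_noselfaffinity_phi14", n_block=4, f_het=0.75, u_HH=0.0)
    # stiffer shell
    add("stiff_shell", n_block=6, stiff_shell=True)
    return grid


# ---------------------------------------------------------------------------
# scenario runner

@dataclass
class ScenarioResult:
    config: ScenarioConfig
    seed: int
    trajectory: Trajectory
    spectrum: object
    rms: float
    profile: object
    median_radius: dict
    compaction: dict

    def summary(self) -> dict:
        return {
            "scenario_id": self.config.scenario_id,
            "seed": self.seed,
            "rms": self.rms,
            "mean_shell_radius": float(self.spectrum.mean_radius),
            "median_radius": self.median_radius,
            "mean_rg": float(np.mean(self.compaction["rg"]))
            if len(self.compaction["rg"]) else None,
        }


def run_scenario_seed(cfg: ScenarioConfig, seed: int) -> ScenarioResult:
    """Build, run the staged protocol and analyze one seed of a scenario."""
    if cfg.scale != "reduced":
        raise ValueError("only the reduced scale is runnable on a desk machine")
    preset = cfg.make_preset()
    config = build_reduced_configuration(
        n_block=cfg.n_block, f_het=cfg.f_het, seed=seed, crosslinks=cfg.crosslinks,
    )
    schedule = ProtocolSchedule.reduced(inverted=preset.is_inverted)
    if cfg.steps_factor != 1.0:
        schedule.scale_factor = cfg.steps_factor
        schedule = schedule.scaled()
    traj = run_protocol(config, preset, schedule, IntegratorConfig(seed=seed))
    prod = traj.select_phase("production")
    spectrum = fluctuation_spectrum(prod, SliceSpec(), average_axes=True)
    return ScenarioResult(
        config=cfg,
        seed=seed,
        trajectory=traj,
        spectrum=spectrum,
        rms=spectrum.rms,
        profile=radial_density_profile(prod),
        median_radius=median_radius_by_type(prod),
        compaction=chain_compaction(prod, last_fraction=0.5),
    )


def run_scenario(cfg: ScenarioConfig, outdir=None) -> dict:
    """Run every seed of a scenario; returns per-seed results plus rms mean +- sd.

    With ``outdir`` set, writes a self-describing bundle (config copy, CSV
    observables, JSON summary, final-frame XYZ) keyed by scenario id and seed.
    """
    results = [run_scenario_seed(cfg, s) for s in cfg.seeds]
    rms = np.array([r.rms for r in results])
    bundle = {
        "config": cfg.to_dict(),
        "results": results,
        "rms_per_seed": rms,
        "rms_mean": float(rms.mean()),
        "rms_sd": float(rms.std(ddof=1)) if len(rms) > 1 else 0.0,
    }
    if outdir is not None:
        from . import io as nio
        nio.write_scenario_bundle(bundle, outdir)
    return bundle


def shell_relaxation_shrinkage(seed: int, R0: float = REDUCED_R0) -> float:
    """Percent reduction of the mean shell radius over the shell-relaxation phase.

    Builds a chromatin-free shell at the construction radius, runs the
    overdamped relaxation phase of the reduced schedule and reports
    100 * (R0 - mean equilibrated radius) / R0, with the equilibrated radius
    averaged over the last few snapshots.
    """
    from .builder import build_shell_mesh

    sched = ProtocolSchedule.reduced()
    mesh = build_shell_mesh(R0=R0, seed=seed)
    config = InitialConfiguration(
        plans=[], chain_positions=np.empty((0, 3)), shell=mesh
    )
    traj = run_protocol(
        config,
        make_preset(),
        ProtocolSchedule(
            shell_relax_steps=sched.shell_relax_steps,
            polymer_relax_steps=0, production_steps=0, snapshot_interval=500,
        ),
        IntegratorConfig(seed=seed),
    )
    relax = traj.select_phase("shell_relax")
    r_end = float(np.mean(relax.mean_shell_radius[-3:]))
    return 100.0 * (R0 - r_end) / R0


# ---------------------------------------------------------------------------
# analytic shell fixtures

@dataclass
class AnalyticShellFixture:
    """Sphere with imposed equatorial Fourier modes, for analysis-stage oracles."""

    base_radius: float = 20.0
    perturbations: list[tuple[int, float, float]] = field(default_factory=list)
    bead_count: int = 4000
    noise_sd: float = 0.0
    band_halfwidth: float = 2.0  # axial half-extent of the perturbed band (sigma)

    def __post_init__(self) -> None:
        for q, A, _ in self.perturbations:
            if abs(A) >= self.base_radius:
                raise ValueError("perturbation amplitude must be below the base radius")
            if q < 1:
                raise ValueError("mode numbers must be >= 1")


def generate_analytic_shell(fixture: AnalyticShellFixture, seed: int = 0) -> SystemState:
    """Shell-only snapshot whose equatorial band follows r(theta) = R + sum A cos(q theta + phase).

    Beads are placed quasi-uniformly (randomly rotated Fibonacci lattice,
    emulating the relaxed bonded shell's even coverage); beads within the
    axial band get the imposed radial perturbation, others stay on the base
    sphere.  Optional Gaussian radial noise on top.
    """
    n = fixture.bead_count
    max_q = max((q for q, _, _ in fixture.perturbations), default=0)
    beads_in_band = n * fixture.band_halfwidth / fixture.base_radius
    if max_q > 0 and 2 * max_q >= beads_in_band:
        raise ValueError("mode number beyond the angular Nyquist limit of the band")
    rng = np.random.default_rng(seed)
    ks = np.arange(n)
    z = 1.0 - 2.0 * (ks + 0.5) / n
    th = np.pi * (3.0 - np.sqrt(5.0)) * ks
    rho = np.sqrt(1.0 - z ** 2)
    unit = np.column_stack([rho * np.cos(th), rho * np.sin(th), z])
    # seeded random rotation (uniform via normalized quaternion)
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, zz = q
    rot = np.array([
        [1 - 2 * (y * y + zz * zz), 2 * (x * y - w * zz), 2 * (x * zz + w * y)],
        [2 * (x * y + w * zz), 1 - 2 * (x * x + zz * zz), 2 * (y * zz - w * x)],
        [2 * (x * zz - w * y), 2 * (y * zz + w * x), 1 - 2 * (x * x + y * y)],
    ])
    unit = unit @ rot.T
    r = np.full(n, fixture.base_radius)
    band = np.abs(unit[:, 2]) * fixture.base_radius < fixture.band_halfwidth
    theta = np.arctan2(unit[:, 1], unit[:, 0])
    for q, A, phase in fixture.perturbations:
        r[band] += A * np.cos(q * theta[band] + phase)
    if fixture.noise_sd > 0:
        r += rng.normal(scale=fixture.noise_sd, size=n)
    pos = unit * r[:, None]
    n_beads = len(pos)
    empty = np.empty(0, dtype=np.int64)
    return SystemState(
        positions=pos,
        velocities=np.zeros_like(pos),
        types=np.full(n_beads, BeadType.S, dtype=np.int8),
        chain_id=np.full(n_beads, -1, dtype=np.int64),
        bond_i=empty, bond_j=empty,
        bond_kind=np.empty(0, dtype=np.int8),
        bond_r0=np.empty(0), bond_k=np.empty(0), bond_dmax=np.empty(0),
    )


def fixture_trajectory(fixture: AnalyticShellFixture, n_frames: int = 8,
                       seed: int = 0) -> Trajectory:
    """Static trajectory of independent fixture realizations (one per frame)."""
    import pandas as pd

    frames, radii = [], []
    types = chain_id = None
    for k in range(n_frames):
        st = generate_analytic_shell(fixture, seed=seed + k)
        frames.append(st.positions.astype(np.float32))
        radii.append(st.mean_shell_radius())
        types, chain_id = st.types, st.chain_id
    return Trajectory(
        frames=np.array(frames),
        steps=np.arange(n_frames),
        phases=["fixture"] * n_frames,
        types=types,
        chain_id=chain_id,
        mean_shell_radius=np.array(radii),
        diagnostics=pd.DataFrame(),
    )
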