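"""Core data containers: bead types, chain plans, shell meshes and system state."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import IntEnum
from typing import Sequence

import numpy as np

from .units import KB_PER_BEAD


class BeadType(IntEnum):
    """Closed enumeration of bead species.

    E  euchromatin
    F  facultative heterochromatin
    C  constitutive heterochromatin
    T  telomere
    S  shell (lamina); never appears inside a chromosome chain
    """

    E = 0
    F = 1
    C = 2
    T = 3
    S = 4


TYPE_CODES = "EFCTS"
N_TYPES = 5
CHROMATIN_TYPES = (BeadType.E, BeadType.F, BeadType.C, BeadType.T)


def codes_to_ints(codes: Sequence[str] | str) -> np.ndarray:
    return np.array([TYPE_CODES.index(c) for c in codes], dtype=np.int8)


def ints_to_codes(types: np.ndarray) -> str:
    return "".join(TYPE_CODES[t] for t in np.asarray(types))


@dataclass
class ChromosomePlan:
    """Per-bead type sequence of one chromosome chain.

    A chain is a triblock copolymer: one telomere bead at each terminus, a
    contiguous constitutive-heterochromatin (C) block at one end, and a
    compartment region of alternating euchromatin (E) / facultative
    heterochromatin (F) blocks.  ``f_het`` records the requested F fraction of
    the compartment region.
    """

    bead_types: np.ndarray
    n_constitutive: int
    n_compartment: int
    n_telomere: int = 2
    f_het: float = 0.5
    kb_per_bead: float = KB_PER_BEAD

    def __post_init__(self) -> None:
        self.bead_types = np.asarray(self.bead_types, dtype=np.int8)
        if len(self.bead_types) != self.n_beads:
            raise ValueError(
                f"bead_types length {len(self.bead_types)} != declared "
                f"{self.n_constitutive}+{self.n_compartment}+{self.n_telomere}"
            )

    @property
    def n_beads(self) -> int:
        return self.n_constitutive + self.n_compartment + self.n_telomere

    @property
    def compartment_slice(self) -> slice:
        # layout: [T, C-block, compartment, T]
        start = self.n_telomere // 2 + self.n_constitutive
        return slice(start, start + self.n_compartment)

    @property
    def f_realized(self) -> float:
        """Realized F fraction of the compartment region."""
        if self.n_compartment == 0:
            return 0.0
        comp = self.bead_types[self.compartment_slice]
        return float(np.count_nonzero(comp == BeadType.F) / self.n_compartment)

    def type_counts(self) -> dict[str, int]:
        return {
            code: int(np.count_nonzero(self.bead_types == BeadType[code]))
            for code in "EFCT"
        }

    def copy(self) -> "ChromosomePlan":
        return replace(self, bead_types=self.bead_types.copy())


@dataclass
class ShellMesh:
    """Bonded-bead lamina shell.

    ``positions`` are the construction-time bead coordinates on a sphere of
    radius ``R0``; ``bonds`` is a (M, 2) array of bead index pairs with per-bond
    equilibrium length ``rest_length`` (set below the construction length so
    the shell contracts during relaxation).  Bead and bond counts never change
    after construction.
    """

    positions: np.ndarray
    bonds: np.ndarray
    rest_length: np.ndarray
    bond_stiffness: float
    R0: float

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.float64)
        self.bonds = np.asarray(self.bonds, dtype=np.int64)
        self.rest_length = np.asarray(self.rest_length, dtype=np.float64)

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_beads, dtype=np.int64)
        np.add.at(deg, self.bonds[:, 0], 1)
        np.add.at(deg, self.bonds[:, 1], 1)
        return deg

    def validate(self) -> None:
        b = self.bonds
        if b.size:
            if np.any(b[:, 0] == b[:, 1]):
                raise ValueError("shell mesh contains self-bonds")
            key = np.sort(b, axis=1)
            if len(np.unique(key, axis=0)) != len(key):
                raise ValueError("shell mesh contains duplicate bonds")
        if len(self.rest_length) != self.n_bonds:
            raise ValueError("rest_length must have one entry per bond")


@dataclass
class CrosslinkSet:
    """Permanent bonds between constitutive-heterochromatin bead pairs."""

    pairs: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=np.int64))
    enabled: bool = False

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=np.int64).reshape(-1, 2)

    @property
    def n_pairs(self) -> int:
        return 0 if not self.enabled else len(self.pairs)


@dataclass
class InitialConfiguration:
    """Chains with positions, a shell mesh and optional crosslinks.

    Chain beads are stored concatenated in ``chain_positions`` with the same
    ordering as the plans; shell beads follow in the assembled system state.
    ``phi_nominal`` is the label volume fraction (percent) of the condition
    the chain count emulates.
    """

    plans: list[ChromosomePlan]
    chain_positions: np.ndarray
    shell: ShellMesh
    crosslinks: CrosslinkSet = field(default_factory=CrosslinkSet)
    phi_nominal: float | None = None

    @property
    def n_block(self) -> int:
        return len(self.plans)

    @property
    def n_chain_beads(self) -> int:
        return sum(p.n_beads for p in self.plans)

    @property
    def n_beads(self) -> int:
        return self.n_chain_beads + self.shell.n_beads

    def chain_types(self) -> np.ndarray:
        if not self.plans:
            return np.empty(0, dtype=np.int8)
        return np.concatenate([p.bead_types for p in self.plans])

    def chain_ids(self) -> np.ndarray:
        """Chain index per chain bead (shell beads are -1 in the system state)."""
        if not self.plans:
            return np.empty(0, dtype=np.int64)
        return np.repeat(np.arange(len(self.plans)), [p.n_beads for p in self.plans])


# bond kind codes used in SystemState / kernels
BOND_BACKBONE = 0
BOND_SHELL = 1
BOND_CROSSLINK = 2


@dataclass
class SystemState:
    """Evolving simulation state: positions, velocities, topology, RNG-free.

    All per-bond parameters are stored per bond so heterogeneous rest lengths
    (shell) and kinds coexist in one array set.  Chain beads come first (in
    plan order), shell beads last; ``chain_id`` is -1 for shell beads.
    """

    positions: np.ndarray
    velocities: np.ndarray
    types: np.ndarray
    chain_id: np.ndarray
    bond_i: np.ndarray
    bond_j: np.ndarray
    bond_kind: np.ndarray
    bond_r0: np.ndarray
    bond_k: np.ndarray
    bond_dmax: np.ndarray
    step: int = 0

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    @property
    def shell_mask(self) -> np.ndarray:
        return self.types == BeadType.S

    @property
    def chain_mask(self) -> np.ndarray:
        return self.types != BeadType.S

    def mean_shell_radius(self) -> float:
        sp = self.positions[self.shell_mask]
        com = sp.mean(axis=0)
        return float(np.linalg.norm(sp - com, axis=1).mean())

    def copy(self) -> "SystemState":
        return SystemState(
            positions=self.positions.copy(),
            velocities=self.velocities.copy(),
            types=self.types.copy(),
            chain_id=self.chain_id.copy(),
            bond_i=self.bond_i.copy(),
            bond_j=self.bond_j.copy(),
            bond_kind=self.bond_kind.copy(),
            bond_r0=self.bond_r0.copy(),
            bond_k=self.bond_k.copy(),
            bond_dmax=self.bond_dmax.copy(),
            step=self.step,
        )


@dataclass
class Trajectory:
    """Snapshots of a run: positions per frame plus light-weight diagnostics."""

    frames: np.ndarray            # (F, N, 3) float32
    steps: np.ndarray             # (F,) step stamp per frame
    phases: list[str]             # phase label per frame
    types: np.ndarray             # (N,) bead types
    chain_id: np.ndarray          # (N,)
    mean_shell_radius: np.ndarray  # (F,)
    diagnostics: "object" = None  # pandas DataFrame (step, phase, energies...)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_beads(self) -> int:
        return self.frames.shape[1]

    def frame_state_positions(self, i: int) -> np.ndarray:
        return np.asarray(self.frames[i], dtype=np.float64)

    @staticmethod
    def concatenate(parts: Sequence["Trajectory"]) -> "Trajectory":
        import pandas as pd

        parts = [p for p in parts if p.n_frames > 0]
        if not parts:
            raise ValueError("nothing to concatenate")
        diags = [p.diagnostics for p in parts if p.diagnostics is not None]
        return Trajectory(
            frames=np.concatenate([p.frames for p in parts]),
            steps=np.concatenate([p.steps for p in parts]),
            phases=sum((list(p.phases) for p in parts), []),
            types=parts[0].types,
            chain_id=parts[0].chain_id,
            mean_shell_radius=np.concatenate(
                [p.mean_shell_radius for p in parts]
            ),
            diagnostics=pd.concat(diags, ignore_index=True) if diags else None,
        )

    def select_phase(self, phase: str) -> "Trajectory":
        idx = np.array([i for i, p in enumerate(self.phases) if p == phase])
        if idx.size == 0:
            raise ValueError(f"no frames with phase {phase!r}")
        return Trajectory(
            frames=self.frames[idx],
            steps=self.steps[idx],
            phases=[self.phases[i] for i in idx],
            types=self.types,
            chain_id=self.chain_id,
            mean_shell_radius=self.mean_shell_radius[idx],
            diagnostics=self.diagnostics,
        )
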