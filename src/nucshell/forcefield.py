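"""Pairwise and bonded interactions.

Nonbonded interactions are truncated-and-shifted 12-6 Lennard-Jones wells whose
*shifted* depth equals the tabulated affinity ``u_XY`` in kT exactly (the raw
LJ epsilon is rescaled to absorb the cutoff shift).  Pairs flagged repulsive-
only use the purely repulsive (WCA) form, cut at the potential minimum, with a
1 kT excluded-volume scale.  Bonds are finite-extensible: chain backbones and
crosslinks use the standard Kremer-Grest FENE spring (stiffness 30 kT/sigma^2,
maximum extension 1.5 sigma); shell bonds use a finite-extensible spring
centered on the per-bond rest length so the minimum sits at the prescribed
rest length and the bond diverges at rest +- Delta.

The conventional affinity hierarchy is

    u_TS > u_CC > u_FC > u_HS > u_FF > u_EC > u_EF > u_EE

with anchors u_TS = 2.20 kT and u_EE = 0.05 kT; intermediate defaults
are configurable and chosen to satisfy the ordering.  The inverted organization
is obtained by zeroing every chromatin-shell attraction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .types import N_TYPES, BeadType

# ---------------------------------------------------------------------------
# constants of the pair parameterization

ATTRACTIVE_CUTOFF = 2.5          # in units of the pair sigma
WCA_CUTOFF = 2.0 ** (1.0 / 6.0)  # potential-minimum distance
WCA_EPS = 1.0                    # excluded-volume energy scale, kT

# raw truncated-shifted LJ at the minimum has depth (1 + phi(rc)); rescale so
# the shifted well depth equals u exactly
_PHI_RC = 4.0 * (ATTRACTIVE_CUTOFF ** -12 - ATTRACTIVE_CUTOFF ** -6)
DEPTH_NORM = 1.0 + _PHI_RC  # ~0.98368

# default conventional affinities (kT); u_TS and u_EE anchor the hierarchy,
# intermediates are package defaults satisfying the ordering
DEFAULT_U = {
    ("E", "E"): 0.05,
    ("E", "F"): 0.15,
    ("E", "C"): 0.30,
    ("F", "F"): 0.50,
    ("F", "S"): 0.75,   # u_HS, facultative-shell
    ("C", "S"): 0.75,   # u_HS, constitutive-shell
    ("F", "C"): 1.00,
    ("C", "C"): 1.50,
    ("T", "S"): 2.20,   # u_TS
}

HIERARCHY = ("u_TS", "u_CC", "u_FC", "u_HS", "u_FF", "u_EC", "u_EF", "u_EE")
_HIERARCHY_PAIRS = {
    "u_TS": ("T", "S"),
    "u_CC": ("C", "C"),
    "u_FC": ("F", "C"),
    "u_HS": ("F", "S"),
    "u_FF": ("F", "F"),
    "u_EC": ("E", "C"),
    "u_EF": ("E", "F"),
    "u_EE": ("E", "E"),
}

DEFAULT_BOND_K = 30.0        # kT/sigma^2, chain backbone / crosslinks
SHELL_BOND_K = 300.0         # kT/sigma^2; shell bonds are effectively non-extensible
BACKBONE_MAX_EXT = 1.5       # sigma
SHELL_EXT_FACTOR = 0.6       # shell bond max extension = (1 + factor) * rest


def _idx(t: "str | BeadType") -> int:
    return BeadType[t] if isinstance(t, str) else int(t)


@dataclass
class InteractionTable:
    """Symmetric type-pair affinity matrix over (E, F, C, T, S).

    ``u`` holds well depths in kT; ``repulsive_only`` marks pairs interacting
    through excluded volume alone; ``sigma`` is the pair length scale (1 sigma
    everywhere by default).  Cutoffs follow from the flags: 2.5 sigma for
    attractive pairs, the potential minimum for repulsive-only pairs.
    """

    u: np.ndarray
    repulsive_only: np.ndarray
    sigma: np.ndarray = field(default_factory=lambda: np.ones((N_TYPES, N_TYPES)))

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=np.float64)
        self.repulsive_only = np.asarray(self.repulsive_only, dtype=bool)
        self.sigma = np.asarray(self.sigma, dtype=np.float64)
        for name, arr in (("u", self.u), ("repulsive_only", self.repulsive_only),
                          ("sigma", self.sigma)):
            if arr.shape != (N_TYPES, N_TYPES):
                raise ValueError(f"{name} must be {N_TYPES}x{N_TYPES}")
            if not np.array_equal(arr, arr.T):
                raise ValueError(f"{name} must be symmetric")
        if np.any(self.u < 0):
            raise ValueError("affinities must be non-negative")

    @classmethod
    def conventional(cls) -> "InteractionTable":
        u = np.zeros((N_TYPES, N_TYPES))
        rep = np.ones((N_TYPES, N_TYPES), dtype=bool)
        for (a, b), val in DEFAULT_U.items():
            i, j = _idx(a), _idx(b)
            u[i, j] = u[j, i] = val
            rep[i, j] = rep[j, i] = False
        return cls(u=u, repulsive_only=rep)

    # -- element access ----------------------------------------------------
    def get(self, a, b) -> float:
        return float(self.u[_idx(a), _idx(b)])

    def set(self, a, b, value: float, repulsive_only: bool | None = None) -> None:
        i, j = _idx(a), _idx(b)
        self.u[i, j] = self.u[j, i] = float(value)
        if repulsive_only is None:
            repulsive_only = value == 0.0
        self.repulsive_only[i, j] = self.repulsive_only[j, i] = repulsive_only

    def cutoff(self) -> np.ndarray:
        """Per-pair interaction cutoff in sigma."""
        return np.where(
            self.repulsive_only, WCA_CUTOFF * self.sigma, ATTRACTIVE_CUTOFF * self.sigma
        )

    def copy(self) -> "InteractionTable":
        return InteractionTable(
            u=self.u.copy(), repulsive_only=self.repulsive_only.copy(),
            sigma=self.sigma.copy(),
        )

    def with_shell_attraction_off(self) -> "InteractionTable":
        """Variant with every chromatin-shell attraction replaced by excluded volume.

        Used during shell relaxation (attractions switched on only afterwards)
        and to derive the inverted organization.
        """
        t = self.copy()
        s = int(BeadType.S)
        for x in (BeadType.E, BeadType.F, BeadType.C, BeadType.T):
            t.u[x, s] = t.u[s, x] = 0.0
            t.repulsive_only[x, s] = t.repulsive_only[s, x] = True
        return t

    # -- kernel tables -----------------------------------------------------
    def kernel_tables(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(A, C, rc2, sig2) arrays for the force kernels.

        Pair energy is U(r) = A*(s^12 - s^6) - C with s = sigma/r, zero beyond
        sqrt(rc2); the constant C makes U continuous (zero) at the cutoff.
        """
        A = np.where(self.repulsive_only, 4.0 * WCA_EPS, 4.0 * self.u / DEPTH_NORM)
        rc = self.cutoff()
        s_over_rc = self.sigma / rc
        C = A * (s_over_rc ** 12 - s_over_rc ** 6)
        return (
            np.ascontiguousarray(A),
            np.ascontiguousarray(C),
            np.ascontiguousarray(rc ** 2),
            np.ascontiguousarray(self.sigma ** 2),
        )

    def max_cutoff(self) -> float:
        return float(self.cutoff().max())


# ---------------------------------------------------------------------------
# scalar pair energy/force (reference API; kernels use kernel_tables)

def pair_energy(type_a, type_b, r, table: InteractionTable):
    """Truncated-and-shifted pair energy in kT at separation r (sigma).

    Vectorized over ``r``.  Raises on non-positive separations (singular
    geometry).
    """
    r = np.asarray(r, dtype=np.float64)
    if np.any(r <= 0):
        raise ValueError("pair separation must be strictly positive")
    i, j = _idx(type_a), _idx(type_b)
    A, C, rc2, sig2 = (t[i, j] for t in table.kernel_tables())
    s2 = sig2 / (r * r)
    s6 = s2 ** 3
    e = np.where(r * r < rc2, A * (s6 * s6 - s6) - C, 0.0)
    return e if e.ndim else float(e)


def pair_force(type_a, type_b, r, table: InteractionTable):
    """Radial force -dU/dr in kT/sigma (positive = repulsive); zero beyond cutoff."""
    r = np.asarray(r, dtype=np.float64)
    if np.any(r <= 0):
        raise ValueError("pair separation must be strictly positive")
    i, j = _idx(type_a), _idx(type_b)
    A, _, rc2, sig2 = (t[i, j] for t in table.kernel_tables())
    s2 = sig2 / (r * r)
    s6 = s2 ** 3
    f = np.where(r * r < rc2, (A / r) * (12.0 * s6 * s6 - 6.0 * s6), 0.0)
    return f if f.ndim else float(f)


# ---------------------------------------------------------------------------
# bonds

class BondOverstretchError(RuntimeError):
    pass


@dataclass(frozen=True)
class BondSpec:
    """Finite-extensible bond: minimum at ``rest_length``, divergence at ``max_extension``.

    ``rest_length = 0`` recovers the standard Kremer-Grest FENE spring used for
    chain backbones and crosslinks; shell bonds carry a positive rest length so
    the relaxed shell contracts onto its prescribed geometry.
    """

    kind: str
    stiffness: float = DEFAULT_BOND_K
    rest_length: float = 0.0
    max_extension: float = BACKBONE_MAX_EXT

    def __post_init__(self) -> None:
        if self.max_extension <= self.rest_length:
            raise ValueError("max_extension must exceed rest_length")
        if self.stiffness <= 0:
            raise ValueError("stiffness must be positive")

    @property
    def delta(self) -> float:
        return self.max_extension - self.rest_length


def backbone_bond() -> BondSpec:
    return BondSpec("backbone", DEFAULT_BOND_K, 0.0, BACKBONE_MAX_EXT)


def crosslink_bond() -> BondSpec:
    return BondSpec("crosslink", DEFAULT_BOND_K, 0.0, BACKBONE_MAX_EXT)


def shell_bond(rest_length: float, stiffness: float = SHELL_BOND_K,
               ext_factor: float = SHELL_EXT_FACTOR) -> BondSpec:
    return BondSpec("shell", stiffness, rest_length,
                    rest_length * (1.0 + ext_factor))


def bond_energy(spec: BondSpec, r):
    """Bond energy in kT; diverges as r -> max_extension (and rest - delta)."""
    r = np.asarray(r, dtype=np.float64)
    if np.any(r <= 0):
        raise ValueError("bond length must be strictly positive")
    y = (r - spec.rest_length) / spec.delta
    if np.any(np.abs(y) >= 1.0):
        raise BondOverstretchError(
            f"{spec.kind} bond beyond finite extensibility (r={np.max(r):.3f}, "
            f"max={spec.max_extension:.3f})"
        )
    e = -0.5 * spec.stiffness * spec.delta ** 2 * np.log1p(-(y * y))
    return e if e.ndim else float(e)


def bond_force(spec: BondSpec, r):
    """Radial bond force -dU/dr in kT/sigma."""
    r = np.asarray(r, dtype=np.float64)
    y = (r - spec.rest_length) / spec.delta
    if np.any(np.abs(y) >= 1.0):
        raise BondOverstretchError(f"{spec.kind} bond beyond finite extensibility")
    f = -spec.stiffness * spec.delta * y / (1.0 - y * y)
    return f if f.ndim else float(f)


# ---------------------------------------------------------------------------
# hierarchy validation

def hierarchy_values(table: InteractionTable) -> dict[str, float]:
    return {name: table.get(*_HIERARCHY_PAIRS[name]) for name in HIERARCHY}


def validate_hierarchy(table: InteractionTable) -> list[str]:
    """Return the list of violated strict inequalities in the conventional ordering.

    Empty list means the full chain u_TS > u_CC > u_FC > u_HS > u_FF > u_EC >
    u_EF > u_EE holds strictly.
    """
    vals = hierarchy_values(table)
    violations = []
    for hi, lo in zip(HIERARCHY[:-1], HIERARCHY[1:]):
        if not vals[hi] > vals[lo]:
            violations.append(f"{hi} > {lo}")
    return violations


# ---------------------------------------------------------------------------
# presets

PRESET_NAMES = ("conventional", "inverted", "stiff_shell", "custom")
HET_SHELL_SCOPES = ("both", "c_only", "f_only")
STIFF_SHELL_FACTOR = 4.0


@dataclass
class ForceFieldPreset:
    """A named, fully resolved force field: pair table + bond templates."""

    name: str
    table: InteractionTable
    backbone: BondSpec = field(default_factory=backbone_bond)
    crosslink: BondSpec = field(default_factory=crosslink_bond)
    shell_stiffness: float = SHELL_BOND_K
    shell_ext_factor: float = SHELL_EXT_FACTOR
    het_shell_scope: str = "both"

    @property
    def is_inverted(self) -> bool:
        s = int(BeadType.S)
        return all(
            self.table.u[x, s] == 0.0
            for x in (BeadType.F, BeadType.C, BeadType.T)
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "name": self.name,
                "types": list("EFCTS"),
                "u": self.table.u.tolist(),
                "repulsive_only": self.table.repulsive_only.tolist(),
                "sigma": self.table.sigma.tolist(),
                "backbone": vars(self.backbone).copy(),
                "crosslink": vars(self.crosslink).copy(),
                "shell_stiffness": self.shell_stiffness,
                "shell_ext_factor": self.shell_ext_factor,
                "het_shell_scope": self.het_shell_scope,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, doc: str) -> "ForceFieldPreset":
        d = json.loads(doc)
        return cls(
            name=d["name"],
            table=InteractionTable(
                u=np.array(d["u"]),
                repulsive_only=np.array(d["repulsive_only"], dtype=bool),
                sigma=np.array(d["sigma"]),
            ),
            backbone=BondSpec(**d["backbone"]),
            crosslink=BondSpec(**d["crosslink"]),
            shell_stiffness=d["shell_stiffness"],
            shell_ext_factor=d["shell_ext_factor"],
            het_shell_scope=d["het_shell_scope"],
        )


def make_preset(
    name: str = "conventional",
    u_HS: float | None = None,
    u_HH: float | None = None,
    het_shell_scope: str = "both",
    stiffness_factor: float = 1.0,
    u_CC: float | None = None,
) -> ForceFieldPreset:
    """Build a named force-field preset.

    ``u_HS`` overrides both heterochromatin-shell affinities (F-S and C-S),
    restricted by ``het_shell_scope``; ``u_HH`` overrides the facultative
    self-affinity (F-F); ``u_CC`` overrides the constitutive self-affinity
    (0 turns it into pure excluded volume).  ``stiffness_factor`` scales the
    shell bond stiffness (the stiff-shell variant uses x4) and changes nothing
    else.
    """
    if name == "stiff_shell":
        base = "conventional"
        stiffness_factor = stiffness_factor if stiffness_factor != 1.0 else STIFF_SHELL_FACTOR
    elif name in PRESET_NAMES:
        base = name
    else:
        raise ValueError(f"unknown preset {name!r}; expected one of {PRESET_NAMES}")
    if het_shell_scope not in HET_SHELL_SCOPES:
        raise ValueError(f"het_shell_scope must be one of {HET_SHELL_SCOPES}")
    for label, v in (("u_HS", u_HS), ("u_HH", u_HH), ("u_CC", u_CC)):
        if v is not None and v < 0:
            raise ValueError(f"{label} override must be non-negative")

    table = InteractionTable.conventional()
    if u_HS is not None:
        table.set("F", "S", u_HS)
        table.set("C", "S", u_HS)
    if het_shell_scope == "c_only":
        table.set("F", "S", 0.0)
    elif het_shell_scope == "f_only":
        table.set("C", "S", 0.0)
    if u_HH is not None:
        table.set("F", "F", u_HH)
    if u_CC is not None:
        table.set("C", "C", u_CC)
    if base == "inverted":
        table = table.with_shell_attraction_off()

    return ForceFieldPreset(
        name=name,
        table=table,
        shell_stiffness=SHELL_BOND_K * stiffness_factor,
        het_shell_scope=het_shell_scope,
    )
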