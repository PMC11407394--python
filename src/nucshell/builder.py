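"""Construction of initial configurations: chromosome chains and the lamina shell.

Full-scale defaults build 6002-bead triblock chains (one telomere bead per
terminus, a 1000-bead constitutive-heterochromatin block at one end and 5000
compartment beads tiled with alternating euchromatin / facultative blocks) and
a bonded-bead shell of radius R0 = 42 sigma whose bead degrees all fall in
[5, 8].  Everything scales: the reduced desk-scale system used for the
scenario sweeps keeps the same composition ratios at R0 = 14 sigma.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .forcefield import SHELL_BOND_K
from .types import (
    BeadType,
    ChromosomePlan,
    CrosslinkSet,
    InitialConfiguration,
    ShellMesh,
)

# full-scale composition
FULL_N_CONSTITUTIVE = 1000
FULL_N_COMPARTMENT = 5000
FULL_SCALE_R0 = 42.0
DEFAULT_BLOCK_LENGTH = 40.0  # beads; mean alternating E/F block length
DEFAULT_REST_LENGTH_FACTOR = 0.7

# shell construction spacing (sigma).  Post-relaxation spacing is
# rest_length_factor * this, chosen so the contracted shell is void-free for
# 1-sigma chromatin beads and an equatorial slice of width 1 sigma holds
# enough beads to be analyzable.
SHELL_SPACING = 1.714

PHI_BY_NBLOCK = {4: 14.0, 6: 19.0, 8: 23.0}


class ConstructionError(RuntimeError):
    pass


def default_shell_count(R0: float, spacing: float = SHELL_SPACING) -> int:
    """Bead count giving hexagonal-lattice spacing ``spacing`` on a sphere of radius R0."""
    area_per_bead = (np.sqrt(3.0) / 2.0) * spacing ** 2
    return int(round(4.0 * np.pi * R0 ** 2 / area_per_bead))


# ---------------------------------------------------------------------------
# chromosome plans

def _alternating_blocks(n: int, f_het: float, block_length_mean: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Tile n compartment beads with alternating E/F blocks, F fraction ~ f_het."""
    out = np.empty(n, dtype=np.int8)
    if n == 0:
        return out
    # geometric block lengths; per-type means chosen so the long-run F
    # fraction is f_het while the overall mean block length stays at the mean
    mean_f = max(1.0, 2.0 * f_het * block_length_mean)
    mean_e = max(1.0, 2.0 * (1.0 - f_het) * block_length_mean)
    cur = BeadType.F if rng.random() < f_het else BeadType.E
    pos = 0
    while pos < n:
        mean = mean_f if cur == BeadType.F else mean_e
        length = 1 + rng.geometric(min(1.0, 1.0 / mean))
        length = min(length, n - pos)
        out[pos:pos + length] = cur
        pos += length
        cur = BeadType.E if cur == BeadType.F else BeadType.F
    return out


def _adjust_f_count(comp: np.ndarray, target: int, rng: np.random.Generator) -> None:
    """Flip E<->F beads (boundary-first) until the F count equals target."""
    while True:
        n_f = int(np.count_nonzero(comp == BeadType.F))
        if n_f == target:
            return
        src = BeadType.F if n_f > target else BeadType.E
        dst = BeadType.E if n_f > target else BeadType.F
        cand = np.flatnonzero(comp == src)
        # prefer block-boundary beads to keep blocks contiguous
        is_boundary = np.zeros(len(cand), dtype=bool)
        for k, i in enumerate(cand):
            if (i > 0 and comp[i - 1] == dst) or (i + 1 < len(comp) and comp[i + 1] == dst):
                is_boundary[k] = True
        pool = cand[is_boundary] if is_boundary.any() else cand
        n_flip = min(abs(n_f - target), len(pool))
        comp[rng.choice(pool, size=n_flip, replace=False)] = dst


def build_chromosome_plan(
    n_constitutive: int = FULL_N_CONSTITUTIVE,
    n_compartment: int = FULL_N_COMPARTMENT,
    f_het: float = 0.5,
    block_length_mean: float = DEFAULT_BLOCK_LENGTH,
    seed: int = 0,
) -> ChromosomePlan:
    """Build one chain plan: [T | C-block | alternating E/F blocks | T].

    The realized facultative fraction of the compartment region equals
    round(f_het * n_compartment) beads exactly.
    """
    if n_constitutive < 0 or n_compartment < 0:
        raise ValueError("bead counts must be non-negative")
    if not 0.0 <= f_het <= 1.0:
        raise ValueError("f_het must lie in [0, 1]")
    if block_length_mean < 1:
        raise ValueError("block_length_mean must be >= 1 bead")
    rng = np.random.default_rng(seed)
    comp = _alternating_blocks(n_compartment, f_het, block_length_mean, rng)
    _adjust_f_count(comp, int(round(f_het * n_compartment)), rng)
    types = np.concatenate([
        [BeadType.T],
        np.full(n_constitutive, BeadType.C, dtype=np.int8),
        comp,
        [BeadType.T],
    ]).astype(np.int8)
    return ChromosomePlan(
        bead_types=types,
        n_constitutive=n_constitutive,
        n_compartment=n_compartment,
        n_telomere=2,
        f_het=f_het,
    )


def reassign_heterochromatin_fraction(
    plan: ChromosomePlan, f_target: float, seed: int = 0
) -> ChromosomePlan:
    """Randomly convert E<->F compartment beads to reach a new F fraction.

    Only compartment beads change; constitutive and telomere beads are
    untouched.  Conversion sites are chosen uniformly at random.
    """
    if not 0.0 <= f_target <= 1.0:
        raise ValueError("f_target must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    new = plan.copy()
    comp = new.bead_types[new.compartment_slice]
    target = int(round(f_target * plan.n_compartment))
    n_f = int(np.count_nonzero(comp == BeadType.F))
    if n_f != target:
        src = BeadType.F if n_f > target else BeadType.E
        dst = BeadType.E if n_f > target else BeadType.F
        pool = np.flatnonzero(comp == src)
        comp[rng.choice(pool, size=abs(n_f - target), replace=False)] = dst
    new.bead_types[new.compartment_slice] = comp
    new.f_het = f_target
    return new


# ---------------------------------------------------------------------------
# shell mesh

def _relax_on_sphere(pos: np.ndarray, R0: float, spacing: float,
                     n_iter: int = 250) -> np.ndarray:
    """Repulsive relaxation constrained to the sphere surface.

    Spreads the randomly placed beads toward quasi-uniform coverage (removes
    clumps and thins out sparse patches) so the subsequent distance-cutoff
    bonding yields a narrow bond-length distribution.
    """
    pos = pos.copy()
    target = 1.1 * spacing
    for it in range(n_iter):
        tree = cKDTree(pos)
        pairs = tree.query_pairs(target, output_type="ndarray")
        if len(pairs) == 0:
            break
        disp = np.zeros_like(pos)
        d = pos[pairs[:, 0]] - pos[pairs[:, 1]]
        r = np.linalg.norm(d, axis=1, keepdims=True)
        r = np.maximum(r, 1e-9)
        push = 0.2 * (target - r) * d / r
        np.add.at(disp, pairs[:, 0], push)
        np.add.at(disp, pairs[:, 1], -push)
        pos += disp
        pos *= R0 / np.linalg.norm(pos, axis=1, keepdims=True)
    return pos


def build_shell_mesh(
    n_shell: int | None = None,
    R0: float = FULL_SCALE_R0,
    bond_cutoff: float | None = None,
    rest_length_factor: float = DEFAULT_REST_LENGTH_FACTOR,
    bond_stiffness: float = SHELL_BOND_K,
    seed: int = 0,
) -> ShellMesh:
    """Construct the bonded-bead lamina shell.

    Beads are placed randomly on the sphere of radius R0, spread by a short
    on-surface repulsive relaxation, bonded to all neighbors within
    ``bond_cutoff``, then degree-repaired so every bead has between 5 and 8
    bonds.  Bond rest lengths are ``rest_length_factor`` times the construction
    length, so the relaxed shell contracts by about (1 - factor).
    """
    if n_shell is None:
        n_shell = default_shell_count(R0)
    if not 0.0 < rest_length_factor <= 1.0:
        raise ValueError("rest_length_factor must lie in (0, 1]")
    spacing = np.sqrt(4.0 * np.pi * R0 ** 2 / (n_shell * np.sqrt(3.0) / 2.0))
    if bond_cutoff is None:
        bond_cutoff = 1.5 * spacing
    if bond_cutoff <= spacing * 0.9:
        raise ConstructionError(
            f"bond_cutoff {bond_cutoff:.2f} below mean spacing {spacing:.2f}: "
            "bonds would be too sparse to reach the degree bounds"
        )

    rng = np.random.default_rng(seed)
    v = rng.normal(size=(n_shell, 3))
    pos = R0 * v / np.linalg.norm(v, axis=1, keepdims=True)
    pos = _relax_on_sphere(pos, R0, spacing)

    tree = cKDTree(pos)
    pairs = tree.query_pairs(bond_cutoff, output_type="ndarray")
    bonds = {tuple(sorted(p)) for p in pairs.tolist()}
    neigh: list[set[int]] = [set() for _ in range(n_shell)]
    for i, j in bonds:
        neigh[i].add(j)
        neigh[j].add(i)

    def dist(i: int, j: int) -> float:
        return float(np.linalg.norm(pos[i] - pos[j]))

    # degree repair: raise everyone to >= 5 first, then trim > 8
    order = tree.query(pos, k=min(16, n_shell))[1]
    for _ in range(8 * n_shell):
        degs = np.array([len(s) for s in neigh])
        low = np.flatnonzero(degs < 5)
        if low.size == 0:
            break
        i = int(low[degs[low].argmin()])
        added = False
        for j in order[i][1:]:
            j = int(j)
            if j != i and j not in neigh[i]:
                bonds.add(tuple(sorted((i, j))))
                neigh[i].add(j)
                neigh[j].add(i)
                added = True
                break
        if not added:
            # fall back to global nearest unbonded bead
            cand = [j for j in range(n_shell) if j != i and j not in neigh[i]]
            if not cand:
                raise ConstructionError(f"cannot raise degree of bead {i}: n_shell too small")
            j = min(cand, key=lambda j: dist(i, j))
            bonds.add(tuple(sorted((i, j))))
            neigh[i].add(j)
            neigh[j].add(i)
    for _ in range(8 * n_shell):
        degs = np.array([len(s) for s in neigh])
        high = np.flatnonzero(degs > 8)
        if high.size == 0:
            break
        i = int(high[degs[high].argmax()])
        # drop the longest bond whose partner stays at degree >= 5; if none,
        # drop the longest outright and let the raise pass re-repair
        partners = sorted(neigh[i], key=lambda j: -dist(i, j))
        j = next((j for j in partners if len(neigh[j]) > 5), partners[0])
        bonds.discard(tuple(sorted((i, j))))
        neigh[i].discard(j)
        neigh[j].discard(i)
        if len(neigh[j]) < 5:
            for k in order[j][1:]:
                k = int(k)
                if k != j and k not in neigh[j] and len(neigh[k]) < 8:
                    bonds.add(tuple(sorted((j, k))))
                    neigh[j].add(k)
                    neigh[k].add(j)
                    break
    degs = np.array([len(s) for s in neigh])
    if degs.min() < 5 or degs.max() > 8:
        raise ConstructionError(
            f"degree repair failed: degrees span [{degs.min()}, {degs.max()}]; "
            "increase n_shell or bond_cutoff"
        )

    bond_arr = np.array(sorted(bonds), dtype=np.int64)
    lengths = np.linalg.norm(pos[bond_arr[:, 0]] - pos[bond_arr[:, 1]], axis=1)
    mesh = ShellMesh(
        positions=pos,
        bonds=bond_arr,
        rest_length=rest_length_factor * lengths,
        bond_stiffness=bond_stiffness,
        R0=R0,
    )
    mesh.validate()
    return mesh


# ---------------------------------------------------------------------------
# chain placement

def _compact_saw(n: int, center: np.ndarray, envelope: float, max_radius: float,
                 occupied: cKDTree | None, rng: np.random.Generator,
                 min_sep: float = 0.75, step: float = 0.97,
                 max_retries: int = 60) -> np.ndarray:
    """Compact self-avoiding walk of n beads around ``center``.

    Stays within ``envelope`` of the center and inside ``max_radius`` of the
    origin; retries each step against both intra-chain and previously placed
    beads, relaxing the separation floor if stuck (the overlap is removed by
    the capped pre-push afterwards).
    """
    pos = np.empty((n, 3))
    if occupied is not None and len(occupied.query_ball_point(center, min_sep)) > 0:
        raise ConstructionError("chain seed point overlaps a placed chain")
    pos[0] = center
    grid: dict[tuple[int, int, int], list[int]] = {}
    cell = min_sep

    def cell_of(p):
        return tuple((p // cell).astype(np.int64))

    def near(p, floor):
        ci = cell_of(p)
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    for k in grid.get((ci[0] + dx, ci[1] + dy, ci[2] + dz), ()):
                        if np.dot(p - pos[k], p - pos[k]) < floor * floor:
                            return True
        return False

    grid.setdefault(cell_of(pos[0]), []).append(0)
    i = 1
    stalls = 0
    while i < n:
        floor = min_sep
        placed = False
        for attempt in range(max_retries):
            v = rng.normal(size=3)
            cand = pos[i - 1] + step * v / np.linalg.norm(v)
            if np.linalg.norm(cand - center) > envelope:
                continue
            if np.linalg.norm(cand) > max_radius:
                continue
            if near(cand, floor):
                if attempt and attempt % 20 == 19:
                    floor *= 0.85  # capped-repulsion fallback: tolerate mild overlap
                continue
            if occupied is not None and floor >= min_sep:
                if len(occupied.query_ball_point(cand, floor)) > 0:
                    if attempt and attempt % 20 == 19:
                        floor *= 0.85
                    continue
            pos[i] = cand
            grid.setdefault(cell_of(cand), []).append(i)
            placed = True
            break
        if placed:
            i += 1
            continue
        # dead end: backtrack a stretch and regrow from there
        stalls += 1
        if stalls > 80 * max(1, n // 100):
            raise ConstructionError(
                f"chain placement stalled at bead {i}/{n}; lower the volume fraction"
            )
        back_to = max(1, i - 12)
        for j in range(back_to, i):
            grid[cell_of(pos[j])].remove(j)
        i = back_to
    return pos


def _soft_push(pos: np.ndarray, min_sep: float, max_radius: float,
               bonds: np.ndarray | None = None, bond_max: float = 1.25,
               n_iter: int = 300) -> np.ndarray:
    """Energy-capped overlap removal: bounded pairwise pushes, kept inside max_radius.

    ``bonds`` (consecutive-bead pairs) are pulled back toward ``bond_max``
    whenever a push stretches them, so backbone bonds stay well inside their
    finite-extensibility limit.
    """
    pos = pos.copy()
    for _ in range(n_iter):
        tree = cKDTree(pos)
        pairs = tree.query_pairs(min_sep, output_type="ndarray")
        if len(pairs) == 0 and bonds is None:
            break
        if len(pairs):
            d = pos[pairs[:, 0]] - pos[pairs[:, 1]]
            r = np.maximum(np.linalg.norm(d, axis=1, keepdims=True), 1e-9)
            push = np.clip(0.3 * (min_sep - r), 0.0, 0.1) * d / r
            np.add.at(pos, pairs[:, 0], push)
            np.add.at(pos, pairs[:, 1], -push)
        if bonds is not None and len(bonds):
            d = pos[bonds[:, 0]] - pos[bonds[:, 1]]
            r = np.maximum(np.linalg.norm(d, axis=1, keepdims=True), 1e-9)
            pull = np.clip(0.5 * (r - bond_max), 0.0, 0.2) * d / r
            np.add.at(pos, bonds[:, 0], -pull)
            np.add.at(pos, bonds[:, 1], pull)
        radii = np.linalg.norm(pos, axis=1, keepdims=True)
        over = radii[:, 0] > max_radius
        if over.any():
            pos[over] *= max_radius / radii[over]
        if len(pairs) == 0 and bonds is not None:
            blen = np.linalg.norm(pos[bonds[:, 0]] - pos[bonds[:, 1]], axis=1)
            if blen.max() <= 1.4:
                break
    return pos


def place_compact_chains(
    plans: list[ChromosomePlan],
    shell: ShellMesh,
    seed: int = 0,
    placement_radius_fraction: float = 0.62,
) -> InitialConfiguration:
    """Place each chain as a compact self-avoiding walk near the shell center.

    Chains are seeded at random points within the inner half of the shell and
    grown with 0.97-sigma steps; a final capped-repulsion push removes residual
    overlaps.  All chain beads end strictly inside the shell.
    """
    rng = np.random.default_rng(seed)
    r_place = placement_radius_fraction * shell.R0
    if plans:
        total = sum(p.n_beads for p in plans)
        bead_vol = total * np.pi / 6.0
        place_vol = 4.0 / 3.0 * np.pi * r_place ** 3
        if bead_vol > 0.55 * place_vol:
            raise ConstructionError(
                f"{total} chain beads exceed the packable volume inside "
                f"radius {r_place:.1f}; lower the volume fraction"
            )
    chunks = []
    occupied: cKDTree | None = None
    # well-separated seed directions (Fibonacci sphere), jittered per attempt,
    # so every chain starts in its own sector of the placement volume
    golden = np.pi * (3.0 - np.sqrt(5.0))
    n_dirs = max(len(plans), 1)
    ks = np.arange(n_dirs)
    z = 1.0 - 2.0 * (ks + 0.5) / n_dirs
    th = golden * ks
    fib_dirs = np.column_stack([
        np.sqrt(1 - z ** 2) * np.cos(th), np.sqrt(1 - z ** 2) * np.sin(th), z
    ])
    for plan_index, plan in enumerate(plans):
        base_envelope = max(2.0, (plan.n_beads * 0.33) ** (1.0 / 3.0) + 1.0)
        envelope = base_envelope
        r_now = r_place
        chain = None
        for attempt in range(150):
            if attempt < 30:
                # jittered sector seed along this chain's Fibonacci direction
                u = fib_dirs[plan_index] + 0.25 * rng.normal(size=3)
                u /= np.linalg.norm(u)
                center = (0.45 + 0.1 * rng.random()) * r_now * u
            else:
                # fall back to the emptiest random candidate
                u = rng.normal(size=(30, 3))
                u /= np.linalg.norm(u, axis=1, keepdims=True)
                radius = (rng.random(30) ** (1.0 / 3.0)) * max(r_now - envelope, 1.0)
                cand = u * radius[:, None]
                if occupied is not None:
                    d, _ = occupied.query(cand, k=1)
                    center = cand[int(np.argmax(d))]
                else:
                    center = cand[0]
            try:
                chain = _compact_saw(
                    plan.n_beads, center, envelope, r_now, occupied, rng
                )
                break
            except ConstructionError:
                # genuine growth stall: loosen compactness, then the region itself
                envelope = min(envelope * 1.15, 0.95 * r_now)
                if attempt >= 20:
                    r_now = min(r_now * 1.02, 0.68 * shell.R0)
        if chain is None:
            raise ConstructionError("could not place all chains; lower the volume fraction")
        chunks.append(chain)
        occupied = cKDTree(np.concatenate(chunks))
    if chunks:
        backbone = []
        off = 0
        for ch in chunks:
            n = len(ch)
            backbone.append(np.column_stack([np.arange(off, off + n - 1),
                                             np.arange(off + 1, off + n)]))
            off += n
        all_pos = _soft_push(np.concatenate(chunks), 0.9, r_place,
                             bonds=np.concatenate(backbone))
        blen = np.linalg.norm(
            all_pos[np.concatenate(backbone)[:, 0]]
            - all_pos[np.concatenate(backbone)[:, 1]], axis=1)
        if blen.max() >= 1.45:
            raise ConstructionError(
                f"backbone bond stretched to {blen.max():.2f} during placement"
            )
    else:
        all_pos = np.empty((0, 3))
    phi = PHI_BY_NBLOCK.get(len(plans))
    return InitialConfiguration(
        plans=[p.copy() for p in plans],
        chain_positions=all_pos,
        shell=shell,
        crosslinks=CrosslinkSet(),
        phi_nominal=phi,
    )


# ---------------------------------------------------------------------------
# crosslinks

def add_crosslinks(
    config: InitialConfiguration,
    crosslink_cutoff: float = 1.3,
    max_per_bead: int = 2,
    seed: int = 0,
    positions: np.ndarray | None = None,
) -> InitialConfiguration:
    """Permanently crosslink constitutive-heterochromatin bead pairs within a cutoff.

    Pairs are drawn among C beads closer than ``crosslink_cutoff`` (excluding
    backbone neighbors), in seeded random order, with at most ``max_per_bead``
    crosslinks per bead.  Pass ``positions`` to crosslink a relaxed snapshot
    rather than the construction coordinates.
    """
    if crosslink_cutoff < 1.0:
        raise ValueError("crosslink_cutoff below the bead diameter")
    pos = config.chain_positions if positions is None else np.asarray(positions)
    types = config.chain_types()
    c_idx = np.flatnonzero(types == BeadType.C)
    if c_idx.size == 0:
        return InitialConfiguration(
            plans=config.plans, chain_positions=config.chain_positions,
            shell=config.shell, crosslinks=CrosslinkSet(enabled=True),
            phi_nominal=config.phi_nominal,
        )
    tree = cKDTree(pos[c_idx])
    pairs = tree.query_pairs(crosslink_cutoff, output_type="ndarray")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pairs))
    count = np.zeros(len(pos), dtype=np.int64)
    chosen = []
    for k in order:
        i, j = int(c_idx[pairs[k, 0]]), int(c_idx[pairs[k, 1]])
        if abs(i - j) == 1:  # backbone bond already present
            continue
        if count[i] >= max_per_bead or count[j] >= max_per_bead:
            continue
        chosen.append((min(i, j), max(i, j)))
        count[i] += 1
        count[j] += 1
    chosen_arr = (
        np.array(sorted(chosen), dtype=np.int64)
        if chosen else np.empty((0, 2), dtype=np.int64)
    )
    return InitialConfiguration(
        plans=config.plans,
        chain_positions=config.chain_positions,
        shell=config.shell,
        crosslinks=CrosslinkSet(pairs=chosen_arr, enabled=True),
        phi_nominal=config.phi_nominal,
    )
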