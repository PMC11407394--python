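"""File formats: extended XYZ, BED-like block annotations, JSON topology,
HDF5 trajectories and CSV observables."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    BeadType,
    ChromosomePlan,
    InitialConfiguration,
    SystemState,
    Trajectory,
    TYPE_CODES,
)


# ---------------------------------------------------------------------------
# extended XYZ

def write_xyz(path, positions: np.ndarray, types: np.ndarray,
              comment: str = "") -> None:
    """Extended-XYZ frame: species column = bead type code."""
    positions = np.asarray(positions)
    with open(path, "w") as fh:
        fh.write(f"{len(positions)}\n")
        props = 'Properties=species:S:1:pos:R:3'
        fh.write(f"{props} {comment}".strip() + "\n")
        for t, (x, y, z) in zip(types, positions):
            fh.write(f"{TYPE_CODES[t]} {x:.6f} {y:.6f} {z:.6f}\n")


def read_xyz(path) -> tuple[np.ndarray, np.ndarray]:
    """Read one extended-XYZ frame; returns (positions, types)."""
    with open(path) as fh:
        n = int(fh.readline())
        fh.readline()
        types = np.empty(n, dtype=np.int8)
        pos = np.empty((n, 3))
        for i in range(n):
            parts = fh.readline().split()
            types[i] = TYPE_CODES.index(parts[0])
            pos[i] = [float(v) for v in parts[1:4]]
    return pos, types


def write_xyz_trajectory(path, traj: Trajectory) -> None:
    with open(path, "w") as fh:
        for fi in range(traj.n_frames):
            fh.write(f"{traj.n_beads}\n")
            fh.write(
                f"Properties=species:S:1:pos:R:3 step={traj.steps[fi]} "
                f"phase={traj.phases[fi]}\n"
            )
            for t, (x, y, z) in zip(traj.types, traj.frames[fi]):
                fh.write(f"{TYPE_CODES[t]} {x:.4f} {y:.4f} {z:.4f}\n")


# ---------------------------------------------------------------------------
# BED-like block annotations (chain_id, start_bead, end_bead half-open, type)

def plans_to_bed(plans: list[ChromosomePlan]) -> str:
    lines = []
    for cid, plan in enumerate(plans):
        types = plan.bead_types
        start = 0
        for i in range(1, len(types) + 1):
            if i == len(types) or types[i] != types[start]:
                lines.append(f"{cid}\t{start}\t{i}\t{TYPE_CODES[types[start]]}")
                start = i
    return "\n".join(lines) + "\n"


def write_bed(path, plans: list[ChromosomePlan]) -> None:
    Path(path).write_text(plans_to_bed(plans))


def plans_from_bed(text: str) -> list[ChromosomePlan]:
    """Rebuild chain plans from a 4-column BED-like annotation."""
    rows = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        cid, start, end, code = line.split()
        rows.append((int(cid), int(start), int(end), code))
    plans = []
    for cid in sorted({r[0] for r in rows}):
        segs = sorted([r for r in rows if r[0] == cid], key=lambda r: r[1])
        n = segs[-1][2]
        types = np.empty(n, dtype=np.int8)
        for _, s, e, code in segs:
            types[s:e] = BeadType[code]
        counts = {c: int(np.count_nonzero(types == BeadType[c])) for c in "EFCT"}
        n_comp = counts["E"] + counts["F"]
        plans.append(ChromosomePlan(
            bead_types=types,
            n_constitutive=counts["C"],
            n_compartment=n_comp,
            n_telomere=counts["T"],
            f_het=counts["F"] / n_comp if n_comp else 0.0,
        ))
    return plans


def read_bed(path) -> list[ChromosomePlan]:
    return plans_from_bed(Path(path).read_text())


# ---------------------------------------------------------------------------
# topology sidecar

def topology_json(config: InitialConfiguration) -> str:
    return json.dumps({
        "n_block": config.n_block,
        "phi_nominal": config.phi_nominal,
        "chain_lengths": [p.n_beads for p in config.plans],
        "f_het": [p.f_het for p in config.plans],
        "shell": {
            "n_beads": config.shell.n_beads,
            "R0": config.shell.R0,
            "bonds": config.shell.bonds.tolist(),
            "rest_length": config.shell.rest_length.tolist(),
            "bond_stiffness": config.shell.bond_stiffness,
        },
        "crosslinks": {
            "enabled": bool(config.crosslinks.enabled),
            "pairs": config.crosslinks.pairs.tolist(),
        },
    })


# ---------------------------------------------------------------------------
# HDF5 trajectory container

def write_trajectory_h5(path, traj: Trajectory) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("frames", data=traj.frames, compression="gzip")
        f.create_dataset("steps", data=traj.steps)
        f.create_dataset("phases", data=np.array(traj.phases, dtype="S"))
        f.create_dataset("types", data=traj.types)
        f.create_dataset("chain_id", data=traj.chain_id)
        f.create_dataset("mean_shell_radius", data=traj.mean_shell_radius)
        if traj.diagnostics is not None and len(traj.diagnostics):
            g = f.create_group("diagnostics")
            for col in traj.diagnostics.columns:
                data = traj.diagnostics[col].to_numpy()
                if data.dtype == object:
                    data = data.astype("S")
                g.create_dataset(col, data=data)


def read_trajectory_h5(path) -> Trajectory:
    import h5py

    with h5py.File(path, "r") as f:
        diags = None
        if "diagnostics" in f:
            cols = {}
            for col in f["diagnostics"]:
                data = f["diagnostics"][col][()]
                if data.dtype.kind == "S":
                    data = data.astype(str)
                cols[col] = data
            diags = pd.DataFrame(cols)
        return Trajectory(
            frames=f["frames"][()],
            steps=f["steps"][()],
            phases=[p.decode() for p in f["phases"][()]],
            types=f["types"][()],
            chain_id=f["chain_id"][()],
            mean_shell_radius=f["mean_shell_radius"][()],
            diagnostics=diags,
        )


# ---------------------------------------------------------------------------
# observable tables

def spectrum_to_csv(path, spectrum) -> None:
    pd.DataFrame({
        "mode": spectrum.mode_numbers,
        "amplitude": spectrum.amplitudes,
    }).to_csv(path, index=False)


def profile_to_csv(path, profile) -> None:
    centers = 0.5 * (profile.bin_edges[1:] + profile.bin_edges[:-1])
    rows = []
    for code, dens in profile.density.items():
        for c, d in zip(centers, dens):
            rows.append({"r_norm": c, "type": code, "density": d})
    pd.DataFrame(rows).to_csv(path, index=False)


def write_scenario_bundle(bundle: dict, outdir) -> None:
    """Self-describing result directory: config, summaries, CSVs, final XYZ."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = bundle["config"]
    (out / "scenario.json").write_text(json.dumps(cfg, indent=1))
    summary = {
        "scenario_id": cfg["scenario_id"],
        "rms_mean": bundle["rms_mean"],
        "rms_sd": bundle["rms_sd"],
        "rms_per_seed": list(map(float, bundle["rms_per_seed"])),
        "seeds": cfg["seeds"],
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1))
    for res in bundle["results"]:
        tag = f"seed{res.seed}"
        spectrum_to_csv(out / f"spectrum_{tag}.csv", res.spectrum)
        profile_to_csv(out / f"profile_{tag}.csv", res.profile)
        traj = res.trajectory
        write_xyz(out / f"final_{tag}.xyz", traj.frames[-1], traj.types)
        if traj.diagnostics is not None:
            traj.diagnostics.to_csv(out / f"diagnostics_{tag}.csv", index=False)
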