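import numpy as np
import pandas as pd
import pytest

from nucshell.types import BeadType, Trajectory


def make_trajectory(frame_positions, types, chain_id=None, phases=None):
    """Assemble a Trajectory from raw frames (test helper)."""
    frames = np.asarray(frame_positions, dtype=np.float32)
    if frames.ndim == 2:
        frames = frames[None]
    n = frames.shape[1]
    types = np.asarray(types, dtype=np.int8)
    if chain_id is None:
        chain_id = np.where(types == BeadType.S, -1, 0).astype(np.int64)
    shell = types == BeadType.S
    radii = []
    for f in frames:
        if shell.any():
            sp = f[shell]
            com = sp.mean(axis=0)
            radii.append(float(np.linalg.norm(sp - com, axis=1).mean()))
        else:
            radii.append(np.nan)
    return Trajectory(
        frames=frames,
        steps=np.arange(len(frames)),
        phases=phases or ["test"] * len(frames),
        types=types,
        chain_id=np.asarray(chain_id, dtype=np.int64),
        mean_shell_radius=np.array(radii),
        diagnostics=pd.DataFrame(),
    )


@pytest.fixture(scope="session")
def small_shell():
    from nucshell.builder import build_shell_mesh

    return build_shell_mesh(n_shell=500, R0=10.0, seed=11)
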