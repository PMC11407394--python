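"""Measurements on trajectories: shape-fluctuation spectra, radial profiles,
contact maps and chain compaction.

The fluctuation analysis follows the thin-slice construction: shell beads
within a 1-sigma slab through the shell center of mass are projected onto the
slice plane, their in-plane radial displacements from the slice-mean radius
are resampled onto a uniform angular grid, and the FFT amplitudes of the
lowest modes are time-averaged over the last half of the trajectory.  The
amplitude normalization is fixed so an imposed cosine of amplitude A at mode q
reports A at mode q.  The RMS shape fluctuation is the time-averaged standard
deviation of the raw (non-resampled) radial displacements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .types import BeadType, Trajectory

AXES = {"x": 0, "y": 1, "z": 2}
DEFAULT_MODES = 230
MIN_SLICE_BEADS = 16


class SliceTooSparseError(ValueError):
    pass


@dataclass
class SliceSpec:
    """Thin equatorial slice through the shell center of mass."""

    normal_axis: str = "z"
    width: float = 1.0

    def __post_init__(self) -> None:
        if self.normal_axis not in AXES:
            raise ValueError("normal_axis must be one of x, y, z")
        if self.width <= 0:
            raise ValueError("slice width must be positive")


@dataclass
class FluctuationSpectrum:
    """Time-averaged per-mode amplitudes (sigma) and RMS radial deviation."""

    mode_numbers: np.ndarray
    amplitudes: np.ndarray
    rms: float
    n_frames_averaged: int
    mean_radius: float
    normalized_by_radius: bool = False

    def amplitude(self, q: int) -> float:
        return float(self.amplitudes[np.searchsorted(self.mode_numbers, q)])


@dataclass
class RadialProfile:
    """Per-type radial densities in units of the instantaneous mean shell radius."""

    bin_edges: np.ndarray
    density: dict[str, np.ndarray]
    counts: dict[str, float] = field(default_factory=dict)

    def outer_mass_fraction(self, code: str, r_from: float = 0.75) -> float:
        """Fraction of a type's beads beyond normalized radius ``r_from``."""
        centers = 0.5 * (self.bin_edges[1:] + self.bin_edges[:-1])
        vol = np.diff(self.bin_edges ** 3)
        mass = self.density[code] * vol
        total = mass.sum()
        return float(mass[centers >= r_from].sum() / total) if total > 0 else 0.0


@dataclass
class ContactMap:
    matrix: np.ndarray
    bin_size: int
    contact_cutoff: float


# ---------------------------------------------------------------------------

def _shell_com(positions: np.ndarray, types: np.ndarray) -> np.ndarray:
    """Shell center by least-squares sphere fit (Kasa method).

    The bead center of mass carries a sampling error of order R/sqrt(N) that
    leaks into the lowest Fourier mode; the algebraic sphere fit recovers the
    exact center for an ideal sphere and is robust for wrinkled shells.
    """
    shell = positions[types == BeadType.S]
    if len(shell) == 0:
        raise ValueError("no shell beads in frame")
    A = np.column_stack([2.0 * shell, np.ones(len(shell))])
    b = (shell ** 2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    return sol[:3]


def _next_pow2(n: int) -> int:
    p = 1
    while p < n:
        p *= 2
    return p


def slice_radial_displacements(
    positions: np.ndarray,
    types: np.ndarray,
    spec: SliceSpec | None = None,
):
    """Angular signal of radial displacements of shell beads in a thin slice.

    Returns ``(theta_grid, resampled, raw_displacements)``: the uniform angular
    grid, the linearly interpolated displacement signal on it, and the raw
    per-bead displacements (mean-subtracted in-plane radii) used for the RMS.
    """
    spec = spec or SliceSpec()
    ax = AXES[spec.normal_axis]
    in_plane = [d for d in range(3) if d != ax]
    com = _shell_com(positions, types)
    shell = positions[types == BeadType.S] - com
    sel = np.abs(shell[:, ax]) < 0.5 * spec.width
    band = shell[sel]
    if len(band) < MIN_SLICE_BEADS:
        raise SliceTooSparseError(
            f"slice holds {len(band)} shell beads (< {MIN_SLICE_BEADS}); "
            "widen the slice or densify the shell"
        )
    rho = np.hypot(band[:, in_plane[0]], band[:, in_plane[1]])
    theta = np.arctan2(band[:, in_plane[1]], band[:, in_plane[0]])
    disp = rho - rho.mean()
    order = np.argsort(theta, kind="stable")
    theta, disp = theta[order], disp[order]
    grid_n = _next_pow2(2 * len(band))
    theta_grid = -np.pi + 2.0 * np.pi * np.arange(grid_n) / grid_n
    # periodic linear interpolation
    theta_ext = np.concatenate([theta, [theta[0] + 2.0 * np.pi]])
    disp_ext = np.concatenate([disp, [disp[0]]])
    resampled = np.interp(theta_grid, theta_ext, disp_ext, period=2.0 * np.pi)
    return theta_grid, resampled, disp


def _frame_spectrum(signal: np.ndarray, Q: int) -> np.ndarray:
    n = len(signal)
    coeffs = np.fft.rfft(signal)
    # cosine of amplitude A at mode q -> |X_q| = A*n/2
    return 2.0 * np.abs(coeffs[1:Q + 1]) / n


def fluctuation_spectrum(
    traj: Trajectory,
    spec: SliceSpec | None = None,
    Q: int | None = None,
    average_axes: bool = False,
    last_fraction: float = 0.5,
    normalize_by_radius: bool = False,
) -> FluctuationSpectrum:
    """Time-averaged Fourier fluctuation spectrum and RMS radial deviation.

    Amplitudes of modes 1..Q are averaged over the last ``last_fraction`` of
    frames (the default last half).  ``average_axes`` additionally averages the
    three orthogonal equatorial slices of each frame, exploiting the model's
    isotropy.  ``normalize_by_radius`` divides amplitudes and RMS by the
    time-mean shell radius (dimensionless output); default is raw sigma.
    """
    if traj.n_frames < 4:
        raise ValueError("need at least 4 frames for a time-averaged spectrum")
    spec = spec or SliceSpec()
    first = int(np.floor(traj.n_frames * (1.0 - last_fraction)))
    frames = range(first, traj.n_frames)
    axes = ("x", "y", "z") if average_axes else (spec.normal_axis,)

    q_cap = DEFAULT_MODES if Q is None else Q
    amp_sum = np.zeros(q_cap)
    mode_count = np.zeros(q_cap)
    rms_sum = 0.0
    count = 0
    for fi in frames:
        pos = traj.frame_state_positions(fi)
        for axis in axes:
            sub = SliceSpec(normal_axis=axis, width=spec.width)
            _, signal, raw = slice_radial_displacements(pos, traj.types, sub)
            nyq = len(signal) // 2 - 1
            if Q is not None and Q > nyq:
                raise ValueError(f"Q={Q} exceeds the Nyquist bound {nyq}")
            q_frame = min(q_cap, nyq)
            a = _frame_spectrum(signal, q_frame)
            amp_sum[:q_frame] += a
            mode_count[:q_frame] += 1
            rms_sum += raw.std()
            count += 1
    valid = mode_count > 0
    amplitudes = amp_sum[valid] / mode_count[valid]
    rms = rms_sum / count
    mean_radius = float(np.nanmean(traj.mean_shell_radius[first:]))
    if normalize_by_radius:
        amplitudes = amplitudes / mean_radius
        rms = rms / mean_radius
    return FluctuationSpectrum(
        mode_numbers=np.arange(1, len(amplitudes) + 1),
        amplitudes=amplitudes,
        rms=float(rms),
        n_frames_averaged=traj.n_frames - first,
        mean_radius=mean_radius,
        normalized_by_radius=normalize_by_radius,
    )


def rms_shape_fluctuation(traj: Trajectory, **kwargs) -> float:
    """Shorthand for the RMS radial deviation of the shell (sigma)."""
    return fluctuation_spectrum(traj, **kwargs).rms


# ---------------------------------------------------------------------------

def radial_density_profile(
    traj: Trajectory,
    types: str = "EFCT",
    n_bins: int = 22,
    last_fraction: float = 0.5,
) -> RadialProfile:
    """Time-averaged per-type radial density around the shell center of mass.

    Radii are normalized by the instantaneous mean shell radius; densities are
    per unit normalized-shell volume, so integrating density * bin volume over
    the bins recovers each type's bead count.
    """
    if traj.n_frames < 1:
        raise ValueError("empty trajectory")
    first = int(np.floor(traj.n_frames * (1.0 - last_fraction)))
    edges = np.linspace(0.0, 1.1, n_bins + 1)
    acc = {c: np.zeros(n_bins) for c in types}
    n_frames = 0
    for fi in range(first, traj.n_frames):
        pos = traj.frame_state_positions(fi)
        com = _shell_com(pos, traj.types)
        r_mean = traj.mean_shell_radius[fi]
        if not np.isfinite(r_mean):
            r_mean = 1.0
        r = np.linalg.norm(pos - com, axis=1) / r_mean
        for c in types:
            mask = traj.types == BeadType[c]
            if mask.any():
                h, _ = np.histogram(np.clip(r[mask], 0, 1.1 - 1e-9), bins=edges)
                acc[c] += h
        n_frames += 1
    vol = 4.0 / 3.0 * np.pi * np.diff(edges ** 3)
    density = {c: acc[c] / n_frames / vol for c in types}
    counts = {c: float(acc[c].sum() / n_frames) for c in types}
    return RadialProfile(bin_edges=edges, density=density, counts=counts)


def median_radius_by_type(
    traj: Trajectory, last_fraction: float = 0.5
) -> dict[str, float]:
    """Median radial position per chromatin type over the last frames (sigma)."""
    first = int(np.floor(traj.n_frames * (1.0 - last_fraction)))
    radii: dict[str, list] = {c: [] for c in "EFCT"}
    for fi in range(first, traj.n_frames):
        pos = traj.frame_state_positions(fi)
        com = _shell_com(pos, traj.types)
        r = np.linalg.norm(pos - com, axis=1)
        for c in "EFCT":
            mask = traj.types == BeadType[c]
            if mask.any():
                radii[c].append(np.median(r[mask]))
    return {c: float(np.mean(v)) for c, v in radii.items() if v}


# ---------------------------------------------------------------------------

def contact_map(
    positions: np.ndarray,
    chain_id: np.ndarray,
    bin_size: int = 1,
    contact_cutoff: float = 1.5,
) -> ContactMap:
    """Hi-C-like symmetric contact matrix over genomic bins of one frame.

    Chain beads are indexed genomically (concatenated chains); every bead pair
    within ``contact_cutoff`` adds one contact to its bin pair, and each bead
    contributes a self-contact so the diagonal is maximal.
    """
    mask = np.asarray(chain_id) >= 0
    pos = np.asarray(positions)[mask]
    n = len(pos)
    nbin = (n + bin_size - 1) // bin_size
    m = np.zeros((nbin, nbin), dtype=np.float64)
    gbin = np.arange(n) // bin_size
    np.add.at(m, (gbin, gbin), 1.0)  # self contacts
    pairs = cKDTree(pos).query_pairs(contact_cutoff, output_type="ndarray")
    if len(pairs):
        bi, bj = gbin[pairs[:, 0]], gbin[pairs[:, 1]]
        np.add.at(m, (bi, bj), 1.0)
        off = bi != bj
        np.add.at(m, (bj[off], bi[off]), 1.0)
        same = ~off
        np.add.at(m, (bj[same], bi[same]), 1.0)  # keep symmetry count on diagonal
    return ContactMap(matrix=m, bin_size=bin_size, contact_cutoff=contact_cutoff)


def mean_intra_type_contact_density(
    positions: np.ndarray, chain_id: np.ndarray, types: np.ndarray,
    contact_cutoff: float = 1.5,
) -> dict[str, float]:
    """Mean per-bead count of same-type spatial contacts for E, F and C."""
    mask = np.asarray(chain_id) >= 0
    pos = np.asarray(positions)[mask]
    t = np.asarray(types)[mask]
    pairs = cKDTree(pos).query_pairs(contact_cutoff, output_type="ndarray")
    out = {}
    for c in "EFC":
        code = BeadType[c]
        nt = np.count_nonzero(t == code)
        if nt == 0:
            continue
        both = (t[pairs[:, 0]] == code) & (t[pairs[:, 1]] == code)
        out[c] = float(2.0 * np.count_nonzero(both) / nt)
    return out


# ---------------------------------------------------------------------------

def chain_compaction(traj: Trajectory, last_fraction: float = 1.0):
    """Per-chain radius of gyration and pairwise chain-center distances.

    Returns a dict with time-averaged ``rg`` (per chain), ``com_distances``
    (condensed pairwise), and the per-frame series of both.
    """
    if traj.n_frames < 1:
        raise ValueError("empty trajectory")
    ids = np.asarray(traj.chain_id)
    chains = np.unique(ids[ids >= 0])
    first = int(np.floor(traj.n_frames * (1.0 - last_fraction)))
    rg_series = []
    dist_series = []
    for fi in range(first, traj.n_frames):
        pos = traj.frame_state_positions(fi)
        coms = []
        rgs = []
        for c in chains:
            p = pos[ids == c]
            com = p.mean(axis=0)
            coms.append(com)
            rgs.append(np.sqrt(((p - com) ** 2).sum(axis=1).mean()))
        rg_series.append(rgs)
        coms_arr = np.array(coms)
        if len(chains) > 1:
            iu = np.triu_indices(len(chains), k=1)
            d = np.linalg.norm(coms_arr[iu[0]] - coms_arr[iu[1]], axis=1)
        else:
            d = np.empty(0)
        dist_series.append(d)
    rg_series = np.array(rg_series)
    dist_series = np.array(dist_series)
    return {
        "chains": chains,
        "rg": rg_series.mean(axis=0) if rg_series.size else np.empty(0),
        "com_distances": dist_series.mean(axis=0) if dist_series.size else np.empty(0),
        "rg_series": rg_series,
        "com_distance_series": dist_series,
    }
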