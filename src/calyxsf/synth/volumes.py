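"""Synthetic two-channel fluorescence volumes.

The fill channel holds a biocytin-like filled soma (a mildly anisotropic
ellipsoid); the marker channel holds VGluT-like presynaptic caps: spherical-
cap shells apposed to the soma surface across a synaptic-cleft gap, one per
input, pairwise disconnected. Cap angular extents are solved numerically on
the offset ellipsoid surface so the delivered contact area matches the
requested one up to voxelization. Both channels are blurred by a Gaussian
PSF and corrupted by the configured noise model; the returned ground-truth
contact report is measured on the noise-free label geometry with the same
estimator the analysis uses.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.ndimage import distance_transform_edt, gaussian_filter, label

from ..datatypes import CellGroundTruth, ClusterSet, ContactReport, SomaMask, VolumeParams, VoxelVolume
from ..errors import GenerationError
from .. import seg3d

__all__ = ["synth_volume", "cap_area_to_angle"]

MIN_CAP_AREA = 0.2  # µm²; smaller requested caps are below marker resolution

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


def _cap_area_profile(axes, u, n_psi: int = 256, n_phi: int = 128, psi_max: float = 0.49 * math.pi):
    """Cumulative surface area (µm²) of the radial cap around direction ``u``
    on the ellipsoid with semi-axes ``axes`` (ZYX), vs polar angle psi."""
    u = np.asarray(u, float)
    u = u / np.linalg.norm(u)
    # orthonormal frame
    a = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(u, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    psi = np.linspace(0.0, psi_max, n_psi)
    phi = np.linspace(0.0, 2 * math.pi, n_phi, endpoint=False)
    P, F = np.meshgrid(psi, phi, indexing="ij")
    d = (
        np.cos(P)[..., None] * u
        + (np.sin(P) * np.cos(F))[..., None] * e1
        + (np.sin(P) * np.sin(F))[..., None] * e2
    )  # (n_psi, n_phi, 3)
    rho = 1.0 / np.sqrt(np.sum((d / np.asarray(axes)) ** 2, axis=-1))
    S = rho[..., None] * d
    dS_psi = np.gradient(S, psi, axis=0)
    dS_phi = np.gradient(S, axis=1) / (phi[1] - phi[0])
    cross = np.cross(dS_psi, dS_phi)
    dA = np.linalg.norm(cross, axis=-1)
    ring = dA.sum(axis=1) * (phi[1] - phi[0])
    cum = np.concatenate([[0.0], np.cumsum(0.5 * (ring[1:] + ring[:-1]) * np.diff(psi))])
    return psi, cum


def cap_area_to_angle(axes, u, area: float) -> float:
    """Polar half-angle (rad) of the radial cap of the given surface area."""
    psi, cum = _cap_area_profile(axes, u)
    if area > cum[-1]:
        raise GenerationError(f"requested cap area {area:.1f} µm² exceeds the soma surface")
    return float(np.interp(area, cum, psi))


def _place_caps(rng, axes, areas, gap_um: float, max_tries: int = 400, max_frac: float = 0.40):
    """Random non-overlapping cap directions (rejection sampling).

    A requested area larger than ``max_frac`` of the soma surface is clipped
    to it: a near-hemispheric terminal cannot be voxelized as a disjoint cap,
    and its measured contact is a lower bound in any case."""
    r_mean = float(np.mean(axes))
    _, cum = _cap_area_profile(axes, np.array([0.0, 0.0, 1.0]), psi_max=0.995 * math.pi)
    max_area = max_frac * float(cum[-1])
    dirs, angles = [], []
    for area in areas:
        area = min(area, max_area)
        for attempt in range(max_tries):
            u = rng.standard_normal(3)
            u /= np.linalg.norm(u)
            theta = cap_area_to_angle(axes, u, area)
            ok = all(
                math.acos(np.clip(np.dot(u, u2), -1, 1)) > theta + t2 + gap_um / r_mean
                for u2, t2 in zip(dirs, angles)
            )
            if ok:
                dirs.append(u)
                angles.append(theta)
                break
        else:
            raise GenerationError(
                "could not place non-overlapping marker caps; retry with a new seed"
            )
    return dirs, angles


def synth_volume(
    cell: CellGroundTruth,
    vparams: VolumeParams,
    min_cap_area: float = MIN_CAP_AREA,
    soma_intensity: float = 100.0,
    marker_intensity: float = 100.0,
    full_output: bool = False,
):
    """Voxelize one cell: returns ``(fill, marker, true_report)``.

    ``true_report`` is a :class:`ContactReport` measured on the noise-free
    label geometry (soma dilated across the cleft, caps as labels), i.e. the
    value a perfect segmentation of this volume should recover.
    With ``full_output=True`` a dict of intermediate truth objects (masks,
    labels, cap directions) is appended to the return tuple.
    """
    vs = np.asarray(vparams.voxel_size)
    axes = cell.soma_radius * np.asarray(vparams.anisotropy)
    margin = vparams.margin
    if np.any(margin / vs < 10):
        raise GenerationError("soma must fit with a >= 10-voxel margin on every axis")
    half = axes + margin
    shape = tuple(2 * np.ceil(half / vs).astype(int) + 1)
    center = (np.asarray(shape) - 1) / 2.0

    zz, yy, xx = np.meshgrid(
        (np.arange(shape[0]) - center[0]) * vs[0],
        (np.arange(shape[1]) - center[1]) * vs[1],
        (np.arange(shape[2]) - center[2]) * vs[2],
        indexing="ij",
    )
    soma = (zz / axes[0]) ** 2 + (yy / axes[1]) ** 2 + (xx / axes[2]) ** 2 <= 1.0
    dist_out = distance_transform_edt(~soma, sampling=vs)

    cleft, shell = vparams.cleft_offset, vparams.shell_thickness
    shell_mask = (dist_out >= cleft) & (dist_out <= cleft + shell)

    # caps live on the offset (cleft-dilated) surface: solve angular extents
    # there so the contacted area matches the requested one
    rng = np.random.default_rng(vparams.seed)
    areas_all = np.asarray(cell.true_contact_areas, float)
    cap_idx = [i for i, a in enumerate(areas_all) if a >= min_cap_area]
    axes_eff = axes + cleft
    dirs, angles = _place_caps(rng, axes_eff, areas_all[cap_idx], gap_um=3 * float(vs.max()))

    labels = np.zeros(shape, dtype=np.int32)
    if cap_idx:
        sh = np.flatnonzero(shell_mask.ravel())
        pz, py, px = zz.ravel()[sh], yy.ravel()[sh], xx.ravel()[sh]
        norm = np.sqrt(pz**2 + py**2 + px**2)
        norm[norm == 0] = 1.0
        flat = labels.ravel()
        for k, (u, theta) in enumerate(zip(dirs, angles)):
            cosang = (pz * u[0] + py * u[1] + px * u[2]) / norm
            sel = cosang >= math.cos(theta)
            flat[sh[sel]] = k + 1
        labels = flat.reshape(shape)
        # verify disjointness under 26-connectivity
        _, n_found = label(labels > 0, structure=_STRUCT26)
        if n_found != len(cap_idx):
            raise GenerationError("marker caps merged after voxelization; retry with a new seed")

    # ground truth measured on the noise-free geometry, with the reference
    # surface embedded two lateral voxels into the marker shell so the
    # coincident-footprint estimator applies
    soma_true = SomaMask(mask=soma, voxel_size=tuple(vs))
    dilated_true = seg3d.dilate_soma(soma_true, cleft + 2 * float(vs.min()))
    clusters_true = ClusterSet(labels=labels, voxel_size=tuple(vs))
    true_report = seg3d.contact_report(dilated_true, clusters_true)

    def _corrupt(img):
        img = img.astype(np.float32)
        sig = np.asarray(vparams.psf_sigma) / vs
        if np.any(sig > 0):
            img = gaussian_filter(img, sigma=sig)
        if vparams.poisson_scale > 0:
            img = rng.poisson(np.clip(img, 0, None) * vparams.poisson_scale).astype(
                np.float32
            ) / vparams.poisson_scale
        if vparams.gaussian_sd > 0:
            img = img + rng.normal(0, vparams.gaussian_sd, size=img.shape).astype(np.float32)
        return img

    fill = VoxelVolume(
        intensities=_corrupt(soma * soma_intensity),
        voxel_size=tuple(vs),
        channel_name="fill",
    )
    marker = VoxelVolume(
        intensities=_corrupt((labels > 0) * marker_intensity),
        voxel_size=tuple(vs),
        channel_name="marker",
    )
    if full_output:
        extras = dict(
            soma_mask=soma,
            labels=labels,
            cap_input_indices=cap_idx,
            cap_directions=dirs,
            cap_angles=angles,
            requested_areas=areas_all[cap_idx],
            seed=vparams.seed,
        )
        return fill, marker, true_report, extras
    return fill, marker, true_report
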