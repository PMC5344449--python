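"""Optode/channel geometry, MNI registration, and channel-to-voxel interpolation.

An fNIRS channel is an emitter-detector pair; its nominal location is the
scalp midpoint between the two optodes.  This module houses:

* :class:`ProbeLayout` — optode positions, channel pairing and fiducials,
  with a default 98-channel montage (30 emitters / 29 detectors at 3 cm
  nominal spacing) covering frontal, temporal and parietal cortex;
* fiducial-based similarity registration to a template head
  (:func:`fiducial_transform`);
* group alignment of per-subject channel values onto the median channel
  coordinates (:func:`register_to_median`);
* interpolation of channel values onto a voxel grid for cluster-level
  inference (:class:`VolumeGrid`, :func:`channels_to_volume`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "ProbeLayout",
    "VolumeGrid",
    "default_probe_layout",
    "default_analysis_grid",
    "fit_head_circle",
    "TEMPLATE_FIDUCIALS",
    "channels_from_optodes",
    "fiducial_transform",
    "register_to_median",
    "channels_to_volume",
    "read_polhemus",
    "write_polhemus",
]

#: Template head-landmark positions (mm, MNI-like RAS).  Used as the fixed
#: target of the per-subject fiducial registration.
TEMPLATE_FIDUCIALS: dict[str, np.ndarray] = {
    "nasion": np.array([0.0, 84.0, -40.0]),
    "inion": np.array([0.0, -110.0, -25.0]),
    "Cz": np.array([0.0, -12.0, 98.0]),
    "T3": np.array([-82.0, -18.0, -12.0]),
    "T4": np.array([82.0, -18.0, -12.0]),
}


@dataclass
class ProbeLayout:
    """Optode montage: emitter/detector positions, channel pairing, fiducials.

    Positions are 3-D scalp coordinates in mm.  ``channel_pairs[i]`` gives
    the (emitter index, detector index) of channel ``i``; channel numbering
    in tables is 1-based (``channel_names``).
    """

    emitters: np.ndarray          # (n_emitters, 3) mm
    detectors: np.ndarray         # (n_detectors, 3) mm
    channel_pairs: np.ndarray     # (n_channels, 2) int: (emitter, detector)
    fiducials: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.emitters = np.asarray(self.emitters, float)
        self.detectors = np.asarray(self.detectors, float)
        self.channel_pairs = np.asarray(self.channel_pairs, int)
        if self.channel_pairs.ndim != 2 or self.channel_pairs.shape[1] != 2:
            raise ValueError("channel_pairs must be (n_channels, 2)")
        if self.channel_pairs[:, 0].max(initial=-1) >= len(self.emitters):
            raise IndexError("channel pair references missing emitter")
        if self.channel_pairs[:, 1].max(initial=-1) >= len(self.detectors):
            raise IndexError("channel pair references missing detector")

    @property
    def n_channels(self) -> int:
        return len(self.channel_pairs)

    @property
    def channel_names(self) -> list[str]:
        return [f"CH{i + 1}" for i in range(self.n_channels)]

    def channel_coordinates(self) -> np.ndarray:
        """Midpoint of each emitter-detector pair, shape (n_channels, 3)."""
        return channels_from_optodes(self)

    def separations(self) -> np.ndarray:
        """Emitter-detector Euclidean distance per channel (mm)."""
        e = self.emitters[self.channel_pairs[:, 0]]
        d = self.detectors[self.channel_pairs[:, 1]]
        return np.linalg.norm(e - d, axis=1)

    def transformed(self, affine: np.ndarray) -> "ProbeLayout":
        """Apply a 4x4 affine to all optode and fiducial positions."""
        A, t = affine[:3, :3], affine[:3, 3]
        return ProbeLayout(
            emitters=self.emitters @ A.T + t,
            detectors=self.detectors @ A.T + t,
            channel_pairs=self.channel_pairs.copy(),
            fiducials={k: A @ v + t for k, v in self.fiducials.items()},
        )


def channels_from_optodes(layout: ProbeLayout) -> np.ndarray:
    """Channel coordinates as emitter-detector midpoints, (n_channels, 3) mm."""
    e = layout.emitters[layout.channel_pairs[:, 0]]
    d = layout.detectors[layout.channel_pairs[:, 1]]
    return 0.5 * (e + d)


def default_probe_layout(
    spacing: float = 30.0,
    head_radius: float = 85.0,
) -> ProbeLayout:
    """Build the default 98-channel montage.

    Thirty emitters and 29 detectors are laid out as a 4-row x 15-column
    checkerboard band wrapped around a head of radius ``head_radius`` mm,
    with one inferior-posterior-left detector position unpopulated.  Nearest
    neighbours at the nominal ``spacing`` (3 cm) form the 98 measurement
    channels, covering frontal, temporal and parietal cortex bilaterally;
    there is no occipital coverage.

    Rows run from ear level upward; columns sweep from the left posterior
    temporal region through the forehead to the right posterior temporal
    region.  Channel numbering is row-major from left to right within a row,
    inferior rows last, so low numbers sit superior-frontal and the highest
    numbers posterior-temporal — mirroring the conventional montage layout
    of frontal/temporal Stroop studies.
    """
    n_rows, n_cols = 4, 15
    dtheta = spacing / head_radius
    removed = (0, 1)  # unpopulated inferior posterior-left detector slot

    # grid node -> scalp position on a cylinder of the head radius
    def node_pos(r: int, c: int) -> np.ndarray:
        theta = (c - (n_cols - 1) / 2) * dtheta  # 0 = anterior midline
        x = head_radius * np.sin(theta)
        y = head_radius * np.cos(theta) - 20.0   # head centre behind AC origin
        z = -10.0 + spacing * r
        return np.array([x, y, z])

    emitters, detectors = [], []
    node_index: dict[tuple[int, int], tuple[str, int]] = {}
    for r in range(n_rows):
        for c in range(n_cols):
            if (r, c) == removed:
                continue
            if (r + c) % 2 == 0:
                node_index[(r, c)] = ("E", len(emitters))
                emitters.append(node_pos(r, c))
            else:
                node_index[(r, c)] = ("D", len(detectors))
                detectors.append(node_pos(r, c))

    # channels: 4-neighbour grid edges (always emitter-detector by parity);
    # order rows top-down so posterior-temporal channels get high numbers
    pairs = []
    for r in range(n_rows - 1, -1, -1):
        for c in range(n_cols):
            for (r2, c2) in ((r, c + 1), (r - 1, c)):
                if (r, c) not in node_index or (r2, c2) not in node_index:
                    continue
                if not (0 <= r2 < n_rows and 0 <= c2 < n_cols):
                    continue
                a, b = node_index[(r, c)], node_index[(r2, c2)]
                if a[0] == "E":
                    pairs.append((a[1], b[1]))
                else:
                    pairs.append((b[1], a[1]))

    return ProbeLayout(
        emitters=np.array(emitters),
        detectors=np.array(detectors),
        channel_pairs=np.array(pairs),
        fiducials={k: v.copy() for k, v in TEMPLATE_FIDUCIALS.items()},
    )


def fiducial_transform(
    subject_fiducials: dict[str, np.ndarray] | np.ndarray,
    template_fiducials: dict[str, np.ndarray] | np.ndarray,
) -> tuple[np.ndarray, float]:
    """Least-squares similarity transform (rotation + isotropic scale +
    translation) mapping subject landmarks onto template landmarks.

    Uses the Umeyama closed-form solution.  Returns the 4x4 affine and the
    RMS landmark residual (mm) after transformation.

    Raises
    ------
    ValueError
        If fewer than 4 landmark pairs are given or the landmarks are
        (near-)coplanar, which leaves the rotation under-determined.
    """
    if isinstance(subject_fiducials, dict):
        keys = sorted(set(subject_fiducials) & set(template_fiducials))
        src = np.array([subject_fiducials[k] for k in keys], float)
        dst = np.array([template_fiducials[k] for k in keys], float)
    else:
        src = np.asarray(subject_fiducials, float)
        dst = np.asarray(template_fiducials, float)
    if src.shape != dst.shape or src.shape[0] < 4:
        raise ValueError("need >=4 matched landmark pairs")

    mu_s, mu_d = src.mean(0), dst.mean(0)
    xs, xd = src - mu_s, dst - mu_d
    # degenerate if source landmarks are coplanar: covariance loses rank
    if np.linalg.matrix_rank(xs, tol=1e-6 * max(1.0, np.abs(xs).max())) < 3:
        raise ValueError("landmarks are coplanar or degenerate; similarity fit is singular")

    cov = xd.T @ xs / len(src)
    U, S, Vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    R = U @ D @ Vt
    var_s = (xs**2).sum() / len(src)
    scale = float(np.trace(np.diag(S) @ D) / var_s)
    t = mu_d - scale * R @ mu_s

    affine = np.eye(4)
    affine[:3, :3] = scale * R
    affine[:3, 3] = t
    resid = src @ (scale * R).T + t - dst
    rms = float(np.sqrt((resid**2).sum(axis=1).mean()))
    return affine, rms


def apply_affine(affine: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Apply a 4x4 affine to an (n, 3) point array."""
    points = np.asarray(points, float)
    return points @ affine[:3, :3].T + affine[:3, 3]


def register_to_median(
    coords_per_subject: np.ndarray,
    values_per_subject: np.ndarray,
    k: int = 4,
) -> tuple[np.ndarray, np.ndarray]:
    """Align per-subject channel values onto the group-median channel grid.

    The group coordinate of each channel is the component-wise median of
    that channel's position across subjects.  Each subject's values are then
    interpolated at those median coordinates by inverse-squared-distance
    (Shepard) weighting over the subject's ``k`` nearest channels (a channel
    exactly at the target coordinate wins outright).

    Parameters
    ----------
    coords_per_subject : (n_subjects, n_channels, 3) array, mm
    values_per_subject : (n_subjects, n_channels) array
    k : nearest-channel count for the inverse-distance weights

    Returns
    -------
    aligned : (n_subjects, n_channels) interpolated values
    median_coords : (n_channels, 3) group-median coordinates
    """
    coords = np.asarray(coords_per_subject, float)
    values = np.asarray(values_per_subject, float)
    n_subj, n_chan, _ = coords.shape
    if values.shape != (n_subj, n_chan):
        raise ValueError("values_per_subject shape mismatch")
    if n_chan < k:
        raise ValueError(f"subjects must have >= k={k} usable channels")

    median_coords = np.median(coords, axis=0)
    aligned = np.empty_like(values)
    for s in range(n_subj):
        tree = cKDTree(coords[s])
        dist, idx = tree.query(median_coords, k=k)
        dist = np.atleast_2d(dist)
        idx = np.atleast_2d(idx)
        exact = dist[:, 0] < 1e-12
        with np.errstate(divide="ignore"):
            w = 1.0 / dist**2
        w[exact] = 0.0
        w[exact, 0] = 1.0
        aligned[s] = (w * values[s, idx]).sum(axis=1) / w.sum(axis=1)
    return aligned, median_coords


def fit_head_circle(points: np.ndarray) -> tuple[float, float, float]:
    """Least-squares (Kasa) circle fit to the x-y footprint of scalp points.

    fNIRS optodes sit on the scalp; their axial (x, y) footprint is close
    to circular.  Returns (cx, cy, radius) of the fitted scalp circle, used
    to define cortical depth below the scalp surface.
    """
    pts = np.asarray(points, float)
    x, y = pts[:, 0], pts[:, 1]
    A = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    b = x**2 + y**2
    (cx, cy, c), *_ = np.linalg.lstsq(A, b, rcond=None)
    return float(cx), float(cy), float(np.sqrt(c + cx**2 + cy**2))


@dataclass
class VolumeGrid:
    """Regular voxel grid in MNI mm with a brain/channel-support mask.

    The mask keeps voxels within ``max_support_distance`` of at least one
    channel — the superficial sensitivity of scalp fNIRS — optionally
    intersected with a cortical-depth shell below the scalp surface (the
    brain-mask part: fNIRS does not sample the scalp itself or anything
    deeper than a few centimetres).
    """

    origin: np.ndarray            # (3,) mm, centre of voxel [0,0,0]
    voxel_size: float             # mm, isotropic
    shape: tuple[int, int, int]
    mask: np.ndarray              # boolean, self.shape

    @classmethod
    def around_channels(
        cls,
        channel_coords: np.ndarray,
        voxel_size: float = 4.0,
        max_support_distance: float = 20.0,
        head_circle: tuple[float, float, float] | None = None,
        cortical_depth: tuple[float, float] = (5.0, 25.0),
    ) -> "VolumeGrid":
        """Grid covering the montage plus a support margin.

        Default 4 mm isotropic voxels masked to within 20 mm of any
        channel.  If ``head_circle`` (cx, cy, scalp radius; see
        :func:`fit_head_circle`) is given, the mask is additionally
        restricted to voxels whose depth below the scalp surface lies in
        ``cortical_depth`` (mm), approximating the cortical shell fNIRS
        is sensitive to.
        """
        coords = np.asarray(channel_coords, float)
        lo = np.floor((coords.min(0) - max_support_distance) / voxel_size) * voxel_size
        hi = coords.max(0) + max_support_distance
        shape = tuple(int(np.ceil((h - l) / voxel_size)) + 1 for l, h in zip(lo, hi))
        grid = cls(origin=lo, voxel_size=voxel_size, shape=shape,
                   mask=np.ones(shape, bool))
        centers = grid.voxel_centers()
        dist, _ = cKDTree(coords).query(centers)
        mask = dist <= max_support_distance
        if head_circle is not None:
            cx, cy, radius = head_circle
            depth = radius - np.hypot(centers[:, 0] - cx, centers[:, 1] - cy)
            mask &= (depth >= cortical_depth[0]) & (depth <= cortical_depth[1])
        grid.mask = mask.reshape(shape)
        return grid

    def voxel_centers(self) -> np.ndarray:
        """World coordinates of every voxel centre, (n_voxels, 3) mm."""
        axes = [self.origin[i] + self.voxel_size * np.arange(self.shape[i])
                for i in range(3)]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    def masked_centers(self) -> np.ndarray:
        return self.voxel_centers()[self.mask.ravel()]

    @property
    def n_masked(self) -> int:
        return int(self.mask.sum())

    def embed(self, masked_values: np.ndarray, fill: float = np.nan) -> np.ndarray:
        """Scatter a masked-voxel vector back into the full 3-D array."""
        vol = np.full(self.shape, fill, float)
        vol[self.mask] = masked_values
        return vol


def interpolation_weights(
    channel_coords: np.ndarray,
    grid: VolumeGrid,
    kernel_fwhm: float = 15.0,
) -> np.ndarray:
    """Normalized Gaussian-kernel weights from channels to masked voxels.

    Returns a dense (n_masked_voxels, n_channels) matrix whose rows sum
    to 1, so interpolation is a weighted average (a partition of unity:
    constant channel values map to the same constant everywhere).
    """
    if grid.n_masked == 0:
        raise ValueError("grid mask is empty")
    centers = grid.masked_centers()
    coords = np.asarray(channel_coords, float)
    d2 = ((centers[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
    if kernel_fwhm <= 0:
        # nearest-channel limit
        W = np.zeros_like(d2)
        W[np.arange(len(d2)), d2.argmin(1)] = 1.0
        return W
    sigma = kernel_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    W = np.exp(-0.5 * d2 / sigma**2)
    norm = W.sum(1, keepdims=True)
    if np.any(norm == 0):
        raise ValueError("masked voxel with empty kernel support; "
                         "increase kernel_fwhm or shrink the mask")
    return W / norm


def channels_to_volume(
    channel_values: np.ndarray,
    channel_coords: np.ndarray,
    grid: VolumeGrid,
    kernel_fwhm: float = 15.0,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Interpolate channel values onto the grid's masked voxels.

    ``channel_values`` may be (n_channels,) or (n_subjects, n_channels);
    the result is the matching (n_masked,) or (n_subjects, n_masked) array.
    Precomputed ``weights`` from :func:`interpolation_weights` can be passed
    to amortize the kernel evaluation across many maps.
    """
    if weights is None:
        weights = interpolation_weights(channel_coords, grid, kernel_fwhm)
    values = np.asarray(channel_values, float)
    return values @ weights.T


def default_analysis_grid(
    layout: ProbeLayout,
    voxel_size: float = 4.0,
    max_support_distance: float = 20.0,
    cortical_depth: tuple[float, float] = (5.0, 25.0),
) -> VolumeGrid:
    """The default group-analysis grid for a montage.

    4 mm isotropic voxels, masked to the cortical shell 5-25 mm below the
    scalp surface (circle fitted to the optode footprint) and within 20 mm
    of at least one channel.
    """
    optodes = np.vstack([layout.emitters, layout.detectors])
    return VolumeGrid.around_channels(
        layout.channel_coordinates(),
        voxel_size=voxel_size,
        max_support_distance=max_support_distance,
        head_circle=fit_head_circle(optodes),
        cortical_depth=cortical_depth,
    )


# ---------------------------------------------------------------------------
# Polhemus-style digitizer text I/O: one "label x y z" line per point (mm).

def read_polhemus(path) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Read a digitizer file; returns (fiducials, optode table).

    Labels matching the standard landmarks (nasion/inion/Cz/T3/T4, case
    insensitive) are returned as fiducials; all other rows as a DataFrame
    with columns label/x/y/z.
    """
    fid_names = {k.lower(): k for k in TEMPLATE_FIDUCIALS}
    fiducials: dict[str, np.ndarray] = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            parts = line.replace(":", " ").replace(",", " ").split()
            if len(parts) < 4:
                continue
            label, xyz = parts[0], np.array([float(v) for v in parts[1:4]])
            if label.lower() in fid_names:
                fiducials[fid_names[label.lower()]] = xyz
            else:
                rows.append({"label": label, "x": xyz[0], "y": xyz[1], "z": xyz[2]})
    return fiducials, pd.DataFrame(rows)


def write_polhemus(path, fiducials: dict[str, np.ndarray],
                   optodes: pd.DataFrame | None = None) -> None:
    with open(path, "w") as fh:
        for label, xyz in fiducials.items():
            fh.write(f"{label} {xyz[0]:.3f} {xyz[1]:.3f} {xyz[2]:.3f}\n")
        if optodes is not None:
            for _, row in optodes.iterrows():
                fh.write(f"{row['label']} {row['x']:.3f} {row['y']:.3f} {row['z']:.3f}\n")
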