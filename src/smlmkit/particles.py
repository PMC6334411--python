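"""Feature-based, template-free particle averaging.

Many copies of the same nanoscale structure (e.g. DNA double-strand-break
repair foci), each captured in its own ROI, are brought into a common frame
without a template and without iterative all-to-all registration.  Each
particle is aligned on a reference channel in three steps:

1. **center** — translate the reference channel's center of mass to the
   origin;
2. **rotate** — turn the major principal axis of the reference-channel
   coordinate covariance onto the x-axis;
3. **orient** — if the heavier half (localization count, or photon sum when
   photon counts exist) lies at x > 0, mirror about the y-axis so the
   highest-intensity side ends up on the left.

The per-particle rigid transform is then applied to *all* channels, and the
aligned particles are merged (concatenated localizations) and/or averaged
as rendered images, revealing features common across the population.

The remaining up/down mirror ambiguity (reflection about the x-axis) is not
resolved by default; pass ``resolve_top=True`` to also force the heavier
half below the axis.  Particles with elongation below 1.1 have a noise-
dominated major axis and are flagged orientation-unreliable but still
processed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from smlmkit.io import LocalizationTable, ROICollection, LocalizationError
from smlmkit.render import ImageGeometry, RenderedImage, render_gaussian, render_kde

#: below this major/minor spread ratio the principal axis is noise-dominated
ELONGATION_RELIABLE = 1.1


class AlignmentError(ValueError):
    """Raised when a particle cannot be aligned (degenerate reference channel)."""


@dataclass
class RigidTransform:
    """Rigid-body transform: translate, then rotate about the origin, then
    optionally reflect about the y-axis (x → −x).

    All pairwise distances are preserved (reflection included), so the
    transform is an isometry of the plane.
    """

    dx: float = 0.0
    dy: float = 0.0
    theta: float = 0.0
    flip_x: bool = False
    orientation_reliable: bool = True

    def apply_xy(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        xt = np.asarray(x, float) + self.dx
        yt = np.asarray(y, float) + self.dy
        c, s = np.cos(self.theta), np.sin(self.theta)
        xr = c * xt - s * yt
        yr = s * xt + c * yt
        if self.flip_x:
            xr = -xr
        return xr, yr


def apply_transform(table: LocalizationTable, t: RigidTransform) -> LocalizationTable:
    """Apply a rigid transform to the coordinates; all other fields untouched."""
    x, y = t.apply_xy(table.x, table.y)
    return table.with_xy(x, y)


def compute_alignment(
    table: LocalizationTable,
    reference_channel: int = 1,
    *,
    resolve_top: bool = False,
) -> RigidTransform:
    """Alignment transform that brings the reference channel into canonical pose.

    After applying the result, the reference channel's centroid is at the
    origin, its major covariance axis lies along x, and its heavier side
    (by localization count, or photon sum when available) is at x < 0.

    Raises
    ------
    AlignmentError
        If the reference channel has fewer than 2 localizations or all its
        points coincide (no orientation can be defined).
    """
    ref = table.select(table.channel == reference_channel)
    if len(ref) < 2:
        raise AlignmentError(
            f"reference channel {reference_channel} has {len(ref)} localization(s); "
            "need at least 2"
        )
    xy = ref.xy
    centroid = xy.mean(axis=0)
    centered = xy - centroid
    cov = np.cov(centered, rowvar=False, bias=True)
    evals, evecs = np.linalg.eigh(cov)
    sd_minor, sd_major = np.sqrt(np.maximum(evals, 0.0))
    scale = float(np.abs(centered).max())
    if sd_major <= 1e-9 * max(scale, 1.0):
        raise AlignmentError(
            f"reference channel {reference_channel}: all points coincide, "
            "orientation undefined"
        )
    vx, vy = evecs[:, 1]
    if vx < 0 or (vx == 0 and vy < 0):
        vx, vy = -vx, -vy  # eigenvector sign is arbitrary; fix it so theta in (-pi/2, pi/2]
    theta = -float(np.arctan2(vy, vx))

    weights = ref.photons if ref.photons is not None else np.ones(len(ref))

    def heavier_positive(vals: np.ndarray) -> bool:
        # mass balance across the axis; exact ties (possible with unit
        # weights and an even count) fall back to the continuous third
        # moment, which is odd under mirroring and generically nonzero
        diff = weights[vals > 0].sum() - weights[vals < 0].sum()
        if diff == 0:
            diff = float(np.sum(weights * vals**3))
        return bool(diff > 0)

    c, s = np.cos(theta), np.sin(theta)
    x_rot = c * centered[:, 0] - s * centered[:, 1]
    flip = heavier_positive(x_rot)

    t = RigidTransform(
        dx=-float(centroid[0]),
        dy=-float(centroid[1]),
        theta=theta,
        flip_x=flip,
        orientation_reliable=bool(sd_minor == 0 or sd_major / max(sd_minor, 1e-300) >= ELONGATION_RELIABLE),
    )
    if resolve_top:
        y_rot = s * centered[:, 0] + c * centered[:, 1]
        if heavier_positive(y_rot):
            # fold the heavy half below the axis: rotate by pi and re-flip
            t = RigidTransform(t.dx, t.dy, t.theta + np.pi, not t.flip_x,
                               t.orientation_reliable)
            # pi-rotation also swaps left/right; the extra flip restores it
    return t


@dataclass
class AlignedParticleSet:
    """Result of :func:`average_particles`.

    ``particles[i]`` is the i-th usable ROI table after its transform;
    ``merged`` concatenates them with a ``particle`` column (1-based index
    into the *input* ROI list); ``skipped`` records (input index, reason)
    for particles that failed alignment.
    """

    particles: list[LocalizationTable]
    transforms: list[RigidTransform]
    merged: LocalizationTable
    mean_image: RenderedImage | None = None
    skipped: list[tuple[int, str]] = field(default_factory=list)


def average_particles(
    rois: ROICollection,
    reference_channel: int = 1,
    geometry: ImageGeometry | None = None,
    render_mode: str = "merged_render",
    renderer: str = "gaussian",
    resolve_top: bool = False,
) -> AlignedParticleSet:
    """Align every ROI on its reference channel and merge/average.

    Each particle's transform is estimated from its reference channel alone
    and applied to all channels, so the relative geometry between channels
    is preserved.  With a geometry (which should be centered on the origin,
    where aligned particles land), an average image is produced either as a
    render of the merged localizations (``merged_render``) or as the
    pixel-wise mean of per-particle renders (``mean_of_renders``).
    Particles whose reference channel is degenerate are skipped and listed
    in ``skipped``.
    """
    if render_mode not in ("merged_render", "mean_of_renders"):
        raise ValueError(f"unknown render_mode: {render_mode!r}")
    if renderer not in ("gaussian", "kde"):
        raise ValueError(f"unknown renderer: {renderer!r}")

    aligned: list[LocalizationTable] = []
    transforms: list[RigidTransform] = []
    skipped: list[tuple[int, str]] = []
    merged_frames = []
    for idx, (_, table) in enumerate(rois):
        try:
            t = compute_alignment(table, reference_channel, resolve_top=resolve_top)
        except AlignmentError as e:
            skipped.append((idx, str(e)))
            continue
        moved = apply_transform(table, t)
        aligned.append(moved)
        transforms.append(t)
        df = moved.df.copy()
        df["particle"] = idx + 1
        merged_frames.append(df)

    if not aligned:
        raise LocalizationError("no particle could be aligned")

    import pandas as pd

    merged_df = pd.concat(merged_frames, ignore_index=True)
    merged_df["id"] = np.arange(len(merged_df))
    merged = LocalizationTable(merged_df, validate=False)

    mean_image = None
    if geometry is not None:
        render = render_gaussian if renderer == "gaussian" else render_kde
        if render_mode == "merged_render":
            mean_image = render(merged, geometry)
        else:
            acc = np.zeros(geometry.shape)
            for part in aligned:
                acc += render(part, geometry).pixels
            acc /= len(aligned)
            mean_image = RenderedImage(geometry, acc, mode=renderer)
    return AlignedParticleSet(
        particles=aligned,
        transforms=transforms,
        merged=merged,
        mean_image=mean_image,
        skipped=skipped,
    )
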