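"""Ground-truthed synthetic localization data.

Two generators drive the test and benchmark machinery:

* a cluster benchmark — six isolated circular (isotropic Gaussian) clusters
  of 50 localizations, one 100-localization component made of two
  overlapping sub-clusters, and 300 uniformly distributed noise
  localizations (700 rows total under the defaults) — with per-row ground
  truth for the clustering performance metrics;
* asymmetric elongated particles under recorded random rigid motions, for
  testing alignment recovery in particle averaging.

Geometry defaults emulate dSTORM-scale data: a 3 µm field, 25 nm cluster
spread, 60 nm overlap offset and lognormal precisions with 10 nm median.
Every generator is a pure function of its configuration and seed, so
replays are bit-identical.  Blinking kinetics, drift, multi-frame emitters
and camera noise are not simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from smlmkit.io import LocalizationTable, RectROI, ROICollection
from smlmkit.particles import RigidTransform


class PlacementError(RuntimeError):
    """Cluster centers could not be placed at the required separation."""


def apply_motion(
    x: np.ndarray, y: np.ndarray, motion: RigidTransform
) -> tuple[np.ndarray, np.ndarray]:
    """Apply a recorded particle motion to canonical-frame coordinates.

    Motions recorded by :func:`make_elongated_particles` compose in the
    order mirror (x → −x), rotate by ``theta``, translate by ``(dx, dy)`` —
    the order in which the generator perturbs a canonical particle.  (Note
    this differs from :func:`smlmkit.particles.apply_transform`, whose
    alignment transforms translate first.)
    """
    xs = -np.asarray(x, float) if motion.flip_x else np.asarray(x, float)
    ys = np.asarray(y, float)
    c, s = np.cos(motion.theta), np.sin(motion.theta)
    return c * xs - s * ys + motion.dx, s * xs + c * ys + motion.dy


@dataclass
class GroundTruth:
    """Per-localization true component labels.

    ``component`` is 0 for noise and a positive component id otherwise;
    ``component_kind`` is one of ``noise``, ``cluster``, ``overlap_pair``,
    ``particle`` per row.
    """

    component: np.ndarray
    component_kind: np.ndarray

    def __post_init__(self) -> None:
        self.component = np.asarray(self.component, dtype=np.int64)
        self.component_kind = np.asarray(self.component_kind, dtype=object)
        if len(self.component) != len(self.component_kind):
            raise ValueError("component and component_kind must align")

    def __len__(self) -> int:
        return len(self.component)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": np.arange(len(self.component)),
                "component": self.component,
                "component_kind": self.component_kind,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GroundTruth":
        return cls(df["component"].to_numpy(), df["component_kind"].to_numpy())


@dataclass
class S2Config:
    """Configuration of the cluster benchmark.

    Defaults reproduce the benchmark composition: 6 isolated clusters of
    50 localizations, one overlapping pair totalling 100, and 300 uniform
    noise localizations.  Spatial scales (3000 nm field, 25 nm cluster
    spread, 60 nm overlap offset, 400 nm center separation) and the
    precision distribution (lognormal, 10 nm median, 0.3 log-sd) are this
    package's declared dSTORM-typical choices.
    """

    field_size: float = 3000.0
    n_isolated_clusters: int = 6
    n_per_cluster: int = 50
    cluster_sd: float = 25.0
    n_overlap_total: int = 100
    overlap_offset: float = 60.0
    n_noise: int = 300
    min_center_separation: float = 400.0
    precision_median: float = 10.0
    precision_sigma_log: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_isolated_clusters", "n_per_cluster", "n_overlap_total", "n_noise"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.overlap_offset < 4 * self.cluster_sd:
            raise ValueError("overlap_offset must be < 4*cluster_sd so the pair overlaps")


def _rng(rng: np.random.Generator | int | None) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def _precisions(n: int, median: float, sigma_log: float, rng: np.random.Generator) -> np.ndarray:
    return np.exp(rng.normal(np.log(median), sigma_log, size=n))


def sample_cluster(
    n: int,
    center: tuple[float, float],
    sd: float,
    rng: np.random.Generator | int | None = None,
    *,
    precision_median: float = 10.0,
    precision_sigma_log: float = 0.3,
    channel: int = 1,
    disc: bool = False,
) -> LocalizationTable:
    """Sample an isotropic cluster of ``n`` localizations.

    By default points follow an isotropic bivariate normal with standard
    deviation ``sd`` per axis; with ``disc=True`` they are instead uniform
    on a disc of radius ``2·sd``.  Precisions are lognormal.
    """
    if sd <= 0:
        raise ValueError("sd must be > 0")
    rng = _rng(rng)
    if disc:
        r = 2.0 * sd * np.sqrt(rng.uniform(size=n))
        phi = rng.uniform(0, 2 * np.pi, size=n)
        x = center[0] + r * np.cos(phi)
        y = center[1] + r * np.sin(phi)
    else:
        x = rng.normal(center[0], sd, size=n)
        y = rng.normal(center[1], sd, size=n)
    prec = _precisions(n, precision_median, precision_sigma_log, rng)
    return LocalizationTable.from_arrays(x, y, prec, channel=channel)


def sample_uniform_noise(
    n: int,
    field_size: float,
    rng: np.random.Generator | int | None = None,
    *,
    precision_median: float = 10.0,
    precision_sigma_log: float = 0.3,
    channel: int = 1,
) -> LocalizationTable:
    """``n`` i.i.d. uniform localizations in the square [0, field_size)²."""
    rng = _rng(rng)
    x = rng.uniform(0.0, field_size, size=n)
    y = rng.uniform(0.0, field_size, size=n)
    prec = _precisions(n, precision_median, precision_sigma_log, rng)
    return LocalizationTable.from_arrays(x, y, prec, channel=channel)


def _place_centers(
    n: int, field_size: float, min_sep: float, margin: float, rng: np.random.Generator
) -> np.ndarray:
    """Rejection-sample ``n`` centers pairwise >= min_sep apart, inside margins."""
    lo, hi = margin, field_size - margin
    if hi <= lo:
        raise PlacementError(
            f"field_size {field_size} too small for margin {margin}; enlarge the field"
        )
    centers: list[np.ndarray] = []
    for _ in range(n):
        for _attempt in range(10_000):
            c = rng.uniform(lo, hi, size=2)
            if all(np.hypot(*(c - p)) >= min_sep for p in centers):
                centers.append(c)
                break
        else:
            raise PlacementError(
                f"could not place {n} centers {min_sep} nm apart in a "
                f"{field_size} nm field; enlarge the field or relax the separation"
            )
    return np.array(centers)


def make_s2_testset(
    config: S2Config | None = None,
    rng: np.random.Generator | int | None = None,
) -> tuple[LocalizationTable, GroundTruth]:
    """Generate the cluster benchmark with per-row ground truth.

    Component labels: 1..n_isolated for the isolated clusters, the next id
    (7 under defaults) for the whole overlapping pair, 0 for noise.  Rows
    are emitted clusters-first, then the pair, then noise; component counts
    equal the configuration exactly.
    """
    config = config or S2Config()
    rng = _rng(config.seed if rng is None else rng)

    margin = 4 * config.cluster_sd + config.overlap_offset
    n_centers = config.n_isolated_clusters + 1
    centers = _place_centers(
        n_centers, config.field_size, config.min_center_separation, margin, rng
    )

    prec_kw = dict(
        precision_median=config.precision_median,
        precision_sigma_log=config.precision_sigma_log,
    )
    parts: list[LocalizationTable] = []
    comp: list[np.ndarray] = []
    kind: list[np.ndarray] = []
    for k in range(config.n_isolated_clusters):
        t = sample_cluster(
            config.n_per_cluster, tuple(centers[k]), config.cluster_sd, rng, **prec_kw
        )
        parts.append(t)
        comp.append(np.full(len(t), k + 1))
        kind.append(np.full(len(t), "cluster", dtype=object))

    # overlapping pair: two sub-clusters of half the total, centers
    # overlap_offset apart in a random direction, one shared component id
    pair_id = config.n_isolated_clusters + 1
    phi = rng.uniform(0, 2 * np.pi)
    offset = 0.5 * config.overlap_offset * np.array([np.cos(phi), np.sin(phi)])
    n_a = config.n_overlap_total // 2
    n_b = config.n_overlap_total - n_a
    for n_sub, sign in ((n_a, +1), (n_b, -1)):
        t = sample_cluster(
            n_sub, tuple(centers[-1] + sign * offset), config.cluster_sd, rng, **prec_kw
        )
        parts.append(t)
        comp.append(np.full(len(t), pair_id))
        kind.append(np.full(len(t), "overlap_pair", dtype=object))

    noise = sample_uniform_noise(config.n_noise, config.field_size, rng, **prec_kw)
    parts.append(noise)
    comp.append(np.zeros(len(noise)))
    kind.append(np.full(len(noise), "noise", dtype=object))

    df = pd.concat([p.df for p in parts], ignore_index=True)
    df["id"] = np.arange(len(df))
    table = LocalizationTable(df, validate=False)
    truth = GroundTruth(np.concatenate(comp), np.concatenate(kind))
    return table, truth


def make_elongated_particles(
    k: int = 50,
    n_per: int = 300,
    length_sd: float = 100.0,
    width_sd: float = 30.0,
    left_fraction: float = 0.7,
    field_size: float = 2000.0,
    rng: np.random.Generator | int | None = None,
    *,
    precision_median: float = 10.0,
    precision_sigma_log: float = 0.3,
    mirror_probability: float = 0.5,
) -> tuple[ROICollection, GroundTruth, list[RigidTransform]]:
    """Asymmetric elongated particles under recorded random rigid motions.

    Each particle is built in a canonical frame: an anisotropic Gaussian
    with axis standard deviations (length_sd, width_sd) along (x, y), in
    which exactly ``round(left_fraction·n_per)`` points sit at x < 0 (the
    heavy, "high intensity" side).  The canonical points are then rotated
    by a uniform random angle, mirrored with probability
    ``mirror_probability``, and translated to the center of the particle's
    own ROI (a square of side ``field_size``); the motion applied to each
    particle is recorded and returned so alignment recovery can be tested
    against it.

    Returns
    -------
    (ROICollection, GroundTruth, list[RigidTransform])
        One ROI + table per particle (tables in ROI-local coordinates),
        per-row truth with ``component`` = particle id (1-based), and the
        recorded canonical→ROI motions (``flip_x`` applied before the
        rotation/translation, mirroring the canonical particle).
    """
    if not (0.5 <= left_fraction <= 1.0):
        raise ValueError("left_fraction must be in [0.5, 1]")
    if length_sd <= width_sd:
        raise ValueError("length_sd must exceed width_sd (elongated particle)")
    rng = _rng(rng)

    rois: list[RectROI] = []
    tables: list[LocalizationTable] = []
    motions: list[RigidTransform] = []
    comp: list[np.ndarray] = []
    n_left = int(round(left_fraction * n_per))

    # Two-sided half-normal along x: exactly n_left points on the negative
    # side with scale a, the rest positive with scale b = (f/(1-f))·a.  The
    # scales are chosen so the population mean is 0 (the canonical particle
    # is centered) and the overall x standard deviation equals length_sd.
    f = left_fraction
    if f >= 1.0:
        scale_left, scale_right = length_sd, length_sd
    else:
        scale_left = length_sd * np.sqrt((1.0 - f) / f)
        scale_right = length_sd * np.sqrt(f / (1.0 - f))

    for p in range(k):
        mag = np.abs(rng.normal(0.0, 1.0, size=n_per))
        x_can = np.concatenate(
            [-scale_left * mag[:n_left], scale_right * mag[n_left:]]
        )
        y_can = rng.normal(0.0, width_sd, size=n_per)

        theta = rng.uniform(0.0, 2.0 * np.pi)
        flip = bool(rng.uniform() < mirror_probability)
        jitter = rng.uniform(-0.05 * field_size, 0.05 * field_size, size=2)
        tx, ty = field_size / 2 + jitter[0], field_size / 2 + jitter[1]

        motion = RigidTransform(dx=tx, dy=ty, theta=theta, flip_x=flip)
        x, y = apply_motion(x_can, y_can, motion)

        prec = _precisions(n_per, precision_median, precision_sigma_log, rng)
        tables.append(LocalizationTable.from_arrays(x, y, prec))
        rois.append(
            RectROI(
                f"particle_{p + 1:03d}",
                x_min=p * field_size,
                y_min=0.0,
                x_max=(p + 1) * field_size,
                y_max=field_size,
            )
        )
        motions.append(motion)
        comp.append(np.full(n_per, p + 1))

    truth = GroundTruth(
        np.concatenate(comp) if comp else np.array([], dtype=np.int64),
        np.full(k * n_per, "particle", dtype=object),
    )
    return ROICollection(rois=rois, tables=tables), truth, motions
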