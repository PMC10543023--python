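"""Across-patient spatial methods.

Inverse-distance interpolation of per-channel values onto a common grid of
points in a standard (MNI-style) space, estimation of a connectomic
decoding network map (R-map) by voxel-wise correlation of connectivity
fingerprints with decoding performance, fingerprint-based channel
selection, and leave-one-out validation of the fitted map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd
import scipy.stats

__all__ = [
    "GridSpec",
    "VoxelVolume",
    "ChannelPerformanceRecord",
    "default_sensorimotor_grid",
    "project_to_grid",
    "fit_decoding_network_map",
    "select_channel_by_fingerprint",
    "leave_one_out_map_validation",
]


@dataclass
class GridSpec:
    """A common-space point grid with a channel-inclusion radius.

    ``points`` is (n, 3) in millimetres; channels farther than
    ``max_dist_mm`` from a grid point never contribute to it.
    """

    points: np.ndarray
    max_dist_mm: float = 20.0

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if self.max_dist_mm <= 0:
            raise ValueError("max_dist_mm must be positive")
        if len(np.unique(self.points, axis=0)) != len(self.points):
            raise ValueError("grid points must be distinct")


def default_sensorimotor_grid(max_dist_mm: float = 20.0) -> GridSpec:
    """A synthetic 38-point lattice over a bilateral sensorimotor bounding
    box (19 points per hemisphere along the precentral strip). The true
    cortical grid geometry is study-specific and user-supplied; this
    default only fixes a plausible test geometry.
    """
    ys = np.linspace(-40.0, 10.0, 19)
    points = []
    for x_sign in (-1.0, 1.0):
        for y in ys:
            # crude arc: lateral at central sulcus, higher toward midline
            points.append([x_sign * 40.0, y, 45.0 + 0.35 * (y + 15.0)])
    return GridSpec(points=np.array(points), max_dist_mm=max_dist_mm)


def project_to_grid(
    channel_values: np.ndarray,
    channel_locs: np.ndarray,
    grid: GridSpec,
) -> np.ndarray:
    """Inverse-distance interpolation of channel values onto grid points.

    ``x_grid[n] = sum_m x_m / d(n, m) / sum_m 1 / d(n, m)`` over channels
    with ``d <= max_dist_mm``; points with no channel in range are NaN. A
    channel exactly at a grid point returns its value exactly (limit
    convention). Linear in the channel values and invariant to channel
    permutation.
    """
    values = np.asarray(channel_values, dtype=float)
    locs = np.asarray(channel_locs, dtype=float).reshape(-1, 3)
    if values.shape[0] != locs.shape[0]:
        raise ValueError("one location per channel value required")
    dists = np.linalg.norm(grid.points[:, None, :] - locs[None, :, :], axis=2)
    out = np.full(len(grid.points), np.nan)
    for n in range(len(grid.points)):
        d = dists[n]
        sel = d <= grid.max_dist_mm
        if not sel.any():
            continue
        if (d[sel] == 0).any():
            out[n] = values[sel][d[sel] == 0][0]
            continue
        w = 1.0 / d[sel]
        out[n] = float(np.sum(values[sel] * w) / np.sum(w))
    return out


# ---------------------------------------------------------------------------


@dataclass
class VoxelVolume:
    """A scalar 3-D volume with a voxel-to-mm affine and optional mask."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine must be invertible")

    def valid(self) -> np.ndarray:
        v = np.isfinite(self.data)
        if self.mask is not None:
            v &= self.mask.astype(bool)
        return v

    @classmethod
    def from_nifti(cls, path: str) -> "VoxelVolume":
        img = nib.load(path)
        return cls(data=np.asarray(img.get_fdata()), affine=img.affine)

    def to_nifti(self, path: str) -> None:
        nib.save(nib.Nifti1Image(self.data.astype(np.float64), self.affine), path)


@dataclass
class ChannelPerformanceRecord:
    """One channel's location, decoding performance and connectivity
    fingerprint; ``subject`` groups channels for subject-level validation."""

    name: str
    location_mm: np.ndarray | None = None
    performance: float | None = None
    fingerprint: VoxelVolume | None = None
    subject: str | None = None


def _check_geometry(records: list[ChannelPerformanceRecord]) -> None:
    ref = records[0].fingerprint
    for rec in records[1:]:
        fp = rec.fingerprint
        if fp.data.shape != ref.data.shape or not np.allclose(fp.affine, ref.affine):
            raise ValueError("fingerprint volumes must share shape and affine")


def fit_decoding_network_map(
    records: list[ChannelPerformanceRecord],
    method: str = "spearman",
) -> VoxelVolume:
    """Correlate fingerprints with performance voxel-wise -> R-map.

    Each voxel valid in every fingerprint holds the correlation (Spearman
    by default, Pearson via ``method``) across records between the
    fingerprint value and the channel's decoding performance. Voxels with
    zero variance across records — and every voxel when performances are
    all identical — are NaN.
    """
    if len(records) < 3:
        raise ValueError("need at least 3 records to fit a network map")
    _check_geometry(records)
    fps = np.stack([r.fingerprint.data for r in records])  # (R, *shape)
    perf = np.array([r.performance for r in records], dtype=float)
    valid = np.all([r.fingerprint.valid() for r in records], axis=0)
    flat = fps.reshape(len(records), -1)
    if method == "spearman":
        flat = scipy.stats.rankdata(flat, axis=0)
        perf = scipy.stats.rankdata(perf)
    elif method != "pearson":
        raise ValueError(f"unknown correlation method {method!r}")
    perf_c = perf - perf.mean()
    flat_c = flat - flat.mean(axis=0)
    denom = np.sqrt((flat_c**2).sum(axis=0) * (perf_c**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (flat_c * perf_c[:, None]).sum(axis=0) / denom
    r[denom == 0] = np.nan
    rmap = r.reshape(fps.shape[1:])
    rmap[~valid] = np.nan
    return VoxelVolume(
        data=rmap, affine=records[0].fingerprint.affine.copy(), mask=valid
    )


def _similarity(template: VoxelVolume, fp: VoxelVolume, method: str) -> float:
    joint = template.valid() & fp.valid()
    if joint.sum() < 2:
        raise ValueError("no jointly valid voxels")
    a, b = template.data[joint], fp.data[joint]
    if method == "spearman":
        rho = scipy.stats.spearmanr(a, b).statistic
    else:
        rho = scipy.stats.pearsonr(a, b).statistic
    return float(rho)


def select_channel_by_fingerprint(
    template: VoxelVolume,
    candidates: list[ChannelPerformanceRecord],
    method: str = "spearman",
) -> tuple[ChannelPerformanceRecord, dict[str, float]]:
    """Pick the candidate whose fingerprint is most similar to the map.

    Similarity is the spatial correlation over jointly valid voxels; ties
    resolve to the earliest candidate with a warning. Returns the chosen
    record and all similarity scores.
    """
    if template.valid().sum() < 2:
        raise ValueError("template needs at least 2 valid voxels")
    scores = {
        c.name: _similarity(template, c.fingerprint, method) for c in candidates
    }
    best = max(scores.values())
    winners = [c for c in candidates if scores[c.name] == best]
    if len(winners) > 1:
        warnings.warn(
            f"similarity tie between {[c.name for c in winners]}; "
            "keeping channel order",
            stacklevel=2,
        )
    return winners[0], scores


def leave_one_out_map_validation(
    records: list[ChannelPerformanceRecord],
    unit: str = "channel",
    method: str = "spearman",
) -> pd.DataFrame:
    """Leave-one-channel/subject-out validation of the network map.

    For each held-out unit the template is fitted on the remaining
    records only; the held-out channels' predicted performance is their
    fingerprint similarity to that template. Returns a frame of
    (unit, channel, predicted, actual) pairs with the pooled Spearman
    correlation in ``frame.attrs['rho']``.
    """
    if unit == "channel":
        groups = {r.name: [r] for r in records}
    elif unit == "subject":
        if any(r.subject is None for r in records):
            raise ValueError("subject labels required for unit='subject'")
        groups = {}
        for r in records:
            groups.setdefault(r.subject, []).append(r)
    else:
        raise ValueError(f"unknown unit {unit!r}")
    if len(groups) < 4:
        raise ValueError("need at least 4 units for leave-one-out validation")
    rows = []
    for key, held in groups.items():
        held_set = set(id(r) for r in held)
        train = [r for r in records if id(r) not in held_set]
        template = fit_decoding_network_map(train, method=method)
        for r in held:
            rows.append(
                {
                    "unit": key,
                    "channel": r.name,
                    "predicted": _similarity(template, r.fingerprint, method),
                    "actual": r.performance,
                }
            )
    frame = pd.DataFrame(rows)
    frame.attrs["rho"] = float(
        scipy.stats.spearmanr(frame["predicted"], frame["actual"]).statistic
    )
    return frame
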