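"""ROI statistics, tumor/periphery contrast, photobleaching and release kinetics.

Summary statistics over regions of interest drive the downstream science:
tumor-to-periphery contrast ratios of concentration maps, percent change of
photosensitizer concentration across a light treatment (photobleaching
dosimetry), and the time course of drug release after triggered liposome
opening, including detection of the plateau where release levels off.

Statistical caveat: significance tests treat ROI pixels as independent
samples; spatial autocorrelation makes the effective sample size smaller
than the pixel count, so p-values are optimistic.  This caveat is recorded
in every stats report the module writes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from matplotlib.path import Path as MplPath
from scipy import stats

from .fluorescence import ConcentrationMap

__all__ = [
    "ROI",
    "KineticsSeries",
    "roi_stats",
    "percent_change",
    "contrast_ratio",
    "release_kinetics",
    "compare_rois",
    "PLATEAU_REL_STEP",
    "INDEPENDENCE_CAVEAT",
]

# a step-to-step relative change of the ROI mean below this, sustained to the
# end of the series, marks the release plateau
PLATEAU_REL_STEP = 0.05

INDEPENDENCE_CAVEAT = (
    "p-values treat ROI pixels as independent samples; spatial "
    "autocorrelation inflates the effective sample size"
)


@dataclass
class ROI:
    """A labelled region of interest: polygon vertices or a boolean mask.

    Polygon vertices are (row, col) pixel coordinates; a pixel belongs to a
    polygon ROI if its center is inside by the even-odd rule, so vertex
    ordering (clockwise or counterclockwise) does not matter.
    """

    label: str
    polygon: np.ndarray | None = None  # (k, 2) array of (row, col) vertices
    mask_array: np.ndarray | None = None

    def __post_init__(self) -> None:
        if (self.polygon is None) == (self.mask_array is None):
            raise ValueError("give exactly one of polygon or mask_array")
        if self.polygon is not None:
            self.polygon = np.asarray(self.polygon, dtype=float)
            if self.polygon.ndim != 2 or self.polygon.shape[0] < 3 or self.polygon.shape[1] != 2:
                raise ValueError("polygon needs >= 3 (row, col) vertices")
        else:
            self.mask_array = np.asarray(self.mask_array, dtype=bool)
            if not self.mask_array.any():
                raise ValueError("mask ROI is empty")

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        if self.mask_array is not None:
            if self.mask_array.shape != tuple(shape):
                raise ValueError("ROI mask shape differs from image shape")
            return self.mask_array
        if np.any(self.polygon < -0.5) or np.any(
            self.polygon >= np.asarray(shape, dtype=float) - 0.0
        ):
            raise ValueError("polygon vertices outside image bounds")
        verts = self.polygon
        # canonical winding so boundary pixels resolve identically for
        # clockwise and counterclockwise vertex orderings
        area2 = np.sum(
            verts[:, 0] * np.roll(verts[:, 1], -1)
            - np.roll(verts[:, 0], -1) * verts[:, 1]
        )
        if area2 < 0:
            verts = verts[::-1]
        path = MplPath(verts[:, ::-1])  # matplotlib wants (x=col, y=row)
        rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
        pts = np.column_stack([cc.ravel(), rr.ravel()])
        return path.contains_points(pts, radius=1e-9).reshape(shape)

    def to_json(self, path: str | Path) -> None:
        if self.polygon is None:
            raise ValueError("only polygon ROIs serialize to JSON")
        Path(path).write_text(
            json.dumps({"label": self.label, "vertices_rc": self.polygon.tolist()})
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "ROI":
        d = json.loads(Path(path).read_text())
        return cls(label=d["label"], polygon=np.asarray(d["vertices_rc"]))


@dataclass
class KineticsSeries:
    """ROI concentration time course with plateau annotation."""

    times_min: np.ndarray
    mean_ugml: np.ndarray
    sd: np.ndarray
    n_pixels: np.ndarray
    plateau_time_min: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        if np.any(np.diff(self.times_min) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(np.asarray(self.sd) < 0):
            raise ValueError("sd must be nonnegative")

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "time_min": self.times_min,
                "mean_ugml": self.mean_ugml,
                "sd": self.sd,
                "n": self.n_pixels,
            }
        ).to_csv(path, index=False)


def _values_in_roi(cmap: ConcentrationMap | np.ndarray, roi: ROI) -> np.ndarray:
    if isinstance(cmap, ConcentrationMap):
        arr, valid = cmap.c, cmap.mask
    else:
        arr = np.asarray(cmap, dtype=float)
        valid = np.isfinite(arr)
    m = roi.mask(arr.shape) & valid & np.isfinite(arr)
    vals = arr[m]
    if vals.size == 0:
        raise ValueError(f"ROI {roi.label!r} contains no valid pixels")
    return vals


def roi_stats(cmap: ConcentrationMap | np.ndarray, roi: ROI) -> tuple[float, float, int]:
    """Sample mean, sample standard deviation (ddof=1) and pixel count in an ROI."""
    vals = _values_in_roi(cmap, roi)
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return float(np.mean(vals)), sd, int(vals.size)


def percent_change(pre_value: float, post_value: float) -> float:
    """Percent decrease from pre to post: 100 * (pre - post) / pre.

    Positive values mean a decrease (the photobleaching sign convention).
    """
    if pre_value <= 0:
        raise ValueError("pre_value must be positive")
    return 100.0 * (pre_value - post_value) / pre_value


def contrast_ratio(region_a_mean: float, region_b_mean: float) -> float:
    """Ratio of two region means (e.g. tumor / periphery)."""
    if region_b_mean <= 0:
        raise ValueError("denominator region mean must be positive")
    return region_a_mean / region_b_mean


def release_kinetics(maps, roi: ROI, times_min, label: str = "") -> KineticsSeries:
    """ROI time course over ordered concentration maps, with plateau detection.

    The plateau time is the first timepoint from which every subsequent
    step changes the ROI mean by less than ``PLATEAU_REL_STEP`` (5%)
    relative; ``None`` if the series never levels off.
    """
    times_min = np.asarray(times_min, dtype=float)
    if len(maps) != len(times_min):
        raise ValueError(f"{len(maps)} maps but {len(times_min)} timepoints")
    if len(maps) < 2:
        raise ValueError("need at least two timepoints")
    means, sds, ns = [], [], []
    for m in maps:
        mean, sd, n = roi_stats(m, roi)
        means.append(mean)
        sds.append(sd)
        ns.append(n)
    means = np.asarray(means)

    plateau = None
    denom = np.maximum(np.abs(means[:-1]), 1e-12)
    rel_steps = np.abs(np.diff(means)) / denom
    quiet = rel_steps < PLATEAU_REL_STEP
    for i in range(len(quiet)):
        if quiet[i:].all():
            plateau = float(times_min[i])
            break
    return KineticsSeries(
        times_min=times_min,
        mean_ugml=means,
        sd=np.asarray(sds),
        n_pixels=np.asarray(ns),
        plateau_time_min=plateau,
        label=label,
    )


def compare_rois(group_a, group_b) -> tuple[float, float]:
    """Welch two-sample t-test between two pixel samples.

    Returns ``(t_statistic, two_sided_p)``.  Two degenerate samples with
    equal means return ``(0.0, 1.0)`` by convention.
    """
    a = np.asarray(group_a, dtype=float).ravel()
    b = np.asarray(group_b, dtype=float).ravel()
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two pixels")
    if np.var(a) == 0 and np.var(b) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0
        return np.inf if np.mean(a) > np.mean(b) else -np.inf, 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def stats_report(entries: dict, path: str | Path) -> None:
    """Write a JSON stats report; always records the independence caveat."""
    doc = dict(entries)
    doc["caveat"] = INDEPENDENCE_CAVEAT
    Path(path).write_text(json.dumps(doc, indent=1))
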