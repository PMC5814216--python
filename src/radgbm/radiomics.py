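"""First-order radiomic feature extraction over tumor ROIs.

The feature registry holds 82 named features: 12 size/volume features
(pixel count, in-plane area, volume — on the contrast-enhancing T1CE ROI and
the T2FLAIR hyperintensity ROI, plus their ADC-valid restrictions) and
70 histogram features (mean, median, SD, 5th/95th percentile, quartiles of
each of the five physiologic maps rADC/rCBF/rCBV/MTT/TTP over each of the
two ROIs). Names follow the ``{MAP}n{T1|T2}_{STAT}`` convention of the
clinical software the registry mirrors, typos included, so that exported
tables are column-compatible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ROIMask",
    "FeatureSpec",
    "feature_registry",
    "subtract_exclusions",
    "volume_features",
    "histogram_features",
    "extract_patient_features",
]

HISTOGRAM_STATS = ("mean", "median", "sd", "p5", "p95", "q1", "q3")
_STAT_SUFFIX = {
    "mean": "MEAN",
    "median": "MEDIAN",
    "sd": "SD",
    "p5": "X5P",
    "p95": "X95P",
    "q1": "Q1",
    "q3": "Q3",
}
_HISTOGRAM_MAPS = ("rCBF", "rCBV", "MTT", "TTP", "rADC")


@dataclass(frozen=True)
class ROIMask:
    """A binary tumor mask tied to the structural image that defined it."""

    voxels: np.ndarray
    basis: str  # "T1CE" or "T2FLAIR"
    spacing: tuple  # (dx, dy, dz) in mm

    def __post_init__(self):
        object.__setattr__(self, "voxels", np.asarray(self.voxels, dtype=bool))
        if self.basis not in ("T1CE", "T2FLAIR"):
            raise ValueError(f"unknown ROI basis {self.basis!r}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacings must be positive")

    @property
    def n_voxels(self) -> int:
        return int(np.count_nonzero(self.voxels))


@dataclass(frozen=True)
class FeatureSpec:
    """One registry row: a named statistic of a map over an ROI."""

    name: str
    source_map: str  # T1CE-mask | T2FLAIR-mask | rADC | rCBF | rCBV | MTT | TTP
    roi_basis: str  # "T1CE" or "T2FLAIR"
    statistic: str  # pixel_count | area_cm2 | volume_ml | histogram stat


def feature_registry() -> list[FeatureSpec]:
    """The 82-feature registry, in canonical table order.

    Rows 1-6 are the raw mask size features; rows 7-12 repeat them restricted
    to ADC-valid voxels (they differ only when map voxels were invalidated);
    rows 13-82 are the 7 histogram statistics of the 5 physiologic maps over
    the 2 ROI bases.
    """
    specs: list[FeatureSpec] = []
    vol_stats = ("pixel_count", "area_cm2", "volume_ml")
    for basis, tag in (("T1CE", "T1CE"), ("T2FLAIR", "T2FLAIR")):
        for stat, suffix in zip(vol_stats, ("PIXEL", "AREA", "VOL")):
            # "T2FALIR_VOL" reproduces the registry's historical typo
            name = f"{tag}_{suffix}" if not (tag == "T2FLAIR" and suffix == "VOL") else "T2FALIR_VOL"
            specs.append(FeatureSpec(name, f"{basis}-mask", basis, stat))
    for basis, tag in (("T1CE", "T1"), ("T2FLAIR", "T2")):
        for stat, suffix in zip(vol_stats, ("PIXEL", "AREA", "VOL")):
            specs.append(FeatureSpec(f"rADCn{tag}_{suffix}", "rADC", basis, stat))
    for map_name in _HISTOGRAM_MAPS:
        for basis, tag in (("T1CE", "T1"), ("T2FLAIR", "T2")):
            for stat in HISTOGRAM_STATS:
                specs.append(
                    FeatureSpec(
                        f"{map_name}n{tag}_{_STAT_SUFFIX[stat]}", map_name, basis, stat
                    )
                )
    names = [s.name for s in specs]
    assert len(specs) == 82 and len(set(names)) == 82
    return specs


def subtract_exclusions(roi: ROIMask, necrosis=None, vessels=None) -> ROIMask:
    """Remove necrotic-core and vessel voxels from a tumor ROI.

    Returns ``roi \\ (necrosis | vessels)``; raises if nothing remains.
    """
    out = roi.voxels.copy()
    for excl in (necrosis, vessels):
        if excl is None:
            continue
        ev = excl.voxels if isinstance(excl, ROIMask) else np.asarray(excl, dtype=bool)
        if ev.shape != out.shape:
            raise ValueError("exclusion mask grid does not match ROI grid")
        out &= ~ev
    if not out.any():
        raise ValueError("ROI is empty after necrosis/vessel subtraction")
    return ROIMask(out, roi.basis, roi.spacing)


def volume_features(roi: ROIMask):
    """Size features of a mask: (pixel_count, area_cm2, volume_ml).

    Area is total in-plane area summed over slices (count * dx * dy), so
    volume = area * dz for a uniform slice thickness.
    """
    n = roi.n_voxels
    if n == 0:
        raise ValueError("empty ROI mask")
    dx, dy, dz = roi.spacing
    area_cm2 = n * dx * dy / 100.0
    volume_ml = n * dx * dy * dz / 1000.0
    return n, area_cm2, volume_ml


def histogram_features(voxel_map, roi: ROIMask, warn_missing_frac=0.5):
    """First-order statistics of a map over the valid voxels of an ROI.

    Returns a dict with keys mean/median/sd/p5/p95/q1/q3. NaN voxels
    (failed fits, clamps) are excluded; a warning flag is included when more
    than ``warn_missing_frac`` of ROI voxels are missing. Percentiles use
    linear interpolation between order statistics; SD uses the n-1
    denominator.
    """
    voxel_map = np.asarray(voxel_map, dtype=float)
    if voxel_map.shape != roi.voxels.shape:
        raise ValueError("map and ROI grids differ")
    vals = voxel_map[roi.voxels]
    valid = vals[np.isfinite(vals)]
    if valid.size < 2:
        raise ValueError(f"need >=2 valid voxels in ROI, got {valid.size}")
    missing_frac = 1.0 - valid.size / vals.size
    p5, q1, med, q3, p95 = np.percentile(valid, [5, 25, 50, 75, 95])
    return {
        "mean": float(valid.mean()),
        "median": float(med),
        "sd": float(valid.std(ddof=1)),
        "p5": float(p5),
        "p95": float(p95),
        "q1": float(q1),
        "q3": float(q3),
        "n_valid": int(valid.size),
        "high_missing": bool(missing_frac > warn_missing_frac),
    }


def _adc_valid_mask(roi: ROIMask, radc_map: np.ndarray) -> ROIMask:
    sub = roi.voxels & np.isfinite(np.asarray(radc_map, dtype=float))
    if not sub.any():
        raise ValueError("no ADC-valid voxels inside ROI")
    return ROIMask(sub, roi.basis, roi.spacing)


def extract_patient_features(maps: dict, rois: dict) -> pd.Series:
    """Extract the full 82-feature vector for one patient.

    Parameters
    ----------
    maps
        ``{"rADC": arr, "rCBF": arr, "rCBV": arr, "MTT": arr, "TTP": arr}`` —
        normalised physiologic maps on the shared grid.
    rois
        ``{"T1CE": ROIMask, "T2FLAIR": ROIMask}`` — exclusion-subtracted ROIs.

    Returns a Series indexed by registry name, in registry order.
    """
    missing = [m for m in _HISTOGRAM_MAPS if m not in maps]
    if missing:
        specs = [s.name for s in feature_registry() if s.source_map in missing]
        raise ValueError(f"missing maps {missing}; affected features: {specs}")
    for basis in ("T1CE", "T2FLAIR"):
        if basis not in rois:
            raise ValueError(f"missing {basis} ROI")
    values = {}
    for spec in feature_registry():
        roi = rois[spec.roi_basis]
        if spec.source_map.endswith("-mask"):
            n, area, vol = volume_features(roi)
        elif spec.statistic in ("pixel_count", "area_cm2", "volume_ml"):
            n, area, vol = volume_features(_adc_valid_mask(roi, maps["rADC"]))
        else:
            stats = histogram_features(maps[spec.source_map], roi)
            values[spec.name] = stats[spec.statistic]
            continue
        values[spec.name] = {"pixel_count": n, "area_cm2": area, "volume_ml": vol}[
            spec.statistic
        ]
    return pd.Series(values, name="features")[[s.name for s in feature_registry()]]


def registry_table() -> pd.DataFrame:
    """The registry as a DataFrame (name, source_map, roi_basis, statistic)."""
    return pd.DataFrame([vars(s) for s in feature_registry()])
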