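"""Region-of-interest summaries of contrast maps.

The fixed region vocabulary mirrors the analysis design: whole brain, gray
and white matter, and seven cortical gray-matter regions around the dorsal
anterior cingulate slice — cingulate gyrus (CG), juxtapositional lobule
cortex (JLC), paracingulate gyrus (ParaG), frontal pole (FP), middle frontal
gyrus (MFG), precentral gyrus (PreG) and postcentral gyrus (PostG).

Label maps use integer codes; the seven cortical regions are gray matter, so
the GM summary aggregates the generic-GM code together with all cortical
codes.  Statistics run over valid voxels only; a region with no valid voxel
is reported as missing (absence is not zero), and regions with fewer than
``min_voxels`` valid voxels are flagged low-confidence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .contrast import GluCESTMap

__all__ = [
    "REGIONS",
    "CORTICAL_REGIONS",
    "REGION_LABELS",
    "RegionSummary",
    "labels_for_region",
    "regional_means",
    "normalized_volumes",
    "summaries_to_frame",
]

#: Integer label codes of the disjoint tissue classes in a label map.
REGION_LABELS: dict[str, int] = {
    "WM": 1,
    "GM": 2,
    "CG": 3,
    "JLC": 4,
    "ParaG": 5,
    "FP": 6,
    "MFG": 7,
    "PreG": 8,
    "PostG": 9,
}

CORTICAL_REGIONS: tuple[str, ...] = ("CG", "JLC", "ParaG", "FP", "MFG", "PreG", "PostG")

#: Reporting vocabulary (aggregates first, then the cortical regions).
REGIONS: tuple[str, ...] = ("WholeBrain", "GM", "WM") + CORTICAL_REGIONS

_GM_CODES = frozenset(REGION_LABELS[r] for r in ("GM",) + CORTICAL_REGIONS)
_WM_CODES = frozenset({REGION_LABELS["WM"]})


def labels_for_region(region: str) -> frozenset[int]:
    """Label codes aggregated by a region name from the fixed vocabulary."""
    if region == "WholeBrain":
        return frozenset(REGION_LABELS.values())
    if region == "GM":
        return _GM_CODES
    if region == "WM":
        return _WM_CODES
    if region in REGION_LABELS:
        return frozenset({REGION_LABELS[region]})
    raise KeyError(f"unknown region {region!r}; expected one of {REGIONS}")


@dataclass
class RegionSummary:
    region: str
    mean_percent: float
    sd_percent: float
    n_voxels: int
    missing: bool = False
    low_confidence: bool = False

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(f"region {self.region!r} not in the fixed vocabulary")
        if self.n_voxels < 0:
            raise ValueError("n_voxels must be >= 0")


def regional_means(
    gmap: GluCESTMap, labels: np.ndarray, min_voxels: int = 10
) -> list[RegionSummary]:
    """One summary per vocabulary region over the valid voxels of ``gmap``."""
    labels = np.asarray(labels)
    if labels.shape != gmap.percent.shape:
        raise ValueError(
            f"label map shape {labels.shape} does not match contrast map "
            f"shape {gmap.percent.shape}"
        )
    out = []
    for region in REGIONS:
        codes = labels_for_region(region)
        sel = np.isin(labels, list(codes)) & gmap.valid
        n = int(sel.sum())
        if n == 0:
            out.append(RegionSummary(region, np.nan, np.nan, 0, missing=True))
            continue
        vals = gmap.percent[sel]
        sd = float(np.std(vals, ddof=1)) if n > 1 else 0.0
        out.append(
            RegionSummary(
                region, float(vals.mean()), sd, n, low_confidence=n < min_voxels
            )
        )
    return out


def normalized_volumes(labels: np.ndarray) -> tuple[float, float]:
    """Gray- and white-matter voxel fractions of total brain volume.

    Brain is every nonzero label; fractions are voxel-count ratios (uniform
    voxel size on a single slice).
    """
    labels = np.asarray(labels)
    brain = int((labels > 0).sum())
    if brain == 0:
        raise ValueError("label map contains no brain voxels")
    gm = int(np.isin(labels, list(_GM_CODES)).sum())
    wm = int(np.isin(labels, list(_WM_CODES)).sum())
    return gm / brain, wm / brain


def summaries_to_frame(
    summaries: list[RegionSummary], subject_id: str | None = None
) -> pd.DataFrame:
    """Tabular form with one row per region; optional subject id column."""
    df = pd.DataFrame(
        {
            "region": [s.region for s in summaries],
            "mean_percent": [s.mean_percent for s in summaries],
            "sd_percent": [s.sd_percent for s in summaries],
            "n_voxels": [s.n_voxels for s in summaries],
            "missing": [s.missing for s in summaries],
            "low_confidence": [s.low_confidence for s in summaries],
        }
    )
    if subject_id is not None:
        df.insert(0, "subject_id", subject_id)
    return df
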