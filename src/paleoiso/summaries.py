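"""Cohort descriptive statistics, diet-space PCA, and strontium screening.

Small-cohort bioarchaeology reports a handful of standard summaries: per-
proxy cohort means, a principal-component view of modelled diet
contributions (so individuals and groups can be compared in two dimensions
instead of five), and enamel 87Sr/86Sr locality screening against the
bioavailable-strontium envelope of a region.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

__all__ = [
    "SrMeasurement",
    "cohort_isotope_means",
    "diet_pca",
    "sr_locality",
    "spread_statistic",
    "load_sr_measurements",
    "load_isoscape",
    "reference_sr_measurements",
    "synthetic_isoscape",
]


@dataclass(frozen=True)
class SrMeasurement:
    """Enamel radiogenic strontium ratio with 95% CI half-width."""

    burial_id: str
    tooth: str
    ratio: float
    ci95: float

    def __post_init__(self) -> None:
        if not 0.700 <= self.ratio <= 0.730:
            raise ValueError(f"87Sr/86Sr {self.ratio} outside plausible range")
        if self.ci95 <= 0:
            raise ValueError("ci95 must be > 0")


def _round_half_up(x: float, digits: int) -> float:
    """Report-style rounding: half away from zero on the shortest decimal
    representation (so a mean of 8.85 prints as 8.9, not 8.8)."""
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def cohort_isotope_means(
    table: pd.DataFrame, proxies: Sequence[str]
) -> dict[str, tuple[float, float]]:
    """Arithmetic mean and sample sd per proxy column, rounded to 1 decimal.

    Rows missing a proxy are excluded from that proxy's summary with a
    warning. Requires at least two contributing rows per proxy.
    """
    out: dict[str, tuple[float, float]] = {}
    for p in proxies:
        if p not in table.columns:
            raise KeyError(f"proxy column {p!r} not in table")
        col = pd.to_numeric(table[p], errors="coerce")
        n_missing = int(col.isna().sum())
        if n_missing:
            warnings.warn(
                f"{p}: excluded {n_missing} row(s) with missing values",
                stacklevel=2,
            )
        vals = sorted(col.dropna().tolist())
        if len(vals) < 2:
            raise ValueError(f"{p}: need >= 2 values for a cohort mean")
        mean = math.fsum(vals) / len(vals)
        sd = math.sqrt(
            math.fsum((v - mean) ** 2 for v in vals) / (len(vals) - 1)
        )
        out[p] = (_round_half_up(mean, 1), _round_half_up(sd, 1))
    return out


def diet_pca(
    contributions: pd.DataFrame | np.ndarray, scale: bool = False
) -> dict:
    """Centered PCA of a diet-contribution matrix (individuals x groups).

    Constant columns are dropped with a warning; each component's sign is
    fixed so its largest-magnitude loading is positive. Set ``scale=True``
    for unit-variance scaling of the columns.

    Returns dict with 'loadings' (components x variables DataFrame),
    'scores' (individuals x components), 'explained_pct'.
    """
    df = pd.DataFrame(contributions).copy()
    if df.shape[0] < 3:
        raise ValueError("need at least 3 individuals for PCA")
    const = [c for c in df.columns if df[c].nunique() <= 1]
    if const:
        warnings.warn(f"dropping constant column(s): {const}", stacklevel=2)
        df = df.drop(columns=const)
    X = df.to_numpy(dtype=float)
    if scale:
        X = (X - X.mean(0)) / X.std(0, ddof=1)
    pca = PCA()
    scores = pca.fit_transform(X)
    loadings = pca.components_
    # deterministic sign: largest-|loading| entry positive per component
    for i in range(loadings.shape[0]):
        j = int(np.argmax(np.abs(loadings[i])))
        if loadings[i, j] < 0:
            loadings[i] = -loadings[i]
            scores[:, i] = -scores[:, i]
    names = [f"PC{i+1}" for i in range(loadings.shape[0])]
    return {
        "loadings": pd.DataFrame(loadings, index=names, columns=df.columns),
        "scores": pd.DataFrame(scores, index=df.index, columns=names),
        "explained_pct": 100.0 * pca.explained_variance_ratio_,
    }


def sr_locality(
    meas: SrMeasurement,
    envelope: Optional[Mapping[str, tuple[float, float]]],
    region: str,
) -> str:
    """Classify an individual as 'local' / 'non-local' / 'indeterminate'.

    Local means the measurement's 95% CI interval intersects the region's
    bioavailable-Sr range; indeterminate when no envelope is available.
    """
    if envelope is None or region not in envelope:
        return "indeterminate"
    lo, hi = envelope[region]
    if lo >= hi:
        raise ValueError(f"degenerate envelope for region {region!r}")
    m_lo, m_hi = meas.ratio - meas.ci95, meas.ratio + meas.ci95
    return "local" if (m_hi >= lo and m_lo <= hi) else "non-local"


def spread_statistic(measurements: Sequence[SrMeasurement]) -> float:
    """Range (max - min) of measured 87Sr/86Sr ratios across the cohort."""
    if len(measurements) < 2:
        raise ValueError("need >= 2 measurements")
    ratios = [m.ratio for m in measurements]
    return max(ratios) - min(ratios)


def load_sr_measurements(path: str | Path) -> list[SrMeasurement]:
    df = pd.read_csv(path, comment="#")
    return [
        SrMeasurement(str(r.burial_id), str(r.tooth), float(r.ratio), float(r.ci95))
        for r in df.itertuples()
    ]


def load_isoscape(path: str | Path) -> dict[str, tuple[float, float]]:
    df = pd.read_csv(path, comment="#")
    return {
        str(r.region): (float(r.ratio_min), float(r.ratio_max))
        for r in df.itertuples()
    }


def reference_sr_measurements() -> list[SrMeasurement]:
    """Packaged enamel Sr table for the Ortiz burials."""
    return load_sr_measurements(Path(__file__).parent / "data" / "ortiz_sr.csv")


def synthetic_isoscape() -> dict[str, tuple[float, float]]:
    """Packaged SYNTHETIC bioavailable-Sr envelope (placeholder ranges for
    exercising the screening logic; replace with published tables for real
    provenance inference)."""
    return load_isoscape(Path(__file__).parent / "data" / "synthetic_sr_isoscape.csv")
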