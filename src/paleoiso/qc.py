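"""Collagen and apatite preservation screening.

Ancient bone in neotropical burial environments loses collagen and takes up
diagenetic carbonate; isotope values from poorly preserved tissue are not
dietary signals. Samples are screened on extraction yield, elemental
composition, and the atomic C:N ratio of the extracted "collagen" before any
dietary modelling, following the standard quality criteria for bone collagen
(yield > 0.5 wt%, C > 4.5 wt%, N > 0.9 wt%, atomic C:N within 2.9-3.6) and
a 21-63 wt% acceptance window for structural-carbonate (apatite) yield.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import math

import pandas as pd

__all__ = [
    "SpecimenSample",
    "QCThresholds",
    "QCVerdict",
    "screen_collagen",
    "screen_apatite",
    "gate_cohort",
    "load_specimens",
    "screen_table",
    "reference_specimens",
]


def _isnull(x: Optional[float]) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


@dataclass(frozen=True)
class SpecimenSample:
    """Per-specimen preservation chemistry, with optional isotope payload.

    Yield and elemental fields are wt%; missing measurements are ``None``.
    """

    burial_id: str
    collagen_yield: Optional[float] = None
    wtC: Optional[float] = None
    wtN: Optional[float] = None
    cn_atomic: Optional[float] = None
    apatite_yield: Optional[float] = None
    d13C_co: Optional[float] = None
    d15N_co: Optional[float] = None
    d13C_ap: Optional[float] = None
    d18O_ap: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("collagen_yield", "wtC", "wtN", "cn_atomic", "apatite_yield"):
            v = getattr(self, name)
            if not _isnull(v) and v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")


@dataclass(frozen=True)
class QCThresholds:
    """Preservation cutoffs. Collagen yield uses a strict '>' comparison;
    the C:N window is inclusive at both ends; apatite yield above the upper
    bound is tolerated up to ``apatite_tolerance`` (with a warning) since
    slight over-range yields are routinely retained.

    ``collagen_yield_preferred`` is informational only (flagged, never a
    gate)."""

    collagen_yield_min: float = 0.5
    wtC_min: float = 4.5
    wtN_min: float = 0.9
    cn_low: float = 2.9
    cn_high: float = 3.6
    apatite_low: float = 21.0
    apatite_high: float = 63.0
    apatite_tolerance: float = 2.0
    collagen_yield_preferred: float = 3.5

    def __post_init__(self) -> None:
        if not self.cn_low < self.cn_high:
            raise ValueError("cn_low must be < cn_high")
        if not self.apatite_low < self.apatite_high:
            raise ValueError("apatite_low must be < apatite_high")
        for name in ("collagen_yield_min", "wtC_min", "wtN_min", "cn_low", "apatite_low"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class QCVerdict:
    burial_id: str
    collagen_pass: bool
    apatite_pass: bool
    failed_criteria: tuple[str, ...] = ()
    warnings: tuple[str, ...] = ()


def screen_collagen(
    sample: SpecimenSample, thresholds: QCThresholds = QCThresholds()
) -> QCVerdict:
    """Screen the collagen fraction; any missing required field fails with a
    'missing' reason rather than passing silently."""
    t = thresholds
    failed: list[str] = []
    warns: list[str] = []

    def check(value: Optional[float], name: str, ok) -> None:
        if _isnull(value):
            failed.append(f"{name}: missing")
        elif not ok(value):
            failed.append(name)

    check(sample.collagen_yield, "collagen_yield", lambda v: v > t.collagen_yield_min)
    check(sample.wtC, "wtC", lambda v: v > t.wtC_min)
    check(sample.wtN, "wtN", lambda v: v > t.wtN_min)
    check(sample.cn_atomic, "cn_atomic", lambda v: t.cn_low <= v <= t.cn_high)
    if (
        not _isnull(sample.collagen_yield)
        and sample.collagen_yield <= t.collagen_yield_preferred
    ):
        warns.append("collagen_yield below preferred 3.5 wt% (informational)")
    return QCVerdict(
        burial_id=sample.burial_id,
        collagen_pass=not failed,
        apatite_pass=False,
        failed_criteria=tuple(failed),
        warnings=tuple(warns),
    )


def screen_apatite(
    sample: SpecimenSample, thresholds: QCThresholds = QCThresholds()
) -> QCVerdict:
    """Screen apatite (structural carbonate) yield against the acceptance
    window, tolerating slightly-above-range yields with a warning."""
    t = thresholds
    y = sample.apatite_yield
    failed: list[str] = []
    warns: list[str] = []
    if _isnull(y):
        failed.append("apatite_yield: missing")
    elif not (t.apatite_low <= y <= t.apatite_high + t.apatite_tolerance):
        failed.append("apatite_yield")
    elif y > t.apatite_high:
        warns.append("apatite_yield above range (retained within tolerance)")
    return QCVerdict(
        burial_id=sample.burial_id,
        collagen_pass=False,
        apatite_pass=not failed,
        failed_criteria=tuple(failed),
        warnings=tuple(warns),
    )


def gate_cohort(
    samples: Sequence[SpecimenSample], thresholds: QCThresholds = QCThresholds()
) -> list[str]:
    """Burial ids eligible for diet modelling: those passing the collagen
    screen, sorted by id."""
    return sorted(
        s.burial_id for s in samples if screen_collagen(s, thresholds).collagen_pass
    )


_NUMERIC = (
    "collagen_yield",
    "wtC",
    "wtN",
    "cn_atomic",
    "apatite_yield",
    "d13C_co",
    "d15N_co",
    "d13C_ap",
    "d18O_ap",
)


def load_specimens(path: str | Path) -> list[SpecimenSample]:
    """Read a per-specimen QC/isotope table (CSV; blank cells = missing)."""
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        kwargs = {"burial_id": str(row["burial_id"])}
        for c in _NUMERIC:
            if c in df.columns:
                v = row[c]
                kwargs[c] = None if pd.isna(v) else float(v)
        out.append(SpecimenSample(**kwargs))
    return out


def screen_table(
    samples: Sequence[SpecimenSample], thresholds: QCThresholds = QCThresholds()
) -> pd.DataFrame:
    """Full verdict report for a cohort, one row per specimen."""
    rows = []
    for s in samples:
        c = screen_collagen(s, thresholds)
        a = screen_apatite(s, thresholds)
        rows.append(
            {
                "burial_id": s.burial_id,
                "collagen_pass": c.collagen_pass,
                "apatite_pass": a.apatite_pass,
                "failed_criteria": "; ".join(c.failed_criteria + a.failed_criteria),
                "warnings": "; ".join(c.warnings + a.warnings),
            }
        )
    return pd.DataFrame(rows)


def reference_specimens() -> list[SpecimenSample]:
    """The packaged Ortiz/Maruca specimen table."""
    return load_specimens(Path(__file__).parent / "data" / "ortiz_specimens.csv")
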