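"""Loaders for the packaged reference tables.

The package ships the published per-specimen chemistry/isotope table, the
AMS dates with reservoir parameters, the enamel strontium table, the
five-group dietary source matrix, and a synthetic strontium isoscape
fixture. All are plain CSV under ``paleoiso/data``.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .calibration import RadiocarbonDate

__all__ = [
    "data_path",
    "load_dates",
    "reference_dates",
]

_DATA = Path(__file__).parent / "data"


def data_path(name: str) -> Path:
    """Absolute path of a packaged data file."""
    p = _DATA / name
    if not p.exists():
        raise FileNotFoundError(f"no packaged data file {name!r}")
    return p


def load_dates(path: str | Path) -> list[RadiocarbonDate]:
    """Read AMS dates (lab_code, burial_id, cra, sigma, d13C_reported,
    deltaR, deltaR_sd) from CSV; marine fractions are attached later from
    the diet posteriors."""
    df = pd.read_csv(path, comment="#")
    return [
        RadiocarbonDate(
            lab_code=str(r.lab_code),
            burial_id=str(r.burial_id),
            cra=float(r.cra),
            sigma=float(r.sigma),
            d13C_reported=float(r.d13C_reported),
            deltaR=float(r.deltaR),
            deltaR_sd=float(r.deltaR_sd),
        )
        for r in df.itertuples()
    ]


def reference_dates() -> list[RadiocarbonDate]:
    """The packaged Ortiz AMS dates (four individuals, local deltaR)."""
    return load_dates(data_path("ortiz_dates.csv"))
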