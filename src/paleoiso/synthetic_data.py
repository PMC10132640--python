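"""Synthetic fixtures: consumers, QC tables, and calibration curves.

Everything the pipeline consumes can be generated here with known ground
truth: consumers are forward-simulated through the same routing model the
fitter inverts (known diet -> predicted proxies -> instrumental noise), QC
tables are built with a prescribed pass/fail structure, and calibration
curves follow simple analytic models (identity, constant marine offset,
or sinusoidal wiggles). A single scenario seed fixes all randomness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .calibration import CalibrationCurve, write_curve
from .diet_model import ConsumerObservation, OffsetSpec, RoutingSpec, predict_signals
from .foodweb import FoodGroup
from .qc import QCThresholds, SpecimenSample

__all__ = [
    "SyntheticScenario",
    "default_scenario",
    "gen_consumers",
    "gen_curves",
    "gen_qc_table",
]

#: diets roughly at the Ortiz posterior-mean scale, rows on the simplex
_DEFAULT_DIETS = np.array(
    [
        [0.26, 0.17, 0.31, 0.12, 0.14],
        [0.38, 0.14, 0.27, 0.12, 0.09],
        [0.28, 0.17, 0.34, 0.08, 0.13],
        [0.23, 0.18, 0.34, 0.11, 0.14],
    ]
)


@dataclass(frozen=True)
class SyntheticScenario:
    """Study conditions for a synthetic cohort.

    ``noise_sd`` is the per-proxy instrumental noise (0.1 permil, the same
    figure stipulated for the measured data); ``curve_model`` is one of
    "identity", "offset-marine" (terrestrial + 400 14C yr), or "wiggly"
    (sinusoid added to the identity curve).
    """

    seed: int = 42
    n_consumers: int = 4
    true_diets: Optional[np.ndarray] = None  # rows on the simplex
    routing: RoutingSpec = field(default_factory=RoutingSpec)
    offsets: OffsetSpec = field(default_factory=OffsetSpec)
    noise_sd: float = 0.1
    curve_model: str = "offset-marine"
    curve_span: tuple[float, float] = (0.0, 6000.0)
    curve_step: float = 5.0
    marine_shift: float = 400.0  # constant synthetic reservoir, 14C yr
    wiggle_amplitude: float = 20.0
    wiggle_period: float = 500.0

    def diets(self) -> np.ndarray:
        if self.true_diets is not None:
            d = np.asarray(self.true_diets, dtype=float)
        else:
            reps = int(np.ceil(self.n_consumers / len(_DEFAULT_DIETS)))
            d = np.tile(_DEFAULT_DIETS, (reps, 1))[: self.n_consumers]
        if d.ndim != 2 or np.any(d < 0) or not np.allclose(d.sum(axis=1), 1.0):
            raise ValueError("true_diets rows must be non-negative and sum to 1")
        return d

    def __post_init__(self) -> None:
        if self.curve_model not in ("identity", "offset-marine", "wiggly"):
            raise ValueError(f"unknown curve model {self.curve_model!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def default_scenario(seed: int = 42) -> SyntheticScenario:
    """The default cohort mirrors the Ortiz scale: four consumers with
    diets near the published posterior means."""
    return SyntheticScenario(seed=seed)


def gen_consumers(
    scenario: SyntheticScenario, groups: Sequence[FoodGroup]
) -> tuple[list[ConsumerObservation], pd.DataFrame]:
    """Forward-simulate consumers from known diets.

    Proxies are the routing model's noise-free predictions at the groups'
    mean source values and mean offsets, plus Normal instrumental noise.
    Returns the observations and a truth table (one row per consumer with
    the generating diet and noise-free signals).
    """
    rng = np.random.default_rng(scenario.seed)
    diets = scenario.diets()
    consumers, truth_rows = [], []
    for i, diet in enumerate(diets):
        bid = f"SYN{i+1}"
        co, n15, ap = predict_signals(
            diet, groups, scenario.routing, scenario.offsets
        )
        noise = rng.normal(0.0, scenario.noise_sd, size=3) if scenario.noise_sd else np.zeros(3)
        consumers.append(
            ConsumerObservation(
                burial_id=bid,
                d13C_co=co + noise[0],
                d15N_co=n15 + noise[1],
                d13C_ap=ap + noise[2],
            )
        )
        row = {"burial_id": bid, "d13C_co_true": co, "d15N_co_true": n15, "d13C_ap_true": ap}
        row.update({f"alpha_{g.name}": diet[j] for j, g in enumerate(groups)})
        truth_rows.append(row)
    return consumers, pd.DataFrame(truth_rows)


def gen_curves(
    scenario: SyntheticScenario, out_dir: Optional[str | Path] = None
) -> tuple[CalibrationCurve, CalibrationCurve]:
    """Build (terrestrial, marine) synthetic curves.

    Identity model: mu_terr(t) = t with sigma 10; the marine curve is the
    terrestrial one shifted by a constant synthetic reservoir (+400 14C yr)
    with sigma 15. The wiggly model adds a sinusoid to the terrestrial
    mean. Optionally writes both as `.14c` files into ``out_dir``.
    """
    lo, hi = scenario.curve_span
    t = np.arange(lo, hi + scenario.curve_step / 2, scenario.curve_step)
    mu = t.copy()
    if scenario.curve_model == "wiggly":
        mu = t + scenario.wiggle_amplitude * np.sin(
            2 * np.pi * t / scenario.wiggle_period
        )
    terr = CalibrationCurve("synthetic_terrestrial", t, mu, np.full_like(t, 10.0))
    marine = CalibrationCurve(
        "synthetic_marine", t, mu + scenario.marine_shift, np.full_like(t, 15.0)
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_curve(terr, out_dir / "synthetic_terrestrial.14c")
        write_curve(marine, out_dir / "synthetic_marine.14c")
    return terr, marine


#: (field, value) templates violating exactly one collagen criterion each
_VIOLATIONS = [
    ("collagen_yield", 0.2),
    ("wtC", 2.0),
    ("wtN", 0.4),
    ("cn_atomic", 4.5),
]


def gen_qc_table(
    n_pass: int, n_fail: int, seed: int = 0, thresholds: QCThresholds = QCThresholds()
) -> tuple[list[SpecimenSample], dict[str, str]]:
    """Generate specimens with a known pass/fail structure.

    Passing rows are drawn inside every collagen threshold; each failing
    row violates exactly one criterion, cycling through yield, %C, %N and
    C:N. Returns (samples, truth) where truth maps burial_id to "pass" or
    the violated field name.
    """
    if n_pass < 0 or n_fail < 0:
        raise ValueError("counts must be >= 0")
    rng = np.random.default_rng(seed)
    t = thresholds
    samples: list[SpecimenSample] = []
    truth: dict[str, str] = {}

    def passing_kwargs() -> dict:
        return {
            "collagen_yield": float(rng.uniform(t.collagen_yield_min + 0.5, 5.0)),
            "wtC": float(rng.uniform(t.wtC_min + 5, 45.0)),
            "wtN": float(rng.uniform(t.wtN_min + 2, 15.0)),
            "cn_atomic": float(rng.uniform(t.cn_low + 0.1, t.cn_high - 0.1)),
            "apatite_yield": float(rng.uniform(t.apatite_low + 5, t.apatite_high - 5)),
        }

    for i in range(n_pass):
        bid = f"PASS{i+1}"
        samples.append(SpecimenSample(burial_id=bid, **passing_kwargs()))
        truth[bid] = "pass"
    for i in range(n_fail):
        bid = f"FAIL{i+1}"
        kwargs = passing_kwargs()
        fieldname, bad = _VIOLATIONS[i % len(_VIOLATIONS)]
        kwargs[fieldname] = bad
        samples.append(SpecimenSample(burial_id=bid, **kwargs))
        truth[bid] = fieldname
    return samples, truth
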