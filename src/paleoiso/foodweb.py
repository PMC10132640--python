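"""Food-group source matrix construction.

Builds the dietary source matrix used by the mixing model from individual
foodstuff records: industrial-era (Suess) correction of modern reference
foods, macronutrient caloric profiles, fraction-specific carbon isotope
values derived from bulk measurements via fixed fat/carbohydrate offsets and
macronutrient mass balance, and aggregation of items into named food groups.

Conventions: all carbon isotope ratios are delta-13C in permil vs VPDB, all
nitrogen delta-15N in permil vs AIR. Macronutrient fractions are percent of
calories; "energy" lumps fats and carbohydrates, complementary to protein.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd

__all__ = [
    "FoodItem",
    "MacronutrientProfile",
    "FoodGroup",
    "GROUP_LABELS",
    "SUESS_SHIFT",
    "FAT_OFFSET",
    "CARB_OFFSET",
    "suess_correct",
    "energy_fraction_delta",
    "protein_delta_mass_balance",
    "bulk_from_fractions",
    "aggregate_group",
    "load_food_groups",
    "write_food_groups",
    "reference_food_groups",
]

#: Canonical food-group labels: C3 plants, C4/CAM plants, combined
#: freshwater+terrestrial fauna, and two marine groups (M1 pelagic/high
#: trophic level, M2 reef/seagrass/shellfish).
GROUP_LABELS = ("C3", "C4CAM", "FWTERR", "M1", "M2")

#: Industrial-era depletion of atmospheric delta-13C: modern reference foods
#: are shifted by +1.5 permil to be comparable with archaeological tissues.
SUESS_SHIFT = 1.5

#: Lipid synthesis discriminates against 13C: fat runs ~6 permil below the
#: bulk tissue value, carbohydrate ~0.5 permil above it.
FAT_OFFSET = -6.0
CARB_OFFSET = 0.5

Era = Literal["modern", "archaeological"]


@dataclass(frozen=True)
class FoodItem:
    """A single foodstuff record with bulk isotope values."""

    id: str
    group_label: str
    era: Era
    d13C_bulk: float
    d15N: float
    suess_applied: bool = False
    edible_tissue_corrected: bool = False

    def __post_init__(self) -> None:
        if self.group_label not in GROUP_LABELS:
            raise ValueError(f"unknown group label {self.group_label!r}")
        if self.era not in ("modern", "archaeological"):
            raise ValueError(f"era must be 'modern' or 'archaeological', got {self.era!r}")
        if not -40.0 <= self.d13C_bulk <= 0.0:
            raise ValueError(f"d13C_bulk {self.d13C_bulk} outside plausible [-40, 0] permil")
        if not -5.0 <= self.d15N <= 25.0:
            raise ValueError(f"d15N {self.d15N} outside plausible [-5, 25] permil")
        if self.suess_applied and self.era != "modern":
            raise ValueError("suess_applied is only meaningful for modern items")


@dataclass(frozen=True)
class MacronutrientProfile:
    """Caloric macronutrient composition of a foodstuff.

    ``protein_pct`` and ``energy_pct`` are percent of calories and must sum
    to 100 exactly (in the means); ``digestibility`` and the per-macronutrient
    carbon concentrations are per-item correction knobs with identity
    defaults, used when compiling sources from raw food-composition tables.
    """

    protein_pct: float
    energy_pct: float
    protein_pct_sd: float = 0.0
    energy_pct_sd: float = 0.0
    digestibility: float = 1.0
    carbon_conc_protein: float = 1.0
    carbon_conc_energy: float = 1.0
    fat_share: float = 0.0  # fraction of energy calories that are fat

    def __post_init__(self) -> None:
        if abs(self.protein_pct + self.energy_pct - 100.0) > 1e-9:
            raise ValueError("protein_pct + energy_pct must equal 100")
        if self.protein_pct_sd < 0 or self.energy_pct_sd < 0:
            raise ValueError("macronutrient sds must be >= 0")
        if not 0.0 < self.digestibility <= 1.0:
            raise ValueError("digestibility must be in (0, 1]")
        if not 0.0 <= self.fat_share <= 1.0:
            raise ValueError("fat_share must be in [0, 1]")


@dataclass(frozen=True)
class FoodGroup:
    """One row of the source matrix: a food group with macronutrient caloric
    fractions and fraction-specific isotope signatures, all with 1-sd
    uncertainties."""

    name: str
    n_items: int
    protein_pct: float
    protein_pct_sd: float
    energy_pct: float
    energy_pct_sd: float
    d13C_bulk: float
    d13C_bulk_sd: float
    d13C_protein: float
    d13C_protein_sd: float
    d13C_energy: float
    d13C_energy_sd: float
    d15N_protein: float
    d15N_protein_sd: float

    def __post_init__(self) -> None:
        if abs(self.protein_pct + self.energy_pct - 100.0) > 1e-6:
            raise ValueError("protein_pct + energy_pct must equal 100")
        for f in (
            self.protein_pct_sd,
            self.energy_pct_sd,
            self.d13C_bulk_sd,
            self.d13C_protein_sd,
            self.d13C_energy_sd,
            self.d15N_protein_sd,
        ):
            if f < 0:
                raise ValueError("sds must be >= 0")

    def mass_balance_residual(self) -> float:
        """Signed difference between the stored bulk delta-13C and the one
        reconstructed from the macronutrient-weighted fraction deltas."""
        recon = bulk_from_fractions(
            self.protein_pct, self.energy_pct, self.d13C_protein, self.d13C_energy
        )
        return self.d13C_bulk - recon


def suess_correct(item: FoodItem, shift: float = SUESS_SHIFT) -> FoodItem:
    """Apply the fossil-fuel (Suess) correction to a modern item's bulk
    delta-13C. Archaeological items are returned unchanged; re-applying to an
    already-corrected item raises."""
    if item.era == "archaeological":
        return item
    if item.suess_applied:
        raise ValueError(f"Suess correction already applied to item {item.id!r}")
    return replace(item, d13C_bulk=item.d13C_bulk + shift, suess_applied=True)


def energy_fraction_delta(d13C_bulk: float, fat_share: float) -> float:
    """delta-13C of the combined energy (fat + carbohydrate) fraction.

    Fat sits at bulk-6 permil and carbohydrate at bulk+0.5 permil; the energy
    fraction is their caloric-share-weighted average.
    """
    if not 0.0 <= fat_share <= 1.0:
        raise ValueError(f"fat_share must be in [0, 1], got {fat_share}")
    return fat_share * (d13C_bulk + FAT_OFFSET) + (1.0 - fat_share) * (d13C_bulk + CARB_OFFSET)


def protein_delta_mass_balance(
    d13C_bulk: float, protein_pct: float, energy_pct: float, d13C_energy: float
) -> float:
    """delta-13C of the protein fraction by mass balance.

    Solves (p/100)*dP + (e/100)*dE = dBulk for dP, so that the caloric-share
    weighted average of the fraction values reproduces the measured bulk.
    """
    if protein_pct <= 0:
        raise ValueError("protein_pct must be > 0 for mass balance")
    return (100.0 * d13C_bulk - energy_pct * d13C_energy) / protein_pct


def bulk_from_fractions(
    protein_pct: float, energy_pct: float, d13C_protein: float, d13C_energy: float
) -> float:
    """Inverse of :func:`protein_delta_mass_balance`: reconstruct the bulk
    delta-13C from the fraction-specific values."""
    return (protein_pct * d13C_protein + energy_pct * d13C_energy) / 100.0


def aggregate_group(
    items: Sequence[FoodItem],
    profiles: Sequence[MacronutrientProfile],
    label: str,
    ddof: int = 1,
) -> FoodGroup:
    """Aggregate corrected items with matching ``label`` into a FoodGroup.

    Items are weighted equally. ``ddof=1`` gives the sample sd (0 for n=1);
    pass ``ddof=0`` for the population sd. Fraction-specific deltas are
    derived per item (energy via fat/carb offsets, protein via mass balance)
    before averaging, so the group means close the mass balance by
    construction up to averaging of the nonlinear protein step.
    """
    if len(items) != len(profiles):
        raise ValueError("items and profiles must be parallel sequences")
    picked = [(it, pr) for it, pr in zip(items, profiles) if it.group_label == label]
    if not picked:
        raise ValueError(f"no items with label {label!r}")
    for it, _ in picked:
        if it.era == "modern" and not it.suess_applied:
            raise ValueError(f"modern item {it.id!r} lacks Suess correction")

    def mean_sd(vals: list[float]) -> tuple[float, float]:
        n = len(vals)
        m = sum(vals) / n
        if n <= ddof:
            return m, 0.0
        var = sum((v - m) ** 2 for v in vals) / (n - ddof)
        return m, math.sqrt(var)

    bulks = [it.d13C_bulk for it, _ in picked]
    prot_pcts = [pr.protein_pct for _, pr in picked]
    en_pcts = [pr.energy_pct for _, pr in picked]
    d13c_en = [energy_fraction_delta(it.d13C_bulk, pr.fat_share) for it, pr in picked]
    d13c_pr = [
        protein_delta_mass_balance(it.d13C_bulk, pr.protein_pct, pr.energy_pct, de)
        for (it, pr), de in zip(picked, d13c_en)
    ]
    d15n = [it.d15N for it, _ in picked]

    pm, ps = mean_sd(prot_pcts)
    em, es = mean_sd(en_pcts)
    bm, bs = mean_sd(bulks)
    prm, prs = mean_sd(d13c_pr)
    enm, ens = mean_sd(d13c_en)
    nm, ns = mean_sd(d15n)
    # re-close the bulk mean on the averaged fraction values so the group
    # satisfies the mass-balance invariant exactly
    bm = bulk_from_fractions(pm, em, prm, enm)
    return FoodGroup(
        name=label,
        n_items=len(picked),
        protein_pct=pm,
        protein_pct_sd=ps,
        energy_pct=em,
        energy_pct_sd=es,
        d13C_bulk=bm,
        d13C_bulk_sd=bs,
        d13C_protein=prm,
        d13C_protein_sd=prs,
        d13C_energy=enm,
        d13C_energy_sd=ens,
        d15N_protein=nm,
        d15N_protein_sd=ns,
    )


_COLUMNS = [
    "name",
    "n_items",
    "protein_pct",
    "protein_pct_sd",
    "energy_pct",
    "energy_pct_sd",
    "d13C_bulk",
    "d13C_bulk_sd",
    "d13C_protein",
    "d13C_protein_sd",
    "d13C_energy",
    "d13C_energy_sd",
    "d15N_protein",
    "d15N_protein_sd",
]


def load_food_groups(path: str | Path) -> list[FoodGroup]:
    """Read a source matrix CSV (one row per food group)."""
    df = pd.read_csv(path)
    missing = set(_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"source matrix missing columns: {sorted(missing)}")
    return [FoodGroup(**{c: row[c] for c in _COLUMNS}) for _, row in df.iterrows()]


def write_food_groups(groups: Iterable[FoodGroup], path: str | Path) -> None:
    pd.DataFrame([{c: getattr(g, c) for c in _COLUMNS} for g in groups]).to_csv(
        path, index=False
    )


def reference_food_groups() -> list[FoodGroup]:
    """The packaged five-group Caribbean source matrix (compiled from 611
    faunal and floral foodstuffs; already era- and tissue-corrected and
    aggregated)."""
    return load_food_groups(Path(__file__).parent / "data" / "table1_food_groups.csv")
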