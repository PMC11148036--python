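"""Shotgun-lipidomics quantification and unsaturation profiling.

Peak areas of endogenous glycerophospholipid species are converted to
absolute amounts by reference to one spiked internal standard per headgroup
class, normalized to the protein content of the sample (pmol lipid per mg
protein).  Apoptotic-vs-control comparisons are replicate-paired fold
changes; saturation classes are keyed on the total number of double bonds
in the species label.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

HEADGROUP_CLASSES = frozenset(
    {"PC", "PE", "PI", "PS", "PG", "PA", "CL", "SM", "Cer"}
)

#: pmol of internal standard spiked per sample, per headgroup class
#: (17:0-20:4 glycerophospholipid standards of the shotgun workflow).
DEFAULT_STANDARD_AMOUNTS_PMOL = {
    "PC": 125.0,
    "PE": 138.0,
    "PI": 118.0,
    "PS": 118.0,
    "PG": 61.0,
    "PA": 72.0,
}

_LABEL_RE = re.compile(r"^\s*([A-Za-z]+)\s+(\d+):(\d+)\s*$")


@dataclass(frozen=True)
class LipidSpecies:
    """A lipid species at shotgun (sum-composition) resolution.

    ``label`` round-trips: ``LipidSpecies.from_label(s.label) == s``.
    """

    headgroup_class: str
    total_carbons: int
    double_bonds: int

    def __post_init__(self) -> None:
        if self.headgroup_class not in HEADGROUP_CLASSES:
            raise ValueError(f"unknown headgroup class {self.headgroup_class!r}")
        if self.total_carbons < 0 or self.double_bonds < 0:
            raise ValueError("carbons and double bonds must be non-negative")
        if self.double_bonds > self.total_carbons:
            raise ValueError(
                f"{self.double_bonds} double bonds exceed "
                f"{self.total_carbons} carbons"
            )

    @property
    def label(self) -> str:
        return f"{self.headgroup_class} {self.total_carbons}:{self.double_bonds}"

    @classmethod
    def from_label(cls, label: str) -> "LipidSpecies":
        m = _LABEL_RE.match(label)
        if m is None:
            raise ValueError(f"cannot parse species label {label!r}")
        return cls(m.group(1), int(m.group(2)), int(m.group(3)))

    @property
    def saturation_class(self) -> str:
        """'saturated' (0 double bonds), 'monounsaturated' (1) or
        'polyunsaturated' (>= 2)."""
        if self.double_bonds == 0:
            return "saturated"
        if self.double_bonds == 1:
            return "monounsaturated"
        return "polyunsaturated"


@dataclass(frozen=True)
class InternalStandard:
    """Spiked class standard: known amount, measured peak area."""

    headgroup_class: str
    amount_pmol: float
    peak_area: float

    def __post_init__(self) -> None:
        if self.amount_pmol <= 0:
            raise ValueError("standard amount must be positive")
        if self.peak_area <= 0:
            raise ValueError("standard peak area must be positive")


# CompositionTable: a DataFrame with columns
#   species (label str), headgroup_class, total_carbons, double_bonds,
#   condition, replicate, amount  [pmol/mg protein]
COMPOSITION_COLUMNS = [
    "species",
    "headgroup_class",
    "total_carbons",
    "double_bonds",
    "condition",
    "replicate",
    "amount",
]


def _species_row(label: str) -> dict:
    sp = LipidSpecies.from_label(label)
    return {
        "species": sp.label,
        "headgroup_class": sp.headgroup_class,
        "total_carbons": sp.total_carbons,
        "double_bonds": sp.double_bonds,
    }


def composition_table(
    records: list[dict], unit: str = "pmol/mg"
) -> pd.DataFrame:
    """Assemble a composition table from (species, condition, replicate,
    amount) records.  ``unit`` may be 'pmol/mg' or 'nmol/mg'; amounts are
    standardized to pmol/mg internally."""
    if unit not in ("pmol/mg", "nmol/mg"):
        raise ValueError(f"unsupported unit {unit!r}")
    scale = 1000.0 if unit == "nmol/mg" else 1.0
    rows = []
    for rec in records:
        row = _species_row(rec["species"])
        row["condition"] = rec["condition"]
        row["replicate"] = int(rec["replicate"])
        amount = float(rec["amount"]) * scale
        if amount < 0:
            raise ValueError("amounts must be non-negative")
        row["amount"] = amount
        rows.append(row)
    df = pd.DataFrame(rows, columns=COMPOSITION_COLUMNS)
    dup = df.duplicated(["species", "condition", "replicate"])
    if dup.any():
        raise ValueError("duplicate (species, condition, replicate) rows")
    return df


def read_composition_csv(path) -> pd.DataFrame:
    """Read a composition CSV (columns species, condition, replicate,
    amount, unit) into a standardized table."""
    raw = pd.read_csv(path)
    unit = raw["unit"].iloc[0] if "unit" in raw.columns else "pmol/mg"
    if "unit" in raw.columns and raw["unit"].nunique() > 1:
        raise ValueError("mixed units within one CSV are not supported")
    return composition_table(raw.to_dict("records"), unit=unit)


def quantify_species(
    peak_areas: dict[str, float],
    standards: dict[str, InternalStandard],
    protein_mg: float,
    condition: str = "sample",
    replicate: int = 1,
) -> pd.DataFrame:
    """Quantify species from peak areas against per-class internal standards.

    amount(s) = area(s) / area(IS_class) * amount_pmol(IS_class) / protein_mg,
    in pmol per mg protein.
    """
    if protein_mg <= 0:
        raise ValueError("protein mass must be positive")
    records = []
    for label, area in peak_areas.items():
        sp = LipidSpecies.from_label(label)
        std = standards.get(sp.headgroup_class)
        if std is None:
            raise KeyError(
                f"no internal standard for class {sp.headgroup_class!r}"
            )
        if area < 0:
            raise ValueError(f"negative peak area for {label!r}")
        amount = area / std.peak_area * std.amount_pmol / protein_mg
        records.append(
            {
                "species": label,
                "condition": condition,
                "replicate": replicate,
                "amount": amount,
            }
        )
    return composition_table(records)


def fold_change_table(
    apoptotic: pd.DataFrame, control: pd.DataFrame, drop_all_zero: bool = True
) -> pd.DataFrame:
    """Replicate-paired fold changes, apoptotic / control.

    Returns one row per species with columns ``mean_fc`` (mean over defined
    replicate FCs), ``n_replicates``, ``n_undefined`` (control = 0 cells,
    excluded from the mean) and per-replicate columns ``fc_r<k>``.  Rows are
    sorted in descending order of mean FC.  Species with zero amount in
    every replicate of both conditions are dropped when ``drop_all_zero``.
    """
    a = apoptotic.set_index(["species", "replicate"])["amount"]
    c = control.set_index(["species", "replicate"])["amount"]
    if set(a.index) != set(c.index):
        raise ValueError("apoptotic and control tables must share "
                         "(species, replicate) keys")
    c = c.reindex(a.index)
    if drop_all_zero:
        totals = a.groupby("species").sum() + c.groupby("species").sum()
        keep = totals[totals > 0].index
        a, c = a[a.index.get_level_values(0).isin(keep)], c[
            c.index.get_level_values(0).isin(keep)
        ]
    fc = a / c.replace(0.0, np.nan)
    n_undef = int(fc.isna().sum())
    if n_undef:
        warnings.warn(
            f"{n_undef} fold-change cell(s) undefined (control amount 0); "
            "excluded from means",
            stacklevel=2,
        )
    wide = fc.unstack("replicate")
    wide.columns = [f"fc_r{r}" for r in wide.columns]
    out = pd.DataFrame(
        {
            "mean_fc": wide.mean(axis=1, skipna=True),
            "n_replicates": wide.notna().sum(axis=1),
            "n_undefined": wide.isna().sum(axis=1),
        }
    ).join(wide)
    return out.sort_values("mean_fc", ascending=False)


def unsaturation_profile(table: pd.DataFrame) -> pd.DataFrame:
    """Per-headgroup-class amount fractions in saturated / monounsaturated /
    polyunsaturated species.  Fractions sum to 1 within each class."""
    if table.empty:
        raise ValueError("composition table is empty")
    t = table.copy()
    t["saturation"] = [
        LipidSpecies.from_label(s).saturation_class for s in t["species"]
    ]
    sums = t.groupby(["headgroup_class", "saturation"])["amount"].sum()
    prof = sums.unstack("saturation", fill_value=0.0).reindex(
        columns=["saturated", "monounsaturated", "polyunsaturated"],
        fill_value=0.0,
    )
    totals = prof.sum(axis=1)
    if (totals <= 0).any():
        raise ValueError("headgroup class with zero total amount")
    return prof.div(totals, axis=0)


@dataclass(frozen=True)
class PairedTestResult:
    t: float
    df: int
    p: float
    undefined: bool = False


def paired_class_test(
    control: np.ndarray, apoptotic: np.ndarray
) -> PairedTestResult:
    """Two-tailed paired t-test on replicate-matched values.

    Degenerate case (all differences identical, zero variance) is reported
    with ``undefined=True`` and NaN statistics rather than infinity.
    """
    control = np.asarray(control, dtype=float)
    apoptotic = np.asarray(apoptotic, dtype=float)
    if control.shape != apoptotic.shape:
        raise ValueError("paired vectors must have equal length")
    n = control.size
    if n < 2:
        raise ValueError("paired test needs at least 2 replicates")
    d = apoptotic - control
    sd = d.std(ddof=1)
    if sd == 0:
        return PairedTestResult(np.nan, n - 1, np.nan, undefined=True)
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return PairedTestResult(float(t), n - 1, float(p))
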