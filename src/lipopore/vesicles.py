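"""Vesicle permeabilization quantification.

Liposome (LUV) dye-release kinetics are normalized between a
liposome-only baseline and a detergent-lysed maximum; giant unilamellar
vesicle (GUV) tables of per-vesicle lumen/exterior/background intensities
yield a degree of filling per dye, from which the permeabilized fraction,
the permeabilization mechanism (all-or-none vs graded), pore stability
across sequentially added dyes and size selectivity between a small and a
large fluorescent marker are derived.  Cell-death kinetics are summarized
as trapezoidal area under the curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_THRESHOLD = 0.5  # degree-of-filling cutoff for "permeabilized"


def percent_release(
    ff: np.ndarray, fi: float, fm: float
) -> np.ndarray:
    """%release(t) = 100 (Ff - Fi) / (Fm - Fi).

    Fi is the liposome-only baseline, Fm the detergent (full-lysis)
    maximum; Ff = Fm gives exactly 100%.  Affine rescaling of all
    fluorescence values leaves the result unchanged.
    """
    if fm <= fi:
        raise ValueError("maximum fluorescence must exceed baseline")
    return 100.0 * (np.asarray(ff, dtype=float) - fi) / (fm - fi)


def endpoint_release(
    time_min: np.ndarray, release: np.ndarray, t_end: float = 60.0
) -> float:
    """%release at ``t_end`` (minutes), linearly interpolated between the
    flanking samples."""
    t = np.asarray(time_min, dtype=float)
    r = np.asarray(release, dtype=float)
    if t.size != r.size or t.size < 1:
        raise ValueError("time and release series must match and be nonempty")
    if not (t.min() <= t_end <= t.max()):
        raise ValueError(f"t_end = {t_end} outside observed range "
                         f"[{t.min()}, {t.max()}]")
    order = np.argsort(t)
    return float(np.interp(t_end, t[order], r[order]))


def degree_of_filling(
    lumen: float, exterior: float, background: float
) -> tuple[float, bool]:
    """DF = (lumen - background) / (exterior - background), clamped to
    [0, 1].  Returns (DF, clamped_flag)."""
    if exterior <= background:
        raise ValueError("exterior intensity must exceed background")
    raw = (lumen - background) / (exterior - background)
    clamped = raw < 0.0 or raw > 1.0
    return float(np.clip(raw, 0.0, 1.0)), clamped


def vesicle_table(records: pd.DataFrame | list[dict]) -> pd.DataFrame:
    """Build a per-vesicle table from rows of (vesicle_id, dye, lumen,
    exterior, background); adds ``df`` (degree of filling) and ``clamped``."""
    df = pd.DataFrame(records)
    out = []
    for _, row in df.iterrows():
        val, clamped = degree_of_filling(
            row["lumen"], row["exterior"], row["background"]
        )
        out.append({**row.to_dict(), "df": val, "clamped": clamped})
    return pd.DataFrame(out)


def percent_permeabilized(
    table: pd.DataFrame, dye: str, threshold: float = DEFAULT_THRESHOLD
) -> float:
    """Percentage of vesicles with DF_dye >= threshold."""
    sub = table[table["dye"] == dye]
    if sub.empty:
        raise ValueError(f"no vesicles measured for dye {dye!r}")
    return 100.0 * float((sub["df"] >= threshold).mean())


def threshold_sensitivity(
    table: pd.DataFrame, dye: str, thresholds=(0.3, 0.4, 0.5, 0.6, 0.7)
) -> pd.Series:
    """Permeabilized percentage across a range of DF cutoffs."""
    return pd.Series(
        {th: percent_permeabilized(table, dye, th) for th in thresholds},
        name=dye,
    )


@dataclass(frozen=True)
class MechanismResult:
    mechanism: str  # 'all_or_none' or 'graded'
    intermediate_fraction: float
    n: int


def classify_mechanism(
    dfs: np.ndarray,
    band: tuple[float, float] = (0.2, 0.8),
    max_intermediate: float = 0.10,
) -> MechanismResult:
    """All-or-none vs graded permeabilization from the DF distribution.

    All-or-none populations are bimodal (vesicles empty or full); graded
    populations carry mass at intermediate filling.  Classified all-or-none
    when the fraction of vesicles with DF strictly inside ``band`` is below
    ``max_intermediate``.
    """
    x = np.asarray(dfs, dtype=float)
    if x.size < 20:
        raise ValueError(f"insufficient vesicles ({x.size} < 20)")
    inter = float(((x > band[0]) & (x < band[1])).mean())
    mech = "all_or_none" if inter < max_intermediate else "graded"
    return MechanismResult(mech, inter, int(x.size))


@dataclass(frozen=True)
class StabilityResult:
    conditional: float  # P(dye2 filled | dye1 filled)
    joint: tuple[tuple[int, int], tuple[int, int]]  # 2x2 counts
    undefined: bool = False


def pore_stability(
    table: pd.DataFrame,
    dye1: str,
    dye2: str,
    threshold: float = DEFAULT_THRESHOLD,
) -> StabilityResult:
    """Fraction of dye1-filled vesicles also filled with a later dye2.

    A stable (long-lived or re-opening) pore fills both dyes; the joint
    2x2 filled/unfilled counts are returned alongside."""
    wide = table.pivot(index="vesicle_id", columns="dye", values="df")
    if dye1 not in wide.columns or dye2 not in wide.columns:
        raise ValueError("both dyes must be present in the table")
    wide = wide.dropna(subset=[dye1, dye2])
    f1 = wide[dye1] >= threshold
    f2 = wide[dye2] >= threshold
    joint = (
        (int((f1 & f2).sum()), int((f1 & ~f2).sum())),
        (int((~f1 & f2).sum()), int((~f1 & ~f2).sum())),
    )
    if not f1.any():
        return StabilityResult(np.nan, joint, undefined=True)
    return StabilityResult(float(f2[f1].mean()), joint)


SIZE_CLASSES = ("impermeable", "size_limited", "large_pore", "anomalous")


def size_selectivity(
    table: pd.DataFrame,
    small_marker: str = "small_12kDa",
    large_marker: str = "large_104kDa",
    threshold: float = DEFAULT_THRESHOLD,
) -> tuple[pd.Series, pd.Series]:
    """Classify vesicles by which size markers entered.

    impermeable: neither marker in; size_limited: small in, large out
    (pore passes ~12 kDa but excludes ~104 kDa); large_pore: both in;
    large-only entry is flagged anomalous.  Returns (per-vesicle classes,
    population fractions over the four classes).
    """
    wide = table.pivot(index="vesicle_id", columns="dye", values="df")
    for marker in (small_marker, large_marker):
        if marker not in wide.columns:
            raise ValueError(f"marker {marker!r} missing from table")
    wide = wide.dropna(subset=[small_marker, large_marker])
    small = wide[small_marker] >= threshold
    large = wide[large_marker] >= threshold
    classes = pd.Series(
        np.select(
            [~small & ~large, small & ~large, small & large],
            ["impermeable", "size_limited", "large_pore"],
            default="anomalous",
        ),
        index=wide.index,
        name="class",
    )
    fractions = (
        classes.value_counts(normalize=True)
        .reindex(SIZE_CLASSES, fill_value=0.0)
    )
    return classes, fractions


def auc_cell_death(time_h: np.ndarray, percent_positive: np.ndarray) -> float:
    """Trapezoidal area under a cell-death kinetics curve (% x h)."""
    t = np.asarray(time_h, dtype=float)
    y = np.asarray(percent_positive, dtype=float)
    if t.size != y.size or t.size < 2:
        raise ValueError("need matched time/value series of length >= 2")
    if not (np.diff(t) > 0).all():
        raise ValueError("time values must be strictly increasing")
    return float(np.trapezoid(y, t))
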