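"""Lipid enrichment near a membrane pore, with decorrelation-aware tests.

Per-frame counts of each lipid species among the pore-associated set are
reduced to time-uncorrelated segment means: the integrated autocorrelation
time is estimated for every species' count series, the largest one sets
the segment length, the same length is discarded from the start of each
replicate (decorrelation from the starting configuration), and the
remainder is cut into contiguous segments.  Fold-change enrichment is the
near-pore amount fraction of a species divided by its bulk leaflet
fraction, tested against 1 with a two-tailed one-sample t-test,
Bonferroni-corrected, with family-wise 99% confidence intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .pore import Trajectory, VicinitySpec, lipid_species_map, pore_associated_lipids


@dataclass(frozen=True)
class AutocorrResult:
    """Integrated autocorrelation time tau_int = dt (1 + 2 sum rho_k),
    summed over the initial positive sequence of lags."""

    tau_int: float  # ns
    window: int  # number of lags summed
    dt: float  # ns


@dataclass(frozen=True)
class EnrichmentResult:
    target: str
    mean_fc: float
    ci_low: float
    ci_high: float
    t: float
    df: int
    p_raw: float
    p_adj: float
    m: int
    n_segments: int
    undefined: bool = False

    @property
    def significant(self) -> bool:
        return (not self.undefined) and self.p_adj < 0.01


def species_counts_near_pore(
    traj: Trajectory,
    vic: VicinitySpec | None = None,
    leaflet: str = "cyto",
) -> pd.DataFrame:
    """Per-frame counts of each species among pore-associated lipids of one
    leaflet.  Frames with an empty vicinity yield all-zero rows (kept)."""
    vic = vic or VicinitySpec()
    species_in_leaflet: set[str] = set()
    for frame in traj:
        sel = frame.leaflet == leaflet
        species_in_leaflet.update(np.unique(frame.species[sel]).tolist())
    all_species = sorted(species_in_leaflet)
    rows = []
    for t, frame in enumerate(traj):
        near = pore_associated_lipids(frame, vic)[leaflet]
        smap = lipid_species_map(frame)
        counts = {s: 0 for s in all_species}
        for lid in near:
            counts[smap[lid]] += 1
        for s in all_species:
            rows.append(
                {
                    "replicate": traj.replicate,
                    "frame": t,
                    "species": s,
                    "leaflet": leaflet,
                    "count": counts[s],
                }
            )
    return pd.DataFrame(rows)


def integrated_autocorr_time(
    series: np.ndarray, dt: float = 1.0
) -> AutocorrResult:
    """Integrated autocorrelation time of a time series.

    tau_int = dt * (1 + 2 * sum_{k=1..W} rho_k), with W the lag before the
    first negative autocorrelation (initial positive sequence window).
    """
    x = np.asarray(series, dtype=float)
    if x.size < 50:
        raise ValueError("series too short for autocorrelation estimate "
                         f"({x.size} < 50)")
    x = x - x.mean()
    var = np.dot(x, x) / x.size
    if var == 0:
        raise ValueError("zero variance: constant series")
    n = x.size
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n].real / n
    rho = acov / acov[0]
    neg = np.nonzero(rho[1:] < 0)[0]
    window = int(neg[0]) if neg.size else n - 1
    tau = dt * (1.0 + 2.0 * rho[1 : window + 1].sum())
    return AutocorrResult(tau_int=max(float(tau), dt), window=window, dt=dt)


def segment_series(
    values: np.ndarray, tau_max: float, dt: float = 1.0
) -> np.ndarray:
    """Cut one replicate's per-frame values into decorrelated segment means.

    The first tau_max of the series is discarded (decorrelation from the
    starting configuration); the remainder is partitioned into contiguous
    segments of length tau_max, whose means are returned.  ``values`` may
    be 1-D (one quantity) or 2-D (frames x quantities); NaN frames are
    excluded from segment means.
    """
    v = np.asarray(values, dtype=float)
    n = v.shape[0]
    block = max(1, int(round(tau_max / dt)))
    if n <= 3 * block:
        raise ValueError(
            f"insufficient sampling: {n} frames for segment length {block}"
        )
    v = v[block:]
    n_seg = v.shape[0] // block
    if n_seg < 3:
        raise ValueError(f"insufficient sampling: only {n_seg} segments")
    v = v[: n_seg * block]
    shaped = v.reshape((n_seg, block) + v.shape[1:])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = np.nanmean(shaped, axis=1)
    return means


def fold_change_enrichment(
    segment_fractions: np.ndarray,
    species: list[str],
    leaflet_composition: dict[str, float],
) -> pd.DataFrame:
    """Per-segment fold changes FC(s) = near-pore fraction / leaflet fraction.

    ``segment_fractions`` is (n_segments, n_species) of near-pore amount
    fractions (each row sums to 1).  Leaflet fractions must be positive for
    every species present.
    """
    comp = np.array([leaflet_composition.get(s, 0.0) for s in species])
    if (comp <= 0).any():
        missing = [s for s, c in zip(species, comp) if c <= 0]
        raise ValueError(f"leaflet fraction is zero for {missing}")
    total = sum(leaflet_composition.values())
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"leaflet composition sums to {total}, expected 1")
    fc = np.asarray(segment_fractions, dtype=float) / comp
    return pd.DataFrame(fc, columns=species)


def test_enrichment(
    segment_fcs: np.ndarray, m: int = 1, target: str = ""
) -> EnrichmentResult:
    """Two-tailed one-sample t-test of segment fold changes against 1.

    Bonferroni adjustment over ``m`` comparisons: p_adj = min(1, m p); the
    confidence interval is family-wise 99% (per-test level 1 - 0.01/m).
    """
    x = np.asarray(segment_fcs, dtype=float)
    x = x[~np.isnan(x)]
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 segment values")
    if m < 1:
        raise ValueError("m must be >= 1")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    df = n - 1
    if sd == 0:
        return EnrichmentResult(
            target, mean, mean, mean, np.nan, df, np.nan, np.nan, m, n,
            undefined=True,
        )
    se = sd / np.sqrt(n)
    t = (mean - 1.0) / se
    p = 2.0 * stats.t.sf(abs(t), df=df)
    p_adj = min(1.0, m * p)
    tcrit = stats.t.ppf(1.0 - (0.01 / m) / 2.0, df=df)
    return EnrichmentResult(
        target=target,
        mean_fc=mean,
        ci_low=mean - tcrit * se,
        ci_high=mean + tcrit * se,
        t=float(t),
        df=df,
        p_raw=float(p),
        p_adj=float(p_adj),
        m=m,
        n_segments=n,
    )


def _fractions_per_frame(pivot: pd.DataFrame) -> np.ndarray:
    """Counts (frames x species) -> amount fractions; zero-total frames NaN."""
    counts = pivot.to_numpy(dtype=float)
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(totals > 0, counts / totals, np.nan)
    n_empty = int((totals == 0).sum())
    if n_empty:
        warnings.warn(
            f"{n_empty} frame(s) with no pore-associated lipids excluded "
            "from segment means",
            stacklevel=3,
        )
    return frac


def analyze_enrichment(
    counts: pd.DataFrame,
    leaflet_composition: dict[str, float],
    dt_ns: float = 1.0,
    m: int | None = None,
    by_headgroup: bool = False,
    test_population: str = "segments",
) -> tuple[pd.DataFrame, dict]:
    """Full enrichment analysis from a per-frame count table.

    ``counts`` has columns replicate, frame, species, count (one leaflet).
    Steps: estimate tau_int per species count series per replicate, take the
    largest as the segment length, segment each replicate's per-frame
    fraction vectors, form fold changes against ``leaflet_composition``,
    and t-test each species (Bonferroni m = number of targets by default).

    ``by_headgroup=True`` aggregates species to their headgroup class
    before the analysis.  ``test_population`` is 'segments' (pooled segment
    means across replicates; default) or 'replicates' (test on the
    per-replicate averages, n = number of replicates).

    Returns (result table, info dict with tau_max_ns, segment length and
    per-replicate segment counts).
    """
    df = counts.copy()
    if by_headgroup:
        df["species"] = df["species"].str.split(" ").str[0]
        df = (
            df.groupby(["replicate", "frame", "species"], as_index=False)[
                "count"
            ].sum()
        )
        comp: dict[str, float] = {}
        for s, f in leaflet_composition.items():
            cls = s.split(" ")[0]
            comp[cls] = comp.get(cls, 0.0) + f
        leaflet_composition = comp

    species = sorted(df["species"].unique())
    replicates = sorted(df["replicate"].unique())

    # largest integrated autocorrelation time over species and replicates
    tau_max = dt_ns
    for rep in replicates:
        sub = df[df["replicate"] == rep]
        pivot = sub.pivot(index="frame", columns="species", values="count")
        for s in species:
            x = pivot[s].to_numpy(dtype=float)
            if np.ptp(x) == 0:
                continue  # constant count series carries no timescale
            tau = integrated_autocorr_time(x, dt=dt_ns).tau_int
            tau_max = max(tau_max, tau)

    seg_fcs = []
    rep_means = []
    n_segments = {}
    for rep in replicates:
        sub = df[df["replicate"] == rep]
        pivot = (
            sub.pivot(index="frame", columns="species", values="count")
            .reindex(columns=species)
            .sort_index()
        )
        frac = _fractions_per_frame(pivot)
        seg = segment_series(frac, tau_max, dt=dt_ns)
        fc = fold_change_enrichment(seg, species, leaflet_composition)
        seg_fcs.append(fc)
        rep_means.append(fc.mean(axis=0))
        n_segments[rep] = len(fc)

    pooled = pd.concat(seg_fcs, ignore_index=True)
    m_eff = m if m is not None else len(species)
    if test_population == "segments":
        test_data = pooled
    elif test_population == "replicates":
        test_data = pd.DataFrame(rep_means)
    else:
        raise ValueError("test_population must be 'segments' or 'replicates'")

    results = [
        test_enrichment(test_data[s].to_numpy(), m=m_eff, target=s)
        for s in species
    ]
    table = pd.DataFrame([r.__dict__ for r in results]).set_index("target")
    info = {
        "tau_max_ns": tau_max,
        "segment_frames": max(1, int(round(tau_max / dt_ns))),
        "n_segments": n_segments,
        "replicate_means": pd.DataFrame(rep_means, index=replicates),
    }
    return table, info
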