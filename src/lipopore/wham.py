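"""Umbrella-sampling free-energy reconstruction along the pore coordinate.

Harmonically biased windows along xi in [0, 1] are combined with the
weighted histogram analysis method (WHAM): the unbiased bin probabilities
P(xi_b) and window free energies F_i are iterated to self-consistency,

    P(b) = sum_i n_i(b) / sum_i N_i exp[(F_i - w_i(b)) / kT]
    F_i  = -kT ln sum_b P(b) exp(-w_i(b) / kT)

and the potential of mean force is G = -kT ln P, shifted so its minimum is
zero.  Errors are estimated by Monte-Carlo block bootstrap that respects
the time correlation of each window's samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .enrichment import integrated_autocorr_time

KB = 0.0083145  # kJ/mol/K


@dataclass
class UmbrellaWindow:
    """One harmonic umbrella window: bias w(xi) = k/2 (xi - center)^2."""

    center: float
    stiffness: float  # kJ/mol per unit xi^2
    samples: np.ndarray
    temperature: float = 300.0  # K
    offset: float = 0.0  # constant added to the bias; cancels in WHAM

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.stiffness < 0:
            raise ValueError("stiffness must be non-negative")
        if self.samples.size and (
            self.samples.min() < 0.0 or self.samples.max() > 1.0
        ):
            raise ValueError("samples must lie within [0, 1]")

    @property
    def kT(self) -> float:
        return KB * self.temperature


@dataclass
class PMFProfile:
    """Free-energy profile G(xi) in kJ/mol, minimum shifted to zero.

    Bins never visited by any window are masked (NaN), not extrapolated.
    """

    bin_centers: np.ndarray
    free_energy: np.ndarray
    error: np.ndarray | None = None
    kT: float = KB * 300.0
    window_free_energies: np.ndarray | None = None
    n_iterations: int = 0

    def interpolate(self, xi: float) -> float:
        valid = np.isfinite(self.free_energy)
        lo, hi = self.bin_centers[valid][0], self.bin_centers[valid][-1]
        if not lo <= xi <= hi:
            raise ValueError(
                f"xi = {xi} outside profile support [{lo:.3f}, {hi:.3f}]"
            )
        return float(
            np.interp(xi, self.bin_centers[valid], self.free_energy[valid])
        )


def bias_potential(window: UmbrellaWindow, xi) -> np.ndarray | float:
    """Harmonic umbrella bias w(xi) = k/2 (xi - c)^2, kJ/mol."""
    xi = np.asarray(xi, dtype=float)
    out = 0.5 * window.stiffness * (xi - window.center) ** 2 + window.offset
    return float(out) if out.ndim == 0 else out


def _check_overlap(hists: np.ndarray) -> None:
    """Require the window-overlap graph (shared occupied bins) connected."""
    n_win = hists.shape[0]
    occupied = hists > 0
    adj = (occupied[:, None, :] & occupied[None, :, :]).any(axis=2)
    seen = np.zeros(n_win, dtype=bool)
    stack = [0]
    seen[0] = True
    while stack:
        i = stack.pop()
        for j in np.nonzero(adj[i] & ~seen)[0]:
            seen[j] = True
            stack.append(j)
    if not seen.all():
        missing = np.nonzero(~seen)[0]
        raise ValueError(
            "umbrella windows do not overlap into a connected ladder; "
            f"window indices {missing.tolist()} are disconnected from window 0"
        )


def wham_solve(
    windows: list[UmbrellaWindow],
    n_bins: int = 200,
    tol: float = 1e-6,
    max_iter: int = 100_000,
    xi_range: tuple[float, float] = (0.0, 1.0),
) -> PMFProfile:
    """Solve the WHAM equations over ``n_bins`` uniform bins on xi_range.

    Converged when every window free energy F_i moves by less than ``tol``
    kJ/mol between iterations.  Raises on a disconnected window ladder or
    if ``max_iter`` is exhausted.
    """
    if not windows:
        raise ValueError("no umbrella windows given")
    kT = windows[0].kT
    edges = np.linspace(xi_range[0], xi_range[1], n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    hists = np.stack(
        [np.histogram(w.samples, bins=edges)[0].astype(float) for w in windows]
    )
    if len(windows) > 1:
        _check_overlap(hists)
    n_tot = hists.sum(axis=0)  # per-bin total counts
    N = hists.sum(axis=1)  # per-window sample counts
    bias = np.stack(
        [bias_potential(w, centers) for w in windows]
    )  # (n_win, n_bins)
    boltz = np.exp(-bias / kT)

    F = np.zeros(len(windows))
    visited = n_tot > 0
    for it in range(1, max_iter + 1):
        denom = (N[:, None] * np.exp(F[:, None] / kT) * boltz).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            P = np.where(visited, n_tot / denom, 0.0)
        weights = (P[None, :] * boltz).sum(axis=1)
        F_new = -kT * np.log(weights)
        F_new -= F_new[0]  # gauge: first window fixed
        delta = np.abs(F_new - F).max()
        F = F_new
        if delta < tol:
            break
    else:
        raise RuntimeError(
            f"WHAM did not converge in {max_iter} iterations "
            f"(residual {delta:.3g} kJ/mol)"
        )

    with np.errstate(divide="ignore"):
        G = np.where(visited, -kT * np.log(np.where(visited, P, 1.0)), np.nan)
    G -= np.nanmin(G)
    return PMFProfile(
        bin_centers=centers,
        free_energy=G,
        kT=kT,
        window_free_energies=F,
        n_iterations=it,
    )


def _block_resample(
    samples: np.ndarray, block: int, rng: np.random.Generator
) -> np.ndarray:
    """Circular block bootstrap preserving within-block time correlation."""
    n = samples.size
    n_blocks = int(np.ceil(n / block))
    starts = rng.integers(0, n, size=n_blocks)
    idx = (starts[:, None] + np.arange(block)[None, :]) % n
    return samples[idx.ravel()[:n]]


def pmf_error_bootstrap(
    windows: list[UmbrellaWindow],
    n_boot: int = 50,
    seed: int = 0,
    n_bins: int = 200,
    tol: float = 1e-6,
    max_iter: int = 100_000,
    xi_range: tuple[float, float] = (0.0, 1.0),
) -> np.ndarray:
    """Per-bin bootstrap standard deviation of the PMF (kJ/mol).

    Each window's samples are resampled in blocks of its integrated
    autocorrelation time and the full WHAM solve repeated ``n_boot`` times.
    """
    if n_boot < 20:
        raise ValueError("n_boot must be at least 20")
    rng = np.random.default_rng(seed)
    blocks = []
    for w in windows:
        try:
            tau = integrated_autocorr_time(w.samples, dt=1.0).tau_int
        except ValueError:  # short or constant window series
            tau = 1.0
        blocks.append(max(1, int(round(tau))))
    profiles = []
    for _ in range(n_boot):
        resampled = [
            UmbrellaWindow(
                center=w.center,
                stiffness=w.stiffness,
                samples=_block_resample(w.samples, b, rng),
                temperature=w.temperature,
            )
            for w, b in zip(windows, blocks)
        ]
        prof = wham_solve(
            resampled, n_bins=n_bins, tol=tol, max_iter=max_iter,
            xi_range=xi_range,
        )
        profiles.append(prof.free_energy)
    arr = np.stack(profiles)
    return np.nanstd(arr, axis=0, ddof=1)


def pore_free_energy(
    profile: PMFProfile, xi_flat: float, xi_open: float
) -> float:
    """Free-energy cost of pore opening, G(xi_open) - G(xi_flat), kJ/mol.
    Invariant to any additive offset of the profile."""
    return profile.interpolate(xi_open) - profile.interpolate(xi_flat)


def compare_profiles(
    p1: PMFProfile, p2: PMFProfile, xi_flat: float, xi_open: float
) -> float:
    """Difference in pore-opening cost between two conditions (kJ/mol)."""
    return pore_free_energy(p1, xi_flat, xi_open) - pore_free_energy(
        p2, xi_flat, xi_open
    )


def read_wham_metadata(meta_path) -> list[UmbrellaWindow]:
    """Read umbrella windows from a Grossfield-dialect metadata file:
    one line per window ``path center stiffness`` (# comments allowed);
    each window file holds two columns, time and xi."""
    import os

    windows = []
    base = os.path.dirname(str(meta_path))
    with open(meta_path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            path, center, stiffness = parts[0], float(parts[1]), float(parts[2])
            if not os.path.isabs(path):
                path = os.path.join(base, path)
            data = np.loadtxt(path)
            windows.append(
                UmbrellaWindow(
                    center=center, stiffness=stiffness, samples=data[:, 1]
                )
            )
    return windows


def write_window_files(windows: list[UmbrellaWindow], out_dir, dt: float = 1.0):
    """Write windows as two-column (time, xi) text plus a metadata file in
    the Grossfield dialect; returns the metadata path."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    meta_path = os.path.join(str(out_dir), "metadata.txt")
    with open(meta_path, "w") as meta:
        for i, w in enumerate(windows):
            name = f"window_{i:03d}.txt"
            path = os.path.join(str(out_dir), name)
            times = np.arange(w.samples.size) * dt
            np.savetxt(path, np.column_stack([times, w.samples]), fmt="%.6f")
            meta.write(f"{name} {w.center:.10g} {w.stiffness:.10g}\n")
    return meta_path
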