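"""Synthetic data with known ground truth for every analysis stage.

The generators emulate, at toy scale, the data each pipeline stage
consumes: a two-leaflet bead membrane with an optional toroidal pore and
controllable per-species enrichment in the pore vicinity, temporally
autocorrelated near-pore count series, Boltzmann samples from analytic
free-energy landscapes under harmonic umbrella biases, GUV populations
under all-or-none vs graded filling, and paired lipidomics tables with a
built-in unsaturation shift.  Each generator is a pure function of its
parameters and seed and returns its ground truth alongside the data.

The membrane geometry is deliberately minimal (3-bead lipids, 4 nm
head-to-head thickness, hard near/far placement zones): it exercises the
geometric selections and the statistics, not membrane physics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lipidomics import LipidSpecies, composition_table
from .pore import ParticleConfiguration, Trajectory
from .wham import KB, UmbrellaWindow

# ---------------------------------------------------------------------------
# membrane / enrichment generators

#: Default per-leaflet composition (species -> lipid count): a mixed
#: PC/PE/PI/PS/PG outer-membrane-like leaflet of 150 lipids.
DEFAULT_LEAFLET_COUNTS = {
    "PC 34:1": 35,
    "PC 36:2": 20,
    "PC 38:4": 15,
    "PE 34:1": 20,
    "PE 36:2": 12,
    "PE 38:4": 15,
    "PI 38:4": 12,
    "PS 36:1": 12,
    "PG 34:1": 9,
}

#: Base probability that a lipid of weight 1 sits in the pore vicinity:
#: the area fraction of a 4 nm vicinity cylinder in a 20 x 20 nm patch.
DEFAULT_NEAR_PROB = 0.125

_HALF_THICKNESS = 2.0  # nm, head planes at +-2 from midplane
_TAIL1_Z = 1.2
_TAIL2_Z = 0.4
_PORE_RADIUS = 1.4  # open-pore channel radius (inside the 1.5 nm CV radius)
_NEAR_ZONE = (1.8, 3.8)  # radial band for pore-associated lipids
_FAR_MARGIN = 0.3  # gap beyond the vicinity radius before the far zone


def enrichment_ground_truth(
    counts: dict[str, int],
    weights: dict[str, float] | None = None,
    near_prob: float = DEFAULT_NEAR_PROB,
) -> dict:
    """Stationary near-pore composition and fold changes of the lipid
    near/far Markov model (exact, not simulated)."""
    weights = weights or {}
    species = sorted(counts)
    n = np.array([counts[s] for s in species], dtype=float)
    w = np.array([weights.get(s, 1.0) for s in species], dtype=float)
    if (w < 0).any():
        raise ValueError("enrichment weights must be non-negative")
    q = np.clip(near_prob * w, 0.0, 0.95)
    bulk = n / n.sum()
    near = n * q / (n * q).sum()
    return {
        "species": species,
        "bulk_fraction": dict(zip(species, bulk)),
        "near_fraction": dict(zip(species, near)),
        "fold_change": dict(zip(species, near / bulk)),
        "near_prob": dict(zip(species, q)),
    }


def _simulate_near_states(
    n_lipids: int,
    q: np.ndarray,
    phi: float,
    n_frames: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Two-state (near/far) Markov chains, one per lipid, with stationary
    near-probability q[i] and indicator autocorrelation phi^k.

    Transition probabilities: stay-near = phi + (1-phi) q, far->near =
    (1-phi) q; the chain starts in its stationary distribution.  Returns a
    boolean (n_frames, n_lipids) array.
    """
    if not 0.0 <= phi < 1.0:
        raise ValueError("phi must be in [0, 1)")
    states = np.empty((n_frames, n_lipids), dtype=bool)
    states[0] = rng.random(n_lipids) < q
    for t in range(1, n_frames):
        u = rng.random(n_lipids)
        p_near = np.where(states[t - 1], phi + (1 - phi) * q, (1 - phi) * q)
        states[t] = u < p_near
    return states


def gen_count_series(
    counts: dict[str, int] | None = None,
    weights: dict[str, float] | None = None,
    n_frames: int = 1000,
    n_replicates: int = 3,
    phi: float = 0.6,
    near_prob: float = DEFAULT_NEAR_PROB,
    dt_ns: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Near-pore count series straight from the lipid state machine.

    This is the coordinate-free fast path of the trajectory generator: the
    same per-lipid near/far Markov chains, tabulated directly as per-frame
    (replicate, frame, species, count) rows without bead placement.
    Returns (long count table, ground truth).  The ground truth includes
    the exact stationary fold changes and tau_int = dt (1+phi)/(1-phi).
    """
    counts = counts or dict(DEFAULT_LEAFLET_COUNTS)
    truth = enrichment_ground_truth(counts, weights, near_prob)
    species = truth["species"]
    q_per_lipid = np.concatenate(
        [np.full(counts[s], truth["near_prob"][s]) for s in species]
    )
    labels = np.concatenate(
        [np.full(counts[s], i, dtype=int) for i, s in enumerate(species)]
    )
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_replicates):
        states = _simulate_near_states(
            q_per_lipid.size, q_per_lipid, phi, n_frames, rng
        )
        # per-frame counts by species: sum indicator over lipids of species
        for i, s in enumerate(species):
            c = states[:, labels == i].sum(axis=1)
            rows.append(
                pd.DataFrame(
                    {
                        "replicate": rep,
                        "frame": np.arange(n_frames),
                        "species": s,
                        "count": c,
                    }
                )
            )
    table = pd.concat(rows, ignore_index=True)
    truth["tau_int"] = dt_ns * (1 + phi) / (1 - phi)
    truth["phi"] = phi
    truth["dt_ns"] = dt_ns
    return table, truth


@dataclass
class MembraneTrajectoryConfig:
    """Parameters of the toy bead-membrane trajectory generator."""

    seed: int = 0
    box: tuple[float, float, float] = (20.0, 20.0, 10.0)
    leaflet_counts: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_LEAFLET_COUNTS)
    )
    pore: str = "open"  # 'open' or 'none'
    enrichment_weights: dict[str, float] = field(default_factory=dict)
    n_frames: int = 50
    dt_ns: float = 1.0
    phi: float = 0.6
    near_prob: float = DEFAULT_NEAR_PROB
    vicinity_radius: float = 4.0
    replicate: int = 0


def _annulus_positions(
    n: int, r_lo: float, r_hi: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform positions in an annulus, returned as (r, theta)."""
    u = rng.random(n)
    r = np.sqrt(u * (r_hi**2 - r_lo**2) + r_lo**2)
    theta = rng.random(n) * 2 * np.pi
    return r, theta


def gen_membrane_trajectory(
    cfg: MembraneTrajectoryConfig,
) -> tuple[Trajectory, dict]:
    """Toy bilayer trajectory with controllable pore and lipid enrichment.

    Lipids are 3-bead stacks (head at the leaflet plane +-2 nm from the
    midplane, first tail and second tail beads toward it).  Each lipid
    follows the near/far Markov chain of :func:`gen_count_series`; lipids
    in the near state are placed inside the vicinity cylinder (outside the
    pore channel), far lipids outside it.  A static polar scaffold provides
    bulk water above and below the membrane inside the pore-coordinate
    cylinder; with ``pore='open'`` the channel itself is lined with water
    beads and rim headgroups, driving the pore coordinate toward 1.
    """
    rng = np.random.default_rng(cfg.seed)
    Lx, Ly, Lz = cfg.box
    axis = (Lx / 2.0, Ly / 2.0)
    z0 = Lz / 2.0
    truth = enrichment_ground_truth(
        cfg.leaflet_counts, cfg.enrichment_weights, cfg.near_prob
    )
    species = truth["species"]
    n_leaf = sum(cfg.leaflet_counts.values())
    r_max = min(Lx, Ly) / 2.0 - 0.5

    # per-lipid species labels and near-state chains, both leaflets
    sp_per_lipid = np.concatenate(
        [np.full(cfg.leaflet_counts[s], s) for s in species]
    )
    q = np.array([truth["near_prob"][s] for s in sp_per_lipid])
    leaflets = ["cyto", "ims"]
    states = {
        leaf: _simulate_near_states(n_leaf, q, cfg.phi, cfg.n_frames, rng)
        for leaf in leaflets
    }

    # static polar scaffold (water columns inside the CV cylinder)
    water_xyz = []
    bulk_z = np.arange(2.1, _HALF_THICKNESS * 2 - 0.05, 0.2)
    for dz in np.concatenate([bulk_z, -bulk_z]):
        water_xyz.append((axis[0] + 0.3, axis[1], z0 + dz))
    if cfg.pore == "open":
        chan_z = np.arange(0.1, 2.05, 0.2)
        for dz in np.concatenate([chan_z, -chan_z]):
            water_xyz.append((axis[0], axis[1] + 0.2, z0 + dz))
    elif cfg.pore != "none":
        raise ValueError("pore must be 'open' or 'none'")
    water_xyz = np.array(water_xyz)

    # rim headgroups lining the open pore (static, unassigned to lipids)
    rim_xyz = []
    if cfg.pore == "open":
        for ang in np.linspace(0, 2 * np.pi, 12, endpoint=False):
            for dz in (-1.0, 0.0, 1.0):
                rim_xyz.append(
                    (
                        axis[0] + _PORE_RADIUS * np.cos(ang),
                        axis[1] + _PORE_RADIUS * np.sin(ang),
                        z0 + dz,
                    )
                )
    rim_xyz = np.array(rim_xyz).reshape(-1, 3)

    near_lo, near_hi = _NEAR_ZONE[0], min(
        _NEAR_ZONE[1], cfg.vicinity_radius - 0.2
    )
    far_lo = cfg.vicinity_radius + _FAR_MARGIN

    frames = []
    # persistent lateral positions; resampled on state change, jittered else
    r_now = {leaf: np.empty(n_leaf) for leaf in leaflets}
    th_now = {leaf: np.empty(n_leaf) for leaf in leaflets}
    for t in range(cfg.n_frames):
        bead_xyz, bead_lid, bead_sp, bead_leaf, bead_role = [], [], [], [], []
        for li, leaf in enumerate(leaflets):
            s_now = states[leaf][t]
            if t == 0:
                changed = np.ones(n_leaf, dtype=bool)
            else:
                changed = s_now != states[leaf][t - 1]
            for zone, sel in (("near", s_now), ("far", ~s_now)):
                pick = changed & sel
                npick = int(pick.sum())
                if npick:
                    lo, hi = (
                        (near_lo, near_hi) if zone == "near" else (far_lo, r_max)
                    )
                    r_new, th_new = _annulus_positions(npick, lo, hi, rng)
                    r_now[leaf][pick] = r_new
                    th_now[leaf][pick] = th_new
            # in-zone angular jitter (keeps radius band, so zone membership)
            th_now[leaf] += rng.normal(0.0, 0.05, n_leaf)

            zsign = 1.0 if leaf == "cyto" else -1.0
            x = axis[0] + r_now[leaf] * np.cos(th_now[leaf])
            y = axis[1] + r_now[leaf] * np.sin(th_now[leaf])
            for role, dz in (
                ("head", _HALF_THICKNESS),
                ("tail_first", _TAIL1_Z),
                ("tail_other", _TAIL2_Z),
            ):
                bead_xyz.append(
                    np.column_stack([x, y, np.full(n_leaf, z0 + zsign * dz)])
                )
                bead_lid.append(np.arange(n_leaf) + li * n_leaf)
                bead_sp.append(sp_per_lipid)
                bead_leaf.append(np.full(n_leaf, leaf))
                bead_role.append(np.full(n_leaf, role))
        # scaffold
        n_w = len(water_xyz)
        bead_xyz.append(water_xyz)
        bead_lid.append(np.full(n_w, -1))
        bead_sp.append(np.full(n_w, "W"))
        bead_leaf.append(np.full(n_w, "none"))
        bead_role.append(np.full(n_w, "water"))
        if len(rim_xyz):
            n_r = len(rim_xyz)
            bead_xyz.append(rim_xyz)
            bead_lid.append(np.full(n_r, -1))
            bead_sp.append(np.full(n_r, "RIM"))
            bead_leaf.append(np.full(n_r, "none"))
            bead_role.append(np.full(n_r, "head"))

        frames.append(
            ParticleConfiguration(
                xyz=np.concatenate(bead_xyz),
                lipid_id=np.concatenate(bead_lid),
                species=np.concatenate(bead_sp),
                leaflet=np.concatenate(bead_leaf),
                role=np.concatenate(bead_role),
                box=cfg.box,
                pore_axis=axis,
            )
        )
    truth["tau_int"] = cfg.dt_ns * (1 + cfg.phi) / (1 - cfg.phi)
    truth["phi"] = cfg.phi
    traj = Trajectory(frames=frames, dt_ns=cfg.dt_ns, replicate=cfg.replicate)
    return traj, truth


# ---------------------------------------------------------------------------
# time-series generator

def gen_ar1_series(
    n: int, phi: float, sigma: float = 1.0, dt: float = 1.0, seed: int = 0
) -> tuple[np.ndarray, dict]:
    """AR(1) series x_t = phi x_{t-1} + eps, eps ~ N(0, sigma^2).

    True integrated autocorrelation time: tau_int = dt (1+phi)/(1-phi).
    The chain starts in its stationary distribution.
    """
    if abs(phi) >= 1:
        raise ValueError("AR(1) requires |phi| < 1")
    rng = np.random.default_rng(seed)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sigma / np.sqrt(1 - phi**2))
    eps = rng.normal(0.0, sigma, n)
    for t in range(1, n):
        x[t] = phi * x[t - 1] + eps[t]
    return x, {"tau_int": dt * (1 + phi) / (1 - phi), "phi": phi, "dt": dt}


# ---------------------------------------------------------------------------
# umbrella-sampling generator

def cosine_landscape(barrier: float = 20.0):
    """Analytic landscape G(xi) = B [1 - cos(2 pi xi)] / 2: minima at the
    ends, a barrier of height B (kJ/mol) at xi = 0.5."""

    def G(xi):
        return barrier * (1.0 - np.cos(2 * np.pi * np.asarray(xi))) / 2.0

    return G


def gen_umbrella_dataset(
    pmf,
    centers: np.ndarray,
    stiffness: float = 400.0,
    n_per_window: int = 20_000,
    temperature: float = 300.0,
    burn_in: int = 2_000,
    step: float = 0.08,
    thin: int = 5,
    seed: int = 0,
) -> tuple[list[UmbrellaWindow], dict]:
    """Metropolis samples from exp(-[G(xi) + k/2 (xi-c)^2]/kT) per window.

    All windows are advanced in lockstep (vectorized chains); proposals
    falling outside [0, 1] are rejected.  Every ``thin``-th state after
    burn-in is recorded, reducing the chain autocorrelation of the
    returned samples.  A warning is attached to the ground truth when any
    window's acceptance rate leaves [0.1, 0.9].
    """
    centers = np.asarray(centers, dtype=float)
    kT = KB * temperature
    rng = np.random.default_rng(seed)
    x = centers.copy()
    energy = pmf(x) + 0.5 * stiffness * (x - centers) ** 2
    n_win = centers.size
    if thin < 1:
        raise ValueError("thin must be >= 1")
    kept = np.empty((n_per_window, n_win))
    accepted = np.zeros(n_win)
    total = burn_in + n_per_window * thin
    for it in range(total):
        prop = x + rng.normal(0.0, step, n_win)
        ok = (prop >= 0.0) & (prop <= 1.0)
        e_prop = np.where(
            ok, pmf(prop) + 0.5 * stiffness * (prop - centers) ** 2, np.inf
        )
        accept = rng.random(n_win) < np.exp(np.minimum(0.0, -(e_prop - energy) / kT))
        accept &= ok
        x = np.where(accept, prop, x)
        energy = np.where(accept, e_prop, energy)
        if it >= burn_in:
            if (it - burn_in) % thin == 0:
                kept[(it - burn_in) // thin] = x
            accepted += accept
    rates = accepted / (n_per_window * thin)
    warnings_ = []
    if ((rates < 0.1) | (rates > 0.9)).any():
        warnings_.append(
            "Metropolis acceptance outside [0.1, 0.9] for some windows; "
            f"adjust step (current {step})"
        )
    windows = [
        UmbrellaWindow(
            center=float(c),
            stiffness=stiffness,
            samples=kept[:, i],
            temperature=temperature,
        )
        for i, c in enumerate(centers)
    ]
    truth = {
        "pmf": pmf,
        "kT": kT,
        "acceptance_rates": rates,
        "warnings": warnings_,
    }
    return windows, truth


# ---------------------------------------------------------------------------
# vesicle generator

def gen_vesicle_population(
    n: int,
    mechanism: str = "all_or_none",
    p_perm: float = 0.6,
    stability: float = 0.9,
    size_limited: bool = False,
    include_size_markers: bool = False,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """GUV population with known permeabilization mechanism.

    all_or_none: DF ~ p Beta(20,1) + (1-p) Beta(1,20) (empty-or-full
    bimodal); graded: DF ~ Beta(5,5).  A second dye fills a dye1-filled
    vesicle with probability ``stability`` (open-or-reopening pore).  With
    ``include_size_markers``, a 12 kDa-like marker mirrors dye1 and a
    104 kDa-like marker is excluded (DF near 0) when ``size_limited``.

    Intensities are emitted as (lumen, exterior, background) = (bg + DF *
    span, bg + span, bg), so degree_of_filling recovers DF exactly.
    """
    if n < 1:
        raise ValueError("need at least one vesicle")
    rng = np.random.default_rng(seed)
    bg, span = 10.0, 100.0

    def draw_full(k):
        return rng.beta(20, 1, k)

    def draw_empty(k):
        return rng.beta(1, 20, k)

    if mechanism == "all_or_none":
        filled1 = rng.random(n) < p_perm
        df1 = np.where(filled1, draw_full(n), draw_empty(n))
        filled2 = filled1 & (rng.random(n) < stability)
        df2 = np.where(filled2, draw_full(n), draw_empty(n))
    elif mechanism == "graded":
        df1 = rng.beta(5, 5, n)
        df2 = np.clip(df1 * stability + rng.normal(0, 0.05, n), 0, 1)
        filled1 = df1 >= 0.5
    else:
        raise ValueError("mechanism must be 'all_or_none' or 'graded'")

    rows = []
    markers = {"dye1": df1, "dye2": df2}
    if include_size_markers:
        markers["small_12kDa"] = df1
        markers["large_104kDa"] = (
            draw_empty(n) if size_limited
            else np.where(filled1, draw_full(n), draw_empty(n))
        )
    for dye, dfs in markers.items():
        for vid, d in enumerate(dfs):
            rows.append(
                {
                    "vesicle_id": vid,
                    "dye": dye,
                    "lumen": bg + d * span,
                    "exterior": bg + span,
                    "background": bg,
                }
            )
    truth = {
        "mechanism": mechanism,
        "p_perm": p_perm,
        "stability": stability,
        "size_limited": size_limited,
    }
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# lipidomics generator

def gen_lipidomics_pair(
    n_species: int = 20,
    unsat_shift: float = 0.5,
    noise: float = 0.15,
    n_replicates: int = 4,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Paired control/apoptotic composition tables with an unsaturation
    shift: apoptotic amounts of polyunsaturated species are multiplied by
    (1 + shift) and saturated species by 1/(1 + shift) (monounsaturated
    unchanged), with lognormal replicate noise of scale ``noise``.
    """
    if unsat_shift < 0:
        raise ValueError("shift must be non-negative")
    rng = np.random.default_rng(seed)
    classes = ["PC", "PE", "PI", "PS", "PG"]
    dbs = [0, 1, 2, 4, 6]
    labels = []
    i = 0
    while len(labels) < n_species:
        cls = classes[i % len(classes)]
        db = dbs[(i // len(classes)) % len(dbs)]
        carbons = 32 + 2 * (i % 5)
        label = f"{cls} {carbons}:{db}"
        if label not in labels:
            labels.append(label)
        i += 1
    base = rng.lognormal(mean=3.0, sigma=0.8, size=n_species)  # pmol/mg

    def shift_factor(label: str) -> float:
        sp = LipidSpecies.from_label(label)
        if sp.saturation_class == "polyunsaturated":
            return 1.0 + unsat_shift
        if sp.saturation_class == "saturated":
            return 1.0 / (1.0 + unsat_shift)
        return 1.0

    recs_c, recs_a = [], []
    for rep in range(1, n_replicates + 1):
        for label, amount in zip(labels, base):
            eps_c = rng.lognormal(0.0, noise)
            eps_a = rng.lognormal(0.0, noise)
            recs_c.append(
                {"species": label, "condition": "control",
                 "replicate": rep, "amount": amount * eps_c}
            )
            recs_a.append(
                {"species": label, "condition": "apoptotic",
                 "replicate": rep, "amount": amount * shift_factor(label) * eps_a}
            )
    truth = {
        "shift": unsat_shift,
        "true_fc": {lbl: shift_factor(lbl) for lbl in labels},
        "n_replicates": n_replicates,
    }
    return composition_table(recs_c), composition_table(recs_a), truth
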