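"""Asymmetric coarse-grained membrane composition.

Turns a measured lipid composition into a two-leaflet membrane build
specification: headgroup classes are split between the cytoplasmic and
intermembrane-space (IMS) leaflets using literature asymmetry fractions,
species fractions are converted to integer per-leaflet counts by
largest-remainder rounding (with a minimum count per retained species,
merging rare tail variants into their nearest same-class neighbour), and
leaflet areas are matched by proportionally removing lipids from the
leaflet with the larger expected area so the juxtaposed bilayer is
tension-free.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .lipidomics import LipidSpecies

#: Fraction of each headgroup class assigned to the cytoplasmic leaflet of
#: the mitochondrial outer membrane (complement goes to the IMS leaflet).
#: PG is a minority component with no measured asymmetry; 50/50 is assumed.
DEFAULT_ASYMMETRY = {
    "PS": 0.30,
    "PI": 0.30,
    "PE": 0.77,
    "PC": 0.55,
    "PG": 0.50,
}

#: Net charge per headgroup class at neutral pH (coarse-grained models).
CLASS_CHARGE = {
    "PC": 0, "PE": 0, "PS": -1, "PI": -1, "PG": -1, "PA": -1, "CL": -2,
    "SM": 0, "Cer": 0,
}

WATER_MOLARITY = 55.5  # mol/L, for converting ionic strength to ion counts


@dataclass
class MembraneSpec:
    """Integer build recipe for an asymmetric bilayer patch."""

    box_x: float  # nm
    box_y: float  # nm
    counts_cyto: dict[str, int]
    counts_ims: dict[str, int]
    apl_cyto: float  # nm^2 per lipid
    apl_ims: float
    hydration: int = 25  # waters per lipid
    ionic_strength: float = 0.15  # mol/L
    flipped_asymmetry: bool = False
    n_water: int = 0
    n_cation: int = 0
    n_anion: int = 0

    @property
    def n_lipids(self) -> int:
        return sum(self.counts_cyto.values()) + sum(self.counts_ims.values())

    def insane_string(self) -> str:
        """Composition in the ``-l SPECIES:COUNT`` dialect of bilayer
        builders (upper leaflet = cytoplasmic, ``-u``; lower = IMS, ``-l``).
        Species labels are compacted ('PC 34:1' -> 'PC34.1') so the colon
        separates name from count unambiguously."""

        def code(s: str) -> str:
            return s.replace(" ", "").replace(":", ".")

        upper = " ".join(
            f"-u {code(s)}:{n}" for s, n in sorted(self.counts_cyto.items())
        )
        lower = " ".join(
            f"-l {code(s)}:{n}" for s, n in sorted(self.counts_ims.items())
        )
        return f"{upper} {lower}"

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


def split_leaflets(
    class_fractions: dict[str, float],
    asymmetry: dict[str, float] | None = None,
    flip: bool = False,
    strict: bool = False,
) -> tuple[dict[str, float], dict[str, float]]:
    """Split whole-membrane class fractions into (cytoplasmic, IMS) shares.

    ``asymmetry[c]`` is the cytoplasmic share of class ``c``; ``flip=True``
    reads the table the other way round (the literature ratio notation does
    not fix the leaflet order).  Classes absent from the table default to
    50/50 with a warning, or raise if ``strict``.
    """
    asym = dict(DEFAULT_ASYMMETRY if asymmetry is None else asymmetry)
    total = sum(class_fractions.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"class fractions sum to {total}, expected 1")
    cyto: dict[str, float] = {}
    ims: dict[str, float] = {}
    for cls, f in class_fractions.items():
        if cls not in asym:
            if strict:
                raise KeyError(f"class {cls!r} missing from asymmetry table")
            warnings.warn(
                f"no asymmetry fraction for class {cls!r}; assuming 50/50",
                stacklevel=2,
            )
            asym[cls] = 0.5
        a = asym[cls]
        if not 0.0 <= a <= 1.0:
            raise ValueError(f"asymmetry fraction for {cls!r} outside [0,1]")
        if flip:
            a = 1.0 - a
        cyto[cls] = f * a
        ims[cls] = f * (1.0 - a)
    return cyto, ims


def _largest_remainder(fractions: dict[str, float], n: int) -> dict[str, int]:
    """Hamilton apportionment of ``n`` units over ``fractions`` (renormalized).

    Ties in remainder broken by descending fraction, then species label.
    """
    keys = list(fractions)
    f = np.array([fractions[k] for k in keys], dtype=float)
    if (f < 0).any():
        raise ValueError("fractions must be non-negative")
    f = f / f.sum()
    quota = f * n
    base = np.floor(quota).astype(int)
    short = n - int(base.sum())
    remainder = quota - base
    order = sorted(
        range(len(keys)),
        key=lambda i: (-remainder[i], -f[i], keys[i]),
    )
    for i in order[:short]:
        base[i] += 1
    return {k: int(c) for k, c in zip(keys, base)}


def _merge_partner(label: str, candidates: list[str]) -> str | None:
    """Nearest same-headgroup species: minimize |dC| then |d double bonds|."""
    sp = LipidSpecies.from_label(label)
    best = None
    best_key = None
    for cand in candidates:
        other = LipidSpecies.from_label(cand)
        if other.headgroup_class != sp.headgroup_class:
            continue
        key = (
            abs(other.total_carbons - sp.total_carbons),
            abs(other.double_bonds - sp.double_bonds),
            cand,
        )
        if best_key is None or key < best_key:
            best, best_key = cand, key
    return best


def allocate_counts(
    leaflet_fractions: dict[str, float],
    n_leaflet: int,
    min_count: int = 5,
) -> dict[str, int]:
    """Integer species counts for one leaflet.

    Largest-remainder rounding to exactly ``n_leaflet``; any species landing
    below ``min_count`` is merged into the same-class species with the
    nearest tail composition and the remainder re-rounded, until every
    retained species has at least ``min_count`` lipids.
    """
    if n_leaflet <= 0:
        raise ValueError("n_leaflet must be positive")
    fractions = {
        k: v for k, v in leaflet_fractions.items() if v > 0
    }
    while True:
        counts = _largest_remainder(fractions, n_leaflet)
        small = [k for k, c in counts.items() if c < min_count]
        if not small:
            return counts
        # merge the scarcest offender first, then re-round
        victim = min(small, key=lambda k: (counts[k], k))
        partner = _merge_partner(
            victim, [k for k in fractions if k != victim]
        )
        if partner is None:
            cls = LipidSpecies.from_label(victim).headgroup_class
            raise ValueError(
                f"class {cls!r} cannot reach {min_count} lipids per leaflet "
                f"and has no merge partner"
            )
        fractions[partner] += fractions.pop(victim)


def match_leaflet_areas(
    counts_a: dict[str, int],
    apl_a: float,
    counts_b: dict[str, int],
    apl_b: float,
    min_count: int = 5,
) -> tuple[dict[str, int], dict[str, int]]:
    """Remove lipids from the higher-area leaflet so expected areas match.

    The leaflet with the larger expected area N*APL is trimmed to
    ``round(N_other * apl_other / apl_self)`` lipids, the removal spread
    proportionally across species by largest remainder.  Species pushed
    below ``min_count`` are merged into their nearest same-class neighbour
    and the trim retried.
    """
    if apl_a <= 0 or apl_b <= 0:
        raise ValueError("area-per-lipid values must be positive")
    n_a, n_b = sum(counts_a.values()), sum(counts_b.values())
    area_a, area_b = n_a * apl_a, n_b * apl_b
    if np.isclose(area_a, area_b, atol=min(apl_a, apl_b) * 0.5):
        return dict(counts_a), dict(counts_b)
    if area_a > area_b:
        target = int(round(area_b / apl_a))
        trimmed = _trim_proportionally(counts_a, target, min_count)
        return trimmed, dict(counts_b)
    target = int(round(area_a / apl_b))
    trimmed = _trim_proportionally(counts_b, target, min_count)
    return dict(counts_a), trimmed


def _trim_proportionally(
    counts: dict[str, int], target: int, min_count: int
) -> dict[str, int]:
    fractions = {k: float(c) for k, c in counts.items()}
    while True:
        new = _largest_remainder(fractions, target)
        small = [k for k, c in new.items() if c < min_count]
        if not small:
            return new
        victim = min(small, key=lambda k: (new[k], k))
        partner = _merge_partner(victim, [k for k in fractions if k != victim])
        if partner is None:
            raise ValueError(
                f"cannot trim leaflet to {target} lipids without pushing "
                f"{victim!r} below {min_count} (no merge partner)"
            )
        fractions[partner] += fractions.pop(victim)


def compose_membrane(
    species_fractions: dict[str, float],
    box_x: float,
    box_y: float,
    apl_cyto: float,
    apl_ims: float,
    asymmetry: dict[str, float] | None = None,
    flip_asymmetry: bool = False,
    min_count: int = 5,
    hydration: int = 25,
    ionic_strength: float = 0.15,
) -> MembraneSpec:
    """Full composition chain: class split -> integer allocation -> area match.

    ``species_fractions`` are whole-membrane amount fractions by species
    label (e.g. from a lipidomics composition table).  Hydration and ion
    counts are recorded (no coordinates): waters = hydration x total lipids;
    ion pairs for the requested ionic strength relative to water, plus
    cations neutralizing the net lipid charge.
    """
    total = sum(species_fractions.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError("species fractions must sum to 1")
    class_fractions: dict[str, float] = {}
    for label, f in species_fractions.items():
        cls = LipidSpecies.from_label(label).headgroup_class
        class_fractions[cls] = class_fractions.get(cls, 0.0) + f
    cyto_cls, ims_cls = split_leaflets(
        class_fractions, asymmetry, flip=flip_asymmetry
    )
    # within-class species proportions carry over unchanged to each leaflet
    def leaflet_species(cls_shares: dict[str, float]) -> dict[str, float]:
        out = {}
        for label, f in species_fractions.items():
            cls = LipidSpecies.from_label(label).headgroup_class
            if class_fractions[cls] > 0:
                out[label] = f / class_fractions[cls] * cls_shares[cls]
        s = sum(out.values())
        return {k: v / s for k, v in out.items()}

    box_area = box_x * box_y
    n_cyto = int(round(box_area / apl_cyto))
    n_ims = int(round(box_area / apl_ims))
    counts_cyto = allocate_counts(leaflet_species(cyto_cls), n_cyto, min_count)
    counts_ims = allocate_counts(leaflet_species(ims_cls), n_ims, min_count)
    counts_cyto, counts_ims = match_leaflet_areas(
        counts_cyto, apl_cyto, counts_ims, apl_ims, min_count
    )

    n_lip = sum(counts_cyto.values()) + sum(counts_ims.values())
    n_water = hydration * n_lip
    lipid_charge = sum(
        CLASS_CHARGE.get(LipidSpecies.from_label(s).headgroup_class, 0) * n
        for counts in (counts_cyto, counts_ims)
        for s, n in counts.items()
    )
    n_pairs = int(round(ionic_strength * n_water / WATER_MOLARITY))
    n_cation = n_pairs + max(0, -lipid_charge)
    n_anion = n_pairs + max(0, lipid_charge)

    return MembraneSpec(
        box_x=box_x,
        box_y=box_y,
        counts_cyto=counts_cyto,
        counts_ims=counts_ims,
        apl_cyto=apl_cyto,
        apl_ims=apl_ims,
        hydration=hydration,
        ionic_strength=ionic_strength,
        flipped_asymmetry=flip_asymmetry,
        n_water=n_water,
        n_cation=n_cation,
        n_anion=n_anion,
    )
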