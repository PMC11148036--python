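"""Coordinate-file interoperability.

Configurations can be read from GRO/PDB (and trajectories from XTC/DCD)
through MDAnalysis.  Because standard coordinate formats carry no notion of
species, leaflet or bead role, a YAML *bead map* supplies the annotation:

    species:            # residue name -> species label
      POPC: "PC 34:1"
    roles:              # atom/bead name -> role
      NC3: head
      PO4: head
      C1A: tail_first
      GL1: glycerol
      W:   water
      NA:  ion
      CL:  ion
    solvent_residues: [W, ION, NA, CL]

Leaflet assignment, when not given explicitly, is geometric: lipids whose
head beads sit above the membrane midplane are 'cyto', below are 'ims'.
"""

from __future__ import annotations

import numpy as np
import yaml

from .pore import ParticleConfiguration, Trajectory


def load_beadmap(path) -> dict:
    with open(path) as fh:
        bm = yaml.safe_load(fh)
    for key in ("species", "roles"):
        if key not in bm:
            raise ValueError(f"bead map missing {key!r} section")
    bm.setdefault("solvent_residues", [])
    return bm


def _annotate(universe, beadmap: dict) -> ParticleConfiguration:
    atoms = universe.atoms
    n = len(atoms)
    resnames = atoms.resnames
    names = atoms.names
    solvent = np.isin(resnames, list(beadmap["solvent_residues"]))

    species = np.array(
        [beadmap["species"].get(rn, "") for rn in resnames], dtype=object
    )
    role = np.array(
        [beadmap["roles"].get(nm, "tail_other") for nm in names], dtype=object
    )
    role[solvent & (role == "tail_other")] = "water"

    lipid_id = np.where(solvent, -1, atoms.resids).astype(int)
    xyz = atoms.positions / 10.0  # Angstrom -> nm
    box = tuple(float(v) / 10.0 for v in universe.dimensions[:3])

    # geometric leaflet call from head-bead height vs midplane
    leaflet = np.full(n, "none", dtype=object)
    heads = (role == "head") & ~solvent
    if heads.any():
        mid = xyz[heads, 2].mean()
        for lid in np.unique(lipid_id[lipid_id >= 0]):
            sel = lipid_id == lid
            h = sel & heads
            zref = xyz[h, 2].mean() if h.any() else xyz[sel, 2].mean()
            leaflet[sel] = "cyto" if zref >= mid else "ims"

    return ParticleConfiguration(
        xyz=xyz,
        lipid_id=lipid_id,
        species=species.astype(str),
        leaflet=leaflet.astype(str),
        role=role.astype(str),
        box=box,
    )


def load_configuration(path, beadmap: dict | str) -> ParticleConfiguration:
    """Read a single GRO/PDB frame into an annotated configuration."""
    import MDAnalysis as mda

    if isinstance(beadmap, str):
        beadmap = load_beadmap(beadmap)
    u = mda.Universe(str(path))
    return _annotate(u, beadmap)


def load_trajectory(
    topology, trajectory, beadmap: dict | str, dt_ns: float = 1.0
) -> Trajectory:
    """Read an XTC/DCD trajectory (with GRO/PDB topology) frame by frame."""
    import MDAnalysis as mda

    if isinstance(beadmap, str):
        beadmap = load_beadmap(beadmap)
    u = mda.Universe(str(topology), str(trajectory))
    frames = []
    for _ in u.trajectory:
        frames.append(_annotate(u, beadmap))
    return Trajectory(frames=frames, dt_ns=dt_ns)


def write_gro(path, config: ParticleConfiguration, title: str = "lipopore") -> None:
    """Write a configuration as a GRO file (bead names from roles, residue
    names from a compacted species label)."""
    role_names = {
        "head": "HD",
        "tail_first": "T1",
        "tail_other": "TX",
        "glycerol": "GL",
        "water": "W",
        "ion": "ION",
    }
    with open(path, "w") as fh:
        fh.write(f"{title}\n{config.n_beads}\n")
        for i in range(config.n_beads):
            lid = int(config.lipid_id[i])
            if lid < 0:
                resname = "SOL"
                resid = 99999 - (0 if config.role[i] == "water" else 1)
            else:
                resname = str(config.species[i]).replace(" ", "").replace(":", "")[:5]
                resid = (lid % 99999) + 1
            name = role_names.get(str(config.role[i]), "X")
            x, y, z = config.xyz[i]
            fh.write(
                f"{resid:>5d}{resname:<5s}{name:>5s}{(i % 99999) + 1:>5d}"
                f"{x:8.3f}{y:8.3f}{z:8.3f}\n"
            )
        fh.write(f"{config.box[0]:10.5f}{config.box[1]:10.5f}{config.box[2]:10.5f}\n")
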