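"""Bead-spring topologies and direct-coexistence system assembly.

Molecules are either linear polyampholyte chains or star polymers: ``f``
copies of the same arm sequence covalently attached to a central, purely
repulsive CORE bead.  The star construction models oligomerization of an
IDR on a multimeric scaffold; ``f`` is the valence.

Assembly places two species p and q at equal polyampholyte mass fraction in
a periodic orthorhombic box; the box is later compressed by the dynamics
engine and extended along z into a slab for direct-coexistence analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from .sequences import ChargeSequence

CORE_TYPE = "CORE"
BOND_LENGTH = 3.8  # Å, Cα–Cα virtual bond of the coarse-grained chain


@dataclass
class SystemTopology:
    """Beads, bonds and molecule bookkeeping for one or many molecules.

    Arrays are per-bead except ``species`` and ``valence`` (per molecule).
    """

    bead_types: np.ndarray      # (N,) unicode: "K", "E" or "CORE"
    charges: np.ndarray         # (N,) float
    bonds: np.ndarray           # (B, 2) int
    molecule_id: np.ndarray     # (N,) int
    species: np.ndarray         # (n_mol,) unicode, e.g. "p"/"q"
    valence: np.ndarray         # (n_mol,) int, 1 = linear

    @property
    def n_beads(self) -> int:
        return len(self.bead_types)

    @property
    def n_molecules(self) -> int:
        return len(self.species)

    @property
    def is_polyampholyte(self) -> np.ndarray:
        """Mask of K/E beads (CORE scaffold beads excluded)."""
        return self.bead_types != CORE_TYPE

    def species_mask(self, label: str, include_core: bool = False) -> np.ndarray:
        mask = self.species[self.molecule_id] == label
        if not include_core:
            mask &= self.is_polyampholyte
        return mask

    def validate(self) -> None:
        n = self.n_beads
        if self.bonds.size and (self.bonds.min() < 0 or self.bonds.max() >= n):
            raise ValueError("bond indices out of range")
        # per-molecule connectivity/acyclicity: beads - bonds = #molecules
        if n - len(self.bonds) != self.n_molecules:
            raise ValueError("bond graph is not a forest of one tree per molecule")


def build_linear(seq: ChargeSequence, species: str = "p") -> SystemTopology:
    """A single linear chain: N beads, N-1 consecutive bonds."""
    n = len(seq)
    if n < 2:
        raise ValueError("a chain needs at least 2 residues")
    bonds = np.column_stack([np.arange(n - 1), np.arange(1, n)])
    return SystemTopology(
        bead_types=np.array(list(seq.residues)),
        charges=seq.charges.copy(),
        bonds=bonds.astype(np.int64),
        molecule_id=np.zeros(n, dtype=np.int64),
        species=np.array([species]),
        valence=np.array([1]),
    )


def build_star(seq: ChargeSequence, f: int, species: str = "p") -> SystemTopology:
    """A star polymer: ``f`` arms of the sequence bonded to one CORE bead.

    The core (bead 0) is charge-free and purely repulsive; each arm's first
    residue bonds to it, so the molecule has f*L + 1 beads and f*L bonds.
    """
    if f < 1:
        raise ValueError("valence f must be >= 1")
    length = len(seq)
    if length < 2:
        raise ValueError("arms need at least 2 residues")
    types = [CORE_TYPE]
    charges = [0.0]
    bonds = []
    for arm in range(f):
        start = 1 + arm * length
        types.extend(seq.residues)
        charges.extend(seq.charges)
        bonds.append((0, start))
        for i in range(length - 1):
            bonds.append((start + i, start + i + 1))
    return SystemTopology(
        bead_types=np.array(types),
        charges=np.array(charges),
        bonds=np.array(bonds, dtype=np.int64),
        molecule_id=np.zeros(f * length + 1, dtype=np.int64),
        species=np.array([species]),
        valence=np.array([f]),
    )


def concat_topologies(tops: list[SystemTopology]) -> SystemTopology:
    """Merge molecule topologies, reindexing beads, bonds and molecule ids."""
    bead_off = 0
    mol_off = 0
    types, charges, bonds, mol_ids, species, valence = [], [], [], [], [], []
    for t in tops:
        types.append(t.bead_types)
        charges.append(t.charges)
        if len(t.bonds):
            bonds.append(t.bonds + bead_off)
        mol_ids.append(t.molecule_id + mol_off)
        species.append(t.species)
        valence.append(t.valence)
        bead_off += t.n_beads
        mol_off += t.n_molecules
    return SystemTopology(
        bead_types=np.concatenate(types),
        charges=np.concatenate(charges),
        bonds=np.concatenate(bonds) if bonds else np.empty((0, 2), dtype=np.int64),
        molecule_id=np.concatenate(mol_ids),
        species=np.concatenate(species),
        valence=np.concatenate(valence),
    )


@dataclass
class BoxedConfiguration:
    """Bead coordinates in a fully periodic orthorhombic box (Å)."""

    positions: np.ndarray       # (N, 3)
    box: np.ndarray             # (3,) edge lengths
    periodic: bool = True

    def wrapped(self) -> np.ndarray:
        return np.mod(self.positions, self.box)

    @property
    def volume(self) -> float:
        return float(np.prod(self.box))

    @property
    def area_xy(self) -> float:
        return float(self.box[0] * self.box[1])


# ---------------------------------------------------------------------------
# assembly


def balanced_copy_numbers(
    mass_p: int, mass_q: int, beads_p: int, beads_q: int, total_beads: int
) -> tuple[int, int]:
    """Copy numbers for an equal-mass binary mixture near a bead-count target.

    ``mass_*`` are polyampholyte bead counts per molecule (the mass proxy;
    CORE beads do not enter the balance), ``beads_*`` the full bead counts.
    Enumerate n_p and pick the (n_p, n_q) whose polyampholyte masses differ
    by at most one molecule's worth, minimizing the bead-count error.
    """
    best = None
    max_np = max(1, total_beads // beads_p + 1)
    for n_p in range(1, max_np + 1):
        n_q = max(1, round(n_p * mass_p / mass_q))
        imbalance = abs(n_p * mass_p - n_q * mass_q)
        if imbalance > max(mass_p, mass_q):
            continue
        bead_err = abs(n_p * beads_p + n_q * beads_q - total_beads)
        key = (bead_err, imbalance, n_p)
        if best is None or key < best[0]:
            best = (key, (n_p, n_q))
    if best is None:
        raise ValueError("no balanced stoichiometry found for the bead target")
    return best[1]


def _grow_molecule(
    top: SystemTopology, rng: np.random.Generator, exclusion: float,
    core_arm_gap: float = 6.0,
) -> np.ndarray:
    """Self-avoiding random-walk conformation of one molecule, core at origin."""
    n = top.n_beads
    neighbours: dict[int, list[int]] = {i: [] for i in range(n)}
    for a, b in top.bonds:
        neighbours[int(a)].append(int(b))
        neighbours[int(b)].append(int(a))
    is_core = top.bead_types[0] == CORE_TYPE
    excl2 = exclusion * exclusion
    # the self-avoiding walk can suffer attrition (no admissible direction);
    # restart the molecule rather than accept an overlapping bead
    for _ in range(50):
        pos = np.zeros((n, 3))
        placed = [0]
        stack = [0]
        stuck = False
        while stack and not stuck:
            parent = stack.pop()
            for child in neighbours[parent]:
                if child in placed:
                    continue
                step = core_arm_gap if is_core and parent == 0 else BOND_LENGTH
                ok = False
                for _ in range(200):
                    u = rng.normal(size=3)
                    u /= np.linalg.norm(u)
                    cand = pos[parent] + step * u
                    d2 = np.sum((pos[placed] - cand) ** 2, axis=1)
                    # parent (bonded) may be close; all other placed beads
                    # must respect the exclusion distance
                    d2[placed.index(parent)] = np.inf
                    if np.all(d2 > excl2):
                        ok = True
                        break
                if not ok:
                    stuck = True
                    break
                pos[child] = cand
                placed.append(child)
                stack.append(child)
        if not stuck:
            return pos
    raise RuntimeError(
        "self-avoiding growth failed repeatedly; molecule too dense for the "
        f"exclusion distance {exclusion}")


def assemble_binary_mixture(
    top_p: SystemTopology,
    top_q: SystemTopology,
    total_beads: int,
    box_edge: float,
    seed: int,
    exclusion: float = 5.3,
    max_attempts: int = 500,
) -> tuple[BoxedConfiguration, SystemTopology]:
    """Randomly place both species at equal polyampholyte mass fraction.

    Molecules get random conformations, rotations and positions, rejection
    sampled so that no inter-molecular bead pair sits closer than
    ``exclusion`` (default 0.9x the smallest bead σ).  Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    mass_p = int(np.sum(top_p.is_polyampholyte))
    mass_q = int(np.sum(top_q.is_polyampholyte))
    n_p, n_q = balanced_copy_numbers(
        mass_p, mass_q, top_p.n_beads, top_q.n_beads, total_beads
    )
    mols = [replace(top_p, species=np.array(["p"])) for _ in range(n_p)]
    mols += [replace(top_q, species=np.array(["q"])) for _ in range(n_q)]
    order = rng.permutation(len(mols))
    box = np.array([box_edge] * 3, dtype=float)

    placed_pos: list[np.ndarray] = []
    tree: cKDTree | None = None
    for mi in order:
        mol = mols[mi]
        local = _grow_molecule(mol, rng, exclusion)
        ok = False
        for _ in range(max_attempts):
            # random rotation via QR of a Gaussian matrix
            qmat, r = np.linalg.qr(rng.normal(size=(3, 3)))
            qmat *= np.sign(np.diag(r))
            cand = local @ qmat.T + rng.uniform(0, box_edge, size=3)
            cand = np.mod(cand, box)
            if tree is None or not tree.query_ball_point(
                cand, exclusion, return_length=True
            ).any():
                ok = True
                break
        if not ok:
            density = sum(len(p) for p in placed_pos) / float(np.prod(box))
            raise RuntimeError(
                f"molecule placement failed at bead density {density:.4f}/Å³; "
                "increase the box or lower the bead target"
            )
        placed_pos.append(cand)
        tree = cKDTree(np.concatenate(placed_pos), boxsize=box)

    topology = concat_topologies([mols[i] for i in order])
    topology.validate()
    positions = np.concatenate(placed_pos)
    return BoxedConfiguration(positions=positions, box=box), topology


def compress_box(
    config: BoxedConfiguration,
    target_edge: float | np.ndarray,
    engine,
    n_steps: int = 2000,
) -> BoxedConfiguration:
    """Shrink the box to ``target_edge`` over ``n_steps`` dynamics steps.

    ``engine`` is a dynamics handle (see :class:`kemix.engine.Simulator`)
    already holding ``config``; the box is rescaled geometrically a little
    each step with dynamics running, so overlaps relax as the system densifies.
    """
    if n_steps < 1:
        raise ValueError("compression needs at least one step")
    target = np.broadcast_to(np.asarray(target_edge, dtype=float), (3,))
    if np.any(target >= config.box):
        raise ValueError("target edges must be smaller than current edges")
    factors = (target / config.box) ** (1.0 / n_steps)
    for _ in range(n_steps):
        engine.rescale_box(engine.box * factors)
        engine.step(1)
    engine.set_box(target.copy())
    return engine.configuration()


def make_slab(
    config: BoxedConfiguration,
    lz_target: float,
    topology: SystemTopology | None = None,
) -> BoxedConfiguration:
    """Extend the box along z, centring the dense region at Lz/2.

    Positions are untouched apart from recentring: a rigid z-shift (circular
    mean over the old periodic z) plus, when a topology is given, per-molecule
    unwrapping along the bond tree so no molecule is split across the old z
    boundary (which would turn bonds into hugely stretched springs once the
    periodic image moves Lz_target - Lz away).  x/y edges are unchanged.
    """
    lz_old = float(config.box[2])
    if lz_target <= lz_old:
        raise ValueError("slab Lz must exceed the current Lz")
    pos = config.wrapped()
    z = pos[:, 2].copy()
    theta = 2 * np.pi * z / lz_old
    zc = (np.arctan2(np.sin(theta).mean(), np.cos(theta).mean()) / (2 * np.pi)) \
        * lz_old % lz_old
    if topology is not None and len(topology.bonds):
        # unwrap each molecule's z along its bond tree
        neigh: dict[int, list[int]] = {}
        for a, b in topology.bonds:
            neigh.setdefault(int(a), []).append(int(b))
            neigh.setdefault(int(b), []).append(int(a))
        seen = np.zeros(len(z), dtype=bool)
        for root in range(len(z)):
            if seen[root]:
                continue
            seen[root] = True
            stack = [root]
            while stack:
                i = stack.pop()
                for j in neigh.get(i, ()):
                    if seen[j]:
                        continue
                    dz = z[j] - z[i]
                    z[j] = z[i] + dz - lz_old * np.rint(dz / lz_old)
                    seen[j] = True
                    stack.append(j)
        # bring each molecule's centre into the old primary cell around zc
        zrel = z - zc
        for mol in range(topology.n_molecules):
            sel = topology.molecule_id == mol
            centre = zrel[sel].mean()
            zrel[sel] -= lz_old * np.rint(centre / lz_old)
    else:
        zrel = (z - zc + lz_old / 2) % lz_old - lz_old / 2
    new_box = config.box.copy()
    new_box[2] = lz_target
    new_pos = pos.copy()
    new_pos[:, 2] = zrel + lz_target / 2
    return BoxedConfiguration(positions=new_pos, box=new_box)


def export_xyz(config: BoxedConfiguration, top: SystemTopology, path) -> None:
    """Plain-text XYZ snapshot for visualization."""
    pos = config.wrapped()
    with open(path, "w") as fh:
        fh.write(f"{top.n_beads}\n")
        fh.write(f'box="{config.box[0]} {config.box[1]} {config.box[2]}"\n')
        for t, p in zip(top.bead_types, pos):
            el = {"K": "N", "E": "O", CORE_TYPE: "S"}.get(t, "C")
            fh.write(f"{el} {p[0]:.3f} {p[1]:.3f} {p[2]:.3f}\n")
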