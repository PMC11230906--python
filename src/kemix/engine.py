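"""Implicit-solvent coarse-grained Langevin dynamics.

The integrator is the BAOAB splitting of Langevin dynamics: half-kick,
half-drift, exact Ornstein–Uhlenbeck velocity update, half-drift, half-kick.
With friction = 0 the O step is the identity and the scheme reduces to
velocity Verlet, which is used as an energy-conservation oracle.

The pressure tensor diagonal is the standard virial expression per axis,
P_aa = (Σ m v_a² + Σ_pairs F_a d_a) / V, including bond contributions, from
which interfacial tension follows via the mechanical (Kirkwood) route.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from . import _kernels
from .forcefield import KB, TIME_UNIT_FS, ForceFieldParams, default_forcefield
from .topology import BoxedConfiguration, SystemTopology


class EngineInstability(RuntimeError):
    """Raised when the dynamics diverge; partial outputs are attached."""

    def __init__(self, message: str, trajectory: "Trajectory | None" = None):
        super().__init__(message)
        self.trajectory = trajectory


def pair_energy(ff: ForceFieldParams, type_i: int, type_j: int, r: float) -> float:
    """Reference (scalar, pure-Python) pair energy: AH + Debye–Hückel, shifted.

    ``type_i``/``type_j`` are type codes (0=K, 1=E, 2=CORE).  Continuous at
    the 2^{1/6}σ_ij switch point and zero beyond each cutoff.
    """
    if r <= 0:
        raise ValueError("pair distance must be positive")
    sij = ff.sigma_pair[type_i, type_j]
    lij = ff.lambda_pair[type_i, type_j]
    e = 0.0
    if r < ff.rc_pair:
        ulj = float(ff.lj_energy(sij, np.array(r)))
        shift = float(ff.lj_energy(sij, np.array(ff.rc_pair)))
        if r <= 2 ** (1 / 6) * sij:
            e += ulj + (1 - lij) * ff.epsilon - lij * shift
        else:
            e += lij * (ulj - shift)
    qq = ff.charge[type_i] * ff.charge[type_j]
    if qq != 0 and r < ff.rc_elec:
        from .forcefield import KE_COULOMB

        pref = qq * KE_COULOMB / ff.dielectric
        e += pref * (
            np.exp(-r / ff.debye_length) / r
            - np.exp(-ff.rc_elec / ff.debye_length) / ff.rc_elec
        )
    return e


@dataclass
class FrameStats:
    """Per-frame thermodynamic record."""

    step: int
    potential_energy: float
    kinetic_energy: float
    temperature: float
    pxx: float
    pyy: float
    pzz: float


@dataclass
class Trajectory:
    """In-memory trajectory: frames, per-frame stats and run metadata."""

    positions: np.ndarray            # (F, N, 3)
    box: np.ndarray                  # (3,)
    stats: pd.DataFrame
    topology: SystemTopology | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return len(self.positions)

    def save(self, path) -> None:
        with h5py.File(path, "w") as fh:
            fh.create_dataset("positions", data=self.positions.astype(np.float32))
            fh.create_dataset("box", data=self.box)
            grp = fh.create_group("stats")
            for col in self.stats.columns:
                grp.create_dataset(col, data=self.stats[col].to_numpy())
            if self.topology is not None:
                tg = fh.create_group("topology")
                tg.create_dataset(
                    "bead_types",
                    data=np.array(self.topology.bead_types, dtype="S8"))
                tg.create_dataset("charges", data=self.topology.charges)
                tg.create_dataset("bonds", data=self.topology.bonds)
                tg.create_dataset("molecule_id", data=self.topology.molecule_id)
                tg.create_dataset(
                    "species", data=np.array(self.topology.species, dtype="S8"))
                tg.create_dataset("valence", data=self.topology.valence)
            fh.attrs["metadata"] = json.dumps(self.metadata, default=str)

    @classmethod
    def load(cls, path) -> "Trajectory":
        with h5py.File(path, "r") as fh:
            positions = fh["positions"][...].astype(float)
            box = fh["box"][...]
            stats = pd.DataFrame(
                {col: fh["stats"][col][...] for col in fh["stats"]})
            top = None
            if "topology" in fh:
                tg = fh["topology"]
                top = SystemTopology(
                    bead_types=tg["bead_types"][...].astype("U8"),
                    charges=tg["charges"][...],
                    bonds=tg["bonds"][...],
                    molecule_id=tg["molecule_id"][...],
                    species=tg["species"][...].astype("U8"),
                    valence=tg["valence"][...],
                )
            metadata = json.loads(fh.attrs.get("metadata", "{}"))
        return cls(positions=positions, box=box, stats=stats,
                   topology=top, metadata=metadata)


class Simulator:
    """Fixed-box (NVT) Langevin dynamics for one boxed configuration.

    Parameters
    ----------
    topology, config : the system to integrate.
    ff : force-field parameters (HPS defaults if omitted).
    dt_fs : time step in femtoseconds (10 fs default).
    temperature : thermostat setpoint in K.
    friction_ps : Langevin friction in ps⁻¹; 0 disables the thermostat,
        recovering velocity-Verlet NVE dynamics.
    seed : master seed; the full trajectory is reproducible from it.
    interactions : "all", or "none" for an ideal gas (pressure validation).
    """

    def __init__(
        self,
        topology: SystemTopology,
        config: BoxedConfiguration,
        ff: ForceFieldParams | None = None,
        *,
        dt_fs: float = 10.0,
        temperature: float = 250.0,
        friction_ps: float = 1.0,
        seed: int = 0,
        interactions: str = "all",
        max_force: float | None = None,
    ):
        self.topology = topology
        self.ff = ff or default_forcefield()
        self.temperature = float(temperature)
        self.dt = dt_fs / TIME_UNIT_FS
        self.friction = friction_ps * 1e-3 * TIME_UNIT_FS  # -> per internal time
        self.rng = np.random.default_rng(seed)
        self.interactions = interactions
        # optional per-bead force cap (kcal/mol/Å): bounds the displacement
        # per step while assembly overlaps relax; None for production
        self.max_force = max_force

        self.box = np.asarray(config.box, dtype=float).copy()
        self.pos = np.mod(np.asarray(config.positions, dtype=float), self.box)
        self.types, self.masses = self.ff.bead_arrays(topology.bead_types)
        self.n = len(self.pos)
        self.step_count = 0

        # bonded-pair exclusion table
        deg = np.zeros(self.n, dtype=np.int64)
        for a, b in topology.bonds:
            deg[a] += 1
            deg[b] += 1
        maxdeg = int(deg.max()) if len(topology.bonds) else 1
        self.excl = np.full((self.n, max(maxdeg, 1)), -1, dtype=np.int64)
        self.n_excl = np.zeros(self.n, dtype=np.int64)
        for a, b in topology.bonds:
            self.excl[a, self.n_excl[a]] = b
            self.n_excl[a] += 1
            self.excl[b, self.n_excl[b]] = a
            self.n_excl[b] += 1

        t = self.ff.tables()
        self._tab = (t["sigma2"], t["lam"], t["eps"], t["lj_shift"], t["qq"],
                     t["kappa"], t["dh_shift"], t["rc_pair2"], t["rc_elec2"])
        self.bonds = topology.bonds.astype(np.int64)

        # Verlet pair list: rebuilt when any bead moves more than skin/2
        self.skin = 3.0
        self._rlist2 = (np.sqrt(max(t["rc_pair2"], t["rc_elec2"])) + self.skin) ** 2
        cap = max(64, self.n * 600)
        self._pi = np.empty(cap, dtype=np.int64)
        self._pj = np.empty(cap, dtype=np.int64)
        self._npairs = -1
        self._pos0 = np.zeros_like(self.pos)

        self._init_velocities()
        self._forces, self._epot, self._virial = self._compute_forces()

    # ------------------------------------------------------------------

    def _init_velocities(self) -> None:
        scale = np.sqrt(KB * self.temperature / self.masses)[:, None]
        self.vel = self.rng.standard_normal((self.n, 3)) * scale
        self.vel -= np.average(self.vel, axis=0, weights=self.masses)

    def _refresh_pairs(self) -> None:
        if self._npairs >= 0 and _kernels.max_displacement2(
                self.pos, self._pos0, self.box) < (self.skin / 2) ** 2:
            return
        while True:
            n = _kernels.build_pairs(self.pos, self.box, self._rlist2,
                                     self.excl, self.n_excl,
                                     self._pi, self._pj)
            if n >= 0:
                break
            cap = 2 * len(self._pi)
            self._pi = np.empty(cap, dtype=np.int64)
            self._pj = np.empty(cap, dtype=np.int64)
        self._npairs = n
        self._pos0[:] = self.pos

    def _compute_forces(self):
        forces = np.zeros((self.n, 3))
        epot = 0.0
        w = np.zeros(3)
        if self.interactions == "all":
            self._refresh_pairs()
            e, wxx, wyy, wzz = _kernels.pair_forces(
                self.pos, self.box, self._pi, self._pj, self._npairs,
                self.types, *self._tab, forces)
            epot += e
            w += (wxx, wyy, wzz)
            if len(self.bonds):
                e, wxx, wyy, wzz = _kernels.bonded(
                    self.pos, self.box, self.bonds,
                    self.ff.bond_k, self.ff.bond_r0, forces)
                epot += e
                w += (wxx, wyy, wzz)
        if not np.all(np.isfinite(forces)):
            bad = int(np.argmax(~np.isfinite(forces).all(axis=1)))
            raise EngineInstability(
                f"non-finite force on bead {bad} at step {self.step_count}")
        if self.max_force is not None:
            norm = np.linalg.norm(forces, axis=1)
            over = norm > self.max_force
            if over.any():
                forces[over] *= (self.max_force / norm[over])[:, None]
        return forces, epot, w

    def forces_energy_virial(self):
        """(forces, potential energy, virial diagonal) at the current state."""
        return self._compute_forces()

    # ------------------------------------------------------------------

    def step(self, n: int = 1) -> None:
        dt = self.dt
        inv_m = (1.0 / self.masses)[:, None]
        c1 = np.exp(-self.friction * dt)
        c2 = np.sqrt(max(0.0, 1.0 - c1 * c1))
        sig = np.sqrt(KB * self.temperature / self.masses)[:, None]
        for _ in range(n):
            self.vel += 0.5 * dt * self._forces * inv_m
            self.pos += 0.5 * dt * self.vel
            if self.friction > 0:
                self.vel = c1 * self.vel + c2 * sig * \
                    self.rng.standard_normal((self.n, 3))
            self.pos += 0.5 * dt * self.vel
            np.mod(self.pos, self.box, out=self.pos)
            self._forces, self._epot, self._virial = self._compute_forces()
            self.vel += 0.5 * dt * self._forces * inv_m
            self.step_count += 1

    def rescale_box(self, new_box: np.ndarray) -> None:
        new_box = np.asarray(new_box, dtype=float)
        self.pos *= new_box / self.box
        self.box = new_box.copy()
        self._npairs = -1
        self._forces, self._epot, self._virial = self._compute_forces()

    set_box = rescale_box

    # ------------------------------------------------------------------

    @property
    def kinetic_energy(self) -> float:
        return float(0.5 * np.sum(self.masses[:, None] * self.vel ** 2))

    @property
    def kinetic_temperature(self) -> float:
        return 2.0 * self.kinetic_energy / (3.0 * self.n * KB)

    def frame_stats(self) -> FrameStats:
        vol = float(np.prod(self.box))
        mv2 = np.sum(self.masses[:, None] * self.vel ** 2, axis=0)
        p = (mv2 + self._virial) / vol
        return FrameStats(
            step=self.step_count,
            potential_energy=self._epot,
            kinetic_energy=self.kinetic_energy,
            temperature=self.kinetic_temperature,
            pxx=float(p[0]), pyy=float(p[1]), pzz=float(p[2]),
        )

    def configuration(self) -> BoxedConfiguration:
        return BoxedConfiguration(
            positions=self.pos.copy(), box=self.box.copy())

    # ------------------------------------------------------------------

    def run(
        self,
        n_steps: int,
        report_interval: int = 500,
        stats_interval: int | None = None,
        record_positions: bool = True,
        max_temperature_factor: float = 10.0,
    ) -> Trajectory:
        """Integrate ``n_steps``, recording frames every ``report_interval``.

        ``stats_interval`` (default: the report interval) sets the spacing
        of FrameStats rows; the pressure tensor comes with every force
        evaluation, so recording it densely costs nothing and sharpens the
        interfacial-tension average.  The initial state is always recorded.
        If the kinetic temperature exceeds ``max_temperature_factor`` times
        the setpoint the run aborts, preserving what was collected.
        """
        stats_every = stats_interval or report_interval
        if report_interval % stats_every:
            raise ValueError("report_interval must be a multiple of "
                             "stats_interval")
        frames = [self.pos.copy()] if record_positions else []
        rows = [self.frame_stats()]
        t0 = time.time()
        done = 0
        try:
            while done < n_steps:
                chunk = min(stats_every, n_steps - done)
                self.step(chunk)
                done += chunk
                st = self.frame_stats()
                rows.append(st)
                if record_positions and done % report_interval == 0:
                    frames.append(self.pos.copy())
                if st.temperature > max_temperature_factor * self.temperature:
                    raise EngineInstability(
                        f"temperature {st.temperature:.0f} K exceeds "
                        f"{max_temperature_factor}x the "
                        f"{self.temperature:.0f} K setpoint")
        except EngineInstability as err:
            err.trajectory = self._package(frames, rows, t0, aborted=True)
            raise
        return self._package(frames, rows, t0, aborted=False)

    def _package(self, frames, rows, t0, aborted):
        stats = pd.DataFrame([vars(r) for r in rows])
        meta = {
            "dt_fs": self.dt * TIME_UNIT_FS,
            "temperature_K": self.temperature,
            "friction_ps": self.friction / (1e-3 * TIME_UNIT_FS),
            "n_beads": self.n,
            "box": self.box.tolist(),
            "wall_seconds": time.time() - t0,
            "aborted": aborted,
        }
        pos = np.array(frames) if frames else np.empty((0, self.n, 3))
        return Trajectory(positions=pos, box=self.box.copy(), stats=stats,
                          topology=self.topology, metadata=meta)


def run_coexistence(
    config: BoxedConfiguration,
    topology: SystemTopology,
    ff: ForceFieldParams | None = None,
    protocol: dict | None = None,
    *,
    temperature: float = 250.0,
    friction_ps: float = 1.0,
    dt_fs: float = 10.0,
    seed: int = 0,
) -> Trajectory:
    """NVT direct-coexistence run on a slab configuration.

    ``protocol`` keys: ``equilibration_steps``, ``production_steps``,
    ``report_interval``.  Equilibration frames are not recorded; production
    frames and stats are.  All parameters and the seed land in the metadata.
    """
    proto = {"equilibration_steps": 5000, "production_steps": 20000,
             "report_interval": 500}
    proto.update(protocol or {})
    if config.box[2] <= max(config.box[0], config.box[1]):
        raise ValueError("coexistence runs require slab geometry (Lz largest)")
    sim = Simulator(topology, config, ff, dt_fs=dt_fs, temperature=temperature,
                    friction_ps=friction_ps, seed=seed)
    if proto["equilibration_steps"]:
        sim.step(proto["equilibration_steps"])
    traj = sim.run(proto["production_steps"],
                   report_interval=proto["report_interval"])
    traj.metadata.update({"seed": seed, "protocol": proto})
    return traj
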