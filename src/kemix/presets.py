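"""Desk-scale direct-coexistence presets.

The full-scale reference protocol uses 50 nm boxes compressed to
20–25 nm, slabs extended to 125 nm along z, microsecond production runs at
250 K with a 1 ps⁻¹ Langevin friction and a 10 fs step.  Those runs are far
beyond a single workstation CPU, so the desk preset keeps the protocol's
shape — assemble dilute, compress dense, extend z, NVT — at small problem
sizes: chains/arms of length 20, ~700 beads, a 15 nm cube compressed to a
5.5 × 5.5 × 14 nm column, extended to a 32 nm slab, and a weaker friction
(0.01 ps⁻¹) purely to accelerate configurational sampling within a few ns
of simulated time.  Desk runs expose trends (orderings of K_p, γ, φ_B),
not converged absolute values.
"""

from __future__ import annotations

from dataclasses import dataclass

from .engine import Simulator, Trajectory
from .forcefield import TIME_UNIT_FS, ForceFieldParams, desk_forcefield
from .sequences import ChargeSequence
from .topology import (assemble_binary_mixture, build_linear, build_star,
                       compress_box, make_slab)


@dataclass
class DeskProtocol:
    """Problem sizes for a desk-scale coexistence run.

    The compressed box is a narrow column (small x/y cross-section, longer
    z): with the cross-section below the typical demixed-domain size, the
    two condensed phases arrange as z-stacked lamellae, which is the
    geometry the z density profile and its tanh fits read directly.
    """

    total_beads: int = 700
    box_initial: float = 150.0       # Å
    box_xy: float = 55.0             # compressed x/y edge, Å
    box_z_dense: float = 140.0       # compressed z edge, Å
    lz_slab: float = 320.0           # Å
    compression_steps: int = 3000
    equilibration_steps: int = 10000
    production_steps: int = 60000
    report_interval: int = 500
    stats_interval: int = 50
    temperature: float = 250.0       # K
    friction_ps: float = 0.01
    dt_fs: float = 10.0


def desk_coexistence(
    seq_p: ChargeSequence,
    seq_q: ChargeSequence,
    f_p: int = 1,
    f_q: int = 1,
    seed: int = 0,
    protocol: DeskProtocol | None = None,
    ff: ForceFieldParams | None = None,
    vacuum: bool = True,
) -> Trajectory:
    """Assemble, compress, extend to a slab and run NVT production.

    Species p and q are mixed at equal polyampholyte mass fraction; either
    may be oligomerized into an f-arm star.  Fully reproducible per seed.

    With ``vacuum=False`` the z-extension is skipped and production runs in
    the fully dense column: the only interfaces are then between the two
    condensed phases, which is the configuration of choice for measuring
    the condensate–condensate interfacial tension (a vacuum-flanked slab
    adds two condensate–vapour interfaces whose fluctuations dominate the
    pressure-tensor anisotropy at desk scale).
    """
    proto = protocol or DeskProtocol()
    ff = ff or desk_forcefield()
    top_p = build_star(seq_p, f_p) if f_p > 1 else build_linear(seq_p)
    top_q = (build_star(seq_q, f_q, species="q") if f_q > 1
             else build_linear(seq_q, species="q"))
    cfg, top = assemble_binary_mixture(
        top_p, top_q, proto.total_beads, proto.box_initial, seed=seed)
    # compression and the first half of equilibration run tightly coupled
    # (0.5 ps⁻¹) with a force cap so assembly contacts relax instead of
    # detonating; production runs uncapped at the preset friction
    sim = Simulator(top, cfg, ff, dt_fs=proto.dt_fs,
                    temperature=proto.temperature,
                    friction_ps=max(proto.friction_ps, 0.5),
                    seed=seed + 1, max_force=100.0)
    cfg = compress_box(
        cfg, (proto.box_xy, proto.box_xy, proto.box_z_dense), sim,
        n_steps=proto.compression_steps)
    slab = make_slab(cfg, proto.lz_slab, top) if vacuum else cfg
    sim2 = Simulator(top, slab, ff, dt_fs=proto.dt_fs,
                     temperature=proto.temperature,
                     friction_ps=max(proto.friction_ps, 0.5), seed=seed + 2,
                     max_force=100.0)
    sim2.step(proto.equilibration_steps // 2)
    sim2.friction = proto.friction_ps * 1e-3 * TIME_UNIT_FS
    sim2.max_force = None
    sim2.step(proto.equilibration_steps - proto.equilibration_steps // 2)
    traj = sim2.run(proto.production_steps,
                    report_interval=proto.report_interval,
                    stats_interval=proto.stats_interval)
    traj.metadata.update({
        "seed": seed,
        "f_p": f_p, "f_q": f_q,
        "seq_p": seq_p.residues, "seq_q": seq_q.residues,
        "protocol": vars(proto),
    })
    return traj
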