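"""Miscibility observables from direct-coexistence trajectories.

- z density profiles per species, recentred per frame on the dense slab
- hyperbolic-tangent fits giving dense/dilute plateau concentrations
- partition coefficient K_p = C_p(q-lean) / C_p(q-rich)
- interfacial tension from the pressure-tensor anisotropy
  γ = (Lz/2) [<P_zz> - (<P_xx> + <P_yy>)/2]
- bond ratio φ_B = heterotypic / homotypic inter-molecular contacts of the
  oligomerized species.

Concentrations are bead-number concentrations (beads/Å³) of polyampholyte
beads; CORE scaffold beads are excluded throughout.  Errors are standard
errors over equal contiguous blocks of production frames after discarding a
burn-in fraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from . import _kernels
from .engine import Trajectory
from .forcefield import ForceFieldParams, default_forcefield, mean_sigma


@dataclass
class DensityProfile:
    """Frame-averaged bead concentration along z."""

    z: np.ndarray               # bin centres (Å)
    rho: np.ndarray             # beads/Å³
    lz: float
    area: float                 # x·y cross-section (Å²)
    n_frames: int
    n_beads: float              # mean bead count represented

    @property
    def bin_width(self) -> float:
        return float(self.z[1] - self.z[0])

    def total_beads(self) -> float:
        return float(self.rho.sum() * self.bin_width * self.area)


def _circular_centre(z: np.ndarray, lz: float,
                     weights: np.ndarray | None = None) -> float:
    """Centre of mass of periodic z coordinates (circular mean)."""
    theta = 2 * np.pi * z / lz
    s = np.average(np.sin(theta), weights=weights)
    c = np.average(np.cos(theta), weights=weights)
    return float((np.arctan2(s, c) / (2 * np.pi)) * lz % lz)


def density_profile(
    traj: Trajectory,
    species: str,
    n_bins: int = 80,
    frame_slice: slice = slice(None),
) -> DensityProfile:
    """Per-species z concentration profile averaged over frames.

    Each frame is recentred on the circular centre of mass of *all*
    polyampholyte beads (so both species share one frame of reference)
    before histogramming the selected species.
    """
    if n_bins < 10:
        raise ValueError("use at least 10 bins")
    top = traj.topology
    sel = top.species_mask(species)
    if not sel.any():
        raise ValueError(f"no beads for species {species!r}")
    allpa = top.is_polyampholyte
    lz = float(traj.box[2])
    area = float(traj.box[0] * traj.box[1])
    edges = np.linspace(0, lz, n_bins + 1)
    binvol = (lz / n_bins) * area
    frames = traj.positions[frame_slice]
    if len(frames) == 0:
        raise ValueError("no frames selected")
    hist = np.zeros(n_bins)
    for pos in frames:
        z = np.mod(pos[:, 2], lz)
        zc = _circular_centre(z[allpa], lz)
        # one shift per frame, shared by both species
        zs = np.mod(z[sel] - zc + lz / 2, lz)
        hist += np.histogram(zs, bins=edges)[0]
    rho = hist / (len(frames) * binvol)
    return DensityProfile(
        z=0.5 * (edges[:-1] + edges[1:]), rho=rho, lz=lz, area=area,
        n_frames=len(frames), n_beads=float(sel.sum()),
    )


# ---------------------------------------------------------------------------
# tanh fit


@dataclass
class TanhFit:
    rho_den: float
    rho_dil: float
    z0: float                   # half-extent of the dense region (Å)
    w: float                    # interface width (Å)
    zc: float                   # slab centre (Å)
    cov: np.ndarray | None
    converged: bool
    flagged: str | None = None
    lz: float | None = None

    def model(self, z: np.ndarray) -> np.ndarray:
        return tanh_profile(z, self.rho_den, self.rho_dil, self.z0, self.w,
                            self.zc, lz=self.lz)


def tanh_profile(z, rho_den, rho_dil, z0, w, zc, lz=None):
    """ρ(z) = (ρden+ρdil)/2 − (ρden−ρdil)/2 · tanh((|z−zc| − z0)/w).

    With ``lz`` given, |z−zc| is the periodic (circular) z distance.
    """
    dz = np.abs(z - zc)
    if lz is not None:
        dz = np.minimum(dz, lz - dz)
    return 0.5 * (rho_den + rho_dil) - 0.5 * (rho_den - rho_dil) * np.tanh(
        (dz - z0) / w)


def fit_tanh(profile: DensityProfile, dynamic_range: float = 3.0) -> TanhFit:
    """Least-squares tanh fit of a two-phase density profile.

    ρ_den ≥ ρ_dil is enforced by construction (the dense excess is fitted as
    a non-negative parameter).  The slab centre zc is a free parameter (a
    species in a demixed binary system occupies a slab away from the box
    middle), using the periodic z distance.  If the profile lacks contrast
    (max/min below ``dynamic_range``) or the fit fails, a flagged result
    carrying robust 10th/90th-percentile plateau estimates is returned
    instead of raising.
    """
    z, rho = profile.z, profile.rho
    lz = profile.lz
    lo, hi = np.percentile(rho, [10, 90])
    fallback = TanhFit(rho_den=float(hi), rho_dil=float(lo),
                       z0=lz / 4, w=profile.bin_width * 2, zc=lz / 2,
                       cov=None, converged=False, lz=lz)
    if hi <= 0 or (lo > 0 and hi / max(lo, 1e-300) < dynamic_range) or hi == lo:
        fallback.flagged = "degenerate: no dense/dilute contrast"
        if hi == lo:
            fallback.rho_den = fallback.rho_dil = float(rho.mean())
        return fallback

    half = 0.5 * (hi + lo)
    dense_bins = rho > half
    z0_guess = max(
        0.5 * dense_bins.sum() * profile.bin_width, profile.bin_width)
    # centroid of the dense bins (circular mean) seeds zc
    zc_guess = _circular_centre(z[dense_bins], lz) if dense_bins.any() \
        else lz / 2

    def model(zv, excess, rho_dil, z0, w, zc):
        return tanh_profile(zv, rho_dil + excess, rho_dil, z0, w, zc, lz=lz)

    p0 = [hi - lo, max(lo, 1e-8 * hi), z0_guess, 4 * profile.bin_width,
          zc_guess]
    bounds = ([0, 0, profile.bin_width * 0.1, profile.bin_width * 0.05,
               zc_guess - lz / 4],
              [np.inf, np.inf, lz / 2, lz / 2, zc_guess + lz / 4])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, pcov = curve_fit(model, z, rho, p0=p0, bounds=bounds,
                                   maxfev=20000)
    except (RuntimeError, ValueError):
        fallback.flagged = "fit did not converge; quantile plateaus reported"
        return fallback
    excess, rho_dil, z0, w, zc = popt
    return TanhFit(rho_den=float(rho_dil + excess), rho_dil=float(rho_dil),
                   z0=float(z0), w=float(w), zc=float(zc % lz), cov=pcov,
                   converged=True, lz=lz)


# ---------------------------------------------------------------------------
# partition coefficient


@dataclass
class PartitionResult:
    kp: float
    sem: float
    per_block: np.ndarray
    miscible: bool              # True when the dilute-side fallback was used


def partition_from_profiles(
    profile_p: DensityProfile,
    profile_q: DensityProfile,
    interface_pad: float = 2.0,
    profile_p_classify: DensityProfile | None = None,
) -> tuple[float, bool]:
    """K_p from one pair of species profiles.

    The q-rich region is where q's fitted profile exceeds its midpoint; the
    q-lean *condensed* region is within p's fitted dense extent but outside
    q-rich.  Bins within ``interface_pad``·w of either fitted interface are
    excluded from the plateau means.  When no condensed q-lean region exists
    (miscible pair, single slab) the q-dilute region is used instead and the
    result is flagged miscible.
    """
    fit_q = fit_tanh(profile_q)
    fit_p = fit_tanh(profile_p)
    z = profile_q.z
    lz = profile_q.lz
    rho_p, rho_q = profile_p.rho, profile_q.rho
    dz_q = np.abs(z - fit_q.zc)
    dz_q = np.minimum(dz_q, lz - dz_q)
    q_rich = dz_q < fit_q.z0 - interface_pad * fit_q.w
    q_out = dz_q > fit_q.z0 + interface_pad * fit_q.w
    dz_p = np.abs(z - fit_p.zc)
    dz_p = np.minimum(dz_p, lz - dz_p)
    p_dense = dz_p < fit_p.z0 - interface_pad * fit_p.w
    q_lean_cond = p_dense & q_out

    if q_rich.any() and q_lean_cond.any():
        denom = float(rho_p[q_rich].mean())
        if denom <= 0:
            return float("nan"), False
        return float(rho_p[q_lean_cond].mean()) / denom, False

    # Miscible single slab (p's and q's dense regions coincide): partition
    # the condensed region by its q *fraction* x_q = ρ_q/(ρ_p+ρ_q), so the
    # shared slab shape cancels and an identical/mixed system reads
    # K_p = 1, the miscible baseline.  The classification profile
    # for p may come from frames disjoint from the measured ρ_p (see
    # partition_coefficient), keeping selection and measurement noise
    # independent.
    rho_p_cls = (profile_p_classify.rho if profile_p_classify is not None
                 else rho_p)
    condensed = p_dense | q_rich
    if not condensed.any():
        condensed = (rho_q + rho_p_cls) > np.median(rho_q + rho_p_cls)
    if not condensed.any():
        return float("nan"), True
    total = rho_q + rho_p_cls
    with np.errstate(invalid="ignore", divide="ignore"):
        x_q = np.where(total > 0, rho_q / np.where(total > 0, total, 1.0), 0.5)
    idx = np.where(condensed)[0]
    order = np.argsort(x_q[idx], kind="stable")
    half = len(idx) // 2
    if half == 0:
        return float("nan"), True
    lean = idx[order[:half]]
    rich = idx[order[half:]]
    denom = float(rho_p[rich].mean())
    if denom <= 0:
        return float("nan"), True
    return float(rho_p[lean].mean()) / denom, True


def partition_coefficient(
    traj: Trajectory,
    n_bins: int = 80,
    n_blocks: int = 5,
    burn_in: float = 0.2,
    species: tuple[str, str] = ("p", "q"),
) -> PartitionResult:
    """Block-averaged K_p ± SEM over independent frame blocks.

    Within each block the q profile (which delimits the q-rich/q-lean
    regions) is built from the even frames and the p profile from the odd
    frames, so region selection and concentration measurement carry
    independent noise; without the split, selecting "q-lean" bins on the
    same noisy data that supplies ρ_p biases K_p away from 1 for miscible
    systems.
    """
    n_frames = traj.n_frames
    start = int(burn_in * n_frames)
    usable = n_frames - start
    if usable < 2 * n_blocks:
        raise ValueError("fewer usable frames than blocks")
    bounds = start + (np.arange(n_blocks + 1) * usable) // n_blocks
    vals, misc = [], []
    for b in range(n_blocks):
        sl_q = slice(bounds[b], bounds[b + 1], 2)
        sl_p = slice(bounds[b] + 1, bounds[b + 1], 2)
        pp = density_profile(traj, species[0], n_bins, frame_slice=sl_p)
        pq = density_profile(traj, species[1], n_bins, frame_slice=sl_q)
        pp_cls = density_profile(traj, species[0], n_bins, frame_slice=sl_q)
        kp, m = partition_from_profiles(pp, pq, profile_p_classify=pp_cls)
        vals.append(kp)
        misc.append(m)
    vals = np.array(vals)
    ok = np.isfinite(vals)
    sem = float(vals[ok].std(ddof=1) / np.sqrt(ok.sum())) if ok.sum() > 1 else 0.0
    return PartitionResult(kp=float(vals[ok].mean()), sem=sem,
                           per_block=vals, miscible=bool(np.all(misc)))


# ---------------------------------------------------------------------------
# interfacial tension


@dataclass
class TensionResult:
    gamma: float                # kcal/mol/Å²
    sem: float
    gamma_reduced: float        # in units of ε/σ̄²
    sem_reduced: float
    per_block: np.ndarray
    per_block_reduced: np.ndarray


def interfacial_tension(
    stats,
    lz: float,
    n_blocks: int = 5,
    burn_in: float = 0.2,
    ff: ForceFieldParams | None = None,
    bead_types: np.ndarray | None = None,
) -> TensionResult:
    """Mechanical-route interfacial tension from pressure-tensor anisotropy.

    γ = (Lz/2)[⟨P_zz⟩ − (⟨P_xx⟩+⟨P_yy⟩)/2]; the 1/2 accounts for the two
    interfaces of a periodic slab.  Reported both in kcal/mol/Å² and in
    reduced ε/σ̄² units with σ̄ the composition-weighted mean bead σ.
    """
    ff = ff or default_forcefield()
    df = stats.stats if isinstance(stats, Trajectory) else stats
    n = len(df)
    start = int(burn_in * n)
    usable = n - start
    if usable < n_blocks:
        raise ValueError("fewer reporting intervals than blocks")
    aniso = (df["pzz"] - 0.5 * (df["pxx"] + df["pyy"])).to_numpy()[start:]
    bounds = (np.arange(n_blocks + 1) * usable) // n_blocks
    per_block = np.array([
        lz / 2 * aniso[bounds[b]:bounds[b + 1]].mean()
        for b in range(n_blocks)
    ])
    gamma = float(per_block.mean())
    sem = float(per_block.std(ddof=1) / np.sqrt(n_blocks)) if n_blocks > 1 else 0.0
    if bead_types is not None:
        sbar = mean_sigma(ff, np.asarray(bead_types))
    else:
        sbar = float(ff.sigma[:2].mean())
    scale = sbar ** 2 / ff.epsilon
    return TensionResult(gamma=gamma, sem=sem, gamma_reduced=gamma * scale,
                         sem_reduced=sem * scale, per_block=per_block,
                         per_block_reduced=per_block * scale)


def count_lamellar_interfaces(
    traj: Trajectory,
    n_bins: int = 64,
    burn_in: float = 0.2,
    smooth: int = 3,
    species: tuple[str, str] = ("p", "q"),
) -> float:
    """Mean number of p/q lamellar interfaces along z (periodic count).

    In a narrow column the demixed phases stack as z-lamellae, and the
    mechanical anisotropy measures (k/2)·γ_pq with k the number of
    composition interfaces — a seed-dependent even integer.  This counts k
    per frame as the number of sign changes of the smoothed q-fraction
    around its median along the periodic z axis (bins nearly empty of
    polyampholyte beads are ignored), enabling a per-interface tension.
    """
    top = traj.topology
    lz = float(traj.box[2])
    edges = np.linspace(0, lz, n_bins + 1)
    sel_p = top.species_mask(species[0])
    sel_q = top.species_mask(species[1])
    start = int(burn_in * traj.n_frames)
    counts = []
    for pos in traj.positions[start:]:
        z = np.mod(pos[:, 2], lz)
        hp = np.histogram(z[sel_p], bins=edges)[0].astype(float)
        hq = np.histogram(z[sel_q], bins=edges)[0].astype(float)
        total = hp + hq
        occupied = total > 0.25 * np.median(total[total > 0])
        x = np.where(total > 0, hq / np.where(total > 0, total, 1), 0.5)
        x = x[occupied]
        if len(x) < 2 * smooth + 2:
            continue
        kernel = np.ones(smooth) / smooth
        xs = np.convolve(np.concatenate([x[-smooth:], x, x[:smooth]]),
                         kernel, mode="same")[smooth:-smooth]
        s = np.sign(xs - np.median(xs))
        s = s[s != 0]
        k = int(np.sum(s != np.roll(s, 1)))
        counts.append(k)
    if not counts:
        raise ValueError("no analyzable frames for interface counting")
    return float(np.mean(counts))


# ---------------------------------------------------------------------------
# bond ratio


@dataclass
class BondRatioResult:
    phi_b: float
    sem: float
    per_frame: np.ndarray
    heterotypic: int
    homotypic: int


def contact_bond_ratio(
    traj: Trajectory,
    oligomerized: str = "p",
    cutoff_factor: float = 1.5,
    burn_in: float = 0.2,
    frame_stride: int = 1,
    ff: ForceFieldParams | None = None,
    n_blocks: int = 5,
) -> BondRatioResult:
    """φ_B: heterotypic over homotypic inter-molecular contacts.

    A non-covalent "bond" is an inter-molecular K/E bead pair within
    ``cutoff_factor``·σ_ij (first coordination shell).  Counts are restricted
    to beads of the oligomerized species; intra-molecular pairs and CORE
    beads never count.  Each homotypic pair engages two contact-ends of the
    oligomerized species while a heterotypic pair engages one, so
    φ_B = heterotypic / (2 · homotypic): per contact-end, a randomly
    relabelled single-species system reads φ_B = 1.  φ_B is the ratio of
    total counts over the analyzed frames; the SEM is over frame blocks of
    the per-frame ratios.
    """
    ff = ff or default_forcefield()
    top = traj.topology
    species = top.species[top.molecule_id]
    if oligomerized not in set(top.species):
        raise ValueError(f"species {oligomerized!r} not present")
    pa = top.is_polyampholyte
    types_all, _ = ff.bead_arrays(top.bead_types)
    sub = np.where(pa)[0]
    types = types_all[sub]
    mol_id = top.molecule_id[sub]
    labels = species[sub]
    olig_mask = labels == oligomerized
    codes = (labels == oligomerized).astype(np.int64)
    sigma2 = ff.sigma_pair ** 2
    factor2 = cutoff_factor ** 2
    rc2 = factor2 * float(sigma2[:2, :2].max())

    start = int(burn_in * traj.n_frames)
    frames = traj.positions[start::frame_stride]
    if len(frames) == 0:
        raise ValueError("no frames to analyze")
    het_tot = hom_tot = 0
    ratios = []
    for pos in frames:
        het, hom = _kernels.contact_counts(
            np.ascontiguousarray(pos[sub]), traj.box.astype(float),
            types, mol_id, codes, olig_mask, sigma2, factor2, rc2)
        het_tot += het
        hom_tot += hom
        ratios.append(het / (2.0 * hom) if hom else np.nan)
    if hom_tot == 0:
        raise ValueError("no homotypic contacts: φ_B undefined for this system")
    ratios = np.array(ratios)
    ok = np.isfinite(ratios)
    nb = min(n_blocks, int(ok.sum()))
    if nb > 1:
        good = ratios[ok]
        bounds = (np.arange(nb + 1) * len(good)) // nb
        blocks = np.array([good[bounds[b]:bounds[b + 1]].mean()
                           for b in range(nb)])
        sem = float(blocks.std(ddof=1) / np.sqrt(nb))
    else:
        sem = 0.0
    return BondRatioResult(phi_b=het_tot / (2.0 * hom_tot), sem=sem,
                           per_frame=ratios, heterotypic=het_tot,
                           homotypic=hom_tot)
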