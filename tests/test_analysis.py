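"""Coexistence observables: profiles, tanh fits, K_p, γ, φ_B."""

import numpy as np
import pandas as pd
import pytest

from kemix import _kernels
from kemix.analysis import (DensityProfile, contact_bond_ratio,
                            density_profile, fit_tanh, interfacial_tension,
                            partition_coefficient, partition_from_profiles,
                            tanh_profile)
from kemix.engine import Trajectory
from kemix.forcefield import default_forcefield
from kemix.synth import synth_density_profile, synth_pressure_series
from kemix.topology import SystemTopology


def bead_trajectory(frames, box, species=None, mol_id=None):
    """Trajectory of unbonded beads with the given species labels."""
    frames = np.asarray(frames, dtype=float)
    n = frames.shape[1]
    mol_id = np.arange(n) if mol_id is None else np.asarray(mol_id)
    n_mol = mol_id.max() + 1
    if species is None:
        species = np.array(["p"] * n_mol)
    top = SystemTopology(
        bead_types=np.array(["K"] * n),
        charges=np.ones(n),
        bonds=np.empty((0, 2), dtype=np.int64),
        molecule_id=mol_id,
        species=np.asarray(species),
        valence=np.ones(n_mol, dtype=int),
    )
    stats = pd.DataFrame({"step": np.arange(len(frames))})
    return Trajectory(positions=frames, box=np.asarray(box, dtype=float),
                      stats=stats, topology=top)


class TestDensityProfile:
    def test_mass_conservation_and_single_bin(self, rng):
        box = [50.0, 50.0, 200.0]
        # all beads on one z plane
        pos = np.column_stack([rng.uniform(0, 50, 300),
                               rng.uniform(0, 50, 300),
                               np.full(300, 77.0)])
        traj = bead_trajectory([pos], box)
        prof = density_profile(traj, "p", n_bins=50)
        assert prof.total_beads() == pytest.approx(300, rel=1e-9)
        assert np.sum(prof.rho > 0) == 1

    def test_recentring_makes_shifted_frames_equivalent(self, rng):
        box = [40.0, 40.0, 160.0]
        base = np.column_stack([rng.uniform(0, 40, 400),
                                rng.uniform(0, 40, 400),
                                rng.normal(80.0, 8.0, 400) % 160.0])
        shifts = [0.0, 23.0, 61.0, 120.0]
        frames = [base + np.array([0, 0, s]) for s in shifts]
        for f in frames:
            f[:, 2] %= 160.0
        traj_shifted = bead_trajectory(frames, box)
        traj_static = bead_trajectory([base] * len(shifts), box)
        p1 = density_profile(traj_shifted, "p", n_bins=40)
        p2 = density_profile(traj_static, "p", n_bins=40)
        np.testing.assert_allclose(p1.rho, p2.rho, atol=1e-12)

    def test_empty_species_rejected(self, rng):
        traj = bead_trajectory([np.zeros((5, 3))], [10, 10, 40])
        with pytest.raises(ValueError, match="no beads"):
            density_profile(traj, "nope")


class TestTanhFit:
    def test_noiseless_recovery_to_machine_tolerance(self):
        prof, truth = synth_density_profile(0.3, 0.01, 80.0, 8.0, lz=300.0,
                                            n_bins=150)
        fit = fit_tanh(prof)
        assert fit.converged
        assert fit.rho_den == pytest.approx(truth["rho_den"], rel=1e-6)
        assert fit.rho_dil == pytest.approx(truth["rho_dil"], rel=1e-6)
        assert fit.z0 == pytest.approx(truth["z0"], rel=1e-6)
        assert fit.w == pytest.approx(truth["w"], rel=1e-6)
        assert fit.zc == pytest.approx(150.0, abs=1e-3)

    def test_off_centre_slab_recovered(self):
        # a species slab away from the box middle (demixed binary geometry)
        z = (np.arange(120) + 0.5) * 300.0 / 120
        rho = tanh_profile(z, 0.2, 0.001, 30.0, 6.0, 100.0, lz=300.0)
        prof = DensityProfile(z=z, rho=rho, lz=300.0, area=2500.0,
                              n_frames=1, n_beads=1.0)
        fit = fit_tanh(prof)
        assert fit.converged
        assert fit.zc == pytest.approx(100.0, abs=0.5)
        assert fit.rho_den == pytest.approx(0.2, rel=1e-4)

    def test_flat_profile_flagged_degenerate(self):
        z = np.linspace(1, 99, 50)
        prof = DensityProfile(z=z, rho=np.full(50, 0.1), lz=100.0,
                              area=100.0, n_frames=1, n_beads=1.0)
        fit = fit_tanh(prof)
        assert not fit.converged
        assert fit.flagged is not None
        assert fit.rho_den == pytest.approx(fit.rho_dil)

    def test_noisy_profiles_unbiased(self):
        # Monte-Carlo recovery at 5% noise: estimates unbiased within 2 SEM
        truth = dict(rho_den=0.3, rho_dil=0.01, z0=80.0, w=8.0)
        dens, dils, z0s, ws = [], [], [], []
        for seed in range(1000, 1060):
            prof, _ = synth_density_profile(
                noise_sd=0.05 * truth["rho_den"], seed=seed, lz=300.0,
                n_bins=150, **truth)
            fit = fit_tanh(prof)
            if fit.converged:
                dens.append(fit.rho_den)
                dils.append(fit.rho_dil)
                z0s.append(fit.z0)
                ws.append(fit.w)
        assert len(dens) > 50
        for vals, key in [(dens, "rho_den"), (z0s, "z0"), (ws, "w")]:
            vals = np.array(vals)
            sem = vals.std(ddof=1) / np.sqrt(len(vals))
            assert abs(vals.mean() - truth[key]) < 2 * sem + 1e-12, key


def two_slab_profiles(rho_p_lean=0.2, rho_p_rich=0.002, lz=300.0, n=150):
    """Constructed demixed profiles: p slab at z=75, q slab at z=165."""
    z = (np.arange(n) + 0.5) * lz / n
    rho_p = tanh_profile(z, rho_p_lean, 1e-5, 40.0, 5.0, 75.0, lz=lz)
    rho_p = rho_p + tanh_profile(z, rho_p_rich, 0.0, 40.0, 5.0, 165.0, lz=lz)
    rho_q = tanh_profile(z, 0.25, 1e-5, 40.0, 5.0, 165.0, lz=lz)
    mk = lambda r: DensityProfile(z=z, rho=r, lz=lz, area=3000.0,
                                  n_frames=1, n_beads=1.0)
    return mk(rho_p), mk(rho_q)


class TestPartition:
    def test_constructed_ratio_of_100(self):
        pp, pq = two_slab_profiles(rho_p_lean=0.2, rho_p_rich=0.002)
        kp, miscible = partition_from_profiles(pp, pq)
        assert not miscible
        assert kp == pytest.approx(100.0, rel=0.05)

    def test_segregation_ordering_preserved(self):
        strong, q1 = two_slab_profiles(rho_p_lean=0.2, rho_p_rich=0.002)
        weak, q2 = two_slab_profiles(rho_p_lean=0.1, rho_p_rich=0.05)
        kp_strong, _ = partition_from_profiles(strong, q1)
        kp_weak, _ = partition_from_profiles(weak, q2)
        assert kp_strong > kp_weak

    def test_identical_species_reads_unity(self, rng):
        # one slab, labels split at random: K_p = 1 within block scatter
        box = [40.0, 40.0, 200.0]
        frames = []
        n = 400
        for _ in range(20):
            pos = np.column_stack([rng.uniform(0, 40, n),
                                   rng.uniform(0, 40, n),
                                   rng.normal(100.0, 12.0, n) % 200.0])
            frames.append(pos)
        labels = np.array(["p"] * (n // 2) + ["q"] * (n // 2))
        traj = bead_trajectory(frames, box, species=labels)
        res = partition_coefficient(traj, n_bins=40, n_blocks=4, burn_in=0.0)
        assert res.miscible
        assert abs(res.kp - 1.0) < max(3 * res.sem, 0.2)


class TestInterfacialTension:
    def test_isotropic_tensor_gives_exact_zero(self):
        stats = synth_pressure_series(n=100, p_iso=2e-4, anisotropy=0.0)
        res = interfacial_tension(stats, lz=300.0, n_blocks=5)
        assert res.gamma == 0.0
        assert res.gamma_reduced == 0.0

    def test_constant_anisotropy_closed_form(self):
        delta = 3.7e-5
        stats = synth_pressure_series(n=200, anisotropy=delta)
        res = interfacial_tension(stats, lz=280.0, n_blocks=5)
        assert res.gamma == pytest.approx(280.0 * delta / 2, rel=1e-12)
        assert res.sem == pytest.approx(0.0, abs=1e-18)
        # reduced units: γ in ε/σ̄² with the K/E mean σ
        ff = default_forcefield()
        sbar = ff.sigma[:2].mean()
        assert res.gamma_reduced == pytest.approx(
            res.gamma * sbar ** 2 / ff.epsilon, rel=1e-12)

    def test_too_few_frames_rejected(self):
        stats = synth_pressure_series(n=4)
        with pytest.raises(ValueError):
            interfacial_tension(stats, lz=100.0, n_blocks=5)


class TestInterfaceCount:
    def test_two_lamellae_counted(self, rng):
        # p beads in one z half, q in the other: one periodic lamella pair
        box = [40.0, 40.0, 120.0]
        n = 400
        frames = []
        for _ in range(4):
            zp = rng.uniform(5, 55, n // 2)
            zq = rng.uniform(65, 115, n // 2)
            pos = np.column_stack([rng.uniform(0, 40, n),
                                   rng.uniform(0, 40, n),
                                   np.concatenate([zp, zq])])
            frames.append(pos)
        labels = np.array(["p"] * (n // 2) + ["q"] * (n // 2))
        traj = bead_trajectory(frames, box, species=labels)
        from kemix.analysis import count_lamellar_interfaces

        k = count_lamellar_interfaces(traj, n_bins=24, burn_in=0.0)
        assert k == pytest.approx(2.0, abs=0.5)


def brute_contacts(pos, box, types, mol_id, labels, olig, sigma_pair, factor):
    het = hom = 0
    n = len(pos)
    for i in range(n - 1):
        for j in range(i + 1, n):
            if mol_id[i] == mol_id[j]:
                continue
            d = pos[i] - pos[j]
            d -= box * np.rint(d / box)
            r = np.linalg.norm(d)
            if r < factor * sigma_pair[types[i], types[j]]:
                if labels[i] == labels[j]:
                    if labels[i] == olig:
                        hom += 1
                elif olig in (labels[i], labels[j]):
                    het += 1
    return het, hom


class TestBondRatio:
    def test_kernel_matches_bruteforce(self, rng):
        ff = default_forcefield()
        n = 120
        pos = rng.uniform(0, 30, (n, 3))
        box = np.array([30.0, 30.0, 30.0])
        mol_id = np.repeat(np.arange(n // 4), 4)
        labels_mol = np.array(["p", "q"] * (n // 8))
        labels = labels_mol[mol_id]
        types = rng.integers(0, 2, n)
        sigma2 = ff.sigma_pair ** 2
        het_k, hom_k = _kernels.contact_counts(
            pos, box, types.astype(np.int64), mol_id.astype(np.int64),
            (labels == "p").astype(np.int64), labels == "p",
            sigma2, 1.5 ** 2, 1.5 ** 2 * sigma2[:2, :2].max())
        het_b, hom_b = brute_contacts(pos, box, types, mol_id, labels, "p",
                                      ff.sigma_pair, 1.5)
        assert (het_k, hom_k) == (het_b, hom_b)

    def test_random_relabelling_reads_unity(self, rng):
        # single species split half/half: per contact-end φ_B = 1
        n_mol, mlen = 40, 5
        n = n_mol * mlen
        frames = [rng.uniform(0, 35, (n, 3)) for _ in range(4)]
        mol_id = np.repeat(np.arange(n_mol), mlen)
        labels = np.array(["p"] * (n_mol // 2) + ["q"] * (n_mol // 2))
        labels = labels[rng.permutation(n_mol)]
        traj = bead_trajectory(frames, [35.0, 35.0, 35.0], species=labels,
                               mol_id=mol_id)
        res = contact_bond_ratio(traj, "p", burn_in=0.0, n_blocks=2)
        assert res.phi_b == pytest.approx(1.0, abs=0.15)

    def test_fully_demixed_clusters_read_zero(self, rng):
        # two tight clusters, no cross contacts
        n_mol, mlen = 20, 4
        a = rng.uniform(5, 25, (n_mol * mlen // 2, 3))
        b = rng.uniform(75, 95, (n_mol * mlen // 2, 3))
        pos = np.vstack([a, b])
        mol_id = np.repeat(np.arange(n_mol), mlen)
        labels = np.array(["p"] * (n_mol // 2) + ["q"] * (n_mol // 2))
        traj = bead_trajectory([pos], [100.0] * 3, species=labels,
                               mol_id=mol_id)
        res = contact_bond_ratio(traj, "p", burn_in=0.0, n_blocks=1)
        assert res.phi_b == 0.0
        assert res.heterotypic == 0

    def test_missing_species_rejected(self, rng):
        traj = bead_trajectory([rng.uniform(0, 20, (8, 3))], [20.0] * 3)
        with pytest.raises(ValueError, match="not present"):
            contact_bond_ratio(traj, "zz")
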