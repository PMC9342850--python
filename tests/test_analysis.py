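"""Structural analytics: Rg, scaling maps, H-bonds, DSSP-3, pi-contacts,
propensities and weighted bootstrap."""

import numpy as np
import pytest

from idpens import analysis, synth
from idpens.core import Conformer, Ensemble, ValidationError
from tests.conftest import make_conformer


class TestRadiusOfGyration:
    def test_two_atoms_half_distance(self):
        conf = make_conformer(
            [
                (0, "N", (0, 0, 0)), (0, "CA", (0, 0, 0)), (0, "C", (0.1, 0, 0)), (0, "O", (0.2, 0, 0)),
                (1, "N", (0.3, 0, 0)), (1, "CA", (0.4, 0, 0)), (1, "C", (0.5, 0, 0)), (1, "O", (0.6, 0, 0)),
            ],
            ["ALA", "ALA"],
        )
        assert analysis.radius_of_gyration(conf) == pytest.approx(0.2)  # d/2

    def test_pairwise_identity(self, coil60):
        """Rg^2 equals (1/2n^2) sum_ij <r_ij^2> exactly (CA point masses)."""
        w = np.random.default_rng(0).dirichlet(np.ones(coil60.n))
        rg2 = analysis.ensemble_rg(coil60, w) ** 2
        ca = coil60.ca_xyz()
        n = ca.shape[1]
        d2 = np.sum((ca[:, :, None, :] - ca[:, None, :, :]) ** 2, axis=-1)
        mean_d2 = np.tensordot(w, d2, axes=1)
        assert rg2 == pytest.approx(mean_d2.sum() / (2 * n * n), abs=1e-10)

    def test_single_residue_rejected(self):
        conf = make_conformer(
            [(0, "N", (0, 0, 0)), (0, "CA", (0, 0, 0)), (0, "C", (0.1, 0, 0)), (0, "O", (0.2, 0, 0))],
            ["ALA"],
        )
        with pytest.raises(ValidationError):
            analysis.radius_of_gyration(conf)


class TestScalingMap:
    def test_self_reference_is_one(self, coil60):
        sm = analysis.scaling_map(coil60, None, coil60)
        off = sm.D[~np.isnan(sm.D)]
        np.testing.assert_allclose(off, 1.0, rtol=1e-12)

    def test_affine_scaling_law(self, coil60):
        scaled = Ensemble(
            [Conformer(c.coords * 1.2, c.topology) for c in coil60.conformers]
        )
        sm = analysis.scaling_map(scaled, None, coil60)
        off = sm.D[~np.isnan(sm.D)]
        np.testing.assert_allclose(off, 1.2, rtol=1e-12)

    def test_symmetry(self, coil60, compact150):
        ref = coil60
        ens = Ensemble(compact150.conformers[:30])
        # different sequences lengths? both 20 vs 90 -> use coil60 vs itself weighted
        w = np.random.default_rng(1).dirichlet(np.ones(coil60.n))
        sm = analysis.scaling_map(coil60, w, ref)
        np.testing.assert_allclose(sm.D, sm.D.T, equal_nan=True)

    def test_upweighting_compact_subpopulation_contracts_map(self, coil60):
        rg = np.array([analysis.radius_of_gyration(c) for c in coil60.conformers])
        compact_half = rg < np.median(rg)
        w = np.where(compact_half, 2.0, 1.0)
        w = w / w.sum()
        sm = analysis.scaling_map(coil60, w, coil60)
        assert sm.mean_offdiag(min_separation=8) < 1.0

    def test_length_mismatch(self, coil60, compact150):
        with pytest.raises(ValidationError):
            analysis.scaling_map(coil60, None, compact150)


class TestHbondAssign:
    def _fixture(self, d_ho, angle_deg):
        """Donor N-H on residue 0 pointing at acceptor O of residue 12."""
        h = np.array([0.0, 0.0, 0.0])
        n = np.array([-0.101, 0.0, 0.0])  # N-H along +x
        theta = np.radians(180.0 - angle_deg)  # N-H...O angle
        o = h + d_ho * np.array([np.cos(theta), np.sin(theta), 0.0])
        atoms = [
            (0, "N", n), (0, "H", h), (0, "CA", n + (0, 0.15, 0)),
            (0, "C", n + (0.1, 0.15, 0)), (0, "O", n + (0.1, 0.27, 0)),
        ]
        for i in range(1, 12):
            base = np.array([2.0 + 0.4 * i, 2.0, 0.0])
            atoms += [
                (i, "N", base), (i, "H", base + (0, 0.1, 0)), (i, "CA", base + (0.15, 0, 0)),
                (i, "C", base + (0.25, 0, 0)), (i, "O", base + (0.25, 0.12, 0)),
            ]
        base = np.array([0.5, 0.5, 0.5])
        atoms += [
            (12, "N", base), (12, "H", base + (0, 0.1, 0)), (12, "CA", base + (0.15, 0, 0)),
            (12, "C", o - (0.123, 0, 0)), (12, "O", o),
        ]
        return make_conformer(atoms, ["GLY"] * 13)

    def test_short_distance_good_angle_is_bond(self):
        conf = self._fixture(0.20, 175.0)
        bonds = analysis.hbond_assign(conf, min_separation=10)
        assert (0, 12) in bonds

    def test_long_distance_no_bond(self):
        conf = self._fixture(0.40, 175.0)
        assert (0, 12) not in analysis.hbond_assign(conf, min_separation=10)

    def test_sharp_angle_no_bond(self):
        conf = self._fixture(0.20, 90.0)
        assert (0, 12) not in analysis.hbond_assign(conf, min_separation=10)

    def test_separation_filter(self):
        conf = self._fixture(0.20, 175.0)
        assert (0, 12) not in analysis.hbond_assign(conf, min_separation=15)


class TestDssp3:
    def test_ideal_helix_interior_is_helix(self, helix15):
        states = analysis.dssp3(helix15)
        assert set(states[2:12]) == {"H"}

    def test_lone_strand_is_coil(self, strand15):
        """An extended strand with no bridge partner gets no E assignment."""
        states = analysis.dssp3(strand15)
        assert set(states) == {"C"}

    def test_two_residue_chain_all_coil(self):
        conf = synth.build_chain("AA", synth.fixed_sampler(-60, -45))
        assert list(analysis.dssp3(conf)) == ["C", "C"]

    def test_agrees_with_mdtraj_on_helix(self, helix15, tmp_path):
        """Independent cross-check of the reduced assignment against the
        reference DSSP implementation shipped with mdtraj."""
        import mdtraj as md

        from idpens.core import save_ensemble

        path = tmp_path / "helix.pdb"
        save_ensemble(path, Ensemble([helix15]))
        traj = md.load_pdb(str(path), standard_names=False)
        ref = md.compute_dssp(traj, simplified=True)[0]
        ours = analysis.dssp3(helix15)
        interior = slice(2, 12)
        assert list(ref[interior]) == list(ours[interior])


class TestHbondPmf:
    def test_no_bond_ensemble_is_delta_at_zero(self, strand15):
        ens = Ensemble([strand15, strand15])
        pmf, mean = analysis.hbond_pmf(ens, min_separation=10)
        assert pmf[0] == pytest.approx(1.0)
        assert mean == 0.0

    def test_hand_weighted_mean(self, coil60):
        counts = np.array([2, 4])
        ens = Ensemble(coil60.conformers[:2])
        pmf, mean = analysis.hbond_pmf(
            ens, np.array([0.25, 0.75]), counts=counts
        )
        assert mean == pytest.approx(3.5)
        assert pmf.sum() == pytest.approx(1.0)
        assert pmf[2] == pytest.approx(0.25) and pmf[4] == pytest.approx(0.75)

    def test_pmf_normalizes_for_any_weights(self, coil60):
        w = np.random.default_rng(2).dirichlet(np.ones(coil60.n))
        pmf, _ = analysis.hbond_pmf(coil60, w, min_separation=0)
        assert pmf.sum() == pytest.approx(1.0)

    def test_rg_anticorrelated_with_long_range_hbonds_on_compact_prior(self, compact150):
        """Attraction produces tertiary contacts: small radii come with more
        long-range (|i-j| > 10) hydrogen bonds."""
        rg = np.array([analysis.radius_of_gyration(c) for c in compact150.conformers])
        nhb = analysis.hbond_counts(compact150, min_separation=10)
        r = np.corrcoef(rg, nhb)[0, 1]
        assert r < 0


def stacked_planes(dz, tilt_deg=0.0):
    a = analysis.Plane(resid=0, kind="bb", center=np.zeros(3), normal=np.array([0.0, 0.0, 1.0]))
    t = np.radians(tilt_deg)
    b = analysis.Plane(
        resid=20, kind="bb", center=np.array([0.0, 0.0, dz]),
        normal=np.array([np.sin(t), 0.0, np.cos(t)]),
    )
    return [a, b]


class TestPiContacts:
    def test_parallel_stack_within_cutoff_is_contact(self):
        contacts = analysis.plane_contacts(stacked_planes(0.40))
        assert len(contacts) == 1 and contacts[0][2] == "bb-bb"

    def test_distant_stack_no_contact(self):
        assert analysis.plane_contacts(stacked_planes(1.0)) == []

    def test_perpendicular_planes_no_contact(self):
        assert analysis.plane_contacts(stacked_planes(0.40, tilt_deg=90.0)) == []

    def test_sequence_separation_filter(self):
        planes = stacked_planes(0.40)
        planes[1].resid = 5
        assert analysis.plane_contacts(planes, min_separation=10) == []

    def test_backbone_planes_enumerated(self, helix15):
        planes = analysis.backbone_planes(helix15)
        assert len(planes) == 14
        for p in planes:
            assert np.isclose(np.linalg.norm(p.normal), 1.0)

    def test_sidechain_plane_from_explicit_atoms(self):
        ring = {
            "CG": (0.0, 0.14, 0.0), "CD1": (0.12, 0.07, 0.0), "CD2": (-0.12, 0.07, 0.0),
            "CE1": (0.12, -0.07, 0.0), "CE2": (-0.12, -0.07, 0.0), "CZ": (0.0, -0.14, 0.0),
        }
        atoms = [
            (0, "N", (-0.5, 0, 0)), (0, "CA", (-0.4, 0, 0)),
            (0, "C", (-0.3, 0, 0)), (0, "O", (-0.3, 0.12, 0)), (0, "CB", (-0.2, 0.1, 0)),
        ] + [(0, name, xyz) for name, xyz in ring.items()]
        conf = make_conformer(atoms, ["PHE"])
        planes = analysis.sidechain_planes(conf)
        assert len(planes) == 1
        assert planes[0].kind == "sc"
        np.testing.assert_allclose(np.abs(planes[0].normal), [0, 0, 1], atol=1e-12)

    def test_degenerate_plane_warns_and_skips(self):
        atoms = [
            (0, "N", (0, 0, 0)), (0, "CA", (0.1, 0, 0)),
            (0, "C", (0.2, 0, 0)), (0, "O", (0.3, 0, 0)),  # collinear C, O, N(1)
            (1, "N", (0.4, 0, 0)), (1, "CA", (0.5, 0, 0)),
            (1, "C", (0.6, 0, 0)), (1, "O", (0.6, 0.12, 0)),
        ]
        conf = make_conformer(atoms, ["GLY", "GLY"])
        with pytest.warns(UserWarning, match="degenerate"):
            planes = analysis.backbone_planes(conf)
        assert planes == []


class TestSsPropensity:
    def test_all_coil_ensemble(self, strand15):
        ens = Ensemble([strand15] * 3)
        df = analysis.ss_propensity(ens)
        np.testing.assert_allclose(df["coil"], 1.0)

    def test_classes_sum_to_one(self, compact150):
        w = np.random.default_rng(3).dirichlet(np.ones(compact150.n))
        df = analysis.ss_propensity(compact150, w)
        np.testing.assert_allclose(
            df[["helix", "extended", "coil"]].sum(axis=1), 1.0, atol=1e-12
        )

    def test_bootstrap_sds_present_and_bounded(self, compact150):
        df = analysis.ss_propensity(compact150, n_bootstrap=50, seed=1)
        assert (df["helix_sd"] >= 0).all()
        assert (df["helix_sd"] < 0.2).all()


class TestBootstrap:
    def test_constant_statistic_zero_sd(self, coil60):
        sd = analysis.bootstrap_sd(lambda ens, idx: 1.0, coil60, n_bootstrap=20, seed=0)
        assert sd == 0.0

    def test_weighted_mean_matches_analytic_se(self, coil60):
        rng = np.random.default_rng(4)
        x = rng.normal(size=coil60.n)
        w = rng.dirichlet(np.ones(coil60.n) * 0.5)  # skewed weights
        sd = analysis.bootstrap_sd(
            lambda ens, idx: float(x[idx].mean()), coil60, w,
            n_bootstrap=2000, seed=5,
        )
        xbar = w @ x
        se = np.sqrt(np.sum(w * (x - xbar) ** 2) / coil60.n)
        assert abs(sd - se) / se < 0.1

    def test_deterministic_under_seed(self, coil60):
        stat = lambda ens, idx: float(idx.mean())
        a = analysis.bootstrap_sd(stat, coil60, n_bootstrap=50, seed=9)
        b = analysis.bootstrap_sd(stat, coil60, n_bootstrap=50, seed=9)
        assert a == b

    def test_too_few_replicates(self, coil60):
        with pytest.raises(ValidationError):
            analysis.bootstrap_sd(lambda e, i: 0.0, coil60, n_bootstrap=1)
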