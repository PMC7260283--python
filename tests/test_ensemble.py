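import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from nterm.ensemble import (
    StructuralEnsemble,
    ca_distance,
    distance_distributions,
    read_ensemble,
    rmsf,
    superpose,
)
from nterm.synthetic import ChainSpec, sample_tethered_chain, write_ensemble_pdb

# hand-written two-atom, two-model fixture; coordinates are literal Å values
TWO_ATOM_PDB = """\
MODEL        1
ATOM      1  CA  ALA A   1       1.000   2.000   3.000  1.00  0.00           C
ATOM      2  CA  GLY A   2       4.000   6.000   3.000  1.00  0.00           C
ENDMDL
MODEL        2
ATOM      1  CA  ALA A   1       1.000   2.000   3.000  1.00  0.00           C
ATOM      2  CA  GLY A   2       1.000   2.000   8.000  1.00  0.00           C
ENDMDL
END
"""


def brute_force_min_rmsd(mobile, reference, n_grid=20000, seed=0):
    """Independent rotation-space minimizer: random quaternion grid search
    refined by Nelder-Mead on unnormalized quaternion components."""
    mob = mobile - mobile.mean(axis=0)
    ref = reference - reference.mean(axis=0)

    def rmsd_of(quat):
        rot = Rotation.from_quat(quat / np.linalg.norm(quat)).as_matrix()
        return float(np.sqrt(np.mean(np.sum((mob @ rot.T - ref) ** 2, axis=1))))

    rng = np.random.default_rng(seed)
    grid = rng.normal(size=(n_grid, 4))
    best = min(grid, key=rmsd_of)
    res = minimize(rmsd_of, best, method="Nelder-Mead",
                   options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 5000})
    return res.fun


@pytest.fixture
def chain_ensemble():
    spec = ChainSpec(n_residues=12, seed=6, reference_site=(2.0, 0.0, 0.0))
    return sample_tethered_chain(spec, 200)


class TestReadEnsemble:
    def test_round_trip_from_writer(self, tmp_path, chain_ensemble):
        path = tmp_path / "ens.pdb"
        write_ensemble_pdb(chain_ensemble, path)
        back = read_ensemble(path, chain="A")
        assert back.n_frames == chain_ensemble.n_frames
        assert np.array_equal(back.residue_ids, chain_ensemble.residue_ids)
        assert np.abs(back.frames - chain_ensemble.frames).max() < 1e-4

    def test_hand_written_fixture_parsed_literally(self, tmp_path):
        path = tmp_path / "two.pdb"
        path.write_text(TWO_ATOM_PDB)
        ens = read_ensemble(path, chain="A")
        assert ens.n_frames == 2 and ens.n_residues == 2
        # Å fields divided by ten
        assert ens.frames[0, 0] == pytest.approx([0.1, 0.2, 0.3])
        assert ens.frames[1, 1] == pytest.approx([0.1, 0.2, 0.8])
        assert ca_distance(ens, 0, 1, 2) == pytest.approx(0.5)
        assert ca_distance(ens, 1, 1, 2) == pytest.approx(0.5)

    def test_missing_chain_errors(self, tmp_path):
        path = tmp_path / "two.pdb"
        path.write_text(TWO_ATOM_PDB)
        with pytest.raises(KeyError, match="Z"):
            read_ensemble(path, chain="Z")

    def test_model_selection(self, tmp_path, chain_ensemble):
        path = tmp_path / "ens.pdb"
        write_ensemble_pdb(chain_ensemble, path)
        sub = read_ensemble(path, chain="A", models=[0, 5])
        assert sub.n_frames == 2
        assert np.abs(sub.frames[1] - chain_ensemble.frames[5]).max() < 1e-4


class TestCaDistance:
    def test_self_distance_zero(self, chain_ensemble):
        assert ca_distance(chain_ensemble, 0, 3, 3) == 0.0

    def test_symmetric_and_rigid_motion_invariant(self, chain_ensemble):
        d_ij = ca_distance(chain_ensemble, 0, 1, 12)
        assert d_ij == ca_distance(chain_ensemble, 0, 12, 1)
        rot = Rotation.from_euler("xyz", [20, -40, 65], degrees=True).as_matrix()
        moved = StructuralEnsemble(
            frames=chain_ensemble.frames @ rot.T + np.array([1.0, -2.0, 0.5]),
            residue_ids=chain_ensemble.residue_ids,
        )
        assert ca_distance(moved, 0, 1, 12) == pytest.approx(d_ij, rel=1e-12)

    def test_missing_residue_errors(self, chain_ensemble):
        with pytest.raises(KeyError):
            ca_distance(chain_ensemble, 0, 1, 999)


class TestDistanceDistributions:
    def test_single_frame_is_delta(self, chain_ensemble):
        single = StructuralEnsemble(
            frames=chain_ensemble.frames[:1],
            residue_ids=chain_ensemble.residue_ids,
        )
        for dist in distance_distributions(single, range(1, 13), anchor=14):
            assert dist.sd == 0.0
            assert np.count_nonzero(dist.densities) == 1

    def test_translated_copies_match_single_frame(self, chain_ensemble):
        base = chain_ensemble.frames[0]
        shifts = np.array([[0, 0, 0], [1, 2, 3], [-4, 0, 2.5]])
        frames = base[None] + shifts[:, None, :]
        ens = StructuralEnsemble(frames=frames,
                                 residue_ids=chain_ensemble.residue_ids)
        for dist in distance_distributions(ens, range(1, 13), anchor=14):
            assert dist.sd == pytest.approx(0.0, abs=1e-12)

    def test_mean_matches_brute_force_average(self, chain_ensemble):
        dists = distance_distributions(chain_ensemble, [3, 8, 12], anchor=14)
        for dist in dists:
            direct = np.mean([
                ca_distance(chain_ensemble, f, dist.residue_id, 14)
                for f in range(chain_ensemble.n_frames)
            ])
            assert dist.mean == pytest.approx(direct, rel=1e-12)

    def test_histogram_normalized_and_consistent(self, chain_ensemble):
        for dist in distance_distributions(chain_ensemble, [12], anchor=14,
                                           bin_width=0.05):
            widths = np.diff(dist.bin_edges)
            assert np.sum(dist.densities * widths) == pytest.approx(1.0, abs=1e-9)
            # histogram-derived mean within one bin width of the exact mean
            centers = 0.5 * (dist.bin_edges[:-1] + dist.bin_edges[1:])
            hist_mean = np.sum(centers * dist.densities * widths)
            assert abs(hist_mean - dist.mean) < 0.05

    def test_empty_targets_rejected(self, chain_ensemble):
        with pytest.raises(ValueError):
            distance_distributions(chain_ensemble, [], anchor=14)


class TestSuperpose:
    def test_identity_on_equal_frames(self):
        pts = np.random.default_rng(1).normal(size=(6, 3))
        rot, trans, rmsd = superpose(pts, pts)
        assert rmsd < 1e-9
        assert rot == pytest.approx(np.eye(3), abs=1e-7)
        assert trans == pytest.approx(np.zeros(3), abs=1e-7)

    def test_recovers_applied_rigid_motion(self):
        rng = np.random.default_rng(2)
        ref = rng.normal(size=(7, 3))
        applied = Rotation.from_euler("z", 30, degrees=True).as_matrix()
        shift = np.array([0.4, -1.0, 2.0])
        mobile = ref @ applied.T + shift
        rot, trans, rmsd = superpose(mobile, ref)
        assert rmsd < 1e-9
        assert rot @ applied == pytest.approx(np.eye(3), abs=1e-7)

    def test_proper_rotation_even_for_reflected_cloud(self):
        rng = np.random.default_rng(3)
        ref = rng.normal(size=(5, 3))
        mirrored = ref * np.array([-1.0, 1.0, 1.0])
        rot, _, _ = superpose(mirrored, ref)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)

    def test_matches_brute_force_minimizer(self):
        rng = np.random.default_rng(4)
        for _ in range(3):
            ref = rng.normal(size=(5, 3))
            mobile = ref + rng.normal(scale=0.2, size=(5, 3))
            _, _, rmsd = superpose(mobile, ref)
            assert abs(rmsd - brute_force_min_rmsd(mobile, ref)) < 1e-6

    def test_degenerate_selections_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError, match="collinear"):
            superpose(line, line)
        with pytest.raises(ValueError):
            superpose(line[:2], line[:2])


class TestRmsf:
    def test_identical_frames_zero(self):
        base = np.random.default_rng(5).normal(size=(9, 3))
        ens = StructuralEnsemble(frames=np.repeat(base[None], 10, axis=0),
                                 residue_ids=np.arange(1, 10))
        assert rmsf(ens, measure_selection=range(1, 10)).rmsf.max() < 1e-12

    def test_rigid_body_motion_removed(self):
        rng = np.random.default_rng(6)
        base = rng.normal(size=(9, 3))
        frames = []
        for _ in range(20):
            rot = Rotation.random(random_state=rng).as_matrix()
            frames.append(base @ rot.T + rng.normal(size=3))
        ens = StructuralEnsemble(frames=np.array(frames),
                                 residue_ids=np.arange(1, 10))
        profile = rmsf(ens, fit_selection=range(1, 10),
                       measure_selection=range(1, 10))
        assert profile.rmsf.max() < 1e-6

    def test_isotropic_jitter_matches_sigma_sqrt3(self):
        rng = np.random.default_rng(7)
        n_frames, sigma = 5000, 0.1
        base = rng.normal(size=(8, 3))
        frames = np.repeat(base[None], n_frames, axis=0)
        frames[:, 4, :] += rng.normal(scale=sigma, size=(n_frames, 3))
        ens = StructuralEnsemble(frames=frames, residue_ids=np.arange(1, 9))
        profile = rmsf(ens, fit_selection=[1, 2, 3, 4, 6, 7, 8],
                       measure_selection=[5])
        sq = np.sum((frames[:, 4, :] - frames[:, 4, :].mean(axis=0)) ** 2, axis=1)
        se_msd = sq.std(ddof=1) / np.sqrt(n_frames)
        se_rmsf = se_msd / (2 * sigma * np.sqrt(3))
        assert abs(profile.rmsf[0] - sigma * np.sqrt(3)) < 3 * se_rmsf

    def test_frame_order_invariance(self, chain_ensemble):
        profile = rmsf(chain_ensemble, fit_selection=[],
                       measure_selection=range(1, 13))
        rng = np.random.default_rng(8)
        perm = rng.permutation(chain_ensemble.n_frames)
        shuffled = StructuralEnsemble(frames=chain_ensemble.frames[perm],
                                      residue_ids=chain_ensemble.residue_ids)
        reordered = rmsf(shuffled, fit_selection=[],
                         measure_selection=range(1, 13))
        assert profile.rmsf == pytest.approx(reordered.rmsf, rel=1e-12)

    def test_single_frame_rejected(self, chain_ensemble):
        single = StructuralEnsemble(frames=chain_ensemble.frames[:1],
                                    residue_ids=chain_ensemble.residue_ids)
        with pytest.raises(ValueError):
            rmsf(single, measure_selection=range(1, 13))


def test_regime_contrast_widths():
    """Locked ensembles are strictly narrower than free ones per residue."""
    common = dict(n_residues=12, reference_site=(2.0, 0.0, 0.0))
    free = sample_tethered_chain(ChainSpec(mode="inward_free", seed=10, **common),
                                 1000)
    locked = sample_tethered_chain(
        ChainSpec(mode="outward_locked", restraint_site=(1.0, 0.5, 0.5),
                  restraint_k=2000.0, seed=11, **common),
        1000,
    )
    ref_id = 14
    sd_free = [d.sd for d in distance_distributions(free, range(1, 13), ref_id)]
    sd_locked = [d.sd for d in distance_distributions(locked, range(1, 13), ref_id)]
    assert all(l < f for l, f in zip(sd_locked, sd_free))
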