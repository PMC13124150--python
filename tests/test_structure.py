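import itertools

import numpy as np
import pytest

from specfret.errors import (
    DegenerateDistanceError,
    EmptyEnsembleError,
    FormatError,
    PrecisionError,
    SiteError,
    StatisticsError,
)
from specfret.structure import (
    LabelEnsemble,
    OriginFit,
    SamplingParams,
    build_label_ensemble,
    construct_prediction,
    correlate_and_fit,
    distance_distribution,
    donor_efficiency_multi_acceptor,
    ensembles_to_pdb,
    find_native_donors,
    load_structure,
    pair_efficiency,
    sample_conformers,
)
from specfret.synth import ToyStructureScenario, make_helix_bundle


def point_ensemble(xyz, site=("A", 1), label="TRP"):
    return LabelEnsemble(site=site, label_type=label,
                         points=np.asarray([xyz], float),
                         weights=np.array([1.0]))


class TestLoadStructure:
    def test_round_trip_toy_bundle(self, toy_dimer, toy_dimer_pdb):
        model = load_structure(toy_dimer_pdb)
        assert model.chains == toy_dimer.model.chains
        assert (model.atoms.array_length()
                == toy_dimer.model.atoms.array_length())

    def test_single_atom_pdb(self, tmp_path):
        path = tmp_path / "one.pdb"
        path.write_text(
            "ATOM      1  CA  ALA A   1      1.000   2.000   3.000"
            "  1.00  0.00           C\nEND\n")
        model = load_structure(path)
        assert model.chains == ["A"]
        assert model.atoms.array_length() == 1

    def test_no_atoms_is_format_error(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("REMARK nothing here\nEND\n")
        with pytest.raises(FormatError):
            load_structure(path)

    def test_mmcif_round_trip(self, toy_dimer, tmp_path):
        import biotite.structure.io.pdbx as pdbxio

        cif = pdbxio.CIFFile()
        pdbxio.set_structure(cif, toy_dimer.model.atoms)
        path = tmp_path / "toy.cif"
        cif.write(str(path))
        model = load_structure(path)
        assert set(model.chains) == set(toy_dimer.model.chains)


class TestFindNativeDonors:
    def test_toy_donors_found(self, toy_dimer):
        donors = find_native_donors(toy_dimer.model)
        got = {(d.chain, d.res_id, d.res_name) for d in donors}
        assert got == {("A", 3, "TRP"), ("A", 6, "TYR"),
                       ("B", 3, "TRP"), ("B", 6, "TYR")}

    def test_no_aromatics_empty(self):
        hb = make_helix_bundle(ToyStructureScenario(n_res=5))
        assert find_native_donors(hb.model) == []

    def test_two_trp_generator_oracle(self):
        hb = make_helix_bundle(ToyStructureScenario(
            n_res=8, donor_sites=((2, "TRP"), (7, "TRP"))))
        donors = find_native_donors(hb.model)
        assert [(d.res_id, d.res_name) for d in donors] == [
            (2, "TRP"), (7, "TRP")]


class TestBuildLabelEnsemble:
    def test_isolated_site_all_survive(self):
        # single-residue chain: no environment, every conformer kept
        hb = make_helix_bundle(ToyStructureScenario(n_res=1))
        ens = build_label_ensemble(hb.model, ("A", 1), "ACD")
        pts, _ = sample_conformers(hb.model, ("A", 1), "ACD",
                                   SamplingParams())
        assert len(ens) == pts.shape[0]
        np.testing.assert_allclose(ens.weights, 1.0 / len(ens))

    def test_total_clash_cage_raises(self):
        # enclose the site in a dense cage of atoms ~2 A away
        cage = []
        for theta in np.linspace(0, np.pi, 12):
            for phi in np.linspace(0, 2 * np.pi, 24, endpoint=False):
                r = 8.0
                cage.append((r * np.sin(theta) * np.cos(phi),
                             r * np.sin(theta) * np.sin(phi),
                             r * np.cos(theta)))
        # a second shell to be safe
        hb = make_helix_bundle(ToyStructureScenario(
            n_res=1, obstructions=tuple(cage)))
        with pytest.raises(EmptyEnsembleError):
            build_label_ensemble(hb.model, ("A", 1), "ACD",
                                 SamplingParams(clash_cutoff=30.0))

    def test_survivors_match_brute_force_oracle(self):
        params = SamplingParams(clash_cutoff=3.0)
        rng = np.random.default_rng(21)
        for trial in range(5):
            obstructions = tuple(
                tuple(rng.uniform(-8, 8, 3)) for _ in range(6))
            hb = make_helix_bundle(ToyStructureScenario(
                n_res=6, obstructions=obstructions,
                donor_sites=((3, "TRP"),)))
            model = hb.model
            pts, _ = sample_conformers(model, ("A", 3), "TRP", params)
            env = model.heavy_coords_excluding("A", 3)
            # brute-force oracle: explicit double loop
            expected = []
            for p in pts:
                ok = True
                for e in env:
                    if float(np.sqrt(np.sum((p - e) ** 2))) < params.clash_cutoff:
                        ok = False
                        break
                if ok:
                    expected.append(tuple(np.round(p, 9)))
            try:
                ens = build_label_ensemble(model, ("A", 3), "TRP", params)
                got = [tuple(np.round(p, 9)) for p in ens.points]
            except EmptyEnsembleError:
                got = []
            assert got == expected

    def test_boltzmann_weighting_downweights_close_conformers(self):
        hb = make_helix_bundle(ToyStructureScenario(
            n_res=6, donor_sites=((3, "TRP"),)))
        uni = build_label_ensemble(
            hb.model, ("A", 3), "TRP",
            SamplingParams(weighting="uniform", clash_cutoff=2.0))
        boltz = build_label_ensemble(
            hb.model, ("A", 3), "TRP",
            SamplingParams(weighting="boltzmann", clash_cutoff=2.0,
                           boltzmann_radius=8.0))
        assert len(uni) == len(boltz)
        assert np.std(boltz.weights) > 0  # no longer uniform
        assert boltz.weights.sum() == pytest.approx(1.0)

    def test_missing_site_raises(self, toy_dimer):
        with pytest.raises(SiteError):
            build_label_ensemble(toy_dimer.model, ("A", 999), "TRP")

    def test_ensembles_to_pdb_parses_back(self, toy_dimer, tmp_path):
        ens = build_label_ensemble(toy_dimer.model, ("A", 3), "TRP")
        path = tmp_path / "cloud.pdb"
        ensembles_to_pdb([ens], path)
        text = path.read_text()
        assert text.count("MODEL") == len(ens)
        assert "HETATM" in text


class TestDistanceDistribution:
    def test_three_four_five(self):
        d = distance_distribution(point_ensemble((0, 0, 0)),
                                  point_ensemble((3, 4, 0), site=("A", 9)))
        np.testing.assert_allclose(d.distances, [5.0])
        np.testing.assert_allclose(d.weights, [1.0])

    def test_product_weights_2x2(self):
        don = LabelEnsemble(("A", 1), "TRP",
                            np.array([[0.0, 0, 0], [1, 0, 0]]),
                            np.array([0.5, 0.5]))
        acc = LabelEnsemble(("A", 9), "ACD",
                            np.array([[0.0, 10, 0], [0, 12, 0]]),
                            np.array([0.5, 0.5]))
        d = distance_distribution(don, acc)
        assert d.distances.size == 4
        np.testing.assert_allclose(d.weights, 0.25)

    def test_mean_matches_brute_force(self):
        rng = np.random.default_rng(3)
        dp = rng.normal(size=(5, 3)) * 4
        ap = rng.normal(size=(7, 3)) * 4 + 15
        dw = rng.uniform(0.1, 1, 5)
        dw /= dw.sum()
        aw = rng.uniform(0.1, 1, 7)
        aw /= aw.sum()
        don = LabelEnsemble(("A", 1), "TRP", dp, dw)
        acc = LabelEnsemble(("B", 9), "ACD", ap, aw)
        got = distance_distribution(don, acc).mean
        expected = sum(
            dw[i] * aw[j] * float(np.linalg.norm(dp[i] - ap[j]))
            for i in range(5) for j in range(7))
        assert got == pytest.approx(expected, rel=1e-12)

    def test_coincident_points_degenerate(self):
        with pytest.raises(DegenerateDistanceError):
            distance_distribution(point_ensemble((1, 1, 1)),
                                  point_ensemble((1, 1, 1), site=("B", 1)))


class TestPairEfficiency:
    def test_forster_midpoint(self):
        d = distance_distribution(point_ensemble((0, 0, 0)),
                                  point_ensemble((23.5, 0, 0), site=("B", 1)))
        assert pair_efficiency(d, 23.5) == 0.5

    def test_near_contact_limit(self):
        r0 = 20.0
        d = distance_distribution(point_ensemble((0, 0, 0)),
                                  point_ensemble((r0 / 10, 0, 0), site=("B", 1)))
        assert pair_efficiency(d, r0) == pytest.approx(1 / (1 + 1e-6))

    def test_two_distance_closed_form(self):
        r0 = 20.0
        don = point_ensemble((0, 0, 0))
        acc = LabelEnsemble(("B", 1), "ACD",
                            np.array([[r0, 0, 0], [2 * r0, 0, 0]]),
                            np.array([0.5, 0.5]))
        d = distance_distribution(don, acc)
        # closed form: (1/2)(1/(1+1) + 1/(1+64)) = (0.5 + 1/65)/2
        assert pair_efficiency(d, r0) == pytest.approx((0.5 + 1 / 65) / 2)

    def test_strictly_decreasing_in_distance(self):
        r0 = 23.5
        effs = [
            pair_efficiency(
                distance_distribution(
                    point_ensemble((0, 0, 0)),
                    point_ensemble((r, 0, 0), site=("B", 1))), r0)
            for r in np.linspace(5, 60, 12)
        ]
        assert np.all(np.diff(effs) < 0)
        assert all(0 < e < 1 for e in effs)


class TestMultiAcceptor:
    def test_single_acceptor_reduces_to_pair(self):
        don = point_ensemble((0, 0, 0))
        acc = point_ensemble((23.5, 0, 0), site=("B", 1), label="ACD")
        e = donor_efficiency_multi_acceptor(don, [acc], 23.5)
        assert e == pytest.approx(0.5)

    def test_two_acceptors_at_r0(self):
        don = point_ensemble((0, 0, 0))
        a1 = point_ensemble((23.5, 0, 0), site=("A", 9), label="ACD")
        a2 = point_ensemble((0, 23.5, 0), site=("B", 9), label="ACD")
        e = donor_efficiency_multi_acceptor(don, [a1, a2], 23.5)
        assert e == pytest.approx(2.0 / 3.0)

    def test_mc_agrees_with_enumeration(self):
        rng = np.random.default_rng(17)
        don = LabelEnsemble(("A", 1), "TRP", rng.normal(size=(3, 3)) * 5,
                            np.full(3, 1 / 3))
        accs = [
            LabelEnsemble(("A", 9), "ACD",
                          rng.normal(size=(3, 3)) * 5 + [18, 0, 0],
                          np.full(3, 1 / 3)),
            LabelEnsemble(("B", 9), "ACD",
                          rng.normal(size=(3, 3)) * 5 + [0, 25, 0],
                          np.full(3, 1 / 3)),
        ]
        exact = donor_efficiency_multi_acceptor(don, accs, 23.5,
                                                method="enumerate")
        mc, se = donor_efficiency_multi_acceptor(
            don, accs, 23.5, method="mc", n_samples=200_000, seed=5,
            return_se=True)
        assert abs(mc - exact) < 3 * max(se, 1e-12)

    def test_mc_reproducible_with_seed(self):
        rng = np.random.default_rng(9)
        don = LabelEnsemble(("A", 1), "TRP", rng.normal(size=(4, 3)) * 6,
                            np.full(4, 0.25))
        acc = LabelEnsemble(("B", 9), "ACD",
                            rng.normal(size=(4, 3)) * 6 + [20, 0, 0],
                            np.full(4, 0.25))
        e1 = donor_efficiency_multi_acceptor(don, [acc], 23.5, method="mc",
                                             n_samples=10_000, seed=42)
        e2 = donor_efficiency_multi_acceptor(don, [acc], 23.5, method="mc",
                                             n_samples=10_000, seed=42)
        assert e1 == e2

    def test_adding_acceptor_never_decreases(self):
        rng = np.random.default_rng(13)
        don = LabelEnsemble(("A", 1), "TRP", rng.normal(size=(3, 3)) * 5,
                            np.full(3, 1 / 3))
        a1 = LabelEnsemble(("A", 9), "ACD",
                           rng.normal(size=(3, 3)) * 5 + [20, 0, 0],
                           np.full(3, 1 / 3))
        a2 = LabelEnsemble(("B", 9), "ACD",
                           rng.normal(size=(3, 3)) * 5 + [0, 30, 0],
                           np.full(3, 1 / 3))
        e1 = donor_efficiency_multi_acceptor(don, [a1], 23.5)
        e12 = donor_efficiency_multi_acceptor(don, [a1, a2], 23.5)
        assert e12 >= e1

    def test_small_mc_sample_precision_error(self):
        rng = np.random.default_rng(1)
        don = LabelEnsemble(("A", 1), "TRP", rng.normal(size=(30, 3)) * 5,
                            np.full(30, 1 / 30))
        accs = [LabelEnsemble((c, 9), "ACD",
                              rng.normal(size=(30, 3)) * 5 + [20, 0, 0],
                              np.full(30, 1 / 30))
                for c in "AB"]  # 30*30*30 = 27000 > enumeration limit
        with pytest.raises(PrecisionError):
            donor_efficiency_multi_acceptor(don, accs, 23.5, n_samples=50)


class TestConstructPrediction:
    def test_symmetric_dimer_equals_single_donor_value(self):
        # C2-symmetric dimer, one TRP per chain: aggregate == per-donor value
        hb = make_helix_bundle(ToyStructureScenario(
            n_res=10, chain_offsets=((0, 0, 0), (26, 0, 0)),
            chain_rotations_z_deg=(0.0, 180.0),
            donor_sites=((3, "TRP"),)))
        pred = construct_prediction(hb.model, 8, mode="all_donors")
        per = pred.per_donor["efficiency"].to_numpy()
        assert per.size == 2
        assert pred.efficiency == pytest.approx(per.mean())
        assert per[0] == pytest.approx(per[1], rel=1e-6)

    def test_intrasubunit_smaller_than_all_donors(self, toy_dimer):
        e_all = construct_prediction(toy_dimer.model, 9,
                                     mode="all_donors").efficiency
        e_intra = construct_prediction(toy_dimer.model, 9,
                                       mode="intrasubunit").efficiency
        assert e_all >= e_intra
        assert e_intra > 0

    def test_rigid_body_invariance(self, toy_dimer):
        from scipy.spatial.transform import Rotation

        rot = Rotation.from_euler("xyz", [0.3, -1.1, 2.0]).as_matrix()
        moved = toy_dimer.model.transformed(rot, np.array([5.0, -3.0, 12.0]))
        e0 = construct_prediction(toy_dimer.model, 9).efficiency
        e1 = construct_prediction(moved, 9).efficiency
        assert e1 == pytest.approx(e0, rel=1e-6)

    def test_donor_at_acceptor_site_excluded(self):
        hb = make_helix_bundle(ToyStructureScenario(
            n_res=10, chain_offsets=((0, 0, 0), (26, 0, 0)),
            donor_sites=((3, "TRP"), (8, "TYR"))))
        pred = construct_prediction(hb.model, 8)
        assert set(pred.per_donor["donor_res_id"]) == {3}

    def test_missing_site_error(self, toy_dimer):
        with pytest.raises(SiteError):
            construct_prediction(toy_dimer.model, 999)

    def test_distance_average_modes_differ(self, toy_dimer):
        e_eff = construct_prediction(toy_dimer.model, 9,
                                     distance_average="efficiency").efficiency
        e_dist = construct_prediction(toy_dimer.model, 9,
                                      distance_average="distance").efficiency
        assert 0 < e_dist < 1
        assert e_eff != e_dist  # Jensen gap on a spread distribution


class TestCorrelateAndFit:
    def test_identity(self):
        v = np.array([0.1, 0.2, 0.3, 0.4])
        fit = correlate_and_fit(v, v)
        assert fit.pearson_r == pytest.approx(1.0)
        assert fit.slope_m == pytest.approx(1.0)

    def test_proportionality(self):
        x = np.array([0.1, 0.2, 0.3])
        fit = correlate_and_fit(2 * x, x)
        assert fit.pearson_r == pytest.approx(1.0)
        assert fit.slope_m == pytest.approx(2.0)

    def test_closed_form_toy_vectors(self):
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([2.0, 4.0, 7.0])
        fit = correlate_and_fit(y, x)
        # hand closed form: m = sum(xy)/sum(x^2) = 31/14
        assert fit.slope_m == pytest.approx(31 / 14)
        # r = cov/(sx sy) computed longhand
        r_oracle = (np.sum((x - x.mean()) * (y - y.mean()))
                    / np.sqrt(np.sum((x - x.mean()) ** 2)
                              * np.sum((y - y.mean()) ** 2)))
        assert fit.pearson_r == pytest.approx(r_oracle)

    def test_zero_variance_error(self):
        with pytest.raises(StatisticsError):
            correlate_and_fit([1.0, 1.0, 1.0], [0.1, 0.2, 0.3])

    def test_n_too_small(self):
        with pytest.raises(StatisticsError):
            correlate_and_fit([1.0, 2.0], [1.0, 2.0])

    def test_origin_fit_invariants(self):
        with pytest.raises(StatisticsError):
            OriginFit(slope_m=1.0, pearson_r=0.5, n=2)
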