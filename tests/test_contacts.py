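"""Contact detection and the normalized contact profiles."""

import numpy as np
import pandas as pd
import pytest

import memlip as ml
from memlip.contacts import contact_pairs, minmax_scale
from memlip.pbc import minimum_image_distance

from conftest import single_bead_system


def brute_force_pairs(coords, box, idx_a, idx_b, cutoff):
    """O(N^2) minimum-image oracle for the neighbor search."""
    out = set()
    for i, a in enumerate(idx_a):
        d = minimum_image_distance(coords[a], coords[idx_b], box)
        for j in np.flatnonzero(d <= cutoff):
            out.add((i, int(j)))
    return out


class TestFindContacts:
    @pytest.mark.parametrize("gap, expected", [(0.54, True), (0.56, False)])
    def test_cutoff_edge(self, gap, expected):
        topo, frame = single_bead_system([[5 + gap, 5, 5]], ["PIP2"],
                                         protein_positions=[[5, 5, 5]])
        pairs = ml.find_contacts(frame, topo, ml.Selection(molecule_kind="protein"),
                                 ml.Selection(molecule_kind="lipid"), cutoff=0.55)
        assert (len(pairs) == 1) is expected

    def test_periodic_image_counted(self):
        topo, frame = single_bead_system([[9.9, 5, 5]], ["PIP2"],
                                         protein_positions=[[0.1, 5, 5]])
        pairs = ml.find_contacts(frame, topo, ml.Selection(molecule_kind="protein"),
                                 ml.Selection(molecule_kind="lipid"), cutoff=0.55)
        assert len(pairs) == 1

    def test_cutoff_beyond_half_box_rejected(self):
        topo, frame = single_bead_system([[1, 1, 1]], ["PIP2"],
                                         protein_positions=[[2, 2, 2]])
        with pytest.raises(ValueError, match="half"):
            ml.find_contacts(frame, topo, ml.Selection(molecule_kind="protein"),
                             ml.Selection(molecule_kind="lipid"), cutoff=6.0)

    def test_overlapping_groups_rejected(self):
        topo, frame = single_bead_system([[1, 1, 1]], ["PIP2"])
        sel = ml.Selection(molecule_kind="lipid")
        with pytest.raises(ValueError, match="disjoint"):
            ml.find_contacts(frame, topo, sel, sel, cutoff=0.55)

    @pytest.mark.parametrize("seed", range(5))
    def test_neighbor_search_equals_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = 200
        box = rng.uniform(4, 12, 3)
        coords = rng.uniform(0, 1, (n, 3)) * box
        idx_a = np.arange(0, n // 2)
        idx_b = np.arange(n // 2, n)
        cutoff = rng.uniform(0.3, 0.45 * box.min())
        got = {(i, j) for i, j in contact_pairs(coords, box, idx_a, idx_b, cutoff)}
        assert got == brute_force_pairs(coords, box, idx_a, idx_b, cutoff)

    def test_translation_invariance(self, bound_run):
        traj, _, _ = bound_run
        topo = traj.topology
        frame = traj.frame(5)
        shifted = ml.Frame(frame.coordinates + np.array([3.1, -2.2, 0.7]),
                           frame.box, frame.time)
        sel_p = ml.Selection(molecule_kind="protein")
        sel_l = ml.Selection(molecule_kind="lipid")
        assert ml.find_contacts(frame, topo, sel_p, sel_l, 0.55) == \
            ml.find_contacts(shifted, topo, sel_p, sel_l, 0.55)


class TestFingerprint:
    def test_permanent_single_lipid_contact_gives_n_equal_one(self):
        topo, frame = single_bead_system([[5.3, 5, 5]], ["PIP2"],
                                         protein_positions=[[5, 5, 5]])
        traj = ml.Trajectory(topo, [ml.Frame(frame.coordinates, frame.box, t * 0.2)
                                    for t in range(6)])
        fp = ml.fingerprint(traj, cutoff=0.55)
        assert fp.n3 == 6
        assert fp.n2["PIP2"] == 1
        assert fp.n1.loc[("P", 1), "PIP2"] == 6
        assert fp.normalized.loc[("P", 1), "PIP2"] == pytest.approx(1.0)

    def test_no_contacts_gives_all_zero(self):
        topo, frame = single_bead_system([[1, 1, 1]], ["PIP2"],
                                         protein_positions=[[8, 8, 8]])
        traj = ml.Trajectory(topo, [frame])
        fp = ml.fingerprint(traj, cutoff=0.55)
        assert (fp.normalized.to_numpy() == 0).all()

    def test_per_lipid_counts_sum_over_lipids(self):
        topo, frame = single_bead_system([[5.3, 5, 5], [4.7, 5, 5]],
                                         ["PIP2", "PIP2"],
                                         protein_positions=[[5, 5, 5]])
        traj = ml.Trajectory(topo, [frame])
        per_lipid = ml.fingerprint(traj, cutoff=0.55, count_mode="per_lipid")
        per_frame = ml.fingerprint(traj, cutoff=0.55, count_mode="per_frame")
        assert per_lipid.n1.loc[("P", 1), "PIP2"] == 2
        assert per_frame.n1.loc[("P", 1), "PIP2"] == 1

    def test_binding_site_residues_prefer_bound_species(self, bound_run):
        traj, _, sites = bound_run
        fp = ml.fingerprint(traj, cutoff=0.55)
        totals = fp.normalized.sum(axis=0)
        assert totals["PIP2"] > totals["POPC"]
        assert totals["PIP3"] > totals["POPC"]

    def test_absent_species_rejected(self, bound_run):
        traj, _, _ = bound_run
        with pytest.raises(ValueError, match="zero lipids"):
            ml.fingerprint(traj, cutoff=0.55, species=["DOPE"])


class TestAcylProfile:
    def _depth_system(self, depths):
        """Protein residues pinned at increasing depth next to one acyl bead."""
        records = []
        coords = []
        from conftest import particle
        for i, z in enumerate(depths):
            records.append(particle(name="BB", kind="protein", mol=i, res=i + 1,
                                    resname="GLY", chain="P", region="CYR",
                                    role="backbone"))
            coords.append([1.0 + i * 2.0, 1.0, z])
        # one lipid per residue with an acyl bead at z=4.0 under it, plus
        # far-away bulk lipids entering only the normalizer
        mol = len(depths)
        for i in range(len(depths)):
            records.append(particle(name="C1A", mol=mol, res=mol + 1,
                                    resname="POPC", species="POPC",
                                    leaflet="inner", role="acyl"))
            coords.append([1.0 + i * 2.0, 1.0, 4.0])
            mol += 1
        for i in range(5):
            records.append(particle(name="C1A", mol=mol, res=mol + 1,
                                    resname="POPC", species="POPC",
                                    leaflet="inner", role="acyl"))
            coords.append([1.0 + i * 2.0, 8.0, 4.0])
            mol += 1
        from conftest import make_topology
        topo = make_topology(records)
        frame = ml.Frame(np.array(coords, dtype=float), np.array([12.0, 12.0, 10.0]))
        return topo, ml.Trajectory(topo, [frame])

    def test_contact_value_is_one_over_total_lipids(self):
        topo, traj = self._depth_system([4.2])
        profile = ml.acyl_contact_profile(traj, cutoff=0.55)
        assert profile.loc[("P", 1)] == pytest.approx(1.0 / 6.0)

    def test_residue_above_headgroups_scores_zero(self):
        topo, traj = self._depth_system([7.5])
        profile = ml.acyl_contact_profile(traj, cutoff=0.55)
        assert profile.loc[("P", 1)] == 0.0

    def test_no_acyl_particles_is_an_error(self):
        topo, frame = single_bead_system([[1, 1, 1]], ["POPC"],
                                         protein_positions=[[2, 2, 2]])
        with pytest.raises(ValueError, match="acyl"):
            ml.acyl_contact_profile(ml.Trajectory(topo, [frame]))


class TestNitrogenContacts:
    def _pe_system(self, with_pe=True):
        from conftest import make_topology, particle
        records = [particle(name="BB", kind="protein", mol=0, res=1, resname="ASP",
                            chain="T", region="TMR", role="backbone")]
        coords = [[5.0, 5.0, 5.0]]
        sp = "POPE" if with_pe else "PIP2"
        name = "NC3" if with_pe else "PO4"
        role = "nitrogen" if with_pe else "phosphate"
        records.append(particle(name=name, mol=1, res=2, resname=sp, species=sp,
                                leaflet="outer", role=role))
        coords.append([5.3, 5.0, 5.0])
        topo = make_topology(records)
        frames = [ml.Frame(np.array(coords), np.array([10.0, 10, 10]), t * 0.2)
                  for t in range(10)]
        return topo, ml.Trajectory(topo, frames)

    def test_pinned_pe_nitrogen_counts_every_frame(self):
        topo, traj = self._pe_system()
        counts = ml.nitrogen_contact_counts(traj, cutoff=0.4,
                                            residue_sel=ml.Selection(region="TMR"))
        assert counts["POPE"] == 10
        assert counts["POPC"] == 0

    def test_system_without_pe_reports_zero(self):
        topo, traj = self._pe_system(with_pe=False)
        counts = ml.nitrogen_contact_counts(traj, cutoff=0.4,
                                            residue_sel=ml.Selection(region="TMR"))
        assert counts["POPE"] == 0

    def test_empty_residue_selection_rejected(self):
        topo, traj = self._pe_system()
        with pytest.raises(ValueError, match="empty"):
            ml.nitrogen_contact_counts(traj, residue_sel=ml.Selection(region="ECD"))


class TestMinMaxScale:
    def test_column_scaling(self):
        scaled = minmax_scale(pd.Series([0.0, 2.0, 4.0]))
        assert list(scaled) == [0.0, 0.5, 1.0]

    def test_all_equal_maps_to_one(self):
        scaled = minmax_scale(pd.Series([3.0, 3.0, 3.0]))
        assert list(scaled) == [1.0, 1.0, 1.0]

    def test_all_zero_warns_and_passes_through(self):
        with pytest.warns(UserWarning, match="all-zero"):
            scaled = minmax_scale(pd.Series([0.0, 0.0]))
        assert list(scaled) == [0.0, 0.0]

    def test_per_species_vs_per_system_differ_iff_maxima_differ(self):
        same = pd.DataFrame({"A": [1.0, 2.0], "B": [2.0, 1.0]})
        diff = pd.DataFrame({"A": [1.0, 2.0], "B": [4.0, 1.0]})
        assert minmax_scale(same, "per_species").equals(minmax_scale(same, "per_system"))
        assert not minmax_scale(diff, "per_species").equals(
            minmax_scale(diff, "per_system"))


class TestBoundLipidSeries:
    def test_fully_bound_series_is_constant_one(self):
        positions = [[5.3 + 0.01 * i, 5, 5] for i in range(3)]
        topo, frame = single_bead_system(positions, ["PIP2"] * 3,
                                         protein_positions=[[5, 5, 5]])
        traj = ml.Trajectory(topo, [ml.Frame(frame.coordinates, frame.box, t * 0.2)
                                    for t in range(8)])
        series, smoothed = ml.bound_lipid_timeseries(traj, 0.55, species=("PIP2",))
        assert np.allclose(series["PIP2"], 1.0)
        assert np.allclose(smoothed["PIP2"], 1.0, atol=1e-9)

    def test_cubic_fit_matches_normal_equations(self, bound_run):
        traj, _, _ = bound_run
        series, smoothed = ml.bound_lipid_timeseries(traj, 0.55,
                                                     species=("PIP2",))
        t, y = traj.times, series["PIP2"].to_numpy()
        vand = np.vander(t, 4, increasing=True)
        beta = np.linalg.solve(vand.T @ vand, vand.T @ y)
        assert np.allclose(smoothed["PIP2"], vand @ beta, atol=1e-8)

    def test_too_few_frames_for_cubic_rejected(self):
        topo, frame = single_bead_system([[5.3, 5, 5]], ["PIP2"],
                                         protein_positions=[[5, 5, 5]])
        traj = ml.Trajectory(topo, [ml.Frame(frame.coordinates, frame.box, t * 0.2)
                                    for t in range(3)])
        with pytest.raises(ValueError, match="frames"):
            ml.bound_lipid_timeseries(traj, 0.55, species=("PIP2",))


class TestInterchain:
    def _two_chain_traj(self, separation):
        from conftest import make_topology, particle
        records, coords = [], []
        for c, chain in enumerate("AB"):
            for r in range(3):
                records.append(particle(name="BB", kind="protein", mol=c, res=r + 1,
                                        resname="GLY", chain=chain, region="CYR",
                                        role="backbone"))
                coords.append([1.0 + r, 1.0 + c * separation, 5.0])
        topo = make_topology(records)
        frames = [ml.Frame(np.array(coords), np.array([20.0, 20, 10]), t * 0.2)
                  for t in range(4)]
        return topo, ml.Trajectory(topo, frames)

    def test_distant_chains_give_zero_profile(self):
        topo, traj = self._two_chain_traj(5.0)
        prof = ml.interchain_contact_profile(traj, 0.55, ml.Selection(chain_id="A"),
                                             ml.Selection(chain_id="B"))
        assert (prof["count"] == 0).all()

    def test_permanent_pair_scales_to_one_on_both_sides(self):
        topo, traj = self._two_chain_traj(0.4)
        prof = ml.interchain_contact_profile(traj, 0.55, ml.Selection(chain_id="A"),
                                             ml.Selection(chain_id="B"))
        assert prof["normalized"].max() == 1.0
        for side in "AB":
            assert prof[prof.side == side]["normalized"].max() == 1.0

    def test_identical_selections_rejected(self):
        topo, traj = self._two_chain_traj(0.4)
        with pytest.raises(ValueError, match="identical"):
            ml.interchain_contact_profile(traj, 0.55, ml.Selection(chain_id="A"),
                                          ml.Selection(chain_id="A"))

    def test_profile_matches_per_frame_enumeration(self):
        topo, traj = self._two_chain_traj(0.4)
        prof = ml.interchain_contact_profile(traj, 0.55, ml.Selection(chain_id="A"),
                                             ml.Selection(chain_id="B"))
        idx_a = ml.Selection(chain_id="A").resolve(topo)
        idx_b = ml.Selection(chain_id="B").resolve(topo)
        counts_a = {int(topo.residue_index[i]): 0 for i in idx_a}
        for f in range(traj.n_frames):
            seen = set()
            for i in idx_a:
                for j in idx_b:
                    d = minimum_image_distance(traj.coordinates[f, i],
                                               traj.coordinates[f, j], traj.boxes[f])
                    if d <= 0.55:
                        seen.add((int(topo.residue_index[i]),
                                  int(topo.residue_index[j])))
            for ra, _ in seen:
                counts_a[ra] += 1
        got = prof[prof.side == "A"].set_index("residue_index")["count"].to_dict()
        assert got == counts_a


class TestStationarySubsampling:
    def test_fingerprint_invariant_under_frame_subsampling(self):
        """On a stationary binding run, stride 1 and stride 2 fingerprints
        agree within 5% for every species that actually binds."""
        mem = ml.build_membrane(
            ml.MembraneSpec(lx=16.0, ly=16.0, protein_exclusion_radius=3.0),
            50, seed=3)
        prot = ml.build_protein(ml.ProteinSpec(
            n_helices=2, chain_ids=["A", "B"], tilt_deg=[0, 0],
            tail_lengths=[6, 6], ecd_sizes=[2, 2]))
        topo, f0 = ml.combine_systems(mem, prot)
        sites = ml.pick_binding_sites(topo, f0, 3.0, 4)
        kin = ml.BindingKineticsSpec(kon={"PIP2": 1.0, "POPS": 1.0},
                                     koff={"PIP2": 0.5, "POPS": 1.0},
                                     site_indices=sites, diffusion=0.0)
        traj, _ = ml.simulate_trajectory(topo, f0, kin, 10000, 0.1, seed=4)
        full = ml.fingerprint(traj, 0.55).normalized.sum(axis=0)
        half = ml.fingerprint(traj.strided(2), 0.55).normalized.sum(axis=0)
        for species in full[full > 0.01].index:
            assert half[species] == pytest.approx(full[species], rel=0.05)
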