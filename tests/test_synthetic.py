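"""Generators: geometry invariants, exact second moments, planted truths."""

import numpy as np
import pytest

from allosterik.correlation import dcc_from_covariance
from allosterik.exceptions import DegenerateModelError, SpecificationError
from allosterik.synthetic import (
    DEFAULT_VARIANT_TABLE,
    STATES,
    CurveSpec,
    ENMTrajectorySpec,
    PanelSpec,
    ToyDimerSpec,
    generate_curve,
    generate_sequence_panel,
    generate_state_suite,
    generate_toy_dimer,
    parse_variant,
    sample_enm_trajectory,
)


class TestToyDimer:
    def test_explicit_domain_map_construction(self):
        spec = ToyDimerSpec(
            residues_per_monomer=20,
            domain_map=(("DBD", 1, 6), ("linker", 7, 9), ("EO", 10, 20)),
        )
        s = generate_toy_dimer(spec)
        assert s.n_atoms == 40
        assert len(s.atoms["domain"]) == 40
        assert list(s.atoms["chain"].unique()) == ["A", "B"]

    def test_default_dgor_size(self):
        s = generate_toy_dimer(ToyDimerSpec())
        assert s.n_atoms == 458
        assert set(s.atoms["chain"]) == {"A", "B"}

    def test_bead_spacing(self, reference):
        for chain in ("A", "B"):
            mask = (reference.atoms["chain"] == chain).to_numpy()
            d = np.linalg.norm(np.diff(reference.coords[mask], axis=0), axis=1)
            assert d.min() >= 3.7 and d.max() <= 3.9

    def test_overlapping_domains_rejected(self):
        with pytest.raises(SpecificationError):
            ToyDimerSpec(
                residues_per_monomer=20,
                domain_map=(("DBD", 1, 8), ("linker", 7, 9), ("EO", 10, 20)),
            )

    def test_incomplete_coverage_rejected(self):
        with pytest.raises(SpecificationError):
            ToyDimerSpec(
                residues_per_monomer=20,
                domain_map=(("DBD", 1, 6), ("linker", 7, 9), ("EO", 10, 19)),
            )


class TestENMTrajectory:
    def test_frozen_limit(self, dimer_spec, reference):
        spec = ENMTrajectorySpec(
            spec=dimer_spec, n_frames=10, temperature_scale=0.0, seed=1
        )
        traj, sigma = sample_enm_trajectory(spec)
        assert np.allclose(traj.coords, reference.coords[None])
        assert np.allclose(sigma, 0.0)

    def test_seed_determinism(self, dimer_spec):
        spec = ENMTrajectorySpec(spec=dimer_spec, n_frames=50, seed=42)
        t1, s1 = sample_enm_trajectory(spec)
        t2, s2 = sample_enm_trajectory(spec)
        assert np.array_equal(t1.coords, t2.coords)
        assert np.array_equal(s1, s2)

    def test_planted_cross_monomer_coupling_raises_correlation(self, dimer_spec):
        """A stiff spring between weakly coupled DBD/EO residues of opposite
        monomers strictly raises their analytic correlation."""
        n = dimer_spec.residues_per_monomer
        i, j = 3, n + 14  # DBD of chain A, EO of chain B
        base = ENMTrajectorySpec(spec=dimer_spec, n_frames=10, seed=0)
        planted = ENMTrajectorySpec(
            spec=dimer_spec, n_frames=10, seed=0, extra_couplings=((i, j, 10.0),)
        )
        _, s0 = sample_enm_trajectory(base)
        _, s1 = sample_enm_trajectory(planted)
        c0 = abs(dcc_from_covariance(s0).C[i - 1, j - 1])
        c1 = abs(dcc_from_covariance(s1).C[i - 1, j - 1])
        assert c1 > c0

    def test_disconnected_network_names_isolated_residues(self, dimer_spec):
        # 6 Å cutoff separates the two chains (11 Å apart)
        spec = ENMTrajectorySpec(spec=dimer_spec, n_frames=10, contact_cutoff=6.0)
        with pytest.raises(DegenerateModelError, match="isolated residues"):
            sample_enm_trajectory(spec)

    def test_covariance_converges_with_frames(self, enm_sample, reference):
        traj, sigma = enm_sample
        disp = (traj.coords - reference.coords[None]).reshape(traj.n_frames, -1)

        def maxerr(m):
            d = disp[:m]
            emp = (d.T @ d) / m
            return np.max(np.abs(emp - sigma))

        assert maxerr(5000) < maxerr(500)

    def test_too_few_frames_rejected(self, dimer_spec):
        with pytest.raises(SpecificationError):
            ENMTrajectorySpec(spec=dimer_spec, n_frames=5)


class TestStateSuite:
    def test_four_states_exactly(self, state_suite):
        assert set(state_suite) == set(STATES) and len(state_suite) == 4

    def test_two_variants_give_eight_systems(self, dimer_spec):
        systems = []
        for v_idx in range(2):
            base = ENMTrajectorySpec(spec=dimer_spec, n_frames=10, seed=v_idx)
            systems.extend(generate_state_suite(base))
        assert len(systems) == 8

    def test_apo_matches_bare_spec(self, dimer_spec, state_suite):
        bare = ENMTrajectorySpec(spec=dimer_spec, n_frames=1500, seed=11)
        traj, _ = sample_enm_trajectory(bare)
        assert np.array_equal(traj.coords, state_suite["APO"][0].coords)


class TestSequencePanel:
    def test_default_panel_dimensions(self):
        result = generate_sequence_panel(PanelSpec.default_dgor_panel(seed=1))
        assert len(result.records) == 340
        assert len(result.reference) == 229
        assert len(result.truth) == 42
        assert result.truth["variant"].nunique() == 12

    def test_truth_table_consistent_with_fasta(self):
        """Re-diffing every record against the reference reproduces the truth."""
        result = generate_sequence_panel(PanelSpec.default_dgor_panel(seed=7))
        observed = []
        for rec_id, seq in result.records:
            for pos, (a, b) in enumerate(zip(result.reference, seq), start=1):
                if a != b:
                    observed.append((f"{a}{pos}{b}", rec_id))
        expected = set(zip(result.truth["variant"], result.truth["carrier_id"]))
        assert set(observed) == expected and len(observed) == len(expected)

    def test_zero_variants_all_identical(self):
        result = generate_sequence_panel(PanelSpec(50, (), 5, seed=2))
        assert all(seq == result.reference for _, seq in result.records)

    def test_single_variant_single_carrier(self):
        result = generate_sequence_panel(
            PanelSpec(30, ((10, "A", "V", 1),), 3, seed=3)
        )
        diffs = [
            (rid, [p for p, (a, b) in enumerate(zip(result.reference, s), 1) if a != b])
            for rid, s in result.records
        ]
        changed = [(rid, d) for rid, d in diffs if d]
        assert len(changed) == 1 and changed[0][1] == [10]

    def test_conflicting_reference_residues_rejected(self):
        with pytest.raises(SpecificationError):
            PanelSpec(30, ((10, "A", "V", 1), (10, "G", "S", 1)), 5)

    def test_carrier_overflow_rejected(self):
        with pytest.raises(SpecificationError):
            PanelSpec(30, ((10, "A", "V", 4),), 3)

    def test_variant_table_sums_to_census(self):
        assert sum(n for _, n in DEFAULT_VARIANT_TABLE) == 42
        assert len(DEFAULT_VARIANT_TABLE) == 12
        assert parse_variant("A152E") == (152, "A", "E")


class TestCurves:
    def test_noiseless_hill_exact(self):
        x = tuple(np.linspace(50, 1600, 12))
        spec = CurveSpec("hill", (("K_D", 494.0), ("n", 1.0)), x, 0.0, 0)
        c = generate_curve(spec)
        expected = np.array(x) / (494.0 + np.array(x))
        assert np.allclose(c.y, expected)

    def test_noiseless_growth_doubles_on_schedule(self):
        params = (("lag", 0.0), ("doubling_time", 1.62), ("od0", 0.03), ("plateau", 100.0))
        t = tuple(np.arange(0.0, 12.0, 0.5))
        c = generate_curve(CurveSpec("growth_lag_exp", params, t, 0.0, 0))
        shifted = generate_curve(
            CurveSpec("growth_lag_exp", params, tuple(np.array(t) + 1.62), 0.0, 0)
        )
        # OD at t+1.62 h is exactly twice OD at t throughout the exponential window
        assert np.allclose(shifted.y, 2.0 * c.y, rtol=1e-9)

    def test_seeded_noise_reproducible(self):
        x = tuple(np.linspace(1, 100, 10))
        spec = CurveSpec("hill", (("K_D", 20.0),), x, 0.05, 9)
        assert np.array_equal(generate_curve(spec).y, generate_curve(spec).y)

    def test_unknown_model_rejected(self):
        with pytest.raises(SpecificationError):
            CurveSpec("langmuir", (("K_D", 1.0),), (1.0, 2.0))

    def test_non_increasing_x_rejected(self):
        with pytest.raises(SpecificationError):
            CurveSpec("hill", (("K_D", 1.0),), (1.0, 1.0, 2.0))
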