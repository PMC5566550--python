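"""Synthetic-ensemble generator: snapshot bookkeeping, well-population
sampling, restraints, determinism and clash rejection."""

import numpy as np
import pytest

from phoslink import geometry as geom
from phoslink.builder import disaccharide_torsion_definitions
from phoslink.ensemble import (
    Ensemble,
    SamplerConfig,
    TorsionTrajectory,
    clash_mask,
    default_populations,
    default_sampler_config,
    n_snapshots,
    realize_ensemble,
    sample_ensemble,
    sample_torsions,
    _clash_pairs,
)
from phoslink.rotamers import ConformerSpec, LinkerConformer, RotamerState as R, classify_rotamer

GP, GM, T = R.GAUCHE_PLUS, R.GAUCHE_MINUS, R.TRANS


def spec_for(linkage):
    return ConformerSpec(linkage, LinkerConformer(GP, GP), 60.0)


class TestSnapshotBookkeeping:
    @pytest.mark.parametrize(
        "length,spacing,expected", [(50, 2, 25000), (1, 1, 1000), (1, 3, 333), (0.5, 2, 250)]
    )
    def test_counts(self, length, spacing, expected):
        assert n_snapshots(length, spacing) == expected

    @pytest.mark.parametrize("length,spacing", [(0, 2), (-1, 2), (50, 0), (50, -2)])
    def test_non_positive_inputs_rejected(self, length, spacing):
        with pytest.raises(ValueError):
            n_snapshots(length, spacing)


class TestSamplerConfig:
    def test_populations_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            SamplerConfig({"zeta1": (0.5, 0.2, 0.2)})

    def test_positive_frame_count_and_spread(self):
        with pytest.raises(ValueError):
            SamplerConfig({"zeta1": (1, 0, 0)}, n_frames=0)
        with pytest.raises(ValueError):
            SamplerConfig({"zeta1": (1, 0, 0)}, spread=0.0)

    def test_counterion_switches_anomeric_default(self):
        with_ion = default_populations("1->3", True)["anomeric"]
        without = default_populations("1->3", False)["anomeric"]
        assert with_ion[0] > with_ion[2]  # gauche+ dominant
        assert without[2] > without[0]    # trans dominant
        assert with_ion == tuple(reversed(without))

    def test_omega_only_for_one_six(self):
        assert "omega" not in default_populations("1->3", True)
        assert "omega" in default_populations("1->6", True)

    def test_unknown_override_label_rejected(self):
        with pytest.raises(ValueError, match="unknown torsion label"):
            default_sampler_config("1->3", seed=1, population_overrides={"omega": (1, 0, 0)})


class TestSampling:
    def test_degenerate_population_stays_in_well(self):
        cfg = SamplerConfig({"zeta1": (1.0, 0.0, 0.0)}, n_frames=500, seed=3)
        traj = sample_torsions(cfg)
        assert all(s is GP for s in traj.states("zeta1"))

    def test_population_recovery_within_binomial_error(self):
        # +/-0.02 is > 4 binomial standard errors at n = 10^4
        cfg = SamplerConfig({"zeta1": (0.7, 0.2, 0.1)}, n_frames=10_000, seed=11)
        traj = sample_torsions(cfg)
        states = traj.states("zeta1")
        fracs = [sum(s is w for s in states) / len(states) for w in (GP, GM, T)]
        assert np.allclose(fracs, (0.7, 0.2, 0.1), atol=0.02)

    def test_seeded_determinism_is_bit_identical(self):
        cfg = default_sampler_config("1->4", seed=42, n_frames=300)
        t1 = sample_torsions(cfg)
        t2 = sample_torsions(cfg)
        assert np.array_equal(t1.angles, t2.angles)

    def test_different_seeds_differ(self):
        a = sample_torsions(default_sampler_config("1->4", seed=1, n_frames=100))
        b = sample_torsions(default_sampler_config("1->4", seed=2, n_frames=100))
        assert not np.array_equal(a.angles, b.angles)

    def test_angles_normalised(self):
        traj = sample_torsions(default_sampler_config("1->6", seed=5, n_frames=2000))
        assert np.all(traj.angles > -180.0) and np.all(traj.angles <= 180.0)

    def test_hold_restraint_never_leaves_window(self):
        cfg = SamplerConfig(
            {"anomeric": (0.0, 0.0, 1.0)},  # population says trans ...
            n_frames=5000,
            seed=9,
            spread=15.0,
            restrained_torsions={"anomeric": (60.0, True)},  # ... restraint wins
        )
        traj = sample_torsions(cfg)
        assert all(s is GP for s in traj.states("anomeric"))

    def test_counterion_absent_gives_trans_dominant_anomeric(self):
        cfg = default_sampler_config("1->3", seed=8, counterion_present=False, n_frames=4000)
        traj = sample_torsions(cfg)
        states = traj.states("anomeric")
        assert sum(s is T for s in states) / len(states) > 0.5


class TestRealization:
    def test_frame_count_preserved(self):
        cfg = default_sampler_config("1->3", seed=2, n_frames=10)
        traj = sample_torsions(cfg)
        ens = realize_ensemble(spec_for("1->3"), traj)
        assert ens.n_frames == 10
        assert len(list(ens)) == 10

    def test_frame_torsions_match_trajectory(self):
        cfg = default_sampler_config("1->6", seed=21, n_frames=25)
        traj = sample_torsions(cfg)
        ens = realize_ensemble(spec_for("1->6"), traj)
        for label in traj.labels:
            got = ens.torsions(label)
            want = traj.column(label)
            assert np.max(np.abs(geom.normalize_angle(got - want))) < 1e-4, label

    def test_missing_torsion_label_is_an_error(self):
        cfg = SamplerConfig(
            {k: (1 / 3, 1 / 3, 1 / 3) for k in ("anomeric", "zeta1", "zeta2")},
            n_frames=5,
            seed=0,
        )
        traj = sample_torsions(cfg)
        with pytest.raises(KeyError, match="reducing_end"):
            realize_ensemble(spec_for("1->3"), traj)

    def test_counterion_absent_ensemble_is_trans_dominant(self):
        cfg = default_sampler_config("1->3", seed=13, counterion_present=False, n_frames=400)
        traj = sample_torsions(cfg)
        ens = realize_ensemble(spec_for("1->3"), traj)
        states = [classify_rotamer(a) for a in ens.torsions("anomeric")]
        assert sum(s is T for s in states) / len(states) > 0.5


class TestClashRejection:
    def test_mask_matches_bruteforce_on_small_ensemble(self):
        cfg = default_sampler_config("1->3", seed=4, n_frames=40)
        traj = sample_torsions(cfg)
        ens = realize_ensemble(spec_for("1->3"), traj)
        pairs, contact = _clash_pairs(ens.topology)
        mask = clash_mask(ens, fraction=0.8)
        for f in range(ens.n_frames):
            d = np.linalg.norm(
                ens.coords[f, pairs[:, 0]] - ens.coords[f, pairs[:, 1]], axis=-1
            )
            assert mask[f] == bool((d < 0.8 * contact).any())

    def test_sample_ensemble_returns_exact_frame_count_without_clashes(self):
        cfg = default_sampler_config("1->3", seed=6, n_frames=150)
        traj, ens = sample_ensemble(spec_for("1->3"), cfg)
        assert traj.n_frames == ens.n_frames == 150
        assert not clash_mask(ens).any()

    def test_sample_ensemble_deterministic(self):
        cfg = default_sampler_config("1->6", seed=14, n_frames=60)
        _, e1 = sample_ensemble(spec_for("1->6"), cfg)
        _, e2 = sample_ensemble(spec_for("1->6"), cfg)
        assert np.array_equal(e1.coords, e2.coords)


class TestTrajectoryIO:
    def test_csv_round_trip(self):
        cfg = default_sampler_config("1->4", seed=7, n_frames=12)
        traj = sample_torsions(cfg)
        back = TorsionTrajectory.from_csv(traj.to_csv())
        assert back.labels == traj.labels
        assert back.frame_spacing == traj.frame_spacing
        assert np.allclose(back.angles, traj.angles, atol=1e-6)

    def test_unknown_column_is_an_error(self):
        traj = sample_torsions(default_sampler_config("1->3", seed=1, n_frames=3))
        with pytest.raises(KeyError, match="unknown torsion label"):
            traj.column("psi")
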