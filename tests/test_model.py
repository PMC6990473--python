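"""Model schema, validation, derived quantities, fixtures."""

import math

import pytest

from latticerd import (
    InitialPlacement,
    LoggerSpec,
    ReactionSpec,
    SpeciesSpec,
    ValidationError,
    compile_model,
    load_model,
    make_fixture,
    write_model,
)
from latticerd.lattice import lattice_volume

from conftest import build_model


class TestLoadSave:
    def test_round_trip(self, tmp_path):
        cfg = make_fixture("reversible", scale=0.05)
        path = tmp_path / "model.json"
        write_model(cfg, path)
        cfg2 = load_model(path)
        assert cfg2.to_dict() == cfg.to_dict()

    def test_minimal_diffusion_model_valid(self, tmp_path):
        cfg = build_model()
        compiled = compile_model(cfg)
        assert len(compiled.walk_groups) == 1

    def test_molecule_radius_convention(self, tmp_path):
        cfg = make_fixture("mapk", scale=0.1)
        assert cfg.lattice.voxel_radius == pytest.approx(1.0209 * 2.5e-3, rel=1e-12)
        assert cfg.radius_convention == "molecule"

    def test_infeasible_rate_surfaced(self):
        cfg = build_model(
            species=[SpeciesSpec(name="B", D=1.0), SpeciesSpec(name="C", D=1.0), SpeciesSpec(name="A", D=1.0)],
            reactions=[ReactionSpec(("B", "C"), ("A",), k=100.0, rate_type="effective")],
            initial=[InitialPlacement(species="B", count=5)],
        )
        with pytest.raises(ValidationError, match="diffusion-limited"):
            compile_model(cfg)

    def test_unknown_species_and_bad_phi_itemized(self):
        cfg = build_model(
            initial=[
                InitialPlacement(species="Zz", count=5),
                InitialPlacement(species="A", phi=1.5),
            ]
        )
        with pytest.raises(ValidationError) as e:
            compile_model(cfg)
        assert len(e.value.problems) >= 2

    def test_duplicate_bimolecular_pair_rejected(self):
        sp = [SpeciesSpec(name=n, D=1.0) for n in "ABC"]
        cfg = build_model(
            species=sp,
            reactions=[
                ReactionSpec(("A", "B"), ("C",), k=0.01),
                ReactionSpec(("B", "A"), (), k=0.01),
            ],
            initial=[InitialPlacement(species="A", count=2)],
        )
        with pytest.raises(ValidationError, match="one channel per unordered"):
            compile_model(cfg)


class TestDerivedQuantities:
    def test_reversible_intrinsic_rates_echoed(self):
        compiled = compile_model(make_fixture("reversible", scale=0.05))
        by_kind = {ch.kind: ch for ch in compiled.channels}
        assert by_kind["bimolecular"].k_intrinsic == pytest.approx(9.80, abs=0.02)
        assert by_kind["unimolecular"].k_intrinsic == pytest.approx(6.61, abs=0.02)

    def test_rescaled_W_at_cap(self):
        compiled = compile_model(make_fixture("reversible", scale=0.05))
        sid = compiled.sid
        # the maximal channel is rescaled exactly to the cap P = 1
        assert compiled.bi_pair_W[sid["B"], sid["C"]] == pytest.approx(1.0, rel=1e-12)
        assert compiled.alpha[sid["B"]] == pytest.approx(1 / 11.541, abs=1e-3)

    def test_mapk_walk_schedule_matches_published_run(self):
        compiled = compile_model(make_fixture("mapk", scale=0.1, D=0.06))
        sid = compiled.sid
        assert round(float(compiled.tau_d[sid["KK"]]) * 1e6) == 72
        assert compiled.alpha[sid["KK"]] == pytest.approx(0.028, abs=5e-4)
        assert round(float(compiled.tau_e[sid["KK"]]) * 1e6) == 2


class TestFixtures:
    def test_full_scale_reversible_counts(self):
        cfg = make_fixture("reversible")
        assert cfg.lattice.dims == (960, 960, 960)
        counts = {p.species: p.count for p in cfg.initial}
        assert counts == {"B": 64000, "C": 64000}

    def test_full_scale_mm_counts(self):
        cfg = make_fixture("mm_benchmark")
        counts = {p.species: p.count for p in cfg.initial}
        assert counts == {"E": 9090, "S": 90910}
        assert lattice_volume(cfg.lattice) == pytest.approx(909.0, rel=1e-9)

    @pytest.mark.parametrize("name", ["reversible", "irreversible", "mm_benchmark", "mapk"])
    def test_scaling_preserves_concentrations(self, name):
        full = compile_model(make_fixture(name))
        desk = compile_model(make_fixture(name, scale=0.1))
        vf, vd = full.volume, desk.volume
        for sp, n_full in full.initial_counts().items():
            n_desk = desk.initial_counts()[sp]
            if n_full == 0:
                continue
            if n_full * vd / vf < 5:
                continue  # integer rounding dominates tiny counts
            assert n_desk / vd == pytest.approx(n_full / vf, rel=0.1)

    def test_crowded_fixture_phi_counts_total_occupancy(self):
        cfg = make_fixture("crowded_irreversible", phi=0.7, scale=0.5)
        compiled = compile_model(cfg)
        n_vox = cfg.lattice.n_voxels
        assert sum(compiled.initial_counts().values()) == round(0.7 * n_vox)

    def test_unknown_fixture(self):
        from latticerd import ConfigurationError

        with pytest.raises(ConfigurationError):
            make_fixture("nope")
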