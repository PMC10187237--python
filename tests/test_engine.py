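"""Stochastic engine: event tables, sampling laws, trajectory invariants."""

import numpy as np
import pytest

from mtelong import (
    FITTED_PARAMS,
    KineticParams,
    LatticeParams,
    Nucleotide,
    SimConfig,
    SolutionState,
    dissociation_rate,
    enumerate_events,
    ensemble_growth,
    gillespie_step,
    init_lattice,
    run_ensemble,
    run_trajectory,
    tip_sites,
)
from mtelong.engine import ASSOCIATION, DISSOCIATION, EXCHANGE, Event


def grown_blunt_lattice(end="plus", layers=1):
    lat = init_lattice(LatticeParams(), end, 10)
    for _ in range(layers):
        for pf in range(lat.n_pf):
            lat.add_subunit(pf, Nucleotide.CPP)
    return lat


class TestEnumerateEvents:
    def test_blunt_grown_lattice_channel_count_and_total(self):
        """Direct enumeration oracle: one association channel per
        protofilament plus one dissociation channel per dissociable tip."""
        lat = grown_blunt_lattice()
        sol = SolutionState(1.25)
        events = enumerate_events(lat, FITTED_PARAMS, sol, "plus")
        assert len(events) == 26
        assoc = [e for e in events if e.kind == ASSOCIATION]
        diss = [e for e in events if e.kind == DISSOCIATION]
        assert len(assoc) == len(diss) == 13
        assert sum(e.rate for e in assoc) == pytest.approx(13 * 0.925)
        expected_diss = sum(
            dissociation_rate(t, FITTED_PARAMS, "plus") for t in tip_sites(lat)
        )
        assert sum(e.rate for e in diss) == pytest.approx(expected_diss)

    def test_seed_only_lattice_has_association_channels_only(self):
        lat = init_lattice(LatticeParams(), "plus", 10)
        events = enumerate_events(lat, FITTED_PARAMS, SolutionState(1.0), "plus")
        assert all(e.kind == ASSOCIATION for e in events)

    def test_minus_end_has_no_exchange_channels(self):
        p = KineticParams(k_exch_gdp=0.4)
        sol = SolutionState.from_nucleotide_mix(1.25, 25.0)
        minus = enumerate_events(grown_blunt_lattice("minus"), p, sol, "minus")
        assert not any(e.kind == EXCHANGE for e in minus)
        plus = enumerate_events(grown_blunt_lattice("plus"), p, sol, "plus")
        assert sum(e.kind == EXCHANGE for e in plus) > 0


class TestGillespieStep:
    def test_waiting_times_are_exponential(self, rng):
        events = [Event(ASSOCIATION, 0, 2.5)]
        dts = np.array([gillespie_step(events, rng)[1] for _ in range(100_000)])
        se = 1 / 2.5 / np.sqrt(len(dts))
        assert abs(dts.mean() - 1 / 2.5) < 3 * se

    def test_selection_frequencies_match_rates(self, rng):
        events = [Event(ASSOCIATION, 0, 1.0), Event(DISSOCIATION, 0, 3.0)]
        n = 100_000
        picks = sum(gillespie_step(events, rng)[0].kind == DISSOCIATION for _ in range(n))
        se = np.sqrt(0.75 * 0.25 / n)
        assert abs(picks / n - 0.75) < 4 * se

    def test_zero_total_rate_is_rejected(self, rng):
        with pytest.raises(ValueError):
            gillespie_step([Event(ASSOCIATION, 0, 0.0)], rng)

    def test_identical_rng_gives_identical_choices(self):
        events = [Event(ASSOCIATION, p, 0.5 + p) for p in range(5)]
        a = [gillespie_step(events, np.random.default_rng(7)) for _ in range(1)]
        b = [gillespie_step(events, np.random.default_rng(7)) for _ in range(1)]
        assert a == b


class TestTrajectories:
    def test_zero_tubulin_flatlines_at_the_seed(self):
        cfg = SimConfig(
            params=FITTED_PARAMS, solution=SolutionState(0.0), end="plus",
            duration=30.0, n_replicates=1, rng_seed=0,
        )
        traj = run_trajectory(cfg)
        assert np.all(traj.mean_length == 0.0)
        assert (traj.final_heights == 10).all()

    @pytest.mark.parametrize("kernel", ["numba", "reference"])
    def test_conservation_of_length(self, kernel):
        cfg = SimConfig(
            params=FITTED_PARAMS, solution=SolutionState(1.25), end="plus",
            duration=40.0, n_replicates=1, rng_seed=5,
        )
        traj = run_trajectory(cfg, kernel=kernel)
        per = 8.0 / 13.0
        assert traj.mean_length[-1] == pytest.approx((traj.n_assoc - traj.n_diss) * per)

    def test_seed_never_dissociates_under_shrinking_conditions(self):
        # far below the critical concentration everything above the seed goes
        p = KineticParams(kon_plus=1.0, kon_minus=1.0, kd_long=100.0, kd_corner=50.0)
        cfg = SimConfig(
            params=p, solution=SolutionState(0.01), end="plus",
            duration=120.0, n_replicates=1, rng_seed=2,
        )
        traj = run_trajectory(cfg, kernel="reference", check_invariants=True)
        assert (traj.final_heights >= 10).all()
        assert traj.mean_length[-1] == pytest.approx(0.0, abs=8.0)

    def test_determinism_and_substream_independence(self):
        cfg = SimConfig(
            params=FITTED_PARAMS, solution=SolutionState(1.25), end="plus",
            duration=30.0, n_replicates=3, rng_seed=11,
        )
        e1 = run_ensemble(cfg)
        e2 = run_ensemble(cfg)
        for a, b in zip(e1, e2):
            assert np.array_equal(a.mean_length, b.mean_length)
        assert not np.array_equal(e1[0].mean_length, e1[1].mean_length)

    def test_minus_end_trajectories_are_mechanism_invariant(self):
        """At the minus end the terminal nucleotide is the interfacial one,
        so self- and interface-acting rules fire identical event chains."""
        outs = []
        for mech in ("self_acting", "interface_acting"):
            cfg = SimConfig(
                params=FITTED_PARAMS.with_mechanism(mech),
                solution=SolutionState.from_gdp_tubulin_fraction(1.25, 0.25),
                end="minus", duration=60.0, n_replicates=2, rng_seed=3,
            )
            outs.append(run_ensemble(cfg))
        for a, b in zip(*outs):
            assert np.array_equal(a.mean_length, b.mean_length)
            assert (a.n_assoc, a.n_diss) == (b.n_assoc, b.n_diss)

    def test_single_protofilament_matches_reversible_polymer_closed_form(self):
        """One filament far from the seed grows at kon*([tub]-KD_long):
        0.5 dimers/s * 8 nm = 4 nm/s for kon=1, [tub]=1, KD=0.5."""
        p = KineticParams(kon_plus=1.0, kon_minus=1.0, kd_long=0.5, kd_corner=0.49)
        cfg = SimConfig(
            params=p, solution=SolutionState(1.0), end="plus",
            duration=300.0, n_replicates=40, rng_seed=8,
            lattice=LatticeParams(n_protofilaments=1), seed_layers=5,
        )
        m = ensemble_growth(run_ensemble(cfg))
        assert m.mean_rate == pytest.approx(4.0, abs=3 * m.sem)

    def test_numba_and_reference_kernels_agree_statistically(self):
        cfg = SimConfig(
            params=FITTED_PARAMS, solution=SolutionState(1.25), end="plus",
            duration=120.0, n_replicates=16, rng_seed=9,
        )
        mn = ensemble_growth(run_ensemble(cfg, kernel="numba"), window=(20, None))
        mr = ensemble_growth(run_ensemble(cfg, kernel="reference"), window=(20, None))
        pooled = np.sqrt(mn.sem**2 + mr.sem**2)
        assert abs(mn.mean_rate - mr.mean_rate) < 4 * pooled

    def test_trajectory_csv(self, tmp_path):
        cfg = SimConfig(
            params=FITTED_PARAMS, solution=SolutionState(1.0), end="plus",
            duration=5.0, n_replicates=1, rng_seed=1,
        )
        traj = run_trajectory(cfg)
        path = tmp_path / "traj.csv"
        traj.to_csv(path)
        lines = path.read_text().strip().splitlines()
        assert lines[0] == "time_s,mean_length_nm"
        assert len(lines) == len(traj.times) + 1


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(duration=0.0),
            dict(n_replicates=0),
            dict(record_interval=700.0),
            dict(end="both"),
        ],
    )
    def test_invalid_configs(self, kwargs):
        base = dict(
            params=FITTED_PARAMS, solution=SolutionState(1.0), end="plus",
            duration=600.0, n_replicates=1,
        )
        base.update(kwargs)
        with pytest.raises(Exception):
            SimConfig(**base)
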