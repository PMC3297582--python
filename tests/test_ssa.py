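"""SSA engine: exactness on autonomous networks, determinism, convergence."""

import numpy as np
import pytest
from scipy import integrate, linalg, stats as sps

from upticksim.network import DRIVE_G, Reaction, ReactionNetwork
from upticksim.params import ModelParams, StrainConfig
from upticksim.promoter import global_activity
from upticksim.ssa import run_ensemble, simulate


def _generic_net(species, reactions, label="generic"):
    return ReactionNetwork(
        species=species,
        reactions=reactions,
        params=ModelParams(),
        strain=StrainConfig(label=label),
        mrna_species=[],
    )


def birth_death_net(birth=10.0, death=1.0, x0=0):
    return _generic_net(
        {"X": x0},
        [
            Reaction("birth", birth, (("X", +1),)),
            Reaction("death", death, (("X", -1),), reactants=("X",)),
        ],
        label="birth_death",
    )


class TestExactness:
    def test_immigration_death_time_average(self):
        """Stationary mean of an immigration-death process is birth/death."""
        traj = simulate(birth_death_net(10.0, 1.0), t_end=100.0, seed=5)
        x = traj.species("X")
        sel = traj.grid >= 10.0
        mean = x[sel].mean()
        # ~90 autocorrelation times (tau = 1 h) of data
        sem = np.std(x[sel]) / np.sqrt(45)
        assert mean == pytest.approx(10.0, abs=3 * max(sem, 0.3))
        assert np.all(traj.snapshots >= 0)

    def test_stationary_poisson_variance(self):
        """At stationarity the immigration-death copy number is Poisson:
        variance equals mean."""
        finals = np.array(
            [simulate(birth_death_net(10.0, 1.0), 8.0, seed=300 + i).species("X")[-1]
             for i in range(400)]
        )
        ratio = finals.var(ddof=1) / finals.mean()
        assert ratio == pytest.approx(1.0, abs=0.25)

    def test_telegraph_stationary_distribution(self):
        """Two-state telegraph + birth-death mRNA: the empirical stationary
        distribution matches the chemical-master-equation solution
        (chi-square goodness of fit)."""
        kon, koff, ktx, delta = 1.5, 1.0, 12.0, 1.5
        n_max = 40

        def net():
            return _generic_net(
                {"G_off": 1, "G_on": 0, "M": 0},
                [
                    Reaction("switch_on", kon, (("G_off", -1), ("G_on", +1)), reactants=("G_off",)),
                    Reaction("switch_off", koff, (("G_on", -1), ("G_off", +1)), reactants=("G_on",)),
                    Reaction("tx", ktx, (("M", +1),), reactants=("G_on",)),
                    Reaction("deg", delta, (("M", -1),), reactants=("M",)),
                ],
                label="telegraph",
            )

        # independent oracle: stationary solution of the truncated CME
        n_states = 2 * (n_max + 1)

        def sid(g, m):
            return g * (n_max + 1) + m

        gen = np.zeros((n_states, n_states))
        for g in (0, 1):
            for m in range(n_max + 1):
                i = sid(g, m)
                if g == 0:
                    gen[sid(1, m), i] += kon
                    gen[i, i] -= kon
                else:
                    gen[sid(0, m), i] += koff
                    gen[i, i] -= koff
                    if m < n_max:
                        gen[sid(1, m + 1), i] += ktx
                        gen[i, i] -= ktx
                if m > 0:
                    gen[sid(g, m - 1), i] += delta * m
                    gen[i, i] -= delta * m
        w, v = linalg.eig(gen)
        pi = np.real(v[:, np.argmin(np.abs(w))])
        pi = np.abs(pi) / np.abs(pi).sum()
        p_m = pi[: n_max + 1] + pi[n_max + 1 :]

        n_runs = 2500
        samples = np.empty(n_runs, dtype=int)
        for i in range(n_runs):
            traj = simulate(net(), t_end=10.0, seed=50_000 + i)
            samples[i] = traj.species("M")[-1]
        # merge tail bins so every expected count is >= 5
        counts = np.bincount(samples, minlength=n_max + 1)[: n_max + 1]
        expected = p_m * n_runs
        cut = np.searchsorted(np.cumsum(expected[::-1]), 5.0)
        k = len(expected) - cut - 1
        obs = np.append(counts[:k], counts[k:].sum())
        exp = np.append(expected[:k], expected[k:].sum())
        chi2 = ((obs - exp) ** 2 / exp).sum()
        p = sps.chi2.sf(chi2, df=len(obs) - 1)
        assert p > 0.01


class TestContracts:
    def test_absorbing_state_yields_no_events(self):
        net = _generic_net(
            {"X": 3},
            [Reaction("never", 0.0, (("X", +1),))],
            label="frozen",
        )
        traj = simulate(net, t_end=2.0, seed=1)
        assert len(traj.event_times) == 0
        assert np.all(traj.species("X") == 3)

    def test_same_seed_bit_identical(self):
        from upticksim.network import build_network
        from upticksim.params import strain_preset

        net = build_network(strain_preset("wt"), ModelParams())
        a = simulate(net, 3.0, seed=99)
        b = simulate(net, 3.0, seed=99)
        assert np.array_equal(a.event_times, b.event_times)
        assert np.array_equal(a.event_ids, b.event_ids)
        assert np.array_equal(a.snapshots, b.snapshots)
        c = simulate(net, 3.0, seed=100)
        assert not np.array_equal(a.event_times, c.event_times)

    def test_invalid_arguments(self):
        net = birth_death_net()
        with pytest.raises(ValueError):
            simulate(net, t_end=0.0, seed=1)
        with pytest.raises(ValueError):
            run_ensemble(net, 0, 1.0, 1)

    def test_ensemble_of_one_matches_simulate(self):
        from upticksim.network import build_network
        from upticksim.params import strain_preset

        net = build_network(strain_preset("wt"), ModelParams())
        ens = run_ensemble(net, 1, 3.0, base_seed=7)
        traj = simulate(net, 3.0, seed=7)
        assert np.array_equal(ens.mrna_counts[0, 0], traj.species("p1.mRNA"))
        assert np.array_equal(ens.tx_times[0][0], traj.tx_event_times[0])

    def test_tx_events_subset_of_events(self, small_ensembles):
        from upticksim.network import build_network
        from upticksim.params import strain_preset

        net = build_network(strain_preset("wt"), ModelParams())
        traj = simulate(net, 4.0, seed=123)
        assert np.all(np.diff(traj.event_times) >= 0)
        assert set(traj.tx_event_times[0]) <= set(traj.event_times)

    def test_csv_export_headers(self, tmp_path, small_ensembles):
        import pandas as pd

        traj = simulate(birth_death_net(5.0, 1.0), 2.0, seed=3)
        p = tmp_path / "traj.csv"
        traj.to_csv(p)
        assert p.read_text().startswith("# trajectory seed=3\n")
        back = pd.read_csv(p, comment="#")
        assert np.array_equal(back["X"].to_numpy(), traj.species("X"))

        q = tmp_path / "ens.csv"
        small_ensembles["wt"].to_csv(q)
        header = q.read_text().splitlines()[0]
        assert "strain=wt" in header and "n_runs=300" in header

    def test_no_negative_counts_in_ensembles(self, small_ensembles):
        for ens in small_ensembles.values():
            assert np.all(ens.mrna_counts >= 0)


class TestTimeDependence:
    def test_dt_max_convergence(self):
        """Ensemble-mean transcription counts under the drive agree with
        the exact integral of g(t), and halving dt_max moves them < 1%."""
        k = 8.0
        exact = k * integrate.quad(
            lambda t: float(global_activity(t, ModelParams())), 0, 6, limit=200
        )[0]

        def drive_net():
            return _generic_net(
                {"M": 0},
                [Reaction("tx", k, (("M", +1),), drive=DRIVE_G)],
                label="drive_only",
            )

        means = {}
        for dt in (0.01, 0.005):
            total = 0
            n = 8000
            for i in range(n):
                traj = simulate(drive_net(), 6.0, seed=10_000 + i, dt_max=dt)
                total += traj.species("M")[-1]
            means[dt] = total / n
        sem = np.sqrt(exact / 8000)
        for dt, m in means.items():
            assert m == pytest.approx(exact, abs=4 * sem)
        assert abs(means[0.01] - means[0.005]) / exact < 0.01
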