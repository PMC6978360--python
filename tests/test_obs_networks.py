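"""Dynamic network counting, bias partitions and sociogram rates."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oadiff import event_io, obs_networks
from oadiff.errors import DataValidationError
from oadiff.event_io import Individual

from conftest import make_event, make_roster


class TestCounting:
    def test_cumulative_strictly_before(self):
        roster = make_roster(3)
        events = [
            make_event(0, 10.0, "G2", "lift", observers=["G1"]),
            make_event(1, 20.0, "G2", "lift", observers=["G1"]),
        ]
        net = obs_networks.build_dynamic_network(events, roster)["G"]
        # experiment clock starts at the first event (t=10 -> 0)
        assert net.count("G1", "G2", "lift", 15.0) == 2
        assert net.count("G1", "G2", "lift", 5.0) == 1
        assert net.count("G1", "G2", "lift", 0.0) == 0
        assert net.count("G1", "G2", "pull", 15.0) == 0

    def test_monotone_in_time(self):
        roster = make_roster(3)
        events = [
            make_event(i, 10.0 * i, "G2", "lift", observers=["G1", "G3"]) for i in range(5)
        ]
        net = obs_networks.build_dynamic_network(events, roster)["G"]
        counts = [net.count("G1", "G2", "lift", t) for t in np.linspace(0, 50, 11)]
        assert counts == sorted(counts)

    def test_attempts_do_not_count_by_default(self):
        roster = make_roster(2)
        events = [
            make_event(0, 1.0, "G2", "lift", outcome="attempt", observers=["G1"]),
            make_event(1, 2.0, "G2", "lift", observers=["G1"]),
        ]
        net = obs_networks.build_dynamic_network(events, roster)["G"]
        assert net.count("G1", "G2", "lift", 100.0) == 1
        counting = obs_networks.build_dynamic_network(events, roster, count_attempts=True)["G"]
        assert counting.count("G1", "G2", "lift", 100.0) == 2

    def test_no_self_observation(self):
        net = obs_networks.DynamicObservationNetwork("G")
        with pytest.raises(DataValidationError):
            net.add("G1", "G1", "lift", 1.0)

    def test_shuffled_file_gives_same_network(self, small_experiment):
        events = list(small_experiment.events)
        rng = np.random.default_rng(0)
        shuffled = [events[i] for i in rng.permutation(len(events))]
        a = obs_networks.build_dynamic_network(events, small_experiment.roster)
        b = obs_networks.build_dynamic_network(shuffled, small_experiment.roster)
        for g in a:
            assert a[g].times == b[g].times

    def test_matches_simulator_ledger_cell_for_cell(self, small_experiment):
        nets = obs_networks.build_dynamic_network(small_experiment.events, small_experiment.roster)
        for g, net in nets.items():
            counts = {k: len(v) for k, v in net.times.items()}
            assert counts == small_experiment.ledger[g]


class TestPartition:
    def test_rank_direction(self):
        roster = make_roster(4)
        events = [make_event(0, 1.0, "G2", "lift", observers=["G4"])]  # dem rank 2 -> obs rank 4
        net = obs_networks.build_dynamic_network(events, roster)["G"]
        part = obs_networks.partition_network(net, roster, "rank")
        assert part.components["HL"].count("G4", "G2", "lift", 10.0) == 1
        assert part.components["LH"].total() == 0

    def test_kin_components(self):
        roster = [
            Individual("mum", "G", "female", "adult", 1),
            Individual("kid1", "G", "male", "juvenile", 2, "mum"),
            Individual("kid2", "G", "female", "juvenile", 3, "mum"),
            Individual("other", "G", "male", "adult", 4),
        ]
        events = [
            make_event(0, 1.0, "mum", "lift", observers=["kid1", "other"]),
            make_event(1, 2.0, "kid1", "pull", observers=["mum", "kid2"]),
        ]
        net = obs_networks.build_dynamic_network(events, roster)["G"]
        part = obs_networks.partition_network(net, roster, "kin")
        assert part.components["mother_to_offspring"].count("kid1", "mum", "lift", 10) == 1
        assert part.components["offspring_to_mother"].count("mum", "kid1", "pull", 10) == 1
        assert part.components["siblings"].count("kid2", "kid1", "pull", 10) == 1
        assert part.components["nonkin"].count("other", "mum", "lift", 10) == 1
        # nothing from the mother-offspring dyad leaks into nonkin
        assert part.components["nonkin"].count("kid1", "mum", "lift", 10) == 0

    @pytest.mark.parametrize("bias", ["rank", "sex", "age", "kin"])
    def test_partition_exhaustive_on_simulation(self, bias, small_experiment):
        nets = obs_networks.build_dynamic_network(small_experiment.events, small_experiment.roster)
        rng = np.random.default_rng(1)
        for g, net in nets.items():
            part = obs_networks.partition_network(net, small_experiment.roster, bias)
            assert sum(c.total() for c in part.components.values()) == net.total()
            keys = list(net.times)
            for _ in range(50):
                i, j, l = keys[rng.integers(len(keys))]
                t = float(rng.uniform(0, 1.2 * max(net.times[(i, j, l)])))
                total = sum(
                    c.count(i, j, l, t) for c in part.components.values()
                )
                assert total == net.count(i, j, l, t)

    @given(st.integers(min_value=2, max_value=6), st.integers(min_value=0, max_value=30),
           st.randoms(use_true_random=False))
    @settings(max_examples=25, deadline=None)
    def test_partition_exhaustive_property(self, n, n_obs, rnd):
        roster = make_roster(n)
        if n >= 3:
            roster[1] = Individual(roster[1].id, "G", roster[1].sex, roster[1].age_class,
                                   roster[1].rank, roster[0].id)
        net = obs_networks.DynamicObservationNetwork("G")
        ids = [r.id for r in roster]
        for _ in range(n_obs):
            i, j = rnd.sample(ids, 2)
            net.add(i, j, rnd.choice(["lift", "pull"]), rnd.uniform(0, 100))
        for ts in net.times.values():
            ts.sort()
        for bias in ("rank", "sex", "age", "kin"):
            part = obs_networks.partition_network(net, roster, bias)
            assert sum(c.total() for c in part.components.values()) == net.total()


class TestSociogram:
    def test_simple_rate_arithmetic(self):
        roster = make_roster(2)
        # B (=G2) solves lift at clock 0, 100, 200; A observes all three;
        # A never learns -> denominator = end - first lift success = 600
        events = [
            make_event(0, 0.0, "G2", "lift", observers=["G1"]),
            make_event(1, 100.0, "G2", "lift", observers=["G1"]),
            make_event(2, 200.0, "G2", "lift", observers=["G1"]),
            make_event(3, 600.0, "G2", "pull", observers=[]),
        ]
        ds = event_io.build_diffusion_dataset(events, roster)["G"]
        net = obs_networks.build_dynamic_network(events, roster)["G"]
        edges = obs_networks.sociogram_rates(ds, net)
        row = edges[(edges.observer == "G1") & (edges.demonstrator == "G2")]
        # lift window 600 s + pull window 0 s; 3 naive lift observations
        assert row.rate_per_s.item() == pytest.approx(3 / 600.0)

    def test_no_observation_no_edge(self):
        roster = make_roster(3)
        events = [make_event(0, 0.0, "G2", "lift"), make_event(1, 50.0, "G2", "lift")]
        ds = event_io.build_diffusion_dataset(events, roster)["G"]
        net = obs_networks.build_dynamic_network(events, roster)["G"]
        edges = obs_networks.sociogram_rates(ds, net)
        assert edges.empty

    def test_replay_oracle_on_simulation(self, small_experiment):
        """Rates equal an independent per-event replay with explicit windows."""
        roster = small_experiment.roster
        ds = event_io.build_diffusion_dataset(small_experiment.events, roster)
        nets = obs_networks.build_dynamic_network(small_experiment.events, roster)
        timed, _ = event_io.experiment_clock(event_io.sort_events(small_experiment.events))
        for g, d in ds.items():
            acq = {(a.individual_id, a.option): a.time_s for a in d.acquisitions}
            first = d.first_option_success_time
            num: dict[tuple[str, str], int] = {}
            for ev, t in timed:
                if ev.group != g or ev.outcome != "success" or ev.technique not in ("lift", "pull"):
                    continue
                for o in ev.observer_ids:
                    if t < acq.get((o, ev.technique), d.end_time):
                        num[(o, ev.actor_id)] = num.get((o, ev.actor_id), 0) + 1
            edges = obs_networks.sociogram_rates(d, nets[g])
            assert len(edges) == len(num)
            for (o, dem), count in num.items():
                denom = sum(
                    max(0.0, acq.get((o, l), d.end_time) - first[l])
                    for l in ("lift", "pull")
                    if l in first
                )
                row = edges[(edges.observer == o) & (edges.demonstrator == dem)]
                assert row.rate_per_s.item() == pytest.approx(count / denom, rel=1e-12)
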