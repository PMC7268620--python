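import itertools
from datetime import date

import numpy as np
import pytest

from nestfate import (
    CandidateSite,
    FilterSpec,
    LabeledSite,
    RevisitationMetrics,
    apply_rules,
    buffer_sensitivity,
    evaluate_performance,
    filter_candidates,
    fit_cart,
    label_sites,
    resolve_overlaps,
    simulate_labeled_metrics,
)

import oracles


def site(consec=5, days_vis=50.0, top=50.0, n=10, first=1, last=10, lon=12.0, lat=44.0, tid="t"):
    m = RevisitationMetrics(
        consec_days=consec,
        perc_days_vis=days_vis,
        perc_top_vis=top,
        n_fixes_in=n,
        first_day=date(2021, 4, first),
        last_day=date(2021, 4, last),
    )
    return CandidateSite(
        track_id=tid, center_index=first, center_lon=lon, center_lat=lat,
        metrics=m, member_fix_indices=np.arange(n),
    )


class TestFilterCandidates:
    def test_threshold_combinations_enumerated(self):
        # candidates straddling each threshold of the stork-style rule
        spec = FilterSpec(min_consec_days=14, min_top_vis_pct=79.0)
        cands = [
            site(consec=c, top=t)
            for c, t in itertools.product([13, 14, 15], [78.0, 79.0, 80.0])
        ]
        survivors = filter_candidates(cands, spec)
        expected = sum(1 for c, t in itertools.product([13, 14, 15], [78.0, 79.0, 80.0]) if c >= 14 and t >= 79.0)
        assert len(survivors) == expected == 4

    def test_empty_input(self):
        assert filter_candidates([], FilterSpec(1, 1, 1)) == []

    def test_monotone_in_thresholds(self, rng):
        cands = [
            site(consec=int(rng.integers(1, 30)), days_vis=float(rng.uniform(0, 100)), top=float(rng.uniform(0, 100)))
            for _ in range(50)
        ]
        base = FilterSpec(5, 20.0, 30.0)
        loose = len(filter_candidates(cands, base))
        for tighter in [FilterSpec(6, 20, 30), FilterSpec(5, 25, 30), FilterSpec(5, 20, 35)]:
            assert len(filter_candidates(cands, tighter)) <= loose

    def test_zero_spec_is_passthrough(self, rng):
        cands = [site(consec=int(rng.integers(1, 30))) for _ in range(10)]
        assert len(filter_candidates(cands, FilterSpec())) == 10

    def test_rules_disjunction(self):
        cands = [site(consec=20, top=10.0), site(consec=2, top=90.0), site(consec=2, top=10.0)]
        rules = [FilterSpec(min_consec_days=15), FilterSpec(min_top_vis_pct=80.0)]
        assert len(apply_rules(cands, rules)) == 2


class TestResolveOverlaps:
    def test_most_visited_wins(self):
        a = site(n=50, first=1, last=10)
        b = site(n=30, first=5, last=15)
        out = resolve_overlaps([a, b])
        assert len(out) == 1 and out[0].n_fixes_in == 50

    def test_disjoint_attempts_both_kept(self):
        a = site(n=50, first=1, last=10)
        b = site(n=30, first=12, last=20)
        assert len(resolve_overlaps([a, b])) == 2

    def test_output_pairwise_disjoint(self, rng):
        cands = []
        for i in range(15):
            f = int(rng.integers(1, 20))
            cands.append(site(n=int(rng.integers(1, 100)), first=f, last=min(28, f + int(rng.integers(0, 9)))))
        out = resolve_overlaps(cands)
        for a, b in itertools.combinations(out, 2):
            assert a.last_day < b.first_day or b.last_day < a.first_day

    def test_matches_greedy_oracle(self, rng):
        for trial in range(20):
            cands = []
            for i in range(10):
                f = int(rng.integers(1, 20))
                cands.append(
                    site(n=int(rng.integers(1, 100)), first=f, last=min(28, f + int(rng.integers(0, 9))), lon=12.0 + i)
                )
            got = {c.center_lon for c in resolve_overlaps(cands)}
            expect = oracles.best_disjoint_first(
                [(c.n_fixes_in, c.first_day, c.last_day, c.center_lon) for c in cands]
            )
            assert got == expect


class TestLabelSites:
    def test_matched_candidate_is_nest(self):
        c = site(lon=12.0, lat=44.0)
        out = label_sites([c], [(12.0 + 5 / 111_000.0 / np.cos(np.radians(44)), 44.0)], match_radius=40.0)
        assert out[0].label == "nest"

    def test_distant_overlapping_candidate_is_non_nest(self):
        nest = site(lon=12.0, first=1, last=20, n=100)
        far = site(lon=12.05, first=5, last=15, n=20)  # ~4 km away, overlapping span
        out = label_sites([nest, far], [(12.0, 44.0)], match_radius=40.0)
        labels = {s.site.center_lon: s.label for s in out}
        assert labels[12.0] == "nest" and labels[12.05] == "non-nest"

    def test_non_overlapping_distant_candidate_dropped(self):
        nest = site(lon=12.0, first=1, last=10, n=100)
        later = site(lon=12.05, first=15, last=25, n=20)
        out = label_sites([nest, later], [(12.0, 44.0)], match_radius=40.0)
        assert len(out) == 1

    def test_no_match_warns_and_empty(self):
        c = site(lon=12.0)
        with pytest.warns(UserWarning, match="no candidate matched"):
            assert label_sites([c], [(13.0, 45.0)], match_radius=40.0) == []

    def test_planted_confounders(self):
        nest = site(lon=12.0, first=1, last=30, n=200)
        confs = [site(lon=12.0 + 0.02 * (i + 1), first=2, last=28, n=20) for i in range(3)]
        out = label_sites([nest] + confs, [(12.0, 44.0)], 40.0)
        assert sum(1 for s in out if s.label == "nest") == 1
        assert sum(1 for s in out if s.label == "non-nest") == 3


def labeled_from_frame(df):
    return [
        LabeledSite(
            RevisitationMetrics(
                consec_days=int(r.consec_days),
                perc_days_vis=float(r.perc_days_vis),
                perc_top_vis=float(r.perc_top_vis),
                n_fixes_in=10,
                first_day=date(2021, 4, 1),
                last_day=date(2021, 4, 30),
            ),
            r.label,
        )
        for r in df.itertuples()
    ]


class TestFitCart:
    def test_separable_single_split(self, rng):
        rows = []
        for _ in range(30):
            rows.append({"consec_days": int(rng.integers(15, 41)), "perc_days_vis": 50.0, "perc_top_vis": 50.0, "label": "nest"})
            rows.append({"consec_days": int(rng.integers(1, 11)), "perc_days_vis": 50.0, "perc_top_vis": 50.0, "label": "non-nest"})
        import pandas as pd

        res = fit_cart(labeled_from_frame(pd.DataFrame(rows)), seed=0)
        assert len(res.rules) == 1
        assert 10 < res.rules[0].min_consec_days < 15
        X = np.array([[r["consec_days"], 50.0, 50.0] for r in rows])
        y = np.array([1 if r["label"] == "nest" else 0 for r in rows])
        assert (res.tree.predict(X) == y).all()

    def test_two_rule_recovery(self):
        df = simulate_labeled_metrics(400, rule={"consec_days": 12, "perc_top_vis": 60.0}, label_noise=0.05, seed=1)
        res = fit_cart(labeled_from_frame(df), seed=1)
        lo_c = min(r.min_consec_days for r in res.rules if r.min_consec_days > 0)
        lo_t = min(r.min_top_vis_pct for r in res.rules if r.min_top_vis_pct > 0)
        assert abs(lo_c - 12) <= 2
        assert abs(lo_t - 60) <= 2

    def test_pruned_not_larger_than_unpruned(self):
        df = simulate_labeled_metrics(300, label_noise=0.1, seed=2)
        data = labeled_from_frame(df)
        pruned = fit_cart(data, seed=2, prune=True)
        unpruned = fit_cart(data, seed=2, prune=False)
        assert pruned.tree.tree_.node_count <= unpruned.tree.tree_.node_count

    def test_single_class_errors(self):
        df = simulate_labeled_metrics(50, seed=3)
        df["label"] = "nest"
        with pytest.raises(ValueError, match="both classes"):
            fit_cart(labeled_from_frame(df))

    def test_too_few_sites_errors(self):
        df = simulate_labeled_metrics(8, seed=3)
        with pytest.raises(ValueError, match="at least 10"):
            fit_cart(labeled_from_frame(df))

    def test_missing_consec_split_requires_floor(self):
        # nests differ only in top-day attendance: no consec_days split exists
        df = simulate_labeled_metrics(300, rule={"perc_top_vis": 50.0}, label_noise=0.0, seed=4)
        data = labeled_from_frame(df)
        with pytest.raises(ValueError, match="min_consec_floor"):
            fit_cart(data, seed=4)
        res = fit_cart(data, seed=4, min_consec_floor=8)
        assert all(r.min_consec_days == 8 for r in res.rules)

    def test_node_counts_reported(self):
        df = simulate_labeled_metrics(200, seed=5)
        res = fit_cart(labeled_from_frame(df), seed=5)
        root = res.node_counts.iloc[0]
        assert root.n_nest + root.n_non_nest == 200


class TestEvaluatePerformance:
    def test_perfect_detection(self):
        found = [site(lon=12.0), site(lon=13.0)]
        rep = evaluate_performance(found, [(12.0, 44.0), (13.0, 44.0)], {"nb1": [], "nb2": []}, 40.0)
        assert (rep.ppv, rep.sensitivity, rep.fnr, rep.fpr) == (100.0, 100.0, 0.0, 0.0)

    def test_partial_counts(self):
        known = [(float(i), 44.0) for i in range(10)]
        found = [site(lon=float(i)) for i in range(8)] + [site(lon=50.0)]
        rep = evaluate_performance(found, known, None, 40.0)
        assert rep.ppv == pytest.approx(100 * 8 / 9)
        assert rep.sensitivity == pytest.approx(80.0)
        assert rep.fnr == pytest.approx(20.0)

    def test_nonbreeder_false_positive_rate(self):
        nb = {f"nb{i}": ([site()] if i < 8 else []) for i in range(16)}
        rep = evaluate_performance([], [], nb, 40.0)
        assert rep.fpr == pytest.approx(50.0)

    def test_zero_denominators_are_nan(self):
        rep = evaluate_performance([], [], None, 40.0)
        assert np.isnan(rep.ppv) and np.isnan(rep.sensitivity) and np.isnan(rep.fpr)

    def test_sensitivity_plus_fnr_is_100(self, rng):
        known = [(float(i), 44.0) for i in range(7)]
        found = [site(lon=float(i)) for i in rng.choice(7, size=4, replace=False)]
        rep = evaluate_performance(found, known, None, 40.0)
        assert rep.sensitivity + rep.fnr == 100.0


class TestBufferSensitivity:
    def test_single_radius_errors(self):
        with pytest.raises(ValueError, match="at least 2"):
            buffer_sensitivity([], {}, [40.0], spec=FilterSpec())

    def test_gps_scatter_favors_larger_buffer(self):
        from nestfate import SimScenario, simulate_track

        tracks, known = [], {}
        for i in range(3):
            sc = SimScenario(track_id=f"b{i}", t_full=30, seed=100 + i, gps_noise_sd_m=25.0, nest_lon=12.0 + i)
            tr, truth = simulate_track(sc)
            tracks.append(tr)
            known[tr.id] = (truth["nest_lon"], truth["nest_lat"])
        spec = FilterSpec(min_consec_days=10, min_top_vis_pct=50.0)
        table, best = buffer_sensitivity(tracks, known, [10.0, 30.0], spec=spec)
        assert table.loc[30.0, "sensitivity"] >= table.loc[10.0, "sensitivity"]
        assert best in (10.0, 30.0)
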