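"""Scoring of predictions: confusion, quality measures, recovery, summaries."""

import numpy as np
import pytest

from motifbench import (
    GroundTruthSite,
    PredictedSite,
    PredictionRun,
    WeightMatrix,
    build_wm_from_sites,
    f_difference,
    f_value,
    generate_wm,
    match_sites,
    quality_measures,
    read_predictions,
    recovery,
    simulate_coregulation_space,
    summarize_test,
    write_predictions,
)
from motifbench.evaluate import correct_model


def P(start, end, species="REF", gene="g0", seq=""):
    return PredictedSite(species=species, gene=gene, start=start, end=end, sequence=seq)


def T(start, end, species="REF", gene="g0"):
    return GroundTruthSite(species=species, gene=gene, start=start, end=end)


# -- independent oracle: re-derive TP/FP/FN directly from the half-length
#    rule (best-overlap partner, ties to leftmost truth start)
def brute_force_confusion(predicted, truth):
    tp, fp = set(), set()
    for p in predicted:
        cands = [t for t in truth if (t.species, t.gene) == (p.species, p.gene)]
        best = None
        for t in sorted(cands, key=lambda t: t.start):
            ov = min(p.end, t.end) - max(p.start, t.start)
            if best is None or ov > best[0]:
                best = (ov, t)
        if best is not None and best[0] >= (best[1].end - best[1].start) / 2:
            tp.add(p)
        else:
            fp.add(p)
    fn = {
        t for t in truth
        if not any(
            (p.species, p.gene) == (t.species, t.gene)
            and min(p.end, t.end) - max(p.start, t.start) >= (t.end - t.start) / 2
            for p in predicted
        )
    }
    return tp, fp, fn


class TestMatchSites:
    def test_exact_match_is_tp(self):
        tp, fp, fn = match_sites([P(100, 113)], [T(100, 113)])
        assert len(tp) == 1 and not fp and not fn

    def test_half_length_boundary(self):
        # width-13 truth: overlap 7 >= 6.5 passes, overlap 6 fails
        tp, fp, fn = match_sites([P(106, 119)], [T(100, 113)])
        assert len(tp) == 1 and not fn
        tp, fp, fn = match_sites([P(107, 120)], [T(100, 113)])
        assert not tp and len(fp) == 1 and len(fn) == 1

    def test_empty_predictions_leave_all_truths_fn(self):
        truths = [T(10, 23), T(50, 63, gene="g1")]
        tp, fp, fn = match_sites([], truths)
        assert not tp and not fp and fn == set(truths)

    def test_matching_is_confined_to_same_sequence(self):
        tp, fp, fn = match_sites([P(100, 113, gene="g1")], [T(100, 113, gene="g2")])
        assert not tp and len(fp) == 1 and len(fn) == 1

    def test_agrees_with_brute_force_on_random_instances(self, rng):
        for _ in range(1000):
            genes = [f"g{i}" for i in range(3)]
            preds = [
                P(int(s), int(s) + int(rng.integers(5, 20)),
                  gene=str(rng.choice(genes)))
                for s in rng.integers(0, 80, size=rng.integers(0, 7))
            ]
            truths_raw = [
                (str(rng.choice(genes)), int(s), int(s) + 13)
                for s in rng.integers(0, 80, size=rng.integers(0, 7))
            ]
            # unique (species, gene, start) so set semantics are unambiguous
            truths = [T(s, e, gene=g) for g, s, e in dict.fromkeys(truths_raw)]
            preds = list(dict.fromkeys(preds))
            expected = brute_force_confusion(preds, truths)
            assert match_sites(preds, truths) == expected


class TestQualityMeasures:
    def test_direct_formulas(self):
        tp = {P(0, 13), P(20, 33, gene="g1"), P(40, 53, gene="g2")}
        fp = {P(60, 73, gene="g3")}
        q = quality_measures(tp, fp, set())
        assert q.ppv == pytest.approx(75.0)
        assert q.sens == pytest.approx(100.0)

    def test_species_filter_semantics(self):
        # every prediction sits in an ortholog; reference truths exist
        tp = {P(0, 13, species="S1")}
        fn = {T(0, 13, species="REF")}
        q = quality_measures(tp, set(), fn)
        assert q.sp_ppv is None  # no reference predictions at all
        assert q.sp_sens == 0.0

    def test_undefined_when_no_predictions_and_no_truths(self):
        q = quality_measures(set(), set(), set())
        assert q.ppv is None and q.sens is None

    def test_adding_fp_lowers_ppv_not_sens(self):
        tp, fn = {P(0, 13)}, {T(50, 63)}
        q1 = quality_measures(tp, set(), fn)
        q2 = quality_measures(tp, {P(80, 93)}, fn)
        assert q2.ppv < q1.ppv and q2.sens == q1.sens

    def test_matches_brute_force_counts_on_small_instances(self, rng):
        for _ in range(200):
            preds = list({
                P(int(s), int(s) + 13, species=str(rng.choice(["REF", "S1"])))
                for s in rng.integers(0, 60, size=rng.integers(0, 5))
            })
            truths = list({
                T(int(s), int(s) + 13, species=str(rng.choice(["REF", "S1"])))
                for s in rng.integers(0, 60, size=rng.integers(0, 5))
            })
            tp, fp, fn = match_sites(preds, truths)
            q = quality_measures(tp, fp, fn)
            if tp or fp:
                assert q.ppv == pytest.approx(100 * len(tp) / (len(tp) + len(fp)))
            else:
                assert q.ppv is None
            if tp or fn:
                assert q.sens == pytest.approx(100 * len(tp) / (len(tp) + len(fn)))


class TestRecovery:
    @pytest.fixture
    def setting(self, rng):
        wm = generate_wm(13, 22.0, seed=5, label="true")
        ds = simulate_coregulation_space(10, wm, rng=rng, dataset_id="rec")
        return ds, correct_model(ds)

    def _run(self, ds, sites, model=None):
        return PredictionRun("rec", "f", has_output=True, sites=sites, model=model)

    def test_predicted_model_equal_to_correct_matches(self, setting):
        ds, cm = setting
        run = self._run(ds, [], model=cm)
        assert recovery(run, cm, ds) == 1

    def test_rescue_rule_decisions(self, setting):
        ds, cm = setting
        far = WeightMatrix(np.tile([1.0, 0, 0, 0], (13, 1)))  # no-match model

        def safe_start(gene):
            # a window at least 13 bp clear of the gene's truth site
            t = next(s for s in ds.sites if s.gene == gene)
            return 0 if t.start > 30 else 100

        def run_with_quality(n_tp, n_fp):
            # n_tp exact hits on real truths plus n_fp non-overlapping sites
            sites = [P(t.start, t.end, gene=t.gene) for t in ds.sites[:n_tp]]
            sites += [P(safe_start(g), safe_start(g) + 13, gene=g)
                      for g in (f"g{i}" for i in range(n_fp))]
            return PredictionRun("rec", "f", True, sites, model=far)

        # spPPV = spSens = 60% -> rescued by the both-above-50 rule
        r60 = run_with_quality(6, 4)
        q = quality_measures(*match_sites(r60.sites, ds.sites))
        assert q.sp_ppv == pytest.approx(60.0) and q.sp_sens == pytest.approx(60.0)
        assert recovery(r60, cm, ds) == 1
        # spPPV 100%, spSens 20% -> rescued by the single-measure >80 rule
        r_hi = run_with_quality(2, 0)
        q = quality_measures(*match_sites(r_hi.sites, ds.sites))
        assert q.sp_ppv > 80.0 and q.sp_sens < 50.0
        assert recovery(r_hi, cm, ds) == 1
        # spPPV = spSens = 40% -> no rescue
        r40 = run_with_quality(4, 6)
        assert recovery(r40, cm, ds) == 0

    def test_run_without_output_is_an_error(self, setting):
        ds, cm = setting
        with pytest.raises(ValueError):
            recovery(PredictionRun("rec", "f", False), cm, ds)


class TestFValue:
    def test_closed_forms(self):
        assert f_value(100, 100) == pytest.approx(100.0)
        assert f_value(73.2, 0) == 0.0
        assert f_value(50, 100) == pytest.approx(200 / 3)

    def test_bounded_by_min_and_max(self, rng):
        for _ in range(100):
            a, b = rng.uniform(0, 100, 2)
            f = f_value(a, b)
            assert min(a, b) - 1e-9 <= f <= max(a, b) + 1e-9
        assert f_value(37.0, 37.0) == pytest.approx(37.0)


def perfect_run(ds):
    sites = [
        PredictedSite(species=t.species, gene=t.gene, start=t.start, end=t.end,
                      sequence=ds.record(t.species, t.gene).sequence[t.start:t.end])
        for t in ds.sites
    ]
    return PredictionRun(ds.dataset_id, "perfect", True, sites)


class TestSummarize:
    def _perfect_run(self, ds):
        return perfect_run(ds)

    def test_perfect_predictor_is_fully_correct(self, rng):
        wm = generate_wm(13, 22.0, seed=6)
        runs, datasets = [], {}
        for i in range(5):
            ds = simulate_coregulation_space(10, wm, rng=rng, dataset_id=f"d{i}")
            datasets[ds.dataset_id] = ds
            runs.append(self._perfect_run(ds))
        s = summarize_test(runs, datasets)
        assert s.d1_or_r1 == 5 and s.rr == 100.0
        assert s.ppv == s.sens == s.sp_ppv == s.sp_sens == 100.0
        assert s.f_value == pytest.approx(100.0)

    def test_no_output_runs_lower_d1_and_rr_undefined_at_zero(self, rng):
        wm = generate_wm(13, 22.0, seed=6)
        ds = simulate_coregulation_space(10, wm, rng=rng, dataset_id="d0")
        runs = [PredictionRun("d0", "f", False) for _ in range(3)]
        s = summarize_test(runs, ds)
        assert s.d1_or_r1 == 0 and s.rr is None and s.f_value is None

    def test_means_are_taken_over_correct_outputs_only(self, rng):
        wm = generate_wm(13, 22.0, seed=8)
        runs, datasets = [], {}
        for i in range(6):
            ds = simulate_coregulation_space(10, wm, rng=rng, dataset_id=f"d{i}")
            datasets[ds.dataset_id] = ds
            if i < 4:
                runs.append(self._perfect_run(ds))
            else:  # junk predictions: output, but not correct
                junk = [PredictedSite(species="REF", gene=f"g{j}", start=450, end=463,
                                      sequence="A" * 13) for j in range(10)]
                runs.append(PredictionRun(ds.dataset_id, "perfect", True, junk))
        s = summarize_test(runs, datasets)
        assert s.d1_or_r1 == 6
        assert s.rr == pytest.approx(100 * 4 / 6)
        assert s.ppv == 100.0  # junk runs excluded from the mean
        assert s.f_value == pytest.approx(100.0)

    def test_d1_counts_all_outputs(self, rng):
        wm = generate_wm(13, 22.0, seed=6)
        ds = simulate_coregulation_space(10, wm, rng=rng, dataset_id="d0")
        runs = [self._perfect_run(ds) for _ in range(4)]
        runs += [PredictionRun("d0", "perfect", False)]
        s = summarize_test(runs, ds, mode="per-run")
        assert s.n_runs == 5 and s.d1_or_r1 == 4 and s.rr == 100.0

    def test_empty_run_list_rejected(self):
        with pytest.raises(ValueError):
            summarize_test([], {})


class TestPredictionsTsv:
    def test_round_trip_preserves_runs(self, tmp_path, rng):
        wm = generate_wm(13, 22.0, seed=6)
        ds = simulate_coregulation_space(10, wm, rng=rng, dataset_id="d0")
        sites = [PredictedSite(species=t.species, gene=t.gene, start=t.start,
                               end=t.end, sequence="A" * 13, score=1.5)
                 for t in ds.sites[:3]]
        runs = [
            PredictionRun("d0", "gibbs", True, sites),
            PredictionRun("d1", "gibbs", False),
        ]
        path = tmp_path / "pred.tsv"
        write_predictions(runs, path)
        back = read_predictions(path)
        assert len(back) == 2
        by_id = {r.dataset_id: r for r in back}
        assert by_id["d0"].sites == sites
        assert by_id["d1"].has_output is False and not by_id["d1"].sites

    def test_f_difference_of_summaries(self, rng):
        wm = generate_wm(13, 22.0, seed=6)
        ds = simulate_coregulation_space(10, wm, rng=rng, dataset_id="d0")
        perfect = summarize_test([perfect_run(ds)], ds)
        assert f_difference(perfect, perfect) == 0.0
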