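"""Score cut-off sweeps, optimum selection and template ranking."""

import numpy as np
import pytest

from chorusmatch.calibration import (
    CalibrationResult,
    RocCurve,
    RocPoint,
    rank_templates,
    select_optimal_cutoff,
    sweep_cutoffs,
)
from chorusmatch.evaluation import AnnotatedFile, ConfusionCounts, compute_metrics, tally
from chorusmatch.matching import detections_to_frame, find_detections, score_template

from conftest import make_spectrogram, make_template


def toy_counts(pa_tp, pa_fp, pa_fn, pa_tn):
    return ConfusionCounts(count_tp=pa_tp, count_fp=pa_fp, pa_tp=pa_tp,
                           pa_fp=pa_fp, pa_fn=pa_fn, pa_tn=pa_tn,
                           n_files=pa_tp + pa_fp + pa_fn + pa_tn)


def curve_from_rocs(cutoffs, rocs):
    # counts engineered so (pa_tp+pa_tn)/n equals the requested roc over n=10
    points = []
    for c, r in zip(cutoffs, rocs):
        # place k correctly classified files among 10 (5 present, 5 absent)
        k = int(round(r * 10))
        tp = min(k, 5)
        tn = k - tp
        counts = toy_counts(tp, 5 - tn, 5 - tp, tn)
        points.append(RocPoint(c, counts, compute_metrics(counts).roc_value))
    return RocCurve(points=tuple(points), template_name="t", species="sp")


@pytest.fixture
def synthetic_survey_set(rng):
    """Five toy spectrograms with planted hot blocks plus annotations."""
    mask = np.zeros((4, 5), dtype=bool)
    mask[1:3, 1:4] = True
    template = make_template(mask, first_bin=2, species="sp")
    surveys, ann = {}, []
    for i in range(5):
        amp = rng.uniform(-60, -30, size=(10, 40))
        present = i < 3
        if present:
            # plant two call-like hot blocks with different contrasts
            amp[3:5, 5:8] = -4.0
            amp[3:5, 20:23] = -12.0
        surveys[f"f{i}"] = make_spectrogram(amp)
        ann.append(AnnotatedFile(f"f{i}", frozenset({"sp"} if present else ())))
    return template, surveys, ann


class TestSweepCutoffs:
    def test_no_annotations_errors(self, synthetic_survey_set):
        template, surveys, _ = synthetic_survey_set
        with pytest.raises(ValueError, match="no annotated files"):
            sweep_cutoffs(template, surveys, [])

    def test_all_scores_below_start_gives_absence_accuracy(self, rng):
        mask = np.ones((2, 3), dtype=bool)
        mask[0, 0] = False
        template = make_template(mask, first_bin=1, species="sp")
        surveys = {
            f"f{i}": make_spectrogram(rng.uniform(-51, -49, size=(8, 30)))
            for i in range(4)
        }
        ann = [AnnotatedFile(f"f{i}", frozenset({"sp"} if i < 2 else ()))
               for i in range(4)]
        curve = sweep_cutoffs(template, surveys, ann, start=3.0, step=0.2)
        for point in curve.points:
            assert point.counts.pa_tp == 0 and point.counts.pa_fp == 0
            assert point.roc_value == 0.5  # prevalence of absence

    def test_rethreshold_equals_independent_rerun(self, synthetic_survey_set):
        template, surveys, ann = synthetic_survey_set
        fast = sweep_cutoffs(template, surveys, ann, start=3.0, step=0.2,
                             stop=3.4, mode="rethreshold")
        slow = sweep_cutoffs(template, surveys, ann, start=3.0, step=0.2,
                             stop=3.4, mode="rematch")
        assert [p.score_cutoff for p in fast.points] == [3.0, 3.2, 3.4]
        for a, b in zip(fast.points, slow.points):
            assert a.counts == b.counts

    def test_each_point_equals_manual_threshold(self, synthetic_survey_set):
        template, surveys, ann = synthetic_survey_set
        curve = sweep_cutoffs(template, surveys, ann, start=3.0, step=0.2,
                              stop=3.4)
        for point in curve.points:
            detections = []
            for sid, spec in surveys.items():
                trace = score_template(template, spec)
                trace.survey_id = sid
                detections.extend(
                    find_detections(trace, point.score_cutoff,
                                    template.duration_frames))
            manual = tally(detections_to_frame(detections), ann, "sp")
            assert manual == point.counts

    def test_pa_counts_monotone_over_grid(self, synthetic_survey_set):
        template, surveys, ann = synthetic_survey_set
        curve = sweep_cutoffs(template, surveys, ann, start=3.0, step=0.2)
        pa_tp = [p.counts.pa_tp for p in curve.points]
        pa_fp = [p.counts.pa_fp for p in curve.points]
        assert all(a >= b for a, b in zip(pa_tp, pa_tp[1:]))
        assert all(a >= b for a, b in zip(pa_fp, pa_fp[1:]))

    def test_default_stop_brackets_max_score(self, synthetic_survey_set):
        template, surveys, ann = synthetic_survey_set
        max_score = max(score_template(template, s).scores.max()
                        for s in surveys.values())
        curve = sweep_cutoffs(template, surveys, ann)
        assert curve.cutoffs[-1] >= max_score


class TestSelectOptimalCutoff:
    def test_unimodal_curve_picks_peak(self):
        curve = curve_from_rocs([3.0, 3.2, 3.4, 3.6], [0.5, 0.9, 0.7, 0.6])
        assert select_optimal_cutoff(curve).optimal_cutoff == 3.2

    def test_flat_curve_ties_to_highest_cutoff(self):
        curve = curve_from_rocs([3.0, 3.2, 3.4], [0.7, 0.7, 0.7])
        assert select_optimal_cutoff(curve).optimal_cutoff == 3.4

    def test_agrees_with_exhaustive_scan(self, rng):
        for _ in range(20):
            rocs = rng.integers(0, 11, size=10) / 10
            cutoffs = [3.0 + 0.2 * i for i in range(10)]
            result = select_optimal_cutoff(curve_from_rocs(cutoffs, rocs))
            best = max(range(10), key=lambda i: (rocs[i], cutoffs[i]))
            assert result.optimal_cutoff == pytest.approx(cutoffs[best])
            assert result.roc_value == pytest.approx(rocs[best])

    def test_empty_curve_errors(self):
        with pytest.raises(ValueError, match="empty"):
            select_optimal_cutoff(RocCurve((), "t", "sp"))


class TestRankTemplates:
    def _result(self, name, roc, species="sp"):
        counts = toy_counts(3, 1, 2, 4)
        curve = RocCurve((RocPoint(3.0, counts, roc),), name, species)
        return CalibrationResult(name, species, 3.0, counts, roc, curve)

    def test_single_template_selected(self):
        table = rank_templates([self._result("only", 0.8)])
        assert table.selected.all()

    def test_fourth_best_excluded_at_keep_three(self):
        rocs = {"t1": 0.897, "t2": 0.872, "t3": 0.833, "t4": 0.808}
        table = rank_templates(
            [self._result(n, r) for n, r in rocs.items()], keep=3)
        excluded = set(table.loc[table.excluded, "template_name"])
        assert excluded == {"t4"}

    def test_permutation_invariance(self, rng):
        results = [self._result(f"t{i}", r)
                   for i, r in enumerate([0.9, 0.7, 0.8, 0.6, 0.85])]
        base = rank_templates(results, keep=2)
        perm = [results[i] for i in rng.permutation(len(results))]
        shuffled = rank_templates(perm, keep=2)
        assert base.template_name.tolist() == shuffled.template_name.tolist()
        assert base.selected.tolist() == shuffled.selected.tolist()


def test_plot_roc_curves_labels_templates(tmp_path):
    import matplotlib
    matplotlib.use("Agg")
    from chorusmatch.calibration import plot_roc_curves

    curves = [curve_from_rocs([3.0, 3.2], [0.5, 0.8])]
    fig = plot_roc_curves(curves, tmp_path / "roc.png")
    labels = [t.get_text() for t in fig.axes[0].get_legend().get_texts()]
    assert labels == ["t"]
    assert (tmp_path / "roc.png").exists()
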