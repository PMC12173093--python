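import numpy as np
import pandas as pd
import pytest
import scipy.linalg

from phenovis.io import SurveySchema, ValidationError, make_survey_table
from phenovis.mca import (
    IndicatorMatrix,
    McaResult,
    build_indicator,
    eigengaps,
    fit_mca,
    mca_trend,
)

from conftest import long_rows


def random_indicator(rng, n_dates=None, section="mood"):
    """Random complete one-hot design: a few questions with 2-4 levels."""
    n = n_dates or int(rng.integers(3, 11))
    n_q = int(rng.integers(2, 5))
    cols, blocks = [], []
    for qi in range(n_q):
        L = int(rng.integers(2, 5))
        labels = rng.integers(0, L, n)
        blocks.append(np.eye(L)[labels])
        cols.extend((f"q{qi}", lv) for lv in range(L))
    Z = np.hstack(blocks)
    return IndicatorMatrix(
        section=section,
        dates=pd.date_range("2021-06-01", periods=n),
        columns=cols,
        values=Z,
        n_questions=n_q,
    )


def oracle_eigs_and_scores(Z, Q):
    """Independent route: eigendecomposition of S S^T on the standardized
    residuals, scores from the eigenvectors."""
    N = Z.sum()
    P = Z / N
    r, c = P.sum(axis=1), P.sum(axis=0)
    keep = c > 0
    S = (P[:, keep] - np.outer(r, c[keep])) / np.sqrt(np.outer(r, c[keep]))
    w, V = scipy.linalg.eigh(S @ S.T)
    order = np.argsort(w)[::-1]
    w, V = np.clip(w[order], 0, None), V[:, order]
    scores = V * np.sqrt(w)[None, :] / np.sqrt(r)[:, None]
    return w, scores


class TestBuildIndicator:
    def test_single_date_coding(self):
        schema = SurveySchema(
            ("mood",), {"mood": ("q1", "q2")},
            {("mood", "q1"): (0, 1, 2), ("mood", "q2"): (0, 1)},
        )
        table = make_survey_table(
            long_rows(schema, [{("mood", "q1"): 1, ("mood", "q2"): 0}]), schema
        )
        ind = build_indicator(table, schema, "mood")
        assert ind.values.tolist() == [[0, 1, 0, 1, 0]]
        assert ind.values.sum() == 2

    def test_identical_dates_identical_rows(self, tiny_schema):
        days = [{("mood", "m1"): 2, ("mood", "m2"): 1}] * 3
        table = make_survey_table(long_rows(tiny_schema, days), tiny_schema)
        ind = build_indicator(table, tiny_schema, "mood")
        assert (ind.values == ind.values[0]).all()

    def test_unused_level_column_retained(self, tiny_schema):
        days = [{("mood", "m1"): 0, ("mood", "m2"): 0}] * 2
        table = make_survey_table(long_rows(tiny_schema, days), tiny_schema)
        ind = build_indicator(table, tiny_schema, "mood")
        assert len(ind.columns) == 8  # 2 questions x 4 levels, zeros kept
        assert (ind.values.sum(axis=0) == 0).sum() == 6

    def test_missing_cell_is_error(self, tiny_schema):
        days = [{("mood", "m1"): 1, ("mood", "m2"): np.nan}]
        table = make_survey_table(long_rows(tiny_schema, days), tiny_schema)
        with pytest.raises(ValidationError, match="impute first"):
            build_indicator(table, tiny_schema, "mood")


class TestFitMca:
    def test_zero_inertia_degenerate(self, tiny_schema):
        days = [{("mood", "m1"): 2, ("mood", "m2"): 1}] * 4
        table = make_survey_table(long_rows(tiny_schema, days), tiny_schema)
        res = fit_mca(build_indicator(table, tiny_schema, "mood"))
        assert res.degenerate
        assert np.all(res.eigenvalues == 0)
        assert np.all(mca_trend(res).to_numpy() == 0)
        assert eigengaps(res) == (0.0, 0.0)

    def test_two_opposite_binary_dates(self):
        # 2x2 indicator [[1,0],[0,1]]: hand-worked CA gives one eigenvalue 1
        # and row scores +-1 symmetric about zero
        ind = IndicatorMatrix(
            "mood",
            pd.date_range("2021-06-01", periods=2),
            [("q1", 0), ("q1", 1)],
            np.eye(2),
            1,
        )
        res = fit_mca(ind)
        assert res.eigenvalues[0] == pytest.approx(1.0, abs=1e-12)
        s = mca_trend(res).to_numpy()
        assert s[0] == pytest.approx(-s[1], abs=1e-12)
        assert abs(s[0]) == pytest.approx(1.0, abs=1e-12)

    def test_oracle_equivalence_random_instances(self):
        rng = np.random.default_rng(123)
        checked = 0
        while checked < 40:
            ind = random_indicator(rng)
            res = fit_mca(ind)
            if res.degenerate:
                continue
            w, scores = oracle_eigs_and_scores(ind.values, ind.n_questions)
            m = len(res.eigenvalues)
            assert np.abs(res.eigenvalues - w[:m]).max() < 1e-8
            # scores are only identified for simple (well-separated) nonzero
            # eigenvalues: repeated ones admit arbitrary eigenspace rotations
            padded = np.concatenate([[np.inf], w[: m + 1], [-np.inf]])
            simple = (
                (w[:m] > 1e-10)
                & (padded[:m] - w[:m] > 1e-6)
                & (w[:m] - padded[2 : m + 2] > 1e-6)
            )
            assert (
                np.abs(
                    np.abs(res.row_scores.to_numpy()[:, simple])
                    - np.abs(scores[:, :m][:, simple])
                ).max(initial=0.0)
                < 1e-8
            )
            checked += 1

    def test_total_inertia_complete_design(self):
        # all levels realized: total inertia is (J - Q) / Q
        rng = np.random.default_rng(5)
        for _ in range(20):
            ind = random_indicator(rng, n_dates=10)
            if (ind.values.sum(axis=0) == 0).any():
                continue
            J, Q = ind.values.shape[1], ind.n_questions
            res = fit_mca(ind)
            assert res.total_inertia == pytest.approx((J - Q) / Q, abs=1e-10)

    def test_row_order_invariance(self):
        rng = np.random.default_rng(9)
        ind = random_indicator(rng, n_dates=8)
        res = fit_mca(ind)
        perm = rng.permutation(8)
        ind_p = IndicatorMatrix(
            ind.section, ind.dates[perm], ind.columns, ind.values[perm],
            ind.n_questions,
        )
        res_p = fit_mca(ind_p)
        assert np.allclose(res.eigenvalues, res_p.eigenvalues, atol=1e-10)
        trend, trend_p = mca_trend(res), mca_trend(res_p)
        assert np.allclose(
            trend.to_numpy()[perm], trend_p.to_numpy(), atol=1e-10
        )

    def test_mass_weighted_score_mean_is_zero(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            ind = random_indicator(rng)
            res = fit_mca(ind)
            if res.degenerate:
                continue
            r = np.full(len(ind.dates), 1.0 / len(ind.dates))
            assert np.abs(r @ res.row_scores.to_numpy()).max() < 1e-8

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(33)
        ind = random_indicator(rng, n_dates=9)
        a, b = fit_mca(ind), fit_mca(ind)
        assert np.array_equal(a.row_scores.to_numpy(), b.row_scores.to_numpy())
        # convention: first component correlates non-negatively with the
        # dates' mean raw response
        mean_resp = ind.mean_responses()
        trend = mca_trend(a).to_numpy()
        assert trend @ (mean_resp - mean_resp.mean()) >= -1e-12


class TestEigengaps:
    def _result_with_proportions(self, props):
        props = np.asarray(props, dtype=float)
        eigs = props.copy()
        dates = pd.date_range("2021-06-01", periods=2)
        return McaResult(
            section="mood",
            dates=dates,
            eigenvalues=eigs,
            inertia_proportions=props,
            row_scores=pd.DataFrame(
                np.zeros((2, len(props))), index=dates,
                columns=[f"component_{i+1}" for i in range(len(props))],
            ),
            first_eigengap=np.nan,
            second_eigengap=np.nan,
            total_inertia=float(eigs.sum()),
        )

    @pytest.mark.parametrize(
        "props,expected",
        [
            ([0.6, 0.3, 0.1], (0.3, 0.2)),
            ([1.0], (1.0, 0.0)),  # padded with zeros
            ([1 / 3, 1 / 3, 1 / 3], (0.0, 0.0)),
        ],
    )
    def test_arithmetic(self, props, expected):
        first, second = eigengaps(self._result_with_proportions(props))
        assert (first, second) == pytest.approx(expected)


def test_noisier_responses_flatten_the_spectrum():
    """More erratic answering should never raise the first eigengap, as a
    Monte-Carlo average: consistent days concentrate inertia on one
    dominant dimension, noise spreads it out."""
    from phenovis.synth import SynthConfig, generate_patient
    from phenovis.imputation import impute_locf
    from phenovis.mca import fit_section

    gaps = {}
    for sd in (0.3, 1.2):
        vals = []
        for seed in range(25):
            cfg = SynthConfig(
                n_patients=1, span_days=40, relapse_spec={0: []},
                baseline_response_sd=sd, missing_rate=0.0, seed=1000 + seed,
            )
            survey, _, _ = generate_patient(cfg, 0)
            res = fit_section(survey, cfg.schema, "mood")
            vals.append(eigengaps(res)[0])
        gaps[sd] = np.mean(vals)
    assert gaps[1.2] <= gaps[0.3]
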