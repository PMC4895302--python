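import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cyspred.evaluation import CVConfig
from cyspred.io_formats import AA_ORDER, AAIndexEntry
from cyspred.model import SVMConfig
from cyspred.selection import (
    FScoreTable,
    f_score,
    f_score_columns,
    forward_select,
    rank_by_single_accuracy,
    score_properties,
)
from cyspred.synthetic import SyntheticConfig, generate_fragments, random_aaindex_entries


def f_score_oracle(pos, neg):
    """Literal transcription of the F-score definition."""
    pos, neg = list(pos), list(neg)
    n_pos, n_neg = len(pos), len(neg)
    mean_all = sum(pos + neg) / (n_pos + n_neg)
    mean_pos = sum(pos) / n_pos
    mean_neg = sum(neg) / n_neg
    numerator = (mean_pos - mean_all) ** 2 + (mean_neg - mean_all) ** 2
    denominator = (
        sum((x - mean_pos) ** 2 for x in pos) / (n_pos - 1)
        + sum((x - mean_neg) ** 2 for x in neg) / (n_neg - 1)
    )
    if numerator == 0:
        return 0.0
    if denominator == 0:
        return math.inf
    return numerator / denominator


class TestFScore:
    def test_worked_example(self):
        assert f_score([2, 4], [0, 2]) == pytest.approx(0.5)

    def test_equal_means_zero(self):
        assert f_score([1, 0], [0, 1]) == 0.0

    def test_degenerate_infinite(self):
        assert f_score([5, 5], [0, 0]) == math.inf

    def test_too_few_samples_errors(self):
        with pytest.raises(ValueError):
            f_score([1], [0, 1])

    @given(
        pos=st.lists(st.floats(-100, 100), min_size=2, max_size=30),
        neg=st.lists(st.floats(-100, 100), min_size=2, max_size=30),
    )
    @settings(max_examples=500, deadline=None)
    def test_matches_literal_oracle(self, pos, neg):
        expected = f_score_oracle(pos, neg)
        got = f_score(pos, neg)
        if math.isinf(expected):
            assert math.isinf(got)
        else:
            assert got == pytest.approx(expected, rel=1e-12, abs=1e-12)

    @given(
        pos=st.lists(st.floats(-10, 10), min_size=2, max_size=15),
        neg=st.lists(st.floats(-10, 10), min_size=2, max_size=15),
        a=st.floats(0.1, 50),
        b=st.floats(-20, 20),
    )
    @settings(max_examples=200, deadline=None)
    def test_affine_invariance(self, pos, neg, a, b):
        base = f_score(pos, neg)
        transformed = f_score([a * x + b for x in pos], [a * x + b for x in neg])
        if math.isinf(base):
            assert math.isinf(transformed)
        elif base > 1e-12:
            assert transformed == pytest.approx(base, rel=1e-6)

    def test_vectorized_matches_scalar(self, rng):
        Xp = rng.normal(size=(20, 7))
        Xn = rng.normal(loc=0.5, size=(25, 7))
        cols = f_score_columns(Xp, Xn)
        for j in range(7):
            assert cols[j] == pytest.approx(f_score(Xp[:, j], Xn[:, j]))


def _planted_config(entry, effect=0.5, seed=0, n=150):
    return SyntheticConfig(
        n_pos=n, n_neg=n, window_n=5,
        informative_property=entry, property_effect=effect, seed=seed,
    )


@pytest.fixture(scope="module")
def planted():
    entry = AAIndexEntry(
        "INFO000001", "planted informative axis",
        {a: float(i) for i, a in enumerate(AA_ORDER)},
    )
    noise = random_aaindex_entries(19, seed=11)
    pos, neg = generate_fragments(_planted_config(entry))
    return entry, noise, pos + neg


class TestScoreProperties:
    def test_constant_property_scores_zero(self, planted):
        _, _, frags = planted
        flat = AAIndexEntry("FLAT000001", "constant", {a: 1.0 for a in AA_ORDER})
        table = score_properties(frags, [flat], normalize="raw")
        assert table.scores["FLAT000001"] == 0.0

    def test_planted_property_ranks_first(self, planted):
        entry, noise, frags = planted
        table = score_properties(frags, [entry] + noise)
        assert table.ranked()[0][0] == "INFO000001"

    def test_proportional_properties_tie(self, planted):
        entry, _, frags = planted
        scaled = AAIndexEntry(
            "INFO000002", "affine copy",
            {a: 3.0 * v + 7.0 for a, v in entry.values.items()},
        )
        table = score_properties(frags, [entry, scaled])
        assert table.scores["INFO000001"] == pytest.approx(
            table.scores["INFO000002"], rel=1e-9
        )

    def test_table_tsv(self, planted, tmp_path):
        entry, noise, frags = planted
        table = score_properties(frags, [entry] + noise[:3])
        path = tmp_path / "fscores.tsv"
        table.write_tsv(path)
        lines = path.read_text().splitlines()
        assert lines[0] == "property\tscore\trank"
        assert lines[1].startswith("INFO000001")


class TestRankBySingleAccuracy:
    def test_planted_property_first(self, planted):
        entry, noise, frags = planted
        ranked = rank_by_single_accuracy(
            [entry] + noise[:5], frags,
            SVMConfig(C=2.0, gamma=0.1), CVConfig(k=3, seed=0),
        )
        assert ranked[0].entry.accession == "INFO000001"

    def test_single_property(self, planted):
        entry, _, frags = planted
        ranked = rank_by_single_accuracy(
            [entry], frags, SVMConfig(), CVConfig(k=3, seed=0)
        )
        assert len(ranked) == 1

    def test_deterministic(self, planted):
        entry, noise, frags = planted
        args = ([entry] + noise[:3], frags, SVMConfig(), CVConfig(k=3, seed=5))
        a = rank_by_single_accuracy(*args)
        b = rank_by_single_accuracy(*args)
        assert [r.entry.accession for r in a] == [r.entry.accession for r in b]

    def test_empty_errors(self, planted):
        _, _, frags = planted
        with pytest.raises(ValueError):
            rank_by_single_accuracy([], frags, SVMConfig(), CVConfig(k=3))


class TestForwardSelect:
    def _separable_base(self, n=60, seed=3):
        rng = np.random.default_rng(seed)
        X = np.vstack([
            rng.normal(2.0, 1.0, size=(n, 4)),
            rng.normal(-2.0, 1.0, size=(n, 4)),
        ])
        y = np.array([1] * n + [-1] * n)
        return X, y, rng

    def test_pure_noise_candidates_not_kept(self):
        X, y, rng = self._separable_base()
        candidates = [
            (f"noise{i}", rng.normal(size=(len(y), 3))) for i in range(4)
        ]
        trace = forward_select(X, candidates, y, SVMConfig(C=4.0, gamma=0.1),
                               CVConfig(k=3, seed=0))
        assert trace.base_metrics.mcc == 1.0
        assert trace.best_prefix == []
        assert trace.best_metrics.mcc == trace.base_metrics.mcc

    def test_informative_candidate_included(self):
        rng = np.random.default_rng(8)
        n = 60
        X = rng.normal(size=(2 * n, 4))  # uninformative base
        y = np.array([1] * n + [-1] * n)
        signal = np.concatenate([
            rng.normal(2.0, 0.5, size=n), rng.normal(-2.0, 0.5, size=n)
        ]).reshape(-1, 1)
        candidates = [("signal", signal),
                      ("noise", rng.normal(size=(2 * n, 2)))]
        trace = forward_select(X, candidates, y, SVMConfig(C=4.0, gamma=0.1),
                               CVConfig(k=3, seed=0))
        assert "signal" in trace.best_prefix
        assert trace.best_metrics.mcc > trace.base_metrics.mcc

    def test_trace_records_every_candidate(self):
        X, y, rng = self._separable_base(n=30)
        candidates = [(f"c{i}", rng.normal(size=(len(y), 1))) for i in range(5)]
        trace = forward_select(X, candidates, y, SVMConfig(), CVConfig(k=3, seed=0))
        assert [s.feature for s in trace.steps] == [f"c{i}" for i in range(5)]

    def test_best_prefix_never_below_base(self):
        X, y, rng = self._separable_base(n=25, seed=12)
        candidates = [(f"c{i}", rng.normal(size=(len(y), 2))) for i in range(3)]
        for mode in ("cumulative", "greedy"):
            trace = forward_select(X, candidates, y, SVMConfig(),
                                   CVConfig(k=3, seed=0), mode=mode)
            assert trace.best_metrics.mcc >= trace.base_metrics.mcc

    def test_empty_candidates_error(self):
        X, y, _ = self._separable_base(n=20)
        with pytest.raises(ValueError):
            forward_select(X, [], y, SVMConfig(), CVConfig(k=3, seed=0))

    def test_trace_tsv(self, tmp_path):
        X, y, rng = self._separable_base(n=20)
        candidates = [("c0", rng.normal(size=(len(y), 1)))]
        trace = forward_select(X, candidates, y, SVMConfig(), CVConfig(k=3, seed=0))
        path = tmp_path / "trace.tsv"
        trace.write_tsv(path)
        lines = path.read_text().splitlines()
        assert lines[0].startswith("step\tproperty")
        assert len(lines) == 3
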