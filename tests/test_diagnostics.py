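"""Diagnostic accuracy and agreement statistics, checked against hand
computations and statsmodels as an independent reference."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats import inter_rater

from qsmrim.diagnostics import (
    ContingencyTable,
    agreement_stats,
    build_contingency,
    cohen_kappa,
    diagnostic_metrics,
    fleiss_kappa,
    landis_koch_label,
    majority_vote,
    percent_round_half_up,
)

# The study's two published 2x2 tables (test = rim call, truth = Perls' iron)
QSM_TABLE = ContingencyTable(tp=10, fp=0, fn=1, tn=21)
PHASE_TABLE = ContingencyTable(tp=10, fp=6, fn=1, tn=15)


class TestContingency:
    def test_build_from_calls(self):
        calls = pd.Series(
            ["rim+"] * 10 + ["rim-"] * 1 + ["rim+"] * 6 + ["rim-"] * 15,
            index=[f"L{i}" for i in range(32)],
        )
        truth = pd.Series(
            ["iron+"] * 11 + ["iron-"] * 21, index=[f"L{i}" for i in range(32)]
        )
        t = build_contingency(calls, truth)
        assert (t.tp, t.fp, t.fn, t.tn) == (10, 6, 1, 15)
        assert t.total == 32

    def test_empty_input(self):
        t = build_contingency(pd.Series(dtype=object), pd.Series(dtype=object))
        assert (t.tp, t.fp, t.fn, t.tn) == (0, 0, 0, 0)

    def test_mismatched_lesion_sets(self):
        with pytest.raises(ValueError, match="different lesion sets"):
            build_contingency(
                pd.Series({"a": "rim+"}), pd.Series({"b": "iron+"})
            )

    def test_permutation_invariance(self, rng):
        ids = [f"L{i}" for i in range(20)]
        calls = pd.Series(rng.choice(["rim+", "rim-"], 20), index=ids)
        truth = pd.Series(rng.choice(["iron+", "iron-"], 20), index=ids)
        t1 = build_contingency(calls, truth)
        perm = rng.permutation(ids)
        t2 = build_contingency(calls.loc[perm], truth.loc[perm])
        assert t1 == t2


class TestDiagnosticMetrics:
    def test_qsm_published_percentages(self):
        m = diagnostic_metrics(QSM_TABLE)
        assert (
            m.sensitivity_pct,
            m.specificity_pct,
            m.ppv_pct,
            m.npv_pct,
            m.accuracy_pct,
        ) == (91, 100, 100, 95, 97)

    def test_phase_published_percentages(self):
        m = diagnostic_metrics(PHASE_TABLE)
        assert (
            m.sensitivity_pct,
            m.specificity_pct,
            m.ppv_pct,
            m.npv_pct,
            m.accuracy_pct,
        ) == (91, 71, 63, 94, 78)

    def test_half_up_rounding_convention(self):
        assert percent_round_half_up(10 / 16) == 63  # 62.5 prints as 63
        assert percent_round_half_up(0.625) == 63
        assert percent_round_half_up(0.615) == 62

    def test_degenerate_denominators_flagged(self):
        m = diagnostic_metrics(ContingencyTable(0, 0, 0, 5))
        assert m.sensitivity is None and m.ppv is None
        assert m.specificity_pct == 100 and m.accuracy_pct == 100

    def test_accuracy_prevalence_identity(self, rng):
        for _ in range(20):
            tp, fp, fn, tn = rng.integers(1, 30, size=4)
            m = diagnostic_metrics(ContingencyTable(int(tp), int(fp), int(fn), int(tn)))
            prev = (tp + fn) / (tp + fp + fn + tn)
            assert m.accuracy == pytest.approx(
                m.sensitivity * prev + m.specificity * (1 - prev), abs=1e-12
            )


class TestMajorityVote:
    def test_basic_votes(self):
        ratings = pd.DataFrame(
            {
                "r1": ["rim+", "rim-"],
                "r2": ["rim+", "rim-"],
                "r3": ["rim-", "rim-"],
            },
            index=["L1", "L2"],
        )
        out = majority_vote(ratings)
        assert list(out) == ["rim+", "rim-"]

    def test_even_raters_rejected(self):
        ratings = pd.DataFrame({"r1": ["rim+"] * 3, "r2": ["rim-"] * 3})
        with pytest.raises(ValueError, match="odd"):
            majority_vote(ratings)

    def test_study_scale(self, rng):
        ratings = pd.DataFrame(
            rng.choice(["rim+", "rim-"], size=(32, 3)),
            columns=["r1", "r2", "r3"],
        )
        assert len(majority_vote(ratings)) == 32


class TestCohenKappa:
    def test_perfect_agreement(self):
        s = ["rim+", "rim-", "rim+", "rim-"]
        assert cohen_kappa(s, s) == 1.0

    def test_complement_on_balanced_set(self):
        s1 = ["rim+", "rim+", "rim-", "rim-"]
        s2 = ["rim-", "rim-", "rim+", "rim+"]
        assert cohen_kappa(s1, s2) == pytest.approx(-1.0, abs=1e-12)

    def test_hand_computed_fixture(self):
        # agreement counts (a,b,c,d) = (20,5,5,20): p_o = 0.8, p_e = 0.5
        s1 = ["+"] * 25 + ["-"] * 25
        s2 = ["+"] * 20 + ["-"] * 5 + ["+"] * 5 + ["-"] * 20
        assert cohen_kappa(s1, s2) == pytest.approx(0.6, abs=1e-12)

    def test_degenerate_marginals(self):
        # both sessions single-category: p_e = 1 and agreement is perfect
        assert cohen_kappa(["+", "+"], ["+", "+"]) == 1.0
        # one degenerate session: chance-corrected agreement collapses to 0
        assert cohen_kappa(["+", "+", "+"], ["+", "+", "-"]) == 0.0

    def test_matches_statsmodels(self, rng):
        s1 = rng.choice(["+", "-"], 200)
        s2 = np.where(rng.random(200) < 0.7, s1, rng.choice(["+", "-"], 200))
        table = pd.crosstab(pd.Series(s1), pd.Series(s2)).to_numpy()
        ref = inter_rater.cohens_kappa(table, return_results=False)
        assert cohen_kappa(s1, s2) == pytest.approx(ref, abs=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            cohen_kappa(["+"], ["+", "-"])


class TestFleissKappa:
    def test_perfect_agreement_both_categories(self):
        ratings = pd.DataFrame(
            {"r1": ["+", "-", "+"], "r2": ["+", "-", "+"], "r3": ["+", "-", "+"]}
        )
        assert fleiss_kappa(ratings) == 1.0

    def test_hand_computed_fixture(self):
        # items (+,+,-) and (-,-,+): P_i = 1/3, p_j = 0.5 -> kappa = -1/3
        ratings = pd.DataFrame(
            {"r1": ["+", "-"], "r2": ["+", "-"], "r3": ["-", "+"]}
        )
        assert fleiss_kappa(ratings) == pytest.approx(-1.0 / 3.0, abs=1e-12)

    def test_independent_raters_null(self):
        rng = np.random.default_rng(42)
        ratings = pd.DataFrame(
            rng.choice(["+", "-"], size=(2000, 3)), columns=["r1", "r2", "r3"]
        )
        assert abs(fleiss_kappa(ratings)) < 0.05

    def test_matches_statsmodels(self, rng):
        ratings = pd.DataFrame(rng.choice(["+", "-"], size=(60, 4)))
        counts, _ = inter_rater.aggregate_raters(ratings.to_numpy())
        ref = inter_rater.fleiss_kappa(counts, method="fleiss")
        assert fleiss_kappa(ratings) == pytest.approx(ref, abs=1e-12)

    def test_two_rater_relation_to_pooled_expected_agreement(self):
        """With two raters, Fleiss kappa equals (p_o - p_e)/(1 - p_e) with
        p_e computed from the pooled category proportions (not the
        per-rater marginal products Cohen uses)."""
        ratings = pd.DataFrame(
            {"r1": ["+", "+", "-", "-", "+"], "r2": ["+", "-", "-", "+", "+"]}
        )
        arr = ratings.to_numpy()
        p_o = np.mean(arr[:, 0] == arr[:, 1])
        pooled = np.mean(arr == "+")
        p_e = pooled**2 + (1 - pooled) ** 2
        assert fleiss_kappa(ratings) == pytest.approx(
            (p_o - p_e) / (1 - p_e), abs=1e-12
        )

    def test_missing_cells_rejected(self):
        ratings = pd.DataFrame({"r1": ["+", None], "r2": ["+", "-"]})
        with pytest.raises(ValueError, match="missing"):
            fleiss_kappa(ratings)


class TestLandisKoch:
    @pytest.mark.parametrize(
        "kappa,label",
        [
            (0.57, "moderate"),
            (0.33, "fair"),
            (0.85, "almost perfect"),
            (1.0, "almost perfect"),
            (0.20, "slight"),  # band edges closed on the right
            (0.0, "slight"),
            (-0.2, "poor"),
        ],
    )
    def test_default_bands(self, kappa, label):
        assert landis_koch_label(kappa) == label

    def test_kappa_above_one_rejected(self):
        with pytest.raises(ValueError):
            landis_koch_label(1.2)


class TestAgreementStats:
    def test_two_session_summary(self, rng):
        from qsmrim.phantom import generate_rating_matrix

        truth = pd.DataFrame(
            {
                "lesion_id": [f"L{i}" for i in range(32)],
                "class_label": "rim",
                "iron_rim_status": rng.choice(["iron+", "iron-"], 32),
            }
        )
        s1 = generate_rating_matrix(truth, [0.9, 0.8, 0.85], [0.9, 0.85, 0.8], seed=1)
        s2 = generate_rating_matrix(truth, [0.9, 0.8, 0.85], [0.9, 0.85, 0.8], seed=2)
        stats = agreement_stats(s1, s2)
        assert -1.0 <= stats.fleiss_kappa <= 1.0
        assert set(stats.cohen_kappas) == {"rater_1", "rater_2", "rater_3"}
        assert stats.fleiss_label in {
            "poor", "slight", "fair", "moderate", "substantial", "almost perfect",
        }
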