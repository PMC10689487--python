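"""Metric arithmetic, McNemar test, report tables."""

import math

import numpy as np
import pytest
from scipy import stats

from pphkit.corpus_io import GoldAnnotation, IcdRecord
from pphkit.evaluation import (
    ConfusionCounts,
    PairedOutcomes,
    binary_metrics,
    ebl_icd_crosstab,
    extraction_metrics,
    macro_f1,
    mcnemar,
)
from pphkit.extraction import ConceptCall


class TestBinaryMetrics:
    def test_worked_example(self):
        m = binary_metrics(ConfusionCounts(tp=3, fp=1, fn=1, tn=5))
        assert m["sensitivity"] == pytest.approx(0.75)
        assert m["ppv"] == pytest.approx(0.75)
        assert m["binary_f1"] == pytest.approx(0.75)
        assert m["accuracy"] == pytest.approx(0.8)
        assert m["specificity"] == pytest.approx(5 / 6)

    def test_perfect_predictor(self):
        m = binary_metrics(ConfusionCounts(tp=7, fp=0, fn=0, tn=13))
        assert all(v == 1.0 for v in m.values())

    def test_undefined_denominators_flagged_not_zero(self):
        m = binary_metrics(ConfusionCounts(tp=0, fp=0, fn=2, tn=3))
        assert math.isnan(m["ppv"])  # no positive predictions
        m2 = binary_metrics(ConfusionCounts(tp=0, fp=1, fn=0, tn=3))
        assert math.isnan(m2["sensitivity"])  # no gold positives

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, fp=0, fn=0, tn=0)

    def test_recount_oracle_on_random_fixtures(self):
        rng = np.random.default_rng(11)
        for _ in range(1000):
            n = int(rng.integers(1, 40))
            pred = rng.random(n) < 0.5
            gold = rng.random(n) < 0.5
            c = ConfusionCounts(
                tp=int(np.sum(pred & gold)),
                fp=int(np.sum(pred & ~gold)),
                fn=int(np.sum(~pred & gold)),
                tn=int(np.sum(~pred & ~gold)),
            )
            m = binary_metrics(c)
            # brute-force recount
            sens = np.sum(pred & gold) / np.sum(gold) if np.sum(gold) else math.nan
            acc = np.mean(pred == gold)
            if math.isnan(sens):
                assert math.isnan(m["sensitivity"])
            else:
                assert m["sensitivity"] == pytest.approx(sens)
            assert m["accuracy"] == pytest.approx(acc)

    def test_macro_f1_is_mean_of_class_f1s(self):
        c = ConfusionCounts(tp=3, fp=1, fn=1, tn=5)
        pos = binary_metrics(c)["binary_f1"]
        neg = binary_metrics(ConfusionCounts(tp=5, fp=1, fn=1, tn=3))["binary_f1"]
        assert macro_f1(c) == pytest.approx((pos + neg) / 2)


class TestExtractionMetrics:
    def test_exact_match_single_note(self):
        m = extraction_metrics({"n1": {500.0}}, {"n1": {500.0}})
        assert m == {"sensitivity": 1.0, "ppv": 1.0, "note_accuracy": 1.0}

    def test_both_empty_counts_toward_accuracy_only(self):
        m = extraction_metrics({"n1": set()}, {"n1": set()})
        assert m["note_accuracy"] == 1.0
        assert math.isnan(m["sensitivity"]) and math.isnan(m["ppv"])

    def test_superset_prediction(self):
        m = extraction_metrics({"n1": {500.0, 800.0}}, {"n1": {500.0}})
        assert m["sensitivity"] == 1.0
        assert m["ppv"] == 0.5
        assert m["note_accuracy"] == 0.0

    def test_total_mode_switch(self):
        # {300, 500} vs {800}: different sets, equal totals
        m = extraction_metrics({"n1": {300.0, 500.0}}, {"n1": {800.0}}, note_accuracy_mode="total")
        assert m["note_accuracy"] == 1.0

    def test_mismatched_universe_rejected(self):
        with pytest.raises(ValueError):
            extraction_metrics({"n1": set()}, {"n2": set()})

    def test_pooled_recount_oracle_on_random_fixtures(self):
        rng = np.random.default_rng(29)
        values = [100.0, 300.0, 500.0, 800.0, 1500.0]
        for _ in range(1000):
            n = int(rng.integers(1, 10))
            pred = {f"n{i}": {v for v in values if rng.random() < 0.3} for i in range(n)}
            gold = {f"n{i}": {v for v in values if rng.random() < 0.3} for i in range(n)}
            m = extraction_metrics(pred, gold)
            tp = sum(len(pred[k] & gold[k]) for k in gold)
            ng = sum(len(gold[k]) for k in gold)
            npred = sum(len(pred[k]) for k in pred)
            exact = sum(pred[k] == gold[k] for k in gold)
            assert (math.isnan(m["sensitivity"]) and ng == 0) or m["sensitivity"] == pytest.approx(tp / ng)
            assert (math.isnan(m["ppv"]) and npred == 0) or m["ppv"] == pytest.approx(tp / npred)
            assert m["note_accuracy"] == pytest.approx(exact / n)


class TestMcNemar:
    def test_exact_mode_b10_c0(self):
        r = mcnemar(PairedOutcomes(n11=5, n10=10, n01=0, n00=5), mode="exact")
        assert r["p_value"] == pytest.approx(2 * 0.5**10)
        assert r["mode_used"] == "exact"

    def test_balanced_discordance_p_one(self):
        r = mcnemar(PairedOutcomes(n11=0, n10=3, n01=3, n00=0), mode="exact")
        assert r["p_value"] == pytest.approx(1.0)

    def test_no_discordance_p_one(self):
        r = mcnemar(PairedOutcomes(n11=10, n10=0, n01=0, n00=10))
        assert r["p_value"] == 1.0

    def test_chi2cc_closed_form(self):
        r = mcnemar(PairedOutcomes(n11=0, n10=40, n01=20, n00=0), mode="chi2cc")
        expected_stat = (abs(40 - 20) - 1) ** 2 / 60
        assert r["statistic"] == pytest.approx(expected_stat)
        assert expected_stat == pytest.approx(6.0167, abs=1e-4)
        assert r["p_value"] == pytest.approx(stats.chi2.sf(expected_stat, df=1))

    def test_auto_threshold_at_25_discordant(self):
        assert mcnemar(PairedOutcomes(0, 12, 12, 0))["mode_used"] == "exact"
        assert mcnemar(PairedOutcomes(0, 13, 12, 0))["mode_used"] == "chi2cc"

    def test_exact_agrees_with_binomial_tail_oracle_exhaustive(self):
        """All discordant splits with b + c <= 20 match the direct tail sum."""
        for n in range(1, 21):
            for b in range(n + 1):
                c = n - b
                r = mcnemar(PairedOutcomes(n11=2, n10=b, n01=c, n00=2), mode="exact")
                k = min(b, c)
                if b == c:
                    expected = 1.0
                else:
                    tail = sum(math.comb(n, i) for i in range(k + 1)) / 2**n
                    expected = min(1.0, 2 * tail)
                assert r["p_value"] == pytest.approx(expected, rel=1e-12), (b, c)

    def test_symmetry_swapping_methods(self):
        for mode in ("exact", "chi2cc"):
            a = mcnemar(PairedOutcomes(5, 9, 3, 5), mode=mode)
            b = mcnemar(PairedOutcomes(5, 3, 9, 5), mode=mode)
            assert a["p_value"] == pytest.approx(b["p_value"])


class TestConceptReport:
    def test_perfect_calls_on_synthetic_gold(self, registry, clean_corpus_small):
        from pphkit.evaluation import concept_report

        notes, _, gold, calls = clean_corpus_small
        df = concept_report(calls, gold, registry)
        assert len(df) == 24
        binary = df[df["kind"] == "binary"]
        present = binary[binary["n"] > 0]
        assert (present["binary_f1"] == 1.0).all()

    def test_n_column_equals_gold_positive_count(self, registry, clean_corpus_small):
        from pphkit.evaluation import concept_report

        notes, _, gold, calls = clean_corpus_small
        df = concept_report(calls, gold, registry)
        for cid in ("uterine_atony", "laceration", "cesarean_delivery"):
            brute = sum(1 for g in gold if g.concept_id == cid and g.label)
            assert df.loc[cid, "n"] == brute

    def test_brute_force_tally_on_small_fixture(self, registry):
        from pphkit.evaluation import concept_report

        gold = []
        calls = []
        # 20 notes, plant predictions with known errors for one concept
        for i in range(20):
            truth = i % 2 == 0
            pred = truth if i not in (0, 1) else not truth  # one fn, one fp
            gold.append(GoldAnnotation(f"n{i}", "uterine_atony", label=truth))
            calls.append(ConceptCall(f"n{i}", "uterine_atony", label=pred))
            gold.append(GoldAnnotation(f"n{i}", "estimated_blood_loss", values=frozenset({500.0})))
            calls.append(ConceptCall(f"n{i}", "estimated_blood_loss", segments=frozenset({"500 mL"})))
        with pytest.warns(UserWarning):  # other 22 concepts have no gold
            df = concept_report(calls, gold, registry)
        row = df.loc["uterine_atony"]
        # tp=9 fn=1 fp=1 tn=9 by hand
        assert row["sensitivity"] == pytest.approx(0.9)
        assert row["ppv"] == pytest.approx(0.9)
        assert df.loc["estimated_blood_loss", "note_accuracy"] == 1.0

    def test_measurement_values_normalized_before_comparison(self, registry):
        from pphkit.evaluation import concept_report

        gold = [GoldAnnotation("n0", "estimated_blood_loss", values=frozenset({1500.0}))]
        calls = [ConceptCall("n0", "estimated_blood_loss", segments=frozenset({"1.5 L"}))]
        with pytest.warns(UserWarning):
            df = concept_report(calls, gold, registry)
        assert df.loc["estimated_blood_loss", "sensitivity"] == 1.0


class TestEblIcdCrosstab:
    def _assessment(self, pid, total, values, d):
        from datetime import date
        from pphkit.phenotyping import DeliveryAssessment

        return DeliveryAssessment(
            delivery_id=pid, patient_id=pid, note_ids=(pid,), note_dates=(d,),
            ebl_values=values, total_ebl_ml=total, mode="vaginal", pph=total > 500,
        )

    def test_fully_coded_population(self):
        from datetime import date

        d = date(2005, 6, 1)
        assessments = [self._assessment(f"p{i}", 600.0, (600.0,), d) for i in range(4)]
        codes = [IcdRecord(f"p{i}", "666.12", d, "ICD9") for i in range(4)]
        df = ebl_icd_crosstab(assessments, codes, [500, 1000], ["666"])
        assert df.loc["[500, 1000)", "proportion"] == 1.0

    def test_empty_code_table(self):
        from datetime import date

        d = date(2005, 6, 1)
        assessments = [self._assessment("p0", 0.0, (), d), self._assessment("p1", 1200.0, (1200.0,), d)]
        df = ebl_icd_crosstab(assessments, [], [500, 1000], ["666"])
        assert df.loc["no EBL", "n"] == 1
        assert df.loc[">= 1000", "proportion"] == 0.0

    def test_recount_oracle_random(self):
        from datetime import date

        rng = np.random.default_rng(8)
        d = date(2005, 6, 1)
        assessments = []
        codes = []
        for i in range(100):
            total = float(rng.choice([0, 200, 600, 1200, 2500]))
            values = (total,) if total else ()
            assessments.append(self._assessment(f"p{i}", total, values, d))
            if rng.random() < 0.4:
                codes.append(IcdRecord(f"p{i}", "666.12", d, "ICD9"))
        df = ebl_icd_crosstab(assessments, codes, [500, 1000, 2000], ["666"])
        coded = {c.patient_id for c in codes}
        assert df["n"].sum() == 100
        assert df["n_coded"].sum() == sum(1 for a in assessments if a.patient_id in coded)
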