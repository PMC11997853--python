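import numpy as np
import pandas as pd
import pytest

from ctlar.strata import (
    NationalCounts,
    StratumSummary,
    apply_eol_exclusion,
    estimate_exams_per_patient,
    largest_remainder_round,
    mean_exams_per_patient,
    scale_to_national,
    summarize_strata,
)
from ctlar.vocab import DOSE_COLUMNS, ORGANS, StratumKey


def _records(rows):
    """Build an exam table from (sex, age_group, category, dose, patient_id)
    tuples; every organ gets the same dose."""
    data = []
    for i, (sex, group, cat, dose, pid) in enumerate(rows):
        row = {
            "exam_id": i, "patient_id": pid, "age_years": 30, "sex": sex,
            "age_group": group, "category": cat, "multiphase": False,
            "last_year_of_life": False, "excluded_reason": "none",
        }
        row.update({c: dose for c in DOSE_COLUMNS})
        data.append(row)
    return pd.DataFrame(data)


def _summary(sex, group, cat, proportion, n=100, dose=10.0):
    return StratumSummary(
        key=StratumKey(sex, group, cat),
        n_exams=n,
        proportion=proportion,
        dose_mean={o: dose for o in ORGANS},
        dose_sd={o: 0.0 for o in ORGANS},
    )


class TestSummarizeStrata:
    def test_single_stratum_identical_exams(self):
        rows = [("female", "30-39", "chest_routine", 10.0, i) for i in range(24)]
        out = summarize_strata(_records(rows))
        assert len(out) == 1
        s = out[0]
        assert s.n_exams == 24
        assert s.proportion == 1.0
        assert s.dose_mean["lung"] == pytest.approx(10.0)
        assert s.dose_sd["lung"] == 0.0

    def test_minimum_size_rule_drops_small_strata(self):
        """A stratum with 11 exams is dropped; proportions renormalize."""
        rows = [("female", "30-39", "chest_routine", 10.0, i) for i in range(11)]
        rows += [("female", "30-39", "head_routine", 5.0, 100 + i) for i in range(100)]
        out = summarize_strata(_records(rows))
        assert len(out) == 1
        assert out[0].key.category == "head_routine"
        assert out[0].proportion == 1.0

    def test_excluded_reasons_removed(self):
        df = _records(
            [("female", "30-39", "chest_routine", 10.0, i) for i in range(30)]
        )
        df.loc[:9, "excluded_reason"] = "pet"
        out = summarize_strata(df)
        assert out[0].n_exams == 20

    def test_all_excluded_raises(self):
        df = _records([("female", "30-39", "chest_routine", 10.0, 1)] * 15)
        df["excluded_reason"] = "research"
        with pytest.raises(ValueError, match="exclusion"):
            summarize_strata(df)

    def test_group_means_match_bruteforce_oracle(self):
        rng = np.random.default_rng(42)
        rows = []
        pid = 0
        for cat, n in (("chest_routine", 40), ("head_routine", 60)):
            for _ in range(n):
                rows.append(("male", "40-49", cat, float(rng.uniform(5, 50)), pid))
                pid += 1
        df = _records(rows)
        out = {s.key.category: s for s in summarize_strata(df)}
        assert sum(s.proportion for s in out.values()) == pytest.approx(1.0, abs=1e-12)
        for cat in ("chest_routine", "head_routine"):
            sub = df[df["category"] == cat]
            assert out[cat].dose_mean["lung"] == pytest.approx(
                sub["dose_lung_mGy"].mean()
            )
            assert out[cat].dose_sd["lung"] == pytest.approx(
                sub["dose_lung_mGy"].std(ddof=1)
            )

    def test_proportions_invariant_to_duplication(self):
        rows = [("female", "30-39", "chest_routine", 10.0, i) for i in range(20)]
        rows += [("female", "30-39", "head_routine", 8.0, 50 + i) for i in range(40)]
        df = _records(rows)
        once = {s.key: s.proportion for s in summarize_strata(df)}
        doubled = pd.concat([df, df.assign(exam_id=df["exam_id"] + 1000)],
                            ignore_index=True)
        twice = {s.key: s.proportion for s in summarize_strata(doubled)}
        assert once == twice


class TestExamsPerPatient:
    def test_every_patient_one_exam(self):
        df = _records([("female", "30-39", "chest_routine", 1.0, i) for i in range(20)])
        cells, overall = estimate_exams_per_patient(df)
        assert overall == 1.0
        assert cells[("female", "30-39")] == 1.0

    def test_simple_mean(self):
        df = _records([
            ("female", "30-39", "chest_routine", 1.0, 0),
            ("female", "30-39", "chest_routine", 1.0, 1),
            ("female", "30-39", "chest_routine", 1.0, 1),
        ])
        _, overall = estimate_exams_per_patient(df)
        assert overall == pytest.approx(1.5)

    def test_national_totals_give_mean_1_51(self):
        """93 million exams over 61.51 million patients -> 1.51/patient."""
        assert round(mean_exams_per_patient(93_000_000, 61_510_000), 2) == 1.51


class TestScaleToNational:
    def test_pediatric_share_allocation(self):
        """3.3% of 93 million examinations -> 3,069,000 in children."""
        summaries = [
            _summary("female", "5-9", "head_routine", 1.0),
            _summary("female", "40-49", "chest_routine", 1.0),
        ]
        counts = scale_to_national(summaries, 93_000_000, 0.033)
        t = counts.table
        child = t.loc[t["age_group"] == "5-9", "scaled_exams"].sum()
        assert child == 3_069_000
        assert t["scaled_exams"].sum() == 93_000_000

    def test_equal_split_adults(self):
        summaries = [
            _summary("female", "40-49", "chest_routine", 0.5),
            _summary("male", "40-49", "chest_routine", 0.5),
        ]
        counts = scale_to_national(summaries, 100, 0.0)
        assert sorted(counts.table["scaled_exams"]) == [50, 50]

    def test_conservation_arbitrary_proportions(self):
        rng = np.random.default_rng(0)
        props = rng.dirichlet(np.ones(9))
        cats = ["chest_routine", "head_routine", "abdomen_pelvis_routine"]
        groups = ["30-39", "50-59", "70-79"]
        summaries = [
            _summary("male", g, c, p)
            for p, (g, c) in zip(props, [(g, c) for g in groups for c in cats])
        ]
        counts = scale_to_national(summaries, 1_234_567, 0.0)
        assert counts.table["scaled_exams"].sum() == 1_234_567

    def test_pediatric_share_without_child_strata_errors(self):
        summaries = [_summary("female", "40-49", "chest_routine", 1.0)]
        with pytest.raises(ValueError, match="pediatric"):
            scale_to_national(summaries, 100, 0.05)

    def test_patient_totals_derived_from_epp(self):
        summaries = [_summary("female", "40-49", "chest_routine", 1.0)]
        counts = scale_to_national(
            summaries, 1500, 0.0, exams_per_patient={("female", "40-49"): 1.5}
        )
        assert counts.total_patients == pytest.approx(1000.0)


class TestEolExclusion:
    def _counts(self, spec):
        rows = [
            {"sex": s, "age_group": g, "category": c, "scaled_exams": n,
             "eol_excluded": 0, "included_exams": float(n)}
            for s, g, c, n in spec
        ]
        t = pd.DataFrame(rows)
        return NationalCounts(table=t, total_exams=int(t["scaled_exams"].sum()))

    def test_zero_map_changes_nothing(self):
        counts = self._counts([("female", "40-49", "chest_routine", 1000)])
        out = apply_eol_exclusion(counts, {("female", "40-49"): 0.0})
        assert out.table["included_exams"].iloc[0] == 1000

    def test_flat_fraction_arithmetic(self):
        """10.6% of 93 million -> 83,142,000 included examinations."""
        counts = self._counts([("female", "40-49", "chest_routine", 93_000_000)])
        out = apply_eol_exclusion(counts, {("female", "40-49"): 0.106})
        assert out.table["included_exams"].iloc[0] == 83_142_000

    def test_cell_specific_map_matches_weighted_average_oracle(self):
        spec = [
            ("female", "40-49", "chest_routine", 10_000),
            ("male", "70-79", "head_routine", 30_000),
            ("female", "5-9", "head_routine", 5_000),
        ]
        eol = {("female", "40-49"): 0.04, ("male", "70-79"): 0.20,
               ("female", "5-9"): 0.01}
        counts = self._counts(spec)
        out = apply_eol_exclusion(counts, eol)
        oracle = sum(n * eol[(s, g)] for s, g, _, n in spec)
        assert out.table["eol_excluded"].sum() == pytest.approx(oracle, abs=1.0)
        assert (out.table["included_exams"]
                == out.table["scaled_exams"] - out.table["eol_excluded"]).all()

    def test_missing_cell_names_it(self):
        counts = self._counts([("female", "40-49", "chest_routine", 100)])
        with pytest.raises(ValueError, match="40-49"):
            apply_eol_exclusion(counts, {("male", "40-49"): 0.1})


def test_largest_remainder_rounding_exact_total():
    rng = np.random.default_rng(1)
    for _ in range(20):
        w = rng.random(15)
        total = int(rng.integers(1, 10**6))
        out = largest_remainder_round(w, total)
        assert out.sum() == total
        assert (out >= 0).all()
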