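"""Transmission scoring: probabilities, likelihoods, standardization,
event classification and the brute-force scoring oracle."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from strainshare import snv_profiles as sp
from strainshare import transmission as tr


class TestPairProbabilities:
    @pytest.mark.parametrize(
        "f, expected",
        [
            (0.5, (0.25, 0.25, 0.25, 0.25)),
            (0.2, (0.04, 0.64, 0.16, 0.16)),
            (1.0, (1.0, 0.0, 0.0, 0.0)),
        ],
    )
    def test_product_model(self, f, expected):
        assert tr.pair_probabilities(f) == pytest.approx(expected)

    @given(st.floats(0.001, 0.999))
    def test_probabilities_sum_to_one(self, f):
        assert sum(tr.pair_probabilities(f)) == pytest.approx(1.0, abs=1e-9)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            tr.pair_probabilities(1.2)

    def test_literal_formulas_are_the_printed_differences(self):
        # the subtractive difference forms: provided for inspection, not valid
        # probabilities (p11 = f1 - f2 vanishes for equal incidences)
        p11, p00, p10, p01 = tr.pair_probabilities(0.3, formula="literal")
        assert p11 == pytest.approx(0.0)
        assert p10 == pytest.approx(0.3 - 0.7)

    def test_clamping_bounds(self):
        assert tr.clamp_incidence(0.0, 10) == pytest.approx(0.05)
        assert tr.clamp_incidence(1.0, 10) == pytest.approx(0.95)
        assert tr.clamp_incidence(0.5, 10) == pytest.approx(0.5)


class TestOverlapLikelihood:
    def test_all_agreement_at_symmetric_f(self):
        n = 7
        l_obs, l_min = tr.overlap_likelihood([(0, 0)] * n, [0.5] * n)
        assert l_obs == pytest.approx(n * math.log(0.25))
        assert l_min == pytest.approx(n * math.log(0.25))
        assert tr.raw_score(l_obs, l_min) == pytest.approx(1.0)

    def test_two_allele_worked_example(self):
        l_obs, l_min = tr.overlap_likelihood([(1, 1), (0, 1)], [0.2, 0.8])
        assert l_obs == pytest.approx(math.log(0.04) - math.log(0.16), abs=1e-9)
        assert l_min == pytest.approx(2 * math.log(0.04), abs=1e-9)
        assert tr.raw_score(l_obs, l_min) == pytest.approx(0.2154, abs=1e-4)

    def test_empty_comparison_rejected(self):
        with pytest.raises(ValueError):
            tr.overlap_likelihood([], [])

    def test_raw_score_requires_negative_l_min(self):
        with pytest.raises(ValueError):
            tr.raw_score(-1.0, 0.0)

    @pytest.mark.parametrize("l_obs, l_min, expected", [(-2.0, -2.0, 1.0), (0.0, -5.0, 0.0)])
    def test_raw_score_values(self, l_obs, l_min, expected):
        assert tr.raw_score(l_obs, l_min) == expected


class TestStandardize:
    def test_unit_spacing(self):
        assert tr.standardize([1.0, 2.0, 3.0]) == pytest.approx([-1.0, 0.0, 1.0])

    def test_worked_example(self):
        got = tr.standardize([0.1, 0.2, 0.2, 0.5])
        assert got == pytest.approx([-0.866, -0.289, -0.289, 1.443], abs=1e-3)

    def test_degenerate_spread_is_missing(self):
        assert np.isnan(tr.standardize([0.3, 0.3, 0.3])).all()

    @given(st.lists(st.floats(-5, 5), min_size=3, max_size=30, unique=True))
    def test_mean_zero_sd_one(self, values):
        z = tr.standardize(values)
        assert z.mean() == pytest.approx(0.0, abs=1e-9)
        assert z.std(ddof=1) == pytest.approx(1.0, rel=1e-9)


class TestClassifyEvent:
    def _meta(self, host, species, site):
        return {"host_id": host, "host_species": species, "gut_site": site}

    def test_three_types(self):
        goat_a_rumen = self._meta("gA", "goat", "rumen")
        goat_a_cecum = self._meta("gA", "goat", "cecum")
        goat_b_cecum = self._meta("gB", "goat", "cecum")
        pig_c_cecum = self._meta("pC", "pig", "cecum")
        assert tr.classify_event(goat_a_rumen, goat_a_cecum) == "foregut_hindgut"
        assert tr.classify_event(goat_a_cecum, goat_b_cecum) == "intra_species"
        assert tr.classify_event(goat_a_cecum, pig_c_cecum) == "inter_species"

    def test_same_host_same_site_rejected(self):
        m = self._meta("gA", "goat", "cecum")
        with pytest.raises(ValueError):
            tr.classify_event(m, m)


def _brute_force_scores(profiles, metadata, min_alleles=20):
    """Independent re-derivation of every scored pair: naive per-allele loops
    over the screened profiles, no matrix algebra shared with the package."""
    screened, _ = sp.presence_filter(profiles)
    by_strain = {}
    for p in screened:
        by_strain.setdefault(p.strain_id, []).append(p)
    pairs = tr.evaluated_pairs(metadata)
    rows = []
    for strain, plist in by_strain.items():
        prof = {p.sample_id: p for p in plist}
        # incidence: coverage-aware denominator
        alleles = sorted({al for p in plist for al in p.alleles})
        f_of = {}
        for al in alleles:
            pos = al[0]
            covering = [p for p in plist if pos in p.covered_positions]
            n_present = sum(al in p.alleles for p in covering)
            f_of[al] = n_present / len(covering)
        n_screen = len(plist)
        eps = 1 / (2 * n_screen)
        for r in pairs.itertuples():
            pa, pb = prof.get(r.sample_a), prof.get(r.sample_b)
            if pa is None or pb is None:
                continue
            evaluated = [
                al
                for al in alleles
                if al[0] in pa.covered_positions and al[0] in pb.covered_positions
            ]
            if len(evaluated) < min_alleles:
                continue
            l_obs = l_min = 0.0
            for al in evaluated:
                f = min(max(f_of[al], eps), 1 - eps)
                p11, p00, p10, p01 = f * f, (1 - f) ** 2, f * (1 - f), (1 - f) * f
                a, b = al in pa.alleles, al in pb.alleles
                if a and b:
                    l_obs += math.log(p11)
                elif not a and not b:
                    l_obs += math.log(p00)
                elif a:
                    l_obs -= math.log(p10)
                else:
                    l_obs -= math.log(p01)
                l_min += min(math.log(p11), math.log(p00))
            rows.append(
                {
                    "strain_id": strain,
                    "sample_a": r.sample_a,
                    "sample_b": r.sample_b,
                    "L_obs": l_obs,
                    "L_min": l_min,
                    "P_raw": l_obs / l_min,
                }
            )
    return pd.DataFrame(rows)


class TestScoringAgainstOracle:
    def test_matrix_path_matches_brute_force(self, small_study, small_profiles, small_scores):
        oracle = _brute_force_scores(small_profiles, small_study["metadata"])
        key = ["strain_id", "sample_a", "sample_b"]
        merged = small_scores.merge(oracle, on=key, suffixes=("", "_bf"))
        assert len(merged) == len(small_scores) == len(oracle)
        for col in ("L_obs", "L_min", "P_raw"):
            np.testing.assert_allclose(merged[col], merged[f"{col}_bf"], atol=1e-9)

    def test_symmetry_under_sample_swap(self):
        classes = [(1, 1), (0, 1), (1, 0), (0, 0)]
        swapped = [(b, a) for a, b in classes]
        f = [0.3, 0.6, 0.7, 0.2]
        assert tr.overlap_likelihood(classes, f) == pytest.approx(
            tr.overlap_likelihood(swapped, f)
        )

    def test_standardized_scores_have_mean_zero_sd_one(self, small_scores):
        for _, grp in small_scores.dropna(subset=["S_T"]).groupby("strain_id"):
            if len(grp) < 3:
                continue
            assert grp["S_T"].mean() == pytest.approx(0.0, abs=1e-9)
            assert grp["S_T"].std(ddof=1) == pytest.approx(1.0, rel=1e-9)


class TestDetectAndSummarize:
    def test_no_scores_above_threshold_no_events(self, small_scores, small_study):
        events = tr.detect_events(small_scores, small_study["metadata"], threshold=np.inf)
        assert events.empty

    def test_infinitely_low_threshold_calls_every_eligible_pair(
        self, small_scores, small_study
    ):
        events = tr.detect_events(small_scores, small_study["metadata"], threshold=-np.inf)
        eligible = small_scores[
            (small_scores["pair_role"] == "eligible") & small_scores["S_T"].notna()
        ]
        assert len(events) == len(eligible)

    def test_planted_pairs_beat_background_median(self, small_scores, small_study):
        truth = small_study["truth"].shared_pairs
        key = ["strain_id", "sample_a", "sample_b"]
        st_col = small_scores.set_index(key)["S_T"]
        planted = truth.merge(small_scores, on=key)["S_T"].dropna()
        background = small_scores[small_scores["pair_role"] == "background"]["S_T"].dropna()
        assert len(planted) > 10
        assert planted.median() > background.median()

    def test_summarize_events_partition(self):
        events = pd.DataFrame(
            {
                "strain_id": ["s1", "s1", "s2", "s3", "s3"],
                "sample_a": ["a"] * 5,
                "sample_b": ["b"] * 5,
                "S_T": [3.0] * 5,
                "event_type": [
                    "intra_species",
                    "inter_species",
                    "intra_species",
                    "foregut_hindgut",
                    "foregut_hindgut",
                ],
            }
        )
        got = tr.summarize_events(events, total_strains=10)
        assert got["transmitted_strains"] == 3
        assert got["transmitted_pct"] == 30.0
        assert got["only_intra_species"] == 1
        assert got["only_foregut_hindgut"] == 1
        assert got["multiple_types"] == 1
        assert (
            got["only_intra_species"]
            + got["only_inter_species"]
            + got["only_foregut_hindgut"]
            + got["multiple_types"]
            == got["transmitted_strains"]
        )

    def test_summarize_empty(self):
        events = pd.DataFrame(columns=["strain_id", "sample_a", "sample_b", "S_T", "event_type"])
        got = tr.summarize_events(events, total_strains=5)
        assert got["transmitted_strains"] == 0
        assert got["transmitted_pct"] == 0.0

    def test_transmitted_abundance_fraction(self):
        events = pd.DataFrame({"strain_id": ["s1"], "sample_a": ["a"], "sample_b": ["b"],
                               "S_T": [3.0], "event_type": ["intra_species"]})
        ab = pd.DataFrame({"x": [250_000.0, 750_000.0]}, index=["s1", "s2"])
        frac = tr.transmitted_abundance_fraction(events, ab)
        assert frac["x"] == pytest.approx(0.25)
        none = tr.transmitted_abundance_fraction(events.iloc[:0], ab)
        assert none["x"] == 0.0
        all_ev = pd.DataFrame({"strain_id": ["s1", "s2"], "sample_a": ["a"] * 2,
                               "sample_b": ["b"] * 2, "S_T": [3.0] * 2,
                               "event_type": ["intra_species"] * 2})
        assert tr.transmitted_abundance_fraction(all_ev, ab)["x"] == pytest.approx(1.0)
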