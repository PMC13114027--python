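"""Virtual cohort generator: structure, exactness, and effect-size algebra."""

import dataclasses
import math

import numpy as np
import pytest

from cochmap import (
    CochlearMeasurements,
    GeneratorConfig,
    GeometryConfig,
    cohort_to_frame,
    eca_cdl,
    generate_cohort,
    partial_correlation,
    solve_effect_size,
)
from cochmap.synthetic_cohort import MEASURES, TIMEPOINTS


class TestSolveEffectSize:
    def test_zero_target_gives_zero_coefficient(self):
        assert solve_effect_size(0.0, 1.0) == 0.0

    def test_headline_effect_size(self):
        """r = -0.52 with unit noise needs a coefficient of about -0.609."""
        gamma = solve_effect_size(-0.52, 1.0)
        assert gamma == pytest.approx(-0.609, abs=1e-3)
        # plugging back: population partial correlation equals the target
        assert gamma / math.hypot(gamma, 1.0) == pytest.approx(-0.52, abs=1e-12)

    def test_large_sample_recovery(self, rng):
        """At n = 1e5 the realized partial correlation matches the target."""
        n, target = 100_000, -0.52
        gamma = solve_effect_size(target, 1.0)
        z = rng.standard_normal((n, 2))
        mm = rng.standard_normal(n)
        y = z @ [-0.2, -0.2] + gamma * mm + rng.standard_normal(n)
        res = partial_correlation(mm, y, z)
        assert res.r == pytest.approx(target, abs=0.01)

    @pytest.mark.parametrize("r", [1.0, -1.0, 1.2])
    def test_infeasible_targets_rejected(self, r):
        with pytest.raises(ValueError):
            solve_effect_size(r, 1.0)


class TestCohortStructure:
    def test_counts_are_exact(self, default_cohort):
        assert len(default_cohort) == 44
        codes = [r.exclusion_code for r in default_cohort]
        assert codes.count("extracochlear") == 6
        assert codes.count("second_ci") == 3
        assert codes.count("none") == 35

    def test_analysis_subset_sex_split(self, default_cohort):
        sub = [r for r in default_cohort if r.exclusion_code == "none"]
        assert sum(r.sex == "male" for r in sub) == 15
        assert sum(r.sex == "female" for r in sub) == 20

    def test_attrition_exact_and_nested(self, default_cohort):
        sub = [r for r in default_cohort if r.exclusion_code == "none"]
        missing = {
            tp: {r.id for r in sub if math.isnan(r.scores[("consonant", tp)])}
            for tp in TIMEPOINTS
        }
        assert [len(sub) - len(missing[tp]) for tp in TIMEPOINTS] == [35, 33, 27]
        assert missing["3m"] <= missing["6m"] <= missing["12m"]
        # missingness hits every measure at a timepoint, not single cells
        for r in sub:
            for tp in TIMEPOINTS:
                flags = {math.isnan(r.scores[(m, tp)]) for m in MEASURES}
                assert len(flags) == 1

    def test_covariates_within_stated_ranges(self, default_cohort):
        for r in default_cohort:
            assert 21.0 <= r.age <= 89.0
            for key, score in r.scores.items():
                assert math.isnan(score) or 0.0 <= score <= 100.0

    def test_calipers_consistent_with_duct_length(self, default_cohort):
        """(A, B) are back-solved so the elliptic estimator reproduces the
        drawn CDL."""
        for r in default_cohort[:10]:
            m = CochlearMeasurements(A=r.A, B=r.B, sex=r.sex, side=r.side)
            assert eca_cdl(m, GeometryConfig()) == pytest.approx(r.cdl, rel=1e-9)

    def test_partial_insertions_marked_incomplete(self, default_cohort):
        for r in default_cohort:
            if r.exclusion_code == "extracochlear":
                assert not r.insertion_complete
            else:
                assert r.insertion_complete

    def test_same_seed_reproduces_identical_cohort(self):
        a = cohort_to_frame(generate_cohort(GeneratorConfig(seed=99)))
        b = cohort_to_frame(generate_cohort(GeneratorConfig(seed=99)))
        assert a.equals(b)

    def test_upstream_invariants_hold_across_draws(self):
        """Angles, coverage and the shallow-only mismatch direction hold in
        at least 99% of generated ears."""
        ok = total = 0
        for seed in range(20):
            for r in generate_cohort(GeneratorConfig(seed=seed)):
                total += 1
                ok += (
                    0.0 < r.aid_deg <= 900.0
                    and 0.0 < r.coverage_pct <= 100.0
                    and r.c6_place_hz > r.c6_center_hz
                    and r.mismatch_c6 >= 0.0
                )
        assert ok / total >= 0.99


class TestEffectStructure:
    def test_null_generator_gives_null_correlations(self):
        """With all effect targets at zero the estimated partial
        correlations scatter around zero."""
        cfg = GeneratorConfig(
            seed=0, target_r={k: 0.0 for k in GeneratorConfig().target_r}
        )
        rs = []
        for seed in range(100):
            recs = generate_cohort(dataclasses.replace(cfg, seed=seed))
            sub = [r for r in recs if r.exclusion_code == "none"]
            mm = np.array([r.mismatch_c6 for r in sub])
            y = np.array([r.scores[("consonant", "3m")] for r in sub])
            z = np.array([[r.age, r.pta] for r in sub])
            rs.append(partial_correlation(mm, y, z).r)
        assert abs(np.mean(rs)) < 0.05

    def test_sentence_ceiling_compresses_high_scores(self, default_cohort):
        sub = [r for r in default_cohort if r.exclusion_code == "none"]
        late = [r.scores[("sentence", "12m")] for r in sub]
        late = [s for s in late if not math.isnan(s)]
        assert sum(s > 80.0 for s in late) / len(late) > 0.3

    def test_infeasible_config_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            GeneratorConfig(target_r={("consonant", "3m"): 1.0})
        with pytest.raises(ValueError):
            GeneratorConfig(attrition=(35, 36, 27))
        with pytest.raises(ValueError):
            GeneratorConfig(n_male=10, n_female=29)
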