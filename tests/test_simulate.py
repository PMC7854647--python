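import numpy as np

from adta.pipeline import score_cohort
from adta.scoring import HIGH_RISK, LOW_RISK, score_image_with_membership
from adta.simulate import (
    SimConfig,
    expected_event_fraction,
    expected_positive_fraction,
    gen_cohort,
    gen_image,
    write_cohort,
)


def test_determinism_same_seed_identical_cohorts(tmp_path):
    """Identical config (seed included) yields byte-identical serialized
    cohorts; a different seed does not."""
    cfg = SimConfig(seed=11, n_patients=6)
    d1, d2, d3 = tmp_path / "a", tmp_path / "b", tmp_path / "c"
    write_cohort(gen_cohort(cfg), d1)
    write_cohort(gen_cohort(SimConfig(seed=11, n_patients=6)), d2)
    write_cohort(gen_cohort(SimConfig(seed=12, n_patients=6)), d3)
    files1 = sorted(p.relative_to(d1) for p in d1.rglob("*.csv"))
    assert files1 == sorted(p.relative_to(d2) for p in d2.rglob("*.csv"))
    for rel in files1:
        assert (d1 / rel).read_bytes() == (d2 / rel).read_bytes()
    assert (d1 / "clinical.csv").read_bytes() != (d3 / "clinical.csv").read_bytes()


class TestGenImage:
    def test_lambda_zero_limit(self, rng):
        """With no hot patches and a background component with ~zero mass
        above the threshold, scored values are ~0."""
        cfg = SimConfig(seed=0, grid_dims=(12, 12))
        vals = []
        for i in range(20):
            ips, _, in_tumor = gen_image(cfg, 0.0, rng, f"i{i}")
            vals.append(score_image_with_membership(ips, in_tumor).value)
        assert np.mean(vals) < 0.005

    def test_lambda_one_limit(self, rng):
        """All in-tumor patches hot, high component mass ~1 above the
        threshold: scores near 1."""
        cfg = SimConfig(seed=0, grid_dims=(12, 12), prob_mean_hot=0.97,
                        prob_noise=40.0)
        ips, _, in_tumor = gen_image(cfg, 1.0, rng, "i")
        assert score_image_with_membership(ips, in_tumor).value > 0.95

    def test_mean_score_matches_closed_form(self, rng):
        """Mean scored value over many images at fixed lambda lies within 3
        Monte-Carlo SEs of the closed-form expected positive fraction."""
        cfg = SimConfig(seed=0, grid_dims=(15, 15))
        for lam in (0.03, 0.15, 0.30):
            obs, exp = [], []
            for i in range(150):
                ips, _, in_tumor = gen_image(cfg, lam, rng, f"i{i}")
                obs.append(score_image_with_membership(ips, in_tumor).value)
                exp.append(expected_positive_fraction(cfg, lam, int(in_tumor.sum())))
            se = np.std(obs, ddof=1) / np.sqrt(len(obs))
            assert abs(np.mean(obs) - np.mean(exp)) < 3 * max(se, 1e-4)

    def test_coverage_bounds(self, rng):
        cfg = SimConfig(seed=0, grid_dims=(15, 15))
        for i in range(10):
            _, _, in_tumor = gen_image(cfg, 0.1, rng, f"i{i}")
            assert 0.30 <= in_tumor.mean() <= 0.90

    def test_monotone_in_lambda(self):
        """Mean scored value is non-decreasing over a lambda grid (paired
        seeds)."""
        cfg = SimConfig(seed=0, grid_dims=(12, 12))
        grid = [0.0, 0.05, 0.1, 0.2, 0.3, 0.45]
        means = []
        for lam in grid:
            rng = np.random.default_rng(99)  # paired: same stream per lambda
            vals = [
                score_image_with_membership(
                    *_ips_mem(gen_image(cfg, lam, rng, f"i{k}"))
                ).value
                for k in range(40)
            ]
            means.append(np.mean(vals))
        assert all(a <= b + 1e-12 for a, b in zip(means, means[1:]))


def _ips_mem(triple):
    ips, _, mem = triple
    return ips, mem


class TestGenCohort:
    def test_marginals(self, small_cohort):
        recs = [p.clinical for p in small_cohort.patients]
        assert len(recs) == 30
        assert all(r.followup_months > 0 for r in recs)
        assert all(r.til_grade in (0, 1, 2) for r in recs)
        assert {p.true_risk_class for p in small_cohort.patients} <= {
            HIGH_RISK, LOW_RISK
        }
        # true risk class consistent with expected score vs cutoff
        for p in small_cohort.patients:
            expect_high = p.true_expected_adta < small_cohort.config.risk_cutoff
            assert (p.true_risk_class == HIGH_RISK) == expect_high

    def test_event_fraction_matches_closed_form(self):
        """Cohort event fraction lies within 3 SEs of the per-patient
        closed-form exponential/uniform-censoring expectation."""
        cfg = SimConfig(seed=5, n_patients=400)
        cohort = gen_cohort(cfg)
        expected = []
        for p in cohort.patients:
            z = 1 if p.true_risk_class == HIGH_RISK else 0
            rate = cfg.baseline_hazard * np.exp(
                cfg.beta_risk * z
                + cfg.beta_depth * p.clinical.depth_mm
                + cfg.beta_ulc * p.clinical.ulceration
            )
            expected.append(expected_event_fraction(rate, cfg.censor_window_months))
        observed = np.mean([p.clinical.dss_event for p in cohort.patients])
        mu = np.mean(expected)
        se = np.sqrt(np.mean([e * (1 - e) for e in expected]) / len(expected))
        assert abs(observed - mu) < 3 * se

    def test_event_rate_in_stated_band(self):
        cohort = gen_cohort(SimConfig(seed=2, n_patients=500))
        ev = np.mean([p.clinical.dss_event for p in cohort.patients])
        assert 0.40 <= ev <= 0.55

    def test_scores_span_stated_range(self, small_cohort):
        vals = [s.adta for s in score_cohort(small_cohort)]
        assert min(vals) < 0.05 and max(vals) < 0.55
        assert any(v > 0.065 for v in vals) and any(v < 0.065 for v in vals)

    def test_ground_truth_frame(self, small_cohort):
        gt = small_cohort.ground_truth()
        assert set(gt.columns) == {
            "patient_id", "lambda", "true_expected_adta", "true_risk_class"
        }
        assert len(gt) == 30

    def test_image_index_partitions_images(self, small_cohort):
        index = small_cohort.image_index()
        n_images = sum(len(v) for v in index.mapping.values())
        assert n_images == sum(len(p.images) for p in small_cohort.patients)
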