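import numpy as np
import pytest

from adta.io import ClinicalRecord, ImagePatchSet, PatchRecord, TumorAnnotation
from adta.masking import TumorMask, patch_membership, rasterize
from adta.scoring import (
    HIGH_RISK,
    LOW_RISK,
    ImageScore,
    NoTumorPatchesError,
    ScoringConfig,
    derive_stage,
    score_image,
    score_image_with_membership,
    score_patient,
    t_stage_from_depth,
)

from conftest import random_star
from oracles import brute_force_image_score


def full_mask(n=300):
    return TumorMask("m", np.ones((n, n), dtype=np.uint8))


def patch_set(probs, patch_size=100):
    patches = [PatchRecord(i * patch_size, 0, p) for i, p in enumerate(probs)]
    return ImagePatchSet("im", patch_size, patches)


class TestScoreImage:
    def test_ratio_definition(self):
        ips = patch_set([0.9, 0.8, 0.1, 0.5])
        mask = full_mask(400)
        s = score_image(ips, mask, ScoringConfig())
        assert (s.n_total, s.n_pos) == (4, 2)
        assert s.value == 0.5

    @pytest.mark.parametrize(
        "rule,expected_pos", [("at_least", 1), ("strictly_above", 0)]
    )
    def test_boundary_rule_at_threshold(self, rule, expected_pos):
        ips = patch_set([0.775])
        s = score_image(ips, full_mask(), ScoringConfig(boundary_rule=rule))
        assert s.n_pos == expected_pos

    def test_no_tumor_patches_is_error(self):
        ips = patch_set([0.9])
        empty = TumorMask("e", np.zeros((300, 300), dtype=np.uint8))
        with pytest.raises(NoTumorPatchesError, match="no tumor patches"):
            score_image(ips, empty, ScoringConfig())

    def test_matches_brute_force_on_random_grids(self, rng):
        """Exhaustive per-patch oracle (ray-cast centre test + threshold
        loop) on random grids and polygons."""
        cfg = ScoringConfig()
        for _ in range(30):
            ps = 10
            gw, gh = int(rng.integers(3, 20)), int(rng.integers(3, 20))
            coords = [(x * ps, y * ps) for y in range(gh) for x in range(gw)]
            probs = rng.random(len(coords))
            ring = random_star(rng, gw * ps, gh * ps)
            ring = ring + [ring[0]]
            ann = TumorAnnotation("r", [(ring, [])])
            mask = rasterize(ann, gw * ps, gh * ps)
            ips = ImagePatchSet(
                "r", ps, [PatchRecord(x, y, p) for (x, y), p in zip(coords, probs)]
            )
            n_total, n_pos = brute_force_image_score(
                coords, probs, [ring], ps, cfg.positivity_threshold
            )
            if n_total == 0:
                with pytest.raises(NoTumorPatchesError):
                    score_image(ips, mask, cfg)
                continue
            s = score_image(ips, mask, cfg)
            assert (s.n_total, s.n_pos) == (n_total, n_pos)

    def test_monotone_in_threshold(self, rng):
        """The image score is non-increasing as the positivity threshold
        rises."""
        ips = patch_set(rng.random(50), patch_size=10)
        mask = full_mask(600)
        values = [
            score_image(ips, mask, ScoringConfig(positivity_threshold=t)).value
            for t in np.linspace(0.05, 0.95, 19)
        ]
        assert all(a >= b for a, b in zip(values, values[1:]))

    def test_out_of_mask_patches_never_change_score(self, rng):
        """Adding patches outside the tumor region leaves the score fixed."""
        probs = rng.random(9)
        ring = [(0.0, 0.0), (300.0, 0.0), (300.0, 300.0), (0.0, 300.0), (0.0, 0.0)]
        ann = TumorAnnotation("t", [(ring, [])])
        inside = [PatchRecord(x * 100, y * 100, p)
                  for (x, y), p in zip([(i % 3, i // 3) for i in range(9)], probs)]
        extra = [PatchRecord(1000 + 100 * i, 0, float(rng.random()))
                 for i in range(5)]
        cfg = ScoringConfig()
        base = score_image_with_membership(
            ImagePatchSet("t", 100, inside),
            patch_membership(ann, np.array([(p.x, p.y) for p in inside]), 100),
            cfg,
        )
        both = ImagePatchSet("t", 100, inside + extra)
        s = score_image_with_membership(
            both,
            patch_membership(ann, both.coords(), 100),
            cfg,
        )
        assert (s.n_total, s.n_pos) == (base.n_total, base.n_pos)


class TestScorePatient:
    @pytest.mark.parametrize(
        "values,expected",
        [([0.1, 0.3, 0.2], 0.2), ([0.1, 0.3], 0.2), ([0.07], 0.07)],
    )
    def test_median_aggregation(self, values, expected):
        images = [ImageScore(f"i{k}", 100, round(v * 100))
                  for k, v in enumerate(values)]
        ps = score_patient("P", images)
        assert ps.adta == pytest.approx(expected)

    def test_risk_direction_and_boundary(self):
        """Score at or above the cutoff means high infiltrate -> low risk."""
        cfg = ScoringConfig(risk_cutoff=0.065)
        at = score_patient("A", [ImageScore("i", 1000, 70)], cfg)   # 0.07
        below = score_patient("B", [ImageScore("i", 1000, 60)], cfg)  # 0.06
        exactly = score_patient("C", [ImageScore("i", 1000, 65)], cfg)
        assert at.risk_class == LOW_RISK
        assert below.risk_class == HIGH_RISK
        assert exactly.risk_class == LOW_RISK  # inclusive on low risk

    def test_permutation_invariance(self, rng):
        images = [ImageScore(f"i{k}", 200, int(rng.integers(0, 201)))
                  for k in range(7)]
        base = score_patient("P", images).adta
        for _ in range(5):
            perm = list(rng.permutation(len(images)))
            assert score_patient("P", [images[i] for i in perm]).adta == base

    def test_empty_image_list_is_error(self):
        with pytest.raises(ValueError, match="no scored images"):
            score_patient("P", [])


class TestDeriveStage:
    def rec(self, **kw):
        return ClinicalRecord(patient_id="X", dss_event=0, followup_months=10,
                              **kw)

    def test_node_positive_is_stage_three(self):
        assert derive_stage(self.rec(node_or_satellite_positive=1,
                                     depth_mm=0.5)) == 3

    @pytest.mark.parametrize("t,expected", [(2, 1), (6, 2), (3, 1), (4, 2)])
    def test_t_stage_split(self, t, expected):
        # T1b -> I, T3b -> II, T2a -> I, T2b -> II
        assert derive_stage(self.rec(node_or_satellite_positive=0,
                                     t_stage=t)) == expected

    def test_depth_fallback_and_missing(self):
        assert derive_stage(self.rec(node_or_satellite_positive=0,
                                     depth_mm=3.0, ulceration=1)) == 2
        assert derive_stage(self.rec()) is None

    @pytest.mark.parametrize(
        "depth,ulc,code",
        [(0.5, 0, 1), (0.5, 1, 2), (1.5, 0, 3), (3.0, 1, 6), (5.0, 0, 7)],
    )
    def test_t_stage_from_depth(self, depth, ulc, code):
        assert t_stage_from_depth(depth, ulc) == code
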