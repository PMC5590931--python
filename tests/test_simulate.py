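"""Synthetic study generator: determinism, calibration, effect sizes."""

import numpy as np
import pandas as pd
import pytest

from ozotox import (
    EffectProfile,
    StudyDesign,
    default_profile,
    gen_comet_cells,
    gen_mn_scores,
    gen_study,
    gen_viability,
    null_profile,
)
from ozotox.indices import MNScoreRecord, aggregate_mn, replication_index
from ozotox.simulate import _viability_targets


def records_from_frame(df):
    return [
        MNScoreRecord(**{k: row[k] for k in (
            "slide_id", "cell_line", "condition", "time_h", "n_mono", "n_bi",
            "n_tri", "n_tetra", "n_total", "n_bn_scored", "n_mn",
        )})
        for _, row in df.iterrows()
    ]


def pooled_ri(df, t):
    recs = records_from_frame(df[df.time_h == t])
    trt = aggregate_mn([r for r in recs if r.condition == "ozone"])
    ctl = aggregate_mn([r for r in recs if r.condition == "control"])
    return replication_index(trt, ctl)


class TestDeterminism:
    def test_identical_seed_identical_tables(self):
        d, p = StudyDesign(), default_profile("A549")
        for gen in (gen_viability, gen_mn_scores, gen_comet_cells):
            t1, t2 = gen(d, p, seed=42), gen(d, p, seed=42)
            pd.testing.assert_frame_equal(t1, t2)
            t3 = gen(d, p, seed=43)
            assert not t1.equals(t3)

    def test_bundle_deterministic(self):
        b1, b2 = gen_study("Hs27", seed=5), gen_study("Hs27", seed=5)
        for k in b1:
            pd.testing.assert_frame_equal(b1[k], b2[k])


class TestViability:
    def test_noiseless_means_hit_targets_exactly(self):
        d = StudyDesign()
        p = default_profile("A549")
        p = EffectProfile(**{**p.__dict__, "noise_cv": 0.0})
        df = gen_viability(d, p, seed=0)
        gm = df.groupby(["condition", "time_h"]).rlu.mean()
        targets = _viability_targets(d, p)
        for (cond, t), target in targets.items():
            assert gm[cond, t] == pytest.approx(target, rel=1e-12)

    def test_printed_effect_sizes_with_noise(self):
        # mean of group means over seeds is unbiased for the targets
        deltas, drops_c, drops_t = [], [], []
        d, p = StudyDesign(), default_profile("A549")
        for seed in range(20):
            gm = gen_viability(d, p, seed).groupby(["condition", "time_h"]).rlu.mean()
            deltas.append((gm["ozone", 24] / gm["control", 24] - 1) * 100)
            drops_c.append((1 - gm["control", 72] / gm["control", 48]) * 100)
            drops_t.append((1 - gm["ozone", 72] / gm["ozone", 48]) * 100)
        assert np.mean(deltas) == pytest.approx(-21.5, abs=1.5)
        assert np.mean(drops_c) == pytest.approx(50.0, abs=2.0)
        assert np.mean(drops_t) == pytest.approx(26.0, abs=2.5)

    def test_impossible_profile_rejected(self):
        p = default_profile("A549")
        with pytest.raises(ValueError):
            EffectProfile(**{
                **p.__dict__,
                "viability_deficit_by_time": {24.0: 1.5},
            })


class TestMnScores:
    def test_null_profile_ri_near_100(self):
        d = StudyDesign()
        p = null_profile("A549")
        ris = [pooled_ri(gen_mn_scores(d, p, s), 48.0) for s in range(30)]
        assert np.mean(ris) == pytest.approx(100.0, abs=1.5)

    def test_default_ri_deficit_calibrated(self):
        d, p = StudyDesign(), default_profile("A549")
        ris = [pooled_ri(gen_mn_scores(d, p, s), 48.0) for s in range(50)]
        assert 87.0 <= np.mean(ris) <= 91.0  # expectation 89

    def test_mn_fold_near_two(self):
        d, p = StudyDesign(), default_profile("A549")
        folds = []
        for s in range(30):
            df = gen_mn_scores(d, p, s)
            at48 = df[df.time_h == 48.0]
            mn = at48.groupby("condition").apply(
                lambda g: g.n_mn.sum() / g.n_bn_scored.sum(), include_groups=False
            )
            folds.append(mn["ozone"] / mn["control"])
        assert np.mean(folds) == pytest.approx(2.0, abs=0.25)

    def test_rows_satisfy_record_invariants(self):
        df = gen_mn_scores(StudyDesign(), default_profile("A549"), seed=3)
        records_from_frame(df)  # would raise on violation
        assert (df.n_bn_scored == 1000).all()

    def test_excessive_fold_rejected(self):
        d, p = StudyDesign(), default_profile("A549")
        bad = EffectProfile(**{**p.__dict__, "mn_fold": {48.0: 1000.0, 72.0: 1.0},
                               "mn_base_rate_per_1000": 12.5})
        with pytest.raises(ValueError, match="ceiling"):
            gen_mn_scores(d, bad, seed=0)


class TestCometCells:
    def test_group_means_near_targets(self):
        d, p = StudyDesign(), default_profile("A549")
        df = gen_comet_cells(d, p, seed=0)
        df["otm"] = df.tail_dna_pct * df.centroid_distance / 100.0
        g = df[df.time_h == 48.0].groupby("condition")
        m = g[["tail_dna_pct", "otm"]].mean()
        n = g.size().iloc[0]
        for cond, (pct_t, otm_t) in ((c, p.comet_means[(48.0, c)])
                                     for c in ("control", "ozone")):
            se_pct = g.tail_dna_pct.std()[cond] / np.sqrt(n)
            se_otm = g.otm.std()[cond] / np.sqrt(n)
            assert abs(m.tail_dna_pct[cond] - pct_t) < 2.5 * se_pct
            assert abs(m.otm[cond] - otm_t) < 2.5 * se_otm

    def test_cells_per_slide_and_invariants(self):
        d = StudyDesign()
        df = gen_comet_cells(d, default_profile("Hs27"), seed=1)
        per_slide = df.groupby("slide_id").size()
        assert (per_slide == d.cells_per_slide).all()
        assert df.tail_dna_pct.between(0, 100).all()
        assert (df.tail_length >= 0).all() and (df.centroid_distance >= 0).all()

    def test_zero_damage_profile(self):
        p = default_profile("A549")
        zero = EffectProfile(**{
            **p.__dict__,
            "comet_means": {(t, c): (0.0, 0.0) for t in (48.0, 72.0)
                            for c in ("control", "ozone")},
        })
        df = gen_comet_cells(StudyDesign(), zero, seed=0)
        assert (df.tail_dna_pct == 0).all()
        assert (df.tail_dna_pct * df.centroid_distance == 0).all()


class TestDesign:
    def test_replicate_floor(self):
        with pytest.raises(ValueError, match="replicates"):
            StudyDesign(n_replicates=2)

    def test_unknown_cell_line_profile(self):
        with pytest.raises(ValueError):
            default_profile("HeLa")
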