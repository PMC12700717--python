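"""Synthetic study generator: determinism, planted structure, moments."""

import numpy as np
import pandas as pd
import pytest

from sonotx.synthetic import (BIOMARKER_DIRECTIONS, HUB_MIRNAS, TARGET_GENES,
                              StudyConfig, gen_clinical, gen_expression,
                              gen_images, gen_interactions, gen_tics)


def tiny_cfg(**kw):
    base = dict(n_healthy=3, n_T2c=4, n_T3b=3, image_size=32, n_mrna=120,
                n_mirna=60, n_planted_de=5, seed=1)
    base.update(kw)
    return StudyConfig(**base)


class TestConfig:
    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            StudyConfig(n_healthy=0)
        with pytest.raises(ValueError):
            StudyConfig(image_size=30)
        with pytest.raises(ValueError):
            StudyConfig(nb_dispersion=0.0)

    def test_cohort_defaults_mirror_study(self):
        cfg = StudyConfig()
        assert (cfg.n_healthy, cfg.n_T2c, cfg.n_T3b) == (22, 35, 13)


class TestImages:
    def test_one_pair_per_subject_and_roi_size(self):
        cfg = tiny_cfg()
        ims = gen_images(cfg)
        assert len(ims) == 2 * 10
        assert all(im.mask.sum() >= 100 for im in ims)
        assert {im.modality for im in ims} == {"Bmode", "CEUS-peak"}

    def test_seed_determinism_bit_identical(self):
        a = gen_images(tiny_cfg())
        b = gen_images(tiny_cfg())
        assert all(np.array_equal(x.image, y.image) for x, y in zip(a, b))

    def test_contrast_shifts_roi_texture(self):
        """At a strong planted contrast, at least one texture feature
        separates T2c from T3b sharply."""
        from scipy import stats
        from sonotx.texture import extract_all
        cfg = StudyConfig(n_healthy=1, n_T2c=10, n_T3b=10, image_size=64,
                          texture_contrast=2.0, seed=0)
        rows, grp = [], []
        for im in gen_images(cfg):
            if im.modality == "Bmode" and im.group != "healthy":
                rows.append(extract_all(im.image, im.mask))
                grp.append(im.group)
        df = pd.DataFrame(rows)
        grp = np.array(grp)
        p = stats.ttest_ind(df[grp == "T2c"], df[grp == "T3b"],
                            equal_var=False).pvalue
        assert np.nanmin(p) < 0.01


class TestTics:
    def test_truth_returned_and_noise_free_exact(self):
        cfg = tiny_cfg(tic_noise_sd=0.0)
        tics, truth = gen_tics(cfg)
        sid = list(tics)[0]
        a, b = truth.loc[sid, ["A", "beta"]]
        expect = a * (1 - np.exp(-b * tics[sid].t))
        assert np.allclose(tics[sid].intensity, expect)
        assert tics[sid].intensity[0] == 0.0

    def test_seed_determinism(self):
        t1, _ = gen_tics(tiny_cfg())
        t2, _ = gen_tics(tiny_cfg())
        sid = list(t1)[0]
        assert np.array_equal(t1[sid].intensity, t2[sid].intensity)


class TestExpression:
    def test_seed_determinism(self):
        m1, mi1, _ = gen_expression(tiny_cfg())
        m2, mi2, _ = gen_expression(tiny_cfg())
        assert m1.equals(m2) and mi1.equals(mi2)

    def test_truth_table_labels_every_planted_effect(self):
        cfg = tiny_cfg()
        _, _, truth = gen_expression(cfg)
        effects = truth["effect"].value_counts()
        assert effects["biomarker"] == 6
        # mRNA plants n_planted_de per stage, miRNA a third of that
        per_stage = cfg.n_planted_de + max(cfg.n_planted_de // 3, 1)
        assert effects["T2c_specific"] == per_stage
        assert effects["T3b_specific"] == per_stage
        assert effects["monotone_dec"] >= 9
        assert effects["monotone_inc"] >= 4
        assert truth["feature"].is_unique

    def test_biomarker_group_means_follow_directions(self):
        cfg = StudyConfig(n_healthy=4, n_T2c=60, n_T3b=60, seed=2,
                          n_mrna=120, n_mirna=60, n_planted_de=5)
        mrna, mirna, _ = gen_expression(cfg)
        g = cfg.subjects()["group"]
        both = pd.concat([mrna, mirna])
        m2 = both[g.index[g == "T2c"]].mean(axis=1)
        m3 = both[g.index[g == "T3b"]].mean(axis=1)
        for name, d in BIOMARKER_DIRECTIONS.items():
            if d == "up":
                assert m3[name] > m2[name], name
            else:
                assert m3[name] < m2[name], name

    def test_overplanting_rejected(self):
        with pytest.raises(ValueError):
            gen_expression(tiny_cfg(n_planted_de=100))


class TestClinical:
    def test_large_sample_matches_published_moments(self):
        cfg = StudyConfig(n_healthy=1, n_T2c=10000, n_T3b=1, seed=3)
        clin = gen_clinical(cfg)
        age = clin.loc[clin["group"] == "T2c", "age"]
        se = 7.90 / np.sqrt(len(age))
        assert abs(age.mean() - 70.11) < 3 * se

    def test_all_positive_and_determinism(self):
        c1 = gen_clinical(tiny_cfg())
        c2 = gen_clinical(tiny_cfg())
        assert c1.equals(c2)
        for col in ("age", "tPSA", "fPSA_ratio", "trus_volume", "psa_density"):
            assert (c1[col] > 0).all()

    def test_gleason_categories_by_group(self):
        clin = gen_clinical(StudyConfig(seed=4))
        assert (clin.loc[clin["group"] == "healthy", "gleason"] == "none").all()
        tumor = clin.loc[clin["group"] != "healthy", "gleason"]
        assert set(tumor) <= {"3+3", "3+4", "4+3", ">=8"}


class TestInteractions:
    def test_planted_hub_structure(self):
        edges = gen_interactions(tiny_cfg())
        deg = edges[edges["mirna"].isin(HUB_MIRNAS)].groupby("mirna").size()
        assert sorted(deg.tolist(), reverse=True) == [3, 2, 2, 2]
        covered = set(edges[edges["mirna"].isin(HUB_MIRNAS)]["gene"])
        assert covered == set(TARGET_GENES)

    def test_top_four_by_degree_are_hubs(self):
        edges = gen_interactions(tiny_cfg())
        deg = edges.groupby("mirna").size().sort_values(ascending=False)
        assert set(deg.index[:4]) == set(HUB_MIRNAS)

    def test_seed_determinism(self):
        assert gen_interactions(tiny_cfg()).equals(gen_interactions(tiny_cfg()))


def test_null_config_has_no_planted_signal(small_study):
    """With all effect sizes zero the biomarker filter passes ~nothing."""
    from sonotx.expression import de_test, biomarker_filter
    from sonotx.synthetic import BIOMARKER_MRNAS
    cfg = StudyConfig(de_log2fc=0.0, texture_contrast=0.0, seed=6,
                      n_mrna=200, n_mirna=60, n_planted_de=5)
    mrna, _, _ = gen_expression(cfg)
    g = cfg.subjects()["group"]
    res = de_test(mrna, list(g.index[g == "T2c"]), list(g.index[g == "T3b"]))
    out = biomarker_filter(res, list(BIOMARKER_MRNAS))
    assert len(out) <= 1
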