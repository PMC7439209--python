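"""Generator contracts: determinism, anatomy, null symmetry, injected effects."""

import numpy as np
import pandas as pd
import pytest

import hemimorph as hm
from hemimorph.synthetic_cohort import ConfigurationError

from conftest import TINY_REGIONS


def small_config(**kw):
    base = dict(n_female=2, n_male=2, n_regions_per_hemisphere=3,
                vertices_per_region=60, region_names=("REC", "TPOmid", "SPG"),
                seed=3)
    base.update(kw)
    return hm.GeneratorConfig(**base)


class TestSurface:
    def test_default_config_yields_78_labeled_regions(self, default_template):
        by_hemi = default_template.groupby("hemisphere")["region"].nunique()
        assert by_hemi["L"] == 39 and by_hemi["R"] == 39
        assert default_template.groupby(["hemisphere", "region"]).ngroups == 78

    def test_same_seed_reproduces_identical_tables(self):
        cfg = small_config()
        a = hm.generate_surface(cfg)
        b = hm.generate_surface(cfg)
        pd.testing.assert_frame_equal(a, b)
        ta, _ = hm.generate_cohort(a, cfg)
        tb, _ = hm.generate_cohort(b, cfg)
        for x, y in zip(ta, tb):
            pd.testing.assert_frame_equal(x, y)

    def test_single_region_degenerate_partition(self):
        cfg = hm.GeneratorConfig(n_regions_per_hemisphere=1,
                                 vertices_per_region=100,
                                 region_names=("REC",), seed=0)
        tpl = hm.generate_surface(cfg)
        for hemi in ("L", "R"):
            assert (tpl.loc[tpl.hemisphere == hemi, "region"] == "REC").all()

    def test_coordinates_unit_norm(self, tiny_template):
        norms = np.linalg.norm(tiny_template[["x", "y", "z"]].to_numpy(), axis=1)
        assert np.allclose(norms, 1.0, atol=1e-6)

    def test_hemispheres_disjoint_vertex_ids(self, tiny_template):
        left = set(tiny_template.loc[tiny_template.hemisphere == "L", "vertex_id"])
        right = set(tiny_template.loc[tiny_template.hemisphere == "R", "vertex_id"])
        assert not left & right


class TestCohort:
    def test_manifest_matches_study_composition(self):
        cfg = small_config(n_female=150, n_male=135, vertices_per_region=8,
                           within_region_sd=0.3, field_sd=0.0)
        tpl = hm.generate_surface(cfg)
        tables, manifest = hm.generate_cohort(tpl, cfg)
        assert len(manifest) == 285
        assert (manifest.gender == "F").sum() == 150
        assert (manifest.gender == "M").sum() == 135
        assert manifest.subject_id.is_unique
        assert manifest.age.between(22, 36).all()
        assert (manifest.handedness >= 50).all()
        assert len(tables) == 285

    def test_thickness_positive_and_region_parameterized(self, tiny_cohort):
        tables, _ = tiny_cohort
        for t in tables:
            assert (t.thickness > 0).all()

    def test_unknown_effect_region_rejected(self):
        cfg = small_config(effect_specs=(hm.EffectSpec("nope", "L", "F", 0.5),))
        with pytest.raises(ConfigurationError, match="unknown region"):
            cfg.validate()

    def test_handedness_below_filter_rejected(self):
        with pytest.raises(ConfigurationError):
            small_config(handedness_min=40).validate()

    def test_injected_mean_shift_recovered_at_large_n(self):
        """A +0.5 mm left-TPOmid shift in females moves the L-R sample-mean
        difference of that region by ~0.5 mm in the female group average."""
        eff = (hm.EffectSpec("TPOmid", "L", "F", dmean=0.5),)
        cfg = small_config(n_female=400, n_male=0, effect_specs=eff, seed=2)
        tpl = hm.generate_surface(cfg)
        tables, _ = hm.generate_cohort(tpl, cfg)
        diffs = []
        for t in tables:
            sel = t[t.region == "TPOmid"]
            diffs.append(sel.loc[sel.hemisphere == "L", "thickness"].mean()
                         - sel.loc[sel.hemisphere == "R", "thickness"].mean())
        assert abs(np.mean(diffs) - 0.5) < 0.08

    def test_null_generator_ai_sign_balanced(self):
        """With no injected effects, a downstream asymmetry index (here of
        regional mean thickness) is symmetric about zero across subjects."""
        cfg = small_config(n_female=100, n_male=100, seed=9)
        tpl = hm.generate_surface(cfg)
        tables, _ = hm.generate_cohort(tpl, cfg)
        ais = []
        for t in tables:
            g = t.groupby(["hemisphere", "region"])["thickness"].mean()
            for region in ("REC", "TPOmid", "SPG"):
                ais.append(hm.asymmetry_index(g["L", region], g["R", region]))
        frac_pos = np.mean(np.asarray(ais) > 0)
        # 600 signs, 99% binomial band around 0.5
        assert 0.5 - 2.576 * 0.5 / np.sqrt(len(ais)) < frac_pos \
            < 0.5 + 2.576 * 0.5 / np.sqrt(len(ais))

    def test_effect_monotonicity_in_degree_asymmetry(self):
        """Stronger injected spread inflation in right TPOmid yields a
        monotonically larger expected leftward degree asymmetry."""
        from hemimorph.pipeline import PipelineConfig, cohort_analysis
        mean_ai = []
        for scale in (1.0, 2.5, 5.0):
            eff = (hm.EffectSpec("TPOmid", "R", "F", sd_scale=scale),)
            gen = hm.GeneratorConfig(
                n_female=12, n_male=0, n_regions_per_hemisphere=6,
                vertices_per_region=150, region_names=TINY_REGIONS,
                seed=21, anatomy_seed=0, effect_specs=eff)
            cfg = PipelineConfig(generator=gen, randomization=None,
                                 target_per_hemisphere=24, seed=21)
            tpl = hm.generate_surface(gen)
            tables, man = hm.generate_cohort(tpl, gen)
            parc = hm.upsample(tpl, seed=0, target_per_hemisphere=24)
            res = cohort_analysis(tables, man, parc, cfg)
            ai = res["ai"]
            sel = ai[(ai.scope == "region") & (ai.region == "TPOmid")
                     & (ai.metric == "degree")]
            mean_ai.append(sel.ai.mean())
        assert mean_ai[0] < mean_ai[1] < mean_ai[2]
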