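import numpy as np
import pandas as pd
import pytest

from absp.phantom import (
    DegenerateGeometryError,
    GroupSignature,
    PhantomSpec,
    build_template_geometry,
    default_signatures,
    generate_cohort,
    synthesize_subject,
)
from absp.topography import fit_quadrants
from conftest import measure_truth_subject


class TestTemplateGeometry:
    def test_structure_containment(self, template):
        for side in ("L", "R"):
            snc = template.iron_masks[("SNc", side)].data
            sn = template.iron_masks[("SN", side)].data
            bs = template.iron_masks[("brainstem", "both")].data
            assert not (snc & ~sn).any(), "SNc must lie inside SN"
            assert not (sn & ~bs).any(), "SN must lie inside the brainstem"
            assert not (template.iron_masks[("RN", side)].data & sn).any()
        bs_nm = template.nm_masks[("brainstem", "both")].data
        for side in ("L", "R"):
            assert not (template.nm_masks[("LC", side)].data & ~bs_nm).any()

    def test_left_right_volume_ratio_matches_asymmetry(self, noiseless_spec):
        tpl = build_template_geometry(noiseless_spec, asymmetry=1.10)
        ratio = (
            tpl.nm_masks[("SNc", "L")].n_voxels / tpl.nm_masks[("SNc", "R")].n_voxels
        )
        assert ratio == pytest.approx(1.10, rel=0.05)

    def test_coarse_spacing_rejected_for_lc(self):
        spec = PhantomSpec(nm_spacing=(1.5, 1.5, 1.5))
        with pytest.raises(DegenerateGeometryError):
            build_template_geometry(spec)


class TestSubjectSynthesis:
    def test_noiseless_cr_recovered_exactly(self, hc_subject):
        measured = measure_truth_subject(hc_subject).set_index(
            ["sequence", "structure", "side"]
        )
        truth = hc_subject.truth_measures.set_index(["sequence", "structure", "side"])
        joined = measured.join(truth[["cr_true"]])
        # float32 volume storage bounds the attainable precision
        assert (joined["cr"] - joined["cr_true"]).abs().max() < 1e-6

    def test_quadrant_loss_concentrates_where_prescribed(self, signatures):
        # zero deformation so the subject's pre-erosion SNc is the template's
        spec = PhantomSpec(noise_sd=0.0, deform_amplitude=0.0, rng_seed=0)
        template = build_template_geometry(spec)
        sig = signatures["iPD"]  # loss weighted onto Q1 (ventral) and Q2 (lateral)
        subj = synthesize_subject(template, sig, spec, 21)
        for side in ("L", "R"):
            full = template.nm_masks[("SNc", side)]
            part = fit_quadrants(full)
            eroded = subj.truth_masks[("NM", "SNc", side)]
            # compare voxel loss per quadrant of the template frame
            lost = full.data & ~eroded.data
            labels = part.labels
            loss_q = [np.sum(lost & (labels == q)) for q in (1, 2, 3, 4)]
            assert loss_q[0] + loss_q[1] > loss_q[2] + loss_q[3]

    def test_same_seed_is_bit_identical(self, template, signatures):
        spec = PhantomSpec(noise_sd=2.0, deform_amplitude=0.5)
        a = synthesize_subject(template, signatures["HC"], spec, 42)
        b = synthesize_subject(template, signatures["HC"], spec, 42)
        assert np.array_equal(a.nm_volume.data, b.nm_volume.data)
        assert np.array_equal(a.iron_volume.data, b.iron_volume.data)
        assert a.truth_measures.equals(b.truth_measures)

    def test_emptying_volume_scale_rejected(self, template, noiseless_spec):
        sig = GroupSignature(group="HC", lc_nm_vol_scale=1e-3)
        with pytest.raises(DegenerateGeometryError):
            synthesize_subject(template, sig, noiseless_spec, 1)

    def test_more_iron_contrast_darkens_sn(self, template, noiseless_spec):
        lo = GroupSignature(group="HC", snc_iron_cr=0.05)
        hi = GroupSignature(group="HC", snc_iron_cr=0.25)
        a = synthesize_subject(template, lo, noiseless_spec, 3)
        b = synthesize_subject(template, hi, noiseless_spec, 3)
        mask = a.truth_masks[("iron", "SN", "L")]
        assert (
            b.iron_volume.data[b.truth_masks[("iron", "SN", "L")].data].mean()
            < a.iron_volume.data[mask.data].mean()
        )


class TestCohort:
    def test_cohort_counts_and_files(self, tmp_path):
        spec = PhantomSpec(n_per_group=2, rng_seed=5)
        subjects, truth, cov = generate_cohort(
            spec, default_signatures(), out_dir=tmp_path
        )
        assert len(subjects) == 6
        assert len(list(tmp_path.glob("*_nm.nii.gz"))) == 6
        assert len(list(tmp_path.glob("*_iron.nii.gz"))) == 6
        assert cov.shape[0] == 6
        assert set(truth["subject_id"].unique()) == {s.subject_id for s in subjects}
        assert (tmp_path / "truth.csv").exists()

    def test_zero_deformation_shares_template_anatomy(self):
        spec = PhantomSpec(
            n_per_group=2, rng_seed=9, deform_amplitude=0.0, noise_sd=0.0,
            scale_sd=0.0, cr_sd=0.0, snc_effect_d=0.0, gm_volume_sd=0.0,
            inter_seq_rotation_deg=0.0, inter_seq_translation_mm=0.0,
        )
        sig = {"HC": default_signatures()["HC"]}
        subjects, _, _ = generate_cohort(spec, sig)
        a, b = subjects
        for key in a.truth_masks:
            assert np.array_equal(a.truth_masks[key].data, b.truth_masks[key].data)

    def test_prescribed_effect_size_realised(self):
        """HC-vs-PD standardized difference of true SNc nVol tracks the
        planning effect size (within Monte-Carlo sampling error)."""
        spec = PhantomSpec(n_per_group=80, rng_seed=11)
        _, truth, _ = generate_cohort(spec, default_signatures(), truth_only=True)
        t = truth[
            (truth.structure == "SNc")
            & (truth.sequence == "NM")
            & (truth.side == "both")
        ]
        hc = t[t.group == "HC"].nvol_true.to_numpy()
        pd_arm = t[t.group != "HC"].nvol_true.to_numpy()
        d = (hc.mean() - pd_arm.mean()) / np.sqrt(
            (hc.var(ddof=1) + pd_arm.var(ddof=1)) / 2
        )
        # 3 SE(d) at these arm sizes is about 0.45
        assert d == pytest.approx(1.20, abs=0.45)

    def test_fast_truth_sampler_matches_prescribed_effect(self):
        """The analytic truth sampler realises the planning effect size
        tightly at large n (it shares the full synthesizer's draws but
        skips per-subject voxelization)."""
        from absp.phantom import sample_truth_nvols

        t = sample_truth_nvols(PhantomSpec(rng_seed=5), n_per_group=20_000)
        hc = t[t.group == "HC"]["nvol_true"].to_numpy()
        pd_arm = t[t.group != "HC"]["nvol_true"].to_numpy()
        d = (hc.mean() - pd_arm.mean()) / np.sqrt(
            (hc.var(ddof=1) + pd_arm.var(ddof=1)) / 2
        )
        assert d == pytest.approx(1.20, abs=0.05)
        ipd = t[t.group == "iPD"]["nvol_true"].mean()
        assert 100 * (1 - ipd / hc.mean()) == pytest.approx(25.0, abs=1.5)

    def test_truth_asymmetry_ratio(self):
        spec = PhantomSpec(n_per_group=12, rng_seed=3)
        _, truth, _ = generate_cohort(spec, default_signatures(), truth_only=True)
        t = truth[(truth.structure == "SNc") & (truth.sequence == "NM")]
        wide = t.pivot_table(index="subject_id", columns="side", values="nvol_true")
        assert (wide["L"] / wide["R"]).mean() == pytest.approx(1.10, abs=0.04)
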