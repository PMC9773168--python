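"""Phantom generator: exact ground truth, determinism, parameter recovery."""

import dataclasses

import numpy as np
import pytest

from cinestrain.geometry import polygon_area, polygon_perimeter
from cinestrain.pipeline import measure_stack
from cinestrain.strain import allocate_regions, strain_curve
from cinestrain.synthetic import (
    AcquisitionParams,
    CohortConfig,
    ConfigurationError,
    DegenerateGeometryError,
    GroupSpec,
    activation_profile,
    all_groups,
    analytic_ed_volume_ml,
    default_distributions,
    ellipsoid_radius_profile,
    generate_cohort,
    sample_subject,
    synthesize_cine,
)


def test_twelve_distinct_groups():
    groups = all_groups()
    assert len(groups) == 12
    assert len(set(groups)) == 12


def test_sample_subject_deterministic(healthy_group, distributions):
    d = distributions[("healthy", "55-64")]
    a = sample_subject(healthy_group, d, rng_seed=11)
    b = sample_subject(healthy_group, d, rng_seed=11)
    assert a == b


def test_sampled_attributes_respect_inclusion_windows(healthy_group, distributions):
    d = distributions[("healthy", "55-64")]
    for seed in range(40):
        s = sample_subject(healthy_group, d, rng_seed=seed)
        assert 55.0 <= s.age <= 64.0
        assert 18.5 <= s.bmi <= 30.0
        # derived height is consistent with BMI = weight / height²
        assert s.weight_kg / (s.height_cm / 100.0) ** 2 == pytest.approx(s.bmi, abs=0.1)
        for c in (s.c_base, s.c_mid, s.c_apex):
            assert 0.0 < c < 1.0


def test_uniform_contraction_mode(healthy_group, distributions):
    d = dataclasses.replace(distributions[("healthy", "55-64")], contraction_mode="uniform")
    s = sample_subject(healthy_group, d, rng_seed=5)
    assert s.c_base == s.c_mid == s.c_apex


def test_contraction_deficit_halves_affected_region(distributions):
    group = GroupSpec("male", "65-74", "unhealthy")
    base = distributions[("unhealthy", "65-74")]
    modified = dataclasses.replace(base, contraction_deficit=0.5, deficit_region="mid")
    s_ref = sample_subject(group, base, rng_seed=9)
    s_mod = sample_subject(group, modified, rng_seed=9)
    assert s_mod.c_mid == pytest.approx(0.5 * s_ref.c_mid)
    assert s_mod.c_base == s_ref.c_base
    assert s_mod.c_apex == s_ref.c_apex


def test_activation_profile_shape():
    w = activation_profile(25, 0.4)
    assert w[0] == 0.0 and w[-1] == 0.0
    assert w.max() == 1.0
    t_es = int(np.argmax(w))
    assert t_es == round(0.4 * 24)
    assert np.all(np.diff(w[: t_es + 1]) >= 0)
    assert np.all(np.diff(w[t_es:]) <= 0)


def test_clean_phantom_strain_is_exact(subject, clean_stack):
    """With jitter off, every slice's peak perimeter strain equals −c_region
    to machine precision (perimeter scales linearly with radius)."""
    alloc = allocate_regions(clean_stack.n_slices)
    c_expected = {"base": subject.c_base, "mid": subject.c_mid, "apex": subject.c_apex}
    for region, rng_idx in alloc.slice_ranges().items():
        for s in rng_idx:
            perims = [polygon_perimeter(c) for c in clean_stack.contours[s]]
            curve = strain_curve(np.array(perims), s)
            assert curve.peak == pytest.approx(-c_expected[region], abs=1e-12)


def test_clean_phantom_edv_matches_draw_exactly(subject, clean_stack):
    m = measure_stack(clean_stack)
    assert m["EDV"] == pytest.approx(subject.edv_true, rel=1e-12)
    assert m["ESV"] < m["EDV"]
    assert m["MCS"] == pytest.approx(-100.0 * subject.c_mid, abs=1e-9)


def test_frame_zero_is_strain_reference(clean_stack):
    for frames in clean_stack.contours:
        perims = np.array([polygon_perimeter(c) for c in frames])
        assert strain_curve(perims).eps[0] == 0.0
        assert perims.argmax() == 0  # ED is the largest perimeter


def test_stack_volume_matches_analytic_ellipsoid(subject, noise_free_acq):
    """Slice-summation ED volume agrees with the closed-form truncated
    semi-ellipsoid volume to within 2% at 8 slices, improving with more."""
    stack = synthesize_cine(subject, noise_free_acq, rng_seed=0)
    spacing = noise_free_acq.slice_spacing_mm
    profile = ellipsoid_radius_profile(8, spacing)
    areas = [polygon_area(frames[0]) for frames in stack.contours]
    measured = sum(areas) * spacing / 1000.0
    r_eq = np.sqrt(areas[0] / np.pi) / profile[0]
    analytic = analytic_ed_volume_ml(r_eq, 8, spacing)
    assert measured == pytest.approx(analytic, rel=0.02)

    errors = []
    for n in (6, 8, 10):
        prof = ellipsoid_radius_profile(n, spacing)
        quad = np.pi * np.sum(prof**2) * spacing
        exact = (2 / 3) * np.pi * (n * spacing)
        errors.append(abs(quad - exact) / exact)
    assert errors[0] < 0.02
    assert errors == sorted(errors, reverse=True)  # converging in n


def test_dilatation_increases_edv_monotonically(subject, noise_free_acq):
    edvs = []
    for f in (1.0, 1.1, 1.2):
        s = dataclasses.replace(subject, dilatation_factor=f)
        edvs.append(measure_stack(synthesize_cine(s, noise_free_acq, 0))["EDV"])
    assert edvs[0] < edvs[1] < edvs[2]
    assert edvs[1] == pytest.approx(edvs[0] * 1.1**2, rel=1e-9)


def test_lvef_decreases_with_weaker_contraction(subject, noise_free_acq):
    lvefs = []
    for scale in (1.0, 0.8, 0.6):
        s = dataclasses.replace(
            subject,
            c_base=scale * subject.c_base,
            c_mid=scale * subject.c_mid,
            c_apex=scale * subject.c_apex,
        )
        lvefs.append(measure_stack(synthesize_cine(s, noise_free_acq, 0))["LVEF"])
    assert lvefs[0] > lvefs[1] > lvefs[2]


def test_degenerate_contraction_rejected(subject, noise_free_acq):
    bad = dataclasses.replace(subject, c_mid=1.2)
    with pytest.raises(DegenerateGeometryError):
        synthesize_cine(bad, noise_free_acq, 0)


def test_cohort_counts_and_determinism():
    sizes = {g.label: 3 for g in all_groups()}
    cfg = CohortConfig(group_sizes=sizes, acquisition=AcquisitionParams(n_slices=6, n_frames=9))
    a = generate_cohort(cfg, master_seed=21)
    b = generate_cohort(cfg, master_seed=21)
    assert len(a) == 36
    for (sa, ka), (sb, kb) in zip(a, b):
        assert sa == sb
        assert all(
            np.array_equal(ca.points, cb.points)
            for fa, fb in zip(ka.contours, kb.contours)
            for ca, cb in zip(fa, fb)
        )


def test_empty_cohort_rejected():
    sizes = {g.label: 0 for g in all_groups()}
    with pytest.raises(ConfigurationError):
        generate_cohort(CohortConfig(group_sizes=sizes), master_seed=0)


def test_parameter_recovery_at_rate_sd_over_sqrt_n():
    """Cohort means of configured strain and volume variables land within
    3 SE of the configured means at n = 200 (jitter on)."""
    sizes = {g.label: 0 for g in all_groups()}
    sizes["male_healthy_65-74"] = 100
    sizes["female_healthy_65-74"] = 100
    cfg = CohortConfig(
        group_sizes=sizes, acquisition=AcquisitionParams(n_frames=13)
    )
    cohort = generate_cohort(cfg, master_seed=5)
    measured = [measure_stack(stack) for _, stack in cohort]
    d = default_distributions()[("healthy", "65-74")]
    n = len(measured)
    for var, dist in (("MCS", d.mcs), ("ACS", d.acs), ("BCS", d.bcs), ("EDV", d.edv)):
        mean = np.mean([m[var] for m in measured])
        se = dist.sd / np.sqrt(n)
        assert abs(mean - dist.mean) < 3 * se, f"{var}: {mean} vs {dist.mean} (se {se})"
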