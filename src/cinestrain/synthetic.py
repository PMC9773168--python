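"""Parametric beating-LV phantom cohorts.

Generates synthetic subjects — demographics plus a short-axis cine stack of
endocardial contours — whose pipeline-measured strains and volumes follow
configured group-level normal distributions.  The default distributions are
published cohort characteristics of a large population CMR study
(healthy/unhealthy × three age bands); sex is a stratification label drawn
on top of the shared age-band distributions.

Phantom geometry
----------------
The cavity is a prolate semi-ellipsoid truncated at its equatorial base
plane, long semi-axis equal to the stack extent (n_slices × slice spacing).
Slice planes sit at the through-slice midpoints, so slice-summation volume
is a midpoint-rule quadrature of the analytic semi-ellipsoid volume
(2/3 π R² a).  The equatorial endocardial radius is solved so the polygonal
slice-summation end-diastolic volume equals the subject's EDV draw exactly.

Each slice contracts as a material ring::

    R_s(t) = R_s(0) · (1 − c_s · w(t))

where c_s is the region's peak perimeter-contraction fraction and w(t) a
raised-cosine activation rising 0→1 over systole and returning to 0 by the
last frame.  Perimeter scales linearly under uniform scaling, so with
jitter off the measured peak slice strain is −c_s to machine precision.
Through-plane motion is deliberately absent: it is a known confound of
short-axis strain, and omitting it gives exact ground truth.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import Contour, make_circle_contour, regular_polygon_area_factor
from .strain import MAX_SLICES, MIN_SLICES, allocate_regions

__all__ = [
    "SEXES",
    "AGE_BANDS",
    "HEALTH_STATES",
    "AGE_BAND_RANGES",
    "GroupSpec",
    "Normal",
    "GroupDistributions",
    "AcquisitionParams",
    "SubjectRecord",
    "ContourStack",
    "CohortConfig",
    "all_groups",
    "default_distributions",
    "sample_subject",
    "synthesize_cine",
    "generate_cohort",
    "activation_profile",
]

SEXES = ("male", "female")
AGE_BANDS = ("45-54", "55-64", "65-74")
HEALTH_STATES = ("healthy", "unhealthy")
AGE_BAND_RANGES = {"45-54": (45.0, 54.0), "55-64": (55.0, 64.0), "65-74": (65.0, 74.0)}

BMI_INCLUSION_RANGE = (18.5, 30.0)


class ConfigurationError(ValueError):
    """Missing or inconsistent generator configuration."""


class DegenerateGeometryError(ValueError):
    """Contraction fraction or sizing that collapses the cavity."""


@dataclass(frozen=True)
class GroupSpec:
    """One stratification cell: sex × age band × health status."""

    sex: str
    age_band: str
    health: str

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ConfigurationError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.age_band not in AGE_BANDS:
            raise ConfigurationError(f"age_band must be one of {AGE_BANDS}, got {self.age_band!r}")
        if self.health not in HEALTH_STATES:
            raise ConfigurationError(
                f"health must be one of {HEALTH_STATES}, got {self.health!r}"
            )

    @property
    def label(self) -> str:
        return f"{self.sex}_{self.health}_{self.age_band}"


def all_groups() -> list[GroupSpec]:
    """The 12 stratification cells in (sex, health, age band) order."""
    return [
        GroupSpec(sex=s, age_band=a, health=h)
        for s, h, a in itertools.product(SEXES, HEALTH_STATES, AGE_BANDS)
    ]


@dataclass(frozen=True)
class Normal:
    """Mean/SD pair for a normally distributed cohort variable."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ConfigurationError(f"SD must be positive, got {self.sd}")


@dataclass(frozen=True)
class GroupDistributions:
    """Distribution parameters for one (health, age band) cell.

    Strain means are in percent and must be negative; volumes in ml,
    weight kg, BMI kg/m², heart rate bpm, age years.  ``contraction_deficit``
    multiplies the affected region's contraction fraction by (1 − deficit);
    ``dilatation_factor`` multiplies all end-diastolic radii.  Both default
    to neutral because the unhealthy distribution columns already encode
    dilatation and reduced contraction.
    """

    acs: Normal
    mcs: Normal
    bcs: Normal
    edv: Normal
    weight: Normal
    bmi: Normal
    heart_rate: Normal
    age: Normal
    contraction_deficit: float = 0.0
    deficit_region: str = "mid"
    dilatation_factor: float = 1.0
    contraction_mode: str = "regional"  # or "uniform": one draw for all regions

    def __post_init__(self) -> None:
        for name in ("acs", "mcs", "bcs"):
            if getattr(self, name).mean >= 0:
                raise ConfigurationError(f"{name} mean strain must be negative (%)")
        if not (0.0 <= self.contraction_deficit < 1.0):
            raise ConfigurationError("contraction_deficit must lie in [0, 1)")
        if self.deficit_region not in ("base", "mid", "apex"):
            raise ConfigurationError(f"unknown deficit_region {self.deficit_region!r}")
        if self.dilatation_factor <= 0:
            raise ConfigurationError("dilatation_factor must be positive")
        if self.contraction_mode not in ("regional", "uniform"):
            raise ConfigurationError(f"unknown contraction_mode {self.contraction_mode!r}")


def default_distributions() -> dict[tuple[str, str], GroupDistributions]:
    """Published cohort means/SDs per (health, age band) cell."""
    rows = {
        # (health, band): age, HR, BMI, weight, EDV, ACS, MCS, BCS
        ("healthy", "45-54"): ((52.0, 2.0), (59.9, 8.0), (25.4, 2.6), (74.9, 12.1),
                               (151.6, 31.1), (-41.7, 7.4), (-28.5, 3.6), (-31.6, 5.0)),
        ("healthy", "55-64"): ((60.0, 3.0), (61.1, 9.4), (24.8, 2.7), (72.4, 11.9),
                               (141.2, 30.9), (-41.9, 8.0), (-29.6, 4.3), (-31.5, 3.9)),
        ("healthy", "65-74"): ((69.0, 3.0), (62.7, 9.6), (25.1, 2.6), (72.1, 10.7),
                               (136.3, 30.9), (-41.6, 8.1), (-30.0, 4.4), (-31.8, 4.8)),
        ("unhealthy", "45-54"): ((53.0, 1.0), (53.6, 11.2), (27.3, 2.1), (76.7, 6.2),
                                 (170.6, 22.8), (-36.7, 10.3), (-29.0, 5.2), (-30.5, 3.9)),
        ("unhealthy", "55-64"): ((61.0, 3.0), (57.0, 10.4), (25.0, 2.5), (75.9, 8.9),
                                 (169.8, 25.6), (-40.2, 14.6), (-28.3, 8.4), (-29.2, 5.8)),
        ("unhealthy", "65-74"): ((69.0, 3.0), (57.0, 9.2), (25.6, 2.3), (75.9, 10.5),
                                 (158.8, 41.6), (-37.8, 13.8), (-26.8, 6.8), (-29.3, 8.0)),
    }
    out = {}
    for key, (age, hr, bmi_, wt, edv, acs, mcs, bcs) in rows.items():
        out[key] = GroupDistributions(
            acs=Normal(*acs), mcs=Normal(*mcs), bcs=Normal(*bcs), edv=Normal(*edv),
            weight=Normal(*wt), bmi=Normal(*bmi_), heart_rate=Normal(*hr), age=Normal(*age),
        )
    return out


@dataclass(frozen=True)
class AcquisitionParams:
    """Short-axis cine acquisition geometry and phantom rendering options.

    ``n_slices=None`` draws a per-subject count uniformly from 6–10 (the
    protocol's observed range).  ``n_frames=25`` spans roughly one cardiac
    cycle at 31.56 ms temporal resolution and ~60 bpm.  ``systole_fraction``
    places end systole at 40% of the cycle.

    ``jitter_sd_mm`` is the pointwise SD (mm) of zero-mean Gaussian radial
    jitter applied to every contour.  The jitter is spatially *correlated*
    along the ring (a random combination of the lowest ``jitter_modes``
    Fourier modes), emulating the smooth boundary-placement errors of real
    segmentations; independent per-vertex noise would systematically
    lengthen the polygonal perimeter and bias strain toward zero.
    """

    slice_thickness_mm: float = 8.0
    slice_gap_mm: float = 2.0
    temporal_resolution_ms: float = 31.56
    n_slices: int | None = None
    n_frames: int = 25
    n_contour_points: int = 100
    systole_fraction: float = 0.4
    jitter_sd_mm: float = 0.2
    jitter_modes: int = 8
    eccentricity: float = 0.0

    def __post_init__(self) -> None:
        if self.n_slices is not None and not (MIN_SLICES <= self.n_slices <= MAX_SLICES):
            raise ConfigurationError(
                f"n_slices must be in [{MIN_SLICES}, {MAX_SLICES}] or None, got {self.n_slices}"
            )
        if self.n_frames < 3:
            raise ConfigurationError("n_frames must be >= 3")
        if not (0.0 < self.systole_fraction < 1.0):
            raise ConfigurationError("systole_fraction must lie in (0, 1)")
        if self.slice_thickness_mm <= 0 or self.slice_gap_mm < 0:
            raise ConfigurationError("invalid slice geometry")
        if self.jitter_sd_mm < 0:
            raise ConfigurationError("jitter_sd_mm must be >= 0")
        if self.jitter_modes < 1:
            raise ConfigurationError("jitter_modes must be >= 1")
        if self.eccentricity < 0:
            raise ConfigurationError("eccentricity must be >= 0")

    @property
    def slice_spacing_mm(self) -> float:
        return self.slice_thickness_mm + self.slice_gap_mm


@dataclass
class SubjectRecord:
    """One synthetic participant: demographics plus phantom ground truth.

    ``c_base/c_mid/c_apex`` are the per-region peak perimeter-contraction
    fractions (post disease modifiers); the jitter-free pipeline recovers
    regional strain −100·c exactly.  ``edv_true`` is the end-diastolic
    volume the stack is sized to (before any dilatation factor).  Measured
    indices are filled in by the analysis pipeline, not the generator.
    """

    subject_id: str
    sex: str
    age_band: str
    health: str
    age: float
    height_cm: float
    weight_kg: float
    bmi: float
    heart_rate: float
    edv_true: float
    c_base: float
    c_mid: float
    c_apex: float
    dilatation_factor: float = 1.0
    diabetes: bool = False
    smoker: bool = False
    qualifying_ethnicity: bool = True
    measured: dict = field(default_factory=dict)

    @property
    def group(self) -> GroupSpec:
        return GroupSpec(sex=self.sex, age_band=self.age_band, health=self.health)


@dataclass
class ContourStack:
    """Per-subject cine stack: contours[slice][frame], base → apex, frame 0 = ED."""

    subject_id: str
    acquisition: AcquisitionParams
    contours: list[list[Contour]]

    @property
    def n_slices(self) -> int:
        return len(self.contours)

    @property
    def n_frames(self) -> int:
        return len(self.contours[0])

    def __post_init__(self) -> None:
        if not self.contours:
            raise DegenerateGeometryError("stack has no slices")
        n_frames = {len(s) for s in self.contours}
        if len(n_frames) != 1:
            raise DegenerateGeometryError("slices disagree on frame count")


def _truncated_normal(rng: np.random.Generator, dist: Normal, lo: float, hi: float) -> float:
    """Rejection-sample N(mean, sd) restricted to [lo, hi]."""
    if not (lo <= hi):
        raise ConfigurationError(f"empty truncation interval [{lo}, {hi}]")
    for _ in range(10_000):
        x = rng.normal(dist.mean, dist.sd)
        if lo <= x <= hi:
            return float(x)
    # distribution mass in the window is vanishing; clamp deterministically
    return float(min(max(dist.mean, lo), hi))


def sample_subject(
    group: GroupSpec,
    dists: GroupDistributions | None = None,
    rng_seed: int | np.random.SeedSequence = 0,
    *,
    subject_id: str | None = None,
) -> SubjectRecord:
    """Draw one subject's attributes and ground-truth contraction fractions.

    Attributes come from the configured normals, truncated to the study's
    inclusion windows (age within its band, BMI 18.5–30).  Regional
    contraction fractions are −strain/100 draws from the regional strain
    distributions (one shared draw in ``uniform`` mode), after which the
    unhealthy contraction deficit is applied to its region.
    """
    if dists is None:
        dists = default_distributions()[(group.health, group.age_band)]
    rng = np.random.default_rng(rng_seed)

    lo, hi = AGE_BAND_RANGES[group.age_band]
    age = _truncated_normal(rng, dists.age, lo, hi)
    bmi_val = _truncated_normal(rng, dists.bmi, *BMI_INCLUSION_RANGE)
    weight = _truncated_normal(rng, dists.weight, 35.0, 200.0)
    height_cm = 100.0 * float(np.sqrt(weight / bmi_val))
    heart_rate = _truncated_normal(rng, dists.heart_rate, 30.0, 150.0)
    edv = _truncated_normal(rng, dists.edv, 30.0, 400.0)

    def draw_c(strain_dist: Normal) -> float:
        # strain (%) in (−95, −5) keeps the ring geometry non-degenerate
        return -_truncated_normal(rng, strain_dist, -95.0, -5.0) / 100.0

    if dists.contraction_mode == "uniform":
        c = draw_c(dists.mcs)
        c_base = c_mid = c_apex = c
    else:
        c_apex = draw_c(dists.acs)
        c_mid = draw_c(dists.mcs)
        c_base = draw_c(dists.bcs)

    if dists.contraction_deficit > 0.0:
        factor = 1.0 - dists.contraction_deficit
        if dists.deficit_region == "base":
            c_base *= factor
        elif dists.deficit_region == "mid":
            c_mid *= factor
        else:
            c_apex *= factor

    return SubjectRecord(
        subject_id=subject_id or f"{group.label}_{int(rng.integers(1 << 31)):08d}",
        sex=group.sex,
        age_band=group.age_band,
        health=group.health,
        age=age,
        height_cm=height_cm,
        weight_kg=weight,
        bmi=bmi_val,
        heart_rate=heart_rate,
        edv_true=edv,
        c_base=c_base,
        c_mid=c_mid,
        c_apex=c_apex,
        dilatation_factor=dists.dilatation_factor,
    )


def activation_profile(n_frames: int, systole_fraction: float = 0.4) -> np.ndarray:
    """Raised-cosine activation w(t): 0 at ED, 1 at end systole, 0 at cycle end."""
    t_es = int(round(systole_fraction * (n_frames - 1)))
    t_es = min(max(t_es, 1), n_frames - 2)
    w = np.empty(n_frames)
    up = np.arange(t_es + 1)
    w[: t_es + 1] = 0.5 * (1.0 - np.cos(np.pi * up / t_es))
    down = np.arange(1, n_frames - t_es)
    w[t_es + 1 :] = 0.5 * (1.0 + np.cos(np.pi * down / (n_frames - 1 - t_es)))
    w[0] = 0.0
    w[-1] = 0.0
    w[t_es] = 1.0
    return w


def ellipsoid_radius_profile(n_slices: int, spacing_mm: float) -> np.ndarray:
    """Relative base→apex radius profile of the truncated semi-ellipsoid.

    Slice s sits at z = (s + 1/2)·spacing from the equatorial base plane;
    the long semi-axis is a = n_slices·spacing, so the apical slice keeps a
    positive radius.  Returned values are r(z)/R_equator.
    """
    a = n_slices * spacing_mm
    z = (np.arange(n_slices) + 0.5) * spacing_mm
    return np.sqrt(1.0 - (z / a) ** 2)


def analytic_ed_volume_ml(r_equator_mm: float, n_slices: int, spacing_mm: float) -> float:
    """Closed-form volume (ml) of the semi-ellipsoid the stack discretises."""
    a = n_slices * spacing_mm
    return (2.0 / 3.0) * np.pi * r_equator_mm**2 * a / 1000.0


def _smooth_radial_noise(
    rng: np.random.Generator, n_points: int, sd: float, n_modes: int
) -> np.ndarray:
    """Zero-mean radial perturbation with pointwise SD ``sd``, band-limited
    to Fourier modes 1..n_modes around the ring."""
    spectrum = np.zeros(n_points // 2 + 1, dtype=complex)
    k_max = min(n_modes, n_points // 2)
    coef = rng.standard_normal(k_max) + 1j * rng.standard_normal(k_max)
    spectrum[1 : k_max + 1] = coef
    noise = np.fft.irfft(spectrum, n_points)
    scale = noise.std()
    return noise * (sd / scale) if scale > 0 else noise


def synthesize_cine(
    subject: SubjectRecord,
    acq: AcquisitionParams | None = None,
    rng_seed: int | np.random.SeedSequence = 0,
) -> ContourStack:
    """Render one subject's beating short-axis contour stack.

    Frame 0 is end diastole.  With jitter off, the polygonal slice-sum
    volume at frame 0 equals ``subject.edv_true × dilatation_factor²``
    exactly, and every slice's peak perimeter strain equals −c_region.
    """
    acq = acq or AcquisitionParams()
    rng = np.random.default_rng(rng_seed)

    for c in (subject.c_base, subject.c_mid, subject.c_apex):
        if not (0.0 <= c < 1.0):
            raise DegenerateGeometryError(f"contraction fraction {c} outside [0, 1)")

    n_slices = acq.n_slices if acq.n_slices is not None else int(rng.integers(MIN_SLICES, MAX_SLICES + 1))
    spacing = acq.slice_spacing_mm
    profile = ellipsoid_radius_profile(n_slices, spacing)

    # equatorial radius such that polygonal slice-sum ED volume = EDV draw
    kappa = regular_polygon_area_factor(acq.n_contour_points)
    edv_mm3 = subject.edv_true * 1000.0
    r_eq = float(np.sqrt(edv_mm3 / (kappa * np.pi * spacing * np.sum(profile**2))))
    r_eq *= subject.dilatation_factor

    alloc = allocate_regions(n_slices)
    c_by_region = {"base": subject.c_base, "mid": subject.c_mid, "apex": subject.c_apex}
    c_slice = np.empty(n_slices)
    for region, rng_idx in alloc.slice_ranges().items():
        c_slice[rng_idx.start : rng_idx.stop] = c_by_region[region]

    w = activation_profile(acq.n_frames, acq.systole_fraction)
    # area-preserving anisotropy so EDV sizing holds for elliptical sections
    ax = np.sqrt(1.0 + acq.eccentricity)

    contours: list[list[Contour]] = []
    for s in range(n_slices):
        r0 = r_eq * profile[s]
        frames = []
        theta = 2.0 * np.pi * np.arange(acq.n_contour_points) / acq.n_contour_points
        for t in range(acq.n_frames):
            r = r0 * (1.0 - c_slice[s] * w[t])
            radii = np.full(acq.n_contour_points, r)
            if acq.jitter_sd_mm > 0:
                radii = radii + _smooth_radial_noise(
                    rng, acq.n_contour_points, acq.jitter_sd_mm, acq.jitter_modes
                )
            pts = np.column_stack([radii * np.cos(theta) * ax, radii * np.sin(theta) / ax])
            frames.append(Contour(pts))
        contours.append(frames)
    return ContourStack(subject_id=subject.subject_id, acquisition=replace(acq, n_slices=n_slices), contours=contours)


@dataclass(frozen=True)
class CohortConfig:
    """Cohort composition and generator settings.

    ``group_sizes`` maps cell labels (``sex_health_ageband``) to counts.
    The default composition mirrors the source study's selection: 100 per
    healthy sex × age cell; unhealthy cells pass through at their observed
    sizes (males 5/24/82, females 1/4/15 across the three bands).
    """

    group_sizes: dict = field(default_factory=dict)
    distributions: dict = field(default_factory=default_distributions)
    acquisition: AcquisitionParams = field(default_factory=AcquisitionParams)

    def sizes(self) -> dict[GroupSpec, int]:
        default_unhealthy = {
            ("male", "45-54"): 5, ("male", "55-64"): 24, ("male", "65-74"): 82,
            ("female", "45-54"): 1, ("female", "55-64"): 4, ("female", "65-74"): 15,
        }
        out = {}
        for g in all_groups():
            if g.label in self.group_sizes:
                n = int(self.group_sizes[g.label])
            elif g.health == "healthy":
                n = 100
            else:
                n = default_unhealthy[(g.sex, g.age_band)]
            if n < 0:
                raise ConfigurationError(f"negative group size for {g.label}")
            out[g] = n
        return out


def generate_cohort(
    config: CohortConfig | None = None,
    master_seed: int = 0,
) -> list[tuple[SubjectRecord, ContourStack]]:
    """Generate a reproducible cohort of (subject, cine stack) pairs.

    Per-subject seeds are spawned deterministically from ``master_seed``;
    the same seed and config give an identical cohort.
    """
    config = config or CohortConfig()
    sizes = config.sizes()
    if all(n == 0 for n in sizes.values()):
        raise ConfigurationError("cohort is empty: all group sizes are zero")
    root = np.random.SeedSequence(master_seed)
    cohort: list[tuple[SubjectRecord, ContourStack]] = []
    counter = 0
    for group in all_groups():
        n = sizes[group]
        dists = config.distributions[(group.health, group.age_band)]
        for i in range(n):
            child = np.random.SeedSequence(entropy=root.entropy, spawn_key=(counter,))
            subj_seed, cine_seed = child.spawn(2)
            subject = sample_subject(
                group, dists, subj_seed, subject_id=f"{group.label}_{i:04d}"
            )
            stack = synthesize_cine(subject, config.acquisition, cine_seed)
            cohort.append((subject, stack))
            counter += 1
    return cohort
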