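"""Synthetic FAIR kidney acquisitions and repeated-measures cohorts.

The phantom is a 2-D kidney-like object built from concentric ellipses:
an outer cortical rim, a medullary band and a bright central calyceal
region, each at its own M0-relative gray level.  Perfusion-weighted signal
differences are synthesized by inverting the single-TI FAIR quantification
formula, so a noiseless phantom round-trips through quantification to the
specified true perfusion exactly.  Per-pair affine jitter emulates
imperfect breath-holds; optionally some pairs are corrupted with a large
translation, the failure mode that registration QC must catch.

The cohort generator draws a repeated-measures table (subject x session x
repetition) from a two-level normal model, the design used to assess
scan-rescan reproducibility: subject truths around a population mean, plus
independent within-subject measurement noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .compartments import BACKGROUND, CALYX, CORTEX, MEDULLA
from .perfusion import AcquisitionMeta, AslSeries, QuantificationParams
from .pipeline import PerfusionSummary
from .transform import AffineTransform2D

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "CohortSpec",
    "PhantomSpecError",
    "make_phantom",
    "make_cohort",
    "default_seed_points",
]


class PhantomSpecError(ValueError):
    """Raised when a phantom specification is geometrically or physically invalid."""


# Default compartment truths: cohort means of a healthy-volunteer renal ASL
# study (cortex 337.10, medulla 279.61 mL/min/100 g); with a cortex:medulla
# area ratio of 0.93 their area-weighted mean is the whole-kidney 307.26.
@dataclass
class PhantomSpec:
    """Geometry, contrast, truth and corruption settings for one phantom."""

    image_shape: tuple[int, int] = (96, 96)
    kidney_center: tuple[float, float] = (48.0, 48.0)  # (row, col)
    kidney_axes: tuple[float, float] = (20.0, 30.0)  # semi-axes (row, col), px
    cortex_medulla_area_ratio: float = 0.93
    calyx_area_fraction: float = 0.18  # calyx area / whole-kidney area
    hilum_depth: float = 0.15  # fractional radial indentation of the hilar notch
    hilum_angle: float = 20.0  # degrees, direction of the notch
    hilum_width: float = 0.5  # radians, angular half-width of the notch
    true_perfusion_cortex: float = 337.10  # mL/min/100 g
    true_perfusion_medulla: float = 279.61  # mL/min/100 g
    gray_levels: dict[str, float] = field(
        default_factory=lambda: {
            "background": 0.10,
            "calyx": 0.95,
            "medulla": 0.55,
            "cortex": 0.75,
        }
    )
    m0_scale: float = 1000.0  # arbitrary signal units of the M0 plateau
    global_signal_fraction: float = 0.6  # inversion-recovery attenuation of globals
    noise_sd: float = 0.02  # fraction of m0_scale, additive Gaussian
    jitter_max_translation: float = 2.0  # px
    jitter_max_rotation: float = 2.0  # degrees
    n_pairs: int = 8
    n_corrupted_pairs: int = 0
    seed: int = 0

    def validate(self) -> None:
        rows, cols = self.image_shape
        ar, ac = self.kidney_axes
        cr, cc = self.kidney_center
        margin = 4.0 * self.jitter_max_translation  # worst-case corrupted shift
        if not (
            cr - ar - margin >= 0
            and cr + ar + margin <= rows - 1
            and cc - ac - margin >= 0
            and cc + ac + margin <= cols - 1
        ):
            raise PhantomSpecError("kidney ellipse (plus jitter margin) does not fit the image")
        if ar <= 0 or ac <= 0:
            raise PhantomSpecError("kidney semi-axes must be positive")
        if self.n_pairs < 1:
            raise PhantomSpecError("need at least one inversion pair")
        if not 0 <= self.n_corrupted_pairs <= self.n_pairs:
            raise PhantomSpecError("n_corrupted_pairs must lie in [0, n_pairs]")
        if self.n_corrupted_pairs > 0 and self.jitter_max_translation <= 0:
            raise PhantomSpecError("corrupted pairs need a positive jitter bound to exceed")
        if min(self.true_perfusion_cortex, self.true_perfusion_medulla) < 0:
            raise PhantomSpecError("true perfusion values must be non-negative")
        if self.noise_sd < 0 or self.jitter_max_translation < 0 or self.jitter_max_rotation < 0:
            raise PhantomSpecError("noise and jitter bounds must be non-negative")
        if not 0 < self.calyx_area_fraction < 1:
            raise PhantomSpecError("calyx_area_fraction must lie in (0, 1)")
        if not 0 <= self.hilum_depth < 1 or self.hilum_width <= 0:
            raise PhantomSpecError("hilum_depth must lie in [0, 1) and hilum_width be positive")
        if self.cortex_medulla_area_ratio <= 0:
            raise PhantomSpecError("cortex_medulla_area_ratio must be positive")
        needed = {"background", "calyx", "medulla", "cortex"}
        if set(self.gray_levels) != needed:
            raise PhantomSpecError(f"gray_levels must define exactly {sorted(needed)}")
        if len(set(self.gray_levels.values())) != 4:
            raise PhantomSpecError("gray levels must be pairwise distinct")


@dataclass
class PhantomTruth:
    """Ground truth accompanying one phantom acquisition."""

    label_image: np.ndarray  # 0 bg, 1 calyx, 2 medulla, 3 cortex
    per_pair_transform: list[AffineTransform2D]
    true_summary: PerfusionSummary
    kidney_mask: np.ndarray
    corrupted_indices: tuple[int, ...] = ()


def _label_image(spec: PhantomSpec, transform: AffineTransform2D | None = None) -> np.ndarray:
    """Rasterize the compartment geometry, optionally moved by an affine.

    The moved phantom is evaluated analytically (each pixel is classified
    by pulling its coordinates back through the transform), the way a
    scanner samples a kidney that has actually moved -- no interpolation
    blur is introduced by the generator itself.
    """
    rows, cols = spec.image_shape
    rr, cc = np.mgrid[0:rows, 0:cols]
    if transform is not None and not transform.is_identity:
        inv = np.linalg.inv(transform.matrix(spec.kidney_center))
        x = inv[0, 0] * cc + inv[0, 1] * rr + inv[0, 2]
        y = inv[1, 0] * cc + inv[1, 1] * rr + inv[1, 2]
        rr, cc = y, x
    ry = (rr - spec.kidney_center[0]) / spec.kidney_axes[0]
    rx = (cc - spec.kidney_center[1]) / spec.kidney_axes[1]
    rho = np.sqrt(ry**2 + rx**2)
    # Bean-like outline: a smooth hilar notch indents the ellipse on one
    # side.  All compartment boundaries are scaled by the same angular
    # profile, so the compartment area ratios are unaffected.
    if spec.hilum_depth > 0:
        psi = np.arctan2(ry, rx)
        dpsi = np.angle(np.exp(1j * (psi - np.deg2rad(spec.hilum_angle))))
        profile = 1.0 - spec.hilum_depth * np.exp(-0.5 * (dpsi / spec.hilum_width) ** 2)
        rho = rho / profile
    c2 = spec.calyx_area_fraction
    # Solve (1 - s2) / (s2 - c2) = ratio for the cortex/medulla boundary.
    s2 = (1.0 + spec.cortex_medulla_area_ratio * c2) / (1.0 + spec.cortex_medulla_area_ratio)
    labels = np.full(spec.image_shape, BACKGROUND, dtype=np.int64)
    labels[rho <= 1.0] = CORTEX
    labels[rho <= math.sqrt(s2)] = MEDULLA
    labels[rho <= math.sqrt(c2)] = CALYX
    return labels


def _base_maps(
    spec: PhantomSpec,
    meta: AcquisitionMeta,
    params: QuantificationParams,
    transform: AffineTransform2D | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(labels, M0 signal, FAIR signal difference) for one phantom pose."""
    labels = _label_image(spec, transform)
    gray = np.empty(spec.image_shape, dtype=float)
    for name, lab in (
        ("background", BACKGROUND),
        ("calyx", CALYX),
        ("medulla", MEDULLA),
        ("cortex", CORTEX),
    ):
        gray[labels == lab] = spec.gray_levels[name]
    m0_base = gray * spec.m0_scale
    perf_true = np.zeros(spec.image_shape, dtype=float)
    perf_true[labels == CORTEX] = spec.true_perfusion_cortex
    perf_true[labels == MEDULLA] = spec.true_perfusion_medulla
    # Invert f = 60*lambda*dM*exp(TI/T1b)/(2*M0*TI) for the signal difference.
    ti = meta.inversion_time
    dm = (
        perf_true
        * 2.0
        * m0_base
        * ti
        / (60.0 * params.lambda_partition * math.exp(ti / params.t1_blood))
    )
    return labels, m0_base, dm


def make_phantom(
    spec: PhantomSpec,
    meta: AcquisitionMeta | None = None,
    params: QuantificationParams | None = None,
) -> tuple[AslSeries, PhantomTruth]:
    """Generate one synthetic acquisition plus its ground truth.

    Deterministic for a fixed ``spec.seed``.
    """
    spec.validate()
    meta = meta or AcquisitionMeta()
    params = params or QuantificationParams()
    rng = np.random.default_rng(spec.seed)

    labels, m0_base, _ = _base_maps(spec, meta, params)

    # Per-pair breathing jitter; a corrupted pair gets a translation at
    # least three times the jitter bound, in a random direction.
    transforms: list[AffineTransform2D] = []
    for _ in range(spec.n_pairs):
        ty, tx = rng.uniform(-spec.jitter_max_translation, spec.jitter_max_translation, size=2)
        rot = rng.uniform(-spec.jitter_max_rotation, spec.jitter_max_rotation)
        transforms.append(AffineTransform2D(tx=tx, ty=ty, rotation=rot))
    corrupted = tuple(
        sorted(rng.choice(spec.n_pairs, size=spec.n_corrupted_pairs, replace=False).tolist())
    )
    for i in corrupted:
        ang = rng.uniform(0.0, 2.0 * math.pi)
        mag = rng.uniform(3.0, 4.0) * spec.jitter_max_translation
        transforms[i] = AffineTransform2D(
            tx=mag * math.cos(ang), ty=mag * math.sin(ang), rotation=transforms[i].rotation
        )

    noise_scale = spec.noise_sd * spec.m0_scale
    m0 = m0_base + noise_scale * rng.standard_normal(spec.image_shape)
    pairs = []
    for tf in transforms:
        _, m0_pose, dm_pose = _base_maps(spec, meta, params, tf)
        global_pose = spec.global_signal_fraction * m0_pose
        g = global_pose + noise_scale * rng.standard_normal(spec.image_shape)
        s = global_pose + dm_pose + noise_scale * rng.standard_normal(spec.image_shape)
        pairs.append((g, s))

    n_cortex = int((labels == CORTEX).sum())
    n_medulla = int((labels == MEDULLA).sum())
    whole = (
        n_cortex * spec.true_perfusion_cortex + n_medulla * spec.true_perfusion_medulla
    ) / (n_cortex + n_medulla)
    truth = PhantomTruth(
        label_image=labels,
        per_pair_transform=transforms,
        true_summary=PerfusionSummary(
            whole_parenchyma=whole,
            cortex=spec.true_perfusion_cortex,
            medulla=spec.true_perfusion_medulla,
        ),
        kidney_mask=labels != BACKGROUND,
        corrupted_indices=corrupted,
    )
    return AslSeries(m0=m0, pairs=pairs, meta=meta), truth


def default_seed_points(spec: PhantomSpec, n_seeds: int = 4) -> list[tuple[int, int]]:
    """Seed points on the kidney boundary for the live-wire step.

    Points are placed at equal parametric angles on the outer ellipse and
    nudged inward onto the outermost kidney pixel, mimicking a user
    clicking on the visible edge.
    """
    labels = _label_image(spec)
    cr, cc = spec.kidney_center
    ar, ac = spec.kidney_axes
    seeds = []
    for k in range(n_seeds):
        t = 2.0 * math.pi * k / n_seeds
        r = cr + ar * math.sin(t)
        c = cc + ac * math.cos(t)
        rr, ccol = int(round(r)), int(round(c))
        # step towards the center until inside the kidney
        while labels[rr, ccol] == BACKGROUND:
            rr += int(np.sign(round(cr) - rr)) if rr != round(cr) else 0
            ccol += int(np.sign(round(cc) - ccol)) if ccol != round(cc) else 0
        seeds.append((rr, ccol))
    return seeds


@dataclass
class CohortSpec:
    """Design of a simulated scan-rescan reproducibility study.

    Defaults mirror a 14-subject design measured 3 times on each of 2
    occasions (6 repeated measurements per subject), with a population
    mean and between-subject dispersion typical of whole-kidney perfusion
    and a within-subject SD equal to a 3.43% repetition CV.
    """

    n_subjects: int = 14
    n_sessions: int = 2
    n_reps_per_session: int = 3
    population_mean: float = 307.26  # mL/min/100 g
    between_subject_sd: float = 25.65
    within_subject_sd: float = 10.54
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_subjects, self.n_sessions, self.n_reps_per_session) < 1:
            raise PhantomSpecError("cohort counts must be >= 1")
        if self.between_subject_sd < 0 or self.within_subject_sd < 0:
            raise PhantomSpecError("cohort SDs must be non-negative")


def make_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Simulate a repeated-measures table (subject, session, repetition, value).

    value(s, j, r) = truth(s) + noise with truth ~ N(mean, between_sd^2)
    and noise ~ N(0, within_sd^2), independent across measurements.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    truths = rng.normal(spec.population_mean, spec.between_subject_sd, size=spec.n_subjects)
    rows = []
    for s in range(spec.n_subjects):
        for j in range(spec.n_sessions):
            for r in range(spec.n_reps_per_session):
                value = truths[s] + rng.normal(0.0, spec.within_subject_sd)
                rows.append((s + 1, j + 1, r + 1, value))
    return pd.DataFrame(rows, columns=["subject", "session", "repetition", "value"])
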