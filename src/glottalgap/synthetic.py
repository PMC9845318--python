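"""Synthetic phonation-mask simulator.

Generates labeled mask sequences with the geometric and temporal structure
of segmented high-speed laryngeal video: an oscillating glottis between two
fold bands, an optional persistent posterior (rear) gap, rigid
rotation/translation/zoom of the larynx in the frame, and boundary jitter.
Defaults follow the clinical acquisition regime these masks emulate:
256 x 256 px frames, 4000 frames/s, 100 consecutive frames, f0 around
200 Hz (female speaking voice).

The glottal axis is split into a *membranous* (anterior 80%) and a
*posterior* (rear 20%) zone, mirroring the membranous vs cartilaginous
glottis.  The membranous zone is an elliptic lens whose half-width follows
a half-rectified sinusoid ``w(t) = A * max(0, sin(2*pi*f0*t/fps + phase))``
— the simplest periodic waveform with a distinct closed phase, a testing
device rather than a biomechanical model.  The posterior zone opens only as
a brief small "vestige" around peak opening (the arytenoids parting
slightly), except in gap subjects where a constant-half-width slot persists
through the whole cycle.  A 10%-from-the-rear measurement line therefore
falls in the posterior zone and reads the persistent gap, while a 50% line
falls mid-membranous and reads the oscillation, identically in both groups.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .mask_io import BACKGROUND, GLOTTIS, LEFT_FOLD, RIGHT_FOLD, LabeledFrame, MaskSequence

#: Fraction of the glottal axis (from the rear) forming the posterior zone.
REAR_ZONE_AXIS_FRACTION = 0.20


@dataclass(frozen=True)
class PhonationParams:
    """Geometry and dynamics of one simulated recording.

    Lengths are in pixels; the fold axis is vertical before rotation, with
    the posterior (rear) end at the top of the frame.
    """

    width: int = 256
    height: int = 256
    n_frames: int = 100
    fps: float = 4000.0
    f0: float = 200.0
    glottis_half_length: float = 60.0
    max_opening_halfwidth: float = 12.0
    rear_gap_halfwidth: float = 0.0
    rear_vestige_halfwidth: float = 1.2
    rear_vestige_threshold: float = 0.95
    fold_width: float = 40.0
    fold_axis_margin: float = 10.0  # folds extend this far beyond the glottis
    rotation_deg: float = 0.0
    translation: tuple[float, float] = (0.0, 0.0)
    boundary_jitter_px: float = 0.0
    phase: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fps <= 0 or self.f0 <= 0:
            raise ValueError("fps and f0 must be > 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.rear_gap_halfwidth < 0:
            raise ValueError("rear_gap_halfwidth must be >= 0")
        if not 0.0 <= self.rear_vestige_threshold < 1.0:
            raise ValueError("rear_vestige_threshold must be in [0, 1)")
        if min(self.width, self.height) < 8:
            raise ValueError("frame must be at least 8x8")
        # the larynx (rotated, translated) must fit inside the frame
        hx = self.max_opening_halfwidth + self.fold_width
        hy = self.glottis_half_length + self.fold_axis_margin
        th = np.deg2rad(self.rotation_deg)
        ex = abs(hx * np.cos(th)) + abs(hy * np.sin(th))
        ey = abs(hx * np.sin(th)) + abs(hy * np.cos(th))
        cx = self.width / 2.0 + self.translation[0]
        cy = self.height / 2.0 + self.translation[1]
        if cx - ex < 0 or cx + ex > self.width or cy - ey < 0 or cy + ey > self.height:
            raise ValueError("larynx geometry exceeds frame bounds")


class _Renderer:
    """Caches the (rotated, translated) pixel coordinate grids of one recording."""

    def __init__(self, params: PhonationParams):
        self.p = params
        xs = np.arange(params.width) + 0.5
        ys = np.arange(params.height) + 0.5
        X, Y = np.meshgrid(xs, ys)  # indexed [j, i], lower-left origin
        cx = params.width / 2.0 + params.translation[0]
        cy = params.height / 2.0 + params.translation[1]
        th = np.deg2rad(params.rotation_deg)
        dx, dy = X - cx, Y - cy
        # larynx-local coordinates: u along the axis (rear = +u), v lateral
        self.u = -np.sin(th) * dx + np.cos(th) * dy
        self.v = np.cos(th) * dx + np.sin(th) * dy
        L = params.glottis_half_length
        self.rear_zone_start = L * (1.0 - 2.0 * REAR_ZONE_AXIS_FRACTION)
        # membranous lens spans [-L, rear_zone_start]
        self.lens_center = (-L + self.rear_zone_start) / 2.0
        self.lens_half_len = (self.rear_zone_start + L) / 2.0
        Lf = L + params.fold_axis_margin
        self.Lf = Lf
        self.in_axis = np.abs(self.u) <= Lf
        self.in_rear = (self.u >= self.rear_zone_start) & (self.u <= L)
        frac = 1.0 - ((self.u - self.lens_center) / self.lens_half_len) ** 2
        self.lens_profile = np.sqrt(np.clip(frac, 0.0, None))
        self.outer = params.max_opening_halfwidth + params.fold_width
        self.jitter_knots = np.arange(-Lf - 4.0, Lf + 8.0, 4.0)

    def opening(self, t: int) -> float:
        p = self.p
        return max(0.0, float(np.sin(2.0 * np.pi * p.f0 * t / p.fps + p.phase)))

    def frame(self, t: int, rng: np.random.Generator) -> LabeledFrame:
        p = self.p
        s = self.opening(t)
        hw = (p.max_opening_halfwidth * s) * self.lens_profile
        vestige = p.rear_vestige_halfwidth * max(
            0.0, (s - p.rear_vestige_threshold) / (1.0 - p.rear_vestige_threshold)
        )
        rear_hw = max(vestige, p.rear_gap_halfwidth)
        if rear_hw > 0.0:
            hw = np.where(self.in_rear, np.maximum(hw, rear_hw), hw)

        if p.boundary_jitter_px > 0:
            # smooth per-frame edge noise, one draw per fold edge,
            # linearly interpolated over 4-px knots along the axis
            nz_l = rng.normal(0.0, p.boundary_jitter_px, self.jitter_knots.size)
            nz_r = rng.normal(0.0, p.boundary_jitter_px, self.jitter_knots.size)
            eta_l = np.interp(self.u, self.jitter_knots, nz_l)
            eta_r = np.interp(self.u, self.jitter_knots, nz_r)
        else:
            eta_l = eta_r = 0.0

        edge_left = -np.maximum(hw + eta_l, 0.0)
        edge_right = np.maximum(hw + eta_r, 0.0)

        v = self.v
        glottis = self.in_axis & (v > edge_left) & (v < edge_right)
        left = self.in_axis & (v <= edge_left) & (v >= -self.outer)
        right = self.in_axis & (v >= edge_right) & (v <= self.outer)

        labels = np.full((p.height, p.width), BACKGROUND, dtype=np.uint8)
        labels[glottis] = GLOTTIS
        labels[left] = LEFT_FOLD
        labels[right] = RIGHT_FOLD
        return LabeledFrame(labels, frame_index=t)


def generate_sequence(params: PhonationParams) -> MaskSequence:
    """Render a deterministic mask sequence from phonation parameters."""
    rng = np.random.default_rng(params.seed)
    renderer = _Renderer(params)
    frames = [renderer.frame(t, rng) for t in range(params.n_frames)]
    group = "gap" if params.rear_gap_halfwidth > 0 else "normal"
    return MaskSequence(
        frames, fps=params.fps, subject_id=f"sim{params.seed:08d}", group=group
    )


def generate_cohort(
    n_normal: int,
    n_gap: int,
    base: PhonationParams = PhonationParams(),
    gap_px: float = 4.0,
    between_subject_sd: float = 0.75,
    seed: int = 0,
    amplitude_cv: float = 0.25,
    vestige_cv: float = 0.15,
) -> list[tuple[MaskSequence, str]]:
    """Simulate a case-control cohort of recordings.

    The gap group draws a per-subject rear gap half-width from
    ``max(0, Normal(gap_px/2, between_subject_sd))``; the normal group has
    none.  Every subject gets its own rotation (uniform +-15 deg),
    translation (uniform +-8 px), f0 (uniform 190-225 Hz, the female
    speaking range), phase, and anatomical scaling of the opening amplitude
    and posterior vestige (lognormal multipliers with coefficients of
    variation ``amplitude_cv`` and ``vestige_cv``), all reproducible from
    ``seed``.
    """
    if n_normal < 0 or n_gap < 0:
        raise ValueError("subject counts must be >= 0")
    rng = np.random.default_rng(seed)
    out = []
    groups = ["normal"] * n_normal + ["gap"] * n_gap
    for k, grp in enumerate(groups):
        gap_hw = (
            max(0.0, rng.normal(gap_px / 2.0, between_subject_sd))
            if grp == "gap"
            else 0.0
        )
        params = replace(
            base,
            rear_gap_halfwidth=gap_hw,
            max_opening_halfwidth=base.max_opening_halfwidth
            * float(np.exp(rng.normal(0.0, amplitude_cv))),
            rear_vestige_halfwidth=base.rear_vestige_halfwidth
            * float(np.exp(rng.normal(0.0, vestige_cv))),
            rotation_deg=rng.uniform(-15.0, 15.0),
            translation=(rng.uniform(-8.0, 8.0), rng.uniform(-8.0, 8.0)),
            f0=rng.uniform(190.0, 225.0),
            phase=rng.uniform(0.0, 2.0 * np.pi),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        seq = generate_sequence(params)
        seq.subject_id = f"subj{k:03d}"
        seq.group = grp
        seq.meta = {
            "true_gap_px": 2.0 * gap_hw,
            "rotation_deg": params.rotation_deg,
            "f0": params.f0,
            "seed": params.seed,
        }
        out.append((seq, grp))
    return out
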