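"""Synthesis of dynamic-occlusion random-dot stimuli.

A stimulus consists of an irregular central disc of random dots that
translate coherently behind a static outline, surrounded by an annulus of
random dots whose frame-to-frame survival probability (temporal coherence)
is controlled independently.  Because the outline never moves, the only
depth-order cue in the display is the accretion-deletion of center dots at
the outline: dots are deleted at the leading edge of motion and fresh dots
accrete at the trailing edge.

Geometry and conventions
------------------------
* Coordinates are row-major, origin top-left, 0-based.
* ``motion_direction_deg`` is measured counter-clockwise from rightward
  motion, so 90 deg is upward (decreasing row index).
* Dots are single pixels, drawn i.i.d. Bernoulli(``dot_density``); a dot's
  two luminance levels are symmetric about ``mean_luminance`` so that
  contrast manipulations never change a region's mean luminance.
* Motion is sampled on the pixel grid: the per-frame displacement and both
  of its components must be integers; specs that would require sub-pixel
  motion are rejected rather than silently rounded.

Per-region random streams are derived independently from ``rng_seed`` so
that manipulating the surround (e.g. its temporal coherence) can never
perturb the center's pixel stream.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

__all__ = [
    "GeometryError",
    "StimulusSpec",
    "FrameSequence",
    "DEPTH_ORDER_MODELS",
    "DEFAULT_SWITCH_RATE",
    "make_center_mask",
    "make_surround_mask",
    "coherence_to_survival",
    "generate_sequence",
    "set_region_contrast",
    "measure_density",
    "measure_michelson",
    "measure_survival",
    "st_plot",
]

#: The two depth-order interpretations of the display: center far (F, the
#: center is occluded by the surround) or center near (N, the center
#: translates over the surround).
DEPTH_ORDER_MODELS = ("F", "N")

#: Per-pixel switch probability used by the explicit near-model generator
#: (and, by default, by the Ideal Observer's N model).
DEFAULT_SWITCH_RATE = 0.05

_OUTLINE_FREQS = (3, 4, 5, 6, 7)
_INT_TOL = 1e-6


class GeometryError(ValueError):
    """Raised when a stimulus geometry does not fit the frame."""


@dataclass(frozen=True)
class StimulusSpec:
    """Full parameterization of one stimulus movie.

    Defaults reproduce the study conditions: 50% dot density, Michelson
    contrast 1.0, a 6.2-deg-diameter center translating at 6 deg/s, 75 Hz
    frames for 4 s, and a static (100% temporally coherent) surround.  At
    25 px/deg and 75 Hz the 6 deg/s translation is exactly 2 px/frame.
    """

    frame_size_px: tuple[int, int] = (256, 256)
    pixels_per_degree: float = 25.0
    stimulus_diameter_deg: float = 6.2
    center_outline_seed: int = 0
    dot_density: float = 0.5
    center_contrast: float = 1.0
    surround_contrast: float = 1.0
    mean_luminance: float = 0.5
    center_speed_deg_per_s: float = 6.0
    motion_direction_deg: float = 90.0
    frame_rate_hz: float = 75.0
    duration_s: float = 4.0
    surround_temporal_coherence: float = 1.0
    outline_perturbation: float = 0.1
    rng_seed: int = 0

    # -- derived quantities -------------------------------------------------
    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.frame_rate_hz))

    @property
    def displacement_px(self) -> int:
        """Per-frame translation magnitude in pixels (exact integer)."""
        if self.center_speed_deg_per_s == 0:
            return 0
        d = self.center_speed_deg_per_s * self.pixels_per_degree / self.frame_rate_hz
        d_int = int(round(d))
        if d_int < 1 or abs(d - d_int) > _INT_TOL:
            raise GeometryError(
                f"per-frame displacement {d:.6g} px is not a positive integer; "
                "adjust speed, pixels_per_degree or frame_rate_hz"
            )
        return d_int

    @property
    def displacement_vector(self) -> tuple[int, int]:
        """(drow, dcol) per-frame displacement of the center texture."""
        d = self.displacement_px
        theta = np.deg2rad(self.motion_direction_deg)
        drow = -d * np.sin(theta)
        dcol = d * np.cos(theta)
        ri, ci = round(drow), round(dcol)
        if abs(drow - ri) > 1e-3 or abs(dcol - ci) > 1e-3:
            raise GeometryError(
                "motion direction must yield integer per-frame pixel "
                f"displacements; got ({drow:.3f}, {dcol:.3f})"
            )
        return int(ri), int(ci)

    def validate(self) -> None:
        h, w = self.frame_size_px
        if h < 2 or w < 2:
            raise GeometryError("frame must be at least 2x2 pixels")
        if not (0.0 < self.dot_density <= 1.0):
            raise ValueError("dot_density must be in (0, 1]")
        for name in ("center_contrast", "surround_contrast"):
            c = getattr(self, name)
            if not (0.0 <= c <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if not (0.0 < self.mean_luminance < 1.0):
            raise ValueError("mean_luminance must be in (0, 1)")
        if self.center_speed_deg_per_s < 0:
            raise ValueError("center_speed_deg_per_s must be non-negative")
        if self.frame_rate_hz <= 0 or self.duration_s <= 0:
            raise ValueError("frame_rate_hz and duration_s must be positive")
        coh = _coherence_as_fraction(self.surround_temporal_coherence)
        if not (0.5 <= coh <= 1.0):
            raise ValueError("surround_temporal_coherence must lie in [0.5, 1.0]")
        if self.stimulus_diameter_deg * self.pixels_per_degree > min(h, w):
            raise GeometryError("stimulus diameter exceeds the frame")
        # trigger integer-displacement checks
        self.displacement_px
        self.displacement_vector

    # -- luminance levels ---------------------------------------------------
    def region_levels(self, region: str) -> tuple[float, float]:
        """(off, on) luminance levels of a region, symmetric about the mean."""
        c = {"center": self.center_contrast, "surround": self.surround_contrast}[region]
        mu = self.mean_luminance
        return mu * (1.0 - c), mu * (1.0 + c)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["frame_size_px"] = list(self.frame_size_px)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusSpec":
        d = dict(d)
        d["frame_size_px"] = tuple(d["frame_size_px"])
        return cls(**d)


@dataclass
class FrameSequence:
    """An ordered stack of luminance frames plus static region labels.

    ``frames`` has shape (T, H, W) with values in [0, 1].  ``center_mask``
    and ``surround_mask`` are disjoint H x W booleans, constant over time
    (the center and surround never move relative to each other).
    ``hidden_texture`` is the underlying translating center texture,
    retained as ground truth for oracles; ``hidden_frame(t)`` samples it at
    frame ``t`` over the full frame extent.
    """

    frames: np.ndarray
    center_mask: np.ndarray
    surround_mask: np.ndarray
    spec: StimulusSpec
    hidden_texture: np.ndarray
    texture_origin: tuple[int, int]
    depth_model: str = "F"
    n_switch_rate: float = DEFAULT_SWITCH_RATE

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def region_mask(self, region: str) -> np.ndarray:
        try:
            return {"center": self.center_mask, "surround": self.surround_mask}[region]
        except KeyError:
            raise ValueError(f"unknown region {region!r}") from None

    def binary_states(self, t: int, region: str | None = None) -> np.ndarray:
        """Dot on/off states at frame ``t`` (optionally within one region)."""
        on = self.frames[t] > self.spec.mean_luminance
        if region is None:
            return on
        return on[self.region_mask(region)]

    def hidden_frame(self, t: int) -> np.ndarray:
        """Ground-truth center texture sampled at frame ``t`` (H x W bool)."""
        h, w = self.spec.frame_size_px
        drow, dcol = self.spec.displacement_vector
        oy, ox = self.texture_origin
        r0 = oy - t * drow
        c0 = ox - t * dcol
        return self.hidden_texture[r0 : r0 + h, c0 : c0 + w]


# ---------------------------------------------------------------------------
# geometry


def make_center_mask(
    frame_size_px: tuple[int, int],
    stimulus_diameter_deg: float,
    pixels_per_degree: float,
    center_outline_seed: int,
    outline_perturbation: float = 0.1,
) -> np.ndarray:
    """Irregular, simply-connected central disc.

    The outline is a radial-frequency perturbed circle,
    ``r(theta) = R * (1 + A * sum_k sin(k*theta + phi_k))`` with low
    frequencies k in {3..7} and phases drawn from ``center_outline_seed``.
    ``outline_perturbation`` A = 0 gives an exact circular disc.  Because
    r(theta) stays positive, the region is star-shaped about the frame
    center and hence simply connected.
    """
    h, w = frame_size_px
    radius = stimulus_diameter_deg * pixels_per_degree / 2.0
    if 2 * radius > min(h, w):
        raise GeometryError(
            f"stimulus diameter {2 * radius:.1f} px exceeds frame {frame_size_px}"
        )
    rng = np.random.default_rng(center_outline_seed)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=len(_OUTLINE_FREQS))

    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    rows = np.arange(h)[:, None] - cy
    cols = np.arange(w)[None, :] - cx
    dist = np.hypot(rows, cols)
    theta = np.arctan2(-rows, cols)  # y-axis up
    perturb = np.zeros_like(theta)
    for k, phi in zip(_OUTLINE_FREQS, phases):
        perturb += np.sin(k * theta + phi)
    r_theta = radius * (1.0 + outline_perturbation * perturb)
    return dist < r_theta


def make_surround_mask(
    center_mask: np.ndarray, frame_size_px: tuple[int, int], margin_px: int = 2
) -> np.ndarray:
    """Annulus from the center outline to the largest circle in the frame."""
    h, w = frame_size_px
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    rows = np.arange(h)[:, None] - cy
    cols = np.arange(w)[None, :] - cx
    dist = np.hypot(rows, cols)
    outer = min(h, w) / 2.0 - margin_px
    return (dist <= outer) & ~center_mask


def _coherence_as_fraction(value: float) -> float:
    """Accept coherence either as a fraction in [0.5, 1] or percent in [50, 100]."""
    if 50.0 <= value <= 100.0:
        return value / 100.0
    return float(value)


def coherence_to_survival(surround_temporal_coherence: float) -> float:
    """Map temporal coherence to a per-frame dot survival probability.

    The mapping is the identity: 100% coherence means static dots (survival
    1.0) and 50% coherence means random flicker (survival 0.5).  Accepts
    fractions in [0.5, 1.0] or percentages in [50, 100].
    """
    s = _coherence_as_fraction(surround_temporal_coherence)
    if not (0.5 <= s <= 1.0):
        raise ValueError(
            "temporal coherence must lie in [0.5, 1.0] (or [50, 100] percent); "
            f"got {surround_temporal_coherence!r}"
        )
    return s


# ---------------------------------------------------------------------------
# generation


def generate_sequence(
    spec: StimulusSpec,
    depth_model: str = "F",
    n_switch_rate: float = DEFAULT_SWITCH_RATE,
) -> FrameSequence:
    """Synthesize a stimulus movie from a :class:`StimulusSpec`.

    Under the default far model (``depth_model="F"``) the center subimage is
    a hidden texture translating behind the static outline: dots crossing
    the leading boundary are deleted and fresh dots accrete at the trailing
    boundary.  Surround dots survive each frame with probability equal to
    the temporal coherence; non-survivors are resampled at ``dot_density``.

    ``depth_model="N"`` produces the explicit near-model counterpart used
    to test the Ideal Observer: identical except that pixels in the
    deletion band (area 3) *persist*, keeping their previous state and
    switching with probability ``n_switch_rate``, as a near, un-occluded
    surface's dots would.

    Deterministic given ``spec.rng_seed``; the center, surround and
    near-model streams are independent, so specs differing only in
    surround parameters share a bit-identical center stream.
    """
    spec.validate()
    if depth_model not in DEPTH_ORDER_MODELS:
        raise ValueError(f"depth_model must be one of {DEPTH_ORDER_MODELS}")

    h, w = spec.frame_size_px
    n_frames = spec.n_frames
    drow, dcol = spec.displacement_vector

    center_mask = make_center_mask(
        spec.frame_size_px,
        spec.stimulus_diameter_deg,
        spec.pixels_per_degree,
        spec.center_outline_seed,
        spec.outline_perturbation,
    )
    surround_mask = make_surround_mask(center_mask, spec.frame_size_px)

    ss = np.random.SeedSequence(spec.rng_seed)
    child_tex, child_sur, child_n = ss.spawn(3)
    rng_tex = np.random.default_rng(child_tex)
    rng_sur = np.random.default_rng(child_sur)
    rng_n = np.random.default_rng(child_n)

    # Hidden texture large enough to cover the frame over the whole movie.
    span_r = abs(drow) * (n_frames - 1)
    span_c = abs(dcol) * (n_frames - 1)
    tex = rng_tex.random((h + span_r, w + span_c)) < spec.dot_density
    origin = (max(0, drow * (n_frames - 1)), max(0, dcol * (n_frames - 1)))

    ci, cj = np.nonzero(center_mask)
    ci_flat = np.flatnonzero(center_mask.ravel())
    si = np.flatnonzero(surround_mask.ravel())
    n_sur = si.size
    survival = coherence_to_survival(spec.surround_temporal_coherence)

    c_off, c_on = spec.region_levels("center")
    s_off, s_on = spec.region_levels("surround")

    if depth_model == "N":
        from .ideal_observer import area3  # local import to avoid a cycle

        a3 = area3(center_mask, spec.displacement_px, spec.motion_direction_deg)
        a3_in_center = a3.pixels[center_mask]  # boolean over center pixel list

    frames = np.full((n_frames, h, w), spec.mean_luminance, dtype=np.float32)
    oy, ox = origin
    prev_center = None
    sur_states = rng_sur.random(n_sur) < spec.dot_density
    for t in range(n_frames):
        center_states = tex[ci + (oy - t * drow), cj + (ox - t * dcol)]
        if depth_model == "N" and t > 0:
            switches = rng_n.random(int(a3_in_center.sum())) < n_switch_rate
            center_states = center_states.copy()
            center_states[a3_in_center] = prev_center[a3_in_center] ^ switches
        if t > 0:
            survives = rng_sur.random(n_sur) < survival
            fresh = rng_sur.random(n_sur) < spec.dot_density
            sur_states = np.where(survives, sur_states, fresh)
        frame = frames[t].ravel()
        frame[ci_flat] = np.where(center_states, c_on, c_off).astype(np.float32)
        frame[si] = np.where(sur_states, s_on, s_off).astype(np.float32)
        prev_center = center_states

    return FrameSequence(
        frames=frames,
        center_mask=center_mask,
        surround_mask=surround_mask,
        spec=spec,
        hidden_texture=tex,
        texture_origin=origin,
        depth_model=depth_model,
        n_switch_rate=n_switch_rate,
    )


# ---------------------------------------------------------------------------
# manipulations and probes


def set_region_contrast(
    sequence: FrameSequence, region: str, new_contrast: float
) -> FrameSequence:
    """Return a copy with one region's Michelson contrast changed.

    Dot luminances are compressed toward ``mean_luminance`` so that the
    region's two levels become ``mu * (1 -/+ new_contrast)``; the on/off
    pattern and its dynamics are untouched (in particular, surround flicker
    is unaffected by contrast manipulations).
    """
    if not (0.0 <= new_contrast <= 1.0):
        raise ValueError("new_contrast must be in [0, 1]")
    mask = sequence.region_mask(region)  # raises on unknown region
    spec = sequence.spec
    old = {"center": spec.center_contrast, "surround": spec.surround_contrast}[region]
    if old == 0.0:
        raise ValueError("cannot rescale a region generated at zero contrast")
    mu = spec.mean_luminance
    frames = sequence.frames.copy()
    sub = frames[:, mask]
    frames[:, mask] = (mu + (sub - mu) * (new_contrast / old)).astype(frames.dtype)
    new_spec = dataclasses.replace(spec, **{f"{region}_contrast": new_contrast})
    return dataclasses.replace(sequence, frames=frames, spec=new_spec)


def measure_density(sequence: FrameSequence, region: str) -> float:
    """Fraction of region pixels in the 'dot on' state, pooled over frames."""
    mask = sequence.region_mask(region)
    if not mask.any():
        raise ValueError(f"region {region!r} is empty")
    return float((sequence.frames[:, mask] > sequence.spec.mean_luminance).mean())


def measure_michelson(sequence: FrameSequence, region: str) -> float:
    """Michelson contrast (Lmax - Lmin) / (Lmax + Lmin) of a region."""
    mask = sequence.region_mask(region)
    if not mask.any():
        raise ValueError(f"region {region!r} is empty")
    vals = sequence.frames[:, mask]
    lmax, lmin = float(vals.max()), float(vals.min())
    if lmax + lmin == 0:
        return 0.0
    return (lmax - lmin) / (lmax + lmin)


def measure_survival(sequence: FrameSequence) -> float:
    """Estimate the surround dots' per-frame survival probability.

    Raw consecutive-frame pixel agreement ``a`` overestimates survival
    because non-surviving dots can be resampled into the same state; with
    density d the chance-match rate is ``m = d**2 + (1 - d)**2`` and the
    estimate inverts ``a = s + (1 - s) * m``.
    """
    if sequence.n_frames < 2:
        raise ValueError("need at least two frames to estimate survival")
    mask = sequence.surround_mask
    if not mask.any():
        raise ValueError("surround region is empty")
    states = sequence.frames[:, mask] > sequence.spec.mean_luminance
    a = float((states[1:] == states[:-1]).mean())
    d = sequence.spec.dot_density
    m = d * d + (1.0 - d) * (1.0 - d)
    return (a - m) / (1.0 - m)


def st_plot(
    sequence: FrameSequence, column_band: tuple[int, int] | None = None
) -> np.ndarray:
    """Space-time plot: rows are time, columns are space along the motion axis.

    The band of pixel lines perpendicular to the motion axis selected by
    ``column_band`` (half-open index interval, default the central line) is
    averaged.  Moving center dots trace oblique lines of slope 1/v frames
    per pixel; static surround dots trace lines parallel to the time axis.
    """
    drow, dcol = sequence.spec.displacement_vector
    h, w = sequence.spec.frame_size_px
    vertical_motion = abs(drow) >= abs(dcol)
    extent = w if vertical_motion else h
    if column_band is None:
        mid = extent // 2
        column_band = (mid, mid + 1)
    lo, hi = column_band
    if not (0 <= lo < hi <= extent):
        raise ValueError(f"column band {column_band} outside frame")
    if vertical_motion:
        return np.asarray(sequence.frames[:, :, lo:hi].mean(axis=2))
    return np.asarray(sequence.frames[:, lo:hi, :].mean(axis=1))
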