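"""Looming-stimulus kinematics and receptive-field coverage.

A dark disc simulating an approaching object grows as
``theta(t) = 2 atan(l / (v |t|))`` for constant approach velocity (t = 0 is
the theoretical contact time, where the object would subtend 180 deg), or
linearly as ``theta(t) = v_a t`` for constant angular velocity.  Coverage of
a cell's receptive field by the stimulus at maximum size is computed as an
area fraction on the tangent plane at the RF centre (stimuli of <= 30 deg
keep the spherical excess below the model's fidelity).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

_GOLDEN = np.pi * (3.0 - np.sqrt(5.0))


@dataclass(frozen=True)
class LoomingStimulus:
    """A looming disc (or vertical disc array) in eye coordinates."""

    mode: str = "constant_velocity"  # or "constant_angular_velocity"
    l: float = 0.01  # virtual object radius (length units)
    v: float = 0.5  # approach speed (length/time)
    v_a: float = 500.0  # angular velocity (deg/s)
    centre: tuple = (0.0, 0.0)  # (azimuth, elevation) deg
    max_diameter_deg: float = 180.0
    n_discs: int = 1
    disc_spacing_deg: float = 0.0

    def __post_init__(self):
        if self.mode not in ("constant_velocity", "constant_angular_velocity"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "constant_velocity" and (self.l <= 0 or self.v <= 0):
            raise ValueError("l and v must be positive in constant_velocity mode")
        if self.mode == "constant_angular_velocity" and self.v_a <= 0:
            raise ValueError("v_a must be positive in constant_angular_velocity mode")
        if not 0 < self.max_diameter_deg <= 180:
            raise ValueError("max diameter must be in (0, 180]")
        if self.n_discs < 1:
            raise ValueError("need at least one disc")

    def disc_centres(self) -> np.ndarray:
        """(azimuth, elevation) of each disc in the vertical array."""
        az, el = self.centre
        offsets = (np.arange(self.n_discs) - (self.n_discs - 1) / 2) * self.disc_spacing_deg
        return np.column_stack([np.full(self.n_discs, az), el + offsets])

    def recentred(self, azimuth: float, elevation: float | None = None) -> "LoomingStimulus":
        el = self.centre[1] if elevation is None else elevation
        return dataclasses.replace(self, centre=(azimuth, el))


def angular_size(stim: LoomingStimulus, t: float) -> float:
    """Angular diameter (degrees) of the stimulus at time t.

    Constant-velocity looming is defined for t < 0 only (pre-contact) and
    grows toward 180 deg as t -> 0-. Constant-angular-velocity looming grows
    linearly from 0 at t = 0. Sizes are clamped to the maximum diameter.
    """
    if stim.mode == "constant_velocity":
        if t >= 0:
            raise ValueError("constant-velocity looming undefined at or after contact (t >= 0)")
        theta = np.degrees(2.0 * np.arctan(stim.l / (stim.v * abs(t))))
    else:
        theta = stim.v_a * max(t, 0.0)
    return float(min(theta, stim.max_diameter_deg))


def _lens_area(r1: float, r2: float, d: float) -> float:
    """Intersection area of two discs with radii r1, r2 at centre distance d."""
    if d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2):
        r = min(r1, r2)
        return np.pi * r * r
    a1 = r1 * r1 * np.arccos((d * d + r1 * r1 - r2 * r2) / (2 * d * r1))
    a2 = r2 * r2 * np.arccos((d * d + r2 * r2 - r1 * r1) / (2 * d * r2))
    tri = 0.5 * np.sqrt(max(0.0, (-d + r1 + r2) * (d + r1 - r2) * (d - r1 + r2) * (d + r1 + r2)))
    return float(a1 + a2 - tri)


def _fibonacci_disc(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic quasi-uniform points on the unit disc (sunflower spiral)."""
    i = np.arange(n) + 0.5
    r = np.sqrt(i / n)
    th = i * _GOLDEN
    return r * np.cos(th), r * np.sin(th)


def overlap_fraction(
    rf,
    stim: LoomingStimulus,
    coverage_mode: str = "area",
    n_quad: int = 10_000,
) -> float:
    """Fraction of a Gaussian RF covered by the stimulus at maximum size.

    The RF is represented by its equivalent disc of radius sigma centred at
    the RF centre; geometry is planar on the tangent plane at that centre
    (azimuth differences scaled by cos(elevation)).  ``coverage_mode``
    "area" (default) returns the covered area fraction of the sigma-disc;
    "gaussian" weights coverage by the Gaussian mass instead.
    """
    sigma = float(rf.sigma_deg)
    if sigma <= 0:
        raise ValueError("RF sigma must be positive")
    az0, el0 = rf.centre
    cos_el = np.cos(np.deg2rad(el0))
    r_stim = stim.max_diameter_deg / 2.0
    discs = stim.disc_centres()
    centres = np.column_stack([(discs[:, 0] - az0) * cos_el, discs[:, 1] - el0])
    dists = np.linalg.norm(centres, axis=1)

    if coverage_mode == "area":
        if len(centres) == 1:
            return _lens_area(sigma, r_stim, dists[0]) / (np.pi * sigma * sigma)
        # pairwise-disjoint stimulus discs: inclusion-exclusion is exact
        sep = True
        for i in range(len(centres)):
            for j in range(i + 1, len(centres)):
                if np.linalg.norm(centres[i] - centres[j]) < 2 * r_stim:
                    sep = False
        if sep:
            total = sum(_lens_area(sigma, r_stim, d) for d in dists)
            return float(min(1.0, total / (np.pi * sigma * sigma)))
        # overlapping array: quasi-random quadrature over the RF disc
        x, y = _fibonacci_disc(n_quad)
        x, y = x * sigma, y * sigma
        inside = np.zeros(n_quad, bool)
        for c in centres:
            inside |= (x - c[0]) ** 2 + (y - c[1]) ** 2 <= r_stim * r_stim
        return float(inside.mean())
    elif coverage_mode == "gaussian":
        # Gaussian-mass weighting, sampled out to 3 sigma
        x, y = _fibonacci_disc(n_quad)
        x, y = x * 3 * sigma, y * 3 * sigma
        w = np.exp(-(x * x + y * y) / (2 * sigma * sigma))
        inside = np.zeros(n_quad, bool)
        for c in centres:
            inside |= (x - c[0]) ** 2 + (y - c[1]) ** 2 <= r_stim * r_stim
        return float(w[inside].sum() / w.sum())
    raise ValueError(f"unknown coverage_mode {coverage_mode!r}")


def fig_style_array(azimuth: float, pitch_deg: float = -20.0) -> LoomingStimulus:
    """Three-disc vertical looming array (each disc expanding 0-30 deg at
    500 deg/s), centred at ``azimuth`` with the stimulus plane pitched down."""
    return LoomingStimulus(
        mode="constant_angular_velocity",
        v_a=500.0,
        centre=(azimuth, pitch_deg),
        max_diameter_deg=30.0,
        n_discs=3,
        disc_spacing_deg=30.0,
    )
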