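"""Numerosity dot-display construction and run-sequence scheduling.

Displays are clouds of equal-sized dots confined to a small circular field
(radius 0.75 deg) around fixation.  Total dot surface area is held constant
across numerosities, so display luminance does not covary with dot count;
the spatial-frequency content of the image then becomes the stimulus
quantity that tracks numerosity (see :func:`aggregate_fourier_power`).

A scanning run interleaves, within every 1.4 s volume (TR), an *adaptor*
display and a *changing* display.  The changing numerosity sweeps 1..7 and
back with long 20-dot baselines; the adaptor defines the condition (constant
1, constant 20, or yoked to the changing numerosity).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "DotDisplay",
    "RunSequence",
    "DEFAULT_FIELD_RADIUS",
    "DEFAULT_TOTAL_AREA",
    "generate_dot_display",
    "rasterize",
    "aggregate_fourier_power",
    "mean_power_table",
    "build_run_sequence",
    "events_table",
    "display_to_table",
    "save_display_png",
]

#: Radius of the circular stimulus field, degrees of visual angle.
DEFAULT_FIELD_RADIUS = 0.75

#: Total dot surface area (deg^2), chosen so a single dot has a 0.5 deg
#: diameter — comfortably inside the 0.75 deg field.
DEFAULT_TOTAL_AREA = math.pi * 0.25**2

#: Minimum centre spacing as a multiple of the dot radius.
DEFAULT_SPACING_FACTOR = 2.2

TR_SECONDS = 1.4
#: Within-TR event timing (seconds): adaptor display, blank, changing
#: display, blank.
WITHIN_TR_TIMING = {"adaptor": (0.0, 0.3), "changing": (0.7, 0.3)}

CONDITIONS = ("low", "high", "changing")

_MAX_PLACEMENT_TRIES = 10_000
_MAX_RESTARTS = 50


@dataclass(frozen=True)
class DotDisplay:
    """One numerosity frame: equal-sized dots inside the stimulus field."""

    numerosity: int
    dot_centres: np.ndarray  # (n, 2) degrees, origin at fixation, y up
    dot_radius: float  # degrees
    colour: str = "black"  # {"black", "white"}
    field_radius: float = DEFAULT_FIELD_RADIUS

    def __post_init__(self) -> None:
        centres = np.asarray(self.dot_centres, dtype=float).reshape(-1, 2)
        object.__setattr__(self, "dot_centres", centres)
        if self.numerosity != len(centres):
            raise ValueError(
                f"numerosity {self.numerosity} != {len(centres)} centres"
            )
        if self.colour not in ("black", "white"):
            raise ValueError(f"colour must be black or white, got {self.colour!r}")
        dist = np.hypot(centres[:, 0], centres[:, 1])
        if np.any(dist + self.dot_radius > self.field_radius + 1e-12):
            raise ValueError("dot disc extends beyond the stimulus field")

    @property
    def total_area(self) -> float:
        """Summed dot surface area (deg^2)."""
        return self.numerosity * math.pi * self.dot_radius**2


@dataclass(frozen=True)
class RunSequence:
    """Per-TR (adaptor, changing) numerosity schedule for one condition."""

    condition: str
    adaptor_n: np.ndarray  # (n_trs,) int
    changing_n: np.ndarray  # (n_trs,) int
    adaptor_oddball: np.ndarray  # (n_trs,) bool — white-dot presentations
    changing_oddball: np.ndarray
    tr_seconds: float = TR_SECONDS

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        n = len(self.changing_n)
        for name in ("adaptor_n", "adaptor_oddball", "changing_oddball"):
            if len(getattr(self, name)) != n:
                raise ValueError("sequence arrays have mismatched lengths")

    @property
    def n_trs(self) -> int:
        return len(self.changing_n)

    @property
    def duration_s(self) -> float:
        return self.n_trs * self.tr_seconds


def _dot_radius(numerosity: int, total_area: float) -> float:
    return math.sqrt(total_area / (numerosity * math.pi))


def generate_dot_display(
    numerosity: int,
    total_area: float = DEFAULT_TOTAL_AREA,
    seed: int | np.random.Generator = 0,
    min_spacing: float | None = None,
    field_radius: float = DEFAULT_FIELD_RADIUS,
    colour: str = "black",
) -> DotDisplay:
    """Place ``numerosity`` equal-area dots pseudo-randomly in the field.

    Dot radius is fixed analytically by the constant-total-area rule,
    ``r = sqrt(total_area / (n * pi))``.  Centres are drawn by rejection
    sampling: uniform in the disc of radius ``field_radius - r`` (so every
    dot lies fully inside the field), rejecting proposals closer than
    ``min_spacing`` (default ``2.2 * r``) to any accepted centre, which
    spreads the dots out and avoids perceptual grouping.

    Raises
    ------
    ValueError
        If the packing is infeasible after a bounded number of restarts.
    """
    if numerosity < 1:
        raise ValueError("numerosity must be >= 1")
    rng = np.random.default_rng(seed)
    r = _dot_radius(numerosity, total_area)
    if min_spacing is None:
        min_spacing = DEFAULT_SPACING_FACTOR * r
    max_c = field_radius - r
    if max_c < 0:
        raise ValueError(
            f"dot radius {r:.3f} deg exceeds field radius {field_radius} deg"
        )
    min_sq = min_spacing**2
    for _ in range(_MAX_RESTARTS):
        centres = np.empty((numerosity, 2))
        placed = 0
        tries = 0
        while placed < numerosity and tries < _MAX_PLACEMENT_TRIES:
            tries += 1
            p = rng.uniform(-max_c, max_c, size=2)
            if p[0] ** 2 + p[1] ** 2 > max_c**2:
                continue
            if placed:
                d2 = np.sum((centres[:placed] - p) ** 2, axis=1)
                if d2.min() < min_sq:
                    continue
            centres[placed] = p
            placed += 1
        if placed == numerosity:
            return DotDisplay(
                numerosity=numerosity,
                dot_centres=centres,
                dot_radius=r,
                colour=colour,
                field_radius=field_radius,
            )
    raise ValueError(
        f"could not place {numerosity} dots of radius {r:.3f} deg with "
        f"min spacing {min_spacing:.3f} deg in a {field_radius} deg field"
    )


def rasterize(
    display: DotDisplay,
    pixels_per_degree: int = 64,
    image_extent: float = 2.0,
    background: float = 0.5,
) -> np.ndarray:
    """Render a display to a square luminance image.

    Black dots are drawn at 0.0, white (oddball) dots at 1.0, on a
    ``background`` grey.  The image spans ``image_extent`` degrees on each
    side, row-major with row 0 at the top (+y) and the origin (fixation) at
    the image centre; pixel centres sit on a half-integer grid.
    """
    if pixels_per_degree <= 0:
        raise ValueError("pixels_per_degree must be positive")
    if image_extent / 2 < display.field_radius:
        raise ValueError(
            f"image extent {image_extent} deg does not cover the "
            f"{display.field_radius} deg stimulus field"
        )
    n_px = int(round(pixels_per_degree * image_extent))
    ax = (np.arange(n_px) + 0.5) / pixels_per_degree - image_extent / 2
    xs, ys = np.meshgrid(ax, -ax)  # row 0 at +y
    img = np.full((n_px, n_px), background, dtype=float)
    level = 0.0 if display.colour == "black" else 1.0
    r2 = display.dot_radius**2
    for cx, cy in display.dot_centres:
        img[(xs - cx) ** 2 + (ys - cy) ** 2 <= r2] = level
    return img


def aggregate_fourier_power(image: np.ndarray, method: str = "amplitude") -> float:
    """Aggregate spatial-frequency content of a display image.

    The image mean (DC component) is removed, then the 2-D FFT magnitudes
    are summed over all remaining frequency bins.  ``method="amplitude"``
    (default) sums ``|F|``; ``method="energy"`` sums ``|F|^2``.

    At fixed total dot area the pixel-value histogram is nearly independent
    of numerosity, so by Parseval the squared sum is too; the magnitude sum
    instead grows as the dots shrink and the spectrum broadens, and is the
    quantity that follows numerosity closely.  Both are exposed so the
    aggregation is a one-line config switch.
    """
    image = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    spectrum = np.abs(np.fft.fft2(image - image.mean()))
    if method == "amplitude":
        return float(spectrum.sum())
    if method == "energy":
        return float((spectrum**2).sum())
    raise ValueError(f"unknown method {method!r}")


def mean_power_table(
    numerosities: Iterable[int] = (1, 2, 3, 4, 5, 6, 7, 20),
    total_area: float = DEFAULT_TOTAL_AREA,
    n_seeds: int = 20,
    seed: int = 0,
    method: str = "amplitude",
    pixels_per_degree: int = 64,
    image_extent: float = 2.0,
) -> dict[int, float]:
    """Mean aggregate Fourier power per numerosity over fresh random displays.

    This is the numerosity -> power lookup used by the monotonic response
    model in its log-power mode.
    """
    rng = np.random.default_rng(seed)
    table: dict[int, float] = {}
    for n in numerosities:
        vals = []
        for _ in range(n_seeds):
            disp = generate_dot_display(n, total_area=total_area, seed=rng)
            img = rasterize(disp, pixels_per_degree, image_extent)
            vals.append(aggregate_fourier_power(img, method=method))
        table[int(n)] = float(np.mean(vals))
    return table


def _changing_cycle() -> np.ndarray:
    """One 66-TR cycle: 1..7 ascending at 3 TRs each, 12 TRs of 20,
    7..1 descending at 3 TRs each, 12 TRs of 20."""
    asc = np.repeat(np.arange(1, 8), 3)
    base = np.full(12, 20)
    return np.concatenate([asc, base, asc[::-1], base])


def build_run_sequence(
    condition: str,
    oddball_fraction: float = 0.10,
    seed: int = 0,
    n_cycles: int = 4,
) -> RunSequence:
    """Build the per-TR schedule for one scanning run of one condition.

    The changing-numerosity schedule is identical across conditions (four
    66-TR cycles, 264 TRs, 369.6 s).  The adaptor is constant 1 (``low``),
    constant 20 (``high``), or a copy of the changing schedule
    (``changing``).  Each display is independently flagged as a white
    "oddball" with probability ``oddball_fraction``; oddballs serve the
    in-scanner attention task and are excluded from response predictors.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}, got {condition!r}")
    changing = np.tile(_changing_cycle(), n_cycles)
    if condition == "low":
        adaptor = np.ones_like(changing)
    elif condition == "high":
        adaptor = np.full_like(changing, 20)
    else:
        adaptor = changing.copy()
    rng = np.random.default_rng(seed)
    odd_a = rng.random(len(changing)) < oddball_fraction
    odd_c = rng.random(len(changing)) < oddball_fraction
    return RunSequence(
        condition=condition,
        adaptor_n=adaptor,
        changing_n=changing,
        adaptor_oddball=odd_a,
        changing_oddball=odd_c,
    )


def events_table(seq: RunSequence) -> pd.DataFrame:
    """BIDS-style events table: onset_s, duration_s, role, numerosity, oddball."""
    rows = []
    for t in range(seq.n_trs):
        t0 = t * seq.tr_seconds
        for role, (offset, dur) in WITHIN_TR_TIMING.items():
            n = seq.adaptor_n[t] if role == "adaptor" else seq.changing_n[t]
            odd = (
                seq.adaptor_oddball[t] if role == "adaptor" else seq.changing_oddball[t]
            )
            rows.append(
                {
                    "onset_s": round(t0 + offset, 6),
                    "duration_s": dur,
                    "role": role,
                    "numerosity": int(n),
                    "oddball": bool(odd),
                }
            )
    return pd.DataFrame(rows)


def display_to_table(display: DotDisplay) -> pd.DataFrame:
    """One row per dot: x_deg, y_deg, radius_deg, colour."""
    return pd.DataFrame(
        {
            "x_deg": display.dot_centres[:, 0],
            "y_deg": display.dot_centres[:, 1],
            "radius_deg": display.dot_radius,
            "colour": display.colour,
        }
    )


def save_display_png(display: DotDisplay, path, **raster_kwargs) -> None:
    """Rasterize and save a display as a greyscale PNG."""
    import matplotlib.image

    img = rasterize(display, **raster_kwargs)
    matplotlib.image.imsave(path, img, cmap="gray", vmin=0.0, vmax=1.0)
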