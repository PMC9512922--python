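"""Raw-frame correction and calibration chain.

Converts the five raw frames of an imaging session (probe, dark, pre-injection
background, uniform phantom, Rhodamine B standard) into a calibrated
fluorescence image — the 60-minute summary parameter (2-NBDG60 or TMRE60)
used by all downstream statistics.  The chain is

1. dark + background subtraction (scalar means),
2. flat-field correction against the smoothed, unit-mean phantom,
3. division by the session's Rhodamine B calibration factor,

which removes autofluorescence, the non-uniform (Gaussian) illumination
profile, and day-to-day system gain respectively.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "ImagingSession",
    "CalibratedImage",
    "subtract_dark_background",
    "flatfield_correct",
    "calibrate",
    "process_session",
]

_FRAME_ROLES = (
    "probe_frame",
    "dark_frame",
    "background_frame",
    "phantom_frame",
    "rhodamine_frame",
)


@dataclass
class ImagingSession:
    """One probe/timepoint acquisition: five co-dimensional raw frames."""

    probe_frame: np.ndarray
    dark_frame: np.ndarray
    background_frame: np.ndarray
    phantom_frame: np.ndarray
    rhodamine_frame: np.ndarray
    probe: str = "NBDG"
    mouse_id: str = ""
    timepoint: str = ""
    session_date: str = ""
    # exposure times are metadata only; no exposure normalization is applied
    exposure_s: float | None = None

    def __post_init__(self) -> None:
        shapes = set()
        for role in _FRAME_ROLES:
            frame = getattr(self, role)
            if frame is None:
                raise ValueError(f"session is missing its {role}")
            frame = np.asarray(frame, dtype=float)
            if frame.size == 0:
                raise ValueError(f"{role} is empty")
            setattr(self, role, frame)
            shapes.add(frame.shape)
        if len(shapes) != 1:
            raise ValueError(f"frame dimensions differ across roles: {shapes}")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.probe_frame.shape


@dataclass
class CalibratedImage:
    """Pixel field of a summary parameter in calibrated fluorescence units."""

    pixels: np.ndarray
    probe: str
    mouse_id: str = ""
    timepoint: str = ""
    valid_mask: np.ndarray | None = None
    qc_flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.pixels.shape, dtype=bool)

    @property
    def valid_pixels(self) -> np.ndarray:
        return self.pixels[self.valid_mask]


def _check_codimensional(*frames: np.ndarray) -> None:
    shapes = {np.asarray(f).shape for f in frames}
    if len(shapes) != 1:
        raise ValueError(f"frames are not co-dimensional: {shapes}")


def subtract_dark_background(
    probe_frame: np.ndarray,
    dark_frame: np.ndarray,
    background_frame: np.ndarray,
    *,
    clip_negative: bool = True,
) -> tuple[np.ndarray, float]:
    """Remove the scalar dark mean, then the scalar dark-corrected background
    mean.

    Returns ``(image, clipped_fraction)``.  Negative pixels are clipped to 0
    (pixel distributions downstream need nonnegative support); the clipped
    fraction is reported for QC.
    """
    probe_frame = np.asarray(probe_frame, dtype=float)
    dark_frame = np.asarray(dark_frame, dtype=float)
    background_frame = np.asarray(background_frame, dtype=float)
    for name, f in (
        ("probe", probe_frame),
        ("dark", dark_frame),
        ("background", background_frame),
    ):
        if f.size == 0:
            raise ValueError(f"{name} frame is empty")
    _check_codimensional(probe_frame, dark_frame, background_frame)
    dark_mean = float(dark_frame.mean())
    background_mean = float(background_frame.mean() - dark_mean)
    out = probe_frame - dark_mean - background_mean
    clipped = 0.0
    if clip_negative:
        negative = out < 0
        clipped = float(negative.mean())
        out = np.where(negative, 0.0, out)
    return out, clipped


def _normalized_phantom(
    phantom_frame: np.ndarray,
    dark_frame: np.ndarray,
    sigma: float,
) -> np.ndarray:
    """Dark-subtract, smooth, and normalize the phantom to unit mean."""
    phantom = np.asarray(phantom_frame, dtype=float) - float(
        np.asarray(dark_frame, dtype=float).mean()
    )
    if sigma > 0:
        phantom = ndimage.gaussian_filter(phantom, sigma=sigma)
    mean = phantom.mean()
    if mean <= 0:
        raise ValueError("phantom frame is nonpositive after dark subtraction")
    return phantom / mean


def flatfield_correct(
    image: np.ndarray,
    phantom_frame: np.ndarray,
    dark_frame: np.ndarray,
    *,
    sigma: float = 5.0,
    epsilon: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Divide out the beam shape.

    The phantom is dark-subtracted, Gaussian-smoothed (``sigma`` pixels, to
    avoid amplifying phantom shot noise) and normalized to unit mean.  Pixels
    where the normalized phantom falls below ``epsilon`` are flagged invalid
    and left undivided.  Returns ``(corrected, valid_mask)``.
    """
    image = np.asarray(image, dtype=float)
    _check_codimensional(image, phantom_frame, dark_frame)
    phantom = _normalized_phantom(phantom_frame, dark_frame, sigma)
    valid = phantom >= epsilon
    out = image.copy()
    out[valid] = image[valid] / phantom[valid]
    return out, valid


def calibrate(
    image: np.ndarray,
    rhodamine_frame: np.ndarray,
    dark_frame: np.ndarray,
    phantom_frame: np.ndarray,
    *,
    sigma: float = 5.0,
    epsilon: float = 0.05,
    summary: str = "mean",
) -> tuple[np.ndarray, float]:
    """Divide by the session's Rhodamine B factor to remove day-to-day gain.

    The factor is the mean (configurable to median) of the dark-subtracted,
    flat-fielded Rhodamine frame over its valid pixels.  Returns
    ``(calibrated, factor)``.
    """
    image = np.asarray(image, dtype=float)
    rho = np.asarray(rhodamine_frame, dtype=float) - float(
        np.asarray(dark_frame, dtype=float).mean()
    )
    rho_flat, valid = flatfield_correct(
        rho, phantom_frame, dark_frame, sigma=sigma, epsilon=epsilon
    )
    reducer = np.median if summary == "median" else np.mean
    factor = float(reducer(rho_flat[valid]))
    if factor <= 0:
        raise ValueError("Rhodamine calibration factor is nonpositive")
    return image / factor, factor


def process_session(
    session: ImagingSession,
    *,
    phantom_sigma: float = 5.0,
    epsilon: float = 0.05,
    rhodamine_summary: str = "mean",
) -> CalibratedImage:
    """Full correction chain: subtraction -> flat field -> calibration."""
    try:
        corrected, clipped_fraction = subtract_dark_background(
            session.probe_frame, session.dark_frame, session.background_frame
        )
    except ValueError as err:
        raise ValueError(f"dark/background subtraction failed: {err}") from err
    try:
        flat, valid = flatfield_correct(
            corrected,
            session.phantom_frame,
            session.dark_frame,
            sigma=phantom_sigma,
            epsilon=epsilon,
        )
    except ValueError as err:
        raise ValueError(f"flat-field correction failed: {err}") from err
    try:
        calibrated, factor = calibrate(
            flat,
            session.rhodamine_frame,
            session.dark_frame,
            session.phantom_frame,
            sigma=phantom_sigma,
            epsilon=epsilon,
            summary=rhodamine_summary,
        )
    except ValueError as err:
        raise ValueError(f"Rhodamine calibration failed: {err}") from err
    invalid_fraction = float(1.0 - valid.mean())
    if clipped_fraction > 0.05:
        warnings.warn(
            f"{clipped_fraction:.1%} of pixels clipped to zero after "
            "background subtraction",
            stacklevel=2,
        )
    return CalibratedImage(
        pixels=calibrated,
        probe=session.probe,
        mouse_id=session.mouse_id,
        timepoint=session.timepoint,
        valid_mask=valid,
        qc_flags={
            "clipped_fraction": clipped_fraction,
            "invalid_fraction": invalid_fraction,
            "rhodamine_factor": factor,
        },
    )
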