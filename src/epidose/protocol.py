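"""Acquisition-protocol arithmetic for the commissioning session.

The imager runs in cine mode at a fixed frame rate with consecutive
frames averaged into each stored image; commissioning consists of a fixed
set of slab irradiations at a fixed MU and dose rate; the displacement
factor is measured over a symmetric series of couch shifts.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "FRAME_RATE_FPS",
    "FRAMES_PER_IMAGE",
    "COMMISSIONING_IRRADIATIONS",
    "MU_PER_IRRADIATION",
    "MU_RATE_PER_MIN",
    "images_per_second",
    "commissioning_beam_on_minutes",
    "displacement_series",
]

FRAME_RATE_FPS = 10.0
FRAMES_PER_IMAGE = 8
COMMISSIONING_IRRADIATIONS = 59
MU_PER_IRRADIATION = 100.0
MU_RATE_PER_MIN = 300.0


def images_per_second(frame_rate: float = FRAME_RATE_FPS,
                      frames_per_image: int = FRAMES_PER_IMAGE) -> float:
    """Effective stored-image rate of the cine acquisition (images/sec)."""
    if frame_rate <= 0 or frames_per_image < 1:
        raise ValueError("frame rate must be positive and averaging >= 1 frame")
    return frame_rate / frames_per_image


def commissioning_beam_on_minutes(n_irradiations: int = COMMISSIONING_IRRADIATIONS,
                                  mu_per_beam: float = MU_PER_IRRADIATION,
                                  mu_rate: float = MU_RATE_PER_MIN) -> float:
    """Total beam-on time of the commissioning session, minutes."""
    if min(n_irradiations, mu_per_beam, mu_rate) <= 0:
        raise ValueError("counts and rates must be positive")
    return n_irradiations * mu_per_beam / mu_rate


def displacement_series(start: float = -10.0, stop: float = 10.0,
                        step: float = 2.5) -> np.ndarray:
    """Phantom displacements (cm) of the f-factor series, endpoints included."""
    if step <= 0 or stop < start:
        raise ValueError("need step > 0 and stop >= start")
    n = int(round((stop - start) / step)) + 1
    return start + step * np.arange(n)
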