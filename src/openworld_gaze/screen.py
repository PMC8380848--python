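"""Screen-coordinate import helper.

Recorded gaze is sometimes exported in screen pixels rather than degrees of
visual angle.  :func:`pixels_to_degrees` converts pixel coordinates to the
degree-scaled, screen-centered coordinates the detector expects, given the
viewing distance and the monitor's physical size (defaults: a 1920x1080
23.8-inch panel viewed at 70 cm).
"""

from __future__ import annotations

import numpy as np


def pixels_to_degrees(px, py, screen_px: tuple[int, int] = (1920, 1080),
                      screen_m: tuple[float, float] = (0.527, 0.296),
                      distance_m: float = 0.70):
    """Convert screen-pixel gaze coordinates to degrees of visual angle.

    Pixels are measured from the top-left corner; the returned coordinates
    are centered on the screen midpoint with +x rightward and +y upward.

    Parameters
    ----------
    px, py : array-like
        Pixel coordinates.
    screen_px : (width, height) in pixels.
    screen_m : (width, height) of the visible panel in meters.
    distance_m : eye-to-screen distance in meters.

    Returns
    -------
    (x_deg, y_deg) : ndarrays of visual angle in degrees.
    """
    if distance_m <= 0:
        raise ValueError("distance_m must be positive")
    px = np.asarray(px, dtype=float)
    py = np.asarray(py, dtype=float)
    mx = screen_m[0] / screen_px[0]
    my = screen_m[1] / screen_px[1]
    x_m = (px - screen_px[0] / 2.0) * mx
    y_m = (screen_px[1] / 2.0 - py) * my
    return (np.degrees(np.arctan2(x_m, distance_m)),
            np.degrees(np.arctan2(y_m, distance_m)))
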