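"""Solar geometry: day length from latitude and day of year.

Day length is computed from the standard sunrise-hour-angle relation

    cos(h0) = (sin(a) - sin(phi) sin(delta)) / (cos(phi) cos(delta))

with latitude ``phi``, solar declination ``delta`` (Cooper's approximation)
and a configurable sun elevation threshold ``a``.  ``a = 0`` gives the
geometric (center-of-disc) day length; ``a = -6`` (civil twilight) is the
photoperiod convention used by many crop models and is the default used
when a day-length column is absent from a weather file.
"""

from __future__ import annotations

import numpy as np

from .errors import UnsupportedLatitudeError

#: Sun elevation thresholds (degrees relative to the horizon).
GEOMETRIC_HORIZON = 0.0
CIVIL_TWILIGHT = -6.0

#: Default threshold for derived photoperiod.
DEFAULT_SUN_ANGLE = CIVIL_TWILIGHT

_MAX_LATITUDE = 66.5


def solar_declination(day_of_year):
    """Solar declination in degrees (Cooper 1969 approximation).

    Parameters
    ----------
    day_of_year : int or array-like
        Day of year, 1..366.
    """
    doy = np.asarray(day_of_year, dtype=float)
    return 23.45 * np.sin(2.0 * np.pi * (284.0 + doy) / 365.0)


def daylength(latitude: float, day_of_year, sun_angle_deg: float = DEFAULT_SUN_ANGLE):
    """Hours between sun crossing ``sun_angle_deg`` in the morning and evening.

    Parameters
    ----------
    latitude : float
        Site latitude in decimal degrees; must satisfy ``|latitude| < 66.5``
        (no polar day/night handling).
    day_of_year : int or array-like
        Day of year, 1..366.
    sun_angle_deg : float
        Sun elevation threshold in degrees. 0 is the geometric horizon,
        -6 the civil-twilight convention (default).

    Returns
    -------
    float or ndarray
        Day length in hours, in (0, 24].
    """
    if abs(latitude) >= _MAX_LATITUDE:
        raise UnsupportedLatitudeError(
            f"latitude {latitude!r} is polar; day length is only defined for "
            f"|latitude| < {_MAX_LATITUDE}"
        )
    phi = np.radians(latitude)
    delta = np.radians(solar_declination(day_of_year))
    a = np.radians(sun_angle_deg)
    cos_h0 = (np.sin(a) - np.sin(phi) * np.sin(delta)) / (np.cos(phi) * np.cos(delta))
    cos_h0 = np.clip(cos_h0, -1.0, 1.0)
    hours = 2.0 * np.degrees(np.arccos(cos_h0)) / 15.0
    if np.ndim(day_of_year) == 0:
        return float(hours)
    return hours
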