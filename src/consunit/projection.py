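"""Geographic ↔ projected coordinate transforms.

Implements the transverse-Mercator projection on the GRS80 ellipsoid using
the Krüger series in the form given by Karney (2011), accurate to well below
a millimetre within a UTM/MGA zone width.  This covers the Map Grid of
Australia (MGA) zones of the GDA94 datum — the metric CRS the unit-definition
grid and eps math require — without any external projection library.

CRS codes accepted by :func:`get_crs`:

* ``"EPSG:283zz"`` — GDA94 / MGA zone ``zz`` (49–56), e.g. ``EPSG:28356``.
* ``"EPSG:326zz"`` / ``"EPSG:327zz"`` — WGS84 UTM north/south (GRS80≈WGS84
  at sub-mm level for this purpose).
* ``"mga<zone>"`` — shorthand for the MGA code.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import numpy as np

__all__ = ["TransverseMercator", "get_crs", "mga_zone_for_longitude", "suggest_crs"]

# GRS80 ellipsoid
_A = 6378137.0
_F = 1.0 / 298.257222101


def _kruger_coefficients(n: float):
    """Series coefficients alpha (forward) and beta (inverse) to n^6."""
    n2, n3, n4, n5, n6 = n**2, n**3, n**4, n**5, n**6
    alpha = np.array([
        n / 2 - 2 * n2 / 3 + 5 * n3 / 16 + 41 * n4 / 180 - 127 * n5 / 288
        + 7891 * n6 / 37800,
        13 * n2 / 48 - 3 * n3 / 5 + 557 * n4 / 1440 + 281 * n5 / 630
        - 1983433 * n6 / 1935360,
        61 * n3 / 240 - 103 * n4 / 140 + 15061 * n5 / 26880 + 167603 * n6 / 181440,
        49561 * n4 / 161280 - 179 * n5 / 168 + 6601661 * n6 / 7257600,
        34729 * n5 / 80640 - 3418889 * n6 / 1995840,
        212378941 * n6 / 319334400,
    ])
    beta = np.array([
        n / 2 - 2 * n2 / 3 + 37 * n3 / 96 - n4 / 360 - 81 * n5 / 512
        + 96199 * n6 / 604800,
        n2 / 48 + n3 / 15 - 437 * n4 / 1440 + 46 * n5 / 105 - 1118711 * n6 / 3870720,
        17 * n3 / 480 - 37 * n4 / 840 - 209 * n5 / 4480 + 5569 * n6 / 90720,
        4397 * n4 / 161280 - 11 * n5 / 504 - 830251 * n6 / 7257600,
        4583 * n5 / 161280 - 108847 * n6 / 3991680,
        20648693 * n6 / 638668800,
    ])
    return alpha, beta


@dataclass(frozen=True)
class TransverseMercator:
    """A transverse-Mercator projection with standard UTM-style parameters."""

    code: str
    lon0_deg: float
    k0: float = 0.9996
    false_easting: float = 500_000.0
    false_northing: float = 0.0  # 10 000 000 for southern-hemisphere zones

    def __post_init__(self):
        n = _F / (2.0 - _F)
        alpha, beta = _kruger_coefficients(n)
        object.__setattr__(self, "_alpha", alpha)
        object.__setattr__(self, "_beta", beta)
        rect_a = _A / (1 + n) * (1 + n**2 / 4 + n**4 / 64 + n**6 / 256)
        object.__setattr__(self, "_rect_a", rect_a)
        e2 = _F * (2 - _F)
        object.__setattr__(self, "_e", math.sqrt(e2))

    # -- forward -----------------------------------------------------------
    def forward(self, lon, lat):
        """(lon, lat) in degrees → (easting, northing) in metres."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        e = self._e
        phi = np.radians(lat)
        lam = np.radians(lon - self.lon0_deg)

        sphi = np.sin(phi)
        # conformal latitude, tau' = tan(chi)
        tau = np.tan(phi)
        sigma = np.sinh(e * np.arctanh(e * sphi))
        taup = tau * np.sqrt(1 + sigma**2) - sigma * np.sqrt(1 + tau**2)

        xi_p = np.arctan2(taup, np.cos(lam))
        eta_p = np.arcsinh(np.sin(lam) / np.hypot(taup, np.cos(lam)))

        j = np.arange(1, 7)
        xi = xi_p + np.sum(
            self._alpha * np.sin(2 * j * xi_p[..., None]) * np.cosh(2 * j * eta_p[..., None]),
            axis=-1,
        )
        eta = eta_p + np.sum(
            self._alpha * np.cos(2 * j * xi_p[..., None]) * np.sinh(2 * j * eta_p[..., None]),
            axis=-1,
        )
        x = self.false_easting + self.k0 * self._rect_a * eta
        y = self.false_northing + self.k0 * self._rect_a * xi
        return x, y

    # -- inverse -----------------------------------------------------------
    def inverse(self, x, y):
        """(easting, northing) in metres → (lon, lat) in degrees."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        e = self._e
        xi = (y - self.false_northing) / (self.k0 * self._rect_a)
        eta = (x - self.false_easting) / (self.k0 * self._rect_a)

        j = np.arange(1, 7)
        xi_p = xi - np.sum(
            self._beta * np.sin(2 * j * xi[..., None]) * np.cosh(2 * j * eta[..., None]),
            axis=-1,
        )
        eta_p = eta - np.sum(
            self._beta * np.cos(2 * j * xi[..., None]) * np.sinh(2 * j * eta[..., None]),
            axis=-1,
        )
        taup = np.sin(xi_p) / np.hypot(np.sinh(eta_p), np.cos(xi_p))
        lam = np.arctan2(np.sinh(eta_p), np.cos(xi_p))

        # invert conformal latitude by Newton iteration on tau = tan(phi)
        e2 = e * e
        tau = taup / (1 - e2)
        for _ in range(6):
            sigma = np.sinh(e * np.arctanh(e * tau / np.hypot(1.0, tau)))
            taup_i = tau * np.sqrt(1 + sigma**2) - sigma * np.hypot(1.0, tau)
            dtau = (
                (taup - taup_i)
                * (1 + (1 - e2) * tau**2)
                / ((1 - e2) * np.hypot(1.0, taup_i) * np.hypot(1.0, tau))
            )
            tau = tau + dtau
            if np.all(np.abs(dtau) < 1e-14 * np.maximum(1.0, np.abs(tau))):
                break
        phi = np.arctan(tau)
        return self.lon0_deg + np.degrees(lam), np.degrees(phi)

    def domain_ok(self, lon) -> np.ndarray:
        """True where longitudes fall within ±3.5° of the central meridian."""
        return np.abs(np.asarray(lon, dtype=float) - self.lon0_deg) <= 3.5


def mga_zone_for_longitude(lon_deg: float) -> int:
    """MGA/UTM zone number containing the given longitude."""
    zone = int(math.floor((lon_deg + 180.0) / 6.0)) + 1
    return min(max(zone, 1), 60)


def suggest_crs(lon_deg: float) -> str:
    """GDA94 / MGA EPSG code for data centred on the given longitude."""
    return f"EPSG:{28300 + mga_zone_for_longitude(lon_deg)}"


_EPSG_RE = re.compile(r"^EPSG:(\d{5})$", re.IGNORECASE)
_MGA_RE = re.compile(r"^mga(\d{1,2})$", re.IGNORECASE)


def get_crs(code: str) -> TransverseMercator:
    """Resolve a CRS code to a projection instance."""
    m = _MGA_RE.match(code.strip())
    if m:
        code = f"EPSG:{28300 + int(m.group(1))}"
    m = _EPSG_RE.match(code.strip())
    if not m:
        raise ValueError(f"unsupported CRS code: {code!r}")
    epsg = int(m.group(1))
    if 28349 <= epsg <= 28356:  # GDA94 / MGA
        zone = epsg - 28300
        south = True
    elif 32601 <= epsg <= 32660:  # WGS84 UTM north
        zone = epsg - 32600
        south = False
    elif 32701 <= epsg <= 32760:  # WGS84 UTM south
        zone = epsg - 32700
        south = True
    else:
        raise ValueError(f"unsupported EPSG code: {epsg} (expected MGA or UTM)")
    return TransverseMercator(
        code=f"EPSG:{epsg}",
        lon0_deg=zone * 6.0 - 183.0,
        false_northing=10_000_000.0 if south else 0.0,
    )
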