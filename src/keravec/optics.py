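"""Paraxial corneal optics: keratometry, power vectors, dioptric power
matrices and the Gullstrand thick-lens combination.

The cornea is treated as a thick lens with two spherocylindrical
refracting surfaces.  Each surface is summarised by a three-component
power vector ``(veq, v0, v45)``: the equivalent (mean meridional) power
and the projections of the steep-minus-flat cylinder onto the 0/90 and
45/135 degree meridians.  A power vector maps to a symmetric 2x2
dioptric power matrix, on which the Gullstrand thick-lens formula

    P = Pa + Pp - Pp . Pa . d / n

acts by ordinary matrix algebra, so that total corneal power with
arbitrary (possibly crossed) surface axes falls out of the same
arithmetic as the spherical case.

Conventions
-----------
* Radii and intraocular distances are stored in millimetres; every power
  formula converts to metres at the point of use, so powers are always
  in dioptres.
* A meridian axis is the axis of the *flat* meridian, in degrees,
  normalised to the half-open interval [0, 180).
* ``v0``/``v45`` carry the full steep-minus-flat cylinder (not the
  half-cylinder of the Jackson-cross notation); for a surface of
  negative power (the corneal back surface) the signed cylinder is
  negative.
* All fields accept scalars or equal-shaped numpy arrays; every
  operation broadcasts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RefractiveIndices",
    "Keratometry",
    "PowerVector",
    "PowerMatrix",
    "mean_radius",
    "keratometric_power",
    "surface_power_vector",
    "power_vector_to_matrix",
    "matrix_to_power_vector",
    "gullstrand_total_power",
    "total_power_vector",
    "equivalent_radius",
]


@dataclass(frozen=True)
class RefractiveIndices:
    """Refractive indices of the schematic eye.

    ``keratometer_index`` is the fictitious index of classical
    keratometry (1.3375, i.e. power = 337.5/R with R in mm); it enters
    only :func:`keratometric_power`, never the thick-lens chain.
    """

    n_cornea: float = 1.376
    n_aqueous: float = 1.336
    keratometer_index: float = 1.3375
    n_vitreous: float = 1.336

    def __post_init__(self) -> None:
        for name in ("n_cornea", "n_aqueous", "keratometer_index", "n_vitreous"):
            if not np.all(np.asarray(getattr(self, name)) > 1.0):
                raise ValueError(f"{name} must exceed 1.0")


@dataclass(frozen=True)
class Keratometry:
    """Flat/steep meridian radii of one corneal surface.

    ``r1`` is the radius of the flat meridian (mm), ``r2`` the steep
    meridian, ``axis`` the flat-meridian axis in degrees (normalised
    modulo 180 on construction).
    """

    r1: float | np.ndarray
    r2: float | np.ndarray
    axis: float | np.ndarray = 0.0

    def __post_init__(self) -> None:
        if not (np.all(np.asarray(self.r1) > 0) and np.all(np.asarray(self.r2) > 0)):
            raise ValueError("keratometry radii must be positive")
        object.__setattr__(self, "axis", np.mod(self.axis, 180.0))


@dataclass(frozen=True)
class PowerVector:
    """Spherocylindrical power as (equivalent, 0/90, 45/135) components, dpt."""

    veq: float | np.ndarray
    v0: float | np.ndarray
    v45: float | np.ndarray

    def __post_init__(self) -> None:
        for name in ("veq", "v0", "v45"):
            if not np.all(np.isfinite(np.asarray(getattr(self, name)))):
                raise ValueError(f"power vector component {name} must be finite")

    @property
    def cylinder(self) -> float | np.ndarray:
        """Unsigned astigmatism magnitude sqrt(v0^2 + v45^2)."""
        return np.hypot(self.v0, self.v45)

    def as_array(self) -> np.ndarray:
        """Stack components on the last axis, shape (..., 3)."""
        return np.stack(np.broadcast_arrays(self.veq, self.v0, self.v45), axis=-1)


@dataclass(frozen=True)
class PowerMatrix:
    """2x2 dioptric power matrix.

    Matrices built from a :class:`PowerVector` are symmetric; the
    Gullstrand product of two such matrices with crossed axes need not
    be, which is why extraction averages the off-diagonal entries.
    """

    p11: float | np.ndarray
    p12: float | np.ndarray
    p21: float | np.ndarray
    p22: float | np.ndarray

    def as_array(self) -> np.ndarray:
        """Shape (..., 2, 2)."""
        p11, p12, p21, p22 = np.broadcast_arrays(self.p11, self.p12, self.p21, self.p22)
        return np.stack(
            [np.stack([p11, p12], axis=-1), np.stack([p21, p22], axis=-1)], axis=-2
        )


def mean_radius(k: Keratometry) -> float | np.ndarray:
    """Arithmetic mean of the flat and steep radii, mm."""
    return 0.5 * (np.asarray(k.r1) + np.asarray(k.r2))


def keratometric_power(k: Keratometry, idx: RefractiveIndices = RefractiveIndices()) -> float | np.ndarray:
    """Mean keratometric power, dpt (classical keratometer-index convention).

    Averages the meridional keratometric powers, i.e.
    ``0.5 * ((n_k - 1)/r1 + (n_k - 1)/r2)`` with radii in metres — for
    the default index 1.3375 this is 0.5*(337.5/r1 + 337.5/r2) with
    radii in mm.
    """
    nk = idx.keratometer_index - 1.0
    return 0.5 * (nk * 1000.0 / np.asarray(k.r1) + nk * 1000.0 / np.asarray(k.r2))


def surface_power_vector(k: Keratometry, n_before: float, n_after: float) -> PowerVector:
    """Power vector of a single refracting surface.

    With ``dn = n_after - n_before`` and radii converted to metres:

        veq = 0.5 * (dn/r1 + dn/r2)
        v0  = (dn/r2 - dn/r1) * cos(2*axis)
        v45 = (dn/r2 - dn/r1) * sin(2*axis)
    """
    dn = n_after - n_before
    p1 = dn * 1000.0 / np.asarray(k.r1)
    p2 = dn * 1000.0 / np.asarray(k.r2)
    two_axis = np.deg2rad(2.0 * np.asarray(k.axis))
    cyl = p2 - p1
    return PowerVector(
        veq=0.5 * (p1 + p2), v0=cyl * np.cos(two_axis), v45=cyl * np.sin(two_axis)
    )


def power_vector_to_matrix(pv: PowerVector) -> PowerMatrix:
    """Symmetric 2x2 power matrix [[veq+v0, v45], [v45, veq-v0]]."""
    return PowerMatrix(
        p11=pv.veq + pv.v0, p12=pv.v45, p21=pv.v45, p22=pv.veq - pv.v0
    )


def matrix_to_power_vector(P: PowerMatrix) -> PowerVector:
    """Extract (veq, v0, v45) from a 2x2 power matrix.

    veq = (p11+p22)/2, v0 = (p11-p22)/2, v45 = (p12+p21)/2 — the unique
    convention under which this inverts :func:`power_vector_to_matrix`;
    asymmetry of a matrix product is absorbed by the off-diagonal mean.
    """
    return PowerVector(
        veq=0.5 * (np.asarray(P.p11) + np.asarray(P.p22)),
        v0=0.5 * (np.asarray(P.p11) - np.asarray(P.p22)),
        v45=0.5 * (np.asarray(P.p12) + np.asarray(P.p21)),
    )


def gullstrand_total_power(
    pa: PowerMatrix,
    pp: PowerMatrix,
    cct: float | np.ndarray,
    idx: RefractiveIndices = RefractiveIndices(),
) -> PowerMatrix:
    """Thick-lens total power matrix  Pa + Pp - Pp.Pa * cct/n_cornea.

    ``cct`` in mm (converted to metres in the product term).  The matrix
    product is taken in the order Pp.Pa.
    """
    if not np.all(np.asarray(cct) >= 0):
        raise ValueError("corneal thickness must be non-negative")
    d = np.asarray(cct) * 1e-3 / idx.n_cornea
    # explicit 2x2 product so scalar and array fields both broadcast
    q11 = pp.p11 * pa.p11 + pp.p12 * pa.p21
    q12 = pp.p11 * pa.p12 + pp.p12 * pa.p22
    q21 = pp.p21 * pa.p11 + pp.p22 * pa.p21
    q22 = pp.p21 * pa.p12 + pp.p22 * pa.p22
    return PowerMatrix(
        p11=pa.p11 + pp.p11 - q11 * d,
        p12=pa.p12 + pp.p12 - q12 * d,
        p21=pa.p21 + pp.p21 - q21 * d,
        p22=pa.p22 + pp.p22 - q22 * d,
    )


def total_power_vector(
    front: Keratometry,
    back: Keratometry,
    cct: float | np.ndarray,
    idx: RefractiveIndices = RefractiveIndices(),
) -> PowerVector:
    """Total corneal power vector via the power-matrix Gullstrand chain."""
    pv_a = surface_power_vector(front, 1.0, idx.n_cornea)
    pv_p = surface_power_vector(back, idx.n_cornea, idx.n_aqueous)
    peq = gullstrand_total_power(
        power_vector_to_matrix(pv_a), power_vector_to_matrix(pv_p), cct, idx
    )
    return matrix_to_power_vector(peq)


def equivalent_radius(pv: PowerVector, delta_n: float) -> float | np.ndarray:
    """Radius (mm) of the spherical surface with power ``veq`` for index step ``delta_n``.

    The index step is an explicit parameter (0.376 for a single front
    surface in air, 0.3375 for the keratometric convention, ...).
    """
    veq = np.asarray(pv.veq)
    if np.any(veq == 0):
        raise ValueError("equivalent power must be nonzero to back-calculate a radius")
    return delta_n * 1000.0 / veq
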