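"""Paraxial intraocular lens power with a thick-cornea three-surface model.

The pseudophakic eye is modelled as three refracting surfaces: corneal
front surface, corneal back surface and the IOL as a thin lens, with a
spectacle plane at a configurable vertex distance.  Spherical-equivalent
(mean-radius) powers only; toric IOL selection is out of scope.

The axial position of the IOL (effective lens position, ELP, measured
from the corneal *front* apex) is predicted from preoperative biometry
with a linear regression on ACD, LT and AL — the prediction scheme of
the Castrop formula family, whose constants are lens-model specific and
supplied as configuration.  For lens power calculation only, the
measured axial length may first be remapped by another linear rule
(the Cooke "modified axial length" sum-of-segments correction for long
and short eyes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .optics import Keratometry, RefractiveIndices, surface_power_vector

__all__ = [
    "LensConstants",
    "EyeModel",
    "IOLResult",
    "DegenerateGeometryError",
    "adjust_axial_length",
    "predict_elp",
    "iol_power_for_target",
    "batch_iol_comparison",
]

log = logging.getLogger(__name__)


class DegenerateGeometryError(ValueError):
    """Predicted geometry is optically impossible (ELP outside the eye,
    or a conjugate focus falls exactly on a refracting surface)."""


@dataclass(frozen=True)
class LensConstants:
    """Formula constants for one IOL model.

    ELP (mm, from the corneal front apex):

        elp = elp_intercept + elp_coef_acd*ACD + elp_coef_lt*LT + elp_coef_al*AL

    Axial length used for power calculation (mm):

        al' = al_adjust_intercept + al_adjust_coef_al*AL + al_adjust_coef_lt*LT

    ``refraction_offset`` (dpt) is added to the target spherical
    equivalent at the spectacle plane; ``vertex_distance`` is the
    spectacle vertex distance in mm.

    Defaults: ELP coefficients are representative values for a modern
    hydrophobic acrylic one-piece IOL (ELP = ACD + 0.30*LT + 0.20); the
    AL adjustment defaults to the published Cooke modified-axial-length
    regression 1.23853 + 0.95855*AL - 0.05467*LT.  Both are ordinary
    configuration, to be replaced by optimised constants for a concrete
    lens model.
    """

    elp_intercept: float = 0.20
    elp_coef_acd: float = 1.0
    elp_coef_lt: float = 0.30
    elp_coef_al: float = 0.0
    refraction_offset: float = 0.0
    al_adjust_intercept: float = 1.23853
    al_adjust_coef_al: float = 0.95855
    al_adjust_coef_lt: float = -0.05467
    vertex_distance: float = 12.0

    def __post_init__(self) -> None:
        if self.vertex_distance < 0:
            raise ValueError("vertex distance must be non-negative")

    @classmethod
    def identity(cls) -> "LensConstants":
        """ELP = ACD and unadjusted AL; handy for testing and as a
        neutral starting point."""
        return cls(
            elp_intercept=0.0,
            elp_coef_acd=1.0,
            elp_coef_lt=0.0,
            elp_coef_al=0.0,
            al_adjust_intercept=0.0,
            al_adjust_coef_al=1.0,
            al_adjust_coef_lt=0.0,
        )


@dataclass(frozen=True)
class EyeModel:
    """Preoperative biometry of one eye (distances mm, from the corneal
    front apex along the optical axis)."""

    al: float
    cct: float
    acd: float
    lt: float
    front: Keratometry
    back: Keratometry
    indices: RefractiveIndices = RefractiveIndices()

    def __post_init__(self) -> None:
        if not (self.al > 0 and self.cct > 0 and self.acd > 0 and self.lt > 0):
            raise ValueError("all distances must be positive")
        if self.al <= self.cct:
            raise ValueError("axial length must exceed corneal thickness")
        if self.acd < self.cct:
            raise ValueError("ACD (from the front apex) cannot be smaller than CCT")


@dataclass(frozen=True)
class IOLResult:
    iolp: float
    elp: float
    adjusted_al: float
    target_seq: float


def adjust_axial_length(al: float, lt: float, c: LensConstants) -> float:
    """Axial length remapped for power calculation (mm)."""
    return c.al_adjust_intercept + c.al_adjust_coef_al * al + c.al_adjust_coef_lt * lt


def predict_elp(eye: EyeModel, c: LensConstants) -> float:
    """Predicted effective lens position (mm from the corneal front apex)."""
    elp = (
        c.elp_intercept
        + c.elp_coef_acd * eye.acd
        + c.elp_coef_lt * eye.lt
        + c.elp_coef_al * eye.al
    )
    if not (eye.cct < elp < eye.al):
        raise DegenerateGeometryError(
            f"predicted ELP {elp:.3f} mm outside the interval "
            f"({eye.cct:.3f}, {eye.al:.3f}) mm"
        )
    return elp


def _propagate(v: float, distance_m: float, n: float) -> float:
    """Transfer a vergence over a homogeneous gap of reduced thickness d/n."""
    denom = 1.0 - (distance_m / n) * v
    if denom == 0.0:
        raise DegenerateGeometryError("conjugate focus falls on a refracting surface")
    return v / denom


def iol_power_for_target(
    eye: EyeModel, c: LensConstants, target_seq: float = 0.0
) -> IOLResult:
    """Thin-IOL power (dpt) achieving ``target_seq`` at the spectacle plane.

    Scalar (spherical-equivalent) vergence calculation through the
    corneal front surface (mean radius), corneal thickness, corneal back
    surface (mean radius) and aqueous up to the predicted ELP; the IOL
    power is the vergence jump needed so that the image lands on the
    retina of the (adjusted) axial length.
    """
    idx = eye.indices
    elp = predict_elp(eye, c)
    al_adj = adjust_axial_length(eye.al, eye.lt, c)
    if elp >= al_adj:
        raise DegenerateGeometryError(
            f"ELP {elp:.3f} mm not anterior to the adjusted axial length {al_adj:.3f} mm"
        )

    ref = target_seq + c.refraction_offset
    denom = 1.0 - (c.vertex_distance * 1e-3) * ref
    if denom == 0.0:
        raise DegenerateGeometryError("target refraction focuses at the corneal vertex")
    v = ref / denom  # vergence incident on the corneal front surface

    p_front = float(surface_power_vector(eye.front, 1.0, idx.n_cornea).veq)
    p_back = float(surface_power_vector(eye.back, idx.n_cornea, idx.n_aqueous).veq)

    v = v + p_front
    v = _propagate(v, eye.cct * 1e-3, idx.n_cornea)
    v = v + p_back
    v = _propagate(v, (elp - eye.cct) * 1e-3, idx.n_aqueous)

    v_out = idx.n_vitreous / ((al_adj - elp) * 1e-3)
    return IOLResult(iolp=v_out - v, elp=elp, adjusted_al=al_adj, target_seq=target_seq)


_BIOMETRY_COLS = ("al", "cct", "acd", "lt", "r1a", "r2a", "aa", "r1p", "r2p", "ap")


def _eye_from_row(row: pd.Series, suffix: str, idx: RefractiveIndices) -> EyeModel:
    g = {c: float(row[f"{c}_{suffix}"]) for c in _BIOMETRY_COLS}
    return EyeModel(
        al=g["al"],
        cct=g["cct"],
        acd=g["acd"],
        lt=g["lt"],
        front=Keratometry(g["r1a"], g["r2a"], g["aa"]),
        back=Keratometry(g["r1p"], g["r2p"], g["ap"]),
        indices=idx,
    )


def batch_iol_comparison(
    cohort: pd.DataFrame,
    c: LensConstants,
    target_seq: float = 0.0,
    indices: RefractiveIndices = RefractiveIndices(),
) -> pd.DataFrame:
    """Per-eye IOL power from both devices' measurements with identical
    constants.

    ``cohort`` is a paired frame with the biometry columns suffixed
    ``_z`` and ``_h``.  Returns a frame with ``iolp_z``, ``iolp_h`` and
    ``iolp_diff`` (H - Z); eyes with degenerate geometry on either
    device are skipped with a log message.
    """
    rows = []
    for i, row in cohort.iterrows():
        try:
            rz = iol_power_for_target(_eye_from_row(row, "z", indices), c, target_seq)
            rh = iol_power_for_target(_eye_from_row(row, "h", indices), c, target_seq)
        except (DegenerateGeometryError, ValueError) as exc:
            log.warning("skipping eye %s: %s", row.get("patient_id", i), exc)
            continue
        rows.append(
            {
                "patient_id": row.get("patient_id", i),
                "eye": row.get("eye", ""),
                "iolp_z": rz.iolp,
                "iolp_h": rh.iolp,
                "iolp_diff": rh.iolp - rz.iolp,
                "elp_z": rz.elp,
                "elp_h": rh.elp,
            }
        )
    return pd.DataFrame(rows)
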