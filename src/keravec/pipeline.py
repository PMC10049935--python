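"""Ingestion of device-export CSV tables, pairing, exclusion filtering
and the end-to-end comparison pipeline.

Export tables are plain CSVs with one row per examination.  A
:class:`DialectProfile` maps a device's column names onto the canonical
schema (``patient_id``, ``eye``, ``exam_date``, ``al``, ``cct``,
``acd``, ``lt``, ``r1a``, ``r2a``, ``aa``, ``r1p``, ``r2p``, ``ap``)
and declares the unit of the thickness column (some devices export CCT
in micrometres).  Internally everything is mm / degrees.

Pairing follows the study protocol: records from the two devices are
inner-joined on patient ID, eye side and the calendar date of the
examination (same-day measurements only), then reduced to one eye per
patient by a seeded random choice.  Exclusions run in a fixed order —
duplicates, clinical flags, completeness — so the per-rule counts in
the :class:`ExclusionLog` are well defined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import stats as cstats
from .conversion import CrossValReport, cross_validate, fit_affine_conversion
from .iol import LensConstants, batch_iol_comparison
from .optics import (
    Keratometry,
    PowerVector,
    RefractiveIndices,
    keratometric_power,
    mean_radius,
    surface_power_vector,
    total_power_vector,
)
from .simulate import (
    BIOMETRY_COLUMNS,
    KEY_COLUMNS,
    PopulationParams,
    cohort_to_exports,
    generate_cohort,
)

__all__ = [
    "DialectProfile",
    "ExclusionLog",
    "PipelineConfig",
    "read_export_csv",
    "merge_paired",
    "select_one_eye_per_patient",
    "apply_exclusions",
    "derive_power_columns",
    "run_pipeline",
]

log = logging.getLogger(__name__)

REQUIRED_COLUMNS = KEY_COLUMNS + BIOMETRY_COLUMNS
PUPIL_WIDTH_LIMIT_MM = 5.2  # exclusion: pharmacologic mydriasis, strictly greater


@dataclass(frozen=True)
class DialectProfile:
    """Column mapping and units for one device's export dialect.

    ``column_map`` maps canonical names to the device's column headers;
    canonical names absent from the map are assumed to appear verbatim.
    """

    column_map: dict[str, str] = field(default_factory=dict)
    cct_unit: str = "mm"  # "mm" | "um"

    def __post_init__(self) -> None:
        if self.cct_unit not in ("mm", "um"):
            raise ValueError("cct_unit must be 'mm' or 'um'")


@dataclass
class ExclusionLog:
    """Per-rule removal accounting; removals plus survivors equal the input."""

    input_rows: int = 0
    duplicates: int = 0
    pseudophakic: int = 0
    mydriasis: int = 0
    refractive_surgery: int = 0
    ectasia: int = 0
    incomplete: int = 0
    second_eye: int = 0
    survivors: int = 0

    @property
    def total_removed(self) -> int:
        return (
            self.duplicates
            + self.pseudophakic
            + self.mydriasis
            + self.refractive_surgery
            + self.ectasia
            + self.incomplete
            + self.second_eye
        )

    def check(self) -> None:
        if self.input_rows != self.total_removed + self.survivors:
            raise AssertionError("exclusion accounting does not reconcile")


def read_export_csv(path: str | Path, profile: DialectProfile = DialectProfile()) -> pd.DataFrame:
    """Read one device export into the canonical schema and units.

    Raises on a missing required column (naming it); rows with
    unparseable numeric fields are dropped with a log message.
    """
    raw = pd.read_csv(path, dtype=str)
    rename = {}
    missing = []
    for canon in REQUIRED_COLUMNS:
        source = profile.column_map.get(canon, canon)
        if source not in raw.columns:
            missing.append(canon)
        else:
            rename[source] = canon
    if missing:
        raise ValueError(f"export {path} is missing required columns: {', '.join(missing)}")
    df = raw.rename(columns=rename)[list(REQUIRED_COLUMNS)].copy()

    for col in BIOMETRY_COLUMNS:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    parseable = df[list(BIOMETRY_COLUMNS)].notna().any(axis=1)
    if (~parseable).any():
        log.warning(
            "dropping %d rows with no parseable biometry in %s",
            int((~parseable).sum()), path,
        )
        df = df[parseable]

    if profile.cct_unit == "um":
        df["cct"] = df["cct"] / 1000.0
    df["exam_date"] = pd.to_datetime(df["exam_date"]).dt.date.astype(str)
    df["eye"] = df["eye"].str.upper().str[0]
    return df.reset_index(drop=True)


def write_canonical_csv(df: pd.DataFrame, path: str | Path, decimals: int = 4) -> None:
    """Write a canonical table with fixed 4-decimal numeric precision."""
    df.to_csv(path, index=False, float_format=f"%.{decimals}f")


def merge_paired(z: pd.DataFrame, h: pd.DataFrame) -> pd.DataFrame:
    """Inner join of two canonical tables on (patient, eye, same-day
    date); unmatched rows are logged."""
    merged = pd.merge(z, h, on=list(KEY_COLUMNS), how="inner", suffixes=("_z", "_h"))
    unmatched = len(z) + len(h) - 2 * len(merged)
    if unmatched:
        log.info("%d export rows had no same-day counterpart", unmatched)
    return merged.reset_index(drop=True)


def select_one_eye_per_patient(cohort: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Keep one randomly selected eye per patient (seeded)."""
    rng = np.random.default_rng(seed)
    keep = []
    for _, idx in cohort.groupby("patient_id", sort=True).indices.items():
        keep.append(idx[rng.integers(len(idx))] if len(idx) > 1 else idx[0])
    return cohort.loc[np.sort(keep)].reset_index(drop=True)


def apply_exclusions(
    cohort: pd.DataFrame, flags: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, ExclusionLog]:
    """Apply the study's exclusion rules in a fixed order.

    Order: exact duplicate examinations (same patient/eye/date, keeping
    the first), clinical flags (pseudophakia, pupil width strictly
    greater than 5.2 mm, prior refractive surgery, corneal ectasia),
    incomplete biometry.  ``flags`` is an optional per-patient-eye table
    with boolean columns ``pseudophakic``, ``refractive_surgery``,
    ``ectasia`` and a numeric ``pupil_width`` (mm).
    """
    elog = ExclusionLog(input_rows=len(cohort))
    df = cohort.copy()

    dup = df.duplicated(subset=list(KEY_COLUMNS), keep="first")
    elog.duplicates = int(dup.sum())
    df = df[~dup]

    if flags is not None:
        join_keys = [k for k in ("patient_id", "eye") if k in flags.columns]
        flagged = df[join_keys].merge(flags, on=join_keys, how="left")
        flagged.index = df.index
        for rule, attr in (
            ("pseudophakic", "pseudophakic"),
            ("refractive_surgery", "refractive_surgery"),
            ("ectasia", "ectasia"),
        ):
            if rule in flagged.columns:
                mask = flagged[rule].fillna(False).astype(bool)
                setattr(elog, attr, int(mask.sum()))
                df = df[~mask]
                flagged = flagged[~mask]
        if "pupil_width" in flagged.columns:
            mask = flagged["pupil_width"].astype(float) > PUPIL_WIDTH_LIMIT_MM
            mask = mask.fillna(False)
            elog.mydriasis = int(mask.sum())
            df = df[~mask]

    value_cols = [c for c in df.columns if c not in KEY_COLUMNS]
    complete = df[value_cols].notna().all(axis=1)
    elog.incomplete = int((~complete).sum())
    df = df[complete]

    elog.survivors = len(df)
    elog.check()
    return df.reset_index(drop=True), elog


_DISTANCE_VARS = ("al", "cct", "acd", "lt")
_PV_VARS = ("veqa", "v0a", "v45a", "veqp", "v0p", "v45p", "vtpeq", "vtp0", "vtp45")


def derive_power_columns(
    cohort: pd.DataFrame, indices: RefractiveIndices = RefractiveIndices()
) -> pd.DataFrame:
    """Add per-device derived columns: mean radii, keratometric power,
    surface power vectors and the Gullstrand total power vector."""
    out = cohort.copy()
    for dev in ("z", "h"):
        front = Keratometry(
            out[f"r1a_{dev}"].to_numpy(),
            out[f"r2a_{dev}"].to_numpy(),
            out[f"aa_{dev}"].to_numpy(),
        )
        back = Keratometry(
            out[f"r1p_{dev}"].to_numpy(),
            out[f"r2p_{dev}"].to_numpy(),
            out[f"ap_{dev}"].to_numpy(),
        )
        out[f"r12a_{dev}"] = mean_radius(front)
        out[f"r12p_{dev}"] = mean_radius(back)
        out[f"k12_{dev}"] = keratometric_power(front, indices)
        pv_a = surface_power_vector(front, 1.0, indices.n_cornea)
        pv_p = surface_power_vector(back, indices.n_cornea, indices.n_aqueous)
        pv_t = total_power_vector(front, back, out[f"cct_{dev}"].to_numpy(), indices)
        for tag, pv in (("a", pv_a), ("p", pv_p)):
            out[f"veq{tag}_{dev}"] = pv.veq
            out[f"v0{tag}_{dev}"] = pv.v0
            out[f"v45{tag}_{dev}"] = pv.v45
        out[f"vtpeq_{dev}"] = pv_t.veq
        out[f"vtp0_{dev}"] = pv_t.v0
        out[f"vtp45_{dev}"] = pv_t.v45
    return out


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of the end-to-end synthetic comparison run."""

    seed: int = 0
    population: PopulationParams | None = None  # defaults to seeded study conditions
    lens_constants: LensConstants = LensConstants()
    indices: RefractiveIndices = RefractiveIndices()
    train_fraction: float = 0.7
    outdir: str | Path | None = None


def _pv_cols(df: pd.DataFrame, names: tuple[str, str, str], dev: str) -> np.ndarray:
    return df[[f"{n}_{dev}" for n in names]].to_numpy()


_SURFACE_COMPONENTS = {
    "front": ("veqa", "v0a", "v45a"),
    "back": ("veqp", "v0p", "v45p"),
    "total": ("vtpeq", "vtp0", "vtp45"),
}


def run_pipeline(config: PipelineConfig) -> dict:
    """Generate (or accept) a paired cohort, filter it, derive corneal
    powers and produce every comparison product.

    Returns a bundle with the filtered cohort, per-variable difference
    summaries, Bland-Altman fits, double-angle summaries, fitted
    conversion models with cross-validation reports, and the paired IOL
    power comparison.  Deterministic given the config.  If ``outdir``
    is set, tidy CSV summaries and the derived cohort are written there.
    """
    pop = config.population or PopulationParams(seed=config.seed)
    raw = generate_cohort(pop)

    # round-trip through the export representation to mimic ingestion
    z_exp, h_exp = cohort_to_exports(raw)
    cohort = merge_paired(z_exp, h_exp)
    cohort = select_one_eye_per_patient(cohort, seed=config.seed)
    cohort, elog = apply_exclusions(cohort)
    cohort = derive_power_columns(cohort, config.indices)

    diff_summaries: dict[str, cstats.DescriptiveSummary] = {}
    bland_altman: dict[str, cstats.BlandAltmanResult] = {}
    for var in _DISTANCE_VARS + ("r12a", "r12p", "k12") + _PV_VARS:
        z, h = cohort[f"{var}_z"], cohort[f"{var}_h"]
        diff_summaries[var] = cstats.paired_difference_summary(z, h)
        bland_altman[var] = cstats.bland_altman(z, h)

    double_angle = {}
    for surface, comps in _SURFACE_COMPONENTS.items():
        pv_z = PowerVector(*(cohort[f"{c}_z"].to_numpy() for c in comps))
        pv_h = PowerVector(*(cohort[f"{c}_h"].to_numpy() for c in comps))
        double_angle[surface] = cstats.astigmatism_difference_centroid(pv_z, pv_h)

    conversions: dict[str, dict] = {}
    for surface, comps in _SURFACE_COMPONENTS.items():
        x = _pv_cols(cohort, comps, "z")
        y = _pv_cols(cohort, comps, "h")
        cv: CrossValReport = cross_validate(
            x, y, config.train_fraction, seed=config.seed, surface=surface, direction="z_to_h"
        )
        full = fit_affine_conversion(x, y, surface=surface, direction="z_to_h")
        conversions[surface] = {"model": full, "cross_validation": cv}

    iol = batch_iol_comparison(cohort, config.lens_constants, indices=config.indices)
    iol_summary = cstats.descriptive_summary(iol["iolp_diff"])

    bundle = {
        "cohort": cohort,
        "exclusion_log": elog,
        "diff_summaries": diff_summaries,
        "bland_altman": bland_altman,
        "double_angle": double_angle,
        "conversions": conversions,
        "iol_comparison": iol,
        "iol_diff_summary": iol_summary,
        "seed": config.seed,
        "n": len(cohort),
    }
    if config.outdir is not None:
        _write_bundle(bundle, Path(config.outdir))
    return bundle


def _write_bundle(bundle: dict, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    write_canonical_csv(bundle["cohort"], outdir / "cohort_derived.csv")
    rows = []
    for var, summ in bundle["diff_summaries"].items():
        for stat, value in summ.as_dict().items():
            rows.append({"variable": var, "statistic": f"diff_{stat}", "value": value})
    for var, ba in bundle["bland_altman"].items():
        for stat in ("slope", "intercept", "r_squared", "rmse"):
            rows.append({"variable": var, "statistic": f"ba_{stat}", "value": getattr(ba, stat)})
    for stat, value in bundle["iol_diff_summary"].as_dict().items():
        rows.append({"variable": "iolp", "statistic": f"diff_{stat}", "value": value})
    pd.DataFrame(rows).to_csv(outdir / "summaries.csv", index=False, float_format="%.6f")
    bundle["iol_comparison"].to_csv(outdir / "iol_comparison.csv", index=False, float_format="%.4f")
    for surface, entry in bundle["conversions"].items():
        entry["model"].to_json(outdir / f"conversion_{surface}_z_to_h.json")
    with open(outdir / "run_manifest.txt", "w") as fh:
        fh.write(f"seed={bundle['seed']}\nn={bundle['n']}\n")
        fh.write(f"exclusions={bundle['exclusion_log']}\n")
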