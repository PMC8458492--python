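"""Absolute quantification: reference standardization, external
calibration, and isotope response factors.

Reference standardization (RS) is single-point quantification against a
pooled reference serum analyzed in the same batch:

    conc_sample = conc_reference * intensity_sample / intensity_reference

Its two-point variant, available when a chemical is certified and detected
in both SRM-1957 (nonfortified) and SRM-1958 (fortified), fits an
unweighted line through the two (certified concentration, measured
intensity) points and inverts it; when that line's x intercept is positive
(it would predict signal at zero concentration crossing below the axis on
the wrong side), the method falls back to single-point RS against
SRM-1958.

External calibration fits ordinary least squares to a neat-solvent
dilution series, screens linearity with the absolute Spearman statistic
(|rho| > 0.98 passes), and derives the instrument detection limit as
3 x SD(responses at the lowest nonzero level) / slope.

Because every estimator is a monotone function of the same quantifier
intensity, rank correlations between methods are exactly 1 under a
noise-free proportional response -- the cross-method validation this
module's ``compare_methods`` performs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotate import MatchResult
from .io import CertifiedReference, FeatureTable, ValidationError

__all__ = [
    "CalibrationModel",
    "QuantResult",
    "ResponseFactor",
    "fit_calibration",
    "rs_single",
    "rs_two_point",
    "compute_rf",
    "rf_quant",
    "external_quant",
    "compare_methods",
    "quantify_study",
]

logger = logging.getLogger(__name__)

LINEARITY_THRESHOLD = 0.98


@dataclass
class CalibrationModel:
    chemical_name: str
    levels: tuple[float, ...]
    slope: float
    intercept: float
    linearity_rho: float
    idl: float
    fit_n: int
    quantifiable: bool = True

    @property
    def passes_linearity(self) -> bool:
        return self.linearity_rho > LINEARITY_THRESHOLD


@dataclass
class QuantResult:
    chemical_name: str
    sample_id: str
    concentration: float | None
    unit: str
    method: str  # rs_single | rs_two_point | external_curve | response_factor
    flags: list[str] = field(default_factory=list)
    batch_id: object | None = None


@dataclass(frozen=True)
class ResponseFactor:
    """Instrument intensity per unit concentration, derived from the
    measured intensity of a 13C-labeled isotope in fortified reference
    serum with certified mass fraction."""

    chemical_name: str
    rf: float
    source: str = "srm_1958"

    def __post_init__(self) -> None:
        if not self.rf > 0:
            raise ValidationError(f"{self.chemical_name}: response factor must be > 0")


# ---------------------------------------------------------------------------
# External calibration
# ---------------------------------------------------------------------------


def fit_calibration(
    levels: Sequence[float],
    responses: Sequence[float],
    chemical_name: str = "",
    *,
    idl_multiplier: float = 3.0,
) -> CalibrationModel:
    """OLS fit of response on concentration over a dilution series.

    ``levels`` and ``responses`` are aligned arrays (replicates appear as
    repeated levels).  The linearity statistic is the absolute Spearman
    correlation of mean response versus level.  The detection limit is
    ``idl_multiplier`` x SD(responses at the lowest nonzero level) /
    slope; with fewer than two replicates at that level the SD -- hence
    the IDL -- is 0.
    """
    x = np.asarray(levels, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("levels and responses must align")
    uniq = np.unique(x)
    if len(uniq) < 2:
        raise ValidationError(f"{chemical_name}: need >= 2 distinct levels")
    if np.any(y < 0):
        raise ValidationError(f"{chemical_name}: negative responses")

    fit = stats.linregress(x, y)
    slope, intercept = float(fit.slope), float(fit.intercept)

    means = np.array([y[x == u].mean() for u in uniq])
    if np.all(np.diff(means) > 0) or np.all(np.diff(means) < 0):
        rho = 1.0  # strictly monotone mean response
    else:
        rho = abs(float(stats.spearmanr(uniq, means).statistic))

    nonzero = uniq[uniq > 0]
    idl = 0.0
    quantifiable = slope > 0
    if quantifiable and len(nonzero):
        low = y[x == nonzero.min()]
        sd = float(low.std(ddof=1)) if len(low) > 1 else 0.0
        idl = idl_multiplier * sd / slope
    return CalibrationModel(
        chemical_name=chemical_name,
        levels=tuple(float(u) for u in uniq),
        slope=slope,
        intercept=intercept,
        linearity_rho=rho,
        idl=idl,
        fit_n=len(x),
        quantifiable=quantifiable,
    )


def external_quant(
    intensity_sample: float,
    model: CalibrationModel,
    sample_id: str = "",
    *,
    recovery: float | None = None,
    unit: str = "ng/mL",
) -> QuantResult:
    """Invert the calibration line: conc = (intensity - intercept) / slope,
    optionally divided by a fractional recovery.  Negative predictions are
    floored at 0 and flagged; values below the detection limit are
    flagged."""
    flags: list[str] = []
    if not model.quantifiable:
        return QuantResult(
            model.chemical_name, sample_id, None, unit, "external_curve",
            flags=["non_quantifiable"],
        )
    conc = (intensity_sample - model.intercept) / model.slope
    if recovery is not None:
        if not recovery > 0:
            raise ValidationError("recovery must be > 0")
        conc /= recovery
    if conc < 0:
        conc = 0.0
        flags.append("negative_floored")
    if conc < model.idl:
        flags.append("below_idl")
    return QuantResult(
        model.chemical_name, sample_id, float(conc), unit, "external_curve", flags=flags
    )


# ---------------------------------------------------------------------------
# Reference standardization
# ---------------------------------------------------------------------------


def rs_single(
    intensity_sample: float,
    intensity_reference: float,
    concentration_reference: float,
    *,
    chemical_name: str = "",
    sample_id: str = "",
    unit: str = "ng/mL",
) -> QuantResult:
    """Single-point reference standardization:
    conc = conc_ref * I_sample / I_ref."""
    if not concentration_reference > 0:
        raise ValidationError("concentration_reference must be > 0")
    if (
        intensity_reference is None
        or math.isnan(intensity_reference)
        or not intensity_reference > 0
    ):
        return QuantResult(
            chemical_name, sample_id, None, unit, "rs_single",
            flags=["reference_missing"],
        )
    conc = concentration_reference * intensity_sample / intensity_reference
    return QuantResult(chemical_name, sample_id, float(conc), unit, "rs_single")


def rs_two_point(
    srm_intensities: Mapping[str, float],
    references: Mapping[str, CertifiedReference],
    intensity_sample: float,
    *,
    chemical_name: str = "",
    sample_id: str = "",
) -> QuantResult:
    """Two-point reference standardization through both SRMs.

    The unweighted line passes through (certified concentration, measured
    intensity) for SRM-1957 and SRM-1958; the unknown concentration is
    (intensity - intercept) / slope.  A positive x intercept
    (-intercept/slope > 0), equal reference concentrations, or a
    non-positive slope each trigger the single-point fallback against
    SRM-1958 with the appropriate flag."""
    for srm in ("srm_1957", "srm_1958"):
        if srm not in srm_intensities or srm not in references:
            raise ValidationError(f"rs_two_point requires both SRMs; missing {srm}")
    ref58 = references["srm_1958"]
    units = {r.unit for r in references.values()}
    if len(units) > 1:
        raise ValidationError(f"mixed reference units: {sorted(units)}")
    unit = ref58.unit
    i57, i58 = srm_intensities["srm_1957"], srm_intensities["srm_1958"]
    if not (i57 > 0 and i58 > 0):
        return QuantResult(
            chemical_name, sample_id, None, unit, "rs_two_point",
            flags=["reference_missing"],
        )
    c57, c58 = references["srm_1957"].mass_fraction, ref58.mass_fraction

    def fallback(flag: str) -> QuantResult:
        res = rs_single(
            intensity_sample, i58, c58,
            chemical_name=chemical_name, sample_id=sample_id, unit=unit,
        )
        res.flags.append(flag)
        return res

    if c57 == c58:
        return fallback("degenerate_references")
    slope = (i58 - i57) / (c58 - c57)
    intercept = i58 - slope * c58
    if slope <= 0:
        res = fallback("non_positive_slope")
        return res
    x_intercept = -intercept / slope
    # relative guard: an x intercept within FP rounding of zero (as arises
    # when the two points lie on an exact proportional response) is not
    # treated as positive
    if x_intercept > 1e-9 * c58:
        return fallback("x_intercept_fallback")
    conc = (intensity_sample - intercept) / slope
    flags: list[str] = []
    if conc < 0:
        conc = 0.0
        flags.append("negative_floored")
    return QuantResult(
        chemical_name, sample_id, float(conc), unit, "rs_two_point", flags=flags
    )


# ---------------------------------------------------------------------------
# Response factors
# ---------------------------------------------------------------------------


def compute_rf(
    intensities_isotope_in_srm: float | Sequence[float],
    certified_concentration: float,
    *,
    chemical_name: str = "",
    source: str = "srm_1958",
) -> ResponseFactor:
    """RF = mean isotope intensity in the SRM / certified mass fraction."""
    vals = np.atleast_1d(np.asarray(intensities_isotope_in_srm, dtype=float))
    if np.any(vals <= 0):
        raise ValidationError(f"{chemical_name}: non-positive isotope intensity")
    if not certified_concentration > 0:
        raise ValidationError(f"{chemical_name}: certified concentration must be > 0")
    return ResponseFactor(
        chemical_name=chemical_name,
        rf=float(vals.mean() / certified_concentration),
        source=source,
    )


def rf_quant(
    intensity_sample: float,
    rf: ResponseFactor,
    sample_id: str = "",
    unit: str = "ng/mL",
) -> QuantResult:
    """conc = intensity / RF."""
    return QuantResult(
        rf.chemical_name,
        sample_id,
        float(intensity_sample / rf.rf),
        unit,
        "response_factor",
    )


# ---------------------------------------------------------------------------
# Cross-method comparison
# ---------------------------------------------------------------------------


def compare_methods(
    results_a: Iterable[QuantResult],
    results_b: Iterable[QuantResult],
    min_overlap: int = 3,
) -> pd.DataFrame:
    """Per-chemical absolute Spearman correlation between two sets of
    concentration estimates over their shared (chemical, sample) pairs.

    Chemicals with fewer than ``min_overlap`` shared quantified samples are
    reported with rho NaN and a note."""

    def frame(res: Iterable[QuantResult]) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"chemical": r.chemical_name, "sample": r.sample_id, "conc": r.concentration}
                for r in res
                if r.concentration is not None
            ]
        )

    a, b = frame(results_a), frame(results_b)
    if a.empty or b.empty:
        return pd.DataFrame(columns=["chemical", "rho_abs", "n", "note"])
    merged = a.merge(b, on=["chemical", "sample"], suffixes=("_a", "_b"))
    rows = []
    for chem, grp in merged.groupby("chemical"):
        if len(grp) < min_overlap:
            rows.append(
                {"chemical": chem, "rho_abs": np.nan, "n": len(grp),
                 "note": "insufficient overlap"}
            )
            continue
        ra = grp["conc_a"].rank().to_numpy()
        rb = grp["conc_b"].rank().to_numpy()
        if np.array_equal(ra, rb) or np.array_equal(ra, ra.max() + ra.min() - rb):
            # exact (possibly reversed) rank agreement is rho = +/-1 by
            # definition; bypass the Pearson-of-ranks rounding
            rho = 1.0
        else:
            rho = stats.spearmanr(grp["conc_a"], grp["conc_b"]).statistic
        rows.append(
            {"chemical": chem, "rho_abs": abs(float(rho)), "n": len(grp), "note": ""}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Study-level cascade
# ---------------------------------------------------------------------------


def quantify_study(
    table: FeatureTable,
    matches: Sequence[MatchResult],
    references: Sequence[CertifiedReference],
    calibrations: Mapping[str, CalibrationModel] | None = None,
    response_factors: Mapping[str, ResponseFactor] | None = None,
    *,
    recovery: Mapping[str, float] | None = None,
    excluded_srm_samples: Iterable[str] = (),
) -> list[QuantResult]:
    """Quantify every identified chemical in every study sample, batchwise.

    Method cascade per chemical and batch: two-point RS when the chemical
    is certified in both SRMs and detected in both of the batch's SRM
    samples; else single-point RS against SRM-1958 when certified and
    detected there; else the external curve if provided; else the response
    factor if provided; else the chemical is reported unquantified with a
    reason.  "Detected" in an SRM sample means the targeted match passed
    and its quantifier intensity is present in that sample.  Each sample
    is quantified against its own batch's SRM intensities, which makes the
    estimates invariant to per-batch global intensity scaling.
    """
    calibrations = calibrations or {}
    response_factors = response_factors or {}
    excluded = set(excluded_srm_samples)
    refs: dict[tuple[str, str], CertifiedReference] = {}
    units = set()
    for r in references:
        key = (r.chemical_name, r.srm_id)
        if key in refs:
            raise ValidationError(f"duplicate reference for {key}")
        refs[key] = r
        units.add(r.unit)
    if len(units) > 1:
        raise ValidationError(f"mixed reference units: {sorted(units)}")
    unit = units.pop() if units else "ng/mL"

    manifest = table.manifest
    results: list[QuantResult] = []
    for res in matches:
        if not res.identified or res.quantifier_intensity is None:
            continue
        chem = res.chemical_name
        intens = res.quantifier_intensity
        cal = calibrations.get(chem)
        rf = response_factors.get(chem)
        rec = recovery.get(chem) if recovery else None
        for batch in sorted(manifest["batch_id"].unique()):
            in_batch = manifest["batch_id"] == batch
            srm_int: dict[str, float] = {}
            srm_detected: dict[str, bool] = {}
            for srm in ("srm_1957", "srm_1958"):
                cols = [
                    s
                    for s in manifest.index[in_batch & (manifest["role"] == srm)]
                    if s not in excluded
                ]
                vals = intens[cols].dropna() if cols else pd.Series(dtype=float)
                srm_detected[srm] = len(vals) > 0 and (vals > 0).all()
                srm_int[srm] = float(vals.mean()) if len(vals) else float("nan")
            study_samples = list(manifest.index[in_batch & (manifest["role"] == "study")])
            both_certified = (chem, "srm_1957") in refs and (chem, "srm_1958") in refs
            cert_58 = (chem, "srm_1958") in refs

            for s in study_samples:
                i_s = intens[s]
                if pd.isna(i_s):
                    i_s = 0.0
                if both_certified and srm_detected["srm_1957"] and srm_detected["srm_1958"]:
                    q = rs_two_point(
                        srm_int,
                        {k: refs[(chem, k)] for k in ("srm_1957", "srm_1958")},
                        i_s,
                        chemical_name=chem,
                        sample_id=s,
                    )
                elif cert_58 and srm_detected["srm_1958"]:
                    q = rs_single(
                        i_s, srm_int["srm_1958"], refs[(chem, "srm_1958")].mass_fraction,
                        chemical_name=chem, sample_id=s,
                        unit=refs[(chem, "srm_1958")].unit,
                    )
                elif cal is not None and cal.quantifiable:
                    q = external_quant(i_s, cal, sample_id=s, recovery=rec, unit=unit)
                elif rf is not None:
                    q = rf_quant(i_s, rf, sample_id=s, unit=unit)
                else:
                    q = QuantResult(
                        chem, s, None, unit, "none", flags=["no_applicable_method"]
                    )
                if cal is not None and q.concentration is not None and q.concentration < cal.idl:
                    if "below_idl" not in q.flags:
                        q.flags.append("below_idl")
                q.batch_id = batch
                results.append(q)
    return results


def results_frame(results: Iterable[QuantResult]) -> pd.DataFrame:
    """Long DataFrame view of quantification results."""
    return pd.DataFrame(
        [
            {
                "chemical": r.chemical_name,
                "sample": r.sample_id,
                "batch": r.batch_id,
                "concentration": r.concentration,
                "unit": r.unit,
                "method": r.method,
                "flags": ";".join(r.flags),
            }
            for r in results
        ],
        columns=["chemical", "sample", "batch", "concentration", "unit", "method", "flags"],
    )
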