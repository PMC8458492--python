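"""Quality control: method-blank prefiltering, total-ion-intensity checks,
sentinel-chemical monitoring in SRM-1958, and batch-layout validation.

The central operation is the blank prefilter: a feature is retained only if
its mean intensity over nonblank samples is strictly greater than
``fold`` (default 10) times its mean intensity over saline method blanks.
Missing intensities are excluded from the means; a feature absent from all
method blanks has blank mean 0 and passes whenever it carries any signal.
Only saline method blanks enter the denominator -- solvent and isooctane
blanks serve as baseline references, not as the filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
import yaml

from .io import BLANK_ROLES, FeatureTable, LibraryEntry, ValidationError

__all__ = [
    "DEFAULT_SENTINELS",
    "DEFAULT_BATCH_LAYOUT",
    "QcReport",
    "LayoutViolation",
    "blank_filter",
    "total_ion_intensity",
    "sentinel_check",
    "validate_batch_layout",
]

logger = logging.getLogger(__name__)

#: Matrix-interference-sensitive chemicals monitored in every SRM-1958
#: injection: DDE/DDT, HCB, the three BHC isomers, three indicator PCBs,
#: three PBDEs and PBB-153.
DEFAULT_SENTINELS = (
    "4,4'-DDE",
    "4,4'-DDT",
    "HCB",
    "alpha-BHC",
    "beta-BHC",
    "gamma-BHC",
    "PCB-138",
    "PCB-153",
    "PCB-180",
    "PBDE-47",
    "PBDE-85",
    "PBDE-153",
    "PBB-153",
)

#: Expected per-batch role counts: each batch of study samples runs with
#: both SRMs, two isooctane blanks, two solvent blanks and two saline
#: method blanks.
DEFAULT_BATCH_LAYOUT: dict[str, int] = {
    "srm_1957": 1,
    "srm_1958": 1,
    "isooctane_blank": 2,
    "solvent_blank": 2,
    "method_blank": 2,
}


class LayoutViolation(NamedTuple):
    batch_id: object
    role: str
    expected: int
    observed: int

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"batch {self.batch_id}: expected {self.expected} x {self.role}, "
            f"found {self.observed}"
        )


@dataclass
class QcReport:
    """Per-run QC summary."""

    total_ion_intensity: dict[str, float] = field(default_factory=dict)
    empty_samples: list[str] = field(default_factory=list)
    baselines: dict[str, float] = field(default_factory=dict)
    n_features_before: int = 0
    n_features_after: int = 0
    removed_features: list[str] = field(default_factory=list)
    sentinel: pd.DataFrame | None = None
    layout_violations: list[LayoutViolation] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {
            "total_ion_intensity": {k: float(v) for k, v in self.total_ion_intensity.items()},
            "empty_samples": list(self.empty_samples),
            "baselines": {k: float(v) for k, v in self.baselines.items()},
            "n_features_before": int(self.n_features_before),
            "n_features_after": int(self.n_features_after),
            "n_features_removed": len(self.removed_features),
            "layout_violations": [list(v) for v in self.layout_violations],
        }
        if self.sentinel is not None:
            d["sentinel"] = self.sentinel.to_dict(orient="records")
        return d

    def write_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()), encoding="utf-8")


def blank_filter(
    table: FeatureTable,
    fold: float = 10.0,
    *,
    numerator_roles: Iterable[str] = ("study", "srm_1957", "srm_1958"),
) -> tuple[FeatureTable, QcReport]:
    """Remove features not exceeding ``fold`` times the saline-blank level.

    A feature is retained iff
    ``mean(nonblank intensities) > fold * mean(method-blank intensities)``
    with strict inequality, missing values excluded from both means, and an
    all-missing blank mean defined as 0.
    """
    if not fold > 0:
        raise ValidationError("fold must be > 0")
    blank_cols = table.samples_with_role("method_blank")
    if not blank_cols:
        raise ValidationError("no method_blank samples in manifest")
    num_cols = table.samples_with_role(set(numerator_roles))
    if not num_cols:
        raise ValidationError("no samples with numerator roles in manifest")

    num_mean = table.intensities[num_cols].mean(axis=1).fillna(0.0)
    blank_mean = table.intensities[blank_cols].mean(axis=1).fillna(0.0)
    keep = num_mean > fold * blank_mean
    kept_ids = list(table.meta.index[keep])
    removed = list(table.meta.index[~keep])
    filtered = table.subset(kept_ids)

    report = QcReport(
        total_ion_intensity={},
        n_features_before=table.n_features,
        n_features_after=len(kept_ids),
        removed_features=removed,
    )
    tii, empty = total_ion_intensity(table)
    report.total_ion_intensity = tii.to_dict()
    report.empty_samples = empty
    for role in sorted(BLANK_ROLES):
        cols = table.samples_with_role(role)
        if cols:
            report.baselines[role] = float(tii[cols].mean())
    for b in table.batches():
        n_b = int((table.manifest["batch_id"] == b).sum())
        logger.info(
            "blank_filter: batch %s, %d samples, %d/%d features retained",
            b, n_b, len(kept_ids), table.n_features,
        )
    return filtered, report


def total_ion_intensity(table: FeatureTable) -> tuple[pd.Series, list[str]]:
    """Per-sample sum of all detected (non-missing) peak intensities.

    Returns the sums plus the list of samples with no detected peaks at
    all (their sum is 0 and they are flagged)."""
    tii = table.intensities.sum(axis=0, skipna=True)
    empty = list(tii.index[table.intensities.notna().sum(axis=0) == 0])
    return tii, empty


def sentinel_check(
    table: FeatureTable,
    library: Sequence[LibraryEntry],
    sentinel_names: Sequence[str] = DEFAULT_SENTINELS,
    tolerance_band: tuple[float, float] = (0.5, 2.0),
    *,
    ppm_tol: float = 5.0,
    rt_tol_s: float = 30.0,
) -> pd.DataFrame:
    """Monitor quantifier intensities of the sentinel chemicals in every
    SRM-1958 sample.

    Each sentinel's quantifier-fragment intensity is matched in the table;
    a (batch, chemical) entry fails if the sentinel is missing from that
    SRM injection or lies outside ``tolerance_band`` times the running
    median across all SRM-1958 injections.

    Returns a DataFrame (batch_id, sample_id, chemical, intensity,
    running_median, status).
    """
    from .annotate import match_chemical  # local import: avoid cycle

    by_name = {e.chemical_name: e for e in library}
    missing = [n for n in sentinel_names if n not in by_name]
    if missing:
        raise ValidationError(f"sentinel(s) not in library: {missing}")
    srm_samples = table.samples_with_role("srm_1958")
    rows = []
    for name in sentinel_names:
        entry = by_name[name]
        result = match_chemical(
            table, entry, ppm_tol=ppm_tol, rt_tol_s=rt_tol_s, min_fragments=1
        )
        intens = (
            result.quantifier_intensity
            if result.quantifier_intensity is not None
            else pd.Series(np.nan, index=table.sample_ids)
        )
        values = intens[srm_samples]
        detected = values.dropna()
        median = float(detected.median()) if len(detected) else np.nan
        for s in srm_samples:
            v = values[s]
            if pd.isna(v):
                status = "fail_missing"
            elif np.isnan(median):
                status = "fail_missing"
            elif tolerance_band[0] * median <= v <= tolerance_band[1] * median:
                status = "pass"
            else:
                status = "fail_band"
            rows.append(
                {
                    "batch_id": table.manifest.loc[s, "batch_id"],
                    "sample_id": s,
                    "chemical": name,
                    "intensity": None if pd.isna(v) else float(v),
                    "running_median": None if np.isnan(median) else median,
                    "status": status,
                }
            )
    return pd.DataFrame(rows)


def validate_batch_layout(
    manifest: pd.DataFrame,
    expected: dict[str, int] | None = None,
) -> list[LayoutViolation]:
    """Check that every batch carries the expected role counts.

    ``expected`` maps role -> required count (study samples are not
    constrained by default).  Returns an empty list iff all batches
    conform."""
    expected = DEFAULT_BATCH_LAYOUT if expected is None else expected
    violations: list[LayoutViolation] = []
    for batch_id, group in manifest.groupby("batch_id"):
        counts = group["role"].value_counts().to_dict()
        for role, want in expected.items():
            got = int(counts.get(role, 0))
            if got != want:
                violations.append(LayoutViolation(batch_id, role, want, got))
    return violations
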