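"""Targeted identification by co-eluting accurate-mass fragments.

A library chemical is identified in a feature table when at least
``min_fragments`` (default 3) of its library fragments each have a feature
within ±``ppm_tol`` (default 5 ppm, computed against the library m/z) and
within ``rt_tol_s`` (default 30 s) of the library retention time.  The
quantifier fragment -- the most abundant library m/z -- supplies the
per-sample intensity used downstream for quantification.

Ties (several features inside one fragment's window) break
deterministically: smallest ppm error, then smallest |rt delta|, then
highest mean intensity.  Within one chemical a feature can satisfy at most
one fragment.

Also here: the chromatographic retention-index scale (piecewise-linear
interpolation between index chemicals) and recovery computation against a
volumetric internal standard.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import FeatureTable, LibraryEntry, ValidationError

__all__ = [
    "FragmentMatch",
    "MatchResult",
    "RetentionIndexScale",
    "RetentionIndexValue",
    "match_chemical",
    "match_all",
    "retention_index",
    "recovery_percent",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FragmentMatch:
    library_mz: float
    feature_id: str
    ppm_error: float
    rt_delta_s: float
    mean_intensity: float


@dataclass
class MatchResult:
    """Outcome of matching one library chemical against a feature table."""

    chemical_name: str
    chemical_class: str
    matched_fragments: list[FragmentMatch]
    identified: bool
    quantifier_feature: str | None = None
    quantifier_intensity: pd.Series | None = None

    @property
    def n_fragments_matched(self) -> int:
        return len(self.matched_fragments)


def _candidate_key(cand: FragmentMatch) -> tuple[float, float, float]:
    return (abs(cand.ppm_error), abs(cand.rt_delta_s), -cand.mean_intensity)


def match_chemical(
    table: FeatureTable,
    entry: LibraryEntry,
    ppm_tol: float = 5.0,
    rt_tol_s: float = 30.0,
    min_fragments: int = 3,
    *,
    coelution_window_s: float | None = None,
) -> MatchResult:
    """Match one library chemical; absence of a match is a negative result.

    ``coelution_window_s`` optionally enforces a stricter mutual-coelution
    criterion: the rt spread of the matched fragments must not exceed the
    window, farthest-from-median matches being dropped until it does.
    """
    rt_tol_min = rt_tol_s / 60.0
    mz = table.meta["mz"].to_numpy()
    rt = table.meta["rt"].to_numpy()
    ids = table.meta.index.to_numpy()
    mean_int = table.intensities.mean(axis=1).fillna(0.0).to_numpy()

    used: set[str] = set()
    matches: list[FragmentMatch] = []
    for frag_mz, _rel in entry.fragments:
        ppm_err = (mz - frag_mz) / frag_mz * 1e6
        in_win = (np.abs(ppm_err) <= ppm_tol) & (
            np.abs(rt - entry.rt_expected) <= rt_tol_min
        )
        cands = [
            FragmentMatch(
                library_mz=frag_mz,
                feature_id=str(ids[i]),
                ppm_error=float(ppm_err[i]),
                rt_delta_s=float((rt[i] - entry.rt_expected) * 60.0),
                mean_intensity=float(mean_int[i]),
            )
            for i in np.flatnonzero(in_win)
            if ids[i] not in used
        ]
        if not cands:
            continue
        best = min(cands, key=_candidate_key)
        matches.append(best)
        used.add(best.feature_id)

    if coelution_window_s is not None:
        matches = _enforce_coelution(matches, table, coelution_window_s)

    identified = len(matches) >= min_fragments
    quant_feature = None
    quant_intensity = None
    for m in matches:
        if m.library_mz == entry.quantifier_mz:
            quant_feature = m.feature_id
            quant_intensity = table.intensities.loc[m.feature_id]
            break
    return MatchResult(
        chemical_name=entry.chemical_name,
        chemical_class=entry.chemical_class,
        matched_fragments=matches,
        identified=identified,
        quantifier_feature=quant_feature,
        quantifier_intensity=quant_intensity,
    )


def _enforce_coelution(
    matches: list[FragmentMatch], table: FeatureTable, window_s: float
) -> list[FragmentMatch]:
    matches = list(matches)
    while len(matches) > 1:
        rts = np.array([table.meta.loc[m.feature_id, "rt"] for m in matches]) * 60.0
        if rts.max() - rts.min() <= window_s:
            break
        med = np.median(rts)
        worst = int(np.argmax(np.abs(rts - med)))
        matches.pop(worst)
    return matches


def match_all(
    table: FeatureTable,
    library: Sequence[LibraryEntry],
    ppm_tol: float = 5.0,
    rt_tol_s: float = 30.0,
    min_fragments: int = 3,
    *,
    coelution_window_s: float | None = None,
) -> tuple[list[MatchResult], pd.DataFrame]:
    """Match every library entry; report features claimed by more than one
    chemical.

    A feature may back at most one chemical's *quantifier*: quantifier
    conflicts resolve by the tie-break key (smallest ppm error, then
    smallest |rt delta|, then highest mean intensity); the losing result
    keeps its identification but loses its quantifier.  All multiply
    claimed features appear in the conflict report.
    """
    results = [
        match_chemical(
            table,
            e,
            ppm_tol=ppm_tol,
            rt_tol_s=rt_tol_s,
            min_fragments=min_fragments,
            coelution_window_s=coelution_window_s,
        )
        for e in library
    ]

    claims: dict[str, list[tuple[str, FragmentMatch]]] = {}
    for res in results:
        for m in res.matched_fragments:
            claims.setdefault(m.feature_id, []).append((res.chemical_name, m))
    conflict_rows = [
        {
            "feature_id": fid,
            "chemicals": ";".join(sorted(c for c, _ in claimants)),
            "n_claims": len(claimants),
        }
        for fid, claimants in claims.items()
        if len(claimants) > 1
    ]

    # resolve quantifier conflicts deterministically
    by_quant: dict[str, list[MatchResult]] = {}
    for res in results:
        if res.quantifier_feature is not None:
            by_quant.setdefault(res.quantifier_feature, []).append(res)
    for fid, contenders in by_quant.items():
        if len(contenders) < 2:
            continue
        def key(r: MatchResult) -> tuple[float, float, float]:
            m = next(m for m in r.matched_fragments if m.feature_id == fid)
            return _candidate_key(m)
        winner = min(contenders, key=key)
        for r in contenders:
            if r is not winner:
                logger.info(
                    "quantifier conflict on %s: kept %s, dropped %s",
                    fid, winner.chemical_name, r.chemical_name,
                )
                r.quantifier_feature = None
                r.quantifier_intensity = None

    conflicts = pd.DataFrame(
        conflict_rows, columns=["feature_id", "chemicals", "n_claims"]
    )
    return results, conflicts


# ---------------------------------------------------------------------------
# Retention index
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RetentionIndexValue:
    value: float
    extrapolated: bool


@dataclass
class RetentionIndexScale:
    """Ordered anchors (chemical name, observed rt in minutes, assigned
    index value); rt must be strictly increasing with index."""

    anchors: list[tuple[str, float, float]]

    def __post_init__(self) -> None:
        if len(self.anchors) < 2:
            raise ValidationError("retention-index scale needs >= 2 anchors")
        self.anchors = sorted(self.anchors, key=lambda a: a[1])
        rts = [a[1] for a in self.anchors]
        idx = [a[2] for a in self.anchors]
        if any(rts[i] >= rts[i + 1] for i in range(len(rts) - 1)):
            raise ValidationError("anchor retention times must be strictly increasing")
        if any(idx[i] >= idx[i + 1] for i in range(len(idx) - 1)):
            raise ValidationError("anchor index values must be strictly increasing")


def retention_index(rt: float, scale: RetentionIndexScale) -> RetentionIndexValue:
    """Piecewise-linear interpolation between bracketing anchors; linear
    extrapolation from the terminal segment outside the anchor range
    (flagged)."""
    rts = [a[1] for a in scale.anchors]
    idx = [a[2] for a in scale.anchors]
    if rt < rts[0]:
        seg = (0, 1)
        extrapolated = True
    elif rt > rts[-1]:
        seg = (len(rts) - 2, len(rts) - 1)
        extrapolated = True
    else:
        return RetentionIndexValue(float(np.interp(rt, rts, idx)), False)
    i, j = seg
    slope = (idx[j] - idx[i]) / (rts[j] - rts[i])
    return RetentionIndexValue(idx[i] + slope * (rt - rts[i]), extrapolated)


# ---------------------------------------------------------------------------
# Recovery
# ---------------------------------------------------------------------------


def recovery_percent(
    processed: Sequence[tuple[float, float]],
    unprocessed: Sequence[tuple[float, float]],
) -> tuple[float, float]:
    """Percent recovery of a chemical through extraction.

    Each replicate is an (analyte area, volumetric-internal-standard area)
    pair; normalizing to the IS removes injection-volume variation.
    Recovery = 100 x mean(processed ratio) / mean(unprocessed ratio); the
    standard error propagates the replicate SEMs of both means.
    """
    if not processed or not unprocessed:
        raise ValidationError("need >= 1 replicate in each condition")
    for label, pairs in (("processed", processed), ("unprocessed", unprocessed)):
        if any(a <= 0 or b <= 0 for a, b in pairs):
            raise ValidationError(f"non-positive area in {label} replicates")
    rp = np.array([a / b for a, b in processed])
    ru = np.array([a / b for a, b in unprocessed])
    recovery = 100.0 * rp.mean() / ru.mean()
    sem_p = rp.std(ddof=1) / math.sqrt(len(rp)) if len(rp) > 1 else 0.0
    sem_u = ru.std(ddof=1) / math.sqrt(len(ru)) if len(ru) > 1 else 0.0
    se = recovery * math.sqrt((sem_p / rp.mean()) ** 2 + (sem_u / ru.mean()) ** 2)
    return float(recovery), float(se)
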