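"""Data model and delimited-text I/O for GC-HRMS feature tables.

The in-memory containers mirror the shape of peak-picked, aligned GC-HRMS
data: a feature table (accurate-mass features x samples, intensities in
arbitrary units), a sample manifest assigning each injection a role in the
batch design (study sample, SRM reference serum, or one of three blank
types), a targeted chemical library (retention time plus the most abundant
EI fragment m/z values per chemical), certified reference values for the
NIST serum SRMs, and pseudo-spectrum records exportable to NIST MSP text.

Missing intensities are a first-class state (NaN), distinct from zero: a
peak that was not detected in a sample is *absent*, and downstream
computations (blank filtering, correlation) exclude it rather than treating
it as a zero measurement.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ROLES",
    "BLANK_ROLES",
    "NONBLANK_ROLES",
    "MZ_RANGE",
    "RT_RANGE",
    "ValidationError",
    "InstrumentRangeWarning",
    "Feature",
    "FeatureTable",
    "LibraryEntry",
    "CertifiedReference",
    "PseudoSpectrumRecord",
    "read_feature_table",
    "write_feature_table",
    "read_library",
    "write_library",
    "read_references",
    "write_references",
    "write_pseudospectra_msp",
    "read_pseudospectra_msp",
]

#: Allowed sample roles in a batch.
ROLES = (
    "study",
    "srm_1957",
    "srm_1958",
    "method_blank",
    "solvent_blank",
    "isooctane_blank",
)

#: Roles that are blanks of some kind (not quantified).
BLANK_ROLES = frozenset({"method_blank", "solvent_blank", "isooctane_blank"})

#: Default numerator roles for blank filtering ("nonblank" samples).
NONBLANK_ROLES = frozenset({"study", "srm_1957", "srm_1958"})

#: Instrument scan range in Da (full-scan EI acquisition).
MZ_RANGE = (85.0, 850.0)

#: Chromatographic acquisition window in minutes.
RT_RANGE = (3.0, 24.37)


class ValidationError(ValueError):
    """A malformed input that names the offending record."""


class InstrumentRangeWarning(UserWarning):
    """Feature m/z or retention time outside the configured instrument range."""


@dataclass(frozen=True)
class Feature:
    """One accurate-mass feature: an (m/z, retention time) pair with
    per-sample intensities.  ``intensities`` is a pandas Series indexed by
    sample_id; NaN marks a missing (undetected) peak."""

    feature_id: str
    mz: float
    rt: float
    intensities: pd.Series

    def shared_samples(self, other: "Feature") -> pd.Index:
        """Samples where both features have a non-missing intensity."""
        a = self.intensities.dropna()
        b = other.intensities.dropna()
        return a.index.intersection(b.index)


@dataclass
class FeatureTable:
    """Feature x sample intensity matrix plus the sample manifest.

    Attributes
    ----------
    meta : DataFrame indexed by feature_id with columns ``mz`` and ``rt``.
    intensities : DataFrame indexed by feature_id, one column per sample;
        NaN encodes a missing peak.
    manifest : DataFrame indexed by sample_id with columns ``role``,
        ``batch_id`` and optionally ``injection_replicates``.
    """

    meta: pd.DataFrame
    intensities: pd.DataFrame
    manifest: pd.DataFrame

    def __post_init__(self) -> None:
        validate_feature_table(self.meta, self.intensities, self.manifest)

    # -- basic queries -------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.meta.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.manifest.index)

    @property
    def n_features(self) -> int:
        return len(self.meta)

    def samples_with_role(self, roles: str | Iterable[str]) -> list[str]:
        if isinstance(roles, str):
            roles = {roles}
        roles = set(roles)
        mask = self.manifest["role"].isin(roles)
        return list(self.manifest.index[mask])

    def batches(self) -> list:
        return sorted(self.manifest["batch_id"].unique())

    def feature(self, feature_id: str) -> Feature:
        row = self.meta.loc[feature_id]
        return Feature(
            feature_id=feature_id,
            mz=float(row["mz"]),
            rt=float(row["rt"]),
            intensities=self.intensities.loc[feature_id],
        )

    def iter_features(self) -> Iterator[Feature]:
        for fid in self.meta.index:
            yield self.feature(fid)

    # -- derived tables ------------------------------------------------
    def subset(self, feature_ids: Sequence[str]) -> "FeatureTable":
        ids = list(feature_ids)
        return FeatureTable(
            meta=self.meta.loc[ids].copy(),
            intensities=self.intensities.loc[ids].copy(),
            manifest=self.manifest.copy(),
        )

    def rt_window(self, start: float, end: float) -> "FeatureTable":
        """Features with start <= rt <= end (minutes)."""
        mask = (self.meta["rt"] >= start) & (self.meta["rt"] <= end)
        return self.subset(list(self.meta.index[mask]))


def validate_feature_table(
    meta: pd.DataFrame,
    intensities: pd.DataFrame,
    manifest: pd.DataFrame,
    *,
    check_instrument_range: bool = True,
    mz_range: tuple[float, float] = MZ_RANGE,
    rt_range: tuple[float, float] = RT_RANGE,
) -> None:
    """Validate invariants; raise :class:`ValidationError` naming offenders.

    Out-of-range m/z or retention time produces an
    :class:`InstrumentRangeWarning` rather than an error, since archived
    tables may legitimately carry features from a different acquisition
    window.
    """
    if meta.index.duplicated().any():
        dupes = sorted(meta.index[meta.index.duplicated()].unique())
        raise ValidationError(f"duplicate feature_id(s): {dupes}")
    if not meta.index.equals(intensities.index):
        raise ValidationError("meta and intensity rows disagree on feature_ids")

    table_samples = set(intensities.columns)
    manifest_samples = set(manifest.index)
    if manifest.index.duplicated().any():
        dupes = sorted(manifest.index[manifest.index.duplicated()].unique())
        raise ValidationError(f"duplicate sample_id(s) in manifest: {dupes}")
    missing = sorted(table_samples - manifest_samples)
    if missing:
        raise ValidationError(f"sample(s) in table absent from manifest: {missing}")
    extra = sorted(manifest_samples - table_samples)
    if extra:
        raise ValidationError(f"sample(s) in manifest absent from table: {extra}")

    bad_roles = sorted(set(manifest["role"]) - set(ROLES))
    if bad_roles:
        raise ValidationError(f"unknown sample role(s): {bad_roles}")

    neg = intensities.lt(0).any(axis=1)
    if neg.any():
        raise ValidationError(
            f"negative intensity in feature(s): {sorted(meta.index[neg])}"
        )

    if check_instrument_range:
        out_mz = meta.index[(meta["mz"] < mz_range[0]) | (meta["mz"] > mz_range[1])]
        if len(out_mz):
            warnings.warn(
                f"feature(s) outside m/z scan range {mz_range}: {sorted(out_mz)}",
                InstrumentRangeWarning,
                stacklevel=2,
            )
        out_rt = meta.index[(meta["rt"] < rt_range[0]) | (meta["rt"] > rt_range[1])]
        if len(out_rt):
            warnings.warn(
                f"feature(s) outside rt window {rt_range}: {sorted(out_rt)}",
                InstrumentRangeWarning,
                stacklevel=2,
            )


# ---------------------------------------------------------------------------
# Library entries and certified references
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LibraryEntry:
    """A target chemical: expected retention time plus its most abundant EI
    fragment m/z values.  The quantifier is the base-peak fragment whose
    intensity carries quantification.  ``linearity_rho`` is the absolute
    Spearman statistic from library qualification against a dilution series
    (chemicals with |rho| > 0.98 pass the inclusion screen)."""

    chemical_name: str
    rt_expected: float
    fragments: tuple[tuple[float, float], ...]  # (mz, relative_abundance) desc
    quantifier_mz: float
    chemical_class: str = ""
    linearity_rho: float | None = None

    def __post_init__(self) -> None:
        if not self.fragments:
            raise ValidationError(f"{self.chemical_name}: no fragments")
        rels = [r for _, r in self.fragments]
        if any(r <= 0 or r > 1 for r in rels):
            raise ValidationError(
                f"{self.chemical_name}: relative abundances must lie in (0, 1]"
            )
        if any(rels[i] < rels[i + 1] for i in range(len(rels) - 1)):
            raise ValidationError(
                f"{self.chemical_name}: fragments not sorted by relative abundance"
            )
        if not any(mz == self.quantifier_mz for mz, _ in self.fragments):
            raise ValidationError(
                f"{self.chemical_name}: quantifier m/z {self.quantifier_mz} "
                "is not one of the fragments"
            )
        if self.linearity_rho is not None and not (0.0 <= self.linearity_rho <= 1.0):
            raise ValidationError(
                f"{self.chemical_name}: linearity_rho outside [0, 1]"
            )

    @classmethod
    def build(
        cls,
        chemical_name: str,
        rt_expected: float,
        fragments: Iterable[tuple[float, float]],
        quantifier_mz: float,
        chemical_class: str = "",
        linearity_rho: float | None = None,
    ) -> "LibraryEntry":
        """Construct with fragments sorted by descending relative abundance."""
        frags = tuple(sorted(fragments, key=lambda fr: (-fr[1], fr[0])))
        return cls(
            chemical_name=chemical_name,
            rt_expected=rt_expected,
            fragments=frags,
            quantifier_mz=quantifier_mz,
            chemical_class=chemical_class,
            linearity_rho=linearity_rho,
        )

    @property
    def fragment_mzs(self) -> list[float]:
        return [mz for mz, _ in self.fragments]


@dataclass(frozen=True)
class CertifiedReference:
    """A certified (or estimated) mass fraction for one chemical in one NIST
    serum SRM, with its declared unit."""

    chemical_name: str
    srm_id: str  # "srm_1957" | "srm_1958"
    mass_fraction: float
    unit: str = "ng/mL"
    uncertainty: float | None = None

    def __post_init__(self) -> None:
        if self.srm_id not in ("srm_1957", "srm_1958"):
            raise ValidationError(
                f"{self.chemical_name}: unknown srm_id {self.srm_id!r}"
            )
        if not self.mass_fraction > 0:
            raise ValidationError(
                f"{self.chemical_name}/{self.srm_id}: mass_fraction must be > 0"
            )


@dataclass
class PseudoSpectrumRecord:
    """A pseudo-spectrum: the weighted EI fragment peaks attributed to one
    (possibly unidentified) chemical by untargeted clustering."""

    cluster_id: str
    rt: float
    peaks: list[tuple[float, float]]  # (mz, weighted_intensity), desc intensity
    excluded: list[tuple[str, float]] = field(default_factory=list)

    def validate(self) -> None:
        if len(self.peaks) < 3:
            raise ValidationError(
                f"{self.cluster_id}: pseudo-spectrum needs >=3 peaks, "
                f"got {len(self.peaks)}"
            )
        if any(i <= 0 for _, i in self.peaks):
            raise ValidationError(
                f"{self.cluster_id}: non-positive weighted intensity"
            )


# ---------------------------------------------------------------------------
# Readers / writers (CSV dialect: comma-separated, UTF-8, header row)
# ---------------------------------------------------------------------------


def read_feature_table(
    path: str | Path,
    manifest_path: str | Path,
    *,
    check_instrument_range: bool = True,
    combine_replicates: str | None = None,
) -> FeatureTable:
    """Read a feature-table CSV (feature_id, mz, rt, then one column per
    sample) and its manifest CSV (sample_id, role, batch_id[,
    injection_replicates][, parent_sample]).

    ``combine_replicates="mean"`` averages columns sharing a
    ``parent_sample`` in the manifest into one column per parent (the
    per-sample measurement is then the mean over repeated injections);
    ``None`` leaves columns untouched.
    """
    df = pd.read_csv(path)
    for col in ("feature_id", "mz", "rt"):
        if col not in df.columns:
            raise ValidationError(f"feature table missing column {col!r}")
    df = df.set_index("feature_id")
    meta = df[["mz", "rt"]].astype(float)
    intensities = df.drop(columns=["mz", "rt"]).astype(float)

    manifest = pd.read_csv(manifest_path).set_index("sample_id")
    if "injection_replicates" not in manifest.columns:
        manifest["injection_replicates"] = 1

    if combine_replicates is not None:
        if combine_replicates != "mean":
            raise ValidationError(
                f"unknown replicate-combining mode {combine_replicates!r}"
            )
        if "parent_sample" in manifest.columns and manifest["parent_sample"].notna().any():
            intensities, manifest = _combine_replicates(intensities, manifest)

    validate_feature_table(
        meta, intensities, manifest, check_instrument_range=check_instrument_range
    )
    return FeatureTable(meta=meta, intensities=intensities, manifest=manifest)


def _combine_replicates(
    intensities: pd.DataFrame, manifest: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    parent = manifest["parent_sample"].fillna(pd.Series(manifest.index, index=manifest.index))
    groups: dict[str, list[str]] = {}
    for sample, par in parent.items():
        groups.setdefault(str(par), []).append(sample)
    new_cols = {}
    rows = []
    for par, members in groups.items():
        new_cols[par] = intensities[members].mean(axis=1)
        first = manifest.loc[members[0]]
        rows.append(
            {
                "sample_id": par,
                "role": first["role"],
                "batch_id": first["batch_id"],
                "injection_replicates": len(members),
            }
        )
    new_int = pd.DataFrame(new_cols, index=intensities.index)
    new_manifest = pd.DataFrame(rows).set_index("sample_id")
    return new_int, new_manifest


def write_feature_table(
    table: FeatureTable, path: str | Path, manifest_path: str | Path
) -> None:
    out = pd.concat([table.meta, table.intensities], axis=1)
    out.index.name = "feature_id"
    out.to_csv(path)
    man = table.manifest.copy()
    man.index.name = "sample_id"
    man.to_csv(manifest_path)


_MAX_LIB_FRAGMENTS = 12


def read_library(path: str | Path) -> list[LibraryEntry]:
    """Read a chemical-library CSV with columns chemical, rt, mz1..mzK,
    rel1..relK, quantifier_index (1-based, into the mz columns), class and
    optionally linearity_rho.  Blank mz cells allow fewer than K fragments."""
    df = pd.read_csv(path)
    entries: list[LibraryEntry] = []
    mz_cols = [c for c in df.columns if c.startswith("mz")]
    for _, row in df.iterrows():
        name = str(row["chemical"])
        frags: list[tuple[float, float]] = []
        for col in mz_cols:
            k = col[2:]
            mz = row.get(col)
            if pd.isna(mz):
                continue
            rel = row.get(f"rel{k}")
            if pd.isna(rel):
                raise ValidationError(f"{name}: fragment mz{k} has no rel{k}")
            frags.append((float(mz), float(rel)))
        qi = row.get("quantifier_index")
        if pd.isna(qi):
            raise ValidationError(f"{name}: no quantifier flagged")
        qi = int(qi)
        if not (1 <= qi <= len(frags)):
            raise ValidationError(
                f"{name}: quantifier_index {qi} outside 1..{len(frags)}"
            )
        rho = row.get("linearity_rho")
        entries.append(
            LibraryEntry.build(
                chemical_name=name,
                rt_expected=float(row["rt"]),
                fragments=frags,
                quantifier_mz=frags[qi - 1][0],
                chemical_class=str(row.get("class", "") or ""),
                linearity_rho=None if pd.isna(rho) else float(rho),
            )
        )
    return entries


def write_library(entries: Sequence[LibraryEntry], path: str | Path) -> None:
    k = max((len(e.fragments) for e in entries), default=1)
    rows = []
    for e in entries:
        row: dict = {"chemical": e.chemical_name, "rt": e.rt_expected}
        for i, (mz, rel) in enumerate(e.fragments, start=1):
            row[f"mz{i}"] = mz
            row[f"rel{i}"] = rel
        row["quantifier_index"] = 1 + [m for m, _ in e.fragments].index(e.quantifier_mz)
        row["class"] = e.chemical_class
        row["linearity_rho"] = e.linearity_rho
        rows.append(row)
    cols = ["chemical", "rt"]
    for i in range(1, k + 1):
        cols += [f"mz{i}", f"rel{i}"]
    cols += ["quantifier_index", "class", "linearity_rho"]
    pd.DataFrame(rows).reindex(columns=cols).to_csv(path, index=False)


def read_references(path: str | Path) -> list[CertifiedReference]:
    """Read certified reference values: chemical, srm_id, mass_fraction,
    unit[, uncertainty].  A (chemical, srm) pair may appear at most once."""
    df = pd.read_csv(path)
    seen: set[tuple[str, str]] = set()
    refs: list[CertifiedReference] = []
    for _, row in df.iterrows():
        key = (str(row["chemical"]), str(row["srm_id"]))
        if key in seen:
            raise ValidationError(f"duplicate reference row for {key}")
        seen.add(key)
        unc = row.get("uncertainty")
        refs.append(
            CertifiedReference(
                chemical_name=key[0],
                srm_id=key[1],
                mass_fraction=float(row["mass_fraction"]),
                unit=str(row.get("unit", "ng/mL") or "ng/mL"),
                uncertainty=None if pd.isna(unc) else float(unc),
            )
        )
    return refs


def write_references(refs: Sequence[CertifiedReference], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "chemical": r.chemical_name,
                "srm_id": r.srm_id,
                "mass_fraction": r.mass_fraction,
                "unit": r.unit,
                "uncertainty": r.uncertainty,
            }
            for r in refs
        ]
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# MSP pseudo-spectrum export (NIST text dialect)
# ---------------------------------------------------------------------------

_MZ_DECIMALS = 5
_INT_DECIMALS = 4


def write_pseudospectra_msp(
    records: Sequence[PseudoSpectrumRecord], path: str | Path
) -> None:
    """Write pseudo-spectra as NIST MSP text: per record a ``Name:`` line,
    an RT comment, ``Num Peaks:`` and one "mz intensity" pair per line.
    An empty record list yields an empty file."""
    lines: list[str] = []
    for rec in records:
        rec.validate()
        lines.append(f"Name: {rec.cluster_id}")
        lines.append(f"Comment: RT={rec.rt:.{_MZ_DECIMALS}f} min")
        lines.append(f"Num Peaks: {len(rec.peaks)}")
        for mz, inten in rec.peaks:
            lines.append(f"{mz:.{_MZ_DECIMALS}f} {inten:.{_INT_DECIMALS}f}")
        lines.append("")
    Path(path).write_text("\n".join(lines), encoding="utf-8")


def read_pseudospectra_msp(path: str | Path) -> list[PseudoSpectrumRecord]:
    records: list[PseudoSpectrumRecord] = []
    name: str | None = None
    rt = math.nan
    peaks: list[tuple[float, float]] = []
    n_expected = 0

    def flush() -> None:
        nonlocal name, rt, peaks, n_expected
        if name is None:
            return
        if len(peaks) != n_expected:
            raise ValidationError(
                f"{name}: expected {n_expected} peaks, got {len(peaks)}"
            )
        rec = PseudoSpectrumRecord(cluster_id=name, rt=rt, peaks=peaks)
        rec.validate()
        records.append(rec)
        name, rt, peaks, n_expected = None, math.nan, [], 0

    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        line = raw.strip()
        if not line:
            flush()
            continue
        if line.startswith("Name:"):
            flush()
            name = line.split(":", 1)[1].strip()
        elif line.startswith("Comment:"):
            txt = line.split(":", 1)[1].strip()
            if txt.startswith("RT="):
                rt = float(txt[3:].split()[0])
        elif line.startswith("Num Peaks:"):
            n_expected = int(line.split(":", 1)[1])
        else:
            mz_s, int_s = line.split()
            peaks.append((float(mz_s), float(int_s)))
    flush()
    return records
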