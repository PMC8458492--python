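"""Synthetic GC-HRMS study generator with known ground truth.

Emulates the acquisition this workflow consumes: a batch of 20 study
samples plus one SRM-1957, one SRM-1958, two saline method blanks, two
solvent blanks and two isooctane blanks; features in m/z 85-850 Da and
retention time 3-24.37 min; a linear intensity-concentration response per
fragment with optional intercept and a per-chemical multiplicative recovery
factor (constant within a run, emulating consistent extraction recovery in
the 65-110% range); log-normal between-sample concentrations, positively
skewed as real population exposure distributions are; Gaussian m/z jitter
in ppm and retention-time jitter in minutes; and uniform low-intensity
background features present in every injection, which the 10-fold blank
filter should remove.

The reported intensity of each (feature, sample) cell is the mean over
``injection_replicates`` simulated injections, matching acquisition designs
where each sample is injected repeatedly (three times for plasma) and the
per-sample measurement is the replicate mean.  ``intensity_cv`` is the
per-injection multiplicative CV.

Everything is driven by a single integer seed through numpy's PCG64
generator, so a fixed seed reproduces the full stream bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .io import (
    MZ_RANGE,
    RT_RANGE,
    CertifiedReference,
    FeatureTable,
    LibraryEntry,
)

__all__ = [
    "NoiseModel",
    "SyntheticChemical",
    "GroundTruth",
    "DEFAULT_DILUTION_LEVELS",
    "DEFAULT_BATCH_BLANKS",
    "make_universe",
    "simulate_study",
    "simulate_calibration_series",
    "write_ground_truth",
    "config_snapshot",
]

#: Default external-calibration dilution series in ng/mL.
DEFAULT_DILUTION_LEVELS = (0.0, 0.05, 0.1, 0.25, 0.5, 1.0, 2.0)

#: Blank/reference layout accompanying each batch of study samples.
DEFAULT_BATCH_BLANKS = {
    "srm_1957": 1,
    "srm_1958": 1,
    "method_blank": 2,
    "solvent_blank": 2,
    "isooctane_blank": 2,
}


@dataclass
class NoiseModel:
    """Magnitudes of the simulated measurement noise.

    ppm_sigma : Gaussian m/z jitter (ppm of the true m/z); default 1.5 so
        nearly all features stay within a +/-5 ppm match window (~3.3 sigma).
    rt_sigma : Gaussian retention-time jitter in minutes (default 1 s).
    intensity_cv : per-injection multiplicative intensity CV.
    blank_background_features : count of background contaminant features
        present in all injections (blanks included).
    blank_background_mu / _sigma : log-normal parameters (natural log) of
        background intensity.
    seed : fixes the full random stream.
    """

    ppm_sigma: float = 1.5
    rt_sigma: float = 1.0 / 60.0
    intensity_cv: float = 0.1
    blank_background_features: int = 60
    blank_background_mu: float = 8.0  # e^8 ~= 3000 counts
    blank_background_sigma: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.ppm_sigma, self.rt_sigma, self.intensity_cv) < 0:
            raise ValueError("noise sigmas must be >= 0")
        if self.blank_background_features < 0:
            raise ValueError("blank_background_features must be >= 0")

    @classmethod
    def noiseless(cls, seed: int = 0, **overrides) -> "NoiseModel":
        """All noise off; background features off unless overridden."""
        kw = dict(
            ppm_sigma=0.0,
            rt_sigma=0.0,
            intensity_cv=0.0,
            blank_background_features=0,
            seed=seed,
        )
        kw.update(overrides)
        return cls(**kw)


@dataclass
class SyntheticChemical:
    """Ground-truth description of one planted chemical."""

    chemical_name: str
    rt_true: float
    fragments: list[tuple[float, float]]  # (mz_true, relative_abundance) desc
    response_slope: float  # intensity per concentration unit (quantifier)
    response_intercept: float = 0.0
    srm_concentrations: dict[str, float] = field(default_factory=dict)
    recovery_factor: float = 1.0
    chemical_class: str = ""

    def __post_init__(self) -> None:
        rels = [r for _, r in self.fragments]
        if not any(r == 1.0 for r in rels):
            raise ValueError(f"{self.chemical_name}: no base-peak fragment (rel 1.0)")
        if any(r <= 0 or r > 1 for r in rels):
            raise ValueError(f"{self.chemical_name}: relative abundance outside (0,1]")
        if not self.response_slope > 0:
            raise ValueError(f"{self.chemical_name}: response_slope must be > 0")
        if not (0 < self.recovery_factor <= 1.2):
            raise ValueError(f"{self.chemical_name}: recovery_factor outside (0,1.2]")

    @property
    def quantifier_mz(self) -> float:
        return max(self.fragments, key=lambda fr: fr[1])[0]


@dataclass
class GroundTruth:
    """What was planted: enough to score every downstream stage.

    feature_map : one row per chemical fragment feature (feature_id,
        chemical, fragment_index, mz_true, rt_true, relative_abundance).
    background_ids : feature_ids of background contaminant features.
    concentrations : long table (sample_id, chemical, concentration) for
        study and SRM samples.
    """

    feature_map: pd.DataFrame
    background_ids: list[str]
    concentrations: pd.DataFrame

    def concentration(self, chemical: str, sample: str) -> float:
        sel = self.concentrations[
            (self.concentrations["chemical"] == chemical)
            & (self.concentrations["sample_id"] == sample)
        ]
        return float(sel["concentration"].iloc[0])

    def concentration_frame(self) -> pd.DataFrame:
        """chemical x sample matrix of true concentrations."""
        return self.concentrations.pivot(
            index="chemical", columns="sample_id", values="concentration"
        )

    def chemical_of(self) -> dict[str, str]:
        """feature_id -> chemical name (chemical fragment features only)."""
        return dict(
            zip(self.feature_map["feature_id"], self.feature_map["chemical"])
        )

    def labels_for(self, feature_ids: Sequence[str]) -> list[str]:
        """Cluster-scoring labels: chemical name, or 'background'."""
        mapping = self.chemical_of()
        return [mapping.get(fid, "background") for fid in feature_ids]


# ---------------------------------------------------------------------------
# Universe construction
# ---------------------------------------------------------------------------


def _sample_spaced(
    rng: np.random.Generator,
    n: int,
    low: float,
    high: float,
    min_spacing: float,
    max_tries: int = 200_000,
) -> np.ndarray:
    """Uniform draws on [low, high] with pairwise separation >= min_spacing."""
    if n * min_spacing > (high - low):
        raise ValueError(
            f"cannot place {n} values with spacing {min_spacing} in "
            f"[{low}, {high}]: range too dense"
        )
    placed: list[float] = []
    tries = 0
    while len(placed) < n:
        tries += 1
        if tries > max_tries:
            raise ValueError(
                f"failed to place {n} values with spacing {min_spacing} in "
                f"[{low}, {high}] after {max_tries} draws"
            )
        x = float(rng.uniform(low, high))
        if all(abs(x - p) >= min_spacing for p in placed):
            placed.append(x)
    return np.array(placed)


def make_universe(
    n_chemicals: int,
    n_fragments_range: tuple[int, int] = (3, 6),
    noise: NoiseModel | None = None,
    *,
    rt_range: tuple[float, float] = RT_RANGE,
    mz_range: tuple[float, float] = MZ_RANGE,
    min_mz_spacing: float = 0.5,
    min_rt_spacing: float = 0.05,
    slope_range: tuple[float, float] = (5e4, 2e5),
    recovery_range: tuple[float, float] = (0.65, 1.10),
    srm_1958_range: tuple[float, float] = (0.5, 2.0),
    srm_1957_range: tuple[float, float] = (0.05, 0.5),
    intercept: float = 0.0,
    chemical_classes: Sequence[str] = ("PCB", "OCP", "PBDE", "PAH"),
) -> tuple[list[SyntheticChemical], list[LibraryEntry], list[CertifiedReference]]:
    """Generate planted chemicals, the (noiseless) library built from them,
    and certified reference values equal to the true SRM concentrations.

    The library mirrors one built from authentic standards: it carries the
    TRUE retention times and fragment m/z.  SRM-1958 emulates fortified
    serum (higher concentrations) and SRM-1957 nonfortified serum.
    """
    if n_chemicals < 1:
        raise ValueError("n_chemicals must be >= 1")
    lo, hi = n_fragments_range
    if not (1 <= lo <= hi <= 12):
        raise ValueError("n_fragments_range must lie within [1, 12]")
    noise = noise or NoiseModel()
    rng = np.random.default_rng(noise.seed)

    n_frags = rng.integers(lo, hi + 1, size=n_chemicals)
    all_mz = _sample_spaced(
        rng, int(n_frags.sum()), mz_range[0], mz_range[1], min_mz_spacing
    )
    rts = _sample_spaced(rng, n_chemicals, rt_range[0], rt_range[1], min_rt_spacing)

    chemicals: list[SyntheticChemical] = []
    library: list[LibraryEntry] = []
    references: list[CertifiedReference] = []
    pos = 0
    for i in range(n_chemicals):
        k = int(n_frags[i])
        mzs = all_mz[pos : pos + k]
        pos += k
        rels = np.concatenate([[1.0], rng.uniform(0.1, 0.9, size=k - 1)])
        order = np.argsort(-rels)
        frags = [(float(mzs[j]), float(rels[j])) for j in order]
        name = f"CHEM{i + 1:03d}"
        chem = SyntheticChemical(
            chemical_name=name,
            rt_true=float(rts[i]),
            fragments=frags,
            response_slope=float(rng.uniform(*slope_range)),
            response_intercept=intercept,
            srm_concentrations={
                "srm_1957": float(rng.uniform(*srm_1957_range)),
                "srm_1958": float(rng.uniform(*srm_1958_range)),
            },
            recovery_factor=float(rng.uniform(*recovery_range)),
            chemical_class=str(chemical_classes[i % len(chemical_classes)]),
        )
        chemicals.append(chem)
        library.append(
            LibraryEntry.build(
                chemical_name=name,
                rt_expected=chem.rt_true,
                fragments=chem.fragments,
                quantifier_mz=chem.quantifier_mz,
                chemical_class=chem.chemical_class,
                linearity_rho=1.0,
            )
        )
        for srm_id, conc in chem.srm_concentrations.items():
            references.append(
                CertifiedReference(
                    chemical_name=name,
                    srm_id=srm_id,
                    mass_fraction=conc,
                    unit="ng/mL",
                )
            )
    return chemicals, library, references


# ---------------------------------------------------------------------------
# Study simulation
# ---------------------------------------------------------------------------


def _measured_intensity(
    rng: np.random.Generator, true_level: float, cv: float, n_injections: int
) -> float:
    """Mean of n_injections draws of true_level * (1 + eps), eps ~ N(0, cv),
    floored at zero per injection."""
    if true_level <= 0:
        return 0.0
    if cv == 0:
        return true_level
    draws = true_level * (1.0 + rng.normal(0.0, cv, size=n_injections))
    return float(np.maximum(draws, 0.0).mean())


def simulate_study(
    chemicals: Sequence[SyntheticChemical],
    n_study_samples: int = 20,
    *,
    n_batches: int = 1,
    noise: NoiseModel | None = None,
    concentration_median: float = 0.2,
    concentration_sigma: float = 1.0,
    planted: Sequence[str] | None = None,
    batch_scale: Sequence[float] | None = None,
    carryover_fraction: float = 0.0,
    injection_replicates: int = 3,
    blank_layout: dict[str, int] | None = None,
) -> tuple[FeatureTable, GroundTruth]:
    """Simulate one or more acquisition batches.

    Each batch holds ``n_study_samples`` study samples plus the blank/SRM
    layout in ``blank_layout`` (default: one SRM-1957, one SRM-1958, two
    method blanks, two solvent blanks, two isooctane blanks).  Study-sample
    concentrations are log-normal (median ``concentration_median``, log-sd
    ``concentration_sigma``); SRM samples use the chemicals' true SRM
    concentrations; blanks carry no chemical signal unless
    ``carryover_fraction`` > 0, in which case method blanks receive that
    fraction of the batch's mean study signal.

    ``planted`` restricts which chemicals contribute features (others are
    library decoys absent from the data).  ``batch_scale`` multiplies all
    chemical responses of a batch by a constant, emulating between-batch
    instrument drift.
    """
    if n_study_samples < 1:
        raise ValueError("n_study_samples must be >= 1")
    noise = noise or NoiseModel()
    rng = np.random.default_rng(np.random.SeedSequence([noise.seed, 1]))
    blank_layout = dict(DEFAULT_BATCH_BLANKS if blank_layout is None else blank_layout)
    if batch_scale is None:
        batch_scale = [1.0] * n_batches
    if len(batch_scale) != n_batches:
        raise ValueError("batch_scale must have one entry per batch")
    planted_set = (
        {c.chemical_name for c in chemicals} if planted is None else set(planted)
    )

    # --- manifest ------------------------------------------------------
    rows = []
    for b in range(1, n_batches + 1):
        for i in range(1, n_study_samples + 1):
            rows.append((f"B{b:02d}_S{i:02d}", "study", b))
        for role, count in blank_layout.items():
            for i in range(1, count + 1):
                rows.append((f"B{b:02d}_{role}_{i}", role, b))
    manifest = pd.DataFrame(rows, columns=["sample_id", "role", "batch_id"])
    manifest["injection_replicates"] = injection_replicates
    manifest = manifest.set_index("sample_id")
    samples = list(manifest.index)
    batch_of = manifest["batch_id"].to_dict()
    role_of = manifest["role"].to_dict()

    # --- true concentrations ------------------------------------------
    conc_rows = []
    conc: dict[tuple[str, str], float] = {}
    mu = np.log(concentration_median)
    for chem in chemicals:
        if chem.chemical_name not in planted_set:
            continue
        for s in samples:
            role = role_of[s]
            if role == "study":
                c = float(rng.lognormal(mu, concentration_sigma))
            elif role in ("srm_1957", "srm_1958"):
                c = chem.srm_concentrations.get(role, 0.0)
            else:
                c = 0.0
            conc[(chem.chemical_name, s)] = c
            if role in ("study", "srm_1957", "srm_1958"):
                conc_rows.append((s, chem.chemical_name, c))

    # --- chemical fragment features -----------------------------------
    meta_rows = []
    intensity_rows = []
    fmap_rows = []
    fid_n = 0
    for chem in chemicals:
        if chem.chemical_name not in planted_set:
            continue
        for frag_idx, (mz_true, rel) in enumerate(chem.fragments):
            fid_n += 1
            fid = f"F{fid_n:05d}"
            mz_obs = mz_true * (1.0 + rng.normal(0.0, noise.ppm_sigma) * 1e-6)
            rt_obs = chem.rt_true + rng.normal(0.0, noise.rt_sigma)
            rt_obs = float(np.clip(rt_obs, RT_RANGE[0], RT_RANGE[1]))
            # noiseless per-sample response level for this fragment
            levels: dict[str, float] = {}
            for s in samples:
                scale = batch_scale[batch_of[s] - 1]
                c = conc[(chem.chemical_name, s)]
                if c > 0:
                    levels[s] = (
                        rel
                        * chem.response_slope
                        * chem.recovery_factor
                        * c
                        * scale
                        + rel * chem.response_intercept
                    )
                else:
                    levels[s] = 0.0
            if carryover_fraction > 0:
                for b in range(1, n_batches + 1):
                    study_b = [
                        levels[s]
                        for s in samples
                        if batch_of[s] == b and role_of[s] == "study"
                    ]
                    trace = carryover_fraction * float(np.mean(study_b))
                    for s in samples:
                        if batch_of[s] == b and role_of[s] == "method_blank":
                            levels[s] = trace
            row = {}
            for s in samples:
                val = _measured_intensity(
                    rng, levels[s], noise.intensity_cv, injection_replicates
                )
                row[s] = val if val > 0 else np.nan
            meta_rows.append((fid, float(mz_obs), rt_obs))
            intensity_rows.append(row)
            fmap_rows.append(
                (fid, chem.chemical_name, frag_idx, mz_true, chem.rt_true, rel)
            )

    # --- background contaminant features ------------------------------
    background_ids: list[str] = []
    for _ in range(noise.blank_background_features):
        fid_n += 1
        fid = f"F{fid_n:05d}"
        background_ids.append(fid)
        mz = float(rng.uniform(*MZ_RANGE))
        rt = float(rng.uniform(*RT_RANGE))
        base = float(rng.lognormal(noise.blank_background_mu, noise.blank_background_sigma))
        row = {}
        for s in samples:
            cv = max(noise.intensity_cv, 0.05)  # background always fluctuates a bit
            row[s] = _measured_intensity(rng, base, cv, injection_replicates)
        meta_rows.append((fid, mz, rt))
        intensity_rows.append(row)

    meta = pd.DataFrame(meta_rows, columns=["feature_id", "mz", "rt"]).set_index(
        "feature_id"
    )
    intensities = pd.DataFrame(intensity_rows, index=meta.index)[samples]
    table = FeatureTable(meta=meta, intensities=intensities, manifest=manifest)
    truth = GroundTruth(
        feature_map=pd.DataFrame(
            fmap_rows,
            columns=[
                "feature_id",
                "chemical",
                "fragment_index",
                "mz_true",
                "rt_true",
                "relative_abundance",
            ],
        ),
        background_ids=background_ids,
        concentrations=pd.DataFrame(
            conc_rows, columns=["sample_id", "chemical", "concentration"]
        ),
    )
    return table, truth


def simulate_calibration_series(
    chemical: SyntheticChemical,
    levels: Sequence[float] = DEFAULT_DILUTION_LEVELS,
    replicates: int = 3,
    noise: NoiseModel | None = None,
) -> pd.DataFrame:
    """Simulate the neat-solvent external-calibration dilution series for
    one chemical (quantifier fragment; no matrix, no recovery loss).

    Returns a long DataFrame (level, replicate, response)."""
    levels = list(levels)
    if len(set(levels)) < 2:
        raise ValueError("need >= 2 distinct calibration levels")
    if any(l < 0 for l in levels):
        raise ValueError("calibration levels must be non-negative")
    noise = noise or NoiseModel()
    rng = np.random.default_rng(np.random.SeedSequence([noise.seed, 2]))
    rows = []
    for level in levels:
        true = chemical.response_slope * level + chemical.response_intercept
        for rep in range(1, replicates + 1):
            if noise.intensity_cv > 0:
                resp = max(0.0, true * (1.0 + rng.normal(0.0, noise.intensity_cv)))
            else:
                resp = true
            rows.append((level, rep, resp))
    return pd.DataFrame(rows, columns=["level", "replicate", "response"])


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    """Ground-truth CSV: one row per (feature, sample) with the chemical,
    fragment index and true concentration."""
    merged = truth.feature_map.merge(truth.concentrations, on="chemical")
    merged[
        ["feature_id", "chemical", "fragment_index", "sample_id", "concentration"]
    ].rename(columns={"concentration": "true_concentration"}).to_csv(path, index=False)


def config_snapshot(noise: NoiseModel, extra: dict | None = None) -> dict:
    """Serializable record of the generator settings, including the RNG
    algorithm, for run-to-run provenance."""
    snap = {
        "generator": "numpy.random.Generator(PCG64)",
        "noise": asdict(noise),
    }
    if extra:
        snap.update(extra)
    return snap


def write_config_snapshot(noise: NoiseModel, path: str | Path, extra: dict | None = None) -> None:
    Path(path).write_text(yaml.safe_dump(config_snapshot(noise, extra)), encoding="utf-8")
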