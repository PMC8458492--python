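"""End-to-end orchestration: validate -> blank filter -> targeted match ->
cluster the unmatched residue -> export pseudo-spectra -> quantify ->
report.

The pipeline is a pure function of (inputs, config): two runs with the
same config and inputs produce byte-identical CSV outputs.  Matched
features are removed before untargeted clustering by default so that
pseudo-spectra describe the unidentified residue ("dark matter"); set
``cluster_matched=True`` for the inclusive behavior.

A demo mode runs the whole workflow on the bundled synthetic generator,
so the pipeline is exercisable without any acquisition data.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

from . import annotate, cluster, qc, quantify, simulate
from .io import (
    FeatureTable,
    read_feature_table,
    read_library,
    read_references,
    write_feature_table,
    write_library,
    write_pseudospectra_msp,
    write_references,
)
from .quantify import QuantResult, results_frame

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "summarize_coexposure"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage rejected its input; carries the stage's diagnostic."""


@dataclass
class RunConfig:
    """Everything a run needs; serializable to YAML beside its outputs."""

    out_dir: str = "gcexpose_run"
    seed: int = 0
    # input paths (all None -> demo mode on synthetic data)
    feature_table: str | None = None
    manifest: str | None = None
    library: str | None = None
    references: str | None = None
    # demo-mode generator settings
    demo_n_chemicals: int = 30
    demo_n_study_samples: int = 20
    demo_unknown_fraction: float = 0.3  # planted chemicals absent from the library
    demo_noise: dict = field(default_factory=dict)
    # QC
    blank_fold: float = 10.0
    enforce_layout: bool = True
    # matching
    ppm_tol: float = 5.0
    rt_tol_s: float = 30.0
    min_fragments: int = 3
    # clustering
    sigma_rt: float = 0.05
    sigma_corr: float = 0.5
    correlation_kind: str = "spearman"
    cut_height: float = 0.5
    min_cluster_size: int = 3
    cluster_window_min: float = 2.0
    cluster_matched: bool = False

    @property
    def demo_mode(self) -> bool:
        return self.feature_table is None

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text(encoding="utf-8")))

    def similarity_params(self) -> cluster.SimilarityParams:
        return cluster.SimilarityParams(
            sigma_rt=self.sigma_rt,
            sigma_corr=self.sigma_corr,
            correlation_kind=self.correlation_kind,
            cut_height=self.cut_height,
            min_cluster_size=self.min_cluster_size,
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _cluster_windowed(
    table: FeatureTable, params: cluster.SimilarityParams, window_min: float
) -> cluster.ClusterResult:
    """Cluster in rt slabs of ``window_min`` minutes with 3*sigma_rt overlap;
    overlap features belong to the window whose center is nearer."""
    if table.n_features == 0:
        return cluster.ClusterResult(clusters=[], unclustered=[])
    rt = table.meta["rt"]
    lo, hi = float(rt.min()), float(rt.max())
    if hi - lo <= window_min:
        return cluster.cluster_features(table, params)
    edges = np.arange(lo, hi + window_min, window_min)
    clusters: list[cluster.SpectralCluster] = []
    unclustered: list[str] = []
    for k in range(len(edges) - 1):
        last = k == len(edges) - 2
        # half-open slabs (last one closed) so each feature lands in
        # exactly one window -- the one whose center is nearest
        sel = [
            fid
            for fid in table.feature_ids
            if edges[k] <= rt[fid] < edges[k + 1] or (last and rt[fid] >= edges[k + 1])
        ]
        if not sel:
            continue
        res = cluster.cluster_features(table.subset(sel), params)
        for c in res.clusters:
            c.cluster_id = f"W{k + 1:02d}_{c.cluster_id}"
        clusters.extend(res.clusters)
        unclustered.extend(res.unclustered)
    return cluster.ClusterResult(clusters=clusters, unclustered=unclustered)


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; returns an artifact manifest with per-stage counts
    and output-file checksums.  Any stage rejection raises
    :class:`PipelineError` carrying the stage diagnostic."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # -- stage 0: inputs ------------------------------------------------
    if config.demo_mode:
        noise = simulate.NoiseModel(seed=config.seed, **config.demo_noise)
        chems, library, references = simulate.make_universe(
            config.demo_n_chemicals, noise=noise
        )
        # hold back a fraction of planted chemicals from the library so the
        # untargeted stage has an unidentified residue to cluster
        n_known = max(1, round(config.demo_n_chemicals * (1 - config.demo_unknown_fraction)))
        known = {c.chemical_name for c in chems[:n_known]}
        library = [e for e in library if e.chemical_name in known]
        references = [r for r in references if r.chemical_name in known]
        table, truth = simulate.simulate_study(
            chems, config.demo_n_study_samples, noise=noise
        )
        write_feature_table(table, out / "features.csv", out / "manifest.csv")
        write_library(library, out / "library.csv")
        write_references(references, out / "references.csv")
        simulate.write_ground_truth(truth, out / "ground_truth.csv")
        simulate.write_config_snapshot(noise, out / "generator.yaml")
    else:
        try:
            table = read_feature_table(config.feature_table, config.manifest)
            library = read_library(config.library)
            references = read_references(config.references) if config.references else []
        except Exception as exc:
            raise PipelineError(f"input stage: {exc}") from exc
    n_total = table.n_features
    logger.info("inputs: %d features, %d samples", n_total, len(table.sample_ids))

    # -- stage 1: layout validation --------------------------------------
    violations = qc.validate_batch_layout(table.manifest)
    if violations and config.enforce_layout:
        raise PipelineError(
            "layout validation: " + "; ".join(str(v) for v in violations)
        )

    # -- stage 2: blank filter -------------------------------------------
    try:
        filtered, report = qc.blank_filter(table, fold=config.blank_fold)
    except Exception as exc:
        raise PipelineError(f"blank_filter: {exc}") from exc
    report.layout_violations = violations
    logger.info(
        "blank_filter: %d -> %d features", n_total, filtered.n_features
    )

    # -- stage 3: targeted matching --------------------------------------
    matches, conflicts = annotate.match_all(
        filtered,
        library,
        ppm_tol=config.ppm_tol,
        rt_tol_s=config.rt_tol_s,
        min_fragments=config.min_fragments,
    )
    matched_ids = sorted(
        {m.feature_id for res in matches if res.identified for m in res.matched_fragments}
    )
    n_identified = sum(res.identified for res in matches)
    logger.info(
        "match_all: %d/%d chemicals identified, %d features matched",
        n_identified, len(library), len(matched_ids),
    )

    # -- stage 4: untargeted clustering of the residue --------------------
    if config.cluster_matched:
        residue = filtered
    else:
        residue = filtered.subset(
            [f for f in filtered.feature_ids if f not in set(matched_ids)]
        )
    cres = _cluster_windowed(
        residue, config.similarity_params(), config.cluster_window_min
    )
    logger.info(
        "clustering: %d features -> %d clusters, %d unclustered",
        residue.n_features, len(cres.clusters), len(cres.unclustered),
    )

    # -- stage 5: pseudo-spectrum export ----------------------------------
    records = []
    for c in cres.clusters:
        rec = cluster.weighted_spectrum(c, residue, config.similarity_params())
        if len(rec.peaks) >= 3:
            records.append(rec)
    write_pseudospectra_msp(records, out / "pseudospectra.msp")

    # -- stage 6: quantification ------------------------------------------
    quant = quantify.quantify_study(filtered, matches, references)
    results_frame(quant).to_csv(out / "quantification.csv", index=False)

    # -- stage 7: reports ---------------------------------------------------
    match_rows = [
        {
            "chemical": r.chemical_name,
            "class": r.chemical_class,
            "n_fragments": r.n_fragments_matched,
            "identified": r.identified,
            "quantifier_feature": r.quantifier_feature,
        }
        for r in matches
    ]
    pd.DataFrame(match_rows).to_csv(out / "matches.csv", index=False)
    conflicts.to_csv(out / "conflicts.csv", index=False)
    cluster_rows = [
        {
            "cluster_id": c.cluster_id,
            "n_members": len(c.members),
            "members": ";".join(c.members),
            "rt": c.cluster_rt,
            "mean_internal_correlation": c.mean_internal_correlation,
        }
        for c in cres.clusters
    ]
    pd.DataFrame(cluster_rows).to_csv(out / "clusters.csv", index=False)
    report.write_yaml(out / "qc_report.yaml")
    config.to_yaml(out / "config.yaml")

    n_clustered = sum(len(c.members) for c in cres.clusters)
    manifest = {
        "counts": {
            "features_total": n_total,
            "features_blank_removed": n_total - filtered.n_features,
            "features_matched": len(matched_ids),
            "features_clustered": n_clustered,
            "features_unclustered": len(cres.unclustered),
            "chemicals_identified": n_identified,
            "clusters": len(cres.clusters),
        },
        "artifacts": {
            p.name: _sha256(p) for p in sorted(out.iterdir()) if p.is_file()
        },
    }
    (out / "run_manifest.yaml").write_text(
        yaml.safe_dump(manifest), encoding="utf-8"
    )
    return manifest


# ---------------------------------------------------------------------------
# Co-exposure summary
# ---------------------------------------------------------------------------


@dataclass
class CoexposureSummary:
    correlation: pd.DataFrame  # chemical x chemical rank correlation
    order: list[str]  # dendrogram leaf order
    linkage_matrix: np.ndarray | None
    note: str = ""


def summarize_coexposure(
    quant: Iterable[QuantResult],
    *,
    min_common_samples: int = 3,
    correlation_kind: str = "spearman",
) -> CoexposureSummary:
    """Rank-correlation matrix among quantified chemicals across samples,
    with an average-linkage ordering on distance 1 - |rho|.

    Concentrations are log-transformed as log(x + eps) with eps = half the
    smallest positive value (rank correlation is unaffected; the transform
    matters for the Pearson mode)."""
    df = results_frame(list(quant)).dropna(subset=["concentration"])
    if df.empty:
        return CoexposureSummary(pd.DataFrame(), [], None, "no quantified results")
    mat = df.pivot_table(
        index="sample", columns="chemical", values="concentration", aggfunc="mean"
    )
    mat = mat.dropna(axis=1, thresh=min_common_samples)
    if mat.shape[1] < 2:
        return CoexposureSummary(
            pd.DataFrame(), list(mat.columns), None,
            "fewer than 2 chemicals with enough common samples",
        )
    positive = mat.values[mat.values > 0]
    eps = positive.min() / 2.0 if positive.size else 1e-12
    logged = np.log(mat + eps)
    corr = logged.corr(method=correlation_kind, min_periods=min_common_samples)
    dist = 1.0 - corr.abs().fillna(0.0).to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    Z = linkage(squareform(dist, checks=False), method="average")
    order = [corr.columns[i] for i in leaves_list(Z)]
    return CoexposureSummary(corr, order, Z)


def coexposure_groups(summary: CoexposureSummary, n_groups: int) -> dict[str, int]:
    """Cut the coexposure dendrogram into ``n_groups`` chemical groups."""
    from scipy.cluster.hierarchy import fcluster

    if summary.linkage_matrix is None:
        return {}
    labels = fcluster(summary.linkage_matrix, t=n_groups, criterion="maxclust")
    return dict(zip(summary.correlation.columns, (int(l) for l in labels)))
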