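"""Gaussian-product similarity, pseudo-spectrum clustering, weighting and
cosine matching."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata
from sklearn.metrics import adjusted_rand_score

from gcexpose import (
    NoiseModel,
    PseudoSpectrumRecord,
    SimilarityParams,
    cluster_features,
    cosine_match,
    feature_similarity,
    make_universe,
    similarity_matrix,
    simulate_study,
    sweep_cut_height,
    weighted_spectrum,
)
from gcexpose.cluster import SpectralCluster


def _feature_pair(make_table, rt_i, rt_j, vals_i, vals_j):
    samples = [f"S{k}" for k in range(len(vals_i))]
    rows = [("Fi", 300.0, rt_i, dict(zip(samples, vals_i))),
            ("Fj", 310.0, rt_j, dict(zip(samples, vals_j)))]
    manifest = [(s, "study", 1) for s in samples] + [("MB", "method_blank", 1)]
    for r in rows:
        r[3]["MB"] = None
    table = make_table(rows, manifest)
    return table.feature("Fi"), table.feature("Fj")


class TestFeatureSimilarity:
    def test_identical_profiles_at_same_rt_give_one(self, make_table):
        fi, fj = _feature_pair(make_table, 10.0, 10.0, [1, 2, 3, 4], [2, 4, 6, 8])
        assert feature_similarity(fi, fj) == pytest.approx(1.0)

    def test_one_sigma_rt_offset_gives_exp_minus_half(self, make_table):
        params = SimilarityParams(sigma_rt=0.05)
        fi, fj = _feature_pair(make_table, 10.0, 10.05, [1, 2, 3, 4], [2, 4, 6, 8])
        assert feature_similarity(fi, fj, params) == pytest.approx(math.exp(-0.5))

    def test_zero_correlation_closed_form(self, make_table):
        params = SimilarityParams(sigma_corr=0.5)
        # rank-correlation 0 by construction, same rt
        fi, fj = _feature_pair(make_table, 10.0, 10.0, [1, 2, 3, 4], [2, 4, 1, 3])
        assert feature_similarity(fi, fj, params) == pytest.approx(
            math.exp(-1.0 / (2 * 0.5**2))
        )

    def test_too_few_shared_samples_gives_zero(self, make_table):
        fi, fj = _feature_pair(make_table, 10.0, 10.0, [1, None, None, 4],
                               [2, 4, 6, 8])
        assert feature_similarity(fi, fj) == 0.0

    def test_matrix_equals_scalar_loop_oracle(self, noisy_study):
        """The similarity matrix equals an element-by-element oracle that
        recomputes rank correlation from scratch with numpy."""
        _, _, _, table, _ = noisy_study
        sub = table.subset(table.feature_ids[:30])
        params = SimilarityParams()
        ids, S = similarity_matrix(sub, params)
        assert np.allclose(S, S.T)
        assert np.allclose(np.diag(S), 1.0)

        nonblank = sub.samples_with_role({"study", "srm_1957", "srm_1958"})
        X = sub.intensities[nonblank]
        meta = sub.meta
        for a in range(len(ids)):
            for b in range(a + 1, len(ids)):
                xa, xb = X.loc[ids[a]], X.loc[ids[b]]
                shared = xa.dropna().index.intersection(xb.dropna().index)
                if len(shared) < 3:
                    expected = 0.0
                else:
                    ra = rankdata(xa[shared])
                    rb = rankdata(xb[shared])
                    r = np.corrcoef(ra, rb)[0, 1]
                    drt = meta.loc[ids[a], "rt"] - meta.loc[ids[b], "rt"]
                    expected = math.exp(-drt**2 / (2 * params.sigma_rt**2)) * math.exp(
                        -((1 - r) ** 2) / (2 * params.sigma_corr**2)
                    )
                assert S[a, b] == pytest.approx(expected, rel=1e-9, abs=1e-12)


class TestClusterFeatures:
    def test_two_well_separated_chemicals_recovered_exactly(self):
        noise = NoiseModel.noiseless(seed=6)
        chems, _, _ = make_universe(2, (5, 5), noise, min_rt_spacing=1.0)
        table, truth = simulate_study(chems, 8, noise=noise)
        res = cluster_features(table)
        assert len(res.clusters) == 2
        assert sorted(len(c.members) for c in res.clusters) == [5, 5]
        assert res.unclustered == []
        truth_groups = {
            chem: set(grp["feature_id"])
            for chem, grp in truth.feature_map.groupby("chemical")
        }
        assert {frozenset(c.members) for c in res.clusters} == {
            frozenset(g) for g in truth_groups.values()
        }

    def test_min_size_rule_reports_singletons_unclustered(self):
        noise = NoiseModel(seed=8, ppm_sigma=0.0, rt_sigma=0.0, intensity_cv=0.0,
                           blank_background_features=2)
        chems, _, _ = make_universe(1, (5, 5), noise)
        table, truth = simulate_study(chems, 8, noise=noise)
        res = cluster_features(table)
        assert len(res.clusters) == 1
        assert len(res.clusters[0].members) == 5
        assert set(res.unclustered) == set(truth.background_ids)

    def test_partition_property(self, noisy_study):
        _, _, _, table, _ = noisy_study
        res = cluster_features(table)
        assigned = [m for c in res.clusters for m in c.members] + res.unclustered
        assert sorted(assigned) == sorted(table.feature_ids)
        assert all(len(c.members) >= 3 for c in res.clusters)

    def test_invariant_under_relabeling(self, noisy_study):
        _, _, _, table, _ = noisy_study
        sub = table.subset(table.feature_ids[:40])
        base = cluster_features(sub)
        rng = np.random.default_rng(1)
        order = list(sub.feature_ids)
        rng.shuffle(order)
        shuffled = cluster_features(sub.subset(order))
        assert {frozenset(c.members) for c in base.clusters} == {
            frozenset(c.members) for c in shuffled.clusters
        }

    def test_empty_window_warns(self, noisy_study):
        _, _, _, table, _ = noisy_study
        with pytest.warns(UserWarning, match="window"):
            res = cluster_features(table, rt_window=(0.1, 0.2))
        assert res.clusters == [] and res.unclustered == []

    def test_noiseless_sweep_reports_perfect_interval(self):
        noise = NoiseModel.noiseless(seed=13)
        chems, _, _ = make_universe(5, (4, 4), noise, rt_range=(18.0, 20.0),
                                    min_rt_spacing=0.3)
        table, truth = simulate_study(chems, 10, noise=noise)
        labels = dict(zip(truth.feature_map["feature_id"], truth.feature_map["chemical"]))
        sweep = sweep_cut_height(table, SimilarityParams(), labels,
                                 heights=[0.2, 0.4, 0.6, 0.8])
        perfect = sweep[sweep["ari"] == 1.0]
        assert len(perfect) >= 1


class TestWeightedSpectrum:
    def test_perfectly_correlated_members_weighted_by_mean_intensity(self):
        noise = NoiseModel.noiseless(seed=3)
        chems, _, _ = make_universe(1, (4, 4), noise)
        table, truth = simulate_study(chems, 6, noise=noise)
        members = list(truth.feature_map["feature_id"])
        cluster = SpectralCluster("C001", members, 10.0, 1.0)
        rec = weighted_spectrum(cluster, table)
        nonblank = table.samples_with_role({"study", "srm_1957", "srm_1958"})
        expected = {
            round(float(table.meta.loc[m, "mz"]), 9): float(
                table.intensities.loc[m, nonblank].mean()
            )
            for m in members
        }
        for mz, w in rec.peaks:
            assert w == pytest.approx(expected[round(mz, 9)])
        assert [w for _, w in rec.peaks] == sorted(
            (w for _, w in rec.peaks), reverse=True
        )

    def test_uncorrelated_member_flagged_with_zero_weight(self, make_table):
        samples = [f"S{k}" for k in range(4)]
        manifest = [(s, "study", 1) for s in samples] + [("MB", "method_blank", 1)]
        up = [1.0, 2.0, 3.0, 4.0]
        rows = [
            ("F1", 300.0, 10.0, dict(zip(samples, up), MB=None)),
            ("F2", 310.0, 10.0, dict(zip(samples, [2 * v for v in up]), MB=None)),
            ("F3", 320.0, 10.0, dict(zip(samples, [3 * v for v in up]), MB=None)),
            # zero rank correlation to the others
            ("F4", 330.0, 10.0, dict(zip(samples, [2.0, 4.0, 1.0, 3.0]), MB=None)),
        ]
        table = make_table(rows, manifest)
        cluster = SpectralCluster("C001", ["F1", "F2", "F3", "F4"], 10.0, 0.5)
        rec = weighted_spectrum(cluster, table)
        assert len(rec.peaks) == 3
        assert [fid for fid, _ in rec.excluded] == ["F4"]
        assert rec.excluded[0][1] == pytest.approx(0.0)

    def test_matches_scalar_loop_oracle(self, noisy_study):
        _, _, _, table, truth = noisy_study
        chem = truth.feature_map["chemical"].iloc[0]
        members = list(
            truth.feature_map.loc[truth.feature_map["chemical"] == chem, "feature_id"]
        )
        cluster = SpectralCluster("C001", members, 10.0, 0.9)
        rec = weighted_spectrum(cluster, table)
        nonblank = table.samples_with_role({"study", "srm_1957", "srm_1958"})
        # independent oracle via numpy rank correlation
        weights = {}
        for m in members:
            xm = table.intensities.loc[m, nonblank]
            rs = []
            for o in members:
                if o == m:
                    continue
                xo = table.intensities.loc[o, nonblank]
                shared = xm.dropna().index.intersection(xo.dropna().index)
                if len(shared) < 3:
                    rs.append(0.0)
                else:
                    rs.append(
                        float(np.corrcoef(rankdata(xm[shared]), rankdata(xo[shared]))[0, 1])
                    )
            weights[float(table.meta.loc[m, "mz"])] = float(xm.mean()) * float(
                np.mean(rs)
            )
        got = dict(rec.peaks)
        got.update({table.meta.loc[m, "mz"]: w for m, w in rec.excluded})
        for mz, w in weights.items():
            assert got[mz] == pytest.approx(w, rel=1e-9)


class TestCosineMatch:
    REF = PseudoSpectrumRecord("R", 10.0, [(300.0, 4.0), (250.0, 3.0), (180.0, 3.0)])

    def test_identical_spectra_score_one(self):
        assert cosine_match(self.REF, self.REF) == pytest.approx(1.0)

    def test_disjoint_spectra_score_zero(self):
        other = PseudoSpectrumRecord("Q", 10.0, [(500.0, 1.0), (450.0, 1.0), (400.0, 1.0)])
        assert cosine_match(other, self.REF) == 0.0

    def test_one_peak_removed_hand_computed_ratio(self):
        # paired sum = 4 + 3 = 7; norm = sqrt(7 * 10) -> score = sqrt(0.7)
        query = PseudoSpectrumRecord("Q", 10.0, [(300.0, 4.0), (250.0, 3.0)])
        assert cosine_match(query, self.REF) == pytest.approx(math.sqrt(0.7))


class TestClusteringRecovery:
    def test_twenty_planted_spectra_in_two_minute_window(self):
        """20 five-fragment chemicals confined to an 18-20 min window:
        perfect recovery without noise, ARI >= 0.9 at default noise."""
        n0 = NoiseModel.noiseless(seed=3)
        chems0, _, _ = make_universe(20, (5, 5), n0, rt_range=(18.0, 20.0),
                                     min_rt_spacing=0.06)
        t0, tr0 = simulate_study(chems0, 20, noise=n0)
        res0 = cluster_features(t0, rt_window=(18.0, 20.0))
        assert _ari(res0, tr0) == 1.0

        noise = NoiseModel(seed=7)
        chems, _, _ = make_universe(20, (5, 5), noise, rt_range=(18.0, 20.0),
                                    min_rt_spacing=0.06)
        table, truth = simulate_study(chems, 20, noise=noise)
        res = cluster_features(table, rt_window=(18.0, 20.0))
        assert _ari(res, truth) >= 0.9
        assert all(len(c.members) >= 3 for c in res.clusters)


def _ari(result, truth):
    pred = {}
    for c in result.clusters:
        for m in c.members:
            pred[m] = c.cluster_id
    for i, m in enumerate(result.unclustered):
        pred[m] = f"singleton_{i}"
    feats = list(pred)
    return adjusted_rand_score(truth.labels_for(feats), [pred[f] for f in feats])
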