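"""QC filters, BMIQ, SVD batch scan and ComBat."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from parityewas import simulate_cohort
from parityewas.preprocessing import (EmptyCohortError, _beta_mixture_em,
                                      bmiq_normalize, combat_adjust,
                                      filter_probes, filter_samples,
                                      retention_percent, svd_batch_scan)
from conftest import small_config


def _matrices(n_probes, samples, fail_counts, rng):
    """Detection-p matrix with a planted number of failures per sample."""
    det = pd.DataFrame(rng.uniform(0, 1e-3, (n_probes, len(samples))),
                       index=[f"cg{i:06d}" for i in range(n_probes)],
                       columns=samples)
    for j, k in enumerate(fail_counts):
        det.iloc[:k, j] = rng.uniform(0.011, 1.0, k)
    beta = pd.DataFrame(rng.uniform(0.05, 0.95, det.shape),
                        index=det.index, columns=det.columns)
    return beta, det


class TestSampleFilter:
    def test_clean_sample_retained(self, rng):
        beta, det = _matrices(1000, ["a", "b"], [0, 0], rng)
        out, rep = filter_samples(beta, det)
        assert list(out.columns) == ["a", "b"] and not rep.excluded_samples

    def test_strict_ratio_boundary(self, rng):
        # 1100 probes: 100 failed / 1000 ok = 0.1 exactly -> retained;
        # 101 / 999 ~ 0.1011 -> excluded (strictly greater than 0.1)
        beta, det = _matrices(1100, ["at", "above"], [100, 101], rng)
        out, rep = filter_samples(beta, det)
        assert "at" in out.columns
        assert ("above", "low_quality") in rep.excluded_samples

    def test_hand_computed_fixture(self, rng):
        """Planted failure counts {0, 500, 5000, 90000, 100} of 100,000
        probes: only the 90,000-failure sample crosses ratio 0.1."""
        fails = [0, 500, 5000, 90000, 100]
        beta, det = _matrices(100_000, list("abcde"), fails, rng)
        out, rep = filter_samples(beta, det)
        excluded = {s for s, _ in rep.excluded_samples}
        # hand arithmetic: f/(100000-f) > 0.1 only for f=90000 (ratio 9.0)
        assert excluded == {"d"}
        assert set(out.columns) == {"a", "b", "c", "e"}

    def test_all_failing_raises(self, rng):
        beta, det = _matrices(100, ["a"], [50], rng)
        with pytest.raises(EmptyCohortError):
            filter_samples(beta, det)


def _probe_fixture(rng, n=200, n_samples=40):
    pids = [f"cg{i:06d}" for i in range(n)]
    cols = [f"s{j}" for j in range(n_samples)]
    beta = pd.DataFrame(rng.uniform(0.05, 0.95, (n, n_samples)),
                        index=pids, columns=cols)
    det = pd.DataFrame(rng.uniform(0, 1e-3, beta.shape), index=pids, columns=cols)
    beads = pd.DataFrame(rng.poisson(15, beta.shape).clip(min=3),
                         index=pids, columns=cols)
    anno = pd.DataFrame({"chrom": "1", "pos": np.arange(n) * 1000 + 1,
                         "non_cpg": False, "snp_related": False,
                         "multi_hit": False}, index=pids)
    return beta, det, beads, anno


class TestProbeFilter:
    def test_chrx_excluded_as_non_autosomal(self, rng):
        beta, det, beads, anno = _probe_fixture(rng)
        anno.loc["cg000003", "chrom"] = "X"
        out, rep = filter_probes(beta, det, beads, anno)
        assert ("cg000003", "non_autosomal") in rep.excluded_probes
        assert "cg000003" not in out.index

    def test_bead_count_boundary(self, rng):
        # 40 samples: 2/40 = 5.0% -> excluded; 1/40 = 2.5% -> retained
        beta, det, beads, anno = _probe_fixture(rng)
        beads.iloc[0, :2] = 2
        beads.iloc[1, :1] = 2
        out, rep = filter_probes(beta, det, beads, anno)
        reasons = dict(rep.excluded_probes)
        assert reasons.get("cg000000") == "bead_count"
        assert "cg000001" in out.index

    def test_reason_precedence(self, rng):
        beta, det, beads, anno = _probe_fixture(rng)
        det.iloc[0, 0] = 0.5           # low_quality ...
        anno.iloc[0, anno.columns.get_loc("non_cpg")] = True  # ... and flagged
        _, rep = filter_probes(beta, det, beads, anno)
        assert dict(rep.excluded_probes)["cg000000"] == "low_quality"

    def test_missing_annotation_is_error(self, rng):
        beta, det, beads, anno = _probe_fixture(rng)
        with pytest.raises(KeyError, match="annotation missing"):
            filter_probes(beta, det, beads, anno.iloc[1:], )

    def test_planted_fixture_retained_fraction(self, rng):
        """867 probes with 117 planted failures -> 86.5% retained,
        matching the hand count."""
        beta, det, beads, anno = _probe_fixture(rng, n=867)
        bad = rng.choice(867, 117, replace=False)
        for i, j in enumerate(bad):
            kind = i % 3
            if kind == 0:
                det.iloc[j, 5] = 0.9
            elif kind == 1:
                beads.iloc[j, :2] = 1
            else:
                anno.iloc[j, anno.columns.get_loc("snp_related")] = True
        out, rep = filter_probes(beta, det, beads, anno)
        assert rep.n_probes_after == 867 - 117
        assert rep.retained_fraction == pytest.approx(100 * 750 / 867)

    def test_idempotent(self, rng):
        beta, det, beads, anno = _probe_fixture(rng)
        det.iloc[0, 0] = 0.5
        out1, _ = filter_probes(beta, det, beads, anno)
        out2, rep2 = filter_probes(out1, det, beads, anno)
        assert out2.shape == out1.shape and not rep2.excluded_probes

    def test_planted_qc_targets_recovered(self, small_dataset):
        """Retention on the synthetic cohort matches the generator's
        planted exclusions exactly."""
        ds = small_dataset
        beta, _ = filter_samples(ds.beta, ds.detection_p)
        out, rep = filter_probes(beta, ds.detection_p, ds.bead_counts,
                                 ds.annotation)
        planted = set()
        for ids in ds.truth.qc_fail_probes.values():
            planted.update(ids)
        excluded = {p for p, _ in rep.excluded_probes}
        assert abs(len(excluded) - len(planted)) <= 1
        assert excluded == planted


def test_retention_percent_matches_reported_scale():
    assert retention_percent(747_000, 867_000) == pytest.approx(86.16, abs=0.01)


class TestBmiq:
    @staticmethod
    def _fixture(rng, n1=600, n2=2400, shift=0.0):
        """Bimodal beta mix for both design types; optional type-II shift."""
        def draw(n, delta):
            comp = rng.choice(3, n, p=(0.45, 0.45, 0.10))
            x = np.where(comp == 0, rng.beta(2, 14, n),
                         np.where(comp == 1, rng.beta(14, 2, n),
                                  rng.beta(8, 8, n)))
            if delta:
                x = np.clip(x + delta * (0.5 - np.abs(x - 0.5)) * 2, 1e-3, 1 - 1e-3)
            return x
        v1, v2 = draw(n1, 0.0), draw(n2, shift)
        pids = [f"cg{i:06d}" for i in range(n1 + n2)]
        beta = pd.DataFrame({"s1": np.concatenate([v1, v2])}, index=pids)
        anno = pd.DataFrame({"design_type": ["I"] * n1 + ["II"] * n2}, index=pids)
        return beta, anno

    def test_identity_when_distributions_match(self, rng):
        """Type-II values that are an exact copy of the type-I set map
        (nearly) onto themselves."""
        v1 = np.concatenate([rng.beta(2, 14, 500), rng.beta(14, 2, 500)])
        beta = pd.DataFrame({"s1": np.concatenate([v1, v1])},
                            index=[f"cg{i:06d}" for i in range(2 * v1.size)])
        anno = pd.DataFrame({"design_type": ["I"] * v1.size + ["II"] * v1.size},
                            index=beta.index)
        out = bmiq_normalize(beta, anno)
        assert np.abs(out.values - beta.values).max() < 0.01

    def test_rank_preservation(self, rng):
        beta, anno = self._fixture(rng, shift=0.05)
        out = bmiq_normalize(beta, anno)
        t2 = anno["design_type"] == "II"
        rho = stats.spearmanr(beta.loc[t2, "s1"], out.loc[t2, "s1"]).statistic
        assert rho == pytest.approx(1.0, abs=1e-12)

    def test_type1_unchanged_and_in_range(self, rng):
        beta, anno = self._fixture(rng, shift=0.08)
        out = bmiq_normalize(beta, anno)
        t1 = anno["design_type"] == "I"
        assert np.array_equal(out.loc[t1].values, beta.loc[t1].values)
        assert ((out.values > 0) & (out.values < 1)).all()

    def test_em_recovers_mixture_states(self, rng):
        """EM on a known 3-state mixture (states near 0.1/0.5/0.9)
        recovers the state means within 0.05."""
        x = np.concatenate([rng.beta(9, 81, 2000),     # mean 0.1
                            rng.beta(50, 50, 1000),    # mean 0.5
                            rng.beta(81, 9, 2000)])    # mean 0.9
        w, a, b, ok = _beta_mixture_em(x)
        assert ok
        means = a / (a + b)
        assert np.abs(np.sort(means) - [0.1, 0.5, 0.9]).max() < 0.05

    def test_requires_both_types(self, rng):
        beta, anno = self._fixture(rng)
        anno["design_type"] = "II"
        with pytest.raises(ValueError, match="both probe design types"):
            bmiq_normalize(beta, anno)


class TestSvdScan:
    def test_null_simulation_mostly_clean(self):
        """With batch_sd = 0 the scan of the plate factor over the top 3
        components finds nothing in nearly every seed."""
        clean = 0
        n_seeds = 12
        for seed in range(n_seeds):
            cfg = small_config(seed=seed, batch_sd=0.0, n_probes=800,
                               n_spiked_dmps=0, n_signature_per_type=20,
                               n_clock_cpgs=0, dmr_specs=[])
            ds = simulate_cohort(cfg)
            scan = svd_batch_scan(ds.beta, ds.sample_sheet,
                                  factors=["Plate"], k=3)
            clean += not scan["significant"].any()
        assert clean >= n_seeds - 2

    def test_planted_plate_effect_detected(self):
        cfg = small_config(seed=5, batch_sd=0.3, noise_sd=0.05)
        ds = simulate_cohort(cfg)
        scan = svd_batch_scan(ds.beta, ds.sample_sheet, factors=["Plate"], k=3)
        assert scan["significant"].any()

    def test_constant_factor_skipped(self, small_dataset):
        sheet = small_dataset.sample_sheet.copy()
        sheet["const"] = "x"
        with pytest.warns(UserWarning, match="constant"):
            scan = svd_batch_scan(small_dataset.beta, sheet,
                                  factors=["const"], k=2)
        assert len(scan) == 0

    def test_one_level_per_sample_skipped(self, small_dataset):
        sheet = small_dataset.sample_sheet.copy()
        sheet["unique"] = [f"u{i}" for i in range(len(sheet))]
        with pytest.warns(UserWarning, match="one level per sample"):
            scan = svd_batch_scan(small_dataset.beta, sheet,
                                  factors=["unique"], k=2)
        assert len(scan) == 0

    def test_continuous_factor_tested(self, small_dataset):
        scan = svd_batch_scan(small_dataset.beta, small_dataset.sample_sheet,
                              factors=["age"], k=2)
        assert len(scan) == 2
        assert scan["association_p"].between(0, 1).all()


class TestCombat:
    def test_single_batch_is_noop(self, rng):
        beta = pd.DataFrame(rng.uniform(0.1, 0.9, (50, 10)))
        labels = pd.Series(["b1"] * 10, index=beta.columns)
        out = combat_adjust(beta, labels)
        assert np.abs(out.values - beta.values).max() < 1e-8

    def test_singleton_batch_rejected(self, rng):
        beta = pd.DataFrame(rng.uniform(0.1, 0.9, (50, 5)))
        labels = pd.Series(["a", "a", "a", "a", "b"], index=beta.columns)
        with pytest.raises(ValueError, match="'b'"):
            combat_adjust(beta, labels)

    def test_planted_shift_reduced(self):
        """A planted 0.05-logit plate shift: between-batch probe-mean
        spread shrinks by at least 80% after adjustment."""
        cfg = small_config(seed=2, batch_sd=0.05, noise_sd=0.05,
                           batch_levels={"Plate": 4},
                           n_samples_per_group=48)
        ds = simulate_cohort(cfg)
        labels = ds.sample_sheet["Plate"]

        def spread(mat):
            means = np.stack([mat.values[:, (labels == lv).values].mean(axis=1)
                              for lv in labels.unique()], axis=1)
            return np.abs(means - means.mean(axis=1, keepdims=True)).mean()

        out = combat_adjust(ds.beta, labels)
        assert spread(out) <= 0.2 * spread(ds.beta)
        assert ((out.values > 0) & (out.values < 1)).all()

    def test_group_effect_preserved(self):
        """Groups balanced across batches: spiked parity deltas move by
        under 0.005 through the adjustment."""
        cfg = small_config(seed=4, batch_sd=0.05, n_samples_per_group=48,
                           spiked_delta_range=(0.08, 0.08))
        ds = simulate_cohort(cfg)
        par = ds.sample_sheet["parity"].values == 1
        out = combat_adjust(ds.beta, ds.sample_sheet[["Plate", "Chip",
                                                      "Position"]],
                            covariates=ds.sample_sheet[["parity"]])
        sp = ds.truth.spiked_dmps["probe_id"]
        before = (ds.beta.loc[sp].values[:, par].mean(axis=1)
                  - ds.beta.loc[sp].values[:, ~par].mean(axis=1))
        after = (out.loc[sp].values[:, par].mean(axis=1)
                 - out.loc[sp].values[:, ~par].mean(axis=1))
        assert np.abs(after - before).mean() < 0.005
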