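"""Whole-blood EWAS: M-values, per-probe models, DMP/DMR calling and
the matched-pair sensitivity scan, checked against brute-force oracles."""
import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from parityewas import SimulationConfig, simulate_cohort
from parityewas import deconvolution as dec
from parityewas import differential as diff
from conftest import small_config


class TestBetaToM:
    def test_known_values(self):
        b = pd.DataFrame({"s": [0.5, 0.8]}, index=["p1", "p2"])
        m = diff.beta_to_m(b)
        assert m.loc["p1", "s"] == pytest.approx(0.0)
        assert m.loc["p2", "s"] == pytest.approx(2.0)  # log2(4)

    def test_round_trip(self, rng):
        b = rng.uniform(0.01, 0.99, 500)
        m = diff.beta_to_m(pd.DataFrame(b))
        assert np.abs(np.asarray(diff.m_to_beta(m)).ravel() - b).max() < 1e-10

    def test_monotone(self, rng):
        b = np.sort(rng.uniform(0.001, 0.999, 100))
        m = diff.beta_to_m(pd.DataFrame(b)).values.ravel()
        assert (np.diff(m) > 0).all()


def brute_force_bh(p):
    """Textbook BH: sorted step-up with cumulative minimum."""
    p = np.asarray(p, float)
    n = len(p)
    order = np.argsort(p)
    q = np.empty(n)
    prev = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        q[i] = min(prev, p[i] * n / rank)
        prev = q[i]
    return q


class TestDmpCalling:
    @staticmethod
    def _toy_results(pvals, deltas):
        idx = [f"cg{i:02d}" for i in range(len(pvals))]
        res = pd.DataFrame({"p_value": pvals, "delta_meth": deltas,
                            "coef": deltas, "se": 1.0,
                            "mean_parous": 0.5, "mean_nulligravida": 0.5},
                           index=idx)
        anno = pd.DataFrame({"chrom": "1", "pos": np.arange(len(pvals)) * 10_000,
                             "gene": "", "feature": "Body",
                             "island_context": "opensea"}, index=idx)
        return res, anno

    def test_bh_matches_enumeration_oracle(self, rng):
        pvals = rng.uniform(0, 0.2, 10)
        res, anno = self._toy_results(pvals, np.full(10, 0.02))
        table, _ = diff.call_dmps(res, anno)
        assert np.allclose(table["fdr"].values, brute_force_bh(pvals))

    def test_delta_threshold_excludes_small_effects(self):
        res, anno = self._toy_results([1e-6, 1e-6], [0.005, 0.02])
        table, summary = diff.call_dmps(res, anno)
        assert not table.loc["cg00", "is_dmp"]   # fdr ok, delta 0.5% -> out
        assert table.loc["cg01", "is_dmp"]
        assert summary["n_dmps"] == 1

    def test_direction_percentages_match_printed_arithmetic(self):
        pct = diff.direction_percentages(2046, 940)
        assert pct["pct_hyper"] == pytest.approx(68.5, abs=0.05)
        assert pct["pct_hypo"] == pytest.approx(31.5, abs=0.05)

    def test_island_context_percentages(self):
        ctx = pd.Series(["island"] * 143_779 + ["opensea"] * (746_969 - 143_779))
        pct = diff.context_percentages(ctx)
        assert pct["island"] == pytest.approx(19.2, abs=0.05)

    def test_fdr_at_least_p(self, rng):
        res, anno = self._toy_results(rng.uniform(0, 1, 20), rng.normal(0, 0.02, 20))
        table, _ = diff.call_dmps(res, anno)
        assert (table["fdr"] >= table["p_value"] - 1e-12).all()
        hyper = table["delta_meth"] > 0
        assert (table.loc[hyper, "direction"] == "hyper").all()


class TestDmpModels:
    def test_null_pvalues_uniform(self):
        pooled = []
        for seed in range(6):
            cfg = small_config(seed=seed, n_spiked_dmps=0, dmr_specs=[],
                               n_clock_cpgs=0, batch_sd=0.0, n_probes=1000,
                               n_samples_per_group=48)
            ds = simulate_cohort(cfg)
            fr = dec.estimate_cell_fractions(ds.beta, ds.reference)
            res = diff.fit_dmp_models(ds.beta, ds.sample_sheet, fr)
            pooled.append(res["p_value"].values)
        ks = stats.kstest(np.concatenate(pooled), "uniform")
        assert ks.pvalue > 0.01

    def test_spiked_probe_power(self):
        """A 10% spike at n = 192, logit noise 0.1 reaches p < 1e-6 in
        nearly every seed."""
        hits = total = 0
        for seed in range(10):
            cfg = SimulationConfig(
                n_probes=800, n_samples_per_group=96, n_spiked_dmps=5,
                spiked_delta_range=(0.10, 0.10), n_signature_per_type=20,
                n_clock_cpgs=0, dmr_specs=[], noise_sd=0.1, seed=seed)
            ds = simulate_cohort(cfg)
            fr = dec.estimate_cell_fractions(ds.beta, ds.reference)
            res = diff.fit_dmp_models(ds.beta, ds.sample_sheet, fr)
            pv = res.loc[ds.truth.spiked_dmps["probe_id"], "p_value"]
            hits += (pv < 1e-6).sum()
            total += len(pv)
        assert hits / total >= 0.95

    def test_all_six_fractions_collinear(self, small_dataset):
        ds = small_dataset
        fr = ds.truth.true_fractions  # simplex: all six sum to one
        sheet = ds.sample_sheet
        X = np.column_stack([np.ones(len(sheet)), sheet["parity"],
                             fr.values, sheet["smoking"]])
        names = ["intercept", "parity", *fr.columns, "smoking"]
        with pytest.raises(np.linalg.LinAlgError, match="collinear"):
            diff.ols_by_probe(ds.beta.values[:5], X, 1, names)


def _dmr_input(rows):
    """rows: (probe, chrom, pos, fdr, delta)"""
    df = pd.DataFrame(rows, columns=["probe", "chrom", "pos", "fdr",
                                     "delta_meth"]).set_index("probe")
    df["is_dmp"] = True
    return df


def brute_force_dmrs(table, min_cpgs=5, fdr=0.01, max_gap=1000):
    """Enumerate every candidate window; keep maximal qualifying runs."""
    qual = table[table["fdr"] < fdr]
    out = []
    for (chrom, sign), grp in qual.groupby(
            ["chrom", np.sign(qual["delta_meth"])]):
        grp = grp.sort_values("pos")
        idx = list(grp.index)
        n = len(idx)
        best = []
        for i, j in itertools.combinations(range(n), 2):
            window = grp.iloc[i:j + 1]
            gaps = np.diff(window["pos"].values)
            if len(window) >= min_cpgs and (gaps <= max_gap).all():
                best.append(set(window.index))
        # maximal sets only
        for s in best:
            if not any(s < t for t in best):
                out.append((chrom, frozenset(s)))
    return set(out)


class TestDmrCaller:
    def test_seven_cpg_region_width(self):
        """A chr17 region of 7 qualifying CpGs spanning
        76,128,906-76,130,139 -> one region of width 1233 bp."""
        pos = [76128906, 76129061, 76129333, 76129538, 76129778, 76129901,
               76130139]
        rows = [(f"cg{i}", "17", p, 0.005, 0.015) for i, p in enumerate(pos)]
        dmrs = diff.call_dmrs(_dmr_input(rows))
        assert len(dmrs) == 1
        r = dmrs.iloc[0]
        assert (r["width"], r["n_cpgs"], r["direction"]) == (1233, 7, "hyper")

    def test_fourteen_cpg_region_width(self):
        """A chr19 region of 14 CpGs spanning 52,390,810-52,391,789 ->
        width 979 bp, hypomethylated."""
        pos = np.linspace(52390810, 52391789, 14).round().astype(int)
        pos[0], pos[-1] = 52390810, 52391789
        rows = [(f"cg{i}", "19", int(p), 0.004, -0.023)
                for i, p in enumerate(pos)]
        dmrs = diff.call_dmrs(_dmr_input(rows))
        assert len(dmrs) == 1
        r = dmrs.iloc[0]
        assert (r["width"], r["n_cpgs"], r["direction"]) == (979, 14, "hypo")
        assert r["delta_max"] == pytest.approx(-0.023)

    def test_four_members_insufficient(self):
        rows = [(f"cg{i}", "1", 1000 + 500 * i, 0.005, 0.02) for i in range(4)]
        assert len(diff.call_dmrs(_dmr_input(rows))) == 0

    def test_gap_over_1000_splits_run(self):
        pos = [1000, 1500, 2000, 3001, 3500, 4000]  # 1001 bp gap after 3rd
        rows = [(f"cg{i}", "1", p, 0.005, 0.02) for i, p in enumerate(pos)]
        assert len(diff.call_dmrs(_dmr_input(rows))) == 0

    def test_exact_1000_gap_allowed(self):
        pos = [1000, 2000, 3000, 4000, 5000]
        rows = [(f"cg{i}", "1", p, 0.005, 0.02) for i, p in enumerate(pos)]
        dmrs = diff.call_dmrs(_dmr_input(rows))
        assert len(dmrs) == 1 and dmrs.iloc[0]["width"] == 4000

    def test_direction_split(self):
        rows = ([(f"a{i}", "1", 1000 + 200 * i, 0.005, 0.02) for i in range(5)]
                + [(f"b{i}", "1", 1100 + 200 * i, 0.005, -0.02)
                   for i in range(5)])
        dmrs = diff.call_dmrs(_dmr_input(rows))
        assert len(dmrs) == 2
        assert set(dmrs["direction"]) == {"hyper", "hypo"}

    def test_order_invariance(self, rng):
        rows = [(f"cg{i}", "2", 5000 + 300 * i, 0.003, 0.03) for i in range(8)]
        base = diff.call_dmrs(_dmr_input(rows))
        shuffled = _dmr_input(rows).sample(frac=1, random_state=1)
        again = diff.call_dmrs(shuffled)
        pd.testing.assert_frame_equal(base, again)

    def test_matches_brute_force_enumeration(self, rng):
        """Random <=50-probe instances agree with all-windows search."""
        for trial in range(15):
            n = int(rng.integers(10, 50))
            rows = [(f"cg{i:03d}", str(rng.integers(1, 3)),
                     int(rng.integers(0, 12) * 400 + i),
                     float(rng.choice([0.005, 0.5])),
                     float(rng.choice([-0.02, 0.02]))) for i in range(n)]
            table = _dmr_input(rows)
            got = {(r["chrom"], frozenset(r["probe_ids"]))
                   for _, r in diff.call_dmrs(table).iterrows()}
            expected = {(c, s) for c, s in brute_force_dmrs(table)
                        if len(s) >= 5}
            assert got == expected


class TestSensitivityScan:
    @staticmethod
    def _cohort(seed=0, n=48):
        cfg = small_config(seed=seed, n_samples_per_group=n, n_probes=500,
                           n_signature_per_type=20, n_clock_cpgs=0,
                           n_pairs_treatment_on=max(4, n // 3),
                           n_pairs_treatment_off=max(3, n // 6))
        return simulate_cohort(cfg)

    def test_treatment_uses_concordant_pairs_only(self, cohort_dataset):
        ds = cohort_dataset
        pairs = diff.pairs_from_sheet(ds.sample_sheet)
        treat = diff.concordant_treatment_covariate(ds.sample_sheet, pairs)
        cov = pd.DataFrame({"treatment": treat.values,
                            "symptom_duration": np.arange(len(pairs))})
        res = diff.paired_sensitivity_scan(ds.beta.iloc[:200], pairs, cov)
        row = res[res["covariate"] == "treatment"].iloc[0]
        assert row["n_pairs"] == 54  # 40 concordant-on + 14 concordant-off

    def test_null_covariate_uniform(self):
        pvals = []
        for seed in range(12):
            ds = self._cohort(seed)
            pairs = diff.pairs_from_sheet(ds.sample_sheet)
            rng = np.random.default_rng(seed)
            cov = pd.DataFrame({"noise": rng.normal(size=len(pairs))})
            res = diff.paired_sensitivity_scan(ds.beta, pairs, cov)
            pvals.append(res["p_value"].iloc[0])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_planted_dependence_detected(self):
        """Pair-level mean methylation difference constructed to track a
        covariate linearly is flagged at FDR < 0.05."""
        detected = 0
        for seed in range(8):
            ds = self._cohort(seed)
            pairs = diff.pairs_from_sheet(ds.sample_sheet)
            rng = np.random.default_rng(100 + seed)
            duration = rng.uniform(0, 20, len(pairs))
            beta = ds.beta.copy()
            for (n_id, p_id), d in zip(pairs, duration):
                beta[p_id] = np.clip(beta[p_id] + 0.001 * d, 0.001, 0.999)
            cov = pd.DataFrame({"symptom_duration": duration})
            res = diff.paired_sensitivity_scan(beta, pairs, cov)
            detected += bool(res["significant"].iloc[0])
        assert detected >= 7

    def test_too_few_pairs_skipped(self, small_dataset):
        pairs = diff.pairs_from_sheet(small_dataset.sample_sheet)[:4]
        cov = pd.DataFrame({"sparse": [1.0, np.nan, np.nan, np.nan]})
        with pytest.warns(UserWarning, match="fewer than 3"):
            res = diff.paired_sensitivity_scan(small_dataset.beta.iloc[:50],
                                               pairs, cov)
        assert len(res) == 0
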