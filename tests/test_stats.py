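"""Cohort statistics: rank-sum tests, Spearman panels, Cox models."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from repclon import (
    correlation_panel,
    cox_panel,
    generate_cohort,
    metrics_table,
    p_stars,
    pairwise_wilcoxon,
    rank_sum_test,
)
from repclon.io_clonotypes import SUBTYPES
from repclon.scores import add_inflammatory_score

from conftest import light_profile


def exact_rank_sum_oracle(x, y):
    """Two-sided rank-sum p by full enumeration of rank allocations."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = np.argsort(np.argsort(pooled)) + 1
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    us = np.array(
        [
            ranks[list(comb)].sum() - n1 * (n1 + 1) / 2
            for comb in itertools.combinations(range(len(pooled)), n1)
        ]
    )
    p_le = (us <= u_obs).mean()
    p_ge = (us >= u_obs).mean()
    return min(1.0, 2 * min(p_le, p_ge))


class TestRankSum:
    def test_separated_triples_give_exact_p_of_one_tenth(self):
        _, p = rank_sum_test([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)

    def test_identical_groups_not_rejected(self):
        _, p = rank_sum_test([1.0, 2.0, 3.0, 4.0], [1.5, 2.5, 3.5, 0.5])
        assert p > 0.05

    def test_agrees_with_enumeration_for_small_groups(self, rng):
        for _ in range(20):
            n1, n2 = rng.integers(3, 9, size=2)
            x, y = rng.normal(size=int(n1)), rng.normal(size=int(n2))
            _, p = rank_sum_test(x, y)
            assert p == pytest.approx(exact_rank_sum_oracle(x, y), abs=1e-12)

    def test_tiny_groups_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([1.0], [2.0, 3.0])

    def test_star_annotation_thresholds(self):
        assert [p_stars(p) for p in (0.2, 0.04, 0.004, 0.0004)] == [
            "", "*", "**", "***",
        ]


def _metrics_frame(rng, n_per=8):
    rows = []
    for s in SUBTYPES:
        for i in range(n_per):
            rows.append(
                dict(sample_id=f"{s}{i}", subtype=s, chain="IGH",
                     expression=float(rng.random()), entropy=float(rng.random() * 5))
            )
    df = pd.DataFrame(rows)
    return df.drop(columns="subtype"), df[["sample_id", "subtype"]].drop_duplicates()


class TestPairwiseWilcoxon:
    def test_five_subtypes_give_ten_pairs_per_measure(self, rng):
        metrics, meta = _metrics_frame(rng)
        out = pairwise_wilcoxon(metrics, meta)
        assert len(out) == 10 * 2  # C(5,2) pairs x 2 measures
        assert out["p_value"].between(0, 1).all()

    def test_undersized_groups_are_skipped(self, rng):
        metrics, meta = _metrics_frame(rng, n_per=3)
        # leave a single LumNS sample
        keep = ~meta["sample_id"].str.startswith("LumNS") | (
            meta["sample_id"] == "LumNS0"
        )
        meta = meta[keep]
        metrics = metrics[metrics["sample_id"].isin(meta["sample_id"])]
        out = pairwise_wilcoxon(metrics, meta)
        assert not ((out["subtype_a"] == "LumNS") | (out["subtype_b"] == "LumNS")).any()

    def test_bh_flag_adds_q_values(self, rng):
        metrics, meta = _metrics_frame(rng)
        out = pairwise_wilcoxon(metrics, meta, bh=True)
        assert "q_value" in out and (out["q_value"] >= out["p_value"] - 1e-12).all()


class TestCorrelationPanel:
    def _panel(self, values, covariate_values):
        n = len(values)
        metrics = pd.DataFrame(
            dict(sample_id=[f"S{i}" for i in range(n)], chain="IGH",
                 expression=values, entropy=values)
        )
        meta = pd.DataFrame(
            dict(sample_id=[f"S{i}" for i in range(n)], subtype="LumP",
                 nsmr=covariate_values, smr=covariate_values,
                 inflammatory_score=covariate_values)
        )
        return correlation_panel(metrics, meta, stratify_by_subtype=False)

    def test_monotone_increasing_gives_rho_one(self):
        x = np.arange(10.0)
        out = self._panel(x, 2 * x)
        assert out["rho"].dropna().unique() == pytest.approx([1.0])

    def test_monotone_decreasing_gives_rho_minus_one(self):
        x = np.linspace(-2, 2, 10)
        out = self._panel(x, -(x**3))
        assert out["rho"].dropna().unique() == pytest.approx([-1.0])

    def test_constant_covariate_gives_missing_rho(self):
        out = self._panel(np.arange(10.0), np.ones(10))
        assert out["rho"].isna().all()

    def test_rho_invariant_to_monotone_transforms(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        r1 = self._panel(x, y)["rho"].iloc[0]
        r2 = self._panel(np.exp(x), y)["rho"].iloc[0]
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_grid_shape_all_plus_subtypes(self, rng):
        from conftest import light_profile

        cohort, _ = generate_cohort([light_profile(12)], seed=5)
        metrics = metrics_table(cohort, chains=("TRB",))
        meta = add_inflammatory_score(cohort.metadata_frame())
        out = correlation_panel(metrics, meta)
        # 1 chain x 2 measures x 3 covariates x (All + 5 subtypes)
        assert len(out) == 1 * 2 * 3 * 6
        assert out.loc[out["subtype"] == "LumNS", "rho"].isna().all()


class TestCoxPanel:
    def _fit(self, seed, n=120, log_hr=0.0):
        cohort, _ = generate_cohort([light_profile(n, log_hr=log_hr)], seed=seed)
        metrics = metrics_table(cohort, chains=("TRB",))
        meta = add_inflammatory_score(cohort.metadata_frame())
        return cox_panel(metrics, meta, measures=("entropy",),
                         stratify_by_subtype=False)

    def test_reports_hr_ci_and_counts(self):
        out = self._fit(seed=11)
        r = out.iloc[0]
        assert r.converged
        assert r.ci_low <= r.hazard_ratio <= r.ci_high
        assert r.n <= 120 and r.events <= r.n

    def test_stratum_below_floor_is_skipped(self):
        cohort, _ = generate_cohort([light_profile(8)], seed=3)
        metrics = metrics_table(cohort, chains=("TRB",))
        meta = add_inflammatory_score(cohort.metadata_frame())
        out = cox_panel(metrics, meta, measures=("entropy",),
                        stratify_by_subtype=False, min_samples=10)
        assert len(out) == 0

    def test_estimator_bias_shrinks_with_sample_size(self):
        """Consistency: |bias of log-HR| at n=1000 below that at n=100."""
        true = math.log(0.7)
        bias = {}
        for n in (100, 1000):
            errs = []
            for rep in range(25):
                out = self._fit(seed=7000 + rep + n, n=n, log_hr=true)
                errs.append(math.log(out.iloc[0].hazard_ratio) - true)
            bias[n] = abs(np.mean(errs))
        assert bias[1000] < bias[100]

    def test_interaction_model_reports_per_subtype_slopes(self):
        profiles = [light_profile(60, log_hr=math.log(0.6))]
        p2 = light_profile(60, log_hr=0.0)
        p2.name = "Ba/Sq"
        profiles.append(p2)
        cohort, _ = generate_cohort(profiles, seed=21)
        metrics = metrics_table(cohort, chains=("TRB",))
        meta = add_inflammatory_score(cohort.metadata_frame())
        out = cox_panel(metrics, meta, measures=("entropy",), interaction=True)
        assert set(out["subtype"]) == {"LumP", "Ba/Sq"}
        assert out["converged"].all()
        assert (out["ci_low"] <= out["hazard_ratio"]).all()
        assert (out["hazard_ratio"] <= out["ci_high"]).all()
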