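"""Per-lab OLS fits, REML variance components and summaries.

The REML optimiser is checked against two independent routes: the
closed-form expected-mean-squares (ANOVA) estimator on balanced data with
interior optima, and lme4's ``lmer`` run through Rscript on a small
fixture.
"""

import subprocess

import numpy as np
import pandas as pd
import pytest

from qeegvar import (
    emm_contrast,
    fit_crosslab,
    fit_per_lab,
    log10_endpoint,
    method_of_moments,
    simulate_endpoint_table,
    tukey_summary,
    variance_table,
)
from qeegvar.errors import DesignError, InsufficientDataError, QeegError


def _table(groups_values, lab="Lab1", endpoint="e"):
    rows = []
    for g, vals in groups_values.items():
        for i, v in enumerate(vals):
            rows.append(
                dict(lab_id=lab, subject_id=f"{g}{i}", group=g, endpoint=endpoint, value=v)
            )
    return pd.DataFrame(rows)


class TestLog10:
    def test_values(self):
        assert log10_endpoint([1.0, 100.0]).tolist() == [0.0, 2.0]

    def test_monotone(self):
        v = np.array([0.3, 2.0, 7.0])
        assert np.all(np.diff(log10_endpoint(v)) > 0)

    def test_nonpositive_names_offender(self):
        with pytest.raises(QeegError, match="Lab2"):
            log10_endpoint([1.0, -2.0], labels=["Lab1/m1", "Lab2/m3"])


class TestPerLab:
    def test_contrast_matches_pooled_t_oracle(self):
        """Hand-computed pooled-variance two-sample t on {1,2,3} vs {2,3,4}."""
        fit = fit_per_lab(_table({"WT": [1, 2, 3], "TG": [2, 3, 4]}), "Lab1", "e")
        (c,) = fit.contrasts
        assert c.name == "TG - WT"
        assert c.estimate == pytest.approx(1.0)
        assert fit.sigma_e2 == pytest.approx(1.0)
        assert c.se == pytest.approx(np.sqrt(2 / 3))
        assert c.df == 4
        assert c.stat == pytest.approx(1.224744871391589)
        assert c.p == pytest.approx(0.28786413472669053)
        assert c.ci_low == pytest.approx(-1.2669579355275191)
        assert c.ci_high == pytest.approx(3.266957935527519)
        assert fit.group_means["WT"][0] == pytest.approx(2.0)
        assert fit.group_means["TG"][0] == pytest.approx(3.0)

    def test_identical_groups_null(self):
        fit = fit_per_lab(_table({"WT": [1, 2, 3], "TG": [1, 2, 3]}), "Lab1", "e")
        (c,) = fit.contrasts
        assert c.estimate == 0.0
        assert c.p == pytest.approx(1.0)

    def test_three_groups_pairwise(self):
        fit = fit_per_lab(
            _table({"vehicle": [1, 2], "lo": [2, 3], "hi": [4, 5]}), "Lab1", "e"
        )
        names = [c.name for c in fit.contrasts]
        assert names == ["lo - vehicle", "hi - vehicle", "hi - lo"]
        assert fit.df == 3

    def test_single_subject_group_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_per_lab(_table({"WT": [1.0], "TG": [2, 3]}), "Lab1", "e")


class TestCrosslab:
    def test_reml_equals_moments_on_balanced_interior(self):
        df, _ = simulate_endpoint_table(
            n_labs=8, n_per_group=12, beta0=2.0, beta_d=0.3,
            sigma_b2=1.0, sigma_d2=0.5, sigma_e2=0.7, seed=5,
            endpoint="e",
        )
        b2, d2, e2 = method_of_moments(df, "e")
        assert min(b2, d2, e2) > 0  # interior case
        fit = fit_crosslab(df, "e")
        assert fit.sigma_b2 == pytest.approx(b2, abs=1e-6)
        assert fit.sigma_d2 == pytest.approx(d2, abs=1e-6)
        assert fit.sigma_e2 == pytest.approx(e2, abs=1e-6)

    def test_matches_lmer(self, tmp_path):
        """Independent oracle: lme4's lmer on the same table."""
        df, _ = simulate_endpoint_table(
            n_labs=6, n_per_group=8, beta0=1.0, beta_d=0.4,
            sigma_b2=0.8, sigma_d2=0.2, sigma_e2=0.5, seed=9, endpoint="e",
        )
        fit = fit_crosslab(df, "e")
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        script = f"""
        suppressMessages(library(lme4))
        d <- read.csv("{csv}")
        m <- lmer(value ~ group + (1|lab_id) + (1|lab_id:group), data=d, REML=TRUE)
        vc <- as.data.frame(VarCorr(m))
        cat(vc$vcov[vc$grp=="lab_id"], vc$vcov[vc$grp=="lab_id:group"],
            vc$vcov[vc$grp=="Residual"], REMLcrit(m), sep="\\n")
        """
        out = subprocess.run(
            ["Rscript", "-"], input=script, capture_output=True, text=True, check=True
        )
        b2, d2, e2, crit = map(float, out.stdout.split())
        assert fit.sigma_b2 == pytest.approx(b2, rel=1e-4)
        assert fit.sigma_d2 == pytest.approx(d2, rel=1e-3)
        assert fit.sigma_e2 == pytest.approx(e2, rel=1e-4)
        assert -2 * fit.loglik == pytest.approx(crit, abs=1e-3)

    def test_zero_lab_variance_hits_boundary(self):
        hits = 0
        for seed in range(20):
            df, _ = simulate_endpoint_table(
                n_labs=12, n_per_group=24, beta0=0.0, beta_d=0.5,
                sigma_b2=0.0, sigma_d2=0.0, sigma_e2=1.0, seed=seed, endpoint="e",
            )
            fit = fit_crosslab(df, "e")
            if fit.sigma_b2 <= 0.05 * fit.sigma_e2 and fit.sigma_d2 <= 0.05 * fit.sigma_e2:
                hits += 1
        assert hits >= 18  # >= 90% of replicates at/near the boundary

    def test_parameter_recovery_small(self):
        ests = []
        for seed in range(20):
            df, _ = simulate_endpoint_table(
                n_labs=20, n_per_group=12, beta0=2.0, beta_d=0.3,
                sigma_b2=1.0, sigma_d2=0.25, sigma_e2=0.5, seed=100 + seed,
                endpoint="e",
            )
            fit = fit_crosslab(df, "e")
            ests.append([fit.sigma_b2, fit.sigma_d2, fit.sigma_e2])
        med = np.median(ests, axis=0)
        assert med[0] == pytest.approx(1.0, rel=0.15)
        assert med[1] == pytest.approx(0.25, rel=0.15)
        assert med[2] == pytest.approx(0.5, rel=0.15)

    def test_single_lab_rejected(self):
        df, _ = simulate_endpoint_table(
            n_labs=1, n_per_group=4, beta0=0, beta_d=0,
            sigma_b2=0, sigma_d2=0, sigma_e2=1, seed=0, endpoint="e",
        )
        with pytest.raises(DesignError):
            fit_crosslab(df, "e")

    def test_invariants_on_every_fit(self):
        for seed in range(5):
            df, _ = simulate_endpoint_table(
                n_labs=5, n_per_group=5, beta0=1, beta_d=0.2,
                sigma_b2=0.4, sigma_d2=0.1, sigma_e2=0.3, seed=seed, endpoint="e",
            )
            fit = fit_crosslab(df, "e")
            assert fit.sigma_b2 >= 0 and fit.sigma_d2 >= 0 and fit.sigma_e2 > 0
            assert fit.total == fit.sigma_b2 + fit.sigma_d2 + fit.sigma_e2
            assert sum(fit.shares.values()) == pytest.approx(100.0, abs=1e-9)


class TestEmmContrast:
    def test_reduces_to_pooled_ols_without_lab_variance(self):
        df, _ = simulate_endpoint_table(
            n_labs=4, n_per_group=10, beta0=1.0, beta_d=0.4,
            sigma_b2=0.0, sigma_d2=0.0, sigma_e2=0.6, seed=3, endpoint="e",
        )
        fit = fit_crosslab(df, "e")
        c = emm_contrast(fit)
        # pooled OLS over all labs ignoring lab structure
        wt = df[df.group == "WT"]["value"]
        tg = df[df.group == "TG"]["value"]
        est = tg.mean() - wt.mean()
        n1, n2 = len(tg), len(wt)
        s2 = (
            ((tg - tg.mean()) ** 2).sum() + ((wt - wt.mean()) ** 2).sum()
        ) / (n1 + n2 - 2)
        assert fit.sigma_b2 == 0.0 and fit.sigma_d2 == 0.0  # boundary reached
        assert c.estimate == pytest.approx(est, abs=1e-6)
        assert c.se == pytest.approx(np.sqrt(s2 * (1 / n1 + 1 / n2)), rel=1e-3)

    def test_mean_recovery_over_replicates(self):
        ests = []
        for seed in range(60):
            df, _ = simulate_endpoint_table(
                n_labs=20, n_per_group=6, beta0=0.0, beta_d=0.3,
                sigma_b2=0.3, sigma_d2=0.05, sigma_e2=0.3, seed=500 + seed,
                endpoint="e",
            )
            ests.append(emm_contrast(fit_crosslab(df, "e")).estimate)
        assert np.mean(ests) == pytest.approx(0.3, abs=0.02)

    def test_se_grows_with_interaction_variance(self):
        ses = []
        for sd2 in (0.0, 0.3, 1.0):
            df, _ = simulate_endpoint_table(
                n_labs=10, n_per_group=8, beta0=0.0, beta_d=0.3,
                sigma_b2=0.2, sigma_d2=sd2, sigma_e2=0.2, seed=77, endpoint="e",
            )
            ses.append(emm_contrast(fit_crosslab(df, "e")).se)
        assert ses[0] < ses[1] < ses[2]


class TestVarianceTable:
    def test_printed_shares_from_components(self):
        table = variance_table({"Localisation": (27.8751, 0.0, 0.0925)})
        col = table["Localisation"]
        assert col["ContributorID"] == "27.8751 (99.67%)"
        assert col["TestgroupID:ContributorID"] == "0.0000 (0.00%)"
        assert col["Residual"] == "0.0925 (0.33%)"
        assert col["Total"] == "27.9676 (100.00%)"

    def test_total_is_exact_sum_and_shares_add_up(self):
        table = variance_table({"c": (0.0607, 0.0029, 0.1039)})
        col = table["c"]
        assert col["Total"].startswith("0.1675")  # 0.0607+0.0029+0.1039
        shares = [float(col[r].split("(")[1].rstrip("%)")) for r in
                  ["ContributorID", "TestgroupID:ContributorID", "Residual"]]
        assert sum(shares) == pytest.approx(100.0, abs=0.02)


class TestTukey:
    def test_outlier_and_whiskers(self):
        s = tukey_summary(list(range(1, 10)) + [100])
        assert s.whisker_high == 9.0
        assert s.outliers == [100.0]
        assert s.whisker_low == 1.0
        assert s.q1 == pytest.approx(3.25)
        assert s.q3 == pytest.approx(7.75)

    def test_single_value(self):
        s = tukey_summary([4.2])
        assert (s.q1, s.median, s.q3) == (4.2, 4.2, 4.2)
        assert s.whisker_low == s.whisker_high == 4.2
        assert s.outliers == []

    def test_symmetric_data_centres_median(self):
        s = tukey_summary([-3, -2, -1, 0, 1, 2, 3])
        assert s.median == pytest.approx((s.q1 + s.q3) / 2)
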