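import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from wmnet.stats import (
    anova_group_by_load,
    behavior_correlations,
    correct_site_effects,
    fdr_correct,
    group_tests_per_observation,
    load_contrast_tests,
    motion_summaries,
)


def make_table(values: dict, observation="avg", measure="C_net"):
    """values: {(group, load, subject): value} -> long-form metric table."""
    rows = []
    for (group, load, subj), v in values.items():
        rows.append({"subject": subj, "group": group,
                     "site": "siteA" if str(subj)[-1] in "02468" else "siteB",
                     "load": load, "observation": observation,
                     "degree": np.nan, "measure": measure, "value": v})
    return pd.DataFrame(rows)


def balanced_table(rng, n=8, effect=None):
    vals = {}
    for g in ("HC", "SZ"):
        for load in ("L1", "L3", "L5"):
            for i in range(n):
                v = rng.normal(1.0, 0.1)
                if effect and (g, load) == effect[0]:
                    v += effect[1]
                vals[(g, load, f"{g}{i}")] = v
    return make_table(vals)


# ---------------------------------------------------------------------------
# site correction
# ---------------------------------------------------------------------------

class TestSiteCorrection:
    def test_single_site_identity(self, rng):
        t = balanced_table(rng)
        t["site"] = "only"
        out = correct_site_effects(t)
        assert np.allclose(out["value"], t["value"])

    def test_offset_sites_equalized(self, rng):
        t = balanced_table(rng)
        t.loc[t["site"] == "siteB", "value"] += 0.7
        out = correct_site_effects(t)
        means = out.groupby("site")["value"].mean()
        assert means["siteA"] == pytest.approx(means["siteB"], abs=1e-12)

    def test_group_effect_preserved_when_balanced(self, rng):
        t = balanced_table(rng, effect=(("SZ", "L3"), -0.4))
        t.loc[t["site"] == "siteB", "value"] += 1.3
        raw_diff = (t[t.group == "HC"]["value"].mean()
                    - t[t.group == "SZ"]["value"].mean())
        out = correct_site_effects(t)
        diff = (out[out.group == "HC"]["value"].mean()
                - out[out.group == "SZ"]["value"].mean())
        assert diff == pytest.approx(raw_diff, abs=1e-10)


# ---------------------------------------------------------------------------
# ANOVA
# ---------------------------------------------------------------------------

def anova_oracle(table):
    """Closed-form sums of squares for a balanced two-way design."""
    d = table[table["observation"] == "avg"]
    groups = sorted(d["group"].unique())
    loads = sorted(d["load"].unique())
    n = len(d) // (len(groups) * len(loads))
    grand = d["value"].mean()
    cell = d.groupby(["group", "load"])["value"].mean()
    gm = d.groupby("group")["value"].mean()
    lm = d.groupby("load")["value"].mean()
    ss_a = n * len(loads) * sum((gm[g] - grand) ** 2 for g in groups)
    ss_b = n * len(groups) * sum((lm[l] - grand) ** 2 for l in loads)
    ss_ab = n * sum((cell[(g, l)] - gm[g] - lm[l] + grand) ** 2
                    for g in groups for l in loads)
    ss_e = sum((row.value - cell[(row.group, row.load)]) ** 2
               for row in d.itertuples())
    df_a, df_b = len(groups) - 1, len(loads) - 1
    df_ab = df_a * df_b
    df_e = len(d) - len(groups) * len(loads)
    out = {}
    for term, ss, df in (("group", ss_a, df_a), ("load", ss_b, df_b),
                         ("group:load", ss_ab, df_ab)):
        f = (ss / df) / (ss_e / df_e)
        out[term] = (f, 1 - sps.f.cdf(f, df, df_e))
    return out


class TestAnova:
    def test_matches_sums_of_squares_oracle(self, rng):
        t = balanced_table(rng, n=7, effect=(("SZ", "L3"), -0.2))
        got = anova_group_by_load(t, "C_net").set_index("term")
        expected = anova_oracle(t)
        for term, (f, p) in expected.items():
            assert got.loc[term, "F"] == pytest.approx(f, abs=1e-8)
            assert got.loc[term, "p"] == pytest.approx(p, abs=1e-8)

    def test_constant_data_degenerate(self, rng):
        t = balanced_table(rng)
        t["value"] = 3.0
        got = anova_group_by_load(t, "C_net")
        assert (got["p"] == 1.0).all()

    def test_single_level_factor_rejected(self, rng):
        t = balanced_table(rng)
        with pytest.raises(ValueError, match="levels"):
            anova_group_by_load(t[t["group"] == "HC"], "C_net")

    def test_planted_interaction_detected(self, rng):
        t = balanced_table(rng, n=35, effect=(("SZ", "L3"), -0.3))
        got = anova_group_by_load(t, "C_net").set_index("term")
        assert got.loc["group:load", "p"] < 0.001


# ---------------------------------------------------------------------------
# FDR
# ---------------------------------------------------------------------------

def bh_oracle(p):
    """Definitional Benjamini-Hochberg step-up adjustment."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p[i] / rank)
        adj[i] = running
    return adj


class TestFdr:
    def test_hand_example(self):
        assert np.allclose(fdr_correct([0.01, 0.02, 0.03, 0.04]),
                           [0.04, 0.04, 0.04, 0.04])

    def test_edge_cases(self):
        assert fdr_correct([0.2]) == pytest.approx([0.2])
        assert np.allclose(fdr_correct([1.0, 1.0, 1.0]), 1.0)

    def test_matches_definitional_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            m = int(rng.integers(1, 40))
            p = rng.random(m)
            assert np.allclose(fdr_correct(p), bh_oracle(p), atol=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=30))
    def test_adjusted_at_least_raw_and_order_preserving(self, p):
        adj = fdr_correct(p)
        p = np.asarray(p)
        assert np.all(adj >= p - 1e-15)
        assert np.all(adj <= 1.0)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_correct([0.5, 1.5])


# ---------------------------------------------------------------------------
# group tests per observation
# ---------------------------------------------------------------------------

def obs_table(rng, n=10, shift_obs=None, shift=0.0, n_obs=16):
    rows = []
    for obs in range(1, n_obs + 1):
        for g in ("HC", "SZ"):
            for i in range(n):
                v = rng.normal(0.0, 1.0)
                if g == "SZ" and (shift_obs is None or obs == shift_obs):
                    v += shift
                rows.append({"subject": f"{g}{i}", "group": g, "site": "a",
                             "load": "L3", "observation": obs,
                             "degree": float(obs), "measure": "C_net",
                             "value": v})
    return pd.DataFrame(rows)


class TestGroupTests:
    def test_identical_groups_mostly_accept(self, rng):
        t = obs_table(rng, shift=0.0)
        res = group_tests_per_observation(t, "C_net", load="L3")
        assert len(res) == 16
        assert np.all(res["p_fdr"] >= res["p_raw"] - 1e-15)

    def test_single_shifted_observation_survives_fdr(self, rng):
        t = obs_table(rng, shift_obs=7, shift=3.0)
        res = group_tests_per_observation(t, "C_net", load="L3")
        sig = res[res["p_fdr"] < 0.05]["observation"].tolist()
        assert sig == [7]

    def test_cross_load_comparison_spec(self, rng):
        t3 = obs_table(rng, shift=-2.5)
        t5 = obs_table(rng)
        t5["load"] = "L5"
        full = pd.concat([t3, t5], ignore_index=True)
        res = group_tests_per_observation(
            full, "C_net", comparison=(("HC", "L5"), ("SZ", "L3")))
        assert len(res) == 16
        # the planted SZ-L3 shift shows up against HC-L5
        assert (res["p_fdr"] < 0.05).sum() > 8

    def test_empty_cell_raises(self, rng):
        t = obs_table(rng)
        with pytest.raises(ValueError, match="empty cell"):
            group_tests_per_observation(t, "C_net", load="L1")


class TestLoadContrasts:
    def test_identical_loads_give_t0_p_half(self):
        t = pd.DataFrame([
            {"subject": f"s{i}", "group": "HC", "site": "a", "load": l,
             "observation": "avg", "degree": np.nan, "measure": "C_net",
             "value": 1.0}
            for i in range(6) for l in ("L1", "L3")])
        res = load_contrast_tests(t, "C_net", "L1", "L3", "increase", "HC")
        assert res["t"].iloc[0] == 0.0
        assert res["p_raw"].iloc[0] == 0.5

    def test_v_shape_detected(self, rng):
        rows = []
        base = {"L1": 1.0, "L3": 0.6, "L5": 1.0}
        for i in range(20):
            for l in ("L1", "L3", "L5"):
                rows.append({"subject": f"s{i}", "group": "SZ", "site": "a",
                             "load": l, "observation": "avg", "degree": np.nan,
                             "measure": "C_net",
                             "value": base[l] + rng.normal(0, 0.1)})
        t = pd.DataFrame(rows)
        dec = load_contrast_tests(t, "C_net", "L1", "L3", "decrease", "SZ")
        inc = load_contrast_tests(t, "C_net", "L3", "L5", "increase", "SZ")
        assert dec["p_raw"].iloc[0] < 0.01
        assert inc["p_raw"].iloc[0] < 0.01

    def test_missing_subject_raises(self, rng):
        t = pd.DataFrame([
            {"subject": "s0", "group": "HC", "site": "a", "load": "L1",
             "observation": "avg", "degree": np.nan, "measure": "C_net",
             "value": 1.0},
            {"subject": "s1", "group": "HC", "site": "a", "load": "L3",
             "observation": "avg", "degree": np.nan, "measure": "C_net",
             "value": 1.0},
        ])
        with pytest.raises(ValueError, match="missing"):
            load_contrast_tests(t, "C_net", "L1", "L3", "increase", "HC")

    def test_bad_direction_rejected(self, rng):
        with pytest.raises(ValueError, match="direction"):
            load_contrast_tests(balanced_table(rng), "C_net", "L1", "L3",
                                "sideways", "HC")


# ---------------------------------------------------------------------------
# behavior and motion
# ---------------------------------------------------------------------------

class TestBehaviorCorrelations:
    def _table_and_behavior(self, rng, slope=-400.0, noise=0.0):
        vals, beh = {}, []
        for g in ("HC", "SZ"):
            for i in range(15):
                v = rng.uniform(0.1, 0.4)
                vals[(g, "L3", f"{g}{i}")] = v
                beh.append({"subject": f"{g}{i}", "group": g, "load": "L3",
                            "accuracy": 0.97,
                            "rt_ms": 700 + slope * v + rng.normal(0, noise)})
        return make_table(vals), pd.DataFrame(beh)

    def test_exact_linear_gives_r_minus_one(self, rng):
        t, b = self._table_and_behavior(rng)
        res = behavior_correlations(t, b, "C_net", "L3").set_index("scope")
        assert res.loc["all", "r"] == pytest.approx(-1.0)
        assert res.loc["HC", "r"] == pytest.approx(-1.0)

    def test_shuffled_rt_uncorrelated(self, rng):
        t, b = self._table_and_behavior(rng, slope=0.0, noise=50.0)
        res = behavior_correlations(t, b, "C_net", "L3").set_index("scope")
        assert abs(res.loc["all", "r"]) < 0.4

    def test_zero_variance_raises(self, rng):
        t, b = self._table_and_behavior(rng)
        t["value"] = 0.3
        with pytest.raises(ValueError, match="variance"):
            behavior_correlations(t, b, "C_net", "L3")


class TestMotionSummaries:
    def test_zero_trace(self):
        out = motion_summaries(np.zeros((10, 6)))
        assert out == {"mean_motion": 0.0, "max_motion": 0.0,
                       "mean_rotation": 0.0, "n_movements": 0}

    def test_single_step_convention(self):
        # one 1 mm jump among n frames: mean over the n-1 displacements
        tr = np.zeros((5, 6))
        tr[2:, 0] = 1.0
        out = motion_summaries(tr)
        assert out["mean_motion"] == pytest.approx(1 / 4)
        assert out["max_motion"] == 1.0
        assert out["n_movements"] == 1

    def test_rotation_only(self):
        tr = np.zeros((6, 6))
        tr[3:, 4] = 0.01
        out = motion_summaries(tr)
        assert out["mean_motion"] == 0.0
        assert out["mean_rotation"] > 0.0

    def test_wrong_shape_rejected(self):
        with pytest.raises(ValueError, match="6"):
            motion_summaries(np.zeros((10, 4)))
        with pytest.raises(ValueError, match="frames"):
            motion_summaries(np.zeros((1, 6)))
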