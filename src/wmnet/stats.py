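"""Group x load statistics on network-metric tables.

Reproduces the study's statistical battery on a long-form metric table
(subject, group, site, load, observation 1..G or "avg", measure, value):
site-mean correction, two-way group x load ANOVA on the per-subject
averaged measures, per-observation two-sample t-tests with
Benjamini-Hochberg FDR across the observation grid, one-tailed paired
load-contrast tests, Pearson correlations between averaged measures and
reaction time, and rigid-body head-motion summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# site correction
# --------------------------------------------------------------------------

def correct_site_effects(table: pd.DataFrame) -> pd.DataFrame:
    """Remove per-site means within each (measure, load, observation) cell.

    Equivalent to regressing each measure on site and keeping residuals,
    with the grand mean restored so values stay on their original scale.
    Single-site tables pass through unchanged (logged).
    """
    table = table.copy()
    if table["site"].nunique() < 2:
        log.info("single-site table: site correction is the identity")
        return table
    counts = table.groupby("site")["subject"].nunique()
    if (counts < 2).any():
        log.warning("a site has < 2 subjects; site correction skipped")
        return table

    keys = ["measure", "load", "observation"]
    grand = table.groupby(keys)["value"].transform("mean")
    site_means = table.groupby(keys + ["site"])["value"].transform("mean")
    table["value"] = table["value"] - site_means + grand
    return table


# --------------------------------------------------------------------------
# ANOVA
# --------------------------------------------------------------------------

def anova_group_by_load(
    table: pd.DataFrame,
    measure: str,
    use_averaged: bool = True,
    observation: int | None = None,
) -> pd.DataFrame:
    """Two-way ANOVA with group, load and their interaction.

    Operates on one value per subject x load: the average over the
    observation grid by default, or a single observation.  Returns a frame
    with F and p for 'group', 'load' and 'group:load'.
    """
    sel = table[table["measure"] == measure]
    if use_averaged:
        sel = sel[sel["observation"] == "avg"]
    else:
        if observation is None:
            raise ValueError("observation index required when use_averaged=False")
        sel = sel[sel["observation"] == observation]
    if sel.empty:
        raise ValueError(f"no rows for measure {measure!r}")
    for factor in ("group", "load"):
        if sel[factor].nunique() < 2:
            raise ValueError(f"factor {factor!r} has < 2 levels")
    if sel["value"].std() == 0:
        return pd.DataFrame({
            "term": ["group", "load", "group:load"],
            "F": [0.0] * 3, "p": [1.0] * 3,
        })
    model = smf.ols("value ~ C(group) * C(load)", data=sel).fit()
    aov = sm.stats.anova_lm(model, typ=2)
    rename = {"C(group)": "group", "C(load)": "load",
              "C(group):C(load)": "group:load"}
    rows = []
    for name, label in rename.items():
        rows.append({"term": label,
                     "F": float(aov.loc[name, "F"]),
                     "p": float(aov.loc[name, "PR(>F)"])})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# multiple testing
# --------------------------------------------------------------------------

def fdr_correct(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values outside [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


# --------------------------------------------------------------------------
# group comparisons per observation
# --------------------------------------------------------------------------

def group_tests_per_observation(
    table: pd.DataFrame,
    measure: str,
    load: str | None = None,
    comparison: tuple[tuple[str, str], tuple[str, str]] | None = None,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Two-sample t-test at every observation degree, FDR across the grid.

    Either ``load`` compares HC vs SZ at one load, or ``comparison`` gives
    two explicit (group, load) cells — e.g. (("HC", "L5"), ("SZ", "L3"))
    for the cross-load contrast.  Returns observation, degree, t, p_raw,
    p_fdr.
    """
    if comparison is None:
        if load is None:
            raise ValueError("give either load or comparison")
        comparison = (("HC", load), ("SZ", load))
    (g1, l1), (g2, l2) = comparison
    sel = table[(table["measure"] == measure)
                & (table["observation"] != "avg")]
    obs_values = sorted(sel["observation"].unique())
    rows = []
    for obs in obs_values:
        d = sel[sel["observation"] == obs]
        a = d[(d["group"] == g1) & (d["load"] == l1)]["value"].to_numpy()
        b = d[(d["group"] == g2) & (d["load"] == l2)]["value"].to_numpy()
        if len(a) == 0 or len(b) == 0:
            raise ValueError(
                f"empty cell at observation {obs}: "
                f"({g1},{l1}) n={len(a)}, ({g2},{l2}) n={len(b)}"
            )
        t, p = sps.ttest_ind(a, b, equal_var=equal_var)
        degree = d["degree"].iloc[0]
        rows.append({"observation": obs, "degree": degree,
                     "t": float(t), "p_raw": float(p)})
    out = pd.DataFrame(rows)
    out["p_fdr"] = fdr_correct(out["p_raw"].to_numpy())
    return out


def load_contrast_tests(
    table: pd.DataFrame,
    measure: str,
    from_load: str,
    to_load: str,
    direction: str,
    group: str,
    use_averaged: bool = True,
) -> pd.DataFrame:
    """One-tailed one-sample t-test on per-subject load contrasts.

    ``direction`` is "increase" (to > from) or "decrease".  With
    ``use_averaged=False``, one test per observation with FDR across the
    grid; otherwise a single test on the averaged measure.
    """
    if direction not in ("increase", "decrease"):
        raise ValueError("direction must be 'increase' or 'decrease'")
    alternative = "greater" if direction == "increase" else "less"
    sel = table[(table["measure"] == measure) & (table["group"] == group)]
    obs_values = ["avg"] if use_averaged else [
        o for o in sorted(sel["observation"].unique()) if o != "avg"
    ]
    rows = []
    for obs in obs_values:
        d = sel[sel["observation"] == obs]
        a = d[d["load"] == from_load].set_index("subject")["value"]
        b = d[d["load"] == to_load].set_index("subject")["value"]
        missing = sorted(set(a.index) ^ set(b.index))
        if missing:
            raise ValueError(f"subjects missing one load: {missing}")
        diff = (b - a.reindex(b.index)).to_numpy()
        if np.allclose(diff, 0):
            t, p = 0.0, 0.5
        else:
            t, p = sps.ttest_1samp(diff, 0.0, alternative=alternative)
        rows.append({"observation": obs, "t": float(t), "p_raw": float(p),
                     "direction": direction, "group": group,
                     "contrast": f"{from_load}->{to_load}"})
    out = pd.DataFrame(rows)
    if not use_averaged:
        out["p_fdr"] = fdr_correct(out["p_raw"].to_numpy())
    return out


# --------------------------------------------------------------------------
# behavior and motion
# --------------------------------------------------------------------------

def behavior_correlations(
    table: pd.DataFrame,
    behavior: pd.DataFrame,
    measure: str,
    load: str,
) -> pd.DataFrame:
    """Pearson r between the averaged measure and mean correct-trial RT.

    Reported pooled over all subjects and within each group.  Raises on a
    zero-variance input (r undefined).
    """
    m = table[(table["measure"] == measure)
              & (table["observation"] == "avg")
              & (table["load"] == load)][["subject", "group", "value"]]
    b = behavior[behavior["load"] == load][["subject", "rt_ms"]]
    d = m.merge(b, on="subject", how="inner")
    rows = []
    for label, sub in (("all", d),
                       *((g, d[d["group"] == g]) for g in sorted(d["group"].unique()))):
        if sub["value"].nunique() <= 1 or sub["rt_ms"].nunique() <= 1:
            raise ValueError(f"zero variance in {label} cell; correlation undefined")
        r, p = sps.pearsonr(sub["value"], sub["rt_ms"])
        rows.append({"scope": label, "n": len(sub),
                     "r": float(r), "p": float(p)})
    return pd.DataFrame(rows)


def motion_summaries(
    trace: np.ndarray, movement_threshold_mm: float = 0.1
) -> dict:
    """Head-motion summary of one 6-column rigid-body trace.

    Translation displacement is the Euclidean norm of the frame-to-frame
    difference of (tx, ty, tz) in mm; rotation magnitude likewise over
    (rx, ry, rz) in radians.  Means are taken over the n-1 frame-to-frame
    displacements; "number of movements" counts displacements above the
    threshold (default 0.1 mm).
    """
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 2 or trace.shape[1] != 6:
        raise ValueError(f"expected an n x 6 trace, got shape {trace.shape}")
    if trace.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    d = np.diff(trace, axis=0)
    trans = np.linalg.norm(d[:, :3], axis=1)
    rot = np.linalg.norm(d[:, 3:], axis=1)
    return {
        "mean_motion": float(trans.mean()),
        "max_motion": float(trans.max()),
        "mean_rotation": float(rot.mean()),
        "n_movements": int((trans > movement_threshold_mm).sum()),
    }


def motion_group_tests(
    motion: dict[str, list[np.ndarray]],
    subject_info: dict[str, dict],
    movement_threshold_mm: float = 0.1,
) -> pd.DataFrame:
    """Per-subject motion summaries (runs concatenated) with group t-tests."""
    rows = []
    for subj, runs in motion.items():
        trace = np.concatenate(runs, axis=0)
        s = motion_summaries(trace, movement_threshold_mm)
        rows.append({"subject": subj, "group": subject_info[subj]["group"], **s})
    per_subject = pd.DataFrame(rows)
    tests = []
    for col in ("mean_motion", "max_motion", "mean_rotation", "n_movements"):
        a = per_subject[per_subject["group"] == "HC"][col]
        b = per_subject[per_subject["group"] == "SZ"][col]
        t, p = sps.ttest_ind(a, b)
        tests.append({"summary": col, "t": float(t), "p": float(p),
                      "mean_HC": float(a.mean()), "mean_SZ": float(b.mean())})
    tests = pd.DataFrame(tests)
    tests.attrs["per_subject"] = per_subject
    return tests


# --------------------------------------------------------------------------
# report assembly
# --------------------------------------------------------------------------

@dataclass
class StatReport:
    """Bundle of every statistical result the pipeline produces."""

    anova: pd.DataFrame
    group_tests: dict[str, pd.DataFrame]        # per (measure, load) key
    contrast_tests: pd.DataFrame
    behavior: pd.DataFrame
    motion: pd.DataFrame | None

    def to_dict(self) -> dict:
        return {
            "anova": self.anova.to_dict(orient="records"),
            "group_tests": {k: v.to_dict(orient="records")
                            for k, v in self.group_tests.items()},
            "contrast_tests": self.contrast_tests.to_dict(orient="records"),
            "behavior": self.behavior.to_dict(orient="records"),
            "motion": (self.motion.to_dict(orient="records")
                       if self.motion is not None else None),
        }


def run_statistics(
    table: pd.DataFrame,
    behavior: pd.DataFrame | None = None,
    motion: dict[str, list[np.ndarray]] | None = None,
    subject_info: dict[str, dict] | None = None,
    measures: tuple[str, ...] = ("C_net", "L_net", "E_local", "E_global"),
    loads: tuple[str, ...] = ("L1", "L3", "L5"),
    alpha: float = 0.05,
    correct_sites: bool = True,
) -> StatReport:
    """The full battery: site correction, ANOVAs, t-tests, FDR, correlations."""
    if correct_sites:
        table = correct_site_effects(table)

    anova_rows = []
    for meas in measures:
        a = anova_group_by_load(table, meas)
        a.insert(0, "measure", meas)
        anova_rows.append(a)
    anova = pd.concat(anova_rows, ignore_index=True)

    group_tests = {}
    for meas in measures:
        for load in loads:
            group_tests[f"{meas}@{load}"] = group_tests_per_observation(
                table, meas, load=load
            )
        group_tests[f"{meas}@HC-L5_vs_SZ-L3"] = group_tests_per_observation(
            table, meas, comparison=(("HC", "L5"), ("SZ", "L3"))
        )

    contrast_rows = []
    for meas in measures:
        for group in ("HC", "SZ"):
            for frm, to in (("L1", "L3"), ("L3", "L5")):
                for direction in ("increase", "decrease"):
                    row = load_contrast_tests(
                        table, meas, frm, to, direction, group
                    )
                    row.insert(0, "measure", meas)
                    contrast_rows.append(row)
    contrasts = pd.concat(contrast_rows, ignore_index=True)

    beh_rows = []
    if behavior is not None:
        for meas in measures:
            for load in loads:
                r = behavior_correlations(table, behavior, meas, load)
                r.insert(0, "measure", meas)
                r.insert(1, "load", load)
                beh_rows.append(r)
    beh = (pd.concat(beh_rows, ignore_index=True)
           if beh_rows else pd.DataFrame())

    motion_df = None
    if motion is not None and subject_info is not None:
        motion_df = motion_group_tests(motion, subject_info)

    return StatReport(
        anova=anova, group_tests=group_tests,
        contrast_tests=contrasts, behavior=beh, motion=motion_df,
    )
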