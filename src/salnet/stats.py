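"""Group-by-condition inference on salience-network measures.

The primary model is a mixed-design (split-plot) repeated-measures ANOVA:
condition (RS, Std, Dev) within subjects, group between subjects. Mauchly's
test screens sphericity; when it fails (p < .05) the Greenhouse–Geisser
ε-corrected p-values are reported as primary, for the condition effect and
the interaction alike. Normality is screened by the conventional
skewness/kurtosis rule (|skewness| < 2, |excess kurtosis| < 7; the Fisher
*excess* convention is used throughout). Post-hoc group contrasts use a
percentile bootstrap (5,000 resamples) of the mean difference instead of
multiplicity-corrected t-tests.

Testing order is gated: global strength is tested first and the three edges
only when the strength interaction is notable (default gate p ≤ 0.10 —
a configurable screening choice, not an inference about any canonical
threshold). The gate changes the procedure's error rates, so the module also
ships a calibration simulation that reports the empirical type-I rate of the
full gated procedure under the null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import CONDITIONS, EDGES


@dataclass
class NormalityResult:
    skewness: float
    kurtosis: float            # Fisher excess convention
    passed: bool
    valid: bool = True         # False for degenerate (constant) input


def normality_screen(values, skew_limit: float = 2.0,
                     kurt_limit: float = 7.0) -> NormalityResult:
    """Skewness/kurtosis screen for approximate normality."""
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0:
        return NormalityResult(np.nan, np.nan, passed=False, valid=False)
    g1 = float(sps.skew(x, bias=True))
    g2 = float(sps.kurtosis(x, fisher=True, bias=True))
    return NormalityResult(g1, g2,
                           passed=abs(g1) < skew_limit and abs(g2) < kurt_limit)


@dataclass
class RmAnovaResult:
    f_group: float
    p_group: float
    f_condition: float
    p_condition: float
    f_interaction: float
    p_interaction: float
    mauchly_w: float
    mauchly_p: float
    gg_epsilon: float
    p_condition_gg: float
    p_interaction_gg: float
    sphericity_ok: bool
    correction_applied: bool
    df_within: tuple[float, float]

    @property
    def p_condition_reported(self) -> float:
        return self.p_condition_gg if self.correction_applied \
            else self.p_condition

    @property
    def p_interaction_reported(self) -> float:
        return self.p_interaction_gg if self.correction_applied \
            else self.p_interaction


def rm_anova(values: np.ndarray, groups,
             conditions: tuple[str, ...] = CONDITIONS,
             sphericity_alpha: float = 0.05) -> RmAnovaResult:
    """Mixed-design ANOVA of a subjects × conditions matrix.

    ``values`` has one row per subject and one column per condition;
    ``groups`` labels each row. Greenhouse–Geisser correction is applied to
    the within and interaction effects when Mauchly's test rejects
    sphericity at ``sphericity_alpha``.
    """
    import pingouin as pg

    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    n, k = values.shape
    if k != len(conditions):
        raise ValueError("one column per condition required")
    uniq = np.unique(groups)
    if uniq.size != 2:
        raise ValueError("exactly two groups required")
    if min((groups == g).sum() for g in uniq) < 2:
        raise ValueError("need at least 2 subjects per group")
    if not np.all(np.isfinite(values)):
        raise ValueError("missing cells are not allowed")
    if np.ptp(values) == 0:
        raise ValueError("constant data: ANOVA undefined")

    long = pd.DataFrame({
        "subject": np.repeat(np.arange(n), k),
        "group": np.repeat(groups, k),
        "condition": np.tile(conditions, n),
        "y": values.ravel(),
    })
    aov = pg.mixed_anova(data=long, dv="y", within="condition",
                         subject="subject", between="group", correction=True)
    aov = aov.set_index("Source")
    row_g, row_c, row_i = aov.loc["group"], aov.loc["condition"], \
        aov.loc["Interaction"]
    eps = float(row_c["eps"])
    w = float(row_c.get("W_spher", np.nan))
    p_spher = float(row_c.get("p_spher", np.nan))
    df1, df2 = float(row_c["DF1"]), float(row_c["DF2"])
    # pingouin reports the GG-corrected p only for the within effect; the
    # interaction shares eps and dfs, so correct it the same way
    p_c_gg = float(row_c["p_GG_corr"]) if np.isfinite(eps) else np.nan
    p_i_gg = float(sps.f.sf(row_i["F"], eps * df1, eps * df2))
    sphericity_ok = bool(p_spher >= sphericity_alpha) \
        if np.isfinite(p_spher) else True
    return RmAnovaResult(
        f_group=float(row_g["F"]), p_group=float(row_g["p_unc"]),
        f_condition=float(row_c["F"]), p_condition=float(row_c["p_unc"]),
        f_interaction=float(row_i["F"]), p_interaction=float(row_i["p_unc"]),
        mauchly_w=w, mauchly_p=p_spher, gg_epsilon=eps,
        p_condition_gg=p_c_gg, p_interaction_gg=p_i_gg,
        sphericity_ok=sphericity_ok,
        correction_applied=not sphericity_ok,
        df_within=(df1, df2),
    )


@dataclass
class BootstrapResult:
    observed: float            # mean(a) - mean(b)
    ci_low: float
    ci_high: float
    p_value: float
    n_resamples: int
    seed: int | None = None


def bootstrap_posthoc(group_a, group_b, n_resamples: int = 5000,
                      seed: int | None = 0) -> BootstrapResult:
    """Percentile bootstrap of the group mean difference.

    Each group is resampled with replacement; the 95% CI is the percentile
    interval of the resampled differences and the two-sided p-value is
    2 × min(P(diff* ≤ 0), P(diff* ≥ 0)), floored at 1/n. Deterministic
    under the seed.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    rng = np.random.default_rng(seed)
    ra = a[rng.integers(0, a.size, (n_resamples, a.size))].mean(axis=1)
    rb = b[rng.integers(0, b.size, (n_resamples, b.size))].mean(axis=1)
    diffs = ra - rb
    lo, hi = np.percentile(diffs, [2.5, 97.5])
    p = 2.0 * min(np.mean(diffs <= 0), np.mean(diffs >= 0))
    p = max(min(p, 1.0), 1.0 / n_resamples)
    return BootstrapResult(float(a.mean() - b.mean()), float(lo), float(hi),
                           float(p), n_resamples, seed)


# ---------------------------------------------------------------------------
# gated testing procedure


def _pivot(df: pd.DataFrame, value_col: str):
    wide = df.pivot_table(index="subject", columns="condition",
                          values=value_col)
    wide = wide[list(CONDITIONS)]
    groups = df.drop_duplicates("subject").set_index("subject")["group"]
    groups = groups.loc[wide.index]
    return wide.to_numpy(), groups.to_numpy()


def gated_network_tests(networks: pd.DataFrame, band: str,
                        groups: tuple[str, str] = ("nrMDD", "rMDD"),
                        gate_p: float = 0.10, alpha: float = 0.05,
                        n_bootstrap: int = 5000,
                        seed: int = 0) -> dict:
    """Strength first; edges only on a notable strength interaction.

    ``networks`` is the tidy per-subject table (columns subject, group, band,
    condition, strength, wpli_<a>_<b>). When an edge interaction is
    significant, a bootstrap post-hoc group contrast is run per condition.
    Returns a nested dict of RmAnovaResult / BootstrapResult objects.
    """
    sub = networks[(networks["band"] == band)
                   & networks["group"].isin(groups)]
    vals, glab = _pivot(sub, "strength")
    strength_res = rm_anova(vals, glab)
    out = {"strength": strength_res, "edges": {}, "posthoc": {},
           "gate_passed": strength_res.p_interaction_reported <= gate_p}
    if not out["gate_passed"]:
        return out
    for a, b in EDGES:
        col = f"wpli_{a}_{b}"
        vals, glab = _pivot(sub, col)
        res = rm_anova(vals, glab)
        out["edges"][(a, b)] = res
        if res.p_interaction_reported < alpha:
            for ci, cond in enumerate(CONDITIONS):
                x = vals[glab == groups[0], ci]
                y = vals[glab == groups[1], ci]
                out["posthoc"][(a, b, cond)] = bootstrap_posthoc(
                    x, y, n_bootstrap, seed)
    return out


def interaction_type1_rate(n_reps: int = 1000, n_per_group=(14, 17),
                           alpha: float = 0.05, seed: int = 0) -> float:
    """Empirical type-I rate of the interaction test under an exchangeable
    Gaussian null (no group effect, compound-symmetric conditions)."""
    rng = np.random.default_rng(seed)
    n1, n2 = n_per_group
    groups = np.array(["a"] * n1 + ["b"] * n2)
    hits = 0
    for _ in range(n_reps):
        subj = rng.standard_normal((n1 + n2, 1))
        y = subj + 0.5 * rng.standard_normal((n1 + n2, 3))
        res = rm_anova(y, groups)
        if res.p_interaction_reported < alpha:
            hits += 1
    return hits / n_reps


def bootstrap_coverage(n_reps: int = 1000, n_per_group=(14, 17),
                       true_diff: float = 1.0, sd: float = 1.0,
                       n_resamples: int = 2000, seed: int = 0) -> float:
    """Fraction of replicates whose percentile 95% CI covers the true
    group mean difference (Gaussian data)."""
    rng = np.random.default_rng(seed)
    n1, n2 = n_per_group
    covered = 0
    for _ in range(n_reps):
        a = true_diff + sd * rng.standard_normal(n1)
        b = sd * rng.standard_normal(n2)
        res = bootstrap_posthoc(a, b, n_resamples,
                                seed=int(rng.integers(2 ** 31)))
        if res.ci_low <= true_diff <= res.ci_high:
            covered += 1
    return covered / n_reps


def calibrate_gated_procedure(n_reps: int = 200, n_per_group=(14, 17),
                              gate_p: float = 0.10, alpha: float = 0.05,
                              seed: int = 0) -> dict:
    """Empirical error rates of the full gated procedure under the null.

    Reports how often the gate opens and how often any edge interaction is
    declared significant — the family-wise rate the gate is meant to keep
    near the nominal level.
    """
    rng = np.random.default_rng(seed)
    n1, n2 = n_per_group
    groups = np.array(["a"] * n1 + ["b"] * n2)
    gate_open = 0
    any_edge = 0
    for _ in range(n_reps):
        subj = rng.standard_normal((n1 + n2, 1))
        strength = subj + 0.5 * rng.standard_normal((n1 + n2, 3))
        res = rm_anova(strength, groups)
        if res.p_interaction_reported > gate_p:
            continue
        gate_open += 1
        hit = False
        for _edge in EDGES:
            ev = subj + 0.5 * rng.standard_normal((n1 + n2, 3))
            if rm_anova(ev, groups).p_interaction_reported < alpha:
                hit = True
        if hit:
            any_edge += 1
    return {"n_reps": n_reps, "gate_open_rate": gate_open / n_reps,
            "any_edge_significant_rate": any_edge / n_reps}


def stats_tables(results: dict, band: str) -> pd.DataFrame:
    """Flatten gated-test results to one row per (measure, effect)."""
    rows = []

    def add(measure: str, res: RmAnovaResult):
        for eff, f, p, p_rep in (
                ("group", res.f_group, res.p_group, res.p_group),
                ("condition", res.f_condition, res.p_condition,
                 res.p_condition_reported),
                ("interaction", res.f_interaction, res.p_interaction,
                 res.p_interaction_reported)):
            rows.append({"band": band, "measure": measure, "effect": eff,
                         "F": f, "p_uncorrected": p, "p_reported": p_rep,
                         "epsilon": res.gg_epsilon,
                         "gg_applied": res.correction_applied,
                         "mauchly_W": res.mauchly_w,
                         "mauchly_p": res.mauchly_p})

    add("strength", results["strength"])
    for edge, res in results["edges"].items():
        add(f"wpli_{edge[0]}_{edge[1]}", res)
    df = pd.DataFrame(rows)
    boot_rows = []
    for (a, b, cond), br in results.get("posthoc", {}).items():
        boot_rows.append({"band": band, "measure": f"wpli_{a}_{b}",
                          "effect": f"posthoc_{cond}",
                          "observed_diff": br.observed, "ci_low": br.ci_low,
                          "ci_high": br.ci_high, "p_bootstrap": br.p_value,
                          "n_resamples": br.n_resamples, "seed": br.seed})
    if boot_rows:
        df = pd.concat([df, pd.DataFrame(boot_rows)], ignore_index=True)
    return df
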