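"""Group comparison and clinical-correlation layer.

Two-sample pooled-variance t-tests with Benjamini-Hochberg FDR control
within each comparison family, Spearman correlations against clinical
severity scores, and a chi-square / t-test demographics table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


class StatsError(ValueError):
    pass


# --------------------------------------------------------------- primitives


def two_sample_ttest(x, y, equal_var: bool = True) -> tuple[float, float, float]:
    """Two-tailed two-sample t-test; pooled variance (Student) by default.

    Returns (t, df, p).  Zero pooled variance with equal means gives
    (0, df, 1); with unequal means it is an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise StatsError("each sample needs at least 2 values")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise StatsError("samples must be finite")
    nx, ny = x.size, y.size
    if equal_var:
        df = nx + ny - 2.0
        sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / df
        if sp2 <= 0.0:
            if np.isclose(x.mean(), y.mean()):
                return 0.0, df, 1.0
            raise StatsError("zero pooled variance with unequal means")
        t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1.0 / nx + 1.0 / ny))
    else:
        vx, vy = x.var(ddof=1) / nx, y.var(ddof=1) / ny
        if vx + vy <= 0.0:
            if np.isclose(x.mean(), y.mean()):
                return 0.0, float(nx + ny - 2), 1.0
            raise StatsError("zero variance with unequal means")
        t = (x.mean() - y.mean()) / np.sqrt(vx + vy)
        df = (vx + vy) ** 2 / (vx**2 / (nx - 1) + vy**2 / (ny - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(df), float(min(p, 1.0))


def bh_fdr(pvalues, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up.

    q_i = min over j >= rank(i) of m * p_(j) / j, capped at 1; rejections
    are q <= alpha.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise StatsError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q, q <= alpha


def spearman_p_from_rho(rho: float, n: int, alternative: str = "two-sided") -> float:
    """Student-t approximation p-value for a Spearman coefficient.

    t = rho * sqrt((n - 2) / (1 - rho^2)), df = n - 2.
    """
    if n < 3:
        raise StatsError("need n >= 3")
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    df = n - 2
    if alternative == "two-sided":
        return float(2.0 * sps.t.sf(abs(t), df))
    if alternative == "greater":
        return float(sps.t.sf(t, df))
    if alternative == "less":
        return float(sps.t.cdf(t, df))
    raise StatsError(f"unknown alternative {alternative!r}")


@dataclass(frozen=True)
class CorrelationResult:
    descriptor: str
    score: str
    rho: float
    n: int
    p: float
    defined: bool = True


def spearman_corr(x, y, alternative: str = "two-sided",
                  descriptor: str = "", score: str = "") -> CorrelationResult:
    """Spearman rank correlation with mid-ranks for ties.

    The p-value uses the Student-t approximation.  Constant input yields
    an undefined (flagged) result rather than a number.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise StatsError("samples must be paired")
    if x.size < 3:
        raise StatsError("need at least 3 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return CorrelationResult(descriptor, score, float("nan"), int(x.size),
                                 float("nan"), defined=False)
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    p = spearman_p_from_rho(rho, x.size, alternative)
    return CorrelationResult(descriptor, score, rho, int(x.size), p)


def chi_square_2x2(table) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, df = 1, no continuity correction."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise StatsError("table must be 2x2")
    if np.any(t < 0):
        raise StatsError("counts must be non-negative")
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    n = t.sum()
    if np.any(rows <= 0) or np.any(cols <= 0):
        raise StatsError("both margins must be positive")
    a, b, c, d = t.ravel()
    chi2 = n * (a * d - b * c) ** 2 / (rows[0] * rows[1] * cols[0] * cols[1])
    return float(chi2), float(sps.chi2.sf(chi2, df=1))


# ---------------------------------------------------------- group analysis


def group_compare(metrics: pd.DataFrame, patient_group: str, control_group: str,
                  alpha: float = 0.05, equal_var: bool = True) -> pd.DataFrame:
    """Per-unit group t-tests with BH-FDR within each family.

    A family is one (unit_level, metric, state) combination: all units
    shown together are corrected together.  Subjects lacking windows in a
    state (NaN metric) are dropped per unit with a warning; units with
    fewer than 2 subjects in either group are excluded.
    """
    results = []
    families = metrics.groupby(["unit_level", "state"], sort=False)
    for (level, state), block in families:
        for metric in ("mli", "lf"):
            rows = []
            for unit, sub in block.groupby("unit_id", sort=False):
                vals = sub.dropna(subset=[metric])
                dropped = len(sub) - len(vals)
                if dropped:
                    warnings.warn(
                        f"{level}/{unit}/{metric}/state {state}: dropped "
                        f"{dropped} subjects with missing metric",
                        stacklevel=2,
                    )
                x = vals.loc[vals["group"] == patient_group, metric].to_numpy()
                y = vals.loc[vals["group"] == control_group, metric].to_numpy()
                if x.size < 2 or y.size < 2:
                    warnings.warn(
                        f"{level}/{unit}/{metric}/state {state}: fewer than 2 "
                        "subjects per group, excluded",
                        stacklevel=2,
                    )
                    continue
                t, df, p = two_sample_ttest(x, y, equal_var=equal_var)
                rows.append(
                    {
                        "family": f"{level}|{metric}|state={state}",
                        "unit_id": unit,
                        "unit_level": level,
                        "metric": metric.upper(),
                        "state": state,
                        "mean_patient": x.mean(),
                        "sd_patient": x.std(ddof=1),
                        "n_patient": x.size,
                        "mean_control": y.mean(),
                        "sd_control": y.std(ddof=1),
                        "n_control": y.size,
                        "t": t,
                        "df": df,
                        "p": p,
                    }
                )
            if not rows:
                continue
            fam = pd.DataFrame(rows)
            q, rej = bh_fdr(fam["p"].to_numpy(), alpha=alpha)
            fam["q"] = q
            fam["significant"] = rej
            results.append(fam)
    if not results:
        return pd.DataFrame()
    return pd.concat(results, ignore_index=True)


def clinical_correlations(metrics: pd.DataFrame, scores: pd.DataFrame,
                          selection: pd.DataFrame, patient_group: str,
                          alternative: str = "two-sided") -> pd.DataFrame:
    """Spearman rho between selected metrics and clinical scores, patients only.

    ``selection`` carries rows with unit_id / unit_level / metric / state
    (typically the significant rows of :func:`group_compare`); ``scores``
    is indexed by subject_id with one column per scale.
    """
    out = []
    patients = metrics[metrics["group"] == patient_group]
    for _, sel in selection.iterrows():
        block = patients[
            (patients["unit_id"] == sel["unit_id"])
            & (patients["unit_level"] == sel["unit_level"])
            & (patients["state"] == str(sel["state"]))
        ]
        col = sel["metric"].lower()
        block = block.dropna(subset=[col]).set_index("subject_id")
        for score_name in scores.columns:
            joined = block.join(scores[score_name], how="inner").dropna(
                subset=[score_name]
            )
            if len(joined) < 3:
                warnings.warn(
                    f"{sel['unit_id']}/{sel['metric']}: fewer than 3 scored "
                    "patients, skipped",
                    stacklevel=2,
                )
                continue
            res = spearman_corr(
                joined[col].to_numpy(), joined[score_name].to_numpy(),
                alternative=alternative,
                descriptor=f"{sel['unit_id']}|{sel['metric']}|state={sel['state']}",
                score=score_name,
            )
            out.append(
                {
                    "unit_id": sel["unit_id"],
                    "unit_level": sel["unit_level"],
                    "metric": sel["metric"],
                    "state": sel["state"],
                    "score": score_name,
                    "rho": res.rho,
                    "n": res.n,
                    "p": res.p,
                    "defined": res.defined,
                }
            )
    return pd.DataFrame(out)


def handedness_score(right, left) -> np.ndarray:
    """(Right - Left) / (Right + Left) laterality quotient."""
    right = np.asarray(right, dtype=float)
    left = np.asarray(left, dtype=float)
    total = right + left
    if np.any(total <= 0):
        raise StatsError("Right + Left must be positive")
    return (right - left) / total


def demographics_table(demo: pd.DataFrame, patient_group: str, control_group: str,
                       continuous=("age", "education", "handscore"),
                       gender_col: str = "gender") -> pd.DataFrame:
    """Group means +/- SD with t-test p (continuous) and chi-square p (gender)."""
    required = set(continuous) | {gender_col, "group"}
    missing_cols = sorted(required - set(demo.columns))
    if missing_cols:
        raise StatsError(f"demographics missing columns {missing_cols}")
    for col in list(continuous) + [gender_col]:
        bad = demo[demo[col].isna()]
        if len(bad):
            raise StatsError(
                f"missing {col} for subjects {sorted(bad['subject_id'])}"
                if "subject_id" in demo.columns
                else f"missing values in {col}"
            )
    pat = demo[demo["group"] == patient_group]
    ctl = demo[demo["group"] == control_group]
    rows = []
    for col in continuous:
        x = pat[col].to_numpy(dtype=float)
        y = ctl[col].to_numpy(dtype=float)
        t, df, p = two_sample_ttest(x, y)
        rows.append(
            {
                "field": col,
                "patient": f"{x.mean():.2f} ± {x.std(ddof=1):.2f}",
                "control": f"{y.mean():.2f} ± {y.std(ddof=1):.2f}",
                "test": "t",
                "p": p,
            }
        )
    table = [
        [int((ctl[gender_col] == "M").sum()), int((ctl[gender_col] == "F").sum())],
        [int((pat[gender_col] == "M").sum()), int((pat[gender_col] == "F").sum())],
    ]
    chi2, p = chi_square_2x2(table)
    rows.append(
        {
            "field": gender_col,
            "patient": f"{table[1][0]}/{table[1][1]}",
            "control": f"{table[0][0]}/{table[0][1]}",
            "test": "chi2",
            "p": p,
        }
    )
    return pd.DataFrame(rows)
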