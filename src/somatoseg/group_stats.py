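"""Group-level statistics linking segregation, sensitivity and geometry.

Pearson/Spearman correlations between IoS and tSNR, ANCOVA of IoS on tSNR
and resolution (with interaction, Type-II tests, nested model comparison and
per-level simple slopes), MANOVA with Pillai's trace on center-of-mass
coordinates, and 1-/2-way ANOVAs with Bonferroni-Holm post hocs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.multivariate.manova import MANOVA
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multitest import multipletests

from .core import ValidationError


@dataclass
class AnovaResult:
    """Term table (sum_sq, df, F, p) plus model-level fit statistics."""

    table: pd.DataFrame
    r_squared: float
    adj_r_squared: float
    df_resid: int
    model_f: float = float("nan")
    model_f_p: float = float("nan")
    posthoc: pd.DataFrame | None = None
    comparison_f: float = float("nan")
    comparison_p: float = float("nan")
    simple_slopes: pd.DataFrame | None = None


@dataclass
class ManovaResult:
    terms: pd.DataFrame  # term, pillai, F, df_num, df_den, p


def correlate(x, y) -> dict[str, float]:
    """Pearson and Spearman correlation with p-values."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValidationError("need paired vectors of length >= 4")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValidationError("non-finite values in input")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("zero variance input")
    pr, pp = stats.pearsonr(x, y)
    sr, sp = stats.spearmanr(x, y)
    return {"pearson_r": float(pr), "pearson_p": float(pp),
            "spearman_rho": float(sr), "spearman_p": float(sp)}


def _check_levels(factor: pd.Series, min_per_level: int = 2) -> None:
    counts = factor.value_counts()
    if len(counts) < 2:
        raise ValidationError("factor needs at least 2 levels")
    if (counts < min_per_level).any():
        raise ValidationError("need >= 2 observations per factor level")


def ancova_ios(ios, tsnr, resolution) -> AnovaResult:
    """ANCOVA of IoS on tSNR (covariate) x resolution (3-level factor).

    Treatment coding with the lowest resolution as reference; Type-II F
    tests; nested model comparison against ``ios ~ tsnr``; per-level simple
    slopes of tSNR as planned post hocs.
    """
    df = pd.DataFrame({
        "ios": np.asarray(ios, dtype=float),
        "tsnr": np.asarray(tsnr, dtype=float),
        "resolution": pd.Categorical([str(r) for r in resolution]),
    })
    _check_levels(df["resolution"])
    levels = sorted(df["resolution"].cat.categories, key=float)
    ref = levels[0]
    formula = f"ios ~ tsnr * C(resolution, Treatment('{ref}'))"
    try:
        full = smf.ols(formula, data=df).fit()
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise ValidationError(f"singular ANCOVA design: {exc}") from exc
    if full.df_resid < 1 or np.linalg.matrix_rank(full.model.exog) < full.model.exog.shape[1]:
        aliased = _aliased_columns(full.model.exog, full.model.exog_names)
        raise ValidationError(f"singular ANCOVA design; aliased terms: {aliased}")
    table = anova_lm(full, typ=2)

    reduced = smf.ols("ios ~ tsnr", data=df).fit()
    cmp_tab = anova_lm(reduced, full)
    comparison_f = float(cmp_tab["F"].iloc[1])
    comparison_p = float(cmp_tab["Pr(>F)"].iloc[1])

    # simple slope of tsnr within each resolution level
    slope_rows = []
    names = full.model.exog_names
    for lev in levels:
        c = np.zeros(len(names))
        c[names.index("tsnr")] = 1.0
        inter = f"tsnr:C(resolution, Treatment('{ref}'))[T.{lev}]"
        if inter in names:
            c[names.index(inter)] = 1.0
        ft = full.f_test(c)
        slope_rows.append({"resolution": lev, "F": float(ft.fvalue),
                           "p": float(ft.pvalue), "df_num": 1,
                           "df_den": int(full.df_resid)})
    return AnovaResult(
        table=table, r_squared=float(full.rsquared),
        adj_r_squared=float(full.rsquared_adj), df_resid=int(full.df_resid),
        model_f=float(full.fvalue), model_f_p=float(full.f_pvalue),
        comparison_f=comparison_f, comparison_p=comparison_p,
        simple_slopes=pd.DataFrame(slope_rows),
    )


def _aliased_columns(exog: np.ndarray, names: list[str]) -> list[str]:
    _, R = np.linalg.qr(exog)
    diag = np.abs(np.diag(R))
    tol = diag.max() * 1e-10 if diag.size else 0.0
    return [names[i] for i in range(len(names)) if diag[i] <= tol]


def manova_coords(coords: np.ndarray, body_part, resolution) -> ManovaResult:
    """MANOVA on k x 3 coordinates with body part and resolution factors;
    Pillai's trace per term with its standard F approximation."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValidationError("coords must be k x 3")
    df = pd.DataFrame(coords, columns=["cx", "cy", "cz"])
    df["body_part"] = list(body_part)
    df["resolution"] = [str(r) for r in resolution]
    _check_levels(df["body_part"])
    _check_levels(df["resolution"])
    mv = MANOVA.from_formula("cx + cy + cz ~ C(body_part) + C(resolution)", data=df)
    res = mv.mv_test()
    rows = []
    for term in ["C(body_part)", "C(resolution)"]:
        stat = res.results[term]["stat"]
        row = stat.loc["Pillai's trace"]
        rows.append({"term": term.replace("C(", "").replace(")", ""),
                     "pillai": float(row["Value"]), "F": float(row["F Value"]),
                     "df_num": float(row["Num DF"]), "df_den": float(row["Den DF"]),
                     "p": float(row["Pr > F"])})
    return ManovaResult(pd.DataFrame(rows))


def anova_oneway_twoway(y, factors: dict[str, "list | np.ndarray"],
                        alpha: float = 0.05,
                        interaction: bool = True) -> AnovaResult:
    """Standard ANOVA with 1 or 2 factors (Type-II for two-way) and
    Bonferroni-Holm-corrected pairwise level comparisons per factor."""
    if not 1 <= len(factors) <= 2:
        raise ValidationError("provide 1 or 2 factors")
    df = pd.DataFrame({"y": np.asarray(y, dtype=float)})
    for name, vals in factors.items():
        df[name] = [str(v) for v in vals]
        if df[name].nunique() < 2:
            raise ValidationError(f"factor {name!r} has a single level")
    terms = [f"C({name})" for name in factors]
    rhs = " * ".join(terms) if (len(terms) == 2 and interaction) else " + ".join(terms)
    full = smf.ols(f"y ~ {rhs}", data=df).fit()
    table = anova_lm(full, typ=2)

    # Holm-adjusted pairwise contrasts within each factor (pooled-error F tests)
    rows = []
    for name in factors:
        levels = sorted(df[name].unique())
        pvals, meta = [], []
        for a, b in combinations(levels, 2):
            sub = df[df[name].isin([a, b])]
            ya, yb = sub.loc[sub[name] == a, "y"], sub.loc[sub[name] == b, "y"]
            num = (ya.mean() - yb.mean()) ** 2 / (1 / len(ya) + 1 / len(yb))
            mse = full.mse_resid
            F = float(num / mse)
            p = float(stats.f.sf(F, 1, full.df_resid))
            pvals.append(p)
            meta.append((name, a, b, F))
        if pvals:
            rej, p_adj, _, _ = multipletests(pvals, alpha=alpha, method="holm")
            for (nm, a, b, F), p, pa, rj in zip(meta, pvals, p_adj, rej):
                rows.append({"factor": nm, "level_a": a, "level_b": b, "F": F,
                             "p": p, "p_holm": pa, "significant": bool(rj)})
    posthoc = pd.DataFrame(rows)
    return AnovaResult(
        table=table, r_squared=float(full.rsquared),
        adj_r_squared=float(full.rsquared_adj), df_resid=int(full.df_resid),
        model_f=float(full.fvalue), model_f_p=float(full.f_pvalue),
        posthoc=posthoc,
    )
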