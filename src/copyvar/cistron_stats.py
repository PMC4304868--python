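"""Position-level and sample-level statistics over polymorphism calls.

Two position-level models ask whether cistron region (subunit vs spacer) and
secondary structure (paired vs unpaired) shape where polymorphisms fall:

* a two-factor logistic regression with interaction on the binary response
  "polymorphic (or highly polymorphic) in at least one individual", with
  paired spacer positions as the reference level and Wald 95% CIs on the
  odds ratios;
* a two-way ANOVA with type III sums of squares (sum-to-zero contrasts, the
  convention for unbalanced designs) on the square root of the number of
  polymorphic individuals per position.

Sample-level summaries (mean/min/max and extremal samples of the per-sample
polymorphic-site columns) are computed from a Table-1-style summary table; a
transcription of the published *Asclepias* table ships with the package.
"""

from __future__ import annotations

import warnings
from importlib import resources
from typing import Dict, Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = [
    "fit_site_logistic",
    "anova_sqrt_counts",
    "summarize_samples",
    "load_table1",
]


def _check_factors(df: pd.DataFrame) -> pd.DataFrame:
    d = pd.DataFrame(
        {
            "subunit": (df["region_class"] == "subunit").astype(int),
            "unpaired": (df["pairing"] == "unpaired").astype(int),
        }
    )
    for col in ("subunit", "unpaired"):
        if d[col].nunique() < 2:
            raise ValueError(f"factor {col!r} has a single level")
    cells = d.groupby(["subunit", "unpaired"]).size()
    if len(cells) < 4:
        warnings.warn("empty factor cell: some terms are not estimable")
    return d


def fit_site_logistic(data: pd.DataFrame, response: str = "any_poly") -> pd.DataFrame:
    """Two-factor logistic regression with interaction on a per-position
    binary response.

    ``data`` needs columns ``region_class`` (subunit/spacer), ``pairing``
    (paired/unpaired) and the binary response (``any_poly`` or ``any_high``).
    The reference level is a paired spacer position.  Returns a coefficient
    table with Wald statistics and exponentiated estimates:
    odds ratio and 95% CI = exp(estimate +/- 1.96 SE).
    """
    y = data[response].astype(int)
    if y.nunique() < 2:
        raise ValueError(f"response {response!r} is constant; nothing to fit")
    d = _check_factors(data)
    X = pd.DataFrame(
        {
            "Intercept": 1.0,
            "subunit": d["subunit"],
            "unpaired": d["unpaired"],
            "subunit:unpaired": d["subunit"] * d["unpaired"],
        }
    )
    try:
        fit = sm.Logit(y.to_numpy(), X).fit(disp=False)
    except PerfectSeparationError as exc:
        raise ValueError(
            "complete separation: maximum likelihood does not exist; "
            "consider exact logistic regression"
        ) from exc
    est = fit.params
    se = fit.bse
    table = pd.DataFrame(
        {
            "estimate": est,
            "std_error": se,
            "z": fit.tvalues,
            "p": fit.pvalues,
            "odds_ratio": np.exp(est),
            "ci_low": np.exp(est - 1.96 * se),
            "ci_high": np.exp(est + 1.96 * se),
        }
    )
    table.index = X.columns
    return table


def anova_sqrt_counts(data: pd.DataFrame, count_col: str = "n_poly_individuals") -> pd.DataFrame:
    """Two-way type III ANOVA on square-root-transformed per-position counts
    of polymorphic individuals.

    Factors are ``pairing`` and ``region_class``; type III sums of squares
    are computed under sum-to-zero contrasts, so every cell of the 2x2
    design must be populated.  Returns a table with terms Intercept, paired,
    subunit, paired:subunit and Residual (SS, df, F, P).
    """
    if data[count_col].min() < 0:
        raise ValueError("counts must be non-negative")
    d = pd.DataFrame(
        {
            "y": np.sqrt(data[count_col].astype(float)),
            "paired": np.where(data["pairing"] == "paired", "yes", "no"),
            "subunit": np.where(data["region_class"] == "subunit", "yes", "no"),
        }
    )
    cells = d.groupby(["paired", "subunit"]).size()
    if len(cells) < 4:
        raise ValueError("empty factor cell: type III sums of squares undefined")
    model = smf.ols("y ~ C(paired, Sum) * C(subunit, Sum)", data=d).fit()
    table = sm.stats.anova_lm(model, typ=3)
    rename = {
        "C(paired, Sum)": "paired",
        "C(subunit, Sum)": "subunit",
        "C(paired, Sum):C(subunit, Sum)": "paired:subunit",
    }
    table = table.rename(index=rename)
    table.columns = ["sum_sq", "df", "F", "p"]
    return table


_ROUND = {"poly_n": 0, "high_n": 0, "poly_pct": 2, "high_pct": 2}


def summarize_samples(table: pd.DataFrame, sample_col: str = "sample") -> pd.DataFrame:
    """Mean/min/max (with extremal samples) per numeric column of a
    Table-1-style summary table.

    ``mean_rounded`` rounds to the conventional printed precision: whole
    numbers for counts, two decimals for percentages.
    """
    if table.empty:
        raise ValueError("empty summary table")
    if sample_col not in table.columns:
        sample_col = table.columns[0]
    rows = {}
    for col in table.columns:
        if not pd.api.types.is_numeric_dtype(table[col]):
            continue
        s = table[col]
        digits = _ROUND.get(col, 2)
        mean = float(s.mean())
        rounded = round(mean, digits)
        rows[col] = {
            "mean": mean,
            "mean_rounded": int(rounded) if digits == 0 else rounded,
            "min": s.min(),
            "max": s.max(),
            "argmin": table.loc[s.idxmin(), sample_col],
            "argmax": table.loc[s.idxmax(), sample_col],
        }
    return pd.DataFrame(rows).T


def load_table1() -> pd.DataFrame:
    """The published per-sample polymorphic-site table for *Asclepias*
    (125 samples), shipped with the package.

    Columns: taxon, voucher, poly_n, poly_pct, high_n, high_pct, sra.
    """
    with resources.files("copyvar.data").joinpath("table1.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
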