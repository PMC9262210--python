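"""Estimator algebra for sibling indirect genetic effects.

Covariate-adjusted PGS associations are fitted by OLS per stratum; the
sibling IGE is then estimated either from the difference of the
non-singleton and singleton slopes (delta-method SE, assuming zero
covariance between the non-overlapping samples) scaled by two, or from the
number-of-siblings x PGS interaction coefficient, likewise doubled:

    2 * (beta_NS - beta_S) = k_S          (difference route)
    2 * beta_{N x PGS}     = k_S          (interaction route)

Attenuation expresses the difference as a percentage of a reference slope;
its confidence interval divides the difference CI by the fixed reference
point estimate, ignoring denominator uncertainty (anti-conservative, and
stated as such).  95% intervals use the normal 1.96 multiplier throughout,
appropriate at biobank-scale n.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "AssocEstimate",
    "DifferenceEstimate",
    "InteractionEstimate",
    "IGEEstimate",
    "fit_association",
    "estimate_difference",
    "fit_sibling_interaction",
    "scale_sibling_ige",
    "associations_by_sibship",
    "heterogeneity_z",
    "group_differences",
]

Z95 = 1.959963984540054  # normal 97.5% quantile

DEFAULT_COVARIATES = ["sex", "birth_year"] + [f"pc{i}" for i in range(1, 11)]


@dataclass(frozen=True)
class AssocEstimate:
    """Stratified OLS slope of phenotype on PGS (trait units per SD PGS)."""

    beta: float
    se: float
    n: int
    stratum: str
    trait: str
    covariates: tuple[str, ...] = ()

    @property
    def ci95(self) -> tuple[float, float]:
        return (self.beta - Z95 * self.se, self.beta + Z95 * self.se)

    @property
    def p(self) -> float:
        if self.se == 0:
            return 0.0 if self.beta != 0 else 1.0
        return 2.0 * stats.norm.sf(abs(self.beta / self.se))


@dataclass(frozen=True)
class DifferenceEstimate:
    """Delta-method difference of two independent slopes."""

    delta: float
    se_delta: float
    ci95: tuple[float, float]
    p: float
    attenuation_pct: float | None = None
    attenuation_ci95: tuple[float, float] | None = None
    label: str = ""


@dataclass(frozen=True)
class InteractionEstimate:
    """Coefficients from the number-of-siblings x PGS interaction model."""

    beta_pgs: float
    beta_N: float
    beta_NxPGS: float
    se_pgs: float
    se_N: float
    se_NxPGS: float
    p_NxPGS: float
    n: int
    beta_N2: float | None = None
    beta_N2xPGS: float | None = None
    se_N2: float | None = None
    se_N2xPGS: float | None = None
    p_N2xPGS: float | None = None

    @property
    def quadratic(self) -> bool:
        return self.beta_N2xPGS is not None


@dataclass(frozen=True)
class IGEEstimate:
    """Sibling IGE: input coefficient, SE and CI bounds all doubled."""

    k_S_hat: float
    se: float
    ci95: tuple[float, float]


def _check_collinearity(X: pd.DataFrame) -> None:
    """Reject rank-deficient designs, naming a dependent column."""
    arr = X.to_numpy(dtype=float)
    if np.linalg.matrix_rank(arr) < arr.shape[1]:
        rank = 0
        for j in range(arr.shape[1]):
            new_rank = np.linalg.matrix_rank(arr[:, : j + 1])
            if new_rank == rank:
                raise ValueError(f"collinear design: column {X.columns[j]!r}")
            rank = new_rank


def _ols(y: pd.Series, X: pd.DataFrame):
    _check_collinearity(X)
    return sm.OLS(np.asarray(y, float), X.astype(float)).fit()


def fit_association(
    cohort: pd.DataFrame,
    trait: str,
    stratum: str | None = None,
    covariates: list[str] | None = None,
    pgs_column: str | None = None,
    stratum_query=None,
) -> AssocEstimate:
    """OLS of phenotype on PGS plus covariates within one stratum.

    ``stratum`` picks rows by the boolean/label columns created by
    ``assign_strata``: "singleton", "non-singleton", "firstborn",
    "non-firstborn", a sibship category like "3" or "6+", or None for the
    full sample.  ``stratum_query`` overrides with an explicit boolean
    mask.  Complete-case analysis; classical homoskedastic SEs.
    """
    pgs_column = pgs_column or f"pgs_{trait}"
    covariates = list(covariates) if covariates is not None else []
    if stratum_query is not None:
        mask = stratum_query
    elif stratum is None:
        mask = pd.Series(True, index=cohort.index)
    elif stratum in ("singleton", "non-singleton"):
        mask = (cohort["singleton"] == (stratum == "singleton")).fillna(False)
    elif stratum in ("firstborn", "non-firstborn"):
        # birth-order strata are defined among individuals with siblings, so
        # they stay disjoint from (and comparable to) the singleton stratum
        mask = (
            (cohort["firstborn"] == (stratum == "firstborn"))
            & (cohort["singleton"] == False)  # noqa: E712
        ).fillna(False)
    else:
        mask = (cohort["sibship_category"] == stratum).fillna(False)

    cols = [trait, pgs_column] + covariates
    missing_cols = [c for c in cols if c not in cohort.columns]
    if missing_cols:
        raise ValueError(f"columns absent from cohort: {missing_cols}")
    data = cohort.loc[np.asarray(mask, bool), cols].dropna()
    if data.empty:
        raise ValueError(f"stratum {stratum!r} is empty after exclusions")
    X = sm.add_constant(data[[pgs_column] + covariates])
    res = _ols(data[trait], X)
    return AssocEstimate(
        beta=float(res.params[pgs_column]),
        se=float(res.bse[pgs_column]),
        n=int(res.nobs),
        stratum=stratum or "all",
        trait=trait,
        covariates=tuple(covariates),
    )


def estimate_difference(
    a: AssocEstimate | tuple[float, float],
    b: AssocEstimate | tuple[float, float],
    reference: str | None = "a",
    label: str = "",
) -> DifferenceEstimate:
    """a minus b with delta-method SE sqrt(se_a^2 + se_b^2).

    ``reference`` ("a" | "b" | None) selects the denominator for %
    attenuation = 100 * delta / beta_reference; the CI bounds are divided
    by the same fixed denominator.  A zero reference slope leaves
    attenuation undefined (None).
    """
    beta_a, se_a = (a.beta, a.se) if isinstance(a, AssocEstimate) else a
    beta_b, se_b = (b.beta, b.se) if isinstance(b, AssocEstimate) else b
    if (
        isinstance(a, AssocEstimate)
        and isinstance(b, AssocEstimate)
        and a.trait != b.trait
    ):
        raise ValueError(f"traits differ: {a.trait!r} vs {b.trait!r}")
    delta = beta_a - beta_b
    se_delta = float(np.sqrt(se_a**2 + se_b**2))
    ci = (delta - Z95 * se_delta, delta + Z95 * se_delta)
    p = 2.0 * stats.norm.sf(abs(delta / se_delta)) if se_delta > 0 else (
        1.0 if delta == 0 else 0.0
    )
    att = att_ci = None
    if reference is not None:
        ref = beta_a if reference == "a" else beta_b
        if ref == 0:
            att = att_ci = None  # undefined, flagged by None
        else:
            att = 100.0 * delta / ref
            att_ci = (100.0 * ci[0] / ref, 100.0 * ci[1] / ref)
    return DifferenceEstimate(
        delta=delta,
        se_delta=se_delta,
        ci95=ci,
        p=float(p),
        attenuation_pct=att,
        attenuation_ci95=att_ci,
        label=label,
    )


def fit_sibling_interaction(
    cohort: pd.DataFrame,
    trait: str,
    model: str = "linear",
    exclusion: str = "none",
    covariates: list[str] | None = None,
    pgs_column: str | None = None,
) -> InteractionEstimate:
    """OLS interaction model: trait ~ PGS + N + N*PGS (+ N^2 + N^2*PGS) + covariates.

    N is the self-reported number of siblings.  ``exclusion="6+_removed"``
    drops individuals with N >= 6 before fitting (the outlier rule).
    """
    if model not in ("linear", "quadratic"):
        raise ValueError(f"model must be 'linear' or 'quadratic', got {model!r}")
    pgs_column = pgs_column or f"pgs_{trait}"
    covariates = list(covariates) if covariates is not None else []
    cols = [trait, pgs_column, "n_siblings"] + covariates
    data = cohort[cols].dropna()
    if exclusion == "6+_removed":
        data = data[data["n_siblings"] < 6]
    elif exclusion != "none":
        raise ValueError(f"unknown exclusion {exclusion!r}")
    N = data["n_siblings"].astype(float)
    if model == "quadratic" and N.max() <= 1:
        raise ValueError("quadratic model is degenerate with max(N) <= 1")
    X = pd.DataFrame(
        {
            "pgs": data[pgs_column].astype(float),
            "N": N,
            "NxPGS": N * data[pgs_column],
        },
        index=data.index,
    )
    if model == "quadratic":
        X["N2"] = N**2
        X["N2xPGS"] = N**2 * data[pgs_column]
    for c in covariates:
        X[c] = data[c]
    X = sm.add_constant(X)
    res = _ols(data[trait], X)
    quad = model == "quadratic"
    return InteractionEstimate(
        beta_pgs=float(res.params["pgs"]),
        beta_N=float(res.params["N"]),
        beta_NxPGS=float(res.params["NxPGS"]),
        se_pgs=float(res.bse["pgs"]),
        se_N=float(res.bse["N"]),
        se_NxPGS=float(res.bse["NxPGS"]),
        p_NxPGS=float(res.pvalues["NxPGS"]),
        n=int(res.nobs),
        beta_N2=float(res.params["N2"]) if quad else None,
        beta_N2xPGS=float(res.params["N2xPGS"]) if quad else None,
        se_N2=float(res.bse["N2"]) if quad else None,
        se_N2xPGS=float(res.bse["N2xPGS"]) if quad else None,
        p_N2xPGS=float(res.pvalues["N2xPGS"]) if quad else None,
    )


def scale_sibling_ige(
    estimate: float | InteractionEstimate | DifferenceEstimate,
    se: float | None = None,
) -> IGEEstimate:
    """Double a per-half-sibling-share coefficient into a sibling IGE.

    The index individual shares half their PGS variance with a sibling, so
    the coefficient attributable to one sibling's score is half the IGE;
    point estimate, SE and CI bounds are all multiplied by exactly two.
    Accepts an interaction estimate (uses the N x PGS term), a difference
    estimate, or a raw (coefficient, se) pair.
    """
    if isinstance(estimate, InteractionEstimate):
        point, se = estimate.beta_NxPGS, estimate.se_NxPGS
    elif isinstance(estimate, DifferenceEstimate):
        point, se = estimate.delta, estimate.se_delta
    else:
        point = float(estimate)
        if se is None:
            raise ValueError("se is required with a raw coefficient")
    if not np.isfinite(se):
        raise ValueError("estimate must have a finite se")
    ci = (point - Z95 * se, point + Z95 * se)
    return IGEEstimate(k_S_hat=2.0 * point, se=2.0 * se, ci95=(2.0 * ci[0], 2.0 * ci[1]))


def associations_by_sibship(
    cohort: pd.DataFrame,
    trait: str,
    top_category: int = 6,
    covariates: list[str] | None = None,
    pgs_column: str | None = None,
) -> tuple[list[AssocEstimate | None], DifferenceEstimate | None]:
    """Per-sibship-size PGS associations plus the top-vs-rest difference.

    Returns one estimate per category "0".."<top-1>" and "<top>+" (None with
    n = 0 for an empty category), and the delta-method difference between
    the "<top>+" group and the pooled remainder (reference: the pooled
    remainder).
    """
    cats = [str(i) for i in range(top_category)] + [f"{top_category}+"]
    out: list[AssocEstimate | None] = []
    for cat in cats:
        try:
            out.append(
                fit_association(
                    cohort, trait, stratum=cat, covariates=covariates,
                    pgs_column=pgs_column,
                )
            )
        except ValueError:
            out.append(None)
    top = out[-1]
    diff = None
    if top is not None:
        rest_mask = (
            cohort["sibship_category"].notna()
            & (cohort["sibship_category"] != f"{top_category}+")
        )
        rest = fit_association(
            cohort, trait, stratum=f"<{top_category}", covariates=covariates,
            pgs_column=pgs_column, stratum_query=rest_mask,
        )
        diff = estimate_difference(
            top, rest, reference="b", label=f"{top_category}+ vs rest"
        )
    return out, diff


def heterogeneity_z(
    a: tuple[float, float] | AssocEstimate,
    b: tuple[float, float] | AssocEstimate,
) -> dict[str, float]:
    """Two-sample z-test for heterogeneity of independent estimates."""
    est_a, se_a = (a.beta, a.se) if isinstance(a, AssocEstimate) else a
    est_b, se_b = (b.beta, b.se) if isinstance(b, AssocEstimate) else b
    denom = np.sqrt(se_a**2 + se_b**2)
    if denom == 0:
        raise ValueError("both standard errors are zero")
    z = (est_a - est_b) / denom
    return {"z": float(z), "p": float(2.0 * stats.norm.sf(abs(z)))}


def group_differences(
    cohort: pd.DataFrame,
    variables: list[str],
    comparison: str = "singleton-vs-nonsingleton",
    adjustment: str = "none",
) -> pd.DataFrame:
    """Group-level differences (group B minus group A) for listed variables.

    ``adjustment="none"`` uses the two-means delta method (SE from the
    per-group sample variances); ``"sex+age"`` fits OLS of the variable on
    a group indicator plus sex and birth year.  Returns a table with
    columns {variable, difference, se, ci_low, ci_high, p}.
    """
    if comparison == "singleton-vs-nonsingleton":
        ga = (cohort["singleton"] == True).fillna(False)  # noqa: E712
        gb = (cohort["singleton"] == False).fillna(False)  # noqa: E712
    elif comparison == "singleton-vs-firstborn":
        ga = (cohort["singleton"] == True).fillna(False)  # noqa: E712
        gb = (cohort["firstborn"] == True).fillna(False)  # noqa: E712
    else:
        raise ValueError(f"unknown comparison {comparison!r}")
    rows = []
    for var in variables:
        if var not in cohort.columns:
            raise ValueError(f"unknown variable {var!r}")
        if adjustment == "none":
            xa = cohort.loc[np.asarray(ga, bool), var].dropna()
            xb = cohort.loc[np.asarray(gb, bool), var].dropna()
            diff = float(xb.mean() - xa.mean())
            se = float(np.sqrt(xa.var(ddof=1) / len(xa) + xb.var(ddof=1) / len(xb)))
        elif adjustment == "sex+age":
            sub = cohort.loc[np.asarray(ga | gb, bool), [var, "sex", "birth_year"]]
            sub = sub.assign(group=np.asarray(gb, bool)[np.asarray(ga | gb, bool)])
            sub = sub.dropna()
            X = sm.add_constant(
                pd.DataFrame(
                    {
                        "group": sub["group"].astype(float),
                        "sex": sub["sex"].astype(float),
                        "birth_year": sub["birth_year"].astype(float),
                    },
                    index=sub.index,
                )
            )
            res = _ols(sub[var], X)
            diff, se = float(res.params["group"]), float(res.bse["group"])
        else:
            raise ValueError(f"unknown adjustment {adjustment!r}")
        z = diff / se if se > 0 else np.inf * np.sign(diff) if diff else 0.0
        rows.append(
            {
                "variable": var,
                "difference": diff,
                "se": se,
                "ci_low": diff - Z95 * se,
                "ci_high": diff + Z95 * se,
                "p": float(2.0 * stats.norm.sf(abs(z))) if np.isfinite(z) else 0.0,
            }
        )
    return pd.DataFrame(rows)


def estimates_table(estimates: list, analysis: str) -> pd.DataFrame:
    """Serialize estimates into the common results-table schema."""
    rows = []
    for e in estimates:
        if e is None:
            continue
        if isinstance(e, AssocEstimate):
            lo, hi = e.ci95
            rows.append(
                dict(
                    analysis=analysis, trait=e.trait, stratum=e.stratum, n=e.n,
                    estimate=e.beta, se=e.se, ci_low=lo, ci_high=hi, p=e.p,
                )
            )
        elif isinstance(e, DifferenceEstimate):
            rows.append(
                dict(
                    analysis=analysis, trait="", stratum=e.label, n=np.nan,
                    estimate=e.delta, se=e.se_delta, ci_low=e.ci95[0],
                    ci_high=e.ci95[1], p=e.p,
                )
            )
        elif isinstance(e, IGEEstimate):
            rows.append(
                dict(
                    analysis=analysis, trait="", stratum="sibling_ige", n=np.nan,
                    estimate=e.k_S_hat, se=e.se, ci_low=e.ci95[0],
                    ci_high=e.ci95[1], p=np.nan,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "analysis", "trait", "stratum", "n", "estimate", "se",
            "ci_low", "ci_high", "p",
        ],
    )
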