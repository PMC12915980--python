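"""Log-log length–mass regression with vessel-type interaction.

The model is an ordinary least-squares fit of

    log(mass) = a_t * log(LOA) + b_t

with a separate slope ``a_t`` and intercept ``b_t`` for every vessel type
``t`` (a full type × log-LOA interaction).  Natural logarithms are used so
that the back-transform ``mass = exp(b_t) * LOA^a_t`` yields the power-law
coefficient form.  The slope is the elasticity of mass with respect to
length; a value near 3 corresponds to isometric scaling of a hull.

Two parameterisations of the same model are used internally:

* treatment coding (reference level + differences) for the headline overall
  F statistic and adjusted R², and for pairwise type contrasts by literal
  releveling;
* cell-means coding (``0 + C(type) + C(type):log_loa``) so each type's
  absolute ``(a, b)`` and standard errors are read off directly — these are
  identical to what a refit with that type as the reference level reports.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.stats.diagnostic import het_breuschpagan

from .errors import ContrastError, FittingError, LookupError_
from .vessel_model import VesselRecord, VesselType

__all__ = [
    "TypeCoefficients",
    "RegressionFit",
    "PowerLawEntry",
    "PowerLawCoefficients",
    "fit_loglog",
    "to_power",
    "predict_mass",
    "ContrastMatrix",
    "pairwise_type_contrasts",
    "pairwise_contrasts_covariance",
]


@dataclass(frozen=True)
class TypeCoefficients:
    """Absolute log-scale coefficients for one vessel type."""

    intercept: float
    intercept_se: float
    slope: float
    slope_se: float


@dataclass(frozen=True)
class PowerLawEntry:
    """``mass_kg = multiplier * LOA^exponent`` for one type."""

    multiplier: float
    exponent: float

    def rounded(self, decimals: int = 2) -> "PowerLawEntry":
        """Printed-precision form (display only; carry full precision)."""
        return PowerLawEntry(
            multiplier=round(self.multiplier, decimals),
            exponent=round(self.exponent, decimals),
        )


@dataclass(frozen=True)
class PowerLawCoefficients:
    """Per-type power-law coefficient set."""

    entries: Mapping[VesselType, PowerLawEntry]

    def __getitem__(self, vessel_type: VesselType) -> PowerLawEntry:
        try:
            return self.entries[VesselType(vessel_type)]
        except (KeyError, ValueError) as exc:
            raise LookupError_(f"no coefficients for type {vessel_type!r}") from exc

    def __contains__(self, vessel_type) -> bool:
        try:
            return VesselType(vessel_type) in self.entries
        except ValueError:
            return False


@dataclass
class RegressionFit:
    """Result of :func:`fit_loglog`.

    ``coefficients`` maps each type to its absolute (intercept, slope) on
    the natural-log kg/m scales with standard errors.  ``f_value`` and the
    degrees of freedom refer to the overall regression F test of the full
    interaction model; ``diagnostics`` holds residual normality and
    homoscedasticity summaries (informative, not gates).
    """

    coefficients: dict[VesselType, TypeCoefficients]
    df_model: int
    df_resid: int
    adj_r_squared: float
    f_value: float
    alpha: float = 0.05
    diagnostics: dict = field(default_factory=dict)
    _frame: Optional[pd.DataFrame] = field(default=None, repr=False)
    _cellmeans: object = field(default=None, repr=False)

    @property
    def types(self) -> list[VesselType]:
        return list(self.coefficients)

    def coefficient_table(self) -> pd.DataFrame:
        """Tidy per-type coefficient table (log scale + power form)."""
        power = to_power(self)
        rows = []
        for t, c in self.coefficients.items():
            e = power[t]
            rows.append(
                {
                    "vessel_type": t.value,
                    "intercept": c.intercept,
                    "intercept_se": c.intercept_se,
                    "slope": c.slope,
                    "slope_se": c.slope_se,
                    "multiplier": e.multiplier,
                    "exponent": e.exponent,
                }
            )
        return pd.DataFrame(rows)

    def to_json(self, path=None) -> str:
        """Serialize coefficients and fit statistics to JSON."""
        payload = {
            "model": "log(mass_kg) ~ log(loa_m) * vessel_type (natural log, OLS)",
            "adj_r_squared": self.adj_r_squared,
            "f_value": self.f_value,
            "df_model": self.df_model,
            "df_resid": self.df_resid,
            "alpha": self.alpha,
            "diagnostics": self.diagnostics,
            "coefficients": {
                t.value: vars(c).copy() for t, c in self.coefficients.items()
            },
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _prepare_frame(
    records: Iterable[VesselRecord], masses_kg: Optional[Sequence[float]]
) -> pd.DataFrame:
    records = list(records)
    if masses_kg is None:
        masses_kg = [r.displacement_kg for r in records]
    masses_kg = list(masses_kg)
    if len(masses_kg) != len(records):
        raise FittingError("masses_kg length does not match records")
    rows = []
    for r, m in zip(records, masses_kg):
        if m is None:
            raise FittingError(f"record {r.record_id} has no displacement")
        if not (m > 0 and r.loa_m > 0):
            raise ValueError(
                f"record {r.record_id}: mass and LOA must be > 0 (mass={m}, loa={r.loa_m})"
            )
        rows.append(
            {"vtype": r.vessel_type.value, "log_loa": np.log(r.loa_m), "log_mass": np.log(m)}
        )
    df = pd.DataFrame(rows)
    if df.empty:
        raise FittingError("no records to fit")
    for t, grp in df.groupby("vtype"):
        if len(grp) < 2 or grp["log_loa"].nunique() < 2:
            raise FittingError(
                f"type {t!r} needs >= 2 records with >= 2 distinct LOA values"
            )
    return df


_CM_INTERCEPT = re.compile(r"^C\(vtype\)\[(.+)\]$")
_CM_SLOPE = re.compile(r"^(?:C\(vtype\)\[(.+)\]:log_loa|log_loa:C\(vtype\)\[(.+)\])$")


def fit_loglog(
    records: Iterable[VesselRecord],
    masses_kg: Optional[Sequence[float]] = None,
    alpha: float = 0.05,
) -> RegressionFit:
    """Fit the log-log length–mass model with a full type interaction.

    Parameters
    ----------
    records : iterable of VesselRecord
        Each type must contribute at least two records with at least two
        distinct LOA values.
    masses_kg : sequence of float, optional
        Displacements to regress on; defaults to each record's
        ``displacement_kg`` (which must then be set, e.g. after running
        :func:`vesselmass.displacement.estimate_fleet`).
    alpha : float
        Significance level carried to contrast tests (default 0.05).
    """
    df = _prepare_frame(records, masses_kg)

    n_types = df["vtype"].nunique()
    if n_types > 1:
        treatment = smf.ols("log_mass ~ log_loa * C(vtype)", data=df).fit()
    else:
        treatment = smf.ols("log_mass ~ log_loa", data=df).fit()
    cellmeans = smf.ols("log_mass ~ 0 + C(vtype) + C(vtype):log_loa", data=df).fit()

    coefficients: dict[VesselType, TypeCoefficients] = {}
    intercepts, slopes = {}, {}
    for name in cellmeans.params.index:
        m = _CM_INTERCEPT.match(name)
        if m:
            intercepts[m.group(1)] = name
            continue
        m = _CM_SLOPE.match(name)
        if m:
            slopes[m.group(1) or m.group(2)] = name
    for label in sorted(df["vtype"].unique()):
        coefficients[VesselType(label)] = TypeCoefficients(
            intercept=float(cellmeans.params[intercepts[label]]),
            intercept_se=float(cellmeans.bse[intercepts[label]]),
            slope=float(cellmeans.params[slopes[label]]),
            slope_se=float(cellmeans.bse[slopes[label]]),
        )

    resid = np.asarray(treatment.resid)
    diag: dict = {"n": int(len(resid))}
    if 3 <= len(resid) <= 5000:
        sw = stats.shapiro(resid)
        diag["shapiro_w"] = float(sw.statistic)
        diag["shapiro_p"] = float(sw.pvalue)
    try:
        bp = het_breuschpagan(resid, treatment.model.exog)
        diag["breusch_pagan_lm"] = float(bp[0])
        diag["breusch_pagan_p"] = float(bp[1])
    except (ValueError, np.linalg.LinAlgError):
        pass
    sd = resid.std(ddof=1) if len(resid) > 1 else 0.0
    diag["n_abs_resid_gt_3sd"] = int((np.abs(resid) > 3 * sd).sum()) if sd > 0 else 0

    return RegressionFit(
        coefficients=coefficients,
        df_model=int(treatment.df_model),
        df_resid=int(treatment.df_resid),
        adj_r_squared=float(treatment.rsquared_adj),
        f_value=float(treatment.fvalue),
        alpha=alpha,
        diagnostics=diag,
        _frame=df,
        _cellmeans=cellmeans,
    )


def to_power(fit_or_pair) -> PowerLawCoefficients | PowerLawEntry:
    """Back-transform log-scale coefficients to power-law form.

    The intercept ``b`` becomes the multiplier ``exp(b)`` (mass in kg of a
    1 m vessel) and the slope ``a`` is carried as the exponent.  Accepts a
    :class:`RegressionFit` (returns a :class:`PowerLawCoefficients`) or a
    single ``(a, b)`` pair (returns one :class:`PowerLawEntry`).
    """
    if isinstance(fit_or_pair, RegressionFit):
        return PowerLawCoefficients(
            entries={
                t: PowerLawEntry(multiplier=float(np.exp(c.intercept)), exponent=c.slope)
                for t, c in fit_or_pair.coefficients.items()
            }
        )
    a, b = fit_or_pair
    return PowerLawEntry(multiplier=float(np.exp(b)), exponent=float(a))


def predict_mass(
    coeffs: PowerLawCoefficients, vessel_type: VesselType, loa_m
) -> float:
    """Predicted mass in kg: ``multiplier * LOA^exponent``."""
    loa = np.asarray(loa_m, dtype=float)
    if np.any(loa <= 0):
        raise ValueError("loa_m must be > 0")
    e = coeffs[vessel_type]
    out = e.multiplier * loa**e.exponent
    return float(out) if out.ndim == 0 else out


@dataclass
class ContrastMatrix:
    """All-pairs type-difference tests from releveled refits.

    ``p_intercept[i, j]`` / ``p_slope[i, j]`` hold the p-value for the
    difference of type j's intercept / slope from reference type i; the
    matrices are symmetric because the underlying model is the same
    regardless of reference level.  Significance flags use ``alpha``,
    Bonferroni-adjusted across unordered pairs only when requested.
    """

    p_intercept: pd.DataFrame
    p_slope: pd.DataFrame
    significant_intercept: pd.DataFrame
    significant_slope: pd.DataFrame
    alpha: float
    bonferroni: bool
    #: fitted log-mass values from each releveled refit, keyed by reference
    #: type — identical across references up to numerical noise.
    fitted_by_reference: dict[str, np.ndarray] = field(default_factory=dict)


def pairwise_type_contrasts(
    fit: RegressionFit,
    records: Iterable[VesselRecord] | None = None,
    masses_kg: Optional[Sequence[float]] = None,
    alpha: Optional[float] = None,
    bonferroni: bool = False,
) -> ContrastMatrix:
    """Compare every vessel type to every other by literal releveling.

    The interaction model is refitted once with each type as the reference
    level; the reported p-values for the other types' intercept and slope
    terms are the pairwise difference tests against that reference.  No
    multiple-testing correction is applied unless ``bonferroni=True``.
    """
    if fit._frame is not None and records is None:
        df = fit._frame
    else:
        if records is None:
            raise ContrastError("fit carries no data; pass records")
        df = _prepare_frame(records, masses_kg)
    labels = sorted(df["vtype"].unique())
    if len(labels) < 2:
        raise ContrastError("pairwise contrasts require >= 2 vessel types")
    alpha = fit.alpha if alpha is None else alpha

    p_int = pd.DataFrame(np.nan, index=labels, columns=labels)
    p_slo = pd.DataFrame(np.nan, index=labels, columns=labels)
    fitted: dict[str, np.ndarray] = {}
    int_re = re.compile(r"^C\(vtype, Treatment\(reference=['\"](?:.+)['\"]\)\)\[T\.(.+)\]$")
    slo_re = re.compile(
        r"^log_loa:C\(vtype, Treatment\(reference=['\"](?:.+)['\"]\)\)\[T\.(.+)\]$"
    )
    for ref in labels:
        formula = (
            f"log_mass ~ log_loa * C(vtype, Treatment(reference={ref!r}))"
        )
        res = smf.ols(formula, data=df).fit()
        fitted[ref] = np.asarray(res.fittedvalues)
        for name, p in res.pvalues.items():
            m = int_re.match(name)
            if m:
                p_int.loc[ref, m.group(1)] = p
                continue
            m = slo_re.match(name)
            if m:
                p_slo.loc[ref, m.group(1)] = p

    threshold = alpha
    if bonferroni:
        n_pairs = len(labels) * (len(labels) - 1) // 2
        threshold = alpha / n_pairs
    sig_int = p_int < threshold
    sig_slo = p_slo < threshold
    for lab in labels:  # self-contrast: zero difference, never significant
        sig_int.loc[lab, lab] = False
        sig_slo.loc[lab, lab] = False
    return ContrastMatrix(
        p_intercept=p_int,
        p_slope=p_slo,
        significant_intercept=sig_int,
        significant_slope=sig_slo,
        alpha=alpha,
        bonferroni=bonferroni,
        fitted_by_reference=fitted,
    )


def pairwise_contrasts_covariance(fit: RegressionFit) -> ContrastMatrix:
    """Same pairwise tests via linear contrasts on the cell-means fit.

    Independent route to the releveling computation: each pairwise
    difference is tested as a linear combination of the cell-means
    parameters using the fitted covariance matrix.  Used as a consistency
    cross-check for :func:`pairwise_type_contrasts`.
    """
    if fit._cellmeans is None:
        raise ContrastError("fit carries no model; refit with fit_loglog")
    res = fit._cellmeans
    labels = sorted(t.value for t in fit.coefficients)
    if len(labels) < 2:
        raise ContrastError("pairwise contrasts require >= 2 vessel types")
    names = list(res.params.index)
    int_name = {}
    slo_name = {}
    for name in names:
        m = _CM_INTERCEPT.match(name)
        if m:
            int_name[m.group(1)] = name
            continue
        m = _CM_SLOPE.match(name)
        if m:
            slo_name[m.group(1) or m.group(2)] = name
    p_int = pd.DataFrame(np.nan, index=labels, columns=labels)
    p_slo = pd.DataFrame(np.nan, index=labels, columns=labels)
    k = len(names)
    for i, a in enumerate(labels):
        for b in labels:
            if a == b:
                continue
            for table, mapping in ((p_int, int_name), (p_slo, slo_name)):
                L = np.zeros(k)
                L[names.index(mapping[b])] = 1.0
                L[names.index(mapping[a])] = -1.0
                table.loc[a, b] = float(res.t_test(L).pvalue)
    sig_int = p_int < fit.alpha
    sig_slo = p_slo < fit.alpha
    for lab in labels:
        sig_int.loc[lab, lab] = False
        sig_slo.loc[lab, lab] = False
    return ContrastMatrix(
        p_intercept=p_int,
        p_slope=p_slo,
        significant_intercept=sig_int,
        significant_slope=sig_slo,
        alpha=fit.alpha,
        bonferroni=False,
    )
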