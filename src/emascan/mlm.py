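"""Multilevel (linear mixed) models for EMA outcomes with person-mean centering.

The 2-level model treats momentary observations (level 1) as nested within
subjects (level 2): the outcome Y_tj is regressed on within-person predictors
centered at each subject's own mean, with a between-subject predictor Z_j and
cross-level interactions optional, and with the intercept and any subset of
slopes allowed to vary randomly across subjects.  The 3-level variant adds a
day level between observations and subjects (random day intercepts/slopes).
Predictor centering still uses the subject mean by default even in the 3-level
model; day-mean centering is available as an option.

Estimation is restricted maximum likelihood (REML) by default via a Gaussian
linear mixed model; fixed-effect inference uses Wald z statistics, with a
between-within degrees-of-freedom t option.

The canonical entry points are :class:`MultilevelModel` (a model object whose
``fit`` returns :class:`MultilevelResults`) and the convenience functions
:func:`fit_mlm` and :func:`fit_scan_model` (the univariate random-intercept
model fitted in every cell of the window scan).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .exceptions import (
    InsufficientDataError,
    SingularDesignError,
    ValidationError,
)

__all__ = [
    "CenteredPredictor",
    "ModelSpec",
    "MultilevelModel",
    "MultilevelResults",
    "person_center",
    "fit_mlm",
    "fit_scan_model",
]


@dataclass
class CenteredPredictor:
    """A predictor split into person means and within-person deviations.

    Deviations sum to zero within every subject (over non-missing rows);
    rows that are missing in the raw predictor stay missing in the deviation.
    """

    name: str
    raw: pd.Series
    person_mean: pd.Series
    deviation: pd.Series


def person_center(
    data: pd.DataFrame, predictor: str, subject_col: str = "subject"
) -> CenteredPredictor:
    """Center ``predictor`` at each subject's own mean of its non-missing values."""
    if predictor not in data.columns:
        raise ValidationError(f"predictor {predictor!r} not in data")
    raw = data[predictor].astype(float)
    mean = raw.groupby(data[subject_col]).transform("mean")
    return CenteredPredictor(
        name=predictor, raw=raw, person_mean=mean, deviation=raw - mean
    )


def _day_center(data: pd.DataFrame, predictor: str, subject_col: str, day_col: str):
    raw = data[predictor].astype(float)
    mean = raw.groupby([data[subject_col], data[day_col]]).transform("mean")
    return CenteredPredictor(
        name=predictor, raw=raw, person_mean=mean, deviation=raw - mean
    )


@dataclass
class ModelSpec:
    """Declarative model description (loadable from YAML/JSON config)."""

    outcome: str
    within: Sequence[str] = field(default_factory=list)
    between: Optional[str] = None
    cross_level: bool = False
    random_intercept: bool = True
    random_slopes: Sequence[str] = field(default_factory=list)
    levels: int = 2
    day_random_intercept: bool = True
    day_random_slopes: Sequence[str] = field(default_factory=list)
    centering: str = "person"  # or "day"
    reml: bool = True
    subject_col: str = "subject"
    day_col: str = "day"

    def __post_init__(self) -> None:
        if self.levels not in (2, 3):
            raise ValidationError("levels must be 2 or 3")
        for s in list(self.random_slopes) + list(self.day_random_slopes):
            if s not in self.within:
                raise ValidationError(
                    f"random slope {s!r} has no corresponding within predictor"
                )
        if self.centering not in ("person", "day"):
            raise ValidationError("centering must be 'person' or 'day'")

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ModelSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


class MultilevelResults:
    """Estimates, uncertainties and diagnostics of a fitted multilevel model."""

    def __init__(
        self,
        params: pd.Series,
        bse: pd.Series,
        vcomp: dict[str, float],
        llf: float,
        converged: bool,
        n_obs: int,
        n_subjects: int,
        n_days: Optional[int],
        method: str,
        model: "MultilevelModel",
    ):
        self.params = params
        self.bse = bse
        self.vcomp = vcomp
        self.llf = llf
        self.converged = converged
        self.n_obs = n_obs
        self.n_subjects = n_subjects
        self.n_days = n_days
        self.method = method
        self.model = model

    @property
    def zvalues(self) -> pd.Series:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        """Two-sided Wald z p-values for the fixed effects."""
        return pd.Series(
            2 * sps.norm.sf(np.abs(self.zvalues.to_numpy())), index=self.params.index
        )

    def pvalues_t(self, df: Optional[float] = None) -> pd.Series:
        """Two-sided t p-values with between-within degrees of freedom.

        Default df = n_subjects − (number of fixed effects).
        """
        if df is None:
            df = max(self.n_subjects - len(self.params), 1)
        return pd.Series(
            2 * sps.t.sf(np.abs(self.zvalues.to_numpy()), df), index=self.params.index
        )

    # convenience accessors for the univariate scan model -------------------
    @property
    def slope_term(self) -> str:
        within = self.model.within
        if not within:
            raise ValidationError("model has no within predictor")
        return within[0]

    @property
    def slope(self) -> float:
        return float(self.params[self.slope_term])

    @property
    def slope_se(self) -> float:
        return float(self.bse[self.slope_term])

    @property
    def slope_pvalue(self) -> float:
        return float(self.pvalues[self.slope_term])

    def fe_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.params.index,
                "estimate": self.params.to_numpy(),
                "se": self.bse.to_numpy(),
                "z": self.zvalues.to_numpy(),
                "p": self.pvalues.to_numpy(),
            }
        )

    def vc_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"component": list(self.vcomp), "variance": list(self.vcomp.values())}
        )

    def to_csv(self, prefix: str) -> None:
        """Write ``<prefix>.fixed.csv`` and ``<prefix>.variance.csv``."""
        self.fe_table().to_csv(f"{prefix}.fixed.csv", index=False)
        self.vc_table().to_csv(f"{prefix}.variance.csv", index=False)

    def summary(self) -> str:
        lines = [
            f"Multilevel linear model ({self.model.levels} levels, {self.method})",
            f"N obs: {self.n_obs}   N subjects: {self.n_subjects}"
            + (f"   N subject-days: {self.n_days}" if self.n_days else ""),
            f"Log-likelihood: {self.llf:.4f}   Converged: {self.converged}",
            "",
            "Fixed effects (Wald z):",
            self.fe_table().to_string(index=False, float_format=lambda v: f"{v:.6g}"),
            "",
            "Variance components:",
            self.vc_table().to_string(index=False, float_format=lambda v: f"{v:.6g}"),
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        state = "converged" if self.converged else "NOT converged"
        return f"<MultilevelResults: {len(self.params)} fixed effects, {state}>"


class MultilevelModel:
    """Linear mixed model over EMA data, built from a long-format DataFrame.

    Parameters
    ----------
    data : DataFrame with one row per EMA observation, containing the outcome,
        raw within-person predictors, optional between-subject predictor and
        the subject (and, for 3-level models, day) identifier columns.
    Remaining arguments mirror :class:`ModelSpec`.

    Rows with a missing outcome or predictor are listwise deleted before
    centering, so within-subject deviations sum to zero in every fit.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        outcome: str,
        within: Sequence[str] = (),
        between: Optional[str] = None,
        cross_level: bool = False,
        random_intercept: bool = True,
        random_slopes: Sequence[str] = (),
        levels: int = 2,
        day_random_intercept: bool = True,
        day_random_slopes: Sequence[str] = (),
        centering: str = "person",
        subject_col: str = "subject",
        day_col: str = "day",
    ):
        self.outcome = outcome
        self.within = list(within)
        self.between = between
        self.cross_level = cross_level
        self.random_intercept = random_intercept
        self.random_slopes = list(random_slopes)
        self.levels = levels
        self.day_random_intercept = day_random_intercept
        self.day_random_slopes = list(day_random_slopes)
        self.centering = centering
        self.subject_col = subject_col
        self.day_col = day_col

        needed = [outcome, *self.within] + ([between] if between else [])
        for c in needed + [subject_col] + ([day_col] if levels == 3 else []):
            if c not in data.columns:
                raise ValidationError(f"column {c!r} not in data")
        if levels == 3 and data[day_col].isna().any():
            raise ValidationError("3-level model requires day_index on all observations")

        work = data.dropna(subset=needed).copy()
        if work.empty:
            raise ValidationError("no complete observations (all-missing outcome/predictors)")
        if work[subject_col].nunique() < 2:
            raise InsufficientDataError("need at least 2 subjects")

        # center within predictors on the post-deletion rows
        self.centered: dict[str, CenteredPredictor] = {}
        for p in self.within:
            if centering == "day":
                cp = _day_center(work, p, subject_col, day_col)
            else:
                cp = person_center(work, p, subject_col)
            self.centered[p] = cp
            dev = cp.deviation
            if np.allclose(dev.to_numpy(), 0.0):
                raise SingularDesignError(
                    f"predictor {p!r} constant within every subject"
                )
            work[f"_dev_{p}"] = dev

        n_re = int(random_intercept) + len(self.random_slopes)
        if work[subject_col].nunique() <= n_re:
            raise SingularDesignError(
                "fewer subjects than subject-level random-effect dimensions"
            )

        self._data = work
        self._term_map = self._build_terms()

    # ------------------------------------------------------------------
    def _build_terms(self) -> dict[str, str]:
        """Map internal design names to user-facing term labels."""
        terms = {"Intercept": "Intercept"}
        rhs = ["1"]
        if self.between:
            self._data["_zvar"] = self._data[self.between].astype(float)
            rhs.append("_zvar")
            terms["_zvar"] = self.between
        for p in self.within:
            rhs.append(f"_dev_{p}")
            terms[f"_dev_{p}"] = p
        if self.cross_level:
            if not self.between:
                raise ValidationError("cross_level requires a between predictor")
            for p in self.within:
                rhs.append(f"_zvar:_dev_{p}")
                terms[f"_zvar:_dev_{p}"] = f"{self.between}:{p}"
        self._formula = "_y ~ " + " + ".join(rhs)
        self._data["_y"] = self._data[self.outcome].astype(float)
        return terms

    def _re_formulas(self):
        re_parts = ["1"] if self.random_intercept else ["0"]
        re_parts += [f"_dev_{p}" for p in self.random_slopes]
        re_formula = " + ".join(re_parts)
        vc_formula = {}
        if self.levels == 3:
            if self.day_random_intercept:
                vc_formula["day"] = f"0 + C({self.day_col})"
            for p in self.day_random_slopes:
                vc_formula[f"day_{p}"] = f"0 + C({self.day_col}):_dev_{p}"
        return re_formula, vc_formula

    def fit(self, reml: bool = True, maxiter: int = 200) -> MultilevelResults:
        """Fit by (RE)ML; non-convergence is flagged, never raised."""
        re_formula, vc_formula = self._re_formulas()
        model = smf.mixedlm(
            self._formula,
            self._data,
            groups=self._data[self.subject_col],
            re_formula=re_formula,
            vc_formula=vc_formula or None,
        )
        labels = [self._term_map.get(n, n) for n in model.exog_names]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                warnings.simplefilter("ignore", RuntimeWarning)
                warnings.simplefilter("ignore", UserWarning)
                # retry ladder: default lbfgs, then gradient-free optimizers
                res = None
                for method in (None, "powell", "nm"):
                    kw = {"method": method} if method else {}
                    try:
                        candidate = model.fit(reml=reml, maxiter=maxiter, **kw)
                    except (np.linalg.LinAlgError, ValueError, ZeroDivisionError):
                        continue
                    res = candidate
                    if getattr(res, "converged", False):
                        break
                if res is None:
                    raise np.linalg.LinAlgError("all optimizers failed")
                fe = np.asarray(res.fe_params)
                fe_se = np.asarray(res.bse_fe)  # lazy; may warn on a singular fit
                llf = float(res.llf)
        except (np.linalg.LinAlgError, ValueError, ZeroDivisionError):
            nan = pd.Series(np.nan, index=labels)
            return MultilevelResults(
                params=nan, bse=nan.copy(), vcomp={}, llf=np.nan, converged=False,
                n_obs=len(self._data),
                n_subjects=self._data[self.subject_col].nunique(),
                n_days=self._n_days(), method="REML" if reml else "ML", model=self,
            )

        params = pd.Series(fe, index=labels)
        bse = pd.Series(fe_se, index=labels)
        vcomp = {"var(residual)": float(max(res.scale, 0.0))}
        cov_re = np.atleast_2d(np.asarray(res.cov_re))
        re_names = list(res.cov_re.index) if hasattr(res.cov_re, "index") else []
        for i, nm in enumerate(re_names):
            label = {"Group": "intercept"}.get(nm, self._term_map.get(nm, nm))
            vcomp[f"var({label}|subject)"] = float(max(cov_re[i, i], 0.0))
            for k in range(i + 1, len(re_names)):
                other = {"Group": "intercept"}.get(re_names[k],
                                                   self._term_map.get(re_names[k], re_names[k]))
                vcomp[f"cov({label},{other}|subject)"] = float(cov_re[i, k])
        if vc_formula:
            vc_names = list(getattr(model.exog_vc, "names", vc_formula))
            for nm, v in zip(vc_names, np.atleast_1d(np.asarray(res.vcomp))):
                vcomp[f"var({nm})"] = float(max(v, 0.0))

        converged = bool(getattr(res, "converged", True)) and bool(
            np.isfinite(params.to_numpy()).all()
        )
        return MultilevelResults(
            params=params, bse=bse, vcomp=vcomp, llf=llf,
            converged=converged, n_obs=len(self._data),
            n_subjects=self._data[self.subject_col].nunique(),
            n_days=self._n_days(), method="REML" if reml else "ML", model=self,
        )

    def _n_days(self) -> Optional[int]:
        if self.levels != 3:
            return None
        return int(
            self._data.groupby(self.subject_col)[self.day_col].nunique().sum()
        )

    @classmethod
    def from_spec(cls, data: pd.DataFrame, spec: ModelSpec) -> "MultilevelModel":
        return cls(
            data,
            outcome=spec.outcome,
            within=spec.within,
            between=spec.between,
            cross_level=spec.cross_level,
            random_intercept=spec.random_intercept,
            random_slopes=spec.random_slopes,
            levels=spec.levels,
            day_random_intercept=spec.day_random_intercept,
            day_random_slopes=spec.day_random_slopes,
            centering=spec.centering,
            subject_col=spec.subject_col,
            day_col=spec.day_col,
        )


def fit_mlm(data: pd.DataFrame, spec: ModelSpec) -> MultilevelResults:
    """Build and fit the multilevel model described by ``spec``."""
    return MultilevelModel.from_spec(data, spec).fit(reml=spec.reml)


def fit_scan_model(
    data: pd.DataFrame,
    outcome: str = "affect",
    predictor: str = "x",
    subject_col: str = "subject",
    reml: bool = True,
) -> MultilevelResults:
    """Univariate random-intercept model fitted in each scan cell.

    Y_tj = γ00 + γ10 (X_tj − X̄_j) + ζ0j + ε_tj, with the predictor
    person-centered over the rows entering the fit.  Rows with a missing
    predictor or outcome are dropped first.
    """
    usable = data.dropna(subset=[outcome, predictor])
    per_subject = usable.groupby(subject_col).size()
    if (per_subject >= 2).sum() < 2:
        raise InsufficientDataError(
            "need at least 2 subjects with at least 2 usable prompts"
        )
    model = MultilevelModel(
        usable,
        outcome=outcome,
        within=[predictor],
        random_intercept=True,
        subject_col=subject_col,
    )
    return model.fit(reml=reml)
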