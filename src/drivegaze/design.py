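"""Design coding and model fitting for the cohort analyses.

The predictor codings follow the study's conventions exactly:

* eccentricity: 0 = close (10 m from the road), 1 = far (30 m);
* course: 0 = "field" (easy), 1 = "ancient" (difficult);
* video-game experience: two dummies against the minimum-experience
  baseline — ``vg_moderate`` and ``vg_extensive`` (mutually exclusive);
* gender: 0 = male, 1 = female; malaise: 0 = no, 1 = yes;
* age: exactly mean-centred (``age_c``).

Two-way interaction columns are products of the coded main effects (the
product of the two mutually exclusive video-game dummies is identically
zero and therefore never formed).

Model fitting is delegated to statsmodels: a random-intercept linear mixed
model (REML) with subject as the grouping factor, and a binomial logistic
regression for incidence outcomes.  For mixed models a fixed effect is
flagged significant when |t| > 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .exceptions import CodingError, InsufficientDataError, RankDeficiencyError

__all__ = ["CodedDesign", "FitResult", "code_design", "fit_lmm", "fit_logistic",
           "DEFAULT_FIXED_EFFECTS", "T_SIGNIFICANCE"]

#: |t| beyond which a mixed-model fixed effect is flagged significant.
T_SIGNIFICANCE = 2.0

DEFAULT_FIXED_EFFECTS = ("age_c", "eccentricity", "course", "vg_moderate", "vg_extensive")

_ECC_CODES = {"close": 0, "far": 1}
_COURSE_CODES = {"field": 0, "ancient": 1}
_VG_CODES = {"minimum": (0, 0), "moderate": (1, 0), "extensive": (0, 1)}
_GENDER_CODES = {"male": 0, "female": 1}
_YESNO_CODES = {"no": 0, "yes": 1}


@dataclass
class CodedDesign:
    """A response vector plus coded predictors and the grouping factor."""

    data: pd.DataFrame
    response: str
    fixed_effects: list[str]
    interactions: list[str] = field(default_factory=list)

    @property
    def terms(self) -> list[str]:
        return list(self.fixed_effects) + list(self.interactions)

    def exog(self) -> pd.DataFrame:
        X = self.data[self.terms].astype(float)
        X.insert(0, "intercept", 1.0)
        return X


@dataclass
class FitResult:
    """Estimates, standard errors and test statistics of one model fit."""

    terms: list[str]
    estimates: np.ndarray
    se: np.ndarray
    stat: np.ndarray          # t for mixed models, z for logistic
    significant: np.ndarray   # |t| > 2 (LMM) or p < 0.05 (logistic)
    subject_sd: float | None = None
    residual_sd: float | None = None
    model: str = "lmm"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.terms,
                "estimate": self.estimates,
                "se": self.se,
                "stat": self.stat,
                "significant": self.significant,
            }
        )

    def __getitem__(self, term: str) -> dict:
        k = self.terms.index(term)
        return {
            "estimate": float(self.estimates[k]),
            "se": float(self.se[k]),
            "stat": float(self.stat[k]),
            "significant": bool(self.significant[k]),
        }


def _code_column(series: pd.Series, mapping: dict, what: str) -> pd.Series:
    if pd.api.types.is_numeric_dtype(series):
        vals = {float(v) for v in pd.unique(series.dropna())}
        if not vals <= {0.0, 1.0}:
            raise CodingError(f"{what}: numeric values {sorted(vals)} are not valid 0/1 codes")
        return series.astype(float)
    unknown = set(series.dropna()) - set(mapping)
    if unknown:
        raise CodingError(f"{what}: unknown label(s) {sorted(unknown)}")
    return series.map(mapping).astype(float)


def code_design(
    table: pd.DataFrame,
    response: str,
    fixed_effects=DEFAULT_FIXED_EFFECTS,
    interactions: bool = True,
) -> CodedDesign:
    """Code a raw cohort table into the study's regression design.

    ``table`` must contain a ``subject`` column, the raw predictor columns
    (``age`` or pre-centred ``age_c``, ``eccentricity``, ``course``,
    ``vg_group`` or pre-coded dummies, optionally ``gender``, ``malaise``,
    ``driving_experience``) and the response column.  Coding is idempotent:
    an already coded table passes through unchanged.
    """
    if response not in table.columns:
        raise CodingError(f"response column {response!r} not in table")
    if "subject" not in table.columns:
        raise CodingError("table must contain a 'subject' column")
    resp = table[response]
    if not pd.api.types.is_numeric_dtype(resp):
        known = {"eccentricity": _ECC_CODES, "course": _COURSE_CODES,
                 "gender": _GENDER_CODES, "malaise": _YESNO_CODES}
        if response in known:
            resp = _code_column(resp, known[response], response)
        else:
            raise CodingError(f"response column {response!r} is not numeric")
    df = pd.DataFrame({"subject": table["subject"], response: resp.astype(float)})

    if "age_c" in table.columns:
        df["age_c"] = table["age_c"].astype(float)
    elif "age" in table.columns:
        age = table["age"].astype(float)
        df["age_c"] = age - age.mean()
    if "eccentricity" in table.columns:
        df["eccentricity"] = _code_column(table["eccentricity"], _ECC_CODES, "eccentricity")
    if "course" in table.columns:
        df["course"] = _code_column(table["course"], _COURSE_CODES, "course")
    if "vg_group" in table.columns:
        vg = table["vg_group"]
        unknown = set(vg.dropna()) - set(_VG_CODES)
        if unknown:
            raise CodingError(f"vg_group: unknown label(s) {sorted(unknown)}")
        df["vg_moderate"] = vg.map({k: v[0] for k, v in _VG_CODES.items()}).astype(float)
        df["vg_extensive"] = vg.map({k: v[1] for k, v in _VG_CODES.items()}).astype(float)
    else:
        for col in ("vg_moderate", "vg_extensive"):
            if col in table.columns:
                df[col] = table[col].astype(float)
    if "gender" in table.columns:
        df["gender"] = _code_column(table["gender"], _GENDER_CODES, "gender")
    if "malaise" in table.columns:
        df["malaise"] = _code_column(table["malaise"], _YESNO_CODES, "malaise")
    if "driving_experience" in table.columns:
        df["driving_experience"] = table["driving_experience"].astype(float)

    fixed = [f for f in fixed_effects]
    missing = [f for f in fixed if f not in df.columns]
    if missing:
        raise CodingError(f"fixed effect(s) not derivable from table: {missing}")

    inter_names: list[str] = []
    if interactions:
        for i, a in enumerate(fixed):
            for b in fixed[i + 1 :]:
                if {a, b} == {"vg_moderate", "vg_extensive"}:
                    continue  # mutually exclusive dummies: product is always 0
                name = f"{a}:{b}"
                df[name] = df[a] * df[b]
                inter_names.append(name)
    return CodedDesign(data=df, response=response, fixed_effects=fixed, interactions=inter_names)


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        const = [c for c in X.columns if c != "intercept" and X[c].nunique() <= 1]
        detail = f" (constant column(s): {const})" if const else ""
        raise RankDeficiencyError(
            f"design matrix is rank deficient: rank {rank} < {arr.shape[1]} columns{detail}"
        )


def fit_lmm(design: CodedDesign) -> FitResult:
    """Random-intercept linear mixed model (REML) with subject grouping."""
    groups = design.data["subject"]
    if groups.nunique() < 2:
        raise InsufficientDataError("mixed model needs at least 2 subjects")
    X = design.exog()
    _check_rank(X)
    endog = design.data[design.response].to_numpy(dtype=float)
    model = sm.MixedLM(endog, X, groups=groups)
    result = model.fit(reml=True)
    names = list(X.columns)
    est = np.asarray(result.fe_params)
    se = np.asarray(result.bse_fe)
    tvals = est / se
    return FitResult(
        terms=names,
        estimates=est,
        se=se,
        stat=tvals,
        significant=np.abs(tvals) > T_SIGNIFICANCE,
        subject_sd=float(np.sqrt(result.cov_re.iloc[0, 0])),
        residual_sd=float(np.sqrt(result.scale)),
        model="lmm",
    )


def fit_logistic(design: CodedDesign) -> FitResult:
    """Binomial logistic regression on a 0/1 response."""
    X = design.exog()
    _check_rank(X)
    endog = design.data[design.response].to_numpy(dtype=float)
    model = sm.GLM(endog, X, family=sm.families.Binomial())
    result = model.fit()
    est = np.asarray(result.params)
    se = np.asarray(result.bse)
    zvals = est / se
    return FitResult(
        terms=list(X.columns),
        estimates=est,
        se=se,
        stat=zvals,
        significant=np.asarray(result.pvalues) < 0.05,
        subject_sd=None,
        residual_sd=None,
        model="logistic",
    )
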