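"""Association models between the network impact score and PSCI.

Three model families, all logistic on the odds-ratio scale:

* Repeated-measures GEE — a marginal binary logistic model fit with
  generalized estimating equations, autoregressive AR(1) working
  correlation indexed by visit order, and robust (sandwich) standard
  errors, using every assessment of every patient (1 to 6 per patient).
* Interval-stratified ordinary logistic — one fit per post-stroke time
  stratum, using the earliest assessment per patient within the stratum.
* Transition logistic — recovery modelled within baseline-PSCI patients,
  decline within baseline-no-PSCI patients.

Covariate conventions (the adjustment set used throughout): log network
impact score per 1-point increase, age per decade, male sex vs female
reference, three education indicators vs a less-than-high-school reference,
clinical history of stroke, infarct volume per 10 mL, and study-site
fixed-effect indicators with the largest site as reference. Rows with
missing model covariates are dropped listwise with a mandatory count report.
Confidence intervals are Wald, 95%, on the exponentiated coefficient scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from . import cognition
from .errors import (
    ConvergenceError,
    DegenerateOutcomeError,
    EmptySubsetError,
    SeparationError,
    ValidationError,
)

__all__ = [
    "ModelSpec",
    "ModelResult",
    "Design",
    "covariate_design",
    "fit_gee_logistic",
    "fit_stratified_logistic",
    "fit_transition_logistic",
]

EDUCATION_LEVELS = [
    "less_than_high_school",  # reference
    "high_school",
    "technical_college",
    "university_or_higher",
]

TERM_LABELS = {
    "log_score": "Network impact score (per 1-point)",
    "age_decades": "Age (per decade)",
    "male": "Male sex (vs female)",
    "edu_high_school": "Education: high school (vs less than high school)",
    "edu_technical_college": "Education: technical/college (vs less than high school)",
    "edu_university_or_higher": "Education: university or higher (vs less than high school)",
    "prior_stroke": "Clinical history of stroke",
    "volume_per_10ml": "Total infarct volume (per 10 mL)",
}


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: outcome, adjustment, correlation structure, filters.

    ``correlation`` applies only to the GEE fit ("ar1" or "independence");
    ``interval`` restricts stratified fits to one time stratum;
    ``exclude_sites`` implements site-based sensitivity analyses (e.g.
    dropping the cohort on which the score was originally developed);
    ``univariable`` keeps only the score term.
    """

    outcome: str = "psci"  # psci | recovery | decline
    univariable: bool = False
    correlation: str = "ar1"  # ar1 | independence
    interval: str | None = None
    exclude_sites: tuple = ()
    adjust_site: bool = True
    score_col: str = "log_score"


@dataclass
class Design:
    """Materialised design matrix plus bookkeeping of exclusions."""

    y: np.ndarray = field(repr=False)
    X: pd.DataFrame = field(repr=False)
    groups: np.ndarray = field(repr=False)
    time: np.ndarray = field(repr=False)
    n_subjects: int = 0
    n_obs: int = 0
    n_dropped_missing: int = 0
    dropped_patient_ids: tuple = ()
    site_reference: object = None


@dataclass
class ModelResult:
    """Fitted association model in odds-ratio form.

    ``terms`` has one row per coefficient (intercept excluded): odds ratio,
    Wald 95% CI, p-value. ``working_corr`` is the estimated working
    correlation parameter (GEE only).
    """

    model: str
    outcome: str
    terms: pd.DataFrame = field(repr=False)
    n_subjects: int = 0
    n_obs: int = 0
    converged: bool = True
    working_corr: float | None = None
    n_dropped_missing: int = 0

    def term(self, name: str) -> pd.Series:
        return self.terms.set_index("term").loc[name]

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "outcome": self.outcome,
            "n_subjects": int(self.n_subjects),
            "n_obs": int(self.n_obs),
            "converged": bool(self.converged),
            "working_corr": None if self.working_corr is None else float(self.working_corr),
            "n_dropped_missing": int(self.n_dropped_missing),
            "terms": self.terms.to_dict("records"),
        }

    def format_table(self) -> str:
        """Human-readable OR table, one labelled row per term."""
        lines = [
            f"Outcome: {self.outcome}  model: {self.model}  "
            f"n={self.n_subjects} subjects / {self.n_obs} observations",
            f"{'term':55s} {'OR':>6s} {'95% CI':>16s} {'p':>8s}",
        ]
        for _, row in self.terms.iterrows():
            label = TERM_LABELS.get(row["term"], row["term"])
            ci = f"({row['ci_low']:.2f}-{row['ci_high']:.2f})"
            p = "<0.001" if row["p"] < 0.001 else f"{row['p']:.3f}"
            lines.append(f"{label:55s} {row['or']:6.2f} {ci:>16s} {p:>8s}")
        if self.n_dropped_missing:
            lines.append(
                f"({self.n_dropped_missing} observations excluded for missing covariates)"
            )
        return "\n".join(lines)


_COVARIATE_COLS = ["age_years", "sex", "education_category", "prior_stroke", "infarct_volume_ml"]


def covariate_design(rows: pd.DataFrame, spec: ModelSpec, outcome_col: str) -> Design:
    """Build the model design matrix from cohort rows.

    Applies, in order: site-exclusion filter, removal of rows with a missing
    outcome, listwise deletion of rows with missing model covariates (with a
    count and the affected patient ids reported on the result), covariate
    scaling (age/10, volume/10), categorical coding (sex male=1, three
    education indicators, site indicators vs the largest site).
    """
    df = rows.copy()
    if spec.exclude_sites:
        df = df[~df["site_id"].isin(spec.exclude_sites)]
    df = df[df[outcome_col].notna()]
    if len(df) == 0:
        raise EmptySubsetError("no rows remain after outcome/site filtering")

    needed = [spec.score_col] if spec.univariable else [spec.score_col, *_COVARIATE_COLS]
    if not spec.univariable:
        bad = set(df["education_category"].dropna()) - set(EDUCATION_LEVELS)
        if bad:
            raise ValidationError(f"unknown education categories: {sorted(bad)}")
    complete = df[needed].notna().all(axis=1)
    dropped = df.loc[~complete, "patient_id"]
    df = df[complete]
    if len(df) == 0:
        raise EmptySubsetError("no rows with complete covariates")

    X = pd.DataFrame(index=df.index)
    X["const"] = 1.0
    X["log_score"] = df[spec.score_col].astype(float)
    if not spec.univariable:
        X["age_decades"] = df["age_years"].astype(float) / 10.0
        X["male"] = (df["sex"] == "male").astype(float)
        for level in EDUCATION_LEVELS[1:]:
            X[f"edu_{level}"] = (df["education_category"] == level).astype(float)
        X["prior_stroke"] = df["prior_stroke"].astype(float)
        X["volume_per_10ml"] = df["infarct_volume_ml"].astype(float) / 10.0
        if spec.adjust_site and df["site_id"].nunique() > 1:
            site_ref = df["site_id"].value_counts().idxmax()
            for site in sorted(s for s in df["site_id"].unique() if s != site_ref):
                X[f"site_{site}"] = (df["site_id"] == site).astype(float)
        else:
            site_ref = None
    else:
        site_ref = None

    # a stratum/subset may lack a category entirely; its all-zero (or all-one)
    # indicator would make the design singular, so constant indicators go
    constant = [
        c for c in X.columns
        if (c.startswith(("edu_", "site_")) or c in ("male", "prior_stroke"))
        and X[c].nunique() == 1
    ]
    X = X.drop(columns=constant)

    # visit order within subject indexes the AR(1) working correlation
    order_col = "visit" if "visit" in df.columns else "days_post_stroke"
    df = df.sort_values(["patient_id", order_col], kind="mergesort")
    X = X.loc[df.index]
    time = df.groupby("patient_id", sort=False).cumcount().to_numpy()

    return Design(
        y=df[outcome_col].to_numpy(dtype=float),
        X=X,
        groups=df["patient_id"].to_numpy(),
        time=time,
        n_subjects=int(df["patient_id"].nunique()),
        n_obs=int(len(df)),
        n_dropped_missing=int((~complete).sum()),
        dropped_patient_ids=tuple(dropped.unique().tolist()),
        site_reference=site_ref,
    )


def _check_outcome(y: np.ndarray) -> None:
    if len(np.unique(y)) < 2:
        raise DegenerateOutcomeError(
            f"outcome takes a single value ({y[0]:g}) in {len(y)} rows"
        )


def _terms_frame(names, params, cov, drop_intercept=True) -> pd.DataFrame:
    se = np.sqrt(np.diag(cov))
    z = params / se
    from scipy import stats as sps

    p = 2 * sps.norm.sf(np.abs(z))
    lo = np.exp(params - 1.959963984540054 * se)
    hi = np.exp(params + 1.959963984540054 * se)
    out = pd.DataFrame(
        {
            "term": names,
            "or": np.exp(params),
            "ci_low": lo,
            "ci_high": hi,
            "p": p,
            "coef": params,
            "se": se,
        }
    )
    if drop_intercept:
        out = out[out["term"] != "const"].reset_index(drop=True)
    return out


def fit_gee_logistic(rows: pd.DataFrame, spec: ModelSpec | None = None) -> ModelResult:
    """Repeated-measures logistic association fit by GEE.

    ``rows`` is a classified cohort table (one row per assessment) carrying
    the outcome column ``psci`` (1/0, NaN for indeterminate), the log score
    and the covariate columns. Robust sandwich covariance throughout; the
    AR(1) working correlation is indexed by within-subject visit order.
    """
    spec = spec or ModelSpec()
    design = covariate_design(rows, spec, outcome_col="psci")
    _check_outcome(design.y)
    if design.n_subjects < 2:
        raise DegenerateOutcomeError("GEE needs >= 2 subjects")
    if spec.correlation == "ar1":
        cov_struct = sm.cov_struct.Autoregressive(grid=True)
    elif spec.correlation == "independence":
        cov_struct = sm.cov_struct.Independence()
    else:
        raise ValidationError(f"unknown correlation structure {spec.correlation!r}")
    model = sm.GEE(
        design.y,
        design.X,
        groups=design.groups,
        time=design.time,
        family=sm.families.Binomial(),
        cov_struct=cov_struct,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = model.fit(maxiter=100)
        except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
            raise SeparationError(f"GEE fit failed: {exc}") from exc
    if not getattr(fit, "converged", True):
        raise ConvergenceError("GEE did not converge in 100 iterations", trace=fit.fit_history)
    if np.abs(fit.params).max() > 30:
        raise SeparationError("implausibly large coefficients suggest separation")
    dep = np.asarray(cov_struct.dep_params, dtype=float).ravel()
    return ModelResult(
        model=f"gee_{spec.correlation}",
        outcome="psci",
        terms=_terms_frame(list(design.X.columns), fit.params, fit.cov_params()),
        n_subjects=design.n_subjects,
        n_obs=design.n_obs,
        converged=True,
        working_corr=float(dep[0]) if dep.size else None,
        n_dropped_missing=design.n_dropped_missing,
    )


def _fit_logistic(design: Design, model_name: str, outcome: str) -> ModelResult:
    _check_outcome(design.y)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            # IRLS (GLM) rather than Newton: far more stable with sparse
            # categorical cells, identical maximum-likelihood solution
            fit = sm.GLM(design.y, design.X, family=sm.families.Binomial()).fit(maxiter=200)
        except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
            raise SeparationError(f"logistic fit failed: {exc}") from exc
    if not fit.converged:
        raise ConvergenceError("logistic fit did not converge", trace=fit.fit_history)
    if np.abs(fit.params).max() > 30:
        raise SeparationError("implausibly large coefficients suggest separation")
    return ModelResult(
        model=model_name,
        outcome=outcome,
        terms=_terms_frame(list(design.X.columns), fit.params, fit.cov_params()),
        n_subjects=design.n_subjects,
        n_obs=design.n_obs,
        converged=True,
        working_corr=None,
        n_dropped_missing=design.n_dropped_missing,
    )


def fit_stratified_logistic(rows: pd.DataFrame, spec: ModelSpec) -> ModelResult:
    """Ordinary logistic fit within one post-stroke time stratum.

    Uses the earliest assessment per patient falling in the stratum. A
    stratum with fewer than 10 outcome events triggers a warning but the
    fit is still returned.
    """
    if spec.interval not in cognition.INTERVAL_LABELS:
        raise ValidationError(
            f"interval must be one of {cognition.INTERVAL_LABELS}, got {spec.interval!r}"
        )
    df = rows[rows["interval"] == spec.interval]
    if len(df) == 0:
        raise EmptySubsetError(f"no assessments in stratum {spec.interval!r}")
    df = (
        df.sort_values(["patient_id", "days_post_stroke"], kind="mergesort")
        .groupby("patient_id", sort=True, as_index=False)
        .first()
    )
    design = covariate_design(df, spec, outcome_col="psci")
    n_events = int(np.nansum(design.y))
    if n_events < 10:
        warnings.warn(
            f"stratum {spec.interval!r} has only {n_events} events; "
            "estimates will be unstable",
            UserWarning,
            stacklevel=2,
        )
    return _fit_logistic(design, "logistic_stratified", f"psci[{spec.interval}]")


def fit_transition_logistic(rows: pd.DataFrame, outcome: str, spec: ModelSpec | None = None) -> ModelResult:
    """Logistic model of cognitive recovery or decline.

    ``rows`` is a classified cohort table. Transitions are computed per
    patient; the recovery model conditions on baseline-PSCI patients
    (recovery=1 vs stable PSCI=0), the decline model on baseline-no-PSCI
    patients (decline=1 vs stable no-PSCI=0). Covariates are taken from the
    patient's first record.
    """
    if outcome not in ("recovery", "decline"):
        raise ValidationError(f"transition outcome must be recovery|decline, got {outcome!r}")
    spec = spec or ModelSpec()
    spec = replace(spec, outcome=outcome)
    transitions = cognition.classify_transitions(rows)
    if outcome == "recovery":
        eligible = {cognition.RECOVERY, cognition.STABLE_PSCI}
        positive = cognition.RECOVERY
    else:
        eligible = {cognition.DECLINE, cognition.STABLE_NO_PSCI}
        positive = cognition.DECLINE
    tr = transitions[transitions["transition"].isin(eligible)]
    if len(tr) == 0:
        raise EmptySubsetError(
            f"no patients in the conditioning set for {outcome!r} "
            "(wrong baseline arm or no evaluable transitions)"
        )
    per_patient = (
        rows.sort_values(["patient_id", "days_post_stroke"], kind="mergesort")
        .groupby("patient_id", sort=True, as_index=False)
        .first()
    )
    df = per_patient.merge(tr[["patient_id", "transition"]], on="patient_id", how="inner")
    df[outcome] = (df["transition"] == positive).astype(float)
    design = covariate_design(df, spec, outcome_col=outcome)
    return _fit_logistic(design, "logistic_transition", outcome)
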