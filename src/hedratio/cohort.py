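"""Cohort analysis pipeline for HED and transplant outcomes.

Stages, in running order: early-death exclusion, endpoint derivation
(disease-free and overall survival), stratified train/test split, baseline
comparison, univariate Cox screening with FDR control, multivariable Cox
screening of each HED variable against fixed controls, backward-stepwise
final models, competing-risk cumulative incidence, and logistic models of
immune-subset recovery.

Cox proportional-hazards fits are delegated to lifelines; the bespoke
content of this module is the procedure around them (selection rules, FDR
families, endpoint definitions, the competing-risk estimator).  Records
missing a covariate are dropped from that model only and never imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy import stats

logger = logging.getLogger(__name__)

#: Controls retained for the multivariable HED screening and final models.
DEFAULT_CONTROLS = (
    "disease_status",
    "hct_number",
    "conditioning",
    "tbi",
    "hla_match",
    "graft_source",
)

CATEGORICAL_LEVELS = {
    "gender": ["female", "male"],
    "diagnosis": ["AML", "MRC-AML"],
    "disease_status": ["early", "intermediate", "advanced"],
    "hct_number": ["first", "second_or_higher"],
    "hct_period": ["2006-2010", "2010-2015", "2015-2019"],
    "graft_source": ["BM", "CB", "PB"],
    "hla_match": [
        "identical sibling",
        "matched unrelated",
        "mismatched unrelated",
        "haplo-identical",
    ],
    "conditioning": ["MAC", "RIC"],
    "tbi": ["no", "yes"],
}


class CohortError(ValueError):
    pass


class FitError(CohortError):
    pass


@dataclass
class AnalysisConfig:
    """Tunable knobs of the pipeline, readable from a key=value text file."""

    seed: int = 0
    train_frac: float = 338 / 470
    strata: tuple[str, ...] = (
        "disease_status", "hct_number", "conditioning", "hla_match", "hct_period",
    )
    univariate_fdr: float = 0.10
    screen_fdr: float = 0.05
    removal_threshold: float = 0.05
    final_p_cutoff: float = 0.01
    competing_risk_mode: str = "aalen-johansen"  # or "one-minus-km"
    dichotomization: str = "median"  # immune-subset outcome rule

    @classmethod
    def from_file(cls, path) -> "AnalysisConfig":
        kwargs = {}
        for line in open(path):
            line = line.split("#")[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key in ("seed",):
                kwargs[key] = int(value)
            elif key in ("train_frac", "univariate_fdr", "screen_fdr",
                         "removal_threshold", "final_p_cutoff"):
                kwargs[key] = float(value)
            elif key in ("strata",):
                kwargs[key] = tuple(v.strip() for v in value.split(","))
            elif key in ("competing_risk_mode", "dichotomization"):
                kwargs[key] = value
            else:
                raise CohortError(f"unknown config key {key!r}")
        return cls(**kwargs)


# --- record validation and exclusions --------------------------------------

def validate_cohort(df: pd.DataFrame) -> None:
    """Check clinical-record invariants (event days, categorical levels)."""
    day_cols = [
        c for c in (
            "death_day", "relapse_day", "agvhd_onset_day", "cgvhd_onset_day",
            "neutrophil_recovery_day", "platelet_recovery_day",
        ) if c in df.columns
    ]
    for col in day_cols:
        if (df[col].dropna() < 0).any():
            raise CohortError(f"negative values in {col}")
        late = df[col] > df["last_followup_day"]
        if late.any():
            raise CohortError(
                f"{col} after last_followup_day for subjects "
                f"{df.loc[late, 'subject_id'].tolist()[:5]}"
            )
    for col, levels in CATEGORICAL_LEVELS.items():
        if col in df.columns:
            bad = set(df[col].dropna()) - set(levels)
            if bad:
                raise CohortError(f"invalid levels in {col}: {sorted(bad)}")


def apply_exclusions(df: pd.DataFrame, min_day: int = 14) -> pd.DataFrame:
    """Drop subjects who died before ``min_day`` (strict inequality).

    A death on day ``min_day`` itself is retained.
    """
    if (df["death_day"].dropna() < 0).any():
        raise CohortError("negative death_day")
    early = df["death_day"].notna() & (df["death_day"] < min_day)
    logger.info("excluded %d of %d subjects for death before day %d",
                int(early.sum()), len(df), min_day)
    return df.loc[~early].copy()


def derive_endpoints(df: pd.DataFrame) -> pd.DataFrame:
    """Attach OS and DFS (time, event) columns.

    OS: time to death, censored at last follow-up.  DFS: time to relapse or
    death, whichever first, censored at last follow-up.
    """
    out = df.copy()
    no_event = out["death_day"].isna() & out["relapse_day"].isna()
    if out.loc[no_event, "last_followup_day"].isna().any():
        raise CohortError("missing last_followup_day for event-free subject")
    out["os_event"] = out["death_day"].notna().astype(int)
    out["os_time"] = out["death_day"].fillna(out["last_followup_day"])
    dfs_day = out[["relapse_day", "death_day"]].min(axis=1)
    out["dfs_event"] = dfs_day.notna().astype(int)
    out["dfs_time"] = dfs_day.fillna(out["last_followup_day"])
    return out


ENDPOINTS = {"DFS": ("dfs_time", "dfs_event"), "OS": ("os_time", "os_event")}


# --- split and baseline -----------------------------------------------------

def stratified_split(
    df: pd.DataFrame,
    strata_vars,
    train_frac: float,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Disjoint, exhaustive train/test partition, stratified on covariates.

    Within each stratum cell the train count is round(train_frac * size),
    clamped to [1, size-1] for cells of two or more; singleton cells go to
    train.  Deterministic given the seed.
    """
    if not 0 < train_frac < 1:
        raise CohortError(f"train_frac must be in (0,1), got {train_frac}")
    if df.empty:
        raise CohortError("empty cohort")
    rng = np.random.default_rng(seed)
    key = df[list(strata_vars)].astype(str).agg("|".join, axis=1)
    train_idx: list = []
    for _, cell in df.groupby(key, sort=True):
        size = len(cell)
        if size == 1:
            train_idx.extend(cell.index)
            continue
        n_train = int(np.clip(round(train_frac * size), 1, size - 1))
        picked = rng.choice(cell.index.to_numpy(), size=n_train, replace=False)
        train_idx.extend(picked)
    train = df.loc[sorted(train_idx)]
    test = df.drop(index=train_idx)
    return train.copy(), test.copy()


def baseline_table(
    train: pd.DataFrame,
    test: pd.DataFrame,
    variables: dict[str, str],
) -> pd.DataFrame:
    """Compare train and test sets variable by variable.

    ``variables`` maps column name to "continuous" or "categorical".
    Continuous: median [IQR] per set and a two-sample t-test.  Categorical:
    n (%) per level and a chi-squared test on the contingency table.
    """
    if train.empty or test.empty:
        raise CohortError("both sets must be non-empty")
    rows = []
    for var, kind in variables.items():
        if kind == "continuous":
            a, b = train[var].dropna(), test[var].dropna()
            _, p = stats.ttest_ind(a, b)
            fmt = lambda s: (
                f"{s.median():.2f} [{s.quantile(.25):.2f}-{s.quantile(.75):.2f}]"
            )
            rows.append({"variable": var, "level": "",
                         "train": fmt(a), "test": fmt(b), "p": p})
        elif kind == "categorical":
            levels = [
                l for l in (CATEGORICAL_LEVELS.get(var)
                            or sorted(pd.concat([train[var], test[var]]).dropna().unique()))
            ]
            counts = np.array([
                [(train[var] == l).sum(), (test[var] == l).sum()] for l in levels
            ])
            keep = counts.sum(axis=1) > 0
            if not keep.all():
                dropped = [l for l, k in zip(levels, keep) if not k]
                logger.warning("baseline_table: dropping empty levels %s of %s",
                               dropped, var)
            counts, levels = counts[keep], [l for l, k in zip(levels, keep) if k]
            if len(levels) < 2:
                p = np.nan
            else:
                _, p, _, _ = stats.chi2_contingency(counts.T)
            for i, l in enumerate(levels):
                rows.append({
                    "variable": var, "level": l,
                    "train": f"{counts[i, 0]} ({100 * counts[i, 0] / len(train):.1f})",
                    "test": f"{counts[i, 1]} ({100 * counts[i, 1] / len(test):.1f})",
                    "p": p if i == 0 else np.nan,
                })
        else:
            raise CohortError(f"unknown variable kind {kind!r} for {var}")
    return pd.DataFrame(rows)


# --- multiple testing -------------------------------------------------------

def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    adjusted[i] = min over ranks >= rank(i) of m * p_(k) / k, capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise CohortError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


# --- design-matrix helper ---------------------------------------------------

def _design(df: pd.DataFrame, terms) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Dummy-encode terms; returns (matrix, term -> column names).

    Categorical terms use fixed level order (reference = first level) so
    coefficients are reproducible; numeric terms pass through.
    """
    cols: dict[str, pd.Series] = {}
    mapping: dict[str, list[str]] = {}
    for term in terms:
        s = df[term]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            observed = set(s.dropna().unique())
            if observed <= {"low", "mid", "high", "missing"}:
                # group labels from stratify(): "missing" is a missing
                # value (dropped from the model), not a category
                s = s.replace("missing", np.nan)
                observed = set(s.dropna().unique())
                # group labels: reference = low, so coefficients read
                # as the hazard of the higher group vs low
                levels = [l for l in ("low", "mid", "high") if l in observed]
            else:
                levels = CATEGORICAL_LEVELS.get(term) or sorted(observed)
            levels = [l for l in levels if (s == l).any()]
            names = []
            for level in levels[1:]:
                name = f"{term}[{level}]"
                col = (s == level).astype(float)
                col[s.isna()] = np.nan
                cols[name] = col
                names.append(name)
            mapping[term] = names
        else:
            cols[term] = s.astype(float)
            mapping[term] = [term]
    return pd.DataFrame(cols, index=df.index), mapping


def _fit_cox(df: pd.DataFrame, time_col: str, event_col: str, terms):
    """Fit a Cox model on dummy-encoded terms; drops NA rows with a log."""
    X, mapping = _design(df, terms)
    data = pd.concat([df[[time_col, event_col]], X], axis=1)
    n0 = len(data)
    data = data.dropna()
    if len(data) < n0:
        logger.info("cox fit on %s: dropped %d rows with missing covariates",
                    time_col, n0 - len(data))
    if data[event_col].sum() == 0:
        raise FitError(f"no events for {event_col}; degenerate input")
    cph = CoxPHFitter(penalizer=0.0)
    try:
        cph.fit(data, duration_col=time_col, event_col=event_col)
    except Exception as exc:  # convergence / collinearity surfaced by name
        raise FitError(f"cox fit failed for terms {list(terms)}: {exc}") from exc
    return cph, mapping, data


def _lr_drop_pvalue(df, time_col, event_col, terms, term) -> float:
    """Likelihood-ratio p-value for dropping one (possibly multi-level) term."""
    full, mapping, data = _fit_cox(df, time_col, event_col, terms)
    reduced_terms = [t for t in terms if t != term]
    if reduced_terms:
        # refit on the same rows so the likelihoods are comparable
        reduced, _, _ = _fit_cox(df.loc[data.index], time_col, event_col, reduced_terms)
        ll0 = reduced.log_likelihood_
    else:
        ll0 = _null_loglik(data, time_col, event_col)
    lr = 2 * (full.log_likelihood_ - ll0)
    dof = len(mapping[term])
    return float(stats.chi2.sf(max(lr, 0.0), dof))


def _null_loglik(data, time_col, event_col) -> float:
    """Cox partial log-likelihood of the empty (no-covariate) model."""
    t = data[time_col].to_numpy()
    e = data[event_col].to_numpy().astype(bool)
    # Breslow ties: each event contributes -log(size of its risk set)
    risk = np.array([np.sum(t >= ti) for ti in t[e]])
    return float(-np.sum(np.log(risk)))


# --- screening --------------------------------------------------------------

def univariate_screen(
    df: pd.DataFrame,
    candidate_vars,
    fdr: float = 0.10,
) -> tuple[list[str], pd.DataFrame]:
    """Single-covariate Cox fits per variable and endpoint, BH per endpoint.

    Returns the variables whose FDR-adjusted p is below ``fdr`` on BOTH
    disease-free and overall survival, plus the full screening table.
    Non-convergent variables are flagged and excluded with a warning.
    """
    rows = []
    for endpoint, (time_col, event_col) in ENDPOINTS.items():
        for var in candidate_vars:
            try:
                cph, mapping, _ = _fit_cox(df, time_col, event_col, [var])
                p = float(cph.log_likelihood_ratio_test().p_value)
            except FitError as exc:
                logger.warning("univariate screen: %s on %s excluded (%s)",
                               var, endpoint, exc)
                p = np.nan
            rows.append({"variable": var, "endpoint": endpoint, "p": p})
    table = pd.DataFrame(rows, columns=["variable", "endpoint", "p"])
    table["p_adj"] = np.nan
    for endpoint in ENDPOINTS:
        mask = (table["endpoint"] == endpoint) & table["p"].notna()
        if mask.any():
            table.loc[mask, "p_adj"] = bh_adjust(table.loc[mask, "p"])
    selected = []
    for var in candidate_vars:
        sub = table[table["variable"] == var]
        if sub["p_adj"].notna().all() and (sub["p_adj"] < fdr).all():
            selected.append(var)
    return selected, table


def hed_cox_screen(
    df: pd.DataFrame,
    hed_vars,
    controls=DEFAULT_CONTROLS,
) -> pd.DataFrame:
    """One multivariable Cox fit per HED variable plus all controls.

    Reports the HED term's adjusted hazard ratio, 95% CI, raw and
    BH-adjusted p (family = screened HED variables, per endpoint).
    """
    missing = [c for c in controls if c not in df.columns]
    if missing:
        raise CohortError(f"controls absent from cohort: {missing}")
    rows = []
    for endpoint, (time_col, event_col) in ENDPOINTS.items():
        for var in hed_vars:
            cph, mapping, _ = _fit_cox(df, time_col, event_col, [var, *controls])
            col = mapping[var][0]
            s = cph.summary.loc[col]
            rows.append({
                "variable": var, "endpoint": endpoint,
                "hr": float(s["exp(coef)"]),
                "ci_lower": float(s["exp(coef) lower 95%"]),
                "ci_upper": float(s["exp(coef) upper 95%"]),
                "p": float(s["p"]),
            })
    table = pd.DataFrame(rows)
    table["p_adj"] = np.nan
    for endpoint in ENDPOINTS:
        mask = table["endpoint"] == endpoint
        table.loc[mask, "p_adj"] = bh_adjust(table.loc[mask, "p"])
    return table


def final_model(
    df: pd.DataFrame,
    exposure: str,
    endpoint: str,
    controls=DEFAULT_CONTROLS,
    removal_threshold: float = 0.05,
) -> pd.DataFrame:
    """Backward-stepwise Cox model keeping the exposure term throughout.

    Starting from exposure + all controls, iteratively removes the control
    with the largest p at or above ``removal_threshold`` (likelihood-ratio
    drop test for multi-level terms, Wald for single columns), refitting
    until every remaining control passes.  The exposure is never removed.
    Returns HR, 95% CI and p for every retained coefficient, with the term
    each row belongs to.
    """
    exp_vals = df[exposure].dropna().unique()
    if len(exp_vals) < 2:
        raise CohortError(f"exposure {exposure!r} has a single group; degenerate")
    time_col, event_col = ENDPOINTS[endpoint]
    terms = [exposure, *controls]
    while True:
        cph, mapping, _ = _fit_cox(df, time_col, event_col, terms)
        if removal_threshold >= 1.0:  # no elimination: the full fit stands
            break
        worst, worst_p = None, -np.inf
        for term in terms:
            if term == exposure:
                continue
            cols = mapping[term]
            if len(cols) == 1:
                p = float(cph.summary.loc[cols[0], "p"])
            else:
                p = _lr_drop_pvalue(df, time_col, event_col, terms, term)
            if p > worst_p:
                worst, worst_p = term, p
        if worst is None or worst_p < removal_threshold:
            break
        logger.info("final model %s: removing %s (p=%.3f)", endpoint, worst, worst_p)
        terms.remove(worst)
    out = cph.summary.reset_index().rename(columns={
        "covariate": "coefficient", "exp(coef)": "hr",
        "exp(coef) lower 95%": "ci_lower", "exp(coef) upper 95%": "ci_upper",
    })[["coefficient", "hr", "ci_lower", "ci_upper", "p"]]
    col_to_term = {c: t for t, cs in mapping.items() for c in cs}
    out.insert(0, "term", out["coefficient"].map(col_to_term))
    return out


# --- competing-risk cumulative incidence ------------------------------------

def cumulative_incidence(
    time,
    status,
    groups=None,
    mode: str = "aalen-johansen",
) -> dict[str, pd.DataFrame]:
    """Aalen-Johansen cumulative incidence of the event of interest.

    ``status``: 0 = censored, 1 = event of interest, 2 = competing event
    (death before the event).  With ``mode="one-minus-km"`` competing
    events are treated as censorings and the curve is 1 - Kaplan-Meier,
    which equals Aalen-Johansen exactly when no competing events occur.
    Returns, per group, a DataFrame of step coordinates (time, cif).
    Groups with zero subjects are omitted with a warning.
    """
    time = np.asarray(time, dtype=float)
    status = np.asarray(status, dtype=int)
    if (time < 0).any():
        raise CohortError("negative event times")
    if groups is None:
        groups = np.array(["all"] * len(time))
    else:
        groups = np.asarray(groups, dtype=object)
    out: dict[str, pd.DataFrame] = {}
    for g in pd.unique(groups):
        mask = groups == g
        if not mask.any():
            logger.warning("cumulative_incidence: empty group %r omitted", g)
            continue
        t, s = time[mask], status[mask]
        if mode == "one-minus-km":
            s = np.where(s == 2, 0, s)
        order = np.argsort(t, kind="stable")
        t, s = t[order], s[order]
        times = np.unique(t[s > 0])
        surv = 1.0  # all-cause KM survivor just before current time
        cif = 0.0
        rows = [(0.0, 0.0)]
        for ti in times:
            n_risk = np.sum(t >= ti)
            d_event = np.sum((t == ti) & (s == 1))
            d_comp = np.sum((t == ti) & (s == 2))
            cif += surv * d_event / n_risk
            surv *= 1.0 - (d_event + d_comp) / n_risk
            if d_event > 0:  # competing-only times shift risk, not the curve
                rows.append((float(ti), float(cif)))
        out[str(g)] = pd.DataFrame(rows, columns=["time", "cif"])
    return out


# --- immune reconstitution ---------------------------------------------------

def immune_logistic(
    df: pd.DataFrame,
    timepoint: int,
    subsets,
    exposure: str = "classI_mean_group",
    controls=("hla_match", "conditioning"),
    dichotomization: str = "median",
    thresholds: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Logistic regression of subset recovery on high vs low class I HED.

    Per subset, the binary outcome is the count at ``timepoint`` months
    above the dichotomization threshold (subcohort median by default, or
    fixed values via ``thresholds``); exposure is the high-vs-low median
    class I HED group; controls are HLA matching and conditioning.  Reports
    odds ratio and 95% CI; complete separation is flagged per subset and
    its CI marked unstable.
    """
    import statsmodels.api as sm

    exp_levels = df[exposure].dropna().unique()
    if len(exp_levels) < 2:
        raise CohortError(f"exposure {exposure!r} constant; degenerate")
    rows = []
    for subset in subsets:
        col = f"{subset}_m{timepoint}"
        if col not in df.columns:
            raise CohortError(f"missing subset column {col}")
        sub = df.dropna(subset=[col, exposure, *controls])
        if dichotomization == "median":
            thr = float(sub[col].median())
        elif dichotomization == "fixed":
            if not thresholds or subset not in thresholds:
                raise CohortError(f"no fixed threshold for subset {subset}")
            thr = thresholds[subset]
        else:
            raise CohortError(f"unknown dichotomization {dichotomization!r}")
        y = (sub[col] > thr).astype(float)
        X, mapping = _design(sub, [exposure, *controls])
        X = sm.add_constant(X, has_constant="add")
        unstable = False
        try:
            fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
            exp_col = mapping[exposure][0]
            coef = float(fit.params[exp_col])
            se = float(fit.bse[exp_col])
            if not np.isfinite(se) or se > 50:
                unstable = True
        except Exception:
            unstable, coef, se = True, np.nan, np.nan
        if unstable:
            logger.warning("immune_logistic: separation/instability for %s", subset)
        rows.append({
            "subset": subset, "timepoint_months": timepoint,
            "n": len(sub), "threshold": thr,
            "or": float(np.exp(coef)) if np.isfinite(coef) else np.nan,
            "ci_lower": float(np.exp(coef - 1.96 * se)) if np.isfinite(se) else np.nan,
            "ci_upper": float(np.exp(coef + 1.96 * se)) if np.isfinite(se) else np.nan,
            "unstable": unstable,
        })
    return pd.DataFrame(rows)
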