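"""Cohort-level statistical evaluation of dichotomized biomarkers.

Implements the evaluation recipe used for neoadjuvant-response biomarker
studies: two-pathologist visual-TIL case averaging, median dichotomization
(zero/non-zero for the mitotic rate), ROC AUC with DeLong confidence
intervals and p-values, Spearman correlation, and a change-in-estimate
confounder screen feeding a multivariable logistic regression. p-values
are reported uncorrected for multiple testing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps


@dataclass
class EvalResult:
    """AUC of one biomarker for predicting the binary outcome."""

    biomarker: str
    auc: float
    ci95: tuple[float, float]
    p_value: float
    n: int
    n_pcr: int


@dataclass
class LogisticResult:
    """Unadjusted and confounder-adjusted odds ratios of one biomarker."""

    biomarker: str
    or_unadjusted: float
    ci95: tuple[float, float]
    p: float
    or_adjusted: float | None
    ci95_adj: tuple[float, float] | None
    p_adj: float | None
    confounders_included: list[str] = field(default_factory=list)
    adjusted_computable: bool = True
    note: str = ""


def vtils_case_score(
    slide_scores_per_pathologist: Mapping[str, Sequence[float | None]],
) -> float | None:
    """Two-stage visual-TIL averaging: mean over a pathologist's scorable
    slides, then mean over pathologists. Returns None (case unscorable)
    when any pathologist has no scorable slide."""
    means = []
    for scores in slide_scores_per_pathologist.values():
        vals = [s for s in scores if s is not None and not np.isnan(s)]
        if any(not 0 <= v <= 100 for v in vals):
            raise ValueError("visual TIL scores must lie in [0, 100]")
        if not vals:
            return None
        means.append(float(np.mean(vals)))
    if not means:
        return None
    return float(np.mean(means))


@dataclass
class Dichotomy:
    labels: np.ndarray
    threshold: float
    rule: str  # "median" or "zero"
    degenerate: bool = False


def dichotomize(values: Sequence[float], biomarker: str = "") -> Dichotomy:
    """Split into low/high groups.

    Non-MTR biomarkers: high iff value > median (ties go to the low
    group). MTR: high iff value > 0, since most slides have no kept
    mitosis at all.
    """
    v = np.asarray(values, dtype=float)
    if np.isnan(v).any():
        raise ValueError("dichotomize expects defined values only")
    if len(v) < 2:
        raise ValueError("need at least two values to dichotomize")
    if biomarker.lower() == "mtr":
        thr, rule = 0.0, "zero"
    else:
        thr, rule = float(np.median(v)), "median"
    labels = (v > thr).astype(int)
    degenerate = len(np.unique(labels)) < 2
    return Dichotomy(labels=labels, threshold=thr, rule=rule, degenerate=degenerate)


def _delong_variance(pos: np.ndarray, neg: np.ndarray) -> tuple[float, float]:
    """Mann-Whitney AUC and its DeLong variance via structural components."""
    m, n = len(pos), len(neg)
    # psi(x, y) = 1[x>y] + 0.5*1[x==y]
    cmp = (pos[:, None] > neg[None, :]).astype(float)
    cmp += 0.5 * (pos[:, None] == neg[None, :])
    auc = float(cmp.mean())
    v10 = cmp.mean(axis=1)  # per-positive components
    v01 = cmp.mean(axis=0)  # per-negative components
    s10 = float(np.var(v10, ddof=1)) if m > 1 else 0.0
    s01 = float(np.var(v01, ddof=1)) if n > 1 else 0.0
    return auc, s10 / m + s01 / n


def roc_auc(
    scores: Sequence[float],
    labels: Sequence[int],
    biomarker: str = "",
    method: str = "delong",
    n_boot: int = 2000,
    seed: int = 0,
) -> EvalResult:
    """AUC with 95% CI and a two-sided p-value against AUC = 0.5.

    The point estimate is the tie-corrected Mann-Whitney statistic; the CI
    and p-value use DeLong's method by default, or a stratified bootstrap
    (``method="bootstrap"``).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape:
        raise ValueError("scores and labels must align")
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    pos, neg = s[y == 1], s[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both outcome classes must be present")

    auc, var = _delong_variance(pos, neg)
    if method == "delong":
        se = float(np.sqrt(var))
    elif method == "bootstrap":
        rng = np.random.default_rng(seed)
        reps = np.empty(n_boot)
        for i in range(n_boot):
            bp = pos[rng.integers(0, len(pos), len(pos))]
            bn = neg[rng.integers(0, len(neg), len(neg))]
            reps[i], _ = _delong_variance(bp, bn)
        se = float(np.std(reps, ddof=1))
    else:
        raise ValueError(f"unknown CI method {method!r}")

    if se > 0:
        z = (auc - 0.5) / se
        p = float(2 * sps.norm.sf(abs(z)))
        lo, hi = auc - 1.959963984540054 * se, auc + 1.959963984540054 * se
    else:
        p = 1.0 if auc == 0.5 else 0.0
        lo = hi = auc
    return EvalResult(
        biomarker=biomarker,
        auc=auc,
        ci95=(max(0.0, lo), min(1.0, hi)),
        p_value=p,
        n=len(s),
        n_pcr=int(y.sum()),
    )


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation with average ranks for ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 3:
        raise ValueError("need at least 3 defined pairs")
    if np.unique(x[ok]).size < 2 or np.unique(y[ok]).size < 2:
        raise ValueError("spearman undefined for constant input")
    rho, _ = sps.spearmanr(x[ok], y[ok])
    return float(rho)


#: Binary encodings of the clinical covariates: value 1 for the second level.
COVARIATE_ENCODINGS = {
    "age": ("age_years", lambda s: (s > 50).astype(float)),  # <=50 vs >50
    "grade": ("grade", lambda s: (s == 3).astype(float)),  # 2 vs 3
    "t_stage": ("t_stage", lambda s: (s == "T3/4").astype(float)),  # T1/2 vs T3/4
    "n_stage": ("n_stage", lambda s: (s == "N1").astype(float)),  # N0 vs N1
}

DEFAULT_COVARIATES = ["age", "grade", "t_stage", "n_stage"]


def _fit_logit(y: np.ndarray, X: pd.DataFrame):
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.Logit(y, sm.add_constant(X, has_constant="add"))
            res = model.fit(disp=0, maxiter=200)
    except Exception as exc:  # statsmodels raises several separation/LinAlg types
        if type(exc).__name__ in {"PerfectSeparationError", "LinAlgError", "Singular matrix"}:
            raise RuntimeError(f"logistic fit failed: {exc}") from exc
        raise
    if not res.mle_retvals.get("converged", False):
        raise RuntimeError("logistic fit did not converge")
    if np.abs(res.params).max() > 15:
        raise RuntimeError("quasi-separation (diverging coefficients)")
    return res


def confounder_screen(
    cohort: pd.DataFrame,
    biomarker: str,
    covariates: Sequence[str] | None = None,
    outcome: str = "pcr",
    change_threshold: float = 0.10,
) -> LogisticResult:
    """Change-in-estimate confounder screen and final logistic model.

    Fits the unadjusted model (outcome ~ biomarker), then one covariate at
    a time; a covariate is retained as confounder iff adding it changes
    the biomarker odds ratio by at least ``change_threshold`` relative to
    the unadjusted OR. The final model contains the biomarker plus every
    retained confounder; p-values are per-variable Wald tests. For the MTR
    biomarker, grade is never tested (mitotic count is part of grading).
    Complete cases across all candidate covariates are used so the nested
    odds ratios are comparable. When the adjusted model cannot be fit
    (separation, too few events), it is reported as not computable.
    """
    candidates = list(covariates) if covariates is not None else list(DEFAULT_COVARIATES)
    if biomarker.lower() == "mtr" or biomarker.lower().endswith("_mtr"):
        candidates = [c for c in candidates if c != "grade"]

    cols = {biomarker: cohort[biomarker]}
    for c in candidates:
        src, enc = COVARIATE_ENCODINGS[c]
        cols[c] = enc(cohort[src])
    X_all = pd.DataFrame(cols, index=cohort.index)
    y_all = pd.to_numeric(cohort[outcome])
    ok = ~(X_all.isna().any(axis=1) | y_all.isna())
    X_all, y = X_all.loc[ok], y_all.loc[ok].to_numpy(dtype=float)

    res_u = _fit_logit(y, X_all[[biomarker]])
    or_u = float(np.exp(res_u.params[biomarker]))
    ci_u = tuple(np.exp(res_u.conf_int().loc[biomarker]).tolist())
    p_u = float(res_u.pvalues[biomarker])

    retained: list[str] = []
    for c in candidates:  # decision per covariate; order-independent
        try:
            res_c = _fit_logit(y, X_all[[biomarker, c]])
        except RuntimeError:
            continue
        or_c = float(np.exp(res_c.params[biomarker]))
        if abs(or_c - or_u) / or_u >= change_threshold:
            retained.append(c)

    if not retained:
        return LogisticResult(
            biomarker=biomarker,
            or_unadjusted=or_u,
            ci95=ci_u,  # type: ignore[arg-type]
            p=p_u,
            or_adjusted=or_u,
            ci95_adj=ci_u,  # type: ignore[arg-type]
            p_adj=p_u,
            confounders_included=[],
            note="no confounder retained; adjusted model equals unadjusted",
        )
    try:
        res_a = _fit_logit(y, X_all[[biomarker] + retained])
        return LogisticResult(
            biomarker=biomarker,
            or_unadjusted=or_u,
            ci95=ci_u,  # type: ignore[arg-type]
            p=p_u,
            or_adjusted=float(np.exp(res_a.params[biomarker])),
            ci95_adj=tuple(np.exp(res_a.conf_int().loc[biomarker]).tolist()),  # type: ignore[arg-type]
            p_adj=float(res_a.pvalues[biomarker]),
            confounders_included=retained,
        )
    except RuntimeError as exc:
        return LogisticResult(
            biomarker=biomarker,
            or_unadjusted=or_u,
            ci95=ci_u,  # type: ignore[arg-type]
            p=p_u,
            or_adjusted=None,
            ci95_adj=None,
            p_adj=None,
            confounders_included=retained,
            adjusted_computable=False,
            note=f"adjusted model not computable: {exc}",
        )


def evaluate_biomarkers(
    panels: pd.DataFrame,
    cohort: pd.DataFrame,
    biomarkers: Sequence[str] = ("ctils", "ltr", "itr", "mtr"),
    by_subtype: bool = True,
) -> pd.DataFrame:
    """AUC / dichotomized logistic evaluation of case-level biomarkers.

    ``panels`` must hold one row per case with biomarker columns (missing =
    undefined, excluded); ``cohort`` supplies pcr, subtype and covariates.
    Evaluated separately per subtype when subtype information is present.
    Returns one row per (subtype, biomarker) with AUC, CI, p, and the
    dichotomized odds-ratio results.
    """
    merged = panels.merge(cohort, left_on="id", right_on="case_id", how="inner")
    groups: list[tuple[str, pd.DataFrame]]
    if by_subtype and "subtype" in merged.columns and merged["subtype"].notna().any():
        groups = [(str(k), g) for k, g in merged.groupby("subtype")]
    else:
        groups = [("all", merged)]

    rows = []
    for subtype, g in groups:
        for bm in biomarkers:
            sub = g.dropna(subset=[bm, "pcr"])
            row: dict = {"subtype": subtype, "biomarker": bm, "n": len(sub)}
            if len(sub) < 4 or sub["pcr"].nunique() < 2:
                row["note"] = "too few cases or single-class outcome"
                rows.append(row)
                continue
            ev = roc_auc(sub[bm], sub["pcr"].astype(int), biomarker=bm)
            row.update(
                auc=ev.auc, auc_lo=ev.ci95[0], auc_hi=ev.ci95[1],
                auc_p=ev.p_value, n_pcr=ev.n_pcr,
            )
            dich = dichotomize(sub[bm].to_numpy(), biomarker=bm)
            row["threshold"] = dich.threshold
            if dich.degenerate:
                row["note"] = "degenerate dichotomization"
            else:
                sub = sub.assign(_bm_high=dich.labels)
                cand = [
                    c for c in DEFAULT_COVARIATES
                    if not (bm.lower() == "mtr" and c == "grade")
                    and COVARIATE_ENCODINGS[c][0] in sub.columns
                ]
                try:
                    lr = confounder_screen(sub, "_bm_high", covariates=cand)
                    row.update(
                        or_unadjusted=lr.or_unadjusted,
                        or_lo=lr.ci95[0], or_hi=lr.ci95[1], or_p=lr.p,
                        or_adjusted=lr.or_adjusted,
                        confounders=";".join(lr.confounders_included),
                    )
                    if not lr.adjusted_computable:
                        row["note"] = lr.note
                except RuntimeError as exc:
                    row["note"] = f"logistic not computable: {exc}"
            if "vtils" in sub.columns and sub["vtils"].notna().sum() >= 3:
                try:
                    row["spearman_vtils"] = spearman(sub[bm], sub["vtils"])
                except ValueError:
                    pass
            rows.append(row)
    return pd.DataFrame(rows)
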