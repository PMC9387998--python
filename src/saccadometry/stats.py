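"""Univariate group/task inference on saccade-level metrics.

Each metric (latency, damping ratio, amplitude, ...) is modelled with a
linear mixed model: fixed effects of group (PD vs. control, between
subjects) and response type (correct prosaccade vs. correct antisaccade
vs. erroneous antisaccade, within subjects), their interaction, and a
random intercept per participant.  Fixed effects are tested with type-II
likelihood-ratio tests (ML fits of nested models); estimated marginal
means (EMMs) on the group x response-type grid and Bonferroni-corrected
pairwise contrasts are computed from the REML fit.  An optional square-
root transform handles right-skewed non-negative responses; EMMs and
their confidence limits are back-transformed by squaring.

The antisaccade directional error rate — one value per participant — is
compared between groups with a Mann-Whitney U test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

from .preprocess import AS_CORRECT, AS_ERROR, PS_CORRECT

__all__ = [
    "MixedModelSpec",
    "MixedModelResult",
    "fit_metric_model",
    "mann_whitney_error_rate",
]

_RTYPE_ORDER = (PS_CORRECT, AS_ERROR, AS_CORRECT)


@dataclass
class MixedModelSpec:
    """What to model and how."""

    response: str
    transform: str = "identity"  # "identity" | "sqrt"
    family: str = "gaussian"

    def __post_init__(self):
        if self.transform not in ("identity", "sqrt"):
            raise ValueError("transform must be 'identity' or 'sqrt'")
        if self.family != "gaussian":
            raise NotImplementedError(
                "only the Gaussian linear mixed model is implemented; "
                "right-skewed responses can use transform='sqrt'"
            )


@dataclass
class MixedModelResult:
    response: str
    transform: str
    fixed_effects: dict  # term -> {"chi2", "df", "pvalue"}
    emms: pd.DataFrame  # group, response_type, emm, se, ci_low, ci_high
    contrasts: pd.DataFrame  # contrast, estimate, se, z, pvalue, p_bonf
    diagnostics: dict = field(default_factory=dict)
    singular: bool = False

    def to_dict(self):
        return {
            "response": self.response,
            "transform": self.transform,
            "fixed_effects": self.fixed_effects,
            "emms": self.emms.to_dict(orient="records"),
            "contrasts": self.contrasts.to_dict(orient="records"),
            "diagnostics": self.diagnostics,
            "singular": self.singular,
        }


def _levels(df):
    groups = sorted(df["group"].unique(), key=lambda g: (g != "control", g))
    rtypes = [r for r in _RTYPE_ORDER if r in set(df["response_type"])]
    extra = [r for r in sorted(df["response_type"].unique()) if r not in rtypes]
    return groups, rtypes + extra


def _design_row(g, r, groups, rtypes, with_group, with_task, with_inter):
    row = [1.0]
    gd = [1.0 if g == x else 0.0 for x in groups[1:]]
    rd = [1.0 if r == x else 0.0 for x in rtypes[1:]]
    if with_group:
        row += gd
    if with_task:
        row += rd
    if with_inter:
        row += [a * b for a in gd for b in rd]
    return np.array(row)


def _design(df, groups, rtypes, with_group=True, with_task=True, with_inter=True):
    X = np.vstack(
        [
            _design_row(g, r, groups, rtypes, with_group, with_task, with_inter)
            for g, r in zip(df["group"], df["response_type"])
        ]
    )
    names = ["intercept"]
    if with_group:
        names += [f"group[{g}]" for g in groups[1:]]
    if with_task:
        names += [f"rtype[{r}]" for r in rtypes[1:]]
    if with_inter:
        names += [f"group[{g}]:rtype[{r}]" for g in groups[1:] for r in rtypes[1:]]
    return X, names


def _fit_lmm(y, X, part_ids, reml):
    """MixedLM fit with optimizer fallback (mirrors lme4's all_fit idea)."""
    last_err = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, X, groups=part_ids)
        for method in ("lbfgs", "bfgs", "powell", "nm"):
            try:
                res = model.fit(reml=reml, method=method, maxiter=500)
                if np.isfinite(res.llf):
                    return res
                last_err = ValueError("non-finite log-likelihood")
            except (np.linalg.LinAlgError, ValueError) as err:
                last_err = err
    raise RuntimeError(f"mixed-model fit failed with every optimizer: {last_err}")


def fit_metric_model(data: pd.DataFrame, spec: MixedModelSpec) -> MixedModelResult:
    """Fit the mixed model for one metric and report tests, EMMs, contrasts.

    ``data`` needs columns ``participant_id``, ``group``,
    ``response_type`` and the response named by ``spec.response``; rows
    with missing response are dropped.
    """
    df = data.dropna(subset=[spec.response]).copy()
    if df["group"].nunique() < 2:
        raise ValueError("need two groups")
    if df.groupby("group")["participant_id"].nunique().min() < 2:
        raise ValueError("need at least 2 participants per group")
    y = df[spec.response].to_numpy(dtype=float)
    if spec.transform == "sqrt":
        if (y < 0).any():
            raise ValueError("sqrt transform requires non-negative response")
        y = np.sqrt(y)
    groups, rtypes = _levels(df)
    pid = df["participant_id"].to_numpy()

    # --- type-II likelihood-ratio tests on ML fits
    def ll(with_group, with_task, with_inter):
        X, _ = _design(df, groups, rtypes, with_group, with_task, with_inter)
        return _fit_lmm(y, X, pid, reml=False).llf

    ll_full = ll(True, True, True)
    ll_add = ll(True, True, False)
    ll_nog = ll(False, True, False)
    ll_not = ll(True, False, False)
    dfg, dft = len(groups) - 1, len(rtypes) - 1
    tests = {}
    for term, stat, dof in (
        ("group", 2 * (ll_add - ll_nog), dfg),
        ("response_type", 2 * (ll_add - ll_not), dft),
        ("group:response_type", 2 * (ll_full - ll_add), dfg * dft),
    ):
        stat = max(float(stat), 0.0)
        tests[term] = {
            "chi2": stat,
            "df": dof,
            "pvalue": float(sps.chi2.sf(stat, dof)),
        }

    # --- REML fit of the full model for EMMs and contrasts
    X_full, names = _design(df, groups, rtypes)
    res = _fit_lmm(y, X_full, pid, reml=True)
    k = X_full.shape[1]
    beta = np.asarray(res.fe_params)
    cov = np.asarray(res.cov_params())[:k, :k]
    re_var = float(np.asarray(res.cov_re)[0, 0])
    singular = (not res.converged) or re_var < 1e-8

    def back(v):
        return v**2 if spec.transform == "sqrt" else v

    grid, rows = [], []
    for g in groups:
        for r in rtypes:
            row = _design_row(g, r, groups, rtypes, True, True, True)
            est = float(row @ beta)
            se = float(np.sqrt(row @ cov @ row))
            grid.append(
                dict(
                    group=g,
                    response_type=r,
                    emm=back(est),
                    se_model_scale=se,
                    ci_low=back(est - 1.96 * se),
                    ci_high=back(est + 1.96 * se),
                )
            )
            rows.append((g, r, row))
    emms = pd.DataFrame(grid)

    # contrast family: within-group response-type pairs + within-type group pairs
    crows = []
    row_of = {(g, r): row for g, r, row in rows}
    for g in groups:
        for i in range(len(rtypes)):
            for j in range(i + 1, len(rtypes)):
                L = row_of[(g, rtypes[j])] - row_of[(g, rtypes[i])]
                crows.append((f"{g}: {rtypes[j]} - {rtypes[i]}", L))
    for r in rtypes:
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                L = row_of[(groups[j], r)] - row_of[(groups[i], r)]
                crows.append((f"{r}: {groups[j]} - {groups[i]}", L))
    n_family = len(crows)
    recs = []
    for label, L in crows:
        est = float(L @ beta)
        se = float(np.sqrt(L @ cov @ L))
        z = est / se if se > 0 else np.nan
        p = float(2 * sps.norm.sf(abs(z))) if np.isfinite(z) else np.nan
        recs.append(
            dict(
                contrast=label,
                estimate=est,
                se=se,
                z=z,
                pvalue=p,
                p_bonf=min(1.0, p * n_family) if np.isfinite(p) else np.nan,
            )
        )
    contrasts = pd.DataFrame(recs)

    resid = np.asarray(res.resid)
    sd = resid.std()
    pearson = resid / sd if sd > 0 else resid
    diagnostics = {
        "residual_skewness": float(sps.skew(pearson)),
        "residual_excess_kurtosis": float(sps.kurtosis(pearson, fisher=True)),
        "random_intercept_var": re_var,
        "n_obs": int(len(df)),
    }

    return MixedModelResult(
        response=spec.response,
        transform=spec.transform,
        fixed_effects=tests,
        emms=emms,
        contrasts=contrasts,
        diagnostics=diagnostics,
        singular=singular,
    )


def mann_whitney_error_rate(rates_pd, rates_hc):
    """Two-tailed Mann-Whitney U comparison of per-participant AS error
    rates.

    Returns ``(U, p)`` where U is the statistic for the PD sample (number
    of (PD, control) pairs won by PD, ties counting half).  Small samples
    without ties use the exact distribution; otherwise the normal
    approximation with tie correction and continuity correction.
    """
    x = np.asarray(list(rates_pd), dtype=float)
    y = np.asarray(list(rates_hc), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (not has_ties and max(x.size, y.size) <= 20) else "asymptotic"
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)
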