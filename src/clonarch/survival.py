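"""Kaplan-Meier / log-rank comparisons and stepwise Cox modelling.

Per-gene overall survival is compared across the three clonality groups
(clonal / subclonal / WT carriers) with the log-rank test, and gene
clonality enters multivariable Cox proportional-hazards models as two
dummies against WT ("Subclonal vs WT", "Clonal vs WT"), which backward
stepwise elimination removes jointly. Ties use the Efron approximation
(the lifelines default); model stability is assessed by patient-level
bootstrap with per-covariate inclusion frequencies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank
from lifelines.statistics import multivariate_logrank_test

from .association import WT
from .ccf import CLONAL, SUBCLONAL

#: Wald standard error above which a covariate is flagged as a monotone-
#: likelihood / zero-event artifact ("0 0-Inf"-style row).
SE_FLAG = 10.0


@dataclass(frozen=True)
class SurvivalCurve:
    group: str
    event_times: np.ndarray
    at_risk: np.ndarray
    survival: np.ndarray

    def probability_at(self, t: float) -> float:
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class CoxResult:
    stage: str  # univariate / multivariate / stepwise / bootstrap
    summary: pd.DataFrame  # per covariate: coef, hr, ci_low, ci_high, p, flagged
    inclusion_frequency: dict[str, float] = field(default_factory=dict)
    converged: bool = True

    @property
    def covariates(self) -> list[str]:
        return list(self.summary.index)


def km_estimate(times, events, group: str = "all") -> SurvivalCurve:
    """Product-limit survival estimate at the observed event times."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("no subjects")
    if (times < 0).any():
        raise ValueError("negative survival times")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    event_times = np.unique(times[events == 1])
    if event_times.size == 0:
        return SurvivalCurve(group, event_times, np.array([]), np.array([]))
    surv = kmf.survival_function_at_times(event_times).to_numpy()
    at_risk = np.array([(times >= t).sum() for t in event_times])
    return SurvivalCurve(group, event_times, at_risk, surv)


def logrank_test(
    groups: dict[str, tuple[Sequence[float], Sequence[int]]]
) -> tuple[float, int, float]:
    """Log-rank comparison of two or more survival groups.

    Parameters: mapping group label -> (times, events).
    Returns (chi-square statistic, degrees of freedom, p-value).
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for label, (t, e) in groups.items():
        if len(t) == 0:
            raise ValueError(f"group '{label}' has zero subjects")
    if len(groups) == 2:
        (t1, e1), (t2, e2) = (groups[k] for k in groups)
        res = _ll_logrank(t1, t2, event_observed_A=e1, event_observed_B=e2)
        return float(res.test_statistic), 1, float(res.p_value)
    times = np.concatenate([np.asarray(t, float) for t, _ in groups.values()])
    events = np.concatenate([np.asarray(e, int) for _, e in groups.values()])
    labels = np.concatenate(
        [np.repeat(k, len(t)) for k, (t, _) in groups.items()]
    )
    res = multivariate_logrank_test(times, labels, events)
    return float(res.test_statistic), len(groups) - 1, float(res.p_value)


def _fit_cox(df: pd.DataFrame, covariates: list[str]) -> tuple[CoxPHFitter | None, bool]:
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df[covariates + ["os_time", "os_event"]],
                    duration_col="os_time", event_col="os_event")
        return cph, True
    except (ConvergenceError, ValueError, np.linalg.LinAlgError):
        return None, False


def _summarize(cph: CoxPHFitter) -> pd.DataFrame:
    s = cph.summary
    out = pd.DataFrame(
        {
            "coef": s["coef"],
            "hr": s["exp(coef)"],
            "ci_low": np.exp(s["coef lower 95%"]),
            "ci_high": np.exp(s["coef upper 95%"]),
            "p": s["p"],
            "se": s["se(coef)"],
        }
    )
    out["flagged"] = out["se"] > SE_FLAG
    return out


def cox_fit(
    df: pd.DataFrame, covariates: list[str], ph_diagnostic: bool = False
) -> CoxResult:
    """Multivariable Cox PH fit (Efron ties) with Wald CIs and p-values.

    ``df`` must carry ``os_time`` and ``os_event`` plus numeric covariate
    columns; rows with missing values in the fitted columns are dropped
    (complete-case). Monotone-likelihood covariates (e.g. a level with
    zero events) are reported with a flagged, effectively infinite CI.
    """
    data = df[covariates + ["os_time", "os_event"]].dropna()
    cph, ok = _fit_cox(data, covariates)
    if not ok:
        return CoxResult(
            stage="multivariate",
            summary=pd.DataFrame(
                np.nan, index=covariates,
                columns=["coef", "hr", "ci_low", "ci_high", "p", "se"],
            ).assign(flagged=True),
            converged=False,
        )
    summary = _summarize(cph)
    if ph_diagnostic:
        # Schoenfeld-residual check, reported but never enforced
        try:
            from lifelines.statistics import proportional_hazard_test

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ph = proportional_hazard_test(cph, data)
            summary["ph_p"] = ph.summary["p"].groupby(level=0).min().reindex(summary.index)
        except Exception:
            summary["ph_p"] = np.nan
    return CoxResult(stage="multivariate", summary=summary)


def cox_univariate(df: pd.DataFrame, covariates: list[str],
                   groups: dict[str, list[str]] | None = None) -> CoxResult:
    """One Cox fit per covariate (or per joint covariate group)."""
    groups = groups or {}
    grouped = set(c for g in groups.values() for c in g)
    blocks = [[c] for c in covariates if c not in grouped] + list(groups.values())
    frames = []
    for block in blocks:
        frames.append(cox_fit(df, block).summary)
    out = pd.concat(frames)
    return CoxResult(stage="univariate", summary=out.loc[[c for c in covariates if c in out.index]])


def stepwise_backward(
    df: pd.DataFrame,
    covariates: list[str],
    threshold: float = 0.05,
    groups: dict[str, list[str]] | None = None,
) -> CoxResult:
    """Backward stepwise elimination of non-significant Cox covariates.

    Repeatedly refits after removing the covariate with the largest Wald
    p-value above ``threshold``; covariates named together in ``groups``
    (e.g. a gene's two clonality dummies) are scored by their smallest
    p-value and removed jointly. Stops when every remaining p <= threshold.
    """
    groups = dict(groups or {})
    remaining = list(covariates)
    while remaining:
        res = cox_fit(df, remaining)
        if not res.converged:
            return CoxResult(stage="stepwise", summary=res.summary, converged=False)
        pvals = res.summary["p"]
        block_p: dict[str, float] = {}
        for name, members in groups.items():
            live = [m for m in members if m in remaining]
            if live:
                block_p[name] = float(pvals[live].min())
        grouped = {m for g in groups.values() for m in g}
        for cov in remaining:
            if cov not in grouped:
                block_p[cov] = float(pvals[cov])
        worst = max(block_p, key=lambda k: block_p[k])
        if block_p[worst] <= threshold:
            res.stage = "stepwise"
            return res
        drop = groups.get(worst, [worst])
        remaining = [c for c in remaining if c not in drop]
    return CoxResult(
        stage="stepwise",
        summary=pd.DataFrame(
            columns=["coef", "hr", "ci_low", "ci_high", "p", "se", "flagged"]
        ),
        converged=True,
    )


def bootstrap_stability(
    df: pd.DataFrame,
    covariates: list[str],
    B: int = 1000,
    seed: int = 0,
    threshold: float = 0.05,
    groups: dict[str, list[str]] | None = None,
) -> CoxResult:
    """Bootstrap the stepwise pipeline; report per-covariate inclusion rates.

    Patients are resampled with replacement B times; the fraction of
    successful replicates retaining each covariate is the inclusion
    frequency. Replicates whose full-model fit fails are excluded from the
    denominator and counted in the returned summary attrs.
    """
    rng = np.random.default_rng(seed)
    n = len(df)
    retained = {c: 0 for c in covariates}
    hr_sums = {c: [] for c in covariates}
    n_ok = 0
    n_failed = 0
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        boot = df.iloc[idx].reset_index(drop=True)
        res = stepwise_backward(boot, covariates, threshold=threshold, groups=groups)
        if not res.converged:
            n_failed += 1
            continue
        n_ok += 1
        for c in res.covariates:
            retained[c] += 1
            hr_sums[c].append(res.summary.loc[c, "hr"])
    freq = {c: (retained[c] / n_ok if n_ok else np.nan) for c in covariates}
    summary = pd.DataFrame(
        {
            "inclusion_frequency": pd.Series(freq),
            "hr_mean": pd.Series(
                {c: (float(np.mean(v)) if v else np.nan) for c, v in hr_sums.items()}
            ),
        }
    )
    summary.attrs["n_replicates"] = B
    summary.attrs["n_ok"] = n_ok
    summary.attrs["n_failed"] = n_failed
    out = CoxResult(stage="bootstrap", summary=summary, inclusion_frequency=freq)
    return out


@dataclass(frozen=True)
class GeneSurvivalResult:
    gene: str
    eligible: bool
    p_overall: float | None = None
    p_clonal_vs_wt: float | None = None
    p_subclonal_vs_wt: float | None = None
    p_clonal_vs_subclonal: float | None = None


def gene_survival_scan(
    categories: pd.DataFrame,
    clinical: pd.DataFrame,
    min_patients: int = 5,
    subgroup: pd.Series | None = None,
) -> list[GeneSurvivalResult]:
    """Three-group KM/log-rank scan across genes.

    ``categories`` is the patients x genes clonality-category table;
    ``clinical`` must carry os_time/os_event indexed by patient. A gene
    needs >= min_patients clonal AND >= min_patients subclonal carriers.
    ``subgroup`` optionally restricts patients (boolean series) before
    testing; a pairwise test whose category empties is left None.
    """
    clin = clinical.reindex(categories.index)
    keep = clin["os_time"].notna() & clin["os_event"].notna()
    if subgroup is not None:
        keep &= subgroup.reindex(categories.index).fillna(False).astype(bool)

    results = []
    for gene in categories.columns:
        col = categories[gene]
        eligible = (
            int((col == CLONAL).sum()) >= min_patients
            and int((col == SUBCLONAL).sum()) >= min_patients
        )
        if not eligible:
            results.append(GeneSurvivalResult(gene, False))
            continue
        col = col[keep]
        sub_clin = clin[keep]
        grp = {
            lab: (
                sub_clin.loc[col == lab, "os_time"].to_numpy(),
                sub_clin.loc[col == lab, "os_event"].to_numpy(int),
            )
            for lab in (CLONAL, SUBCLONAL, WT)
            if (col == lab).sum() > 0
        }
        p_overall = logrank_test(grp)[2] if len(grp) >= 2 else None

        def pairwise(a: str, b: str) -> float | None:
            if a not in grp or b not in grp:
                return None
            return logrank_test({a: grp[a], b: grp[b]})[2]

        results.append(
            GeneSurvivalResult(
                gene,
                True,
                p_overall=p_overall,
                p_clonal_vs_wt=pairwise(CLONAL, WT),
                p_subclonal_vs_wt=pairwise(SUBCLONAL, WT),
                p_clonal_vs_subclonal=pairwise(CLONAL, SUBCLONAL),
            )
        )
    return results


def clonality_dummies(categories: pd.DataFrame, gene: str) -> pd.DataFrame:
    """Two indicator columns for one gene: subclonal-vs-WT, clonal-vs-WT."""
    col = categories[gene]
    return pd.DataFrame(
        {
            f"{gene}_subclonal": (col == SUBCLONAL).astype(float),
            f"{gene}_clonal": (col == CLONAL).astype(float),
        },
        index=categories.index,
    )
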