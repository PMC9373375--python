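"""Cancer-cell-fraction inference and clonal/subclonal classification.

For a mutation with ``t`` alt reads out of depth ``N``, tumor purity ``p``
and local absolute tumor copy number ``q`` (normal copy number 2 on
autosomes, mutation multiplicity fixed at 1), the expected variant allele
frequency at cancer cell fraction ``f`` is

    VAF(f) = p * f * m / (2 * (1 - p) + p * q)

The likelihood Binomial(t | N, VAF(f)) is evaluated on a uniform grid of
100 CCF values 0.01, 0.02, ..., 1.00 and normalized into a discrete
posterior. A mutation is called subclonal when its equal-tailed 95%
credible interval excludes 1 AND the posterior mass below CCF 0.9 exceeds
0.5; otherwise it is clonal. Multiplicity 1 deliberately biases calls
toward clonal, avoiding overcalled subclonality at amplified loci.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .io import AUTOSOMES, NON_SILENT_CLASSES, CohortBundle, MutationRecord

CLONAL = "clonal"
SUBCLONAL = "subclonal"

#: Default posterior-mass threshold defining P(subclonal) = P(CCF < 0.9).
SUBCLONAL_CCF = 0.9
#: Default decision threshold on P(subclonal).
P_SUBCLONAL_THRESHOLD = 0.5
#: Default credible level of the equal-tailed interval.
CI_LEVEL = 0.95


def ccf_grid(n: int = 100) -> np.ndarray:
    """Uniform CCF grid 1/n, 2/n, ..., 1 (default 0.01..1.00)."""
    return np.arange(1, n + 1) / n


@dataclass(frozen=True)
class CCFPosterior:
    """Discrete CCF posterior on the grid, with MAP, CI and subclonal mass."""

    grid: np.ndarray
    probs: np.ndarray
    map_ccf: float
    ci_low: float
    ci_high: float
    p_subclonal: float


@dataclass(frozen=True)
class ClonalityCall:
    """Classification of one mutation, with the inputs used to produce it."""

    mutation: MutationRecord
    label: str
    posterior: CCFPosterior
    purity: float
    local_cn: int
    multiplicity: int = 1


@dataclass
class GeneClonalitySummary:
    """Per-gene clonal/subclonal mutation tallies and patient categories."""

    gene: str
    c1: int = 0
    s1: int = 0
    patients_clonal_only: int = 0
    patients_subclonal_only: int = 0
    patients_both: int = 0
    patients_wt: int = 0

    @property
    def n(self) -> int:
        return self.c1 + self.s1


def expected_vaf(
    purity: float,
    ccf: float,
    local_cn: float,
    normal_cn: float = 2.0,
    multiplicity: float = 1.0,
) -> float:
    """Expected variant allele frequency at a given cancer cell fraction."""
    denom = normal_cn * (1.0 - purity) + purity * local_cn
    if denom <= 0.0:
        raise ValueError(
            f"degenerate locus: normal_cn={normal_cn}, purity={purity}, local_cn={local_cn}"
        )
    return purity * ccf * multiplicity / denom


def ccf_posterior(
    t_alt: int,
    t_depth: int,
    purity: float,
    local_cn: int,
    *,
    grid: np.ndarray | None = None,
    normal_cn: float = 2.0,
    multiplicity: float = 1.0,
    ci_level: float = CI_LEVEL,
    subclonal_ccf: float = SUBCLONAL_CCF,
) -> CCFPosterior:
    """Grid posterior over CCF for one mutation's read counts.

    Likelihoods are computed in log space (max-subtraction) so that large
    depths cannot underflow. Ties for the MAP break toward the larger grid
    value, biasing toward clonal.
    """
    g = ccf_grid() if grid is None else np.asarray(grid, dtype=float)
    vaf = np.array([expected_vaf(purity, f, local_cn, normal_cn, multiplicity) for f in g])
    vaf = np.clip(vaf, 0.0, 1.0)
    loglik = stats.binom.logpmf(t_alt, t_depth, vaf)
    finite = np.isfinite(loglik)
    if not finite.any():
        raise ValueError(
            f"degenerate posterior for t={t_alt}, N={t_depth}, "
            f"purity={purity}, cn={local_cn}: all grid likelihoods are zero"
        )
    loglik = np.where(finite, loglik, -np.inf)
    probs = np.exp(loglik - loglik[finite].max())
    probs /= probs.sum()

    map_idx = int(np.flatnonzero(probs >= probs.max() * (1.0 - 1e-12))[-1])
    cum = np.cumsum(probs)
    alpha = (1.0 - ci_level) / 2.0
    lo_idx = int(np.searchsorted(cum, alpha))
    hi_idx = int(np.searchsorted(cum, 1.0 - alpha))
    hi_idx = min(hi_idx, len(g) - 1)
    # a nearly flat posterior can put < alpha mass on the MAP grid point;
    # widen so the interval always contains the MAP
    lo_idx = min(lo_idx, map_idx)
    hi_idx = max(hi_idx, map_idx)
    # strict inequality: mass at grid values below the subclonal threshold
    p_sub = float(probs[g < subclonal_ccf - 1e-12].sum())
    return CCFPosterior(
        grid=g,
        probs=probs,
        map_ccf=float(g[map_idx]),
        ci_low=float(g[lo_idx]),
        ci_high=float(g[hi_idx]),
        p_subclonal=p_sub,
    )


def classify_clonality(
    posterior: CCFPosterior, p_threshold: float = P_SUBCLONAL_THRESHOLD
) -> str:
    """Subclonal iff the 95% CI excludes 1 and P(subclonal) > threshold."""
    top = float(posterior.grid[-1])
    if posterior.ci_high < top - 1e-12 and posterior.p_subclonal > p_threshold:
        return SUBCLONAL
    return CLONAL


@dataclass
class AnnotatedMutation:
    mutation: MutationRecord
    purity: float
    local_cn: int


def annotate_mutations(
    bundle: CohortBundle, *, autosomes_only: bool = True
) -> tuple[list[AnnotatedMutation], pd.DataFrame]:
    """Join each mutation to its sample purity and covering segment.

    Returns the annotated mutations plus an exclusion table with one row per
    dropped mutation and its reason (no-purity, non-autosome, no-segment,
    homozygous-deletion).
    """
    purity = bundle.purity_map()
    seg_index: dict[tuple[str, str], list] = {}
    for s in bundle.segments:
        seg_index.setdefault((s.sample_id, s.chrom), []).append(s)
    for segs in seg_index.values():
        segs.sort(key=lambda s: s.start)

    kept: list[AnnotatedMutation] = []
    dropped: list[dict] = []
    for m in bundle.mutations:
        if m.sample_id not in purity:
            dropped.append({"sample": m.sample_id, "gene": m.gene, "chrom": m.chrom,
                            "pos": m.pos, "reason": "no-purity"})
            continue
        if autosomes_only and m.chrom not in AUTOSOMES:
            dropped.append({"sample": m.sample_id, "gene": m.gene, "chrom": m.chrom,
                            "pos": m.pos, "reason": "non-autosome"})
            continue
        segs = seg_index.get((m.sample_id, m.chrom), [])
        starts = [s.start for s in segs]
        idx = np.searchsorted(starts, m.pos, side="right") - 1
        seg = segs[idx] if 0 <= idx < len(segs) and segs[idx].covers(m.pos) else None
        if seg is None:
            dropped.append({"sample": m.sample_id, "gene": m.gene, "chrom": m.chrom,
                            "pos": m.pos, "reason": "no-segment"})
            continue
        if seg.absolute_cn == 0:
            dropped.append({"sample": m.sample_id, "gene": m.gene, "chrom": m.chrom,
                            "pos": m.pos, "reason": "homozygous-deletion"})
            continue
        kept.append(AnnotatedMutation(m, purity[m.sample_id], seg.absolute_cn))
    skip = pd.DataFrame(dropped, columns=["sample", "gene", "chrom", "pos", "reason"])
    return kept, skip


def _posterior_batch(
    t_alt: np.ndarray,
    t_depth: np.ndarray,
    purity: np.ndarray,
    local_cn: np.ndarray,
    grid: np.ndarray,
    subclonal_ccf: float,
    ci_level: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized grid posteriors for many mutations at once.

    Returns (probs matrix, map_ccf, ci_low, ci_high, p_subclonal).
    """
    denom = 2.0 * (1.0 - purity) + purity * local_cn
    vaf = np.clip(purity[:, None] * grid[None, :] / denom[:, None], 0.0, 1.0)
    loglik = stats.binom.logpmf(t_alt[:, None], t_depth[:, None], vaf)
    loglik = np.where(np.isfinite(loglik), loglik, -np.inf)
    mx = loglik.max(axis=1, keepdims=True)
    if not np.isfinite(mx).all():
        raise ValueError("degenerate posterior in batch: all grid likelihoods zero")
    probs = np.exp(loglik - mx)
    probs /= probs.sum(axis=1, keepdims=True)

    # tie-break toward the larger grid value
    rev_argmax = np.argmax(probs[:, ::-1] >= probs.max(axis=1, keepdims=True) * (1 - 1e-12), axis=1)
    map_idx = probs.shape[1] - 1 - rev_argmax
    cum = np.cumsum(probs, axis=1)
    alpha = (1.0 - ci_level) / 2.0
    lo_idx = np.minimum((cum < alpha).sum(axis=1), map_idx)
    hi_idx = np.maximum(
        np.minimum((cum < 1.0 - alpha).sum(axis=1), len(grid) - 1), map_idx
    )
    sub_mask = grid < subclonal_ccf - 1e-12
    p_sub = probs[:, sub_mask].sum(axis=1)
    return probs, grid[map_idx], grid[lo_idx], grid[hi_idx], p_sub


@dataclass
class CohortCalls:
    """All per-mutation calls plus gene- and patient-level summaries."""

    calls: pd.DataFrame
    gene_summaries: dict[str, GeneClonalitySummary]
    patient_architecture: pd.DataFrame
    skip_report: pd.DataFrame


def call_cohort(
    bundle: CohortBundle,
    *,
    non_silent_only: bool = True,
    non_silent_classes: frozenset[str] = NON_SILENT_CLASSES,
    subclonal_ccf: float = SUBCLONAL_CCF,
    p_threshold: float = P_SUBCLONAL_THRESHOLD,
    ci_level: float = CI_LEVEL,
    grid: np.ndarray | None = None,
) -> CohortCalls:
    """Classify every (non-silent) annotated mutation in the cohort.

    The per-mutation table carries map_ccf, the 95% CI, P(subclonal) and
    the clonal/subclonal label; gene summaries tally c1/s1 and partition
    patients into clonal-only / subclonal-only / both / WT per gene.
    """
    annotated, skip = annotate_mutations(bundle)
    if non_silent_only:
        silent = [a for a in annotated if a.mutation.variant_class not in non_silent_classes]
        skip_extra = pd.DataFrame(
            [
                {"sample": a.mutation.sample_id, "gene": a.mutation.gene,
                 "chrom": a.mutation.chrom, "pos": a.mutation.pos, "reason": "silent"}
                for a in silent
            ],
            columns=skip.columns,
        )
        if len(skip_extra):
            skip = pd.concat([skip, skip_extra], ignore_index=True)
        annotated = [a for a in annotated if a.mutation.variant_class in non_silent_classes]

    g = ccf_grid() if grid is None else np.asarray(grid, dtype=float)
    if annotated:
        t_alt = np.array([a.mutation.t_alt for a in annotated], dtype=float)
        t_depth = np.array([a.mutation.t_depth for a in annotated], dtype=float)
        pur = np.array([a.purity for a in annotated], dtype=float)
        cn = np.array([a.local_cn for a in annotated], dtype=float)
        _, map_ccf, ci_lo, ci_hi, p_sub = _posterior_batch(
            t_alt, t_depth, pur, cn, g, subclonal_ccf, ci_level
        )
        top = g[-1]
        labels = np.where(
            (ci_hi < top - 1e-12) & (p_sub > p_threshold), SUBCLONAL, CLONAL
        )
    else:
        map_ccf = ci_lo = ci_hi = p_sub = np.array([])
        labels = np.array([], dtype=str)

    calls = pd.DataFrame(
        {
            "sample": [a.mutation.sample_id for a in annotated],
            "gene": [a.mutation.gene for a in annotated],
            "chrom": [a.mutation.chrom for a in annotated],
            "pos": [a.mutation.pos for a in annotated],
            "variant_class": [a.mutation.variant_class for a in annotated],
            "t_alt": [a.mutation.t_alt for a in annotated],
            "t_depth": [a.mutation.t_depth for a in annotated],
            "purity": [a.purity for a in annotated],
            "local_cn": [a.local_cn for a in annotated],
            "map_ccf": map_ccf,
            "ci_low": ci_lo,
            "ci_high": ci_hi,
            "p_subclonal": p_sub,
            "label": labels,
        }
    )

    all_patients = bundle.sample_ids() or sorted(calls["sample"].unique())
    n_patients = len(all_patients)
    gene_summaries: dict[str, GeneClonalitySummary] = {}
    arch_rows = []
    for gene, sub in calls.groupby("gene", sort=True):
        summ = GeneClonalitySummary(gene=gene)
        summ.c1 = int((sub["label"] == CLONAL).sum())
        summ.s1 = int((sub["label"] == SUBCLONAL).sum())
        per_patient = sub.groupby("sample")["label"].agg(
            lambda s: "both" if len(set(s)) == 2 else s.iloc[0]
        )
        for sample, cat in per_patient.items():
            arch_rows.append({"sample": sample, "gene": gene, "category": cat})
        counts = per_patient.value_counts()
        summ.patients_clonal_only = int(counts.get(CLONAL, 0))
        summ.patients_subclonal_only = int(counts.get(SUBCLONAL, 0))
        summ.patients_both = int(counts.get("both", 0))
        summ.patients_wt = n_patients - len(per_patient)
        gene_summaries[gene] = summ

    arch = pd.DataFrame(arch_rows, columns=["sample", "gene", "category"])
    return CohortCalls(
        calls=calls,
        gene_summaries=gene_summaries,
        patient_architecture=arch,
        skip_report=skip,
    )


def ks_uniformity(ccf_values: Iterable[float]) -> tuple[float | None, float | None, bool]:
    """One-sample KS test of a gene's MAP CCFs against Uniform(0, 1).

    Returns (statistic, p_value, evaluable); fewer than 3 values is flagged
    not-evaluable rather than tested.
    """
    values = np.asarray(list(ccf_values), dtype=float)
    if values.size < 3:
        return None, None, False
    stat, p = stats.kstest(values, "uniform")
    return float(stat), float(p), True


def gene_summary_frame(summaries: dict[str, GeneClonalitySummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": s.gene,
                "n": s.n,
                "c1": s.c1,
                "s1": s.s1,
                "patients_clonal_only": s.patients_clonal_only,
                "patients_subclonal_only": s.patients_subclonal_only,
                "patients_both": s.patients_both,
                "patients_wt": s.patients_wt,
            }
            for s in summaries.values()
        ]
    )
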