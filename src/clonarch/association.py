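"""Clonality vs clinicopathology association tests.

Per gene, each patient is assigned one of three categories — clonal,
subclonal, or WT (wild type) — and tested against binarized clinical
variables in a 2 x 3 contingency table with the Freeman-Halton extension
of Fisher's exact test (full enumeration of tables with fixed margins,
summing the conditional probabilities not exceeding the observed table's).
Mutation-burden comparisons across clinical groups use the two-sided
unpaired t-test or Wilcoxon rank-sum, and per-gene mutation-type vs
clonality contrasts (indel vs other, nonsense vs other) use the classical
2 x 2 Fisher exact test.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import lgamma
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ccf import CLONAL, SUBCLONAL
from .io import INDEL_CLASSES, ClinicalRecord, clinical_frame

WT = "WT"

#: Largest number of candidate tables enumerated exactly before falling
#: back to Monte-Carlo estimation.
ENUMERATION_BOUND = 2_000_000
MC_DRAWS = 100_000
#: Relative tolerance when comparing table probabilities to the observed
#: one (guards against ties lost to rounding; same convention as R).
_REL_EPS = 1e-7


@dataclass(frozen=True)
class ContingencyTable:
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    counts: np.ndarray  # integer matrix, rows x cols

    def dropped_zero_margins(self) -> "ContingencyTable":
        c = np.asarray(self.counts)
        rows = c.sum(axis=1) > 0
        cols = c.sum(axis=0) > 0
        return ContingencyTable(
            tuple(l for l, k in zip(self.row_labels, rows) if k),
            tuple(l for l, k in zip(self.col_labels, cols) if k),
            c[np.ix_(rows, cols)],
        )


@dataclass(frozen=True)
class AssociationResult:
    gene: str
    variable: str
    table: ContingencyTable | None
    p_value: float | None
    test: str  # fisher-exact / fisher-montecarlo / not-evaluable
    eligible: bool = True


def _log_table_prob(counts: np.ndarray, lg_margins: float) -> float:
    return lg_margins - sum(lgamma(v + 1.0) for v in counts.ravel())


def fisher_exact_2xk(
    table, *, seed: int = 0, enumeration_bound: int = ENUMERATION_BOUND, mc_draws: int = MC_DRAWS
) -> tuple[float | None, str]:
    """Two-sided Fisher exact p-value for a 2 x k table (Freeman-Halton).

    Rows/columns with zero margin are dropped first. The p-value sums the
    conditional (multivariate hypergeometric) probabilities of all tables
    with the observed margins whose probability does not exceed the
    observed table's. Tables too large to enumerate are estimated by a
    seeded Monte-Carlo permutation with ``mc_draws`` draws and flagged.

    Returns (p_value, estimator) where estimator is "fisher-exact",
    "fisher-montecarlo", or (None, "not-evaluable") for degenerate tables.
    """
    counts = np.asarray(table, dtype=np.int64)
    if counts.ndim != 2:
        raise ValueError("table must be 2-dimensional")
    rows = counts.sum(axis=1) > 0
    cols = counts.sum(axis=0) > 0
    counts = counts[np.ix_(rows, cols)]
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        return None, "not-evaluable"
    if counts.shape[0] != 2:
        raise ValueError("only 2 x k tables are supported")

    row_m = counts.sum(axis=1)
    col_m = counts.sum(axis=0)
    total = counts.sum()
    lg_margins = (
        sum(lgamma(v + 1.0) for v in row_m)
        + sum(lgamma(v + 1.0) for v in col_m)
        - lgamma(total + 1.0)
    )
    logp_obs = _log_table_prob(counts, lg_margins)

    k = counts.shape[1]
    n_candidates = int(np.prod([min(row_m[0], c) + 1 for c in col_m[:-1]]))
    if n_candidates <= enumeration_bound:
        p = 0.0
        ranges = [range(min(row_m[0], col_m[j]) + 1) for j in range(k - 1)]
        for first_row in itertools.product(*ranges):
            last = row_m[0] - sum(first_row)
            if last < 0 or last > col_m[k - 1]:
                continue
            top = np.array(first_row + (last,), dtype=np.int64)
            bottom = col_m - top
            if (bottom < 0).any():
                continue
            cand = np.vstack([top, bottom])
            logp = _log_table_prob(cand, lg_margins)
            if logp <= logp_obs + abs(logp_obs) * _REL_EPS + 1e-12:
                p += float(np.exp(logp))
        return min(p, 1.0), "fisher-exact"

    # Monte-Carlo: permute column assignments at fixed margins
    rng = np.random.default_rng(seed)
    col_vec = np.repeat(np.arange(k), col_m)
    hits = 0
    thresh = logp_obs + abs(logp_obs) * _REL_EPS + 1e-12
    for _ in range(mc_draws):
        perm = rng.permutation(col_vec)
        top = np.bincount(perm[: row_m[0]], minlength=k)
        cand = np.vstack([top, col_m - top])
        if _log_table_prob(cand, lg_margins) <= thresh:
            hits += 1
    return (hits + 1) / (mc_draws + 1), "fisher-montecarlo"


def patient_gene_category(
    calls: pd.DataFrame,
    all_patients: Sequence[str],
    rule: Literal["clonal-dominant", "subclonal-dominant"] = "clonal-dominant",
) -> pd.DataFrame:
    """Per patient x gene category in {clonal, subclonal, WT}.

    Patients carrying both a clonal and a subclonal mutation in the gene
    collapse to one category per ``rule`` (default clonal-dominant).
    Returns a patients x genes DataFrame filled with WT where unmutated.
    """
    dominant = CLONAL if rule == "clonal-dominant" else SUBCLONAL
    genes = sorted(calls["gene"].unique())
    out = pd.DataFrame(WT, index=list(all_patients), columns=genes)
    for (sample, gene), sub in calls.groupby(["sample", "gene"]):
        if sample not in out.index:
            continue
        labels = set(sub["label"])
        out.loc[sample, gene] = dominant if len(labels) == 2 else next(iter(labels))
    return out


#: Clinical binarizations used across the association scan; each maps a
#: ClinicalRecord frame to a binary series (labels) with NaN for missing.
def binarize_clinical(clin: pd.DataFrame) -> dict[str, pd.Series]:
    """Binary groupings of the clinical table, pairwise-deleting missing."""
    out: dict[str, pd.Series] = {}
    age = pd.to_numeric(clin["age"], errors="coerce")
    med = age.median()
    out["age"] = pd.Series(
        np.where(age.isna(), None, np.where(age < med, "<median", ">=median")),
        index=clin.index, dtype=object,
    )
    out["sex"] = clin["sex"].where(clin["sex"].isin(["female", "male"]), None)
    out["msi_status"] = clin["msi_status"].where(clin["msi_status"].isin(["MSI", "MSS"]), None)
    out["tumour_site"] = clin["tumour_site"].where(
        clin["tumour_site"].isin(["left-sided", "right-sided"]), None
    )
    ajcc = pd.to_numeric(clin["ajcc_stage"], errors="coerce")
    out["ajcc_stage"] = pd.Series(
        np.where(ajcc.isna(), None, np.where(ajcc <= 2, "stage1/2", "stage3/4")),
        index=clin.index, dtype=object,
    )
    t = pd.to_numeric(clin["t_stage"], errors="coerce")
    out["t_stage"] = pd.Series(
        np.where(t.isna(), None, np.where(t <= 2, "T1/T2", "T3/T4")),
        index=clin.index, dtype=object,
    )
    n = pd.to_numeric(clin["n_stage"], errors="coerce")
    out["n_stage"] = pd.Series(
        np.where(n.isna(), None, np.where(n == 0, "N0", "N1/N2")),
        index=clin.index, dtype=object,
    )
    m = pd.to_numeric(clin["m_stage"], errors="coerce")
    out["m_stage"] = pd.Series(
        np.where(m.isna(), None, np.where(m == 0, "M0", "M1")),
        index=clin.index, dtype=object,
    )
    return out


def association_scan(
    categories: pd.DataFrame,
    clinical: Sequence[ClinicalRecord] | pd.DataFrame,
    min_patients: int = 5,
    *,
    seed: int = 0,
) -> tuple[list[AssociationResult], pd.DataFrame]:
    """Gene x clinical-variable Fisher scan over 2 x 3 tables.

    A gene is eligible when at least ``min_patients`` patients carry clonal
    mutations AND at least ``min_patients`` carry subclonal mutations
    (patients carrying both count on their collapsed category). Returns the
    per-test results and a genes x variables matrix of -log2(p) for the
    eligible tests.
    """
    clin = clinical if isinstance(clinical, pd.DataFrame) else clinical_frame(clinical)
    clin = clin.reindex(categories.index)
    groupings = binarize_clinical(clin)

    results: list[AssociationResult] = []
    eligible_genes = []
    for gene in categories.columns:
        col = categories[gene]
        n_clonal = int((col == CLONAL).sum())
        n_subclonal = int((col == SUBCLONAL).sum())
        eligible = n_clonal >= min_patients and n_subclonal >= min_patients
        if eligible:
            eligible_genes.append(gene)
        for var, grouping in groupings.items():
            if not eligible:
                results.append(AssociationResult(gene, var, None, None, "not-evaluable", False))
                continue
            mask = grouping.notna()
            sub = pd.crosstab(grouping[mask], col[mask])
            sub = sub.reindex(columns=[CLONAL, SUBCLONAL, WT], fill_value=0)
            table = ContingencyTable(
                tuple(str(i) for i in sub.index),
                tuple(sub.columns),
                sub.to_numpy(),
            )
            if sub.shape[0] < 2:
                results.append(AssociationResult(gene, var, table, None, "not-evaluable", True))
                continue
            p, estimator = fisher_exact_2xk(sub.to_numpy(), seed=seed)
            results.append(AssociationResult(gene, var, table, p, estimator, True))

    matrix = pd.DataFrame(index=eligible_genes, columns=list(groupings), dtype=float)
    for r in results:
        if r.eligible and r.p_value is not None:
            matrix.loc[r.gene, r.variable] = -np.log2(max(r.p_value, 1e-300))
    return results, matrix


def burden_compare(
    counts: pd.Series,
    grouping: pd.Series,
    method: Literal["t-test", "wilcoxon"] = "t-test",
) -> tuple[float | None, bool]:
    """Two-sided comparison of per-patient mutation counts between two groups.

    Returns (p_value, evaluable); a group with fewer than 2 patients makes
    the test not-evaluable.
    """
    mask = grouping.notna() & counts.notna()
    groups = [counts[mask & (grouping == g)].to_numpy(dtype=float)
              for g in pd.unique(grouping[mask])]
    if len(groups) != 2 or min(len(g) for g in groups) < 2:
        return None, False
    a, b = groups
    if method == "t-test":
        t, p = stats.ttest_ind(a, b, equal_var=True)
    elif method == "wilcoxon":
        _, p = stats.ranksums(a, b)
    else:
        raise ValueError(f"unknown method '{method}'")
    if np.isnan(p):  # zero variance in both groups with equal means
        p = 1.0
    return float(p), True


def mutation_type_vs_clonality(
    calls: pd.DataFrame, contrast: Literal["indel", "nonsense"] = "indel"
) -> list[AssociationResult]:
    """Per-gene 2 x 2 Fisher test of mutation type against clonality.

    ``contrast="indel"`` tests indel vs all other classes; ``"nonsense"``
    tests nonsense vs other. Genes whose classified mutations span fewer
    than 2 type groups (or fewer than 2 labels) are flagged not-evaluable.
    """
    if contrast == "indel":
        in_group = calls["variant_class"].isin(INDEL_CLASSES)
    elif contrast == "nonsense":
        in_group = calls["variant_class"] == "nonsense"
    else:
        raise ValueError(f"unknown contrast '{contrast}'")
    type_label = np.where(in_group, contrast, "other")

    results = []
    for gene, idx in calls.groupby("gene").groups.items():
        sub_types = pd.Series(type_label[calls.index.get_indexer(idx)])
        sub_labels = calls.loc[idx, "label"].reset_index(drop=True)
        tab = pd.crosstab(sub_types, sub_labels)
        tab = tab.reindex(index=[contrast, "other"], columns=[CLONAL, SUBCLONAL], fill_value=0)
        table = ContingencyTable(
            tuple(tab.index), tuple(tab.columns), tab.to_numpy()
        )
        trimmed = table.dropped_zero_margins()
        if trimmed.counts.shape[0] < 2 or trimmed.counts.shape[1] < 2:
            results.append(
                AssociationResult(gene, f"{contrast}-vs-clonality", table, None,
                                  "not-evaluable", True)
            )
            continue
        _, p = stats.fisher_exact(trimmed.counts)
        results.append(
            AssociationResult(gene, f"{contrast}-vs-clonality", table, float(p),
                              "fisher-exact", True)
        )
    return results


def association_frame(results: list[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": r.gene,
                "variable": r.variable,
                "p_value": r.p_value,
                "test": r.test,
                "eligible": r.eligible,
            }
            for r in results
        ]
    )
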