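"""Permutation test for per-gene clonal/subclonal mutation enrichment.

A gene with n classified non-silent mutations, c1 clonal and s1 subclonal,
has observed clonal ratio c1/s1 and subclonal ratio s1/c1. Each permutation
draws n mutations without replacement from the cohort-wide background label
multiset and counts the clonal draws c*; because c* determines the ratio
monotonically at fixed n, comparing counts is equivalent to comparing
ratios. P-values use the add-one permutation estimator

    p_clonal = (#{c* >= c1} + 1) / (n_perm + 1)

(at-least-as-extreme rather than strictly-greater, so a maximal observed
ratio cannot yield p = 0), and Benjamini-Hochberg FDR q-values are reported
alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .ccf import CLONAL, SUBCLONAL


@dataclass(frozen=True)
class EnrichmentResult:
    gene: str
    n: int
    c1: int
    s1: int
    clonal_ratio: float  # inf when s1 == 0
    subclonal_ratio: float  # inf when c1 == 0
    p_clonal: float
    p_subclonal: float
    q_clonal: float
    q_subclonal: float
    n_perm: int
    seed: int


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def enrichment_test(
    gene_counts: dict[str, tuple[int, int]],
    background_labels,
    n_perm: int = 1000,
    seed: int = 0,
    *,
    with_replacement: bool = False,
) -> list[EnrichmentResult]:
    """Permutation enrichment p-values and BH q-values for each gene.

    Parameters
    ----------
    gene_counts
        Mapping gene -> (c1, s1) observed clonal/subclonal counts.
    background_labels
        Clonality labels of all classified non-silent mutations cohort-wide
        (strings "clonal"/"subclonal", or 1/0). The genes' own mutations are
        expected to be part of this pool.
    with_replacement
        Draw labels with replacement instead of permuting the pool.

    Each gene consumes an independent child stream of ``seed`` keyed by its
    position in sorted gene order, so results are reproducible and a global
    clonal/subclonal label swap maps p_clonal onto p_subclonal exactly.
    """
    labels = np.asarray(
        [1 if lab in (1, True, CLONAL) else 0 for lab in background_labels], dtype=np.int8
    )
    n_bg = labels.size
    genes = sorted(gene_counts)
    streams = np.random.SeedSequence(seed).spawn(len(genes))

    raw: list[dict] = []
    for gene, ss in zip(genes, streams):
        c1, s1 = gene_counts[gene]
        n = c1 + s1
        if n < 1:
            raise ValueError(f"gene {gene} has no classified mutations")
        if not with_replacement and n > n_bg:
            raise ValueError(
                f"gene {gene} has {n} mutations but the background holds only {n_bg}"
            )
        rng = np.random.default_rng(ss)
        if with_replacement:
            draws = rng.choice(labels, size=(n_perm, n), replace=True)
            c_star = draws.sum(axis=1)
        else:
            # indices drawn without replacement; label-independent index
            # streams keep the clonal/subclonal swap symmetry exact
            c_star = np.empty(n_perm, dtype=np.int64)
            for b in range(n_perm):
                idx = rng.choice(n_bg, size=n, replace=False, shuffle=False)
                c_star[b] = labels[idx].sum()
        s_star = n - c_star
        p_clonal = (np.count_nonzero(c_star >= c1) + 1) / (n_perm + 1)
        p_subclonal = (np.count_nonzero(s_star >= s1) + 1) / (n_perm + 1)
        raw.append(
            {
                "gene": gene,
                "n": n,
                "c1": c1,
                "s1": s1,
                "clonal_ratio": c1 / s1 if s1 else np.inf,
                "subclonal_ratio": s1 / c1 if c1 else np.inf,
                "p_clonal": p_clonal,
                "p_subclonal": p_subclonal,
            }
        )

    q_clonal = fdr_adjust([r["p_clonal"] for r in raw])
    q_subclonal = fdr_adjust([r["p_subclonal"] for r in raw])
    return [
        EnrichmentResult(
            gene=r["gene"],
            n=r["n"],
            c1=r["c1"],
            s1=r["s1"],
            clonal_ratio=r["clonal_ratio"],
            subclonal_ratio=r["subclonal_ratio"],
            p_clonal=r["p_clonal"],
            p_subclonal=r["p_subclonal"],
            q_clonal=float(qc),
            q_subclonal=float(qs),
            n_perm=n_perm,
            seed=seed,
        )
        for r, qc, qs in zip(raw, q_clonal, q_subclonal)
    ]


def enrichment_from_calls(
    calls: pd.DataFrame, n_perm: int = 1000, seed: int = 0
) -> list[EnrichmentResult]:
    """Run the enrichment test from a per-mutation calls table.

    The background is every classified non-silent mutation in ``calls``.
    """
    counts = {
        gene: (
            int((sub["label"] == CLONAL).sum()),
            int((sub["label"] == SUBCLONAL).sum()),
        )
        for gene, sub in calls.groupby("gene")
    }
    return enrichment_test(counts, calls["label"].to_numpy(), n_perm=n_perm, seed=seed)


def enrichment_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
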