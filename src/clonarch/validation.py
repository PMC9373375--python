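"""Self-validation benchmarks for the clonality pipeline.

Each function recomputes one quantitative property of the pipeline from
scratch — reproducing the published contingency-table p-values, measuring
CCF parameter recovery and classifier specificity on simulated reads,
calibrating the permutation enrichment test against its exact
hypergeometric oracle, and recovering a configured survival effect through
the full generator -> CCF -> stepwise-Cox path. All randomness derives
from the ``seed`` argument.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats

from .association import fisher_exact_2xk, patient_gene_category
from .ccf import _posterior_batch, ccf_grid, expected_vaf
from .datasets import iter_published_tables
from .enrichment import enrichment_test
from .io import clinical_frame
from .simulate import ClinicalEffects, GeneSpec, SimulationConfig, simulate_cohort
from .survival import clonality_dummies, logrank_test, stepwise_backward


def published_table_pvalues() -> dict[str, float]:
    """Freeman-Halton p-values recomputed from the published 2 x 3 tables."""
    out = {}
    for gene, variable, counts, _ in iter_published_tables():
        p, estimator = fisher_exact_2xk(counts)
        assert estimator == "fisher-exact"
        out[f"{gene.lower()}_{variable}"] = float(p)
    return out


def _direct_binom_pmf(t: int, depth: int, v: float) -> float:
    """Binomial pmf by direct multiplication, no logs.

    Interleaves the binomial-coefficient ratio with the success factors so
    intermediates stay near the final magnitude instead of underflowing
    through v**t alone.
    """
    p = 1.0
    for k in range(1, t + 1):
        p *= (depth - t + k) / k * v
    for _ in range(depth - t):
        p *= 1.0 - v
    return p


def _naive_posterior(t: int, depth: int, purity: float, cn: int) -> np.ndarray | None:
    """Direct-probability grid posterior (no log space): the oracle."""
    grid = ccf_grid()
    probs = []
    for f in grid:
        v = min(max(expected_vaf(purity, f, cn), 0.0), 1.0)
        probs.append(_direct_binom_pmf(t, depth, v))
    probs = np.array(probs)
    total = probs.sum()
    # near the double-precision floor the direct products lose relative
    # accuracy (denormals); the oracle only applies clear of underflow
    if total == 0.0 or not np.isfinite(total) or probs.max() < 1e-250:
        return None
    return probs / total


def ccf_oracle_max_tv(seed: int, n_cases: int = 300) -> float:
    """Max total-variation distance between log-space and naive posteriors."""
    rng = np.random.default_rng(seed)
    grid = ccf_grid()
    worst = 0.0
    for _ in range(n_cases):
        depth = int(rng.integers(5, 600))
        t = int(rng.integers(0, depth + 1))
        purity = float(rng.uniform(0.1, 1.0))
        cn = int(rng.integers(1, 6))
        naive = _naive_posterior(t, depth, purity, cn)
        if naive is None:
            continue
        probs, *_ = _posterior_batch(
            np.array([t], float), np.array([depth], float),
            np.array([purity]), np.array([cn], float), grid, 0.9, 0.95,
        )
        worst = max(worst, float(0.5 * np.abs(probs[0] - naive).sum()))
    return worst


def _batch_calls(t_alt, depth, purity, cn):
    grid = ccf_grid()
    n = len(t_alt)
    probs, map_ccf, ci_lo, ci_hi, p_sub = _posterior_batch(
        np.asarray(t_alt, float),
        np.full(n, depth, float),
        np.full(n, purity),
        np.full(n, cn, float),
        grid, 0.9, 0.95,
    )
    labels = np.where((ci_hi < 1.0 - 1e-12) & (p_sub > 0.5), "subclonal", "clonal")
    return map_ccf, labels


def map_recovery_rate(
    seed: int, n: int = 2000, depth: int = 500, purity: float = 0.7, cn: int = 2,
    ccf_range: tuple[float, float] = (0.2, 0.8), tol: float = 0.05,
) -> float:
    """Fraction of simulated mutations whose MAP CCF lands within ``tol``."""
    rng = np.random.default_rng(seed)
    truth = rng.uniform(*ccf_range, size=n)
    vafs = purity * truth / (2.0 * (1.0 - purity) + purity * cn)
    t_alt = rng.binomial(depth, vafs)
    map_ccf, _ = _batch_calls(t_alt, depth, purity, cn)
    return float(np.mean(np.abs(map_ccf - truth) <= tol + 1e-12))


def clonal_call_rate(
    seed: int, n: int = 20000, depth: int = 500, purity: float = 0.7, cn: int = 2
) -> float:
    """Fraction of true clonal (CCF = 1) mutations classified clonal.

    The exact rate at these settings is ~0.96 (one minus the binomial lower
    tail at the largest alt count still called subclonal); ``n`` is sized
    so the Monte-Carlo SE (~0.0014) is small against the margin over 0.95.
    """
    rng = np.random.default_rng(seed)
    v = expected_vaf(purity, 1.0, cn)
    t_alt = rng.binomial(depth, v, size=n)
    _, labels = _batch_calls(t_alt, depth, purity, cn)
    return float(np.mean(labels == "clonal"))


def enrichment_oracle_max_se(seed: int, n_perm: int = 1000) -> float:
    """Worst |permutation p - exact hypergeometric tail| in MC-SE units.

    Covers clonal- and subclonal-leaning genes against a 300/200 background;
    the (k+1)/(B+1) estimator contributes at most 1/(B+1), absorbed into
    the reported SE units.
    """
    labels = [1] * 300 + [0] * 200
    worst = 0.0
    for c1, s1 in ((10, 0), (8, 2), (5, 5), (2, 8), (0, 10), (20, 5)):
        res = enrichment_test({"G": (c1, s1)}, labels, n_perm=n_perm, seed=seed)[0]
        n = c1 + s1
        for perm_p, exact in (
            (res.p_clonal, float(stats.hypergeom.sf(c1 - 1, 500, 300, n))),
            (res.p_subclonal, float(stats.hypergeom.sf(s1 - 1, 500, 200, n))),
        ):
            se = math.sqrt(max(exact * (1.0 - exact), 1e-12) / n_perm)
            dev = max(abs(perm_p - exact) - 1.0 / (n_perm + 1), 0.0)
            worst = max(worst, dev / se)
    return worst


def null_type1_rate(
    seed: int, n_genes: int = 400, clonal_frac: float = 0.8,
    size_range: tuple[int, int] = (100, 300), n_perm: int = 1000,
) -> float:
    """Empirical rate of p_clonal <= 0.05 across null genes.

    Genes draw their labels i.i.d. from the background distribution; per-
    gene mutation counts are mixed over ``size_range`` so the attainable
    size of the discrete one-sided test sits near (conservatively below)
    the nominal level rather than collapsing onto a single lattice value.
    """
    rng = np.random.default_rng(seed)
    sizes = rng.integers(size_range[0], size_range[1] + 1, size=n_genes)
    c1s = rng.binomial(sizes, clonal_frac)
    labels = np.concatenate(
        [np.concatenate([np.ones(c, np.int8), np.zeros(n - c, np.int8)])
         for n, c in zip(sizes, c1s)]
    )
    counts = {f"g{i:04d}": (int(c1s[i]), int(sizes[i] - c1s[i])) for i in range(n_genes)}
    results = enrichment_test(counts, labels, n_perm=n_perm, seed=seed)
    return float(np.mean([r.p_clonal <= 0.05 for r in results]))


SURVIVAL_PANEL = [
    GeneSpec("ANK1", 0.20, 0.5),
    GeneSpec("TP53", 0.50, 0.9),
    GeneSpec("KRAS", 0.40, 0.9),
    GeneSpec("APC", 0.60, 0.85),
    GeneSpec("SMAD4", 0.15, 0.75),
]


def survival_recovery_rate(
    seed: int, n_seeds: int = 50, n_patients: int = 1000, hr: float = 3.0
) -> float:
    """Fraction of replicates where stepwise Cox recovers a subclonal effect.

    Each replicate runs the full path — generator (ANK1 subclonal log-HR =
    log(hr), depth 200) -> CCF classification -> patient categories ->
    backward stepwise Cox with joint gene-dummy removal — and scores a hit
    when the ANK1-subclonal dummy is retained with a positive coefficient
    and p <= 0.05.
    """
    base = np.random.SeedSequence(seed).generate_state(n_seeds) % (2**31)
    eff = ClinicalEffects(log_hr={"ANK1:subclonal": math.log(hr)})
    hits = 0
    for s in base:
        cfg = SimulationConfig(
            n_patients=n_patients,
            genes=SURVIVAL_PANEL,
            clinical_effects=eff,
            depth_mean=200.0,
            censor_rate=0.5,
            seed=int(s),
        )
        bundle, _ = simulate_cohort(cfg)
        from .ccf import call_cohort

        calls = call_cohort(bundle)
        clin = clinical_frame(bundle.clinical)
        cats = patient_gene_category(calls.calls, list(clin.index))
        model = clin[["os_time", "os_event"]].copy()
        groups = {}
        for g in cats.columns:
            d = clonality_dummies(cats, g)
            model = model.join(d)
            groups[g] = list(d.columns)
        covs = [c for c in model.columns if c not in ("os_time", "os_event")]
        res = stepwise_backward(model, covs, groups=groups)
        s_ = res.summary
        if (
            "ANK1_subclonal" in s_.index
            and s_.loc["ANK1_subclonal", "coef"] > 0
            and s_.loc["ANK1_subclonal", "p"] <= 0.05
        ):
            hits += 1
    return hits / n_seeds


def _logrank_oracle(t1, e1, t2, e2) -> float:
    """Independent O-E/V chi-square over pooled event times."""
    t1, e1, t2, e2 = map(np.asarray, (t1, e1, t2, e2))
    O = E = V = 0.0
    for t in np.unique(np.concatenate([t1[e1 == 1], t2[e2 == 1]])):
        n1, n2 = (t1 >= t).sum(), (t2 >= t).sum()
        d1 = ((t1 == t) & (e1 == 1)).sum()
        d2 = ((t2 == t) & (e2 == 1)).sum()
        n, d = n1 + n2, d1 + d2
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    return (O - E) ** 2 / V if V > 0 else 0.0


def logrank_oracle_max_diff(seed: int, n_cases: int = 100) -> float:
    """Max |log-rank statistic - O-E/V oracle| over random toy datasets."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_cases):
        n1, n2 = rng.integers(5, 30, size=2)
        t1 = rng.exponential(10, n1).round(1) + 0.1
        t2 = rng.exponential(16, n2).round(1) + 0.1
        e1 = rng.integers(0, 2, n1)
        e2 = rng.integers(0, 2, n2)
        if e1.sum() + e2.sum() == 0:
            continue
        stat, _, _ = logrank_test({"a": (t1, e1), "b": (t2, e2)})
        worst = max(worst, abs(stat - _logrank_oracle(t1, e1, t2, e2)))
    return worst


def pipeline_determinism(seed: int, out_dir) -> bool:
    """Two pipeline runs with one config produce byte-identical outputs."""
    from pathlib import Path

    from .pipeline import PipelineConfig, run_pipeline

    out = Path(out_dir)
    manifests = []
    for name in ("a", "b"):
        cfg = PipelineConfig(
            out_dir=str(out / name),
            simulation={"n_patients": 120},
            n_perm=100,
            bootstrap_b=10,
            seed=seed,
        )
        manifests.append(run_pipeline(cfg))
    return manifests[0]["files"] == manifests[1]["files"]
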