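"""Synthetic tumor-cohort generator with known clonal ground truth.

Emulates the inputs of a TCGA-style colorectal cohort: per-sample tumor
purity, MAF-style read counts produced by the same binomial observation
model the inference inverts, absolute copy-number segments covering each
mutated site, clinical covariates optionally correlated with clonality
(e.g. MSI patients enriched for subclonal mutations and carrying a higher
mutation burden), and exponential survival times whose hazard is
multiplied by configured per-gene clonality effects.

Ground truth: clonal mutations have true CCF exactly 1; subclonal true
CCFs are drawn uniformly from a range strictly below 0.9 so that truth
labels agree with the 0.9-threshold definition used downstream.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ccf import expected_vaf
from .io import (
    ClinicalRecord,
    CohortBundle,
    CopyNumberSegment,
    MutationRecord,
    SamplePurity,
    write_clinical,
    write_maf,
    write_purity,
    write_segments,
)


@dataclass(frozen=True)
class GeneSpec:
    """One simulated driver gene.

    rate: per-patient probability of carrying a mutation in the gene;
    clonal_bias: probability that the mutation is clonal (true CCF = 1);
    indel_rate: probability that the mutation is a frameshift indel
    rather than a missense SNV.
    """

    name: str
    rate: float
    clonal_bias: float
    indel_rate: float = 0.1
    chrom: str | None = None
    pos: int | None = None


@dataclass
class ClinicalEffects:
    """Couplings between clonality and the clinical layer.

    subclonal_msi_odds: per-gene odds multiplier on a mutation being
    subclonal when the patient is MSI; msi_burden_multiplier: factor on all
    per-gene mutation rates in MSI patients; log_hr: per "gene:label" log
    hazard ratio applied multiplicatively to the patient's event hazard.
    """

    subclonal_msi_odds: dict[str, float] = field(default_factory=dict)
    msi_burden_multiplier: float = 1.0
    log_hr: dict[str, float] = field(default_factory=dict)


@dataclass
class SimulationConfig:
    """Study conditions of the emulated cohort.

    Defaults mirror a TCGA-scale colorectal cohort: 536 patients, exome
    depth around 100x with a floor of 30, purity between 0.3 and 0.9,
    mostly diploid loci, and a driver panel whose rates and clonal biases
    echo the frequently mutated CRC genes.
    """

    n_patients: int = 536
    genes: list[GeneSpec] = field(default_factory=lambda: DEFAULT_GENES.copy())
    purity_range: tuple[float, float] = (0.3, 0.9)
    depth_mean: float = 100.0
    depth_floor: int = 30
    subclonal_ccf_range: tuple[float, float] = (0.1, 0.7)
    cn_states: list[tuple[int, float]] = field(
        default_factory=lambda: [(1, 0.10), (2, 0.70), (3, 0.15), (4, 0.05)]
    )
    clinical_effects: ClinicalEffects = field(default_factory=ClinicalEffects)
    msi_rate: float = 0.15
    baseline_hazard: float = 1.0 / 2000.0  # per day
    censor_rate: float = 0.55
    both_rate: float = 0.0  # chance of an extra opposite-clonality mutation
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.subclonal_ccf_range
        if not (0.0 < lo < hi < 0.9):
            raise ValueError("subclonal_ccf_range must lie strictly inside (0, 0.9)")
        if self.n_patients < 1:
            raise ValueError("need at least one patient")
        if not self.genes:
            raise ValueError("need at least one gene")
        total = sum(p for _, p in self.cn_states)
        if abs(total - 1.0) > 1e-9:
            raise ValueError("cn_states probabilities must sum to 1")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ValueError("censor_rate must be in [0, 1)")


#: Driver panel loosely following the frequently mutated CRC genes; the
#: clonal biases put most genes in the clonal-enriched regime with a few
#: subclonal-leaning ones (BCLAF1-like), matching the structure the
#: analysis is designed to detect.
DEFAULT_GENES: list[GeneSpec] = [
    GeneSpec("APC", 0.70, 0.85),
    GeneSpec("TP53", 0.55, 0.92),
    GeneSpec("KRAS", 0.42, 0.92),
    GeneSpec("PIK3CA", 0.25, 0.85),
    GeneSpec("FBXW7", 0.15, 0.80),
    GeneSpec("ARID1A", 0.15, 0.80),
    GeneSpec("FAT3", 0.15, 0.70),
    GeneSpec("BRAF", 0.12, 0.90),
    GeneSpec("SMAD4", 0.12, 0.75),
    GeneSpec("BCLAF1", 0.10, 0.35),
    GeneSpec("MLH1", 0.08, 0.50),
    GeneSpec("ANK1", 0.08, 0.50),
    GeneSpec("CASP8", 0.07, 0.80),
    GeneSpec("SMAD2", 0.06, 0.85),
    GeneSpec("TCF7L2", 0.12, 0.85),
]


@dataclass(frozen=True)
class TruthRecord:
    sample_id: str
    gene: str
    chrom: str
    pos: int
    true_ccf: float
    true_label: str  # clonal / subclonal
    local_cn: int
    purity: float


def simulate_reads(
    true_ccf: float,
    purity: float,
    local_cn: int,
    depth: int,
    rng: np.random.Generator,
) -> tuple[int, int]:
    """Draw (t_alt, t_depth) from the binomial observation model."""
    if not 0.0 < true_ccf <= 1.0:
        raise ValueError(f"true_ccf must be in (0, 1], got {true_ccf}")
    if local_cn < 1 or depth < 1:
        raise ValueError("local_cn and depth must be >= 1")
    vaf = expected_vaf(purity, true_ccf, local_cn)
    if not 0.0 <= vaf <= 1.0:
        raise ValueError(f"expected VAF {vaf} outside [0, 1]")
    return int(rng.binomial(depth, vaf)), int(depth)


def _gene_site(i: int, spec: GeneSpec) -> tuple[str, int]:
    chrom = spec.chrom if spec.chrom is not None else str(i % 22 + 1)
    pos = spec.pos if spec.pos is not None else 1_000_000 * (i + 1)
    return chrom, pos


def _truncated_poisson(rng: np.random.Generator, mean: float, floor: int, size: int) -> np.ndarray:
    out = rng.poisson(mean, size=size)
    bad = out < floor
    while bad.any():
        out[bad] = rng.poisson(mean, size=int(bad.sum()))
        bad = out < floor
    return out


def simulate_cohort(config: SimulationConfig) -> tuple[CohortBundle, list[TruthRecord]]:
    """Generate a cohort and its ground-truth clonality records.

    Fully reproducible from ``config.seed``. Each mutated patient x gene
    yields one mutation (plus, with probability ``both_rate``, a second of
    the opposite clonality at an offset position), a covering copy-number
    segment, and binomial read counts at a truncated-Poisson depth.
    """
    rng = np.random.default_rng(config.seed)
    eff = config.clinical_effects
    n = config.n_patients
    samples = [f"P{i:04d}" for i in range(n)]

    purity = rng.uniform(*config.purity_range, size=n)
    age = np.clip(rng.normal(66.0, 12.0, size=n), 30.0, 90.0)
    sex = np.where(rng.random(n) < 0.47, "female", "male")
    msi = rng.random(n) < config.msi_rate
    site = np.where(
        rng.random(n) < np.where(msi, 0.7, 0.3), "right-sided", "left-sided"
    )
    ajcc = rng.choice([1, 2, 3, 4], size=n, p=[0.20, 0.35, 0.30, 0.15])
    t_stage = rng.choice([1, 2, 3, 4], size=n, p=[0.05, 0.12, 0.63, 0.20])
    n_stage = np.where(ajcc <= 2, 0, rng.choice([1, 2], size=n, p=[0.6, 0.4]))
    m_stage = (ajcc == 4).astype(int)

    cn_vals = np.array([c for c, _ in config.cn_states])
    cn_probs = np.array([p for _, p in config.cn_states])
    lo, hi = config.subclonal_ccf_range

    mutations: list[MutationRecord] = []
    segments: list[CopyNumberSegment] = []
    truth: list[TruthRecord] = []
    log_hazard = np.full(n, np.log(config.baseline_hazard))

    for gi, spec in enumerate(config.genes):
        chrom, pos = _gene_site(gi, spec)
        rate = np.clip(
            spec.rate * np.where(msi, eff.msi_burden_multiplier, 1.0), 0.0, 0.95
        )
        mutated = rng.random(n) < rate

        odds = spec.clonal_bias / max(1.0 - spec.clonal_bias, 1e-12)
        sub_odds_mult = eff.subclonal_msi_odds.get(spec.name, 1.0)
        clonal_odds = np.where(msi, odds / sub_odds_mult, odds)
        p_clonal = clonal_odds / (1.0 + clonal_odds)
        is_clonal = rng.random(n) < p_clonal

        for pi in np.flatnonzero(mutated):
            entries = [bool(is_clonal[pi])]
            if config.both_rate > 0 and rng.random() < config.both_rate:
                entries.append(not entries[0])
            for j, clonal in enumerate(entries):
                mpos = pos + j * 100
                ccf = 1.0 if clonal else float(rng.uniform(lo, hi))
                cn = int(rng.choice(cn_vals, p=cn_probs))
                depth = int(_truncated_poisson(rng, config.depth_mean, config.depth_floor, 1)[0])
                t_alt, t_depth = simulate_reads(ccf, float(purity[pi]), cn, depth, rng)
                vclass = (
                    "frameshift-indel" if rng.random() < spec.indel_rate else "missense"
                )
                mutations.append(
                    MutationRecord(
                        sample_id=samples[pi], gene=spec.name, chrom=chrom, pos=mpos,
                        variant_class=vclass, t_alt=t_alt, t_depth=t_depth,
                    )
                )
                segments.append(
                    CopyNumberSegment(
                        sample_id=samples[pi], chrom=chrom,
                        start=max(1, pos - 1000), end=pos + 1000 + 100, absolute_cn=cn,
                    )
                )
                label = "clonal" if clonal else "subclonal"
                truth.append(
                    TruthRecord(samples[pi], spec.name, chrom, mpos, ccf, label,
                                cn, float(purity[pi]))
                )
                key = f"{spec.name}:{label}"
                if key in eff.log_hr:
                    log_hazard[pi] += eff.log_hr[key]

    # collapse duplicate segments (both-clonality pairs share one segment)
    seen: set[tuple] = set()
    uniq_segments = []
    for s in segments:
        k = (s.sample_id, s.chrom, s.start, s.end)
        if k not in seen:
            seen.add(k)
            uniq_segments.append(s)

    event_time = rng.exponential(1.0 / np.exp(log_hazard))
    censored = rng.random(n) < config.censor_rate
    os_time = np.where(censored, rng.uniform(0.0, event_time), event_time)
    os_event = (~censored).astype(int)

    clinical = [
        ClinicalRecord(
            sample_id=samples[i],
            age=float(round(age[i], 1)),
            sex=str(sex[i]),
            msi_status="MSI" if msi[i] else "MSS",
            tumour_site=str(site[i]),
            ajcc_stage=int(ajcc[i]),
            t_stage=int(t_stage[i]),
            n_stage=int(n_stage[i]),
            m_stage=int(m_stage[i]),
            os_time=float(round(os_time[i], 2)),
            os_event=int(os_event[i]),
        )
        for i in range(n)
    ]
    purities = [SamplePurity(samples[i], float(round(purity[i], 4))) for i in range(n)]
    bundle = CohortBundle(
        mutations=mutations, segments=uniq_segments, purities=purities, clinical=clinical
    )
    return bundle, truth


def write_cohort(
    bundle: CohortBundle, truth: list[TruthRecord], out_dir: str | Path
) -> dict[str, Path]:
    """Write the four cohort TSVs plus truth.tsv; re-readable by io readers."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "maf": write_maf(bundle.mutations, out / "maf.tsv"),
        "segments": write_segments(bundle.segments, out / "segments.tsv"),
        "purity": write_purity(bundle.purities, out / "purity.tsv"),
        "clinical": write_clinical(bundle.clinical, out / "clinical.tsv"),
    }
    tdf = pd.DataFrame([dataclasses.asdict(t) for t in truth])
    if len(tdf):
        tdf["true_ccf"] = tdf["true_ccf"].map(lambda v: f"{v:.6g}")
        tdf["purity"] = tdf["purity"].map(lambda v: f"{v:.6g}")
    tdf.to_csv(out / "truth.tsv", sep="\t", index=False)
    paths["truth"] = out / "truth.tsv"
    return paths


def config_from_dict(data: dict) -> SimulationConfig:
    """Build a SimulationConfig from a parsed YAML/JSON mapping."""
    data = dict(data)
    if "genes" in data:
        data["genes"] = [
            GeneSpec(**g) if isinstance(g, dict) else g for g in data["genes"]
        ]
    if "clinical_effects" in data and isinstance(data["clinical_effects"], dict):
        data["clinical_effects"] = ClinicalEffects(**data["clinical_effects"])
    for key in ("purity_range", "subclonal_ccf_range"):
        if key in data:
            data[key] = tuple(data[key])
    if "cn_states" in data:
        data["cn_states"] = [tuple(x) for x in data["cn_states"]]
    return SimulationConfig(**data)
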