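"""Domain types and tab-separated readers/writers for somatic-mutation cohorts.

The pipeline consumes four tables: a MAF-style somatic mutation table
(TCGA column conventions), a SEG-style absolute copy-number segment table,
a per-sample tumor purity table, and a per-patient clinical table.
Coordinates are 1-based and inclusive on both the MAF and SEG side.
Missing values are encoded as "NA" on output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

NA = "NA"

#: Variant classes counted as non-silent. Configurable; silent/UTR/intron
#: classes never enter the clonality analyses.
NON_SILENT_CLASSES = frozenset(
    {
        "missense",
        "nonsense",
        "frameshift-indel",
        "in-frame-indel",
        "splice-site",
        "nonstop",
        "translation-start-site",
    }
)

#: TCGA MAF Variant_Classification spellings mapped onto the internal classes.
MAF_CLASS_ALIASES = {
    "Missense_Mutation": "missense",
    "Nonsense_Mutation": "nonsense",
    "Frame_Shift_Del": "frameshift-indel",
    "Frame_Shift_Ins": "frameshift-indel",
    "In_Frame_Del": "in-frame-indel",
    "In_Frame_Ins": "in-frame-indel",
    "Splice_Site": "splice-site",
    "Nonstop_Mutation": "nonstop",
    "Translation_Start_Site": "translation-start-site",
    "Silent": "silent",
}

INDEL_CLASSES = frozenset({"frameshift-indel", "in-frame-indel"})

AUTOSOMES = frozenset(str(i) for i in range(1, 23)) | frozenset(
    f"chr{i}" for i in range(1, 23)
)


class CohortIOError(ValueError):
    """Raised on contract violations in the input tables."""


@dataclass(frozen=True)
class MutationRecord:
    """One somatic variant with its tumor read counts."""

    sample_id: str
    gene: str
    chrom: str
    pos: int
    variant_class: str
    t_alt: int
    t_depth: int

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise CohortIOError(f"pos must be >= 1, got {self.pos}")
        if self.t_depth < 1:
            raise CohortIOError(f"t_depth must be >= 1, got {self.t_depth}")
        if not 0 <= self.t_alt <= self.t_depth:
            raise CohortIOError(
                f"t_alt must satisfy 0 <= t_alt <= t_depth, got {self.t_alt}/{self.t_depth}"
            )

    @property
    def vaf(self) -> float:
        return self.t_alt / self.t_depth

    @property
    def is_non_silent(self) -> bool:
        return self.variant_class in NON_SILENT_CLASSES

    @property
    def key(self) -> tuple[str, str, str, int]:
        return (self.sample_id, self.gene, self.chrom, self.pos)


@dataclass(frozen=True)
class CopyNumberSegment:
    """Absolute tumor copy number over a 1-based inclusive interval."""

    sample_id: str
    chrom: str
    start: int
    end: int
    absolute_cn: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise CohortIOError(f"segment start {self.start} > end {self.end}")
        if self.absolute_cn < 0:
            raise CohortIOError(f"absolute_cn must be >= 0, got {self.absolute_cn}")

    def covers(self, pos: int) -> bool:
        return self.start <= pos <= self.end


@dataclass(frozen=True)
class SamplePurity:
    """Tumor purity (cancer-cell fraction of the bulk sample) in (0, 1]."""

    sample_id: str
    purity: float

    def __post_init__(self) -> None:
        if not 0.0 < self.purity <= 1.0:
            raise CohortIOError(f"purity must be in (0, 1], got {self.purity}")


@dataclass(frozen=True)
class ClinicalRecord:
    """Per-patient clinicopathological covariates and overall survival."""

    sample_id: str
    age: float | None = None
    sex: str | None = None  # female / male
    msi_status: str | None = None  # MSI / MSS
    tumour_site: str | None = None  # left-sided / right-sided
    ajcc_stage: int | None = None  # 1..4
    t_stage: int | None = None  # 1..4
    n_stage: int | None = None  # 0..2
    m_stage: int | None = None  # 0..1
    os_time: float | None = None
    os_event: int | None = None  # 0 censored, 1 death

    def __post_init__(self) -> None:
        if self.os_time is not None and self.os_time < 0:
            raise CohortIOError(f"os_time must be >= 0, got {self.os_time}")


@dataclass
class SkipReport:
    """Bookkeeping for rows a reader dropped or coerced to missing."""

    n_rows: int = 0
    n_kept: int = 0
    n_skipped: int = 0
    reasons: dict[str, int] = field(default_factory=dict)
    n_warnings: int = 0

    def skip(self, reason: str) -> None:
        self.n_skipped += 1
        self.reasons[reason] = self.reasons.get(reason, 0) + 1

    def warn(self, reason: str) -> None:
        self.n_warnings += 1
        self.reasons[reason] = self.reasons.get(reason, 0) + 1


@dataclass
class CohortBundle:
    """All per-cohort inputs joined by sample_id."""

    mutations: list[MutationRecord]
    segments: list[CopyNumberSegment]
    purities: list[SamplePurity]
    clinical: list[ClinicalRecord]

    def purity_map(self) -> dict[str, float]:
        return {p.sample_id: p.purity for p in self.purities}

    def sample_ids(self) -> list[str]:
        return [c.sample_id for c in self.clinical]

    def unresolvable_samples(self) -> set[str]:
        """Mutation sample_ids with no purity record."""
        have = {p.sample_id for p in self.purities}
        return {m.sample_id for m in self.mutations} - have


# ---------------------------------------------------------------------------
# readers


_MAF_REQUIRED = [
    "Hugo_Symbol",
    "Chromosome",
    "Start_Position",
    "Variant_Classification",
    "t_alt_count",
    "Tumor_Sample_Barcode",
]


def _read_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[0] == 0:
        raise CohortIOError(f"{path}: no data rows")
    return df


def _require(df: pd.DataFrame, cols: Iterable[str], path: str | Path) -> None:
    for col in cols:
        if col not in df.columns:
            raise CohortIOError(f"{path}: missing required column '{col}'")


def _to_int(value: str) -> int | None:
    try:
        f = float(value)
    except (TypeError, ValueError):
        return None
    if not np.isfinite(f) or f != int(f):
        return None
    return int(f)


def read_maf(
    path: str | Path, *, class_aliases: dict[str, str] | None = None
) -> tuple[list[MutationRecord], SkipReport]:
    """Read a MAF-style TSV into MutationRecords.

    ``t_depth`` is taken from the ``t_depth`` column when present, else
    computed as ``t_alt_count + t_ref_count``. Rows whose counts or position
    cannot be parsed are dropped and tallied in the returned SkipReport.
    """
    aliases = MAF_CLASS_ALIASES if class_aliases is None else class_aliases
    df = _read_tsv(path)
    _require(df, _MAF_REQUIRED, path)
    if "t_ref_count" not in df.columns and "t_depth" not in df.columns:
        raise CohortIOError(f"{path}: missing required column 't_ref_count' (or 't_depth')")

    report = SkipReport(n_rows=len(df))
    records: list[MutationRecord] = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        pos = _to_int(d["Start_Position"])
        t_alt = _to_int(d["t_alt_count"])
        if "t_depth" in d and _to_int(d["t_depth"]) is not None:
            t_depth = _to_int(d["t_depth"])
        else:
            t_ref = _to_int(d.get("t_ref_count", ""))
            t_depth = None if (t_ref is None or t_alt is None) else t_alt + t_ref
        if pos is None or pos < 1:
            report.skip("unparseable-position")
            continue
        if t_alt is None or t_depth is None:
            report.skip("unparseable-counts")
            continue
        if t_depth < 1 or t_alt < 0 or t_alt > t_depth:
            report.skip("invalid-counts")
            continue
        vclass = d["Variant_Classification"]
        vclass = aliases.get(vclass, vclass)
        records.append(
            MutationRecord(
                sample_id=d["Tumor_Sample_Barcode"],
                gene=d["Hugo_Symbol"],
                chrom=str(d["Chromosome"]),
                pos=pos,
                variant_class=vclass,
                t_alt=t_alt,
                t_depth=t_depth,
            )
        )
    report.n_kept = len(records)
    return records, report


def write_maf(records: Sequence[MutationRecord], path: str | Path) -> Path:
    """Write MutationRecords back to a MAF-style TSV (round-trips read_maf)."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "Hugo_Symbol": [r.gene for r in records],
            "Chromosome": [r.chrom for r in records],
            "Start_Position": [r.pos for r in records],
            "Variant_Classification": [r.variant_class for r in records],
            "t_alt_count": [r.t_alt for r in records],
            "t_ref_count": [r.t_depth - r.t_alt for r in records],
            "Tumor_Sample_Barcode": [r.sample_id for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)
    return path


def read_segments(path: str | Path) -> tuple[list[CopyNumberSegment], SkipReport]:
    """Read a SEG-style TSV with an explicit integer absolute_cn column.

    Segments are returned sorted per (sample, chrom) by start; overlapping
    segments within one sample+chromosome are a hard error.
    """
    df = _read_tsv(path)
    _require(df, ["sample", "chrom", "start", "end", "absolute_cn"], path)
    report = SkipReport(n_rows=len(df))
    segs: list[CopyNumberSegment] = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        start, end = _to_int(d["start"]), _to_int(d["end"])
        cn = _to_int(d["absolute_cn"])
        if cn is None:
            raise CohortIOError(
                f"{path}: non-integer absolute_cn '{d['absolute_cn']}' "
                f"(sample {d['sample']}, {d['chrom']}:{d['start']}-{d['end']})"
            )
        if start is None or end is None:
            report.skip("unparseable-interval")
            continue
        segs.append(
            CopyNumberSegment(
                sample_id=d["sample"], chrom=str(d["chrom"]), start=start, end=end, absolute_cn=cn
            )
        )
    segs.sort(key=lambda s: (s.sample_id, s.chrom, s.start, s.end))
    for a, b in zip(segs, segs[1:]):
        if a.sample_id == b.sample_id and a.chrom == b.chrom and b.start <= a.end:
            raise CohortIOError(
                f"{path}: overlapping segments for sample {a.sample_id} {a.chrom}: "
                f"{a.start}-{a.end} and {b.start}-{b.end}"
            )
    report.n_kept = len(segs)
    return segs, report


def write_segments(segments: Sequence[CopyNumberSegment], path: str | Path) -> Path:
    df = pd.DataFrame(
        {
            "sample": [s.sample_id for s in segments],
            "chrom": [s.chrom for s in segments],
            "start": [s.start for s in segments],
            "end": [s.end for s in segments],
            "absolute_cn": [s.absolute_cn for s in segments],
        }
    )
    df.to_csv(path, sep="\t", index=False)
    return path


def read_purity(path: str | Path) -> tuple[list[SamplePurity], SkipReport]:
    """Read the per-sample purity TSV; purity outside (0, 1] is a hard error."""
    df = _read_tsv(path)
    _require(df, ["sample", "purity"], path)
    report = SkipReport(n_rows=len(df))
    seen: set[str] = set()
    out: list[SamplePurity] = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        sid = d["sample"]
        if sid in seen:
            raise CohortIOError(f"{path}: duplicate sample_id '{sid}'")
        seen.add(sid)
        try:
            purity = float(d["purity"])
        except ValueError as exc:
            raise CohortIOError(f"{path}: unparseable purity '{d['purity']}'") from exc
        if not 0.0 < purity <= 1.0:
            raise CohortIOError(f"{path}: purity {purity} outside (0, 1] for sample {sid}")
        out.append(SamplePurity(sample_id=sid, purity=purity))
    report.n_kept = len(out)
    return out, report


def write_purity(purities: Sequence[SamplePurity], path: str | Path) -> Path:
    df = pd.DataFrame(
        {"sample": [p.sample_id for p in purities], "purity": [f"{p.purity:.6g}" for p in purities]}
    )
    df.to_csv(path, sep="\t", index=False)
    return path


_CLINICAL_DOMAINS = {
    "sex": {"female", "male"},
    "msi_status": {"MSI", "MSS"},
    "tumour_site": {"left-sided", "right-sided"},
    "ajcc_stage": {1, 2, 3, 4},
    "t_stage": {1, 2, 3, 4},
    "n_stage": {0, 1, 2},
    "m_stage": {0, 1},
}


def read_clinical(path: str | Path) -> tuple[list[ClinicalRecord], SkipReport]:
    """Read the clinical TSV.

    Categorical values outside their stated domain become missing and are
    counted as warnings in the SkipReport; duplicate sample_ids are a hard
    error.
    """
    df = _read_tsv(path)
    _require(df, ["sample"], path)
    report = SkipReport(n_rows=len(df))
    seen: set[str] = set()
    out: list[ClinicalRecord] = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        sid = d["sample"]
        if sid in seen:
            raise CohortIOError(f"{path}: duplicate sample_id '{sid}'")
        seen.add(sid)

        def cat(name: str):
            raw = d.get(name, NA)
            if raw in ("", NA):
                return None
            domain = _CLINICAL_DOMAINS[name]
            value = raw
            if all(isinstance(v, int) for v in domain):
                value = _to_int(raw)
            if value not in domain:
                report.warn(f"{name}-out-of-domain")
                return None
            return value

        def num(name: str):
            raw = d.get(name, NA)
            if raw in ("", NA):
                return None
            try:
                return float(raw)
            except ValueError:
                report.warn(f"{name}-unparseable")
                return None

        os_event = _to_int(d.get("os_event", NA)) if d.get("os_event", NA) not in ("", NA) else None
        if os_event is not None and os_event not in (0, 1):
            report.warn("os_event-out-of-domain")
            os_event = None
        out.append(
            ClinicalRecord(
                sample_id=sid,
                age=num("age"),
                sex=cat("sex"),
                msi_status=cat("msi_status"),
                tumour_site=cat("tumour_site"),
                ajcc_stage=cat("ajcc_stage"),
                t_stage=cat("t_stage"),
                n_stage=cat("n_stage"),
                m_stage=cat("m_stage"),
                os_time=num("os_time"),
                os_event=os_event,
            )
        )
    report.n_kept = len(out)
    return out, report


def write_clinical(records: Sequence[ClinicalRecord], path: str | Path) -> Path:
    rows = []
    for r in records:
        d = dataclasses.asdict(r)
        d["sample"] = d.pop("sample_id")
        for k, v in d.items():
            if v is None:
                d[k] = NA
            elif isinstance(v, float):
                d[k] = f"{v:.6g}"
        rows.append(d)
    cols = [
        "sample",
        "age",
        "sex",
        "msi_status",
        "tumour_site",
        "ajcc_stage",
        "t_stage",
        "n_stage",
        "m_stage",
        "os_time",
        "os_event",
    ]
    pd.DataFrame(rows)[cols].to_csv(path, sep="\t", index=False)
    return path


def clinical_frame(records: Sequence[ClinicalRecord]) -> pd.DataFrame:
    """Clinical records as a DataFrame indexed by sample_id (None -> NaN)."""
    df = pd.DataFrame([dataclasses.asdict(r) for r in records])
    return df.set_index("sample_id")


def read_cohort(
    maf: str | Path, seg: str | Path, purity: str | Path, clinical: str | Path
) -> tuple[CohortBundle, dict[str, SkipReport]]:
    """Read all four tables into a CohortBundle plus per-table skip reports."""
    muts, r1 = read_maf(maf)
    segs, r2 = read_segments(seg)
    purs, r3 = read_purity(purity)
    clin, r4 = read_clinical(clinical)
    bundle = CohortBundle(mutations=muts, segments=segs, purities=purs, clinical=clin)
    return bundle, {"maf": r1, "segments": r2, "purity": r3, "clinical": r4}
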