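"""Variant filtering, per-sample detection, burden trajectories, spectrum.

The calling rule for emergent resistance mutations in plasma: keep coding,
non-silent variants, drop the common germline P72R polymorphism, and
require VAF strictly above the calibrated threshold (1% by default). A
sample is "detected" when at least one variant passes; per-patient burden
is the sum of passing-variant VAFs expressed in percent. The substitution
spectrum (transitions vs transversions) over unique mutation events feeds
the test against a chemotherapy-exposed haematopoietic origin.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .variant_io import SampleRecord, VariantCall

#: Germline polymorphism excluded from all analyses.
GERMLINE_POLYMORPHISM = "P72R"

#: Effects that are non-coding or silent and therefore excluded.
_EXCLUDED_EFFECTS = frozenset({"silent", "noncoding"})

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


@dataclass(frozen=True)
class BurdenPoint:
    """Mutation allele burden for one patient at one timepoint."""

    patient_id: str
    timepoint_weeks: float
    burden_pct: float  # sum of passing-variant VAFs x 100
    n_passing: int

    def __post_init__(self) -> None:
        if self.burden_pct < 0:
            raise ValueError("burden cannot be negative")
        if self.n_passing == 0 and self.burden_pct != 0:
            raise ValueError("burden must be 0 with no passing variants")

    @property
    def detected(self) -> bool:
        return self.n_passing >= 1


@dataclass(frozen=True)
class SpectrumCounts:
    n_transitions: int
    n_transversions: int

    @property
    def n_total(self) -> int:
        return self.n_transitions + self.n_transversions

    @property
    def transversion_fraction(self) -> float:
        return self.n_transversions / self.n_total if self.n_total else 0.0


def filter_variants(
    variants: Iterable[VariantCall], vaf_threshold: float = 0.01
) -> list[VariantCall]:
    """Apply the calling rule: coding and non-silent, not the germline
    P72R polymorphism, and VAF strictly above the threshold.

    Indels are retained when coding and non-silent. Stable order;
    idempotent.
    """
    if not 0.0 < vaf_threshold < 1.0:
        raise ValueError("vaf_threshold must be in (0, 1)")
    return [
        v
        for v in variants
        if v.effect not in _EXCLUDED_EFFECTS
        and v.protein_change != GERMLINE_POLYMORPHISM
        and v.vaf > vaf_threshold
    ]


def sample_detected(record: SampleRecord, vaf_threshold: float = 0.01) -> bool:
    """True iff at least one variant passes the calling rule."""
    if record.material != "plasma_cfdna":
        raise ValueError(
            f"detection is defined for plasma cfDNA, got {record.material}"
        )
    return len(filter_variants(record.variants, vaf_threshold)) >= 1


def burden_series(
    records: Sequence[SampleRecord], vaf_threshold: float = 0.01
) -> list[BurdenPoint]:
    """Per-timepoint allele burden for one patient, sorted by week.

    Burden at a timepoint is the sum over passing variants of VAF x 100;
    a timepoint with no passing variants contributes burden 0 and
    detected=False.
    """
    if not records:
        return []
    patients = {r.patient_id for r in records}
    if len(patients) > 1:
        raise ValueError(f"records span multiple patients: {sorted(patients)}")
    points = []
    for rec in records:
        if rec.material != "plasma_cfdna":
            raise ValueError(f"sample {rec.sample_id!r} is not plasma cfDNA")
        if rec.timepoint_weeks is None:
            raise ValueError(f"sample {rec.sample_id!r} lacks a timepoint")
        passing = filter_variants(rec.variants, vaf_threshold)
        points.append(
            BurdenPoint(
                patient_id=rec.patient_id,
                timepoint_weeks=rec.timepoint_weeks,
                burden_pct=100.0 * sum(v.vaf for v in passing),
                n_passing=len(passing),
            )
        )
    return sorted(points, key=lambda p: p.timepoint_weeks)


def classify_substitution(ref: str, alt: str) -> str:
    """``transition`` (purine<->purine or pyrimidine<->pyrimidine) or
    ``transversion`` (purine<->pyrimidine); SNVs only."""
    if len(ref) != 1 or len(alt) != 1:
        raise ValueError("spectrum is defined for single-nucleotide variants only")
    ref, alt = ref.upper(), alt.upper()
    if ref == alt:
        raise ValueError("ref and alt are identical")
    for base in (ref, alt):
        if base not in _PURINES | _PYRIMIDINES:
            raise ValueError(f"not a DNA base: {base!r}")
    same_class = (ref in _PURINES) == (alt in _PURINES)
    return "transition" if same_class else "transversion"


def spectrum(
    variants: Iterable[VariantCall],
    patient_of: dict[str, str] | None = None,
    dedup: str = "per_patient",
) -> SpectrumCounts:
    """Transition/transversion counts over unique SNV mutation events.

    A mutation observed at several timepoints of the same patient is one
    event. ``dedup`` chooses the identity used: ``per_patient`` counts
    unique (patient, contig, pos, ref, alt) tuples (``patient_of`` maps
    sample_id -> patient_id; defaults to sample_id); ``cohort`` counts
    unique (contig, pos, ref, alt) across all samples. Indels are ignored.
    """
    if dedup not in ("per_patient", "cohort"):
        raise ValueError(f"unknown dedup mode {dedup!r}")
    seen: set[tuple] = set()
    n_ts = n_tv = 0
    for v in variants:
        if not v.is_snv:
            continue
        if dedup == "per_patient":
            patient = (patient_of or {}).get(v.sample_id, v.sample_id)
            ident = (patient, *v.key)
        else:
            ident = v.key
        if ident in seen:
            continue
        seen.add(ident)
        if classify_substitution(v.ref, v.alt) == "transition":
            n_ts += 1
        else:
            n_tv += 1
    return SpectrumCounts(n_transitions=n_ts, n_transversions=n_tv)
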