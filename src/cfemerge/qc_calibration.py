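"""Strand-bias QC and data-driven VAF-threshold calibration.

Two empirical observations anchor the calling threshold for plasma cfDNA:
healthy-donor plasma yields many low-frequency artefact calls that are
strongly strand-biased and stay below ~0.5% VAF, and in matched
tumour/plasma pairs the cfDNA variants above 1% VAF are overwhelmingly
confirmed in the tumour while those below are not. This module scores
strand bias (ALT_RATIO) and tabulates tumour concordance above/below a
candidate VAF threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .variant_io import SampleRecord, VariantCall


@dataclass(frozen=True)
class ConcordanceTable:
    """Tumour-concordance counts for cfDNA variants split at a VAF threshold."""

    threshold_vaf: float
    n_above: int
    n_above_concordant: int
    n_below: int
    n_below_concordant: int

    def __post_init__(self) -> None:
        if self.n_above_concordant > self.n_above:
            raise ValueError("concordant count exceeds total above threshold")
        if self.n_below_concordant > self.n_below:
            raise ValueError("concordant count exceeds total below threshold")

    @property
    def pct_above(self) -> float:
        """Percent of above-threshold cfDNA variants also seen in tumour."""
        return 100.0 * self.n_above_concordant / self.n_above if self.n_above else 0.0

    @property
    def pct_below(self) -> float:
        return 100.0 * self.n_below_concordant / self.n_below if self.n_below else 0.0


@dataclass(frozen=True)
class NoiseProfile:
    """Aggregate of a healthy-donor (normal plasma) panel's variant calls."""

    n_samples: int
    max_vaf: float
    per_variant: tuple[tuple[VariantCall, float], ...]  # (variant, alt_ratio)


def compute_alt_ratio(alt_fwd: int, alt_rev: int) -> float:
    """Strand-bias score: fraction of alt reads on the less-abundant strand.

    0.5 means perfectly balanced (no bias); 0 means all alt reads on one
    strand (maximally artefact-like). Symmetric under swapping strands.
    """
    total = alt_fwd + alt_rev
    if total <= 0:
        raise ValueError("no alt-supporting reads: ALT_RATIO undefined")
    if min(alt_fwd, alt_rev) < 0:
        raise ValueError("negative strand count")
    return min(alt_fwd, alt_rev) / total


def strand_bias_flag(v: VariantCall, min_alt_ratio: float = 0.25) -> bool:
    """True if the variant looks artefact-like (ALT_RATIO strictly below
    the cutoff). Advisory QC only — the hard filter is the VAF threshold."""
    return compute_alt_ratio(v.alt_fwd, v.alt_rev) < min_alt_ratio


def noise_ceiling(panel: Sequence[SampleRecord]) -> NoiseProfile:
    """Aggregate all variants of a normal-plasma panel with per-variant
    ALT_RATIO, reporting the maximum VAF observed (0 for an empty panel)."""
    for rec in panel:
        if rec.material != "normal_plasma":
            raise ValueError(
                f"sample {rec.sample_id!r} is {rec.material}, expected normal_plasma"
            )
    per_variant = tuple(
        (v, compute_alt_ratio(v.alt_fwd, v.alt_rev))
        for rec in panel
        for v in rec.variants
    )
    max_vaf = max((v.vaf for v, _ in per_variant), default=0.0)
    return NoiseProfile(n_samples=len(panel), max_vaf=max_vaf, per_variant=per_variant)


def concordance_at_threshold(
    pairs: Sequence[tuple[SampleRecord, SampleRecord]],
    threshold_vaf: float,
) -> ConcordanceTable:
    """Tabulate tumour concordance of cfDNA variants at a VAF threshold.

    A cfDNA variant is concordant iff a variant with identical
    (contig, pos, ref, alt) exists in the matched tumour sample, at any
    tumour VAF. "Above" is strict (VAF > threshold); a variant exactly at
    the threshold counts as below.
    """
    if not 0.0 < threshold_vaf < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    n_above = n_above_conc = n_below = n_below_conc = 0
    for plasma, tumour in pairs:
        if plasma.patient_id != tumour.patient_id:
            raise ValueError(
                f"unmatched pair: plasma {plasma.patient_id!r} vs "
                f"tumour {tumour.patient_id!r}"
            )
        tumour_keys = {v.key for v in tumour.variants}
        for v in plasma.variants:
            concordant = v.key in tumour_keys
            if v.vaf > threshold_vaf:
                n_above += 1
                n_above_conc += concordant
            else:
                n_below += 1
                n_below_conc += concordant
    return ConcordanceTable(
        threshold_vaf=threshold_vaf,
        n_above=n_above,
        n_above_concordant=n_above_conc,
        n_below=n_below,
        n_below_concordant=n_below_conc,
    )
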