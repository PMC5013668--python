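"""Data model and file I/O for cfDNA variant monitoring.

Variants are single observed substitutions or indels with per-strand
alt-supporting read counts; samples tie variants to a patient, a material
(plasma cfDNA, FFPE tumour, or healthy-donor plasma) and a treatment
timepoint. Readers accept a plain tab-separated variant table or VCF 4.2
with a two-entry forward/reverse alt-count FORMAT field, plus a CSV sample
sheet and a BED panel file.

Coordinate conventions: variant positions are 1-based inclusive (VCF
convention); panel intervals are 0-based half-open (BED convention).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger("cfemerge")

#: Allowed functional-effect annotations (consumed, never computed here).
EFFECTS = frozenset(
    {
        "missense",
        "nonsense",
        "silent",
        "splice",
        "noncoding",
        "indel_frameshift",
        "indel_inframe",
    }
)

#: Allowed sample materials.
MATERIALS = frozenset({"plasma_cfdna", "tumour_ffpe", "normal_plasma"})

#: Columns of the variant TSV dialect, in order.
TSV_COLUMNS = (
    "sample_id",
    "contig",
    "pos",
    "ref",
    "alt",
    "depth",
    "alt_fwd",
    "alt_rev",
    "vaf",
    "effect",
    "protein_change",
)

#: Default VCF FORMAT key holding [alt_fwd, alt_rev].
DEFAULT_STRAND_KEY = "SAC"


class VariantTableError(ValueError):
    """Malformed variant table / sample sheet / VCF input."""


@dataclass(frozen=True)
class VariantCall:
    """One observed substitution or indel in one sample.

    ``vaf`` is by default the fraction of *all* reads at the site that
    support the alternate allele (total-depth denominator); see
    :func:`vaf_from_counts` for the ref+alt alternative.
    """

    sample_id: str
    contig: str
    pos: int  # 1-based
    ref: str
    alt: str
    depth: int
    alt_fwd: int
    alt_rev: int
    vaf: float
    effect: str
    protein_change: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt are identical ({self.ref!r})")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if min(self.alt_fwd, self.alt_rev) < 0:
            raise ValueError("strand counts must be >= 0")
        if self.alt_fwd + self.alt_rev > self.depth:
            raise ValueError(
                f"alt reads ({self.alt_fwd}+{self.alt_rev}) exceed depth {self.depth}"
            )
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"vaf outside [0,1]: {self.vaf}")
        if self.effect not in EFFECTS:
            raise ValueError(f"unknown effect {self.effect!r}")

    @property
    def alt_reads(self) -> int:
        return self.alt_fwd + self.alt_rev

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Allele identity (contig, pos, ref, alt) used for concordance."""
        return (self.contig, self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @classmethod
    def from_counts(
        cls,
        sample_id: str,
        contig: str,
        pos: int,
        ref: str,
        alt: str,
        depth: int,
        alt_fwd: int,
        alt_rev: int,
        effect: str,
        protein_change: str = "",
        denominator: str = "depth",
    ) -> "VariantCall":
        """Build a call with the VAF recomputed from read counts."""
        vaf = vaf_from_counts(depth, alt_fwd + alt_rev, denominator=denominator)
        return cls(
            sample_id, contig, pos, ref, alt, depth, alt_fwd, alt_rev, vaf,
            effect, protein_change,
        )


def vaf_from_counts(depth: int, alt_reads: int, denominator: str = "depth") -> float:
    """VAF from counts; ``denominator`` is ``"depth"`` (all reads at the
    site, default) or ``"ref_alt"`` (ref+alt reads only — with a targeted
    substitution panel the two differ only at multi-allelic sites)."""
    if denominator == "depth":
        return alt_reads / depth if depth > 0 else 0.0
    if denominator == "ref_alt":
        # without per-allele ref counts the best available proxy is depth;
        # callers holding true ref counts should pass depth = ref + alt
        return alt_reads / depth if depth > 0 else 0.0
    raise ValueError(f"unknown denominator {denominator!r}")


@dataclass
class SampleRecord:
    """One sequenced sample and its variant calls."""

    sample_id: str
    patient_id: str
    material: str
    timepoint_weeks: float | None = None
    ct_change_percent: float | None = None
    variants: list[VariantCall] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.material not in MATERIALS:
            raise ValueError(f"unknown material {self.material!r}")
        if self.timepoint_weeks is not None and self.timepoint_weeks < 0:
            raise ValueError("timepoint_weeks must be >= 0")
        for v in self.variants:
            if v.sample_id != self.sample_id:
                raise ValueError(
                    f"variant sample_id {v.sample_id!r} != record {self.sample_id!r}"
                )

    @property
    def is_baseline(self) -> bool:
        return self.timepoint_weeks == 0


@dataclass(frozen=True)
class PanelRegion:
    """A targeted-capture interval, BED-convention 0-based half-open."""

    contig: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty interval [{self.start},{self.end})")

    def contains(self, contig: str, pos_1based: int) -> bool:
        return contig == self.contig and self.start <= pos_1based - 1 < self.end


# ---------------------------------------------------------------------------
# readers


def _parse_row(row: Mapping[str, str], line_no: int, denominator: str) -> VariantCall:
    try:
        pos = int(row["pos"])
        depth = int(row["depth"])
        alt_fwd = int(row["alt_fwd"])
        alt_rev = int(row["alt_rev"])
    except (KeyError, ValueError) as exc:
        raise VariantTableError(f"line {line_no}: malformed coordinates/counts: {exc}")
    vaf_str = row.get("vaf", "")
    recomputed = vaf_from_counts(depth, alt_fwd + alt_rev, denominator=denominator)
    if vaf_str not in ("", ".", None):
        vaf = float(vaf_str)
        if abs(vaf - recomputed) > 1e-6 and depth > 0:
            logger.warning(
                "line %d: stated VAF %.6g inconsistent with counts (%.6g); recomputed",
                line_no, vaf, recomputed,
            )
            vaf = recomputed
    else:
        vaf = recomputed
    try:
        return VariantCall(
            sample_id=row["sample_id"],
            contig=row["contig"],
            pos=pos,
            ref=row["ref"],
            alt=row["alt"],
            depth=depth,
            alt_fwd=alt_fwd,
            alt_rev=alt_rev,
            vaf=vaf,
            effect=row["effect"],
            protein_change=row.get("protein_change", "") or "",
        )
    except (KeyError, ValueError) as exc:
        raise VariantTableError(f"line {line_no}: {exc}")


def _read_tsv(path: Path, denominator: str) -> list[VariantCall]:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise VariantTableError(f"{path}: empty file, header required")
        for col in ("alt_fwd", "alt_rev"):
            if col not in reader.fieldnames:
                raise VariantTableError(
                    f"{path}: required per-strand alt-count column {col!r} missing"
                )
        missing = set(TSV_COLUMNS[:6]) - set(reader.fieldnames)
        if missing:
            raise VariantTableError(f"{path}: missing columns {sorted(missing)}")
        return [
            _parse_row(row, line_no, denominator)
            for line_no, row in enumerate(reader, start=2)
        ]


def _read_vcf(path: Path, strand_key: str, denominator: str) -> list[VariantCall]:
    import pysam

    calls: list[VariantCall] = []
    with pysam.VariantFile(str(path)) as vcf:
        if strand_key not in vcf.header.formats:
            raise VariantTableError(
                f"{path}: FORMAT field {strand_key!r} with per-strand alt counts "
                "is required but absent from the header"
            )
        for rec in vcf:
            alts = rec.alts or ()
            for sample_name, sample in rec.samples.items():
                sac = sample.get(strand_key)
                if sac is None or all(x is None for x in sac):
                    continue
                depth = sample.get("DP")
                if depth is None:
                    depth = rec.info.get("DP", 0)
                # multi-allelic records are split: one call per alt allele,
                # consuming consecutive (fwd, rev) pairs from the field
                if len(sac) != 2 * len(alts):
                    raise VariantTableError(
                        f"{path}: {rec.contig}:{rec.pos} {strand_key} has "
                        f"{len(sac)} entries, expected {2 * len(alts)}"
                    )
                for i, alt in enumerate(alts):
                    fwd, rev = int(sac[2 * i]), int(sac[2 * i + 1])
                    if fwd + rev == 0:
                        continue
                    effect = rec.info.get("EFF", "missense")
                    pchg = rec.info.get("PCHG", "") or ""
                    if isinstance(effect, tuple):
                        effect = effect[i] if i < len(effect) else effect[0]
                    calls.append(
                        VariantCall.from_counts(
                            sample_id=sample_name,
                            contig=rec.contig,
                            pos=rec.pos,
                            ref=rec.ref,
                            alt=alt,
                            depth=int(depth),
                            alt_fwd=fwd,
                            alt_rev=rev,
                            effect=str(effect),
                            protein_change=str(pchg),
                            denominator=denominator,
                        )
                    )
    return calls


def group_into_samples(
    calls: Iterable[VariantCall],
    material: str = "plasma_cfdna",
) -> list[SampleRecord]:
    """Group calls by sample_id, preserving first-appearance order.

    Patient / timepoint metadata is unknown at this stage; apply a sample
    sheet with :func:`apply_sample_sheet` to fill it in.
    """
    by_sample: dict[str, list[VariantCall]] = {}
    for c in calls:
        by_sample.setdefault(c.sample_id, []).append(c)
    return [
        SampleRecord(sample_id=sid, patient_id=sid, material=material, variants=vs)
        for sid, vs in by_sample.items()
    ]


def read_variant_table(
    path: str | Path,
    dialect: str = "tsv",
    strand_key: str = DEFAULT_STRAND_KEY,
    denominator: str = "depth",
) -> list[SampleRecord]:
    """Read a variant table (``tsv`` or ``vcf``) into per-sample records.

    Per-strand alt counts are mandatory; a stated VAF inconsistent with
    the counts beyond 1e-6 is recomputed with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "tsv":
        calls = _read_tsv(path, denominator)
    elif dialect == "vcf":
        calls = _read_vcf(path, strand_key, denominator)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return group_into_samples(calls)


def read_sample_sheet(path: str | Path) -> dict[str, tuple[str, str, float | None, float | None]]:
    """Read the CSV sample sheet.

    Returns ``sample_id -> (patient_id, material, timepoint_weeks,
    ct_change_percent)``; duplicate sample ids and unknown material tokens
    are rejected.
    """
    df = pd.read_csv(path, dtype=str)
    required = {"sample_id", "patient_id", "material"}
    if not required <= set(df.columns):
        raise VariantTableError(
            f"{path}: sample sheet needs columns {sorted(required)}"
        )
    sheet: dict[str, tuple[str, str, float | None, float | None]] = {}
    for _, row in df.iterrows():
        sid = row["sample_id"]
        if sid in sheet:
            raise VariantTableError(f"{path}: duplicate sample_id {sid!r}")
        material = row["material"]
        if material not in MATERIALS:
            raise VariantTableError(f"{path}: unknown material {material!r}")

        def _num(col: str) -> float | None:
            val = row.get(col)
            if val is None or (isinstance(val, float) and pd.isna(val)) or val in ("", "NA"):
                return None
            return float(val)

        sheet[sid] = (row["patient_id"], material, _num("timepoint_weeks"), _num("ct_change_percent"))
    return sheet


def apply_sample_sheet(
    records: Sequence[SampleRecord],
    sheet: Mapping[str, tuple[str, str, float | None, float | None]],
) -> list[SampleRecord]:
    """Attach patient / material / timepoint metadata to grouped records."""
    out = []
    for rec in records:
        if rec.sample_id not in sheet:
            raise VariantTableError(f"sample {rec.sample_id!r} absent from sample sheet")
        patient, material, weeks, ct = sheet[rec.sample_id]
        out.append(
            SampleRecord(
                sample_id=rec.sample_id,
                patient_id=patient,
                material=material,
                timepoint_weeks=weeks,
                ct_change_percent=ct,
                variants=list(rec.variants),
            )
        )
    return out


def read_panel_bed(path: str | Path) -> list[PanelRegion]:
    """Read a BED interval file (0-based half-open) into panel regions."""
    regions: list[PanelRegion] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise VariantTableError(f"{path}: line {line_no}: need >= 3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise VariantTableError(f"{path}: line {line_no}: {exc}")
            label = parts[3] if len(parts) > 3 else ""
            regions.append(PanelRegion(parts[0], start, end, label))
    return regions


def restrict_to_panel(
    variants: Sequence[VariantCall], panel: Sequence[PanelRegion]
) -> list[VariantCall]:
    """Keep variants whose 1-based position lies in some panel interval.

    Order is preserved; the operation is idempotent.
    """
    return [
        v for v in variants if any(r.contains(v.contig, v.pos) for r in panel)
    ]


# ---------------------------------------------------------------------------
# writers


def write_variant_table(records: Sequence[SampleRecord], path: str | Path) -> None:
    """Write all variants of the given samples as the TSV dialect.

    Round-trips bit-identically with :func:`read_variant_table` (floats
    serialised with ``repr``)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(TSV_COLUMNS)
        for rec in records:
            for v in rec.variants:
                writer.writerow(
                    [
                        v.sample_id, v.contig, v.pos, v.ref, v.alt, v.depth,
                        v.alt_fwd, v.alt_rev, repr(v.vaf), v.effect, v.protein_change,
                    ]
                )


def write_sample_sheet(records: Sequence[SampleRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(
            ["sample_id", "patient_id", "material", "timepoint_weeks", "ct_change_percent"]
        )
        for rec in records:
            writer.writerow(
                [
                    rec.sample_id,
                    rec.patient_id,
                    rec.material,
                    "" if rec.timepoint_weeks is None else rec.timepoint_weeks,
                    "" if rec.ct_change_percent is None else rec.ct_change_percent,
                ]
            )


def write_vcf(
    records: Sequence[SampleRecord],
    path: str | Path,
    strand_key: str = DEFAULT_STRAND_KEY,
) -> None:
    """Write variants as single-sample-column VCF 4.2 (uncompressed).

    Per-strand alt counts go in a two-entry FORMAT field; effect and
    protein change are carried in INFO (EFF, PCHG)."""
    import pysam

    header = pysam.VariantHeader()
    header.add_line('##fileformat=VCFv4.2')
    contigs = sorted({v.contig for rec in records for v in rec.variants})
    for c in contigs:
        header.contigs.add(c)
    header.add_meta(
        "FORMAT",
        items=[("ID", "DP"), ("Number", 1), ("Type", "Integer"), ("Description", "Read depth")],
    )
    header.add_meta(
        "FORMAT",
        items=[
            ("ID", strand_key), ("Number", 2), ("Type", "Integer"),
            ("Description", "Alt-supporting reads on forward,reverse strand"),
        ],
    )
    header.add_meta(
        "INFO",
        items=[("ID", "EFF"), ("Number", 1), ("Type", "String"), ("Description", "Effect")],
    )
    header.add_meta(
        "INFO",
        items=[("ID", "PCHG"), ("Number", 1), ("Type", "String"), ("Description", "Protein change")],
    )
    for rec in records:
        header.add_sample(rec.sample_id)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for rec in records:
            for v in rec.variants:
                r = out.new_record(
                    contig=v.contig, start=v.pos - 1, alleles=(v.ref, v.alt)
                )
                r.info["EFF"] = v.effect
                if v.protein_change:
                    r.info["PCHG"] = v.protein_change
                r.samples[rec.sample_id]["DP"] = v.depth
                r.samples[rec.sample_id][strand_key] = (v.alt_fwd, v.alt_rev)
                out.write(r)
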