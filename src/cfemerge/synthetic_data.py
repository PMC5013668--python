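"""Seeded synthetic cfDNA cohorts with the structure the analysis assumes.

Three generators cover the three data layers of the study design:

* a healthy-donor plasma panel whose variant calls are sequencing
  artefacts — strand-biased, with underlying VAFs drawn from an
  exponential truncated at 1% (scale 0.1%), so observed VAFs concentrate
  below 0.5%;
* matched tumour/plasma pairs sharing planted true variants (plasma VAF
  above 1%, tumour VAF much higher) on top of independent plasma
  artefacts, with truth labels retained;
* a treated cohort in which resistant subclones carrying DNA-binding-
  domain missense hotspot mutations emerge after treatment start and grow
  logistically, with tumour-size change linked linearly to log10 of the
  true mutation burden.

Generation is at the site-count level: read counts are drawn binomially
at the sample depth, true variants with balanced strands, artefacts with
a skewed strand split. Everything is driven by one numpy Generator seeded
once per call, so identical seed + config give bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .emergence import BurdenPoint
from .variant_io import PanelRegion, SampleRecord, VariantCall

_BASES = "ACGT"

# Toy coordinate space: one contig, positions self-consistent but not
# hg19-exact. Codon c sits at positions 100+3c .. 102+3c.
CONTIG = "TP53"
PANEL = [PanelRegion(CONTIG, 0, 1400, "TP53_toy")]


def _codon_pos(aa: int, offset: int = 1) -> int:
    return 100 + 3 * aa + offset


#: DNA-binding-domain missense hotspots (protein change, ref, alt,
#: transversion?). Substitution letters are chosen so the transition/
#: transversion class matches the flag; Y220 appears twice (independent
#: variants at the most frequently altered residue).
HOTSPOTS: list[tuple[str, int, str, str, bool]] = [
    # transitions
    ("R175H", _codon_pos(175), "G", "A", False),
    ("Y220C", _codon_pos(220), "A", "G", False),
    ("G245S", _codon_pos(245), "G", "A", False),
    ("R248Q", _codon_pos(248), "G", "A", False),
    ("R248W", _codon_pos(248, 0), "C", "T", False),
    ("R273H", _codon_pos(273), "G", "A", False),
    ("R273C", _codon_pos(273, 0), "C", "T", False),
    ("R282W", _codon_pos(282), "C", "T", False),
    ("H179R", _codon_pos(179), "A", "G", False),
    ("Y234C", _codon_pos(234), "A", "G", False),
    # transversions
    ("R249S", _codon_pos(249), "G", "T", True),
    ("C176F", _codon_pos(176), "G", "T", True),
    ("V157F", _codon_pos(157), "G", "T", True),
    ("R158L", _codon_pos(158), "G", "T", True),
    ("Y220S", _codon_pos(220), "A", "C", True),
    ("C242F", _codon_pos(242), "G", "T", True),
]

#: The common germline polymorphism, planted heterozygous to exercise the
#: germline exclusion filter.
P72R = ("P72R", _codon_pos(72), "C", "G")


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic study, defaulting to the study conditions:
    20-patient expansion cohort, ~6-weekly sampling, 8000x mean coverage,
    a quarter of patients developing resistant clones, 20% transversions,
    and a tumour-size link ct_change = 10 + 30 log10(burden%) + noise."""

    seed: int = 0
    n_patients: int = 20
    sampling_weeks: tuple[float, ...] = (0.0, 6.0, 12.0, 18.0, 24.0)
    mean_depth: int = 8000
    # artefact noise process
    artefact_rate: float = 8.0          # expected artefact calls per sample
    artefact_vaf_scale: float = 0.001   # exponential scale of underlying VAF
    artefact_max_vaf: float = 0.01      # hard truncation of underlying VAF
    artefact_strand_skew: float = 0.9   # P(artefact read on its dominant strand)
    # resistant-clone process
    clone_prob: float = 0.25            # P(patient develops >= 1 clone)
    extra_clones_mean: float = 3.0      # clones per affected patient: 1 + Poisson
    transversion_prob: float = 0.2
    emergence_weeks: tuple[float, ...] = (6.0, 12.0, 18.0)
    carrying_vaf_range: tuple[float, float] = (0.05, 0.5)
    growth_rate_range: tuple[float, float] = (0.2, 0.6)  # per week
    init_vaf: float = 0.005
    decay_after_peak: bool = False      # allow burden to fall after a peak week
    # clinical link
    ct_link: tuple[float, float, float] = (10.0, 30.0, 10.0)  # intercept, slope, sd
    baseline_ct_noise: float = 10.0     # sd for samples with zero true burden
    germline_p72r_prob: float = 0.5
    # matched-pair layer
    pair_truth_rate: float = 0.3        # expected planted true variants per pair

    def __post_init__(self) -> None:
        for name in ("artefact_strand_skew", "clone_prob", "transversion_prob",
                     "germline_p72r_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} outside [0,1]: {v}")
        if list(self.sampling_weeks) != sorted(self.sampling_weeks):
            raise ValueError("sampling_weeks must be sorted")
        if self.carrying_vaf_range[1] > 0.5:
            raise ValueError("carrying VAF cannot exceed 0.5 (heterozygous clone)")
        if self.artefact_rate < 0 or self.mean_depth <= 0:
            raise ValueError("rates and depth must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key in ("sampling_weeks", "emergence_weeks", "carrying_vaf_range",
                    "growth_rate_range", "ct_link"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass(frozen=True)
class CloneTrajectory:
    """One synthetic resistant subclone and its logistic VAF growth."""

    patient_id: str
    contig: str
    pos: int
    ref: str
    alt: str
    protein_change: str
    emergence_week: float
    carrying_vaf: float
    growth_rate: float
    init_vaf: float
    transversion: bool
    peak_week: float | None = None      # decay after this week if set
    decay_rate: float = 0.1             # per week, used only past peak_week

    def vaf_at(self, week: float) -> float:
        """Underlying clone VAF at a treatment week (0 before emergence)."""
        if week < self.emergence_week:
            return 0.0
        t = week - self.emergence_week
        k, v0 = self.carrying_vaf, self.init_vaf
        v = k * v0 / (v0 + (k - v0) * math.exp(-self.growth_rate * t))
        if self.peak_week is not None and week > self.peak_week:
            v_peak = self.vaf_at(self.peak_week)
            return v_peak * math.exp(-self.decay_rate * (week - self.peak_week))
        return v


# ---------------------------------------------------------------------------
# low-level draws


def _truncated_exp(rng: np.random.Generator, scale: float, upper: float, size: int):
    """Exponential(scale) truncated to (0, upper] by inverse CDF."""
    u = rng.random(size)
    return -scale * np.log1p(-u * (1.0 - math.exp(-upper / scale)))


def _draw_artefacts(
    rng: np.random.Generator, sample_id: str, cfg: SimulationConfig
) -> list[VariantCall]:
    n = rng.poisson(cfg.artefact_rate)
    if n == 0:
        return []
    span = PANEL[0].end
    pos = rng.integers(1, span + 1, size=n)
    p_true = _truncated_exp(rng, cfg.artefact_vaf_scale, cfg.artefact_max_vaf, n)
    depth = rng.poisson(cfg.mean_depth, size=n)
    alt_total = rng.binomial(depth, p_true)
    dom_fwd = rng.random(n) < 0.5
    alt_dom = rng.binomial(alt_total, cfg.artefact_strand_skew)
    ref_idx = rng.integers(0, 4, size=n)
    alt_shift = rng.integers(1, 4, size=n)
    effects = rng.choice(
        ["noncoding", "silent", "missense"], size=n, p=[0.5, 0.2, 0.3]
    )
    calls = []
    for i in range(n):
        if alt_total[i] == 0:
            continue
        fwd = int(alt_dom[i]) if dom_fwd[i] else int(alt_total[i] - alt_dom[i])
        rev = int(alt_total[i]) - fwd
        ref = _BASES[ref_idx[i]]
        alt = _BASES[(ref_idx[i] + alt_shift[i]) % 4]
        calls.append(
            VariantCall.from_counts(
                sample_id=sample_id, contig=CONTIG, pos=int(pos[i]),
                ref=ref, alt=alt, depth=int(depth[i]),
                alt_fwd=fwd, alt_rev=rev, effect=str(effects[i]),
            )
        )
    return calls


def _observe_variant(
    rng: np.random.Generator,
    sample_id: str,
    pos: int,
    ref: str,
    alt: str,
    true_vaf: float,
    mean_depth: int,
    effect: str = "missense",
    protein_change: str = "",
) -> VariantCall | None:
    """Binomial sampling of a true variant at the sample depth, balanced
    strands; returns None when no alt read is drawn."""
    depth = int(rng.poisson(mean_depth))
    if depth == 0:
        return None
    alt_total = int(rng.binomial(depth, min(true_vaf, 1.0)))
    if alt_total == 0:
        return None
    fwd = int(rng.binomial(alt_total, 0.5))
    return VariantCall.from_counts(
        sample_id=sample_id, contig=CONTIG, pos=pos, ref=ref, alt=alt,
        depth=depth, alt_fwd=fwd, alt_rev=alt_total - fwd,
        effect=effect, protein_change=protein_change,
    )


# ---------------------------------------------------------------------------
# generators


def simulate_normal_panel(
    config: SimulationConfig, n_samples: int = 10
) -> list[SampleRecord]:
    """Healthy-donor plasma panel: artefact variants only."""
    rng = np.random.default_rng(config.seed)
    records = []
    for i in range(n_samples):
        sid = f"HD{i + 1:02d}"
        records.append(
            SampleRecord(
                sample_id=sid,
                patient_id=sid,
                material="normal_plasma",
                variants=_draw_artefacts(rng, sid, config),
            )
        )
    return records


def simulate_matched_pairs(
    config: SimulationConfig, n_pairs: int = 60
) -> tuple[list[tuple[SampleRecord, SampleRecord]], list[dict]]:
    """Matched tumour/plasma pairs with planted shared true variants.

    Each pair carries Poisson(pair_truth_rate) true variants present in
    both materials — plasma VAF log-uniform on [1.2%, 20%], tumour VAF
    uniform on [20%, 80%] — plus independent plasma artefacts. Returns the
    pairs and a truth table (one dict per planted variant).
    """
    if n_pairs < 1:
        raise ValueError("need at least one pair")
    rng = np.random.default_rng(config.seed)
    pairs = []
    truths: list[dict] = []
    for i in range(n_pairs):
        pid = f"PAIR{i + 1:03d}"
        plasma_id, tumour_id = f"{pid}_P", f"{pid}_T"
        plasma_vars: list[VariantCall] = []
        tumour_vars: list[VariantCall] = []
        n_true = rng.poisson(config.pair_truth_rate)
        hot_idx = rng.choice(len(HOTSPOTS), size=min(n_true, len(HOTSPOTS)),
                             replace=False)
        for j in hot_idx:
            pchg, pos, ref, alt, _ = HOTSPOTS[j]
            plasma_vaf = float(10 ** rng.uniform(math.log10(0.012), math.log10(0.2)))
            tumour_vaf = float(rng.uniform(0.2, 0.8))
            pv = _observe_variant(rng, plasma_id, pos, ref, alt, plasma_vaf,
                                  config.mean_depth, protein_change=pchg)
            tv = _observe_variant(rng, tumour_id, pos, ref, alt, tumour_vaf,
                                  config.mean_depth, protein_change=pchg)
            if pv is not None:
                plasma_vars.append(pv)
            if tv is not None:
                tumour_vars.append(tv)
            truths.append(
                {"patient_id": pid, "contig": CONTIG, "pos": pos, "ref": ref,
                 "alt": alt, "plasma_vaf": plasma_vaf, "tumour_vaf": tumour_vaf}
            )
        plasma_vars.extend(_draw_artefacts(rng, plasma_id, config))
        pairs.append(
            (
                SampleRecord(plasma_id, pid, "plasma_cfdna", variants=plasma_vars),
                SampleRecord(tumour_id, pid, "tumour_ffpe", variants=tumour_vars),
            )
        )
    return pairs, truths


def _draw_clones(
    rng: np.random.Generator, patient_id: str, cfg: SimulationConfig
) -> list[CloneTrajectory]:
    if rng.random() >= cfg.clone_prob:
        return []
    n_clones = 1 + int(rng.poisson(cfg.extra_clones_mean))
    ts_pool = [h for h in HOTSPOTS if not h[4]]
    tv_pool = [h for h in HOTSPOTS if h[4]]
    rng.shuffle(ts_pool)
    rng.shuffle(tv_pool)
    clones = []
    for _ in range(n_clones):
        want_tv = rng.random() < cfg.transversion_prob
        pool = tv_pool if want_tv else ts_pool
        if not pool:
            pool = ts_pool or tv_pool
        if not pool:
            break
        pchg, pos, ref, alt, is_tv = pool.pop()
        emergence = float(rng.choice(cfg.emergence_weeks))
        peak = None
        if cfg.decay_after_peak and rng.random() < 0.2:
            peak = float(max(cfg.sampling_weeks))
        clones.append(
            CloneTrajectory(
                patient_id=patient_id, contig=CONTIG, pos=pos, ref=ref, alt=alt,
                protein_change=pchg, emergence_week=emergence,
                carrying_vaf=float(rng.uniform(*cfg.carrying_vaf_range)),
                growth_rate=float(rng.uniform(*cfg.growth_rate_range)),
                init_vaf=cfg.init_vaf, transversion=is_tv, peak_week=peak,
            )
        )
    return clones


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[list[SampleRecord], list[CloneTrajectory], pd.DataFrame]:
    """Treated cohort: plasma samples over the sampling weeks, resistant
    clones emerging after treatment start, artefact noise, an optional
    germline P72R heterozygote, and a tumour-size change generated from
    the true burden by the linear-log link.

    Baseline (week 0) samples never carry true clone variants. Returns
    the samples, the clone trajectories, and a per-sample truth table
    (sample_id, patient_id, week, true burden in percent, number of
    clones present, max true clone VAF).
    """
    rng = np.random.default_rng(config.seed)
    a, b, link_sd = config.ct_link
    records: list[SampleRecord] = []
    clones_all: list[CloneTrajectory] = []
    truth_rows: list[dict] = []
    for i in range(config.n_patients):
        pid = f"P{i + 1:03d}"
        clones = _draw_clones(rng, pid, config)
        clones_all.extend(clones)
        has_germline = rng.random() < config.germline_p72r_prob
        for week in config.sampling_weeks:
            sid = f"{pid}_w{int(week):02d}"
            variants: list[VariantCall] = []
            true_vafs = [c.vaf_at(week) for c in clones]
            for clone, v in zip(clones, true_vafs):
                if v <= 0:
                    continue
                call = _observe_variant(
                    rng, sid, clone.pos, clone.ref, clone.alt, v,
                    config.mean_depth, protein_change=clone.protein_change,
                )
                if call is not None:
                    variants.append(call)
            if has_germline:
                pchg, pos, ref, alt = P72R
                call = _observe_variant(
                    rng, sid, pos, ref, alt, 0.5, config.mean_depth,
                    protein_change=pchg,
                )
                if call is not None:
                    variants.append(call)
            variants.extend(_draw_artefacts(rng, sid, config))
            true_burden_pct = 100.0 * sum(true_vafs)
            if true_burden_pct > 0:
                ct = a + b * math.log10(true_burden_pct) + rng.normal(0, link_sd)
            else:
                ct = rng.normal(0, config.baseline_ct_noise)
            records.append(
                SampleRecord(
                    sample_id=sid, patient_id=pid, material="plasma_cfdna",
                    timepoint_weeks=week, ct_change_percent=float(ct),
                    variants=variants,
                )
            )
            truth_rows.append(
                {
                    "sample_id": sid,
                    "patient_id": pid,
                    "timepoint_weeks": week,
                    "true_burden_pct": true_burden_pct,
                    "n_clones_present": int(sum(v > 0 for v in true_vafs)),
                    "max_true_vaf": max(true_vafs, default=0.0),
                }
            )
    return records, clones_all, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# truth accounting


def truth_report(
    truth: pd.DataFrame,
    burdens: Sequence[BurdenPoint],
    high_vaf: float = 0.02,
) -> dict:
    """Per-sample detection confusion summary against the simulation truth.

    A sample is truth-positive when its true clone burden is positive.
    ``sensitivity_high`` restricts to samples whose largest true clone VAF
    exceeds ``high_vaf`` (clones that deep sequencing should essentially
    always observe). ``burden_mae_pct`` is the mean absolute error of the
    measured burden over truth-positive detected samples.
    """
    by_key = {(p.patient_id, p.timepoint_weeks): p for p in burdens}
    tp = fp = fn = tn = 0
    high_total = high_detected = 0
    abs_errors = []
    for row in truth.itertuples(index=False):
        key = (row.patient_id, row.timepoint_weeks)
        if key not in by_key:
            raise ValueError(f"no pipeline output for sample {row.sample_id!r}")
        point = by_key[key]
        positive = row.true_burden_pct > 0
        if positive and point.detected:
            tp += 1
            abs_errors.append(abs(point.burden_pct - row.true_burden_pct))
        elif positive:
            fn += 1
        elif point.detected:
            fp += 1
        else:
            tn += 1
        if row.max_true_vaf > high_vaf:
            high_total += 1
            high_detected += point.detected
    return {
        "n_samples": int(len(truth)),
        "tp": tp, "fp": fp, "fn": fn, "tn": tn,
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "sensitivity_high": high_detected / high_total if high_total else float("nan"),
        "burden_mae_pct": float(np.mean(abs_errors)) if abs_errors else float("nan"),
    }
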