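"""Per-arm and genome-wide readout statistics and the ALT-positivity caller.

Per-arm tables mirror the appendix-style layout: counts, category
percentages, overall/end-telomere/internal-telomere means, the arm's
longest telomere, and the per-arm coefficient of variation (CV).  "Overall"
statistics pool end-telomere lengths, internal (ITS+) telomere lengths, and
zeros for TFE and ITS- sightings — the 0-kb convention makes the zero-rich
ALT+ length distributions visible in the mean and CV.

Genome-wide, five readouts feed the ALT caller: fusion/ITS+ %, fusion/ITS-
%, TFE %, the super-long telomere fraction (measured telomeres > 15 kb),
and the CV of overall telomere length (sd / mean; > 1 is the ALT+ regime).
All dispersion statistics use the sample (n-1) standard deviation.
"""

from __future__ import annotations

import re

import numpy as np
from scipy.stats import t as t_dist

from .errors import InsufficientDataError
from .model import (
    ALTCall,
    ALTThresholds,
    ArmStats,
    Category,
    ClassifiedMolecule,
    ReadoutSummary,
    TTestResult,
)
from .model import ARM_CATEGORIES

__all__ = [
    "arm_sort_key",
    "collect_arm_sightings",
    "arm_stats",
    "compute_arm_tables",
    "genome_summary",
    "welch_t_test",
    "compare_cell_lines",
    "call_alt",
    "COMPARE_METRICS",
]

SUPER_LONG_MOLECULE_KB = 15.0
SUPER_LONG_ARM_KB = 10.0


def arm_sort_key(arm_id: str):
    """Chromosome order: 1p, 1q, ..., 22q, then sex-chromosome ends, then others."""
    m = re.fullmatch(r"(\d+)([pq])", arm_id)
    if m:
        return (0, int(m.group(1)), m.group(2))
    return (1, 0, arm_id)


def _sample_sd(values: np.ndarray) -> float:
    return float(np.std(values, ddof=1)) if values.size >= 2 else 0.0


def _length_kb(cm: ClassifiedMolecule) -> float:
    """Length entering overall statistics (0-kb convention for TFE/ITS-)."""
    return cm.telomere_length_kb if cm.category in (
        Category.END_TEL, Category.FUSION_ITS_PLUS) else 0.0


def collect_arm_sightings(classified: list[ClassifiedMolecule]) -> dict[str, list[ClassifiedMolecule]]:
    """Group arm-anchored calls by arm of record.

    A fusion recorded on two arms is a sighting of each arm's end and
    appears in both groups (twice in one group for a same-arm fusion);
    ECTR and unclassified molecules never enter per-arm tables.
    """
    out: dict[str, list[ClassifiedMolecule]] = {}
    for cm in classified:
        if cm.category not in ARM_CATEGORIES:
            continue
        for arm in cm.arms_of_record:
            out.setdefault(arm, []).append(cm)
    return {arm: out[arm] for arm in sorted(out, key=arm_sort_key)}


def arm_stats(arm_id: str, sightings: list[ClassifiedMolecule]) -> ArmStats | None:
    """Per-arm statistics row; None marks an empty (unmeasured) arm, which
    is dropped from reports."""
    if not sightings:
        return None
    n = len(sightings)
    by_cat = {c: [s for s in sightings if s.category is c] for c in ARM_CATEGORIES}
    counts = {c: len(v) for c, v in by_cat.items()}
    lengths = np.asarray([_length_kb(s) for s in sightings])
    endtel = np.asarray([s.telomere_length_kb for s in by_cat[Category.END_TEL]])
    its_plus = np.asarray([s.telomere_length_kb for s in by_cat[Category.FUSION_ITS_PLUS]])
    mean = float(lengths.mean())
    sd = _sample_sd(lengths)
    return ArmStats(
        arm_id=arm_id,
        overall_count=n,
        endtel_count=counts[Category.END_TEL],
        tfe_count=counts[Category.TFE],
        its_plus_count=counts[Category.FUSION_ITS_PLUS],
        its_minus_count=counts[Category.FUSION_ITS_MINUS],
        overall_mean_kb=mean,
        overall_sd_kb=sd,
        overall_max_kb=float(lengths.max()),
        endtel_mean_kb=float(endtel.mean()) if endtel.size else None,
        endtel_sd_kb=_sample_sd(endtel) if endtel.size else None,
        its_plus_mean_kb=float(its_plus.mean()) if its_plus.size else None,
        endtel_pct=100.0 * counts[Category.END_TEL] / n,
        tfe_pct=100.0 * counts[Category.TFE] / n,
        its_plus_pct=100.0 * counts[Category.FUSION_ITS_PLUS] / n,
        its_minus_pct=100.0 * counts[Category.FUSION_ITS_MINUS] / n,
        cv=(sd / mean) if mean > 0 else None,
    )


def compute_arm_tables(classified: list[ClassifiedMolecule]) -> dict[str, ArmStats]:
    """Per-arm table over all arms with at least one sighting."""
    return {
        arm: row
        for arm, sightings in collect_arm_sightings(classified).items()
        if (row := arm_stats(arm, sightings)) is not None
    }


def genome_summary(
    classified: list[ClassifiedMolecule],
    arm_tables: dict[str, ArmStats] | None = None,
) -> ReadoutSummary:
    """Genome-wide readouts over unique arm-anchored molecules.

    Percentages and pooled length statistics count each molecule once
    (fusions sighted on two arms are still one molecule); per-arm CVs and
    the arm-level super-long share come from the per-arm table.
    """
    if arm_tables is None:
        arm_tables = compute_arm_tables(classified)
    anchored = [cm for cm in classified if cm.category in ARM_CATEGORIES]
    if not anchored:
        raise InsufficientDataError("no arm-anchored molecules: all arms empty")
    n = len(anchored)
    counts = {c: sum(1 for cm in anchored if cm.category is c) for c in ARM_CATEGORIES}
    lengths = np.asarray([_length_kb(cm) for cm in anchored])
    endtel = np.asarray([cm.telomere_length_kb for cm in anchored if cm.category is Category.END_TEL])
    its_plus = np.asarray([cm.telomere_length_kb for cm in anchored
                           if cm.category is Category.FUSION_ITS_PLUS])
    measured = np.concatenate([endtel, its_plus])
    mean = float(lengths.mean())
    sd = _sample_sd(lengths)
    per_arm_cvs = {arm: row.cv for arm, row in arm_tables.items() if row.cv is not None}
    maxima = np.asarray([row.overall_max_kb for row in arm_tables.values()])
    return ReadoutSummary(
        n_molecules=n,
        overall_mean_kb=mean,
        overall_sd_kb=sd,
        endtel_mean_kb=float(endtel.mean()) if endtel.size else None,
        endtel_sd_kb=_sample_sd(endtel) if endtel.size else None,
        its_plus_mean_kb=float(its_plus.mean()) if its_plus.size else None,
        its_plus_sd_kb=_sample_sd(its_plus) if its_plus.size else None,
        cv=(sd / mean) if mean > 0 else 0.0,
        endtel_pct=100.0 * counts[Category.END_TEL] / n,
        tfe_pct=100.0 * counts[Category.TFE] / n,
        its_plus_pct=100.0 * counts[Category.FUSION_ITS_PLUS] / n,
        its_minus_pct=100.0 * counts[Category.FUSION_ITS_MINUS] / n,
        frac_gt_15kb=float((measured > SUPER_LONG_MOLECULE_KB).mean()) if measured.size else 0.0,
        n_measured_telomeres=int(measured.size),
        frac_arms_max_gt_10kb=float((maxima > SUPER_LONG_ARM_KB).mean()) if maxima.size else 0.0,
        per_arm_cvs=per_arm_cvs,
        median_cv=float(np.median(list(per_arm_cvs.values()))) if per_arm_cvs else None,
        ectr_count=sum(1 for cm in classified if cm.category is Category.ECTR),
        n_unclassified=sum(1 for cm in classified if cm.category is Category.UNCLASSIFIED),
    )


def welch_t_test(sample_a, sample_b) -> TTestResult:
    """Two-tailed unequal-variance t-test.

    t = (mean_a - mean_b) / sqrt(s2_a/m + s2_b/n) with Welch-Satterthwaite
    degrees of freedom.  Two zero-variance samples with equal means give
    t = 0, p = 1 (no evidence of a difference in a degenerate comparison).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("each sample needs >= 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    sea, seb = va / a.size, vb / b.size
    denom = np.sqrt(sea + seb)
    diff = a.mean() - b.mean()
    if denom == 0.0:
        if diff == 0.0:
            return TTestResult(0.0, float(a.size + b.size - 2), 1.0)
        return TTestResult(float(np.sign(diff)) * np.inf, float(a.size + b.size - 2), 0.0)
    t = diff / denom
    df = (sea + seb) ** 2 / (sea ** 2 / (a.size - 1) + seb ** 2 / (b.size - 1))
    p = 2.0 * float(t_dist.sf(abs(t), df))
    return TTestResult(float(t), float(df), min(p, 1.0))


#: metric name -> per-arm value extractor (None values are skipped pairwise)
COMPARE_METRICS = {
    "its_plus_pct_by_arm": lambda row: row["its_plus_pct"],
    "its_minus_pct_by_arm": lambda row: row["its_minus_pct"],
    "tfe_pct_by_arm": lambda row: row["tfe_pct"],
    "endtel_mean_by_arm": lambda row: row["endtel_mean_kb"],
    "overall_max_by_arm": lambda row: row["overall_max_kb"],
    "cv_by_arm": lambda row: row["cv"],
}


def _row_mapping(row) -> dict:
    if isinstance(row, dict):
        return row
    return {
        "its_plus_pct": row.its_plus_pct,
        "its_minus_pct": row.its_minus_pct,
        "tfe_pct": row.tfe_pct,
        "endtel_mean_kb": row.endtel_mean_kb,
        "overall_max_kb": row.overall_max_kb,
        "cv": row.cv,
    }


def compare_cell_lines(
    tables: dict[str, dict[str, object]],
    metric: str,
) -> dict[tuple[str, str], TTestResult | None]:
    """Pairwise Welch tests of a per-arm metric between cell lines.

    ``tables`` maps cell-line name -> per-arm table (ArmStats rows or plain
    mappings).  Each pair is tested on the arms analyzed in both lines with
    a defined metric value; pairs with fewer than 2 shared arms get None
    (insufficient data).  The result is symmetric in p, antisymmetric in t.
    """
    if len(tables) < 2:
        raise InsufficientDataError("need >= 2 cell lines to compare")
    if metric not in COMPARE_METRICS:
        raise KeyError(f"unknown metric {metric!r}; options: {sorted(COMPARE_METRICS)}")
    get = COMPARE_METRICS[metric]
    names = list(tables)
    out: dict[tuple[str, str], TTestResult | None] = {}
    for i, na in enumerate(names):
        for nb in names[i:]:
            shared = [
                (get(_row_mapping(tables[na][arm])), get(_row_mapping(tables[nb][arm])))
                for arm in tables[na] if arm in tables[nb]
            ]
            shared = [(x, y) for x, y in shared if x is not None and y is not None]
            if len(shared) < 2:
                res = None
            else:
                xs, ys = zip(*shared)
                res = welch_t_test(xs, ys)
            out[(na, nb)] = res
            if na != nb:
                out[(nb, na)] = None if res is None else TTestResult(
                    -res.t_statistic, res.degrees_of_freedom, res.p_value_two_tailed)
    return out


def call_alt(summary: ReadoutSummary, thresholds: ALTThresholds | None = None) -> ALTCall:
    """Five-readout ALT-positivity vote.

    Flags fire on fusion/ITS+ %, fusion/ITS- %, TFE %, genome CV, and the
    super-long telomere share; the call is ALT_positive when at least
    ``votes_required`` flags are up.
    """
    thresholds = thresholds or ALTThresholds()
    flags = {
        "its_plus": summary.its_plus_pct >= thresholds.its_plus_pct,
        "its_minus": summary.its_minus_pct >= thresholds.its_minus_pct,
        "tfe": summary.tfe_pct >= thresholds.tfe_pct,
        "cv": summary.cv >= thresholds.cv,
        "super_long": 100.0 * summary.frac_gt_15kb >= thresholds.super_long_pct,
    }
    n_positive = sum(flags.values())
    call = "ALT_positive" if n_positive >= thresholds.votes_required else "ALT_negative"
    return ALTCall(flags=flags, thresholds=thresholds, n_positive=n_positive, call=call)
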