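"""Core domain types for single-molecule two-color optical maps of chromosome ends.

Coordinates are 0-based base-pair floats along a molecule or reference map;
intervals are half-open.  A reference arm map is anchored so that the
chromosome terminus (telomere-proximal edge) sits at the maximal coordinate,
``chrom_end_pos == map_length_bp``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConsistencyError, InvalidParameterError, UnknownArmError

__all__ = [
    "Category",
    "ReferenceArmMap",
    "ReferenceSet",
    "NoiseModel",
    "LengthDistribution",
    "CellLineProfile",
    "MoleculeTruth",
    "Molecule",
    "AlignmentParams",
    "Alignment",
    "CalibrationModel",
    "ClassifyParams",
    "ClassifiedMolecule",
    "ReportRow",
    "ArmStats",
    "ReadoutSummary",
    "TTestResult",
    "ALTThresholds",
    "ALTCall",
    "EXCLUDED_ARMS",
    "DEFAULT_INTENSITY_PER_KB",
]

#: Acrocentric short arms with essentially no mappable subtelomeric
#: segment; excluded from simulation and reporting.
EXCLUDED_ARMS = frozenset({"13p", "14p", "15p", "21p", "22p"})

#: Intensity calibration constant: fluorescence units emitted per kb of
#: telomere repeat.  Arbitrary (only the product k*length is observable);
#: recorded here so the length readout is exactly invertible.
DEFAULT_INTENSITY_PER_KB = 1000.0


class Category(str, enum.Enum):
    """Chromosome-end feature categories callable from a single molecule."""

    END_TEL = "END_TEL"
    TFE = "TFE"
    FUSION_ITS_PLUS = "FUSION_ITS_PLUS"
    FUSION_ITS_MINUS = "FUSION_ITS_MINUS"
    ECTR = "ECTR"
    UNCLASSIFIED = "UNCLASSIFIED"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Categories whose sightings enter per-arm tables (arm-anchored calls).
ARM_CATEGORIES = (
    Category.END_TEL,
    Category.TFE,
    Category.FUSION_ITS_PLUS,
    Category.FUSION_ITS_MINUS,
)


@dataclass(frozen=True)
class ReferenceArmMap:
    """Nick-label coordinate map of one subtelomeric arm segment.

    The chromosome terminus is anchored at the maximal coordinate:
    ``chrom_end_pos == map_length_bp``.
    """

    arm_id: str
    label_positions: np.ndarray  # ascending bp, within [0, chrom_end_pos]
    chrom_end_pos: float
    map_length_bp: float

    def __post_init__(self):
        pos = np.asarray(self.label_positions, dtype=float)
        object.__setattr__(self, "label_positions", pos)
        if pos.ndim != 1:
            raise InvalidParameterError("label_positions must be 1-D")
        if pos.size and (np.any(np.diff(pos) <= 0)):
            raise ConsistencyError(f"{self.arm_id}: label positions not strictly ascending")
        if pos.size and (pos[0] < 0 or pos[-1] > self.chrom_end_pos):
            raise ConsistencyError(f"{self.arm_id}: labels outside [0, chrom_end]")
        if self.chrom_end_pos != self.map_length_bp:
            raise ConsistencyError(f"{self.arm_id}: chrom_end_pos must equal map_length_bp")

    @property
    def n_labels(self) -> int:
        return int(self.label_positions.size)


@dataclass(frozen=True)
class ReferenceSet:
    """Collection of arm maps keyed by arm id."""

    arms: dict[str, ReferenceArmMap]
    excluded_arms: frozenset[str] = EXCLUDED_ARMS

    def __post_init__(self):
        for arm_id, arm in self.arms.items():
            if arm.arm_id != arm_id:
                raise ConsistencyError(f"key {arm_id!r} != arm_id {arm.arm_id!r}")

    def __len__(self) -> int:
        return len(self.arms)

    def __getitem__(self, arm_id: str) -> ReferenceArmMap:
        try:
            return self.arms[arm_id]
        except KeyError:
            raise UnknownArmError(arm_id) from None

    def __contains__(self, arm_id: str) -> bool:
        return arm_id in self.arms

    def arm_ids(self) -> list[str]:
        return list(self.arms)

    @property
    def mean_label_spacing_bp(self) -> float:
        gaps = np.concatenate([np.diff(a.label_positions) for a in self.arms.values() if a.n_labels > 1])
        return float(gaps.mean())


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise model for simulated single-molecule maps.

    Parameters
    ----------
    sizing_sd_bp
        Gaussian sd applied to each observed label position.
    dropout_prob
        Per-label probability that a true nick label is missed.
    false_label_rate_per_100kb
        Poisson rate of spurious nick labels along the backbone.
    intensity_cv
        Multiplicative Gaussian coefficient of variation on telomere-label
        intensity.
    detection_floor_kb
        Minimum detectable telomere length; shorter telomeres emit no label.
    """

    sizing_sd_bp: float = 250.0
    dropout_prob: float = 0.10
    false_label_rate_per_100kb: float = 1.0
    intensity_cv: float = 0.10
    detection_floor_kb: float = 0.1

    def __post_init__(self):
        if min(self.sizing_sd_bp, self.false_label_rate_per_100kb, self.intensity_cv,
               self.dropout_prob, self.detection_floor_kb) < 0:
            raise InvalidParameterError("noise rates must be >= 0")
        if self.dropout_prob >= 1:
            raise InvalidParameterError("dropout_prob must be < 1")

    @classmethod
    def disabled(cls, detection_floor_kb: float = 0.1) -> "NoiseModel":
        """A noise-free model (used for worked fixtures and round trips)."""
        return cls(0.0, 0.0, 0.0, 0.0, detection_floor_kb)


@dataclass(frozen=True)
class LengthDistribution:
    """Telomere-length distribution: lognormal body plus optional heavy lognormal tail.

    The body is parameterized by its target mean and sd (kb); the tail by
    its median and log-scale sigma.  ``tail_weight`` is the mixture mass of
    the tail component and is what tail calibration solves for.
    """

    body_mean_kb: float
    body_sd_kb: float
    tail_weight: float = 0.0
    tail_median_kb: float = 20.0
    tail_sigma: float = 0.6

    def __post_init__(self):
        if self.body_mean_kb <= 0 or self.body_sd_kb <= 0:
            raise InvalidParameterError("body mean/sd must be > 0")
        if not (0 <= self.tail_weight < 1):
            raise InvalidParameterError("tail_weight must be in [0, 1)")
        if self.tail_median_kb <= 0 or self.tail_sigma <= 0:
            raise InvalidParameterError("tail parameters must be > 0")

    @property
    def body_lognorm_params(self) -> tuple[float, float]:
        """(mu, sigma) of the body lognormal matching the target moments."""
        sigma2 = np.log1p((self.body_sd_kb / self.body_mean_kb) ** 2)
        mu = np.log(self.body_mean_kb) - sigma2 / 2.0
        return float(mu), float(np.sqrt(sigma2))

    def sf_kb(self, x_kb: float) -> float:
        """P(length > x_kb) of the mixture (analytic)."""
        from scipy.stats import lognorm

        mu, sigma = self.body_lognorm_params
        body = lognorm.sf(x_kb, s=sigma, scale=np.exp(mu))
        tail = lognorm.sf(x_kb, s=self.tail_sigma, scale=self.tail_median_kb)
        return float((1.0 - self.tail_weight) * body + self.tail_weight * tail)

    def sample_kb(self, rng: np.random.Generator, n: int, min_kb: float = 0.0) -> np.ndarray:
        """Draw n lengths, resampling below ``min_kb`` (truncation at the
        detection floor: simulated categories defined by a *detected*
        telomere only ever carry detectable ones)."""
        mu, sigma = self.body_lognorm_params
        out = np.empty(n)
        todo = np.arange(n)
        while todo.size:
            m = todo.size
            is_tail = rng.random(m) < self.tail_weight
            draw = np.where(
                is_tail,
                self.tail_median_kb * np.exp(self.tail_sigma * rng.standard_normal(m)),
                np.exp(mu + sigma * rng.standard_normal(m)),
            )
            out[todo] = draw
            todo = todo[draw < min_kb]
        return out

    def with_tail_weight(self, w: float) -> "LengthDistribution":
        return replace(self, tail_weight=w)


@dataclass(frozen=True)
class CellLineProfile:
    """Generative profile for one cell line's chromosome-end population.

    Mixture fractions are over arm-anchored molecules; ECTRs are emitted
    additionally at ``ectr_per_100_molecules`` per 100 arm-anchored
    molecules and never enter the fractions.
    """

    name: str
    frac_endtel: float
    frac_tfe: float
    frac_its_plus: float
    frac_its_minus: float
    ectr_per_100_molecules: float
    endtel_len: LengthDistribution
    its_plus_len: LengthDistribution
    ectr_len: LengthDistribution
    mean_molecules_per_arm: float = 30.0
    noise: NoiseModel = field(default_factory=NoiseModel)
    #: configured cell-line-level mass of measured telomeres above 15 kb
    #: (end telomeres plus internal telomeres pooled); None = not calibrated.
    frac_telomeres_gt_15kb: float | None = None

    def __post_init__(self):
        fracs = (self.frac_endtel, self.frac_tfe, self.frac_its_plus, self.frac_its_minus)
        if any(f < 0 for f in fracs):
            raise InvalidParameterError("category fractions must be >= 0")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise InvalidParameterError("category fractions must sum to 1")
        if self.ectr_per_100_molecules < 0 or self.mean_molecules_per_arm <= 0:
            raise InvalidParameterError("rates must be positive")

    @property
    def category_fractions(self) -> dict[Category, float]:
        return {
            Category.END_TEL: self.frac_endtel,
            Category.TFE: self.frac_tfe,
            Category.FUSION_ITS_PLUS: self.frac_its_plus,
            Category.FUSION_ITS_MINUS: self.frac_its_minus,
        }


@dataclass(frozen=True)
class MoleculeTruth:
    """Simulation ground truth attached to a molecule."""

    category: Category
    arms: tuple[str, ...]
    telomere_kb: float


@dataclass
class Molecule:
    """One imaged DNA fiber.

    ``nick_labels`` are ascending genome-channel label positions (bp);
    ``tel_positions``/``tel_intensities`` carry the telomere channel.
    """

    molecule_id: int
    length_bp: float
    nick_labels: np.ndarray
    tel_positions: np.ndarray
    tel_intensities: np.ndarray
    truth: MoleculeTruth | None = None

    def __post_init__(self):
        self.nick_labels = np.asarray(self.nick_labels, dtype=float)
        self.tel_positions = np.asarray(self.tel_positions, dtype=float)
        self.tel_intensities = np.asarray(self.tel_intensities, dtype=float)
        if self.length_bp <= 0:
            raise ConsistencyError(f"molecule {self.molecule_id}: non-positive length")
        for arr, nm in ((self.nick_labels, "nick"), (self.tel_positions, "telomere")):
            if arr.size and (arr.min() < 0 or arr.max() > self.length_bp):
                raise ConsistencyError(f"molecule {self.molecule_id}: {nm} label outside [0, length]")
        if self.nick_labels.size > 1 and np.any(np.diff(self.nick_labels) <= 0):
            raise ConsistencyError(f"molecule {self.molecule_id}: nick labels not ascending")
        if self.tel_positions.size != self.tel_intensities.size:
            raise ConsistencyError(f"molecule {self.molecule_id}: telomere position/intensity arity mismatch")
        if self.tel_intensities.size and self.tel_intensities.min() <= 0:
            raise ConsistencyError(f"molecule {self.molecule_id}: non-positive telomere intensity")


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring parameters of the nick-pattern dynamic-programming aligner.

    Matching compares successive label *gaps* (interval agreement), which is
    invariant to the unknown offset of a molecule within the arm.  A
    consecutive matched pair is feasible when
    ``|d_ref - d_mol| <= max(abs_tol_bp, rel_tol * d_ref)``.
    """

    abs_tol_bp: float = 500.0
    rel_tol: float = 0.12
    miss_penalty: float = 1.0       # per skipped reference label inside the aligned core
    extra_penalty: float = 1.0      # per skipped molecule label inside the aligned core
    match_bonus: float = 3.0
    min_matched_labels: int = 8
    min_score: float = 15.0
    max_lookback: int = 6           # max labels skippable between consecutive matches + 1
    max_segments: int = 2           # split-alignment cap (fusions are two-part)
    candidate_arms: int | None = 16  # max arms pre-screened per pass; None = exhaustive
    patience: int = 6               # stop after this many non-improving candidates

    def __post_init__(self):
        if min(self.miss_penalty, self.extra_penalty) < 0:
            raise InvalidParameterError("penalties must be >= 0")
        if self.min_matched_labels < 3:
            raise InvalidParameterError("min_matched_labels must be >= 3")
        if self.max_lookback < 1:
            raise InvalidParameterError("max_lookback must be >= 1")


@dataclass(frozen=True)
class Alignment:
    """A scored monotone matching of molecule nick labels to one arm.

    ``matched_pairs`` holds (molecule_label_index, reference_label_index)
    pairs, strictly monotone in both coordinates (decreasing in the molecule
    index for reverse orientation when read along the reference).
    ``end_anchored`` is True when the reference's distal-most label (the one
    nearest the chromosome end) is matched.

    ``distal_mol_pos_bp`` is the molecule coordinate of the matched label
    nearest the chromosome end, and ``chrom_end_offset_bp`` the distance
    from that label to the terminus along the reference; together with
    ``orientation`` (the terminus lies toward increasing molecule
    coordinates for "forward", decreasing for "reverse") they let the
    classifier reason about the terminal region without the reference.
    """

    molecule_id: int
    arm_id: str
    orientation: str                      # "forward" | "reverse"
    matched_pairs: tuple[tuple[int, int], ...]
    mol_span_bp: tuple[float, float]      # half-open on the molecule
    ref_span_bp: tuple[float, float]      # half-open on the reference
    score: float
    end_anchored: bool
    distal_mol_pos_bp: float = 0.0
    chrom_end_offset_bp: float = 0.0

    @property
    def n_matched(self) -> int:
        return len(self.matched_pairs)


@dataclass(frozen=True)
class CalibrationModel:
    """Linear intensity-to-length calibration of the telomere channel."""

    k_units_per_kb: float = DEFAULT_INTENSITY_PER_KB
    detection_floor_kb: float = 0.1
    detection_ceiling_kb: float = 110.0

    def __post_init__(self):
        if self.k_units_per_kb <= 0:
            raise InvalidParameterError("k must be > 0")
        if not (0 <= self.detection_floor_kb < self.detection_ceiling_kb):
            raise InvalidParameterError("floor must be >= 0 and < ceiling")


@dataclass(frozen=True)
class ClassifyParams:
    """Geometric thresholds of the chromosome-end classifier."""

    #: max distance from the distal-most matched reference label to the
    #: chromosome end for the alignment to provide end context
    end_window_bp: float = 20_000.0
    #: min unlabeled molecule overhang past the distal matched label to call
    #: a telomere-free end rather than a truncated fiber
    tfe_min_overhang_bp: float = 5_000.0
    #: min molecule span carrying >=1 nick label distal to a telomere
    #: cluster for the telomere to count as internal (a fusion junction)
    internal_min_flank_bp: float = 10_000.0
    #: max gap merging telomere labels into one cluster
    cluster_gap_bp: float = 3_000.0

    def __post_init__(self):
        if min(self.end_window_bp, self.tfe_min_overhang_bp,
               self.internal_min_flank_bp, self.cluster_gap_bp) <= 0:
            raise InvalidParameterError("classifier thresholds must be positive")


@dataclass(frozen=True)
class ClassifiedMolecule:
    """Category call for one molecule.

    Telomere-free ends and fusions without internal telomere signal are
    assigned a length of 0 kb by convention; that convention is enforced
    here structurally.
    """

    molecule_id: int
    category: Category
    arms_of_record: tuple[str, ...]
    telomere_length_kb: float
    truth: MoleculeTruth | None = None

    def __post_init__(self):
        if self.category in (Category.TFE, Category.FUSION_ITS_MINUS):
            if self.telomere_length_kb != 0.0:
                raise ConsistencyError("TFE/ITS- molecules carry length 0 by convention")
        if self.category in (Category.ECTR, Category.UNCLASSIFIED) and self.arms_of_record:
            raise ConsistencyError(f"{self.category} must have no arms of record")
        if self.category in (Category.END_TEL, Category.FUSION_ITS_PLUS, Category.ECTR):
            if self.telomere_length_kb <= 0:
                raise ConsistencyError(f"{self.category} requires a positive measured length")


@dataclass(frozen=True)
class ReportRow:
    """Per-arm statistics row (appendix-style table layout).

    ``overall_*`` statistics pool end-telomere lengths, internal-telomere
    (ITS+) lengths, and zeros for TFE/ITS- sightings.  ``cv`` is
    overall_sd/overall_mean, None when the mean is 0.  Means that have no
    supporting molecules are None and render as NA.
    """

    arm_id: str
    overall_count: int
    endtel_count: int
    tfe_count: int
    its_plus_count: int
    its_minus_count: int
    overall_mean_kb: float
    overall_sd_kb: float
    overall_max_kb: float
    endtel_mean_kb: float | None
    endtel_sd_kb: float | None
    its_plus_mean_kb: float | None
    endtel_pct: float
    tfe_pct: float
    its_plus_pct: float
    its_minus_pct: float
    cv: float | None

    def __post_init__(self):
        if self.overall_count != (self.endtel_count + self.tfe_count
                                  + self.its_plus_count + self.its_minus_count):
            raise ConsistencyError(f"{self.arm_id}: overall_count != sum of category counts")
        for p in (self.endtel_pct, self.tfe_pct, self.its_plus_pct, self.its_minus_pct):
            if not (0.0 <= p <= 100.0):
                raise ConsistencyError(f"{self.arm_id}: percentage outside [0, 100]")

    @property
    def its_count(self) -> int:
        return self.its_plus_count + self.its_minus_count

    @property
    def its_pct(self) -> float:
        return self.its_plus_pct + self.its_minus_pct


# Per-arm statistics and report rows share one layout.
ArmStats = ReportRow


@dataclass(frozen=True)
class ReadoutSummary:
    """Genome-wide readouts over all classified arm-anchored molecules."""

    n_molecules: int                 # unique arm-anchored molecules
    overall_mean_kb: float
    overall_sd_kb: float
    endtel_mean_kb: float | None
    endtel_sd_kb: float | None
    its_plus_mean_kb: float | None
    its_plus_sd_kb: float | None
    cv: float
    endtel_pct: float
    tfe_pct: float
    its_plus_pct: float
    its_minus_pct: float
    frac_gt_15kb: float              # of measured telomeres (END_TEL + ITS+)
    n_measured_telomeres: int
    frac_arms_max_gt_10kb: float
    per_arm_cvs: dict[str, float]
    median_cv: float | None
    ectr_count: int
    n_unclassified: int

    @property
    def fusion_pct(self) -> float:
        return self.its_plus_pct + self.its_minus_pct


@dataclass(frozen=True)
class TTestResult:
    """Two-tailed unequal-variance (Welch) t-test result."""

    t_statistic: float
    degrees_of_freedom: float
    p_value_two_tailed: float

    def __post_init__(self):
        if not (0.0 <= self.p_value_two_tailed <= 1.0):
            raise ConsistencyError("p-value outside [0, 1]")


@dataclass(frozen=True)
class ALTThresholds:
    """Decision thresholds of the five-readout ALT caller.

    Each threshold sits between the observed ALT+ minima and the TEL+ /
    senescent maxima of the corresponding readout; a 3-of-5 vote keeps a
    single noisy readout from flipping the call.
    """

    its_plus_pct: float = 1.0
    its_minus_pct: float = 0.25
    tfe_pct: float = 1.0
    cv: float = 1.0
    super_long_pct: float = 0.5     # percent of measured telomeres > 15 kb
    votes_required: int = 3


@dataclass(frozen=True)
class ALTCall:
    """Five-flag ALT-positivity decision."""

    flags: dict[str, bool]
    thresholds: ALTThresholds
    n_positive: int
    call: str                        # "ALT_positive" | "ALT_negative"

    def __post_init__(self):
        expected = "ALT_positive" if self.n_positive >= self.thresholds.votes_required else "ALT_negative"
        if self.call != expected:
            raise ConsistencyError("call inconsistent with vote count")
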