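"""Synthetic single-molecule optical maps of chromosome ends.

Generates reference arm maps and molecule populations with the statistical
structure the downstream analysis assumes: a per-cell-line mixture of end
telomeres, telomere-free ends (TFEs), fusions with/without internal
telomere signal (ITS+/ITS-), and extrachromosomal telomeric repeats
(ECTRs), plus single-molecule measurement noise (label sizing error,
dropout, false labels, intensity noise).

Packaged profiles transcribe the published readout table for six cell
lines (three ALT+, two telomerase-positive, one senescent fibroblast
line); their super-long-telomere mass is calibrated with
:func:`calibrate_tail`.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import replace

import numpy as np
import yaml

from .errors import CalibrationError, InvalidParameterError, UnknownArmError, UnknownProfileError
from .model import (
    DEFAULT_INTENSITY_PER_KB,
    EXCLUDED_ARMS,
    Category,
    CellLineProfile,
    LengthDistribution,
    Molecule,
    MoleculeTruth,
    NoiseModel,
    ReferenceArmMap,
    ReferenceSet,
)

__all__ = [
    "ARM_NAME_SEQUENCE",
    "SUPER_LONG_KB",
    "make_reference",
    "calibrate_tail",
    "profile_from_table1",
    "list_profiles",
    "simulate_cell_line",
    "build_worked_fixture",
]

#: Human chromosome-arm naming sequence with the acrocentric short arms
#: (no mappable subtelomere) skipped; the sex-chromosome ends are the
#: pseudoautosomal XpYp / XqYq arms.
ARM_NAME_SEQUENCE: tuple[str, ...] = tuple(
    f"{c}{pq}" for c in range(1, 23) for pq in ("p", "q") if f"{c}{pq}" not in EXCLUDED_ARMS
) + ("XpYp", "XqYq")

#: Molecule-level super-long telomere threshold (kb).
SUPER_LONG_KB = 15.0

#: The terminal telomere-repeat region carries no nickase sites, so the
#: distal-most reference nick label sits at least this far from the
#: chromosome terminus.
TERMINAL_GAP_BP = 6_000.0

# Fiber geometry (bp).  Molecules must pass the >150 kb loading threshold;
# ECTRs are exempt because they are telomere-only fibers.  Fusions combine
# a long subtelomeric fragment with a partner fragment large enough to
# carry nick labels of its own.
MIN_BACKBONE_BP = 150_000.0
MAX_BACKBONE_BP = 400_000.0
FUSION_MIN_BACKBONE_BP = 220_000.0
FUSION_MAX_BACKBONE_BP = 420_000.0
FUSION_MIN_SUBTEL_BP = 150_000.0
FUSION_MIN_PARTNER_BP = 40_000.0
#: Probability that a fusion partner fragment is another arm's reversed
#: subtelomere (otherwise an unmapped random label pattern).
FUSION_MAPPED_PARTNER_PROB = 0.5


def make_reference(
    n_arms: int = 41,
    mean_label_spacing_bp: float = 9_000.0,
    map_length_bp: float = 300_000.0,
    min_spacing_bp: float = 1_500.0,
    seed: int = 0,
    terminal_gap_bp: float = TERMINAL_GAP_BP,
) -> ReferenceSet:
    """Generate a synthetic reference set of subtelomeric arm maps.

    Each arm gets Poisson-interval nick-label positions (exponential
    inter-label gaps conditioned on >= ``min_spacing_bp``, i.e. min-shifted
    by memorylessness, with the rate set so the mean gap equals
    ``mean_label_spacing_bp`` exactly) over a map of ``map_length_bp``,
    anchored with the chromosome terminus at the maximal coordinate.  Arm
    ids follow the human arm naming sequence, skipping the excluded
    acrocentric p-arms.
    """
    if mean_label_spacing_bp <= 0 or map_length_bp <= 0 or min_spacing_bp <= 0:
        raise InvalidParameterError("spacings and map length must be positive")
    if min_spacing_bp >= mean_label_spacing_bp:
        raise InvalidParameterError("min_spacing_bp must be below the mean spacing")
    if n_arms < 1:
        raise InvalidParameterError("n_arms must be >= 1")
    if map_length_bp < 10 * mean_label_spacing_bp:
        raise InvalidParameterError("map_length_bp must be >= 10x mean label spacing")

    names = list(ARM_NAME_SEQUENCE) + [f"extra{i}" for i in range(1, max(0, n_arms - len(ARM_NAME_SEQUENCE)) + 1)]
    rng = np.random.default_rng(seed)
    arms: dict[str, ReferenceArmMap] = {}
    for arm_id in names[:n_arms]:
        # anchor at the chromosome end: the terminal repeat region carries
        # no nick sites, so the distal-most label sits terminal_gap_bp from
        # the terminus, with Poisson intervals proceeding inward
        pos, x = [], map_length_bp - terminal_gap_bp
        while x >= 0.0:
            pos.append(x)
            x -= min_spacing_bp + rng.exponential(mean_label_spacing_bp - min_spacing_bp)
        arms[arm_id] = ReferenceArmMap(
            arm_id=arm_id,
            label_positions=np.asarray(pos[::-1]),
            chrom_end_pos=map_length_bp,
            map_length_bp=map_length_bp,
        )
    return ReferenceSet(arms=arms)


def calibrate_tail(
    dist: LengthDistribution,
    target_frac_gt_15kb: float,
    tol: float = 1e-3,
) -> LengthDistribution:
    """Solve the tail mixture weight so that P(length > 15 kb) hits a target.

    Monotone bisection on ``tail_weight``: the survival mass at 15 kb is
    increasing in the weight whenever the tail component is heavier there
    than the body.  Raises :class:`CalibrationError` when the target cannot
    be reached (below the body's intrinsic mass, or above the tail's).
    """
    if not (0.0 <= target_frac_gt_15kb <= 0.5):
        raise InvalidParameterError("target fraction must be in [0, 0.5]")
    from scipy.stats import lognorm

    p_body = dist.with_tail_weight(0.0).sf_kb(SUPER_LONG_KB)
    p_tail_mass = float(lognorm.sf(SUPER_LONG_KB, s=dist.tail_sigma, scale=dist.tail_median_kb))

    if target_frac_gt_15kb <= p_body:
        if p_body - target_frac_gt_15kb <= tol:
            return dist.with_tail_weight(0.0)
        raise CalibrationError(
            f"target {target_frac_gt_15kb:.4f} below the body's intrinsic >15 kb mass {p_body:.4f}"
        )
    if target_frac_gt_15kb > p_tail_mass:
        raise CalibrationError(
            f"target {target_frac_gt_15kb:.4f} above the tail component's >15 kb mass {p_tail_mass:.4f}"
        )

    lo, hi = 0.0, 1.0 - 1e-9
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if dist.with_tail_weight(mid).sf_kb(SUPER_LONG_KB) < target_frac_gt_15kb:
            lo = mid
        else:
            hi = mid
    out = dist.with_tail_weight(0.5 * (lo + hi))
    if abs(out.sf_kb(SUPER_LONG_KB) - target_frac_gt_15kb) > tol:
        raise CalibrationError("bisection did not converge to the target mass")
    return out


def _canonical_profile_name(name: str) -> str:
    return "".join(ch for ch in name.lower() if ch.isalnum())


def list_profiles() -> list[str]:
    """Names of the packaged cell-line profiles."""
    root = importlib.resources.files("telomap") / "data" / "profiles"
    return sorted(p.name[: -len(".yaml")] for p in root.iterdir() if p.name.endswith(".yaml"))


def _load_profile_yaml(name: str) -> dict:
    root = importlib.resources.files("telomap") / "data" / "profiles"
    wanted = _canonical_profile_name(name)
    for p in root.iterdir():
        if p.name.endswith(".yaml") and _canonical_profile_name(p.name[:-5]) == wanted:
            return yaml.safe_load(p.read_text())
    raise UnknownProfileError(name)


def profile_from_yaml(path_or_dict) -> CellLineProfile:
    """Build a profile from a YAML file path or an already-parsed mapping."""
    if isinstance(path_or_dict, dict):
        raw = path_or_dict
    else:
        with open(path_or_dict) as fh:
            raw = yaml.safe_load(fh)
    return _build_profile(raw)


def _build_profile(raw: dict) -> CellLineProfile:
    def dist(d: dict) -> LengthDistribution:
        return LengthDistribution(
            body_mean_kb=float(d["body_mean_kb"]),
            body_sd_kb=float(d["body_sd_kb"]),
            tail_weight=float(d.get("tail_weight", 0.0)),
            tail_median_kb=float(d.get("tail_median_kb", 20.0)),
            tail_sigma=float(d.get("tail_sigma", 0.6)),
        )

    noise = NoiseModel(**raw.get("noise", {}))
    frac_its_plus = float(raw["frac_its_plus"])
    frac_its_minus = float(raw["frac_its_minus"])
    frac_tfe = float(raw["frac_tfe"])
    frac_endtel = raw.get("frac_endtel")
    if frac_endtel is None:
        frac_endtel = 1.0 - frac_its_plus - frac_its_minus - frac_tfe
    endtel_len = dist(raw["endtel_len"])
    its_plus_len = dist(raw["its_plus_len"])

    # Calibrate the end-telomere tail so that the pooled measured-telomere
    # population (end telomeres + internal ITS+ telomeres, weighted by
    # their mixture fractions) carries the configured >15 kb mass.  The
    # ITS+ body already contributes some mass of its own.
    target = raw.get("frac_telomeres_gt_15kb")
    if target is not None and frac_endtel > 0:
        target = float(target)
        w_end = frac_endtel / (frac_endtel + frac_its_plus)
        p_its = its_plus_len.sf_kb(SUPER_LONG_KB)
        endtel_target = max(0.0, (target - (1.0 - w_end) * p_its) / w_end)
        try:
            endtel_len = calibrate_tail(endtel_len, min(endtel_target, 0.5))
        except CalibrationError:
            # Target below the body's intrinsic tail: the lightest
            # admissible configuration is no tail component at all.
            endtel_len = endtel_len.with_tail_weight(0.0)

    return CellLineProfile(
        name=str(raw["name"]),
        frac_endtel=float(frac_endtel),
        frac_tfe=frac_tfe,
        frac_its_plus=frac_its_plus,
        frac_its_minus=frac_its_minus,
        ectr_per_100_molecules=float(raw.get("ectr_per_100_molecules", 0.0)),
        endtel_len=endtel_len,
        its_plus_len=its_plus_len,
        ectr_len=dist(raw.get("ectr_len", {"body_mean_kb": 11.0, "body_sd_kb": 8.0})),
        mean_molecules_per_arm=float(raw.get("mean_molecules_per_arm", 30.0)),
        noise=noise,
        frac_telomeres_gt_15kb=None if target is None else float(target),
    )


def profile_from_table1(cell_line_name: str) -> CellLineProfile:
    """Packaged profile for one of the six published cell lines.

    Category fractions and mean telomere lengths transcribe the published
    readout table; the end-telomere length distribution's heavy tail is
    calibrated against the cell line's reported super-long (>15 kb)
    telomere mass.
    """
    return _build_profile(_load_profile_yaml(cell_line_name))


# ----------------------------------------------------------------------
# molecule construction


def _window_labels(arm: ReferenceArmMap, span_bp: float) -> np.ndarray:
    """Reference nick labels in the subtelomeric window [chrom_end - span, chrom_end),
    shifted to molecule coordinates starting at 0."""
    start = max(0.0, arm.chrom_end_pos - span_bp)
    labels = arm.label_positions
    return labels[labels >= start] - start


def _reversed_partner_labels(arm: ReferenceArmMap, span_bp: float) -> np.ndarray:
    """Another arm's subtelomeric window, reversed so its chromosome end
    faces coordinate 0 (the fusion junction)."""
    win = _window_labels(arm, span_bp)
    span = min(span_bp, arm.chrom_end_pos)
    return np.sort(span - win)


def _random_partner_labels(rng: np.random.Generator, span_bp: float, spacing_bp: float) -> np.ndarray:
    # a fusion partner fragment must be labeled to be recognizable as a
    # fused fragment at all, so the Poisson count is conditioned on >= 2
    n = 0
    while n < 2:
        n = rng.poisson(span_bp / spacing_bp)
    return np.sort(rng.uniform(0.0, span_bp, size=n))


def _flip(positions: np.ndarray, length: float) -> np.ndarray:
    return np.sort(length - np.asarray(positions))


class _Builder:
    """Accumulates raw (noise-free) molecules for one simulation run."""

    def __init__(self, reference: ReferenceSet, rng: np.random.Generator, k_units_per_kb: float):
        self.reference = reference
        self.rng = rng
        self.k = k_units_per_kb
        self.spacing = reference.mean_label_spacing_bp
        self.molecules: list[Molecule] = []
        self._next_id = 1

    def _emit(self, length, nicks, tel_pos, tel_int, truth, random_flip=True):
        nicks = np.asarray(nicks, dtype=float)
        tel_pos = np.asarray(tel_pos, dtype=float)
        if random_flip and self.rng.random() < 0.5:
            order = np.argsort(length - tel_pos)
            nicks = _flip(nicks, length)
            tel_pos = (length - tel_pos)[order]
            tel_int = np.asarray(tel_int, dtype=float)[order]
        self.molecules.append(
            Molecule(
                molecule_id=self._next_id,
                length_bp=float(length),
                nick_labels=nicks,
                tel_positions=tel_pos,
                tel_intensities=np.asarray(tel_int, dtype=float),
                truth=truth,
            )
        )
        self._next_id += 1

    def end_tel(self, arm: ReferenceArmMap, t_kb: float, random_flip=True):
        t_bp = 1000.0 * t_kb
        backbone = self.rng.uniform(MIN_BACKBONE_BP, MAX_BACKBONE_BP)
        span = min(arm.chrom_end_pos, max(MIN_BACKBONE_BP, backbone - t_bp))
        nicks = _window_labels(arm, span)
        length = span + t_bp
        # terminal telomere label sits at the fiber end: nothing lies distal
        self._emit(length, nicks, [length], [self.k * t_kb],
                   MoleculeTruth(Category.END_TEL, (arm.arm_id,), t_kb), random_flip)

    def tfe(self, arm: ReferenceArmMap, random_flip=True):
        span = min(arm.chrom_end_pos, self.rng.uniform(MIN_BACKBONE_BP, MAX_BACKBONE_BP))
        nicks = _window_labels(arm, span)
        self._emit(span, nicks, [], [],
                   MoleculeTruth(Category.TFE, (arm.arm_id,), 0.0), random_flip)

    def fusion(self, arm: ReferenceArmMap, t_kb: float, random_flip=True):
        """Fusion molecule: arm subtelomere + (optional internal telomere) + partner."""
        t_bp = 1000.0 * t_kb
        backbone = self.rng.uniform(FUSION_MIN_BACKBONE_BP, FUSION_MAX_BACKBONE_BP)
        hi = min(arm.chrom_end_pos, backbone - FUSION_MIN_PARTNER_BP - t_bp)
        sub_span = self.rng.uniform(FUSION_MIN_SUBTEL_BP, hi) if hi > FUSION_MIN_SUBTEL_BP else FUSION_MIN_SUBTEL_BP
        sub_span = min(sub_span, arm.chrom_end_pos)
        partner_span = max(FUSION_MIN_PARTNER_BP, backbone - sub_span - t_bp)
        junction = sub_span + t_bp
        nicks = [_window_labels(arm, sub_span)]
        partner_arm: tuple[str, ...] = ()
        if self.rng.random() < FUSION_MAPPED_PARTNER_PROB:
            other = self.reference[self.rng.choice(self.reference.arm_ids())]
            partner = _reversed_partner_labels(other, partner_span)
            partner_span = min(partner_span, other.chrom_end_pos)
            partner_arm = (other.arm_id,)
        else:
            partner = _random_partner_labels(self.rng, partner_span, self.spacing)
        nicks.append(junction + partner)
        length = junction + partner_span
        if t_kb > 0:
            tel_pos, tel_int = [sub_span + t_bp / 2.0], [self.k * t_kb]
            cat = Category.FUSION_ITS_PLUS
        else:
            tel_pos, tel_int = [], []
            cat = Category.FUSION_ITS_MINUS
        self._emit(length, np.concatenate(nicks), tel_pos, tel_int,
                   MoleculeTruth(cat, (arm.arm_id,) + partner_arm, t_kb), random_flip)

    def ectr(self, t_kb: float, random_flip=True):
        length = max(1000.0 * t_kb, 1.0)
        self._emit(length, [], [length / 2.0], [self.k * t_kb],
                   MoleculeTruth(Category.ECTR, (), t_kb), random_flip)


def _apply_noise(mol: Molecule, noise: NoiseModel, rng: np.random.Generator) -> Molecule:
    L = mol.length_bp
    nicks = mol.nick_labels
    if noise.dropout_prob > 0 and nicks.size:
        nicks = nicks[rng.random(nicks.size) >= noise.dropout_prob]
    n_false = rng.poisson(noise.false_label_rate_per_100kb * L / 100_000.0)
    if n_false:
        nicks = np.concatenate([nicks, rng.uniform(0.0, L, size=n_false)])
    if noise.sizing_sd_bp > 0 and nicks.size:
        nicks = nicks + rng.normal(0.0, noise.sizing_sd_bp, size=nicks.size)
    # snap to the 0.1 bp precision of the molecule file dialect so jittered
    # labels cannot collide only after serialization round-off
    nicks = np.unique(np.minimum(np.round(np.clip(nicks, 0.0, L), 1), L))

    tel_pos, tel_int = mol.tel_positions, mol.tel_intensities
    if tel_pos.size:
        if noise.sizing_sd_bp > 0:
            tel_pos = np.clip(tel_pos + rng.normal(0.0, noise.sizing_sd_bp, size=tel_pos.size), 0.0, L)
        if noise.intensity_cv > 0:
            tel_int = tel_int * np.maximum(1e-3, 1.0 + rng.normal(0.0, noise.intensity_cv, size=tel_int.size))
        order = np.argsort(tel_pos)
        tel_pos, tel_int = tel_pos[order], tel_int[order]
    return Molecule(mol.molecule_id, L, nicks, tel_pos, tel_int, mol.truth)


def simulate_cell_line(
    profile: CellLineProfile,
    reference: ReferenceSet,
    seed: int,
    k_units_per_kb: float = DEFAULT_INTENSITY_PER_KB,
    apply_noise: bool = True,
) -> list[Molecule]:
    """Simulate one cell line's molecule population over a reference set.

    Per arm, Poisson(``mean_molecules_per_arm``) arm-anchored molecules are
    drawn, each assigned a category by the profile's mixture fractions and
    constructed with the geometry of that chromosome-end feature.  ECTR
    molecules are emitted additionally at the configured per-100-molecules
    rate.  Measurement noise is applied last (disable with
    ``apply_noise=False``); truth records are retained on every molecule.

    Telomere lengths for categories defined by a *detected* telomere
    (END_TEL, ITS+, ECTR) are drawn truncated at the detection floor.
    """
    if len(reference) == 0:
        raise InvalidParameterError("reference set is empty")
    rng = np.random.default_rng(seed)
    b = _Builder(reference, rng, k_units_per_kb)
    floor = profile.noise.detection_floor_kb
    cats = list(profile.category_fractions)
    probs = np.asarray([profile.category_fractions[c] for c in cats])

    n_anchored = 0
    for arm_id in reference.arm_ids():
        if arm_id in reference.excluded_arms:
            continue
        arm = reference[arm_id]
        for _ in range(rng.poisson(profile.mean_molecules_per_arm)):
            n_anchored += 1
            cat = cats[rng.choice(len(cats), p=probs)]
            if cat is Category.END_TEL:
                b.end_tel(arm, float(profile.endtel_len.sample_kb(rng, 1, floor)[0]))
            elif cat is Category.TFE:
                b.tfe(arm)
            elif cat is Category.FUSION_ITS_PLUS:
                b.fusion(arm, float(profile.its_plus_len.sample_kb(rng, 1, floor)[0]))
            else:
                b.fusion(arm, 0.0)
    for _ in range(rng.poisson(n_anchored * profile.ectr_per_100_molecules / 100.0)):
        b.ectr(float(profile.ectr_len.sample_kb(rng, 1, floor)[0]))

    molecules = b.molecules
    if apply_noise:
        molecules = [_apply_noise(m, profile.noise, rng) for m in molecules]
        # below-floor telomeres emit no label
        if floor > 0:
            out = []
            for m in molecules:
                keep = m.tel_intensities >= 0  # all, unless truth says undetectable
                if m.truth is not None and m.truth.telomere_kb < floor and m.tel_positions.size:
                    keep = np.zeros(m.tel_positions.size, dtype=bool)
                out.append(Molecule(m.molecule_id, m.length_bp, m.nick_labels,
                                    m.tel_positions[keep], m.tel_intensities[keep], m.truth))
            molecules = out
    return molecules


def build_worked_fixture(
    arm_id: str,
    composition: list[tuple],
    reference: ReferenceSet,
    k_units_per_kb: float = DEFAULT_INTENSITY_PER_KB,
) -> list[Molecule]:
    """Construct a noiseless per-arm molecule set with an exact composition.

    ``composition`` is a list of ``(category, count, telomere_kb)`` tuples;
    categories are the four arm-anchored ones.  Geometry guarantees the
    downstream classification: end telomeres terminate the fiber, fusions
    carry a >=40 kb labeled partner fragment, TFEs end at the chromosome
    terminus.  Deterministic: no randomness is used.
    """
    if arm_id not in reference:
        raise UnknownArmError(arm_id)
    arm = reference[arm_id]
    rng = np.random.default_rng(0)  # unused draws; _Builder requires a generator
    b = _Builder(reference, rng, k_units_per_kb)
    sub_span = min(arm.chrom_end_pos, 250_000.0)
    partner_span = 60_000.0
    partner = np.arange(9_000.0, partner_span - 3_000.0, 9_000.0)
    for category, count, t_kb in composition:
        cat = Category(category)
        if cat not in (Category.END_TEL, Category.TFE,
                       Category.FUSION_ITS_PLUS, Category.FUSION_ITS_MINUS):
            raise InvalidParameterError(f"{cat}: not an arm-anchored worked-fixture category")
        if count < 0:
            raise InvalidParameterError("counts must be >= 0")
        for _ in range(int(count)):
            if cat is Category.END_TEL:
                t_bp = 1000.0 * t_kb
                nicks = _window_labels(arm, sub_span)
                b._emit(sub_span + t_bp, nicks, [sub_span + t_bp], [k_units_per_kb * t_kb],
                        MoleculeTruth(cat, (arm_id,), t_kb), random_flip=False)
            elif cat is Category.TFE:
                nicks = _window_labels(arm, sub_span)
                b._emit(sub_span, nicks, [], [],
                        MoleculeTruth(cat, (arm_id,), 0.0), random_flip=False)
            else:
                t_bp = 1000.0 * t_kb if cat is Category.FUSION_ITS_PLUS else 0.0
                junction = sub_span + t_bp
                nicks = np.concatenate([_window_labels(arm, sub_span), junction + partner])
                tel_pos = [sub_span + t_bp / 2.0] if t_bp > 0 else []
                tel_int = [k_units_per_kb * t_kb] if t_bp > 0 else []
                b._emit(junction + partner_span, nicks, tel_pos, tel_int,
                        MoleculeTruth(cat, (arm_id,), t_kb if t_bp > 0 else 0.0), random_flip=False)
    return b.molecules
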