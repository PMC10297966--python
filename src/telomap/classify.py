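"""Telomere-length readout and chromosome-end classification.

The telomere channel reports label intensity proportional to repeat length;
:func:`estimate_telomere_length` inverts that linear model with a detection
floor (about 100 bp) and ceiling.  :func:`classify_molecule` combines the
telomere clusters with the arm alignments and calls one of the categories:

* END_TEL — an end-anchored arm with a terminal telomere signal;
* TFE — the chromosome end is reached but carries no telomere signal;
* FUSION_ITS_PLUS — a telomere signal internal to the fiber at the junction
  between the arm's end and a further labeled fragment;
* FUSION_ITS_MINUS — the arm's end continues into a labeled fragment with
  no telomere signal at the junction;
* ECTR — an unalignable telomere-only fiber;
* UNCLASSIFIED — anything else (e.g. a fiber truncated short of the end
  window, which must not inflate the TFE count).

TFE and FUSION_ITS_MINUS are assigned a telomere length of 0 kb by
convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError
from .model import (
    Alignment,
    CalibrationModel,
    Category,
    ClassifiedMolecule,
    ClassifyParams,
    Molecule,
)

__all__ = [
    "TelomereCluster",
    "estimate_telomere_length",
    "merge_telomere_clusters",
    "classify_molecule",
]

_EPS_BP = 1.0


def estimate_telomere_length(cluster_intensity: float, cal: CalibrationModel) -> float:
    """Telomere length (kb) from summed cluster intensity.

    length = intensity / k, clamped to the detection ceiling; below-floor
    signal reports 0 (undetected).
    """
    if cluster_intensity < 0:
        raise InvalidParameterError("intensity must be >= 0")
    length = cluster_intensity / cal.k_units_per_kb
    if length < cal.detection_floor_kb:
        return 0.0
    return min(length, cal.detection_ceiling_kb)


@dataclass(frozen=True)
class TelomereCluster:
    """A run of telomere labels merged across gaps <= cluster_gap_bp."""

    start_bp: float
    end_bp: float
    total_intensity: float

    @property
    def centroid_bp(self) -> float:
        return 0.5 * (self.start_bp + self.end_bp)

    @property
    def span_bp(self) -> tuple[float, float]:
        return (self.start_bp, self.end_bp)


def merge_telomere_clusters(
    tel_positions: np.ndarray,
    tel_intensities: np.ndarray,
    cluster_gap_bp: float,
) -> list[TelomereCluster]:
    """Merge position-sorted telomere labels into clusters, summing intensity."""
    pos = np.asarray(tel_positions, dtype=float)
    inten = np.asarray(tel_intensities, dtype=float)
    if pos.size == 0:
        return []
    if np.any(np.diff(pos) < 0):
        raise InvalidParameterError("telomere labels must be position-sorted")
    out: list[TelomereCluster] = []
    start = end = pos[0]
    total = inten[0]
    for p, w in zip(pos[1:], inten[1:]):
        if p - end <= cluster_gap_bp:
            end, total = p, total + w
        else:
            out.append(TelomereCluster(start, end, total))
            start = end = p
            total = w
    out.append(TelomereCluster(start, end, total))
    return out


def _oriented_frame(molecule: Molecule, aln: Alignment, clusters: list[TelomereCluster]):
    """Mirror the molecule if needed so the chromosome end lies toward
    increasing coordinates; returns (nicks, clusters, last_matched, end)."""
    L = molecule.length_bp
    if aln.orientation == "forward":
        return molecule.nick_labels, clusters, aln.distal_mol_pos_bp, L
    nicks = np.sort(L - molecule.nick_labels)
    mirrored = sorted(
        (TelomereCluster(L - c.end_bp, L - c.start_bp, c.total_intensity) for c in clusters),
        key=lambda c: c.start_bp,
    )
    return nicks, mirrored, L - aln.distal_mol_pos_bp, L


def classify_molecule(
    molecule: Molecule,
    alignments: list[Alignment],
    params: ClassifyParams | None = None,
    cal: CalibrationModel | None = None,
) -> ClassifiedMolecule:
    """Call the chromosome-end category of one molecule.

    The primary (best-scoring) alignment whose distal matched label lies
    within ``end_window_bp`` of the chromosome terminus provides end
    context; the molecule is read in that alignment's orientation so the
    terminus points distal.  Every end-anchored segment contributes an arm
    of record (a fusion of two arms is a sighting of each arm's end; a
    same-arm fusion records the arm twice).
    """
    params = params or ClassifyParams()
    cal = cal or CalibrationModel()
    clusters = merge_telomere_clusters(molecule.tel_positions, molecule.tel_intensities,
                                       params.cluster_gap_bp)
    detected = [c for c in clusters if estimate_telomere_length(c.total_intensity, cal) > 0]

    end_aligned = sorted(
        (a for a in alignments if a.chrom_end_offset_bp <= params.end_window_bp),
        key=lambda a: -a.score,
    )
    if not end_aligned:
        if not alignments and detected:
            total = sum(c.total_intensity for c in detected)
            return ClassifiedMolecule(
                molecule.molecule_id, Category.ECTR, (),
                estimate_telomere_length(total, cal), molecule.truth,
            )
        return ClassifiedMolecule(molecule.molecule_id, Category.UNCLASSIFIED, (), 0.0, molecule.truth)

    primary = end_aligned[0]
    arms = tuple(a.arm_id for a in end_aligned)
    nicks, oriented, last_matched, end = _oriented_frame(molecule, primary, detected)
    distal_clusters = [c for c in oriented if c.centroid_bp > last_matched + _EPS_BP]

    if distal_clusters:
        c = distal_clusters[0]  # the cluster nearest the junction/terminus
        length_kb = estimate_telomere_length(c.total_intensity, cal)
        flank = end - c.end_bp
        has_distal_nick = bool(np.any(nicks > c.end_bp + _EPS_BP))
        if flank >= params.internal_min_flank_bp and has_distal_nick:
            return ClassifiedMolecule(molecule.molecule_id, Category.FUSION_ITS_PLUS,
                                      arms, length_kb, molecule.truth)
        return ClassifiedMolecule(molecule.molecule_id, Category.END_TEL,
                                  (primary.arm_id,), length_kb, molecule.truth)

    overhang = end - last_matched
    has_nick = bool(np.any(nicks > last_matched + _EPS_BP))
    if overhang >= params.internal_min_flank_bp and has_nick:
        return ClassifiedMolecule(molecule.molecule_id, Category.FUSION_ITS_MINUS,
                                  arms, 0.0, molecule.truth)
    # a true telomere-free end leaves only the short label-free terminal
    # stretch of the reference beyond its last matched label; an unlabeled
    # overhang running far past the projected terminus is not credible as
    # "the chromosome end was reached" and abstains instead
    if params.tfe_min_overhang_bp <= overhang <= params.end_window_bp:
        return ClassifiedMolecule(molecule.molecule_id, Category.TFE,
                                  (primary.arm_id,), 0.0, molecule.truth)
    return ClassifiedMolecule(molecule.molecule_id, Category.UNCLASSIFIED, (), 0.0, molecule.truth)
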