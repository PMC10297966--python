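"""End-to-end orchestration: align -> classify -> summarize -> call."""

from __future__ import annotations

from dataclasses import dataclass, field

from .align import AlignmentParams, ArmPrefilter, align_molecule
from .classify import classify_molecule
from .model import (
    ALTCall,
    ALTThresholds,
    ArmStats,
    CalibrationModel,
    CellLineProfile,
    ClassifiedMolecule,
    ClassifyParams,
    Molecule,
    ReadoutSummary,
    ReferenceSet,
)
from .readouts import call_alt, compute_arm_tables, genome_summary
from .simulate import simulate_cell_line

__all__ = ["AnalysisResult", "analyze_molecules", "simulate_and_analyze"]


@dataclass
class AnalysisResult:
    """Everything the pipeline computes for one molecule set."""

    classified: list[ClassifiedMolecule]
    arm_tables: dict[str, ArmStats]
    summary: ReadoutSummary
    alt_call: ALTCall
    n_molecules: int = field(default=0)


def analyze_molecules(
    molecules: list[Molecule],
    reference: ReferenceSet,
    align_params: AlignmentParams | None = None,
    classify_params: ClassifyParams | None = None,
    calibration: CalibrationModel | None = None,
    thresholds: ALTThresholds | None = None,
) -> AnalysisResult:
    """Run the full readout pipeline on a molecule set."""
    align_params = align_params or AlignmentParams()
    prefilter = ArmPrefilter(reference) if align_params.candidate_arms is not None else None
    classified = []
    for mol in molecules:
        alignments = align_molecule(mol, reference, align_params, prefilter)
        classified.append(classify_molecule(mol, alignments, classify_params, calibration))
    arm_tables = compute_arm_tables(classified)
    summary = genome_summary(classified, arm_tables)
    return AnalysisResult(
        classified=classified,
        arm_tables=arm_tables,
        summary=summary,
        alt_call=call_alt(summary, thresholds),
        n_molecules=len(molecules),
    )


def simulate_and_analyze(
    profile: CellLineProfile,
    reference: ReferenceSet,
    seed: int,
    apply_noise: bool = True,
    **kwargs,
) -> AnalysisResult:
    """Simulate one cell line and analyze it (convenience wrapper)."""
    molecules = simulate_cell_line(profile, reference, seed, apply_noise=apply_noise)
    return analyze_molecules(molecules, reference, **kwargs)
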