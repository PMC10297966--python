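"""File formats: simplified BNX/CMAP dialects, truth sidecar, and reports.

The molecule and reference files are documented, versioned subsets of the
community single-molecule optical-map formats (full grammars are out of
scope; the field layout is kept compatible where it overlaps):

BNX dialect (``# telomap-bnx 1.0``), four rows per molecule::

    0     <molecule_id>  <length_bp>
    1     <nick position> ...            (channel 1: genome-wide nick labels)
    2     <telomere position> ...        (channel 2: telomere labels)
    QX21  <telomere intensity> ...

CMAP dialect (``# telomap-cmap 1.0``): an ``# arm`` header comment per map
(``# arm  <map_id>  <arm_id>  <map_length_bp>``) and one data row per
label: ``map_id  map_length_bp  label_index  position``.

Positions are 0-based bp floats written to 0.1 bp; intensities to 6
significant digits.  Writers are deterministic; readers reject malformed
input with located errors.
"""

from __future__ import annotations

import json
from dataclasses import asdict

import numpy as np

from .errors import ConsistencyError, ParseError
from .model import (
    ALTCall,
    ArmStats,
    Category,
    Molecule,
    MoleculeTruth,
    ReadoutSummary,
    ReferenceArmMap,
    ReferenceSet,
    ReportRow,
)

__all__ = [
    "write_bnx", "read_bnx",
    "write_cmap", "read_cmap",
    "write_truth_tsv", "read_truth_tsv",
    "write_report", "summary_to_dict", "alt_call_to_dict", "arm_row_to_dict",
    "read_summary_json",
]

BNX_MAGIC = "# telomap-bnx 1.0"
CMAP_MAGIC = "# telomap-cmap 1.0"

_REPORT_COLUMNS = (
    "arm_id", "overall_count", "endtel_count", "tfe_count", "its_count",
    "its_plus_count", "its_minus_count", "overall_mean_kb", "overall_sd_kb",
    "overall_max_kb", "endtel_mean_kb", "endtel_sd_kb", "its_plus_mean_kb",
    "endtel_pct", "tfe_pct", "its_pct", "its_plus_pct", "its_minus_pct", "cv",
)


def _fmt_pos(values) -> str:
    return "\t".join(f"{v:.1f}" for v in values)


def _fmt_intensity(values) -> str:
    return "\t".join(f"{v:.6g}" for v in values)


# ----------------------------------------------------------------------
# BNX


def write_bnx(molecules: list[Molecule], path, header_comments: list[str] | None = None) -> None:
    """Write molecules in the simplified BNX dialect (deterministic bytes)."""
    lines = [BNX_MAGIC]
    for comment in header_comments or []:
        lines.append(f"# {comment}")
    for m in molecules:
        lines.append(f"0\t{m.molecule_id}\t{m.length_bp:.1f}")
        lines.append(("1\t" + _fmt_pos(m.nick_labels)).rstrip("\t"))
        lines.append(("2\t" + _fmt_pos(m.tel_positions)).rstrip("\t"))
        lines.append(("QX21\t" + _fmt_intensity(m.tel_intensities)).rstrip("\t"))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _parse_floats(fields: list[str], lineno: int, what: str) -> np.ndarray:
    try:
        return np.asarray([float(x) for x in fields])
    except ValueError:
        raise ParseError(f"non-numeric {what}", lineno) from None


def read_bnx(path) -> list[Molecule]:
    """Read a simplified-BNX file; raises :class:`ParseError` with the line
    number on any malformed record."""
    with open(path) as fh:
        raw = fh.read().splitlines()
    rows = [(i + 1, line) for i, line in enumerate(raw) if line.strip() and not line.startswith("#")]
    if len(rows) % 4 != 0:
        lineno = rows[-1][0] if rows else 1
        raise ParseError("truncated molecule record (expected 4 rows per molecule)", lineno)
    molecules = []
    for k in range(0, len(rows), 4):
        (ln0, l0), (ln1, l1), (ln2, l2), (lnq, lq) = rows[k: k + 4]
        f0 = l0.split("\t")
        if f0[0] != "0" or len(f0) != 3:
            raise ParseError("expected '0 <id> <length>' backbone row", ln0)
        for line, lineno, tag in ((l1, ln1, "1"), (l2, ln2, "2"), (lq, lnq, "QX21")):
            if line.split("\t", 1)[0] != tag:
                raise ParseError(f"expected '{tag}' row", lineno)
        try:
            mol_id, length = int(f0[1]), float(f0[2])
        except ValueError:
            raise ParseError("non-numeric molecule id/length", ln0) from None
        nicks = _parse_floats(l1.split("\t")[1:], ln1, "nick position")
        tel_pos = _parse_floats(l2.split("\t")[1:], ln2, "telomere position")
        tel_int = _parse_floats(lq.split("\t")[1:], lnq, "telomere intensity")
        if tel_pos.size != tel_int.size:
            raise ParseError("intensity row arity differs from telomere position row", lnq)
        try:
            molecules.append(Molecule(mol_id, length, nicks, tel_pos, tel_int))
        except ConsistencyError as exc:
            raise ParseError(str(exc), ln0) from None
    return molecules


# ----------------------------------------------------------------------
# CMAP


def write_cmap(reference: ReferenceSet, path) -> None:
    """Write a reference set in the simplified CMAP dialect."""
    lines = [CMAP_MAGIC]
    arm_ids = reference.arm_ids()
    for map_id, arm_id in enumerate(arm_ids, start=1):
        arm = reference[arm_id]
        lines.append(f"# arm\t{map_id}\t{arm_id}\t{arm.map_length_bp:.1f}")
    for map_id, arm_id in enumerate(arm_ids, start=1):
        arm = reference[arm_id]
        for idx, pos in enumerate(arm.label_positions, start=1):
            lines.append(f"{map_id}\t{arm.map_length_bp:.1f}\t{idx}\t{pos:.1f}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_cmap(path) -> ReferenceSet:
    """Read a simplified-CMAP file into a :class:`ReferenceSet`."""
    with open(path) as fh:
        raw = fh.read().splitlines()
    arm_names: dict[int, str] = {}
    lengths: dict[int, float] = {}
    labels: dict[int, dict[int, float]] = {}
    for lineno, line in enumerate(raw, start=1):
        if not line.strip():
            continue
        if line.startswith("#"):
            fields = line[1:].strip().split("\t")
            if fields and fields[0] == "arm":
                if len(fields) != 4:
                    raise ParseError("expected '# arm <map_id> <arm_id> <length>'", lineno)
                try:
                    map_id, length = int(fields[1]), float(fields[3])
                except ValueError:
                    raise ParseError("non-numeric map id/length in arm header", lineno) from None
                if map_id in arm_names:
                    raise ParseError(f"duplicate arm header for map {map_id}", lineno)
                arm_names[map_id] = fields[2]
                lengths[map_id] = length
            continue
        fields = line.split("\t")
        if len(fields) != 4:
            raise ParseError("expected 'map_id map_length label_index position'", lineno)
        try:
            map_id, length, idx, pos = int(fields[0]), float(fields[1]), int(fields[2]), float(fields[3])
        except ValueError:
            raise ParseError("non-numeric CMAP field", lineno) from None
        if map_id not in arm_names:
            raise ParseError(f"map {map_id} has no '# arm' header", lineno)
        if length != lengths[map_id]:
            raise ParseError(f"map {map_id} length differs from its header", lineno)
        if idx in labels.setdefault(map_id, {}):
            raise ParseError(f"duplicate label index {idx} for map {map_id}", lineno)
        labels[map_id][idx] = pos
    if not arm_names:
        raise ParseError("empty reference: no arm maps found", 1)
    arms: dict[str, ReferenceArmMap] = {}
    for map_id in sorted(arm_names):
        rows = labels.get(map_id, {})
        pos = np.asarray([rows[i] for i in sorted(rows)])
        try:
            arms[arm_names[map_id]] = ReferenceArmMap(
                arm_id=arm_names[map_id],
                label_positions=pos,
                chrom_end_pos=lengths[map_id],
                map_length_bp=lengths[map_id],
            )
        except ConsistencyError as exc:
            raise ParseError(str(exc), 1) from None
    return ReferenceSet(arms=arms)


# ----------------------------------------------------------------------
# truth sidecar


def write_truth_tsv(molecules: list[Molecule], path) -> None:
    """Simulation ground truth: molecule_id, category, arms, true telomere kb."""
    lines = ["molecule_id\tcategory\tarms\ttrue_kb"]
    for m in molecules:
        if m.truth is None:
            continue
        t = m.truth
        lines.append(f"{m.molecule_id}\t{t.category.value}\t{','.join(t.arms)}\t{t.telomere_kb:.4f}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_truth_tsv(path) -> dict[int, MoleculeTruth]:
    with open(path) as fh:
        raw = fh.read().splitlines()
    out: dict[int, MoleculeTruth] = {}
    for lineno, line in enumerate(raw[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 4:
            raise ParseError("expected 4 truth columns", lineno)
        arms = tuple(a for a in fields[2].split(",") if a)
        try:
            out[int(fields[0])] = MoleculeTruth(Category(fields[1]), arms, float(fields[3]))
        except ValueError:
            raise ParseError("malformed truth row", lineno) from None
    return out


# ----------------------------------------------------------------------
# reports


def _fmt_cell(name: str, value) -> str:
    if value is None:
        return "NA"
    if name == "cv":
        return f"{value:.2f}"
    if name.endswith(("_kb", "_pct")):
        return f"{value:.1f}"
    return str(value)


def arm_row_to_dict(row: ArmStats) -> dict:
    d = {c: getattr(row, c) for c in _REPORT_COLUMNS}
    return d


def summary_to_dict(summary: ReadoutSummary) -> dict:
    d = asdict(summary)
    d["fusion_pct"] = summary.fusion_pct
    return d


def alt_call_to_dict(call: ALTCall) -> dict:
    return {
        "flags": dict(call.flags),
        "thresholds": asdict(call.thresholds),
        "n_positive": call.n_positive,
        "call": call.call,
    }


def write_report(
    arm_tables: dict[str, ArmStats],
    summary: ReadoutSummary,
    tsv_path,
    json_path,
    alt_call: ALTCall | None = None,
    config: dict | None = None,
) -> None:
    """Write the per-arm TSV (appendix-style layout: one row per arm, fixed
    column order, 1-decimal kb and percentages) and the genome-level JSON
    summary.  Rows are re-validated; inconsistent rows refuse to write."""
    for arm_id, row in arm_tables.items():
        if row.overall_count != (row.endtel_count + row.tfe_count
                                 + row.its_plus_count + row.its_minus_count):
            raise ConsistencyError(f"{arm_id}: counts do not sum to overall_count")
    lines = ["\t".join(_REPORT_COLUMNS)]
    for arm_id in sorted(arm_tables, key=_arm_order):
        row = arm_tables[arm_id]
        lines.append("\t".join(_fmt_cell(c, getattr(row, c)) for c in _REPORT_COLUMNS))
    with open(tsv_path, "w") as fh:
        fh.write("\n".join(lines) + "\n")

    payload = {
        "summary": summary_to_dict(summary),
        "alt_call": alt_call_to_dict(alt_call) if alt_call is not None else None,
        "arms": {arm: arm_row_to_dict(row) for arm, row in arm_tables.items()},
        "config": config or {},
    }
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def _arm_order(arm_id: str):
    from .readouts import arm_sort_key

    return arm_sort_key(arm_id)


def read_summary_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
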