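"""Dynamic-programming alignment of molecule nick-label patterns to arm maps.

The aligner matches successive label *gaps* (interval agreement) rather than
absolute positions, which is invariant to the unknown offset of a molecule
within the arm — the standard approach for optical maps.  A chain of matched
pairs is feasible when every consecutive gap agrees within
``max(abs_tol_bp, rel_tol * d_ref)``; the score is
``match_bonus * n_matched`` minus per-label penalties for reference labels
(``miss_penalty``) and molecule labels (``extra_penalty``) skipped inside
the aligned core.  End gaps on both sequences are free (local alignment).

:func:`align_molecule` performs a greedy split alignment: the best accepted
alignment over all arms and orientations is found, its molecule span is
masked, and the remaining labels get one more pass — fusion molecules are
two-part, so at most two segments are reported.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .model import Alignment, AlignmentParams, Molecule, ReferenceArmMap, ReferenceSet

__all__ = ["align_to_arm", "align_molecule", "ArmPrefilter"]

_NEG = -1.0e18


@njit(cache=False)
def _dp_kernel(mol, ref, abs_tol, rel_tol, match_bonus, miss_pen, extra_pen, lookback):
    """Fill the chain DP table.

    ``score[i, j]`` is the best score of a chain whose last matched pair is
    (molecule label i, reference label j); ``pi/pj`` hold the predecessor
    pair for backtracking (-1 marks a chain start).
    """
    n = mol.shape[0]
    m = ref.shape[0]
    score = np.full((n, m), _NEG)
    pi = np.full((n, m), -1, dtype=np.int64)
    pj = np.full((n, m), -1, dtype=np.int64)
    for i in range(n):
        di_max = i if i < lookback else lookback
        for j in range(m):
            best = match_bonus  # start a new chain: end gaps are free
            bi = -1
            bj = -1
            dj_max = j if j < lookback else lookback
            for di in range(1, di_max + 1):
                dm = mol[i] - mol[i - di]
                for dj in range(1, dj_max + 1):
                    dr = ref[j] - ref[j - dj]
                    tol = abs_tol if abs_tol > rel_tol * dr else rel_tol * dr
                    d = dm - dr
                    if -tol <= d <= tol:
                        s = (score[i - di, j - dj] + match_bonus
                             - miss_pen * (dj - 1) - extra_pen * (di - 1))
                        if s > best:
                            best = s
                            bi = i - di
                            bj = j - dj
            score[i, j] = best
            pi[i, j] = bi
            pj[i, j] = bj
    return score, pi, pj


def _best_chain(mol_pos: np.ndarray, ref_pos: np.ndarray, params: AlignmentParams):
    """Best-scoring feasible chain; returns (score, [(i, j), ...])."""
    if mol_pos.size == 0 or ref_pos.size == 0:
        return _NEG, []
    score, pi, pj = _dp_kernel(
        mol_pos, ref_pos,
        params.abs_tol_bp, params.rel_tol, params.match_bonus,
        params.miss_penalty, params.extra_penalty, params.max_lookback,
    )
    flat = int(np.argmax(score))
    i, j = divmod(flat, ref_pos.size)
    best = float(score[i, j])
    pairs = []
    while i >= 0:
        pairs.append((i, j))
        i, j = int(pi[i, j]), int(pj[i, j])
    pairs.reverse()
    return best, pairs


@njit(cache=False)
def _trigram_counts(mol_tri, ref_tri, ref_arm, n_arms, abs_tol, rel_tol):
    """Per-arm counts of molecule gap triples supported by a reference
    triple within tolerance, in forward and reverse reading order."""
    fwd = np.zeros(n_arms, dtype=np.int64)
    rev = np.zeros(n_arms, dtype=np.int64)
    seen_f = np.zeros(n_arms, dtype=np.uint8)
    seen_r = np.zeros(n_arms, dtype=np.uint8)
    for i in range(mol_tri.shape[0]):
        seen_f[:] = 0
        seen_r[:] = 0
        for r in range(ref_tri.shape[0]):
            k = ref_arm[r]
            if not seen_f[k]:
                ok = True
                for c in range(3):
                    d = mol_tri[i, c] - ref_tri[r, c]
                    tol = abs_tol if abs_tol > rel_tol * ref_tri[r, c] else rel_tol * ref_tri[r, c]
                    if d > tol or d < -tol:
                        ok = False
                        break
                if ok:
                    seen_f[k] = 1
                    fwd[k] += 1
            if not seen_r[k]:
                ok = True
                for c in range(3):
                    d = mol_tri[i, 2 - c] - ref_tri[r, c]
                    tol = abs_tol if abs_tol > rel_tol * ref_tri[r, c] else rel_tol * ref_tri[r, c]
                    if d > tol or d < -tol:
                        ok = False
                        break
                if ok:
                    seen_r[k] = 1
                    rev[k] += 1
    return fwd, rev


class ArmPrefilter:
    """Candidate-arm screen based on consecutive gap 3-grams.

    Individual exponential gaps are not distinctive (a random gap falls
    within the matching tolerance of *some* reference gap far too often),
    but an ordered triple of consecutive gaps is.  Each molecule gap triple
    is checked against every arm's (gap_k, gap_{k+1}, gap_{k+2}) triples in
    both reading directions; arms are ranked by the number of supported
    molecule triples.
    """

    _ABS_TOL = 600.0     # support tolerance, slightly looser than the DP's
    _REL_TOL = 0.13

    def __init__(self, reference: ReferenceSet):
        self.arm_ids = reference.arm_ids()
        tris, owners = [], []
        for k, arm_id in enumerate(self.arm_ids):
            g = np.diff(reference[arm_id].label_positions)
            if g.size < 3:
                continue
            tri = np.column_stack([g[:-2], g[1:-1], g[2:]])
            tris.append(tri)
            owners.append(np.full(tri.shape[0], k, dtype=np.int64))
        self._ref_tri = np.concatenate(tris) if tris else np.empty((0, 3))
        self._ref_arm = np.concatenate(owners) if owners else np.empty(0, dtype=np.int64)

    def rank_arms(self, label_positions: np.ndarray) -> list[tuple[str, str]]:
        """(arm_id, orientation hint) ranked by 3-gram support (desc).

        The hint is "forward"/"reverse" when one reading direction clearly
        dominates, else "both"."""
        g = np.diff(label_positions)
        if g.size < 3 or self._ref_tri.shape[0] == 0:
            return [(a, "both") for a in self.arm_ids]
        mol_tri = np.column_stack([g[:-2], g[1:-1], g[2:]])
        fwd, rev = _trigram_counts(mol_tri, self._ref_tri, self._ref_arm,
                                   len(self.arm_ids), self._ABS_TOL, self._REL_TOL)
        counts = np.maximum(fwd, rev)
        order = np.argsort(-counts, kind="stable")
        out = []
        for k in order:
            if fwd[k] > rev[k] + 2:
                hint = "forward"
            elif rev[k] > fwd[k] + 2:
                hint = "reverse"
            else:
                hint = "both"
            out.append((self.arm_ids[k], hint))
        return out


def _align_positions(
    positions: np.ndarray,
    index_map: np.ndarray,
    molecule: Molecule,
    arm: ReferenceArmMap,
    params: AlignmentParams,
    orientation: str,
) -> Alignment | None:
    """Align a subset of molecule labels (given by ``index_map`` into the
    molecule's nick array) to one arm in one orientation."""
    if positions.size < params.min_matched_labels:
        return None
    if orientation == "forward":
        view = positions
        view_map = index_map
    else:
        view = np.sort(molecule.length_bp - positions)
        view_map = index_map[::-1]
    score, pairs = _best_chain(view, arm.label_positions, params)
    if len(pairs) < params.min_matched_labels or score < params.min_score:
        return None
    mol_idx = [int(view_map[i]) for i, _ in pairs]
    ref_idx = [j for _, j in pairs]
    mol_pos = molecule.nick_labels[mol_idx]
    end_anchored = ref_idx[-1] == arm.n_labels - 1
    distal_ref_pos = float(arm.label_positions[ref_idx[-1]])
    return Alignment(
        molecule_id=molecule.molecule_id,
        arm_id=arm.arm_id,
        orientation=orientation,
        matched_pairs=tuple(zip(mol_idx, ref_idx)),
        mol_span_bp=(float(mol_pos.min()), float(mol_pos.max())),
        ref_span_bp=(float(arm.label_positions[ref_idx[0]]), distal_ref_pos),
        score=float(score),
        end_anchored=end_anchored,
        distal_mol_pos_bp=float(mol_pos[-1]),
        chrom_end_offset_bp=float(arm.chrom_end_pos - distal_ref_pos),
    )


def align_to_arm(
    molecule: Molecule,
    arm: ReferenceArmMap,
    params: AlignmentParams | None = None,
    orientation: str = "forward",
) -> Alignment | None:
    """Best accepted alignment of a molecule to one arm in one orientation,
    or None when no chain reaches the acceptance floors."""
    params = params or AlignmentParams()
    idx = np.arange(molecule.nick_labels.size)
    return _align_positions(molecule.nick_labels, idx, molecule, arm, params, orientation)


def _better(a: Alignment | None, b: Alignment | None) -> Alignment | None:
    """Higher score wins; ties break to lexicographic arm id, then forward."""
    if a is None:
        return b
    if b is None:
        return a
    if abs(a.score - b.score) > 1e-9:
        return a if a.score > b.score else b
    if a.arm_id != b.arm_id:
        return a if a.arm_id < b.arm_id else b
    return a if a.orientation == "forward" else b


def _best_over_arms(
    positions: np.ndarray,
    index_map: np.ndarray,
    molecule: Molecule,
    reference: ReferenceSet,
    params: AlignmentParams,
    prefilter: ArmPrefilter | None,
) -> Alignment | None:
    if positions.size < params.min_matched_labels:
        return None
    if prefilter is not None and params.candidate_arms is not None:
        candidates = prefilter.rank_arms(positions)[: params.candidate_arms]
    else:
        candidates = [(a, "both") for a in reference.arm_ids()]
    # a chain matching nearly every label cannot be beaten meaningfully by a
    # later (lower-ranked) arm; stop scanning once one is found, and give up
    # after `patience` consecutive non-improving candidates
    stop_score = params.match_bonus * 0.8 * positions.size
    best: Alignment | None = None
    best_rank = -1
    for rank, (arm_id, hint) in enumerate(candidates):
        arm = reference[arm_id]
        if arm.n_labels < params.min_matched_labels:
            continue
        orientations = ("forward", "reverse") if hint == "both" else (hint,)
        for orientation in orientations:
            improved = _align_positions(positions, index_map, molecule, arm, params, orientation)
            new_best = _better(best, improved)
            if new_best is not best:
                best, best_rank = new_best, rank
        if best is not None:
            if best.score >= stop_score and positions.size >= 12:
                break
            if rank - best_rank >= params.patience:
                break
    return best


def align_molecule(
    molecule: Molecule,
    reference: ReferenceSet,
    params: AlignmentParams | None = None,
    prefilter: ArmPrefilter | None = None,
) -> list[Alignment]:
    """Greedy split alignment of a molecule against a reference set.

    Finds the best accepted alignment over all arms and orientations, masks
    its molecule span, and aligns the largest remaining label block once
    more (fusions are two-part).  Returns 0-2 alignments sorted by molecule
    coordinate.  Pass a shared :class:`ArmPrefilter` when aligning many
    molecules against the same reference.
    """
    params = params or AlignmentParams()
    if len(reference) == 0:
        return []
    if prefilter is None and params.candidate_arms is not None:
        prefilter = ArmPrefilter(reference)
    labels = molecule.nick_labels
    idx = np.arange(labels.size)
    first = _best_over_arms(labels, idx, molecule, reference, params, prefilter)
    if first is None:
        return []
    out = [first]
    if params.max_segments >= 2:
        lo, hi = first.mol_span_bp
        second: Alignment | None = None
        for mask in (labels < lo, labels > hi):   # labels flanking the first segment
            second = _better(second,
                             _best_over_arms(labels[mask], idx[mask], molecule,
                                             reference, params, prefilter))
        if second is not None:
            out.append(second)
    out.sort(key=lambda a: a.mol_span_bp[0])
    return out
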