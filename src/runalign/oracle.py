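"""Independent alignment oracles for validating the engine.

Two oracles, neither sharing any structure with the engine's recurrence
(no depth nodes, no gap-state factoring, no zero-state seeding):

* :func:`brute_force_align` — true exhaustive enumeration of alignments
  as monotone edit-graph paths (local mode: from every start cell, taking
  the running maximum over every path prefix, with the empty alignment
  scoring 0).  Exponential; guarded to tiny inputs.
* :func:`path_dp_score` — an explicit path-state formulation: the best
  score over all paths ending at a cell with an exact trailing-run length
  and last operation.  Polynomial, so usable at sizes where enumeration
  is not; it considers exactly the same alignment set and scoring as the
  enumerator and is cross-validated against it in the test suite.

Both score alignments by the run-length semantics of
:func:`runalign.engine.rescore`: a match run of length n scores f(n)
(incrementally via delta_f), each mismatch costs rho_m, and a k-column
gap costs rho_o_effective + k * rho_e.
"""

from __future__ import annotations

from typing import Dict, Optional, Tuple

from .engine import InputError, _clean_sequence
from .scoring import ScoringScheme

__all__ = ["brute_force_align", "path_dp_score"]


def brute_force_align(
    target: str, query: str, scheme: ScoringScheme, max_product: int = 100
) -> float:
    """Exhaustively enumerate all alignments and return the optimum score.

    Mode (local/global) and gap model come from ``scheme``.  Guarded to
    ``len(target) * len(query) <= max_product``; note local enumeration is
    exponential and is only practical well below the guard (it is used
    exhaustively at lengths <= 4).
    """
    t = _clean_sequence(target, "target")
    q = _clean_sequence(query, "query")
    n, m = len(t), len(q)
    if n * m > max_product:
        raise InputError(
            f"brute-force guard exceeded: {n} * {m} > {max_product}"
        )
    local = scheme.alignment_mode == "local"
    rho_m = scheme.mismatch_penalty
    rho_e = scheme.gap_extend
    open_cost = scheme.gap_open_cost
    delta = scheme.delta

    best = [0 if local else float("-inf")]

    def explore(i: int, j: int, score: float, run: int, last: str) -> None:
        if local:
            if score > best[0]:
                best[0] = score
        elif i == n and j == m:
            if score > best[0]:
                best[0] = score
            return
        if i < n and j < m:
            if t[i] == q[j] and t[i] != "N":
                explore(i + 1, j + 1, score + delta(run + 1), run + 1, "M")
            else:
                explore(i + 1, j + 1, score - rho_m, 0, "X")
        if j < m:
            cost = rho_e if last == "H" else open_cost
            explore(i, j + 1, score - cost, 0, "H")
        if i < n:
            cost = rho_e if last == "V" else open_cost
            explore(i + 1, j, score - cost, 0, "V")

    if local:
        for si in range(n + 1):
            for sj in range(m + 1):
                explore(si, sj, 0, 0, "S")
    else:
        explore(0, 0, 0, 0, "S")
    return best[0]


def path_dp_score(target: str, query: str, scheme: ScoringScheme) -> float:
    """Optimum alignment score via an explicit path-state DP.

    State: (trailing match-run length, last operation) per cell; the value
    is the best score of any path ending there in that state.  Local mode
    seeds an empty-start state at every cell and takes the global maximum
    (floored at 0); global mode seeds only (0, 0) and reads the terminal
    cell.
    """
    t = _clean_sequence(target, "target")
    q = _clean_sequence(query, "query")
    n, m = len(t), len(q)
    local = scheme.alignment_mode == "local"
    rho_m = scheme.mismatch_penalty
    rho_e = scheme.gap_extend
    open_cost = scheme.gap_open_cost
    delta = scheme.delta

    State = Tuple[int, str]
    best_overall = 0 if local else float("-inf")
    prev_row: list = [None] * (m + 1)
    cur_row: list = [None] * (m + 1)

    for i in range(n + 1):
        for j in range(m + 1):
            cell: Dict[State, float] = {}
            if local or (i == 0 and j == 0):
                cell[(0, "S")] = 0
            if i > 0 and j > 0:
                diag = prev_row[j - 1]
                if t[i - 1] == q[j - 1] and t[i - 1] != "N":
                    for (run, _last), s in diag.items():
                        key = (run + 1, "M")
                        val = s + delta(run + 1)
                        if val > cell.get(key, float("-inf")):
                            cell[key] = val
                else:
                    for (_run, _last), s in diag.items():
                        val = s - rho_m
                        if val > cell.get((0, "X"), float("-inf")):
                            cell[(0, "X")] = val
            if j > 0:
                left = cur_row[j - 1]
                for (_run, last), s in left.items():
                    val = s - (rho_e if last == "H" else open_cost)
                    if val > cell.get((0, "H"), float("-inf")):
                        cell[(0, "H")] = val
            if i > 0:
                up = prev_row[j]
                for (_run, last), s in up.items():
                    val = s - (rho_e if last == "V" else open_cost)
                    if val > cell.get((0, "V"), float("-inf")):
                        cell[(0, "V")] = val
            cur_row[j] = cell
            if local and cell:
                mx = max(cell.values())
                if mx > best_overall:
                    best_overall = mx
        prev_row, cur_row = cur_row, [None] * (m + 1)

    if local:
        return best_overall
    end = prev_row[m]
    return max(end.values()) if end else float("-inf")
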