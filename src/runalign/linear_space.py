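"""Memory-reduced alignment with full traceback via check-pointing.

The forward pass keeps only the previous row of dynamic-programming state,
but stores a full copy of every ``checkpoint_interval``-th row.  During
traceback, the block of rows between the current position and the nearest
checkpoint below it is recomputed from that checkpoint, traced, and
discarded.  Because checkpoints hold the complete per-cell state (all
contiguity-depth nodes and both gap states), block recomputation is exact
and the result is bitwise identical to the full-matrix aligner.

Peak retained rows are bounded by ``2 + ceil(N / interval)`` checkpoint
rows plus one working block of ``interval`` rows, versus ``N + 1`` for the
full matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional

from .engine import (
    NEG_INF,
    AlignmentError,
    AlignmentResult,
    BandError,
    _band_bounds,
    _Engine,
    _Row,
)
from .scoring import ScoringScheme

__all__ = ["Checkpoint", "align_linear_space"]


@dataclass
class Checkpoint:
    """A stored full-state DP row (all depth nodes and gap states)."""

    row_index: int
    states: _Row


def align_linear_space(
    target: str,
    query: str,
    scheme: Optional[ScoringScheme] = None,
    checkpoint_interval: Optional[int] = None,
    stats: Optional[dict] = None,
) -> AlignmentResult:
    """Align like :func:`runalign.engine.align` but in reduced memory.

    ``checkpoint_interval`` defaults to ``ceil(sqrt(N))`` (N = target
    length), balancing recompute passes against retained rows.  When
    ``stats`` is a dict, ``stats["peak_rows"]`` records the maximum number
    of rows retained at any moment.  The returned result — score,
    intervals, operations — is identical to the full-matrix aligner's.
    """
    if scheme is None:
        scheme = ScoringScheme()
    eng = _Engine(target, query, scheme)
    n, m = eng.n, eng.m
    interval = checkpoint_interval if checkpoint_interval is not None else max(
        1, math.ceil(math.sqrt(n))
    )
    if interval < 1:
        raise AlignmentError("checkpoint_interval must be >= 1")

    checkpoints: Dict[int, _Row] = {0: eng.row0()}
    peak = 1

    prev = checkpoints[0]
    best_val, best_i, best_j = NEG_INF, 0, 0
    last_row = prev
    for i in range(1, n + 1):
        row = eng.next_row(i, prev)
        if eng.local:
            lo, hi = _band_bounds(i, n, m, eng.band)
            rbest = row.best
            for j in range(lo, hi + 1):
                if rbest[j] > best_val:
                    best_val, best_i, best_j = rbest[j], i, j
        if i % interval == 0:
            checkpoints[i] = row
        peak = max(peak, len(checkpoints) + 2)
        prev = row
        last_row = row

    if eng.local:
        if best_val <= 0:
            if stats is not None:
                stats["peak_rows"] = peak
            return eng.empty_result()
        end_i, end_j, score = best_i, best_j, best_val
    else:
        score = last_row.best[m]
        if score == NEG_INF:
            raise BandError("band excludes global path")
        end_i, end_j = n, m

    # traceback by blocks, recomputing each from the checkpoint below it
    cp_indices = sorted(checkpoints)
    state = (end_i, end_j, ("best",), score)
    ops_rev: List = []
    while True:
        i = state[0]
        base = max(c for c in cp_indices if c <= i)
        if base == i and i > 0:
            base = max(c for c in cp_indices if c < i)
        window: Dict[int, _Row] = {base: checkpoints[base]}
        block_prev = checkpoints[base]
        for r in range(base + 1, i + 1):
            row = eng.next_row(r, block_prev)
            window[r] = row
            block_prev = row
        peak = max(peak, len(checkpoints) + len(window) - 1)
        ops, state, done = eng.traceback_window(window, state, base)
        ops_rev.extend(ops)
        if done:
            break
    if stats is not None:
        stats["peak_rows"] = peak
    start_i, start_j = state[0], state[1]
    return eng.build_result(score, end_i, end_j, start_i, start_j, ops_rev)
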