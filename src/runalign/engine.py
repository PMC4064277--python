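"""Contiguity-aware pairwise alignment engine.

The aligner generalizes gap-affine Smith–Waterman by scoring runs of
consecutive matching nucleotides with an arbitrary function ``f(n)``
instead of a per-column constant.  The edit graph gains a third dimension:
each cell ``(i, j)`` (row ``i`` over the target, column ``j`` over the
query) holds one *depth node* per possible trailing-run length
``n = 1..d(i,j)``, where ``d(i,j)`` is the length of the matching suffix
ending at ``(i, j)``.  The recurrences are

    S(i,j,n)   = S(i-1,j-1,n-1) + delta_f(n)          n >= 1 (match)
    S(i,j,0)   = best(i-1,j-1)  - rho_m               (mismatch)
    H(i,j)     = max(H(i,j-1) - rho_e,  best(i,j-1) - (rho_o + rho_e))
    V(i,j)     = max(V(i-1,j) - rho_e,  best(i-1,j) - (rho_o + rho_e))
    best(i,j)  = max(S(i,j,n) for all n,  H(i,j),  V(i,j) [, 0 if local])

A fresh match run (n = 1) is seeded from the predecessor cell's
*zero-contiguity* value ``z(i-1,j-1) = max(S(.,.,0), H, V [, 0])`` — the
best way to arrive there with no trailing match — so matches may follow
gaps and mismatches.  Depth nodes are allocated on demand; with a linear
``f`` a single node per cell suffices and the engine is exactly the
classic SW (linear gaps) / Gotoh (affine gaps) recurrence.  Removing the
local-restart 0 turns the aligner global, with boundary rows charged as
gaps.

Scores are exact (Python ints) whenever ``f`` and the penalties are
integer-valued, which underpins the bit-compatibility guarantees with the
classic schemes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, List, Optional, Sequence, Tuple

from .scoring import ScoringScheme, delta_f

__all__ = [
    "AlignOp",
    "AlignmentResult",
    "AlignmentError",
    "InputError",
    "BandError",
    "CellState",
    "align",
    "align_banded",
    "compute_cell",
    "rescore",
]

NEG_INF = float("-inf")

_VALID = set("ACGTN")


class AlignmentError(Exception):
    """Base class for alignment failures."""


class InputError(AlignmentError):
    """Malformed sequence or operation input."""


class BandError(AlignmentError):
    """The diagonal band excludes every global path."""


class AlignOp(str, Enum):
    """Column-level edit operations.

    ``INSERT_TARGET_GAP`` places a gap in the target row (consumes a query
    base; CIGAR ``I``); ``INSERT_QUERY_GAP`` places a gap in the query row
    (consumes a target base; CIGAR ``D``).
    """

    MATCH = "M"
    MISMATCH = "X"
    INSERT_TARGET_GAP = "I"
    INSERT_QUERY_GAP = "D"


#: Which operations consume a target / query base.
CONSUMES_TARGET = {AlignOp.MATCH, AlignOp.MISMATCH, AlignOp.INSERT_QUERY_GAP}
CONSUMES_QUERY = {AlignOp.MATCH, AlignOp.MISMATCH, AlignOp.INSERT_TARGET_GAP}


@dataclass(frozen=True)
class AlignmentResult:
    """One pairwise alignment: score, coordinates, and edit operations.

    Intervals are 0-based half-open on the input sequences.  ``operations``
    is a run-length encoded list of ``(AlignOp, length)`` pairs;
    re-scoring it under the same scheme reproduces ``score`` exactly.
    ``max_depth_nodes`` instruments the engine: the largest number of
    contiguity-depth nodes allocated in any cell during the fill.
    """

    score: float
    target_interval: Tuple[int, int]
    query_interval: Tuple[int, int]
    operations: Tuple[Tuple[AlignOp, int], ...]
    aligned_target: str
    aligned_query: str
    max_contiguity: int
    identity: float
    max_depth_nodes: int = 0

    @property
    def n_columns(self) -> int:
        return sum(length for _, length in self.operations)

    def cigar(self) -> str:
        """CIGAR string with X for mismatch (M is true match only)."""
        return "".join(f"{length}{op.value}" for op, length in self.operations)


@dataclass
class CellState:
    """Full dynamic-programming state of one cell ``(i, j)``.

    ``depth_scores[k]`` is the score of the best path arriving with a
    trailing match run of length ``k + 1`` (depth node ``n = k + 1``);
    ``zero`` is the best arrival with no trailing match (mismatch, gap or
    local restart); ``gap_h`` / ``gap_v`` are the horizontal / vertical
    gap states; ``depth`` is the matching-suffix length ``d(i, j)``.
    """

    best: float = NEG_INF
    zero: float = NEG_INF
    depth_scores: Tuple[float, ...] = ()
    gap_h: float = NEG_INF
    gap_v: float = NEG_INF
    depth: int = 0

    @classmethod
    def boundary(cls, local: bool) -> "CellState":
        """Sentinel state outside the matrix (or the local virtual border)."""
        if local:
            return cls(best=0, zero=0)
        return cls()


def compute_cell(
    prev_diag: CellState,
    prev_up: CellState,
    prev_left: CellState,
    is_match: bool,
    scheme: ScoringScheme,
) -> CellState:
    """Compute one cell's state from its three neighbours.

    Reference single-cell form of the recurrence; the batch fill in
    :func:`align` inlines the same arithmetic.  Boundary cells receive
    sentinel neighbours from :meth:`CellState.boundary`.
    """
    local = scheme.alignment_mode == "local"
    rho_e = scheme.gap_extend
    open_cost = scheme.gap_open_cost

    gap_h = max(
        prev_left.gap_h - rho_e if prev_left.gap_h > NEG_INF else NEG_INF,
        prev_left.best - open_cost if prev_left.best > NEG_INF else NEG_INF,
    )
    gap_v = max(
        prev_up.gap_v - rho_e if prev_up.gap_v > NEG_INF else NEG_INF,
        prev_up.best - open_cost if prev_up.best > NEG_INF else NEG_INF,
    )

    if is_match:
        depth = prev_diag.depth + 1
        cap = scheme.effective_depth_cap
        length = depth if cap is None else min(depth, cap)
        nodes: List[float] = []
        seed = prev_diag.zero
        nodes.append(seed + scheme.delta(1) if seed > NEG_INF else NEG_INF)
        for n in range(2, length + 1):
            prev_node = prev_diag.depth_scores[n - 2]
            nodes.append(
                prev_node + scheme.delta(n) if prev_node > NEG_INF else NEG_INF
            )
        if cap is not None and depth > cap:
            merged = prev_diag.depth_scores[cap - 1]
            if merged > NEG_INF:
                nodes[cap - 1] = max(nodes[cap - 1], merged + scheme.delta(cap))
        mismatch_state = NEG_INF
    else:
        depth = 0
        nodes = []
        mismatch_state = (
            prev_diag.best - scheme.mismatch_penalty
            if prev_diag.best > NEG_INF
            else NEG_INF
        )

    zero = max(mismatch_state, gap_h, gap_v, 0 if local else NEG_INF)
    best = max(zero, max(nodes, default=NEG_INF))
    return CellState(
        best=best,
        zero=zero,
        depth_scores=tuple(nodes),
        gap_h=gap_h,
        gap_v=gap_v,
        depth=depth,
    )


def _clean_sequence(seq: str, label: str) -> str:
    """Uppercase and validate a nucleotide sequence (A, C, G, T, N)."""
    if not isinstance(seq, str):
        seq = str(seq)
    if not seq:
        raise InputError(f"{label} sequence is empty")
    up = seq.upper()
    for pos, ch in enumerate(up):
        if ch not in _VALID:
            raise InputError(
                f"{label} sequence: invalid character {ch!r} at position {pos}"
            )
    return up


class _Row:
    """One DP row as parallel lists over columns 0..M (unreachable = -inf)."""

    __slots__ = ("best", "zero", "gap_h", "gap_v", "depth", "nodes")

    def __init__(self, m1: int):
        self.best = [NEG_INF] * m1
        self.zero = [NEG_INF] * m1
        self.gap_h = [NEG_INF] * m1
        self.gap_v = [NEG_INF] * m1
        self.depth = [0] * m1
        self.nodes: List[Tuple[float, ...]] = [()] * m1


def _band_bounds(i: int, n: int, m: int, width: Optional[int]) -> Tuple[int, int]:
    """Inclusive column range of row ``i`` inside the diagonal band.

    The band is centred on the resampled diagonal joining (0,0)-(N,M):
    column j is reachable iff ``|j - i*M/N| <= width``.
    """
    if width is None:
        return 0, m
    center = i * m / n if n else 0.0
    lo = math.ceil(center - width)
    hi = math.floor(center + width)
    return max(0, lo), min(m, hi)


class _Engine:
    """Shared forward fill + traceback used by all alignment entry points."""

    def __init__(self, target: str, query: str, scheme: ScoringScheme,
                 band_width: Optional[int] = None):
        self.target = _clean_sequence(target, "target")
        self.query = _clean_sequence(query, "query")
        self.scheme = scheme
        self.n = len(self.target)
        self.m = len(self.query)
        self.local = scheme.alignment_mode == "local"
        self.band = band_width if band_width is not None else scheme.band_width
        self.rho_m = scheme.mismatch_penalty
        self.rho_e = scheme.gap_extend
        self.open_cost = scheme.gap_open_cost
        cap = scheme.effective_depth_cap
        self.cap = cap
        # delta_f table, lazily extended; index n (df[0] unused).
        self.df: List[float] = [0.0]
        self.max_depth_nodes = 0

    def _delta(self, n: int) -> float:
        cap = self.cap
        if cap is not None and n > cap:
            n = cap
        df = self.df
        while len(df) <= n:
            df.append(delta_f(self.scheme.fn, len(df)))
        return df[n]

    # -- forward fill -----------------------------------------------------

    def row0(self) -> _Row:
        row = _Row(self.m + 1)
        lo, hi = _band_bounds(0, self.n, self.m, self.band)
        if self.local:
            for j in range(lo, hi + 1):
                row.best[j] = 0
                row.zero[j] = 0
        else:
            if lo == 0:
                row.best[0] = 0
                row.zero[0] = 0
            for j in range(max(1, lo), hi + 1):
                cost = self.scheme.effective_gap_open + j * self.rho_e
                row.best[j] = -cost
                row.zero[j] = -cost
                row.gap_h[j] = -cost
        return row

    def next_row(self, i: int, prev: _Row) -> _Row:
        """Compute row ``i`` (1-based over target) from row ``i - 1``."""
        n, m = self.n, self.m
        row = _Row(m + 1)
        lo, hi = _band_bounds(i, n, m, self.band)
        local = self.local
        rho_m, rho_e, open_cost = self.rho_m, self.rho_e, self.open_cost
        cap = self.cap
        tchar = self.target[i - 1]
        query = self.query
        p_best, p_zero, p_gv = prev.best, prev.zero, prev.gap_v
        p_depth, p_nodes = prev.depth, prev.nodes
        best, zero, gh_row, gv_row = row.best, row.zero, row.gap_h, row.gap_v
        depth_row, nodes_row = row.depth, row.nodes
        df = self.df
        fn_eval = self.scheme.fn.evaluate

        if lo == 0:
            # column 0 boundary
            if local:
                best[0] = 0
                zero[0] = 0
            else:
                cost = self.scheme.effective_gap_open + i * rho_e
                best[0] = -cost
                zero[0] = -cost
                gv_row[0] = -cost
            jstart = 1
        else:
            jstart = lo

        tracked_max = self.max_depth_nodes
        for j in range(jstart, hi + 1):
            # gap states
            ghl = gh_row[j - 1]
            bl = best[j - 1]
            gap_h = ghl - rho_e if ghl > NEG_INF else NEG_INF
            if bl > NEG_INF:
                cand = bl - open_cost
                if cand > gap_h:
                    gap_h = cand
            gvu = p_gv[j]
            bu = p_best[j]
            gap_v = gvu - rho_e if gvu > NEG_INF else NEG_INF
            if bu > NEG_INF:
                cand = bu - open_cost
                if cand > gap_v:
                    gap_v = cand

            qchar = query[j - 1]
            if tchar == qchar and tchar != "N":
                d = p_depth[j - 1] + 1
                length = d if cap is None else (d if d <= cap else cap)
                while len(df) <= length:
                    k = len(df)
                    df.append(fn_eval(k) - fn_eval(k - 1))
                pz = p_zero[j - 1]
                pn = p_nodes[j - 1]
                nodes = [pz + df[1] if pz > NEG_INF else NEG_INF]
                for nn in range(2, length + 1):
                    pv = pn[nn - 2]
                    nodes.append(pv + df[nn] if pv > NEG_INF else NEG_INF)
                if cap is not None and d > cap:
                    merged = pn[cap - 1]
                    if merged > NEG_INF:
                        cand = merged + df[cap]
                        if cand > nodes[cap - 1]:
                            nodes[cap - 1] = cand
                if length > tracked_max:
                    tracked_max = length
                mis = NEG_INF
                node_best = max(nodes)
            else:
                d = 0
                nodes = ()
                pb = p_best[j - 1]
                mis = pb - rho_m if pb > NEG_INF else NEG_INF
                node_best = NEG_INF

            z = mis
            if gap_h > z:
                z = gap_h
            if gap_v > z:
                z = gap_v
            if local and z < 0:
                z = 0
            b = z if z > node_best else node_best

            best[j] = b
            zero[j] = z
            gh_row[j] = gap_h
            gv_row[j] = gap_v
            depth_row[j] = d
            nodes_row[j] = tuple(nodes)

        self.max_depth_nodes = tracked_max
        return row

    # -- traceback --------------------------------------------------------

    def _eq(self, a: float, b: float) -> bool:
        if a == b:
            return True
        if a == NEG_INF or b == NEG_INF:
            return False
        return abs(a - b) <= 1e-9

    def mismatch_value(self, rows, i: int, j: int) -> float:
        """Recompute the mismatch-arrival state at (i, j)."""
        if i < 1 or j < 1:
            return NEG_INF
        if self.target[i - 1] == self.query[j - 1] and self.target[i - 1] != "N":
            return NEG_INF
        pb = rows[i - 1].best[j - 1]
        return pb - self.rho_m if pb > NEG_INF else NEG_INF

    def resolve_best(self, rows, i: int, j: int, value: float):
        """Attribute ``value`` at (i, j) to a component, by preference:
        deeper match node > mismatch > vertical gap > horizontal gap >
        local restart."""
        row = rows[i]
        nodes = row.nodes[j]
        for k in range(len(nodes), 0, -1):
            if self._eq(nodes[k - 1], value):
                return ("D", k)
        return self.resolve_zero(rows, i, j, value)

    def resolve_zero(self, rows, i: int, j: int, value: float):
        row = rows[i]
        mis = self.mismatch_value(rows, i, j)
        if self._eq(mis, value):
            return ("X",)
        if self._eq(row.gap_v[j], value):
            return ("V",)
        if self._eq(row.gap_h[j], value):
            return ("H",)
        if self.local and self._eq(value, 0):
            return ("0",)
        if not self.local and i == 0 and j == 0:
            return ("0",)
        if not self.local and (i == 0 or j == 0):
            # boundary gap chain
            return ("H",) if i == 0 else ("V",)
        raise AlignmentError(
            f"traceback failed at cell ({i}, {j}): no component matches "
            f"value {value!r}"
        )

    def traceback_window(self, rows, state, min_row: int):
        """Trace until the local/global start or until row ``min_row`` is
        reached and further progress needs rows above the window.

        ``rows`` maps absolute row index -> _Row for indices in
        ``[min_row, current row]``.  ``state`` is
        ``(i, j, kind, value)`` with kind one of ``("D", n)``, ``("X",)``,
        ``("V",)``, ``("H",)``, ``("best",)``, ``("zero",)``, ``("0",)``.
        Returns ``(ops_reversed, new_state, done)``; ops are column-level
        AlignOp values emitted end-to-start.
        """
        i, j, kind, value = state
        ops: List[AlignOp] = []
        while True:
            if kind == ("best",) or kind == ("zero",):
                # mismatch-arrival resolution peeks at row i - 1
                if i > 0 and i - 1 < min_row:
                    return ops, (i, j, kind, value), False
                resolver = self.resolve_best if kind == ("best",) else self.resolve_zero
                kind = resolver(rows, i, j, value)
                continue
            if kind == ("0",):
                return ops, (i, j, kind, value), True
            if kind[0] == "D":
                if i - 1 < min_row:
                    return ops, (i, j, kind, value), False
                k = kind[1]
                ops.append(AlignOp.MATCH)
                prow = rows[i - 1]
                pn = prow.nodes[j - 1]
                need = None
                dfk = self._delta(k)
                target_val = value - dfk
                # merged-cap predecessor (deeper) first
                if (
                    self.cap is not None
                    and k == self.cap
                    and prow.depth[j - 1] >= self.cap
                    and self._eq(pn[self.cap - 1], target_val)
                ):
                    need = ("D", self.cap)
                    value = pn[self.cap - 1]
                elif k > 1 and self._eq(pn[k - 2], target_val):
                    need = ("D", k - 1)
                    value = pn[k - 2]
                elif self._eq(prow.zero[j - 1], target_val):
                    need = ("zero",)
                    value = prow.zero[j - 1]
                if need is None:
                    raise AlignmentError(
                        f"traceback failed: no predecessor for depth node "
                        f"{k} at ({i}, {j})"
                    )
                i, j, kind = i - 1, j - 1, need
                continue
            if kind == ("X",):
                if i - 1 < min_row:
                    return ops, (i, j, kind, value), False
                ops.append(AlignOp.MISMATCH)
                prow = rows[i - 1]
                value = prow.best[j - 1]
                i, j, kind = i - 1, j - 1, ("best",)
                continue
            if kind == ("V",):
                if i - 1 < min_row:
                    return ops, (i, j, kind, value), False
                ops.append(AlignOp.INSERT_QUERY_GAP)
                prow = rows[i - 1]
                ext = prow.gap_v[j]
                if ext > NEG_INF and self._eq(ext - self.rho_e, value):
                    value = ext
                    i, kind = i - 1, ("V",)
                elif prow.best[j] > NEG_INF and self._eq(
                    prow.best[j] - self.open_cost, value
                ):
                    value = prow.best[j]
                    i, kind = i - 1, ("best",)
                else:
                    raise AlignmentError(
                        f"traceback failed: vertical gap at ({i}, {j})"
                    )
                continue
            if kind == ("H",):
                row = rows[i]
                ops.append(AlignOp.INSERT_TARGET_GAP)
                ext = row.gap_h[j - 1]
                if ext > NEG_INF and self._eq(ext - self.rho_e, value):
                    value = ext
                    j, kind = j - 1, ("H",)
                elif row.best[j - 1] > NEG_INF and self._eq(
                    row.best[j - 1] - self.open_cost, value
                ):
                    value = row.best[j - 1]
                    j, kind = j - 1, ("best",)
                else:
                    raise AlignmentError(
                        f"traceback failed: horizontal gap at ({i}, {j})"
                    )
                continue
            raise AlignmentError(f"unknown traceback state {kind!r}")

    # -- result assembly --------------------------------------------------

    def build_result(self, score, end_i, end_j, start_i, start_j, ops_rev):
        ops = list(reversed(ops_rev))
        rle: List[Tuple[AlignOp, int]] = []
        for op in ops:
            if rle and rle[-1][0] is op:
                rle[-1] = (op, rle[-1][1] + 1)
            else:
                rle.append((op, 1))
        at, aq = [], []
        ti, qi = start_i, start_j
        matches = 0
        max_run = 0
        run = 0
        for op in ops:
            if op is AlignOp.MATCH:
                at.append(self.target[ti]); aq.append(self.query[qi])
                ti += 1; qi += 1
                matches += 1
                run += 1
                max_run = max(max_run, run)
            elif op is AlignOp.MISMATCH:
                at.append(self.target[ti]); aq.append(self.query[qi])
                ti += 1; qi += 1
                run = 0
            elif op is AlignOp.INSERT_QUERY_GAP:
                at.append(self.target[ti]); aq.append("-")
                ti += 1
                run = 0
            else:  # INSERT_TARGET_GAP
                at.append("-"); aq.append(self.query[qi])
                qi += 1
                run = 0
        ncols = len(ops)
        return AlignmentResult(
            score=score,
            target_interval=(start_i, end_i),
            query_interval=(start_j, end_j),
            operations=tuple((op, length) for op, length in rle),
            aligned_target="".join(at),
            aligned_query="".join(aq),
            max_contiguity=max_run,
            identity=matches / ncols if ncols else 0.0,
            max_depth_nodes=self.max_depth_nodes,
        )

    def empty_result(self) -> AlignmentResult:
        return AlignmentResult(
            score=0,
            target_interval=(0, 0),
            query_interval=(0, 0),
            operations=(),
            aligned_target="",
            aligned_query="",
            max_contiguity=0,
            identity=0.0,
            max_depth_nodes=self.max_depth_nodes,
        )

    # -- full-matrix alignment --------------------------------------------

    def run(self) -> AlignmentResult:
        rows: List[_Row] = [self.row0()]
        best_val, best_i, best_j = NEG_INF, 0, 0
        for i in range(1, self.n + 1):
            row = self.next_row(i, rows[-1])
            rows.append(row)
            if self.local:
                rbest = row.best
                lo, hi = _band_bounds(i, self.n, self.m, self.band)
                for j in range(lo, hi + 1):
                    if rbest[j] > best_val:
                        best_val, best_i, best_j = rbest[j], i, j
        if self.local:
            if best_val <= 0:
                return self.empty_result()
            end_i, end_j, score = best_i, best_j, best_val
        else:
            score = rows[self.n].best[self.m]
            if score == NEG_INF:
                raise BandError("band excludes global path")
            end_i, end_j = self.n, self.m
        ops_rev, state, done = self.traceback_window(
            rows, (end_i, end_j, ("best",), score), 0
        )
        if not done:
            raise AlignmentError("traceback did not terminate")
        start_i, start_j = state[0], state[1]
        return self.build_result(score, end_i, end_j, start_i, start_j, ops_rev)


def align(target: str, query: str, scheme: Optional[ScoringScheme] = None) -> AlignmentResult:
    """Optimally align two nucleotide sequences under ``scheme``.

    Local mode returns the maximal-scoring local alignment (the empty
    alignment with score 0 when nothing scores positively); global mode
    aligns both sequences end to end, charging boundary gaps.  ``N`` bases
    never match anything (including ``N``); lowercase input is uppercased.
    Respects ``scheme.band_width`` when set.
    """
    if scheme is None:
        scheme = ScoringScheme()
    return _Engine(target, query, scheme).run()


def align_banded(
    target: str, query: str, scheme: ScoringScheme, band_width: int
) -> AlignmentResult:
    """Banded alignment: cells more than ``band_width`` columns from the
    resampled (0,0)-(N,M) diagonal are never created.

    With ``band_width >= max(N, M)`` the result is bitwise identical to the
    unbanded :func:`align`.  In global mode a band too narrow to connect the
    corners raises :class:`BandError`.
    """
    if band_width < 1:
        raise InputError("band_width must be >= 1")
    return _Engine(target, query, scheme, band_width=band_width).run()


def rescore(
    operations: Sequence[Tuple[AlignOp, int]], scheme: ScoringScheme
) -> float:
    """Independently re-score a run-length operation list.

    MATCH runs score ``f(run)`` (under the scheme's depth cap), each
    MISMATCH column costs rho_m, and each gap run costs
    ``rho_o_effective + rho_e`` for its first column plus ``rho_e`` per
    additional column.  For any engine output this reproduces the reported
    score exactly.
    """
    total = 0
    prev_op: Optional[AlignOp] = None
    for entry in operations:
        try:
            op, length = entry
            op = AlignOp(op)
        except (TypeError, ValueError) as exc:
            raise InputError(f"malformed operation entry {entry!r}") from exc
        if not isinstance(length, int) or length < 1:
            raise InputError(f"operation length must be a positive int: {entry!r}")
        if op is AlignOp.MATCH:
            if prev_op is AlignOp.MATCH:
                raise InputError("adjacent MATCH runs must be merged")
            total += scheme.run_score(length)
        elif op is AlignOp.MISMATCH:
            total -= length * scheme.mismatch_penalty
        else:
            total -= scheme.gap_open_cost + (length - 1) * scheme.gap_extend
            if prev_op is op:
                raise InputError("adjacent identical gap runs must be merged")
        prev_op = op
    return total
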