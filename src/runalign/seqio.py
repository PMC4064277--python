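"""FASTA input and alignment output (text block, TSV, CIGAR).

The TSV schema, in fixed column order::

    target_id  query_id  score  t_start  t_end  q_start  q_end
    identity  max_contiguity  cigar

CIGAR strings use ``M`` for true matches only, ``X`` for mismatches and
``I``/``D`` for gaps in the target/query row, so match contiguity — the
engine's central quantity — is recoverable from the string alone.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

from .engine import AlignOp, AlignmentResult, InputError

__all__ = [
    "SequenceRecord",
    "read_fasta",
    "write_fasta",
    "write_alignment",
    "tsv_header",
    "tsv_row",
    "read_alignment_tsv",
    "cigar_to_operations",
]

TSV_COLUMNS = (
    "target_id",
    "query_id",
    "score",
    "t_start",
    "t_end",
    "q_start",
    "q_end",
    "identity",
    "max_contiguity",
    "cigar",
)

_AMBIGUOUS = set("RYSWKMBDHV")


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence (FASTA record)."""

    id: str
    description: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


def read_fasta(path: str) -> List[SequenceRecord]:
    """Parse a FASTA file into :class:`SequenceRecord` objects.

    Wrapped sequence lines are joined and uppercased.  Rejects files with
    leading non-FASTA content, empty records, duplicate ids, and IUPAC
    ambiguity codes other than N (match semantics for partial ambiguity
    are undefined in this scoring model).
    """
    if not os.path.exists(path):
        raise InputError(f"FASTA file not found: {path}")
    records: List[SequenceRecord] = []
    header: Optional[str] = None
    chunks: List[str] = []
    seen = set()

    def flush():
        if header is None:
            return
        name, _, desc = header.partition(" ")
        if not name:
            raise InputError(f"{path}: FASTA record with empty id")
        seq = "".join(chunks).upper()
        if not seq:
            raise InputError(f"{path}: empty record {name!r}")
        for ch in set(seq):
            if ch in _AMBIGUOUS:
                raise InputError(
                    f"{path}: record {name!r} contains IUPAC ambiguity code "
                    f"{ch!r}; only A, C, G, T and N are supported"
                )
        if name in seen:
            raise InputError(f"{path}: duplicate record id {name!r}")
        seen.add(name)
        records.append(SequenceRecord(name, desc, seq))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
                chunks = []
            else:
                if header is None:
                    raise InputError(
                        f"{path}:{lineno}: sequence data before first FASTA header"
                    )
                chunks.append(line)
    flush()
    if not records:
        raise InputError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            head = f">{rec.id}"
            if rec.description:
                head += f" {rec.description}"
            fh.write(head + "\n")
            seq = rec.sequence
            for k in range(0, len(seq), width):
                fh.write(seq[k : k + width] + "\n")


# -- alignment output -----------------------------------------------------


def tsv_header() -> str:
    return "\t".join(TSV_COLUMNS)


def _fmt_num(x) -> str:
    if isinstance(x, float) and x.is_integer():
        return str(int(x))
    return str(x)


def tsv_row(result: AlignmentResult, target_id: str = "target",
            query_id: str = "query") -> str:
    ts, te = result.target_interval
    qs, qe = result.query_interval
    return "\t".join(
        [
            target_id,
            query_id,
            _fmt_num(result.score),
            str(ts),
            str(te),
            str(qs),
            str(qe),
            f"{result.identity:.4f}",
            str(result.max_contiguity),
            result.cigar() or ".",
        ]
    )


def _text_block(result: AlignmentResult, target_id: str, query_id: str,
                width: int = 60) -> str:
    ts, te = result.target_interval
    qs, qe = result.query_interval
    lines = [
        f"# target={target_id} query={query_id} score={_fmt_num(result.score)} "
        f"t=[{ts},{te}) q=[{qs},{qe}) identity={result.identity:.4f} "
        f"max_contiguity={result.max_contiguity}"
    ]
    if not result.operations:
        lines.append("(empty alignment)")
        return "\n".join(lines) + "\n"
    at, aq = result.aligned_target, result.aligned_query
    bar = "".join(
        "|" if a == b and a != "-" and a != "N" else " " for a, b in zip(at, aq)
    )
    tpos, qpos = ts, qs
    for k in range(0, len(at), width):
        seg_t = at[k : k + width]
        seg_q = aq[k : k + width]
        seg_b = bar[k : k + width]
        t0 = tpos
        q0 = qpos
        tpos += sum(1 for c in seg_t if c != "-")
        qpos += sum(1 for c in seg_q if c != "-")
        lines.append(f"T {t0:>8} {seg_t}")
        lines.append(f"  {'':>8} {seg_b}")
        lines.append(f"Q {q0:>8} {seg_q}")
        lines.append("")
    return "\n".join(lines).rstrip("\n") + "\n"


def write_alignment(
    result: AlignmentResult,
    format: str = "text",
    target_id: str = "target",
    query_id: str = "query",
) -> str:
    """Render one alignment as ``text`` (pairwise block with match bars),
    ``tsv`` (one row, no header) or ``cigar``."""
    if format == "cigar":
        return result.cigar()
    if format == "tsv":
        return tsv_row(result, target_id, query_id)
    if format == "text":
        return _text_block(result, target_id, query_id)
    raise InputError(f"unknown alignment format {format!r}; use text, tsv or cigar")


_CIGAR_RE = re.compile(r"(\d+)([MXID])")


def cigar_to_operations(cigar: str) -> Tuple[Tuple[AlignOp, int], ...]:
    """Parse an M/X/I/D CIGAR string into run-length operations."""
    if cigar in (".", ""):
        return ()
    pos = 0
    ops: List[Tuple[AlignOp, int]] = []
    for m in _CIGAR_RE.finditer(cigar):
        if m.start() != pos:
            raise InputError(f"malformed CIGAR {cigar!r} at offset {pos}")
        ops.append((AlignOp(m.group(2)), int(m.group(1))))
        pos = m.end()
    if pos != len(cigar):
        raise InputError(f"malformed CIGAR {cigar!r} at offset {pos}")
    return tuple(ops)


def read_alignment_tsv(path: str) -> List[dict]:
    """Read an engine TSV back into row dicts with parsed operations.

    Each row gains a reconstructed :class:`AlignmentResult` under
    ``"result"`` (aligned strings are not stored in TSV and are left
    empty).
    """
    if not os.path.exists(path):
        raise InputError(f"alignment TSV not found: {path}")
    rows: List[dict] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[: len(TSV_COLUMNS)] == list(TSV_COLUMNS):
                continue  # header
            if len(fields) != len(TSV_COLUMNS):
                raise InputError(
                    f"{path}:{lineno}: expected {len(TSV_COLUMNS)} columns, "
                    f"got {len(fields)}"
                )
            row = dict(zip(TSV_COLUMNS, fields))
            ops = cigar_to_operations(row["cigar"])
            score = float(row["score"])
            matches = sum(l for op, l in ops if op is AlignOp.MATCH)
            ncols = sum(l for _, l in ops)
            runs = [l for op, l in ops if op is AlignOp.MATCH]
            row["result"] = AlignmentResult(
                score=int(score) if score.is_integer() else score,
                target_interval=(int(row["t_start"]), int(row["t_end"])),
                query_interval=(int(row["q_start"]), int(row["q_end"])),
                operations=ops,
                aligned_target="",
                aligned_query="",
                max_contiguity=max(runs, default=0),
                identity=matches / ncols if ncols else 0.0,
            )
            rows.append(row)
    return rows
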