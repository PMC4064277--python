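"""Cross-genome alignment-consistency metrics.

Given pairwise alignments of many orthologous genome sequences to one
reference, these metrics quantify how consistently the aligners place
each reference position:

* a per-position *agreement profile* — the fraction of genomes whose
  aligned base matches the reference (denominator either all genomes or
  only the genomes whose alignment covers the position);
* *conserved elements* — maximal runs of >= ``min_len`` consecutive
  reference positions each matched in >= ``min_frac`` of the aligned
  genomes (defaults 6 and 0.9, the poly-adenylation-signal setting);
* k-mer tallies within conserved elements (default 6-mers, for counting
  motifs such as AATAAA);
* a method-comparison summary computed after restricting every genome's
  coverage to the regions where all compared methods report alignments,
  so the methods are scored on common ground.

The backing structure is a :class:`MatchMatrix`: per genome, boolean
``covered`` and ``matched`` masks over reference positions.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .engine import AlignOp, AlignmentResult, InputError
from .seqio import SequenceRecord

__all__ = [
    "MatchMatrix",
    "ConservedElement",
    "build_match_matrix",
    "agreement_profile",
    "agreement_histogram",
    "find_conserved_elements",
    "kmer_frequencies",
    "summarize_methods",
    "restrict_to_common_regions",
    "elements_to_bed",
]


@dataclass
class MatchMatrix:
    """Genomes x reference-position match/coverage masks.

    ``matched[g, p]`` — genome g's alignment puts an identical base at
    reference position p; ``covered[g, p]`` — p lies inside genome g's
    reported alignment on the reference.  Matched implies covered.
    """

    reference_id: str
    n_positions: int
    genome_ids: List[str]
    matched: np.ndarray
    covered: np.ndarray

    def __post_init__(self) -> None:
        self.matched = np.asarray(self.matched, dtype=bool)
        self.covered = np.asarray(self.covered, dtype=bool)
        g = len(self.genome_ids)
        if self.matched.shape != (g, self.n_positions):
            raise ValueError("matched mask has wrong shape")
        if self.covered.shape != (g, self.n_positions):
            raise ValueError("covered mask has wrong shape")
        if np.any(self.matched & ~self.covered):
            raise ValueError("matched positions must be covered")

    @property
    def n_genomes(self) -> int:
        return len(self.genome_ids)

    def matched_nucleotides(self) -> int:
        """Total matched cells, summed over genomes and positions."""
        return int(self.matched.sum())


@dataclass(frozen=True)
class ConservedElement:
    """Maximal reference interval of consecutively agreeing positions."""

    interval: Tuple[int, int]
    length: int
    min_agreement: float

    def __post_init__(self) -> None:
        if self.length != self.interval[1] - self.interval[0]:
            raise ValueError("length must equal interval size")


def build_match_matrix(
    reference: SequenceRecord,
    alignments: Sequence[Tuple[str, AlignmentResult, Optional[str]]],
) -> MatchMatrix:
    """Build the masks from per-genome pairwise alignments to ``reference``.

    Each entry is ``(genome_id, result, genome_sequence)``; the alignment's
    target must be the reference (the genome sequence is carried for
    provenance and may be None).  Walking the operations: MATCH marks
    matched+covered, MISMATCH covered, a query-gap (deletion in the
    genome) covers the gapped reference positions, a target-gap consumes
    no reference positions.
    """
    npos = len(reference.sequence)
    ids: List[str] = []
    matched_rows = []
    covered_rows = []
    for genome_id, result, _seq in alignments:
        if genome_id in ids:
            raise InputError(f"duplicate genome_id {genome_id!r}")
        ts, te = result.target_interval
        if ts < 0 or te > npos:
            raise InputError(
                f"alignment interval [{ts},{te}) exceeds reference "
                f"{reference.id!r} of length {npos}"
            )
        matched = np.zeros(npos, dtype=bool)
        covered = np.zeros(npos, dtype=bool)
        pos = ts
        for op, length in result.operations:
            if op is AlignOp.MATCH:
                matched[pos : pos + length] = True
                covered[pos : pos + length] = True
                pos += length
            elif op is AlignOp.MISMATCH:
                covered[pos : pos + length] = True
                pos += length
            elif op is AlignOp.INSERT_QUERY_GAP:
                covered[pos : pos + length] = True
                pos += length
            # INSERT_TARGET_GAP consumes no reference positions
        if pos != te:
            raise InputError(
                f"operations of genome {genome_id!r} span [{ts},{pos}) but "
                f"the reported target interval is [{ts},{te})"
            )
        ids.append(genome_id)
        matched_rows.append(matched)
        covered_rows.append(covered)
    if not ids:
        raise InputError("at least one genome alignment is required")
    return MatchMatrix(
        reference_id=reference.id,
        n_positions=npos,
        genome_ids=ids,
        matched=np.vstack(matched_rows),
        covered=np.vstack(covered_rows),
    )


def agreement_profile(
    mm: MatchMatrix, denominator: str = "covered_genomes"
) -> np.ndarray:
    """Per-position fraction of genomes matching the reference.

    ``denominator="all_genomes"`` divides by the total genome count;
    ``"covered_genomes"`` divides by the number of genomes covering each
    position, yielding NaN where no genome covers it (such positions are
    excluded from histograms and elements).
    """
    if denominator == "all_genomes":
        return mm.matched.sum(axis=0) / mm.n_genomes
    if denominator == "covered_genomes":
        cov = mm.covered.sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(cov > 0, mm.matched.sum(axis=0) / np.maximum(cov, 1),
                            np.nan)
    raise ValueError(f"unknown denominator {denominator!r}")


def agreement_histogram(
    mm: MatchMatrix,
    bins: int = 10,
    baseline: Optional[MatchMatrix] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Normalised counts of covered positions per agreement bin.

    Returns ``(bin_edges, values)`` with ``bins`` equal-width bins over
    [0, 1].  Counts are divided by the number of covered positions; with
    a ``baseline`` matrix the baseline's normalised counts are
    subtracted bin by bin (the SW-difference view).
    """
    if bins < 2:
        raise ValueError("bins must be >= 2")

    def normalised(matrix: MatchMatrix) -> np.ndarray:
        prof = agreement_profile(matrix, "covered_genomes")
        vals = prof[~np.isnan(prof)]
        counts, _ = np.histogram(vals, bins=bins, range=(0.0, 1.0))
        total = vals.size
        return counts / total if total else counts.astype(float)

    edges = np.linspace(0.0, 1.0, bins + 1)
    own = normalised(mm)
    if baseline is None:
        return edges, own
    if baseline.n_positions != mm.n_positions:
        raise ValueError("baseline matrix has a different n_positions")
    return edges, own - normalised(baseline)


def find_conserved_elements(
    mm: MatchMatrix, min_len: int = 6, min_frac: float = 0.9
) -> List[ConservedElement]:
    """Maximal runs of positions with agreement >= ``min_frac`` (covered
    denominator) of length >= ``min_len``.

    Positions with agreement exactly equal to ``min_frac`` are inside
    elements; uncovered positions break runs.
    """
    if not (0 < min_frac <= 1):
        raise ValueError("min_frac must be in (0, 1]")
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    prof = agreement_profile(mm, "covered_genomes")
    ok = np.zeros(mm.n_positions, dtype=bool)
    defined = ~np.isnan(prof)
    # tolerate float division noise at the exact threshold
    ok[defined] = prof[defined] >= min_frac - 1e-12
    elements: List[ConservedElement] = []
    pos = 0
    npos = mm.n_positions
    while pos < npos:
        if not ok[pos]:
            pos += 1
            continue
        end = pos
        while end < npos and ok[end]:
            end += 1
        if end - pos >= min_len:
            elements.append(
                ConservedElement(
                    interval=(pos, end),
                    length=end - pos,
                    min_agreement=float(np.min(prof[pos:end])),
                )
            )
        pos = end
    return elements


def kmer_frequencies(
    reference_sequence: str,
    elements: Sequence[ConservedElement],
    k: int = 6,
) -> Counter:
    """Counts of every k-window lying fully inside a conserved element.

    Overlapping windows are counted; elements shorter than ``k``
    contribute nothing.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    counts: Counter = Counter()
    seq = reference_sequence.upper()
    for el in elements:
        s, e = el.interval
        for i in range(s, e - k + 1):
            counts[seq[i : i + k]] += 1
    return counts


def restrict_to_common_regions(
    matrices: Mapping[str, MatchMatrix]
) -> Dict[str, MatchMatrix]:
    """Intersect every genome's covered mask across methods.

    Each returned matrix keeps only coverage (and hence matches) inside
    the regions where *all* methods report alignment for that genome.
    Idempotent and symmetric in the methods.
    """
    mats = list(matrices.values())
    first = mats[0]
    for mm in mats[1:]:
        if mm.n_positions != first.n_positions or mm.reference_id != first.reference_id:
            raise InputError("methods cover different references")
        if mm.genome_ids != first.genome_ids:
            raise InputError("methods cover different genome sets")
    common = mats[0].covered.copy()
    for mm in mats[1:]:
        common &= mm.covered
    out = {}
    for name, mm in matrices.items():
        out[name] = MatchMatrix(
            reference_id=mm.reference_id,
            n_positions=mm.n_positions,
            genome_ids=list(mm.genome_ids),
            matched=mm.matched & common,
            covered=common.copy(),
        )
    return out


def summarize_methods(
    method_matrices: Mapping[str, Sequence[MatchMatrix]],
    references: Sequence[SequenceRecord],
    min_len: int = 6,
    min_frac: float = 0.9,
    focal_kmer: str = "AATAAA",
) -> pd.DataFrame:
    """Method-comparison table over a common set of references.

    For each method (after the common-region restriction applied per
    reference): total matched nucleotides, number of conserved elements,
    total sequence inside elements, and occurrences of ``focal_kmer``
    within elements.  ``method_matrices[name][r]`` must correspond to
    ``references[r]``.
    """
    methods = list(method_matrices)
    if len(methods) < 1:
        raise InputError("at least one method is required")
    nrefs = len(references)
    for name in methods:
        if len(method_matrices[name]) != nrefs:
            raise InputError(
                f"method {name!r} has {len(method_matrices[name])} matrices "
                f"for {nrefs} references"
            )
    totals = {
        name: dict(matched_nucleotides=0, n_elements=0,
                   sequence_in_elements=0, focal_kmer_count=0)
        for name in methods
    }
    k = len(focal_kmer)
    for r, ref in enumerate(references):
        per_method = {name: method_matrices[name][r] for name in methods}
        for name, mm in per_method.items():
            if mm.reference_id != ref.id:
                raise InputError(
                    f"method {name!r} matrix {r} is for reference "
                    f"{mm.reference_id!r}, expected {ref.id!r}"
                )
        restricted = (
            restrict_to_common_regions(per_method)
            if len(methods) > 1
            else per_method
        )
        for name, mm in restricted.items():
            elements = find_conserved_elements(mm, min_len=min_len, min_frac=min_frac)
            row = totals[name]
            row["matched_nucleotides"] += mm.matched_nucleotides()
            row["n_elements"] += len(elements)
            row["sequence_in_elements"] += sum(el.length for el in elements)
            row["focal_kmer_count"] += kmer_frequencies(
                ref.sequence, elements, k=k
            ).get(focal_kmer.upper(), 0)
    frame = pd.DataFrame(
        [{"method": name, **totals[name]} for name in methods]
    )
    return frame


def elements_to_bed(
    elements: Sequence[ConservedElement], reference_id: str
) -> str:
    """Render conserved elements as BED (0-based half-open) text."""
    lines = [
        f"{reference_id}\t{el.interval[0]}\t{el.interval[1]}\t"
        f"element_{i}\t{el.min_agreement:.3f}"
        for i, el in enumerate(elements)
    ]
    return "\n".join(lines) + ("\n" if lines else "")
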