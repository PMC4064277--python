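"""End-to-end helpers: align an ortholog family and score motif recovery."""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

from .consistency import (
    ConservedElement,
    MatchMatrix,
    build_match_matrix,
    find_conserved_elements,
)
from .engine import align, align_banded
from .scoring import ScoringScheme
from .seqio import SequenceRecord

__all__ = ["align_family", "recovered_motifs"]


def align_family(
    reference: SequenceRecord,
    orthologs: Sequence[SequenceRecord],
    scheme: ScoringScheme,
    band_width: Optional[int] = None,
) -> MatchMatrix:
    """Align every ortholog to the reference and build the match matrix.

    The reference is the alignment target.  ``band_width`` restricts the
    search to a diagonal band (useful for long, near-colinear orthologs);
    ``None`` runs the full matrix.
    """
    triples = []
    for rec in orthologs:
        if band_width is not None:
            result = align_banded(reference.sequence, rec.sequence, scheme, band_width)
        else:
            result = align(reference.sequence, rec.sequence, scheme)
        triples.append((rec.id, result, rec.sequence))
    return build_match_matrix(reference, triples)


def recovered_motifs(
    elements: Sequence[ConservedElement],
    motif_intervals: Sequence[Tuple[int, int]],
) -> int:
    """Number of planted motif intervals fully contained in some element."""
    count = 0
    for s, e in motif_intervals:
        if any(el.interval[0] <= s and e <= el.interval[1] for el in elements):
            count += 1
    return count
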