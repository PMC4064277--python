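"""Synthetic ortholog families with planted conserved motifs.

Emulates the 3'UTR setting the consistency metrics were designed for:
a random reference sequence carries a few short, highly conserved
recognition motifs (default the poly-adenylation signal ``AATAAA``), and
each simulated ortholog diverges from the reference by per-position
substitutions and indels in the flanks while the motifs stay (nearly)
intact.  Divergence is star-shaped — every ortholog diverges from the
reference independently; phylogenetic correlation between orthologs is
deliberately not modelled.

All randomness flows from a single family seed; per-genome sub-streams
are spawned deterministically, so a family is bitwise reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np

from .seqio import SequenceRecord

__all__ = ["FamilySpec", "FamilyTruth", "simulate_family", "random_sequence"]

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_ALPHABET = "ACGT"


@dataclass(frozen=True)
class FamilySpec:
    """Parameters of one simulated ortholog family.

    Rates are per-position event probabilities (substitution rates may be
    1.0 to force full flank divergence); indel lengths
    are geometric with success probability ``indel_length_geometric_p``
    (mean ``1/p``).  Motif placements are non-overlapping and at least one
    motif length apart.
    """

    ref_length: int = 300
    n_genomes: int = 10
    motif: str = "AATAAA"
    n_motifs: int = 3
    flank_sub_rate: float = 0.3
    flank_indel_rate: float = 0.02
    motif_sub_rate: float = 0.01
    indel_length_geometric_p: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("flank_sub_rate", "motif_sub_rate"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not (0 <= self.flank_indel_rate < 1):
            raise ValueError(
                f"flank_indel_rate must be in [0, 1), got {self.flank_indel_rate}"
            )
        if not (0 < self.indel_length_geometric_p <= 1):
            raise ValueError("indel_length_geometric_p must be in (0, 1]")
        if self.ref_length < self.n_motifs * 2 * len(self.motif):
            raise ValueError(
                "ref_length too small to place "
                f"{self.n_motifs} non-overlapping motifs"
            )
        if self.n_genomes < 1 or self.n_motifs < 0:
            raise ValueError("n_genomes must be >= 1 and n_motifs >= 0")
        if self.motif and set(self.motif.upper()) - set(_ALPHABET):
            raise ValueError("motif must be over A, C, G, T")


@dataclass(frozen=True)
class FamilyTruth:
    """Ground truth of a simulated family.

    ``motif_intervals`` are 0-based half-open intervals on the reference;
    ``preserved[g][k]`` is True iff genome ``g`` carries motif ``k``
    without any substitution.
    """

    motif_intervals: Tuple[Tuple[int, int], ...]
    preserved: Tuple[Tuple[bool, ...], ...]


def random_sequence(length: int, seed: int) -> str:
    """Uniform i.i.d. nucleotide sequence over A, C, G, T."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    return "".join(np.array(list(_ALPHABET))[rng.integers(0, 4, size=length)])


def _place_motifs(rng, ref_length: int, motif_len: int, n_motifs: int,
                  max_tries: int = 1000) -> List[int]:
    """Sample non-overlapping motif starts >= motif_len apart."""
    if n_motifs == 0:
        return []
    for _ in range(max_tries):
        starts = sorted(rng.integers(0, ref_length - motif_len + 1, size=n_motifs))
        ok = all(
            b - a >= 2 * motif_len for a, b in zip(starts, starts[1:])
        )
        if ok:
            return [int(s) for s in starts]
    raise ValueError("infeasible motif placement after bounded retries")


def _mutate(rng, reference: str, in_motif: np.ndarray, spec: FamilySpec):
    """Derive one ortholog; returns (sequence, per-motif substitution-free)."""
    out: List[str] = []
    sub_hit = np.zeros(len(reference), dtype=bool)
    n = len(reference)
    i = 0
    alphabet = _ALPHABET
    while i < n:
        base = reference[i]
        motif_pos = in_motif[i]
        sub_rate = spec.motif_sub_rate if motif_pos else spec.flank_sub_rate
        if not motif_pos and spec.flank_indel_rate > 0 and rng.random() < spec.flank_indel_rate:
            length = int(rng.geometric(spec.indel_length_geometric_p))
            if rng.random() < 0.5:
                # insertion before this position
                ins = rng.integers(0, 4, size=length)
                out.append("".join(alphabet[k] for k in ins))
                # fall through to emit position i normally
            else:
                # deletion of up to `length` flank positions, never into a motif
                end = i
                while end < n and end - i < length and not in_motif[end]:
                    end += 1
                i = end
                continue
        if sub_rate > 0 and rng.random() < sub_rate:
            choices = alphabet.replace(base, "")
            base = choices[rng.integers(0, len(choices))]
            sub_hit[i] = True
        out.append(base)
        i += 1
    return "".join(out), sub_hit


def simulate_family(
    spec: FamilySpec,
) -> Tuple[SequenceRecord, List[SequenceRecord], FamilyTruth]:
    """Generate one family: reference, orthologs, and planted-motif truth.

    With all rates 0 every ortholog equals the reference and every motif
    is flagged preserved.  Fully reproducible from ``spec.seed``.
    """
    motif = spec.motif.upper()
    mlen = len(motif)
    root = np.random.SeedSequence(spec.seed)
    ref_ss, place_ss, *genome_ss = root.spawn(2 + spec.n_genomes)
    ref_rng = np.random.default_rng(ref_ss)

    ref_chars = [
        _ALPHABET[k] for k in ref_rng.integers(0, 4, size=spec.ref_length)
    ]
    place_rng = np.random.default_rng(place_ss)
    starts = _place_motifs(place_rng, spec.ref_length, mlen, spec.n_motifs)
    in_motif = np.zeros(spec.ref_length, dtype=bool)
    for s in starts:
        ref_chars[s : s + mlen] = list(motif)
        in_motif[s : s + mlen] = True
    reference = "".join(ref_chars)
    intervals = tuple((s, s + mlen) for s in starts)

    orthologs: List[SequenceRecord] = []
    preserved: List[Tuple[bool, ...]] = []
    for g, ss in enumerate(genome_ss):
        rng = np.random.default_rng(ss)
        seq, sub_hit = _mutate(rng, reference, in_motif, spec)
        orthologs.append(
            SequenceRecord(f"genome_{g}", f"simulated ortholog {g}", seq)
        )
        preserved.append(
            tuple(not sub_hit[s : s + mlen].any() for s in starts)
        )

    ref_rec = SequenceRecord("reference", "simulated reference", reference)
    return ref_rec, orthologs, FamilyTruth(intervals, tuple(preserved))
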