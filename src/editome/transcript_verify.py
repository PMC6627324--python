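"""Verification of predicted editing sites against transcript sequences.

Assembled transcripts are aligned to the genomic CDS; each mismatch column
is classified by its base pair (genomic C vs transcript T supports C-to-U,
genomic T vs transcript C supports U-to-C, anything else is 'other'), and
predicted sites are counted as confirmed when a direction-matching mismatch
sits at the predicted position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

from Bio import Align
from Bio.Seq import reverse_complement

from .edit_predict import EditingSite

__all__ = [
    "MismatchRecord",
    "VerificationSummary",
    "TranscriptAlignment",
    "TranscriptNotAssignableError",
    "align_transcript",
    "classify_mismatches",
    "verify_predictions",
]

logger = logging.getLogger(__name__)

MismatchClass = Literal["C2U_support", "U2C_support", "other"]

_SUPPORT_OF = {"C2U": "C2U_support", "U2C": "U2C_support"}


class TranscriptNotAssignableError(ValueError):
    """Transcript too diverged from the CDS to be its product."""


@dataclass(frozen=True)
class MismatchRecord:
    cds_position: int  # 1-based
    genomic_base: str
    transcript_base: str
    klass: MismatchClass


@dataclass
class TranscriptAlignment:
    aligned_cds: str
    aligned_transcript: str
    identity: float
    #: (cds 1-based position, transcript 1-based position) per aligned column
    pairs: list[tuple[int, int]]
    reoriented: bool = False


def _nt_aligner(match: float, mismatch: float, open_gap: float, extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = open_gap
    aligner.extend_gap_score = extend
    return aligner


def align_transcript(
    cds: str,
    transcript: str,
    match: float = 2.0,
    mismatch: float = -3.0,
    open_gap: float = -5.0,
    extend: float = -2.0,
    min_identity: float = 0.70,
) -> TranscriptAlignment:
    """Globally align a transcript to its CDS (nucleotide level).

    Transcripts are expected in CDS orientation; a reverse-complement input
    is detected by comparing alignment scores of the two orientations and
    reoriented. Raises :class:`TranscriptNotAssignableError` when identity
    over aligned columns is below ``min_identity``.
    """
    cds = cds.upper().replace("U", "T")
    transcript = transcript.upper().replace("U", "T")
    if not cds or not transcript:
        raise ValueError("empty sequence")
    aligner = _nt_aligner(match, mismatch, open_gap, extend)
    fwd = aligner.align(cds, transcript)
    rev = aligner.align(cds, reverse_complement(transcript))
    reoriented = rev.score > fwd.score
    aln = (rev if reoriented else fwd)[0]
    if reoriented:
        logger.info("transcript reoriented to CDS strand (score %s > %s)", rev.score, fwd.score)
    pairs: list[tuple[int, int]] = []
    matches = 0
    tseq = reverse_complement(transcript) if reoriented else transcript
    for (cs, ce), (ts, te) in zip(*aln.aligned):
        for k in range(ce - cs):
            pairs.append((int(cs) + k + 1, int(ts) + k + 1))
            if cds[cs + k] == tseq[ts + k]:
                matches += 1
    identity = matches / len(pairs) if pairs else 0.0
    if identity < min_identity:
        raise TranscriptNotAssignableError(
            f"transcript not assignable: identity {identity:.3f} < {min_identity:.2f}"
        )
    return TranscriptAlignment(
        aligned_cds=str(aln[0]),
        aligned_transcript=str(aln[1]),
        identity=identity,
        pairs=pairs,
        reoriented=reoriented,
    )


def classify_mismatches(
    alignment: TranscriptAlignment, cds: str, transcript: str
) -> list[MismatchRecord]:
    """Classify every aligned non-gap mismatch column by its base pair."""
    cds = cds.upper().replace("U", "T")
    transcript = transcript.upper().replace("U", "T")
    if alignment.reoriented:
        transcript = reverse_complement(transcript)
    records = []
    for cpos, tpos in alignment.pairs:
        g, t = cds[cpos - 1], transcript[tpos - 1]
        if g == t:
            continue
        if g == "C" and t == "T":
            klass: MismatchClass = "C2U_support"
        elif g == "T" and t == "C":
            klass = "U2C_support"
        else:
            klass = "other"
        records.append(
            MismatchRecord(cds_position=cpos, genomic_base=g, transcript_base=t, klass=klass)
        )
    return records


@dataclass
class VerificationSummary:
    """Predicted vs transcript-confirmed site counts, per direction."""

    predicted: dict[str, int] = field(default_factory=lambda: {"C2U": 0, "U2C": 0})
    confirmed: dict[str, int] = field(default_factory=lambda: {"C2U": 0, "U2C": 0})
    observed_not_predicted: dict[str, int] = field(
        default_factory=lambda: {"C2U": 0, "U2C": 0}
    )

    def ratio(self, direction: str) -> Optional[float]:
        """Confirmed-to-predicted fraction; None for 0 predicted."""
        if self.predicted[direction] == 0:
            return None
        return self.confirmed[direction] / self.predicted[direction]


def verify_predictions(
    sites: Sequence[EditingSite],
    mismatches: Sequence[MismatchRecord],
    cds_length: Optional[int] = None,
) -> VerificationSummary:
    """Count predicted sites with direction-matching transcript support.

    A predicted site is confirmed when some mismatch record at the same CDS
    position carries the matching support class. Direction-matching evidence
    wins over conflicting 'other' mismatches at the same position (conflicts
    are logged). Zero predictions yield a 0/0 summary, not an error.
    """
    if cds_length is not None:
        bad = [s.position for s in sites if not 1 <= s.position <= cds_length]
        bad += [m.cds_position for m in mismatches if not 1 <= m.cds_position <= cds_length]
        if bad:
            raise ValueError(f"positions outside CDS of length {cds_length}: {sorted(bad)}")
    support_at: dict[tuple[int, str], bool] = {}
    conflict_positions = set()
    for m in mismatches:
        if m.klass in ("C2U_support", "U2C_support"):
            support_at[(m.cds_position, m.klass)] = True
        else:
            conflict_positions.add(m.cds_position)
    summary = VerificationSummary()
    predicted_positions: dict[str, set[int]] = {"C2U": set(), "U2C": set()}
    for s in sites:
        summary.predicted[s.direction] += 1
        predicted_positions[s.direction].add(s.position)
        if (s.position, _SUPPORT_OF[s.direction]) in support_at:
            summary.confirmed[s.direction] += 1
            if s.position in conflict_positions:
                logger.info(
                    "position %d: direction-matching evidence retained despite "
                    "conflicting mismatches",
                    s.position,
                )
    for (pos, klass) in support_at:
        direction = "C2U" if klass == "C2U_support" else "U2C"
        if pos not in predicted_positions[direction]:
            summary.observed_not_predicted[direction] += 1
    return summary
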