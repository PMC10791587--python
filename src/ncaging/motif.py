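"""IUPAC motif scanning of mature miRNA sequences.

Used to search for extracellular-vesicle sorting signals (EXOmotifs such
as CNGGNC) in mature miRNA sequences, exactly or allowing a bounded number
of mismatching positions.  DNA input (T) is transparently converted to RNA
(U); no reverse-complement scanning (mature miRNAs are single-stranded).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

logger = logging.getLogger(__name__)

IUPAC_RNA: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "U": frozenset("U"),
    "R": frozenset("AG"), "Y": frozenset("CU"), "S": frozenset("GC"),
    "W": frozenset("AU"), "K": frozenset("GU"), "M": frozenset("AC"),
    "B": frozenset("CGU"), "D": frozenset("AGU"), "H": frozenset("ACU"),
    "V": frozenset("ACG"), "N": frozenset("ACGU"),
}


@dataclass(frozen=True)
class MotifHit:
    feature_id: str
    motif: str
    position: int              # 0-based offset
    mismatches: int
    matched_substring: str


def _to_rna(seq: str) -> str:
    up = seq.upper()
    if "T" in up:
        logger.info("DNA input detected: converting T -> U")
        up = up.replace("T", "U")
    return up


def scan_motif(sequence: str, motif: str, max_mismatch: int = 0,
               feature_id: str = "") -> list[MotifHit]:
    """All offsets where the sequence matches the IUPAC motif with at most
    ``max_mismatch`` violating positions.

    Hits are sorted by (mismatches, position).  An invalid IUPAC symbol in
    the motif is an error; sequence letters outside {A,C,G,U,N} (after
    T->U conversion) never match a non-N motif position.
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    motif_rna = _to_rna(motif)
    bad = [ch for ch in motif_rna if ch not in IUPAC_RNA]
    if bad:
        raise ValueError(f"invalid IUPAC symbol(s) in motif: {bad}")
    seq = _to_rna(sequence)
    k = len(motif_rna)
    classes = [IUPAC_RNA[ch] for ch in motif_rna]
    hits = []
    for pos in range(len(seq) - k + 1):
        window = seq[pos:pos + k]
        mism = sum(base not in cls for base, cls in zip(window, classes))
        if mism <= max_mismatch:
            hits.append(MotifHit(feature_id=feature_id, motif=motif_rna,
                                 position=pos, mismatches=mism,
                                 matched_substring=window))
    hits.sort(key=lambda h: (h.mismatches, h.position))
    return hits


def scan_sequences(seqs: Mapping[str, str], motif: str,
                   max_mismatch: int = 0) -> list[MotifHit]:
    """Scan a whole id -> sequence map (e.g. a mature-sequence FASTA)."""
    out: list[MotifHit] = []
    for fid, seq in seqs.items():
        out.extend(scan_motif(seq, motif, max_mismatch, feature_id=fid))
    return out
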