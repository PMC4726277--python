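"""Sequence-level utilities shared by all pipeline stages.

Frame-guided translation and ORF prediction, tryptic digestion, assembly
length statistics (N50/N80/N20) and greedy redundancy clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
from Bio.Align import PairwiseAligner
from Bio.Data.CodonTable import standard_dna_table

__all__ = [
    "TranscriptRecord",
    "BestHit",
    "AssemblyStats",
    "Cluster",
    "translate_frame",
    "predict_orf",
    "tryptic_digest",
    "assembly_stats",
    "cluster_redundant",
    "read_fasta",
    "write_fasta",
]

MIN_ORF_LEN = 10  # residues; shorter segments yield a no-call

_CODON_TO_AA = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODON_TO_AA[_stop] = "*"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class BestHit:
    """Top similarity-search hit for a transcript (tabular 12-column row)."""

    query_id: str
    subject_id: str
    evalue: float
    bitscore: float
    frame: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int

    def __post_init__(self) -> None:
        if abs(self.frame) not in (1, 2, 3):
            raise ValueError(f"frame must be in ±{{1,2,3}}, got {self.frame}")
        if self.q_start > self.q_end:
            raise ValueError("q_start must be <= q_end")
        if self.s_start < 1:
            raise ValueError("s_start must be >= 1")


@dataclass
class TranscriptRecord:
    """A nucleotide sequence plus optional best-hit annotation."""

    id: str
    sequence: str
    best_hit: Optional[BestHit] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"transcript {self.id}: empty sequence")
        bad = set(self.sequence.upper()) - set("ACGTN")
        if bad:
            raise ValueError(
                f"transcript {self.id}: invalid characters {sorted(bad)}"
            )
        self.sequence = self.sequence.upper()

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AssemblyStats:
    n_sequences: int
    shortest: int
    longest: int
    n50: int
    n80: int
    n20: int
    n_over_n50: int


@dataclass
class Cluster:
    representative: str
    members: list = field(default_factory=list)


def reverse_complement(sequence: str) -> str:
    return sequence.upper().translate(_COMPLEMENT)[::-1]


def translate_frame(sequence: str, frame: int) -> str:
    """Translate ``sequence`` in the given signed reading frame.

    Negative frames translate the reverse complement.  Stop codons are
    rendered as ``*``; a trailing partial codon is dropped; codons containing
    characters outside A/C/G/T translate to ``X``.
    """
    if not sequence:
        raise ValueError("cannot translate an empty sequence")
    if abs(frame) not in (1, 2, 3):
        raise ValueError(f"frame must be in ±{{1,2,3}}, got {frame}")
    seq = sequence.upper()
    if frame < 0:
        seq = reverse_complement(seq)
    offset = abs(frame) - 1
    out = []
    for i in range(offset, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        out.append(_CODON_TO_AA.get(codon, "X"))
    return "".join(out)


def _orf_candidates(protein: str, require_met: bool = True) -> Iterator[str]:
    """Yield one ORF candidate per stop-free segment of a translation.

    Within each segment the candidate starts at the first Met when one
    exists; otherwise the full segment is the candidate.
    """
    for segment in protein.split("*"):
        if not segment:
            continue
        if require_met:
            met = segment.find("M")
            yield segment[met:] if met >= 0 else segment
        else:
            yield segment


def predict_orf(record: TranscriptRecord, min_len: int = MIN_ORF_LEN) -> Optional[str]:
    """Predict the protein encoded by a transcript.

    With a best hit, the hit's frame is translated and the longest stop-free
    segment overlapping the aligned region is returned.  Without one, all six
    frames are scanned for the longest ORF (starting at the first Met of the
    segment when present).  Segments shorter than ``min_len`` give a no-call
    (``None``).
    """
    if record.best_hit is not None:
        hit = record.best_hit
        protein = translate_frame(record.sequence, hit.frame)
        # map aligned nucleotide span onto this frame's residue coordinates
        if hit.frame > 0:
            nt_lo, nt_hi = hit.q_start, hit.q_end
        else:
            n = len(record.sequence)
            nt_lo, nt_hi = n - hit.q_end + 1, n - hit.q_start + 1
        offset = abs(hit.frame) - 1
        aa_lo = max(0, (nt_lo - 1 - offset) // 3)
        aa_hi = min(len(protein), (nt_hi - 1 - offset) // 3 + 1)
        best = None
        pos = 0
        for segment in protein.split("*"):
            start, end = pos, pos + len(segment)
            pos = end + 1
            if end <= aa_lo or start >= aa_hi:
                continue
            if best is None or len(segment) > len(best):
                best = segment
        if best is None or len(best) < min_len:
            return None
        return best

    best = None
    for frame in (1, 2, 3, -1, -2, -3):
        protein = translate_frame(record.sequence, frame)
        for cand in _orf_candidates(protein):
            if best is None or len(cand) > len(best):
                best = cand
    if best is None or len(best) < min_len:
        return None
    return best


def tryptic_digest(
    protein: str, missed_cleavages: int = 0, min_len: int = 6
) -> list[str]:
    """In-silico trypsin digestion.

    Cleaves after K or R unless the next residue is P.  With
    ``missed_cleavages`` = m, all concatenations of up to m+1 adjacent
    fragments are included.  Peptides shorter than ``min_len`` are dropped.
    """
    if not protein:
        raise ValueError("cannot digest an empty protein")
    fragments = []
    start = 0
    for i, aa in enumerate(protein):
        if aa in "KR" and i + 1 < len(protein) and protein[i + 1] != "P":
            fragments.append(protein[start : i + 1])
            start = i + 1
    if start < len(protein):
        fragments.append(protein[start:])

    peptides = []
    for i in range(len(fragments)):
        for j in range(i, min(i + missed_cleavages + 1, len(fragments))):
            pep = "".join(fragments[i : j + 1])
            if len(pep) >= min_len:
                peptides.append(pep)
    return peptides


def assembly_stats(lengths: Sequence[int]) -> AssemblyStats:
    """Length statistics of an assembly: Nx by descending cumulative sum.

    Nx is the length L such that sequences of length >= L cover >= x% of the
    total assembled bases.  ``n_over_n50`` counts sequences strictly longer
    than N50.
    """
    if len(lengths) == 0:
        raise ValueError("lengths must be non-empty")
    arr = np.asarray(lengths, dtype=np.int64)
    if (arr <= 0).any():
        raise ValueError("lengths must be positive")
    desc = np.sort(arr)[::-1]
    cum = np.cumsum(desc)
    total = cum[-1]

    def nx(frac: float) -> int:
        idx = int(np.searchsorted(cum, frac * total))
        return int(desc[idx])

    n50 = nx(0.5)
    return AssemblyStats(
        n_sequences=int(arr.size),
        shortest=int(arr.min()),
        longest=int(arr.max()),
        n50=n50,
        n80=nx(0.8),
        n20=nx(0.2),
        n_over_n50=int((arr > n50).sum()),
    )


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = -1
    aligner.extend_gap_score = -1
    return aligner


def pairwise_identity(a: str, b: str, aligner: Optional[PairwiseAligner] = None) -> float:
    """Fraction of exactly matching aligned residues over the shorter length.

    'X' never counts as a match.
    """
    if aligner is None:
        aligner = _make_aligner()
    alignment = aligner.align(a, b)[0]
    matches = 0
    for (a_lo, a_hi), (b_lo, b_hi) in zip(*alignment.aligned):
        for x, y in zip(a[a_lo:a_hi], b[b_lo:b_hi]):
            if x == y and x != "X":
                matches += 1
    return matches / min(len(a), len(b))


def cluster_redundant(
    proteins: dict[str, str] | Sequence[tuple[str, str]],
    identity_cutoff: float = 0.5,
) -> list[Cluster]:
    """Greedy incremental clustering (longest-first, CD-HIT convention).

    Each sequence joins the first cluster whose representative shares
    identity >= ``identity_cutoff`` with it, else founds a new cluster.
    Identity denominator is the shorter sequence's length.
    """
    items = list(proteins.items()) if isinstance(proteins, dict) else list(proteins)
    if not items:
        raise ValueError("proteins must be non-empty")
    order = sorted(range(len(items)), key=lambda i: (-len(items[i][1]), i))
    aligner = _make_aligner()
    clusters: list[Cluster] = []
    reps: list[str] = []
    for i in order:
        name, seq = items[i]
        placed = False
        for cluster, rep_seq in zip(clusters, reps):
            if pairwise_identity(seq, rep_seq, aligner) >= identity_cutoff:
                cluster.members.append(name)
                placed = True
                break
        if not placed:
            clusters.append(Cluster(representative=name, members=[name]))
            reps.append(seq)
    return clusters


# ---------------------------------------------------------------------------
# FASTA I/O (60-column wrapped output; minimal reader adequate for our files)

def read_fasta(path) -> list[tuple[str, str]]:
    records = []
    name = None
    chunks: list[str] = []
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    records.append((name, "".join(chunks)))
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        records.append((name, "".join(chunks)))
    return records


def write_fasta(path, records: Iterable[tuple[str, str]], width: int = 60) -> None:
    with open(path, "w") as handle:
        for name, seq in records:
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")
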