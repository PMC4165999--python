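"""Greedy length-ordered identity-threshold clustering of protein sequences.

This is the incremental scheme popularised by CD-HIT: sort sequences from
longest to shortest, walk the list once, and attach each sequence to the
first existing cluster whose representative it matches at or above the
identity threshold; otherwise it founds a new cluster and becomes that
cluster's representative.  A shared-k-mer count gives a provably safe lower
bound that lets most below-threshold alignments be skipped without ever
changing the result.

Identity here is defined from one optimal global alignment under the scoring
match +1 / mismatch 0 / linear gap -1: the number of identical aligned
residues divided by the alignment length (gap columns included).
"""

from __future__ import annotations

import dataclasses
import math
from collections import Counter
from typing import Sequence

from Bio import Align

from .seqio import ProteinRecord

__all__ = ["ClusterSet", "pairwise_identity", "greedy_cluster", "representatives"]


@dataclasses.dataclass(frozen=True)
class Cluster:
    representative: str
    members: tuple[str, ...]  # insertion order; representative is members[0]


@dataclasses.dataclass(frozen=True)
class ClusterSet:
    threshold: float
    clusters: tuple[Cluster, ...]

    def __len__(self) -> int:
        return len(self.clusters)

    def member_to_cluster(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for i, c in enumerate(self.clusters):
            for m in c.members:
                out[m] = i
        return out


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = -1
    aligner.extend_gap_score = -1
    return aligner


_ALIGNER = _make_aligner()


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of identical columns in an optimal global alignment of a and b.

    Symmetric by construction (the argument pair is canonically ordered before
    aligning, so tie-breaking among co-optimal alignments cannot depend on
    argument order).
    """
    if not a or not b:
        raise ValueError("pairwise_identity requires non-empty sequences")
    if b < a:
        a, b = b, a
    aln = _ALIGNER.align(a, b)[0]
    counts = aln.counts()
    length = counts.identities + counts.mismatches + counts.gaps
    return counts.identities / length


def _kmer_spectrum(seq: str, k: int) -> Counter:
    return Counter(seq[i : i + k] for i in range(len(seq) - k + 1))


def _may_reach_threshold(
    short_len: int,
    long_len: int,
    shared_kmers: int,
    threshold: float,
    k: int,
) -> bool:
    """Necessary condition for identity >= threshold from shared k-mer counts.

    If identity >= t then the match count M >= t * alignment_length >= t * long_len,
    so the shorter sequence has at most e = short_len - ceil(t * long_len)
    residues outside match columns.  Each such residue can break at most k of
    the shorter sequence's k-mers, hence the two spectra must share at least
    (short_len - k + 1) - k*e k-mers (multiset intersection).  Returns False
    only when threshold identity is provably impossible.
    """
    min_matches = math.ceil(threshold * long_len)
    if min_matches > short_len:
        return False
    e_max = short_len - min_matches
    required = (short_len - k + 1) - k * e_max
    if required <= 0:
        return True
    return shared_kmers >= required


def greedy_cluster(
    records: Sequence[ProteinRecord],
    threshold: float,
    word_size: int = 2,
    use_prefilter: bool = True,
) -> ClusterSet:
    """Cluster sequences greedily at the given identity threshold.

    Sequences are processed longest first (length ties by ascending id); each
    joins the first cluster whose representative identity reaches the
    threshold, else founds a new one.  ``use_prefilter`` toggles the k-mer
    skip rule; it is an optimisation only and never changes the clustering.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    ordered = sorted(records, key=lambda r: (-len(r), r.id))
    reps: list[ProteinRecord] = []
    rep_spectra: list[Counter] = []
    members: list[list[str]] = []
    for rec in ordered:
        spectrum = _kmer_spectrum(rec.sequence, word_size) if use_prefilter else None
        placed = False
        for ci, rep in enumerate(reps):
            if use_prefilter:
                # rep is always >= rec in length because of processing order
                shared = sum(
                    min(n, rep_spectra[ci][w]) for w, n in spectrum.items()
                )
                if not _may_reach_threshold(
                    len(rec), len(rep), shared, threshold, word_size
                ):
                    continue
            if pairwise_identity(rec.sequence, rep.sequence) >= threshold:
                members[ci].append(rec.id)
                placed = True
                break
        if not placed:
            reps.append(rec)
            rep_spectra.append(
                _kmer_spectrum(rec.sequence, word_size) if use_prefilter else Counter()
            )
            members.append([rec.id])
    clusters = tuple(
        Cluster(representative=rep.id, members=tuple(mem))
        for rep, mem in zip(reps, members)
    )
    return ClusterSet(threshold=threshold, clusters=clusters)


def representatives(cs: ClusterSet) -> list[str]:
    """Representative ids, one per cluster, in cluster-creation order."""
    return [c.representative for c in cs.clusters]
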