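"""Host-read subtraction by exact canonical k-mer screening.

In samples where host DNA predominates (biopsies especially), a large share
of amplicon reads derives from off-target amplification of the host genome
and must be subtracted before denoising.  At full scale this is done by
mapping reads to the host genome with a short-read aligner; this module
implements the same contract with an exact canonical k-mer screen against a
host reference: a sequence is called host when the fraction of its k-mers
present in the host index reaches a threshold.  The screen is exact,
dependency-free and conservative (pair-level removal when either mate is
host); a precomputed external read-id list from a real aligner can be
supplied instead for full-scale runs.

Also computes the per-sample percentage of ASVs classified as host — the
summary statistic of how much of an amplicon survey off-target products
consume.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from amplikit.primer_model import revcomp

__all__ = [
    "HostIndex",
    "HostCallSummary",
    "build_host_index",
    "classify_sequence",
    "subtract_host",
    "host_asv_percent",
]

_N_SPACER = re.compile(r"N+")


@dataclass
class HostIndex:
    """Strand-collapsed exact k-mer set of a host reference."""

    k: int
    kmers: set[str]
    source_ids: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.kmers)

    def merge(self, other: "HostIndex") -> "HostIndex":
        if other.k != self.k:
            raise ValueError("cannot merge indexes with different k")
        return HostIndex(
            self.k, self.kmers | other.kmers, self.source_ids + other.source_ids
        )


def _canonical(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def build_host_index(
    host_records: list[tuple[str, str]], k: int = 21
) -> HostIndex:
    """Index every canonical k-mer of the host reference sequences.

    ``k`` must be odd and in [11, 31] (odd k makes canonicalization
    unambiguous); k-mers containing non-ACGT letters are skipped.
    """
    if k % 2 == 0 or not 11 <= k <= 31:
        raise ValueError("k must be odd and within [11, 31]")
    if not host_records:
        raise ValueError("empty host reference")
    kmers: set[str] = set()
    for _, seq in host_records:
        seq = seq.upper()
        for i in range(len(seq) - k + 1):
            km = seq[i : i + k]
            if all(c in "ACGT" for c in km):
                kmers.add(_canonical(km))
    return HostIndex(k, kmers, tuple(r[0] for r in host_records))


def classify_sequence(
    seq: str, index: HostIndex, theta: float = 0.5
) -> tuple[str, float]:
    """Call a sequence host or non_host by canonical k-mer hit fraction.

    Returns ``(call, hit_fraction)``; host iff the fraction of the
    sequence's k-mers found in the index is >= theta.  Sequences shorter
    than k are non_host with fraction 0.
    """
    seq = seq.upper()
    k = index.k
    n = len(seq) - k + 1
    if n <= 0:
        return ("non_host", 0.0)
    hits = 0
    for i in range(n):
        km = seq[i : i + k]
        if "N" in km:
            continue
        if _canonical(km) in index.kmers:
            hits += 1
    frac = hits / n
    return ("host" if frac >= theta else "non_host", frac)


@dataclass
class HostCallSummary:
    n_pairs_total: int = 0
    n_pairs_host: int = 0
    n_asv_total: int = 0
    n_asv_host: int = 0

    @property
    def host_read_fraction(self) -> float:
        """Percentage of read pairs called host."""
        if self.n_pairs_total == 0:
            return 0.0
        return 100.0 * self.n_pairs_host / self.n_pairs_total

    @property
    def host_asv_percent(self) -> float:
        if self.n_asv_total == 0:
            return 0.0
        return 100.0 * self.n_asv_host / self.n_asv_total

    def to_dict(self) -> dict:
        return {
            "n_pairs_total": self.n_pairs_total,
            "n_pairs_host": self.n_pairs_host,
            "host_read_fraction": self.host_read_fraction,
            "n_asv_total": self.n_asv_total,
            "n_asv_host": self.n_asv_host,
            "host_asv_percent": self.host_asv_percent,
        }


def subtract_host(
    reads1: list[tuple[str, str, str]],
    reads2: list[tuple[str, str, str]],
    index: HostIndex,
    theta: float = 0.5,
    host_ids: set[str] | None = None,
) -> tuple[list, list, HostCallSummary]:
    """Remove read pairs classified as host.

    A PAIR is removed when either mate classifies host (conservative
    subtraction of successfully host-matched reads); surviving order is
    preserved.  ``host_ids`` optionally bypasses the k-mer screen with an
    external aligner's read-id list.  Raises on desynchronized inputs.
    """
    if len(reads1) != len(reads2):
        raise ValueError("desynchronized pair files")
    out1, out2 = [], []
    summary = HostCallSummary(n_pairs_total=len(reads1))
    for r1, r2 in zip(reads1, reads2):
        if _pair_ids_differ(r1[0], r2[0]):
            raise ValueError(f"desynchronized pair: {r1[0]} vs {r2[0]}")
        if host_ids is not None:
            base = r1[0].split("/")[0].split()[0]
            is_host = base in host_ids or r1[0] in host_ids
        else:
            is_host = (
                classify_sequence(r1[1], index, theta)[0] == "host"
                or classify_sequence(r2[1], index, theta)[0] == "host"
            )
        if is_host:
            summary.n_pairs_host += 1
        else:
            out1.append(r1)
            out2.append(r2)
    return out1, out2, summary


def _pair_ids_differ(t1: str, t2: str) -> bool:
    b1 = t1.split()[0].rsplit("/", 1)[0]
    b2 = t2.split()[0].rsplit("/", 1)[0]
    return b1 != b2


def host_asv_percent(
    asv_sequences: list[str], index: HostIndex, theta: float = 0.5
) -> float:
    """Percentage of ASV sequences classifying as host.

    Concatenated ASVs are split at their N spacer and called host if any
    segment classifies host.
    """
    if not asv_sequences:
        return 0.0
    n_host = 0
    for seq in asv_sequences:
        segments = [s for s in _N_SPACER.split(seq.upper()) if s]
        if any(
            classify_sequence(s, index, theta)[0] == "host" for s in segments
        ):
            n_host += 1
    return 100.0 * n_host / len(asv_sequences)
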