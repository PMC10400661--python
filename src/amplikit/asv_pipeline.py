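"""Read-to-ASV pipeline: filter/trim, dereplicate, denoise, pair, clean.

The stages mirror the standard amplicon operating procedure with paired-read
concatenation added for amplicons longer than twice the read length:

1. quality filter/trim (ambiguous-base cap, expected-error cap, fixed
   3'-tail truncation),
2. dereplication into unique sequences with abundances and mean qualities,
3. greedy abundance-skew denoising (error reads are absorbed into more
   abundant centers within a small Hamming radius),
4. per-pair merge-else-concatenate: overlapping mates are merged into a
   consensus, non-overlapping mates are joined with a 10-N spacer,
5. de novo bimera flagging (two-parent exact-segment test), and
6. contaminant flagging from a genus signature list plus a
   negative-control prevalence rule.

The denoiser replaces a learned parametric error model with an
abundance-skew rule: a unique sequence is absorbed by a more abundant
center at Hamming distance d when its abundance is at most
``center * 2**(-alpha*d)``.  The contract — sequencing-error reads collapse
onto the true template sequences — is the same and is what downstream
recovery tests exercise.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from amplikit.primer_model import revcomp

__all__ = [
    "FilterParams",
    "ASVTable",
    "expected_errors",
    "filter_and_trim",
    "dereplicate",
    "denoise",
    "merge_or_concat",
    "remove_bimeras",
    "remove_contaminants",
    "load_contaminant_signatures",
    "run_pipeline",
    "N_SPACER",
]

logger = logging.getLogger(__name__)

N_SPACER = "N" * 10
_SPACER_RUN = re.compile(r"N+")


@dataclass(frozen=True)
class FilterParams:
    """Quality-filter settings (per mate; a failing mate drops the pair)."""

    max_n: int = 0
    max_ee: float = 2.0
    trunc_tail: int = 10
    min_len: int = 50

    def __post_init__(self) -> None:
        if min(self.max_n, self.max_ee, self.trunc_tail, self.min_len) < 0:
            raise ValueError("filter parameters must be >= 0")


def expected_errors(quality: str) -> float:
    """Expected number of errors implied by a Phred+33 quality string."""
    if not quality:
        return 0.0
    arr = np.frombuffer(quality.encode(), dtype=np.uint8)
    if arr.min() < 33:
        raise ValueError("quality character below '!' (not Phred+33)")
    q = arr.astype(float) - 33.0
    return float(np.sum(10.0 ** (-q / 10.0)))


def filter_and_trim(
    reads1: list[tuple[str, str, str]],
    reads2: list[tuple[str, str, str]],
    params: FilterParams = FilterParams(),
) -> tuple[list, list, dict]:
    """Truncate the 3' tail of each mate, then drop failing pairs.

    A pair is dropped when either truncated mate has more than ``max_n``
    ambiguous bases, expected errors above ``max_ee``, or length below
    ``min_len``.  Returns (kept1, kept2, counts) with
    counts = {"in", "kept", "dropped"}.
    """
    if len(reads1) != len(reads2):
        raise ValueError("desynchronized pair files")
    out1, out2 = [], []
    for r1, r2 in zip(reads1, reads2):
        keep = True
        trimmed = []
        for title, seq, qual in (r1, r2):
            if params.trunc_tail:
                seq = seq[: -params.trunc_tail] or ""
                qual = qual[: -params.trunc_tail] or ""
            if (
                len(seq) < params.min_len
                or seq.count("N") > params.max_n
                or expected_errors(qual) > params.max_ee
            ):
                keep = False
                break
            trimmed.append((title, seq, qual))
        if keep:
            out1.append(trimmed[0])
            out2.append(trimmed[1])
    counts = {
        "in": len(reads1),
        "kept": len(out1),
        "dropped": len(reads1) - len(out1),
    }
    return out1, out2, counts


def dereplicate(
    reads: list[tuple[str, str, str]] | list[str],
) -> list[tuple[str, int, np.ndarray]]:
    """Collapse reads into unique sequences.

    Returns ``(sequence, abundance, per-position mean quality)`` sorted by
    descending abundance then lexicographically.  Plain sequence lists get
    a flat Q30 placeholder quality.
    """
    groups: dict[str, list[str]] = {}
    for r in reads:
        if isinstance(r, str):
            seq, qual = r, None
        else:
            _, seq, qual = r
        groups.setdefault(seq, []).append(qual)
    out = []
    for seq, quals in groups.items():
        if quals[0] is None:
            mean_q = np.full(len(seq), 30.0)
        else:
            qarr = np.stack(
                [
                    np.frombuffer(q.encode(), dtype=np.uint8).astype(float) - 33.0
                    for q in quals
                ]
            )
            mean_q = qarr.mean(axis=0)
        out.append((seq, len(quals), mean_q))
    out.sort(key=lambda t: (-t[1], t[0]))
    return out


def _hamming_within(a: str, b: str, limit: int) -> int:
    """Hamming distance, or limit+1 as soon as it exceeds the limit."""
    d = 0
    for x, y in zip(a, b):
        if x != y:
            d += 1
            if d > limit:
                return d
    return d


def denoise(
    uniques: list[tuple[str, int, np.ndarray]] | list[tuple[str, int]],
    alpha: float = 2.0,
    d_max: int = 2,
    min_abundance: int = 1,
) -> tuple[list[tuple[str, int]], dict[str, str]]:
    """Greedy abundance-skew denoising of dereplicated sequences.

    Processing uniques in descending abundance, each sequence joins the most
    abundant existing center of the same length within Hamming distance
    ``d_max`` whose abundance ratio satisfies
    ``abundance(u) <= abundance(center) * 2**(-alpha*d)``; otherwise it
    founds a new center.  ``d_max=0`` is the identity.  A unique that
    neither joins a center nor reaches ``min_abundance`` is discarded
    (reads carrying more errors than the Hamming radius would otherwise
    seed spurious low-abundance centers); discarded uniques are absent
    from the returned mapping.  Returns the centers with corrected
    (absorbed) abundances and the unique->center mapping.
    """
    items = sorted(
        ((u[0], u[1]) for u in uniques), key=lambda t: (-t[1], t[0])
    )
    centers: list[tuple[str, int]] = []  # (seq, founding abundance)
    corrected: dict[str, int] = {}
    mapping: dict[str, str] = {}
    for seq, abundance in items:
        assigned = None
        if d_max > 0:
            for c_seq, c_ab in centers:  # already in descending abundance
                if len(c_seq) != len(seq):
                    continue
                d = _hamming_within(seq, c_seq, d_max)
                if d == 0:
                    continue  # identical sequences were dereplicated
                if d <= d_max and abundance <= c_ab * 2.0 ** (-alpha * d):
                    assigned = c_seq
                    break
        if assigned is None:
            if d_max > 0 and abundance < min_abundance:
                continue  # discarded: likely a many-error read
            centers.append((seq, abundance))
            corrected[seq] = abundance
            mapping[seq] = seq
        else:
            corrected[assigned] += abundance
            mapping[seq] = assigned
    result = sorted(corrected.items(), key=lambda t: (-t[1], t[0]))
    return result, mapping


def merge_or_concat(
    seq1: str,
    seq2: str,
    qual1: np.ndarray | None = None,
    qual2: np.ndarray | None = None,
    min_overlap: int = 12,
    max_overlap_mismatch: int = 0,
) -> tuple[str, str]:
    """Merge a read pair by overlap, else concatenate with a 10-N spacer.

    ``seq2`` is reverse-complemented before the overlap search.  The best
    (longest) overlap of at least ``min_overlap`` bases with at most
    ``max_overlap_mismatch`` mismatches yields a merged consensus (the
    higher-quality base wins at conflicts); otherwise the pair is joined as
    ``seq1 + 10*N + revcomp(seq2)``.  Returns (sequence, construction) with
    construction in {"merged", "concatenated"}.
    """
    rc2 = revcomp(seq2)
    q2 = qual2[::-1] if qual2 is not None else None
    max_ov = min(len(seq1), len(rc2))
    for ov in range(max_ov, min_overlap - 1, -1):
        left = seq1[-ov:]
        right = rc2[:ov]
        mism = [i for i in range(ov) if left[i] != right[i]]
        if len(mism) > max_overlap_mismatch:
            continue
        merged = list(seq1 + rc2[ov:])
        for i in mism:
            p1 = len(seq1) - ov + i
            s1_q = qual1[p1] if qual1 is not None else 30.0
            s2_q = q2[i] if q2 is not None else 30.0
            merged[p1] = left[i] if s1_q >= s2_q else right[i]
        return "".join(merged), "merged"
    return seq1 + N_SPACER + rc2, "concatenated"


class ASVTable:
    """ASV sequences x samples count matrix with provenance flags.

    ``counts`` is a DataFrame indexed by asv_id with one column per sample;
    ``meta`` is indexed by asv_id with columns ``sequence``,
    ``construction`` (merged|concatenated) and boolean flags ``chimera``,
    ``contaminant``, ``host``.  Flagged rows are excluded from downstream
    statistics via :meth:`unflagged`.
    """

    def __init__(self, counts: pd.DataFrame, meta: pd.DataFrame):
        if not counts.index.equals(meta.index):
            raise ValueError("counts and meta must share the asv_id index")
        if (counts.values < 0).any():
            raise ValueError("counts must be >= 0")
        for col in ("chimera", "contaminant", "host"):
            if col not in meta.columns:
                meta[col] = False
        for seq, constr in zip(meta["sequence"], meta["construction"]):
            runs = _SPACER_RUN.findall(seq)
            if constr == "concatenated":
                if runs != [N_SPACER]:
                    raise ValueError(
                        "concatenated ASV must contain exactly one 10-N run"
                    )
            elif any(len(r) >= len(N_SPACER) for r in runs):
                raise ValueError("merged ASV must not contain a spacer-length N run")
        self.counts = counts
        self.meta = meta

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def sequences(self) -> list[str]:
        return list(self.meta["sequence"])

    def flagged_mask(self) -> pd.Series:
        return (
            self.meta["chimera"] | self.meta["contaminant"] | self.meta["host"]
        )

    def unflagged(self) -> "ASVTable":
        keep = ~self.flagged_mask()
        return ASVTable(self.counts.loc[keep].copy(), self.meta.loc[keep].copy())

    def to_tsv(self, counts_path: str | Path, meta_path: str | Path) -> None:
        out = self.counts.copy()
        out.insert(0, "asv_id", out.index)
        out.to_csv(counts_path, sep="\t", index=False)
        meta = self.meta.copy()
        flags = [
            ";".join(
                f for f in ("chimera", "contaminant", "host") if row[f]
            )
            for _, row in meta.iterrows()
        ]
        side = pd.DataFrame(
            {
                "asv_id": meta.index,
                "sequence": meta["sequence"],
                "construction": meta["construction"],
                "flags": flags,
            }
        )
        side.to_csv(meta_path, sep="\t", index=False)


def remove_bimeras(table: ASVTable) -> ASVTable:
    """Flag two-parent chimeras (bimeras) in the table.

    An ASV is a bimera in one sample when some split point partitions its
    sequence into a left segment exactly matching the prefix of one parent
    and a right segment exactly matching the suffix of another, both
    parents being at least twice as abundant in that sample.  The flag is
    set when the per-sample verdicts are chimeric in a strict majority of
    the samples where the ASV occurs.
    """
    counts = table.counts
    meta = table.meta.copy()
    seqs = meta["sequence"]
    order = counts.sum(axis=1).sort_values(ascending=False).index
    chimera = meta["chimera"].copy()
    for asv in order:
        a_seq = seqs[asv]
        present = counts.columns[counts.loc[asv] > 0]
        if len(present) == 0:
            continue
        votes = 0
        for sample in present:
            a_count = counts.at[asv, sample]
            parents = [
                p for p in counts.index
                if p != asv and counts.at[p, sample] >= 2 * a_count
            ]
            if len(parents) < 2:
                continue
            found = False
            for split in range(1, len(a_seq)):
                left, right = a_seq[:split], a_seq[split:]
                lefts = [
                    p for p in parents if seqs[p].startswith(left)
                ]
                if not lefts:
                    continue
                rights = [
                    p for p in parents if seqs[p].endswith(right)
                ]
                if any(
                    p1 != p2 for p1 in lefts for p2 in rights
                ):
                    found = True
                    break
            if found:
                votes += 1
        if votes > len(present) / 2:
            chimera[asv] = True
    meta["chimera"] = chimera
    return ASVTable(counts, meta)


def load_contaminant_signatures(path: str | Path | None = None) -> list[str]:
    """Load the contaminant genus signature list (one genus per line).

    The packaged default lists genera widely reported as reagent/laboratory
    ("kitome") contaminants; it is an editable placeholder and should be
    replaced with a study-specific list for real analyses.
    """
    if path is None:
        src = resources.files("amplikit.data").joinpath(
            "contaminant_genera.tsv"
        )
        text = src.read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    return [
        line.strip()
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    ]


def _genus_of(lineage_or_genus: str) -> str | None:
    value = lineage_or_genus.strip()
    if not value:
        return None
    if ";" in value or "__" in value:
        parts = [p.strip() for p in value.split(";")]
        for p in parts:
            if p.startswith("g__"):
                return p[3:] or None
        if len(parts) >= 6 and parts[5]:
            p = parts[5]
            return p.split("__", 1)[-1] or None
        return None
    return value


def remove_contaminants(
    table: ASVTable,
    taxonomy: dict[str, str],
    signature_list: list[str] | None = None,
    negative_controls: list[str] | None = None,
) -> ASVTable:
    """Flag contaminant ASVs by genus signature and control prevalence.

    An ASV is flagged when its assigned genus is on the signature list, or
    when it occurs in the negative controls and its prevalence there is at
    least its prevalence in the true samples.  ASVs without a genus-rank
    assignment skip the signature rule (logged).
    """
    signature_list = signature_list or []
    negative_controls = negative_controls or []
    signatures = {g.lower() for g in signature_list}
    counts = table.counts
    true_samples = [c for c in counts.columns if c not in negative_controls]
    meta = table.meta.copy()
    contaminant = meta["contaminant"].copy()
    for asv in counts.index:
        genus = _genus_of(taxonomy.get(asv, ""))
        if genus is None:
            if signatures:
                logger.info("ASV %s has no genus assignment; signature rule "
                            "skipped", asv)
        elif genus.lower() in signatures:
            contaminant[asv] = True
            continue
        if negative_controls and true_samples:
            prev_ctrl = float(
                (counts.loc[asv, negative_controls] > 0).mean()
            )
            prev_true = float((counts.loc[asv, true_samples] > 0).mean())
            if prev_ctrl > 0 and prev_ctrl >= prev_true:
                contaminant[asv] = True
    meta["contaminant"] = contaminant
    return ASVTable(counts, meta)


def run_pipeline(
    samples: dict[str, tuple[list, list]],
    params: FilterParams = FilterParams(),
    alpha: float = 2.0,
    d_max: int = 2,
    min_abundance: int = 2,
    min_overlap: int = 12,
    max_overlap_mismatch: int = 0,
    host_index=None,
    host_theta: float = 0.5,
    taxonomy: dict[str, str] | None = None,
    signature_list: list[str] | None = None,
    negative_controls: list[str] | None = None,
) -> tuple[ASVTable, dict]:
    """Run reads -> ASV table for a set of samples.

    ``samples`` maps sample name to a (reads1, reads2) pair of lists of
    (title, sequence, quality).  Host subtraction runs first when a host
    index is given; contaminant flagging runs last when a taxonomy mapping
    is given.  Returns the ASV table and a per-sample summary dict.
    """
    from amplikit import host_filter as hf

    per_sample_counts: dict[str, dict[str, int]] = {}
    constructions: dict[str, str] = {}
    summary: dict[str, dict] = {}
    for name, (reads1, reads2) in samples.items():
        stage: dict = {"n_pairs_in": len(reads1)}
        if host_index is not None:
            reads1, reads2, host_summary = hf.subtract_host(
                reads1, reads2, host_index, host_theta
            )
            stage["host"] = host_summary.to_dict()
        reads1, reads2, filter_counts = filter_and_trim(reads1, reads2, params)
        stage["filter"] = filter_counts
        uniq1 = dereplicate(reads1)
        uniq2 = dereplicate(reads2)
        _, map1 = denoise(uniq1, alpha, d_max, min_abundance)
        _, map2 = denoise(uniq2, alpha, d_max, min_abundance)
        qual1 = {seq: q for seq, _, q in uniq1}
        qual2 = {seq: q for seq, _, q in uniq2}
        pair_counts: dict[tuple[str, str], int] = {}
        n_denoise_dropped = 0
        for (_, s1, _), (_, s2, _) in zip(reads1, reads2):
            if s1 not in map1 or s2 not in map2:
                n_denoise_dropped += 1
                continue
            key = (map1[s1], map2[s2])
            pair_counts[key] = pair_counts.get(key, 0) + 1
        stage["denoise_dropped"] = n_denoise_dropped
        sample_counts: dict[str, int] = {}
        for (c1, c2), n in sorted(pair_counts.items()):
            seq, construction = merge_or_concat(
                c1, c2, qual1.get(c1), qual2.get(c2),
                min_overlap, max_overlap_mismatch,
            )
            sample_counts[seq] = sample_counts.get(seq, 0) + n
            constructions.setdefault(seq, construction)
        per_sample_counts[name] = sample_counts
        stage["n_asv"] = len(sample_counts)
        summary[name] = stage

    all_seqs = sorted(
        {s for c in per_sample_counts.values() for s in c},
        key=lambda s: (-sum(c.get(s, 0) for c in per_sample_counts.values()), s),
    )
    asv_ids = [f"ASV{i + 1}" for i in range(len(all_seqs))]
    counts = pd.DataFrame(
        {
            name: [per_sample_counts[name].get(s, 0) for s in all_seqs]
            for name in samples
        },
        index=asv_ids,
    )
    meta = pd.DataFrame(
        {
            "sequence": all_seqs,
            "construction": [constructions[s] for s in all_seqs],
        },
        index=asv_ids,
    )
    table = ASVTable(counts, meta)
    table = remove_bimeras(table)
    if host_index is not None:
        host_flags = []
        for seq in table.sequences:
            segments = [s for s in _SPACER_RUN.split(seq) if s]
            host_flags.append(
                any(
                    hf.classify_sequence(s, host_index, host_theta)[0] == "host"
                    for s in segments
                )
            )
        table.meta["host"] = host_flags
    if taxonomy is not None:
        table = remove_contaminants(
            table, taxonomy, signature_list, negative_controls
        )
    return table, summary
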