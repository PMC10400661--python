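"""Ground-truthed paired-end amplicon library simulator.

Emulates a 2x150 paired-end short-read amplicon experiment on a bacterial
community mixed with host off-target amplicons: taxon references (with
SILVA-style lineages) are amplified in silico by a primer system, read pairs
are drawn from the resulting amplicons according to configured relative
abundances plus a host fraction, and i.i.d. substitution errors are planted
at a configurable per-base rate with Phred strings that encode the same
probabilities.  Every emitted pair carries a ground-truth record (origin,
source coordinates, planted error positions) so downstream host subtraction,
denoising and taxonomy stages can be scored exactly.

Toy reference builders plant concrete primer-binding loci in random
backbones, including the dropout configuration where a clade carries a
two-base mismatch under the forward primer's 3' terminus (amplifiable only
once a degenerate companion primer joins the mixture) and a host record with
near-match sites in convergent orientation (the mitochondrial off-target
situation).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from amplikit.insilico_pcr import AmpPolicy, predict_amplicons
from amplikit.primer_model import IUPAC_CODES, PrimerSet, revcomp

__all__ = [
    "TaxonSpec",
    "SimConfig",
    "TruthRecord",
    "simulate_library",
    "make_toy_references",
    "make_toy_host",
    "write_truth",
    "DROPOUT_LOCUS_V12",
]

# A concrete 16S forward-primer locus variant that carries exactly two
# mismatches inside the 3'-terminal 5-base window of the 68F binding region
# (so extension fails and the clade drops out of a V1-V2 survey) while the
# degenerate companion primer 68F_M binds it with a single tolerated
# 3'-window mismatch.  Mirrors the situation of Fusobacteriota under
# S-D-Bact-0049-a-S-21.
DROPOUT_LOCUS_V12 = "GTAACACATGCAAGTCGACTGGA"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class TaxonSpec:
    """One community member: reference sequence, lineage, abundance."""

    ref_id: str
    lineage: str
    sequence: str
    abundance: float


@dataclass
class SimConfig:
    """Simulation settings for one amplicon library.

    Abundances plus ``host_fraction`` must sum to 1.  ``error_rate`` is the
    per-base substitution probability; the emitted Phred strings encode the
    same per-base probability (flat by default, with an optional linear
    3'-quality drop of ``quality_drop`` Phred units to exercise
    expected-error filtering).
    """

    taxa: list[TaxonSpec]
    host_sequences: list[tuple[str, str]] = field(default_factory=list)
    host_fraction: float = 0.0
    n_pairs: int = 1000
    read_length: int = 150
    error_rate: float = 0.001
    quality_drop: int = 0
    seed: int = 0

    def validate(self) -> None:
        total = sum(t.abundance for t in self.taxa) + self.host_fraction
        if any(t.abundance < 0 for t in self.taxa) or self.host_fraction < 0:
            raise ValueError("abundances and host_fraction must be >= 0")
        if abs(total - 1.0) > 1e-6:
            raise ValueError(
                f"abundances + host_fraction must sum to 1 (got {total:.6f})"
            )
        if self.read_length < 50:
            raise ValueError("read_length must be >= 50")


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one emitted read pair."""

    read_id: str
    origin: str  # taxon ref_id or "host"
    target_id: str
    start: int
    end: int
    errors1: tuple[int, ...]
    errors2: tuple[int, ...]


def _quality_profile(length: int, error_rate: float, quality_drop: int):
    """Per-position Phred values and error probabilities."""
    if error_rate <= 0:
        q0 = 40.0
    else:
        q0 = -10.0 * np.log10(error_rate)
    qs = q0 - quality_drop * np.linspace(0.0, 1.0, num=length)
    qs = np.clip(np.round(qs), 2, 40).astype(int)
    if error_rate <= 0:
        probs = np.zeros(length)
    else:
        # substitution probabilities follow the (rounded) Phred values, so
        # the quality strings and the planted error process agree exactly
        probs = 10.0 ** (-qs / 10.0)
    qual = "".join(chr(33 + q) for q in qs)
    return qual, probs


def simulate_library(
    primer_set: PrimerSet,
    config: SimConfig,
    policy: AmpPolicy = AmpPolicy(),
) -> tuple[list[tuple[str, str, str]], list[tuple[str, str, str]], list[TruthRecord]]:
    """Simulate a paired-end amplicon library with ground truth.

    Read 1 is the first ``read_length`` bases of the amplicon top strand,
    read 2 the first ``read_length`` bases of the bottom strand.  Returns
    ``(reads1, reads2, truth)`` with reads as (title, sequence, quality).
    Deterministic given ``config.seed``.  A taxon whose reference yields no
    amplicon under the primer system is rejected by name.
    """
    config.validate()
    categories: list[tuple[str, str, int, int, str]] = []
    probs: list[float] = []
    for taxon in config.taxa:
        amps = predict_amplicons(
            primer_set, taxon.sequence, policy, target_id=taxon.ref_id
        )
        if not amps:
            raise ValueError(
                f"taxon {taxon.ref_id!r} yields no amplicon under "
                f"{primer_set.name}"
            )
        amp = amps[0]
        seq = taxon.sequence[amp.fwd_site.start : amp.rev_site.end]
        categories.append(
            (taxon.ref_id, taxon.ref_id, amp.fwd_site.start, amp.rev_site.end, seq)
        )
        probs.append(taxon.abundance)
    if config.host_fraction > 0:
        host_amps = []
        for rec_id, seq in config.host_sequences:
            for amp in predict_amplicons(primer_set, seq, policy, target_id=rec_id):
                host_amps.append(
                    ("host", rec_id, amp.fwd_site.start, amp.rev_site.end,
                     seq[amp.fwd_site.start : amp.rev_site.end])
                )
        if not host_amps:
            raise ValueError(
                "host_fraction > 0 but no host off-target amplicon predicted"
            )
        for cat in host_amps:
            categories.append(cat)
            probs.append(config.host_fraction / len(host_amps))

    p = np.asarray(probs, dtype=float)
    p = p / p.sum()
    rng_origin = np.random.default_rng([config.seed, 101])
    rng_err = np.random.default_rng([config.seed, 202])
    origins = rng_origin.choice(len(categories), size=config.n_pairs, p=p)

    L = config.read_length
    reads1: list[tuple[str, str, str] | None] = [None] * config.n_pairs
    reads2: list[tuple[str, str, str] | None] = [None] * config.n_pairs
    truth: list[TruthRecord | None] = [None] * config.n_pairs

    # Pre-compute per-category read templates and quality strings.
    templates = []
    for origin, target_id, start, end, amp_seq in categories:
        t1 = amp_seq[:L]
        t2 = revcomp(amp_seq)[:L]
        q1, p1 = _quality_profile(len(t1), config.error_rate, config.quality_drop)
        q2, p2 = _quality_profile(len(t2), config.error_rate, config.quality_drop)
        templates.append((t1, t2, q1, q2, p1, p2))

    for cat_idx in range(len(categories)):
        pair_idx = np.nonzero(origins == cat_idx)[0]
        if pair_idx.size == 0:
            continue
        origin, target_id, start, end, _ = categories[cat_idx]
        t1, t2, q1, q2, p1, p2 = templates[cat_idx]
        mates = []
        for template, pvec in ((t1, p1), (t2, p2)):
            arr = np.tile(
                np.frombuffer(template.encode(), dtype=np.uint8),
                (pair_idx.size, 1),
            )
            if config.error_rate > 0:
                mask = rng_err.random(arr.shape) < pvec[None, :]
                if mask.any():
                    # substitute with one of the three other bases
                    base_idx = np.searchsorted(_BASES, arr[mask])
                    shift = rng_err.integers(1, 4, size=int(mask.sum()))
                    arr[mask] = _BASES[(base_idx + shift) % 4]
            else:
                mask = np.zeros(arr.shape, dtype=bool)
            mates.append((arr, mask))
        (a1, m1), (a2, m2) = mates
        for row, i in enumerate(pair_idx):
            rid = f"sim_{i}"
            e1 = tuple(int(x) for x in np.nonzero(m1[row])[0])
            e2 = tuple(int(x) for x in np.nonzero(m2[row])[0])
            reads1[i] = (f"{rid}/1", a1[row].tobytes().decode(), q1)
            reads2[i] = (f"{rid}/2", a2[row].tobytes().decode(), q2)
            truth[i] = TruthRecord(rid, origin, target_id, start, end, e1, e2)
    return list(reads1), list(reads2), list(truth)  # type: ignore[arg-type]


def write_truth(path: str | Path, truth: list[TruthRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\torigin\ttarget_id\tstart\tend\terrors1\terrors2\n")
        for t in truth:
            fh.write(
                f"{t.read_id}\t{t.origin}\t{t.target_id}\t{t.start}\t{t.end}\t"
                f"{','.join(map(str, t.errors1))}\t"
                f"{','.join(map(str, t.errors2))}\n"
            )


def _first_expansion(iupac: str) -> str:
    """Deterministic concrete expansion (lexicographically first base)."""
    return "".join(sorted(IUPAC_CODES[c])[0] for c in iupac)


def _random_dna(rng, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _plant(backbone: np.ndarray, pos: int, segment: str) -> None:
    backbone[pos : pos + len(segment)] = np.frombuffer(
        segment.encode(), dtype=np.uint8
    )


def make_toy_references(
    primer_set: PrimerSet,
    n_taxa: int = 10,
    length: int = 600,
    divergence: float = 0.1,
    seed: int = 0,
    amplicon_length: int | None = None,
    dropout_taxa: tuple[int, ...] = (),
    forward_3prime_mismatches: dict[int, int] | None = None,
) -> list[tuple[str, str, str]]:
    """Random reference sequences with planted primer-binding loci.

    Each taxon is a mutated copy (per-base substitution probability
    ``divergence``) of a common random backbone with exact forward/reverse
    binding loci planted so the primer system amplifies a product of
    ``amplicon_length`` (default 253 bp for a V4-targeting system — read
    pairs overlap — else 290 bp, forcing the concatenation path at 2x150).

    ``dropout_taxa`` plant the two-base 3'-mismatch locus variant
    (:data:`DROPOUT_LOCUS_V12`) instead of the exact forward locus, so those
    taxa fail with the base system but amplify once the companion primer is
    in the mixture.  ``forward_3prime_mismatches`` maps taxon index to a
    number of arbitrary incompatible substitutions planted inside the
    forward 3' window (amplification then fails for every system sharing
    that forward primer).  Returns ``(id, lineage, sequence)`` records.
    """
    if not 0 <= divergence < 1:
        raise ValueError("divergence must be in [0, 1)")
    forward_3prime_mismatches = forward_3prime_mismatches or {}
    if amplicon_length is None:
        amplicon_length = 253 if primer_set.target_region == "V4" else 290
    fwd_region = primer_set.forward[0].binding_region
    rev_region = primer_set.reverse.binding_region
    fwd_locus = _first_expansion(fwd_region)
    rev_locus = revcomp(_first_expansion(rev_region))
    pos_f = 50
    pos_r = pos_f + amplicon_length - len(rev_locus)
    if pos_r <= pos_f + len(fwd_locus) + len(DROPOUT_LOCUS_V12):
        raise ValueError("amplicon_length too short for the primer loci")
    if length < pos_f + amplicon_length + 50:
        raise ValueError("reference length too short for the amplicon span")

    rng = np.random.default_rng([seed, 303])
    backbone = _random_dna(rng, length)
    refs = []
    w = 5
    for i in range(n_taxa):
        seq = backbone.copy()
        if divergence > 0:
            mask = rng.random(length) < divergence
            shift = rng.integers(1, 4, size=int(mask.sum()))
            base_idx = np.searchsorted(_BASES, seq[mask])
            seq[mask] = _BASES[(base_idx + shift) % 4]
        # plant loci after mutation so they stay exact
        if i in dropout_taxa:
            _plant(seq, pos_f, DROPOUT_LOCUS_V12)
        else:
            _plant(seq, pos_f, fwd_locus)
        _plant(seq, pos_r, rev_locus)
        if i in forward_3prime_mismatches:
            n_mm = forward_3prime_mismatches[i]
            # mutate the last n_mm positions of the forward 3' window to
            # bases incompatible with the primer code there
            for offset in range(len(fwd_region) - 1,
                                len(fwd_region) - 1 - n_mm, -1):
                allowed = IUPAC_CODES[fwd_region[offset]]
                bad = sorted(set("ACGT") - set(allowed))[0]
                seq[pos_f + offset] = ord(bad)
        lineage = (
            f"d__Bacteria;p__Phylum{i};c__Class{i};o__Order{i};"
            f"f__Family{i};g__Genus{i};s__species{i}"
        )
        refs.append((f"taxon{i}", lineage, seq.tobytes().decode()))
    return refs


def make_toy_host(
    primer_set: PrimerSet,
    length: int | None = None,
    seed: int = 0,
    amplicon_length: int = 260,
    fwd_mismatches: int = 2,
    rev_mismatches: int = 2,
    n_loci: int = 1,
) -> tuple[str, str]:
    """A synthetic host record with near-match off-target primer sites.

    Plants ``n_loci`` copies of the primer system's forward/reverse loci in
    convergent orientation with the requested number of mismatches placed
    OUTSIDE the 3' windows, emulating host (mitochondrion-like) loci that
    amplify off-target.  Multiple loci model the sequence diversity of host
    off-target products (each locus yields a distinct amplicon).  Returns
    ``(record_id, sequence)``.
    """
    spacing = amplicon_length + 150
    if length is None:
        length = 400 + n_loci * spacing
    if length < 400 + n_loci * spacing:
        raise ValueError("host length too short for the requested loci")
    rng = np.random.default_rng([seed, 404])
    seq = _random_dna(rng, length)
    fwd_locus = list(_first_expansion(primer_set.forward[0].binding_region))
    rev_locus_primer = list(_first_expansion(primer_set.reverse.binding_region))
    for locus, region, n_mm in (
        (fwd_locus, primer_set.forward[0].binding_region, fwd_mismatches),
        (rev_locus_primer, primer_set.reverse.binding_region, rev_mismatches),
    ):
        for offset in range(n_mm):  # 5'-proximal positions, far from 3' end
            allowed = IUPAC_CODES[region[offset]]
            locus[offset] = sorted(set("ACGT") - set(allowed))[0]
    for i in range(n_loci):
        pos_f = 200 + i * spacing
        pos_r = pos_f + amplicon_length - len(rev_locus_primer)
        _plant(seq, pos_f, "".join(fwd_locus))
        _plant(seq, pos_r, revcomp("".join(rev_locus_primer)))
    return ("host_mt_synthetic", seq.tobytes().decode())


def config_from_json(path: str | Path) -> dict:
    """Load a simulation config mapping from JSON (CLI helper)."""
    with open(path) as fh:
        return json.load(fh)
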