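"""Degenerate-oligo data model and the built-in amplicon primer registry.

One-step Illumina 16S amplicon oligos are composites: a flow-cell adaptor
(including the index region), a pad that doubles as part of the custom
sequencing-primer site, and a 3'-terminal binding region that anneals to the
16S rRNA gene.  This module models such oligos over the IUPAC alphabet,
provides the IUPAC algebra (expansion, reverse complement, compatibility),
and ships a registry of three primer systems:

``V4``
    515F/806R targeting the V4 hypervariable region.
``V1-V2``
    68F/338R targeting V1-V2, designed for short-amplicon 2x150 sequencing.
``V1-V2M``
    The V1-V2 system plus the extra degenerate forward primer 68F_M, mixed
    with 68F to rescue taxa (notably Fusobacteriota) that carry a two-base
    mismatch under the 3' terminus of 68F.

Internal-consistency validation checks the structural identities a correctly
transcribed system must satisfy: Index1 = revcomp(Read2) and
Index2 = revcomp(Read1), and the sequencing primers being (degenerate-subset)
compatible with the amplification oligos they read from.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

__all__ = [
    "IUPAC_CODES",
    "IUPAC_COMPLEMENT",
    "Oligo",
    "PrimerSet",
    "ValidationFinding",
    "ValidationReport",
    "expand_degenerate",
    "revcomp",
    "degeneracy",
    "codes_compatible",
    "compare_degenerate",
    "load_registry",
    "load_primer_table",
    "validate_set",
]

# IUPAC nucleotide codes -> the set of concrete bases each denotes.
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

IUPAC_COMPLEMENT: dict[str, str] = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W",
    "K": "M", "M": "K", "B": "V", "V": "B",
    "D": "H", "H": "D", "N": "N",
}

# 3'-terminal binding regions used to decompose the full Table-style oligos;
# each is the published reference primer the composite oligo is built on.
_BINDING_REGIONS: dict[str, str] = {
    "515F": "GTGYCAGCMGCCGCGGTAA",
    "806R": "GGACTACNVGGGTWTCTAAT",
    "68F": "GTNANACATGCAAGTCGRRSG",
    "68F_M": "GTAACACATGCAAGTCRACTYGA",
    "338R": "AGCTGCCTCCCGTAGGAGT",
}


def _clean(sequence: str) -> str:
    """Uppercase and map U->T (rRNA gene context)."""
    return sequence.strip().upper().replace("U", "T")


def _check_iupac(sequence: str) -> None:
    for i, ch in enumerate(sequence):
        if ch not in IUPAC_CODES:
            raise ValueError(
                f"non-IUPAC character {ch!r} at position {i} in {sequence!r}"
            )


def expand_degenerate(sequence: str) -> set[str]:
    """Expand an IUPAC string into the set of concrete A/C/G/T sequences.

    The cardinality of the result is the product of the per-position code
    sizes.  Raises ``ValueError`` naming the offending position for any
    non-IUPAC character.

    >>> sorted(expand_degenerate("R"))
    ['A', 'G']
    """
    seq = _clean(sequence)
    _check_iupac(seq)
    pools = [sorted(IUPAC_CODES[ch]) for ch in seq]
    return {"".join(p) for p in itertools.product(*pools)}


def degeneracy(sequence: str) -> int:
    """Product of per-position IUPAC code cardinalities."""
    seq = _clean(sequence)
    _check_iupac(seq)
    n = 1
    for ch in seq:
        n *= len(IUPAC_CODES[ch])
    return n


def revcomp(sequence: str) -> str:
    """Reverse complement of an IUPAC string (degenerate codes included)."""
    seq = _clean(sequence)
    _check_iupac(seq)
    return "".join(IUPAC_COMPLEMENT[ch] for ch in reversed(seq))


def codes_compatible(a: str, b: str) -> bool:
    """True if two IUPAC codes share at least one concrete base."""
    return bool(IUPAC_CODES[a] & IUPAC_CODES[b])


def compare_degenerate(a: str, b: str) -> list[tuple[int, str]]:
    """Position-wise comparison of two equal-length IUPAC strings.

    Returns ``(position, status)`` per position with status one of
    ``exact`` (identical code), ``compatible-subset`` (one code's base set
    contains the other's), ``overlap`` (sets intersect but neither contains
    the other) or ``mismatch`` (disjoint sets).
    """
    a, b = _clean(a), _clean(b)
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    _check_iupac(a)
    _check_iupac(b)
    out = []
    for i, (x, y) in enumerate(zip(a, b)):
        sx, sy = IUPAC_CODES[x], IUPAC_CODES[y]
        if x == y:
            status = "exact"
        elif sx <= sy or sy <= sx:
            status = "compatible-subset"
        elif sx & sy:
            status = "overlap"
        else:
            status = "mismatch"
        out.append((i, status))
    return out


@dataclass(frozen=True)
class Oligo:
    """A (possibly degenerate) oligo with its structural segmentation.

    ``segments`` is an ordered list of ``(role, (start, end))`` with role in
    {flowcell_adaptor, pad, binding_region} using 0-based half-open spans;
    spans are contiguous, cover the sequence, and exactly one binding_region
    segment sits at the 3' end.  Plain primers (no adaptor structure) carry a
    single binding_region segment spanning the whole sequence.
    """

    name: str
    sequence: str
    segments: tuple[tuple[str, tuple[int, int]], ...] = ()
    concentration: float | None = None  # µmol/L, metadata

    def __post_init__(self) -> None:
        seq = _clean(self.sequence)
        object.__setattr__(self, "sequence", seq)
        _check_iupac(seq)
        segs = tuple(self.segments) or (("binding_region", (0, len(seq))),)
        object.__setattr__(self, "segments", segs)
        pos = 0
        for role, (start, end) in segs:
            if role not in {"flowcell_adaptor", "pad", "binding_region"}:
                raise ValueError(f"unknown segment role {role!r}")
            if start != pos or end <= start:
                raise ValueError(f"segments of {self.name} are not contiguous")
            pos = end
        if pos != len(seq):
            raise ValueError(f"segments of {self.name} do not cover the sequence")
        binding = [s for s in segs if s[0] == "binding_region"]
        if len(binding) != 1 or segs[-1][0] != "binding_region":
            raise ValueError(
                f"{self.name}: exactly one 3'-terminal binding_region required"
            )

    @property
    def binding_region(self) -> str:
        (start, end) = next(s for r, s in self.segments if r == "binding_region")
        return self.sequence[start:end]

    @property
    def tail(self) -> str:
        """Everything 5' of the binding region (adaptor + pad)."""
        (start, _) = next(s for r, s in self.segments if r == "binding_region")
        return self.sequence[:start]

    def segment(self, role: str) -> str | None:
        for r, (start, end) in self.segments:
            if r == role:
                return self.sequence[start:end]
        return None


@dataclass(frozen=True)
class PrimerSet:
    """A complete amplification + sequencing primer system."""

    name: str
    forward: tuple[Oligo, ...]
    reverse: Oligo
    read1: str
    read2: str
    index1: str
    index2: str
    target_region: str

    def __post_init__(self) -> None:
        if not self.forward:
            raise ValueError("at least one forward oligo required")
        for attr in ("read1", "read2", "index1", "index2"):
            seq = _clean(getattr(self, attr))
            _check_iupac(seq)
            object.__setattr__(self, attr, seq)


@dataclass
class ValidationFinding:
    check: str
    status: str  # "pass" | "compatible-subset" | "fail"
    detail: str = ""


@dataclass
class ValidationReport:
    set_name: str
    findings: list[ValidationFinding] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return all(f.status != "fail" for f in self.findings)

    def to_dict(self) -> dict:
        return {
            "set": self.set_name,
            "ok": self.ok,
            "findings": [
                {"check": f.check, "status": f.status, "detail": f.detail}
                for f in self.findings
            ],
        }


def _anchor_segments(name: str, sequence: str, read_primer: str | None) -> tuple:
    """Decompose a full oligo into adaptor/pad/binding spans.

    The binding region is the known 3'-terminal reference-primer substring;
    the pad is the longest suffix of the remainder matching a prefix of the
    corresponding sequencing primer (at most one incompatible position is
    tolerated, covering the printed pad variant of 806R); the rest is the
    flow-cell adaptor.
    """
    binding = _BINDING_REGIONS.get(name)
    if binding is None or not sequence.endswith(binding):
        # Unknown oligo: treat the whole sequence as binding region.
        return (("binding_region", (0, len(sequence))),)
    b_start = len(sequence) - len(binding)
    pad_len = 0
    if read_primer:
        remainder = sequence[:b_start]
        for length in range(min(len(remainder), len(read_primer)), 0, -1):
            suffix = remainder[-length:]
            prefix = read_primer[:length]
            bad = sum(
                1 for x, y in zip(suffix, prefix) if not codes_compatible(x, y)
            )
            if bad <= 1:
                pad_len = length
                break
    segs = []
    if b_start - pad_len > 0:
        segs.append(("flowcell_adaptor", (0, b_start - pad_len)))
    if pad_len > 0:
        segs.append(("pad", (b_start - pad_len, b_start)))
    segs.append(("binding_region", (b_start, len(sequence))))
    return tuple(segs)


def load_primer_table(path: str | Path | None = None) -> list[dict]:
    """Read a primer TSV (region/name/conc_umol_per_L/sequence/role)."""
    if path is None:
        src = resources.files("amplikit.data").joinpath("primers_table.tsv")
        text = src.read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    rows = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 5:
            raise ValueError(f"malformed primer TSV row: {line!r}")
        region, name, conc, sequence, role = parts
        rows.append(
            {
                "region": region,
                "name": name,
                "conc_umol_per_L": None if conc in {"NA", ""} else float(conc),
                "sequence": _clean(sequence),
                "role": role,
            }
        )
    return rows


def _build_set(name: str, target: str, rows: Iterable[dict]) -> PrimerSet:
    by_role: dict[str, list[dict]] = {}
    for r in rows:
        by_role.setdefault(r["role"], []).append(r)
    read1 = by_role["read1"][0]["sequence"]
    read2 = by_role["read2"][0]["sequence"]
    forward = tuple(
        Oligo(
            r["name"],
            r["sequence"],
            _anchor_segments(r["name"], r["sequence"], read1),
            r["conc_umol_per_L"],
        )
        for r in by_role["forward"]
    )
    rev_row = by_role["reverse"][0]
    reverse = Oligo(
        rev_row["name"],
        rev_row["sequence"],
        _anchor_segments(rev_row["name"], rev_row["sequence"], read2),
        rev_row["conc_umol_per_L"],
    )
    return PrimerSet(
        name=name,
        forward=forward,
        reverse=reverse,
        read1=read1,
        read2=read2,
        index1=by_role["index1"][0]["sequence"],
        index2=by_role["index2"][0]["sequence"],
        target_region=target,
    )


def load_registry(path: str | Path | None = None) -> dict[str, PrimerSet]:
    """Build the three built-in primer systems (or from a user TSV).

    Returns a mapping with keys ``V4``, ``V1-V2`` and ``V1-V2M``; the last is
    the V1-V2 system with the 68F_M forward oligo added to the mixture.
    """
    rows = load_primer_table(path)
    by_region: dict[str, list[dict]] = {}
    for r in rows:
        by_region.setdefault(r["region"], []).append(r)
    registry: dict[str, PrimerSet] = {}
    if "V4" in by_region:
        registry["V4"] = _build_set("V4", "V4", by_region["V4"])
    if "V1-V2" in by_region:
        registry["V1-V2"] = _build_set("V1-V2", "V1-V2", by_region["V1-V2"])
        extra = by_region.get("V1-V2M", [])
        registry["V1-V2M"] = _build_set(
            "V1-V2M", "V1-V2", by_region["V1-V2"] + extra
        )
    return registry


def _compare_report(
    report: ValidationReport, check: str, observed: str, expected: str
) -> None:
    if len(observed) != len(expected):
        report.findings.append(
            ValidationFinding(
                check, "fail", f"length {len(observed)} != {len(expected)}"
            )
        )
        return
    statuses = compare_degenerate(observed, expected)
    bad = [(i, s) for i, s in statuses if s in {"mismatch", "overlap"}]
    subset = [i for i, s in statuses if s == "compatible-subset"]
    if bad:
        report.findings.append(
            ValidationFinding(
                check, "fail", f"incompatible positions {[i for i, _ in bad]}"
            )
        )
    elif subset:
        report.findings.append(
            ValidationFinding(
                check, "compatible-subset", f"subset positions {subset}"
            )
        )
    else:
        report.findings.append(ValidationFinding(check, "pass"))


def validate_set(primer_set: PrimerSet) -> ValidationReport:
    """Internal-consistency validation of a primer system.

    Checks the two index identities (index1 = revcomp(read2), index2 =
    revcomp(read1)) and that each sequencing primer is degenerate-compatible
    with the amplification oligo region it reads from.  A position where one
    code's base set is a subset of the other's is reported as
    ``compatible-subset``, not failure.
    """
    report = ValidationReport(primer_set.name)
    _compare_report(
        report, "index1 == revcomp(read2)", primer_set.index1,
        revcomp(primer_set.read2),
    )
    _compare_report(
        report, "index2 == revcomp(read1)", primer_set.index2,
        revcomp(primer_set.read1),
    )
    # Sequencing primers must align to the pad+binding structure of the
    # amplification oligos: read1 against a forward oligo, read2 against the
    # reverse oligo.
    for oligo, read, label in (
        (primer_set.forward[0], primer_set.read1, "read1 ~ forward oligo"),
        (primer_set.reverse, primer_set.read2, "read2 ~ reverse oligo"),
    ):
        pad = oligo.segment("pad") or ""
        window = (pad + oligo.binding_region)[: len(read)]
        if len(window) < len(read):
            report.findings.append(
                ValidationFinding(label, "fail", "oligo shorter than read primer")
            )
            continue
        statuses = compare_degenerate(read, window)
        # The pad portion may differ between the printed amplification oligo
        # and the sequencing primer (a known pad variant); only the
        # binding-region portion must be degenerate-compatible.
        pad_diffs = [i for i, s in statuses if i < len(pad) and s != "exact"]
        bind = [(i, s) for i, s in statuses if i >= len(pad)]
        bad = [i for i, s in bind if s == "mismatch"]
        nonexact = [i for i, s in bind if s != "exact"]
        if bad:
            report.findings.append(
                ValidationFinding(label, "fail", f"incompatible positions {bad}")
            )
        elif nonexact:
            report.findings.append(
                ValidationFinding(
                    label, "compatible-subset", f"non-exact positions {nonexact}"
                )
            )
        else:
            report.findings.append(ValidationFinding(label, "pass"))
        if pad_diffs:
            report.findings.append(
                ValidationFinding(
                    f"{label} (pad)", "pad-variant",
                    f"pad positions {pad_diffs} differ from the printed oligo",
                )
            )
    return report
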