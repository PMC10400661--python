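"""IUPAC-aware in-silico PCR: primer-binding search and amplicon prediction.

Primer annealing is modelled positionally (ungapped): a primer placement on a
target is scored by its per-position mismatch profile, where a position
matches iff the primer code's base set intersects the target code's base set
(reference databases occasionally contain ambiguity codes).  Amplification
uses a binary 3'-terminal policy: a binding site supports extension only if
it carries fewer than ``max_mismatch_3prime`` mismatches within the
3'-terminal window of ``w`` bases.  This is the mechanism behind
primer-system taxon dropout — a two-base mismatch under a forward primer's
3' end silently removes whole clades from an amplicon survey — and behind
off-target amplification of host (e.g. mitochondrial) DNA by near-matching
sites in convergent orientation.

Coordinates are 0-based half-open on the + strand throughout; reverse-primer
sites are stored by their + strand footprint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from amplikit.primer_model import (
    IUPAC_CODES,
    Oligo,
    PrimerSet,
    codes_compatible,
    degeneracy,
    revcomp,
)

__all__ = [
    "AmpPolicy",
    "BindingSite",
    "Amplicon",
    "TaxonCoverageReport",
    "find_binding_sites",
    "predict_amplicons",
    "off_target_screen",
    "render_alignment",
    "taxon_coverage",
    "suggest_rescue_primer",
]


@dataclass(frozen=True)
class AmpPolicy:
    """Amplification policy for in-silico PCR.

    ``max_mismatch_total``: most mismatches tolerated anywhere in a binding
    site for it to be considered at all.  ``max_mismatch_3prime``: a site
    supports extension only if its 3'-window mismatch count is strictly
    below this (default 2: amplification fails with >= 2 mismatches in the
    last ``w`` bases).  ``w``: 3'-terminal window length (default 5).
    ``min_length``/``max_length``: product-length bounds in bp (16S span).
    """

    max_mismatch_total: int = 3
    max_mismatch_3prime: int = 2
    w: int = 5
    min_length: int = 50
    max_length: int = 2000


@dataclass(frozen=True)
class BindingSite:
    """An ungapped primer placement on a target sequence."""

    target_id: str
    primer_name: str
    strand: str  # "+" or "-"
    start: int
    end: int
    mismatch_positions: tuple[int, ...]  # offsets from the primer 5' end
    n_mismatch_total: int
    n_mismatch_3prime: int

    def extends(self, policy: AmpPolicy) -> bool:
        return self.n_mismatch_3prime < policy.max_mismatch_3prime


@dataclass(frozen=True)
class Amplicon:
    """A predicted PCR product (forward site on +, reverse site on -)."""

    target_id: str
    fwd_site: BindingSite
    rev_site: BindingSite
    insert_span: tuple[int, int]  # between the two primer footprints
    length_16s: int  # fwd_site.start -> rev_site.end
    length_library: int  # length_16s + non-binding tails of both oligos


@dataclass
class TaxonCoverageReport:
    """Per-taxon amplification coverage at a taxonomic rank."""

    rank: str
    taxa: dict[str, dict] = field(default_factory=dict)
    # per failing reference: best available forward/reverse site profiles
    failing: dict[str, dict] = field(default_factory=dict)

    def coverage(self, taxon: str) -> float:
        return self.taxa[taxon]["coverage_fraction"]


def find_binding_sites(
    binding_region: str,
    target: str,
    max_mismatch: int = 0,
    w: int | None = None,
    target_id: str = "",
    primer_name: str = "",
) -> list[BindingSite]:
    """All ungapped placements of a degenerate primer on both strands.

    Returns sites with at most ``max_mismatch`` total mismatches, sorted by
    (n_mismatch_total, start).  Mismatch offsets are counted from the primer
    5' end; the 3' window is the last ``w`` primer positions (default 5,
    clipped to the primer length when left unspecified).
    """
    primer = binding_region.strip().upper().replace("U", "T")
    target = target.strip().upper().replace("U", "T")
    if not primer or not target or len(target) < len(primer):
        return []
    L = len(primer)
    if w is None:
        w = min(5, L)
    if not 1 <= w <= L:
        raise ValueError(f"3' window w={w} must be in [1, {L}]")
    sites: list[BindingSite] = []
    # Primer code base sets for + strand comparison and (reverse-complement)
    # for the - strand footprint; target codes resolved per position.
    fwd_sets = [IUPAC_CODES[c] for c in primer]
    rc = revcomp(primer)
    rc_sets = [IUPAC_CODES[c] for c in rc]
    three_prime_cut = L - w
    for i in range(len(target) - L + 1):
        window = target[i : i + L]
        # + strand: primer offset j aligns to window[j]
        mm = []
        for j in range(L):
            t = IUPAC_CODES.get(window[j])
            if t is None or not (fwd_sets[j] & t):
                mm.append(j)
                if len(mm) > max_mismatch:
                    break
        if len(mm) <= max_mismatch:
            n3 = sum(1 for j in mm if j >= three_prime_cut)
            sites.append(
                BindingSite(target_id, primer_name, "+", i, i + L,
                            tuple(mm), len(mm), n3)
            )
        # - strand: revcomp(primer)[m] aligns to window[m]; primer offset
        # j corresponds to window index L-1-j.
        mm = []
        for m in range(L):
            t = IUPAC_CODES.get(window[m])
            if t is None or not (rc_sets[m] & t):
                mm.append(L - 1 - m)
                if len(mm) > max_mismatch:
                    break
        if len(mm) <= max_mismatch:
            mm = sorted(mm)
            n3 = sum(1 for j in mm if j >= three_prime_cut)
            sites.append(
                BindingSite(target_id, primer_name, "-", i, i + L,
                            tuple(mm), len(mm), n3)
            )
    sites.sort(key=lambda s: (s.n_mismatch_total, s.start, s.strand))
    return sites


def predict_amplicons(
    primer_set: PrimerSet,
    target: str,
    policy: AmpPolicy = AmpPolicy(),
    target_id: str = "",
) -> list[Amplicon]:
    """Predict PCR products of a primer system on one target sequence.

    Forward sites (any mixture member suffices) on the + strand are paired
    with reverse sites on the - strand in convergent, non-overlapping
    orientation; both sites must pass the 3'-window extension policy and the
    product length must fall within the policy bounds.
    """
    fwd_sites = []
    for oligo in primer_set.forward:
        fwd_sites.extend(
            s
            for s in find_binding_sites(
                oligo.binding_region, target, policy.max_mismatch_total,
                policy.w, target_id, oligo.name,
            )
            if s.strand == "+" and s.extends(policy)
        )
    rev_sites = [
        s
        for s in find_binding_sites(
            primer_set.reverse.binding_region, target,
            policy.max_mismatch_total, policy.w, target_id,
            primer_set.reverse.name,
        )
        if s.strand == "-" and s.extends(policy)
    ]
    fwd_tails = {o.name: len(o.tail) for o in primer_set.forward}
    rev_tail = len(primer_set.reverse.tail)
    out = []
    for f in fwd_sites:
        for r in rev_sites:
            if f.end > r.start:
                continue  # overlapping or divergent primer footprints
            length = r.end - f.start
            if not policy.min_length <= length <= policy.max_length:
                continue
            out.append(
                Amplicon(
                    target_id=target_id,
                    fwd_site=f,
                    rev_site=r,
                    insert_span=(f.end, r.start),
                    length_16s=length,
                    length_library=length + fwd_tails[f.primer_name] + rev_tail,
                )
            )
    out.sort(key=lambda a: (a.fwd_site.start, a.rev_site.end))
    return out


def render_alignment(primer: str, target: str, site: BindingSite) -> str:
    """Human-readable primer-vs-target alignment block for one site.

    ``|`` marks an exact base match, ``:`` a degenerate-compatible position
    and a space a mismatch; the target line carries + strand coordinates.
    """
    window = target[site.start : site.end]
    if site.strand == "-":
        shown_primer = primer
        shown_target = revcomp(window)
    else:
        shown_primer = primer
        shown_target = window
    bars = []
    for p, t in zip(shown_primer, shown_target):
        if p == t:
            bars.append("|")
        elif t in IUPAC_CODES and codes_compatible(p, t):
            bars.append(":")
        else:
            bars.append(" ")
    name = site.primer_name or "primer"
    coords = f"{site.target_id}:{site.start}-{site.end}({site.strand})"
    pad = max(len(name), len("target"))
    return (
        f"{name:>{pad}} 5'-{shown_primer}-3'\n"
        f"{'':>{pad}}    {''.join(bars)}\n"
        f"{'target':>{pad}}    {shown_target}    {coords}"
    )


def off_target_screen(
    primer_set: PrimerSet,
    host_records: list[tuple[str, str]],
    policy: AmpPolicy = AmpPolicy(),
) -> tuple[list[Amplicon], str]:
    """Screen host sequences for off-target products of a primer system.

    Returns the predicted amplicons and a text report with an alignment
    block for each primer site involved.
    """
    amplicons: list[Amplicon] = []
    blocks: list[str] = []
    oligos = {o.name: o for o in primer_set.forward}
    oligos[primer_set.reverse.name] = primer_set.reverse
    for rec_id, seq in host_records:
        for amp in predict_amplicons(primer_set, seq, policy, target_id=rec_id):
            amplicons.append(amp)
            blocks.append(
                f"off-target product {rec_id}:{amp.fwd_site.start}-"
                f"{amp.rev_site.end} ({amp.length_16s} bp)"
            )
            for site in (amp.fwd_site, amp.rev_site):
                blocks.append(
                    render_alignment(
                        oligos[site.primer_name].binding_region, seq, site
                    )
                )
    if not amplicons:
        blocks.append(f"no off-target amplicons predicted for {primer_set.name}")
    return amplicons, "\n\n".join(blocks)


def _best_site(
    primer: Oligo, target: str, w: int, max_mismatch: int | None = None
) -> BindingSite | None:
    """Best available placement (fewest total, then fewest 3' mismatches)."""
    if max_mismatch is None:
        max_mismatch = max(3, len(primer.binding_region) // 3)
    sites = find_binding_sites(
        primer.binding_region, target, max_mismatch, w, primer_name=primer.name
    )
    if not sites:
        return None
    return min(sites, key=lambda s: (s.n_mismatch_total, s.n_mismatch_3prime))


def taxon_coverage(
    primer_set: PrimerSet,
    refs: list[tuple[str, str, str]],
    policy: AmpPolicy = AmpPolicy(),
    rank: int | str = "phylum",
) -> TaxonCoverageReport:
    """Fraction of reference sequences amplified per taxon at a rank.

    ``refs`` is a list of ``(id, lineage, sequence)`` with semicolon-separated
    lineages; ``rank`` is a rank name (domain/phylum/class/order/family/
    genus/species) or a 0-based lineage index.  References whose lineage
    cannot be parsed at the rank are counted under ``unclassified``.
    Failing references carry the best-available mismatch profile of each
    primer so the dropout mechanism (e.g. a two-base 3' mismatch) is visible.
    """
    rank_names = ["domain", "phylum", "class", "order", "family", "genus",
                  "species"]
    idx = rank_names.index(rank) if isinstance(rank, str) else int(rank)
    report = TaxonCoverageReport(rank=str(rank))
    for ref_id, lineage, seq in refs:
        parts = [p.strip() for p in lineage.split(";")] if lineage else []
        parts = [p.split("__", 1)[1] if "__" in p else p for p in parts]
        taxon = parts[idx] if idx < len(parts) and parts[idx] else "unclassified"
        entry = report.taxa.setdefault(
            taxon, {"n_refs": 0, "n_amplified": 0, "coverage_fraction": 0.0}
        )
        entry["n_refs"] += 1
        if predict_amplicons(primer_set, seq, policy, target_id=ref_id):
            entry["n_amplified"] += 1
        else:
            profiles = {}
            for oligo in (*primer_set.forward, primer_set.reverse):
                best = _best_site(oligo, seq, policy.w)
                profiles[oligo.name] = (
                    None
                    if best is None
                    else {
                        "strand": best.strand,
                        "start": best.start,
                        "n_mismatch_total": best.n_mismatch_total,
                        "n_mismatch_3prime": best.n_mismatch_3prime,
                        "mismatch_positions": list(best.mismatch_positions),
                    }
                )
            report.failing[ref_id] = {"taxon": taxon, "best_sites": profiles}
    for entry in report.taxa.values():
        entry["coverage_fraction"] = entry["n_amplified"] / entry["n_refs"]
    return report


def _union_code(bases: set[str]) -> str:
    for code, s in IUPAC_CODES.items():
        if s == frozenset(bases):
            return code
    raise ValueError(f"no IUPAC code for base set {bases}")


def suggest_rescue_primer(
    base_primer: Oligo,
    failing_refs: list[tuple[str, str]],
    max_extra_oligos: int = 1,
    max_degeneracy: int = 64,
    w: int = 5,
) -> tuple[list[Oligo], list[str]]:
    """Design extra forward primer(s) rescuing references a primer misses.

    For each failing reference the best available binding locus of
    ``base_primer`` is located and the reference's actual sequence there is
    extracted (primer orientation).  Loci are greedily grouped into at most
    ``max_extra_oligos`` clusters whose position-wise IUPAC union stays
    within ``max_degeneracy``; each cluster yields one proposed oligo that
    reuses the base primer's adaptor+pad and matches every member reference
    with zero mismatches (in particular in the 3' window).  References with
    no locatable site, or not fitting any cluster, are reported unrescuable.

    This generalizes the design of a degenerate companion primer mixed into
    an existing system to recover clades lost to 3'-terminal mismatches.
    """
    loci: list[tuple[str, str]] = []  # (ref_id, locus sequence, primer frame)
    unrescuable: list[str] = []
    for ref_id, seq in failing_refs:
        best = _best_site(base_primer, seq, w)
        if best is None:
            unrescuable.append(ref_id)
            continue
        window = seq[best.start : best.end]
        locus = revcomp(window) if best.strand == "-" else window
        if any(c not in "ACGT" for c in locus):
            unrescuable.append(ref_id)
            continue
        loci.append((ref_id, locus))
    clusters: list[dict] = []  # {"profile": list[set], "members": [ids]}
    for ref_id, locus in loci:
        placed = False
        for cl in clusters:
            if len(cl["profile"]) != len(locus):
                continue
            merged = [s | {b} for s, b in zip(cl["profile"], locus)]
            deg = 1
            for s in merged:
                deg *= len(s)
            if deg <= max_degeneracy:
                cl["profile"] = merged
                cl["members"].append(ref_id)
                placed = True
                break
        if not placed:
            if len(clusters) < max_extra_oligos:
                clusters.append(
                    {"profile": [{b} for b in locus], "members": [ref_id]}
                )
            else:
                unrescuable.append(ref_id)
    tail = base_primer.tail
    adaptor = base_primer.segment("flowcell_adaptor")
    pad = base_primer.segment("pad")
    proposals = []
    for i, cl in enumerate(clusters, start=1):
        region = "".join(_union_code(s) for s in cl["profile"])
        assert degeneracy(region) <= max_degeneracy
        segments = []
        pos = 0
        if adaptor:
            segments.append(("flowcell_adaptor", (0, len(adaptor))))
            pos = len(adaptor)
        if pad:
            segments.append(("pad", (pos, pos + len(pad))))
            pos += len(pad)
        segments.append(("binding_region", (pos, pos + len(region))))
        proposals.append(
            Oligo(
                name=f"{base_primer.name}_M{i}",
                sequence=tail + region,
                segments=tuple(segments),
                concentration=base_primer.concentration,
            )
        )
    return proposals, unrescuable
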