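"""Gene-family assignment, diagnostic sites, and mosaic (chimera) screening.

Paralogous gene families that diverged long before the within-family
coalescent carry many fixed differences; columns where two families are each
fixed for distinct alleles are *diagnostic sites*.  A PCR template switch
(or a genomic recombination event) produces a haplotype whose diagnostic-site
votes flip from one family to the other at a single breakpoint.  The screen
formalizes that: a haplotype is called MOSAIC when a two-segment model fits
its diagnostic votes strictly better than any single family and both
segments carry a minimum run of concordant diagnostic sites.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np

from .popgen import SaturationError, jc_correct
from .seq import AlignedSet, NucSequence, pairwise_differences


@dataclass
class FamilyPanel:
    """Reference haplotype sets per family, on a common column space."""

    families: dict[str, AlignedSet]

    def __post_init__(self) -> None:
        if len(self.families) < 2:
            raise ValueError("a family panel needs >= 2 families")
        lengths = {a.length for a in self.families.values()}
        if len(lengths) != 1:
            raise ValueError("families must share one alignment column space")

    @property
    def length(self) -> int:
        return next(iter(self.families.values())).length

    @property
    def names(self) -> list[str]:
        return list(self.families)


@dataclass
class DiagnosticSite:
    column: int
    alleles: dict[str, str]  # family -> fixed allele


@dataclass
class DiagnosticSiteSet:
    family_a: str
    family_b: str
    sites: list[DiagnosticSite]

    def __len__(self) -> int:
        return len(self.sites)

    @property
    def columns(self) -> list[int]:
        return [s.column for s in self.sites]


@dataclass
class FamilyCall:
    haplotype_id: str
    family: str  # family name, "MOSAIC", or "UNDETERMINED"
    margin: float | None = None
    distances: dict[str, float] = field(default_factory=dict)
    votes: list[str] | None = None  # per diagnostic site: family name or "."
    breakpoint: tuple[int, int] | None = None  # column interval containing it
    segments: tuple[str, str] | None = None  # family of left / right segment
    exclusive_variants: list[tuple[int, str]] = field(default_factory=list)

    @property
    def is_mosaic(self) -> bool:
        return self.family == "MOSAIC"


def diagnostic_sites(
    panel: FamilyPanel, families: tuple[str, str]
) -> DiagnosticSiteSet:
    """Columns where each family is fixed for a distinct non-gap allele.

    N never matches and never counts as a fixed allele; columns with any gap
    or N in either family are excluded.
    """
    fa, fb = families
    a, b = panel.families[fa], panel.families[fb]
    sites = []
    for col in range(1, panel.length + 1):
        xa = set(a.column(col))
        xb = set(b.column(col))
        if len(xa) == 1 and len(xb) == 1:
            ba, bb = next(iter(xa)), next(iter(xb))
            if ba != bb and ba in "ACGT" and bb in "ACGT":
                sites.append(DiagnosticSite(col, {fa: ba, fb: bb}))
    return DiagnosticSiteSet(fa, fb, sites)


def assign_family(hap: NucSequence, panel: FamilyPanel) -> FamilyCall:
    """Nearest family by mean JC-corrected distance; ties -> UNDETERMINED."""
    dists: dict[str, float] = {}
    for name, fam in panel.families.items():
        ds = []
        for m in fam.members:
            diffs, n = pairwise_differences(hap.residues, m.residues)
            if n == 0:
                continue
            try:
                ds.append(jc_correct(diffs / n))
            except SaturationError:
                continue
        if ds:
            dists[name] = float(np.mean(ds))
    if not dists:
        return FamilyCall(hap.id, "UNDETERMINED", distances={})
    ranked = sorted(dists.items(), key=lambda kv: (kv[1], kv[0]))
    best, second = ranked[0], ranked[1] if len(ranked) > 1 else (None, None)
    margin = None if second[1] is None else second[1] - best[1]
    if margin is not None and margin == 0.0:
        return FamilyCall(hap.id, "UNDETERMINED", margin=0.0, distances=dists)
    return FamilyCall(hap.id, best[0], margin=margin, distances=dists)


def _votes(hap: str, sites: DiagnosticSiteSet) -> list[str]:
    votes = []
    for s in sites.sites:
        base = hap[s.column - 1]
        if base == s.alleles[sites.family_a]:
            votes.append(sites.family_a)
        elif base == s.alleles[sites.family_b]:
            votes.append(sites.family_b)
        else:
            votes.append(".")
    return votes


def _max_run(votes: Sequence[str], family: str) -> int:
    best = cur = 0
    for v in votes:
        if v == family:
            cur += 1
            best = max(best, cur)
        elif v == ".":
            continue
        else:
            cur = 0
    return best


def detect_mosaic(
    hap: NucSequence,
    sites: DiagnosticSiteSet,
    min_run: int = 3,
) -> FamilyCall:
    """Single-breakpoint scan over diagnostic-site votes.

    The best breakpoint minimizes misassigned votes under a two-segment
    model (left segment one family, right segment the other).  MOSAIC
    requires (i) strictly fewer misassignments than the best single-family
    model and (ii) at least ``min_run`` consecutive concordant diagnostic
    sites in each segment.  Haplotypes covering fewer than 2 x min_run
    informative sites are UNDETERMINED.
    """
    votes = _votes(hap.residues, sites)
    informative = [(i, v) for i, v in enumerate(votes) if v != "."]
    call = FamilyCall(hap.id, "UNDETERMINED", votes=votes)
    if len(informative) < 2 * min_run:
        return call
    fa, fb = sites.family_a, sites.family_b
    labels = [v for _, v in informative]
    na = labels.count(fa)
    nb = labels.count(fb)
    one_family_mis = min(na, nb)
    m = len(labels)
    # prefix counts of fa votes
    pref_a = np.cumsum([1 if v == fa else 0 for v in labels])
    pref_b = np.cumsum([1 if v == fb else 0 for v in labels])
    best = None
    for k in range(1, m):  # breakpoint after informative site k-1 (0-based)
        # left = fa, right = fb: left misses = fb votes in left; right misses = fa votes in right
        left_b = int(pref_b[k - 1])
        right_a = int(na - pref_a[k - 1])
        mis1 = left_b + right_a
        # left = fb, right = fa
        left_a = int(pref_a[k - 1])
        right_b = int(nb - pref_b[k - 1])
        mis2 = left_a + right_b
        for mis, orient in ((mis1, (fa, fb)), (mis2, (fb, fa))):
            if best is None or mis < best[0]:
                best = (mis, k, orient)
    if best is None:
        return call
    mis, k, orient = best
    if mis >= one_family_mis:
        call.family = fa if na >= nb else fb
        if na == nb:
            call.family = "UNDETERMINED"
        return call
    left_votes = labels[:k]
    right_votes = labels[k:]
    if _max_run(left_votes, orient[0]) < min_run or _max_run(right_votes, orient[1]) < min_run:
        call.family = fa if na > nb else fb if nb > na else "UNDETERMINED"
        return call
    call.family = "MOSAIC"
    call.segments = orient
    left_col = sites.sites[informative[k - 1][0]].column
    right_col = sites.sites[informative[k][0]].column
    call.breakpoint = (left_col, right_col)
    return call


def brute_force_mosaic(
    hap: NucSequence, sites: DiagnosticSiteSet, min_run: int = 3
) -> FamilyCall:
    """Exhaustive reference implementation of the breakpoint scan (oracle)."""
    votes = _votes(hap.residues, sites)
    informative = [(i, v) for i, v in enumerate(votes) if v != "."]
    call = FamilyCall(hap.id, "UNDETERMINED", votes=votes)
    if len(informative) < 2 * min_run:
        return call
    fa, fb = sites.family_a, sites.family_b
    labels = [v for _, v in informative]
    one_family = min(labels.count(fa), labels.count(fb))
    best = None
    for k in range(1, len(labels)):
        for orient in ((fa, fb), (fb, fa)):
            mis = sum(1 for v in labels[:k] if v not in (orient[0], ".")) + sum(
                1 for v in labels[k:] if v not in (orient[1], ".")
            )
            if best is None or mis < best[0]:
                best = (mis, k, orient)
    mis, k, orient = best
    na, nb = labels.count(fa), labels.count(fb)
    if (
        mis < one_family
        and _max_run(labels[:k], orient[0]) >= min_run
        and _max_run(labels[k:], orient[1]) >= min_run
    ):
        call.family = "MOSAIC"
        call.segments = orient
        call.breakpoint = (
            sites.sites[informative[k - 1][0]].column,
            sites.sites[informative[k][0]].column,
        )
        return call
    call.family = fa if na > nb else fb if nb > na else "UNDETERMINED"
    return call


def shared_exclusive_variants(
    calls: list[FamilyCall],
    haps: dict[str, NucSequence],
    panel: FamilyPanel,
    sites: DiagnosticSiteSet | None = None,
    min_shared: int = 2,
) -> list[list[str]]:
    """Group haplotypes sharing exclusive variants in like-family segments.

    A variant is *exclusive* when, within the columns a haplotype's assigned
    family (or, for mosaics, the family of the containing segment) covers,
    the haplotype carries an allele found in no panel member of that family.
    Haplotypes sharing at least ``min_shared`` exclusive variants are grouped
    as putative single-origin recombinant lineages.
    """
    for call in calls:
        hap = haps[call.haplotype_id]
        variants: list[tuple[int, str]] = []
        for col in range(1, panel.length + 1):
            base = hap.residues[col - 1]
            if base not in "ACGT":
                continue
            fam = _segment_family(call, col, sites)
            if fam is None or fam not in panel.families:
                continue
            panel_alleles = set(panel.families[fam].column(col))
            if base not in panel_alleles:
                variants.append((col, base))
        call.exclusive_variants = variants
    groups: list[list[str]] = []
    used: set[str] = set()
    call_by_id = {c.haplotype_id: c for c in calls}
    ids = sorted(call_by_id)
    for i, a in enumerate(ids):
        if a in used:
            continue
        group = [a]
        va = set(call_by_id[a].exclusive_variants)
        for b in ids[i + 1 :]:
            if b in used:
                continue
            vb = set(call_by_id[b].exclusive_variants)
            if len(va & vb) >= min_shared:
                group.append(b)
                used.add(b)
        if len(group) > 1:
            used.update(group)
            groups.append(group)
    return groups


def _segment_family(
    call: FamilyCall, col: int, sites: DiagnosticSiteSet | None
) -> str | None:
    if not call.is_mosaic:
        return call.family if call.family not in ("MOSAIC", "UNDETERMINED") else None
    if call.breakpoint is None or call.segments is None:
        return None
    left_col, right_col = call.breakpoint
    if col <= left_col:
        return call.segments[0]
    if col >= right_col:
        return call.segments[1]
    return None


def exclude_recombinants(
    haps: Sequence[NucSequence], calls: list[FamilyCall]
) -> tuple[list[NucSequence], list[str]]:
    """Drop MOSAIC-flagged haplotypes before evolutionary analyses."""
    mosaic_ids = {c.haplotype_id for c in calls if c.is_mosaic}
    kept = [h for h in haps if h.id not in mosaic_ids]
    return kept, sorted(mosaic_ids)
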