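"""Diversity, divergence and neutrality statistics.

The counting machinery follows the (modified) Nei-Gojobori convention:
synonymous/nonsynonymous *sites* are fractional counts in which each possible
single-base change at a codon position is weighted R for a transition and 1
for each transversion; *differences* between codons are averaged over all
minimal mutational pathways, excluding pathways that pass through stop
codons.  Silent variation pools synonymous codon positions with noncoding
columns, the convention used for intron-bearing amplicons.  All per-pair
proportions are Jukes-Cantor corrected before averaging.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import permutations

import numpy as np
from scipy import stats as sps
from Bio.Data import CodonTable

from .seq import AlignedSet, SiteClassMap

_TABLE = CodonTable.unambiguous_dna_by_id[1]
CODON_AA: dict[str, str] = dict(_TABLE.forward_table)
for _stop in _TABLE.stop_codons:
    CODON_AA[_stop] = "*"
SENSE_CODONS = sorted(c for c, a in CODON_AA.items() if a != "*")

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}
BASES = "ACGT"


class SaturationError(ValueError):
    """Observed divergence beyond the Jukes-Cantor limit p >= 0.75."""


def is_transition(a: str, b: str) -> bool:
    return (a in _PURINES and b in _PURINES) or (
        a in _PYRIMIDINES and b in _PYRIMIDINES
    )


def haplotype_diversity(counts: list[int]) -> float:
    """Nei's haplotype diversity Hd = n(1 - sum p_i^2) / (n - 1)."""
    if any(c <= 0 for c in counts):
        raise ValueError("haplotype counts must be positive")
    n = sum(counts)
    if n < 2:
        raise ValueError("haplotype diversity needs n >= 2 sequences")
    sum_p2 = sum((c / n) ** 2 for c in counts)
    return n * (1.0 - sum_p2) / (n - 1)


def jc_correct(p: float) -> float:
    """Jukes-Cantor distance d = -(3/4) ln(1 - 4p/3)."""
    if p < 0:
        raise ValueError("proportion of differences must be >= 0")
    if p >= 0.75:
        raise SaturationError(f"p = {p:.4f} >= 0.75 (JC saturation)")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def jc_invert(d: float) -> float:
    """Expected proportion of differences at JC distance ``d``."""
    return 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))


def jc_gamma(p: float, a: float) -> float:
    """Gamma-rate Jukes-Cantor distance, shape ``a``:
    d = (3a/4) ((1 - 4p/3)^(-1/a) - 1); the a -> inf limit is plain JC."""
    if p < 0:
        raise ValueError("proportion of differences must be >= 0")
    if p >= 0.75:
        raise SaturationError(f"p = {p:.4f} >= 0.75 (JC saturation)")
    return 0.75 * a * ((1.0 - 4.0 * p / 3.0) ** (-1.0 / a) - 1.0)


@lru_cache(maxsize=None)
def ng_sites(codon: str, R: float = 2.0) -> tuple[float, float]:
    """Weighted synonymous/nonsynonymous site counts for one sense codon.

    At each position the three possible changes are weighted R (the
    transition) or 1 (each transversion) and the synonymous fraction of the
    weight is accumulated; changes to stop codons count as nonsynonymous.
    Always returns counts summing to exactly 3.
    """
    codon = codon.upper()
    if len(codon) != 3 or any(b not in BASES for b in codon):
        raise ValueError(f"invalid codon {codon!r}")
    aa = CODON_AA[codon]
    if aa == "*":
        raise ValueError(f"stop codon {codon!r} has no site counts")
    syn = 0.0
    for pos in range(3):
        total_w = R + 2.0
        for alt in BASES:
            if alt == codon[pos]:
                continue
            w = R if is_transition(codon[pos], alt) else 1.0
            mutant = codon[:pos] + alt + codon[pos + 1 :]
            if CODON_AA[mutant] == aa:
                syn += w / total_w
    return syn, 3.0 - syn


@lru_cache(maxsize=None)
def ng_differences(codon1: str, codon2: str) -> tuple[float, float]:
    """Pathway-averaged synonymous/nonsynonymous differences between codons.

    All minimal mutational pathways (orderings of the differing positions)
    are enumerated; pathways passing through a stop codon are excluded.  If
    every pathway is blocked by a stop intermediate, the average falls back
    to all pathways.  The two counts sum to the number of differing
    positions.
    """
    c1, c2 = codon1.upper(), codon2.upper()
    for c in (c1, c2):
        if len(c) != 3 or any(b not in BASES for b in c):
            raise ValueError(f"invalid codon {c!r}")
        if CODON_AA[c] == "*":
            raise ValueError(f"stop codon {c!r} not comparable")
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths: list[tuple[float, float]] = []
    blocked: list[tuple[float, float]] = []
    for order in permutations(diff_pos):
        cur = c1
        syn = non = 0.0
        hit_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if CODON_AA[nxt] == "*":
                hit_stop = True
            if CODON_AA[nxt] == CODON_AA[cur]:
                syn += 1.0
            else:
                non += 1.0
            cur = nxt
        (blocked if hit_stop else paths).append((syn, non))
    use = paths if paths else blocked
    s = sum(p[0] for p in use) / len(use)
    return s, len(diff_pos) - s


# ---------------------------------------------------------------------------
# Per-pair class-specific counts
# ---------------------------------------------------------------------------

@dataclass
class PairClassCounts:
    """Raw difference and site counts for one sequence pair."""

    noncoding_diffs: int = 0
    noncoding_sites: int = 0
    syn_diffs: float = 0.0
    syn_sites: float = 0.0
    nonsyn_diffs: float = 0.0
    nonsyn_sites: float = 0.0

    @property
    def p_silent(self) -> float | None:
        den = self.noncoding_sites + self.syn_sites
        if den <= 0:
            return None
        return (self.noncoding_diffs + self.syn_diffs) / den

    @property
    def p_nonsyn(self) -> float | None:
        if self.nonsyn_sites <= 0:
            return None
        return self.nonsyn_diffs / self.nonsyn_sites

    @property
    def p_syn(self) -> float | None:
        if self.syn_sites <= 0:
            return None
        return self.syn_diffs / self.syn_sites


def _codon_ok(c: str) -> bool:
    return all(b in BASES for b in c) and CODON_AA.get(c) != "*"


def pair_class_counts(
    a: str, b: str, site_map: SiteClassMap, R: float = 2.0
) -> PairClassCounts:
    """Class-specific counts for one aligned pair, pairwise gap deletion.

    Codons containing gaps, N, or a stop in either sequence are excluded;
    noncoding columns with a gap or N in either sequence are excluded.
    """
    out = PairClassCounts()
    for col in site_map.noncoding_columns:
        x, y = a[col - 1], b[col - 1]
        if x in "N-" or y in "N-":
            continue
        out.noncoding_sites += 1
        if x != y:
            out.noncoding_diffs += 1
    for c1c, c2c, c3c in site_map.codons():
        ca = a[c1c - 1] + a[c2c - 1] + a[c3c - 1]
        cb = b[c1c - 1] + b[c2c - 1] + b[c3c - 1]
        if not (_codon_ok(ca) and _codon_ok(cb)):
            continue
        sa, na = ng_sites(ca, R)
        sb, nb = ng_sites(cb, R)
        out.syn_sites += (sa + sb) / 2.0
        out.nonsyn_sites += (na + nb) / 2.0
        sd, nd = ng_differences(ca, cb)
        out.syn_diffs += sd
        out.nonsyn_diffs += nd
    return out


# ---------------------------------------------------------------------------
# Diversity
# ---------------------------------------------------------------------------

@dataclass
class DiversityResult:
    n: int
    S: int
    Hd: float | None
    pi_silent: float | None
    pi_nonsyn: float | None
    pi_syn: float | None
    tajima_D: float | None
    silent_sites: float
    nonsyn_sites: float
    saturated_pairs: int = 0


def _mean_or_none(values: list[float]) -> float | None:
    return float(np.mean(values)) if values else None


def nucleotide_diversity(
    aln: AlignedSet, site_map: SiteClassMap, R: float = 2.0
) -> DiversityResult:
    """Nei's pi with JC correction, separately at silent and replacement
    sites; correction is applied per pair, then averaged over pairs."""
    if len(aln) < 2:
        raise ValueError("diversity needs >= 2 sequences")
    sil: list[float] = []
    non: list[float] = []
    syn: list[float] = []
    sil_sites: list[float] = []
    non_sites: list[float] = []
    saturated = 0
    members = aln.members
    for i in range(len(members)):
        for j in range(i + 1, len(members)):
            cc = pair_class_counts(members[i].residues, members[j].residues, site_map, R)
            for p, acc in (
                (cc.p_silent, sil),
                (cc.p_nonsyn, non),
                (cc.p_syn, syn),
            ):
                if p is None:
                    continue
                try:
                    acc.append(jc_correct(p))
                except SaturationError:
                    saturated += 1
            sil_sites.append(cc.noncoding_sites + cc.syn_sites)
            non_sites.append(cc.nonsyn_sites)
    uniq = {}
    for m in members:
        uniq[m.residues] = uniq.get(m.residues, 0) + 1
    return DiversityResult(
        n=len(members),
        S=segregating_sites(aln),
        Hd=haplotype_diversity(list(uniq.values())),
        pi_silent=_mean_or_none(sil),
        pi_nonsyn=_mean_or_none(non),
        pi_syn=_mean_or_none(syn),
        tajima_D=tajima_D(aln),
        silent_sites=float(np.mean(sil_sites)) if sil_sites else 0.0,
        nonsyn_sites=float(np.mean(non_sites)) if non_sites else 0.0,
        saturated_pairs=saturated,
    )


def _complete_columns(aln: AlignedSet) -> np.ndarray:
    """Boolean mask of columns with no gap/N in any sequence."""
    mat = aln.to_matrix()
    bad = (mat == ord("-")) | (mat == ord("N"))
    return ~bad.any(axis=0)


def segregating_sites(aln: AlignedSet) -> int:
    mat = aln.to_matrix()
    ok = _complete_columns(aln)
    var = (mat != mat[0]).any(axis=0)
    return int((var & ok).sum())


def tajima_D(aln: AlignedSet) -> float | None:
    """Tajima's D over gap-complete columns; None when S = 0 or n < 4."""
    n = len(aln)
    if n < 4:
        return None
    mat = aln.to_matrix()[:, _complete_columns(aln)]
    S = int((mat != mat[0]).any(axis=0).sum())
    if S == 0:
        return None
    diffs = []
    for i in range(n):
        for j in range(i + 1, n):
            diffs.append(int((mat[i] != mat[j]).sum()))
    pi_hat = float(np.mean(diffs))
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    return (pi_hat - S / a1) / math.sqrt(var)


# ---------------------------------------------------------------------------
# Divergence
# ---------------------------------------------------------------------------

@dataclass
class DivergenceResult:
    K_silent: float | None
    K_syn: float | None
    K_nonsyn: float | None
    silent_sites: float
    syn_sites: float
    nonsyn_sites: float
    n_pairs: int
    saturated_pairs: int = 0

    @property
    def ka_ks(self) -> float | None:
        """K_A over silent-site K; None when the denominator is 0/undefined."""
        if self.K_nonsyn is None or not self.K_silent:
            return None
        return self.K_nonsyn / self.K_silent


def divergence(
    group_a: AlignedSet,
    group_b: AlignedSet,
    site_map: SiteClassMap,
    R: float = 2.0,
) -> DivergenceResult:
    """Mean JC-corrected class-specific distance over all between-group pairs.

    When the two groups are the same object this reduces to within-group pi.
    Saturated pairs are dropped from the mean and counted.
    """
    sil: list[float] = []
    syn: list[float] = []
    non: list[float] = []
    sil_sites: list[float] = []
    syn_sites: list[float] = []
    non_sites: list[float] = []
    saturated = 0
    same = group_a is group_b
    n_pairs = 0
    for i, ma in enumerate(group_a.members):
        bs = group_b.members[i + 1 :] if same else group_b.members
        for mb in bs:
            n_pairs += 1
            cc = pair_class_counts(ma.residues, mb.residues, site_map, R)
            for p, acc in ((cc.p_silent, sil), (cc.p_syn, syn), (cc.p_nonsyn, non)):
                if p is None:
                    continue
                try:
                    acc.append(jc_correct(p))
                except SaturationError:
                    saturated += 1
            sil_sites.append(cc.noncoding_sites + cc.syn_sites)
            syn_sites.append(cc.syn_sites)
            non_sites.append(cc.nonsyn_sites)
    return DivergenceResult(
        K_silent=_mean_or_none(sil),
        K_syn=_mean_or_none(syn),
        K_nonsyn=_mean_or_none(non),
        silent_sites=float(np.mean(sil_sites)) if sil_sites else 0.0,
        syn_sites=float(np.mean(syn_sites)) if syn_sites else 0.0,
        nonsyn_sites=float(np.mean(non_sites)) if non_sites else 0.0,
        n_pairs=n_pairs,
        saturated_pairs=saturated,
    )


# ---------------------------------------------------------------------------
# McDonald-Kreitman
# ---------------------------------------------------------------------------

@dataclass
class MKTable:
    Dn: float
    Ds: float
    Pn: float
    Ps: float
    p_value: float | None = None

    @property
    def neutrality_index(self) -> float | None:
        if self.Ds and self.Pn is not None and self.Ps and self.Dn:
            return (self.Pn / self.Ps) / (self.Dn / self.Ds)
        return None

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.Dn, self.Ds, self.Pn, self.Ps)


def mk_test(
    ingroup: AlignedSet, outgroup: AlignedSet, site_map: SiteClassMap
) -> MKTable:
    """McDonald-Kreitman 2x2 contingency test on a shared coding window.

    Per codon position: a site polymorphic within the ingroup contributes
    (k - 1) polymorphic changes (k alleles); a site monomorphic within the
    ingroup where every outgroup sequence carries a different allele
    contributes one fixed change.  Changes are classified synonymous or
    replacement by substituting the allele into the majority ingroup codon.
    Sites both polymorphic and divergent count as polymorphic only.
    Columns with a gap or N in any sequence are excluded (complete deletion).
    """
    if len(ingroup) < 2:
        raise ValueError("MK test needs >= 2 ingroup sequences")
    if len(outgroup) < 1:
        raise ValueError("MK test needs >= 1 outgroup sequence")
    all_members = ingroup.members + outgroup.members
    clean = set()
    for col in range(1, site_map.length + 1):
        if all(m.residues[col - 1] in BASES for m in all_members):
            clean.add(col)
    Dn = Ds = Pn = Ps = 0.0
    for cols in site_map.codons():
        if not all(c in clean for c in cols):
            continue
        in_codons = [
            m.residues[cols[0] - 1] + m.residues[cols[1] - 1] + m.residues[cols[2] - 1]
            for m in ingroup.members
        ]
        out_codons = [
            m.residues[cols[0] - 1] + m.residues[cols[1] - 1] + m.residues[cols[2] - 1]
            for m in outgroup.members
        ]
        if any(CODON_AA[c] == "*" for c in in_codons + out_codons):
            continue
        # majority ingroup codon as mutational context
        context = max(set(in_codons), key=lambda c: (in_codons.count(c), c))
        for pos in range(3):
            in_alleles = {c[pos] for c in in_codons}
            out_alleles = {c[pos] for c in out_codons}
            if len(in_alleles) > 1:
                major = max(
                    in_alleles, key=lambda b: ([c[pos] for c in in_codons].count(b), b)
                )
                base_codon = context[:pos] + major + context[pos + 1 :]
                for allele in sorted(in_alleles - {major}):
                    mutant = context[:pos] + allele + context[pos + 1 :]
                    if CODON_AA[mutant] == CODON_AA[base_codon]:
                        Ps += 1
                    else:
                        Pn += 1
            elif out_alleles and in_alleles.isdisjoint(out_alleles):
                major_out = max(
                    out_alleles,
                    key=lambda b: ([c[pos] for c in out_codons].count(b), b),
                )
                mutant = context[:pos] + major_out + context[pos + 1 :]
                if CODON_AA[mutant] == CODON_AA[context]:
                    Ds += 1
                else:
                    Dn += 1
    table = MKTable(Dn, Ds, Pn, Ps)
    if (Dn + Ds) > 0 and (Pn + Ps) > 0 and (Dn + Pn) > 0 and (Ds + Ps) > 0:
        _, p = sps.fisher_exact(
            [[Dn, Ds], [Pn, Ps]], alternative="two-sided"
        )
        table.p_value = float(p)
    return table
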