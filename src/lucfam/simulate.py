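"""Synthetic gene families, individuals and error-laden amplicon reads.

The generator realizes the structure the downstream analysis assumes: a
small number of paralogous gene families produced by duplication of a common
ancestor, with between-family synonymous divergence far exceeding
within-family diversity; several gene copies per individual; PCR chimeras
with a single breakpoint; and a sequencing error process in which short
(1-2 nt) indels arise preferentially inside homopolymer runs with a strand
bias, as on semiconductor (Ion Torrent style) platforms.

Because true haplotypes never gain insertions (only optional structural
deletions), every simulated sequence lives in the ancestor's coordinate
system and family panels are aligned by construction.

Divergence targets are imposed, not emergent: family branch lengths are
solved from the target matrix (star decomposition), within-family radiation
adds pi/2 per tip branch, and substitution counts per branch are Poisson
with mean = branch length x sequence length.  Nonsynonymous proposals are
accepted with probability omega; synonymous and noncoding proposals always.
With the proposal kernel's transition:transversion weighting matched to the
site-counting weights (R = 2), the realized silent divergence recovered by
the Nei-Gojobori/JC machinery is calibrated to the targets.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .popgen import CODON_AA, SENSE_CODONS, jc_invert
from .seq import AlignedSet, GeneModel, NucSequence, SiteClassMap, classify_sites

BASES = "ACGT"
_TS = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TV = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}

#: targets beyond this corrected distance put the expected observed p so
#: close to the 0.75 JC ceiling that recovery is numerically unstable
MAX_TARGET_K = 2.0


class ConfigError(ValueError):
    pass


@dataclass
class ReadErrorModel:
    substitution_rate: float = 0.005
    indel_rate_per_homopolymer_base: float = 0.01
    strand_bias: float = 0.8  # P(indel is a deletion | forward strand)
    length_distribution: tuple[int, int] | None = None  # uniform (lo, hi); None = full


def _default_target_ks() -> list[list[float]]:
    return [[0.0, 0.82, 0.82], [0.82, 0.0, 0.164], [0.82, 0.164, 0.0]]


def _default_gene_model() -> GeneModel:
    # 900-column locus: 200 codons of coding sequence in two exons separated
    # by noncoding flanks/intron (columns 1-100, 401-550, 851-900 noncoding)
    return GeneModel([(101, 400), (551, 850)], 0)


def _default_windows() -> list[tuple[int, int]]:
    # amplicon windows per family: ~360 columns for families 1-2, ~300 for 3
    return [(231, 590), (231, 590), (231, 530)]


def _default_copies() -> dict[int, float]:
    return {1: 0.30, 2: 0.30, 3: 0.20, 4: 0.10, 5: 0.05, 6: 0.05}


@dataclass
class SimulationConfig:
    seed: int = 0
    n_families: int = 3
    alignment_length: int = 900
    gene_model: GeneModel = field(default_factory=_default_gene_model)
    target_ks: list[list[float]] = field(default_factory=_default_target_ks)
    omega: float = 0.05
    within_pi_sil: list[float] = field(default_factory=lambda: [0.160, 0.156, 0.130])
    haplotypes_per_family: int = 8
    copies_per_individual: int | dict[int, float] = field(default_factory=_default_copies)
    n_individuals: int = 3
    amplicon_windows: list[tuple[int, int]] = field(default_factory=_default_windows)
    chimera_rate: float = 0.02
    reads_per_sample: int = 300
    uniform_coverage: bool = False
    read_error: ReadErrorModel = field(default_factory=ReadErrorModel)
    ts_tv: float = 2.0
    structural_deletions: list[tuple[int, int, int, int]] = field(default_factory=list)
    # (family index 1-based, haplotype index 1-based, start col, end col)

    def validate(self) -> None:
        n = self.n_families
        if n < 1:
            raise ConfigError("need at least one family")
        D = np.asarray(self.target_ks, dtype=float)
        if n > 1:
            if D.shape != (n, n):
                raise ConfigError("target_ks must be n_families x n_families")
            if not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0):
                raise ConfigError("target_ks must be symmetric with zero diagonal")
            if (D > MAX_TARGET_K).any():
                raise ConfigError(
                    f"target divergence beyond {MAX_TARGET_K} is effectively "
                    f"saturated (observed p -> {jc_invert(MAX_TARGET_K):.2f})"
                )
        if len(self.within_pi_sil) != n:
            raise ConfigError("within_pi_sil needs one value per family")
        for r in (
            [self.omega, self.chimera_rate, self.read_error.substitution_rate,
             self.read_error.indel_rate_per_homopolymer_base,
             self.read_error.strand_bias]
            + list(self.within_pi_sil)
        ):
            if not 0.0 <= r <= 1.0:
                raise ConfigError(f"rate {r} outside [0, 1]")
        if len(self.amplicon_windows) < n:
            raise ConfigError("need an amplicon window per family")
        for s, e in self.amplicon_windows[:n]:
            if not (1 <= s <= e <= self.alignment_length):
                raise ConfigError(f"amplicon window ({s}, {e}) out of bounds")
        for b in family_branch_lengths(self):
            if b < 0:
                raise ConfigError(
                    "within-family diversity exceeds the between-family "
                    "divergence budget (negative effective branch length)"
                )


@dataclass
class ReadRecord:
    read_id: str
    individual: str
    family: int
    sources: tuple[str, ...]  # 1 haplotype id, or 2 for chimeras
    breakpoint: int | None  # aligned column of last base from sources[0]
    strand: str
    n_subs: int
    n_indels: int


@dataclass
class TruthSet:
    """Ground truth for a simulation run."""

    haplotypes: dict[str, tuple[int, str]] = field(default_factory=dict)
    # hap_id -> (family, aligned sequence)
    inventories: dict[str, dict[int, list[str]]] = field(default_factory=dict)
    # individual -> family -> hap ids (one entry per gene copy)
    reads: list[ReadRecord] = field(default_factory=list)

    def distinct_alleles(self, individual: str, family: int) -> list[str]:
        seen: list[str] = []
        for h in self.inventories.get(individual, {}).get(family, []):
            if h not in seen:
                seen.append(h)
        return seen

    def reads_table(self) -> str:
        lines = ["read_id\tindividual\tfamily\tsources\tbreakpoint\tstrand\tn_subs\tn_indels"]
        for r in self.reads:
            bp = "" if r.breakpoint is None else str(r.breakpoint)
            lines.append(
                f"{r.read_id}\t{r.individual}\t{r.family}\t{','.join(r.sources)}"
                f"\t{bp}\t{r.strand}\t{r.n_subs}\t{r.n_indels}"
            )
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Sequence evolution
# ---------------------------------------------------------------------------

def _codon_lookup(site_map: SiteClassMap) -> dict[int, tuple[tuple[int, int, int], int]]:
    """column -> (codon column triple, 0-based position within codon)."""
    out = {}
    for triple in site_map.codons():
        for p, col in enumerate(triple):
            out[col] = (triple, p)
    return out


def _mutate_base(base: str, R: float, rng: np.random.Generator) -> str:
    if rng.random() < R / (R + 2.0):
        return _TS[base]
    return _TV[base][rng.integers(2)]


def evolve(
    seq: str,
    site_map: SiteClassMap,
    branch_length: float,
    omega: float,
    R: float,
    rng: np.random.Generator,
    codon_lookup: dict | None = None,
) -> str:
    """Evolve ``seq`` along a branch of ``branch_length`` expected accepted
    silent substitutions per silent site.

    Proposals arrive as Poisson(branch_length x length) uniform over sites;
    noncoding and synonymous proposals are always accepted, nonsynonymous
    ones with probability omega, and proposals creating a stop codon are
    always rejected (the open reading frame is preserved).
    """
    if branch_length <= 0:
        return seq
    s = list(seq)
    lookup = codon_lookup if codon_lookup is not None else _codon_lookup(site_map)
    n_prop = rng.poisson(branch_length * len(s))
    cols = rng.integers(1, len(s) + 1, size=n_prop)
    for col in cols:
        col = int(col)
        old = s[col - 1]
        new = _mutate_base(old, R, rng)
        if site_map.codon_index[col - 1] == 0 or col not in lookup:
            s[col - 1] = new
            continue
        triple, pos = lookup[col]
        codon = "".join(s[c - 1] for c in triple)
        mutant = codon[:pos] + new + codon[pos + 1 :]
        if CODON_AA[mutant] == "*":
            continue
        if CODON_AA[mutant] == CODON_AA[codon] or rng.random() < omega:
            s[col - 1] = new
    return "".join(s)


def random_ancestor(
    length: int, site_map: SiteClassMap, rng: np.random.Generator
) -> str:
    s = [BASES[rng.integers(4)] for _ in range(length)]
    for triple in site_map.codons():
        codon = SENSE_CODONS[rng.integers(len(SENSE_CODONS))]
        for p, col in enumerate(triple):
            s[col - 1] = codon[p]
    return "".join(s)


def family_branch_lengths(config: SimulationConfig) -> list[float]:
    """Per-family branch lengths from the star decomposition of the target
    matrix, with half the within-family diversity subtracted so that mean
    raw between-family distance hits the target."""
    n = config.n_families
    if n == 1:
        return [0.0]
    D = np.asarray(config.target_ks, dtype=float)
    if n == 2:
        b = [D[0, 1] / 2.0] * 2
    else:
        S = D[np.triu_indices(n, 1)].sum()
        b = [(D[i].sum() - S / (n - 1)) / (n - 2) for i in range(n)]
    return [b[i] - config.within_pi_sil[i] / 2.0 for i in range(n)]


def simulate_families(
    config: SimulationConfig,
) -> tuple[list[AlignedSet], TruthSet]:
    """Generate aligned haplotype panels for each family plus ground truth."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    site_map = classify_sites(config.alignment_length, config.gene_model)
    lookup = _codon_lookup(site_map)
    ancestor = random_ancestor(config.alignment_length, site_map, rng)
    branches = family_branch_lengths(config)
    truth = TruthSet()
    families: list[AlignedSet] = []
    for f in range(config.n_families):
        founder = evolve(
            ancestor, site_map, branches[f], config.omega, config.ts_tv, rng, lookup
        )
        tip_branch = config.within_pi_sil[f] / 2.0
        members = []
        for h in range(1, config.haplotypes_per_family + 1):
            hap = evolve(
                founder, site_map, tip_branch, config.omega, config.ts_tv, rng, lookup
            )
            hap_id = f"F{f + 1}_H{h}"
            members.append(NucSequence(hap_id, hap))
            truth.haplotypes[hap_id] = (f + 1, hap)
        families.append(AlignedSet(members))
    for fam_idx, hap_idx, start, end in config.structural_deletions:
        fam = families[fam_idx - 1]
        m = fam.members[hap_idx - 1]
        res = m.residues[: start - 1] + "-" * (end - start + 1) + m.residues[end:]
        fam.members[hap_idx - 1] = NucSequence(m.id, res)
        truth.haplotypes[m.id] = (fam_idx, res)
    return families, truth


def simulate_individuals(
    families: Sequence[AlignedSet],
    config: SimulationConfig,
    truth: TruthSet,
) -> dict[str, dict[int, list[str]]]:
    """Draw per-individual gene-copy inventories (alleles with replacement:
    paralogous loci may carry the same allele)."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    copies = config.copies_per_individual
    inventories: dict[str, dict[int, list[str]]] = {}
    for i in range(1, config.n_individuals + 1):
        ind = f"Ind{i}"
        inventories[ind] = {}
        for f, fam in enumerate(families, start=1):
            if isinstance(copies, dict):
                ks = sorted(copies)
                ps = np.array([copies[k] for k in ks], dtype=float)
                k = int(rng.choice(ks, p=ps / ps.sum()))
            else:
                k = int(copies)
            ids = [fam.members[int(j)].id for j in rng.integers(len(fam.members), size=k)]
            inventories[ind][f] = ids
    truth.inventories = inventories
    return inventories


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------

def homopolymer_runs(s: str, min_len: int = 2) -> list[tuple[int, int]]:
    """(0-based start, length) of runs of identical bases with length >= min_len."""
    runs = []
    i = 0
    while i < len(s):
        j = i
        while j < len(s) and s[j] == s[i]:
            j += 1
        if j - i >= min_len:
            runs.append((i, j - i))
        i = j
    return runs


def _amplicon(aligned_seq: str, window: tuple[int, int]) -> str:
    return aligned_seq[window[0] - 1 : window[1]].replace("-", "")


def _apply_errors(
    read: str, model: ReadErrorModel, strand: str, rng: np.random.Generator
) -> tuple[str, list[int], int, int]:
    chars = list(read)
    quals = [35] * len(chars)
    n_subs = 0
    sub_flags = rng.random(len(chars)) < model.substitution_rate
    for i in np.flatnonzero(sub_flags):
        chars[int(i)] = _mutate_base(chars[int(i)], 2.0, rng)
        quals[int(i)] = 15
        n_subs += 1
    n_indels = 0
    if model.indel_rate_per_homopolymer_base > 0:
        out_c: list[str] = []
        out_q: list[int] = []
        s = "".join(chars)
        pos = 0
        p_del = model.strand_bias if strand == "+" else 1.0 - model.strand_bias
        for start, length in homopolymer_runs(s, 2):
            out_c.extend(chars[pos:start])
            out_q.extend(quals[pos:start])
            seg_c = chars[start : start + length]
            seg_q = quals[start : start + length]
            if rng.random() < min(1.0, model.indel_rate_per_homopolymer_base * length):
                n_indels += 1
                ev_len = 1 if rng.random() < 0.8 else 2
                if rng.random() < p_del:
                    drop = min(ev_len, length - 1) or 1
                    seg_c = seg_c[drop:]
                    seg_q = seg_q[drop:]
                else:
                    seg_c = [seg_c[0]] * ev_len + seg_c
                    seg_q = [15] * ev_len + seg_q
            out_c.extend(seg_c)
            out_q.extend(seg_q)
            pos = start + length
        out_c.extend(chars[pos:])
        out_q.extend(quals[pos:])
        chars, quals = out_c, out_q
    if model.length_distribution is not None:
        lo, hi = model.length_distribution
        L = int(rng.integers(lo, hi + 1))
        chars = chars[:L]
        quals = quals[:L]
    return "".join(chars), quals, n_subs, n_indels


def simulate_reads(
    inventories: dict[str, dict[int, list[str]]],
    config: SimulationConfig,
    truth: TruthSet,
) -> dict[str, dict[int, list[NucSequence]]]:
    """Amplicon reads per individual and family, with injected errors and
    chimeras; every read is recorded in the truth table."""
    if not inventories:
        raise ValueError("empty inventory: run simulate_individuals first")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    reads: dict[str, dict[int, list[NucSequence]]] = {}
    for ind in sorted(inventories):
        reads[ind] = {}
        for f in sorted(inventories[ind]):
            window = config.amplicon_windows[f - 1]
            copy_ids = inventories[ind][f]
            n = config.reads_per_sample
            if config.uniform_coverage:
                per = [n // len(copy_ids)] * len(copy_ids)
                for r in range(n - sum(per)):
                    per[r] += 1
                assignment = [
                    cid for cid, k in zip(copy_ids, per) for _ in range(k)
                ]
            else:
                assignment = [
                    copy_ids[int(j)] for j in rng.integers(len(copy_ids), size=n)
                ]
            distinct = truth.distinct_alleles(ind, f)
            out = []
            for ri, src in enumerate(assignment, start=1):
                strand = "+" if rng.random() < 0.5 else "-"
                breakpoint = None
                sources = (src,)
                if (
                    config.chimera_rate > 0
                    and len(distinct) >= 2
                    and rng.random() < config.chimera_rate
                ):
                    others = [d for d in distinct if d != src]
                    mate = others[int(rng.integers(len(others)))]
                    breakpoint = int(rng.integers(window[0], window[1]))
                    left = truth.haplotypes[src][1]
                    right = truth.haplotypes[mate][1]
                    joined = (
                        left[window[0] - 1 : breakpoint]
                        + right[breakpoint : window[1]]
                    ).replace("-", "")
                    base = joined
                    sources = (src, mate)
                else:
                    base = _amplicon(truth.haplotypes[src][1], window)
                seq, quals, n_subs, n_indels = _apply_errors(
                    base, config.read_error, strand, rng
                )
                rid = f"{ind}_F{f}_r{ri}"
                out.append(NucSequence(rid, seq, quals))
                truth.reads.append(
                    ReadRecord(rid, ind, f, sources, breakpoint, strand, n_subs, n_indels)
                )
            reads[ind][f] = out
    return reads


def simulate_all(
    config: SimulationConfig,
) -> tuple[list[AlignedSet], dict[str, dict[int, list[NucSequence]]], TruthSet]:
    families, truth = simulate_families(config)
    inventories = simulate_individuals(families, config, truth)
    reads = simulate_reads(inventories, config, truth)
    return families, reads, truth
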