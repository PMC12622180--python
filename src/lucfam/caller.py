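"""Amplicon haplotype calling: EM error-correction plus the filter chain.

Reads are aligned to a family reference amplicon, projected into reference
columns, and clustered by identical projection.  A mixture model over the
distinct read strings with a single per-base error rate epsilon is fitted by
expectation-maximization; each cluster then receives a posterior probability
that its sequence is a true haplotype rather than an error derivative of a
more frequent neighbour.  Candidates that clear the posterior cutoff pass
through two sequence-level filters taken from amplicon practice on
homopolymer-error-prone platforms: short (1-2 nt) indels and premature stop
codons are treated as artifacts unless present in a trusted (cloned)
sequence, and haplotypes below a per-sample frequency floor are discarded
unless confirmed by a trusted clone or seen in multiple independent samples.

Filter chain order: length -> posterior -> artifact indel -> frequency/rescue.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .popgen import CODON_AA
from .seq import (
    AlignedSet,
    BandTooNarrowError,
    IndelEvent,
    NucSequence,
    SiteClassMap,
    align_pair_global,
    pairwise_differences,
)

REJECT_LOW_POSTERIOR = "low_posterior"
REJECT_ARTIFACT_INDEL = "artifact_indel"
REJECT_STOP_CODON = "stop_codon"
REJECT_LOW_FREQUENCY = "low_frequency"


@dataclass
class FilterConfig:
    min_read_length: int = 150
    min_posterior: float = 0.95
    min_frequency: float = 0.15
    max_artifact_indel: int = 2
    stop_codon_filter: bool = True
    multi_sample_rescue: bool = True
    #: frequency denominator: reads of posterior-passed candidates
    #: ("posterior_passed") or of all candidates ("all_candidates")
    frequency_denominator: str = "posterior_passed"
    #: minimum reads for a cluster to seed a mixture component
    min_component_reads: int = 2
    band: int = 30
    em_max_iter: int = 500
    em_tol: float = 1e-9


@dataclass
class LengthReport:
    total: int
    passed: int

    @property
    def fraction(self) -> float | None:
        if self.total == 0:
            return None
        return self.passed / self.total

    @property
    def percent(self) -> float | None:
        f = self.fraction
        return None if f is None else 100.0 * f


def length_filter(
    reads: Sequence[NucSequence], min_len: int = 150
) -> tuple[list[NucSequence], LengthReport]:
    """Keep reads strictly longer than ``min_len`` bases."""
    kept = [r for r in reads if len(r) > min_len]
    return kept, LengthReport(total=len(reads), passed=len(kept))


@dataclass
class CandidateHaplotype:
    """A called haplotype in reference-column space.

    ``sequence`` has one character per reference position ('-' marks a
    deletion); insertions relative to the reference are carried as events.
    """

    sequence: str
    insertions: tuple[tuple[str, int, int, str], ...]
    read_count: int  # after error correction (reads attributed to this haplotype)
    sample_counts: dict[str, int]
    posteriors: dict[str, float]
    raw_read_count: int = 0  # identical-read cluster size before correction
    frequencies: dict[str, float] = field(default_factory=dict)
    flags: set[str] = field(default_factory=set)
    status: str = "CANDIDATE"
    reject_reason: str | None = None

    @property
    def posterior(self) -> float:
        return max(self.posteriors.values()) if self.posteriors else 0.0

    @property
    def detected_samples(self) -> list[str]:
        """Samples where this haplotype passed the posterior cutoff."""
        return [s for s, flag in self._detections.items() if flag]

    _detections: dict[str, bool] = field(default_factory=dict)

    def key(self) -> tuple[str, tuple]:
        return (self.sequence, self.insertions)

    def ungapped(self) -> str:
        return self.sequence.replace("-", "")

    def deletion_events(self, reference: str) -> list[IndelEvent]:
        events = []
        i = 0
        while i < len(self.sequence):
            if self.sequence[i] == "-":
                start = i
                while i < len(self.sequence) and self.sequence[i] == "-":
                    i += 1
                events.append(
                    IndelEvent("del", start + 1, i - start, reference[start:i])
                )
            else:
                i += 1
        return events

    def indel_events(self, reference: str) -> list[IndelEvent]:
        return self.deletion_events(reference) + [
            IndelEvent(*e) for e in self.insertions
        ]


# ---------------------------------------------------------------------------
# Projection and EM
# ---------------------------------------------------------------------------

def _project(read: NucSequence, reference: NucSequence, config: FilterConfig):
    """Project a read into reference columns; None if it does not cover the
    reference window."""
    band = max(config.band, abs(len(read) - len(reference)) + 2)
    try:
        aln = align_pair_global(read, reference, band=band)
    except BandTooNarrowError:
        aln = align_pair_global(read, reference, band=None)
    proj = []
    insertions = []
    ref_pos = 0
    pending_ins: list[str] = []
    for qb, rb in zip(aln.aligned_query, aln.aligned_ref):
        if rb == "-":
            pending_ins.append(qb)
            continue
        if pending_ins and ref_pos > 0:
            insertions.append(("ins", ref_pos, len(pending_ins), "".join(pending_ins)))
        pending_ins = []
        ref_pos += 1
        proj.append(qb)
    projected = "".join(proj)
    # terminal deletion runs mean the read does not span the window
    lead = len(projected) - len(projected.lstrip("-"))
    trail = len(projected) - len(projected.rstrip("-"))
    if lead > config.max_artifact_indel or trail > config.max_artifact_indel:
        return None
    return projected, tuple(insertions)


def _cluster_distances(keys: list[tuple[str, tuple]]) -> np.ndarray:
    mats = np.frombuffer(
        "".join(k[0] for k in keys).encode(), dtype=np.uint8
    ).reshape(len(keys), -1)
    d = (mats[:, None, :] != mats[None, :, :]).sum(axis=2).astype(float)
    # insertions contribute their length when not shared
    for i, (_, ins_i) in enumerate(keys):
        for j, (_, ins_j) in enumerate(keys):
            if i >= j or ins_i == ins_j:
                continue
            si, sj = set(ins_i), set(ins_j)
            pen = sum(e[2] for e in si.symmetric_difference(sj))
            d[i, j] += pen
            d[j, i] += pen
    return d


def _em_mixture(
    counts: np.ndarray,
    dist: np.ndarray,
    comp_idx: np.ndarray,
    L: int,
    config: FilterConfig,
) -> tuple[np.ndarray, float, bool]:
    """Fit mixture frequencies and a single per-base error rate.

    Mixture components are the clusters indexed by ``comp_idx`` (by default
    those supported by at least two reads; fitting one component per
    observed string is degenerate, since the likelihood is then maximized by
    eps = 0 and the empirical frequencies, which would make every error
    string its own "haplotype").  All clusters contribute as data:
    P(read r | component h) = (eps/3)^d(r,h) (1-eps)^(L-d).
    Returns (component frequencies, eps, converged).
    """
    N = counts.sum()
    f = counts[comp_idx] / counts[comp_idx].sum()
    eps = 0.01
    converged = False
    dist_c = dist[:, comp_idx]
    for _ in range(config.em_max_iter):
        eps_safe = max(eps, 1e-12)
        log_lik = dist_c * (math.log(eps_safe) - math.log(3.0)) + (
            L - dist_c
        ) * math.log1p(-eps_safe)
        # rows = read cluster r, cols = component h
        logw = np.log(np.maximum(f, 1e-300))[None, :] + log_lik
        mx = logw.max(axis=1, keepdims=True)
        w = np.exp(logw - mx)
        w /= w.sum(axis=1, keepdims=True)
        f_new = (counts[:, None] * w).sum(axis=0) / N
        eps_new = float((counts[:, None] * w * dist_c).sum() / (N * L))
        if abs(eps_new - eps) < config.em_tol and np.abs(f_new - f).max() < config.em_tol:
            f, eps = f_new, eps_new
            converged = True
            break
        f, eps = f_new, eps_new
    return f, eps, converged


def _posteriors(
    counts: np.ndarray,
    f: np.ndarray,
    comp_idx: np.ndarray,
    eps: float,
    dist: np.ndarray,
    L: int,
) -> np.ndarray:
    """Posterior that each cluster is a true haplotype rather than an error
    derivative of a more frequent component (likelihood-ratio normalized).

    For cluster s with n_s reads the "real" hypothesis has per-read
    likelihood f_s (1-eps)^L (an error-free read of a real haplotype at
    frequency f_s); the error hypothesis sums, over components h with
    f_h > f_s, f_h C(L,d) eps^d (1-eps)^(L-d) -- the probability that a read
    of h acquires *some* d errors, since any of the C(L,d) 3^d strings at
    distance d is an equally good error derivative.  Both are raised to n_s
    and the posterior is the normalized ratio.
    """
    m = len(counts)
    N = counts.sum()
    post = np.ones(m)
    if eps <= 1e-12:
        eps = 1e-12
    log_e = math.log(eps)
    log_ne = math.log1p(-eps)

    def log_comb(n: int, k: float) -> float:
        return (
            math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)
        )

    f_full = np.zeros(m)
    f_full[comp_idx] = f
    is_comp = np.zeros(m, dtype=bool)
    is_comp[comp_idx] = True
    for s in range(m):
        fs = f_full[s] if is_comp[s] else counts[s] / N
        a = counts[s] * (math.log(max(fs, 1e-300)) + L * log_ne)
        b_terms = []
        for h in comp_idx:
            if h == s or f_full[h] <= fs:
                continue
            d = dist[s, h]
            lp = (
                math.log(max(f_full[h], 1e-300))
                + log_comb(L, d)
                + d * log_e
                + (L - d) * log_ne
            )
            b_terms.append(counts[s] * lp)
        if not b_terms:
            continue
        bmax = max(b_terms)
        b = bmax + math.log(sum(math.exp(x - bmax) for x in b_terms))
        top = max(a, b)
        post[s] = math.exp(a - top) / (math.exp(a - top) + math.exp(b - top))
    return post


@dataclass
class SampleCall:
    sample: str
    clusters: dict[tuple, int]  # raw identical-read clusters
    assigned: dict[tuple, int]  # read counts after error correction
    posteriors: dict[tuple, float]
    frequencies: dict[tuple, float]
    epsilon: float
    converged: bool
    n_reads_used: int
    n_reads_dropped: int


def call_candidates(
    reads: Sequence[NucSequence],
    reference: NucSequence,
    config: FilterConfig | None = None,
    sample: str = "sample",
) -> SampleCall:
    """Cluster one sample's reads and fit the EM mixture."""
    config = config or FilterConfig()
    clusters: dict[tuple, int] = {}
    dropped = 0
    for read in reads:
        proj = _project(read, reference, config)
        if proj is None:
            dropped += 1
            continue
        clusters[proj] = clusters.get(proj, 0) + 1
    if not clusters:
        return SampleCall(sample, {}, {}, {}, {}, 0.0, True, 0, dropped)
    keys = sorted(clusters)
    counts = np.array([clusters[k] for k in keys], dtype=float)
    dist = _cluster_distances(keys)
    L = len(reference)
    comp_idx = np.flatnonzero(counts >= config.min_component_reads)
    if comp_idx.size == 0:
        comp_idx = np.arange(len(counts))
    f, eps, converged = _em_mixture(counts, dist, comp_idx, L, config)
    post = _posteriors(counts, f, comp_idx, eps, dist, L)
    f_full = np.zeros(len(counts))
    f_full[comp_idx] = f
    # error correction: reads of clusters that fail the posterior cutoff are
    # attributed to their best-supported component; clusters that pass keep
    # their own reads (they are themselves called haplotypes)
    assigned = {k: 0 for k in keys}
    eps_safe = max(eps, 1e-12)
    log_lik = dist[:, comp_idx] * (math.log(eps_safe) - math.log(3.0)) + (
        L - dist[:, comp_idx]
    ) * math.log1p(-eps_safe)
    logw = np.log(np.maximum(f, 1e-300))[None, :] + log_lik
    best_comp = comp_idx[np.argmax(logw, axis=1)]
    for r, k in enumerate(keys):
        if post[r] > config.min_posterior:
            assigned[k] += int(counts[r])
        else:
            assigned[keys[int(best_comp[r])]] += int(counts[r])
    return SampleCall(
        sample,
        {k: int(clusters[k]) for k in keys},
        assigned,
        {k: float(p) for k, p in zip(keys, post)},
        {k: float(fi) for k, fi in zip(keys, f_full)},
        eps,
        converged,
        int(counts.sum()),
        dropped,
    )


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def _trusted_projections(
    trusted: Sequence[NucSequence], reference: NucSequence, config: FilterConfig
) -> list[tuple[str, tuple]]:
    out = []
    for t in trusted:
        proj = _project(t, reference, config)
        if proj is not None:
            out.append(proj)
    return out


def _stop_codon_positions(seq: str, site_map: SiteClassMap) -> set[int]:
    stops = set()
    for cols in site_map.codons():
        codon = "".join(seq[c - 1] for c in cols)
        if all(b in "ACGT" for b in codon) and CODON_AA[codon] == "*":
            stops.add(cols[0])
    return stops


def artifact_indel_filter(
    candidates: list[CandidateHaplotype],
    trusted: Sequence[NucSequence],
    reference: NucSequence,
    config: FilterConfig | None = None,
    site_map: SiteClassMap | None = None,
) -> list[CandidateHaplotype]:
    """Reject candidates with short novel indels or novel premature stops.

    An indel of length <= max_artifact_indel must match a trusted clone's
    indel exactly (kind, position, length, allele); longer indels are not the
    targeted artifact class and pass.  When a site-class map is supplied,
    premature stop codons must likewise occur in a trusted sequence.
    """
    config = config or FilterConfig()
    use_stop_filter = site_map is not None and config.stop_codon_filter
    trusted_proj = _trusted_projections(trusted, reference, config)
    trusted_indels: set[tuple] = set()
    trusted_stops: set[int] = set()
    for proj, ins in trusted_proj:
        cand = CandidateHaplotype(proj, ins, 0, {}, {})
        trusted_indels.update(e.key() for e in cand.indel_events(reference.residues))
        if use_stop_filter:
            trusted_stops.update(_stop_codon_positions(proj, site_map))
    for cand in candidates:
        if cand.status != "CANDIDATE":
            continue
        novel = [
            e
            for e in cand.indel_events(reference.residues)
            if e.length <= config.max_artifact_indel and e.key() not in trusted_indels
        ]
        if novel:
            cand.status = "REJECTED"
            cand.reject_reason = REJECT_ARTIFACT_INDEL
            cand.flags.add("artifact_indel")
            continue
        if use_stop_filter:
            stops = _stop_codon_positions(cand.sequence, site_map)
            if stops:
                cand.flags.add("stop_codon")
                if not stops <= trusted_stops:
                    cand.status = "REJECTED"
                    cand.reject_reason = REJECT_STOP_CODON
    return candidates


def frequency_rescue_filter(
    candidates: list[CandidateHaplotype],
    pcs_set: Sequence[NucSequence],
    reference: NucSequence,
    config: FilterConfig | None = None,
) -> list[CandidateHaplotype]:
    """Apply the per-sample frequency floor with clone / multi-sample rescue.

    A candidate passes if it reaches ``min_frequency`` of the reads in at
    least one sample (denominator per config); otherwise it is rescued if its
    sequence matches a trusted clone over the reference window, or (when
    enabled) if it was detected in two or more independent samples.
    """
    config = config or FilterConfig()
    pcs_keys = {p for p in _trusted_projections(pcs_set, reference, config)}
    live = [c for c in candidates if c.status == "CANDIDATE"]
    samples: set[str] = set()
    for c in live:
        samples.update(c.sample_counts)
    totals: dict[str, int] = {}
    pool = live if config.frequency_denominator == "posterior_passed" else candidates
    for s in samples:
        totals[s] = sum(c.sample_counts.get(s, 0) for c in pool)
    for c in live:
        c.frequencies = {
            s: c.sample_counts.get(s, 0) / totals[s]
            for s in samples
            if totals.get(s, 0) > 0 and c.sample_counts.get(s, 0) > 0
        }
        if any(f >= config.min_frequency for f in c.frequencies.values()):
            c.status = "ACCEPTED"
            continue
        if c.key() in pcs_keys:
            c.status = "RESCUED"
            c.flags.add("pcs_confirmed")
            continue
        if config.multi_sample_rescue and len(c.detected_samples) >= 2:
            c.status = "RESCUED"
            c.flags.add("multi_sample")
            continue
        c.status = "REJECTED"
        c.reject_reason = REJECT_LOW_FREQUENCY
    return candidates


# ---------------------------------------------------------------------------
# Full per-dataset calling
# ---------------------------------------------------------------------------

@dataclass
class CallResult:
    candidates: list[CandidateHaplotype]
    sample_calls: dict[str, SampleCall]
    length_report: LengthReport
    report: dict

    @property
    def accepted(self) -> list[CandidateHaplotype]:
        return [c for c in self.candidates if c.status == "ACCEPTED"]

    @property
    def rescued(self) -> list[CandidateHaplotype]:
        return [c for c in self.candidates if c.status == "RESCUED"]

    @property
    def passing(self) -> list[CandidateHaplotype]:
        return [c for c in self.candidates if c.status in ("ACCEPTED", "RESCUED")]

    @property
    def rejected(self) -> list[CandidateHaplotype]:
        return [c for c in self.candidates if c.status == "REJECTED"]


def call_haplotypes(
    reads_by_sample: dict[str, Sequence[NucSequence]],
    reference: NucSequence,
    trusted: Sequence[NucSequence] = (),
    config: FilterConfig | None = None,
    site_map: SiteClassMap | None = None,
) -> CallResult:
    """Run the full filter chain over per-sample read pools.

    Samples are assumed to come from independent amplifications, so the
    multi-sample rescue arm treats detection in two of them as independent
    evidence.
    """
    config = config or FilterConfig()
    total_reads = 0
    total_passed = 0
    sample_calls: dict[str, SampleCall] = {}
    merged: dict[tuple, CandidateHaplotype] = {}
    for sample in sorted(reads_by_sample):
        reads, rep = length_filter(reads_by_sample[sample], config.min_read_length)
        total_reads += rep.total
        total_passed += rep.passed
        call = call_candidates(reads, reference, config, sample)
        sample_calls[sample] = call
        for key, count in call.clusters.items():
            if key not in merged:
                merged[key] = CandidateHaplotype(
                    sequence=key[0],
                    insertions=key[1],
                    read_count=0,
                    sample_counts={},
                    posteriors={},
                )
            cand = merged[key]
            corrected = call.assigned[key]
            cand.read_count += corrected
            cand.raw_read_count += count
            cand.sample_counts[sample] = corrected
            cand.posteriors[sample] = call.posteriors[key]
            cand._detections[sample] = call.posteriors[key] > config.min_posterior
    candidates = [merged[k] for k in sorted(merged)]
    for cand in candidates:
        if not cand.detected_samples:
            cand.status = "REJECTED"
            cand.reject_reason = REJECT_LOW_POSTERIOR
    artifact_indel_filter(candidates, trusted, reference, config, site_map)
    frequency_rescue_filter(candidates, trusted, reference, config)
    report = {
        "reads_total": total_reads,
        "reads_after_length_filter": total_passed,
        "reads_dropped_not_spanning": sum(
            c.n_reads_dropped for c in sample_calls.values()
        ),
        "candidates": len(candidates),
        "accepted": sum(1 for c in candidates if c.status == "ACCEPTED"),
        "rescued": sum(1 for c in candidates if c.status == "RESCUED"),
        "rejected": {
            reason: sum(
                1
                for c in candidates
                if c.status == "REJECTED" and c.reject_reason == reason
            )
            for reason in (
                REJECT_LOW_POSTERIOR,
                REJECT_ARTIFACT_INDEL,
                REJECT_STOP_CODON,
                REJECT_LOW_FREQUENCY,
            )
        },
        "em_converged": all(c.converged for c in sample_calls.values()),
    }
    return CallResult(candidates, sample_calls, LengthReport(total_reads, total_passed), report)


# ---------------------------------------------------------------------------
# Support profile
# ---------------------------------------------------------------------------

@dataclass
class SupportProfile:
    weak_mean: float
    weak_se: float
    strong_mean: float
    strong_se: float
    weak_nearest: dict[str, tuple[str, int]]

    def summary(self) -> str:
        return (
            f"weak {self.weak_mean:.1f} +/- {self.weak_se:.2f} vs "
            f"strong {self.strong_mean:.1f} +/- {self.strong_se:.2f} (mean +/- SE)"
        )


def support_profile(
    weak: AlignedSet | Sequence[NucSequence],
    strong: AlignedSet | Sequence[NucSequence],
) -> SupportProfile | None:
    """Compare mutation profiles of weakly vs strongly supported haplotypes.

    For each weak haplotype: nucleotide differences (gap-excluded) to its
    nearest strong haplotype; for each strong haplotype: distance to its
    nearest other strong haplotype.  Similar means indicate the weak set
    behaves like true rare alleles rather than error derivatives (which
    would sit ~1 change from a strong neighbour).
    Returns None when fewer than two strong haplotypes exist.
    """
    weak_list = list(weak.members if isinstance(weak, AlignedSet) else weak)
    strong_list = list(strong.members if isinstance(strong, AlignedSet) else strong)
    if len(strong_list) < 2:
        return None

    def dist(a: NucSequence, b: NucSequence) -> int:
        d, _ = pairwise_differences(a.residues, b.residues)
        return d

    weak_d = []
    nearest = {}
    for w in weak_list:
        ds = [(dist(w, s), s.id) for s in strong_list]
        dmin, sid = min(ds)
        weak_d.append(dmin)
        nearest[w.id] = (sid, dmin)
    strong_d = []
    for i, s in enumerate(strong_list):
        strong_d.append(min(dist(s, t) for j, t in enumerate(strong_list) if j != i))

    def mean_se(xs: list[float]) -> tuple[float, float]:
        if not xs:
            return float("nan"), float("nan")
        if len(xs) == 1:
            return float(xs[0]), 0.0
        return float(np.mean(xs)), float(np.std(xs, ddof=1) / math.sqrt(len(xs)))

    wm, wse = mean_se(weak_d)
    sm, sse = mean_se(strong_d)
    return SupportProfile(wm, wse, sm, sse, nearest)
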