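import numpy as np
import pytest

from lucfam.caller import (
    CandidateHaplotype,
    FilterConfig,
    artifact_indel_filter,
    call_candidates,
    call_haplotypes,
    frequency_rescue_filter,
    length_filter,
    support_profile,
)
from lucfam.seq import NucSequence

from conftest import random_seq


def _reads(seq: str, n: int, prefix: str) -> list[NucSequence]:
    return [NucSequence(f"{prefix}{i}", seq) for i in range(n)]


class TestLengthFilter:
    def test_strictly_greater_boundary(self):
        reads = [NucSequence(f"r{n}", "A" * n) for n in (149, 150, 151)]
        kept, rep = length_filter(reads, 150)
        assert [len(r) for r in kept] == [151]
        assert rep.total == 3 and rep.passed == 1

    def test_reported_run_accounting(self):
        # per-individual totals with the published number of passing reads
        rep_total = 21472 + 27189 + 29345
        from lucfam.caller import LengthReport

        rep = LengthReport(total=rep_total, passed=51047)
        assert round(rep.percent, 1) == 65.4

    def test_empty_input(self):
        kept, rep = length_filter([], 150)
        assert kept == [] and rep.fraction is None and rep.percent is None


class TestCallCandidates:
    def test_two_haplotypes_70_30(self, rng):
        ref_seq = random_seq(rng, 200)
        hap2 = list(ref_seq)
        for pos in (40, 90, 150):
            hap2[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[hap2[pos]]
        hap2 = "".join(hap2)
        reads = _reads(ref_seq, 70, "a") + _reads(hap2, 30, "b")
        call = call_candidates(reads, NucSequence("ref", ref_seq))
        assert len(call.clusters) == 2
        freqs = sorted(call.frequencies.values())
        assert freqs[0] == pytest.approx(0.3, abs=0.02)
        assert freqs[1] == pytest.approx(0.7, abs=0.02)
        assert all(p > 0.99 for p in call.posteriors.values())

    def test_all_reads_identical(self, rng):
        s = random_seq(rng, 150)
        call = call_candidates(_reads(s, 50, "r"), NucSequence("ref", s))
        assert len(call.clusters) == 1
        assert list(call.posteriors.values()) == [1.0]

    def test_singleton_error_clusters_dropped(self, rng):
        """One haplotype, 1000 reads at 0.5% substitution error: error-derived
        clusters must fall below the 0.95 posterior, the true one above."""
        true = random_seq(rng, 200)
        reads = []
        for i in range(1000):
            s = list(true)
            for c in range(len(s)):
                if rng.random() < 0.005:
                    s[c] = "ACGT"[rng.integers(4)]
            reads.append(NucSequence(f"r{i}", "".join(s)))
        call = call_candidates(reads, NucSequence("ref", true))
        key_true = (true, ())
        assert call.posteriors[key_true] > 0.95
        single_errors = [
            k for k, n in call.clusters.items() if n == 1 and k != key_true
        ]
        assert single_errors
        assert all(call.posteriors[k] < 0.95 for k in single_errors)


def _candidate(seq, ins=(), counts=None, posts=None):
    counts = counts or {"s1": 10}
    posts = posts or {s: 0.99 for s in counts}
    c = CandidateHaplotype(
        sequence=seq, insertions=tuple(ins), read_count=sum(counts.values()),
        sample_counts=dict(counts), posteriors=dict(posts),
    )
    for s, p in posts.items():
        c._detections[s] = p > 0.95
    return c


class TestArtifactIndelFilter:
    def setup_method(self):
        self.ref = NucSequence("ref", "ACGTAC" * 20)

    def test_novel_short_deletion_rejected(self):
        cand = _candidate("ACG-AC" + "ACGTAC" * 19)
        artifact_indel_filter([cand], [], self.ref)
        assert cand.status == "REJECTED"
        assert cand.reject_reason == "artifact_indel"

    def test_deletion_matching_trusted_clone_retained(self):
        trusted = NucSequence("t", "ACGAC" + "ACGTAC" * 19)  # same 1 bp deletion
        cand = _candidate("ACG-AC" + "ACGTAC" * 19)
        artifact_indel_filter([cand], [trusted], self.ref)
        assert cand.status == "CANDIDATE"

    def test_long_deletion_not_an_artifact(self):
        # 30 bp deletions are real structural variants, not sequencer noise
        seq = "ACGTAC" * 5 + "-" * 30 + "ACGTAC" * 10
        cand = _candidate(seq)
        artifact_indel_filter([cand], [], self.ref)
        assert cand.status == "CANDIDATE"


class TestFrequencyRescue:
    def setup_method(self):
        self.ref = NucSequence("ref", "ACGTAC" * 20)
        self.major = _candidate(self.ref.residues, counts={"s1": 90, "s2": 90},
                                posts={"s1": 0.99, "s2": 0.99})

    def test_low_frequency_single_sample_rejected(self):
        minor_seq = "T" + self.ref.residues[1:]
        minor = _candidate(minor_seq, counts={"s1": 10}, posts={"s1": 0.99})
        frequency_rescue_filter([self.major, minor], [], self.ref)
        assert minor.status == "REJECTED"
        assert minor.reject_reason == "low_frequency"

    def test_multi_sample_rescue(self):
        minor_seq = "T" + self.ref.residues[1:]
        minor = _candidate(minor_seq, counts={"s1": 10, "s2": 10},
                           posts={"s1": 0.99, "s2": 0.99})
        frequency_rescue_filter([self.major, minor], [], self.ref)
        assert minor.status == "RESCUED"
        assert "multi_sample" in minor.flags

    def test_trusted_clone_rescue(self):
        minor_seq = "T" + self.ref.residues[1:]
        minor = _candidate(minor_seq, counts={"s1": 10}, posts={"s1": 0.99})
        pcs = [NucSequence("clone", minor_seq)]
        frequency_rescue_filter([self.major, minor], pcs, self.ref)
        assert minor.status == "RESCUED"
        assert "pcs_confirmed" in minor.flags

    def test_above_threshold_accepted(self):
        minor_seq = "T" + self.ref.residues[1:]
        minor = _candidate(minor_seq, counts={"s1": 30}, posts={"s1": 0.99})
        frequency_rescue_filter([self.major, minor], [], self.ref)
        assert minor.status == "ACCEPTED"


class TestFilterChainInvariants:
    def _simulate_and_call(self, seed, min_posterior=0.95, min_frequency=0.15):
        from lucfam.simulate import ReadErrorModel, SimulationConfig, simulate_all

        cfg = SimulationConfig(
            seed=seed, chimera_rate=0.0, uniform_coverage=True,
            read_error=ReadErrorModel(0.005, 0.0), reads_per_sample=150,
        )
        fams, reads, truth = simulate_all(cfg)
        w = cfg.amplicon_windows[0]
        ref = NucSequence(
            "ref", fams[0].members[0].residues[w[0] - 1 : w[1]].replace("-", "")
        )
        fc = FilterConfig(min_posterior=min_posterior, min_frequency=min_frequency)
        return call_haplotypes({i: reads[i][1] for i in reads}, ref, config=fc)

    def test_counts_reconcile(self):
        res = self._simulate_and_call(21)
        rep = res.report
        assert rep["candidates"] == (
            rep["accepted"] + rep["rescued"] + sum(rep["rejected"].values())
        )
        for c in res.rejected:
            assert c.reject_reason is not None

    def test_monotone_in_posterior_and_frequency(self):
        base = {c.key() for c in self._simulate_and_call(22).passing}
        stricter_post = {
            c.key() for c in self._simulate_and_call(22, min_posterior=0.999).passing
        }
        stricter_freq = {
            c.key() for c in self._simulate_and_call(22, min_frequency=0.3).passing
        }
        assert stricter_post <= base
        assert stricter_freq <= base


class TestSupportProfile:
    def test_weak_identical_to_strong_distance_zero(self):
        strong = [NucSequence("a", "ACGTACGT"), NucSequence("b", "ACGTACGA")]
        weak = [NucSequence("w", "ACGTACGT")]
        prof = support_profile(weak, strong)
        assert prof.weak_nearest["w"] == ("a", 0)

    def test_error_derivatives_sit_one_step_away(self, rng):
        base = random_seq(rng, 100)
        strong = []
        for i in range(4):
            s = list(base)
            for c in rng.choice(100, size=6, replace=False):
                s[c] = "ACGT"[rng.integers(4)]
            strong.append(NucSequence(f"s{i}", "".join(s)))
        weak = []
        for i, s in enumerate(strong):
            w = list(s.residues)
            pos = int(rng.integers(100))
            w[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[w[pos]]
            weak.append(NucSequence(f"w{i}", "".join(w)))
        prof = support_profile(weak, strong)
        assert prof.weak_mean == pytest.approx(1.0, abs=0.01)
        assert prof.weak_mean < prof.strong_mean

    def test_true_rare_alleles_match_strong_profile(self, rng):
        """Weak haplotypes drawn from the same mutational process as strong
        ones have comparable nearest-neighbour distances."""
        base = random_seq(rng, 200)

        def derive():
            s = list(base)
            for c in rng.choice(200, size=4, replace=False):
                s[c] = "ACGT"[rng.integers(4)]
            return "".join(s)

        strong = [NucSequence(f"s{i}", derive()) for i in range(6)]
        weak = [NucSequence(f"w{i}", derive()) for i in range(6)]
        prof = support_profile(weak, strong)
        assert prof.weak_mean == pytest.approx(prof.strong_mean, rel=0.6)

    def test_fewer_than_two_strong_is_null(self):
        assert support_profile([], [NucSequence("a", "ACGT")]) is None
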