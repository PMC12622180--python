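"""End-to-end orchestration: simulate -> call -> classify -> popgen -> tree.

A single seed fans out to per-stage seeds through ``numpy.random.SeedSequence``
(the simulator derives its own stage streams the same way), so identical
configuration plus seed yields byte-identical outputs and each stage can be
re-run independently.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import popgen
from .caller import CallResult, FilterConfig, call_haplotypes
from .families import (
    FamilyPanel,
    assign_family,
    detect_mosaic,
    diagnostic_sites,
    exclude_recombinants,
)
from .phylo import bootstrap, clade_support, write_newick
from .seq import (
    AlignedSet,
    GeneModel,
    NucSequence,
    classify_sites,
    restrict,
    write_fasta,
    write_fastq,
)
from .simulate import ReadErrorModel, SimulationConfig, simulate_all


@dataclass
class RunConfig:
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    filters: FilterConfig = field(default_factory=FilterConfig)
    min_run: int = 3  # mosaic screen: concordant diagnostic sites per segment
    ts_tv: float = 2.0
    gamma_a: float = 1.0
    bootstrap_reps: int = 1000
    analysis_window: tuple[int, int] | None = None
    run_popgen: bool = True
    run_tree: bool = True

    def __post_init__(self) -> None:
        self.simulation.seed = self.seed

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim_raw = raw.pop("simulation", {})
        gm = sim_raw.pop("gene_model", None)
        if gm is not None:
            sim_raw["gene_model"] = GeneModel(
                [tuple(iv) for iv in gm["exons"]], gm.get("frame_offset", 0)
            )
        err = sim_raw.pop("read_error", None)
        if err is not None:
            sim_raw["read_error"] = ReadErrorModel(**err)
        if "amplicon_windows" in sim_raw:
            sim_raw["amplicon_windows"] = [tuple(w) for w in sim_raw["amplicon_windows"]]
        filt = raw.pop("filters", {})
        if "analysis_window" in raw and raw["analysis_window"] is not None:
            raw["analysis_window"] = tuple(raw["analysis_window"])
        return cls(
            simulation=SimulationConfig(**sim_raw),
            filters=FilterConfig(**filt),
            **raw,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class RunReport:
    config: dict
    stages: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {"config": self.config, "stages": self.stages},
            indent=2,
            default=_jsonable,
        )


def _jsonable(obj):
    if isinstance(obj, (set, tuple)):
        return list(obj)
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    if hasattr(obj, "item"):
        return obj.item()
    return str(obj)


def candidates_table(result: CallResult) -> pd.DataFrame:
    rows = []
    for i, c in enumerate(result.candidates, start=1):
        rows.append(
            {
                "candidate": f"C{i}",
                "status": c.status,
                "reject_reason": c.reject_reason or "",
                "reads": c.read_count,
                "posterior": round(c.posterior, 4),
                "flags": ",".join(sorted(c.flags)),
                **{f"reads_{s}": n for s, n in sorted(c.sample_counts.items())},
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig, outdir: str | Path) -> RunReport:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=config.to_dict())
    (outdir / "config.json").write_text(json.dumps(config.to_dict(), indent=2, default=_jsonable))

    # --- simulate -----------------------------------------------------------
    sim = config.simulation
    families, reads, truth = simulate_all(sim)
    site_map = classify_sites(sim.alignment_length, sim.gene_model)
    for f, fam in enumerate(families, start=1):
        write_fasta(fam.members, outdir / f"family{f}_haplotypes.fasta")
    for ind in reads:
        for f in reads[ind]:
            write_fastq(reads[ind][f], outdir / f"reads_{ind}_F{f}.fastq")
    (outdir / "truth_reads.tsv").write_text(truth.reads_table())
    report.stages["simulate"] = {
        "families": len(families),
        "haplotypes": len(truth.haplotypes),
        "individuals": len(truth.inventories),
        "reads": len(truth.reads),
        "chimeric_reads": sum(1 for r in truth.reads if r.breakpoint is not None),
    }

    # --- call ---------------------------------------------------------------
    called: dict[int, CallResult] = {}
    called_sets: dict[int, list[NucSequence]] = {}
    call_stage = {}
    for f in range(1, sim.n_families + 1):
        window = sim.amplicon_windows[f - 1]
        ref = NucSequence(
            f"F{f}_ref",
            families[f - 1].members[0].residues[window[0] - 1 : window[1]].replace("-", ""),
        )
        reads_by_sample = {ind: reads[ind][f] for ind in reads}
        trusted = families[f - 1].members  # clone-verified panel
        win_aln, win_model = restrict(families[f - 1], window, sim.gene_model)
        win_map = classify_sites(win_aln.length, win_model) if win_model else None
        result = call_haplotypes(
            reads_by_sample, ref, trusted=trusted, config=config.filters, site_map=win_map
        )
        called[f] = result
        called_sets[f] = [
            NucSequence(f"F{f}_hap{i}", c.sequence)
            for i, c in enumerate(result.passing, start=1)
        ]
        candidates_table(result).to_csv(outdir / f"called_F{f}.tsv", sep="\t", index=False)
        if called_sets[f]:
            write_fasta(called_sets[f], outdir / f"called_F{f}.fasta")
        call_stage[f"F{f}"] = result.report
    report.stages["call"] = call_stage

    # --- classify (family assignment + mosaic screen) -----------------------
    panel = FamilyPanel({f"F{f}": families[f - 1] for f in range(1, sim.n_families + 1)})
    classify_stage = {}
    kept_by_family: dict[int, list[NucSequence]] = {}
    if sim.n_families >= 2:
        pair = (f"F{sim.n_families - 1}", f"F{sim.n_families}")
        sites = diagnostic_sites(panel, pair)
        calls = []
        all_haps = [m for fam in families for m in fam.members]
        for hap in all_haps:
            call = assign_family(hap, panel)
            mos = detect_mosaic(hap, sites, config.min_run)
            if mos.is_mosaic:
                call = mos
            calls.append(call)
        kept, removed = exclude_recombinants(all_haps, calls)
        classify_stage = {
            "diagnostic_sites": len(sites),
            "assigned": {
                fam: sum(1 for c in calls if c.family == fam) for fam in panel.names
            },
            "mosaic_removed": removed,
        }
        for f in range(1, sim.n_families + 1):
            kept_by_family[f] = [h for h in kept if h.id.startswith(f"F{f}_")]
        pd.DataFrame(
            [
                {
                    "haplotype": c.haplotype_id,
                    "family": c.family,
                    "margin": c.margin,
                    "breakpoint": c.breakpoint,
                }
                for c in calls
            ]
        ).to_csv(outdir / "family_calls.tsv", sep="\t", index=False)
    report.stages["classify"] = classify_stage

    # --- popgen -------------------------------------------------------------
    if config.run_popgen:
        window = config.analysis_window
        stats_stage = {}
        per_family_alns = {}
        for f in range(1, sim.n_families + 1):
            members = kept_by_family.get(f) or list(families[f - 1].members)
            aln = AlignedSet(members)
            model = sim.gene_model
            if window is not None:
                aln, model = restrict(aln, window, sim.gene_model)
            fam_map = classify_sites(aln.length, model)
            per_family_alns[f] = (aln, fam_map)
            div = popgen.nucleotide_diversity(aln, fam_map, config.ts_tv)
            stats_stage[f"F{f}"] = {
                "n": div.n,
                "S": div.S,
                "Hd": div.Hd,
                "pi_silent": div.pi_silent,
                "pi_nonsyn": div.pi_nonsyn,
                "tajima_D": div.tajima_D,
            }
        for f in range(1, sim.n_families):
            a, amap = per_family_alns[f]
            b, _ = per_family_alns[f + 1]
            k = popgen.divergence(a, b, amap, config.ts_tv)
            stats_stage[f"K_F{f}_F{f + 1}"] = {
                "K_silent": k.K_silent,
                "K_nonsyn": k.K_nonsyn,
                "ka_ks": k.ka_ks,
            }
        if sim.n_families >= 2:
            a, amap = per_family_alns[sim.n_families - 1]
            b, _ = per_family_alns[sim.n_families]
            mk = popgen.mk_test(a, b, amap)
            stats_stage["mk_test"] = {
                "Dn": mk.Dn,
                "Ds": mk.Ds,
                "Pn": mk.Pn,
                "Ps": mk.Ps,
                "p_value": mk.p_value,
                "neutrality_index": mk.neutrality_index,
            }
        report.stages["popgen"] = stats_stage
        pd.DataFrame(
            [{"group": k, **v} for k, v in stats_stage.items() if isinstance(v, dict)]
        ).to_csv(outdir / "popgen.tsv", sep="\t", index=False)

    # --- tree ---------------------------------------------------------------
    if config.run_tree and sum(len(f) for f in families) >= 4:
        allhaps = AlignedSet([m for fam in families for m in fam.members])
        boot = bootstrap(
            allhaps,
            site_map,
            n_reps=config.bootstrap_reps,
            seed=config.seed,
            R=config.ts_tv,
            gamma_a=config.gamma_a,
        )
        write_newick(boot.tree, outdir / "tree.nwk")
        report.stages["tree"] = {
            "replicates": boot.n_replicates,
            "dropped_replicates": boot.n_dropped,
            "family_support": {
                f"F{f}": clade_support(
                    boot, {m.id for m in families[f - 1].members}
                )
                for f in range(1, sim.n_families + 1)
            },
        }

    (outdir / "report.json").write_text(report.to_json())
    return report
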