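"""End-to-end orchestration: simulate (or load) -> call -> validate ->
diversity -> site selection, with a consolidated, reproducible report.

Every stage writes its outputs under the run directory; the report is
serialized as JSON (sorted keys) plus TSV tables so a fixed seed gives a
byte-identical rerun.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as _io
from .calling import CallingConfig, CallingResult, run_calling
from .diversity import build_codon_alignment, diversity_summary
from .frame import PBR_EXON3_DNDS
from .selection import run_selection
from .simulate import SimulationConfig, TruthTable, simulate
from .validate import AlleleCall, align_exon3, validate_alleles

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    outdir: Path = Path("wadermhc-run")
    seed: int = 0
    simulation: SimulationConfig | None = None  # None -> load sample_sheet
    sample_sheet: Path | None = None
    calling: CallingConfig = field(default_factory=CallingConfig)
    pbr_mask: frozenset[int] = PBR_EXON3_DNDS
    bootstrap_reps: int = 1000
    p_threshold: float = 0.1
    write_reads: bool = False  # also materialize simulated reads as FASTA

    def __post_init__(self) -> None:
        if self.simulation is None and self.sample_sheet is None:
            raise ValueError("either a simulation config or a sample sheet is required")


def summarize_genotypes(
    genotypes: dict[str, set[str]], length_classes: dict[str, str]
) -> dict:
    """Per-individual long/short counts and population allele frequencies."""
    per_ind = {}
    for ind, alleles in sorted(genotypes.items()):
        n_long = sum(length_classes.get(a) == "long" for a in alleles)
        n_short = sum(length_classes.get(a) == "short" for a in alleles)
        per_ind[ind] = {"total": len(alleles), "long": n_long, "short": n_short}
    totals = [v["total"] for v in per_ind.values()]
    n_ind = len(per_ind)
    freq = {}
    for alleles in genotypes.values():
        for a in alleles:
            freq[a] = freq.get(a, 0) + 1
    frequencies = {
        a: {"count": c, "frequency": c / n_ind if n_ind else 0.0,
            "length_class": length_classes.get(a, "unknown")}
        for a, c in sorted(freq.items())
    }
    def _stats(values):
        if not values:
            return {"min": 0, "max": 0, "mean": 0.0, "sd": 0.0}
        return {
            "min": int(min(values)),
            "max": int(max(values)),
            "mean": round(float(np.mean(values)), 4),
            "sd": round(float(np.std(values, ddof=1)), 4) if len(values) > 1 else 0.0,
        }
    long_counts = [v["long"] for v in per_ind.values()]
    short_counts = [v["short"] for v in per_ind.values() if v["short"] > 0]
    return {
        "n_individuals": n_ind,
        "alleles_per_individual": _stats(totals),
        "long_per_individual": _stats(long_counts),
        "short_per_carrier": _stats(short_counts),
        "n_individuals_long_only": sum(1 for v in per_ind.values() if v["short"] == 0),
        "n_individuals_with_short": sum(1 for v in per_ind.values() if v["short"] > 0),
        "per_individual": per_ind,
        "allele_frequencies": frequencies,
    }


def _dnds_row(r) -> dict:
    return {
        "partition": r.partition, "dN": round(r.dn, 4), "dN_SE": round(r.dn_se, 4),
        "dS": round(r.ds, 4), "dS_SE": round(r.ds_se, 4),
        "dN_dS": round(r.ratio, 4) if r.ds > 0 else None,
        "n": r.n, "z_p_value": round(r.z_p_value, 4),
    }


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage and return the consolidated report (also written to
    ``<outdir>/report.json``)."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": cfg.seed}

    # --- stage 1: data ---
    truth: TruthTable | None = None
    if cfg.simulation is not None:
        sim_cfg = cfg.simulation
        amplicons, truth = simulate(sim_cfg)
        if cfg.write_reads:
            from .simulate import write_simulation

            write_simulation(amplicons, truth, outdir / "simulated", sim_cfg)
    else:
        sheet = _io.read_sample_sheet(cfg.sample_sheet)
        amplicons = _io.read_amplicons(sheet)
    report["n_amplicons_in"] = len(amplicons)

    # --- stage 2: calling cascade ---
    result: CallingResult = run_calling(amplicons, cfg.calling)
    clustered = result.clustered
    n_merged = sum(len(c.merged) for ca in clustered for c in ca.clusters)
    chimera_freqs = [
        c.frequency for ca in clustered for c in ca.clusters if "chimera" in c.flags
    ]
    report["calling"] = {
        "n_amplicons_dropped": len(result.dropped_amplicons),
        "dropped": result.dropped_amplicons,
        "threshold": round(result.threshold, 4),
        "n_variants_merged": n_merged,
        "n_subdominant_clusters": sum(
            1 for ca in clustered for c in ca.clusters if "subdominant" in c.flags
        ),
        "n_chimera_clusters": len(chimera_freqs),
        "max_chimera_frequency": round(max(chimera_freqs), 4) if chimera_freqs else 0.0,
        "duplicate_concordance": result.duplicate_concordance,
    }
    if result.calibration_curve:
        pd.DataFrame(result.calibration_curve).to_csv(
            outdir / "calibration_curve.tsv", sep="\t", index=False
        )

    # --- stage 3: validation and naming ---
    ordered = sorted(result.allele_depths, key=lambda s: (-result.allele_depths[s], s))
    calls: list[AlleleCall] = validate_alleles(ordered)
    by_seq = {c.sequence: c for c in calls}
    valid = [c for c in calls if c.length_class in ("long", "short") and c.functional]
    report["alleles"] = {
        "n_called": len(calls),
        "n_valid": len(valid),
        "n_long": sum(c.length_class == "long" for c in valid),
        "n_short": sum(c.length_class == "short" for c in valid),
        "n_rejected": len(calls) - len(valid),
        "n_protein_classes": len({c.protein for c in valid}),
    }
    _io.write_fasta(
        [_io.SequenceRecord(c.name, c.sequence) for c in valid],
        outdir / "alleles.fasta",
    )
    allele_table = pd.DataFrame([
        {
            "name": c.name, "length_class": c.length_class,
            "protein_class": c.protein_class_id,
            "residue_170": c.motifs.residue_170 if c.motifs else None,
            "EDGTV_147_151": c.motifs.has_edgtv_147_151 if c.motifs else None,
            "GENE_148_151": c.motifs.has_gene_148_151 if c.motifs else None,
            "main_chain_deviations": ";".join(
                f"{p}{e}>{f}" for p, e, f in c.motifs.main_chain_deviations
            ) if c.motifs else None,
            "functional": c.functional,
            "rejection_reason": c.rejection_reason,
        }
        for c in calls
    ])
    allele_table.to_csv(outdir / "alleles.tsv", sep="\t", index=False)

    genotypes_named = {
        ind: {by_seq[s].name for s in g.alleles if s in by_seq and by_seq[s].functional
              and by_seq[s].length_class in ("long", "short")}
        for ind, g in result.genotypes.items()
    }
    _io.write_genotype_table(genotypes_named, outdir / "genotypes.tsv")
    length_classes = {c.name: c.length_class for c in valid}
    report["genotype_summary"] = summarize_genotypes(genotypes_named, length_classes)

    # --- truth comparison for simulated runs ---
    if truth is not None:
        ok = 0
        evaluated = 0
        for ind, g in result.genotypes.items():
            evaluated += 1
            if g.alleles == frozenset(truth.genotype_sequences(ind)):
                ok += 1
        report["truth"] = {
            "n_individuals_scored": evaluated,
            "exact_genotype_recovery": round(ok / evaluated, 4) if evaluated else None,
        }

    # --- stage 4: diversity / divergence ---
    aligned = align_exon3([_io.SequenceRecord(c.name, c.sequence) for c in valid])
    sets = {"all": aligned}
    long_ids = {c.name for c in valid if c.length_class == "long"}
    short_ids = {c.name for c in valid if c.length_class == "short"}
    if len(long_ids) >= 2:
        sets["long"] = [r for r in aligned if r.id in long_ids]
    if len(short_ids) >= 2:
        sets["short"] = [r for r in aligned if r.id in short_ids]
    diversity_report = {}
    table_rows = []
    for label, records in sets.items():
        div, pbr, non = diversity_summary(
            records, cfg.pbr_mask, cfg.bootstrap_reps, cfg.seed
        )
        diversity_report[label] = {
            "S_nt": div.s_nt, "S_aa": div.s_aa, "pi": round(div.pi, 4),
            "d_nt": round(div.d_nt, 4), "d_nt_SE": round(div.d_nt_se, 4),
            "d_aa": round(div.d_aa, 4), "d_aa_SE": round(div.d_aa_se, 4),
            "n_nt": div.n_nt, "n_aa": div.n_aa,
            "PBR": _dnds_row(pbr), "non_PBR": _dnds_row(non),
        }
        for r in (pbr, non):
            table_rows.append({"set": label, **_dnds_row(r),
                               "S_aa": div.s_aa, "pi": round(div.pi, 4)})
    report["diversity"] = diversity_report
    pd.DataFrame(table_rows).to_csv(outdir / "diversity.tsv", sep="\t", index=False)

    # --- stage 5: per-site selection ---
    if len(valid) >= 3:
        caln = build_codon_alignment(aligned)
        tree, sites = run_selection(caln, cfg.p_threshold, cfg.pbr_mask)
        _io.write_newick(tree, outdir / "nj_tree.nwk")
        site_df = pd.DataFrame([
            {
                "position": s.position, "syn": round(s.obs_syn, 3),
                "nonsyn": round(s.obs_nonsyn, 3),
                "dn_minus_ds": round(s.dn_minus_ds, 4),
                "p_value": round(s.p_value, 4),
                "class": s.classification, "PBR": s.in_pbr,
            }
            for s in sites
        ])
        site_df.to_csv(outdir / "site_selection.tsv", sep="\t", index=False)
        positives = [s.position for s in sites if s.classification == "positive"]
        report["selection"] = {
            "n_sites": len(sites),
            "positive_sites": positives,
            "negative_sites": [
                s.position for s in sites if s.classification == "negative"
            ],
        }

    (outdir / "report.json").write_text(
        json.dumps(report, sort_keys=True, indent=1, default=str)
    )
    return report
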