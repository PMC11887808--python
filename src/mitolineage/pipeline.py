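"""End-to-end orchestration: simulate -> call -> classify -> shift ->
signatures -> clonal -> stats -> report.

Every stage writes self-describing TSVs ('#key=value' headers carrying
the package version, config hash and seed) into one output directory;
a MANIFEST file records stage completion so partial runs are
detectable. Identical config + seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, calling, clonal, lineage, signatures, stats
from .reference import CircularReference
from .simulate import (
    SimulationConfig,
    default_annotation,
    run_simulation,
    sequence_all,
    write_run,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of an end-to-end run."""

    outdir: str = "mitolineage_run"
    seed: int = 0
    hf_threshold: float = 0.005
    min_depth: int = 50
    min_run: int = 5  # homopolymer run length
    high_hf_threshold: float = 0.6
    alpha: float = 0.05
    catalog_path: str | None = None
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self) -> None:
        if not 0 <= self.hf_threshold <= 1:
            raise ValueError("hf_threshold must be in [0, 1]")
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")
        self.simulation.seed = self.seed

    def config_hash(self) -> str:
        d = asdict(self)
        d.pop("outdir", None)  # hash covers analysis parameters, not paths
        d["simulation"]["signature_weights"] = [
            round(float(x), 12) for x in self.simulation.signature_weights
        ]
        return hashlib.sha256(
            json.dumps(d, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def demo_config(outdir: str = "mitolineage_demo", seed: int = 0) -> RunConfig:
    """A small configuration (~30 cells, 3 kb genome) that exercises
    every stage in well under five minutes on one CPU."""
    sim = SimulationConfig(
        seed=seed,
        n_cells={f"{cond}.{ct}": 5 for cond in ("ctrl", "mutant")
                 for ct in ("ipsc", "astroglia", "neuron")},
        genome_length=3000,
        t_expansion=10,
        t_differentiation=15,
    )
    return RunConfig(outdir=outdir, seed=seed, simulation=sim)


def _meta(config: RunConfig) -> dict:
    return {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "L_strand": "FASTA sequence (flippable by convention)",
    }


def run_end_to_end(config: RunConfig) -> dict:
    """Run every stage; returns a summary dict (also written to disk)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = outdir / "MANIFEST"
    done: list[str] = []

    def mark(stage: str) -> None:
        done.append(stage)
        manifest_path.write_text(
            "\n".join(done) + "\ncomplete=false\n"
        )

    meta = _meta(config)
    summary: dict = {"seed": config.seed, "config_hash": meta["config_hash"]}

    try:
        # --- simulate -------------------------------------------------
        result = run_simulation(config.simulation)
        tables = sequence_all(result)
        write_run(result, tables, outdir)
        annot = default_annotation(result.reference.length)
        annot.to_tsv(outdir / "annotation.tsv")
        mark("simulate")

        # --- call -----------------------------------------------------
        mask = result.reference.find_homopolymers(min_run=config.min_run)
        all_calls = []
        for cell in sorted(result.cells, key=lambda c: c.cell_id):
            calls = calling.call_variants(
                tables[cell.cell_id], mask,
                hf_threshold=config.hf_threshold, min_depth=config.min_depth,
            )
            calls.insert(1, "condition", cell.condition)
            calls.insert(2, "cell_type", cell.cell_type)
            all_calls.append(calls)
        calls = pd.concat(all_calls, ignore_index=True) if all_calls else pd.DataFrame(
            columns=["cell_id", "condition", "cell_type", "pos", "ref", "alt",
                     "hf_run1", "hf_run2", "hf", "depth_run1", "depth_run2",
                     "filters", "pass"]
        )
        calling.write_calls(calls, outdir / "calls.tsv", meta)
        passing = calls[calls["pass"]] if not calls.empty else calls
        if not passing.empty:
            r2 = calling.replicate_r2(passing["hf_run1"], passing["hf_run2"])
        else:
            r2 = float("nan")
        summary["n_calls_pass"] = int(len(passing))
        summary["replicate_r2"] = r2
        mark("call")

        # --- lineage + shift -----------------------------------------
        shift_frames, lineage_frames, burden_frames, fate_frames = [], [], [], []
        spectra: dict[str, signatures.SubstitutionSpectrum] = {}
        for condition in ("ctrl", "mutant"):
            cond_calls = passing[passing["condition"] == condition] if not passing.empty else passing
            ipsc_calls = cond_calls[cond_calls["cell_type"] == "ipsc"] if not cond_calls.empty else cond_calls
            founder = lineage.build_founder_set(
                ipsc_calls, line_id=condition, allow_empty=True
            )
            summary[f"founder_size_{condition}"] = len(founder)
            org_calls = cond_calls[cond_calls["cell_type"] != "ipsc"] if not cond_calls.empty else cond_calls
            if len(founder) and not org_calls.empty:
                fate = lineage.founder_fate(founder, org_calls)
                fate.insert(0, "condition", condition)
                fate_frames.append(fate)
            for cell_type in ("astroglia", "neuron"):
                ct_calls = org_calls[org_calls["cell_type"] == cell_type] if not org_calls.empty else org_calls
                group = f"{condition}.{cell_type}"
                if ct_calls.empty:
                    continue
                classified = lineage.classify(ct_calls, founder)
                fractions = lineage.cell_fractions(classified)
                fractions.insert(0, "group", group)
                lineage_frames.append(fractions)
                if len(founder):
                    shifts = lineage.heteroplasmy_shift(founder, ct_calls)
                    shifts.insert(0, "group", group)
                    shift_frames.append(shifts)
                de_novo = classified[classified["lineage_class"] == "de_novo"]
                if not de_novo.empty:
                    spectra[group] = signatures.build_spectrum(
                        list(zip(de_novo["pos"], de_novo["ref"], de_novo["alt"])),
                        result.reference, normalize=True, label=group,
                    )
            counts, _ = lineage.burden_metrics(cond_calls)
            if not counts.empty:
                counts.insert(0, "condition", condition)
                burden_frames.append(counts)
            if not ipsc_calls.empty:
                spectra[f"{condition}.ipsc"] = signatures.build_spectrum(
                    list(zip(ipsc_calls["pos"], ipsc_calls["ref"], ipsc_calls["alt"])),
                    result.reference, normalize=True, label=f"{condition}.ipsc",
                )
        empty_cols = {
            "lineage.tsv": ["group", "cell_id", "n_variants", "n_shared",
                            "n_de_novo", "frac_shared", "frac_de_novo"],
            "burden.tsv": ["condition", "cell_id", "n_variants"],
            "shift.tsv": ["group", "cell_id", "pos", "alt", "hf_ipsc",
                          "hf_cell", "ahs", "nhs"],
            "founder_fate.tsv": ["condition", "pos", "alt", "founder_hf",
                                 "carriers", "fate"],
        }
        for frames, name in [
            (lineage_frames, "lineage.tsv"),
            (burden_frames, "burden.tsv"),
            (shift_frames, "shift.tsv"),
            (fate_frames, "founder_fate.tsv"),
        ]:
            df = (pd.concat(frames, ignore_index=True) if frames
                  else pd.DataFrame(columns=empty_cols[name]))
            lineage.write_tsv(df, outdir / name, meta)
        if shift_frames:
            shifts_all = pd.concat(shift_frames, ignore_index=True)
            summary["mean_nhs"] = float(shifts_all["nhs"].mean())
        if lineage_frames:
            lin_all = pd.concat(lineage_frames, ignore_index=True)
            summary["mean_frac_de_novo"] = float(lin_all["frac_de_novo"].mean())
        mark("lineage")
        mark("shift")

        # --- signatures -----------------------------------------------
        if config.catalog_path:
            catalog = signatures.SignatureCatalog.from_csv(config.catalog_path)
        else:
            catalog = signatures.SignatureCatalog.synthetic()
        corr_frames = []
        for group, spec in sorted(spectra.items()):
            corr = signatures.correlate_catalog(spec, catalog)
            corr.insert(0, "group", group)
            corr_frames.append(corr)
        corr_all = pd.concat(corr_frames, ignore_index=True) if corr_frames else pd.DataFrame()
        lineage.write_tsv(corr_all, outdir / "signature_correlations.tsv", meta)
        if spectra:
            pd.DataFrame({g: s.to_series() for g, s in sorted(spectra.items())}).to_csv(
                outdir / "spectra.tsv", sep="\t"
            )
            top = {
                g: corr_all[corr_all["group"] == g].iloc[0]["signature"]
                for g in sorted(spectra)
            }
            summary["top_signature"] = top
        mark("signatures")

        # --- clonal ---------------------------------------------------
        flags_frames = []
        for condition in ("ctrl", "mutant"):
            for cell_type in ("astroglia", "neuron"):
                group_cells = [
                    c.cell_id for c in result.cells_of(condition, cell_type)
                ]
                grp_calls = passing[passing["cell_id"].isin(group_cells)] if not passing.empty else passing
                matrix = clonal.build_hf_matrix(grp_calls, cells=group_cells)
                clonal.write_matrix(
                    matrix, outdir / f"hf_matrix.{condition}.{cell_type}.tsv"
                )
                if len(matrix) >= 2 and matrix.shape[1] > 0:
                    cr = clonal.cluster_cells(matrix)
                    (outdir / f"dendrogram.{condition}.{cell_type}.nwk").write_text(
                        cr.to_newick() + "\n"
                    )
                flags = clonal.flag_high_hf(
                    matrix, threshold=config.high_hf_threshold, annot=annot
                )
                if not flags.empty:
                    flags.insert(0, "group", f"{condition}.{cell_type}")
                    flags_frames.append(flags)
        flags_all = pd.concat(flags_frames, ignore_index=True) if flags_frames else pd.DataFrame()
        lineage.write_tsv(flags_all, outdir / "high_hf_flags.tsv", meta)
        summary["n_high_hf_flags"] = int(len(flags_all))
        mark("clonal")

        # --- stats ----------------------------------------------------
        tests: dict[str, stats.TestResult] = {}
        if not passing.empty:
            groups = {
                g: grp["hf"].to_numpy()
                for g, grp in passing.groupby(
                    passing["condition"] + "." + passing["cell_type"]
                )
            }
            pairs = [
                ("ctrl.astroglia", "mutant.astroglia"),
                ("ctrl.neuron", "mutant.neuron"),
                ("ctrl.ipsc", "mutant.ipsc"),
            ]
            for a, b in pairs:
                if a in groups and b in groups:
                    tests[f"hf_ks:{a}-vs-{b}"] = stats.ks_two_sample(groups[a], groups[b])
                    tests[f"hf_ranksum:{a}-vs-{b}"] = stats.rank_sum(groups[a], groups[b])
            burden_groups = {
                g: grp.groupby("cell_id").size().to_numpy(dtype=float)
                for g, grp in passing.groupby(
                    passing["condition"] + "." + passing["cell_type"]
                )
            }
            burden_groups = {g: v for g, v in burden_groups.items() if v.size >= 2}
            if len(burden_groups) >= 2:
                an = stats.anova_tukey(burden_groups)
                tests["burden_anova"] = stats.TestResult(
                    an.F, an.p, "anova_oneway", an.n
                )
                an.tukey.to_csv(outdir / "burden_tukey.tsv", sep="\t", index=False)
        if shift_frames:
            shifts_all = pd.concat(shift_frames, ignore_index=True)
            by_group = {g: grp["nhs"].to_numpy() for g, grp in shifts_all.groupby("group")}
            keys = sorted(by_group)
            for i, a in enumerate(keys):
                for b in keys[i + 1:]:
                    tests[f"nhs_ks:{a}-vs-{b}"] = stats.ks_two_sample(
                        by_group[a], by_group[b]
                    )
        stats.write_results(tests, outdir / "stats.tsv")
        summary["n_tests"] = len(tests)
        mark("stats")

        # --- report ---------------------------------------------------
        lines = [f"mitolineage {__version__} end-to-end summary",
                 f"seed={config.seed} config_hash={meta['config_hash']}", ""]
        for k, v in summary.items():
            lines.append(f"{k}: {v}")
        (outdir / "summary.txt").write_text("\n".join(lines) + "\n")
        (outdir / "summary.json").write_text(
            json.dumps(summary, indent=2, default=str) + "\n"
        )
        done.append("report")
        manifest_path.write_text("\n".join(done) + "\ncomplete=true\n")
    except Exception as exc:
        manifest_path.write_text(
            "\n".join(done) + f"\ncomplete=false\nfailed_after={done[-1] if done else 'start'}\n"
        )
        raise RuntimeError(
            f"pipeline failed after stage "
            f"{done[-1] if done else '(none)'}: {exc}"
        ) from exc
    return summary
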