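"""In-silico validation experiments for the whole pipeline.

Each function runs one self-contained experiment on synthetic data and
returns the measured quantities next to their independent closed-form
or ground-truth expectations: caller specificity/sensitivity against
the binomial-tail oracle, the neutral-drift variance law, recovery of
negative selection through the normalized heteroplasmy shift, recovery
of a known mutational signature, clonal-subset recovery, and type-I
calibration of the statistical battery. The experiments double as the
reproducibility entry points exposed by ``scripts/acceptance.py``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import calling, clonal, lineage, signatures, stats
from .simulate import (
    CellState,
    MutationSiteIndex,
    SimulationConfig,
    SimulationResult,
    Variant,
    acquire_mutations,
    divide,
    run_simulation,
    seed_subclone,
    sequence_all,
    sequence_cell,
    synthetic_reference,
)


def _sub_seed(seed: int, tag: int) -> int:
    """Deterministic sub-seed below 2^31."""
    return int(np.random.SeedSequence((seed, tag)).generate_state(1)[0] % 2**31)


def call_simulation(
    result: SimulationResult,
    tables: dict[str, list[calling.AlleleCountTable]],
    hf_threshold: float = 0.005,
    min_depth: int = 50,
    min_run: int = 5,
) -> pd.DataFrame:
    """Concordance-call every simulated cell; passing calls only."""
    mask = result.reference.find_homopolymers(min_run=min_run)
    frames = []
    for cell in sorted(result.cells, key=lambda c: c.cell_id):
        calls = calling.call_variants(
            tables[cell.cell_id], mask,
            hf_threshold=hf_threshold, min_depth=min_depth,
        )
        if calls.empty:
            continue
        calls.insert(1, "condition", cell.condition)
        calls.insert(2, "cell_type", cell.cell_type)
        frames.append(calls)
    if not frames:
        return pd.DataFrame(
            columns=["cell_id", "condition", "cell_type", "pos", "ref", "alt",
                     "hf_run1", "hf_run2", "hf", "depth_run1", "depth_run2",
                     "filters", "pass"]
        )
    out = pd.concat(frames, ignore_index=True)
    return out[out["pass"]].reset_index(drop=True)


def caller_error_rates(
    seed: int,
    n_cells: int = 50,
    n_sites: int = 16_500,
    depth: float = 2500.0,
    error_rate: float = 1e-3,
    hf_threshold: float = 0.005,
    true_hf: float = 0.05,
    n_true_sites: int = 10_000,
) -> dict:
    """Caller specificity and sensitivity against the binomial-tail oracle.

    Specificity arm: ``n_cells`` variant-free cells over ``n_sites``
    sites, duplicate runs at Poisson(depth) coverage and miscall rate
    ``error_rate``; the observed false-call rate is compared to the
    closed form 3 * P(Binom(depth, e/3) > thr*depth)^2 per site.
    Sensitivity arm: one cell carrying a true variant at ``true_hf`` at
    ``n_true_sites`` sites; detection fraction vs the analogous tail
    product at the error-adjusted alt fraction.
    """
    ref = synthetic_reference(n_sites, seed=_sub_seed(seed, 1))
    cfg = SimulationConfig(
        seed=seed, error_rate=error_rate, depth_mean=depth,
        depth_sdlog=1e-9, n_runs=2, genome_length=n_sites,
    )
    rng = np.random.default_rng(_sub_seed(seed, 2))

    false_calls = 0
    for i in range(n_cells):
        cell = CellState(f"null{i:03d}", "ipsc", "ctrl", 100, {})
        tables = sequence_cell(cell, ref, cfg, rng)
        calls = calling.call_variants(
            tables, mask=frozenset(), hf_threshold=hf_threshold, min_depth=1
        )
        false_calls += len(calls)
    n_null_sites = n_cells * n_sites
    false_rate = false_calls / n_null_sites
    d = int(depth)
    p_one_run = float(sps.binom.sf(int(np.floor(hf_threshold * d)), d,
                                   error_rate / 3.0))
    expected_false = 3.0 * p_one_run**2
    se_false = float(np.sqrt(max(expected_false * (1 - expected_false), 1e-300)
                             / n_null_sites))

    rng2 = np.random.default_rng(_sub_seed(seed, 3))
    positions = rng2.choice(n_sites, size=n_true_sites, replace=False) + 1
    N = 10_000
    genotype = {}
    for pos in positions:
        ref_base = ref.base(int(pos))
        alt = "G" if ref_base != "G" else "T"
        genotype[Variant(int(pos), ref_base, alt)] = int(true_hf * N)
    cell = CellState("true000", "ipsc", "ctrl", N, genotype)
    tables = sequence_cell(cell, ref, cfg, rng2)
    calls = calling.call_variants(
        tables, mask=frozenset(), hf_threshold=hf_threshold, min_depth=1
    )
    called = set(zip(calls["pos"], calls["alt"]))
    detected = sum(
        1 for v in genotype if (v.pos, v.alt) in called
    )
    detection = detected / n_true_sites
    e = error_rate
    q = true_hf * (1 - e) + (1 - true_hf) * e / 3.0
    p_det_one = float(sps.binom.sf(int(np.floor(hf_threshold * d)), d, q))
    expected_detection = p_det_one**2

    return {
        "false_call_rate": false_rate,
        "expected_false_call_rate": expected_false,
        "false_rate_se": se_false,
        "n_null_sites": n_null_sites,
        "detection_rate": detection,
        "expected_detection_rate": expected_detection,
        "n_true_sites": n_true_sites,
    }


def drift_experiment(
    seed: int,
    N: int = 500,
    t: int = 20,
    p0: float = 0.3,
    n_cells: int = 2000,
) -> dict:
    """Neutral Wright-Fisher drift: empirical Var(HF) and mean HF after
    t divisions vs the closed form p0(1-p0)(1-(1-1/N)^t) and the
    martingale expectation p0."""
    rng = np.random.default_rng(_sub_seed(seed, 4))
    v = Variant(1, "A", "G")
    hf = np.empty(n_cells)
    for i in range(n_cells):
        cell = CellState("c", "ipsc", "ctrl", N, {v: int(round(p0 * N))})
        for _ in range(t):
            cell = divide(cell, {}, rng)
        hf[i] = cell.hf(v)
    expected_var = p0 * (1 - p0) * (1 - (1 - 1 / N) ** t)
    return {
        "var_hf": float(hf.var(ddof=1)),
        "expected_var": expected_var,
        "var_ratio": float(hf.var(ddof=1) / expected_var),
        "mean_hf": float(hf.mean()),
        "p0": p0,
        "se_mean": float(hf.std(ddof=1) / np.sqrt(n_cells)),
        "n_cells": n_cells,
    }


def _shift_arm(seed: int, s_founder: float, n_diff_cells: int) -> pd.DataFrame:
    cfg = SimulationConfig(
        seed=seed,
        n_cells={"ctrl.ipsc": 20, "ctrl.astroglia": n_diff_cells},
        genome_length=2000,
        t_expansion=10,
        t_differentiation=20,
        mu={"default": 0.0},
        s={"founder": s_founder},
        copy_number={"default": 500},
        founder_hf=(0.05, 0.35),
    )
    res = run_simulation(cfg)
    tables = sequence_all(res)
    calls = call_simulation(res, tables)
    ipsc = calls[calls["cell_type"] == "ipsc"]
    founder = lineage.build_founder_set(ipsc, line_id="ctrl", allow_empty=True)
    org = calls[calls["cell_type"] == "astroglia"]
    if len(founder) == 0 or org.empty:
        return pd.DataFrame(columns=["nhs"])
    return lineage.heteroplasmy_shift(founder, org)


def selection_recovery(
    seed: int,
    n_replicates: int = 10,
    n_diff_cells: int = 200,
    s_founder: float = -0.1,
) -> dict:
    """Negative selection on founder variants during differentiation vs a
    neutral control arm of equal size: success = mean nHS < 0 in the
    selected arm and two-sample KS p < 0.01 between the arms' nHS."""
    successes = 0
    mean_sel, mean_ctrl = [], []
    for r in range(n_replicates):
        sel = _shift_arm(_sub_seed(seed, 100 + 2 * r), s_founder, n_diff_cells)
        ctrl = _shift_arm(_sub_seed(seed, 101 + 2 * r), 0.0, n_diff_cells)
        if sel.empty or ctrl.empty:
            continue
        ks = stats.ks_two_sample(sel["nhs"], ctrl["nhs"])
        ok = (sel["nhs"].mean() < 0) and (ks.p < 0.01)
        successes += int(ok)
        mean_sel.append(sel["nhs"].mean())
        mean_ctrl.append(ctrl["nhs"].mean())
    return {
        "success_rate": successes / n_replicates,
        "n_replicates": n_replicates,
        "mean_nhs_selected": float(np.mean(mean_sel)) if mean_sel else float("nan"),
        "mean_nhs_neutral": float(np.mean(mean_ctrl)) if mean_ctrl else float("nan"),
    }


def signature_recovery(
    seed: int,
    n_replicates: int = 100,
    n_variants: int = 500,
    row_index: int = 7,
    ref=None,
    site_index=None,
) -> dict:
    """De novo variants drawn from one catalog signature; success = that
    signature ranks first in the spectrum-catalog correlation."""
    catalog = signatures.SignatureCatalog.synthetic()
    if ref is None:
        ref = synthetic_reference(16_569, seed=_sub_seed(seed, 5))
    if site_index is None:
        site_index = MutationSiteIndex(ref)
    cfg = SimulationConfig(
        seed=seed, signature_weights=catalog.matrix[row_index],
        genome_length=ref.length,
    )
    target = catalog.names[row_index]
    hits = 0
    for r in range(n_replicates):
        rng = np.random.default_rng(_sub_seed(seed, 200 + r))
        cell = CellState("c", "astroglia", "ctrl", 10**6, {})
        meta: dict = {}
        cell = acquire_mutations(
            cell, float(n_variants), cfg, site_index, rng, meta,
            "post-differentiation",
        )
        spec = signatures.build_spectrum(
            [(v.pos, v.ref, v.alt) for v in cell.genotype], ref,
            normalize=False, label="denovo",
        )
        ranked = signatures.correlate_catalog(spec, catalog)
        hits += int(ranked.iloc[0]["signature"] == target)
    return {
        "success_rate": hits / n_replicates,
        "n_replicates": n_replicates,
        "target_signature": target,
        "n_variants": n_variants,
    }


def clonal_recovery(
    seed: int,
    n_replicates: int = 20,
    n_astroglia: int = 24,
    subclone_size: int = 8,
    subclone_hf: float = 0.7,
) -> dict:
    """A planted subclone carrying a high-HF variant must come back as
    one flat cluster (cut at k=2) with every member flagged by the
    strict HF > 0.6 rule.

    Standard single-cell QC applies before lineage tracing: cells whose
    mean coverage falls below ``min_mean_depth`` cannot be genotyped at
    the calling depth filter and are excluded from the clustering
    universe; the planted site avoids the homopolymer mask (variants
    there are excluded by design)."""
    min_mean_depth = 100.0
    successes = 0
    for r in range(n_replicates):
        rep_seed = _sub_seed(seed, 300 + r)
        cfg = SimulationConfig(
            seed=rep_seed,
            n_cells={"ctrl.ipsc": 4, "ctrl.astroglia": n_astroglia},
            genome_length=2000,
            t_expansion=8,
            t_differentiation=10,
            mu={"default": 0.0},
            s={},
            n_founder_variants=4,
            copy_number={"default": 500},
        )
        res = run_simulation(cfg)
        rng = np.random.default_rng(_sub_seed(rep_seed, 1))
        astro = sorted(
            c.cell_id for c in res.cells if c.cell_type == "astroglia"
        )
        members = list(rng.choice(astro, size=subclone_size, replace=False))
        mask = res.reference.find_homopolymers(min_run=5)
        seed_subclone(res, members, hf=subclone_hf, rng=rng,
                      exclude_positions=frozenset(mask))
        tables = sequence_all(res)
        mean_depth = {
            cid: float(np.mean([t.depth.mean() for t in runs]))
            for cid, runs in tables.items()
        }
        astro = [c for c in astro if mean_depth[c] >= min_mean_depth]
        members = [c for c in members if c in set(astro)]
        if len(members) < 2:
            continue
        calls = call_simulation(res, tables)
        matrix = clonal.build_hf_matrix(
            calls[calls["cell_type"] == "astroglia"], cells=astro
        )
        if matrix.shape[1] == 0:
            continue
        cr = clonal.cluster_cells(matrix)
        clusters = cr.flat_clusters(k=2)
        member_labels = {clusters[c] for c in members}
        others = {clusters[c] for c in astro if c not in members}
        one_clade = len(member_labels) == 1 and member_labels.isdisjoint(others)
        flags = clonal.flag_high_hf(matrix, threshold=0.6)
        flagged_cells = set(flags["cell_id"]) if not flags.empty else set()
        all_flagged = set(members) <= flagged_cells
        successes += int(one_clade and all_flagged)
    return {
        "success_rate": successes / n_replicates,
        "n_replicates": n_replicates,
        "subclone_size": subclone_size,
        "subclone_hf": subclone_hf,
    }


def type_i_calibration(seed: int, n_sims: int = 10_000, alpha: float = 0.05) -> dict:
    """Null rejection rates of the statistical battery at alpha.

    Sample sizes sit in each test's near-continuous regime (rank-sum
    50/50 normal; KS 100/150 normal — unequal sizes avoid the equal-n
    lattice; Fisher 2x2 with margins 2000; ANOVA 3 x 20 normal) so the
    nominal level is meaningful rather than discreteness-bound."""
    rng = np.random.default_rng(_sub_seed(seed, 6))
    rej = {"rank_sum": 0, "ks": 0, "fisher": 0, "anova": 0}
    for _ in range(n_sims):
        if stats.rank_sum(rng.normal(size=50), rng.normal(size=50)).p < alpha:
            rej["rank_sum"] += 1
        if stats.ks_two_sample(rng.normal(size=100), rng.normal(size=150)).p < alpha:
            rej["ks"] += 1
        x1, x2 = rng.binomial(2000, 0.3, size=2)
        if stats.fisher_exact([[x1, 2000 - x1], [x2, 2000 - x2]]).p < alpha:
            rej["fisher"] += 1
        groups = {k: rng.normal(size=20) for k in "abc"}
        if stats.anova_oneway(groups).p < alpha:
            rej["anova"] += 1
    return {f"type1_{k}": v / n_sims for k, v in rej.items()} | {"n_sims": n_sims}


def replicate_agreement(seed: int) -> dict:
    """Replicate HF agreement (OLS R^2 of run 2 on run 1) on a full
    default-design simulation scaled to a 4 kb genome."""
    cfg = SimulationConfig(
        seed=_sub_seed(seed, 8),
        n_cells={f"{cond}.{ct}": 10 for cond in ("ctrl", "mutant")
                 for ct in ("ipsc", "astroglia", "neuron")},
        genome_length=4000,
        t_expansion=12,
        t_differentiation=18,
    )
    res = run_simulation(cfg)
    tables = sequence_all(res)
    calls = call_simulation(res, tables)
    r2 = calling.replicate_r2(calls["hf_run1"], calls["hf_run2"])
    return {"replicate_r2": float(r2), "n_pairs": int(len(calls))}
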