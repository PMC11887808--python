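"""Synthetic single-cell mtDNA heteroplasmy data generator.

Emulates the sequencing design of a single-cell mtDNA study of
hiPSC-derived brain organoids: per-condition founder hiPSC clones carry
a handful of heteroplasmic variants; each sampled cell descends from
its founder through clonal-expansion divisions and (for differentiated
cell types) further differentiation divisions. At every division the
intracellular population of N mtDNA copies is resampled
(Wright-Fisher style binomial resampling per variant, weight 1+s for
mutant copies), new mutations arrive as a Poisson process over a
96-class trinucleotide signature, and each final cell is sequenced in
independent replicate runs with Poisson depth and a uniform miscall
error model.

The generator's defaults are the study conditions being emulated:
three cell types (ipsc, astroglia, neuron) x two conditions
(ctrl, mutant), ~35 cells per group, duplicate runs, mean depth 2515
with a heavy-tailed (lognormal) per-cell depth distribution, founder
variants at appreciable heteroplasmy, negative selection on founder
variants during differentiation, and a higher de novo mutation rate in
mutant astroglia. Mutation rate and selection strength are not
quantities measured by single-cell sequencing itself; the defaults are
illustrative and recorded in output metadata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .calling import AlleleCountTable, BASES
from .reference import CircularReference
from . import signatures as sig

logger = logging.getLogger(__name__)

CELL_TYPES = ("ipsc", "astroglia", "neuron")
CONDITIONS = ("ctrl", "mutant")
ORIGINS = ("founder", "post-founder", "post-differentiation")

_BASE_IDX = {b: i for i, b in enumerate(BASES)}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


class Variant(NamedTuple):
    """A single-nucleotide variant on the circular reference (L strand)."""

    pos: int
    ref: str
    alt: str

    @property
    def vid(self) -> str:
        return f"{self.pos}:{self.ref}>{self.alt}"


@dataclass
class VariantInfo:
    """Simulation-truth metadata attached to one variant."""

    variant: Variant
    origin: str  # founder | post-founder | post-differentiation
    class96: int
    strand: str
    selection_class: str
    patho_score: float


@dataclass
class CellState:
    """One cell: its mtDNA population as variant copy counts out of N."""

    cell_id: str
    cell_type: str
    condition: str
    N: int
    genotype: dict[Variant, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for v, k in self.genotype.items():
            if not 0 < k <= self.N:
                raise ValueError(f"copy count {k} for {v.vid} outside (0, {self.N}]")

    def hf(self, variant: Variant) -> float:
        return self.genotype.get(variant, 0) / self.N

    def copy(self) -> "CellState":
        return CellState(
            self.cell_id, self.cell_type, self.condition, self.N, dict(self.genotype)
        )


def default_signature_weights() -> np.ndarray:
    """Transition-dominated 96-class weights (mtDNA spectra are heavily
    skewed toward C>T and T>C changes, consistent with replication-linked
    deamination damage rather than UV- or tobacco-type processes)."""
    w = np.full(96, 0.1)
    for i, label in enumerate(sig.CLASS_LABELS):
        if "[C>T]" in label:
            w[i] = 1.0
        elif "[T>C]" in label:
            w[i] = 0.8
    return w / w.sum()


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults are the emulated study design.

    ``mu`` (expected de novo mutations per cell division) and
    ``copy_number`` accept keys of the form ``"condition.cell_type"``,
    plain ``"cell_type"`` or ``"default"``, most specific wins.
    ``s`` maps a selection class (``founder``, ``post-founder``,
    ``post-differentiation``) to a coefficient > -1 applied during
    differentiation divisions; expansion divisions are neutral.
    """

    seed: int = 0
    n_cells: dict[str, int] = field(
        default_factory=lambda: {
            f"{cond}.{ct}": n
            for cond in CONDITIONS
            for ct, n in (("ipsc", 37), ("astroglia", 35), ("neuron", 31))
        }
    )
    copy_number: dict[str, int] = field(
        default_factory=lambda: {
            "ipsc": 500,
            "astroglia": 450,
            "mutant.astroglia": 350,
            "neuron": 700,
        }
    )
    t_expansion: int = 20
    t_differentiation: int = 30
    mu: dict[str, float] = field(
        default_factory=lambda: {
            "ipsc": 0.2,
            "astroglia": 0.4,
            "mutant.astroglia": 0.8,
            "neuron": 0.3,
        }
    )
    s: dict[str, float] = field(
        default_factory=lambda: {
            "founder": -0.05,
            "post-founder": -0.05,
            "post-differentiation": 0.0,
        }
    )
    signature_weights: np.ndarray = field(default_factory=default_signature_weights)
    n_founder_variants: int = 6
    founder_hf: tuple[float, float] | list[float] = (0.02, 0.35)
    depth_mean: float = 2515.0
    depth_sdlog: float = 1.0
    error_rate: float = 1e-3
    n_runs: int = 2
    genome_length: int = 16569

    def __post_init__(self) -> None:
        self.signature_weights = np.asarray(self.signature_weights, dtype=float)
        if self.signature_weights.shape != (96,):
            raise ValueError("signature_weights must be a 96-vector")
        if (self.signature_weights < 0).any():
            raise ValueError("signature_weights must be nonnegative")
        tot = self.signature_weights.sum()
        if tot <= 0:
            raise ValueError("signature_weights must not be all zero")
        if abs(tot - 1.0) > 1e-9:
            self.signature_weights = self.signature_weights / tot
        if not 0 <= self.error_rate <= 0.01:
            raise ValueError("error_rate must be in [0, 0.01]")
        for cls, val in self.s.items():
            if val <= -1:
                raise ValueError(f"selection coefficient for {cls} must be > -1")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")

    def lookup(self, table: dict, condition: str, cell_type: str, fallback=None):
        for key in (f"{condition}.{cell_type}", cell_type, "default"):
            if key in table:
                return table[key]
        if fallback is None:
            raise KeyError(f"no entry for {condition}.{cell_type}")
        return fallback


def synthetic_reference(
    length: int = 16569, seed: int = 0, name: str = "chrM_syn"
) -> CircularReference:
    """A random circular genome with a few embedded homopolymer tracts,
    mimicking the poly-C stretches of real mtDNA. Synthetic stand-in for
    a real mitochondrial reference; any circular FASTA may be used instead."""
    rng = np.random.default_rng(seed)
    seq = rng.choice(list("ACGT"), size=length, p=[0.31, 0.31, 0.13, 0.25])
    n_tracts = max(1, length // 2500)
    for _ in range(n_tracts):
        start = int(rng.integers(0, length))
        run = int(rng.integers(6, 10))
        base = rng.choice(list("AC"))
        for k in range(run):
            seq[(start + k) % length] = base
    return CircularReference(name=name, sequence="".join(seq))


def default_annotation(length: int) -> "pd.DataFrame":
    """Placeholder gene-model coordinates scaled to the genome length,
    loosely shaped like the mitochondrial gene map (a control-region
    gap, two rRNAs, protein-coding complexes, interspersed tRNAs)."""
    from .reference import Region, RegionAnnotation

    def sc(x: float) -> int:
        return max(1, min(length, int(round(x * length))))

    regions = [
        Region(sc(0.966), sc(0.035), "noncoding", "D-loop"),
        Region(sc(0.04), sc(0.095), "rRNA", "RNR1"),
        Region(sc(0.10), sc(0.19), "rRNA", "RNR2"),
        Region(sc(0.20), sc(0.30), "protein_coding", "ND1-2"),
        Region(sc(0.31), sc(0.33), "tRNA", "tRNA-cluster1"),
        Region(sc(0.35), sc(0.50), "protein_coding", "CO1-3"),
        Region(sc(0.51), sc(0.53), "tRNA", "tRNA-cluster2"),
        Region(sc(0.55), sc(0.75), "protein_coding", "ND3-5"),
        Region(sc(0.76), sc(0.78), "tRNA", "tRNA-cluster3"),
        Region(sc(0.80), sc(0.96), "protein_coding", "CYB-ND6"),
    ]
    return RegionAnnotation(length=length, regions=regions)


class MutationSiteIndex:
    """Per-96-class lists of mutable genome sites.

    For class c the candidate sites are the L-strand positions whose
    pyrimidine-centered context matches c (variant = class alt), plus
    the H-strand positions (purine centers on L) whose reverse
    complement matches (variant = complemented alt)."""

    def __init__(self, ref: CircularReference):
        self.ref = ref
        sites: list[list[tuple[int, str, str, str]]] = [[] for _ in range(96)]
        for pos in range(1, ref.length + 1):
            base = ref.base(pos)
            if base == "N":
                continue
            ctx = ref.trinucleotide_context(pos)
            if "N" in ctx:
                continue
            for alt in BASES:
                if alt == base:
                    continue
                cls, strand = sig.classify_substitution(ref, pos, base, alt)
                sites[cls].append((pos, base, alt, strand))
        self.sites = [tuple(s) for s in sites]

    def sample(self, cls: int, rng: np.random.Generator):
        cand = self.sites[cls]
        if not cand:
            return None
        return cand[int(rng.integers(0, len(cand)))]


def simulate_founder(
    config: SimulationConfig,
    ref: CircularReference,
    rng: np.random.Generator,
    site_index: MutationSiteIndex | None = None,
    condition: str = "ctrl",
) -> tuple[CellState, dict[Variant, VariantInfo]]:
    """Draw the founder hiPSC clone and its variant metadata.

    Founder HFs come from ``config.founder_hf``: an explicit list is
    used as-is (must fit in (0,1)); a (lo, hi) tuple draws uniformly.
    Copy counts are quantized to k = round(hf * N), clamped to >= 1.
    """
    if site_index is None:
        site_index = MutationSiteIndex(ref)
    N = config.lookup(config.copy_number, condition, "ipsc")
    if isinstance(config.founder_hf, (list, np.ndarray)):
        hfs = [float(h) for h in config.founder_hf][: config.n_founder_variants]
        if len(hfs) < config.n_founder_variants:
            raise ValueError("founder_hf list shorter than n_founder_variants")
    else:
        lo, hi = config.founder_hf
        hfs = rng.uniform(lo, hi, size=config.n_founder_variants).tolist()
    meta: dict[Variant, VariantInfo] = {}
    genotype: dict[Variant, int] = {}
    for hf in hfs:
        if not 0 < hf < 1:
            raise ValueError(f"founder HF {hf} outside (0, 1)")
        variant, info = _draw_new_variant(
            config, site_index, rng, genotype, origin="founder"
        )
        k = min(N - 1, max(1, int(round(hf * N))))
        genotype[variant] = k
        meta[variant] = info
    founder = CellState(
        cell_id=f"{condition}.founder", cell_type="ipsc", condition=condition,
        N=N, genotype=genotype,
    )
    return founder, meta


def _draw_new_variant(
    config: SimulationConfig,
    site_index: MutationSiteIndex,
    rng: np.random.Generator,
    existing: dict[Variant, int],
    origin: str,
    max_tries: int = 1000,
    exclude_positions: frozenset[int] = frozenset(),
) -> tuple[Variant, VariantInfo]:
    occupied = {v.pos for v in existing} | set(exclude_positions)
    for _ in range(max_tries):
        cls = int(rng.choice(96, p=config.signature_weights))
        drawn = site_index.sample(cls, rng)
        if drawn is None:
            logger.info("no genome position matches class %s; class re-drawn",
                        sig.CLASS_LABELS[cls])
            continue
        pos, ref_base, alt, strand = drawn
        if pos in occupied:
            continue
        variant = Variant(pos, ref_base, alt)
        score = float(rng.beta(2.0, 5.0))
        info = VariantInfo(
            variant=variant, origin=origin, class96=cls, strand=strand,
            selection_class=origin, patho_score=score,
        )
        return variant, info
    raise RuntimeError("could not place a new variant (genome saturated?)")


def divide(
    cell: CellState,
    s_map: dict[str, float],
    rng: np.random.Generator,
    classes: dict[Variant, str] | None = None,
    N_new: int | None = None,
) -> CellState:
    """One cell division: binomial resampling of each variant's copies.

    A mutant copy has weight 1 + s (s looked up by the variant's
    selection class, default 0); with allele frequency p the resampling
    probability is p(1+s)/(1+ps), so E[p'] = p(1+s)/(1+ps). Variants are
    resampled independently (infinite-sites simplification). k' = 0
    drops the variant; k' = N fixes it. ``N_new`` resamples into a
    different copy number (cell-type transition)."""
    N_new = cell.N if N_new is None else N_new
    classes = classes or {}
    new_geno: dict[Variant, int] = {}
    for variant, k in cell.genotype.items():
        s = s_map.get(classes.get(variant, ""), 0.0)
        w = 1.0 + s
        p = k / cell.N
        p_sel = (p * w) / (1.0 - p + p * w) if w > 0 else 0.0
        k_new = int(rng.binomial(N_new, p_sel)) if 0.0 < p_sel < 1.0 else int(round(p_sel * N_new))
        if k_new > 0:
            new_geno[variant] = k_new
    return CellState(cell.cell_id, cell.cell_type, cell.condition, N_new, new_geno)


def acquire_mutations(
    cell: CellState,
    mu: float,
    config: SimulationConfig,
    site_index: MutationSiteIndex,
    rng: np.random.Generator,
    meta: dict[Variant, VariantInfo],
    origin: str,
) -> CellState:
    """Add Poisson(mu) de novo variants, each entering at a single copy
    (HF = 1/N, single-molecule origin); sites drawn from the 96-class
    signature weights, collisions at occupied sites re-drawn."""
    if mu < 0:
        raise ValueError("mu must be >= 0")
    n_new = int(rng.poisson(mu)) if mu > 0 else 0
    if n_new == 0:
        return cell
    new_cell = cell.copy()
    for _ in range(n_new):
        variant, info = _draw_new_variant(
            config, site_index, rng, new_cell.genotype, origin=origin
        )
        new_cell.genotype[variant] = 1
        meta[variant] = info
    return new_cell


def _evolve_cell(
    founder: CellState,
    cell_id: str,
    cell_type: str,
    condition: str,
    config: SimulationConfig,
    site_index: MutationSiteIndex,
    meta: dict[Variant, VariantInfo],
    rng: np.random.Generator,
) -> CellState:
    """One independent lineage founder -> sampled cell."""
    cell = founder.copy()
    cell.cell_id = cell_id
    mu_ipsc = config.lookup(config.mu, condition, "ipsc", fallback=0.0)
    classes = {v: info.selection_class for v, info in meta.items()}
    # clonal expansion: neutral drift + hiPSC-stage mutation
    for _ in range(config.t_expansion):
        cell = divide(cell, {}, rng, classes=classes)
        cell = acquire_mutations(
            cell, mu_ipsc, config, site_index, rng, meta, origin="post-founder"
        )
        classes = {v: meta[v].selection_class for v in cell.genotype}
    if cell_type == "ipsc":
        return cell
    # differentiation: type-specific copy number, selection, mutation rate
    cell.cell_type = cell_type
    N_type = config.lookup(config.copy_number, condition, cell_type)
    mu_type = config.lookup(config.mu, condition, cell_type, fallback=0.0)
    for t in range(config.t_differentiation):
        cell = divide(
            cell, config.s, rng, classes=classes,
            N_new=N_type if t == 0 else None,
        )
        cell = acquire_mutations(
            cell, mu_type, config, site_index, rng, meta,
            origin="post-differentiation",
        )
        classes = {v: meta[v].selection_class for v in cell.genotype}
    return cell


@dataclass
class SimulationResult:
    cells: list[CellState]
    truth: pd.DataFrame
    reference: CircularReference
    config: SimulationConfig
    meta: dict[Variant, VariantInfo] = field(repr=False, default_factory=dict)
    founders: dict[str, CellState] = field(repr=False, default_factory=dict)

    def cells_of(self, condition: str, cell_type: str) -> list[CellState]:
        return [
            c for c in self.cells
            if c.condition == condition and c.cell_type == cell_type
        ]


def run_simulation(
    config: SimulationConfig, ref: CircularReference | None = None
) -> SimulationResult:
    """Full generative run: per-condition founder, expansion,
    differentiation, and the per-(cell, variant) ground-truth table.

    Deterministic given config.seed; per-cell randomness comes from
    substreams spawned off one master SeedSequence so cell count changes
    do not reshuffle unrelated cells."""
    master = np.random.SeedSequence(config.seed)
    ss_ref, ss_founder, ss_cells = master.spawn(3)
    if ref is None:
        ref = synthetic_reference(
            config.genome_length, seed=int(ss_ref.generate_state(1)[0] % 2**31)
        )
    site_index = MutationSiteIndex(ref)

    founders: dict[str, CellState] = {}
    meta: dict[Variant, VariantInfo] = {}
    founder_rng = np.random.default_rng(ss_founder)
    for condition in CONDITIONS:
        founder, fmeta = simulate_founder(
            config, ref, founder_rng, site_index, condition=condition
        )
        founders[condition] = founder
        meta.update(fmeta)

    cells: list[CellState] = []
    group_keys = sorted(config.n_cells)
    streams = ss_cells.spawn(len(group_keys))
    for ss_group, key in zip(streams, group_keys):
        condition, cell_type = key.split(".")
        if condition not in CONDITIONS or cell_type not in CELL_TYPES:
            raise ValueError(f"bad group key {key!r}")
        n = config.n_cells[key]
        for ss_cell, i in zip(ss_group.spawn(n), range(n)):
            rng = np.random.default_rng(ss_cell)
            cell = _evolve_cell(
                founders[condition], f"{key}.c{i:03d}", cell_type, condition,
                config, site_index, meta, rng,
            )
            cells.append(cell)

    rows = []
    for cell in cells:
        for variant, k in sorted(cell.genotype.items()):
            info = meta[variant]
            rows.append({
                "cell_id": cell.cell_id,
                "condition": cell.condition,
                "cell_type": cell.cell_type,
                "pos": variant.pos,
                "ref": variant.ref,
                "alt": variant.alt,
                "true_hf": k / cell.N,
                "origin": info.origin,
                "class96": sig.CLASS_LABELS[info.class96],
                "strand": info.strand,
                "selection_class": info.selection_class,
                "patho_score": info.patho_score,
            })
    truth = pd.DataFrame(
        rows,
        columns=["cell_id", "condition", "cell_type", "pos", "ref", "alt",
                 "true_hf", "origin", "class96", "strand",
                 "selection_class", "patho_score"],
    )
    return SimulationResult(
        cells=cells, truth=truth, reference=ref, config=config, meta=meta,
        founders=founders,
    )


def seed_subclone(
    result: SimulationResult,
    cell_ids: list[str],
    hf: float,
    rng: np.random.Generator,
    origin: str = "post-founder",
    exclude_positions: frozenset[int] = frozenset(),
) -> Variant:
    """Plant one extra variant at a given HF into a subset of cells.

    Models a clonal expansion event: the chosen cells share a common
    ancestor carrying the variant. The site is drawn from the configured
    signature weights at a position unused in every target cell (and
    outside ``exclude_positions``, e.g. a homopolymer mask); truth rows
    are appended. Returns the planted variant."""
    if not 0 < hf < 1:
        raise ValueError("subclone HF must be in (0, 1)")
    targets = [c for c in result.cells if c.cell_id in set(cell_ids)]
    if len(targets) != len(set(cell_ids)):
        raise ValueError("unknown cell id among subclone targets")
    site_index = MutationSiteIndex(result.reference)
    occupied: dict[Variant, int] = {}
    for c in targets:
        for v in c.genotype:
            occupied[v] = 1
    variant, info = _draw_new_variant(
        result.config, site_index, rng, occupied, origin=origin,
        exclude_positions=exclude_positions,
    )
    result.meta[variant] = info
    rows = []
    for cell in targets:
        k = min(cell.N - 1, max(1, int(round(hf * cell.N))))
        cell.genotype[variant] = k
        rows.append({
            "cell_id": cell.cell_id, "condition": cell.condition,
            "cell_type": cell.cell_type, "pos": variant.pos,
            "ref": variant.ref, "alt": variant.alt, "true_hf": k / cell.N,
            "origin": origin, "class96": sig.CLASS_LABELS[info.class96],
            "strand": info.strand, "selection_class": info.selection_class,
            "patho_score": info.patho_score,
        })
    result.truth = pd.concat(
        [result.truth, pd.DataFrame(rows)], ignore_index=True
    )
    return variant


def sequence_cell(
    cell: CellState,
    ref: CircularReference,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[AlleleCountTable]:
    """Replicate-run sequencing of one cell.

    One mean coverage is drawn per cell from a lognormal whose mean is
    ``depth_mean`` (meanlog = ln(depth_mean) - sdlog^2/2); each run then
    draws per-site depths Poisson(coverage) independently, reads from
    the cell's true allele mix, and miscalls each read to a uniformly
    chosen other base with probability ``error_rate``."""
    L = ref.length
    mix = np.zeros((L, 4))
    ref_idx = np.fromiter((_BASE_IDX[b] for b in ref.sequence), dtype=int, count=L)
    mix[np.arange(L), ref_idx] = 1.0
    for variant, k in cell.genotype.items():
        p = k / cell.N
        i = variant.pos - 1
        mix[i, _BASE_IDX[variant.ref]] -= p
        mix[i, _BASE_IDX[variant.alt]] += p
    e = config.error_rate
    observed = mix * (1.0 - e) + (1.0 - mix) * (e / 3.0)
    observed = observed / observed.sum(axis=1, keepdims=True)

    meanlog = np.log(config.depth_mean) - config.depth_sdlog**2 / 2.0
    coverage = float(rng.lognormal(meanlog, config.depth_sdlog))
    tables = []
    for run in range(1, config.n_runs + 1):
        depths = rng.poisson(coverage, size=L)
        counts = rng.multinomial(depths, observed)
        df = pd.DataFrame({
            "pos": np.arange(1, L + 1),
            "ref": list(ref.sequence),
            "A": counts[:, 0], "C": counts[:, 1],
            "G": counts[:, 2], "T": counts[:, 3],
        })
        tables.append(
            AlleleCountTable(cell_id=cell.cell_id, run_id=f"run{run}", counts=df)
        )
    return tables


def sequence_all(
    result: SimulationResult, seed: int | None = None
) -> dict[str, list[AlleleCountTable]]:
    """Sequence every simulated cell; returns cell_id -> per-run tables.

    Uses a seed substream per cell (ordered by cell id) so output is
    reproducible under a fixed master seed."""
    config = result.config
    base = config.seed if seed is None else seed
    master = np.random.SeedSequence((base, 7))
    cells = sorted(result.cells, key=lambda c: c.cell_id)
    out: dict[str, list[AlleleCountTable]] = {}
    for ss, cell in zip(master.spawn(len(cells)), cells):
        rng = np.random.default_rng(ss)
        out[cell.cell_id] = sequence_cell(cell, result.reference, config, rng)
    return out


def write_run(
    result: SimulationResult,
    tables: dict[str, list[AlleleCountTable]],
    outdir: str | Path,
) -> None:
    """Write counts/, cells manifest, truth table and the reference FASTA."""
    outdir = Path(outdir)
    counts_dir = outdir / "counts"
    counts_dir.mkdir(parents=True, exist_ok=True)
    result.reference.to_fasta(outdir / "reference.fasta")
    manifest = []
    for cell in sorted(result.cells, key=lambda c: c.cell_id):
        for table in tables.get(cell.cell_id, []):
            fname = f"{cell.cell_id}.{table.run_id}.tsv"
            table.to_tsv(counts_dir / fname)
            manifest.append({
                "cell_id": cell.cell_id,
                "condition": cell.condition,
                "cell_type": cell.cell_type,
                "run_id": table.run_id,
                "path": f"counts/{fname}",
            })
    pd.DataFrame(manifest).to_csv(outdir / "cells.tsv", sep="\t", index=False)
    with open(outdir / "truth.tsv", "w") as fh:
        fh.write("#ground truth; illustrative mutation/selection parameters\n")
        fh.write(f"#seed={result.config.seed}\n")
        result.truth.to_csv(fh, sep="\t", index=False)


def config_to_yaml(config: SimulationConfig, path: str | Path) -> None:
    import yaml

    d = asdict(config)
    d["signature_weights"] = [float(x) for x in config.signature_weights]
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def config_from_yaml(path: str | Path) -> SimulationConfig:
    import yaml

    with open(path) as fh:
        d = yaml.safe_load(fh)
    if "founder_hf" in d and isinstance(d["founder_hf"], list) and len(d["founder_hf"]) == 2:
        d["founder_hf"] = tuple(d["founder_hf"])
    return SimulationConfig(**d)
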