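"""Replicate-concordance heteroplasmy variant calling.

Each cell is sequenced in independent technical replicate runs. A
candidate mtSNV at a site is accepted only when its heteroplasmy
fraction (HF = alt reads / depth) strictly exceeds the threshold
(default 0.005) in *every* run — low-frequency artifacts are unlikely to
recur across independent amplification + library + sequencing rounds.
Candidates are additionally filtered on per-run depth and on membership
in homopolymer tracts. The merged HF reported per call is the
arithmetic mean of the per-run HFs.

An exact per-site binomial error test (the product of per-run binomial
tail probabilities under a uniform miscall model) is provided as an
optional evidence column, and replicate agreement is summarized by the
OLS coefficient of determination of run-2 HF on run-1 HF.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

BASES = ("A", "C", "G", "T")

CALL_COLUMNS = [
    "cell_id", "pos", "ref", "alt",
    "hf_run1", "hf_run2", "hf",
    "depth_run1", "depth_run2",
    "filters", "pass",
]


@dataclass
class AlleleCountTable:
    """Per-cell per-run read counts: one row per covered position.

    ``counts`` columns: pos, ref, A, C, G, T. Depth at a position is the
    sum of the four base counts.
    """

    cell_id: str
    run_id: str
    counts: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = ["pos", "ref", *BASES]
        missing = [c for c in required if c not in self.counts.columns]
        if missing:
            raise ValueError(f"count table missing columns {missing}")
        if self.counts["pos"].duplicated().any():
            raise ValueError("count table has duplicate positions")

    @property
    def depth(self) -> pd.Series:
        return self.counts[list(BASES)].sum(axis=1)

    @classmethod
    def from_tsv(cls, path, cell_id: str, run_id: str) -> "AlleleCountTable":
        df = pd.read_csv(path, sep="\t", comment="#")
        return cls(cell_id=cell_id, run_id=run_id, counts=df)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# cell_id={self.cell_id}\trun_id={self.run_id}\n")
            fh.write("# coordinates 1-based inclusive\n")
            self.counts.to_csv(fh, sep="\t", index=False)


def estimate_hf(row: pd.Series, alt_base: str) -> float:
    """HF of one alt base in one count row: alt reads / depth.

    Depth-zero rows are undefined and must be skipped by the caller.
    """
    depth = sum(int(row[b]) for b in BASES)
    if depth == 0:
        raise ValueError("HF undefined at zero depth")
    return int(row[alt_base]) / depth


def call_variants(
    tables: list[AlleleCountTable],
    mask: frozenset[int] | set[int] = frozenset(),
    hf_threshold: float = 0.005,
    min_depth: int = 50,
) -> pd.DataFrame:
    """Concordance-call mtSNVs for one cell from >= 2 replicate runs.

    A site/alt is a candidate iff HF > hf_threshold (strict) in every
    run. Candidates in the homopolymer mask or with any run's depth
    below ``min_depth`` carry filters and ``pass = False``. Zero-depth
    sites in any run are skipped. Output is sorted by (pos, alt);
    multi-allelic sites yield independent rows per alt.
    """
    if len(tables) < 2:
        raise ValueError("replicate calling needs >= 2 runs")
    cell_ids = {t.cell_id for t in tables}
    if len(cell_ids) != 1:
        raise ValueError(f"tables from different cells: {sorted(cell_ids)}")
    cell_id = tables[0].cell_id

    merged = None
    for i, t in enumerate(tables, start=1):
        df = t.counts[["pos", "ref", *BASES]].copy()
        df = df.rename(columns={b: f"{b}_{i}" for b in BASES})
        if merged is None:
            merged = df
        else:
            ref_map = dict(zip(merged["pos"], merged["ref"]))
            for p, r in zip(df["pos"], df["ref"]):
                if p in ref_map and ref_map[p] != r:
                    raise ValueError(f"reference mismatch between runs at pos {p}")
            merged = merged.merge(df, on=["pos", "ref"], how="inner")
    n_runs = len(tables)

    depths = np.stack(
        [merged[[f"{b}_{i}" for b in BASES]].sum(axis=1).to_numpy()
         for i in range(1, n_runs + 1)],
        axis=1,
    )
    covered = (depths > 0).all(axis=1)

    records = []
    pos_arr = merged["pos"].to_numpy()
    ref_arr = merged["ref"].to_numpy()
    for alt in BASES:
        alt_counts = np.stack(
            [merged[f"{alt}_{i}"].to_numpy() for i in range(1, n_runs + 1)], axis=1
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            hf = np.where(depths > 0, alt_counts / depths, np.nan)
        candidate = covered & (ref_arr != alt) & (hf > hf_threshold).all(axis=1)
        for idx in np.nonzero(candidate)[0]:
            filters = []
            if int(pos_arr[idx]) in mask:
                filters.append("homopolymer")
            if (depths[idx] < min_depth).any():
                filters.append("low_depth")
            rec = {
                "cell_id": cell_id,
                "pos": int(pos_arr[idx]),
                "ref": ref_arr[idx],
                "alt": alt,
                "hf": float(hf[idx].mean()),
                "filters": ",".join(filters),
                "pass": not filters,
            }
            for i in range(n_runs):
                rec[f"hf_run{i + 1}"] = float(hf[idx, i])
                rec[f"depth_run{i + 1}"] = int(depths[idx, i])
            records.append(rec)

    cols = (
        ["cell_id", "pos", "ref", "alt"]
        + [f"hf_run{i}" for i in range(1, n_runs + 1)]
        + ["hf"]
        + [f"depth_run{i}" for i in range(1, n_runs + 1)]
        + ["filters", "pass"]
    )
    out = pd.DataFrame(records, columns=cols)
    return out.sort_values(["pos", "alt"]).reset_index(drop=True)


def binomial_error_test(
    alt_counts: list[int], depths: list[int], error_rate: float
) -> float:
    """Joint null probability of the observed alt counts across runs.

    Under H0 (no variant) the alt count of a *specific* base in a run is
    Binomial(depth, e/3) — a uniform miscall model sends e/3 of the
    error mass to each alternative base. The statistic is the product
    over runs of P(X >= observed); by independence of the replicate
    runs this is the joint tail probability. Smaller = stronger evidence
    of a real variant.
    """
    if not 0 < error_rate < 1:
        raise ValueError("error_rate must be in (0, 1)")
    if len(alt_counts) != len(depths):
        raise ValueError("alt_counts and depths must align")
    p = 1.0
    for k, n in zip(alt_counts, depths):
        p *= float(sps.binom.sf(k - 1, n, error_rate / 3.0))
    return p


def replicate_r2(hf_run1, hf_run2) -> float:
    """OLS coefficient of determination of run-2 HF regressed on run-1 HF.

    Requires >= 3 paired observations; a zero-variance predictor makes
    the fit undefined (NaN).
    """
    x = np.asarray(hf_run1, dtype=float)
    y = np.asarray(hf_run2, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired HF observations")
    if np.allclose(x, x[0]):
        return float("nan")
    res = sps.linregress(x, y)
    return float(res.rvalue**2)


def write_calls(calls: pd.DataFrame, path, metadata: dict | None = None) -> None:
    """Write a combined calls TSV with '#key=value' metadata headers."""
    with open(path, "w") as fh:
        fh.write("#coordinates=1-based inclusive\n")
        fh.write("#hf_merge=arithmetic mean of per-run HFs\n")
        for k, v in (metadata or {}).items():
            fh.write(f"#{k}={v}\n")
        calls.to_csv(fh, sep="\t", index=False)


def read_calls(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_vcf(calls: pd.DataFrame, path, reference_name: str) -> None:
    """Minimal per-cell VCF-like export of passing calls (INFO HF=...)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={reference_name}>\n")
        fh.write('##INFO=<ID=HF,Number=1,Type=Float,Description="Merged heteroplasmy fraction">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for _, row in calls[calls["pass"]].iterrows():
            fh.write(
                f"{reference_name}\t{row['pos']}\t.\t{row['ref']}\t{row['alt']}"
                f"\t.\tPASS\tHF={row['hf']:.6g}\n"
            )
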