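"""Lineage classification of mtSNVs and heteroplasmy-shift analysis.

Variants called in differentiated cells are classified against the
founder hiPSC variant set of the same line: a variant present in the
founder set is *shared*, otherwise *de novo*. Symmetrically, a founder
variant re-detected in at least one differentiated cell of the line is
*transmitted*, otherwise *lost*. Per-founder-variant, per-cell
heteroplasmy shifts quantify selection during differentiation:

    aHS = HF_cell - HF_founder                       (absolute shift)
    nHS = aHS / (1 - HF_founder)   if aHS >= 0       (gain / headroom)
          aHS / HF_founder         if aHS <  0       (loss / standing HF)

so nHS is bounded in [-1, 1]: -1 is complete loss, +1 fixation.
Normalizing removes the dependence of the absolute shift on the
founder-level HF of each variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class FounderSet:
    """Union of passing hiPSC calls of one line.

    ``variants`` maps (pos, alt) to (mean HF across carrier cells,
    carrier count). Founder membership is keyed on (pos, alt) only.
    """

    line_id: str
    variants: dict[tuple[int, str], tuple[float, int]] = field(default_factory=dict)

    def __contains__(self, key: tuple[int, str]) -> bool:
        return key in self.variants

    def hf(self, key: tuple[int, str]) -> float:
        return self.variants[key][0]

    def __len__(self) -> int:
        return len(self.variants)


def build_founder_set(
    ipsc_calls: pd.DataFrame, line_id: str, allow_empty: bool = False
) -> FounderSet:
    """Founder set = union of passing calls over hiPSC cells of a line;
    per-variant HF is the mean over carrier cells only."""
    if ipsc_calls.empty and not allow_empty:
        raise ValueError(
            "no hiPSC calls supplied; pass allow_empty=True to accept an "
            "empty founder set"
        )
    passing = ipsc_calls[ipsc_calls["pass"]] if "pass" in ipsc_calls.columns else ipsc_calls
    if passing.empty and not allow_empty:
        raise ValueError("no passing hiPSC calls")
    variants: dict[tuple[int, str], tuple[float, int]] = {}
    if not passing.empty:
        grouped = passing.groupby(["pos", "alt"])["hf"].agg(["mean", "count"])
        for (pos, alt), row in grouped.iterrows():
            variants[(int(pos), alt)] = (float(row["mean"]), int(row["count"]))
    return FounderSet(line_id=line_id, variants=variants)


def classify(calls: pd.DataFrame, founder: FounderSet) -> pd.DataFrame:
    """Label organoid-side calls shared / de_novo against the founder set.

    Input must be pass-filtered calls of differentiated cells (any
    number of cells). Adds a ``lineage_class`` column.
    """
    out = calls.copy()
    keys = list(zip(out["pos"].astype(int), out["alt"]))
    out["lineage_class"] = [
        "shared" if k in founder else "de_novo" for k in keys
    ]
    return out


def cell_fractions(classified: pd.DataFrame) -> pd.DataFrame:
    """Per-cell counts and fractions of shared vs de novo variants.

    Cells with zero calls are absent from the input and cannot be
    reported here; fractions always sum to 1 per reported cell.
    """
    rows = []
    for cell_id, grp in classified.groupby("cell_id"):
        n = len(grp)
        n_shared = int((grp["lineage_class"] == "shared").sum())
        n_de_novo = n - n_shared
        rows.append({
            "cell_id": cell_id,
            "n_variants": n,
            "n_shared": n_shared,
            "n_de_novo": n_de_novo,
            "frac_shared": n_shared / n,
            "frac_de_novo": n_de_novo / n,
        })
    return pd.DataFrame(
        rows, columns=["cell_id", "n_variants", "n_shared", "n_de_novo",
                       "frac_shared", "frac_de_novo"],
    )


def founder_fate(founder: FounderSet, organoid_calls: pd.DataFrame) -> pd.DataFrame:
    """Line-wide transmitted/lost status of each founder variant:
    transmitted iff detected (passing) in >= 1 differentiated cell."""
    detected = set(
        zip(organoid_calls["pos"].astype(int), organoid_calls["alt"])
    ) if not organoid_calls.empty else set()
    rows = []
    for (pos, alt), (hf, carriers) in sorted(founder.variants.items()):
        rows.append({
            "pos": pos, "alt": alt, "founder_hf": hf, "carriers": carriers,
            "fate": "transmitted" if (pos, alt) in detected else "lost",
        })
    return pd.DataFrame(rows, columns=["pos", "alt", "founder_hf", "carriers", "fate"])


def burden_metrics(calls: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, list[float]]]:
    """Per-cell passing-variant counts plus the per-cell HF lists that
    feed ECDF / cumulative-frequency comparisons."""
    if calls.empty:
        return pd.DataFrame(columns=["cell_id", "n_variants"]), {}
    counts = calls.groupby("cell_id").size().rename("n_variants").reset_index()
    hf_lists = {
        cell_id: grp["hf"].tolist() for cell_id, grp in calls.groupby("cell_id")
    }
    return counts, hf_lists


def normalized_shift(hf_founder: float, hf_cell: float) -> tuple[float, float]:
    """(aHS, nHS) for one founder variant in one differentiated cell."""
    if not 0 < hf_founder <= 1:
        raise ValueError("founder HF must be in (0, 1]")
    ahs = hf_cell - hf_founder
    if ahs >= 0:
        denom = 1.0 - hf_founder
        nhs = ahs / denom if denom > 0 else 0.0
    else:
        nhs = ahs / hf_founder
    return ahs, nhs


def heteroplasmy_shift(
    founder: FounderSet,
    cell_calls: pd.DataFrame,
    include_undetected: bool = True,
) -> pd.DataFrame:
    """Shift records: one row per founder variant per differentiated cell.

    ``cell_calls`` are pass-filtered calls of differentiated cells.
    A founder variant undetected in a cell contributes hf_cell = 0 when
    ``include_undetected`` (loss is the signal of interest), else the
    record is omitted. Founder variants with HF 0 cannot be normalized
    and are skipped."""
    if len(founder) == 0:
        raise ValueError("founder set is empty")
    hf_map: dict[tuple[str, int, str], float] = {}
    cell_ids: set[str] = set()
    if not cell_calls.empty:
        cell_ids.update(cell_calls["cell_id"])
        for _, row in cell_calls.iterrows():
            hf_map[(row["cell_id"], int(row["pos"]), row["alt"])] = float(row["hf"])
    rows = []
    for cell_id in sorted(cell_ids):
        for (pos, alt), (hf_f, _) in sorted(founder.variants.items()):
            if hf_f <= 0:
                continue
            hf_cell = hf_map.get((cell_id, pos, alt))
            if hf_cell is None:
                if not include_undetected:
                    continue
                hf_cell = 0.0
            ahs, nhs = normalized_shift(hf_f, hf_cell)
            rows.append({
                "cell_id": cell_id, "pos": pos, "alt": alt,
                "hf_ipsc": hf_f, "hf_cell": hf_cell, "ahs": ahs, "nhs": nhs,
            })
    return pd.DataFrame(
        rows, columns=["cell_id", "pos", "alt", "hf_ipsc", "hf_cell", "ahs", "nhs"]
    )


def write_tsv(df: pd.DataFrame, path, metadata: dict | None = None) -> None:
    """Tidy TSV with '#key=value' header lines."""
    meta = {
        "coordinates": "1-based inclusive",
        "nhs_formula": "gain/(1-hf_ipsc); loss/hf_ipsc",
    }
    meta.update(metadata or {})
    with open(path, "w") as fh:
        for k, v in meta.items():
            fh.write(f"#{k}={v}\n")
        df.to_csv(fh, sep="\t", index=False)
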