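"""Clonal structure from the cell x variant heteroplasmy matrix.

Cells sharing heteroplasmic variants at similar frequencies descend
from a common clone, so hierarchical clustering of the HF matrix
recovers clonal subsets; variants exceeding the conventional
pathogenicity threshold frequency (HF > 0.6, strict) are flagged with
their genomic-region annotation, and clades are scored for how many of
their cells carry a flagged variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from skbio.tree import TreeNode

from .reference import RegionAnnotation


def build_hf_matrix(calls: pd.DataFrame, cells: list[str] | None = None) -> pd.DataFrame:
    """Cells x variants matrix of merged HFs; uncalled entries are 0.

    Variant columns are ``pos:ref>alt`` identifiers ordered by
    (pos, alt). ``cells`` fixes the row universe (cells with no calls
    appear as all-zero rows); duplicate (cell, variant) records are a
    contract violation."""
    if calls.empty:
        return pd.DataFrame(index=pd.Index(cells or [], name="cell_id"))
    passing = calls[calls["pass"]] if "pass" in calls.columns else calls
    dup = passing.duplicated(subset=["cell_id", "pos", "alt"])
    if dup.any():
        raise ValueError("duplicate (cell, variant) records in calls")
    df = passing.copy()
    df["variant"] = [
        f"{int(p)}:{r}>{a}" for p, r, a in zip(df["pos"], df["ref"], df["alt"])
    ]
    order = (
        df[["variant", "pos", "alt"]]
        .drop_duplicates()
        .sort_values(["pos", "alt"])["variant"]
        .tolist()
    )
    mat = df.pivot_table(index="cell_id", columns="variant", values="hf", fill_value=0.0)
    mat = mat.reindex(columns=order, fill_value=0.0)
    if cells is not None:
        mat = mat.reindex(index=cells, fill_value=0.0)
    mat.index.name = "cell_id"
    return mat


@dataclass
class ClusterResult:
    """Dendrogram over cells plus helpers for flat cuts and Newick export."""

    cell_ids: list[str]
    linkage: np.ndarray = field(repr=False)

    def flat_clusters(self, k: int | None = None, height: float | None = None) -> dict[str, int]:
        """Cut into flat clusters by count k or merge height."""
        if (k is None) == (height is None):
            raise ValueError("specify exactly one of k or height")
        if k is not None:
            labels = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        else:
            labels = hierarchy.fcluster(self.linkage, t=height, criterion="distance")
        return dict(zip(self.cell_ids, (int(x) for x in labels)))

    def to_newick(self) -> str:
        tree = TreeNode.from_linkage_matrix(self.linkage, self.cell_ids)
        return str(tree).strip()

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]


def cluster_cells(
    matrix: pd.DataFrame, metric: str = "euclidean", method: str = "complete"
) -> ClusterResult:
    """Agglomerative clustering of cells on the HF matrix.

    Euclidean distance with complete linkage by default; ``average``
    linkage and ``correlation`` (1 - Pearson) distance are accepted
    alternatives. A single cell yields a singleton result."""
    cell_ids = [str(c) for c in matrix.index]
    if len(cell_ids) < 2:
        return ClusterResult(cell_ids=cell_ids, linkage=np.empty((0, 4)))
    X = matrix.to_numpy(dtype=float)
    if X.shape[1] == 0:
        dists = np.zeros(len(cell_ids) * (len(cell_ids) - 1) // 2)
    else:
        dists = pdist(X, metric=metric)
        dists = np.nan_to_num(dists, nan=0.0)
    Z = hierarchy.linkage(dists, method=method)
    return ClusterResult(cell_ids=cell_ids, linkage=Z)


def flag_high_hf(
    matrix: pd.DataFrame,
    threshold: float = 0.6,
    annot: RegionAnnotation | None = None,
) -> pd.DataFrame:
    """All (cell, variant) entries with HF strictly above the threshold,
    joined to region-class / gene labels when an annotation is given."""
    rows = []
    for cell_id in matrix.index:
        for variant in matrix.columns:
            hf = float(matrix.at[cell_id, variant])
            if hf > threshold:
                pos = int(variant.split(":")[0])
                rec = {"cell_id": cell_id, "variant": variant, "pos": pos, "hf": hf}
                if annot is not None:
                    region_class, label = annot.annotate_position(pos)
                    rec["region_class"] = region_class
                    rec["region_label"] = label
                rows.append(rec)
    cols = ["cell_id", "variant", "pos", "hf"]
    if annot is not None:
        cols += ["region_class", "region_label"]
    return pd.DataFrame(rows, columns=cols)


def clade_enrichment(
    clusters: dict[str, int], flagged: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-clade carrier counts of flagged variants, plus the variants
    that *define* a clade (carried above threshold by all of its cells
    and by no cell outside it)."""
    carriers_by_variant: dict[str, set[str]] = {}
    if not flagged.empty:
        for variant, grp in flagged.groupby("variant"):
            carriers_by_variant[variant] = set(grp["cell_id"])
    flagged_cells = set(flagged["cell_id"]) if not flagged.empty else set()

    clade_rows = []
    for clade in sorted(set(clusters.values())):
        members = [c for c, cl in clusters.items() if cl == clade]
        carriers = [c for c in members if c in flagged_cells]
        clade_rows.append({
            "clade": clade,
            "n_cells": len(members),
            "n_carriers": len(carriers),
            "frac_carriers": len(carriers) / len(members) if members else 0.0,
        })
    clades = pd.DataFrame(
        clade_rows, columns=["clade", "n_cells", "n_carriers", "frac_carriers"]
    )

    defining_rows = []
    for variant, carriers in sorted(carriers_by_variant.items()):
        for clade in sorted(set(clusters.values())):
            members = {c for c, cl in clusters.items() if cl == clade}
            if carriers == members:
                defining_rows.append({"variant": variant, "clade": clade,
                                      "n_cells": len(members)})
    defining = pd.DataFrame(defining_rows, columns=["variant", "clade", "n_cells"])
    return clades, defining


def write_matrix(matrix: pd.DataFrame, path, triplet_path=None) -> None:
    """Dense TSV plus optional sparse triplet CSV (cell, variant, hf)."""
    matrix.to_csv(path, sep="\t")
    if triplet_path is not None:
        trip = matrix.stack().rename("hf").reset_index()
        trip.columns = ["cell_id", "variant", "hf"]
        trip = trip[trip["hf"] > 0]
        trip.to_csv(triplet_path, index=False)
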