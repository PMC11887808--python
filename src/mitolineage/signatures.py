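"""Strand-aware 96-class trinucleotide substitution spectra.

Single-base substitutions are reduced to the conventional 96 classes:
six pyrimidine-centered substitutions (C>A, C>G, C>T, T>A, T>C, T>G)
crossed with the 16 combinations of 5' and 3' flanking bases. A
substitution whose reference base is a purine is complemented and its
context reverse-complemented, and is attributed to the heavy (H) strand;
pyrimidine-reference substitutions are attributed to the light (L)
strand (the FASTA strand).

Class rates can be normalized by the frequency of each trinucleotide
context on its strand of origin in the reference genome, so spectra are
comparable across genomes with different base composition. Spectra are
compared to a 30-signature reference catalog by Pearson correlation
over the 96 paired rates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .reference import (
    CircularReference,
    ContextUnavailableError,
    PYRIMIDINES,
    revcomp,
)

logger = logging.getLogger(__name__)

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
BASES = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: The 96 class labels, e.g. "A[C>A]A", in (substitution, 5' flank, 3' flank)
#: lexicographic order. Index = sub*16 + 5'*4 + 3'.
CLASS_LABELS = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in BASES
    for three in BASES
)
CLASS_INDEX = {label: i for i, label in enumerate(CLASS_LABELS)}


def class_of(five: str, sub: str, three: str) -> int:
    return CLASS_INDEX[f"{five}[{sub}]{three}"]


def class_context(idx: int) -> str:
    """Pyrimidine-centered reference trinucleotide of a class (e.g. 'ACG')."""
    label = CLASS_LABELS[idx]
    return label[0] + label[2] + label[6]


def class_alt(idx: int) -> str:
    """Alternative base (on the pyrimidine strand) of a class."""
    return CLASS_LABELS[idx][4]


def classify_substitution(
    ref: CircularReference, pos: int, ref_base: str, alt_base: str
) -> tuple[int, str]:
    """Map a substitution to its (96-class index, strand).

    Pyrimidine reference base: class from the L-strand context, strand L.
    Purine: the substitution is complemented and the context
    reverse-complemented, strand H. Raises
    :class:`ContextUnavailableError` when the window contains N.
    """
    ref_base = ref_base.upper()
    alt_base = alt_base.upper()
    actual = ref.base(pos)
    if actual != ref_base:
        raise ValueError(
            f"reference base mismatch at {pos}: expected {actual}, got {ref_base}"
        )
    if alt_base == ref_base:
        raise ValueError("alt base equals reference base")
    ctx = ref.trinucleotide_context(pos)
    if "N" in ctx:
        raise ContextUnavailableError(f"N in context window at position {pos}")
    if ref_base in PYRIMIDINES:
        strand = "L"
        sub = f"{ref_base}>{alt_base}"
    else:
        strand = "H"
        sub = f"{_COMP[ref_base]}>{_COMP[alt_base]}"
        ctx = revcomp(ctx)
    return class_of(ctx[0], sub, ctx[2]), strand


@dataclass
class SubstitutionSpectrum:
    """A 96-class substitution spectrum for one group of variants.

    ``rates`` sum to 1 when any substitution contributed; ``raw_counts``
    are integer tallies; ``strand_counts`` keeps the per-strand split
    before pooling.
    """

    label: str
    rates: np.ndarray
    raw_counts: np.ndarray
    strand_counts: pd.DataFrame = field(repr=False)

    @property
    def total(self) -> int:
        return int(self.raw_counts.sum())

    def to_series(self) -> pd.Series:
        return pd.Series(self.rates, index=list(CLASS_LABELS), name=self.label)


def build_spectrum(
    variants,
    ref: CircularReference,
    normalize: bool = True,
    label: str = "spectrum",
) -> SubstitutionSpectrum:
    """Tally variants into a 96-class spectrum.

    Parameters
    ----------
    variants :
        Iterable of ``(pos, ref_base, alt_base)`` tuples.
    normalize :
        When True, each strand's class counts are divided by that
        strand's trinucleotide-context frequency in the reference before
        pooling L and H; the pooled 96-vector is then renormalized to
        sum 1. When False, raw pooled counts are renormalized directly.

    Unclassifiable variants (N in the context window) and classes whose
    reference context frequency is zero are dropped with a log message.
    """
    counts = np.zeros((96, 2), dtype=int)  # columns: L, H
    for pos, ref_base, alt_base in variants:
        try:
            cls, strand = classify_substitution(ref, pos, ref_base, alt_base)
        except ContextUnavailableError as exc:
            logger.info("build_spectrum: excluded variant (%s)", exc)
            continue
        counts[cls, 0 if strand == "L" else 1] += 1

    raw = counts.sum(axis=1)
    if normalize:
        freq_l = ref.context_frequencies("L")
        freq_h = ref.context_frequencies("H")
        rates = np.zeros(96, dtype=float)
        for i in range(96):
            ctx = class_context(i)
            for j, freq in enumerate((freq_l, freq_h)):
                c = counts[i, j]
                if c == 0:
                    continue
                f = freq.get(ctx, 0)
                if f == 0:
                    logger.info(
                        "build_spectrum: class %s has zero context frequency "
                        "on strand %s; %d counts dropped",
                        CLASS_LABELS[i], "LH"[j], c,
                    )
                    continue
                rates[i] += c / f
    else:
        rates = raw.astype(float)

    total_rate = rates.sum()
    if total_rate > 0:
        rates = rates / total_rate
    strand_df = pd.DataFrame(counts, index=list(CLASS_LABELS), columns=["L", "H"])
    return SubstitutionSpectrum(
        label=label, rates=rates, raw_counts=raw, strand_counts=strand_df
    )


@dataclass
class SignatureCatalog:
    """A reference catalog of mutational signatures (rows sum to 1).

    Layout mirrors the COSMIC-v2 30-signature table: one row per
    signature, 96 class columns in the conventional order. Any
    row-stochastic CSV in this layout can be loaded; the packaged
    default is a synthetic catalog (this package ships no third-party
    signature data).
    """

    names: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 96:
            raise ValueError("catalog matrix must be (n_signatures, 96)")
        if len(self.names) != self.matrix.shape[0]:
            raise ValueError("names/matrix shape mismatch")
        if (self.matrix < 0).any():
            raise ValueError("catalog entries must be nonnegative")
        sums = self.matrix.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("catalog rows must each sum to 1")

    @classmethod
    def from_csv(cls, path: str | Path) -> "SignatureCatalog":
        df = pd.read_csv(path, index_col=0)
        missing = [c for c in CLASS_LABELS if c not in df.columns]
        if missing:
            raise ValueError(f"catalog missing class columns, e.g. {missing[:3]}")
        mat = df[list(CLASS_LABELS)].to_numpy(dtype=float)
        return cls(names=[str(n) for n in df.index], matrix=mat)

    @classmethod
    def synthetic(cls) -> "SignatureCatalog":
        """The packaged synthetic 30-signature catalog."""
        with resources.as_file(
            resources.files("mitolineage.data") / "synthetic_signature_catalog.csv"
        ) as p:
            return cls.from_csv(p)

    def row(self, name: str) -> np.ndarray:
        return self.matrix[self.names.index(name)]


def correlate_catalog(
    spectrum: SubstitutionSpectrum, catalog: SignatureCatalog
) -> pd.DataFrame:
    """Pearson r (and its t-approximation p-value, n = 96) of a spectrum
    against every catalog signature, ranked by r descending (ties by name).

    Returns a DataFrame (signature, r, p, rank). With a zero-variance
    spectrum all correlations are undefined and returned as NaN.
    """
    if spectrum.total <= 0:
        raise ValueError("spectrum has no contributing substitutions")
    rows = []
    degenerate = np.allclose(spectrum.rates, spectrum.rates[0])
    for name, sig in zip(catalog.names, catalog.matrix):
        if degenerate or np.allclose(sig, sig[0]):
            r, p = np.nan, np.nan
        else:
            r, p = sps.pearsonr(spectrum.rates, sig)
        rows.append({"signature": name, "r": r, "p": p})
    df = pd.DataFrame(rows)
    df = df.sort_values(
        ["r", "signature"], ascending=[False, True], na_position="last"
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def spectrum_similarity(a: SubstitutionSpectrum, b: SubstitutionSpectrum) -> float:
    """Pearson correlation between two spectra (symmetric; r(a,a) = 1)."""
    if a.total <= 0 or b.total <= 0:
        raise ValueError("both spectra must have contributing substitutions")
    if np.allclose(a.rates, a.rates[0]) or np.allclose(b.rates, b.rates[0]):
        return float("nan")
    r, _ = sps.pearsonr(a.rates, b.rates)
    return float(r)
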