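"""Expression quantification for a three-library transcriptome comparison.

The analysis works on one count matrix with three libraries: the paternal
parent (``A``), the maternal parent (``B``) and their polyploid hybrid
(``C``).  This module holds the count-matrix container and the
quantification steps that precede any testing:

* RPKM normalization (reads per kilobase of gene model per million
  assigned reads),
* expressed-gene calling by a minimum read count,
* the seven-region Venn partition of expressed genes across libraries,
* gene-length and read-coverage binning summaries,
* read-subsampling saturation analysis with nested draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ComputeError, ConfigError

#: Library keys, in fixed order: paternal parent, maternal parent, hybrid.
LIBRARIES: tuple[str, str, str] = ("A", "B", "C")

#: Human-readable role of each library key.
LIBRARY_ROLES: dict[str, str] = {
    "A": "paternal parent",
    "B": "maternal parent",
    "C": "hybrid",
}

#: Left edges of the gene-length bins (bp); the last bin is open-ended.
LENGTH_BIN_EDGES: tuple[int, ...] = (100, 500, 1000, 1500, 2000)
LENGTH_BIN_LABELS: tuple[str, ...] = (
    "100-500",
    "500-1000",
    "1000-1500",
    "1500-2000",
    ">=2000",
)


def round_half_up(x, ndigits: int = 0):
    """Round with ties away from zero, as tables of percentages print them.

    numpy/Python round half to even; summary percentages here follow the
    half-up convention instead so that printed tables are reproduced
    digit for digit.
    """
    x = np.asarray(x, dtype=float)
    scale = 10.0**ndigits
    out = np.floor(np.abs(x) * scale + 0.5) / scale * np.sign(x)
    if out.ndim == 0:
        return float(out)
    return out


# ---------------------------------------------------------------------------
# Count matrix container
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Per-gene read counts for the three libraries plus library totals.

    ``counts`` is indexed by gene id with columns ``A``, ``B``, ``C``;
    ``totals`` holds the total assigned reads per library (N), which may
    exceed the column sums when reads were assigned to genes outside the
    table.
    """

    counts: pd.DataFrame
    totals: pd.Series

    def __post_init__(self) -> None:
        counts = self.counts
        if list(counts.columns) != list(LIBRARIES):
            missing = [c for c in LIBRARIES if c not in counts.columns]
            if missing:
                raise ConfigError(f"count matrix lacks library columns {missing}")
            counts = counts.loc[:, list(LIBRARIES)]
        if counts.index.has_duplicates:
            dup = counts.index[counts.index.duplicated()].unique().tolist()
            raise ConfigError(f"duplicate gene ids in count matrix: {dup[:5]}")
        if not all(np.issubdtype(d, np.integer) for d in counts.dtypes):
            raise ConfigError("counts must be integers")
        if (counts.to_numpy() < 0).any():
            raise ConfigError("counts must be nonnegative")
        totals = pd.Series(self.totals, dtype=np.int64).reindex(list(LIBRARIES))
        if totals.isna().any():
            raise ConfigError("library totals must cover libraries A, B, C")
        if (totals <= 0).any():
            raise ConfigError("library totals must be positive")
        sums = counts.sum(axis=0)
        bad = [lib for lib in LIBRARIES if sums[lib] > totals[lib]]
        if bad:
            raise ConfigError(
                f"per-library count sums exceed declared totals for {bad}"
            )
        self.counts = counts
        self.totals = totals

    @classmethod
    def from_frame(
        cls, counts: pd.DataFrame, totals: pd.Series | dict | None = None
    ) -> "CountMatrix":
        """Build a matrix, defaulting totals to the realized column sums."""
        if totals is None:
            totals = counts.sum(axis=0)
        return cls(counts=counts.copy(), totals=pd.Series(totals))

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    def __len__(self) -> int:
        return len(self.counts)


def _length_series(catalog: pd.DataFrame) -> pd.Series:
    """Extract a gene_id-indexed length series from a catalog frame."""
    if "gene_id" in catalog.columns:
        lengths = catalog.set_index("gene_id")["length_bp"]
    else:
        lengths = catalog["length_bp"]
    if lengths.index.has_duplicates:
        raise ConfigError("duplicate gene ids in catalog")
    return lengths


# ---------------------------------------------------------------------------
# RPKM and expressed-gene calls
# ---------------------------------------------------------------------------


def compute_rpkm(counts: CountMatrix, catalog: pd.DataFrame) -> pd.DataFrame:
    """Reads per kilobase of gene model per million assigned reads.

    rpkm = count / (length_bp / 1000) / (library_total / 1e6)

    Parameters
    ----------
    counts
        The three-library count matrix.
    catalog
        Frame with ``gene_id`` and ``length_bp`` columns (or gene-id index).

    Raises
    ------
    ComputeError
        If any gene in the count matrix has no catalog entry; the error
        message lists the offending ids.
    """
    lengths = _length_series(catalog)
    missing = counts.gene_ids.difference(lengths.index)
    if len(missing) > 0:
        shown = list(missing[:10])
        raise ComputeError(
            f"{len(missing)} gene(s) missing from the length catalog: {shown}"
        )
    lengths = lengths.loc[counts.gene_ids].astype(float)
    if (lengths <= 0).any():
        raise ConfigError("gene lengths must be positive")
    kb = lengths / 1000.0
    rpkm = counts.counts.astype(float)
    for lib in LIBRARIES:
        rpkm[lib] = rpkm[lib] / kb / (float(counts.totals[lib]) / 1e6)
    return rpkm


def call_expressed(counts: CountMatrix, min_count: int = 1) -> pd.DataFrame:
    """Per-gene, per-library expression flags: count >= ``min_count``."""
    if min_count < 1:
        raise ConfigError("min_count must be >= 1")
    return counts.counts >= int(min_count)


# ---------------------------------------------------------------------------
# Venn partition
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VennPartition:
    """Counts of the seven regions of a three-set Venn diagram.

    Region names follow membership: ``abc`` is the triple intersection,
    ``ab``/``ac``/``bc`` are pairwise-only regions, and ``a``/``b``/``c``
    are library-specific genes.
    """

    abc: int
    ab: int
    ac: int
    bc: int
    a: int
    b: int
    c: int

    def library_total(self, lib: str) -> int:
        """Number of genes expressed in one library (sum of its 4 regions)."""
        if lib == "A":
            return self.abc + self.ab + self.ac + self.a
        if lib == "B":
            return self.abc + self.ab + self.bc + self.b
        if lib == "C":
            return self.abc + self.ac + self.bc + self.c
        raise ConfigError(f"unknown library {lib!r}")

    @property
    def library_totals(self) -> dict[str, int]:
        return {lib: self.library_total(lib) for lib in LIBRARIES}

    @property
    def grand_total(self) -> int:
        """Genes expressed in at least one library."""
        return self.abc + self.ab + self.ac + self.bc + self.a + self.b + self.c

    def to_dict(self) -> dict[str, int]:
        d = {
            "ABC": self.abc,
            "AB_only": self.ab,
            "AC_only": self.ac,
            "BC_only": self.bc,
            "A_only": self.a,
            "B_only": self.b,
            "C_only": self.c,
        }
        d.update({f"total_{k}": v for k, v in self.library_totals.items()})
        d["grand_total"] = self.grand_total
        return d


def venn_partition(flags: pd.DataFrame) -> VennPartition:
    """Partition expressed-gene flags into the seven Venn regions."""
    fa = flags["A"].to_numpy(dtype=bool)
    fb = flags["B"].to_numpy(dtype=bool)
    fc = flags["C"].to_numpy(dtype=bool)
    return VennPartition(
        abc=int((fa & fb & fc).sum()),
        ab=int((fa & fb & ~fc).sum()),
        ac=int((fa & ~fb & fc).sum()),
        bc=int((~fa & fb & fc).sum()),
        a=int((fa & ~fb & ~fc).sum()),
        b=int((~fa & fb & ~fc).sum()),
        c=int((~fa & ~fb & fc).sum()),
    )


# ---------------------------------------------------------------------------
# Length and coverage binning
# ---------------------------------------------------------------------------


def length_bin_counts(lengths) -> np.ndarray:
    """Counts of genes in the five length bins ([100,500), ..., [2000, inf))."""
    lengths = np.asarray(lengths)
    if len(lengths) == 0:
        raise ConfigError("empty gene set")
    if (lengths < LENGTH_BIN_EDGES[0]).any():
        raise ConfigError(f"gene lengths below {LENGTH_BIN_EDGES[0]} bp")
    edges = list(LENGTH_BIN_EDGES) + [np.inf]
    counts, _ = np.histogram(lengths, bins=edges)
    return counts.astype(int)


def bin_percentages(counts) -> np.ndarray:
    """Percentages of a bin-count vector, rounded half-up to 2 decimals."""
    counts = np.asarray(counts, dtype=float)
    return round_half_up(counts / counts.sum() * 100.0, 2)


def length_bin_summary(lengths) -> pd.DataFrame:
    """Five-bin length distribution of a gene set, with printed-style shares."""
    counts = length_bin_counts(lengths)
    return pd.DataFrame(
        {
            "bin": LENGTH_BIN_LABELS,
            "count": counts,
            "percentage": bin_percentages(counts),
        }
    )


def coverage_bins(fractions) -> pd.DataFrame:
    """Decile binning of per-gene covered fraction, per library.

    Accepts a Series (one library) or a genes x libraries frame of covered
    fractions in [0, 1].  Bins are (0,10%], (10%,20%], ..., (90%,100%];
    a fraction of exactly 0 means the gene was not matched by any read and
    is excluded.
    """
    if isinstance(fractions, pd.Series):
        fractions = fractions.to_frame("coverage")
    vals = fractions.to_numpy(dtype=float)
    if np.isnan(vals).any() or (vals < 0).any() or (vals > 1).any():
        raise ConfigError("coverage fractions must lie in [0, 1]")
    labels = [f"{10 * i}-{10 * (i + 1)}%" for i in range(10)]
    out = {}
    edges = np.linspace(0.0, 1.0, 11)
    for col in fractions.columns:
        v = fractions[col].to_numpy(dtype=float)
        v = v[v > 0]
        # right-closed bins; searchsorted maps (0,0.1] -> 0, ..., (0.9,1] -> 9
        idx = np.clip(np.searchsorted(edges, v, side="left") - 1, 0, 9)
        out[col] = np.bincount(idx, minlength=10)
    return pd.DataFrame(out, index=labels)


# ---------------------------------------------------------------------------
# Saturation analysis
# ---------------------------------------------------------------------------


@dataclass
class SaturationCurve:
    """Genes detected at increasing subsampling depths.

    ``detected`` holds one row per replicate; ``detected_mean`` is the
    across-replicate average used by :func:`saturation_point`.
    """

    depths: np.ndarray
    detected: np.ndarray  # shape (n_reps, n_depths)
    min_count: int
    detected_mean: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=np.int64)
        self.detected = np.atleast_2d(np.asarray(self.detected, dtype=float))
        self.detected_mean = self.detected.mean(axis=0)


def saturation_curve(
    gene_counts,
    depths,
    min_count: int = 1,
    n_reps: int = 3,
    seed: int | None | np.random.Generator = None,
) -> SaturationCurve:
    """Subsample reads to increasing depths and count detected genes.

    Reads are drawn without replacement (multivariate hypergeometric over
    the per-gene counts).  Within a replicate the draws are nested: the
    sample at each depth is a subsample of the next deeper one, so every
    replicate's detection curve is monotone nondecreasing by construction.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = np.asarray(gene_counts, dtype=np.int64)
    if (counts < 0).any():
        raise ConfigError("gene counts must be nonnegative")
    total = int(counts.sum())
    depths = np.unique(np.asarray(depths, dtype=np.int64))
    if (depths < 0).any():
        raise ConfigError("depths must be nonnegative")
    if depths.max(initial=0) > total:
        raise ConfigError(
            f"requested depth {int(depths.max())} exceeds library total {total}"
        )
    if min_count < 1:
        raise ConfigError("min_count must be >= 1")
    detected = np.zeros((n_reps, len(depths)), dtype=float)
    for rep in range(n_reps):
        sample = counts
        for j in range(len(depths) - 1, -1, -1):
            d = int(depths[j])
            if d == int(sample.sum()):
                pass  # full depth: the sample is the library itself
            else:
                sample = rng.multivariate_hypergeometric(sample, d)
            detected[rep, j] = int((sample >= min_count).sum())
    return SaturationCurve(depths=depths, detected=detected, min_count=min_count)


def saturation_point(
    curve: SaturationCurve, gain_threshold: float = 0.005
) -> int | None:
    """Depth at which gene discovery effectively plateaus.

    Returns the smallest grid depth after which the marginal detection
    rate, expressed as genes gained per additional million reads, falls
    below ``gain_threshold`` times the total genes detected at full depth.
    Returns ``None`` if the curve never flattens on the grid.
    """
    if len(curve.depths) < 3:
        raise ConfigError("saturation grid needs at least 3 depths")
    det = curve.detected_mean
    depths = curve.depths.astype(float)
    total_detected = det[-1]
    if total_detected <= 0:
        return None
    for i in range(len(depths) - 1):
        gain_per_million = (det[i + 1] - det[i]) / ((depths[i + 1] - depths[i]) / 1e6)
        if gain_per_million < gain_threshold * total_detected:
            return int(curve.depths[i])
    return None
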