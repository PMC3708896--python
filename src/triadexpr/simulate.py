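"""Ground-truth simulator for three-library allopolyploid count data.

Generates the kind of dataset the downstream analysis assumes: one
paternal-parent library (A), one maternal-parent library (B) and one
hybrid library (C), with

* a gene catalog whose length distribution follows five configurable
  length bins,
* library-specific (truly silent elsewhere) genes,
* a configurable fraction of parent-divergent genes with symmetric
  log2 effects,
* a configurable fraction of nonadditive genes whose hybrid mean deviates
  from the parental midpoint, with a paternal-bias knob controlling which
  parent the hybrid tends to deviate away from,
* negative-binomial (Poisson in the zero-dispersion limit) read counts.

Every stage is driven by a named substream of one global seed, so the
catalog, the truth table and the counts can be regenerated independently.
The defaults emulate the study conditions this pipeline is built around:
~32.6k detected genes, the printed length-bin shares, library depths in
the 5.5-8.6 million assigned-read range, ~7.8% nonadditive genes and a
positive paternal bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import ComputeError, ConfigError
from .quantify import CountMatrix, LIBRARIES

_STREAMS = {"catalog": 0, "truth": 1, "counts": 2}

#: Fold-change threshold defining a "true" expression difference in the
#: truth table (matches the pipeline's headline two-fold rule).
TRUE_DE_LOG2_MIN = 1.0


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic three-library experiment.

    Attributes
    ----------
    n_genes
        Catalog size.
    length_bin_weights
        Probabilities over the five length bins
        [100,500), [500,1000), [1000,1500), [1500,2000), [2000,inf).
    library_sizes
        Target assigned-read totals for (A, B, C).
    frac_specific
        Per-library probability that a gene is expressed only there
        (true-zero expression elsewhere); scalar or one value per library.
    frac_de_parents
        Probability that a gene's parental means differ; the signed log2
        effect is Laplace(0, ``de_log2_scale``) distributed (symmetric,
        heavy-tailed, so a realistic share of effects sit below any
        fold-change threshold).
    frac_nonadditive
        Probability that the hybrid mean deviates from the parental
        midpoint; the deviation magnitude is ``nonadditive_log2_min`` plus
        an Exponential(``nonadditive_log2_scale``) excess, so every
        nonadditive gene deviates by at least the configured minimum.
    paternal_bias
        In [-1, 1]; the probability that a nonadditive deviation moves the
        hybrid away from the paternal parent A (toward B) is
        (1 + paternal_bias) / 2 for parent-divergent genes.
    dispersion
        Negative-binomial overdispersion alpha (variance = m + alpha m^2);
        0 gives Poisson counts.
    base_log_rpkm_mean, base_log_rpkm_sd
        Natural-log parameters of the log-normal base expression level;
        levels are rescaled afterwards so the expected assigned reads of
        library A match its configured size.
    seed
        Global seed; three named substreams derive from it.
    """

    n_genes: int = 32642
    length_bin_weights: tuple = (0.1546, 0.3071, 0.2541, 0.1362, 0.1480)
    library_sizes: tuple = (8_594_083, 5_479_383, 6_267_830)
    frac_specific: tuple = (0.0426, 0.0284, 0.0277)
    frac_de_parents: float = 0.25
    de_log2_scale: float = 1.5
    frac_nonadditive: float = 0.078
    nonadditive_log2_min: float = 1.0
    nonadditive_log2_scale: float = 0.5
    paternal_bias: float = 0.2
    dispersion: float = 0.05
    base_log_rpkm_mean: float = 1.0
    base_log_rpkm_sd: float = 1.5
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ConfigError("n_genes must be positive")
        w = np.asarray(self.length_bin_weights, dtype=float)
        if w.shape != (5,) or (w < 0).any() or abs(w.sum() - 1.0) > 1e-6:
            raise ConfigError(
                "length_bin_weights must be 5 nonnegative values summing to 1"
            )
        sizes = np.asarray(self.library_sizes)
        if sizes.shape != (3,) or (sizes < 1).any():
            raise ConfigError("library_sizes must be 3 positive integers")
        fs = np.atleast_1d(np.asarray(self.frac_specific, dtype=float))
        if fs.size == 1:
            fs = np.repeat(fs, 3)
        if fs.shape != (3,) or (fs < 0).any() or (fs > 1).any() or fs.sum() > 1:
            raise ConfigError(
                "frac_specific must be per-library probabilities with sum <= 1"
            )
        object.__setattr__(self, "frac_specific", tuple(float(x) for x in fs))
        for name in ("frac_de_parents", "frac_nonadditive"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        if not -1.0 <= self.paternal_bias <= 1.0:
            raise ConfigError("paternal_bias must lie in [-1, 1]")
        if self.dispersion < 0:
            raise ConfigError("dispersion must be nonnegative")
        for name in ("de_log2_scale", "nonadditive_log2_scale"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be nonnegative")
        if self.nonadditive_log2_min < 0:
            raise ConfigError("nonadditive_log2_min must be nonnegative")

    def rng(self, stream: str) -> np.random.Generator:
        """Named, independent substream of the global seed."""
        key = _STREAMS[stream]
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(key,))
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["length_bin_weights"] = list(self.length_bin_weights)
        d["library_sizes"] = [int(x) for x in self.library_sizes]
        d["frac_specific"] = list(self.frac_specific)
        return d


# ---------------------------------------------------------------------------
# Catalog
# ---------------------------------------------------------------------------

_BIN_BOUNDS = ((100, 500), (500, 1000), (1000, 1500), (1500, 2000))
#: Mean excess length (bp) beyond 2000 in the open-ended bin
#: (shifted geometric tail).
_TAIL_MEAN_EXCESS = 1400.0


def generate_catalog(config: SimulationConfig) -> pd.DataFrame:
    """Draw a gene catalog: unique ids plus lengths per the bin weights.

    Lengths are uniform within each bounded bin; the open-ended >=2000 bin
    uses a shifted geometric tail with mean excess ``_TAIL_MEAN_EXCESS``.
    """
    rng = config.rng("catalog")
    n = config.n_genes
    bins = rng.choice(5, size=n, p=np.asarray(config.length_bin_weights))
    lengths = np.empty(n, dtype=np.int64)
    for b, (lo, hi) in enumerate(_BIN_BOUNDS):
        mask = bins == b
        lengths[mask] = rng.integers(lo, hi, size=int(mask.sum()))
    tail = bins == 4
    lengths[tail] = 2000 + rng.geometric(1.0 / _TAIL_MEAN_EXCESS, size=int(tail.sum())) - 1
    width = max(6, len(str(n)))
    ids = [f"g{i:0{width}d}" for i in range(1, n + 1)]
    return pd.DataFrame({"gene_id": ids, "length_bp": lengths})


# ---------------------------------------------------------------------------
# Truth table
# ---------------------------------------------------------------------------


def _true_log2(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    """log2(num/den) with +-inf for on/off genes and NaN when both are 0."""
    out = np.full(num.shape, np.nan)
    both = (num > 0) & (den > 0)
    out[both] = np.log2(num[both] / den[both])
    out[(num > 0) & (den == 0)] = np.inf
    out[(num == 0) & (den > 0)] = -np.inf
    return out


def _true_de(log2fc: np.ndarray) -> np.ndarray:
    """True two-fold differences; NaN (double-zero) is not a difference."""
    with np.errstate(invalid="ignore"):
        return np.abs(log2fc) >= TRUE_DE_LOG2_MIN


def _pattern_group(
    de_a: np.ndarray, de_b: np.ndarray, l2a: np.ndarray, l2b: np.ndarray
) -> np.ndarray:
    """Four-way pattern group from the signs of the hybrid/parent ratios.

    Group 1: down vs both parents; 2: down vs A, up vs B; 3: up vs A,
    down vs B; 4: up vs both.  A ratio of exactly 1 (log ratio 0) counts
    as "down" so the groups partition.  0 means not differential.
    """
    up_a = l2a > 0
    up_b = l2b > 0
    group = np.where(up_a, np.where(up_b, 4, 3), np.where(up_b, 2, 1)).astype(np.int8)
    group[~(de_a | de_b)] = 0
    # genes silent everywhere carry no pattern
    group[np.isnan(l2a) & np.isnan(l2b)] = 0
    return group


def generate_truth(catalog: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    """Draw per-gene true expression states for the three libraries.

    Parental means split a log-normal base level symmetrically by the
    drawn log2 effect; the hybrid mean is the parental midpoint unless the
    gene is nonadditive, in which case it is shifted by the drawn signed
    log2 deviation.  Library-specific genes are truly zero elsewhere.
    Levels are calibrated so library A's expected assigned reads equal its
    configured size.
    """
    rng = config.rng("truth")
    n = len(catalog)
    base = np.exp(rng.normal(config.base_log_rpkm_mean, config.base_log_rpkm_sd, n))

    de = rng.random(n) < config.frac_de_parents
    eff = np.zeros(n)
    eff[de] = rng.laplace(0.0, config.de_log2_scale, int(de.sum()))
    mean_a = base * 2.0 ** (-eff / 2.0)
    mean_b = base * 2.0 ** (eff / 2.0)

    nonadd = rng.random(n) < config.frac_nonadditive
    mag = config.nonadditive_log2_min + rng.exponential(
        config.nonadditive_log2_scale, n
    )
    toward_b = rng.random(n) < (1.0 + config.paternal_bias) / 2.0
    coin = rng.choice(np.array([-1.0, 1.0]), size=n)
    # deviation direction: away from the paternal parent with probability
    # (1+bias)/2 when the parents diverge; coin flip when they do not
    divergent = eff != 0.0
    away_sign = np.where(toward_b, np.sign(eff), -np.sign(eff))
    direction = np.where(divergent, away_sign, coin)
    dev = np.where(nonadd, direction * mag, 0.0)

    # library-specific silence (true zeros elsewhere); the divergence and
    # deviation draws no longer apply to specific genes
    fa, fb, fc = config.frac_specific
    u = rng.random(n)
    specific = np.select(
        [u < fa, u < fa + fb, u < fa + fb + fc], ["A", "B", "C"], default=""
    )
    is_specific = specific != ""
    mean_a[np.isin(specific, ["B", "C"])] = 0.0
    mean_b[np.isin(specific, ["A", "C"])] = 0.0
    eff[is_specific] = 0.0
    de[is_specific] = False
    dev[is_specific] = 0.0

    deviates_from = np.full(n, "", dtype=object)
    hit = nonadd & divergent & ~is_specific
    deviates_from[hit] = np.where(toward_b[hit], "A", "B")

    # calibrate so library A's expected assigned reads hit the target,
    # then derive the hybrid mean from the *scaled* parental midpoint so
    # that additive genes sit on the midparent value bit-for-bit
    kb = catalog["length_bp"].to_numpy(dtype=float) / 1000.0
    mass_a = float((mean_a * kb).sum())
    if mass_a <= 0:
        raise ComputeError("library A has zero expected expression mass")
    scale = 1e6 / mass_a
    mean_a = mean_a * scale
    mean_b = mean_b * scale

    mpv = (mean_a + mean_b) / 2.0
    mean_c = np.where(dev != 0.0, mpv * 2.0**dev, mpv)
    mean_c[np.isin(specific, ["A", "B"])] = 0.0
    mean_c[specific == "C"] = base[specific == "C"] * scale

    nonadditive = mean_c != mpv
    mpv_log2_dev = _true_log2(mean_c, mpv)
    mpv_log2_dev[~nonadditive] = 0.0

    l2ca = _true_log2(mean_c, mean_a)
    l2cb = _true_log2(mean_c, mean_b)
    de_vs_a = _true_de(l2ca)
    de_vs_b = _true_de(l2cb)

    return pd.DataFrame(
        {
            "gene_id": catalog["gene_id"].to_numpy(),
            "mean_rpkm_A": mean_a,
            "mean_rpkm_B": mean_b,
            "mean_rpkm_C": mean_c,
            "specific_to": specific,
            "de_parents": de,
            "parent_log2fc": eff,
            "nonadditive": nonadditive,
            "mpv_log2_dev": mpv_log2_dev,
            "deviates_from": deviates_from,
            "true_log2_CA": l2ca,
            "true_log2_CB": l2cb,
            "de_vs_A": de_vs_a,
            "de_vs_B": de_vs_b,
            "pattern_group": _pattern_group(de_vs_a, de_vs_b, l2ca, l2cb),
        }
    )


# ---------------------------------------------------------------------------
# Count sampling
# ---------------------------------------------------------------------------


def sample_counts(
    truth: pd.DataFrame, catalog: pd.DataFrame, config: SimulationConfig
) -> CountMatrix:
    """Draw the three-library count matrix from the truth table.

    Counts are negative-binomial with mean
    ``true_rate * (length/1000) * (library_size/1e6)`` and variance
    ``m + dispersion * m**2`` (gamma-Poisson mixture); ``dispersion=0``
    degenerates to Poisson.  Realized column sums become the library
    totals of the returned matrix.
    """
    rng = config.rng("counts")
    kb = catalog["length_bp"].to_numpy(dtype=float) / 1000.0
    cols = {}
    for lib, size in zip(LIBRARIES, config.library_sizes):
        m = truth[f"mean_rpkm_{lib}"].to_numpy(dtype=float) * kb * (float(size) / 1e6)
        if (m < 0).any() or not np.isfinite(m).all():
            raise ComputeError(f"negative or non-finite expected counts in {lib}")
        if m.max(initial=0.0) > 2**53:
            raise ComputeError("expected counts overflow the integer range")
        if config.dispersion > 0:
            lam = np.zeros_like(m)
            pos = m > 0
            shape = 1.0 / config.dispersion
            lam[pos] = rng.gamma(shape, config.dispersion * m[pos])
            cols[lib] = rng.poisson(lam)
        else:
            cols[lib] = rng.poisson(m)
    counts = pd.DataFrame(cols, index=pd.Index(truth["gene_id"], name="gene_id"))
    counts = counts.astype(np.int64)
    return CountMatrix.from_frame(counts)


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, CountMatrix]:
    """Convenience wrapper: catalog, truth table and counts in one call."""
    catalog = generate_catalog(config)
    truth = generate_truth(catalog, config)
    counts = sample_counts(truth, catalog, config)
    return catalog, truth, counts
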