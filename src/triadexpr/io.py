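"""File formats, pipeline configuration and the end-to-end report runner.

All tabular interchange is header-carrying TSV; summaries are JSON.  The
count table uses columns ``gene_id, count_A, count_B, count_C`` (a
``length`` column, as written by the simulator, is tolerated); gene
lengths come either from a two-column TSV (``gene_id, length_bp``) or a
BED file, whose lengths are ``end - start`` in 0-based half-open
coordinates.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bias as bias_mod
from . import categories as categories_mod
from . import nonadditivity as nonadd_mod
from . import patterns as patterns_mod
from .diffexpr import call_degs, deg_direction_counts
from .errors import ComputeError, ConfigError, ParseError
from .quantify import (
    LIBRARIES,
    CountMatrix,
    call_expressed,
    compute_rpkm,
    coverage_bins,
    length_bin_summary,
    saturation_curve,
    saturation_point,
    venn_partition,
)

logger = logging.getLogger(__name__)

COUNT_COLUMNS = {lib: f"count_{lib}" for lib in LIBRARIES}


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def read_counts(path, totals: dict | None = None) -> CountMatrix:
    """Read the three-library count TSV into a validated count matrix.

    Library totals default to the column sums unless supplied (e.g. when
    reads were also assigned to genes outside the table).
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if "gene_id" not in frame.columns:
        raise ParseError(f"{path}: missing required column 'gene_id'")
    for lib, col in COUNT_COLUMNS.items():
        if col not in frame.columns:
            if lib in frame.columns:  # bare library names also accepted
                frame = frame.rename(columns={lib: col})
            else:
                raise ParseError(f"{path}: missing required column {col!r}")
    dup = frame["gene_id"][frame["gene_id"].duplicated()]
    if len(dup) > 0:
        lines = [str(i + 2) for i in dup.index[:5]]  # +2: header + 1-based
        raise ParseError(
            f"{path}: duplicate gene id(s) {sorted(set(dup))[:5]} "
            f"(line(s) {', '.join(lines)})"
        )
    counts = frame.set_index("gene_id")[list(COUNT_COLUMNS.values())]
    for col in counts.columns:
        vals = counts[col]
        numeric = pd.to_numeric(vals, errors="coerce")
        bad = numeric.isna() | (numeric != numeric.round()) | (numeric < 0)
        if bad.any():
            line = int(np.argmax(bad.to_numpy())) + 2
            raise ParseError(
                f"{path}: column {col!r} must hold nonnegative integers "
                f"(first offence at line {line})"
            )
        counts[col] = numeric.astype(np.int64)
    counts.columns = list(LIBRARIES)
    try:
        return CountMatrix.from_frame(counts, totals=totals)
    except ConfigError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def read_lengths(path) -> pd.DataFrame:
    """Read a gene catalog from a 2-column TSV or a BED file.

    TSV needs ``gene_id`` and ``length_bp`` columns (or two unnamed
    columns in that order).  BED rows contribute ``end - start``; the
    name field (column 4) supplies the gene id, falling back to column 1.
    """
    path = Path(path)
    try:
        with open(path) as fh:
            first = fh.readline()
    except OSError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if not first.strip():
        raise ParseError(f"{path}: empty file")
    fields = first.rstrip("\n").split("\t")

    def _is_int(s: str) -> bool:
        try:
            int(s)
            return True
        except ValueError:
            return False

    is_bed = len(fields) >= 3 and _is_int(fields[1]) and _is_int(fields[2])
    if is_bed:
        # parse by hand: BED rows legitimately vary in column count
        ids, lengths = [], []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                cols = line.split("\t")
                if len(cols) < 3 or not (_is_int(cols[1]) and _is_int(cols[2])):
                    raise ParseError(f"{path}: malformed BED line {lineno}")
                ids.append(cols[3] if len(cols) >= 4 else cols[0])
                lengths.append(int(cols[2]) - int(cols[1]))
        catalog = pd.DataFrame(
            {"gene_id": ids, "length_bp": np.asarray(lengths, dtype=np.int64)}
        )
    else:
        tsv = pd.read_csv(path, sep="\t")
        if "gene_id" not in tsv.columns or "length_bp" not in tsv.columns:
            if tsv.shape[1] == 2:
                tsv.columns = ["gene_id", "length_bp"]
            else:
                raise ParseError(
                    f"{path}: expected 'gene_id' and 'length_bp' columns or BED"
                )
        catalog = tsv[["gene_id", "length_bp"]].copy()
        catalog["gene_id"] = catalog["gene_id"].astype(str)
    if (catalog["length_bp"] < 1).any():
        bad = catalog.loc[catalog["length_bp"] < 1, "gene_id"].tolist()[:5]
        raise ParseError(f"{path}: nonpositive gene length(s) for {bad}")
    if catalog["gene_id"].duplicated().any():
        dup = catalog["gene_id"][catalog["gene_id"].duplicated()].tolist()[:5]
        raise ParseError(f"{path}: duplicate gene id(s) {dup}")
    return catalog.reset_index(drop=True)


def read_categories(path) -> pd.DataFrame:
    """Read the two-column gene-to-category annotation TSV."""
    path = Path(path)
    frame = pd.read_csv(path, sep="\t")
    if "gene_id" not in frame.columns or "category" not in frame.columns:
        if frame.shape[1] == 2:
            frame.columns = ["gene_id", "category"]
        else:
            raise ParseError(f"{path}: expected 'gene_id' and 'category' columns")
    frame["gene_id"] = frame["gene_id"].astype(str)
    return frame


def read_coverage(path) -> pd.DataFrame:
    """Read a per-gene covered-fraction table (gene_id + one column per library)."""
    frame = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    if "gene_id" not in frame.columns:
        raise ParseError(f"{path}: missing required column 'gene_id'")
    return frame.set_index("gene_id")


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_counts(counts: CountMatrix, catalog: pd.DataFrame, path) -> None:
    """Write the simulator-style count TSV (with a length column)."""
    lengths = catalog.set_index("gene_id")["length_bp"]
    out = counts.counts.rename(columns=COUNT_COLUMNS).copy()
    out.insert(0, "length", lengths.loc[counts.gene_ids].to_numpy())
    out.to_csv(path, sep="\t", index_label="gene_id")


def write_table(frame: pd.DataFrame, path, float_decimals: int = 6) -> None:
    frame.to_csv(path, sep="\t", float_format=f"%.{float_decimals}g")


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)!r}")


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Pipeline configuration and report runner
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Everything the end-to-end report runner needs.

    ``saturation_depths`` defaults to an 8-point grid up to each
    library's realized total.  Thresholds follow the headline DEG rule
    (two-fold, FDR 0.001, one read to count a gene as expressed).
    """

    counts_path: str
    lengths_path: str
    categories_path: str | None = None
    coverage_path: str | None = None
    min_count: int = 1
    fc_min: float = 2.0
    fdr_max: float = 0.001
    epsilon: float = 0.001
    saturation_depths: list | None = None
    saturation_reps: int = 2
    gain_threshold: float = 0.005
    seed: int = 1
    library_totals: dict | None = None
    summed_fc_method: str = "fold_change"

    def __post_init__(self) -> None:
        if self.min_count < 1:
            raise ConfigError("min_count must be >= 1")
        if self.fc_min < 1:
            raise ConfigError("fc_min must be >= 1")
        if not 0 < self.fdr_max <= 1:
            raise ConfigError("fdr_max must lie in (0, 1]")
        if self.epsilon <= 0:
            raise ConfigError("epsilon must be positive")
        if self.saturation_reps < 1:
            raise ConfigError("saturation_reps must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        try:
            return cls(**data)
        except TypeError as exc:
            raise ConfigError(f"{path}: {exc}") from exc

    def to_dict(self) -> dict:
        return asdict(self)


def _stage(name: str):
    """Decorator-free stage guard: re-raise with the failing stage's name."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is None or not isinstance(exc, Exception):
                return False
            if isinstance(exc, (ConfigError, ParseError)):
                raise type(exc)(f"stage '{name}': {exc}") from exc
            raise ComputeError(f"stage '{name}' failed: {exc}") from exc

    return _Ctx()


def run_report(config: PipelineConfig, out_dir) -> dict:
    """Run the full analysis and write the JSON + TSV bundle.

    Stages: quantify (RPKM, expressed flags, Venn, length bins,
    saturation, optional coverage bins) -> DEG calling for both
    hybrid/parent comparisons -> nonadditivity vs the MPV -> pattern
    assignment -> parental-bias summary -> optional category contrast.
    Deterministic given the seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config": config.to_dict()}

    with _stage("quantify"):
        counts = read_counts(config.counts_path, totals=config.library_totals)
        catalog = read_lengths(config.lengths_path)
        rpkm = compute_rpkm(counts, catalog)
        flags = call_expressed(counts, min_count=config.min_count)
        venn = venn_partition(flags)
        detected = flags.any(axis=1)
        bins = length_bin_summary(
            catalog.set_index("gene_id")["length_bp"].loc[counts.gene_ids[detected]]
        )
        write_table(rpkm, out_dir / "rpkm.tsv")
        write_json(venn.to_dict(), out_dir / "venn.json")
        bins.to_csv(out_dir / "length_bins.tsv", sep="\t", index=False)
        summary["venn"] = venn.to_dict()
        summary["length_bins"] = bins.to_dict(orient="list")

    with _stage("saturate"):
        rng = np.random.default_rng(config.seed)
        sat_rows = []
        sat_depths = {}
        for lib in LIBRARIES:
            total = int(counts.counts[lib].sum())
            if config.saturation_depths is not None:
                depths = [d for d in config.saturation_depths if d <= total]
            else:
                depths = np.unique(
                    np.linspace(0, total, 9, dtype=np.int64)
                ).tolist()
            curve = saturation_curve(
                counts.counts[lib].to_numpy(),
                depths,
                min_count=config.min_count,
                n_reps=config.saturation_reps,
                seed=rng,
            )
            plateau = saturation_point(curve, gain_threshold=config.gain_threshold)
            sat_depths[lib] = plateau
            for d, m in zip(curve.depths, curve.detected_mean):
                sat_rows.append({"library": lib, "depth": int(d), "detected": m})
        pd.DataFrame(sat_rows).to_csv(out_dir / "saturation.tsv", sep="\t", index=False)
        summary["saturation_depth"] = sat_depths

    if config.coverage_path:
        with _stage("coverage"):
            cov = read_coverage(config.coverage_path)
            cov_bins = coverage_bins(cov)
            cov_bins.to_csv(out_dir / "coverage_bins.tsv", sep="\t", index_label="bin")
            summary["coverage_bins"] = cov_bins.to_dict(orient="list")

    degs = {}
    with _stage("deg"):
        for ref in ("A", "B"):
            table = call_degs(
                counts,
                rpkm,
                test_lib="C",
                ref_lib=ref,
                fc_min=config.fc_min,
                fdr_max=config.fdr_max,
                epsilon=config.epsilon,
                min_count=config.min_count,
            )
            degs[ref] = table
            write_table(table, out_dir / f"deg_C_vs_{ref}.tsv")
            counts_dir = deg_direction_counts(table)
            counts_dir["summed_fold_change"] = bias_mod.summed_fold_change(
                table, method=config.summed_fc_method
            )
            summary[f"deg_C_vs_{ref}"] = counts_dir
        union = degs["A"].index[degs["A"]["is_deg"]].union(
            degs["B"].index[degs["B"]["is_deg"]]
        )
        summary["deg_union"] = int(len(union))

    with _stage("nonadditive"):
        calls = nonadd_mod.classify_additivity(
            counts,
            rpkm,
            catalog,
            fc_min=config.fc_min,
            fdr_max=config.fdr_max,
            epsilon=config.epsilon,
            min_count=config.min_count,
        )
        write_table(calls, out_dir / "nonadditive.tsv")
        summary["nonadditivity"] = nonadd_mod.additivity_summary(
            calls, n_detected=int(detected.sum())
        )

    with _stage("patterns"):
        profiles = patterns_mod.log_ratio_profiles(rpkm, epsilon=config.epsilon)
        assignment = patterns_mod.assign_patterns(degs["A"], degs["B"], profiles)
        write_table(assignment, out_dir / "patterns.tsv")
        summary["pattern_groups"] = {
            str(k): v for k, v in patterns_mod.group_counts(assignment).items()
        }
        summary["pattern_clusters"] = {
            str(k): v
            for k, v in patterns_mod.group_counts(assignment, "cluster").items()
        }
        summary["nonadditive_deg_overlap"] = nonadd_mod.deg_overlap(
            calls, degs["A"], degs["B"], patterns=assignment
        )

    with _stage("bias"):
        d = bias_mod.score_deg_union(rpkm, degs["A"], degs["B"], epsilon=config.epsilon)
        if len(d) > 0:
            bsum = bias_mod.bias_summary(d.to_numpy())
            summary["bias"] = bsum.to_dict()
            write_json(bsum.to_dict(), out_dir / "bias_summary.json")
        else:
            summary["bias"] = None

    if config.categories_path:
        with _stage("contrast"):
            ann = read_categories(config.categories_path)
            contrast = categories_mod.contrast_categories(calls, ann)
            write_table(contrast, out_dir / "category_contrast.tsv")
            summary["category_contrast"] = {
                "tested": int(len(contrast)),
                "significant_fdr_0.05": int((contrast["fdr"] <= 0.05).sum())
                if len(contrast)
                else 0,
            }

    write_json(summary, out_dir / "report.json")
    return summary
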