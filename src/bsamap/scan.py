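"""The |Δ(SNP-index)| scan: indices, filters, windows, bootstrap thresholds.

The SNP index of a bulk at a variant is the fraction of reads carrying the
non-reference allele; Δ is the female-bulk index minus the male-bulk index.
For highly heterozygous outbred material the ref/alt labelling can flip
locally ("pseudoexchange effect"), so the scan statistic is |Δ| — invariant
under any labelling — averaged over sliding genomic windows and compared to
depth-specific null thresholds obtained by simulating bulk composition and
read sampling under no trait-locus effect.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ScanConfig",
    "ThresholdTable",
    "ZeroDepthError",
    "compute_snp_index",
    "delta_index",
    "add_snp_indices",
    "filter_variants",
    "sliding_windows",
    "bootstrap_thresholds",
    "attach_thresholds",
    "call_regions",
    "scan",
]


class ZeroDepthError(ValueError):
    """The SNP index is undefined at zero read depth."""


@dataclass
class ScanConfig:
    """Tuning parameters of the scan.

    min_index / min_depth reproduce the variant filter (drop a variant whose
    index is below ``min_index`` in both bulks, or whose depth is below
    ``min_depth``); ``depth_rule`` selects whether the depth cut triggers
    when *either* bulk (default) or only when *both* bulks are shallow.
    Window and step sizes, bootstrap replicates and confidence levels
    default to the standard 2 Mb / 100 kb / 1000 / {95%, 99%} settings.

    ``null_model`` chooses the no-locus resampling scheme for thresholds:
    ``"two_stage"`` (default) draws the bulk composition of a paternal
    testcross site — k heterozygous individuals ~ Binomial(bulk_size, 1/2),
    alternate haplotype frequency k/(2*bulk_size) — then reads binomially;
    ``"read_only"`` skips the composition stage and uses the fixed read
    probability ``null_p``.
    """

    min_index: float = 0.3
    min_depth: int = 7
    window_bp: int = 2_000_000
    step_bp: int = 100_000
    n_bootstrap: int = 1000
    conf_levels: tuple[float, ...] = (0.95, 0.99)
    bulk_size: int = 30
    null_model: str = "two_stage"
    null_p: float = 0.25
    depth_rule: str = "either"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.step_bp > self.window_bp:
            raise ValueError("step_bp must not exceed window_bp")
        if self.step_bp <= 0 or self.window_bp <= 0:
            raise ValueError("window_bp and step_bp must be positive")
        if not all(0 < c < 1 for c in self.conf_levels):
            raise ValueError("confidence levels must lie in (0, 1)")
        if self.null_model not in ("two_stage", "read_only"):
            raise ValueError("null_model must be 'two_stage' or 'read_only'")
        if self.depth_rule not in ("either", "both"):
            raise ValueError("depth_rule must be 'either' or 'both'")
        if self.bulk_size <= 0:
            raise ValueError("bulk_size must be positive")


def _level_col(level: float) -> str:
    return f"thr{round(level * 100):d}"


def compute_snp_index(alt_count, depth):
    """SNP index = alt_count / depth, element-wise for arrays.

    Raises :class:`ZeroDepthError` if any depth is zero: a zero-depth record
    has no defined index and must be filtered, never silently scored 0.
    """
    alt = np.asarray(alt_count)
    d = np.asarray(depth)
    if np.any(d == 0):
        raise ZeroDepthError("SNP index undefined at zero depth")
    if np.any((alt < 0) | (alt > d)):
        raise ValueError("alt_count must satisfy 0 <= alt_count <= depth")
    index = alt / d
    return float(index) if index.ndim == 0 else index


def delta_index(index_f, index_m):
    """(Δ, |Δ|): female-bulk index minus male-bulk index and its magnitude."""
    delta = np.asarray(index_f) - np.asarray(index_m)
    if delta.ndim == 0:
        return float(delta), float(abs(delta))
    return delta, np.abs(delta)


def add_snp_indices(counts: pd.DataFrame) -> pd.DataFrame:
    """Attach depth, index, Δ and |Δ| columns to an allele-count table.

    Records with zero depth in either bulk carry no defined index and are
    dropped (with a logged count) before the indices are computed.
    """
    df = counts.copy()
    df["depthF"] = df["refF"] + df["altF"]
    df["depthM"] = df["refM"] + df["altM"]
    zero = (df["depthF"] == 0) | (df["depthM"] == 0)
    if zero.any():
        logger.warning("dropping %d zero-depth records", int(zero.sum()))
        df = df.loc[~zero].reset_index(drop=True)
    df["indexF"] = compute_snp_index(df["altF"].to_numpy(), df["depthF"].to_numpy())
    df["indexM"] = compute_snp_index(df["altM"].to_numpy(), df["depthM"].to_numpy())
    # Δ from an integer cross-multiplied numerator: swapping ref/alt labels
    # negates the numerator exactly, so |Δ| is bit-identical under the
    # pseudoexchange effect (a/dF - b/dM in floats is not).
    dF = df["depthF"].to_numpy(dtype=np.int64)
    dM = df["depthM"].to_numpy(dtype=np.int64)
    num = df["altF"].to_numpy(dtype=np.int64) * dM - df["altM"].to_numpy(dtype=np.int64) * dF
    df["delta"] = num / (dF * dM)
    df["abs_delta"] = np.abs(num) / (dF * dM)
    return df.sort_values(["chrom", "pos"], ignore_index=True)


def filter_variants(records: pd.DataFrame, config: ScanConfig) -> pd.DataFrame:
    """Drop low-index and low-depth variants.

    A record is removed when its SNP index is below ``min_index`` in *both*
    bulks (uninformative or erroneous everywhere), or when the read depth is
    below ``min_depth`` — in either bulk by default (an unreliable index on
    one side corrupts Δ), or in both bulks under ``depth_rule="both"``.
    """
    low_index = (records["indexF"] < config.min_index) & (records["indexM"] < config.min_index)
    shallow_f = records["depthF"] < config.min_depth
    shallow_m = records["depthM"] < config.min_depth
    if config.depth_rule == "either":
        low_depth = shallow_f | shallow_m
    else:
        low_depth = shallow_f & shallow_m
    keep = ~(low_index | low_depth)
    return records.loc[keep].reset_index(drop=True)


@dataclass
class ThresholdTable:
    """Null |Δ| quantiles per read depth at each configured confidence level."""

    levels: tuple[float, ...]
    table: dict[int, tuple[float, ...]] = field(default_factory=dict)

    def quantile(self, depth: int, level: float) -> float:
        return self.table[int(depth)][self.levels.index(level)]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"depth": d, **{_level_col(lv): q for lv, q in zip(self.levels, qs)}}
            for d, qs in sorted(self.table.items())
        ]
        return pd.DataFrame(rows, columns=["depth"] + [_level_col(lv) for lv in self.levels])


def _nearest_rank(sorted_sample: np.ndarray, level: float) -> float:
    """Nearest-rank empirical quantile of an ascending-sorted sample."""
    n = sorted_sample.size
    idx = max(math.ceil(level * n) - 1, 0)
    return float(sorted_sample[idx])


def bootstrap_thresholds(
    depths,
    config: ScanConfig,
    rng: np.random.Generator | None = None,
) -> ThresholdTable:
    """Simulate the no-locus null of |Δ| at each read depth.

    For each depth d and each of ``n_bootstrap`` replicates, both bulks are
    resampled independently under the configured null model and |Δ| of the
    resulting indices recorded; the table stores its nearest-rank empirical
    quantiles at the configured confidence levels.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_bootstrap
    table: dict[int, tuple[float, ...]] = {}
    for d in sorted({int(d) for d in np.asarray(depths, dtype=np.int64)}):
        if d <= 0:
            raise ValueError("depths must be positive")
        indices = []
        for _bulk in range(2):
            if config.null_model == "two_stage":
                k = rng.binomial(config.bulk_size, 0.5, size=n)
                p = k / (2 * config.bulk_size)
            else:
                p = np.full(n, config.null_p)
            alt = rng.binomial(d, p)
            indices.append(alt / d)
        abs_delta = np.sort(np.abs(indices[0] - indices[1]))
        table[d] = tuple(_nearest_rank(abs_delta, lv) for lv in config.conf_levels)
    return ThresholdTable(levels=config.conf_levels, table=table)


def attach_thresholds(
    records: pd.DataFrame,
    config: ScanConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, ThresholdTable]:
    """Per-variant null thresholds, keyed by the variant's shallower depth.

    The null table is simulated with both bulks at a common depth; a variant
    with unequal bulk depths is assigned the table row of
    ``min(depthF, depthM)``, the conservative choice (the shallower bulk
    dominates the sampling noise of Δ).
    """
    df = records.copy()
    eff_depth = np.minimum(df["depthF"].to_numpy(), df["depthM"].to_numpy())
    thresholds = bootstrap_thresholds(np.unique(eff_depth), config, rng=rng)
    for i, level in enumerate(config.conf_levels):
        lookup = {d: qs[i] for d, qs in thresholds.table.items()}
        df[_level_col(level)] = [lookup[int(d)] for d in eff_depth]
    return df, thresholds


def sliding_windows(
    records: pd.DataFrame,
    chrom_lengths: dict[str, int],
    config: ScanConfig,
) -> pd.DataFrame:
    """Mean |Δ| (and mean per-variant thresholds, if present) per window.

    Windows are half-open ``[start, start + window_bp)`` in 1-based
    coordinates, starting at 1, 1+step, ... on every chromosome; the
    terminal windows are truncated at the chromosome end.  A window averages
    the variants it contains; windows with no variants carry NaN statistics
    and never contribute to region calls.
    """
    value_cols = ["abs_delta"] + [
        c for c in records.columns if c.startswith("thr") and c[3:].isdigit()
    ]
    out = []
    for chrom, length in chrom_lengths.items():
        sub = records.loc[records["chrom"] == chrom]
        pos = sub["pos"].to_numpy()
        if pos.size and np.any(np.diff(pos) < 0):
            raise ValueError("records must be sorted by (chrom, pos)")
        starts = np.arange(1, length + 1, config.step_bp, dtype=np.int64)
        ends = np.minimum(starts + config.window_bp, length + 1)
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, ends, side="left")
        n_var = hi - lo
        frame = {"chrom": chrom, "start": starts, "end": ends, "n_variants": n_var}
        with np.errstate(invalid="ignore"):
            for col in value_cols:
                csum = np.concatenate([[0.0], np.cumsum(sub[col].to_numpy())])
                mean = np.where(n_var > 0, (csum[hi] - csum[lo]) / np.maximum(n_var, 1), np.nan)
                frame["mean_abs_delta" if col == "abs_delta" else col] = mean
        out.append(pd.DataFrame(frame))
    cols = ["chrom", "start", "end", "n_variants", "mean_abs_delta"] + [
        _level_col(lv) for lv in config.conf_levels if _level_col(lv) in records.columns
    ]
    if not out:
        return pd.DataFrame(columns=cols)
    return pd.concat(out, ignore_index=True)


def call_regions(windows: pd.DataFrame, level: float) -> pd.DataFrame:
    """Merge above-threshold windows into candidate regions.

    A window is marked when its mean |Δ| strictly exceeds its own
    window-averaged null threshold at the requested confidence level.
    Overlapping or touching marked windows (half-open coordinates) merge; a
    single marked window is a valid region.  Returns a table with columns
    chrom, start, end (1-based half-open), peak_value, n_windows, level.
    """
    col = _level_col(level)
    if col not in windows.columns:
        raise KeyError(f"windows carry no thresholds at level {level}")
    defined = windows.loc[windows["n_variants"] > 0]
    marked = defined.loc[defined["mean_abs_delta"] > defined[col]]
    regions = []
    for chrom, sub in marked.groupby("chrom", sort=True):
        sub = sub.sort_values("start")
        cur = None
        for row in sub.itertuples(index=False):
            if cur is not None and row.start <= cur["end"]:
                cur["end"] = max(cur["end"], row.end)
                cur["peak_value"] = max(cur["peak_value"], row.mean_abs_delta)
                cur["n_windows"] += 1
            else:
                if cur is not None:
                    regions.append(cur)
                cur = {
                    "chrom": chrom,
                    "start": int(row.start),
                    "end": int(row.end),
                    "peak_value": float(row.mean_abs_delta),
                    "n_windows": 1,
                }
        if cur is not None:
            regions.append(cur)
    out = pd.DataFrame(regions, columns=["chrom", "start", "end", "peak_value", "n_windows"])
    out["level"] = level
    return out


@dataclass
class ScanResult:
    """Everything the scan produces, ready for writing or plotting."""

    records: pd.DataFrame
    windows: pd.DataFrame
    thresholds: ThresholdTable
    regions: dict[float, pd.DataFrame]


def scan(
    counts: pd.DataFrame,
    chrom_lengths: dict[str, int],
    config: ScanConfig | None = None,
) -> ScanResult:
    """Run the full scan on an allele-count table.

    Pipeline: compute indices -> filter variants -> bootstrap depth-specific
    null thresholds -> average statistic and thresholds over sliding windows
    -> call candidate regions at every configured confidence level.
    """
    config = config or ScanConfig()
    records = filter_variants(add_snp_indices(counts), config)
    if records.empty:
        empty_windows = sliding_windows(records.assign(), chrom_lengths, config)
        return ScanResult(records, empty_windows, ThresholdTable(config.conf_levels), {})
    records, thresholds = attach_thresholds(records, config)
    windows = sliding_windows(records, chrom_lengths, config)
    regions = {level: call_regions(windows, level) for level in config.conf_levels}
    return ScanResult(records, windows, thresholds, regions)
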