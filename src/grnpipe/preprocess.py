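"""Probe collapsing, per-array total normalization, and sample QC.

The same methodology is applied to training and query matrices: probeset
rows mapping to the same gene are averaged, each array (column) is divided
by its total and rescaled to a fixed constant, and outlying arrays are
excluded by robust deviation of total intensity or inter-array correlation.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

DEFAULT_SCALE = 1e5


def collapse_probes(probes: pd.DataFrame, probe_map: pd.Series | dict) -> pd.DataFrame:
    """Average probe rows mapping to the same gene.

    ``probe_map`` maps probe id -> gene symbol (many probes to one gene).
    Probes absent from the map are dropped with a warning. Raises if no
    probe in the matrix is mapped.
    """
    if isinstance(probe_map, dict):
        probe_map = pd.Series(probe_map)
    if probe_map.index.has_duplicates:
        raise ValueError("probe map assigns some probe to more than one gene")
    mapped = probes.index.intersection(probe_map.index)
    if len(mapped) == 0:
        raise ValueError("no probe in the matrix is present in the probe map")
    dropped = probes.index.difference(probe_map.index)
    if len(dropped) > 0:
        logger.warning(
            "dropping %d unmapped probes (e.g. %s)", len(dropped), list(dropped[:3])
        )
    sub = probes.loc[mapped]
    genes = probe_map.loc[mapped]
    out = sub.groupby(genes.values).mean()
    out.index.name = probes.index.name or "gene"
    return out.sort_index()


def normalize_total(expr: pd.DataFrame, scale: float = DEFAULT_SCALE) -> pd.DataFrame:
    """Divide each column by its total and rescale to ``scale``.

    Every output column sums to ``scale`` (within floating tolerance).
    Raises on a zero-total column, naming the sample.
    """
    if scale <= 0:
        raise ValueError(f"scale must be > 0, got {scale}")
    totals = expr.sum(axis=0)
    bad = totals.index[totals <= 0]
    if len(bad) > 0:
        raise ValueError(f"zero-total column(s): {list(bad)}")
    return expr * (scale / totals)


def qc_filter(
    expr: pd.DataFrame, k_mad: float = 5.0
) -> tuple[list[str], list[str], pd.DataFrame]:
    """Flag outlying samples by robust deviation on two per-array metrics.

    A sample is excluded when its log total intensity, or its median
    Spearman correlation with the other samples, deviates from the cohort
    median by more than ``k_mad`` (scaled) median absolute deviations.
    Returns (kept sample ids, excluded sample ids, per-sample report).
    """
    if expr.shape[1] < 3:
        raise ValueError("qc_filter requires at least 3 samples")
    log_total = np.log(expr.sum(axis=0).to_numpy())

    ranks = np.apply_along_axis(rankdata, 0, expr.to_numpy())
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(ranks, rowvar=False)
    np.fill_diagonal(corr, np.nan)
    med_corr = np.nanmedian(corr, axis=0)
    med_corr = np.nan_to_num(med_corr, nan=0.0)

    def robust_z(values: np.ndarray) -> np.ndarray:
        med = np.median(values)
        mad = np.median(np.abs(values - med))
        scale = max(1.4826 * mad, 1e-12 * max(1.0, abs(med)))
        return (values - med) / scale

    z_total = robust_z(log_total)
    z_corr = robust_z(med_corr)
    excluded_mask = (np.abs(z_total) > k_mad) | (np.abs(z_corr) > k_mad)

    report = pd.DataFrame(
        {
            "sample_id": expr.columns,
            "log_total": log_total,
            "z_log_total": z_total,
            "median_spearman": med_corr,
            "z_median_spearman": z_corr,
            "excluded": excluded_mask,
        }
    )
    kept = list(expr.columns[~excluded_mask])
    excluded = list(expr.columns[excluded_mask])
    if excluded:
        logger.warning("QC excluded %d sample(s): %s", len(excluded), excluded)
    return kept, excluded, report
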