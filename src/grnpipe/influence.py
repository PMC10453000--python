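"""Network influence scores: rank TFs by how far their subnetwork sits from
a class's training distribution in a query group.

NIS(t) = w_t * zbar_t + sum over targets g of w_g * zbar_g * s(t, g), where
zbar is the mean clipped z-score of the query group against the class
training distribution, w are classifier importance weights, and s(t, g) is
the sign of the training correlation on the edge. The most negative NIS
marks the TF whose subnetwork is most under-established; the table is
sorted ascending, ties broken by TF name.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from grnpipe.grn import ClassGRN
from grnpipe.status import TrainingStats

logger = logging.getLogger(__name__)


def _clipped_z(expr: pd.DataFrame, cls: str, stats: TrainingStats) -> pd.DataFrame:
    cs = stats.per_class[cls]
    vals = expr.reindex(cs.mu.index).to_numpy(dtype=float)
    z = (vals - cs.mu.to_numpy()[:, None]) / cs.sigma.to_numpy()[:, None]
    z = np.clip(z, -stats.z_cap, stats.z_cap)
    z = np.nan_to_num(z, nan=-stats.z_cap)  # missing gene: maximally low
    return pd.DataFrame(z, index=cs.mu.index, columns=expr.columns)


def network_influence(
    query_expr: pd.DataFrame,
    cls: str,
    class_grn: ClassGRN,
    stats: TrainingStats,
    per_sample: bool = False,
) -> pd.DataFrame:
    """Rank the class GRN's TFs by signed, importance-weighted dysregulation.

    With ``per_sample=False`` (the default) z-scores are averaged over the
    query group before scoring; with ``per_sample=True`` one NIS column per
    query sample is returned alongside the group ranking.
    Returns a table (tf, nis, rank) sorted by ascending NIS; an empty table
    (with a warning) when the GRN has no TFs.
    """
    if cls not in stats.per_class:
        raise KeyError(f"no training stats for class {cls!r}")
    tfs = class_grn.tfs
    if not tfs:
        logger.warning("class %s GRN has no TFs; empty NIS table", cls)
        return pd.DataFrame(columns=["tf", "nis", "rank"])
    cs = stats.per_class[cls]
    z = _clipped_z(query_expr, cls, stats)
    zbar = z.mean(axis=1)
    w = cs.weights

    def score(zvec: pd.Series) -> pd.Series:
        out = {}
        for tf in tfs:
            val = float(w.get(tf, 0.0) * zvec.get(tf, 0.0))
            sub = class_grn.edges[class_grn.edges["tf"] == tf]
            for row in sub.itertuples(index=False):
                sign = 1.0 if row.rho >= 0 else -1.0
                val += float(w.get(row.target, 0.0) * zvec.get(row.target, 0.0) * sign)
            out[tf] = val
        return pd.Series(out)

    nis = score(zbar)
    table = pd.DataFrame({"tf": nis.index, "nis": nis.values})
    table = table.sort_values(["nis", "tf"], kind="stable").reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    if per_sample:
        per = pd.DataFrame({c: score(z[c]) for c in z.columns})
        per.index.name = "tf"
        table = table.merge(per.reset_index(), on="tf", how="left")
    return table
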