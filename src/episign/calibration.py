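"""Control-subsampling null calibration of the significant-CpG count.

The background rate of DMP calls is estimated by repeatedly drawing k
controls (k = 1..15 by default) without replacement, treating them as a
pseudo-case group against the remaining controls, and running the same
site-level scan and significance rules as a real contrast.  Because a
single pseudo-case cannot support a Welch test, the linear-model path is
used whenever k < 2.  The distribution of counts across draws gives the
scale of chance findings a real case group must exceed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sitetest import SignificanceParams, call_significant_sites, differential_scan

logger = logging.getLogger(__name__)


@dataclass
class NullCalibration:
    counts: pd.DataFrame  # columns k, rep, n_significant
    k_range: tuple
    reps: int
    seed: int

    @property
    def mean(self) -> float:
        return float(self.counts["n_significant"].mean())

    @property
    def min(self) -> int:
        return int(self.counts["n_significant"].min())

    @property
    def max(self) -> int:
        return int(self.counts["n_significant"].max())

    def summary(self) -> dict:
        return {
            "mean": self.mean,
            "min": self.min,
            "max": self.max,
            "n_draws": int(len(self.counts)),
        }


def subsample_null(
    control_beta: pd.DataFrame,
    k_range: range | tuple = range(1, 16),
    reps: int = 20,
    seed: int = 0,
    params: SignificanceParams | None = None,
) -> NullCalibration:
    """Run the control-subsampling calibration.

    ``control_beta`` is sites x control-sample ids.  For each k in
    ``k_range`` and each of ``reps`` independent draws, k controls are
    sampled without replacement as pseudo-cases; the count of called
    DMPs against the remaining controls is recorded.  k values that
    leave fewer than 2 reference controls are skipped with a warning.
    """
    params = params or SignificanceParams()
    ids = list(control_beta.columns)
    n = len(ids)
    ks = [int(k) for k in k_range]
    if n < max(ks) + 2:
        logger.warning("control pool of %d is small for k up to %d", n, max(ks))
    rng = np.random.default_rng(seed)
    rows = []
    for k in ks:
        if k >= n - 1:
            logger.warning("k=%d leaves too few reference controls; skipped", k)
            continue
        for rep in range(reps):
            pick = rng.choice(n, size=k, replace=False)
            case_ids = [ids[i] for i in pick]
            ctrl_ids = [i for i in ids if i not in case_ids]
            p = params if k >= 2 else SignificanceParams(
                params.q_threshold, params.min_abs_delta, "linear_model"
            )
            res = differential_scan(control_beta, case_ids, ctrl_ids, params=p)
            n_sig = len(call_significant_sites(res, p))
            rows.append((k, rep, n_sig))
    counts = pd.DataFrame(rows, columns=["k", "rep", "n_significant"])
    return NullCalibration(counts, tuple(ks), reps, seed)
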