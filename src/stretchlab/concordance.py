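"""Tissue-cell strain concordance classification.

Each cell-step carries a cellular step strain eps_C and a tissue step
strain eps_T sampled under the same footprint.  Two statistics summarize
the pair:

* d = eps_C - eps_T, the concordance deviation;
* s, a movement-magnitude statistic, by default |eps_C + eps_T|
  (``variant='abs_sum'``); the alternative |eps_C| + |eps_T| is available
  as ``variant='sum_abs'``.

Classification against 1-SD thresholds (estimated from the data or
supplied by the user):

* grey — insignificant movement: s <= sigma_sum (takes precedence);
* yellow — concordant: |d| <= sigma_diff;
* magenta — discordant, cell strained more: d > sigma_diff;
* cyan — discordant, tissue strained more: d < -sigma_diff.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CATEGORIES = ("grey", "yellow", "magenta", "cyan")


@dataclass
class ConcordanceThresholds:
    sigma_diff: float
    sigma_sum: float
    source: str = "from_data"   # or "user"
    variant: str = "abs_sum"

    def __post_init__(self) -> None:
        if self.sigma_diff < 0 or self.sigma_sum < 0:
            raise ValueError("thresholds must be >= 0")


@dataclass
class ConcordanceResult:
    records: pd.DataFrame            # adds columns d, s, category
    fractions: dict[str, float]
    thresholds: ConcordanceThresholds
    n_skipped: int = 0

    def summary(self) -> dict:
        return {
            "n_records": int(len(self.records)),
            "n_skipped": int(self.n_skipped),
            "fractions": self.fractions,
            "sigma_diff": self.thresholds.sigma_diff,
            "sigma_sum": self.thresholds.sigma_sum,
            "threshold_source": self.thresholds.source,
            "s_variant": self.thresholds.variant,
        }


def s_statistic(eps_cell, eps_tissue, variant: str = "abs_sum"):
    """Movement-magnitude statistic of a cell-step."""
    c = np.asarray(eps_cell, dtype=float)
    t = np.asarray(eps_tissue, dtype=float)
    if variant == "abs_sum":
        out = np.abs(c + t)
    elif variant == "sum_abs":
        out = np.abs(c) + np.abs(t)
    else:
        raise ValueError("variant must be 'abs_sum' or 'sum_abs'")
    return float(out) if out.ndim == 0 else out


def concordance_thresholds(
    records: pd.DataFrame, variant: str = "abs_sum"
) -> ConcordanceThresholds:
    """1-SD thresholds estimated from the cell-step records.

    ``sigma_diff`` is the sample SD of d = eps_cell - eps_tissue and
    ``sigma_sum`` the sample SD of s, both over records with finite strains.
    """
    c = records["eps_xx_cell"].to_numpy(dtype=float)
    t = records["eps_xx_tissue"].to_numpy(dtype=float)
    ok = np.isfinite(c) & np.isfinite(t)
    if ok.sum() < 2:
        raise ValueError("need at least 2 complete records to estimate thresholds")
    d = c[ok] - t[ok]
    s = s_statistic(c[ok], t[ok], variant)
    sigma_diff = float(np.std(d, ddof=1))
    sigma_sum = float(np.std(s, ddof=1))
    if sigma_diff == 0 or sigma_sum == 0:
        logger.warning("degenerate concordance thresholds (zero SD); "
                       "all records are identical along that statistic")
    return ConcordanceThresholds(sigma_diff, sigma_sum, source="from_data",
                                 variant=variant)


def classify(
    records: pd.DataFrame,
    thresholds: ConcordanceThresholds | None = None,
    variant: str | None = None,
) -> ConcordanceResult:
    """Classify each cell-step as grey / yellow / magenta / cyan.

    When ``thresholds`` is omitted they are estimated from the data.
    Records with a missing strain are skipped and tallied separately;
    fractions are over classified records and sum to 1.
    """
    if thresholds is None:
        thresholds = concordance_thresholds(records, variant or "abs_sum")
    if variant is not None and variant != thresholds.variant:
        raise ValueError("s-variant of thresholds and classification differ")
    if not (np.isfinite(thresholds.sigma_diff) and np.isfinite(thresholds.sigma_sum)):
        raise ValueError("thresholds must be finite")

    c = records["eps_xx_cell"].to_numpy(dtype=float)
    t = records["eps_xx_tissue"].to_numpy(dtype=float)
    ok = np.isfinite(c) & np.isfinite(t)
    d = c - t
    s = s_statistic(c, t, thresholds.variant)

    cat = np.full(len(records), "", dtype=object)
    grey = s <= thresholds.sigma_sum
    yellow = ~grey & (np.abs(d) <= thresholds.sigma_diff)
    magenta = ~grey & ~yellow & (d > thresholds.sigma_diff)
    cyan = ~grey & ~yellow & ~magenta
    for name, m in zip(CATEGORIES, (grey, yellow, magenta, cyan)):
        cat[m & ok] = name
    cat[~ok] = None

    out = records.copy()
    out["d"] = np.where(ok, d, np.nan)
    out["s"] = np.where(ok, s, np.nan)
    out["category"] = cat
    n_cls = int(ok.sum())
    fractions = {
        name: (float(np.sum(cat[ok] == name)) / n_cls if n_cls else float("nan"))
        for name in CATEGORIES
    }
    return ConcordanceResult(out, fractions, thresholds, n_skipped=int((~ok).sum()))


def plot_concordance(result: ConcordanceResult, ax=None):
    """Scatter of d versus s with shaded category regions (optional QC plot)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    th = result.thresholds
    df = result.records.dropna(subset=["d", "s"])
    colors = {"grey": "0.6", "yellow": "#c8a400", "magenta": "m", "cyan": "c"}
    smax = max(df["s"].max() if len(df) else 1.0, th.sigma_sum * 2) * 1.1
    ax.axhspan(0, th.sigma_sum, color="0.85", zorder=0)
    ax.axvspan(-th.sigma_diff, th.sigma_diff, ymin=0, color="#fff3b0", zorder=0)
    for name, grp in df.groupby("category"):
        ax.scatter(grp["d"], grp["s"], s=12, c=colors.get(name, "k"), label=name)
    ax.set_xlabel("d = eps_cell - eps_tissue")
    ax.set_ylabel(f"s ({th.variant})")
    ax.set_ylim(0, smax)
    ax.legend(fontsize="small")
    return ax
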