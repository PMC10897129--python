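"""Structure-activity analytics over screening readouts.

Reproduces the analysis stages of a two-channel lipidoid screen:

* (m, n) heat maps of median log10 readout per tail combination;
* marginal body-tail and branch-tail activity profiles;
* a binned total-carbon x symmetry-deviation contour table, whose argmax
  bin localizes the potency ridge;
* a two-tailed Pearson correlation test between log10 in vitro and log10
  in vivo readouts (p from the t distribution with n-2 df);
* the threshold-necessity analysis: the fraction of in vivo hits above an
  in vitro RLU floor, plus the converse (sufficiency) fraction that shows
  the threshold is necessary but not sufficient.

Medians (not means) summarize cells throughout: the readouts are
log-normal and medians are robust to their heavy tails.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

DEFAULT_D_BINS = (0.0, 0.25, 0.5, 1.0, 2.0, np.inf)

CHANNELS = {"invitro": "invitro_rlu", "invivo": "invivo_flux"}


def _merged(records: pd.DataFrame, descriptors: pd.DataFrame) -> pd.DataFrame:
    cols = [c for c in ("name", "m", "n", "total_carbons", "deviation") if c in descriptors.columns]
    return records.merge(descriptors[cols], on="name", how="inner")


def build_heatmap(
    records: pd.DataFrame, descriptors: pd.DataFrame, channel: str = "invivo"
) -> pd.DataFrame:
    """Median log10 readout per (m, n) cell; missing combinations are NaN.

    Rows are body-tail carbons m, columns branch-tail carbons n.
    """
    if channel not in CHANNELS:
        raise ValidationError(
            f"unknown channel {channel!r}; expected one of {sorted(CHANNELS)}"
        )
    df = _merged(records, descriptors)
    if df.empty:
        raise ValidationError("no records map to (m, n) descriptors")
    df["log10_value"] = np.log10(df[CHANNELS[channel]])
    return df.pivot_table(
        index="m", columns="n", values="log10_value", aggfunc="median"
    )


def marginal_profiles(
    records: pd.DataFrame, descriptors: pd.DataFrame, channel: str = "invivo"
) -> dict[str, pd.Series]:
    """Per-m and per-n median log10 activity profiles."""
    heat = build_heatmap(records, descriptors, channel)
    return {"by_m": heat.median(axis=1), "by_n": heat.median(axis=0)}


def contour_stats(
    records: pd.DataFrame,
    descriptors: pd.DataFrame,
    tc_bins=None,
    d_bins=DEFAULT_D_BINS,
) -> pd.DataFrame:
    """Binned medians over (total carbons, symmetry deviation).

    Returns one row per non-empty bin with the record count and median
    log10 flux; the attribute ``df.attrs["argmax"]`` holds the bin with the
    highest median. Integer TC values get unit-width bins by default.
    """
    df = _merged(records, descriptors)
    if df.empty:
        raise ValidationError("no records map to descriptors")
    if tc_bins is None:
        lo, hi = int(df["total_carbons"].min()), int(df["total_carbons"].max())
        tc_bins = np.arange(lo - 0.5, hi + 1.5, 1.0)
    df["log10_flux"] = np.log10(df["invivo_flux"])
    df["tc_bin"] = pd.cut(df["total_carbons"], bins=tc_bins)
    df["d_bin"] = pd.cut(df["deviation"], bins=list(d_bins), right=False)
    table = (
        df.groupby(["tc_bin", "d_bin"], observed=True)
        .agg(count=("log10_flux", "size"), median_log10_flux=("log10_flux", "median"))
        .reset_index()
    )
    table = table[table["count"] > 0].reset_index(drop=True)
    best = table.loc[table["median_log10_flux"].idxmax()]
    table.attrs["argmax"] = {
        "tc_bin": str(best["tc_bin"]),
        "tc_mid": float(best["tc_bin"].mid),
        "d_bin": str(best["d_bin"]),
        "d_left": float(best["d_bin"].left),
        "d_right": float(best["d_bin"].right),
        "median_log10_flux": float(best["median_log10_flux"]),
    }
    return table


def correlation_test(records: pd.DataFrame) -> dict:
    """Two-tailed Pearson correlation between the log10 channels."""
    n = len(records)
    if n < 3:
        raise ValidationError("need at least 3 paired readouts")
    x = np.log10(records["invitro_rlu"].to_numpy(dtype=float))
    y = np.log10(records["invivo_flux"].to_numpy(dtype=float))
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ValidationError("zero variance in a channel")
    res = stats.pearsonr(x, y)
    return {"r": float(res.statistic), "p": float(res.pvalue), "n": n}


def threshold_necessity(records: pd.DataFrame, threshold: float = 1e4) -> dict:
    """How necessary/sufficient an in vitro floor is for in vivo hits.

    ``fraction_hits_above`` is P(in vitro >= threshold | hit) — the
    necessity direction; ``fraction_above_that_hit`` is the converse
    sufficiency fraction. Contingency counts are included for inspection.
    Fractions are None when their denominator is empty.
    """
    hits = records["is_hit"].to_numpy(dtype=bool)
    above = records["invitro_rlu"].to_numpy(dtype=float) >= threshold
    counts = {
        "hit_above": int(np.sum(hits & above)),
        "hit_below": int(np.sum(hits & ~above)),
        "nonhit_above": int(np.sum(~hits & above)),
        "nonhit_below": int(np.sum(~hits & ~above)),
    }
    n_hits = counts["hit_above"] + counts["hit_below"]
    n_above = counts["hit_above"] + counts["nonhit_above"]
    return {
        "threshold": threshold,
        "fraction_hits_above": (counts["hit_above"] / n_hits) if n_hits else None,
        "fraction_above_that_hit": (counts["hit_above"] / n_above) if n_above else None,
        "counts": counts,
    }


@dataclass
class SARReport:
    """Bundle of every analysis stage over one screen."""

    heatmap: pd.DataFrame
    marginals: dict[str, pd.Series]
    contour_table: pd.DataFrame
    correlation: dict
    necessity: dict

    def to_dict(self) -> dict:
        return {
            "heatmap": {
                str(m): {str(n): _none_if_nan(v) for n, v in row.items()}
                for m, row in self.heatmap.iterrows()
            },
            "marginals": {
                key: {str(k): _none_if_nan(v) for k, v in series.items()}
                for key, series in self.marginals.items()
            },
            "contour": [
                {
                    "tc_bin": str(row["tc_bin"]),
                    "d_bin": str(row["d_bin"]),
                    "count": int(row["count"]),
                    "median_log10_flux": float(row["median_log10_flux"]),
                }
                for _, row in self.contour_table.iterrows()
            ],
            "contour_argmax": self.contour_table.attrs.get("argmax"),
            "correlation": self.correlation,
            "necessity": self.necessity,
        }

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2))
        return path


def _none_if_nan(v):
    v = float(v)
    return None if math.isnan(v) else v


def analyze(
    records: pd.DataFrame,
    descriptors: pd.DataFrame,
    threshold: float = 1e4,
    d_bins=DEFAULT_D_BINS,
) -> SARReport:
    """Run every SAR stage over one set of screen records."""
    return SARReport(
        heatmap=build_heatmap(records, descriptors, "invivo"),
        marginals=marginal_profiles(records, descriptors, "invivo"),
        contour_table=contour_stats(records, descriptors, d_bins=d_bins),
        correlation=correlation_test(records),
        necessity=threshold_necessity(records, threshold),
    )


def plot_heatmap(heatmap: pd.DataFrame, path: str | Path, channel: str = "invivo") -> Path:
    """Save the (m, n) heat map as a figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(heatmap.to_numpy(), origin="lower", cmap="viridis")
    ax.set_xticks(range(len(heatmap.columns)), heatmap.columns)
    ax.set_yticks(range(len(heatmap.index)), heatmap.index)
    ax.set_xlabel("branch tail carbons n")
    ax.set_ylabel("body tail carbons m")
    fig.colorbar(im, ax=ax, label=f"median log10 {channel}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
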