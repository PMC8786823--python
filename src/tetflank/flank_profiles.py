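"""Flank-preference statistics from single-molecule oxidation records.

The central objects are

* the obs/exp table: for every flank position and base, the frequency of
  that base among oxidized product molecules divided by its frequency in
  the whole retained library — >1 means the base enhances activity at that
  position, <1 means it reduces it;
* the per-position variance score sum_b (obs/exp - 1)^2, scaled to the
  largest position, which localizes where flanking effects act;
* context profiles: mean oxidation per NNCXNN context (256 contexts for
  two randomized positions per side), the substrate of ranking, extreme
  subsets (sequence-logo matrices), profile correlations and the
  competitive CpX specificity summary.

Records are pandas DataFrames with columns ``context`` (concatenated
flanks, upper strand), ``x_base``, ``site_class`` and ``call``; ambiguous
molecules are excluded from every statistic.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from tetflank.deep_readout import CALL_AMBIGUOUS, CALL_OXIDIZED

BASES = ("A", "C", "G", "T")


def position_labels(flank_len: int) -> list[int]:
    """Flank positions -flank_len..-1, +1..+flank_len (no 0 / +0')."""
    return list(range(-flank_len, 0)) + list(range(1, flank_len + 1))


def _clean(records: pd.DataFrame) -> pd.DataFrame:
    return records[records["call"] != CALL_AMBIGUOUS]


# ---------------------------------------------------------------------------
# obs/exp enrichment
# ---------------------------------------------------------------------------


@dataclass
class ObsExpTable:
    """Observed/expected base enrichment in the oxidized product pool."""

    ratio: pd.DataFrame  # index: flank position, columns: A/C/G/T
    observed_freq: pd.DataFrame
    expected_freq: pd.DataFrame
    n_product: int
    n_reference: int

    def to_tsv(self, path: str | Path) -> None:
        self.ratio.rename_axis("position").to_csv(path, sep="\t")


def _base_freqs(contexts: pd.Series, positions: Sequence[int]) -> pd.DataFrame:
    mat = np.frombuffer("".join(contexts).encode(), dtype=np.uint8).reshape(len(contexts), -1)
    freq = pd.DataFrame(
        {b: (mat == ord(b)).mean(axis=0) for b in BASES}, index=list(positions)
    )
    return freq


def obs_exp(
    records: pd.DataFrame,
    product_call: str = CALL_OXIDIZED,
    expected: str = "empirical",
) -> ObsExpTable:
    """Per-position, per-base enrichment of the product pool.

    ``expected='empirical'`` (default) uses the base frequencies of all
    retained molecules of the same sample, which corrects library
    composition bias and reduces to 0.25 for unbiased libraries;
    ``'uniform'`` fixes the expectation at 0.25.
    """
    retained = _clean(records)
    product = retained[retained["call"] == product_call]
    if len(product) == 0:
        raise ValueError("empty product pool: no molecules with the product call")
    flank_len = len(retained["context"].iloc[0]) // 2
    positions = position_labels(flank_len)

    observed = _base_freqs(product["context"], positions)
    if expected == "empirical":
        expected_freq = _base_freqs(retained["context"], positions)
    elif expected == "uniform":
        expected_freq = pd.DataFrame(0.25, index=list(positions), columns=list(BASES))
    else:
        raise ValueError("expected must be 'empirical' or 'uniform'")

    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = observed / expected_freq
    ratio = ratio.where(expected_freq > 0)
    return ObsExpTable(
        ratio=ratio,
        observed_freq=observed,
        expected_freq=expected_freq,
        n_product=len(product),
        n_reference=len(retained),
    )


def position_variance(table: ObsExpTable) -> pd.DataFrame:
    """Per-position flanking-effect score sum_b (obs/exp - 1)^2.

    The ``scaled`` column divides by the maximum over positions so the
    most influential position scores 1.0; for a completely flat table the
    scaling is skipped and the ``flat`` attribute is set.
    """
    raw = ((table.ratio - 1.0) ** 2).sum(axis=1, skipna=True)
    out = pd.DataFrame({"raw": raw})
    top = raw.max()
    if top > 0:
        out["scaled"] = raw / top
        out.attrs["flat"] = False
    else:
        out["scaled"] = raw
        out.attrs["flat"] = True
    return out


# ---------------------------------------------------------------------------
# context profiles
# ---------------------------------------------------------------------------


def all_contexts(x_base: str, k_per_side: int = 2) -> list[str]:
    """All NN..CX..NN labels in lexicographic order of the N positions."""
    return [
        "".join(left) + "C" + x_base + "".join(right)
        for left in itertools.product(BASES, repeat=k_per_side)
        for right in itertools.product(BASES, repeat=k_per_side)
    ]


def _context_label(row_context: str, x_base: str, k: int) -> str:
    flank_len = len(row_context) // 2
    return row_context[flank_len - k : flank_len] + "C" + x_base + row_context[flank_len : flank_len + k]


def context_average(
    records: pd.DataFrame,
    k_per_side: int = 2,
    low_coverage_floor: int = 20,
) -> pd.DataFrame:
    """Mean oxidation per NNCXNN context for records of one site class.

    Returns a DataFrame indexed by the full context label (lexicographic,
    all 4^(2k) entries present) with columns ``value`` (mean oxidized
    indicator; NaN where the context was never observed), ``n`` and
    ``low_coverage``.
    """
    classes = records["site_class"].unique()
    if len(classes) != 1:
        raise ValueError(f"records span several site classes: {sorted(classes)}")
    retained = _clean(records)
    x = classes[0][-1]

    labels = [
        _context_label(c, x, k_per_side) for c in retained["context"]
    ]
    oxidized = (retained["call"] == CALL_OXIDIZED).to_numpy()
    grouped = pd.DataFrame({"context": labels, "ox": oxidized}).groupby("context")["ox"]
    profile = pd.DataFrame(index=pd.Index(all_contexts(x, k_per_side), name="context"))
    agg = grouped.agg(["mean", "size"])
    profile["value"] = agg["mean"]
    profile["n"] = agg["size"].reindex(profile.index).fillna(0).astype(int)
    profile["low_coverage"] = profile["n"] < low_coverage_floor
    return profile


def rank_context(profile: pd.DataFrame, context: str) -> int:
    """Rank of ``context`` by descending value (1 = most preferred).

    Ties share the minimal rank; contexts with null values rank last.
    """
    values = profile["value"]
    if context not in values.index:
        raise KeyError(context)
    v = values.loc[context]
    if pd.isna(v):
        return int(values.notna().sum()) + 1
    return int((values > v).sum()) + 1


def extreme_subsets(
    profile: pd.DataFrame, n_top: int = 10, n_bottom: int = 10
) -> tuple[list[str], list[str], pd.DataFrame, pd.DataFrame]:
    """Most preferred / most disfavored context subsets plus logo matrices.

    The matrices give per-position base probabilities within each subset
    (rows are the randomized context positions, e.g. -2, -1, +1, +2 for
    NNCGNN; each row sums to 1) — the direct input for a sequence logo.
    """
    values = profile["value"].dropna()
    if n_top + n_bottom > len(profile):
        raise ValueError("n_top + n_bottom exceeds the number of contexts")
    order = values.sort_values(ascending=False, kind="mergesort")
    top = list(order.index[:n_top])
    bottom = list(order.index[-n_bottom:])
    return top, bottom, logo_matrix(top), logo_matrix(bottom)


def logo_matrix(contexts: Sequence[str]) -> pd.DataFrame:
    """Per-position base probabilities of a context set (rows sum to 1)."""
    if not contexts:
        raise ValueError("empty context set")
    length = len(contexts[0])
    k = (length - 2) // 2
    rows = list(range(-k, 0)) + list(range(1, k + 1))
    mat = np.frombuffer("".join(contexts).encode(), dtype=np.uint8).reshape(len(contexts), length)
    keep = list(range(k)) + list(range(k + 2, length))  # drop the central CX
    mat = mat[:, keep]
    return pd.DataFrame(
        {b: (mat == ord(b)).mean(axis=0) for b in BASES}, index=rows
    ).rename_axis("position")


def profile_correlation(profiles: Mapping[str, pd.DataFrame | pd.Series]) -> pd.DataFrame:
    """Pairwise Pearson correlation matrix of context profiles.

    Null-valued contexts are excluded pairwise; the result is symmetric
    with a unit diagonal.
    """
    columns = {
        name: (p["value"] if isinstance(p, pd.DataFrame) else p)
        for name, p in profiles.items()
    }
    return pd.DataFrame(columns).corr(method="pearson")


# ---------------------------------------------------------------------------
# CpX specificity
# ---------------------------------------------------------------------------


@dataclass
class CpxSummary:
    relative_activity: pd.Series  # percent of the best class
    profiles: dict[str, pd.DataFrame] = field(default_factory=dict)
    histogram: pd.DataFrame | None = None  # contexts per relative-activity bin
    excluded_classes: list[str] = field(default_factory=list)


def cpx_summary(
    records: pd.DataFrame,
    k_per_side: int = 2,
    low_coverage_floor: int = 20,
    molecule_floor: int = 200,
    activity_floor: float = 0.03,
    bin_width: float = 20.0,
) -> CpxSummary:
    """Specificity summary for a competitive CpN reaction.

    All site classes come from one reaction, so their mean oxidation
    levels share a scale; they are reported relative to the best class
    (= 100%).  Classes below ``molecule_floor`` molecules are excluded
    from the histogram, and classes whose mean oxidation falls below
    ``activity_floor`` (the fate of mCpT in practice) are excluded from
    the per-class profile analysis.
    """
    retained = _clean(records)
    means = (
        retained.assign(ox=(retained["call"] == CALL_OXIDIZED))
        .groupby("site_class")["ox"]
        .agg(["mean", "size"])
    )
    relative = 100.0 * means["mean"] / means["mean"].max()
    relative = relative.sort_values(ascending=False)

    summary = CpxSummary(relative_activity=relative)
    histogram_rows = {}
    # bin edges in percent of the best context across all classes
    for site_class, row in means.iterrows():
        if row["size"] < molecule_floor:
            summary.excluded_classes.append(site_class)
            continue
        if row["mean"] < activity_floor:
            summary.excluded_classes.append(site_class)
            continue
        summary.profiles[site_class] = context_average(
            retained[retained["site_class"] == site_class],
            k_per_side=k_per_side,
            low_coverage_floor=low_coverage_floor,
        )

    if summary.profiles:
        best = max(
            p["value"].max() for p in summary.profiles.values()
        )
        edges = np.arange(0.0, 100.0 + bin_width, bin_width)
        for site_class, prof in summary.profiles.items():
            rel = 100.0 * prof["value"].dropna() / best
            counts, _ = np.histogram(rel.clip(upper=100.0 - 1e-12), bins=edges)
            histogram_rows[site_class] = counts
        labels = [f"{int(lo)}-{int(hi)}" for lo, hi in zip(edges[:-1], edges[1:])]
        summary.histogram = pd.DataFrame(histogram_rows, index=labels).rename_axis("relative_activity_pct")
    return summary


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def write_profile(profile: pd.DataFrame, path: str | Path) -> None:
    profile.to_csv(path, sep="\t")


def read_profile(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="context")
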