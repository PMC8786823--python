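"""Genomic 5mC/5hmC pattern analysis against TET flanking preferences.

Loads per-CpG modification tracks (bedGraph-style TSV), extracts NNCGNN
contexts from a reference FASTA, derives the hydroxymethylome from paired
BS/oxBS levels, aggregates levels per context, predicts genomic 5hmC
patterns as a mixture of 5mC levels and TET enzyme preferences, scans the
genome with 18-CpG sliding-window correlations, and measures base
enrichment at sites gaining methylation after TET knock-out.

Coordinates are 0-based half-open (bedGraph convention); only + strand
CpGs are considered.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from pyfaidx import Fasta

from tetflank.flank_profiles import BASES, all_contexts, extreme_subsets


# ---------------------------------------------------------------------------
# loading and context extraction
# ---------------------------------------------------------------------------


def load_and_filter(
    path: str | Path,
    min_coverage: int = 10,
    columns: Sequence[str] = ("chrom", "start", "end", "level", "coverage"),
) -> tuple[pd.DataFrame, dict]:
    """Read a bedGraph-style TSV of + strand CpG sites and apply the
    coverage filter.

    Malformed rows (wrong field count, non-numeric values, levels outside
    [0, 1], negative coverage) are rejected and reported with their line
    numbers.  Returns (sites, report); sites columns are chrom, pos,
    level, coverage.
    """
    rows = []
    rejected: list[int] = []
    n_input = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("track", "#")):
                continue
            n_input += 1
            fields = line.split("\t")
            if len(fields) != len(columns):
                rejected.append(lineno)
                continue
            rec = dict(zip(columns, fields))
            try:
                pos = int(rec["start"])
                end = int(rec.get("end", pos + 1))
                level = float(rec["level"])
                coverage = int(rec["coverage"])
            except (KeyError, ValueError):
                rejected.append(lineno)
                continue
            if not (0.0 <= level <= 1.0) or coverage < 0 or end <= pos:
                rejected.append(lineno)
                continue
            rows.append((rec["chrom"], pos, level, coverage))
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "level", "coverage"])
    retained = sites[sites["coverage"] >= min_coverage].reset_index(drop=True)
    report = {
        "input_records": n_input,
        "malformed": rejected,
        "below_coverage": int(len(sites) - len(retained)),
        "retained": int(len(retained)),
    }
    return retained, report


def extract_contexts(
    sites: pd.DataFrame, reference: str | Path | Fasta, k_per_side: int = 2
) -> tuple[pd.DataFrame, dict]:
    """Attach the upper-strand NNCGNN context to every site.

    The context is the (2k+2)-mer centred on the CpG.  Sites whose
    extracted dinucleotide is not CG, that lie too close to a chromosome
    edge, or whose context contains non-ACGT characters are rejected and
    counted in the report.
    """
    fasta = reference if isinstance(reference, Fasta) else Fasta(str(reference))
    contexts = []
    reasons = {"out_of_bounds": 0, "not_cpg": 0, "non_acgt": 0}
    for chrom, pos in zip(sites["chrom"], sites["pos"]):
        chrom_len = len(fasta[chrom])
        if pos < k_per_side or pos + 2 + k_per_side > chrom_len:
            contexts.append(None)
            reasons["out_of_bounds"] += 1
            continue
        ctx = str(fasta[chrom][pos - k_per_side : pos + 2 + k_per_side]).upper()
        if ctx[k_per_side : k_per_side + 2] != "CG":
            contexts.append(None)
            reasons["not_cpg"] += 1
        elif any(b not in "ACGT" for b in ctx):
            contexts.append(None)
            reasons["non_acgt"] += 1
        else:
            contexts.append(ctx)
    out = sites.copy()
    out["context"] = contexts
    kept = out[out["context"].notna()].reset_index(drop=True)
    report = {"rejected": reasons, "retained": int(len(kept))}
    return kept, report


def hydroxymethylome(bs_level, oxbs_level):
    """Split paired BS / oxBS levels into (5hmC, 5mC).

    BS measures 5mC+5hmC, oxBS measures 5mC alone; the difference is the
    5hmC level, clamped at 0 where sampling noise makes it negative.
    """
    bs = np.asarray(bs_level, dtype=float)
    oxbs = np.asarray(oxbs_level, dtype=float)
    hmc = np.clip(bs - oxbs, 0.0, None)
    return hmc, oxbs.copy()


# ---------------------------------------------------------------------------
# aggregation and prediction
# ---------------------------------------------------------------------------


def context_aggregate(sites: pd.DataFrame, level_col: str) -> pd.DataFrame:
    """Mean level and site count per NNCGNN context (all 256 rows)."""
    agg = sites.groupby("context")[level_col].agg(["mean", "size"])
    profile = pd.DataFrame(index=pd.Index(all_contexts("G", 2), name="context"))
    profile["value"] = agg["mean"]
    profile["n"] = agg["size"].reindex(profile.index).fillna(0).astype(int)
    return profile


def ratio_profile(hmc_profile: pd.DataFrame, mc_profile: pd.DataFrame) -> pd.DataFrame:
    """Per-context 5hmC/5mC ratio; contexts with zero 5mC become null."""
    mc = mc_profile["value"]
    ratio = hmc_profile["value"] / mc.where(mc > 0)
    out = pd.DataFrame({"value": ratio})
    out["n"] = hmc_profile["n"]
    out["flagged_zero_mc"] = mc.le(0) | mc.isna()
    return out


def ratio_extreme_logos(
    hmc_profile: pd.DataFrame, mc_profile: pd.DataFrame, n_top: int = 10, n_bottom: int = 10
):
    """Logo matrices for the contexts with extreme 5hmC/5mC ratios."""
    return extreme_subsets(ratio_profile(hmc_profile, mc_profile), n_top, n_bottom)


def combine_preferences(*profiles: pd.Series | pd.DataFrame) -> pd.Series:
    """Average several enzyme preference profiles after min-max
    normalization, so enzymes with different absolute activity scales
    contribute equally (used e.g. to pool TET1 and TET2 preferences)."""
    normalized = []
    for i, p in enumerate(profiles):
        s = p["value"] if isinstance(p, pd.DataFrame) else p
        normalized.append(_minmax(s, f"profile {i}"))
    return pd.concat(normalized, axis=1).mean(axis=1)


def _minmax(values: pd.Series, name: str) -> pd.Series:
    lo, hi = values.min(), values.max()
    if not np.isfinite(hi - lo) or hi == lo:
        raise ValueError(f"{name} profile has zero variance")
    return (values - lo) / (hi - lo)


@dataclass
class MixPredictResult:
    alpha: float  # TET-activity weight of the best mixture
    r: float  # Pearson r of the best mixture with the 5hmC profile
    r_mc_only: float  # alpha = 0
    r_tet_only: float  # alpha = 1
    predicted: pd.Series = field(repr=False, default=None)


def mix_predict(
    tet_profile: pd.Series | pd.DataFrame,
    mc_profile: pd.Series | pd.DataFrame,
    hmc_profile: pd.Series | pd.DataFrame,
    grid_step: float = 0.01,
) -> MixPredictResult:
    """Best mixture of TET preference and 5mC level explaining 5hmC.

    All three profiles are min-max normalized to [0, 1]; the prediction
    ``alpha * TET + (1 - alpha) * 5mC`` is scanned over an alpha grid and
    the mixture maximizing the Pearson correlation with the (normalized)
    5hmC profile is returned.
    """

    def series(p):
        return p["value"] if isinstance(p, pd.DataFrame) else p

    tet, mc, hmc = series(tet_profile), series(mc_profile), series(hmc_profile)
    joined = pd.DataFrame({"tet": tet, "mc": mc, "hmc": hmc}).dropna()
    if len(joined) < 3:
        raise ValueError("fewer than 3 shared contexts")
    t = _minmax(joined["tet"], "TET").to_numpy()
    m = _minmax(joined["mc"], "5mC").to_numpy()
    h = _minmax(joined["hmc"], "5hmC").to_numpy()

    alphas = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    rs = np.array(
        [np.corrcoef(a * t + (1 - a) * m, h)[0, 1] for a in alphas]
    )
    best = int(np.nanargmax(rs))
    alpha = float(alphas[best])
    predicted = pd.Series(alpha * t + (1 - alpha) * m, index=joined.index, name="predicted")
    return MixPredictResult(
        alpha=alpha,
        r=float(rs[best]),
        r_mc_only=float(rs[0]),
        r_tet_only=float(rs[-1]),
        predicted=predicted,
    )


# ---------------------------------------------------------------------------
# sliding-window correlation
# ---------------------------------------------------------------------------


@dataclass
class WindowCorrelation:
    windows: pd.DataFrame  # chrom, start_pos, end_pos, r
    histogram: pd.DataFrame  # per |R| bin: pos_frac, neg_frac, ratio
    n_skipped_zero_variance: int


def sliding_window_correlation(
    sites: pd.DataFrame,
    tet_profile: pd.Series | pd.DataFrame,
    window: int = 18,
    hmc_col: str = "hmc_level",
    max_gap: int | None = None,
    bin_width: float = 0.1,
) -> WindowCorrelation:
    """Correlation of local 5hmC with TET context preferences.

    For every run of >= ``window`` consecutive retained CpGs (ordered by
    coordinate; runs break where the gap exceeds ``max_gap`` bases, if
    set) the Pearson R between the sites' 5hmC levels and the TET
    preference looked up from each site's context is computed in windows
    sliding by one site.  Windows where either vector has zero variance
    are skipped and counted.  The histogram reports, per |R| bin, the
    fraction of windows with positive and negative R and their ratio.
    """
    pref = tet_profile["value"] if isinstance(tet_profile, pd.DataFrame) else tet_profile
    rows = []
    skipped = 0
    for chrom, group in sites.groupby("chrom", sort=False):
        group = group.sort_values("pos")
        pos = group["pos"].to_numpy()
        h = group[hmc_col].to_numpy(dtype=float)
        p = pref.reindex(group["context"]).to_numpy(dtype=float)
        if max_gap is None:
            runs = [np.arange(len(group))]
        else:
            breaks = np.where(np.diff(pos) > max_gap)[0] + 1
            runs = np.split(np.arange(len(group)), breaks)
        for run in runs:
            if len(run) < window:
                continue
            for i in range(len(run) - window + 1):
                idx = run[i : i + window]
                x, y = h[idx], p[idx]
                if np.isnan(y).any() or x.std() == 0 or y.std() == 0:
                    skipped += 1
                    continue
                r = float(np.corrcoef(x, y)[0, 1])
                rows.append((chrom, int(pos[idx[0]]), int(pos[idx[-1]] + 1), r))
    windows = pd.DataFrame(rows, columns=["chrom", "start_pos", "end_pos", "r"])

    edges = np.arange(0.0, 1.0 + bin_width / 2, bin_width)
    labels = [f"{lo:.1f}-{hi:.1f}" for lo, hi in zip(edges[:-1], edges[1:])]
    n_total = max(len(windows), 1)
    pos_counts, _ = np.histogram(windows.loc[windows["r"] > 0, "r"], bins=edges)
    neg_counts, _ = np.histogram(-windows.loc[windows["r"] < 0, "r"], bins=edges)
    hist = pd.DataFrame(
        {
            "pos_frac": pos_counts / n_total,
            "neg_frac": neg_counts / n_total,
        },
        index=pd.Index(labels, name="abs_r_bin"),
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        hist["ratio"] = hist["pos_frac"] / hist["neg_frac"]
    return WindowCorrelation(windows=windows, histogram=hist, n_skipped_zero_variance=skipped)


# ---------------------------------------------------------------------------
# knock-out delta-m analysis
# ---------------------------------------------------------------------------


@dataclass
class DeltaMResult:
    table: pd.DataFrame  # shared sites with delta_m
    mean_delta_m: float
    top_sites: pd.DataFrame
    enrichment: pd.DataFrame  # obs/exp of bases at -1 and +1 in the top set


def ko_delta_m(
    wt_sites: pd.DataFrame, ko_sites: pd.DataFrame, top_n: int = 10_000
) -> DeltaMResult:
    """Methylation change after knock-out and its flank enrichment.

    Sites are intersected on (chrom, pos); delta_m = level(KO) -
    level(wt).  The ``top_n`` sites with the largest methylation gain
    (ties broken by coordinate) are compared with all shared sites:
    obs/exp of each base at the -1 and +1 flank positions, read from the
    NNCGNN context.
    """
    shared = wt_sites.merge(
        ko_sites[["chrom", "pos", "level"]],
        on=["chrom", "pos"],
        suffixes=("_wt", "_ko"),
    )
    if shared.empty:
        raise ValueError("no shared sites between wt and ko tables")
    shared["delta_m"] = shared["level_ko"] - shared["level_wt"]
    top = shared.sort_values(
        ["delta_m", "chrom", "pos"], ascending=[False, True, True], kind="mergesort"
    ).head(top_n)

    def base_freq(contexts: pd.Series, offset: int) -> pd.Series:
        chars = contexts.str[offset]
        return chars.value_counts(normalize=True).reindex(BASES).fillna(0.0)

    rows = {}
    for label, offset in (("-1", 1), ("+1", 4)):
        obs = base_freq(top["context"], offset)
        exp = base_freq(shared["context"], offset)
        with np.errstate(divide="ignore", invalid="ignore"):
            rows[label] = (obs / exp.where(exp > 0)).astype(float)
    enrichment = pd.DataFrame(rows).T.rename_axis("position")
    return DeltaMResult(
        table=shared,
        mean_delta_m=float(shared["delta_m"].mean()),
        top_sites=top,
        enrichment=enrichment,
    )
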