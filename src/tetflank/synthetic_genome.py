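"""Synthetic genome and methylome generator for the genomic analyses.

Emulates the structure of whole-genome BS/oxBS data (per-CpG 5mC and 5hmC
levels with coverage) and of RRBS wild-type/knock-out pairs, on a random
reference sequence: CpG sites receive beta-distributed methylation levels,
5hmC is generated with a configurable coupling to a TET flanking-sequence
preference table, and observed levels are binomial draws at
Poisson-distributed coverage.  This reproduces the *shape* of real data
(context-dependent levels, sampling noise, coverage variation) but none of
its biology (CpG islands, domains, strand asymmetries).
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from tetflank.flank_profiles import all_contexts

#: per-position base weights emulating the measured TET preferences:
#: A preferred / G disfavored at -1, C disfavored at +1, milder effects
#: at -2 and +2.  Multiplicative across positions.
_DEFAULT_POSITION_WEIGHTS: dict[int, dict[str, float]] = {
    -2: {"A": 1.2, "C": 0.9, "G": 0.8, "T": 1.1},
    -1: {"A": 3.0, "C": 1.0, "G": 0.35, "T": 1.3},
    1: {"A": 1.1, "C": 0.5, "G": 0.9, "T": 1.5},
    2: {"A": 1.0, "C": 0.8, "G": 0.9, "T": 1.3},
}


def synthetic_tet_preferences(
    position_weights: Mapping[int, Mapping[str, float]] | None = None,
    x_base: str = "G",
) -> pd.Series:
    """Multiplicative per-position preference table over NNCXNN contexts.

    Returns relative activities (arbitrary units) for all 256 contexts,
    the stand-in for a measured TET enzyme preference profile.
    """
    weights = dict(_DEFAULT_POSITION_WEIGHTS if position_weights is None else position_weights)
    contexts = all_contexts(x_base, k_per_side=2)
    values = []
    for ctx in contexts:
        by_pos = {-2: ctx[0], -1: ctx[1], 1: ctx[4], 2: ctx[5]}
        v = 1.0
        for pos, base in by_pos.items():
            v *= weights.get(pos, {}).get(base, 1.0)
        values.append(v)
    return pd.Series(values, index=pd.Index(contexts, name="context"), name="preference")


def random_genome(
    length: int = 2_000_000, n_chromosomes: int = 1, seed: int | None = None, gc: float = 0.42
) -> dict[str, str]:
    """Random reference sequence split over ``n_chromosomes``."""
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    per = length // n_chromosomes
    return {
        f"chr{i + 1}": "".join(rng.choice(list("ACGT"), size=per, p=p))
        for i in range(n_chromosomes)
    }


def write_fasta(genome: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def find_cpg_sites(genome: Mapping[str, str]) -> pd.DataFrame:
    """0-based positions of the C of every + strand CpG, with contexts.

    Sites too close to a chromosome edge for an NNCGNN context are
    omitted.
    """
    rows = []
    for chrom, seq in genome.items():
        start = 0
        while True:
            pos = seq.find("CG", start)
            if pos == -1:
                break
            start = pos + 1
            if 2 <= pos <= len(seq) - 4:
                rows.append((chrom, pos, seq[pos - 2 : pos + 4]))
    return pd.DataFrame(rows, columns=["chrom", "pos", "context"])


def simulate_methylome(
    genome: Mapping[str, str],
    tet_profile: pd.Series | None = None,
    coupling: float = 0.7,
    hmc_scale: float = 0.3,
    mean_mc: float = 0.7,
    mc_concentration: float = 8.0,
    mc_profile: pd.Series | None = None,
    mc_profile_weight: float = 0.3,
    mean_coverage: float = 30.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-CpG BS/oxBS methylome with TET-coupled 5hmC.

    True 5mC levels are Beta(mean*c, (1-mean)*c); the true 5hmC level of a
    site is ``hmc_scale * mc * ((1-coupling)*noise + coupling*pref)`` with
    the min-max-normalized TET preference of its NNCGNN context and
    Beta(2,2) noise.  Observed BS level (5mC+5hmC) and oxBS level (5mC)
    are binomial draws at Poisson(``mean_coverage``) coverage.  Columns:
    chrom, pos, context, coverage, bs_level, oxbs_level plus the true
    levels (mc_true, hmc_true) for oracle tests.

    ``mc_profile`` optionally makes the 5mC level itself context
    dependent (real methylomes carry DNMT flanking preferences): the
    per-site beta mean is shifted toward the normalized profile value
    with weight ``mc_profile_weight``.
    """
    if not 0.0 <= coupling <= 1.0:
        raise ValueError("coupling must be in [0, 1]")
    rng = np.random.default_rng(seed)
    sites = find_cpg_sites(genome)
    n = len(sites)
    if tet_profile is None:
        tet_profile = synthetic_tet_preferences()
    pref = tet_profile.reindex(sites["context"]).to_numpy(dtype=float)
    pref = (pref - np.nanmin(pref)) / (np.nanmax(pref) - np.nanmin(pref))

    mu = np.full(n, mean_mc)
    if mc_profile is not None:
        mpref = mc_profile.reindex(sites["context"]).to_numpy(dtype=float)
        mpref = (mpref - np.nanmin(mpref)) / (np.nanmax(mpref) - np.nanmin(mpref))
        mu = np.clip((1 - mc_profile_weight) * mu + mc_profile_weight * mpref, 0.05, 0.95)
    mc = rng.beta(mu * mc_concentration, (1 - mu) * mc_concentration, size=n)
    noise = rng.beta(2.0, 2.0, size=n)
    hmc = hmc_scale * mc * (coupling * pref + (1 - coupling) * noise)

    coverage = rng.poisson(mean_coverage, size=n)
    pos_cov = np.maximum(coverage, 1)
    bs = rng.binomial(pos_cov, np.clip(mc + hmc, 0, 1)) / pos_cov
    oxbs = rng.binomial(pos_cov, mc) / pos_cov

    out = sites.copy()
    out["coverage"] = coverage
    out["bs_level"] = bs
    out["oxbs_level"] = oxbs
    out["mc_true"] = mc
    out["hmc_true"] = hmc
    return out


def simulate_ko_pair(
    methylome: pd.DataFrame,
    tet_profile: pd.Series | None = None,
    gain_scale: float = 0.15,
    coupling: float = 0.8,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Wild-type / TET-knock-out methylation pair from a methylome table.

    Knocking out the enzyme raises methylation most where the enzyme was
    most active, i.e. the gain is coupled to the TET preference of the
    site's context.  Returns (wt, ko) tables with columns chrom, pos,
    context, level, coverage.
    """
    rng = np.random.default_rng(seed)
    if tet_profile is None:
        tet_profile = synthetic_tet_preferences()
    pref = tet_profile.reindex(methylome["context"]).to_numpy(dtype=float)
    pref = (pref - np.nanmin(pref)) / (np.nanmax(pref) - np.nanmin(pref))
    n = len(methylome)

    wt_level = methylome["oxbs_level"].to_numpy()
    noise = rng.beta(2.0, 2.0, size=n)
    gain = gain_scale * (coupling * pref + (1 - coupling) * noise) * (1 - wt_level)
    cov = methylome["coverage"].to_numpy()
    pos_cov = np.maximum(cov, 1)
    ko_level = rng.binomial(pos_cov, np.clip(wt_level + gain, 0, 1)) / pos_cov

    base = methylome[["chrom", "pos", "context"]].copy()
    wt = base.assign(level=wt_level, coverage=cov)
    ko = base.assign(level=ko_level, coverage=cov)
    return wt, ko


def write_bedgraph(
    sites: pd.DataFrame, path: str | Path, level_col: str = "level", coverage_col: str = "coverage"
) -> None:
    """bedGraph-style TSV: chrom, start, end, level, coverage."""
    out = pd.DataFrame(
        {
            "chrom": sites["chrom"],
            "start": sites["pos"],
            "end": sites["pos"] + 1,
            "level": sites[level_col],
            "coverage": sites[coverage_col],
        }
    )
    out.to_csv(path, sep="\t", index=False, header=False)
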