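"""Simulation of randomized-flank TET substrate libraries and their readout.

A library molecule is a double-stranded oligonucleotide whose upper strand
carries a single modified cytosine (5mC or 5hmC) in a CpG or CpX context,
flanked by ``flank_len`` randomized nucleotides on each side and invariant
primer arms.  The lower strand is unmodified (hemimodified design).
Oxidation of the target base by a TET enzyme is simulated as a
continuous-time Markov jump process over the four-species chain

    5mC --k1--> 5hmC --k2--> 5fC --k3--> 5caC

with an optional processive branch 5mC --k12--> 5fC that skips the free
5hmC intermediate.  Bisulfite conversion and sequencing are then simulated
to produce a converted read pair (upper strand, lower strand) per molecule,
which downstream modules reconstruct.

All stochastic operations require an explicit seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np

BASES = ("A", "C", "G", "T")
STATES = ("5mC", "5hmC", "5fC", "5caC")
_STATE_CODE = {s: i for i, s in enumerate(STATES)}

#: Invariant primer arms flanking the randomized core.  The exact arm
#: sequences are irrelevant to the flank statistics; these defaults are
#: arbitrary 20-mers and can be overridden everywhere they are used.
DEFAULT_LEFT_ARM = "GTAGGTAGAAGGTTAGTGTA"
DEFAULT_RIGHT_ARM = "TAGTGGTTAAGGAGTTGGTA"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SubstrateMolecule:
    """One hemimodified library molecule.

    ``upper_seq`` is the top strand 5'->3': left arm, ``flank_len`` random
    bases, the target C, the +0' base X (G for CpG libraries), ``flank_len``
    random bases, right arm.  ``target_index`` is the 0-based offset of the
    target C.  The lower strand is the unmodified reverse complement.
    """

    molecule_id: str
    upper_seq: str
    target_index: int
    flank_len: int
    start_state: str
    current_state: str

    def __post_init__(self) -> None:
        if self.upper_seq[self.target_index] != "C":
            raise ValueError("upper_seq[target_index] must be C")
        if self.start_state not in ("5mC", "5hmC"):
            raise ValueError(f"bad start_state {self.start_state!r}")
        if self.current_state not in STATES:
            raise ValueError(f"bad current_state {self.current_state!r}")

    @property
    def left_flank(self) -> str:
        """Randomized bases at positions -flank_len..-1 (upper strand)."""
        return self.upper_seq[self.target_index - self.flank_len : self.target_index]

    @property
    def right_flank(self) -> str:
        """Randomized bases at positions +1..+flank_len (3' of the X base)."""
        return self.upper_seq[self.target_index + 2 : self.target_index + 2 + self.flank_len]

    @property
    def x_base(self) -> str:
        """The +0' base immediately 3' of the target C (G for CpG)."""
        return self.upper_seq[self.target_index + 1]

    @property
    def context(self) -> str:
        """Flank string: positions -flank_len..-1 then +1..+flank_len."""
        return self.left_flank + self.right_flank

    @property
    def site_class(self) -> str:
        return "Cp" + self.x_base

    def nncxnn(self, k: int = 2) -> str:
        """Local context as a (2k+2)-mer, e.g. the NNCGNN 6-mer for k=2."""
        return self.left_flank[-k:] + "C" + self.x_base + self.right_flank[:k]


@dataclass
class GroundTruthModel:
    """Context-dependent rate model generating a library's oxidation.

    ``rate_fn`` maps a molecule's full context string (left flank + right
    flank, with the X base appended for CpX libraries) to the four rate
    constants ``(k1, k2, k12, k3)`` in reciprocal arbitrary time units.
    ``mixture_weights`` gives the +0' base distribution for CpN libraries;
    the default is the 1:3 CpG:CpH design (G = 1/4, each of A/C/T = 1/4).
    """

    site_type: str
    rate_fn: Callable[[str], tuple[float, float, float, float]]
    mixture_weights: Mapping[str, float] = field(
        default_factory=lambda: {"G": 0.25, "A": 0.25, "C": 0.25, "T": 0.25}
    )

    def __post_init__(self) -> None:
        if self.site_type not in ("mCpG", "hmCpG", "mCpX"):
            raise ValueError(f"bad site_type {self.site_type!r}")
        total = sum(self.mixture_weights.values())
        if not np.isclose(total, 1.0):
            raise ValueError("mixture weights must sum to 1")

    def rates_for(self, molecule: SubstrateMolecule) -> tuple[float, float, float, float]:
        key = molecule.context
        if self.site_type == "mCpX":
            key = key + molecule.x_base
        k = tuple(float(v) for v in self.rate_fn(key))
        if len(k) != 4 or any(v < 0 for v in k):
            raise ValueError("rate_fn must return four non-negative rates")
        return k


def constant_rates(k1: float, k2: float, k12: float, k3: float):
    """Convenience rate_fn: the same rates for every context."""

    def fn(_context: str) -> tuple[float, float, float, float]:
        return (k1, k2, k12, k3)

    return fn


@dataclass(frozen=True)
class ReadPair:
    """Converted reads for both strands of one molecule.

    ``upper`` is the bisulfite-converted upper strand 5'->3'; ``lower`` is
    the converted lower strand 5'->3' (i.e. reverse-complement orientation
    relative to the upper frame).  The hairpin that physically links the
    two strands in the wet-lab protocol is abstracted as this pairing.
    """

    molecule_id: str
    upper: str
    lower: str

    def concatenated(self, spacer: str = "TTTT") -> str:
        """Single-record hairpin dialect: upper + spacer + converted lower."""
        return self.upper + spacer + self.lower


# ---------------------------------------------------------------------------
# library generation
# ---------------------------------------------------------------------------


def generate_library(
    n_molecules: int,
    site_type: str,
    flank_len: int = 10,
    seed: int | None = None,
    mixture_weights: Mapping[str, float] | None = None,
    composition: Sequence[float] | None = None,
    left_arm: str = DEFAULT_LEFT_ARM,
    right_arm: str = DEFAULT_RIGHT_ARM,
) -> list[SubstrateMolecule]:
    """Draw a hemimodified substrate library.

    Flank bases are i.i.d. uniform over A/C/G/T unless ``composition``
    (probabilities for A, C, G, T) is supplied.  For ``site_type='mCpX'``
    the +0' base is drawn from ``mixture_weights`` (default 1:3 CpG:CpH);
    for CpG libraries it is fixed to G.  Deterministic under a fixed seed.
    """
    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    if flank_len < 2:
        raise ValueError("flank_len must be >= 2 (NNCXNN statistics need two flanking bases per side)")
    if site_type not in ("mCpG", "hmCpG", "mCpX"):
        raise ValueError(f"bad site_type {site_type!r}")

    rng = np.random.default_rng(seed)
    p = None if composition is None else np.asarray(composition, dtype=float)
    if p is not None:
        if p.shape != (4,) or not np.isclose(p.sum(), 1.0):
            raise ValueError("composition must be 4 probabilities summing to 1")
    flanks = rng.choice(np.array(list("ACGT")), size=(n_molecules, 2 * flank_len), p=p)

    if site_type == "mCpX":
        weights = dict(mixture_weights) if mixture_weights is not None else {
            "G": 0.25, "A": 0.25, "C": 0.25, "T": 0.25
        }
        if not np.isclose(sum(weights.values()), 1.0):
            raise ValueError("mixture weights must sum to 1")
        xs = rng.choice(list(weights), size=n_molecules, p=list(weights.values()))
    else:
        xs = np.full(n_molecules, "G")

    start_state = "5hmC" if site_type == "hmCpG" else "5mC"
    target_index = len(left_arm) + flank_len

    library = []
    for i in range(n_molecules):
        row = flanks[i]
        upper = (
            left_arm
            + "".join(row[:flank_len])
            + "C"
            + xs[i]
            + "".join(row[flank_len:])
            + right_arm
        )
        library.append(
            SubstrateMolecule(
                molecule_id=f"mol{i}",
                upper_seq=upper,
                target_index=target_index,
                flank_len=flank_len,
                start_state=start_state,
                current_state=start_state,
            )
        )
    return library


# ---------------------------------------------------------------------------
# oxidation dynamics
# ---------------------------------------------------------------------------


def simulate_oxidation(
    library: Sequence[SubstrateMolecule],
    model: GroundTruthModel,
    t: float,
    mechanism: str = "processive_k12",
    seed: int | None = None,
) -> list[SubstrateMolecule]:
    """Advance every molecule's oxidation state to time ``t``.

    Exact stochastic simulation: each molecule follows a continuous-time
    Markov chain with exponential waiting times (rate k1+k12 out of 5mC,
    branching k1:k12 between 5hmC and 5fC; k2 out of 5hmC; k3 out of 5fC),
    so marginal species fractions converge to the deterministic four-species
    solution as the library grows.  ``mechanism='distributive'`` forces
    k12 = 0; ``'processive_k12'`` uses the model's k12.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    if mechanism not in ("distributive", "processive_k12"):
        raise ValueError(f"bad mechanism {mechanism!r}")

    n = len(library)
    rates = np.array([model.rates_for(m) for m in library], dtype=float)
    k1, k2, k12, k3 = rates[:, 0], rates[:, 1], rates[:, 2], rates[:, 3]
    if mechanism == "distributive":
        k12 = np.zeros(n)

    rng = np.random.default_rng(seed)
    with np.errstate(divide="ignore"):
        # residence times in 5mC, 5hmC and 5fC (inf where the exit rate is 0)
        out_m = k1 + k12
        tau_m = np.where(out_m > 0, rng.exponential(size=n) / np.where(out_m > 0, out_m, 1.0), np.inf)
        tau_h = np.where(k2 > 0, rng.exponential(size=n) / np.where(k2 > 0, k2, 1.0), np.inf)
        tau_f = np.where(k3 > 0, rng.exponential(size=n) / np.where(k3 > 0, k3, 1.0), np.inf)
    to_f_direct = rng.random(n) * np.where(out_m > 0, out_m, 1.0) < k12

    start = np.array([_STATE_CODE[m.current_state] for m in library])
    state = start.copy()

    # molecules starting in 5mC
    m_mask = start == 0
    left_m = m_mask & (tau_m <= t)
    # branch: direct to 5fC (processive) or via 5hmC
    via_h = left_m & ~to_f_direct
    direct = left_m & to_f_direct
    state[via_h] = 1
    reach_f_via_h = via_h & (tau_m + tau_h <= t)
    state[reach_f_via_h] = 2
    state[direct] = 2
    # time of 5fC arrival for molecules that got there from 5mC
    arrive_f = np.where(direct, tau_m, tau_m + tau_h)
    reach_ca = (direct | reach_f_via_h) & (arrive_f + tau_f <= t)
    state[reach_ca] = 3

    # molecules starting in 5hmC (hmCpG libraries): k1/k12 are irrelevant
    h_mask = start == 1
    reach_f = h_mask & (tau_h <= t)
    state[reach_f] = 2
    state[reach_f & (tau_h + tau_f <= t)] = 3

    return [
        dataclasses.replace(mol, current_state=STATES[s]) for mol, s in zip(library, state)
    ]


def species_fractions(library: Sequence[SubstrateMolecule]) -> dict[str, float]:
    """Fraction of molecules currently in each of the four species."""
    n = len(library)
    counts = {s: 0 for s in STATES}
    for m in library:
        counts[m.current_state] += 1
    return {s: c / n for s, c in counts.items()}


# ---------------------------------------------------------------------------
# bisulfite conversion and sequencing
# ---------------------------------------------------------------------------


def _convert_strand(
    seqs: np.ndarray,
    protected: np.ndarray,
    conv_failure_rate: float,
    over_conversion_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Bisulfite-convert a (n, L) byte matrix of strand sequences.

    ``protected`` flags cytosines whose modification state blocks
    deamination (5mC/5hmC).  Unprotected C (including 5fC/5caC) reads T
    except with probability ``conv_failure_rate``; protected C reads C
    except with probability ``over_conversion_rate``.
    """
    out = seqs.copy()
    is_c = seqs == ord("C")
    u = rng.random(seqs.shape)
    convert = is_c & ~protected & (u >= conv_failure_rate)
    overconv = is_c & protected & (u < over_conversion_rate)
    out[convert | overconv] = ord("T")
    return out


def _seq_matrix(strings: Sequence[str]) -> np.ndarray:
    length = len(strings[0])
    if any(len(s) != length for s in strings):
        raise ValueError("all sequences must share one length")
    return np.frombuffer("".join(strings).encode(), dtype=np.uint8).reshape(len(strings), length).copy()


def simulate_bisulfite_reads(
    library: Sequence[SubstrateMolecule],
    conv_failure_rate: float = 0.0,
    over_conversion_rate: float = 0.0,
    seq_error_rate: float = 0.0,
    seed: int | None = None,
) -> list[ReadPair]:
    """Bisulfite conversion + sequencing of both strands of every molecule.

    On each strand independently, unmodified C and the target in 5fC/5caC
    deaminate to T while 5mC/5hmC stay C (subject to the failure /
    over-conversion rates); uniform substitution noise is then applied at
    ``seq_error_rate``.  Returns one :class:`ReadPair` per molecule.
    """
    for name, r in (
        ("conv_failure_rate", conv_failure_rate),
        ("over_conversion_rate", over_conversion_rate),
        ("seq_error_rate", seq_error_rate),
    ):
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")

    rng = np.random.default_rng(seed)
    uppers = _seq_matrix([m.upper_seq for m in library])
    lowers = _seq_matrix([reverse_complement(m.upper_seq) for m in library])
    n, length = uppers.shape

    protected_up = np.zeros_like(uppers, dtype=bool)
    idx = np.array([m.target_index for m in library])
    keep = np.array([m.current_state in ("5mC", "5hmC") for m in library])
    protected_up[np.arange(n)[keep], idx[keep]] = True
    # lower strand is fully unmodified (hemimodified design)
    protected_lo = np.zeros_like(lowers, dtype=bool)

    conv_up = _convert_strand(uppers, protected_up, conv_failure_rate, over_conversion_rate, rng)
    conv_lo = _convert_strand(lowers, protected_lo, conv_failure_rate, over_conversion_rate, rng)

    if seq_error_rate > 0:
        base_codes = np.frombuffer(b"ACGT", dtype=np.uint8)
        for mat in (conv_up, conv_lo):
            hit = rng.random(mat.shape) < seq_error_rate
            # substitute with a uniform choice among the three other bases
            shift = rng.integers(1, 4, size=mat.shape)
            cur = np.searchsorted(base_codes, mat)
            mat[hit] = base_codes[(cur[hit] + shift[hit]) % 4]

    return [
        ReadPair(
            molecule_id=m.molecule_id,
            upper=conv_up[i].tobytes().decode(),
            lower=conv_lo[i].tobytes().decode(),
        )
        for i, m in enumerate(library)
    ]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def write_fastq(
    pairs: Sequence[ReadPair],
    path_r1: str | Path,
    path_r2: str | Path,
    quality_char: str = "I",
) -> None:
    """Write the pair list as two FASTQ files (Phred+33, constant quality)."""
    with open(path_r1, "w") as f1, open(path_r2, "w") as f2:
        for p in pairs:
            f1.write(f"@{p.molecule_id}/1\n{p.upper}\n+\n{quality_char * len(p.upper)}\n")
            f2.write(f"@{p.molecule_id}/2\n{p.lower}\n+\n{quality_char * len(p.lower)}\n")


def write_sidecar(library: Sequence[SubstrateMolecule], path: str | Path) -> None:
    """Ground-truth sidecar TSV: one row per molecule."""
    with open(path, "w") as fh:
        fh.write("molecule_id\tcontext\tx_base\tsite_class\tstart_state\tend_state\n")
        for m in library:
            fh.write(
                f"{m.molecule_id}\t{m.context}\t{m.x_base}\t{m.site_class}\t"
                f"{m.start_state}\t{m.current_state}\n"
            )


def write_manifest(path: str | Path, **params) -> None:
    """Log the run parameters (seed included) for reproducibility."""
    Path(path).write_text(json.dumps(params, indent=2, sort_keys=True) + "\n")


def read_key_value_config(path: str | Path) -> dict[str, str]:
    """Parse a plain ``key = value`` config file; '#' starts a comment."""
    config: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, value = line.split("=", 1)
        config[key.strip()] = value.strip()
    return config
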