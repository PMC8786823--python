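"""Single-molecule readout: from converted read pairs to molecule records.

The library design is fixed-length with invariant primer arms, so reads are
frame-anchored by matching the (conversion-aware) arm sequences rather than
aligned.  For every molecule the original duplex is reconstituted from the
two converted strands, and the oxidation state of the target cytosine is
called: a protected target (reads C, partner G) means 5mC or 5hmC; a
converted target (reads T, partner G) means 5fC or 5caC.  For a 5mC
library a converted call therefore implies at least two oxidation steps,
for a 5hmC library at least one.

Coordinates follow the upper strand 5'->3': the target C is position 0,
negative positions lie 5' of it, +0' is the base 3' of the C (the G of a
CpG), and +1..+flank_len continue 3' of the +0' base.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd

from tetflank.synthetic_library import (
    DEFAULT_LEFT_ARM,
    DEFAULT_RIGHT_ARM,
    reverse_complement,
)

CALL_UNCONVERTED = "unconverted"
CALL_OXIDIZED = "oxidized"
CALL_AMBIGUOUS = "ambiguous"

#: duplex resolution in the upper frame: (upper base, lower-strand base at
#: the pairing position) -> (original upper base, status).  A converted
#: cytosine on either strand appears as T on its own strand; every other
#: combination is conversion-inconsistent.
_PAIR_RULES = {
    ("A", "T"): ("A", "match"),
    ("T", "A"): ("T", "match"),
    ("G", "C"): ("G", "match"),
    ("G", "T"): ("G", "lower_converted"),
    ("C", "G"): ("C", "protected"),
    ("T", "G"): ("C", "converted"),
}


@dataclass(frozen=True)
class FastqRead:
    name: str
    seq: str
    qual: str

    @property
    def mean_quality(self) -> float:
        return sum(ord(c) - 33 for c in self.qual) / len(self.qual)


@dataclass(frozen=True)
class MoleculeRecord:
    """One reconstructed molecule: flank context plus its oxidation call."""

    molecule_id: str
    context: str  # flanks -flank_len..-1 then +1..+flank_len, upper strand
    x_base: str  # the +0' base
    site_class: str  # CpG/CpA/CpC/CpT
    call: str  # unconverted / oxidized / ambiguous


def read_fastq(path: str | Path) -> Iterator[FastqRead]:
    with open(path) as fh:
        while True:
            header = fh.readline().rstrip()
            if not header:
                return
            seq = fh.readline().rstrip()
            fh.readline()
            qual = fh.readline().rstrip()
            yield FastqRead(name=header[1:].split()[0], seq=seq, qual=qual)


def _strip_mate(name: str) -> str:
    return re.sub(r"/[12]$", "", name)


def read_fastq_pairs(path_r1: str | Path, path_r2: str | Path) -> list[tuple[FastqRead, FastqRead]]:
    pairs = list(zip(read_fastq(path_r1), read_fastq(path_r2)))
    for r1, r2 in pairs:
        if _strip_mate(r1.name) != _strip_mate(r2.name):
            raise ValueError(f"read pair mismatch: {r1.name} vs {r2.name}")
    return pairs


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------


def filter_reads(
    pairs: Iterable[tuple[FastqRead, FastqRead]],
    min_quality: float = 20.0,
    length_window: tuple[int, int] | None = None,
) -> tuple[list[tuple[FastqRead, FastqRead]], dict[str, int]]:
    """Quality/length filter: keep a pair iff both mates pass.

    A mate passes when its mean Phred quality is >= ``min_quality`` and its
    length falls inside the inclusive ``length_window`` (no length check if
    None).  Returns the retained pairs and QC counts.
    """
    kept: list[tuple[FastqRead, FastqRead]] = []
    qc = {"input_pairs": 0, "fail_quality": 0, "fail_length": 0, "retained_pairs": 0}
    for pair in pairs:
        qc["input_pairs"] += 1
        if any(r.mean_quality < min_quality for r in pair):
            qc["fail_quality"] += 1
            continue
        if length_window is not None:
            lo, hi = length_window
            if any(not lo <= len(r.seq) <= hi for r in pair):
                qc["fail_length"] += 1
                continue
        kept.append(pair)
        qc["retained_pairs"] += 1
    if qc["input_pairs"] == 0:
        warnings.warn("filter_reads received no read pairs", stacklevel=2)
    return kept, qc


# ---------------------------------------------------------------------------
# reconstruction
# ---------------------------------------------------------------------------


def _bisulfite_mismatches(expected: str, observed: str) -> int:
    """Hamming distance where an expected C also accepts T (conversion)."""
    return sum(
        o != e and not (e == "C" and o == "T") for e, o in zip(expected, observed)
    )


@dataclass(frozen=True)
class ReconstructedMolecule:
    molecule_id: str
    original: str  # reconstituted upper-strand sequence, '?' where ambiguous
    converted: tuple[bool, ...]  # per position: upper-strand C was deaminated
    ambiguous: tuple[int, ...]  # positions with inconsistent strand evidence


def reconstruct_molecule(
    upper_read: str,
    lower_read: str,
    left_arm: str = DEFAULT_LEFT_ARM,
    right_arm: str = DEFAULT_RIGHT_ARM,
    max_arm_mismatch: int = 2,
    molecule_id: str = "",
) -> ReconstructedMolecule:
    """Reconstitute the original duplex from the two converted strands.

    The lower read (converted lower strand, 5'->3') is reversed into the
    upper frame so position i pairs upper[i] with lower[i]; Watson-Crick
    plus bisulfite rules then resolve each position (see module docstring).
    The mate orientation is auto-detected from the arm sequences, so
    swapping the two reads yields the identical reconstruction.  A molecule
    whose arms exceed ``max_arm_mismatch`` conversion-aware mismatches per
    arm on both orientations is rejected.
    """
    if len(upper_read) != len(lower_read):
        raise ValueError("mates must have equal length (fixed-length design)")

    def arm_cost(up: str) -> int:
        return max(
            _bisulfite_mismatches(left_arm, up[: len(left_arm)]),
            _bisulfite_mismatches(right_arm, up[len(up) - len(right_arm) :]),
        )

    candidates = [(upper_read, lower_read), (lower_read, upper_read)]
    costs = [arm_cost(u) for u, _ in candidates]
    best = min(range(2), key=lambda i: costs[i])
    if costs[best] > max_arm_mismatch:
        raise ValueError(
            f"molecule {molecule_id or '<unnamed>'}: arm mismatch {costs[best]} exceeds "
            f"tolerance {max_arm_mismatch} in both orientations"
        )
    upper, lower = candidates[best]

    lower_in_frame = lower[::-1]
    original = []
    converted = []
    ambiguous = []
    for i, (u, l) in enumerate(zip(upper, lower_in_frame)):
        base, status = _PAIR_RULES.get((u, l), ("?", "ambiguous"))
        original.append(base)
        converted.append(status == "converted")
        if status == "ambiguous":
            ambiguous.append(i)
    return ReconstructedMolecule(
        molecule_id=molecule_id,
        original="".join(original),
        converted=tuple(converted),
        ambiguous=tuple(ambiguous),
    )


def call_state(recon: ReconstructedMolecule, target_index: int) -> str:
    """Oxidation call at the target position.

    C with partner G -> ``unconverted`` (5mC or 5hmC); T with partner G ->
    ``oxidized`` (5fC or 5caC); anything else, including an originally
    non-C target, is ``ambiguous``.
    """
    if target_index in recon.ambiguous or recon.original[target_index] != "C":
        return CALL_AMBIGUOUS
    return CALL_OXIDIZED if recon.converted[target_index] else CALL_UNCONVERTED


# ---------------------------------------------------------------------------
# full readout pipeline
# ---------------------------------------------------------------------------


def readout(
    pairs: Iterable[tuple[FastqRead, FastqRead]],
    flank_len: int = 10,
    left_arm: str = DEFAULT_LEFT_ARM,
    right_arm: str = DEFAULT_RIGHT_ARM,
    min_quality: float = 20.0,
    length_window: tuple[int, int] | None = None,
    max_arm_mismatch: int = 2,
    expected_site_class: str | None = None,
) -> tuple[list[MoleculeRecord], dict]:
    """Filter, reconstruct and call every read pair.

    Returns the molecule records (ambiguous-flank molecules are kept with
    call=ambiguous and excluded from statistics downstream) plus a QC
    report.  Molecules whose reconstructed site class disagrees with
    ``expected_site_class`` (e.g. CpT in a CpG library) are routed to the
    QC report under ``site_class_mismatch`` but still returned.
    """
    kept, qc = filter_reads(pairs, min_quality=min_quality, length_window=length_window)
    target_index = len(left_arm) + flank_len

    records: list[MoleculeRecord] = []
    qc.update(arm_rejected=0, flank_ambiguous=0, site_class_mismatch=0, calls={})
    for r1, r2 in kept:
        try:
            recon = reconstruct_molecule(
                r1.seq,
                r2.seq,
                left_arm=left_arm,
                right_arm=right_arm,
                max_arm_mismatch=max_arm_mismatch,
                molecule_id=r1.name,
            )
        except ValueError:
            qc["arm_rejected"] += 1
            continue

        left = recon.original[target_index - flank_len : target_index]
        right = recon.original[target_index + 2 : target_index + 2 + flank_len]
        x = recon.original[target_index + 1]
        call = call_state(recon, target_index)
        if "?" in left + right + x:
            qc["flank_ambiguous"] += 1
            call = CALL_AMBIGUOUS
        site_class = "Cp" + x if x != "?" else "Cp?"
        if expected_site_class is not None and site_class != expected_site_class:
            qc["site_class_mismatch"] += 1
        records.append(
            MoleculeRecord(
                molecule_id=_strip_mate(r1.name),
                context=left + right,
                x_base=x,
                site_class=site_class,
                call=call,
            )
        )
        qc["calls"][call] = qc["calls"].get(call, 0) + 1
    return records, qc


def records_to_frame(records: Sequence[MoleculeRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "molecule_id": [r.molecule_id for r in records],
            "context": [r.context for r in records],
            "x_base": [r.x_base for r in records],
            "site_class": [r.site_class for r in records],
            "call": [r.call for r in records],
        }
    )


def write_records(records: Sequence[MoleculeRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False)


def read_records(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)


def write_qc(qc: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(qc, indent=2, sort_keys=True) + "\n")
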