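import numpy as np
import pandas as pd
import pytest

from tetflank import synthetic_library as sl
from tetflank.deep_readout import FastqRead


def pairs_to_fastq_reads(pairs, quality_char="I"):
    """Wrap simulated read pairs as FASTQ read objects (constant quality)."""
    return [
        (
            FastqRead(p.molecule_id + "/1", p.upper, quality_char * len(p.upper)),
            FastqRead(p.molecule_id + "/2", p.lower, quality_char * len(p.lower)),
        )
        for p in pairs
    ]


def records_from_truth(library):
    """Ground-truth molecule records straight from simulated states.

    Bypasses the read/reconstruction layer (tested separately) so that
    statistics tests are not confounded by readout errors.
    """
    return pd.DataFrame(
        {
            "molecule_id": [m.molecule_id for m in library],
            "context": [m.context for m in library],
            "x_base": [m.x_base for m in library],
            "site_class": [m.site_class for m in library],
            "call": [
                "oxidized" if m.current_state in ("5fC", "5caC") else "unconverted"
                for m in library
            ],
        }
    )


def pwm_rate_fn(position_weights, base_rate=0.3, flank_len=10):
    """Rate function multiplicative over flank positions.

    ``position_weights`` maps flank position (negative = 5' of the target
    C, positive = 3' of the X base) to per-base weights; k1 is modulated,
    the other steps keep fixed proportions of k1.
    """

    def fn(context):
        left, right = context[:flank_len], context[flank_len : 2 * flank_len]
        k1 = base_rate
        for pos, weights in position_weights.items():
            base = left[pos] if pos < 0 else right[pos - 1]
            k1 *= weights.get(base, 1.0)
        return (k1, 0.6 * k1, 0.15 * k1, 0.3 * k1)

    return fn


@pytest.fixture(scope="session")
def mcpg_library():
    return sl.generate_library(2000, "mCpG", seed=11)


@pytest.fixture(scope="session")
def oxidized_mcpg_library(mcpg_library):
    model = sl.GroundTruthModel("mCpG", sl.constant_rates(0.5, 0.3, 0.1, 0.1))
    return sl.simulate_oxidation(mcpg_library, model, 2.0, seed=12)


@pytest.fixture(scope="session")
def tet_preferences():
    from tetflank.synthetic_genome import synthetic_tet_preferences

    return synthetic_tet_preferences()
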