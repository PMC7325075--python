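import numpy as np
import pandas as pd
import pytest

from gcpsr.seqio import AMPLIFIED, FAILED, LocusAlignment, SampleTable


@pytest.fixture
def make_table():
    """Build a SampleTable from {sample: species} and optional failures."""

    def build(sample_species: dict[str, str], loci: list[str],
              failed: set[tuple[str, str]] = frozenset()):
        frame = pd.DataFrame(
            {
                "species_id": list(sample_species.values()),
                "voucher": ["v" for _ in sample_species],
            },
            index=pd.Index(list(sample_species), name="sample_id"),
        )
        status = {
            s: {
                loc: FAILED if (s, loc) in failed else AMPLIFIED
                for loc in loci
            }
            for s in sample_species
        }
        return SampleTable(frame, status)

    return build


@pytest.fixture
def random_alignment():
    """Random alignment with occasional gaps and Ns."""

    def build(n_seqs: int, length: int, seed: int, gap_frac: float = 0.05):
        rng = np.random.default_rng(seed)
        chars = np.array([b"A", b"C", b"G", b"T", b"-", b"N"])
        probs = np.array([1, 1, 1, 1, 0, 0], dtype=float)
        probs[4] = probs[5] = 4 * gap_frac / (2 - 2 * gap_frac)
        probs /= probs.sum()
        matrix = rng.choice(chars, size=(n_seqs, length), p=probs)
        ids = [f"t{i}" for i in range(n_seqs)]
        return LocusAlignment("rand", ids, matrix)

    return build
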