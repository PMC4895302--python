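import numpy as np
import pytest

from cyspred.dataset import Fragment
from cyspred.io_formats import AA_ORDER, AAIndexEntry, ProteinRecord


def make_fragment(sequence: str, protein_id: str = "p", center: int | None = None,
                  label: int = 0) -> Fragment:
    """Build a fragment from a raw window string (center must be C)."""
    n = len(sequence) // 2
    if center is None:
        center = n + 1
    return Fragment(protein_id, center, sequence, label)


@pytest.fixture
def frag21() -> Fragment:
    return make_fragment("A" * 10 + "C" + "A" * 10)


@pytest.fixture
def hydro_entry() -> AAIndexEntry:
    """A deterministic physicochemical index with distinct values."""
    values = {a: float(i - 10) / 4.0 for i, a in enumerate(AA_ORDER)}
    return AAIndexEntry("TEST000001", "synthetic test index", values)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


AAINDEX_TEXT = """\
H GUYH850101
D Apparent partition energies (Guy, 1985)
R LIT:2004051b
A Guy, H.R.
T Amino acid side-chain partition energies
J Biophys. J. 47, 61-70 (1985)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    0.10    1.91    0.48    0.78   -1.42    0.95    0.83    0.33   -0.50   -1.13
   -1.18    1.40   -1.59   -2.12    0.73    0.52    0.07   -0.51   -0.21   -1.27
//
H NATEST0001
D Index with a missing value
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    0.10    1.91    0.48    0.78      NA    0.95    0.83    0.33   -0.50   -1.13
   -1.18    1.40   -1.59   -2.12    0.73    0.52    0.07   -0.51   -0.21   -1.27
//
"""


@pytest.fixture
def aaindex_file(tmp_path):
    path = tmp_path / "aaindex1.txt"
    path.write_text(AAINDEX_TEXT)
    return path
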