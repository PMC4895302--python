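"""Position-specific composition statistics for fragment sets.

Provides per-position residue frequency matrices, a two-sample
logo-style enrichment test (per position x residue two-proportion
comparison), per-position solvent-accessibility profiles, and Venn
overlap counts between site sets of different modification types.

The default enrichment test is a Welch two-sample t-test on the binary
occurrence indicators, computed in closed form from the count matrices;
Fisher's exact test is available for small counts. No multiple-testing
correction is applied by default (per-cell significance), Bonferroni is
available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .dataset import Fragment
from .io_formats import ALPHABET21, ResidueTrack

_SYM_INDEX = {a: i for i, a in enumerate(ALPHABET21)}


@dataclass(frozen=True)
class PositionFrequencyMatrix:
    """21 symbols x window positions of relative frequencies."""

    matrix: np.ndarray
    n_fragments: int

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape[0] != len(ALPHABET21):
            raise ValueError("matrix must have 21 symbol rows")
        if not np.allclose(m.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("position columns must sum to 1")
        object.__setattr__(self, "matrix", m)

    @property
    def width(self) -> int:
        return self.matrix.shape[1]

    @property
    def positions(self) -> list[int]:
        n = self.width // 2
        return list(range(-n, n + 1))

    def frequency(self, residue: str, position: int) -> float:
        n = self.width // 2
        return float(self.matrix[_SYM_INDEX[residue], position + n])

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("symbol\t" + "\t".join(f"{p:+d}" for p in self.positions) + "\n")
            for sym, row in zip(ALPHABET21, self.matrix):
                fh.write(sym + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")


@dataclass(frozen=True)
class EnrichmentCell:
    position: int  # window offset, center = 0
    residue: str
    direction: str  # "enriched" | "depleted"
    freq_a: float
    freq_b: float
    p_value: float


def _count_matrix(fragments: Sequence[Fragment]) -> np.ndarray:
    if not fragments:
        raise ValueError("empty fragment set")
    width = len(fragments[0].sequence)
    if any(len(f.sequence) != width for f in fragments):
        raise ValueError("fragments must have uniform length")
    counts = np.zeros((len(ALPHABET21), width))
    for f in fragments:
        for j, aa in enumerate(f.sequence):
            counts[_SYM_INDEX[aa], j] += 1
    return counts


def position_frequencies(fragments: Sequence[Fragment]) -> PositionFrequencyMatrix:
    """Per-position relative frequencies of the 21 symbols."""
    counts = _count_matrix(fragments)
    return PositionFrequencyMatrix(counts / len(fragments), len(fragments))


def _welch_from_counts(k1: np.ndarray, n1: int, k2: np.ndarray, n2: int) -> np.ndarray:
    """Two-sided Welch t-test p-values on binary indicators, vectorized
    over a count array."""
    p1 = k1 / n1
    p2 = k2 / n2
    var1 = p1 * (1 - p1) * n1 / (n1 - 1)
    var2 = p2 * (1 - p2) * n2 / (n2 - 1)
    se2 = var1 / n1 + var2 / n2
    pvals = np.ones_like(p1, dtype=float)
    nonzero = se2 > 0
    t = np.zeros_like(p1)
    t[nonzero] = (p1[nonzero] - p2[nonzero]) / np.sqrt(se2[nonzero])
    df = np.ones_like(p1)
    with np.errstate(divide="ignore", invalid="ignore"):
        df_num = se2**2
        df_den = (var1 / n1) ** 2 / (n1 - 1) + (var2 / n2) ** 2 / (n2 - 1)
        df[nonzero] = df_num[nonzero] / df_den[nonzero]
    pvals[nonzero] = 2 * stats.t.sf(np.abs(t[nonzero]), df[nonzero])
    # zero variance in both samples: identical -> 1, different -> 0
    degenerate = ~nonzero & (p1 != p2)
    pvals[degenerate] = 0.0
    return pvals


def two_sample_logo(
    set_a: Sequence[Fragment],
    set_b: Sequence[Fragment],
    alpha: float = 0.01,
    test: str = "ttest",
    bonferroni: bool = False,
) -> list[EnrichmentCell]:
    """Per (position, residue) two-proportion comparison of two fragment
    sets; cells significant at *alpha* are returned, labeled enriched
    (freq_a > freq_b) or depleted."""
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    if test not in ("ttest", "fisher"):
        raise ValueError(f"unknown test {test!r}")
    counts_a = _count_matrix(set_a)
    counts_b = _count_matrix(set_b)
    if counts_a.shape != counts_b.shape:
        raise ValueError("fragment sets must have equal window width")
    n_a, n_b = len(set_a), len(set_b)
    if test == "ttest":
        if n_a < 2 or n_b < 2:
            raise ValueError("t-test requires at least 2 fragments per set")
        pvals = _welch_from_counts(counts_a, n_a, counts_b, n_b)
    else:
        pvals = np.ones_like(counts_a)
        for i in range(counts_a.shape[0]):
            for j in range(counts_a.shape[1]):
                ka, kb = int(counts_a[i, j]), int(counts_b[i, j])
                table = [[ka, n_a - ka], [kb, n_b - kb]]
                pvals[i, j] = stats.fisher_exact(table)[1]
    n_cells = pvals.size
    threshold = alpha / n_cells if bonferroni else alpha
    freq_a = counts_a / n_a
    freq_b = counts_b / n_b
    width = counts_a.shape[1]
    n = width // 2
    cells: list[EnrichmentCell] = []
    for i, sym in enumerate(ALPHABET21):
        for j in range(width):
            p = float(pvals[i, j])
            if p < threshold or threshold >= 1.0:
                direction = "enriched" if freq_a[i, j] >= freq_b[i, j] else "depleted"
                cells.append(
                    EnrichmentCell(j - n, sym, direction,
                                   float(freq_a[i, j]), float(freq_b[i, j]), p)
                )
    return cells


def write_enrichment_tsv(cells: Sequence[EnrichmentCell], path) -> None:
    with open(path, "w") as fh:
        fh.write("position\tresidue\tdirection\tfreq_a\tfreq_b\tp\n")
        for c in cells:
            fh.write(
                f"{c.position:+d}\t{c.residue}\t{c.direction}\t"
                f"{c.freq_a:.6g}\t{c.freq_b:.6g}\t{c.p_value:.6g}\n"
            )


def asa_profile_compare(
    set_a: Sequence[Fragment],
    tracks_a: Mapping[str, ResidueTrack],
    set_b: Sequence[Fragment],
    tracks_b: Mapping[str, ResidueTrack],
) -> tuple[np.ndarray, np.ndarray]:
    """Per-position mean normalized ASA for two fragment sets.

    Padding positions (window cells outside the protein) are excluded
    from the means. Returns two length-(2n+1) vectors.
    """

    def profile(frags: Sequence[Fragment], tracks: Mapping[str, ResidueTrack]) -> np.ndarray:
        if not frags:
            raise ValueError("empty fragment set")
        width = len(frags[0].sequence)
        n = width // 2
        total = np.zeros(width)
        count = np.zeros(width)
        for f in frags:
            if f.protein_id not in tracks:
                raise ValueError(f"no ASA track for protein {f.protein_id!r}")
            track = tracks[f.protein_id]
            center0 = f.center_position - 1
            for j in range(width):
                row = center0 + (j - n)
                if 0 <= row < len(track.values):
                    total[j] += min(max(track.values[row] / 100.0, 0.0), 1.0)
                    count[j] += 1
        with np.errstate(invalid="ignore"):
            return np.where(count > 0, total / np.maximum(count, 1), np.nan)

    return profile(set_a, tracks_a), profile(set_b, tracks_b)


def overlap_sets(site_sets: Mapping[str, set]) -> dict[str, int]:
    """Exclusive Venn-region counts for >= 2 named sets.

    Keys are '&'-joined sorted name combinations; each count is the
    number of elements belonging to exactly that combination of sets.
    """
    if len(site_sets) < 2:
        raise ValueError("need at least 2 sets")
    from itertools import combinations

    names = sorted(site_sets)
    regions: dict[str, int] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(site_sets[n] for n in combo))
            others = [site_sets[n] for n in names if n not in combo]
            outside = set().union(*others) if others else set()
            regions["&".join(combo)] = len(inside - outside)
    return regions
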