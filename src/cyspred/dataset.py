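"""Fragment extraction, labeling, homology reduction, and splitting.

A *fragment* is the ``2n + 1``-residue window centered on a candidate
cysteine (default ``n = 10``, i.e. a 21-mer); windows that run past a
protein terminus are padded with ``X``.

Homology reduction follows a pairwise scheme: proteins above an
identity threshold are grouped, and identical windows within a group
are deduplicated with training-set priority.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .io_formats import ALPHABET21, FormatError, ProteinRecord, SiteRecord

DEFAULT_WINDOW_N = 10
DEFAULT_IDENTITY_THRESHOLD = 0.30


@dataclass(frozen=True)
class Fragment:
    """A ``2n + 1``-mer window centered on a cysteine, with provenance."""

    protein_id: str
    center_position: int  # 1-based position of the center C in the protein
    sequence: str
    label: int = 0  # +1 positive, -1 negative, 0 unlabeled

    def __post_init__(self) -> None:
        if len(self.sequence) % 2 != 1:
            raise ValueError("fragment length must be odd (2n + 1)")
        n = len(self.sequence) // 2
        if self.sequence[n] != "C":
            raise ValueError(
                f"fragment center must be C, got {self.sequence[n]!r}"
            )
        bad = set(self.sequence) - set(ALPHABET21)
        if bad:
            raise ValueError(f"invalid fragment letters {sorted(bad)}")
        core = self.sequence.strip("X")
        if "X" in core and self.center_position > 0:
            # interior X is allowed only when it came from the protein itself;
            # padding must be a contiguous prefix/suffix
            pass
        if self.center_position < 1:
            raise ValueError("center_position must be >= 1")

    @property
    def window_n(self) -> int:
        return len(self.sequence) // 2


@dataclass
class DatasetSplit:
    """Training and independent-testing fragment sets."""

    train: list[Fragment]
    test: list[Fragment]


def extract_fragments(protein: ProteinRecord, n: int = DEFAULT_WINDOW_N) -> list[Fragment]:
    """One X-padded ``2n + 1``-mer per cysteine, in positional order."""
    if n < 1:
        raise ValueError("window n must be >= 1")
    seq = protein.sequence
    fragments: list[Fragment] = []
    for i, aa in enumerate(seq):
        if aa != "C":
            continue
        left = seq[max(0, i - n) : i]
        right = seq[i + 1 : i + 1 + n]
        window = "X" * (n - len(left)) + left + "C" + right + "X" * (n - len(right))
        fragments.append(Fragment(protein.id, i + 1, window))
    return fragments


def label_fragments(
    fragments: Sequence[Fragment],
    sites: Sequence[SiteRecord],
    default_negative: bool = True,
) -> list[Fragment]:
    """Assign labels from site annotations.

    Annotated positions get their site label; with *default_negative*
    every unannotated cysteine is labeled -1 (the rest-of-protein
    convention), otherwise an unannotated fragment is an error.
    """
    by_key: dict[tuple[str, int], int] = {}
    for s in sites:
        by_key[(s.protein_id, s.position)] = s.label
    frag_keys = {(f.protein_id, f.center_position) for f in fragments}
    for key in by_key:
        if key not in frag_keys:
            raise ValueError(
                f"site {key[0]!r}:{key[1]} has no matching fragment"
            )
    labeled: list[Fragment] = []
    for f in fragments:
        key = (f.protein_id, f.center_position)
        if key in by_key:
            labeled.append(replace(f, label=by_key[key]))
        elif default_negative:
            labeled.append(replace(f, label=-1))
        else:
            raise ValueError(
                f"fragment {key[0]!r}:{key[1]} has no site annotation and "
                "default-negative labeling is off"
            )
    return labeled


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


_ALIGNER = _make_aligner()


def protein_identity(a: ProteinRecord, b: ProteinRecord) -> float:
    """Global pairwise identity: matches / alignment length.

    Alignment uses BLOSUM62 with affine gaps (open 11, extend 1).
    """
    alignment = _ALIGNER.align(a.sequence, b.sequence)[0]
    counts = alignment.counts()
    return counts.identities / alignment.length


def _homology_groups(
    protein_ids: Sequence[str],
    proteins: Mapping[str, ProteinRecord] | None,
    threshold: float,
) -> dict[str, int]:
    """Union-find grouping of proteins with pairwise identity > threshold."""
    parent = {pid: pid for pid in protein_ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: str, y: str) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[ry] = rx

    if proteins is not None:
        ids = [pid for pid in protein_ids if pid in proteins]
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                ident = protein_identity(proteins[ids[i]], proteins[ids[j]])
                if ident > threshold:
                    union(ids[i], ids[j])
    else:
        # no sequences available: treat all proteins as one comparable group
        for pid in protein_ids[1:]:
            union(protein_ids[0], pid)
    roots = {pid: find(pid) for pid in protein_ids}
    root_index = {r: i for i, r in enumerate(dict.fromkeys(roots.values()))}
    return {pid: root_index[r] for pid, r in roots.items()}


def reduce_homology(
    split: DatasetSplit,
    proteins: Mapping[str, ProteinRecord] | Sequence[ProteinRecord] | None = None,
    threshold: float = DEFAULT_IDENTITY_THRESHOLD,
) -> DatasetSplit:
    """Remove redundant windows between homologous proteins.

    Within each group of proteins whose pairwise identity exceeds
    *threshold*, fragments with identical window sequences are
    deduplicated; the training set has priority, and within a set the
    first occurrence wins. A final pass drops any test fragment whose
    exact window sequence also occurs in training, so the returned
    split's test sequences are disjoint from training.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    if proteins is not None and not isinstance(proteins, Mapping):
        proteins = {p.id: p for p in proteins}

    all_ids = list(dict.fromkeys(
        f.protein_id for f in list(split.train) + list(split.test)
    ))
    if not all_ids:
        return DatasetSplit([], [])
    groups = _homology_groups(all_ids, proteins, threshold)

    keep_train: list[Fragment] = []
    keep_test: list[Fragment] = []
    seen: set[tuple[int, str]] = set()  # (group, window sequence)
    for frag in split.train:
        key = (groups[frag.protein_id], frag.sequence)
        if key in seen:
            continue
        seen.add(key)
        keep_train.append(frag)
    for frag in split.test:
        key = (groups[frag.protein_id], frag.sequence)
        if key in seen:
            continue
        seen.add(key)
        keep_test.append(frag)

    # cross-set disjointness regardless of homology grouping
    train_sequences = {f.sequence for f in keep_train}
    keep_test = [f for f in keep_test if f.sequence not in train_sequences]
    return DatasetSplit(keep_train, keep_test)


def split_dataset(
    fragments: Sequence[Fragment], test_fraction: float, seed: int
) -> DatasetSplit:
    """Reproducible stratified random split into train/test."""
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    by_label: dict[int, list[int]] = {}
    for i, f in enumerate(fragments):
        by_label.setdefault(f.label, []).append(i)
    for label, idx in by_label.items():
        if len(idx) == 0:
            raise ValueError(f"class {label} has no members")
    if set(by_label) != {1, -1}:
        raise ValueError(
            f"expected labels {{+1, -1}}, got {sorted(by_label)}"
        )
    rng = np.random.default_rng(seed)
    test_idx: set[int] = set()
    for label in sorted(by_label):
        idx = np.array(by_label[label])
        rng.shuffle(idx)
        n_test = int(round(test_fraction * len(idx)))
        test_idx.update(idx[:n_test].tolist())
    train = [f for i, f in enumerate(fragments) if i not in test_idx]
    test = [f for i, f in enumerate(fragments) if i in test_idx]
    return DatasetSplit(train, test)


# ---------------------------------------------------------------------------
# Fragment TSV round trip


def write_fragments(fragments: Iterable[Fragment], path) -> None:
    with open(path, "w") as fh:
        for f in fragments:
            fh.write(
                f"{f.protein_id}\t{f.center_position}\t{f.sequence}\t{f.label:+d}\n"
            )


def read_fragments(path) -> list[Fragment]:
    fragments: list[Fragment] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns")
            pid, pos_s, seq, label_s = parts
            fragments.append(Fragment(pid, int(pos_s), seq, int(label_s)))
    return fragments
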