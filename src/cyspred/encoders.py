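"""Fragment-to-vector feature encodings.

Eight encodings are provided: per-residue one-hot (binary), amino-acid
composition (AAC), amino-acid-pair composition (AAPC), BLOSUM62
substitution rows, position weight matrix (PWM), position-specific
scoring matrix (PSSM), physicochemical index (AAindex), and per-residue
tracks (ASA / secondary structure).

Column order for residue-indexed features is the alphabetical one-letter
order ``A, C, D, ..., Y`` (A -> bit 1, C -> bit 2). The padding symbol
``X`` is represented as an all-zero row for binary/BLOSUM62/PSSM/track
features and as a 21st alphabet symbol for the composition features.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
from Bio.Align import substitution_matrices

from .dataset import Fragment
from .io_formats import (
    AA_ORDER,
    ALPHABET21,
    AAIndexEntry,
    PSSMProfile,
    ResidueTrack,
)

_AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}
_SYM_INDEX = {a: i for i, a in enumerate(ALPHABET21)}
_SS_ORDER = "HEC"


@dataclass(frozen=True, eq=False)
class FeatureVector:
    """A named, ordered numeric encoding of one fragment."""

    names: tuple
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        names = tuple(self.names)
        if len(names) != values.shape[0]:
            raise ValueError("names and values must have equal length")
        if len(set(names)) != len(names):
            raise ValueError("feature names must be unique")
        object.__setattr__(self, "names", names)
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return len(self.names)


@dataclass(frozen=True)
class PWMatrix:
    """Position weight matrix: 21 symbols x window positions, columns
    summing to 1."""

    matrix: np.ndarray  # 21 x W

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != len(ALPHABET21):
            raise ValueError(f"PWM must have 21 rows, got shape {m.shape}")
        colsums = m.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-9):
            raise ValueError("PWM columns must sum to 1")
        object.__setattr__(self, "matrix", m)

    @property
    def width(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]


def _positions(width: int) -> list[int]:
    n = width // 2
    return list(range(-n, n + 1))


def _load_blosum62() -> np.ndarray:
    full = substitution_matrices.load("BLOSUM62")
    m = np.empty((20, 20))
    for i, a in enumerate(AA_ORDER):
        for j, b in enumerate(AA_ORDER):
            m[i, j] = full[a, b]
    return m


#: 20 x 20 BLOSUM62 block over the standard residues, alphabetical order.
BLOSUM62 = _load_blosum62()
_B62_MIN = BLOSUM62.min()
_B62_MAX = BLOSUM62.max()
_B62_SCALED = (BLOSUM62 - _B62_MIN) / (_B62_MAX - _B62_MIN)


def encode_binary(fragment: Fragment) -> FeatureVector:
    """Per-residue one-hot over the 20 standard residues; X -> zeros."""
    width = len(fragment.sequence)
    values = np.zeros(width * 20)
    names = []
    for j, (pos, aa) in enumerate(zip(_positions(width), fragment.sequence)):
        names.extend(f"binary:{pos:+d}:{a}" for a in AA_ORDER)
        if aa != "X":
            values[j * 20 + _AA_INDEX[aa]] = 1.0
    return FeatureVector(names, values)


def encode_aac(fragment: Fragment) -> FeatureVector:
    """Occurrence frequencies of the 21 symbols; sums to 1."""
    counts = np.zeros(21)
    for aa in fragment.sequence:
        counts[_SYM_INDEX[aa]] += 1
    names = [f"aac:{s}" for s in ALPHABET21]
    return FeatureVector(names, counts / len(fragment.sequence))


def encode_aapc(fragment: Fragment) -> FeatureVector:
    """Frequencies of adjacent ordered symbol pairs over the 21 x 21
    pair alphabet (441 elements); sums to 1."""
    counts = np.zeros((21, 21))
    seq = fragment.sequence
    for a, b in zip(seq, seq[1:]):
        counts[_SYM_INDEX[a], _SYM_INDEX[b]] += 1
    names = [f"aapc:{a}{b}" for a in ALPHABET21 for b in ALPHABET21]
    return FeatureVector(names, counts.ravel() / (len(seq) - 1))


def encode_blosum62(fragment: Fragment) -> FeatureVector:
    """Per-residue BLOSUM62 row rescaled to [0, 1] by the matrix's
    global min/max; X -> zeros."""
    width = len(fragment.sequence)
    values = np.zeros(width * 20)
    names = []
    for j, (pos, aa) in enumerate(zip(_positions(width), fragment.sequence)):
        names.extend(f"blosum62:{pos:+d}:{a}" for a in AA_ORDER)
        if aa != "X":
            values[j * 20 : (j + 1) * 20] = _B62_SCALED[_AA_INDEX[aa]]
    return FeatureVector(names, values)


def build_pwm(positives: Sequence[Fragment]) -> PWMatrix:
    """Per-column symbol frequencies estimated from positive fragments."""
    if not positives:
        raise ValueError("cannot build a PWM from an empty fragment set")
    width = len(positives[0].sequence)
    if any(len(f.sequence) != width for f in positives):
        raise ValueError("fragments must have uniform length")
    counts = np.zeros((21, width))
    for f in positives:
        for j, aa in enumerate(f.sequence):
            counts[_SYM_INDEX[aa], j] += 1
    return PWMatrix(counts / len(positives))


def encode_pwm(fragment: Fragment, pwm: PWMatrix) -> FeatureVector:
    """Element j = PWM frequency of the fragment's residue at column j."""
    if len(fragment.sequence) != pwm.width:
        raise ValueError(
            f"fragment length {len(fragment.sequence)} != PWM width {pwm.width}"
        )
    values = np.array([
        pwm.matrix[_SYM_INDEX[aa], j] for j, aa in enumerate(fragment.sequence)
    ])
    names = [f"pwm:{pos:+d}" for pos in _positions(pwm.width)]
    return FeatureVector(names, values)


def encode_pssm(fragment: Fragment, profile: PSSMProfile) -> FeatureVector:
    """Window rows of the protein's PSSM, squashed through the logistic
    1 / (1 + e^-s); rows falling outside the protein (padding) -> zeros."""
    n = fragment.window_n
    width = 2 * n + 1
    scores = profile.reordered(AA_ORDER)
    length = scores.shape[0]
    center0 = fragment.center_position - 1
    if not 0 <= center0 < length:
        raise ValueError(
            f"fragment center {fragment.center_position} outside profile "
            f"for {fragment.protein_id!r} (length {length})"
        )
    values = np.zeros(width * 20)
    names = []
    for j, pos in enumerate(_positions(width)):
        names.extend(f"pssm:{pos:+d}:{a}" for a in AA_ORDER)
        row = center0 + pos
        if 0 <= row < length:
            values[j * 20 : (j + 1) * 20] = 1.0 / (1.0 + np.exp(-scores[row]))
    return FeatureVector(names, values)


def encode_aaindex(
    fragment: Fragment, entry: AAIndexEntry, normalize: str = "zscore"
) -> FeatureVector:
    """Per-position value of one physicochemical index; X -> 0.

    With ``normalize="zscore"`` (default) the 20 index values are first
    standardized to mean 0 / sd 1 over residue types; ``"raw"`` uses the
    values as published.
    """
    if entry.has_na:
        raise ValueError(f"{entry.accession}: entry has NA values")
    if normalize not in ("zscore", "raw"):
        raise ValueError(f"unknown normalization {normalize!r}")
    vec = entry.vector(AA_ORDER)
    if normalize == "zscore":
        sd = vec.std()
        vec = (vec - vec.mean()) / sd if sd > 0 else vec - vec.mean()
    width = len(fragment.sequence)
    values = np.array([
        0.0 if aa == "X" else vec[_AA_INDEX[aa]] for aa in fragment.sequence
    ])
    names = [f"{entry.accession}:{pos:+d}" for pos in _positions(width)]
    return FeatureVector(names, values)


def encode_track(fragment: Fragment, track: ResidueTrack) -> FeatureVector:
    """ASA -> per-position percent/100 clipped to [0, 1]; SS -> per-
    position one-hot over {H, E, C}. Padding positions -> zeros."""
    if track.protein_id != fragment.protein_id:
        raise ValueError(
            f"track {track.protein_id!r} does not match fragment protein "
            f"{fragment.protein_id!r}"
        )
    n = fragment.window_n
    width = 2 * n + 1
    center0 = fragment.center_position - 1
    length = len(track.values)
    positions = _positions(width)
    if track.kind == "ASA":
        values = np.zeros(width)
        for j, pos in enumerate(positions):
            row = center0 + pos
            if 0 <= row < length:
                values[j] = min(max(track.values[row] / 100.0, 0.0), 1.0)
        names = [f"asa:{pos:+d}" for pos in positions]
    else:
        values = np.zeros(width * 3)
        names = []
        for j, pos in enumerate(positions):
            names.extend(f"ss:{pos:+d}:{s}" for s in _SS_ORDER)
            row = center0 + pos
            if 0 <= row < length:
                values[j * 3 + _SS_ORDER.index(track.values[row])] = 1.0
    return FeatureVector(names, values)


def concat_features(vectors: Sequence[FeatureVector]) -> FeatureVector:
    """Concatenate encodings into one hybrid vector; duplicate feature
    names are an error."""
    if not vectors:
        raise ValueError("cannot concatenate an empty list of vectors")
    names: list[str] = []
    for v in vectors:
        names.extend(v.names)
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate feature names after concatenation: {dupes[:5]}")
    values = np.concatenate([v.values for v in vectors])
    return FeatureVector(names, values)


# ---------------------------------------------------------------------------
# Encoder registry

Encoder = Callable[[Fragment], FeatureVector]


def make_encoder(
    name: str,
    *,
    pwm: PWMatrix | None = None,
    profiles: Mapping[str, PSSMProfile] | None = None,
    aaindex: Mapping[str, AAIndexEntry] | None = None,
    asa_tracks: Mapping[str, ResidueTrack] | None = None,
    ss_tracks: Mapping[str, ResidueTrack] | None = None,
    aaindex_normalize: str = "zscore",
) -> Encoder:
    """Resolve an encoder name into a fragment -> FeatureVector callable.

    Recognized names: ``binary``, ``aac``, ``aapc``, ``blosum62``,
    ``pwm``, ``pssm``, ``aaindex:<accession>``, ``asa``, ``ss``.
    """
    if name == "binary":
        return encode_binary
    if name == "aac":
        return encode_aac
    if name == "aapc":
        return encode_aapc
    if name == "blosum62":
        return encode_blosum62
    if name == "pwm":
        if pwm is None:
            raise ValueError("encoder 'pwm' requires a fitted PWMatrix")
        return lambda f: encode_pwm(f, pwm)
    if name == "pssm":
        if profiles is None:
            raise ValueError("encoder 'pssm' requires per-protein profiles")

        def _pssm(f: Fragment) -> FeatureVector:
            if f.protein_id not in profiles:
                raise ValueError(f"no PSSM profile for protein {f.protein_id!r}")
            return encode_pssm(f, profiles[f.protein_id])

        return _pssm
    if name.startswith("aaindex:"):
        accession = name.split(":", 1)[1]
        if aaindex is None or accession not in aaindex:
            raise ValueError(f"AAindex entry {accession!r} not available")
        entry = aaindex[accession]
        return lambda f: encode_aaindex(f, entry, normalize=aaindex_normalize)
    if name == "asa":
        if asa_tracks is None:
            raise ValueError("encoder 'asa' requires ASA tracks")

        def _asa(f: Fragment) -> FeatureVector:
            if f.protein_id not in asa_tracks:
                raise ValueError(f"no ASA track for protein {f.protein_id!r}")
            return encode_track(f, asa_tracks[f.protein_id])

        return _asa
    if name == "ss":
        if ss_tracks is None:
            raise ValueError("encoder 'ss' requires SS tracks")

        def _ss(f: Fragment) -> FeatureVector:
            if f.protein_id not in ss_tracks:
                raise ValueError(f"no SS track for protein {f.protein_id!r}")
            return encode_track(f, ss_tracks[f.protein_id])

        return _ss
    raise ValueError(f"unknown encoder {name!r}")


def encode_matrix(
    fragments: Sequence[Fragment], encoder: Encoder
) -> tuple[np.ndarray, tuple]:
    """Encode a fragment list into a dense (n_fragments, n_features)
    matrix, returning the shared feature-name tuple."""
    if not fragments:
        raise ValueError("no fragments to encode")
    first = encoder(fragments[0])
    matrix = np.empty((len(fragments), len(first)))
    matrix[0] = first.values
    for i, frag in enumerate(fragments[1:], 1):
        vec = encoder(frag)
        if vec.names != first.names:
            raise ValueError("inconsistent feature names across fragments")
        matrix[i] = vec.values
    return matrix, first.names


def write_feature_matrix(matrix: np.ndarray, names: Sequence[str], path) -> None:
    """Dense TSV with a header row of feature names."""
    with open(path, "w") as fh:
        fh.write("\t".join(names) + "\n")
        for row in matrix:
            fh.write("\t".join(f"{v:.6g}" for v in row) + "\n")
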