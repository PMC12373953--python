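"""Alignment handling, diversity statistics, chimeras and PCA projections.

The working objects are a gap-free :class:`ReferenceSequence` (for the group I
intron studied here, 197 nt), an :class:`Msa` of aligned homologs over
``ACGU-``, and gap-free :class:`SequenceSet` collections of designs. All
coordinates are 1-based reference positions once an alignment has been
projected onto the reference.
"""

from __future__ import annotations

import io
import itertools
from dataclasses import dataclass, field

import numpy as np
from Bio import AlignIO, SeqIO

from . import alphabet as ab
from .errors import FormatError, InputError, NumericalError

__all__ = [
    "ReferenceSequence",
    "Msa",
    "SequenceSet",
    "DistanceStats",
    "PcaProjection",
    "read_msa",
    "read_reference",
    "write_fasta",
    "project_to_reference",
    "distance_stats",
    "effective_nucleotides",
    "make_chimeras",
    "pca_project",
    "hamming",
]


@dataclass(frozen=True)
class ReferenceSequence:
    """A gap-free reference over ACGU; positions are numbered 1..L."""

    id: str
    residues: str

    def __post_init__(self):
        s = ab.normalize(self.residues)
        if ab.GAP in s:
            raise InputError("reference sequence may not contain gaps")
        object.__setattr__(self, "residues", s)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def codes(self) -> np.ndarray:
        return ab.encode(self.residues)


@dataclass
class Msa:
    """Aligned rows over ``ACGU-`` with per-row weights.

    ``column_map`` (optional) gives, for each reference position (0-based
    internally), the alignment column it occupies; it is strictly increasing.
    """

    rows: list[str]
    ids: list[str]
    weights: np.ndarray = None
    column_map: np.ndarray | None = None

    def __post_init__(self):
        if not self.rows:
            raise InputError("empty alignment")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise FormatError("alignment rows have unequal lengths")
        self.rows = [ab.normalize(r) for r in self.rows]
        if self.weights is None:
            self.weights = np.ones(len(self.rows))
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights <= 0):
            raise InputError("row weights must be positive")
        if self.column_map is not None:
            cm = np.asarray(self.column_map)
            if np.any(np.diff(cm) <= 0):
                raise InputError("column_map must be strictly increasing")
            self.column_map = cm

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def width(self) -> int:
        return len(self.rows[0])

    @property
    def codes(self) -> np.ndarray:
        return ab.encode_rows(self.rows, allow_gap=True)


@dataclass
class SequenceSet:
    """Gap-free sequences of uniform length, with a model label each."""

    sequences: list[str]
    labels: list[str] = None

    def __post_init__(self):
        if not self.sequences:
            raise InputError("empty sequence set")
        self.sequences = [ab.normalize(s) for s in self.sequences]
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise InputError("sequence set has unequal lengths")
        if any(ab.GAP in s for s in self.sequences):
            raise InputError("sequence sets are gap-free")
        if self.labels is None:
            self.labels = [""] * len(self.sequences)
        if len(self.labels) != len(self.sequences):
            raise InputError("labels/sequences length mismatch")

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def codes(self) -> np.ndarray:
        return ab.encode_rows(self.sequences, allow_gap=False)


def hamming(a: str | np.ndarray, b: str | np.ndarray) -> int:
    """Hamming distance between two equal-length sequences."""
    ca = ab.encode(a, allow_gap=True) if isinstance(a, str) else np.asarray(a)
    cb = ab.encode(b, allow_gap=True) if isinstance(b, str) else np.asarray(b)
    if ca.shape != cb.shape:
        raise InputError("length mismatch in Hamming distance")
    return int(np.count_nonzero(ca != cb))


# ---------------------------------------------------------------------------
# I/O


def read_msa(path, format: str = "fasta") -> Msa:
    """Read a Stockholm or aligned-FASTA alignment.

    Symbols are uppercased, T is mapped to U, and both ``.`` and ``-`` are
    read as gaps. Row weights are initialized to 1.
    """
    if format not in ("fasta", "stockholm"):
        raise InputError(f"unknown alignment format {format!r}")
    try:
        aln = AlignIO.read(str(path), format)
    except ValueError as exc:
        msg = str(exc)
        if "No records" in msg or "Empty file" in msg.lower():
            raise InputError(f"no alignment records in {path}") from exc
        raise FormatError(f"cannot parse {path} as {format}: {exc}") from exc
    rows = [str(rec.seq) for rec in aln]
    ids = [rec.id for rec in aln]
    if not rows:
        raise InputError(f"no alignment records in {path}")
    return Msa(rows=rows, ids=ids)


def read_reference(path) -> ReferenceSequence:
    """Read a single-record FASTA reference sequence."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise InputError(f"expected exactly one record in {path}, got {len(records)}")
    return ReferenceSequence(id=records[0].id, residues=str(records[0].seq))


def write_fasta(seqs: SequenceSet, path, ids: list[str] | None = None) -> None:
    if ids is None:
        ids = [f"seq{i}" for i in range(len(seqs))]
    with open(path, "w") as fh:
        for name, seq in zip(ids, seqs.sequences):
            fh.write(f">{name}\n{seq}\n")


# ---------------------------------------------------------------------------
# Operations


def project_to_reference(
    msa: Msa, ref: ReferenceSequence, column_map: np.ndarray | None = None
) -> Msa:
    """Restrict an alignment to the columns occupied by the reference.

    Insertions relative to the reference are dropped, so column *i* of the
    result corresponds to reference position *i* (1-based externally). The
    reference row is located by exact match after degapping unless an explicit
    ``column_map`` is supplied. Idempotent on already-projected alignments.
    """
    if column_map is None:
        target = ref.residues
        for row in msa.rows:
            if row.replace(ab.GAP, "") == target:
                column_map = np.flatnonzero(
                    np.array(list(row)) != ab.GAP
                )
                break
        else:
            raise InputError(
                "no alignment row matches the reference after degapping "
                "and no column_map was supplied"
            )
    column_map = np.asarray(column_map)
    if column_map.size != len(ref):
        raise InputError(
            f"column_map covers {column_map.size} positions, reference has {len(ref)}"
        )
    rows = ["".join(r[c] for c in column_map) for r in msa.rows]
    return Msa(
        rows=rows,
        ids=list(msa.ids),
        weights=msa.weights.copy(),
        column_map=np.arange(len(ref)),
    )


@dataclass
class DistanceStats:
    """Summary of Hamming distances, either within a set or set-to-set."""

    distances: np.ndarray  # pairwise (within) or per-sequence minima (to b)
    mean: float
    max: int
    histogram: np.ndarray  # counts indexed by distance 0..max

    @classmethod
    def from_distances(cls, d: np.ndarray) -> "DistanceStats":
        d = np.asarray(d, dtype=int)
        hist = np.bincount(d) if d.size else np.zeros(1, dtype=int)
        return cls(
            distances=d,
            mean=float(d.mean()) if d.size else float("nan"),
            max=int(d.max()) if d.size else 0,
            histogram=hist,
        )


def distance_stats(a: SequenceSet, b: SequenceSet | None = None) -> DistanceStats:
    """Hamming-distance summary.

    With ``b`` omitted: all unordered within-set pairs of ``a`` (no
    self-pairs). With ``b``: per sequence of ``a``, the minimum distance to
    any member of ``b``.
    """
    ca = a.codes
    if b is None:
        n = len(a)
        d = np.array(
            [
                np.count_nonzero(ca[i] != ca[j])
                for i, j in itertools.combinations(range(n), 2)
            ],
            dtype=int,
        )
        return DistanceStats.from_distances(d)
    cb = b.codes
    if ca.shape[1] != cb.shape[1]:
        raise InputError("sequence sets have different lengths")
    # (na, nb) distance matrix in blocks to bound memory
    mins = np.empty(len(a), dtype=int)
    for i in range(len(a)):
        mins[i] = int((ca[i][None, :] != cb).sum(axis=1).min())
    return DistanceStats.from_distances(mins)


def effective_nucleotides(s: SequenceSet | Msa) -> np.ndarray:
    """Per-position effective alphabet size exp(H_i).

    H_i is the Shannon entropy of the observed symbol frequencies at position
    i; for an :class:`Msa` the gap counts as a fifth symbol. Values lie in
    [1, q] and reach q only for a uniform column.
    """
    codes = s.codes
    q = ab.Q_GAPPED if isinstance(s, Msa) else ab.Q_RNA
    n, L = codes.shape
    out = np.empty(L)
    for i in range(L):
        counts = np.bincount(codes[:, i], minlength=q).astype(float)
        f = counts / counts.sum()
        nz = f[f > 0]
        out[i] = float(np.exp(-(nz * np.log(nz)).sum()))
    return out


def make_chimeras(
    msa: Msa,
    ref: ReferenceSequence,
    distance_plan: list[int],
    seed: int,
    n: int = 1,
) -> SequenceSet:
    """Build fixed-length chimeric variants of the reference.

    For each target load *k* in ``distance_plan`` (``n`` chimeras per load),
    *k* positions are chosen uniformly among the positions where the projected
    alignment shows at least one non-reference nucleotide, and each is
    substituted by a draw from that column's non-reference, non-gap frequency
    distribution (weighted by row weights). Every output is therefore at
    Hamming distance exactly *k* from the reference.
    """
    if msa.width != len(ref):
        raise InputError("msa must be reference-projected before making chimeras")
    codes = msa.codes
    w = msa.weights
    L = len(ref)
    refc = ref.codes
    # per-column weighted counts over ACGU, reference nucleotide and gap excluded
    donor = np.zeros((L, ab.Q_RNA))
    for i in range(L):
        for a in range(ab.Q_RNA):
            if a == refc[i]:
                continue
            donor[i, a] = w[codes[:, i] == a].sum()
    polymorphic = np.flatnonzero(donor.sum(axis=1) > 0)
    rng = np.random.default_rng(seed)
    seqs, labels = [], []
    for k in distance_plan:
        if k > polymorphic.size:
            raise InputError(
                f"load {k} exceeds the {polymorphic.size} polymorphic positions"
            )
        for _ in range(n):
            out = refc.copy()
            pos = rng.choice(polymorphic, size=k, replace=False)
            for i in pos:
                p = donor[i] / donor[i].sum()
                out[i] = rng.choice(ab.Q_RNA, p=p)
            seqs.append(ab.decode(out))
            labels.append("CHI")
    return SequenceSet(sequences=seqs, labels=labels)


@dataclass
class PcaProjection:
    """2-D coordinates from a one-hot PCA computed on a basis set."""

    coords: np.ndarray  # (n, 2)
    explained_variance: np.ndarray  # leading eigenvalues of the basis covariance
    ref_coords: np.ndarray | None = None  # projection of the reference, if given


def _one_hot(codes: np.ndarray) -> np.ndarray:
    n, L = codes.shape
    X = np.zeros((n, L * ab.Q_RNA))
    rows = np.repeat(np.arange(n), L)
    cols = (np.tile(np.arange(L), n) * ab.Q_RNA + codes.ravel()).astype(int)
    X[rows, cols] = 1.0
    return X


def pca_project(
    target: SequenceSet,
    basis: SequenceSet,
    ref: ReferenceSequence | None = None,
) -> PcaProjection:
    """Project sequences on the first two principal axes of a basis set.

    Sequences are one-hot encoded (4 indicators per position); axes are the
    leading eigenvectors of the basis covariance; the target is centered on
    the basis mean. When a reference is given, coordinates are translated so
    the reference maps to the origin.
    """
    if len({len(basis.sequences[0]), len(target.sequences[0])}) != 1:
        raise InputError("target and basis must have equal sequence length")
    if len(set(basis.sequences)) < 2:
        raise NumericalError("degenerate PCA basis: all sequences identical")
    Xb = _one_hot(basis.codes)
    mean = Xb.mean(axis=0)
    Xb = Xb - mean
    try:
        _, svals, vt = np.linalg.svd(Xb, full_matrices=False)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - numpy internal
        raise NumericalError(f"SVD failed on PCA basis: {exc}") from exc
    axes = vt[:2]  # (2, 4L); a rank-1 basis gives ~0 second coordinates
    coords = (_one_hot(target.codes) - mean) @ axes.T
    ref_coords = None
    if ref is not None:
        ref_coords = (_one_hot(ref.codes[None, :]) - mean) @ axes.T
        coords = coords - ref_coords
        ref_coords = np.zeros(2)
    ev = (svals**2) / max(len(basis) - 1, 1)
    return PcaProjection(coords=coords, explained_variance=ev[:2], ref_coords=ref_coords)
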