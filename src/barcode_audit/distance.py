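"""Kimura 2-parameter distances under pairwise deletion.

The K2P model corrects observed divergence with separate rates for
transitions (A<->G, C<->T) and transversions (all other changes):

    d = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))

where P and Q are the proportions of sites differing by a transition and
a transversion, computed over the sites where *both* sequences carry an
unambiguous A/C/G/T ("pairwise deletion": gaps, N and IUPAC ambiguity
codes are excluded per pair). At extreme divergence the logarithm's
argument can become non-positive; such pairs are reported as *undefined*
rather than clamped, so saturation cannot silently corrupt
maximum-distance summaries.

Distances are stored as proportions (0.1 = 10%); report writers format
them as percentages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .library import BarcodeLibrary

#: default minimum number of comparable sites for a defined distance
DEFAULT_MIN_OVERLAP = 100

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}  # A,G even (purines); C,T odd


def encode_sequences(seqs) -> np.ndarray:
    """Encode sequences as an int8 matrix: A=0 C=1 G=2 T=3, missing=-1."""
    seq_list = list(seqs)
    if not seq_list:
        return np.empty((0, 0), dtype=np.int8)
    lengths = {len(s) for s in seq_list}
    if len(lengths) != 1:
        raise ValueError("sequences must be equal length (aligned)")
    lut = np.full(256, -1, dtype=np.int8)
    for ch, v in _CODE.items():
        lut[ord(ch)] = v
        lut[ord(ch.lower())] = v
    arr = np.frombuffer(
        "".join(seq_list).encode("ascii"), dtype=np.uint8
    ).reshape(len(seq_list), -1)
    return lut[arr]


@dataclass(frozen=True)
class PairComparison:
    """Site counts for one sequence pair under pairwise deletion."""

    comparable_sites: int
    transitions: int
    transversions: int

    @property
    def P(self) -> float:
        return self.transitions / self.comparable_sites if self.comparable_sites else float("nan")

    @property
    def Q(self) -> float:
        return self.transversions / self.comparable_sites if self.comparable_sites else float("nan")


def k2p_from_pq(P: float, Q: float) -> float:
    """Closed-form K2P distance; NaN when the correction is undefined."""
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        return float("nan")
    return -0.5 * float(np.log(w1 * np.sqrt(w2))) + 0.0


def compare_pair(seq_a: str, seq_b: str) -> PairComparison:
    """Count comparable sites, transitions and transversions for one pair."""
    a, b = encode_sequences([seq_a, seq_b])
    valid = (a >= 0) & (b >= 0)
    diff = valid & (a != b)
    ts = diff & ((a & 1) == (b & 1))
    return PairComparison(
        comparable_sites=int(valid.sum()),
        transitions=int(ts.sum()),
        transversions=int((diff & ~ts).sum()),
    )


def k2p_distance(
    seq_a: str, seq_b: str, min_overlap: int = DEFAULT_MIN_OVERLAP
) -> tuple[float, PairComparison]:
    """K2P distance for one aligned pair.

    Returns ``(distance, PairComparison)``; distance is NaN when fewer
    than ``min_overlap`` comparable sites remain or the K2P correction is
    undefined.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must be equal length (aligned)")
    cmp = compare_pair(seq_a, seq_b)
    if cmp.comparable_sites < min_overlap:
        return float("nan"), cmp
    return k2p_from_pq(cmp.P, cmp.Q), cmp


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric K2P distance matrix with per-pair comparable-site counts.

    ``d`` holds proportions with NaN marking undefined pairs; the
    diagonal is zero by construction.
    """

    ids: tuple[str, ...]
    d: np.ndarray
    sites: np.ndarray
    species: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "ids", tuple(self.ids))
        object.__setattr__(self, "species", tuple(self.species))
        n = len(self.ids)
        if self.d.shape != (n, n) or self.sites.shape != (n, n):
            raise ValueError("matrix shape does not match number of ids")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def undefined_pairs(self) -> list[tuple[str, str]]:
        iu, ju = np.triu_indices(len(self), 1)
        mask = np.isnan(self.d[iu, ju])
        return [(self.ids[a], self.ids[b]) for a, b in zip(iu[mask], ju[mask])]

    def condensed(self, drop_undefined: bool = True) -> np.ndarray:
        """Upper-triangle distances as a 1-D array (NaN dropped by default)."""
        iu, ju = np.triu_indices(len(self), 1)
        vals = self.d[iu, ju]
        return vals[~np.isnan(vals)] if drop_undefined else vals

    def index_of(self, specimen_id: str) -> int:
        return self.ids.index(specimen_id)

    def submatrix(self, specimen_ids) -> "DistanceMatrix":
        idx = np.array([self.index_of(s) for s in specimen_ids])
        return DistanceMatrix(
            ids=tuple(self.ids[i] for i in idx),
            d=self.d[np.ix_(idx, idx)].copy(),
            sites=self.sites[np.ix_(idx, idx)].copy(),
            species=tuple(self.species[i] for i in idx) if self.species else (),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=list(self.ids), columns=list(self.ids))


def _pair_counts(X: np.ndarray):
    """Vectorized per-pair site counts: returns (L, ts, tv) full matrices."""
    n = X.shape[0]
    L = np.zeros((n, n), dtype=np.int32)
    TS = np.zeros((n, n), dtype=np.int32)
    TV = np.zeros((n, n), dtype=np.int32)
    present = X >= 0
    parity = X & 1
    for i in range(n - 1):
        valid = present[i] & present[i + 1 :]
        diff = valid & (X[i] != X[i + 1 :])
        ts = diff & (parity[i] == parity[i + 1 :])
        L[i, i + 1 :] = valid.sum(axis=1)
        TS[i, i + 1 :] = ts.sum(axis=1)
        TV[i, i + 1 :] = (diff & ~ts).sum(axis=1)
    L += L.T
    TS += TS.T
    TV += TV.T
    np.fill_diagonal(L, present.sum(axis=1))
    return L, TS, TV


def pairwise_matrix(
    library: BarcodeLibrary,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    strict: bool = False,
) -> DistanceMatrix:
    """All-against-all K2P matrix for an aligned library.

    Undefined pairs (insufficient overlap or saturated correction) are
    NaN; with ``strict=True`` any undefined pair raises instead.
    """
    library.require_aligned("pairwise distance computation")
    if len(library) < 2:
        raise ValueError("distance analysis needs at least 2 records")
    X = encode_sequences(r.sequence for r in library)
    L, TS, TV = _pair_counts(X)

    with np.errstate(divide="ignore", invalid="ignore"):
        Lf = L.astype(float)
        P = np.where(L > 0, TS / np.maximum(Lf, 1), np.nan)
        Q = np.where(L > 0, TV / np.maximum(Lf, 1), np.nan)
        w1 = 1.0 - 2.0 * P - Q
        w2 = 1.0 - 2.0 * Q
        d = np.where((w1 > 0) & (w2 > 0), -0.5 * np.log(w1 * np.sqrt(np.abs(w2))), np.nan)
    d = d + 0.0  # normalize -0.0 from log(1)
    d[L < min_overlap] = np.nan
    np.fill_diagonal(d, 0.0)

    dm = DistanceMatrix(
        ids=tuple(library.ids),
        d=d,
        sites=L,
        species=tuple(library.species_labels),
    )
    if strict and len(dm.undefined_pairs) > 0:
        first = dm.undefined_pairs[0]
        raise ValueError(
            f"{len(dm.undefined_pairs)} undefined pair(s) in strict mode, "
            f"first: {first[0]} vs {first[1]}"
        )
    return dm


def base_composition(library: BarcodeLibrary) -> dict[str, float]:
    """Mean per-record base frequencies over unambiguous A/C/G/T sites.

    Per-record frequencies are averaged unweighted across records, so a
    long and a short barcode contribute equally (the convention used by
    barcode-workbench composition summaries). Records with no unambiguous
    site are excluded.
    """
    if len(library) == 0:
        raise ValueError("empty library")
    per_record = []
    for rec in library:
        counts = np.array([rec.sequence.count(b) for b in "ACGT"], dtype=float)
        total = counts.sum()
        if total == 0:
            continue
        per_record.append(counts / total)
    if not per_record:
        raise ValueError("no record has unambiguous sites")
    mean = np.mean(per_record, axis=0)
    return dict(zip("ACGT", mean.tolist()))


# ---------------------------------------------------------------------------
# matrix IO


def write_matrix_tsv(dm: DistanceMatrix, sink) -> None:
    """Square TSV with specimen IDs as header and index (proportions)."""
    dm.to_dataframe().to_csv(sink, sep="\t", float_format="%.10g")


def read_matrix_tsv(source, library: BarcodeLibrary | None = None) -> DistanceMatrix:
    df = pd.read_csv(source, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if list(df.index) != list(df.columns):
        raise ValueError("matrix TSV rows and columns disagree")
    species: tuple[str, ...] = ()
    if library is not None:
        sp = dict(zip(library.ids, library.species_labels))
        missing = [i for i in df.index if i not in sp]
        if missing:
            raise ValueError(f"matrix IDs absent from library: {missing[:5]}")
        species = tuple(sp[i] for i in df.index)
    d = df.to_numpy(dtype=float)
    return DistanceMatrix(
        ids=tuple(df.index),
        d=d,
        sites=np.zeros_like(d, dtype=np.int32),
        species=species,
    )


def write_matrix_phylip(dm: DistanceMatrix, sink) -> None:
    """PHYLIP-style lower-triangle matrix (undefined pairs as NA)."""
    close = False
    if isinstance(sink, str):
        sink = open(sink, "w")
        close = True
    try:
        sink.write(f"{len(dm)}\n")
        for i, name in enumerate(dm.ids):
            cells = []
            for j in range(i):
                v = dm.d[i, j]
                cells.append("NA" if np.isnan(v) else f"{v:.8f}")
            sink.write("\t".join([name, *cells]) + "\n")
    finally:
        if close:
            sink.close()
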