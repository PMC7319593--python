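"""PSSM-derived and sequence-based feature encoders.

Six encoders turn a protein (sequence + PSSM) into fixed-dimension
descriptors:

================  ====  =======================================================
encoder           dim   description
================  ====  =======================================================
AAC                 20  amino-acid composition (residue frequencies)
DPC                400  dipeptide composition (ordered pair frequencies)
PSSM_COMP          400  PSSM rows summed and length-averaged per residue type
DPC_PSSM           400  adjacent-row cross-products of PSSM columns
PSSM_AC         20*LG   per-column autocovariance at lags 1..LG (default 200)
RPSSM              110  squared adjacent-row differences and column variances
                        on a 10-column physicochemically reduced PSSM
================  ====  =======================================================

All PSSM encoders operate on the canonical (alphabetical) column order
and compute in double precision. Formulas, written for a protein of
length L with PSSM P (1-based indices):

* PSSM_COMP row i:  R_i = (1/L) * sum_k r_k * delta_k, where delta_k = 1
  iff sequence residue p_k is amino-acid type a_i. The 20x20 matrix is
  flattened row by row.
* DPC_PSSM:  y[i,j] = (1/(L-1)) * sum_{k=1..L-1} P[k,i] * P[k+1,j],
  flattened as (y[1,1], ..., y[1,20], y[2,1], ..., y[20,20]).
* PSSM_AC(j, lg) = sum_{i=1..L-lg} (P[i,j]-mean_j)(P[i+lg,j]-mean_j)/(L-lg),
  ordered column-major: residue column j outer, lag lg = 1..LG inner.
* RPSSM: the 20 columns are merged into 10 groups
  (FYW, ML, IV, ATS, NH, QED, RK, C, G, P) by averaging; then
  D[s,t] = (1/(L-1)) * sum_i (p[i,s]-p[i+1,t])^2 / 2  and
  D[s]   = (1/L) * sum_i (p[i,s]-mean_s)^2,
  concatenated as [D[1,1], D[1,2], ..., D[10,10], D[1], ..., D[10]].
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io import AA_ORDER, InputError, ProteinRecord, PSSMatrix

__all__ = [
    "EVOLUTIONARY_ENCODERS",
    "ALL_ENCODERS",
    "EncoderConfig",
    "FeatureVector",
    "ReducedPSSM",
    "encoder_dimension",
    "aac",
    "dpc",
    "pssm_composition",
    "dpc_pssm",
    "pssm_ac",
    "reduce_pssm",
    "rpssm",
    "encode_all",
    "write_feature_table",
    "read_feature_table",
]

#: The four evolutionary encoders used by the ensemble model, in the
#: fixed order they are trained and averaged.
EVOLUTIONARY_ENCODERS = ("PSSM_COMP", "DPC_PSSM", "PSSM_AC", "RPSSM")

#: All encoders, including the two sequence-based baselines.
ALL_ENCODERS = ("AAC", "DPC") + EVOLUTIONARY_ENCODERS

#: Column-merge groups defining the reduced PSSM, in output order.
RPSSM_GROUPS = ("FYW", "ML", "IV", "ATS", "NH", "QED", "RK", "C", "G", "P")

_AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}


@dataclass(frozen=True)
class EncoderConfig:
    """Tunable encoder settings.

    lag:
        Maximum autocovariance lag LG for PSSM_AC. The default 10 gives
        a 200-dimensional vector and requires L > 10 (guaranteed by the
        length-50 dataset filter).
    pssm_rescale:
        When True, scores are passed through the logistic function
        1/(1+exp(-x)) before encoding. Default off: the descriptor
        formulas consume the raw log-odds scores.
    """

    lag: int = 10
    pssm_rescale: bool = False

    def __post_init__(self) -> None:
        if self.lag < 1:
            raise InputError("PSSM_AC lag must be >= 1")


@dataclass(frozen=True)
class FeatureVector:
    """A named fixed-dimension encoding of one protein."""

    protein_id: str
    encoder: str
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 1:
            raise InputError("feature values must be a flat vector")
        if not np.all(np.isfinite(values)):
            raise InputError(
                f"non-finite feature values for {self.protein_id!r} ({self.encoder})"
            )
        object.__setattr__(self, "values", values)

    @property
    def dimension(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class ReducedPSSM:
    """L x 10 matrix obtained by merging PSSM columns into residue groups."""

    protein_id: str
    scores: np.ndarray

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=np.float64)
        if scores.ndim != 2 or scores.shape[1] != 10:
            raise InputError(f"reduced PSSM must be L x 10, got {scores.shape}")
        object.__setattr__(self, "scores", scores)


def encoder_dimension(encoder: str, config: EncoderConfig | None = None) -> int:
    """The fixed output dimension of ``encoder`` under ``config``."""
    config = config or EncoderConfig()
    dims = {
        "AAC": 20,
        "DPC": 400,
        "PSSM_COMP": 400,
        "DPC_PSSM": 400,
        "PSSM_AC": 20 * config.lag,
        "RPSSM": 110,
    }
    if encoder not in dims:
        raise InputError(f"unknown encoder {encoder!r}")
    return dims[encoder]


def _pssm_values(pssm: PSSMatrix, config: EncoderConfig) -> np.ndarray:
    P = pssm.canonical_scores()
    if config.pssm_rescale:
        P = 1.0 / (1.0 + np.exp(-P))
    return P


# ---------------------------------------------------------------------------
# Sequence-based baselines


def aac(record: ProteinRecord) -> FeatureVector:
    """Amino-acid composition: residue counts divided by sequence length."""
    L = len(record)
    counts = np.zeros(20)
    for res in record.sequence:
        idx = _AA_INDEX.get(res)
        if idx is not None:  # masked nonstandard residues contribute nothing
            counts[idx] += 1
    return FeatureVector(record.id, "AAC", counts / L)


def dpc(record: ProteinRecord) -> FeatureVector:
    """Dipeptide composition: ordered-pair counts divided by L-1."""
    L = len(record)
    if L < 2:
        raise InputError(f"DPC requires length >= 2, got {L} for {record.id!r}")
    counts = np.zeros((20, 20))
    seq = record.sequence
    for k in range(L - 1):
        i = _AA_INDEX.get(seq[k])
        j = _AA_INDEX.get(seq[k + 1])
        if i is not None and j is not None:
            counts[i, j] += 1
    return FeatureVector(record.id, "DPC", counts.ravel() / (L - 1))


# ---------------------------------------------------------------------------
# PSSM-derived encoders


def pssm_composition(
    pssm: PSSMatrix, config: EncoderConfig | None = None
) -> FeatureVector:
    """Sum PSSM rows per residue type, average by L, flatten row-major."""
    config = config or EncoderConfig()
    P = _pssm_values(pssm, config)
    L = len(pssm)
    if L == 0:
        raise InputError(f"empty PSSM for {pssm.protein_id!r}")
    R = np.zeros((20, 20))
    for k, res in enumerate(pssm.row_residues):
        i = _AA_INDEX.get(res)
        if i is not None:
            R[i] += P[k]
    return FeatureVector(pssm.protein_id, "PSSM_COMP", R.ravel() / L)


def dpc_pssm(pssm: PSSMatrix, config: EncoderConfig | None = None) -> FeatureVector:
    """Adjacent-row column cross-products y[i,j], averaged over L-1 pairs."""
    config = config or EncoderConfig()
    P = _pssm_values(pssm, config)
    L = len(pssm)
    if L < 2:
        raise InputError(f"DPC_PSSM requires L >= 2, got {L} for {pssm.protein_id!r}")
    Y = P[:-1].T @ P[1:] / (L - 1)
    return FeatureVector(pssm.protein_id, "DPC_PSSM", Y.ravel())


def pssm_ac(pssm: PSSMatrix, config: EncoderConfig | None = None) -> FeatureVector:
    """Column autocovariance at lags 1..LG, mean-centred per column.

    Output ordering is column-major: all LG lags of column 1, then all
    LG lags of column 2, and so on.
    """
    config = config or EncoderConfig()
    P = _pssm_values(pssm, config)
    L = len(pssm)
    LG = config.lag
    if L <= LG:
        raise InputError(
            f"PSSM_AC requires L > LG: L={L}, LG={LG} for {pssm.protein_id!r}"
        )
    centred = P - P.mean(axis=0)
    out = np.empty((20, LG))
    for lg in range(1, LG + 1):
        out[:, lg - 1] = (centred[: L - lg] * centred[lg:]).sum(axis=0) / (L - lg)
    return FeatureVector(pssm.protein_id, "PSSM_AC", out.ravel())


def reduce_pssm(pssm: PSSMatrix, config: EncoderConfig | None = None) -> ReducedPSSM:
    """Merge the 20 PSSM columns into 10 physicochemical groups by averaging.

    Group order: FYW, ML, IV, ATS, NH, QED, RK, C, G, P.
    """
    config = config or EncoderConfig()
    P = _pssm_values(pssm, config)
    cols = np.empty((len(pssm), 10))
    for g, group in enumerate(RPSSM_GROUPS):
        idx = [_AA_INDEX[a] for a in group]
        cols[:, g] = P[:, idx].mean(axis=1)
    return ReducedPSSM(pssm.protein_id, cols)


def rpssm(pssm: PSSMatrix, config: EncoderConfig | None = None) -> FeatureVector:
    """Reduced-PSSM descriptor: 100 adjacent-row terms plus 10 variances."""
    config = config or EncoderConfig()
    reduced = reduce_pssm(pssm, config).scores
    L = reduced.shape[0]
    if L < 2:
        raise InputError(f"RPSSM requires L >= 2, got {L} for {pssm.protein_id!r}")
    # D[s,t]: mean over adjacent row pairs of (p[i,s]-p[i+1,t])^2 / 2
    diffs = reduced[:-1, :, None] - reduced[1:, None, :]
    D_st = (diffs**2).sum(axis=0) / (2.0 * (L - 1))
    # D[s]: population variance of each reduced column
    D_s = ((reduced - reduced.mean(axis=0)) ** 2).sum(axis=0) / L
    return FeatureVector(pssm.protein_id, "RPSSM", np.concatenate([D_st.ravel(), D_s]))


_ENCODER_FUNCS = {
    "AAC": lambda rec, pssm, cfg: aac(rec),
    "DPC": lambda rec, pssm, cfg: dpc(rec),
    "PSSM_COMP": lambda rec, pssm, cfg: pssm_composition(pssm, cfg),
    "DPC_PSSM": lambda rec, pssm, cfg: dpc_pssm(pssm, cfg),
    "PSSM_AC": lambda rec, pssm, cfg: pssm_ac(pssm, cfg),
    "RPSSM": lambda rec, pssm, cfg: rpssm(pssm, cfg),
}


def encode_all(
    pssm: PSSMatrix,
    record: ProteinRecord,
    config: EncoderConfig | None = None,
    encoders: Sequence[str] = EVOLUTIONARY_ENCODERS,
) -> dict[str, FeatureVector]:
    """Encode one record/PSSM pair with the requested encoders.

    By default returns the four evolutionary descriptors used by the
    ensemble model; pass ``encoders=ALL_ENCODERS`` to add the AAC and
    DPC baselines. The record and matrix must be a verified pair.
    """
    config = config or EncoderConfig()
    pssm.check_pairing(record)
    out: dict[str, FeatureVector] = {}
    for name in encoders:
        if name not in _ENCODER_FUNCS:
            raise InputError(f"unknown encoder {name!r}")
        out[name] = _ENCODER_FUNCS[name](record, pssm, config)
    return out


# ---------------------------------------------------------------------------
# Feature table I/O


def write_feature_table(
    vectors: Iterable[FeatureVector], path: str | Path, header_lines: Sequence[str] = ()
) -> None:
    """Write feature vectors as TSV: protein_id, encoder, then values.

    Floats are serialized with 17 significant digits so a read-back
    restores them bit-identically.
    """
    with Path(path).open("w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        for vec in vectors:
            vals = "\t".join(f"{v:.17g}" for v in vec.values)
            fh.write(f"{vec.protein_id}\t{vec.encoder}\t{vals}\n")


def read_feature_table(path: str | Path) -> list[FeatureVector]:
    """Read back a table written by :func:`write_feature_table`."""
    vectors: list[FeatureVector] = []
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise InputError(f"{path}: malformed feature row at line {lineno}")
            vectors.append(
                FeatureVector(
                    parts[0], parts[1], np.array([float(v) for v in parts[2:]])
                )
            )
    return vectors


def feature_matrix(
    vectors: Mapping[str, FeatureVector] | Sequence[FeatureVector],
) -> np.ndarray:
    """Stack feature vectors (same encoder) into a 2-D design matrix."""
    if isinstance(vectors, Mapping):
        vectors = list(vectors.values())
    encoders = {v.encoder for v in vectors}
    if len(encoders) != 1:
        raise InputError(f"cannot stack mixed encoders: {sorted(encoders)}")
    return np.vstack([v.values for v in vectors])
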