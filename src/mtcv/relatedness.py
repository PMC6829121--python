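"""Genomic relationship matrices (GRMs): loading, synthesis, validation, partitioning.

A GRM ``K`` encodes the additive-genetic covariance structure among lines.
Cross-validation partitions it into a testing ("n", new) block and a training
("o", old) block::

    K = [[Knn, Kno],
         [Kon, Koo]]

The conditional (Schur-complement) blocks derived from this partition drive
both the GBLUP predictors and the bias correction for naive cross-validation:
``projection = Kno @ inv(Koo)`` maps training genetic values onto test lines,
and ``schur = Knn - Kno @ inv(Koo) @ Kon`` is the conditional genetic
covariance of the test lines given the training lines.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg

logger = logging.getLogger(__name__)

#: maximum asymmetry tolerated when reading a GRM from disk (averaged away below this)
SYMMETRY_TOL = 1e-6
#: default eigenvalue floor used when jittering a GRM to positive definiteness
DEFAULT_MIN_EIG = 1e-8


class GRMError(ValueError):
    """Base class for GRM problems."""


class GRMFormatError(GRMError):
    """The file (or array) does not have the shape/layout of a dense GRM."""


class GRMParseError(GRMError):
    """A cell of the GRM file could not be parsed as a number."""


class GRMValidationError(GRMError):
    """The matrix violates a GRM invariant (symmetry, positive diagonal, ...)."""


@dataclass(frozen=True)
class GRM:
    """A genomic relationship matrix with ordered line identifiers.

    Invariants enforced at construction: square, ids match dimension,
    symmetric within 1e-8, strictly positive diagonal. Positive definiteness
    is *not* enforced here; apply :func:`ensure_positive_definite` when a
    factorization is needed.
    """

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise GRMFormatError(f"GRM must be square, got shape {v.shape}")
        if len(self.ids) != v.shape[0]:
            raise GRMValidationError(
                f"{len(self.ids)} ids for a {v.shape[0]}x{v.shape[1]} matrix"
            )
        if len(set(self.ids)) != len(self.ids):
            raise GRMValidationError("duplicate line ids")
        asym = float(np.max(np.abs(v - v.T))) if v.size else 0.0
        if asym > 1e-8:
            raise GRMValidationError(f"GRM not symmetric (max asymmetry {asym:.3g})")
        if v.size and np.min(np.diag(v)) <= 0:
            raise GRMValidationError("GRM diagonal entries must be strictly positive")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "ids", tuple(str(i) for i in self.ids))

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, ids: Sequence[str]) -> np.ndarray:
        """Positions of ``ids`` in this GRM's ordering."""
        lookup = {lid: i for i, lid in enumerate(self.ids)}
        try:
            return np.array([lookup[str(i)] for i in ids], dtype=int)
        except KeyError as e:  # pragma: no cover - defensive
            raise GRMValidationError(f"unknown line id {e.args[0]!r}") from None


@dataclass(frozen=True)
class Partition:
    """Disjoint test ("n"), train ("o") and optional surrogate ("x") id sets.

    ``surrogate_ids`` (used by the nearest-relative CV2* design) is aligned
    with ``test_ids``: ``surrogate_ids[k]`` is the designated close relative
    of ``test_ids[k]``.
    """

    test_ids: tuple[str, ...]
    train_ids: tuple[str, ...]
    surrogate_ids: tuple[str, ...] | None = None

    def __post_init__(self):
        test = tuple(str(i) for i in self.test_ids)
        train = tuple(str(i) for i in self.train_ids)
        surr = None if self.surrogate_ids is None else tuple(str(i) for i in self.surrogate_ids)
        if not test or not train:
            raise GRMValidationError("train and test sets must be non-empty")
        groups = [set(test), set(train)] + ([set(surr)] if surr else [])
        total = sum(len(g) for g in groups)
        if len(set().union(*groups)) != total:
            raise GRMValidationError("partition sets must be disjoint")
        if surr is not None and len(surr) != len(test):
            raise GRMValidationError("surrogate set must match test set size")
        object.__setattr__(self, "test_ids", test)
        object.__setattr__(self, "train_ids", train)
        object.__setattr__(self, "surrogate_ids", surr)

    @property
    def n_test(self) -> int:
        return len(self.test_ids)

    @property
    def n_train(self) -> int:
        return len(self.train_ids)


@dataclass(frozen=True)
class ConditionalBlocks:
    """Conditional covariance machinery for a partitioned GRM.

    ``projection = Kno @ inv(Koo)`` and ``schur = Knn - Kno @ inv(Koo) @ Kon``.
    Rows/columns follow the order of ``Partition.test_ids``.
    """

    projection: np.ndarray
    schur: np.ndarray


def load_grm(path: str | Path, format: str = "dense_delimited") -> GRM:
    """Read a dense delimited GRM (first row and column are line ids).

    Comma or tab delimited; the delimiter is sniffed. Mild asymmetry
    (< ``SYMMETRY_TOL``) is averaged away; worse asymmetry is an error.
    """
    if format != "dense_delimited":
        raise GRMFormatError(f"unsupported GRM format {format!r}")
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    delimiter = "," if header.count(",") >= header.count("\t") else "\t"
    try:
        # round_trip parsing keeps the writer->reader cycle bit-identical
        df = pd.read_csv(path, sep=delimiter, index_col=0,
                         float_precision="round_trip")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as e:
        raise GRMFormatError(f"could not parse {path}: {e}") from e
    if df.shape[0] != df.shape[1]:
        raise GRMFormatError(
            f"GRM file must be square, got {df.shape[0]} rows x {df.shape[1]} columns"
        )
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as e:
        raise GRMParseError(f"non-numeric cell in {path}: {e}") from e
    if np.isnan(values).any():
        raise GRMParseError(f"missing/non-numeric cell in {path}")
    row_ids = [str(i) for i in df.index]
    col_ids = [str(c) for c in df.columns]
    if row_ids != col_ids:
        raise GRMValidationError("row and column ids disagree")
    asym = float(np.max(np.abs(values - values.T)))
    if asym >= SYMMETRY_TOL:
        raise GRMValidationError(
            f"asymmetry {asym:.3g} >= {SYMMETRY_TOL}; refusing to symmetrize"
        )
    values = 0.5 * (values + values.T)
    return GRM(ids=tuple(row_ids), values=values)


def write_grm(grm: GRM, path: str | Path, delimiter: str = ",") -> None:
    """Write a GRM in the same dense dialect ``load_grm`` reads.

    17 significant digits, so the writer->reader round trip is bit-identical.
    """
    df = pd.DataFrame(grm.values, index=list(grm.ids), columns=list(grm.ids))
    df.to_csv(Path(path), sep=delimiter, float_format="%.17g")


def grm_from_genotypes(X: np.ndarray, ids: Sequence[str] | None = None,
                       normalize_diagonal: bool = True) -> GRM:
    """VanRaden GRM from a lines x markers dosage matrix (0/1/2).

    ``K = Z Z' / (2 * sum(p*(1-p)))`` with ``Z = X - 2p`` and ``p`` the
    observed allele frequencies; monomorphic markers are dropped. If
    ``normalize_diagonal`` the matrix is rescaled to mean diagonal 1, the
    convention under which trait heritabilities are proportions of
    phenotypic variance.
    """
    X = np.asarray(X, dtype=float)
    p = X.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if poly.sum() < 2:
        raise GRMValidationError("fewer than 2 polymorphic markers")
    Z = X[:, poly] - 2.0 * p[poly]
    denom = 2.0 * np.sum(p[poly] * (1.0 - p[poly]))
    K = (Z @ Z.T) / denom
    if normalize_diagonal:
        K = K / np.mean(np.diag(K))
    K = 0.5 * (K + K.T)
    if ids is None:
        ids = [f"L{i:04d}" for i in range(X.shape[0])]
    return GRM(ids=tuple(ids), values=K)


def simulate_breeding_grm(n_lines: int, n_families: int, n_markers: int,
                          seed: int | np.random.Generator | np.random.SeedSequence,
                          fst: float = 0.25) -> GRM:
    """Synthesize a GRM that mimics a line-breeding program with family structure.

    Families are modelled with Balding-Nichols family-specific allele
    frequencies (differentiation ``fst``); line genotypes are binomial draws
    from the family frequency. After VanRaden scaling and normalization to
    mean diagonal 1, the expected within-family relatedness is
    ``2*fst/(1+fst)`` (0.4 at the default), close relatives in the 0.3-0.5
    band typical of breeding populations; between-family relatedness is near
    zero. Ids encode family membership as ``F<fam>_L<line>``.
    """
    if n_lines < 2 * n_families:
        raise GRMValidationError("need n_lines >= 2 * n_families")
    if n_markers < 100:
        raise GRMValidationError("need n_markers >= 100")
    if not 0 < fst < 1:
        raise GRMValidationError("fst must be in (0, 1)")
    rng = np.random.default_rng(seed)
    base = n_lines // n_families
    sizes = [base + (1 if f < n_lines % n_families else 0) for f in range(n_families)]
    shape = (1.0 - fst) / fst
    for attempt in range(10):
        p = rng.uniform(0.1, 0.9, size=n_markers)
        rows, ids = [], []
        for f, size in enumerate(sizes):
            q = rng.beta(p * shape, (1.0 - p) * shape)
            rows.append(rng.binomial(2, q, size=(size, n_markers)))
            ids.extend(f"F{f:03d}_L{j:03d}" for j in range(size))
        X = np.vstack(rows).astype(float)
        freq = X.mean(axis=0) / 2.0
        if np.any((freq > 0) & (freq < 1)):
            grm = grm_from_genotypes(X, ids=ids)
            return ensure_positive_definite(grm, DEFAULT_MIN_EIG)
        logger.warning("all markers fixed on attempt %d; regenerating", attempt + 1)
    raise GRMValidationError("degenerate allele frequencies after 10 attempts")


def ensure_positive_definite(grm: GRM, min_eig: float = DEFAULT_MIN_EIG) -> GRM:
    """Raise the diagonal just enough that the smallest eigenvalue is >= ``min_eig``."""
    lam_min = float(linalg.eigvalsh(grm.values, subset_by_index=[0, 0])[0])
    if lam_min >= min_eig:
        return grm
    jitter = min_eig - lam_min
    logger.info("jittering GRM diagonal by %.3g (min eigenvalue %.3g)", jitter, lam_min)
    return GRM(ids=grm.ids, values=grm.values + jitter * np.eye(grm.n))


def conditional_blocks(grm: GRM, partition: Partition) -> ConditionalBlocks:
    """Projection ``Kno Koo^-1`` and Schur complement ``Knn - Kno Koo^-1 Kon``.

    Solves against ``Koo`` (Cholesky) rather than inverting the full GRM.
    """
    n_idx = grm.index_of(partition.test_ids)
    o_idx = grm.index_of(partition.train_ids)
    Koo = grm.values[np.ix_(o_idx, o_idx)]
    Kno = grm.values[np.ix_(n_idx, o_idx)]
    Knn = grm.values[np.ix_(n_idx, n_idx)]
    try:
        cho = linalg.cho_factor(Koo, lower=True)
    except linalg.LinAlgError as e:
        raise GRMValidationError(
            "Koo is singular; jitter the GRM with ensure_positive_definite"
        ) from e
    projection = linalg.cho_solve(cho, Kno.T).T
    schur = Knn - projection @ Kno.T
    schur = 0.5 * (schur + schur.T)
    return ConditionalBlocks(projection=projection, schur=schur)
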