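"""Trait-pair simulation on a GRM and cross-validation partition schemes.

Two traits (a focal trait 1 and a secondary trait 2) are drawn from a
matrix-normal model::

    Y = U + E,   U ~ MN(0, K, G),   E ~ MN(0, I_n, R)

where ``K`` is the genomic relationship matrix among lines, ``G`` and ``R``
are the 2x2 genetic and residual trait covariance matrices. Phenotypic
variances are standardized to 1 per trait, so ``G`` carries the
heritabilities on its diagonal (``g11 = h1^2``) and ``R`` the residual
variances (``r11 = 1 - h1^2``).

Sampling uses the two-sided Cholesky transform ``U = L_K Z_u L_G'`` with
standard-normal ``Z_u``; reusing the same ``Z`` matrices across genetic
architectures (common random numbers) makes across-architecture comparisons
much less noisy.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import linalg

from .relatedness import GRM, GRMValidationError, Partition


@dataclass(frozen=True)
class GeneticArchitecture:
    """Heritabilities and trait correlations defining one simulation scenario.

    ``h1_sq``/``h2_sq`` in (0,1); ``rho_g``/``rho_r`` in (-1,1). The implied
    G and R matrices are positive definite on the open parameter box.
    """

    h1_sq: float
    h2_sq: float
    rho_g: float
    rho_r: float

    def __post_init__(self):
        for name in ("h1_sq", "h2_sq"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name}={v} must be in (0, 1)")
        for name in ("rho_g", "rho_r"):
            v = getattr(self, name)
            if not -1.0 < v < 1.0:
                raise ValueError(f"{name}={v} must be in (-1, 1); +/-1 gives a singular covariance")

    def label(self) -> str:
        return f"h1={self.h1_sq:g},h2={self.h2_sq:g},rg={self.rho_g:g},rr={self.rho_r:g}"


def build_covariances(arch: GeneticArchitecture) -> tuple[np.ndarray, np.ndarray]:
    """2x2 genetic and residual covariance matrices for an architecture.

    ``G = [[h1^2, rho_g*h1*h2], [., h2^2]]`` and
    ``R = [[1-h1^2, rho_r*sqrt((1-h1^2)(1-h2^2))], [., 1-h2^2]]``.
    """
    h1 = math.sqrt(arch.h1_sq)
    h2 = math.sqrt(arch.h2_sq)
    g12 = arch.rho_g * h1 * h2
    r11 = 1.0 - arch.h1_sq
    r22 = 1.0 - arch.h2_sq
    r12 = arch.rho_r * math.sqrt(r11 * r22)
    G = np.array([[arch.h1_sq, g12], [g12, arch.h2_sq]])
    R = np.array([[r11, r12], [r12, r22]])
    return G, R


@dataclass(frozen=True)
class CommonRandomDraws:
    """Per-replicate standard-normal draws shared across all architectures."""

    Z_u: np.ndarray
    Z_e: np.ndarray
    replicate_index: int = 0

    def __post_init__(self):
        if self.Z_u.shape != self.Z_e.shape or self.Z_u.ndim != 2 or self.Z_u.shape[1] != 2:
            raise ValueError("Z_u and Z_e must both be (n_lines, 2)")


def draw_common(n_lines: int, rng: np.random.Generator,
                replicate_index: int = 0) -> CommonRandomDraws:
    """Fresh (n_lines, 2) standard-normal matrices for one replicate."""
    return CommonRandomDraws(
        Z_u=rng.standard_normal((n_lines, 2)),
        Z_e=rng.standard_normal((n_lines, 2)),
        replicate_index=replicate_index,
    )


@dataclass(frozen=True)
class TraitReplicate:
    """One simulated dataset: truth, residuals, phenotypes, optional clone copies.

    ``Y = U + E`` holds exactly. ``Y_a``/``Y_b`` (when present) are the two
    independent clone-phenotype copies of the validation lines used by the
    CV2* clone design: the same ``U`` rows with fresh residuals of variance
    ``2R``; training rows keep the original ``Y``.
    """

    ids: tuple[str, ...]
    U: np.ndarray
    E: np.ndarray
    Y: np.ndarray
    replicate_index: int = 0
    Y_a: np.ndarray | None = None
    Y_b: np.ndarray | None = None


def simulate_traits(grm: GRM, arch: GeneticArchitecture, draws: CommonRandomDraws,
                    chol_k: np.ndarray | None = None) -> TraitReplicate:
    """Draw U, E, Y for one architecture from common random numbers.

    ``chol_k`` (lower Cholesky of the GRM) may be precomputed once per GRM
    and reused across replicates/architectures.
    """
    G, R = build_covariances(arch)
    if chol_k is None:
        try:
            chol_k = linalg.cholesky(grm.values, lower=True)
        except linalg.LinAlgError as e:
            raise GRMValidationError(
                "GRM is not positive definite; apply ensure_positive_definite"
            ) from e
    if draws.Z_u.shape[0] != grm.n:
        raise ValueError("draws were generated for a different number of lines")
    L_G = linalg.cholesky(G, lower=True)
    L_R = linalg.cholesky(R, lower=True)
    U = chol_k @ draws.Z_u @ L_G.T
    E = draws.Z_e @ L_R.T
    return TraitReplicate(ids=grm.ids, U=U, E=E, Y=U + E,
                          replicate_index=draws.replicate_index)


def make_partition(grm: GRM, scheme: str, test_fraction: float,
                   seed: int | np.random.Generator | np.random.SeedSequence) -> Partition:
    """Draw a train/test split, optionally with nearest-relative surrogates.

    ``random_split`` samples ``ceil(test_fraction * n)`` test lines uniformly
    without replacement. ``nearest_relative`` additionally assigns each test
    line its most-related remaining line (``argmax_j K_ij``) as a surrogate,
    processing test lines greedily in descending order of their best
    available relatedness (ties broken by lowest index) so strong matches are
    not squandered; surrogates leave the training set.
    """
    if not 0.0 < test_fraction <= 0.5:
        raise ValueError("test_fraction must be in (0, 0.5]")
    if scheme not in ("random_split", "nearest_relative"):
        raise ValueError(f"unknown partition scheme {scheme!r}")
    rng = np.random.default_rng(seed)
    n = grm.n
    n_test = math.ceil(test_fraction * n)
    test_idx = np.sort(rng.choice(n, size=n_test, replace=False))
    test_set = set(test_idx.tolist())
    if scheme == "random_split":
        train = tuple(grm.ids[i] for i in range(n) if i not in test_set)
        return Partition(test_ids=tuple(grm.ids[i] for i in test_idx), train_ids=train)

    K = grm.values
    candidates = [j for j in range(n) if j not in test_set]
    # order test lines by their strongest available match, best first
    best = {i: max(K[i, j] for j in candidates) for i in test_idx}
    order = sorted(test_idx.tolist(), key=lambda i: (-best[i], i))
    available = set(candidates)
    surrogate_of: dict[int, int] = {}
    for i in order:
        if not available:
            raise GRMValidationError("no remaining candidates for nearest-relative surrogates")
        j = min(available, key=lambda j: (-K[i, j], j))
        surrogate_of[i] = j
        available.remove(j)
    surr_set = set(surrogate_of.values())
    train = tuple(grm.ids[j] for j in range(n) if j not in test_set and j not in surr_set)
    return Partition(
        test_ids=tuple(grm.ids[i] for i in test_idx),
        train_ids=train,
        surrogate_ids=tuple(grm.ids[surrogate_of[i]] for i in test_idx),
    )


def make_clone_phenotypes(rep: TraitReplicate, arch: GeneticArchitecture,
                          partition: Partition,
                          draws_extra: np.random.Generator | tuple[np.ndarray, np.ndarray],
                          ) -> TraitReplicate:
    """Attach two independent clone-phenotype copies for the test lines.

    Each copy is ``U + E_*`` with residuals drawn from ``N(0, 2R)`` per line:
    a clone plot carries half the data of a line mean, hence twice the
    residual variance. Training rows are left at the original ``Y``.
    ``draws_extra`` is either a Generator or a pre-drawn pair of
    ``(n_test, 2)`` standard-normal matrices (for common random numbers
    across architectures).
    """
    _, R = build_covariances(arch)
    lookup = {lid: i for i, lid in enumerate(rep.ids)}
    n_idx = np.array([lookup[i] for i in partition.test_ids], dtype=int)
    if isinstance(draws_extra, np.random.Generator):
        Z_a = draws_extra.standard_normal((len(n_idx), 2))
        Z_b = draws_extra.standard_normal((len(n_idx), 2))
    else:
        Z_a, Z_b = draws_extra
    L2R = linalg.cholesky(2.0 * R, lower=True)
    Y_a = rep.Y.copy()
    Y_b = rep.Y.copy()
    Y_a[n_idx] = rep.U[n_idx] + Z_a @ L2R.T
    Y_b[n_idx] = rep.U[n_idx] + Z_b @ L2R.T
    return replace(rep, Y_a=Y_a, Y_b=Y_b)


def seed_streams(root_seed: int | np.random.SeedSequence,
                 names: tuple[str, ...] = ("grm", "draws", "partitions", "clones", "misc"),
                 ) -> dict[str, np.random.Generator]:
    """Spawn independent named random streams from one root seed."""
    ss = root_seed if isinstance(root_seed, np.random.SeedSequence) else np.random.SeedSequence(root_seed)
    children = ss.spawn(len(names))
    return {name: np.random.default_rng(child) for name, child in zip(names, children)}


def write_phenotypes(rep: TraitReplicate, path: str | Path, delimiter: str = "\t") -> None:
    """Write a tidy phenotype table (truth retained for evaluation)."""
    df = pd.DataFrame({
        "id": list(rep.ids),
        "y1": rep.Y[:, 0], "y2": rep.Y[:, 1],
        "u1": rep.U[:, 0], "u2": rep.U[:, 1],
    })
    df.to_csv(Path(path), sep=delimiter, index=False, float_format="%.17g")
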