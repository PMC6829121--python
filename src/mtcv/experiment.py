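"""Factorial simulation experiments and model-selection frequencies.

``run_grid`` sweeps genetic architectures x replicates, simulating trait
pairs on one GRM with common random numbers across architectures, fitting
the training models, computing the single-trait / CV1 / CV2 predictions, and
scoring every requested accuracy estimator. Results come back as a tidy
table (one row per architecture, replicate, design, method, estimator) that
``selection_frequency`` and ``summarize`` consume.

Designs (each with its own partition scheme and estimators):

* ``naive``           — 90:10 random split; true, naive, and semi-parametric
                        accuracies (optionally the full-data-EBV predictand).
* ``parametric``      — 50:50 random split; selection-index estimates fitted
                        on the validation half.
* ``cv2star_clone``   — 90:10 split with two independent clone-phenotype
                        copies (residual variance 2R) for the test lines.
* ``cv2star_relative``— 80:10:10 nearest-relative split; validation against
                        the surrogate relatives' focal phenotypes.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg

from . import accuracy as acc
from .mixedmodel import fit_bivariate_reml, fit_univariate_reml
from .predict import predict_cv1, predict_cv2, predict_single
from .relatedness import GRM, conditional_blocks, load_grm, simulate_breeding_grm
from .simulate import (GeneticArchitecture, draw_common, make_clone_phenotypes,
                       make_partition, simulate_traits)

logger = logging.getLogger(__name__)

ARCH_COLS = ["h1_sq", "h2_sq", "rho_g", "rho_r"]
DESIGNS = ("naive", "parametric", "cv2star_clone", "cv2star_relative")
DEFAULT_TEST_FRACTIONS = {
    "naive": 0.1, "parametric": 0.5, "cv2star_clone": 0.1, "cv2star_relative": 0.1,
}


@dataclass
class GridConfig:
    """Everything needed to reproduce a grid run from a root seed."""

    h1_sq: Sequence[float] = (0.2,)
    h2_sq: Sequence[float] = (0.2, 0.6)
    rho_g: Sequence[float] = (0.0, 0.3, 0.6)
    rho_r: Sequence[float] = (-0.6, -0.4, -0.2, 0.0, 0.2, 0.4, 0.6)
    reps: int = 200
    designs: Sequence[str] = ("naive",)
    seed: int = 0
    grm_path: str | None = None
    n_lines: int = 400
    n_families: int = 40
    n_markers: int = 2000
    fst: float = 0.25
    test_fractions: dict = field(default_factory=dict)
    correction: str = "h"
    include_ebv: bool = False
    drop_nonconverged: bool = False
    n_jobs: int = 1

    def __post_init__(self):
        for d in self.designs:
            if d not in DESIGNS:
                raise ValueError(f"unknown design {d!r}; choose from {DESIGNS}")
        self.test_fractions = {**DEFAULT_TEST_FRACTIONS, **(self.test_fractions or {})}

    @property
    def architectures(self) -> list[GeneticArchitecture]:
        return [GeneticArchitecture(*combo) for combo in
                itertools.product(self.h1_sq, self.h2_sq, self.rho_g, self.rho_r)]

    @classmethod
    def from_dict(cls, d: dict) -> "GridConfig":
        d = dict(d)
        grid = d.pop("grid", {})
        grm = d.pop("grm", {})
        kwargs = {**grid, **d}
        if grm:
            kwargs["grm_path"] = grm.get("path")
            for key in ("n_lines", "n_families", "n_markers", "fst"):
                if key in grm:
                    kwargs[key] = grm[key]
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GridConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def resolve_grm(config: GridConfig,
                seed: np.random.SeedSequence | int | None = None) -> GRM:
    """Load the configured GRM file, or synthesize a breeding GRM."""
    if config.grm_path:
        return load_grm(config.grm_path)
    if seed is None:
        seed = np.random.SeedSequence(config.seed).spawn(1)[0]
    return simulate_breeding_grm(config.n_lines, config.n_families,
                                 config.n_markers, seed, fst=config.fst)


# partition-context machinery -------------------------------------------------

_DESIGN_KEYS = {
    "naive": ("random_split", "naive"),
    "parametric": ("random_split", "parametric"),
    "cv2star_clone": ("random_split", "cv2star_clone"),
    "cv2star_relative": ("nearest_relative", "cv2star_relative"),
}


@dataclass
class _Ctx:
    """Per-replicate partition context shared across architectures."""

    partition: object
    n_idx: np.ndarray
    o_idx: np.ndarray
    x_idx: np.ndarray | None
    Koo: np.ndarray
    Knn: np.ndarray
    eig_oo: tuple
    blocks: object
    eig_nn: tuple | None = None


def _build_ctx(grm: GRM, scheme: str, frac: float, rng: np.random.Generator,
               need_eig_nn: bool) -> _Ctx:
    part = make_partition(grm, scheme, frac, rng)
    n_idx = grm.index_of(part.test_ids)
    o_idx = grm.index_of(part.train_ids)
    x_idx = None if part.surrogate_ids is None else grm.index_of(part.surrogate_ids)
    Koo = grm.values[np.ix_(o_idx, o_idx)]
    Knn = grm.values[np.ix_(n_idx, n_idx)]
    eig_oo = linalg.eigh(Koo)
    eig_oo = (eig_oo[0], eig_oo[1])
    eig_nn = None
    if need_eig_nn:
        w, v = linalg.eigh(Knn)
        eig_nn = (w, v)
    blocks = conditional_blocks(grm, part)
    return _Ctx(partition=part, n_idx=n_idx, o_idx=o_idx, x_idx=x_idx,
                Koo=Koo, Knn=Knn, eig_oo=eig_oo, blocks=blocks, eig_nn=eig_nn)


def _fit_training(ctx: _Ctx, Y: np.ndarray):
    """(univariate fit, bivariate fit) on the training partition; None on failure."""
    uni = biv = None
    try:
        uni = fit_univariate_reml(Y[ctx.o_idx, 0], ctx.Koo, eig=ctx.eig_oo)
    except Exception as e:  # noqa: BLE001 - record as missing, never abort the grid
        logger.warning("univariate fit failed: %s", e)
    try:
        biv = fit_bivariate_reml(Y[ctx.o_idx], ctx.Koo, eig=ctx.eig_oo)
    except Exception as e:  # noqa: BLE001
        logger.warning("bivariate fit failed: %s", e)
    return uni, biv


def _run_replicate(rep: int, rep_ss: np.random.SeedSequence, grm: GRM,
                   chol_k: np.ndarray, archs: list[GeneticArchitecture],
                   config: GridConfig) -> list[dict]:
    ss_draws, ss_part, ss_clone = rep_ss.spawn(3)
    rng_draws = np.random.default_rng(ss_draws)
    rng_part = np.random.default_rng(ss_part)
    rng_clone = np.random.default_rng(ss_clone)

    draws = draw_common(grm.n, rng_draws, replicate_index=rep)

    # one partition per distinct (scheme, fraction); shared across designs
    ctxs: dict[tuple, _Ctx] = {}
    for design in config.designs:
        scheme, _ = _DESIGN_KEYS[design]
        key = (scheme, round(float(config.test_fractions[design]), 6))
        if key not in ctxs:
            ctxs[key] = _build_ctx(grm, key[0], key[1], rng_part,
                                   need_eig_nn="parametric" in config.designs)
    clone_Z = None
    if "cv2star_clone" in config.designs:
        key = ("random_split", round(float(config.test_fractions["cv2star_clone"]), 6))
        n_test = len(ctxs[key].n_idx)
        clone_Z = (rng_clone.standard_normal((n_test, 2)),
                   rng_clone.standard_normal((n_test, 2)))

    rows: list[dict] = []
    for arch in archs:
        trep = simulate_traits(grm, arch, draws, chol_k=chol_k)
        fits: dict[tuple, tuple] = {}
        preds: dict[tuple, dict] = {}
        for key, ctx in ctxs.items():
            uni, biv = _fit_training(ctx, trep.Y)
            fits[key] = (uni, biv)
            p: dict[str, np.ndarray | None] = {"single": None, "cv1": None, "cv2": None}
            if uni is not None:
                p["single"] = predict_single(uni, ctx.blocks)
            if biv is not None:
                p["cv1"] = predict_cv1(biv, ctx.blocks)
                p["cv2"] = predict_cv2(biv, ctx.blocks, trep.Y[ctx.n_idx, 1])
            preds[key] = p

        base = {c: getattr(arch, c) for c in ARCH_COLS}
        base["replicate"] = rep
        for design in config.designs:
            scheme, _ = _DESIGN_KEYS[design]
            key = (scheme, round(float(config.test_fractions[design]), 6))
            ctx = ctxs[key]
            uni, biv = fits[key]
            evaluator = _EVALUATORS[design]
            rows.extend(evaluator(base, design, grm, arch, trep, ctx, uni, biv,
                                  preds[key], clone_Z, config))
    return rows


def _row(base, design, method, estimator, value, converged=True):
    return {**base, "design": design, "method": method, "estimator": estimator,
            "value": float(value) if value is not None and np.isfinite(value) else np.nan,
            "converged": bool(converged)}


def _eval_naive(base, design, grm, arch, trep, ctx, uni, biv, preds, clone_Z, config):
    rows = []
    u_true = trep.U[ctx.n_idx, 0]
    y_n1 = trep.Y[ctx.n_idx, 0]
    conv = biv is not None and biv.converged
    for method, pred, ok in (("single", preds["single"], uni is not None),
                             ("cv1", preds["cv1"], conv),
                             ("cv2", preds["cv2"], conv)):
        if pred is None or (config.drop_nonconverged and not ok):
            rows.append(_row(base, design, method, "true", np.nan, ok))
            rows.append(_row(base, design, method, "naive", np.nan, ok))
            if method == "cv2":
                rows.append(_row(base, design, method, "semiparametric", np.nan, ok))
            continue
        rows.append(_row(base, design, method, "true",
                         acc.true_accuracy(pred, u_true), ok))
        rows.append(_row(base, design, method, "naive",
                         acc.naive_accuracy(pred, y_n1, arch.h1_sq, config.correction), ok))
        if method == "cv2":
            bias = acc.semiparametric_bias(biv, ctx.blocks, pred, y_n1)
            naive_cor = acc._pearson(pred, y_n1)
            rows.append(_row(base, design, method, "semiparametric",
                             acc.semiparametric_accuracy(naive_cor, bias, arch.h1_sq,
                                                         config.correction), ok))
    if config.include_ebv:
        try:
            u_tilde = acc.full_data_ebv_predictand(trep.Y, grm, ctx.partition)
            for method, pred in (("single", preds["single"]), ("cv1", preds["cv1"]),
                                 ("cv2", preds["cv2"])):
                if pred is not None:
                    rows.append(_row(base, design, method, "ebv",
                                     acc.true_accuracy(pred, u_tilde), conv))
        except Exception as e:  # noqa: BLE001
            logger.warning("full-data EBV fit failed: %s", e)
    return rows


def _eval_parametric(base, design, grm, arch, trep, ctx, uni, biv, preds, clone_Z, config):
    rows = []
    u_true = trep.U[ctx.n_idx, 0]
    y_n1 = trep.Y[ctx.n_idx, 0]
    conv = biv is not None and biv.converged
    for method, pred, ok in (("single", preds["single"], uni is not None),
                             ("cv2", preds["cv2"], conv)):
        if pred is None:
            rows.append(_row(base, design, method, "true", np.nan, ok))
            rows.append(_row(base, design, method, "parametric", np.nan, ok))
            continue
        rows.append(_row(base, design, method, "true",
                         acc.true_accuracy(pred, u_true), ok))
        rows.append(_row(base, design, method, "parametric",
                         acc.parametric_accuracy(pred, y_n1, ctx.Knn, eig=ctx.eig_nn), ok))
    return rows


def _eval_cv2star_clone(base, design, grm, arch, trep, ctx, uni, biv, preds, clone_Z, config):
    rows = []
    crep = make_clone_phenotypes(trep, arch, ctx.partition, clone_Z)
    u_true = trep.U[ctx.n_idx, 0]
    y_x1 = crep.Y_b[ctx.n_idx, 0]     # validation copy
    r11 = 1.0 - arch.h1_sq
    conv = biv is not None and biv.converged
    pred_cv2 = None
    if biv is not None:
        # prediction uses the secondary phenotype of clone copy A
        pred_cv2 = predict_cv2(biv, ctx.blocks, crep.Y_a[ctx.n_idx, 1])
    for method, pred, ok in (("single", preds["single"], uni is not None),
                             ("cv2", pred_cv2, conv)):
        if pred is None:
            rows.append(_row(base, design, method, "true", np.nan, ok))
            rows.append(_row(base, design, method, "cv2star", np.nan, ok))
            continue
        rows.append(_row(base, design, method, "true",
                         acc.true_accuracy(pred, u_true), ok))
        rows.append(_row(base, design, method, "cv2star",
                         acc.cv2star_accuracy(pred, y_x1, arch.h1_sq, "clone", r11=r11), ok))
    return rows


def _eval_cv2star_relative(base, design, grm, arch, trep, ctx, uni, biv, preds, clone_Z, config):
    rows = []
    u_true = trep.U[ctx.n_idx, 0]
    y_x1 = trep.Y[ctx.x_idx, 0]       # surrogate relatives, aligned with test ids
    conv = biv is not None and biv.converged
    for method, pred, ok in (("single", preds["single"], uni is not None),
                             ("cv2", preds["cv2"], conv)):
        if pred is None:
            rows.append(_row(base, design, method, "true", np.nan, ok))
            rows.append(_row(base, design, method, "cv2star", np.nan, ok))
            continue
        rows.append(_row(base, design, method, "true",
                         acc.true_accuracy(pred, u_true), ok))
        rows.append(_row(base, design, method, "cv2star",
                         acc.cv2star_accuracy(pred, y_x1, arch.h1_sq, "relative"), ok))
    return rows


_EVALUATORS = {
    "naive": _eval_naive,
    "parametric": _eval_parametric,
    "cv2star_clone": _eval_cv2star_clone,
    "cv2star_relative": _eval_cv2star_relative,
}


def run_grid(config: GridConfig, grm: GRM | None = None) -> pd.DataFrame:
    """Run the factorial study; fully reproducible from (config, seed)."""
    root = np.random.SeedSequence(config.seed)
    grm_ss, reps_ss = root.spawn(2)
    if grm is None:
        grm = resolve_grm(config, seed=grm_ss)
    chol_k = linalg.cholesky(grm.values, lower=True)
    archs = config.architectures
    rep_seeds = reps_ss.spawn(config.reps)

    if config.n_jobs and config.n_jobs != 1:
        from joblib import Parallel, delayed

        chunks = Parallel(n_jobs=config.n_jobs)(
            delayed(_run_replicate)(rep, rep_seeds[rep], grm, chol_k, archs, config)
            for rep in range(config.reps)
        )
    else:
        chunks = []
        for rep in range(config.reps):
            chunks.append(_run_replicate(rep, rep_seeds[rep], grm, chol_k, archs, config))
            if (rep + 1) % 25 == 0:
                logger.info("finished replicate %d/%d", rep + 1, config.reps)
    rows = [row for chunk in chunks for row in chunk]
    return pd.DataFrame(rows)


def selection_frequency(grid: pd.DataFrame, estimator: str,
                        methods: tuple[str, str] = ("single", "cv2"),
                        design: str | None = None) -> pd.DataFrame:
    """How often an estimator picks the truly better of two methods.

    The "truly better" method per architecture is the one with the higher
    mean true accuracy over replicates; the fraction counts replicates where
    the estimator ranks it highest (exact ties count 0.5; replicates with a
    missing estimate for either method are excluded from the denominator).

    An estimator that applies to only one method (the semi-parametric
    correction exists only for CV2-style predictions) is compared against the
    other method's naive estimate, mirroring how a practitioner would use the
    correction.
    """
    if estimator not in set(grid["estimator"]):
        raise ValueError(f"estimator {estimator!r} not present in results")
    sub = grid
    if design is not None:
        sub = grid[grid["design"] == design]
    else:
        cand = set(sub.loc[sub["estimator"] == estimator, "design"])
        if len(cand) > 1:
            raise ValueError(f"estimator {estimator!r} spans designs {sorted(cand)}; "
                             "pass design=...")
        sub = sub[sub["design"].isin(cand)]
    sub = sub[sub["method"].isin(methods)]
    out = []
    for arch, g in sub.groupby(ARCH_COLS, sort=False):
        true_mean = (g[g["estimator"] == "true"]
                     .groupby("method")["value"].mean())
        if not all(m in true_mean.index for m in methods):
            raise ValueError(f"missing true accuracies for {methods} at {arch}")
        best = true_mean[list(methods)].idxmax()
        other = methods[0] if best == methods[1] else methods[1]
        est_rows = g[g["estimator"] == estimator]
        cols = {}
        for m in methods:
            m_rows = est_rows[est_rows["method"] == m]
            if m_rows.empty:  # estimator not defined for this method: use naive
                m_rows = g[(g["estimator"] == "naive") & (g["method"] == m)]
            if m_rows.empty:
                raise ValueError(f"no {estimator!r} or 'naive' values for method {m!r}")
            cols[m] = m_rows.set_index("replicate")["value"]
        est = pd.DataFrame(cols).dropna()
        if est.empty:
            frac, n_eff = np.nan, 0
        else:
            diff = est[best] - est[other]
            frac = float(np.mean(np.where(diff > 0, 1.0, np.where(diff < 0, 0.0, 0.5))))
            n_eff = int(len(est))
        out.append(dict(zip(ARCH_COLS, arch),
                        best_method=best, fraction_correctly_selected=frac,
                        n_replicates=n_eff))
    return pd.DataFrame(out)


def summarize(grid: pd.DataFrame) -> pd.DataFrame:
    """Per-architecture mean and Monte-Carlo standard error of every estimator."""
    if grid.empty:
        raise ValueError("empty results table")
    keys = ARCH_COLS + ["design", "method", "estimator"]
    agg = (grid.groupby(keys)["value"]
           .agg(mean="mean", sd="std", n="count")
           .reset_index())
    agg["se"] = agg["sd"] / np.sqrt(agg["n"].clip(lower=1))
    agg["ci_low"] = agg["mean"] - 1.96 * agg["se"]
    agg["ci_high"] = agg["mean"] + 1.96 * agg["se"]
    return agg.drop(columns="sd")


def plot_summary(summary: pd.DataFrame, path: str | Path, design: str = "naive",
                 estimators: tuple[str, ...] = ("true",)) -> None:
    """Mean +/- 1.96 SE accuracy curves vs residual correlation, per method."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = summary[(summary["design"] == design) & summary["estimator"].isin(estimators)]
    if sub.empty:
        raise ValueError(f"nothing to plot for design {design!r}")
    panels = sorted(sub.groupby(["h1_sq", "h2_sq", "rho_g"]).groups)
    fig, axes = plt.subplots(1, len(panels), figsize=(3.2 * len(panels), 3.2),
                             sharey=True, squeeze=False)
    for ax, panel in zip(axes[0], panels):
        h1, h2, rg = panel
        p = sub[(sub.h1_sq == h1) & (sub.h2_sq == h2) & (sub.rho_g == rg)]
        for (method, estimator), gsub in p.groupby(["method", "estimator"]):
            gsub = gsub.sort_values("rho_r")
            style = "-" if estimator == "true" else "--"
            line, = ax.plot(gsub.rho_r, gsub["mean"], style, marker="o", ms=3,
                            label=f"{method} ({estimator})")
            ax.fill_between(gsub.rho_r, gsub.ci_low, gsub.ci_high,
                            alpha=0.2, color=line.get_color())
        ax.set_title(f"$h_1^2$={h1:g}, $h_2^2$={h2:g}, $\\rho_g$={rg:g}", fontsize=9)
        ax.set_xlabel(r"$\rho_R$")
    axes[0][0].set_ylabel("accuracy")
    axes[0][-1].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
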