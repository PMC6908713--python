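"""Fitting the lifespan clock.

The clock is a two-stage model. Stage one regresses natural-log maximum
lifespan on promoter CpG densities with an elastic-net penalty,

    (1/(2n)) * sum (y - w0 - Xw)^2 + lambda * (alpha*||w||_1 + (1-alpha)/2*||w||_2^2),

with lambda chosen at the cross-validation MSE minimum. Stage two is a
phylogenetic generalized least squares (PGLS) calibration of the stage-one
raw score x = w0 + sum w_i d_i against ln lifespan, with vertebrate-class
intercept and slope offsets, under a Brownian-motion trait covariance
derived from divergence times:

    ln(max lifespan) = c0 + c1*x + a*x + b,

where (a, b) depend on the vertebrate class (reference class: a = b = 0).
The published clock uses c0 = -4.38996 and c1 = 2.57328.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet, ElasticNetCV
from sklearn.model_selection import KFold

logger = logging.getLogger(__name__)

VERTEBRATE_CLASSES = ("Aves", "Fish", "Mammalia", "Reptilia", "Amphibia")

#: class absorbed into the global intercept/slope; unlisted classes use a=b=0
DEFAULT_REFERENCE_CLASS = "Amphibia"


@dataclass(frozen=True)
class SpeciesRecord:
    """One species: taxonomic class, maximum lifespan, and record provenance."""

    species_id: str
    vertebrate_class: str
    max_lifespan: float
    source: str = "unknown"

    def __post_init__(self) -> None:
        if self.max_lifespan <= 0:
            raise ValueError(f"{self.species_id}: max lifespan must be > 0 years")


@dataclass
class TrainingConfig:
    """Knobs for the clock fit.

    alpha is the elastic-net L1/L2 mixing parameter (1 = lasso, 0 = ridge);
    lambda is selected on a descending path by cv_folds-fold CV. The seed
    drives every stochastic step (split, CV fold assignment).
    """

    alpha: float = 0.5
    cv_folds: int = 10
    train_fraction: float = 0.7
    seed: int = 0
    standardize: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")


@dataclass
class ClockModel:
    """The fitted two-stage lifespan clock (serializable)."""

    promoter_weights: dict[str, float]
    enet_intercept: float
    selected_lambda: float
    global_intercept: float
    global_slope: float
    class_coefficients: dict[str, tuple[float, float]]
    promoter_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.promoter_weights = {k: v for k, v in self.promoter_weights.items() if v != 0.0}

    def class_ab(self, vertebrate_class: str) -> tuple[float, float]:
        """(a, b) for a class; classes absent from the calibration use (0, 0)."""
        return self.class_coefficients.get(vertebrate_class, (0.0, 0.0))

    def to_dict(self) -> dict:
        return {
            "global_intercept": self.global_intercept,
            "global_slope": self.global_slope,
            "enet_intercept": self.enet_intercept,
            "selected_lambda": self.selected_lambda,
            "weights": dict(self.promoter_weights),
            "class_coefficients": {
                c: {"a": a, "b": b} for c, (a, b) in self.class_coefficients.items()
            },
            "promoter_order": list(self.promoter_order),
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: Mapping) -> "ClockModel":
        return cls(
            promoter_weights=dict(d["weights"]),
            enet_intercept=float(d["enet_intercept"]),
            selected_lambda=float(d["selected_lambda"]),
            global_intercept=float(d["global_intercept"]),
            global_slope=float(d["global_slope"]),
            class_coefficients={
                c: (float(v["a"]), float(v["b"]))
                for c, v in d["class_coefficients"].items()
            },
            promoter_order=list(d.get("promoter_order", [])),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "ClockModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def load_published_clock() -> ClockModel:
    """The printed clock: global constants and per-class calibration.

    Promoter weights are not public at full precision, so the weight map is
    empty; the model is usable for formula evaluation given a raw score.
    """
    ref = resources.files("cpgclock.data").joinpath("published_clock.json")
    return ClockModel.from_dict(json.loads(ref.read_text()))


def split_train_test(
    records: Iterable[SpeciesRecord],
    config: TrainingConfig,
) -> tuple[list[str], list[str]]:
    """Class-stratified random train/test split, reproducible from the seed.

    Within each class, round(train_fraction * n) species go to training. A
    class with a single member goes entirely to training (with a warning).
    """
    records = list(records)
    rng = np.random.default_rng(config.seed)
    by_class: dict[str, list[str]] = {}
    for r in records:
        by_class.setdefault(r.vertebrate_class, []).append(r.species_id)
    train: list[str] = []
    test: list[str] = []
    for cls in sorted(by_class):
        ids = by_class[cls]
        if len(ids) == 1:
            warnings.warn(f"class {cls!r} has a single member; assigned to training")
            train.extend(ids)
            continue
        n_train = int(np.floor(config.train_fraction * len(ids) + 0.5))
        n_train = min(max(n_train, 1), len(ids) - 1)
        perm = rng.permutation(len(ids))
        train.extend(ids[i] for i in perm[:n_train])
        test.extend(ids[i] for i in perm[n_train:])
    return train, test


def fit_elastic_net(
    X: pd.DataFrame,
    y: Sequence[float],
    config: TrainingConfig,
    fixed_lambda: float | None = None,
) -> tuple[dict[str, float], float, float]:
    """Elastic-net fit of ln lifespan on densities.

    Predictors are standardized internally (when config.standardize) and the
    weights reported back on the original density scale; only nonzero
    weights are returned. lambda is the CV-MSE minimum over a descending
    path unless ``fixed_lambda`` pins it.
    """
    y = np.asarray(y, dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("response is constant; nothing to fit")
    Xv = X.to_numpy(dtype=float)
    n = Xv.shape[0]
    if fixed_lambda is None and n < config.cv_folds:
        raise ValueError(f"{n} training rows < {config.cv_folds} CV folds")

    if config.standardize:
        mu = Xv.mean(axis=0)
        sd = Xv.std(axis=0)
        sd_safe = np.where(sd > 0, sd, 1.0)
        Xs = (Xv - mu) / sd_safe
    else:
        mu = np.zeros(Xv.shape[1])
        sd_safe = np.ones(Xv.shape[1])
        Xs = Xv

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", UserWarning)
        if fixed_lambda is not None:
            model = ElasticNet(
                alpha=max(fixed_lambda, 0.0), l1_ratio=config.alpha,
                fit_intercept=True, max_iter=100_000, tol=1e-10,
            )
            model.fit(Xs, y)
            lam = float(fixed_lambda)
            coef, intercept = model.coef_, float(model.intercept_)
        else:
            cv = KFold(n_splits=config.cv_folds, shuffle=True, random_state=config.seed)
            model = ElasticNetCV(
                l1_ratio=config.alpha, alphas=100, cv=cv,
                fit_intercept=True, max_iter=20_000, tol=1e-7,
            )
            model.fit(Xs, y)
            lam = float(model.alpha_)
            coef, intercept = model.coef_, float(model.intercept_)

    # back to the original density scale
    w = coef / sd_safe
    w0 = intercept - float(np.dot(coef, mu / sd_safe))
    weights = {pid: float(wi) for pid, wi in zip(X.columns, w) if wi != 0.0}
    return weights, w0, lam


def elastic_net_path_nonzeros(
    X: pd.DataFrame, y: Sequence[float], config: TrainingConfig, n_lambdas: int = 30,
) -> list[tuple[float, int]]:
    """(lambda, nonzero-weight count) along a descending lambda path."""
    y = np.asarray(y, dtype=float)
    Xv = X.to_numpy(dtype=float)
    mu, sd = Xv.mean(axis=0), Xv.std(axis=0)
    Xs = (Xv - mu) / np.where(sd > 0, sd, 1.0)
    n = len(y)
    lam_max = np.max(np.abs(Xs.T @ (y - y.mean()))) / (n * max(config.alpha, 1e-3))
    lambdas = np.geomspace(lam_max, lam_max * 1e-3, n_lambdas)
    out = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for lam in lambdas:
            m = ElasticNet(alpha=lam, l1_ratio=config.alpha, max_iter=20_000, tol=1e-8)
            m.fit(Xs, y)
            out.append((float(lam), int(np.count_nonzero(m.coef_))))
    return out


def raw_score(model: ClockModel, densities: Mapping[str, float] | pd.Series) -> float:
    """Stage-one linear predictor x = w0 + sum_i w_i * d_i (missing d -> 0)."""
    x = model.enet_intercept
    for pid, w in model.promoter_weights.items():
        d = densities.get(pid, 0.0) if hasattr(densities, "get") else densities[pid]
        x += w * float(d)
    return x


@dataclass
class PhyloCovariance:
    """Species x species Brownian-motion trait covariance (shared time, MY)."""

    species_ids: list[str]
    V: np.ndarray

    def aligned(self, order: Sequence[str]) -> np.ndarray:
        idx = [self.species_ids.index(s) for s in order]
        return self.V[np.ix_(idx, idx)]


def covariance_from_divergence(
    divergence: pd.DataFrame | str | Path | dendropy.Tree,
) -> PhyloCovariance:
    """Brownian covariance from pairwise divergence times or a tree.

    From a divergence-time matrix (MYA, symmetric, zero diagonal):
    T = max t_ij, V_ij = max(0, T - t_ij), V_ii = T (ultrametric clock
    assumption). From a tree with branch lengths: V_ij = root-to-MRCA path
    length, V_ii = root-to-tip depth.
    """
    if isinstance(divergence, dendropy.Tree):
        return _covariance_from_tree(divergence)
    if isinstance(divergence, (str, Path)):
        text = str(divergence)
        if text.lstrip().startswith("(") or text.endswith((".nwk", ".newick", ".tre")):
            tree = dendropy.Tree.get(
                data=text, schema="newick",
            ) if text.lstrip().startswith("(") else dendropy.Tree.get(
                path=text, schema="newick",
            )
            return _covariance_from_tree(tree)
        raise ValueError(f"cannot interpret divergence input {text!r}")
    df = divergence
    t = df.to_numpy(dtype=float)
    if t.shape[0] != t.shape[1]:
        raise ValueError("divergence matrix must be square")
    if not np.allclose(t, t.T):
        raise ValueError("divergence matrix must be symmetric")
    if (t < 0).any():
        raise ValueError("divergence times must be non-negative")
    T = float(t.max())
    V = np.maximum(T - t, 0.0)
    np.fill_diagonal(V, T)
    return PhyloCovariance(species_ids=[str(s) for s in df.index], V=V)


def _covariance_from_tree(tree: dendropy.Tree) -> PhyloCovariance:
    tree = tree.clone(depth=1)
    depth: dict[int, float] = {id(tree.seed_node): 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        depth[id(node)] = depth[id(node.parent_node)] + (node.edge.length or 0.0)
    leaves = tree.leaf_nodes()
    labels = [lf.taxon.label for lf in leaves]
    index = {id(lf): i for i, lf in enumerate(leaves)}
    n = len(leaves)
    V = np.zeros((n, n))
    for i, lf in enumerate(leaves):
        V[i, i] = depth[id(lf)]
    # MRCA depth for each leaf pair, via postorder leaf-set merging
    subtree: dict[int, list[int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            subtree[id(node)] = [index[id(node)]]
            continue
        groups = [subtree.pop(id(c)) for c in node.child_nodes()]
        d = depth[id(node)]
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                for a in groups[gi]:
                    for b in groups[gj]:
                        V[a, b] = V[b, a] = d
        subtree[id(node)] = [x for g in groups for x in g]
    return PhyloCovariance(species_ids=labels, V=V)


def fit_pgls_calibration(
    x: Sequence[float],
    y: Sequence[float],
    classes: Sequence[str],
    cov: PhyloCovariance | np.ndarray | None = None,
    species_ids: Sequence[str] | None = None,
    reference_class: str | None = None,
) -> tuple[float, float, dict[str, tuple[float, float]]]:
    """PGLS of ln lifespan on raw score with per-class slope/intercept offsets.

    Generalized least squares, beta = (X' V^-1 X)^-1 X' V^-1 y, on the design
    [1, x, class indicators, class x interactions]; the reference class is
    absorbed into the global terms. Returns (global_intercept, global_slope,
    {class: (a, b)}) where a is the slope offset and b the intercept offset.
    Classes with fewer than 2 members are excluded from calibration (a=b=0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    classes = list(classes)
    n = len(x)
    if isinstance(cov, PhyloCovariance):
        V = cov.aligned(species_ids) if species_ids is not None else cov.V
    elif cov is None:
        V = np.eye(n)
    else:
        V = np.asarray(cov, dtype=float)
    if V.shape != (n, n):
        raise ValueError(f"covariance shape {V.shape} does not match n = {n}")

    counts = pd.Series(classes).value_counts()
    if reference_class is None:
        reference_class = (
            DEFAULT_REFERENCE_CLASS if DEFAULT_REFERENCE_CLASS in counts.index
            else sorted(counts.index)[0]
        )
    if counts.get(reference_class, 0) < 2:
        # a singleton reference makes the global terms collinear with the
        # class dummies; re-reference to the largest class (a = b = 0 there)
        largest = counts.idxmax()
        warnings.warn(
            f"reference class {reference_class!r} has < 2 members; "
            f"re-referencing to {largest!r}"
        )
        reference_class = largest
    calibrated = sorted(
        c for c in counts.index
        if c != reference_class and counts[c] >= 2
    )
    for c in counts.index:
        if c != reference_class and counts[c] < 2:
            warnings.warn(f"class {c!r} has < 2 members; excluded from calibration (a=b=0)")
    for c in calibrated:
        mask = np.array([ci == c for ci in classes])
        if np.ptp(x[mask]) == 0:
            raise ValueError(f"class {c!r} has constant raw score; singular design")

    cols = [np.ones(n), x]
    for c in calibrated:
        ind = np.array([float(ci == c) for ci in classes])
        cols.extend([ind, ind * x])
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular calibration design matrix")
    try:
        fit = sm.GLS(y, X, sigma=V).fit()
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"covariance matrix is not invertible: {exc}") from None
    params = fit.params
    global_intercept, global_slope = float(params[0]), float(params[1])
    class_coefficients = {
        c: (float(params[2 + 2 * i + 1]), float(params[2 + 2 * i]))
        for i, c in enumerate(calibrated)
    }
    return global_intercept, global_slope, class_coefficients


def assemble_clock(
    weights: Mapping[str, float],
    enet_intercept: float,
    selected_lambda: float,
    calibration: tuple[float, float, Mapping[str, tuple[float, float]]],
    promoter_order: Sequence[str] | None = None,
) -> ClockModel:
    """Bundle both fitted stages into one serializable model."""
    global_intercept, global_slope, class_coefficients = calibration
    if global_intercept is None or global_slope is None:
        raise ValueError("calibration must provide global intercept and slope")
    return ClockModel(
        promoter_weights=dict(weights),
        enet_intercept=float(enet_intercept),
        selected_lambda=float(selected_lambda),
        global_intercept=float(global_intercept),
        global_slope=float(global_slope),
        class_coefficients={c: (float(a), float(b)) for c, (a, b) in class_coefficients.items()},
        promoter_order=list(promoter_order or weights.keys()),
    )


def train_clock(
    densities,
    records: Iterable[SpeciesRecord],
    divergence,
    config: TrainingConfig,
) -> tuple[ClockModel, list[str], list[str]]:
    """End-to-end clock fit: split, elastic net, PGLS calibration.

    ``densities`` is a DensityMatrix or DataFrame (species x promoters);
    ``divergence`` a divergence-time DataFrame, newick, or None (identity
    covariance). Returns (model, train_ids, test_ids).
    """
    frame = densities.frame if hasattr(densities, "frame") else densities
    records = list(records)
    rec_by_id = {r.species_id: r for r in records}
    missing = [r.species_id for r in records if r.species_id not in frame.index]
    if missing:
        raise ValueError(f"species missing from density matrix: {missing[:5]}")
    train_ids, test_ids = split_train_test(records, config)

    X_train = frame.loc[train_ids]
    y_train = np.log([rec_by_id[s].max_lifespan for s in train_ids])
    weights, w0, lam = fit_elastic_net(X_train, y_train, config)

    stub = ClockModel(
        promoter_weights=weights, enet_intercept=w0, selected_lambda=lam,
        global_intercept=0.0, global_slope=1.0, class_coefficients={},
    )
    x_train = np.array([raw_score(stub, frame.loc[s]) for s in train_ids])
    classes = [rec_by_id[s].vertebrate_class for s in train_ids]
    cov = covariance_from_divergence(divergence) if divergence is not None else None
    calibration = fit_pgls_calibration(
        x_train, y_train, classes, cov=cov,
        species_ids=train_ids if cov is not None else None,
    )
    model = assemble_clock(weights, w0, lam, calibration, promoter_order=list(frame.columns))
    return model, train_ids, test_ids
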