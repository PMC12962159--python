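"""Partial least squares path modeling (PLS-PM) with reflective blocks.

A PLS path model couples a *measurement model* — each latent variable is
reflected by a block of observed indicators, x = lambda * xi + epsilon —
with a *structural model* — a recursive (acyclic) system of standardized
regressions among the latent scores, eta = B eta + zeta. Estimation
follows the classical alternating algorithm:

1. latent scores as standardized weighted sums of their block indicators
   (outer approximation);
2. inner proxies as weighted sums of adjacent latent scores, with inner
   weights from the centroid, factorial or path scheme;
3. Mode A outer-weight update: each indicator's weight proportional to
   its covariance with the block's inner proxy;

iterated to convergence of the outer weights. Loadings are then the
indicator-score correlations, structural ("path") coefficients come from
OLS of each endogenous score on its predecessors' scores, and overall fit
is summarised by GOF = sqrt(mean communality x mean R²) with weak /
medium / strong read at 0.10 / 0.25 / 0.36.

Effects decompose along the DAG: the direct effect of one latent on
another is the structural coefficient on the edge; the indirect effect is
the sum over all directed multi-edge paths of the products of edge
coefficients; total = direct + indirect. Inference is by nonparametric
bootstrap over rows with sign alignment to the base fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["PathModelSpec", "PLSFit", "EffectsTable", "default_path_model",
           "fit_pls_pm", "gof_label", "effects", "bootstrap_inference"]

GOF_THRESHOLDS = [(0.36, "strong"), (0.25, "medium"), (0.10, "weak")]


@dataclass
class PathModelSpec:
    """Latent blocks and directed structural edges (acyclic).

    ``latent_names`` must be ordered so every edge points from an earlier
    to a later latent (the structural matrix is strictly lower-triangular).
    ``edges`` lists (source, target) pairs.
    """

    latent_names: list[str]
    blocks: Mapping[str, list[str]]
    edges: list[tuple[str, str]]
    inner_scheme: Literal["path", "centroid", "factorial"] = "path"
    max_iter: int = 300
    tol: float = 1e-6

    def __post_init__(self) -> None:
        idx = {n: i for i, n in enumerate(self.latent_names)}
        seen: set[str] = set()
        for latent in self.latent_names:
            inds = self.blocks.get(latent, [])
            if not inds:
                raise ValueError(f"latent {latent!r} has an empty indicator block")
            dup = seen.intersection(inds)
            if dup:
                raise ValueError(f"indicators in more than one block: {sorted(dup)}")
            seen.update(inds)
        for src, dst in self.edges:
            if idx[src] >= idx[dst]:
                raise ValueError(
                    f"edge {src}->{dst} is not forward in latent order (cycle?)")

    @property
    def adjacency(self) -> np.ndarray:
        """Boolean matrix: adjacency[i, j] True if edge j -> i exists."""
        idx = {n: i for i, n in enumerate(self.latent_names)}
        A = np.zeros((len(idx), len(idx)), dtype=bool)
        for src, dst in self.edges:
            A[idx[dst], idx[src]] = True
        return A

    def predecessors(self, latent: str) -> list[str]:
        return [s for s, d in self.edges if d == latent]

    @property
    def endogenous(self) -> list[str]:
        targets = {d for _, d in self.edges}
        return [n for n in self.latent_names if n in targets]


def default_path_model(inner_scheme: str = "path") -> PathModelSpec:
    """The four-hypothesis driving-mechanism model.

    Terrain (Ter), human activity (Hum), climate (Clm) and vegetation
    (Veg) drive the coupling coordination degree directly; terrain also
    acts through human activity and vegetation, human activity through
    climate and vegetation, and climate through vegetation.
    """
    from .synthetic import DRIVER_BLOCKS

    blocks = {**{k: list(v) for k, v in DRIVER_BLOCKS.items()}, "CCD": ["CCD"]}
    edges = [("Ter", "Hum"), ("Ter", "Veg"), ("Ter", "CCD"),
             ("Hum", "Clm"), ("Hum", "Veg"), ("Hum", "CCD"),
             ("Clm", "Veg"), ("Clm", "CCD"),
             ("Veg", "CCD")]
    return PathModelSpec(["Ter", "Hum", "Clm", "Veg", "CCD"], blocks, edges,
                         inner_scheme=inner_scheme)  # type: ignore[arg-type]


@dataclass
class PLSFit:
    """Fitted PLS path model."""

    spec: PathModelSpec
    outer_weights: dict[str, float]
    loadings: dict[str, float]
    scores: pd.DataFrame                      # n x latents, mean 0 / var 1
    path_coefficients: pd.DataFrame           # [target, source] structural matrix
    r2: dict[str, float]                      # per endogenous latent
    communality: dict[str, float]             # per indicator (loading²)
    block_communality: dict[str, float]
    gof: float
    gof_label: str
    n_iterations: int
    converged: bool

    @property
    def path_matrix(self) -> np.ndarray:
        return self.path_coefficients.to_numpy()


def _standardize(X: np.ndarray) -> np.ndarray:
    sd = X.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("constant indicator column")
    return (X - X.mean(axis=0)) / sd


def fit_pls_pm(table: pd.DataFrame, spec: PathModelSpec | None = None) -> PLSFit:
    """Estimate a PLS path model from an indicator table (Mode A blocks)."""
    spec = spec or default_path_model()
    names = spec.latent_names
    p = len(names)
    cols = [c for latent in names for c in spec.blocks[latent]]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"missing indicator columns: {missing}")
    data = table.loc[:, cols].dropna(axis=0)  # listwise deletion
    n = len(data)
    if n <= len(cols):
        raise ValueError("need more rows than indicators")
    X = _standardize(data.to_numpy(dtype=float))
    slices: dict[str, slice] = {}
    start = 0
    for latent in names:
        k = len(spec.blocks[latent])
        slices[latent] = slice(start, start + k)
        start += k

    adj = spec.adjacency
    neigh = adj | adj.T
    W = [np.ones(len(spec.blocks[latent])) for latent in names]

    def scores_from(weights: list[np.ndarray]) -> np.ndarray:
        Y = np.empty((n, p))
        for i, latent in enumerate(names):
            y = X[:, slices[latent]] @ weights[i]
            Y[:, i] = y / y.std()
        return Y

    converged = False
    it = 0
    w_norm = [w / np.linalg.norm(w) for w in W]
    for it in range(1, spec.max_iter + 1):
        Y = scores_from(W)
        R = (Y.T @ Y) / n  # score correlations
        E = np.zeros((p, p))
        if spec.inner_scheme == "centroid":
            E[neigh] = np.sign(R[neigh])
        elif spec.inner_scheme == "factorial":
            E[neigh] = R[neigh]
        else:  # path scheme
            for i in range(p):
                pred = np.where(adj[i])[0]
                if pred.size:
                    E[i, pred] = np.linalg.solve(R[np.ix_(pred, pred)], R[pred, i])
                succ = np.where(adj[:, i])[0]
                E[i, succ] = R[succ, i]
        Z = Y @ E.T
        new_W = []
        for i, latent in enumerate(names):
            z = Z[:, i]
            if not np.any(neigh[i]):  # isolated latent: keep its own score
                z = Y[:, i]
            w = X[:, slices[latent]].T @ z / n  # Mode A update
            new_W.append(w)
        new_norm = [w / np.linalg.norm(w) for w in new_W]
        delta = max(float(np.max(np.abs(a - b))) for a, b in zip(new_norm, w_norm))
        W, w_norm = new_W, new_norm
        if delta < spec.tol:
            converged = True
            break
    if not converged:
        warnings.warn("PLS-PM outer weights did not converge", stacklevel=2)

    Y = scores_from(W)
    loadings: dict[str, float] = {}
    outer_weights: dict[str, float] = {}
    for i, latent in enumerate(names):
        block_cols = spec.blocks[latent]
        lams = X[:, slices[latent]].T @ Y[:, i] / n
        if lams.sum() < 0:  # sign convention: dominant orientation positive
            W[i] = -W[i]
            Y[:, i] = -Y[:, i]
            lams = -lams
        for c, lam, w in zip(block_cols, lams, W[i]):
            loadings[c] = float(lam)
            outer_weights[c] = float(w / (np.linalg.norm(W[i]) or 1.0))

    B = np.zeros((p, p))
    r2: dict[str, float] = {}
    for i, latent in enumerate(names):
        pred = np.where(adj[i])[0]
        if pred.size == 0:
            continue
        R = (Y.T @ Y) / n
        try:
            beta = np.linalg.solve(R[np.ix_(pred, pred)], R[pred, i])
        except np.linalg.LinAlgError as exc:
            raise ValueError(f"singular structural regression for {latent}") from exc
        B[i, pred] = beta
        r2[latent] = float(beta @ R[pred, i])

    communality = {c: loadings[c] ** 2 for c in cols}
    block_comm = {latent: float(np.mean([communality[c] for c in spec.blocks[latent]]))
                  for latent in names}
    mean_comm = float(np.mean([communality[c] for c in cols]))
    mean_r2 = float(np.mean(list(r2.values()))) if r2 else 0.0
    gof = float(np.sqrt(max(mean_comm * mean_r2, 0.0)))

    return PLSFit(
        spec=spec,
        outer_weights=outer_weights,
        loadings=loadings,
        scores=pd.DataFrame(Y, columns=names, index=data.index),
        path_coefficients=pd.DataFrame(B, index=names, columns=names),
        r2=r2,
        communality=communality,
        block_communality=block_comm,
        gof=gof,
        gof_label=gof_label(gof)[1],
        n_iterations=it,
        converged=converged,
    )


def gof_label(value: float) -> tuple[float, str]:
    """GOF value with its qualitative label (boundaries closed from above)."""
    for thr, label in GOF_THRESHOLDS:
        if value >= thr:
            return value, label
    return value, "poor"


@dataclass
class EffectsTable:
    """Direct / indirect / total effects per ordered latent pair."""

    table: pd.DataFrame                        # columns: source, target, direct, indirect, total
    paths: dict[tuple[str, str], list[tuple[tuple[str, ...], float]]] = field(default_factory=dict)

    def effect(self, source: str, target: str, kind: str = "total") -> float:
        sel = self.table[(self.table.source == source) & (self.table.target == target)]
        return float(sel[kind].iloc[0]) if len(sel) else 0.0


def _enumerate_paths(adj_from: dict[str, list[str]], src: str, dst: str,
                     B: pd.DataFrame) -> list[tuple[tuple[str, ...], float]]:
    out: list[tuple[tuple[str, ...], float]] = []

    def walk(node: str, trail: tuple[str, ...], prod: float) -> None:
        if node == dst:
            out.append((trail, prod))
            return
        for nxt in adj_from.get(node, []):
            walk(nxt, trail + (nxt,), prod * float(B.loc[nxt, node]))

    for nxt in adj_from.get(src, []):
        walk(nxt, (src, nxt), float(B.loc[nxt, src]))
    return out


def effects(fit: PLSFit) -> EffectsTable:
    """Path-tracing effect decomposition; equals sum_{k>=1} B^k at each pair."""
    spec = fit.spec
    names = spec.latent_names
    B = fit.path_coefficients
    adj_from: dict[str, list[str]] = {}
    for src, dst in spec.edges:
        adj_from.setdefault(src, []).append(dst)
    rows = []
    paths: dict[tuple[str, str], list[tuple[tuple[str, ...], float]]] = {}
    for i, src in enumerate(names):
        for dst in names[i + 1:]:
            plist = _enumerate_paths(adj_from, src, dst, B)
            if not plist:
                continue
            direct = float(B.loc[dst, src])
            total = float(sum(prod for _, prod in plist))
            rows.append({"source": src, "target": dst, "direct": direct,
                         "indirect": total - direct, "total": total})
            paths[(src, dst)] = plist
    return EffectsTable(pd.DataFrame(rows, columns=["source", "target", "direct",
                                                    "indirect", "total"]), paths)


def total_effects_matrix(fit: PLSFit) -> pd.DataFrame:
    """Matrix identity sum_{k>=1} B^k (independent of path enumeration)."""
    B = fit.path_matrix
    total = np.zeros_like(B)
    power = np.eye(B.shape[0])
    for _ in range(B.shape[0]):
        power = power @ B
        total += power
    return pd.DataFrame(total, index=fit.spec.latent_names, columns=fit.spec.latent_names)


@dataclass
class BootstrapResult:
    """Per-path bootstrap inference (rows = edges)."""

    table: pd.DataFrame     # source, target, estimate, se, z, p, stars, ci_lo, ci_hi
    n_failed: int
    B: int

    def stars(self, source: str, target: str) -> str:
        sel = self.table[(self.table.source == source) & (self.table.target == target)]
        return str(sel["stars"].iloc[0]) if len(sel) else ""


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def bootstrap_inference(table: pd.DataFrame, spec: PathModelSpec | None = None,
                        B: int = 999, seed: int = 0,
                        base_fit: PLSFit | None = None) -> BootstrapResult:
    """Nonparametric bootstrap SEs, normal-approximation p-values and stars.

    Resamples rows with replacement, refits, aligns each resample's latent
    signs to the base fit block-by-block (flipping a latent flips its
    loadings and every structural coefficient touching it), and reads the
    per-edge SE off the aligned bootstrap distribution. Resamples whose
    fit fails are dropped and counted; more than 10% failures aborts.
    """
    spec = spec or default_path_model()
    if B < 100:
        raise ValueError("B must be at least 100")
    fit0 = base_fit if base_fit is not None else fit_pls_pm(table, spec)
    names = spec.latent_names
    idx = {n: i for i, n in enumerate(names)}
    base_load = {latent: np.array([fit0.loadings[c] for c in spec.blocks[latent]])
                 for latent in names}
    rng = np.random.default_rng(seed)
    n = len(table)
    draws = np.empty((B, len(spec.edges)))
    failed = 0
    kept = 0
    for b in range(B):
        sample = table.iloc[rng.integers(0, n, n)]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit_b = fit_pls_pm(sample, spec)
        except (ValueError, np.linalg.LinAlgError):
            failed += 1
            continue
        flip = np.ones(len(names))
        for latent in names:
            lam_b = np.array([fit_b.loadings[c] for c in spec.blocks[latent]])
            if float(lam_b @ base_load[latent]) < 0:
                flip[idx[latent]] = -1.0
        Bmat = fit_b.path_matrix * np.outer(flip, flip)
        draws[kept] = [Bmat[idx[d], idx[s]] for s, d in spec.edges]
        kept += 1
    if failed > 0.1 * B:
        raise RuntimeError(f"bootstrap failed on {failed}/{B} resamples")
    draws = draws[:kept]
    rows = []
    for j, (src, dst) in enumerate(spec.edges):
        est = float(fit0.path_coefficients.loc[dst, src])
        se = float(draws[:, j].std(ddof=1))
        z = est / se if se > 0 else np.inf * np.sign(est or 1)
        pval = float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else 0.0
        lo, hi = np.percentile(draws[:, j], [2.5, 97.5])
        rows.append({"source": src, "target": dst, "estimate": est, "se": se,
                     "z": float(z), "p": pval, "stars": _stars(pval),
                     "ci_lo": float(lo), "ci_hi": float(hi)})
    return BootstrapResult(pd.DataFrame(rows), n_failed=failed, B=B)
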