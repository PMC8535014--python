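"""Bayesian-framework logistic-regression gene prioritizer and ROC.

The prioritizer treats disease-gene identification as binary
classification on the integrated network:

1. *Priors.*  A candidate belonging to protein complexes gets prior
   P = A/B, where A counts focal-disease genes and B counts any-disease
   genes in the union of its complexes; candidates outside complexes (or
   with B = 0) fall back to P = C/D with C the number of known focal-
   disease genes and D the total number of human genes.  Known disease
   genes have prior 1.
2. *Labels.*  Each unknown gene draws u ~ U(0,1) and is labelled 1 iff
   u <= P; known genes are always 1.
3. *Features.*  phi_i = (1, phi_i1, phi_i0, phi_i1', phi_i0'): counts of
   label-1/label-0 direct neighbours and of label-1/label-0 nodes at
   shortest-path distance exactly 2.
4. *Fit.*  Logistic regression by penalised maximum likelihood
   (Newton iterations with step halving; a small ridge keeps the optimum
   finite under complete separation).
5. *Posterior and decision score.*  P_i = sigmoid(w' phi_i); the decision
   score is the percentile q_i = |{j : P_i >= P_j}| / n.

A single label draw makes results seed-dependent, so the integrated run
averages posteriors over repeated label draws (default 50); one
repetition reproduces the single-pass procedure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from sklearn.metrics import roc_curve

from .graphio import ComplexCatalog, DiseaseCatalog, GeneNetwork

logger = logging.getLogger(__name__)


@dataclass
class PriorVector:
    priors: dict[str, float]
    known: set[str]

    def __post_init__(self) -> None:
        for g, p in self.priors.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prior of {g!r} outside [0, 1]")
        for g in self.known:
            if self.priors.get(g) != 1.0:
                raise ValueError(f"known gene {g!r} must have prior 1")


@dataclass
class LabelVector:
    labels: dict[str, int]
    known: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for g in self.known:
            if self.labels.get(g) != 1:
                raise ValueError(f"known gene {g!r} must have label 1")


@dataclass
class FeatureMatrix:
    """Per-gene feature rows (1, phi_1, phi_0, phi_1', phi_0')."""

    genes: list[str]
    rows: np.ndarray

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=float)
        if self.rows.shape != (len(self.genes), 5):
            raise ValueError("feature matrix must be n_genes x 5")
        if not np.allclose(self.rows[:, 0], 1.0):
            raise ValueError("first feature must be the intercept 1")


@dataclass
class WeightVector:
    w: np.ndarray
    converged: bool
    iterations: int
    ll_path: list[float] = field(default_factory=list)


@dataclass
class PosteriorResult:
    posteriors: dict[str, float]
    scores: dict[str, float]
    n_scored: int


@dataclass
class RocCurve:
    points: np.ndarray  # (FPR, TPR) pairs from (0,0) to (1,1)
    auc: float


# ---------------------------------------------------------------------------
# priors and labels
# ---------------------------------------------------------------------------


def complex_priors(
    candidates: set[str],
    cat: ComplexCatalog,
    dis: DiseaseCatalog,
    combine: str = "union",
) -> PriorVector:
    """Complex-informed disease priors.

    ``combine='union'`` pools the member unions of all complexes a gene
    belongs to before computing A/B; ``'max'`` takes the maximum per-
    complex A/B instead.
    """
    if dis.total_human_genes <= 0:
        raise ValueError("total_human_genes must be positive")
    focal = dis.focal_genes
    all_disease = dis.all_disease_genes()
    fallback = len(focal) / dis.total_human_genes  # C / D
    membership: dict[str, list[str]] = {}
    for cid, members in cat.complexes.items():
        for g in members:
            membership.setdefault(g, []).append(cid)

    priors: dict[str, float] = {}
    known = candidates & focal
    for g in sorted(candidates):
        if g in focal:
            priors[g] = 1.0
            continue
        cids = membership.get(g)
        if not cids:
            priors[g] = fallback
            continue
        if combine == "union":
            pool: set[str] = set()
            for cid in cids:
                pool |= cat.complexes[cid]
            a = len(pool & focal)
            b = len(pool & all_disease)
            priors[g] = a / b if b > 0 else fallback
        elif combine == "max":
            best = None
            for cid in cids:
                members = cat.complexes[cid]
                b = len(members & all_disease)
                if b > 0:
                    ratio = len(members & focal) / b
                    best = ratio if best is None else max(best, ratio)
            priors[g] = fallback if best is None else best
        else:
            raise ValueError(f"unknown combine mode {combine!r}")
    return PriorVector(priors=priors, known=known)


def sample_labels(pr: PriorVector, seed: int) -> LabelVector:
    """Label 1 iff u <= P_i with u ~ U(0,1); known genes always 1."""
    rng = np.random.default_rng(seed)
    labels: dict[str, int] = {}
    for g in sorted(pr.priors):
        if g in pr.known:
            labels[g] = 1
        else:
            labels[g] = int(rng.uniform() <= pr.priors[g])
    return LabelVector(labels=labels, known=set(pr.known))


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------


def _neighbor_matrices(net: GeneNetwork, nodes: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Boolean adjacency and exact-distance-2 indicator matrices."""
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    a = np.zeros((n, n), dtype=bool)
    for u, v in net.iter_edges():
        a[idx[u], idx[v]] = True
        a[idx[v], idx[u]] = True
    two = (a.astype(np.int64) @ a.astype(np.int64)) > 0
    np.fill_diagonal(two, False)
    a2 = two & ~a
    return a, a2


def build_features(net: GeneNetwork, lab: LabelVector) -> FeatureMatrix:
    """Feature rows (1, phi_1, phi_0, phi_1', phi_0') for every node."""
    nodes = sorted(net.nodes)
    missing = [v for v in nodes if v not in lab.labels]
    if missing:
        raise ValueError(f"unlabeled node(s): {missing[:5]}")
    a, a2 = _neighbor_matrices(net, nodes)
    x = np.array([lab.labels[v] for v in nodes], dtype=float)
    rows = np.column_stack(
        [
            np.ones(len(nodes)),
            a @ x,
            a @ (1.0 - x),
            a2 @ x,
            a2 @ (1.0 - x),
        ]
    )
    return FeatureMatrix(genes=nodes, rows=rows)


# ---------------------------------------------------------------------------
# logistic fit
# ---------------------------------------------------------------------------


def _log_likelihood(phi: np.ndarray, x: np.ndarray, w: np.ndarray, ridge: float) -> float:
    f = phi @ w
    return float(np.sum(x * f - np.logaddexp(0.0, f)) - ridge * np.dot(w, w))


def fit_logistic(
    F: FeatureMatrix,
    lab: LabelVector,
    ridge: float = 1e-6,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> WeightVector:
    """Penalised-MLE logistic fit by Newton iterations with step halving.

    Maximises sum_i [x_i w'phi_i - ln(1 + e^{w'phi_i})] - ridge ||w||^2;
    the penalised objective is recorded per iteration and never decreases.
    """
    phi = F.rows
    x = np.array([float(lab.labels[g]) for g in F.genes])
    w = np.zeros(phi.shape[1])
    ll = _log_likelihood(phi, x, w, ridge)
    path = [ll]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        p = expit(phi @ w)
        grad = phi.T @ (x - p) - 2.0 * ridge * w
        if np.linalg.norm(grad) < tol:
            converged = True
            break
        weights = np.clip(p * (1.0 - p), 1e-12, None)
        hess = (phi * weights[:, None]).T @ phi + 2.0 * ridge * np.eye(phi.shape[1])
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:  # pragma: no cover - degenerate Hessian
            step = np.linalg.lstsq(hess, grad, rcond=None)[0]
        t = 1.0
        while t > 1e-10:
            cand = _log_likelihood(phi, x, w + t * step, ridge)
            if cand >= ll - 1e-12:
                break
            t /= 2.0
        w = w + t * step
        ll = max(cand, ll)
        path.append(ll)
    if not converged:
        logger.warning("logistic fit did not converge in %d iterations", max_iter)
    return WeightVector(w=w, converged=converged, iterations=it, ll_path=path)


def posterior(F: FeatureMatrix, w: WeightVector) -> dict[str, float]:
    """Sigmoid posteriors P(x_i = 1 | phi_i), overflow-safe."""
    p = expit(F.rows @ w.w)
    return {g: float(v) for g, v in zip(F.genes, p)}


def decision_scores(posteriors: dict[str, float]) -> PosteriorResult:
    """Percentile decision scores q_i = |{j : P_i >= P_j}| / n."""
    if not posteriors:
        raise ValueError("no posteriors to score")
    genes = sorted(posteriors)
    vals = np.array([posteriors[g] for g in genes])
    order = np.sort(vals)
    n = len(vals)
    q = np.searchsorted(order, vals, side="right") / n
    return PosteriorResult(
        posteriors={g: float(v) for g, v in zip(genes, vals)},
        scores={g: float(s) for g, s in zip(genes, q)},
        n_scored=n,
    )


# ---------------------------------------------------------------------------
# integrated run and ROC
# ---------------------------------------------------------------------------


def run_integrated(
    net: GeneNetwork,
    cat: ComplexCatalog,
    dis: DiseaseCatalog,
    reps: int = 50,
    seed: int = 0,
    ridge: float = 1e-6,
    combine: str = "union",
) -> PosteriorResult:
    """Full prioritizer: priors -> (labels -> features -> fit -> posterior)
    averaged over ``reps`` label draws, then percentile decision scores."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    nodes = sorted(net.nodes)
    if not nodes:
        raise ValueError("empty network")
    priors = complex_priors(set(nodes), cat, dis, combine=combine)
    a, a2 = _neighbor_matrices(net, nodes)
    known = priors.known
    pvec = np.array([priors.priors[g] for g in nodes])
    is_known = np.array([g in known for g in nodes])

    master = np.random.default_rng(seed)
    rep_seeds = master.integers(0, 2**31 - 1, size=reps)
    acc = np.zeros(len(nodes))
    ones = np.ones(len(nodes))
    for rs in rep_seeds:
        rng = np.random.default_rng(int(rs))
        u = rng.uniform(size=len(nodes))
        x = np.where(is_known, 1.0, (u <= pvec).astype(float))
        phi = np.column_stack([ones, a @ x, a @ (1.0 - x), a2 @ x, a2 @ (1.0 - x)])
        fmat = FeatureMatrix(genes=nodes, rows=phi)
        lvec = LabelVector(labels={g: int(v) for g, v in zip(nodes, x)})
        wv = fit_logistic(fmat, lvec, ridge=ridge)
        acc += expit(phi @ wv.w)
    acc /= reps
    return decision_scores({g: float(p) for g, p in zip(nodes, acc)})


def roc_auc(
    scores: dict[str, float], positives: set[str], negatives: set[str]
) -> RocCurve:
    """ROC threshold sweep and trapezoidal AUC over labelled controls.

    The AUC equals the tie-corrected Mann-Whitney statistic on the
    positive/negative score samples.
    """
    if positives & negatives:
        raise ValueError("positives and negatives overlap")
    if not positives or not negatives:
        raise ValueError("both control sets must be non-empty")
    missing = (positives | negatives) - set(scores)
    if missing:
        raise ValueError(f"unscored control gene(s): {sorted(missing)[:5]}")
    labelled = sorted(positives | negatives)
    y = np.array([1 if g in positives else 0 for g in labelled])
    s = np.array([scores[g] for g in labelled])
    fpr, tpr, _ = roc_curve(y, s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(points=np.column_stack([fpr, tpr]), auc=auc)
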