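"""Kmer-SVM training, cross-validation, weight extraction and scoring.

The classifier is a soft-margin SVM over the strand-collapsed kmer feature
map of :mod:`kmersvm.kmerfeat`.  Because the spectrum kernel is the inner
product of that explicit map, training a linear SVM on the stacked feature
matrix is mathematically identical to the kernelized dual problem — and the
primal coefficient vector *is* the table of per-kmer weights that makes the
model interpretable.  The equivalence (primal weight scores vs the dual
support-vector expansion) is exposed on the model and checked in the tests.

Class imbalance is handled by a positive-set weight PSW: the misclassification
cost is C·PSW for positives and C for negatives, with the default
PSW = 1 + ln(N/P) growing logarithmically with the negative/positive ratio
(floored at 1 when the positives outnumber the negatives).

Cross-validation is stratified and seeded; every input sequence is scored
exactly once as a held-out test item, and those pooled held-out scores are
what both the performance curves and the posterior calibration consume.
Calibration is Platt scaling — a sigmoid P(+|s) = 1/(1 + exp(A·s + B)) fitted
by regularized maximum likelihood with the standard numerically stable
Newton iteration — so that scores from arbitrary query sequences can be
reported as posterior probabilities.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .kmerfeat import (
    FeatureVector,
    KmerFeatureSpace,
    build_feature_space,
    featurize,
    featurize_matrix,
    reverse_complement,
)
from .seqio import GenomicInterval, SequenceRecord, load_genome, GenomeLike

__all__ = [
    "TrainConfig",
    "SVMModel",
    "CVPrediction",
    "auto_psw",
    "train",
    "cross_validate",
    "extract_weights",
    "fit_posterior",
    "score_sequences",
    "split_genome",
    "save_weights",
    "load_weights",
]


@dataclass(frozen=True)
class TrainConfig:
    """SVM training configuration.

    kernel   "spectrum" (single k) or "weighted_spectrum" (k_min..k_max,
             equal weighting).
    k        kmer length for the spectrum kernel (default 6).
    C        misclassification cost for negatives; positives cost C*psw.
    E        solver termination tolerance; looser E means fewer support
             vectors and a cheaper, slightly less exact fit.
    psw      positive-set weight, or "auto" for 1 + ln(N/P).
    n_folds  cross-validation folds (stratified).
    seed     seed for fold assignment (the solver itself is deterministic).
    """

    kernel: str = "spectrum"
    k: int = 6
    k_min: int | None = None
    k_max: int | None = None
    C: float = 1.0
    E: float = 1e-5
    psw: Union[float, str] = "auto"
    n_folds: int = 5
    seed: int = 1

    def __post_init__(self) -> None:
        if self.kernel not in ("spectrum", "weighted_spectrum"):
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if self.kernel == "weighted_spectrum":
            if self.k_min is None or self.k_max is None or self.k_min > self.k_max:
                raise ValueError("weighted_spectrum requires k_min <= k_max")
        if self.C <= 0 or self.E <= 0:
            raise ValueError("C and E must be positive")
        if self.psw != "auto" and float(self.psw) <= 0:
            raise ValueError("psw must be positive or 'auto'")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")

    @property
    def k_values(self) -> tuple[int, ...]:
        if self.kernel == "spectrum":
            return (self.k,)
        return tuple(range(self.k_min, self.k_max + 1))

    def feature_space(self) -> KmerFeatureSpace:
        return build_feature_space(self.k_values)


def auto_psw(P: int, N: int) -> float:
    """Default positive-set weight: 1 + ln(N/P), floored at 1.

    Weighs positives more heavily when the negative set is large; the floor
    keeps the weight from dropping below 1 when positives outnumber
    negatives.
    """
    if P < 1 or N < 1:
        raise ValueError("both class counts must be >= 1")
    return max(1.0, 1.0 + math.log(N / P))


@dataclass
class CVPrediction:
    """Held-out score of one sequence from one cross-validation round."""

    seq_id: str
    fold: int
    svm_score: float
    true_label: int


@dataclass
class SVMModel:
    """A trained kmer-SVM: per-kmer weights, bias, and calibration.

    ``weights`` lives in the canonical-kmer coordinate system of
    ``feature_space``; score(x) = weights . featurize(x) + bias.  The dual
    representation (support vectors and their coefficients) is retained so
    the primal/dual score identity can be verified.
    """

    feature_space: KmerFeatureSpace
    weights: np.ndarray
    bias: float
    config: TrainConfig
    n_pos: int
    n_neg: int
    psw: float
    posterior_A: float | None = None
    posterior_B: float | None = None
    support_vectors: np.ndarray | None = field(default=None, repr=False)
    dual_coef: np.ndarray | None = field(default=None, repr=False)

    # -- scoring ----------------------------------------------------------
    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return X @ self.weights + self.bias

    def decision_function_dual(self, X: np.ndarray) -> np.ndarray:
        """Score via the support-vector kernel expansion (identity check)."""
        if self.support_vectors is None or self.dual_coef is None:
            raise ValueError("model carries no dual representation")
        return (self.dual_coef @ (self.support_vectors @ X.T)).ravel() + self.bias

    def score_record(self, record: Union[SequenceRecord, str]) -> float:
        fv = featurize(record, self.feature_space)
        return float(fv.values @ self.weights + self.bias)

    def posterior(self, scores: np.ndarray) -> np.ndarray:
        """Platt posterior P(positive | score); requires calibration."""
        if self.posterior_A is None or self.posterior_B is None:
            raise ValueError("model is not calibrated; fit_posterior first")
        z = self.posterior_A * np.asarray(scores, dtype=float) + self.posterior_B
        # stable sigmoid: 1 / (1 + exp(z))
        out = np.empty_like(z, dtype=float)
        pos = z >= 0
        out[pos] = np.exp(-z[pos]) / (1.0 + np.exp(-z[pos]))
        out[~pos] = 1.0 / (1.0 + np.exp(z[~pos]))
        return out


def _as_matrix(
    vectors: Union[np.ndarray, Sequence[FeatureVector]],
    space: KmerFeatureSpace,
) -> np.ndarray:
    if isinstance(vectors, np.ndarray):
        if vectors.ndim != 2 or vectors.shape[1] != space.n_features:
            raise ValueError("feature matrix does not match the feature space")
        return vectors
    if len(vectors) == 0:
        raise ValueError("empty sequence set")
    for fv in vectors:
        if fv.space != space:
            raise ValueError("mixed feature spaces in input")
    return np.vstack([fv.values for fv in vectors])


def _resolve_psw(config: TrainConfig, P: int, N: int) -> float:
    if config.psw == "auto":
        return auto_psw(P, N)
    return float(config.psw)


def train(
    pos: Union[np.ndarray, Sequence[FeatureVector]],
    neg: Union[np.ndarray, Sequence[FeatureVector]],
    config: TrainConfig | None = None,
    space: KmerFeatureSpace | None = None,
) -> SVMModel:
    """Train a kmer-SVM on featurized positive and negative sets.

    Inputs may be lists of :class:`FeatureVector` or prebuilt matrices (with
    ``space`` given).  The solver works in the explicit canonical-kmer space
    with per-class costs C·PSW (positives) and C (negatives); tolerance is
    driven by E.  Deterministic for fixed inputs and config.
    """
    config = config or TrainConfig()
    if space is None:
        if isinstance(pos, np.ndarray):
            raise ValueError("space must be given when passing raw matrices")
        space = pos[0].space if len(pos) else None
        if space is None:
            raise ValueError("empty positive set")
    Xp = _as_matrix(pos, space)
    Xn = _as_matrix(neg, space)
    P, N = Xp.shape[0], Xn.shape[0]
    psw = _resolve_psw(config, P, N)

    X = np.vstack([Xp, Xn])
    y = np.concatenate([np.ones(P), -np.ones(N)])
    svc = SVC(
        kernel="linear",
        C=config.C,
        tol=config.E,
        class_weight={1: psw, -1: 1.0},
        cache_size=500,
        shrinking=True,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # libsvm convergence chatter on degenerate toys
        svc.fit(X, y)

    return SVMModel(
        feature_space=space,
        weights=svc.coef_.ravel().copy(),
        bias=float(svc.intercept_[0]),
        config=config,
        n_pos=P,
        n_neg=N,
        psw=psw,
        support_vectors=svc.support_vectors_.copy(),
        dual_coef=svc.dual_coef_.copy(),
    )


def cross_validate(
    pos: Union[np.ndarray, Sequence[FeatureVector]],
    neg: Union[np.ndarray, Sequence[FeatureVector]],
    config: TrainConfig | None = None,
    space: KmerFeatureSpace | None = None,
    pos_ids: Sequence[str] | None = None,
    neg_ids: Sequence[str] | None = None,
) -> list[CVPrediction]:
    """Stratified n-fold CV; every sequence is scored once as a test item.

    Fold assignment is seeded from the config; per-fold models are trained
    with the same configuration as the full model.
    """
    config = config or TrainConfig()
    if space is None:
        if isinstance(pos, np.ndarray):
            raise ValueError("space must be given when passing raw matrices")
        space = pos[0].space
    Xp = _as_matrix(pos, space)
    Xn = _as_matrix(neg, space)
    P, N = Xp.shape[0], Xn.shape[0]
    if config.n_folds > min(P, N):
        raise ValueError(
            f"n_folds={config.n_folds} exceeds the smaller class size {min(P, N)}"
        )
    ids = list(pos_ids) if pos_ids is not None else [f"pos_{i}" for i in range(P)]
    ids += list(neg_ids) if neg_ids is not None else [f"neg_{i}" for i in range(N)]

    X = np.vstack([Xp, Xn])
    y = np.concatenate([np.ones(P, dtype=int), -np.ones(N, dtype=int)])
    skf = StratifiedKFold(
        n_splits=config.n_folds, shuffle=True, random_state=config.seed
    )
    predictions: list[CVPrediction] = []
    for fold, (train_idx, test_idx) in enumerate(skf.split(X, y)):
        model = train(
            X[train_idx][y[train_idx] == 1],
            X[train_idx][y[train_idx] == -1],
            config,
            space=space,
        )
        scores = model.decision_function(X[test_idx])
        for i, s in zip(test_idx, scores):
            predictions.append(
                CVPrediction(
                    seq_id=ids[i], fold=fold, svm_score=float(s),
                    true_label=int(y[i]),
                )
            )
    return predictions


def extract_weights(model: SVMModel) -> pd.DataFrame:
    """Ranked weight table: every canonical kmer, weight-descending.

    Ties break lexicographically on the kmer so the table is deterministic.
    Columns: kmer, revcomp, weight.
    """
    kmers = model.feature_space.kmers
    df = pd.DataFrame(
        {
            "kmer": kmers,
            "revcomp": [reverse_complement(k) for k in kmers],
            "weight": model.weights,
        }
    )
    return (
        df.sort_values(["weight", "kmer"], ascending=[False, True])
        .reset_index(drop=True)
    )


# ---------------------------------------------------------------------------
# Platt posterior calibration
# ---------------------------------------------------------------------------

def fit_posterior(
    predictions: Union[Sequence[CVPrediction], tuple[np.ndarray, np.ndarray]],
) -> tuple[float, float]:
    """Fit Platt sigmoid parameters (A, B) on held-out scores.

    P(+|s) = 1 / (1 + exp(A·s + B)), fitted by regularized maximum
    likelihood with Bayesian-prior targets (P+1)/(P+2) and 1/(N+2) on the
    two classes, using a damped Newton iteration on the stable form of the
    cross-entropy.  A is negative whenever higher scores favor the positive
    class.
    """
    if isinstance(predictions, tuple):
        scores, labels = (np.asarray(a, dtype=float) for a in predictions)
    else:
        scores = np.array([p.svm_score for p in predictions], dtype=float)
        labels = np.array([p.true_label for p in predictions], dtype=float)
    pos_mask = labels > 0
    n1, n0 = int(pos_mask.sum()), int((~pos_mask).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("posterior calibration needs scores from both classes")

    hi = (n1 + 1.0) / (n1 + 2.0)
    lo = 1.0 / (n0 + 2.0)
    t = np.where(pos_mask, hi, lo)

    A, B = 0.0, math.log((n0 + 1.0) / (n1 + 1.0))
    sigma = 1e-12  # Hessian damping

    def _objective(a: float, b: float) -> float:
        z = a * scores + b
        # t*z + log(1 + exp(-z)) computed stably on both branches
        return float(
            np.sum(np.where(z >= 0, t * z + np.log1p(np.exp(-z)),
                            (t - 1.0) * z + np.log1p(np.exp(z))))
        )

    fval = _objective(A, B)
    for _ in range(100):
        z = A * scores + B
        p = np.where(z >= 0, np.exp(-z) / (1 + np.exp(-z)), 1 / (1 + np.exp(z)))
        d1 = t - p                       # dF/dz per point
        d2 = p * (1 - p)
        g_a = float(np.dot(d1, scores))
        g_b = float(np.sum(d1))
        if abs(g_a) < 1e-10 and abs(g_b) < 1e-10:
            break
        h11 = float(np.dot(d2, scores * scores)) + sigma
        h22 = float(np.sum(d2)) + sigma
        h12 = float(np.dot(d2, scores))
        det = h11 * h22 - h12 * h12
        dA = -(h22 * g_a - h12 * g_b) / det
        dB = -(-h12 * g_a + h11 * g_b) / det
        # backtracking line search on the gradient direction
        step = 1.0
        gd = g_a * dA + g_b * dB
        while step >= 1e-10:
            newA, newB = A + step * dA, B + step * dB
            newf = _objective(newA, newB)
            if newf < fval + 1e-4 * step * gd:
                A, B, fval = newA, newB, newf
                break
            step /= 2.0
        else:
            break
    return A, B


def calibrate(model: SVMModel, predictions: Sequence[CVPrediction]) -> SVMModel:
    """Return a copy of the model carrying fitted posterior parameters."""
    A, B = fit_posterior(predictions)
    return replace(model, posterior_A=A, posterior_B=B)


def score_sequences(
    records: Iterable[Union[SequenceRecord, str]],
    model: SVMModel,
) -> pd.DataFrame:
    """Score query sequences: columns (seq_id, svm_score, posterior, flagged).

    Sequences shorter than the smallest k featurize to the zero vector and
    score at the bias; these rows are flagged.  Posterior is NaN when the
    model is not calibrated.
    """
    min_k = min(model.feature_space.k_values)
    rows = []
    for i, rec in enumerate(records):
        if isinstance(rec, str):
            rec = SequenceRecord(f"seq_{i}", rec)
        fv = featurize(rec, model.feature_space)
        flagged = fv.norm == 0.0 or len(rec.sequence) < min_k
        if flagged:
            warnings.warn(
                f"sequence {rec.id!r} has no countable kmer window; "
                "score equals the model bias",
                stacklevel=2,
            )
        rows.append((rec.id, float(fv.values @ model.weights + model.bias), flagged))
    df = pd.DataFrame(rows, columns=["seq_id", "svm_score", "flagged"])
    if model.posterior_A is not None:
        df["posterior"] = model.posterior(df["svm_score"].to_numpy())
    else:
        df["posterior"] = np.nan
    return df[["seq_id", "svm_score", "posterior", "flagged"]]


def split_genome(
    genome: Union[GenomeLike, dict[str, int]],
    chunk: int,
    overlap: int,
) -> list[GenomicInterval]:
    """Tile each chromosome with windows of length `chunk` overlapping by
    `overlap` bp (step = chunk − overlap).

    A trailing shorter window is emitted only when at least chunk/2 bp of the
    chromosome would otherwise remain uncovered, avoiding near-empty windows
    at chromosome ends.
    """
    if not (0 <= overlap < chunk):
        raise ValueError(f"need 0 <= overlap < chunk, got {overlap} >= {chunk}")
    if isinstance(genome, dict) and genome and isinstance(
        next(iter(genome.values())), int
    ):
        lengths = dict(genome)
    else:
        lengths = {name: len(seq) for name, seq in load_genome(genome).items()}

    step = chunk - overlap
    windows: list[GenomicInterval] = []
    for chrom, length in lengths.items():
        covered = 0
        start = 0
        while start + chunk <= length:
            windows.append(GenomicInterval(chrom, start, start + chunk))
            covered = start + chunk
            start += step
        if length - covered >= chunk / 2 and start < length:
            windows.append(GenomicInterval(chrom, start, length))
    return windows


# ---------------------------------------------------------------------------
# Weights table persistence
# ---------------------------------------------------------------------------

def save_weights(model: SVMModel, path: Union[str, Path]) -> None:
    """Write the ranked weight table with calibration/config header lines."""
    df = extract_weights(model)
    cfg = model.config
    header = io.StringIO()
    a = model.posterior_A if model.posterior_A is not None else float("nan")
    b = model.posterior_B if model.posterior_B is not None else float("nan")
    header.write(f"#A={a!r}\n#B={b!r}\n#bias={model.bias!r}\n")
    header.write(
        "#config=kernel:{};k_values:{};C:{};E:{};psw:{};n_folds:{};seed:{};"
        "n_pos:{};n_neg:{}\n".format(
            cfg.kernel, ",".join(map(str, cfg.k_values)), cfg.C, cfg.E,
            model.psw, cfg.n_folds, cfg.seed, model.n_pos, model.n_neg,
        )
    )
    with open(path, "w") as fh:
        fh.write(header.getvalue())
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def load_weights(path: Union[str, Path]) -> SVMModel:
    """Rebuild a scoring model (no dual representation) from a weights table."""
    meta: dict[str, str] = {}
    lines = Path(path).read_text().splitlines(keepends=True)
    n_header = 0
    for line in lines:
        if not line.startswith("#"):
            break
        key, _, value = line[1:].strip().partition("=")
        meta[key] = value
        n_header += 1
    df = pd.read_csv(io.StringIO("".join(lines[n_header:])), sep="\t")
    cfg_fields = dict(
        item.split(":", 1) for item in meta.get("config", "").split(";") if item
    )
    k_values = tuple(int(k) for k in cfg_fields["k_values"].split(","))
    if len(k_values) == 1:
        config = TrainConfig(
            kernel="spectrum", k=k_values[0],
            C=float(cfg_fields["C"]), E=float(cfg_fields["E"]),
            psw=float(cfg_fields["psw"]), n_folds=int(cfg_fields["n_folds"]),
            seed=int(cfg_fields["seed"]),
        )
    else:
        config = TrainConfig(
            kernel="weighted_spectrum", k_min=k_values[0], k_max=k_values[-1],
            C=float(cfg_fields["C"]), E=float(cfg_fields["E"]),
            psw=float(cfg_fields["psw"]), n_folds=int(cfg_fields["n_folds"]),
            seed=int(cfg_fields["seed"]),
        )
    space = build_feature_space(k_values)
    weights = np.zeros(space.n_features)
    for kmer, w in zip(df["kmer"], df["weight"]):
        weights[space.index_of(kmer)] = w
    A = float(meta.get("A", "nan"))
    B = float(meta.get("B", "nan"))
    return SVMModel(
        feature_space=space,
        weights=weights,
        bias=float(meta["bias"]),
        config=config,
        n_pos=int(cfg_fields.get("n_pos", 0)),
        n_neg=int(cfg_fields.get("n_neg", 0)),
        psw=float(cfg_fields["psw"]),
        posterior_A=None if math.isnan(A) else A,
        posterior_B=None if math.isnan(B) else B,
    )
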