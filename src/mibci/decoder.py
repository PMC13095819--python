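"""The calibration core: CSP spatial filtering, log-variance features, LDA
classification, run-wise cross-validation and the 70% competence gate.

Multiclass CSP uses one-vs-rest generalized eigendecompositions: for each
class the eigenproblem of (class covariance, class + rest covariance) is
solved, eigenvalues near 0 or 1 marking directions whose variance ratio
discriminates that class.  Filters are retained round-robin across classes
by eigenvalue extremeness, up to ``n_components`` (default 6), with
near-duplicate directions skipped.  Features are log-variances of the
spatially filtered windows; classification is pooled-covariance linear
discriminant analysis (scikit-learn), with shrinkage engaged automatically
when covariances are ill-conditioned.

Cross-validation folds by *run* (series): all windows of a run stay
together, so overlapping windows of one trial can never leak across folds.
Accuracy is the ratio of correct window decisions to total decisions; the
trial-level variant (majority vote over a trial's windows) is optional.
"""

from __future__ import annotations

import datetime as _dt
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import linalg
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .recording import LabeledWindowSet, canonical_class_order

EPS_VAR = 1e-12
COND_MAX = 1e8  # shrinkage trigger for covariance conditioning


# ---------------------------------------------------------------------------
# CSP
# ---------------------------------------------------------------------------

@dataclass
class SpatialFilterBank:
    """CSP filters W (components x channels), patterns A = pinv(W)
    (channels x components) and per-component discriminability scores."""

    filters: np.ndarray
    patterns: np.ndarray
    component_scores: np.ndarray  # |2*lambda - 1| in [0, 1]
    component_class: list[str]    # the one-vs-rest class each filter serves
    channel_names: list[str]

    def __post_init__(self):
        k, n_ch = self.filters.shape
        if k > n_ch:
            raise ValueError("more components than channels")
        if np.max(np.abs(self.filters @ self.patterns - np.eye(k))) > 1e-6:
            raise ValueError("patterns are not a right inverse of the filters")

    @property
    def n_components(self) -> int:
        return self.filters.shape[0]

    def apply(self, windows: np.ndarray) -> np.ndarray:
        """Spatially filter windows -> (n, components, samples)."""
        return np.einsum("kc,ncs->nks", self.filters, windows)


def _shrink(cov: np.ndarray, gamma: float = 0.1) -> np.ndarray:
    mu = np.trace(cov) / cov.shape[0]
    return (1 - gamma) * cov + gamma * mu * np.eye(cov.shape[0])


def _class_covariances(ws: LabeledWindowSet) -> dict[str, np.ndarray]:
    """Per-class covariance: the average of per-window sample covariances."""
    covs = {}
    X = ws.windows - ws.windows.mean(axis=-1, keepdims=True)
    nsamp = X.shape[-1]
    for cls in ws.classes:
        idx = ws.labels == cls
        c = np.einsum("ncs,nds->cd", X[idx], X[idx]) / (idx.sum() * (nsamp - 1))
        if np.linalg.cond(c) > COND_MAX:
            c = _shrink(c)
        covs[cls] = c
    return covs


def csp_eigen(cov_class: np.ndarray, cov_rest: np.ndarray):
    """One-vs-rest generalized eigendecomposition.

    Solves ``cov_class w = lambda (cov_class + cov_rest) w``; eigenvalues lie
    in (0, 1), 0.5 meaning no variance contrast along that direction.
    Returns eigenvalues (ascending) and eigenvectors as columns.
    """
    a, b = cov_class, cov_class + cov_rest
    try:
        evals, evecs = linalg.eigh(a, b)
    except linalg.LinAlgError:
        evals, evecs = linalg.eigh(_shrink(a), _shrink(b))
    return evals, evecs


def fit_csp(ws: LabeledWindowSet, n_components: int = 6) -> SpatialFilterBank:
    """Fit a one-vs-rest CSP filter bank on labeled windows.

    Filters are ranked per class by eigenvalue extremeness ``|2l - 1|`` and
    retained round-robin across classes until ``n_components`` are
    collected; directions nearly collinear with an already retained filter
    are skipped (one-vs-rest problems of a 2-class set are mirror images).
    """
    classes = ws.classes
    if len(classes) < 2:
        raise ValueError("CSP needs at least 2 classes")
    n_ch = ws.windows.shape[1]
    for cls in classes:
        n_cls = int(np.sum(ws.labels == cls))
        if n_cls < max(2, n_ch // 4):
            raise ValueError(f"class {cls!r} has {n_cls} windows; need at "
                             f"least {max(2, n_ch // 4)} for {n_ch} channels")
    if n_components > n_ch:
        raise ValueError("n_components cannot exceed the channel count")
    covs = _class_covariances(ws)
    # Per class: candidate filters sorted by extremeness.
    candidates = {}
    for cls in classes:
        rest = np.mean([covs[c] for c in classes if c != cls], axis=0)
        evals, evecs = csp_eigen(covs[cls], rest)
        order = np.argsort(-np.abs(2 * evals - 1))
        candidates[cls] = [(np.abs(2 * evals[i] - 1), evecs[:, i]) for i in order]

    filters, scores, comp_class = [], [], []
    cursors = {cls: 0 for cls in classes}

    def is_duplicate(w):
        for f in filters:
            c = abs(w @ f) / (np.linalg.norm(w) * np.linalg.norm(f))
            if c > 1 - 1e-6:
                return True
        return False

    while len(filters) < n_components:
        progressed = False
        for cls in classes:
            if len(filters) >= n_components:
                break
            cand = candidates[cls]
            while cursors[cls] < len(cand):
                score, w = cand[cursors[cls]]
                cursors[cls] += 1
                if not is_duplicate(w):
                    filters.append(w)
                    scores.append(score)
                    comp_class.append(cls)
                    progressed = True
                    break
        if not progressed:
            break  # every remaining candidate is a duplicate
    W = np.array(filters)
    A = np.linalg.pinv(W)
    return SpatialFilterBank(filters=W, patterns=A,
                             component_scores=np.array(scores),
                             component_class=comp_class,
                             channel_names=list(ws.channel_names))


def csp_features(windows, bank: SpatialFilterBank) -> np.ndarray:
    """Log-variance features: ``feature[i, j] = log(var(w_j . x_i))``.

    Accepts a window stack or a :class:`LabeledWindowSet`.  Constant windows
    are floored at ``log(1e-12)`` with a warning rather than -inf.
    """
    if isinstance(windows, LabeledWindowSet):
        if list(windows.channel_names) != list(bank.channel_names):
            raise ValueError("window channels do not match the filter bank")
        windows = windows.windows
    y = bank.apply(np.asarray(windows, dtype=float))
    var = y.var(axis=-1, ddof=1)
    if np.any(var < EPS_VAR):
        warnings.warn("constant window(s): log-variance floored at log(1e-12)")
        var = np.maximum(var, EPS_VAR)
    return np.log(var)


# ---------------------------------------------------------------------------
# LDA
# ---------------------------------------------------------------------------

@dataclass
class LdaModel:
    """Pooled-covariance linear discriminant, canonical class order.

    Posteriors sum to 1; exact posterior ties resolve to the lowest class
    index (deterministic).
    """

    coef: np.ndarray        # (n_classes, n_features) in sklearn class order
    intercept: np.ndarray
    sk_classes: list[str]   # sklearn's (sorted) class order
    classes: list[str]      # canonical order used for output columns

    def posteriors(self, X: np.ndarray) -> np.ndarray:
        scores = X @ self.coef.T + self.intercept
        if len(self.sk_classes) == 2:
            # sklearn binary convention: one decision column for classes_[1]
            scores = np.column_stack([np.zeros(len(scores)), scores[:, -1]])
        scores -= scores.max(axis=1, keepdims=True)
        p = np.exp(scores)
        p /= p.sum(axis=1, keepdims=True)
        reorder = [self.sk_classes.index(c) for c in self.classes]
        return p[:, reorder]

    def predict(self, X: np.ndarray) -> np.ndarray:
        p = self.posteriors(X)
        return np.array(self.classes, dtype=object)[np.argmax(p, axis=1)]


def fit_lda(features: np.ndarray, labels) -> LdaModel:
    """Fit LDA on feature vectors (scikit-learn, 'lsqr' solver).

    Shrinkage is engaged automatically when the pooled covariance is
    ill-conditioned.  Requires >= 2 classes with >= 2 samples each.
    """
    labels = np.asarray(labels)
    classes = canonical_class_order(np.unique(labels))
    if len(classes) < 2:
        raise ValueError("LDA needs at least 2 classes")
    for cls in classes:
        if np.sum(labels == cls) < 2:
            raise ValueError(f"class {cls!r} needs at least 2 samples")
    X = np.asarray(features, dtype=float)
    resid = X - np.stack([X[labels == l].mean(axis=0) for l in labels])
    pooled = np.cov(resid.T) if X.shape[1] > 1 else np.atleast_2d(np.var(resid))
    shrinkage = None if np.linalg.cond(pooled) < COND_MAX else "auto"
    lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=shrinkage)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lda.fit(X, labels.astype(str))
    return LdaModel(coef=np.atleast_2d(lda.coef_),
                    intercept=np.atleast_1d(lda.intercept_),
                    sk_classes=[str(c) for c in lda.classes_],
                    classes=classes)


# ---------------------------------------------------------------------------
# The fitted decoder
# ---------------------------------------------------------------------------

@dataclass
class DecoderModel:
    """Portable CSP-LDA brain decoder: filter bank + discriminant + metadata."""

    bank: SpatialFilterBank
    lda: LdaModel
    training_accuracy: float
    metadata: dict = field(default_factory=dict)

    @property
    def classes(self) -> list[str]:
        return self.lda.classes

    @property
    def channel_names(self) -> list[str]:
        return self.bank.channel_names

    def decision(self, windows: np.ndarray):
        """Posterior matrix and predicted labels for raw windows."""
        feats = csp_features(windows, self.bank)
        return self.lda.posteriors(feats), self.lda.predict(feats)

    def to_json(self) -> str:
        b, l = self.bank, self.lda
        return json.dumps({
            "format": "mibci-decoder-1",
            "filters": b.filters.tolist(), "patterns": b.patterns.tolist(),
            "component_scores": b.component_scores.tolist(),
            "component_class": b.component_class,
            "channel_names": b.channel_names,
            "lda_coef": l.coef.tolist(), "lda_intercept": l.intercept.tolist(),
            "sk_classes": l.sk_classes, "classes": l.classes,
            "training_accuracy": self.training_accuracy,
            "metadata": self.metadata,
        })

    @classmethod
    def from_json(cls, text: str) -> "DecoderModel":
        d = json.loads(text)
        bank = SpatialFilterBank(
            filters=np.array(d["filters"]), patterns=np.array(d["patterns"]),
            component_scores=np.array(d["component_scores"]),
            component_class=list(d["component_class"]),
            channel_names=list(d["channel_names"]))
        lda = LdaModel(coef=np.array(d["lda_coef"]),
                       intercept=np.array(d["lda_intercept"]),
                       sk_classes=list(d["sk_classes"]),
                       classes=list(d["classes"]))
        return cls(bank=bank, lda=lda,
                   training_accuracy=float(d["training_accuracy"]),
                   metadata=dict(d["metadata"]))

    def save(self, path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path) -> "DecoderModel":
        return cls.from_json(Path(path).read_text())


def fit_decoder(ws: LabeledWindowSet, n_components: int = 6,
                metadata: dict | None = None) -> DecoderModel:
    """Fit the CSP-LDA decoder on the full (calibration) window set."""
    bank = fit_csp(ws, n_components)
    feats = csp_features(ws, bank)
    lda = fit_lda(feats, ws.labels)
    acc = float(np.mean(lda.predict(feats) == ws.labels))
    meta = {"fit_time": _dt.datetime.now().isoformat(timespec="seconds"),
            "n_windows": len(ws), "window_s": ws.window_length,
            **(metadata or {})}
    return DecoderModel(bank=bank, lda=lda, training_accuracy=acc,
                        metadata=meta)


# ---------------------------------------------------------------------------
# Cross-validation and the competence gate
# ---------------------------------------------------------------------------

@dataclass
class CvReport:
    """Run-wise k-fold cross-validation accuracies."""

    fold_accuracies: list[float]
    k: int
    fold_composition: list[list[int]]  # run ids per fold

    def __post_init__(self):
        if len(self.fold_accuracies) != self.k:
            raise ValueError("fold count does not match k")

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))


def cross_validate(ws: LabeledWindowSet, k: int | None = None,
                   n_components: int = 6,
                   trial_level: bool = False) -> CvReport:
    """Grouped k-fold cross-validation with runs as the fold unit.

    ``k`` defaults to the number of runs (one series per fold, e.g. 9 for a
    competence test).  CSP and LDA are refit on the training folds only.
    Accuracy is the fraction of correct window decisions (or trial-majority
    decisions with ``trial_level=True``).
    """
    runs = ws.runs
    if len(runs) < 2:
        raise ValueError("need at least 2 runs to cross-validate")
    classes = set(ws.classes)
    for r in runs:
        present = set(np.unique(ws.labels[ws.run_id == r]))
        if present != classes:
            raise ValueError(f"run {r} is missing class(es) "
                             f"{sorted(classes - present)}")
    k = len(runs) if k is None else int(k)
    if not 2 <= k <= len(runs):
        raise ValueError("k must lie between 2 and the number of runs")
    folds = [list(map(int, f)) for f in np.array_split(runs, k)]
    accs = []
    for fold in folds:
        test = np.isin(ws.run_id, fold)
        model = fit_decoder(ws.subset(~test), n_components)
        _, pred = model.decision(ws.windows[test])
        truth = ws.labels[test]
        if trial_level:
            trials = ws.trial_id[test]
            correct = []
            for t in np.unique(trials):
                m = trials == t
                labs, counts = np.unique(pred[m], return_counts=True)
                correct.append(labs[np.argmax(counts)] == truth[m][0])
            accs.append(float(np.mean(correct)))
        else:
            accs.append(float(np.mean(pred == truth)))
    return CvReport(fold_accuracies=accs, k=k, fold_composition=folds)


@dataclass(frozen=True)
class GateDecision:
    """Outcome of one competence-test attempt against the inclusion gate."""

    passed: bool
    mean_accuracy: float
    threshold: float
    attempt: int


def competence_gate(report: CvReport, threshold: float = 0.70,
                    attempt: int = 1) -> GateDecision:
    """Inclusion gate: pass iff mean CV accuracy >= threshold ("reach" reads
    inclusive).  At most three attempts are allowed; a fourth is refused."""
    if attempt not in (1, 2, 3):
        raise ValueError("attempt must be 1, 2 or 3: a maximum of three "
                         "competence-test attempts is allowed")
    return GateDecision(passed=report.mean_accuracy >= threshold,
                        mean_accuracy=report.mean_accuracy,
                        threshold=threshold, attempt=attempt)
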