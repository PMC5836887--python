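"""Fingerprint-based activity model and the latent-search objective score.

Activity is predicted by a support vector machine with a Gaussian (RBF)
kernel over extended-connectivity fingerprints of diameter 6 (ECFP6, radius
3, folded to 2048 bits by default).  The Bayesian-optimization objective at a
latent point z is

    S(z) = mean P_active over the predicted actives (P_active > 0.5)
           among the valid sampled compounds, falling back to the mean over
           all valid compounds when none is predicted active,

and 0 when nothing valid decodes at z.  Generated structures containing a
ring of more than eight atoms are discarded before scoring (macrocycles
score well but are rarely synthesizable).
"""

from __future__ import annotations

import warnings
from contextlib import contextmanager
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold, cross_val_predict
from sklearn.svm import SVC

from .codec import SmilesParseError
from .generate import GenerationReport


def ecfp_fingerprint(smiles: str, radius: int = 3, n_bits: int = 2048) -> np.ndarray:
    """ECFP fingerprint (diameter = 2 * radius) as a dense 0/1 vector."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None or mol.GetNumAtoms() == 0:
        raise SmilesParseError(f"cannot fingerprint invalid SMILES: {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    fp = gen.GetFingerprint(mol)
    arr = np.zeros(n_bits, dtype=np.uint8)
    for bit in fp.GetOnBits():
        arr[bit] = 1
    return arr


def tanimoto(fp_a: np.ndarray, fp_b: np.ndarray) -> float:
    """|A ∩ B| / |A ∪ B| over fingerprint bit sets (1.0 for two empty sets)."""
    a = fp_a.astype(bool)
    b = fp_b.astype(bool)
    union = np.sum(a | b)
    if union == 0:
        return 1.0
    return float(np.sum(a & b) / union)


def macrocycle_filter(smiles: str, max_ring: int = 8) -> bool:
    """True (keep) iff no SSSR ring has more than ``max_ring`` atoms."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None or mol.GetNumAtoms() == 0:
        raise SmilesParseError(f"invalid SMILES: {smiles!r}")
    return all(len(ring) <= max_ring for ring in mol.GetRingInfo().AtomRings())


@contextmanager
def _quiet_svc():
    # sklearn >= 1.9 deprecation chatter about SVC(probability=True)
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", category=FutureWarning,
                                module=r"sklearn\..*")
        yield


class ActivityClassifier(BaseEstimator, ClassifierMixin):
    """ECFP6 + Gaussian-kernel SVM activity model with probability outputs.

    Fit on SMILES strings and 0/1 activity labels.  C and gamma are selected
    by cross-validated grid search (AUROC); ``class_weight="balanced"``
    guards against the heavy active/inactive imbalance typical of
    bioactivity tables.  The decision threshold for "active" is fixed at
    P_active > 0.5.

    Attributes (after fit): ``model_`` (the SVC), ``best_params_``,
    ``cv_auroc_`` (cross-validated AUROC on the training table).
    """

    THRESHOLD = 0.5

    def __init__(self, radius=3, n_bits=2048, C_grid=(1.0, 10.0, 100.0),
                 gamma_grid=("scale", 0.01, 0.1), cv=3,
                 class_weight="balanced", random_state=0):
        self.radius = radius
        self.n_bits = n_bits
        self.C_grid = C_grid
        self.gamma_grid = gamma_grid
        self.cv = cv
        self.class_weight = class_weight
        self.random_state = random_state

    def _featurize(self, smiles_list) -> np.ndarray:
        return np.array(
            [ecfp_fingerprint(s, self.radius, self.n_bits) for s in smiles_list],
            dtype=np.float64,
        )

    def fit(self, X, y):
        y = np.asarray(y, dtype=int)
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("need both active and inactive examples")
        self.classes_ = classes
        F = self._featurize(list(X))
        cv = StratifiedKFold(n_splits=self.cv, shuffle=True,
                             random_state=self.random_state)
        search = GridSearchCV(
            SVC(kernel="rbf", probability=True, class_weight=self.class_weight,
                random_state=self.random_state),
            {"C": list(self.C_grid), "gamma": list(self.gamma_grid)},
            scoring="roc_auc", cv=cv,
        )
        with _quiet_svc():
            search.fit(F, y)
            self.model_ = search.best_estimator_
            self.best_params_ = search.best_params_
            proba = cross_val_predict(self.model_, F, y, cv=cv,
                                      method="predict_proba")[:, 1]
        self.cv_auroc_ = float(roc_auc_score(y, proba))
        return self

    def predict_proba(self, X) -> np.ndarray:
        F = self._featurize(list(X))
        with _quiet_svc():
            return self.model_.predict_proba(F)

    def p_active(self, X) -> np.ndarray:
        """P_active for each SMILES."""
        pos = int(np.where(self.model_.classes_ == 1)[0][0])
        return self.predict_proba(X)[:, pos]

    def predict(self, X) -> np.ndarray:
        return (self.p_active(X) > self.THRESHOLD).astype(int)


def train_activity_model(actives, inactives, **config) -> ActivityClassifier:
    """Convenience wrapper: fit from separate active/inactive SMILES lists."""
    actives = list(actives)
    inactives = list(inactives)
    if not actives or not inactives:
        raise ValueError("both classes must be non-empty")
    clf = ActivityClassifier(**config)
    return clf.fit(actives + inactives, [1] * len(actives) + [0] * len(inactives))


@dataclass
class ScoreResult:
    """S(z) for one latent point's generation report."""

    score: float
    n_valid: int
    n_active: int
    per_smiles: dict[str, float] = field(default_factory=dict)


def score_probabilities(p_active: np.ndarray) -> float:
    """Two-branch score: mean over actives (p > 0.5) else mean over all."""
    p_active = np.asarray(p_active, dtype=float)
    if p_active.size == 0:
        return 0.0
    actives = p_active[p_active > ActivityClassifier.THRESHOLD]
    if actives.size:
        return float(np.mean(actives))
    return float(np.mean(p_active))


def activity_score(report: GenerationReport, model: ActivityClassifier,
                   unique: bool = True, max_ring: int | None = 8) -> ScoreResult:
    """Score a generation report with the two-branch formula.

    Invalid strings are excluded; with ``max_ring`` set, structures carrying
    a larger ring are also excluded.  ``unique=True`` scores each distinct
    compound once (set False to weight by sampling frequency).
    """
    from . import codec

    counts: dict[str, int] = {}
    for s, n in report.frequency_table.items():
        if not codec.is_valid_smiles(s):
            continue
        if max_ring is not None and not macrocycle_filter(s, max_ring):
            continue
        counts[s] = n
    if not counts:
        return ScoreResult(score=0.0, n_valid=0, n_active=0, per_smiles={})
    smiles = sorted(counts)
    p = model.p_active(smiles)
    per = dict(zip(smiles, map(float, p)))
    weights = np.ones(len(smiles)) if unique else np.array([counts[s] for s in smiles])
    expanded = np.repeat(p, weights.astype(int))
    score = score_probabilities(expanded)
    n_active = int(np.sum(p > ActivityClassifier.THRESHOLD))
    return ScoreResult(score=score, n_valid=len(smiles), n_active=n_active,
                       per_smiles=per)
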