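"""Fine-grained personalization: Sugeno ANFIS over (EEG probability, HRV
composite, clinical composite), PSO-tuned premises, HRV transition-pattern
risk staging, and preictal/SPH localization.

Pattern language over a feature series, with relative change
``rel(i) = (v[i+1] - v[i]) / |v[i]|`` discretized by two thresholds
(delta_small ~ "approximately equal", delta_large ~ "much greater"):

    '=' : |rel| <= delta_small
    '<' : delta_small < rel <= delta_large
    '>' : rel > delta_large
    '-' : rel < -delta_small (drop)

alpha (high risk, Pk1)   = '<' '>'          (then sustained: no later drop)
beta  (medium risk, Pk2) = '=' '<' '>'
gamma (low risk, Pk3)    = '=' '=' '<' '>'

Each feature is scanned left to right; the earliest-starting match wins, with
alpha > beta > gamma priority at the same index. The five HRV features vote;
ties break toward the higher risk.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .types import ClinicalRecord, HRVSeries, HRV_FEATURES, RiskAssessment

__all__ = [
    "TABLE1_RANGES",
    "FuzzyVariable",
    "ANFISModel",
    "PSOConfig",
    "aggregate_inputs",
    "anfis_predict",
    "train_anfis_pso",
    "discretize_changes",
    "classify_hrv_pattern",
    "stage_risk",
    "localize_preictal_sph",
]

PATTERN_FOR_CLASS = {"Pk1": "alpha", "Pk2": "beta", "Pk3": "gamma"}
CLASS_FOR_PATTERN = {v: k for k, v in PATTERN_FOR_CLASS.items()}
_PATTERN_PRIORITY = {"alpha": 0, "beta": 1, "gamma": 2}

#: Per-variable (low, medium, high) value ranges used to seed the triangular
#: membership functions. "Class 3" is always the high-RISK class, whatever the
#: numeric direction of the feature (e.g. low pNN50 is high risk).
TABLE1_RANGES: dict[str, tuple[tuple[float, float], ...]] = {
    "EEG": ((0.0, 0.3), (0.31, 0.6), (0.61, 1.0)),
    "Lmax": ((198.0, 238.0), (239.0, 245.0), (245.0, 290.0)),
    "LF_HF": ((1.3, 1.7), (1.1, 2.1), (1.3, 2.9)),
    "SDNN": ((109.0, 141.6), (85.4, 165.0), (83.7, 159.1)),
    "MeanHR": ((65.2, 76.2), (71.6, 81.4), (72.1, 92.5)),
    "pNN50": ((6.2, 17.6), (2.5, 8.1), (1.6, 9.6)),
    "composite": ((0.0, 1 / 3), (1 / 3, 2 / 3), (2 / 3, 1.0)),
}


# ---------------------------------------------------------------------------
# fuzzy variables
# ---------------------------------------------------------------------------

@dataclass
class FuzzyVariable:
    """Three triangular membership functions (Low, Medium, High)."""

    name: str
    mfs: list[tuple[float, float, float]]  # (left, peak, right) per class

    def __post_init__(self) -> None:
        if len(self.mfs) != 3:
            raise ValueError("exactly three membership functions required")
        for l, p, r in self.mfs:
            if not l <= p <= r:
                raise ValueError(f"{self.name}: need left <= peak <= right")

    @classmethod
    def from_class_ranges(
        cls, name: str, ranges: Sequence[tuple[float, float]], spread: float = 0.35
    ) -> "FuzzyVariable":
        """Triangles centered on each class midpoint, feet at the class bounds
        widened by ``spread`` of the range so neighbouring supports overlap and
        every in-range value keeps positive total membership."""
        mfs = []
        for lo, hi in ranges:
            width = max(hi - lo, 1e-9)
            mfs.append((lo - spread * width, 0.5 * (lo + hi), hi + spread * width))
        return cls(name=name, mfs=mfs)

    def fuzzify(self, value: float) -> np.ndarray:
        """Membership triple at ``value`` (clipped to the variable support)."""
        lo = min(m[0] for m in self.mfs)
        hi = max(m[2] for m in self.mfs)
        v = float(np.clip(value, lo, hi))
        out = np.zeros(3)
        for i, (l, p, r) in enumerate(self.mfs):
            if v == p:
                out[i] = 1.0
            elif l < v < p:
                out[i] = (v - l) / (p - l)
            elif p < v < r:
                out[i] = (r - v) / (r - p)
        return out

    def classify(self, value: float) -> int:
        """Argmax class index (0=Low, 1=Medium, 2=High); ties -> higher risk."""
        mu = self.fuzzify(value)
        best = mu.max()
        return int(max(i for i in range(3) if mu[i] >= best - 1e-12))

    def premise_vector(self) -> np.ndarray:
        return np.array(self.mfs, dtype=float).ravel()

    @classmethod
    def from_premise_vector(cls, name: str, vec: np.ndarray) -> "FuzzyVariable":
        mfs = []
        for i in range(3):
            l, p, r = np.sort(vec[3 * i : 3 * i + 3])
            mfs.append((float(l), float(p), float(r)))
        return cls(name=name, mfs=mfs)


def _clinical_score(record: ClinicalRecord) -> float:
    """Clinical composite per the class table: boolean flags map No->Low,
    Yes->High (ties toward higher risk), event count by the class bands."""
    vals = []
    vals.append(1.0 if record.genetic else 0.0)
    vals.append(1.0 if record.metabolic else 0.0)
    n = record.seizure_event_count
    if n > 5:
        vals.append(1.0)
    elif n >= 3:
        vals.append(0.5)
    else:
        vals.append(0.0)
    return float(np.mean(vals))


def aggregate_inputs(
    eeg_prob: float,
    hrv_features: dict[str, float],
    clinical: ClinicalRecord,
) -> np.ndarray:
    """Collapse the nine raw parameters into the three ANFIS inputs.

    EEG probability passes through; the HRV composite is the mean of the five
    features' fuzzified class indices mapped to {0, 0.5, 1}; the clinical
    composite does the same over its three features.
    """
    missing = [k for k in HRV_FEATURES if k not in hrv_features]
    if missing:
        raise ValueError(f"missing HRV feature(s): {missing}")
    hrv_scores = []
    for k in HRV_FEATURES:
        var = FuzzyVariable.from_class_ranges(k, TABLE1_RANGES[k])
        hrv_scores.append(var.classify(float(hrv_features[k])) * 0.5)
    return np.array([float(eeg_prob), float(np.mean(hrv_scores)), _clinical_score(clinical)])


# ---------------------------------------------------------------------------
# Sugeno ANFIS
# ---------------------------------------------------------------------------

_INPUT_NAMES = ("EEG", "HRV", "Clinical")


def _default_variables() -> list[FuzzyVariable]:
    return [
        FuzzyVariable.from_class_ranges("EEG", TABLE1_RANGES["EEG"]),
        FuzzyVariable.from_class_ranges("HRV", TABLE1_RANGES["composite"]),
        FuzzyVariable.from_class_ranges("Clinical", TABLE1_RANGES["composite"]),
    ]


@dataclass
class ANFISModel:
    """3-input, 3-MF, 27-rule first-order Sugeno system."""

    variables: list[FuzzyVariable] = field(default_factory=_default_variables)
    consequents: np.ndarray = field(
        default_factory=lambda: np.zeros((27, 4))
    )  # per rule: bias + 3 linear coefficients
    output_min: float = 0.0
    output_max: float = 1.0
    mae_log: list[float] = field(default_factory=list)

    def rule_index(self, i: int, j: int, k: int) -> int:
        return 9 * i + 3 * j + k

    def firing_strengths(self, x: np.ndarray) -> np.ndarray:
        """Normalized rule firing strengths (n, 27); product T-norm."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        mus = [np.vstack([v.fuzzify(xi) for xi in x[:, d]]) for d, v in enumerate(self.variables)]
        w = (
            mus[0][:, :, None, None]
            * mus[1][:, None, :, None]
            * mus[2][:, None, None, :]
        ).reshape(len(x), 27)
        total = w.sum(axis=1, keepdims=True)
        total = np.where(total > 0, total, 1.0)
        return w / total

    def raw_output(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        wbar = self.firing_strengths(x)
        ext = np.hstack([np.ones((len(x), 1)), x])  # (n, 4)
        rule_out = ext @ self.consequents.T  # (n, 27)
        return (wbar * rule_out).sum(axis=1)

    def scaled_output(self, x: np.ndarray) -> np.ndarray:
        span = self.output_max - self.output_min
        if span <= 0:
            return np.full(len(np.atleast_2d(x)), 0.5)
        return np.clip((self.raw_output(x) - self.output_min) / span, 0.0, 1.0)

    def premise_vector(self) -> np.ndarray:
        return np.concatenate([v.premise_vector() for v in self.variables])

    def set_premise_vector(self, vec: np.ndarray) -> None:
        self.variables = [
            FuzzyVariable.from_premise_vector(name, vec[9 * d : 9 * (d + 1)])
            for d, name in enumerate(_INPUT_NAMES)
        ]


def anfis_predict(model: ANFISModel, x: np.ndarray) -> tuple[np.ndarray, list[str]]:
    """(continuous risk level in [0,1], risk class) per row of ``x``.

    Class by thirds of the min-max-scaled output: top third -> Pk1 (high),
    middle -> Pk2, bottom -> Pk3.
    """
    out = model.scaled_output(x)
    classes = ["Pk1" if o >= 2 / 3 else ("Pk2" if o >= 1 / 3 else "Pk3") for o in out]
    return out, classes


def _fit_consequents(model: ANFISModel, X: np.ndarray, y: np.ndarray) -> None:
    """Least-squares consequent estimate given the current premises."""
    wbar = model.firing_strengths(X)  # (n, 27)
    ext = np.hstack([np.ones((len(X), 1)), X])  # (n, 4)
    phi = (wbar[:, :, None] * ext[:, None, :]).reshape(len(X), 27 * 4)
    coef, *_ = np.linalg.lstsq(phi, y, rcond=None)
    model.consequents = coef.reshape(27, 4)


def _mae(model: ANFISModel, X: np.ndarray, y: np.ndarray) -> float:
    return float(np.abs(model.raw_output(X) - y).mean())


def _hybrid_train(
    model: ANFISModel,
    X: np.ndarray,
    y: np.ndarray,
    epochs: int = 8,
    premise_lr: float = 0.02,
) -> ANFISModel:
    """Hybrid loop: LSE for consequents, numerical-gradient MAE steps on the
    premise parameters."""
    _fit_consequents(model, X, y)
    model.mae_log = [_mae(model, X, y)]
    vec = model.premise_vector()
    scale = np.maximum(np.abs(vec), 1.0)
    for _ in range(epochs):
        base = _mae(model, X, y)
        grad = np.zeros_like(vec)
        h = 1e-4 * scale
        for i in range(len(vec)):
            probe = vec.copy()
            probe[i] += h[i]
            model.set_premise_vector(probe)
            grad[i] = (_mae(model, X, y) - base) / h[i]
        step = premise_lr * scale * np.sign(grad) * (np.abs(grad) > 0)
        candidate = vec - step
        model.set_premise_vector(candidate)
        _fit_consequents(model, X, y)
        new = _mae(model, X, y)
        if new <= base:
            vec = candidate
        else:  # reject uphill move
            model.set_premise_vector(vec)
            _fit_consequents(model, X, y)
            new = _mae(model, X, y)
        model.mae_log.append(new)
    out = model.raw_output(X)
    model.output_min = float(out.min())
    model.output_max = float(out.max())
    return model


@dataclass
class PSOConfig:
    swarm: int = 30
    iterations: int = 50
    inertia: float = 0.7
    cognitive: float = 1.5
    social: float = 1.5
    hybrid_epochs: int = 8
    validation_split: float = 0.25


def train_anfis_pso(
    model: ANFISModel,
    X: np.ndarray,
    y: np.ndarray,
    pso: Optional[PSOConfig] = None,
    seed: int = 42,
) -> ANFISModel:
    """PSO over premise initializations; the best learner (by validation MAE)
    wins, each candidate being hybrid-trained (LSE consequents + gradient
    premises). ``swarm=1, iterations=0`` reduces to plain hybrid training from
    the initial premises.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if len(y) < 10:
        raise ValueError("need at least 10 training pairs")
    pso = pso or PSOConfig()
    if np.ptp(y) == 0:
        warnings.warn("all-identical targets: returning a constant model")
        model.consequents = np.zeros((27, 4))
        model.consequents[:, 0] = y[0]
        model.output_min, model.output_max = float(y[0]) - 0.5, float(y[0]) + 0.5
        model.mae_log = [0.0]
        return model

    rng = np.random.default_rng(seed)
    n = len(y)
    if pso.validation_split > 0 and n >= 12:
        perm = rng.permutation(n)
        k = max(1, int(round(pso.validation_split * n)))
        va, tr = perm[:k], perm[k:]
    else:
        tr = va = np.arange(n)

    base_vec = model.premise_vector()
    scale = np.maximum(np.abs(base_vec), 1.0)
    dim = len(base_vec)

    def fitness(vec: np.ndarray) -> tuple[float, ANFISModel]:
        cand = ANFISModel()
        cand.set_premise_vector(vec)
        _hybrid_train(cand, X[tr], y[tr], epochs=pso.hybrid_epochs)
        return -_mae(cand, X[va], y[va]), cand

    # particle 0 sits on the table-derived initialization
    pos = base_vec[None, :] + np.vstack(
        [np.zeros(dim)]
        + [rng.normal(0.0, 0.1, dim) * scale for _ in range(pso.swarm - 1)]
    )
    vel = np.zeros_like(pos)
    pbest = pos.copy()
    pbest_fit = np.full(pso.swarm, -np.inf)
    gbest_fit = -np.inf
    gbest_model = None
    gbest = base_vec.copy()

    for p in range(pso.swarm):
        f, m = fitness(pos[p])
        pbest_fit[p] = f
        if f > gbest_fit:
            gbest_fit, gbest, gbest_model = f, pos[p].copy(), m

    for _ in range(pso.iterations):
        r1 = rng.random(pos.shape)
        r2 = rng.random(pos.shape)
        vel = (
            pso.inertia * vel
            + pso.cognitive * r1 * (pbest - pos)
            + pso.social * r2 * (gbest[None, :] - pos)
        )
        pos = pos + vel
        for p in range(pso.swarm):
            f, m = fitness(pos[p])
            if f > pbest_fit[p]:
                pbest_fit[p] = f
                pbest[p] = pos[p].copy()
            if f > gbest_fit:
                gbest_fit, gbest, gbest_model = f, pos[p].copy(), m

    assert gbest_model is not None
    model.variables = gbest_model.variables
    model.consequents = gbest_model.consequents
    model.output_min = gbest_model.output_min
    model.output_max = gbest_model.output_max
    model.mae_log = gbest_model.mae_log
    return model


# ---------------------------------------------------------------------------
# HRV transition patterns, risk staging, SPH
# ---------------------------------------------------------------------------

def relative_changes(values: np.ndarray) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    denom = np.where(np.abs(v[:-1]) > 1e-12, np.abs(v[:-1]), 1e-12)
    return np.diff(v) / denom


def discretize_changes(values: np.ndarray, delta_small: float, delta_large: float) -> str:
    """Symbol string over the relative-change sequence ('=', '<', '>', '-')."""
    rel = relative_changes(values)
    out = []
    for r in rel:
        if abs(r) <= delta_small:
            out.append("=")
        elif delta_small < r <= delta_large:
            out.append("<")
        elif r > delta_large:
            out.append(">")
        else:
            out.append("-")
    return "".join(out)


def _match_feature(
    values: np.ndarray, delta_small: float, delta_large: float
) -> tuple[str, Optional[int]]:
    """Earliest pattern match in one feature series (pattern, start index)."""
    sym = discretize_changes(values, delta_small, delta_large)
    n = len(sym)
    for i in range(n):
        # priority at equal start index: alpha > beta > gamma
        if i + 1 < n and sym[i] == "<" and sym[i + 1] == ">":
            if "-" not in sym[i + 2 :]:  # sustained: no later drop
                return "alpha", i
        if i + 2 < n and sym[i] == "=" and sym[i + 1] == "<" and sym[i + 2] == ">":
            return "beta", i
        if (
            i + 3 < n
            and sym[i] == "="
            and sym[i + 1] == "="
            and sym[i + 2] == "<"
            and sym[i + 3] == ">"
        ):
            return "gamma", i
    return "none", None


def classify_hrv_pattern(
    series: HRVSeries, delta_small: float = 0.05, delta_large: float = 0.25
) -> tuple[str, Optional[int]]:
    """Majority-vote transition pattern over the five HRV features.

    Each feature series is matched independently (earliest match wins within a
    feature); the modal pattern across features is returned, ties breaking
    toward the higher risk. The match index is the earliest among the features
    voting for the winning pattern.
    """
    if series.n_points < 5:
        raise ValueError("need at least 5 HRV points for pattern matching")
    votes: dict[str, list[int]] = {}
    for k in HRV_FEATURES:
        pattern, idx = _match_feature(series.features[k], delta_small, delta_large)
        votes.setdefault(pattern, []).append(-1 if idx is None else idx)
    winner = max(
        votes,
        key=lambda p: (len(votes[p]), -_PATTERN_PRIORITY.get(p, 3)),
    )
    if winner == "none":
        return "none", None
    return winner, min(i for i in votes[winner] if i >= 0)


def stage_risk(
    anfis_output: float,
    hrv_pattern: str,
    subject_id: str = "",
    eeg_prob: Optional[float] = None,
) -> RiskAssessment:
    """Risk class: the HRV pattern decides when present (alpha->Pk1,
    beta->Pk2, gamma->Pk3); otherwise the ANFIS output tier does."""
    if hrv_pattern in CLASS_FOR_PATTERN:
        risk = CLASS_FOR_PATTERN[hrv_pattern]
    else:
        risk = "Pk1" if anfis_output >= 2 / 3 else ("Pk2" if anfis_output >= 1 / 3 else "Pk3")
    return RiskAssessment(
        subject_id=subject_id,
        risk_class=risk,
        pattern=hrv_pattern,
        anfis_output=float(anfis_output),
    )


def localize_preictal_sph(
    series: HRVSeries | np.ndarray,
    seizure_onset_s: float,
    delta_large: float = 0.25,
    times: Optional[np.ndarray] = None,
) -> tuple[Optional[float], Optional[float], Optional[float]]:
    """(preictal_start_s, alarm_onset_s, sph_s) from the HRV jump structure.

    Finds the earliest k with two successive relative increases > delta_large;
    the preceding segment (k-1, clamped to the series start) marks the
    preictal start = alarm onset; SPH = seizure onset - alarm onset. Returns
    (None, None, None) when no qualifying k exists.
    """
    if isinstance(series, HRVSeries):
        t = series.times
        candidates = [series.features[k] for k in HRV_FEATURES]
    else:
        v = np.asarray(series, dtype=float)
        t = np.asarray(times) if times is not None else np.arange(len(v), dtype=float)
        candidates = [v]
    if seizure_onset_s < t[0]:
        raise ValueError("seizure onset precedes the series span")

    best_k: Optional[int] = None
    for values in candidates:
        rel = relative_changes(values)
        for k in range(len(rel) - 1):
            if rel[k] > delta_large and rel[k + 1] > delta_large:
                if best_k is None or k < best_k:
                    best_k = k
                break
    if best_k is None:
        return None, None, None
    start = float(t[max(best_k - 1, 0)])
    sph = float(seizure_onset_s - start)
    if sph < 0:
        raise ValueError("alarm onset after seizure onset")
    return start, start, sph
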