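"""Discrete-observation hidden Markov model core.

A model is the triplet lambda = (A, B, pi) over named states and a named
observation alphabet, plus a boolean ``structure_mask`` that freezes the
topology (left-right chains for the waveform layer): transitions the mask
forbids carry probability zero and stay zero through every operation.

Provided operations: scaled forward log-likelihood, Viterbi decoding with
a documented lowest-index tie-break, supervised (counting) estimation from
annotated sequences, Baum-Welch expectation-maximization, and the
expert-annotation-assisted training loop: a supervised initialization from
the first expert's small annotation, one EM iteration on the long
unlabeled stream, then for each further expert a fresh supervised
initialization + single EM iteration whose result is either rejected as
discrepant (total-variation gate) or blended into the running model by a
convex combination.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "HmmModel",
    "AnnotatedSequence",
    "ExpertTrainConfig",
    "ExpertTrainResult",
    "left_right_mask",
    "forward_loglik",
    "viterbi",
    "supervised_estimate",
    "baum_welch_iterate",
    "reject_discrepant_annotation",
    "expert_assisted_train",
    "sample_model",
]

_ATOL = 1e-9


def left_right_mask(n_states: int, cyclic: bool = True) -> np.ndarray:
    """Self-loops plus the single forward transition; optionally wrapping
    the last state back to the first (a cyclic chain over repeated beats)."""
    mask = np.eye(n_states, dtype=bool)
    for i in range(n_states - 1):
        mask[i, i + 1] = True
    if cyclic and n_states > 1:
        mask[n_states - 1, 0] = True
    return mask


@dataclass
class HmmModel:
    """lambda = (A, B, pi) with named states/alphabet and a topology mask."""

    states: tuple[str, ...]
    alphabet: tuple[str, ...]
    A: np.ndarray
    B: np.ndarray
    pi: np.ndarray
    structure_mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.states = tuple(self.states)
        self.alphabet = tuple(self.alphabet)
        self.A = np.asarray(self.A, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        k, v = len(self.states), len(self.alphabet)
        if self.structure_mask is None:
            self.structure_mask = np.ones((k, k), dtype=bool)
        else:
            self.structure_mask = np.asarray(self.structure_mask, dtype=bool)
        self.validate()

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def n_symbols(self) -> int:
        return len(self.alphabet)

    def validate(self) -> None:
        k, v = self.n_states, self.n_symbols
        if self.A.shape != (k, k) or self.B.shape != (k, v) or self.pi.shape != (k,):
            raise ValueError("A/B/pi shapes inconsistent with states and alphabet")
        if self.structure_mask.shape != (k, k):
            raise ValueError("structure_mask shape mismatch")
        for name, m in (("A", self.A), ("B", self.B)):
            if np.any(m < -_ATOL):
                raise ValueError(f"{name} has negative entries")
            if not np.allclose(m.sum(axis=1), 1.0, atol=_ATOL):
                raise ValueError(f"rows of {name} must sum to 1")
        if np.any(self.pi < -_ATOL) or not np.isclose(self.pi.sum(), 1.0, atol=_ATOL):
            raise ValueError("pi must be a probability vector")
        if np.any(self.A[~self.structure_mask] != 0.0):
            raise ValueError("A must be exactly zero on mask-forbidden transitions")

    def copy(self) -> "HmmModel":
        return HmmModel(self.states, self.alphabet, self.A.copy(), self.B.copy(),
                        self.pi.copy(), self.structure_mask.copy())

    def to_dict(self) -> dict:
        return {
            "states": list(self.states),
            "alphabet": list(self.alphabet),
            "A": self.A.tolist(),
            "B": self.B.tolist(),
            "pi": self.pi.tolist(),
            "mask": self.structure_mask.astype(int).tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HmmModel":
        return cls(states=tuple(d["states"]), alphabet=tuple(d["alphabet"]),
                   A=np.array(d["A"]), B=np.array(d["B"]), pi=np.array(d["pi"]),
                   structure_mask=np.array(d["mask"], dtype=bool))


@dataclass
class AnnotatedSequence:
    """An observation sequence with matching expert hidden-state labels."""

    observations: np.ndarray
    state_labels: np.ndarray
    annotator_id: str = ""

    def __post_init__(self) -> None:
        self.observations = np.asarray(self.observations, dtype=np.int64)
        self.state_labels = np.asarray(self.state_labels, dtype=np.int64)
        if self.observations.shape != self.state_labels.shape:
            raise ValueError("observations and state_labels must have equal length")


def _check_obs(model: HmmModel, observations) -> np.ndarray:
    obs = np.asarray(observations, dtype=np.int64)
    if obs.size == 0:
        raise ValueError("empty observation sequence")
    if obs.min() < 0 or obs.max() >= model.n_symbols:
        raise ValueError("observation symbol outside the model alphabet")
    return obs


def _forward_scaled(model: HmmModel, obs: np.ndarray):
    """Scaled forward pass; returns (loglik, alpha_hat (T,K), scales (T,))."""
    t_len, k = obs.size, model.n_states
    alpha = np.empty((t_len, k))
    scales = np.empty(t_len)
    a = model.pi * model.B[:, obs[0]]
    for t in range(t_len):
        if t:
            a = (alpha[t - 1] @ model.A) * model.B[:, obs[t]]
        s = a.sum()
        scales[t] = s
        if s == 0.0:
            alpha[t:] = 0.0
            scales[t:] = 0.0
            return -np.inf, alpha, scales
        alpha[t] = a / s
    return float(np.log(scales).sum()), alpha, scales


def _backward_scaled(model: HmmModel, obs: np.ndarray, scales: np.ndarray) -> np.ndarray:
    t_len, k = obs.size, model.n_states
    beta = np.empty((t_len, k))
    beta[-1] = 1.0 / scales[-1]
    for t in range(t_len - 2, -1, -1):
        beta[t] = (model.A @ (model.B[:, obs[t + 1]] * beta[t + 1])) / scales[t]
    return beta


def forward_loglik(model: HmmModel, observations) -> float:
    """log P(O | lambda) by the scaled forward recursion (-inf if O is
    impossible under the model)."""
    obs = _check_obs(model, observations)
    ll, _, _ = _forward_scaled(model, obs)
    return ll


def viterbi(model: HmmModel, observations) -> tuple[np.ndarray, float]:
    """Most probable state path and its log probability.

    Ties are broken toward the lower state index at every step.  If no
    path has positive probability, raises with the first position at which
    every continuation dies.
    """
    obs = _check_obs(model, observations)
    t_len, k = obs.size, model.n_states
    with np.errstate(divide="ignore"):
        log_a = np.log(model.A)
        log_b = np.log(model.B)
        log_pi = np.log(model.pi)
    delta = log_pi + log_b[:, obs[0]]
    psi = np.zeros((t_len, k), dtype=np.int64)
    if np.all(np.isinf(delta)):
        raise ValueError("no possible state path: impossible symbol at position 0")
    for t in range(1, t_len):
        cand = delta[:, None] + log_a  # (from, to)
        psi[t] = np.argmax(cand, axis=0)  # first (lowest) index on ties
        delta = cand[psi[t], np.arange(k)] + log_b[:, obs[t]]
        if np.all(np.isinf(delta)):
            raise ValueError(f"no possible state path: impossible symbol at position {t}")
    path = np.empty(t_len, dtype=np.int64)
    path[-1] = int(np.argmax(delta))
    logp = float(delta[path[-1]])
    for t in range(t_len - 1, 0, -1):
        path[t - 1] = psi[t, path[t]]
    return path, logp


def supervised_estimate(annotated: Sequence[AnnotatedSequence],
                        states: Sequence[str], alphabet: Sequence[str],
                        pseudocount: float = 1e-3,
                        structure_mask: Optional[np.ndarray] = None) -> HmmModel:
    """Counting MLE from labeled sequences, with additive smoothing.

    Mask-forbidden transitions get no count and no pseudocount, so they
    stay exactly zero.  A state never observed (with zero pseudocount)
    yields a uniform row over allowed entries, with a warning.
    """
    if not annotated:
        raise ValueError("need at least one annotated sequence")
    k, v = len(states), len(alphabet)
    mask = np.ones((k, k), dtype=bool) if structure_mask is None else \
        np.asarray(structure_mask, dtype=bool)
    count_a = np.zeros((k, k))
    count_b = np.zeros((k, v))
    count_pi = np.zeros(k)
    for seq in annotated:
        s, o = seq.state_labels, seq.observations
        if s.size == 0:
            continue
        if s.min() < 0 or s.max() >= k or o.min() < 0 or o.max() >= v:
            raise ValueError("annotation indices outside state/alphabet ranges")
        count_pi[s[0]] += 1
        np.add.at(count_b, (s, o), 1)
        np.add.at(count_a, (s[:-1], s[1:]), 1)
    count_a = (count_a + pseudocount) * mask
    count_b = count_b + pseudocount
    count_pi = count_pi + pseudocount

    def _norm(m: np.ndarray, allowed: Optional[np.ndarray], what: str) -> np.ndarray:
        out = m.astype(float)
        sums = out.sum(axis=1)
        dead = sums == 0.0
        if np.any(dead):
            warnings.warn(f"{what}: state(s) {np.flatnonzero(dead).tolist()} never "
                          "observed; using uniform rows over allowed entries",
                          stacklevel=3)
            fill = (allowed if allowed is not None else np.ones_like(out, dtype=bool))
            out[dead] = fill[dead] / fill[dead].sum(axis=1, keepdims=True)
            sums = out.sum(axis=1)
        return out / sums[:, None]

    a = _norm(count_a, mask, "transition counts")
    b = _norm(count_b, None, "emission counts")
    pi = count_pi / count_pi.sum() if count_pi.sum() else np.full(k, 1.0 / k)
    return HmmModel(tuple(states), tuple(alphabet), a, b, pi, mask)


def baum_welch_iterate(model: HmmModel, observations, n_iterations: int = 1
                       ) -> tuple[HmmModel, list[float]]:
    """Standard EM re-estimation for ``n_iterations`` steps.

    Returns the updated model and the log-likelihood trace (the likelihood
    of the model *entering* each iteration); the trace is non-decreasing.
    Mask-forbidden transitions remain exactly zero.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    obs = _check_obs(model, observations)
    if np.any(model.A.sum(axis=1) == 0) or np.any(model.B.sum(axis=1) == 0):
        raise ValueError("degenerate model: a row of A or B is all zeros")
    model = model.copy()
    trace: list[float] = []
    t_len = obs.size
    for _ in range(n_iterations):
        ll, alpha, scales = _forward_scaled(model, obs)
        if not np.isfinite(ll):
            raise ValueError("observation sequence has zero probability under the model")
        trace.append(ll)
        beta = _backward_scaled(model, obs, scales)
        gamma = alpha * beta * scales[:, None]
        gamma /= gamma.sum(axis=1, keepdims=True)
        if t_len > 1:
            b_next = model.B[:, obs[1:]].T * beta[1:]            # (T-1, K)
            xi = alpha[:-1, :, None] * model.A[None] * b_next[:, None, :]
            xi_sum = xi.sum(axis=0)
            denom = gamma[:-1].sum(axis=0)[:, None]
            a_new = np.divide(xi_sum, xi_sum.sum(axis=1, keepdims=True),
                              out=model.A.copy(),
                              where=xi_sum.sum(axis=1, keepdims=True) > 0)
        else:
            a_new = model.A.copy()
        b_counts = np.zeros_like(model.B)
        np.add.at(b_counts.T, obs, gamma)
        b_sums = b_counts.sum(axis=1, keepdims=True)
        b_new = np.divide(b_counts, b_sums, out=model.B.copy(), where=b_sums > 0)
        model = HmmModel(model.states, model.alphabet, a_new, b_new,
                         gamma[0] / gamma[0].sum(), model.structure_mask)
    return model, trace


def reject_discrepant_annotation(candidate: HmmModel, reference: HmmModel,
                                 threshold: float = 0.25) -> bool:
    """Invalidation rule for a dramatically discrepant expert annotation.

    Rejects (returns True) when the mean total-variation distance across
    corresponding rows of A and B exceeds ``threshold``.  Structure-masked
    rows of A are nearly pinned by the topology, which dilutes the mean;
    the default threshold is chosen low enough that a scrambled annotation
    still trips it (see docs/methods.md).
    """
    if (candidate.A.shape != reference.A.shape
            or candidate.B.shape != reference.B.shape):
        raise ValueError("models must share shape")
    tv_a = 0.5 * np.abs(candidate.A - reference.A).sum(axis=1)
    tv_b = 0.5 * np.abs(candidate.B - reference.B).sum(axis=1)
    return float(np.concatenate([tv_a, tv_b]).mean()) > threshold


@dataclass(frozen=True)
class ExpertTrainConfig:
    blend_weight: float = 0.5        # weight of the running model in the blend
    reject_threshold: float = 0.25   # mean-TV gate for discrepant annotations
    pseudocount: float = 1e-3


@dataclass
class ExpertTrainResult:
    model: HmmModel
    accepted: list[str]
    rejected: list[str]
    loglik_trace: list[float]
    state_path: Optional[np.ndarray] = None


def _blend(current: HmmModel, candidate: HmmModel, w: float) -> HmmModel:
    a = w * current.A + (1 - w) * candidate.A
    b = w * current.B + (1 - w) * candidate.B
    pi = w * current.pi + (1 - w) * candidate.pi
    a[~current.structure_mask] = 0.0
    a /= a.sum(axis=1, keepdims=True)
    b /= b.sum(axis=1, keepdims=True)
    return HmmModel(current.states, current.alphabet, a, b, pi / pi.sum(),
                    current.structure_mask)


def expert_assisted_train(annotations: Sequence[AnnotatedSequence],
                          observations,
                          states: Sequence[str], alphabet: Sequence[str],
                          structure_mask: Optional[np.ndarray] = None,
                          config: ExpertTrainConfig = ExpertTrainConfig()
                          ) -> ExpertTrainResult:
    """Expert-annotation-assisted Baum-Welch training loop.

    The first expert's short annotation supplies the supervised
    initialization; one EM iteration on the long unlabeled stream follows.
    Each subsequent expert re-derives an initial model from its own
    annotation, runs one EM iteration, and is either rejected as
    discrepant with the running model (TV gate) or blended in; the running
    model then decodes the stream.  The loop runs to the last expert.
    """
    if not annotations:
        raise ValueError("need at least one expert annotation")
    obs = np.asarray(observations, dtype=np.int64)
    for seq in annotations:
        if seq.observations.size > obs.size:
            raise ValueError("expert annotations must not be longer than the "
                             "unlabeled observation stream")
    model = supervised_estimate([annotations[0]], states, alphabet,
                                pseudocount=config.pseudocount,
                                structure_mask=structure_mask)
    model, trace = baum_welch_iterate(model, obs, 1)
    accepted = [annotations[0].annotator_id or "expert-0"]
    rejected: list[str] = []
    path: Optional[np.ndarray] = None
    for i, ann in enumerate(annotations[1:], start=1):
        name = ann.annotator_id or f"expert-{i}"
        candidate = supervised_estimate([ann], states, alphabet,
                                        pseudocount=config.pseudocount,
                                        structure_mask=structure_mask)
        candidate, tr = baum_welch_iterate(candidate, obs, 1)
        if reject_discrepant_annotation(candidate, model, config.reject_threshold):
            rejected.append(name)
            continue
        model = _blend(model, candidate, config.blend_weight)
        accepted.append(name)
        trace.append(forward_loglik(model, obs))
        path, _ = viterbi(model, obs)
    if path is None:
        path, _ = viterbi(model, obs)
    return ExpertTrainResult(model=model, accepted=accepted, rejected=rejected,
                             loglik_trace=trace, state_path=path)


def sample_model(model: HmmModel, length: int, rng: np.random.Generator
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Draw (states, observations) of the given length from the model."""
    k, v = model.n_states, model.n_symbols
    states = np.empty(length, dtype=np.int64)
    obs = np.empty(length, dtype=np.int64)
    s = rng.choice(k, p=model.pi)
    for t in range(length):
        states[t] = s
        obs[t] = rng.choice(v, p=model.B[s])
        s = rng.choice(k, p=model.A[s])
    return states, obs
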