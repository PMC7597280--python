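"""Greedy forward selection and its diagnostics in the tree model.

The greedy rule appends, at each step, the candidate maximizing the chosen
criterion given the already-selected set (ties go to the canonical order:
actives by index, the child last).  Because criterion values here are
theoretical (quadrature-exact, no data), traces are deterministic.

Diagnostics cover the model's two failure modes: the step at which JMI
starts preferring the redundant child over the weakest active (gamma < 1),
the analogous CIFE crossover at gamma = 1, and the Positive Selection Rate
of the stopping-rule variant, which can become arbitrarily small.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable

from .gtm import (
    CRITERIA,
    CHILD,
    GTMSpec,
    VariableId,
    jmi_scores_closed,
    cife_scores_closed,
    variables,
)
from .mixtures import DomainError, QuadratureConfig

__all__ = [
    "SelectionStep",
    "SelectionTrace",
    "greedy_select",
    "jmi_crossover_k",
    "cife_gamma1_crossover_k",
    "psr",
]

log = logging.getLogger(__name__)

#: scores closer than this are treated as tied (tie broken by variable order)
_TIE_TOL = 1e-12


@dataclass(frozen=True)
class SelectionStep:
    index: int  # 1-based step number
    chosen: VariableId
    score: float
    scores: dict[VariableId, float] = field(compare=False)


@dataclass(frozen=True)
class SelectionTrace:
    criterion_name: str
    steps: tuple[SelectionStep, ...]
    stopped_early: bool

    @property
    def selected(self) -> tuple[VariableId, ...]:
        return tuple(s.chosen for s in self.steps)

    def step_of(self, v: VariableId) -> int | None:
        """1-based step at which ``v`` was selected, or None."""
        for s in self.steps:
            if s.chosen == v:
                return s.index
        return None

    def to_records(self) -> list[dict]:
        """Flat records (one per step) with winner, runner-up and scores."""
        records = []
        for s in self.steps:
            others = sorted(
                ((v, x) for v, x in s.scores.items() if v != s.chosen),
                key=lambda t: -t[1],
            )
            runner, runner_score = (str(others[0][0]), others[0][1]) if others else ("", float("nan"))
            records.append(
                {
                    "step": s.index,
                    "chosen": str(s.chosen),
                    "score": s.score,
                    "runner_up": runner,
                    "runner_up_score": runner_score,
                }
            )
        return records

    def to_json(self) -> str:
        """JSON dump of the full trace, including every step's score map."""
        payload = {
            "criterion": self.criterion_name,
            "stopped_early": self.stopped_early,
            "steps": [
                {
                    "step": s.index,
                    "chosen": str(s.chosen),
                    "score": s.score,
                    "scores": {str(v): x for v, x in sorted(s.scores.items())},
                }
                for s in self.steps
            ],
        }
        return json.dumps(payload, indent=2)


def greedy_select(
    spec: GTMSpec,
    criterion: str,
    n_steps: int | None = None,
    stopping: bool = False,
    cfg: QuadratureConfig | None = None,
) -> SelectionTrace:
    """Run greedy forward selection with the named criterion.

    Step 1 selects from the empty conditioning set (all criteria then
    reduce to marginal relevance).  With ``stopping`` on, the procedure
    halts *before* appending a winner whose score is not strictly
    positive.  Every step records the full score map over the remaining
    candidates.
    """
    if criterion not in CRITERIA:
        raise DomainError(f"unknown criterion {criterion!r}; choose from {sorted(CRITERIA)}")
    pool = variables(spec)
    if n_steps is None:
        n_steps = len(pool)
    if not (1 <= n_steps <= len(pool)):
        raise DomainError(f"n_steps must be in 1..{len(pool)}")
    fn = CRITERIA[criterion]
    selected: list[VariableId] = []
    steps: list[SelectionStep] = []
    stopped = False
    for step in range(1, n_steps + 1):
        remaining = [v for v in pool if v not in selected]
        scores = {v: fn(spec, v, tuple(selected), cfg) for v in remaining}
        best = max(scores.values())
        # smallest canonical order among (near-)ties
        chosen = next(v for v in remaining if scores[v] >= best - _TIE_TOL)
        if stopping and scores[chosen] <= 0.0:
            log.info(
                "step %d: stopping, best candidate %s has score %.6g <= 0",
                step, chosen, scores[chosen],
            )
            stopped = True
            break
        log.info("step %d: selected %s (%s = %.6g)", step, chosen, criterion, scores[chosen])
        selected.append(chosen)
        steps.append(SelectionStep(step, chosen, scores[chosen], scores))
    return SelectionTrace(criterion, tuple(steps), stopped)


def jmi_crossover_k(gamma: float, cfg: QuadratureConfig | None = None) -> int:
    """Smallest k for which JMI prefers the child to X_{k+1} given {X_1..X_k}.

    Exists (finitely) for every gamma < 1: once gamma^{2k} < 1/2 every
    summand of the difference is positive while the active's advantage
    decays to zero.  The search bound multiplies the positivity threshold
    -log 2 / (2 log gamma) by a safety factor; exceeding it raises, since
    that would contradict the underlying monotonicity argument.
    """
    if not (0.0 < gamma < 1.0):
        raise DomainError("gamma must lie strictly in (0, 1); no crossover at gamma = 1")
    bound = 10 * math.ceil(-math.log(2.0) / (2.0 * math.log(gamma))) + 50
    for k in range(1, bound + 1):
        active, child = jmi_scores_closed(k, gamma, cfg)
        if active < child:
            return k
    raise RuntimeError(
        f"no JMI crossover found for gamma={gamma} up to k={bound}; "
        "this contradicts the finiteness argument"
    )


def cife_gamma1_crossover_k(cfg: QuadratureConfig | None = None) -> int:
    """Smallest k with CIFE(X_{k+1}|X_1..X_k) < CIFE(X1^(1)|X_1..X_k) at gamma = 1.

    Both scores are affine in k with negative slopes; the active's slope is
    steeper, so the crossover is finite.
    """
    for k in range(1, 1001):
        active, child = cife_scores_closed(k, 1.0, cfg)
        if active < child:
            return k
    raise RuntimeError("no CIFE crossover found up to k=1000")  # pragma: no cover


def psr(selected: Iterable[VariableId], spec: GTMSpec) -> float:
    """Positive Selection Rate: fraction of the Markov blanket recovered.

    The blanket is {X_1, ..., X_{k+1}}; the child never counts.
    """
    blanket = set(variables(spec)) - {CHILD}
    chosen = set(selected)
    if not chosen <= set(variables(spec)):
        raise DomainError("selected contains variables outside the model")
    return len(chosen & blanket) / len(blanket)
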