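"""Criterion tables and figure-style curve data as DataFrames.

These functions back the command-line interface: score tables along each
criterion's own greedy path (the conditioning sets therefore differ
between criteria once their choices diverge), the decay of the chain-rule
CMI increment with model size, JMI crossover points on a gamma grid, and
active-versus-child score curves.
"""

from __future__ import annotations

import math
from typing import Sequence

import pandas as pd

from .gtm import GTMSpec, cmi_last_active_closed, jmi_scores_closed, cife_scores_closed
from .mixtures import QuadratureConfig
from .selection import greedy_select, jmi_crossover_k

__all__ = [
    "criterion_table",
    "table1_panels",
    "to_wide",
    "cmi_curve",
    "crossover_table",
    "criterion_curves",
]

_LN2 = math.log(2.0)


def _set_label(S) -> str:
    return ";".join(str(v) for v in S)


def _clean(value: float, decimals: int | None) -> float:
    if decimals is not None:
        value = round(value, decimals)
    return 0.0 if value == 0.0 else value  # normalize -0.0


def criterion_table(
    spec: GTMSpec,
    criterion: str,
    n_steps: int | None = None,
    cfg: QuadratureConfig | None = None,
    decimals: int | None = 4,
) -> pd.DataFrame:
    """Per-step candidate scores along the criterion's own greedy path.

    Long format with one row per (step, candidate): columns criterion,
    step, candidate, conditioning_set (semicolon-joined, in selection
    order), value_nats, value_bits, chosen.  Values are rounded to
    ``decimals`` (None disables rounding).
    """
    trace = greedy_select(spec, criterion, n_steps=n_steps, cfg=cfg)
    rows = []
    selected: list = []
    for step in trace.steps:
        label = _set_label(selected)
        for cand in sorted(step.scores):
            nats = step.scores[cand]
            rows.append(
                {
                    "criterion": criterion,
                    "step": step.index,
                    "candidate": str(cand),
                    "conditioning_set": label,
                    "value_nats": _clean(nats, decimals),
                    "value_bits": _clean(nats / _LN2, decimals),
                    "chosen": cand == step.chosen,
                }
            )
        selected.append(step.chosen)
    return pd.DataFrame(rows)


def table1_panels(
    spec: GTMSpec | None = None,
    cfg: QuadratureConfig | None = None,
    decimals: int | None = 4,
) -> dict[str, pd.DataFrame]:
    """The three criterion panels (CMI / JMI / CIFE) for a model.

    Defaults to M(2, 2/3).  Each panel follows its criterion's own greedy
    path, so the JMI panel's third conditioning set contains the child.
    """
    spec = spec or GTMSpec(2, 2.0 / 3.0)
    return {
        crit: criterion_table(spec, crit, cfg=cfg, decimals=decimals)
        for crit in ("cmi", "jmi", "cife")
    }


def to_wide(table: pd.DataFrame) -> pd.DataFrame:
    """Pivot a long criterion table to candidates x conditioning-set columns."""
    wide = table.pivot(index="candidate", columns="step", values="value_nats")
    sets = table.drop_duplicates("step").set_index("step")["conditioning_set"]
    wide.columns = [
        "marginal" if sets[s] == "" else f"given {sets[s]}" for s in wide.columns
    ]
    order = sorted(
        wide.index, key=lambda name: (name == "X1^(1)", len(name), name)
    )
    return wide.loc[order]


def cmi_curve(
    gammas: Sequence[float],
    k_max: int,
    cfg: QuadratureConfig | None = None,
) -> pd.DataFrame:
    """I(X_{k+1}, Y | X_1..X_k) for k = 1..k_max on a gamma grid.

    Strictly decreasing in k for each gamma: each extra active adds less
    about the label.
    """
    rows = [
        {"gamma": g, "k": k, "value": cmi_last_active_closed(GTMSpec(k, g), cfg)}
        for g in gammas
        for k in range(1, k_max + 1)
    ]
    return pd.DataFrame(rows)


def crossover_table(
    gammas: Sequence[float], cfg: QuadratureConfig | None = None
) -> pd.DataFrame:
    """Minimal k at which JMI prefers the child over X_{k+1}, per gamma < 1."""
    rows = [{"gamma": g, "minimal_k": jmi_crossover_k(g, cfg)} for g in gammas]
    return pd.DataFrame(rows)


def criterion_curves(
    gammas: Sequence[float],
    k_max: int,
    criteria: Sequence[str] = ("jmi", "cife"),
    cfg: QuadratureConfig | None = None,
) -> pd.DataFrame:
    """Active (X_{k+1}) versus child (X1^(1)) scores given {X_1..X_k}.

    Rows (criterion, gamma, k, score_active, score_child, difference);
    a negative difference means the redundant child outscores the weakest
    active.  For CIFE this happens only at gamma = 1.
    """
    closed = {"jmi": jmi_scores_closed, "cife": cife_scores_closed}
    rows = []
    for crit in criteria:
        if crit not in closed:
            raise ValueError(f"unsupported criterion {crit!r} (choose from jmi, cife)")
        for g in gammas:
            for k in range(1, k_max + 1):
                active, child = closed[crit](k, g, cfg)
                rows.append(
                    {
                        "criterion": crit,
                        "gamma": g,
                        "k": k,
                        "score_active": active,
                        "score_child": child,
                        "difference": active - child,
                    }
                )
    return pd.DataFrame(rows)
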