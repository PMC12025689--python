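"""Task-achievement model: from per-event accuracy to task success.

A passive (ErrP) avoidance needs one correctly classified event; an active
(SSVEP) avoidance needs three sequential correct commands (left, right, left
or the mirror sequence). Commands are modelled as independent with identical
per-event accuracy p, so the expected task success is p**m with m the number
of required commands — reported both analytically and by Monte Carlo.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "TaskScheme",
    "TaskOutcome",
    "expected_success",
    "simulate_tasks",
    "predict_task_percents",
]


@dataclass(frozen=True)
class TaskScheme:
    """Number of sequential correct commands a task needs (passive 1, active 3)."""

    mode: str  # 'passive' | 'active'
    commands_required: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("passive", "active"):
            raise ValueError("mode must be 'passive' or 'active'")
        if self.commands_required == 0:
            object.__setattr__(self, "commands_required", 1 if self.mode == "passive" else 3)
        if self.commands_required < 1:
            raise ValueError("commands_required must be >= 1")


PASSIVE = TaskScheme("passive")
ACTIVE = TaskScheme("active")


@dataclass
class TaskOutcome:
    """Analytic (and optionally Monte-Carlo) task-success estimate."""

    p_event: float
    commands_required: int
    expected_success: float
    percent: int
    mc_estimate: float | None = None
    mc_standard_error: float | None = None
    n_tasks: int | None = None


def _percent_half_up(p: float) -> int:
    return int(math.floor(100.0 * p + 0.5))


def expected_success(p_event: float, scheme: TaskScheme) -> TaskOutcome:
    """Expected task success p_event**commands_required, as probability and
    half-up-rounded integer percent."""
    if not 0.0 <= p_event <= 1.0:
        raise ValueError(f"p_event must lie in [0, 1], got {p_event}")
    p = p_event ** scheme.commands_required
    return TaskOutcome(
        p_event=p_event,
        commands_required=scheme.commands_required,
        expected_success=p,
        percent=_percent_half_up(p),
    )


def simulate_tasks(p_event: float, scheme: TaskScheme, n_tasks: int, seed: int = 0) -> TaskOutcome:
    """Monte-Carlo twin of :func:`expected_success`: each task succeeds iff
    all required independent Bernoulli(p_event) commands succeed."""
    if n_tasks < 1:
        raise ValueError("n_tasks must be >= 1")
    out = expected_success(p_event, scheme)
    rng = np.random.default_rng(seed)
    draws = rng.random((n_tasks, scheme.commands_required)) < p_event
    frac = float(draws.all(axis=1).mean())
    out.mc_estimate = frac
    out.mc_standard_error = float(np.sqrt(frac * (1.0 - frac) / n_tasks))
    out.n_tasks = n_tasks
    return out


def predict_task_percents(event_accuracies_percent, scheme: TaskScheme) -> list[int]:
    """Apply the task model to per-subject per-event accuracies given in
    percent; returns half-up-rounded task-achievement percents."""
    out = []
    for acc in event_accuracies_percent:
        if not 0.0 <= acc <= 100.0:
            raise ValueError(f"accuracy {acc} outside [0, 100]")
        out.append(expected_success(acc / 100.0, scheme).percent)
    return out
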