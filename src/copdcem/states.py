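"""The 16-state semi-Markov state space and its monthly transition matrix.

Nine chronic states (three GOLD severity levels x three exacerbation-history
strata), six one-cycle exacerbation tunnel states (severity x moderate/severe
event) and one absorbing death state. Severity never improves; exacerbations
are discrete one-cycle events routed through the severity-matched tunnel;
history is updated on tunnel exit.

Competing risks within a cycle are resolved in a fixed order: death first
(mortality inputs are all-cause), then severe and moderate exacerbation among
survivors, then severity progression among exacerbation-free survivors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .parameters import ARM_BGF, HISTORIES, SEVERITIES, ParameterError, ParameterSet

N_STATES = 16

EXAC_TYPES = ("moderate_exac", "severe_exac")

#: history stratum a patient lands in after each tunnel type
_EXIT_HISTORY = {"moderate_exac": "post_moderate", "severe_exac": "post_severe"}

#: next severity level down the progression cascade (very severe is terminal)
_NEXT_SEVERITY = {"moderate": "severe", "severe": "very_severe"}


@dataclass(frozen=True)
class HealthState:
    kind: str  # chronic | tunnel_moderate_exac | tunnel_severe_exac | death
    severity: Optional[str] = None
    history: Optional[str] = None

    def label(self) -> str:
        if self.kind == "death":
            return "death"
        if self.kind == "chronic":
            return f"{self.severity}|{self.history}"
        exac = self.kind.removeprefix("tunnel_")
        return f"{self.severity}|{exac}"


def enumerate_states() -> list[HealthState]:
    """Canonical ordering: chronic by severity then history, tunnels by
    severity then exacerbation type, death last."""
    states = [
        HealthState("chronic", severity=s, history=h)
        for s in SEVERITIES
        for h in HISTORIES
    ]
    states += [
        HealthState(f"tunnel_{e}", severity=s)
        for s in SEVERITIES
        for e in EXAC_TYPES
    ]
    states.append(HealthState("death"))
    return states


STATES = enumerate_states()
STATE_INDEX = {st: i for i, st in enumerate(STATES)}
STATE_LABELS = [st.label() for st in STATES]
DEATH = STATE_INDEX[HealthState("death")]

#: boolean masks / lookup arrays over the canonical order
ALIVE_MASK = np.array([st.kind != "death" for st in STATES])
CHRONIC_MASK = np.array([st.kind == "chronic" for st in STATES])
TUNNEL_MOD_MASK = np.array([st.kind == "tunnel_moderate_exac" for st in STATES])
TUNNEL_SEV_MASK = np.array([st.kind == "tunnel_severe_exac" for st in STATES])
SEVERITY_OF = [st.severity for st in STATES]


def chronic_index(severity: str, history: str) -> int:
    return STATE_INDEX[HealthState("chronic", severity=severity, history=history)]


def tunnel_index(severity: str, exac_type: str) -> int:
    return STATE_INDEX[HealthState(f"tunnel_{exac_type}", severity=severity)]


@dataclass
class TransitionMatrix:
    entries: np.ndarray  # (16, 16) row-stochastic
    cycle: int
    arm: str

    def __post_init__(self) -> None:
        sums = self.entries.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-12):
            bad = int(np.argmax(np.abs(sums - 1.0)))
            raise ParameterError(
                f"row {STATE_LABELS[bad]} sums to {sums[bad]!r} at cycle {self.cycle}"
            )


def initial_cohort(ps: ParameterSet) -> np.ndarray:
    """Occupancy at model start: the baseline severity mix, all in the
    no-exacerbation-history chronic states."""
    occ = np.zeros(N_STATES)
    for s in SEVERITIES:
        occ[chronic_index(s, "none")] = ps.baseline_distribution[s]
    return occ


def build_transition_matrix(
    ps: ParameterSet, arm: str, cycle: int, death_probs: np.ndarray
) -> TransitionMatrix:
    """Build the row-stochastic matrix for one arm and cycle.

    ``death_probs`` is the per-state monthly death probability (entry for the
    death state is ignored). Within each chronic row the event cascade is
    death -> severe exacerbation -> moderate exacerbation -> progression;
    tunnel rows resolve death then exit to the severity-matched chronic state
    with the history implied by the exacerbation type.
    """
    death_probs = np.asarray(death_probs, dtype=float)
    if np.any((death_probs[ALIVE_MASK] < 0) | (death_probs[ALIVE_MASK] > 1)):
        raise ParameterError(f"death probabilities outside [0, 1] at cycle {cycle}")

    P = np.zeros((N_STATES, N_STATES))
    for i, st in enumerate(STATES):
        if st.kind == "death":
            P[i, DEATH] = 1.0
            continue
        q = death_probs[i]
        P[i, DEATH] = q
        survive = 1.0 - q
        if st.kind == "chronic":
            p_mod, p_sev = ps.exacerbation_probs.monthly(st.severity, st.history, arm)
            if p_mod + p_sev > 1.0:
                raise ParameterError(
                    f"row {st.label()} cycle {cycle}: exacerbation probabilities "
                    f"moderate={p_mod} + severe={p_sev} exceed 1"
                )
            P[i, tunnel_index(st.severity, "severe_exac")] += survive * p_sev
            P[i, tunnel_index(st.severity, "moderate_exac")] += survive * p_mod
            no_exac = survive * (1.0 - p_mod - p_sev)
            nxt = _NEXT_SEVERITY.get(st.severity)
            if nxt is not None:
                prog = ps.transition_probs.monthly(st.history, cycle, arm)
                p_prog = (
                    prog.mod_to_sev if st.severity == "moderate" else prog.sev_to_vsev
                )
                P[i, chronic_index(nxt, st.history)] += no_exac * p_prog
                P[i, i] += no_exac * (1.0 - p_prog)
            else:
                P[i, i] += no_exac
        else:  # tunnel: one-cycle residence, exit with updated history
            exac = st.kind.removeprefix("tunnel_")
            P[i, chronic_index(st.severity, _EXIT_HISTORY[exac])] += survive
    return TransitionMatrix(entries=P, cycle=cycle, arm=arm)
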