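"""Synchronous Boolean network engine with node clamping.

Models the dFOXO-AOP-PNT-lifespan circuit: nodes take values 0/1
(inactive/short life, active/long life), all ruled nodes update
simultaneously from the previous state, clamped nodes are pinned to a
constant (modelling constitutive over-expression), and free nodes — nodes
with neither rule nor clamp, like dFOXO itself — hold their initial value.
The probability that the target node ("lifespan") is active after a long
run of state transitions is computed either exactly, by enumerating every
initial state of the unclamped nodes, or by Monte-Carlo sampling of initial
states.

Two built-in wirings are compared: a linear cascade
(dFOXO -> AOP -| PNT -| lifespan) and a feed-forward loop in which dFOXO
also feeds a NAND gate with PNT on lifespan, so that only the *combined*
activity of dFOXO and PNT is detrimental.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genomics_core import ValidationError

__all__ = [
    "Rule",
    "BooleanNetwork",
    "SimulationResult",
    "parse_network",
    "build_feedforward_model",
    "build_linear_model",
    "synchronous_step",
    "simulate_probability",
    "compare_models",
    "SCENARIOS",
]


@dataclass(frozen=True)
class Rule:
    """An update rule: named inputs and a Boolean function over them."""

    inputs: tuple[str, ...]
    fn: Callable[..., int]
    expr: str = ""

    def __call__(self, state: Mapping[str, int]) -> int:
        return int(bool(self.fn(*(state[i] for i in self.inputs))))


@dataclass
class BooleanNetwork:
    """Named binary nodes with truth-table update rules and a clamp set.

    Nodes without a rule are "free": unless clamped they keep whatever value
    they were initialised with.  Clamps always override rules.
    """

    nodes: tuple[str, ...]
    rules: dict[str, Rule]
    clamps: dict[str, int] = field(default_factory=dict)
    target: str = "lifespan"

    def __post_init__(self):
        self.nodes = tuple(self.nodes)
        if len(set(self.nodes)) != len(self.nodes):
            raise ValidationError("duplicate node names")
        for node, rule in self.rules.items():
            if node not in self.nodes:
                raise ValidationError(f"rule for unknown node {node!r}")
            for inp in rule.inputs:
                if inp not in self.nodes:
                    raise ValidationError(f"rule for {node!r} uses unknown input {inp!r}")
        for node, v in self.clamps.items():
            if node not in self.nodes:
                raise ValidationError(f"clamp on unknown node {node!r}")
            if v not in (0, 1):
                raise ValidationError(f"clamp value must be 0/1, got {v!r}")
        if self.target not in self.nodes:
            raise ValidationError(f"target {self.target!r} is not a node")

    def with_clamps(self, clamps: Mapping[str, int]) -> "BooleanNetwork":
        return BooleanNetwork(self.nodes, dict(self.rules), dict(clamps), self.target)

    @property
    def unclamped(self) -> tuple[str, ...]:
        return tuple(n for n in self.nodes if n not in self.clamps)


@dataclass
class SimulationResult:
    """Probability that the target node is active at the final transition."""

    probability_target_active: float
    mode: str  # "exact" | "monte_carlo"
    n_transitions: int
    n_runs: int | None = None
    seed: int | None = None


# ---------------------------------------------------------------------------
# Rule-text parser: one line per node, ``node <- EXPR`` with
# NOT / AND / OR / NAND, parentheses, node names and 0/1 literals.

_TOKEN = re.compile(r"\s*(\(|\)|[A-Za-z_][A-Za-z0-9_]*|[01])")


def _parse_expr(text: str, line_label: str) -> tuple[tuple[str, ...], Callable[..., int], str]:
    tokens: list[str] = []
    i = 0
    while i < len(text):
        m = _TOKEN.match(text, i)
        if not m:
            raise ValidationError(f"{line_label}: cannot tokenize {text[i:]!r}")
        tokens.append(m.group(1))
        i = m.end()
    pos = 0

    def peek() -> str | None:
        return tokens[pos] if pos < len(tokens) else None

    def take() -> str:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    names: list[str] = []

    def factor():
        tok = peek()
        if tok is None:
            raise ValidationError(f"{line_label}: unexpected end of expression")
        if tok.upper() == "NOT":
            take()
            sub = factor()
            return lambda st: 1 - sub(st)
        if tok == "(":
            take()
            sub = expr()
            if peek() != ")":
                raise ValidationError(f"{line_label}: missing ')'")
            take()
            return sub
        if tok in ("0", "1"):
            take()
            v = int(tok)
            return lambda st: v
        take()
        if tok.upper() in ("AND", "OR", "NAND"):
            raise ValidationError(f"{line_label}: operator {tok} in operand position")
        if tok not in names:
            names.append(tok)
        return lambda st, n=tok: st[n]

    def term():
        left = factor()
        while peek() is not None and peek().upper() in ("AND", "NAND"):
            op = take().upper()
            right = factor()
            if op == "AND":
                left = (lambda a, b: (lambda st: a(st) & b(st)))(left, right)
            else:
                left = (lambda a, b: (lambda st: 1 - (a(st) & b(st))))(left, right)
        return left

    def expr():
        left = term()
        while peek() is not None and peek().upper() == "OR":
            take()
            right = term()
            left = (lambda a, b: (lambda st: a(st) | b(st)))(left, right)
        return left

    tree = expr()
    if pos != len(tokens):
        raise ValidationError(f"{line_label}: trailing tokens {tokens[pos:]}")
    inputs = tuple(names)

    def fn(*vals: int) -> int:
        return tree(dict(zip(inputs, vals)))

    return inputs, fn, text.strip()


def parse_network(text: str, target: str = "lifespan") -> BooleanNetwork:
    """Parse a network definition: ``node <- EXPR`` lines, ``#`` comments.

    A bare node name on its own line declares a free node.
    """
    nodes: list[str] = []
    rules: dict[str, Rule] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "<-" in line:
            name, rhs = (s.strip() for s in line.split("<-", 1))
            inputs, fn, expr_text = _parse_expr(rhs, f"line {lineno}")
            rules[name] = Rule(inputs, fn, expr_text)
            if name not in nodes:
                nodes.append(name)
            for inp in inputs:
                if inp not in nodes:
                    nodes.append(inp)
        else:
            if not re.fullmatch(r"[A-Za-z_][A-Za-z0-9_]*", line):
                raise ValidationError(f"line {lineno}: malformed line {raw!r}")
            if line not in nodes:
                nodes.append(line)
    return BooleanNetwork(tuple(nodes), rules, {}, target)


FEEDFORWARD_RULES = """\
dFOXO
AOP <- dFOXO
PNT <- NOT AOP
lifespan <- dFOXO NAND PNT
"""

LINEAR_RULES = """\
dFOXO
AOP <- dFOXO
PNT <- NOT AOP
lifespan <- NOT PNT
"""


def build_feedforward_model() -> BooleanNetwork:
    """The feed-forward circuit: dFOXO activates AOP, AOP represses PNT, and
    lifespan = NAND(dFOXO, PNT) — only joint dFOXO+PNT activity is
    detrimental."""
    return parse_network(FEEDFORWARD_RULES)


def build_linear_model() -> BooleanNetwork:
    """The linear cascade: dFOXO -> AOP -| PNT -| lifespan."""
    return parse_network(LINEAR_RULES)


# ---------------------------------------------------------------------------
# Dynamics


def synchronous_step(net: BooleanNetwork, state: Mapping[str, int]) -> dict[str, int]:
    """One synchronous update: ruled nodes from the previous state, clamped
    nodes pinned, free unclamped nodes unchanged."""
    missing = set(net.nodes) - set(state)
    if missing:
        raise ValidationError(f"state missing nodes: {sorted(missing)}")
    new: dict[str, int] = {}
    for node in net.nodes:
        if node in net.clamps:
            new[node] = net.clamps[node]
        elif node in net.rules:
            new[node] = net.rules[node](state)
        else:
            new[node] = int(state[node])
    return new


def _final_state(net: BooleanNetwork, init: tuple[int, ...], n_transitions: int) -> tuple[int, ...]:
    """State after n_transitions steps, via cycle detection (deterministic map)."""
    seen: dict[tuple[int, ...], int] = {}
    traj: list[tuple[int, ...]] = []
    state = init
    for step in range(n_transitions + 1):
        if state in seen:
            start = seen[state]
            cycle = step - start
            return traj[start + (n_transitions - start) % cycle]
        seen[state] = step
        traj.append(state)
        if step == n_transitions:
            return state
        d = synchronous_step(net, dict(zip(net.nodes, state)))
        state = tuple(d[n] for n in net.nodes)
    return state


def _initial_tuple(net: BooleanNetwork, assignment: Mapping[str, int]) -> tuple[int, ...]:
    return tuple(
        net.clamps.get(n, assignment.get(n, 0)) for n in net.nodes
    )


def simulate_probability(
    net: BooleanNetwork,
    target: str | None = None,
    clamps: Mapping[str, int] | None = None,
    n_transitions: int = 1000,
    mode: str = "exact",
    n_runs: int = 10_000,
    seed: int | None = None,
) -> SimulationResult:
    """P(target = 1 after ``n_transitions`` synchronous updates).

    The initial state is uniform over {0,1}^(unclamped nodes) with clamped
    nodes at their clamp value.  ``mode='exact'`` enumerates every initial
    state; ``mode='monte_carlo'`` samples ``n_runs`` initial states with a
    seeded generator.
    """
    if clamps is not None:
        net = net.with_clamps(clamps)
    target = target if target is not None else net.target
    if target not in net.nodes:
        raise ValidationError(f"target {target!r} is not a node")
    t_idx = net.nodes.index(target)
    free = net.unclamped
    if mode == "exact":
        total = 0
        for bits in itertools.product((0, 1), repeat=len(free)):
            init = _initial_tuple(net, dict(zip(free, bits)))
            total += _final_state(net, init, n_transitions)[t_idx]
        prob = total / (2 ** len(free))
        return SimulationResult(prob, "exact", n_transitions)
    if mode == "monte_carlo":
        if n_runs < 1:
            raise ValidationError("n_runs must be >= 1")
        rng = np.random.default_rng(seed)
        # memoize over the (small) space of initial assignments
        cache: dict[tuple[int, ...], int] = {}
        total = 0
        draws = rng.integers(0, 2, size=(n_runs, len(free)))
        for row in draws:
            init = _initial_tuple(net, dict(zip(free, row.tolist())))
            if init not in cache:
                cache[init] = _final_state(net, init, n_transitions)[t_idx]
            total += cache[init]
        return SimulationResult(total / n_runs, "monte_carlo", n_transitions, n_runs, seed)
    raise ValidationError(f"unknown mode {mode!r}")


SCENARIOS: dict[str, dict[str, int]] = {
    "dFOXO_active": {"dFOXO": 1},
    "PNT_active": {"PNT": 1},
    "both_active": {"dFOXO": 1, "PNT": 1},
}


def compare_models(
    models: Mapping[str, BooleanNetwork],
    scenarios: Mapping[str, Mapping[str, int]] | None = None,
    n_transitions: int = 1000,
) -> pd.DataFrame:
    """Exact P(lifespan = 1) per model x clamping scenario, plus a synergy flag.

    ``synergy`` is true when clamping both factors is strictly worse than the
    worst single clamp — the signature of the feed-forward (NAND) wiring
    that a linear cascade cannot produce.
    """
    if scenarios is None:
        scenarios = SCENARIOS
    rows = []
    for name, net in models.items():
        probs = {
            sc: simulate_probability(net, clamps=clamp, n_transitions=n_transitions).probability_target_active
            for sc, clamp in scenarios.items()
        }
        singles = [p for sc, p in probs.items() if sc != "both_active"]
        synergy = bool(
            "both_active" in probs and singles and probs["both_active"] < min(singles)
        )
        rows.append({"model": name, **probs, "synergy": synergy})
    return pd.DataFrame(rows).set_index("model")
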