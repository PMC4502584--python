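"""Environments: the sensor/actuator channels a grammar executes against.

An environment binds terminal names to effects.  ``emit`` applies an
actuator; ``peek`` tests whether a sensor would match without consuming;
``read`` matches and consumes.  Sensors named ``Symbol`` and ``Weight``
are *class* sensors (used by the root grammar): ``Weight`` matches any
dotted-decimal token such as ``0.5``, ``Symbol`` matches every other
token — the two classes are disjoint by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol

from .errors import EnvironmentError_

__all__ = [
    "Environment",
    "RecorderEnvironment",
    "TokenStreamEnvironment",
    "TapeState",
    "TapeEnvironment",
    "is_weight_token",
    "token_matches",
]


def is_weight_token(token: str) -> bool:
    """A weight token is a decimal with a dot (``0.5``, ``1.0``, ``.3``)."""
    if "." not in token:
        return False
    try:
        float(token)
    except ValueError:
        return False
    return True


def token_matches(sensor: str, token: str) -> bool:
    """Default sensor/token matcher, including the class sensors."""
    if sensor == "Weight":
        return is_weight_token(token)
    if sensor == "Symbol":
        return not is_weight_token(token)
    return sensor == token


class Environment(Protocol):
    """Contract for pluggable environments."""

    def peek(self, sensor: str) -> bool:
        """Would ``read(sensor)`` match right now?  Never consumes."""
        ...

    def read(self, sensor: str) -> bool:
        """Match a sensor; consume the input on match.  Side-effect-free
        on no-match."""
        ...

    def emit(self, actuator: str) -> None:
        """Apply an actuator.  Never fails on a valid actuator."""
        ...

    def snapshot(self) -> object:
        """Opaque state for logging/inspection."""
        ...


@dataclass
class RecorderEnvironment:
    """Pure-production environment: records emissions, matches no sensor."""

    events: list[str] = field(default_factory=list)

    def peek(self, sensor: str) -> bool:
        return False

    def read(self, sensor: str) -> bool:
        return False

    def emit(self, actuator: str) -> None:
        self.events.append(actuator)

    def snapshot(self):
        return tuple(self.events)


@dataclass
class TokenStreamEnvironment:
    """A finite stream of input tokens (one sensor event each) plus a
    recorder for emissions."""

    tokens: list[str]
    position: int = 0
    emitted: list[str] = field(default_factory=list)

    def peek(self, sensor: str) -> bool:
        return self.position < len(self.tokens) and token_matches(
            sensor, self.tokens[self.position]
        )

    def read(self, sensor: str) -> bool:
        if self.peek(sensor):
            self.position += 1
            return True
        return False

    def emit(self, actuator: str) -> None:
        self.emitted.append(actuator)

    @property
    def exhausted(self) -> bool:
        return self.position >= len(self.tokens)

    def snapshot(self):
        return (self.position, tuple(self.emitted))


# ---------------------------------------------------------------------------
# Turing tape
# ---------------------------------------------------------------------------

#: actuator name -> tape symbol written (E erases)
_PRINT_OPS = {"Pe": "e", "P0": "0", "P1": "1", "Px": "x"}
_TAPE_SYMBOLS = {"0", "1", "e", "x"}


@dataclass
class TapeState:
    """A bidirectional tape, sparse over blank cells, with a head position.

    Cells holding binary digits are the *figures* of the computed sequence;
    marker cells (``e``, ``x``) are scaffolding.
    """

    cells: dict[int, str] = field(default_factory=dict)
    head: int = 0

    def current(self) -> str | None:
        return self.cells.get(self.head)

    def figures(self) -> str:
        """Binary figures in increasing tape-position order."""
        return "".join(
            sym for _, sym in sorted(self.cells.items()) if sym in ("0", "1")
        )

    def figure_count(self) -> int:
        return sum(1 for sym in self.cells.values() if sym in ("0", "1"))

    def copy(self) -> "TapeState":
        return TapeState(cells=dict(self.cells), head=self.head)


def read_figures(tape: TapeState, n: int) -> str:
    """First ``n`` binary figures of the tape in position order."""
    if n < 0:
        raise ValueError("n must be >= 0")
    figs = tape.figures()
    if len(figs) < n:
        raise EnvironmentError_(f"tape holds {len(figs)} figures, {n} requested")
    return figs[:n]


@dataclass
class TapeEnvironment:
    """Turing-machine environment.

    Actuators: ``Pe``/``P0``/``P1``/``Px`` overwrite the scanned cell,
    ``R``/``L`` move the head, ``E`` blanks the cell.  Sensors ``0``, ``1``,
    ``x``, ``e`` match the scanned symbol and ``None`` matches a blank;
    tape reads are non-destructive, so ``read`` and ``peek`` coincide.
    ``log`` keeps the actuator history for step-for-step comparison with an
    independent machine.
    """

    tape: TapeState = field(default_factory=TapeState)
    log: list[str] = field(default_factory=list)

    def peek(self, sensor: str) -> bool:
        current = self.tape.current()
        if sensor == "None":
            return current is None
        if sensor in _TAPE_SYMBOLS:
            return current == sensor
        return False

    def read(self, sensor: str) -> bool:
        return self.peek(sensor)

    def emit(self, actuator: str) -> None:
        if actuator in _PRINT_OPS:
            self.tape.cells[self.tape.head] = _PRINT_OPS[actuator]
        elif actuator == "R":
            self.tape.head += 1
        elif actuator == "L":
            self.tape.head -= 1
        elif actuator == "E":
            self.tape.cells.pop(self.tape.head, None)
        else:
            raise EnvironmentError_(f"unknown tape actuator {actuator!r}")
        self.log.append(actuator)

    def snapshot(self):
        return (self.tape.head, tuple(sorted(self.tape.cells.items())))
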