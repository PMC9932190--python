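"""Minimal core-functional-dataflow (CFDF) runtime.

Actors execute in discrete firings.  Each actor owns a set of *modes*; a
mode has a fixed, declared token production/consumption rate on every
incident port (the *dataflow table*), and every firing executes exactly one
mode and then names the mode of the next firing.  Edges are unbounded FIFO
token queues.

The runtime enforces the dataflow contract: a firing that moves a different
number of tokens than its table row declares raises
:class:`DataflowContractError`.  A simple sweep scheduler ("fire any
fireable actor until the sink terminates") drives the single optimization
loop this package builds; block firings of the evaluation actor may be
spread over a thread pool, with results re-inserted in candidate order so
the schedule stays deterministic.
"""

from __future__ import annotations

import threading
from collections import deque
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from typing import Any, Callable, Iterable, Mapping, Sequence

__all__ = [
    "Token",
    "Edge",
    "CfdfActor",
    "Graph",
    "DataflowContractError",
    "SchedulingError",
    "threaded_block_fire",
]


class DataflowContractError(RuntimeError):
    """A firing moved tokens inconsistently with the dataflow table."""


class SchedulingError(RuntimeError):
    """No actor is fireable but the graph has not terminated."""


@dataclass
class Token:
    """One unit of data on an edge (candidate vector, evaluation pair,
    fitness record, ...)."""

    payload: Any


class Edge:
    """FIFO token queue between an output port and an input port."""

    def __init__(self, source: tuple[str, str], sink: tuple[str, str]):
        self.source = source  # (actor name, port name)
        self.sink = sink
        self.queue: deque[Token] = deque()
        self.total_produced = 0
        self.total_consumed = 0

    def produce(self, tokens: Iterable[Token]) -> None:
        for t in tokens:
            self.queue.append(t)
            self.total_produced += 1

    def consume(self, count: int) -> list[Token]:
        if len(self.queue) < count:
            raise DataflowContractError(
                f"edge {self.source}->{self.sink}: consume {count} "
                f"requested, {len(self.queue)} queued"
            )
        out = [self.queue.popleft() for _ in range(count)]
        self.total_consumed += count
        return out

    def __len__(self) -> int:
        return len(self.queue)


class CfdfActor:
    """Base class for CFDF actors.

    Subclasses declare ``table`` — ``{mode: {port: signed rate}}`` with
    negative rates on input ports and positive on output ports, mirroring
    the printed dataflow-table convention — and implement one method per
    mode named ``mode_<name>`` (dashes become underscores).  A mode method
    receives ``{port: [payload, ...]}`` for its consumed tokens and returns
    ``(outputs, next_mode)`` where ``outputs`` maps output ports to payload
    lists.
    """

    name: str = "actor"

    def __init__(self, name: str, table: Mapping[str, Mapping[str, int]],
                 initial_mode: str):
        self.name = name
        self.table = {m: dict(ports) for m, ports in table.items()}
        if initial_mode not in self.table:
            raise DataflowContractError(
                f"{name}: initial mode {initial_mode!r} not in dataflow table"
            )
        self.mode = initial_mode
        self.terminated = False
        self.firings = 0
        self.mode_history: list[str] = []

    # -- dataflow-table views -------------------------------------------------
    @property
    def modes(self) -> tuple[str, ...]:
        return tuple(self.table)

    def consumption(self, mode: str) -> dict[str, int]:
        return {p: -r for p, r in self.table[mode].items() if r < 0}

    def production(self, mode: str) -> dict[str, int]:
        return {p: r for p, r in self.table[mode].items() if r > 0}

    # -- firing ---------------------------------------------------------------
    def invoke(self, mode: str, consumed: dict[str, list]) -> tuple[dict, str]:
        fn = getattr(self, "mode_" + mode.replace("-", "_"), None)
        if fn is None:
            raise DataflowContractError(
                f"{self.name}: no implementation for mode {mode!r}"
            )
        return fn(consumed)


class Graph:
    """A CFDF graph: actors plus FIFO edges, with a sweep scheduler."""

    def __init__(self, actors: Sequence[CfdfActor], edges: Sequence[Edge],
                 log: Callable[[str], None] | None = None):
        self.actors = {a.name: a for a in actors}
        self.edges = list(edges)
        self.log = log
        self._in: dict[str, dict[str, Edge]] = {a: {} for a in self.actors}
        self._out: dict[str, dict[str, Edge]] = {a: {} for a in self.actors}
        for e in self.edges:
            src, sport = e.source
            snk, kport = e.sink
            self._out[src][sport] = e
            self._in[snk][kport] = e

    def input_edges(self, actor: CfdfActor) -> dict[str, Edge]:
        return self._in[actor.name]

    def output_edges(self, actor: CfdfActor) -> dict[str, Edge]:
        return self._out[actor.name]

    def can_fire(self, actor: CfdfActor) -> bool:
        """True iff every input edge holds at least the current mode's
        declared consumption."""
        if actor.mode not in actor.table:
            raise DataflowContractError(
                f"{actor.name}: mode {actor.mode!r} missing from table"
            )
        if actor.terminated:
            return False
        need = actor.consumption(actor.mode)
        ins = self._in[actor.name]
        for port, count in need.items():
            if port not in ins:
                raise DataflowContractError(
                    f"{actor.name}: no edge bound to input port {port!r}"
                )
            if len(ins[port]) < count:
                return False
        return True

    def fire(self, actor: CfdfActor) -> str:
        """Execute one firing of ``actor`` in its current mode, enforcing
        the declared token motion; returns the next mode."""
        mode = actor.mode
        need = actor.consumption(mode)
        consumed = {
            port: [t.payload for t in self._in[actor.name][port].consume(cnt)]
            for port, cnt in need.items()
        }
        outputs, next_mode = actor.invoke(mode, consumed)
        self._emit(actor, mode, outputs)
        if next_mode not in actor.table:
            raise DataflowContractError(
                f"{actor.name}: firing of {mode!r} transitioned to unknown "
                f"mode {next_mode!r}"
            )
        actor.mode = next_mode
        actor.firings += 1
        actor.mode_history.append(mode)
        if self.log is not None:
            n_in = sum(need.values())
            n_out = sum(len(v) for v in (outputs or {}).values())
            self.log(f"{actor.name}\t{mode}\t{n_in}\t{n_out}")
        return next_mode

    def _emit(self, actor: CfdfActor, mode: str, outputs: dict | None) -> None:
        outputs = outputs or {}
        declared = actor.production(mode)
        for port, cnt in declared.items():
            payloads = outputs.get(port, [])
            if len(payloads) != cnt:
                raise DataflowContractError(
                    f"{actor.name}/{mode}: declared {cnt} tokens on port "
                    f"{port!r}, produced {len(payloads)}"
                )
            if port not in self._out[actor.name]:
                raise DataflowContractError(
                    f"{actor.name}: no edge bound to output port {port!r}"
                )
            self._out[actor.name][port].produce(Token(p) for p in payloads)
        for port in outputs:
            if port not in declared and outputs[port]:
                raise DataflowContractError(
                    f"{actor.name}/{mode}: produced tokens on undeclared "
                    f"port {port!r}"
                )

    def fire_block(self, actor: CfdfActor) -> int:
        """Fire a block-capable single-port actor once per queued token,
        spreading the firings over the actor's thread pool.  Token motion
        and logging are identical to the equivalent sequential firings;
        results are re-inserted in candidate order.  Returns the number of
        firings executed."""
        (edge_in,) = self._in[actor.name].values()
        (edge_out,) = self._out[actor.name].values()
        payloads = [t.payload for t in edge_in.queue]
        results = threaded_block_fire(
            actor.block_evaluate, payloads, getattr(actor, "n_threads", 1)
        )
        mode = actor.mode
        for res in results:
            edge_in.consume(1)
            edge_out.produce([Token(res)])
            actor.firings += 1
            actor.mode_history.append(mode)
            if self.log is not None:
                self.log(f"{actor.name}\t{mode}\t1\t1")
        return len(results)

    def run(self, terminated: Callable[[], bool],
            max_firings: int = 10_000_000) -> None:
        """Sweep scheduler: repeatedly fire any fireable actor until the
        termination predicate holds.  Deadlock raises SchedulingError with
        a queue/mode dump."""
        order = list(self.actors.values())
        fired_total = 0
        while not terminated():
            fired = False
            for actor in order:
                blocky = (
                    getattr(actor, "supports_block", False)
                    and getattr(actor, "n_threads", 1) > 1
                )
                while self.can_fire(actor):
                    if blocky:
                        fired_total += self.fire_block(actor)
                        fired = True
                        if terminated():
                            return
                        continue
                    self.fire(actor)
                    fired = True
                    fired_total += 1
                    if fired_total > max_firings:
                        raise SchedulingError("firing budget exceeded")
                    if terminated():
                        return
            if not fired:
                raise SchedulingError(
                    "deadlock: no actor fireable\n" + self.describe()
                )

    def describe(self) -> str:
        lines = [
            f"  actor {a.name}: mode={a.mode} firings={a.firings}"
            for a in self.actors.values()
        ]
        lines += [
            f"  edge {e.source}->{e.sink}: queued={len(e)} "
            f"produced={e.total_produced} consumed={e.total_consumed}"
            for e in self.edges
        ]
        return "\n".join(lines)

    def check_conservation(self) -> None:
        for e in self.edges:
            if e.total_produced != e.total_consumed + len(e):
                raise DataflowContractError(
                    f"token conservation violated on {e.source}->{e.sink}"
                )


def threaded_block_fire(
    evaluate: Callable[[Any], Any],
    payloads: Sequence[Any],
    n_threads: int,
) -> list[Any]:
    """Evaluate a block of candidate payloads, ``n_threads`` at a time.

    Firings are spread over a thread pool in waves; the result list is in
    candidate order, so for a deterministic evaluation function the outcome
    is identical to a sequential loop regardless of ``n_threads``.  Worker
    exceptions propagate annotated with the candidate index.
    """
    if n_threads < 1:
        raise ValueError("n_threads must be >= 1")
    if n_threads == 1 or len(payloads) <= 1:
        return [evaluate(p) for p in payloads]
    results: list[Any] = [None] * len(payloads)
    with ThreadPoolExecutor(max_workers=n_threads) as pool:
        futures = {pool.submit(evaluate, p): i for i, p in enumerate(payloads)}
        for fut, i in futures.items():
            try:
                results[i] = fut.result()
            except Exception as exc:  # annotate with candidate index
                raise RuntimeError(f"evaluation of candidate {i} failed") from exc
    return results
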