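"""Mixed-workload benchmark harness with sliding-window throughput reporting.

Reproduces the stress-test methodology used to characterise the service:
worker threads issue requests drawn i.i.d. from a configurable mix of create/
read/update/delete operations (plus a no-op ping baseline) against the
in-process service, as fast as they can, for a fixed duration.  Throughput is
counted in transactions per second, where a transaction is a *successful*
request; the series is reported both per second and as sliding-window means.

Absolute TPS numbers depend entirely on the host; the harness is also a
concurrency stress test — persistence invariants must hold after any run.
"""

from __future__ import annotations

import random
import threading
import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .errors import EmptySeriesError, ValidationError
from .service import Principal, Request, Service


@dataclass(frozen=True)
class WorkloadMix:
    """Operation proportions; must sum to 1."""

    create_frac: float
    read_frac: float
    update_frac: float
    delete_frac: float
    ping_frac: float = 0.0

    def __post_init__(self):
        total = (self.create_frac + self.read_frac + self.update_frac
                 + self.delete_frac + self.ping_frac)
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"mix fractions sum to {total}, expected 1")

    def draw(self, rng: random.Random) -> str:
        x = rng.random()
        for op, frac in (("create", self.create_frac), ("read", self.read_frac),
                         ("update", self.update_frac),
                         ("delete", self.delete_frac)):
            if x < frac:
                return op
            x -= frac
        return "ping"


#: The standard scenarios: read-heavy, write-heavy, balanced, and a no-op
#: baseline that never touches storage.
PRESETS: Dict[str, WorkloadMix] = {
    "mostly_read": WorkloadMix(0.23, 0.75, 0.01, 0.01),
    "mostly_write": WorkloadMix(0.75, 0.23, 0.01, 0.01),
    "read_write": WorkloadMix(0.49, 0.49, 0.01, 0.01),
    "ping": WorkloadMix(0.0, 0.0, 0.0, 0.0, 1.0),
}


@dataclass
class ThroughputSeries:
    """Per-second successful-transaction counts plus windowed means."""

    per_second: List[int]
    window: int = 60

    def windowed(self) -> List[float]:
        if not self.per_second:
            return []
        w = min(self.window, len(self.per_second))
        arr = np.asarray(self.per_second, dtype=float)
        kernel = np.ones(w) / w
        return list(np.convolve(arr, kernel, mode="valid"))


@dataclass
class OperationLedger:
    """Outcome bookkeeping for one scenario run."""

    counts: Dict[str, int] = field(default_factory=dict)
    successes: Dict[str, int] = field(default_factory=dict)
    failures: Dict[str, int] = field(default_factory=dict)

    def record(self, op: str, ok: bool) -> None:
        self.counts[op] = self.counts.get(op, 0) + 1
        bucket = self.successes if ok else self.failures
        bucket[op] = bucket.get(op, 0) + 1

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def summarize(series: ThroughputSeries) -> Tuple[float, float]:
    """Mean and (sample) standard deviation over the windowed TPS values."""
    values = series.windowed()
    if not values:
        raise EmptySeriesError("throughput series is empty")
    arr = np.asarray(values)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return float(arr.mean()), sd


def run_scenario(service: Service, mix: WorkloadMix, duration: float,
                 concurrency: int, principal: Principal, domain: str,
                 seed: int = 0, window: int = 60
                 ) -> Tuple[ThroughputSeries, OperationLedger]:
    """Stress the service with an i.i.d. operation mix for ``duration`` seconds.

    Read/update/delete operations target pseudonyms sampled uniformly from
    the client-side pool of currently live pseudonyms; deletes are permanent
    (a later read of a deleted key fails and is excluded from TPS, since
    only successful requests count).
    """
    if duration <= 0:
        raise ValidationError("duration must be positive")
    live: List[str] = []
    live_lock = threading.Lock()
    events: List[Tuple[float, bool]] = []
    events_lock = threading.Lock()
    ledger = OperationLedger()
    ledger_lock = threading.Lock()
    counter = [0]
    start = time.monotonic()
    deadline = start + duration

    def pick_live(rng: random.Random) -> Optional[str]:
        with live_lock:
            return rng.choice(live) if live else None

    def worker(worker_id: int) -> None:
        rng = random.Random((seed << 8) ^ worker_id)
        while time.monotonic() < deadline:
            op = mix.draw(rng)
            ok = _issue(op, rng)
            now = time.monotonic()
            with events_lock:
                events.append((now - start, ok))
            with ledger_lock:
                ledger.record(op, ok)

    def _issue(op: str, rng: random.Random) -> bool:
        if op == "ping":
            return service.handle(Request("GET", "/ping")).ok
        if op == "create":
            with live_lock:
                counter[0] += 1
                ident = f"subject-{counter[0]}"
            resp = service.handle(
                Request("POST", f"/domains/{domain}/pseudonym",
                        {"identifier": ident}), principal)
            if resp.ok:
                with live_lock:
                    live.append(resp.body["pseudonym"])
            return resp.ok
        target = pick_live(rng)
        if target is None:
            return False
        if op == "read":
            return service.handle(
                Request("GET", f"/domains/{domain}/pseudonym",
                        {"key": target,
                         "direction": "pseudonym->identifier"}),
                principal).ok
        if op == "update":
            return service.handle(
                Request("PUT", f"/domains/{domain}/pseudonym",
                        {"pseudonym": target, "changes": {}}), principal).ok
        # delete: permanent; drop from the live pool on success
        resp = service.handle(
            Request("DELETE", f"/domains/{domain}/pseudonym",
                    {"pseudonym": target}), principal)
        if resp.ok:
            with live_lock:
                if target in live:
                    live.remove(target)
        return resp.ok

    threads = [threading.Thread(target=worker, args=(i,))
               for i in range(concurrency)]
    for t in threads:
        t.start()
    for t in threads:
        t.join()

    seconds = max(1, int(np.ceil(duration)))
    per_second = [0] * seconds
    for t_rel, ok in events:
        if ok:
            per_second[min(int(t_rel), seconds - 1)] += 1
    return ThroughputSeries(per_second, window=window), ledger


__all__ = ["WorkloadMix", "PRESETS", "ThroughputSeries", "OperationLedger",
           "run_scenario", "summarize"]
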