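"""Master-worker parallel enumeration with dynamic load balancing.

One master process (the caller) plus ``n_workers`` worker processes share
the refinement stack. The master seeds its stack with the completely
unrefined root state; workers start empty and ask for work. Two worker
messages exist: *need_work* (the worker is idle) and *share_states* (the
worker's stack grew past a configurable threshold and it sheds the oldest
— shallowest, hence work-richest — half back to the master for
redistribution). The master answers need_work with *grant_state* (exactly
one state) or *terminate*. Because state refinements are independent, a
shared stack yields a complete, non-duplicating exploration, and the
merged output equals the serial enumeration.

Every worker recomputes the fill tables locally from the run parameters,
which keeps states the only payload on the message channel. Completed
structures go to per-worker spill files merged (and optionally sorted) at
the end; a worker failure aborts the whole run rather than returning
silent partial results.

Transport is process-based message passing over pipes; the message
contract is backend-agnostic so a cluster transport could reuse the
enumeration code unchanged.
"""

from __future__ import annotations

import json
import tempfile
import traceback
from collections import deque
from dataclasses import dataclass, field
from multiprocessing import Pipe, Process
from multiprocessing.connection import wait
from pathlib import Path

from .constraints import ConstraintSet
from .energies import INF, EnergyParameters, load_parameters
from .errors import ValidationError
from .fold import fill_matrices
from .options import FoldOptions
from .structure import SecondaryStructure, normalize_sequence
from .subopt import PartialState, refine_state, root_state


@dataclass
class WorkMessage:
    """One message on the master-worker channel."""

    kind: str  # need_work | share_states | grant_state | terminate | error
    payload: list[bytes] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind == "share_states" and not self.payload:
            raise ValidationError("share_states payload must be non-empty")
        if self.kind == "grant_state" and len(self.payload) != 1:
            raise ValidationError("grant_state payload holds exactly one state")


@dataclass
class RunConfig:
    """Parallel run shape: worker count and the stack-sharing threshold."""

    n_workers: int = 2
    share_threshold: int = 64

    def __post_init__(self) -> None:
        if self.n_workers < 1:
            raise ValidationError("n_workers must be >= 1")
        if self.share_threshold < 1:
            raise ValidationError("share_threshold must be >= 1")


# ---------------------------------------------------------------------------
# state serialization (round-trip exact, including energies and cursor)


def state_serialize(s: PartialState) -> bytes:
    doc = {
        "sigma": [[i, j, k] for i, j, k in s.sigma],
        "pairs": sorted(s.pairs),
        "dg_p": s.dg_p,
        "dg_sigma": s.dg_sigma,
        "resume_cursor": s.resume_cursor,
    }
    return json.dumps(doc, separators=(",", ":")).encode()


def state_deserialize(data: bytes) -> PartialState:
    try:
        doc = json.loads(data.decode())
        return PartialState(
            sigma=tuple((int(i), int(j), str(k)) for i, j, k in doc["sigma"]),
            pairs=frozenset((int(i), int(j)) for i, j in doc["pairs"]),
            dg_p=int(doc["dg_p"]),
            dg_sigma=int(doc["dg_sigma"]),
            resume_cursor=doc["resume_cursor"],
        )
    except (ValueError, KeyError, TypeError, UnicodeDecodeError) as exc:
        raise ValidationError(f"corrupt state payload: {exc}") from exc


# ---------------------------------------------------------------------------
# worker


def _passes_filters(pairs, opts: FoldOptions, n: int) -> bool:
    if opts.helix_filter is None:
        return True
    from .filters import helix_filter_pass

    return helix_filter_pass(SecondaryStructure(n=n, pairs=pairs), opts.helix_filter)


def _spill_leaf(fh, s: PartialState, opts: FoldOptions, n: int) -> None:
    if _passes_filters(s.pairs, opts, n):
        st = SecondaryStructure(n=n, pairs=s.pairs)
        fh.write(f"{st.to_dotbracket()}\t{s.dg_p}\n")


def _worker_main(conn, spill_path, seq, cs, opts, params, config) -> None:
    try:
        m = fill_matrices(seq, params, cs, opts)
        threshold = None
        if opts.window is not None:
            threshold = m.mfe_deci + round(opts.window * 10)
        stack: list[PartialState] = []
        processed = 0
        with open(spill_path, "w") as fh:
            while True:
                if not stack:
                    conn.send(WorkMessage("need_work"))
                    msg = conn.recv()
                    if msg.kind == "terminate":
                        break
                    stack.append(state_deserialize(msg.payload[0]))
                    continue
                s = stack.pop()
                if s.is_leaf:
                    _spill_leaf(fh, s, opts, m.n)
                    continue
                processed += 1
                stack.extend(refine_state(s, m, seq, cs, opts, params, threshold))
                if len(stack) > config.share_threshold:
                    k = len(stack) // 2
                    excess, stack = stack[:k], stack[k:]
                    conn.send(
                        WorkMessage("share_states", [state_serialize(x) for x in excess])
                    )
            fh.write(f"# processed {processed}\n")
    except Exception:  # noqa: BLE001 - forwarded to the master for abort
        conn.send(WorkMessage("error", [traceback.format_exc().encode()]))
        raise


# ---------------------------------------------------------------------------
# master


def run_parallel(
    seq: str,
    cs: ConstraintSet | None = None,
    opts: FoldOptions | None = None,
    params: EnergyParameters | None = None,
    config: RunConfig | None = None,
    run_dir: str | Path | None = None,
    stats: dict | None = None,
) -> list[SecondaryStructure]:
    """Enumerate in parallel; the merged result equals the serial run.

    ``stats``, when given, receives ``states_processed`` (summed over the
    master and all workers: each state is refined exactly once somewhere)
    and ``states_granted``/``states_shared`` message counters.
    """
    seq = normalize_sequence(seq)
    n = len(seq)
    cs = cs if cs is not None else ConstraintSet.empty(n)
    opts = opts if opts is not None else FoldOptions()
    params = params if params is not None else load_parameters("default")
    config = config if config is not None else RunConfig()

    m = fill_matrices(seq, params, cs, opts)
    threshold = None
    if opts.window is not None:
        if m.mfe_deci >= INF:
            return []
        threshold = m.mfe_deci + round(opts.window * 10)

    tmp = None
    if run_dir is None:
        tmp = tempfile.TemporaryDirectory(prefix="subfold-run-")
        run_dir = tmp.name
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)

    conns, workers, spills = [], [], []
    try:
        for w in range(config.n_workers):
            master_conn, worker_conn = Pipe(duplex=True)
            spill = run_dir / f"worker-{w}.subopt"
            proc = Process(
                target=_worker_main,
                args=(worker_conn, spill, seq, cs, opts, params, config),
                daemon=True,
            )
            proc.start()
            worker_conn.close()
            conns.append(master_conn)
            workers.append(proc)
            spills.append(spill)

        master_spill = run_dir / "master.subopt"
        stack: deque[PartialState] = deque()
        root = root_state(m)
        if root.dg_sigma < INF:
            stack.append(root)
        idle: set[int] = set()
        granted = shared = master_processed = 0

        with open(master_spill, "w") as fh:
            while True:
                while idle and stack:
                    w = idle.pop()
                    conns[w].send(
                        WorkMessage("grant_state", [state_serialize(stack.popleft())])
                    )
                    granted += 1
                if not stack and len(idle) == config.n_workers:
                    for conn in conns:
                        conn.send(WorkMessage("terminate"))
                    break
                ready = wait(conns, timeout=0.02)
                if ready:
                    for conn in ready:
                        wi = conns.index(conn)
                        msg = conn.recv()
                        if msg.kind == "need_work":
                            idle.add(wi)
                        elif msg.kind == "share_states":
                            stack.extend(state_deserialize(b) for b in msg.payload)
                            shared += len(msg.payload)
                        elif msg.kind == "error":
                            raise RuntimeError(
                                f"worker {wi} failed:\n{msg.payload[0].decode()}"
                            )
                        else:  # pragma: no cover
                            raise RuntimeError(f"unexpected message {msg.kind}")
                elif stack:
                    # no worker messages: the master works a state itself
                    s = stack.pop()
                    if s.is_leaf:
                        _spill_leaf(fh, s, opts, m.n)
                    else:
                        master_processed += 1
                        stack.extend(refine_state(s, m, seq, cs, opts, params, threshold))
            fh.write(f"# processed {master_processed}\n")

        for proc in workers:
            proc.join(timeout=60)
            if proc.exitcode != 0:
                raise RuntimeError(f"worker exited with code {proc.exitcode}")

        structures, processed_total = [], master_processed
        for spill in [*spills, master_spill]:
            for line in spill.read_text().splitlines():
                if line.startswith("# processed"):
                    if spill != master_spill:
                        processed_total += int(line.split()[-1])
                    continue
                db, deci = line.split("\t")
                structures.append(
                    SecondaryStructure.from_dotbracket(db, energy=int(deci) / 10.0)
                )
        if stats is not None:
            stats.update(
                states_processed=processed_total,
                states_granted=granted,
                states_shared=shared,
            )
        if opts.sort_output:
            structures.sort(key=lambda st: (round(st.energy * 10), st.to_dotbracket()))
        return structures
    finally:
        for proc in workers:
            if proc.is_alive():
                proc.terminate()
        if tmp is not None:
            tmp.cleanup()
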